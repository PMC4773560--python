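"""Fold-change prediction, the REX/JGG optimizer, and supporting statistics."""

import numpy as np
import pandas as pd
import pytest

from adrenosim.moa import (
    EnzymeActivityProfile,
    FoldChangeProfile,
    MoAConfig,
    cluster_profiles,
    estimate_moa,
    jgg_step,
    moa_objective,
    rex_crossover,
    welch_bonferroni,
)
from adrenosim.species import LCMS_STEROIDS, MOA_ENZYMES


def profile_with(**activities) -> EnzymeActivityProfile:
    base = {e: 1.0 for e in MOA_ENZYMES}
    base.update(activities)
    return EnzymeActivityProfile(base)


class TestDomainTypes:
    def test_activity_bounds_enforced(self):
        with pytest.raises(ValueError):
            EnzymeActivityProfile(np.full(8, 1000.0))
        with pytest.raises(ValueError):
            EnzymeActivityProfile(np.full(8, 1e-4))

    def test_activity_dimension_is_eight(self):
        assert len(MOA_ENZYMES) == 8
        assert "CYP19A1" not in MOA_ENZYMES
        full = profile_with().full_activities()
        assert full.shape == (9,)
        assert np.all(full == 1.0)

    def test_foldchange_needs_positive_quantified_ratios(self):
        with pytest.raises(ValueError):
            FoldChangeProfile(np.zeros(12))
        flags = np.zeros(12, dtype=bool)
        flags[0] = True
        values = np.ones(12)
        values[0] = -5.0  # censored entries carry no numeric requirement
        FoldChangeProfile(values, flags)

    def test_profile_is_order_independent(self):
        d = {s: 1.0 + i / 10 for i, s in enumerate(LCMS_STEROIDS)}
        shuffled = dict(reversed(list(d.items())))
        assert np.array_equal(FoldChangeProfile(d).values,
                              FoldChangeProfile(shuffled).values)


class TestPredictFoldchange:
    def test_unperturbed_gives_exact_ones(self, baseline_model):
        fc = baseline_model.predict_foldchange(profile_with())
        assert np.all(fc.values == 1.0)

    def test_cyp11b2_inhibition_monotone_in_aldo(self, baseline_model):
        ratios = [baseline_model.predict_foldchange(
            profile_with(CYP11B2=a))["ALDO"] for a in (0.05, 0.3, 0.7)]
        assert all(r < 1.0 for r in ratios)
        assert ratios[0] < ratios[1] < ratios[2]

    def test_hsd3b2_block_accumulates_upstream(self, baseline_model):
        """Strong HSD3B2 inhibition raises the delta-5 precursors and
        depletes the downstream delta-4 steroids."""
        fc = baseline_model.predict_foldchange(profile_with(HSD3B2=0.05))
        assert fc["PREG"] > 1.0
        assert fc["HPREG"] > 1.0
        assert fc["DHEA"] > 1.0
        assert fc["PROG"] < 1.0
        assert fc["CORTICO"] < 1.0


class TestMoaObjective:
    def test_exact_match_is_zero(self):
        obs = FoldChangeProfile(np.linspace(0.5, 2.0, 12))
        assert moa_objective(obs, obs) == 0.0

    def test_hand_value(self):
        # obs=(2, 0.5), sim=(1, 1): (1/2)^2 + (-0.5/0.5)^2 = 1.25
        obs_v = np.ones(12)
        obs_v[0], obs_v[1] = 2.0, 0.5
        sim = np.ones(12)
        flags = np.ones(12, dtype=bool)
        flags[0] = flags[1] = False  # only two quantified steroids
        obs = FoldChangeProfile(obs_v, flags)
        assert moa_objective(obs, sim) == pytest.approx(1.25)

    def test_censoring_removes_exactly_its_term(self):
        obs_v = np.ones(12)
        obs_v[0], obs_v[1] = 2.0, 0.5
        sim = np.ones(12)
        flags = np.zeros(12, dtype=bool)
        flags[1] = True
        obs = FoldChangeProfile(obs_v, flags)
        assert moa_objective(obs, sim) == pytest.approx(0.25)

    def test_raw_ssr_switch(self):
        obs_v = np.ones(12)
        obs_v[0] = 2.0
        obs = FoldChangeProfile(obs_v)
        assert moa_objective(obs, np.ones(12), normalized=False) == \
            pytest.approx(1.0)

    def test_all_censored_rejected(self):
        obs = FoldChangeProfile(np.ones(12), np.ones(12, dtype=bool))
        with pytest.raises(ValueError):
            moa_objective(obs, np.ones(12))


class TestRexCrossover:
    def test_identical_parents_give_identical_children(self, rng):
        point = np.full((6, 8), 0.37)
        children = rex_crossover(point, 25, rng)
        assert children.shape == (25, 8)
        assert np.allclose(children, 0.37)

    def test_children_dimension_matches_parents(self, rng):
        parents = rng.uniform(-1, 1, size=(6, 8))
        assert rex_crossover(parents, 25, rng).shape == (25, 8)

    @pytest.mark.parametrize("distribution", ["uniform", "normal"])
    def test_child_mean_matches_centroid(self, distribution):
        rng = np.random.default_rng(42)
        parents = rng.uniform(-1.5, 1.5, size=(6, 8))
        children = rex_crossover(parents, 10_000, rng,
                                 distribution=distribution)
        centroid = parents.mean(axis=0)
        se = children.std(axis=0, ddof=1) / np.sqrt(children.shape[0])
        assert np.all(np.abs(children.mean(axis=0) - centroid) < 3 * se + 1e-12)

    def test_children_respect_bounds(self):
        rng = np.random.default_rng(0)
        parents = np.array([[-2.0] * 8, [2.0] * 8] * 3)
        children = rex_crossover(parents, 200, rng)
        assert children.min() >= -2.0 and children.max() <= 2.0

    def test_fewer_than_two_parents_rejected(self, rng):
        with pytest.raises(ValueError):
            rex_crossover(np.zeros((1, 8)), 5, rng)


class TestJggStep:
    @staticmethod
    def sphere(X):
        return np.sum(np.asarray(X) ** 2, axis=1)

    def test_population_size_and_nonparents_preserved(self):
        rng = np.random.default_rng(3)
        pop = rng.uniform(-2, 2, size=(100, 8))
        fit = self.sphere(pop)
        cfg = MoAConfig()
        rng2 = np.random.default_rng(3)
        idx = rng2.choice(100, size=cfg.n_parents, replace=False)
        new_pop, new_fit, n_evals = jgg_step(pop, fit, self.sphere, cfg,
                                             np.random.default_rng(3))
        assert new_pop.shape == pop.shape
        assert n_evals == cfg.n_children
        untouched = np.setdiff1d(np.arange(100), idx)
        assert np.array_equal(new_pop[untouched], pop[untouched])

    @pytest.mark.parametrize("seed", range(5))
    def test_sphere_function_convergence(self, seed):
        """Best-so-far objective is monotone and improves substantially."""
        rng = np.random.default_rng(seed)
        pop = rng.uniform(-2, 2, size=(100, 8))
        fit = self.sphere(pop)
        best_history = [fit.min()]
        cfg = MoAConfig()
        for _ in range(200):
            pop, fit, _ = jgg_step(pop, fit, self.sphere, cfg, rng)
            best_history.append(min(best_history[-1], fit.min()))
        assert np.all(np.diff(best_history) <= 0)
        assert best_history[-1] < 0.01 * best_history[0]


class TestEstimateMoa:
    CFG = dict(max_generations=80, population_size=50)

    def test_null_profile_recovers_no_mechanism(self, baseline_model):
        obs = FoldChangeProfile(np.ones(12))
        res = estimate_moa(obs, baseline_model,
                           MoAConfig(seed=11, **self.CFG))
        acts = res.activities.values
        assert np.all((acts > 0.7) & (acts < 1.4))
        assert res.fitness <= moa_objective(
            obs, baseline_model.predict_foldchange(profile_with()))  + 1e-12

    def test_planted_single_enzyme_recovered(self, baseline_model):
        planted = profile_with(CYP11B1=0.1)
        obs = baseline_model.predict_foldchange(planted)
        res = estimate_moa(obs, baseline_model,
                           MoAConfig(seed=5, **self.CFG))
        assert res.activities["CYP11B1"] == pytest.approx(0.1, rel=0.2)
        for e in MOA_ENZYMES:
            if e != "CYP11B1":
                assert 0.7 < res.activities[e] < 1.4

    def test_duplicate_runs_agree_within_twofold(self, baseline_model):
        planted = profile_with(HSD3B2=0.2)
        obs = baseline_model.predict_foldchange(planted)
        res = estimate_moa(obs, baseline_model,
                           MoAConfig(seed=2, duplicate=True,
                                     max_generations=60,
                                     population_size=40))
        assert res.duplicate is not None
        assert res.agreement_with(res.duplicate) <= 2.0

    def test_identifiability_flags_follow_censoring(self, baseline_model):
        values = np.ones(12)
        flags = np.zeros(12, dtype=bool)
        flags[LCMS_STEROIDS.index("ALDO")] = True
        obs = FoldChangeProfile(values, flags)
        res = estimate_moa(obs, baseline_model,
                           MoAConfig(seed=1, max_generations=5,
                                     population_size=20))
        assert res.identifiability["CYP11B2"] is False
        assert res.identifiability["HSD3B2"] is True


class TestWelchBonferroni:
    def test_identical_groups_adjusted_p_is_one(self):
        x = np.array([[1.0, 2.0, 3.0, 4.0]] * 3)
        out = welch_bonferroni(x, x)
        assert np.all(out["p_adjusted"] == 1.0)

    def test_single_species_adjusted_equals_raw(self, rng):
        t = rng.normal(10, 1, size=(1, 4))
        c = rng.normal(0, 1, size=(1, 4))
        out = welch_bonferroni(t, c)
        assert out["p_adjusted"][0] == pytest.approx(out["p_raw"][0])

    def test_tenfold_shift_detected_at_adjusted_001(self, rng):
        """10x shift, N=4, 5% CV: significant after correcting 12 tests."""
        m = 12
        control = 100.0 * (1 + 0.05 * rng.standard_normal((m, 4)))
        treated = control * 0.1 * (1 + 0.05 * rng.standard_normal((m, 4)))
        out = welch_bonferroni(treated, control)
        assert out["significant"].all()

    def test_zero_variance_flagged(self):
        t = np.full((2, 4), 5.0)
        c = np.full((2, 4), 1.0)
        out = welch_bonferroni(t, c)
        assert out["zero_variance"].all()
        assert out["p_raw"].isna().all()

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ValueError):
            welch_bonferroni(np.ones((3, 1)), np.ones((3, 4)))


class TestClusterProfiles:
    def test_duplicate_profiles_merge_first_at_zero_distance(self):
        profiles = pd.DataFrame(
            [[1.0, 2.0, 0.5], [1.0, 2.0, 0.5], [5.0, -1.0, 3.0]],
            index=["a", "a2", "b"])
        res = cluster_profiles(profiles)
        assert res.distance_matrix.loc["a", "a2"] == 0.0
        assert res.linkage[0, 2] == 0.0  # first merge height
        assert set(res.linkage[0, :2].astype(int)) == {0, 1}

    def test_two_planted_groups_separate(self, rng):
        inhib = rng.normal(-3.0, 0.2, size=(4, 12))
        null = rng.normal(0.0, 0.2, size=(4, 12))
        profiles = pd.DataFrame(np.vstack([inhib, null]),
                                index=[f"i{k}" for k in range(4)]
                                + [f"n{k}" for k in range(4)])
        clusters = cluster_profiles(profiles).flat_clusters(2)
        inhib_ids = {clusters[f"i{k}"] for k in range(4)}
        null_ids = {clusters[f"n{k}"] for k in range(4)}
        assert len(inhib_ids) == 1 and len(null_ids) == 1
        assert inhib_ids != null_ids

    def test_three_profile_ward_heights_match_hand_oracle(self):
        """Ward linkage heights recomputed by the Lance-Williams update."""
        X = np.array([[0.0, 0.0], [1.0, 0.0], [4.0, 2.0]])
        profiles = pd.DataFrame(X, index=["p", "q", "r"])
        res = cluster_profiles(profiles)
        # standardized Euclidean by column variances (ddof=1)
        v = X.var(axis=0, ddof=1)
        d = np.zeros((3, 3))
        for i in range(3):
            for j in range(3):
                d[i, j] = np.sqrt((((X[i] - X[j]) ** 2) / v).sum())
        # first merge: closest pair (p, q); Ward height equals their distance
        assert res.linkage[0, 2] == pytest.approx(d[0, 1])
        # second merge height from the Ward/Lance-Williams formula
        d2 = np.sqrt((2 * d[0, 2] ** 2 + 2 * d[1, 2] ** 2 - d[0, 1] ** 2) / 3)
        assert res.linkage[1, 2] == pytest.approx(d2)

    def test_constant_column_gets_floor(self):
        profiles = pd.DataFrame([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]])
        res = cluster_profiles(profiles)
        assert np.all(np.isfinite(res.linkage))

    def test_single_profile_rejected(self):
        with pytest.raises(ValueError):
            cluster_profiles(pd.DataFrame([[1.0, 2.0]]))
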