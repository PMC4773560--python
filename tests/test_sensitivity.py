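"""Dynamic sensitivity oracles, AUC ranking, and phenotype classification."""

import numpy as np
import pytest

from adrenosim.parameters import default_initial_state_vector
from adrenosim.sensitivity import (
    SensitivityMatrix,
    auc_ranking,
    classify_phenotype,
    dynamic_sensitivity,
    scan_2d,
    sensitivity_heatmap,
)
from adrenosim.simulate import simulate
from adrenosim.species import ENZYMES, N_STATE, STEROIDS, cell_index, medium_index
from conftest import make_zero_rate_params


def decay_setup():
    """CORTICO -> ALDO at k=1/h with everything else frozen.

    Closed forms: CORTICO(t) = C0 e^{-akt}, ALDO(t) = C0 (1 - e^{-akt}),
    so the +10% sensitivities are exactly
    S_CORTICO = (e^{-0.1kt} - 1)/0.1 and
    S_ALDO = (e^{-kt} - e^{-1.1kt}) / (0.1 (1 - e^{-kt})).
    """
    p = make_zero_rate_params(k_CYP11B2=1.0)
    y0 = np.zeros(N_STATE)
    y0[cell_index("CORTICO")] = 100.0
    return p, y0


class TestDynamicSensitivity:
    def test_decay_oracle(self):
        p, y0 = decay_setup()
        S = dynamic_sensitivity(p, "k_CYP11B2", times=(0.5, 1.0),
                                compartment="intracellular",
                                initial_state=y0)
        for t in (0.5, 1.0):
            oracle = (np.exp(-0.1 * t) - 1.0) / 0.1
            assert S.loc["CORTICO", t] == pytest.approx(oracle, abs=1e-6)

    def test_product_growth_oracle_and_proportional_limit(self):
        p, y0 = decay_setup()
        S = dynamic_sensitivity(p, "k_CYP11B2", times=(0.01, 0.5, 1.0),
                                compartment="intracellular",
                                initial_state=y0)
        for t in (0.01, 0.5, 1.0):
            oracle = (np.exp(-t) - np.exp(-1.1 * t)) / (0.1 * (1 - np.exp(-t)))
            assert S.loc["ALDO", t] == pytest.approx(oracle, abs=1e-6)
        # for kt -> 0 the product grows linearly in k, so S -> 1 exactly
        assert S.loc["ALDO", 0.01] == pytest.approx(1.0, abs=0.01)

    def test_parameter_without_influence_is_zero(self, params):
        p = params.with_updates({"VmaxB_HSD17B3": 0.0})
        S = dynamic_sensitivity(p, "VmaxB_HSD17B3", times=(6.0, 24.0))
        assert np.all(S.to_numpy() == 0.0)

    def test_zero_baseline_concentration_flagged(self):
        p, y0 = decay_setup()
        S = dynamic_sensitivity(p, "k_CYP11B2", times=(1.0,),
                                compartment="intracellular",
                                initial_state=y0)
        assert np.isnan(S.loc["PREG", 1.0])  # PREG stays at zero


@pytest.fixture(scope="module")
def small_matrix(params):
    names = ("VmaxA_CYP17H", "VmaxA_HSD3B2", "VmaxA_CYP21A2",
             "VmaxA_CYP11B1", "Vmax_CYP11A1", "Km_CYP11A1")
    return sensitivity_heatmap(params, parameters=names)


@pytest.fixture(scope="module")
def coarse_grid(params):
    return scan_2d(params, multipliers=np.array([0.0, 0.5, 1.0, 1.5, 2.0]))


class TestSensitivityHeatmap:

    def test_dimensions(self, params):
        mat = sensitivity_heatmap(params, parameters=("Vmax_CYP11A1",))
        assert mat.values.shape == (1, 14, 12)
        assert tuple(mat.times) == tuple(float(t) for t in range(6, 73, 6))

    def test_product_positive_substrate_negative_at_early_times(
            self, small_matrix):
        pairs = {"VmaxA_CYP17H": ("HPREG", "PREG"),
                 "VmaxA_HSD3B2": ("PROG", "PREG"),
                 "VmaxA_CYP21A2": ("DCORTICO", "PROG"),
                 "VmaxA_CYP11B1": ("CORTICO", "DCORTICO")}
        for par, (product, substrate) in pairs.items():
            t6 = small_matrix.table(par)[6.0]
            assert t6[product] > 0.0
            assert t6[substrate] < 0.0

    def test_vmax_outweighs_km_when_substrate_saturating(self, small_matrix):
        """CHON sits far above Km_CYP11A1 in the default model, so the
        maximum velocity dominates the paired Michaelis constant."""
        rank = auc_ranking(small_matrix).set_index("parameter")["total_auc"]
        assert rank["Vmax_CYP11A1"] > rank["Km_CYP11A1"]


class TestAucRanking:
    @staticmethod
    def matrix_from(values, times):
        values = np.asarray(values, dtype=float)
        return SensitivityMatrix(
            values=values, parameters=tuple(f"p{k}"
                                            for k in range(values.shape[0])),
            steroids=tuple(f"s{k}" for k in range(values.shape[1])),
            times=np.asarray(times, float), compartment="medium", delta=0.1)

    def test_zero_matrix_all_ties_at_zero(self):
        mat = self.matrix_from(np.zeros((3, 2, 4)), [6, 12, 18, 24])
        out = auc_ranking(mat)
        assert np.all(out["total_auc"] == 0.0)

    def test_two_point_trapezoid_hand_value(self):
        # S rises from 0 (at t=0) to 1 at t=6: area = 6 * 1 / 2 = 3
        mat = self.matrix_from(np.ones((1, 1, 1)), [6.0])
        assert auc_ranking(mat)["total_auc"][0] == pytest.approx(3.0)

    def test_ranking_is_descending(self, rng):
        mat = self.matrix_from(rng.normal(size=(5, 3, 12)),
                               list(range(6, 73, 6)))
        out = auc_ranking(mat)
        assert np.all(np.diff(out["total_auc"]) <= 0)


class TestClassifyPhenotype:
    def test_identical_trajectories_all_steroid(self, params):
        traj = simulate(params)
        y0 = default_initial_state_vector()
        assert classify_phenotype(traj.states[-1], traj.states[-1],
                                  y0) == "all_steroid"

    def test_all_enzymes_off_terminates_upstream(self, params):
        traj = simulate(params)
        dead = simulate(params, activities=np.zeros(9))
        y0 = default_initial_state_vector()
        assert classify_phenotype(dead.states[-1], traj.states[-1],
                                  y0) == "terminated"

    def test_theta_stability_for_baseline(self, params):
        traj = simulate(params)
        y0 = default_initial_state_vector()
        for theta in (0.005, 0.01, 0.02):
            assert classify_phenotype(traj.states[-1], traj.states[-1],
                                      y0, theta) == "all_steroid"


class TestScan2d:
    def test_baseline_cell_is_all_steroid(self, coarse_grid):
        assert coarse_grid.category_at(1.0, 1.0) == "all_steroid"

    def test_no_cell_fails(self, coarse_grid):
        assert not coarse_grid.failed.any()

    def test_cyp17h_knockout_loses_the_17alpha_branch(self, params,
                                                      coarse_grid):
        """With CYP17H at 0 only the mineralocorticoid branch runs."""
        assert coarse_grid.category_at(0.0, 1.0) == "mineralocorticoid"
        acts = np.ones(9)
        acts[ENZYMES.index("CYP17H")] = 0.0
        traj = simulate(params, activities=acts)
        base = simulate(params)
        y0 = default_initial_state_vector()

        def production(t, s):
            return t.medium(s)[-1] - y0[medium_index(s)]

        # 17alpha-branch production collapses (small residual conversion of
        # initial precursors remains); the mineralocorticoid branch persists
        for s in ("HPREG", "DHEA", "HPROG", "DIONE"):
            assert production(traj, s) < 0.05 * production(base, s)
        assert production(traj, "ALDO") > 0.5 * production(base, "ALDO")

    def test_deterministic(self, params):
        mult = np.array([0.0, 1.0, 2.0])
        a = scan_2d(params, multipliers=mult)
        b = scan_2d(params, multipliers=mult)
        assert np.array_equal(a.categories, b.categories)
        assert a.medium_72h.tobytes() == b.medium_72h.tobytes()

    def test_export_frame_covers_grid(self, coarse_grid):
        frame = coarse_grid.to_frame()
        assert len(frame) == 25
        assert {"cyp17h_pct", "hsd3b2_pct", "category"} <= set(frame.columns)
        assert set(STEROIDS) <= set(frame.columns)
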