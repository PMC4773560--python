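"""NLSD objective, LLOQ censoring, LM fitting, and fitting sensitivity."""

import numpy as np
import pandas as pd
import pytest

from adrenosim.calibration import (
    CalibrationDataset,
    diffusion_equilibrium,
    equilibrate_initial_state,
    fit_parameters,
    fitting_sensitivity,
    nlsd,
)
from adrenosim.parameters import default_initial_state_vector
from adrenosim.simulate import Trajectory
from adrenosim.species import N_STATE, medium_index
from adrenosim.synth import SynthSpec, generate_timecourse


def tiny_dataset(values, censored=(False, False), species="CORT",
                 times=(0.0, 8.0)):
    rows = [{"compartment": "medium", "species": species, "time_h": t,
             "replicate": 0, "value": v, "below_lloq": c}
            for t, v, c in zip(times, values, censored)]
    return CalibrationDataset(pd.DataFrame(rows))


def tiny_trajectory(sim_values, species="CORT", times=(0.0, 8.0)):
    states = np.zeros((len(times), N_STATE))
    states[:, medium_index(species)] = sim_values
    return Trajectory(times=np.asarray(times, float), states=states,
                      step_log=pd.DataFrame(), params=None,
                      activities=np.ones(9))


class TestNlsd:
    def test_perfect_fit_is_zero(self):
        ds = tiny_dataset([4.0, 2.0])
        assert nlsd(ds, tiny_trajectory([4.0, 2.0])) == 0.0

    def test_hand_value(self):
        # exp=(4,2), sim=(2,2), Xmax=4: (4-2)^2/16 + 0 = 0.25
        ds = tiny_dataset([4.0, 2.0])
        assert nlsd(ds, tiny_trajectory([2.0, 2.0])) == pytest.approx(0.25)

    def test_lloq_censoring_drops_the_term(self):
        # censoring the (already matching) second point changes nothing;
        # censoring the first removes its 0.25 contribution entirely
        ds = tiny_dataset([4.0, 2.0], censored=(False, True))
        assert nlsd(ds, tiny_trajectory([2.0, 2.0])) == pytest.approx(0.25)
        ds2 = tiny_dataset([4.0, 2.0], censored=(True, False))
        assert nlsd(ds2, tiny_trajectory([2.0, 2.0])) == 0.0

    def test_unit_rescaling_invariance(self):
        ds = tiny_dataset([4.0, 2.0])
        base = nlsd(ds, tiny_trajectory([3.0, 1.0]))
        scaled = tiny_dataset([4000.0, 2000.0])
        assert nlsd(scaled, tiny_trajectory([3000.0, 1000.0])) == \
            pytest.approx(base)

    def test_missing_simulated_time_rejected(self):
        ds = tiny_dataset([4.0, 2.0], times=(0.0, 24.0))
        with pytest.raises(KeyError):
            nlsd(ds, tiny_trajectory([4.0, 2.0], times=(0.0, 8.0)))

    def test_unknown_species_rejected(self):
        frame = pd.DataFrame([{"compartment": "medium", "species": "XXX",
                               "time_h": 0.0, "replicate": 0, "value": 1.0,
                               "below_lloq": False}])
        with pytest.raises(ValueError, match="unknown species"):
            CalibrationDataset(frame)


class TestEquilibrateInitialState:
    def test_symmetric_transport_equalizes_compartments(self, params):
        ds, _ = generate_timecourse(SynthSpec(cv=0.0, seed=0, lloq={}))
        y0 = equilibrate_initial_state(ds, params)
        for s in ("PREG", "CORT", "ALDO"):
            assert y0[medium_index(s)] == pytest.approx(
                y0[medium_index(s) - 14])  # cell index = medium index - 14

    def test_flux_balance_with_asymmetric_constants(self, params):
        ds = tiny_dataset([1.0, 1.0], species="PREG")
        y0 = equilibrate_initial_state(
            ds, params, transport_ratio={"PREG": (2.0, 1.0)})
        from adrenosim.species import cell_index
        assert y0[cell_index("PREG")] == pytest.approx(2.0)
        assert diffusion_equilibrium(1.0, kf=2.0, kb=1.0) == 2.0

    def test_missing_species_warns_and_zeroes(self, params):
        ds = tiny_dataset([1.0, 1.0], species="PREG")
        with pytest.warns(UserWarning, match="CORT"):
            y0 = equilibrate_initial_state(ds, params)
        assert y0[medium_index("CORT")] == 0.0


@pytest.fixture(scope="module")
def clean_dataset():
    ds, _ = generate_timecourse(SynthSpec(cv=0.0, seed=1))
    return ds


@pytest.fixture(scope="module")
def noisy_dataset():
    ds, _ = generate_timecourse(SynthSpec(cv=0.05, seed=7))
    return ds


class TestFitParameters:
    def test_fixed_point_at_ground_truth(self, params, clean_dataset):
        res = fit_parameters(clean_dataset, params, ["VmaxA_HSD3B2"],
                             initial_state=default_initial_state_vector(),
                             max_nfev=10)
        assert res.final_nlsd < 1e-6
        assert res.params["VmaxA_HSD3B2"] == pytest.approx(
            params["VmaxA_HSD3B2"], rel=1e-4)

    def test_single_perturbed_vmax_recovered(self, params, clean_dataset):
        start = params.with_updates(
            {"VmaxA_HSD3B2": 3.0 * params["VmaxA_HSD3B2"]})
        res = fit_parameters(clean_dataset, start, ["VmaxA_HSD3B2"],
                             initial_state=default_initial_state_vector())
        assert res.params["VmaxA_HSD3B2"] == pytest.approx(
            params["VmaxA_HSD3B2"], rel=0.01)
        assert res.final_nlsd <= res.initial_nlsd

    @pytest.mark.filterwarnings("ignore:no t=0 medium measurement")
    def test_noisy_three_parameter_recovery_study(self, params):
        """5% noise, 3 free maximum velocities: recovered within 25%."""
        free = ["VmaxA_HSD3B2", "Vmax_CYP11A1", "VmaxA_CYP21A2"]
        start_factors = (2.0, 0.5, 1.8)
        good = 0
        n_seeds = 10
        for seed in range(n_seeds):
            ds, _ = generate_timecourse(SynthSpec(cv=0.05, seed=seed))
            start = params.with_updates(
                {n: params[n] * f for n, f in zip(free, start_factors)})
            res = fit_parameters(ds, start, free)
            rel = max(abs(res.params[n] / params[n] - 1.0) for n in free)
            good += rel <= 0.25
        assert good >= 0.9 * n_seeds

    def test_objective_never_increases(self, params, clean_dataset):
        start = params.with_updates(
            {"Vmax_CYP11A1": 2.0 * params["Vmax_CYP11A1"]})
        res = fit_parameters(clean_dataset, start, ["Vmax_CYP11A1"],
                             initial_state=default_initial_state_vector())
        best = res.trace
        assert np.all(np.diff(best) <= 1e-15)
        assert res.final_nlsd <= res.initial_nlsd

    def test_empty_free_set_rejected(self, params, clean_dataset):
        with pytest.raises(ValueError):
            fit_parameters(clean_dataset, params, [])


class TestFittingSensitivity:
    @pytest.mark.filterwarnings("ignore:no t=0 medium measurement")
    def test_inert_parameter_scores_zero(self, params, noisy_dataset):
        # a maximum velocity of zero stays zero under a +10% perturbation
        p = params.with_updates({"VmaxB_HSD17B3": 0.0})
        table = fitting_sensitivity(p, noisy_dataset,
                                    names=("VmaxB_HSD17B3", "Vmax_CYP11A1"))
        scores = dict(zip(table["parameter"], table["score"]))
        assert scores["VmaxB_HSD17B3"] == 0.0
        assert scores["Vmax_CYP11A1"] > 0.0

    @pytest.mark.filterwarnings("ignore:no t=0 medium measurement")
    def test_high_flux_vmax_outranks_unused_km(self, params, noisy_dataset):
        table = fitting_sensitivity(
            params, noisy_dataset,
            names=("VmaxA_HSD3B2", "KmB_CYP19A1"))
        scores = dict(zip(table["parameter"], table["score"]))
        assert scores["VmaxA_HSD3B2"] > scores["KmB_CYP19A1"]
        assert list(table["parameter"])[0] == "VmaxA_HSD3B2"
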