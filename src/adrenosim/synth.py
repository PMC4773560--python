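"""Synthetic assay data with the statistical structure of the real study.

Generates (a) steroid time-course datasets (2 compartments, sampling at
{0, 8, 24, 48, 72} h, 4 replicate wells per time point, multiplicative
log-normal noise, LLOQ censoring) for calibration benchmarks and (b) 72-h
fold-change profiles and inhibitor panels with planted enzyme-activity
perturbations for end-to-end mechanism-of-action recovery studies.

Noise is multiplicative log-normal with unit mean: a measured value is
``true * exp(N(-sigma^2/2, sigma))`` with ``sigma^2 = ln(1 + CV^2)``, so
the expectation equals the simulated value and the coefficient of
variation is exactly ``CV`` (LC-MS-like; concentrations stay positive).
Everything is reproducible from (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .calibration import CalibrationDataset, SAMPLING_TIMES, observable
from .moa import BaselineModel, EnzymeActivityProfile, FoldChangeProfile
from .parameters import KineticParameterSet, default_initial_state_vector, default_parameters
from .simulate import IntegratorConfig, Trajectory, simulate
from .species import LCMS_STEROIDS, MOA_ENZYMES, STEROIDS

#: Default medium LLOQ per steroid (nmol/L).  The minor steroids carry the
#: highest quantification limits, which is what censors ALDO/TESTO under
#: strong upstream inhibition.
DEFAULT_LLOQ: dict[str, float] = {s: 0.05 for s in STEROIDS}
DEFAULT_LLOQ.update({"ALDO": 0.2, "TESTO": 0.1, "E2": 0.01})


@dataclass(frozen=True)
class SynthSpec:
    """Design of a synthetic steroidogenesis experiment."""

    params: KineticParameterSet | None = None
    planted: EnzymeActivityProfile | None = None
    cv: float = 0.10
    replicates: int = 4
    lloq: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_LLOQ))
    seed: int = 0
    times: tuple[float, ...] = SAMPLING_TIMES

    def __post_init__(self):
        if self.cv < 0:
            raise ValueError("CV must be nonnegative")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")

    def resolve_params(self) -> KineticParameterSet:
        return self.params if self.params is not None else default_parameters()

    def activities(self) -> np.ndarray:
        planted = self.planted or EnzymeActivityProfile.unperturbed()
        return planted.full_activities()


def _noise_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    if cv == 0.0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def generate_timecourse(spec: SynthSpec
                        ) -> tuple[CalibrationDataset, Trajectory]:
    """Simulate, sample with replicate noise, and censor below LLOQ.

    Returns the dataset and the noise-free ground-truth trajectory.
    """
    rng = np.random.default_rng(spec.seed)
    params = spec.resolve_params()
    grid = np.asarray(spec.times, dtype=float)
    config = IntegratorConfig(duration=float(grid[-1]), record_grid=grid)
    truth = simulate(params, spec.activities(), config,
                     default_initial_state_vector())
    rows = []
    for compartment in ("medium", "intracellular"):
        for species in ("CHOL",) + STEROIDS:
            clean = observable(truth.states, compartment, species)
            for j, t in enumerate(grid):
                noisy = clean[j] * _noise_factors(rng, spec.cv,
                                                 spec.replicates)
                lloq = (spec.lloq.get(species, 0.0)
                        if compartment == "medium" else 0.0)
                for r, v in enumerate(noisy):
                    rows.append({
                        "compartment": compartment, "species": species,
                        "time_h": t, "replicate": r, "value": float(v),
                        "below_lloq": bool(v < lloq),
                    })
    frame = pd.DataFrame(rows)
    frame.attrs["seed"] = spec.seed
    return CalibrationDataset(frame), truth


def generate_foldchange(spec: SynthSpec,
                        model: BaselineModel | None = None
                        ) -> tuple[FoldChangeProfile, EnzymeActivityProfile]:
    """Noisy treated/control fold-change profile for a planted perturbation.

    Both arms receive independent replicate noise; an arm whose replicates
    all fall below the LLOQ is censored, and the steroid's ratio is flagged
    undefined.  Returns the profile and the planted ground truth.
    """
    rng = np.random.default_rng(spec.seed)
    planted = spec.planted or EnzymeActivityProfile.unperturbed()
    if model is None:
        model = BaselineModel(spec.resolve_params())
    treated_clean = model.predict_foldchange(planted).values * \
        model.baseline_medium
    control_clean = model.baseline_medium
    values = np.ones(len(LCMS_STEROIDS))
    flags = np.zeros(len(LCMS_STEROIDS), dtype=bool)
    for i, steroid in enumerate(LCMS_STEROIDS):
        lloq = spec.lloq.get(steroid, 0.0)
        arms = []
        for clean in (treated_clean[i], control_clean[i]):
            reps = clean * _noise_factors(rng, spec.cv, spec.replicates)
            quantified = reps[reps >= lloq]
            arms.append(quantified.mean() if quantified.size else np.nan)
        treated, control = arms
        if np.isnan(treated) or np.isnan(control) or control <= 0:
            flags[i] = True
        else:
            values[i] = treated / control
    return FoldChangeProfile(values, flags), planted


def inhibition_activity(dose: float, ic50: float) -> float:
    """Fractional remaining activity of a competitive inhibitor, 1/(1+dose/IC50)."""
    if dose < 0 or ic50 <= 0:
        raise ValueError("dose must be >= 0 and IC50 > 0")
    return 1.0 / (1.0 + dose / ic50)


@dataclass
class InhibitorPanel:
    """A panel of synthetic compounds with known mechanisms."""

    profiles: dict[tuple[str, float], FoldChangeProfile]
    truth: pd.DataFrame

    def log2_matrix(self) -> pd.DataFrame:
        """Compounds x steroids log2 fold changes (censored -> 0)."""
        rows = {}
        for (compound, dose), profile in self.profiles.items():
            v = np.where(profile.below_lloq, 1.0, profile.values)
            rows[f"{compound}@{dose:g}"] = np.log2(v)
        return pd.DataFrame.from_dict(rows, orient="index",
                                      columns=list(LCMS_STEROIDS))


def make_inhibitor_panel(n_compounds: int = 6,
                         seed: int = 0,
                         spec: SynthSpec | None = None,
                         model: BaselineModel | None = None,
                         doses: tuple[float, ...] = (1.0, 10.0, 100.0)
                         ) -> InhibitorPanel:
    """Synthetic compound panel: null compounds plus enzyme inhibitors.

    Odd-numbered compounds are nulls (no enzymatic effect); the others
    inhibit one or two randomly chosen enzymes with IC50 drawn log-uniformly
    between the lowest dose and a tenth of the highest, so planted activity
    falls monotonically with dose as ``1/(1 + dose/IC50)`` and the top dose
    reaches strong (>=90%) inhibition.  Returns all profiles plus a truth
    table for benchmarking.
    """
    if n_compounds < 2:
        raise ValueError("a panel needs at least 2 compounds")
    rng = np.random.default_rng(seed)
    spec = spec or SynthSpec(seed=seed)
    if model is None:
        model = BaselineModel(spec.resolve_params())
    profiles = {}
    truth_rows = []
    for c in range(n_compounds):
        name = f"compound_{c:02d}"
        is_null = c % 2 == 1
        if is_null:
            targets = {}
        else:
            n_targets = int(rng.integers(1, 3))
            chosen = rng.choice(len(MOA_ENZYMES), size=n_targets,
                                replace=False)
            lo, hi = np.log10(min(doses)), np.log10(max(doses)) - 1.0
            targets = {MOA_ENZYMES[i]: float(10.0 ** rng.uniform(lo, hi))
                       for i in chosen}
        for dose in doses:
            acts = {e: inhibition_activity(dose, ic50)
                    for e, ic50 in targets.items()}
            planted = EnzymeActivityProfile(
                {**{e: 1.0 for e in MOA_ENZYMES}, **acts})
            sub = replace(spec, planted=planted,
                          seed=int(rng.integers(0, 2 ** 31)))
            profile, _ = generate_foldchange(sub, model=model)
            profiles[(name, dose)] = profile
            for e in MOA_ENZYMES:
                truth_rows.append({
                    "compound": name, "dose": dose, "enzyme": e,
                    "activity": planted[e], "is_null": is_null,
                })
    return InhibitorPanel(profiles=profiles,
                          truth=pd.DataFrame(truth_rows))
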