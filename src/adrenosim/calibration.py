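"""Fitting the kinetic model to measured time courses.

The objective is the normalized least-squares distance (NLSD)

    NLSD = sum_h sum_i sum_j (X^exp_hij - X^sim_hij)^2 / (X^max_hi)^2

over compartments h (medium / intracellular), species i (cholesterol and
the 14 steroids), and sampling times j ({0, 8, 24, 48, 72} h), where
X^max_hi is the largest measured concentration of that trace.  Observations
below the lower limit of quantification (LLOQ) are excluded -- never
imputed.  Optimization runs in log space (all parameters are positive and
span decades) with the Levenberg-Marquardt algorithm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .parameters import (
    DEFAULT_INITIAL_STATE,
    INVENTORY_42,
    KineticParameterSet,
)
from .simulate import IntegratorConfig, Trajectory, simulate
from .species import (
    CHOLESTEROL_POOLS,
    POOL_INDEX,
    STEROIDS,
    cell_index,
    medium_index,
)

#: Default sampling design of the steroidogenesis assay.
SAMPLING_TIMES = (0.0, 8.0, 24.0, 48.0, 72.0)

#: Intracellular pools summed to form the measurable "cholesterol" observable
#: (a bulk assay cannot resolve the model's localization pools).
_INTRACELLULAR_CHOL_POOLS = ("CHOS", "CHOC", "CHOM", "CHON", "CHOR")


def observable(states: np.ndarray, compartment: str, species: str) -> np.ndarray:
    """Map recorded state rows to a measured quantity (nmol/L)."""
    if species == "CHOL":
        if compartment == "medium":
            return states[..., POOL_INDEX["CHOL"]]
        idx = [POOL_INDEX[p] for p in _INTRACELLULAR_CHOL_POOLS]
        return states[..., idx].sum(axis=-1)
    if compartment == "medium":
        return states[..., medium_index(species)]
    if compartment == "intracellular":
        return states[..., cell_index(species)]
    raise ValueError(f"unknown compartment {compartment!r}")


class CalibrationDataset:
    """Measured concentrations with LLOQ flags, in tidy long form.

    Expects columns ``compartment`` (medium | intracellular), ``species``
    (CHOL or a steroid), ``time_h``, ``replicate``, ``value``,
    ``below_lloq``.  Fitting uses per-time-point means over quantified
    replicates; a point with no quantified replicate is censored.
    """

    REQUIRED_COLUMNS = ("compartment", "species", "time_h", "replicate",
                        "value", "below_lloq")

    def __init__(self, frame: pd.DataFrame):
        missing = set(self.REQUIRED_COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"dataset missing columns {sorted(missing)}")
        bad = set(frame["species"]) - set(STEROIDS) - {"CHOL"}
        if bad:
            raise ValueError(f"unknown species in dataset: {sorted(bad)}")
        self.frame = frame.reset_index(drop=True)
        quant = frame[~frame["below_lloq"].astype(bool)]
        means = (quant.groupby(["compartment", "species", "time_h"])["value"]
                 .mean())
        sds = (quant.groupby(["compartment", "species", "time_h"])["value"]
               .std())
        self.means = means
        self.sds = sds
        #: per-(compartment, species) normalizer: max mean over time points
        self.xmax = means.groupby(["compartment", "species"]).max()
        if (self.xmax <= 0).any():
            bad = self.xmax[self.xmax <= 0].index.tolist()
            raise ValueError(f"nonpositive X^max for traces {bad}")

    @property
    def times(self) -> np.ndarray:
        return np.sort(self.frame["time_h"].unique())

    def points(self):
        """Iterate (compartment, species, time, mean value, xmax)."""
        for (h, i, j), v in self.means.items():
            yield h, i, j, v, self.xmax[(h, i)]

    # -- IO -----------------------------------------------------------------

    @classmethod
    def read_csv(cls, path) -> "CalibrationDataset":
        return cls(pd.read_csv(path))

    def write_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def nlsd(dataset: CalibrationDataset, trajectory: Trajectory) -> float:
    """Normalized least-squares distance between data and a simulation.

    Censored (below-LLOQ) points contribute nothing.  Raises if a dataset
    time is absent from the trajectory's record grid (no interpolation).
    """
    return float(np.sum(np.square(_residuals(dataset, trajectory))))


def _residuals(dataset: CalibrationDataset, trajectory: Trajectory) -> np.ndarray:
    res = []
    for h, i, j, x_exp, x_max in dataset.points():
        state = trajectory.state_at(j)
        x_sim = float(observable(state, h, i))
        res.append((x_exp - x_sim) / x_max)
    return np.array(res)


@dataclass
class FitResult:
    """Outcome of a Levenberg-Marquardt calibration run."""

    params: KineticParameterSet
    initial_nlsd: float
    final_nlsd: float
    #: best objective value after each function evaluation
    trace: np.ndarray
    n_evaluations: int
    free_names: tuple[str, ...]
    message: str = ""

    def __post_init__(self):
        if self.final_nlsd > self.initial_nlsd + 1e-12:
            raise RuntimeError("fit ended above its starting objective")


def _fit_config(dataset: CalibrationDataset,
                config: IntegratorConfig | None) -> IntegratorConfig:
    times = dataset.times
    if config is not None:
        grid = config.grid()
        if not all(np.any(np.isclose(grid, t)) for t in times):
            raise ValueError("integrator record grid misses dataset times")
        return config
    return IntegratorConfig(duration=float(times[-1]),
                            record_grid=np.asarray(times, dtype=float))


def fit_parameters(dataset: CalibrationDataset,
                   initial_params: KineticParameterSet,
                   free_names,
                   bounds: tuple[float, float] | None = None,
                   initial_state: np.ndarray | None = None,
                   activities: np.ndarray | None = None,
                   config: IntegratorConfig | None = None,
                   max_nfev: int | None = None) -> FitResult:
    """Levenberg-Marquardt fit of the selected parameters in log10 space.

    ``free_names`` selects which kinetic parameters move; the rest stay at
    their ``initial_params`` values.  ``bounds`` is an optional (lo, hi)
    multiplicative range applied to every free parameter; when given, the
    trust-region reflective variant is used (plain LM is unbounded).
    Deterministic for a fixed starting point.
    """
    free_names = tuple(free_names)
    if not free_names:
        raise ValueError("free_names must select at least one parameter")
    for n in free_names:
        if n not in initial_params:
            raise KeyError(f"unknown parameter {n!r}")
    config = _fit_config(dataset, config)
    if initial_state is None:
        initial_state = equilibrate_initial_state(dataset, initial_params)

    x0 = np.log10([initial_params[n] for n in free_names])
    trace: list[float] = []

    def residuals(x):
        p = initial_params.with_updates(
            {n: 10.0 ** xi for n, xi in zip(free_names, x)})
        try:
            traj = simulate(p, activities, config, initial_state)
            r = _residuals(dataset, traj)
        except FloatingPointError:
            r = np.full(len(list(dataset.points())), 1e6)
        trace.append(float(np.sum(r * r)))
        return r

    initial_obj = float(np.sum(residuals(x0) ** 2))
    if bounds is None:
        sol = least_squares(residuals, x0, method="lm", max_nfev=max_nfev)
    else:
        lo, hi = np.log10(bounds[0]), np.log10(bounds[1])
        sol = least_squares(residuals, x0, method="trf",
                            bounds=(x0 + lo, x0 + hi), max_nfev=max_nfev)
    best = np.minimum.accumulate(trace)
    fitted = initial_params.with_updates(
        {n: 10.0 ** xi for n, xi in zip(free_names, sol.x)})
    final_obj = float(2.0 * sol.cost)
    if final_obj > best[-1]:
        # LM can end on a rejected trial; keep the best visited point
        k = int(np.argmin(trace))
        final_obj = trace[k]
    return FitResult(params=fitted, initial_nlsd=initial_obj,
                     final_nlsd=min(final_obj, initial_obj),
                     trace=best, n_evaluations=len(trace),
                     free_names=free_names, message=sol.message)


def fitting_sensitivity(params: KineticParameterSet,
                        dataset: CalibrationDataset,
                        delta: float = 0.1,
                        initial_state: np.ndarray | None = None,
                        activities: np.ndarray | None = None,
                        config: IntegratorConfig | None = None,
                        names=None) -> pd.DataFrame:
    """Relative finite-difference effect of each static parameter on NLSD.

    ``score_x = |NLSD(x (1+delta)) - NLSD(x)| / (NLSD(x) delta)``; when the
    baseline NLSD is zero the scores are reported on an absolute scale and
    the ``absolute_scale`` column is set.  Returns a table sorted by score.
    """
    names = tuple(names) if names is not None else INVENTORY_42
    config = _fit_config(dataset, config)
    if initial_state is None:
        initial_state = equilibrate_initial_state(dataset, params)
    if activities is None:
        activities = np.ones(9)
    activities = np.asarray(activities, dtype=float)

    base = nlsd(dataset, simulate(params, activities, config, initial_state))

    # batch all perturbed runs through the compiled ensemble driver
    times = np.asarray(config.grid(), dtype=float)
    pvec = params.to_vector()
    objs = np.empty(len(names))
    for k, name in enumerate(names):
        p = params.with_updates({name: params[name] * (1.0 + delta)})
        traj = simulate(p, activities, config, initial_state)
        objs[k] = nlsd(dataset, traj)
    absolute = base == 0.0
    if absolute:
        scores = np.abs(objs - base) / delta
    else:
        scores = np.abs(objs - base) / (base * delta)
    out = pd.DataFrame({"parameter": names, "score": scores,
                        "nlsd_perturbed": objs})
    out["nlsd_baseline"] = base
    out["absolute_scale"] = absolute
    return out.sort_values("score", ascending=False).reset_index(drop=True)


def diffusion_equilibrium(medium_value: float, kf: float = 1.0,
                          kb: float = 1.0) -> float:
    """Intracellular concentration balancing influx kf*M against efflux kb*C."""
    if kb <= 0:
        raise ValueError("backward (efflux) constant must be positive")
    if medium_value < 0 or kf < 0:
        raise ValueError("concentration and rate constants must be nonnegative")
    return kf * medium_value / kb


def equilibrate_initial_state(dataset: CalibrationDataset,
                              params: KineticParameterSet,
                              cholesterol_pools: dict[str, float] | None = None,
                              transport_ratio: dict[str, tuple[float, float]] | None = None,
                              ) -> np.ndarray:
    """Initial state at t=0: medium from data, steroids at transport balance.

    Medium steroid concentrations come from the t=0 measurements; each
    intracellular steroid starts at the equilibrium of its passive-transport
    law (equal to the medium value for the symmetric clearance used by the
    model; ``transport_ratio`` can supply per-steroid (kf, kb) pairs).
    Cholesterol pool initials come from ``cholesterol_pools`` (default: the
    shipped initial table).  A steroid missing from the t=0 data starts at
    zero with a warning.
    """
    from .species import N_STATE

    pools = dict(cholesterol_pools or
                 {k: DEFAULT_INITIAL_STATE[k] for k in CHOLESTEROL_POOLS})
    vec = np.zeros(N_STATE)
    for pool, idx in POOL_INDEX.items():
        if pool == "CHOL":
            continue
        vec[idx] = pools.get(pool, 0.0)
    try:
        vec[POOL_INDEX["CHOL"]] = dataset.means[("medium", "CHOL", 0.0)]
    except KeyError:
        vec[POOL_INDEX["CHOL"]] = pools.get("CHOL", 0.0)
    for s in STEROIDS:
        try:
            med0 = float(dataset.means[("medium", s, 0.0)])
        except KeyError:
            warnings.warn(f"no t=0 medium measurement for {s}; "
                          "initializing to 0")
            med0 = 0.0
        kf, kb = (transport_ratio or {}).get(s, (1.0, 1.0))
        vec[medium_index(s)] = med0
        vec[cell_index(s)] = diffusion_equilibrium(med0, kf, kb)
    return vec
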