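"""Adaptive fourth-order Runge-Kutta simulation of the pathway model.

The step size follows the largest instantaneous flux magnitude:
``dt = clamp(c / max|rate|, dt_min, dt_max)``.  The constant ``c`` (nmol/L)
is chosen so that the fastest-moving pool changes by well under 0.1% per
step at the default model's concentration scale (~2e5 nmol/L); it is
exposed in the configuration.  Record times are hit exactly by shortening the final
step of each segment, so objective functions evaluated on the record grid
never interpolate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _core
from .parameters import KineticParameterSet, default_initial_state_vector
from .species import N_STATE, STEROIDS, cell_index, medium_index, POOL_INDEX


def default_record_grid(duration: float = 72.0) -> np.ndarray:
    """Every 0.5 h from 0 to ``duration`` (includes 0, 8, 24, 48, 72)."""
    return np.round(np.arange(0.0, duration + 1e-9, 0.5), 6)


@dataclass(frozen=True)
class IntegratorConfig:
    """Settings of the variable-step RK4 integrator."""

    dt_min: float = 1e-5          # h
    dt_max: float = 1e-2          # h
    step_constant: float = 100.0  # c in dt = c / max|rate| (nmol/L)
    duration: float = 72.0        # h
    record_grid: np.ndarray | None = None

    def __post_init__(self):
        if not (0 < self.dt_min <= self.dt_max):
            raise ValueError("require 0 < dt_min <= dt_max")
        if self.duration <= 0 or self.step_constant <= 0:
            raise ValueError("duration and step_constant must be positive")

    def grid(self) -> np.ndarray:
        if self.record_grid is not None:
            g = np.asarray(self.record_grid, dtype=float)
            if g[0] != 0.0 or np.any(np.diff(g) <= 0) or g[-1] != self.duration:
                raise ValueError("record grid must increase from 0 to duration")
            return g
        return default_record_grid(self.duration)


def adaptive_dt(max_rate: float, config: IntegratorConfig) -> float:
    """Step size implied by the largest flux magnitude (nmol/L/h)."""
    if not np.isfinite(max_rate) or max_rate < 0:
        raise ValueError("max_rate must be finite and nonnegative")
    if max_rate == 0.0:
        return config.dt_max
    return float(np.clip(config.step_constant / max_rate,
                         config.dt_min, config.dt_max))


@dataclass
class Trajectory:
    """A recorded simulation: times (h) and states (n_times, 35) in nmol/L."""

    times: np.ndarray
    states: np.ndarray
    #: per-segment step statistics: n_steps, smallest and largest dt used
    step_log: pd.DataFrame
    params: KineticParameterSet
    activities: np.ndarray

    def state_at(self, t: float) -> np.ndarray:
        j = np.nonzero(np.isclose(self.times, t, atol=1e-9))[0]
        if len(j) == 0:
            raise KeyError(f"time {t} h is not on the record grid")
        return self.states[j[0]]

    def medium(self, steroid: str) -> np.ndarray:
        return self.states[:, medium_index(steroid)]

    def cell(self, steroid: str) -> np.ndarray:
        return self.states[:, cell_index(steroid)]

    def pool(self, name: str) -> np.ndarray:
        return self.states[:, POOL_INDEX[name]]

    def to_tidy_frame(self) -> pd.DataFrame:
        """Long-form table (time_h, compartment, species, value)."""
        rows = []
        for name, idx, comp in (
            [("CHOL", POOL_INDEX["CHOL"], "medium")]
            + [(p, POOL_INDEX[p], "intracellular")
               for p in POOL_INDEX if p != "CHOL"]
            + [(s, cell_index(s), "intracellular") for s in STEROIDS]
            + [(s, medium_index(s), "medium") for s in STEROIDS]
        ):
            rows.append(pd.DataFrame({
                "time_h": self.times,
                "compartment": comp,
                "species": name,
                "value": self.states[:, idx],
            }))
        return pd.concat(rows, ignore_index=True)

    def write_csv(self, path) -> None:
        self.to_tidy_frame().to_csv(path, index=False)


def simulate(params: KineticParameterSet,
             activities: np.ndarray | None = None,
             config: IntegratorConfig | None = None,
             initial_state: np.ndarray | None = None,
             fixed_dt: float | None = None) -> Trajectory:
    """Integrate the model over ``config.duration`` hours.

    Deterministic: identical inputs give byte-identical trajectories.
    ``fixed_dt`` forces a constant step (used for numerical-error audits).
    """
    config = config or IntegratorConfig()
    if activities is None:
        activities = np.ones(9)
    activities = np.asarray(activities, dtype=float)
    if activities.shape != (9,) or np.any(activities < 0):
        raise ValueError("activities must be 9 nonnegative multipliers")
    if initial_state is None:
        initial_state = default_initial_state_vector()
    y0 = np.asarray(initial_state, dtype=float)
    if y0.shape != (N_STATE,):
        raise ValueError(f"initial state must have shape ({N_STATE},)")
    times = config.grid()
    fdt = float(fixed_dt) if fixed_dt is not None else -1.0
    Y, seg_steps, seg_lo, seg_hi, ok, t_bad = _core.integrate_record(
        y0, params.to_vector(), activities, params.geometry.to_vector(),
        params.dilution, times, config.step_constant,
        config.dt_min, config.dt_max, fdt)
    if not ok:
        j = int(np.searchsorted(times, t_bad))
        bad = Y[max(j - 1, 0)]
        worst = int(np.nanargmax(np.abs(bad))) if np.any(np.isfinite(bad)) else 0
        raise FloatingPointError(
            f"integration diverged at t={t_bad:.4g} h "
            f"(last dt range [{seg_lo[max(j-1,0)]:.3g}, {seg_hi[max(j-1,0)]:.3g}] h, "
            f"largest state entry index {worst})")
    step_log = pd.DataFrame({
        "t_start": times[:-1], "t_end": times[1:],
        "n_steps": seg_steps, "dt_min": seg_lo, "dt_max": seg_hi,
    })
    return Trajectory(times=times, states=Y, step_log=step_log,
                      params=params, activities=activities)


def error_ratio(params: KineticParameterSet,
                activities: np.ndarray | None = None,
                config: IntegratorConfig | None = None,
                initial_state: np.ndarray | None = None,
                fixed_dts=(1e-5, 1e-4, 1e-3, 1e-2),
                floor: float = 1e-12) -> tuple[float, dict[float, float]]:
    """Deviation of the adaptive run from fixed-step reference runs.

    For each fixed dt, computes the max over recorded species/times of
    ``|x_adaptive - x_fixed| / max(|x_fixed|, floor)``.  Returns the overall
    maximum and the per-dt breakdown.
    """
    config = config or IntegratorConfig()
    adaptive = simulate(params, activities, config, initial_state)
    per_dt: dict[float, float] = {}
    for dt in fixed_dts:
        if not (config.dt_min <= dt <= config.dt_max):
            raise ValueError(f"fixed dt {dt} outside [dt_min, dt_max]")
        ref = simulate(params, activities, config, initial_state, fixed_dt=dt)
        denom = np.maximum(np.abs(ref.states), floor)
        per_dt[dt] = float(np.max(np.abs(adaptive.states - ref.states) / denom))
    return max(per_dt.values()), per_dt
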