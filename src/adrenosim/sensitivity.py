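"""Dynamic sensitivity analysis and the 2-D enzyme-activity phenotype scan.

The dynamic sensitivity of steroid concentration y to kinetic parameter x is
the time-resolved relative response to a one-sided +10% perturbation,

    S_{x,y}(t) = (Delta y(t) / y(t)) / (Delta x / x),

evaluated on a 6-h grid to 72 h from one forward simulation per parameter.
Parameters are ranked by the total area under |S(t)| summed over species
(unsigned, so sign-changing curves do not cancel).

The phenotype scan perturbs CYP17H and HSD3B2 activities on a 21 x 21 grid
(0-200% in 10% steps) and classifies each cell by which steroid classes it
still produces at 72 h: all-steroid, mineralocorticoid (ALDO) only,
glucocorticoid (DCORT/CORT) only, both corticoid branches, or terminated
upstream.  A steroid counts as "produced" when its net 72-h medium
production reaches a fraction theta (default 1%) of the baseline net
production; net production is used because residual t=0 material would
otherwise mask a dead branch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _core
from .parameters import (
    INVENTORY_42,
    KineticParameterSet,
    default_initial_state_vector,
)
from .simulate import IntegratorConfig, simulate
from .species import ENZYMES, STEROIDS, cell_index, medium_index

SENSITIVITY_GRID = tuple(float(t) for t in range(6, 73, 6))

CATEGORIES = ("all_steroid", "mineralocorticoid", "glucocorticoid",
              "both_corticoid", "terminated")

_MINERALO_MARKERS = ("ALDO",)
_GLUCO_MARKERS = ("DCORT", "CORT")


def _steroid_rows(states: np.ndarray, compartment: str) -> np.ndarray:
    idx = ([medium_index(s) for s in STEROIDS] if compartment == "medium"
           else [cell_index(s) for s in STEROIDS])
    return states[..., idx]


# ---------------------------------------------------------------------------
# Dynamic sensitivity
# ---------------------------------------------------------------------------


def dynamic_sensitivity(params: KineticParameterSet,
                        name: str,
                        times=SENSITIVITY_GRID,
                        delta: float = 0.1,
                        compartment: str = "medium",
                        activities: np.ndarray | None = None,
                        initial_state: np.ndarray | None = None,
                        config: IntegratorConfig | None = None) -> pd.DataFrame:
    """S(t) of every steroid to a one-sided ``+delta`` change of one parameter.

    Returns a steroids x times table; entries where the baseline
    concentration is zero are NaN (undefined).
    """
    times = np.asarray(sorted(times), dtype=float)
    grid = np.unique(np.concatenate([[0.0], times]))
    config = config or IntegratorConfig(duration=float(grid[-1]),
                                        record_grid=grid)
    if initial_state is None:
        initial_state = default_initial_state_vector()
    base = simulate(params, activities, config, initial_state)
    pert = simulate(params.with_updates({name: params[name] * (1 + delta)}),
                    activities, config, initial_state)
    sel = np.isin(config.grid(), times)
    y0 = _steroid_rows(base.states[sel], compartment)
    y1 = _steroid_rows(pert.states[sel], compartment)
    with np.errstate(divide="ignore", invalid="ignore"):
        S = ((y1 - y0) / y0) / delta
    S[y0 == 0.0] = np.nan
    return pd.DataFrame(S.T, index=list(STEROIDS), columns=times)


@dataclass
class SensitivityMatrix:
    """values[x, y, t]: 42 parameters x 14 steroids x the 6-h time grid."""

    values: np.ndarray
    parameters: tuple[str, ...]
    steroids: tuple[str, ...]
    times: np.ndarray
    compartment: str
    delta: float

    def table(self, parameter: str) -> pd.DataFrame:
        return pd.DataFrame(self.values[self.parameters.index(parameter)],
                            index=list(self.steroids), columns=self.times)

    def to_frame(self) -> pd.DataFrame:
        """Tidy export (parameter, species, time_h, sensitivity)."""
        px, sx, tx = np.meshgrid(range(len(self.parameters)),
                                 range(len(self.steroids)),
                                 range(len(self.times)), indexing="ij")
        return pd.DataFrame({
            "parameter": np.asarray(self.parameters)[px.ravel()],
            "species": np.asarray(self.steroids)[sx.ravel()],
            "time_h": self.times[tx.ravel()],
            "sensitivity": self.values.ravel(),
        })

    def plot(self, ax=None):  # pragma: no cover - thin matplotlib shim
        """Heat-map of time-averaged sensitivities (parameters x steroids)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(10, 8))
        mean_s = np.nanmean(self.values, axis=2)
        vmax = np.nanmax(np.abs(mean_s)) or 1.0
        im = ax.imshow(mean_s, aspect="auto", cmap="RdBu_r",
                       vmin=-vmax, vmax=vmax)
        ax.set_yticks(range(len(self.parameters)),
                      labels=self.parameters, fontsize=5)
        ax.set_xticks(range(len(self.steroids)),
                      labels=self.steroids, rotation=90, fontsize=6)
        ax.figure.colorbar(im, ax=ax, label="mean S over time")
        return ax


def sensitivity_heatmap(params: KineticParameterSet,
                        times=SENSITIVITY_GRID,
                        delta: float = 0.1,
                        compartment: str = "medium",
                        activities: np.ndarray | None = None,
                        initial_state: np.ndarray | None = None,
                        config: IntegratorConfig | None = None,
                        parameters=None) -> SensitivityMatrix:
    """Full dynamic-sensitivity array over the 42-parameter inventory.

    One baseline plus one perturbed forward simulation per parameter, run as
    a compiled batch.  ``compartment`` selects medium (the displayed
    convention) or intracellular concentrations.
    """
    names = tuple(parameters) if parameters is not None else INVENTORY_42
    times = np.asarray(sorted(times), dtype=float)
    grid = np.unique(np.concatenate([[0.0], times]))
    config = config or IntegratorConfig(duration=float(grid[-1]),
                                        record_grid=grid)
    if initial_state is None:
        initial_state = default_initial_state_vector()
    if activities is None:
        activities = np.ones(len(ENZYMES))
    activities = np.asarray(activities, dtype=float)

    base = simulate(params, activities, config, initial_state)
    sel = np.isin(config.grid(), times)
    y0 = _steroid_rows(base.states[sel], compartment)  # (T, 14)

    S = np.empty((len(names), len(STEROIDS), len(times)))
    for k, name in enumerate(names):
        pert = simulate(params.with_updates({name: params[name] * (1 + delta)}),
                        activities, config, initial_state)
        y1 = _steroid_rows(pert.states[sel], compartment)
        with np.errstate(divide="ignore", invalid="ignore"):
            s = ((y1 - y0) / y0) / delta
        s[y0 == 0.0] = np.nan
        S[k] = s.T
    return SensitivityMatrix(values=S, parameters=names,
                             steroids=STEROIDS, times=times,
                             compartment=compartment, delta=delta)


def auc_ranking(matrix: SensitivityMatrix) -> pd.DataFrame:
    """Parameters ranked by total trapezoidal area under |S(t)|.

    S is taken as 0 at t=0 (no perturbation response yet), the curve is
    integrated per steroid with the trapezoid rule, and areas are summed
    over steroids.  NaN entries (undefined sensitivities) contribute 0.
    """
    t = np.concatenate([[0.0], matrix.times])
    absS = np.abs(np.nan_to_num(matrix.values, nan=0.0))
    padded = np.concatenate(
        [np.zeros(absS.shape[:2] + (1,)), absS], axis=2)
    per_species = np.trapezoid(padded, t, axis=2)
    total = per_species.sum(axis=1)
    out = pd.DataFrame({"parameter": matrix.parameters, "total_auc": total})
    return out.sort_values("total_auc", ascending=False,
                           kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# 2-D phenotype scan
# ---------------------------------------------------------------------------


def classify_phenotype(final_state: np.ndarray,
                       baseline_final: np.ndarray,
                       initial_state: np.ndarray,
                       theta: float = 0.01) -> str:
    """Category of a scanned cell from its 72-h medium production pattern.

    A steroid is produced when its net medium production (final minus
    initial) is at least ``theta`` times the baseline net production.
    Steroids whose baseline production is not positive are excluded from
    the all-steroid test with a warning.
    """
    med = [medium_index(s) for s in STEROIDS]
    prod = final_state[med] - initial_state[med]
    base_prod = baseline_final[med] - initial_state[med]
    usable = base_prod > 0.0
    if not usable.all():
        skipped = [s for s, u in zip(STEROIDS, usable) if not u]
        warnings.warn(f"baseline produces none of {skipped}; excluded from "
                      "the all-steroid criterion")
    produced = prod >= theta * base_prod
    produced_map = dict(zip(STEROIDS, produced))
    if all(produced_map[s] for s, u in zip(STEROIDS, usable) if u):
        return "all_steroid"
    mineralo = all(produced_map[s] for s in _MINERALO_MARKERS)
    gluco = all(produced_map[s] for s in _GLUCO_MARKERS)
    if mineralo and gluco:
        return "both_corticoid"
    if mineralo:
        return "mineralocorticoid"
    if gluco:
        return "glucocorticoid"
    return "terminated"


@dataclass
class ScanGrid:
    """Result of the 2-D activity scan (first enzyme on axis 0)."""

    enzymes: tuple[str, str]
    multipliers: np.ndarray
    categories: np.ndarray          # (n, n) of category strings
    medium_72h: np.ndarray          # (n, n, 14) steroid medium conc
    failed: np.ndarray              # (n, n) bool, integration failures
    theta: float

    def category_at(self, mult_a: float, mult_b: float) -> str:
        i = int(np.argmin(np.abs(self.multipliers - mult_a)))
        j = int(np.argmin(np.abs(self.multipliers - mult_b)))
        return str(self.categories[i, j])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, a in enumerate(self.multipliers):
            for j, b in enumerate(self.multipliers):
                row = {
                    f"{self.enzymes[0].lower()}_pct": a * 100.0,
                    f"{self.enzymes[1].lower()}_pct": b * 100.0,
                    "category": self.categories[i, j],
                    "failed": bool(self.failed[i, j]),
                }
                row.update({s: self.medium_72h[i, j, k]
                            for k, s in enumerate(STEROIDS)})
                rows.append(row)
        return pd.DataFrame(rows)


def scan_2d(params: KineticParameterSet,
            enzymes: tuple[str, str] = ("CYP17H", "HSD3B2"),
            multipliers: np.ndarray | None = None,
            theta: float = 0.01,
            initial_state: np.ndarray | None = None,
            config: IntegratorConfig | None = None) -> ScanGrid:
    """Simulate and classify every cell of the 2-D activity grid.

    Defaults to the 21 x 21 grid of 0-200% in 10% steps.  Cells whose
    integration fails are flagged and the scan continues.
    """
    e0, e1 = enzymes
    for e in enzymes:
        if e not in ENZYMES:
            raise ValueError(f"unknown enzyme {e!r}")
    if multipliers is None:
        multipliers = np.round(np.arange(0.0, 2.0001, 0.1), 10)
    multipliers = np.asarray(multipliers, dtype=float)
    config = config or IntegratorConfig()
    if initial_state is None:
        initial_state = default_initial_state_vector()
    y0 = np.asarray(initial_state, dtype=float)

    n = len(multipliers)
    pairs = [(a, b) for a in multipliers for b in multipliers]
    A = np.ones((n * n, len(ENZYMES)))
    A[:, ENZYMES.index(e0)] = [a for a, _ in pairs]
    A[:, ENZYMES.index(e1)] = [b for _, b in pairs]

    Y0 = np.tile(y0, (n * n, 1))
    P = np.tile(params.to_vector(), (n * n, 1))
    finals, ok = _core.final_states_ensemble(
        Y0, P, A, params.geometry.to_vector(), params.dilution,
        config.duration, config.step_constant, config.dt_min, config.dt_max)

    baseline = simulate(params, None, config, y0).states[-1]
    med_idx = [medium_index(s) for s in STEROIDS]
    categories = np.empty((n, n), dtype=object)
    medium = np.empty((n, n, len(STEROIDS)))
    failed = np.zeros((n, n), dtype=bool)
    for k, (a, b) in enumerate(pairs):
        i, j = divmod(k, n)
        medium[i, j] = finals[k, med_idx]
        if not ok[k]:
            failed[i, j] = True
            categories[i, j] = "failed"
            continue
        categories[i, j] = classify_phenotype(finals[k], baseline, y0, theta)
    return ScanGrid(enzymes=(e0, e1), multipliers=multipliers,
                    categories=categories, medium_72h=medium,
                    failed=failed, theta=theta)
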