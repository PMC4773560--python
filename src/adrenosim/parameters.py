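"""Kinetic parameters, cell geometry, and the shipped default parameter set.

The kinetic inventory has 42 entries: nine transport/localization rate
constants (items 1-9) followed by the Km/Vmax constants of the nine
steroidogenic enzymes (items 10-42, substrate letters A/B/C fixed by the
reaction table in :mod:`adrenosim.species`).  On top of the inventory the
model needs one passive-diffusion clearance per steroid, the exponential
cell-growth law, and the medium volume.

Units
-----
concentrations      nmol/L
time                hours
rate constants      1/h
Vmax                nmol/L/h (intracellular volume basis)
Km                  nmol/L
diffusion clearance mL/h (amount flux = kdiff * (C_cell - C_medium) * 1e-3 L/mL)
volumes             mL

The shipped defaults are a plausibility-checked set, chosen so that the
simulated 72-h medium concentrations fall in the ranges and rank order
reported for stimulated NCI-H295R cells (PREG and the corticoid chain
dominate; ALDO, TESTO, and E2 are trace species).  They are NOT a measured
parameterization of any particular cell batch and should be replaced by a
calibrated set for quantitative work.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .species import STEROIDS

# ---------------------------------------------------------------------------
# Name inventories
# ---------------------------------------------------------------------------

TRANSPORT_NAMES = (
    "k_CholesterolTransport",  # medium cholesterol uptake
    "k_CEH",                   # cholesterol-ester hydrolysis CHOS -> CHOC
    "kf_MTR", "kb_MTR",        # cytosol <-> mitochondria transfer
    "kf_acc", "kb_acc",        # ester accumulation CHOC <-> CHOS
    "kf_loc", "kb_loc",        # StAR-mediated localization CHOR <-> CHON
    "k_OxysterolSynthesis",    # bypass CHOC -> OXY
)

ENZYME_PARAM_NAMES = (
    "Km_CYP11A1", "Vmax_CYP11A1",
    "KmA_CYP17H", "KmB_CYP17H", "VmaxA_CYP17H", "VmaxB_CYP17H",
    "KmA_CYP17L", "KmB_CYP17L", "VmaxA_CYP17L", "VmaxB_CYP17L",
    "KmA_HSD3B2", "KmB_HSD3B2", "KmC_HSD3B2",
    "VmaxA_HSD3B2", "VmaxB_HSD3B2", "VmaxC_HSD3B2",
    "KmA_CYP21A2", "KmB_CYP21A2", "VmaxA_CYP21A2", "VmaxB_CYP21A2",
    "KmA_CYP11B1", "KmB_CYP11B1", "VmaxA_CYP11B1", "VmaxB_CYP11B1",
    "k_CYP11B2",
    "KmA_HSD17B3", "KmB_HSD17B3", "VmaxA_HSD17B3", "VmaxB_HSD17B3",
    "KmA_CYP19A1", "KmB_CYP19A1", "VmaxA_CYP19A1", "VmaxB_CYP19A1",
)

#: The canonical 42-item kinetic inventory (transport constants, then enzyme
#: constants).  Positions are 0-based; item *n* of the conventional numbered
#: legend is ``INVENTORY_42[n - 1]``.
INVENTORY_42 = TRANSPORT_NAMES + ENZYME_PARAM_NAMES
assert len(INVENTORY_42) == 42

DIFFUSION_NAMES = tuple(f"kdiff_{s}" for s in STEROIDS)

#: Every kinetic parameter carried in the packed vector, in packing order.
PARAM_NAMES = INVENTORY_42 + DIFFUSION_NAMES
N_PARAMS = len(PARAM_NAMES)
PARAM_INDEX = {name: i for i, name in enumerate(PARAM_NAMES)}

GEOMETRY_NAMES = (
    "cell_count_0", "cell_growth_rate",
    "cell_volume_0_mL", "cell_volume_growth_rate",
    "medium_volume_mL",
)

_KM_NAMES = frozenset(n for n in PARAM_NAMES if n.startswith("Km"))


# ---------------------------------------------------------------------------
# Cell geometry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CellGeometry:
    """Exponential cell proliferation and the two compartment volumes.

    ``N(t) = N0 exp(gN t)`` cells of mean volume ``v(t) = v0 exp(gv t)`` mL;
    the total intracellular volume is their product and the medium volume is
    constant.
    """

    cell_count_0: float = 1.2e6
    cell_growth_rate: float = 0.010      # 1/h
    cell_volume_0_mL: float = 2.5e-9     # ~2.5 pL per cell
    cell_volume_growth_rate: float = 0.002  # 1/h
    medium_volume_mL: float = 2.0

    def __post_init__(self):
        for name in GEOMETRY_NAMES:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if min(self.cell_count_0, self.cell_volume_0_mL,
               self.medium_volume_mL) <= 0:
            raise ValueError("cell count, cell volume, and medium volume "
                             "must be positive")

    def cell_count(self, t: float) -> float:
        return self.cell_count_0 * np.exp(self.cell_growth_rate * t)

    def cell_volume(self, t: float) -> float:
        """Mean single-cell volume in mL at time t."""
        return self.cell_volume_0_mL * np.exp(self.cell_volume_growth_rate * t)

    def intracellular_volume_mL(self, t: float) -> float:
        return self.cell_count(t) * self.cell_volume(t)

    @property
    def total_growth_rate(self) -> float:
        """d ln(total intracellular volume)/dt, the dilution rate (1/h)."""
        return self.cell_growth_rate + self.cell_volume_growth_rate

    def to_vector(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in GEOMETRY_NAMES])


# ---------------------------------------------------------------------------
# Default values
# ---------------------------------------------------------------------------

#: Default kinetic values (see module docstring for provenance and caveats).
DEFAULT_VALUES: dict[str, float] = {
    # transport / localization (1/h)
    "k_CholesterolTransport": 2.0e-4,
    "k_CEH": 0.02,
    "kf_MTR": 0.10,
    "kb_MTR": 0.05,
    "kf_acc": 0.05,
    "kb_acc": 0.01,
    "kf_loc": 0.20,
    "kb_loc": 0.10,
    "k_OxysterolSynthesis": 0.02,
    # CYP11A1: CHON -> PREG
    "Km_CYP11A1": 8.0e3, "Vmax_CYP11A1": 6.0e3,
    # CYP17H: PREG -> HPREG (A), PROG -> HPROG (B)
    "KmA_CYP17H": 6.0e3, "KmB_CYP17H": 6.0e3,
    "VmaxA_CYP17H": 3.0e3, "VmaxB_CYP17H": 1.5e3,
    # CYP17L: HPREG -> DHEA (A), HPROG -> DIONE (B)
    "KmA_CYP17L": 8.0e3, "KmB_CYP17L": 8.0e3,
    "VmaxA_CYP17L": 750.0, "VmaxB_CYP17L": 500.0,
    # HSD3B2: PREG -> PROG (A), HPREG -> HPROG (B), DHEA -> DIONE (C)
    "KmA_HSD3B2": 6.0e3, "KmB_HSD3B2": 6.0e3, "KmC_HSD3B2": 6.0e3,
    "VmaxA_HSD3B2": 4.5e3, "VmaxB_HSD3B2": 2.0e3, "VmaxC_HSD3B2": 1.0e3,
    # CYP21A2: PROG -> DCORTICO (A), HPROG -> DCORT (B)
    "KmA_CYP21A2": 5.0e3, "KmB_CYP21A2": 5.0e3,
    "VmaxA_CYP21A2": 3.5e3, "VmaxB_CYP21A2": 3.0e3,
    # CYP11B1: DCORTICO -> CORTICO (A), DCORT -> CORT (B)
    "KmA_CYP11B1": 5.0e3, "KmB_CYP11B1": 5.0e3,
    "VmaxA_CYP11B1": 2.0e3, "VmaxB_CYP11B1": 1.75e3,
    # CYP11B2: CORTICO -> ALDO (first-order)
    "k_CYP11B2": 0.004,
    # HSD17B3: DIONE -> TESTO (A), E1 -> E2 (B)
    "KmA_HSD17B3": 8.0e3, "KmB_HSD17B3": 8.0e3,
    "VmaxA_HSD17B3": 75.0, "VmaxB_HSD17B3": 50.0,
    # CYP19A1: DIONE -> E1 (A), TESTO -> E2 (B)
    "KmA_CYP19A1": 8.0e3, "KmB_CYP19A1": 8.0e3,
    "VmaxA_CYP19A1": 125.0, "VmaxB_CYP19A1": 50.0,
}
# one passive-diffusion clearance per steroid (mL/h)
DEFAULT_VALUES.update({f"kdiff_{s}": 1.5e-3 for s in STEROIDS})

#: Default initial concentrations (nmol/L).  Steroid entries are medium
#: concentrations; intracellular steroid levels start at diffusion
#: equilibrium with the medium.
DEFAULT_INITIAL_STATE: dict[str, float] = {
    "CHOL": 2.0e5,
    "CHOS": 8.0e5,
    "CHOC": 2.0e5,
    "CHOM": 3.0e4,
    "CHON": 1.5e4,
    "CHOR": 3.0e4,
    "OXY": 0.0,
    "PREG": 5.0, "HPREG": 3.0, "DHEA": 2.0, "PROG": 3.0, "HPROG": 3.0,
    "DIONE": 1.0, "TESTO": 0.1, "DCORTICO": 10.0, "DCORT": 6.0,
    "CORTICO": 12.0, "CORT": 8.0, "ALDO": 0.05, "E1": 0.5, "E2": 0.02,
}


# ---------------------------------------------------------------------------
# Parameter set container
# ---------------------------------------------------------------------------


class KineticParameterSet:
    """The full parameterization: kinetic vector + cell geometry + switches.

    Parameters are accessed by canonical name (``params["Vmax_CYP11A1"]``).
    Unknown names are rejected with the list of expected names so that file
    typos surface immediately.
    """

    def __init__(self,
                 values: Mapping[str, float] | None = None,
                 geometry: CellGeometry | None = None,
                 dilution: bool = True,
                 partial: bool = False):
        base = dict(DEFAULT_VALUES) if partial else {}
        if values is not None:
            unknown = set(values) - set(PARAM_NAMES)
            if unknown:
                raise KeyError(
                    f"unknown parameter names {sorted(unknown)}; expected "
                    f"names from: {list(PARAM_NAMES)}")
            base.update(values)
        elif not partial:
            base = dict(DEFAULT_VALUES)
        if not partial:
            missing = set(PARAM_NAMES) - set(base)
            if missing:
                raise KeyError(f"missing parameters: {sorted(missing)}")
        self._values = {n: float(base[n]) for n in PARAM_NAMES if n in base}
        self.geometry = geometry if geometry is not None else CellGeometry()
        #: whether intracellular concentrations are diluted by volume growth
        self.dilution = bool(dilution)
        self.validate()

    # -- mapping-style access ------------------------------------------------

    def __getitem__(self, name: str) -> float:
        return self._values[name]

    def __setitem__(self, name: str, value: float) -> None:
        if name not in PARAM_INDEX:
            raise KeyError(f"unknown parameter {name!r}")
        self._values[name] = float(value)
        self._check_one(name, self._values[name])

    def __contains__(self, name: str) -> bool:
        return name in self._values

    def keys(self) -> Iterable[str]:
        return self._values.keys()

    def items(self):
        return self._values.items()

    # -- validation ----------------------------------------------------------

    @staticmethod
    def _check_one(name: str, value: float) -> None:
        if not np.isfinite(value):
            raise ValueError(f"{name} is not finite")
        if name in _KM_NAMES:
            if value <= 0:
                raise ValueError(f"Km parameter {name} must be > 0")
        elif value < 0:
            raise ValueError(f"{name} must be >= 0")

    def validate(self) -> None:
        for name, value in self._values.items():
            self._check_one(name, value)

    # -- conversions ----------------------------------------------------------

    def to_vector(self) -> np.ndarray:
        """Pack the kinetic values into the canonical order for the solver."""
        return np.array([self._values[n] for n in PARAM_NAMES])

    @classmethod
    def from_vector(cls, vector: np.ndarray,
                    geometry: CellGeometry | None = None,
                    dilution: bool = True) -> "KineticParameterSet":
        vector = np.asarray(vector, dtype=float)
        if vector.shape != (N_PARAMS,):
            raise ValueError(f"expected shape ({N_PARAMS},), got {vector.shape}")
        return cls(dict(zip(PARAM_NAMES, vector)), geometry=geometry,
                   dilution=dilution)

    def copy(self) -> "KineticParameterSet":
        return KineticParameterSet(dict(self._values),
                                   geometry=self.geometry,
                                   dilution=self.dilution)

    def with_updates(self, updates: Mapping[str, float]) -> "KineticParameterSet":
        values = dict(self._values)
        values.update(updates)
        return KineticParameterSet(values, geometry=self.geometry,
                                   dilution=self.dilution)

    def __eq__(self, other) -> bool:
        return (isinstance(other, KineticParameterSet)
                and self._values == other._values
                and self.geometry == other.geometry
                and self.dilution == other.dilution)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"KineticParameterSet({N_PARAMS} kinetic parameters, "
                f"dilution={self.dilution})")


def default_parameters() -> KineticParameterSet:
    """The shipped (non-authoritative) default parameter set."""
    return KineticParameterSet()


def default_initial_state_vector() -> np.ndarray:
    """Initial state vector with steroids at diffusion equilibrium."""
    from .species import N_STATE, POOL_INDEX, cell_index, medium_index

    vec = np.zeros(N_STATE)
    for pool, idx in POOL_INDEX.items():
        vec[idx] = DEFAULT_INITIAL_STATE[pool]
    for s in STEROIDS:
        vec[medium_index(s)] = DEFAULT_INITIAL_STATE[s]
        vec[cell_index(s)] = DEFAULT_INITIAL_STATE[s]
    return vec
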