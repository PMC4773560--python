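"""Species inventory, state-vector layout, and the reaction network.

The model tracks cholesterol through a chain of intracellular pools down to
the steroid products secreted into the culture medium:

* ``CHOL``  -- cholesterol in the culture medium (the supply),
* ``CHOS``  -- cholesterol esters stored in the endoplasmic reticulum,
* ``CHOC``  -- intracellular free cholesterol,
* ``CHOM``  -- mitochondrial free cholesterol,
* ``CHOR``  -- mitochondrial cholesterol remote from CYP11A1,
* ``CHON``  -- mitochondrial cholesterol adjacent to CYP11A1 (the StAR-
  delivered pool that feeds side-chain cleavage),
* ``OXY``   -- an oxysterol sink that drains free cholesterol out of the
  steroidogenic pathway,

plus 14 steroids, each present in the intracellular space and in the
culture medium.  All concentrations are in nmol/L and time is in hours.

The enzymatic network is the classical C21 steroid biosynthesis pathway:
17 reactions catalysed by 9 enzymes, where several enzymes accept more
than one steroid substrate (labelled A/B/C below).  Shared-site substrate
competition between those substrates is what gives the pathway its
characteristic branch-balancing behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

# ---------------------------------------------------------------------------
# Species inventory
# ---------------------------------------------------------------------------

#: Cholesterol / oxysterol pools, in state-vector order.  CHOL lives in the
#: medium; every other pool is intracellular.
CHOLESTEROL_POOLS = ("CHOL", "CHOS", "CHOC", "CHOM", "CHON", "CHOR", "OXY")

#: The 14 steroids, in state-vector order.
STEROIDS = (
    "PREG", "HPREG", "DHEA", "PROG", "HPROG", "DIONE", "TESTO",
    "DCORTICO", "DCORT", "CORTICO", "CORT", "ALDO", "E1", "E2",
)

#: The 12 steroids quantified by LC-MS/MS (E1/E2 are immunoassay species and
#: are excluded from fold-change profiles).
LCMS_STEROIDS = (
    "PREG", "HPREG", "DHEA", "PROG", "HPROG", "DIONE",
    "DCORTICO", "DCORT", "CORTICO", "CORT", "ALDO", "TESTO",
)

#: The nine steroidogenic enzymes.  CYP17H and CYP17L are the hydroxylase and
#: lyase activities of the same CYP17A1 protein, modelled as separate
#: activities as is conventional.
ENZYMES = (
    "CYP11A1", "CYP17H", "CYP17L", "HSD3B2", "CYP21A2",
    "CYP11B1", "CYP11B2", "HSD17B3", "CYP19A1",
)

#: Enzymes whose relative activity is estimated in mechanism-of-action
#: inference (CYP19A1 is held at its baseline activity).
MOA_ENZYMES = tuple(e for e in ENZYMES if e != "CYP19A1")

N_POOLS = len(CHOLESTEROL_POOLS)
N_STEROIDS = len(STEROIDS)
#: Total state dimension: 7 pools + 14 steroids x {cell, medium}.
N_STATE = N_POOLS + 2 * N_STEROIDS

# index helpers ------------------------------------------------------------

POOL_INDEX = {name: i for i, name in enumerate(CHOLESTEROL_POOLS)}
STEROID_INDEX = {name: i for i, name in enumerate(STEROIDS)}


def cell_index(steroid: str) -> int:
    """State-vector index of a steroid's intracellular concentration."""
    return N_POOLS + STEROID_INDEX[steroid]


def medium_index(steroid: str) -> int:
    """State-vector index of a steroid's culture-medium concentration."""
    return N_POOLS + N_STEROIDS + STEROID_INDEX[steroid]


#: Names of every state entry, in vector order.
STATE_NAMES = (
    CHOLESTEROL_POOLS
    + tuple(f"{s}_cell" for s in STEROIDS)
    + tuple(f"{s}_medium" for s in STEROIDS)
)


# ---------------------------------------------------------------------------
# Reaction network
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Reaction:
    """One enzymatic conversion (1:1 stoichiometry, intracellular)."""

    enzyme: str
    substrate: str
    product: str
    #: "competing" for shared-site rapid-equilibrium kinetics,
    #: "first_order" for a simple linear rate law.
    law: str
    #: Substrate letter within its enzyme (A/B/C); fixes the Km/Vmax naming.
    letter: str


#: The 17 enzymatic reactions of the pathway.
REACTIONS = (
    Reaction("CYP11A1", "CHON", "PREG", "competing", "A"),
    Reaction("CYP17H", "PREG", "HPREG", "competing", "A"),
    Reaction("CYP17H", "PROG", "HPROG", "competing", "B"),
    Reaction("CYP17L", "HPREG", "DHEA", "competing", "A"),
    Reaction("CYP17L", "HPROG", "DIONE", "competing", "B"),
    Reaction("HSD3B2", "PREG", "PROG", "competing", "A"),
    Reaction("HSD3B2", "HPREG", "HPROG", "competing", "B"),
    Reaction("HSD3B2", "DHEA", "DIONE", "competing", "C"),
    Reaction("CYP21A2", "PROG", "DCORTICO", "competing", "A"),
    Reaction("CYP21A2", "HPROG", "DCORT", "competing", "B"),
    Reaction("CYP11B1", "DCORTICO", "CORTICO", "competing", "A"),
    Reaction("CYP11B1", "DCORT", "CORT", "competing", "B"),
    Reaction("CYP11B2", "CORTICO", "ALDO", "first_order", "A"),
    Reaction("HSD17B3", "DIONE", "TESTO", "competing", "A"),
    Reaction("HSD17B3", "E1", "E2", "competing", "B"),
    Reaction("CYP19A1", "DIONE", "E1", "competing", "A"),
    Reaction("CYP19A1", "TESTO", "E2", "competing", "B"),
)


def reactions_of(enzyme: str) -> tuple[Reaction, ...]:
    """All reactions catalysed by ``enzyme``, in substrate-letter order."""
    return tuple(sorted((r for r in REACTIONS if r.enzyme == enzyme),
                        key=lambda r: r.letter))


def _validate_network() -> None:
    assert len(REACTIONS) == 17
    assert len({r.enzyme for r in REACTIONS}) == 9
    produced = {r.product for r in REACTIONS}
    for s in STEROIDS:
        if s != "PREG":
            assert s in produced, s


_validate_network()


# ---------------------------------------------------------------------------
# State container
# ---------------------------------------------------------------------------


class SpeciesState:
    """A concentration state: 7 cholesterol pools + 14 steroids x 2 compartments.

    Thin wrapper over a length-35 float vector (nmol/L) with named access.
    """

    __slots__ = ("vector",)

    def __init__(self, vector: Sequence[float] | np.ndarray | None = None):
        if vector is None:
            vector = np.zeros(N_STATE)
        vec = np.asarray(vector, dtype=float)
        if vec.shape != (N_STATE,):
            raise ValueError(
                f"state vector must have shape ({N_STATE},), got {vec.shape}")
        self.vector = vec

    # -- named access ------------------------------------------------------

    def pool(self, name: str) -> float:
        return float(self.vector[POOL_INDEX[name]])

    def cell(self, steroid: str) -> float:
        return float(self.vector[cell_index(steroid)])

    def medium(self, steroid: str) -> float:
        return float(self.vector[medium_index(steroid)])

    def set_pool(self, name: str, value: float) -> None:
        self.vector[POOL_INDEX[name]] = value

    def set_cell(self, steroid: str, value: float) -> None:
        self.vector[cell_index(steroid)] = value

    def set_medium(self, steroid: str, value: float) -> None:
        self.vector[medium_index(steroid)] = value

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        """Raise if any entry is negative (beyond round-off) or non-finite."""
        if not np.all(np.isfinite(self.vector)):
            bad = [STATE_NAMES[i] for i in
                   np.nonzero(~np.isfinite(self.vector))[0]]
            raise ValueError(f"non-finite concentrations: {bad}")
        if np.any(self.vector < -1e-9):
            bad = [STATE_NAMES[i] for i in np.nonzero(self.vector < -1e-9)[0]]
            raise ValueError(f"negative concentrations: {bad}")

    def copy(self) -> "SpeciesState":
        return SpeciesState(self.vector.copy())

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        tot = float(self.vector.sum())
        return f"SpeciesState(n={N_STATE}, total={tot:.4g} nmol/L)"
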