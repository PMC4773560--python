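"""Model-level operations: the assembled ODE right-hand side and mass audit.

The pathway wiring implemented here:

* ``CHOL -> CHOC`` first-order uptake from the medium,
* ``CHOC <-> CHOS`` ester accumulation (``kf_acc``/``kb_acc``) plus
  hydrolase release (``k_CEH``),
* ``CHOC <-> CHOM <-> CHOR`` mitochondrial import and partition toward the
  CYP11A1-remote pool (both legs share ``kf_MTR``/``kb_MTR``),
* ``CHOR <-> CHON`` StAR-mediated localization (``kf_loc``/``kb_loc``),
* ``CHOC -> OXY`` irreversible oxysterol bypass,
* the 17 enzymatic reactions (competing-substrate kinetics, CYP11B2
  first-order) acting on intracellular concentrations,
* per-steroid passive diffusion between the cell and the medium with
  volume-correct amount bookkeeping,
* dilution of intracellular concentrations by exponential volume growth
  (switchable; with the switch on, dilution exactly compensates volume
  growth so total molar amount is conserved).
"""

from __future__ import annotations

import numpy as np

from . import _core
from .parameters import KineticParameterSet
from .species import N_POOLS, N_STATE, SpeciesState, STATE_NAMES


def ode_rhs(t: float,
            state: np.ndarray | SpeciesState,
            params: KineticParameterSet,
            activities: np.ndarray | None = None) -> np.ndarray:
    """Time derivative of the full state vector at time ``t`` (hours).

    ``activities`` is the 9-vector of relative enzyme activities in
    :data:`adrenosim.species.ENZYMES` order (default: all 1).  Raises with
    the offending species name if the derivative is non-finite.
    """
    y = state.vector if isinstance(state, SpeciesState) else np.asarray(state, float)
    if y.shape != (N_STATE,):
        raise ValueError(f"state must have shape ({N_STATE},)")
    if activities is None:
        activities = np.ones(9)
    activities = np.asarray(activities, dtype=float)
    if activities.shape != (9,):
        raise ValueError("activities must be a length-9 vector")
    if np.any(activities < 0):
        raise ValueError("enzyme activities must be nonnegative")
    dy = np.empty(N_STATE)
    _core.rhs(float(t), y, params.to_vector(), activities,
              params.geometry.to_vector(), params.dilution, dy)
    if not np.all(np.isfinite(dy)):
        bad = [STATE_NAMES[i] for i in np.nonzero(~np.isfinite(dy))[0]]
        raise FloatingPointError(f"non-finite derivative for species: {bad}")
    return dy


def total_mass(state: np.ndarray | SpeciesState,
               params: KineticParameterSet,
               t: float = 0.0) -> float:
    """Total moles (nmol) of cholesterol-derived material at time ``t``.

    Sums concentration x compartment volume over every pool and steroid in
    both compartments, including the OXY sink.  Along a trajectory of the
    full model (dilution on) this quantity is conserved.
    """
    y = state.vector if isinstance(state, SpeciesState) else np.asarray(state, float)
    geom = params.geometry
    vc_L = geom.intracellular_volume_mL(t) * 1e-3
    vm_L = geom.medium_volume_mL * 1e-3
    medium = y[_core.I_CHOL] * vm_L + y[_core.MED0:].sum() * vm_L
    intracellular = (y[1:N_POOLS].sum() + y[_core.CELL0:_core.MED0].sum()) * vc_L
    return float(medium + intracellular)
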