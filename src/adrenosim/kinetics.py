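"""Rate laws: shared-site competing-substrate kinetics and first-order flux.

Most steroidogenic enzymes accept several steroid substrates at one active
site.  Under the rapid-equilibrium assumption each substrate's turnover is

    v_i = a * Vmax_i * (S_i / Km_i) / (1 + sum_j S_j / Km_j)

where ``a`` is a relative-activity multiplier (1 = unperturbed enzyme).
Every competing substrate appears in the shared denominator, so raising one
substrate depresses the turnover of the others -- the substrate-inhibition
behaviour that shapes branch balance in the pathway.
"""

from __future__ import annotations

import numpy as np


def competing_substrate_rates(vmax, km, s, activity: float = 1.0) -> np.ndarray:
    """Per-substrate turnover of a shared-site enzyme.

    Parameters
    ----------
    vmax, km, s
        Same-length sequences: maximum rates, Michaelis constants, and
        substrate concentrations for each competing substrate.
    activity
        Relative enzyme activity multiplier (>= 0).

    Returns
    -------
    numpy.ndarray
        ``rate[i] = activity * vmax[i] * (s[i]/km[i]) / (1 + sum_j s[j]/km[j])``.
        Each rate lies in ``[0, activity * vmax[i]]``.
    """
    vmax = np.asarray(vmax, dtype=float)
    km = np.asarray(km, dtype=float)
    s = np.asarray(s, dtype=float)
    if not (vmax.shape == km.shape == s.shape) or vmax.ndim != 1 or vmax.size < 1:
        raise ValueError("vmax, km, and s must be 1-d sequences of equal length")
    if np.any(km <= 0):
        raise ValueError("Km values must be positive")
    if np.any(vmax < 0) or np.any(s < 0) or activity < 0:
        raise ValueError("vmax, s, and activity must be nonnegative")
    occupancy = s / km
    return activity * vmax * occupancy / (1.0 + occupancy.sum())


def first_order_flux(k: float, s: float) -> float:
    """Linear rate law ``flux = k * s`` (used for transport and CYP11B2)."""
    if k < 0 or s < 0:
        raise ValueError("rate constant and concentration must be nonnegative")
    return k * s
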