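"""Genetic map functions.

A map function converts a recombination fraction ``r`` (probability of an
odd number of crossovers between two loci in one meiosis, bounded by 0.5)
into an additive map distance in centimorgans, and back.  Haldane's function
assumes crossovers occur with no interference (a Poisson process along the
chromosome); Kosambi's allows partial positive interference and is the
function used to assign positions on the linkage map.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "kosambi_cm",
    "kosambi_inv",
    "haldane_cm",
    "haldane_inv",
    "MAP_FUNCTIONS",
]


def kosambi_cm(r):
    """Kosambi map distance d = 25*ln((1+2r)/(1-2r)) in cM.

    Raises ``ValueError`` for r >= 0.5, where the distance is undefined.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0) or np.any(r >= 0.5):
        raise ValueError("recombination fraction must lie in [0, 0.5)")
    d = 25.0 * np.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))
    return d if d.ndim else float(d)


def kosambi_inv(d_cm):
    """Inverse Kosambi: r = 0.5*tanh(d/50) for d >= 0 cM."""
    d = np.asarray(d_cm, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be nonnegative")
    r = 0.5 * np.tanh(d / 50.0)
    return r if r.ndim else float(r)


def haldane_cm(r):
    """Haldane map distance d = -50*ln(1-2r) in cM."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0) or np.any(r >= 0.5):
        raise ValueError("recombination fraction must lie in [0, 0.5)")
    d = -50.0 * np.log(1.0 - 2.0 * r)
    return d if d.ndim else float(d)


def haldane_inv(d_cm):
    """Inverse Haldane: r = (1 - exp(-d/50))/2."""
    d = np.asarray(d_cm, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be nonnegative")
    r = 0.5 * (1.0 - np.exp(-d / 50.0))
    return r if r.ndim else float(r)


MAP_FUNCTIONS = {
    "kosambi": (kosambi_cm, kosambi_inv),
    "haldane": (haldane_cm, haldane_inv),
}
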