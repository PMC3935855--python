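"""Competitive Langmuir sorption.

Maps instantaneous analyte concentrations to the fraction of a sensor's
binding sites occupied by each analyte.  The multicomponent (extended)
Langmuir isotherm is used:

    x_j = K_j c_j / (1 + sum_k K_k c_k)

It is competitive — raising the concentration of one analyte strictly
lowers the sorbed fraction of every other analyte present — bounded
(0 <= x_j < 1, sum x_j < 1), linear at low concentrations and saturating
at high ones.  Larger affinity magnitudes (the ``alpha`` scaling) push the
response deeper into the nonlinear regime.
"""

from __future__ import annotations

import numpy as np

__all__ = ["langmuir_sorbed", "sorbed_fractions", "mixture_suppression_check"]


def langmuir_sorbed(affinity, conc) -> np.ndarray:
    """Sorbed fractions for one concentration vector.

    Parameters
    ----------
    affinity : array-like, shape (3,)
        Langmuir constants K_j, strictly positive, in 1/(vol.%).
    conc : array-like, shape (3,)
        Analyte concentrations c_j in vol.%, nonnegative.

    Returns
    -------
    ndarray, shape (3,)
        x_j = K_j c_j / (1 + sum K_k c_k).
    """
    K = np.asarray(affinity, float)
    c = np.asarray(conc, float)
    if np.any(K <= 0):
        raise ValueError("affinities must be strictly positive")
    if np.any(c < 0):
        raise ValueError("concentrations must be nonnegative")
    kc = K * c
    return kc / (1.0 + kc.sum())


def sorbed_fractions(affinity, conc_matrix) -> np.ndarray:
    """Vectorized sorption for an ``n x 3`` concentration matrix."""
    K = np.asarray(affinity, float)
    C = np.atleast_2d(np.asarray(conc_matrix, float))
    if np.any(K <= 0):
        raise ValueError("affinities must be strictly positive")
    if np.any(C < 0):
        raise ValueError("concentrations must be nonnegative")
    kc = C * K
    return kc / (1.0 + kc.sum(axis=1, keepdims=True))


def mixture_suppression_check(affinity, conc, j: int, k: int, delta: float) -> bool:
    """Check the competitive-suppression property at one point.

    Returns True iff the sorbed fraction of analyte ``j`` strictly
    decreases when the concentration of a competitor analyte ``k`` is
    raised by ``delta`` — or vacuously, when ``c_j`` is zero and the sorbed
    fraction stays at zero.  Under the competitive Langmuir law this holds
    at every point with ``c_j > 0``.
    """
    if not (0 <= j < 3) or not (0 <= k < 3):
        raise ValueError("analyte indices must be in 0..2")
    if j == k:
        raise ValueError("the perturbed channel must differ from the observed one")
    if delta <= 0:
        raise ValueError("delta must be > 0")
    c = np.asarray(conc, float)
    x_before = langmuir_sorbed(affinity, c)
    c_after = c.copy()
    c_after[k] += delta
    x_after = langmuir_sorbed(affinity, c_after)
    if c[j] == 0:
        return x_after[j] == 0.0
    return x_after[j] < x_before[j]
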