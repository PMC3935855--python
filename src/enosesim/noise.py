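"""The three stochastic injectors: concentration, sensor and drift noise.

Each injector takes a scaling level (``csd``, ``ssd``, ``dsd``) calibrated
so that 0 means noise-free and 1 means the reference noise level; output
variance scales with the square of the level.

* Concentration noise perturbs the delivered analyte concentrations with a
  zero-mean Gaussian of covariance ``csd^2 * cov``, applied only to the
  channels actually present in the gas (delivery imprecision does not
  create phantom analytes) and clipped at zero.
* Sensor noise perturbs a sensor's sensitivity vector once per pulse with
  covariance ``ssd^2 * cov``.
* Drift is a random walk in a fixed low-rank subspace of sensor space:
  a latent coordinate vector z (one entry per drift component) advances
  once per pulse with independent Gaussian steps of variance
  ``dsd^2 * step_sd^2 * ndvar_i``, and the per-sensor offsets are ``D z``
  where D has unit-norm columns.  Offsets are constant within a pulse, so
  baseline-subtracted (step) features cancel drift exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DriftState",
    "psd_factor",
    "add_concentration_noise",
    "add_sensor_noise",
    "advance_drift",
    "set_noise_levels",
]


def psd_factor(cov) -> np.ndarray:
    """A matrix L with L L^T = cov, for drawing correlated Gaussians.

    Uses Cholesky when the matrix is positive definite and falls back to an
    eigendecomposition with clipped eigenvalues for the semi-definite case.
    """
    cov = np.asarray(cov, float)
    try:
        return np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(cov)
        return v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))


def add_concentration_noise(conc_row, csd: float, cov, rng, factor=None) -> np.ndarray:
    """Perturb one concentration row; identity at ``csd = 0``."""
    if csd < 0:
        raise ValueError("csd must be >= 0")
    c = np.asarray(conc_row, float).copy()
    if csd == 0:
        return c
    L = psd_factor(cov) if factor is None else factor
    eps = csd * (L @ rng.standard_normal(L.shape[1]))
    mask = c > 0
    c[mask] = np.clip(c[mask] + eps[mask], 0.0, None)
    return c


def add_sensor_noise(sensitivity, ssd: float, cov, rng, factor=None) -> np.ndarray:
    """Perturb a sensitivity vector; identity at ``ssd = 0``."""
    if ssd < 0:
        raise ValueError("ssd must be >= 0")
    b = np.asarray(sensitivity, float).copy()
    if ssd == 0:
        return b
    L = psd_factor(cov) if factor is None else factor
    return b + ssd * (L @ rng.standard_normal(L.shape[1]))


@dataclass
class DriftState:
    """Latent drift coordinates plus the subspace they live in."""

    basis: np.ndarray           # nsensors x ndcomp, unit-norm columns
    importance: np.ndarray      # ndvar, length ndcomp, entries in [0, 1]
    step_sd: float              # per-pulse walk scale at dsd = 1
    z: np.ndarray = None        # latent coordinates, length ndcomp

    def __post_init__(self):
        self.basis = np.asarray(self.basis, float)
        self.importance = np.asarray(self.importance, float)
        ndcomp = self.basis.shape[1]
        if not (1 <= ndcomp <= 3):
            raise ValueError("the number of drift components must be 1, 2 or 3")
        if self.importance.shape != (ndcomp,):
            raise ValueError("importance length must match the number of components")
        if np.any(self.importance < 0) or np.any(self.importance > 1):
            raise ValueError("drift importances must lie in [0, 1]")
        norms = np.linalg.norm(self.basis, axis=0)
        if not np.allclose(norms, 1.0):
            raise ValueError("drift basis columns must have unit norm")
        if self.z is None:
            self.z = np.zeros(ndcomp)


def advance_drift(state: DriftState, dsd: float, rng):
    """Advance the drift walk one pulse; returns ``(state, offsets)``.

    The latent step is zero-mean Gaussian with diagonal covariance
    ``dsd^2 * step_sd^2 * diag(ndvar)``; the per-sensor offsets are the
    image of the updated coordinates under the basis.  At ``dsd = 0`` the
    state never moves and the offsets are identically zero.
    """
    if dsd < 0:
        raise ValueError("dsd must be >= 0")
    xi = rng.standard_normal(state.z.shape[0])
    state.z = state.z + dsd * state.step_sd * np.sqrt(state.importance) * xi
    return state, state.basis @ state.z


def set_noise_levels(array, value=None, *, csd=None, ssd=None, dsd=None, dcsd=None):
    """Update an array's noise levels in place (usable mid-simulation).

    ``value`` sets all three levels at once; the keyword arguments set them
    individually.  ``dcsd`` is accepted as an alias for ``dsd``.  Returns
    the array for chaining.
    """
    if dcsd is not None:
        if dsd is not None:
            raise ValueError("pass either dsd or its alias dcsd, not both")
        dsd = dcsd
    if value is not None:
        csd = ssd = dsd = value
    for name, level in (("csd", csd), ("ssd", ssd), ("dsd", dsd)):
        if level is None:
            continue
        if level < 0:
            raise ValueError(f"{name} must be >= 0")
        setattr(array, name, float(level))
    return array
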