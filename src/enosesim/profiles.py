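"""Sensor prototype bank.

A virtual sensor array is assembled from a bank of 17 sensor prototypes,
each prototype describing one conducting-polymer sensor type: its Langmuir
sorption affinities for the three analytes A (ammonia), B (propanoic acid)
and C (n-butanol), its calibration coefficients (baseline plus per-analyte
sensitivities), the half-widths of the uniform diversity distributions the
``beta`` scaling draws replica coefficients from, the covariance of the
per-pulse sensor-noise perturbation of the coefficients, and the rise/decay
time constants of the first-order transient response.

The bank is synthetic but structured: prototype types 1-3 are selective for
analyte C, types 13, 14 and 17 are selective for analyte A and carry a much
larger A-channel coefficient-noise variance (they respond "noisily" to A),
and the remaining types interpolate diverse selectivity patterns.  The bank
also owns the array-level noise parameterization: the concentration-noise
covariance, the drift-basis generator and the drift importance defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GAS_NAMES",
    "CONC_RANGES",
    "CONC_MIDPOINTS",
    "N_TYPES",
    "SensorProfile",
    "ProfileBank",
    "generate_profile_bank",
    "scale_affinities",
    "sample_sensitivities",
    "write_bank_csv",
    "read_bank_csv",
]

#: Analyte labels, in column order.
GAS_NAMES = ("A", "B", "C")

#: Dynamic range of each analyte in vol.% (A: ammonia, B: propanoic acid,
#: C: n-butanol).  Concentrations outside these ranges are legal inputs
#: (the saturation region is a documented use case) but trigger warnings.
CONC_RANGES = {"A": (0.01, 0.05), "B": (0.01, 0.05), "C": (0.1, 1.0)}

#: Midpoint of each dynamic range, used to anchor the selectivity structure.
CONC_MIDPOINTS = np.array([0.03, 0.03, 0.55])

#: Number of sensor prototypes in a bank.
N_TYPES = 17

# Base A-vs-C selectivity fraction per type (fraction of the mid-range
# occupancy owed to analyte A).  Types 1-3 low (C-selective), types
# 13/14/17 high (A-selective); the rest span the middle.  A small seeded
# jitter is added on top, narrow enough that the group ordering holds for
# every seed.
_BASE_A_SELECTIVITY = np.array(
    [0.10, 0.14, 0.18,                       # types 1-3: C-affine
     0.26, 0.32, 0.38, 0.44, 0.50, 0.56,     # types 4-9
     0.62, 0.68, 0.74,                       # types 10-12
     0.84, 0.88,                             # types 13-14: A-affine
     0.58, 0.36,                             # types 15-16
     0.92]                                   # type 17: A-affine
)
_SELECTIVITY_JITTER = 0.02

#: Sensor types whose response to analyte A is very noisy.
NOISY_A_TYPES = (13, 14, 17)

# Coefficient-noise relative standard deviation at reference level
# (ssd = 1): 5% of the coefficient, inflated to 25% on the A channel for
# the noisy-in-A types.
_COEFF_NOISE_REL = 0.05
_COEFF_NOISE_REL_NOISY_A = 0.25

# Concentration-delivery noise at reference level (csd = 1): standard
# deviation equal to 10% of each analyte's dynamic-range midpoint.
_CONC_NOISE_REL = 0.10

# Per-pulse drift random-walk scale (signal units) at dsd = 1.
_DRIFT_STEP_SD = 0.1

_SEED_MOD = 2**63


def _seed_entry(seed: int) -> int:
    """Map an arbitrary integer to a nonnegative SeedSequence entry."""
    return int(seed) % _SEED_MOD


@dataclass(frozen=True)
class SensorProfile:
    """Parameters of one sensor prototype.

    Attributes
    ----------
    type_id : int
        Prototype index in 1..17.
    affinity : ndarray, shape (3,)
        Langmuir sorption affinities K_j, one per analyte, in 1/(vol.%).
    baseline : float
        Air-level signal b0 (arbitrary signal units).
    sensitivity : ndarray, shape (3,)
        Calibration coefficients b_j: signal gain per unit sorbed fraction.
    sensitivity_halfwidth : ndarray, shape (3,)
        Relative half-width h_j of the uniform diversity distribution per
        analyte; the ``beta`` scaling factor multiplies it.
    coeff_noise_cov : ndarray, shape (3, 3)
        Covariance of the per-pulse sensor-noise perturbation of the
        sensitivity vector, at noise level 1.
    tau_rise, tau_decay : float
        First-order time constants (time units) of the transient response
        during exposition and cleaning respectively.
    """

    type_id: int
    affinity: np.ndarray
    baseline: float
    sensitivity: np.ndarray
    sensitivity_halfwidth: np.ndarray
    coeff_noise_cov: np.ndarray
    tau_rise: float
    tau_decay: float

    def __post_init__(self):
        object.__setattr__(self, "affinity", np.asarray(self.affinity, float))
        object.__setattr__(self, "sensitivity", np.asarray(self.sensitivity, float))
        object.__setattr__(
            self, "sensitivity_halfwidth", np.asarray(self.sensitivity_halfwidth, float)
        )
        object.__setattr__(
            self, "coeff_noise_cov", np.asarray(self.coeff_noise_cov, float)
        )
        if not (1 <= self.type_id <= N_TYPES):
            raise ValueError(f"type_id must be in 1..{N_TYPES}, got {self.type_id}")
        if self.affinity.shape != (3,) or np.any(self.affinity <= 0):
            raise ValueError("affinity must be a strictly positive 3-vector")
        if np.any(self.sensitivity_halfwidth < 0):
            raise ValueError("sensitivity_halfwidth entries must be >= 0")
        if self.tau_rise < 1 or self.tau_decay < 1:
            raise ValueError("transient time constants must be >= 1")
        cov = self.coeff_noise_cov
        if cov.shape != (3, 3) or not np.allclose(cov, cov.T):
            raise ValueError("coeff_noise_cov must be a symmetric 3x3 matrix")
        if np.any(np.linalg.eigvalsh(cov) < -1e-12):
            raise ValueError("coeff_noise_cov must be positive semi-definite")


@dataclass(frozen=True)
class ProfileBank:
    """The 17-prototype bank plus array-level noise parameters."""

    profiles: tuple
    conc_noise_cov: np.ndarray
    drift_importance_default: tuple = (0.86, 0.06, 0.05)
    drift_step_sd: float = _DRIFT_STEP_SD
    bank_seed: int = 0

    def __post_init__(self):
        object.__setattr__(
            self, "conc_noise_cov", np.asarray(self.conc_noise_cov, float)
        )
        if len(self.profiles) != N_TYPES:
            raise ValueError(f"a bank holds exactly {N_TYPES} profiles")
        ids = [p.type_id for p in self.profiles]
        if ids != list(range(1, N_TYPES + 1)):
            raise ValueError("profiles must be ordered with type_ids 1..17")
        if not all(0.0 <= v <= 1.0 for v in self.drift_importance_default):
            raise ValueError("drift importances must lie in [0, 1]")

    def profile(self, type_id: int) -> SensorProfile:
        if not (1 <= type_id <= N_TYPES):
            raise ValueError(f"sensor type must be in 1..{N_TYPES}, got {type_id}")
        return self.profiles[type_id - 1]

    def drift_basis(self, nsensors: int) -> np.ndarray:
        """Realize the drift subspace basis for an array of ``nsensors``.

        Returns an ``nsensors x min(3, nsensors)`` matrix with orthonormal
        (hence unit-norm) columns, deterministic in ``(bank_seed, nsensors)``.
        Arrays of different sizes get different but reproducible bases.
        """
        if nsensors < 1:
            raise ValueError("nsensors must be >= 1")
        ncols = min(3, nsensors)
        rng = np.random.default_rng(
            np.random.SeedSequence([_seed_entry(self.bank_seed), 4, nsensors])
        )
        g = rng.standard_normal((nsensors, ncols))
        q, r = np.linalg.qr(g)
        # fix the sign convention so the basis is unique
        q = q * np.sign(np.diag(r))
        return q


def generate_profile_bank(bank_seed: int = 0) -> ProfileBank:
    """Generate the synthetic 17-type prototype bank.

    The bank is a pure function of ``bank_seed``: calling it twice with the
    same seed yields bitwise-identical parameters.  For any seed the
    selectivity structure is preserved: types 1-3 satisfy
    ``K_C * mid_C > K_A * mid_A`` (C-selective at mid-range concentrations),
    types 13, 14 and 17 the reverse, and the latter group carries a larger
    A-channel coefficient-noise variance.

    Parameters
    ----------
    bank_seed : int
        Any integer; negative seeds are folded into the valid range.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([_seed_entry(bank_seed), 0])
    )
    mid_a, mid_b, mid_c = CONC_MIDPOINTS

    jitter = rng.uniform(-_SELECTIVITY_JITTER, _SELECTIVITY_JITTER, N_TYPES)
    a_frac = _BASE_A_SELECTIVITY + jitter
    # total mid-range occupancy K.c at alpha = 1; moderate, so the default
    # alpha = 2.25 pushes the upper dynamic range into visible saturation
    occupancy = rng.uniform(0.4, 0.9, N_TYPES)
    b_frac = rng.uniform(0.10, 0.30, N_TYPES)  # B is a minor interferent

    profiles = []
    for i in range(N_TYPES):
        type_id = i + 1
        k_a = a_frac[i] * occupancy[i] / mid_a
        k_c = (1.0 - a_frac[i]) * occupancy[i] / mid_c
        k_b = b_frac[i] * occupancy[i] / mid_b
        affinity = np.array([k_a, k_b, k_c])

        sensitivity = rng.uniform(2.0, 6.0, 3)
        halfwidth = np.full(3, 0.1)

        rel = np.full(3, _COEFF_NOISE_REL)
        if type_id in NOISY_A_TYPES:
            rel[0] = _COEFF_NOISE_REL_NOISY_A
        coeff_cov = np.diag((rel * sensitivity) ** 2)

        tau_rise, tau_decay = rng.uniform(4.0, 10.0, 2)

        profiles.append(
            SensorProfile(
                type_id=type_id,
                affinity=affinity,
                baseline=1.0,
                sensitivity=sensitivity,
                sensitivity_halfwidth=halfwidth,
                coeff_noise_cov=coeff_cov,
                tau_rise=tau_rise,
                tau_decay=tau_decay,
            )
        )

    conc_sd = _CONC_NOISE_REL * CONC_MIDPOINTS
    conc_cov = np.diag(conc_sd**2)
    return ProfileBank(
        profiles=tuple(profiles),
        conc_noise_cov=conc_cov,
        bank_seed=int(bank_seed),
    )


def scale_affinities(affinity, alpha: float) -> np.ndarray:
    """Scale sorption affinities by the nonlinearity factor ``alpha``.

    The scaling is plain elementwise multiplication, so the relative
    relationship between analytes and across the 17 sorption profiles is
    preserved; ``alpha = 1`` is the identity.  ``alpha`` must be strictly
    positive — zero would void the sorption model.
    """
    if alpha <= 0:
        raise ValueError("alpha must be > 0 (the value of zero is not allowed)")
    return alpha * np.asarray(affinity, float)


def sample_sensitivities(profile: SensorProfile, beta: float, rng) -> tuple:
    """Draw replica calibration coefficients for one sensor.

    With ``beta = 0`` the prototype coefficients are returned verbatim.
    With ``beta > 0`` each sensitivity ``b_j`` is drawn from
    ``Uniform(b_j (1 - beta h_j), b_j (1 + beta h_j))`` where ``h_j`` is the
    prototype's relative half-width, so the spread of replicas grows
    monotonically with ``beta``.  The baseline is never perturbed.

    Returns ``(baseline, sensitivity)``.
    """
    if beta < 0:
        raise ValueError("beta must be >= 0")
    b = profile.sensitivity
    if beta == 0:
        return profile.baseline, b.copy()
    half = beta * profile.sensitivity_halfwidth * np.abs(b)
    drawn = rng.uniform(b - half, b + half)
    return profile.baseline, drawn


# ---------------------------------------------------------------------------
# CSV round trip

_PROFILE_COLS = [
    "type_id", "K_A", "K_B", "K_C", "b0", "b_A", "b_B", "b_C",
    "h_A", "h_B", "h_C", "tau_rise", "tau_decay",
]


def write_bank_csv(bank: ProfileBank, profiles_path, cov_path) -> None:
    """Export a bank as two CSV files: per-type parameters and covariances.

    The covariance file holds all 3x3 matrices in long format plus the
    bank-level scalars (seed, drift step scale, drift importances) under the
    ``bank_meta`` pseudo-matrix.  Values survive the round trip exactly.
    """
    rows = []
    for p in bank.profiles:
        rows.append(
            [p.type_id, *p.affinity, p.baseline, *p.sensitivity,
             *p.sensitivity_halfwidth, p.tau_rise, p.tau_decay]
        )
    pd.DataFrame(rows, columns=_PROFILE_COLS).to_csv(profiles_path, index=False)

    cov_rows = []
    for i in range(3):
        for j in range(3):
            cov_rows.append(["conc", i, j, bank.conc_noise_cov[i, j]])
    for p in bank.profiles:
        for i in range(3):
            for j in range(3):
                cov_rows.append([f"type{p.type_id:02d}", i, j, p.coeff_noise_cov[i, j]])
    cov_rows.append(["bank_meta", "bank_seed", "", float(bank.bank_seed)])
    cov_rows.append(["bank_meta", "drift_step_sd", "", bank.drift_step_sd])
    for i, v in enumerate(bank.drift_importance_default):
        cov_rows.append(["bank_meta", f"ndvar{i + 1}", "", v])
    pd.DataFrame(cov_rows, columns=["matrix", "row", "col", "value"]).to_csv(
        cov_path, index=False
    )


def read_bank_csv(profiles_path, cov_path) -> ProfileBank:
    """Rebuild a :class:`ProfileBank` from the two CSV files."""
    prof_df = pd.read_csv(profiles_path, float_precision="round_trip")
    missing = set(_PROFILE_COLS) - set(prof_df.columns)
    if missing:
        raise ValueError(f"profiles CSV is missing columns: {sorted(missing)}")
    cov_df = pd.read_csv(cov_path, float_precision="round_trip")

    def matrix(name: str) -> np.ndarray:
        sub = cov_df[cov_df["matrix"] == name]
        m = np.zeros((3, 3))
        for _, r in sub.iterrows():
            m[int(r["row"]), int(r["col"])] = r["value"]
        return m

    meta = cov_df[cov_df["matrix"] == "bank_meta"].set_index("row")["value"]
    ndvar = tuple(
        float(meta[k]) for k in sorted(m for m in meta.index if str(m).startswith("ndvar"))
    )

    profiles = []
    for _, r in prof_df.sort_values("type_id").iterrows():
        tid = int(r["type_id"])
        profiles.append(
            SensorProfile(
                type_id=tid,
                affinity=np.array([r["K_A"], r["K_B"], r["K_C"]]),
                baseline=float(r["b0"]),
                sensitivity=np.array([r["b_A"], r["b_B"], r["b_C"]]),
                sensitivity_halfwidth=np.array([r["h_A"], r["h_B"], r["h_C"]]),
                coeff_noise_cov=matrix(f"type{tid:02d}"),
                tau_rise=float(r["tau_rise"]),
                tau_decay=float(r["tau_decay"]),
            )
        )
    return ProfileBank(
        profiles=tuple(profiles),
        conc_noise_cov=matrix("conc"),
        drift_importance_default=ndvar,
        drift_step_sd=float(meta["drift_step_sd"]),
        bank_seed=int(meta["bank_seed"]),
    )
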