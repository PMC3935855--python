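"""The virtual sensor array: profiles + scaling + dynamics + noise.

:class:`SensorArray` assembles ``nsensors`` virtual sensors from the
prototype bank.  Each sensor adopts one of the 17 prototypes (slot
``num``; when fewer types than sensors are given the types recycle
cyclically), its affinities are scaled by ``alpha`` and its calibration
coefficients re-drawn with diversity ``beta``, so two sensors of the same
type are distinct replicas unless ``beta = 0``.

``predict`` maps an (annotated or raw) concentration matrix to the sensor
signal matrix.  The per-row pipeline is: concentration noise (one draw per
pulse) -> competitive Langmuir sorption -> steady-state target with the
pulse's sensor-noise-perturbed coefficients -> first-order transient
advance (bypassed when ``tunit`` is 1) -> plus the pulse's drift offset.

Randomness is organized as named substreams keyed by the master seed, the
noise source and the (sensor, pulse) indices, so toggling one noise source
never shifts another's draws and the output is bitwise-identical for any
worker count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from . import noise as _noise
from .noise import DriftState, psd_factor, set_noise_levels
from .profiles import (
    GAS_NAMES,
    N_TYPES,
    ProfileBank,
    generate_profile_bank,
    sample_sensitivities,
    scale_affinities,
)
from .sorption import sorbed_fractions

__all__ = ["ArrayConfig", "SensorArray", "create_array", "infer_pulses"]

_SEED_MOD = 2**63

# substream tags
_STREAM_BETA = 0
_STREAM_CONC = 1
_STREAM_SENSOR = 2
_STREAM_DRIFT = 3

_DEFAULT_NDVAR = (0.86, 0.06, 0.05)


def _rng(*key) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(k) % _SEED_MOD for k in key]))


@dataclass(frozen=True)
class ArrayConfig:
    """Basic slots parameterizing a virtual sensor array.

    Defaults follow the standard basic configuration: two sensors of types
    1 and 2, nonlinearity ``alpha = 2.25``, diversity ``beta = 2``, all
    three noise levels at 0.1 (moderate), one drift component of
    importance 0.86 and steady-state-only pulses (``tunit = 1``).
    """

    num: tuple = (1, 2)
    nsensors: int = None
    alpha: float = 2.25
    beta: float = 2.0
    csd: float = 0.1
    ssd: float = 0.1
    dsd: float = 0.1
    ndcomp: int = 1
    ndvar: tuple = None
    tunit: int = 1
    seed: int = 0

    def __post_init__(self):
        num = tuple(int(t) for t in (self.num if np.iterable(self.num) else (self.num,)))
        if not num:
            raise ValueError("num must list at least one sensor type")
        if any(not (1 <= t <= N_TYPES) for t in num):
            raise ValueError(f"sensor types must be in 1..{N_TYPES}, got {num}")
        object.__setattr__(self, "num", num)
        nsensors = len(num) if self.nsensors is None else int(self.nsensors)
        if nsensors < 1:
            raise ValueError("nsensors must be >= 1")
        object.__setattr__(self, "nsensors", nsensors)
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0 (the value of zero is not allowed)")
        for name in ("beta", "csd", "ssd", "dsd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.ndcomp not in (1, 2, 3):
            raise ValueError("ndcomp must be 1, 2 or 3")
        ndvar = self.ndvar
        if ndvar is None:
            ndvar = _DEFAULT_NDVAR[: self.ndcomp]
        elif np.isscalar(ndvar):
            ndvar = (float(ndvar),)
        else:
            ndvar = tuple(float(v) for v in ndvar)
        if len(ndvar) != self.ndcomp:
            raise ValueError("ndvar must have exactly ndcomp entries")
        if any(not (0.0 <= v <= 1.0) for v in ndvar):
            raise ValueError("ndvar entries must lie in [0, 1]")
        object.__setattr__(self, "ndvar", ndvar)
        if self.tunit < 1:
            raise ValueError("tunit must be >= 1")

    @property
    def types(self) -> tuple:
        """Sensor types recycled cyclically to length ``nsensors``."""
        return tuple(self.num[i % len(self.num)] for i in range(self.nsensors))


class SensorArray:
    """A virtual gas sensor array; the package's data generation tool."""

    def __init__(self, num=(1, 2), nsensors=None, *, alpha=2.25, beta=2.0,
                 csd=0.1, ssd=0.1, dsd=0.1, ndcomp=1, ndvar=None, tunit=1,
                 seed=0, bank: ProfileBank = None):
        config = ArrayConfig(
            num=num, nsensors=nsensors, alpha=alpha, beta=beta, csd=csd,
            ssd=ssd, dsd=dsd, ndcomp=ndcomp, ndvar=ndvar, tunit=tunit,
            seed=seed,
        )
        self._init_from_config(config, bank)

    @classmethod
    def from_config(cls, config: ArrayConfig, bank: ProfileBank = None) -> "SensorArray":
        obj = cls.__new__(cls)
        obj._init_from_config(config, bank)
        return obj

    def _init_from_config(self, config: ArrayConfig, bank) -> None:
        self.config = config
        self.bank = generate_profile_bank(0) if bank is None else bank
        self.seed = int(config.seed)
        self.tunit = int(config.tunit)
        self.csd = float(config.csd)
        self.ssd = float(config.ssd)
        self.dsd = float(config.dsd)

        self.types = config.types
        self.profiles = [self.bank.profile(t) for t in self.types]
        # realized (post-alpha) affinities and (post-beta) coefficients
        self.affinities = np.array(
            [scale_affinities(p.affinity, config.alpha) for p in self.profiles]
        )
        baselines, sens = [], []
        for i, p in enumerate(self.profiles):
            rng = _rng(self.seed, _STREAM_BETA, i)
            b0, b = sample_sensitivities(p, config.beta, rng)
            baselines.append(b0)
            sens.append(b)
        self.baselines = np.array(baselines)
        self.sensitivities = np.array(sens)
        self._coeff_factors = [psd_factor(p.coeff_noise_cov) for p in self.profiles]
        self._conc_factor = psd_factor(self.bank.conc_noise_cov)

        basis = self.bank.drift_basis(config.nsensors)
        if config.ndcomp > basis.shape[1]:
            raise ValueError(
                "ndcomp exceeds the drift subspace dimension available for "
                f"an array of {config.nsensors} sensor(s)"
            )
        self.drift_basis = basis[:, : config.ndcomp]
        self.ndvar = np.asarray(config.ndvar, float)

    # -- introspection ----------------------------------------------------

    @property
    def nsensors(self) -> int:
        return self.config.nsensors

    @property
    def sensor_names(self) -> list:
        return [f"S{i + 1}" for i in range(self.nsensors)]

    def coefficients(self) -> pd.DataFrame:
        """Realized sorption affinities per sensor (post-alpha scaling)."""
        df = pd.DataFrame(self.affinities, columns=[f"K_{g}" for g in GAS_NAMES])
        df.insert(0, "type", self.types)
        df.index = self.sensor_names
        return df

    def sensitivity_coefficients(self) -> pd.DataFrame:
        """Realized calibration coefficients per sensor (post-beta draw)."""
        df = pd.DataFrame(self.sensitivities, columns=[f"b_{g}" for g in GAS_NAMES])
        df.insert(0, "type", self.types)
        df.insert(1, "b0", self.baselines)
        df.index = self.sensor_names
        return df

    def nsd(self, value=None, **kwargs) -> "SensorArray":
        """Set noise levels on the fly; ``nsd(0)`` suppresses all noise."""
        return set_noise_levels(self, value, **kwargs)

    # -- simulation -------------------------------------------------------

    def predict(self, conc, workers: int = 1, nclusters: int = None) -> pd.DataFrame:
        """Simulate the array response to a concentration matrix.

        Parameters
        ----------
        conc : DataFrame or ndarray
            Either an annotated concentration matrix (columns ``A, B, C``
            plus optional ``pulse`` annotations) or a raw ``n x 3`` array;
            pulse boundaries are inferred from air/gas transitions when no
            annotation is present.
        workers : int
            Number of parallel workers (alias ``nclusters``); the result
            is bitwise-identical for any worker count.

        Returns
        -------
        DataFrame
            ``n x nsensors`` signal matrix with columns ``S1..Sn``.
        """
        if nclusters is not None:
            workers = nclusters
        C, pulses = self._coerce_conc(conc)
        n = C.shape[0]
        gas_row = (C > 0).any(axis=1)
        order = list(dict.fromkeys(pulses.tolist()))  # pulse ids in time order

        # concentration noise: one delivery-error draw per pulse
        Cn = C.copy()
        if self.csd > 0:
            for p in order:
                rng = _rng(self.seed, _STREAM_CONC, p)
                eps = self.csd * (self._conc_factor @ rng.standard_normal(3))
                rows = np.flatnonzero(pulses == p)
                block = Cn[rows]
                mask = block > 0
                Cn[rows] = np.where(mask, np.clip(block + eps, 0.0, None), block)

        # drift: latent walk advanced once per pulse, offsets per sensor
        offsets = {}
        state = DriftState(
            basis=self.drift_basis,
            importance=self.ndvar,
            step_sd=self.bank.drift_step_sd,
        )
        for p in order:
            rng = _rng(self.seed, _STREAM_DRIFT, p)
            state, off = _noise.advance_drift(state, self.dsd, rng)
            offsets[p] = off

        pulse_pos = {p: i for i, p in enumerate(order)}
        offset_mat = np.array([offsets[p] for p in order])  # npulses x nsensors
        row_pulse_pos = np.array([pulse_pos[p] for p in pulses])

        sensor_ids = list(range(self.nsensors))
        if workers and workers > 1:
            cols = Parallel(n_jobs=int(workers))(
                delayed(self._sensor_column)(i, Cn, pulses, order, gas_row)
                for i in sensor_ids
            )
        else:
            cols = [self._sensor_column(i, Cn, pulses, order, gas_row) for i in sensor_ids]

        sdata = np.column_stack(cols) + offset_mat[row_pulse_pos]
        index = conc.index if isinstance(conc, pd.DataFrame) else pd.RangeIndex(n)
        return pd.DataFrame(sdata, columns=self.sensor_names, index=index)

    def _sensor_column(self, i, Cn, pulses, order, gas_row) -> np.ndarray:
        """Noise-perturbed transient signal of sensor ``i`` (no drift)."""
        prof = self.profiles[i]
        b0 = self.baselines[i]
        # per-pulse coefficient perturbation (sensor noise)
        b_pulse = {}
        for p in order:
            rng = _rng(self.seed, _STREAM_SENSOR, i, p)
            b_pulse[p] = _noise.add_sensor_noise(
                self.sensitivities[i], self.ssd, prof.coeff_noise_cov, rng,
                factor=self._coeff_factors[i],
            )
        X = sorbed_fractions(self.affinities[i], Cn)  # n x 3
        B = np.array([b_pulse[p] for p in pulses])    # n x 3
        targets = b0 + np.einsum("ij,ij->i", X, B)
        if self.tunit == 1:
            return targets
        y = np.empty(len(targets))
        current = b0
        for t in range(len(targets)):
            tau = prof.tau_rise if gas_row[t] else prof.tau_decay
            current = current + (targets[t] - current) / tau
            y[t] = current
        return y

    @staticmethod
    def _coerce_conc(conc):
        if isinstance(conc, pd.DataFrame):
            missing = [g for g in GAS_NAMES if g not in conc.columns]
            if missing:
                raise ValueError(f"concentration matrix lacks columns {missing}")
            C = conc.loc[:, list(GAS_NAMES)].to_numpy(float)
            pulses = (
                conc["pulse"].to_numpy()
                if "pulse" in conc.columns
                else infer_pulses(C)
            )
        else:
            C = np.asarray(conc, float)
            if C.ndim != 2 or C.shape[1] != 3:
                raise ValueError("a raw concentration matrix must have 3 columns")
            pulses = infer_pulses(C)
        if np.any(C < 0):
            raise ValueError("concentrations must be nonnegative")
        if not np.all(np.isfinite(C)):
            raise ValueError("concentrations must be finite")
        return C, np.asarray(pulses)


def infer_pulses(conc_matrix) -> np.ndarray:
    """Infer 1-based pulse indices from air/gas structure of a raw matrix.

    A new pulse starts at the beginning of the record and at every
    transition from a gas row back to an air row (the start of the next
    cleaning phase), matching the cleaning-then-exposition pulse layout.
    """
    C = np.asarray(conc_matrix, float)
    gas = (C > 0).any(axis=1)
    ids = np.empty(len(gas), dtype=int)
    current = 1
    for t in range(len(gas)):
        if t > 0 and gas[t - 1] and not gas[t]:
            current += 1
        ids[t] = current
    return ids


def create_array(config: ArrayConfig, bank: ProfileBank = None) -> SensorArray:
    """Instantiate a virtual array from a configuration and a bank."""
    return SensorArray.from_config(config, bank)
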