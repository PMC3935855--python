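"""Scenario definition: from gas labels to annotated concentration matrices.

A scenario is a compact description of a measurement campaign: gas labels
("A 0.01", "A 0.01, C 0.6", "air"), the number of pulses per label in a
training and a validation set, the pulse half-length ``tunit`` and an
optional randomization of pulse order.  Building a scenario yields an
annotated concentration matrix: one row per time sample with the analyte
concentrations (vol.%), the gas label, the set flag, a phase tag
(``tpoint``) and the pulse index.

Each pulse is a cleaning (air) phase of ``tunit`` samples followed by an
exposition (gas) phase of the same length; the last exposition sample
(``gasout``) carries the steady-state value and the last cleaning sample
(``airout``) the baseline used by the step feature.  With the paper-style
tunit of 60, three pulses place their ``gasout`` tags at time units 120,
240 and 360 (1-based).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .profiles import CONC_RANGES, GAS_NAMES

__all__ = [
    "GasLabel",
    "Scenario",
    "parse_gas_label",
    "format_gas_label",
    "build_concentration_matrix",
    "add_labels",
    "scenario_summary",
]

TPOINT_VALUES = ("air", "airin", "airout", "gas", "gasin", "gasout")

_TERM_RE = re.compile(r"^\s*([A-Za-z]+)\s*([0-9]*\.?[0-9]+(?:[eE][+-]?[0-9]+)?)\s*$")

_SEED_MOD = 2**63


def parse_gas_label(text: str, gas_names=GAS_NAMES, ranges=None) -> np.ndarray:
    """Parse a gas label into a concentration 3-vector.

    ``"air"`` maps to the zero vector.  Otherwise the label is a
    comma-separated list of ``"<gas> <concentration>"`` terms (``"A0.01"``
    without the space is also accepted); unlisted gases are zero.  A
    mixture may name at most three analytes.  Concentrations outside the
    dynamic range raise a warning, not an error — the saturation region is
    a legitimate input.
    """
    if ranges is None:
        ranges = CONC_RANGES
    text = text.strip()
    conc = np.zeros(len(gas_names))
    if text.lower() == "air" or text == "":
        return conc
    for term in text.split(","):
        m = _TERM_RE.match(term)
        if m is None:
            raise ValueError(f"cannot parse gas label term {term!r}")
        gas, value = m.group(1), float(m.group(2))
        if gas not in gas_names:
            raise ValueError(f"unknown gas name {gas!r} in label {text!r}")
        conc[gas_names.index(gas)] = value
        lo, hi = ranges.get(gas, (-np.inf, np.inf))
        if not (lo <= value <= hi):
            warnings.warn(
                f"concentration {value} of gas {gas} is outside the dynamic "
                f"range [{lo}, {hi}] vol.%",
                stacklevel=2,
            )
    return conc


def format_gas_label(conc, gas_names=GAS_NAMES) -> str:
    """Canonical label text for a concentration vector (inverse of parsing)."""
    conc = np.asarray(conc, float)
    if np.all(conc == 0):
        return "air"
    terms = [
        f"{g} {c:g}" for g, c in zip(gas_names, conc) if c > 0
    ]
    return ", ".join(terms)


@dataclass(frozen=True)
class GasLabel:
    """A gas label: canonical text plus its concentration vector."""

    text: str
    conc: np.ndarray

    @classmethod
    def parse(cls, text: str, gas_names=GAS_NAMES) -> "GasLabel":
        conc = parse_gas_label(text, gas_names)
        return cls(text=format_gas_label(conc, gas_names), conc=conc)


@dataclass(frozen=True)
class Scenario:
    """A measurement design: labelled pulses in a train and a validation set.

    Parameters mirror the scenario machinery of virtual-array simulators:
    ``train`` / ``valid`` are lists of ``(label_text, count)`` pairs,
    ``tunit`` is the half-length of every pulse (cleaning and exposition
    phases each last ``tunit`` samples), ``randomize`` shuffles pulse order
    independently within each set and ``seed`` makes the shuffle
    reproducible.
    """

    train: tuple = ()
    valid: tuple = ()
    tunit: int = 1
    randomize: bool = False
    seed: int = 0
    gas_names: tuple = GAS_NAMES

    def __post_init__(self):
        object.__setattr__(self, "train", tuple((str(l), int(n)) for l, n in self.train))
        object.__setattr__(self, "valid", tuple((str(l), int(n)) for l, n in self.valid))
        if self.tunit < 1:
            raise ValueError("tunit must be >= 1")
        for lab, n in (*self.train, *self.valid):
            if n < 1:
                raise ValueError(f"pulse count for label {lab!r} must be positive")
            parse_gas_label(lab, self.gas_names)  # fail fast on bad labels

    @property
    def n_train_pulses(self) -> int:
        return sum(n for _, n in self.train)

    @property
    def n_valid_pulses(self) -> int:
        return sum(n for _, n in self.valid)

    def add(self, labels, counts, which_set: str = "train") -> "Scenario":
        return add_labels(self, labels, counts, which_set)

    def summary(self) -> str:
        return scenario_summary(self)

    def build(self) -> pd.DataFrame:
        return build_concentration_matrix(self)


def add_labels(sc: Scenario, labels, counts, which_set: str = "train") -> Scenario:
    """Return a scenario with extra labels appended to one set."""
    if which_set not in ("train", "valid"):
        raise ValueError("which_set must be 'train' or 'valid'")
    labels = list(labels)
    counts = list(counts)
    if len(labels) != len(counts):
        raise ValueError("labels and counts must have the same length")
    extra = tuple((str(l), int(n)) for l, n in zip(labels, counts))
    if which_set == "train":
        return replace(sc, train=sc.train + extra)
    return replace(sc, valid=sc.valid + extra)


def _phase_tags(tunit: int, kind: str) -> list:
    """tpoint tags for one phase ('air' or 'gas') of length tunit."""
    if tunit == 1:
        return [f"{kind}out"]
    return [f"{kind}in"] + [kind] * (tunit - 2) + [f"{kind}out"]


def _pulse_order(entries, rng, randomize: bool) -> list:
    pulses = []
    for lab, n in entries:
        pulses.extend([lab] * n)
    if randomize and len(pulses) > 1:
        pulses = [pulses[i] for i in rng.permutation(len(pulses))]
    return pulses


def build_concentration_matrix(sc: Scenario) -> pd.DataFrame:
    """Expand a scenario into its annotated concentration matrix.

    Returns a DataFrame with columns ``A, B, C`` (vol.%), ``lab`` (gas
    label text, ``"air"`` on cleaning rows), ``set`` (``train`` or
    ``valid``), ``tpoint`` (phase tag) and ``pulse`` (1-based pulse index).
    The row count is exactly ``2 * tunit * (total pulses)``, all train
    pulses precede all validation pulses, and every pulse contributes
    exactly one ``airout`` row followed (tunit rows later) by one
    ``gasout`` row.
    """
    if not sc.train and not sc.valid:
        raise ValueError("scenario has no labels in either set")
    rng = np.random.default_rng(
        np.random.SeedSequence([int(sc.seed) % _SEED_MOD, 10])
    )
    gas_names = sc.gas_names
    air_tags = _phase_tags(sc.tunit, "air")
    gas_tags = _phase_tags(sc.tunit, "gas")

    rows = {g: [] for g in gas_names}
    lab_col, set_col, tpoint_col, pulse_col = [], [], [], []
    pulse_index = 0
    for set_name, entries in (("train", sc.train), ("valid", sc.valid)):
        for lab in _pulse_order(entries, rng, sc.randomize):
            pulse_index += 1
            conc = parse_gas_label(lab, gas_names)
            canonical = format_gas_label(conc, gas_names)
            for phase_conc, phase_lab, tags in (
                (np.zeros_like(conc), "air", air_tags),
                (conc, canonical, gas_tags),
            ):
                for tag in tags:
                    for g, v in zip(gas_names, phase_conc):
                        rows[g].append(v)
                    lab_col.append(phase_lab)
                    set_col.append(set_name)
                    tpoint_col.append(tag)
                    pulse_col.append(pulse_index)

    df = pd.DataFrame(rows)
    df["lab"] = lab_col
    df["set"] = set_col
    df["tpoint"] = tpoint_col
    df["pulse"] = pulse_col
    return df


def scenario_summary(sc: Scenario) -> str:
    """Human-readable summary: unique labels and counts per set, tunit."""
    lines = [f"Scenario: tunit={sc.tunit}, randomize={sc.randomize}"]
    for set_name, entries in (("train", sc.train), ("valid", sc.valid)):
        counts: dict = {}
        for lab, n in entries:
            canonical = format_gas_label(parse_gas_label(lab, sc.gas_names), sc.gas_names)
            counts[canonical] = counts.get(canonical, 0) + n
        lines.append(f"{set_name} set: {len(counts)} unique label(s)")
        for lab in sorted(counts):
            lines.append(f"  {lab}: {counts[lab]} pulse(s)")
    return "\n".join(lines)
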