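"""CSV and config interchange.

CSV is the only interchange format: concentration matrices use columns
``A, B, C`` (plus the optional annotation columns ``lab, set, tpoint,
pulse``), sensor data use ``S1..Sn``.  Columns are mapped by name, never
by position, values round-trip losslessly (shortest-repr floats) and the
decimal separator is always the point regardless of locale.

Run configurations are YAML with two sections, ``array`` (the slots of
:class:`~enosesim.array.ArrayConfig`) and ``scenario`` (gas labels and
counts for the train/valid sets, tunit, randomize, seed), plus a top-level
``feature`` choice.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import yaml

from .array import ArrayConfig
from .profiles import GAS_NAMES
from .scenario import Scenario

__all__ = [
    "read_conc_csv",
    "write_conc_csv",
    "read_sdata_csv",
    "write_sdata_csv",
    "scenario_from_dict",
    "array_config_from_dict",
    "load_run_config",
]

_ANNOT_COLS = ("lab", "set", "tpoint", "pulse")


def write_conc_csv(conc: pd.DataFrame, path) -> None:
    """Write a (possibly annotated) concentration matrix."""
    cols = [g for g in GAS_NAMES] + [c for c in _ANNOT_COLS if c in conc.columns]
    conc.loc[:, cols].to_csv(path, index=False)


def read_conc_csv(path) -> pd.DataFrame:
    """Read a concentration matrix, mapping columns by name.

    Unknown columns and non-numeric concentration cells are reported by
    name/position in the error message.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    allowed = set(GAS_NAMES) | set(_ANNOT_COLS)
    unknown = [c for c in df.columns if c not in allowed]
    if unknown:
        raise ValueError(f"unexpected column(s) in concentration CSV: {unknown}")
    missing = [g for g in GAS_NAMES if g not in df.columns]
    if missing:
        raise ValueError(f"concentration CSV is missing column(s): {missing}")
    for g in GAS_NAMES:
        values = pd.to_numeric(df[g], errors="coerce")
        bad = df.index[values.isna() & df[g].notna()]
        if len(bad):
            raise ValueError(
                f"non-numeric value in column {g!r} at row {int(bad[0]) + 1}"
            )
        df[g] = values
    order = [g for g in GAS_NAMES] + [c for c in _ANNOT_COLS if c in df.columns]
    return df.loc[:, order]


def write_sdata_csv(sdata: pd.DataFrame, path) -> None:
    sdata.to_csv(path, index=False)


def read_sdata_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    bad = [c for c in df.columns if not (c.startswith("S") and c[1:].isdigit())]
    if bad:
        raise ValueError(f"unexpected column(s) in sensor data CSV: {bad}")
    for c in df.columns:
        values = pd.to_numeric(df[c], errors="coerce")
        rows = df.index[values.isna() & df[c].notna()]
        if len(rows):
            raise ValueError(
                f"non-numeric value in column {c!r} at row {int(rows[0]) + 1}"
            )
        df[c] = values
    # keep natural sensor order S1, S2, ... regardless of file order
    return df.loc[:, sorted(df.columns, key=lambda c: int(c[1:]))]


def scenario_from_dict(d: dict) -> Scenario:
    """Build a :class:`Scenario` from a config mapping."""
    def entries(key):
        return tuple(
            (item["label"], int(item.get("n", 1))) for item in d.get(key, [])
        )

    return Scenario(
        train=entries("train"),
        valid=entries("valid"),
        tunit=int(d.get("tunit", 1)),
        randomize=bool(d.get("randomize", False)),
        seed=int(d.get("seed", 0)),
    )


def array_config_from_dict(d: dict) -> ArrayConfig:
    """Build an :class:`ArrayConfig` from a config mapping.

    ``dcsd`` is accepted as an alias of ``dsd``.
    """
    d = dict(d)
    if "dcsd" in d:
        d.setdefault("dsd", d.pop("dcsd"))
    known = {
        "num", "nsensors", "alpha", "beta", "csd", "ssd", "dsd",
        "ndcomp", "ndvar", "tunit", "seed",
    }
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown array config key(s): {sorted(unknown)}")
    if "num" in d and not np.iterable(d["num"]):
        d["num"] = (d["num"],)
    return ArrayConfig(**d)


def load_run_config(path):
    """Load a YAML run config; returns ``(array_config, scenario, feature)``.

    The scenario's ``tunit`` is authoritative: the array inherits it so the
    transient model and the pulse layout always agree.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "scenario" not in raw:
        raise ValueError("run config is missing the 'scenario' section")
    scenario = scenario_from_dict(raw["scenario"])
    array_section = dict(raw.get("array", {}))
    array_section["tunit"] = scenario.tunit
    config = array_config_from_dict(array_section)
    feature = raw.get("feature", "ss")
    return config, scenario, feature
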