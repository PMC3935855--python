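"""Feature extraction and numeric backends for exploratory analysis.

Three feature extractors turn a (concentration, signal) matrix pair into
an analysis table joining concentrations, sensor features and annotations:

``transient``
    every time sample is kept;
``ss`` (steady-state)
    one row per pulse, the signal at the ``gasout`` sample (end of the
    exposition phase);
``step``
    the steady-state signal minus the same pulse's ``airout`` baseline —
    the standard drift-correction feature, which cancels any within-pulse
    constant offset exactly.

The module also provides the numeric summaries behind the usual
exploratory plots: mean-centred PCA scores with variance-explained
fractions, and per-label boxplot statistics.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .profiles import GAS_NAMES

__all__ = ["extract_features", "sensor_columns", "pca_scores", "class_summaries"]

FEATURE_NAMES = ("transient", "ss", "step", "steady-state")


def sensor_columns(table: pd.DataFrame) -> list:
    """Names of the sensor feature columns (S1..Sn) in a table."""
    return [c for c in table.columns if c.startswith("S") and c[1:].isdigit()]


def extract_features(conc_annot: pd.DataFrame, sdata, feature: str = "ss") -> pd.DataFrame:
    """Join annotations, concentrations and extracted sensor features.

    Parameters
    ----------
    conc_annot : DataFrame
        Annotated concentration matrix with columns ``A, B, C, lab, set,
        tpoint, pulse``.
    sdata : DataFrame or ndarray
        Sensor signal matrix with one row per time sample.
    feature : str
        ``"transient"``, ``"ss"`` (alias ``"steady-state"``) or ``"step"``.

    Returns
    -------
    DataFrame
        One row per sample (transient) or per pulse (ss/step).  Air rows
        are excluded from the ss and step tables by construction.
    """
    if feature not in FEATURE_NAMES:
        raise ValueError(f"unknown feature {feature!r}; expected one of {FEATURE_NAMES}")
    if feature == "steady-state":
        feature = "ss"
    for col in ("lab", "set", "tpoint", "pulse", *GAS_NAMES):
        if col not in conc_annot.columns:
            raise ValueError(f"annotated concentration matrix lacks column {col!r}")
    S = np.asarray(sdata, float)
    if S.ndim == 1:
        S = S[:, None]
    if S.shape[0] != len(conc_annot):
        raise ValueError(
            f"sensor data has {S.shape[0]} rows but the concentration matrix "
            f"has {len(conc_annot)}"
        )
    if isinstance(sdata, pd.DataFrame):
        sensor_names = list(sdata.columns)
    else:
        sensor_names = [f"S{i + 1}" for i in range(S.shape[1])]

    annot = conc_annot.reset_index(drop=True)
    if feature == "transient":
        return pd.concat(
            [
                annot[list(GAS_NAMES)],
                pd.DataFrame(S, columns=sensor_names),
                annot[["lab", "set", "tpoint", "pulse"]],
            ],
            axis=1,
        )

    gas_idx = np.flatnonzero(annot["tpoint"].to_numpy() == "gasout")
    values = S[gas_idx]
    if feature == "step":
        air_idx = np.flatnonzero(annot["tpoint"].to_numpy() == "airout")
        gas_pulse = annot["pulse"].to_numpy()[gas_idx]
        air_pulse = annot["pulse"].to_numpy()[air_idx]
        baseline_of = dict(zip(air_pulse.tolist(), air_idx.tolist()))
        try:
            base_rows = np.array([baseline_of[p] for p in gas_pulse])
        except KeyError as exc:
            raise ValueError(f"pulse {exc.args[0]} has no airout baseline row") from None
        values = values - S[base_rows]

    return pd.concat(
        [
            annot.iloc[gas_idx][list(GAS_NAMES)].reset_index(drop=True),
            pd.DataFrame(values, columns=sensor_names),
            annot.iloc[gas_idx][["lab", "set", "pulse"]].reset_index(drop=True),
        ],
        axis=1,
    )


def pca_scores(features: pd.DataFrame, ncomp: int = 2, scale: bool = False):
    """Mean-centred PCA of the sensor feature columns.

    Returns ``(scores, variance_fractions)``: the scores of each sample on
    the first ``ncomp`` principal components and the fraction of total
    variance each component captures (nonincreasing, summing to <= 1).
    Degenerate input with zero total variance yields all-zero scores and
    fractions.
    """
    cols = sensor_columns(features)
    if not cols:
        raise ValueError("feature table has no sensor columns (S1..Sn)")
    X = features[cols].to_numpy(float)
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least two samples")
    if ncomp < 1:
        raise ValueError("ncomp must be >= 1")
    ncomp = min(ncomp, min(X.shape[0] - 1, X.shape[1]))
    Xc = X - X.mean(axis=0)
    if scale:
        sd = Xc.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Xc = Xc / sd
    total_var = Xc.var(axis=0, ddof=1).sum()
    if total_var <= 1e-30:
        scores = np.zeros((X.shape[0], ncomp))
        fractions = np.zeros(ncomp)
    else:
        pca = PCA(n_components=ncomp, svd_solver="full")
        scores = pca.fit_transform(Xc)
        fractions = pca.explained_variance_ratio_
    scores_df = pd.DataFrame(
        scores, columns=[f"PC{i + 1}" for i in range(ncomp)], index=features.index
    )
    for col in ("lab", "set"):
        if col in features.columns:
            scores_df[col] = features[col].to_numpy()
    return scores_df, fractions


def class_summaries(features: pd.DataFrame) -> pd.DataFrame:
    """Boxplot statistics per (gas label, sensor).

    For every label and sensor column the returned tidy table holds the
    median, the quartiles and the Tukey whiskers (most extreme data points
    within 1.5 interquartile ranges of the box).
    """
    if len(features) == 0:
        raise ValueError("feature table is empty")
    if "lab" not in features.columns:
        raise ValueError("feature table lacks the 'lab' column")
    cols = sensor_columns(features)
    if not cols:
        raise ValueError("feature table has no sensor columns (S1..Sn)")
    rows = []
    for lab, group in features.groupby("lab", sort=True):
        for s in cols:
            v = group[s].to_numpy(float)
            q1, med, q3 = np.percentile(v, [25, 50, 75])
            iqr = q3 - q1
            lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
            inside = v[(v >= lo_fence) & (v <= hi_fence)]
            rows.append(
                {
                    "lab": lab,
                    "sensor": s,
                    "n": len(v),
                    "median": med,
                    "q1": q1,
                    "q3": q3,
                    "whisker_low": inside.min() if len(inside) else np.nan,
                    "whisker_high": inside.max() if len(inside) else np.nan,
                }
            )
    return pd.DataFrame(rows)
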