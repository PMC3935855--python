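"""Feature extraction, PCA backend, boxplot summaries."""

import numpy as np
import pandas as pd
import pytest

from enosesim import (
    Scenario,
    SensorArray,
    build_concentration_matrix,
    class_summaries,
    extract_features,
    pca_scores,
)


@pytest.fixture(scope="module")
def fig1(bank):
    sc = Scenario(train=[("A 0.01", 1), ("A 0.02", 1), ("A 0.05", 1)], tunit=60)
    conc = build_concentration_matrix(sc)
    sa = SensorArray(num=(1, 5, 9, 13), tunit=60, seed=7, bank=bank)
    return conc, sa.predict(conc)


def test_row_conservation(fig1):
    conc, sdata = fig1
    assert len(extract_features(conc, sdata, "transient")) == len(conc)
    assert len(extract_features(conc, sdata, "ss")) == 3
    assert len(extract_features(conc, sdata, "step")) == 3


def test_ss_rows_are_the_gasout_samples(fig1):
    conc, sdata = fig1
    ss = extract_features(conc, sdata, "ss")
    expected = sdata.to_numpy()[[119, 239, 359]]  # time units 120/240/360
    assert np.array_equal(ss[["S1", "S2", "S3", "S4"]].to_numpy(), expected)
    assert "tpoint" not in ss.columns
    assert not (ss["lab"] == "air").any()


def test_step_subtracts_the_pulse_baseline(fig1):
    conc, sdata = fig1
    step = extract_features(conc, sdata, "step")
    S = sdata.to_numpy()
    expected = S[[119, 239, 359]] - S[[59, 179, 299]]
    assert np.allclose(step[["S1", "S2", "S3", "S4"]].to_numpy(), expected)


def test_step_cancels_constant_within_pulse_offsets(fig1):
    conc, sdata = fig1
    step0 = extract_features(conc, sdata, "step")
    shifted = sdata.copy()
    rng = np.random.default_rng(0)
    for p in conc["pulse"].unique():
        shifted.loc[conc["pulse"].to_numpy() == p] += rng.normal(size=4)
    step1 = extract_features(conc, shifted, "step")
    cols = ["S1", "S2", "S3", "S4"]
    assert np.allclose(step0[cols].to_numpy(), step1[cols].to_numpy(), atol=1e-9)
    ss0 = extract_features(conc, sdata, "ss")
    ss1 = extract_features(conc, shifted, "ss")
    assert not np.allclose(ss0[cols].to_numpy(), ss1[cols].to_numpy())


def test_twelve_labels_give_twelve_ss_rows(bank):
    labels = [
        (lab, 1)
        for lab in (
            "A 0.01", "A 0.02", "A 0.05", "A 0.1",
            "C 0.1", "C 0.5", "C 1", "C 2",
            "A 0.01, C 0.1", "A 0.02, C 0.5", "A 0.05, C 1", "A 0.1, C 2",
        )
    ]
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # saturation-region inputs warn by design
        sc = Scenario(train=labels, tunit=1)
        conc = build_concentration_matrix(sc)
    sa = SensorArray(num=tuple(range(1, 18)), nsensors=20, bank=bank)
    df = extract_features(conc, sa.predict(conc), "ss")
    assert len(df) == 12
    assert df["lab"].nunique() == 12


def test_invalid_inputs(fig1):
    conc, sdata = fig1
    with pytest.raises(ValueError):
        extract_features(conc, sdata, "wavelet")
    with pytest.raises(ValueError):
        extract_features(conc, sdata.iloc[:100], "ss")


def test_pca_matches_eigendecomposition_oracle():
    """Scores and variance fractions agree with a brute-force
    eigendecomposition of the covariance matrix."""
    rng = np.random.default_rng(8)
    X = rng.normal(size=(10, 5)) @ np.diag([3.0, 2.0, 1.0, 0.5, 0.1])
    feats = pd.DataFrame(X, columns=[f"S{i + 1}" for i in range(5)])
    scores, fractions = pca_scores(feats, ncomp=3)

    Xc = X - X.mean(axis=0)
    cov = Xc.T @ Xc / (len(X) - 1)
    w, v = np.linalg.eigh(cov)
    w, v = w[::-1], v[:, ::-1]
    oracle_scores = Xc @ v[:, :3]
    oracle_fracs = w[:3] / w.sum()
    assert np.allclose(fractions, oracle_fracs, rtol=1e-8)
    for j in range(3):  # eigenvector sign is arbitrary
        col = scores[f"PC{j + 1}"].to_numpy()
        assert np.allclose(col, oracle_scores[:, j], atol=1e-8) or np.allclose(
            col, -oracle_scores[:, j], atol=1e-8
        )
    assert np.all(np.diff(fractions) <= 1e-12)
    assert fractions.sum() <= 1 + 1e-12


def test_pca_degenerate_and_errors():
    feats = pd.DataFrame(np.ones((6, 3)), columns=["S1", "S2", "S3"])
    scores, fractions = pca_scores(feats, 2)
    assert np.allclose(scores[["PC1", "PC2"]].to_numpy(), 0)
    assert np.allclose(fractions, 0)
    with pytest.raises(ValueError):
        pca_scores(feats.iloc[:1], 2)
    with pytest.raises(ValueError):
        pca_scores(pd.DataFrame({"A": [1, 2]}), 1)


def test_mixed_array_shows_more_pca_diversity(bank):
    """A balanced array of C-affine and A-affine types captures less
    variance in two components than either homogeneous array."""
    labels = ["A 0.01", "A 0.05", "C 0.1", "C 1", "A 0.01, C 0.1", "A 0.05, C 1"]
    sc = Scenario(train=[(l, 10) for l in labels], tunit=1, randomize=True, seed=5)
    conc = build_concentration_matrix(sc)

    def twocomp(types):
        sa = SensorArray(num=types, nsensors=12, dsd=0, seed=1, bank=bank)
        feats = extract_features(conc, sa.predict(conc), "ss")
        return pca_scores(feats, 2)[1].sum()

    v_c_affine = twocomp((1, 2, 3))
    v_a_affine = twocomp((13, 14, 17))
    v_mixed = twocomp((1, 2, 3, 13, 14, 17))
    assert v_mixed < min(v_c_affine, v_a_affine)


def test_class_summaries_saturating_response(bank):
    """Median response rises with concentration but with shrinking
    increments (Langmuir saturation), on a noise-suppressed array."""
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sc = Scenario(
            train=[("A 0.01", 8), ("A 0.02", 8), ("A 0.05", 8), ("A 0.1", 8)],
            tunit=1, seed=3,
        )
        conc = build_concentration_matrix(sc)
    sa = SensorArray(num=(1, 2, 3, 13, 14, 17), seed=2, bank=bank).nsd(0)
    feats = extract_features(conc, sa.predict(conc), "ss")
    box = class_summaries(feats)
    assert box["lab"].nunique() == 4
    for sensor, sub in box.groupby("sensor"):
        sub = sub.set_index("lab").loc[["A 0.01", "A 0.02", "A 0.05", "A 0.1"]]
        med = sub["median"].to_numpy()
        assert np.all(np.diff(med) > 0)
        rel_gain = np.diff(med) / np.diff([0.01, 0.02, 0.05, 0.1])
        assert np.all(np.diff(rel_gain) < 0)  # diminishing returns per vol.%


def test_class_summaries_shape_and_errors():
    feats = pd.DataFrame({"S1": [1.0, 1.0, 2.0], "lab": ["x", "x", "y"]})
    box = class_summaries(feats)
    assert set(box["lab"]) == {"x", "y"}
    const = box[box["lab"] == "x"].iloc[0]
    assert const["q3"] - const["q1"] == 0
    with pytest.raises(ValueError):
        class_summaries(feats.iloc[:0])
    with pytest.raises(ValueError):
        class_summaries(pd.DataFrame({"lab": ["x"]}))
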