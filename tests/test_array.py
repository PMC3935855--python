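"""Virtual sensor array: assembly, determinism, the predict contract."""

import numpy as np
import pytest

from enosesim import (
    ArrayConfig,
    Scenario,
    SensorArray,
    build_concentration_matrix,
    create_array,
    extract_features,
    infer_pulses,
)


def test_default_configuration(bank):
    sa = SensorArray(bank=bank)
    assert sa.types == (1, 2)
    assert sa.nsensors == 2
    cfg = sa.config
    assert (cfg.alpha, cfg.beta) == (2.25, 2.0)
    assert (cfg.csd, cfg.ssd, cfg.dsd) == (0.1, 0.1, 0.1)
    assert (cfg.ndcomp, cfg.tunit) == (1, 1)
    assert cfg.ndvar == (0.86,)


def test_type_recycling(bank):
    sa = SensorArray(num=(1, 2, 3), nsensors=12, bank=bank)
    assert sa.types == (1, 2, 3) * 4
    assert sa.sensor_names[0] == "S1" and sa.sensor_names[-1] == "S12"


def test_invalid_configurations(bank):
    with pytest.raises(ValueError):
        SensorArray(num=(18,), bank=bank)
    with pytest.raises(ValueError):
        SensorArray(alpha=0, bank=bank)
    with pytest.raises(ValueError):
        SensorArray(ndcomp=2, ndvar=(0.5,), bank=bank)
    with pytest.raises(ValueError):
        SensorArray(ndcomp=4, bank=bank)
    with pytest.raises(ValueError):
        SensorArray(num=(1,), nsensors=1, ndcomp=2, bank=bank)  # subspace too small
    with pytest.raises(ValueError):
        SensorArray(tunit=0, bank=bank)


def test_replica_array_reproduces_the_bank(bank):
    """alpha=1, beta=0 replicates the prototype parameters exactly."""
    sa = SensorArray(num=tuple(range(1, 18)), alpha=1, beta=0, bank=bank)
    proto = np.array([p.affinity for p in bank.profiles])
    assert np.array_equal(sa.affinities, proto)
    coeffs = sa.coefficients()
    assert list(coeffs["type"]) == list(range(1, 18))
    assert np.array_equal(coeffs[["K_A", "K_B", "K_C"]].to_numpy(), proto)
    sens = sa.sensitivity_coefficients()
    assert np.array_equal(
        sens[["b_A", "b_B", "b_C"]].to_numpy(),
        np.array([p.sensitivity for p in bank.profiles]),
    )


def test_alpha_scales_affinities_linearly(bank):
    sa1 = SensorArray(num=(1, 5), alpha=1.0, seed=3, bank=bank)
    sa2 = SensorArray(num=(1, 5), alpha=2.0, seed=3, bank=bank)
    assert np.allclose(sa2.affinities, 2.0 * sa1.affinities)


def test_beta_controls_replica_diversity(bank):
    same = SensorArray(num=(4, 4), beta=0, seed=1, bank=bank)
    assert np.array_equal(same.sensitivities[0], same.sensitivities[1])
    diverse = SensorArray(num=(4, 4), beta=2, seed=1, bank=bank)
    assert not np.array_equal(diverse.sensitivities[0], diverse.sensitivities[1])


@pytest.fixture(scope="module")
def fig1_conc():
    sc = Scenario(
        train=[("A 0.01", 1), ("A 0.02", 1), ("A 0.05", 1)], tunit=60
    )
    return build_concentration_matrix(sc)


def test_fig1_signal_matrix_shape(bank, fig1_conc):
    sa = SensorArray(num=(1, 5, 9, 13), tunit=60, seed=7, bank=bank)
    sdata = sa.predict(fig1_conc)
    assert sdata.shape == (360, 4)
    assert list(sdata.columns) == ["S1", "S2", "S3", "S4"]
    assert np.all(np.isfinite(sdata.to_numpy()))


def test_noise_free_air_gives_baseline(bank):
    sa = SensorArray(num=(1, 2), csd=0, ssd=0, dsd=0, bank=bank)
    out = sa.predict(np.zeros((5, 3)))
    assert np.allclose(out.to_numpy(), sa.baselines, atol=1e-12)


def test_seed_determinism_and_parallel_equivalence(bank, fig1_conc):
    sa_a = SensorArray(num=(1, 5, 9, 13), tunit=60, seed=7, bank=bank)
    sa_b = SensorArray(num=(1, 5, 9, 13), tunit=60, seed=7, bank=bank)
    serial = sa_a.predict(fig1_conc, workers=1)
    again = sa_b.predict(fig1_conc, workers=1)
    parallel = sa_b.predict(fig1_conc, workers=3)
    assert np.array_equal(serial.to_numpy(), again.to_numpy())
    assert np.array_equal(serial.to_numpy(), parallel.to_numpy())
    other_seed = SensorArray(num=(1, 5, 9, 13), tunit=60, seed=8, bank=bank)
    assert not np.array_equal(serial.to_numpy(), other_seed.predict(fig1_conc).to_numpy())


def test_raw_matrix_equals_annotated_input(bank, fig1_conc):
    """Pulse inference on a raw matrix recovers the scenario's annotation."""
    raw = fig1_conc[["A", "B", "C"]].to_numpy()
    assert np.array_equal(infer_pulses(raw), fig1_conc["pulse"].to_numpy())
    sa = SensorArray(num=(1, 5, 9, 13), tunit=60, seed=7, bank=bank)
    assert np.array_equal(
        sa.predict(fig1_conc).to_numpy(), sa.predict(raw).to_numpy()
    )


def test_predict_input_validation(bank):
    sa = SensorArray(bank=bank)
    with pytest.raises(ValueError):
        sa.predict(np.zeros((4, 2)))
    bad = np.zeros((4, 3))
    bad[1, 0] = -0.1
    with pytest.raises(ValueError):
        sa.predict(bad)


def test_noise_free_steady_state_injectivity(bank):
    """Distinct pure-analyte inputs map to distinct response vectors."""
    sa = SensorArray(num=(1, 13), csd=0, ssd=0, dsd=0, bank=bank)
    concs = np.array(
        [[0.01, 0, 0], [0.05, 0, 0], [0, 0, 0.1], [0, 0, 1.0], [0.01, 0, 0.1]]
    )
    out = sa.predict(concs).to_numpy()
    for i in range(len(out)):
        for j in range(i + 1, len(out)):
            assert not np.allclose(out[i], out[j], atol=1e-9)


def test_fig1_concentration_steps_are_discriminable(bank):
    """At noise level 0.1 the three A concentrations separate by far more
    than the within-class spread of their steady-state features."""
    labels = [("A 0.01", 10), ("A 0.02", 10), ("A 0.05", 10)]
    sc = Scenario(train=labels, tunit=1, randomize=True, seed=2)
    conc = build_concentration_matrix(sc)
    sa = SensorArray(num=(1, 5, 9, 13), seed=7, bank=bank)  # noise at 0.1
    feats = extract_features(conc, sa.predict(conc), "ss")
    groups = feats.groupby("lab")["S1"]
    means = groups.mean().sort_values()
    sds = groups.std()
    gaps = np.diff(means.to_numpy())
    assert np.all(gaps > 3 * sds.max())


def test_create_array_from_config(bank):
    cfg = ArrayConfig(num=(2, 7), alpha=1.5, seed=11)
    sa = create_array(cfg, bank)
    assert sa.types == (2, 7)
    assert np.allclose(
        sa.affinities,
        1.5 * np.array([bank.profile(2).affinity, bank.profile(7).affinity]),
    )
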