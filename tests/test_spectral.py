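"""ERSP, ERD means, energy curves, characteristic frequencies, entropy."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import erdkit
from erdkit.spectral import ERSPMap, EnergyCurve
from conftest import make_trials

FS = 250.0


def _stationary_trials(n_trials=6, freq=10.3):
    # off the 1 Hz grid so spectral leakage keeps every row's power nonzero
    t = np.arange(round(9 * FS)) / FS
    x = np.sin(2 * np.pi * freq * t)
    return make_trials(np.tile(x, (n_trials, 1, 1)), fs=FS, time_origin=-3.0)


def _toy_map(values, freqs=None, times=None):
    values = np.asarray(values, dtype=float)
    nf, nt = values.shape
    return ERSPMap(
        freqs=freqs if freqs is not None else np.arange(1.0, 1.0 + nf),
        times=times if times is not None else np.linspace(0.0, 4.0, nt),
        values=values,
        n_trials=2,
        baseline_interval=(-2.5, -0.6),
    )


# ------------------------------------------------------------------ ersp


def test_stationary_signal_gives_flat_ersp():
    ts = _stationary_trials()
    tf_map = erdkit.ersp(ts, "ch0")
    rows = (tf_map.freqs >= 8) & (tf_map.freqs <= 13)
    assert np.abs(tf_map.values[rows]).max() < 0.5


def test_average_of_identical_trials_equals_single_trial_map():
    ts = _stationary_trials(n_trials=1)
    data = np.repeat(ts.data, 4, axis=0)
    two = make_trials(data[:2], fs=FS, time_origin=-3.0)
    four = make_trials(data, fs=FS, time_origin=-3.0)
    np.testing.assert_allclose(
        erdkit.ersp(two, "ch0").values, erdkit.ersp(four, "ch0").values,
        rtol=0, atol=1e-12,
    )


def test_trial_union_is_count_weighted_average_of_power():
    rng = np.random.default_rng(5)
    a = make_trials(rng.standard_normal((3, 1, round(9 * FS))), fs=FS,
                    time_origin=-3.0)
    b = make_trials(rng.standard_normal((5, 1, round(9 * FS))), fs=FS,
                    time_origin=-3.0)
    union = erdkit.TrialSet.concatenate([a, b])
    pa = erdkit.ersp(a, "ch0").power
    pb = erdkit.ersp(b, "ch0").power
    pu = erdkit.ersp(union, "ch0").power
    np.testing.assert_allclose(pu, (3 * pa + 5 * pb) / 8, rtol=1e-12)


def test_injected_alpha_erd_recovered_in_band_window_mean():
    cfg = erdkit.GeneratorConfig(
        sampling_rate=FS, n_channels=2, n_trials_per_condition=40,
        alpha_peak=10.0, beta_peak=19.0, seed=7,
        erd_depth_db={"MI": {"alpha": -3.0, "beta": 0.0}},
        erd_depth_jitter_shared_db=0.0, erd_depth_jitter_cond_db=0.0,
    )
    ts = erdkit.generate_subject(cfg)
    tf_map = erdkit.ersp(erdkit.bandpass(ts), "Cz")
    erd = erdkit.erd_mean(tf_map, (9.0, 11.0), (0.5, 3.5)).erd_db
    assert -3.5 <= erd <= -2.5


def test_ersp_validates_inputs(subject):
    one = subject.select_trials([0])
    with pytest.raises(ValueError, match="2 trials"):
        erdkit.ersp(one, "Cz")
    with pytest.raises(ValueError, match="precede MI onset"):
        erdkit.ersp(subject, "Cz", baseline_interval=(0.0, 1.0))
    with pytest.raises(ValueError, match="no STFT bins"):
        erdkit.ersp(subject, "Cz", baseline_interval=(-20.0, -15.0))
    with pytest.raises(ValueError, match="longer than trial"):
        erdkit.ersp(subject, "Cz", stft_params=erdkit.StftParams(window_s=20.0))


# ------------------------------------------------------------------ erd_mean


def test_erd_mean_identities():
    zeros = _toy_map(np.zeros((3, 5)))
    assert erdkit.erd_mean(zeros, (1, 3), (0, 4)).erd_db == 0.0
    const = _toy_map(np.full((3, 5), -2.5))
    assert erdkit.erd_mean(const, (1, 3), (0, 4)).erd_db == -2.5


def test_erd_mean_matches_brute_force_on_toy_map():
    values = np.array([[-1, -1, -1], [-2, -2, -2], [0, 0, 0]], dtype=float)
    toy = _toy_map(values)
    # band covers the first two rows: hand sum = -9 over 6 bins
    assert erdkit.erd_mean(toy, (1, 2), (0, 4)).erd_db == pytest.approx(-1.5)


def test_erd_mean_empty_selection_rejected():
    toy = _toy_map(np.zeros((3, 5)))
    with pytest.raises(ValueError, match="no ERSP bins"):
        erdkit.erd_mean(toy, (10, 20), (0, 4))


# -------------------------------------------------------------- energy curve


def test_energy_curve_identities():
    flat = erdkit.energy_curve(_toy_map(np.zeros((4, 5))), (0, 4))
    assert (flat.energy_db == 0).all()
    values = np.zeros((4, 5))
    values[2] = -4.0
    curve = erdkit.energy_curve(_toy_map(values), (0, 4))
    assert curve.freqs[int(np.argmin(curve.energy_db))] == 3.0
    assert curve.energy_db.min() == -4.0
    with pytest.raises(ValueError, match="no ERSP time bins"):
        erdkit.energy_curve(_toy_map(values), (10, 12))


# ------------------------------------------------- characteristic frequency


def test_characteristic_frequency_on_v_curve():
    freqs = np.arange(6.0, 16.0)
    energy = np.abs(freqs - 10.0) - 2.0  # V shape, min -2 at 10 Hz
    res = erdkit.characteristic_frequency(
        EnergyCurve(freqs, energy), erdkit.ALPHA_BAND
    )
    assert res.characteristic_frequency == 10.0
    assert res.band_name == "alpha"
    assert not res.no_erd
    lo, hi = res.characteristic_band
    assert lo <= 10.0 <= hi
    # clipped to the search range even though the dip extends below 8 Hz
    assert lo >= erdkit.ALPHA_BAND[0]


def test_flat_curve_flags_no_erd():
    freqs = np.arange(1.0, 31.0)
    res = erdkit.characteristic_frequency(
        EnergyCurve(freqs, np.zeros_like(freqs)), erdkit.ALPHA_BAND
    )
    assert res.no_erd
    assert res.characteristic_frequency is None
    assert res.characteristic_band is None


def test_argmin_tie_breaks_to_lowest_frequency():
    freqs = np.arange(6.0, 16.0)
    energy = np.zeros_like(freqs)
    energy[(freqs == 9) | (freqs == 11)] = -1.0
    res = erdkit.characteristic_frequency(
        EnergyCurve(freqs, energy), erdkit.ALPHA_BAND
    )
    assert res.characteristic_frequency == 9.0


def test_empty_search_band_rejected():
    curve = EnergyCurve(np.arange(1.0, 5.0), np.zeros(4))
    with pytest.raises(ValueError, match="no curve bins"):
        erdkit.characteristic_frequency(curve, (20.0, 25.0))


def test_synthetic_dip_located_near_injected_peak():
    cfg = erdkit.GeneratorConfig(
        sampling_rate=FS, n_channels=2, n_trials_per_condition=40,
        alpha_peak=9.0, beta_peak=19.0, seed=4,
        erd_depth_db={"MI": {"alpha": -3.0, "beta": 0.0}},
        erd_depth_jitter_shared_db=0.0, erd_depth_jitter_cond_db=0.0,
    )
    ts = erdkit.generate_subject(cfg)
    curve = erdkit.energy_curve(erdkit.ersp(erdkit.bandpass(ts), "Cz"), (0, 4))
    res = erdkit.characteristic_frequency(curve, erdkit.ALPHA_BAND)
    assert abs(res.characteristic_frequency - 9.0) <= 1.0
    assert curve.energy_db.min() < -1.0


# ------------------------------------------------------------------ entropy


def test_entropy_limits_exact():
    assert erdkit.entropy_of_density(np.full(64, 1 / 64)) == pytest.approx(
        np.log(64), abs=1e-12
    )
    one_hot = np.zeros(16)
    one_hot[3] = 1.0
    assert erdkit.entropy_of_density(one_hot) == 0.0


def test_entropy_matches_direct_summation_on_gaussian_density():
    x = np.linspace(-3, 3, 33)
    p = np.exp(-0.5 * x**2)
    p /= p.sum()
    direct = -sum(pi * np.log(pi) for pi in p if pi > 0)  # brute force
    assert erdkit.entropy_of_density(p) == pytest.approx(direct, abs=1e-12)


@given(
    st.lists(st.floats(min_value=0.0, max_value=1e6), min_size=2, max_size=64)
    .filter(lambda v: sum(v) > 0)
)
def test_entropy_bounds(weights):
    h = erdkit.entropy_of_density(np.array(weights))
    assert 0.0 <= h <= np.log(len(weights)) + 1e-12


def test_entropy_invalid_densities_rejected():
    with pytest.raises(ValueError):
        erdkit.entropy_of_density(np.zeros(8))
    with pytest.raises(ValueError):
        erdkit.entropy_of_density(np.array([0.5, -0.5, 1.0]))


def test_spectral_entropy_of_trials(subject):
    res = erdkit.spectral_entropy(subject, "Cz", (0.0, 4.0))
    assert 0.0 < res.entropy <= np.log(res.density_bins.size)
    assert res.density_bins.sum() == pytest.approx(1.0, abs=1e-9)
    assert (res.density_bins >= 0).all()
    # a near-line spectrum is far less entropic than this broadband signal
    t = np.arange(round(9 * FS)) / FS
    sine = make_trials(
        np.tile(np.sin(2 * np.pi * 10 * t), (2, 1, 1)), fs=FS, time_origin=-3.0
    )
    res_sine = erdkit.spectral_entropy(sine, "ch0", (0.0, 4.0))
    assert res_sine.entropy < res.entropy


def test_spectral_entropy_zero_signal_rejected(subject):
    silent = make_trials(np.zeros((2, 1, round(9 * FS))), fs=FS, time_origin=-3.0)
    with pytest.raises(ValueError, match="no power"):
        erdkit.spectral_entropy(silent, "ch0", (0.0, 4.0))
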