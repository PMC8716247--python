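"""Descriptive/inferential statistics against hand-computed oracles and the
published per-subject reference tables."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import erdkit
from erdkit import reference as ref
from erdkit.stats import PairedSample


def test_describe_constant_and_validation():
    mean, std = erdkit.describe([5.0, 5.0, 5.0])
    assert mean == 5.0 and std == 0.0
    with pytest.raises(ValueError):
        erdkit.describe([1.0])


def test_describe_reproduces_consistent_reference_cells():
    """Mean/STD cells of the reference tables that match their own printed
    columns are recovered exactly at printed precision."""
    mean, std = erdkit.describe(ref.ERD_DB["alpha"]["LFMI"])
    assert mean == pytest.approx(-1.3487, abs=5e-5)
    assert std == pytest.approx(0.5276, abs=5e-5)
    _, std_h = erdkit.describe(ref.ERD_DB["alpha"]["HFMI"])
    assert std_h == pytest.approx(0.4960, abs=5e-5)
    mean_b, std_b = erdkit.describe(ref.ERD_DB["beta"]["LFMI"])
    assert mean_b == pytest.approx(-2.2891, abs=5e-5)
    assert std_b == pytest.approx(0.6725, abs=5e-5)
    for band, expected in (("alpha", (9.0, 10.0)), ("beta", (18.0, 20.0))):
        for cond, want in zip(("HFMI", "LFMI"), expected):
            mean_cf, _ = erdkit.describe(
                ref.CHARACTERISTIC_FREQUENCY_HZ[band][cond]
            )
            assert mean_cf == want


def test_paired_t_matches_brute_force_on_reference_erd():
    # oracle: d = a - b, t = mean(d) / (sd(d)/sqrt(n)); frozen values below
    sample = PairedSample(
        np.array(ref.ERD_DB["alpha"]["HFMI"]),
        np.array(ref.ERD_DB["alpha"]["LFMI"]),
        ("HFMI", "LFMI"),
    )
    res = erdkit.paired_t(sample)
    assert res.t == pytest.approx(-5.1479, abs=1e-3)
    assert res.p == pytest.approx(6.048e-4, rel=1e-3)
    assert res.dof == 9
    swapped = erdkit.paired_t(sample.swapped())
    assert swapped.t == pytest.approx(-res.t, abs=1e-12)
    assert swapped.p == pytest.approx(res.p, abs=1e-12)


def test_paired_t_degenerate_paths():
    a = np.array([1.0, 2.0, 3.0, 4.0])
    same = erdkit.paired_t(PairedSample(a, a))
    assert same.degenerate and np.isnan(same.t)
    shifted = erdkit.paired_t(PairedSample(a + 1.0, a))
    assert shifted.degenerate  # zero variance of differences
    with pytest.raises(ValueError):
        PairedSample(np.array([1.0, 2.0]), np.array([1.0, 2.0]))


def test_pearson_r_exact_cases():
    a = np.array([1.0, 2.0, 4.0, 8.0])
    assert erdkit.pearson_r(PairedSample(a, 2 * a)).r == pytest.approx(1.0)
    assert erdkit.pearson_r(PairedSample(a, -a)).r == pytest.approx(-1.0)
    sample = PairedSample(
        np.array(ref.CHARACTERISTIC_FREQUENCY_HZ["alpha"]["HFMI"], float),
        np.array(ref.CHARACTERISTIC_FREQUENCY_HZ["alpha"]["LFMI"], float),
    )
    # hand computation: cov 6, variances 8 and 6 -> r = 6/sqrt(48)
    assert erdkit.pearson_r(sample).r == pytest.approx(6 / np.sqrt(48),
                                                       abs=1e-12)
    flat = erdkit.pearson_r(PairedSample(np.ones(5), np.arange(5.0)))
    assert flat.degenerate


@given(
    st.floats(min_value=0.01, max_value=100.0),
    st.floats(min_value=-50.0, max_value=50.0),
)
def test_pearson_invariant_to_positive_affine_transform(scale, shift):
    rng = np.random.default_rng(9)
    a = rng.standard_normal(12)
    b = rng.standard_normal(12) + 0.5 * a
    r0 = erdkit.pearson_r(PairedSample(a, b)).r
    r1 = erdkit.pearson_r(PairedSample(scale * a + shift, b)).r
    assert r1 == pytest.approx(r0, abs=1e-9)


# ---------------------------------------------------------------- reports


def _records(n=10, erd_shift=0.0, seed=0):
    rng = np.random.default_rng(seed)
    records = []
    for k in range(n):
        records.append(
            {
                "subject_id": f"S{k + 1}",
                "characteristic_frequency": {
                    "alpha": {"HFMI": 9 + (k % 3), "LFMI": 10 + (k % 2)},
                    "beta": {"HFMI": 18.0, "LFMI": 20.0},
                },
                "erd": {
                    "alpha": {
                        "HFMI": -1.8 + erd_shift + 0.2 * rng.standard_normal(),
                        "LFMI": -1.3 + 0.2 * rng.standard_normal(),
                    },
                    "beta": {"HFMI": -3.4, "LFMI": -2.3},
                },
                "recognition": {"HFMI": 0.8 + 0.01 * k, "LFMI": 0.7 + 0.01 * k},
            }
        )
    return records


def test_report_shape_and_footer_consistency():
    report = erdkit.build_report(_records())
    for table in (report.characteristic_frequencies, report.erd_means,
                  report.recognition_rates):
        assert list(table.index[-2:]) == ["Mean", "STD"]
        assert table.shape[0] == 12
        for col in table.columns:
            mean, std = erdkit.describe(table[col].to_numpy()[:-2])
            assert table.loc["Mean", col] == pytest.approx(mean, abs=1e-12)
            assert table.loc["STD", col] == pytest.approx(std, abs=1e-12)
    assert {"erd_alpha", "erd_beta", "recognition"} <= set(report.statistics)


def test_report_rejects_bad_cohorts():
    with pytest.raises(ValueError, match="at least 3"):
        erdkit.build_report(_records(2))
    dup = _records(4)
    dup[1]["subject_id"] = "S1"
    with pytest.raises(ValueError, match="duplicate"):
        erdkit.build_report(dup)
    mixed = _records(4)
    del mixed[2]["characteristic_frequency"]["beta"]
    with pytest.raises(ValueError, match="mixed"):
        erdkit.build_report(mixed)


def test_cohort_with_deeper_condition_yields_negative_significant_t():
    """A 10-subject synthetic cohort with a 1.5 dB deeper alpha ERD in one
    condition gives a negative paired t with p < 0.05 on recovered values."""
    tmpl = erdkit.GeneratorConfig(
        sampling_rate=160.0, n_channels=2, n_trials_per_condition=30,
        erd_depth_db={"HFMI": {"alpha": -2.8, "beta": -3.4},
                      "LFMI": {"alpha": -1.3, "beta": -2.3}},
    )
    from erdkit.synth import cohort_configs

    configs = cohort_configs(10, tmpl, seed=5)
    cohort = erdkit.generate_cohort(10, tmpl, seed=5)
    a_vals, b_vals = [], []
    for cfg, ts in zip(configs, cohort):
        filtered = erdkit.bandpass(ts)
        band = (cfg.alpha_peak - 1, cfg.alpha_peak + 1)
        for cond, store in (("HFMI", a_vals), ("LFMI", b_vals)):
            tf = erdkit.ersp(filtered.select_condition(cond), "Cz")
            store.append(erdkit.erd_mean(tf, band, (0.5, 3.5)).erd_db)
    res = erdkit.paired_t(PairedSample(np.array(a_vals), np.array(b_vals),
                                       ("HFMI", "LFMI")))
    assert res.t < 0
    assert res.p < 0.05


def test_report_written_to_disk(tmp_path):
    report = erdkit.build_report(_records())
    written = report.to_dir(tmp_path / "report")
    assert all(p.exists() for p in written)
    assert (tmp_path / "report" / "statistics.json").exists()
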