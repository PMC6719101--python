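"""Feature extractors: hand-computed values, analytic constructions, and
ground-truth event recovery."""

import dataclasses

import numpy as np
import pytest

from cravesense.core import FEATURE_NAMES, WASH_OFF
from cravesense.features import (FeatureConfig, covariance_features,
                                 detect_blinks, detect_saccades,
                                 estimate_hr_series, estimate_rr_series,
                                 extract_features, gsr_features,
                                 hr_rr_features)
from cravesense.preprocess import preprocess_trial
from cravesense.simulate import SimulationConfig, simulate_trial_with_truth


def test_hr_rr_summary_statistics_by_hand():
    stdhr, mhr, stdrr, mrr = hr_rr_features([60, 60, 60], [58, 60, 62])
    assert (stdhr, mhr) == (0.0, 60.0)
    assert mrr == 60.0
    assert stdrr == pytest.approx(2.0)  # sample SD of {58, 60, 62}
    stdhr, mhr, _, _ = hr_rr_features([], [])
    assert np.isnan(stdhr) and np.isnan(mhr)


def test_flat_ppg_flags_hr_invalid():
    assert estimate_hr_series(np.zeros(51200), 2048.0).size == 0
    assert estimate_rr_series(np.zeros(51200), 2048.0).size == 0


def test_unmodulated_ppg_flags_rr_invalid():
    cfg = SimulationConfig(resp_mod_depth=0.0, hr_sd=0.0, noise_sd=0.0)
    trial, _ = simulate_trial_with_truth(cfg, WASH_OFF, 4)
    pt = preprocess_trial(trial)
    assert estimate_rr_series(pt.ppg_f, pt.fs_raw).size == 0


def test_rr_estimates_order_slow_vs_fast_breathing():
    means = {}
    for rr in (12.0, 24.0):
        cfg = dataclasses.replace(SimulationConfig(), rr_mean=rr, fs_raw=256.0)
        vals = []
        for s in range(5):
            trial, _ = simulate_trial_with_truth(cfg, WASH_OFF, 50 + s)
            pt = preprocess_trial(trial)
            vals.append(np.mean(estimate_rr_series(pt.ppg_f, pt.fs_raw)))
        means[rr] = vals
    assert all(a < b for a, b in zip(means[12.0], means[24.0]))


def test_hr_features_ignore_the_first_ten_seconds(fast_processed):
    pt, _ = fast_processed
    hr_ref = estimate_hr_series(pt.ppg_f, pt.fs_raw)
    perturbed = pt.ppg_f.copy()
    n10 = int(10 * pt.fs_raw)
    perturbed[:n10] += 0.05 * np.sin(2 * np.pi * 3.0 * np.arange(n10) / pt.fs_raw)
    hr_pert = estimate_hr_series(perturbed, pt.fs_raw)
    assert abs(np.mean(hr_pert) - np.mean(hr_ref)) < 0.5


def test_gsr_zscore_and_single_bump_peak():
    t = np.linspace(0, 25, 400)
    x = 2.0 + np.exp(-0.5 * ((t - 12.5) / 2.0) ** 2)
    mnsc, minnsc = gsr_features(x)
    z = (x - x.mean()) / x.std()
    assert mnsc == pytest.approx(np.max(z))   # a single symmetric bump -> one peak
    assert minnsc == pytest.approx(np.min(z))
    assert np.isnan(gsr_features(np.full(400, 1.0))[0])  # flat trace is invalid
    # trace mode averages the normalized trace itself
    mnsc_trace, _ = gsr_features(x, FeatureConfig(mnsc_mode="trace"))
    assert mnsc_trace == pytest.approx(0.0, abs=1e-12)


def test_blink_intervals_merge_across_one_sample_gap():
    v = np.zeros(400)
    v[100:103] = 100.0
    v[104:107] = 100.0  # 1-sample gap -> same blink
    _, ne, _ = detect_blinks(v)
    assert ne == 1
    v2 = np.zeros(400)
    v2[100:103] = 100.0
    v2[110:113] = 100.0  # 7-sample gap -> two blinks
    _, ne2, _ = detect_blinks(v2)
    assert ne2 == 2


def test_blinkless_trace_returned_unchanged():
    rng = np.random.default_rng(2)
    v = rng.normal(0, 1.0, size=400)
    _, ne, out = detect_blinks(v)
    assert ne == 0
    np.testing.assert_array_equal(out, v)


def test_simulated_blink_count_recovered(fast_processed):
    pt, truth = fast_processed
    _, ne, _ = detect_blinks(pt.veog)
    assert ne == len(truth.blink_intervals)


def test_saccade_features_zero_without_saccades():
    f = detect_saccades(np.zeros(400), np.zeros(400))
    assert f == {"DHSM": 0.0, "DVSM": 0.0, "mDHV": 0.0, "DSM": 0.0}


def _steps(times, amp, n=400):
    x = np.zeros(n)
    for i, t in enumerate(times):
        x[int(t * 16):] += amp * (-1) ** i  # alternate directions
    return x


def test_single_horizontal_step_amplitude_recovery():
    h = _steps([12.3], 2.0)
    f = detect_saccades(h, np.zeros(400))
    assert f["DHSM"] == pytest.approx(2.0, rel=0.05)
    assert f["DVSM"] == 0.0
    assert f["mDHV"] == pytest.approx(1.0, rel=0.05)
    assert f["DSM"] == pytest.approx(2.0, rel=0.05)


def test_equal_amplitude_saccade_sum_within_ten_percent():
    times = [2.0, 5.0, 8.0, 11.0, 14.0, 17.0, 20.0]
    rng = np.random.default_rng(3)
    h = _steps(times, 3.0) + rng.normal(0, 0.05, size=400)
    f = detect_saccades(h, np.zeros(400))
    assert f["DHSM"] == pytest.approx(len(times) * 3.0, rel=0.10)


def test_oblique_saccade_combines_euclideanly():
    h = _steps([12.0], 3.0)
    v = _steps([12.0], 4.0)
    f = detect_saccades(h, v)
    assert f["DSM"] == pytest.approx(5.0, rel=0.05)  # sqrt(3^2 + 4^2)
    assert f["mDHV"] == pytest.approx(3.5, rel=0.05)


def test_covariance_identities():
    rng = np.random.default_rng(4)
    v = rng.normal(size=400)
    chv, chp, cvp = covariance_features(v, v, np.zeros(400), fs_raw=16.0)
    assert chv == pytest.approx(np.var(v, ddof=1))
    chv2, _, _ = covariance_features(2 * v, v, np.zeros(400), fs_raw=16.0)
    assert chv2 == pytest.approx(2 * np.var(v, ddof=1))
    # independent components decorrelate on average
    vals = []
    for s in range(100):
        r = np.random.default_rng(s)
        c, _, _ = covariance_features(r.normal(size=400), r.normal(size=400),
                                      np.zeros(400), fs_raw=16.0)
        vals.append(c)
    assert abs(np.mean(vals)) < 0.02


def test_extract_features_is_finite_deterministic_and_consistent(fast_trial):
    trial, _ = fast_trial
    fv1 = extract_features(preprocess_trial(trial))
    fv2 = extract_features(preprocess_trial(trial))
    arr = fv1.to_array()
    assert arr.shape == (14,)
    assert np.all(np.isfinite(arr))
    np.testing.assert_array_equal(arr, fv2.to_array())
    assert fv1.mDHV == (fv1.DHSM + fv1.DVSM) / 2.0
    assert fv1.NE == int(fv1.NE) >= 0
    for name in ("stdHR", "stdRR", "DHSM", "DVSM", "mDHV", "DSM"):
        assert getattr(fv1, name) >= 0


def test_feature_table_layout(fast_features):
    assert len(fast_features) == 108
    assert list(fast_features.columns[:5]) == [
        "subject_id", "session_id", "trial_index", "kind", "craving_score"]
    assert list(fast_features.columns[5:]) == list(FEATURE_NAMES)
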