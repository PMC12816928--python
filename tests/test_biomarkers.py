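import numpy as np
import pytest

from hypoglyc import (
    DetectorConfig,
    QCConfig,
    aggregate_subject,
    daily_biomarkers,
    detect_episodes,
    episode_auc,
    segment_days,
)
from hypoglyc.biomarkers import DailyBiomarkers, IneligibleSubjectError

from conftest import brute_force_episodes, grid_day, make_trace, random_short_trace


def episodes_as_index_pairs(trace, det):
    eps = detect_episodes(trace.times, trace.glucose, det)
    pairs = []
    for ep in eps:
        i = int(np.flatnonzero(trace.times == ep.start)[0])
        j = int(np.flatnonzero(trace.times == ep.end)[0])
        pairs.append((i, j))
    return pairs


# ---------------------------------------------------------------- detection

def test_no_samples_below_threshold_gives_no_episode(det):
    trace = make_trace([0, 15, 30], [90, 70.0, 75])  # 70.0 is not "below 70"
    assert detect_episodes(trace.times, trace.glucose, det) == []


def test_single_isolated_low_sample_is_not_an_episode(det):
    trace = make_trace([0, 15, 30], [85, 65, 85])
    assert detect_episodes(trace.times, trace.glucose, det) == []


def test_example_run_detected_with_exact_boundaries(det):
    trace = make_trace([0, 15, 30, 45], [72, 68, 65, 71])
    (ep,) = detect_episodes(trace.times, trace.glucose, det)
    assert np.array_equal(ep.glucose, [68, 65])
    assert episodes_as_index_pairs(trace, det) == [(1, 2)]


def test_low_pair_beyond_gap_limit_is_no_episode(det):
    # two sub-70 samples 45 min apart (intervening samples missing)
    trace = make_trace([0, 45], [65, 64])
    assert detect_episodes(trace.times, trace.glucose, det) == []


def test_gap_splits_run_into_separate_episodes(det):
    trace = make_trace([0, 15, 60, 75], [65, 64, 63, 62])
    assert episodes_as_index_pairs(trace, det) == [(0, 1), (2, 3)]


def test_detector_matches_brute_force_oracle_on_random_traces(det, rng):
    """Exhaustive maximal-run oracle agrees on 1000 random short traces."""
    for _ in range(1000):
        trace = random_short_trace(rng)
        got = episodes_as_index_pairs(trace, det)
        expected = brute_force_episodes(trace.times, trace.glucose, det)
        assert got == expected


# ---------------------------------------------------------------- AUC

def test_auc_hand_computed_two_samples(det):
    trace = make_trace([15, 30], [68.0, 65.0])
    (ep,) = detect_episodes(trace.times, trace.glucose, det)
    assert ep.auc == pytest.approx(52.5, abs=1e-9)


def test_auc_hand_computed_constant_low_run(det):
    trace = make_trace([0, 15, 30, 45], [60.0] * 4)
    (ep,) = detect_episodes(trace.times, trace.glucose, det)
    assert ep.auc == pytest.approx(450.0, abs=1e-9)


def test_auc_scales_linearly_with_deficit(det):
    times = make_trace([0, 15, 30], [65, 60, 68]).times
    base = episode_auc(det=det, times=times, glucose=np.array([65.0, 60.0, 68.0]))
    scaled = episode_auc(
        det=det, times=times, glucose=det.threshold - 3 * (det.threshold - np.array([65.0, 60.0, 68.0]))
    )
    assert scaled == pytest.approx(3 * base)


def test_auc_rejects_samples_at_or_above_threshold(det):
    times = make_trace([0, 15], [60, 60]).times
    with pytest.raises(ValueError):
        episode_auc(det=det, times=times, glucose=np.array([60.0, 70.0]))


def test_auc_monotone_in_deficit_and_additive_over_episodes(det, rng):
    """Lowering a sub-threshold sample never decreases the day's AUC, and the
    day total is the sum over its episodes, on random traces."""
    for _ in range(1000):
        trace = random_short_trace(rng, lo=55.0, hi=90.0)
        if trace.n_samples == 0:
            continue
        eps = detect_episodes(trace.times, trace.glucose, det)
        total = sum(ep.auc for ep in eps)
        assert total >= 0
        for ep in eps:
            # trapezoid integral is additive over a split of the episode
            if ep.n_samples > 2:
                k = ep.n_samples // 2
                left = episode_auc(det=det, times=ep.times[: k + 1],
                                   glucose=ep.glucose[: k + 1])
                right = episode_auc(det=det, times=ep.times[k:],
                                    glucose=ep.glucose[k:])
                assert left + right == pytest.approx(ep.auc)
        low = np.flatnonzero(trace.glucose < det.threshold)
        if low.size:
            k = int(rng.choice(low))
            lowered = trace.glucose.copy()
            lowered[k] = max(lowered[k] - rng.uniform(0, 10), 1.0)
            eps2 = detect_episodes(trace.times, lowered, det)
            assert sum(ep.auc for ep in eps2) >= total - 1e-9
        # raising everything above threshold removes all episodes
        raised = trace.glucose + (det.threshold - trace.glucose.min()) + 1
        assert detect_episodes(trace.times, raised, det) == []


# ---------------------------------------------------------------- daily

def test_constant_day_biomarkers(det):
    qc = QCConfig()
    (window,) = segment_days(grid_day(96, value=90.0), qc)
    daily = daily_biomarkers(window, det)
    assert daily.mean_glycaemia == 90.0
    assert daily.min_glycaemia == 90.0
    assert daily.cv == 0.0
    assert daily.hypo_auc == 0.0 and daily.n_episodes == 0


def test_cv_uses_sample_standard_deviation(det):
    qc = QCConfig(min_completeness=0.03)  # accept a 3-sample day
    trace = make_trace([0, 15, 30], [80.0, 100.0, 120.0],
                       start="2024-01-02T00:00:00")
    (window,) = segment_days(trace, qc)
    daily = daily_biomarkers(window, det)
    assert daily.mean_glycaemia == pytest.approx(100.0)
    assert daily.cv == pytest.approx(0.20)  # sd with n-1 denominator is 20


def test_isolated_low_sample_affects_min_but_not_auc(det):
    qc = QCConfig()
    glucose = np.full(96, 90.0)
    glucose[40] = 65.0
    trace = make_trace(np.arange(96) * 15, glucose, start="2024-01-02T00:00:00")
    (window,) = segment_days(trace, qc)
    daily = daily_biomarkers(window, det)
    assert daily.min_glycaemia == 65.0 < det.threshold
    assert daily.hypo_auc == 0.0 and daily.n_episodes == 0


def test_min_never_exceeds_mean_and_cv_time_shift_invariant(det, rng):
    qc = QCConfig(min_completeness=0.05)
    for _ in range(50):
        n = int(rng.integers(5, 88))  # keep the +60-min shift within the day
        glucose = rng.uniform(55, 130, size=n)
        base = make_trace(np.arange(n) * 15, glucose, start="2024-01-02T00:00:00")
        shifted = make_trace(np.arange(n) * 15 + 60, glucose,
                             start="2024-01-02T00:00:00")
        (w1,) = segment_days(base, qc)
        (w2,) = segment_days(shifted, qc)
        d1, d2 = daily_biomarkers(w1, det), daily_biomarkers(w2, det)
        assert d1.min_glycaemia <= d1.mean_glycaemia
        assert d1.cv == pytest.approx(d2.cv)


def test_invalid_window_is_a_contract_violation(det):
    (window,) = segment_days(grid_day(10), QCConfig())
    assert not window.valid
    with pytest.raises(ValueError, match="completeness"):
        daily_biomarkers(window, det)


# ---------------------------------------------------------------- aggregation

def _daily(date, mean, minimum, cv, auc, neps):
    return DailyBiomarkers(date, 96, mean, minimum, cv, auc, neps)


def test_aggregate_identical_days_reproduces_daily_values():
    d = _daily("2024-01-02", 90.0, 70.0, 0.1, 12.5, 1)
    agg = aggregate_subject([d, d], "S1")
    assert (agg.mean_glycaemia, agg.min_glycaemia, agg.cv, agg.hypo_auc) == (
        90.0, 70.0, 0.1, 12.5,
    )
    assert agg.n_valid_days == 2


def test_aggregate_means_daily_values_and_ignores_order():
    days = [
        _daily("2024-01-02", 92.0, 75.0, 0.10, 0.0, 0),
        _daily("2024-01-03", 88.0, 65.0, 0.14, 100.0, 2),
    ]
    a = aggregate_subject(days, "S1")
    b = aggregate_subject(days[::-1], "S1")
    assert a.hypo_auc == 50.0
    assert a == b


def test_aggregate_requires_minimum_valid_days():
    d = _daily("2024-01-02", 90.0, 70.0, 0.1, 0.0, 0)
    with pytest.raises(IneligibleSubjectError):
        aggregate_subject([d], "S1", min_valid_days=2)


def test_detector_config_validation():
    with pytest.raises(ValueError):
        DetectorConfig(min_consecutive=1)
    with pytest.raises(ValueError):
        DetectorConfig(threshold=0)
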