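import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pupilswitch.config import GapProcess
from pupilswitch.preprocess import (
    N_ANALYSIS_SAMPLES,
    N_BINS,
    PreprocessError,
    aggregate_condition,
    average_eyes,
    baseline_correct,
    bin_series,
    compute_missing_rate,
    expected_samples,
    interpolate_gaps,
    lowpass_4hz,
    preprocess_trial,
    read_timecourse,
    run_preprocess,
    select_trials,
    write_timecourse,
)
from pupilswitch.synth import (
    ParticipantProfile,
    generate_dataset,
    generate_trial_trace,
    pupil_kernel,
)


def _trace(cfg, condition="familiar", seed=0, amp=1.0):
    profile = ParticipantProfile("p0", "15mo", 3.5, amp)
    return generate_trial_trace(cfg, profile, condition, np.random.default_rng(seed))


# ----------------------------------------------------------------------
# missing rate
# ----------------------------------------------------------------------
def test_missing_rate_zero_when_complete(quiet_config):
    trial = _trace(quiet_config)
    assert compute_missing_rate(trial) == 0.0


def test_missing_rate_threshold_boundary(quiet_config):
    trial = _trace(quiet_config)
    trial.left_valid[:384] = False
    trial.right_valid[:384] = False
    trial.left_pupil_mm[:384] = np.nan
    trial.right_pupil_mm[:384] = np.nan
    rate = compute_missing_rate(trial)
    assert rate == pytest.approx(0.40)
    # strict '<' at the threshold: exactly 40% is excluded
    pt = preprocess_trial(trial)
    assert not pt.included
    assert pt.exclusion_reason == "missing_rate"


def test_missing_rate_counts_single_eye_as_present(quiet_config):
    trial = _trace(quiet_config)
    trial.left_valid[:150] = False
    trial.left_pupil_mm[:150] = np.nan
    trial.right_valid[:100] = False
    trial.right_pupil_mm[:100] = np.nan
    # 100 samples missing both eyes, 50 missing only the left
    assert compute_missing_rate(trial) == pytest.approx(100 / 960)


def test_expected_samples():
    assert expected_samples(8000.0, 120.0) == 960
    with pytest.raises(PreprocessError):
        expected_samples(0.0, 120.0)


# ----------------------------------------------------------------------
# interpolation
# ----------------------------------------------------------------------
def test_interpolation_linear_example():
    values = np.array([3.0, np.nan, np.nan, 3.3])
    valid = np.array([True, False, False, True])
    filled, gaps = interpolate_gaps(values, valid, 10.0)
    np.testing.assert_allclose(filled, [3.0, 3.1, 3.2, 3.3])
    assert gaps == [20.0]


def test_interpolation_identity_without_gaps(rng):
    values = rng.normal(3.5, 0.1, 100)
    filled, gaps = interpolate_gaps(values, np.ones(100, bool), 8.333)
    np.testing.assert_array_equal(filled, values)
    assert gaps == []


def test_interpolation_edge_hold():
    values = np.array([np.nan, np.nan, 2.0, 4.0, np.nan])
    valid = np.array([False, False, True, True, False])
    filled, gaps = interpolate_gaps(values, valid, 10.0)
    np.testing.assert_allclose(filled, [2.0, 2.0, 2.0, 4.0, 4.0])
    assert gaps == []  # edge holds are not interior interpolations


def test_interpolation_all_missing_marks_unusable():
    filled, gaps = interpolate_gaps(np.full(10, np.nan), np.zeros(10, bool), 10.0)
    assert np.isnan(filled).all()


@given(
    seed=st.integers(0, 10_000),
    slope=st.floats(-0.01, 0.01),
    intercept=st.floats(2.0, 5.0),
)
@settings(max_examples=50, deadline=None)
def test_interpolation_exact_on_linear_ramp(seed, slope, intercept):
    """Any interior gap pattern on a linear ramp is reconstructed exactly."""
    n = 120
    values = intercept + slope * np.arange(n)
    rng = np.random.default_rng(seed)
    valid = rng.random(n) > 0.4
    valid[0] = valid[-1] = True  # keep the gaps interior
    masked = np.where(valid, values, np.nan)
    filled, _ = interpolate_gaps(masked, valid, 8.333)
    np.testing.assert_allclose(filled, values, atol=1e-9)


# ----------------------------------------------------------------------
# filtering
# ----------------------------------------------------------------------
def test_filter_dc_gain_one():
    out = lowpass_4hz(np.full(960, 3.5), 120.0)
    np.testing.assert_allclose(out, 3.5, atol=1e-9)


def _filtfilt_gain(freq_hz: float, rate: float = 120.0) -> float:
    """Independent frequency-response oracle from the transfer function."""
    from scipy import signal

    b, a = signal.butter(2, 4.0, btype="low", fs=rate)
    _, h = signal.freqz(b, a, worN=[2 * np.pi * freq_hz / rate])
    return float(np.abs(h[0]) ** 2)  # forward+backward squares the magnitude


def test_filter_attenuates_10hz_sine():
    rate = 120.0
    t = np.arange(960) / rate
    out = lowpass_4hz(np.sin(2 * np.pi * 10.0 * t), rate)
    # steady-state amplitude away from the edges
    amp = np.abs(out[200:-200]).max()
    oracle = _filtfilt_gain(10.0)
    assert amp < 0.1
    assert amp == pytest.approx(oracle, rel=0.05)


def test_filter_passes_low_frequency():
    rate = 120.0
    t = np.arange(2400) / rate
    out = lowpass_4hz(np.sin(2 * np.pi * 0.5 * t), rate)
    amp = np.abs(out[400:-400]).max()
    assert amp >= 0.95
    assert amp == pytest.approx(_filtfilt_gain(0.5), rel=0.02)


def test_filter_separates_mixed_sines():
    rate = 120.0
    t = np.arange(2400) / rate
    low = np.sin(2 * np.pi * 0.5 * t)
    high = np.sin(2 * np.pi * 15.0 * t)
    out = lowpass_4hz(low + high, rate)
    inner = slice(300, -300)
    rms_err = np.sqrt(np.mean((out[inner] - low[inner] * _filtfilt_gain(0.5)) ** 2))
    assert rms_err < 0.1


def test_filter_too_short_series():
    with pytest.raises(PreprocessError, match="samples"):
        lowpass_4hz(np.ones(5), 120.0)


def test_filter_rejects_nan():
    series = np.ones(100)
    series[3] = np.nan
    with pytest.raises(PreprocessError):
        lowpass_4hz(series, 120.0)


# ----------------------------------------------------------------------
# eye averaging
# ----------------------------------------------------------------------
def test_average_eyes_basic():
    left = np.array([3.0, 3.0, 3.0])
    right = np.array([3.4, 3.0, np.nan])
    np.testing.assert_allclose(average_eyes(left, right), [3.2, 3.0, 3.0])
    np.testing.assert_array_equal(average_eyes(left, left), left)


# ----------------------------------------------------------------------
# baseline correction
# ----------------------------------------------------------------------
def test_baseline_constant_series_zeroed():
    t = np.arange(960) * (1000.0 / 120.0)
    out = baseline_correct(np.full(960, 4.2), t, 3680.0)
    np.testing.assert_allclose(out, 0.0, atol=1e-12)
    assert out.size == np.sum(t >= 3680.0)


def test_baseline_step_series():
    t = np.arange(960) * (1000.0 / 120.0)
    series = np.where(t < 3680.0, 3.0, 3.2)
    out = baseline_correct(series, t, 3680.0)
    np.testing.assert_allclose(out, 0.2, atol=1e-12)


@given(c=st.floats(-2.0, 2.0), seed=st.integers(0, 1000))
@settings(max_examples=30, deadline=None)
def test_baseline_shift_invariance(c, seed):
    t = np.arange(960) * (1000.0 / 120.0)
    series = 3.5 + 0.1 * np.sin(t / 500.0) + np.random.default_rng(seed).normal(0, 0.01, 960)
    a = baseline_correct(series, t, 3680.0)
    b = baseline_correct(series + c, t, 3680.0)
    np.testing.assert_allclose(a, b, atol=1e-9)


def test_baseline_missing_window_errors():
    t = np.arange(100) * (1000.0 / 120.0) + 5000.0
    with pytest.raises(PreprocessError):
        baseline_correct(np.ones(100), t, 3680.0)


# ----------------------------------------------------------------------
# binning
# ----------------------------------------------------------------------
def test_bin_constant():
    bins = bin_series(np.full(520, 0.3))
    assert bins.shape == (86,)
    np.testing.assert_allclose(bins, 0.3)


def test_bin_index_ramp_oracle():
    bins = bin_series(np.arange(520, dtype=float))
    np.testing.assert_allclose(bins, 6 * np.arange(86) + 2.5)


def test_bin_discards_last_four():
    series = np.zeros(520)
    series[516:] = 99.0  # discarded samples must not leak into any bin
    np.testing.assert_allclose(bin_series(series), 0.0)


def test_bin_too_short_errors():
    with pytest.raises(PreprocessError, match="excluded"):
        bin_series(np.zeros(519))


# ----------------------------------------------------------------------
# trial pipeline & invariants
# ----------------------------------------------------------------------
def test_pipeline_baseline_window_mean_zero(small_config):
    ds = generate_dataset(small_config)
    checked = 0
    for trial in ds.test_trials():
        pt = preprocess_trial(trial)
        if not pt.included:
            continue
        # recompute the corrected full series the way the pipeline does
        from pupilswitch.preprocess import lowpass_4hz as lp

        eyes = []
        for values, valid in (
            (trial.left_pupil_mm, trial.left_valid),
            (trial.right_pupil_mm, trial.right_valid),
        ):
            filled, _ = interpolate_gaps(values, valid, trial.sample_period_ms)
            eyes.append(lp(filled, trial.sampling_rate))
        combined = average_eyes(eyes[0], eyes[1])
        corrected = baseline_correct(
            combined, trial.t_ms, trial.sound_onset_ms, restrict=False
        )
        window = (trial.t_ms >= trial.sound_onset_ms - 1000.0) & (
            trial.t_ms < trial.sound_onset_ms
        )
        assert abs(corrected[window].mean()) < 1e-9
        checked += 1
    assert checked > 5


def test_pipeline_rejects_familiarization():
    import dataclasses

    from pupilswitch.config import SimulationConfig

    cfg = SimulationConfig().validate()
    profile = ParticipantProfile("p0", "15mo", 3.5, 1.0)
    fam = generate_trial_trace(
        cfg, profile, "A1", np.random.default_rng(0), phase="familiarization", block=0
    )
    with pytest.raises(PreprocessError):
        preprocess_trial(fam)


def test_noise_free_binned_difference_matches_kernel(quiet_config):
    """End-to-end: binned condition differences equal the binned generator
    kernel away from onset edges (filter edge effects excluded)."""
    cfg = quiet_config
    fam = preprocess_trial(_trace(cfg, "familiar"))
    nov = preprocess_trial(_trace(cfg, "novel"))
    swi = preprocess_trial(_trace(cfg, "switched"))
    onset = cfg.timeline.sound_onset_ms
    from pupilswitch.config import ASSOCIATION, PERCEPTUAL

    comps = {c.name: c for c in cfg.components["15mo"]}
    # time axis of the analysis window (last 520 samples of the trial)
    t_win = _trace(cfg, "familiar").t_ms[-N_ANALYSIS_SAMPLES:]
    for pt, comp_name in ((nov, PERCEPTUAL), (swi, ASSOCIATION)):
        comp = comps[comp_name]
        kernel_bins = bin_series(pupil_kernel(t_win - onset, comp))
        diff_bins = pt.bins - fam.bins
        onset_bin = int(np.ceil(comp.onset_latency_ms / 50.0))
        keep = np.ones(N_BINS, bool)
        keep[max(0, onset_bin - 2) : onset_bin + 3] = False  # onset edge
        keep[:3] = keep[-3:] = False  # filtfilt edge effects
        rms = np.sqrt(np.mean((diff_bins[keep] - kernel_bins[keep]) ** 2))
        assert rms < 0.02 * comp.amplitude_mm


# ----------------------------------------------------------------------
# selection
# ----------------------------------------------------------------------
def test_select_trials_all_clean(quiet_config):
    ds = generate_dataset(quiet_config)
    preprocessed = [preprocess_trial(t) for t in ds.test_trials()]
    kept, retained, report = select_trials(preprocessed)
    assert len(kept) == len(preprocessed)
    assert report.n_retained_participants == report.n_participants


def test_participant_without_novel_dropped(quiet_config):
    ds = generate_dataset(quiet_config)
    preprocessed = [preprocess_trial(t) for t in ds.test_trials()]
    victim = preprocessed[0].trial.participant_id
    for pt in preprocessed:
        if pt.trial.participant_id == victim and pt.trial.condition == "novel":
            pt.included = False
            pt.exclusion_reason = "missing_rate"
    kept, retained, report = select_trials(preprocessed)
    kept_pids = {pt.trial.participant_id for pt in kept}
    assert victim not in kept_pids
    assert victim in sum(report.dropped_participants.values(), [])


def test_exclusion_levels_near_target_rates():
    """Default cohort tuned so that about 72/90 test trials survive in the
    larger group and 60/80 in the smaller one."""
    from pupilswitch.config import SimulationConfig

    cfg = SimulationConfig(seed=3).validate()
    ds = generate_dataset(cfg)
    preprocessed = [preprocess_trial(t) for t in ds.test_trials()]
    _, _, report = select_trials(preprocessed)
    assert report.n_trials == {"10mo": 90, "15mo": 80}
    # binomial 3-sigma bands around the target inclusion rates
    for age, target in (("10mo", 72), ("15mo", 60)):
        n = report.n_trials[age]
        p = target / n
        sd = np.sqrt(n * p * (1 - p))
        assert abs(report.n_included_trials[age] - target) < 3 * sd


# ----------------------------------------------------------------------
# aggregation & time-course round trip
# ----------------------------------------------------------------------
def test_aggregate_single_trials(quiet_config):
    ds = generate_dataset(quiet_config)
    preprocessed = [preprocess_trial(t) for t in ds.test_trials()]
    kept, _, _ = select_trials(preprocessed)
    tc = aggregate_condition(
        [pt for pt in kept if pt.trial.age_group == "15mo"], "15mo"
    )
    assert tc.data.shape == (2, 3, 86)
    # familiar/switched have 2 trials each, novel has 1
    np.testing.assert_array_equal(tc.trial_counts, [[2, 2, 1]] * 2)
    # the novel cell must equal that participant's single novel trial
    pid = tc.participants[0]
    novel_bins = next(
        pt.bins
        for pt in kept
        if pt.trial.participant_id == pid and pt.trial.condition == "novel"
    )
    np.testing.assert_array_equal(tc.data[0, 2], novel_bins)


def test_aggregate_mean_of_two_trials(quiet_config):
    ds = generate_dataset(quiet_config)
    preprocessed = [preprocess_trial(t) for t in ds.test_trials()]
    kept, _, _ = select_trials(preprocessed)
    pts = [pt for pt in kept if pt.trial.age_group == "15mo"]
    tc = aggregate_condition(pts, "15mo")
    pid = tc.participants[0]
    fams = [
        pt.bins
        for pt in pts
        if pt.trial.participant_id == pid and pt.trial.condition == "familiar"
    ]
    assert len(fams) == 2
    np.testing.assert_allclose(tc.data[0, 0], (fams[0] + fams[1]) / 2.0)


def test_aggregate_missing_condition_asserts(quiet_config):
    ds = generate_dataset(quiet_config)
    preprocessed = [preprocess_trial(t) for t in ds.test_trials()]
    kept, _, _ = select_trials(preprocessed)
    pts = [
        pt
        for pt in kept
        if pt.trial.age_group == "15mo" and pt.trial.condition != "novel"
    ]
    with pytest.raises(AssertionError):
        aggregate_condition(pts, "15mo")


def test_timecourse_tsv_round_trip(tmp_path, small_config):
    ds = generate_dataset(small_config)
    tcs, _ = run_preprocess(ds)
    path = tmp_path / "tc.tsv"
    write_timecourse(tcs, str(path))
    back = read_timecourse(str(path))
    assert set(back) == set(tcs)
    for age in tcs:
        assert back[age].participants == tcs[age].participants
        np.testing.assert_allclose(back[age].data, tcs[age].data)
        np.testing.assert_array_equal(back[age].trial_counts, tcs[age].trial_counts)


def test_qc_gap_fit(small_config):
    ds = generate_dataset(small_config)
    _, qc = run_preprocess(ds)
    d = qc.to_dict()
    for age, fit in d["gap_exp_fit"].items():
        if fit["n"] > 20:
            assert fit["ci_low"] < fit["mean_ms"] < fit["ci_high"]
            assert d["fraction_gaps_below_500ms"][age] > 0.9
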