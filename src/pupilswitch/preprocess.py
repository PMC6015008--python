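"""Test-trial preprocessing: inclusion, interpolation, filtering, binocular
averaging, baseline correction, binning, and per-condition aggregation.

The stage order is fixed: missing-rate inclusion decision first (computed
on the raw validity flags), then per-eye linear interpolation of gaps,
zero-phase 4-Hz low-pass filtering per eye over the full trial, binocular
averaging, subtraction of the mean over the 1000-ms pre-sound baseline
window, and finally averaging into 50-ms bins.

Windowing note: the nominal post-onset stretch (8000 − 3680 = 4320 ms at
120 Hz) contains 518 whole samples, yet the analysis convention expects
520 samples → 86 bins + 4 discarded. We therefore take the trailing 520
samples of the nominal 960-sample trial (the window starts two samples,
~16.7 ms, before nominal sound onset), which reproduces the 520/86/4
arithmetic exactly.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import signal as sp_signal
from scipy import stats as sp_stats

from .config import CONDITIONS
from .io import GazeDataset, TrialRecording

#: trials are kept only when the missing rate is strictly below this
MISSING_RATE_THRESHOLD = 0.40

#: samples per 50-ms bin at 120 Hz, and bins per test trial
SAMPLES_PER_BIN = 6
N_BINS = 86

#: analysis window length in samples (86 bins * 6 + 4 discarded)
N_ANALYSIS_SAMPLES = N_BINS * SAMPLES_PER_BIN + 4

BASELINE_WINDOW_MS = 1000.0

FILTER_CUTOFF_HZ = 4.0
FILTER_ORDER = 2  # applied forward and backward -> effective 4th order


class PreprocessError(ValueError):
    pass


def expected_samples(duration_ms: float, sampling_rate: float) -> int:
    """Nominal sample count of a trial (e.g. 960 for 8000 ms at 120 Hz)."""
    if duration_ms <= 0:
        raise PreprocessError("zero or negative trial duration")
    return int(round(duration_ms * sampling_rate / 1000.0))


def compute_missing_rate(trial: TrialRecording) -> float:
    """Fraction of nominal samples with no valid eye.

    The denominator is the nominal expected sample count for the trial
    duration; samples missing entirely from the recording and samples
    where both validity flags are false both count as missing. A sample
    with at least one valid eye counts as present.
    """
    n_expected = expected_samples(trial.duration_ms, trial.sampling_rate)
    n_present = int(np.sum(trial.left_valid | trial.right_valid))
    return (n_expected - n_present) / n_expected


def interpolate_gaps(
    values: np.ndarray, valid: np.ndarray, sample_period_ms: float
) -> tuple[np.ndarray, list[float]]:
    """Fill invalid runs of a single-eye series.

    Interior gaps are bridged linearly between the last valid sample
    before and the first valid sample after the gap. Leading/trailing gaps
    are filled by nearest-value hold. Returns the filled series and the
    lengths (ms) of the interior gaps that were linearly interpolated.

    An all-missing series is returned as-is (all NaN): that eye is
    unusable and is ignored by the binocular average.
    """
    values = np.asarray(values, float)
    valid = np.asarray(valid, bool)
    n = values.size
    if not valid.any():
        return np.full(n, np.nan), []
    idx = np.arange(n)
    filled = np.interp(idx, idx[valid], values[valid])
    first = idx[valid][0]
    # run boundaries of invalid stretches
    edges = np.flatnonzero(np.diff(np.concatenate(([False], ~valid, [False])).astype(int)))
    starts, ends = edges[::2], edges[1::2]
    interior = (starts > first) & (ends < n)  # leading/trailing runs are held
    gap_lengths = [
        float((e - s) * sample_period_ms) for s, e in zip(starts[interior], ends[interior])
    ]
    return filled, gap_lengths


def lowpass_4hz(
    series: np.ndarray,
    sampling_rate: float,
    cutoff_hz: float = FILTER_CUTOFF_HZ,
    order: int = FILTER_ORDER,
) -> np.ndarray:
    """Zero-phase Butterworth low-pass (−3 dB at ``cutoff_hz``).

    The filter is applied forward and backward (`filtfilt`), so the
    effective magnitude response is the squared Butterworth response and
    the phase is exactly zero. DC gain is 1: a constant series passes
    through unchanged.
    """
    series = np.asarray(series, float)
    if np.isnan(series).any():
        raise PreprocessError("lowpass filter requires a gap-free series")
    b, a = sp_signal.butter(order, cutoff_hz, btype="low", fs=sampling_rate)
    padlen = 3 * max(len(a), len(b))
    if series.size <= padlen:
        raise PreprocessError(
            f"series too short to filter: need more than {padlen} samples, "
            f"got {series.size}"
        )
    return sp_signal.filtfilt(b, a, series)


def average_eyes(left: np.ndarray, right: np.ndarray) -> np.ndarray:
    """Per-sample mean of the available eyes.

    Samples where one eye is NaN pass the other eye through; both-NaN
    samples stay NaN (those trials are removed upstream by the
    missing-rate criterion).
    """
    left = np.asarray(left, float)
    right = np.asarray(right, float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
        return np.nanmean(np.stack([left, right]), axis=0)


def baseline_correct(
    series: np.ndarray,
    t_ms: np.ndarray,
    sound_onset_ms: float,
    window_ms: float = BASELINE_WINDOW_MS,
    restrict: bool = True,
) -> np.ndarray:
    """Subtract the mean over the pre-onset baseline window.

    The window is ``[sound_onset_ms - window_ms, sound_onset_ms)``. With
    ``restrict=True`` (the op-level contract) only samples at/after sound
    onset are returned; the pipeline calls with ``restrict=False`` and
    slices its fixed-length analysis window instead.
    """
    series = np.asarray(series, float)
    t_ms = np.asarray(t_ms, float)
    in_window = (t_ms >= sound_onset_ms - window_ms) & (t_ms < sound_onset_ms)
    if not in_window.any():
        raise PreprocessError("no samples in the baseline window")
    corrected = series - np.nanmean(series[in_window])
    if restrict:
        return corrected[t_ms >= sound_onset_ms]
    return corrected


def baseline_window_coverage(trial: TrialRecording, window_ms: float = BASELINE_WINDOW_MS) -> float:
    """Fraction of the nominal baseline window with at least one valid eye."""
    onset = trial.sound_onset_ms
    if onset is None:
        raise PreprocessError("trial has no sound onset")
    in_window = (trial.t_ms >= onset - window_ms) & (trial.t_ms < onset)
    n_expected = int(round(window_ms * trial.sampling_rate / 1000.0))
    present = int(np.sum(in_window & (trial.left_valid | trial.right_valid)))
    return present / n_expected


def bin_series(
    rel_series: np.ndarray,
    n_bins: int = N_BINS,
    samples_per_bin: int = SAMPLES_PER_BIN,
    min_samples: int = N_ANALYSIS_SAMPLES,
) -> np.ndarray:
    """Average consecutive groups of ``samples_per_bin`` samples into bins.

    A 520-sample input yields 86 bins with the trailing 4 samples
    discarded. Input shorter than ``min_samples`` is an error — such
    trials are excluded upstream; longer input is truncated.
    """
    rel_series = np.asarray(rel_series, float)
    if rel_series.size < min_samples:
        raise PreprocessError(
            f"cannot bin {rel_series.size} samples (need >= {min_samples}); "
            "trial should be excluded"
        )
    used = n_bins * samples_per_bin
    return rel_series[:used].reshape(n_bins, samples_per_bin).mean(axis=1)


def bin_start_times_ms(
    sound_onset_ms: float = 3680.0, n_bins: int = N_BINS, bin_ms: float = 50.0
) -> np.ndarray:
    """Nominal start time of each bin, ms after sound onset."""
    return np.arange(n_bins) * bin_ms


# ----------------------------------------------------------------------
@dataclass
class PreprocessedTrial:
    trial: TrialRecording
    missing_rate: float
    included: bool
    exclusion_reason: str | None = None
    rel_series: np.ndarray | None = None
    bins: np.ndarray | None = None
    interpolated_gap_lengths_ms: list[float] = field(default_factory=list)


def preprocess_trial(
    trial: TrialRecording,
    threshold: float = MISSING_RATE_THRESHOLD,
    n_analysis_samples: int = N_ANALYSIS_SAMPLES,
) -> PreprocessedTrial:
    """Run the full single-trial pipeline in the canonical order."""
    if trial.phase != "test" or trial.sound_onset_ms is None:
        raise PreprocessError("preprocessing applies to test trials only")
    missing_rate = compute_missing_rate(trial)
    if not missing_rate < threshold:  # strict '<' at the threshold
        return PreprocessedTrial(trial, missing_rate, False, "missing_rate")
    if baseline_window_coverage(trial) < 0.5:
        return PreprocessedTrial(trial, missing_rate, False, "baseline_window")
    if trial.n_samples < n_analysis_samples:
        return PreprocessedTrial(trial, missing_rate, False, "too_short")

    period = trial.sample_period_ms
    gap_lengths: list[float] = []
    eyes = []
    for values, valid in (
        (trial.left_pupil_mm, trial.left_valid),
        (trial.right_pupil_mm, trial.right_valid),
    ):
        filled, gaps = interpolate_gaps(values, valid, period)
        if np.isnan(filled).all():
            eyes.append(filled)  # eye unusable
        else:
            gap_lengths.extend(gaps)
            eyes.append(lowpass_4hz(filled, trial.sampling_rate))
    combined = average_eyes(eyes[0], eyes[1])
    corrected = baseline_correct(
        combined, trial.t_ms, trial.sound_onset_ms, restrict=False
    )
    rel_series = corrected[-n_analysis_samples:]
    bins = bin_series(rel_series)
    return PreprocessedTrial(
        trial,
        missing_rate,
        True,
        None,
        rel_series=rel_series,
        bins=bins,
        interpolated_gap_lengths_ms=gap_lengths,
    )


# ----------------------------------------------------------------------
@dataclass
class SelectionReport:
    """Per-age inclusion bookkeeping for the exclusion report."""

    n_trials: dict[str, int]
    n_included_trials: dict[str, int]
    n_participants: dict[str, int]
    n_retained_participants: dict[str, int]
    dropped_participants: dict[str, list[str]]


def select_trials(
    preprocessed: Sequence[PreprocessedTrial],
    conditions: Sequence[str] = CONDITIONS,
) -> tuple[list[PreprocessedTrial], dict[str, list[str]], SelectionReport]:
    """Apply the participant-level retention rule.

    A participant is retained only if, among their included trials, at
    least one trial remains in every condition. Returns the included
    trials of retained participants, the retained participant ids per age
    group, and a report with counts.
    """
    by_age_trials: dict[str, int] = {}
    by_age_included: dict[str, int] = {}
    participants: dict[tuple[str, str], dict[str, int]] = {}
    for pt in preprocessed:
        age = pt.trial.age_group
        by_age_trials[age] = by_age_trials.get(age, 0) + 1
        key = (age, pt.trial.participant_id)
        participants.setdefault(key, {c: 0 for c in conditions})
        if pt.included:
            by_age_included[age] = by_age_included.get(age, 0) + 1
            participants[key][pt.trial.condition] += 1

    retained: dict[str, list[str]] = {}
    dropped: dict[str, list[str]] = {}
    for (age, pid), counts in participants.items():
        ok = all(counts[c] >= 1 for c in conditions)
        (retained if ok else dropped).setdefault(age, []).append(pid)

    retained_set = {(a, p) for a, ps in retained.items() for p in ps}
    kept = [
        pt
        for pt in preprocessed
        if pt.included and (pt.trial.age_group, pt.trial.participant_id) in retained_set
    ]
    report = SelectionReport(
        n_trials=by_age_trials,
        n_included_trials={a: by_age_included.get(a, 0) for a in by_age_trials},
        n_participants={
            a: sum(1 for (ag, _p) in participants if ag == a) for a in by_age_trials
        },
        n_retained_participants={a: len(retained.get(a, [])) for a in by_age_trials},
        dropped_participants=dropped,
    )
    return kept, retained, report


# ----------------------------------------------------------------------
@dataclass
class ConditionTimeCourse:
    """Participant × condition × bin array of mean relative pupil change."""

    age_group: str
    participants: list[str]
    conditions: tuple[str, ...]
    data: np.ndarray  # (n_participants, n_conditions, n_bins)
    trial_counts: np.ndarray  # (n_participants, n_conditions)

    @property
    def n_participants(self) -> int:
        return len(self.participants)

    @property
    def n_bins(self) -> int:
        return self.data.shape[2]


def aggregate_condition(
    included: Sequence[PreprocessedTrial],
    age_group: str,
    conditions: Sequence[str] = CONDITIONS,
) -> ConditionTimeCourse:
    """Average each participant's included trials per condition into bins."""
    by_participant: dict[str, dict[str, list[np.ndarray]]] = {}
    for pt in included:
        if pt.trial.age_group != age_group:
            continue
        assert pt.included and pt.bins is not None
        by_participant.setdefault(pt.trial.participant_id, {}).setdefault(
            pt.trial.condition, []
        ).append(pt.bins)
    pids = sorted(by_participant)
    n_bins = N_BINS if not included else next(
        pt.bins.size for pt in included if pt.bins is not None
    )
    data = np.empty((len(pids), len(conditions), n_bins))
    counts = np.zeros((len(pids), len(conditions)), dtype=int)
    for i, pid in enumerate(pids):
        for j, cond in enumerate(conditions):
            stack = by_participant[pid].get(cond, [])
            assert stack, (
                f"participant {pid} lacks condition {cond!r}: "
                "select_trials should have dropped them"
            )
            data[i, j] = np.mean(stack, axis=0)
            counts[i, j] = len(stack)
    return ConditionTimeCourse(age_group, pids, tuple(conditions), data, counts)


def write_timecourse(timecourses: Mapping[str, ConditionTimeCourse], path: str) -> None:
    """Write per-age condition time courses as a long-format TSV."""
    rows = []
    for age, tc in timecourses.items():
        for i, pid in enumerate(tc.participants):
            for j, cond in enumerate(tc.conditions):
                for b in range(tc.n_bins):
                    rows.append(
                        (age, pid, cond, b, b * 50.0, tc.data[i, j, b],
                         int(tc.trial_counts[i, j]))
                    )
    import pandas as pd

    frame = pd.DataFrame(
        rows,
        columns=["age_group", "participant_id", "condition", "bin",
                 "t_start_ms", "value", "n_trials"],
    )
    frame.to_csv(path, sep="\t", index=False)


def read_timecourse(path: str) -> dict[str, ConditionTimeCourse]:
    """Read a time-course TSV written by :func:`write_timecourse`."""
    import pandas as pd

    frame = pd.read_csv(path, sep="\t", dtype={"participant_id": str})
    out: dict[str, ConditionTimeCourse] = {}
    for age, g in frame.groupby("age_group", sort=True):
        pids = sorted(g["participant_id"].unique())
        conds = tuple(c for c in CONDITIONS if c in set(g["condition"]))
        n_bins = int(g["bin"].max()) + 1
        data = np.full((len(pids), len(conds), n_bins), np.nan)
        counts = np.zeros((len(pids), len(conds)), dtype=int)
        pidx = {p: i for i, p in enumerate(pids)}
        cidx = {c: j for j, c in enumerate(conds)}
        for (pid, cond), gg in g.groupby(["participant_id", "condition"]):
            i, j = pidx[pid], cidx[cond]
            data[i, j, gg["bin"].to_numpy()] = gg["value"].to_numpy()
            counts[i, j] = int(gg["n_trials"].iloc[0])
        if np.isnan(data).any():
            raise PreprocessError(f"incomplete time course for age group {age!r}")
        out[str(age)] = ConditionTimeCourse(str(age), pids, conds, data, counts)
    return out


# ----------------------------------------------------------------------
@dataclass
class QCReport:
    selection: SelectionReport
    missing_rates: dict[str, list[float]]
    gap_lengths_ms: dict[str, list[float]]
    gap_exp_fit: dict[str, dict[str, float]]

    def to_dict(self) -> dict:
        return {
            "selection": {
                "n_trials": self.selection.n_trials,
                "n_included_trials": self.selection.n_included_trials,
                "n_participants": self.selection.n_participants,
                "n_retained_participants": self.selection.n_retained_participants,
                "dropped_participants": self.selection.dropped_participants,
            },
            "missing_rates": self.missing_rates,
            "gap_exp_fit": self.gap_exp_fit,
            "fraction_gaps_below_500ms": {
                age: (
                    float(np.mean(np.asarray(g) < 500.0)) if g else float("nan")
                )
                for age, g in self.gap_lengths_ms.items()
            },
        }


def fit_gap_exponential(gap_lengths_ms: Sequence[float]) -> dict[str, float]:
    """Exponential (MLE) fit of gap lengths with a 95% CI on the mean.

    Uses the exact chi-square interval for the exponential mean.
    """
    g = np.asarray(gap_lengths_ms, float)
    n = g.size
    if n == 0:
        return {"mean_ms": float("nan"), "ci_low": float("nan"), "ci_high": float("nan"), "n": 0}
    mean = float(g.mean())
    total = g.sum()
    lo = 2 * total / sp_stats.chi2.ppf(0.975, 2 * n)
    hi = 2 * total / sp_stats.chi2.ppf(0.025, 2 * n)
    return {"mean_ms": mean, "ci_low": float(lo), "ci_high": float(hi), "n": int(n)}


def run_preprocess(
    dataset: GazeDataset,
) -> tuple[dict[str, ConditionTimeCourse], QCReport]:
    """Preprocess every test trial and build per-age condition time courses."""
    preprocessed = [preprocess_trial(t) for t in dataset.test_trials()]
    kept, retained, selection = select_trials(preprocessed)
    timecourses = {
        age: aggregate_condition(
            [pt for pt in kept if pt.trial.age_group == age], age
        )
        for age in sorted(retained)
        if retained[age]
    }
    missing_rates: dict[str, list[float]] = {}
    gap_lengths: dict[str, list[float]] = {}
    for pt in preprocessed:
        age = pt.trial.age_group
        missing_rates.setdefault(age, []).append(float(pt.missing_rate))
        gap_lengths.setdefault(age, []).extend(pt.interpolated_gap_lengths_ms)
    qc = QCReport(
        selection=selection,
        missing_rates=missing_rates,
        gap_lengths_ms=gap_lengths,
        gap_exp_fit={age: fit_gap_exponential(g) for age, g in gap_lengths.items()},
    )
    return timecourses, qc
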