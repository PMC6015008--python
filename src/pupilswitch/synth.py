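"""Synthetic eye-tracking sessions with the statistical structure the
analysis pipeline assumes.

A cohort consists of two age groups; each participant contributes a
familiarization phase (blocks of fixed-pairing trials) and a test phase
(familiar / switched / novel trials). Test-trial pupil traces are the sum
of a participant baseline, a slow within-trial drift, condition-specific
gamma-shaped dilation components time-locked to sound onset, and
independent per-eye Gaussian noise. Missing data are injected as Poisson
gap onsets with (mostly short) exponential gap lengths.

Everything is driven by a :class:`~pupilswitch.config.SimulationConfig`
through a `numpy` SeedSequence hierarchy, so identical config + seed
yields a bit-identical dataset.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .config import (
    CONDITIONS,
    ComponentParams,
    ConfigError,
    GapProcess,
    SimulationConfig,
)
from .io import GazeDataset, TrialRecording

FAMILIARIZATION_PAIRS = ("A1", "A2")


def pupil_kernel(
    t_ms: np.ndarray, component: ComponentParams
) -> np.ndarray:
    """Evaluate a dilation component kernel at times ``t_ms`` after sound onset.

    Gamma-density-shaped rise and decay, normalized so the peak equals
    ``amplitude_mm`` and occurs ``rise_time_ms`` after ``onset_latency_ms``.
    Zero (exactly) at and before the onset latency.
    """
    tau = np.asarray(t_ms, float) - component.onset_latency_ms
    out = np.zeros_like(tau)
    pos = tau > 0
    x = tau[pos] / component.rise_time_ms
    a = component.shape
    out[pos] = component.amplitude_mm * x**a * np.exp(a * (1.0 - x))
    return out


@dataclass(frozen=True)
class ParticipantProfile:
    """Participant-level latent parameters, fixed across trials."""

    participant_id: str
    age_group: str
    baseline_mm: float
    amplitude_scale: float


def participant_profile(
    config: SimulationConfig, participant_id: str, age_group: str, rng: np.random.Generator
) -> ParticipantProfile:
    if age_group not in config.n_participants:
        raise ConfigError(f"unknown age group {age_group!r}")
    baseline = rng.normal(config.baseline_pupil_mean_mm, config.baseline_pupil_sd_mm)
    baseline = float(np.clip(baseline, 1.5, 8.0))
    amp = float(max(0.0, rng.normal(1.0, config.amplitude_subject_sd)))
    return ParticipantProfile(participant_id, age_group, baseline, amp)


def _two_state_chain(
    n: int, p_on: float, mean_away_samples: float, rng: np.random.Generator
) -> np.ndarray:
    """Sample an on/off sequence from a two-state Markov chain.

    Dwell times are geometric; the away dwell mean is ``mean_away_samples``
    and the looking dwell mean is chosen so the stationary probability of
    looking equals ``p_on``.
    """
    mean_on = mean_away_samples * p_on / (1.0 - p_on)
    state = bool(rng.random() < p_on)
    out = np.empty(n, dtype=bool)
    i = 0
    while i < n:
        mean = mean_on if state else mean_away_samples
        dwell = int(rng.geometric(min(1.0, 1.0 / mean)))
        j = min(n, i + dwell)
        out[i:j] = state
        i = j
        state = not state
    return out


def _drift(n: int, rate: float, drift_sd: float, rng: np.random.Generator) -> np.ndarray:
    """Slow within-trial fluctuation: a low-frequency sinusoid with random
    amplitude/frequency/phase. Survives the 4-Hz low-pass by design."""
    if drift_sd == 0.0:
        # keep the stream advancing identically whether or not drift is on
        rng.normal()
        rng.uniform()
        rng.uniform()
        return np.zeros(n)
    amp = rng.normal(0.0, drift_sd)
    freq_hz = rng.uniform(0.05, 0.25)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    t_s = np.arange(n) / rate
    return amp * np.sin(2.0 * np.pi * freq_hz * t_s + phase)


def generate_trial_trace(
    config: SimulationConfig,
    profile: ParticipantProfile,
    condition: str,
    rng: np.random.Generator,
    phase: str = "test",
    block: int | None = None,
    trial_idx: int = 0,
) -> TrialRecording:
    """Generate one gap-free trial for a participant.

    Both eyes share ``baseline + drift + applicable component kernels``
    (kernels time-locked to sound onset) and differ only by independent
    Gaussian noise. The on-screen flag comes from the two-state looking
    chain; missingness is injected separately by :func:`inject_missingness`.
    """
    if phase == "test":
        if condition not in CONDITIONS:
            raise ConfigError(f"unknown test condition {condition!r}")
        duration = config.timeline.test_duration_ms
        onset: float | None = config.timeline.sound_onset_ms
        p_on = config.looking.p_onscreen.get(condition, 0.9)
    else:
        if condition not in FAMILIARIZATION_PAIRS:
            raise ConfigError(f"unknown familiarization pair {condition!r}")
        if block is None or not 0 <= block < config.n_familiarization_blocks:
            raise ConfigError("familiarization trials need a valid block index")
        duration = config.timeline.familiarization_duration_ms
        onset = None
        p_on = config.looking.familiarization_block_p[block]
    if profile.age_group not in config.components:
        raise ConfigError(f"unknown age group {profile.age_group!r}")

    rate = config.sampling_rate
    n = int(round(duration * rate / 1000.0))
    t = np.round(np.arange(n) * (1000.0 / rate), 3)

    signal = np.full(n, profile.baseline_mm)
    signal += _drift(n, rate, config.drift_sd_mm, rng)
    if phase == "test":
        assert onset is not None
        for comp in config.components[profile.age_group]:
            if condition in comp.conditions_affected:
                signal += profile.amplitude_scale * pupil_kernel(t - onset, comp)

    if config.noise_sd_mm > 0:
        left = signal + rng.normal(0.0, config.noise_sd_mm, n)
        right = signal + rng.normal(0.0, config.noise_sd_mm, n)
    else:
        rng.normal(size=2 * n)  # keep stream alignment
        left = signal.copy()
        right = signal.copy()

    mean_away = config.looking.away_mean_ms * rate / 1000.0
    on_screen = _two_state_chain(n, p_on, mean_away, rng)

    return TrialRecording(
        participant_id=profile.participant_id,
        age_group=profile.age_group,
        phase=phase,
        block=block,
        trial_idx=trial_idx,
        condition=condition,
        duration_ms=duration,
        sound_onset_ms=onset,
        sampling_rate=rate,
        t_ms=t,
        left_pupil_mm=left,
        right_pupil_mm=right,
        left_valid=np.ones(n, dtype=bool),
        right_valid=np.ones(n, dtype=bool),
        on_screen=on_screen,
    )


def _apply_gap(
    trial: TrialRecording, start_ms: float, length_ms: float, eyes: tuple[bool, bool]
) -> None:
    mask = (trial.t_ms >= start_ms) & (trial.t_ms < start_ms + length_ms)
    if eyes[0]:
        trial.left_valid[mask] = False
        trial.left_pupil_mm[mask] = np.nan
    if eyes[1]:
        trial.right_valid[mask] = False
        trial.right_pupil_mm[mask] = np.nan


def inject_missingness(
    trial: TrialRecording, gap_process: GapProcess, rng: np.random.Generator
) -> TrialRecording:
    """Return a copy of ``trial`` with blink/dropout gaps injected.

    Gap start times follow a Poisson process; gap lengths are exponential
    with the configured mean, mixed with rare long gaps. Each gap hits
    both eyes with probability ``both_eyes_prob``, otherwise one random
    eye. The input trial must be gap-free.
    """
    if not (trial.left_valid.all() and trial.right_valid.all()):
        raise ValueError("inject_missingness requires a gap-free trial")
    out = dataclasses.replace(
        trial,
        t_ms=trial.t_ms.copy(),
        left_pupil_mm=trial.left_pupil_mm.copy(),
        right_pupil_mm=trial.right_pupil_mm.copy(),
        left_valid=trial.left_valid.copy(),
        right_valid=trial.right_valid.copy(),
        on_screen=trial.on_screen.copy(),
    )
    if gap_process.gap_rate_per_s == 0:
        return out
    duration_s = trial.duration_ms / 1000.0
    n_gaps = int(rng.poisson(gap_process.gap_rate_per_s * duration_s))
    for _ in range(n_gaps):
        start = rng.uniform(0.0, trial.duration_ms)
        length = sample_gap_length(gap_process, rng)
        if rng.random() < gap_process.both_eyes_prob:
            eyes = (True, True)
        else:
            eyes = (True, False) if rng.random() < 0.5 else (False, True)
        _apply_gap(out, start, length, eyes)
    return out


def sample_gap_length(gap_process: GapProcess, rng: np.random.Generator) -> float:
    """One gap length in ms: exponential, with a rare long-gap mixture."""
    if rng.random() < gap_process.long_gap_prob:
        return float(rng.exponential(gap_process.long_gap_length_mean_ms))
    return float(rng.exponential(gap_process.gap_length_mean_ms))


def _inject_dropout_burst(trial: TrialRecording, rng: np.random.Generator) -> None:
    """Force a trial over the missing-rate threshold with one huge gap."""
    frac = rng.uniform(0.45, 0.70)
    length = frac * trial.duration_ms
    start = rng.uniform(0.0, trial.duration_ms - length)
    _apply_gap(trial, start, length, (True, True))


def generate_dataset(config: SimulationConfig) -> GazeDataset:
    """Generate the full synthetic cohort for both age groups.

    Per participant: ``n_familiarization_blocks`` blocks of
    ``trials_per_block`` familiarization trials (pair labels alternating,
    order shuffled within block), then the test trials (familiar/switched
    shuffled, novel last). A random subset of test trials (per-age
    ``exclusion_target`` fraction) receives a long dropout burst so that
    it exceeds the downstream missing-rate criterion.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    trials: list[TrialRecording] = []
    for gi, age in enumerate(config.age_groups):
        group_seq = np.random.SeedSequence(config.seed, spawn_key=(gi,))
        for pi in range(config.n_participants[age]):
            pid = f"{age}_p{pi:03d}"
            child = np.random.SeedSequence(config.seed, spawn_key=(gi, pi))
            rng = np.random.default_rng(child)
            profile = participant_profile(config, pid, age, rng)

            idx = 0
            for block in range(config.n_familiarization_blocks):
                pairs = [
                    FAMILIARIZATION_PAIRS[k % len(FAMILIARIZATION_PAIRS)]
                    for k in range(config.trials_per_block)
                ]
                rng.shuffle(pairs)
                for pair in pairs:
                    trial = generate_trial_trace(
                        config, profile, pair, rng,
                        phase="familiarization", block=block, trial_idx=idx,
                    )
                    trial = inject_missingness(trial, config.gap_process, rng)
                    trials.append(trial)
                    idx += 1

            test_conditions = list(
                ("familiar",) * config.n_familiar_trials
                + ("switched",) * config.n_switched_trials
            )
            rng.shuffle(test_conditions)
            test_conditions += ["novel"] * config.n_novel_trials
            idx = 0
            for condition in test_conditions:
                trial = generate_trial_trace(
                    config, profile, condition, rng, phase="test", trial_idx=idx
                )
                trial = inject_missingness(trial, config.gap_process, rng)
                if rng.random() < config.exclusion_target[age]:
                    _inject_dropout_burst(trial, rng)
                trials.append(trial)
                idx += 1
        del group_seq  # reserved for future per-group streams
    del root
    meta = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "sampling_rate": config.sampling_rate,
        "test_duration_ms": config.timeline.test_duration_ms,
        "sound_onset_ms": config.timeline.sound_onset_ms,
        "familiarization_duration_ms": config.timeline.familiarization_duration_ms,
    }
    return GazeDataset(trials=trials, meta=meta)
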