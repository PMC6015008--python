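"""Run configuration for synthetic cohorts and analysis.

All durations are milliseconds and all pupil sizes millimetres. A single
:class:`SimulationConfig` fully determines a synthetic cohort: the same
config and seed always produce a bit-identical dataset.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import yaml

CONDITIONS = ("familiar", "switched", "novel")
AGE_GROUPS = ("10mo", "15mo")

PERCEPTUAL = "perceptual_novelty"
ASSOCIATION = "association_novelty"

#: conditions each named dilation component is allowed to affect
_COMPONENT_CONDITIONS = {
    PERCEPTUAL: ("novel",),
    ASSOCIATION: ("switched",),
}


class ConfigError(ValueError):
    """Invalid or inconsistent simulation/analysis configuration."""


@dataclass(frozen=True)
class TrialTimeline:
    """Nominal durations of the two trial types and the sound onset."""

    test_duration_ms: float = 8000.0
    sound_onset_ms: float = 3680.0
    familiarization_duration_ms: float = 9000.0

    def validate(self) -> None:
        for name in ("test_duration_ms", "sound_onset_ms", "familiarization_duration_ms"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        if self.sound_onset_ms >= self.test_duration_ms:
            raise ConfigError("sound_onset_ms must be < test_duration_ms")


@dataclass(frozen=True)
class ComponentParams:
    """One dilation component: a gamma-shaped kernel time-locked to sound onset.

    ``onset_latency_ms`` is measured from sound onset; the kernel is zero
    before it, rises to ``amplitude_mm`` at ``onset_latency_ms +
    rise_time_ms`` and decays smoothly afterwards. ``shape`` controls the
    width of the gamma bump (larger = narrower).
    """

    name: str
    onset_latency_ms: float
    rise_time_ms: float
    amplitude_mm: float
    conditions_affected: tuple[str, ...]
    shape: float = 4.0

    def validate(self) -> None:
        if self.onset_latency_ms < 0:
            raise ConfigError("onset_latency_ms must be >= 0")
        if self.rise_time_ms <= 0:
            raise ConfigError("rise_time_ms must be > 0")
        if self.amplitude_mm < 0:
            raise ConfigError("amplitude_mm must be >= 0")
        if self.shape <= 0:
            raise ConfigError("shape must be > 0")
        for c in self.conditions_affected:
            if c not in CONDITIONS:
                raise ConfigError(f"unknown condition {c!r}")
        allowed = _COMPONENT_CONDITIONS.get(self.name)
        if allowed is not None and tuple(self.conditions_affected) != allowed:
            raise ConfigError(
                f"component {self.name!r} may only affect {allowed}, "
                f"got {self.conditions_affected}"
            )


@dataclass(frozen=True)
class GapProcess:
    """Blink/dropout model: Poisson gap starts, exponential gap lengths.

    A small fraction of gaps (``long_gap_prob``) is drawn from a much
    longer exponential to mimic look-aways; under the defaults well over
    98% of gaps are shorter than 500 ms.
    """

    gap_rate_per_s: float = 2.0
    gap_length_mean_ms: float = 37.4
    long_gap_prob: float = 0.01
    long_gap_length_mean_ms: float = 800.0
    both_eyes_prob: float = 0.8

    def validate(self) -> None:
        if self.gap_rate_per_s < 0:
            raise ConfigError("gap_rate_per_s must be >= 0")
        if self.gap_length_mean_ms <= 0 or self.long_gap_length_mean_ms <= 0:
            raise ConfigError("exponential gap-length means must be > 0")
        if not 0.0 <= self.long_gap_prob <= 1.0:
            raise ConfigError("long_gap_prob must be in [0, 1]")
        if not 0.0 <= self.both_eyes_prob <= 1.0:
            raise ConfigError("both_eyes_prob must be in [0, 1]")


@dataclass(frozen=True)
class LookingParams:
    """Two-state (looking/away) Markov model for the on-screen flag.

    ``p_onscreen`` gives the stationary looking probability per test
    condition; ``familiarization_block_p`` gives it per familiarization
    block (declining across blocks). ``away_mean_ms`` is the mean dwell of
    an away episode.
    """

    p_onscreen: Mapping[str, float] = field(
        default_factory=lambda: {"familiar": 0.87, "switched": 0.91, "novel": 0.96}
    )
    familiarization_block_p: tuple[float, ...] = (0.92, 0.88, 0.86, 0.79)
    away_mean_ms: float = 500.0

    def validate(self, n_blocks: int) -> None:
        for c, p in self.p_onscreen.items():
            if c not in CONDITIONS:
                raise ConfigError(f"unknown condition {c!r} in p_onscreen")
            if not 0.0 < p < 1.0:
                raise ConfigError("p_onscreen values must be in (0, 1)")
        if len(self.familiarization_block_p) != n_blocks:
            raise ConfigError("familiarization_block_p must have one entry per block")
        for p in self.familiarization_block_p:
            if not 0.0 < p < 1.0:
                raise ConfigError("familiarization_block_p values must be in (0, 1)")
        if self.away_mean_ms <= 0:
            raise ConfigError("away_mean_ms must be > 0")


def _default_components() -> dict[str, tuple[ComponentParams, ...]]:
    return {
        "15mo": (
            ComponentParams(PERCEPTUAL, 1300.0, 700.0, 0.11, ("novel",)),
            ComponentParams(ASSOCIATION, 3950.0, 250.0, 0.23, ("switched",)),
        ),
        "10mo": (
            ComponentParams(PERCEPTUAL, 2000.0, 700.0, 0.10, ("novel",)),
        ),
    }


@dataclass(frozen=True)
class SimulationConfig:
    """Full parameterization of a synthetic cohort."""

    n_participants: Mapping[str, int] = field(
        default_factory=lambda: {"10mo": 18, "15mo": 16}
    )
    sampling_rate: float = 120.0
    timeline: TrialTimeline = field(default_factory=TrialTimeline)
    n_familiar_trials: int = 2
    n_switched_trials: int = 2
    n_novel_trials: int = 1
    n_familiarization_blocks: int = 4
    trials_per_block: int = 4
    baseline_pupil_mean_mm: float = 3.8
    baseline_pupil_sd_mm: float = 0.4
    noise_sd_mm: float = 0.05
    drift_sd_mm: float = 0.02
    amplitude_subject_sd: float = 0.12
    components: Mapping[str, tuple[ComponentParams, ...]] = field(
        default_factory=_default_components
    )
    gap_process: GapProcess = field(default_factory=GapProcess)
    exclusion_target: Mapping[str, float] = field(
        default_factory=lambda: {"10mo": 0.20, "15mo": 0.25}
    )
    looking: LookingParams = field(default_factory=LookingParams)
    seed: int = 0

    # ------------------------------------------------------------------
    @property
    def age_groups(self) -> tuple[str, ...]:
        return tuple(self.n_participants)

    @property
    def n_test_trials(self) -> int:
        return self.n_familiar_trials + self.n_switched_trials + self.n_novel_trials

    def test_condition_sequence(self) -> tuple[str, ...]:
        return (
            ("familiar",) * self.n_familiar_trials
            + ("switched",) * self.n_switched_trials
            + ("novel",) * self.n_novel_trials
        )

    def validate(self) -> "SimulationConfig":
        self.timeline.validate()
        if self.sampling_rate <= 0:
            raise ConfigError("sampling_rate must be > 0")
        for age, n in self.n_participants.items():
            if n < 0:
                raise ConfigError(f"negative participant count for {age!r}")
        for n in (self.n_familiar_trials, self.n_switched_trials, self.n_novel_trials):
            if n < 0:
                raise ConfigError("trial counts must be >= 0")
        if self.baseline_pupil_mean_mm <= 0 or self.baseline_pupil_sd_mm < 0:
            raise ConfigError("baseline pupil parameters out of range")
        if self.noise_sd_mm < 0 or self.drift_sd_mm < 0:
            raise ConfigError("noise parameters must be >= 0")
        # extra entries for absent age groups are tolerated (defaults carry both)
        for comps in self.components.values():
            for comp in comps:
                comp.validate()
        for age in self.n_participants:
            if age not in self.components:
                raise ConfigError(f"no components entry for age group {age!r}")
            if age not in self.exclusion_target:
                raise ConfigError(f"no exclusion_target entry for age group {age!r}")
        for age, frac in self.exclusion_target.items():
            if not 0.0 <= frac <= 1.0:
                raise ConfigError("exclusion_target must be in [0, 1]")
        self.gap_process.validate()
        self.looking.validate(self.n_familiarization_blocks)
        if not isinstance(self.seed, int):
            raise ConfigError("seed must be an integer")
        return self

    # ------------------------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        def encode(obj: Any) -> Any:
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: encode(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, Mapping):
                return {k: encode(v) for k, v in obj.items()}
            if isinstance(obj, tuple):
                return [encode(v) for v in obj]
            return obj

        return encode(self)

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "SimulationConfig":
        d = dict(d)
        if "timeline" in d:
            d["timeline"] = TrialTimeline(**d["timeline"])
        if "gap_process" in d:
            d["gap_process"] = GapProcess(**d["gap_process"])
        if "looking" in d:
            lk = dict(d["looking"])
            if "familiarization_block_p" in lk:
                lk["familiarization_block_p"] = tuple(lk["familiarization_block_p"])
            d["looking"] = LookingParams(**lk)
        if "components" in d:
            comps: dict[str, tuple[ComponentParams, ...]] = {}
            for age, lst in d["components"].items():
                comps[age] = tuple(
                    ComponentParams(
                        **{**c, "conditions_affected": tuple(c["conditions_affected"])}
                    )
                    for c in lst
                )
            d["components"] = comps
        try:
            cfg = cls(**d)
        except TypeError as exc:  # unknown keys etc.
            raise ConfigError(str(exc)) from exc
        return cfg.validate()

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def replace(self, **kwargs: Any) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)


def null_config(**overrides: Any) -> SimulationConfig:
    """A config with no dilation components, no drift, no exclusions.

    Useful for calibration studies: condition labels are exchangeable by
    construction.
    """
    base = SimulationConfig()
    comps = {age: () for age in base.n_participants}
    excl = {age: 0.0 for age in base.n_participants}
    cfg = base.replace(components=comps, exclusion_target=excl)
    if overrides:
        cfg = cfg.replace(**overrides)
    return cfg.validate()


def load_config(path: str) -> SimulationConfig:
    """Load a :class:`SimulationConfig` from a YAML (or JSON) file."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, Mapping):
        raise ConfigError(f"config file {path} does not contain a mapping")
    return SimulationConfig.from_dict(data)


def save_config(config: SimulationConfig, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
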