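"""Gaze-table reading/writing and trial assembly.

The on-disk dialect is a tab-separated UTF-8 table, one row per 120-Hz
sample, '.' decimal separator, missing pupil diameters as empty fields and
validity flags as 0/1. Lines starting with ``#`` are header comments and
carry provenance (seed, config hash). Real exports with different column
names can be adapted with a schema mapping instead of code changes.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .config import TrialTimeline

logger = logging.getLogger(__name__)

#: canonical column order of the gaze TSV dialect
COLUMNS = (
    "participant_id",
    "age_group",
    "phase",
    "block",
    "trial_idx",
    "condition",
    "t_ms",
    "left_pupil_mm",
    "right_pupil_mm",
    "left_valid",
    "right_valid",
    "on_screen",
)

PHASES = ("familiarization", "test")

#: plausible physical range for a pupil diameter, mm (exclusive bounds)
PUPIL_RANGE_MM = (0.0, 10.0)


class SchemaError(ValueError):
    """The input table does not provide the required columns."""


class DataError(ValueError):
    """The input table violates a structural invariant (e.g. timestamps)."""


class GazeSample(NamedTuple):
    """A single binocular sample, trial-relative time in ms."""

    t_ms: float
    left_pupil_mm: float  # NaN when invalid
    right_pupil_mm: float
    left_valid: bool
    right_valid: bool
    on_screen: bool


@dataclass
class TrialRecording:
    """All samples of one trial plus its design metadata.

    Sample arrays are parallel and sorted by strictly increasing ``t_ms``;
    pupil values are NaN exactly where the corresponding validity flag is
    False.
    """

    participant_id: str
    age_group: str
    phase: str
    block: int | None
    trial_idx: int
    condition: str
    duration_ms: float
    sound_onset_ms: float | None
    sampling_rate: float
    t_ms: np.ndarray
    left_pupil_mm: np.ndarray
    right_pupil_mm: np.ndarray
    left_valid: np.ndarray
    right_valid: np.ndarray
    on_screen: np.ndarray

    @property
    def n_samples(self) -> int:
        return int(self.t_ms.size)

    @property
    def expected_samples(self) -> int:
        """Nominal sample count for the trial duration at the nominal rate."""
        return int(round(self.duration_ms * self.sampling_rate / 1000.0))

    @property
    def sample_period_ms(self) -> float:
        return 1000.0 / self.sampling_rate

    def samples(self) -> Iterator[GazeSample]:
        for i in range(self.n_samples):
            yield GazeSample(
                float(self.t_ms[i]),
                float(self.left_pupil_mm[i]),
                float(self.right_pupil_mm[i]),
                bool(self.left_valid[i]),
                bool(self.right_valid[i]),
                bool(self.on_screen[i]),
            )

    def key(self) -> tuple:
        return (self.participant_id, self.phase, self.block, self.trial_idx)

    def validate(self) -> "TrialRecording":
        n = self.n_samples
        for name in ("left_pupil_mm", "right_pupil_mm", "left_valid", "right_valid", "on_screen"):
            if getattr(self, name).shape != (n,):
                raise DataError(f"{name} length mismatch in trial {self.key()}")
        if n and np.any(np.diff(self.t_ms) <= 0):
            raise DataError(f"non-monotone timestamps in trial {self.key()}")
        if n and self.t_ms[0] < 0:
            raise DataError(f"negative timestamp in trial {self.key()}")
        if n > int(np.ceil(self.duration_ms * self.sampling_rate / 1000.0)):
            raise DataError(
                f"trial {self.key()} has {n} samples, more than the nominal "
                f"maximum for {self.duration_ms} ms at {self.sampling_rate} Hz"
            )
        for eye, valid in (("left", self.left_valid), ("right", self.right_valid)):
            vals = getattr(self, f"{eye}_pupil_mm")
            if np.any(valid & ~np.isfinite(vals)):
                raise DataError(f"valid {eye} samples without a diameter in {self.key()}")
            if np.any(~valid & np.isfinite(vals)):
                raise DataError(f"invalid {eye} samples carrying a diameter in {self.key()}")
        return self


@dataclass
class GazeDataset:
    """An ordered collection of trials with provenance metadata."""

    trials: list[TrialRecording] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self) -> Iterator[TrialRecording]:
        return iter(self.trials)

    def participants(self) -> list[tuple[str, str]]:
        seen: dict[tuple[str, str], None] = {}
        for t in self.trials:
            seen.setdefault((t.age_group, t.participant_id), None)
        return list(seen)

    def test_trials(self) -> list[TrialRecording]:
        return [t for t in self.trials if t.phase == "test"]

    def familiarization_trials(self) -> list[TrialRecording]:
        return [t for t in self.trials if t.phase == "familiarization"]

    def design_table(self) -> pd.DataFrame:
        rows = [
            {
                "participant_id": t.participant_id,
                "age_group": t.age_group,
                "phase": t.phase,
                "block": t.block,
                "trial_idx": t.trial_idx,
                "condition": t.condition,
                "duration_ms": t.duration_ms,
                "n_samples": t.n_samples,
            }
            for t in self.trials
        ]
        return pd.DataFrame(rows)


def trial_to_frame(trial: TrialRecording) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "participant_id": trial.participant_id,
            "age_group": trial.age_group,
            "phase": trial.phase,
            "block": -1 if trial.block is None else trial.block,
            "trial_idx": trial.trial_idx,
            "condition": trial.condition,
            "t_ms": trial.t_ms,
            "left_pupil_mm": trial.left_pupil_mm,
            "right_pupil_mm": trial.right_pupil_mm,
            "left_valid": trial.left_valid.astype(int),
            "right_valid": trial.right_valid.astype(int),
            "on_screen": trial.on_screen.astype(int),
        }
    )


def write_gaze_table(dataset: GazeDataset, path: str) -> None:
    """Write a dataset in the canonical TSV dialect.

    Header comment lines record the seed and config hash so an export can
    be traced back to the run that produced it. ``read(write(x))`` is
    lossless for every field.
    """
    header_lines = ["# pupilswitch gaze export v1"]
    for key in ("seed", "config_hash", "sampling_rate", "test_duration_ms",
                "sound_onset_ms", "familiarization_duration_ms"):
        if key in dataset.meta:
            header_lines.append(f"# {key}={dataset.meta[key]}")
    if dataset.trials:
        frame = pd.concat([trial_to_frame(t) for t in dataset.trials], ignore_index=True)
    else:
        frame = pd.DataFrame(columns=list(COLUMNS))
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for line in header_lines:
            fh.write(line + "\n")
        # shortest round-trip formatting so read(write(x)) is bit-exact
        frame.to_csv(
            fh, sep="\t", index=False, lineterminator="\n",
            float_format=lambda v: repr(float(v)),
        )


def _read_header_meta(path: str) -> dict:
    meta: dict = {}
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                key, _, value = body.partition("=")
                meta[key.strip()] = value.strip()
    for key in ("seed",):
        if key in meta:
            meta[key] = int(meta[key])
    for key in ("sampling_rate", "test_duration_ms", "sound_onset_ms",
                "familiarization_duration_ms"):
        if key in meta:
            meta[key] = float(meta[key])
    return meta


def read_gaze_table(
    path: str,
    schema: Mapping[str, str] | None = None,
    timeline: TrialTimeline | None = None,
    sampling_rate: float | None = None,
) -> GazeDataset:
    """Read a gaze TSV into trials grouped by (participant, phase, block, trial).

    Parameters
    ----------
    schema
        Optional mapping from canonical column names to the file's column
        names, for adapting foreign exports.
    timeline, sampling_rate
        Override the trial timeline / rate; by default taken from the
        file's header comments, falling back to the standard timeline.

    Malformed rows (validity flag inconsistent with the diameter field,
    out-of-range diameters, rows beyond the nominal per-trial maximum) are
    rejected and logged with line numbers. Non-monotone timestamps within
    a trial raise :class:`DataError`.
    """
    meta = _read_header_meta(path)
    if timeline is None:
        timeline = TrialTimeline(
            test_duration_ms=meta.get("test_duration_ms", 8000.0),
            sound_onset_ms=meta.get("sound_onset_ms", 3680.0),
            familiarization_duration_ms=meta.get("familiarization_duration_ms", 9000.0),
        )
    if sampling_rate is None:
        sampling_rate = meta.get("sampling_rate", 120.0)

    raw = pd.read_csv(
        path, sep="\t", comment="#", dtype={"participant_id": str},
        float_precision="round_trip",
    )
    if schema:
        rename = {src: dst for dst, src in schema.items()}
        missing_src = [src for src in rename if src not in raw.columns]
        if missing_src:
            raise SchemaError(f"schema maps absent columns: {missing_src}")
        raw = raw.rename(columns=rename)
    missing = [c for c in COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    # data rows start after the header comments and the column header line
    n_header = len([k for k in open(path, encoding="utf-8") if k.startswith("#")])
    raw = raw.reset_index(drop=True)
    raw["_line"] = raw.index + n_header + 2  # 1-based physical line numbers

    rejected: list[tuple[int, str]] = []

    def _flag(series: pd.Series) -> np.ndarray:
        return series.astype(float).fillna(0).astype(int).astype(bool).to_numpy()

    lv = _flag(raw["left_valid"])
    rv = _flag(raw["right_valid"])
    lp = pd.to_numeric(raw["left_pupil_mm"], errors="coerce").to_numpy(float)
    rp = pd.to_numeric(raw["right_pupil_mm"], errors="coerce").to_numpy(float)
    lo, hi = PUPIL_RANGE_MM
    bad = (
        (lv & ~np.isfinite(lp))
        | (rv & ~np.isfinite(rp))
        | (lv & np.isfinite(lp) & ((lp <= lo) | (lp >= hi)))
        | (rv & np.isfinite(rp) & ((rp <= lo) | (rp >= hi)))
    )
    for line in raw.loc[bad, "_line"]:
        rejected.append((int(line), "validity flag inconsistent with diameter field"))
    keep = ~bad
    raw = raw.loc[keep].copy()
    raw["left_valid"], raw["right_valid"] = lv[keep], rv[keep]
    raw["left_pupil_mm"], raw["right_pupil_mm"] = lp[keep], rp[keep]
    # invalid samples never carry a diameter
    raw.loc[~raw["left_valid"], "left_pupil_mm"] = np.nan
    raw.loc[~raw["right_valid"], "right_pupil_mm"] = np.nan

    trials: list[TrialRecording] = []
    group_cols = ["participant_id", "age_group", "phase", "block", "trial_idx"]
    for (pid, age, phase, block, idx), g in raw.groupby(group_cols, sort=True):
        if phase not in PHASES:
            raise DataError(f"unknown phase {phase!r} for participant {pid}")
        g = g.sort_values("t_ms", kind="mergesort")
        t = g["t_ms"].to_numpy(float)
        if t.size and np.any(np.diff(t) <= 0):
            raise DataError(
                f"non-monotone timestamps in trial (participant={pid}, phase={phase}, "
                f"trial={idx})"
            )
        if phase == "test":
            duration = timeline.test_duration_ms
            onset: float | None = timeline.sound_onset_ms
        else:
            duration = timeline.familiarization_duration_ms
            onset = None
        cap = int(np.ceil(duration * sampling_rate / 1000.0))
        if len(g) > cap:
            for line in g["_line"].iloc[cap:]:
                rejected.append((int(line), "sample beyond nominal trial maximum"))
            g = g.iloc[:cap]
            t = t[:cap]
        trial = TrialRecording(
            participant_id=str(pid),
            age_group=str(age),
            phase=str(phase),
            block=None if int(block) < 0 else int(block),
            trial_idx=int(idx),
            condition=str(g["condition"].iloc[0]),
            duration_ms=duration,
            sound_onset_ms=onset,
            sampling_rate=sampling_rate,
            t_ms=t,
            left_pupil_mm=g["left_pupil_mm"].to_numpy(float),
            right_pupil_mm=g["right_pupil_mm"].to_numpy(float),
            left_valid=g["left_valid"].to_numpy(bool),
            right_valid=g["right_valid"].to_numpy(bool),
            on_screen=_flag(g["on_screen"]),
        ).validate()
        trials.append(trial)

    for line, reason in rejected:
        logger.warning("rejected row at line %d: %s", line, reason)
    meta["rejected_rows"] = rejected
    return GazeDataset(trials=trials, meta=meta)
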