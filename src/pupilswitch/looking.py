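"""Proportion-of-looking-time measures and their tests.

Looking time is recomputed from the per-sample on-screen flag (whole
screen as the area of interest): summed on-screen sample time divided by
the trial duration. Familiarization is summarized per block with a
block-1-vs-4 paired t; the test phase gets a three-condition RM-ANOVA plus
planned one-tailed paired comparisons (novel > familiar,
switched > familiar), uncorrected.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .config import CONDITIONS
from .io import GazeDataset, TrialRecording
from .stats import BinTestResult, hedges_g_av, paired_t, rm_anova_bin


@dataclass
class LookingRecord:
    participant_id: str
    age_group: str
    phase: str
    block: int | None
    trial_idx: int
    condition: str
    looking_ms: float
    proportion: float


def proportion_looking(trial: TrialRecording) -> float:
    """Fraction of the trial the infant spent looking at the screen.

    Time-weighted: on-screen sample count × sample period over the trial
    duration, so the value is invariant to the sampling rate.
    """
    n_on = int(np.sum(trial.on_screen))
    prop = n_on * trial.sample_period_ms / trial.duration_ms
    return float(min(1.0, prop))


def looking_records(dataset: GazeDataset) -> list[LookingRecord]:
    out = []
    for t in dataset:
        prop = proportion_looking(t)
        out.append(
            LookingRecord(
                t.participant_id,
                t.age_group,
                t.phase,
                t.block,
                t.trial_idx,
                t.condition,
                looking_ms=prop * t.duration_ms,
                proportion=prop,
            )
        )
    return out


def _records_frame(records: Sequence[LookingRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "participant_id": [r.participant_id for r in records],
            "age_group": [r.age_group for r in records],
            "phase": [r.phase for r in records],
            "block": [r.block for r in records],
            "condition": [r.condition for r in records],
            "proportion": [r.proportion for r in records],
        }
    )


@dataclass
class FamiliarizationSummary:
    """Per-block group means/SEs and the block 1-vs-4 decline test."""

    age_group: str
    n_participants: int
    block_means: np.ndarray  # group mean proportion per block
    block_ses: np.ndarray
    t: float
    df: int
    p_two_tailed: float
    g_av: float
    degenerate: bool = False
    per_participant_block_means: pd.DataFrame | None = None


def familiarization_block_summary(
    records: Sequence[LookingRecord], age_group: str, n_blocks: int = 4
) -> FamiliarizationSummary:
    """Block-level looking summary with the first-vs-last-block paired t.

    Participants missing any block are dropped from the test with a
    warning. Zero-variance block differences are flagged degenerate.
    """
    df = _records_frame(records)
    df = df[(df["phase"] == "familiarization") & (df["age_group"] == age_group)]
    if df.empty:
        raise ValueError(f"no familiarization records for {age_group!r}")
    per = df.groupby(["participant_id", "block"])["proportion"].mean().unstack("block")
    complete = per.dropna(axis=0)
    incomplete = sorted(set(per.index) - set(complete.index))
    if incomplete:
        warnings.warn(
            f"participants missing a familiarization block dropped from the "
            f"block test: {incomplete}",
            RuntimeWarning,
            stacklevel=2,
        )
    per = complete
    missing_blocks = [b for b in range(n_blocks) if b not in per.columns]
    if missing_blocks or per.shape[0] < 2:
        raise ValueError("need >= 2 participants with all blocks present")
    first = per[0].to_numpy()
    last = per[n_blocks - 1].to_numpy()
    t, dof, p = paired_t(first, last)
    diffs = first - last
    degenerate = bool(np.std(diffs, ddof=1) == 0)
    if degenerate:
        warnings.warn(
            "zero-variance block-1-vs-4 differences", RuntimeWarning, stacklevel=2
        )
    if np.all(first == last):
        g = 0.0
    else:
        try:
            g = hedges_g_av(first, last).value
        except ValueError:
            g = float("nan")
    means = per.mean(axis=0).reindex(range(n_blocks)).to_numpy()
    ses = (per.std(axis=0, ddof=1) / np.sqrt(per.shape[0])).reindex(range(n_blocks)).to_numpy()
    return FamiliarizationSummary(
        age_group=age_group,
        n_participants=int(per.shape[0]),
        block_means=means,
        block_ses=ses,
        t=t,
        df=dof,
        p_two_tailed=p,
        g_av=g,
        degenerate=degenerate,
        per_participant_block_means=per,
    )


@dataclass
class PlannedComparison:
    label: str
    t: float
    df: int
    p_one_tailed: float
    g_av: float
    degenerate: bool = False


@dataclass
class TestPhaseSummary:
    age_group: str
    n_participants: int
    condition_means: dict[str, float]
    condition_ses: dict[str, float]
    anova: BinTestResult
    comparisons: list[PlannedComparison]
    per_participant_means: pd.DataFrame | None = None


def _one_tailed_greater(t: float, df: int) -> float:
    """p for H1: difference > 0. Equals half the two-tailed p when the
    sample effect is in the predicted direction, else 1 − half."""
    return float(sp_stats.t.sf(t, df))


def test_phase_comparisons(
    records: Sequence[LookingRecord],
    age_group: str,
    conditions: Sequence[str] = CONDITIONS,
) -> TestPhaseSummary:
    """Three-condition looking-time RM-ANOVA plus the planned one-tailed
    paired comparisons novel > familiar and switched > familiar
    (uncorrected by design)."""
    df = _records_frame(records)
    df = df[(df["phase"] == "test") & (df["age_group"] == age_group)]
    if df.empty:
        raise ValueError(f"no test-phase records for {age_group!r}")
    per = (
        df.groupby(["participant_id", "condition"])["proportion"].mean().unstack("condition")
    )
    per = per.reindex(columns=list(conditions)).dropna(axis=0)
    if per.shape[0] < 2:
        raise ValueError("need >= 2 participants with all conditions present")
    matrix = per.to_numpy()
    anova = rm_anova_bin(matrix)
    cidx = {c: i for i, c in enumerate(conditions)}
    comparisons = []
    for hi, lo in (("novel", "familiar"), ("switched", "familiar")):
        x1, x2 = matrix[:, cidx[hi]], matrix[:, cidx[lo]]
        d = x1 - x2
        degenerate = bool(np.std(d, ddof=1) == 0)
        if degenerate:
            warnings.warn(
                f"zero-variance differences in planned comparison {hi}>{lo}",
                RuntimeWarning,
                stacklevel=2,
            )
        t, dof, _p2 = paired_t(x1, x2)
        if degenerate and np.all(d == 0):
            p1 = 0.5
        else:
            p1 = _one_tailed_greater(t, dof)
        if np.all(x1 == x2):
            g = 0.0
        else:
            try:
                g = hedges_g_av(x1, x2).value
            except ValueError:
                g = float("nan")
        comparisons.append(PlannedComparison(f"{hi}>{lo}", t, dof, p1, g, degenerate))
    means = {c: float(per[c].mean()) for c in conditions}
    ses = {
        c: float(per[c].std(ddof=1) / np.sqrt(per.shape[0])) for c in conditions
    }
    return TestPhaseSummary(
        age_group=age_group,
        n_participants=int(per.shape[0]),
        condition_means=means,
        condition_ses=ses,
        anova=anova,
        comparisons=comparisons,
        per_participant_means=per,
    )


def looking_summary_table(
    records: Sequence[LookingRecord], age_groups: Sequence[str]
) -> pd.DataFrame:
    """Long-format summary (one row per statistic) shaped like the
    familiarization/test looking-time tables."""
    rows: list[dict] = []
    for age in age_groups:
        fam = familiarization_block_summary(records, age)
        for b, (m, se) in enumerate(zip(fam.block_means, fam.block_ses)):
            rows.append(
                {
                    "age_group": age,
                    "phase": "familiarization",
                    "level": f"block{b + 1}",
                    "statistic": "mean_pct",
                    "value": 100.0 * m,
                    "se_pct": 100.0 * se,
                }
            )
        rows.append(
            {
                "age_group": age,
                "phase": "familiarization",
                "level": "block1_vs_4",
                "statistic": "paired_t",
                "value": fam.t,
                "df": fam.df,
                "p": fam.p_two_tailed,
                "g_av": fam.g_av,
            }
        )
        test = test_phase_comparisons(records, age)
        for cond in test.condition_means:
            rows.append(
                {
                    "age_group": age,
                    "phase": "test",
                    "level": cond,
                    "statistic": "mean_pct",
                    "value": 100.0 * test.condition_means[cond],
                    "se_pct": 100.0 * test.condition_ses[cond],
                }
            )
        rows.append(
            {
                "age_group": age,
                "phase": "test",
                "level": "omnibus",
                "statistic": "rm_anova_F",
                "value": test.anova.F,
                "df": f"{test.anova.df[0]},{test.anova.df[1]}",
                "p": test.anova.p_param,
                "eta_p2": test.anova.eta_p2,
            }
        )
        for comp in test.comparisons:
            rows.append(
                {
                    "age_group": age,
                    "phase": "test",
                    "level": comp.label,
                    "statistic": "planned_one_tailed_t",
                    "value": comp.t,
                    "df": comp.df,
                    "p": comp.p_one_tailed,
                    "g_av": comp.g_av,
                }
            )
    return pd.DataFrame(rows)
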