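"""Figure helpers: condition time-courses and per-bin F / effect-size traces."""
from __future__ import annotations

from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .preprocess import ConditionTimeCourse, bin_start_times_ms
from .stats import BinTestResult, f_critical

_CONDITION_COLORS = {"familiar": "#4477aa", "switched": "#ee6677", "novel": "#228833"}


def plot_timecourse(tc: ConditionTimeCourse, path: str) -> None:
    """Mean relative pupil change ±1 SE per condition over bins."""
    t = bin_start_times_ms(n_bins=tc.n_bins)
    fig, ax = plt.subplots(figsize=(7, 4))
    for j, cond in enumerate(tc.conditions):
        values = tc.data[:, j, :]
        mean = values.mean(axis=0)
        se = values.std(axis=0, ddof=1) / np.sqrt(tc.n_participants)
        color = _CONDITION_COLORS.get(cond)
        ax.plot(t, mean, label=cond, color=color)
        ax.fill_between(t, mean - se, mean + se, alpha=0.25, color=color, lw=0)
    ax.axhline(0.0, color="k", lw=0.5)
    ax.set_xlabel("Time after sound onset (ms)")
    ax.set_ylabel("Relative pupil change (mm)")
    ax.set_title(f"{tc.age_group} (n={tc.n_participants})")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_bin_tests(
    results: Sequence[BinTestResult],
    path: str,
    alpha: float = 0.05,
    label: str = "",
) -> None:
    """Per-bin F values with the critical-value line, and eta_p2 below."""
    t = bin_start_times_ms(n_bins=len(results))
    F = np.array([r.F for r in results])
    eta = np.array([r.eta_p2 for r in results])
    df1, df2 = results[0].df
    crit = f_critical(alpha, df1, df2)
    fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(7, 6), sharex=True)
    ax1.plot(t, F, color="k")
    ax1.axhline(crit, ls="--", color="gray", label=f"F({df1},{df2}) crit = {crit:.2f}")
    rule = np.array([r.significant_rule for r in results])
    if rule.any():
        ax1.scatter(t[rule], F[rule], s=12, color="crimson", zorder=3,
                    label="consecutive-bin rule")
    ax1.set_ylabel("F")
    ax1.legend(frameon=False)
    if label:
        ax1.set_title(label)
    ax2.plot(t, eta, color="k")
    ax2.set_ylabel(r"partial $\eta^2$")
    ax2.set_xlabel("Time after sound onset (ms)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
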