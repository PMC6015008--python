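"""Per-bin repeated-measures ANOVA, the consecutive-bin significance rule,
Bonferroni post-hoc paired tests, Hedges' g effect sizes, and the
Monte-Carlo cluster permutation correction.

The per-bin statistics use the classical one-way within-subject
decomposition: SS_total = SS_subjects + SS_conditions + SS_error with
F = (SS_cond/df1)/(SS_error/df2), df1 = k−1, df2 = (k−1)(n−1), and
partial eta-squared = SS_cond/(SS_cond + SS_error).

The family-wise correction is the max-cluster-mass permutation scheme
standard in EEG/MEG time-series analysis: clusters of contiguous bins
exceeding the parametric threshold, cluster mass = summed statistic,
permutation by shuffling condition labels independently within each
participant, Monte-Carlo p = (1 + #{perm max ≥ observed}) / (1 + n_perm).
When the full permutation group is smaller than the requested number of
draws it is enumerated exhaustively instead and the p-value is exact.
"""
from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sp_stats

DEFAULT_ALPHA = 0.05
DEFAULT_N_PERM = 1000


# ----------------------------------------------------------------------
# Per-bin RM-ANOVA
# ----------------------------------------------------------------------
@dataclass
class BinTestResult:
    bin_index: int
    F: float
    df: tuple[int, int]
    p_param: float
    eta_p2: float
    significant_raw: bool = False
    significant_rule: bool = False
    degenerate: bool = False


def _anova_f_array(data: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized within-subject one-way F on a ``(..., n, k, B)`` array,
    computed per bin. Returns (F, ss_cond, ss_error), each ``(..., B)``."""
    cell = np.asarray(data, float)
    subj_mean = cell.mean(axis=-2, keepdims=True)  # over conditions
    cond_mean = cell.mean(axis=-3, keepdims=True)  # over participants
    grand = subj_mean.mean(axis=-3, keepdims=True)
    n = cell.shape[-3]
    k = cell.shape[-2]
    ss_cond = n * ((cond_mean - grand) ** 2).sum(axis=(-3, -2))
    resid = cell - subj_mean - cond_mean + grand
    ss_error = (resid**2).sum(axis=(-3, -2))
    df1, df2 = k - 1, (k - 1) * (n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ss_cond / df1) / (ss_error / df2)
    # degenerate zero-variance cells contribute statistic 0, not NaN/inf
    F = np.where(ss_error == 0, np.where(ss_cond == 0, 0.0, np.inf), F)
    return F, ss_cond, ss_error


def rm_anova_bin(
    data: np.ndarray, bin_index: int = 0, alpha: float = DEFAULT_ALPHA
) -> BinTestResult:
    """One-way repeated-measures ANOVA on an ``(n participants, k conditions)``
    matrix for a single time bin."""
    data = np.asarray(data, float)
    if data.ndim != 2:
        raise ValueError("expected a (participants, conditions) matrix")
    n, k = data.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 participants and 2 conditions")
    if np.isnan(data).any():
        raise ValueError("rm_anova_bin requires complete rows")
    F, ss_cond, ss_error = _anova_f_array(data[:, :, None])
    F = float(F[0])
    df1, df2 = k - 1, (k - 1) * (n - 1)
    degenerate = bool(ss_error[0] == 0 and ss_cond[0] == 0)
    if degenerate:
        warnings.warn(
            f"bin {bin_index}: zero between- and within-condition variance; "
            "F undefined, marked non-significant",
            RuntimeWarning,
            stacklevel=2,
        )
        p = 1.0
        eta = 0.0
    else:
        p = float(sp_stats.f.sf(F, df1, df2))
        eta = float(ss_cond[0] / (ss_cond[0] + ss_error[0]))
    return BinTestResult(
        bin_index=bin_index,
        F=F,
        df=(df1, df2),
        p_param=p,
        eta_p2=eta,
        significant_raw=(not degenerate) and p < alpha,
        degenerate=degenerate,
    )


def rm_anova_timecourse(
    data: np.ndarray, alpha: float = DEFAULT_ALPHA
) -> list[BinTestResult]:
    """Per-bin RM-ANOVA over a ``(participants, conditions, bins)`` array,
    with the consecutive-bin rule applied to the parametric p-values."""
    data = np.asarray(data, float)
    if data.ndim != 3:
        raise ValueError("expected a (participants, conditions, bins) array")
    results = [
        rm_anova_bin(data[:, :, b], bin_index=b, alpha=alpha)
        for b in range(data.shape[2])
    ]
    mask = consecutive_rule(np.array([r.p_param for r in results]), alpha=alpha)
    for r, flag in zip(results, mask):
        r.significant_rule = bool(flag)
    return results


def per_bin_f_test(data: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized per-bin F, parametric p and partial eta-squared for a
    ``(participants, conditions, bins)`` array. Degenerate zero-variance
    bins get F = 0, p = 1, eta = 0."""
    data = np.asarray(data, float)
    if data.ndim != 3:
        raise ValueError("expected a (participants, conditions, bins) array")
    n, k, _ = data.shape
    F, ss_cond, ss_error = _anova_f_array(data)
    df1, df2 = k - 1, (k - 1) * (n - 1)
    p = np.where(np.isfinite(F), sp_stats.f.sf(np.where(np.isfinite(F), F, 0.0), df1, df2), 0.0)
    degenerate = (ss_cond == 0) & (ss_error == 0)
    p = np.where(degenerate, 1.0, p)
    with np.errstate(invalid="ignore", divide="ignore"):
        eta = np.where(degenerate, 0.0, ss_cond / (ss_cond + ss_error))
    return F, p, eta


def f_critical(alpha: float, df1: int, df2: int) -> float:
    """Upper critical value of the F distribution at level ``alpha``."""
    return float(sp_stats.f.ppf(1.0 - alpha, df1, df2))


# ----------------------------------------------------------------------
# Consecutive-bin rule
# ----------------------------------------------------------------------
def consecutive_rule(p_values: np.ndarray, alpha: float = DEFAULT_ALPHA) -> np.ndarray:
    """Flag bin b iff p_b, p_{b−1} and p_{b+1} are all below alpha.

    The first and last bins can never be flagged. Equivalent to keeping
    the interior of runs of at least three successive significant bins
    (150 ms at 50-ms bins).
    """
    p = np.asarray(p_values, float)
    sig = p < alpha
    out = np.zeros_like(sig)
    if p.size >= 3:
        out[1:-1] = sig[1:-1] & sig[:-2] & sig[2:]
    return out


# ----------------------------------------------------------------------
# Effect sizes
# ----------------------------------------------------------------------
@dataclass
class EffectSize:
    kind: str  # 'g_av' | 'g_s' | 'eta_p2'
    value: float
    components: dict = field(default_factory=dict)


def _hedges_j(df: int) -> float:
    """Small-sample bias correction J = 1 − 3/(4·df − 1)."""
    return 1.0 - 3.0 / (4.0 * df - 1.0)


def hedges_g_av(x1: np.ndarray, x2: np.ndarray) -> EffectSize:
    """Within-participant standardized mean difference with the average-SD
    denominator and small-sample correction.

    d_av = (mean1 − mean2) / ((SD1 + SD2)/2);  g_av = d_av · J,
    J = 1 − 3/(4(n−1) − 1). At n = 2, J = 0 and g_av degenerates to 0.
    """
    x1 = np.asarray(x1, float)
    x2 = np.asarray(x2, float)
    if x1.shape != x2.shape or x1.ndim != 1:
        raise ValueError("paired samples must be 1-d arrays of equal length")
    n = x1.size
    if n < 2:
        raise ValueError("need n >= 2 pairs")
    sd1, sd2 = x1.std(ddof=1), x2.std(ddof=1)
    if sd1 == 0 and sd2 == 0:
        raise ValueError("g_av undefined: both SDs are zero")
    d_av = (x1.mean() - x2.mean()) / ((sd1 + sd2) / 2.0)
    j = _hedges_j(n - 1)
    return EffectSize(
        "g_av",
        float(d_av * j),
        components={
            "mean1": float(x1.mean()),
            "mean2": float(x2.mean()),
            "sd1": float(sd1),
            "sd2": float(sd2),
            "n": n,
            "d_av": float(d_av),
            "J": float(j),
        },
    )


def hedges_g_s(group1: np.ndarray, group2: np.ndarray) -> EffectSize:
    """Between-participant standardized mean difference (pooled SD) with
    small-sample correction, J based on df = n1 + n2 − 2."""
    g1 = np.asarray(group1, float)
    g2 = np.asarray(group2, float)
    n1, n2 = g1.size, g2.size
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    df = n1 + n2 - 2
    pooled_var = ((n1 - 1) * g1.var(ddof=1) + (n2 - 1) * g2.var(ddof=1)) / df
    if pooled_var == 0:
        raise ValueError("g_s undefined: pooled SD is zero")
    d_s = (g1.mean() - g2.mean()) / math.sqrt(pooled_var)
    j = _hedges_j(df)
    return EffectSize(
        "g_s",
        float(d_s * j),
        components={
            "mean1": float(g1.mean()),
            "mean2": float(g2.mean()),
            "pooled_sd": float(math.sqrt(pooled_var)),
            "n1": n1,
            "n2": n2,
            "d_s": float(d_s),
            "J": float(j),
        },
    )


# ----------------------------------------------------------------------
# Paired t-tests
# ----------------------------------------------------------------------
@dataclass
class PairedTResult:
    t: float
    df: int
    p_two_tailed: float
    p_bonf: float
    g_av: float
    degenerate: bool = False


def paired_t(x1: np.ndarray, x2: np.ndarray) -> tuple[float, int, float]:
    """Classical paired t on the differences; returns (t, df, two-tailed p)."""
    d = np.asarray(x1, float) - np.asarray(x2, float)
    n = d.size
    if n < 2:
        raise ValueError("need n >= 2 pairs")
    sd = d.std(ddof=1)
    if sd == 0:
        return (0.0 if d.mean() == 0 else math.copysign(math.inf, d.mean()), n - 1,
                1.0 if d.mean() == 0 else 0.0)
    t = d.mean() / (sd / math.sqrt(n))
    p = 2.0 * float(sp_stats.t.sf(abs(t), n - 1))
    return float(t), n - 1, p


def posthoc_paired_t(
    data: np.ndarray,
    pair: tuple[int, int],
    n_comparisons: int = 3,
) -> PairedTResult:
    """Bonferroni-corrected two-tailed paired t between two condition columns
    of an ``(n participants, k conditions)`` matrix."""
    data = np.asarray(data, float)
    x1, x2 = data[:, pair[0]], data[:, pair[1]]
    d = x1 - x2
    degenerate = bool(d.std(ddof=1) == 0)
    if degenerate:
        warnings.warn(
            "zero-variance differences in post-hoc paired t", RuntimeWarning,
            stacklevel=2,
        )
    t, df, p = paired_t(x1, x2)
    p_bonf = min(1.0, p * n_comparisons)
    if np.all(x1 == x2):
        g = 0.0
    else:
        try:
            g = hedges_g_av(x1, x2).value
        except ValueError:
            g = float("nan")
    return PairedTResult(t, df, p, p_bonf, g, degenerate)


# ----------------------------------------------------------------------
# Cluster permutation
# ----------------------------------------------------------------------
@dataclass
class ClusterResult:
    contrast: str
    start_bin: int
    end_bin: int  # inclusive
    mass: float
    p_mc: float
    n_permutations: int
    seed: int | None
    exhaustive: bool = False


def _find_clusters(stat: np.ndarray, above: np.ndarray) -> list[tuple[int, int, float]]:
    """Runs of contiguous True in ``above``; mass = summed |stat|."""
    clusters: list[tuple[int, int, float]] = []
    b = 0
    B = above.size
    while b < B:
        if above[b]:
            start = b
            while b < B and above[b]:
                b += 1
            clusters.append((start, b - 1, float(np.abs(stat[start:b]).sum())))
        else:
            b += 1
    return clusters


def _max_cluster_mass(stat: np.ndarray, threshold: float) -> np.ndarray:
    """Max cluster mass per row of a 2-d |stat| array ``(m, B)``.

    Vectorized over rows: contiguous supra-threshold runs are summed via
    cumulative sums with resets.
    """
    a = np.abs(np.asarray(stat, float))
    above = a > threshold
    m, B = a.shape
    masses = np.zeros(m)
    # cumulative mass with resets at run boundaries, done column-wise
    run = np.zeros(m)
    for b in range(B):
        run = np.where(above[:, b], run + a[:, b], 0.0)
        masses = np.maximum(masses, run)
    return masses


def _paired_t_array(diffs: np.ndarray) -> np.ndarray:
    """t statistics over axis −2 (participants) of ``(..., n, B)`` diffs.
    Zero-variance bins contribute statistic 0."""
    n = diffs.shape[-2]
    mean = diffs.mean(axis=-2)
    sd = diffs.std(axis=-2, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / math.sqrt(n))
    return np.where(sd == 0, 0.0, t)


def _omnibus_permutations(
    n: int, k: int, n_perm: int, rng: np.random.Generator
) -> tuple[np.ndarray, bool]:
    """Per-participant condition-label permutations, ``(m, n, k)`` index array.

    Enumerates the full group of size (k!)^n when it does not exceed
    ``n_perm``; otherwise draws ``n_perm`` random assignments.
    """
    perms = np.array(list(itertools.permutations(range(k))))
    n_total = len(perms) ** n
    if n_total <= n_perm:
        codes = np.array(
            list(itertools.product(range(len(perms)), repeat=n))
        )  # (n_total, n)
        return perms[codes], True
    codes = rng.integers(0, len(perms), size=(n_perm, n))
    return perms[codes], False


def cluster_permutation(
    data: np.ndarray,
    contrast: str | tuple[int, int] = "omnibus",
    n_perm: int = DEFAULT_N_PERM,
    alpha: float = DEFAULT_ALPHA,
    seed: int | None = None,
    conditions: Sequence[str] | None = None,
) -> list[ClusterResult]:
    """Max-cluster-mass Monte-Carlo permutation test on a
    ``(participants, conditions, bins)`` array.

    For the omnibus contrast the per-bin statistic is the RM-ANOVA F and
    labels are permuted independently within each participant; for a
    pairwise contrast ``(i, j)`` the statistic is the paired t and the
    permutation swaps the two labels per participant (sign flip of the
    difference). Clusters are contiguous bins exceeding the parametric
    alpha threshold; cluster mass is the summed statistic. When the full
    permutation group fits within ``n_perm`` it is enumerated and the
    p-value is exact; otherwise p = (1 + #{max ≥ observed})/(1 + n_perm).
    """
    data = np.asarray(data, float)
    if data.ndim != 3:
        raise ValueError("expected a (participants, conditions, bins) array")
    n, k, B = data.shape
    if np.isnan(data).any():
        raise ValueError("cluster_permutation requires a complete array")
    if n_perm < 100:
        warnings.warn(
            f"n_perm={n_perm} gives a coarse Monte-Carlo p resolution",
            RuntimeWarning,
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)

    if contrast == "omnibus":
        label = "omnibus"
        F, _, _ = _anova_f_array(data)
        threshold = f_critical(alpha, k - 1, (k - 1) * (n - 1))
        observed = _find_clusters(F, F > threshold)
        perm_idx, exhaustive = _omnibus_permutations(n, k, n_perm, rng)
        m = perm_idx.shape[0]
        # gather: permuted[p, i, c, :] = data[i, perm_idx[p, i, c], :]
        permuted = data[np.arange(n)[None, :, None], perm_idx, :]
        perm_F, _, _ = _anova_f_array(permuted)  # (m, B)
        null_max = _max_cluster_mass(perm_F, threshold)
    else:
        i, j = contrast
        if conditions is not None:
            label = f"{conditions[i]}-vs-{conditions[j]}"
        else:
            label = f"cond{i}-vs-cond{j}"
        diffs = data[:, i, :] - data[:, j, :]  # (n, B)
        t_obs = _paired_t_array(diffs)
        threshold = float(sp_stats.t.ppf(1.0 - alpha / 2.0, n - 1))
        observed = _find_clusters(t_obs, np.abs(t_obs) > threshold)
        if 2**n <= n_perm:
            signs = np.array(list(itertools.product((1.0, -1.0), repeat=n)))
            exhaustive = True
        else:
            signs = rng.choice((1.0, -1.0), size=(n_perm, n))
            exhaustive = False
        m = signs.shape[0]
        perm_t = _paired_t_array(signs[:, :, None] * diffs[None, :, :])
        null_max = _max_cluster_mass(perm_t, threshold)

    results: list[ClusterResult] = []
    for start, end, mass in observed:
        # tolerance so permutations tied with the observed mass (up to
        # float summation order) count as >=
        cut = mass - 1e-9 * max(1.0, abs(mass))
        if exhaustive:
            p = float(np.mean(null_max >= cut))
        else:
            p = (1.0 + float(np.sum(null_max >= cut))) / (1.0 + m)
        results.append(
            ClusterResult(
                contrast=label,
                start_bin=start,
                end_bin=end,
                mass=mass,
                p_mc=p,
                n_permutations=m,
                seed=seed,
                exhaustive=exhaustive,
            )
        )
    return results
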