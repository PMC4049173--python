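"""Group-level statistics for cohort comparisons.

Thin, explicit wrappers around scipy.stats returning a common
:class:`~zebratrain.types.GroupComparisonResult`: pooled-variance Student t
(from raw samples or printed summaries), paired t, Pearson chi-squared
without continuity correction, Spearman/Pearson correlation, one-way ANOVA
with Tukey or Bonferroni post hoc, the drug wash-in effect, and the f-I
(input-output) slope. Conventions match standard electrophysiology
reporting: two-sided p-values unless one-tailed is requested, pooled (not
Welch) variance for the unpaired t.
"""
from __future__ import annotations

from itertools import combinations
from typing import Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import InvalidConfigError, UndefinedMetricError
from .types import GroupComparisonResult

__all__ = [
    "two_sample_t",
    "paired_t",
    "pearson_chi2",
    "correlate",
    "one_way_anova",
    "washin_effect",
    "fi_slope",
    "aggregate_by_lobule",
]

Summary = Tuple[float, float, int]  # (mean, sd, n)


def _summarize(x: np.ndarray) -> Summary:
    return float(np.mean(x)), float(np.std(x, ddof=1)), int(x.size)


def two_sample_t(a: Union[Summary, Sequence[float]],
                 b: Union[Summary, Sequence[float]],
                 one_tailed: bool = False) -> GroupComparisonResult:
    """Pooled-variance (Student) unpaired t test.

    Each argument is either a raw sample or a printed summary ``(mean, sd, n)``
    (a 3-tuple whose last element is an integer count), so statistics reported
    from group summaries can be recomputed exactly.
    """
    def as_summary(x) -> Summary:
        if (isinstance(x, (tuple, list)) and len(x) == 3
                and isinstance(x[2], (int, np.integer))):
            m, s, n = x
            return float(m), float(s), int(n)
        arr = np.asarray(x, dtype=float)
        if arr.size < 2:
            raise InvalidConfigError("two_sample_t: need n >= 2 per group")
        return _summarize(arr)

    (m1, s1, n1), (m2, s2, n2) = as_summary(a), as_summary(b)
    if n1 < 2 or n2 < 2:
        raise InvalidConfigError("two_sample_t: need n >= 2 per group")
    if s1 < 0 or s2 < 0:
        raise InvalidConfigError("two_sample_t: SDs must be >= 0")
    res = sps.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2, equal_var=True)
    p = float(res.pvalue)
    if one_tailed:
        p = p / 2.0
    return GroupComparisonResult(
        statistic_name="t", value=float(res.statistic), df=n1 + n2 - 2, p=p,
        group_summaries=((m1, s1, n1), (m2, s2, n2)),
        degenerate=not np.isfinite(res.statistic),
    )


def paired_t(before: Sequence[float], after: Sequence[float]) -> GroupComparisonResult:
    """Paired Student t test on the pairwise differences (df = n - 1)."""
    x = np.asarray(before, dtype=float)
    y = np.asarray(after, dtype=float)
    if x.shape != y.shape:
        raise InvalidConfigError("paired_t: samples must have equal length")
    if x.size < 2:
        raise InvalidConfigError("paired_t: need n >= 2 pairs")
    d = x - y
    sd = np.std(d, ddof=1)
    if sd == 0:
        val = 0.0 if np.mean(d) == 0 else np.inf * np.sign(np.mean(d))
        return GroupComparisonResult(
            statistic_name="t", value=float(val), df=x.size - 1,
            p=1.0 if val == 0 else 0.0,
            group_summaries=(_summarize(x), _summarize(y)),
            degenerate=val != 0.0,
        )
    res = sps.ttest_rel(x, y)
    return GroupComparisonResult(
        statistic_name="t", value=float(res.statistic), df=x.size - 1,
        p=float(res.pvalue),
        group_summaries=(_summarize(x), _summarize(y)),
    )


def pearson_chi2(table) -> GroupComparisonResult:
    """Pearson chi-squared on a 2x2 contingency table, no continuity correction."""
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise InvalidConfigError("pearson_chi2: expected a 2x2 table")
    if np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise InvalidConfigError("pearson_chi2: counts must be non-negative integers")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise InvalidConfigError("pearson_chi2: zero row or column margin")
    chi2, p, dof, expected = sps.chi2_contingency(t, correction=False)
    return GroupComparisonResult(
        statistic_name="chi2", value=float(chi2), df=int(dof), p=float(p),
        extra={"expected": expected, "observed": t},
    )


def correlate(x: Sequence[float], y: Sequence[float],
              method: str = "spearman") -> GroupComparisonResult:
    """Spearman (average-rank ties) or Pearson correlation with two-sided p."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size != ya.size or xa.size < 3:
        raise InvalidConfigError("correlate: need equal-length samples, n >= 3")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise UndefinedMetricError("correlate: constant input")
    if method == "spearman":
        res = sps.spearmanr(xa, ya)
        name = "rho"
    elif method == "pearson":
        res = sps.pearsonr(xa, ya)
        name = "r"
    else:
        raise InvalidConfigError(f"correlate: unknown method {method!r}")
    return GroupComparisonResult(
        statistic_name=name, value=float(res.statistic), df=xa.size - 2,
        p=float(res.pvalue),
    )


def one_way_anova(groups: Sequence[Sequence[float]],
                  posthoc: Optional[str] = None) -> GroupComparisonResult:
    """One-way ANOVA; optional Tukey HSD or Bonferroni-corrected pairwise t.

    ``posthoc`` must be named explicitly ("tukey" or "bonferroni") — the
    field mixes both, so no silent default is taken.
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2 or any(g.size < 2 for g in gs):
        raise InvalidConfigError("one_way_anova: need >= 2 groups with n >= 2 each")
    k = len(gs)
    n_total = sum(g.size for g in gs)
    if all(np.std(g, ddof=1) == 0 for g in gs) and len({g.mean() for g in gs}) == 1:
        return GroupComparisonResult(
            statistic_name="F", value=np.nan, df=(k - 1, n_total - k), p=np.nan,
            group_summaries=tuple(_summarize(g) for g in gs), degenerate=True,
        )
    res = sps.f_oneway(*gs)
    extra = {}
    if posthoc == "tukey":
        hsd = sps.tukey_hsd(*gs)
        extra["posthoc"] = pd.DataFrame(
            [(i, j, float(hsd.statistic[i, j]), float(hsd.pvalue[i, j]))
             for i, j in combinations(range(k), 2)],
            columns=["group_i", "group_j", "mean_diff", "p_adj"],
        )
    elif posthoc == "bonferroni":
        m = k * (k - 1) // 2
        rows = []
        for i, j in combinations(range(k), 2):
            t = two_sample_t(gs[i], gs[j])
            rows.append((i, j, t.value, min(t.p * m, 1.0)))
        extra["posthoc"] = pd.DataFrame(
            rows, columns=["group_i", "group_j", "t", "p_adj"])
    elif posthoc is not None:
        raise InvalidConfigError(f"one_way_anova: unknown posthoc {posthoc!r}")
    return GroupComparisonResult(
        statistic_name="F", value=float(res.statistic),
        df=(k - 1, n_total - k), p=float(res.pvalue),
        group_summaries=tuple(_summarize(g) for g in gs), extra=extra,
    )


def washin_effect(ss_times: Sequence[float], drug_onset_s: float,
                  duration_s: Optional[float] = None,
                  pre_window_s: float = 120.0,
                  post_window_s: Tuple[float, float] = (300.0, 420.0)) -> float:
    """Percent rate reduction from pre-drug baseline to the post window.

    pre = mean rate over the 2 minutes before drug onset; post = mean rate
    over minutes 5-7 after the drug reached the chamber. Returns
    ``100 * (pre - post) / pre`` (positive = reduction).
    """
    t = np.asarray(ss_times, dtype=float)
    lo_pre = drug_onset_s - pre_window_s
    hi_post = drug_onset_s + post_window_s[1]
    if lo_pre < 0:
        raise UndefinedMetricError(
            "washin_effect: recording does not cover the 2-min pre-drug window")
    if duration_s is not None and duration_s < hi_post:
        raise UndefinedMetricError(
            f"washin_effect: recording must cover {hi_post:.0f} s "
            f"(duration {duration_s} s)")
    pre_count = np.count_nonzero((t >= lo_pre) & (t < drug_onset_s))
    pre = pre_count / pre_window_s
    if pre == 0:
        raise UndefinedMetricError("washin_effect: zero pre-drug rate")
    p0, p1 = post_window_s
    post_count = np.count_nonzero(
        (t >= drug_onset_s + p0) & (t < drug_onset_s + p1))
    post = post_count / (p1 - p0)
    return float(100.0 * (pre - post) / pre)


def fi_slope(currents_na: Sequence[float], rates_hz: Sequence[float]) -> float:
    """Ordinary least-squares slope of firing rate vs injected current (spk/s/nA)."""
    x = np.asarray(currents_na, dtype=float)
    y = np.asarray(rates_hz, dtype=float)
    if x.size != y.size or x.size < 3:
        raise InvalidConfigError("fi_slope: need >= 3 (current, rate) points")
    if np.ptp(x) == 0:
        raise InvalidConfigError("fi_slope: constant currents")
    return float(sps.linregress(x, y).slope)


def aggregate_by_lobule(metrics: pd.DataFrame,
                        intensity: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    """Per-lobule mean/SD/n of rate, CF pause and CV2, joined with intensity.

    ``metrics`` needs columns ``lobule``, ``ss_rate_hz``, and optionally
    ``cf_pause_ms`` / ``ss_mean_cv2``; ``intensity`` needs ``lobule`` and
    ``normalized_intensity``. Cells whose lobule is missing/NaN are excluded
    with a warning. The result is ready for :func:`correlate`.
    """
    if metrics.empty:
        raise InvalidConfigError("aggregate_by_lobule: empty metrics table")
    df = metrics.copy()
    bad = df["lobule"].isna() | (df["lobule"].astype(str).str.len() == 0)
    if bad.any():
        import warnings
        warnings.warn(f"{int(bad.sum())} cells without lobule label excluded",
                      stacklevel=2)
        df = df[~bad]
    if df.empty:
        raise InvalidConfigError("aggregate_by_lobule: no cells with a lobule label")
    agg_spec = {"ss_rate_mean": ("ss_rate_hz", "mean"),
                "ss_rate_sd": ("ss_rate_hz", lambda s: s.std(ddof=1)),
                "n_cells": ("ss_rate_hz", "size")}
    for col, out in (("cf_pause_ms", "cf_pause_mean"),
                     ("ss_mean_cv2", "cv2_mean")):
        if col in df.columns:
            agg_spec[out] = (col, "mean")
    out = df.groupby("lobule", sort=True).agg(**agg_spec).reset_index()
    if intensity is not None:
        out = out.merge(intensity[["lobule", "normalized_intensity"]],
                        on="lobule", how="left")
    return out
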