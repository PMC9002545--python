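"""Within-subject condition statistics.

Three complementary tests for the n-subjects x 3-conditions design:

* :func:`rm_anova` — one-way repeated-measures ANOVA.  Total variation is
  decomposed as SS_total = SS_subjects + SS_conditions + SS_error;
  F = MS_conditions / MS_error with df (c-1, (c-1)(n-1)) and effect size
  partial eta squared = SS_conditions / (SS_conditions + SS_error).  No
  sphericity correction is applied (uncorrected df are reported).
* :func:`wilks_one_sample` — one-sample multivariate test on within-subject
  difference scores.  With p difference variables over n subjects,
  Hotelling's T² = n d̄' S⁻¹ d̄, Wilks' Λ = 1/(1 + T²/(n-1)), and the exact
  F = ((n-p)/p) · T²/(n-1) with df (p, n-p).  With n=15 subjects and p=6
  difference variables (2 condition contrasts x 3 channels of a region)
  this yields df (6, 9).
* :func:`bonferroni_posthoc` — the three pairwise paired t tests with
  Bonferroni-adjusted p = min(1, 3p), per channel family.

:func:`percent_change` expresses a task-condition mean relative to the
baseline mean in percent, as used for fractal-dimension summaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .signal_io import CONDITIONS

__all__ = [
    "PairedDesign",
    "StatResult",
    "PairwiseResult",
    "rm_anova",
    "wilks_one_sample",
    "bonferroni_posthoc",
    "percent_change",
]


@dataclass(frozen=True)
class PairedDesign:
    """Complete-case subjects x conditions value matrix."""

    values: np.ndarray  # n_subjects x n_conditions
    conditions: tuple[str, ...] = CONDITIONS
    subjects: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 2 or values.shape[1] != len(self.conditions):
            raise ValueError(
                f"values must be n x {len(self.conditions)}, got shape {values.shape}"
            )
        if values.shape[0] < 3:
            raise ValueError("need at least 3 subjects")
        if not np.all(np.isfinite(values)):
            raise ValueError("missing or non-finite cell in paired design")

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class StatResult:
    statistic_name: str
    statistic: float
    df1: float
    df2: float
    p: float
    effect_size: float


@dataclass(frozen=True)
class PairwiseResult:
    pair: tuple[str, str]
    t: float
    df: int
    p_raw: float
    p_adjusted: float
    significant: bool


def rm_anova(design: PairedDesign) -> StatResult:
    """One-way within-subject ANOVA F test with partial eta squared."""
    y = design.values
    n, c = y.shape
    grand = y.mean()
    ss_subj = c * np.sum((y.mean(axis=1) - grand) ** 2)
    ss_cond = n * np.sum((y.mean(axis=0) - grand) ** 2)
    ss_tot = np.sum((y - grand) ** 2)
    ss_err = ss_tot - ss_subj - ss_cond
    df1, df2 = c - 1, (c - 1) * (n - 1)
    ms_cond = ss_cond / df1
    ms_err = ss_err / df2
    if ms_err <= 0:
        f = 0.0 if ss_cond == 0 else np.inf
    else:
        f = ms_cond / ms_err
    p = float(stats.f.sf(f, df1, df2)) if np.isfinite(f) else 0.0
    denom = ss_cond + ss_err
    eta = float(ss_cond / denom) if denom > 0 else 0.0
    return StatResult("F", float(f), float(df1), float(df2), p, eta)


def wilks_one_sample(diffs: np.ndarray | Sequence[Sequence[float]]) -> StatResult:
    """One-sample Hotelling/Wilks test that a mean difference vector is zero.

    ``diffs`` is n subjects x p difference variables.  Requires p < n and a
    non-singular sample covariance.
    """
    d = np.asarray(diffs, dtype=float)
    if d.ndim != 2:
        raise ValueError(f"diffs must be 2-D (subjects x variables), got {d.shape}")
    n, p = d.shape
    if p >= n:
        raise ValueError(f"need more subjects than variables (n={n}, p={p})")
    mean = d.mean(axis=0)
    if np.all(mean == 0):
        t2 = 0.0  # exact null identity; no covariance inversion needed
    else:
        cov = np.cov(d, rowvar=False, ddof=1).reshape(p, p)
        sign, logdet = np.linalg.slogdet(cov)
        if sign <= 0 or not np.isfinite(logdet):
            raise ValueError("singular difference covariance (collinear variables?)")
        t2 = float(n * mean @ np.linalg.solve(cov, mean))
    lam = 1.0 / (1.0 + t2 / (n - 1))
    f = ((n - p) / p) * t2 / (n - 1)
    pval = float(stats.f.sf(f, p, n - p))
    return StatResult("Wilks_Lambda", float(lam), float(p), float(n - p), pval, 1.0 - lam)


def bonferroni_posthoc(design: PairedDesign, alpha: float = 0.05) -> list[PairwiseResult]:
    """All pairwise paired t tests with Bonferroni adjustment over the family."""
    y = design.values
    c = y.shape[1]
    pairs = [(i, j) for i in range(c) for j in range(i + 1, c)]
    m = len(pairs)
    out = []
    for i, j in pairs:
        diff = y[:, i] - y[:, j]
        if np.allclose(diff.std(ddof=1), 0.0):
            t, p = (0.0, 1.0) if np.allclose(diff.mean(), 0.0) else (np.inf, 0.0)
        else:
            t, p = stats.ttest_rel(y[:, i], y[:, j])
        p_adj = min(1.0, m * float(p))
        out.append(
            PairwiseResult(
                pair=(design.conditions[i], design.conditions[j]),
                t=float(t),
                df=y.shape[0] - 1,
                p_raw=float(p),
                p_adjusted=p_adj,
                significant=p_adj < alpha,
            )
        )
    return out


def percent_change(baseline_mean: float, task_mean: float) -> float:
    """100 x (task - baseline) / baseline."""
    if baseline_mean == 0:
        raise ZeroDivisionError("baseline mean is zero; percent change undefined")
    return 100.0 * (task_mean - baseline_mean) / baseline_mean
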