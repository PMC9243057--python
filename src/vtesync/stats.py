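"""The study's statistical battery.

One-way repeated-measures ANOVA with Greenhouse-Geisser sphericity
correction, paired and one-sample t-tests with 95% confidence intervals,
Bonferroni conversion (raw p multiplied by the number of comparisons,
capped at 1), Cohen's d effect sizes, and Pearson correlation with an
optional log transform of either variable.  All tests are two-sided.
Incomplete subject rows are dropped listwise, with the dropped subjects
reported rather than silently discarded.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sst

__all__ = [
    "RmAnovaResult",
    "TTestResult",
    "rm_anova_oneway",
    "t_tests",
    "bonferroni_convert",
    "cohens_d",
    "pearson_r",
]


@dataclass
class RmAnovaResult:
    f_stat: float
    df_effect: float
    df_error: float
    p_raw: float
    gg_epsilon: float
    p_gg: float
    n_subjects: int
    dropped_subjects: list[int]


@dataclass
class TTestResult:
    t_stat: float
    df: int
    p_raw: float
    p_bonferroni: float
    ci_low: float
    ci_high: float
    cohen_d: float | None
    n: int


def _complete_cases(values: np.ndarray) -> tuple[np.ndarray, list[int]]:
    values = np.asarray(values, dtype=float)
    keep = np.all(np.isfinite(values), axis=1)
    return values[keep], list(np.flatnonzero(~keep))


def rm_anova_oneway(values: np.ndarray) -> RmAnovaResult:
    """Within-subject one-way ANOVA (subjects x conditions matrix).

    F = MS_condition / MS_(condition x subject); the Greenhouse-Geisser
    epsilon comes from the sample covariance of the condition columns,
    and the corrected p uses epsilon-scaled degrees of freedom.  Rows
    with missing values are dropped listwise and reported.
    """
    values, dropped = _complete_cases(values)
    n, k = values.shape if values.ndim == 2 else (0, 0)
    if k < 2:
        raise ValueError("need >= 2 conditions")
    if n < 2:
        raise ValueError("fewer than 2 complete subjects after listwise deletion")

    grand = values.mean()
    subj_means = values.mean(axis=1)
    cond_means = values.mean(axis=0)
    ss_cond = n * np.sum((cond_means - grand) ** 2)
    ss_subj = k * np.sum((subj_means - grand) ** 2)
    ss_total = np.sum((values - grand) ** 2)
    ss_err = ss_total - ss_cond - ss_subj
    df_cond = k - 1
    df_err = (k - 1) * (n - 1)
    ms_cond = ss_cond / df_cond
    ms_err = ss_err / df_err
    if ms_err <= 0:
        f = 0.0 if ms_cond == 0 else np.inf
    else:
        f = ms_cond / ms_err
    p_raw = float(sst.f.sf(f, df_cond, df_err)) if np.isfinite(f) else 0.0

    # Greenhouse-Geisser epsilon from the sample covariance of conditions
    cov = np.cov(values, rowvar=False, ddof=1)
    mean_diag = np.trace(cov) / k
    mean_all = cov.mean()
    row_means = cov.mean(axis=1)
    num = (k * (mean_diag - mean_all)) ** 2
    den = (k - 1) * (np.sum(cov**2) - 2 * k * np.sum(row_means**2) + k**2 * mean_all**2)
    eps = 1.0 if den == 0 else float(num / den)
    eps = min(max(eps, 1.0 / (k - 1)), 1.0)
    p_gg = float(sst.f.sf(f, df_cond * eps, df_err * eps)) if np.isfinite(f) else 0.0

    return RmAnovaResult(
        f_stat=float(f), df_effect=float(df_cond), df_error=float(df_err),
        p_raw=p_raw, gg_epsilon=eps, p_gg=max(p_gg, p_raw), n_subjects=n,
        dropped_subjects=dropped,
    )


def t_tests(
    a: np.ndarray,
    b: np.ndarray | None = None,
    mode: str = "one_sample",
    comparisons: int = 1,
    alpha: float = 0.05,
) -> TTestResult:
    """Paired or one-sample (against 0) t-test with CI and effect size.

    ``mode='paired'`` tests mean(a - b) = 0; ``mode='one_sample'`` tests
    mean(a) = 0 (or mean(a - b) if b is given as a constant baseline).
    The confidence interval is the two-sided (1 - alpha) interval for the
    mean (difference).
    """
    a = np.asarray(a, dtype=float)
    if mode == "paired":
        if b is None:
            raise ValueError("paired mode requires b")
        b = np.asarray(b, dtype=float)
        if a.shape != b.shape:
            raise ValueError("paired mode requires equal lengths")
        diff = a - b
    elif mode == "one_sample":
        diff = a - (0.0 if b is None else float(np.asarray(b).item()))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    n = len(diff)
    if n < 2:
        raise ValueError("need n >= 2")
    sd = diff.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance: t statistic undefined")
    se = sd / np.sqrt(n)
    t = float(diff.mean() / se)
    df = n - 1
    p = float(2 * sst.t.sf(abs(t), df))
    tcrit = float(sst.t.ppf(1 - alpha / 2, df))
    d = float(diff.mean() / sd)
    return TTestResult(
        t_stat=t, df=df, p_raw=p, p_bonferroni=bonferroni_convert(p, comparisons),
        ci_low=float(diff.mean() - tcrit * se), ci_high=float(diff.mean() + tcrit * se),
        cohen_d=d, n=n,
    )


def bonferroni_convert(p: float, comparisons: int) -> float:
    """Converted p-value: raw p times the number of comparisons, capped at 1."""
    if not 0 <= p <= 1:
        raise ValueError("p must be in [0, 1]")
    if comparisons < 1:
        raise ValueError("comparisons must be >= 1")
    return min(p * comparisons, 1.0)


def cohens_d(a: np.ndarray, b: np.ndarray | None = None, mode: str = "one_sample") -> float:
    """Cohen's d effect size.

    Paired and one-sample: mean of the (difference) scores over their SD
    (ddof=1).  Independent: difference of means over the pooled SD.
    """
    a = np.asarray(a, dtype=float)
    if mode in ("paired", "one_sample"):
        if mode == "paired":
            if b is None:
                raise ValueError("paired mode requires b")
            diff = a - np.asarray(b, dtype=float)
        else:
            diff = a
        sd = diff.std(ddof=1)
        if sd == 0:
            raise ValueError("zero SD: effect size undefined")
        return float(diff.mean() / sd)
    if mode == "independent":
        if b is None:
            raise ValueError("independent mode requires b")
        b = np.asarray(b, dtype=float)
        na, nb = len(a), len(b)
        pooled = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2))
        if pooled == 0:
            raise ValueError("zero pooled SD: effect size undefined")
        return float((a.mean() - b.mean()) / pooled)
    raise ValueError(f"unknown mode {mode!r}")


def pearson_r(
    x: np.ndarray,
    y: np.ndarray,
    log_x: bool = False,
    log_y: bool = False,
) -> tuple[float, float]:
    """Pearson correlation with two-sided t-based p.

    ``log_x``/``log_y`` apply a natural-log transform first (used for
    right-skewed variables such as time spent at the choice point).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or len(x) < 3:
        raise ValueError("need equal-length inputs with n >= 3")
    if log_x:
        if np.any(x <= 0):
            raise ValueError("log transform requires positive values")
        x = np.log(x)
    if log_y:
        if np.any(y <= 0):
            raise ValueError("log transform requires positive values")
        y = np.log(y)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in an input")
    r, p = sst.pearsonr(x, y)
    return float(r), float(p)
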