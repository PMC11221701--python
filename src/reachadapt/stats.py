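"""Group-comparison statistics: Welch/Student/paired t tests, Cohen's d,
95% confidence intervals, and the early-vs-late change regression.

The default comparison policy mirrors the study's rule: normality is
assessed per sample with the Shapiro-Wilk test, and Welch's correction is
applied when it is violated (Student's pooled test otherwise).  Bayes
factors (JZS) are attached as informational output when pingouin is
available; they are never part of any quantitative check here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["TestResult", "welch_t", "student_t", "paired_t", "compare_groups",
           "change_regression", "cohens_d_independent"]


@dataclass
class TestResult:
    statistic: float
    df: float
    p: float
    effect_size_d: float
    ci95: tuple[float, float]  # of the mean difference
    test: str = "welch_t"
    degenerate: bool = False
    bf10: float | None = None


def cohens_d_independent(a: np.ndarray, b: np.ndarray) -> float:
    """Pooled-SD Cohen's d for two independent samples (a minus b)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    sp = np.sqrt(
        ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    )
    if sp == 0.0:
        return 0.0 if a.mean() == b.mean() else float("inf")
    return float((a.mean() - b.mean()) / sp)


def _two_sample(a, b, equal_var: bool) -> TestResult:
    a, b = np.asarray(a, float), np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    df = float(res.df)
    diff = a.mean() - b.mean()
    if equal_var:
        sp2 = (
            (len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)
        ) / (len(a) + len(b) - 2)
        se = np.sqrt(sp2 * (1 / len(a) + 1 / len(b)))
    else:
        se = np.sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b))
    degenerate = se == 0.0
    if degenerate:
        ci = (diff, diff)
        stat, p = (0.0, 1.0) if diff == 0 else (float("inf"), 0.0)
    else:
        tcrit = sps.t.ppf(0.975, df)
        ci = (diff - tcrit * se, diff + tcrit * se)
        stat, p = float(res.statistic), float(res.pvalue)
    return TestResult(
        statistic=stat,
        df=df,
        p=p,
        effect_size_d=cohens_d_independent(a, b),
        ci95=(float(ci[0]), float(ci[1])),
        test="student_t" if equal_var else "welch_t",
        degenerate=degenerate,
        bf10=_bf10_ind(a, b),
    )


def welch_t(a, b) -> TestResult:
    """Welch's two-sample t test (Satterthwaite df) with pooled-SD d."""
    return _two_sample(a, b, equal_var=False)


def student_t(a, b) -> TestResult:
    """Student's pooled-variance two-sample t test."""
    return _two_sample(a, b, equal_var=True)


def paired_t(pre, post) -> TestResult:
    """Paired t test on post - pre; d = mean(diff) / sd(diff)."""
    pre, post = np.asarray(pre, float), np.asarray(post, float)
    if len(pre) != len(post):
        raise ValueError("paired samples must have equal length")
    if len(pre) < 2:
        raise ValueError("need n >= 2 pairs")
    diff = post - pre
    sd = diff.std(ddof=1)
    n = len(diff)
    if sd == 0.0:
        m = diff.mean()
        return TestResult(
            statistic=0.0 if m == 0 else float("inf"),
            df=n - 1,
            p=1.0 if m == 0 else 0.0,
            effect_size_d=0.0 if m == 0 else float("inf"),
            ci95=(float(m), float(m)),
            test="paired_t",
            degenerate=True,
        )
    res = sps.ttest_rel(post, pre)
    se = sd / np.sqrt(n)
    tcrit = sps.t.ppf(0.975, n - 1)
    return TestResult(
        statistic=float(res.statistic),
        df=float(n - 1),
        p=float(res.pvalue),
        effect_size_d=float(diff.mean() / sd),
        ci95=(float(diff.mean() - tcrit * se), float(diff.mean() + tcrit * se)),
        test="paired_t",
        bf10=_bf10_paired(pre, post),
    )


def compare_groups(a, b, policy: str = "shapiro_gated", alpha: float = 0.05) -> TestResult:
    """Two-group comparison under a normality-gating policy.

    ``shapiro_gated`` (default): Welch's test if either sample fails the
    Shapiro-Wilk normality check at ``alpha``, Student's otherwise;
    ``always_welch`` / ``always_student`` force one test.
    """
    if policy == "always_welch":
        return welch_t(a, b)
    if policy == "always_student":
        return student_t(a, b)
    if policy != "shapiro_gated":
        raise ValueError(f"unknown policy {policy!r}")
    a, b = np.asarray(a, float), np.asarray(b, float)
    violated = any(
        len(s) >= 3 and sps.shapiro(s).pvalue < alpha for s in (a, b)
    )
    return welch_t(a, b) if violated else student_t(a, b)


def change_regression(early_change, late_change) -> dict:
    """OLS of late change on early change: r2, slope and its p value."""
    x = np.asarray(early_change, float)
    y = np.asarray(late_change, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length samples with n >= 3")
    if x.var() == 0.0:
        raise ValueError("zero-variance predictor")
    res = sps.linregress(x, y)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r2": float(res.rvalue**2),
        "p": float(res.pvalue),
    }


def _bf10_ind(a, b) -> float | None:
    try:
        import pingouin as pg

        t = sps.ttest_ind(a, b, equal_var=False).statistic
        return float(pg.bayesfactor_ttest(t, nx=len(a), ny=len(b), paired=False))
    except Exception:
        return None


def _bf10_paired(pre, post) -> float | None:
    try:
        import pingouin as pg

        t = sps.ttest_rel(post, pre).statistic
        return float(pg.bayesfactor_ttest(t, nx=len(pre), paired=True))
    except Exception:
        return None
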