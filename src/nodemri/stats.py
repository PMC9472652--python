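"""Statistical layer: group comparisons, the PRE logistic score, ROC/Youden
diagnostics and observer-agreement ICC.

Conventions follow the clinical-reporting style of the response-prediction
literature: pooled-variance two-sample t-tests (or Mann-Whitney U when a
Shapiro-Wilk gate rejects normality), paired t / Wilcoxon signed-rank for
pre-vs-post contrasts, Pearson chi-square for 2x2 tables, and an empirical
ROC whose AUC is the Mann-Whitney concordance probability (ties counted
half).  The ROC cutoff maximizes the Youden index J = sensitivity +
specificity - 1, with ties broken toward higher specificity; the AUC
confidence interval is DeLong's.

The composite predictor PRE is a binary logistic regression of responder
status on pretreatment perfusion fraction (PF, reporting scale x1e-3) and
Ktrans (x1e-3 /min):  Logit(P) = b0 + b_pf*PF + b_kt*Ktrans, and
PRE = exp(Logit)/(1 + exp(Logit)).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import DataError

__all__ = [
    "GroupSummary",
    "ComparisonResult",
    "PreModel",
    "DiagnosticPerformance",
    "DEFAULT_PRE_MODEL",
    "PRE_CUTOFF_TEXT",
    "PRE_CUTOFF_TABLE",
    "paired_compare",
    "two_group_compare",
    "pooled_t_from_summary",
    "chisq_2x2",
    "pre_score",
    "fit_pre_model",
    "roc_analysis",
    "diagnostic_metrics",
    "icc_two_observers",
]


@dataclass(frozen=True)
class GroupSummary:
    """Mean +- SD summary of one group, as printed in clinical tables."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise DataError("sd must be non-negative")
        if self.n < 2:
            raise DataError("n must be at least 2")


@dataclass(frozen=True)
class ComparisonResult:
    statistic: float
    p_value: float
    test_name: str
    df: float | None = None


@dataclass(frozen=True)
class PreModel:
    """Coefficients of the PRE logistic score on reporting-scale inputs."""

    intercept: float = -5.654
    coef_pf: float = 0.013  # per 1e-3 PF unit
    coef_ktrans: float = 0.003  # per 1e-3/min Ktrans unit
    converged: bool = True
    note: str | None = None


DEFAULT_PRE_MODEL = PreModel()

# The published PRE cutoff is printed inconsistently (abstract/text vs the
# diagnostics table); both are carried as named constants and neither is a
# computed quantity here.
PRE_CUTOFF_TEXT = 0.6624
PRE_CUTOFF_TABLE = 0.6224


@dataclass(frozen=True)
class DiagnosticPerformance:
    """One predictor's diagnostic profile at its Youden-optimal cutoff.

    ``sensitivity``/``specificity``/``youden`` are fractions; ``ppv`` and
    ``npv`` are percentages (the tables' convention); likelihood ratios are
    plain ratios.
    """

    youden: float
    sensitivity: float
    specificity: float
    lr_pos: float
    lr_neg: float
    ppv: float
    npv: float
    auc: float | None = None
    auc_ci_95: tuple[float, float] | None = None
    cutoff: float | None = None


# ------------------------------------------------------------- comparisons


def _as_1d(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if not np.all(np.isfinite(arr)):
        raise DataError(f"{name} contains non-finite values")
    return arr


def _passes_shapiro(x: np.ndarray, alpha: float) -> bool:
    if np.ptp(x) == 0:  # constant sample: normality gate cannot pass
        return False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return bool(sps.shapiro(x).pvalue >= alpha)


def paired_compare(pre, post, normality_alpha: float = 0.05) -> ComparisonResult:
    """Paired t-test, or Wilcoxon signed-rank when the paired differences
    fail a Shapiro-Wilk normality check at ``normality_alpha``.

    The statistic is oriented as pre minus post (an increase after treatment
    yields a negative t/Z).  For n > 25 the Wilcoxon result is reported as
    the normal-approximation Z.
    """
    a = _as_1d(pre, "pre")
    b = _as_1d(post, "post")
    if a.size != b.size:
        raise DataError("pre and post must have equal length")
    if a.size < 3:
        raise DataError("paired_compare needs n >= 3")
    diff = a - b
    if np.allclose(diff, 0.0):
        return ComparisonResult(0.0, 1.0, "paired t", df=float(a.size - 1))
    if _passes_shapiro(diff, normality_alpha):
        res = sps.ttest_rel(a, b)
        return ComparisonResult(
            float(res.statistic), float(res.pvalue), "paired t", df=float(a.size - 1)
        )
    method = "approx" if a.size > 25 else "exact"
    try:
        res = sps.wilcoxon(a, b, method=method)
    except ValueError:  # exact method with ties falls back to approximation
        res = sps.wilcoxon(a, b, method="approx")
        method = "approx"
    stat = float(getattr(res, "zstatistic", res.statistic)) if method == "approx" else float(res.statistic)
    name = "wilcoxon signed-rank (Z)" if method == "approx" else "wilcoxon signed-rank"
    return ComparisonResult(stat, float(res.pvalue), name)


def two_group_compare(a, b, normality_alpha: float = 0.05) -> ComparisonResult:
    """Independent two-group comparison between e.g. RG and NRG.

    Pooled-variance t-test when both groups pass Shapiro-Wilk at
    ``normality_alpha``, Mann-Whitney U otherwise.  Oriented as group a
    minus group b.
    """
    x = _as_1d(a, "a")
    y = _as_1d(b, "b")
    if x.size < 3 or y.size < 3:
        raise DataError("two_group_compare needs n >= 3 per group")
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        if x[0] == y[0]:
            return ComparisonResult(0.0, 1.0, "pooled t", df=float(x.size + y.size - 2))
        raise DataError("degenerate zero-variance groups with unequal means")
    normal = _passes_shapiro(x, normality_alpha) and _passes_shapiro(y, normality_alpha)
    if normal:
        res = sps.ttest_ind(x, y, equal_var=True)
        return ComparisonResult(
            float(res.statistic),
            float(res.pvalue),
            "pooled t",
            df=float(x.size + y.size - 2),
        )
    res = sps.mannwhitneyu(x, y, alternative="two-sided")
    return ComparisonResult(float(res.statistic), float(res.pvalue), "mann-whitney U")


def pooled_t_from_summary(g1: GroupSummary, g2: GroupSummary) -> float:
    """Pooled-variance two-sample t statistic from printed summaries.

    t = (m1 - m2) / (s_p * sqrt(1/n1 + 1/n2)) with
    s_p^2 = ((n1-1)s1^2 + (n2-1)s2^2) / (n1 + n2 - 2).
    """
    sp2 = ((g1.n - 1) * g1.sd**2 + (g2.n - 1) * g2.sd**2) / (g1.n + g2.n - 2)
    se = math.sqrt(sp2) * math.sqrt(1.0 / g1.n + 1.0 / g2.n)
    if se == 0:
        raise DataError("zero pooled variance")
    return (g1.mean - g2.mean) / se


def chisq_2x2(a: int, b: int, c: int, d: int, correction: str = "none") -> ComparisonResult:
    """2x2 contingency test on counts [[a, b], [c, d]].

    ``correction`` selects Pearson chi-square ("none"), the Yates continuity
    adjustment ("yates"), or Fisher's exact test ("fisher", p-value only,
    odds ratio reported as the statistic).
    """
    counts = np.array([[a, b], [c, d]], dtype=float)
    if np.any(counts < 0) or np.any(counts != np.floor(counts)):
        raise DataError("counts must be non-negative integers")
    if counts.sum() == 0:
        raise DataError("empty table")
    if correction == "fisher":
        odds, p = sps.fisher_exact(counts)
        return ComparisonResult(float(odds), float(p), "fisher exact")
    if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
        raise DataError("chi-square undefined with a zero margin")
    if correction not in ("none", "yates"):
        raise DataError(f"unknown correction {correction!r}")
    res = sps.chi2_contingency(counts, correction=(correction == "yates"))
    return ComparisonResult(
        float(res.statistic),
        float(res.pvalue),
        "chi-square" + (" (yates)" if correction == "yates" else ""),
        df=float(res.dof),
    )


# ------------------------------------------------------------ PRE logistic


def pre_score(pf, ktrans, model: PreModel = DEFAULT_PRE_MODEL):
    """PRE predicted probability from reporting-scale PF and Ktrans.

    Strictly increasing in both inputs for positive coefficients.
    """
    pf = np.asarray(pf, dtype=float)
    ktrans = np.asarray(ktrans, dtype=float)
    logit = model.intercept + model.coef_pf * pf + model.coef_ktrans * ktrans
    out = sps.logistic.cdf(logit)
    return float(out) if out.ndim == 0 else out


def fit_pre_model(pf, ktrans, labels, positive: str = "RG") -> PreModel:
    """Maximum-likelihood logistic regression of responder status on
    (PF, Ktrans), both on reporting scales; responders coded 1.

    Newton-Raphson with tolerance 1e-8 and at most 100 iterations
    (statsmodels).  Perfect separation yields a flagged, non-converged
    result rather than an exception.
    """
    import statsmodels.api as sm

    pf = _as_1d(pf, "pf")
    kt = _as_1d(ktrans, "ktrans")
    y = np.asarray([1.0 if l == positive else 0.0 for l in labels])
    if pf.size != kt.size or pf.size != y.size:
        raise DataError("pf, ktrans and labels must have equal length")
    if pf.size < 10:
        raise DataError("fit_pre_model needs n >= 10")
    if y.min() == y.max():
        raise DataError("both classes must be present")
    X = sm.add_constant(np.column_stack([pf, kt]))
    note = None
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            res = sm.Logit(y, X).fit(disp=0, method="newton", tol=1e-8, maxiter=100)
            params = res.params
            converged = bool(res.mle_retvals.get("converged", True))
        except Exception as exc:  # perfect separation raises in statsmodels
            converged = False
            note = f"logistic fit failed: {exc}"
            params = np.array([0.0, 0.0, 0.0])
        for w in caught:
            if "separation" in str(w.message).lower() or "converge" in str(w.message).lower():
                converged = False
                note = str(w.message)
    return PreModel(
        intercept=float(params[0]),
        coef_pf=float(params[1]),
        coef_ktrans=float(params[2]),
        converged=converged,
        note=note,
    )


# ------------------------------------------------------------ ROC / Youden


def diagnostic_metrics(
    sens: float, spec: float, n_pos: int, n_neg: int
) -> DiagnosticPerformance:
    """Youden index, likelihood ratios and predictive values.

    Predictive values use the sample prevalence n_pos / (n_pos + n_neg) and
    are returned as percentages; lr_pos is infinite at perfect specificity.
    """
    if not (0 <= sens <= 1 and 0 <= spec <= 1):
        raise DataError("sens and spec must be in [0, 1]")
    if n_pos < 1 or n_neg < 1:
        raise DataError("n_pos and n_neg must be at least 1")
    youden = sens + spec - 1.0
    lr_pos = math.inf if spec == 1.0 else sens / (1.0 - spec)
    lr_neg = math.inf if spec == 0.0 else (1.0 - sens) / spec
    tp = sens * n_pos
    fp = (1.0 - spec) * n_neg
    tn = spec * n_neg
    fn = (1.0 - sens) * n_pos
    ppv = 100.0 * tp / (tp + fp) if tp + fp > 0 else math.nan
    npv = 100.0 * tn / (tn + fn) if tn + fn > 0 else math.nan
    return DiagnosticPerformance(
        youden=youden,
        sensitivity=sens,
        specificity=spec,
        lr_pos=lr_pos,
        lr_neg=lr_neg,
        ppv=ppv,
        npv=npv,
    )


def _delong_se(pos: np.ndarray, neg: np.ndarray) -> float:
    """DeLong standard error of the empirical AUC (placement-value form)."""
    comp = (pos[:, None] > neg[None, :]).astype(float)
    comp += 0.5 * (pos[:, None] == neg[None, :])
    v10 = comp.mean(axis=1)  # per-positive placement
    v01 = comp.mean(axis=0)  # per-negative placement
    m, n = pos.size, neg.size
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return math.sqrt(s10 / m + s01 / n)


def roc_analysis(scores, labels, positive: str = "RG") -> DiagnosticPerformance:
    """Empirical ROC analysis of a continuous score against binary labels.

    AUC is the Mann-Whitney concordance probability (ties count one half);
    candidate cutoffs are the distinct observed scores with the decision
    rule "positive if score >= cutoff"; the returned cutoff maximizes the
    Youden index, ties broken toward higher specificity.  The 95% AUC CI is
    the DeLong normal interval, clipped to [0, 1].
    """
    s = _as_1d(scores, "scores")
    lab = list(labels)
    if len(lab) != s.size:
        raise DataError("scores and labels must have equal length")
    is_pos = np.array([l == positive for l in lab], dtype=bool)
    if is_pos.all() or not is_pos.any():
        raise DataError("both classes must be present")
    pos = s[is_pos]
    neg = s[~is_pos]

    comp = (pos[:, None] > neg[None, :]).astype(float)
    comp += 0.5 * (pos[:, None] == neg[None, :])
    auc = float(comp.mean())
    se = _delong_se(pos, neg)
    ci = (max(0.0, auc - 1.959963984540054 * se), min(1.0, auc + 1.959963984540054 * se))

    thresholds = np.unique(s)
    best = None
    for thr in thresholds:  # ascending: later candidates have >= specificity
        sens = float(np.mean(pos >= thr))
        spec = float(np.mean(neg < thr))
        j = sens + spec - 1.0
        if best is None or j > best[0] + 1e-12 or (
            abs(j - best[0]) <= 1e-12 and spec > best[2]
        ):
            best = (j, sens, spec, float(thr))
    _, sens, spec, cutoff = best
    perf = diagnostic_metrics(sens, spec, int(pos.size), int(neg.size))
    return DiagnosticPerformance(
        youden=perf.youden,
        sensitivity=sens,
        specificity=spec,
        lr_pos=perf.lr_pos,
        lr_neg=perf.lr_neg,
        ppv=perf.ppv,
        npv=perf.npv,
        auc=auc,
        auc_ci_95=ci,
        cutoff=cutoff,
    )


# -------------------------------------------------------------------- ICC


def icc_two_observers(x1, x2) -> float:
    """Two-way random-effects, absolute-agreement, single-measure ICC(2,1).

    Computed from the ANOVA mean squares of the subjects x raters layout
    with two raters.  Returns NaN (with a warning) when the between-subject
    variance is zero, where the coefficient is undefined.
    """
    a = _as_1d(x1, "x1")
    b = _as_1d(x2, "x2")
    if a.size != b.size:
        raise DataError("observer series must have equal length")
    n = a.size
    if n < 3:
        raise DataError("icc needs at least 3 subjects")
    k = 2
    data = np.column_stack([a, b])
    grand = data.mean()
    subj_means = data.mean(axis=1)
    rater_means = data.mean(axis=0)
    msr = k * np.sum((subj_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((rater_means - grand) ** 2) / (k - 1)
    resid = data - subj_means[:, None] - rater_means[None, :] + grand
    mse = np.sum(resid**2) / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if msr <= 0 or denom <= 0:
        warnings.warn("ICC undefined: zero between-subject variance", stacklevel=2)
        return math.nan
    return float((msr - mse) / denom)
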