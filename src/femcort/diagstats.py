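"""Diagnostic statistics: correlation, ROC/AUC, Youden cut-offs,
predictive values, ICC reliability and group comparisons.

The ROC machinery is written directly on the empirical definition (the
curve over all distinct thresholds; trapezoid AUC, which equals the
Mann-Whitney concordance probability), with a Hanley-McNeil standard
error for the AUC confidence interval.  Cut-offs maximize the Youden
index J = Se + Sp - 1 and are reported as midpoints between the adjacent
distinct score values straddling the optimum.

:func:`reconstruct_confusion` is a verification oracle: it enumerates
all integer 2x2 tables of a given total and returns the one whose
sensitivity/specificity (and one auxiliary predictive value) round to
printed values -- the tool used to check a published diagnostic table
for internal consistency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import Decimal

import numpy as np
from scipy import stats


class StatisticsError(ValueError):
    """Raised when an estimator's preconditions are not met."""


# ---------------------------------------------------------------------------
# correlation


@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int


def pearson(x, y) -> CorrelationResult:
    """Pearson product-moment correlation with the t-transform p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise StatisticsError("inputs must be equal-length 1D arrays")
    if x.size < 3:
        raise StatisticsError("need n >= 3 for a correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise StatisticsError("correlation undefined for a constant input")
    res = stats.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), p=float(res.pvalue), n=x.size)


# ---------------------------------------------------------------------------
# ROC / AUC / Youden


@dataclass
class ROCResult:
    """Empirical ROC curve with AUC and a Hanley-McNeil 95% CI.

    ``fpr``/``tpr`` are the curve vertices (monotone non-decreasing);
    ``thresholds`` are the distinct decision thresholds in the oriented
    score space.  ``scores``/``labels`` keep the (oriented) inputs so
    cut-off selection can report midpoints between raw values.
    """

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    ci: tuple[float, float]
    n_pos: int
    n_neg: int
    orientation: str
    scores: np.ndarray = field(repr=False, default=None)
    labels: np.ndarray = field(repr=False, default=None)

    @property
    def youden(self) -> np.ndarray:
        return self.tpr - self.fpr


def _hanley_mcneil_ci(auc: float, n_pos: int, n_neg: int) -> tuple[float, float]:
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc * auc / (1.0 + auc)
    var = (auc * (1 - auc) + (n_pos - 1) * (q1 - auc ** 2)
           + (n_neg - 1) * (q2 - auc ** 2)) / (n_pos * n_neg)
    se = math.sqrt(max(var, 0.0))
    z = stats.norm.ppf(0.975)
    return (max(0.0, auc - z * se), min(1.0, auc + z * se))


def roc(scores, labels, orientation: str = "higher") -> ROCResult:
    """Empirical ROC over all distinct thresholds.

    ``labels`` are boolean (True = diseased).  ``orientation`` states
    which direction indicates disease: "higher" (larger score = more
    diseased) or "lower" (e.g. thinner cortex = osteoporotic).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape or s.ndim != 1:
        raise StatisticsError("scores and labels must be equal-length 1D arrays")
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise StatisticsError("both classes must be present")
    if orientation == "lower":
        s_or = -s
    elif orientation == "higher":
        s_or = s
    else:
        raise StatisticsError("orientation must be 'higher' or 'lower'")

    order = np.argsort(-s_or, kind="mergesort")
    ss = s_or[order]
    yy = y[order]
    distinct = np.r_[np.flatnonzero(np.diff(ss)), ss.size - 1]
    tps = np.cumsum(yy)[distinct]
    fps = np.cumsum(~yy)[distinct]
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    thresholds = np.r_[np.inf, ss[distinct]]

    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(fpr=fpr, tpr=tpr, thresholds=thresholds, auc=auc,
                     ci=_hanley_mcneil_ci(auc, n_pos, n_neg),
                     n_pos=n_pos, n_neg=n_neg, orientation=orientation,
                     scores=s, labels=y)


def auc_brute_force(scores, labels, orientation: str = "higher") -> float:
    """O(n^2) pairwise concordance AUC -- the independent oracle.

    AUC = P(score_pos ranks more diseased than score_neg), ties counting
    one half.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if orientation == "lower":
        s = -s
    pos = s[y]
    neg = s[~y]
    if pos.size == 0 or neg.size == 0:
        raise StatisticsError("both classes must be present")
    if pos.size * neg.size > 25_000_000:
        raise StatisticsError("brute-force oracle is for small inputs only")
    diff = pos[:, None] - neg[None, :]
    return float((np.sum(diff > 0) + 0.5 * np.sum(diff == 0)) / diff.size)


def youden_cutoff(rocresult: ROCResult) -> tuple[float, float, float]:
    """Cut-off maximizing J = Se + Sp - 1.

    Returns (cutoff, Se, Sp) with the cut-off mapped back to the raw
    score scale as the midpoint between the adjacent distinct values
    straddling the optimal threshold; ties in J resolve to the smallest
    raw cut-off.
    """
    r = rocresult
    if r.thresholds.size < 2:
        raise StatisticsError("degenerate ROC; cannot select a cut-off")
    j = r.youden
    best = float(j.max())
    cand = np.flatnonzero(j >= best - 1e-12)
    cand = cand[cand > 0]  # threshold = inf carries J = 0 anyway

    uniq = np.unique(r.scores)  # ascending raw scores

    def raw_cutoff(k: int) -> float:
        thr_or = r.thresholds[k]
        thr_raw = -thr_or if r.orientation == "lower" else thr_or
        # positives are raw < thr for "lower", raw > prev for "higher":
        # report the midpoint of the straddling distinct raw values
        i = np.searchsorted(uniq, thr_raw)
        if r.orientation == "lower":
            lo = uniq[i + 1] if i + 1 < uniq.size else thr_raw
            return float((thr_raw + lo) / 2.0)
        hi = uniq[i - 1] if i >= 1 else thr_raw
        return float((thr_raw + hi) / 2.0)

    cuts = [raw_cutoff(int(k)) for k in cand]
    pick = int(np.argmin(cuts))
    k = int(cand[pick])
    return cuts[pick], float(r.tpr[k]), float(1.0 - r.fpr[k])


# ---------------------------------------------------------------------------
# confusion matrices and predictive values


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0 or self.total == 0:
            raise StatisticsError("confusion counts must be non-negative, total > 0")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class PredictiveValues:
    """Se, Sp, PPV, NPV and accuracy; undefined ratios are None-flagged."""

    se: float | None
    sp: float | None
    ppv: float | None
    npv: float | None
    accuracy: float
    undefined: tuple[str, ...] = ()


def predictive_values(cm: ConfusionMatrix) -> PredictiveValues:
    def ratio(num: int, den: int, name: str, undef: list[str]) -> float | None:
        if den == 0:
            undef.append(name)
            return None
        return num / den

    undef: list[str] = []
    se = ratio(cm.tp, cm.tp + cm.fn, "se", undef)
    sp = ratio(cm.tn, cm.tn + cm.fp, "sp", undef)
    ppv = ratio(cm.tp, cm.tp + cm.fp, "ppv", undef)
    npv = ratio(cm.tn, cm.tn + cm.fn, "npv", undef)
    acc = (cm.tp + cm.tn) / cm.total
    return PredictiveValues(se=se, sp=sp, ppv=ppv, npv=npv, accuracy=acc,
                            undefined=tuple(undef))


def confusion_at_cutoff(scores, labels, cutoff: float,
                        orientation: str = "lower") -> ConfusionMatrix:
    """Cross-classify a below/above-cutoff test against true labels."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    pred = s < cutoff if orientation == "lower" else s > cutoff
    return ConfusionMatrix(tp=int(np.sum(pred & y)), fp=int(np.sum(pred & ~y)),
                           fn=int(np.sum(~pred & y)), tn=int(np.sum(~pred & ~y)))


class ReconstructionError(StatisticsError):
    """Zero or multiple integer tables satisfy the printed constraints."""

    def __init__(self, message: str, candidates: list[ConfusionMatrix]):
        super().__init__(message)
        self.candidates = candidates


def _decimals(x: float) -> int:
    exp = Decimal(str(x)).as_tuple().exponent
    return max(0, -int(exp))


def _rounds_to(value: float, printed: float) -> bool:
    d = _decimals(printed)
    return abs(round(value, d) - printed) < 10.0 ** (-d - 6)


def reconstruct_confusion(n: int, se_printed: float, sp_printed: float,
                          aux_constraint: tuple[str, float] | None = None
                          ) -> ConfusionMatrix:
    """Exhaustively reconstruct the unique 2x2 table behind printed values.

    Enumerates every integer table with total ``n`` whose sensitivity and
    specificity round to the printed values (at their printed precision,
    inferred from the decimal representation) and which satisfies the
    auxiliary constraint, e.g. ``("npv", 0.846)``.  Raises
    :class:`ReconstructionError` unless exactly one table survives.
    """
    if n <= 0:
        raise StatisticsError("n must be positive")
    survivors: list[ConfusionMatrix] = []
    for p in range(1, n):                 # diseased total = tp + fn
        nn = n - p                        # healthy total = fp + tn
        tps = [tp for tp in range(p + 1) if _rounds_to(tp / p, se_printed)]
        tns = [tn for tn in range(nn + 1) if _rounds_to(tn / nn, sp_printed)]
        for tp in tps:
            for tn in tns:
                cm = ConfusionMatrix(tp=tp, fp=nn - tn, fn=p - tp, tn=tn)
                if aux_constraint is not None:
                    name, printed = aux_constraint
                    pv = predictive_values(cm)
                    val = getattr(pv, name)
                    if val is None or not _rounds_to(val, printed):
                        continue
                survivors.append(cm)
    if len(survivors) != 1:
        raise ReconstructionError(
            f"{len(survivors)} tables match (n={n}, Se={se_printed}, "
            f"Sp={sp_printed}, aux={aux_constraint}); need exactly one",
            survivors)
    return survivors[0]


# ---------------------------------------------------------------------------
# ICC


@dataclass
class ICCResult:
    value: float
    form: str
    ci: tuple[float, float]
    degenerate: bool = False


def icc(ratings: np.ndarray, form: str = "ICC2,1", alpha: float = 0.05) -> ICCResult:
    """Intraclass correlation from the two-way ANOVA decomposition.

    ``ratings`` is subjects x raters with no missing cells.  The default
    form is ICC(2,1): two-way random effects, absolute agreement, single
    measures.  ICC(3,1) (two-way mixed, consistency) is also available.
    The CI uses the standard F-distribution bounds.
    """
    X = np.asarray(ratings, dtype=float)
    if X.ndim != 2 or X.shape[0] < 5 or X.shape[1] < 2:
        raise StatisticsError("need >= 5 subjects and >= 2 raters")
    if np.any(~np.isfinite(X)):
        raise StatisticsError("ratings must not contain missing cells")
    n, k = X.shape
    grand = X.mean()
    row_m = X.mean(axis=1)
    col_m = X.mean(axis=0)
    ss_rows = k * np.sum((row_m - grand) ** 2)
    ss_cols = n * np.sum((col_m - grand) ** 2)
    ss_tot = np.sum((X - grand) ** 2)
    ss_err = ss_tot - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    if msr <= 0 or ss_rows < 1e-12 * max(ss_tot, 1.0):
        return ICCResult(value=0.0, form=form, ci=(0.0, 0.0), degenerate=True)

    if form == "ICC3,1":
        value = (msr - mse) / (msr + (k - 1) * mse)
        fstat = msr / mse
        df1, df2 = n - 1, (n - 1) * (k - 1)
        fl = fstat / stats.f.ppf(1 - alpha / 2, df1, df2)
        fu = fstat * stats.f.ppf(1 - alpha / 2, df2, df1)
        lo = (fl - 1) / (fl + (k - 1))
        hi = (fu - 1) / (fu + (k - 1))
        return ICCResult(value=float(value), form=form,
                         ci=(float(max(-1, lo)), float(min(1, hi))))
    if form != "ICC2,1":
        raise StatisticsError(f"unsupported ICC form {form!r}")

    value = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    # McGraw & Wong F-based bounds for ICC(A,1)
    r = float(value)
    a = k * r / (n * (1 - r)) if r < 1 else np.inf
    b = 1 + k * r * (n - 1) / (n * (1 - r)) if r < 1 else np.inf
    if np.isfinite(a) and (a * msc + b * mse) > 0:
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1)))
        f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
        f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
        denom_l = f_l * (k * msc + (k * n - k - n) * mse) + n * msr
        denom_u = k * msc + (k * n - k - n) * mse + n * f_u * msr
        lo = n * (msr - f_l * mse) / denom_l if denom_l != 0 else -1.0
        hi = n * (f_u * msr - mse) / denom_u if denom_u != 0 else 1.0
    else:  # pragma: no cover - r == 1 exactly
        lo = hi = 1.0
    return ICCResult(value=r, form="ICC2,1",
                     ci=(float(max(-1.0, lo)), float(min(1.0, hi))))


# ---------------------------------------------------------------------------
# group comparisons


@dataclass
class GroupComparison:
    variable: str
    method: str            # "welch-t", "student-t", "rank-sum", "chi-square", "fisher"
    statistic: float
    p: float
    summary: dict


def summary_ttest(mean1: float, sd1: float, n1: int,
                  mean2: float, sd2: float, n2: int,
                  variable: str = "", equal_var: bool = False) -> GroupComparison:
    """Two-sample t-test from summary statistics only."""
    res = stats.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2,
                                     equal_var=equal_var)
    return GroupComparison(
        variable=variable, method="student-t" if equal_var else "welch-t",
        statistic=float(res.statistic), p=float(res.pvalue),
        summary={"group1": (mean1, sd1, n1), "group2": (mean2, sd2, n2)})


def _continuous_test(x: np.ndarray, y: np.ndarray, method: str) -> tuple[str, float, float]:
    if method == "auto":
        # normality pre-test on each group (Shapiro), rank-sum on failure
        p1 = stats.shapiro(x[:5000]).pvalue if x.size >= 3 else 1.0
        p2 = stats.shapiro(y[:5000]).pvalue if y.size >= 3 else 1.0
        method = "welch" if min(p1, p2) > 0.05 else "ranksum"
    if method == "welch":
        r = stats.ttest_ind(x, y, equal_var=False)
        return "welch-t", float(r.statistic), float(r.pvalue)
    if method == "student":
        r = stats.ttest_ind(x, y, equal_var=True)
        return "student-t", float(r.statistic), float(r.pvalue)
    if method == "ranksum":
        r = stats.mannwhitneyu(x, y, alternative="two-sided")
        return "rank-sum", float(r.statistic), float(r.pvalue)
    raise StatisticsError(f"unknown continuous method {method!r}")


def _categorical_test(x, y) -> tuple[str, float, float]:
    levels = sorted(set(x) | set(y))
    table = np.array([[np.sum(np.asarray(x) == lv) for lv in levels],
                      [np.sum(np.asarray(y) == lv) for lv in levels]])
    table = table[:, table.sum(axis=0) > 0]
    if table.shape[1] < 2:
        return "chi-square", 0.0, 1.0
    chi2, p, _, expected = stats.chi2_contingency(table)
    if (expected < 5).any() and table.shape == (2, 2):
        stat, p = stats.fisher_exact(table)
        return "fisher", float(stat), float(p)
    return "chi-square", float(chi2), float(p)


def compare_groups(frame, group_mask, variables,
                   continuous: str = "welch") -> list[GroupComparison]:
    """Compare two cohort subgroups variable by variable.

    ``group_mask`` is boolean (True = group 1).  ``variables`` is a list
    of column names or (name, kind) pairs with kind "continuous" or
    "categorical"; unlabelled columns are classified by dtype.
    ``continuous`` is "welch" (default), "student", "ranksum" or "auto"
    (Shapiro pre-test, rank-sum on failure).
    """
    mask = np.asarray(group_mask, dtype=bool)
    if mask.all() or not mask.any():
        raise StatisticsError("both groups must be non-empty")
    out: list[GroupComparison] = []
    for var in variables:
        name, kind = var if isinstance(var, tuple) else (var, None)
        col = frame[name]
        if kind is None:
            kind = "continuous" if np.issubdtype(np.asarray(col).dtype, np.number) \
                else "categorical"
        g1 = col[mask]
        g2 = col[~mask]
        if kind == "continuous":
            x = np.asarray(g1, dtype=float)
            y = np.asarray(g2, dtype=float)
            x, y = x[np.isfinite(x)], y[np.isfinite(y)]
            method, statv, p = _continuous_test(x, y, continuous)
            summary = {"group1": (float(x.mean()), float(x.std(ddof=1)), x.size),
                       "group2": (float(y.mean()), float(y.std(ddof=1)), y.size)}
        else:
            method, statv, p = _categorical_test(np.asarray(g1), np.asarray(g2))
            summary = {"group1": dict(zip(*np.unique(np.asarray(g1), return_counts=True))),
                       "group2": dict(zip(*np.unique(np.asarray(g2), return_counts=True)))}
        out.append(GroupComparison(variable=name, method=method,
                                   statistic=statv, p=float(p), summary=summary))
    return out


# ---------------------------------------------------------------------------
# diagnostic summary (the published-table shape)


@dataclass
class DiagnosticSummary:
    """One row of the diagnostic-efficiency table for a screening parameter."""

    parameter: str
    auc: float
    ci: tuple[float, float]
    cutoff: float
    se: float
    sp: float
    ppv: float
    npv: float
    n: int

    def rounded(self, digits: int = 3) -> dict:
        return {
            "parameter": self.parameter,
            "auc": round(self.auc, digits),
            "ci_low": round(float(self.ci[0]), digits),
            "ci_high": round(float(self.ci[1]), digits),
            "cutoff": round(self.cutoff, digits),
            "se": round(self.se, digits),
            "sp": round(self.sp, digits),
            "ppv": round(self.ppv, digits),
            "npv": round(self.npv, digits),
            "n": self.n,
        }


def diagnostic_summary(scores, labels, parameter: str,
                       orientation: str = "lower") -> DiagnosticSummary:
    """AUC, CI, Youden cut-off and the predictive values at that cut-off."""
    r = roc(scores, labels, orientation=orientation)
    cutoff, se, sp = youden_cutoff(r)
    cm = confusion_at_cutoff(scores, labels, cutoff, orientation=orientation)
    pv = predictive_values(cm)
    if pv.undefined:
        raise StatisticsError(
            f"predictive values undefined at the selected cut-off: {pv.undefined}")
    return DiagnosticSummary(parameter=parameter, auc=r.auc, ci=r.ci,
                             cutoff=cutoff, se=pv.se, sp=pv.sp,
                             ppv=pv.ppv, npv=pv.npv, n=int(len(scores)))


def table3_report(cohort, parameters=("cth_roi21", "hu_roi14")) -> list[DiagnosticSummary]:
    """Diagnostic-efficiency rows for a DXA-verified training cohort.

    Uses the DXA-diagnosed osteoporosis flag as truth and each configured
    screening parameter (lower = osteoporotic) as the score.
    """
    sub = cohort[cohort["osteoporotic_dxa"].notna()]
    labels = sub["osteoporotic_dxa"].astype(bool).to_numpy()
    if labels.sum() < 10 or (~labels).sum() < 10:
        raise StatisticsError("need at least 10 patients per class")
    return [diagnostic_summary(sub[p].to_numpy(dtype=float), labels, p)
            for p in parameters]
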