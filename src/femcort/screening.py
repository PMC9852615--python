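"""Osteoporosis diagnosis and CT-based screening rules.

The reference diagnosis follows the WHO densitometric criterion: a
patient is osteoporotic when the DXA T-score at any measured region is
strictly below -2.5.  The two CT screening rules classify a patient as
osteoporotic when the ROI-21 cortical thickness falls below 3.185 mm or
the ROI-14 cortical HU falls below 424.97 HU; a value exactly at the
cut-off is nonosteoporotic (the groups are ">= cut-off" vs "< cut-off").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar

from .cohort import DXARecord, WHO_T_THRESHOLD

#: ROI-21 cortical thickness cut-off, mm (full printed precision;
#: 3.19 is display rounding)
CTH_ROI21_CUTOFF = 3.185
#: ROI-14 cortical HU cut-off
HU_ROI14_CUTOFF = 424.97

OSTEOPOROTIC = "osteoporotic"
NONOSTEOPOROTIC = "nonosteoporotic"


@dataclass(frozen=True)
class ScreeningRule:
    """A below-cutoff-means-osteoporotic screening rule."""

    parameter: str          # "cth_roi21" or "hu_roi14"
    cutoff: float

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")


CTH_RULE = ScreeningRule("cth_roi21", CTH_ROI21_CUTOFF)
HU_RULE = ScreeningRule("hu_roi14", HU_ROI14_CUTOFF)
DEFAULT_RULES = (CTH_RULE, HU_RULE)


def dxa_diagnose(dxa: DXARecord) -> str:
    """WHO rule: osteoporotic iff min(T-scores) < -2.5 (strict)."""
    ts = (dxa.t_hip, dxa.t_lumbar)
    if any(t is None or not np.isfinite(t) for t in ts):
        raise ValueError("missing T-score; cannot apply the WHO criterion")
    return OSTEOPOROTIC if min(ts) < WHO_T_THRESHOLD else NONOSTEOPOROTIC


def apply_rule(value: float, rule: ScreeningRule) -> str:
    """Classify one measurement; exact ties with the cutoff are negative."""
    if not np.isfinite(value) or value <= 0:
        raise ValueError(f"measurement for {rule.parameter} must be finite and positive")
    return OSTEOPOROTIC if value < rule.cutoff else NONOSTEOPOROTIC


def apply_rule_series(values, rule: ScreeningRule) -> np.ndarray:
    """Vectorized :func:`apply_rule`; returns a boolean osteoporotic flag."""
    v = np.asarray(values, dtype=float)
    if np.any(~np.isfinite(v)) or np.any(v <= 0):
        raise ValueError(f"measurements for {rule.parameter} must be finite and positive")
    return v < rule.cutoff


@dataclass
class AgreementResult:
    """Cross-classification of two binary classifiers over one cohort.

    ``table`` is the 2x2 count matrix [[both+, A+B-], [A-B+, both-]].
    Fisher's exact test addresses association between the two rules;
    McNemar's test addresses marginal disagreement (exact binomial on the
    discordant cells when b + c < 25, else the continuity-corrected
    chi-square -- the printed variant is not identifiable, so it is
    selectable).
    """

    table: np.ndarray
    fisher_p: float
    mcnemar_stat: float
    mcnemar_p: float
    mcnemar_variant: str
    degenerate: bool = False

    @property
    def n(self) -> int:
        return int(self.table.sum())


def agreement(status_a, status_b, mcnemar_variant: str = "auto") -> AgreementResult:
    """Agreement analysis between two per-patient binary labelings.

    ``status_a``/``status_b`` are boolean arrays (True = osteoporotic).
    ``mcnemar_variant``: "auto" (exact when b+c < 25), "exact",
    "corrected" or "uncorrected".
    """
    a = np.asarray(status_a, dtype=bool)
    b = np.asarray(status_b, dtype=bool)
    if a.shape != b.shape or a.ndim != 1 or a.size == 0:
        raise ValueError("labelings must be equal-length non-empty 1D arrays")
    t11 = int(np.sum(a & b))
    t10 = int(np.sum(a & ~b))
    t01 = int(np.sum(~a & b))
    t00 = int(np.sum(~a & ~b))
    table = np.array([[t11, t10], [t01, t00]])

    degenerate = min(t11 + t10, t01 + t00) == 0 or min(t11 + t01, t10 + t00) == 0
    if degenerate:
        import warnings

        warnings.warn("degenerate single-class 2x2 table; Fisher p set to 1",
                      stacklevel=2)
        fisher_p = 1.0
    else:
        fisher_p = float(stats.fisher_exact(table)[1])

    disc = t10 + t01
    if mcnemar_variant == "auto":
        variant = "exact" if disc < 25 else "corrected"
    else:
        variant = mcnemar_variant
    if variant == "exact":
        res = _sm_mcnemar(table, exact=True)
    elif variant == "corrected":
        res = _sm_mcnemar(table, exact=False, correction=True)
    elif variant == "uncorrected":
        res = _sm_mcnemar(table, exact=False, correction=False)
    else:
        raise ValueError(f"unknown McNemar variant {variant!r}")
    mc_p = 1.0 if disc == 0 else float(res.pvalue)
    return AgreementResult(table=table, fisher_p=fisher_p,
                           mcnemar_stat=float(res.statistic),
                           mcnemar_p=min(mc_p, 1.0),
                           mcnemar_variant=variant, degenerate=degenerate)


def screen_cohort(cohort: pd.DataFrame, rules=DEFAULT_RULES) -> pd.DataFrame:
    """Label a cohort with every screening rule; returns a label table."""
    out = pd.DataFrame({"patient_id": cohort["patient_id"]})
    for rule in rules:
        flag = apply_rule_series(cohort[rule.parameter], rule)
        out[f"osteoporotic_{rule.parameter}"] = flag
    return out
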