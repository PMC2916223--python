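"""Validation statistics for HER-2 scoring.

Agreement between two raters (e.g. automated review vs pathologist) is
summarised by a 3x3 cross-tabulation over the ordinal categories
0/1+ < 2+ < 3+, with overall concordance, Cohen's chance-corrected kappa
and its Landis-Koch verbal label. Diagnostic accuracy against FISH as the
gold standard reports sensitivity and specificity with equivocal test
calls excluded (they are referred for FISH, not called), and FISH-equivocal
gold-standard cases dropped from the denominators. A rank-based,
tie-corrected ROC AUC and a cell-line control drift check complete the
layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .classify import Her2Category, parse_category
from .errors import ValidationError

CATEGORY_ORDER = (Her2Category.NEG, Her2Category.EQUIVOCAL, Her2Category.POSITIVE)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def cohens_kappa(counts: np.ndarray) -> float:
    """Unweighted Cohen's kappa from a square contingency table.

    kappa = (p_o - p_e) / (1 - p_e), with p_e the chance agreement from the
    row/column marginal products.
    """
    c = np.asarray(counts, dtype=float)
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise ValidationError("kappa needs a square contingency table")
    n = c.sum()
    if n <= 0:
        raise ValidationError("empty contingency table")
    p_o = np.trace(c) / n
    p_e = float((c.sum(axis=1) * c.sum(axis=0)).sum()) / n**2
    if p_e >= 1.0 - 1e-15:
        if p_o >= 1.0 - 1e-15:
            return 1.0
        raise ValidationError("degenerate table: chance agreement is 1")
    return float((p_o - p_e) / (1.0 - p_e))


def landis_koch_label(kappa: float) -> str:
    """Verbal strength-of-agreement label for a kappa value."""
    if not (-1.0 <= kappa <= 1.0):
        raise ValidationError(f"kappa {kappa} outside [-1, 1]")
    if kappa <= 0.0:
        return "poor"
    if kappa <= 0.20:
        return "slight"
    if kappa <= 0.40:
        return "fair"
    if kappa <= 0.60:
        return "moderate"
    if kappa <= 0.80:
        return "substantial"
    return "almost perfect"


@dataclass
class ConfusionSummary:
    """3x3 cross-tabulation (rows rater A, cols rater B) with agreement stats."""

    counts: np.ndarray
    n: int = field(init=False)
    concordance_pct: float = field(init=False)
    kappa: float = field(init=False)
    kappa_label: str = field(init=False)

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.shape != (3, 3) or (c < 0).any():
            raise ValidationError("counts must be a non-negative 3x3 table")
        self.counts = c.astype(int)
        self.n = int(c.sum())
        if self.n == 0:
            raise ValidationError("empty contingency table")
        self.concordance_pct = 100.0 * float(np.trace(c)) / self.n
        self.kappa = cohens_kappa(c)
        self.kappa_label = landis_koch_label(self.kappa)

    @property
    def n_agreements(self) -> int:
        return int(np.trace(self.counts))

    def n_reclassified(self, category: Her2Category) -> int:
        """Cases rater A put in ``category`` that rater B called differently."""
        row = self.counts[int(category)]
        return int(row.sum() - row[int(category)])

    def to_frame(self) -> pd.DataFrame:
        labels = [str(c) for c in CATEGORY_ORDER]
        return pd.DataFrame(self.counts, index=labels, columns=labels)

    def report(self) -> str:
        return (
            f"{self.to_frame()}\n"
            f"n = {self.n}, agreements = {self.n_agreements}\n"
            f"concordance = {self.concordance_pct:.1f}%\n"
            f"kappa = {self.kappa:.3f} ({self.kappa_label})"
        )


def confusion_matrix(calls_a, calls_b) -> ConfusionSummary:
    """Cross-tabulate two paired lists of HER-2 categories."""
    a = [parse_category(v) for v in calls_a]
    b = [parse_category(v) for v in calls_b]
    if len(a) != len(b):
        raise ValidationError(f"paired call lists differ in length: {len(a)} vs {len(b)}")
    if not a:
        raise ValidationError("empty call lists")
    counts = np.zeros((3, 3), dtype=int)
    for x, y in zip(a, b):
        counts[int(x), int(y)] += 1
    return ConfusionSummary(counts)


@dataclass
class DiagnosticAccuracy:
    """Sensitivity/specificity vs FISH; NaN marks an undefined quantity."""

    sensitivity_pct: float
    specificity_pct: float
    n_informative: int
    n_equivocal_excluded: int
    n_fish_equivocal_excluded: int = 0
    tp: int = 0
    fn: int = 0
    tn: int = 0
    fp: int = 0

    @property
    def sensitivity_defined(self) -> bool:
        return not math.isnan(self.sensitivity_pct)

    @property
    def specificity_defined(self) -> bool:
        return not math.isnan(self.specificity_pct)


def _binarize_fish(fish) -> tuple[list[bool | None], int]:
    """FISH input to amplified/not; equivocal cases map to None.

    Accepts `Her2Category` values, category label strings, or raw numeric
    HER2/Chr17 ratios (converted through the clinical thresholds).
    """
    from .classify import fish_category

    out: list[bool | None] = []
    n_eq = 0
    for v in fish:
        if isinstance(v, Her2Category):
            c = v
        elif isinstance(v, str):
            c = parse_category(v)
        else:
            c = fish_category(float(v))
        if c == Her2Category.EQUIVOCAL:
            out.append(None)
            n_eq += 1
        else:
            out.append(c == Her2Category.POSITIVE)
    return out, n_eq


def diagnostic_accuracy(
    test_calls, fish, exclude_equivocal: bool = True
) -> DiagnosticAccuracy:
    """Sensitivity and specificity of categorical calls vs FISH.

    ``fish`` may hold categories or raw HER2/Chr17 ratios. FISH-equivocal
    cases are always dropped; equivocal *test* calls are excluded from both
    denominators when ``exclude_equivocal`` (the default — those cases are
    referred, not called).
    """
    calls = [parse_category(v) for v in test_calls]
    truth, n_fish_eq = _binarize_fish(fish)
    if len(calls) != len(truth):
        raise ValidationError("test calls and FISH results differ in length")
    tp = fn = tn = fp = n_test_eq = 0
    for c, amp in zip(calls, truth):
        if amp is None:
            continue
        if c == Her2Category.EQUIVOCAL:
            n_test_eq += 1
            if not exclude_equivocal:
                # an equivocal call is neither positive nor negative; with
                # exclusion disabled it counts against both denominators
                if amp:
                    fn += 1
                else:
                    fp += 1
            continue
        pos_call = c == Her2Category.POSITIVE
        if amp and pos_call:
            tp += 1
        elif amp:
            fn += 1
        elif pos_call:
            fp += 1
        else:
            tn += 1
    sens = 100.0 * tp / (tp + fn) if (tp + fn) > 0 else math.nan
    spec = 100.0 * tn / (tn + fp) if (tn + fp) > 0 else math.nan
    return DiagnosticAccuracy(
        sensitivity_pct=sens,
        specificity_pct=spec,
        n_informative=tp + fn + tn + fp,
        n_equivocal_excluded=n_test_eq if exclude_equivocal else 0,
        n_fish_equivocal_excluded=n_fish_eq,
        tp=tp, fn=fn, tn=tn, fp=fp,
    )


@dataclass
class ConcordanceResult:
    pct: float            # unrounded
    pct_rounded: int      # half-up integer, as reported
    n_informative: int
    n_matching: int


def fish_concordance(test_calls, fish) -> ConcordanceResult:
    """Percent agreement of informative calls with binary FISH status.

    Equivocal test calls and FISH-equivocal cases do not enter the
    denominator; a negative call matches "not amplified" and a positive
    call matches "amplified".
    """
    calls = [parse_category(v) for v in test_calls]
    truth, _ = _binarize_fish(fish)
    if len(calls) != len(truth):
        raise ValidationError("test calls and FISH results differ in length")
    n = match = 0
    for c, amp in zip(calls, truth):
        if amp is None or c == Her2Category.EQUIVOCAL:
            continue
        n += 1
        if (c == Her2Category.POSITIVE) == amp:
            match += 1
    if n == 0:
        raise ValidationError("no informative calls for FISH concordance")
    pct = 100.0 * match / n
    return ConcordanceResult(pct=pct, pct_rounded=_round_half_up(pct),
                             n_informative=n, n_matching=match)


def roc_auc(scores, truth) -> float:
    """Rank-based AUC with tie correction (concordant + half-tied pairs)."""
    s = np.asarray(scores, dtype=float)
    t = np.asarray(truth).astype(bool)
    if s.shape != t.shape or s.ndim != 1:
        raise ValidationError("scores and truth must be equal-length 1-D")
    n1 = int(t.sum())
    n0 = len(t) - n1
    if n1 == 0 or n0 == 0:
        raise ValidationError("ROC needs both classes present")
    ranks = rankdata(s)  # average ranks handle ties
    return float((ranks[t].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


# -- cell-line control drift ---------------------------------------------


@dataclass
class ReferenceRanges:
    """Per-feature reference mean and SD from prior control batches."""

    mean: pd.Series
    sd: pd.Series

    @classmethod
    def from_batches(cls, batches: pd.DataFrame) -> "ReferenceRanges":
        if len(batches) < 3:
            raise ValidationError(
                "need >= 3 reference batches to establish control ranges"
            )
        num = batches.select_dtypes("number")
        return cls(mean=num.mean(), sd=num.std(ddof=1))


@dataclass
class DriftFlag:
    feature: str
    value: float
    lower: float
    upper: float


@dataclass
class BatchDriftReport:
    batch: object
    passed: bool
    flags: list[DriftFlag] = field(default_factory=list)


def control_drift_check(
    batches: pd.DataFrame,
    reference: ReferenceRanges,
    k: float = 3.0,
) -> list[BatchDriftReport]:
    """Flag control batches drifting outside mean +/- k*SD of the reference.

    ``batches`` has one row per staining batch and one numeric column per
    control-slide feature; features absent from the reference are ignored.
    """
    if reference is None:
        raise ValidationError("no reference ranges provided")
    reports = []
    for idx, row in batches.iterrows():
        flags = []
        for feat in reference.mean.index:
            if feat not in row.index:
                continue
            lo = reference.mean[feat] - k * reference.sd[feat]
            hi = reference.mean[feat] + k * reference.sd[feat]
            v = float(row[feat])
            if not (lo <= v <= hi):
                flags.append(DriftFlag(feature=feat, value=v,
                                       lower=float(lo), upper=float(hi)))
        reports.append(BatchDriftReport(batch=idx, passed=not flags, flags=flags))
    return reports
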