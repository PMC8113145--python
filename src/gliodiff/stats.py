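"""Diagnostic-performance statistics for two-class imaging biomarkers.

Implements the statistical machinery used to compare tumor progression (TP)
against treatment-related changes (TRC): Mann-Whitney U intergroup tests,
ROC curves with trapezoidal AUC and DeLong confidence intervals, optimal
cutoff selection by the maximum product of sensitivity and specificity,
confusion-matrix metrics with exact (Clopper-Pearson) binomial confidence
intervals, Cohen's kappa, and Pearson correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "RocCurve",
    "AucEstimate",
    "CutoffResult",
    "ConfusionMetrics",
    "mann_whitney",
    "roc_auc",
    "optimal_cutoff",
    "confusion",
    "cohens_kappa",
    "pearson_r",
]

HIGHER = "higher"
LOWER = "lower"


@dataclass(frozen=True)
class RocCurve:
    """ROC operating points over candidate thresholds.

    Thresholds are midpoints between consecutive distinct scores, in the
    original units of the marker, flanked by -inf/+inf endpoints so the
    curve always contains the (FPR, TPR) corners (0, 0) and (1, 1).
    ``direction`` states whether high scores ("higher") or low scores
    ("lower") indicate the positive class; calls use strict inequality.
    """

    thresholds: np.ndarray
    sens: np.ndarray
    spec: np.ndarray
    direction: str = HIGHER

    def __post_init__(self):
        if self.direction not in (HIGHER, LOWER):
            raise ValueError(f"direction must be 'higher' or 'lower', got {self.direction!r}")

    @property
    def fpr(self) -> np.ndarray:
        return 1.0 - self.spec

    @property
    def tpr(self) -> np.ndarray:
        return self.sens


@dataclass(frozen=True)
class AucEstimate:
    """Trapezoidal AUC with a DeLong 95% CI and p-value against AUC = 0.5."""

    auc: float
    ci95: tuple[float, float]
    p: float

    def __post_init__(self):
        lo, hi = self.ci95
        if not (0.0 <= lo <= self.auc <= hi <= 1.0):
            raise ValueError(f"ci95 {self.ci95} must lie in [0, 1] and bracket auc {self.auc}")


@dataclass(frozen=True)
class CutoffResult:
    """Optimal cutoff and the operating point it induces.

    ``criterion_value`` is sensitivity * specificity, the optimality
    criterion; strict inequality defines a positive call (score > cutoff for
    higher-positive markers, score < cutoff for lower-positive ones).
    """

    cutoff: float
    sens: float
    spec: float
    criterion_value: float
    direction: str = HIGHER


@dataclass(frozen=True)
class ConfusionMetrics:
    """2x2 confusion counts and rates with exact binomial 95% CIs.

    Rates with a zero denominator are ``None`` and carry no CI.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    sens: float | None
    spec: float | None
    acc: float | None
    ppv: float | None
    npv: float | None
    ci95: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def _as_1d(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError(f"{name} must be non-empty")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Returns (U, p) with U computed for ``x`` via midranks.  Uses exact
    enumeration when n1 + n2 <= 12 and there are no ties, otherwise the
    normal approximation with tie-corrected variance and continuity
    correction.  If every value in both samples is identical the test is
    degenerate: U = n1*n2/2 and p = 1.
    """
    x = _as_1d(x, "x")
    y = _as_1d(y, "y")
    combined = np.concatenate([x, y])
    if np.all(combined == combined[0]):
        return x.size * y.size / 2.0, 1.0
    has_ties = np.unique(combined).size < combined.size
    method = "exact" if (x.size + y.size <= 12 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def _binary_labels(labels, positive) -> np.ndarray:
    lab = np.asarray(labels)
    pos = lab == positive
    if pos.all() or not pos.any():
        raise ValueError("both classes must be represented")
    return pos


def roc_auc(scores, labels, direction: str = HIGHER, positive="TP") -> tuple[RocCurve, AucEstimate]:
    """ROC curve and AUC for a continuous marker.

    ``direction='lower'`` treats low scores as indicating the positive class
    (scores are negated internally; thresholds are reported in original
    units).  The AUC is the trapezoidal area, identical to the midrank
    Mann-Whitney statistic U/(n1*n2).  The CI and the p-value against the
    chance value 0.5 use the DeLong covariance estimator.
    """
    scores = _as_1d(scores, "scores")
    pos = _binary_labels(labels, positive)
    if scores.size != pos.size:
        raise ValueError("scores and labels must have equal length")

    work = scores if direction == HIGHER else -scores
    if direction not in (HIGHER, LOWER):
        raise ValueError(f"unknown direction {direction!r}")

    distinct = np.unique(work)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    thr_work = np.concatenate(([-np.inf], mids, [np.inf]))

    n_pos = int(pos.sum())
    n_neg = int((~pos).sum())
    # positive call: working score strictly above threshold
    calls = work[None, :] > thr_work[:, None]
    sens = (calls & pos).sum(axis=1) / n_pos
    spec = (~calls & ~pos).sum(axis=1) / n_neg

    if direction == LOWER:
        thresholds = -thr_work
    else:
        thresholds = thr_work
    curve = RocCurve(thresholds=thresholds, sens=sens, spec=spec, direction=direction)

    # descending threshold traverses the curve with fpr and tpr both non-decreasing
    auc = float(np.trapezoid(sens[::-1], (1.0 - spec)[::-1]))

    auc_d, var = _delong_variance(work, pos)
    # trapezoid and midrank AUC agree up to rounding; keep the curve-derived value
    assert abs(auc - auc_d) < 1e-9
    if var <= 0:
        ci = (auc, auc)
        p = 1.0 if auc == 0.5 else 0.0
    else:
        se = float(np.sqrt(var))
        z = sps.norm.ppf(0.975)
        ci = (max(0.0, auc - z * se), min(1.0, auc + z * se))
        p = float(2.0 * sps.norm.sf(abs(auc - 0.5) / se))
    return curve, AucEstimate(auc=auc, ci95=ci, p=p)


def _delong_variance(scores: np.ndarray, pos: np.ndarray) -> tuple[float, float]:
    """Midrank AUC and its DeLong variance."""
    x = scores[pos]
    y = scores[~pos]
    m, n = x.size, y.size
    tz = sps.rankdata(np.concatenate([x, y]))
    tx = sps.rankdata(x)
    ty = sps.rankdata(y)
    auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v01 = (tz[:m] - tx) / n          # placement of each positive among negatives
    v10 = 1.0 - (tz[m:] - ty) / m    # placement of each negative among positives
    s01 = v01.var(ddof=1) if m > 1 else 0.0
    s10 = v10.var(ddof=1) if n > 1 else 0.0
    return float(auc), s01 / m + s10 / n


def optimal_cutoff(curve: RocCurve) -> CutoffResult:
    """Cutoff maximizing sensitivity * specificity.

    Candidates are the finite thresholds (midpoints between distinct
    observed scores), so the cutoff always lies inside the observed score
    range.  Criterion ties break toward higher specificity, then toward the
    lower threshold.
    """
    finite = np.isfinite(curve.thresholds)
    if finite.sum() == 0:
        raise ValueError("degenerate ROC curve: no finite thresholds (constant scores)")
    thr = curve.thresholds[finite]
    sens = curve.sens[finite]
    spec = curve.spec[finite]
    crit = sens * spec
    best = None
    for i in range(thr.size):
        key = (crit[i], spec[i], -thr[i])
        if best is None or key > best[0]:
            best = (key, i)
    i = best[1]
    return CutoffResult(cutoff=float(thr[i]), sens=float(sens[i]), spec=float(spec[i]),
                        criterion_value=float(crit[i]), direction=curve.direction)


_RATE_DEFS = {
    "sens": ("tp", "fn"),
    "spec": ("tn", "fp"),
    "ppv": ("tp", "fp"),
    "npv": ("tn", "fn"),
}


def confusion(calls, labels, positive="TP", negative="TRC") -> ConfusionMetrics:
    """Confusion counts and rates with Clopper-Pearson exact 95% CIs."""
    calls = np.asarray(calls)
    labels = np.asarray(labels)
    if calls.shape != labels.shape:
        raise ValueError("calls and labels must have equal length")
    valid = {positive, negative}
    for name, arr in (("calls", calls), ("labels", labels)):
        bad = set(np.unique(arr)) - valid
        if bad:
            raise ValueError(f"{name} contain values outside {valid}: {bad}")
    c = {
        "tp": int(np.sum((calls == positive) & (labels == positive))),
        "fp": int(np.sum((calls == positive) & (labels == negative))),
        "tn": int(np.sum((calls == negative) & (labels == negative))),
        "fn": int(np.sum((calls == negative) & (labels == positive))),
    }
    rates: dict[str, float | None] = {}
    cis: dict[str, tuple[float, float]] = {}
    for rate, (num, other) in _RATE_DEFS.items():
        denom = c[num] + c[other]
        if denom == 0:
            rates[rate] = None
        else:
            rates[rate] = c[num] / denom
            lo, hi = proportion_confint(c[num], denom, alpha=0.05, method="beta")
            cis[rate] = (float(lo), float(hi))
    total = sum(c.values())
    if total == 0:
        rates["acc"] = None
    else:
        correct = c["tp"] + c["tn"]
        rates["acc"] = correct / total
        lo, hi = proportion_confint(correct, total, alpha=0.05, method="beta")
        cis["acc"] = (float(lo), float(hi))
    return ConfusionMetrics(**c, sens=rates["sens"], spec=rates["spec"], acc=rates["acc"],
                            ppv=rates["ppv"], npv=rates["npv"], ci95=cis)


def cohens_kappa(calls_a, calls_b) -> float:
    """Cohen's kappa for two categorical raters.

    kappa = (p_obs - p_exp) / (1 - p_exp) with marginal-product expected
    agreement.  When both raters are constant and identical (p_exp = 1) the
    agreement is perfect by construction and kappa is defined as 1.
    """
    a = np.asarray(calls_a)
    b = np.asarray(calls_b)
    if a.shape != b.shape or a.ndim != 1 or a.size == 0:
        raise ValueError("calls_a and calls_b must be equal-length non-empty 1-D sequences")
    cats = np.unique(np.concatenate([a, b]))
    n = a.size
    p_obs = np.mean(a == b)
    p_exp = sum(np.mean(a == c) * np.mean(b == c) for c in cats)
    if p_exp >= 1.0 - 1e-15:
        return 1.0
    return float((p_obs - p_exp) / (1.0 - p_exp))


def pearson_r(x, y) -> float:
    """Pearson product-moment correlation; requires n >= 3 and nonzero variances."""
    x = _as_1d(x, "x")
    y = _as_1d(y, "y")
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("pearson_r requires n >= 3")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("pearson_r undefined for zero-variance input")
    return float(sps.pearsonr(x, y).statistic)
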