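"""Two-stage sequential PWI + PET classifier for progression vs treatment change.

Stage 1 calls tumor progression (TP) when the perfusion hotspot rCBV_max
exceeds its cutoff — in the reference cohort this call was always correct
(specificity and PPV of 1.0) but insensitive.  Patients below the cutoff go
to stage 2, where the combined amino-acid PET rule calls TP when either
TBR_max exceeds its cutoff or the 20-40 min slope falls below its cutoff
(washout); only patients negative on both are called treatment-related
change (TRC).  All three cutoffs are fitted independently on the full
training cohort by maximizing sensitivity * specificity.

Exposed both as a scikit-learn estimator (``SequentialPwiPetClassifier``)
and as thin module-level functions over a patient table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .stats import ConfusionMetrics, confusion, optimal_cutoff, roc_auc

__all__ = [
    "SequentialCutoffs",
    "StagedCall",
    "FlowSummary",
    "LoocvResult",
    "ThresholdClassifier",
    "SequentialPwiPetClassifier",
    "fit_cutoffs",
    "classify_combined_pet",
    "classify_sequential",
    "evaluate_flow",
    "loocv",
    "FEATURES",
]

#: feature columns consumed by the sequential rule, in canonical order
FEATURES = ("rCBV_max", "TBR_max", "Slope_suv_per_h")

TP, TRC = "TP", "TRC"


@dataclass(frozen=True)
class SequentialCutoffs:
    """The three fitted thresholds of the sequential rule (strict inequalities)."""

    rcbv_cut: float
    tbr_cut: float
    slope_cut: float

    def __post_init__(self):
        for name in ("rcbv_cut", "tbr_cut", "slope_cut"):
            v = getattr(self, name)
            if np.isnan(v):
                raise ValueError(f"{name} must be a number")
        # infinite cutoffs are legal degenerate gates (stage disabled / always on)
        for name in ("rcbv_cut", "tbr_cut"):
            v = getattr(self, name)
            if np.isfinite(v) and v <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class StagedCall:
    """One patient's call with provenance: which stage and which parameter fired."""

    call: str
    stage: int
    triggering_parameter: str | None

    def __post_init__(self):
        if self.stage == 1 and self.call != TP:
            raise ValueError("stage 1 only ever calls TP")


@dataclass(frozen=True)
class FlowSummary:
    """Patient-flow accounting of the two-stage rule.

    Counts mirror the flow diagram (stage-1 TP box, unclassified box,
    stage-2 TP and TRC boxes); metric blocks cover the stage-1-only rule on
    everyone, the PET rule on the stage-2 subset, and the full sequential
    rule.
    """

    n_total: int
    n_stage1_tp: int
    n_remaining: int
    n_stage2_tp: int
    n_stage2_trc: int
    stage1_metrics: ConfusionMetrics
    stage2_metrics: ConfusionMetrics | None
    overall_metrics: ConfusionMetrics

    def __post_init__(self):
        if self.n_stage1_tp + self.n_remaining != self.n_total:
            raise ValueError("stage-1 counts must sum to n_total")
        if self.n_stage2_tp + self.n_stage2_trc != self.n_remaining:
            raise ValueError("stage-2 counts must sum to n_remaining")


@dataclass(frozen=True)
class LoocvResult:
    accuracy: float
    sens: float | None
    spec: float | None
    calls: np.ndarray
    n_skipped: int = 0


def _feature_frame(X) -> pd.DataFrame:
    """Accept a patient table / feature DataFrame or a (n, 3) array."""
    if isinstance(X, pd.DataFrame):
        missing = [c for c in FEATURES if c not in X.columns]
        if missing:
            raise ValueError(f"missing feature columns: {missing}")
        df = X.loc[:, list(FEATURES)]
    else:
        arr = np.asarray(X, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != len(FEATURES):
            raise ValueError(f"expected shape (n, {len(FEATURES)}) with columns {FEATURES}")
        df = pd.DataFrame(arr, columns=list(FEATURES))
    vals = df.to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValueError("features contain missing or non-finite values; imputation is not supported")
    return df


class ThresholdClassifier(BaseEstimator, ClassifierMixin):
    """Single-marker cutoff classifier fitted by max sensitivity * specificity.

    ``direction='higher'`` calls positive when score > cutoff_, 'lower' when
    score < cutoff_ (strict).  X is a single column of marker values.
    """

    def __init__(self, direction: str = "higher", positive_label: str = TP,
                 negative_label: str = TRC):
        self.direction = direction
        self.positive_label = positive_label
        self.negative_label = negative_label

    def fit(self, X, y):
        scores = np.asarray(X, dtype=float).ravel()
        y = np.asarray(y)
        curve, auc = roc_auc(scores, y, direction=self.direction,
                             positive=self.positive_label)
        best = optimal_cutoff(curve)
        self.cutoff_ = best.cutoff
        self.sens_ = best.sens
        self.spec_ = best.spec
        self.criterion_value_ = best.criterion_value
        self.auc_ = auc
        self.classes_ = np.unique(y)
        return self

    def predict(self, X):
        check_is_fitted(self, "cutoff_")
        scores = np.asarray(X, dtype=float).ravel()
        if self.direction == "higher":
            pos = scores > self.cutoff_
        else:
            pos = scores < self.cutoff_
        return np.where(pos, self.positive_label, self.negative_label)


class SequentialPwiPetClassifier(BaseEstimator, ClassifierMixin):
    """The two-stage sequential rule as a scikit-learn classifier.

    Parameters
    ----------
    rcbv_cut, tbr_cut, slope_cut : float or None
        Fixed cutoffs.  Any left as None is fitted on the training cohort by
        maximizing sensitivity * specificity of the corresponding marker
        (rCBV_max and TBR_max higher-positive, Slope lower-positive).

    Attributes
    ----------
    cutoffs_ : SequentialCutoffs
    classes_ : ndarray of ["TP", "TRC"] labels seen in fit
    """

    def __init__(self, rcbv_cut: float | None = None, tbr_cut: float | None = None,
                 slope_cut: float | None = None):
        self.rcbv_cut = rcbv_cut
        self.tbr_cut = tbr_cut
        self.slope_cut = slope_cut

    def fit(self, X, y=None):
        df = _feature_frame(X)
        fixed = (self.rcbv_cut, self.tbr_cut, self.slope_cut)
        if any(c is None for c in fixed):
            if y is None:
                raise ValueError("y is required to fit unfixed cutoffs")
            y = np.asarray(y)
            if np.unique(y).size < 2:
                raise ValueError("training cohort must contain both classes")
            fitted = []
            for col, direction, given in zip(FEATURES, ("higher", "higher", "lower"), fixed):
                if given is not None:
                    fitted.append(float(given))
                else:
                    sub = ThresholdClassifier(direction=direction).fit(df[col], y)
                    fitted.append(sub.cutoff_)
            self.cutoffs_ = SequentialCutoffs(*fitted)
        else:
            self.cutoffs_ = SequentialCutoffs(*(float(c) for c in fixed))
        self.classes_ = np.array([TP, TRC]) if y is None else np.unique(np.asarray(y))
        return self

    def _staged(self, df: pd.DataFrame) -> list[StagedCall]:
        c = self.cutoffs_
        out = []
        for rcbv, tbr, slope in df.itertuples(index=False):
            if rcbv > c.rcbv_cut:
                out.append(StagedCall(TP, 1, "rCBV_max"))
            elif tbr > c.tbr_cut:
                out.append(StagedCall(TP, 2, "TBR_max"))
            elif slope < c.slope_cut:
                out.append(StagedCall(TP, 2, "Slope_suv_per_h"))
            else:
                out.append(StagedCall(TRC, 2, None))
        return out

    def predict(self, X):
        check_is_fitted(self, "cutoffs_")
        return np.array([s.call for s in self._staged(_feature_frame(X))])

    def predict_staged(self, X) -> list[StagedCall]:
        """Per-patient calls with the stage and triggering parameter."""
        check_is_fitted(self, "cutoffs_")
        return self._staged(_feature_frame(X))


# ---------------------------------------------------------------------------
# thin functional surface over the estimator


def fit_cutoffs(cohort: pd.DataFrame) -> SequentialCutoffs:
    """Fit all three cutoffs on a labeled patient table."""
    clf = SequentialPwiPetClassifier().fit(cohort, cohort["label"].to_numpy())
    return clf.cutoffs_


def _clf(cutoffs: SequentialCutoffs) -> SequentialPwiPetClassifier:
    return SequentialPwiPetClassifier(cutoffs.rcbv_cut, cutoffs.tbr_cut,
                                      cutoffs.slope_cut).fit(
        pd.DataFrame([[1.0, 1.0, 0.0]], columns=list(FEATURES)))


def classify_combined_pet(record, cutoffs: SequentialCutoffs) -> str:
    """Stage-2 rule alone: TP iff TBR_max > cutoff or Slope < cutoff (strict)."""
    for name in ("TBR_max", "Slope_suv_per_h"):
        if name not in record or not np.isfinite(record[name]):
            raise ValueError(f"record is missing parameter {name}")
    if record["TBR_max"] > cutoffs.tbr_cut or record["Slope_suv_per_h"] < cutoffs.slope_cut:
        return TP
    return TRC


def classify_sequential(record, cutoffs: SequentialCutoffs) -> StagedCall:
    """Full two-stage call for one patient record (mapping or Series)."""
    if "rCBV_max" not in record or not np.isfinite(record["rCBV_max"]):
        raise ValueError("record is missing parameter rCBV_max")
    df = pd.DataFrame([[record[c] for c in FEATURES]], columns=list(FEATURES))
    return _clf(cutoffs).predict_staged(df)[0]


def evaluate_flow(cohort: pd.DataFrame, cutoffs: SequentialCutoffs) -> FlowSummary:
    """Apply the sequential rule to a labeled cohort and account the patient flow.

    Stage-2 metrics are computed on the stage-2 subset only; overall metrics
    count stage-1 calls as TP calls over the full cohort.
    """
    labels = cohort["label"].to_numpy()
    staged = _clf(cutoffs).predict_staged(cohort)
    calls = np.array([s.call for s in staged])
    stages = np.array([s.stage for s in staged])

    stage1_calls = np.where(stages == 1, TP, TRC)
    stage2_mask = stages == 2
    stage2_metrics = (confusion(calls[stage2_mask], labels[stage2_mask])
                      if stage2_mask.any() else None)
    return FlowSummary(
        n_total=len(cohort),
        n_stage1_tp=int((stages == 1).sum()),
        n_remaining=int(stage2_mask.sum()),
        n_stage2_tp=int((stage2_mask & (calls == TP)).sum()),
        n_stage2_trc=int((stage2_mask & (calls == TRC)).sum()),
        stage1_metrics=confusion(stage1_calls, labels),
        stage2_metrics=stage2_metrics,
        overall_metrics=confusion(calls, labels),
    )


def loocv(cohort: pd.DataFrame) -> LoocvResult:
    """Leave-one-out cross-validation of the full sequential procedure.

    Every fold refits all three cutoffs on the remaining n-1 patients and
    classifies the held-out patient; folds whose training set collapses to a
    single class are skipped with a warning and excluded from the rates.
    """
    if len(cohort) < 3:
        raise ValueError("loocv requires at least 3 patients")
    labels = cohort["label"].to_numpy()
    if np.unique(labels).size < 2:
        raise ValueError("cohort must contain both classes")
    calls = np.full(len(cohort), "", dtype=object)
    skipped = 0
    for i in range(len(cohort)):
        train = cohort.drop(cohort.index[i])
        if np.unique(train["label"]).size < 2:
            warnings.warn(f"fold {i}: single-class training set, skipped", stacklevel=2)
            skipped += 1
            continue
        cuts = fit_cutoffs(train)
        calls[i] = classify_sequential(cohort.iloc[i], cuts).call
    kept = calls != ""
    cm = confusion(calls[kept].astype(str), labels[kept])
    return LoocvResult(accuracy=cm.acc, sens=cm.sens, spec=cm.spec,
                       calls=calls, n_skipped=skipped)
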