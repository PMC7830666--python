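"""GLLE features and logistic classification of cardiac R-R series.

The feature set is GLLE(p) for p in {0.1, 0.5, 1, 2, 3, 4, 5}, each scaled
by 100 so odds ratios are expressed per 0.01 change of the raw exponent.
Two fixed-coefficient logistic scorers are shipped:

* ``MODEL1`` — healthy vs pathology (chf or af), five features, decision
  threshold P > 0.46;
* ``MODEL2`` — congestive heart failure vs atrial fibrillation, three
  features, threshold P > 0.48.

Fresh models can be refit with stepwise variable selection, and classifier
quality is evaluated with precision-recall curves (preferred over ROC for
the unbalanced group sizes) and the Matthews correlation coefficient.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .embedding import EmbeddingParams
from .errors import ParameterError
from .glle import RR_P_GRID, GLLEConfig, glle_spectrum
from .series import TimeSeries

__all__ = [
    "FEATURE_NAMES",
    "FeatureVector",
    "LogisticScorer",
    "MODEL1",
    "MODEL2",
    "ConfusionCounts",
    "PRCurve",
    "extract_features",
    "score_model1",
    "score_model2",
    "fit_stepwise_logistic",
    "prc_auc",
    "prc_auc_ci",
    "mcc",
]

#: fixed feature schema: GLLE(p) * 100 at the seven R-R p-grid points
FEATURE_NAMES: tuple[str, ...] = tuple(f"glle_{p:g}" for p in RR_P_GRID)


@dataclass(frozen=True)
class FeatureVector:
    """The seven named GLLE features (already x 100) of one subject."""

    values: Mapping[str, float]
    subject_id: str = ""
    group: str | None = None

    def __post_init__(self):
        vals = {name: float(self.values[name]) for name in FEATURE_NAMES
                if name in self.values}
        missing = [n for n in FEATURE_NAMES if n not in vals]
        if missing:
            raise ParameterError(f"feature vector missing {missing}")
        if not all(math.isfinite(v) for v in vals.values()):
            raise ParameterError("all features must be finite")
        object.__setattr__(self, "values", vals)

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def as_array(self) -> np.ndarray:
        return np.array([self.values[n] for n in FEATURE_NAMES])


def extract_features(ts: TimeSeries, params: EmbeddingParams,
                     config: GLLEConfig | None = None,
                     subject_id: str = "", group: str | None = None) -> FeatureVector:
    """GLLE spectrum on the seven-point R-R grid, scaled by 100."""
    spec = glle_spectrum(ts, params, p_grid=RR_P_GRID, config=config)
    values = {f"glle_{p:g}": 100.0 * est.glle
              for p, est in zip(RR_P_GRID, spec.estimates)}
    return FeatureVector(values=values, subject_id=subject_id, group=group)


def _sigmoid(z: float) -> float:
    # guard the exp against overflow for extreme logits
    if z >= 0:
        return 1.0 / (1.0 + math.exp(-z))
    e = math.exp(z)
    return e / (1.0 + e)


@dataclass(frozen=True)
class LogisticScorer:
    """intercept + named coefficients + a strict decision threshold."""

    intercept: float
    coefficients: Mapping[str, float]
    threshold: float = 0.5
    positive_label: str = "positive"
    negative_label: str = "negative"

    def __post_init__(self):
        unknown = set(self.coefficients) - set(FEATURE_NAMES)
        if unknown:
            raise ParameterError(f"coefficients name unknown features: {sorted(unknown)}")
        if not (0.0 < self.threshold < 1.0):
            raise ParameterError("threshold must lie in (0, 1)")
        object.__setattr__(self, "coefficients", dict(self.coefficients))

    def logit(self, fv: FeatureVector | Mapping[str, float]) -> float:
        get = fv.__getitem__
        z = self.intercept
        for name, b in self.coefficients.items():
            try:
                z += b * get(name)
            except KeyError:
                raise ParameterError(f"feature {name!r} missing from input") from None
        return z

    def probability(self, fv) -> float:
        """P(positive class) through the logistic link."""
        return _sigmoid(self.logit(fv))

    def label(self, fv) -> str:
        """Positive label iff P strictly exceeds the threshold."""
        return (self.positive_label if self.probability(fv) > self.threshold
                else self.negative_label)

    # -- flat key-value text serialization ---------------------------------
    def to_text(self) -> str:
        lines = [f"intercept = {self.intercept!r}",
                 f"threshold = {self.threshold!r}",
                 f"positive_label = {self.positive_label}",
                 f"negative_label = {self.negative_label}"]
        lines += [f"coef.{k} = {v!r}" for k, v in self.coefficients.items()]
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "LogisticScorer":
        fields: dict = {"coefficients": {}}
        for raw in text.splitlines():
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key.startswith("coef."):
                fields["coefficients"][key[5:]] = float(value)
            elif key in ("intercept", "threshold"):
                fields[key] = float(value)
            elif key in ("positive_label", "negative_label"):
                fields[key] = value
        return cls(**fields)


#: healthy (negative) vs pathology (positive): chf + af pooled
MODEL1 = LogisticScorer(
    intercept=-0.45,
    coefficients={"glle_0.1": 1.02, "glle_0.5": -5.18, "glle_1": -7.09,
                  "glle_4": 105.39, "glle_5": -95.23},
    threshold=0.46,
    positive_label="pathology", negative_label="healthy")

#: congestive heart failure (negative) vs atrial fibrillation (positive)
MODEL2 = LogisticScorer(
    intercept=3.34,
    coefficients={"glle_1": -4.851, "glle_4": 75.71, "glle_5": -70.84},
    threshold=0.48,
    positive_label="af", negative_label="chf")


def score_model1(fv: FeatureVector) -> float:
    """Probability that the subject belongs to the pathology group."""
    return MODEL1.probability(fv)


def score_model2(fv: FeatureVector) -> float:
    """Probability of atrial fibrillation (vs congestive heart failure)."""
    return MODEL2.probability(fv)


@dataclass(frozen=True)
class StepwiseConfig:
    """Forward-entry / backward-stay Wald p-value thresholds."""

    entry_p: float = 0.05
    stay_p: float = 0.10
    max_iter: int = 50


def fit_stepwise_logistic(features: Sequence[FeatureVector] | np.ndarray,
                          labels: Sequence[int],
                          config: StepwiseConfig | None = None,
                          feature_names: Sequence[str] | None = None,
                          threshold: float = 0.5) -> LogisticScorer:
    """Maximum-likelihood logistic fit with stepwise variable selection.

    Forward steps add the candidate with the smallest Wald p-value if it is
    below ``entry_p``; backward steps drop any selected variable whose
    p-value rises above ``stay_p``. Constant columns are never candidates.
    On (quasi-)separation the final refit falls back to an L2-penalized fit
    with a warning, so coefficients stay finite.
    """
    import statsmodels.api as sm

    config = config or StepwiseConfig()
    if feature_names is None:
        feature_names = list(FEATURE_NAMES)
        X = np.array([fv.as_array() for fv in features])
    else:
        X = np.asarray(features, dtype=float)
        feature_names = list(feature_names)
    y = np.asarray(labels, dtype=float)
    if X.shape[0] != y.size:
        raise ParameterError("features and labels disagree in length")
    if X.shape[0] < 10:
        raise ParameterError("need at least 10 observations")
    classes = np.unique(y)
    if classes.size < 2:
        raise ParameterError("labels contain a single class; nothing to separate")

    candidates = [i for i in range(X.shape[1]) if np.ptp(X[:, i]) > 0]

    def wald_p(cols: list[int]):
        Z = sm.add_constant(X[:, cols], has_constant="add")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, Z).fit(disp=0, maxiter=200)
        return res, np.asarray(res.pvalues)[1:]

    selected: list[int] = []
    for _ in range(config.max_iter):
        changed = False
        # forward
        remaining = [i for i in candidates if i not in selected]
        best_i, best_p = None, 1.0
        for i in remaining:
            try:
                _, pv = wald_p(selected + [i])
            except Exception:
                continue
            if pv[-1] < best_p:
                best_i, best_p = i, pv[-1]
        if best_i is not None and best_p < config.entry_p:
            selected.append(best_i)
            changed = True
        # backward
        if selected:
            try:
                _, pv = wald_p(selected)
                worst = int(np.argmax(pv))
                if pv[worst] > config.stay_p:
                    selected.pop(worst)
                    changed = True
            except Exception:
                pass
        if not changed:
            break
    if not selected:
        # separation (or a tiny sample) inflates every Wald standard error,
        # so nothing clears the entry threshold; fall back to a penalized
        # fit over all non-constant candidates
        if not candidates:
            raise ParameterError("no non-constant feature to select from")
        from sklearn.linear_model import LogisticRegression
        warnings.warn("stepwise selection retained no feature (separation or "
                      "insufficient signal); returning an L2-penalized fit "
                      "over all candidates", stacklevel=2)
        clf = LogisticRegression(penalty="l2", C=1.0, max_iter=2000)
        clf.fit(X[:, candidates], y)
        names = [feature_names[i] for i in candidates]
        return LogisticScorer(
            intercept=float(clf.intercept_[0]),
            coefficients=dict(zip(names, map(float, clf.coef_[0]))),
            threshold=threshold)
    selected.sort()

    try:
        res, pv = wald_p(selected)
        if not np.all(np.isfinite(res.params)) or not np.all(np.isfinite(res.bse)):
            raise ValueError("non-finite estimates")
        params = np.asarray(res.params)
    except Exception:
        from sklearn.linear_model import LogisticRegression
        warnings.warn("separation detected; falling back to an L2-penalized fit",
                      stacklevel=2)
        clf = LogisticRegression(penalty="l2", C=1.0, max_iter=2000)
        clf.fit(X[:, selected], y)
        params = np.concatenate([clf.intercept_, clf.coef_[0]])

    names = [feature_names[i] for i in selected]
    return LogisticScorer(intercept=float(params[0]),
                          coefficients=dict(zip(names, map(float, params[1:]))),
                          threshold=threshold)


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary-classification tally."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ParameterError("confusion counts must be non-negative")
        if self.tp + self.fp + self.tn + self.fn == 0:
            raise ParameterError("confusion counts sum to zero")

    @classmethod
    def from_labels(cls, y_true, y_pred) -> "ConfusionCounts":
        y_true = np.asarray(y_true, dtype=bool)
        y_pred = np.asarray(y_pred, dtype=bool)
        return cls(tp=int(np.sum(y_true & y_pred)),
                   fp=int(np.sum(~y_true & y_pred)),
                   tn=int(np.sum(~y_true & ~y_pred)),
                   fn=int(np.sum(y_true & ~y_pred)))


def mcc(conf: ConfusionCounts) -> float:
    """Matthews correlation coefficient in [-1, 1]; 0 if any marginal is 0.

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)).
    """
    tp, fp, tn, fn = conf.tp, conf.fp, conf.tn, conf.fn
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


@dataclass(frozen=True)
class PRCurve:
    """Precision-recall points, trapezoidal AUC, and a chosen threshold."""

    recall: np.ndarray
    precision: np.ndarray
    auc: float
    threshold: float  # score cut maximizing the selection criterion
    criterion: str = "f1"


def prc_auc(scores, labels, criterion: str = "f1") -> PRCurve:
    """Precision-recall curve with trapezoidal AUC over recall.

    The associated decision threshold is the score cut maximizing F1
    (the only criterion currently implemented). Both classes must appear
    in ``labels``.
    """
    from sklearn.metrics import precision_recall_curve

    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if np.unique(y).size < 2:
        raise ParameterError("PRC needs both classes present")
    precision, recall, thresholds = precision_recall_curve(y, scores)
    # sklearn orders recall descending ending at 0; integrate over recall
    auc = float(np.trapezoid(precision[::-1], recall[::-1]))
    if criterion != "f1":
        raise ParameterError(f"unknown threshold criterion {criterion!r}")
    # thresholds align with precision[:-1]/recall[:-1]
    with np.errstate(invalid="ignore", divide="ignore"):
        f1 = 2 * precision[:-1] * recall[:-1] / (precision[:-1] + recall[:-1])
    f1 = np.nan_to_num(f1)
    best = int(np.argmax(f1))
    return PRCurve(recall=recall, precision=precision, auc=auc,
                   threshold=float(thresholds[best]), criterion=criterion)


def prc_auc_ci(scores, labels, n_boot: int = 2000, alpha: float = 0.05,
               seed: int | None = None) -> tuple[float, float, float]:
    """Stratified-bootstrap confidence interval for the PRC AUC.

    Returns (auc, lower, upper) at level 1 - alpha. Resamples each class
    separately so every replicate keeps both classes.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    base = prc_auc(scores, y).auc
    rng = np.random.default_rng(seed)
    pos = np.nonzero(y)[0]
    neg = np.nonzero(~y)[0]
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        idx = np.concatenate([rng.choice(pos, pos.size, replace=True),
                              rng.choice(neg, neg.size, replace=True)])
        aucs[b] = prc_auc(scores[idx], y[idx]).auc
    lo, hi = np.quantile(aucs, [alpha / 2, 1 - alpha / 2])
    return base, float(lo), float(hi)
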