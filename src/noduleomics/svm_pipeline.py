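"""RBF-kernel SVM training, bootstrap hyperparameter tuning and evaluation.

The classifier is tuned by a 100-repetition bootstrap strategy: for each
``(C, gamma)`` pair on a log grid, the training table is repeatedly split
into stratified 70 % / 30 % partitions, the SVM is fitted on the 70 %
part (features standardized with that part's statistics) and scored by
validation accuracy; the pair with the best average wins and is refitted
on the whole training table.  Class probabilities come from a sigmoid
(Platt) fit on the refit model's decision values.

Evaluation reports sensitivity, specificity and accuracy at a fixed 0.5
probability threshold with primary lung cancer (LC) as the positive
class, plus the ROC curve over all unique probability cutoffs and its
trapezoidal AUC.  No class weighting is applied by default (the LM/LC
imbalance, and the low sensitivity it produces, is part of the modelled
protocol); a ``class_weight`` option exists.

The fitted model is stored as plain arrays (support vectors, dual
coefficients, standardization and calibration parameters), so models
serialize losslessly to JSON.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.svm import SVC

from .feature_selection import stratified_split_indices
from .volume_io import FeatureTable, POSITIVE_LABEL

logger = logging.getLogger("noduleomics.svm")

DEFAULT_C_GRID = tuple(10.0**k for k in range(-2, 4))       # 1e-2 .. 1e3
DEFAULT_GAMMA_GRID = tuple(10.0**k for k in range(-4, 2))   # 1e-4 .. 1e1


# ---------------------------------------------------------------------------
# Model container
# ---------------------------------------------------------------------------

@dataclass
class SvmModel:
    """A fitted RBF-SVM with standardization and Platt calibration."""

    features: list[str]
    C: float
    gamma: float
    mean: np.ndarray
    sd: np.ndarray
    support_vectors: np.ndarray
    dual_coef: np.ndarray
    intercept: float
    platt_a: float
    platt_b: float
    bootstrap_accuracy: float = float("nan")
    bootstrap_scores: dict = field(default_factory=dict)

    def decision_function(self, x: np.ndarray) -> np.ndarray:
        z = (np.asarray(x, dtype=float) - self.mean) / self.sd
        d2 = ((z[:, None, :] - self.support_vectors[None, :, :]) ** 2).sum(-1)
        return np.exp(-self.gamma * d2) @ self.dual_coef + self.intercept

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """P(positive class) via the Platt sigmoid on decision values."""
        f = self.decision_function(x)
        return 1.0 / (1.0 + np.exp(self.platt_a * f + self.platt_b))

    def to_dict(self) -> dict:
        return {
            "features": self.features,
            "C": self.C,
            "gamma": self.gamma,
            "mean": self.mean.tolist(),
            "sd": self.sd.tolist(),
            "support_vectors": self.support_vectors.tolist(),
            "dual_coef": self.dual_coef.tolist(),
            "intercept": self.intercept,
            "platt_a": self.platt_a,
            "platt_b": self.platt_b,
            "bootstrap_accuracy": self.bootstrap_accuracy,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SvmModel":
        return cls(
            features=list(d["features"]),
            C=float(d["C"]),
            gamma=float(d["gamma"]),
            mean=np.asarray(d["mean"], dtype=float),
            sd=np.asarray(d["sd"], dtype=float),
            support_vectors=np.asarray(d["support_vectors"], dtype=float),
            dual_coef=np.asarray(d["dual_coef"], dtype=float),
            intercept=float(d["intercept"]),
            platt_a=float(d["platt_a"]),
            platt_b=float(d["platt_b"]),
            bootstrap_accuracy=float(d.get("bootstrap_accuracy", float("nan"))),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "SvmModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _platt_fit(f: np.ndarray, y: np.ndarray, n_iter: int = 100) -> tuple[float, float]:
    """Newton fit of the Platt sigmoid P(y=1|f) = 1/(1+exp(a f + b)).

    Uses the standard smoothed targets so a separable decision function
    does not drive the slope to infinity.
    """
    n1, n0 = int(y.sum()), int((y == 0).sum())
    t = np.where(y == 1, (n1 + 1.0) / (n1 + 2.0), 1.0 / (n0 + 2.0))
    a, b = 0.0, float(np.log((n0 + 1.0) / (n1 + 1.0)))
    for _ in range(n_iter):
        z = a * f + b
        p = 1.0 / (1.0 + np.exp(z))
        # gradient and Hessian of the cross-entropy in (a, b)
        d = t - p
        g = np.array([np.sum(d * f), np.sum(d)])
        w = p * (1.0 - p)
        h = np.array(
            [[np.sum(w * f * f) + 1e-12, np.sum(w * f)],
             [np.sum(w * f), np.sum(w) + 1e-12]]
        )
        step = np.linalg.solve(h, g)
        a, b = a - step[0], b - step[1]
        if np.abs(step).max() < 1e-10:
            break
    return float(a), float(b)


def train_svm(
    train: FeatureTable,
    features: list[str],
    reps: int = 100,
    seed: int = 0,
    C_grid=DEFAULT_C_GRID,
    gamma_grid=DEFAULT_GAMMA_GRID,
    train_frac: float = 0.70,
    class_weight=None,
) -> SvmModel:
    """Tune (C, gamma) by repeated stratified validation, then refit.

    The same ``reps`` partitions are reused for every grid pair so the
    comparison is paired; grid ties keep the first (smallest C, then
    smallest gamma) pair.  Zero-variance features are dropped with a
    warning before standardization.
    """
    if not features:
        raise ValueError("no features to train on")
    y = train.binary_labels()
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise ValueError("each class needs at least 2 training cases")
    x = train.features(features)
    keep = x.std(axis=0) > 0
    if not keep.all():
        dropped = [f for f, k in zip(features, keep) if not k]
        logger.warning("dropping zero-variance features: %s", dropped)
        features = [f for f, k in zip(features, keep) if k]
        x = x[:, keep]
        if x.shape[1] == 0:
            raise ValueError("all features are constant in the training table")

    rng = np.random.default_rng(seed)
    partitions = [stratified_split_indices(y, train_frac, rng) for _ in range(reps)]
    grid = [(c, g) for c in C_grid for g in gamma_grid]
    scores = np.zeros(len(grid))
    for tr, va in partitions:
        mu = x[tr].mean(axis=0)
        sd = x[tr].std(axis=0)
        sd[sd == 0] = 1.0
        x_tr, x_va = (x[tr] - mu) / sd, (x[va] - mu) / sd
        for gi, (c, g) in enumerate(grid):
            clf = SVC(kernel="rbf", C=c, gamma=g, class_weight=class_weight)
            clf.fit(x_tr, y[tr])
            scores[gi] += (clf.predict(x_va) == y[va]).mean()
    scores /= reps
    best = int(np.argmax(scores))  # first best -> deterministic tie-break
    best_c, best_gamma = grid[best]

    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    x_std = (x - mu) / sd
    clf = SVC(kernel="rbf", C=best_c, gamma=best_gamma, class_weight=class_weight)
    clf.fit(x_std, y)
    f_train = clf.decision_function(x_std)
    a, b = _platt_fit(f_train, y)
    return SvmModel(
        features=features,
        C=best_c,
        gamma=best_gamma,
        mean=mu,
        sd=sd,
        support_vectors=clf.support_vectors_.copy(),
        dual_coef=clf.dual_coef_.ravel().copy(),
        intercept=float(clf.intercept_[0]),
        platt_a=a,
        platt_b=b,
        bootstrap_accuracy=float(scores[best]),
        bootstrap_scores={f"C={c:g},gamma={g:g}": float(s) for (c, g), s in zip(grid, scores)},
    )


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

@dataclass
class MetricsReport:
    """Held-out classification metrics (LC positive, threshold on P(LC))."""

    sensitivity: float
    specificity: float
    accuracy: float
    auc: float
    roc_points: list[tuple[float, float]]
    threshold: float = 0.5
    positive_class: str = POSITIVE_LABEL
    n_positive: int = 0
    n_negative: int = 0

    def to_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "auc": self.auc,
            "roc_points": [list(p) for p in self.roc_points],
            "threshold": self.threshold,
            "positive_class": self.positive_class,
            "n_positive": self.n_positive,
            "n_negative": self.n_negative,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MetricsReport":
        return cls(
            sensitivity=d["sensitivity"], specificity=d["specificity"],
            accuracy=d["accuracy"], auc=d["auc"],
            roc_points=[tuple(p) for p in d["roc_points"]],
            threshold=d["threshold"], positive_class=d["positive_class"],
            n_positive=d["n_positive"], n_negative=d["n_negative"],
        )


def roc_curve_points(y: np.ndarray, scores: np.ndarray):
    """ROC over all unique score cutoffs; (0,0) first, (1,1) last.

    Tied scores collapse into a single operating point, so the trapezoid
    area counts tied positive/negative pairs one half each (the
    Mann-Whitney tie convention).
    """
    y = np.asarray(y)
    scores = np.asarray(scores, dtype=float)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        missing = POSITIVE_LABEL if n_pos == 0 else "LM"
        raise ValueError(f"ROC/AUC undefined: no {missing} cases in the test set")
    order = np.argsort(-scores, kind="stable")
    y_sorted = scores_sorted = None
    y_sorted, scores_sorted = y[order], scores[order]
    points = [(0.0, 0.0)]
    tp = fp = 0
    i = 0
    while i < len(y_sorted):
        j = i
        while j < len(y_sorted) and scores_sorted[j] == scores_sorted[i]:
            tp += int(y_sorted[j] == 1)
            fp += int(y_sorted[j] == 0)
            j += 1
        points.append((fp / n_neg, tp / n_pos))
        i = j
    return points


def auc_trapezoid(points) -> float:
    xs = np.array([p[0] for p in points])
    ys = np.array([p[1] for p in points])
    return float(np.trapezoid(ys, xs))


def evaluate(
    model: SvmModel, test: FeatureTable, threshold: float = 0.5
) -> MetricsReport:
    """Score a fitted model on a labelled held-out table."""
    missing = [f for f in model.features if f not in test.feature_columns]
    if missing:
        raise ValueError(f"test table lacks model features: {missing}")
    y = test.binary_labels()
    prob = model.predict_proba(test.features(model.features))
    return metrics_from_scores(y, prob, threshold)


def metrics_from_scores(
    y: np.ndarray, prob: np.ndarray, threshold: float = 0.5
) -> MetricsReport:
    y = np.asarray(y)
    n_pos, n_neg = int((y == 1).sum()), int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        missing = POSITIVE_LABEL if n_pos == 0 else "LM"
        raise ValueError(f"metrics undefined: no {missing} cases in the test set")
    pred = (prob >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    points = roc_curve_points(y, prob)
    return MetricsReport(
        sensitivity=tp / n_pos,
        specificity=tn / n_neg,
        accuracy=(tp + tn) / len(y),
        auc=auc_trapezoid(points),
        roc_points=points,
        threshold=threshold,
        n_positive=n_pos,
        n_negative=n_neg,
    )


def compare_models(
    intra_model: SvmModel, combined_model: SvmModel, test: FeatureTable,
    threshold: float = 0.5,
) -> dict[str, MetricsReport]:
    """Side-by-side evaluation of the intranodular and combined models."""
    return {
        "intranodular": evaluate(intra_model, test, threshold),
        "combined": evaluate(combined_model, test, threshold),
    }
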