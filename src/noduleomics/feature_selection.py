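"""Two-step feature selection: FDR ranking, then LASSO stability selection.

Step 1 scores every feature with the Fisher Discriminant Ratio

    FDR = (m1 - m2)^2 / (s1^2 + s2^2)

(class means m, sample variances s^2) and keeps the top 30 % (ceil) by
descending score.  Step 2 repeatedly (default 100 times) splits the
training table into a 70 % LASSO-training and 30 % LASSO-validation part
(stratified by class), fits an L1-penalised logistic regression over a
log-spaced penalty grid, picks the penalty with the best validation
accuracy, and credits the top 10 features by absolute coefficient.
Features credited more than 60 times out of 100 form the final set.

The held-out test split must never reach this module: callers pass the
training table only.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression

from .volume_io import FeatureTable, POSITIVE_LABEL

logger = logging.getLogger("noduleomics.selection")

#: ranking sentinel for separable features with zero within-class variance
INF_FDR = float("inf")


# ---------------------------------------------------------------------------
# Step 1 - Fisher Discriminant Ratio
# ---------------------------------------------------------------------------

@dataclass
class FdrScore:
    feature: str
    m1: float
    m2: float
    s1_sq: float
    s2_sq: float
    fdr: float


def fisher_discriminant_ratio(x1, x2) -> float:
    """(mean(x1) - mean(x2))^2 / (var(x1) + var(x2)), n-1 variances.

    Zero denominator: returns 0 when the means agree (no information) and
    +inf when they differ (perfect separation; ranked above all finite
    scores, logged).
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if len(x1) < 2 or len(x2) < 2:
        raise ValueError("each class needs at least 2 values")
    num = (x1.mean() - x2.mean()) ** 2
    den = x1.var(ddof=1) + x2.var(ddof=1)
    if den == 0:
        if num == 0:
            return 0.0
        logger.warning("zero within-class variance with unequal means; FDR -> inf")
        return INF_FDR
    return float(num / den)


def fdr_scores(table: FeatureTable) -> list[FdrScore]:
    y = table.binary_labels()
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise ValueError("each class needs at least 2 cases")
    x = table.features()
    out = []
    for col, name in enumerate(table.feature_columns):
        x1, x2 = x[y == 1, col], x[y == 0, col]
        out.append(
            FdrScore(
                feature=name,
                m1=float(x1.mean()),
                m2=float(x2.mean()),
                s1_sq=float(x1.var(ddof=1)),
                s2_sq=float(x2.var(ddof=1)),
                fdr=fisher_discriminant_ratio(x1, x2),
            )
        )
    return out


def fdr_rank_and_cut(
    table: FeatureTable, fraction: float = 0.30
) -> tuple[list[str], list[FdrScore]]:
    """Rank features by descending FDR and keep the top ``fraction``.

    The pool size is ``ceil(fraction * n_features)``; ties are broken by
    feature name so the cut is deterministic.

    Returns (pool, scores-in-ranked-order).
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must lie in (0, 1]")
    scores = fdr_scores(table)
    ranked = sorted(scores, key=lambda s: (-s.fdr, s.feature))
    keep = math.ceil(fraction * len(ranked))
    return [s.feature for s in ranked[:keep]], ranked


# ---------------------------------------------------------------------------
# Step 2 - repeated-LASSO stability selection
# ---------------------------------------------------------------------------

@dataclass
class SelectionResult:
    """Outcome of the two-step selection.

    ``selection_counts`` maps every pooled feature to the number of
    repetitions (0..reps) in which it ranked among the top-k absolute
    LASSO coefficients; ``final_features`` are those with count strictly
    above the threshold.
    """

    ranked_features: list[str]
    fdr_pool: list[str]
    selection_counts: dict[str, int]
    final_features: list[str]
    reps: int
    threshold: int
    rep_seeds: list[int] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "ranked_features": self.ranked_features,
            "fdr_pool": self.fdr_pool,
            "selection_counts": self.selection_counts,
            "final_features": self.final_features,
            "reps": self.reps,
            "threshold": self.threshold,
            "rep_seeds": self.rep_seeds,
        }


def stratified_split_indices(y: np.ndarray, train_frac: float, rng: np.random.Generator):
    """Deterministic stratified train/validation index split."""
    train_idx, val_idx = [], []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        idx = idx[rng.permutation(len(idx))]
        n_train = int(round(train_frac * len(idx)))
        n_train = min(max(n_train, 1), len(idx) - 1)
        train_idx.extend(idx[:n_train])
        val_idx.extend(idx[n_train:])
    return np.sort(train_idx), np.sort(val_idx)


def _lasso_penalty_grid(x_std: np.ndarray, y: np.ndarray, n_values: int = 50,
                        decades: float = 4.0) -> np.ndarray:
    """Log-spaced L1 penalties from the all-zero solution downward.

    For standardized features the smallest penalty nulling every logistic
    coefficient is ``max |X^T (y - ybar)| / n``.
    """
    resid = y - y.mean()
    alpha_max = np.abs(x_std.T @ resid).max() / len(y)
    alpha_max = max(alpha_max, 1e-12)
    return alpha_max * np.logspace(0.0, -decades, n_values)


def _fit_one_repetition(
    x: np.ndarray,
    y: np.ndarray,
    names: list[str],
    tr: np.ndarray,
    va: np.ndarray,
    top_k: int,
    link: str,
) -> list[str]:
    """One stability repetition; returns the credited feature names."""
    mu = x[tr].mean(axis=0)
    sd = x[tr].std(axis=0, ddof=0)
    sd[sd == 0] = 1.0  # constant-in-split features carry no signal
    x_tr = (x[tr] - mu) / sd
    x_va = (x[va] - mu) / sd
    y_tr, y_va = y[tr], y[va]
    alphas = _lasso_penalty_grid(x_tr, y_tr)
    best_acc, best_coef = -1.0, None
    for alpha in alphas:  # strongest penalty first; ties keep the sparser fit
        if link == "logistic":
            model = LogisticRegression(
                l1_ratio=1.0, C=1.0 / (len(y_tr) * alpha), solver="liblinear",
                max_iter=1000, random_state=0,
            )
            model.fit(x_tr, y_tr)
            pred = model.predict(x_va)
            coef = model.coef_.ravel()
        else:  # linear regression on +/-1 labels, thresholded at 0
            model = _l1_linear(x_tr, 2.0 * y_tr - 1.0, alpha)
            pred = (x_va @ model >= 0).astype(int)
            coef = model
        acc = float((pred == y_va).mean())
        if acc > best_acc:
            best_acc, best_coef = acc, coef
    nonzero = np.flatnonzero(np.abs(best_coef) > 1e-12)
    if len(nonzero) < top_k:
        logger.debug("only %d nonzero coefficients this repetition", len(nonzero))
    order = sorted(nonzero, key=lambda i: (-abs(best_coef[i]), names[i]))
    return [names[i] for i in order[:top_k]]


def _l1_linear(x: np.ndarray, y: np.ndarray, alpha: float, n_iter: int = 250) -> np.ndarray:
    """Coordinate-descent lasso for the optional linear-link variant."""
    n, p = x.shape
    w = np.zeros(p)
    col_sq = (x**2).sum(axis=0) / n
    for _ in range(n_iter):
        w_old = w.copy()
        for j in range(p):
            r = y - x @ w + x[:, j] * w[j]
            rho = x[:, j] @ r / n
            w[j] = np.sign(rho) * max(abs(rho) - alpha, 0.0) / max(col_sq[j], 1e-12)
        if np.abs(w - w_old).max() < 1e-8:
            break
    return w


def lasso_stability(
    table: FeatureTable,
    pool: list[str] | None = None,
    reps: int = 100,
    train_frac: float = 0.70,
    top_k: int = 10,
    threshold: int = 60,
    seed: int = 0,
    link: str = "logistic",
    fraction: float = 0.30,
    rerank_per_split: bool = False,
) -> SelectionResult:
    """Repeated-LASSO stability selection over the FDR pool.

    If ``pool`` is None it is computed once globally from ``table`` by
    :func:`fdr_rank_and_cut`; ``rerank_per_split=True`` instead re-ranks
    the FDR within each repetition's 70 % training part.
    """
    ranked_pool, ranked = fdr_rank_and_cut(table, fraction)
    if pool is None:
        pool = ranked_pool
    missing = [f for f in pool if f not in table.feature_columns]
    if missing:
        raise ValueError(f"pool features absent from table: {missing}")
    y = table.binary_labels()
    rng = np.random.default_rng(seed)
    rep_seeds = [int(s) for s in rng.integers(0, 2**31 - 1, size=reps)]
    counts: dict[str, int] = {f: 0 for f in pool}
    for rep_seed in rep_seeds:
        rep_rng = np.random.default_rng(rep_seed)
        tr, va = stratified_split_indices(y, train_frac, rep_rng)
        rep_pool = pool
        if rerank_per_split:
            in_train = np.isin(np.arange(len(y)), tr)
            rep_pool, _ = fdr_rank_and_cut(table.subset(in_train), fraction)
            for f in rep_pool:
                counts.setdefault(f, 0)
        x = table.features(rep_pool)
        credited = _fit_one_repetition(x, y, rep_pool, tr, va, top_k, link)
        for f in credited:
            counts[f] += 1
    final = sorted([f for f, c in counts.items() if c > threshold])
    return SelectionResult(
        ranked_features=[s.feature for s in ranked],
        fdr_pool=list(pool),
        selection_counts=counts,
        final_features=final,
        reps=reps,
        threshold=threshold,
        rep_seeds=rep_seeds,
    )
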