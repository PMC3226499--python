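"""Stepwise linear discriminant toxicity signatures.

Species-specific toxicity signatures are built as two-class Fisher
linear discriminants over in vitro assay scores and pathway
perturbation scores, with forward stepwise feature selection driven by
cross-validated balanced accuracy (BA, the mean of sensitivity and
specificity).  Model statistics follow the reporting conventions of HTS
signature tables: train/test BA, best sensitivity and specificity at
the Youden-optimal operating point, and the Mann–Whitney AUC of the
pooled held-out discriminant scores.

The discriminant direction is ``w = S_pooled⁻¹ (μ₁ − μ₀)`` with a small
ridge on the pooled covariance diagonal; the intercept places the
decision boundary at the midpoint of the projected class means (equal
priors).  Everything is deterministic given the fold seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

DEFAULT_RIDGE = 1e-6


# ---------------------------------------------------------------------------
# elementary statistics


def balanced_accuracy(tp: int, fp: int, tn: int, fn: int) -> float:
    """Mean of sensitivity and specificity from confusion counts."""
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("confusion counts must be nonnegative")
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("both classes must be present")
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    return (sens + spec) / 2.0


def auc(scores: Sequence[float], y: Sequence[int]) -> float:
    """Area under the ROC curve as the Mann–Whitney rank statistic.

    Equals the probability that a random positive scores above a random
    negative, with ties credited 0.5.
    """
    s = np.asarray(scores, dtype=float)
    labels = np.asarray(y, dtype=int)
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(s)  # average ranks handle ties
    r1 = ranks[labels == 1].sum()
    return float((r1 - n1 * (n1 + 1) / 2.0) / (n1 * n0))


# ---------------------------------------------------------------------------
# LDA core


def lda_fit(
    X: np.ndarray | pd.DataFrame,
    y: Sequence[int],
    ridge: float = DEFAULT_RIDGE,
) -> tuple[np.ndarray, float]:
    """Fit a two-class Fisher discriminant.

    Returns ``(w, b)`` with ``w = S_pooled⁻¹ (μ₁ − μ₀)`` (ridge ε added
    to the pooled-covariance diagonal) and ``b`` the negated midpoint of
    the projected class means, so the decision rule is
    ``w·x + b ≥ 0 → class 1``.  Rejects subsets whose pooled covariance
    stays singular after the ridge.
    """
    Xa = np.asarray(X, dtype=float)
    if Xa.ndim == 1:
        Xa = Xa[:, None]
    labels = np.asarray(y, dtype=int)
    n, p = Xa.shape
    if labels.shape != (n,):
        raise ValueError("X and y lengths differ")
    classes = np.unique(labels)
    if not np.array_equal(classes, [0, 1]):
        raise ValueError("y must contain both classes, coded 0/1")
    if n <= p + 1:
        raise ValueError(f"need n > n_features + 1 (n={n}, p={p})")
    X0, X1 = Xa[labels == 0], Xa[labels == 1]
    mu0, mu1 = X0.mean(axis=0), X1.mean(axis=0)
    pooled = np.zeros((p, p))
    dof = 0
    for Xk in (X0, X1):
        if len(Xk) >= 2:
            pooled += np.cov(Xk, rowvar=False, ddof=1) * (len(Xk) - 1)
            dof += len(Xk) - 1
    pooled = pooled / max(dof, 1) + ridge * np.eye(p)
    try:
        w = np.linalg.solve(pooled, mu1 - mu0)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"singular pooled covariance after ridge: {exc}") from exc
    if not np.all(np.isfinite(w)):
        raise ValueError("singular pooled covariance after ridge")
    b = -float(w @ (mu0 + mu1) / 2.0)
    return w, b


def lda_scores(X: np.ndarray, w: np.ndarray, b: float) -> np.ndarray:
    """Discriminant scores ``w·x + b`` (≥ 0 predicts class 1)."""
    Xa = np.asarray(X, dtype=float)
    if Xa.ndim == 1:
        Xa = Xa[:, None]
    return Xa @ np.asarray(w, dtype=float) + b


def _ba_from_predictions(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    tp = int(((y_true == 1) & (y_pred == 1)).sum())
    tn = int(((y_true == 0) & (y_pred == 0)).sum())
    fp = int(((y_true == 0) & (y_pred == 1)).sum())
    fn = int(((y_true == 1) & (y_pred == 0)).sum())
    return balanced_accuracy(tp, fp, tn, fn)


def youden_operating_point(
    scores: np.ndarray, y: np.ndarray
) -> tuple[float, float, float]:
    """(sensitivity, specificity, threshold) maximizing Youden's J.

    Candidate thresholds are the observed scores; prediction is
    ``score ≥ threshold``.  Ties on J resolve to the lowest threshold.
    """
    s = np.asarray(scores, dtype=float)
    labels = np.asarray(y, dtype=int)
    best = (-np.inf, 0.0, 0.0, 0.0)
    for thr in np.unique(s):
        pred = (s >= thr).astype(int)
        sens = float(((labels == 1) & (pred == 1)).sum() / (labels == 1).sum())
        spec = float(((labels == 0) & (pred == 0)).sum() / (labels == 0).sum())
        j = sens + spec - 1.0
        if j > best[0]:
            best = (j, sens, spec, float(thr))
    return best[1], best[2], best[3]


# ---------------------------------------------------------------------------
# cross-validation machinery


def stratified_folds(
    y: Sequence[int], folds: int, seed: int
) -> list[np.ndarray]:
    """Deterministic stratified fold assignment.

    Within each class, sample indices are shuffled by a
    ``numpy.random.default_rng(seed)`` stream and dealt round-robin into
    folds, so every fold holds both classes whenever each class has at
    least ``folds`` members.
    """
    labels = np.asarray(y, dtype=int)
    rng = np.random.default_rng(seed)
    assignment = np.empty(len(labels), dtype=int)
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        assignment[idx] = np.arange(len(idx)) % folds
    return [np.flatnonzero(assignment == f) for f in range(folds)]


@dataclass
class CVStats:
    """Cross-validated model statistics."""

    ba_train: float
    ba_test: float
    sensitivity: float
    specificity: float
    auc: float

    def as_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


@dataclass
class SignatureModel:
    """A fitted stepwise-LDA signature.

    ``features`` lists selected feature ids in inclusion order;
    ``coefficients``/``intercept`` come from the final fit on all
    samples; ``cv_stats`` re-evaluates that feature set on the fold
    partition used during selection.
    """

    features: list[str]
    coefficients: list[float]
    intercept: float
    cv_stats: CVStats
    folds: int
    seed: int
    selection_path: list[tuple[str, float]] = field(default_factory=list)

    def decision_scores(self, X: pd.DataFrame) -> np.ndarray:
        return lda_scores(
            X[self.features].to_numpy(), np.asarray(self.coefficients),
            self.intercept,
        )

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return (self.decision_scores(X) >= 0).astype(int)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "features": self.features,
            "coefficients": self.coefficients,
            "intercept": self.intercept,
            "cv_stats": self.cv_stats.as_dict(),
            "folds": self.folds,
            "seed": self.seed,
            "selection_path": [
                {"feature": f, "cv_ba": ba} for f, ba in self.selection_path
            ],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def _cv_ba(
    X: np.ndarray,
    y: np.ndarray,
    fold_idx: list[np.ndarray],
    ridge: float,
) -> float | None:
    """Mean held-out BA over folds; None if any fold fit is rejected."""
    bas = []
    all_idx = np.arange(len(y))
    for held in fold_idx:
        train = np.setdiff1d(all_idx, held, assume_unique=False)
        if len(np.unique(y[train])) < 2 or len(np.unique(y[held])) < 2:
            return None
        try:
            w, b = lda_fit(X[train], y[train], ridge=ridge)
        except ValueError:
            return None
        pred = (lda_scores(X[held], w, b) >= 0).astype(int)
        bas.append(_ba_from_predictions(y[held], pred))
    return float(np.mean(bas))


def evaluate_features(
    X: pd.DataFrame,
    y: Sequence[int],
    features: Sequence[str],
    folds: int = 5,
    seed: int = 0,
    ridge: float = DEFAULT_RIDGE,
    fold_idx: list[np.ndarray] | None = None,
) -> CVStats:
    """Cross-validate a fixed feature set.

    Train BA averages in-fold training accuracy; test BA scores pooled
    held-out midpoint-threshold predictions; best sensitivity and
    specificity are read at the Youden-optimal point of the pooled
    held-out scores, on which the AUC is also computed.
    """
    labels = np.asarray(y, dtype=int)
    Xa = X[list(features)].to_numpy(dtype=float)
    if fold_idx is None:
        fold_idx = stratified_folds(labels, folds, seed)
    all_idx = np.arange(len(labels))
    train_bas = []
    pooled_scores = np.empty(len(labels))
    for held in fold_idx:
        train = np.setdiff1d(all_idx, held)
        w, b = lda_fit(Xa[train], labels[train], ridge=ridge)
        train_pred = (lda_scores(Xa[train], w, b) >= 0).astype(int)
        train_bas.append(_ba_from_predictions(labels[train], train_pred))
        pooled_scores[held] = lda_scores(Xa[held], w, b)
    test_pred = (pooled_scores >= 0).astype(int)
    ba_test = _ba_from_predictions(labels, test_pred)
    sens, spec, _ = youden_operating_point(pooled_scores, labels)
    return CVStats(
        ba_train=float(np.mean(train_bas)),
        ba_test=ba_test,
        sensitivity=sens,
        specificity=spec,
        auc=auc(pooled_scores, labels),
    )


def stepwise_select(
    X: pd.DataFrame,
    y: Sequence[int],
    folds: int = 5,
    seed: int = 0,
    max_features: int = 10,
    epsilon: float = 1e-6,
    ridge: float = DEFAULT_RIDGE,
) -> SignatureModel:
    """Forward stepwise LDA driven by cross-validated balanced accuracy.

    At each step the feature whose addition maximizes mean held-out BA
    over the stratified folds is included; ties break to the lowest
    column index; selection stops when the improvement over the current
    BA is ≤ ``epsilon`` or ``max_features`` is reached.  The final
    feature set is re-evaluated on the same fold partition and refit on
    all samples for the reported coefficients.  Fully deterministic
    given ``seed``.
    """
    labels = np.asarray(y, dtype=int)
    if not np.array_equal(np.unique(labels), [0, 1]):
        raise ValueError("y must contain both classes, coded 0/1")
    counts = np.bincount(labels, minlength=2)
    if counts.min() < folds:
        raise ValueError(
            f"each class needs ≥ {folds} samples (got {counts.tolist()})"
        )
    feature_names = list(X.columns)
    Xa = X.to_numpy(dtype=float)
    if not np.all(np.isfinite(Xa)):
        raise ValueError("feature matrix contains non-finite values")
    fold_idx = stratified_folds(labels, folds, seed)

    selected: list[int] = []
    path: list[tuple[str, float]] = []
    current_ba = 0.0
    while len(selected) < max_features:
        best_ba, best_j = -np.inf, None
        for j in range(len(feature_names)):
            if j in selected:
                continue
            trial = Xa[:, selected + [j]]
            ba = _cv_ba(trial, labels, fold_idx, ridge)
            if ba is None:
                continue  # subset rejected (singular / degenerate fold)
            if ba > best_ba:
                best_ba, best_j = ba, j
        if best_j is None or best_ba - current_ba <= epsilon:
            break
        selected.append(best_j)
        path.append((feature_names[best_j], best_ba))
        current_ba = best_ba
    if not selected:
        raise ValueError("no admissible feature improved cross-validated BA")

    names = [feature_names[j] for j in selected]
    stats = evaluate_features(
        X, labels, names, folds=folds, seed=seed, ridge=ridge, fold_idx=fold_idx
    )
    w, b = lda_fit(Xa[:, selected], labels, ridge=ridge)
    return SignatureModel(
        features=names,
        coefficients=[float(v) for v in w],
        intercept=float(b),
        cv_stats=stats,
        folds=folds,
        seed=seed,
        selection_path=path,
    )


@dataclass
class StabilityReport:
    """Dispersion of signature statistics under repetition."""

    fixed_seed_identical: bool
    fixed_seed_ba_range: float
    across_seed_bas: list[float]
    ba_std: float


def stability_check(
    X: pd.DataFrame,
    y: Sequence[int],
    repeats: int = 20,
    seed: int = 0,
    folds: int = 5,
    max_features: int = 10,
) -> StabilityReport:
    """Probe determinism and seed-sensitivity of the stepwise signature.

    With the seed held fixed, repeated runs must reproduce bit-identical
    cv_stats; across ``repeats`` distinct seeds, the standard deviation
    of the test BA measures fold-partition sensitivity.
    """
    if repeats < 2:
        raise ValueError("repeats must be ≥ 2")
    fixed = [
        stepwise_select(X, y, folds=folds, seed=seed, max_features=max_features)
        for _ in range(repeats)
    ]
    ref = fixed[0].cv_stats.as_dict()
    identical = all(m.cv_stats.as_dict() == ref for m in fixed)
    fixed_bas = [m.cv_stats.ba_test for m in fixed]
    across = []
    for k in range(repeats):
        m = stepwise_select(
            X, y, folds=folds, seed=seed + k, max_features=max_features
        )
        across.append(m.cv_stats.ba_test)
    return StabilityReport(
        fixed_seed_identical=identical,
        fixed_seed_ba_range=float(max(fixed_bas) - min(fixed_bas)),
        across_seed_bas=across,
        ba_std=float(np.std(across)),
    )
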