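"""Rhythm classification on selected state variables.

The classifier is a plain unregularized logistic regression (maximum
likelihood, IRLS/Newton, no penalty).  Features are standardized internally
with train-set statistics — the high-order derivative features span several
orders of magnitude — and the fitted weights are reported back on the
original feature scale, so standardization is numerically helpful but
mathematically neutral.

Also provided: the seeded stratified 80/20 evaluation, the observation-time
sweep (truncate → re-extract features → re-evaluate), and the two classical
variable-selection baselines (Fisher discriminant axis and PCA components).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.decomposition import PCA
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split

from .errors import InsufficientData, StratificationError
from .features import FeatureMatrix, FeatureName, extract_feature_table
from .rr_timeseries import BeatSequence, truncate_to_duration

__all__ = [
    "LinearModel",
    "EvaluationReport",
    "train_logistic",
    "predict",
    "evaluate_split",
    "duration_sweep",
    "fisher_axis",
    "pca_components",
]


@dataclass(frozen=True)
class LinearModel:
    """w·x + b > 0 ⇒ positive class (classes_[1]); weights on original scale."""

    weights: np.ndarray
    intercept: float
    subset: tuple  # FeatureName ordering of the weights
    classes_: tuple  # (negative_label, positive_label), sorted
    converged: bool = True
    iterations: int = 0


@dataclass(frozen=True)
class EvaluationReport:
    accuracy: float
    seed: int
    n_train: int
    n_val: int
    subset: tuple
    split: tuple = (0.8, 0.2)
    converged: bool = True


def _design(features: FeatureMatrix, subset: Sequence[FeatureName]):
    X = features.values(list(subset))
    y = features.labels
    classes = tuple(sorted(set(y)))
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {classes}")
    return X, y, classes


def _fit(X: np.ndarray, y01: np.ndarray, subset, classes) -> LinearModel:
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    Xs = (X - mu) / sd
    clf = LogisticRegression(
        penalty=None, solver="newton-cholesky", tol=1e-8, max_iter=100
    )
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        clf.fit(Xs, y01)
        if any(issubclass(w.category, ConvergenceWarning) for w in caught):
            converged = False
    # a perfectly separated training set has no finite ML optimum: the fit
    # walks toward infinity and stops only on tolerance/iteration caps.
    # Saturated margins with zero training error diagnose that state even
    # when the gradient-norm test formally "converged".
    eta = Xs @ clf.coef_.ravel() + clf.intercept_[0]
    if np.all((eta > 0) == (y01 == 1)) and np.min(np.abs(eta)) > 10:
        converged = False
    if not converged:
        warnings.warn(
            "logistic likelihood is unbounded (perfect separation) or the "
            "fit hit its iteration cap; capped estimates returned",
            RuntimeWarning,
            stacklevel=3,
        )
    w_std = clf.coef_.ravel()
    w = w_std / sd
    b = float(clf.intercept_[0] - np.sum(w_std * mu / sd))
    return LinearModel(
        weights=w,
        intercept=b,
        subset=tuple(subset),
        classes_=classes,
        converged=converged,
        iterations=int(np.max(clf.n_iter_)),
    )


def train_logistic(
    features: FeatureMatrix, subset: Sequence[FeatureName], labels=None
) -> LinearModel:
    """Unregularized maximum-likelihood logistic fit on the chosen subset."""
    X, y, classes = _design(features, subset)
    if labels is not None:
        y = np.asarray(labels)
    if not np.all(np.isfinite(X)):
        raise ValueError("missing/non-finite feature values")
    y01 = (y == classes[1]).astype(int)
    return _fit(X, y01, subset, classes)


def predict(model: LinearModel, X: np.ndarray) -> np.ndarray:
    """Class labels for rows of X (columns ordered as model.subset)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    score = X @ model.weights + model.intercept
    return np.where(score > 0, model.classes_[1], model.classes_[0])


def evaluate_split(
    features: FeatureMatrix,
    subset: Sequence[FeatureName],
    seed: int = 0,
    test_size: float = 0.2,
) -> EvaluationReport:
    """Seeded stratified 80/20 split; accuracy on the validation part."""
    X, y, classes = _design(features, subset)
    counts = {c: int(np.sum(y == c)) for c in classes}
    if min(counts.values()) < 5:
        raise InsufficientData(f"need >= 5 samples per class, got {counts}")
    X_tr, X_val, y_tr, y_val = train_test_split(
        X, y, test_size=test_size, random_state=seed, stratify=y
    )
    if len(set(y_tr)) < 2 or len(set(y_val)) < 2:
        raise StratificationError("a class is absent from one side of the split")
    model = _fit(X_tr, (y_tr == classes[1]).astype(int), subset, classes)
    acc = float(np.mean(predict(model, X_val) == y_val))
    return EvaluationReport(
        accuracy=acc,
        seed=seed,
        n_train=len(y_tr),
        n_val=len(y_val),
        subset=tuple(subset),
        split=(1 - test_size, test_size),
        converged=model.converged,
    )


def duration_sweep(
    dataset: Sequence[BeatSequence],
    durations: Sequence[float],
    subsets: Sequence[Sequence[FeatureName]],
    seed: int = 0,
) -> dict:
    """Accuracy for every duration × subset cell.

    Each cell truncates every series to the window, re-extracts the features
    the subset needs, and re-evaluates.  Series too short to support the
    subset's top derivative order at that duration are excluded from that
    cell (recorded under ``n_used``); a cell whose surviving groups are too
    small carries an ``error`` note instead of an accuracy.
    """
    results = {}
    for duration in durations:
        for subset in subsets:
            subset = tuple(subset)
            key = (float(duration), subset)
            max_order = max(f.order for f in subset)
            usable = []
            for beats in dataset:
                try:
                    usable.append(truncate_to_duration(beats, duration))
                except InsufficientData:
                    continue
            usable = [b for b in usable if len(b) >= max_order + 3]
            cell = {"n_used": len(usable), "n_total": len(dataset)}
            try:
                if not usable:
                    raise InsufficientData("no evaluable series in this window")
                table = extract_feature_table(usable, max_order=max_order)
                report = evaluate_split(table, subset, seed=seed)
                cell["accuracy"] = report.accuracy
                cell["converged"] = report.converged
            except (InsufficientData, StratificationError, ValueError) as exc:
                cell["accuracy"] = float("nan")
                cell["error"] = str(exc)
            results[key] = cell
    return results


def fisher_axis(features: FeatureMatrix, subset: Sequence[FeatureName] | None = None) -> np.ndarray:
    """Fisher/multiple-discriminant axis: w ∝ S_pooled⁻¹ (μ2 − μ1), unit norm.

    The projection X·w is a 1-D classifier input.  A singular pooled
    covariance is ridge-stabilized with a warning.
    """
    subset = tuple(subset) if subset is not None else tuple(features.feature_names)
    X, y, classes = _design(features, subset)
    X1, X2 = X[y == classes[0]], X[y == classes[1]]
    n1, n2 = len(X1), len(X2)
    if min(n1, n2) < 2:
        raise InsufficientData("each class needs >= 2 samples")
    S1 = np.cov(X1, rowvar=False, ddof=1)
    S2 = np.cov(X2, rowvar=False, ddof=1)
    S = np.atleast_2d(((n1 - 1) * S1 + (n2 - 1) * S2) / (n1 + n2 - 2))
    delta = X2.mean(axis=0) - X1.mean(axis=0)
    try:
        w = np.linalg.solve(S, delta)
    except np.linalg.LinAlgError:
        warnings.warn("singular pooled covariance; ridge applied", RuntimeWarning)
        ridge = 1e-10 * max(float(np.mean(np.diag(S))), 1.0)
        w = np.linalg.solve(S + ridge * np.eye(S.shape[0]), delta)
    norm = np.linalg.norm(w)
    if norm == 0:
        raise InsufficientData("identical class means: no discriminant axis")
    return w / norm


def pca_components(features: FeatureMatrix, n_components: int):
    """Label-blind PCA of the pooled feature matrix.

    Returns (components, explained_variance_ratio, projections); components
    are rows, in descending explained-variance order.
    """
    X = features.values()
    if n_components > X.shape[1]:
        raise ValueError("more components than features")
    pca = PCA(n_components=n_components)
    proj = pca.fit_transform(X)
    return pca.components_, pca.explained_variance_ratio_, proj
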