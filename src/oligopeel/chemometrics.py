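"""PCA, PLS regression classification, cross-validation and VIP scores.

Class labels are encoded numerically (first class 1.0, second class 2.0) and
a single-response PLS regression is fitted; a prediction below 1.5 is read as
the first class, at or above 1.5 as the second.  Variable importance in
projection (VIP) summarises each variable's contribution across the latent
components and is normalized so that the squared scores sum to the number of
variables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import StratifiedKFold

CLASSIFICATION_CUTOFF = 1.5


@dataclass
class PCAResult:
    scores: np.ndarray  # n_samples x n_components
    loadings: np.ndarray  # n_variables x n_components
    explained_variance_ratio: np.ndarray
    mean: np.ndarray
    scale: np.ndarray | None


def pca(
    X: np.ndarray,
    n_components: int | None = None,
    uv_scale: bool = False,
) -> PCAResult:
    """Principal component analysis on centred (optionally UV-scaled) data.

    Sign convention: each loading vector's largest-magnitude element is
    positive, so scores plots are deterministic.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n < 2:
        raise ValueError("PCA needs at least 2 samples")
    mean = X.mean(axis=0)
    Xc = X - mean
    scale = None
    if uv_scale:
        scale = Xc.std(axis=0, ddof=1)
        scale[scale == 0] = 1.0
        Xc = Xc / scale
    rank = np.linalg.matrix_rank(Xc)
    if n_components is None:
        n_components = rank
    elif n_components > rank:
        warnings.warn(f"requested {n_components} components but rank is {rank}; truncating")
        n_components = rank
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    total_var = float((s**2).sum())
    loadings = Vt[:n_components].T
    scores = U[:, :n_components] * s[:n_components]
    # deterministic sign: largest |element| of each loading positive
    for a in range(n_components):
        j = int(np.argmax(np.abs(loadings[:, a])))
        if loadings[j, a] < 0:
            loadings[:, a] *= -1
            scores[:, a] *= -1
    evr = (s[:n_components] ** 2) / total_var if total_var > 0 else np.zeros(n_components)
    return PCAResult(scores, loadings, evr, mean, scale)


@dataclass
class PLSModel:
    """A fitted single-response PLS regression with class encoding."""

    estimator: PLSRegression
    n_components: int
    classes: tuple  # (label encoded 1.0, label encoded 2.0)
    encoding: dict
    cutoff: float = CLASSIFICATION_CUTOFF

    @property
    def x_weights(self) -> np.ndarray:
        return self.estimator.x_weights_

    @property
    def x_scores(self) -> np.ndarray:
        return self.estimator.x_scores_

    @property
    def y_loadings(self) -> np.ndarray:
        return self.estimator.y_loadings_

    @property
    def coef(self) -> np.ndarray:
        return self.estimator.coef_

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(self.estimator.predict(np.asarray(X, dtype=float))).ravel()


def encode_labels(y) -> tuple[np.ndarray, tuple, dict]:
    """Map two class labels to the numeric responses 1.0 and 2.0."""
    y = np.asarray(y)
    classes = sorted(set(y.tolist()))
    if len(classes) != 2:
        raise ValueError(f"PLS classification needs exactly 2 classes, got {classes}")
    encoding = {classes[0]: 1.0, classes[1]: 2.0}
    encoded = np.array([encoding[v] for v in y], dtype=float)
    return encoded, (classes[0], classes[1]), encoding


def pls_fit(X: np.ndarray, y, n_components: int = 2) -> PLSModel:
    """Fit a PLS1 regression of the encoded class response on X."""
    X = np.asarray(X, dtype=float)
    y_arr = np.asarray(y)
    if y_arr.dtype.kind in "fiu" and set(np.unique(y_arr)) <= {1.0, 2.0}:
        encoded = y_arr.astype(float)
        classes, encoding = (1.0, 2.0), {1.0: 1.0, 2.0: 2.0}
        if len(set(encoded.tolist())) < 2:
            raise ValueError("single-class response: cannot fit a classifier")
    else:
        encoded, classes, encoding = encode_labels(y_arr)
    max_comp = min(X.shape[0] - 1, X.shape[1])
    if n_components > max_comp:
        warnings.warn(f"n_components reduced from {n_components} to {max_comp}")
        n_components = max_comp
    est = PLSRegression(n_components=n_components, scale=False)
    est.fit(X, encoded)
    return PLSModel(est, n_components, classes, encoding)


def classify(model: PLSModel, X: np.ndarray) -> np.ndarray:
    """Class labels from predicted response values.

    Predictions below the 1.5 cutoff give the first class; at or above it,
    the second (the boundary itself is read as the second class).
    """
    pred = model.predict(X)
    lab1, lab2 = model.classes
    return np.where(pred < model.cutoff, lab1, lab2)


def vip(model: PLSModel) -> np.ndarray:
    """Variable importance in projection.

    ``VIP_j = sqrt(p * sum_a SSY_a (w_aj/||w_a||)^2 / sum_a SSY_a)`` where
    ``SSY_a`` is the response variance explained by component ``a``; by
    construction the squared scores sum to the number of variables ``p``.
    """
    W = model.x_weights  # p x a
    T = model.x_scores  # n x a
    Q = model.y_loadings  # 1 x a
    p, n_comp = W.shape
    ssy = (T**2).sum(axis=0) * (Q.ravel() ** 2)
    wnorm2 = (W**2).sum(axis=0)
    wnorm2[wnorm2 == 0] = 1.0
    num = ((W**2) / wnorm2[None, :]) @ ssy
    denom = ssy.sum()
    if denom <= 0:
        return np.ones(p)
    return np.sqrt(p * num / denom)


@dataclass
class ConfusionMatrix:
    """2-way confusion counts with the integer-percent classification rate."""

    counts: np.ndarray  # true x predicted
    labels: tuple

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if np.any(self.counts < 0):
            raise ValueError("negative confusion counts")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def classification_rate(self) -> int:
        """Percent of correct classifications, rounded to the nearest integer."""
        return int(round(100.0 * np.trace(self.counts) / self.total))

    def to_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "counts": self.counts.tolist(),
            "classification_rate": self.classification_rate,
        }


def confusion_from_predictions(y_true, y_pred, labels=None) -> ConfusionMatrix:
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    if labels is None:
        labels = sorted(set(y_true.tolist()) | set(y_pred.tolist()))
    index = {lab: i for i, lab in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=int)
    for t, p in zip(y_true, y_pred):
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts, tuple(labels))


def select_n_components(
    X: np.ndarray,
    y_encoded: np.ndarray,
    max_components: int = 6,
    k: int = 3,
    seed: int = 0,
) -> int:
    """Pick the component count minimising cross-validated RMSEP.

    RMSEP is the root-mean-square error of out-of-fold predictions of the
    encoded response; ties go to the smaller model.
    """
    X = np.asarray(X, dtype=float)
    y_encoded = np.asarray(y_encoded, dtype=float)
    max_components = min(max_components, X.shape[0] - int(np.ceil(X.shape[0] / k)) - 1,
                         X.shape[1])
    max_components = max(max_components, 1)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    rmsep = []
    for a in range(1, max_components + 1):
        sq = 0.0
        for train, test in skf.split(X, y_encoded):
            est = PLSRegression(n_components=min(a, len(train) - 1), scale=False)
            est.fit(X[train], y_encoded[train])
            resid = np.asarray(est.predict(X[test])).ravel() - y_encoded[test]
            sq += float((resid**2).sum())
        rmsep.append(np.sqrt(sq / len(y_encoded)))
    return int(np.argmin(rmsep)) + 1


@dataclass
class CVResult:
    confusion: ConfusionMatrix
    predictions: np.ndarray  # out-of-fold predicted responses
    predicted_labels: np.ndarray
    fold_assignment: np.ndarray
    seed: int


def cross_validate(
    X: np.ndarray,
    y,
    k: int = 3,
    seed: int = 0,
    n_components: int | str = "auto",
) -> CVResult:
    """Stratified k-fold cross-validated PLS classification.

    Folds are drawn from ``seed``; out-of-fold predictions are classified at
    the 1.5 cutoff and accumulated into one confusion matrix.  With
    ``n_components="auto"`` each training fold selects its component count by
    inner cross-validated RMSEP (:func:`select_n_components`).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    encoded, classes, encoding = encode_labels(y)
    counts = {c: int((y == c).sum()) for c in classes}
    too_small = [c for c, n in counts.items() if n < k]
    if too_small:
        raise ValueError(
            f"class(es) {too_small} have fewer than k={k} members; use a smaller k"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    pred_values = np.zeros(len(y))
    fold_assignment = np.zeros(len(y), dtype=int)
    pred_labels = np.empty(len(y), dtype=object)
    for fold, (train, test) in enumerate(skf.split(X, y)):
        if n_components == "auto":
            a = select_n_components(X[train], encoded[train], k=k, seed=seed)
        else:
            a = int(n_components)
        model = pls_fit(X[train], y[train], n_components=a)
        pred_values[test] = model.predict(X[test])
        pred_labels[test] = classify(model, X[test])
        fold_assignment[test] = fold
    confusion = confusion_from_predictions(y, pred_labels, labels=list(classes))
    return CVResult(confusion, pred_values, pred_labels, fold_assignment, seed)


def holdout_evaluate(
    X: np.ndarray,
    y,
    test_fraction: float = 0.3,
    seed: int = 0,
    n_components: int = 2,
) -> ConfusionMatrix:
    """Single stratified held-out split evaluation (alternative to k-fold CV)."""
    from sklearn.model_selection import train_test_split

    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=test_fraction, random_state=seed, stratify=y
    )
    model = pls_fit(X_tr, y_tr, n_components=n_components)
    return confusion_from_predictions(y_te, classify(model, X_te))
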