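"""The three detection back ends: k-NN, ridge-penalized multinomial
logistic regression (MLR), and one-vs-one RBF SVM voting.

k-NN votes among the k nearest training rows by Euclidean distance on
normalized features; MLR models the first K-1 class log-odds against a
reference class and is fitted by a quasi-Newton minimizer of the penalized
negative log-likelihood; the SVM reduces the K-class problem to K(K-1)/2
pairwise binary machines whose votes are summed.

All tie rules are deterministic and documented on each function. Feature
normalization (min-max to [0, 1] fitted on the training rows, test rows
clipped to the [-0.5, 1.5] guard range) is applied inside ``knn_fit_predict``
and ``svm_fit_predict``; for the fit/predict-split MLR the caller normalizes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.spatial.distance import cdist
from scipy.special import logsumexp
from sklearn.svm import SVC

from .errors import ConvergenceWarning, DegeneratePairError, DomainError, ParameterError

MINMAX_CLIP = (-0.5, 1.5)


class Normalizer:
    """Per-feature rescaling fitted on training rows only.

    ``minmax`` maps the training range to [0, 1] and clips transformed rows
    to [-0.5, 1.5] so wild out-of-range test values cannot dominate
    distances; ``zscore`` centers and scales by the training SD; ``none``
    is the identity. Constant features map to 0.
    """

    def __init__(self, method: str = "minmax"):
        if method not in ("minmax", "zscore", "none"):
            raise DomainError(f"unknown normalization method {method!r}")
        self.method = method

    def fit(self, X: np.ndarray) -> "Normalizer":
        X = np.asarray(X, dtype=float)
        if self.method == "minmax":
            self.lo_ = X.min(axis=0)
            span = X.max(axis=0) - self.lo_
            self.span_ = np.where(span > 0, span, 1.0)
        elif self.method == "zscore":
            self.mu_ = X.mean(axis=0)
            sd = X.std(axis=0, ddof=0)
            self.sd_ = np.where(sd > 0, sd, 1.0)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.method == "minmax":
            out = (X - self.lo_) / self.span_
            return np.clip(out, *MINMAX_CLIP)
        if self.method == "zscore":
            return (X - self.mu_) / self.sd_
        return X.copy()

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)


def _as_xy(train_X, train_y, test_X):
    X = np.asarray(train_X, dtype=float)
    y = np.asarray(train_y)
    T = np.asarray(test_X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if T.ndim == 1:
        T = T[:, None]
    if X.shape[0] == 0:
        raise ParameterError("training set is empty")
    if X.shape[0] != y.shape[0]:
        raise ParameterError("train_X and train_y length mismatch")
    if X.shape[1] != T.shape[1]:
        raise ParameterError(
            f"feature dimension mismatch: train {X.shape[1]}, test {T.shape[1]}"
        )
    return X, y, T


# ---------------------------------------------------------------------------
# k-nearest neighbours


def _neighbor_order(dist_row: np.ndarray) -> np.ndarray:
    # distance ties resolved toward the lower training-row index
    return np.lexsort((np.arange(dist_row.size), dist_row))


def _vote(ordered_labels: np.ndarray, k: int, classes: np.ndarray):
    """Majority vote among the first k ordered neighbour labels.

    A vote tie between classes is broken in favour of the tied class whose
    nearest representative comes earliest in the neighbour ordering (for a
    two-way tie this is the single nearest neighbour's label when that label
    is among the tied ones).
    """
    top = ordered_labels[:k]
    counts = np.array([(top == c).sum() for c in classes])
    best = counts.max()
    tied = [c for c, n in zip(classes, counts) if n == best]
    if len(tied) > 1:
        first_pos = {c: int(np.argmax(top == c)) for c in tied}
        label = min(tied, key=lambda c: first_pos[c])
    else:
        label = tied[0]
    return label, counts / k


def knn_fit_predict(
    train_X,
    train_y,
    test_X,
    k: int,
    normalization: str = "minmax",
) -> tuple[np.ndarray, pd.DataFrame]:
    """k-NN labels and per-class neighbour-fraction scores for test rows."""
    X, y, T = _as_xy(train_X, train_y, test_X)
    if k < 1 or k > X.shape[0]:
        raise ParameterError(
            f"k={k} outside the usable range 1..{X.shape[0]}"
        )
    norm = Normalizer(normalization).fit(X)
    Xn, Tn = norm.transform(X), norm.transform(T)
    classes = np.unique(y)
    dists = cdist(Tn, Xn, metric="euclidean")
    labels = np.empty(T.shape[0], dtype=y.dtype)
    scores = np.empty((T.shape[0], classes.size))
    for i in range(T.shape[0]):
        order = _neighbor_order(dists[i])
        labels[i], scores[i] = _vote(y[order], k, classes)
    return labels, pd.DataFrame(scores, columns=list(classes))


def select_k(
    train_X,
    train_y,
    k_max: int,
    folds: int,
    seed: int,
    normalization: str = "minmax",
) -> int:
    """Pick the k in 1..k_max with the lowest cross-validated error rate.

    Stratified folds on the training data; error ties go to the smallest k.
    """
    from .evaluation import stratified_kfold  # local import: avoids a cycle

    X = np.asarray(train_X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(train_y)
    if k_max < 1:
        raise ParameterError("k_max must be >= 1")
    fold_of = stratified_kfold(y, folds, seed)
    min_train = min(
        int((fold_of != f).sum()) for f in range(folds)
    )
    if k_max > min_train:
        raise ParameterError(
            f"k_max={k_max} exceeds the smallest training fold ({min_train})"
        )
    errors = np.zeros(k_max)
    n = len(y)
    classes = np.unique(y)
    for f in range(folds):
        test = fold_of == f
        train = ~test
        if not test.any():
            continue
        norm = Normalizer(normalization).fit(X[train])
        Xn, Tn = norm.transform(X[train]), norm.transform(X[test])
        dists = cdist(Tn, Xn, metric="euclidean")
        ytr = y[train]
        for i in range(Tn.shape[0]):
            ordered = ytr[_neighbor_order(dists[i])]
            truth = y[test][i]
            for k in range(1, k_max + 1):
                label, _ = _vote(ordered, k, classes)
                if label != truth:
                    errors[k - 1] += 1
    return int(np.argmin(errors)) + 1  # argmin returns the smallest tied k


# ---------------------------------------------------------------------------
# multinomial logistic regression with a ridge estimator


@dataclass
class MLRModel:
    """Fitted MLR: coefficients for the first K-1 classes vs the last.

    ``B`` has shape (n_features + 1, K - 1); row 0 is the unpenalized
    intercept. Probabilities follow the softmax with the last class as
    reference: P_j = exp(x B_j) / (1 + sum_l exp(x B_l)) for j < K and the
    remainder for the last class.
    """

    B: np.ndarray
    classes: np.ndarray
    ridge_lambda: float
    converged: bool
    final_grad_norm: float
    loss_trace: list = field(default_factory=list)

    @property
    def n_features(self) -> int:
        return self.B.shape[0] - 1


def _mlr_loss_grad(b_flat, Xa, Y, lam):
    n_cols = Y.shape[1] - 1  # K - 1 free columns
    B = b_flat.reshape(Xa.shape[1], n_cols)
    Z = Xa @ B  # (n, K-1)
    Zfull = np.concatenate([Z, np.zeros((Z.shape[0], 1))], axis=1)
    log_norm = logsumexp(Zfull, axis=1)
    log_p = Zfull - log_norm[:, None]
    loss = -float(np.sum(Y * log_p)) + lam * float(np.sum(B[1:] ** 2))
    P = np.exp(log_p)
    G = Xa.T @ (P[:, :n_cols] - Y[:, :n_cols])
    G[1:] += 2.0 * lam * B[1:]
    return loss, G.ravel()


def mlr_fit(
    X,
    y,
    ridge_lambda: float = 1e-8,
    tolerance: float = 1e-6,
    max_iter: int = 500,
) -> MLRModel:
    """Fit MLR by quasi-Newton minimization of the penalized deviance.

    The objective is the negative multinomial log-likelihood plus
    ridge_lambda times the squared norm of the non-intercept coefficients.
    A convergence warning (with the final gradient norm) is issued if the
    optimizer stops before the projected-gradient tolerance is met.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size < 2:
        raise ParameterError("need at least 2 classes to fit MLR")
    if not np.all(np.isfinite(X)):
        raise DomainError("X must be finite")
    Y = (y[:, None] == classes[None, :]).astype(float)
    Xa = np.concatenate([np.ones((X.shape[0], 1)), X], axis=1)
    b0 = np.zeros(Xa.shape[1] * (classes.size - 1))
    trace: list[float] = []

    def record(b):
        trace.append(_mlr_loss_grad(b, Xa, Y, ridge_lambda)[0])

    res = minimize(
        _mlr_loss_grad,
        b0,
        args=(Xa, Y, ridge_lambda),
        method="L-BFGS-B",
        jac=True,
        callback=record,
        options={"maxiter": max_iter, "gtol": tolerance, "ftol": 1e-14},
    )
    grad_norm = float(np.max(np.abs(res.jac)))
    converged = grad_norm <= max(tolerance, 1e-12) or res.success
    if not converged:
        warnings.warn(
            f"MLR optimizer stopped after {res.nit} iterations with "
            f"gradient norm {grad_norm:.3e} > {tolerance:.3e}",
            ConvergenceWarning,
        )
    B = res.x.reshape(Xa.shape[1], classes.size - 1)
    return MLRModel(
        B=B,
        classes=classes,
        ridge_lambda=ridge_lambda,
        converged=converged,
        final_grad_norm=grad_norm,
        loss_trace=trace,
    )


def mlr_predict_proba(model: MLRModel, X) -> np.ndarray:
    """Class-probability matrix; rows sum to 1, columns follow model.classes."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[1] != model.n_features:
        raise ParameterError(
            f"X has {X.shape[1]} features, model expects {model.n_features}"
        )
    Xa = np.concatenate([np.ones((X.shape[0], 1)), X], axis=1)
    Z = Xa @ model.B
    Zfull = np.concatenate([Z, np.zeros((Z.shape[0], 1))], axis=1)
    return np.exp(Zfull - logsumexp(Zfull, axis=1)[:, None])


def mlr_predict(model: MLRModel, X) -> np.ndarray:
    """Most probable class; probability ties go to the earliest label."""
    proba = mlr_predict_proba(model, X)
    return model.classes[np.argmax(proba, axis=1)]


# ---------------------------------------------------------------------------
# one-vs-one RBF support vector machine


def svm_fit_predict(
    train_X,
    train_y,
    test_X,
    C: float = 1.0,
    gamma: Optional[float] = None,
    normalization: str = "minmax",
) -> tuple[np.ndarray, pd.DataFrame]:
    """One-vs-one RBF SVM voting over all K(K-1)/2 class pairs.

    Each pair gets its own soft-margin binary machine; a test row's label is
    the class with the most pairwise votes (argmax ties go to the class
    earliest in sorted label order). Scores are vote shares votes/(K-1).
    """
    X, y, T = _as_xy(train_X, train_y, test_X)
    if C <= 0:
        raise ParameterError("C must be positive")
    classes = np.unique(y)
    K = classes.size
    if K < 2:
        raise ParameterError("need at least 2 classes")
    if gamma is None:
        gamma = 1.0 / X.shape[1]
    if gamma <= 0:
        raise ParameterError("gamma must be positive")
    norm = Normalizer(normalization).fit(X)
    Xn, Tn = norm.transform(X), norm.transform(T)
    votes = np.zeros((T.shape[0], K))
    for a in range(K):
        for b in range(a + 1, K):
            mask = (y == classes[a]) | (y == classes[b])
            ypair = y[mask]
            if np.unique(ypair).size < 2:
                raise DegeneratePairError(
                    f"pair ({classes[a]}, {classes[b]}): a class is absent"
                )
            machine = SVC(kernel="rbf", C=C, gamma=gamma)
            machine.fit(Xn[mask], ypair)
            pred = machine.predict(Tn)
            votes[pred == classes[a], a] += 1
            votes[pred == classes[b], b] += 1
    labels = classes[np.argmax(votes, axis=1)]  # argmax: earliest tied class
    shares = votes / (K - 1)
    return labels, pd.DataFrame(shares, columns=list(classes))
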