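"""Stratified cross-validation, the multiclass metric panel, and the
repeated-sampling experiment protocol.

One experiment repetition draws fresh sample sets, extracts features, and
runs stratified k-fold cross-validation; the per-fold test predictions are
pooled into a single confusion matrix before metrics are computed. The
whole procedure is repeated (20 times by default) with consecutive seeds
and the metric panel is reported as mean and standard error across
repetitions.

Per-class metrics are one-vs-rest: TPR (= recall = sensitivity),
FAR (false alarm rate, 1 - specificity), precision, F-measure, and a
per-class accuracy reported as that class's recall. Overall values are
unweighted macro averages. The panel also carries the kappa statistic
(chance-corrected agreement), the mean absolute error between score
vectors and one-hot truth, and the per-class ROC area.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .classifiers import (
    Normalizer,
    knn_fit_predict,
    mlr_fit,
    mlr_predict,
    mlr_predict_proba,
    select_k,
    svm_fit_predict,
)
from .datatypes import ClassDataset, RunConfig
from .errors import DomainError, StratificationError
from .features import FEATURE_NAMES, build_feature_matrix
from .sampling import build_sample_set

PER_CLASS_METRICS = ("TPR", "FAR", "Precision", "Recall", "F", "Acc")


def stratified_kfold(labels, n_folds: int, seed: int) -> np.ndarray:
    """Assign each row to one of n_folds folds, stratified by label.

    Within every class the rows are shuffled (seeded) and dealt round-robin,
    so per-class counts across folds differ by at most one; the deal pointer
    continues across classes, which also balances total fold sizes.
    """
    y = np.asarray(labels)
    if n_folds < 2:
        raise DomainError("n_folds must be >= 2")
    classes, counts = np.unique(y, return_counts=True)
    if (counts < n_folds).any():
        bad = [str(c) for c, n in zip(classes, counts) if n < n_folds]
        raise StratificationError(
            f"classes smaller than n_folds={n_folds}: {bad}"
        )
    rng = np.random.default_rng(seed)
    fold_of = np.empty(y.shape[0], dtype=int)
    pointer = 0
    for c in classes:
        idx = np.flatnonzero(y == c)
        perm = rng.permutation(idx)
        for row in perm:
            fold_of[row] = pointer % n_folds
            pointer += 1
    return fold_of


@dataclass
class MetricsReport:
    """Metric panel for one pooled set of predictions."""

    classes: list
    confusion: np.ndarray  # rows = true, cols = predicted
    per_class: pd.DataFrame  # index = classes, columns = PER_CLASS_METRICS (%)
    overall: dict  # macro means (%) + kappa, MAE, macro ROC area
    per_class_auc: dict

    def to_dict(self) -> dict:
        return {
            "classes": [str(c) for c in self.classes],
            "confusion": self.confusion.tolist(),
            "per_class": self.per_class.to_dict(orient="index"),
            "overall": dict(self.overall),
            "per_class_auc": dict(self.per_class_auc),
        }


def _roc_auc(truth_pos: np.ndarray, score: np.ndarray) -> float:
    """Rank-based ROC area: P(score_pos > score_neg) + half the ties."""
    n_pos = int(truth_pos.sum())
    n_neg = truth_pos.size - n_pos
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = rankdata(score)  # average ranks handle ties as half
    u = ranks[truth_pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def confusion_and_metrics(
    y_true,
    y_pred,
    scores,
    labels: Optional[Sequence] = None,
) -> MetricsReport:
    """Pooled confusion matrix and the full metric panel.

    ``scores`` is an (n, K) matrix of class scores (probabilities, vote
    shares, or neighbour fractions) with columns in label order. Rates are
    reported in percent; kappa on the [-1, 1] scale; MAE is the mean over
    instances and classes of |score - one-hot truth|.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape[0] != y_pred.shape[0]:
        raise DomainError("y_true and y_pred length mismatch")
    present = np.unique(np.concatenate([y_true, y_pred]))
    if labels is None:
        classes = present
    else:
        classes = np.asarray(labels)
        absent = [c for c in classes if c not in present]
        if absent:
            warnings.warn(
                f"dropping labels absent from truth and predictions: {absent}"
            )
            classes = np.array([c for c in classes if c in present])
    S = np.asarray(scores, dtype=float)
    if S.shape != (y_true.shape[0], classes.size):
        raise DomainError(
            f"scores shape {S.shape} != ({y_true.shape[0]}, {classes.size})"
        )
    K = classes.size
    index = {c: i for i, c in enumerate(classes)}
    conf = np.zeros((K, K), dtype=int)
    for t, p in zip(y_true, y_pred):
        conf[index[t], index[p]] += 1
    total = conf.sum()

    rows = []
    aucs = {}
    for i, c in enumerate(classes):
        tp = conf[i, i]
        fn = conf[i].sum() - tp
        fp = conf[:, i].sum() - tp
        tn = total - tp - fn - fp
        tpr = _safe_div(tp, tp + fn)
        far = _safe_div(fp, fp + tn)
        prec = _safe_div(tp, tp + fp)
        f = _safe_div(2 * prec * tpr, prec + tpr)
        rows.append(
            {
                "TPR": 100 * tpr,
                "FAR": 100 * far,
                "Precision": 100 * prec,
                "Recall": 100 * tpr,
                "F": 100 * f,
                "Acc": 100 * tpr,
            }
        )
        aucs[str(c)] = _roc_auc(y_true == c, S[:, i])

    per_class = pd.DataFrame(rows, index=list(classes))
    p_o = conf.trace() / total
    p_e = float((conf.sum(axis=1) * conf.sum(axis=0)).sum()) / total**2
    kappa = (p_o - p_e) / (1.0 - p_e) if p_e < 1.0 else 1.0
    onehot = (y_true[:, None] == classes[None, :]).astype(float)
    mae = float(np.mean(np.abs(S - onehot)))
    auc_vals = [v for v in aucs.values() if not np.isnan(v)]
    overall = {m: float(per_class[m].mean()) for m in PER_CLASS_METRICS}
    overall["kappa"] = float(kappa)
    overall["MAE"] = mae
    overall["ROC_area"] = float(np.mean(auc_vals)) if auc_vals else float("nan")
    return MetricsReport(
        classes=list(classes),
        confusion=conf,
        per_class=per_class,
        overall=overall,
        per_class_auc=aucs,
    )


def _safe_div(num, den) -> float:
    return float(num / den) if den > 0 else 0.0


@dataclass
class ExperimentReport:
    """Mean and standard error of the metric panel across repetitions."""

    config: dict
    repetition_seeds: list[int]
    realized_sizes: dict  # class -> per-segment sample counts of rep 0
    per_class_mean: pd.DataFrame
    per_class_se: pd.DataFrame
    overall_mean: dict
    overall_se: dict
    per_repetition: list[MetricsReport] = field(repr=False, default_factory=list)

    def to_dict(self) -> dict:
        return {
            "config": dict(self.config),
            "repetition_seeds": list(self.repetition_seeds),
            "realized_sizes": {
                k: list(v) for k, v in self.realized_sizes.items()
            },
            "per_class_mean": self.per_class_mean.to_dict(orient="index"),
            "per_class_se": self.per_class_se.to_dict(orient="index"),
            "overall_mean": dict(self.overall_mean),
            "overall_se": dict(self.overall_se),
            "per_repetition": [r.to_dict() for r in self.per_repetition],
        }


def _classify_fold(train_X, train_y, test_X, config: RunConfig, knn_k: int):
    """Train on one fold, score the held-out rows."""
    if config.classifier == "knn":
        return knn_fit_predict(
            train_X, train_y, test_X, k=knn_k, normalization=config.normalization
        )
    if config.classifier == "svm":
        return svm_fit_predict(
            train_X,
            train_y,
            test_X,
            C=config.svm_c,
            gamma=config.svm_gamma,
            normalization=config.normalization,
        )
    # mlr: normalization handled here because fit and predict are split
    norm = Normalizer(config.normalization).fit(train_X)
    model = mlr_fit(
        norm.transform(train_X),
        train_y,
        ridge_lambda=config.ridge_lambda,
        tolerance=config.mlr_tolerance,
        max_iter=config.mlr_max_iter,
    )
    Tn = norm.transform(test_X)
    proba = mlr_predict_proba(model, Tn)
    labels = mlr_predict(model, Tn)
    return labels, pd.DataFrame(proba, columns=list(model.classes))


def evaluate_feature_matrix(
    matrix: pd.DataFrame, config: RunConfig, seed: int
) -> MetricsReport:
    """Stratified CV of the configured classifier on one feature matrix.

    Per-fold test predictions are pooled into one confusion matrix.
    """
    X = matrix.loc[:, list(FEATURE_NAMES)].to_numpy(dtype=float)
    y = matrix["class"].to_numpy()
    classes = np.unique(y)
    fold_of = stratified_kfold(y, config.n_folds, seed)

    knn_k = config.knn_k
    if config.classifier == "knn" and knn_k is None:
        # the candidate range cannot exceed the smallest training fold
        min_train = min(
            int((fold_of != f).sum()) for f in range(config.n_folds)
        )
        knn_k = select_k(
            X,
            y,
            k_max=min(config.knn_k_max, min_train),
            folds=config.n_folds,
            seed=seed,
            normalization=config.normalization,
        )

    y_pred = np.empty_like(y)
    scores = np.zeros((len(y), classes.size))
    for f in range(config.n_folds):
        test = fold_of == f
        train = ~test
        labels, score_df = _classify_fold(
            X[train], y[train], X[test], config, knn_k
        )
        y_pred[test] = labels
        aligned = score_df.reindex(columns=list(classes), fill_value=0.0)
        scores[test] = aligned.to_numpy()
    return confusion_and_metrics(y, y_pred, scores, labels=classes)


def run_experiment(
    corpus: Sequence[ClassDataset], config: RunConfig
) -> ExperimentReport:
    """The full protocol: repeated sampling, features, CV, metric panel.

    Repetition r uses seed = config.seed + r for both the sampling draws
    and the CV shuffle; each class's draw is further separated by its index
    so classes sample independently. The report aggregates the per-repetition
    panels as mean and standard error.
    """
    if not corpus:
        raise DomainError("corpus must contain at least one class")
    reps: list[MetricsReport] = []
    seeds = [config.seed + r for r in range(config.n_repetitions)]
    realized: dict[str, tuple[int, ...]] = {}
    for r, rep_seed in enumerate(seeds):
        sample_sets = [
            build_sample_set(ds, config, seed=(rep_seed, ci))
            for ci, ds in enumerate(corpus)
        ]
        if r == 0:
            realized = {
                ss.class_label: ss.per_segment_sizes for ss in sample_sets
            }
        matrix = build_feature_matrix(sample_sets)
        reps.append(evaluate_feature_matrix(matrix, config, seed=rep_seed))

    per_class_stack = [rep.per_class for rep in reps]
    mean_pc = sum(per_class_stack) / len(per_class_stack)
    if len(reps) > 1:
        arr = np.stack([df.to_numpy() for df in per_class_stack])
        se = arr.std(axis=0, ddof=1) / np.sqrt(len(reps))
        se_pc = pd.DataFrame(se, index=mean_pc.index, columns=mean_pc.columns)
    else:
        se_pc = mean_pc * 0.0
    keys = reps[0].overall.keys()
    overall_mean = {
        k: float(np.mean([rep.overall[k] for rep in reps])) for k in keys
    }
    overall_se = {
        k: (
            float(
                np.std([rep.overall[k] for rep in reps], ddof=1)
                / np.sqrt(len(reps))
            )
            if len(reps) > 1
            else 0.0
        )
        for k in keys
    }
    return ExperimentReport(
        config=config.to_dict(),
        repetition_seeds=seeds,
        realized_sizes=realized,
        per_class_mean=mean_pc,
        per_class_se=se_pc,
        overall_mean=overall_mean,
        overall_se=overall_se,
        per_repetition=reps,
    )
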