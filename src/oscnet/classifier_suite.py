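"""Classifier families, cross-validation, metrics, and model ranking.

Five families are supported — decision tree (CART), regularised linear
discriminant, gaussian naive Bayes, SVM (linear or gaussian kernel) and
k-nearest neighbour — each fitted with scikit-learn on per-fold
standardised features.  Fitted parameters are extracted into plain
JSON-serialisable form and decision scores are recomputed natively from
them, so a saved model reloads to bit-identical predictions.

Decision-score conventions (positive score => patient-like class):

* svm / discriminant: signed distance to the separating hyperplane;
* naive Bayes: log-likelihood ratio log p(pos|x) - log p(neg|x);
* knn: fraction of the k nearest neighbours that are positive, minus 1/2;
* tree: leaf-node positive-class fraction, minus 1/2.

Cross-validated metrics are computed once on the pooled out-of-fold
predictions; standardisation is fitted within each training fold only.
Gaussian kernel-scale presets follow the common toolbox convention
(medium = sqrt(P), fine = sqrt(P)/4, coarse = 4 sqrt(P), with
gamma = 1/scale^2 for P selected features).

Models whose cross-validated accuracy or AUC falls below 0.75 are
flagged for exclusion from further validation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import roc_curve
from sklearn.model_selection import LeaveOneOut, StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .exceptions import ConfigurationError, InputError
from .feature_selection import SelectionResult
from .network_features import FeatureTable, subset_by_networks

FAMILIES = ("decision_tree", "discriminant", "naive_bayes", "svm", "knn")

#: The 11 network combinations evaluated for the migraine classifier.
NETWORK_COMBINATIONS: tuple[tuple[str, ...], ...] = (
    ("PN", "DMN", "SMN", "Ins-DMN"),
    ("PN", "DMN", "SMN"),
    ("PN", "DMN", "Ins-DMN"),
    ("PN", "SMN", "Ins-DMN"),
    ("PN", "DMN"),
    ("PN", "SMN"),
    ("PN", "Ins-DMN"),
    ("PN",),
    ("DMN",),
    ("SMN",),
    ("Ins-DMN",),
)

#: Accuracy (fraction) / AUC floor below which a model is excluded.
EXCLUSION_THRESHOLD = 0.75


@dataclass(frozen=True)
class AlgorithmSpec:
    """One classifier variant.

    ``kernel_scale`` (SVM gaussian kernel) is 'fine' | 'medium' |
    'coarse' or a positive number; ``k`` is the neighbour count;
    ``max_depth`` bounds the CART tree.
    """

    family: str
    kernel: str = "linear"
    kernel_scale: float | str = "medium"
    k: int = 5
    max_depth: int = 8

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ConfigurationError(f"unknown family {self.family!r}")
        if self.family == "svm" and self.kernel not in ("linear", "gaussian"):
            raise ConfigurationError(f"unknown SVM kernel {self.kernel!r}")
        if isinstance(self.kernel_scale, str):
            if self.kernel_scale not in ("fine", "medium", "coarse"):
                raise ConfigurationError(
                    f"unknown kernel_scale preset {self.kernel_scale!r}"
                )
        elif self.kernel_scale <= 0:
            raise ConfigurationError("numeric kernel_scale must be positive")
        if self.k < 1:
            raise ConfigurationError("k must be >= 1")
        if self.max_depth < 1:
            raise ConfigurationError("max_depth must be >= 1")

    @property
    def label(self) -> str:
        if self.family == "svm":
            if self.kernel == "linear":
                return "svm-linear"
            return f"svm-gaussian-{self.kernel_scale}"
        if self.family == "knn":
            return f"knn-{self.k}"
        return self.family

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "kernel": self.kernel,
            "kernel_scale": self.kernel_scale,
            "k": self.k,
            "max_depth": self.max_depth,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AlgorithmSpec":
        return cls(**d)


@dataclass(frozen=True)
class CvConfig:
    """Cross-validation settings (stratified k-fold; LOO optional)."""

    n_folds: int = 5
    stratified: bool = True
    leave_one_out: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ConfigurationError("n_folds must be >= 2")


def kernel_scale_value(scale: float | str, n_features: int) -> float:
    """Resolve a gaussian kernel-scale preset against the feature count."""
    if isinstance(scale, str):
        root = float(np.sqrt(n_features))
        return {"fine": root / 4.0, "medium": root, "coarse": 4.0 * root}[scale]
    return float(scale)


# ---------------------------------------------------------------------------
# fitting (scikit-learn) and native scoring from extracted parameters


def _fit_params(spec: AlgorithmSpec, X: np.ndarray, y: np.ndarray) -> dict:
    """Fit one family on standardised X / binary y (1 = positive class)
    and extract JSON-able parameters sufficient for native scoring."""
    if spec.family == "svm":
        if spec.kernel == "linear":
            clf = SVC(kernel="linear", C=1.0)
            clf.fit(X, y)
            return {
                "kind": "linear",
                "coef": clf.coef_[0].tolist(),
                "intercept": float(clf.intercept_[0]),
            }
        gamma = 1.0 / kernel_scale_value(spec.kernel_scale, X.shape[1]) ** 2
        clf = SVC(kernel="rbf", C=1.0, gamma=gamma)
        clf.fit(X, y)
        return {
            "kind": "rbf",
            "gamma": gamma,
            "support_vectors": clf.support_vectors_.tolist(),
            "dual_coef": clf.dual_coef_[0].tolist(),
            "intercept": float(clf.intercept_[0]),
        }
    if spec.family == "discriminant":
        clf = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
        clf.fit(X, y)
        return {
            "kind": "linear",
            "coef": clf.coef_[0].tolist(),
            "intercept": float(clf.intercept_[0]),
        }
    if spec.family == "naive_bayes":
        clf = GaussianNB()
        clf.fit(X, y)
        return {
            "kind": "gaussian_nb",
            "theta": clf.theta_.tolist(),
            "var": clf.var_.tolist(),
            "log_prior": np.log(clf.class_prior_).tolist(),
            "classes": clf.classes_.tolist(),
        }
    if spec.family == "knn":
        return {
            "kind": "knn",
            "k": int(min(spec.k, X.shape[0])),
            "X": X.tolist(),
            "y": y.tolist(),
        }
    if spec.family == "decision_tree":
        clf = DecisionTreeClassifier(max_depth=spec.max_depth, random_state=0)
        clf.fit(X, y)
        t = clf.tree_
        counts = t.value[:, 0, :] * t.weighted_n_node_samples[:, None]
        return {
            "kind": "tree",
            "children_left": t.children_left.tolist(),
            "children_right": t.children_right.tolist(),
            "feature": t.feature.tolist(),
            "threshold": t.threshold.tolist(),
            "counts": counts.tolist(),
            "classes": clf.classes_.tolist(),
        }
    raise ConfigurationError(f"unknown family {spec.family!r}")


def _decision_from_params(params: dict, X: np.ndarray) -> np.ndarray:
    """Native decision scores (positive => positive class) on standardised X."""
    kind = params["kind"]
    if kind == "linear":
        return X @ np.asarray(params["coef"]) + params["intercept"]
    if kind == "rbf":
        sv = np.asarray(params["support_vectors"])
        dual = np.asarray(params["dual_coef"])
        d2 = (
            np.sum(X**2, axis=1)[:, None]
            + np.sum(sv**2, axis=1)[None, :]
            - 2.0 * X @ sv.T
        )
        K = np.exp(-params["gamma"] * np.maximum(d2, 0.0))
        return K @ dual + params["intercept"]
    if kind == "gaussian_nb":
        theta = np.asarray(params["theta"])
        var = np.asarray(params["var"])
        log_prior = np.asarray(params["log_prior"])
        classes = list(params["classes"])
        jll = np.empty((X.shape[0], len(classes)))
        for c in range(len(classes)):
            jll[:, c] = (
                log_prior[c]
                - 0.5 * np.sum(np.log(2.0 * np.pi * var[c]))
                - 0.5 * np.sum((X - theta[c]) ** 2 / var[c], axis=1)
            )
        pos, neg = classes.index(1), classes.index(0)
        return jll[:, pos] - jll[:, neg]
    if kind == "knn":
        Xtr = np.asarray(params["X"])
        ytr = np.asarray(params["y"])
        k = params["k"]
        d2 = (
            np.sum(X**2, axis=1)[:, None]
            + np.sum(Xtr**2, axis=1)[None, :]
            - 2.0 * X @ Xtr.T
        )
        order = np.argsort(d2, axis=1, kind="stable")[:, :k]
        return ytr[order].mean(axis=1) - 0.5
    if kind == "tree":
        left = np.asarray(params["children_left"])
        right = np.asarray(params["children_right"])
        feat = np.asarray(params["feature"])
        thr = np.asarray(params["threshold"])
        counts = np.asarray(params["counts"])
        classes = list(params["classes"])
        pos = classes.index(1) if 1 in classes else None
        scores = np.empty(X.shape[0])
        for i, x in enumerate(X):
            node = 0
            while left[node] != -1:
                node = left[node] if x[feat[node]] <= thr[node] else right[node]
            total = counts[node].sum()
            p_pos = counts[node][pos] / total if pos is not None else 0.0
            scores[i] = p_pos - 0.5
        return scores
    raise ConfigurationError(f"unknown model kind {kind!r}")


# ---------------------------------------------------------------------------
# standardisation, trained-model container


def _fit_standardizer(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale = np.where(scale < 1e-12, 1.0, scale)  # constant-column guard
    return mean, scale


@dataclass
class TrainedModel:
    """A fitted classifier with its own standardisation, reloadable from JSON
    to identical predictions."""

    algorithm: AlgorithmSpec
    feature_ids: tuple[str, ...]
    negative_class: str
    positive_class: str
    mean: np.ndarray
    scale: np.ndarray
    params: dict
    selection_id: str | None = None

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != len(self.feature_ids):
            raise InputError(
                f"model expects {len(self.feature_ids)} features, got {X.shape[1]}"
            )
        Z = (X - self.mean) / self.scale
        return _decision_from_params(self.params, Z)

    def predict(self, X: np.ndarray) -> np.ndarray:
        scores = self.decision_scores(X)
        return np.where(scores > 0, self.positive_class, self.negative_class)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "algorithm": self.algorithm.to_dict(),
                "feature_ids": list(self.feature_ids),
                "negative_class": self.negative_class,
                "positive_class": self.positive_class,
                "mean": self.mean.tolist(),
                "scale": self.scale.tolist(),
                "params": self.params,
                "selection_id": self.selection_id,
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, source: str | Path) -> "TrainedModel":
        if isinstance(source, Path):
            text = source.read_text()
        else:
            text = str(source)
            if not text.lstrip().startswith("{"):
                text = Path(text).read_text()
        d = json.loads(text)
        return cls(
            algorithm=AlgorithmSpec.from_dict(d["algorithm"]),
            feature_ids=tuple(d["feature_ids"]),
            negative_class=d["negative_class"],
            positive_class=d["positive_class"],
            mean=np.asarray(d["mean"], dtype=float),
            scale=np.asarray(d["scale"], dtype=float),
            params=d["params"],
            selection_id=d.get("selection_id"),
        )


# ---------------------------------------------------------------------------
# metrics


def roc_auc(
    decision_values: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC as pairwise concordance probability (midrank tie handling),
    plus the ROC curve points.

    ``labels`` is binary with 1 = positive.  Equivalent to the
    Mann-Whitney statistic: P(score_pos > score_neg) + 1/2 P(tie).
    """
    scores = np.asarray(decision_values, dtype=float)
    y = np.asarray(labels).astype(int)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise InputError("both classes must be present to compute AUC")
    ranks = rankdata(scores)
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    fpr, tpr, _ = roc_curve(y, scores)
    return float(auc), fpr, tpr


@dataclass
class PerformanceReport:
    """Classification metrics with the patient-like class positive."""

    accuracy_pct: float
    sensitivity: float
    specificity: float
    auc: float
    tp: int
    fp: int
    tn: int
    fn: int
    roc_decision: tuple[list[float], list[float]]
    roc_label: tuple[list[float], list[float]]

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_scores(
        cls, y: np.ndarray, scores: np.ndarray, preds: np.ndarray | None = None
    ) -> "PerformanceReport":
        y = np.asarray(y).astype(int)
        scores = np.asarray(scores, dtype=float)
        if preds is None:
            preds = (scores > 0).astype(int)
        tp = int(np.sum((preds == 1) & (y == 1)))
        fp = int(np.sum((preds == 1) & (y == 0)))
        tn = int(np.sum((preds == 0) & (y == 0)))
        fn = int(np.sum((preds == 0) & (y == 1)))
        auc, fpr, tpr = roc_auc(scores, y)
        fpr_l, tpr_l, _ = roc_curve(y, preds.astype(float))
        return cls(
            accuracy_pct=100.0 * (tp + tn) / len(y),
            sensitivity=tp / (tp + fn) if (tp + fn) else float("nan"),
            specificity=tn / (tn + fp) if (tn + fp) else float("nan"),
            auc=auc,
            tp=tp,
            fp=fp,
            tn=tn,
            fn=fn,
            roc_decision=(fpr.tolist(), tpr.tolist()),
            roc_label=(fpr_l.tolist(), tpr_l.tolist()),
        )

    def to_dict(self) -> dict:
        return {
            "accuracy_pct": self.accuracy_pct,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "auc": self.auc,
            "confusion": {"tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn},
            "roc_decision": self.roc_decision,
            "roc_label": self.roc_label,
        }


# ---------------------------------------------------------------------------
# cross-validation, final fit, ranking


def _binary_labels(table: FeatureTable, positive_label: str | None) -> tuple[np.ndarray, str, str]:
    names = table.group_names()
    if len(names) != 2:
        raise InputError(f"binary classification needs exactly 2 groups, got {names}")
    if positive_label is None:
        positive_label = "CM" if "CM" in names else names[-1]
    if positive_label not in names:
        raise InputError(f"positive label {positive_label!r} not among groups {names}")
    negative_label = next(n for n in names if n != positive_label)
    y = np.array([1 if g == positive_label else 0 for g in table.groups])
    return y, negative_label, positive_label


def cross_validate(
    table: FeatureTable,
    spec: AlgorithmSpec,
    cv: CvConfig | None = None,
    positive_label: str | None = None,
) -> PerformanceReport:
    """Stratified k-fold CV; metrics on pooled out-of-fold predictions.

    Standardisation is fitted within each training fold only.
    Deterministic given ``cv.seed``.
    """
    cv = cv or CvConfig()
    y, _, _ = _binary_labels(table, positive_label)
    counts = np.bincount(y, minlength=2)
    if not cv.leave_one_out and counts.min() < cv.n_folds:
        raise InputError(
            f"n_folds={cv.n_folds} exceeds the smaller group size {counts.min()}; "
            "every fold must contain both classes"
        )
    if cv.leave_one_out:
        splitter = LeaveOneOut()
    else:
        splitter = StratifiedKFold(
            n_splits=cv.n_folds, shuffle=True, random_state=cv.seed
        )
    scores = np.empty(len(y))
    for train_idx, test_idx in splitter.split(table.data, y):
        Xtr, ytr = table.data[train_idx], y[train_idx]
        mean, scale = _fit_standardizer(Xtr)
        params = _fit_params(spec, (Xtr - mean) / scale, ytr)
        scores[test_idx] = _decision_from_params(
            params, (table.data[test_idx] - mean) / scale
        )
    return PerformanceReport.from_scores(y, scores)


def fit_final(
    table: FeatureTable,
    spec: AlgorithmSpec,
    positive_label: str | None = None,
    selection_id: str | None = None,
) -> TrainedModel:
    """Fit on the full table (own standardisation); frozen for external
    validation."""
    y, neg, pos = _binary_labels(table, positive_label)
    mean, scale = _fit_standardizer(table.data)
    params = _fit_params(spec, (table.data - mean) / scale, y)
    return TrainedModel(
        algorithm=spec,
        feature_ids=table.index.ids,
        negative_class=neg,
        positive_class=pos,
        mean=mean,
        scale=scale,
        params=params,
        selection_id=selection_id,
    )


def default_algorithm_grid() -> tuple[AlgorithmSpec, ...]:
    """The classifier variants evaluated per network combination."""
    return (
        AlgorithmSpec(family="svm", kernel="linear"),
        AlgorithmSpec(family="svm", kernel="gaussian", kernel_scale="fine"),
        AlgorithmSpec(family="svm", kernel="gaussian", kernel_scale="medium"),
        AlgorithmSpec(family="svm", kernel="gaussian", kernel_scale="coarse"),
        AlgorithmSpec(family="discriminant"),
        AlgorithmSpec(family="naive_bayes"),
        AlgorithmSpec(family="knn"),
        AlgorithmSpec(family="decision_tree"),
    )


def rank_models(
    table: FeatureTable,
    selection: SelectionResult,
    combos: Sequence[Sequence[str]] = NETWORK_COMBINATIONS,
    specs: Sequence[AlgorithmSpec] | None = None,
    cv: CvConfig | None = None,
    positive_label: str | None = None,
) -> tuple[pd.DataFrame, dict[tuple[str, str], PerformanceReport]]:
    """Cross-validate every (network combination, algorithm) pair.

    Returns a leaderboard sorted by accuracy then AUC, with sub-0.75
    accuracy / AUC exclusion flags, plus the full reports keyed by
    (combo label, algorithm label).  Combinations whose selection mask is
    empty are skipped with a warning.
    """
    specs = tuple(specs) if specs is not None else default_algorithm_grid()
    cv = cv or CvConfig()
    rows = []
    reports: dict[tuple[str, str], PerformanceReport] = {}
    for combo in combos:
        combo_label = "+".join(combo)
        sub = subset_by_networks(table, combo)
        selected = [fid for fid in selection.selected_ids if fid in set(sub.index.ids)]
        if not selected:
            warnings.warn(
                f"combination {combo_label}: no selected features; skipped",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        sub = sub.select_ids(selected)
        for spec in specs:
            report = cross_validate(sub, spec, cv, positive_label)
            reports[(combo_label, spec.label)] = report
            rows.append(
                {
                    "combo": combo_label,
                    "algorithm": spec.label,
                    "n_features": len(selected),
                    "accuracy_pct": report.accuracy_pct,
                    "sensitivity": report.sensitivity,
                    "specificity": report.specificity,
                    "auc": report.auc,
                    "excluded_accuracy": report.accuracy_pct
                    < 100.0 * EXCLUSION_THRESHOLD,
                    "excluded_auc": report.auc < EXCLUSION_THRESHOLD,
                }
            )
    leaderboard = pd.DataFrame(rows)
    if not leaderboard.empty:
        leaderboard["excluded"] = (
            leaderboard["excluded_accuracy"] | leaderboard["excluded_auc"]
        )
        leaderboard = leaderboard.sort_values(
            ["accuracy_pct", "auc"], ascending=False, kind="stable"
        ).reset_index(drop=True)
    return leaderboard, reports
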