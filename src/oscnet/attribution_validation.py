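"""Permutation significance, Shapley feature attribution, and frozen-model
external validation.

**Permutation test.**  The observed cross-validated accuracy is compared
against a null distribution built by shuffling group labels and re-running
the full training pipeline (feature selection refit per permutation by
default, to avoid optimistic bias).  The default p-value uses add-one
smoothing, p = (1 + #{null >= observed}) / (n_perm + 1), which can never
return 0; the literal exceedance proportion #{null > observed} / n_perm is
also reported.

**Shapley attribution.**  Features are players in a cooperative game whose
value is the model's continuous decision score with absent features
marginalised over a background sample (interventional expectation).  Exact
mode enumerates all 2^P coalitions with Shapley weights (P <= 12); sampled
mode averages marginal contributions over seeded random feature
permutations.  Both modes satisfy efficiency exactly: per subject the
attributions sum to the decision score minus the background baseline.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from math import factorial
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .classifier_suite import (
    AlgorithmSpec,
    CvConfig,
    PerformanceReport,
    TrainedModel,
    cross_validate,
)
from .exceptions import ConfigurationError, InputError
from .feature_selection import SelectionResult, select
from .network_features import FEATURE_ID_SEP, FeatureTable


# ---------------------------------------------------------------------------
# permutation significance


@dataclass
class PermutationResult:
    """Observed accuracy against a label-shuffled null distribution."""

    observed_accuracy_pct: float
    null_accuracy_pct: np.ndarray
    p_value: float
    p_value_literal: float
    n_perm: int
    seed: int

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(
            json.dumps(
                {
                    "observed_accuracy_pct": self.observed_accuracy_pct,
                    "null_accuracy_pct": self.null_accuracy_pct.tolist(),
                    "p_value": self.p_value,
                    "p_value_literal": self.p_value_literal,
                    "n_perm": self.n_perm,
                    "seed": self.seed,
                },
                indent=2,
            )
        )
        return path


def cv_accuracy_builder(
    spec: AlgorithmSpec,
    positive_label: str | None = None,
    q: float | None = None,
    selection_mode: str = "global",
) -> Callable[[FeatureTable, CvConfig], float]:
    """Builder returning cross-validated accuracy (%) for a label
    assignment; if ``q`` is given, feature selection is refit on the
    (possibly permuted) labels before training.

    When a permutation leaves no feature selected there is no usable
    classifier; the majority-class rate is recorded for that draw.
    """

    def builder(table: FeatureTable, cv: CvConfig) -> float:
        if q is not None:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                sel = select(table, q=q, mode=selection_mode)
            if sel.n_selected == 0:
                counts = pd.Series(table.groups).value_counts()
                return 100.0 * counts.iloc[0] / len(table.groups)
            table = sel.apply(table)
        return cross_validate(table, spec, cv, positive_label).accuracy_pct

    return builder


def permutation_pvalue(
    model_builder: Callable[[FeatureTable, CvConfig], float],
    table: FeatureTable,
    cv: CvConfig | None = None,
    n_perm: int = 10_000,
    seed: int = 0,
) -> PermutationResult:
    """Label-permutation significance of the builder's accuracy."""
    if n_perm < 99:
        raise ConfigurationError("n_perm must be >= 99")
    cv = cv or CvConfig()
    observed = model_builder(table, cv)
    if not np.isfinite(observed):
        raise InputError("observed accuracy is undefined")
    rng = np.random.default_rng(seed)
    groups = np.array(table.groups)
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = model_builder(table.with_groups(rng.permutation(groups)), cv)
    p = (1.0 + np.sum(null >= observed)) / (n_perm + 1.0)
    p_literal = float(np.mean(null > observed))
    return PermutationResult(
        observed_accuracy_pct=observed,
        null_accuracy_pct=null,
        p_value=float(p),
        p_value_literal=p_literal,
        n_perm=n_perm,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Shapley attribution


@dataclass
class ShapleyReport:
    """Per-subject, per-feature attributions on the decision-score scale.

    ``values[i, j]`` is feature j's contribution to subject i's decision
    score relative to the background baseline; rows sum to
    ``scores - baseline`` (efficiency).
    """

    values: np.ndarray  # (n_subjects, n_features)
    scores: np.ndarray  # (n_subjects,)
    baseline: float
    feature_ids: tuple[str, ...]
    subject_ids: tuple[str, ...]
    mode: str
    n_samples: int | None
    model_label: str

    @property
    def mean_abs(self) -> pd.Series:
        """Mean |attribution| per feature across subjects."""
        return pd.Series(
            np.abs(self.values).mean(axis=0), index=list(self.feature_ids)
        )

    def by_area(self) -> pd.Series:
        """Mean |attribution| per feature, summed per ROI area (collapsing
        networks and bands), descending."""
        ma = self.mean_abs
        areas = [fid.split(FEATURE_ID_SEP)[2] for fid in self.feature_ids]
        return ma.groupby(pd.Index(areas, name="area")).sum().sort_values(
            ascending=False
        )

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(
            json.dumps(
                {
                    "values": self.values.tolist(),
                    "scores": self.scores.tolist(),
                    "baseline": self.baseline,
                    "feature_ids": list(self.feature_ids),
                    "subject_ids": list(self.subject_ids),
                    "mode": self.mode,
                    "n_samples": self.n_samples,
                    "model_label": self.model_label,
                },
                indent=2,
            )
        )
        return path


def _coalition_values(
    model: TrainedModel, X: np.ndarray, background: np.ndarray
) -> Callable[[np.ndarray], np.ndarray]:
    """Value function v(S): for each subject, the mean decision score over
    background rows with the coalition's columns replaced by the subject's."""
    n_bg = background.shape[0]

    def value(member_mask: np.ndarray) -> np.ndarray:
        hybrid = np.repeat(background[None, :, :], X.shape[0], axis=0)
        hybrid[:, :, member_mask] = X[:, None, member_mask]
        flat = hybrid.reshape(-1, X.shape[1])
        return model.decision_scores(flat).reshape(X.shape[0], n_bg).mean(axis=1)

    return value


def shapley_attribution(
    model: TrainedModel,
    table: FeatureTable,
    background: np.ndarray | FeatureTable | None = None,
    mode: str = "sampled",
    n_samples: int = 2000,
    seed: int = 0,
    max_background: int = 100,
) -> ShapleyReport:
    """Shapley values of the model's decision score for every subject.

    ``background`` defaults to a seeded subsample (<= ``max_background``
    rows) of ``table`` itself.  ``mode='exact'`` enumerates all
    coalitions (requires <= 12 features); ``mode='sampled'`` averages
    marginal contributions over ``n_samples`` random feature
    permutations.
    """
    if tuple(table.index.ids) != tuple(model.feature_ids):
        raise InputError("feature table does not match the model's feature ids")
    X = table.data
    P = X.shape[1]
    rng = np.random.default_rng(seed)
    if background is None:
        background = X
    elif isinstance(background, FeatureTable):
        background = background.data
    background = np.asarray(background, dtype=float)
    if background.size == 0:
        raise InputError("background sample must be nonempty")
    if background.shape[0] > max_background:
        keep = rng.choice(background.shape[0], size=max_background, replace=False)
        background = background[np.sort(keep)]
    value = _coalition_values(model, X, background)
    scores = model.decision_scores(X)
    baseline = float(model.decision_scores(background).mean())
    phi = np.zeros((X.shape[0], P))

    if mode == "exact":
        if P > 12:
            raise ConfigurationError(
                f"exact enumeration limited to 12 features, got {P}"
            )
        v = {}
        for code in range(1 << P):
            mask = np.array([(code >> j) & 1 for j in range(P)], dtype=bool)
            v[code] = value(mask)
        for j in range(P):
            for code in range(1 << P):
                if (code >> j) & 1:
                    continue
                s = bin(code).count("1")
                w = factorial(s) * factorial(P - 1 - s) / factorial(P)
                phi[:, j] += w * (v[code | (1 << j)] - v[code])
    elif mode == "sampled":
        if n_samples < 1:
            raise ConfigurationError("n_samples must be >= 1")
        for _ in range(n_samples):
            order = rng.permutation(P)
            mask = np.zeros(P, dtype=bool)
            prev = value(mask)
            for j in order:
                mask[j] = True
                cur = value(mask)
                phi[:, j] += cur - prev
                prev = cur
        phi /= n_samples
    else:
        raise ConfigurationError(f"unknown mode {mode!r}")

    return ShapleyReport(
        values=phi,
        scores=scores,
        baseline=baseline,
        feature_ids=table.index.ids,
        subject_ids=table.subject_ids,
        mode=mode,
        n_samples=n_samples if mode == "sampled" else None,
        model_label=model.algorithm.label,
    )


def aggregate_shapley_by_area(reports: Sequence[ShapleyReport]) -> pd.Series:
    """Across-model average of per-area aggregated |Shapley| values.

    Per report: mean |value| per feature, summed per ROI area over
    networks and bands; then averaged across the included models.
    """
    if not reports:
        raise InputError("at least one ShapleyReport required")
    frames = [r.by_area() for r in reports]
    return (
        pd.concat(frames, axis=1).fillna(0.0).mean(axis=1).sort_values(ascending=False)
    )


# ---------------------------------------------------------------------------
# frozen-model external validation


def external_validate(
    model: TrainedModel,
    selection: SelectionResult,
    new_table: FeatureTable,
) -> PerformanceReport:
    """Apply the frozen training-set selection mask, standardisation and
    model to a new cohort — no refitting of any kind."""
    selected = selection.selected_ids
    if tuple(selected) != tuple(model.feature_ids):
        missing = set(model.feature_ids) ^ set(selected)
        raise InputError(
            f"selection mask does not match the model's feature ids; "
            f"mismatched ids: {sorted(missing)[:10]}"
        )
    sub = new_table.select_ids(selected)  # raises on unresolvable ids
    y = np.array([1 if g == model.positive_class else 0 for g in sub.groups])
    if y.min() == y.max():
        raise InputError("validation cohort must contain both classes")
    scores = model.decision_scores(sub.data)
    return PerformanceReport.from_scores(y, scores)
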