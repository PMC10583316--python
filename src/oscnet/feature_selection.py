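"""Univariate discriminative-feature selection.

Each node-strength feature is tested with an independent two-sample
t-test (pooled-variance Student by default, Welch optional) between the
two groups; p-values are Benjamini–Hochberg adjusted and features with
adjusted p <= q form the discriminative feature index.  Correction is
applied within each network's feature family by default (matching
selection "from each network"), with a global-pool option.

The resulting mask is serialisable and re-applicable verbatim — by
feature id, not column position — to any table sharing the feature
index, so held-out cohorts are filtered without re-selection.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import ConfigurationError, InputError
from .network_features import FeatureTable

logger = logging.getLogger(__name__)


@dataclass
class SelectionResult:
    """Per-feature statistics and the reusable boolean selection mask."""

    feature_ids: tuple[str, ...]
    t: np.ndarray
    p: np.ndarray
    p_adjusted: np.ndarray
    mask: np.ndarray
    q: float
    mode: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int

    @property
    def selected_ids(self) -> tuple[str, ...]:
        return tuple(fid for fid, m in zip(self.feature_ids, self.mask) if m)

    @property
    def n_selected(self) -> int:
        return int(self.mask.sum())

    def apply(self, table: FeatureTable) -> FeatureTable:
        """Restrict ``table`` to the selected features, matched by id."""
        if self.n_selected == 0:
            raise InputError("selection mask is empty; nothing to apply")
        return table.select_ids(self.selected_ids)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "feature_ids": list(self.feature_ids),
            "t": self.t.tolist(),
            "p": self.p.tolist(),
            "p_adjusted": self.p_adjusted.tolist(),
            "mask": self.mask.astype(int).tolist(),
            "q": self.q,
            "mode": self.mode,
            "group_a": self.group_a,
            "group_b": self.group_b,
            "n_a": self.n_a,
            "n_b": self.n_b,
        }
        path.write_text(json.dumps(payload, indent=2))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "SelectionResult":
        d = json.loads(Path(path).read_text())
        return cls(
            feature_ids=tuple(d["feature_ids"]),
            t=np.asarray(d["t"], dtype=float),
            p=np.asarray(d["p"], dtype=float),
            p_adjusted=np.asarray(d["p_adjusted"], dtype=float),
            mask=np.asarray(d["mask"], dtype=bool),
            q=d["q"],
            mode=d["mode"],
            group_a=d["group_a"],
            group_b=d["group_b"],
            n_a=d["n_a"],
            n_b=d["n_b"],
        )


def ttest_per_feature(
    table: FeatureTable,
    group_a: str,
    group_b: str,
    equal_var: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided independent t-test per feature column.

    Sign convention: t > 0 when the ``group_a`` mean exceeds the
    ``group_b`` mean.  Columns with zero variance in both groups (test
    undefined) get t = 0, p = 1 by convention, logged.
    """
    a = table.data[table.rows_for_group(group_a)]
    b = table.data[table.rows_for_group(group_b)]
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise InputError("each group needs >= 2 subjects for a t-test")
    with np.errstate(invalid="ignore", divide="ignore"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            t, p = stats.ttest_ind(a, b, axis=0, equal_var=equal_var)
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    undefined = ~np.isfinite(t)
    if undefined.any():
        logger.warning(
            "%d features have zero within-group variance; t=0, p=1 by convention",
            int(undefined.sum()),
        )
        t[undefined] = 0.0
        p[undefined] = 1.0
    return t, p


def fdr_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, clipped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise InputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def select(
    table: FeatureTable,
    q: float = 0.05,
    group_a: str | None = None,
    group_b: str | None = None,
    mode: str = "per_network",
    equal_var: bool = True,
) -> SelectionResult:
    """t-test + BH-FDR selection of discriminative features.

    ``mode='per_network'`` adjusts p-values within each network's feature
    family separately; ``mode='global'`` pools all features into one
    correction.
    """
    if mode not in ("per_network", "global"):
        raise ConfigurationError(f"unknown selection mode {mode!r}")
    if not 0.0 <= q <= 1.0:
        raise ConfigurationError("q must lie in [0, 1]")
    names = table.group_names()
    if group_a is None or group_b is None:
        if len(names) != 2:
            raise InputError(
                f"table has groups {names}; specify group_a and group_b explicitly"
            )
        group_a, group_b = names
    t, p = ttest_per_feature(table, group_a, group_b, equal_var=equal_var)
    adjusted = np.empty_like(p)
    if mode == "global":
        adjusted[:] = fdr_adjust(p)
    else:
        networks = np.array([tr[0] for tr in table.index.triples])
        for net in dict.fromkeys(networks):
            sel = networks == net
            adjusted[sel] = fdr_adjust(p[sel])
    mask = adjusted <= q
    if not mask.any():
        warnings.warn(
            "no feature passed FDR selection; downstream training will refuse "
            "an empty mask",
            RuntimeWarning,
            stacklevel=2,
        )
    return SelectionResult(
        feature_ids=table.index.ids,
        t=t,
        p=p,
        p_adjusted=adjusted,
        mask=mask,
        q=q,
        mode=mode,
        group_a=group_a,
        group_b=group_b,
        n_a=int(table.rows_for_group(group_a).sum()),
        n_b=int(table.rows_for_group(group_b).sum()),
    )
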