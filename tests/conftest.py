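from dataclasses import dataclass

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from oscnet.network_features import FeatureIndex, FeatureTable

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@dataclass
class ArrayTS:
    """Minimal time-series container for spectral tests."""

    data: np.ndarray
    sampling_rate: float = 600.0

    @property
    def roi_labels(self):
        return tuple(f"ch{i}" for i in range(self.data.shape[0]))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_gaussian_table(
    rng,
    n_a: int,
    n_b: int,
    n_features: int,
    effect_cols=(),
    effect: float = 0.0,
    group_a: str = "HC",
    group_b: str = "CM",
    network: str = "PN",
) -> FeatureTable:
    """Feature table of iid standard-normal columns; ``effect`` is added to
    the listed columns in group_b (so Cohen's d = effect)."""
    data = rng.standard_normal((n_a + n_b, n_features))
    for c in effect_cols:
        data[n_a:, c] += effect
    index = FeatureIndex(
        triples=tuple((network, "alpha", f"f{k}") for k in range(n_features))
    )
    return FeatureTable(
        data=data,
        subject_ids=tuple(f"s{k}" for k in range(n_a + n_b)),
        groups=(group_a,) * n_a + (group_b,) * n_b,
        index=index,
    )
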