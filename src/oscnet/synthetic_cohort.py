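"""Seeded synthetic cohorts of ROI-level resting-state time series.

Real source-space MEG recordings for this problem are not publicly
deposited, so cohorts are emulated: each ROI channel is 1/f background
noise (plus a white floor), and selected ROI pairs share a band-limited,
phase-lagged source whose amplitude depends on group.  A patient-like
group with *reduced* coupling strength reproduces the decreased-
connectivity regime the classifier pipeline is designed to detect, and a
ground-truth manifest records exactly which (network, band, roi) features
should discriminate.

The phase lag is injected by rotating the analytic signal of the shared
source, so the lag is exact at every frequency the source carries —
imaginary coherence only sees non-zero-lag coupling, so lags near pi/2
maximise detectability while lag 0 is invisible by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy.signal import butter, hilbert, sosfiltfilt

from .exceptions import ConfigurationError, InputError
from .network_features import (
    NetworkCatalog,
    default_network_catalog,
    default_roi_labels,
)
from .spectral_connectivity import DEFAULT_BANDS


@dataclass(frozen=True)
class NoiseSpec:
    """Background noise model per ROI channel.

    ``exponent`` is the 1/f^a power-law slope of the pink component;
    ``white_ratio`` is the fraction of background variance contributed by
    the flat (white) floor; ``amplitude`` scales the whole background
    (0 disables it — useful for noiseless fixtures).
    """

    exponent: float = 1.0
    white_ratio: float = 0.25
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.white_ratio <= 1.0:
            raise ConfigurationError("white_ratio must lie in [0, 1]")
        if self.amplitude < 0:
            raise ConfigurationError("amplitude must be >= 0")


@dataclass(frozen=True)
class CouplingSpec:
    """A planted band-limited, phase-lagged coupling on one ROI pair.

    ``band`` is either a band name from the band book or a
    ``(center_hz, bandwidth_hz)`` pair.  ``strength_by_group`` gives the
    coupling amplitude (in units of background SD) per group; groups
    differing in strength make the edge's endpoints discriminative.
    """

    edge: tuple[str, str]
    band: str | tuple[float, float]
    phase_lag: float = np.pi / 2
    strength_by_group: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.edge[0] == self.edge[1]:
            raise ConfigurationError("coupling edge endpoints must be distinct")
        if not -np.pi < self.phase_lag <= np.pi:
            raise ConfigurationError("phase_lag must lie in (-pi, pi]")
        for g, s in self.strength_by_group.items():
            if s < 0:
                raise ConfigurationError(f"negative strength for group {g!r}")

    def band_edges(self, bands: Mapping[str, tuple[float, float]]) -> tuple[float, float]:
        if isinstance(self.band, str):
            try:
                return bands[self.band]
            except KeyError:
                raise ConfigurationError(f"unknown band {self.band!r}") from None
        center, width = self.band
        return (center - width / 2.0, center + width / 2.0)

    def band_name(self, bands: Mapping[str, tuple[float, float]]) -> str:
        """Resolve to a named band (numeric specs map to the band holding
        their centre frequency)."""
        if isinstance(self.band, str):
            if self.band not in bands:
                raise ConfigurationError(f"unknown band {self.band!r}")
            return self.band
        center = self.band[0]
        for name, (lo, hi) in bands.items():
            if lo <= center <= hi:
                return name
        raise ConfigurationError(
            f"numeric coupling band centred at {center} Hz lies in no named band"
        )


@dataclass(frozen=True)
class CohortConfig:
    """Generative settings for one cohort."""

    groups: Mapping[str, int]
    roi_labels: tuple[str, ...] = field(default_factory=default_roi_labels)
    sampling_rate: float = 600.0
    duration: float = 300.0
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    couplings: tuple[CouplingSpec, ...] = ()
    bands: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BANDS)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.groups:
            raise ConfigurationError("at least one group required")
        for g, n in self.groups.items():
            if n < 1:
                raise ConfigurationError(f"group {g!r} size must be >= 1")
        if len(set(self.roi_labels)) != len(self.roi_labels):
            raise ConfigurationError("ROI labels must be unique")
        highest = max(hi for _, hi in self.bands.values())
        if self.sampling_rate <= 2 * highest:
            raise ConfigurationError(
                f"sampling_rate {self.sampling_rate} Hz must exceed twice the "
                f"highest band edge ({highest} Hz)"
            )
        n = self.duration * self.sampling_rate
        if abs(n - round(n)) > 1e-9:
            raise ConfigurationError("duration x sampling_rate must be an integer")
        roi_set = set(self.roi_labels)
        for c in self.couplings:
            for endpoint in c.edge:
                if endpoint not in roi_set:
                    raise ConfigurationError(
                        f"coupling references unknown ROI {endpoint!r}"
                    )
            c.band_edges(self.bands)

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sampling_rate))

    @property
    def n_subjects(self) -> int:
        return sum(self.groups.values())


@dataclass
class RoiTimeSeries:
    """One subject's ROI x samples signal matrix (arbitrary units)."""

    subject_id: str
    group: str
    sampling_rate: float
    roi_labels: tuple[str, ...]
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape[0] != len(self.roi_labels):
            raise InputError("data rows must match roi_labels")
        if not np.all(np.isfinite(self.data)):
            raise InputError("time series contains non-finite values")


@dataclass
class GroundTruth:
    """Manifest of planted group differences.

    ``discriminative_features`` lists every (network, band, roi) feature
    touched by an edge whose coupling strength differs between groups.
    """

    discriminative_features: tuple[tuple[str, str, str], ...]
    planted_edges: tuple[CouplingSpec, ...]

    def feature_ids(self) -> tuple[str, ...]:
        return tuple("|".join(t) for t in self.discriminative_features)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "discriminative_features": [list(t) for t in self.discriminative_features],
            "planted_edges": [
                {
                    "edge": list(c.edge),
                    "band": c.band if isinstance(c.band, str) else list(c.band),
                    "phase_lag": c.phase_lag,
                    "strength_by_group": dict(c.strength_by_group),
                }
                for c in self.planted_edges
            ],
        }
        path.write_text(json.dumps(payload, indent=2))
        return path


def _pink_noise(rng: np.random.Generator, n: int, exponent: float) -> np.ndarray:
    """Unit-variance 1/f^exponent noise via frequency-domain shaping."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    scale = np.ones_like(freqs)
    scale[1:] = freqs[1:] ** (-exponent / 2.0)
    scale[0] = 0.0
    x = np.fft.irfft(spec * scale, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _band_limited_source(
    rng: np.random.Generator, n: int, fs: float, lo: float, hi: float
) -> np.ndarray:
    """Unit-variance band-limited noise (4th-order Butterworth, two-pass
    zero-phase)."""
    sos = butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = sosfiltfilt(sos, rng.standard_normal(n))
    sd = x.std()
    return x / sd if sd > 0 else x


def _phase_rotate(x: np.ndarray, phase: float) -> np.ndarray:
    """Rotate every spectral component of x by ``phase`` radians (analytic-
    signal rotation); exact constant phase lag across the band."""
    return np.real(hilbert(x) * np.exp(-1j * phase))


def generate_subject(
    config: CohortConfig, group: str, subject_seed: int
) -> RoiTimeSeries:
    """One subject's recording; deterministic given (config.seed, subject_seed)."""
    if group not in config.groups:
        raise ConfigurationError(f"unknown group {group!r}")
    rng = np.random.default_rng([config.seed, subject_seed])
    n = config.n_samples
    fs = config.sampling_rate
    noise = config.noise
    data = np.zeros((len(config.roi_labels), n))
    w = noise.white_ratio
    for i in range(len(config.roi_labels)):
        pink = _pink_noise(rng, n, noise.exponent)
        floor = rng.standard_normal(n)
        data[i] = noise.amplitude * (np.sqrt(1.0 - w) * pink + np.sqrt(w) * floor)
    pos = {lab: i for i, lab in enumerate(config.roi_labels)}
    for coupling in config.couplings:
        lo, hi = coupling.band_edges(config.bands)
        source = _band_limited_source(rng, n, fs, lo, hi)
        strength = coupling.strength_by_group.get(group, 0.0)
        ia, ib = pos[coupling.edge[0]], pos[coupling.edge[1]]
        data[ia] += strength * source
        data[ib] += strength * _phase_rotate(source, coupling.phase_lag)
    return RoiTimeSeries(
        subject_id=f"sub{subject_seed:04d}",
        group=group,
        sampling_rate=fs,
        roi_labels=tuple(config.roi_labels),
        data=data,
    )


def generate_cohort(
    config: CohortConfig, catalog: NetworkCatalog | None = None
) -> tuple[list[RoiTimeSeries], GroundTruth]:
    """All subjects (group order preserved) plus the ground-truth manifest.

    Subject seeds are the subject's index in cohort order, combined with
    ``config.seed`` through the generator's seed sequence, so a subject
    can be regenerated in isolation.
    """
    catalog = catalog or default_network_catalog(
        include_precuneus="Prc_L" in config.roi_labels
    )
    subjects: list[RoiTimeSeries] = []
    idx = 0
    for group, size in config.groups.items():
        for _ in range(size):
            subjects.append(generate_subject(config, group, idx))
            idx += 1
    truth = build_ground_truth(config, catalog)
    return subjects, truth


def build_ground_truth(
    config: CohortConfig, catalog: NetworkCatalog | None = None
) -> GroundTruth:
    """Manifest of features expected to discriminate, from the coupling list."""
    catalog = catalog or default_network_catalog(
        include_precuneus="Prc_L" in config.roi_labels
    )
    differing = []
    for c in config.couplings:
        strengths = [c.strength_by_group.get(g, 0.0) for g in config.groups]
        if max(strengths) - min(strengths) > 0:
            differing.append(c)
    triples: list[tuple[str, str, str]] = []
    for c in differing:
        band = c.band_name(config.bands)
        a, b = c.edge
        for net in catalog.names:
            if (a, b) in catalog.edges(net) or (b, a) in catalog.edges(net):
                for roi in (a, b):
                    t = (net, band, roi)
                    if t not in triples:
                        triples.append(t)
    return GroundTruth(
        discriminative_features=tuple(triples), planted_edges=tuple(differing)
    )


def ground_truth_features(truth: GroundTruth, feature_index) -> np.ndarray:
    """Boolean mask over ``feature_index`` that is true exactly at the
    manifest's (network, band, roi) triples."""
    ids = set(truth.feature_ids())
    index_ids = list(feature_index.ids)
    unresolved = ids - set(index_ids)
    if unresolved:
        raise InputError(f"manifest triples not in feature index: {sorted(unresolved)}")
    return np.array([fid in ids for fid in index_ids], dtype=bool)


def default_study_couplings(
    hc_group: str = "HC",
    cm_group: str = "CM",
    hc_strength: float = 0.8,
    cm_strength: float = 0.3,
    phase_lag: float = np.pi / 2,
) -> tuple[CouplingSpec, ...]:
    """Planted couplings emulating the chronic-migraine connectivity pattern.

    The patient-like group has *reduced* coupling on pain-network edges
    (theta/alpha/beta/gamma), default-mode edges (beta/gamma), a
    sensorimotor edge shared with PN (beta), and insula<->DMN edges
    (beta/gamma); the visual network is left intact.
    """
    s = {hc_group: hc_strength, cm_group: cm_strength}

    def c(a: str, b: str, band: str) -> CouplingSpec:
        return CouplingSpec(edge=(a, b), band=band, phase_lag=phase_lag,
                            strength_by_group=s)

    return (
        c("ACC_L", "Ins_R", "gamma"),
        c("ACC_R", "Ins_L", "theta"),
        c("MI_R", "SI_R", "beta"),
        c("MI_R", "SII_R", "alpha"),
        c("MF_L", "PCC_L", "beta"),
        c("IP_R", "LT_R", "gamma"),
        c("Ins_L", "MF_L", "beta"),
        c("Ins_R", "PCC_R", "gamma"),
    )


def training_cohort_config(
    seed: int,
    duration: float = 300.0,
    n_hc: int = 56,
    n_cm: int = 80,
    couplings: tuple[CouplingSpec, ...] | None = None,
) -> CohortConfig:
    """Default study-regime config: HC/CM sizes of the training cohort."""
    return CohortConfig(
        groups={"HC": n_hc, "CM": n_cm},
        duration=duration,
        couplings=couplings if couplings is not None else default_study_couplings(),
        seed=seed,
    )
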