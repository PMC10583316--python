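"""Study networks, node strength, and feature-table assembly.

Five resting-state networks are defined over bilateral cortical ROIs:

* **PN** (pain-related): primary motor (MI), primary somatosensory (SI),
  secondary somatosensory (SII), anterior cingulate (ACC), insula.
* **DMN** (default mode): medial frontal (MF), inferior parietal (IP),
  posterior cingulate (PCC), lateral temporal (LT), medial temporal (MT);
  an optional toggle adds the precuneus (Prc).
* **SMN** (sensorimotor): SI, SII, MI.
* **VN** (visual): primary visual cortex (V1).
* **Ins-DMN**: bipartite insula <-> DMN coupling (only edges joining an
  insula node to a DMN node count).

The node strength of ROI r within a network is the sum of the connectivity
values between r and its co-members (for bipartite networks, members of the
opposite part).  One feature column exists per (network, band, ROI) triple;
an ROI shared between networks (e.g. SI in PN and SMN) contributes a
separate column per network because its co-member set differs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, InputError
from .spectral_connectivity import BandConnectivity

FEATURE_ID_SEP = "|"


def bilateral(region: str) -> tuple[str, str]:
    """Left/right labels for a bilateral region, e.g. 'MI' -> ('MI_L', 'MI_R')."""
    return (f"{region}_L", f"{region}_R")


@dataclass(frozen=True)
class NetworkCatalog:
    """Mapping network name -> ordered member ROI labels.

    ``bipartite`` maps a network name to its two disjoint parts; node
    strengths in such a network sum only over the opposite part.
    """

    networks: Mapping[str, tuple[str, ...]]
    bipartite: Mapping[str, tuple[tuple[str, ...], tuple[str, ...]]] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        for name, members in self.networks.items():
            if len(members) < 2:
                raise ConfigurationError(f"network {name!r} needs >= 2 ROIs")
            if len(set(members)) != len(members):
                raise ConfigurationError(f"network {name!r} has duplicate ROIs")
        for name, (a, b) in self.bipartite.items():
            if name not in self.networks:
                raise ConfigurationError(f"bipartite spec for unknown network {name!r}")
            if set(a) & set(b):
                raise ConfigurationError(f"bipartite parts of {name!r} overlap")
            if tuple(a) + tuple(b) != tuple(self.networks[name]):
                raise ConfigurationError(
                    f"bipartite parts of {name!r} must concatenate to its member list"
                )

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.networks)

    def members(self, network: str) -> tuple[str, ...]:
        try:
            return tuple(self.networks[network])
        except KeyError:
            raise ConfigurationError(f"unknown network {network!r}") from None

    def edges(self, network: str) -> list[tuple[str, str]]:
        """Unordered ROI pairs forming the network's edge set."""
        members = self.members(network)
        if network in self.bipartite:
            part_a, part_b = self.bipartite[network]
            return [(a, b) for a in part_a for b in part_b]
        return [
            (members[i], members[j])
            for i in range(len(members))
            for j in range(i + 1, len(members))
        ]


def default_roi_labels(include_precuneus: bool = False) -> tuple[str, ...]:
    """The 22 bilateral cortical ROI labels (24 with the precuneus toggle)."""
    regions = ["MI", "SI", "SII", "ACC", "Ins", "MF", "IP", "PCC", "LT", "MT", "V1"]
    if include_precuneus:
        regions.append("Prc")
    labels: list[str] = []
    for region in regions:
        labels.extend(bilateral(region))
    return tuple(labels)


def default_network_catalog(include_precuneus: bool = False) -> NetworkCatalog:
    """The five study networks over the default ROI catalog."""
    def bl(*regions: str) -> tuple[str, ...]:
        out: list[str] = []
        for r in regions:
            out.extend(bilateral(r))
        return tuple(out)

    dmn_regions = ["MF", "IP", "PCC", "LT", "MT"]
    if include_precuneus:
        dmn_regions.append("Prc")
    dmn = bl(*dmn_regions)
    insula = bilateral("Ins")
    networks = {
        "PN": bl("MI", "SI", "SII", "ACC", "Ins"),
        "DMN": dmn,
        "SMN": bl("SI", "SII", "MI"),
        "VN": bl("V1"),
        "Ins-DMN": tuple(insula) + dmn,
    }
    return NetworkCatalog(networks=networks, bipartite={"Ins-DMN": (tuple(insula), dmn)})


@dataclass(frozen=True)
class FeatureIndex:
    """Ordered (network, band, roi) triples with stable string ids.

    Ordering is network (catalog order), then band (band-book order),
    then ROI (network member order).
    """

    triples: tuple[tuple[str, str, str], ...]

    def __post_init__(self) -> None:
        if len(set(self.ids)) != len(self.triples):
            raise ConfigurationError("feature ids are not unique")

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(FEATURE_ID_SEP.join(t) for t in self.triples)

    def __len__(self) -> int:
        return len(self.triples)

    @classmethod
    def build(cls, catalog: NetworkCatalog, bands: Sequence[str]) -> "FeatureIndex":
        triples = [
            (net, band, roi)
            for net in catalog.names
            for band in bands
            for roi in catalog.members(net)
        ]
        return cls(triples=tuple(triples))

    @classmethod
    def from_ids(cls, ids: Sequence[str]) -> "FeatureIndex":
        return cls(triples=tuple(tuple(i.split(FEATURE_ID_SEP)) for i in ids))

    def positions(self, ids: Sequence[str]) -> np.ndarray:
        lookup = {fid: k for k, fid in enumerate(self.ids)}
        try:
            return np.array([lookup[i] for i in ids], dtype=int)
        except KeyError as exc:
            raise InputError(f"feature id {exc.args[0]!r} not in index") from None


@dataclass
class FeatureTable:
    """Subjects x node-strength features with group labels."""

    data: np.ndarray  # (n_subjects, n_features)
    subject_ids: tuple[str, ...]
    groups: tuple[str, ...]
    index: FeatureIndex

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape != (len(self.subject_ids), len(self.index)):
            raise InputError(
                f"feature matrix shape {self.data.shape} does not match "
                f"{len(self.subject_ids)} subjects x {len(self.index)} features"
            )
        if len(self.subject_ids) != len(self.groups):
            raise InputError("subject_ids and groups length mismatch")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    def group_names(self) -> tuple[str, ...]:
        seen: list[str] = []
        for g in self.groups:
            if g not in seen:
                seen.append(g)
        return tuple(seen)

    def rows_for_group(self, group: str) -> np.ndarray:
        mask = np.array([g == group for g in self.groups])
        if not mask.any():
            raise InputError(f"group {group!r} absent from table")
        return mask

    def with_groups(self, groups: Sequence[str]) -> "FeatureTable":
        return FeatureTable(
            data=self.data, subject_ids=self.subject_ids, groups=tuple(groups),
            index=self.index,
        )

    def select_ids(self, ids: Sequence[str]) -> "FeatureTable":
        """Column subset by feature id (order of ``ids`` preserved)."""
        pos = self.index.positions(ids)
        return FeatureTable(
            data=self.data[:, pos],
            subject_ids=self.subject_ids,
            groups=self.groups,
            index=FeatureIndex(tuple(self.index.triples[p] for p in pos)),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.data, columns=list(self.index.ids))
        df.insert(0, "group", list(self.groups))
        df.insert(0, "subject_id", list(self.subject_ids))
        return df

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureTable":
        df = pd.read_csv(path)
        feature_cols = [c for c in df.columns if c not in ("subject_id", "group")]
        return cls(
            data=df[feature_cols].to_numpy(dtype=float),
            subject_ids=tuple(str(s) for s in df["subject_id"]),
            groups=tuple(str(g) for g in df["group"]),
            index=FeatureIndex.from_ids(feature_cols),
        )


def node_strength(
    conn: BandConnectivity, network: str, catalog: NetworkCatalog
) -> pd.DataFrame:
    """Per-ROI node strengths for one network, rows = member ROIs,
    columns = bands.

    strength(r) = sum over co-members r' != r of conn[r, r'] (bipartite
    networks sum only over the opposite part; both parts are reported).
    """
    members = catalog.members(network)
    label_pos = {lab: i for i, lab in enumerate(conn.roi_labels)}
    missing = [m for m in members if m not in label_pos]
    if missing:
        raise ConfigurationError(
            f"network {network!r} members {missing} absent from connectivity matrix"
        )
    out = np.zeros((len(members), len(conn.bands)))
    if network in catalog.bipartite:
        part_a, part_b = catalog.bipartite[network]
        opposite = {m: (part_b if m in part_a else part_a) for m in members}
    else:
        opposite = {m: tuple(x for x in members if x != m) for m in members}
    for bi, band in enumerate(conn.bands):
        mat = conn[band]
        for mi, m in enumerate(members):
            cols = [label_pos[o] for o in opposite[m]]
            out[mi, bi] = mat[label_pos[m], cols].sum()
    return pd.DataFrame(out, index=list(members), columns=list(conn.bands))


def assemble_features(
    connectivities: Sequence[BandConnectivity],
    subject_ids: Sequence[str],
    groups: Sequence[str],
    catalog: NetworkCatalog | None = None,
) -> FeatureTable:
    """Stack per-subject band connectivity into a node-strength feature table."""
    if not connectivities:
        raise InputError("empty cohort")
    if not (len(connectivities) == len(subject_ids) == len(groups)):
        raise InputError("connectivities, subject_ids and groups length mismatch")
    catalog = catalog or default_network_catalog()
    bands = connectivities[0].bands
    for conn in connectivities[1:]:
        if conn.bands != bands:
            raise InputError("subjects disagree on band set")
        if conn.roi_labels != connectivities[0].roi_labels:
            raise InputError("subjects disagree on ROI labels")
    index = FeatureIndex.build(catalog, bands)
    data = np.empty((len(connectivities), len(index)))
    for si, conn in enumerate(connectivities):
        col = 0
        for net in catalog.names:
            strengths = node_strength(conn, net, catalog)  # members x bands
            for band in bands:
                vals = strengths[band].to_numpy()
                data[si, col : col + len(vals)] = vals
                col += len(vals)
        assert col == len(index)
    return FeatureTable(
        data=data,
        subject_ids=tuple(str(s) for s in subject_ids),
        groups=tuple(str(g) for g in groups),
        index=index,
    )


def subset_by_networks(table: FeatureTable, combo: Sequence[str]) -> FeatureTable:
    """Restrict columns to the given networks, preserving column order."""
    known = {t[0] for t in table.index.triples}
    for net in combo:
        if net not in known:
            raise ConfigurationError(f"unknown network {net!r} in combination")
    keep = [k for k, t in enumerate(table.index.triples) if t[0] in set(combo)]
    return FeatureTable(
        data=table.data[:, keep],
        subject_ids=table.subject_ids,
        groups=table.groups,
        index=FeatureIndex(tuple(table.index.triples[k] for k in keep)),
    )
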