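"""Construction of 24-node anterior/posterior hippocampal connectomes.

Nodes are the anterior and posterior hippocampal segments plus their
hemisphere-specific target regions: the anterior hippocampal network (AHN)
holds 8 nodes (anterior hippocampus, temporal pole, anterior parahippocampal
gyrus, frontal orbital cortex; left and right), the posterior hippocampal
network (PHN) holds 16 (posterior hippocampus, posterior parahippocampal
gyrus, posterior cingulate, precuneus, middle frontal gyrus, lingual gyrus,
temporal-occipital fusiform cortex, thalamus; left and right).

Edges are Fisher r-to-z transformed Pearson correlations between node
eigenvariates with negative edges set to zero, giving a symmetric,
non-negative, zero-diagonal 24 x 24 matrix per subject.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .extraction import (
    BoldVolume,
    DegenerateInputError,
    EigenSeries,
    RoiMask,
    extract_eigen_series,
)

__all__ = [
    "NetworkPartition",
    "ConnectivityMatrix",
    "DEFAULT_PARTITION",
    "fisher_z",
    "node_eigenvariates",
    "build_subject_matrix",
    "group_mean_matrix",
]

#: clip |r| below 1 so atanh stays finite for (near-)duplicated series
R_CLIP = 1.0 - 1e-7

_AHN_REGIONS = ("HIPa", "TP", "PHa", "FOC")
_PHN_REGIONS = ("HIPp", "PHp", "CGp", "PCN", "MFG", "LG", "TOF", "Thal")


@dataclass(frozen=True)
class NetworkPartition:
    """Ordered node list with AHN/PHN membership.

    ``nodes`` are ``(label, hemisphere, network)`` triples; the canonical
    order is the AHN block first, left hemisphere before right within each
    region, then the PHN block.
    """

    nodes: tuple[tuple[str, str, str], ...]

    def __post_init__(self) -> None:
        nets = [n[2] for n in self.nodes]
        if len(self.nodes) != 24 or nets.count("AHN") != 8 or nets.count("PHN") != 16:
            raise ValueError("partition must have exactly 8 AHN and 16 PHN nodes")
        labels = [f"{n[0]}_{n[1]}" for n in self.nodes]
        if len(set(labels)) != 24:
            raise ValueError("duplicate node labels in partition")

    @property
    def labels(self) -> list[str]:
        return [f"{region}_{hemi}" for region, hemi, _ in self.nodes]

    @property
    def n_ahn(self) -> int:
        return 8

    @property
    def n_phn(self) -> int:
        return 16

    def network_indices(self, network: str) -> np.ndarray:
        return np.array([i for i, n in enumerate(self.nodes) if n[2] == network], dtype=int)


def _default_partition() -> NetworkPartition:
    nodes = []
    for region in _AHN_REGIONS:
        for hemi in ("L", "R"):
            nodes.append((region, hemi, "AHN"))
    for region in _PHN_REGIONS:
        for hemi in ("L", "R"):
            nodes.append((region, hemi, "PHN"))
    return NetworkPartition(tuple(nodes))


DEFAULT_PARTITION = _default_partition()


@dataclass
class ConnectivityMatrix:
    """A 24 x 24 non-negative Fisher-z connectivity matrix."""

    z: np.ndarray
    subject_id: str
    partition: NetworkPartition = field(default_factory=_default_partition)

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        n = len(self.partition.nodes)
        if self.z.shape != (n, n):
            raise ValueError(f"matrix shape {self.z.shape} != ({n}, {n})")
        if not np.all(np.isfinite(self.z)):
            raise ValueError("matrix contains non-finite entries")
        if not np.allclose(self.z, self.z.T):
            raise ValueError("matrix is not symmetric")
        if np.any(np.diag(self.z) != 0):
            raise ValueError("matrix diagonal must be zero")
        if np.any(self.z < 0):
            raise ValueError("negative edges must be removed")


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """Fisher r-to-z (atanh) with clipping so r = +/-1 stays finite."""
    return np.arctanh(np.clip(r, -R_CLIP, R_CLIP))


def node_eigenvariates(
    volume: BoldVolume,
    masks: dict[str, RoiMask],
    partition: NetworkPartition = DEFAULT_PARTITION,
) -> list[EigenSeries]:
    """Extract one eigenvariate per node, in partition order.

    ``masks`` maps node labels (e.g. ``"HIPa_L"``) to (already gray-matter
    confined) masks; a missing or empty node mask raises naming the node.
    """
    series = []
    for label in partition.labels:
        if label not in masks:
            raise KeyError(f"no mask provided for node {label!r}")
        mask = masks[label]
        if mask.n_voxels == 0:
            raise DegenerateInputError(f"node {label!r} has an empty mask")
        series.append(extract_eigen_series(volume, mask))
    return series


def build_subject_matrix(
    series: list[EigenSeries],
    subject_id: str = "",
    partition: NetworkPartition = DEFAULT_PARTITION,
) -> ConnectivityMatrix:
    """Correlate node eigenvariates, Fisher-transform, zero negative edges."""
    n = len(partition.nodes)
    if len(series) != n:
        raise ValueError(f"expected {n} eigenvariates, got {len(series)}")
    lengths = {len(s.values) for s in series}
    if len(lengths) != 1:
        raise ValueError("eigenvariates differ in length")
    if lengths.pop() < 4:
        raise ValueError("need at least 4 timepoints")
    X = np.column_stack([s.values for s in series])
    if np.any(X.std(axis=0) == 0):
        raise DegenerateInputError("constant eigenvariate series")
    r = np.corrcoef(X, rowvar=False)
    z = fisher_z(r)
    z = np.maximum(z, 0.0)
    np.fill_diagonal(z, 0.0)
    z = (z + z.T) / 2  # symmetrize away float round-off
    return ConnectivityMatrix(z=z, subject_id=subject_id, partition=partition)


def matrix_from_node_series(
    node_series: np.ndarray,
    subject_id: str = "",
    partition: NetworkPartition = DEFAULT_PARTITION,
) -> ConnectivityMatrix:
    """Build a connectivity matrix directly from a (t, 24) node-signal array.

    Used by simulation studies that work at the node-signal level and skip
    the voxel/eigenvariate stage.
    """
    series = [
        EigenSeries(values=node_series[:, i], source_label=lab)
        for i, lab in enumerate(partition.labels)
    ]
    return build_subject_matrix(series, subject_id=subject_id, partition=partition)


def group_mean_matrix(matrices: list[ConnectivityMatrix], label: str = "group") -> ConnectivityMatrix:
    """Elementwise mean of per-subject matrices sharing one partition."""
    if not matrices:
        raise ValueError("need at least one matrix")
    part = matrices[0].partition
    for m in matrices[1:]:
        if m.partition.labels != part.labels:
            raise ValueError("matrices use different node orders")
    z = np.mean([m.z for m in matrices], axis=0)
    return ConnectivityMatrix(z=z, subject_id=label, partition=part)
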