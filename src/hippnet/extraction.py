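"""Representative time-series extraction from masked BOLD data.

The pipeline summarises every region of interest by its *major eigenvariate*:
the single time series capturing the maximum variance of the in-mask voxel
series, i.e. the first temporal principal component of the demeaned
time x voxel matrix.  Compared with the plain mask mean it down-weights
voxels whose series are dominated by noise or partial-volume contamination.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "BoldVolume",
    "RoiMask",
    "EigenSeries",
    "DegenerateInputError",
    "confine_to_gray_matter",
    "extract_eigen_series",
    "mean_series",
]


class DegenerateInputError(ValueError):
    """Raised for empty masks, constant voxel series, or rank-0 data."""


@dataclass
class BoldVolume:
    """A preprocessed 4D BOLD volume on a fixed voxel grid.

    Parameters
    ----------
    data
        Array of shape ``(x, y, z, t)``; all values finite, ``t >= 4``.
    voxel_size
        Voxel edge lengths in mm.
    t_r
        Repetition time in seconds.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (3.0, 3.0, 3.0)
    t_r: float = 2.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"BOLD data must be 4D (x, y, z, t), got shape {self.data.shape}")
        if self.data.shape[3] < 4:
            raise ValueError(f"need at least 4 timepoints, got {self.data.shape[3]}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("BOLD data contains non-finite values")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]


@dataclass
class RoiMask:
    """A binary 3D mask on the volume's spatial grid."""

    data: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError(f"mask {self.label!r} must be 3D, got shape {self.data.shape}")

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def __and__(self, other: "RoiMask") -> "RoiMask":
        return RoiMask(self.data & other.data, label=f"{self.label}&{other.label}")

    def __or__(self, other: "RoiMask") -> "RoiMask":
        return RoiMask(self.data | other.data, label=f"{self.label}|{other.label}")


@dataclass
class EigenSeries:
    """A mask's major eigenvariate, scaled to unit sample variance.

    ``variance_explained`` is the share of total in-mask variance captured by
    the first principal component (first squared singular value over the sum).
    """

    values: np.ndarray
    source_label: str = ""
    variance_explained: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if not 0.0 <= self.variance_explained <= 1.0 + 1e-12:
            raise ValueError(f"variance_explained outside [0,1]: {self.variance_explained}")


def confine_to_gray_matter(mask: RoiMask, gm_probability: np.ndarray, threshold: float = 0.2) -> RoiMask:
    """Restrict ``mask`` to voxels whose gray-matter probability is >= ``threshold``.

    Raises :class:`DegenerateInputError` (naming the mask) if nothing survives.
    """
    gm = np.asarray(gm_probability, dtype=float)
    if gm.shape != mask.data.shape:
        raise ValueError(f"gray-matter map shape {gm.shape} != mask shape {mask.data.shape}")
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"gray-matter threshold must be in [0,1], got {threshold}")
    confined = mask.data & (gm >= threshold)
    if not confined.any():
        raise DegenerateInputError(
            f"mask {mask.label!r} is empty after gray-matter confinement at threshold {threshold}"
        )
    return RoiMask(confined, label=mask.label)


def _in_mask_matrix(volume: BoldVolume, mask: RoiMask) -> np.ndarray:
    """Return the time x voxel matrix of in-mask series."""
    if mask.data.shape != volume.grid_shape:
        raise ValueError(
            f"mask {mask.label!r} shape {mask.data.shape} != volume grid {volume.grid_shape}"
        )
    if mask.n_voxels == 0:
        raise DegenerateInputError(f"mask {mask.label!r} is empty")
    return volume.data[mask.data].T  # (t, v)


def mean_series(volume: BoldVolume, mask: RoiMask) -> np.ndarray:
    """Arithmetic mean over in-mask voxels at each timepoint."""
    return _in_mask_matrix(volume, mask).mean(axis=1)


def extract_eigen_series(
    volume: BoldVolume,
    mask: RoiMask,
    *,
    normalize_voxels: bool = False,
) -> EigenSeries:
    """Extract the major eigenvariate of the in-mask voxel series.

    Each voxel series is demeaned over time (optionally also scaled to unit
    variance when ``normalize_voxels``), the time x voxel matrix is decomposed
    by SVD, and the first left singular vector times its singular value is
    returned rescaled to unit sample variance.  The sign is fixed so the
    eigenvariate correlates non-negatively with the mask mean series (first
    nonzero entry positive if that correlation is exactly zero).
    """
    X = _in_mask_matrix(volume, mask).astype(float)
    X = X - X.mean(axis=0, keepdims=True)
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = int(np.sum(sd == 0))
        raise DegenerateInputError(
            f"mask {mask.label!r} contains {bad} constant voxel series"
        )
    if normalize_voxels:
        X = X / sd
    u, s, _ = np.linalg.svd(X, full_matrices=False)
    if s[0] == 0:
        raise DegenerateInputError(f"mask {mask.label!r}: in-mask data has rank 0")
    pc = u[:, 0] * s[0]
    var_explained = float(s[0] ** 2 / np.sum(s**2))

    m = X.mean(axis=1)
    c = float(pc @ m)
    if c < 0:
        pc = -pc
    elif c == 0 and pc[np.nonzero(pc)[0][0]] < 0:
        pc = -pc
    pc = pc / pc.std(ddof=1)
    return EigenSeries(values=pc, source_label=mask.label, variance_explained=var_explained)
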