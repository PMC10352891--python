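"""Data-driven anterior/posterior segmentation of the hippocampus.

Each hippocampal voxel is correlated with the eigenvariates of two combined
target masks — one built from regions preferentially connected to the
anterior hippocampus (temporal pole, anterior parahippocampal gyrus, frontal
orbital cortex) and one from regions affiliated with the posterior
hippocampus — using *partial* correlations, each controlling for the other
target's eigenvariate.  A voxel with anterior partial correlation r1
exceeding posterior partial correlation r2 is labelled anterior, otherwise
posterior (winner-take-all); subtraction maps (r1 - r2) summed over subjects
and binarized at zero give group-level divisions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .extraction import (
    BoldVolume,
    DegenerateInputError,
    EigenSeries,
    RoiMask,
    extract_eigen_series,
)

__all__ = [
    "TargetPair",
    "PartialCorrelationMaps",
    "SubtractionMap",
    "HippocampalDivision",
    "partial_correlation",
    "compute_partial_maps",
    "subject_division",
    "group_division",
    "division_volume_compare",
]

ANTERIOR, POSTERIOR = 1, 2


@dataclass
class TargetPair:
    """The two combined target masks driving the winner-take-all split."""

    anterior_target: RoiMask
    posterior_target: RoiMask

    def __post_init__(self) -> None:
        if (self.anterior_target.data & self.posterior_target.data).any():
            raise ValueError("anterior and posterior target masks overlap")

    def check_disjoint_from(self, hippocampal_mask: RoiMask) -> None:
        for t in (self.anterior_target, self.posterior_target):
            if (t.data & hippocampal_mask.data).any():
                raise ValueError(f"target mask {t.label!r} overlaps the hippocampal mask")


@dataclass
class PartialCorrelationMaps:
    """Per-hippocampal-voxel partial correlations r1 (anterior), r2 (posterior).

    Values are stored on the flattened in-mask voxel order of ``mask``;
    ``valid`` flags voxels with usable (non-constant) series.
    """

    r1: np.ndarray
    r2: np.ndarray
    mask: RoiMask
    valid: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        n = self.mask.n_voxels
        if len(self.r1) != n or len(self.r2) != n:
            raise ValueError("map length does not match hippocampal mask size")
        ok = self.valid
        if np.any(np.abs(self.r1[ok]) > 1 + 1e-9) or np.any(np.abs(self.r2[ok]) > 1 + 1e-9):
            raise ValueError("partial correlations outside [-1, 1]")


@dataclass
class SubtractionMap:
    """Per-voxel r1 - r2 for one subject, on the hippocampal mask support."""

    values: np.ndarray
    mask: RoiMask
    subject_id: str = ""


@dataclass
class HippocampalDivision:
    """Exhaustive anterior/posterior labelling of the hippocampal mask.

    ``labels`` is aligned with the flattened in-mask voxel order; 1 denotes
    anterior, 2 posterior.
    """

    labels: np.ndarray
    mask: RoiMask
    level: str = "subject"  # "subject" | "group"

    def __post_init__(self) -> None:
        if len(self.labels) != self.mask.n_voxels:
            raise ValueError("labels do not cover the hippocampal mask")
        if not np.isin(self.labels, [ANTERIOR, POSTERIOR]).all():
            raise ValueError("labels must be 1 (anterior) or 2 (posterior)")

    def label_volume(self) -> np.ndarray:
        vol = np.zeros(self.mask.data.shape, dtype=np.uint8)
        vol[self.mask.data] = self.labels
        return vol

    def segment_mask(self, segment: str) -> RoiMask:
        code = ANTERIOR if segment == "anterior" else POSTERIOR
        vol = self.label_volume()
        return RoiMask(vol == code, label=f"hippocampus_{segment}")


def partial_correlation(x: np.ndarray, y: np.ndarray, control: np.ndarray) -> float:
    """First-order partial correlation of x and y controlling for one series.

    Computed by the recursion
    ``(r_xy - r_xc * r_yc) / sqrt((1 - r_xc^2)(1 - r_yc^2))``, which equals
    the Pearson correlation of the residuals of x and y after regressing each
    on the control.
    """
    x, y, control = (np.asarray(v, dtype=float).ravel() for v in (x, y, control))
    n = len(x)
    if not (len(y) == len(control) == n) or n < 4:
        raise ValueError("series must share a common length >= 4")
    for name, v in (("x", x), ("y", y), ("control", control)):
        if np.std(v) == 0:
            raise DegenerateInputError(f"{name} series is constant")
    r = np.corrcoef(np.vstack([x, y, control]))
    r_xy, r_xc, r_yc = r[0, 1], r[0, 2], r[1, 2]
    denom = (1 - r_xc**2) * (1 - r_yc**2)
    if denom <= 0:
        raise DegenerateInputError("control series is collinear with x or y")
    return float((r_xy - r_xc * r_yc) / np.sqrt(denom))


def _bulk_partial(V: np.ndarray, e1: np.ndarray, e2: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized r1 = pcorr(voxel, e1 | e2), r2 = pcorr(voxel, e2 | e1).

    ``V`` is the time x voxel matrix.  Returns (r1, r2, valid).
    """
    t = V.shape[0]
    Vc = V - V.mean(axis=0, keepdims=True)
    sd = Vc.std(axis=0)
    valid = sd > 0
    sd_safe = np.where(valid, sd, 1.0)
    Vn = Vc / (sd_safe * np.sqrt(t))

    def unit(e: np.ndarray) -> np.ndarray:
        ec = e - e.mean()
        return ec / (np.linalg.norm(ec))

    u1, u2 = unit(e1), unit(e2)
    r12 = float(u1 @ u2)
    if abs(r12) >= 1.0 - 1e-12:
        raise DegenerateInputError("target eigenvariates are collinear")
    # Vn columns and u's have unit norm -> dot products are plain correlations
    rv1 = Vn.T @ u1
    rv2 = Vn.T @ u2
    denom = np.sqrt((1 - rv1**2).clip(min=0) * (1 - r12**2))
    denom2 = np.sqrt((1 - rv2**2).clip(min=0) * (1 - r12**2))
    with np.errstate(divide="ignore", invalid="ignore"):
        r1 = np.where(denom2 > 0, (rv1 - rv2 * r12) / np.where(denom2 > 0, denom2, 1.0), 0.0)
        r2 = np.where(denom > 0, (rv2 - rv1 * r12) / np.where(denom > 0, denom, 1.0), 0.0)
    r1 = np.clip(r1, -1.0, 1.0)
    r2 = np.clip(r2, -1.0, 1.0)
    return r1, r2, valid


def compute_partial_maps(
    volume: BoldVolume,
    hippocampal_mask: RoiMask,
    targets: TargetPair,
    subject_id: str = "",
    target_series: tuple[EigenSeries, EigenSeries] | None = None,
) -> PartialCorrelationMaps:
    """Voxel-wise partial-correlation maps of the hippocampus.

    ``target_series`` may carry precomputed target eigenvariates (the pair is
    otherwise extracted here).  Voxels with constant series are flagged
    invalid and excluded from labelling rather than silently classified.
    """
    targets.check_disjoint_from(hippocampal_mask)
    if target_series is None:
        e1 = extract_eigen_series(volume, targets.anterior_target)
        e2 = extract_eigen_series(volume, targets.posterior_target)
    else:
        e1, e2 = target_series
    V = volume.data[hippocampal_mask.data].T.astype(float)
    r1, r2, valid = _bulk_partial(V, e1.values, e2.values)
    return PartialCorrelationMaps(r1=r1, r2=r2, mask=hippocampal_mask, valid=valid, subject_id=subject_id)


def subject_division(maps: PartialCorrelationMaps) -> tuple[HippocampalDivision, SubtractionMap]:
    """Winner-take-all labels (ties -> posterior) and the subtraction map."""
    diff = maps.r1 - maps.r2
    labels = np.where(diff > 0, ANTERIOR, POSTERIOR).astype(np.uint8)
    division = HippocampalDivision(labels=labels, mask=maps.mask, level="subject")
    sub = SubtractionMap(values=diff, mask=maps.mask, subject_id=maps.subject_id)
    return division, sub


def group_division(maps: list[SubtractionMap]) -> HippocampalDivision:
    """Sum subject subtraction maps and binarize at zero (ties -> posterior)."""
    if not maps:
        raise ValueError("need at least one subtraction map")
    support = maps[0].mask
    for m in maps[1:]:
        if not np.array_equal(m.mask.data, support.data):
            raise ValueError("subtraction maps have mismatched voxel supports")
    total = np.sum([m.values for m in maps], axis=0)
    labels = np.where(total > 0, ANTERIOR, POSTERIOR).astype(np.uint8)
    return HippocampalDivision(labels=labels, mask=support, level="group")


def division_volume_compare(
    div_a: HippocampalDivision, div_b: HippocampalDivision
) -> dict[str, dict[str, float]]:
    """Per-label voxel counts and Dice overlap between two divisions."""
    if not np.array_equal(div_a.mask.data, div_b.mask.data):
        raise ValueError("divisions are on different supports")
    out: dict[str, dict[str, float]] = {}
    for name, code in (("anterior", ANTERIOR), ("posterior", POSTERIOR)):
        a = div_a.labels == code
        b = div_b.labels == code
        na, nb = int(a.sum()), int(b.sum())
        inter = int((a & b).sum())
        dice = 2 * inter / (na + nb) if (na + nb) > 0 else 1.0
        out[name] = {"count_a": na, "count_b": nb, "intersection": inter, "dice": dice}
    return out
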