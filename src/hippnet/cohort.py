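"""Synthetic two-group BOLD cohort with planted ground truth.

The generator emulates preprocessed (band-pass filtered, nuisance-regressed)
resting-state data for a case/control study of the anterior and posterior
hippocampal networks:

* 24 latent node signals per subject, drawn from a block-structured
  correlation model — within-network coupling ``rho_intra`` (raised by
  ``delta_intra`` in patients), between-network coupling ``rho_inter`` —
  built as a factor model (shared global factor + network factor +
  idiosyncratic noise) so the correlation matrix is positive semidefinite by
  construction;
* a bilateral hippocampal mask partitioned along the long axis (the grid's
  second axis, posterior -> anterior increasing) at ``anterior_fraction``,
  whose voxels load on the anterior or posterior hippocampal latent signal
  of their hemisphere according to the planted partition;
* 20 cortical/subcortical target-region masks whose voxels load on their
  region's latent signal;
* i.i.d. Gaussian voxel noise with standard deviation ``1/snr`` relative to
  the unit-variance latent signals.

Everything is deterministic given the configuration seed; per-subject RNG
streams are derived from ``(seed, subject_id)`` so generation order does not
matter.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .extraction import BoldVolume, RoiMask
from .network import DEFAULT_PARTITION, NetworkPartition

__all__ = [
    "CohortConfig",
    "SubjectRecord",
    "GroundTruth",
    "Cohort",
    "build_latent_correlation",
    "sample_node_series",
    "generate_subject",
    "generate_cohort",
]

MIN_GRID = (24, 28, 24)

# 3x3x3 region boxes: label -> (y0, z0); x range is hemisphere-specific.
# Anterior-affiliated targets sit at high y (anterior), posterior ones lower.
_REGION_SLOTS = {
    "TP": (22, 3),
    "PHa": (22, 15),
    "FOC": (17, 3),
    "PHp": (17, 15),
    "CGp": (12, 3),
    "PCN": (12, 15),
    "MFG": (7, 3),
    "LG": (7, 15),
    "TOF": (2, 3),
    "Thal": (2, 15),
}
_REGION_X = {"L": (1, 4), "R": (20, 23)}
_HIPP_X = {"L": (4, 8), "R": (16, 20)}
_HIPP_Y = (6, 18)
_HIPP_Z = (8, 11)

ANTERIOR_TARGET_REGIONS = ("TP", "PHa", "FOC")
POSTERIOR_TARGET_REGIONS = ("PHp", "CGp", "PCN", "MFG", "LG", "TOF", "Thal")


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for the synthetic cohort.

    ``snr`` is the ratio of voxel signal sd to voxel noise sd; latent node
    signals have unit variance, so voxel noise has sd ``1/snr``.
    """

    n_controls: int = 20
    n_patients: int = 20
    n_timepoints: int = 144  # volumes after discarding initial scans
    tr_seconds: float = 2.0
    grid_shape: tuple[int, int, int] = MIN_GRID
    snr: float = 1.0
    rho_intra: float = 0.5
    rho_inter: float = 0.2
    delta_intra: float = 0.1
    anterior_fraction: float = 1.0 / 3.0
    seed: int = 0
    # covariate model
    p_male: float = 0.7
    age_mean: float = 37.0
    age_sd: float = 12.0
    age_bounds: tuple[float, float] = (18.0, 65.0)
    # optional cognitive-style score coupled to realized intranetwork strength
    score_name: str = "mccb_composite"
    score_coupling: float = 0.0
    # extra patient-only correlation increment on named node pairs
    effect_edges: tuple[tuple[str, str], ...] = ()
    effect_size: float = 0.0

    def validate(self) -> None:
        if self.n_controls < 0 or self.n_patients < 0:
            raise ValueError("group sizes must be non-negative")
        if self.n_timepoints < 8:
            raise ValueError("n_timepoints must be at least 8 (>= 2x nuisance regressors)")
        if not (0 <= self.rho_inter <= self.rho_intra < 1):
            raise ValueError("require 0 <= rho_inter <= rho_intra < 1")
        if self.delta_intra < 0:
            raise ValueError("delta_intra must be non-negative")
        if self.rho_intra + self.delta_intra >= 1:
            raise ValueError("rho_intra + delta_intra must stay below 1")
        if not 0 < self.anterior_fraction < 1:
            raise ValueError("anterior_fraction must lie in (0, 1)")
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        if any(g < m for g, m in zip(self.grid_shape, MIN_GRID)):
            raise ValueError(
                f"grid {self.grid_shape} too small for the mask layout (need >= {MIN_GRID})"
            )


@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    group: str  # "control" | "patient"
    age: float
    gender: str  # "male" | "female"
    scores: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in ("control", "patient"):
            raise ValueError(f"unknown group {self.group!r}")
        if not np.isfinite(self.age) or self.age <= 0:
            raise ValueError(f"age must be finite and positive, got {self.age}")


@dataclass
class GroundTruth:
    """Planted truth for downstream recovery checks.

    ``voxel_labels`` is a 3D uint8 array: 0 outside the hippocampus,
    1 anterior, 2 posterior.  ``latent_correlations`` maps group to its
    24 x 24 latent node correlation matrix; ``planted_effect_edges`` lists the
    unordered node-label pairs whose correlation differs between groups.
    """

    voxel_labels: np.ndarray
    latent_correlations: dict[str, np.ndarray]
    planted_effect_edges: list[tuple[str, str]]

    def to_json(self) -> str:
        return json.dumps(
            {
                "voxel_labels_shape": list(self.voxel_labels.shape),
                "anterior_voxels": np.argwhere(self.voxel_labels == 1).tolist(),
                "posterior_voxels": np.argwhere(self.voxel_labels == 2).tolist(),
                "latent_correlations": {
                    g: np.round(m, 10).tolist() for g, m in self.latent_correlations.items()
                },
                "planted_effect_edges": [list(e) for e in self.planted_effect_edges],
            }
        )


def build_latent_correlation(
    config: CohortConfig,
    group: str,
    partition: NetworkPartition = DEFAULT_PARTITION,
) -> np.ndarray:
    """24 x 24 latent node correlation matrix for one group.

    Within-network entries equal ``rho_intra`` (plus ``delta_intra`` for
    patients), cross-network entries equal ``rho_inter``; patient-only
    ``effect_edges`` receive an extra ``effect_size``.  The base matrix comes
    from a factor model and is PSD by construction; after edge-specific
    increments the matrix is re-checked and rejected if not PSD.
    """
    config.validate()
    if group not in ("control", "patient"):
        raise ValueError(f"unknown group {group!r}")
    rho_within = config.rho_intra + (config.delta_intra if group == "patient" else 0.0)
    n = len(partition.nodes)
    networks = np.array([node[2] for node in partition.nodes])
    same_net = networks[:, None] == networks[None, :]
    C = np.where(same_net, rho_within, config.rho_inter).astype(float)
    np.fill_diagonal(C, 1.0)

    if group == "patient" and config.effect_edges:
        labels = partition.labels
        for a, b in config.effect_edges:
            if a not in labels or b not in labels:
                raise ValueError(f"effect edge ({a}, {b}) names unknown nodes")
            i, j = labels.index(a), labels.index(b)
            C[i, j] += config.effect_size
            C[j, i] = C[i, j]
        off_diag = ~np.eye(n, dtype=bool)
        if np.any(np.abs(C[off_diag]) >= 1.0 - 1e-12):
            raise ValueError("effect_size pushes a correlation to +/-1")

    w = np.linalg.eigvalsh(C)
    if w[0] < -1e-10:
        raise ValueError(
            f"latent correlation matrix for group {group!r} is not positive "
            f"semidefinite (min eigenvalue {w[0]:.3e}); reduce rho/effect parameters"
        )
    return C


def _psd_factor(C: np.ndarray) -> np.ndarray:
    """Square root factor of a PSD matrix via eigendecomposition."""
    w, V = np.linalg.eigh(C)
    return V * np.sqrt(np.clip(w, 0.0, None))


def sample_node_series(
    config: CohortConfig,
    group: str,
    rng: np.random.Generator,
    n_timepoints: int | None = None,
) -> np.ndarray:
    """Draw a (t, 24) array of latent node signals for one subject."""
    C = build_latent_correlation(config, group)
    L = _psd_factor(C)
    t = config.n_timepoints if n_timepoints is None else n_timepoints
    return rng.standard_normal((t, C.shape[0])) @ L.T


def _subject_rng(seed: int, subject_id: str) -> np.random.Generator:
    digest = hashlib.sha256(subject_id.encode()).digest()
    sub = int.from_bytes(digest[:4], "big")
    return np.random.default_rng(np.random.SeedSequence([int(seed), sub]))


def _box(shape: tuple[int, int, int], x: tuple[int, int], y: tuple[int, int], z: tuple[int, int]) -> np.ndarray:
    m = np.zeros(shape, dtype=bool)
    m[x[0] : x[1], y[0] : y[1], z[0] : z[1]] = True
    return m


def build_masks(config: CohortConfig) -> dict[str, RoiMask]:
    """Deterministic mask layout shared by the whole cohort.

    Returns region masks (``"TP_L"`` ... ``"Thal_R"``), hippocampal masks
    (``"hippocampus"``, ``"hippocampus_L"``, ``"hippocampus_R"``), planted
    hippocampal node masks (``"HIPa_L"`` etc.), hemisphere masks, and the
    gray-matter probability map under key ``"__gm__"`` (a float array wrapped
    for transport, see :func:`gray_matter_map`).
    """
    config.validate()
    shape = tuple(config.grid_shape)
    masks: dict[str, RoiMask] = {}

    for hemi, xr in _HIPP_X.items():
        masks[f"hippocampus_{hemi}"] = RoiMask(
            _box(shape, xr, _HIPP_Y, _HIPP_Z), label=f"hippocampus_{hemi}"
        )
    hipp = masks["hippocampus_L"].data | masks["hippocampus_R"].data
    masks["hippocampus"] = RoiMask(hipp, label="hippocampus")

    for region, (y0, z0) in _REGION_SLOTS.items():
        for hemi, xr in _REGION_X.items():
            lab = f"{region}_{hemi}"
            masks[lab] = RoiMask(_box(shape, xr, (y0, y0 + 3), (z0, z0 + 3)), label=lab)

    for hemi in ("L", "R"):
        m = np.zeros(shape, dtype=bool)
        if hemi == "L":
            m[: shape[0] // 2] = True
        else:
            m[shape[0] // 2 :] = True
        masks[f"hemisphere_{hemi}"] = RoiMask(m, label=f"hemisphere_{hemi}")

    labels = planted_voxel_labels(config, masks)
    for hemi in ("L", "R"):
        hemi_m = masks[f"hemisphere_{hemi}"].data
        masks[f"HIPa_{hemi}"] = RoiMask((labels == 1) & hemi_m, label=f"HIPa_{hemi}")
        masks[f"HIPp_{hemi}"] = RoiMask((labels == 2) & hemi_m, label=f"HIPp_{hemi}")

    # node masks must not overlap each other
    stack = np.zeros(shape, dtype=int)
    for lab in DEFAULT_PARTITION.labels:
        stack += masks[lab].data.astype(int)
    if stack.max() > 1:
        raise ValueError("node masks overlap; grid layout invalid")
    return masks


def planted_voxel_labels(config: CohortConfig, masks: dict[str, RoiMask] | None = None) -> np.ndarray:
    """3D uint8 planted long-axis labels: 1 anterior, 2 posterior, 0 outside.

    The anterior segment is the ``anterior_fraction`` of hippocampal
    y-slices with the highest y (the long axis runs posterior -> anterior
    along the grid's second axis).
    """
    shape = tuple(config.grid_shape)
    labels = np.zeros(shape, dtype=np.uint8)
    y0, y1 = _HIPP_Y
    n_slices = y1 - y0
    n_ant = int(round(config.anterior_fraction * n_slices))
    n_ant = min(max(n_ant, 1), n_slices - 1)  # keep both segments nonempty
    y_cut = y1 - n_ant
    for xr in _HIPP_X.values():
        labels[xr[0] : xr[1], y0:y_cut, _HIPP_Z[0] : _HIPP_Z[1]] = 2
        labels[xr[0] : xr[1], y_cut:y1, _HIPP_Z[0] : _HIPP_Z[1]] = 1
    return labels


def gray_matter_map(config: CohortConfig, masks: dict[str, RoiMask]) -> np.ndarray:
    """Gray-matter probability: high inside all tissue masks, low outside."""
    gm = np.full(tuple(config.grid_shape), 0.05, dtype=float)
    for lab, m in masks.items():
        if lab.startswith("hemisphere"):
            continue
        gm[m.data] = 0.9
    return gm


def ground_truth(config: CohortConfig) -> GroundTruth:
    config.validate()
    labels = planted_voxel_labels(config)
    latent = {g: build_latent_correlation(config, g) for g in ("control", "patient")}
    effects: list[tuple[str, str]] = []
    node_labels = DEFAULT_PARTITION.labels
    diff = latent["patient"] - latent["control"]
    iu = np.triu_indices(len(node_labels), k=1)
    for i, j in zip(*iu):
        if abs(diff[i, j]) > 1e-12:
            effects.append((node_labels[i], node_labels[j]))
    return GroundTruth(voxel_labels=labels, latent_correlations=latent, planted_effect_edges=effects)


def generate_subject(
    config: CohortConfig,
    record: SubjectRecord,
    masks: dict[str, RoiMask] | None = None,
) -> BoldVolume:
    """Generate one subject's 4D BOLD volume (deterministic per seed and id).

    Every voxel receives i.i.d. Gaussian noise of sd ``1/snr``; voxels inside
    a node mask additionally carry that node's unit-variance latent signal.
    """
    config.validate()
    if masks is None:
        masks = build_masks(config)
    rng = _subject_rng(config.seed, record.subject_id)
    t = config.n_timepoints
    latent = sample_node_series(config, record.group, rng)  # (t, 24)
    shape = tuple(config.grid_shape)
    data = rng.standard_normal(shape + (t,)) / config.snr
    for idx, lab in enumerate(DEFAULT_PARTITION.labels):
        data[masks[lab].data] += latent[:, idx]
    return BoldVolume(data=data.astype(np.float32), t_r=config.tr_seconds)


@dataclass
class Cohort:
    """A generated cohort: records, shared masks, planted truth, lazy volumes."""

    config: CohortConfig
    records: list[SubjectRecord]
    masks: dict[str, RoiMask]
    gm: np.ndarray
    truth: GroundTruth

    @property
    def phenotypes(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {"subject_id": r.subject_id, "group": r.group, "age": r.age, "gender": r.gender}
            row.update(r.scores)
            rows.append(row)
        return pd.DataFrame(rows)

    def volume(self, subject_id: str) -> BoldVolume:
        rec = next((r for r in self.records if r.subject_id == subject_id), None)
        if rec is None:
            raise KeyError(f"unknown subject {subject_id!r}")
        return generate_subject(self.config, rec, self.masks)

    def subject_ids(self, group: str | None = None) -> list[str]:
        return [r.subject_id for r in self.records if group is None or r.group == group]


def _draw_records(config: CohortConfig) -> list[SubjectRecord]:
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0x9E3779B9]))
    lo, hi = config.age_bounds
    a, b = (lo - config.age_mean) / config.age_sd, (hi - config.age_mean) / config.age_sd
    records = []
    ids = [f"con{i+1:03d}" for i in range(config.n_controls)] + [
        f"pat{i+1:03d}" for i in range(config.n_patients)
    ]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate subject ids")
    groups = ["control"] * config.n_controls + ["patient"] * config.n_patients
    ages = stats.truncnorm.rvs(a, b, loc=config.age_mean, scale=config.age_sd,
                               size=len(ids), random_state=rng)
    genders = np.where(rng.random(len(ids)) < config.p_male, "male", "female")
    for sid, grp, age, gender in zip(ids, groups, ages, genders):
        records.append(SubjectRecord(subject_id=sid, group=grp, age=float(age), gender=str(gender)))
    return records


def _attach_scores(config: CohortConfig, records: list[SubjectRecord]) -> list[SubjectRecord]:
    """Couple a cognitive-style score to each subject's realized intranetwork strength.

    The subject's realized strength is the mean within-network Fisher-z sample
    correlation of their latent node signals; scores mix its cohort-standardised
    value with independent noise at correlation ``score_coupling`` and are
    rescaled to an MCCB-like location/scale (mean 45, sd 11).
    """
    if not records:
        return records
    strengths = []
    networks = np.array([n[2] for n in DEFAULT_PARTITION.nodes])
    same_net = (networks[:, None] == networks[None, :]) & ~np.eye(24, dtype=bool)
    for rec in records:
        rng = _subject_rng(config.seed, rec.subject_id)
        latent = sample_node_series(config, rec.group, rng)
        r = np.corrcoef(latent, rowvar=False)
        strengths.append(float(np.arctanh(np.clip(r[same_net], -0.999999, 0.999999)).mean()))
    s = np.asarray(strengths)
    if len(s) > 1 and s.std(ddof=1) > 0:
        s_std = (s - s.mean()) / s.std(ddof=1)
    else:
        s_std = np.zeros_like(s)
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0x5EED5C02]))
    rho = config.score_coupling
    raw = rho * s_std + np.sqrt(max(0.0, 1 - rho**2)) * rng.standard_normal(len(s))
    scores = 45.0 + 11.0 * raw
    return [
        replace(rec, scores={**rec.scores, config.score_name: float(sc)})
        for rec, sc in zip(records, scores)
    ]


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate the full cohort bundle (volumes stay lazy; see Cohort.volume)."""
    config.validate()
    if config.n_controls + config.n_patients == 0:
        raise ValueError("cohort must contain at least one subject")
    masks = build_masks(config)
    records = _attach_scores(config, _draw_records(config))
    truth = ground_truth(config)
    gm = gray_matter_map(config, masks)
    return Cohort(config=config, records=records, masks=masks, gm=gm, truth=truth)
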