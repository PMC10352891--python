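"""End-to-end pipeline: generate -> segment -> connect -> measure -> infer.

A :class:`RunConfig` drives one reproducible run.  Stages communicate through
plain files (NIfTI masks/divisions, TSV tables, JSON reports) under the
output directory, so the inference stage can be re-run from cached upstream
outputs; all stochastic stages are seeded from the config.

Output layout::

    out/
      cohort/        phenotypes.tsv, ground_truth.json, masks (NIfTI)
      segmentation/  division_{all,control,patient}.nii.gz, voxel_counts.tsv
      network/       edges.tsv (subject x edge long format), group mean TSVs
      metrics/       metrics.tsv (subject_id, cp_ahn, cp_phn, cpq, k_*)
      inference/     network_level.json, nbs.json, nbs_null_hist.tsv,
                     nodal.json, correlations.json, demographics.json
      manifest.json
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import Cohort, CohortConfig, generate_cohort
from .extraction import RoiMask, confine_to_gray_matter
from .inference import (
    DesignMatrix,
    bonferroni_gate,
    chi_squared_2x2,
    compare_continuous,
    edge_index_pairs,
    fdr_bh,
    glm_group_test,
    nbs,
    partial_correlation_test,
)
from .metrics import composite_scores, nodal_degrees
from .network import DEFAULT_PARTITION, build_subject_matrix, group_mean_matrix, node_eigenvariates
from .segmentation import (
    HippocampalDivision,
    compute_partial_maps,
    group_division,
    subject_division,
)
from .simulations import make_target_pair

__all__ = ["RunConfig", "validate_inputs", "run_pipeline", "stage_infer", "load_run_config"]


@dataclass
class RunConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    gm_threshold: float = 0.2
    n_perm: int = 1000
    primary_p: float = 0.01
    alpha: float = 0.05
    nodal_q: float = 0.05
    division: str = "unbiased"  # "unbiased" | "group"
    out_dir: str = "hippnet_run"
    seed: int = 0
    save_bold: bool = False

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_run_config(path: str | Path) -> RunConfig:
    """Load a YAML run configuration, validating field names and ranges."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("run config must be a YAML mapping")
    cohort_raw = raw.pop("cohort", {})
    known_cohort = {f.name for f in dataclasses.fields(CohortConfig)}
    bad = set(cohort_raw) - known_cohort
    if bad:
        raise ValueError(f"unknown cohort config fields: {sorted(bad)}")
    if "grid_shape" in cohort_raw:
        cohort_raw["grid_shape"] = tuple(cohort_raw["grid_shape"])
    if "effect_edges" in cohort_raw:
        cohort_raw["effect_edges"] = tuple(tuple(e) for e in cohort_raw["effect_edges"])
    if "age_bounds" in cohort_raw:
        cohort_raw["age_bounds"] = tuple(cohort_raw["age_bounds"])
    known_run = {f.name for f in dataclasses.fields(RunConfig)}
    bad = set(raw) - known_run
    if bad:
        raise ValueError(f"unknown run config fields: {sorted(bad)}")
    cfg = RunConfig(cohort=CohortConfig(**cohort_raw), **raw)
    _validate_run_config(cfg)
    return cfg


def _validate_run_config(cfg: RunConfig) -> None:
    if not 0 <= cfg.gm_threshold <= 1:
        raise ValueError("gm_threshold must lie in [0, 1]")
    if not 0 < cfg.primary_p < 1 or not 0 < cfg.alpha < 1 or not 0 < cfg.nodal_q < 1:
        raise ValueError("significance thresholds must lie in (0, 1)")
    if cfg.division not in ("unbiased", "group"):
        raise ValueError("division must be 'unbiased' or 'group'")
    if cfg.n_perm < 100:
        raise ValueError("n_perm must be at least 100")


def validate_inputs(config: RunConfig) -> list[str]:
    """Collect configuration/cohort violations; empty list means valid."""
    violations: list[str] = []
    try:
        _validate_run_config(config)
    except ValueError as exc:
        violations.append(str(exc))
    try:
        config.cohort.validate()
    except ValueError as exc:
        violations.append(str(exc))
        return violations
    if config.cohort.n_controls + config.cohort.n_patients == 0:
        violations.append("cohort has zero subjects")
        return violations
    cohort = generate_cohort(config.cohort)
    violations.extend(validate_cohort(cohort))
    return violations


def validate_cohort(cohort: Cohort) -> list[str]:
    """Grid consistency, node-mask disjointness, phenotype completeness."""
    violations: list[str] = []
    shape = tuple(cohort.config.grid_shape)
    stack = np.zeros(shape, dtype=int)
    for lab in DEFAULT_PARTITION.labels:
        mask = cohort.masks.get(lab)
        if mask is None:
            violations.append(f"missing node mask {lab!r}")
            continue
        if mask.data.shape != shape:
            violations.append(f"node mask {lab!r} off-grid: {mask.data.shape} != {shape}")
            continue
        stack += mask.data.astype(int)
    overlap = int((stack > 1).sum())
    if overlap:
        violations.append(f"node masks overlap on {overlap} voxels")
    phen = cohort.phenotypes
    for col in ("subject_id", "group", "age", "gender"):
        if col not in phen.columns:
            violations.append(f"phenotype table missing column {col!r}")
    if "group" in phen.columns and set(phen["group"]) - {"control", "patient"}:
        violations.append("phenotype group column has unexpected levels")
    if "subject_id" in phen.columns and phen["subject_id"].duplicated().any():
        violations.append("duplicate subject ids in phenotype table")
    return violations


# ---------------------------------------------------------------------------
# file helpers


def _save_mask(mask: np.ndarray, path: Path, dtype=np.uint8) -> None:
    nib.save(nib.Nifti1Image(np.asarray(mask).astype(dtype), affine=np.eye(4)), str(path))


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# stages


def _stage_cohort(cfg: RunConfig, out: Path) -> Cohort:
    cohort = generate_cohort(cfg.cohort)
    d = out / "cohort"
    d.mkdir(parents=True, exist_ok=True)
    cohort.phenotypes.to_csv(d / "phenotypes.tsv", sep="\t", index=False)
    (d / "ground_truth.json").write_text(cohort.truth.to_json() + "\n")
    _save_mask(cohort.masks["hippocampus"].data, d / "hippocampus.nii.gz")
    _save_mask(cohort.gm, d / "gray_matter_probability.nii.gz", dtype=np.float32)
    for lab in DEFAULT_PARTITION.labels:
        _save_mask(cohort.masks[lab].data, d / f"mask_{lab}.nii.gz")
    if cfg.save_bold:
        for sid in cohort.subject_ids():
            vol = cohort.volume(sid)
            nib.save(
                nib.Nifti1Image(vol.data, affine=np.eye(4)), str(d / f"bold_{sid}.nii.gz")
            )
    return cohort


def _stage_segment(cfg: RunConfig, cohort: Cohort, out: Path) -> dict[str, HippocampalDivision]:
    d = out / "segmentation"
    d.mkdir(parents=True, exist_ok=True)
    targets = make_target_pair(cohort, cfg.gm_threshold)
    hipp = confine_to_gray_matter(cohort.masks["hippocampus"], cohort.gm, cfg.gm_threshold)
    sub_maps = {}
    rows = []
    for sid in cohort.subject_ids():
        vol = cohort.volume(sid)
        maps = compute_partial_maps(vol, hipp, targets, subject_id=sid)
        division, sub = subject_division(maps)
        sub_maps[sid] = sub
        rows.append(
            {
                "subject_id": sid,
                "anterior_voxels": int((division.labels == 1).sum()),
                "posterior_voxels": int((division.labels == 2).sum()),
            }
        )
    pd.DataFrame(rows).to_csv(d / "voxel_counts.tsv", sep="\t", index=False)

    divisions: dict[str, HippocampalDivision] = {}
    for name, ids in (
        ("all", cohort.subject_ids()),
        ("control", cohort.subject_ids("control")),
        ("patient", cohort.subject_ids("patient")),
    ):
        if not ids:
            continue
        div = group_division([sub_maps[s] for s in ids])
        divisions[name] = div
        _save_mask(div.label_volume(), d / f"division_{name}.nii.gz")
    return divisions


def _node_masks(
    cfg: RunConfig, cohort: Cohort, divisions: dict[str, HippocampalDivision]
) -> dict[str, dict[str, RoiMask]]:
    """Per-group node masks: division-derived hippocampal segments + regions.

    With ``division='unbiased'`` (default) every subject uses the all-subject
    division; with ``'group'`` each group uses its own.
    """
    out: dict[str, dict[str, RoiMask]] = {}
    for grp in ("control", "patient"):
        div = divisions["all"] if cfg.division == "unbiased" else divisions.get(grp, divisions["all"])
        masks: dict[str, RoiMask] = {}
        for seg, prefix in (("anterior", "HIPa"), ("posterior", "HIPp")):
            seg_mask = div.segment_mask(seg)
            for hemi in ("L", "R"):
                m = RoiMask(
                    seg_mask.data & cohort.masks[f"hemisphere_{hemi}"].data,
                    label=f"{prefix}_{hemi}",
                )
                masks[f"{prefix}_{hemi}"] = confine_to_gray_matter(m, cohort.gm, cfg.gm_threshold)
        for lab in DEFAULT_PARTITION.labels:
            if lab not in masks:
                masks[lab] = confine_to_gray_matter(cohort.masks[lab], cohort.gm, cfg.gm_threshold)
        out[grp] = masks
    return out


def _stage_network(cfg: RunConfig, cohort: Cohort, node_masks, out: Path) -> pd.DataFrame:
    d = out / "network"
    d.mkdir(parents=True, exist_ok=True)
    rows_idx, cols_idx = edge_index_pairs(len(DEFAULT_PARTITION.nodes))
    labels = DEFAULT_PARTITION.labels
    records = []
    matrices = {"control": [], "patient": []}
    for rec in cohort.records:
        vol = cohort.volume(rec.subject_id)
        series = node_eigenvariates(vol, node_masks[rec.group])
        m = build_subject_matrix(series, subject_id=rec.subject_id)
        matrices[rec.group].append(m)
        for i, j in zip(rows_idx, cols_idx):
            records.append(
                {
                    "subject_id": rec.subject_id,
                    "node_i": labels[i],
                    "node_j": labels[j],
                    "z": m.z[i, j],
                }
            )
    edges = pd.DataFrame(records)
    edges.to_csv(d / "edges.tsv", sep="\t", index=False, float_format="%.17g")
    for grp, ms in matrices.items():
        if ms:
            gm_mat = group_mean_matrix(ms, label=grp)
            pd.DataFrame(gm_mat.z, index=labels, columns=labels).to_csv(
                d / f"group_mean_{grp}.tsv", sep="\t", float_format="%.10g"
            )
    return edges


def _stage_metrics(edges: pd.DataFrame, out: Path) -> pd.DataFrame:
    d = out / "metrics"
    d.mkdir(parents=True, exist_ok=True)
    metrics = metrics_from_edges(edges)
    metrics.to_csv(d / "metrics.tsv", sep="\t", index=False, float_format="%.17g")
    return metrics


def metrics_from_edges(edges: pd.DataFrame) -> pd.DataFrame:
    """Composite scores and nodal degrees per subject from the edge table."""
    labels = DEFAULT_PARTITION.labels
    rows_idx, cols_idx = edge_index_pairs(len(labels))
    rows = []
    for sid, grp in edges.groupby("subject_id", sort=False):
        z = np.zeros((len(labels), len(labels)))
        order = {(labels[i], labels[j]): (i, j) for i, j in zip(rows_idx, cols_idx)}
        for _, r in grp.iterrows():
            i, j = order[(r["node_i"], r["node_j"])]
            z[i, j] = z[j, i] = r["z"]
        from .network import ConnectivityMatrix

        m = ConnectivityMatrix(z=z, subject_id=sid)
        cs = composite_scores(m)
        k = nodal_degrees(m).k
        row = {"subject_id": sid, "cp_ahn": cs.cp_ahn, "cp_phn": cs.cp_phn, "cpq": cs.cpq}
        row.update({f"k_{lab}": k[i] for i, lab in enumerate(labels)})
        rows.append(row)
    return pd.DataFrame(rows)


def _stage_infer(
    cfg: RunConfig,
    phenotypes: pd.DataFrame,
    edges: pd.DataFrame,
    metrics: pd.DataFrame,
    out: Path,
) -> dict:
    d = out / "inference"
    d.mkdir(parents=True, exist_ok=True)
    labels = DEFAULT_PARTITION.labels
    rows_idx, cols_idx = edge_index_pairs(len(labels))

    phen = phenotypes.set_index("subject_id").loc[metrics["subject_id"]].reset_index()
    design = DesignMatrix.from_phenotypes(phen)

    # network level: 3 composite scores, Bonferroni over 3 tests
    network_level = {}
    pvals = []
    for name in ("cp_ahn", "cp_phn", "cpq"):
        res = glm_group_test(metrics[name].to_numpy(), design)
        network_level[name] = {
            "group_coefficient": res.group_coefficient,
            "statistic": res.statistic,
            "p": res.p_two_tailed,
        }
        pvals.append(res.p_two_tailed)
    flags = bonferroni_gate(pvals, alpha=cfg.alpha, m=3)
    for name, flag in zip(("cp_ahn", "cp_phn", "cpq"), flags):
        network_level[name]["significant_bonferroni"] = bool(flag)
    network_level["bonferroni_threshold"] = cfg.alpha / 3
    _write_json(network_level, d / "network_level.json")

    # edge level: NBS
    edge_matrix = np.zeros((len(metrics), len(rows_idx)))
    order = {(labels[i], labels[j]): e for e, (i, j) in enumerate(zip(rows_idx, cols_idx))}
    sid_pos = {s: i for i, s in enumerate(metrics["subject_id"])}
    for _, r in edges.iterrows():
        edge_matrix[sid_pos[r["subject_id"]], order[(r["node_i"], r["node_j"])]] = r["z"]
    rng = np.random.default_rng(cfg.seed)
    nbs_res = nbs(edge_matrix, design, primary_p=cfg.primary_p, n_perm=cfg.n_perm, rng=rng)
    nbs_report = {}
    for direction, res in nbs_res.items():
        nbs_report[direction] = {
            "primary_p_threshold": res.primary_p_threshold,
            "components": [
                {"edges": [list(e) for e in c.edges], "size": c.size, "corrected_p": c.corrected_p}
                for c in res.components
            ],
            "n_significant": len(res.significant_components),
        }
    _write_json(nbs_report, d / "nbs.json")
    null = nbs_res["patient_gt_control"].max_null_sizes
    pd.DataFrame({"max_component_size": null}).to_csv(d / "nbs_null_hist.tsv", sep="\t", index=False)

    # nodal level: 24 degrees, BH-FDR
    nodal = {}
    node_p = []
    for lab in labels:
        res = glm_group_test(metrics[f"k_{lab}"].to_numpy(), design)
        nodal[lab] = {"group_coefficient": res.group_coefficient, "statistic": res.statistic, "p": res.p_two_tailed}
        node_p.append(res.p_two_tailed)
    for lab, flag in zip(labels, fdr_bh(node_p, q=cfg.nodal_q)):
        nodal[lab]["significant_fdr"] = bool(flag)
    _write_json(nodal, d / "nodal.json")

    # brain-behaviour partial correlations (any extra numeric phenotype column)
    correlations = {}
    cov = np.column_stack(
        [phen["age"].to_numpy(float), (phen["gender"] == "male").to_numpy(float)]
    )
    score_cols = [
        c for c in phen.columns if c not in ("subject_id", "group", "age", "gender")
        and pd.api.types.is_numeric_dtype(phen[c])
    ]
    for score in score_cols:
        correlations[score] = {}
        for name in ("cp_ahn", "cp_phn", "cpq"):
            r, p = partial_correlation_test(
                phen[score].to_numpy(float), metrics[name].to_numpy(), cov
            )
            correlations[score][name] = {"r_partial": r, "p": p}
    _write_json(correlations, d / "correlations.json")

    # demographic table
    ctrl = phen[phen["group"] == "control"]
    pat = phen[phen["group"] == "patient"]
    demo: dict = {}
    if len(ctrl) >= 5 and len(pat) >= 5:
        demo["age"] = compare_continuous(ctrl["age"].to_numpy(), pat["age"].to_numpy())
        a = int((pat["gender"] == "male").sum())
        b = int((pat["gender"] == "female").sum())
        c = int((ctrl["gender"] == "male").sum())
        dd = int((ctrl["gender"] == "female").sum())
        try:
            chi2, p = chi_squared_2x2(a, b, c, dd)
            demo["gender"] = {"test": "chi_squared", "statistic": chi2, "p": p}
        except ValueError as exc:
            demo["gender"] = {"test": "chi_squared", "error": str(exc)}
        for score in score_cols:
            demo[score] = compare_continuous(ctrl[score].to_numpy(), pat[score].to_numpy())
    _write_json(demo, d / "demographics.json")

    return {
        "network_level": network_level,
        "nbs": nbs_report,
        "nodal": nodal,
        "correlations": correlations,
        "demographics": demo,
    }


def stage_infer(cfg: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Re-run only the inference stage from cached upstream TSV outputs."""
    out = Path(out_dir or cfg.out_dir)
    # round_trip parsing keeps the cached-file path bit-identical to in-memory
    phen = pd.read_csv(out / "cohort" / "phenotypes.tsv", sep="\t", float_precision="round_trip")
    edges = pd.read_csv(out / "network" / "edges.tsv", sep="\t", float_precision="round_trip")
    metrics = pd.read_csv(out / "metrics" / "metrics.tsv", sep="\t", float_precision="round_trip")
    return _stage_infer(cfg, phen, edges, metrics, out)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the results bundle written under out_dir."""
    t0 = time.time()
    violations = validate_inputs(config)
    if violations:
        raise ValueError("invalid run configuration: " + "; ".join(violations))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages: list[str] = []

    def _run(name, fn, *args):
        try:
            result = fn(*args)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        stages.append(name)
        return result

    cohort = _run("synth", _stage_cohort, config, out)
    divisions = _run("segment", _stage_segment, config, cohort, out)
    node_masks = _node_masks(config, cohort, divisions)
    edges = _run("connect", _stage_network, config, cohort, node_masks, out)
    metrics = _run("metrics", _stage_metrics, edges, out)
    reports = _run("infer", _stage_infer, config, cohort.phenotypes, edges, metrics, out)

    tracked = sorted(
        p for p in out.rglob("*") if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "config_hash": config.config_hash(),
        "version": __version__,
        "stages": stages,
        "digests": {str(p.relative_to(out)): _digest(p) for p in tracked},
        "elapsed_seconds": round(time.time() - t0, 3),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    _write_json(manifest, out / "manifest.json")
    return {"reports": reports, "manifest": manifest, "out_dir": str(out)}
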