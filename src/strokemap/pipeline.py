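"""End-to-end orchestration: contrast -> design -> inference -> outputs.

This is the layer the CLI, the examples and the validation experiments all
share. A run takes lesion masks (or connectomes), a cohort table, and a
contrast name, aligns subjects between behavior and imaging, executes the
corresponding analysis, and can write the standard output bundle: beta / p
/ significant-cluster maps (NIfTI) and cluster table (TSV) for the
voxelwise analysis; edge and parcel tables (TSV) and per-patient binary
disconnectomes (TSV) for the connectome analysis; plus a JSON run summary
recording seeds, thresholds, and subject counts, so any run can be
reproduced bit-for-bit.
"""
from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .behavior import CONTRASTS, BehaviorTarget, ContrastSpec, build_contrast_target
from .clsm import (ClsmResult, DisconnectionMatrix, ParcelResult,
                   binarize_disconnection, build_edge_design, edge_inference,
                   parcel_inference)
from .cohort_io import (CohortTable, Connectome, LesionMask, write_edge_table,
                        write_lesion_mask, write_stat_map)
from .exceptions import AlignmentError, ConfigurationError
from .svr_engine import PermutationScheme, SvrConfig
from .vlsm import VlsmResult, build_voxel_design, cluster_inference, report_clusters


@dataclass
class RunConfig:
    """Everything a run needs beyond the data, YAML-serializable."""

    svr: SvrConfig = field(default_factory=SvrConfig)
    scheme: PermutationScheme = field(default_factory=PermutationScheme)
    min_coverage: float = 0.10       # voxel filter, inclusive (>=)
    min_edge_fraction: float = 0.10  # edge filter, strict (>)
    logit_transform: bool = False

    def to_dict(self) -> dict:
        return {
            "svr": asdict(self.svr),
            "permutation": asdict(self.scheme),
            "min_coverage": self.min_coverage,
            "min_edge_fraction": self.min_edge_fraction,
            "logit_transform": self.logit_transform,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(
            svr=SvrConfig(**d.get("svr", {})),
            scheme=PermutationScheme(**d.get("permutation", {})),
            min_coverage=d.get("min_coverage", 0.10),
            min_edge_fraction=d.get("min_edge_fraction", 0.10),
            logit_transform=d.get("logit_transform", False),
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def resolve_contrast(contrast: str | ContrastSpec) -> ContrastSpec:
    if isinstance(contrast, ContrastSpec):
        return contrast
    try:
        return CONTRASTS[contrast]
    except KeyError:
        raise ConfigurationError(
            f"unknown contrast {contrast!r}; built-ins: {sorted(CONTRASTS)}")


def _align(items: list, ids: list[str], wanted: list[str], what: str) -> list:
    by_id = dict(zip(ids, items))
    missing = [s for s in wanted if s not in by_id]
    if missing:
        raise AlignmentError(f"no {what} for subjects: {missing[:5]}")
    return [by_id[s] for s in wanted]


@dataclass
class VlsmRun:
    contrast: ContrastSpec
    target: BehaviorTarget
    result: VlsmResult
    config: RunConfig

    def cluster_table(self) -> pd.DataFrame:
        return report_clusters(self.result.clusters)

    def summary(self) -> dict:
        return {
            "analysis": "vlsm",
            "contrast": self.contrast.to_dict(),
            "config": self.config.to_dict(),
            "n_subjects": len(self.target.subject_ids),
            "n_dropped": self.target.n_dropped,
            "n_voxels_analyzed": self.result.design.n_voxels,
            "n_suprathreshold": self.result.n_suprathreshold,
            "n_clusters": len(self.result.clusters),
            "n_significant_clusters": len(self.result.significant_clusters),
        }


def run_vlsm(masks: list[LesionMask], cohort: CohortTable,
             contrast: str | ContrastSpec,
             config: RunConfig = RunConfig()) -> VlsmRun:
    """Full voxelwise analysis for one contrast."""
    spec = resolve_contrast(contrast)
    target = build_contrast_target(cohort, spec,
                                   logit_transform=config.logit_transform)
    kept = _align(masks, [m.subject_id for m in masks], target.subject_ids,
                  "lesion mask")
    design = build_voxel_design(kept, config.min_coverage)
    result = cluster_inference(design, target, config.svr, config.scheme)
    return VlsmRun(contrast=spec, target=target, result=result, config=config)


def write_vlsm_outputs(run: VlsmRun, out_dir: str | os.PathLike) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_stat_map(run.result.beta_map, out / "beta.nii")
    write_stat_map(run.result.p_map, out / "p.nii")
    write_stat_map(run.result.cluster_label_map, out / "significant_clusters.nii")
    run.cluster_table().to_csv(out / "clusters.tsv", sep="\t", index=False)
    with open(out / "summary.json", "w") as fh:
        json.dump(run.summary(), fh, indent=1, sort_keys=True)


@dataclass
class ClsmRun:
    contrast: ContrastSpec
    target: BehaviorTarget
    result: ClsmResult
    parcels: list[ParcelResult]
    disconnectomes: list[DisconnectionMatrix]
    config: RunConfig

    def parcel_table(self) -> pd.DataFrame:
        rows = [{"parcel": p.parcel, "statistic": p.statistic,
                 "p_fwer": p.p_fwer if p.analyzable else None,
                 "significant": p.significant, "analyzable": p.analyzable,
                 "n_incident_edges": p.n_incident_edges}
                for p in self.parcels]
        return pd.DataFrame(rows)

    def summary(self) -> dict:
        return {
            "analysis": "clsm",
            "contrast": self.contrast.to_dict(),
            "config": self.config.to_dict(),
            "n_subjects": len(self.target.subject_ids),
            "n_dropped": self.target.n_dropped,
            "n_edges_analyzed": self.result.design.n_edges,
            "n_significant_edges": len(self.result.significant_edges),
            "n_significant_parcels": sum(p.significant for p in self.parcels),
        }


def run_clsm(patient_connectomes: list[Connectome], patient_ids: list[str],
             control_connectomes: list[Connectome], cohort: CohortTable,
             contrast: str | ContrastSpec,
             config: RunConfig = RunConfig()) -> ClsmRun:
    """Full connectome-wise analysis for one contrast."""
    spec = resolve_contrast(contrast)
    target = build_contrast_target(cohort, spec,
                                   logit_transform=config.logit_transform)
    kept = _align(patient_connectomes, patient_ids, target.subject_ids,
                  "connectome")
    disconn = [binarize_disconnection(c, control_connectomes, subject_id=sid)
               for c, sid in zip(kept, target.subject_ids)]
    design = build_edge_design(disconn, config.min_edge_fraction)
    result = edge_inference(design, target, config.svr, config.scheme)
    parcels = parcel_inference(result, config.scheme)
    return ClsmRun(contrast=spec, target=target, result=result,
                   parcels=parcels, disconnectomes=disconn, config=config)


def write_clsm_outputs(run: ClsmRun, out_dir: str | os.PathLike) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_edge_table(run.result.edges, out / "edges.tsv")
    run.parcel_table().to_csv(out / "parcels.tsv", sep="\t", index=False)
    disc_dir = out / "disconnectomes"
    disc_dir.mkdir(exist_ok=True)
    for d in run.disconnectomes:
        np.savetxt(disc_dir / f"{d.subject_id}.tsv", d.D, fmt="%d", delimiter="\t")
    with open(out / "summary.json", "w") as fh:
        json.dump(run.summary(), fh, indent=1, sort_keys=True)
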