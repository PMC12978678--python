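"""Voxelwise SVR lesion-symptom mapping with clusterwise permutation FWER.

The design keeps only voxels lesioned in at least 10% of patients
(``coverage >= min_coverage``, with equality included); covariates are then
regressed out of both the voxel matrix and the behavioral target, an SVR is
fit, and voxelwise one-tailed-negative permutation p-values are computed.
Suprathreshold voxels (p below the cluster-forming threshold, default
0.005) are grouped into connected components (default 26-connectivity), and
each observed cluster's size in voxels is compared against the permutation
null of the *maximum* cluster size found in each permutation's own
suprathreshold map — the clusterwise familywise-error correction reported
at alpha = 0.05.

Cluster geometry is reported the way lesion studies print it: size in cm^3
to 3 decimals and the unweighted center of mass of the voxel centers in mm
coordinates to 1 decimal.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .behavior import BehaviorTarget
from .cohort_io import LesionMask, StatMap
from .exceptions import AlignmentError, CohortConsistencyError, EmptyDesignError
from .svr_engine import PermutationNull, PermutationScheme, SvrConfig, permutation_null, residualize

logger = logging.getLogger(__name__)


def connectivity_structure(connectivity: int) -> np.ndarray:
    """3-D adjacency footprint for 6 (faces), 18 (+edges), 26 (+corners)."""
    rank = {6: 1, 18: 2, 26: 3}[connectivity]
    return ndimage.generate_binary_structure(3, rank)


@dataclass
class VoxelDesign:
    """Patients x covered-voxels lesion-status matrix.

    ``voxel_index`` maps column j to its (i, j, k) grid coordinate;
    ``coverage_fraction[j]`` is the fraction of patients lesioned there.
    """

    X: np.ndarray                  # n_patients x n_voxels, {0,1} floats
    voxel_index: np.ndarray        # n_voxels x 3 int
    coverage_fraction: np.ndarray  # n_voxels
    min_coverage: float
    shape: tuple[int, int, int]
    affine: np.ndarray
    subject_ids: list[str]

    @property
    def n_voxels(self) -> int:
        return self.X.shape[1]

    @property
    def voxel_volume_mm3(self) -> float:
        A = self.affine[:3, :3]
        return float(abs(np.dot(A[:, 0], np.cross(A[:, 1], A[:, 2]))))

    def to_grid(self, values: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Scatter a per-column vector back onto the 3-D grid."""
        out = np.full(self.shape, fill, dtype=float)
        out[tuple(self.voxel_index.T)] = values
        return out


def build_voxel_design(masks: list[LesionMask],
                       min_coverage: float = 0.10) -> VoxelDesign:
    """Stack masks and keep voxels with lesion coverage >= ``min_coverage``.

    Requires at least 10 masks with identical geometry. Raises
    :class:`EmptyDesignError` if no voxel survives.
    """
    if len(masks) < 10:
        raise CohortConsistencyError(f"need >= 10 masks, got {len(masks)}")
    shape = masks[0].grid.shape
    affine = masks[0].affine
    for m in masks[1:]:
        if m.grid.shape != shape or np.abs(m.affine - affine).max() > 1e-4:
            raise CohortConsistencyError(
                f"mask {m.subject_id!r} geometry differs from cohort reference")
    stack = np.stack([m.grid for m in masks]).astype(float)  # n x X x Y x Z
    coverage = stack.mean(axis=0)
    keep = coverage >= min_coverage
    if not keep.any():
        raise EmptyDesignError("no voxel reaches the minimum lesion coverage")
    voxel_index = np.argwhere(keep)
    X = stack[:, keep]
    return VoxelDesign(
        X=X,
        voxel_index=voxel_index,
        coverage_fraction=coverage[keep],
        min_coverage=min_coverage,
        shape=shape,
        affine=np.asarray(affine, dtype=float),
        subject_ids=[m.subject_id for m in masks],
    )


@dataclass
class ClusterResult:
    """One suprathreshold connected component with its corrected p-value."""

    voxels: np.ndarray          # m x 3 int grid coordinates
    size_cm3: float
    center_of_mass_mm: np.ndarray
    p_cluster: float
    significant: bool

    @property
    def n_voxels(self) -> int:
        return len(self.voxels)


@dataclass
class VlsmResult:
    """Full output of one voxelwise analysis."""

    clusters: list[ClusterResult]
    beta_map: StatMap
    p_map: StatMap
    cluster_label_map: StatMap   # significant clusters labeled 1..m, else 0
    design: VoxelDesign
    null_max_cluster: np.ndarray  # per-permutation max suprathreshold cluster size
    n_suprathreshold: int

    @property
    def significant_clusters(self) -> list[ClusterResult]:
        return [c for c in self.clusters if c.significant]


def _label_clusters(mask3d: np.ndarray, structure: np.ndarray):
    labels, n = ndimage.label(mask3d, structure=structure)
    return labels, n


def _max_cluster_size(mask3d: np.ndarray, structure: np.ndarray) -> int:
    labels, n = _label_clusters(mask3d, structure)
    if n == 0:
        return 0
    return int(np.bincount(labels.ravel())[1:].max())


def voxel_centers_mm(voxels: np.ndarray, affine: np.ndarray) -> np.ndarray:
    """Map integer voxel coordinates to mm through the affine."""
    homog = np.hstack([voxels, np.ones((len(voxels), 1))])
    return (homog @ affine.T)[:, :3]


def cluster_inference(design: VoxelDesign, target: BehaviorTarget,
                      cfg: SvrConfig = SvrConfig(),
                      scheme: PermutationScheme = PermutationScheme()) -> VlsmResult:
    """Run the full voxelwise analysis for one contrast.

    Residualizes covariates out of both sides, fits the SVR with its
    permutation null, forms clusters at ``scheme.voxel_forming_p``, and
    assigns each observed cluster the add-one corrected p-value
    (1 + #{b : max null size >= observed size}) / (n_perm + 1).
    An empty suprathreshold map yields an empty cluster list, not an error.
    """
    if design.X.shape[0] != len(target.subject_ids):
        raise AlignmentError("design rows do not match behavior target subjects")
    C = target.covariates
    Xr = residualize(design.X, C)
    yr = residualize(target.y.reshape(-1, 1), C).ravel()
    null = permutation_null(Xr, yr, cfg, scheme)

    structure = connectivity_structure(scheme.connectivity)
    thr = scheme.voxel_forming_p

    obs_supra = design.to_grid(null.p < thr, fill=0.0).astype(bool)
    n_supra = int(obs_supra.sum())

    # null distribution of the maximum cluster size, one entry per permutation
    perm_p = null.perm_p()
    null_max = np.zeros(scheme.n_perm, dtype=int)
    for b in range(scheme.n_perm):
        supra_b = design.to_grid(perm_p[b] < thr, fill=0.0).astype(bool)
        null_max[b] = _max_cluster_size(supra_b, structure)

    clusters: list[ClusterResult] = []
    if n_supra:
        labels, n_clusters = _label_clusters(obs_supra, structure)
        vox_vol = design.voxel_volume_mm3
        for lab in range(1, n_clusters + 1):
            voxels = np.argwhere(labels == lab)
            size = len(voxels)
            p_cluster = (1.0 + (null_max >= size).sum()) / (scheme.n_perm + 1.0)
            com = voxel_centers_mm(voxels, design.affine).mean(axis=0)
            clusters.append(ClusterResult(
                voxels=voxels,
                size_cm3=size * vox_vol / 1000.0,
                center_of_mass_mm=com,
                p_cluster=p_cluster,
                significant=bool(p_cluster < scheme.alpha),
            ))
        clusters.sort(key=lambda c: (c.p_cluster, -c.n_voxels))
    else:
        logger.info("no suprathreshold voxels at p < %g", thr)

    beta_map = StatMap(design.to_grid(null.beta_obs), design.affine, "beta")
    p_map = StatMap(design.to_grid(null.p, fill=StatMap.P_SENTINEL),
                    design.affine, "p")
    label_grid = np.zeros(design.shape)
    for i, c in enumerate(clusters):
        if c.significant:
            label_grid[tuple(c.voxels.T)] = i + 1
    label_map = StatMap(label_grid, design.affine, "thresholded")

    return VlsmResult(
        clusters=clusters,
        beta_map=beta_map,
        p_map=p_map,
        cluster_label_map=label_map,
        design=design,
        null_max_cluster=null_max,
        n_suprathreshold=n_supra,
    )


def report_clusters(clusters: list[ClusterResult],
                    voxel_volume_mm3: float | None = None) -> pd.DataFrame:
    """Cluster table in reporting convention.

    Size in cm^3 to 3 decimals, center of mass in mm to 1 decimal, sorted
    by p then size descending.
    """
    rows = []
    for c in sorted(clusters, key=lambda c: (c.p_cluster, -c.n_voxels)):
        x, y, z = np.round(c.center_of_mass_mm, 1)
        rows.append({
            "n_voxels": c.n_voxels,
            "size_cm3": round(c.size_cm3, 3),
            "com_x_mm": x, "com_y_mm": y, "com_z_mm": z,
            "p_cluster": c.p_cluster,
            "significant": c.significant,
        })
    return pd.DataFrame(rows, columns=["n_voxels", "size_cm3", "com_x_mm",
                                       "com_y_mm", "com_z_mm", "p_cluster",
                                       "significant"])
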