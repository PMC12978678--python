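"""I/O and basic geometry for lesion cohorts.

Reads and writes the artifacts a lesion-symptom mapping study consumes and
produces: per-subject binary lesion masks in a common space (NIfTI-1),
weighted structural connectomes (plain delimited matrices plus a label
table, kept diffable on purpose), cohort behavior tables (TSV), and
statistical output maps (NIfTI-1) and edge tables (TSV).

Lesion masks are binarized on load at 0.5 — masks resampled into a template
space may carry fractional edge values even though the traced masks are
binary. All masks in a cohort must share grid shape and affine (within
1e-4); anything else is a cohort-consistency error, since voxelwise designs
assume a common voxel grid.
"""
from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .exceptions import (
    AlignmentError,
    CohortConsistencyError,
    DataError,
    DimensionalityError,
)

logger = logging.getLogger(__name__)

#: Stimulus classes of the oral reading battery: 200 monosyllabic real words
#: and 20 pseudowords each with zero, one, or multiple learned
#: orthography-to-phonology body mappings.
STIM_CLASSES = ("real_word", "PW0M", "PW1M", "PWMM")

AFFINE_TOL = 1e-4


@dataclass
class LesionMask:
    """A subject's binary lesion mask on the common grid.

    ``grid`` holds exactly 0/1 (1 = lesioned voxel); ``affine`` maps voxel
    indices to mm coordinates.
    """

    subject_id: str
    grid: np.ndarray
    affine: np.ndarray

    def __post_init__(self):
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3:
            raise DimensionalityError(
                f"lesion mask for {self.subject_id!r} is {self.grid.ndim}-D, expected 3-D"
            )
        vals = np.unique(self.grid)
        if not np.isin(vals, (0, 1)).all():
            raise DataError(
                f"lesion mask for {self.subject_id!r} contains values other than 0/1"
            )
        self.grid = self.grid.astype(np.uint8)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise DataError("affine must be a 4x4 matrix")

    @property
    def voxel_volume_mm3(self) -> float:
        """Volume of one voxel in mm^3 (|det| of the affine's 3x3 block).

        Computed as the scalar triple product, which is exact (no LU
        round-off) for the axis-aligned affines of template grids.
        """
        A = self.affine[:3, :3]
        vol = float(abs(np.dot(A[:, 0], np.cross(A[:, 1], A[:, 2]))))
        if vol <= 0:
            raise DataError("degenerate affine: voxel volume is not positive")
        return vol

    @property
    def n_lesioned(self) -> int:
        return int(self.grid.sum())


@dataclass
class Connectome:
    """Weighted structural connectivity between atlas parcels.

    Each edge weight is proportional to the cross-sectional area of white
    matter connecting the two parcels; the matrix is symmetric, nonnegative,
    with a zero diagonal.
    """

    parcel_labels: list[str]
    weights: np.ndarray

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        n = len(self.parcel_labels)
        if len(set(self.parcel_labels)) != n:
            raise DataError("duplicate parcel labels")
        if self.weights.shape != (n, n):
            raise DataError(
                f"weights shape {self.weights.shape} does not match {n} labels"
            )
        if (self.weights < 0).any():
            raise DataError("negative connectome weights")
        if not np.allclose(self.weights, self.weights.T, atol=1e-9):
            raise DataError("connectome weights not symmetric within 1e-9")

    @property
    def n_parcels(self) -> int:
        return len(self.parcel_labels)


@dataclass
class StatMap:
    """A 3-D statistical map aligned to the cohort grid.

    ``kind`` is one of ``beta``, ``p``, ``thresholded``. For p-maps, voxels
    outside the analyzed set carry the sentinel 0.0 (a permutation p-value
    is never 0 by the add-one rank formula, so 0 is unambiguous).
    """

    values: np.ndarray
    affine: np.ndarray
    kind: str

    P_SENTINEL = 0.0

    def __post_init__(self):
        if self.kind not in ("beta", "p", "thresholded"):
            raise DataError(f"unknown stat map kind {self.kind!r}")
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise DimensionalityError("stat map must be 3-D")


@dataclass
class CohortTable:
    """Per-subject demographics and trial outcomes.

    ``subjects`` is a wide table with one row per subject: ``subject_id``,
    ``group`` (control/patient), ``age``, ``education``,
    ``lesion_volume_cm3`` (NaN for controls), and per stimulus class
    ``<cls>_presented`` / ``<cls>_correct`` counts.

    ``durations`` is an optional long table of per-item time-on-item
    (``subject_id``, ``stim_class``, ``item``, ``seconds``), each in
    (0, 10] s (trials time out at 10 s).
    """

    subjects: pd.DataFrame
    durations: pd.DataFrame | None = None

    def __post_init__(self):
        required = {"subject_id", "group", "age", "education"}
        missing = required - set(self.subjects.columns)
        if missing:
            raise DataError(f"cohort table missing columns: {sorted(missing)}")
        if not self.subjects["group"].isin(("control", "patient")).all():
            raise DataError("group must be 'control' or 'patient'")
        for cls in STIM_CLASSES:
            pres, corr = f"{cls}_presented", f"{cls}_correct"
            if pres in self.subjects.columns:
                bad = self.subjects[corr] > self.subjects[pres]
                if bad.any():
                    raise DataError(f"n_correct > n_presented for class {cls}")
        if self.durations is not None and len(self.durations):
            s = self.durations["seconds"]
            if (s <= 0).any() or (s > 10).any():
                raise DataError("durations must lie in (0, 10] s")

    @property
    def patients(self) -> pd.DataFrame:
        return self.subjects[self.subjects["group"] == "patient"].reset_index(drop=True)

    @property
    def controls(self) -> pd.DataFrame:
        return self.subjects[self.subjects["group"] == "control"].reset_index(drop=True)

    def to_tsv(self, path: str | os.PathLike) -> None:
        self.subjects.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | os.PathLike,
                 durations_path: str | os.PathLike | None = None) -> "CohortTable":
        subjects = pd.read_csv(path, sep="\t")
        durations = None
        if durations_path is not None:
            durations = pd.read_csv(durations_path, sep="\t")
        return cls(subjects=subjects, durations=durations)


# ---------------------------------------------------------------------------
# lesion masks
# ---------------------------------------------------------------------------

def read_lesion_masks(paths: Sequence[str | os.PathLike]) -> list[LesionMask]:
    """Load binary lesion masks, enforcing a common grid.

    Intensities > 0.5 become 1, everything else 0. The first mask defines
    the reference geometry; any later file whose shape or affine differs
    (affine tolerance 1e-4) raises :class:`CohortConsistencyError` naming
    the offending file.
    """
    masks: list[LesionMask] = []
    ref_shape = ref_affine = None
    for path in paths:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        if data.ndim == 4 and data.shape[3] == 1:
            data = data[..., 0]
        if data.ndim != 3:
            raise DimensionalityError(f"{path}: expected a 3-D volume, got {data.ndim}-D")
        affine = np.asarray(img.affine, dtype=float)
        if ref_shape is None:
            ref_shape, ref_affine = data.shape, affine
        else:
            if data.shape != ref_shape:
                raise CohortConsistencyError(
                    f"{path}: shape {data.shape} differs from cohort shape {ref_shape}"
                )
            if np.abs(affine - ref_affine).max() > AFFINE_TOL:
                raise CohortConsistencyError(
                    f"{path}: affine differs from cohort affine by more than {AFFINE_TOL}"
                )
        grid = (data > 0.5).astype(np.uint8)
        subject_id = _subject_id_from_path(path)
        masks.append(LesionMask(subject_id=subject_id, grid=grid, affine=affine))
    return masks


def _subject_id_from_path(path) -> str:
    name = os.path.basename(str(path))
    for ext in (".nii.gz", ".nii"):
        if name.endswith(ext):
            return name[: -len(ext)]
    return os.path.splitext(name)[0]


def write_lesion_mask(mask: LesionMask, path: str | os.PathLike) -> None:
    img = nib.Nifti1Image(mask.grid.astype(np.uint8), mask.affine)
    nib.save(img, str(path))


def lesion_volume_cm3(mask: LesionMask) -> float:
    """Lesion volume in cm^3: (number of lesioned voxels) x voxel volume / 1000."""
    return mask.n_lesioned * mask.voxel_volume_mm3 / 1000.0


# ---------------------------------------------------------------------------
# connectomes
# ---------------------------------------------------------------------------

def read_parcel_labels(path: str | os.PathLike) -> list[str]:
    """Read a one-column parcel label table (TSV, no header)."""
    with open(path) as fh:
        labels = [line.strip() for line in fh if line.strip()]
    return labels


def write_parcel_labels(labels: Sequence[str], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for lab in labels:
            fh.write(f"{lab}\n")


def read_connectome(path: str | os.PathLike,
                    labels: Sequence[str] | str | os.PathLike) -> Connectome:
    """Read a delimited parcel x parcel weight matrix.

    ``labels`` may be a label list or a path to a label file. The matrix
    must be square and match the label count. Small numeric asymmetry
    (<= 1e-6 max abs difference) is repaired by averaging with the
    transpose; larger asymmetry is an error. A nonzero diagonal is zeroed
    with a warning (self-connections are meaningless here).
    """
    if isinstance(labels, (str, os.PathLike)):
        labels = read_parcel_labels(labels)
    labels = list(labels)
    W = np.loadtxt(str(path), delimiter="\t", ndmin=2)
    if W.shape[0] != W.shape[1]:
        raise DataError(f"{path}: connectome matrix is not square: {W.shape}")
    if W.shape[0] != len(labels):
        raise AlignmentError(
            f"{path}: matrix dimension {W.shape[0]} != {len(labels)} labels"
        )
    if (W < 0).any():
        raise DataError(f"{path}: negative connectome weights")
    asym = np.abs(W - W.T).max()
    if asym > 1e-6:
        raise DataError(f"{path}: asymmetry {asym:.3g} exceeds 1e-6")
    W = (W + W.T) / 2.0
    if np.abs(np.diag(W)).max() > 0:
        logger.warning("%s: nonzero diagonal zeroed", path)
        np.fill_diagonal(W, 0.0)
    return Connectome(parcel_labels=labels, weights=W)


def write_connectome(conn: Connectome, path: str | os.PathLike) -> None:
    np.savetxt(str(path), conn.weights, delimiter="\t", fmt="%.10g")


# ---------------------------------------------------------------------------
# statistical outputs
# ---------------------------------------------------------------------------

def write_stat_map(stat_map: StatMap, path: str | os.PathLike) -> None:
    """Write a stat map as float32 NIfTI (read-back within float32 rounding)."""
    img = nib.Nifti1Image(stat_map.values.astype(np.float32), stat_map.affine)
    nib.save(img, str(path))


def read_stat_map(path: str | os.PathLike, kind: str) -> StatMap:
    img = nib.load(str(path))
    return StatMap(values=np.asanyarray(img.dataobj, dtype=np.float64),
                   affine=np.asarray(img.affine, dtype=float), kind=kind)


EDGE_TABLE_COLUMNS = ("parcel_a", "parcel_b", "beta", "p_fwer", "significant")


def write_edge_table(results, path: str | os.PathLike) -> None:
    """Write edge-level inference results as TSV.

    ``results`` is an iterable of objects with ``parcel_a``, ``parcel_b``,
    ``beta``, ``p_fwer`` and ``significant`` attributes (see
    :mod:`strokemap.clsm`). An empty list yields a header-only file.
    """
    rows = [
        {
            "parcel_a": r.parcel_a,
            "parcel_b": r.parcel_b,
            "beta": r.beta,
            "p_fwer": r.p_fwer,
            "significant": bool(r.significant),
        }
        for r in results
    ]
    pd.DataFrame(rows, columns=list(EDGE_TABLE_COLUMNS)).to_csv(
        path, sep="\t", index=False
    )


def read_edge_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
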