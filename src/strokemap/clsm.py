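"""Connectome-based SVR lesion-symptom mapping on binary disconnectomes.

A patient's **disconnectome** marks an edge (parcel pair) as lesioned (1)
exactly when the connection is absent in the patient's connectome but
present in 100% of control connectomes; edges missing in any control are
excluded from analysis altogether (they cannot be distinguished from
normal anatomical variation, and excluding them reduces Type I error).
"Absent" means a weight of exactly 0 — a tolerance (default 1e-12) guards
float-valued inputs.

Edge designs keep upper-triangle analyzable edges disconnected in strictly
more than 10% of patients (note the strict inequality, in contrast to the
voxel filter's >=). Edge-level familywise error control is single-step
maxT-style: the null statistic for each permutation is the *minimum* beta
over edges, matching the one-tailed negative test; connectome space has no
spatial clusters to exploit.

Parcel-level evaluation aggregates each parcel's retained incident edges.
The statistic is the sum of the negative parts of the incident edge betas
(larger = more deficit-associated disconnection at that parcel), with a
max-statistic permutation null over parcels reusing the identical
permutation stream. The aggregation choice is a package decision — see the
methods note — and alternatives can be swapped in via ``parcel_statistic``.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .behavior import BehaviorTarget
from .cohort_io import Connectome
from .exceptions import AlignmentError, CohortConsistencyError, EmptyDesignError
from .svr_engine import PermutationNull, PermutationScheme, SvrConfig, permutation_null, residualize

logger = logging.getLogger(__name__)

ZERO_TOL = 1e-12


@dataclass
class DisconnectionMatrix:
    """Binary lesion analogue in connectome space for one patient.

    ``D[a, b] = 1`` iff the edge is analyzable (present in all controls)
    and absent in the patient. Symmetric, zero diagonal.
    """

    subject_id: str
    parcel_labels: list[str]
    D: np.ndarray                # binary, symmetric
    analyzable_mask: np.ndarray  # binary, symmetric; 1 = present in 100% of controls

    def __post_init__(self):
        self.D = np.asarray(self.D, dtype=np.uint8)
        self.analyzable_mask = np.asarray(self.analyzable_mask, dtype=np.uint8)
        assert (self.D <= self.analyzable_mask).all()


def binarize_disconnection(patient: Connectome, controls: list[Connectome],
                           subject_id: str = "", zero_tol: float = ZERO_TOL
                           ) -> DisconnectionMatrix:
    """Apply the absent-in-patient AND present-in-all-controls rule.

    Requires at least 2 controls sharing the patient's parcel labels.
    """
    if len(controls) < 2:
        raise CohortConsistencyError("need at least 2 control connectomes")
    for c in controls:
        if c.parcel_labels != patient.parcel_labels:
            raise AlignmentError("parcel labels differ between patient and controls")
    control_stack = np.stack([c.weights for c in controls])
    analyzable = (control_stack > zero_tol).all(axis=0)
    np.fill_diagonal(analyzable, False)
    D = analyzable & (patient.weights <= zero_tol)
    return DisconnectionMatrix(
        subject_id=subject_id or "patient",
        parcel_labels=list(patient.parcel_labels),
        D=D.astype(np.uint8),
        analyzable_mask=analyzable.astype(np.uint8),
    )


@dataclass
class EdgeDesign:
    """Patients x retained-edges binary disconnection matrix.

    ``edge_index[j]`` is the (row, col) upper-triangle parcel-pair of
    column j; ``disconnection_fraction[j]`` the fraction of patients with
    that edge disconnected (each strictly above ``min_fraction``).
    """

    X: np.ndarray
    edge_index: np.ndarray        # n_edges x 2 int (a < b)
    disconnection_fraction: np.ndarray
    min_fraction: float
    parcel_labels: list[str]
    analyzable_mask: np.ndarray
    subject_ids: list[str]

    @property
    def n_edges(self) -> int:
        return self.X.shape[1]

    def edge_labels(self) -> list[tuple[str, str]]:
        return [(self.parcel_labels[a], self.parcel_labels[b])
                for a, b in self.edge_index]


def build_edge_design(disconn: list[DisconnectionMatrix],
                      min_fraction: float = 0.10) -> EdgeDesign:
    """Retain analyzable upper-triangle edges disconnected in > ``min_fraction``.

    The analyzable mask is shared across patients by construction (it
    depends only on the controls); a mismatch raises an alignment error.
    """
    if len(disconn) < 10:
        raise CohortConsistencyError(f"need >= 10 patients, got {len(disconn)}")
    labels = disconn[0].parcel_labels
    mask = disconn[0].analyzable_mask
    for d in disconn[1:]:
        if d.parcel_labels != labels:
            raise AlignmentError("parcel labels differ across disconnectomes")
        if not np.array_equal(d.analyzable_mask, mask):
            raise AlignmentError("analyzable masks differ across disconnectomes")
    n_parcels = len(labels)
    iu = np.triu_indices(n_parcels, k=1)
    stack = np.stack([d.D[iu] for d in disconn]).astype(float)  # n x E
    frac = stack.mean(axis=0)
    keep = (mask[iu] == 1) & (frac > min_fraction)
    if not keep.any():
        raise EmptyDesignError("no edge disconnected in more than the minimum fraction")
    edge_index = np.column_stack([iu[0][keep], iu[1][keep]])
    return EdgeDesign(
        X=stack[:, keep],
        edge_index=edge_index,
        disconnection_fraction=frac[keep],
        min_fraction=min_fraction,
        parcel_labels=list(labels),
        analyzable_mask=mask,
        subject_ids=[d.subject_id for d in disconn],
    )


@dataclass
class EdgeResult:
    """Edge-level inference output for one parcel pair."""

    parcel_a: str
    parcel_b: str
    beta: float
    p_fwer: float
    significant: bool


@dataclass
class ParcelResult:
    """Parcel-level inference output (aggregate over incident edges)."""

    parcel: str
    statistic: float
    p_fwer: float | None
    significant: bool
    analyzable: bool
    n_incident_edges: int


@dataclass
class ClsmResult:
    """Full output of one connectome-wise analysis."""

    edges: list[EdgeResult]
    design: EdgeDesign
    null: PermutationNull

    @property
    def significant_edges(self) -> list[EdgeResult]:
        return [e for e in self.edges if e.significant]


def edge_inference(design: EdgeDesign, target: BehaviorTarget,
                   cfg: SvrConfig = SvrConfig(),
                   scheme: PermutationScheme = PermutationScheme()) -> ClsmResult:
    """Edge-level SVR-CLSM with single-step maxT permutation FWER.

    p_fwer for edge j is (1 + #{b : min_k beta_k^(b) <= beta_j^obs}) /
    (n_perm + 1); significance at p_fwer < alpha.
    """
    if design.X.shape[0] != len(target.subject_ids):
        raise AlignmentError("design rows do not match behavior target subjects")
    C = target.covariates
    Xr = residualize(design.X, C)
    yr = residualize(target.y.reshape(-1, 1), C).ravel()
    null = permutation_null(Xr, yr, cfg, scheme)

    null_min = null.beta_perm.min(axis=1)  # per-permutation extreme statistic
    p_fwer = (1.0 + (null_min[:, None] <= null.beta_obs[None, :]).sum(axis=0)) \
        / (scheme.n_perm + 1.0)

    labels = design.edge_labels()
    edges = [
        EdgeResult(parcel_a=a, parcel_b=b, beta=float(beta), p_fwer=float(p),
                   significant=bool(p < scheme.alpha))
        for (a, b), beta, p in zip(labels, null.beta_obs, p_fwer)
    ]
    return ClsmResult(edges=edges, design=design, null=null)


def parcel_statistic(betas: np.ndarray, incidence: np.ndarray) -> np.ndarray:
    """Sum of negative parts of incident-edge betas, per parcel.

    ``incidence`` is parcels x edges binary; larger statistic = more
    deficit-associated disconnection converging on the parcel.
    """
    return incidence @ np.maximum(-betas, 0.0)


def parcel_inference(result: ClsmResult,
                     scheme: PermutationScheme = PermutationScheme()
                     ) -> list[ParcelResult]:
    """Parcel-level FWER reusing the edge permutation stream.

    The null is, per permutation, the maximum over analyzable parcels of
    the same aggregate computed on that permutation's betas. Parcels with
    no retained incident edge are reported as not analyzable (no p).
    """
    design = result.design
    n_parcels = len(design.parcel_labels)
    incidence = np.zeros((n_parcels, design.n_edges))
    for j, (a, b) in enumerate(design.edge_index):
        incidence[a, j] = 1.0
        incidence[b, j] = 1.0
    has_edges = incidence.sum(axis=1) > 0

    obs_stat = parcel_statistic(result.null.beta_obs, incidence)
    perm_stats = parcel_statistic(result.null.beta_perm.T, incidence)  # parcels x n_perm
    null_max = perm_stats[has_edges].max(axis=0) if has_edges.any() \
        else np.zeros(result.null.beta_perm.shape[0])

    out: list[ParcelResult] = []
    n_perm = result.null.beta_perm.shape[0]
    for i, label in enumerate(design.parcel_labels):
        if not has_edges[i]:
            out.append(ParcelResult(parcel=label, statistic=0.0, p_fwer=None,
                                    significant=False, analyzable=False,
                                    n_incident_edges=0))
            continue
        p = (1.0 + (null_max >= obs_stat[i]).sum()) / (n_perm + 1.0)
        out.append(ParcelResult(parcel=label, statistic=float(obs_stat[i]),
                                p_fwer=float(p), significant=bool(p < scheme.alpha),
                                analyzable=True,
                                n_incident_edges=int(incidence[i].sum())))
    return out
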