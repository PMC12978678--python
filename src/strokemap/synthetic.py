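"""Synthetic stroke cohorts with exported ground truth.

Generates everything the lesion-symptom mapping pipeline consumes — left
hemisphere lesion masks, control and patient structural connectomes, and a
cohort behavior table — from a seeded generative model whose parameters are
modeled on a 64-patient / 71-control left-hemisphere stroke reading study:

* **Atlas** — a miniature two-hemisphere parcellation (seeded Voronoi
  parcels on a 20 x 24 x 20 grid at 2 mm, default 4 parcels per
  hemisphere), with straight-line voxel trajectories between left
  intra-hemispheric parcel pairs and homotopic cross-hemisphere pairs
  standing in for white-matter tracts.
* **Lesions** — spatially contiguous (26-connected) single components
  grown from a random left-hemisphere seed, biased toward a designated
  "perisylvian" territory; target voxel counts are lognormal, matching a
  cohort whose lesion volumes have mean ~90 cm^3 with coefficient of
  variation ~0.87, scaled to the toy grid.
* **Connectomes** — control edge weights are a base weight with
  multiplicative noise; a configurable minority of edges is unreliably
  present (zeroed in a random 30% of controls) to exercise the
  present-in-100%-of-controls filter. A patient's edge weight is zeroed
  exactly when the lesion intersects the edge's tract trajectory, so every
  disconnection is causally explained by the lesion.
* **Behavior** — per stimulus class (200 real words; 20 pseudowords each
  with zero/one/multiple learned spelling-to-sound body mappings),
  n_correct ~ Binomial(n, p) with logit(p) = baseline + covariate effects
  - effect_weight x (damaged fraction of the critical region, or an
  indicator of critical-edge disconnection). Baseline accuracies follow
  the control group's observed means; per-item durations are lognormal,
  capped at the 10 s trial timeout.

With all effect weights at 0 the behavior is independent of the lesions —
the null configuration used to measure empirical familywise error rates.
Regeneration from the same (parameters, seed) is bitwise reproducible.
"""
from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .cohort_io import STIM_CLASSES, CohortTable, Connectome, LesionMask
from .exceptions import ConfigurationError, DataError

logger = logging.getLogger(__name__)

# study-scale demographics emulated by the generator
AGE_MEAN, AGE_SD, AGE_RANGE = 61.6, 11.5, (31.0, 92.0)
EDU_MEAN, EDU_SD, EDU_RANGE = 16.5, 2.8, (9.0, 21.0)

#: trial counts of the oral reading battery
TRIAL_COUNTS = {"real_word": 200, "PW0M": 20, "PW1M": 20, "PWMM": 20}

#: baseline accuracy logits ~ control-group mean accuracies
#: (real 94.3%, 0M 89.7%, 1M 94.3%, MM 93.2%)
BASELINE_LOGIT = {
    "real_word": 2.806,
    "PW0M": 2.165,
    "PW1M": 2.806,
    "PWMM": 2.617,
}


# ---------------------------------------------------------------------------
# atlas
# ---------------------------------------------------------------------------

@dataclass
class ToyAtlas:
    """Miniature two-hemisphere parcellation with tract trajectories.

    ``labels`` assigns every voxel to exactly one parcel (0..2K-1; left
    parcels 0..K-1, mirrored right parcels K..2K-1) or background (-1).
    ``trajectories`` maps an (a, b) parcel pair to the ordered voxel path
    between the two parcel centroids.
    """

    labels: np.ndarray                       # 3-D int
    centroids: np.ndarray                    # 2K x 3 float (voxel units)
    trajectories: dict[tuple[int, int], np.ndarray]
    K: int
    voxel_size_mm: float = 2.0

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def n_parcels(self) -> int:
        return 2 * self.K

    @property
    def affine(self) -> np.ndarray:
        """Voxel -> mm affine, isotropic, grid center at the origin."""
        v = self.voxel_size_mm
        aff = np.diag([v, v, v, 1.0])
        aff[:3, 3] = -(np.array(self.shape) - 1) * v / 2.0
        return aff

    def parcel_labels(self) -> list[str]:
        return [f"L{i + 1}" for i in range(self.K)] + \
               [f"R{i + 1}" for i in range(self.K)]

    def left_mask(self) -> np.ndarray:
        nx = self.shape[0]
        out = np.zeros(self.shape, dtype=bool)
        out[: nx // 2] = True
        return out


def voxel_line(p0, p1) -> np.ndarray:
    """Voxelized straight segment between two integer voxels, inclusive.

    Linear interpolation rounded to the grid: endpoints are exact and
    consecutive voxels differ by at most one step per axis (26-connected).
    """
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    n = int(np.abs(p1 - p0).max())
    if n == 0:
        return p0[None, :].astype(int)
    pts = np.round(np.linspace(p0, p1, n + 1)).astype(int)
    # drop consecutive duplicates produced by rounding
    keep = np.ones(len(pts), dtype=bool)
    keep[1:] = (np.diff(pts, axis=0) != 0).any(axis=1)
    return pts[keep]


def make_atlas(shape=(20, 24, 20), K: int = 4, seed: int = 0,
               voxel_size_mm: float = 2.0) -> ToyAtlas:
    """Seeded-Voronoi left-hemisphere parcels mirrored to the right.

    Trajectories connect every pair of left parcels and every homotopic
    left-right pair. K >= 4 and every axis >= 12 voxels.
    """
    shape = tuple(int(s) for s in shape)
    if K < 4:
        raise ConfigurationError("K must be >= 4")
    if min(shape) < 12:
        raise ConfigurationError("every grid axis must be >= 12 voxels")
    nx, ny, nz = shape
    n_left = (nx // 2) * ny * nz
    if K > n_left // 8:
        raise ConfigurationError(f"K={K} infeasible on a grid with {n_left} left voxels")

    rng = np.random.default_rng([seed, 1])
    left = np.zeros(shape, dtype=bool)
    left[: nx // 2] = True
    left_coords = np.argwhere(left)

    seed_idx = rng.choice(len(left_coords), size=K, replace=False)
    seeds = left_coords[seed_idx].astype(float)

    # nearest-seed assignment over the left half
    d2 = ((left_coords[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
    assign = d2.argmin(axis=1)

    labels = np.full(shape, -1, dtype=np.int32)
    labels[tuple(left_coords.T)] = assign
    # mirror across the midline: right voxel (x,y,z) <- left (nx-1-x,y,z)
    for x in range(nx // 2, nx):
        mirrored = labels[nx - 1 - x]
        labels[x] = np.where(mirrored >= 0, mirrored + K, -1)

    centroids = np.zeros((2 * K, 3))
    for p in range(2 * K):
        centroids[p] = np.argwhere(labels == p).mean(axis=0)

    trajectories: dict[tuple[int, int], np.ndarray] = {}
    ends = np.round(centroids).astype(int)
    for i in range(K):
        for j in range(i + 1, K):
            trajectories[(i, j)] = voxel_line(ends[i], ends[j])
    for i in range(K):  # homotopic cross-hemisphere connections
        trajectories[(i, i + K)] = voxel_line(ends[i], ends[i + K])

    return ToyAtlas(labels=labels, centroids=centroids,
                    trajectories=trajectories, K=K, voxel_size_mm=voxel_size_mm)


def perisylvian_territory(atlas: ToyAtlas, radius_voxels: float | None = None
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Designated lesion-prone territory: a ball in mid-left hemisphere.

    Returns (boolean grid, center voxel coordinate). Default radius is a
    third of the smallest grid axis.
    """
    shape = np.array(atlas.shape)
    center = np.array([shape[0] // 4, shape[1] // 2, shape[2] // 2], dtype=float)
    if radius_voxels is None:
        radius_voxels = min(atlas.shape) / 3.0
    grid = np.indices(atlas.shape).reshape(3, -1).T
    ball = ((grid - center) ** 2).sum(axis=1) <= radius_voxels ** 2
    territory = np.zeros(atlas.shape, dtype=bool)
    territory[tuple(grid[ball].T)] = True
    territory &= atlas.left_mask()
    return territory, center


_NEIGH26 = np.array([(dx, dy, dz)
                     for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
                     if (dx, dy, dz) != (0, 0, 0)])


def simulate_lesions(n: int, atlas: ToyAtlas,
                     volume_lognormal: tuple[float, float] = (5.5, 0.75),
                     territory_bias: float = 0.7,
                     seed: int = 0) -> list[LesionMask]:
    """Grow ``n`` contiguous left-hemisphere lesions by stochastic accretion.

    Each lesion starts at a random left-hemisphere voxel (with probability
    ``territory_bias`` drawn from the perisylvian territory) and grows by
    repeatedly annexing a uniformly chosen 26-neighbor of the current
    component until a lognormal target voxel count is reached, so every
    lesion is a single 26-connected component of exactly the drawn size
    (clipped, with a warning, if it exceeds the hemisphere).

    The default (mu, sigma) = (5.5, 0.75) gives a mean of ~320 voxels
    (2.6 cm^3 at 2 mm) with coefficient of variation ~0.87 — the real
    cohort's lesion-volume CV at toy-grid scale.
    """
    if n < 10:
        raise ConfigurationError("need n >= 10 lesions")
    mu, sigma = volume_lognormal
    territory, _ = perisylvian_territory(atlas)
    left = atlas.left_mask()
    territory_coords = np.argwhere(territory)
    left_coords = np.argwhere(left)
    n_left = len(left_coords)
    affine = atlas.affine
    masks = []
    for i in range(n):
        rng = np.random.default_rng([seed, 2, i])
        target = int(round(rng.lognormal(mu, sigma)))
        target = max(target, 5)
        if target > n_left:
            logger.warning("lesion %d target %d exceeds hemisphere; clipped", i, target)
            target = n_left
        if rng.random() < territory_bias:
            start = tuple(territory_coords[rng.integers(len(territory_coords))])
        else:
            start = tuple(left_coords[rng.integers(len(left_coords))])
        grid = np.zeros(atlas.shape, dtype=np.uint8)
        grid[start] = 1
        frontier: list[tuple[int, int, int]] = []
        in_frontier = set()

        def push_neighbors(vox):
            for d in _NEIGH26:
                nb = (vox[0] + d[0], vox[1] + d[1], vox[2] + d[2])
                if (0 <= nb[0] < atlas.shape[0] and 0 <= nb[1] < atlas.shape[1]
                        and 0 <= nb[2] < atlas.shape[2] and left[nb]
                        and not grid[nb] and nb not in in_frontier):
                    frontier.append(nb)
                    in_frontier.add(nb)

        push_neighbors(start)
        size = 1
        while size < target and frontier:
            idx = rng.integers(len(frontier))
            vox = frontier[idx]
            frontier[idx] = frontier[-1]
            frontier.pop()
            in_frontier.discard(vox)
            grid[vox] = 1
            size += 1
            push_neighbors(vox)
        masks.append(LesionMask(subject_id=f"sub{i + 1:03d}", grid=grid,
                                affine=affine))
    return masks


def simulate_connectomes(atlas: ToyAtlas, lesions: list[LesionMask],
                         n_controls: int = 71,
                         base_weight: float = 10.0,
                         weight_noise: float = 0.1,
                         unreliable_edge_fraction: float = 0.1,
                         control_absence_fraction: float = 0.3,
                         protected_edges: tuple[tuple[int, int], ...] = (),
                         seed: int = 0):
    """Control and patient connectomes tied causally to the lesions.

    Control weights are ``base_weight x (1 + U(-noise, +noise))``; a
    fraction of edges (never those in ``protected_edges``) is unreliably
    present, zeroed in ``control_absence_fraction`` of controls. A
    patient's edge is zeroed exactly when their lesion intersects the
    edge's trajectory; otherwise it gets a control-like weight.

    Returns ``(controls, patients, severed, unreliable_edges)`` where
    ``severed`` maps subject_id to the list of lesion-severed edges —
    the generator's causal bookkeeping.
    """
    labels = atlas.parcel_labels()
    P = atlas.n_parcels
    edges = sorted(atlas.trajectories.keys())
    rng = np.random.default_rng([seed, 3])

    n_unreliable = int(round(unreliable_edge_fraction * len(edges)))
    candidates = [e for e in edges if e not in set(protected_edges)]
    unreliable = [candidates[i] for i in
                  rng.choice(len(candidates), size=min(n_unreliable, len(candidates)),
                             replace=False)] if n_unreliable else []

    n_absent = int(round(control_absence_fraction * n_controls))
    absent_in: dict[tuple[int, int], set[int]] = {}
    for e in unreliable:
        absent_in[e] = set(rng.choice(n_controls, size=n_absent, replace=False).tolist())

    controls = []
    for c in range(n_controls):
        W = np.zeros((P, P))
        for e in edges:
            if c in absent_in.get(e, ()):
                continue
            w = base_weight * (1.0 + rng.uniform(-weight_noise, weight_noise))
            W[e[0], e[1]] = W[e[1], e[0]] = w
        controls.append(Connectome(parcel_labels=labels, weights=W))

    # trajectory voxels as flat indices for fast intersection tests
    flat_traj = {e: np.ravel_multi_index(t.T, atlas.shape)
                 for e, t in atlas.trajectories.items()}
    patients, severed = [], {}
    for mask in lesions:
        flat_lesion = np.flatnonzero(mask.grid.ravel())
        lesion_set = set(flat_lesion.tolist())
        W = np.zeros((P, P))
        cut = []
        for e in edges:
            if any(v in lesion_set for v in flat_traj[e]):
                cut.append(e)
                continue
            w = base_weight * (1.0 + rng.uniform(-weight_noise, weight_noise))
            W[e[0], e[1]] = W[e[1], e[0]] = w
        patients.append(Connectome(parcel_labels=labels, weights=W))
        severed[mask.subject_id] = cut
    return controls, patients, severed, unreliable


# ---------------------------------------------------------------------------
# ground truth + behavior
# ---------------------------------------------------------------------------

@dataclass
class SyntheticTruth:
    """Everything needed to score recovery and reproduce a cohort.

    ``effect_weights``/``edge_effect_weights`` are logit-scale deficits per
    stimulus class: the former scales with the damaged *fraction* of the
    critical region (graded signal for voxelwise mapping), the latter is
    switched by disconnection of any critical edge (binary, matching the
    connectome design matrix).
    """

    critical_region: np.ndarray               # m x 3 voxel coords (may be empty)
    critical_edges: list[tuple[int, int]]
    effect_weights: dict[str, float]
    edge_effect_weights: dict[str, float]
    covariate_coefficients: dict[str, float]
    baseline_logit: dict[str, float]
    trial_counts: dict[str, int]
    seed: int
    severed_edges: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    unreliable_edges: list[tuple[int, int]] = field(default_factory=list)

    def region_centroid(self) -> np.ndarray:
        if len(self.critical_region) == 0:
            raise DataError("truth has no critical region")
        return np.asarray(self.critical_region, dtype=float).mean(axis=0)

    def to_json(self, path) -> None:
        d = {
            "critical_region": np.asarray(self.critical_region).tolist(),
            "critical_edges": [list(e) for e in self.critical_edges],
            "effect_weights": self.effect_weights,
            "edge_effect_weights": self.edge_effect_weights,
            "covariate_coefficients": self.covariate_coefficients,
            "baseline_logit": self.baseline_logit,
            "trial_counts": self.trial_counts,
            "seed": self.seed,
            "severed_edges": {k: [list(e) for e in v]
                              for k, v in self.severed_edges.items()},
            "unreliable_edges": [list(e) for e in self.unreliable_edges],
        }
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            critical_region=np.asarray(d["critical_region"], dtype=int).reshape(-1, 3),
            critical_edges=[tuple(e) for e in d["critical_edges"]],
            effect_weights=d["effect_weights"],
            edge_effect_weights=d["edge_effect_weights"],
            covariate_coefficients=d["covariate_coefficients"],
            baseline_logit=d["baseline_logit"],
            trial_counts={k: int(v) for k, v in d["trial_counts"].items()},
            seed=int(d["seed"]),
            severed_edges={k: [tuple(e) for e in v]
                           for k, v in d["severed_edges"].items()},
            unreliable_edges=[tuple(e) for e in d["unreliable_edges"]],
        )


def critical_region_voxels(atlas: ToyAtlas, size: int = 100) -> np.ndarray:
    """The ``size`` left-hemisphere voxels nearest the territory center."""
    territory, center = perisylvian_territory(atlas)
    left_coords = np.argwhere(atlas.left_mask())
    d2 = ((left_coords - center) ** 2).sum(axis=1)
    order = np.lexsort((left_coords[:, 2], left_coords[:, 1], left_coords[:, 0], d2))
    return left_coords[order[:size]]


def critical_edge_choices(atlas: ToyAtlas, n: int = 1) -> list[tuple[int, int]]:
    """Left intra-hemispheric edges whose trajectories pass nearest the
    territory center — the most lesion-exposed, hence recoverable, edges."""
    _, center = perisylvian_territory(atlas)
    left_edges = [e for e in sorted(atlas.trajectories) if e[1] < atlas.K]
    def min_dist(e):
        t = atlas.trajectories[e].astype(float)
        return ((t - center) ** 2).sum(axis=1).min()
    return sorted(left_edges, key=min_dist)[:n]


def _truncated_normal(rng, mean, sd, lo, hi, size):
    out = rng.normal(mean, sd, size=size)
    for _ in range(100):
        bad = (out < lo) | (out > hi)
        if not bad.any():
            break
        out[bad] = rng.normal(mean, sd, size=bad.sum())
    return np.clip(out, lo, hi)


def simulate_behavior(lesions: list[LesionMask], truth: SyntheticTruth,
                      n_controls: int = 71, seed: int = 0,
                      with_durations: bool = False) -> CohortTable:
    """Draw demographics and binomial trial outcomes for the whole cohort.

    Patients' class-wise accuracy logit is
    ``baseline + b_age*age_z + b_edu*edu_z - w_region*damage_frac
    - w_edge*1[critical edge severed]``; controls have no lesion terms.
    Durations (optional) are lognormal per item, capped at the 10 s
    timeout.
    """
    rng = np.random.default_rng([seed, 4])
    region = np.asarray(truth.critical_region, dtype=int).reshape(-1, 3)
    region_flat = (np.ravel_multi_index(region.T, lesions[0].grid.shape)
                   if len(region) else np.empty(0, dtype=int))

    rows, dur_rows = [], []
    b_age = truth.covariate_coefficients.get("age", 0.0)
    b_edu = truth.covariate_coefficients.get("education", 0.0)

    def add_subject(sid, group, damage_frac, edge_hit, lesion_vol):
        age = _truncated_normal(rng, AGE_MEAN, AGE_SD, *AGE_RANGE, size=1)[0]
        edu = _truncated_normal(rng, EDU_MEAN, EDU_SD, *EDU_RANGE, size=1)[0]
        row = {"subject_id": sid, "group": group,
               "age": round(float(age), 1), "education": round(float(edu), 1),
               "lesion_volume_cm3": lesion_vol}
        age_z = (age - AGE_MEAN) / AGE_SD
        edu_z = (edu - EDU_MEAN) / EDU_SD
        for cls in STIM_CLASSES:
            n_trials = truth.trial_counts[cls]
            lg = (truth.baseline_logit[cls] + b_age * age_z + b_edu * edu_z
                  - truth.effect_weights.get(cls, 0.0) * damage_frac
                  - truth.edge_effect_weights.get(cls, 0.0) * edge_hit)
            p = float(expit(lg))
            row[f"{cls}_presented"] = n_trials
            row[f"{cls}_correct"] = int(rng.binomial(n_trials, p))
            if with_durations:
                d = np.minimum(rng.lognormal(np.log(1.5), 0.5, size=n_trials), 10.0)
                dur_rows.extend(
                    {"subject_id": sid, "stim_class": cls, "item": k + 1,
                     "seconds": float(s)} for k, s in enumerate(d))
        rows.append(row)

    for c in range(n_controls):
        add_subject(f"ctl{c + 1:03d}", "control", 0.0, 0.0, np.nan)
    for mask in lesions:
        if len(region_flat):
            flat = np.flatnonzero(mask.grid.ravel())
            overlap = np.intersect1d(flat, region_flat, assume_unique=True).size
            damage_frac = overlap / len(region_flat)
        else:
            damage_frac = 0.0
        cut = set(map(tuple, truth.severed_edges.get(mask.subject_id, ())))
        edge_hit = float(any(tuple(e) in cut for e in truth.critical_edges))
        vol = mask.n_lesioned * mask.voxel_volume_mm3 / 1000.0
        add_subject(mask.subject_id, "patient", damage_frac, edge_hit, vol)

    durations = pd.DataFrame(dur_rows) if with_durations else None
    return CohortTable(subjects=pd.DataFrame(rows), durations=durations)


# ---------------------------------------------------------------------------
# full-cohort convenience
# ---------------------------------------------------------------------------

@dataclass
class CohortParams:
    """Generator settings; the defaults are the study conditions emulated.

    ``region_effect`` / ``edge_effect`` are the logit-scale deficits wired
    to the critical region / critical edge for the pseudoword classes; 0
    gives a null cohort (behavior independent of lesions).
    """

    n_patients: int = 64
    n_controls: int = 71
    shape: tuple[int, int, int] = (20, 24, 20)
    voxel_size_mm: float = 2.0
    K: int = 4
    volume_lognormal: tuple[float, float] = (5.5, 0.75)
    territory_bias: float = 0.7
    base_weight: float = 10.0
    weight_noise: float = 0.1
    unreliable_edge_fraction: float = 0.1
    control_absence_fraction: float = 0.3
    region_effect: float = 0.0
    edge_effect: float = 0.0
    critical_region_size: int = 100
    n_critical_edges: int = 1
    effect_classes: tuple[str, ...] = ("PW0M", "PW1M", "PWMM")
    covariate_coefficients: dict = field(
        default_factory=lambda: {"age": -0.2, "education": 0.2})
    with_durations: bool = False


@dataclass
class SyntheticCohort:
    """A complete generated cohort plus its ground truth."""

    atlas: ToyAtlas
    masks: list[LesionMask]
    control_connectomes: list[Connectome]
    patient_connectomes: list[Connectome]
    cohort_table: CohortTable
    truth: SyntheticTruth
    params: CohortParams


def simulate_cohort(params: CohortParams = CohortParams(), seed: int = 0
                    ) -> SyntheticCohort:
    """Generate a full cohort deterministically from (params, seed)."""
    atlas = make_atlas(params.shape, params.K, seed=seed,
                       voxel_size_mm=params.voxel_size_mm)
    region = (critical_region_voxels(atlas, params.critical_region_size)
              if params.region_effect != 0.0 else np.empty((0, 3), dtype=int))
    crit_edges = (critical_edge_choices(atlas, params.n_critical_edges)
                  if params.edge_effect != 0.0 else [])
    masks = simulate_lesions(params.n_patients, atlas,
                             params.volume_lognormal, params.territory_bias,
                             seed=seed)
    controls, patients, severed, unreliable = simulate_connectomes(
        atlas, masks, params.n_controls, params.base_weight,
        params.weight_noise, params.unreliable_edge_fraction,
        params.control_absence_fraction,
        protected_edges=tuple(crit_edges), seed=seed)
    truth = SyntheticTruth(
        critical_region=region,
        critical_edges=crit_edges,
        effect_weights={c: params.region_effect for c in params.effect_classes},
        edge_effect_weights={c: params.edge_effect for c in params.effect_classes},
        covariate_coefficients=dict(params.covariate_coefficients),
        baseline_logit=dict(BASELINE_LOGIT),
        trial_counts=dict(TRIAL_COUNTS),
        seed=seed,
        severed_edges=severed,
        unreliable_edges=list(unreliable),
    )
    table = simulate_behavior(masks, truth, params.n_controls, seed=seed,
                              with_durations=params.with_durations)
    return SyntheticCohort(atlas=atlas, masks=masks,
                           control_connectomes=controls,
                           patient_connectomes=patients,
                           cohort_table=table, truth=truth, params=params)


# ---------------------------------------------------------------------------
# recovery scoring
# ---------------------------------------------------------------------------

@dataclass
class RecoveryMetrics:
    dice: float
    centroid_distance_voxels: float | None
    hit: bool


def recovery_metrics(detected, truth) -> RecoveryMetrics:
    """Dice overlap and centroid distance between detection and truth.

    ``detected``/``truth`` are either m x 3 voxel-coordinate arrays or
    collections of parcel-pair tuples (edges). Dice = 2|A∩B|/(|A|+|B|);
    both-empty yields dice 0 (logged). For voxels, ``hit`` means nonzero
    overlap; for edges it means every truth edge was detected.
    """
    if _is_edge_set(detected) or _is_edge_set(truth):
        A = {tuple(e) for e in detected}
        B = {tuple(e) for e in truth}
        dice = _dice(len(A & B), len(A), len(B))
        return RecoveryMetrics(dice=dice, centroid_distance_voxels=None,
                               hit=bool(B) and B <= A)
    A = np.asarray(detected, dtype=int).reshape(-1, 3)
    B = np.asarray(truth, dtype=int).reshape(-1, 3)
    sa = {tuple(v) for v in A}
    sb = {tuple(v) for v in B}
    dice = _dice(len(sa & sb), len(sa), len(sb))
    if len(A) and len(B):
        dist = float(np.linalg.norm(A.mean(axis=0) - B.mean(axis=0)))
    else:
        dist = np.inf
    return RecoveryMetrics(dice=dice, centroid_distance_voxels=dist,
                           hit=len(sa & sb) > 0)


def _is_edge_set(obj) -> bool:
    try:
        seq = list(obj)
    except TypeError:
        return False
    return bool(seq) and all(isinstance(e, tuple) and len(e) == 2 for e in seq)


def _dice(inter: int, na: int, nb: int) -> float:
    if na + nb == 0:
        logger.info("dice of two empty sets defined as 0")
        return 0.0
    return 2.0 * inter / (na + nb)
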