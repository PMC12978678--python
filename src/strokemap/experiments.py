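"""Validation experiments on synthetic cohorts.

Two kinds of study-condition experiments back the package's statistical
claims:

* **Null familywise error rate** — generate many independent cohorts whose
  behavior is independent of the lesions (all effect weights 0), run the
  full pipeline on each, and count the cohorts producing any significant
  finding. For a valid procedure this fraction stays at or below the
  nominal alpha, up to binomial sampling error.
* **Recovery** — wire a known deficit to a 100-voxel critical region (for
  the voxelwise analysis) or a single critical edge (for the
  connectome analysis), and score how often the pipeline localizes it
  (cluster centroid within 2 voxels of truth and Dice > 0.3; critical
  edge flagged significant).

Cohort i uses seed ``(base_seed + i) % 2^31``; the permutation scheme is
seeded with the same value, so every experiment is reproducible from a
single integer.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .exceptions import EmptyDesignError
from .pipeline import RunConfig, run_clsm, run_vlsm
from .svr_engine import PermutationScheme, SvrConfig
from .synthetic import CohortParams, recovery_metrics, simulate_cohort

#: Contrast used by the simulation experiments: pseudoword accuracy
#: controlling for real-word accuracy (the exaggerated-lexicality analysis).
EXPERIMENT_CONTRAST = "pseudowords_vs_realwords"


def _cohort_seed(base_seed: int, i: int) -> int:
    return (base_seed + i) % (2 ** 31)


def _config(n_perm: int, seed: int) -> RunConfig:
    return RunConfig(
        svr=SvrConfig(seed=seed),
        scheme=PermutationScheme(n_perm=n_perm, seed=seed),
    )


@dataclass
class FwerOutcome:
    """Empirical familywise error over replicate null cohorts."""

    n_cohorts: int
    n_with_false_positive: int
    nominal_alpha: float

    @property
    def fraction(self) -> float:
        return self.n_with_false_positive / self.n_cohorts

    @property
    def upper_bound(self) -> float:
        """Nominal level plus two binomial standard errors."""
        a = self.nominal_alpha
        return a + 2.0 * np.sqrt(a * (1.0 - a) / self.n_cohorts)

    @property
    def controlled(self) -> bool:
        return self.fraction <= self.upper_bound


def vlsm_null_fwer(n_cohorts: int = 100, n_perm: int = 500,
                   base_seed: int = 1,
                   params: CohortParams = CohortParams()) -> FwerOutcome:
    """Fraction of null cohorts with >= 1 significant cluster."""
    assert params.region_effect == 0.0 and params.edge_effect == 0.0
    n_fp = 0
    alpha = None
    for i in range(n_cohorts):
        seed = _cohort_seed(base_seed, i)
        cohort = simulate_cohort(params, seed=seed)
        config = _config(n_perm, seed)
        alpha = config.scheme.alpha
        run = run_vlsm(cohort.masks, cohort.cohort_table,
                       EXPERIMENT_CONTRAST, config)
        if run.result.significant_clusters:
            n_fp += 1
    return FwerOutcome(n_cohorts=n_cohorts, n_with_false_positive=n_fp,
                       nominal_alpha=alpha)


def clsm_null_fwer(n_cohorts: int = 100, n_perm: int = 500,
                   base_seed: int = 1,
                   params: CohortParams = CohortParams()) -> FwerOutcome:
    """Fraction of null cohorts with >= 1 significant edge.

    A cohort whose edge design is empty (no edge disconnected in more than
    the minimum fraction of patients) trivially has no significant edge.
    """
    assert params.region_effect == 0.0 and params.edge_effect == 0.0
    n_fp = 0
    alpha = 0.05
    for i in range(n_cohorts):
        seed = _cohort_seed(base_seed, i)
        cohort = simulate_cohort(params, seed=seed)
        config = _config(n_perm, seed)
        alpha = config.scheme.alpha
        try:
            run = run_clsm(cohort.patient_connectomes,
                           [m.subject_id for m in cohort.masks],
                           cohort.control_connectomes, cohort.cohort_table,
                           EXPERIMENT_CONTRAST, config)
        except EmptyDesignError:
            continue
        if run.result.significant_edges:
            n_fp += 1
    return FwerOutcome(n_cohorts=n_cohorts, n_with_false_positive=n_fp,
                       nominal_alpha=alpha)


@dataclass
class RecoveryOutcome:
    """Per-replicate localization scores for a seeded effect."""

    recovered: list[bool]
    dice: list[float]
    centroid_distance: list[float]

    @property
    def recovery_rate(self) -> float:
        return float(np.mean(self.recovered))


def vlsm_recovery(n_replicates: int = 20, n_perm: int = 500,
                  base_seed: int = 1000, region_effect: float = 4.0,
                  max_centroid_distance: float = 2.0,
                  min_dice: float = 0.3) -> RecoveryOutcome:
    """Localize a seeded 100-voxel critical region across replicates.

    A replicate counts as recovered when some significant cluster has
    centroid within ``max_centroid_distance`` voxels of the truth centroid
    and Dice > ``min_dice`` against the truth voxel set.
    """
    params = replace(CohortParams(), region_effect=region_effect)
    recovered, dices, dists = [], [], []
    for i in range(n_replicates):
        seed = _cohort_seed(base_seed, i)
        cohort = simulate_cohort(params, seed=seed)
        run = run_vlsm(cohort.masks, cohort.cohort_table,
                       EXPERIMENT_CONTRAST, _config(n_perm, seed))
        truth_vox = cohort.truth.critical_region
        best_dice, best_dist, ok = 0.0, np.inf, False
        for c in run.result.significant_clusters:
            m = recovery_metrics(c.voxels, truth_vox)
            if m.dice > best_dice:
                best_dice, best_dist = m.dice, m.centroid_distance_voxels
            if (m.centroid_distance_voxels <= max_centroid_distance
                    and m.dice > min_dice):
                ok = True
        recovered.append(ok)
        dices.append(best_dice)
        dists.append(best_dist)
    return RecoveryOutcome(recovered=recovered, dice=dices,
                           centroid_distance=dists)


def clsm_recovery(n_replicates: int = 20, n_perm: int = 500,
                  base_seed: int = 2000, edge_effect: float = 4.0
                  ) -> RecoveryOutcome:
    """Flag a seeded critical edge as significant across replicates."""
    params = replace(CohortParams(), edge_effect=edge_effect)
    recovered, dices = [], []
    for i in range(n_replicates):
        seed = _cohort_seed(base_seed, i)
        cohort = simulate_cohort(params, seed=seed)
        run = run_clsm(cohort.patient_connectomes,
                       [m.subject_id for m in cohort.masks],
                       cohort.control_connectomes, cohort.cohort_table,
                       EXPERIMENT_CONTRAST, _config(n_perm, seed))
        labels = cohort.atlas.parcel_labels()
        truth_edges = {(labels[a], labels[b])
                       for a, b in cohort.truth.critical_edges}
        sig_edges = {(e.parcel_a, e.parcel_b)
                     for e in run.result.significant_edges}
        inter = len(truth_edges & sig_edges)
        denom = len(truth_edges) + len(sig_edges)
        recovered.append(truth_edges <= sig_edges)
        dices.append(2.0 * inter / denom if denom else 0.0)
    return RecoveryOutcome(recovered=recovered, dice=dices,
                           centroid_distance=[np.nan] * n_replicates)
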