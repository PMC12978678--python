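"""Behavioral score derivation and contrast assembly.

Accuracy per stimulus class (or union of classes) is the pooled proportion
sum(n_correct) / sum(n_presented); with the battery's equal pseudoword class
sizes (20 each) pooling and averaging coincide, but pooling stays
well-defined for unequal counts.

Five built-in contrasts operationalize lexical vs. sublexical reading:

``pseudowords_vs_realwords``
    pseudoword accuracy controlling for real-word accuracy (exaggerated
    lexicality effect — phonological alexia pattern);
``realwords_vs_pseudowords``
    the reverse direction (reduced lexicality effect);
``mapped_pw_vs_0m_realwords``
    1M+MM pseudowords controlling for 0M pseudowords and real words
    (application of learned orthography-to-phonology body mappings);
``mm_vs_1m_realwords``
    MM pseudowords controlling for 1M pseudowords and real words
    (selection among multiple plausible mappings);
``0m_vs_mapped_realwords``
    0M pseudowords controlling for 1M+MM pseudowords and real words
    (sublexical assembly without learned body mappings).

Each analysis additionally carries the fixed nuisance covariates lesion
volume, age, and education, which are regressed out of both the lesion/edge
data and the behavioral data before model fitting (see
:mod:`strokemap.svr_engine`). Behavioral covariates and nuisance covariates
enter the same residualization block: "controlling for" prescribes one
mechanism for both.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort_io import STIM_CLASSES, CohortTable
from .exceptions import DataError, InsufficientCohortError

logger = logging.getLogger(__name__)

ClassUnion = tuple[str, ...]

#: Fixed nuisance covariates of every lesion-symptom mapping analysis.
NUISANCE_COVARIATES = ("lesion_volume_cm3", "age", "education")


def _as_union(classes) -> ClassUnion:
    if isinstance(classes, str):
        classes = (classes,)
    union = tuple(classes)
    unknown = set(union) - set(STIM_CLASSES)
    if unknown:
        raise DataError(f"unknown stimulus classes: {sorted(unknown)}")
    if len(set(union)) != len(union):
        raise DataError("duplicate classes in union")
    return union


@dataclass(frozen=True)
class ContrastSpec:
    """One lesion-symptom mapping contrast.

    ``target_class`` is the class union whose pooled accuracy is the
    dependent variable; ``behavioral_covariates`` are class unions whose
    accuracies are controlled for. Target and covariate classes must be
    disjoint. Nuisance covariates are fixed (lesion volume, age, education).
    """

    name: str
    target_class: ClassUnion
    behavioral_covariates: tuple[ClassUnion, ...]
    nuisance: tuple[str, ...] = NUISANCE_COVARIATES

    def __post_init__(self):
        object.__setattr__(self, "target_class", _as_union(self.target_class))
        object.__setattr__(
            self,
            "behavioral_covariates",
            tuple(_as_union(c) for c in self.behavioral_covariates),
        )
        covered = set()
        for cov in self.behavioral_covariates:
            covered.update(cov)
        if covered & set(self.target_class):
            raise DataError(
                f"contrast {self.name!r}: target classes overlap behavioral covariates"
            )

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "target_class": list(self.target_class),
            "behavioral_covariates": [list(c) for c in self.behavioral_covariates],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ContrastSpec":
        return cls(
            name=d["name"],
            target_class=tuple(d["target_class"]),
            behavioral_covariates=tuple(tuple(c) for c in d["behavioral_covariates"]),
        )


PSEUDOWORD_CLASSES: ClassUnion = ("PW0M", "PW1M", "PWMM")

#: The five built-in covariate-controlled reading contrasts.
CONTRASTS: dict[str, ContrastSpec] = {
    spec.name: spec
    for spec in (
        ContrastSpec(
            name="pseudowords_vs_realwords",
            target_class=PSEUDOWORD_CLASSES,
            behavioral_covariates=(("real_word",),),
        ),
        ContrastSpec(
            name="realwords_vs_pseudowords",
            target_class=("real_word",),
            behavioral_covariates=(PSEUDOWORD_CLASSES,),
        ),
        ContrastSpec(
            name="mapped_pw_vs_0m_realwords",
            target_class=("PW1M", "PWMM"),
            behavioral_covariates=(("PW0M",), ("real_word",)),
        ),
        ContrastSpec(
            name="mm_vs_1m_realwords",
            target_class=("PWMM",),
            behavioral_covariates=(("PW1M",), ("real_word",)),
        ),
        ContrastSpec(
            name="0m_vs_mapped_realwords",
            target_class=("PW0M",),
            behavioral_covariates=(("PWMM", "PW1M"), ("real_word",)),
        ),
    )
}


@dataclass
class BehaviorTarget:
    """Dependent variable and covariates for one analysis, row-aligned."""

    subject_ids: list[str]
    y: np.ndarray                    # target accuracy, in [0, 1] (or its logit)
    behavioral_covariates: np.ndarray  # n x b
    nuisance_covariates: np.ndarray    # n x 3 (lesion volume, age, education)
    n_dropped: int = 0

    def __post_init__(self):
        n = len(self.subject_ids)
        self.y = np.asarray(self.y, dtype=float)
        self.behavioral_covariates = np.atleast_2d(
            np.asarray(self.behavioral_covariates, dtype=float)
        )
        self.nuisance_covariates = np.atleast_2d(
            np.asarray(self.nuisance_covariates, dtype=float)
        )
        if not (len(self.y) == self.behavioral_covariates.shape[0]
                == self.nuisance_covariates.shape[0] == n):
            raise DataError("BehaviorTarget rows misaligned")
        if np.isnan(self.y).any() or np.isnan(self.behavioral_covariates).any() \
                or np.isnan(self.nuisance_covariates).any():
            raise DataError("BehaviorTarget contains missing values after assembly")

    @property
    def covariates(self) -> np.ndarray:
        """Single covariate block: nuisance then behavioral columns."""
        return np.hstack([self.nuisance_covariates, self.behavioral_covariates])


def score_accuracy(cohort: CohortTable, classes) -> pd.Series:
    """Pooled accuracy over a class union, per subject.

    Returns sum(n_correct)/sum(n_presented) across the union's classes,
    indexed by subject_id. A subject with zero presented trials for any
    class of the union gets NaN (missing-score flag).
    """
    union = _as_union(classes)
    df = cohort.subjects
    presented = sum(df[f"{c}_presented"].to_numpy(dtype=float) for c in union)
    correct = sum(df[f"{c}_correct"].to_numpy(dtype=float) for c in union)
    any_empty = np.zeros(len(df), dtype=bool)
    for c in union:
        any_empty |= df[f"{c}_presented"].to_numpy(dtype=float) <= 0
    with np.errstate(invalid="ignore", divide="ignore"):
        acc = np.where(any_empty, np.nan, correct / np.where(presented > 0, presented, 1))
    return pd.Series(acc, index=df["subject_id"].to_numpy(), name="+".join(union))


def inverse_duration(seconds):
    """1 / time-on-item, the normalizing transform for skewed durations."""
    seconds = np.asarray(seconds, dtype=float)
    if (seconds <= 0).any():
        raise DataError("duration must be positive")
    out = 1.0 / seconds
    return float(out) if out.ndim == 0 else out


def logit(p):
    p = np.asarray(p, dtype=float)
    return np.log(p / (1.0 - p))


def build_contrast_target(cohort: CohortTable, spec: ContrastSpec,
                          *, logit_transform: bool = False,
                          min_subjects: int = 10) -> BehaviorTarget:
    """Assemble y plus covariate matrices for one contrast (patients only).

    Subjects with any missing score or missing nuisance value are dropped
    (count logged). Fewer than ``min_subjects`` retained raises
    :class:`InsufficientCohortError`. With ``logit_transform`` the raw
    proportions (default) are replaced by their empirical logits, with
    accuracies clipped away from 0/1 by half a trial.
    """
    patients = cohort.patients
    if "lesion_volume_cm3" not in patients.columns:
        raise DataError("cohort table lacks lesion_volume_cm3 for patients")
    patient_cohort = CohortTable(subjects=patients)

    y = score_accuracy(patient_cohort, spec.target_class)
    beh = [score_accuracy(patient_cohort, cov) for cov in spec.behavioral_covariates]
    nuis = patients.set_index("subject_id")[list(spec.nuisance)]

    tbl = pd.concat([y.rename("__y__")] + [b.rename(f"beh{i}") for i, b in enumerate(beh)]
                    + [nuis], axis=1)
    kept = tbl.dropna()
    n_dropped = len(tbl) - len(kept)
    if n_dropped:
        logger.info("contrast %s: dropped %d subjects with missing values",
                    spec.name, n_dropped)
    if len(kept) < min_subjects:
        raise InsufficientCohortError(
            f"contrast {spec.name!r}: only {len(kept)} subjects retained "
            f"(< {min_subjects})"
        )

    yv = kept["__y__"].to_numpy()
    behm = kept[[f"beh{i}" for i in range(len(beh))]].to_numpy()
    if logit_transform:
        n_target = sum(
            patients.set_index("subject_id").loc[kept.index, f"{c}_presented"]
            for c in spec.target_class
        ).to_numpy(dtype=float)
        eps = 0.5 / n_target
        yv = logit(np.clip(yv, eps, 1 - eps))

    return BehaviorTarget(
        subject_ids=list(kept.index),
        y=yv,
        behavioral_covariates=behm,
        nuisance_covariates=kept[list(spec.nuisance)].to_numpy(),
        n_dropped=n_dropped,
    )
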