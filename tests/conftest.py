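import numpy as np
import pandas as pd
import pytest

from strokemap.cohort_io import STIM_CLASSES, CohortTable, LesionMask


def make_subject_row(sid, group="patient", age=60.0, education=16.0,
                     lesion_volume=10.0, **acc):
    """One cohort-table row; ``acc`` maps class -> (n_correct, n_presented)."""
    row = {"subject_id": sid, "group": group, "age": age,
           "education": education,
           "lesion_volume_cm3": lesion_volume if group == "patient" else np.nan}
    defaults = {"real_word": (180, 200), "PW0M": (15, 20), "PW1M": (16, 20),
                "PWMM": (14, 20)}
    for cls in STIM_CLASSES:
        correct, presented = acc.get(cls, defaults[cls])
        row[f"{cls}_presented"] = presented
        row[f"{cls}_correct"] = correct
    return row


def make_cohort(rows):
    return CohortTable(subjects=pd.DataFrame(rows))


@pytest.fixture
def toy_cohort():
    """12 patients with varied scores — enough for contrast assembly."""
    rng = np.random.default_rng(7)
    rows = []
    for i in range(12):
        rows.append(make_subject_row(
            f"p{i:02d}", age=50 + i, education=12 + (i % 8),
            lesion_volume=5.0 + i,
            real_word=(int(rng.integers(150, 201)), 200),
            PW0M=(int(rng.integers(5, 21)), 20),
            PW1M=(int(rng.integers(5, 21)), 20),
            PWMM=(int(rng.integers(5, 21)), 20),
        ))
    return make_cohort(rows)


def make_mask(grid, subject_id="s", affine=None):
    if affine is None:
        affine = np.eye(4)
    return LesionMask(subject_id=subject_id, grid=np.asarray(grid, dtype=np.uint8),
                      affine=affine)


def random_masks(n, shape, density, rng, affine=None):
    return [make_mask((rng.random(shape) < density).astype(np.uint8),
                      subject_id=f"s{i:02d}", affine=affine)
            for i in range(n)]
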