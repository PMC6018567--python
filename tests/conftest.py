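"""Shared fixtures: tiny programmatic cohorts and grids."""

from __future__ import annotations

import numpy as np
import pytest

from iterlesion.cohort import Cohort, Patient, TaskScores
from iterlesion.lesion_io import LesionImage, binarize, lesion_volume

GRID = (8, 8, 8)
AFFINE = np.diag([2.0, 2.0, 2.0, 1.0])


def make_scores(spk=70.0, wri=63.0, rep=61.0, sem=59.0, csp=61.0, cop=60.0):
    return TaskScores(spk_pn=spk, writt_pn=wri, rep_n=rep, sem_m=sem,
                      cspk_w=csp, writt_copy=cop)


def make_patient(pid: str, values: np.ndarray, scores: TaskScores | None = None,
                 kind: str = "fuzzy", affine: np.ndarray = AFFINE) -> Patient:
    img = LesionImage(patient_id=pid, values=np.asarray(values, dtype=np.float32),
                      affine=affine, kind=kind)
    binary = img if kind == "binary" else binarize(img)
    return Patient(patient_id=pid, lesion=img,
                   scores=scores or make_scores(),
                   lesion_volume_cm3=lesion_volume(binary))


def make_cohort(n: int, rng: np.random.Generator,
                grid=GRID, score_spread: float = 8.0) -> Cohort:
    """Random fuzzy blobs with random scores — no built-in lesion-deficit link."""
    patients = []
    for i in range(n):
        vals = np.clip(rng.random(grid) * rng.random(), 0, 1)
        sc = make_scores(
            spk=70 + rng.normal(0, score_spread),
            wri=63 + rng.normal(0, score_spread),
            rep=61 + rng.normal(0, score_spread),
            sem=59 + rng.normal(0, score_spread),
            csp=61 + rng.normal(0, score_spread),
            cop=60 + rng.normal(0, score_spread))
        patients.append(make_patient(f"p{i:03d}", vals, sc))
    return Cohort(patients)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_cohort(rng):
    return make_cohort(12, rng)
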