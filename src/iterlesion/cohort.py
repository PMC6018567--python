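"""Behavioural scores, impairment classification and cohort assembly.

Six language tasks from the Comprehensive Aphasia Test (CAT) are carried as
norm-referenced T-scores.  Each task has a published cut-off: a T-score at
or below the cut-off counts as impaired.  The *deficit of interest* —
word-finding difficulty — is the conjunction of impaired spoken AND written
picture naming; the regressor of interest for lesion mapping is the
*composite* naming score, the mean of the two naming T-scores.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .lesion_io import LesionImage, binarize, lesion_volume, read_lesion_image

__all__ = [
    "TASK_NAMES",
    "TaskScores",
    "ImpairmentCutoffs",
    "DEFAULT_CUTOFFS",
    "Patient",
    "Cohort",
    "composite_score",
    "impairment_flags",
    "deficit_of_interest",
    "assemble_cohort",
]

logger = logging.getLogger(__name__)

#: canonical column order for the six CAT tasks
TASK_NAMES = ("spk_pn", "writt_pn", "rep_n", "sem_m", "cspk_w", "writt_copy")


@dataclass(frozen=True)
class TaskScores:
    """T-scores for the six CAT tasks of one patient."""

    spk_pn: float      # spoken picture naming
    writt_pn: float    # written picture naming
    rep_n: float       # nonword repetition
    sem_m: float       # semantic associations
    cspk_w: float      # spoken word comprehension
    writt_copy: float  # writing copy

    def __post_init__(self) -> None:
        for name in TASK_NAMES:
            v = getattr(self, name)
            if v is None or not np.isfinite(v):
                raise ValueError(f"missing or non-finite T-score for {name}")
            if not (0.0 <= v <= 100.0):
                warnings.warn(
                    f"T-score {name}={v} outside the plausible [0, 100] range",
                    stacklevel=2,
                )

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in TASK_NAMES], dtype=float)


@dataclass(frozen=True)
class ImpairmentCutoffs:
    """Per-task highest T-score still counted as impaired (inclusive)."""

    spk_pn: float = 61.0
    writt_pn: float = 54.0
    rep_n: float = 52.0
    sem_m: float = 50.0
    cspk_w: float = 52.0
    writt_copy: float = 51.0

    def __post_init__(self) -> None:
        for name in TASK_NAMES:
            v = getattr(self, name)
            if not (0.0 < v < 100.0):
                raise ValueError(f"cut-off for {name} must lie in (0, 100)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ImpairmentCutoffs":
        """Load cut-offs from a YAML mapping so other CAT normings can be used."""
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**{k: float(raw[k]) for k in TASK_NAMES})


DEFAULT_CUTOFFS = ImpairmentCutoffs()


@dataclass
class Patient:
    patient_id: str
    lesion: LesionImage
    scores: TaskScores
    lesion_volume_cm3: float


@dataclass
class Cohort:
    """An ordered collection of patients on one shared grid."""

    patients: list[Patient]

    def __post_init__(self) -> None:
        ids = [p.patient_id for p in self.patients]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate patient ids: {dupes}")
        if self.patients:
            ref = self.patients[0].lesion
            for p in self.patients[1:]:
                if p.lesion.shape != ref.shape or not np.allclose(
                        p.lesion.affine, ref.affine):
                    raise ValueError(
                        f"grid/affine mismatch for patient {p.patient_id!r}; "
                        "cohorts are never resampled"
                    )

    def __len__(self) -> int:
        return len(self.patients)

    @property
    def patient_ids(self) -> list[str]:
        return [p.patient_id for p in self.patients]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.patients[0].lesion.shape

    @property
    def affine(self) -> np.ndarray:
        return self.patients[0].lesion.affine

    def scores_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [p.scores.as_array() for p in self.patients],
            index=self.patient_ids, columns=list(TASK_NAMES),
        )

    def lesion_volumes(self) -> np.ndarray:
        return np.array([p.lesion_volume_cm3 for p in self.patients])

    def stacked_values(self) -> np.ndarray:
        """All lesion images as one (n_patients, nx, ny, nz) array."""
        return np.stack([p.lesion.values for p in self.patients])

    def subset(self, keep_ids: Iterable[str]) -> "Cohort":
        keep = set(keep_ids)
        return Cohort([p for p in self.patients if p.patient_id in keep])


def composite_score(spk_pn: float, writt_pn: float) -> float:
    """Composite naming score: mean of spoken and written picture naming."""
    if spk_pn is None or writt_pn is None or not (
            np.isfinite(spk_pn) and np.isfinite(writt_pn)):
        raise ValueError("composite score requires both naming T-scores; "
                         "no imputation is performed")
    return (float(spk_pn) + float(writt_pn)) / 2.0


def impairment_flags(scores: TaskScores,
                     cutoffs: ImpairmentCutoffs = DEFAULT_CUTOFFS) -> dict[str, bool]:
    """Per-task impairment: T-score at or below the task cut-off (inclusive)."""
    return {name: bool(getattr(scores, name) <= getattr(cutoffs, name))
            for name in TASK_NAMES}


def deficit_of_interest(flags: dict[str, bool]) -> bool:
    """Word-finding difficulty: impaired on BOTH naming tasks."""
    return bool(flags["spk_pn"] and flags["writt_pn"])


def _read_manifest(path: str | Path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, dtype={"patient_id": str})
    missing = {"patient_id", "path"} - set(df.columns)
    if missing:
        raise ValueError(f"manifest lacks columns: {sorted(missing)}")
    return df


def _read_scores(path: str | Path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, dtype={"patient_id": str})
    missing = ({"patient_id"} | set(TASK_NAMES)) - set(df.columns)
    if missing:
        raise ValueError(f"scores table lacks columns: {sorted(missing)}")
    return df.set_index("patient_id")


def assemble_cohort(manifest: str | Path, scores_table: str | Path,
                    kind: str = "fuzzy",
                    binarize_u: float = 0.3,
                    cutoffs: ImpairmentCutoffs = DEFAULT_CUTOFFS) -> Cohort:
    """Build a validated Cohort from an image manifest and a scores table.

    Parameters
    ----------
    manifest : path
        CSV/TSV with columns ``patient_id, path`` listing one NIfTI per patient.
    scores_table : path
        CSV/TSV with ``patient_id`` plus the six task columns.
    kind : {'fuzzy', 'binary'}
        How to interpret the image values.
    binarize_u : float
        Threshold used to compute lesion volumes from fuzzy images.

    Lesion volumes are recomputed from the binarized images.  A Table-1 style
    summary (n, per-task impaired counts) is logged.
    """
    man = _read_manifest(manifest)
    sc = _read_scores(scores_table)
    missing = [pid for pid in man["patient_id"] if pid not in sc.index]
    if missing:
        raise ValueError(f"patients without a scores row: {missing}")

    patients = []
    for _, row in man.iterrows():
        pid = row["patient_id"]
        img = read_lesion_image(row["path"], kind=kind, patient_id=pid)
        s = sc.loc[pid]
        scores = TaskScores(**{k: float(s[k]) for k in TASK_NAMES})
        binary = img if kind == "binary" else binarize(img, binarize_u)
        patients.append(Patient(patient_id=pid, lesion=img, scores=scores,
                                lesion_volume_cm3=lesion_volume(binary)))
    cohort = Cohort(patients)

    counts = cohort_impairment_summary(cohort, cutoffs)
    logger.info("assembled cohort: n=%d; impaired per task: %s",
                len(cohort), counts)
    return cohort


def cohort_impairment_summary(cohort: Cohort,
                              cutoffs: ImpairmentCutoffs = DEFAULT_CUTOFFS
                              ) -> dict[str, int]:
    """Per-task impaired counts plus the deficit-of-interest count."""
    out = {name: 0 for name in TASK_NAMES}
    out["deficit_of_interest"] = 0
    for p in cohort.patients:
        flags = impairment_flags(p.scores, cutoffs)
        for name in TASK_NAMES:
            out[name] += int(flags[name])
        out["deficit_of_interest"] += int(deficit_of_interest(flags))
    return out


def cohort_composites(cohort: Cohort) -> np.ndarray:
    """Composite naming score for every patient, in cohort order."""
    return np.array([composite_score(p.scores.spk_pn, p.scores.writt_pn)
                     for p in cohort.patients])


def cohort_deficits(cohort: Cohort,
                    cutoffs: ImpairmentCutoffs = DEFAULT_CUTOFFS) -> np.ndarray:
    """Boolean deficit-of-interest vector, in cohort order."""
    return np.array([deficit_of_interest(impairment_flags(p.scores, cutoffs))
                     for p in cohort.patients])
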