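"""Synthetic stroke-lesion cohorts with OR-structured deficit causation.

The generator builds the statistical situation that defeats pooled
mass-univariate lesion-deficit mapping: several spatially distinct critical
regions whose damage each *independently* produces the same deficit, with
vascular-territory-like lesion co-occurrence.  Three critical boxes live on
a 32x32x32 grid (2 mm isotropic): a posterior "temporal" box T, an anterior
"frontal" box F, and a small central "deep" box P.  Lesions are fuzzy
ellipsoids (sigmoid fall-off over the signed distance to the ellipsoid
surface) drawn from a four-component territory mixture:

* posterior (weight 0.30) — centred near T;
* anterior  (weight 0.30) — centred near F;
* deep      (weight 0.15) — small lesions centred on P that only rarely
  reach T or F;
* large     (weight 0.25) — big lesions covering all three boxes, the
  analogue of whole-territory infarcts in which deep damage co-occurs with
  cortical damage.

A patient carries the latent deficit D when any critical region is damaged
above the fraction threshold theta; naming scores then drop by the deficit
effect.  Because most deficit carriers owe D to T or F damage, the marginal
association at P is diluted in the pooled analysis, while after excluding
patients with >25% damage to T or F the surviving deficit carriers are
mostly deep-territory cases and P becomes detectable — the
false-negative-then-recovery signature the iterative procedure exists to
demonstrate.

Null cohorts keep the identical lesion model but draw all behavioural
scores independently of the lesions, for false-positive-rate checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .cohort import Cohort, Patient, TaskScores, TASK_NAMES, DEFAULT_CUTOFFS
from .lesion_io import LesionImage, ROISet, binarize, lesion_volume

__all__ = [
    "RegionSpec",
    "TerritorySpec",
    "SyntheticConfig",
    "GroundTruth",
    "make_region_layout",
    "sample_lesion_image",
    "sample_behavior",
    "generate_cohort",
    "generate_null_cohort",
    "write_cohort",
]


@dataclass(frozen=True)
class RegionSpec:
    """Axis-aligned box of a true critical region, voxel index units."""

    name: str
    lo: tuple[int, int, int]     # inclusive
    hi: tuple[int, int, int]     # exclusive

    @property
    def n_voxels(self) -> int:
        return int(np.prod([h - l for l, h in zip(self.lo, self.hi)]))


@dataclass(frozen=True)
class TerritorySpec:
    """One vascular-territory mixture component.

    Lesion centres are the anchor plus isotropic Gaussian jitter; ellipsoid
    radii are log-normal, either isotropic (scalar ``radius_log_mu``) or
    with a per-axis median (3-tuple), which yields elongated lesions such
    as the anterior-posterior cortical strip of a middle-cerebral-artery
    infarct.
    """

    name: str
    weight: float
    anchor: tuple[float, float, float]   # voxel coordinates
    center_jitter_sd: float              # voxels
    radius_log_mu: float | tuple[float, float, float]  # log(voxels)
    radius_log_sd: float

    def radius_mus(self) -> np.ndarray:
        mu = self.radius_log_mu
        if np.isscalar(mu):
            return np.full(3, float(mu))
        return np.asarray(mu, dtype=float)


def _default_regions() -> tuple[RegionSpec, ...]:
    return (
        RegionSpec("T", (8, 4, 12), (16, 12, 20)),     # posterior box, 512 vox
        RegionSpec("F", (8, 20, 12), (16, 28, 20)),    # anterior box, 512 vox
        RegionSpec("P", (17, 14, 11), (21, 18, 15)),   # deep box, 64 vox
    )


def _default_territories() -> tuple[TerritorySpec, ...]:
    # Cortical lesions are elongated along the anterior-posterior axis, so
    # posterior and anterior infarcts partially invade the other cortical
    # box — the co-occurrence that lets both cortical regions surface in
    # the pooled analysis.  The deep box sits off the cortical axis; deep
    # lesions are small, centred on it, and only rarely reach T or F.
    cortical_radii = (float(np.log(4.3)), float(np.log(11.0)),
                      float(np.log(4.3)))
    return (
        TerritorySpec("posterior", 0.30, (11.5, 10.0, 16.0), 1.0,
                      cortical_radii, 0.25),
        TerritorySpec("anterior", 0.30, (11.5, 21.0, 16.0), 1.0,
                      cortical_radii, 0.25),
        TerritorySpec("deep", 0.15, (19.0, 15.5, 12.5), 1.4,
                      float(np.log(3.0)), 0.20),
        TerritorySpec("large", 0.25, (13.5, 15.5, 15.0), 1.0,
                      float(np.log(13.0)), 0.08),
    )


@dataclass
class SyntheticConfig:
    """The stated world of the simulator.

    The behavioural model anchors every task at its impairment cut-off plus
    a healthy margin, so that carriers of the latent deficit fall below the
    naming cut-offs with high probability while non-carriers rarely do:

        score_task = cutoff_task + healthy_margin
                     - deficit_effect * D          (naming tasks only)
                     - coupling * damage fraction  (nuisance tasks only)
                     - volume_slope * lesioned voxel count
                     + Gaussian noise (sd = noise_sd)

    With margin 9 and effect 12 the spoken-naming baseline is 61 + 9 = 70
    and a deficit carrier sits 3 points below the cut-off.
    """

    grid_shape: tuple[int, int, int] = (32, 32, 32)
    voxel_size_mm: float = 2.0
    regions: tuple[RegionSpec, ...] = field(default_factory=_default_regions)
    territories: tuple[TerritorySpec, ...] = field(
        default_factory=_default_territories)
    border_width_vox: float = 1.0     # sigmoid width of the fuzzy border
    deficit_theta: float = 0.5        # damage fraction that triggers D
    healthy_margin: float = 9.0       # T-points above the cut-off when intact
    deficit_effect: float = 12.0      # naming drop for deficit carriers
    volume_slope_per_voxel: float = 0.0005  # mild global severity with size
    noise_sd: float = 3.0
    #: nuisance-task couplings: task -> (region name, T-points per unit fraction)
    nuisance_coupling: dict = field(default_factory=lambda: {
        "rep_n": ("F", 3.0), "cspk_w": ("T", 3.0),
        "sem_m": ("T", 2.0), "writt_copy": ("F", 2.0)})
    n_patients: int = 300
    seed: int | None = None

    def __post_init__(self) -> None:
        w = sum(t.weight for t in self.territories)
        if abs(w - 1.0) > 1e-9:
            raise ValueError(f"territory weights must sum to 1, got {w}")
        if not (0.0 < self.deficit_theta < 1.0):
            raise ValueError("deficit_theta must lie in (0, 1)")
        for r in self.regions:
            for lo, hi, n in zip(r.lo, r.hi, self.grid_shape):
                if not (0 <= lo < hi <= n):
                    raise ValueError(
                        f"region {r.name!r} does not fit inside the grid")
        # pairwise disjointness of the critical boxes
        for i, a in enumerate(self.regions):
            for b in self.regions[i + 1:]:
                if all(a.lo[d] < b.hi[d] and b.lo[d] < a.hi[d]
                       for d in range(3)):
                    raise ValueError(
                        f"regions {a.name!r} and {b.name!r} overlap")

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[0, 0] = aff[1, 1] = aff[2, 2] = self.voxel_size_mm
        return aff


@dataclass
class GroundTruth:
    """What the generator knows: true regions and per-patient latent state."""

    rois: ROISet
    region_names: dict[str, int]              # region name -> label
    territory: list[str]                      # per patient
    damage_fractions: np.ndarray              # (n, n_regions), region order
    latent_deficit: np.ndarray                # (n,), bool

    def region_mask(self, name: str) -> np.ndarray:
        return self.rois.mask_of(self.region_names[name])


def make_region_layout(config: SyntheticConfig) -> ROISet:
    """Deterministic labelled grid of the true critical regions."""
    labels = np.zeros(config.grid_shape, dtype=np.int32)
    names = {}
    for k, r in enumerate(config.regions, start=1):
        sl = tuple(slice(lo, hi) for lo, hi in zip(r.lo, r.hi))
        labels[sl] = k
        names[k] = r.name
    return ROISet(labels=labels, names=names)


def _coord_grids(shape: tuple[int, int, int]) -> np.ndarray:
    return np.stack(np.meshgrid(*(np.arange(n, dtype=float) for n in shape),
                                indexing="ij"))


def sample_lesion_image(rng: np.random.Generator, config: SyntheticConfig,
                        patient_id: str = "synthetic",
                        coords: np.ndarray | None = None
                        ) -> tuple[LesionImage, str]:
    """Draw one fuzzy ellipsoidal lesion from the territory mixture.

    The fuzzy value is a sigmoid of the (approximate) signed distance to the
    ellipsoid surface: 1 deep inside, 0.5 on the surface, decaying to 0
    outside over ``border_width_vox``.
    """
    weights = np.array([t.weight for t in config.territories])
    t_idx = int(rng.choice(len(config.territories), p=weights))
    terr = config.territories[t_idx]
    center = np.array(terr.anchor) + rng.normal(
        0.0, terr.center_jitter_sd, size=3)
    radii = np.exp(rng.normal(terr.radius_mus(), terr.radius_log_sd, size=3))
    if coords is None:
        coords = _coord_grids(config.grid_shape)
    # scaled radial coordinate rho: 1 on the ellipsoid surface
    rho = np.sqrt(sum(((coords[d] - center[d]) / radii[d]) ** 2
                      for d in range(3)))
    r_eff = float(np.exp(np.mean(np.log(radii))))
    signed_dist = (rho - 1.0) * r_eff          # approx. voxels outside surface
    values = 1.0 / (1.0 + np.exp(signed_dist / config.border_width_vox))
    img = LesionImage(patient_id=patient_id,
                      values=np.clip(values, 0.0, 1.0).astype(np.float32),
                      affine=config.affine, kind="fuzzy")
    return img, terr.name


def sample_behavior(damage_fractions: np.ndarray, n_lesioned_voxels: float,
                    rng: np.random.Generator, config: SyntheticConfig,
                    null: bool = False) -> tuple[TaskScores, bool]:
    """Draw the six task T-scores given the true damage fractions.

    Returns (scores, latent deficit D).  With ``null=True`` all scores are
    baseline plus noise, independent of the lesion, and D is forced to 0.
    """
    fr = np.asarray(damage_fractions, dtype=float)
    if np.any(fr < 0) or np.any(fr > 1):
        raise ValueError("damage fractions must lie in [0, 1]")
    region_index = {r.name: i for i, r in enumerate(config.regions)}
    deficit = bool(np.any(fr > config.deficit_theta)) and not null
    vol_term = 0.0 if null else (config.volume_slope_per_voxel
                                 * float(n_lesioned_voxels))
    values = {}
    for task in TASK_NAMES:
        mu = getattr(DEFAULT_CUTOFFS, task) + config.healthy_margin
        if not null:
            mu -= vol_term
            if task in ("spk_pn", "writt_pn"):
                mu -= config.deficit_effect * deficit
            else:
                region, slope = config.nuisance_coupling[task]
                mu -= slope * fr[region_index[region]]
        values[task] = mu + rng.normal(0.0, config.noise_sd)
    return TaskScores(**values), deficit


def _fractions(values: np.ndarray, region_masks: list[np.ndarray]
               ) -> np.ndarray:
    return np.array([float(values[m].mean()) for m in region_masks])


def generate_cohort(config: SyntheticConfig,
                    null: bool = False) -> tuple[Cohort, GroundTruth]:
    """Sample a full cohort plus its ground truth, reproducibly from the seed.

    Damage fractions driving the latent deficit are mean fuzzy abnormality
    over each true region; lesion volumes come from the binarized images.
    """
    rng = np.random.default_rng(config.seed)
    layout = make_region_layout(config)
    region_names = {r.name: k + 1 for k, r in enumerate(config.regions)}
    masks = [layout.mask_of(region_names[r.name]) for r in config.regions]
    coords = _coord_grids(config.grid_shape)

    patients, territories, fracs, deficits = [], [], [], []
    for i in range(config.n_patients):
        pid = f"sub-{i + 1:04d}"
        img, terr = sample_lesion_image(rng, config, patient_id=pid,
                                        coords=coords)
        fr = _fractions(img.values, masks)
        binary = binarize(img)
        scores, d = sample_behavior(fr, float(binary.values.sum()), rng,
                                    config, null=null)
        patients.append(Patient(patient_id=pid, lesion=img, scores=scores,
                                lesion_volume_cm3=lesion_volume(binary)))
        territories.append(terr)
        fracs.append(fr)
        deficits.append(d)

    truth = GroundTruth(rois=layout, region_names=region_names,
                        territory=territories,
                        damage_fractions=np.array(fracs),
                        latent_deficit=np.array(deficits, dtype=bool))
    return Cohort(patients), truth


def generate_null_cohort(config: SyntheticConfig) -> Cohort:
    """Same lesion model, but behaviour independent of the lesions."""
    cohort, _ = generate_cohort(config, null=True)
    return cohort


def write_cohort(cohort: Cohort, truth: GroundTruth | None,
                 out_dir: str | Path) -> dict[str, Path]:
    """Write NIfTI lesions, a scores CSV, a manifest, and ground truth JSON.

    The manifest and scores table round-trip through
    :func:`iterlesion.cohort.assemble_cohort`.
    """
    import json

    import pandas as pd

    from .lesion_io import write_image

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lesion_dir = out / "lesions"
    lesion_dir.mkdir(exist_ok=True)
    man_rows, score_rows = [], []
    for p in cohort.patients:
        path = lesion_dir / f"{p.patient_id}.nii.gz"
        write_image(p.lesion.values, p.lesion.affine, path)
        man_rows.append({"patient_id": p.patient_id, "path": str(path)})
        row = {"patient_id": p.patient_id}
        row.update({k: getattr(p.scores, k) for k in TASK_NAMES})
        score_rows.append(row)
    manifest = out / "manifest.csv"
    scores = out / "scores.csv"
    pd.DataFrame(man_rows).to_csv(manifest, index=False)
    pd.DataFrame(score_rows).to_csv(scores, index=False)
    paths = {"manifest": manifest, "scores": scores}
    if truth is not None:
        write_image(truth.rois.labels, cohort.affine,
                    out / "true_regions.nii.gz")
        gt = {
            "region_names": truth.region_names,
            "territory": truth.territory,
            "damage_fractions": truth.damage_fractions.tolist(),
            "latent_deficit": truth.latent_deficit.astype(int).tolist(),
        }
        gt_path = out / "ground_truth.json"
        with open(gt_path, "w") as fh:
            json.dump(gt, fh)
        paths["ground_truth"] = gt_path
    return paths
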