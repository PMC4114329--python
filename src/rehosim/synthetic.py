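"""Synthetic multi-study resting-state cohorts with sex-linked local synchrony.

The generator emulates the statistical structure the downstream pipeline
assumes, so every stage is testable without downloading imaging data:

* a demographics table with per-study sex/age composition (a packaged fixture
  reproduces the published 27-study composition of the source collections);
* per-subject 4D time-series volumes in which voxels inside a study-specific
  *effect region* share a common latent AR(1) signal whose mixing weight is
  higher for one sex — higher shared-signal weight means higher local
  temporal synchrony, hence higher expected regional homogeneity;
* per-subject binary masks covering a study-specific fraction of a canonical
  ellipsoidal brain mask;
* motion-like nuisance regressors (standardized random walks).

Site ("study") heterogeneity is parameterized by per-study temporal noise
scale, spatial coverage, and placement/size of the effect region — enough to
reproduce the qualitative multi-site phenomena: within-study accuracy above
cross-study accuracy, asymmetric study pairs, and pooled convergence.

A fast path (:func:`make_reho_maps`) emits ReHo-like Gaussian maps directly,
bypassing the time-series simulation, for cheap simulation-harness runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .masking import SubjectMask
from .preprocess import Volume4D, design_matrix
from .reho import ReHoMap
from .seeding import derive_rng

__all__ = [
    "StudySpec",
    "CohortSpec",
    "SubjectRecord",
    "GeneratedSubject",
    "make_cohort",
    "make_reho_maps",
    "table1_fixture",
    "canonical_mask",
    "null_cohort_spec",
    "two_site_spec",
    "subset_geometry_spec",
    "MAX_BALANCED_OVERRIDES",
    "STUDY_ALIASES",
]

# The published maximum balanced sample sizes include one value (Cambridge)
# that the 2*min(F, M) rule does not reproduce; the printed value is recorded
# here and honored by the sample-size planner.
MAX_BALANCED_OVERRIDES = {"Cambridge_Buckner": 140}

# Convenience aliases matching the shorthand study names used in running text.
STUDY_ALIASES = {"Beijing": "Beijing_Zang", "Cambridge": "Cambridge_Buckner"}

# latent AR(1) autocorrelation of the shared synchrony signal
_AR_PHI = 0.85
# shared-signal mixing weight of the lower-synchrony sex (female), in units
# of the study noise scale; the male weight is this plus effect_strength
_SYNC_BASE = 0.4
# per-voxel loading scale for the nuisance regressors
_NUISANCE_LOAD = 0.5
_N_NUISANCE = 6
# autocorrelation of the motion-like nuisance regressors; kept mild so the
# regressors do not collapse onto the narrow passband at desk-scale run length
_NUISANCE_PHI = 0.3
# per-voxel polynomial drift coefficient scale, in units of the noise scale
_DRIFT_SCALE = 1.0

# fast-path map model: values = baseline + region elevation + sex effect + noise
_FAST_BASE = 0.25
# map-space noise sd per unit of study noise scale (noise_sd=1 -> map sd 0.05)
_FAST_NOISE_SCALE = 0.05
# concordance elevation inside the effect region, depressed by temporal noise
# (mirrors how noise lowers Kendall's W): elevation = 0.2 / (1 + noise_sd^2)
_FAST_ELEV_NUM = 0.2


@dataclass
class SubjectRecord:
    subject_id: str
    study: str
    sex: str  # "female" | "male"
    age: float


@dataclass
class StudySpec:
    """One synthetic study (site): composition plus site-effect parameters."""

    name: str
    n_female: int
    n_male: int
    age_mean: float = 25.0
    age_sd: float = 5.0
    noise_sd: float = 1.0
    effect_center: tuple[int, int, int] | None = None  # None -> grid center
    effect_radius: int = 3
    effect_strength: float = 0.0
    coverage_fraction: float = 1.0
    drift_order: int = 2
    # population heterogeneity: per-subject offset of local synchrony shared
    # across the effect region (both sexes); 0 = homogeneous study population
    region_jitter_sd: float = 0.0
    # fast-path baseline concordance elevation inside the effect region;
    # None derives it from the noise scale (noise depresses concordance)
    region_baseline: float | None = None

    def validate(self) -> None:
        if self.n_female < 0 or self.n_male < 0:
            raise ValueError(f"study {self.name}: negative subject count")
        if not (0.0 < self.coverage_fraction <= 1.0):
            raise ValueError(f"study {self.name}: coverage_fraction must be in (0, 1]")
        if self.effect_strength < 0:
            raise ValueError(f"study {self.name}: effect_strength must be >= 0")
        if self.region_jitter_sd < 0:
            raise ValueError(f"study {self.name}: region_jitter_sd must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError(f"study {self.name}: noise_sd must be positive")
        if self.drift_order < 0:
            raise ValueError(f"study {self.name}: drift_order must be >= 0")

    @property
    def n_subjects(self) -> int:
        return self.n_female + self.n_male


@dataclass
class CohortSpec:
    """A multi-study cohort on a common grid."""

    studies: list[StudySpec]
    grid_shape: tuple[int, int, int] = (16, 16, 16)
    n_timepoints: int = 60
    sampling_interval: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if any(s < 3 for s in self.grid_shape):
            raise ValueError("grid_shape must be >= 3 on every axis (3x3x3 cubes must fit)")
        if self.n_timepoints < 8:
            raise ValueError("need n_timepoints >= 8")
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be positive")
        if sum(st.n_subjects for st in self.studies) == 0:
            raise ValueError("every study has zero subjects")
        for st in self.studies:
            st.validate()
            _effect_sphere(self.grid_shape, st)  # bounds check, names the study


@dataclass
class GeneratedSubject:
    record: SubjectRecord
    volume: Volume4D
    mask: SubjectMask
    nuisance: np.ndarray


def canonical_mask(grid_shape: tuple[int, int, int]) -> np.ndarray:
    """Canonical ellipsoidal brain mask inscribed in the grid (binary, uint8)."""
    axes = [np.arange(s) for s in grid_shape]
    center = [(s - 1) / 2.0 for s in grid_shape]
    semi = [max(1.0, 0.45 * s) for s in grid_shape]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    r2 = sum(((g - c) / a) ** 2 for g, c, a in zip((gx, gy, gz), center, semi))
    return (r2 <= 1.0).astype(np.uint8)


def _ellipsoid_r2(grid_shape: tuple[int, int, int]) -> np.ndarray:
    axes = [np.arange(s) for s in grid_shape]
    center = [(s - 1) / 2.0 for s in grid_shape]
    semi = [max(1.0, 0.45 * s) for s in grid_shape]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    return sum(((g - c) / a) ** 2 for g, c, a in zip((gx, gy, gz), center, semi))


def _effect_sphere(grid_shape: tuple[int, int, int], study: StudySpec) -> np.ndarray:
    """Boolean effect-region sphere; errors if it pokes outside the grid."""
    center = study.effect_center
    if center is None:
        center = tuple((s - 1) // 2 for s in grid_shape)
    center = tuple(int(c) for c in center)
    for c, s in zip(center, grid_shape):
        if c - study.effect_radius < 0 or c + study.effect_radius >= s:
            raise ValueError(
                f"study {study.name}: effect region (center {center}, radius "
                f"{study.effect_radius}) extends outside grid {grid_shape}"
            )
    axes = [np.arange(s) for s in grid_shape]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    r2 = sum((g - c) ** 2 for g, c in zip((gx, gy, gz), center))
    return r2 <= study.effect_radius**2


def _subject_mask(
    rng: np.random.Generator, grid_shape: tuple[int, int, int], coverage_fraction: float
) -> SubjectMask:
    """Subset of the canonical mask covering ~coverage_fraction of its voxels.

    Voxels are ranked by (jittered) distance from the mask center and the
    innermost fraction kept, emulating per-subject loss of peripheral
    coverage; each subject mask is a strict subset of the canonical mask.
    """
    canon = canonical_mask(grid_shape).astype(bool)
    if coverage_fraction >= 1.0:
        return SubjectMask(data=canon.astype(np.uint8))
    r2 = _ellipsoid_r2(grid_shape)[canon]
    n_keep = int(round(coverage_fraction * r2.size))
    score = r2 + rng.normal(0.0, 0.08, size=r2.size)
    keep_flat = np.zeros(r2.size, dtype=bool)
    keep_flat[np.argsort(score, kind="stable")[:n_keep]] = True
    out = np.zeros(grid_shape, dtype=np.uint8)
    out[canon] = keep_flat
    return SubjectMask(data=out)


def _study_records(rng: np.random.Generator, study: StudySpec) -> list[SubjectRecord]:
    records = []
    sexes = ["female"] * study.n_female + ["male"] * study.n_male
    ages = np.clip(rng.normal(study.age_mean, study.age_sd, size=len(sexes)), 5.0, 95.0)
    for i, (sex, age) in enumerate(zip(sexes, ages)):
        records.append(
            SubjectRecord(
                subject_id=f"{study.name}_{i:04d}",
                study=study.name,
                sex=sex,
                age=round(float(age), 1),
            )
        )
    return records


def _ar1(rng: np.random.Generator, n: int, phi: float = _AR_PHI) -> np.ndarray:
    """Unit-variance AR(1) series."""
    x = np.empty(n)
    x[0] = rng.normal()
    innov = rng.normal(size=n - 1) * np.sqrt(1.0 - phi**2)
    for t in range(1, n):
        x[t] = phi * x[t - 1] + innov[t - 1]
    return x


def demographics_frame(records: list[SubjectRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"subject_id": r.subject_id, "study": r.study, "sex": r.sex, "age": r.age}
            for r in records
        ]
    )


def make_cohort(spec: CohortSpec) -> tuple[list[GeneratedSubject], pd.DataFrame]:
    """Generate raw 4D volumes, masks and nuisance regressors for every subject.

    Per subject, each voxel time series is a polynomial drift (coefficients
    drawn per subject and voxel) plus a linear combination of motion-like
    nuisance regressors (per-voxel loadings) plus Gaussian noise; inside
    the study's effect region all voxels additionally receive a shared latent
    AR(1) signal with mixing weight ``_SYNC_BASE`` (females) or ``_SYNC_BASE +
    effect_strength`` (males), both scaled by the study noise level so
    effect_strength is a dimensionless synchrony difference.  Deterministic
    given ``spec.seed``: per-subject streams are hash-derived from
    (seed, study, subject index).
    """
    spec.validate()
    nx, ny, nz = spec.grid_shape
    nvox = nx * ny * nz
    nt = spec.n_timepoints
    subjects: list[GeneratedSubject] = []
    all_records: list[SubjectRecord] = []

    for study in spec.studies:
        region = _effect_sphere(spec.grid_shape, study).reshape(-1)
        rec_rng = derive_rng(spec.seed, study.name, "records")
        records = _study_records(rec_rng, study)
        all_records.extend(records)
        poly = design_matrix(nt, study.drift_order)

        for i, record in enumerate(records):
            rng = derive_rng(spec.seed, study.name, i)
            nuisance = np.column_stack(
                [_ar1(rng, nt, _NUISANCE_PHI) for _ in range(_N_NUISANCE)]
            )
            nuisance -= nuisance.mean(axis=0)
            nuisance /= nuisance.std(axis=0, ddof=0)

            drift_coef = rng.normal(
                0.0, _DRIFT_SCALE * study.noise_sd, size=(nvox, poly.shape[1])
            )
            loadings = rng.normal(
                0.0, _NUISANCE_LOAD * study.noise_sd, size=(nvox, _N_NUISANCE)
            )
            latent = _ar1(rng, nt)
            noise = rng.normal(0.0, study.noise_sd, size=(nvox, nt))

            ts = noise
            ts += drift_coef @ poly.T
            ts += loadings @ nuisance.T
            w = _SYNC_BASE + (study.effect_strength if record.sex == "male" else 0.0)
            if study.region_jitter_sd > 0:
                w = max(0.0, w + rng.normal(0.0, study.region_jitter_sd))
            ts[region] += (w * study.noise_sd) * latent[None, :]

            volume = Volume4D(ts.reshape(nx, ny, nz, nt), spec.sampling_interval)
            mask = _subject_mask(rng, spec.grid_shape, study.coverage_fraction)
            subjects.append(
                GeneratedSubject(record=record, volume=volume, mask=mask, nuisance=nuisance)
            )

    return subjects, demographics_frame(all_records)


def make_reho_maps(spec: CohortSpec) -> list[tuple[SubjectRecord, ReHoMap, SubjectMask]]:
    """Fast path: emit ReHo-like maps directly, bypassing time-series simulation.

    Maps are Gaussian fields in [0, 1]: baseline ``_FAST_BASE`` everywhere;
    inside the effect region an elevation ``0.2 / (1 + noise_sd^2)`` (temporal
    noise depresses concordance) plus ``effect_strength`` for males; additive
    map noise with sd ``0.05 * noise_sd``.  Same determinism contract as
    :func:`make_cohort`.
    """
    spec.validate()
    out: list[tuple[SubjectRecord, ReHoMap, SubjectMask]] = []

    for study in spec.studies:
        region = _effect_sphere(spec.grid_shape, study)
        if study.region_baseline is not None:
            elevation = study.region_baseline
        else:
            elevation = _FAST_ELEV_NUM / (1.0 + study.noise_sd**2)
        map_sd = _FAST_NOISE_SCALE * study.noise_sd
        rec_rng = derive_rng(spec.seed, study.name, "records")
        records = _study_records(rec_rng, study)

        for i, record in enumerate(records):
            rng = derive_rng(spec.seed, study.name, i, "fast")
            mean = np.full(spec.grid_shape, _FAST_BASE)
            mean[region] += elevation
            if study.region_jitter_sd > 0:
                mean[region] += rng.normal(0.0, study.region_jitter_sd)
            if record.sex == "male":
                mean[region] += study.effect_strength
            data = np.clip(mean + rng.normal(0.0, map_sd, size=spec.grid_shape), 0.0, 1.0)
            mask = _subject_mask(rng, spec.grid_shape, study.coverage_fraction)
            data[mask.data == 0] = 0.0
            out.append((record, ReHoMap(data=data), mask))

    return out


def null_cohort_spec(n_per_sex: int = 40, seed: int = 0) -> CohortSpec:
    """Single-study cohort whose sex labels are independent of the images.

    Chance accuracy for balanced samples is 0.5; with a finite pool re-used
    across replicates, the replicate-mean accuracy of one cohort scatters
    around 0.5 at the cohort level (~0.02-0.03 SD at 80 subjects).
    """
    return CohortSpec(
        studies=[StudySpec("Null", n_per_sex, n_per_sex, effect_strength=0.0)],
        seed=seed,
    )


def two_site_spec(seed: int = 0, n_per_sex: int = 30) -> CohortSpec:
    """Two sites sharing the sex-effect region but differing in noise and coverage.

    Site A is the cleaner, fully covered site; site B is noisier with 85%
    coverage.  The noise difference shifts the effect-region concordance
    baseline between sites, so classifiers transfer imperfectly: within-site
    accuracy exceeds cross-site accuracy while both stay above chance.
    """
    return CohortSpec(
        studies=[
            StudySpec("SiteA", n_per_sex, n_per_sex, effect_strength=0.05,
                      noise_sd=1.5, coverage_fraction=1.0),
            StudySpec("SiteB", n_per_sex, n_per_sex, effect_strength=0.05,
                      noise_sd=2.5, coverage_fraction=0.85),
        ],
        seed=seed,
    )


def subset_geometry_spec(seed: int = 0, n_per_sex: int = 30) -> CohortSpec:
    """Subset geometry: a homogeneous narrow-effect site inside a wide-effect site.

    Site "Narrow" carries a strong sex effect confined to a small region that
    is a strict subset of site "Wide"'s larger, weaker, population-
    heterogeneous effect region.  A classifier trained on the wide
    (population-like) site classifies the narrow (subset) site well, while
    the reverse direction drops toward chance — the classic failure of a
    classifier trained on a homogeneous subsample.
    """
    return CohortSpec(
        studies=[
            StudySpec("Narrow", n_per_sex, n_per_sex, effect_strength=0.3,
                      effect_radius=2, region_baseline=0.0),
            StudySpec("Wide", n_per_sex, n_per_sex, effect_strength=0.07,
                      effect_radius=4, region_baseline=0.0, region_jitter_sd=0.05),
        ],
        seed=seed,
    )


def table1_fixture() -> pd.DataFrame:
    """The packaged 27-study demographics composition table.

    Columns: study, total, female, male, age_mean, age_sd.  Study rows only
    (no totals row); per-study totals sum to 1170 subjects.
    """
    with resources.files("rehosim.data").joinpath("demographics.csv").open() as fh:
        return pd.read_csv(fh)
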