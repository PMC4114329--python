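"""Balanced-resampling simulation of classifier generalizability.

Five configuration families quantify how a sex classifier trained on one
source transfers to another:

* ``within_study``      — train and test on disjoint subjects of one study;
* ``study_to_pooled``   — train on one study, test on subjects pooled from
                          all other studies;
* ``study_pair``        — train on one study, test on a different study;
* ``pooled_to_study``   — train on the pool of all other studies, test on one
                          study;
* ``pooled_to_pooled``  — train and test on disjoint samples from the pool.

Every drawn sample is *balanced* (equal numbers of females and males, so
chance accuracy is exactly 0.5) and train/test sets never overlap.  Each
(configuration, training size) cell is run as many independent replicates
(1000 by default); a replicate rebuilds the group mask from its training
subjects only, vectorizes, fits the PCA+SVM classifier and records test
accuracy.  Replicate seeds are hash-derived from (config seed, train size,
replicate id) so any replicate can be re-run in isolation.

ReHo maps are computed once per subject and cached in a :class:`DataStore`
before any sampling: feature extraction is subject-level, only
masking/PCA/SVM are per-replicate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import classifier as clf
from .masking import GroupMask, SubjectMask, group_mask, vectorize
from .preprocess import PreprocessParams, clean
from .reho import ReHoMap, reho_map
from .seeding import derive_rng, derive_seed
from .synthetic import MAX_BALANCED_OVERRIDES, STUDY_ALIASES, SubjectRecord

__all__ = [
    "FAMILIES",
    "SimulationConfig",
    "ReplicateResult",
    "SummaryResult",
    "DataStore",
    "max_balanced_size",
    "plan_sample_sizes",
    "draw_balanced_sample",
    "run_replicate",
    "run_configuration",
    "summary_matrix",
]

logger = logging.getLogger(__name__)

FAMILIES = (
    "within_study",
    "study_to_pooled",
    "study_pair",
    "pooled_to_study",
    "pooled_to_pooled",
)

POOLED = "pooled"
POOLED_GRID_MAX = 200  # training grid cap for pooled-training families
POOLED_TEST_SIZE = 200  # test sample size drawn from a pooled source
MIN_SIZE = 20
STEP = 10


@dataclass
class SimulationConfig:
    family: str
    train_source: str = POOLED
    test_source: str = POOLED
    excluded_studies: list[str] = field(default_factory=list)
    train_sizes: list[int] = field(default_factory=list)
    test_size: int | str = "equal_to_train"
    n_replicates: int = 1000
    seed: int = 0
    mask_source: str = "whole_brain"
    mask_threshold: float = 0.95
    cost: float = 1.0

    def validate(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        for s in self.train_sizes:
            if s % 2:
                raise ValueError(f"train size {s} is odd; balanced samples need even sizes")
        if isinstance(self.test_size, int) and self.test_size % 2:
            raise ValueError(f"test size {self.test_size} is odd")


@dataclass
class ReplicateResult:
    replicate_id: int
    train_subject_ids: list[str]
    test_subject_ids: list[str]
    accuracy: float
    p_dim: int


@dataclass
class SummaryResult:
    """Per-size mean and SD of test accuracy for one configuration."""

    config: SimulationConfig
    sizes: list[int]
    mean_accuracy: dict[int, float]
    sd_accuracy: dict[int, float]
    mean_p_dim: dict[int, float]
    n_replicates: int
    metadata: dict = field(default_factory=dict)
    replicates: dict[int, np.ndarray] | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "size": self.sizes,
                "mean_acc": [self.mean_accuracy[s] for s in self.sizes],
                "sd_acc": [self.sd_accuracy[s] for s in self.sizes],
                "n_reps": self.n_replicates,
                "mean_p_dim": [self.mean_p_dim[s] for s in self.sizes],
            }
        )


class DataStore:
    """Cached per-subject ReHo maps + masks + demographics, keyed by subject id."""

    def __init__(self, demographics: pd.DataFrame,
                 maps: dict[str, ReHoMap], masks: dict[str, SubjectMask]):
        required = {"subject_id", "study", "sex"}
        missing = required - set(demographics.columns)
        if missing:
            raise ValueError(f"demographics table missing columns {sorted(missing)}")
        if demographics["subject_id"].duplicated().any():
            dup = demographics.loc[demographics["subject_id"].duplicated(), "subject_id"]
            raise ValueError(f"duplicate subject ids: {sorted(set(dup))[:5]}")
        self.demographics = demographics.reset_index(drop=True)
        self.maps = maps
        self.masks = masks

    @classmethod
    def from_subject_maps(cls, triples: list[tuple[SubjectRecord, ReHoMap, SubjectMask]]):
        """Build from (record, reho map, mask) triples, e.g. the fast-path generator."""
        from .synthetic import demographics_frame

        records = [t[0] for t in triples]
        return cls(
            demographics_frame(records),
            maps={t[0].subject_id: t[1] for t in triples},
            masks={t[0].subject_id: t[2] for t in triples},
        )

    @classmethod
    def from_cohort(cls, subjects, demographics: pd.DataFrame,
                    params: PreprocessParams | None = None,
                    tie_correction: bool = False):
        """Preprocess every generated subject's volume and compute its ReHo map once."""
        params = params or PreprocessParams()
        maps, masks = {}, {}
        for subj in subjects:
            cleaned = clean(subj.volume, subj.nuisance, params, subj.mask)
            maps[subj.record.subject_id] = reho_map(cleaned, subj.mask, tie_correction)
            masks[subj.record.subject_id] = subj.mask
        return cls(demographics, maps, masks)

    def pool(self, include: list[str] | None = None,
             exclude: list[str] | None = None) -> pd.DataFrame:
        df = self.demographics
        if include is not None:
            df = df[df["study"].isin(include)]
        if exclude:
            df = df[~df["study"].isin(exclude)]
        return df


# ---------------------------------------------------------------------------
# sample-size planning
# ---------------------------------------------------------------------------

def _sex_counts(demographics: pd.DataFrame, study: str) -> tuple[int, int]:
    study = STUDY_ALIASES.get(study, study)
    if {"female", "male"} <= set(demographics.columns):
        row = demographics[demographics["study"] == study]
        if row.empty:
            raise ValueError(f"study {study!r} not found in demographics")
        return int(row.iloc[0]["female"]), int(row.iloc[0]["male"])
    sub = demographics[demographics["study"] == study]
    if sub.empty:
        raise ValueError(f"study {study!r} not found in demographics")
    return int((sub["sex"] == "female").sum()), int((sub["sex"] == "male").sum())


def max_balanced_size(demographics: pd.DataFrame, study: str,
                      overrides: dict[str, int] | None = None) -> int:
    """Largest multiple of 10 not exceeding twice the smaller sex count.

    ``overrides`` (default: the published per-study override table) wins where
    present.
    """
    if overrides is None:
        overrides = MAX_BALANCED_OVERRIDES
    resolved = STUDY_ALIASES.get(study, study)
    if resolved in overrides:
        return overrides[resolved]
    f, m = _sex_counts(demographics, study)
    return STEP * ((2 * min(f, m)) // STEP)


def _grid(lo: int, hi: int) -> list[int]:
    return list(range(lo, hi + 1, STEP))


def plan_sample_sizes(
    demographics: pd.DataFrame,
    family: str,
    train_source: str | None = None,
    test_source: str | None = None,
    overrides: dict[str, int] | None = None,
) -> tuple[list[int], int | str]:
    """Training-size grid and test size for one configuration.

    Within-study runs use equal train/test sizes from 20 up to the largest
    grid point not exceeding half the study's maximum balanced sample (both
    halves must fit in the study without overlap).  Cross-study training
    grids run from 20 to the study's maximum balanced size; pooled training
    grids run from 20 to 200.  Test sizes are the test study's maximum
    balanced sample for single-study test sets and 200 for pooled test sets.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")

    def train_max() -> int:
        mx = max_balanced_size(demographics, train_source, overrides)
        if mx < MIN_SIZE:
            raise ValueError(
                f"study {train_source!r} too small: maximum balanced size {mx} < {MIN_SIZE}"
            )
        return mx

    if family == "within_study":
        mx = train_max()
        top = STEP * ((mx // 2) // STEP)
        if top < MIN_SIZE:
            raise ValueError(
                f"study {train_source!r} too small for within-study runs "
                f"(half of max balanced size {mx} is below {MIN_SIZE})"
            )
        return _grid(MIN_SIZE, top), "equal_to_train"
    if family == "study_to_pooled":
        return _grid(MIN_SIZE, train_max()), POOLED_TEST_SIZE
    if family == "study_pair":
        test_mx = max_balanced_size(demographics, test_source, overrides)
        return _grid(MIN_SIZE, train_max()), test_mx
    if family == "pooled_to_study":
        test_mx = max_balanced_size(demographics, test_source, overrides)
        return _grid(MIN_SIZE, POOLED_GRID_MAX), test_mx
    # pooled_to_pooled
    return _grid(MIN_SIZE, POOLED_GRID_MAX), POOLED_TEST_SIZE


# ---------------------------------------------------------------------------
# sampling and replicates
# ---------------------------------------------------------------------------

def draw_balanced_sample(
    pool: pd.DataFrame,
    size: int,
    exclude_ids: set[str] | None = None,
    rng: np.random.Generator | None = None,
) -> list[str]:
    """Uniformly sample size/2 females + size/2 males without replacement."""
    if size % 2:
        raise ValueError(f"balanced sample size must be even, got {size}")
    rng = rng or np.random.default_rng()
    exclude_ids = exclude_ids or set()
    avail = pool[~pool["subject_id"].isin(exclude_ids)]
    ids = []
    for sex in ("female", "male"):
        cand = avail.loc[avail["sex"] == sex, "subject_id"].to_numpy()
        if cand.size < size // 2:
            raise ValueError(
                f"need {size // 2} {sex} subjects but only {cand.size} available "
                f"(pool {len(pool)}, excluded {len(exclude_ids)})"
            )
        ids.extend(rng.choice(cand, size=size // 2, replace=False).tolist())
    return ids


def _resolve_pools(config: SimulationConfig, store: DataStore) -> tuple[pd.DataFrame, pd.DataFrame, bool]:
    """(test pool, train pool, shared) per family; shared means draws must be disjoint by id."""
    excl = list(config.excluded_studies)
    alias = lambda s: STUDY_ALIASES.get(s, s)
    fam = config.family
    if fam == "within_study":
        pool = store.pool(include=[alias(config.train_source)])
        return pool, pool, True
    if fam == "study_to_pooled":
        train = store.pool(include=[alias(config.train_source)])
        test = store.pool(exclude=excl + [alias(config.train_source)])
        return test, train, False
    if fam == "study_pair":
        if alias(config.train_source) == alias(config.test_source):
            raise ValueError("study_pair requires two distinct studies")
        return (
            store.pool(include=[alias(config.test_source)]),
            store.pool(include=[alias(config.train_source)]),
            False,
        )
    if fam == "pooled_to_study":
        test = store.pool(include=[alias(config.test_source)])
        train = store.pool(exclude=excl + [alias(config.test_source)])
        return test, train, False
    pool = store.pool(exclude=excl)
    return pool, pool, True


def run_replicate(
    config: SimulationConfig,
    train_size: int,
    replicate_id: int,
    store: DataStore,
    rng: np.random.Generator | None = None,
) -> ReplicateResult:
    """One simulation run: draw test then training sample, train, test.

    The group mask is rebuilt from the training subjects' masks only; test
    masks are never read during training.
    """
    if rng is None:
        rng = derive_rng(config.seed, train_size, replicate_id)
    test_size = train_size if config.test_size == "equal_to_train" else int(config.test_size)

    sex_of = dict(zip(store.demographics["subject_id"], store.demographics["sex"]))
    try:
        test_pool, train_pool, shared = _resolve_pools(config, store)
        test_ids = draw_balanced_sample(test_pool, test_size, rng=rng)
        exclude = set(test_ids) if shared else set()
        train_ids = draw_balanced_sample(train_pool, train_size, exclude_ids=exclude, rng=rng)

        overlap = set(train_ids) & set(test_ids)
        if overlap:
            raise ValueError(f"train/test overlap on {sorted(overlap)[:5]}")

        gmask = group_mask([store.masks[i] for i in train_ids], config.mask_threshold)
        x_train = vectorize([store.maps[i] for i in train_ids], gmask)
        model = clf.fit(x_train, [sex_of[i] for i in train_ids], cost=config.cost, gmask=gmask)
        x_test = vectorize([store.maps[i] for i in test_ids], gmask)
        acc = clf.accuracy(clf.predict(model, x_test), np.array([sex_of[i] for i in test_ids]))
    except Exception as err:
        raise RuntimeError(
            f"replicate {replicate_id} (train size {train_size}) failed: {err}"
        ) from err

    logger.debug(
        "replicate %d: train=%d test=%d p=%d acc=%.3f",
        replicate_id, train_size, test_size, gmask.n_voxels, acc,
    )
    return ReplicateResult(
        replicate_id=replicate_id,
        train_subject_ids=train_ids,
        test_subject_ids=test_ids,
        accuracy=acc,
        p_dim=gmask.n_voxels,
    )


def run_configuration(
    config: SimulationConfig,
    store: DataStore,
    keep_replicates: bool = False,
) -> SummaryResult:
    """Run every (train size x replicate) cell and aggregate mean/SD accuracy.

    Any replicate failure aborts the configuration with context; replicates
    are never silently resampled, keeping the accuracy distribution unbiased.
    """
    config.validate()
    sizes = list(config.train_sizes)
    if not sizes:
        raise ValueError("config.train_sizes is empty; run plan_sample_sizes first")
    mean_acc, sd_acc, mean_p, reps_out = {}, {}, {}, {}
    for size in sizes:
        accs = np.empty(config.n_replicates)
        pdims = np.empty(config.n_replicates)
        for rep in range(config.n_replicates):
            result = run_replicate(config, size, rep, store)
            accs[rep] = result.accuracy
            pdims[rep] = result.p_dim
        mean_acc[size] = float(accs.mean())
        sd_acc[size] = float(accs.std(ddof=1)) if accs.size > 1 else 0.0
        mean_p[size] = float(pdims.mean())
        if keep_replicates:
            reps_out[size] = accs.copy()
    metadata = {"sd_convention": "sample SD (ddof=1); 0 by convention when n_replicates = 1"}
    if config.n_replicates == 1:
        metadata["single_replicate"] = True
    return SummaryResult(
        config=config,
        sizes=sizes,
        mean_accuracy=mean_acc,
        sd_accuracy=sd_acc,
        mean_p_dim=mean_p,
        n_replicates=config.n_replicates,
        metadata=metadata,
        replicates=reps_out if keep_replicates else None,
    )


def null_benchmark(
    seed: int,
    n_cohorts: int = 40,
    reps_per_cohort: int = 5,
    train_size: int = 20,
    n_per_sex: int = 40,
) -> np.ndarray:
    """Null-pipeline accuracies: balanced within-study replicates on cohorts
    whose sex labels are independent of the images.

    The replicates are spread over many independent null cohorts rather than
    one fixed pool: any single finite pool carries a chance sex/image
    association that is shared between its (disjoint) train and test draws,
    so the replicate mean conditional on one cohort scatters around 0.5 with
    a cohort-level SD of ~0.025 at 80 subjects — and the scatter is
    right-skewed, because a chance association can only *help* within-pool
    generalization.  Blocking over fresh cohorts estimates the marginal null
    accuracy — exactly 0.5 in expectation — with correspondingly smaller
    variance.  Returns the pooled accuracy array (``n_cohorts *
    reps_per_cohort`` values).
    """
    from .synthetic import make_cohort, null_cohort_spec

    accs = []
    for c in range(n_cohorts):
        spec = null_cohort_spec(n_per_sex=n_per_sex, seed=derive_seed(seed, "null-cohort", c))
        subjects, demographics = make_cohort(spec)
        store = DataStore.from_cohort(subjects, demographics)
        cfg = SimulationConfig(
            family="within_study", train_source="Null",
            train_sizes=[train_size], test_size="equal_to_train",
            n_replicates=reps_per_cohort, seed=derive_seed(seed, "null-sim", c),
        )
        result = run_configuration(cfg, store, keep_replicates=True)
        accs.append(result.replicates[train_size])
    return np.concatenate(accs)


def summary_matrix(results: list[SummaryResult]) -> pd.DataFrame:
    """Training-source x test-source table of mean accuracy at the largest size.

    Pooled sources appear as the row/column "All/Others"; pairs not covered by
    ``results`` are left as NaN.
    """
    cells: dict[tuple[str, str], float] = {}
    for res in results:
        cfg = res.config
        row = "All/Others" if cfg.family in ("pooled_to_study", "pooled_to_pooled") else cfg.train_source
        if cfg.family == "within_study":
            col = cfg.train_source
        elif cfg.family in ("study_to_pooled", "pooled_to_pooled"):
            col = "All/Others"
        else:
            col = cfg.test_source
        key = (row, col)
        if key in cells:
            raise ValueError(f"duplicate train/test pair {key}")
        top = max(res.sizes)
        cells[key] = res.mean_accuracy[top]
    rows = sorted({k[0] for k in cells}, key=lambda s: (s == "All/Others", s))
    cols = sorted({k[1] for k in cells}, key=lambda s: (s == "All/Others", s))
    mat = pd.DataFrame(index=rows, columns=cols, dtype=float)
    for (r, c), v in cells.items():
        mat.loc[r, c] = v
    mat.index.name = "train"
    mat.columns.name = "test"
    return mat
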