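"""Voxel-based lesion-symptom mapping with cluster-size permutation control.

At every voxel covered by enough patients, a two-sample t test compares the
behavioral scores of patients whose dysfunction mask includes the voxel
against those whose mask does not. Variance due to functional lesion size
is removed beforehand by regressing the score on lesion volume and carrying
the residuals into every voxelwise test. Multiple comparisons are handled
by cluster-size permutation: the score vector is permuted across patients
(lesion anatomy fixed), the suprathreshold cluster sizes of each permuted
map form the null, and an observed cluster survives when its size strictly
exceeds the chosen percentile of that null.

Sign convention: scores are performance-coded (higher = better), and
``t > 0`` means the lesioned group performs worse (deficit-positive).

The residuals are computed once and the same residual vector — permuted or
not — flows through one shared code path for observed and null maps, so no
observed/null asymmetry can arise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Literal, Optional, Sequence

import numpy as np
from scipy import stats as sps
from skimage.measure import label as _sklabel

from .behavior import BehaviorRecord, derive_phenotypes
from .grid import VolumeGrid
from .io import CohortImages
from .lesions import DysfunctionMasks, build_dysfunction_masks

logger = logging.getLogger(__name__)

_CONNECTIVITY_TO_SKIMAGE = {6: 1, 18: 2, 26: 3}

#: smallest positive double; assigned to degenerate zero-variance voxels
MIN_P = float(np.nextafter(0, 1))


@dataclass(frozen=True)
class VlsmConfig:
    """Tunable parameters of the mapping procedure."""

    voxel_p_threshold: float = 0.01
    n_permutations: int = 1000
    cluster_percentile: float = 95.0
    connectivity: Literal[6, 18, 26] = 26
    min_lesion_count: int = 5
    null_pooling: Literal["pooled", "max_per_permutation"] = "pooled"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.voxel_p_threshold < 1:
            raise ValueError("voxel_p_threshold must be in (0, 1)")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not 0 < self.cluster_percentile < 100:
            raise ValueError("cluster_percentile must be in (0, 100)")
        if self.connectivity not in _CONNECTIVITY_TO_SKIMAGE:
            raise ValueError("connectivity must be one of 6, 18, 26")
        if self.null_pooling not in ("pooled", "max_per_permutation"):
            raise ValueError("null_pooling must be 'pooled' or 'max_per_permutation'")


@dataclass
class StatMap:
    """Voxelwise statistic volumes plus the validity mask."""

    grid: VolumeGrid
    t_values: np.ndarray
    p_values: np.ndarray
    valid: np.ndarray
    n_lesioned: np.ndarray
    degenerate: Optional[np.ndarray] = None  # zero-variance voxels flagged

    def significant(self, p_threshold: float) -> np.ndarray:
        """Binary volume of valid voxels with p below threshold."""
        return self.valid & (self.p_values < p_threshold)


@dataclass
class ClusterReport:
    """Suprathreshold clusters and their permutation-based significance."""

    labels: np.ndarray  # integer volume, 0 = background
    cluster_sizes: dict[int, int]
    null_sizes: np.ndarray
    size_threshold: float
    significant_labels: list[int]

    @property
    def significant_mask(self) -> np.ndarray:
        if not self.significant_labels:
            return np.zeros(self.labels.shape, dtype=bool)
        return np.isin(self.labels, self.significant_labels)


def residualize(y: np.ndarray, covariate: np.ndarray) -> np.ndarray:
    """Residuals of the least-squares regression of ``y`` on the covariate.

    Residuals sum to zero and are orthogonal to the covariate. A constant
    covariate degenerates to mean-centering (with a warning).
    """
    y = np.asarray(y, dtype=float)
    covariate = np.asarray(covariate, dtype=float)
    if y.size < 3:
        raise ValueError("residualization needs at least 3 patients")
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(covariate))):
        raise ValueError("non-finite values in outcome or covariate")
    c = covariate - covariate.mean()
    denom = c @ c
    if denom == 0:
        logger.warning("constant covariate: residualization is mean-centering only")
        return y - y.mean()
    slope = (c @ (y - y.mean())) / denom
    return y - y.mean() - slope * c


def _t_columns(
    X: np.ndarray, Y: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pooled-variance two-sample t per (voxel column, score column) pair.

    ``X`` is the patients x voxels lesion indicator (float 0/1), ``Y`` the
    patients x k score matrix. Returns (t, p, degenerate), each voxels x k,
    with t = (intact mean - lesioned mean) / SE so deficits are positive.
    Zero-variance voxels with a nonzero group difference get ``t = +-inf``
    and the smallest representable p.
    """
    n = X.shape[0]
    n1 = X.sum(axis=0)  # lesioned count per voxel
    n0 = n - n1
    s1 = X.T @ Y
    ssq1 = X.T @ (Y**2)
    tot = Y.sum(axis=0)
    sstot = (Y**2).sum(axis=0)
    m1 = s1 / n1[:, None]
    m0 = (tot[None, :] - s1) / n0[:, None]
    ss1 = np.clip(ssq1 - n1[:, None] * m1**2, 0, None)
    ss0 = np.clip(sstot[None, :] - ssq1 - n0[:, None] * m0**2, 0, None)
    dof = n - 2
    pooled = (ss1 + ss0) / dof
    se = np.sqrt(pooled * (1.0 / n1 + 1.0 / n0)[:, None])
    diff = m0 - m1
    degenerate = (se == 0) & (diff != 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    t[(se == 0) & (diff == 0)] = 0.0
    t[degenerate] = np.sign(diff[degenerate]) * np.inf
    p = 2.0 * sps.t.sf(np.abs(np.where(np.isfinite(t), t, 0.0)), dof)
    p = np.minimum(p, 1.0)
    p[degenerate] = MIN_P
    return t, p, degenerate


def voxelwise_t(
    masks: DysfunctionMasks, score: np.ndarray, cfg: VlsmConfig = VlsmConfig()
) -> StatMap:
    """Mass-univariate lesioned-vs-intact t map.

    Voxels with fewer than ``cfg.min_lesion_count`` patients in either group
    are marked invalid and excluded from inference.
    """
    score = np.asarray(score, dtype=float)
    n = masks.n_patients
    if score.shape != (n,):
        raise ValueError(f"score must have one value per patient ({n})")
    if not np.all(np.isfinite(score)):
        raise ValueError("scores must be finite for all included patients")
    flat = masks.masks.reshape(n, -1)
    n_lesioned = flat.sum(axis=0)
    valid_flat = (n_lesioned >= cfg.min_lesion_count) & (
        n - n_lesioned >= cfg.min_lesion_count
    )
    if not valid_flat.any():
        raise ValueError(
            "no voxel has enough lesioned and intact patients "
            f"(min_lesion_count={cfg.min_lesion_count})"
        )
    X = flat[:, valid_flat].astype(np.float64)
    t, p, degen = _t_columns(X, score[:, None])

    shape = masks.grid.shape
    t_vol = np.zeros(shape)
    p_vol = np.ones(shape)
    d_vol = np.zeros(shape, dtype=bool)
    t_vol.reshape(-1)[valid_flat] = t[:, 0]
    p_vol.reshape(-1)[valid_flat] = p[:, 0]
    d_vol.reshape(-1)[valid_flat] = degen[:, 0]
    return StatMap(
        grid=masks.grid,
        t_values=t_vol,
        p_values=p_vol,
        valid=valid_flat.reshape(shape),
        n_lesioned=n_lesioned.reshape(shape).astype(np.int32),
        degenerate=d_vol,
    )


def label_clusters(
    sig: np.ndarray, connectivity: Literal[6, 18, 26] = 26
) -> tuple[np.ndarray, dict[int, int]]:
    """Connected components of a binary volume and their voxel counts."""
    if connectivity not in _CONNECTIVITY_TO_SKIMAGE:
        raise ValueError("connectivity must be one of 6, 18, 26")
    labels = _sklabel(
        np.asarray(sig, dtype=bool),
        connectivity=_CONNECTIVITY_TO_SKIMAGE[connectivity],
    )
    counts = np.bincount(labels.ravel())
    sizes = {int(lab): int(counts[lab]) for lab in range(1, counts.size)}
    return labels, sizes


def _cluster_sizes_flat(
    sig_flat: np.ndarray, shape: tuple[int, int, int], connectivity: int
) -> np.ndarray:
    _, sizes = label_clusters(sig_flat.reshape(shape), connectivity)
    return np.fromiter(sizes.values(), dtype=np.int64, count=len(sizes))


def permutation_correct(
    masks: DysfunctionMasks,
    score: np.ndarray,
    cfg: VlsmConfig = VlsmConfig(),
    covariate: Optional[np.ndarray] = None,
    _chunk: int = 128,
) -> tuple[StatMap, ClusterReport]:
    """Cluster-size permutation correction of the voxelwise map.

    When ``covariate`` is given the score is residualized on it once; the
    resulting residual vector is used for the observed map and its
    permutations for the null, so the covariate adjustment is identical on
    both sides. ``null_pooling='pooled'`` collects every null cluster size
    into one pool; ``'max_per_permutation'`` keeps only the largest cluster
    of each permutation (0 when none), the standard FWER-controlling
    variant. An observed cluster is significant when its size strictly
    exceeds the ``cluster_percentile``-th percentile of the null sizes.
    """
    score = np.asarray(score, dtype=float)
    if covariate is not None:
        score = residualize(score, covariate)

    observed = voxelwise_t(masks, score, cfg)
    sig_obs = observed.significant(cfg.voxel_p_threshold)
    labels, sizes = label_clusters(sig_obs, cfg.connectivity)

    n = masks.n_patients
    flat = masks.masks.reshape(n, -1)
    valid_flat = observed.valid.reshape(-1)
    X = flat[:, valid_flat].astype(np.float64)
    shape = masks.grid.shape
    nvalid = int(valid_flat.sum())

    rng = np.random.default_rng(cfg.seed)
    perms = np.stack([rng.permutation(score) for _ in range(cfg.n_permutations)], axis=1)

    pooled_sizes: list[np.ndarray] = []
    per_perm_max = np.zeros(cfg.n_permutations, dtype=np.int64)
    sig_flat = np.zeros(valid_flat.size, dtype=bool)
    for start in range(0, cfg.n_permutations, _chunk):
        block = perms[:, start : start + _chunk]
        _, p_block, _ = _t_columns(X, block)
        sig_block = p_block < cfg.voxel_p_threshold  # nvalid x k
        for j in range(block.shape[1]):
            sig_flat[:] = False
            sig_flat[valid_flat] = sig_block[:, j]
            csizes = _cluster_sizes_flat(sig_flat, shape, cfg.connectivity)
            if csizes.size:
                pooled_sizes.append(csizes)
                per_perm_max[start + j] = csizes.max()

    if cfg.null_pooling == "pooled":
        null_sizes = (
            np.concatenate(pooled_sizes) if pooled_sizes else np.zeros(0, dtype=np.int64)
        )
    else:
        null_sizes = per_perm_max

    if null_sizes.size == 0:
        logger.warning("no suprathreshold clusters in any permutation; size threshold = 0")
        size_threshold = 0.0
    else:
        size_threshold = float(np.percentile(null_sizes, cfg.cluster_percentile))

    significant = sorted(lab for lab, sz in sizes.items() if sz > size_threshold)
    report = ClusterReport(labels, sizes, null_sizes, size_threshold, significant)
    return observed, report


@dataclass
class VlsmResult:
    """Artifacts of one end-to-end mapping run."""

    stat_map: StatMap
    clusters: ClusterReport
    provenance: dict


def run_vlsm(
    cohort: CohortImages,
    records: Sequence[BehaviorRecord],
    phenotype: Literal["aos", "span"],
    cfg: VlsmConfig = VlsmConfig(),
    ttp_threshold_s: float = 4.0,
    brain_mask: Optional[np.ndarray] = None,
    masks: Optional[DysfunctionMasks] = None,
) -> VlsmResult:
    """Full pipeline for one phenotype: lesions, residuals, t map, correction.

    AOS analyses use the binary AOS flag performance-coded (1 = no AOS) and
    exclude indeterminate patients; span analyses use the raw digit span and
    exclude patients with undefined span. Functional lesion volume is always
    residualized out. Precomputed ``masks`` may be passed to skip the lesion
    stage.
    """
    if phenotype not in ("aos", "span"):
        raise ValueError("phenotype must be 'aos' or 'span'")
    if masks is None:
        masks = build_dysfunction_masks(cohort, ttp_threshold_s, brain_mask)
    if masks.patient_ids != list(cohort.patient_ids):
        raise ValueError("dysfunction masks and cohort patients disagree")
    phen = derive_phenotypes(records)
    if [p.patient_id for p in phen] != list(cohort.patient_ids):
        raise ValueError("behavior records must align with cohort patient order")

    if phenotype == "aos":
        include = np.array([p.aos_status != "indeterminate" for p in phen])
        score_all = np.array(
            [0.0 if p.aos_status == "AOS" else 1.0 for p in phen]
        )  # performance-coded: 1 = intact speech praxis
    else:
        include = np.array([p.digit_span is not None for p in phen])
        score_all = np.array([float(p.digit_span or 0) for p in phen])

    n_excluded = int((~include).sum())
    if n_excluded:
        logger.info("%s analysis: excluding %d patients", phenotype, n_excluded)
    sub = DysfunctionMasks(
        masks.grid,
        [pid for pid, k in zip(masks.patient_ids, include) if k],
        masks.masks[include],
        masks.lesion_volumes[include],
        masks.ttp_threshold_s,
    )
    score = score_all[include]
    if np.ptp(score) == 0:
        # constant phenotype: maps degenerate to t = 0 everywhere and the
        # significant set is empty, which is the correct answer
        logger.warning("%s phenotype is constant across included patients", phenotype)
    observed, report = permutation_correct(
        sub, score, cfg, covariate=sub.lesion_volumes.astype(float)
    )
    provenance = {
        "phenotype": phenotype,
        "config": {
            "voxel_p_threshold": cfg.voxel_p_threshold,
            "n_permutations": cfg.n_permutations,
            "cluster_percentile": cfg.cluster_percentile,
            "connectivity": cfg.connectivity,
            "min_lesion_count": cfg.min_lesion_count,
            "null_pooling": cfg.null_pooling,
            "seed": cfg.seed,
        },
        "ttp_threshold_s": ttp_threshold_s,
        "n_patients_total": cohort.n_patients,
        "n_patients_included": int(include.sum()),
        "n_patients_excluded": n_excluded,
        "n_valid_voxels": int(observed.valid.sum()),
        "n_observed_clusters": len(report.cluster_sizes),
        "n_significant_clusters": len(report.significant_labels),
        "size_threshold": report.size_threshold,
    }
    return VlsmResult(observed, report, provenance)
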