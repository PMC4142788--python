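"""Synthetic acute-stroke cohorts with known ground truth.

The generator emulates the statistical structure the analysis assumes: a
cohort of left-hemisphere lesions of varying size, hypoperfusion extending
beyond the infarct core, deficits caused by dysfunction coverage of planted
critical regions, and a deliberate lesion-size confound for the covariate
stage to remove.

Per patient: a connected infarct core is grown by stochastic accretion from
a uniformly sampled left-hemisphere seed; a perilesional halo of voxels is
hypoperfused with probability ``hypoperfusion_halo_p``; the TTP map is a
constant baseline plus ``ttp_delay_s`` (default 6 s, above the 4 s
criterion) over infarct and halo, so the lesion-definition stage recovers
the true dysfunction mask exactly. Each phenotype is deficit-positive when
the fraction of its critical region covered by dysfunctional tissue exceeds
``coverage_threshold``; the label is then flipped with probability
``noise_rate``, and large lesions add deficits through a logistic
lesion-size term weighted by ``size_confound_gamma``. Behavioral records
(ABA flags, span trials, WAB AQ) are generated to reproduce the assigned
phenotypes exactly under the scoring rules.

The default deficit parameters are set so that the expected prevalences
match the reference cohort this package models: about 17/76 for apraxia of
speech and 15/76 for impaired digit span. All randomness flows from one
seeded generator; config + seed determine every output bit.
"""

from __future__ import annotations

import itertools
import json
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.ndimage import binary_dilation
from scipy.special import expit

from .behavior import BehaviorRecord, write_behavior_table
from .grid import VolumeGrid
from .io import CohortImages, save_volume
from .lesions import DysfunctionMasks

_OFFSETS26 = [
    off for off in itertools.product((-1, 0, 1), repeat=3) if off != (0, 0, 0)
]


@dataclass(frozen=True)
class DeficitModel:
    """Generative model of one binary deficit.

    ``coverage_threshold`` (theta) is the fraction of the critical region
    that must be dysfunctional for a causal deficit; ``noise_rate`` (epsilon)
    flips the label; ``size_confound_gamma`` (gamma) scales a logistic
    lesion-size term that adds non-causal deficits in large lesions.
    """

    coverage_threshold: float = 0.15
    noise_rate: float = 0.02
    size_confound_gamma: float = 0.08

    def __post_init__(self) -> None:
        if not 0 <= self.coverage_threshold <= 1:
            raise ValueError("coverage_threshold must be in [0, 1]")
        if not 0 <= self.noise_rate <= 1:
            raise ValueError("noise_rate must be in [0, 1]")


@dataclass
class SimConfig:
    """Cohort-level generative parameters."""

    grid_shape: tuple[int, int, int] = (24, 24, 24)
    n_patients: int = 76
    lesion_size_range: tuple[int, int] = (20, 150)
    hypoperfusion_halo_p: float = 0.3
    #: probability that a lesion seed is drawn from the vascular territory
    #: around the critical regions rather than uniformly over the hemisphere;
    #: emulates the perisylvian concentration of middle-cerebral-artery stroke
    territory_seed_bias: float = 0.8
    territory_dilation: int = 3
    critical_regions: Optional[dict[str, np.ndarray]] = None
    deficit_models: dict[str, DeficitModel] = field(
        default_factory=lambda: {
            "aos": DeficitModel(coverage_threshold=0.15, size_confound_gamma=0.08),
            "span": DeficitModel(coverage_threshold=0.16, size_confound_gamma=0.06),
        }
    )
    ttp_base_s: float = 15.0
    ttp_delay_s: float = 6.0
    midline_axis: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be positive")
        lo, hi = self.lesion_size_range
        if not 1 <= lo <= hi:
            raise ValueError("lesion_size_range must be 1 <= lo <= hi")

    def make_grid(self) -> VolumeGrid:
        return VolumeGrid(self.grid_shape, midline_axis=self.midline_axis)


def default_critical_regions(grid: VolumeGrid) -> dict[str, np.ndarray]:
    """Two overlapping spherical regions in the left hemisphere.

    The AOS region sits slightly lateral/anterior of the span region; the
    two spheres share a sub-volume, mirroring the partially-overlapping-
    network hypothesis the pipeline is designed to probe. Centers and radii
    scale with the grid so any even-symmetric shape works.
    """
    if grid.midline_axis != 0:
        raise ValueError("default regions assume midline_axis=0")
    sx, sy, sz = grid.shape

    def sphere(center_frac, radius_frac):
        center = [f * s for f, s in zip(center_frac, (sx, sy, sz))]
        radius = radius_frac * min(sx, sy, sz)
        idx = np.indices(grid.shape)
        d2 = sum((idx[i] - center[i]) ** 2 for i in range(3))
        return d2 <= radius**2

    region_a = sphere((0.25, 11 / 24, 11 / 24), 4.0 / 24)
    region_b = sphere((1 / 3, 13 / 24, 13 / 24), 3.6 / 24)
    hemi = grid.analysis_side()
    return {"aos": region_a & hemi, "span": region_b & hemi}


def grow_lesion(
    grid: VolumeGrid,
    seed_voxel: tuple[int, int, int],
    target_size: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Grow a 26-connected mask of exactly ``target_size`` voxels.

    Stochastic accretion from ``seed_voxel``: at each step a uniformly
    random frontier voxel joins the mask. Growth is clipped to the left
    (analysis-side) hemisphere.
    """
    hemi = grid.analysis_side()
    if target_size < 1:
        raise ValueError("target_size must be >= 1")
    if not hemi[seed_voxel]:
        raise ValueError(f"seed voxel {seed_voxel} is not in the left hemisphere")
    capacity = int(hemi.sum())
    if target_size > capacity:
        raise ValueError(f"target_size {target_size} exceeds hemisphere capacity {capacity}")

    shape = grid.shape
    mask = np.zeros(shape, dtype=bool)
    mask[seed_voxel] = True
    size = 1

    def neighbors(v):
        x, y, z = v
        for dx, dy, dz in _OFFSETS26:
            nx, ny, nz = x + dx, y + dy, z + dz
            if 0 <= nx < shape[0] and 0 <= ny < shape[1] and 0 <= nz < shape[2]:
                yield (nx, ny, nz)

    frontier = [v for v in neighbors(seed_voxel) if hemi[v]]
    while size < target_size:
        if not frontier:
            # rebuild from the current boundary (duplicates were consumed)
            shell = binary_dilation(mask, _ball26()) & ~mask & hemi
            frontier = list(map(tuple, np.argwhere(shell)))
        i = int(rng.integers(len(frontier)))
        frontier[i], frontier[-1] = frontier[-1], frontier[i]
        v = frontier.pop()
        if mask[v]:
            continue
        mask[v] = True
        size += 1
        frontier.extend(u for u in neighbors(v) if hemi[u] and not mask[u])
    return mask


def _ball26() -> np.ndarray:
    return np.ones((3, 3, 3), dtype=bool)


def _sample_lesion_size(lo: int, hi: int, rng: np.random.Generator) -> int:
    """Log-uniform draw: stroke lesion volumes are heavily right-skewed,
    with many small lacunar infarcts and few large territorial ones."""
    return int(np.exp(rng.uniform(np.log(lo), np.log(hi))))


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated cohort, regenerable from config + seed."""

    config: SimConfig
    regions: dict[str, np.ndarray]
    true_dysfunction: np.ndarray  # (n, *shape) bool
    coverages: dict[str, np.ndarray]  # per-phenotype, per-patient fractions
    deficits: dict[str, np.ndarray]  # per-phenotype boolean assignments
    lesion_volumes: np.ndarray

    def true_masks(self, grid: VolumeGrid, patient_ids: list[str]) -> DysfunctionMasks:
        vols = self.true_dysfunction.reshape(len(patient_ids), -1).sum(axis=1)
        return DysfunctionMasks(grid, patient_ids, self.true_dysfunction, vols)


def _make_span_trials(
    target_span: int, rng: np.random.Generator
) -> list[tuple[int, int, int]]:
    """Trial records that score exactly ``target_span`` under the span rule."""
    trials = []
    for length in range(2, target_span + 1):
        t1 = int(rng.random() < 0.8)
        t2 = 1 if t1 == 0 else int(rng.random() < 0.6)
        trials.append((length, t1, t2))
    trials.append((target_span + 1 if target_span >= 2 else 2, 0, 0))
    return trials


def simulate_cohort(
    cfg: SimConfig,
) -> tuple[CohortImages, list[BehaviorRecord], SyntheticTruth]:
    """Draw one cohort: images, behavioral records, and ground truth."""
    rng = np.random.default_rng(cfg.seed)
    grid = cfg.make_grid()
    regions = cfg.critical_regions or default_critical_regions(grid)
    for name, reg in regions.items():
        grid.check_conforms(reg, f"region {name}")
        if not reg.any():
            raise ValueError(f"critical region '{name}' is empty")

    hemi = grid.analysis_side()
    hemi_idx = np.argwhere(hemi)
    n = cfg.n_patients
    lo, hi = cfg.lesion_size_range

    territory = np.zeros(grid.shape, dtype=bool)
    for reg in regions.values():
        territory |= reg
    territory = binary_dilation(territory, _ball26(), iterations=cfg.territory_dilation) & hemi
    territory_idx = np.argwhere(territory)

    patient_ids = [f"P{i + 1:03d}" for i in range(n)]
    infarcts = np.zeros((n, *grid.shape), dtype=bool)
    dysfunction = np.zeros((n, *grid.shape), dtype=bool)
    ttp_maps: list[np.ndarray] = []

    for i in range(n):
        size = _sample_lesion_size(lo, hi, rng)
        pool = territory_idx if rng.random() < cfg.territory_seed_bias else hemi_idx
        seed_voxel = tuple(pool[rng.integers(len(pool))])
        infarct = grow_lesion(grid, seed_voxel, size, rng)
        halo_candidates = binary_dilation(infarct, _ball26()) & ~infarct & hemi
        halo = halo_candidates & (rng.random(grid.shape) < cfg.hypoperfusion_halo_p)
        dys = infarct | halo
        ttp = np.full(grid.shape, cfg.ttp_base_s)
        ttp[dys] += cfg.ttp_delay_s
        infarcts[i] = infarct
        dysfunction[i] = dys
        ttp_maps.append(ttp)

    lesion_volumes = dysfunction.reshape(n, -1).sum(axis=1)
    # lesion size on a 0-1 scale for the confound term
    u = (lesion_volumes - lo) / max(hi - lo, 1)

    coverages: dict[str, np.ndarray] = {}
    deficits: dict[str, np.ndarray] = {}
    for name, model in cfg.deficit_models.items():
        region = regions[name]
        reg_size = region.sum()
        cov = dysfunction.reshape(n, -1)[:, region.reshape(-1)].sum(axis=1) / reg_size
        base = cov > model.coverage_threshold
        flipped = base ^ (rng.random(n) < model.noise_rate)
        confound_p = model.size_confound_gamma * expit(6.0 * (u - 0.5))
        deficit = flipped | (rng.random(n) < confound_p)
        coverages[name] = cov
        deficits[name] = deficit

    aos = deficits.get("aos", np.zeros(n, dtype=bool))
    span_imp = deficits.get("span", np.zeros(n, dtype=bool))

    records = []
    for i, pid in enumerate(patient_ids):
        n_abnormal = int(rng.integers(3, 5)) if aos[i] else int(rng.integers(0, 2))
        flags = np.zeros(4, dtype=int)
        flags[rng.choice(4, size=n_abnormal, replace=False)] = 1
        target_span = int(rng.integers(2, 5)) if span_imp[i] else int(rng.integers(5, 9))
        trials = _make_span_trials(target_span, rng)
        any_deficit = bool(aos[i] or span_imp[i])
        aq = float(
            np.clip(100 - 22 * u[i] - 12 * any_deficit + rng.normal(0, 5), 10, 100)
        )
        records.append(BehaviorRecord(pid, tuple(flags), trials, round(aq, 1)))

    cohort = CohortImages(grid, patient_ids, infarcts, ttp_maps)
    truth = SyntheticTruth(cfg, regions, dysfunction, coverages, deficits, lesion_volumes)
    return cohort, records, truth


def simulate_null_masks(
    grid: VolumeGrid,
    n_patients: int,
    lesion_size_range: tuple[int, int],
    rng: np.random.Generator,
) -> DysfunctionMasks:
    """Lesion masks only, for null simulations where scores are independent."""
    hemi_idx = np.argwhere(grid.analysis_side())
    lo, hi = lesion_size_range
    masks = np.zeros((n_patients, *grid.shape), dtype=bool)
    for i in range(n_patients):
        size = _sample_lesion_size(lo, hi, rng)
        seed_voxel = tuple(hemi_idx[rng.integers(len(hemi_idx))])
        masks[i] = grow_lesion(grid, seed_voxel, size, rng)
    vols = masks.reshape(n_patients, -1).sum(axis=1)
    ids = [f"N{i + 1:03d}" for i in range(n_patients)]
    return DysfunctionMasks(grid, ids, masks, vols)


def write_cohort(
    out_dir,
    cohort: CohortImages,
    records: list[BehaviorRecord],
    truth: Optional[SyntheticTruth] = None,
) -> str:
    """Write the manifest/NIfTI/TSV layout the reader consumes.

    Returns the manifest path. Truth volumes and a truth JSON are written
    alongside when provided.
    """
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for i, pid in enumerate(cohort.patient_ids):
        mask_path = os.path.join(out_dir, f"{pid}_infarct.nii.gz")
        save_volume(cohort.infarct_masks[i], cohort.grid, mask_path)
        ttp_path = ""
        if cohort.ttp_maps[i] is not None:
            ttp_path = os.path.join(out_dir, f"{pid}_ttp.nii.gz")
            save_volume(cohort.ttp_maps[i], cohort.grid, ttp_path)
        rows.append((pid, os.path.basename(mask_path),
                     os.path.basename(ttp_path) if ttp_path else ""))
    manifest_path = os.path.join(out_dir, "manifest.tsv")
    with open(manifest_path, "w") as fh:
        fh.write("patient_id\tinfarct_path\tttp_path\n")
        for pid, m, t in rows:
            fh.write(f"{pid}\t{m}\t{t}\n")
    write_behavior_table(records, os.path.join(out_dir, "behavior.tsv"))

    if truth is not None:
        for name, reg in truth.regions.items():
            save_volume(reg, cohort.grid, os.path.join(out_dir, f"truth_region_{name}.nii.gz"))
        for i, pid in enumerate(cohort.patient_ids):
            save_volume(
                truth.true_dysfunction[i], cohort.grid,
                os.path.join(out_dir, f"{pid}_truth_dysfunction.nii.gz"),
            )
        meta = {
            "seed": truth.config.seed,
            "n_patients": truth.config.n_patients,
            "grid_shape": list(truth.config.grid_shape),
            "lesion_volumes": truth.lesion_volumes.tolist(),
            "deficits": {k: v.astype(int).tolist() for k, v in truth.deficits.items()},
            "coverages": {k: np.round(v, 6).tolist() for k, v in truth.coverages.items()},
        }
        with open(os.path.join(out_dir, "truth.json"), "w") as fh:
            json.dump(meta, fh, indent=2)
    return manifest_path
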