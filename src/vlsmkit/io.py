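"""NIfTI and table I/O; assembly of in-memory cohort objects.

Cohorts are described by a tab-separated manifest with columns
``patient_id``, ``infarct_path``, and (optionally) ``ttp_path``; each path
points to a NIfTI-1 volume on the shared template grid. The behavior table
is a separate TSV (see :mod:`vlsmkit.behavior`).

Statistic maps are written with out-of-analysis voxels encoded as 0 and the
validity mask saved as a companion ``*_valid`` volume, so downstream viewers
never have to handle NaN.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Optional, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .behavior import BehaviorRecord, read_behavior_table
from .grid import VolumeGrid


@dataclass
class CohortImages:
    """Stacked, co-registered per-patient volumes on one grid.

    ``infarct_masks`` has shape ``(n_patients, *grid.shape)`` and is boolean;
    ``ttp_maps`` is a list of float volumes in seconds, ``None`` for
    patients without perfusion data.
    """

    grid: VolumeGrid
    patient_ids: list[str]
    infarct_masks: np.ndarray
    ttp_maps: list[Optional[np.ndarray]]

    def __post_init__(self) -> None:
        if len(set(self.patient_ids)) != len(self.patient_ids):
            dupes = {p for p in self.patient_ids if self.patient_ids.count(p) > 1}
            raise ValueError(f"duplicate patient ids: {sorted(dupes)}")
        n = len(self.patient_ids)
        if self.infarct_masks.shape != (n, *self.grid.shape):
            raise ValueError("infarct_masks shape does not match (n_patients, *grid.shape)")
        if len(self.ttp_maps) != n:
            raise ValueError("ttp_maps must have one entry per patient (None allowed)")

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)


def _grid_from_img(img: nib.Nifti1Image) -> VolumeGrid:
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return VolumeGrid(
        shape=tuple(int(s) for s in img.shape[:3]),
        voxel_size=zooms,
        affine=np.asarray(img.affine, dtype=float),
    )


def load_volume(path, grid: Optional[VolumeGrid] = None) -> tuple[np.ndarray, VolumeGrid]:
    """Load a 3D NIfTI volume; check conformance against ``grid`` if given."""
    img = nib.load(os.fspath(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {data.shape}")
    file_grid = _grid_from_img(img)
    if grid is not None:
        if tuple(data.shape) != grid.shape or not np.allclose(file_grid.affine, grid.affine):
            raise ValueError(
                f"{path}: grid mismatch (shape {data.shape} / affine differ from cohort grid)"
            )
        file_grid = grid
    return np.asarray(data), file_grid


def load_binary_mask(path, grid: Optional[VolumeGrid] = None) -> tuple[np.ndarray, VolumeGrid]:
    """Load a volume that must contain only {0, 1}."""
    data, g = load_volume(path, grid)
    vals = np.unique(data)
    if not np.all(np.isin(vals, (0, 1))):
        bad = [v for v in vals if v not in (0, 1)][:5]
        raise ValueError(f"{path}: non-binary mask values {bad}")
    return data.astype(bool), g


def save_volume(data: np.ndarray, grid: VolumeGrid, path, dtype=None) -> None:
    grid.check_conforms(data)
    arr = np.asarray(data)
    if dtype is None:
        dtype = np.uint8 if arr.dtype == bool else (np.int32 if np.issubdtype(arr.dtype, np.integer) else np.float64)
    img = nib.Nifti1Image(arr.astype(dtype), grid.affine)
    img.header.set_zooms(grid.voxel_size)
    nib.save(img, os.fspath(path))


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str})
    required = {"patient_id", "infarct_path"}
    if missing := required - set(df.columns):
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    if "ttp_path" not in df.columns:
        df["ttp_path"] = None
    base = os.path.dirname(os.fspath(path))

    def _resolve(p):
        if p is None or (isinstance(p, float) and np.isnan(p)) or p == "":
            return None
        return p if os.path.isabs(p) else os.path.join(base, p)

    df["infarct_path"] = df["infarct_path"].map(_resolve)
    df["ttp_path"] = df["ttp_path"].map(_resolve)
    return df


def read_cohort(
    mask_paths: Sequence,
    ttp_paths: Optional[Sequence] = None,
    behavior_path=None,
    patient_ids: Optional[Sequence[str]] = None,
    midline_axis: int = 0,
) -> tuple[CohortImages, list[BehaviorRecord]]:
    """Assemble a cohort from per-patient volume files and a behavior table.

    ``mask_paths`` and ``ttp_paths`` are parallel lists (``None`` entries in
    ``ttp_paths`` mark patients without perfusion data). Patient ids default
    to mask-file basenames. The behavior table must contain exactly the
    imaged patients; the returned records are reordered to match
    ``patient_ids`` so every downstream per-patient vector aligns.
    """
    if patient_ids is None:
        patient_ids = [os.path.splitext(os.path.basename(os.fspath(p)))[0].removesuffix(".nii") for p in mask_paths]
    patient_ids = [str(p) for p in patient_ids]
    if ttp_paths is None:
        ttp_paths = [None] * len(mask_paths)
    if len(ttp_paths) != len(mask_paths):
        raise ValueError("ttp_paths must parallel mask_paths")

    grid: Optional[VolumeGrid] = None
    masks = []
    for p in mask_paths:
        m, g = load_binary_mask(p, grid)
        if grid is None:
            grid = VolumeGrid(g.shape, g.voxel_size, midline_axis, g.affine)
        masks.append(m)
    if grid is None:
        raise ValueError("no mask paths given")

    ttp_maps: list[Optional[np.ndarray]] = []
    for p in ttp_paths:
        if p is None:
            ttp_maps.append(None)
        else:
            t, _ = load_volume(p, grid)
            ttp_maps.append(t.astype(float))

    cohort = CohortImages(grid, list(patient_ids), np.stack(masks), ttp_maps)

    records: list[BehaviorRecord] = []
    if behavior_path is not None:
        records = read_behavior_table(behavior_path)
        by_id = {r.patient_id: r for r in records}
        imaged = set(patient_ids)
        tabled = set(by_id)
        if imaged != tabled:
            only_img = sorted(imaged - tabled)
            only_tab = sorted(tabled - imaged)
            raise ValueError(
                "behavior table and images disagree on patients: "
                f"imaged-only {only_img}, table-only {only_tab}"
            )
        records = [by_id[p] for p in patient_ids]
    return cohort, records


def read_cohort_from_manifest(
    manifest_path, behavior_path=None, midline_axis: int = 0
) -> tuple[CohortImages, list[BehaviorRecord]]:
    mf = read_manifest(manifest_path)
    return read_cohort(
        mf["infarct_path"].tolist(),
        mf["ttp_path"].tolist(),
        behavior_path,
        patient_ids=mf["patient_id"].tolist(),
        midline_axis=midline_axis,
    )


def write_stat_map(stat_map, path) -> None:
    """Write a :class:`~vlsmkit.vlsm.StatMap` to NIfTI files.

    ``path`` is a stem or ``.nii.gz`` path; the t map goes to
    ``<stem>_t.nii.gz``, the p map to ``<stem>_p.nii.gz`` and the validity
    mask to ``<stem>_valid.nii.gz``. Invalid voxels are written as 0.
    """
    stem = os.fspath(path)
    for suffix in (".nii.gz", ".nii"):
        stem = stem.removesuffix(suffix)
    grid = stat_map.grid
    t = np.where(stat_map.valid, np.nan_to_num(stat_map.t_values, posinf=0, neginf=0), 0.0)
    # keep infinite t (degenerate zero-variance voxels) as a large finite value
    finite_inf = np.isinf(stat_map.t_values) & stat_map.valid
    t[finite_inf] = np.sign(stat_map.t_values[finite_inf]) * np.finfo(np.float64).max
    p = np.where(stat_map.valid, stat_map.p_values, 0.0)
    save_volume(t, grid, stem + "_t.nii.gz", dtype=np.float64)
    save_volume(p, grid, stem + "_p.nii.gz", dtype=np.float64)
    save_volume(stat_map.valid.astype(np.uint8), grid, stem + "_valid.nii.gz")
    save_volume(stat_map.n_lesioned.astype(np.int32), grid, stem + "_nles.nii.gz")


def read_stat_map(path, midline_axis: int = 0):
    """Re-read a statistic map written by :func:`write_stat_map`."""
    from .vlsm import StatMap  # local import: vlsm depends on io helpers

    stem = os.fspath(path)
    for suffix in (".nii.gz", ".nii"):
        stem = stem.removesuffix(suffix)
    t, g = load_volume(stem + "_t.nii.gz")
    p, _ = load_volume(stem + "_p.nii.gz")
    valid, _ = load_binary_mask(stem + "_valid.nii.gz")
    nles, _ = load_volume(stem + "_nles.nii.gz")
    grid = VolumeGrid(g.shape, g.voxel_size, midline_axis, g.affine)
    return StatMap(grid=grid, t_values=t, p_values=p, valid=valid,
                   n_lesioned=nles.astype(np.int32))
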