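"""Tissue-dysfunction masks from infarct and perfusion asymmetry.

In acute stroke, behaviorally relevant tissue extends beyond the dense
infarct core: hypoperfused but not (yet) infarcted tissue is dysfunctional.
Hypoperfusion is read off the time-to-peak (TTP) map of dynamic-contrast
perfusion imaging by comparing each left-hemisphere voxel with its
homologous voxel in the right hemisphere: a TTP delay of more than 4 s
relative to the homolog marks dysfunction. The per-patient "functional
lesion" entering the lesion-symptom analysis is the union of the infarct
mask and the hypoperfusion mask, and its voxel count is the functional
lesion size used as a covariate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .grid import VolumeGrid
from .io import CohortImages

logger = logging.getLogger(__name__)

#: Interhemispheric TTP delay (seconds) above which tissue counts as
#: hypoperfused; strict inequality.
DEFAULT_TTP_THRESHOLD_S = 4.0


@dataclass
class DysfunctionMasks:
    """Per-patient binary dysfunction masks and their voxel counts."""

    grid: VolumeGrid
    patient_ids: list[str]
    masks: np.ndarray  # (n_patients, *grid.shape), bool
    lesion_volumes: np.ndarray  # (n_patients,), int voxel counts
    ttp_threshold_s: float = DEFAULT_TTP_THRESHOLD_S

    def __post_init__(self) -> None:
        if self.ttp_threshold_s <= 0:
            raise ValueError("ttp_threshold_s must be positive")
        n = len(self.patient_ids)
        if self.masks.shape != (n, *self.grid.shape):
            raise ValueError("masks shape does not match (n_patients, *grid.shape)")
        counts = self.masks.reshape(n, -1).sum(axis=1)
        if not np.array_equal(counts, self.lesion_volumes):
            raise ValueError("lesion_volumes must equal mask voxel counts exactly")

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)


def hypoperfusion_mask(
    ttp: np.ndarray,
    grid: VolumeGrid,
    threshold_s: float = DEFAULT_TTP_THRESHOLD_S,
    brain_mask: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Mark analysis-side voxels whose TTP exceeds the homolog's by > threshold.

    A voxel ``v`` on the analysis (left) side is set iff
    ``ttp[v] - ttp[mirror(v)] > threshold_s`` and both ``v`` and its homolog
    lie inside ``brain_mask``. Right-side voxels are always 0: dysfunction is
    defined against the right-hemisphere homolog, not bidirectionally.
    ``brain_mask`` defaults to the whole grid.
    """
    grid.check_conforms(ttp, "ttp")
    ttp = np.asarray(ttp, dtype=float)
    if brain_mask is None:
        brain_mask = np.ones(grid.shape, dtype=bool)
    else:
        grid.check_conforms(brain_mask, "brain_mask")
        brain_mask = np.asarray(brain_mask, dtype=bool)
    if not np.all(np.isfinite(ttp[brain_mask])):
        raise ValueError("non-finite TTP values inside brain mask")
    delay = ttp - grid.mirror(ttp)
    valid_both = brain_mask & grid.mirror(brain_mask)
    return (delay > threshold_s) & valid_both & grid.analysis_side()


def dysfunction_mask(infarct: np.ndarray, hypoperf: np.ndarray) -> np.ndarray:
    """Voxelwise union of infarct and hypoperfusion (the functional lesion)."""
    infarct = np.asarray(infarct, dtype=bool)
    hypoperf = np.asarray(hypoperf, dtype=bool)
    if infarct.shape != hypoperf.shape:
        raise ValueError(
            f"grid mismatch: infarct {infarct.shape} vs hypoperfusion {hypoperf.shape}"
        )
    return infarct | hypoperf


def build_dysfunction_masks(
    cohort: CohortImages,
    ttp_threshold_s: float = DEFAULT_TTP_THRESHOLD_S,
    brain_mask: Optional[np.ndarray] = None,
) -> DysfunctionMasks:
    """Build every patient's dysfunction mask from infarct + TTP data.

    Patients without a TTP map contribute infarct-only masks (logged as a
    warning): the cohort stays intact when perfusion imaging failed.
    """
    masks = np.zeros_like(cohort.infarct_masks, dtype=bool)
    for i, pid in enumerate(cohort.patient_ids):
        infarct = cohort.infarct_masks[i]
        ttp = cohort.ttp_maps[i]
        if ttp is None:
            logger.warning("patient %s has no TTP map; using infarct-only dysfunction", pid)
            masks[i] = infarct
        else:
            hypo = hypoperfusion_mask(ttp, cohort.grid, ttp_threshold_s, brain_mask)
            masks[i] = dysfunction_mask(infarct, hypo)
    volumes = masks.reshape(cohort.n_patients, -1).sum(axis=1)
    return DysfunctionMasks(
        cohort.grid, list(cohort.patient_ids), masks, volumes, ttp_threshold_s
    )


def coverage_map(masks: DysfunctionMasks) -> np.ndarray:
    """Per-voxel count of patients whose dysfunction mask covers the voxel."""
    if masks.n_patients < 1:
        raise ValueError("coverage map needs at least one patient")
    return masks.masks.sum(axis=0).astype(np.int32)
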