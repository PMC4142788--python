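"""Overlap analysis of two corrected lesion-symptom maps.

Given the significant-voxel masks of two phenotypes, report the shared
territory, the voxels unique to each, and the Dice coefficient
``2|A∩B| / (|A| + |B|)``. An optional user-supplied label volume breaks a
mask down into named regions; no atlas is bundled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class OverlapSummary:
    n_voxels_map1: int
    n_voxels_map2: int
    n_overlap: int
    dice: float
    overlap_mask: np.ndarray
    unique1_mask: np.ndarray
    unique2_mask: np.ndarray


def compare_maps(sig1: np.ndarray, sig2: np.ndarray) -> OverlapSummary:
    """Exact set arithmetic on two significant-voxel masks.

    Dice of two empty masks is defined as 0 (with a warning) to avoid 0/0.
    """
    sig1 = np.asarray(sig1, dtype=bool)
    sig2 = np.asarray(sig2, dtype=bool)
    if sig1.shape != sig2.shape:
        raise ValueError(f"grid mismatch: {sig1.shape} vs {sig2.shape}")
    overlap = sig1 & sig2
    n1, n2, nov = int(sig1.sum()), int(sig2.sum()), int(overlap.sum())
    if n1 + n2 == 0:
        logger.warning("both maps empty; Dice defined as 0")
        dice = 0.0
    else:
        dice = 2.0 * nov / (n1 + n2)
    return OverlapSummary(n1, n2, nov, dice, overlap, sig1 & ~sig2, sig2 & ~sig1)


def label_regions(
    mask: np.ndarray,
    label_volume: np.ndarray,
    label_names: Optional[Mapping[int, str]] = None,
) -> pd.DataFrame:
    """Per-region voxel counts of a binary mask under a label volume.

    Returns a table with columns ``region`` and ``n_voxels``; regions with
    zero count are omitted, and labels absent from ``label_names`` are
    reported as ``unknown_<k>``. Label 0 is background and never counted.
    """
    mask = np.asarray(mask, dtype=bool)
    label_volume = np.asarray(label_volume)
    if mask.shape != label_volume.shape:
        raise ValueError(f"grid mismatch: {mask.shape} vs {label_volume.shape}")
    label_names = dict(label_names or {})
    labs, counts = np.unique(label_volume[mask], return_counts=True)
    rows = []
    for lab, cnt in zip(labs, counts):
        lab = int(lab)
        if lab == 0:
            continue
        rows.append({"region": label_names.get(lab, f"unknown_{lab}"), "n_voxels": int(cnt)})
    return pd.DataFrame(rows, columns=["region", "n_voxels"])
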