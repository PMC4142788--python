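"""Shared voxel grid with a midline mirror symmetry.

Every volume in a cohort lives on one :class:`VolumeGrid`. The grid carries
the axis across which left/right homology is defined: the homolog of a voxel
is its mirror image across the midplane of that axis. The grid must have an
even number of voxels along the midline axis so that every voxel has a
unique homolog on the opposite side (no voxel sits on the midplane).

Convention: voxel indices are 0-based; the *analysis* hemisphere (the
"left" hemisphere of the template) is the lower-index half of the midline
axis. World coordinates exist only through the affine, for display.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class VolumeGrid:
    """Geometry shared by all volumes of a cohort.

    Parameters
    ----------
    shape
        Voxels per axis, strictly positive.
    voxel_size
        Voxel edge lengths in mm.
    midline_axis
        Axis index across which left/right homology is defined.
    affine
        4x4 voxel-to-world transform.
    """

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    midline_axis: int = 0
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        object.__setattr__(self, "shape", shape)
        if len(shape) != 3 or any(s <= 0 for s in shape):
            raise ValueError(f"shape must be a positive integer triple, got {shape}")
        if not 0 <= self.midline_axis <= 2:
            raise ValueError("midline_axis must be 0, 1, or 2")
        if shape[self.midline_axis] % 2 != 0:
            raise ValueError(
                "grid must be even along the midline axis so every voxel has a "
                f"unique homolog; axis {self.midline_axis} has size "
                f"{shape[self.midline_axis]}"
            )
        if self.affine is None:
            aff = np.diag(list(self.voxel_size) + [1.0])
            object.__setattr__(self, "affine", aff)
        else:
            aff = np.asarray(self.affine, dtype=float)
            if aff.shape != (4, 4):
                raise ValueError("affine must be 4x4")
            object.__setattr__(self, "affine", aff)

    # frozen dataclass with an ndarray member: compare by content
    def __eq__(self, other: object) -> bool:
        if not isinstance(other, VolumeGrid):
            return NotImplemented
        return (
            self.shape == other.shape
            and self.midline_axis == other.midline_axis
            and np.allclose(self.voxel_size, other.voxel_size)
            and np.allclose(self.affine, other.affine)
        )

    def __hash__(self) -> int:
        return hash((self.shape, self.midline_axis))

    def check_conforms(self, vol: np.ndarray, name: str = "volume") -> None:
        """Raise ``ValueError`` if ``vol`` is not a 3D array on this grid."""
        if np.asarray(vol).shape != self.shape:
            raise ValueError(
                f"{name} shape {np.asarray(vol).shape} does not match grid {self.shape}"
            )

    def mirror(self, vol: np.ndarray) -> np.ndarray:
        """Reflect a conforming volume across the midline plane."""
        self.check_conforms(vol)
        return np.flip(vol, axis=self.midline_axis)

    def mirror_index(self, idx: tuple[int, int, int]) -> tuple[int, int, int]:
        """Homologous voxel index of ``idx`` (reflection across the midplane)."""
        out = list(idx)
        out[self.midline_axis] = self.shape[self.midline_axis] - 1 - idx[self.midline_axis]
        return tuple(out)

    def analysis_side(self) -> np.ndarray:
        """Boolean volume marking the analysis ("left") hemisphere.

        The analysis side is the lower-index half of the midline axis.
        """
        mask = np.zeros(self.shape, dtype=bool)
        half = self.shape[self.midline_axis] // 2
        sl = [slice(None)] * 3
        sl[self.midline_axis] = slice(0, half)
        mask[tuple(sl)] = True
        return mask

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))
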