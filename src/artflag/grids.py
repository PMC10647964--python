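"""Voxel-lattice containers for dose distributions and anatomical structures.

A :class:`DoseGrid` holds a 3-D scalar dose field (Gy) on a regular lattice;
a :class:`StructureMask` is a boolean region of interest (ROI) on a congruent
lattice, carrying its label and its organ architecture class.  These two types
are the substrate for every DVH metric in :mod:`artflag.dvh`: the upstream
steps that produce them on a common planning grid (daily image registration,
dose recomputation, contour propagation, dose warping) are outside this
package's scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

ORGAN_CLASSES = ("target", "serial", "parallel")


@dataclass(frozen=True)
class DoseGrid:
    """A 3-D dose field on a regular voxel lattice.

    Parameters
    ----------
    values:
        Dose per voxel in Gy; finite and non-negative.
    spacing:
        Voxel edge lengths in mm per axis, strictly positive.
    origin:
        Physical position of the first voxel centre in mm.
    """

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 3:
            raise ValueError(f"dose grid must be 3-D, got ndim={values.ndim}")
        if not np.all(np.isfinite(values)):
            raise ValueError("dose grid contains non-finite values")
        if np.any(values < 0):
            raise ValueError("dose grid contains negative dose")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be 3 strictly positive lengths, got {self.spacing}")
        origin = tuple(float(o) for o in self.origin)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def congruent_with(self, other: "DoseGrid | StructureMask") -> bool:
        """True when ``other`` lives on the same lattice (shape and geometry)."""
        if self.shape != other.shape:
            return False
        if isinstance(other, DoseGrid):
            return np.allclose(self.spacing, other.spacing) and np.allclose(
                self.origin, other.origin
            )
        return True


@dataclass(frozen=True)
class StructureMask:
    """A boolean ROI on a lattice congruent with an associated :class:`DoseGrid`.

    ``organ_class`` encodes the architecture relevant to flagging rules:
    ``target`` (PTV/CTV coverage), ``serial`` (near-maximum dose limits, e.g.
    spinal cord) or ``parallel`` (mean-dose limits, e.g. parotid glands).
    """

    voxels: np.ndarray
    label: str = "ROI"
    organ_class: str | None = None

    def __post_init__(self) -> None:
        voxels = np.asarray(self.voxels, dtype=bool)
        if voxels.ndim != 3:
            raise ValueError(f"structure mask must be 3-D, got ndim={voxels.ndim}")
        if self.organ_class is not None and self.organ_class not in ORGAN_CLASSES:
            raise ValueError(
                f"organ_class must be one of {ORGAN_CLASSES}, got {self.organ_class!r}"
            )
        object.__setattr__(self, "voxels", voxels)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_count(self) -> int:
        return int(self.voxels.sum())


def masked_doses(grid: DoseGrid, mask: StructureMask) -> np.ndarray:
    """Dose values of the voxels inside ``mask``; validates the pairing."""
    if grid.shape != mask.shape:
        raise ValueError(
            f"shape mismatch between dose grid {grid.shape} and mask "
            f"{mask.label!r} {mask.shape}"
        )
    doses = grid.values[mask.voxels]
    if doses.size == 0:
        raise ValueError(f"structure {mask.label!r} is empty: no voxels to evaluate")
    return doses
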