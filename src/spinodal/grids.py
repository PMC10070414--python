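"""Periodic voxel grids and the core field/structure containers.

Everything downstream — the phase-field solver, the morphology toolbox, the
homogenizers and the surrogates — operates on fields living on a fully
periodic rectangular voxel grid.  The grid is dimensionless: ``spacing`` sets
the edge length of one voxel in model units, and the physical domain edge is
``shape * spacing``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = ["GridSpec", "PhaseField", "VoxelStructure", "ValidationError",
           "DEFAULT_SPACING"]

#: canonical voxel edge in model units: a 64-voxel reference cube spans 5.0
#: model-length units, which puts the late-stage mean pore radius near 4
#: voxels for the default physics parameters.
DEFAULT_SPACING = 5.0 / 64.0


class ValidationError(ValueError):
    """Raised when a spec or field violates its invariants."""


@dataclass(frozen=True)
class GridSpec:
    """A periodic 3D voxel grid.

    Parameters
    ----------
    shape : tuple of int
        Voxels per axis; each entry must be >= 8.
    spacing : float
        Edge length of a voxel in model units (> 0).
    periodic : bool
        Simulation grids are always periodic; kept explicit for clarity.
    """

    shape: tuple[int, int, int]
    spacing: float = DEFAULT_SPACING
    periodic: bool = True

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        object.__setattr__(self, "shape", shape)
        if len(shape) != 3:
            raise ValidationError(f"grid shape must have 3 entries, got {shape}")
        if any(s < 8 for s in shape):
            raise ValidationError(f"every grid axis needs >= 8 voxels, got {shape}")
        if not self.spacing > 0:
            raise ValidationError(f"spacing must be positive, got {self.spacing}")

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    @property
    def lengths(self) -> tuple[float, float, float]:
        """Physical edge lengths of the periodic box."""
        return tuple(s * self.spacing for s in self.shape)

    def coordinates(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Voxel-center coordinates, origin at the volume corner.

        Center of voxel ``i`` along an axis sits at ``(i + 0.5) * spacing``,
        so a wave with an integer number of periods over the box is sampled
        commensurately with the periodic wrap.
        """
        axes = [(np.arange(s) + 0.5) * self.spacing for s in self.shape]
        return tuple(np.meshgrid(*axes, indexing="ij"))


@dataclass
class PhaseField:
    """A scalar phase variable on a periodic grid.

    ``values`` holds the order parameter: the two pure phases sit at +1
    (solid precursor) and -1 (pore precursor).  ``time_index`` is the save
    index inside a trajectory (0 = initial condition).
    """

    values: np.ndarray
    grid: GridSpec
    time_index: int = 0

    #: soft bound; exceeding it signals solver divergence, not physics
    SOFT_BOUND: float = 1.5

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.grid.shape:
            raise ValidationError(
                f"field shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("phase field contains non-finite values")

    @property
    def diverged(self) -> bool:
        return bool(np.max(np.abs(self.values)) > self.SOFT_BOUND)

    def shifted(self, shift: tuple[int, int, int]) -> "PhaseField":
        """Circularly shifted copy (the periodic symmetry operation)."""
        return PhaseField(np.roll(self.values, shift, axis=(0, 1, 2)),
                          self.grid, self.time_index)


@dataclass
class VoxelStructure:
    """A binary porous structure: ``solid`` True where material is present."""

    solid: np.ndarray
    grid: GridSpec
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.solid = np.asarray(self.solid, dtype=bool)
        if self.solid.shape != self.grid.shape:
            raise ValidationError(
                f"structure shape {self.solid.shape} != grid shape {self.grid.shape}"
            )

    @property
    def pore(self) -> np.ndarray:
        return ~self.solid

    @property
    def porosity(self) -> float:
        return float(np.mean(~self.solid))

    @property
    def degenerate(self) -> bool:
        """True when one phase is empty (all solid or all pore)."""
        n = int(self.solid.sum())
        return n == 0 or n == self.solid.size

    def complement(self) -> "VoxelStructure":
        prov = dict(self.provenance)
        prov["complemented"] = True
        return VoxelStructure(~self.solid, self.grid, prov)

    def shifted(self, shift: tuple[int, int, int]) -> "VoxelStructure":
        return VoxelStructure(np.roll(self.solid, shift, axis=(0, 1, 2)),
                              self.grid, dict(self.provenance))
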