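"""Core containers: voxel grids, structures, phantoms, fractionation.

All spatial quantities are in millimetres, doses in Gy, LET in keV/µm.
Voxel grids are axis-aligned; voxel ``(i, j, k)`` has its centre at
``origin + (index + 0.5) * voxel_size``.  Arrays attached to a grid are
C-ordered with shape ``grid.shape``; flattened views use
``np.ravel`` / ``np.ravel_multi_index`` in C order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = [
    "Role",
    "VoxelGrid",
    "Structure",
    "Phantom",
    "FractionationScheme",
    "DoseGrid",
    "LETGrid",
    "DEFAULT_ALPHA_BETA",
]


class Role(str, Enum):
    """Clinical role of a structure.

    Targets come in three prescription tiers (high / intermediate /
    standard risk); OARs are split into late-responding nervous tissue
    (brainstem, chiasm, optic nerve, brachial plexus analogues) and
    everything else.  ``external`` is the water-equivalent body contour.
    """

    TARGET_HIGH = "target_high"
    TARGET_INTERMEDIATE = "target_intermediate"
    TARGET_STANDARD = "target_standard"
    OAR_NERVOUS = "oar_nervous"
    OAR_OTHER = "oar_other"
    EXTERNAL = "external"

    @property
    def is_target(self) -> bool:
        return self.value.startswith("target")

    @property
    def is_oar(self) -> bool:
        return self.value.startswith("oar")


#: Default linear-quadratic alpha/beta ratios (Gy).  Nervous tissue is
#: late-responding (low alpha/beta); tumours are early-responding.
DEFAULT_ALPHA_BETA = {
    Role.TARGET_HIGH: 10.0,
    Role.TARGET_INTERMEDIATE: 10.0,
    Role.TARGET_STANDARD: 10.0,
    Role.OAR_NERVOUS: 2.5,
    Role.OAR_OTHER: 2.5,
    Role.EXTERNAL: 2.5,
}


@dataclass(frozen=True)
class VoxelGrid:
    """Regular voxel grid.

    Parameters
    ----------
    shape
        Number of voxels along (x, y, z).  Components of 1 give
        degenerate 2-D / 1-D grids.
    voxel_size
        Voxel edge lengths in mm, all strictly positive.
    origin
        Position (mm) of the lower corner of voxel (0, 0, 0).
    """

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) < 1 for s in self.shape):
            raise ValueError(f"shape components must be >= 1, got {self.shape}")
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel_size must be > 0, got {self.voxel_size}")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "voxel_size", tuple(float(v) for v in self.voxel_size))
        object.__setattr__(self, "origin", tuple(float(v) for v in self.origin))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    @property
    def extent(self) -> np.ndarray:
        """Physical size of the grid along each axis (mm)."""
        return np.asarray(self.shape) * np.asarray(self.voxel_size)

    @property
    def center(self) -> np.ndarray:
        """Geometric centre of the grid (mm)."""
        return np.asarray(self.origin) + self.extent / 2.0

    def voxel_centers(self) -> np.ndarray:
        """(N, 3) array of voxel-centre coordinates in C order (mm)."""
        axes = [
            self.origin[a] + (np.arange(self.shape[a]) + 0.5) * self.voxel_size[a]
            for a in range(3)
        ]
        xx, yy, zz = np.meshgrid(*axes, indexing="ij")
        return np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.asarray(self.origin, dtype=float)
        return lo, lo + self.extent

    def new_array(self, fill: float = 0.0) -> np.ndarray:
        return np.full(self.shape, fill, dtype=float)


@dataclass
class Structure:
    """Named anatomical structure defined by a boolean voxel mask.

    Targets carry ``prescription_per_fraction`` (Gy); OARs carry
    ``desired_max_dose`` (Gy), the clinical maximum-dose goal against
    which the LET objective's dose threshold is expressed.
    """

    name: str
    role: Role
    mask: np.ndarray
    alpha_beta: float | None = None
    desired_max_dose: float | None = None
    prescription_per_fraction: float | None = None

    def __post_init__(self) -> None:
        self.role = Role(self.role)
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError(f"structure {self.name!r} has an empty mask")
        if self.alpha_beta is None:
            self.alpha_beta = DEFAULT_ALPHA_BETA[self.role]
        if self.alpha_beta <= 0:
            raise ValueError(f"alpha_beta must be > 0, got {self.alpha_beta}")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def flat_indices(self) -> np.ndarray:
        return np.flatnonzero(self.mask.ravel())


@dataclass
class Phantom:
    """Voxel grid plus labelled structures (homogeneous water medium)."""

    grid: VoxelGrid
    structures: list[Structure] = field(default_factory=list)
    isocenter: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.isocenter is None:
            self.isocenter = self.grid.center
        self.isocenter = np.asarray(self.isocenter, dtype=float)
        for s in self.structures:
            if tuple(s.mask.shape) != self.grid.shape:
                raise ValueError(
                    f"structure {s.name!r} mask shape {s.mask.shape} does not "
                    f"match grid shape {self.grid.shape}"
                )

    def structure(self, name: str) -> Structure:
        for s in self.structures:
            if s.name == name:
                return s
        raise KeyError(f"no structure named {name!r}")

    @property
    def targets(self) -> list[Structure]:
        return [s for s in self.structures if s.role.is_target]

    @property
    def oars(self) -> list[Structure]:
        return [s for s in self.structures if s.role.is_oar]

    def external(self) -> Structure:
        for s in self.structures:
            if s.role is Role.EXTERNAL:
                return s
        raise KeyError("phantom has no external contour")

    def target_mask(self) -> np.ndarray:
        """Union of all target masks."""
        m = np.zeros(self.grid.shape, dtype=bool)
        for s in self.targets:
            m |= s.mask
        if not m.any():
            raise ValueError("phantom has no target voxels")
        return m


#: Default per-fraction prescriptions (Gy) by target tier.
DEFAULT_DOSE_PER_FRACTION = {
    Role.TARGET_HIGH: 2.0,
    Role.TARGET_INTERMEDIATE: 1.8,
    Role.TARGET_STANDARD: 1.6,
}


@dataclass(frozen=True)
class FractionationScheme:
    """Uniform fractionation: 33 or 35 fractions by default.

    High / intermediate / standard risk targets receive 2.0 / 1.8 /
    1.6 Gy per fraction, giving course totals of 66/70, 59.4/63 and
    52.8/56 Gy for 33/35 fractions.
    """

    n_fractions: int = 33
    dose_per_fraction: tuple[tuple[Role, float], ...] = tuple(
        DEFAULT_DOSE_PER_FRACTION.items()
    )

    def __post_init__(self) -> None:
        if int(self.n_fractions) < 1:
            raise ValueError("n_fractions must be a positive integer")
        object.__setattr__(self, "n_fractions", int(self.n_fractions))

    def per_fraction(self, role: Role) -> float:
        for r, d in self.dose_per_fraction:
            if Role(r) is Role(role):
                return float(d)
        raise KeyError(f"no per-fraction dose for role {role}")

    def total_dose(self, role: Role) -> float:
        """Total course dose (Gy) for a target tier."""
        return self.n_fractions * self.per_fraction(role)


@dataclass
class DoseGrid:
    """Total physical dose (Gy) over a voxel grid."""

    values: np.ndarray
    grid: VoxelGrid
    fractionation: FractionationScheme | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if tuple(self.values.shape) != self.grid.shape:
            raise ValueError("dose values shape does not match grid shape")
        if np.any(self.values < 0):
            raise ValueError("dose values must be nonnegative")

    def per_fraction(self) -> np.ndarray:
        """Physical dose per fraction, D_p (Gy)."""
        if self.fractionation is None:
            raise ValueError("dose grid has no fractionation attached")
        return self.values / self.fractionation.n_fractions


@dataclass
class LETGrid:
    """Dose-averaged LET (keV/µm) over a voxel grid; 0 where dose is
    below the evaluation floor."""

    values: np.ndarray
    grid: VoxelGrid

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if tuple(self.values.shape) != self.grid.shape:
            raise ValueError("LET values shape does not match grid shape")
        if np.any(self.values < 0):
            raise ValueError("LET values must be nonnegative")
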