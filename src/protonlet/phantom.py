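"""Synthetic phantom construction.

Builds a water-equivalent voxel phantom with box/ellipsoid targets and
OARs placed relative to a reference beam axis: at the distal edge
(beyond the target's deepest voxel along the beam), in the entrance
region (shallower than the target), or laterally.  This reproduces the
geometric situation of a nasopharyngeal target abutting the brainstem /
optic chiasm at the distal edge of the fields, with the optic nerves in
the entry dose region.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import DEFAULT_ALPHA_BETA, Phantom, Role, Structure, VoxelGrid

__all__ = ["TargetSpec", "OARSpec", "PhantomConfig", "build_phantom"]


@dataclass(frozen=True)
class TargetSpec:
    name: str = "ctv_high"
    role: Role = Role.TARGET_HIGH
    center_mm: tuple[float, float, float] | None = None  # None -> grid centre
    size_mm: tuple[float, float, float] = (20.0, 20.0, 20.0)
    shape: str = "box"  # box | ellipsoid
    prescription_per_fraction: float = 2.0
    alpha_beta: float | None = None


@dataclass(frozen=True)
class OARSpec:
    name: str = "brainstem"
    role: Role = Role.OAR_NERVOUS
    placement: str = "distal_edge"  # distal_edge | entrance | lateral
    gap_mm: float = 2.0
    size_mm: tuple[float, float, float] = (12.0, 12.0, 12.0)
    shape: str = "box"
    desired_max_dose: float = 60.0
    alpha_beta: float | None = None


@dataclass(frozen=True)
class PhantomConfig:
    grid_shape: tuple[int, int, int] = (60, 60, 1)
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)
    targets: tuple[TargetSpec, ...] = (TargetSpec(),)
    oars: tuple[OARSpec, ...] = (OARSpec(),)
    reference_gantry_angle: float = 90.0
    allow_overlap: bool = False


def _axis_direction(gantry_angle: float) -> np.ndarray:
    g = math.radians(gantry_angle)
    return np.array([-math.sin(g), -math.cos(g), 0.0])


def _mask_for(
    grid: VoxelGrid, center: np.ndarray, size: np.ndarray, shape: str
) -> np.ndarray:
    pts = grid.voxel_centers()
    half = size / 2.0
    if shape == "box":
        inside = np.all(np.abs(pts - center) <= half + 1e-9, axis=1)
    elif shape == "ellipsoid":
        inside = np.sum(((pts - center) / half) ** 2, axis=1) <= 1.0 + 1e-9
    else:
        raise ValueError(f"unknown structure shape {shape!r}")
    return inside.reshape(grid.shape)


def _support_along(mask: np.ndarray, grid: VoxelGrid, d: np.ndarray) -> tuple[float, float]:
    """Min/max projection of a mask's voxel centres onto direction d."""
    pts = grid.voxel_centers()[mask.ravel()]
    proj = pts @ d
    return float(proj.min()), float(proj.max())


def build_phantom(config: PhantomConfig) -> Phantom:
    """Construct a phantom from a declarative config.

    OAR placement is computed relative to the axis of the reference
    beam: ``distal_edge`` places the OAR strictly deeper than every
    target voxel (separated by ``gap_mm``), ``entrance`` strictly
    shallower, ``lateral`` to the side.  Raises if structures overlap
    (unless ``allow_overlap``) or fall outside the grid.
    """
    grid = VoxelGrid(config.grid_shape, config.voxel_size)
    d = _axis_direction(config.reference_gantry_angle)
    e1 = np.array([-d[1], d[0], 0.0])  # in-plane perpendicular

    structures: list[Structure] = []
    target_union = np.zeros(grid.shape, dtype=bool)
    for t in config.targets:
        center = np.asarray(t.center_mm if t.center_mm is not None else grid.center)
        mask = _mask_for(grid, center, np.asarray(t.size_mm, float), t.shape)
        if not mask.any():
            raise ValueError(f"target {t.name!r} lies outside the grid")
        _check_inside(grid, center, np.asarray(t.size_mm, float), t.name)
        structures.append(
            Structure(
                name=t.name,
                role=t.role,
                mask=mask,
                alpha_beta=t.alpha_beta,
                prescription_per_fraction=t.prescription_per_fraction,
            )
        )
        target_union |= mask

    lo_t, hi_t = _support_along(target_union, grid, d)
    t_center = np.asarray(grid.voxel_centers()[target_union.ravel()].mean(axis=0))
    # Project target centre onto the beam axis frame.
    c_depth = float(t_center @ d)
    c_lat = float(t_center @ e1)

    for o in config.oars:
        size = np.asarray(o.size_mm, float)
        half_along = float(np.abs(size / 2.0) @ np.abs(d))
        half_lat = float(np.abs(size / 2.0) @ np.abs(e1))
        if o.placement == "distal_edge":
            # Deepest target voxel centre is at projection hi_t; put the
            # shallowest OAR voxel gap_mm beyond it.
            depth_c = hi_t + o.gap_mm + half_along
            center = depth_c * d + c_lat * e1
        elif o.placement == "entrance":
            depth_c = lo_t - o.gap_mm - half_along
            center = depth_c * d + c_lat * e1
        elif o.placement == "lateral":
            lat_lo, lat_hi = _support_along(target_union, grid, e1)
            center = c_depth * d + (lat_hi + o.gap_mm + half_lat) * e1
        else:
            raise ValueError(f"unknown OAR placement {o.placement!r}")
        center = np.asarray(center, float)
        center[2] = grid.center[2]
        _check_inside(grid, center, size, o.name)
        mask = _mask_for(grid, center, size, o.shape)
        if not mask.any():
            raise ValueError(f"OAR {o.name!r} lies outside the grid")
        if not config.allow_overlap and (mask & target_union).any():
            raise ValueError(
                f"OAR {o.name!r} overlaps a target; set allow_overlap to "
                "accept OAR-over-target precedence"
            )
        structures.append(
            Structure(
                name=o.name,
                role=o.role,
                mask=mask,
                alpha_beta=o.alpha_beta,
                desired_max_dose=o.desired_max_dose,
            )
        )

    external = Structure(
        name="external",
        role=Role.EXTERNAL,
        mask=np.ones(grid.shape, dtype=bool),
        alpha_beta=DEFAULT_ALPHA_BETA[Role.EXTERNAL],
    )
    structures.append(external)
    return Phantom(grid=grid, structures=structures)


def _check_inside(grid: VoxelGrid, center: np.ndarray, size: np.ndarray, name: str) -> None:
    lo, hi = grid.bounds()
    # Degenerate axes (single voxel slab) are exempt from the containment
    # check along that axis.
    for ax in range(3):
        if grid.shape[ax] == 1:
            continue
        if center[ax] - size[ax] / 2 < lo[ax] - 1e-6 or center[ax] + size[ax] / 2 > hi[ax] + 1e-6:
            raise ValueError(f"structure {name!r} extends outside the grid")
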