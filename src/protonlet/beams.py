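"""Beams, spots, arc discretisation and energy-layer placement.

Gantry angles are degrees in [0, 360) measured in the axial (x, y)
plane; gantry 0 places the source on the +y side of the isocenter, and
the angle increases toward +x (gantry 90 = source at +x, beam travelling
along -x).  Couch rotation is carried as a label only: a 180 degree
couch kick mirrors the gantry angle in the axial plane, which is how the
bilateral arc pair is emulated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import Phantom
from .physics import LateralModel, range_straggling_sigma

__all__ = [
    "Spot",
    "Beam",
    "make_arc_beams",
    "place_energy_layers",
    "make_spots",
    "make_pbs_beams",
]

MAX_ARC_BEAMS = 10_000


@dataclass(frozen=True)
class Spot:
    """A pencil-beam spot: water-equivalent range and lateral offset in
    the beam's-eye view (mm)."""

    range_R: float
    lateral_offset: tuple[float, float] = (0.0, 0.0)
    nominal_weight: float = 1.0

    def __post_init__(self) -> None:
        if self.range_R <= 0:
            raise ValueError(f"spot range must be > 0, got {self.range_R}")
        if self.nominal_weight < 0:
            raise ValueError("nominal_weight must be >= 0")


@dataclass
class Beam:
    gantry_angle: float
    couch_angle: float = 0.0
    spots: list[Spot] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.gantry_angle = float(self.gantry_angle) % 360.0
        self.couch_angle = float(self.couch_angle) % 360.0

    def direction(self) -> np.ndarray:
        """Unit vector of beam travel (source -> isocenter)."""
        g = math.radians(self.gantry_angle)
        return np.array([-math.sin(g), -math.cos(g), 0.0])

    def lateral_axes(self) -> tuple[np.ndarray, np.ndarray]:
        """In-plane and axial unit vectors spanning the beam's-eye view."""
        g = math.radians(self.gantry_angle)
        e1 = np.array([-math.cos(g), math.sin(g), 0.0])
        e2 = np.array([0.0, 0.0, 1.0])
        return e1, e2


def make_arc_beams(
    arc_span: float = 130.0,
    start: float = 30.0,
    step: float = 5.0,
    couch: float = 0.0,
    bilateral: bool = True,
) -> list[Beam]:
    """Discretised emulation of a dynamic proton arc.

    Beams are placed at ``start, start + step, ...`` covering ``arc_span``
    degrees (endpoints included).  In bilateral mode a mirrored arc with a
    180 degree couch kick is appended — the two-arc arrangement used for
    bilateral disease; unilateral mode keeps the single arc on the target
    side.
    """
    if step <= 0 or arc_span <= 0:
        raise ValueError("arc_span and step must be > 0")
    n = int(math.floor(arc_span / step + 1e-9)) + 1
    if n > MAX_ARC_BEAMS:
        raise ValueError(
            f"arc discretisation yields {n} beams (> {MAX_ARC_BEAMS}); "
            "runaway configuration"
        )
    angles = [start + i * step for i in range(n)]
    if angles[-1] < start + arc_span - 1e-9:
        angles.append(start + arc_span)
    beams = [Beam(gantry_angle=a, couch_angle=couch) for a in angles]
    if bilateral:
        beams += [
            Beam(gantry_angle=(-a) % 360.0, couch_angle=(couch + 180.0) % 360.0)
            for a in angles
        ]
    return beams


def place_energy_layers(
    z_min: float,
    z_max: float,
    layer_scale: float = 1.0,
    base_spacing: float | None = None,
    min_spacing: float = 0.5,
) -> np.ndarray:
    """Energy-layer ranges (mm) covering a depth extent.

    Layers are spaced ``max(layer_scale * base_spacing, min_spacing)``
    where ``base_spacing`` defaults to 80% of the straggling width at
    mid-range; smaller scales give denser layers (the arc plans use
    scale 0.25 versus 1 for static PBS).  ``min_spacing`` floors the
    spacing at a quarter of the default 2 mm grid resolution, below
    which extra layers are numerically redundant.

    Returns ranges ordered distal to proximal; a zero-depth extent
    yields a single layer.
    """
    if layer_scale <= 0:
        raise ValueError("layer_scale must be > 0")
    if z_max < z_min:
        z_min, z_max = z_max, z_min
    extent = z_max - z_min
    if extent <= 0:
        return np.array([float(z_max)])
    if base_spacing is None:
        base_spacing = 0.8 * range_straggling_sigma(0.5 * (z_min + z_max))
    spacing = max(layer_scale * base_spacing, min_spacing)
    n = int(math.ceil(extent / spacing)) + 1
    return np.linspace(z_max, z_min, n)


def _beam_frame_coords(
    phantom: Phantom, beam: Beam
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Depth from phantom entry surface and lateral offsets of every
    voxel centre, in the frame of ``beam`` (all mm, flat C order)."""
    d = beam.direction()
    e1, e2 = beam.lateral_axes()
    pts = phantom.grid.voxel_centers()
    iso = phantom.isocenter
    lo, hi = phantom.grid.bounds()

    # Central-axis sanity check: the ray through the isocenter must hit
    # the grid box at all.
    t0, t1 = -np.inf, np.inf
    for ax in range(3):
        if abs(d[ax]) < 1e-12:
            if not (lo[ax] <= iso[ax] <= hi[ax]):
                t0, t1 = 1.0, 0.0
                break
        else:
            ta = (lo[ax] - iso[ax]) / d[ax]
            tb = (hi[ax] - iso[ax]) / d[ax]
            t0 = max(t0, min(ta, tb))
            t1 = min(t1, max(ta, tb))
    if t0 > t1:
        raise ValueError(
            f"beam at gantry {beam.gantry_angle} deg misses the grid entirely"
        )

    # Distance from each voxel centre upstream (-d) to the box surface =
    # water-equivalent depth in a homogeneous water box.
    u = -d
    s_exit = np.full(pts.shape[0], np.inf)
    for ax in range(3):
        if u[ax] > 1e-12:
            s_exit = np.minimum(s_exit, (hi[ax] - pts[:, ax]) / u[ax])
        elif u[ax] < -1e-12:
            s_exit = np.minimum(s_exit, (lo[ax] - pts[:, ax]) / u[ax])
    depth = s_exit
    rel = pts - iso
    return depth, rel @ e1, rel @ e2


def make_spots(
    phantom: Phantom,
    beam: Beam,
    layer_scale: float = 1.0,
    spot_spacing: float | None = None,
    spot_scale: float = 0.7,
    lateral_margin: float | None = None,
    lateral_model: LateralModel | None = None,
    min_layer_spacing: float = 0.5,
) -> Beam:
    """Populate ``beam`` with spots covering the phantom's target union.

    Energy layers span the target's depth extent along the beam axis;
    lateral spot positions tile the target's beam's-eye-view footprint.
    ``spot_spacing`` fixes the lateral pitch in mm (the arc setting);
    otherwise the pitch is ``spot_scale`` times the lateral spread at
    mid-depth (the automatic PBS setting).  ``lateral_margin`` extends
    the footprint; it defaults to one pitch.
    """
    if lateral_model is None:
        lateral_model = LateralModel()
    depth, lat1, lat2 = _beam_frame_coords(phantom, beam)
    tmask = phantom.target_mask().ravel()
    z_min, z_max = float(depth[tmask].min()), float(depth[tmask].max())
    layers = place_energy_layers(
        z_min, z_max, layer_scale=layer_scale, min_spacing=min_layer_spacing
    )

    mid = 0.5 * (z_min + z_max)
    pitch = spot_spacing if spot_spacing is not None else spot_scale * float(
        lateral_model.sigma(mid)
    )
    if pitch <= 0:
        raise ValueError("spot pitch must be > 0")
    margin = lateral_margin if lateral_margin is not None else pitch

    def _positions(coords: np.ndarray) -> np.ndarray:
        lo, hi = float(coords.min()) - margin, float(coords.max()) + margin
        span = hi - lo
        if span <= pitch:
            return np.array([0.5 * (lo + hi)])
        n = int(math.floor(span / pitch)) + 1
        width = (n - 1) * pitch
        return lo + (span - width) / 2.0 + pitch * np.arange(n)

    pos1 = _positions(lat1[tmask])
    # Degenerate axial extent (2-D phantom): a single central spot row.
    if phantom.grid.shape[2] == 1:
        pos2 = np.array([0.0])
    else:
        pos2 = _positions(lat2[tmask])

    beam.spots = [
        Spot(range_R=float(R), lateral_offset=(float(a), float(b)))
        for R in layers
        for a in pos1
        for b in pos2
    ]
    return beam


def make_pbs_beams(
    phantom: Phantom,
    gantry_angles: list[float],
    layer_scale: float = 1.0,
    spot_spacing: float | None = None,
    spot_scale: float = 0.7,
    **kwargs,
) -> list[Beam]:
    """Static PBS beams with automatically placed spots."""
    return [
        make_spots(
            phantom,
            Beam(gantry_angle=a),
            layer_scale=layer_scale,
            spot_spacing=spot_spacing,
            spot_scale=spot_scale,
            **kwargs,
        )
        for a in gantry_angles
    ]
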