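"""Per-spot influence data: dose-per-unit-weight and LET over voxels.

For a homogeneous water phantom, each spot deposits

    d_i(v) = B(z_v; R_i) * exp(-rho_v^2 / (2 * sigma_lat(z_v)^2))

where ``B`` is the peak-normalised Bragg curve, ``z_v`` the voxel's
water-equivalent depth along the beam axis and ``rho_v`` its lateral
distance from the spot axis in the beam's-eye view.  The spot's
unrestricted LET at the voxel is the LET depth curve at the same depth.
Entries below ``cutoff`` times the spot's maximum dose are dropped from
both maps, which therefore share one sparsity pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .beams import Beam, _beam_frame_coords
from .core import Phantom, VoxelGrid
from .physics import (
    BRAGG_KLEEMAN_P,
    LateralModel,
    LETCurveParams,
    bragg_depth_dose,
    let_depth_curve,
)

__all__ = ["InfluenceData", "compute_influence"]


@dataclass
class InfluenceData:
    """Sparse per-spot dose and LET maps over a voxel grid.

    ``dose`` and ``let`` are (n_spots, n_voxels) CSR matrices with an
    identical sparsity pattern; dose entries are Gy per unit spot
    weight, LET entries keV/µm.
    """

    dose: sparse.csr_matrix
    let: sparse.csr_matrix
    grid: VoxelGrid
    cutoff: float
    beam_index: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        if self.dose.shape != self.let.shape:
            raise ValueError("dose and LET maps have mismatched shapes")
        if not np.array_equal(self.dose.indptr, self.let.indptr) or not np.array_equal(
            self.dose.indices, self.let.indices
        ):
            raise ValueError("dose and LET maps have mismatched sparsity patterns")
        if self.dose.nnz and (self.dose.data <= 0).any():
            raise ValueError("dose entries must be > 0")
        if self.let.nnz and (self.let.data <= 0).any():
            raise ValueError("LET entries must be > 0 wherever dose entries exist")

    @property
    def n_spots(self) -> int:
        return self.dose.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.dose.shape[1]

    def dose_csc(self) -> sparse.csc_matrix:
        """Column-sliceable view of the dose map (cached)."""
        if not hasattr(self, "_dose_csc"):
            self._dose_csc = self.dose.tocsc()
        return self._dose_csc

    def dose_let_product(self) -> sparse.csr_matrix:
        """Elementwise dose*LET map (cached), the LET_d numerator kernel."""
        if not hasattr(self, "_dose_let"):
            self._dose_let = self.dose.multiply(self.let).tocsr()
        return self._dose_let

    def spot_max_let(self, voxel_idx: np.ndarray | None = None) -> float:
        """Maximum spot LET entry, optionally restricted to voxels."""
        if voxel_idx is None:
            return float(self.let.data.max()) if self.let.nnz else 0.0
        sub = self.let.tocsc()[:, voxel_idx]
        return float(sub.data.max()) if sub.nnz else 0.0


def compute_influence(
    phantom: Phantom,
    beams: list[Beam],
    cutoff: float = 1e-3,
    lateral_model: LateralModel | None = None,
    let_params: LETCurveParams | None = None,
    p: float = BRAGG_KLEEMAN_P,
) -> InfluenceData:
    """Compute sparse influence data for all spots of all beams.

    Raises if a beam's central axis misses the grid, or if ``beams``
    carry no spots.
    """
    if lateral_model is None:
        lateral_model = LateralModel()
    if let_params is None:
        let_params = LETCurveParams()
    n_vox = phantom.grid.n_voxels

    rows_idx: list[np.ndarray] = []
    rows_dose: list[np.ndarray] = []
    rows_let: list[np.ndarray] = []
    beam_of_spot: list[int] = []

    for b_i, beam in enumerate(beams):
        if not beam.spots:
            raise ValueError(
                f"beam at gantry {beam.gantry_angle} deg has no spots"
            )
        depth, lat1, lat2 = _beam_frame_coords(phantom, beam)
        valid = depth >= 0
        sig = np.asarray(lateral_model.sigma(np.maximum(depth, 0.0)))
        for spot in beam.spots:
            dd = np.zeros(n_vox)
            dz = bragg_depth_dose(np.maximum(depth[valid], 0.0), spot.range_R, p=p)
            a, b = spot.lateral_offset
            rho2 = (lat1[valid] - a) ** 2 + (lat2[valid] - b) ** 2
            dd[valid] = dz * np.exp(-rho2 / (2.0 * sig[valid] ** 2))
            mx = dd.max()
            if mx <= 0:
                rows_idx.append(np.array([], dtype=int))
                rows_dose.append(np.array([]))
                rows_let.append(np.array([]))
                beam_of_spot.append(b_i)
                continue
            keep = np.flatnonzero(dd >= cutoff * mx) if cutoff > 0 else np.flatnonzero(dd > 0)
            lv = np.asarray(
                let_depth_curve(np.maximum(depth[keep], 0.0), spot.range_R, let_params)
            )
            # Entries with zero LET (beyond the distal falloff) carry no
            # dose either; guard against roundoff stragglers.
            pos = lv > 0
            rows_idx.append(keep[pos])
            rows_dose.append(dd[keep[pos]])
            rows_let.append(lv[pos])
            beam_of_spot.append(b_i)

    indptr = np.zeros(len(rows_idx) + 1, dtype=np.int64)
    indptr[1:] = np.cumsum([len(r) for r in rows_idx])
    indices = np.concatenate(rows_idx) if rows_idx else np.array([], dtype=int)
    dose = sparse.csr_matrix(
        (np.concatenate(rows_dose), indices, indptr), shape=(len(rows_idx), n_vox)
    )
    let = sparse.csr_matrix(
        (np.concatenate(rows_let), indices.copy(), indptr.copy()),
        shape=(len(rows_idx), n_vox),
    )
    return InfluenceData(
        dose=dose,
        let=let,
        grid=phantom.grid,
        cutoff=cutoff,
        beam_index=np.asarray(beam_of_spot, dtype=int),
    )
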