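"""Coarse-to-fine speckle tracking and angular displacement compounding.

Block-matching displacement estimation runs on each pairing's sector grid
(axial = along the receive beam).  A coarse pass on envelope data seeds a fine
pass on RF data; both use normalized cross-correlation with parabolic
sub-sample refinement, followed by median filtering.  Axial displacements are
then projected onto the vessel-radial direction, ``u_rad = u_ax / cos(theta)``,
masked by the view-angle weight ``M = cos(2 theta)/2 + 1/2`` (zero in the
70-110 degree cut-out where the projection blows up), and fused across the
four pairings as a per-node normalized convex combination in which the two
reciprocal trans-probe fields together count as one view.

Lateral displacement estimates are produced by the matcher for quality
control but are never used in compounding.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.ndimage import median_filter

from . import _kernels
from .geometry import RigidTransform2D, SectorGrid, TransducerGeometry

__all__ = [
    "DisplacementField",
    "AngularMask",
    "TrackingParams",
    "block_match",
    "parabolic_subsample",
    "median_filter_field",
    "coarse_to_fine_track",
    "compute_theta",
    "radial_project",
    "angular_mask",
    "compound_displacements",
    "CUTOUT_DEG",
]

#: view angles (deg) where radial projection is disabled
CUTOUT_DEG = (70.0, 110.0)


@dataclass
class DisplacementField:
    """Per-node frame-to-frame motion estimates on a sector grid."""

    u_ax: np.ndarray  # mm, along the receive beam
    u_lat: np.ndarray  # mm, across the beam (quality control only)
    quality: np.ndarray  # peak correlation per node
    valid: np.ndarray  # bool per node
    grid: SectorGrid
    pairing: tuple
    frame_pair: tuple = (0, 1)
    u_rad: np.ndarray | None = None  # mm, after radial projection
    theta: np.ndarray | None = None  # deg, beam-to-radial angle


@dataclass
class AngularMask:
    """Angle-dependent compounding weight per node."""

    M: np.ndarray  # raw weight in [0, 1], zero in the cut-out
    cutout: tuple = CUTOUT_DEG


@dataclass
class TrackingParams:
    """Kernel / search / filter sizes (mm, axial x lateral) of the two passes.

    Search sizes are the full extent of the region the kernel slides over, so
    the integer lag range per side is ``(search - kernel) / 2``.  Lateral
    sizes are converted to whole lines using the local (depth-dependent)
    line pitch, which reproduces fixed pixel counts across depth.
    """

    coarse_kernel: tuple = (2.6, 5.2)
    coarse_search: tuple = (3.0, 5.7)
    fine_kernel: tuple = (0.8, 2.4)
    fine_search: tuple = (1.0, 2.85)
    median_size: tuple = (11, 11)  # pixels, axial x lateral
    coarse_decimation: tuple = (8, 2)  # node stride of the coarse pass


def parabolic_subsample(c_minus: float, c_0: float, c_plus: float) -> float:
    """Sub-sample peak offset from three correlation samples around the argmax.

    ``(c- - c+) / (2 (c- - 2 c0 + c+))``, clamped to [-0.5, 0.5]; zero
    curvature yields 0.
    """
    if c_0 < max(c_minus, c_plus):
        raise ValueError("central sample must be the argmax")
    denom = c_minus - 2.0 * c_0 + c_plus
    if denom == 0.0:
        return 0.0
    return float(np.clip((c_minus - c_plus) / (2.0 * denom), -0.5, 0.5))


def _mm_sizes_to_halfwidths(grid: SectorGrid, node_ax, node_lat, kernel_mm):
    """Per-node integer half-widths for an (axial_mm, lateral_mm) size."""
    dz = grid.axial_spacing
    ka = max(1, int(round(kernel_mm[0] / dz / 2.0)))
    dgamma = np.deg2rad(grid.beam_angles[1] - grid.beam_angles[0]) if grid.beam_angles.size > 1 else 1.0
    depths = grid.sample_depths[node_ax]
    pitch_mm = (grid.radius_of_curvature + depths) * dgamma
    kl = np.maximum(1, np.round(kernel_mm[1] / pitch_mm / 2.0).astype(np.int64))
    return np.full(node_ax.shape, ka, dtype=np.int64), kl


def _lag_counts(grid: SectorGrid, kernel_mm, search_mm, depth_mid):
    dz = grid.axial_spacing
    lag_ax = max(1, int(round((search_mm[0] - kernel_mm[0]) / 2.0 / dz)))
    dgamma = np.deg2rad(grid.beam_angles[1] - grid.beam_angles[0]) if grid.beam_angles.size > 1 else 1.0
    pitch_mm = (grid.radius_of_curvature + depth_mid) * dgamma
    lag_lat = max(1, int(round((search_mm[1] - kernel_mm[1]) / 2.0 / pitch_mm)))
    return lag_ax, lag_lat


def block_match(
    ref: np.ndarray,
    mov: np.ndarray,
    grid: SectorGrid,
    kernel_mm: tuple,
    search_mm: tuple,
    mode: str = "envelope",
    node_ax: np.ndarray | None = None,
    node_lat: np.ndarray | None = None,
    seed_ax: np.ndarray | None = None,
    seed_lat: np.ndarray | None = None,
    pairing: tuple = (0, 0),
    frame_pair: tuple = (0, 1),
) -> DisplacementField:
    """One block-matching pass between two real-valued sector images.

    ``mode='envelope'`` uses zero-mean NCC, ``mode='rf'`` raw NCC.  ``node_*``
    select the tracked nodes (default: every grid node); ``seed_*`` give
    per-node integer-lag search centers.  Nodes whose kernel or search window
    leaves the grid are marked invalid; a zero-variance kernel yields zero
    displacement with quality 0.
    """
    if mode not in ("envelope", "rf"):
        raise ValueError("mode must be 'envelope' or 'rf'")
    ref = np.ascontiguousarray(ref, dtype=np.float64)
    mov = np.ascontiguousarray(mov, dtype=np.float64)
    n_axg, n_latg = ref.shape
    if node_ax is None:
        A, L = np.meshgrid(np.arange(n_axg), np.arange(n_latg), indexing="ij")
        node_ax, node_lat = A.ravel(), L.ravel()
    node_ax = np.ascontiguousarray(node_ax, dtype=np.int64)
    node_lat = np.ascontiguousarray(node_lat, dtype=np.int64)
    n_nodes = node_ax.size
    if seed_ax is None:
        seed_ax = np.zeros(n_nodes, dtype=np.int64)
    if seed_lat is None:
        seed_lat = np.zeros(n_nodes, dtype=np.int64)
    seed_ax = np.ascontiguousarray(np.round(seed_ax).astype(np.int64))
    seed_lat = np.ascontiguousarray(np.round(seed_lat).astype(np.int64))

    khalf_ax, khalf_lat = _mm_sizes_to_halfwidths(grid, node_ax, node_lat, kernel_mm)
    depth_mid = float(np.median(grid.sample_depths[node_ax])) if n_nodes else 0.0
    lag_ax, lag_lat = _lag_counts(grid, kernel_mm, search_mm, depth_mid)

    du_ax_s, du_lat_s, quality, valid = _kernels.ncc_block_match(
        ref, mov, node_ax, node_lat, khalf_ax, khalf_lat,
        lag_ax, lag_lat, seed_ax, seed_lat, mode == "envelope",
    )

    # convert sample lags to mm at each node
    dz = grid.axial_spacing
    dgamma = np.deg2rad(grid.beam_angles[1] - grid.beam_angles[0]) if grid.beam_angles.size > 1 else 1.0
    pitch_mm = (grid.radius_of_curvature + grid.sample_depths[node_ax]) * dgamma

    def to_grid(vals):
        out = np.full(ref.shape, np.nan)
        out[node_ax, node_lat] = vals
        return out

    return DisplacementField(
        u_ax=to_grid(du_ax_s * dz),
        u_lat=to_grid(du_lat_s * pitch_mm),
        quality=to_grid(quality),
        valid=to_grid(valid.astype(float)) == 1.0,
        grid=grid,
        pairing=pairing,
        frame_pair=frame_pair,
    )


def median_filter_field(field: DisplacementField, size: tuple = (11, 11)) -> DisplacementField:
    """Component-wise sliding-window median with reflected edges.

    NaN nodes (untracked) are excluded by nearest-fill before filtering and
    restored afterwards.
    """

    def filt(a):
        if a is None:
            return None
        nanmask = np.isnan(a)
        if nanmask.all():
            return a.copy()
        work = a.copy()
        if nanmask.any():
            # nearest-neighbour fill so the median window never sees NaN
            from scipy.ndimage import distance_transform_edt

            idx = distance_transform_edt(nanmask, return_distances=False, return_indices=True)
            work = work[tuple(idx)]
        out = median_filter(work, size=size, mode="reflect")
        out[nanmask] = np.nan
        return out

    return replace(
        field,
        u_ax=filt(field.u_ax),
        u_lat=filt(field.u_lat),
        u_rad=filt(field.u_rad),
    )


def coarse_to_fine_track(
    ref_iq: np.ndarray,
    mov_iq: np.ndarray,
    grid: SectorGrid,
    params: TrackingParams = TrackingParams(),
    node_mask: np.ndarray | None = None,
    pairing: tuple = (0, 0),
    frame_pair: tuple = (0, 1),
) -> DisplacementField:
    """Two-pass tracking: coarse on the envelope (decimated nodes, median
    filtered, interpolated to seeds) then fine on the RF, median filtered.

    ``node_mask`` (grid-shaped bool) restricts tracking to a region of
    interest; outside nodes are NaN/invalid in the result.
    """
    env_ref, env_mov = np.abs(ref_iq), np.abs(mov_iq)
    rf_ref, rf_mov = np.real(ref_iq), np.real(mov_iq)
    n_ax, n_lat = env_ref.shape
    if node_mask is None:
        node_mask = np.ones((n_ax, n_lat), dtype=bool)

    # coarse pass on a decimated node lattice
    da, dl = params.coarse_decimation
    A, L = np.meshgrid(np.arange(0, n_ax, da), np.arange(0, n_lat, dl), indexing="ij")
    sel = node_mask[A, L]
    coarse = block_match(
        env_ref, env_mov, grid, params.coarse_kernel, params.coarse_search,
        mode="envelope", node_ax=A[sel], node_lat=L[sel],
        pairing=pairing, frame_pair=frame_pair,
    )
    coarse = median_filter_field(
        coarse, size=(max(3, params.median_size[0] // da), max(3, params.median_size[1] // dl))
    )

    # interpolate the coarse field to integer-lag seeds at all tracked nodes
    Af, Lf = np.nonzero(node_mask)
    dz = grid.axial_spacing
    coarse_ax = coarse.u_ax[A, L]
    coarse_lat = coarse.u_lat[A, L]
    seed_ax = _interp_seed(A[:, 0], L[0, :], coarse_ax, Af, Lf) / dz
    pitch_mid = (grid.radius_of_curvature + np.median(grid.sample_depths)) * (
        np.deg2rad(grid.beam_angles[1] - grid.beam_angles[0]) if grid.beam_angles.size > 1 else 1.0
    )
    seed_lat = _interp_seed(A[:, 0], L[0, :], coarse_lat, Af, Lf) / pitch_mid

    fine = block_match(
        rf_ref, rf_mov, grid, params.fine_kernel, params.fine_search,
        mode="rf", node_ax=Af, node_lat=Lf,
        seed_ax=np.nan_to_num(seed_ax), seed_lat=np.nan_to_num(seed_lat),
        pairing=pairing, frame_pair=frame_pair,
    )
    return median_filter_field(fine, size=params.median_size)


def _interp_seed(ax_coords, lat_coords, values, q_ax, q_lat):
    """Bilinear interpolation of a decimated field at query node indices."""
    vals = np.nan_to_num(values, nan=0.0)
    if ax_coords.size < 2 or lat_coords.size < 2:
        return np.zeros(q_ax.shape)
    interp = RegularGridInterpolator(
        (ax_coords.astype(float), lat_coords.astype(float)),
        vals,
        bounds_error=False,
        fill_value=0.0,
    )
    return interp(np.stack([q_ax, q_lat], axis=1).astype(float))


def compute_theta(
    points: np.ndarray,
    vessel_center: np.ndarray,
    beam_directions: np.ndarray,
) -> np.ndarray:
    """Unsigned angle (deg, in [0, 180)) between the receive-beam direction
    and the outward radial direction from the vessel center, per point.

    Points at the center have no radial direction and return NaN (excluded).
    """
    p = np.asarray(points, dtype=float)
    b = np.asarray(beam_directions, dtype=float)
    rad = p - np.asarray(vessel_center, dtype=float)
    rn = np.linalg.norm(rad, axis=-1)
    bn = np.linalg.norm(b, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.sum(rad * b, axis=-1) / (rn * bn)
    theta = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    theta = np.where(rn == 0, np.nan, theta)
    return np.where(theta >= 180.0, theta - 180.0, theta)


def _in_cutout(theta, cutout=CUTOUT_DEG):
    return (theta >= cutout[0]) & (theta <= cutout[1])


def radial_project(u_ax: np.ndarray, theta: np.ndarray, cutout=CUTOUT_DEG) -> np.ndarray:
    """``u_rad = u_ax / cos(theta)``; NaN inside the cut-out (never evaluated)."""
    theta = np.asarray(theta, dtype=float)
    u_ax = np.asarray(u_ax, dtype=float)
    out = np.full(np.broadcast(u_ax, theta).shape, np.nan)
    ok = ~_in_cutout(theta, cutout) & np.isfinite(theta) & np.isfinite(u_ax)
    out[ok] = np.broadcast_to(u_ax, out.shape)[ok] / np.cos(np.deg2rad(np.broadcast_to(theta, out.shape)[ok]))
    return out


def angular_mask(theta: np.ndarray, cutout=CUTOUT_DEG) -> AngularMask:
    """Cosine view-angle weight ``M = cos(2 theta)/2 + 1/2``, zeroed in the
    cut-out and at undefined angles."""
    theta = np.asarray(theta, dtype=float)
    M = 0.5 * np.cos(2.0 * np.deg2rad(theta)) + 0.5
    M = np.where(_in_cutout(theta, cutout) | ~np.isfinite(theta), 0.0, M)
    return AngularMask(M=M, cutout=cutout)


def compound_displacements(
    u_rad_fields: dict,
    masks: dict,
    trans_probe_pairings=((1, 2), (2, 1)),
):
    """Per-node normalized weighted fusion of projected radial displacements.

    ``u_rad_fields`` and ``masks`` map pairing -> array on a common grid.
    Trans-probe pairings carry half weight (their reciprocal information is
    averaged); weights are renormalized per node over the finite, unmasked
    contributions so the output is displacement-valued.  Returns
    ``(u_rad, valid)`` where nodes with no active contribution are NaN/False.
    """
    keys = list(u_rad_fields.keys())
    if set(keys) != set(masks.keys()):
        raise ValueError("fields and masks must cover the same pairings")
    shape = np.asarray(u_rad_fields[keys[0]]).shape
    num = np.zeros(shape)
    den = np.zeros(shape)
    for k in keys:
        u = np.asarray(u_rad_fields[k], dtype=float)
        m = np.asarray(masks[k].M if isinstance(masks[k], AngularMask) else masks[k], dtype=float)
        w = m * (0.5 if tuple(k) in {tuple(t) for t in trans_probe_pairings} else 1.0)
        ok = np.isfinite(u) & (w > 0)
        num[ok] += w[ok] * u[ok]
        den[ok] += w[ok]
    valid = den > 0
    out = np.full(shape, np.nan)
    out[valid] = num[valid] / den[valid]
    return out, valid
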