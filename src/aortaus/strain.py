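"""Wall-mesh construction, mesh tracking and 2-D least-squares strain.

The vessel wall is represented as a lattice of radial layers x circumferential
positions built from an inner-contour segmentation extrapolated outward by a
uniform wall thickness (default 1.7 mm).  The mesh is advected frame to frame
through the compounded radial displacement field (or a full 2-D field in the
single-perspective comparison mode).  Strain is estimated per node from the
displacement relative to the reference frame: an affine (least-squares) fit of
both displacement components over a 5 x 5 node neighbourhood yields the local
displacement gradient tensor, whose symmetric part is projected on the
reference-frame radial and circumferential directions.  Radial and
circumferential axes are fixed from the reference geometry and midpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.interpolate import RegularGridInterpolator

__all__ = [
    "WallMesh",
    "StrainField",
    "build_wall_mesh",
    "circle_contour",
    "track_mesh",
    "least_squares_strain",
]


@dataclass
class WallMesh:
    """Radial-layer x circumferential-node lattice of the vessel wall."""

    nodes: np.ndarray  # (n_layers, n_circ, 2) mm
    thickness: float  # mm
    center: np.ndarray  # (2,) mm, fixed reference midpoint
    frame_index: int = 0

    @property
    def n_radial_layers(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_circumferential(self) -> int:
        return self.nodes.shape[1]

    @property
    def middle_layer_index(self) -> int:
        return (self.n_radial_layers - 1) // 2

    def middle_layer(self) -> np.ndarray:
        return self.nodes[self.middle_layer_index]

    def inner_contour(self) -> np.ndarray:
        return self.nodes[0]

    def outer_contour(self) -> np.ndarray:
        return self.nodes[-1]

    def node_angles(self) -> np.ndarray:
        """Polar angle of each middle-layer node about the center, radians."""
        rel = self.middle_layer() - self.center
        return np.arctan2(rel[:, 1], rel[:, 0])


@dataclass
class StrainField:
    """Radial/circumferential normal strain per mesh node, vs a reference frame."""

    eps_rad: np.ndarray  # (n_layers, n_circ)
    eps_circ: np.ndarray
    valid: np.ndarray
    reference_frame: int
    frame_index: int


def circle_contour(center, radius: float, n_points: int) -> np.ndarray:
    """Inner-contour stand-in for a manual lumen-wall segmentation: a circle
    sampled at ``n_points`` (simple closed curve, one point per angle)."""
    th = 2.0 * np.pi * np.arange(n_points) / n_points
    c = np.asarray(center, dtype=float)
    return c + radius * np.stack([np.cos(th), np.sin(th)], axis=1)


def _polygon_area(points: np.ndarray) -> float:
    x, z = points[:, 0], points[:, 1]
    return 0.5 * float(np.sum(x * np.roll(z, -1) - np.roll(x, -1) * z))


def _contour_normals(points: np.ndarray, center: np.ndarray) -> np.ndarray:
    """Outward unit normals of a closed contour (central differences)."""
    tang = np.roll(points, -1, axis=0) - np.roll(points, 1, axis=0)
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)
    normals = np.stack([tang[:, 1], -tang[:, 0]], axis=1)
    # orient away from the centroid
    out = points - center
    flip = np.sum(normals * out, axis=1) < 0
    normals[flip] *= -1.0
    return normals


def _cross2(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """z-component of the 2-D cross product, elementwise."""
    return u[..., 0] * v[..., 1] - u[..., 1] * v[..., 0]


def _is_simple_closed(points: np.ndarray) -> bool:
    """Self-intersection test: no two non-adjacent edges of the closed
    polyline may cross (vectorized over all edge pairs)."""
    n = points.shape[0]
    p = points[:, None, :]
    q = np.roll(points, -1, axis=0)[:, None, :]
    r = points[None, :, :]
    s = np.roll(points, -1, axis=0)[None, :, :]
    d1 = _cross2(q - p, r - p)
    d2 = _cross2(q - p, s - p)
    d3 = _cross2(s - r, p - r)
    d4 = _cross2(s - r, q - r)
    crossing = (d1 * d2 < 0) & (d3 * d4 < 0)
    i = np.arange(n)
    adjacent = (
        (i[:, None] == i[None, :])
        | ((i[:, None] + 1) % n == i[None, :])
        | ((i[None, :] + 1) % n == i[:, None])
    )
    return not np.any(crossing & ~adjacent)


def build_wall_mesh(
    inner_points: np.ndarray,
    thickness: float = 1.7,
    n_layers: int = 5,
    center: np.ndarray | None = None,
    check_simple: bool = True,
    anterior_direction: np.ndarray | None = None,
) -> WallMesh:
    """Extrapolate an inner-contour segmentation into a wall mesh.

    Layers are offset along the local outward normal; the middle layer is
    equidistant between inner and outer.  The contour is oriented clockwise
    (as displayed) and, if ``anterior_direction`` is given, rolled to start
    at the node nearest that direction from the center.  Raises if the
    contour is not a simple closed curve or if the offset self-intersects
    (thickness exceeding the local radius of curvature on a concave stretch).
    """
    inner = np.asarray(inner_points, dtype=float)
    if inner.shape[0] < 8:
        raise ValueError("need at least 8 inner contour points")
    if thickness <= 0 or n_layers < 2:
        raise ValueError("thickness must be positive and n_layers >= 2")
    if center is None:
        center = inner.mean(axis=0)
    center = np.asarray(center, dtype=float)
    if check_simple and not _is_simple_closed(inner):
        raise ValueError("inner contour is self-intersecting")
    # orient clockwise as displayed (x right, z down); shoelace area in (x, z)
    # is positive for that orientation
    if _polygon_area(inner) < 0:
        inner = inner[::-1].copy()
    if anterior_direction is not None:
        a = np.asarray(anterior_direction, dtype=float)
        v = inner - center
        ang = np.arctan2(a[0] * v[:, 1] - a[1] * v[:, 0], v @ a)
        inner = np.roll(inner, -int(np.argmin(np.abs(ang))), axis=0)

    normals = _contour_normals(inner, center)
    offsets = np.linspace(0.0, thickness, n_layers)
    nodes = inner[None, :, :] + offsets[:, None, None] * normals[None, :, :]
    outer = nodes[-1]
    if check_simple and not _is_simple_closed(outer):
        raise ValueError("offset contour self-intersects: thickness exceeds local curvature radius")
    return WallMesh(nodes=nodes, thickness=float(thickness), center=center)


class RadialDisplacementSampler:
    """Samples a compounded radial displacement field (on a Cartesian grid)
    as a 2-D displacement vector along the fixed radial direction."""

    def __init__(self, u_rad: np.ndarray, x_coords, z_coords, center):
        self.center = np.asarray(center, dtype=float)
        self._interp = RegularGridInterpolator(
            (np.asarray(z_coords, float), np.asarray(x_coords, float)),
            np.asarray(u_rad, float),
            bounds_error=False,
            fill_value=np.nan,
        )

    def __call__(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        u = self._interp(np.stack([p[:, 1], p[:, 0]], axis=1))
        rad = p - self.center
        rn = np.linalg.norm(rad, axis=1, keepdims=True)
        rn[rn == 0] = np.nan
        return (rad / rn) * u[:, None]


class VectorDisplacementSampler:
    """Samples a full 2-D displacement field (u_x, u_z on a Cartesian grid),
    for the single-perspective mode where no radial projection is applied."""

    def __init__(self, u_x: np.ndarray, u_z: np.ndarray, x_coords, z_coords):
        zc = np.asarray(z_coords, float)
        xc = np.asarray(x_coords, float)
        self._ix = RegularGridInterpolator((zc, xc), np.asarray(u_x, float), bounds_error=False, fill_value=np.nan)
        self._iz = RegularGridInterpolator((zc, xc), np.asarray(u_z, float), bounds_error=False, fill_value=np.nan)

    def __call__(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        q = np.stack([p[:, 1], p[:, 0]], axis=1)
        return np.stack([self._ix(q), self._iz(q)], axis=1)


def track_mesh(mesh0: WallMesh, samplers: list) -> list:
    """Advect the mesh through per-frame-pair displacement samplers.

    Eulerian accumulation: each node samples the frame-k displacement at its
    current position and moves by it.  Nodes that leave field coverage (NaN
    sample) are carried by their last valid displacement.
    """
    meshes = [mesh0]
    last_disp = np.zeros((mesh0.n_radial_layers * mesh0.n_circumferential, 2))
    for k, sampler in enumerate(samplers):
        cur = meshes[-1]
        pts = cur.nodes.reshape(-1, 2)
        disp = sampler(pts)
        bad = ~np.isfinite(disp).all(axis=1)
        disp[bad] = last_disp[bad]
        last_disp = disp
        nxt = replace(cur, nodes=(pts + disp).reshape(cur.nodes.shape), frame_index=k + 1)
        meshes.append(nxt)
    return meshes


def least_squares_strain(
    mesh_seq: list,
    reference: int = 0,
    kernel: tuple = (5, 5),
) -> list:
    """Least-squares strain of every frame relative to ``mesh_seq[reference]``.

    Per node, the displacement (current - reference position) of the
    ``kernel`` neighbourhood (radial x circumferential; radial truncated at
    the mesh edges, circumferential wrapping the closed contour) is fitted
    affinely against the reference positions.  The symmetric part of the
    fitted displacement gradient is projected on the node's reference-frame
    radial/circumferential directions.
    """
    ref_mesh = mesh_seq[reference]
    nl, nc = ref_mesh.n_radial_layers, ref_mesh.n_circumferential
    kr, kc = kernel
    hr, hc = kr // 2, kc // 2
    ref_nodes = ref_mesh.nodes
    center = ref_mesh.center

    rel = ref_nodes - center
    rn = np.linalg.norm(rel, axis=2, keepdims=True)
    e_r = rel / rn
    e_c = np.stack([-e_r[..., 1], e_r[..., 0]], axis=-1)

    # neighbourhood index lists per node (fixed across frames)
    neigh = []
    for i in range(nl):
        r_lo, r_hi = max(0, i - hr), min(nl, i + hr + 1)
        rows = np.arange(r_lo, r_hi)
        for j in range(nc):
            cols = (j + np.arange(-hc, hc + 1)) % nc
            R, C = np.meshgrid(rows, cols, indexing="ij")
            neigh.append((R.ravel(), C.ravel()))

    out = []
    for f, mesh in enumerate(mesh_seq):
        if f == reference:
            out.append(
                StrainField(
                    np.zeros((nl, nc)), np.zeros((nl, nc)),
                    np.ones((nl, nc), bool), reference, mesh.frame_index,
                )
            )
            continue
        U = mesh.nodes - ref_nodes
        eps_r = np.zeros((nl, nc))
        eps_c = np.zeros((nl, nc))
        valid = np.ones((nl, nc), bool)
        idx = 0
        for i in range(nl):
            for j in range(nc):
                R, C = neigh[idx]
                idx += 1
                X = ref_nodes[R, C]
                Y = U[R, C]
                A = np.column_stack([np.ones(X.shape[0]), X[:, 0], X[:, 1]])
                sol, _, rank, _ = np.linalg.lstsq(A, Y, rcond=None)
                if rank < 3:
                    valid[i, j] = False
                    continue
                G = sol[1:].T  # displacement gradient du_i/dx_j
                E = 0.5 * (G + G.T)
                er = e_r[i, j]
                ec = e_c[i, j]
                eps_r[i, j] = er @ E @ er
                eps_c[i, j] = ec @ E @ ec
        out.append(StrainField(eps_r, eps_c, valid, reference, mesh.frame_index))
    return out
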