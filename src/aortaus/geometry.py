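"""Transducer, grid and coordinate-frame definitions shared by all modules.

Conventions
-----------
* Points are arrays of shape ``(..., 2)`` with columns ``(x, z)``: x lateral
  (positive right), z axial depth (positive downward), in millimetres.
* The global frame is probe 1's local frame; its surface apex is the origin.
* Angles are in degrees.  Rotations follow the right-handed convention of
  ``R(phi) @ (x, z)`` with ``R = [[cos, -sin], [sin, cos]]``, so ``phi = 90``
  maps ``(1, 0)`` to ``(0, 1)``.
* Steering angles are measured at the probe origin against the z axis,
  counterclockwise positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal.windows import tukey

__all__ = [
    "TransducerGeometry",
    "RigidTransform2D",
    "CartesianGrid",
    "SectorGrid",
    "TransmitEvent",
    "make_curved_array",
    "apply_transform",
    "transmit_delays",
    "wavelength_mm",
]


def wavelength_mm(f0: float, c: float) -> float:
    """Acoustic wavelength in mm for centre frequency ``f0`` [Hz] and sound speed ``c`` [m/s]."""
    return c * 1e3 / f0


@dataclass
class RigidTransform2D:
    """Rigid in-plane mapping (rotation by ``phi`` then translation).

    Maps probe-2 local coordinates into the probe-1 (global) frame; it is the
    three-degree-of-freedom variable of the probe-localization optimizer.

    Parameters
    ----------
    tx, tz : float
        Translation in mm.
    phi : float
        Rotation in degrees (counterclockwise per the module convention).
    """

    tx: float = 0.0
    tz: float = 0.0
    phi: float = 0.0

    def rotation_matrix(self) -> np.ndarray:
        a = np.deg2rad(self.phi)
        c, s = np.cos(a), np.sin(a)
        return np.array([[c, -s], [s, c]])

    def apply(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        return points @ self.rotation_matrix().T + np.array([self.tx, self.tz])

    def rotate_only(self, vectors: np.ndarray) -> np.ndarray:
        """Rotate direction vectors without translating (for normals)."""
        return np.asarray(vectors, dtype=float) @ self.rotation_matrix().T

    def compose(self, other: "RigidTransform2D") -> "RigidTransform2D":
        """Return the transform equivalent to applying ``other`` first, then ``self``."""
        t = self.apply(np.array([other.tx, other.tz]))
        return RigidTransform2D(t[0], t[1], self.phi + other.phi)

    def inverse(self) -> "RigidTransform2D":
        inv = RigidTransform2D(0.0, 0.0, -self.phi)
        t = inv.rotate_only(np.array([self.tx, self.tz]))
        return RigidTransform2D(-t[0], -t[1], -self.phi)

    def as_vector(self) -> np.ndarray:
        return np.array([self.tx, self.tz, self.phi])

    @staticmethod
    def from_vector(v) -> "RigidTransform2D":
        return RigidTransform2D(float(v[0]), float(v[1]), float(v[2]))


def apply_transform(T: RigidTransform2D, points: np.ndarray) -> np.ndarray:
    """Apply a rigid transform to an ``(..., 2)`` point set (distance preserving)."""
    return T.apply(points)


@dataclass
class TransducerGeometry:
    """Curved-array transducer: elements on a circular arc, convex toward +z.

    The arc center sits at ``(0, -radius_of_curvature)`` in the probe's local
    frame so the central surface point (apex) is the local origin.  Element
    normals point away from the arc center, into the tissue.
    """

    n_elements: int
    element_positions: np.ndarray  # (n, 2) mm, local frame
    element_normals: np.ndarray  # (n, 2) unit vectors
    pitch: float  # mm, arc length between adjacent elements
    radius_of_curvature: float  # mm
    center_frequency: float  # Hz
    bandwidth_fractional: float = 0.6
    label: int = 1

    @property
    def arc_center(self) -> np.ndarray:
        return np.array([0.0, -self.radius_of_curvature])

    def element_angles(self) -> np.ndarray:
        """Angular element positions about the arc center, radians, 0 at the apex."""
        n = self.n_elements
        dgamma = self.pitch / self.radius_of_curvature
        return (np.arange(n) - (n - 1) / 2.0) * dgamma


def make_curved_array(
    n_elements: int,
    pitch: float = 0.508,
    radius: float = 49.57,
    f0: float = 3.7e6,
    bandwidth_fractional: float = 0.6,
    label: int = 1,
) -> TransducerGeometry:
    """Build a curved array with ``n_elements`` spaced ``pitch`` mm along an arc.

    Defaults model a C5-2v-class abdominal probe (3.7 MHz centre frequency).

    Raises
    ------
    ValueError
        If ``n_elements < 2`` or any dimension is non-positive.
    """
    if n_elements < 2:
        raise ValueError("n_elements must be >= 2")
    if pitch <= 0 or radius <= 0 or f0 <= 0:
        raise ValueError("pitch, radius and f0 must be positive")
    dgamma = pitch / radius
    gammas = (np.arange(n_elements) - (n_elements - 1) / 2.0) * dgamma
    normals = np.stack([np.sin(gammas), np.cos(gammas)], axis=1)
    center = np.array([0.0, -radius])
    positions = center + radius * normals
    return TransducerGeometry(
        n_elements=n_elements,
        element_positions=positions,
        element_normals=normals,
        pitch=pitch,
        radius_of_curvature=radius,
        center_frequency=f0,
        bandwidth_fractional=bandwidth_fractional,
        label=label,
    )


@dataclass
class CartesianGrid:
    """Uniform rectangular reconstruction grid (probe-1 frame)."""

    x_coords: np.ndarray  # mm, strictly increasing
    z_coords: np.ndarray  # mm, strictly increasing

    def __post_init__(self):
        self.x_coords = np.asarray(self.x_coords, dtype=float)
        self.z_coords = np.asarray(self.z_coords, dtype=float)
        for c in (self.x_coords, self.z_coords):
            if c.size > 1:
                d = np.diff(c)
                if not np.all(d > 0):
                    raise ValueError("grid coordinates must be strictly increasing")
                if not np.allclose(d, d[0], rtol=1e-9, atol=1e-12):
                    raise ValueError("grid spacing must be uniform")

    @property
    def shape(self) -> tuple:
        return (self.z_coords.size, self.x_coords.size)

    @property
    def spacing(self) -> tuple:
        dx = float(self.x_coords[1] - self.x_coords[0]) if self.x_coords.size > 1 else 0.0
        dz = float(self.z_coords[1] - self.z_coords[0]) if self.z_coords.size > 1 else 0.0
        return (dx, dz)

    def points(self) -> np.ndarray:
        """All node positions, shape ``(nz, nx, 2)``."""
        X, Z = np.meshgrid(self.x_coords, self.z_coords)
        return np.stack([X, Z], axis=-1)

    @staticmethod
    def from_extent(x_min, x_max, z_min, z_max, spacing) -> "CartesianGrid":
        nx = int(np.floor((x_max - x_min) / spacing)) + 1
        nz = int(np.floor((z_max - z_min) / spacing)) + 1
        return CartesianGrid(
            x_min + spacing * np.arange(nx), z_min + spacing * np.arange(nz)
        )


@dataclass
class SectorGrid:
    """Beam-aligned grid of a curved array: lines at fixed beam angles, samples
    at fixed depths along each line.

    Beam lines emanate radially from the arc center; the node at
    ``(angle gamma, depth d)`` lies at ``arc_center + (R + d) * (sin g, cos g)``
    in the probe's local frame, so ``d`` is depth beneath the element surface
    and the axial direction of the grid is the local beam direction.
    """

    beam_angles: np.ndarray  # deg, relative to the probe axis
    sample_depths: np.ndarray  # mm along each beam, uniform spacing
    radius_of_curvature: float  # mm, of the owning probe
    lines_per_pitch: float = 2.0

    def __post_init__(self):
        self.beam_angles = np.asarray(self.beam_angles, dtype=float)
        self.sample_depths = np.asarray(self.sample_depths, dtype=float)
        if self.sample_depths.size > 1:
            d = np.diff(self.sample_depths)
            if not np.allclose(d, d[0], rtol=1e-9, atol=1e-12):
                raise ValueError("axial spacing must be uniform")

    @property
    def shape(self) -> tuple:
        return (self.sample_depths.size, self.beam_angles.size)

    @property
    def axial_spacing(self) -> float:
        return float(self.sample_depths[1] - self.sample_depths[0])

    def local_points(self) -> np.ndarray:
        """Node positions in the owning probe's local frame, ``(n_depth, n_angle, 2)``."""
        g = np.deg2rad(self.beam_angles)[None, :]
        r = (self.radius_of_curvature + self.sample_depths)[:, None]
        x = r * np.sin(g)
        z = r * np.cos(g) - self.radius_of_curvature
        return np.stack([x, z], axis=-1)

    def beam_directions(self) -> np.ndarray:
        """Unit axial direction of every beam line, ``(n_angle, 2)``."""
        g = np.deg2rad(self.beam_angles)
        return np.stack([np.sin(g), np.cos(g)], axis=1)

    def to_sector_coords(self, points_local: np.ndarray) -> tuple:
        """Map local-frame points to (beam angle deg, depth mm) coordinates."""
        p = np.asarray(points_local, dtype=float)
        rel = p + np.array([0.0, self.radius_of_curvature])
        r = np.hypot(rel[..., 0], rel[..., 1])
        ang = np.rad2deg(np.arctan2(rel[..., 0], rel[..., 1]))
        return ang, r - self.radius_of_curvature


def make_sector_grid(
    geom: TransducerGeometry,
    depth_min: float,
    depth_max: float,
    c: float = 1540.0,
    lines_per_pitch: float = 2.0,
    axial_fraction: float = 0.125,
    angle_min: float | None = None,
    angle_max: float | None = None,
) -> SectorGrid:
    """Tracking grid per the acquisition convention: ``lines_per_pitch`` beam
    lines per element pitch laterally and ``axial_fraction * lambda`` axial
    sample spacing (default lambda/8)."""
    lam = wavelength_mm(geom.center_frequency, c)
    dz = axial_fraction * lam
    dgamma = np.rad2deg(geom.pitch / geom.radius_of_curvature) / lines_per_pitch
    half = np.rad2deg(geom.element_angles()[-1]) if angle_max is None else angle_max
    lo = -half if angle_min is None else angle_min
    hi = half if angle_max is None else angle_max
    n_ang = int(np.floor((hi - lo) / dgamma)) + 1
    angles = lo + dgamma * np.arange(n_ang)
    n_dep = int(np.floor((depth_max - depth_min) / dz)) + 1
    depths = depth_min + dz * np.arange(n_dep)
    return SectorGrid(angles, depths, geom.radius_of_curvature, lines_per_pitch)


@dataclass
class TransmitEvent:
    """One diverging-wave transmit: per-element delays, Tukey apodization and
    the virtual source the wavefront appears to emanate from."""

    steering_angle: float  # deg
    element_delays: np.ndarray  # s, min 0
    apodization_weights: np.ndarray  # [0, 1]
    virtual_source: np.ndarray  # (2,) mm, local frame of the transmitting probe


def transmit_delays(
    geom: TransducerGeometry,
    steering_angle: float,
    c: float = 1540.0,
    virtual_source_standoff: float | None = None,
    tukey_alpha: float = 0.25,
) -> TransmitEvent:
    """Diverging-wave transmit delays for a steered virtual source.

    The virtual source is placed behind the probe apex at distance
    ``virtual_source_standoff`` (default: the radius of curvature, i.e. the
    arc center for zero steering) along the steered direction
    ``-(sin a, cos a)``.  The emitted wavefront normal at the probe origin
    therefore makes exactly ``steering_angle`` with the z axis.
    """
    if abs(steering_angle) > 90:
        raise ValueError("|steering_angle| must be <= 90 degrees")
    d = geom.radius_of_curvature if virtual_source_standoff is None else virtual_source_standoff
    a = np.deg2rad(steering_angle)
    vs = -d * np.array([np.sin(a), np.cos(a)])
    dist = np.linalg.norm(geom.element_positions - vs, axis=1)
    delays = (dist - dist.min()) / (c * 1e3)
    apod = tukey(geom.n_elements, alpha=tukey_alpha)
    return TransmitEvent(
        steering_angle=float(steering_angle),
        element_delays=delays,
        apodization_weights=apod,
        virtual_source=vs,
    )
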