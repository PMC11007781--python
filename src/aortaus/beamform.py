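"""Delay-and-sum IQ reconstruction, angle compounding and bistatic fusion.

Any of the four transmit/receive probe pairings can be reconstructed on a
Cartesian grid (probe-1 frame) or on the receiving probe's sector grid.  The
beamformer output at a node is the coherent sum over receive elements of the
baseband sample at the total delay (virtual-source transmit time + receive
travel time), phase-rotated by the carrier — i.e. the analytic RF signal, so
``abs`` gives the envelope and ``real`` the RF.

The fused bistatic image follows the reciprocity-averaged coherent sum
``I11 + I22 + (I12 + I21)/2``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import hilbert

from . import _kernels
from .geometry import CartesianGrid, RigidTransform2D, SectorGrid, TransducerGeometry
from .simulator import ChannelData

__all__ = [
    "BeamformedImage",
    "demodulate",
    "das_beamform",
    "compound_angles",
    "bistatic_compound",
    "envelope_log",
]


@dataclass
class BeamformedImage:
    """Complex samples on a named grid for one probe pairing."""

    iq: np.ndarray  # complex, grid.shape
    grid: CartesianGrid | SectorGrid
    pairing: tuple  # (tx_probe, rx_probe) or ("bistatic", "bistatic")
    steering: float | str = "compounded"
    frame_index: int = 0

    def envelope(self) -> np.ndarray:
        return np.abs(self.iq)

    def rf(self) -> np.ndarray:
        return np.real(self.iq)


def demodulate(channels: ChannelData, f0: float) -> ChannelData:
    """Complex baseband conversion: analytic signal (Hilbert) mixed down by f0."""
    if channels.fs <= 2.0 * f0:
        raise ValueError("fs too low for demodulation")
    analytic = hilbert(channels.samples, axis=1)
    t = channels.t0 + np.arange(channels.samples.shape[1]) / channels.fs
    bb = analytic * np.exp(-2j * np.pi * f0 * t)[None, :]
    return replace(channels, samples=bb, baseband=True)


def _grid_nodes_global(grid, T_rx: RigidTransform2D):
    """Flattened node positions in the global frame plus the grid shape."""
    if isinstance(grid, SectorGrid):
        local = grid.local_points().reshape(-1, 2)
        return T_rx.apply(local), grid.shape
    pts = grid.points().reshape(-1, 2)
    return pts, grid.shape


def das_beamform(
    channels: ChannelData,
    tx_geom: TransducerGeometry,
    rx_geom: TransducerGeometry,
    T_rx: RigidTransform2D,
    grid,
    c: float = 1540.0,
    T_tx: RigidTransform2D | None = None,
    max_element_angle: float = 45.0,
    tx_times: np.ndarray | None = None,
) -> BeamformedImage:
    """Delay-and-sum one demodulated event onto ``grid``.

    ``T_tx``/``T_rx`` map the probes' local frames to the global frame
    (identity for probe 1); a Cartesian grid lives in the global frame while
    a sector grid lives in the receiving probe's frame and is mapped through
    ``T_rx``.  Elements more than ``max_element_angle`` off their normal
    contribute zero, as do delays outside the recorded window.
    ``tx_times`` optionally carries precomputed per-node transmit first-arrival
    times (they do not depend on the receive pose).
    """
    if not channels.baseband:
        raise ValueError("channels must be demodulated before beamforming")
    T_tx = T_tx or RigidTransform2D()
    c_mms = c * 1e3
    nodes, shape = _grid_nodes_global(grid, T_rx)
    nodes = np.ascontiguousarray(nodes)

    if tx_times is None:
        tx_pos = np.ascontiguousarray(T_tx.apply(tx_geom.element_positions))
        delays = np.ascontiguousarray(channels.event.element_delays, dtype=np.float64)
        tx_times = _kernels.first_arrival_times(nodes, tx_pos, delays, c_mms)

    rx_pos = np.ascontiguousarray(T_rx.apply(rx_geom.element_positions))
    rx_norm = np.ascontiguousarray(T_rx.rotate_only(rx_geom.element_normals))
    iq = _kernels.das_sum(
        np.ascontiguousarray(channels.samples, dtype=np.complex128),
        rx_pos,
        rx_norm,
        nodes,
        np.ascontiguousarray(tx_times, dtype=np.float64),
        channels.t0,
        channels.fs,
        tx_geom.center_frequency,
        c_mms,
        np.cos(np.deg2rad(max_element_angle)),
    )
    return BeamformedImage(
        iq=iq.reshape(shape),
        grid=grid,
        pairing=(channels.tx_probe, channels.rx_probe),
        steering=channels.event.steering_angle,
        frame_index=channels.frame_index,
    )


def compound_angles(images: list) -> BeamformedImage:
    """Coherent (complex) sum over steering angles on a shared grid."""
    if not images:
        raise ValueError("no images to compound")
    first = images[0]
    for im in images[1:]:
        if im.iq.shape != first.iq.shape or im.grid is not first.grid and not _same_grid(im.grid, first.grid):
            raise ValueError("grid mismatch between angle images")
        if im.pairing != first.pairing:
            raise ValueError("pairing mismatch between angle images")
    iq = np.sum([im.iq for im in images], axis=0)
    return BeamformedImage(iq, first.grid, first.pairing, "compounded", first.frame_index)


def _same_grid(a, b) -> bool:
    if type(a) is not type(b):
        return False
    if isinstance(a, CartesianGrid):
        return np.array_equal(a.x_coords, b.x_coords) and np.array_equal(a.z_coords, b.z_coords)
    return (
        np.array_equal(a.beam_angles, b.beam_angles)
        and np.array_equal(a.sample_depths, b.sample_depths)
        and a.radius_of_curvature == b.radius_of_curvature
    )


def bistatic_compound(
    I11: BeamformedImage,
    I22: BeamformedImage,
    I12: BeamformedImage,
    I21: BeamformedImage,
) -> BeamformedImage:
    """Reciprocity-averaged coherent fusion ``I11 + I22 + (I12 + I21)/2``."""
    expected = {(1, 1): I11, (2, 2): I22, (1, 2): I12, (2, 1): I21}
    for pairing, im in expected.items():
        if tuple(im.pairing) != pairing:
            raise ValueError(f"image labelled {im.pairing} passed as {pairing}")
        if im.iq.shape != I11.iq.shape or not _same_grid(im.grid, I11.grid):
            raise ValueError("all four images must share one grid")
    iq = I11.iq + I22.iq + 0.5 * (I12.iq + I21.iq)
    return BeamformedImage(iq, I11.grid, ("bistatic", "bistatic"), "compounded", I11.frame_index)


def envelope_log(image: BeamformedImage, dynamic_range: float = 50.0) -> np.ndarray:
    """Log-compressed display image: ``20 log10(|iq| / max)`` clipped to
    ``[-dynamic_range, 0]`` dB."""
    env = np.abs(image.iq)
    peak = env.max()
    if peak == 0.0:
        raise ValueError("all-zero image cannot be log-compressed")
    with np.errstate(divide="ignore"):
        db = 20.0 * np.log10(env / peak)
    return np.clip(db, -dynamic_range, 0.0)
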