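"""Automatic probe localization by maximizing trans-probe signal coherence.

The relative pose of probe 2 (two translations + one rotation) is found by
gradient descent on the negative signal power of the angle-compounded,
envelope-detected T1R2 image: when the assumed receive-element positions are
correct, the trans-probe echoes sum coherently and the image power is maximal,
so the negative power ``P- = -sum |A_i|^2`` is minimal at the true pose.

The coherence surface carries speckle-scale ripple and, far from the truth,
multiple local minima; the optimizer therefore reports its objective history
and best-seen pose rather than claiming global optimality.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .beamform import BeamformedImage, compound_angles, das_beamform
from .geometry import CartesianGrid, RigidTransform2D, TransducerGeometry

__all__ = [
    "RegistrationState",
    "RegistrationProblem",
    "negative_signal_power",
    "objective",
    "numerical_gradient",
    "register_probes",
]

#: central-difference steps: ~lambda/4 (mm) for translations at 3.7 MHz, 0.1 deg rotation
DEFAULT_GRADIENT_STEPS = (0.1, 0.1, 0.1)
#: per-parameter learning rates (mm resp. deg of step per unit relative power
#: gradient); the rotation rate is much larger because rotation is optimized
#: about the ROI center, where the coherence surface is shallow (see
#: register_probes)
DEFAULT_MU = (2.0, 2.0, 25.0)


def negative_signal_power(image, region_mask: np.ndarray | None = None) -> float:
    """Negative signal power ``-sum |A_i|^2`` of an envelope-detected image.

    ``image`` may be a :class:`BeamformedImage` or a plain amplitude array;
    ``region_mask`` restricts the sum to the imaged region of interest.
    """
    amp = np.abs(image.iq) if isinstance(image, BeamformedImage) else np.abs(np.asarray(image))
    if region_mask is not None:
        amp = amp[region_mask]
    if amp.size == 0:
        raise ValueError("empty imaged region")
    return -float(np.sum(amp**2))


class RegistrationProblem:
    """Caches everything that does not depend on the probe-2 pose.

    The transmit first-arrival times per steering angle are fixed (probe 1
    transmits onto a fixed grid); only the receive element positions move with
    the candidate transform, so one objective evaluation is a receive-side
    delay-and-sum per angle plus the power sum.
    """

    def __init__(
        self,
        channels_by_angle: list,
        tx_geom: TransducerGeometry,
        rx_geom: TransducerGeometry,
        grid: CartesianGrid,
        c: float = 1540.0,
        region_mask: np.ndarray | None = None,
        max_element_angle: float = 45.0,
    ):
        for cd in channels_by_angle:
            if not cd.baseband:
                raise ValueError("registration channels must be demodulated")
            if (cd.tx_probe, cd.rx_probe) != (tx_geom.label, rx_geom.label):
                raise ValueError("channels do not match the given tx/rx geometries")
        self.channels = channels_by_angle
        self.tx_geom = tx_geom
        self.rx_geom = rx_geom
        self.grid = grid
        self.c = c
        self.region_mask = region_mask
        self.max_element_angle = max_element_angle
        nodes = np.ascontiguousarray(grid.points().reshape(-1, 2))
        tx_pos = np.ascontiguousarray(tx_geom.element_positions)
        self._tx_times = [
            _kernels.first_arrival_times(
                nodes, tx_pos, np.ascontiguousarray(cd.event.element_delays), c * 1e3
            )
            for cd in channels_by_angle
        ]
        self.n_evaluations = 0

    def compound_image(self, T: RigidTransform2D) -> BeamformedImage:
        images = [
            das_beamform(
                cd,
                self.tx_geom,
                self.rx_geom,
                T,
                self.grid,
                self.c,
                max_element_angle=self.max_element_angle,
                tx_times=tt,
            )
            for cd, tt in zip(self.channels, self._tx_times)
        ]
        return compound_angles(images)

    def objective(self, T: RigidTransform2D) -> float:
        self.n_evaluations += 1
        return negative_signal_power(self.compound_image(T), self.region_mask)


def objective(
    T: RigidTransform2D,
    channels_by_angle: list,
    tx_geom: TransducerGeometry,
    rx_geom: TransducerGeometry,
    grid: CartesianGrid,
    c: float = 1540.0,
    region_mask: np.ndarray | None = None,
) -> float:
    """Negative signal power of the compounded T1R2 image under pose ``T``."""
    return RegistrationProblem(
        channels_by_angle, tx_geom, rx_geom, grid, c, region_mask
    ).objective(T)


def numerical_gradient(
    fun,
    T: RigidTransform2D,
    steps=DEFAULT_GRADIENT_STEPS,
    mode: str = "central",
    f_base: float | None = None,
) -> np.ndarray:
    """Finite-difference gradient of ``fun`` over (tx, tz, phi).

    ``central`` uses six evaluations (two per degree of freedom); ``forward``
    shares one base evaluation (``f_base`` may pass it in).
    """
    steps = np.asarray(steps, dtype=float)
    if np.any(steps <= 0):
        raise ValueError("step sizes must be positive")
    v = T.as_vector()
    g = np.zeros(3)
    if mode == "central":
        for i in range(3):
            e = np.zeros(3)
            e[i] = steps[i]
            g[i] = (
                fun(RigidTransform2D.from_vector(v + e))
                - fun(RigidTransform2D.from_vector(v - e))
            ) / (2.0 * steps[i])
    elif mode == "forward":
        f0 = fun(T) if f_base is None else f_base
        for i in range(3):
            e = np.zeros(3)
            e[i] = steps[i]
            g[i] = (fun(RigidTransform2D.from_vector(v + e)) - f0) / steps[i]
    else:
        raise ValueError("mode must be 'central' or 'forward'")
    return g


@dataclass
class RegistrationState:
    """Result of a gradient-descent probe localization run."""

    T: RigidTransform2D
    mu: np.ndarray
    objective_history: list = field(default_factory=list)
    iteration: int = 0
    converged: bool = False
    diverged: bool = False
    best_T: RigidTransform2D | None = None
    best_objective: float = np.inf


def register_probes(
    channels_by_angle: list,
    tx_geom: TransducerGeometry,
    rx_geom: TransducerGeometry,
    grid: CartesianGrid,
    T_init: RigidTransform2D,
    c: float = 1540.0,
    mu=DEFAULT_MU,
    max_iter: int = 50,
    gradient_steps=DEFAULT_GRADIENT_STEPS,
    gradient_mode: str = "central",
    region_mask: np.ndarray | None = None,
    convergence_window: int = 3,
    convergence_fraction: float = 0.05,
    momentum: float = 0.85,
    max_backtracks: int = 8,
    pose_tolerance: tuple = (0.05, 0.05),
    pivot: np.ndarray | None = None,
    audit_steps: tuple = (0.21, 0.21, 0.25),
) -> RegistrationState:
    """Iterate ``T <- T - mu * grad P-`` from a manual/config initialization.

    Parameterization.  The three degrees of freedom are optimized as two
    translations plus a rotation about a ``pivot`` in the imaged region
    (default: the ROI grid center, i.e. near the vessel).  About that pivot
    the coherence surface is shallow — rotating the probe pose about the
    vessel maps the bright wall ring nearly onto itself — so this "orbit"
    mode gets its own, much larger learning rate (``mu[2]``) to match the
    sensitivity of the stiff translational modes, as a naive shared rate
    stalls the rotation.  The returned transform is in the standard
    (translation + rotation about the probe apex) form.

    Step control.  The raw objective scales with image energy, so the
    gradient is normalized by ``|P-(T_init)|``; ``mu`` is then in mm (resp.
    degrees) per unit of relative power change.  A heavy-ball momentum term
    and a growing/backtracking global step factor let the descent traverse
    the shallow tail and still settle on the sharp peak; set ``momentum=0``
    and ``max_backtracks=0`` for the plain fixed-step update.

    Convergence: once the objective has improved over its starting value,
    both the objective and the pose must remain constant for
    ``convergence_window`` consecutive iterations — per-iteration objective
    change below ``convergence_fraction`` (5%) of the starting value's
    magnitude and pose change below ``pose_tolerance`` (mm, degrees).  A
    candidate convergence is then audited against a multi-scale stencil
    (per-parameter offsets at 1x, 2.5x and 5x ``audit_steps``, plus pattern
    moves extrapolating the recent progress direction): the envelope-power
    surface carries speckle-scale ripple, narrow curved valleys, and a
    near-degenerate direction — a common shift of the receive pose along its
    range axis barely degrades focus quality, costing only a few percent of
    power per millimetre — on which the descent can dwell while still far
    from the optimum.  Probes spanning up to ~1 mm / ~1 degree resolve that
    slope; if one improves the power the optimizer hops there and continues
    (an audit costs about three iterations' worth of evaluations);
    convergence is declared only when no probe improves.  If the
    objective grows for 10 consecutive iterations (possible once backtracking
    is exhausted) the run is flagged divergent; either way the best-seen pose
    is returned on exit.
    """
    problem = RegistrationProblem(
        channels_by_angle, tx_geom, rx_geom, grid, c, region_mask
    )
    if pivot is None:
        pivot = np.array(
            [float(np.mean(grid.x_coords)), float(np.mean(grid.z_coords))]
        )
    pivot = np.asarray(pivot, dtype=float)

    def v_to_T(v):
        """(shift, orbit-about-pivot) parameters -> standard transform."""
        t = np.array([T_init.tx + v[0], T_init.tz + v[1]])
        rot = RigidTransform2D(0.0, 0.0, v[2])
        t2 = rot.apply(t - pivot) + pivot
        return RigidTransform2D(t2[0], t2[1], T_init.phi + v[2])

    fun = lambda v: problem.objective(v_to_T(v))
    steps_arr = np.asarray(gradient_steps, dtype=float)

    def vgrad(v, f_base):
        g = np.zeros(3)
        if gradient_mode == "central":
            for i in range(3):
                e = np.zeros(3)
                e[i] = steps_arr[i]
                g[i] = (fun(v + e) - fun(v - e)) / (2.0 * steps_arr[i])
        elif gradient_mode == "forward":
            for i in range(3):
                e = np.zeros(3)
                e[i] = steps_arr[i]
                g[i] = (fun(v + e) - f_base) / steps_arr[i]
        else:
            raise ValueError("gradient_mode must be 'central' or 'forward'")
        return g

    mu = np.asarray(mu, dtype=float)
    v = np.zeros(3)
    T = v_to_T(v)
    p0 = problem.objective(T)
    state = RegistrationState(T=T, mu=mu, objective_history=[p0])
    state.best_T, state.best_objective = T, p0
    scale = abs(p0)
    if scale == 0.0:  # empty scene: no signal anywhere, nothing to optimize
        state.converged = False
        return state

    conv_count = 0
    up_count = 0
    p_prev = p0
    fac = 1.0
    velocity = np.zeros(3)
    trail: list = []  # recent poses, for the pattern-move audit probes
    it = 0
    while it < max_iter:
        it += 1
        trail.append(v.copy())
        if len(trail) > 6:
            trail.pop(0)
        g = vgrad(v, p_prev)
        velocity = momentum * velocity + fac * mu * g / scale
        v_new = v - velocity
        p = fun(v_new)
        tries = 0
        while p > p_prev and tries < max_backtracks:
            velocity *= 0.5
            v_new = v - velocity
            p = fun(v_new)
            tries += 1
        if tries == 0:
            fac = min(fac * 1.25, 20.0)
        else:
            # shrink the global factor at most two octaves per iteration: a
            # single overshoot must not stall the following iterations
            fac = max(fac * 0.5 ** min(tries, 2), 0.02)
        if p > p_prev:
            # backtracking exhausted without any descent: reject the step
            # (an accepted uphill move can strand the pose in a dead region)
            velocity = np.zeros(3)
            p = p_prev
            v_new = v
            up_count += 1
        else:
            up_count = 0
        T_new = v_to_T(v_new)
        pose_step = T_new.as_vector() - T.as_vector()
        v, T = v_new, T_new
        state.objective_history.append(p)
        state.iteration = it
        if p < state.best_objective:
            state.best_objective, state.best_T = p, T
        if up_count >= 10:
            state.diverged = True
            break
        pose_settled = (
            np.hypot(pose_step[0], pose_step[1]) < pose_tolerance[0]
            and abs(pose_step[2]) < pose_tolerance[1]
        )
        if p < p0 and pose_settled and abs(p - p_prev) < convergence_fraction * abs(p0):
            conv_count += 1
            if conv_count >= convergence_window:
                # audit: is the pose optimal at the half-wavelength scale, or
                # merely dwelling on speckle-scale ripple / crawling along a
                # narrow valley?  Probe the axis stencil plus pattern moves
                # extrapolating the recent net progress direction.
                probes = []
                for i in range(3):
                    for sgn in (-1.0, 1.0):
                        for scale in (1.0, 2.5, 5.0):
                            e = np.zeros(3)
                            e[i] = sgn * scale * audit_steps[i]
                            probes.append(v + e)
                # the known near-degenerate direction: a common shift of the
                # receive pose along its range axis (apex toward ROI center)
                apex = np.array([T.tx, T.tz])
                rng_dir = pivot - apex
                rng_norm = np.linalg.norm(rng_dir)
                if rng_norm > 0:
                    u = rng_dir / rng_norm
                    for s in (-2.0, -1.0, -0.5, 0.5, 1.0, 2.0):
                        probes.append(v + s * np.array([u[0], u[1], 0.0]))
                d = v - trail[0]
                if np.any(d != 0.0):
                    for k in (0.5, 1.0, 2.0, 4.0):
                        probes.append(v + k * d)
                best_probe, best_pp = None, p
                for cand in probes:
                    pp = fun(cand)
                    if pp < best_pp:
                        best_probe, best_pp = cand, pp
                it += 3  # the audit costs about three iterations of evaluations
                state.iteration = it
                if best_probe is None or best_pp > p - 0.005 * abs(p):
                    state.converged = True
                    break
                v = best_probe
                T = v_to_T(v)
                p = best_pp
                state.objective_history.append(p)
                if p < state.best_objective:
                    state.best_objective, state.best_T = p, T
                velocity = np.zeros(3)
                fac = max(fac, 0.1)
                conv_count = 0
        else:
            conv_count = 0
        p_prev = p

    state.T = state.best_T
    return state
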