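"""End-to-end workflow: simulate -> beamform -> register -> track -> strain -> metrics.

Ties the modules into the dual-aperture imaging pipeline: dual-probe channel
data are simulated from a pulsating-vessel phantom, the four probe pairings
are beamformed on sector grids (and on a quarter-wavelength Cartesian grid
for the fused B-mode), probe registration is evaluated on the trans-probe
coherence, displacements are tracked and compounded, the wall mesh is
advected, and strain plus quality metrics are reported.

Two analysis modes exist: ``bistatic`` (all four pairings, angular
displacement compounding) and ``single_perspective`` (reference-probe T1R1
data only, axial+lateral displacements without radial projection) — the
comparison the quality metrics are designed around.

The geometric calibration (the probe-2 pose) is taken as known for the
elastography stages; the registration stage estimates it independently from
the trans-probe data and reports its accuracy, keeping calibration errors out
of the strain validation.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from .beamform import BeamformedImage, bistatic_compound, compound_angles, das_beamform, demodulate
from .geometry import CartesianGrid, RigidTransform2D, SectorGrid, make_sector_grid, wavelength_mm
from .metrics import (
    MetricReport,
    clockwise_angle_deg,
    exclude_lateral_sections,
    gcnr,
    make_rois,
    mean_drift_error,
    partition_regions,
    snre,
)
from .register import RegistrationState, register_probes
from .simulator import CycleData, SceneConfig, simulate_cycle
from .strain import (
    RadialDisplacementSampler,
    VectorDisplacementSampler,
    WallMesh,
    build_wall_mesh,
    circle_contour,
    least_squares_strain,
    track_mesh,
)
from .track import TrackingParams, angular_mask, coarse_to_fine_track, compute_theta, radial_project, compound_displacements

__all__ = [
    "PipelineConfig",
    "RunState",
    "STAGES",
    "run_pipeline",
    "interprobe_time_offset",
]

STAGES = ("simulate", "beamform", "register", "track", "strain", "metrics")


def interprobe_time_offset(prf: float, n_transmits: int) -> float:
    """Time between the two probes' transmit bursts in the interleaved
    scheme: ``n_transmits / prf`` seconds (e.g. 15 transmits at 4 kHz ->
    3.75 ms)."""
    if prf <= 0:
        raise ValueError("prf must be positive")
    return n_transmits / prf


@dataclass
class RegistrationConfig:
    init_offset: tuple = (5.0, 5.0, 3.0)  # mm, mm, deg added to the true pose
    mu: tuple = (2.0, 2.0, 25.0)
    max_iter: int = 50
    gradient_steps: tuple = (0.1, 0.1, 0.1)
    gradient_mode: str = "central"
    roi_half: float = 15.0  # mm, half-extent of the coherence ROI about the vessel
    grid_fraction: float = 0.5  # grid spacing in wavelengths


@dataclass
class StrainStageConfig:
    n_layers: int = 5
    kernel: tuple = (5, 5)
    circ_node_spacing: float = 0.65  # mm at the inner contour (5 nodes ~ 2.6 mm)


@dataclass
class MetricsConfig:
    n_bins: int = 256
    erosion_radius: float = 0.6  # mm
    lateral_exclusion_deg: float = 37.5
    bmode_frame: int = 0


@dataclass
class GridsConfig:
    roi_radius: float = 16.0  # mm about the vessel center (imaging/tracking)
    track_band: tuple = (6.0, 16.0)  # mm radial band of tracked nodes
    disp_spacing: float = 0.2  # mm, common displacement-compounding grid
    bistatic_fraction: float = 0.25  # fused-image grid spacing in wavelengths


@dataclass
class PipelineConfig:
    scene: SceneConfig = field(default_factory=SceneConfig)
    seed: int = 0
    mode: str = "bistatic"  # bistatic | single_perspective | both
    grids: GridsConfig = field(default_factory=GridsConfig)
    registration: RegistrationConfig = field(default_factory=RegistrationConfig)
    tracking: TrackingParams = field(default_factory=TrackingParams)
    strain: StrainStageConfig = field(default_factory=StrainStageConfig)
    metrics: MetricsConfig = field(default_factory=MetricsConfig)
    run_registration: bool = True

    def config_hash(self) -> str:
        blob = yaml.safe_dump(_to_plain(asdict(self)), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @staticmethod
    def from_dict(d: dict) -> "PipelineConfig":
        from .simulator import NoiseModel, PhantomConfig

        d = dict(d)
        scene_d = dict(d.pop("scene", {}))
        if "phantom" in scene_d:
            scene_d["phantom"] = PhantomConfig(**scene_d["phantom"])
        if scene_d.get("noise") is not None:
            scene_d["noise"] = NoiseModel(**scene_d["noise"])
        for k in ("steering_angles",):
            if k in scene_d:
                scene_d[k] = tuple(scene_d[k])
        kwargs = {"scene": SceneConfig(**scene_d)}
        for key, cls in (
            ("grids", GridsConfig),
            ("registration", RegistrationConfig),
            ("tracking", TrackingParams),
            ("strain", StrainStageConfig),
            ("metrics", MetricsConfig),
        ):
            if key in d:
                kwargs[key] = cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in d.pop(key).items()})
        kwargs.update(d)
        return PipelineConfig(**kwargs)

    @staticmethod
    def from_yaml(path) -> "PipelineConfig":
        with open(path) as fh:
            return PipelineConfig.from_dict(yaml.safe_load(fh) or {})


def _to_plain(obj):
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


@dataclass
class RunState:
    """All artifacts produced by the pipeline stages."""

    config: PipelineConfig
    cycle: CycleData | None = None
    sector_grids: dict = field(default_factory=dict)  # rx label -> SectorGrid
    sector_images: dict = field(default_factory=dict)  # (tx, rx) -> [image per frame]
    cart_images: dict = field(default_factory=dict)  # "bistatic"/"single" -> image
    cart_grid: CartesianGrid | None = None
    registration: RegistrationState | None = None
    fields: dict = field(default_factory=dict)  # (tx, rx) -> [DisplacementField per pair]
    disp_grid: CartesianGrid | None = None
    compounded: list = field(default_factory=list)  # per frame pair: (u_rad, valid)
    sp_vectors: list = field(default_factory=list)  # per frame pair: (u_x, u_z)
    meshes: dict = field(default_factory=dict)  # mode -> [WallMesh per frame]
    strains: dict = field(default_factory=dict)  # mode -> [StrainField per frame]
    reports: dict = field(default_factory=dict)  # mode -> MetricReport
    completed: list = field(default_factory=list)

    def require(self, stage: str):
        if stage not in self.completed:
            raise RuntimeError(f"stage '{stage}' has not run; run it before continuing")


# ---------------------------------------------------------------------------
# stage implementations


def _anchor_direction(cfg: PipelineConfig) -> np.ndarray:
    """Reference-probe (probe 1) beam direction through the vessel, pointing
    from the center toward the probe — region 1 of the partition."""
    center = np.asarray(cfg.scene.phantom.vessel_center, float)
    return -(center / np.linalg.norm(center)) if np.linalg.norm(center) else np.array([0.0, -1.0])


def _vessel_sector_grid(cfg: PipelineConfig, geom, T: RigidTransform2D) -> SectorGrid:
    center_local = T.inverse().apply(np.asarray(cfg.scene.phantom.vessel_center, float))
    rel = center_local - geom.arc_center
    rc = float(np.hypot(*rel))
    depth_c = rc - geom.radius_of_curvature
    roi = cfg.grids.roi_radius
    ang_c = float(np.degrees(np.arctan2(rel[0], rel[1])))
    half_ang = float(np.degrees(np.arcsin(min(0.999, roi / rc)))) + 1.0
    return make_sector_grid(
        geom,
        depth_min=max(1.0, depth_c - roi),
        depth_max=depth_c + roi,
        c=cfg.scene.c,
        angle_min=ang_c - half_ang,
        angle_max=ang_c + half_ang,
    )


def stage_simulate(state: RunState) -> RunState:
    state.cycle = simulate_cycle(state.config.scene, state.config.seed)
    state.completed.append("simulate")
    return state


def stage_beamform(state: RunState) -> RunState:
    state.require("simulate")
    cfg = state.config
    cycle = state.cycle
    scene = cfg.scene
    geoms = {1: scene.probe(1), 2: scene.probe(2)}
    transforms = {1: RigidTransform2D(), 2: cycle.transform}
    f0 = scene.f0

    state.sector_grids = {
        rx: _vessel_sector_grid(cfg, geoms[rx], transforms[rx]) for rx in (1, 2)
    }

    pairings = [(1, 1), (2, 2), (1, 2), (2, 1)]
    state.sector_images = {p: [] for p in pairings}
    from . import _kernels

    tx_time_cache: dict = {}
    for k, frame in enumerate(cycle.frames):
        for (tx, rx) in pairings:
            grid = state.sector_grids[rx]
            per_angle = []
            for cd in frame[(tx, rx)]:
                key = (tx, rx, cd.event.steering_angle)
                if key not in tx_time_cache:
                    nodes = np.ascontiguousarray(
                        transforms[rx].apply(grid.local_points().reshape(-1, 2))
                    )
                    tx_pos = np.ascontiguousarray(transforms[tx].apply(geoms[tx].element_positions))
                    tx_time_cache[key] = _kernels.first_arrival_times(
                        nodes, tx_pos, np.ascontiguousarray(cd.event.element_delays), scene.c * 1e3
                    )
                bb = demodulate(cd, f0)
                per_angle.append(
                    das_beamform(
                        bb, geoms[tx], geoms[rx], transforms[rx], grid, scene.c,
                        T_tx=transforms[tx], tx_times=tx_time_cache[key],
                    )
                )
            state.sector_images[(tx, rx)].append(compound_angles(per_angle))

    # fused B-mode on the quarter-wavelength Cartesian grid (metrics frame)
    lam = wavelength_mm(f0, scene.c)
    center = np.asarray(scene.phantom.vessel_center, float)
    roi = cfg.grids.roi_radius
    state.cart_grid = CartesianGrid.from_extent(
        center[0] - roi, center[0] + roi, center[1] - roi, center[1] + roi,
        cfg.grids.bistatic_fraction * lam,
    )
    kf = cfg.metrics.bmode_frame
    cart = {}
    for (tx, rx) in pairings:
        per_angle = [
            das_beamform(
                demodulate(cd, f0), geoms[tx], geoms[rx], transforms[rx],
                state.cart_grid, scene.c, T_tx=transforms[tx],
            )
            for cd in cycle.frames[kf][(tx, rx)]
        ]
        cart[(tx, rx)] = compound_angles(per_angle)
    state.cart_images = {
        "single": cart[(1, 1)],
        "pairings": cart,
        "bistatic": bistatic_compound(cart[(1, 1)], cart[(2, 2)], cart[(1, 2)], cart[(2, 1)]),
    }
    state.completed.append("beamform")
    return state


def stage_register(state: RunState) -> RunState:
    state.require("simulate")
    cfg = state.config
    scene = cfg.scene
    cycle = state.cycle
    if not cfg.run_registration:
        state.completed.append("register")
        return state
    g1, g2 = scene.probe(1), scene.probe(2)
    lam = wavelength_mm(scene.f0, scene.c)
    center = np.asarray(scene.phantom.vessel_center, float)
    half = cfg.registration.roi_half
    grid = CartesianGrid.from_extent(
        center[0] - half, center[0] + half, center[1] - half, center[1] + half,
        cfg.registration.grid_fraction * lam,
    )
    channels = [demodulate(cd, scene.f0) for cd in cycle.frames[0][(1, 2)]]
    off = cfg.registration.init_offset
    T_true = cycle.transform
    T_init = RigidTransform2D(T_true.tx + off[0], T_true.tz + off[1], T_true.phi + off[2])
    state.registration = register_probes(
        channels, g1, g2, grid, T_init, c=scene.c,
        mu=cfg.registration.mu, max_iter=cfg.registration.max_iter,
        gradient_steps=cfg.registration.gradient_steps,
        gradient_mode=cfg.registration.gradient_mode,
    )
    state.completed.append("register")
    return state


def _band_mask(grid: SectorGrid, T: RigidTransform2D, center, band) -> np.ndarray:
    pts = T.apply(grid.local_points().reshape(-1, 2))
    r = np.linalg.norm(pts - np.asarray(center, float), axis=1).reshape(grid.shape)
    return (r >= band[0]) & (r <= band[1])


def stage_track(state: RunState) -> RunState:
    state.require("beamform")
    cfg = state.config
    scene = cfg.scene
    center = np.asarray(scene.phantom.vessel_center, float)
    transforms = {1: RigidTransform2D(), 2: state.cycle.transform}
    geoms = {1: scene.probe(1), 2: scene.probe(2)}
    pairings = [(1, 1), (2, 2), (1, 2), (2, 1)]
    masks = {
        rx: _band_mask(state.sector_grids[rx], transforms[rx], center, cfg.grids.track_band)
        for rx in (1, 2)
    }

    n_pairs = scene.n_frames - 1
    state.fields = {p: [] for p in pairings}
    for k in range(n_pairs):
        for (tx, rx) in pairings:
            ref = state.sector_images[(tx, rx)][k].iq
            mov = state.sector_images[(tx, rx)][k + 1].iq
            fld = coarse_to_fine_track(
                ref, mov, state.sector_grids[rx], cfg.tracking,
                node_mask=masks[rx], pairing=(tx, rx), frame_pair=(k, k + 1),
            )
            state.fields[(tx, rx)].append(fld)

    # common Cartesian grid for displacement compounding
    roi = cfg.grids.roi_radius
    dg = CartesianGrid.from_extent(
        center[0] - roi, center[0] + roi, center[1] - roi, center[1] + roi,
        cfg.grids.disp_spacing,
    )
    state.disp_grid = dg
    pts = dg.points().reshape(-1, 2)

    # per-pairing geometry on the common grid: beam directions and view angles
    from scipy.interpolate import RegularGridInterpolator

    beam_dirs = {}
    for rx in (1, 2):
        ac = transforms[rx].apply(geoms[rx].arc_center)
        d = pts - ac
        beam_dirs[rx] = d / np.linalg.norm(d, axis=1, keepdims=True)
    thetas = {}
    for (tx, rx) in pairings:
        if tx == rx:
            b = beam_dirs[rx]
        else:  # trans-probe: specular normal to the bisector of the two views
            b = beam_dirs[1] + beam_dirs[2]
            b = b / np.linalg.norm(b, axis=1, keepdims=True)
        thetas[(tx, rx)] = compute_theta(pts, center, b).reshape(dg.shape)

    sector_coords = {}
    for rx in (1, 2):
        grid = state.sector_grids[rx]
        local = transforms[rx].inverse().apply(pts)
        ang, dep = grid.to_sector_coords(local)
        sector_coords[rx] = np.stack([dep, ang], axis=1)

    state.compounded = []
    state.sp_vectors = []
    for k in range(n_pairs):
        u_rad_fields, mask_fields = {}, {}
        sp_vec = None
        for (tx, rx) in pairings:
            fld = state.fields[(tx, rx)][k]
            grid = state.sector_grids[rx]
            interp = RegularGridInterpolator(
                (grid.sample_depths, grid.beam_angles), fld.u_ax,
                bounds_error=False, fill_value=np.nan,
            )
            u_ax = interp(sector_coords[rx]).reshape(dg.shape)
            th = thetas[(tx, rx)]
            u_rad_fields[(tx, rx)] = radial_project(u_ax, th)
            mask_fields[(tx, rx)] = angular_mask(th)
            if (tx, rx) == (1, 1):
                ilat = RegularGridInterpolator(
                    (grid.sample_depths, grid.beam_angles), fld.u_lat,
                    bounds_error=False, fill_value=np.nan,
                )
                u_lat = ilat(sector_coords[rx]).reshape(dg.shape)
                d = beam_dirs[1].reshape(dg.shape + (2,))
                lat_dir = np.stack([d[..., 1], -d[..., 0]], axis=-1)
                u_vec = u_ax[..., None] * d + u_lat[..., None] * lat_dir
                sp_vec = (u_vec[..., 0], u_vec[..., 1])
        state.compounded.append(compound_displacements(u_rad_fields, mask_fields))
        state.sp_vectors.append(sp_vec)

    state.completed.append("track")
    return state


def _build_reference_mesh(cfg: PipelineConfig) -> WallMesh:
    scene = cfg.scene
    center = np.asarray(scene.phantom.vessel_center, float)
    r_in = scene.phantom.inner_radius
    n_circ = max(16, int(round(2.0 * np.pi * r_in / cfg.strain.circ_node_spacing)))
    contour = circle_contour(center, r_in, n_circ)
    return build_wall_mesh(
        contour, thickness=scene.phantom.wall_thickness, n_layers=cfg.strain.n_layers,
        center=center, check_simple=False, anterior_direction=_anchor_direction(cfg),
    )


def stage_strain(state: RunState) -> RunState:
    state.require("track")
    cfg = state.config
    mesh0 = _build_reference_mesh(cfg)
    dg = state.disp_grid
    modes = ("bistatic", "single_perspective") if cfg.mode == "both" else (cfg.mode,)
    for mode in modes:
        if mode == "bistatic":
            samplers = [
                RadialDisplacementSampler(u, dg.x_coords, dg.z_coords, mesh0.center)
                for (u, _valid) in state.compounded
            ]
        else:
            samplers = [
                VectorDisplacementSampler(ux, uz, dg.x_coords, dg.z_coords)
                for (ux, uz) in state.sp_vectors
            ]
        meshes = track_mesh(mesh0, samplers)
        state.meshes[mode] = meshes
        state.strains[mode] = least_squares_strain(meshes, reference=0, kernel=cfg.strain.kernel)
    state.completed.append("strain")
    return state


def stage_metrics(state: RunState) -> RunState:
    state.require("strain")
    cfg = state.config
    scene = cfg.scene
    anchor = _anchor_direction(cfg)
    mesh0 = _build_reference_mesh(cfg)
    waveform = scene.pulsation().radius_waveform
    peak_frame = int(np.argmax(waveform))
    keep = exclude_lateral_sections(mesh0, anchor, cfg.metrics.lateral_exclusion_deg)
    part = partition_regions(mesh0, anchor)

    grid = state.cart_grid
    wall_mask, lumen_mask = make_rois(mesh0, grid, cfg.metrics.erosion_radius)
    pix = grid.points()
    pix_ang = clockwise_angle_deg(
        (pix - mesh0.center).reshape(-1, 2), anchor
    ).reshape(grid.shape)
    pix_region = (np.floor(((pix_ang + 22.5) % 360.0) / 45.0).astype(int)) % 8 + 1

    modes = ("bistatic", "single_perspective") if cfg.mode == "both" else (cfg.mode,)
    for mode in modes:
        env = np.abs(state.cart_images["bistatic" if mode == "bistatic" else "single"].iq)
        rep = MetricReport(mode=mode, peak_frame=peak_frame)
        rep.gcnr_global = gcnr(env[wall_mask], env[lumen_mask], cfg.metrics.n_bins)
        for r in range(1, 9):
            sel = wall_mask & (pix_region == r)
            if sel.any():
                rep.gcnr_regions[r] = gcnr(env[sel], env[lumen_mask], cfg.metrics.n_bins)
        meshes = state.meshes[mode]
        # begin/end of cycle at end-diastole: frames of minimal inner radius
        ed_frames = np.flatnonzero(np.isclose(waveform, waveform.min()))
        bs, ed = int(ed_frames[0]), int(ed_frames[-1])
        rep.me = mean_drift_error(meshes[bs], meshes[ed])
        d = np.linalg.norm(
            meshes[bs].middle_layer() - meshes[ed].middle_layer(), axis=1
        )
        for r in range(1, 9):
            sel = part.region_index == r
            if sel.any():
                rep.me_regions[r] = float(np.mean(d[sel]))
        sf = state.strains[mode][peak_frame]
        mid = mesh0.middle_layer_index
        rep.snre_circ = snre(sf.eps_circ[mid][keep])
        rep.snre_rad = snre(sf.eps_rad[mid][keep])
        state.reports[mode] = rep
    state.completed.append("metrics")
    return state


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "beamform": stage_beamform,
    "register": stage_register,
    "track": stage_track,
    "strain": stage_strain,
    "metrics": stage_metrics,
}


def run_pipeline(config: PipelineConfig, stages=None, state: RunState | None = None) -> RunState:
    """Run a contiguous prefix of the pipeline stages on ``config``.

    ``stages`` defaults to all six; it must be a contiguous prefix of
    ``STAGES`` (optionally continuing a partially-run ``state``).
    """
    stages = list(stages) if stages is not None else list(STAGES)
    idx = [STAGES.index(s) for s in stages]
    if idx != list(range(idx[0], idx[0] + len(idx))):
        raise ValueError(f"stages must be a contiguous run of {STAGES}")
    state = state or RunState(config=config)
    for s in stages:
        if s in state.completed:
            continue
        state = _STAGE_FUNCS[s](state)
    return state
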