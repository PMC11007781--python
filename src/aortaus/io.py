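"""HDF5 persistence of pipeline runs.

The container stores the configuration (as YAML), seed and config hash as
root attributes, plus the ground truth, registration trace, compounded
displacement fields, tracked meshes, strain fields and metric reports.  Raw
per-channel data are not persisted (they are cheap to regenerate from the
seed); the stored artifacts are sufficient to rerun the ``metrics`` stage
offline.
"""

from __future__ import annotations

from dataclasses import asdict

import h5py
import numpy as np
import yaml

from .geometry import CartesianGrid, RigidTransform2D
from .metrics import MetricReport
from .pipeline import PipelineConfig, RunState, _to_plain
from .register import RegistrationState
from .strain import StrainField, WallMesh

__all__ = ["save_run", "load_run"]


def save_run(state: RunState, path) -> None:
    cfg = state.config
    with h5py.File(path, "w") as f:
        f.attrs["config_yaml"] = yaml.safe_dump(_to_plain(asdict(cfg)), sort_keys=True)
        f.attrs["config_hash"] = cfg.config_hash()
        f.attrs["seed"] = cfg.seed
        f.attrs["completed"] = ",".join(state.completed)

        if state.cycle is not None:
            g = f.create_group("truth")
            g.create_dataset("transform", data=state.cycle.transform.as_vector())
            g.create_dataset("radius_waveform", data=state.cycle.model.radius_waveform)
            g.create_dataset("scatterer_positions", data=state.cycle.phantom_rest.positions)
            g.create_dataset("scatterer_labels", data=state.cycle.phantom_rest.labels)
            g.create_dataset(
                "displacements", data=np.stack(state.cycle.truth_displacements)
            )

        if state.registration is not None:
            g = f.create_group("registration")
            g.create_dataset("objective_history", data=np.asarray(state.registration.objective_history))
            g.create_dataset("T", data=state.registration.T.as_vector())
            g.attrs["converged"] = state.registration.converged
            g.attrs["diverged"] = state.registration.diverged
            g.attrs["iteration"] = state.registration.iteration

        if state.cart_grid is not None and state.cart_images:
            g = f.create_group("bmode")
            g.create_dataset("x_coords", data=state.cart_grid.x_coords)
            g.create_dataset("z_coords", data=state.cart_grid.z_coords)
            for name in ("bistatic", "single"):
                g.create_dataset(name + "_envelope", data=np.abs(state.cart_images[name].iq))

        if state.compounded:
            g = f.create_group("displacement")
            g.create_dataset("x_coords", data=state.disp_grid.x_coords)
            g.create_dataset("z_coords", data=state.disp_grid.z_coords)
            g.create_dataset("u_rad", data=np.stack([u for u, _ in state.compounded]))
            g.create_dataset("valid", data=np.stack([v for _, v in state.compounded]))
            if state.sp_vectors and state.sp_vectors[0] is not None:
                g.create_dataset("sp_u_x", data=np.stack([v[0] for v in state.sp_vectors]))
                g.create_dataset("sp_u_z", data=np.stack([v[1] for v in state.sp_vectors]))

        for mode, meshes in state.meshes.items():
            g = f.create_group(f"mesh/{mode}")
            g.create_dataset("nodes", data=np.stack([m.nodes for m in meshes]))
            g.attrs["thickness"] = meshes[0].thickness
            g.create_dataset("center", data=meshes[0].center)
        for mode, strains in state.strains.items():
            g = f.create_group(f"strain/{mode}")
            g.create_dataset("eps_rad", data=np.stack([s.eps_rad for s in strains]))
            g.create_dataset("eps_circ", data=np.stack([s.eps_circ for s in strains]))
            g.attrs["reference_frame"] = strains[0].reference_frame
        for mode, rep in state.reports.items():
            g = f.create_group(f"metrics/{mode}")
            for k, v in rep.as_dict().items():
                g.attrs[k] = v


def load_run(path) -> RunState:
    """Restore the persisted artifacts of a run (not the raw channel data)."""
    with h5py.File(path, "r") as f:
        cfg = PipelineConfig.from_dict(yaml.safe_load(f.attrs["config_yaml"]))
        state = RunState(config=cfg)
        state.completed = [s for s in str(f.attrs["completed"]).split(",") if s]

        if "registration" in f:
            g = f["registration"]
            state.registration = RegistrationState(
                T=RigidTransform2D.from_vector(g["T"][()]),
                mu=np.asarray(cfg.registration.mu),
                objective_history=list(g["objective_history"][()]),
                iteration=int(g.attrs["iteration"]),
                converged=bool(g.attrs["converged"]),
                diverged=bool(g.attrs["diverged"]),
            )
        if "displacement" in f:
            g = f["displacement"]
            state.disp_grid = CartesianGrid(g["x_coords"][()], g["z_coords"][()])
            u = g["u_rad"][()]
            v = g["valid"][()]
            state.compounded = [(u[k], v[k]) for k in range(u.shape[0])]
            if "sp_u_x" in g:
                ux, uz = g["sp_u_x"][()], g["sp_u_z"][()]
                state.sp_vectors = [(ux[k], uz[k]) for k in range(ux.shape[0])]
        if "mesh" in f:
            for mode in f["mesh"]:
                g = f[f"mesh/{mode}"]
                nodes = g["nodes"][()]
                center = g["center"][()]
                th = float(g.attrs["thickness"])
                state.meshes[mode] = [
                    WallMesh(nodes=nodes[k], thickness=th, center=center, frame_index=k)
                    for k in range(nodes.shape[0])
                ]
        if "strain" in f:
            for mode in f["strain"]:
                g = f[f"strain/{mode}"]
                er, ec = g["eps_rad"][()], g["eps_circ"][()]
                ref = int(g.attrs["reference_frame"])
                state.strains[mode] = [
                    StrainField(er[k], ec[k], np.isfinite(er[k]), ref, k)
                    for k in range(er.shape[0])
                ]
        if "metrics" in f:
            for mode in f["metrics"]:
                g = f[f"metrics/{mode}"]
                rep = MetricReport(mode=mode)
                rep.gcnr_global = float(g.attrs.get("gcnr_global", np.nan))
                rep.me = float(g.attrs.get("me_mm", np.nan))
                rep.snre_circ = float(g.attrs.get("snre_circ_db", np.nan))
                rep.snre_rad = float(g.attrs.get("snre_rad_db", np.nan))
                rep.peak_frame = int(g.attrs.get("peak_frame", -1))
                state.reports[mode] = rep
    return state
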