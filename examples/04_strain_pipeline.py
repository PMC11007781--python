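"""Full elastography pipeline: bistatic vs single-perspective strain.

Simulates one pulsation cycle of an incompressible-ring vessel (2% peak
inner-radius excursion), tracks the four pairings, compounds the radial
displacements with the angular masks, advects the wall mesh, and estimates
radial/circumferential strain.  The same data processed single-perspective
(T1R1 only, no radial projection) show the lateral-wall drift the bistatic
method removes.  Runs a reduced problem size (~2 min).
"""

import numpy as np

from aortaus.metrics import exclude_lateral_sections
from aortaus.pipeline import PipelineConfig, run_pipeline
from aortaus.simulator import analytic_strain

cfg = PipelineConfig()
cfg.mode = "both"
cfg.seed = 5
cfg.scene.n_elements = 48
cfg.scene.steering_angles = (-12.0, 0.0, 12.0)
cfg.scene.n_frames = 7
cfg.run_registration = False  # pose is taken as known here; see example 03

state = run_pipeline(cfg)

model = state.cycle.model
peak = int(np.argmax(model.radius_waveform))
mesh0 = state.meshes["bistatic"][0]
mid = mesh0.middle_layer_index
r_mid = np.linalg.norm(mesh0.middle_layer() - mesh0.center, axis=1)
_, truth = analytic_strain(model, peak, r_mid)
keep = exclude_lateral_sections(mesh0, np.array([0.0, -1.0]))

print(f"peak systole at frame {peak}: true circumferential strain "
      f"{truth.mean():.4f} at the mid-wall")
for mode in ("bistatic", "single_perspective"):
    est = state.strains[mode][peak].eps_circ[mid]
    err = np.nanmax(np.abs(est[keep] - truth[keep]))
    rep = state.reports[mode]
    print(f"{mode:18s} max |strain error| {err:.4f}   drift error {rep.me:.3f} mm   "
          f"SNRe_circ {rep.snre_circ:5.1f} dB")
# The bistatic drift error is far below the single-perspective one: lateral
# wall motion is recovered from the second probe's axial displacements
# instead of the noisy lateral estimates of a single aperture.
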