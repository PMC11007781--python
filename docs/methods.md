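# Methods

`aortaus` implements bistatic dual-aperture ultrasound imaging and strain
elastography of a vessel cross-section, together with a synthetic acquisition
model that supplies the analytic ground truth such methods lack in vivo.
This note documents the models, the tunable parameters, the numerical
choices, and what the synthetic experiments do and do not show.

## Coordinate conventions

Points are `(x, z)` in millimetres: x lateral (positive right), z depth
(positive downward), origin at the surface apex of the reference probe
(probe 1), whose local frame is the global frame. Rotations are
counterclockwise-positive with `R(phi) @ (x, z)` so `phi = 90 deg` maps
`(1, 0)` to `(0, 1)`. The pose of probe 2 is a rigid transform
(`tx`, `tz` in mm; `phi` in degrees) from its local frame to the global
frame. Steering angles are measured against z at the probe origin.

## Acquisition model

Each probe is a convex curved array (defaults model a C5-2v-class abdominal
probe: 3.7 MHz centre frequency, 0.508 mm pitch, 49.57 mm radius of
curvature; element count is configurable and the desk-scale scenes use 64).
A transmit event is a diverging wave: the virtual source sits behind the
probe apex at a configurable standoff (default: the radius of curvature, so
at zero steering it coincides with the arc center) along the steered
direction, which makes the wavefront normal at the probe origin equal the
steering angle exactly. Element delays are the source-to-element distances
divided by the sound speed, offset to a zero minimum; transmit apodization
is a Tukey window (taper ratio 0.25 by default). The standard scene uses
five steering angles spanning ±12 degrees. In the interleaved dual-probe
scheme the probes transmit alternately and both receive on every event,
yielding the four signals T1R1, T2R2, T1R2, T2R1 per frame; with 15
transmits per probe at a 4 kHz pulse repetition frequency the time between
the probes' bursts is 3.75 ms, short enough that the phantom is held static
within a frame.

## Synthetic scene and ground truth

The phantom is a point-scatterer scene: an echogenic vessel-wall annulus
(inner radius 10 mm, uniform thickness 1.7 mm) around an anechoic lumen,
diffuse background speckle filling a ~40 x 40 mm field, and an optional
bright spine arc below the vessel (off by default). Scatterer counts are
Poisson draws from configured densities (wall 20 /mm², background 1.5 /mm²,
about 5,000 scatterers total); reflectivities are Gaussian with per-region
scales.

Wall and spine scatterers scatter **specularly**: each carries a unit
surface normal (radial for the wall) and its echo is weighted by
`d + (1 - d) |n . b|^p`, where `b` is the bisector of the directions to the
transmit and receive elements (the mirror law for a bistatic geometry),
`p = 30` (half-intensity lobe ≈ ±12 deg) and diffuse floor `d = 0.2`. This
is what makes the simulated scenes exhibit the physics the dual-aperture
method addresses: wall segments parallel to a probe's beam reflect away from
that probe, so a single perspective sees bright anterior/posterior walls and
dim lateral walls, while the second aperture and the trans-probe pairings
fill in the lateral segments. The weighting is symmetric in transmit and
receive, so acoustic reciprocity is preserved. Background scatterers are
isotropic.

Wall motion follows an incompressible ring: if the inner radius moves from
`r_i0` to `r_i(t)`, a wall point at rest radius `r` maps to
`r' = sqrt(r² + r_i(t)² - r_i0²)`, which conserves wall cross-section area
exactly. Ground-truth circumferential strain at rest radius `r` is
`r'/r - 1` and radial strain `r/r' - 1`. The standard cycle is a raised
cosine of the inner radius with a 0.2 mm (2%) peak excursion over 9 frames,
returning to rest at the last frame; a uniform-scaling
(`prescribed_strain`) mode exists for controlled tests. The per-frame
scatterer displacements, the analytic strain and the true probe-2 pose are
stored alongside every simulated cycle.

The forward model is linear single scattering: every channel sample is the
sum over scatterers of reflectivity x element directivities (cosine of the
angle off the element normal, zero beyond 90 deg) x specular weight x a
Gaussian-modulated cosine pulse (-6 dB fractional bandwidth 0.6) at the
round-trip time, sampled at 14.8 MHz (4x the carrier). Transmit timing uses
the *first arrival* over elements of (element delay + travel time) — a
geometric approximation of the diverging wavefront that keeps a full
desk-scale cycle to seconds. An exact element-pair-summation model
(`tx_model="full"`, one pulse per transmit-element/scatterer/receive-element
triple) serves as the reference in the reciprocity tests; it is an order of
magnitude slower and used only at test scale. Additive white Gaussian
channel noise at a configured SNR is available and off by default, so the
oracle tests see a deterministic signal chain. No attenuation, aberration or
multiple scattering is modelled.

What this phantom does **not** emulate: physiologic inhomogeneity of wall
properties, out-of-plane motion, abdominal-wall aberration and reverberation
clutter, blood signal, and the scanner's true pulse and element sensitivity.
Quantities that depend on absolute in vivo contrast or error levels (the
study's 20-volunteer statistics) are therefore out of reach by design; the
synthetic experiments validate the *relationships* the method claims
(bistatic > single-perspective in lateral contrast, drift and strain
precision) and the estimator's accuracy against analytic ground truth.

## Beamforming and fusion

Channel data are demodulated to complex baseband (analytic signal via
Hilbert transform, mixed down by the carrier). Delay-and-sum reconstruction
interpolates the baseband linearly at the total delay (first-arrival
transmit time to the node + node-to-element receive time) and rotates by the
carrier phase `exp(+j 2 pi f0 tau)`; the output is therefore the analytic RF
signal (`abs` = envelope, `real` = RF). Receive elements more than 45 deg
off their normal (configurable) or with delays outside the record contribute
zero; there is no receive apodization. Grids: registration images use a
half-wavelength Cartesian grid; the fused B-mode a quarter-wavelength
Cartesian grid; displacement tracking a per-receive-probe sector grid with
2 lines per element pitch laterally and lambda/8 (0.051-0.052 mm) axial
spacing, where "axial" is along the receive beam. Steering angles are
compounded coherently (complex sum), and the four pairings fuse as
`I_bistatic = I_T1R1 + I_T2R2 + (I_T1R2 + I_T2R1)/2` — the trans-probe
pair carries reciprocal information and is averaged. Note that with
receive-only focusing the two trans-probe images have transposed one-way
point-spread functions, so they agree structurally (smoothed envelopes) but
not speckle-for-speckle.

## Probe localization

The probe-2 pose is found by maximizing the coherence of the
angle-compounded T1R2 image, i.e. gradient descent on the negative signal
power `P- = -sum |A_i|²` of its envelope over a region of interest centred
on the vessel (default 30 x 30 mm at half-wavelength spacing; the imaged
region is configurable). Gradients are central finite differences (default
steps: 0.1 mm ≈ lambda/4 for translations, 0.1 deg for rotation; a
forward-difference mode sharing one base evaluation exists). Only the
receive leg depends on the pose, so the transmit arrival times per angle are
precomputed once and an objective evaluation costs one receive-side sum per
angle.

Two properties of the coherence surface drive the optimizer design:

* a sharp peak (width ~ half a wavelength) sits on a long shallow tail, so a
  fixed step length either crawls on the tail or overshoots the peak — the
  descent therefore uses heavy-ball momentum (0.85) plus a global step
  factor that grows 1.25x after accepted steps and halves on backtracking;
  a step that still increases the objective after exhausting backtracking is
  rejected outright (an accepted uphill move can strand the pose in a
  signal-free region);
* rotating the pose about the vessel center maps the bright wall ring nearly
  onto itself (a 1-degree "orbit" costs only ~5% of the peak power), so the
  three degrees of freedom are optimized as two translations plus a rotation
  about the ROI center, and that orbit parameter gets a proportionally
  larger learning rate (default `mu = (2, 2, 25)` in mm resp. degrees per
  unit relative power gradient, after normalizing the objective by its
  starting magnitude).

Convergence is declared when, having improved on the start, both the
objective (change < 5% of the starting magnitude, for 3 consecutive
iterations) and the pose (steps < 0.05 mm / 0.05 deg) hold constant, and a
subsequent audit finds no better pose on a multi-scale stencil
(per-parameter offsets up to ~1 mm / ~1.25 deg plus pattern moves
extrapolating the recent progress direction; an improving probe is taken
and the descent continues). The audit exists because the power surface has,
besides speckle-scale ripple, a second near-degenerate direction: a combined
translation + small rotation that slides the reconstructed trans-probe image
while barely defocusing the one-way receive aperture costs only a few
percent of power per millimetre, so power constancy alone can leave a
residual of a millimetre or more. Even with the audit, the achievable
accuracy is bounded by a speckle-dependent bias of the power optimum along
that direction (0.05-0.5 mm across phantom realizations). Runs that grow the
objective for 10 consecutive iterations are flagged divergent; the best-seen
pose and the full objective history are always returned — the surface has
genuine local minima far from the truth, and the caller must judge the
objective value rather than assume global optimality. On the standard
noiseless scene, a (5 mm, 5 mm, 3 deg) initialization error converges in
~40 iterations to 0.05 mm and 0.08 deg.

The elastography stages of the pipeline use the known (true) pose;
registration is evaluated as its own stage so that calibration error does
not confound the strain validation.

## Displacement estimation and compounding

Frame-to-frame motion is estimated per pairing on the receive probe's sector
grid by two-pass block matching: a coarse pass on the envelope (kernel
2.6 x ~5.2 mm, search 3.0 x ~5.7 mm, zero-mean normalized cross-correlation,
on a decimated node lattice, median filtered) seeds a fine pass on the RF
(kernel 0.8 x ~2.4 mm, search 1.0 x ~2.85 mm, raw normalized correlation),
followed by an 11 x 11-pixel median filter (reflected edges; untracked
nodes are nearest-filled before filtering and restored after). Millimetre
sizes are converted to whole pixels with the local, depth-dependent line
pitch, which reproduces fixed pixel counts across depth. Sub-sample lags
come from parabolic interpolation of the correlation through the integer
argmax, clamped to ±0.5 samples; ties prefer the smallest-magnitude lag, and
nodes whose kernel or search window leaves the grid are invalid rather than
padded. A zero-variance kernel returns zero displacement with quality 0.
Tracking is restricted to a radial band around the wall (6-16 mm from the
vessel center by default).

Axial displacements are projected radially, `u_rad = u_ax / cos(theta)`,
with `theta` the angle between the receive-beam direction and the outward
radial direction from the (fixed) vessel center; nodes with `theta` in
[70 deg, 110 deg] are cut out to avoid the projection blowing up. For the
trans-probe pairings `theta` is computed against the bisector of the two
probes' beam directions at the node, since a bistatic echo is specular
normal to the bisector. Each projected field is weighted by
`M = cos(2 theta)/2 + 1/2` (zero in the cut-out), the trans-probe fields
carry half weight, and the weights are renormalized per node so the fused
field is displacement-valued; nodes with no active contribution are marked
invalid. Lateral displacement estimates are kept for quality control but
never compounded. Fusion happens on a common 0.2 mm Cartesian grid to which
each pairing's axial field is interpolated bilinearly in its sector
coordinates.

## Wall mesh and strain

The wall is meshed from an inner-contour segmentation (in the simulated
scenes: a circle at the known lumen radius standing in for the manual
segmentation), extrapolated outward along local normals by the uniform
1.7 mm wall thickness into 5 radial layers — enough for the 5-node radial
strain kernel with a genuine middle layer. The circumferential node spacing
is ~0.65 mm at the inner contour so 5 circumferential nodes span ~2.6 mm.
The contour is oriented clockwise (as displayed) starting at the anterior
point. The mesh is advected Eulerian-style: at each frame pair every node
samples the fused radial displacement at its current position and moves
along the fixed radial direction (single-perspective mode instead applies
the T1R1 axial+lateral vector without projection, mirroring a single-probe
analysis); nodes leaving field coverage are carried by their last valid
displacement and flagged.

Strain is computed against the reference (first) frame: per node, both
displacement components over a 5 x 5 node neighbourhood (radial kernel
truncated at the mesh edges, circumferential wrapping the closed contour)
are fitted affinely against the reference positions; the symmetric part of
the fitted displacement gradient is projected on the node's reference-frame
radial and circumferential directions. Fitting the full 2-D displacement
(rather than the radial component alone) makes the estimator exact on
affine deformations and yields the correct hoop strain `u_r / r` for a pure
dilation. Radial/circumferential axes are fixed from the reference geometry
and midpoint; time-varying local frames are out of scope.

## Quality metrics

* **gCNR** between wall and lumen: one minus the overlap of the two regions'
  envelope-amplitude histograms, 256 equal-width bins over the pooled range
  (stable to within ~0.03 against 128/512 bins); an exactly
  monotone-invariant variant with rank (quantile) bin edges is available.
  The wall ROI is the mesh annulus; the lumen ROI is the inner contour
  eroded by a 0.6 mm disk so specular wall reflections are excluded.
* **Regional analysis**: 8 clockwise sectors of 45 deg about the vessel
  center, regions 1 and 5 centred on the reference-probe axis (region 1
  anterior).
* **Mean drift error (ME)**: mean distance between corresponding
  middle-layer nodes at the cycle's first and last end-diastole (frames of
  minimal inner radius — exact for the simulated waveform).
* **SNRe** = `20 log10(|mean| / sd)` of the middle-layer strain; the
  magnitude of the mean is used so contracting strains report the same
  precision as expanding ones; zero variance returns +inf, flagged to the
  caller.
* Strain statistics exclude two lateral sections of the wall (default
  37.5 deg wide, centred on the directions perpendicular to the
  reference-probe axis) where neither aperture contributes reliable signal.
* **Paired comparisons** across regions or datasets use a paired t-test when
  the differences pass Shapiro-Wilk normality at 0.05 and a Wilcoxon
  signed-rank test otherwise, reporting which test ran.

## Problem sizes and runtime

The standard scene — 64 elements per probe, 5 angles, 9 frames, ~5,000
scatterers, all four pairings beamformed and tracked, both analysis modes —
was chosen so a complete simulate-to-metrics run plus a registration takes
a few minutes on one CPU core (the hot loops are numba-compiled). Accuracy
at this size: peak circumferential strain recovered within ~0.003 absolute
of the 0.017-0.02 ground truth; bistatic drift error ~0.001 mm versus
~0.02-0.03 mm single-perspective; registration residual ~0.1-0.15 mm.
Larger scenes (128 elements, 15 angles, multiple cycles) scale linearly in
elements x scatterers x events and are configurable but not exercised by
the test suite.

## Known limitations

* The first-arrival transmit model slightly blurs off-axis transmit timing
  relative to a full wavefront sum; the DAS uses the same model, so the
  mismatch cancels in the oracle tests but absolute point-spread functions
  differ from a physical scanner's.
* Trans-probe images agree structurally, not speckle-exactly (transposed
  one-way PSFs); fusion and displacement compounding do not rely on
  speckle-level agreement.
* The registration objective has local minima for gross initialization
  errors (tens of mm / tens of degrees); the optimizer reports its objective
  history instead of claiming global optimality, and a plain fixed-step
  variant (momentum 0, no backtracking) is available for comparison.
* gCNR in noiseless scenes sits near its ceiling because the lumen is
  strictly anechoic; with channel noise enabled the contrast ordering is
  unchanged but absolute values drop toward in vivo ranges.
* Strain accuracy degrades if the tracked band or the mesh leaves the
  displacement-field coverage; nodes are then carried by their last valid
  displacement and flagged rather than extrapolated.
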