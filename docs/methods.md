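# Methods

`cbct4d` reconstructs time-ordered (4D) cone-beam CT image series of
non-periodically moving anatomy from a single gantry rotation, and
reproduces the digital-phantom experiment that quantifies the temporal
resolution of four reconstruction strategies.

## Model

### Acquisition and data model

A circular cone-beam scan is described by the source-to-axis distance
(SAD, default 1000 mm), source-to-detector distance (SDD, default
1536 mm), a flat panel of `rows x cols` elements (default 512 x 512 at
0.8 mm pitch), an optional cross-line panel offset (0 / 115 / 190 mm
for the S / M / L field-of-view collimations of a linac-mounted kV
imager), and a schedule of gantry angles with acquisition timestamps
(default 360 one-degree frames in 60 s, i.e. 6 deg/s).  SAD, SDD and
pitch are package defaults chosen as typical values for this class of
device; every one of them is configurable.

The forward model is monochromatic line-integral transmission: a single
ray to each detector element center, with the system matrix holding the
exact Siddon intersection lengths between each ray and the voxel grid.
Measured counts follow a Poisson model `n_i ~ Poisson(n0 exp(-y*_i))`
with `y* = A mu`.  The mu-dependent part of the negative log-likelihood,

    L(mu) = sum_i [ n_i y*_i + n0 exp(-y*_i) ],

is the data term; its gradient is `A^T (n - n0 exp(-y*))`.  Detector
cell size, scatter, beam hardening and detector blur are intentionally
outside the model.

### Regularization

MAP reconstruction maximizes the log-posterior, i.e. minimizes
`L(mu) + lambda R(mu)` subject to `mu >= 0`, with

    R(mu) = alpha ||Psi mu||_1  +  beta ||Psi(mu - mu_prior)||_1
            + gamma * (time-chain term),

where `||Psi mu||_1` is the isotropic total variation with forward
differences and a smoothing constant `epsilon` inside the square root
(default 1e-8 mm^-2) so the objective is differentiable.  The weight
presets are (1.0, 0, 0) for TV-only compressed sensing (TVCS),
(0.1, 0.9, 0) for prior-image constrained compressed sensing (PICCS),
and (0.1, 0, 0.9) for the time-ordered chain regularizer (TCGM).

The time-chain term couples each phase image to its temporal
neighbors.  Two readings of the coupling are implemented:

* `sum_of_norms` — `TV(mu_t - mu_{t-1}) + TV(mu_t - mu_{t+1})`, i.e.
  each neighbor difference is penalized separately;
* `second_difference` (default) — the gradient fields of the two
  differences are summed *before* the norm, which by linearity equals
  `TV(2 mu_t - mu_{t-1} - mu_{t+1})`: a second temporal difference
  that is transparent to constant-velocity motion and only penalizes
  temporal irregularity.

At the first and last phases the single available one-sided difference
is doubled, so every phase feels a comparable temporal pull.  The
distinction matters: for a uniformly translating object the
sum-of-norms coupling actively prefers temporally blurred solutions
(the difference of two sharp shifted cavities has more total variation
than the difference of two blurred ones), whereas the second-difference
form is free for sharp uniformly-moving series in the continuum limit
(discretization leaves a residual penalty proportional to the spatial
second derivative times the squared per-phase displacement).  Both forms are
exposed; the per-phase `tcgm_term` API function implements the
sum-of-norms contract (interior: sum of the two one-sided TVs;
boundary: doubled one-sided TV).

### Two-step workflow

1. **Step i** — an FDK reconstruction of the full scan initializes a
   TVCS reconstruction of T = 9 phases with 200-degree windows
   (180 degrees plus the fan angle: the shortest angular range that is
   self-sufficient for a 40 cm field of view).
2. **Step ii** — the TVCS series initializes either PICCS (with the
   per-phase TVCS images as the static prior) or TCGM (no static
   prior; the dynamic neighbors provide the constraint) on 90-degree
   windows.  With `gamma > 0` all phases are updated within the same
   outer iteration (Gauss-Seidel sweep), so the coupling always uses
   the latest neighboring iterates.

### Phase binning

Phases are equally spaced in acquisition time; phase t's window is the
contiguous run of projections whose gantry angle lies within half the
window extent of the phase-center angle, clamped to the acquired range
(the first and last windows are therefore asymmetric and shorter).
Windows overlap whenever the extent exceeds the phase spacing.

## Optimization

Each phase's block objective (its data window plus all regularizer
terms that reference its image) is minimized by monotone accelerated
projected gradient descent: Nesterov extrapolation, a diagonally
preconditioned step, backtracking on a sufficient-decrease condition,
and monotone acceptance (an iterate is kept only if it lowers the block
objective; otherwise the momentum restarts).  The preconditioner is the
classic transmission curvature majorizer `D = A^T (n * A 1)` plus the
local curvature of the smoothed TV terms, floored at 0.1% of its mean
so rarely-sampled edge voxels cannot take unbounded steps.  Because
every accepted step lowers an exact block restriction of the recorded
global objective, the per-outer-iteration objective log is
non-increasing by construction; this is asserted in the test suite.
Plain (unpreconditioned) projected gradient descent was tried first and
converged far too slowly to be usable: the Poisson data term's
curvature varies by orders of magnitude between well- and
poorly-traversed voxels.

The global regularization strength lambda, when not given, is
auto-balanced at the initial iterate: lambda is `balance` times the
median over phases of the ratio of data-gradient to
regularizer-gradient norms.  This rule is deliberately method-adaptive.
At the start of the refinement stage the image equals the PICCS prior,
so the prior term contributes nothing to the denominator and PICCS
receives a large lambda — it stays constrained to its prior, which is
the behavior that defines the method.  The time-chain gradient is
already active at the same initial point (neighboring phases differ),
so TCGM receives a proportionally small lambda and remains data-driven.
An alternative rule referenced to the data stiffness
(`lambda = balance * 0.1 * mu_scale * median(D)`), which ignores how
well the start fits, is available as `lambda_rule="curvature"`; under
that rule both refinement methods receive similar lambdas, and the
chain coupling at such strengths measurably widens the moving cavity
(see limitations below).

## Digital phantom and simulation

The phantom is an elliptic cylinder (semi-axes 110 x 80 mm, attenuation
0.02 mm^-1, values consistent with the display window the experiment
uses) containing a 3 cm air sphere that translates 3 cm along the
rotation axis at constant speed: across the whole 60 s rotation
(0.5 mm/s) or during the central 30 s while the source sweeps from the
90- to the 270-degree position (1.0 mm/s).  Each projection frame sees
the phantom frozen at its timestamp; center-sampled voxelization;
noiseless line integrals (Poisson sampling is available but the study
conditions are noiseless, with n0 = 1e5 entering only as the
statistical weighting of the data term).

The simulator emulates exactly what the experiment needs — rigid
single-structure motion in a uniform background — and none of what real
pelvic scans contain: anatomy, scatter, beam hardening, detector lag,
gantry flex. Passing the phantom tests therefore validates the
reconstruction and metric chain, not clinical image quality.

## Metrics

* **Penumbral width**: the attenuation profile along the central axis
  (bilinear value at x = y = 0, i.e. the mean of the four adjacent
  voxel columns on an even grid) is inverted and normalized to [0, 1]
  between the background level and the cavity minimum; the 10% and 90%
  crossings of each cavity edge are located by linear interpolation and
  the mean of the two edge widths is reported (the two edges are also
  retained individually).  The background, when not supplied, is the
  median of profile samples at least one first-pass cavity-diameter
  away from the cavity center.
* **Occupancy oracle**: for constant-speed motion of extent L the
  time-averaged sphere occupancy of an axial position is a trapezoid
  with ramp width min(L, 2R); its 10-90% width is 0.8 min(L, 2R) —
  24.0 mm for L = 30, R = 15.  A full-rotation time-averaging
  reconstruction (FDK) must reproduce this closed form, which anchors
  the whole metric chain analytically.
* **ROI consistency**: mean pixel value of a circular ROI per phase,
  reported as RMSE over phases normalized by the ROI mean of a
  reference image (percent).  A 316-pixel disc on a 1 mm grid has
  radius 10.03 px; the disc is rasterized with its center on a pixel
  corner, which reproduces exactly 316 pixels (center-of-pixel
  rasterization gives 317).

## Truncated-projection extension

Offset-panel (M FOV) scans truncate every frame on one side.  Before
TV-based reconstruction the frames are extended: (1) FDK of the whole
object from all truncated projections, with sine-feathered redundancy
weights on the doubly-covered central band; (2) reprojection of that
volume onto a widened virtual panel that keeps the real panel's center
and column lattice and adds `ceil(offset/pitch)` columns per side (512
columns + 115 mm offset at 0.8 mm pitch extend to exactly 800); (3) a
mosaic keeping measured values wherever the real panel covers, with a
5-column linear cross-fade into the reprojected periphery.  The virtual
panel keeps the real center (rather than re-centering on the axis)
because the lateral offset is not an integer number of detector
pitches; re-centering would break the one-to-one column mapping that
makes the mosaic exact on measured columns.

## Problem sizes and protocol

The package's canonical full-resolution conditions are a 256 x 256 x 90
grid at 1 mm voxels, a 512 x 512 panel and 360 one-degree projections.
The bundled tests and the acceptance script run a reduced-resolution
preset with identical physics: 64 x 64 x 48 grid at 4 x 4 x 1.75 mm
voxels, a 56 x 96 panel at 2.4 x 4.27 mm pitch, and 120 three-degree
projections in 60 s.  The detector pitch is chosen to (over)sample the
voxel grid at the isocenter in both directions; an undersampled panel
adds a spurious null space in which limited-window reconstructions
drift toward temporally blurred solutions, an artifact of the scaled
geometry rather than of the methods.

The preset protocol runs 30 TVCS iterations (balance 0.01 of the
auto-lambda ratio) and 40 refinement iterations (balance 0.005).  These
balances were calibrated once on the phantom so that the TVCS stage
lands near its window-limited blur rather than over-sharpening through
the TV staircase effect, and so that the refinement stage is
data-dominated; they are package protocol constants, configurable per
run.  Iterative refinement is early-stopped: like most edge-preserving
penalized-likelihood reconstructions, the penumbra narrows quickly in
the first tens of iterations and then drifts as the temporal coupling
slowly equalizes the phase images, so the iteration count is part of
the protocol rather than a convergence target.

## Known limitations

* The reference experiment leaves lambda, the iteration counts, the
  optimizer and the acquisition distances unstated; the widths this
  package computes therefore carry hyperparameter sensitivity, and its
  defaults are declared package choices.
* The temporal chain does not, at this scale, buy measurable axial
  sharpness beyond what the narrow-window data term alone achieves: at
  coupling strengths comparable to the PICCS prior weight, both chain
  readings *widen* the moving cavity (a uniformly translating sharp
  cavity has a higher chain penalty, via its discretized temporal
  second difference, than a blurred one), and at the small
  automatically balanced strength the chain is nearly inert, leaving
  the 90-degree-window refinements — chain-coupled and prior-pinned —
  within about 0.1 mm of each other on the middle phase.  The
  sum-of-norms reading penalizes uniform motion even more strongly
  than the second-difference reading, which is the default for this
  reason.  The chain's practical benefit in this implementation is
  volumetric: chain-coupled series consistently reach the lowest
  whole-volume RMSE against the ground-truth phantom of all methods.
* Offset-detector FDK weighting is implemented only as far as the
  extension procedure needs it; short-scan (Parker-weighted) FDK is out
  of scope.
* Real patient acquisitions (scatter, polychromatic spectra,
  respiratory signals) are outside the scope of the simulator and of
  the validation.
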