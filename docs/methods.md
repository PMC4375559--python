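# Methods

## Hydraulic network model

The trap array is modelled as a lumped one-dimensional resistance network
rather than a finite-element flow field.  Every channel piece — main-row
segment, plug, serpentine turn, manifold feed — is a rectangular duct with
Poiseuille resistance

    R = 12 µ L / (w h³ (1 − 0.63 h/w)),   w ≥ h,

the standard first-order aspect-ratio correction, accurate to a few
percent over the device's aspect ratios (w/h from 1 to 10).  Node
pressures follow from Kirchhoff current conservation: the conductance
Laplacian with Dirichlet pressures at the region inlets and the common
drain, solved with a sparse direct factorisation.  The full 4-region
device is ~8 400 nodes and solves in well under a second.  An
independently coded dense nodal solver serves as the oracle in the tests.

Topology.  Each row has `basins_per_row + 1` main segments whose widths
fall arithmetically from 50 µm to 22 µm; after each basin, a plug edge
(2 × 5 × 35 µm) short-circuits to the geometrically facing junction of the
next row (the serpentine reverses direction row to row, so basin *k* of
row *r* lands on junction *B − k* of row *r + 1*).  Choices where the
printed geometry is silent:

- Along-row site pitch 50 µm (the only printed pitch figure), also used as
  the serpentine-turn length with row-start width — a minimal-assumption
  continuation of the channel.
- The basin interior is lumped into its plug by default: a 22 µm-wide
  antechamber adds negligible resistance in series with a 2 µm plug.  An
  `explicit_basin_edges` switch adds the antechamber edge (its depth
  defaults to 25 µm, deep enough to shield a cell from the main flow; the
  published design notes only that the depth has little effect once
  sufficient).
- The three physical inlets feeding four regions are modelled as one
  pressure inlet per region; the regions are hydraulically parallel and
  identical, so they can be (and are) solved jointly but independently.
- Walls are no-slip throughout.  The published 2-D flow-field figure used
  full-slip walls; the resistance network is the physically standard
  no-slip description, and velocity-field details are not reproduction
  targets.

Relative site resistance.  The ratio reported for site *k* is the
resistance of the entry path through that site — the narrowing main
channel up to the site, then its plug — relative to the full-row bypass
(all row segments plus the turn).  For the default geometry this ratio is
~3 at the first site and grows almost exactly linearly along the row,
which is what keeps downstream sites competitive.

Transport.  Pe = v·D_h/D with D_h = 2h for wide enclosed channels
(aspect ratio ≥ 4, configurable) and 2wh/(w+h) otherwise.  Regimes:
diffusion below Pe = 1, advection above Pe = 10, mixed between; both
thresholds are arguments.  The 1 mm/s main-channel velocity used for the
printed Pe ≈ 5 belongs to the particle-tracing operating point, not to
the 1 kPa case, so velocity is an input to the Péclet analysis rather
than a solved quantity.

## Trapping simulation

Cells are routed as massless tracers on the solved flow (no diffusion, no
inertia; cell size enters only through the blocking rule).  The particle
state is the volumetric flow *q* between its streamline and the basin-side
wall; this absolute-flow bookkeeping is exactly conservative:

- A plug drawing flow *Q_p* captures the particle when *q < Q_p*,
  otherwise *q → q − Q_p*.
- Plug inflow from the row above enters on the opposite wall and leaves
  *q* unchanged.
- At a serpentine turn the basin-bearing wall switches sides:
  *q → Q_turn − q*.

A basin is capturable only while its plug draws at least 5 % of the flow
arriving at its junction (capture threshold, configurable) — this keeps
vanishing side-flows from capturing unphysically.  A particle whose
streamline feeds a non-capturable plug hugs the wall and is drawn into the
next available site, which reproduces the published tracer picture: the
near-wall particle enters the first vacant site, and is deflected to the
second when the first is occupied.

A captured cell seals its plug to a residual conductance of 0.1 (the flow
is "much reduced although non-zero"; configurable).  Recapture at an
occupied basin additionally requires the seal to be weak (residual ≥ 0.5,
configurable): a seated cell physically occupies the plug mouth, so a
second cell can only join when blocking is ineffective.  The
plug-flow-fraction threshold alone would not guarantee exclusivity,
because once many plugs are sealed their *relative* fractions recover
above the threshold.  Under the defaults the exclusivity rate is exactly
1; with a weak seal (residual 0.9) multiple occupancy appears, as
expected.

Cells arrive one at a time (the dilute limit of the intended operating
densities); the flow is re-solved only after a capture, since routing is
deterministic for a fixed occupancy.  Entry positions are either equally
spaced (deterministic, like the published 19-tracer injection) or uniform
under a single integer seed.

## PALM acquisition simulator

Protocol: one activation pulse followed by `frames_per_imaging_block`
(default 10) imaging frames of 33 ms, repeated for `activation_pulses`
pulses and truncated at `max_frames` (default 5000) imaging frames.
Photophysics is reduced to off → (pulse, probability *p*) → on for a
geometric number of frames (mean 2), capped at the block length →
irreversibly bleached; no blinking or dark states, because the pulsed
protocol is designed to exhaust each activated molecule within its block.
The published acquisition reports both ~5000 frames and 147 cycles for a
~3 min run; these are treated as independent printed facts (they are not
mutually consistent with 33 ms frames) and the schedule arithmetic is
checked against the cycle count.

Camera model: the expected photon image is the pixel-integrated 2-D
Gaussian PSF (σ = 130 nm, consistent with a ~250 nm diffraction limit)
plus a uniform Poisson background; per-pixel Poisson shot noise, a
multiplicative EM gain, additive Gaussian read noise, an offset, and
16-bit quantisation.  The EMCCD gain-register cascade (excess-noise factor
≈ √2) is not modelled.  Unprinted acquisition parameters are defaults
chosen once as typical for such systems and are configurable: 100 nm/px
(60×, 1.49 NA objective on a 512² EMCCD), photon budget 300 photons per
on-frame, background 10 photons/px/frame, gain 50, read noise 1
photon-equivalent.

The ground-truth table records every (frame, emitter) emission with the
*expected* photon count and flags frames where another active emitter sits
within 4 PSF σ (`crowded`).  Sparse activation should keep at most about
one active emitter per diffraction-limited region; for clustered emitter
sets this means the activation probability must shrink with cluster size
(the bundled two-cluster experiments use p = 0.01 per pulse for 25
emitters per cluster).

The brightfield generator renders a spherocylinder — the fission-yeast
morphology, ~4 µm across and 7–14 µm long over the division cycle — dark
on a bright field with soft (defocus-dependent) edges, two faint
basin-wall shadows and Gaussian noise, with the pose as ground truth.

## Localization

Detection: local maxima above median + 5 robust σ (MAD-based), greedy
non-overlapping 11 px ROIs fully inside the frame.  Fitting: nonlinear
least squares of A·exp(−((x−x₀)² + (y−y₀)²)/(2σ²)) + b, run twice — an
unweighted pass for starting values, then a refit weighted by the camera
noise model (shot noise of the fitted intensity through the gain, plus
read noise) whose covariance is taken at absolute scale.  The weighting is
essential for honest error bars: photon noise peaks exactly where the
centre information lives, so an unweighted covariance understates the
centre error by ~40 % and the nominal 95 % interval covers only ~50 %.
With weighting, the Monte-Carlo coverage is ~95 % and the empirical RMSE
matches the reported precision to a few percent.

The reported per-molecule precision is ci95 = 1.96 × the standard error
of the fitted centre (mean of the two axes) — the regression's statistical
error, as in the original processing chain — with the photon-statistics
(Thompson-style) estimate available as a cross-check only.  Integrated
photons are 2πAσ²/gain; the offset b absorbs camera baseline and cellular
background, so background is per-ROI, not global.  Fits are rejected, with
reason codes, on non-convergence, a centre outside the ROI, or a width
outside 0.5–3× the nominal PSF width.

Precision scales as 1/√N only while shot noise dominates; with the default
10 photons/px background the scaling exponent is steeper because the
background term falls as 1/N².  The √2-halving property is therefore
verified in a low-background configuration (1 photon/px, 0.5 e⁻ read
noise, 500 → 1000 photons).

Linking merges localizations within 100 nm (≈ 5× the modal precision,
well below typical inter-molecule distances in a 120 nm-scatter punctum)
in consecutive frames (gap ≤ 1).  Rendering paints each accepted molecule
as a unit-mass pixel-integrated Gaussian of width ci95, scaled by its
photons, on a 10 nm grid padded by 6 of the largest ci95 so the image
conserves total photons to better than 10⁻⁶.  The modal precision is the
mode of a 2 nm-binned histogram with bins centred on multiples of the bin
width; ties resolve toward the smaller precision.  An optional
linear-drift estimate (phase cross-correlation between the summed early
and late halves of a movie) is provided but off by default.

## Automation

Detection inverts the brightfield image, applies an Otsu threshold with a
contrast guard (foreground must exceed background by 3 background σ, which
rejects featureless fields), removes small objects, and gates the largest
region on area (10–120 µm²), aspect ratio (≥ 1.5 — low enough to keep a
7 × 4 µm or slightly defocused cell, high enough to reject round debris)
and maximum length (20 µm, which rejects basin-wall shadows).  The
accepted mask is re-thresholded at the half-contrast isophote before
measuring, since Otsu sits below it and inflates the rod by a pixel or two
of soft edge; the long axis is the maximum Feret diameter.

The cell-cycle gate is a closed interval on the long-axis length, default
7–14 µm (the printed range); the "mitosis preset" 11–14 µm is a chosen
convention for the late-cycle sub-interval, not a printed cutoff.
Autofocus maximises the variance of the squared image gradient normalised
by the squared mean, with ties to the lower plane.  Decisions follow a
fixed precedence — no cell → skip, off-centre (> 10 px) → reposition,
defocused → refocus, out of gate → skip(stage), else acquire — so each
corrective action strictly reduces its own criterion and a compliant scene
reaches acquisition within three iterations.  `TrappedCellScene` is a
synthetic single-site microscope world (stage offset, focal planes,
defocus blur) used to exercise the loop; no hardware I/O is modelled.

## What the synthetic data does and does not establish

The generators emulate the *structure* of the real experiment — geometry,
pulse timing, sparse activation, EMCCD-like noise, rod-shaped cells — with
all stochasticity under integer seeds, so every green test is a statement
about the algorithms under the stated noise model.  They do not emulate
cellular autofluorescence structure, mEos2 spectral behaviour, dipole or
3-D PSF effects, stage drift (beyond the optional linear estimate), or
deformable cells altering the flow geometry.  Published in-vivo figures
that depend on unprinted photon statistics of the real data — the 21 nm
modal precision and the 138 molecules from 147 cycles — are consequently
not reproduction targets; the pipeline's calibration is instead
established by ground-truth recovery properties (CI coverage, precision
scaling, cluster-centre and count recovery).

## Numerical notes

- Sparse Dirichlet solve via `scipy.sparse.linalg.spsolve`; interior mass
  defects are at machine precision (≲ 10⁻¹³ of the total flow).
- Plug flow fractions are clipped to [0, 1] against rounding.
- Pixel centres sit at integer indices; pixel *i* spans [i−½, i+½].
  Gaussian masses use the error function over pixel edges within a ±6 σ
  window.
- Fit non-convergence, degenerate ROIs and empty tables return flagged
  records, warnings or errors as documented rather than propagating NaNs.
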