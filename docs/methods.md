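# Methods

`dualspect` implements simultaneous Tl-201/Tc-99m dual-isotope SPECT
reconstruction with Monte-Carlo (MC) based scatter and cross-talk
correction, together with the digital phantoms and evaluation metrics used
to validate it. This note records the models, the defaults and the design
choices behind them.

## The dual-isotope problem and the three-step algorithm

In simultaneous Tl-201/Tc-99m myocardial perfusion SPECT, the 140 keV
Tc-99m photons that Compton-scatter inside the patient can be detected in
the ~72 keV Tl-201 energy window ("down-scatter"). Because the Tc-99m
activity is much higher than the Tl-201 activity, this cross-talk dominates
the Tl-201 window and destroys defect contrast unless corrected.

The reconstruction proceeds in three steps:

1. **Tc-99m OS-EM reconstruction** with attenuation, distance-dependent
   collimator response and MC self-scatter correction.
2. **Down-scatter simulation**: the reconstructed Tc-99m volume drives an
   MC simulation of 140 keV photons scored in the Tl-201 window.
3. **Tl-201 OS-EM reconstruction** where the frozen down-scatter estimate
   is added to the Tl-201 self-scatter term in the EM denominator.

The OS-EM update per subset *s* is
`x <- x * [A_s'(y_s / (A_s x + s_s + eps))] / A_s' 1`, with `A` the
attenuated, PSF-blurred projector, `s` the additive scatter term and
`eps = 1e-10 * mean(y)` a denominator guard. Defaults follow the settings
that were found to saturate image quality: 10 iterations, 8 subsets, and a
3-D Gaussian post-filter of 0.9 cm FWHM. Subsets interleave views
(subset *s* holds views `s, s+8, ...`) and are visited in bit-reversed
order for angular balance; the initial estimate is a uniform positive
volume scaled to the measured counts. Both choices are ours — the
literature leaves them open.

### Acceleration levers

MC scatter estimation is the expensive part; three levers make it cheap:

- **Coarse-grid modelling** (`coarse_factor`, default 2): activity and
  attenuation are folded into factor³ blocks before transport, and the
  scored projections are bilinearly up-sampled back. Scatter is spatially
  smooth, so folding costs little accuracy (the coarse-vs-fine systematic
  difference on the default phantom is ~3% RMS over the scatter region).
- **Intermittent scatter updates** (`scatter_update_iters`, default 2):
  iteration 1 runs scatter-free; the estimate is recomputed from the
  current volume at the start of iterations `2 .. 1+n` and frozen
  afterwards. The refresh is *damped*: the new estimate is averaged with
  the previous term. The scatter term and the volume relax jointly, and
  the undamped replace-with-new map oscillates — the scatter-free first
  iteration over-attributes counts to activity, making the first estimate
  too large, the next one over-corrects, and so on — so freezing after two
  undamped updates would land well off the joint fixed point and break the
  few-updates-suffice property the intermittent scheme exists for. With
  0.5 damping the two-update and ten-update reconstructions agree in
  defect contrast to ~0.01. The down-scatter term is never recomputed
  during Tl-201 iterations — it derives from the completed Tc-99m volume.
- **Photon budget** (`photons`): number of emitted source photons per
  estimate (not per view). Optimised defaults: 1e5 for the self-scatter
  updates inside both reconstructions, 1e6 for the down-scatter estimate.

## System model (projector)

Rotation-based: for each view the volume is rotated so the detector normal
aligns with a grid axis, then planes are swept far-to-near. Each plane's
emission is attenuated by `exp(-mu dl)` accumulated multiplicatively
(sampled at the plane midpoint; the emitting plane contributes a half
step), and the accumulated projection is diffused between planes so the
total blur reaching the detector equals the collimator PSF at that plane's
distance.

- **Rotation** is a cached sparse bilinear-interpolation matrix per angle.
  The back projector applies the exact transpose, so the adjoint identity
  holds to machine precision (measured < 1e-8 relative) — the property EM
  correctness rests on. The transpose adjoint has a per-voxel sensitivity
  ripple of a few percent (interpolation-matrix column sums are not exactly
  one); the EM sensitivity division removes it.
- **Incremental diffusion** uses per-step variance increments
  `dvar = sigma²(d_i) - sigma²(d_{i+1})`, clipped to >= 0. Small increments
  are applied with a 3-tap kernel `[v/2, 1-v, v/2]` whose *discrete*
  variance is exactly `v`; a sampled Gaussian at sigma < ~0.5 px carries
  far less variance than sigma² and would systematically under-blur.
- **Collimator PSF**: Gaussian, `FWHM(d) = 3.8 mm + 0.0445 d` by default —
  representative LEHR figures (the scanner's exact parameters are not
  published); fully configurable.
- **Energy windows**: the forward model carries a global photopeak
  efficiency factor, the Gaussian-resolution probability that an
  unscattered photon is recorded inside its window. This keeps the scatter
  term and the primaries on one counts scale.

## Photon physics

Single-line emission models: Tc-99m at 140 keV; the Tl-201 Hg X-ray
complex collapsed to one 72 keV line (the weak 167 keV line is ignored —
it contributes little to a 72 keV-window study). Interactions are Compton
(Klein-Nishina, sampled by rejection against the forward-scatter maximum)
and photoelectric absorption; coherent scattering and Doppler broadening
are ignored, the standard simplification for fast scatter estimators at
70-140 keV.

Attenuation coefficients come from a per-material table (soft tissue,
lung, bone, water) tabulated at 50-160 keV with log-log interpolation,
anchored to standard 140 keV values (0.155 / 0.040 / 0.25 cm⁻¹ total).
Detector energy resolution defaults to 9.9% FWHM at 140 keV with absolute
FWHM scaling as sqrt(E) — a typical NaI camera; the reference system's
resolution is not published.

A kinematic fact the engine must respect: a single Compton scatter of a
140 keV photon cannot drop below 90.4 keV, above the Tl-201 window's
77.4 keV upper bound. Down-scatter into the Tl-201 window therefore
requires at least two scatter orders (plus the detector-resolution tail),
and `simulate_downscatter` rejects `max_order < 2`. The default order is
3; higher orders contribute marginally at these energies.

## Monte-Carlo engine

Forced detection with survival biasing: emission sites are sampled from
the coarse activity, directions isotropically; free paths use Woodcock
(delta) tracking against a majorant; at each interaction the weight is
multiplied by the local Compton fraction instead of sampling absorption,
and the *expected* contribution to every view is scored — Klein-Nishina
density toward the detector direction, transmission along the exit path at
the scattered energy (per-view line-integral tables, linearly interpolated
in depth), and the energy-window acceptance. Scored deposits are blurred
with the collimator PSF at four depth bins and up-sampled to full binning.
Russian roulette removes weights below 1e-4. Analog detection could not
reach useful variance at 1e5-photon budgets; forced detection makes the
per-bin variance scale as 1/budget (verified empirically: ratio ~10
between budgets 1e4 and 1e5).

Two numerical shortcuts, both documented bias sources well below the MC
noise at the budgets used: the energy dependence of each attenuation
component is treated as a material-independent shape (Klein-Nishina for
Compton, E⁻³ for photoelectric) anchored at 140 keV — exact for the
default table; and window acceptance / attenuation shapes are tabulated on
a 0.5 keV grid. Photon-view pairs whose scattered energy misses the
window by more than five resolution sigmas are skipped.

**Normalisation.** Estimates are scaled so the engine's unscattered
(order-0) scores match the analytic projector's primary totals for the
same input volume. This ties the scatter term to the `A x` scale of the
EM denominator without any free constant; the reference implementation's
normalisation is not published, so this contract is this package's own.

## Phantoms and simulated studies

A simplified parametric torso stands in for the NURBS-based cardiac-torso
anatomy: body ellipsoid, two lung ellipsoids, liver ellipsoid, spine
cylinder (bone) and a half-ellipsoid myocardial shell (outer semi-axes
33/33/45 mm, 12 mm wall — typical LV dimensions at this sampling) with a
ventricular cavity. Organ regions must be pairwise disjoint; the builder
rejects ambiguous geometry. Defects are angular sectors of the shell in
short-axis polar coordinates, default 60° x 20 mm (only position and
residual fraction are published); a defect present in the Tl volume only
is reversible. The four standard activity configurations (Tl
50/3/2/3/3 per voxel for myocardium/ventricle/lung/liver/background; two
Tc variants 180/6/18/90/6 and 95/3/9/189/3; anterior/inferior/septal
defects at 20/40%) ship as versioned defaults. A cylindrical water
phantom with the same cardiac insert and compartment activities in MBq
(8.18/0.34/0.04 Tl; 35.96/1.25/0.17 Tc) emulates a physical Jaszczak-style
acquisition; compartment totals exclude the fillable defect-insert
volumes.

The default grid is 64³ voxels at 6.6 mm with a matching 64x64 detector at
64 views over 360° (orbit radius 250 mm); a finer 128-grid pathway is
supported through `collapse_projections` (factor-2 bin sums, counts
preserved exactly). Simulated windows are 15% wide at 72 and 140 keV.

Expected projections per window are analytic primaries (with the window
efficiency factor) plus MC self-scatter; the dual-study Tl window adds the
Tc down-scatter term simulated from the true Tc activity; the pure-Tl
study omits it. Each window is scaled to its target totals — defaults
76 Mcts (Tc), 80 Mcts (dual Tl), 10 Mcts (pure Tl) — before independent
per-bin Poisson sampling. `count_scale` scales all three; analyses in this
repository use 0.1, keeping clinically plausible noise while staying
desk-sized. Note the simulated mix of Tl primaries versus down-scatter
inside the dual window follows from the physics model; it is not forced to
the published window ratios, which also contain collimator lead X-rays
(see Limitations).

**What the generator does not emulate:** anatomical realism (NURBS
shapes, organ motion, gating), collimator lead X-ray fluorescence and
septal penetration, detector dead-time and pile-up, and CT-derived
attenuation maps. Passing tests therefore demonstrate the correction
machinery under an idealised but physically consistent imaging chain, not
clinical performance.

## Evaluation

Contrast uses the summed-count definition
`(C_myocardium - C_region) / C_myocardium` with three equal-area ROIs
(defect, healthy myocardium, LV cavity) on the short-axis slice where the
defect is most conspicuous (deterministically: the slice maximising the
healthy-minus-defect mean given the known masks). ROIs are machine-placed
from the phantom geometry for reproducibility: the defect ROI takes the
defect-mask pixels nearest its centroid, the LV ROI the cavity pixels
nearest the cavity centre, and the healthy ROI the wall pixels farthest
from *every* defect — the machine equivalent of drawing on visibly healthy
wall (placing it diametrically opposite the defect can land it beside a
second defect in the two-defect configurations and bias the myocardial
counts down). The published ROI sizes are unknown; the default area is 15
pixels, capped at the largest size all three masks support (8 pixels for
the default 60° defect at 6.6 mm sampling) so ROIs stay strictly inside
their regions — this preserves the exact identity contrast = 1 - f on the
true activity. Projection profiles are band means, default width 10
pixels.

## Numerical choices and degenerate inputs

- Sweep accumulators are float64 (the Beer-Lambert slab case is exact to
  1e-6); volumes and projections are float32 at rest.
- All randomness flows from explicit integer seeds; identical seeds give
  bitwise-identical projections, scatter estimates and reconstructions.
  Self-scatter updates inside OS-EM derive a per-iteration seed from the
  base seed.
- Zero activity with a positive budget yields a zero scatter estimate (not
  an error); a budget below 1e3 photons is rejected as meaningless for
  estimation. All-zero projections cannot be scaled to a positive count
  target and are rejected; the study simulator passes zero windows through
  (a pure-Tl phantom has an empty Tc window).
- OS-EM guards its denominator with `eps` and divides only where the
  subset sensitivity is positive; updates preserve non-negativity.

## Known limitations

- Down-scatter is corrected for patient scatter only. Lead X-rays excited
  in the collimator by Tc-99m also land in the Tl-201 window and are
  neither simulated nor corrected, consistently with the scope of the
  method; pure-Tl contrasts therefore exceed corrected dual-isotope
  contrasts.
- The LV-cavity contrast is limited by partial volume: a ~42 mm cavity
  against a ~16 mm system resolution leaves a few percent of wall
  spill-in at the cavity centre, so myocardium-vs-LV contrasts saturate
  near 0.93-0.95 on this phantom geometry.
- The coarse parametric anatomy reproduces activity *structure*, not
  shape; absolute contrasts track the reference values only within the
  tolerances stated in the acceptance checks.
- One emission line per isotope; no high-energy Tl-201 line, no Rayleigh
  scattering, no septal penetration tails.
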