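# Methods

`tomomar` is a self-contained emulation and implementation of projection-domain
metal artifact reduction (MAR) for limited-angle digital tomosynthesis (DT) of
metal implants: a residual denoising CNN is trained to map polychromatic
low-energy projections toward dual-energy virtual-monochromatic (VM) reference
projections, the estimated residual is subtracted in projection space, and the
corrected projections are reconstructed with a weighted hybrid of MLEM and
backprojection. This note documents the models, the parameters that matter,
the numerical choices, and the limits of what the synthetic experiments show.

## Physics simulation

**Materials.** Three basis materials define the prosthesis phantom: a
titanium alloy (Ti-90.255 / Al-5.5 / V-3.5 / Fe-0.40 / O-0.20 / C-0.08 /
N-0.05 / H-0.015 % by mass, 4.43 g/cm³), water (1.0 g/cm³) and a foam
cortical-shell bone analog (H-7.9192 / C-40.4437 / N-15.7213 / O-35.9157 %,
0.48 g/cm³). Elemental mass attenuation coefficients are embedded as static
tables on the standard 10–150 keV grid of the published photon cross-section
compilations and combined by the mass-fraction mixture rule; lookups between
nodes use log-log interpolation, which is exact at the nodes and accurate to
well under a percent for these smooth cross sections. The embedded water
mixture reproduces the published liquid-water coefficients (e.g. 0.1707 cm²/g
at 100 keV) to three significant figures.

**Tube spectra.** The spectrum model is a parametric filtered tungsten-anode
model on a 1 keV grid: continuum `E^a (kVp/E − 1)^b` (a Kramers bremsstrahlung
term with an anode self-absorption hardening correction), tungsten K
characteristic lines for tube potentials above the 69.525 keV K edge with
excitation scaling `(kVp/U_K − 1)^1.65`, and Beer–Lambert filtration through
2.0 mm Al + 0.1 mm Cu (the tube's inherent plus additional filtration). The
measured clinical tube publishes only the fluence-weighted mean energies of
its 70 and 140 kV beams — 49 and 80 keV — so those two numbers define the
calibration surface: the two shape parameters (a = 1.25, b = 0.6) and the
140 kV K-line fluence fraction (0.18) were fixed once so the default spectra
reproduce both printed means after integer rounding (48.89 and 79.99 keV).
The exact spectral shape of the real tube is not recoverable from two means;
all downstream physics (beam hardening, decomposition conditioning) depends
only on the broad shape, which the model captures.

**Phantom.** A water cylinder (case analog, radius 100 mm) holds a tubular
foam-bone analog (outer 22 mm, inner 14 mm, length 160 mm) around a titanium
rod (radius 10 mm) that models an intramedullary nail; a 7 mm transverse
fracture gap interrupts the bone while the nail bridges it. The cylinder axis
is parallel to the detector rows and perpendicular to the source sweep, so
metal streaks spread along the sweep direction of the projections. Voxels
store per-material volume fractions with in-plane supersampling (4×4), so the
voxelized titanium volume matches the analytic cylinder volume to within one
boundary-voxel shell. The default grid is 64³ at 3.5 mm — a desk-scale analog
of the physical φ200 mm phantom, chosen so a full pipeline run takes minutes
on one CPU; radii, lengths, gap and grid are all configuration.

**Geometry.** Linear-sweep tomosynthesis: the source translates along the
sweep axis at 924 mm above the isocenter (source–detector 1100 mm), covering
a 40° swing in 37 equally-spaced views including 0°; the detector is
stationary. The desk-scale detector default is 128×128 pixels at 2.232 mm —
the clinical 1024-pixel, 0.279 mm field of view rebinned 8× — with the
full-resolution matrix reachable through configuration. Reconstruction slices
default to 50 at 1 mm for the geometry object; the study configurations use
21 slices at 5 mm to keep iterative reconstruction at desk scale.

**Forward projection.** Per-material equivalent area densities K (g/cm²) are
integrated along each source-to-pixel ray with a slice-driven Joseph-style
integrator: the fraction volume is sampled by bilinear interpolation on every
voxel plane along the depth axis and summed with the ray-obliquity secant.
For piecewise-constant objects this is exact — a homogeneous slab yields
K = 0.1·t·ρ to machine precision and an oblique ray scales exactly as
1/cos θ — which is why it was preferred over exact-intersection (Siddon)
traversal: identical answers on this phantom class, and it vectorizes in
NumPy. Polychromatic intensities follow the spectral Beer–Lambert quadrature
over the 1 keV bins, normalized so unattenuated intensity is exactly 1;
beam hardening is therefore emergent, not modeled. Optional Poisson noise
draws transmitted counts at a configurable incident photon count per pixel.
The study default is 1e5 photons/pixel, the regime of low-dose pulsed DT
exposures (tens of ms per view); this leaves ~3 % quantum noise behind
20 cm of water and a photon-starved implant shadow, the conditions under
which MAR matters.

## Dual-energy decomposition and the VM reference

Per detector pixel, the measured (normalized) dual-energy intensities are
modeled as a linear combination of six simulated pure-material attenuation
responses at fixed reference area densities, closed by a sum-to-one
constraint on the fractions — a 3×3 solve per pixel. Reference densities
default to the central-ray area density of each material through the phantom,
which keeps the matrix well scaled (condition number ~130 for the default
pair). Raw solutions are clamped to [0,1] and renormalized to sum 1
(idempotent for feasible solutions). The VM projection is the
fraction-weighted sum of the basis materials' mass attenuation coefficients
at 140 keV — an image on the mass-attenuation scale, exactly linear in the
fractions and free of beam-hardening nonlinearity.

Known limitation: the linear-intensity mixture model is crude under strong
beam hardening. Along rays through the implant the constrained solve can
misclassify the metal (typically toward water), so the VM reference largely
erases the implant's own shadow; the corrected projections inherit this.
For artifact metrics this is benign — the streak corridor, not the implant
silhouette, is what the artifact index samples — but the VM image should not
be read as a quantitative material map near metal.

## Residual CNN

Architecture: depth D with one 3×3 conv + ReLU (64-filter default), D−2
blocks of 3×3 conv + batch normalization + ReLU, and a final single-channel
3×3 conv; stride 1, zero padding 1, spatial shape preserved. Training
minimizes the half mean-squared error between the network output U(P_L) and
the residual target P_L − VM over seeded random 32×32 patch crops, by
mini-batch SGD with momentum 0.9, weight decay 1e-4 (convolution weights
only) and constant learning rate 0.1. The published loss norm is ambiguous;
it is implemented per-pixel-averaged, which makes the 0.1 learning rate
independent of patch size (a sum-over-pixels loss diverges immediately at
that rate). Weight init is He-scaled Gaussian, seeded; BN uses ε = 1e-5 and
running-moment retention 0.9. A divergence guard restores the epoch-start
parameters and halves the rate on a non-finite loss (or raises, reporting
the epoch, if disabled). The patch-count rule `mini-batch × epochs × views`
is the default ("total" reading); a "per_epoch" reading and an explicit
count are also exposed.

The implementation is plain NumPy — per-offset tensor contractions for the
convolutions and hand-written backpropagation — so the package has no deep
learning framework dependency. The clinical-scale configuration (depth 20,
64 channels, mini-batch 544, 60 epochs) is expressible but intended for long
runs; tests and examples use depth 5 / 16 channels / 320 patches / 10
epochs, which trains in ~30 s and already removes ~90 % of the held-out
squared deviation between the 70 kV projections and the VM reference.

Inference runs the trained network in evaluation mode (BN running moments);
the corrected stack is the elementwise difference P_L − U(P_L). The
symbolic two-layer filter-sum form of the inference equation (step size β,
regularization ε) is absorbed into the standard feed-forward pass: the
trained network's output *is* the estimated residual.

## Reconstruction

The system operator maps reconstruction slices (detector grid demagnified to
the isocenter scale) to detector images. Because the source moves only along
the sweep axis, each slice-view mapping is a separable affine resampling;
forward projection composes two explicit 1-D linear-interpolation matrices
per slice and backprojection applies their exact transposes, so
⟨Xv, p⟩ = ⟨v, Xᵀp⟩ holds to floating-point accuracy — the property the EM
convergence argument needs, and the most load-bearing test in the suite.

* **MLEM** (default 30 iterations): multiplicative updates
  v ← v·[Xᵀ(p/Xv)]/Xᵀ1 from an all-ones start on non-negative data
  (intensities times a configurable incident count; MLEM is linear in the
  data so the scale cancels, and the pipeline reports volumes back on the
  intensity scale). Voxels outside every ray cone (zero sensitivity) are
  frozen at their start value; ratio denominators are floored at 1e-12.
  Non-negativity, monotone Poisson log-likelihood and the consistent-data
  fixed point are verified exactly.
* **Backprojection**: the plain transpose (the published update), plus a
  normalized variant Xᵀp / Xᵀ1 (shift-and-add average) used by the hybrid so
  both inputs share the intensity scale.
* **Hybrid MAR volume**: voxelwise (1−w)·MLEM + w·BP with w = 0.7 default,
  the published optimum.
* **FBP**: 1-D Shepp–Logan ramp `|f|·sinc(f/2f_N)` applied along the sweep
  axis only (the direction with frequency coverage in a limited-angle sweep)
  via FFT, then normalized backprojection; kernel "none" degenerates to
  plain shift-and-add. Operates on the same intensity-convention stacks as
  the other algorithms.
* **SART-TV** (10 outer / 100 TV iterations): SART updates with matched
  normalizations, interleaved with total-variation gradient descent. The
  published dimensionless "step length of 50" is mapped to a relative rule:
  each TV phase descends a total length of tv_step % of the SART update's
  norm along the normalized TV gradient, with step halving so a phase never
  increases the TV functional; residual growth over three consecutive outer
  iterations sets a divergence flag.

## Metrics

* **Artifact index**: AI_n = √|rsd(artifact ROI n) − rsd(background ROI)|
  over ten 4×14-pixel ROIs, reported as mean ± standard error (SD/√10).
  "Relative SD" is implemented as the coefficient of variation (SD/mean) by
  default, with a plain-SD mode switchable; a zero-mean ROI raises a
  degenerate-ROI error in CV mode.
* **MSE**, **ASF** (per-slice feature-minus-background contrast ratio,
  exactly 1 in the in-focus slice) and **GLCM texture** (clip to
  mean ± SD, 16 linear gray levels, symmetric co-occurrence at a single
  configurable offset; inverse difference moment, contrast, correlation —
  correlation is reported as undefined for a constant image).

Pipeline evaluation conventions: each reconstructed volume is min-max
normalized as a whole before slicing (the published per-algorithm display
ranges, all inside [0,1] with FBP centered near 0.59, are consistent with
volume-level windows, and this gives the zero-mean FBP volume a stable
positive offset for the CV statistic); the AI/ASF ROIs are auto-placed from
the phantom geometry — ten artifact ROIs straddling the implant along the
sweep corridor from 1.5× the implant radius (outside the implant's own blur
penumbra, so streaks rather than the object are sampled) to 70 % of the case
radius (clear of the case boundary), and a background ROI off the corridor
in open water. Explicit ROI sets can be supplied in the configuration.

## Pipeline, seeds and the hyperparameter sweep

One global seed is fanned out through independent named streams (noise,
patch cropping, weight initialization), so a fixed configuration is bitwise
reproducible end to end. The sweep mode varies one of mini-batch size,
epochs or the hybrid weight w over a grid, reusing cached simulation and
decomposition stages (and, for w, the trained network and base
reconstructions — a w-sweep is a pure re-blend); ties are broken by lower
AI mean, then lower standard error, then the smaller parameter value.

## What the synthetic experiments do and do not show

The generator emulates beam hardening, limited-angle geometry, quantum noise
and the three-material composition of a real prosthesis phantom. It does not
model scatter, detector response/lag, focal-spot blur, photon-starvation
electronics effects, or anatomical background texture. Consequently the
published absolute metric values measured on real scanner data are not
reproducible here; what the experiments do establish, under seeded synthetic
conditions, is the *mechanistic* chain — beam hardening emerges from the
polychromatic quadrature and vanishes in the monochromatic limit; the
decomposition inverts exactly where its model holds; the CNN correction
transfers to held-out views; and the reconstruction comparison reproduces
the qualitative ranking (the CNN-corrected hybrid below uncorrected MLEM,
Shepp–Logan FBP worst). Desk-scale problem sizes (64³ phantom, 37×128²
projections, 21 recon slices, depth-5/16-channel network) were chosen so the
full suite runs in minutes on one CPU; every clinical-scale value remains
reachable through configuration. Note the comparator algorithms here run on
uncorrected projections; the clinical study applied an additional adaptive
filtering step to its comparators, which is out of scope, so absolute gaps
between comparators differ from the published ones.
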