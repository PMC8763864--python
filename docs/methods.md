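# Methods

This note documents the models implemented in `mechanoquant`, the
parameters that matter, what the synthetic-data generators do and do not
emulate, and the numerical choices made where the design was open.

## Micropillar traction-force microscopy

**Model.** Each elastomer pillar is an independent linear spring: the
traction force a cell exerts on a pillar is `F = k · u`, with `k` the
pillar bending stiffness (nN/µm) and `u` the deflection of the pillar top
from its zero-force position (µm). The per-pillar *peak force* is the
maximum of `|F|` over the movie; per-cell summaries (mean, sum, max of
peak forces) aggregate the pillars under the cell. Pillar stiffness is
substrate calibration data — it depends on pillar geometry and elastomer
modulus — and must always be supplied by the user; the package asserts no
default.

**Sub-pixel localization.** Pillar tops image as point-spread-function
spots. Each spot is fitted by least squares with an isotropic 2-D
Gaussian (amplitude, centre, width, constant offset) in a window around
the predicted position; if the fit fails or returns an implausible width
the background-subtracted intensity centroid is used and flagged. For
additive Gaussian noise the Cramér–Rao bound for this problem is
`sqrt(2/π)·σ_noise/A` pixels per coordinate, independent of the PSF
width; the fitted estimator operates within a few percent of that bound
(verified by Monte Carlo in the test suite). At a peak-to-noise ratio of
25 this gives ≈ 0.032 px RMSE, i.e. ≈ 5 nm at 0.16 µm/px.

**Tracking and drift.** Tracks are propagated frame to frame by refitting
in a window centred on the previous position; a move of more than half
the lattice spacing is treated as a mis-association and marked missing,
and two tracks collapsing onto one spot are disambiguated by fit
residual. Stage drift is the component-wise **median**, over cell-free
reference pillars, of `p(t) − p(0)`; the median tolerates one bad
reference track where the mean does not. Displacements are
`u(t) = (p(t) − drift(t)) − p(0)`, so frame 0 is the zero-force reference
by construction and `u(0) ≡ 0`. Pillars missing more than 20% of frames
are excluded from cell summaries (logged).

**Defaults.** Square 10×10 lattice, 12 px spacing, PSF σ 1.5 px, pixel
size 0.16 µm/px (a 6.5 µm-pixel sCMOS behind a 40× objective), 0.5 Hz
cadence, 100 frames. Coordinates are x-rightward, y-downward, origin at
the top-left pixel centre, frames 0-based.

## AFM nanoindentation

**Model.** A rigid sphere of radius `R` indenting an elastic half-space
(Hertz): `F = (4/3)·E/(1−ν²)·√R·δ^{3/2}`. Defaults: `ν = 0.5`
(incompressible cell) and `R = 17.5 µm` (half of a 35 µm bead); both are
configurable. Cantilever spring constant defaults to 0.07 N/m. No
viscoelastic, approach-speed, or thin-sample corrections are applied.

**Calibration and conversion.** Sensitivity (m/V) is the inverse slope of
deflection-volts versus height on the steepest contiguous half of the
contact region of a rigid-substrate curve (R² ≥ 0.99 demanded). Raw
curves convert as `d = V·s`, `F = k·d`; a straight line fitted to the
first 30% of approach samples (pre-contact) is subtracted from the force
to remove photodiode offset and optical-interference tilt. Indentation
uses tip–sample separation (height compliance-corrected by the
deflection), not raw piezo height: at 0.07 N/m the cantilever takes up a
non-negligible share of the piezo travel. Sign convention: piezo height
decreases on approach and contact deflection is positive, so separation
is `height + deflection` up to the contact offset.

**Contact point and modulus.** The fit scans candidate contact points
over nearly the whole approach sweep (2–98% of samples). At each
candidate the model is linear in `E` after the `δ^{3/2}` substitution, so
`E` has a closed form; pre-contact samples are modelled as zero force and
the whole-curve residual selects the winner. The candidate span is wide
rather than central because the set-force turnaround (1.5 nN default)
leaves only a short post-contact segment on stiff samples, pushing the
true contact close to the end of the sweep. The discrete winner is then
polished by a bounded continuous search between its neighbouring samples
— the modulus is steeply sensitive to contact-point errors when the
post-contact segment is shallow, and grid quantisation alone (a few nm)
otherwise costs several percent in `E` on 20 kPa curves. A best fit whose
RMS residual exceeds 20% of the maximum force is flagged non-converged.
On noise-free synthetic curves the estimate is exact to < 10⁻⁵ relative;
at 0.02 nN force noise the median modulus error is ≈ 1% and the median
contact-point error ≈ 2 nm across 0.5–20 kPa.

## Image morphometry

**Blob segmentation** is deliberately minimal and deterministic: subtract
a Gaussian background estimate (σ = 20 px default), threshold the
residual inside the cell mask (Otsu by default, fixed threshold
optional), label 8-connected components, and keep objects within a
physical area band (0.25–20 µm² default for focal adhesions; the tests
use wider bands for generic blobs). Zero objects is a valid result.
Counts are invariant to uniform intensity scaling under Otsu.

**Coherency.** The structure tensor is built from Gaussian-derivative
gradients at scale σ (1 px default), smoothed at integration scale ρ
(4 px default); the tensor is averaged over the mask to a single 2×2
matrix and coherency is `(λ₁−λ₂)/(λ₁+λ₂)` ∈ [0, 1], defined 0 for a
degenerate (constant-image) tensor. Averaging the tensor before taking
eigenvalues yields one scalar per cell, which is the quantity plotted in
per-cell comparisons; the mean of per-pixel coherencies would instead be
biased high on noise. Rotation by 90° is an exact invariance (the filters
are separable and symmetric); arbitrary rotations hold to within
interpolation error on band-limited textures.

**Colocalization** is the plain sample Pearson correlation over masked
pixels — no intensity thresholding and no Costes-style randomisation, as
the plain coefficient is the standard reported quantity; bright
artefacts (e.g. magnetic beads) can be removed with an exclusion mask.
Zero variance in a channel is an explicit error rather than a NaN.

**Bead filter.** Mechanically stimulated cells enter analysis only with
1–4 bound beads (inclusive); fewer means no stimulus, more means
uncontrolled load.

## Statistics

The *t*-test defaults to the pooled-variance Student form with a Welch
flag, mirroring common practice in prism-style analyses of per-cell
measurements. The two-way ANOVA uses type III sums of squares with
sum-to-zero contrasts (robust to the unbalanced per-cell designs typical
here; on balanced designs it coincides with type I, which the tests
assert). Tukey HSD comparisons default to all crossed cell means using
the ANOVA residual mean square and the studentized-range distribution
(Tukey–Kramer for unequal n); main-effect-only modes exist. ΔΔCt uses
arithmetic means of replicate Cts and a fixed amplification efficiency of
2 (no efficiency correction). Normality is assumed, not tested. The
empirical type-I-error check drives the t-test with seeded null draws
(n = 30 per group, 2000 simulations in the acceptance run) and must land
in the binomial band around α.

Implementation note: the ANOVA F-tests are computed through
statsmodels OLS; the test suite checks them against hand-computed
textbook sums of squares, and the package's own Tukey implementation
against statsmodels' `pairwise_tukeyhsd`, both to 10⁻⁸.

## Synthetic data: what it does and does not show

The generators reproduce the *statistical structure* each estimator
assumes: Gaussian PSF spots on a constant background with additive
Gaussian camera noise and rigid linear drift; Hertzian contact with a
linear optical baseline and additive force noise; elliptical-Gaussian
blobs with a controllable shared fraction between channels (the shared
count, plus a blend between adjacent counts when the discrete grid is too
coarse, places the noise-free mask-restricted Pearson r within 0.02 of
target); line-segment fibers with normally distributed axial
orientations; Gaussian group noise. Pillar deflections follow a
build-to-peak-then-partial-release profile (peak at 70% of the movie,
relaxing to 70% of peak) so each pillar has a well-defined unique peak
frame, as spreading cells show; peak magnitudes are 0.2–0.4 µm at
defaults.

Omitted on purpose: Poisson shot noise, depth-dependent or spatially
varying PSFs, optical aberrations, uneven illumination, cantilever
hydrodynamic drag, tilted substrates, autofluorescent background
texture, and segmentation-confounding debris. Passing recovery tests
therefore demonstrates estimator correctness and noise efficiency under
the declared noise model — not robustness to every real-microscopy
artefact. Parameters of real acquisitions (pillar stiffness and spacing,
pixel size, bead radius, spring constant) remain user configuration.

All generators draw from a single per-call `numpy` Generator seed; equal
seeds give bit-identical outputs, and truth records serialise to
versioned JSON sidecars that round-trip exactly.

## Problem sizes

The default validation scales — a 10×10 lattice over 100 frames at
peak-SNR 25, 100 curves per modulus at 0.02 nN noise, 500-seed coherency
medians, 2000 null simulations — were chosen so the whole validation
suite characterises every estimator's error distribution in about half a
minute on one CPU while leaving Monte-Carlo error well below the margins
being tested.

## Known limitations

- Tracking assumes pillars never move more than half a lattice spacing
  per frame; faster motion is marked missing rather than re-associated
  globally.
- The Hertz fit assumes a single contact event and a monotone approach;
  adhesion (snap-in) and multiple contacts are not modelled.
- Blob segmentation with Otsu assumes a bimodal residual histogram inside
  the mask; very sparse or very dense scenes may need a fixed threshold.
- The ANOVA layer pools cells across experiments (no nested/mixed-effects
  structure).
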