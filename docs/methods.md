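# Methods

`chemomech` implements five independent quantifications used to study how
pancreatic cancer cells chemotax up a lysophosphatidic-acid (LPA) serum
gradient and couple receptor signaling to contractile force. Each analysis
is a small pipeline over a well-defined input class; a synthetic-data
module generates every input class with known ground truth so that all of
the statistics can be validated by parameter recovery.

## Cell-track chemotaxis statistics (`tracks`)

A track is a time-stamped sequence of (x, y) positions of one cell. The
cohort inclusion rules mirror a direct-viewing chemotaxis chamber: only
cells starting on the bridge (a user-supplied polygon) enter the cohort,
tracks are censored at their first exit, and experimenter-flagged cells
(e.g. dying cells) are dropped. An audit counter records every removal.

The chemotactic index of one cell is Cosθ, the cosine of the angle between
its displacement and the gradient direction. The default uses the **net**
displacement (end − start), giving one value per cell as in per-cell
scatter summaries; a per-step mean of step cosines is available as an
option because published figure legends rarely state which variant they
used. Cells with zero net displacement have an undefined index and are
excluded from cohort means, with the exclusion counted. Speed is total
path length over elapsed time (µm/h), deliberately path-based rather than
net-based.

Directionality is tested with the Rayleigh test on the per-cell
net-displacement angles (cells, not steps, are the experimental unit).
With mean resultant length R̄ = |n⁻¹ Σ e^{iθ}| and Z = nR̄², the p-value
uses the standard series approximation
p = exp(√(1+4n+4(n²−(nR̄)²)) − (1+2n)), clamped to (0, 1]; the test suite
verifies it against a Monte-Carlo null within 10% relative error at
n ∈ {5, 10, 50}, and its type-I error at α = 0.05 is calibrated to
0.05 ± 0.01 over 10⁵ simulations.

Angles follow the mathematical convention (counterclockwise from +x); a
`flip_y` flag at load time converts image-origin coordinates.

## Micropillar traction-force microscopy (`pillar_tfm`)

Cells on a PDMS micropillar array bend the pillars they pull on. A pillar
is modeled as a cylindrical cantilever with tip stiffness

    k = 3EI/L³,  I = πD⁴/64,

so the published geometry (D = 0.5 µm, L = 1.8 µm, E = 2 MPa) gives
k = 3.156 nN/µm ≈ 3.16 nN/µm, and force is F = k·δ per pillar. With D, L
in µm and E in MPa (1 MPa = 10³ nN/µm²) the result is in nN/µm without
further conversion.

The displacement pipeline:

1. **Detection.** Local maxima on the cell-free equilibrium image are
   refined to sub-pixel intensity centroids and snapped to a best-fit
   square lattice (rotation, pitch and origin by least squares over all
   detections; detections > 20% of a pitch off-lattice are dropped and
   counted). Snapping matters for accuracy: the lattice fit averages ~100
   centroid measurements, so the equilibrium positions carry negligible
   noise compared to any single detection.
2. **Drift.** Whole-image phase cross-correlation (sub-pixel, against
   frame 0) registers rigid stage drift; frames are resampled back before
   displacement analysis so drift cannot leak into forces. Out-of-focus
   frames can be screened with a per-frame variance score and excluded by
   the caller.
3. **Displacement.** A phase-aligned mean pillar template is built from
   the equilibrium frame (each pillar window Fourier-shifted onto a common
   centre and averaged — template noise shrinks as 1/√n_pillars). Each
   pillar/frame window is cross-correlated (normalized) against this
   template; the peak is refined by a least-squares 2-D quadratic on the
   3×3 neighbourhood and then by direct maximization of the continuous
   NCC using Fourier-shifted templates, which removes the half-pixel bias
   a quadratic fit alone retains. A second pass recentres the window on
   the first estimate. Displacements approaching half the pitch are the
   contract boundary (beyond it pillar identity is ambiguous, and the
   generator refuses to create such cases); near that boundary a smaller
   window (e.g. 5 px at a 10 px pitch) keeps the neighbouring pillar's
   tail out of the match.

The core accuracy contract — RMS error ≤ 0.05 px over 100 random
sub-pixel deflections at SNR 20 — measures ≈ 0.041 px. This is close to
the single-window information limit: the Cramér–Rao bound for localizing
one Gaussian spot of amplitude A = 1 against pixel noise σ = 0.05 is
≈ 0.04 px per axis here, which is why the template and the equilibrium
reference must carry less noise than the moving window (a naive
noisy-window-vs-noisy-window correlation bottoms out near 0.056 px and
cannot meet the contract).

Per-cell summaries average force magnitudes (forces exerted are reported
as non-negative, matching bar-graph conventions) over a caller-supplied
pillar subset (~20 pillars per cell, assigned manually in the original
protocol, so assignment is input metadata here) and a time window with a
configurable 1.5 h minimum; shorter windows are flagged, not refused.

## SHG collagen texture (`shg_texture`)

A second-harmonic-generation z-stack is maximum-projected, masked by
Otsu's automatic threshold (so dark background never biases the
statistics), linearly quantized, and profiled with gray-level
co-occurrence matrices over 4 directions × 100 distances. Five Haralick
parameters — ASM (Σp², the homogeneity measure of interest), contrast,
correlation, inverse difference moment, entropy (natural log) — give
100 × 4 × 5 = 2,000 values per image. The headline curve is
mean-over-directions ASM versus distance, with mean ± SEM across images
at cohort level.

Design choices where the legacy plugin's conventions are unknown:
64 quantization levels by default (bounds the matrix, configurable to
256); symmetric accumulation (Haralick's convention), with an asymmetric
option; masked pairs require **both** endpoints in the foreground;
direction offsets are defined y-up (0° = (+d, 0), 45° = (+d, +d) in
mathematical coordinates), documented to avoid axis-orientation drift —
note scikit-image's row-down angle convention swaps 45° and 135°, and its
diagonal offsets round d·sin θ so they diverge from true diagonals at
d ≥ 2. The in-package GLCM is validated against a brute-force
pair-enumeration oracle (exact agreement) and against
`skimage.feature.graycomatrix` where the conventions coincide.

Correlation is reported as NaN (flagged undefined) when a marginal is
degenerate, e.g. for a constant foreground whose GLCM is a single cell.

## FLIM-FRET kinetics (`flim_kinetics`)

FRET efficiency is computed from donor lifetimes as E = 1 − τ_sensor/τ_donor,
pointwise against a time-matched donor-only control (ratio normalization;
never baseline subtraction, and the control is only interpolated when
explicitly requested). Acquisition has an early phase (30-s frames for
5 min), a 60-s operator gap, and a late phase (60-s frames for 30 min);
the gap is represented as missing samples and never interpolated.

ΔE is E at the 30-s post-stimulus peak minus the mean of E over the
−300..0 s baseline; a missing 30-s sample is an error rather than a
silent nearest-neighbour. Deactivation is fitted as y = a + b·e^{−c(t−t₀)}
(t₀ = window start, default the 30-s peak) by nonlinear least squares,
initialized from the data (a₀ = last value, b₀ = first − last, c₀ from a
log-linear fit); half-time t½ = ln 2/c. Fits are rejected — never
silently returned — on non-convergence, c ≤ 0, a constant window, or t½
outside (10 s, 10⁴ s); the bounds stand in for the per-cell filtering
that published box plots imply but do not specify. Mean-trace fitting and
per-cell fitting are separate code paths because both are used in
practice. The biphasic check fits the full (30 s–30 min) and early
(30–300 s) windows independently; a genuinely biphasic (fast + slow)
decay yields a shorter early-window half-time, a single exponential does
not.

The published half-times this machinery corresponds to (hundreds of
seconds) are not reproducible without the raw lifetime movies; acceptance
is therefore parameter recovery on synthetic traces whose truth (t½ =
600 s by default) lies between the published group values: noiseless
recovery is exact to 6 significant figures and the median over 200 noisy
traces (σ = 0.05·b) is within 10%.

## Receptor trafficking (`trafficking`)

*Internalization*: membrane fluorescence fraction normalized to its t = 0
value, f(t) = 100·(mem(t)/tot(t))/(mem(0)/tot(0)). The ratio-of-ratios
form is used because the alternative reading (percent of the whole-cell
total each frame) is ambiguous in the source description; the membrane
region itself is an input mask, since manual membrane tracing is not
reproduced. Monotonicity is not assumed (receptors recycle back).

*Recycling / degradation*: in the capture-ELISA protocol, surface
receptors get a cleavable biotin label, internalize, and are chased; a
second reducing-agent (MesNa) step strips the label from receptors that
returned to the surface. The captured signal is therefore the
internalized-not-yet-recycled pool, and recycled% = 100·(s0 − s(t))/s0
**rises** as signal falls — this inversion is made explicit because assay
legends usually elide it. Degradation is direct: remaining% =
100·s(t)/s0. Values are clamped to [0, 100] with out-of-range inputs
warned and the raw (unclamped) values kept alongside; before clamping,
recycled% + remaining-not-recycled% = 100 exactly.

*Colocalization*: Pearson correlation over a 15×15 µm ROI centred on the
cell, after rolling-ball background subtraction (default radius 50 px,
the common ImageJ default; the radius must exceed the feature size, which
is the caller's responsibility). No Costes thresholding — plain Pearson.
Zero-variance channels give a flagged NaN.

*Ligand consumption*: LC-MS peak areas divided by the spiked LPA 17:0
internal-standard area per time point; an optional log-linear first-order
consumption fit reports a rate and half-life and is flagged exploratory
(it assumes simple exponential consumption, which the assay does not
guarantee).

## Synthetic data (`synthetic`)

All generators draw from one `numpy.random.Generator` seeded per call (no
global state; identical seeds are bit-for-bit reproducible) and return
ground truth alongside the data.

* **Tracks**: biased random walk, one step per frame (default 30-min
  frames for 48 h). Headings are von Mises around the gradient axis with
  concentration κ (κ = 0 is an unbiased walk — the truth for the
  null-calibration tests); step lengths are log-normal with mean 6 µm per
  frame (~12 µm/h) and CV 0.5. No published speed/persistence model
  exists for these cells, so the defaults are chosen as plausible for
  mesenchymal cancer cells rather than calibrated; they are placeholders
  in exactly that sense. The walk has no persistence term and no
  self-generated-gradient dynamics (out of scope; no model is defined for
  the latter).
* **Pillars**: unit-peak isotropic Gaussian spots (σ = 0.15 µm) on a
  square lattice (1 µm pitch, 0.1 µm/px); frame 0 is the equilibrium
  reference, later frames apply cumulative global drift (px) then
  per-pillar displacements (µm). Displacements beyond half the pitch are
  refused because pillar identity would be ambiguous. Additive Gaussian
  noise; SNR 20 means noise SD = 5% of the spot peak. No optics/PSF
  modeling — Gaussian spots are adequate for sub-pixel-tracking tests.
* **SHG textures**: a bright disc-shaped foreground on dark background.
  "Homogeneous" is an even layer with low-amplitude fine speckle;
  "fibrous" is high-contrast oriented streaks (anisotropic-smoothed
  noise), with matched per-slice foreground mean so texture differences
  are not mean-intensity differences. The ASM separation between the two
  modes rests on their intensity-spread difference, which is one of the
  ways real degraded-vs-fibrillar collagen differs but not all of them.
* **FLIM**: E(t) steps from e_baseline (0.15) to e_peak (0.30) at
  t = 30 s and decays exponentially (default rate ln 2/600 s⁻¹);
  τ_sensor = τ_donor·(1 − E) + noise with τ_donor = 4.0 ns, plus a
  time-matched constant-lifetime donor control, on the two-phase grid
  with the 60-s gap.
* **ELISA**: two-compartment first-order kinetics — the internalized pool
  loses receptors to recycling (k_rec) and degradation (k_deg), so the
  recycling assay's signal is s0·e^{−(k_rec+k_deg)t} and the degradation
  assay's is s0·e^{−k_deg t}. Multiplicative log-normal noise with a CV,
  because plate-reader signals are positive and scale-proportional. The
  two-compartment model is a synthetic stand-in for testing the
  percentage arithmetic, not a fitted biological model.

What passing these tests shows — and does not. The generators produce
idealized data: Gaussian pillars on exact lattices, mono-exponential
decays, stationary textures, walks with independent increments. Passing
recovery tests demonstrates the estimators are correct and calibrated on
their own model classes at realistic noise; it does not certify
performance on real microscopy with shape irregularities, photobleaching,
focus drift, or model misspecification beyond the specific robustness
cases tested (drift, defocus, biphasic decays, background bias).

## Numerical choices and degenerate inputs

* Problem sizes in tests and the acceptance script (e.g. 100 recovery
  trials, 10⁵ Rayleigh simulations, 200 noisy decay fits, 500-cell
  cohorts) are chosen so each check's Monte-Carlo error is well below the
  tolerance it asserts.
* Rayleigh p-values are clamped to (0, 1]; empty masks, constant images,
  zero-variance ROIs, zero net displacements, and constant decay windows
  all return flagged results or warnings rather than silent numbers.
* The CLI (`chemomech simulate|tracks|tfm|texture|flim|traffic`) is a
  thin layer over the library: YAML/flag configuration, schema validation
  with named offending keys, deterministic outputs for a fixed config,
  and a provenance JSON (package version, config hash, input checksums)
  next to every result. Exit codes: 0 success, 2 config error, 3 data
  error. Colocalization is library-only (it needs in-memory image pairs).

## Known limitations

* No continuum (substrate-deformation) TFM, no cell segmentation, no
  automated tracking from raw movies, no MSD/persistence analysis, no
  fiber-orientation analysis, no frequency-domain lifetime estimation —
  each pipeline starts from the measurement its upstream instrument
  software produces.
* The masked-GLCM conventions (quantization, symmetry, parameter set
  beyond ASM) follow the classical Haralick defaults where the legacy
  plugin left them unspecified; all are configurable.
* Pillar-to-cell assignment and the membrane mask are inputs, not
  inferences.
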