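# Methods

## Scope and data model

The package analyzes single-wavelength fluorescence movies of odor
responses in the honey bee brain: stacks of 100 frames at 5 Hz
(integration ≈ 50 ms/frame), 12-bit camera counts, with the odor given
at frame 15 for 1 s. Frame indices are 1-based and inclusive in every
user-facing parameter (baseline frames 9–11, amplitude windows 19–21
and 49–51), matching the conventions of the imaging literature;
conversion to 0-based array indexing happens in exactly one function
(`types.frames_to_slice`). Movies are stored as multi-page TIFF with a
JSON sidecar for acquisition metadata; masks as binary PNG (0/255);
tables as long CSV with an XLSX import path that requires an explicit
layout mapping, because supplementary spreadsheets have no single
canonical shape.

## Processing pipeline

The stage order is fixed: ΔF/F, then per-frame median subtraction, then
spatial Gaussian filtering, then biphasic amplitude extraction.

* **ΔF/F** is `100·(F − F₀)/F₀` with `F₀` each pixel's mean over the
  baseline frames. Pixels with `F₀ ≤ 0` are a hard error (they cannot
  occur in real camera data with nonzero bias, and the generator keeps
  baselines strictly positive).
* **Median correction** subtracts the median over the *full frame*, not
  the mask, because it runs before masking. It removes any
  frame-constant additive term exactly and is idempotent; applying it
  twice warns, since that indicates pipeline misuse.
* **Gaussian filter**: window 7 px for AL (and whole-brain overviews),
  3 px for LH/MB. The σ of the truncated kernel is not dictated by the
  window alone; we use σ = (window−1)/4 so the window spans ±2σ (a
  common truncation convention), configurable. Boundary handling is
  edge-inclusive reflection, which avoids edge darkening inside masks
  that touch the image border. Whether amplitude windows should be
  taken on filtered or unfiltered ΔF/F is a genuinely open choice; we
  default to filtered (the map you display is the map you quantify),
  with `ProcessingConfig(apply_filter=False)` available.
* **Biphasic amplitude** = mean(frames 19–21) − mean(frames 49–51),
  exploiting both the positive transient and the long undershoot for
  contrast. The map is linear in ΔF/F by construction.

Distances between presentation-averaged maps are plain Euclidean over
in-mask pixels (the square root is applied; a squared-distance mode
exists for sensitivity checks). Per-bee matrices are averaged across
bees entrywise without normalizing by mask area; mask areas are equal
in simulation, but for real cohorts with differing masks this choice
matters and is deliberately exposed rather than hidden.

Ward clustering uses the Ward.D2 criterion (Lance–Williams update on
squared Euclidean distances, scipy's `linkage(method="ward")`); merge
heights are nondecreasing for metric input, which the tests enforce.
The Mantel test correlates upper triangles, jointly permutes one
matrix's rows and columns, and reports the two-sided
`(#{|r_perm| ≥ |r_obs|} + 1)/(B + 1)` p-value; with ≤ 8 labels it
switches to exhaustive enumeration over all n! relabelings. The default
B = 9,999 gives a p floor of 10⁻⁴.

## Statistics

The repeated-measures ANOVA is the classical one-way within-subject
decomposition, reported with uncorrected degrees of freedom
(df = k−1, (k−1)(n−1)); a Greenhouse–Geisser option exists but is off
by default. The Dunnett post hoc reuses the ANOVA error mean square:
`t_i = (ȳ_i − ȳ_ctrl)/√(2·MSE/n)`, and the two-sided adjusted p is
`1 − P(max_j |T_j| ≤ |t_i|)` under the equicorrelated (ρ = 1/2)
multivariate-t null, evaluated by Gauss–Hermite quadrature over the
shared control variate and adaptive quadrature over the studentizing
chi variable (scipy's Dunnett test assumes independent groups and its
own error term, so it cannot be reused here; our CDF is verified
against direct Monte-Carlo simulation in the tests). Dunnett sidedness
is two-sided, the conservative default.

Wilcoxon matched-pairs drops zero differences and uses the exact null
for ≤ 25 nonzero pairs; Friedman reports the chi-square statistic with
df = k−1 and average-rank tie handling. The vapor-pressure regression
is OLS of per-odorant mean amplitude on log₁₀(VP in mmHg), reporting
R² and F with (1, n−2) df — (1, 14) for the 16-odorant panel. The
Fisher z comparison of two correlations is
`z = (atanh r₁ − atanh r₂)/√(1/(n₁−3) + 1/(n₂−3))`.

Vapor pressures for the 16 aliphatic odorants are a constants table
compiled from standard physico-chemical references (~25 °C, mmHg).
They are literature values, not measurements tied to any particular
experiment, and can be overridden per stimulus.

## The synthetic generator

The generator emulates the signal structure the pipeline assumes; it is
a benchmark model, not a biophysical model of GCaMP6f.

**Forward model.** Pixel value at frame f:
`B(x,y) · (1−β)^(f−1) · (1 + A/100 · P(x,y) · k(f)) · (1 + j_f) + ε`,
clipped to [0, 4095] and rounded to integer counts. The response enters
multiplicatively so ΔF/F recovers `A·P·k` *exactly* in the noiseless,
bleach-free limit — this provability is why the model is multiplicative.
`B` is a smooth vignetted baseline (~3,000 counts), β the per-frame
bleach fraction (default 5×10⁻⁴), `j_f` Gaussian illumination jitter
(default 0.2%/frame), ε Gaussian pixel noise (default 8 counts). Noise
magnitudes and bleach rates are free parameters chosen to look like a
well-behaved preparation; the source experiments report no values for
them.

**Kernel.** Piecewise: zero before onset (frame 15), linear rise to a
plateau at frames 19–21, linear decline to the trough (depth −0.3 of
peak) at frame 50, exponential recovery (τ = 30 frames). The lobes are
placed so the pipeline's default measurement windows sit exactly on the
peak plateau and the trough. The kernel contrast
`mean k[19..21] − mean k[49..51]` links injected amplitude to measured
amplitude.

**Spatial patterns.** In AL mode, 23 Gaussian blobs ("glomeruli") on a
hexagonal layout inside an elliptical mask (the count is an arbitrary
but plausible choice at this magnification); LH/MB mode uses 8 much
wider blobs, i.e. a smooth low-spatial-frequency field. Each odorant
has 3-D latent chemical coordinates — chain length (dominant axis),
C–OH vs C=O moiety, subtype within moiety — and each blob a tuning
vector drawn uniformly over a box covering the latent space; blob
weights fall off as a Gaussian in latent distance, so pattern distances
increase monotonically with chemical distance. Bee-level and (smaller)
presentation-level log-normal jitter on blob weights provide individual
variability and trial-to-trial variability. Patterns are nonnegative
and unit-norm within the mask.

The axis scales (chain 1.2/carbon, moiety 0.6, subtype 0.35), the blob
tuning width (0.9) and the amplitude model `A = 30 + 12·log₁₀(VP)` are
chosen together so the generated cohorts exhibit the qualitative odor
code of the real preparation: strong vapor-pressure dependence of
amplitudes coexisting with chain-length-first cluster structure. With
blob tunings drawn from a distribution too narrow for the latent span,
extreme chain lengths fall outside all tunings and their patterns
flatten — the box-uniform tuning draw exists to prevent exactly that.

Geometry detail that matters: the elliptical mask covers *less than
half* the frame. The frame-median illumination correction then sits in
the silent surround, so in the noiseless limit it is exact, and with
bleach/jitter it removes exactly the frame-constant term it is meant to
remove. (With a mask covering most of the frame, the median rides on
the quantized in-mask signal and picks up ~1 count of bias — enough to
violate a 1% recovery budget.)

**Ground truth.** For every bee × stimulus × presentation the generator
records the injected amplitude and the *response gain*: kernel contrast
× in-mask mean of the median-corrected, filtered pattern. The expected
pipeline intensity is amplitude × gain — an analytic consequence of the
forward model, so recovered/injected comparisons are exact inversions,
not circular re-measurements.

**Behavioral matrix.** A 16×16 stand-in for behaviorally measured odor
distances: the latent distance matrix plus seeded symmetric positive
noise scaled by the distortion level; at distortion 0 it equals the
latent matrix exactly, and increasing distortion monotonically degrades
its expected Mantel correlation with the neural matrices.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: movement artifacts, optics/PSF, true
GCaMP kinetics and saturation, glomerulus-to-glomerulus correlation
structure beyond the latent tuning model, inter-animal mask
differences, and mechanosensory air responses. Pipeline correctness on
synthetic data demonstrates that the implementation computes what it
claims; it does not validate the biological assumptions.

## Problem sizes and numerical choices

The validation suite and the acceptance script run cohorts at 64×48
pixels (module tests at 48×36), 100 frames, 10–11 bees, the full
17-stimulus panel with 2 presentations — small enough to run a
20-cohort structure-recovery sweep in a couple of minutes while keeping
every rate and statistic meaningful at the published design sizes
(11 bees × 17 stimuli → F with 16 and 160 df; 16 odorants → 120 pairs,
regression F with 1 and 14 df). Null calibrations use 250 ANOVA and
200 Mantel replicates (999 permutations each). All randomness flows
from explicit seeds through `numpy.random.SeedSequence`, with fixed
integer namespaces separating bee gains, pattern jitters, movie noise
and behavioral distortion, so cohorts are reproducible movie-by-movie
and ground-truth files are byte-identical across runs with one seed.

Degenerate inputs are errors, not silent answers: empty masks,
nonpositive baselines, even filter windows, overlapping amplitude
windows, incomplete block designs (the analysis keeps only animals with
the complete panel), zero-variance matrices in Mantel tests, and
all-zero differences in matched-pairs tests. Distance matrices tolerate
asymmetry only to a configurable 10⁻⁶ (symmetrized by averaging);
anything larger is rejected. Ties in Ward merges are broken
deterministically by scipy's ordering; identical seeds give identical
dendrograms.

## Known limitations

* The supplementary layout of published datasets varies; XLSX import
  deliberately refuses to guess and requires a layout mapping.
* Cross-bee averaging of distance matrices does not normalize by mask
  area (see above); supply equal-area masks or pre-normalize if this
  matters for your data.
* The Friedman statistic is reported as chi-square with df = k−1; some
  software reports an F-transformed variant, which will differ.
* Reported vapor-pressure constants are temperature-dependent
  literature values; regressions against them can shift at the second
  decimal depending on the source table.
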