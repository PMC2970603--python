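# Methods

## What the pipeline computes

The package studies one question on controlled synthetic data: *how much of
the texture information separating MS-plaque tissue from white matter
survives a threefold increase in MRI slice thickness?* Thick slices are not
re-acquired but simulated — each pixel of a "3 mm" slice is the integer-
rounded mean of three consecutive "1 mm" slices — so every other imaging
property is held fixed and any downstream difference is attributable to
thickness alone. Separability is measured twice, on 264 texture parameters
per ROI: statistically (share of parameters with a significant paired
Wilcoxon signed-ranks test at α = 0.05, no multiple-testing correction —
the raw proportion *is* the statistic) and operationally (median accuracy
of repeated discriminant classification on the three best features by
Fisher coefficient).

## Phantom cohort model

Each of `n_subjects` (default 23) phantom subjects is imaged at
`n_levels` (2) anatomical levels with two sequences ("T1", "T1C"), each as
a stack of `slices_per_level` (3, odd) thin slices of `slice_shape`
(128×128) integer intensities in `[0, intensity_depth]` (4095).

**Texture.** Each tissue class (WM, NAWM, plaque) carries a descriptor
(`mean_intensity`, `contrast_scale` in intensity units,
`correlation_length` in pixels, optional causal AR coefficients). The
texture field is a stationary Gaussian random field — white noise convolved
with an isotropic Gaussian kernel of width `correlation_length`, normalised
analytically to unit variance — scaled by `contrast_scale` and added to
`mean_intensity`; with `ar_coefficients` set, a causal four-neighbour
autoregressive field is generated instead (used for parameter-recovery
checks and anisotropic-texture phantoms). Defaults: WM/NAWM mean 600,
contrast 30, correlation length 1.2 px; plaque mean 450 (hypointense on
T1-like images), contrast 55, correlation length 3.0 px. "T1C" adds
`t1c_plaque_offset` (150) to the plaque mean, emulating contrast
enhancement. These values are the package's own choice of a plausible
operating point — the original study reports no per-tissue intensity or
texture statistics — tuned only to reproduce the *qualitative* ordering of
separabilities, which is the phantom's reason to exist.

**Why NAWM gets a zero-mean perturbation.** NAWM must be nearly
indistinguishable from WM. A deterministic offset (e.g. always +2%
contrast) would not achieve that: a paired signed-ranks test across ~46
subject×level pairs detects *any* consistent shift with high power, however
small, so variance-sensitive parameters would all turn significant. NAWM
therefore uses the WM descriptor with contrast multiplied by
`1 + 0.02·u`, `u ~ Uniform(−1, 1)` drawn once per subject: the marginal
perturbation magnitude is kept, but paired differences are symmetric about
zero and the WM-vs-NAWM contrast behaves like a null, as intended.

**Through-plane structure.** Consecutive slices share a correlation
`through_plane_rho` ∈ [0, 1] (default 0.6): each slice's field is
`ρ·previous + √(1−ρ²)·fresh`. ρ = 1 with zero noise gives identical
slices; ρ = 0 gives independent ones, in which case three-slice averaging
reduces the noise SD by √3 (verified by Monte Carlo in the tests).

**Noise.** Rician magnitude noise (`noise_sigma`, default 4 intensity
units) is applied per slice — magnitude MRI noise is Rician, and at the
phantom's signal levels it is nearly Gaussian; set 0 to disable. Intensities
are then rounded half-up and clipped to the integer range.

**ROI geometry.** Per subject×level (shared by both sequences and all
slices): a WM rectangle (16×16), a NAWM rectangle of the same size, an
irregular 4-connected plaque blob with pixel count drawn uniformly from
`msi_size_range` (39–2477, the study's reported range), and a 10×10
rectangle inside a separate 14×14 plaque patch. Blobs are grown by seeded
stochastic (Eden-type) region growth, which guarantees the exact target
size and 4-connectivity — properties a thresholded-random-field
construction cannot guarantee. A spec whose largest plaque cannot fit the
growth region is rejected at generation time.

**What the phantom does not emulate:** anatomy (no brain geometry, no
partial-volume mixing at tissue borders beyond what averaging induces), 
k-space acquisition, bias fields (the study's data were pre-filtered), or
subject-specific plaque load. Consequently, passing tests demonstrate that
the *pipeline* behaves correctly and that the study's qualitative structure
(separability ordering, thickness robustness) emerges under controlled
conditions — they say nothing numerical about clinical tissue.

## Normalization and the texture bank

Each ROI is normalised independently: clip to `[μ−3σ, μ+3σ]` (population
σ; deterministic and immaterial against the sample convention at ROI sizes
≥ 39) and quantize by `level = 1 + floor((x−μ+3σ)/(6σ)·Ng)` with the top
boundary assigned Ng. Ng defaults to 64 (6-bit); co-occurrence and
run-length features use the quantized levels, histogram/gradient/wavelet/AR
features the clipped but unquantized intensities. A constant ROI maps to
level ⌈Ng/2⌉ and raises a degeneracy flag that downstream feature code
turns into explicit NaN markers.

Bank composition (total 264, fixed canonical order):

- **histogram (11):** mean, population variance, skewness, excess
  kurtosis, nearest-rank percentiles 1/10/25/50/75/90/99. The 4-moments +
  7-percentiles split is this package's documented choice for an
  11-parameter histogram group.
- **gradient (4):** moments of `√(((below−above)/2)² + ((right−left)/2)²)`
  over pixels whose four axial neighbours lie in the mask.
- **co-occurrence (220):** symmetric, ROI-confined (both pair endpoints in
  the mask — irregular plaque ROIs must not borrow neighbouring tissue)
  matrices for distances 1–5 and directions 0°/45°/90°/135°, the latter
  written `S(d,−d)`; 11 statistics each (angular second moment, contrast,
  correlation, sum of squares, inverse difference moment, sum
  average/variance/entropy, entropy, difference variance/entropy). Sum
  variance is centred on the sum average; entropies use natural logs with
  0·log 0 = 0.
- **run-length (20):** maximal equal-level runs truncated at the mask
  boundary, four directions; short/long-run emphasis, grey-level and
  run-length non-uniformity, and fraction = runs/pixels.
- **wavelet (4):** one-level orthonormal Haar sub-band energies on the
  mean-filled bounding box (mean-padded to even size), averaging squared
  coefficients whose 2×2 support overlaps the mask. Haar's minimal support
  bounds boundary contamination to one coefficient ring.
- **autoregressive (5):** OLS fit of the causal four-neighbour model on
  mean-centred intensities over pixels with all causal neighbours in the
  mask (≥ 20 required); σ is the residual SD. Rank-deficient systems yield
  NaN.

Every family is checked against an independent brute-force oracle (direct
pair/run/pixel enumeration, or pywt vs a direct 2×2 block filter) to 1e-10
relative tolerance on random irregular ROIs.

## Statistics

**Wilcoxon signed ranks.** Zero differences removed, mid-ranks for ties.
Up to n = 25 the two-sided p is exact: the null distribution of the
(doubled, hence integer) positive-rank sum is built by dynamic programming,
equivalent to enumerating all 2ⁿ sign patterns; `p = 2·min(P(W⁺≤w),
P(W⁺≥w))` capped at 1. Beyond 25, a normal approximation with tie-corrected
variance and continuity correction. Pairing unit is subject × anatomical
level (up to 46 pairs) by default, configurable.

**Type-I calibration.** With WM and NAWM generated from the identical
descriptor, the screening is a true null. Because the 264 parameters are
strongly correlated within families, a *single* cohort draw of the
significant-fraction is overdispersed relative to a binomial reference; the
calibration check therefore averages the percent-significant over three
independent cohort draws and compares against the Binomial(264, 0.05) 99%
band — variance reduction of the estimator, not a widened band.

**Fisher coefficient.** `D = ((m₁−m̄)² + (m₂−m̄)²)/2 = (m₁−m₂)²/4`,
`V = (v₁+v₂)/2` with population variances; `F = D/V`. `V = 0` with `D > 0`
maps to +∞ (ranked above all finite values), `0/0` and parameters with
undefined values are excluded; top-3 ties break lexicographically for
reproducibility.

## Classification protocol

Train fraction 0.5 at (subject, level) granularity — the source experiment
states separateness but not the ratio; a symmetric split maximises both set
sizes and is a config knob. The split is applied to *every* design, not
only cross-thickness ones: stricter, and it removes optimistic bias from
repeated subjects. Feature selection runs per repetition on the training
rows at the training thickness. The linear rule is pooled-covariance LDA
with equal priors; the nonlinear rule ("NDA", never specified in the
MaZda-era literature it descends from) is quadratic discriminant analysis —
deterministic and parameter-free in a 3-feature space; a ridge
`λ = 10⁻⁶·trace/dim` is added once if a covariance is singular. The
reported interval is the [2.5th, 97.5th] percentile of the 100 repetition
accuracies (the interval definition is a reporting knob; accuracy is the
pooled fraction of correct test ROIs, in percent).

## Problem sizes

The default study conditions are the full cohort: 23 subjects × 2 levels ×
2 sequences × 2 thicknesses × 4 ROIs = 736 feature vectors, 100 repetitions
per classification cell. The calibration and noise checks use reduced
phantoms (64×64 slices, single sequence) because they probe scalar
properties whose precision depends on pixel counts, not cohort breadth.

## Known limitations

- Phantom textures are stationary and isotropic (unless AR-configured);
  real white matter is neither, and real plaque texture changes with
  thickness through anatomy-dependent partial-volume effects the averaging
  model only approximates. In particular the *intra-tissue*
  thickness-comparison percentages on the phantom should not be read
  against the clinical ones — the phantom has no mechanism making plaques
  more thickness-sensitive than white matter.
- The 11-histogram/4-gradient group compositions are reconstructions that
  honour the published counts; the originating software's exact
  configuration is not recoverable.
- The Haar sub-band orientation naming (LH vs HL) follows pywt's
  convention; only the energies are used downstream.
- Exact Wilcoxon enumeration is capped at n = 25; beyond that the
  tie-corrected normal approximation is standard but approximate.
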