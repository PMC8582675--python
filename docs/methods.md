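# Methods notes

This note records the modeling assumptions, parameter defaults and
numerical conventions behind `mammotex`, and what the synthetic-data
experiments do and do not demonstrate.

## Feature bank

The bank holds 341 features in eight families (12 histogram, 7
co-occurrence, 7 run-length, 2 fractal, 36 LBP, 125 Laws, 120
co-occurrence-of-Laws, 32 Gabor).  The classical texture literature
defines these families but not a unique member list at exactly these
counts, so the concrete membership is a package decision:

- **Histogram (12)** — mean, SD, skewness, kurtosis, energy, entropy,
  min, max, median, 5th/95th percentile, IQR.  Skewness is Fisher g1
  and kurtosis the non-excess Pearson ratio (a Gaussian scores 3); both
  are defined as 0 for a constant window.  Histogram energy/entropy use
  a 64-bin histogram between the window min and max.
- **Co-occurrence (7)** — energy (angular second moment), contrast,
  correlation, homogeneity, entropy, cluster shade, cluster prominence;
  symmetric matrices at distance 1 in the four principal directions,
  statistics averaged over directions.  Correlation is defined as 0
  when a marginal variance vanishes.
- **Run-length (7)** — SRE, LRE, GLN, RLN, RP, LGRE, HGRE (Galloway/Chu
  set), four directions averaged; grey levels are indexed from 1 in the
  low/high-grey-level emphasis terms.
- **Fractal (2)** — differential box-counting dimension (a flat surface
  scores 2) and the slope β of the radially averaged power spectrum.
  Windows smaller than 8 px per side return 0 for both (too few scales
  or rings to fit a slope).
- **LBP (36)** — classic square-neighbourhood 8-bit codes (threshold
  neighbour ≥ centre) over interior pixels, reduced to their minimal
  cyclic rotation; there are exactly 36 such binary necklaces, and the
  feature vector is the normalised 36-bin histogram.  The common
  circular-interpolated LBP variant samples diagonal neighbours off the
  pixel grid and was deliberately not used, since only the classic code
  yields the 36-pattern count.
- **Laws (125)** — the 25 5×5 kernels from outer products of
  L5/E5/S5/W5/R5, each summarised by mean, mean absolute value, SD,
  energy (mean square) and 64-bin entropy.
- **Co-occurrence of Laws (120)** — the only decomposition of 120
  consistent with the Laws bank: the pure low-pass L5L5 map is
  excluded and the remaining 24 response maps are re-quantized to 64
  levels and summarised by 5 co-occurrence statistics (energy,
  contrast, correlation, homogeneity, entropy).
- **Gabor (32)** — 4 orientations (0°, 45°, 90°, 135°) × 4 wavelengths
  (2, 4, 8, 16 px, a geometric ladder spanning 2–16 px) × mean and SD
  of the complex filter magnitude.

Grey-level quantization for all matrix-based families is a per-window
linear rescale to 64 levels between the window's own min and max
(constant windows map to level 0).  This makes co-occurrence and
run-length features invariant to global positive affine intensity maps,
which is tested.  All entropies use base-2 logarithms.

Filter-based features (Laws, Gabor) are computed on the cropped window
with reflective boundary handling, not on the whole image: each
window's value then depends only on its own pixels, which keeps the
per-window brute-force oracle in the test suite exact.  Gabor responses
use FFT convolution over a symmetrically padded window; this is
numerically identical to direct reflect-mode convolution (verified in
tests against the direct route).

## Lattice

Windows are squares of 6.3 mm side (`round(6.3 / pixel_spacing)` px),
tiled from the corner of the mask's bounding box; only windows whose
in-mask pixel fraction reaches `min_mask_coverage` (default 1.0, i.e.
fully inside the breast) are kept, avoiding edge-window artifacts.
Both parameters are configurable.  The image-level feature value is the
unweighted mean over surviving windows; an image with no surviving
window yields missing values with a warning, never silent zeros.

## Robustness metrics

IAV, IWV and CMV follow the definitions in the README.  Conventions the
definitions leave open:

- **Percentiles** use linear interpolation between order statistics
  (the numpy default).
- **Reference population** — all individual breast images (both sides
  of each woman) with compressed thickness in the band, default
  40–60 mm, i.e. ±10 mm around a 50 mm phantom; at least 20 qualifying
  images are required for stable percentiles.
- **IWV cohort rule** — a woman qualifies when at least one side lies
  in the thickness band, but both sides must exist to form |l − r|;
  women missing a side are excluded with a warning.
- **Degenerate features** (c95 = c5) get missing metrics, never
  infinities, so ranking stays total on valid features.
- No Z-scoring precedes the metrics: the percentile-width denominator
  already makes them scale-free (they are invariant under joint affine
  maps of a feature's phantom and clinical values, which is tested).

## Reduction and classes

The moment filter excludes features with |skewness| > 6 or kurtosis
> 50 on the clinical distribution (thresholds configurable; Z-scoring
first is a no-op for these affine-invariant moments — both raw and
Z-scored values are logged).  Correlation pruning is greedy: while any
pair of survivors has |Pearson r| > 0.95, the highest-|r| pair is
resolved by dropping its lower-IQR member; IQR is computed on raw
values (IQR of Z-scored values would be IQR/σ, a different ordering),
and IQR ties drop the later catalog entry, making the procedure
deterministic and row-order invariant.  Absolute correlation is used
because anti-correlated duplicates are equally redundant.

Survivors are sorted ascending by (CMV, name) and the `count mod 4`
highest-CMV features trimmed so four equal contiguous classes A–D
remain.

## Evaluation design

Fold assignment randomises matching strata, not images, so each
stratum (1 case + 4 controls) stays intact within one fold; with 115
strata and k = 5, every held-out fold contains 23 cases and 92
controls.  Models use 9 features — the events-per-coefficient rule
⌊115 · (4/5) / 10⌋ with one coefficient per feature.  Features are
standardised with training-fold statistics before the
maximum-likelihood logistic fit (logistic MLE is affine-equivariant, so
this only conditions the optimisation); a non-converging fit — in
practice complete separation — is refit with a tiny ridge penalty
(1e-4 · n) rather than dropped, keeping the record design balanced.
Fold AUCs are computed by the rank statistic on the held-out images and
averaged (not pooled) over folds.

The same 10 partitions are reused for every class and model so that
AUC differences reflect features rather than folds; feature subsets are
drawn without replacement with per-(class, model) seeds derived from
the master seed via `numpy.random.SeedSequence`.

The mixed model is a REML random-intercept fit (statsmodels `MixedLM`)
of AUC on class with reference level D and partition as the grouping
factor, with Wald tests at the 0.05 level; a singular random-effect
variance triggers a flagged OLS refit.  The overall p-value is the
joint Wald test of all class coefficients.

## Synthetic data

The generators emulate the structure of the study inputs, not their
anatomy:

- **Textures** are band-limited power-law (1/f^β) Gaussian random
  fields — the standard stochastic model for mammographic parenchyma —
  with offset 1000, amplitude 200 (detector-like units) and β ≈ 3 for
  the phantom; per-woman β ~ U(2.2, 3.4), offset ~ U(800, 1200),
  amplitude ~ U(150, 300) provide inter-woman variation.
- **Acquisition physics** is blur (Gaussian, σ in px) → multiplicative
  contrast gain (kV proxy) → additive Gaussian noise with SD
  proportional to the local signal (mAs proxy; noise ∝ 1/√mAs,
  anchored at 120 mAs with base noise fraction 0.03).  The default
  phantom series replays six clinically plausible (kV, mAs) settings —
  28/160, 29/140, 30/120, 31/120, 31/140, 31/180 — twice each, giving
  12 acquisitions.
- **Bilateral cohorts** realise both sides of a woman from the *same*
  white-noise field with parameters perturbed multiplicatively by
  `bilateral_jitter` (default 0.05), mimicking the similarity of a
  woman's two breasts; per-side thickness is sampled in 35–65 mm so the
  40–60 mm band filter has work to do.
- **Breast masks** are half-ellipses touching the left image edge
  (a CC-view-like outline), giving the lattice both interior and
  boundary windows.  Default images are 256×256 px at 0.2 mm spacing
  (32 px windows, an 8×8 lattice) — a deliberate down-scaling of real
  mammography (~0.07 mm) that preserves the geometry of the method;
  all sizes are parameters.
- **Case-control tables** are generated at the feature level:
  unit-variance Gaussian features, one case and `controls_per_case`
  controls per stratum, cases shifted by `effect_size` (in SD units) on
  designated signal features.  An optional within-stratum random effect
  (`stratum_sd`) models matching-induced correlation; its default is 0
  so the closed-form binormal relation AUC = Φ(effect/√2) holds exactly
  and can serve as a test oracle.
- **Table-level robustness generator** — parameter-recovery tests need
  a known per-feature physics sensitivity, which image-level simulation
  cannot provide in closed form; `simulate_robustness_tables` therefore
  generates phantom/cohort feature tables directly, with phantom values
  responding linearly (slope = the true sensitivity, drawn U(0, 2)) to
  a common physics axis, small replicate noise (SD 0.05), per-woman
  latents (SD 1) and bilateral noise (SD 0.2).

All generator randomness flows from one integer seed through
`SeedSequence([seed, stream_tag, ...])` spawning, so every artifact is
byte-reproducible.

What passing the synthetic experiments shows: the metrics rank feature
robustness correctly when physics sensitivity is the dominant nuisance,
the matched design and resampling machinery are structurally correct,
and planted class-level signal propagates to the mixed model at the
expected magnitude.  What it does not show: behaviour on real
parenchymal texture (no anatomy, no scanner processing, no
thickness-dependent feature drift beyond the band filter, no
covariate-driven matching structure), so real-data robustness
distributions and AUC levels are outside what these tests can certify.

## Problem sizes

Default test and acceptance runs use desk-scale sizes chosen to
exercise every code path with comfortable statistical margins: 256×256
(or 512×512 for the oracle comparison) synthetic images, 12 phantom
acquisitions, 20–100 women, 115 case strata, and the full 10×10
resampling design at 108 features; the replicated class-separation
check runs 20 replicates at a reduced 4-model × 2-partition design per
replicate.

## Known limitations

- Family membership at the fixed counts is a reconstruction; other
  member sets with the same cardinalities exist.
- The 120-feature co-occurrence-of-Laws decomposition (24 maps × 5
  statistics) is the only one consistent with the Laws bank, but it is
  a design choice, not an identity.
- Breast segmentation is out of scope: masks are inputs.
- A single window scale (6.3 mm) is implemented; multi-scale search is
  not.
- Harmonisation/standardisation transforms across scanners are
  deliberately not provided — the package selects robust features
  rather than correcting fragile ones.
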