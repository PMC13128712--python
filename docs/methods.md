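# Methods

## The measurement model

Each chelal digit is registered to its tip→condyle reference axis (length
`L2M` for the moveable digit, `L2F` for the fixed digit, both in μm) and
described two ways:

1. an 18-station equispaced **grid profile** of perpendicular heights
   y₁..y₁₈, with station 1 at the tip where x = 0 and y = 0 by definition;
2. a scored **asperity list** — the locations and heights of every peak
   (tooth) and gullet (valley) on the mastication surface (0 < x ≤ x_ie),
   optionally carrying ATB (alternate-top-bevel, saw-like) or FT (flat-top,
   blade-like) tooth classes, ordered distal→proximal.

Fixed digits are stored in the **occlusal frame**: the native profile is
flipped vertically (y → −y) so that fixed-digit gullets read as positive
relief and the peak/gullet vocabulary is uniform across digits. The flip is
an involution; applying it twice recovers the input. Asperity lists are
authoritative inputs — grid-derived extraction (`extract_asperities`, via
prominence-filtered local extrema with plateau-midpoint tie-breaking) is a
convenience that is never silently substituted.

Sign convention: `tip_offset_um` > 0 means the fixed digit tip overhangs
anteriorly (overbite); < 0 is underbite; exactly 0 is an exact tip match,
counted as neither and reported separately so the three proportions sum to
one exactly.

## Tribological statistics

Over the i_e stations with x ≤ x_ie:

- R_q = √((1/i_e) Σ y_i²), ȳ = mean height, σ² = R_q² − ȳ² (the population
  variance, held as an algebraic identity to 1e-12 relative),
  tel = Σ |y_i| (profile stretch), W = height at the station nearest x_ie
  (nearest-station convention; interpolation would be an alternative but
  the grid spacing ≈ 2 μm makes the difference immaterial at measurement
  precision).
- xRp is the location of the tallest peak asperity. xRv is implemented as
  the location of the **deepest gullet**, read in the occlusal frame as the
  gullet asperity of maximum relief; the alternative reading (a second copy
  of xRp) would carry no information, so the deepest-valley reading is
  adopted. Ties break toward the most distal (smallest x) asperity, which
  makes first tooth contact deterministic.

Lever mechanics: VR = L1U/L2M ∈ (0,1); F2 = VR·F1; mastication-surface
length = L2M − L1U; maximum effective gape angle δ = cos⁻¹((L2M − x_ie)/L2M),
monotone in x_ie with endpoints 0° and 90°.

Tooth summaries report per-digit mean counts of each class and first-order
transition probabilities over consecutive classified teeth read
distal→proximal, pooled over a cohort's specimens. Rows with no observed
transitions are flagged unsupported and left at zero, never fabricated.

## Occlusion distances

Each digit's pooled peaks and gullets are sorted by x into one location
vector; heights weight the locations **within each individual**:

- peak run — moveable digit: w = y; fixed digit: w = (−y) − min(−y)
  = max(y) − y. Subtracting the minimum of the weight vector itself is the
  only reading of the "subtract min(y)" adjustment that guarantees
  non-negative weights, and is the one implemented.
- gullet run — heights are first reflected, y → max(y) − y, then the same
  digit-specific weighting applies.

Weights are always normalized to unit mass; the two runs' distances are
averaged unweighted into `d_mean`. If every weight vanishes (a
constant-height fixed digit), the encoding raises a degenerate-mass error;
an explicit `uniform_fallback` flag substitutes equal weights instead.
A `subset` option restricts the pooled list to peaks or gullets only for
sensitivity analysis; pooled is the default.

W₂ between two weighted distributions on a line is computed exactly by
merging the two cumulative-weight breakpoint sequences and integrating the
squared quantile difference piecewise — no sampling, no LP. The routine is
validated against a discrete optimal-transport linear program on random
instances (agreement to 1e-9; observed ≈ 1e-15).

Location scaling: within one individual the two digits share a physical
scale, so `occlusive_distance` compares raw μm locations. Across species,
digits of unequal axis length are compared, so `cross_digit_distance_matrix`
normalizes each digit's locations by its own x_ie by default (both
behaviours are flags).

A perfectly complementary pair — every moveable asperity meeting an exactly
opposite fixed-digit feature — yields identical encoded point sets and
distance exactly 0 in both runs. Exactness requires the pooled moveable
heights to touch 0 (the gullet floor sits on the reference axis);
`perfect_complement_pair` shifts input heights accordingly and stores the
fixed digit height-flipped (max(y) − y). For constant input heights the
fixed-digit weights degenerate and the uniform fallback must be enabled.

## Ω summaries and Bures–Wasserstein geometry

A cohort's digit profiles at stations k₀..k₁ form the p×n matrix Y (column
per specimen) and the average non-scaled, non-centred SSCP summary
Ω = (1/n)YYᵀ — positive semi-definite by construction, retaining mean
profile size so larger variance weighs more in comparisons. The station
range is a constructor parameter: 2..18 gives the canonical 17×17 form
(the tip is omitted as identically zero); 2..11 restricts to the
mastication surface.

Ω matrices are compared with the Bures–Wasserstein distance
δ(A,B) = [tr A + tr B − 2 tr((A^½BA^½)^½)]^½ — the 2-Wasserstein distance
between centred Gaussians with these covariance-like matrices. The
geodesic γ(t) = (1−t)²A + t²B + t(1−t)[(AB)^½ + (BA)^½] has exact
endpoints, the Wasserstein mean (1/4)[A + B + (AB)^½ + (BA)^½] at its
midpoint, and is bounded above in the Loewner order by (1−t)A + tB; the
bound check is spectral with tolerance 1e-8 of the interpolant's trace.

Numerical choices: matrix square roots go through `scipy.linalg.eigh` with
eigenvalues in [−1e-9·tr, 0) clamped to zero (cohort Ω matrices can be
numerically singular when n is small or profiles collinear); anything below
the band is a hard not-psd error. (AB)^½ is computed via the similarity
A^½(A^½BA^½)^½A^{−½}, with the pseudo-inverse on the clamped spectrum as
the continuous extension at singular A, and (BA)^½ = ((AB)^½)ᵀ. Self-
distances computed through the full formula are zero only to floating
round-off (≈ √ε of the trace scale); tests bound them at 1e-5·tr.

## Ordination and the character network

Metric MDS minimizes stress-1 = √(Σ(d−d̂)²/Σd²) by SMACOF majorization
from a classical-scaling (Torgerson double-centring) start; the recorded
stress sequence is monotone non-increasing and the run is deterministic
given the seed (the seed is only consumed for fully degenerate starts).
Convergence: stress decrease < 1e-9 or 10,000 iterations. An all-zero
distance matrix returns a coincident configuration with stress 0 and a
warning. Because the transport distance is itself a metric, no
similarity-to-distance adjustment is needed; √(1−s) is provided for
similarity inputs and is off by default.

The trophic-character network compares species rows of an integer-coded
character table by unweighted Manhattan distance (a complete graph, with an
optional minimum spanning tree for display). In simulate mode the pipeline
derives a coarse synthetic character table from computed cohort summaries,
since the field-use look-up table the analysis would normally consume is an
external resource.

## The synthetic-cohort generator

Raw per-specimen measurements are deposited externally, so the generator
emulates four species cohorts (default n = 20 females each, the study
scale) whose **cohort-level summaries are the contract**: overbite
probabilities 0.75/0.80/0.50/0.50 and mean overbite scales 0.49/0.44 μm for
the crusher and intermediate archetypes, an exact-tip-match rate of 2/80,
per-digit ATB/FT mean counts (e.g. the lardoglyphid moveable digit at
ATB 0.05, FT 1.35), a mastication-surface mean of 13.5 μm for the
lardoglyphid, a decreasing roughness cline R_q: A10B > C3 > T13, and fixed
digits toothier than moveable ones in every cohort.

Mechanisms (generator choices, not measured facts):

- Moveable-digit peak counts are zero-truncated Poisson with the rate
  solved so the truncated mean equals the preset target exactly. Peaks
  interleave with k+1 gullets (tip-adjacent gullet pinned at height 0); the
  fixed digit is the **occlusal complement** (peaks at gullet sites,
  heights flipped as max(y) − y), perturbed by (1 − complementarity)-scaled
  location and height noise. A k-peak moveable digit therefore yields a
  (k+1)-peak fixed digit — fixed-digit toothiness is structural. At
  complementarity = 1 the exact complement is emitted and the occlusion
  distance is zero (to floating round-off of the height arithmetic,
  ≈ 1e-7 μm).
- Peak locations are Beta-distributed (concentration 70) around a species
  **mass centroid** on the normalized axis, placed proportionally to the
  roughness targets (0.20/0.44/0.60/0.63). This is the dial that encodes
  the empirical covariation the method is meant to recover: rougher
  crusher species carry their asperity mass distally, so the first MDS
  axis of the cross-digit transport matrix tracks R_q (per digit panel,
  |r| ≈ 0.85–0.94 at the study scale).
- Specialist structures are stereotyped: the lardoglyphid's dominant
  moveable-digit blade sits at the species centroid (height ×4) and its two
  fixed-digit pockets are zero-height features at 0.50 and 0.80 of the
  asperity span — low within-species variance is what makes the archetype
  separate as a tight cluster, and pockets/perturbations are suppressed in
  the exact-complement limit.
- Grid profiles are monotone (PCHIP) interpolants through the asperity
  points sampled at 18 stations over the full axis, then rescaled so the
  mastication-surface R_q hits the species target up to lognormal specimen
  noise (σ = 0.10). Geometry is drawn around species means (CV 0.06) with
  x_ie = L2M − L1U by the lever construction.
- Tooth classes are Bernoulli at the rates implied by the per-digit count
  targets; tip offsets are overbite/tie/underbite at the preset
  probabilities with exponential magnitudes whose mean equals the preset
  scale.

What the generator does **not** emulate: measurement error of the
microscopy/drawing workflow, within-digit correlation of tooth wear,
asymmetric left/right chelae, or any out-group species. Passing tests
therefore show that the pipeline recovers structure *that is present at
realistic magnitudes*, not that real deposited data would show the same
magnitudes; the published ordination stresses and correlations are not
reproduction targets because the underlying specimens are not printed.

## Problem sizes and runtime

Defaults keep the whole suite light: study-scale analyses use four species
× 20 specimens (160 digits; the cross-digit matrix is ~12,700 exact W₂
evaluations per digit panel, < 1 s); oracle comparisons use 1,000 random
LP instances with ≤ 6 support points and 1,000 random psd triples for the
metric axioms; roughness-ordering checks average 10 seeds. The full test
suite runs in well under a minute on one CPU.

## Known limitations

- The exact-complement zero is exact for `perfect_complement_pair` but
  only round-off-exact for generated complementarity-1 specimens (the
  heights pass through two independent rescalings).
- Whether the published per-individual summaries pooled peaks and gullets
  or ran them separately is not fully determinate; pooled is the default
  and a subset option exposes the alternative.
- Ω comparisons assume profiles registered to their reference axes; no
  Procrustes superimposition is applied (by design — the registration is
  biomechanically informed).
- The Manhattan network in simulate mode runs on a synthetic character
  table derived from cohort summaries, a stand-in with the same coding
  structure as the external look-up table, not its content.
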