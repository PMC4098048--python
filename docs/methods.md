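# Methods

## Measurement model

The pipeline assumes each analysed run is a centroid-mode MS¹ LC–HRMS
acquisition of a 1:1 (v/v) mixture of a native and a uniformly
¹³C-labelled metabolome. Under a carbon-only isotope model — every
carbon position independently ¹³C with probability *p* — a metabolite
ion with n_C carbons and charge z contributes two binomial isotopologue
ladders spaced 1.00335/z apart in m/z:

* the native ladder, anchored at the monoisotopic signal M, with
  p = p_nat ≈ 0.0111 (natural ¹³C abundance), hence a first-order ratio
  I(M+1)/I(M) = n_C·p_nat/(1 − p_nat);
* the labelled ladder, anchored at the fully labelled signal
  M′ = M + n_C·1.00335/z, with p = p_enr (the enrichment degree,
  0.97–0.995 in practice), hence I(M′−1)/I(M′) = n_C·(1 − p_enr)/p_enr.

Heavier elements (S, Cl, …) are not modelled; the validation ratios are
first-order only, which is exactly what the detector checks. The full
binomial ladders are used only by the simulator.

Enrichment can be estimated from data by inverting the second ratio,
p = n_C/(n_C + ratio), and the largest carbon count for which M′ remains
identifiable among its own pattern (M′−1 not exceeding M′) is
floor(p/(1 − p)): 49 carbons at 98 % enrichment, 5 at 85 %. The boundary
is taken inclusively (ratio exactly 1 still counts); reported
direct-assignment limits in the literature for those enrichments are
somewhat larger (60 and 7), resting on an unstated criterion — the
formula-based bound is used here and the discrepancy simply noted.

## Detection cascade

**Scan-level pairs.** Each scan is searched seed-first over peaks with
intensity ≥ `min_intensity` (default 5000 counts), charges z ∈ {1,2,3}
and carbon counts 1–60. A pair is accepted iff M′ exists at the expected
spacing (±2.5 ppm) above the intensity threshold and both first-order
ratios are within the abundance tolerance. The ±20 % tolerance is
applied on the ratio scale symmetrically: observed/expected ∈
[0.8, 1/0.8]; this keeps acceptance invariant under inversion of the
ratio. M+1 and M′−1 must be *present* — low-abundance principal ions
without visible companions are deliberately lost (underestimation is
accepted; data processing without pattern verification would admit far
more false positives). If one physical (M, M′) peak pair validates at
several charges, the smallest z is kept.

**m/z clustering.** Scan-level pairs are partitioned by exact (n_C, z)
and clustered on m/z with average-linkage hierarchical clustering; the
tree is cut top-down, splitting any node whose members deviate more than
±10 ppm from the node mean. Clusters seen in fewer than `min_scans`
(default 3) distinct scans are discarded.

**Chromatographic confirmation.** XICs (±2.5 ppm, multiple peaks per
scan summed) are extracted at the cluster m/z and its labelled partner.
Peaks are picked by a Mexican-hat CWT ridge-line detector: ricker
convolution at scales {2,3,4,6,8,12,16}, local maxima linked across
scales (window = scale/2, up to two gaps), ridges of at least a quarter
of the scales kept, SNR = best coefficient over the 10th percentile of
the absolute smallest-scale row, threshold 3. (scipy's
`find_peaks_cwt` was found to miss clean truncated Gaussians under
these width lists, so the picker is implemented here; it is ~60 lines
and fully deterministic.) Boundaries are found by valley-walking from
each apex; areas are trapezoidal sums of the raw XIC between boundaries
(no model re-fit). M and M′ peaks are matched by nearest apex within
±15 scans (ties toward the larger labelled area) and kept when the
Pearson correlation of their shapes — over the union of the two
boundary windows, absent scans as zero — exceeds 0.5.

**De-isotoping.** A pair seeded on an isotopologue rather than on the
true monoisotopic/fully labelled signals shows a reduced carbon count
and/or an increased monoisotopic m/z. A pair P is removed when a
co-eluting pair Q (same z, apexes within ±15 scans) exists such that P's
monoisotopic m/z lies on Q's isotopologue grid k ≥ 0 spacings above Q
(±2.5 ppm) while claiming at least max(k, 1) fewer carbons. This covers
the classical M+1 shadow (k = 1, n_C − 1) and the M′−1 shadow (k = 0,
same M, shorter spacing), but also rarer shadows seeded on higher
isotopologues of a co-eluting ion. Removal is evaluated against the
original list in one pass, so the operation is idempotent and
order-independent.

**Grouping.** De-isotoped pairs whose M apexes lie within ±10 scans and
whose M peak shapes correlate at ≥ 0.85 are connected; feature groups
are the connected components (single linkage — chosen for order
independence), each representing one metabolite with its adducts,
in-source fragments and charge states. Pairs with a neutral-mass
estimate > 700 u but fewer than 10 carbons are flagged implausible
(kept, not removed).

## Bracketing and internal standardisation

Across samples, pairs are matched greedily — strongest total area first
— on n_C (exact), m/z (±10 ppm) and Rt (±0.15 min), in that order;
consensus coordinates are intensity-weighted means, and brackets never
mix carbon counts or charges. Missing cells are then re-integrated in a
targeted way: peaks are picked in the M and M′ XICs within the Rt
tolerance of the consensus, without abundance or shape checks, but the
±15-scan M/M′ co-elution window is still enforced when both peaks are
found. Cells with no signal stay empty; nothing is imputed.

The ratio matrix divides each native area by its labelled partner's
area per file. Any multiplicative distortion acting on both
isotopologues alike — matrix effects, source drift, injection volume —
cancels algebraically, which is the entire mechanism of the
standardisation. Evaluation statistics: per-feature CV (sample standard
deviation, n−1, over replicates; only features complete in all
replicates of the sample type), histogrammed in 5 % bins with values
above 120 % capped into the overflow bin; range scaling
(x − mean)/(max − min) per feature, constant rows dropped with a
warning; PCA as an SVD of the range-scaled matrix with samples as
observations (signs fixed by making each component's largest loading
positive), with 95 % covariance ellipses (χ², 2 df) per sample group in
the PC1/PC2 plane.

## The simulator: what it emulates and what it does not

`simulate.generate_run` produces centroid runs with: Gaussian
chromatographic profiles (σ 3–5 scans); 1–3 ESI species per metabolite
from {[M+H]⁺, [M+Na]⁺, [M+H−H₂O]⁺, [M+2H]²⁺}; both binomial ladders
truncated below 10⁻⁴ of their anchor; per-peak m/z jitter uniform within
±1 ppm (below the 2.5 ppm matching tolerance); isolated uniform noise
peaks (default 50/scan at 500–30 000 counts — they cannot satisfy the
3-scan recurrence plus shape-correlation criteria except by chance);
peaks closer than 2 ppm merged at the intensity-weighted mean m/z (a
crude stand-in for finite resolving power); one multiplicative
log-normal matrix factor per sample applied to all intensities; and a
per-metabolite, per-sample biological factor applied to the *native*
ladder only — the labelled reference is the same pooled material in
every sample, which is precisely why the ratio retains biological
variance while shedding technical variance.

Default world: 600 scans at 1 s (a shortened gradient, chosen for
single-CPU test budgets), m/z 100–1000, enrichment 0.995/0.0111. Random
panels draw n_C uniformly in 5–60 and neutral masses at 13–21 u per
carbon; apices are laid on an evenly spaced grid with ±1-scan jitter so
distinct metabolites stay chromatographically separated — truly
co-eluting distinct metabolites are indistinguishable from adducts of
one metabolite *by construction* of the grouping criterion, so a green
recovery test establishes correctness of the machinery, not the ability
to split perfectly co-eluting compounds. The simulator does not model
profile peak shapes, resolution-dependent peak widths,
Fourier-transform artefacts, detector saturation or retention-time
drift between samples (shifts are assumed negligible, as on a
well-equilibrated column; there is no warping/alignment step).

## Numerical choices and degenerate inputs

* Masses: Δ(¹³C−¹²C) = 1.00335 u, proton 1.00728 u (5-decimal
  precision, consistent throughout); carbon-count residual tolerance
  |(m/z′ − m/z)·z − n·1.00335| ≤ ppm·10⁻⁶·m/z′·z.
* Nearest-peak matching inside a ppm window takes the closest peak;
  XIC construction, by contrast, *sums* all peaks in the window
  (deterministic and robust to centroiding splits).
* Retention times are normalised to seconds on read; scan indices are
  0-based regardless of the file dialect.
* Empty spectra, all-zero XICs and empty pair lists flow through every
  stage as valid empty results; division by a zero labelled area yields
  an undefined ratio cell, never an exception.
* Charges beyond the configured range, unknown adducts and profile-mode
  input fail loudly with typed errors.
* All randomness in the simulator derives from one integer seed (plus a
  CRC of the sample id), so fixed seeds give byte-identical runs.

## Known limitations

* Carbon-only isotope arithmetic: no ¹⁵N/³⁴S patterns, no sum-formula
  generation or database annotation.
* The scan-level detector requires visible M+1 and M′−1 companions, so
  very low-abundance ions and n_C ≤ 2 ions (whose companions merge with
  the principal signals) are systematically missed.
* Bracketing assumes negligible retention-time drift between runs.
* Feature groups collect ion species but do not name them (no adduct
  identity assignment).
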