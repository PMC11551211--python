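# Methods

This note documents the models behind each stage, the defaults that
matter, and the choices made where more than one convention exists.

## Community statistics

**Rarefaction** subsamples each sample without replacement to a common
depth using exact multivariate hypergeometric draws; the default depth is
the minimum sample total, and shallower samples are dropped with a
warning.  Alpha diversity is computed after rarefaction (Chao1's
singleton/doubleton correction is only meaningful on integer counts);
beta diversity uses the unrarefied table by default, with rarefaction
available upstream for users who prefer it.

**Alpha diversity.** Shannon H = −Σ pᵢ ln pᵢ (natural log), Simpson is
the Gini-Simpson form 1 − Σ pᵢ² (so values lie in [0, 1), the scale on
which gut-microbiome Simpson indices are conventionally plotted), and
Chao1 = S_obs + F₁(F₁−1)/(2(F₂+1)).

**Beta diversity.** Bray-Curtis and Jaccard (on presence/absence) plus
unweighted and weighted UniFrac; weighted UniFrac uses the normalized
(Lozupone) form so all qualitative/normalized metrics share the [0, 1]
scale.  The pairwise computations run through scikit-bio; the test suite
checks all four metrics against independent brute-force per-pair
implementations to 1e-12.

**PERMANOVA.** Pseudo-F from the classical partition of squared
distances; p = (1 + #{F* ≥ F}) / (1 + n_perm) with free label
permutation (no strata) and ties resolved by the ≥ comparison.  When the
number of distinct relabelings is at most n_perm the null is enumerated
exhaustively, giving exact p-values (multiples of 1/6 for a 2-vs-2
design).  Type-I error is verified by simulation: rejection at α = 0.05
over 500 exchangeable replicates stays within 0.05 ± 0.02.

**PCoA** eigendecomposes the Gower-centered −½ J D² J matrix; negative
eigenvalues (non-Euclidean distances) are reported unmodified rather than
corrected, and simply contribute no axis.

**Composition.** Relative abundance divides by sample totals; features
unassigned at the requested rank collapse to their deepest assigned rank.
The F/B ratio is reported as NaN when Bacteroidetes is absent, never as
infinity.

## Differential statistics

**Two-group tests** are Welch (unequal-variance) t or two-sided
Mann-Whitney; `auto` picks Mann-Whitney when either group fails a
Shapiro-Wilk screen at α = 0.05 (or is too small to screen).  Identical
constant groups return p = 1 by convention.  Multiple testing uses
Benjamini-Hochberg step-up.

**TMM normalization** follows the edgeR algorithm: reference sample by
the upper-quartile rule, per-sample factor 2^(precision-weighted mean of
M-values) after trimming the extreme 30% of M and 5% of A, rescaled to
geometric mean 1.  A frozen-oracle test reproduces edgeR 4.0.16's factors
on a seeded 200-feature table to 1e-6.

**LEfSe** is implemented as a two-class variant: per-sample rescale to
10⁶, Mann-Whitney screen at α = 0.05, then 30 within-class bootstrap
resamples of an LDA effect size (mean of the scaled discriminant-axis
loading and the raw group-mean difference), reported as
log₁₀(max(1, effect)) with threshold 2.  The subclass (within-group
Wilcoxon) stage of the original tool is omitted because a plain two-group
design never exercises it.  The floor at 1 means a feature whose mean
difference is well below 100 counts-per-million cannot reach an LDA score
of 2 (log₁₀ 100 = 2).  Degenerate bootstrap columns receive a small
jitter so the within-class scatter stays invertible.

## LC-MS metabolomics

**Annotation** matches observed m/z to (metabolite, adduct) candidates at
a relative tolerance (default 10 ppm), using the study's positive-mode
(M+H, M+2H, M+Na, M+K, M+NH4) and negative-mode (M−H, M+Cl, M+FA−H,
M−H−H2O) adducts.  Mass shifts are built from standard monoisotopic
element masses (proton 1.007276 Da, Na−H 21.981944, K−H 37.955882,
NH4−H 17.026549, Cl 34.969402, formate 44.998201, H2O 18.010565; M+2H at
(M + 2·1.007276)/2) and ship as a versioned JSON data file.  Ambiguous
features keep all candidates ranked by |ppm error|; a convenience helper
picks the closest.

**Differential features** are Welch t-tests on log₁₀ intensities with BH
adjustment.  At the 5-vs-5 design with a 2-fold shift and 0.1 log₁₀
noise, per-feature power under BH is ≈ 0.7 (noncentral-t arithmetic,
confirmed by simulation); the tests assert this oracle-computed level.

**Pathway over-representation** replaces network-based enrichment with an
explicit hypergeometric test over confidently annotated features:
expected hits = pathway size × overall significant fraction, enrichment
factor = observed/expected, p from the upper hypergeometric tail
(verified against brute-force tail summation).

## Metagenome–metabolome GSEA

Metabolite sets are built feature-level: pathways significant at raw
p < 0.05 (adjusted available by flag) contribute their metabolites'
annotated LC-MS features, pooled per superclass with set-union
deduplication; sets below the minimum size (default 10) are dropped.
Duplicate features mapping to one metabolite are not collapsed (flag
available).

The ranking metric is the two-sample t statistic on log₁₀ intensities
with the GSEA minimum-SD floor s ≥ 0.2·|μ| to keep near-constant features
finite; ties break by feature id so the ranking is fully deterministic.
The enrichment score is the weighted (p = 1) running-sum extremum; exact
ties between the positive and negative extremum (which do occur on real
instances) resolve to the positive side, in both the implementation and
the independent test oracle.

Significance: phenotype permutation recomputes the metric under group
relabelings, enumerated exhaustively when the distinct splits fit within
n_perm.  When either group has fewer than 7 samples the engine falls back
to set permutation (random same-size sets) with a log notice — the
convention of the reference GSEA tool — because at e.g. 5-vs-5 the
relabeling null retains most of any real signal through high-overlap
splits and cannot separate even a perfectly ranked set.  NES divides ES
by the mean |null ES| of matching sign; nominal p is the sign-matched
null tail; FDR is the ratio of pooled-null to observed tail fractions,
made monotone non-increasing in |NES| within each sign class.

## qPCR quantification

The standard curve is a least-squares line Ct vs log₁₀(quantity);
efficiency Eff = 10^(−1/slope) (a perfect doubling series, slope −3.3219,
gives Eff = 2.000).  Total load inverts the curve at the universal-primer
Ct and divides by input fecal mass.  Taxon abundance applies
X = [Eff_uni^Ct_uni / Eff_spec^Ct_spec] × total exactly as written, with
positive Ct exponents; this coincides with the familiar Eff^(−ΔCt) form
when the two efficiencies are equal, and a warning is raised when they
differ by more than 0.1 because the positive-exponent form is then
sensitive to the absolute Ct scale.  Computation runs in log space to
avoid overflow at high Ct.  Ct values at the censoring cycle (default 40)
propagate as below-detection, never as zero.  Technical replicates are
averaged on the Ct scale.

## qbSEM bone analysis

Calibration is the two-point line sending the carbon standard to gray 25
and aluminum to 225, each standard's raw mean averaged over its before-
and after-scan acquisitions (beam-drift compensation); calibrated values
clip to [0, 255].  Pixel size is always an explicit input in µm/pixel
(the phantom default is 1.5 µm, a typical backscatter store resolution at
which 15 µm pores span ten pixels); it is never inferred from the image.

The mineralization histogram uses unit-width bins; the mode is the
maximal bin (lowest gray on ties, with a multimodality warning for
non-adjacent equal maxima) and FWHM interpolates the half-maximum
crossings linearly (a Gaussian phantom with σ = 10 recovers
2√(2 ln 2)·σ ≈ 23.55 within 5%).  Single-bin histograms are flagged
degenerate with FWHM = 1.

Porosity segments below-threshold pixels inside the bone mask into
8-connected components (boundary-touching pores included); equivalent
diameter d = 2√(area/π) classifies pores (> 15 µm vascular, else
lacunar); percentages are relative to the full mask area including pores
(matrix-only denominator by flag).  The default threshold is the midpoint
between the carbon target (25) and the histogram mode: pores (void or
resin) backscatter like the carbon standard, and histogram-splitting
rules such as Otsu's are unreliable here — on nearly pore-free sections
they bisect the matrix peak, and even with a clear pore class they land
at the lower edge of the empty gray gap and clip the pore tail.  An
explicit threshold below the matrix mode is always accepted.

## Synthetic data

The generators define the study conditions the tests run under:

- **16S tables**: Dirichlet-multinomial, 8 samples per age group at
  depth 10 000 with 50 taxa and total concentration 200 (overdispersion
  typical of 16S data); old-group effects multiply the concentration of
  chosen taxa (the bundled configuration plants a 10-fold
  Lactobacillus-like bloom).  Baselines are log-normal (σ = 1.5) for a
  realistic abundance skew.  Lineages are drawn over a mouse-gut-like
  phylum mix dominated by Firmicutes and Bacteroidetes.
- **Phylogenies**: random bifurcating rooted trees with exponential
  branch lengths (mean 0.1 substitutions).
- **LC-MS peaks**: 200 features, 5 samples per group; observed m/z are
  the assigned adduct m/z perturbed within ±5 ppm; log₁₀ intensities are
  Gaussian (σ = 0.1) around feature baselines near 10⁶ counts, with
  planted features shifted 2-fold (0.301 log₁₀) in the old group.
- **qPCR panels**: Ct values invert the quantification formula at a known
  composition, with Gaussian cycle noise per technical replicate
  (triplicate by default, the bench convention); absent taxa are censored
  at cycle 40.
- **Bone phantoms**: Gaussian matrix around a known calibrated mode with
  non-overlapping low-gray pore disks; truth porosity uses the exact
  rendered pixel masks, so recovery is checked against what was actually
  drawn.

What the generators deliberately do not emulate: raw reads and ASV
calling, chromatographic peak shapes, retention-time drift, isotope
patterns, batch effects, chimeras, or instrument noise models.  Passing
tests therefore demonstrate the correctness and calibration of the
statistics on data satisfying the stated models — not robustness to the
upstream artifacts real instruments add.

## Problem sizes and numerical conventions

Monte-Carlo studies use 500 replicates for calibration checks (PERMANOVA
type-I error at 199 permutations; GSEA null-p uniformity at 499
permutations) and 100 replicates for recovery checks (LEfSe at 8/group,
GSEA at 5/group with 1000 permutations) — sizes at which the binomial
standard error is well inside the asserted bands.  All randomness flows
from explicit integer seeds (generators and tests draw from separate
streams so permutation draws never correlate with data draws); no stage
reads the wall clock.  Distance-matrix symmetry, non-negative abundance,
and group-label completeness are validated at container construction.

## Known limitations

- LEfSe is the two-class variant only; multi-class and subclass designs
  are out of scope.
- The GSEA set-permutation null ignores inter-feature correlation; at
  small n this is the standard trade-off against the conservativeness of
  phenotype permutation.
- Annotation is mass-only (no retention-time or isotope-pattern
  scoring), so isomers are indistinguishable and ambiguity is reported
  rather than resolved.
- The qPCR formula is applied exactly as specified even when primer
  efficiencies differ; users are warned because the positive-exponent
  form then depends on the absolute Ct scale.
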