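# Methods

This note documents the models, conventions and parameter choices behind
`methgrad`, the places where the design was genuinely open, and what the
synthetic cohorts do and do not establish about real data.

## Study layout and data model

A discovery cohort is patients × 7 ordered tissue regions
(TC, TE, P5, P10, P15, P20, PN), each sample a Bismark-coverage-style table of
per-CpG methylated/unmethylated read counts. Methylation level is
β = methylated / (methylated + unmethylated) ∈ [0, 1]. Cells with coverage
below 15× are treated as missing ("less than 15×" is strict: 15× is kept), and
sites must be detected in enough samples — either a fixed count (68 of 84) or
a threshold derived from a two-component Gaussian mixture over the per-site
detection counts, fit by EM (quantile initialization, tolerance 1e-8 on the
mean log-likelihood, ≤ 500 iterations, per-iteration monotonicity asserted)
with the threshold at the smallest count whose posterior for the high-mean
component reaches 0.5. The EM split is meaningful only when detection counts
are bimodal, as they are for enzyme-enriched libraries; synthetic cohorts
produce unimodal counts, so the pipeline driver defaults to the fixed rule.
Sites are keyed by (chromosome, 1-based forward-strand position); symmetric
CpG strand merging is not performed. Coordinates are 0-based half-open
internally and in BED output; GTF is read 1-based inclusive; the conversions
live in two functions in `regions`.

## Pairwise tests and the significance matrix

Each region pair is tested with a paired Wilcoxon signed-rank test across
patients, one-tailed in both directions; the smaller tail is compared with
α = 0.05. Zero differences are dropped (no Pratt correction); the exact null
distribution is used for n ≤ 25 without ties, the tie-corrected normal
approximation with continuity correction otherwise. Because single sites can
show significant pairs in both directions, no direction is pre-registered:
both tails are always evaluated. A pair needs at least `min_pairs = 6`
complete patient pairs to be testable (configurable); untestable pairs count
as not significant. Note that min(p_low, p_high) < α admits each null pair
with probability ≈ 2α — this matters for the steep rule below.

The 42-dimensional status vector (row-major off-diagonal cells of the
symmetric matrix, two ones per significant pair) feeds cosine similarity
between neighboring sites. Neighborhood uses a closed ±30 bp window (a site
exactly 30 bp away counts; a site is never its own neighbor).

## Moran's I: the grid convention

Moran's I follows the standard formula with S² the population variance of the
observations. The convention for turning a 7×7 significance matrix into
spatial observations was fixed by reproducing the analytically known worked
example (I = 0.1581) exactly, after a search over the small convention space
(cell set, value encoding, metric, standardization):

* observations = the **42 off-diagonal cells** at their integer (row, column)
  coordinates; diagonal cells are excluded;
* each significant unordered pair contributes a **single 1 in its
  upper-triangle cell**; the mirror cell stays 0 (half-matrix encoding);
* w = inverse **Euclidean** distance between cell coordinates,
  **row-standardized** (each row sums to 1), zero diagonal.

Row standardization and the half-matrix encoding match how the conventional
R implementation (`ape::Moran.I` fed a one-triangle logical matrix) behaves,
and the convention was cross-checked against it. Under value permutation the
expectation of I is −1/(n−1) = −1/41 ≈ −0.0244; the shuffle null (uniform
permutation of the 42 cell values, default 10 shuffles per site, seedable)
reproduces this to < 0.01 at 10⁴ shuffles. Constant matrices (S² = 0) are an
error, as I is undefined.

Binning of I values supports the fixed-width scheme (open start bin ≤ −0.025,
nine 0.025-wide interior bins, open end bin > 0.2 — 11 bins total), quantile
bins, k-component 1-D Gaussian-mixture bins (EM, maximum-posterior
assignment) and Fisher–Jenks natural breaks via the exact O(k·n²) dynamic
program (verified against exhaustive partition search at small n).

## Steep / shallow classification

The direction convention is defined once, in `classify`: a class is `*_rise`
iff methylation increases from TC to PN (τ > 0; tumor side lower), `*_decline`
otherwise. All modules reference it.

**Steep** (evaluated first, from the matrix alone): every significant pair
lies in {TC, TE} × {P5…PN}; at least 3 significant pairs for TC and for TE
against that set; one common direction.

**Shallow** (on the remainder): Kendall τ-b between region ordinal (1–7) and
methylation pooled over all patients' cells (≥ 20 observed cells required;
two-sided tie-corrected asymptotic P), with P < 0.01; at least one significant
{TC, TE}–PN pair; at least one significant pair within {P5…PN}; and monotone
significance — every significant pair's direction agrees with sign(τ).
"Non-monotone significance" is not defined operationally anywhere
authoritative; contradiction-with-sign(τ) is this package's interpretation.
Pooling cells for τ (rather than averaging per-patient τ values) mirrors
rstatix-style usage; a per-patient mode would be a straightforward extension.

**A conservatism bound worth knowing.** For a truly steep site the 11 pairs
outside {TC, TE} × {P5…PN} are null comparisons, each significant with
probability ≈ 2α ≈ 0.09 (≈ 0.066 in practice, with count ties). The
exclusivity condition therefore passes with probability at most
(1 − 0.066)¹¹ ≈ 0.47 regardless of effect size: at α = 0.05 with 12 patients
the steep rule cannot have high sensitivity, and about half of the rejected
steep sites fall through to the shallow class when their chance within-normal
significance happens to be direction-consistent. The analysis scripts
quantify this on the default cohort (steep sensitivity 0.465 with zero false
steep calls; shallow sensitivity 0.98 with FDR 0.16 dominated by exactly this
leakage). This is a property of the published rule, reproduced faithfully,
not a tunable defect; raising sensitivity would require a stricter per-pair α
or a multiplicity-aware exclusivity condition, both out of scope.

## Changing regions and annotation

Regions are maximal runs of ≥ 3 changed sites with successive gaps ≤ 250 bp
(strict "not exceeding"), same direction; direction flips split runs. A
direction-agnostic mode merges on gap alone and flags regions containing both
directions `discarded_bidirectional` (excluded downstream). Member classes
set the category: pure steep / pure shallow / mixed (both kinds, one
direction). The region level is the per-sample median over member sites,
missing cells excluded (even counts give the central-pair midpoint). Gene
bodies are the full transcription span; promoters are the 2 kb upstream of
the strand-aware TSS (for − strand genes, the 2 kb beyond the gene's 3'-most
genomic coordinate), so promoter and body never overlap. Regions may hit
multiple genes and both compartments. Feature-overlap proportions use
point-in-interval membership after merging overlapping track intervals.

## Clustering

Samples are clustered on row-z-scored features (sample SD, ddof = 1; missing
cells imputed to 0 after scaling; constant rows dropped) with Ward.D2
agglomeration on Euclidean distances (scipy's `ward`, equal to the
Lance–Williams squared-distance update; verified against an independent
implementation). Clade stability is the ordinary bootstrap probability over
B row-resamples (default 1000) — deliberately *not* the multiscale/AU
correction: plain bootstrap probabilities are conservative but require no
multi-scale machinery, and only qualitative separation claims rest on them.
Dendrograms serialize to Newick with supports as internal node labels.

## Expression profiles

Relative expression per region is 2^−ΔCt with ΔCt = mean Ct(target) − mean
Ct(reference) over replicates (means of Ct, not of 2^−Ct), then standardized
to TC; replicate SD of ΔCt is propagated to the expression scale. The
steep/shallow/none trend call for expression profiles is an explicit
interpretation and is parameterized for replacement: shallow = |τ| ≥ 0.62
(the two-sided P < 0.05 point for n = 7) with a TE→P5 step below half the
profile range; steep = step ≥ half the range with flanks no wider than the
step; anything else (including constant profiles) = none.

## Prognostic model

d = 100·(β_adjacent − β_tumor)/β_tumor, clamped to ±100% with a warning (the
formula is genuinely unbounded above; a bounded alternative dividing by
max(β_tumor, β_adjacent) is provided behind `denominator="max"`). β_tumor = 0
excludes the record. |d| < threshold (strict; boundary values are
high-difference) marks a low-difference, shallow-like site. Thresholds sweep
3–15%; low-group membership is asserted monotone in the threshold. The
combined rule calls a patient high-risk when ≥ N of a named site set are
low-difference (missing sites count over available sites, flagged). Group
comparisons: Kaplan–Meier, Mantel–Cox log-rank (chi-squared P), and a hazard
ratio from a univariate Cox fit (Efron ties) with its 95% CI; a log-rank O/E
estimator is available behind a flag. Degenerate splits (an empty group) are
reported as undefined rather than guessed. Risk-class × TNM-stage tables use
the chi-squared test, or Fisher's exact test for 2×2 tables with an expected
count below 5.

## The synthetic cohorts

**Discovery generator** (defaults: 12 patients, 7 regions, 100 sites per
pattern, seed 7). Planted per-region mean profiles: steep places the entire
effect (default 0.30 methylation fraction) at the TE|P5 boundary with P5…PN
at the base level; shallow interpolates linearly across the seven positions
(the simplest monotone family — sufficient for Kendall recovery without
assuming a functional form); flat is constant; fluctuating draws region means
independently from base ± effect. Per-patient offsets (SD 0.05) model global
methylation level differences; per-cell jitter (SD 0.02) and beta-binomial
read counts (concentration 1/`coverage_dispersion`, default dispersion 0.01)
model measurement noise over Poisson coverage (mean 30×). `per_cell_sd = 0`
is the noise-free switch: counts become deterministic rounding of the cell
mean, so zero-noise invariants hold exactly up to count rounding. Cells drop
out uniformly at random (default 5%); real missingness is coverage- and
context-dependent, which is not modeled. Sites sit in clusters of 3 spaced
25 bp (CpG-island-like density, inside the ±30 bp neighbor window) with 5 kb
between clusters, so region merging and neighborhood analyses see local
structure. One global seed drives a named substream per site, so partial
regeneration is stable. Base levels are staggered per pattern (0.25–0.55) to
keep profiles inside [0, 1] with noise headroom; planted means outside [0, 1]
clamp with a warning.

**Prognosis generator** (defaults: 59 patients, 6 sites, planted HR 4,
seed 7). Each patient's per-site low-difference status is Bernoulli(0.25),
giving P(≥ 2 low sites) ≈ 0.47 — a near-balanced risk split, matching a
validation cohort whose survival curves show two sizable groups. Low sites
draw |d| within 90% of the 5% reference threshold; high sites draw |d| from
8–60%, so the 3–15% sweep crosses the planted separation and the hazard-ratio
attenuation at wide thresholds is observable. Survival is exponential
(baseline scale 48 months) with the hazard multiplied by the planted HR for
high-risk patients; censoring is exponential, independent given the risk
class, calibrated so every patient is censored with probability
`censor_rate = 0.7` — about 18 expected events in 59 patients. At ~18 events
the sampling SD of log HR is ≈ 0.5, so even a perfectly specified analysis
recovers HR = 4 within a factor of 2 only ≈ 79% of the time (measured over
400 replicates); single-cohort hazard ratios at this sample size carry wide
intervals, which the reported CIs make explicit.

**What passing tests show — and don't.** The generators demonstrate that the
implementation recovers what it plants under idealized noise: independent
cells, uniform missingness, exchangeable patients, exponential survival. They
do not establish performance under batch effects, spatially varying coverage,
strand asymmetries, informative censoring, or misspecified region labels —
all present in real cohorts.

## Numerical and tie-breaking choices

* Wilcoxon: zeros dropped before testing; an all-zero difference vector is
  "not significant" rather than an error.
* Kendall τ on fully tied values returns missing → unordered.
* Fisher–Jenks assigns a value equal to a break to the lower bin.
* Ward ties break by observation order (scipy convention).
* EM enforces an SD floor of 1e-3 to avoid component collapse; a
  single-support-point input raises a degenerate-mixture error, and the
  detection filter then falls back to keeping all sites with a warning.
* The bin scheme's boundary values: −0.025 belongs to the start bin, 0.2 to
  the last interior bin.
* Clamped relative differences and out-of-range thresholds warn rather than
  fail.

## Known limitations

* Strand-merging of symmetric CpGs is not performed; a dinucleotide-aware
  mode would halve the site count and raise per-site coverage.
* No multiple-testing correction across sites or pairs — by design, matching
  the raw per-pair α = 0.05 analysis; the steep-rule sensitivity ceiling
  above is one consequence.
* Bootstrap clade supports are plain proportions, not approximately unbiased
  values; they understate support for clades found against many near-ties.
* The expression trend rule is an interpretation; swap it via the documented
  parameters before comparing against externally defined categories.
* `run_discovery` orchestrates synthetic cohorts end-to-end; wiring arbitrary
  external coverage files through the same driver requires assembling the
  sample tables with `meth_io` directly (the library path is identical).
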