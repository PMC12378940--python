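# Methods

This note documents the models, default parameters, numerical choices and
known limitations of each stage. Everything stated here is computed by the
package's tests or examples; nothing is asserted from outside data.

## Cohort construction

Participants are excluded, in order, for an incomplete questionnaire,
antidepressant use, or a missing blood sample; someone failing several
criteria is counted once under the first (the counting convention is
otherwise arbitrary, so we fix it to the listed order). Depression status
comes from the 30-item Geriatric Depression Scale: one point for "yes" on the
20 symptom-keyed items (2–4, 6, 8, 10–14, 16–18, 20, 22–26, 28) and one point
for "no" on the 10 reverse-keyed items (1, 5, 7, 9, 15, 19, 21, 27, 29, 30);
a total strictly greater than 10 is the clinical cutoff. A useful identity —
score(x) + score(¬x) = 30 — is enforced as a property test.

Matching is greedy 1:1: each case takes the unused control of the same sex
with the smallest absolute age difference, subject to a ±3-year tolerance;
ties are broken by a seeded shuffle, and an unmatchable case is an error
naming the case. Greedy matching is not globally optimal, but with the
roster densities used here it always succeeds, and the output is reproducible
for a fixed seed.

The sample-size routine uses the normal approximation
n = ⌈2(z₁₋α/tails + z_power)²/d²⌉ with a floor of 2. For d = 0.5, α = 0.05,
power = 0.80 it gives 50 per group one-tailed and 63 two-tailed. Exact
noncentral-t root-finding (as in dedicated power software) gives slightly
different values; we document both tails rather than forcing agreement with
any particular software's output.

Baseline tables use the pooled-variance Student t-test by default (the
convention of mainstream statistical packages' independent-samples output);
Welch is a flag. Categorical variables use the Pearson chi-square **without**
Yates continuity correction — required for p-values computed from counts to
match p-values computed from rounded percentages at n = 49 per group.
Percentage→count reconstruction rounds to the nearest integer and is lossy.

## Differential metabolites

Intensities are modelled as log-normal (Gaussian on the log scale), the usual
assumption for MS peak areas with multiplicative noise, so all model fitting
happens on log intensities. Internal-standard normalization divides each
sample by the mean of its retained IS features; an IS whose cross-sample RSD
exceeds 0.3 is excluded from the normalizer when an alternative exists, and
if every IS fails the cutoff they are all used with a warning (`strict=True`
turns that into an error). An optional QC-RSD filter drops unstable features.

OPLS-DA is fitted by NIPALS with one predictive component: the predictive
weight is w ∝ X'y on autoscaled (unit-variance) features; each orthogonal
component removes from X the part of its loading orthogonal to w. Unit
variance scaling (not Pareto) is used because the VIP > 1 convention is
interpretable under it. One orthogonal component is the default;
it is configurable, and `n_ortho=0` reduces the fit to one-component PLS-DA
(verified against scikit-learn's PLS in a test). R²Y is the fraction of class
variance explained by the predictive score. Q² uses stratified k-fold
(default 7) cross-validated PRESS with a seeded fold assignment; folds where
a refit is degenerate are skipped. The permutation test refits the model on
n (default 200) label permutations and reports
p = (1 + #{perm ≥ observed})/(n + 1), which cannot reach zero.

With one predictive component VIP_j = √p·|w_j| for the unit-norm weight, so
mean(VIP²) = 1 holds exactly; this identity is asserted on every fit. The
screen passes a feature iff VIP > threshold and the two-sided pooled t-test
on log2 intensities has p < 0.05. Both the lenient (VIP > 1.0) and strict
(VIP > 1.5) conventions are in community use; the threshold is an explicit
parameter with 1.0 as the default. Fold change is the ratio of group means
of normalized intensities; zero intensities are imputed as half the feature's
minimum positive value before taking logs.

## Co-expression network

The network stage follows the weighted co-expression recipe: keep the top 50%
of features by variance, then pick the smallest soft-threshold exponent β
whose scale-free fit reaches R² ≥ 0.6. The fit statistic is the signed R² of
the regression of log10 bin frequency on log10 mean connectivity over 10
equal-width connectivity bins (positive only when the slope is negative); if
no candidate reaches the target the best one is used with a warning.
Adjacency is unsigned, a_ij = |cor|^β (the historical default; a signed
variant is available), and the topological overlap matrix is
TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j) + 1 − a_ij), checked against a
brute-force double loop in the tests.

Module detection deliberately simplifies the dynamic tree cut: average
linkage on 1 − TOM, a static cut at 0.99 × the dendrogram height, clusters
below the minimum size (default 10) set to grey, then iterative merging of
modules whose eigengenes satisfy 1 − cor < 0.25. On planted block data
(five blocks, within-block r ≈ 0.8, plus noise) this recovers the partition
with adjusted Rand ≥ 0.9, which is the regime the downstream analysis
needs; it is not a general replacement for the hybrid dynamic cut on real
dendrograms with nested structure. Module eigengenes are first principal
component scores of the standardized module block, sign-aligned with the
module mean profile and scaled to unit variance.

Hubs require MM > 0.7 against the feature's own module eigengene, |GS| > 0.2
against the trait (case = 1, control = 0), both correlation p-values below
0.05 (t = r√((n−2)/(1−r²))), and a significant module–trait correlation.
Pearson correlation is used throughout (not biweight midcorrelation).

## Mendelian randomization

Instruments need exposure p < 1e-5 and F = (β/se)² > 10 (the usual
summary-statistic approximation of instrument strength). Clumping is greedy
by ascending p (ties by SNP ID): a SNP is kept iff r² < 0.001 with every kept
SNP within 10,000 kb; a missing LD entry counts as r² = 0 with a warning and
absent positions put every pair in-window. Harmonization aligns outcome
effects to the exposure effect allele, flipping swapped or strand-flipped
alleles; palindromic SNPs with either EAF in (0.42, 0.58) are dropped,
otherwise aligned by frequency. SNPs associated with the outcome at
genome-wide significance (p < 5e-8 by default) are removed so instruments act
through the exposure; note that under a strong simulated causal effect with a
very large outcome GWAS this filter correctly removes *valid* instruments
too — the bundled pipeline therefore simulates a 5,000-sample outcome GWAS,
at which scale the planted effect is detectable in aggregate without making
every individual SNP outcome-significant. Steiger filtering keeps SNPs with
r²_exposure > r²_outcome, using r² ≈ F/(F + n − 2) per side; ties fail.

IVW is weighted least squares of β_out on β_exp through the origin with
weights 1/se_out² (the identity with the ratio form is a test); the default
standard error is multiplicative random-effects, the fixed-effect se inflated
by √max(1, Q/(k−1)). MR-Egger regresses with an intercept after orienting all
exposure effects positive; its standard errors use the residual scale floored
at 1 and t-distribution p-values on k − 2 df; the intercept and its p-value
are the directional-pleiotropy test. The weighted median interpolates the
ratio estimates at cumulative weight 0.5 (weights β_x²/se_y²) with a seeded
parametric bootstrap se. Simple mode is the argmax of a Gaussian-kernel
density of the ratios (Silverman bandwidth × 1). The PRESSO-style global test
compares the observed weighted residual sum of squares around the IVW fit
with 1,000 seeded simulations under a no-outlier model; the distortion and
per-SNP outlier components of the original procedure are intentionally not
re-implemented, hence the conservative name `presso_global`. Raw p-values
drive the significance screen (with a BH-FDR column available), matching the
practice of screening ~1,400 exposures at p < 0.05 unadjusted.

## Pathways and tiers

Enrichment is the one-sided hypergeometric upper tail P(X ≥ k) with the
universe defaulting to all compounds in the loaded database
(override available), BH-corrected across pathways. Pathway impact is the
hit compounds' share of total unnormalized betweenness centrality in the
pathway graph (shortest paths exclusive of endpoints, undirected); a graph
with zero total centrality has impact 0. Betweenness — not degree or
closeness — matches the "relative betweenness centrality" convention of
mainstream metabolomics pathway tools.

The evidence pool is the unweighted union of the KEGG-matched differential,
hub and MR-causal compound lists, de-duplicated by compound ID with
provenance flags kept; unmatched names are reported, never silently dropped.
Per-pathway trend flags are computed within each stream: "up"/"down" when
every hit with a known direction agrees, "mixed" when both occur, "absent"
when none is known.

Tier rules fire in order: (R0) any mixed stream → III*, regardless of impact;
(R1) impact ≥ 0.25 ∧ ≥2 significant methods ∧ pool-enriched ∧ both streams
non-absent and non-mixed → I; (R2) 0.1 ≤ impact < 0.25 ∧ (LC/GC-MS or MR
significant) → II; (R3) min p < 0.05 → III; else unclassified. Two boundary
choices matter: the I/II overlap at impact 0.25 is resolved half-open
(II = [0.1, 0.25)) so the tiers partition the impact axis, and consistency is
judged *within* each stream — an LC/GC-MS "up" with an MR "down" is
compatible with Class I, because expression differences and causal risk
directions measure different things. An absent MR stream blocks Class I but
not Class II. These choices are exactly the ones under which the bundled
12-row published worked example reproduces its printed tier column 12/12
(the package's acceptance check). In that fixture, p-values printed only as
"<0.01" are stored as 0.005, and the two III* rows encode the published
narrative's internally contradictory hit directions as "mixed" (the printed
table collapses both "no trend" and "contradictory" into a single "/" glyph).
One published row prints a hit count of 4 alongside five compound IDs; the
fixture stores both as printed and the classifier uses neither.

## Synthetic data: what it emulates and what it does not

The metabolome generator produces log-normal intensities: standard Gaussian
log values with a one-factor correlation structure inside each planted block
(within-block correlation λ² = block_cor) and an effect_size·SD mean shift of
the planted differential features in cases. It emulates the statistical
structure the pipeline consumes — group separation, correlated modules,
multiplicative noise — but not retention-time drift, batch effects,
missing-not-at-random dropout, or realistic inter-feature correlation beyond
the planted blocks. Passing tests therefore demonstrate correctness of the
statistics, not robustness to real-data artefacts.

The GWAS generator draws per-SNP standard errors as 1/√(2·EAF(1−EAF)·n),
exposure effects sized so F spans a configurable range (default 20–150;
(2, 30) approximates weak instruments), and outcome effects as
causal_beta·β_x plus, for a fraction of SNPs, a direct effect
N(pleiotropy_mean = 0.1, sd = 0.01) oriented to the exposure-increasing
allele (the directional-pleiotropy convention MR-Egger targets; with ~150
instruments the intercept test detects the default scenario in the majority
of seeds, a power chosen when the scenario was fixed). The block-diagonal
AR(1) LD matrix feeds the clumping step only; effect draws are independent
across SNPs, so LD influences instrument pruning but not the simulated
effect correlations — a documented simplification. The roster generator
plants the exclusion counts and guarantees each case a matchable control.

All generators draw from one master seed through `numpy.random.SeedSequence`
spawning, so a fixed seed gives byte-identical outputs.

## Pipeline defaults and problem sizes

The bundled end-to-end pipeline simulates 49 samples per group × 300
features (20 differential at d = 1.5; three correlated blocks of 15 at
r = 0.8), 6 MR exposures × 40 SNPs with a planted causal effect of 0.3 on
alternating exposures, and a 12-pathway toy database; it runs in a few
seconds and is sized for demonstration and testing rather than realism.
Every stage writes TSVs plus a manifest of SHA-256 output hashes; identical
config and seed reproduce identical hashes. Stage thresholds (VIP, p, MM,
GS, instrument p, F, clump r², window, impact bounds, module size, merge
height, scale-free target) each appear once in `PipelineConfig` and the
default YAML.

## Known limitations

- The dynamic tree cut is approximated by a static cut plus eigengene
  merging (above); deeply nested module structures will not be resolved the
  way the reference hybrid algorithm resolves them.
- MR-PRESSO is represented only by the seeded global RSS test; no outlier
  removal or distortion test.
- LD-score regression and genotype-level QC are out of scope: the library
  consumes summary statistics and a user-supplied or synthetic LD matrix.
- Real pathway-database topology is not bundled; impact values on the toy
  database are not comparable with values computed on curated KEGG maps,
  which is why the published worked example enters as a fixture of printed
  numbers rather than being recomputed from graph content.
- Greedy matching and greedy clumping are order-dependent heuristics,
  deterministic under a fixed seed but not globally optimal.
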