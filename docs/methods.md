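# Methods

## Freezing-tolerance model

Electrolyte leakage after a controlled freeze is treated as a sigmoid
function of test temperature. The estimator of EL50 is deliberately the
classical one for this assay: an OLS **third-order polynomial** of mean
leakage on temperature, with EL50 the root of (cubic − 50). A cubic is not
monotone, so a root rule is needed: among real roots we keep those on the
limb where the fitted slope in temperature is negative (leakage rising as
it gets colder — the only physically meaningful branch), prefer roots
inside the tested temperature span, and among several take the one
closest to the temperature of steepest fitted decline, which is where the
sigmoid midpoint lies. Roots outside the span are reported with
`in_range=False` rather than discarded, since extrapolated EL50s are
common when a curve saturates early. Numerically-zero leading
coefficients are trimmed before root finding so that exactly linear or
quadratic data (where the cubic degenerates) do not produce spurious
far-field roots. A fit that never crosses 50%, or is constant at 50%, is
an error, not a number.

The fit uses per-temperature **group means** (the curve as plotted, mean ±
SE of replicates); replicate-level data feed the ANOVA instead. On
noise-free logistic curves with 13 temperatures bracketing the midpoint
the cubic's 50% crossing coincides with the logistic midpoint to
numerical precision (the logistic is odd-symmetric about it), and under
3%-leakage noise the mean recovery error stays well under 0.3 °C; the
acceptance script recomputes both.

The decomposition `cbf_dependent = delta_wt − delta_mut`,
`cbf_independent = delta_mut` is exact arithmetic on two EL50 shifts; the
conservation identity holds to machine precision by construction. The
CBF-dependent *fraction* is reported unrounded plus a nearest-5% display
rounding, the convention used when such fractions are quoted ("about
40%"). When `delta_wt = 0` the fraction is undefined and flagged, never
NaN-by-accident.

**Curve comparison** is a two-way ANOVA of replicate leakage on genotype ×
temperature with temperature categorical (no functional form imposed on
the response), Type-II sums of squares for robustness to mild imbalance,
and the genotype main effect — a single-degree-of-freedom contrast for
the genotype difference averaged over temperatures — as the reported
p-value, with the interaction alongside. One replicate per cell leaves no
error stratum and is rejected. Type-I calibration (identical generating
curves, 1000 simulations) lands within [0.03, 0.07] at α = 0.05.

## Classification rules

Cold induction: log2FC ≥ 1 and q ≤ 0.01, both inclusive ("at least
two-fold"; "FDR = 0.01" read as a cutoff). q-values are consumed, never
computed — the DE engine is upstream of this package. A missing q-value
is an error unless the caller explicitly opts into fold-change-only
classification.

Two percent-reduction conventions exist in the literature's phrasing and
both are implemented and labelled via `criteria_version`:
`induction_ratio` (reduction of the *induction*,
1 − (mut_cold/mut_warm)/(wt_cold/wt_warm)) and `cold_expression_ratio`
(1 − mut_cold/wt_cold). The default for reporting reductions is
`induction_ratio`; the membership criterion uses the WT-vs-mutant fold
change at cold (the `cold_expression_ratio` quantity), since membership
is defined by a between-genotype fold change. When a table carries no
separate mutant-warm measurement the mutant's warm abundance is taken
equal to the wild type's — in the synthetic tables this is exact, because
the CBF pathway is modelled as inactive at warm temperature, making both
conventions coincide.

Histogram bins are (−∞, 0), [0, 10), …, [80, 90), [90, 100]; the top bin
is closed because a 100% reduction is attainable (mutant expression zero)
and must not fall off the histogram. "Reduced more than 50%" is strict
(> 50). Bin counts always sum to the number of genes binned.

## Motif enrichment

The motif is an IUPAC pattern (default rCCGAC) compiled to a regex with a
lookahead so **overlapping matches all count** (the 6-mer can overlap
itself, e.g. GCCGACCGAC contains two). Scanning is case-insensitive;
ambiguity codes in the scanned sequence never match — conservative
counting. Default strand handling is `sense_only` (the element is
conventionally written on the promoter strand); `both_strands` adds the
reverse-complement pattern on the same string, with palindromic patterns
de-duplicated (rCCGAC is not palindromic, so nothing arises).

The null is 1000 random gene sets of the observed size drawn **without
replacement** from all promoter-bearing genes (gene sets contain no
duplicates); the resampled statistic is the per-gene mean count. The
empirical P uses the add-one estimator (1 + #{null ≥ obs})/(n + 1), which
cannot return 0 from finite resampling; its floor is 1/1001 at the
default sample count. Because published P values for strong enrichments
lie far below any resampling floor, the upper normal-tail probability of
Z is reported alongside as `z_tail_p`. Per-gene counts are computed once
and reusable across tests (`count_per_gene`), which keeps 500-replicate
calibration runs cheap. Under the null the Z statistic is calibrated to
|mean| < 0.15 and |SD − 1| < 0.15 across 500 runs at set size 44.

## Set comparison and GO enrichment

The three-way partition is plain set algebra over case-normalized ids;
conservation (regions disjoint, each input reconstructed exactly) is
property-tested over random triples. GO enrichment is the hypergeometric
upper tail P(X ≥ k) for drawing n = |target| genes from a background of N
genes (default 33 278) of which K carry the term. Target genes missing
from the annotation universe still count toward n — the background is the
full nuclear gene set, not the annotated subset. Raw p is the primary
report (sorted ascending); a Benjamini–Hochberg column is emitted for
convenience but not used to rank. The tail is computed via scipy's
hypergeometric survival function (log-space internally, accurate at the
1e-44 scale these tests reach); an independent exact oracle — outright
enumeration of all C(N, n) draws when that count is ≤ 20 000, otherwise
an exact rational pmf sum — pins it to 1e-12 on small instances in the
tests.

## Climate regression

OLS of gene count on minimum monthly low temperature. With the usual
three genotypes any p-value would be decorative, so none is attached: the
fit carries a `small_n_caveat` flag and reports slope, intercept and R²
only. Alternative regulon counts from a relaxed FDR (e.g. 0.05) are
supported simply by passing a different panel table.

## Synthetic data

One seed, one `SeedSequence`, and one spawned child stream per artifact
type (leakage, expression, promoters), so regenerating one artifact never
perturbs another and identical configs give byte-identical tables.

*Leakage*: a 2-parameter logistic L(T) = 100/(1 + exp((T − EL50)/s)) —
the simplest curve with a unique 50% crossing — plus independent Gaussian
noise (SD 3% leakage, the scale of replicate scatter in this assay),
truncated to [0, 100]. Defaults: the eight genotype × acclimation groups
span EL50 −12.4 to −3.8 °C, slope 1.5 °C, 3 replicates, ten test
temperatures from −18 to 0 °C. Groups whose EL50 falls outside the tested
span are flagged, not rejected.

*Expression*: four planted gene classes — cbf_dependent (5%), coregulated
(5%), cbf_independent_cor (5%), non_cor (85%) over 2000 genes — with
class-wise uniform induction log2FC ranges (≥ 1 for the induced classes,
≈ 0 for non_cor) and mutant reduction fractions (0.75–0.95 high,
0.30–0.45 intermediate, ≈ 0 for CBF-independent genes). q-values are
generated directly (well below 0.01 for true effects, diffuse otherwise)
rather than via a simulated testing procedure: the DE engine is out of
scope and only the filtering logic is under test. At the 2-week time
point 65% of induced genes remain induced. What this generator does *not*
emulate: count noise, library-size effects, correlated genes, borderline
q-values; passing tests therefore demonstrate correctness of the
classification logic at the planted separations, not robustness to
marginal real-data effects.

*Promoters*: uniform 25%-per-base composition (making the spontaneous
rCCGAC rate analytically computable: 2 × 4⁻⁶ per eligible position,
≈ 0.49 per kb) with Poisson-planted motif counts — background rate 0.28
per gene, matching the expected per-gene occurrence in genome-wide
promoter scans; target genes use rate 2 for clearly separated power
checks — inserted at uniform non-overlapping positions. A matching
single-contig genome and BED-convention gene models are emitted with
strands alternating + / −, so promoter extraction is round-trip testable
on both strands.

## Numerical and interface choices

Internal coordinates are 0-based half-open; BED is native, GFF3 converted
on ingest. "Translation start" anchors the promoter window at the first
base of the start codon. Promoters truncated at contig edges are kept and
flagged — dropping them would silently bias motif counts. Readers reject
malformed required fields (naming the column or line) rather than
coercing. Problem sizes in the test and acceptance runs — 200 noisy EL50
replicates, 1000 ANOVA null simulations, 500 motif-calibration runs at
1000 resamples each, 200 partition instances — were chosen as the
smallest sizes at which the calibration bounds are statistically
meaningful.

## Known limitations

- The cubic EL50 estimator is faithful to assay convention but not robust
  to strongly asymmetric curves; a logistic/4PL fit is a natural
  cross-check utility but is intentionally not the primary estimator.
- The orthogonal-contrast comparison is implemented pairwise; multi-genotype
  contrast matrices are left to the caller via statsmodels directly.
- GO annotation maps are taken as given — no ancestry propagation up the
  ontology graph.
- The genome-scale published quantities (full regulon lists, genome-wide
  Z-scores, GO tables) require the external genome and expression
  archives and are out of desk-scale reach; the package validates those
  code paths on synthetic data with planted truth instead.
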