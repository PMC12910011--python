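# Methods

## Collapsing burden test

Each gene × model pair is reduced to a 2×2 carrier table (case/control
× carrier/non-carrier). Carrier status is binary — a sample with three
qualifying variants in a gene counts once — because collapsing tests
case-control imbalance of *carriers*, not alleles. The two-sided Fisher
exact P value is the sum of hypergeometric probabilities of all tables
with the observed margins at most as probable as the observed table
(ties included up to a tiny relative tolerance for floating-point
round-off); computation delegates to `scipy.stats.fisher_exact`, which
evaluates the tails in a numerically stable way for margins in the
10,000s. The test suite independently validates the engine against an
exact-integer enumeration oracle on every 2×2 table with total ≤ 40.

Degenerate inputs: an all-zero table, or any table with a zero carrier
margin, returns P = 1; P values are clamped into (0, 1] so −log₁₀
transforms stay finite.

### Minimum-P aggregation

The reported per-gene statistic is the minimum P over the aggregation
set, by default `dominant_stringent`, `recessive_stringent`,
`recessive_cnv` (restricted to models actually scanned), with ties
broken by that fixed order. The minimum is **not** corrected for the
number of models — a deliberate caveat inherited from the discovery
procedure being reproduced; with three heavily correlated models the
inflation is modest, and the downstream use is candidate
prioritisation, not confirmatory inference.

### Multiple testing

The denominator *n* counts genes with ≥ 1 small variant among **cases**
qualifying under a stringent model of the run ("genes affected by
high-impact variation in the cohort"). Counting cases only, and
stringent impact only, is one of several defensible readings; it is the
default and is exposed in code. Both the Bonferroni threshold α/n (used
for the significance flag) and the Šidák threshold
1 − (1 − α)^(1/n) (computed via `expm1`/`log1p` to avoid cancellation)
are reported. A fixed suggestive threshold (default 0.0025) marks
sub-genome-wide candidates. If no gene qualifies for the denominator a
dedicated `NoTestableGenesError` is raised rather than silently
dividing by an arbitrary n.

## Qualification rules

Boundary conventions, chosen once and tested exhaustively: MAF
comparisons are strict (< 0.1 % dominant, < 1 % recessive); CADD (≥ 20)
and all CNV quality thresholds (log-likelihood ≥ 15, correlation ≥ 0.9
ES / ≥ 0.55 GS, in-house frequency ≤ 1 %) are inclusive. The stringent
consequence vocabulary is the six SO terms `stop_gained`,
`frameshift_variant`, `splice_donor_variant`, `splice_acceptor_variant`,
`stop_lost`, `start_lost`; including start/stop-lost among
protein-truncating variants is this package's call and is configurable
per model. Missing MAF passes (absence from population databases is how
ultra-rare variants present); missing CADD fails the deleterious
missense rule. Compound-heterozygote phasing is out of scope: the
recessive models count homozygous or hemizygous calls only.

The CNV evidence gate (CNV carriers admitted only for genes with
qualifying small variants in ≥ 2 cases, default) reflects that exome
CNV calls have a much higher artefact rate than small-variant calls;
requiring independent small-variant corroboration prevents a cluster of
correlated false-positive deletions from creating a spurious gene hit.

## Coordinates and X-linked handling

Variants are 1-based (VCF convention); BED intervals and CNV calls are
0-based half-open; the region-mask test is `pos − 1 ∈ [start, end)`.
Hemizygous genotypes are only legal on X/Y contigs; on ingestion, a
male homozygous call on chrX outside the pseudoautosomal regions
(GRCh38 defaults: X:10,001–2,781,479 and X:155,701,383–156,030,895,
configurable) is reclassified as hemizygous. Hemizygous counts as
homozygous under recessive models.

## Ontology statistics

**Relative height.** Defined as depth/(depth + height) with
longest-path depth (root → term) and height (term → deepest descendant
leaf), and 0 when both are 0 (the root). This is the parameter-free
reading of "relative position of a term in its branch" that maps the
root to 0 and every leaf to 1, is monotone non-decreasing along any
root→leaf chain, and needs no term frequencies. Shortest-path variants
were considered and rejected: on a DAG they can rank a term *above* its
own child. Both statistics are computed by a single topological
relaxation; tests verify them against exhaustive path enumeration on
fixtures ≤ 50 terms.

**Similarity.** The upstream analysis delegated to an off-the-shelf
ontology-similarity package without fixing the measure; this package
fixes a documented, reproducible default: Lin term similarity
2·IC(MICA)/(IC(t₁) + IC(t₂)) with annotation-frequency information
content IC(t) = −ln(n_t/N) (n_t = corpus sets annotated with t or any
descendant), MICA ties broken lexicographically, never-observed terms
assigned the IC of the rarest observed term, and symmetric best-match
average set aggregation. Identical informative sets score 1; sets
sharing only the root score 0. Only the distance matrix
(1 − similarity) is emitted; embedding (UMAP etc.) is explicitly out of
scope.

## Feature matrix

17 columns: HPO mean, HPO count, seven one-hot movement-disorder
subgroup indicators (ataxia, spasticity, dystonia and their
combinations), gender (configurable coding, default male = 1), and
seven one-hot age bins. The source bin labels (0–5, 5–20, …, 60–100)
overlap at the boundaries; this package fixes them as left-closed
right-open [lo, hi) with the final bin closed at 100, so age 20 falls
in 20–30, not 5–20. Missing age zeroes the age block (logged); missing
HPO terms give HPO mean 0 (logged). Yield percentages round
half-away-from-zero at a configurable number of decimals (default 1).
The downstream LASSO fit, cross-validation and ROC are off-the-shelf
library territory and not part of this package's contract — only the
matrix that feeds them is.

## Synthetic cohorts

The generator emulates the statistical structure the scan assumes, at
the reference study's scale by default (2287 cases, 10,845 controls,
50 % male, 85 % exome):

* **Null genes** (default 50): variant count per gene ~ Poisson(3),
  per-variant MAF log-uniform on [10⁻⁵, 0.05], 30 % PTVs / 70 %
  missense with CADD ~ N(20, 8²) clipped to [0, 60]. Genotypes are
  drawn identically for cases and controls: Hardy–Weinberg on autosomes
  (hom p², het 2p(1−p)); on chrX, males are hemizygous with probability
  p and females follow Hardy–Weinberg. A small fraction of genes
  (default 5 %) sit on chrX.
* **Planted genes**: `fraction` mode draws carriers Binomial per group;
  `exact` mode assigns a fixed number of carriers (needed to reproduce
  worked examples like 7 vs 0). X-linked planted carriers are drawn
  among males and are hemizygous; planted variants are PTVs with
  *missing* MAF, exercising the missing-MAF-passes rule.
* **CNV noise**: Poisson-rate random calls (default 0.02/sample) with
  mixed copy number 0/1, exponential log-likelihoods (mean 12), uniform
  reference correlations on [0.3, 1.0], 20 % polymorphism overlap and
  half-missing in-house frequencies — so only a minority pass the
  quality rules, as with real exome CNV calling.
* **HPO annotations**: per patient, terms are sampled by random walks
  from the ontology root — one mandatory downward step, then continue
  with probability equal to the specificity bias (default 0.7). Bias 0
  yields only depth-1 terms; higher bias yields stochastically higher
  mean specificity.

One mandatory seed drives everything; per-table substreams are spawned
from it (`numpy.random.SeedSequence`), so identical configs give
byte-identical output files and enabling CNV noise does not perturb the
variant draws.

What the generator does **not** emulate: linkage disequilibrium and
haplotype structure, relatedness, ancestry stratification, assay-
specific coverage dropout, and annotation error. Passing tests
therefore demonstrate correctness of the *procedure* under its stated
assumptions, not robustness to confounding in real cohorts (the real
analysis explicitly did not preselect for ancestry and relied on
cross-assay region masking, which this package accepts as an input BED
rather than recomputing).

## Problem sizes and numerical choices

The exhaustive Fisher validation sweeps all ~136,000 tables with total
≤ 40 against an exact-integer oracle. The type-I-error experiment uses
one cohort of 2000 null genes at 200 cases / 1000 controls; with the
exact test's conservatism on discrete data the empirical rate of
P ≤ 0.05 lands near 10⁻³, well under the nominal level, and the
Monte-Carlo bound 0.05 + 3·s.e. leaves headroom without being
vacuous. The planted-gene demonstration uses the full 13,132-sample
scale with 30 null genes — the P value of the planted configuration is
determined by its exact carrier counts, so null-gene count affects only
the ranking check. Output ordering is deterministic everywhere
(chromosome then position then gene; fixed model tie-break order), and
`-log₁₀ P` is guarded against P = 0 by clamping at the smallest normal
float.

## Known limitations

* Carrier-based collapsing ignores allele dosage and cannot represent
  compound heterozygosity.
* The minimum-P-across-models statistic is anti-conservative as a
  standalone test (see above).
* The multiple-testing denominator depends on the qualification rules;
  comparisons across runs with different rule sets should fix *n*
  externally.
* VCF ingestion is single-sample and assumes pre-annotated INFO fields;
  no annotation is computed in-package.
* The similarity measure is one defensible default among several
  (Resnik, Jiang–Conrath, asymmetric best-match averages would all be
  consistent with the upstream description).
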