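# Methods

`nbmap` re-implements, as a tested library, a computational framework for
deciding which normal fetal adrenal cell type neuroblastoma cancer cells
resemble. This note records the models, the parameters that matter, the
design choices made where the design was genuinely open, and what the
synthetic data do and do not establish.

## Synthetic data generator (`nbmap.simulate`)

The generator is first-class code: it defines the ground truth against which
every other module is validated.

**Single-cell counts.** Cells belong to one of up to six named populations
(SCP, bridge, chromaffin, sympathoblast, leukocyte, mesenchyme) plus an
optional tumor population. Counts are negative binomial in the
mean–dispersion parameterization, variance = mu + phi·mu², with phi the
square of the `nb_dispersion` parameter (sqrt scale, default 0.4 — the
convention used when a dispersion must be asserted rather than estimated).
Draws use the gamma–Poisson mixture so non-integer shape parameters keep the
mean exact. Per-cell depth is Poisson around `mean_umis` (default 5,000);
overdispersion beyond Poisson enters through the NB gene draws. A shared
log-normal baseline profile (sigma = 1) sets relative gene abundances.

**Markers.** Each population owns `markers_per_type` marker genes (default
20). Markers are moderately expressed in their own type (about 2 counts per
cell at mean depth) and near-silent elsewhere: the off-type baseline is the
in-type level divided by 2^`marker_log2fc`, so the planted elevation is
exactly `marker_log2fc` (log2 units, default 2). This mirrors real
cell-type markers, whose specificity comes from off-type silence rather
than in-type abundance, and is what makes tf-idf-style marker recovery a
meaningful test: a generator that gave markers an ordinary baseline would
make high tf-idf values unreachable at any fold change.

**QC metadata.** Mitochondrial fraction ~ Beta(2, 20), doublet score ~
Beta(1, 30), S and G2-M scores uniform on (−1, −0.01) (non-cycling). A
configurable fraction of cells (`qc_violation_fraction`, default 5%)
receives one planted violation: mito fraction in (0.31, 0.6), depth reduced
to 50–500 UMIs (so detected-gene and UMI counts stay consistent with the
matrix), doublet score in (0.21, 0.6), or a positive cycle score.

**Allele counts.** Within each copy-number segment, per-cell read depth is
Poisson(`mean_allele_depth`) split uniformly over `snps_per_segment` SNPs.
Major-haplotype reads are binomial with probability equal to the segment's
expected major fraction clipped by `allele_error` for tumor cells and 0.5
for normal cells. Each SNP's major allele is randomly ref or alt; the
assignment is recorded as ground truth.

**Bulk cohorts.** Half low-risk, half high-risk samples; 5% of genes carry a
planted risk effect of `marker_log2fc`. Covariates follow neuroblastoma
cohort structure: low-risk samples are young (< 18 months), almost always
MYCN-negative, stage 1/2/4S; high-risk samples older, 40% MYCN-amplified,
stage 3/4. TPM columns are count-derived and sum to 10⁶ exactly. Site
descriptions are drawn from a fixed vocabulary covering adrenal and
extra-adrenal strings.

**Genome annotation.** Genes are placed on one or two synthetic
chromosomes with strictly increasing, distinct TSS coordinates (0-based
half-open everywhere, BED convention); a planted region can be flagged for
smoothing tests.

All generators are bit-deterministic under a fixed seed; each uses an
independent `SeedSequence` stream so adding one generator never perturbs
another.

## Quality control (`nbmap.qc`)

Three preset threshold profiles:

| preset       | mito | min genes | min UMIs | doublet | cluster rule | cycling |
|--------------|------|-----------|----------|---------|--------------|---------|
| `adrenal`    | 0.30 | 300       | 1000     | 0.2     | > 50 % fail  | yes     |
| `tumor10x`   | 0.20 | 300       | 1000     | —       | —            | no      |
| `tumorplate` | 0.20 | 200       | 500      | —       | —            | no      |

Thresholds are strict inequalities in the failing direction: mito exactly
0.30 passes the adrenal preset, exactly 300 genes passes, a cycle score of
exactly 0 is kept. The cluster-level rule fails every member of a
high-resolution cluster whose individually failing fraction strictly
exceeds 50%; exactly half failing spares the passers. High-resolution
clustering is plumbing, delegated to scanpy (PCA → kNN → Leiden, resolution
10 by default, deliberately over-partitioned so the rule acts on small
homogeneous groups). Excluded gene families (nuclear-mitochondrial, heat
shock, ribosomal) are handled by a caller-supplied blacklist rather than a
hard-coded symbol list, which would be genome-version-specific.
Normalization is ln(1 + 10⁴·count/total) per cell, with raw counts retained
in a layer.

## Similarity scoring (`nbmap.similarity`)

One elastic-net logistic model per reference cell type (one-vs-rest,
mixing parameter alpha = 0.99), trained on log-normalized expression over
the genes shared with the query. One-vs-rest rather than multinomial so
that omitting softmax is well-defined per class: query cells are scored on
the raw logit scale and may be negative for every class, which is exactly
what an extrinsic population should do. Cluster summaries are arithmetic
means of member-cell logits; a logit of 0 carries no information.

Free choices, resolved as follows: features are standardized internally
before penalization and coefficients mapped back to the original scale
(the glmnet convention, which also conditions the saga solver);
regularization strength is chosen per class by K-fold (default 3)
cross-validated deviance over a geometric path from the smallest
all-zeroing penalty down 3 decades, taking the strongest penalty within
one standard error of the minimum — standard and conservative. Class
imbalance is not reweighted. Missing query genes contribute zero, so an
all-zero cell scores at the intercepts.

The k-means split of a similarity score (k = 2, used to separate low- and
high-signal tumor cells) labels the cluster with the smaller mean `low`;
ties in initialization are resolved by a seeded 10-start k-means, and
constant inputs are rejected as degenerate.

## Genotyping (`nbmap.genotyping`)

Phasing is a pooled-count estimator: within an imbalanced segment the
retained haplotype is over-represented in the mRNA pool, so each SNP's more
abundant allele (summed over all cells) is assigned to the major haplotype;
confidence is the pooled major fraction, exact 50/50 ties go to the
reference allele and are flagged. The per-cell likelihood is a product over
segments of binomial terms: tumor probability = expected major fraction
clipped into [error_rate, 1 − error_rate] (default error 0.01, a typical
mRNA base-call/mapping error scale and a free parameter), diploid
probability = 0.5; a flat prior (0.5) by default, so a cell with no
informative reads sits at posterior 0.5 — logit 0 meaning "no information".
Calls are definitive-tumor above 0.99, definitive-normal below 0.01; a
cluster is called tumor iff its definitive-tumor cells strictly outnumber
its definitive-normal cells. SNPs are treated as independent given the
haplotype; UMI-level double counting is ignored (counts are used at the
granularity the allele counter emits).

## Markers and differential expression (`nbmap.markers`)

tf-idf uses natural logarithm — required for the cutoff identity to hold: a
gene passes cutoff t exactly when its global expressing rate is below
exp(−t/tf). "Expressed" means count > 0 throughout. Significance is an
upper-tail hypergeometric test (cluster cells drawn from all cells,
successes = globally expressing cells), Benjamini–Hochberg adjusted; BH is
used for every correction in the package. The stringent marker filter adds
a ceiling of 20% expressing cells in any other single cluster and expects
an extrinsic negative-control population among the clusters (its absence is
tolerated with a warning). Tumor-marker merging averages tf-idf over the
lists in which a gene appears (a single-list gene keeps its own value — the
only reading under which "present in either or both lists" is meaningful),
applies a strict cutoff of 0.85, then removes genes expressed by more than
25% of leukocytes.

Rank-sum DE tests genes detected in at least 25% of cells of at least one
group (the semantics of the cited single-cell toolchain's `min.pct`
prefilter) with a two-sided Wilcoxon test on log-normalized values;
fold changes compare de-logged normalized group means with pseudocount 1.

The copy-number DE model is an NB GLM on raw counts with a
log-library-size offset and a group indicator, with overdispersion
estimated independently per gene by profile maximum likelihood (bounded
search over log10 alpha; deliberately no information sharing across genes,
appropriate when both groups are large — a minimum of 10 cells per group is
enforced, with smaller groups directed to the fixed-dispersion model). The
group effect is assessed by a quasi-likelihood F test: deviance difference
scaled by Pearson-chi²/df of the full fit, against F(df_diff, df_resid).
Exact numeric equivalence to any particular reference implementation is not
promised; calibration is established by simulation (null type-I error
within Monte-Carlo tolerance of 5%, fold-change recovery within ±0.3 at
planted log2FC 2).

## Bulk signal (`nbmap.bulk`)

The presence threshold is the mode (argmax of a Gaussian KDE, Silverman
bandwidth, 2048-point grid) of the pooled log2(TPM) distribution over
strictly positive entries — zeros are excluded since log2(0) is undefined
and would otherwise dominate; no pseudocount. A degenerate point mass
returns its log2 value directly. "Present" is strictly above the
threshold. Per-marker-set summaries are per-gene presence fractions
summarized by median and interquartile range over genes (not samples);
this reading is flagged as a choice.

Risk stratification implements exactly two rules — low: age < 18 months
and MYCN-negative; high: age > 18 months and MYCN-positive; stage 4S and
every other combination (including exactly 18 months or missing
covariates) unclassified, with the reason recorded. The extra-adrenal
filter retains samples with a non-empty site description containing none
of seven stop-words (kidney, adrenal, abdominal, abdomen, unknown,
retroperitoneum, other; case-insensitive substring match).

The fixed-dispersion NB GLM (sqrt-dispersion 0.4, the value used when
genuine biological replicates are unavailable) models raw counts with a
log-library-size offset and dummy-coded covariates; the tested variable's
coefficient is reported as a signed log2 fold change with its contrast
named. TPM-only cohorts are refused — TPM values are not valid NB
observations. Rank-deficient designs are rejected naming the aliased
columns. The reporting rule for significance is |log2FC| > 1 and FDR <
0.05.

Fetal-cancer transcript ranking keeps genes expressed in at least 50% of
cancer cells in every tumor dataset, in at most 20% of any other cluster,
and in at least 10% of medullary cells, then sorts ascending by mean
log2(TPM + 1) over non-brain tissues (the pseudocount handles zeros, which
the bare log2(TPM) average would not).

## Genomic smoothing and region tests (`nbmap.smoothing`)

A cell type's track is sum over genes of w_g · N(x; tss_g, sigma²) with
sigma the bandwidth (default 200,000 bp) and w_g the **mean** over that
type's cells of depth-normalized expression — mean rather than sum so that
tracks are comparable between cell types of different sizes, which is the
comparison the method exists for. The evaluation grid defaults to
bandwidth/10, putting quadrature error well below test resolution (track
integrals match total weight to ~0.1% away from chromosome edges).

Recurrent regions are maximal runs of bins altered in at least
`min_samples` tumors (default 200, inclusive), gains and losses assessed
separately. Breakpoint regions are ±1 Mb windows around a transition
point, clipped to the chromosome.

The region test compares the mean of (track_a − track_b) over the region's
grid points (mean over grid points, not an integral — flagged as a choice)
against the same statistic in randomly placed regions of the same length,
uniform over valid start positions across all chromosomes long enough to
hold the region (random regions do not respect the tested region's
chromosome — with one or two synthetic chromosomes the distinction is
immaterial). The p-value is the plain fraction of null differences at
least as large as the observed one, which can be exactly 0; a (+1)/(n+1)
correction is available but off by default to match the printed
definition.

## What the tests do and do not show

Everything is validated on synthetic data with known ground truth. The
generator reproduces the *structure* of the real data — NB counts with
type-specific markers, binomial allelic imbalance, risk-structured
covariates — but not ambient RNA contamination, doublet transcriptomes
(only a score column), gene-length/GC effects, batch structure, or the
continuous differentiation topology of the real medulla. Passing tests
therefore establish correctness of the statistical machinery and
recoverability under the declared generative model, not performance on any
particular patient cohort. Problem sizes in the test suite and acceptance
script (hundreds of cells per type, 500–2,000 genes, cohorts of 80–500
bulk samples, 200–1,000 permutations) were chosen as the smallest at which
the Monte-Carlo assertions have comfortable margins.

## Known limitations

- The quasi-likelihood F test is a standard construction, not a clone of
  any published implementation; p-values agree in calibration, not to the
  digit.
- Pooled-count phasing assumes tumor cells dominate the pooled signal in
  imbalanced segments; cohorts with low tumor purity would need
  genotype-aware phasing upstream.
- The similarity model's lambda path (3 decades, 8 points) and 1-SE rule
  are defaults, not re-derivations of any particular study's protocol.
- Library-size offsets (not trimmed-mean normalization) are used in the NB
  GLMs; strong compositional shifts between groups bias fold changes
  toward zero by the log ratio of library sizes, as in any
  offset-normalized analysis.
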