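# Methods

This note documents the statistical models behind `circlin`, the
defaults and their units, what the synthetic-data generator does and
does not emulate, and the numerical choices made where the design was
genuinely open.

## Detection and filtering

Backsplice evidence arrives as one row per (circRNA, detection
method, sample) with a raw read count; nine methods is the reference
configuration. The consensus per-sample count is the **median over
reporting methods with halves rounded down** (so methods reporting
{5, 7} give 6). Median was chosen over min/max for robustness to one
outlier caller; both alternatives remain available
(`Config.consensus_stat`). A circRNA is *detected* when reported by
at least `min_methods = 2` distinct methods anywhere and its
consensus count reaches `min_reads = 5` in at least one sample. The
two conditions are evaluated globally by default; requiring them to
hold within a single sample is the stricter reading and is available
as `Config.strict_same_sample`.

The breadth rule keeps a circRNA expressed (consensus count ≥ 1) in
at least ⌈n/2⌉ samples of JMML or of HD, or in strictly more than
3/4 of the samples of one molecular subtype. Boundaries are
deliberate: "at least one half" is inclusive, "over three quarters"
is strict.

Annotation classifies a circRNA as exonic when both backsplice ends
fall inside exons (read-through circRNAs whose ends sit in two genes
are exonic with both hosts listed; the locus is the gene containing
the 5′ end), intronic when inside a gene body otherwise, and
intergenic when no gene overlaps. Isoform labels are the exon-number
span on the host gene's longest transcript (total exonic length, ties
broken lexicographically). Intergenic circRNAs are clustered into
`CircClust` pseudo-loci by single linkage with an inter-interval gap
of at most 5,000 nt; cluster numbering follows (chromosome, leftmost
start), making the clustering order-invariant. Coordinates are
0-based half-open throughout; BED export keeps that convention and
the GTF-like export converts to 1-based inclusive. The coordinate
convention of upstream callers is not standardized, so the package
fixes one rather than guessing.

## Differential expression

The engine is a deliberate, self-contained approximation of the
DESeq2 + sva combination rather than a wrapper around them; fidelity
is claimed at the level of statistical properties (calibration, FDR
control, effect recovery), which the test suite measures, never as
value-equality with those packages.

* **Size factors**: median-of-ratios over features with nonzero
  counts in all samples (geometric-mean fallback over positive
  entries when none exist), rescaled to geometric mean 1.
* **`rlog_like`**: log2(count/sf + 1) with each sample's value shrunk
  toward the feature mean by weight 1/(1 + mean normalized count).
  A display/ordination transform only; no test statistic uses it.
* **Dispersion** (Var = μ + αμ²): per-feature method-of-moments α
  from residual variance about the fitted design (hat-matrix
  residuals, df = n − rank(X)), a lowess trend of log α on log mean
  (span 0.5), and a precision-weighted log-space average of raw and
  trend (prior weight 10 pseudo-df). Moderation is asymmetric: the
  final α is floored at both the raw estimate and the trend. The
  floor exists because a plug-in Wald test with an underestimated
  dispersion is anticonservative at n ≈ 6/group; the test suite
  verifies that the resulting null type-I error sits inside
  [0.03, 0.07] at α = 0.05 while power for |LFC| = 2 at base mean
  ≥ 100 stays near 1.
* **GLM / Wald**: log-link NB GLM with log size factors as offset,
  fitted by batched IRLS (all features share the design, so the
  per-feature normal equations are solved as one batched operation);
  Wald z on the group coefficient with two-sided normal p-values;
  no independent filtering; BH adjustment with missing p-values
  excluded from the family. Positive LFC means higher in the
  first-named (JMML/subtype) group. All-zero and non-convergent
  features are reported with missing statistics, never dropped
  silently.
* **Surrogate variables**: the normalized matrix is residualized on
  the primary design and the residuals decomposed by SVD. The number
  of factors comes from permutation parallel analysis (20 row-wise
  permutations of the *original* matrix, 95th-percentile threshold;
  permuting the residual matrix instead shrinks the permuted spectrum
  and systematically overestimates k). Each kept factor is then
  rebuilt as the leading right singular vector of the original
  (row-centered) data restricted to the features most associated with
  the residual direction. This second step matters: residual
  directions are orthogonal to the design by construction, so a
  surrogate taken directly from them cannot carry the batch component
  that is collinear with the condition — including it would shrink
  standard errors without removing the confounded bias. The rebuilt
  surrogate recovers the full latent vector, and the tests verify
  that including it restores type-I control on confounded-null data
  where omitting it inflates the error several-fold. A perfectly
  condition-aligned batch is unidentifiable by any method and is out
  of scope (the generator never produces one when a confounded batch
  is requested).
* **LFC shrinkage is intentionally absent**: reported LFCs are MLEs,
  matching a workflow that reports unshrunken fold changes (values
  above 15 log2 units occur for features absent in one group).

Contrasts: JMML vs HD, each subtype vs HD, and all subtype pairs;
surrogate variables are estimated once on the full cohort and the
same covariate policy applies to every contrast (how the original
study handled subtype contrasts is unstated; one policy for all is
the defensible default). Isoform switches are host genes with one
isoform significantly up and a different one significantly down, in
the same or different contrasts.

## Circular-to-linear proportion

CLP = circ_mean / (circ_mean + lin_mean) on **group means of
size-factor-normalized counts** (figure-level thresholds like
"circular mean expression > 40" are group-mean statements; a
per-sample variant exists behind a flag). Every circular isoform of a
locus is compared against the same linear row. Intergenic circRNAs
have no linear counterpart: lin_mean = 0 and CLP = 1 where expressed.
The exact formula of the original supplementary material is not in
the available text; circ/(circ+lin) follows the in-text definition
("relative expression of a circRNA in relation to the total of
overlapping circular and linear transcripts") and is flagged here as
a reconstruction.

LFC(CLP) is computed as log2(clp_A) − log2(clp_B) with the
pseudo-proportion ε = 10⁻⁹ substituted **only for exact zeros**; CLP
itself is reported without pseudocount. The log-difference form makes
group swap negate the value bitwise and keeps ratio-of-two boundaries
(0.4 vs 0.2) exactly on |LFC| = 1. Screen inequalities follow the
printed thresholds exactly: ≥ 0.33, > 40, ≥ 100, ≥ 0.1, |·| ≥ 1; the
"≥ 100 normalized reads" condition is satisfied by either group
(which group the original figure meant is ambiguous; "either" is the
inclusive choice, switchable).

## Network reconstruction

Both predictors' thresholds mirror the published boundary semantics
exactly (score ≥ 100, energy ≤ −20, ΔG_duplex < −20, ΔG_open > −13;
kcal/mol). "Commonly predicted binding sites" is read as positional
agreement — an A-site must overlap a B-site of the same
(circRNA, miRNA) pair by ≥ 1 nt — rather than the weaker
"same miRNA in both outputs"; `n_sites` counts merged clusters of
overlapping common sites so staggered predictions are not double
counted. miRNAs present in the reference expression series are kept
when nonzero in ≥ 25% of its samples (the original criterion for that
series is unstated; 25% is a conventional presence cut-off,
configurable); miRNAs absent from the series need ≥ 3 common sites on
the same circRNA. Validated target edges default to the
`Functional MTI` strong-evidence label (extensible). Genes count as
expressed at mean JMML TPM strictly > 1. Correlation with the focal
circRNA is Spearman (average ranks for ties) across JMML samples
only, on normalized expression, flagged at ρ ≥ 0.4. The graph is
tripartite by construction (circRNA → miRNA → gene); correlation is a
gene-node annotation, not an edge class.

Sequence assembly joins annotated exons of the longest transcript
within the backsplice span (reverse-complemented for minus-strand
circRNAs) and appends the first `max_site_len − 1` nucleotides so
junction-spanning sites are findable. The bundled seed scanner
(exact reverse-complement match of miRNA nucleotides 2–8, with
deterministic GC-derived pseudo-scores) exists to generate fixtures
that straddle the thresholds; it is not a binding-site predictor.

## qPCR statistics

RQ = E^(Ct_cal − Ct) with the per-assay mean Ct as calibrator (qBase
convention; between-sample ratios are invariant to the calibrator
choice). Efficiencies are fold-per-cycle E ∈ (1, 2.2] (2.0 = 100%;
a converter accepts percent form). NRQ divides RQ by the geometric
mean of the reference assays (TBP, HPRT1, GAPDH); a sample missing
any reference is blanked with a log entry rather than imputed. With
E = 2 everywhere the NRQ group ratio reduces algebraically to the
classic 2^−ΔΔCt, which the tests verify to machine precision.

Mann–Whitney U is two-tailed, exact (no ties, both groups ≤ 8 or
combined n ≤ 12) or normal-approximated with tie correction
otherwise, BH-adjusted across the tested panel (panel-wide adjustment
is the conservative reading of the original reporting; per-family is
available). Kruskal–Wallis covers subtype comparisons with pairwise
Mann–Whitney follow-ups; the p < 0.1 display threshold is a reporting
convention, not a test. Per-target analyses use all samples with
complete data for that target, tolerating missingness.

## Synthetic data

The generator reproduces the study *design*, not its biology:

* cohort structure: 8 PTPN11 + 5 KRAS + 4 NRAS + 2 NF1 JMML patients
  vs 3 HD for discovery; 12 JMML vs 6 HD for validation qPCR;
* NB counts with log-normal baselines (log2 mean 5, sd 1.5) and
  log-normal dispersions (median 0.08, log-sd 0.5) — chosen once for
  testability, since the source describes sequencing depth but not
  dispersion; per-sample depth factors are log-normal (sd 0.3);
* planted effects: a configurable fraction (default 10%) of circRNAs
  at |LFC| = 2, plus one hero circRNA at LFC 6.64. The hero default
  is ~100-fold: the study's standout circRNA is reported as more than
  80-fold up-regulated, and a planted fold just below 80
  (e.g. 2^6.3 ≈ 78.8) could not reproduce a ">80-fold" observation;
* a binary latent batch: each sample gets a ±1 batch sign (optionally
  condition-imbalanced via `batch_confound`, allocated so it is never
  perfectly collinear with condition) and each feature a Gaussian
  log2 loading of scale `batch_effect_sd`. A single common multiplier
  would be absorbed by size factors and unrecoverable; feature-specific
  loadings keep the factor estimable while preserving the
  one-binary-covariate structure. The batch acts on circular counts
  (the matrix surrogate estimation sees);
* per-group CLP targets drawn per circRNA (linear means derived from
  them), with a planted subset shifted by |LFC(CLP)| > 1;
* detection evidence by binomial thinning (sensitivity 0.8 per
  method), guaranteeing per-method counts never exceed truth, plus
  single-method artifact circRNAs (10% of m) with ≥ 5 reads so only
  the multi-method rule can remove them;
* network inputs where every planted pair passes all gates and every
  decoy fails exactly one (sub-threshold score/energy, one-predictor
  support, no positional overlap, too few sites for an unquantified
  miRNA, present-but-silent in the reference, weak evidence label,
  silent target gene) — so precision/recall against planted truth is
  a sharp end-to-end check;
* hero-correlated genes coupled to the hero's within-JMML profile
  with high depth and low dispersion, making the planted ρ ≥ 0.4
  property hold by construction;
* qPCR Ct values from the planted fold change with per-sample loading
  offsets (removed by NRQ normalization), biological log2 spread 0.25
  and 0.1-cycle technical noise.

What it does **not** emulate: read-level data, realistic transcript
structures, GC / length biases, correlated dispersion across loci,
isoform competition within a gene, or qPCR outliers and non-detects.
Passing tests therefore demonstrate correctness of the statistical
machinery under the stated model, not performance on real cohorts.

## Problem sizes and determinism

Test and acceptance runs use deliberately compact sizes — m = 2,000
features at n = 6 vs 6 for calibration (20 replicates for FDR/power),
m = 1,000 for the confounded-batch study, m = 300 with the full
19 vs 3 design for end-to-end recovery — chosen so the whole battery
completes in well under a minute while keeping Monte-Carlo error
small relative to every margin tested. All randomness flows from
explicit seeds; identical parameters give byte-identical outputs.

## Known limitations

* The Wald test relies on plug-in dispersions; calibration is
  verified at the simulated settings, and very small groups (n = 2,
  as in the NF1 subtype) yield unstable subtype contrasts — they are
  computed but should be read descriptively.
* Surrogate estimation assumes the latent structure is low-rank and
  not perfectly collinear with the design.
* The CLP formula is a reconstruction (see above).
* `rlog_like` is an intentionally simple moderation, not a
  likelihood-based variance-stabilizing transform.
* Network reconstruction treats predictor outputs as given; no
  attempt is made to rescore or re-thermodynamicize sites.
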