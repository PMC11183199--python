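# Methods

This note records the statistical models, the numerical choices, and the
reasoning behind the open design decisions in `convergemeth`. Nothing
here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Normalization (GeTMM)

Counts are first length-corrected to reads per kilobase,
RPK = count / (length_bp / 1000), using each sample's own species' gene
length, then scaled by TMM factors computed **on the RPK matrix**:

* M-values M = log2((y/N)/(y_r/N_r)) and A-values
  A = ½·log2((y/N)·(y_r/N_r)) against a reference column, genes with a
  zero in either column excluded;
* double trimming — the central 40% of M-ranks (30% off each tail) and
  central 90% of A-ranks (5% off each tail) are kept;
* inverse asymptotic-variance (delta-method) precision weights
  w = (N−y)/(N·y) + (N_r−y_r)/(N_r·y_r);
* factor = 2^(Σ wM / Σ w), then all factors rescaled to geometric mean 1.

The reference column is the sample whose upper-quartile of
library-scaled RPK is closest to the mean upper quartile. The final unit
is RPK-per-million after TMM scaling; a column's values sum to
10⁶ / factor.

*Scale invariance.* M and A are proportion-based, so with unit weights
the factors are exactly invariant to multiplying one library by a
constant. The precision weights, however, depend on absolute depth (a
deeper library has smaller asymptotic variance), so with weighting on —
the default, and the behaviour of weighted TMM generally — the
invariance holds only approximately. `tmm_factors(..., weighting=False)`
gives the exactly invariant variant; the tests assert exact invariance
there and a 10% bound with weights on.

*Zero filtering.* An orthologue is dropped when **any** species has all
its samples at zero (the stricter of the two readings of "zero
expression across all samples within the same species");
`filter_zero_genes(policy="all_samples_zero")` gives the laxer variant.

## Differential expression

A common-dispersion negative-binomial conditional exact test stands in
for a full GLM machinery; the screening thresholds and downstream logic
are the scientific content here, not the dispersion estimator.

* Dispersion: method-of-moments over all genes,
  φ̂ = Σ[(y−μ̂)² − μ̂]/μ̂² ÷ residual df, with μ̂ the per-group fitted
  mean scaled by effective library sizes (depth × TMM factor), floored
  at 0. Single-sample groups contribute no residual df.
* Test: counts are scaled to the geometric-mean library, group totals
  formed; a sum of n i.i.d. NB(μ, φ) is NB(nμ, size n/φ), so the
  conditional distribution of the group-A total given the overall total
  is available directly. The two-sided p sums the probabilities of all
  splits no more probable than the observed one (minimum-likelihood
  rule); at φ = 0 this is the exact binomial test. A zero total gives
  p = 1 by convention.
* Calls: BH step-up FDR ≤ 0.05 **and** |log2FC| ≥ 1, both inclusive, on
  GeTMM group means with a pseudocount of 1 GeTMM unit on both means.

Calibration and power under the study design (φ = 0.1, 4 vs 3) are
measured in `tests/test_acceptance.py` and by the acceptance script.

## Methylation quantification

All levels are pooled-count ratios ΣmC/Σ(mC+C); the pooled level equals
the coverage-weighted mean of site levels, an identity asserted on
random data. Sites under 10× coverage are removed first (10× kept, 9×
removed). Plus- and minus-strand cytosines are distinct sites (the
aligner's reporting convention); `merge_symmetric_cpgs` optionally sums
the pos/pos+1 pair but is off by default. Bins tile from position 1,
width 10 kb, terminal partial bin kept. Promoters are the 1,000 bp
immediately upstream of the TSS, strand-aware, clipped at the chromosome
edge. Region levels use CpG-context sites only by default (contexts are
a column, so CHG/CHH can be selected). The metagene profile uses 20 bins
per segment — upstream 2-kb flank, body (equal fractions of each gene's
span), downstream flank — oriented 5′→3′; "20 bins" for a three-segment
profile is read as per segment, which reproduces the expected
three-phase shape (flank dip at the promoter, body plateau).

## Liftover and the joint CpG matrix

Chain files are parsed strictly (block sums must equal the header
spans). A position maps through the highest-scoring chain covering it
(input order breaks ties, liftOver-like); positions falling in dt/dq
gaps are unmapped — a lower-scoring overlapping chain is *not*
consulted, matching liftOver's single-best-chain behaviour.
Minus-strand queries reflect the coordinate (q_size − q − 1, 0-based)
and flip the strand. All internal chain arithmetic is 0-based
half-open; the API is 1-based.

The joint matrix keeps a reference CpG only if it is ≥10×-covered in
every reference sample and its lifted coordinate is a ≥10×-covered
CpG-context record in every sample of every other species (the
CpG-identity guard protects against context-destroying substitutions;
`require_cpg=False` disables it). Rows therefore have no missing
entries by construction. Both species contrasts are evaluated on one
joint matrix in reference (giant-panda) coordinates, the "one designated
reference" generalization of lifting the bear onto each panda.

## DMR and DMG calling

The DMR caller is a deliberately simple, exactly testable windowed test
(it replaces smoothing-based beta-binomial callers; downstream logic
consumes only intervals and directions): 500-bp windows at 250-bp step;
per window, counts pooled within each group; candidate iff ≥3 CpGs have
same-sign pooled per-site differences ≥ 0.1, the pooled window
difference is ≥ 0.1, and the two-proportion z-test on pooled counts
gives p < 10⁻⁴. Same-direction overlapping/adjacent candidates merge;
merged statistics are recomputed on the union of sites and must still
satisfy all three constraints or the merge is not emitted. DMR
boundaries are the outermost qualifying CpGs.

Gene-body DMGs: a DMR is assigned to a gene iff the base-pair overlap
with the gene span strictly exceeds half the DMR length; genes are
classed hyper_only / hypo_only / mixed, and only the pure classes feed
enrichment.

Promoter DMGs: eligibility needs ≥2 CpG positions covered by **more
than** 10 reads in **every** sample (the strict per-sample reading;
`rule="pooled"` implements the per-group-pooled alternative) — applied
within each species' own promoter coordinates, since the two groups
live on different genomes. The test is a one-tailed Wilcoxon rank-sum
with midranks, exact by full enumeration of the C(n_A+n_B, n_A) rank
assignments for the study's group sizes (normal approximation with tie
correction beyond 24 pooled samples); the tail follows the sign of the
fold change FC = (mean_A + ε)/(mean_B + ε), ε = 0.005 guarding zero
denominators. A call requires FC > 2 or FC < ½ (strict) and p < 0.05.

## Integration, convergence, enrichment

Integration records pair a gene's promoter (or gene-body) methylation
fold change with its expression fold change; records are retained when
linear methylation FC > 2 or < ½ and |log2 expression FC| > 0.5, both
FCs are log2-transformed, and Spearman's ρ is tested with
t = ρ√((n−2)/(1−ρ²)), two-tailed, df = n−2. Negative-correlation
classes: hypo_high = promoter-hypomethylated DMG ∧ up-regulated DEG;
hyper_low = hypermethylated ∧ down-regulated; discordant pairs belong to
neither. Convergence demands the identical significant call in **both**
panda-versus-bear comparisons (direction and significance, not direction
alone). Enrichment is the hypergeometric upper tail with BH q-values
reported and the significance flag at p < 0.05 as the screen prescribes.
Clustering uses distance 1 − ρ(Spearman) with complete linkage
(average/single selectable); expression is log2(x+1)-transformed before
PCA/clustering, methylation levels are used raw.

## Synthetic-data generator

The generator's defaults are the study conditions:

| parameter | default | rationale |
|---|---|---|
| genes / genome | 200 on 2 × 5 Mb | desk-scale stand-in for the genome-wide screen |
| RNA roster | 4 aml / 4 afu / 2 umr | the real library rosters |
| RNA depth | 0.4 M (pandas), 1.2 M (bear) | the bear was sequenced ≈3× deeper; exercises depth correction |
| NB dispersion φ | 0.1 | typical bulk liver RNA-seq replicate dispersion |
| planted DE | 15 up + 15 down convergent, 10 lineage per panda, log2FC = 2 | clear effects at the screen's own threshold scale |
| WGBS roster | 5 aml / 4 afu / 3 umr | the real library rosters |
| coverage | Poisson(30) | ≈30× genome-wide WGBS |
| CpG spacing | 60 bp promoters, 110 bp genic, 150 bp intergenic | CpG-island-like promoter density |
| baselines | promoter 0.2, gene body 0.75, intergenic 0.7, CHH 0.02 | the mammalian element-level pattern (promoters lowest) |
| lineage structure | logit-scale species deviations, sd 0.4, corr(aml,umr)=0.8 vs 0.3 | phylogeny: giant panda and bear closest |
| planted methylation Δ | 0.3 (promoter 0.2↔0.5, gene body 0.5↔0.8) | the recovery-experiment effect size |
| chains | identity with ~15 intergenic indels (50–500 bp) per chromosome | genic positions always map; the full map is in the truth ledger |

Coupling: the 10+10 negative-correlation genes are convergent-DE genes
whose promoters also receive the opposite-direction methylation shift.
The truth ledger records every planted call, the planted intervals, and
the exact chain arithmetic, and is serialized beside the outputs.

What the generator does **not** emulate: read-level errors and mapping
bias, bisulphite conversion failure, copy-number and SNP effects,
context-destroying substitutions between species, correlated
methylation within regions (species deviations are independent across
sites), and annotation error. Passing recovery tests therefore
demonstrates that the statistics find what they are defined to find at
realistic depth and replication — not that real cross-species data meet
these assumptions.

*The noise-only null.* False-positive rates are measured on a genome
with no planted effects **and** lineage deviations off. With lineage
deviations on, the two species genuinely differ at many individual
sites, so windows crossing them are true detections, not false
positives (real between-species comparisons likewise yield thousands of
DMRs); only the sampling-noise null gives a well-defined FPR.

## Numerical conventions

* 1-based inclusive coordinates everywhere except chain arithmetic and
  BED output (0-based half-open).
* Ties: midranks in the Wilcoxon statistic; merge-sort (stable) ordering
  wherever ranks or sorts influence results; chain ties broken by input
  order.
* Degenerate inputs: zero-coverage levels are NaN, never 0; a zero test
  total gives p = 1; empty gene lists and empty files round-trip as
  empty.
* Exact-test tolerance: split probabilities compared with a 1 + 10⁻¹²
  relative guard so equal-probability splits are included determinately.
* Problem sizes in the suite and acceptance script (200-gene genomes,
  2,000-gene calibration runs, 20 clustering replicates, 100 liftover
  chains) were chosen as the smallest sizes at which the binomial
  uncertainty of the measured rates is comfortably inside the asserted
  bands.

## Known limitations

* The DMR caller does not smooth or shrink; single deep windows can
  dominate merged statistics. DMR counts are not comparable to
  shrinkage-based callers, though directions and gene-level calls are.
* The common-dispersion exact test ignores gene-wise dispersion
  variation; with strongly heterogeneous dispersions the null
  calibration degrades.
* Promoter eligibility across species is checked per species (the two
  groups' promoters live on different genomes); a per-site cross-species
  eligibility would require lifting promoter CpGs individually.
* Only single positions are lifted; split or inverted gene-scale lifts
  are out of scope.
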