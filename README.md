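# convergemeth

Cross-species comparison of liver transcriptomes and DNA methylomes, built
for the question of **diet-driven convergent evolution**: two bamboo-eating
species — the giant panda (*Ailuropoda melanoleuca*, `aml`) and the red
panda (*Ailurus fulgens*, `afu`) — compared against a carnivorous relative,
the polar bear (*Ursus maritimus*, `umr`). The package is aimed at
comparative epigenomics analysts who have post-alignment artifacts in hand
(featureCounts tables, Bismark cytosine reports, a 1:1:1 orthologue map,
GTF annotations, UCSC chain files) and want the full screen from
normalization to convergence calls, with every statistical step testable.

## What it computes

**Expression.** Orthologue counts from all species are joined into one
matrix and normalized with GeTMM (gene-length-corrected TMM): counts are
converted to reads per kilobase, RPK = count / (length/1000), then scaled
with trimmed-mean-of-M-values factors *f*ₛ,

&nbsp;&nbsp;&nbsp;&nbsp;value<sub>g,s</sub> = RPK<sub>g,s</sub> / (Σ<sub>g</sub> RPK<sub>g,s</sub> · *f*ₛ) · 10⁶,

so neither sequencing depth nor between-species gene-length differences
masquerade as expression change. Differential expression between two
species' sample groups uses a common-dispersion negative-binomial
conditional exact test (splits of the group total compared by
minimum likelihood), with genes called at BH FDR ≤ 0.05 and |log₂FC| ≥ 1.

**Methylation.** Every level is a pooled-count ratio ΣmC / Σ(mC + C) —
per site, per 10-kb bin, per promoter (the 1,000 bp upstream of the TSS,
strand-aware), gene body, exon, intron, and per metagene bin (2-kb flanks
and body, 20 bins each) — after removing sites under 10× coverage.
CpG sites are lifted between genomes through UCSC chain files, and the
joint cross-species CpG matrix keeps only sites covered in every sample of
every species.

**Differential methylation.** DMRs come from a sliding-window
pooled-count test (500-bp windows, 250-bp step): ≥3 CpGs with same-sign
per-site group differences ≥ 0.1, window difference ≥ 0.1, and a
two-proportion z-test p < 10⁻⁴, with same-direction windows merged.
Gene-body DMGs are genes overlapped by more than half of a DMR. Promoter
DMGs need ≥2 CpGs covered by >10 reads in every sample, a group
fold-change above 2 (or below ½), and a one-tailed exact Wilcoxon
rank-sum p < 0.05.

**Integration and convergence.** Genes whose promoter methylation and
expression shift in opposite directions are split into hypo-methylated +
up-regulated and hyper-methylated + down-regulated classes; Spearman
correlation of log₂ methylation FC against log₂ expression FC (records
filtered at linear methylation FC > 2 and |log₂ expression FC| > 0.5) is
tested with the t-approximation. A gene is *convergent* when it earns the
same significant call in both panda-versus-bear comparisons. Gene-set
enrichment is upper-tail hypergeometric, p = P[X ≥ k], X ~
Hypergeom(N, K, n), significant at p < 0.05.

**Synthetic data.** `convergemeth.synthetic_data` generates the entire
input surface with a known truth ledger: NB counts with planted convergent
and lineage-specific expression shifts, cytosine reports with planted
promoter/gene-body differentials (Δ = 0.3) on lineage-structured baselines
(giant panda and polar bear deviations more correlated than either with
the red panda), identity-with-indel chain files with an exact mapping
table, and gene sets enriched for the planted genes. Expression therefore
clusters by diet while methylation clusters by phylogeny, the package's
headline structural contrast.

## Worked example

```python
from convergemeth.synthetic_data import GeneratorConfig, simulate
from convergemeth.pipeline import run_pipeline

dataset = simulate(GeneratorConfig(seed=1))   # 200 genes, 2 x 5 Mb, RNA 4/4/2, WGBS 5/4/3
result = run_pipeline(dataset)
for key, comp in result.comparisons.items():
    n_up = sum(d.status == "up" for d in comp.degs)
    n_down = sum(d.status == "down" for d in comp.degs)
    print(f"{key}: {n_up} up / {n_down} down DEGs, "
          f"{len(comp.promoter_dmgs)} promoter DMGs, "
          f"{len(comp.dmrs)} DMRs, {len(comp.genebody_dmgs)} gene-body DMGs")
print(f"convergently expressed genes: {len(result.convergent_expr)}")
print(f"convergent hypo+high / hyper+low genes: {len(result.convergent_negcorr)}")
```

prints

```
aml_vs_umr: 21 up / 20 down DEGs, 24 promoter DMGs, 82 DMRs, 25 gene-body DMGs
afu_vs_umr: 20 up / 20 down DEGs, 24 promoter DMGs, 469 DMRs, 53 gene-body DMGs
convergently expressed genes: 29
convergent hypo+high / hyper+low genes: 17
```

The generator planted 30 convergently expressed genes (15 up, 15 down) and
20 coupled promoter-methylation/expression genes; the screen recovers 29
and 17 of them here (Jaccard 0.85 against the truth ledger). The red-panda
comparison yields many more DMRs than the giant-panda one because the red
panda's methylation baseline is the least correlated with the bear's —
methylation differences track phylogeny, expression differences track
diet.

A thin CLI wraps the same steps:

```sh
convergemeth simulate --seed 1 --out simdata/
convergemeth normalize --counts aml=simdata/counts_aml.tsv \
    --counts afu=simdata/counts_afu.tsv --counts umr=simdata/counts_umr.tsv \
    --ortho simdata/ortho_map.tsv --out expr.tsv
convergemeth run --seed 1 --out results/
```

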