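"""End-to-end orchestration of the comparative methylome/transcriptome screen.

Glue only: every scientific step lives in its own module.  The driver
runs, for each panda-versus-bear comparison, GeTMM normalization and
differential expression, promoter DMG testing on each species' own
annotation, DMR calling on the joint CpG matrix (reference coordinates)
with gene-body assignment, the negative-correlation split, and the
convergence screens across the two comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .io_formats import CountTable, GeneModel
from .expression import NormalizedExpr, OrthoMap, assemble_ortho_matrix, filter_zero_genes, getmm
from .differential_expression import DEGResult, run_differential_expression
from .methylome import MethylomeSet, coverage_filter, promoter_interval, region_level
from .crossmap import ChainSet, JointCpGMatrix, build_joint_matrix
from .diffmeth import (
    DMR,
    GeneBodyDMG,
    PromoterDMG,
    assign_genebody_dmgs,
    call_dmrs,
    call_promoter_dmgs,
    promoter_eligibility,
)
from .integration import (
    ConvergentGene,
    IntegrationRecord,
    convergence_screen,
    negative_correlation_genes,
)
from .synthetic_data import COMPARISONS, REFERENCE, SyntheticDataset, comparison_key

__all__ = ["ComparisonResult", "PipelineResult", "run_pipeline", "promoter_dmgs_for_comparison"]


@dataclass
class ComparisonResult:
    species_a: str
    species_b: str
    degs: list[DEGResult]
    promoter_dmgs: list[PromoterDMG]
    dmrs: list[DMR]
    genebody_dmgs: list[GeneBodyDMG]
    negcorr: dict[str, set[str]]

    @property
    def key(self) -> str:
        return comparison_key(self.species_a, self.species_b)


@dataclass
class PipelineResult:
    expr: NormalizedExpr
    joint: JointCpGMatrix
    comparisons: dict[str, ComparisonResult]
    convergent_expr: list[ConvergentGene]
    convergent_negcorr: list[ConvergentGene]


def promoter_dmgs_for_comparison(
    msets_a: Sequence[MethylomeSet],
    msets_b: Sequence[MethylomeSet],
    models_a: Mapping[str, GeneModel],
    models_b: Mapping[str, GeneModel],
    ortho_ids: Sequence[str],
    min_reads: int = 10,
    min_cpg: int = 2,
) -> list[PromoterDMG]:
    """Promoter DMG screen over orthologues, each species on its own genome.

    ``models_a``/``models_b`` map ortho_id -> that species' gene model.
    Eligibility (>= ``min_cpg`` CpGs covered by more than ``min_reads``
    reads in every sample) is applied within each species' promoter
    coordinates.
    """
    out: list[PromoterDMG] = []
    for og in ortho_ids:
        ma, mb = models_a.get(og), models_b.get(og)
        if ma is None or mb is None:
            continue
        prom_a = promoter_interval(ma)
        prom_b = promoter_interval(mb)
        if prom_a is None or prom_b is None:
            continue
        n_a = promoter_eligibility(msets_a, ma.chrom, prom_a[0], prom_a[1], min_reads)
        n_b = promoter_eligibility(msets_b, mb.chrom, prom_b[0], prom_b[1], min_reads)
        if n_a < min_cpg or n_b < min_cpg:
            continue
        levels_a = [
            region_level(m, ma.chrom, prom_a[0], prom_a[1], og, "promoter").level for m in msets_a
        ]
        levels_b = [
            region_level(m, mb.chrom, prom_b[0], prom_b[1], og, "promoter").level for m in msets_b
        ]
        if any(np.isnan(levels_a)) or any(np.isnan(levels_b)):
            continue
        dmg = call_promoter_dmgs(
            levels_a, levels_b, gene_id=og, n_qualifying_cpg=min(n_a, n_b)
        )
        if dmg is not None:
            out.append(dmg)
    return out


def run_pipeline(dataset: SyntheticDataset, min_cov: int = 10) -> PipelineResult:
    """Run the full two-comparison screen on a generated dataset."""
    cfg = dataset.config

    # --- expression ---
    assembled = assemble_ortho_matrix(dataset.count_tables, dataset.ortho_map)
    expr = filter_zero_genes(getmm(assembled))
    rna_ids = {sp: [s.sample_id for s in t.samples] for sp, t in dataset.count_tables.items()}

    # --- methylation ---
    filtered = {
        sp: [coverage_filter(m, min_cov) for m in msets]
        for sp, msets in dataset.methylomes.items()
    }
    chainsets = {sp: ChainSet(chains) for sp, chains in dataset.chains.items()}
    joint = build_joint_matrix(
        filtered[REFERENCE],
        {sp: (filtered[sp], chainsets[sp]) for sp in filtered if sp != REFERENCE},
        min_cov=min_cov,
    )
    wgbs_ids = {sp: [m.sample.sample_id for m in msets] for sp, msets in filtered.items()}

    # ortho-keyed gene models per species
    models_by_species: dict[str, dict[str, GeneModel]] = {}
    for sp, models in dataset.annotations_by_species.items():
        models_by_species[sp] = dict(zip(dataset.annotation.ortho_ids, models))
    # reference annotation keyed by ortho id for gene-body assignment
    ref_models = [
        GeneModel(og, m.chrom, m.strand, m.start, m.end, list(m.exons))
        for og, m in zip(
            dataset.annotation.ortho_ids, dataset.annotations_by_species[REFERENCE]
        )
    ]

    comparisons: dict[str, ComparisonResult] = {}
    for sp_a, sp_b in COMPARISONS:
        degs = run_differential_expression(assembled, expr, rna_ids[sp_a], rna_ids[sp_b])
        prom = promoter_dmgs_for_comparison(
            filtered[sp_a],
            filtered[sp_b],
            models_by_species[sp_a],
            models_by_species[sp_b],
            dataset.annotation.ortho_ids,
        )
        dmrs = call_dmrs(joint, wgbs_ids[sp_a], wgbs_ids[sp_b])
        gb = assign_genebody_dmgs(dmrs, ref_models)
        negcorr = negative_correlation_genes(prom, degs)
        comparisons[comparison_key(sp_a, sp_b)] = ComparisonResult(
            sp_a, sp_b, degs, prom, dmrs, gb, negcorr
        )

    keys = [comparison_key(a, b) for a, b in COMPARISONS]
    conv_expr = convergence_screen(
        comparisons[keys[0]].degs, comparisons[keys[1]].degs, mode="expression"
    )
    conv_negcorr = convergence_screen(
        comparisons[keys[0]].negcorr, comparisons[keys[1]].negcorr, mode="meth_expr"
    )
    return PipelineResult(
        expr=expr,
        joint=joint,
        comparisons=comparisons,
        convergent_expr=conv_expr,
        convergent_negcorr=conv_negcorr,
    )


def integration_records_from_results(
    result: ComparisonResult, region: str = "promoter"
) -> list[IntegrationRecord]:
    """Pair promoter DMG methylation FCs with expression FCs for integration."""
    deg_by_id = {d.ortho_id: d for d in result.degs}
    records = []
    for dmg in result.promoter_dmgs:
        deg = deg_by_id.get(dmg.gene_id)
        if deg is None or not np.isfinite(deg.log2fc):
            continue
        records.append(
            IntegrationRecord(
                gene_id=dmg.gene_id,
                region=region,
                log2_meth_fc=float(np.log2(dmg.fold_change)),
                log2_expr_fc=float(deg.log2fc),
            )
        )
    return records
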