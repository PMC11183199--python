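"""Synthetic three-species liver dataset generator with a known truth ledger.

The generator emulates the pipeline's entire input surface — gene
annotation, per-species orthologue count tables, per-sample cytosine
reports, cross-species chain files and gene-set collections — for a
bamboo-eater/carnivore design: two "panda" species (aml, afu) sharing
planted convergent expression and promoter-methylation shifts against a
"bear" outgroup (umr), with aml and umr more closely related.

Key design points:

* Expression: counts are negative-binomial around depth x relative
  expression x gene length; convergent genes shift both panda means by
  the configured log2 fold change in the same direction versus the
  bear, lineage genes shift a single species.
* Methylation: CpG sites are placed by element-dependent density;
  baselines follow the element (promoter low, gene body high); every
  site carries a species deviation on the logit scale drawn from a
  correlated trivariate normal in which the aml and umr deviations are
  more correlated than either is with afu.  This makes expression
  cluster by diet and methylation cluster by phylogeny.
* Planted promoter and gene-body differentials move the affected
  species' site-level probability by a fixed delta (default 0.3).
* Chains are identity-with-indels; indels fall only in intergenic
  spacers, so every genic or promoter position maps, and the full
  mapping is recorded in the truth ledger.

Sample rosters default to 4/4/2 RNA libraries and 5/4/3 WGBS libraries
for aml/afu/umr.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    Chain,
    CountTable,
    GeneModel,
    GeneSetCollection,
    SampleMeta,
    ValidationError,
    write_chain,
    write_counts,
    write_cytosine_report,
    write_gmt,
    write_gtf,
)
from .expression import OrthoMap
from .methylome import MethylomeSet, promoter_interval

__all__ = [
    "GeneratorConfig",
    "TruthLedger",
    "AnnotationSet",
    "SyntheticDataset",
    "gen_annotation",
    "gen_counts",
    "gen_methylomes",
    "gen_gene_sets",
    "gen_integration_records",
    "simulate",
]

SPECIES = ("aml", "afu", "umr")
REFERENCE = "aml"
COMPARISONS = (("aml", "umr"), ("afu", "umr"))


@dataclass
class GeneratorConfig:
    """All knobs of the generator; the defaults are the study conditions."""

    seed: int
    n_genes: int = 200
    n_chroms: int = 2
    chrom_size: int = 5_000_000
    gene_length_range: tuple[int, int] = (2000, 6000)
    exon_count_range: tuple[int, int] = (2, 5)
    intergenic_gap_range: tuple[int, int] = (4000, 12_000)
    # RNA roster (libraries per species) and per-species sequencing depth;
    # the bear is sequenced roughly three times deeper, as in the real
    # library rosters, which is what GeTMM has to correct.
    rna_samples: dict[str, int] = field(default_factory=lambda: {"aml": 4, "afu": 4, "umr": 2})
    rna_depth: dict[str, float] = field(
        default_factory=lambda: {"aml": 4e5, "afu": 4e5, "umr": 1.2e6}
    )
    nb_dispersion: float = 0.1
    de_log2fc: float = 2.0
    n_convergent_up: int = 15
    n_convergent_down: int = 15
    n_lineage_per_species: int = 10
    # WGBS roster and coverage
    wgbs_samples: dict[str, int] = field(default_factory=lambda: {"aml": 5, "afu": 4, "umr": 3})
    coverage_mean: float = 30.0
    # CpG placement (mean spacing in bp) and baseline levels per element
    cpg_spacing_promoter: int = 60
    cpg_spacing_genic: int = 110
    cpg_spacing_intergenic: int = 150
    chh_spacing: int = 500
    meth_promoter: float = 0.2
    meth_gene_body: float = 0.75
    meth_intergenic: float = 0.7
    meth_chh: float = 0.02
    # lineage structure on logit(pi): per-site species deviations with
    # corr(aml, umr) > corr(panda, panda) -- phylogeny, not diet
    lineage_sd: float = 0.4
    lineage_corr_aml_umr: float = 0.8
    lineage_corr_other: float = 0.3
    sample_sd: float = 0.1
    # planted methylation differentials
    dmr_delta: float = 0.3
    promoter_low: float = 0.2
    n_negcorr_per_direction: int = 10
    n_promoter_specific: int = 5
    n_genebody_dmr_per_direction: int = 10
    genebody_dmr_width: int = 500
    genebody_dmr_cpgs: int = 7
    genebody_low: float = 0.5
    # chains
    n_indels_per_chrom: int = 15
    indel_size_range: tuple[int, int] = (50, 500)
    # gene sets
    n_decoy_sets: int = 10
    decoy_set_size: int = 30
    enriched_set_size: int = 40

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValidationError("a seed is mandatory")
        for rate in (
            self.meth_promoter,
            self.meth_gene_body,
            self.meth_intergenic,
            self.meth_chh,
        ):
            if not 0 < rate < 1:
                raise ValidationError("baseline methylation levels must lie in (0, 1)")

    @property
    def promoter_high(self) -> float:
        return self.promoter_low + self.dmr_delta

    @property
    def genebody_high(self) -> float:
        return self.genebody_low + self.dmr_delta


@dataclass
class AnnotationSet:
    """Reference-species annotation plus per-gene placement bookkeeping."""

    models: list[GeneModel]
    chrom_sizes: dict[str, int]
    ortho_ids: list[str]  # parallel to models


@dataclass
class TruthLedger:
    """Everything the generator planted, keyed the way the pipeline reports."""

    config: dict
    planted_degs: dict[str, dict[str, str]] = field(default_factory=dict)
    convergent_expr: dict[str, str] = field(default_factory=dict)
    planted_promoter_dmgs: dict[str, dict[str, str]] = field(default_factory=dict)
    planted_genebody_dmgs: dict[str, dict[str, str]] = field(default_factory=dict)
    genebody_dmr_intervals: dict[str, list] = field(default_factory=dict)
    negcorr: dict[str, dict[str, list[str]]] = field(default_factory=dict)
    convergent_negcorr: dict[str, list[str]] = field(default_factory=dict)
    chain_blocks: dict[str, dict[str, list]] = field(default_factory=dict)
    enriched_set_name: str = ""

    def map_position(self, species: str, chrom: str, pos: int) -> int | None:
        """Reference position -> species position by ledger arithmetic.

        Built directly from the indel plan (independent of the chain
        parser/walker).  Returns None when the position was deleted.
        """
        blocks = self.chain_blocks[species][chrom]
        for t_start, q_start, size in blocks:
            if t_start <= pos - 1 < t_start + size:
                return q_start + (pos - 1 - t_start) + 1
        return None

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, default=str))


def comparison_key(species_a: str, species_b: str) -> str:
    return f"{species_a}_vs_{species_b}"


# ---------------------------------------------------------------------------
# annotation


def gen_annotation(cfg: GeneratorConfig, rng: np.random.Generator | None = None) -> AnnotationSet:
    """Place non-overlapping genes with wide intergenic spacers.

    Spacing guarantees that promoters and 2-kb metagene flanks of
    neighbouring genes never overlap another gene's span.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    chrom_sizes = {f"chr{i + 1}": cfg.chrom_size for i in range(cfg.n_chroms)}
    models: list[GeneModel] = []
    ortho_ids: list[str] = []
    if cfg.n_genes == 0:
        return AnnotationSet([], chrom_sizes, [])
    per_chrom = int(np.ceil(cfg.n_genes / cfg.n_chroms))
    gene_no = 0
    for chrom in chrom_sizes:
        cursor = 5000
        for _ in range(per_chrom):
            if gene_no >= cfg.n_genes:
                break
            gap = int(rng.integers(*cfg.intergenic_gap_range))
            length = int(rng.integers(*cfg.gene_length_range))
            start = cursor + gap
            end = start + length - 1
            if end + 5000 > cfg.chrom_size:
                raise ValidationError(
                    f"genes do not fit on {chrom}; increase chrom_size or reduce n_genes"
                )
            strand = "+" if rng.random() < 0.5 else "-"
            n_exons = int(rng.integers(cfg.exon_count_range[0], cfg.exon_count_range[1] + 1))
            # alternate exon/intron pieces; first and last pieces are exons,
            # so the exon chain is flush with the gene span
            n_cuts = 2 * (n_exons - 1)
            candidates = np.arange(start + 100, end - 100, 50)
            if n_cuts > 0 and candidates.size >= n_cuts:
                cuts = np.sort(rng.choice(candidates, size=n_cuts, replace=False))
            else:
                cuts = np.array([], dtype=int)
            bounds = [start] + [int(c) for c in cuts] + [end + 1]
            exons = [
                (bounds[i], bounds[i + 1] - 1)
                for i in range(len(bounds) - 1)
                if i % 2 == 0
            ]
            gene_no += 1
            gid = f"g{gene_no:04d}"
            models.append(GeneModel(gid, chrom, strand, start, end, exons))
            ortho_ids.append(f"OG{gene_no:04d}")
            cursor = end
    if gene_no < cfg.n_genes:
        raise ValidationError("could not place all genes; increase chrom_size")
    return AnnotationSet(models, chrom_sizes, ortho_ids)


# ---------------------------------------------------------------------------
# planted-effect bookkeeping


@dataclass
class _Plan:
    """Internal per-gene planting assignments (indices into the gene list)."""

    conv_up: np.ndarray
    conv_down: np.ndarray
    lineage: dict[str, np.ndarray]
    negcorr_hypo_high: np.ndarray  # subset of conv_up
    negcorr_hyper_low: np.ndarray  # subset of conv_down
    promoter_specific: dict[str, dict[str, np.ndarray]]  # species -> direction -> idx
    genebody_hyper: np.ndarray
    genebody_hypo: np.ndarray


def _make_plan(cfg: GeneratorConfig, n_genes: int, rng: np.random.Generator) -> _Plan:
    need = (
        cfg.n_convergent_up
        + cfg.n_convergent_down
        + 2 * cfg.n_lineage_per_species
        + 2 * cfg.n_promoter_specific
        + 2 * cfg.n_genebody_dmr_per_direction
    )
    if need > n_genes:
        raise ValidationError(f"not enough genes ({n_genes}) for the planting plan ({need})")
    order = rng.permutation(n_genes)
    take = iter(order)

    def grab(k: int) -> np.ndarray:
        return np.array([next(take) for _ in range(k)], dtype=int)

    conv_up = grab(cfg.n_convergent_up)
    conv_down = grab(cfg.n_convergent_down)
    lineage = {"aml": grab(cfg.n_lineage_per_species), "afu": grab(cfg.n_lineage_per_species)}
    promoter_specific = {}
    for sp in ("aml", "afu"):
        idx = grab(cfg.n_promoter_specific)
        half = len(idx) // 2
        promoter_specific[sp] = {"hyper": idx[:half], "hypo": idx[half:]}
    genebody_hyper = grab(cfg.n_genebody_dmr_per_direction)
    genebody_hypo = grab(cfg.n_genebody_dmr_per_direction)
    return _Plan(
        conv_up=conv_up,
        conv_down=conv_down,
        lineage=lineage,
        negcorr_hypo_high=conv_up[: cfg.n_negcorr_per_direction],
        negcorr_hyper_low=conv_down[: cfg.n_negcorr_per_direction],
        promoter_specific=promoter_specific,
        genebody_hyper=genebody_hyper,
        genebody_hypo=genebody_hypo,
    )


# ---------------------------------------------------------------------------
# expression


def gen_counts(
    cfg: GeneratorConfig,
    annotation: AnnotationSet,
    plan: _Plan,
    truth: TruthLedger,
    rng: np.random.Generator,
) -> tuple[dict[str, CountTable], OrthoMap]:
    """Per-species NB count tables plus the 1:1:1 orthologue map."""
    n = len(annotation.models)
    lengths = np.array(
        [sum(e - s + 1 for s, e in m.exons) or m.length for m in annotation.models], dtype=float
    )
    base = rng.lognormal(mean=0.0, sigma=1.0, size=n)
    rate = base * lengths / 1000.0
    rate = rate / rate.sum()

    log2fc = {sp: np.zeros(n) for sp in SPECIES}
    for sp in ("aml", "afu"):
        log2fc[sp][plan.conv_up] += cfg.de_log2fc
        log2fc[sp][plan.conv_down] -= cfg.de_log2fc
    for sp, idx in plan.lineage.items():
        half = len(idx) // 2
        log2fc[sp][idx[:half]] += cfg.de_log2fc
        log2fc[sp][idx[half:]] -= cfg.de_log2fc

    for sp_a, sp_b in COMPARISONS:
        key = comparison_key(sp_a, sp_b)
        planted: dict[str, str] = {}
        delta = log2fc[sp_a] - log2fc[sp_b]
        for i in np.where(delta != 0)[0]:
            planted[annotation.ortho_ids[i]] = "up" if delta[i] > 0 else "down"
        truth.planted_degs[key] = planted
    for i in plan.conv_up:
        truth.convergent_expr[annotation.ortho_ids[i]] = "up"
    for i in plan.conv_down:
        truth.convergent_expr[annotation.ortho_ids[i]] = "down"

    tables: dict[str, CountTable] = {}
    ortho_records: dict[str, dict[str, str]] = {
        og: {sp: f"{sp}_{m.gene_id}" for sp in SPECIES}
        for og, m in zip(annotation.ortho_ids, annotation.models)
    }
    phi = cfg.nb_dispersion
    for sp in SPECIES:
        mean = cfg.rna_depth[sp] * rate * (2.0 ** log2fc[sp])
        n_samples = cfg.rna_samples[sp]
        counts = np.empty((n, n_samples), dtype=np.int64)
        for j in range(n_samples):
            if phi > 0:
                r = 1.0 / phi
                p = r / (r + mean)
                counts[:, j] = rng.negative_binomial(r, p)
            else:
                counts[:, j] = rng.poisson(mean)
        samples = [SampleMeta(f"{sp}_rna{j + 1}", sp, sp) for j in range(n_samples)]
        tables[sp] = CountTable(
            gene_ids=[f"{sp}_{m.gene_id}" for m in annotation.models],
            lengths_bp=lengths.astype(np.int64),
            counts=counts,
            samples=samples,
        )
    ortho = OrthoMap(pd.DataFrame.from_dict(ortho_records, orient="index"))
    return tables, ortho


# ---------------------------------------------------------------------------
# methylomes + chains


def _logit(p: np.ndarray) -> np.ndarray:
    return np.log(p / (1 - p))


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _site_table(
    cfg: GeneratorConfig,
    annotation: AnnotationSet,
    plan: _Plan,
    truth: TruthLedger,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Reference CpG/CHH site table with per-species baseline pi columns."""

    def jittered_positions(start: int, end: int, spacing: int) -> np.ndarray:
        if end < start:
            return np.array([], dtype=np.int64)
        n_max = max(1, int((end - start + 1) / spacing * 2))
        steps = rng.uniform(0.6, 1.4, size=n_max + 4) * spacing
        pos = start + np.cumsum(steps).astype(np.int64)
        return pos[pos <= end]

    gene_for_index = {i: m for i, m in enumerate(annotation.models)}
    rows = {"chrom": [], "pos": [], "context": [], "kind": []}
    pis = {sp: [] for sp in SPECIES}

    def add_sites(chrom, positions, kind, context, pi_by_species):
        k = len(positions)
        if k == 0:
            return
        rows["chrom"].extend([chrom] * k)
        rows["pos"].extend(positions.tolist())
        rows["context"].extend([context] * k)
        rows["kind"].extend([kind] * k)
        for sp in SPECIES:
            pis[sp].extend([pi_by_species[sp]] * k)

    # per-gene promoter pi by species, from the planting plan
    promoter_pi = {
        i: {sp: cfg.promoter_low for sp in SPECIES} for i in range(len(annotation.models))
    }
    for i in plan.negcorr_hypo_high:  # pandas hypo, bear high
        promoter_pi[i] = {"aml": cfg.promoter_low, "afu": cfg.promoter_low, "umr": cfg.promoter_high}
    for i in plan.negcorr_hyper_low:  # pandas hyper
        promoter_pi[i] = {"aml": cfg.promoter_high, "afu": cfg.promoter_high, "umr": cfg.promoter_low}
    for sp in ("aml", "afu"):
        other_panda = "afu" if sp == "aml" else "aml"
        for i in plan.promoter_specific[sp]["hyper"]:
            promoter_pi[i] = {sp: cfg.promoter_high, other_panda: cfg.promoter_low, "umr": cfg.promoter_low}
        for i in plan.promoter_specific[sp]["hypo"]:
            # the untested panda follows the bear so its comparison stays null
            promoter_pi[i] = {sp: cfg.promoter_low, other_panda: cfg.promoter_high, "umr": cfg.promoter_high}

    # planted gene-body DMR windows
    genebody_windows: dict[int, tuple[int, int, str]] = {}
    for i in plan.genebody_hyper:
        genebody_windows[int(i)] = ("hyper",)
    for i in plan.genebody_hypo:
        genebody_windows[int(i)] = ("hypo",)

    for sp_a, sp_b in COMPARISONS:
        key = comparison_key(sp_a, sp_b)
        truth.planted_promoter_dmgs.setdefault(key, {})
        truth.planted_genebody_dmgs.setdefault(key, {})
        truth.genebody_dmr_intervals.setdefault(key, [])
        truth.negcorr.setdefault(key, {"hypo_high": [], "hyper_low": []})

    for i, model in gene_for_index.items():
        og = annotation.ortho_ids[i]
        # promoter
        prom = promoter_interval(model)
        if prom is not None:
            positions = jittered_positions(prom[0], prom[1], cfg.cpg_spacing_promoter)
            add_sites(model.chrom, positions, "promoter", "CpG", promoter_pi[i])
        for sp_a, sp_b in COMPARISONS:
            pa, pb = promoter_pi[i][sp_a], promoter_pi[i][sp_b]
            key = comparison_key(sp_a, sp_b)
            if pa > pb:
                truth.planted_promoter_dmgs[key][og] = "hyper"
            elif pa < pb:
                truth.planted_promoter_dmgs[key][og] = "hypo"

        # gene body, possibly with one planted DMR window
        body_pi = {sp: cfg.meth_gene_body for sp in SPECIES}
        if i in genebody_windows:
            direction = genebody_windows[i][0]
            margin = 100
            lo = model.start + margin
            hi = max(lo, model.end - margin - cfg.genebody_dmr_width)
            w_start = int(rng.integers(lo, hi + 1))
            w_end = w_start + cfg.genebody_dmr_width - 1
            if direction == "hyper":
                win_pi = {"aml": cfg.genebody_high, "afu": cfg.genebody_high, "umr": cfg.genebody_low}
            else:
                win_pi = {"aml": cfg.genebody_low, "afu": cfg.genebody_low, "umr": cfg.genebody_high}
            win_pos = np.linspace(w_start, w_end, cfg.genebody_dmr_cpgs).astype(np.int64)
            add_sites(model.chrom, win_pos, "genebody_dmr", "CpG", win_pi)
            for pre_start, pre_end in ((model.start, w_start - 1), (w_end + 1, model.end)):
                positions = jittered_positions(pre_start, pre_end, cfg.cpg_spacing_genic)
                add_sites(model.chrom, positions, "gene_body", "CpG", body_pi)
            for sp_a, sp_b in COMPARISONS:
                key = comparison_key(sp_a, sp_b)
                truth.planted_genebody_dmgs[key][og] = direction
                truth.genebody_dmr_intervals[key].append(
                    {"gene": og, "chrom": model.chrom, "start": int(w_start), "end": int(w_end), "direction": direction}
                )
        else:
            positions = jittered_positions(model.start, model.end, cfg.cpg_spacing_genic)
            add_sites(model.chrom, positions, "gene_body", "CpG", body_pi)

    # negcorr truth (per comparison and convergent)
    for sp_a, sp_b in COMPARISONS:
        key = comparison_key(sp_a, sp_b)
        truth.negcorr[key]["hypo_high"] = sorted(
            annotation.ortho_ids[i] for i in plan.negcorr_hypo_high
        )
        truth.negcorr[key]["hyper_low"] = sorted(
            annotation.ortho_ids[i] for i in plan.negcorr_hyper_low
        )
    truth.convergent_negcorr = {
        "hypo_high": sorted(annotation.ortho_ids[i] for i in plan.negcorr_hypo_high),
        "hyper_low": sorted(annotation.ortho_ids[i] for i in plan.negcorr_hyper_low),
    }

    # intergenic CpGs and CHH background, avoiding gene+flank neighbourhoods
    inter_pi = {sp: cfg.meth_intergenic for sp in SPECIES}
    chh_pi = {sp: cfg.meth_chh for sp in SPECIES}
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in annotation.chrom_sizes}
    for m in annotation.models:
        occupied[m.chrom].append((m.start - 3000, m.end + 3000))
    for chrom, size in annotation.chrom_sizes.items():
        iv = sorted(occupied[chrom])
        cursor = 1
        gaps = []
        for s, e in iv:
            if s > cursor:
                gaps.append((cursor, s - 1))
            cursor = max(cursor, e + 1)
        if cursor <= size:
            gaps.append((cursor, size))
        for s, e in gaps:
            add_sites(chrom, jittered_positions(s, e, cfg.cpg_spacing_intergenic), "intergenic", "CpG", inter_pi)
        if cfg.chh_spacing:
            add_sites(chrom, jittered_positions(1, size, cfg.chh_spacing), "chh", "CHH", chh_pi)

    df = pd.DataFrame(rows)
    for sp in SPECIES:
        df[f"pi_{sp}"] = np.clip(np.asarray(pis[sp], dtype=float), 1e-3, 1 - 1e-3)
    df = df.sort_values(["chrom", "pos"], kind="mergesort")
    df = df.drop_duplicates(subset=["chrom", "pos"]).reset_index(drop=True)
    return df


def _make_chains(
    cfg: GeneratorConfig,
    annotation: AnnotationSet,
    truth: TruthLedger,
    rng: np.random.Generator,
) -> dict[str, list[Chain]]:
    """Identity-with-indels chains from the reference to each other species."""
    chains: dict[str, list[Chain]] = {}
    for sp in SPECIES:
        if sp == REFERENCE:
            continue
        chains[sp] = []
        truth.chain_blocks[sp] = {}
        for chrom, size in annotation.chrom_sizes.items():
            # candidate indel spots: intergenic midpoints, away from genes
            genes = sorted(
                (m.start, m.end) for m in annotation.models if m.chrom == chrom
            )
            spots = []
            cursor = 1
            for s, e in genes:
                if s - 3500 > cursor + 3500:
                    spots.append((cursor + 3500, s - 3500))
                cursor = e
            if cursor + 3500 < size - 1000:
                spots.append((cursor + 3500, size - 1000))
            chosen = []
            for _ in range(cfg.n_indels_per_chrom):
                lo, hi = spots[int(rng.integers(len(spots)))]
                if hi > lo:
                    chosen.append(int(rng.integers(lo, hi)))
            chosen = sorted(set(chosen))
            blocks: list[tuple[int, int, int]] = []
            truth_blocks: list[tuple[int, int, int]] = []
            t_cursor = 0
            q_cursor = 0
            for spot in chosen:
                block_size = spot - t_cursor
                if block_size <= 0:
                    continue
                indel = int(rng.integers(*cfg.indel_size_range))
                if rng.random() < 0.5:
                    dt, dq = indel, 0  # deletion in the query species
                else:
                    dt, dq = 0, indel  # insertion in the query species
                blocks.append((block_size, dt, dq))
                truth_blocks.append((t_cursor, q_cursor, block_size))
                t_cursor += block_size + dt
                q_cursor += block_size + dq
            final = size - t_cursor
            blocks.append((final, 0, 0))
            truth_blocks.append((t_cursor, q_cursor, final))
            q_size = q_cursor + final
            chain = Chain(
                score=1000.0,
                t_name=chrom,
                t_size=size,
                t_strand="+",
                t_start=0,
                t_end=size,
                q_name=chrom,
                q_size=q_size,
                q_strand="+",
                q_start=0,
                q_end=q_size,
                blocks=blocks,
                chain_id=f"{REFERENCE}_{sp}_{chrom}",
            )
            chain.validate()
            chains[sp].append(chain)
            truth.chain_blocks[sp][chrom] = [list(b) for b in truth_blocks]
    return chains


def _lift_with_truth(truth: TruthLedger, species: str, chrom: str, pos: np.ndarray):
    """Vectorised ledger-arithmetic lift of 1-based positions."""
    blocks = np.array(truth.chain_blocks[species][chrom], dtype=np.int64)
    t_starts, q_starts, sizes = blocks[:, 0], blocks[:, 1], blocks[:, 2]
    pos0 = np.asarray(pos, dtype=np.int64) - 1
    i = np.searchsorted(t_starts, pos0, side="right") - 1
    i = np.clip(i, 0, len(t_starts) - 1)
    offset = pos0 - t_starts[i]
    ok = (offset >= 0) & (offset < sizes[i])
    mapped = np.where(ok, q_starts[i] + offset + 1, 0)
    return mapped, ok


def gen_methylomes(
    cfg: GeneratorConfig,
    annotation: AnnotationSet,
    plan: _Plan,
    truth: TruthLedger,
    rng: np.random.Generator,
) -> tuple[dict[str, list[MethylomeSet]], dict[str, list[Chain]], dict[str, list[GeneModel]], dict[str, dict[str, int]]]:
    """Per-sample cytosine tables, chains, and per-species annotations.

    Returns (methylomes by species, chains by species, gene models by
    species in that species' coordinates, chrom sizes by species).
    """
    sites = _site_table(cfg, annotation, plan, truth, rng)
    chains = _make_chains(cfg, annotation, truth, rng)

    n_sites = len(sites)
    # correlated species deviations on the logit scale
    r_au = cfg.lineage_corr_aml_umr
    r_o = cfg.lineage_corr_other
    corr = np.array([[1, r_o, r_au], [r_o, 1, r_o], [r_au, r_o, 1]])  # aml, afu, umr
    cov = (cfg.lineage_sd**2) * corr
    if cfg.lineage_sd > 0:
        chol = np.linalg.cholesky(cov)
        dev = rng.standard_normal((n_sites, 3)) @ chol.T
    else:
        dev = np.zeros((n_sites, 3))
    dev_by_species = {"aml": dev[:, 0], "afu": dev[:, 1], "umr": dev[:, 2]}

    # per-species site coordinates (reference sites lifted through the ledger)
    coords: dict[str, dict[str, np.ndarray]] = {}
    masks: dict[str, np.ndarray] = {}
    for sp in SPECIES:
        if sp == REFERENCE:
            coords[sp] = {"pos": sites["pos"].to_numpy()}
            masks[sp] = np.ones(n_sites, dtype=bool)
            continue
        mapped = np.zeros(n_sites, dtype=np.int64)
        ok = np.zeros(n_sites, dtype=bool)
        for chrom in annotation.chrom_sizes:
            sel = (sites["chrom"] == chrom).to_numpy()
            m, o = _lift_with_truth(truth, sp, chrom, sites["pos"].to_numpy()[sel])
            mapped[sel] = m
            ok[sel] = o
        coords[sp] = {"pos": mapped}
        masks[sp] = ok

    methylomes: dict[str, list[MethylomeSet]] = {}
    for sp in SPECIES:
        base_logit = _logit(sites[f"pi_{sp}"].to_numpy()) + dev_by_species[sp]
        keep = masks[sp]
        methylomes[sp] = []
        for j in range(cfg.wgbs_samples[sp]):
            noise = rng.standard_normal(n_sites) * cfg.sample_sd
            pi = _expit(base_logit + noise)
            coverage = rng.poisson(cfg.coverage_mean, size=n_sites)
            n_meth = rng.binomial(coverage, pi)
            df = pd.DataFrame(
                {
                    "chrom": sites["chrom"].to_numpy()[keep],
                    "pos": coords[sp]["pos"][keep],
                    "strand": "+",
                    "n_meth": n_meth[keep],
                    "n_unmeth": (coverage - n_meth)[keep],
                    "context": sites["context"].to_numpy()[keep],
                }
            )
            meta = SampleMeta(f"{sp}_wgbs{j + 1}", sp, sp)
            methylomes[sp].append(MethylomeSet(df, meta))

    # per-species annotation in that species' coordinates
    annotations: dict[str, list[GeneModel]] = {}
    chrom_sizes: dict[str, dict[str, int]] = {}
    for sp in SPECIES:
        if sp == REFERENCE:
            annotations[sp] = [
                GeneModel(f"{sp}_{m.gene_id}", m.chrom, m.strand, m.start, m.end, list(m.exons))
                for m in annotation.models
            ]
            chrom_sizes[sp] = dict(annotation.chrom_sizes)
            continue
        shifted = []
        for m in annotation.models:
            s, ok_s = _lift_with_truth(truth, sp, m.chrom, np.array([m.start]))
            e, ok_e = _lift_with_truth(truth, sp, m.chrom, np.array([m.end]))
            if not (ok_s[0] and ok_e[0]):
                raise ValidationError("internal: genic position fell in an indel")
            delta = int(s[0]) - m.start
            shifted.append(
                GeneModel(
                    f"{sp}_{m.gene_id}",
                    m.chrom,
                    m.strand,
                    int(s[0]),
                    int(e[0]),
                    [(a + delta, b + delta) for a, b in m.exons],
                )
            )
        annotations[sp] = shifted
        chrom_sizes[sp] = {c.t_name: c.q_size for c in chains[sp]}
    return methylomes, chains, annotations, chrom_sizes


# ---------------------------------------------------------------------------
# gene sets


def gen_gene_sets(
    truth: TruthLedger,
    cfg: GeneratorConfig,
    universe: Sequence[str],
    rng: np.random.Generator,
    planted_fraction: float = 0.5,
) -> GeneSetCollection:
    """One set enriched for planted convergent genes plus random decoys."""
    universe = list(universe)
    planted = sorted(truth.convergent_expr)
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    if planted:
        n_planted = min(len(planted), int(round(cfg.enriched_set_size * planted_fraction)))
        members = list(rng.choice(planted, size=n_planted, replace=False))
        background = [g for g in universe if g not in set(members)]
        fill = cfg.enriched_set_size - len(members)
        members += list(rng.choice(background, size=min(fill, len(background)), replace=False))
        sets["bamboo_response"] = set(members)
        descriptions["bamboo_response"] = "enriched for planted convergent genes"
        truth.enriched_set_name = "bamboo_response"
    for i in range(cfg.n_decoy_sets):
        name = f"decoy_{i + 1:02d}"
        sets[name] = set(rng.choice(universe, size=cfg.decoy_set_size, replace=False))
        descriptions[name] = "random decoy set"
    return GeneSetCollection(sets, descriptions)


def gen_integration_records(
    rho: float,
    n: int,
    rng: np.random.Generator,
    region: str = "promoter",
):
    """Integration records with a planted population Spearman correlation.

    Uses a Gaussian copula (Pearson r = 2 sin(pi * rho / 6)) pushed
    through monotone maps onto fold changes that pass the integration
    filters (|log2 meth FC| > 1, |log2 expr FC| > 0.5).
    """
    from .integration import IntegrationRecord

    r_pearson = 2 * np.sin(np.pi * rho / 6)
    cov = np.array([[1.0, r_pearson], [r_pearson, 1.0]])
    z = rng.multivariate_normal([0, 0], cov, size=n)
    meth = np.where(z[:, 0] >= 0, 1.05 + z[:, 0], -1.05 + z[:, 0])
    expr = np.where(z[:, 1] >= 0, 0.55 + z[:, 1], -0.55 + z[:, 1])
    return [
        IntegrationRecord(f"g{i:04d}", region, float(meth[i]), float(expr[i])) for i in range(n)
    ]


# ---------------------------------------------------------------------------
# orchestration


@dataclass
class SyntheticDataset:
    config: GeneratorConfig
    truth: TruthLedger
    annotation: AnnotationSet
    count_tables: dict[str, CountTable]
    ortho_map: OrthoMap
    methylomes: dict[str, list[MethylomeSet]]
    chains: dict[str, list[Chain]]
    annotations_by_species: dict[str, list[GeneModel]]
    chrom_sizes_by_species: dict[str, dict[str, int]]
    gene_sets: GeneSetCollection

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for sp, table in self.count_tables.items():
            write_counts(table, out / f"counts_{sp}.tsv")
        self.ortho_map.write_tsv(out / "ortho_map.tsv")
        for sp, models in self.annotations_by_species.items():
            write_gtf(models, out / f"genes_{sp}.gtf")
        for sp, msets in self.methylomes.items():
            for m in msets:
                write_cytosine_report(m.records(), out / f"cx_{m.sample.sample_id}.txt")
        for sp, chains in self.chains.items():
            write_chain(chains, out / f"{REFERENCE}_to_{sp}.chain")
        write_gmt(self.gene_sets, out / "gene_sets.gmt")
        self.truth.to_json(out / "truth.json")


def simulate(cfg: GeneratorConfig) -> SyntheticDataset:
    """Run the full generator under one seed; fully deterministic."""
    rng = np.random.default_rng(cfg.seed)
    truth = TruthLedger(config=asdict(cfg))
    annotation = gen_annotation(cfg, rng)
    plan = _make_plan(cfg, len(annotation.models), rng)
    tables, ortho = gen_counts(cfg, annotation, plan, truth, rng)
    methylomes, chains, annotations, sizes = gen_methylomes(cfg, annotation, plan, truth, rng)
    gene_sets = gen_gene_sets(truth, cfg, annotation.ortho_ids, rng)
    return SyntheticDataset(
        config=cfg,
        truth=truth,
        annotation=annotation,
        count_tables=tables,
        ortho_map=ortho,
        methylomes=methylomes,
        chains=chains,
        annotations_by_species=annotations,
        chrom_sizes_by_species=sizes,
        gene_sets=gene_sets,
    )
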