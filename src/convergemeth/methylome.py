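"""Methylation quantification: sites, 10-kb bins, gene elements, metagene profiles.

All levels are pooled-count ratios, level = sum(mC) / sum(mC + C), never
means of per-site ratios, so deeply covered sites weigh more — the
pooled level equals the coverage-weighted mean of site levels.  Sites
below the coverage floor (10x by default) are removed before any
quantification.

Plus- and minus-strand cytosines are kept as distinct sites (the
Bismark convention); an optional symmetric-CpG merge that sums the
counts of a pos/pos+1 strand pair is available but off by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_formats import CytosineRecord, GeneModel, SampleMeta, ValidationError

__all__ = [
    "MethylomeSet",
    "GenomicBin",
    "RegionLevel",
    "MetageneProfile",
    "coverage_filter",
    "site_level",
    "bin_levels",
    "region_level",
    "promoter_interval",
    "metagene_profile",
    "merge_symmetric_cpgs",
]


class MethylomeSet:
    """Per-sample collection of cytosine records, keyed by (chrom, pos, strand).

    Internally backed by a sorted DataFrame for vectorised range queries;
    records round-trip losslessly.
    """

    _COLS = ["chrom", "pos", "strand", "n_meth", "n_unmeth", "context"]

    def __init__(self, records: Iterable[CytosineRecord] | pd.DataFrame, sample: SampleMeta):
        if isinstance(records, pd.DataFrame):
            df = records[self._COLS].copy()
        else:
            df = pd.DataFrame(
                [(r.chrom, r.pos, r.strand, r.n_meth, r.n_unmeth, r.context) for r in records],
                columns=self._COLS,
            )
        if len(df):
            df = df.sort_values(["chrom", "pos", "strand"], kind="mergesort").reset_index(drop=True)
            dup = df.duplicated(subset=["chrom", "pos", "strand"])
            if dup.any():
                row = df[dup].iloc[0]
                raise ValidationError(
                    f"duplicate cytosine record at {row.chrom}:{row.pos}{row.strand}"
                )
        self.df = df
        self.sample = sample

    def __len__(self) -> int:
        return len(self.df)

    def records(self) -> list[CytosineRecord]:
        return [
            CytosineRecord(r.chrom, int(r.pos), r.strand, int(r.n_meth), int(r.n_unmeth), r.context)
            for r in self.df.itertuples(index=False)
        ]

    @property
    def coverage(self) -> np.ndarray:
        return (self.df["n_meth"] + self.df["n_unmeth"]).to_numpy()

    def subset(self, mask: np.ndarray) -> "MethylomeSet":
        return MethylomeSet(self.df[mask].reset_index(drop=True), self.sample)

    def context_subset(self, context: str) -> "MethylomeSet":
        if context in (None, "all"):
            return self
        return self.subset((self.df["context"] == context).to_numpy())

    def chrom_arrays(self, chrom: str, context: str | None = "CpG"):
        """(pos, n_meth, n_unmeth) sorted arrays for one chromosome."""
        df = self.df
        mask = df["chrom"].to_numpy() == chrom
        if context not in (None, "all"):
            mask &= df["context"].to_numpy() == context
        sub = df[mask]
        return (
            sub["pos"].to_numpy(),
            sub["n_meth"].to_numpy(dtype=float),
            sub["n_unmeth"].to_numpy(dtype=float),
        )

    def chroms(self) -> list[str]:
        return sorted(self.df["chrom"].unique())


@dataclass
class GenomicBin:
    chrom: str
    start: int  # 1-based inclusive
    end: int
    level: float  # NaN when no covered site falls in the bin
    n_sites: int
    total_coverage: int


@dataclass
class RegionLevel:
    region_kind: str  # promoter | gene_body | exon | intron
    gene_id: str
    level: float  # NaN when no covered CpG in the region
    n_cpg_covered: int
    n_meth: int = 0
    n_total: int = 0


@dataclass
class MetageneProfile:
    """Pooled methylation levels over upstream flank, body, downstream flank bins."""

    upstream: np.ndarray
    body: np.ndarray
    downstream: np.ndarray
    sample_id: str = ""

    def all_bins(self) -> np.ndarray:
        return np.concatenate([self.upstream, self.body, self.downstream])


def coverage_filter(mset: MethylomeSet, min_cov: int = 10) -> MethylomeSet:
    """Drop sites covered by fewer than ``min_cov`` reads (10x kept, 9x removed)."""
    return mset.subset(mset.coverage >= min_cov)


def site_level(rec: CytosineRecord) -> float:
    """Per-site methylation level mC / (mC + C); NaN at zero coverage."""
    cov = rec.n_meth + rec.n_unmeth
    if cov == 0:
        return float("nan")
    return rec.n_meth / cov


def bin_levels(
    mset: MethylomeSet,
    bin_size: int = 10_000,
    context: str | None = "CpG",
    chrom_sizes: dict[str, int] | None = None,
) -> list[GenomicBin]:
    """Pooled methylation level per tiling bin, restricted to one context.

    Bins tile from position 1; the terminal partial bin is retained.
    Chromosome lengths are taken from ``chrom_sizes`` or inferred from
    the maximum observed position.
    """
    sub = mset.context_subset(context)
    out: list[GenomicBin] = []
    chroms = sorted(chrom_sizes) if chrom_sizes else sub.chroms()
    for chrom in chroms:
        pos, n_meth, n_unmeth = sub.chrom_arrays(chrom, context=None)
        size = (chrom_sizes or {}).get(chrom, int(pos.max()) if pos.size else 0)
        if size == 0:
            continue
        n_bins = (size + bin_size - 1) // bin_size
        idx = (pos - 1) // bin_size
        meth = np.bincount(idx, weights=n_meth, minlength=n_bins)
        total = meth + np.bincount(idx, weights=n_unmeth, minlength=n_bins)
        counts = np.bincount(idx, minlength=n_bins)
        with np.errstate(invalid="ignore", divide="ignore"):
            levels = np.where(total > 0, meth / np.where(total > 0, total, 1), np.nan)
        for b in range(n_bins):
            out.append(
                GenomicBin(
                    chrom=chrom,
                    start=b * bin_size + 1,
                    end=min((b + 1) * bin_size, size),
                    level=float(levels[b]),
                    n_sites=int(counts[b]),
                    total_coverage=int(total[b]),
                )
            )
    return out


def _pool_interval(
    mset: MethylomeSet, chrom: str, start: int, end: int, context: str | None
) -> tuple[int, int, int]:
    """(n_meth, n_total, n_sites) pooled over sites in [start, end]."""
    pos, n_meth, n_unmeth = mset.chrom_arrays(chrom, context)
    lo = np.searchsorted(pos, start, side="left")
    hi = np.searchsorted(pos, end, side="right")
    m = int(n_meth[lo:hi].sum())
    t = m + int(n_unmeth[lo:hi].sum())
    return m, t, hi - lo


def region_level(
    mset: MethylomeSet,
    chrom: str,
    start: int,
    end: int,
    gene_id: str = "",
    region_kind: str = "gene_body",
    context: str | None = "CpG",
) -> RegionLevel:
    """Pooled level over covered context sites within a 1-based interval."""
    if start > end:
        raise ValidationError(f"invalid interval {chrom}:{start}-{end}")
    m, t, n = _pool_interval(mset, chrom, start, end, context)
    level = m / t if t > 0 else float("nan")
    return RegionLevel(region_kind, gene_id, level, n, m, t)


def promoter_interval(
    model: GeneModel, promoter_bp: int = 1000, chrom_size: int | None = None
) -> tuple[int, int] | None:
    """The 1000 bp immediately upstream of the TSS, strand-aware, clipped at 1.

    Returns None for a plus-strand gene starting at position 1 (no
    upstream sequence exists).
    """
    if model.strand == "+":
        start = max(1, model.start - promoter_bp)
        end = model.start - 1
        if end < start:
            return None
    else:
        start = model.end + 1
        end = model.end + promoter_bp
        if chrom_size is not None:
            end = min(end, chrom_size)
            if end < start:
                return None
    return (start, end)


def gene_element_levels(
    mset: MethylomeSet,
    models: Sequence[GeneModel],
    context: str | None = "CpG",
    promoter_bp: int = 1000,
) -> list[RegionLevel]:
    """Promoter / gene body / exon / intron pooled levels for every gene."""
    out: list[RegionLevel] = []
    for m in models:
        prom = promoter_interval(m, promoter_bp)
        if prom is not None:
            out.append(region_level(mset, m.chrom, prom[0], prom[1], m.gene_id, "promoter", context))
        out.append(region_level(mset, m.chrom, m.start, m.end, m.gene_id, "gene_body", context))
        for kind, intervals in (("exon", m.exons), ("intron", m.introns())):
            tot_m = tot_t = tot_n = 0
            for s, e in intervals:
                mm, tt, nn = _pool_interval(mset, m.chrom, s, e, context)
                tot_m, tot_t, tot_n = tot_m + mm, tot_t + tt, tot_n + nn
            level = tot_m / tot_t if tot_t > 0 else float("nan")
            out.append(RegionLevel(kind, m.gene_id, level, tot_n, tot_m, tot_t))
    return out


def metagene_profile(
    mset: MethylomeSet,
    models: Sequence[GeneModel],
    n_bins: int = 20,
    flank_bp: int = 2000,
    context: str | None = "CpG",
) -> MetageneProfile:
    """Pooled metagene profile: flank/body/flank, ``n_bins`` bins each.

    The upstream flank is the 5' side of the gene (strand-aware); body
    bins are equal fractions of each gene's span; counts are pooled
    across genes within each bin before dividing.
    """
    meth = np.zeros(3 * n_bins)
    total = np.zeros(3 * n_bins)
    for m in models:
        pos_all, nm_all, nu_all = mset.chrom_arrays(m.chrom, context)
        if m.strand == "+":
            segments = [
                (m.start - flank_bp, m.start - 1, 0, False),
                (m.start, m.end, n_bins, False),
                (m.end + 1, m.end + flank_bp, 2 * n_bins, False),
            ]
        else:
            # upstream (5') is to the right of the gene; reverse bin order
            segments = [
                (m.end + 1, m.end + flank_bp, 0, True),
                (m.start, m.end, n_bins, True),
                (m.start - flank_bp, m.start - 1, 2 * n_bins, True),
            ]
        for seg_start, seg_end, offset, flip in segments:
            if seg_end < seg_start:
                continue
            lo = np.searchsorted(pos_all, max(1, seg_start), side="left")
            hi = np.searchsorted(pos_all, seg_end, side="right")
            if hi <= lo:
                continue
            pos = pos_all[lo:hi]
            width = seg_end - seg_start + 1
            rel = (pos - seg_start) / width
            idx = np.minimum((rel * n_bins).astype(int), n_bins - 1)
            if flip:
                idx = n_bins - 1 - idx
            np.add.at(meth, offset + idx, nm_all[lo:hi])
            np.add.at(total, offset + idx, nm_all[lo:hi] + nu_all[lo:hi])
    with np.errstate(invalid="ignore", divide="ignore"):
        levels = np.where(total > 0, meth / np.where(total > 0, total, 1), np.nan)
    return MetageneProfile(
        upstream=levels[:n_bins],
        body=levels[n_bins : 2 * n_bins],
        downstream=levels[2 * n_bins :],
        sample_id=mset.sample.sample_id,
    )


def merge_symmetric_cpgs(mset: MethylomeSet) -> MethylomeSet:
    """Sum counts of +/- strand CpG pairs (pos, pos+1) onto the plus strand.

    Non-CpG contexts and unpaired sites pass through unchanged.
    """
    df = mset.df
    cpg = df[df["context"] == "CpG"]
    other = df[df["context"] != "CpG"]
    plus = cpg[cpg["strand"] == "+"].set_index(["chrom", "pos"])
    minus = cpg[cpg["strand"] == "-"].copy()
    minus["pair_pos"] = minus["pos"] - 1
    minus_idx = minus.set_index(["chrom", "pair_pos"])
    paired = plus.index.intersection(minus_idx.index)
    merged_rows = []
    for chrom, pos in paired:
        p = plus.loc[(chrom, pos)]
        q = minus_idx.loc[(chrom, pos)]
        merged_rows.append(
            (chrom, pos, "+", int(p.n_meth + q.n_meth), int(p.n_unmeth + q.n_unmeth), "CpG")
        )
    unpaired_plus = plus[~plus.index.isin(paired)].reset_index()
    unpaired_minus = minus_idx[~minus_idx.index.isin(paired)].reset_index()
    frames = [
        pd.DataFrame(merged_rows, columns=MethylomeSet._COLS),
        unpaired_plus[MethylomeSet._COLS],
        unpaired_minus.drop(columns=["pair_pos"], errors="ignore")[MethylomeSet._COLS],
        other[MethylomeSet._COLS],
    ]
    combined = pd.concat([f for f in frames if len(f)], ignore_index=True)
    return MethylomeSet(combined, mset.sample)
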