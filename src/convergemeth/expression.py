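"""Cross-species orthologue expression matrix assembly and GeTMM normalization.

GeTMM (gene-length-corrected TMM) first converts counts to reads per
kilobase (RPK), so that per-gene length differences between species do
not masquerade as expression differences, and then applies
trimmed-mean-of-M-values (TMM) scaling factors computed on the RPK
matrix.  The resulting unit is RPK-per-million after TMM scaling,
comparable both between samples and between genes.

TMM parameters follow the original description: 30% trim on M-values,
5% trim on A-values, inverse-asymptotic-variance precision weights, and
a reference sample chosen as the column whose upper-quartile expression
is closest to the mean upper quartile.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .io_formats import CountTable, SampleMeta, ValidationError

__all__ = [
    "OrthoMap",
    "NormalizedExpr",
    "assemble_ortho_matrix",
    "rpk",
    "tmm_factors",
    "getmm",
    "filter_zero_genes",
    "coefficient_of_variation",
]


class OrthoMap:
    """1:1:1 orthologue table: one gene id per species per orthologue row."""

    def __init__(self, table: pd.DataFrame) -> None:
        # index: ortho_id; columns: species; values: per-species gene ids
        if table.index.has_duplicates:
            raise ValidationError("duplicate ortho_id in orthologue map")
        if table.isna().any().any():
            raise ValidationError("orthologue map has missing gene ids")
        for species in table.columns:
            col = table[species]
            if col.duplicated().any():
                dup = col[col.duplicated()].iloc[0]
                raise ValidationError(
                    f"gene {dup!r} appears in more than one orthologue row ({species})"
                )
        self.table = table

    @property
    def ortho_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def species(self) -> list[str]:
        return list(self.table.columns)

    def gene_for(self, ortho_id: str, species: str) -> str:
        return self.table.at[ortho_id, species]

    @classmethod
    def from_records(cls, records: Mapping[str, Mapping[str, str]]) -> "OrthoMap":
        return cls(pd.DataFrame.from_dict(records, orient="index"))

    @classmethod
    def read_tsv(cls, path: str | Path) -> "OrthoMap":
        return cls(pd.read_csv(path, sep="\t", index_col=0, dtype=str))

    def write_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index_label="ortho_id")


@dataclass
class NormalizedExpr:
    """GeTMM-normalized expression values with the factors that produced them."""

    ortho_ids: list[str]
    samples: list[SampleMeta]
    values: np.ndarray
    norm_factors: np.ndarray
    lib_sizes: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.values < 0):
            raise ValidationError("normalized values must be non-negative")
        if np.any(self.norm_factors <= 0):
            raise ValidationError("normalization factors must be positive")
        log_gm = np.mean(np.log(self.norm_factors))
        if abs(log_gm) > 1e-8:
            raise ValidationError("normalization factors must have geometric mean 1")

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ortho_ids, columns=self.sample_ids)

    def group_means(self, sample_ids: list[str]) -> np.ndarray:
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return self.values[:, idx].mean(axis=1)


def assemble_ortho_matrix(tables: Mapping[str, CountTable], ortho: OrthoMap) -> CountTable:
    """Join per-species count tables on the orthologue map.

    Rows are keyed by ortho_id; each sample column carries the counts of
    that sample's species-specific gene, and the length matrix stores
    each species' own gene length (lengths become genes x samples).
    """
    missing_species = [sp for sp in ortho.species if sp not in tables]
    if missing_species:
        raise ValidationError(f"no count table for species {missing_species}")
    samples: list[SampleMeta] = []
    count_cols: list[np.ndarray] = []
    length_cols: list[np.ndarray] = []
    for species in ortho.species:
        table = tables[species]
        index = {g: i for i, g in enumerate(table.gene_ids)}
        rows = []
        for ortho_id in ortho.ortho_ids:
            gid = ortho.gene_for(ortho_id, species)
            if gid not in index:
                raise ValidationError(
                    f"orthologue {ortho_id}: gene {gid!r} missing from {species} count table"
                )
            rows.append(index[gid])
        rows = np.array(rows)
        lengths = table.lengths_bp if table.lengths_bp.ndim == 1 else table.lengths_bp[:, 0]
        for j, meta in enumerate(table.samples):
            if meta.species != species:
                meta = SampleMeta(meta.sample_id, species, meta.group)
            samples.append(meta)
            count_cols.append(table.counts[rows, j])
            length_cols.append(lengths[rows])
    return CountTable(
        gene_ids=ortho.ortho_ids,
        lengths_bp=np.column_stack(length_cols),
        counts=np.column_stack(count_cols),
        samples=samples,
    )


def rpk(counts: np.ndarray, lengths_bp: np.ndarray) -> np.ndarray:
    """Reads per kilobase: counts / (length_bp / 1000)."""
    counts = np.asarray(counts, dtype=float)
    lengths_bp = np.asarray(lengths_bp, dtype=float)
    if np.any(lengths_bp <= 0):
        raise ValidationError("gene lengths must be positive for RPK")
    if lengths_bp.ndim == 1 and counts.ndim == 2:
        lengths_bp = lengths_bp[:, None]
    return counts / (lengths_bp / 1000.0)


def _tmm_pair_factor(
    obs: np.ndarray,
    ref: np.ndarray,
    trim_m: float,
    trim_a: float,
    weighting: bool = True,
) -> float:
    """TMM factor of one column against the reference column."""
    n_obs = obs.sum()
    n_ref = ref.sum()
    keep = (obs > 0) & (ref > 0)
    obs, ref = obs[keep], ref[keep]
    if obs.size == 0:
        return 1.0
    p_obs = obs / n_obs
    p_ref = ref / n_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    if weighting:
        # asymptotic (delta-method) variance of M -> inverse-variance weights;
        # note these depend on absolute depth, so factors are only
        # approximately invariant to rescaling one library
        w = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    else:
        w = np.ones_like(obs)
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = m.size
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rank_m = pd.Series(m).rank().to_numpy()
    rank_a = pd.Series(a).rank().to_numpy()
    keep2 = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not np.any(keep2) or np.sum(1.0 / w[keep2]) == 0:
        return 1.0
    f = np.sum(m[keep2] / w[keep2]) / np.sum(1.0 / w[keep2])
    if not np.isfinite(f):
        return 1.0
    return float(2.0**f)


def tmm_factors(
    rpk_matrix: np.ndarray,
    ref_sample: int | None = None,
    trim_m: float = 0.3,
    trim_a: float = 0.05,
    sample_ids: list[str] | None = None,
    weighting: bool = True,
) -> np.ndarray:
    """Trimmed-mean-of-M-values scaling factors on an RPK matrix.

    Factors are rescaled so their geometric mean is one.  When
    ``ref_sample`` is not supplied the reference is the column whose
    upper quartile (of library-size-scaled values) is closest to the
    mean upper quartile.
    """
    rpk_matrix = np.asarray(rpk_matrix, dtype=float)
    if rpk_matrix.ndim != 2 or rpk_matrix.shape[1] < 2:
        raise ValidationError("TMM needs a matrix with at least two samples")
    lib = rpk_matrix.sum(axis=0)
    zero = np.where(lib == 0)[0]
    if zero.size:
        name = sample_ids[zero[0]] if sample_ids else f"column {zero[0]}"
        raise ValidationError(f"sample {name} has all-zero RPK; cannot normalize")
    if ref_sample is None:
        uq = np.array([np.quantile(rpk_matrix[:, j] / lib[j], 0.75) for j in range(lib.size)])
        ref_sample = int(np.argmin(np.abs(uq - uq.mean())))
    factors = np.array(
        [
            _tmm_pair_factor(
                rpk_matrix[:, j], rpk_matrix[:, ref_sample], trim_m, trim_a, weighting
            )
            for j in range(rpk_matrix.shape[1])
        ]
    )
    factors = factors / np.exp(np.mean(np.log(factors)))
    return factors


def getmm(
    table: CountTable,
    trim_m: float = 0.3,
    trim_a: float = 0.05,
    weighting: bool = True,
) -> NormalizedExpr:
    """GeTMM normalization of a count table.

    values[g, s] = RPK[g, s] / (sum_g RPK[g, s] * factor[s]) * 1e6.
    A single-sample table is passed through with factor 1.
    """
    mat = rpk(table.counts, table.lengths_matrix())
    n_samples = mat.shape[1]
    if n_samples == 1:
        factors = np.array([1.0])
    else:
        factors = tmm_factors(
            mat, trim_m=trim_m, trim_a=trim_a, sample_ids=table.sample_ids, weighting=weighting
        )
    col_sums = mat.sum(axis=0)
    if np.any(col_sums == 0):
        j = int(np.where(col_sums == 0)[0][0])
        raise ValidationError(f"sample {table.sample_ids[j]} has all-zero RPK; cannot normalize")
    values = mat / (col_sums * factors) * 1e6
    return NormalizedExpr(
        ortho_ids=list(table.gene_ids),
        samples=list(table.samples),
        values=values,
        norm_factors=factors,
        lib_sizes=table.counts.sum(axis=0),
    )


def filter_zero_genes(
    expr: NormalizedExpr,
    species_of: Mapping[str, str] | Callable[[str], str] | None = None,
    policy: str = "any_species_all_zero",
) -> NormalizedExpr:
    """Remove orthologues with no expression evidence.

    ``any_species_all_zero`` (default) drops a row if there exists a
    species in which every sample is zero; ``all_samples_zero`` drops
    only rows that are zero everywhere.
    """
    if species_of is None:
        lookup = {s.sample_id: s.species for s in expr.samples}
    elif callable(species_of):
        lookup = {s.sample_id: species_of(s.sample_id) for s in expr.samples}
    else:
        lookup = dict(species_of)
    species = [lookup[s.sample_id] for s in expr.samples]
    if policy == "all_samples_zero":
        keep = ~(expr.values == 0).all(axis=1)
    elif policy == "any_species_all_zero":
        keep = np.ones(len(expr.ortho_ids), dtype=bool)
        for sp in sorted(set(species)):
            cols = [j for j, s in enumerate(species) if s == sp]
            keep &= ~(expr.values[:, cols] == 0).all(axis=1)
    else:
        raise ValueError(f"unknown zero-filter policy {policy!r}")
    return NormalizedExpr(
        ortho_ids=[g for g, k in zip(expr.ortho_ids, keep) if k],
        samples=expr.samples,
        values=expr.values[keep],
        norm_factors=expr.norm_factors,
        lib_sizes=expr.lib_sizes,
    )


def coefficient_of_variation(matrix: np.ndarray) -> np.ndarray:
    """Per-row CV = sample sd (n-1 denominator) / mean; NaN where mean is 0."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[1] < 2:
        raise ValidationError("CV needs at least two samples")
    mean = matrix.mean(axis=1)
    sd = matrix.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean == 0, np.nan, sd / mean)
    return cv
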