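"""Single-position liftover through UCSC chains and the joint cross-species
CpG matrix.

A position is mapped by selecting the highest-scoring chain whose
target span covers it (ties broken by chain input order, like
liftOver), walking the aligned blocks, and translating by offset within
the covering block; positions falling into dt/dq gaps are unmapped.
Minus-strand query chains reflect the coordinate (q_size - q_pos - 1 in
0-based space) and flip the strand.

The joint matrix keeps a reference CpG site only if its lifted
counterpart exists, passes the coverage filter, and is itself a
CpG-context record in every sample of every non-reference species, so
joint rows are complete by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io_formats import Chain, SampleMeta, ValidationError
from .methylome import MethylomeSet

__all__ = ["ChainSet", "JointCpGMatrix", "liftover_position", "build_joint_matrix", "invert_chain"]


class ChainSet:
    """Chains indexed by target chromosome with interval lookup.

    Lookup returns all chains covering a target position ordered by
    descending score, with input order breaking ties.
    """

    def __init__(self, chains: Sequence[Chain]):
        self.chains = list(chains)
        for c in self.chains:
            c.validate()
            if c.t_strand != "+":
                raise ValidationError("chains with reverse target strand are not supported")
        self._trees: dict[str, IntervalTree] = {}
        for order, c in enumerate(self.chains):
            tree = self._trees.setdefault(c.t_name, IntervalTree())
            if c.t_end > c.t_start:
                tree.addi(c.t_start, c.t_end, (order, c))
        # per-chain cumulative block arrays for vectorised mapping
        self._block_cache: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}

    def covering(self, chrom: str, pos0: int) -> list[Chain]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = [(iv.data[1].score, iv.data[0], iv.data[1]) for iv in tree.at(pos0)]
        hits.sort(key=lambda h: (-h[0], h[1]))
        return [h[2] for h in hits]

    def _blocks(self, chain: Chain):
        key = id(chain)
        if key not in self._block_cache:
            sizes = np.array([b[0] for b in chain.blocks], dtype=np.int64)
            dts = np.array([b[1] for b in chain.blocks], dtype=np.int64)
            dqs = np.array([b[2] for b in chain.blocks], dtype=np.int64)
            t_starts = chain.t_start + np.concatenate([[0], np.cumsum(sizes + dts)[:-1]])
            q_starts = chain.q_start + np.concatenate([[0], np.cumsum(sizes + dqs)[:-1]])
            self._block_cache[key] = (t_starts, q_starts, sizes)
        return self._block_cache[key]


def _map_through_chain(chainset: ChainSet, chain: Chain, pos0: int, strand: str):
    t_starts, q_starts, sizes = chainset._blocks(chain)
    i = int(np.searchsorted(t_starts, pos0, side="right")) - 1
    if i < 0:
        return None
    offset = pos0 - t_starts[i]
    if offset >= sizes[i]:
        return None  # inside a dt gap
    q_pos0 = int(q_starts[i] + offset)
    if chain.q_strand == "-":
        q_pos0 = chain.q_size - q_pos0 - 1
        strand = "-" if strand == "+" else "+"
    return (chain.q_name, q_pos0 + 1, strand)


def liftover_position(
    chains: ChainSet, chrom: str, pos: int, strand: str = "+"
) -> tuple[str, int, str] | None:
    """Lift one 1-based position; returns (chrom, pos, strand) or None."""
    if pos < 1:
        raise ValidationError("positions are 1-based")
    pos0 = pos - 1
    covering = chains.covering(chrom, pos0)
    if not covering:
        return None
    # the best covering chain claims the position: a gap there means unmapped
    return _map_through_chain(chains, covering[0], pos0, strand)


def liftover_positions(
    chains: ChainSet, chrom: str, positions: np.ndarray, strand: str = "+"
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised liftover of sorted or unsorted 1-based positions.

    Returns (mapped_pos, mapped_ok): mapped_pos holds 1-based query
    coordinates (0 where unmapped).  Only single-chromosome batches are
    supported; the query chromosome of each mapped position is the
    covering chain's q_name (exposed per chain via ``covering``).
    """
    positions = np.asarray(positions, dtype=np.int64)
    out = np.zeros(positions.size, dtype=np.int64)
    ok = np.zeros(positions.size, dtype=bool)
    tree = chains._trees.get(chrom)
    if tree is None:
        return out, ok
    remaining = np.ones(positions.size, dtype=bool)
    ordered = sorted(
        ((iv.data[1].score, iv.data[0], iv.data[1]) for iv in tree), key=lambda h: (-h[0], h[1])
    )
    for _score, _order, chain in ordered:
        if not remaining.any():
            break
        t_starts, q_starts, sizes = chains._blocks(chain)
        pos0 = positions - 1
        in_span = remaining & (pos0 >= chain.t_start) & (pos0 < chain.t_end)
        if not in_span.any():
            continue
        idx = np.searchsorted(t_starts, pos0[in_span], side="right") - 1
        offset = pos0[in_span] - t_starts[idx]
        inside = offset < sizes[idx]
        qpos0 = q_starts[idx] + offset
        if chain.q_strand == "-":
            qpos0 = chain.q_size - qpos0 - 1
        target_rows = np.where(in_span)[0]
        hit_rows = target_rows[inside]
        out[hit_rows] = qpos0[inside] + 1
        ok[hit_rows] = True
        # a covering chain claims the position whether or not it mapped
        remaining[target_rows] = False
    return out, ok


def invert_chain(chain: Chain) -> Chain:
    """Swap target and query roles; supports minus-strand queries.

    For a plus-strand chain this swaps coordinates and dt/dq per block;
    for a minus-strand query the inverted chain maps query-forward
    coordinates back onto the target with a minus-strand query side.
    """
    if chain.q_strand == "+":
        blocks = [(size, dq, dt) for size, dt, dq in chain.blocks]
        return Chain(
            score=chain.score,
            t_name=chain.q_name,
            t_size=chain.q_size,
            t_strand="+",
            t_start=chain.q_start,
            t_end=chain.q_end,
            q_name=chain.t_name,
            q_size=chain.t_size,
            q_strand="+",
            q_start=chain.t_start,
            q_end=chain.t_end,
            blocks=blocks,
            chain_id=chain.chain_id,
        )
    # minus-strand query: express the query side in forward coordinates
    # (reversing block order), keeping the original target as a minus query.
    blocks = [(size, dq, dt) for size, dt, dq in reversed(chain.blocks)]
    # shift gap annotations: after reversal the (dt, dq) of block i refer to
    # the gap preceding it in original orientation; recompute from spans.
    sizes = [b[0] for b in blocks]
    t_gaps = [b[1] for b in blocks]
    q_gaps = [b[2] for b in blocks]
    # rotate gaps so each block carries the gap that follows it
    t_gaps = t_gaps[1:] + [0]
    q_gaps = q_gaps[1:] + [0]
    blocks = list(zip(sizes, t_gaps, q_gaps))
    return Chain(
        score=chain.score,
        t_name=chain.q_name,
        t_size=chain.q_size,
        t_strand="+",
        t_start=chain.q_size - chain.q_end,
        t_end=chain.q_size - chain.q_start,
        q_name=chain.t_name,
        q_size=chain.t_size,
        q_strand="-",
        q_start=chain.t_size - chain.t_end,
        q_end=chain.t_size - chain.t_start,
        blocks=blocks,
        chain_id=chain.chain_id,
    )


@dataclass
class JointCpGMatrix:
    """Cross-species CpG methylation matrix in reference coordinates."""

    chrom: np.ndarray  # site keys (reference coordinates)
    pos: np.ndarray
    strand: np.ndarray
    meth: np.ndarray  # sites x samples methylated read counts
    cov: np.ndarray  # sites x samples total coverage
    samples: list[SampleMeta]
    provenance: pd.DataFrame | None = None  # per-site source coordinate per species

    @property
    def levels(self) -> np.ndarray:
        return self.meth / self.cov

    @property
    def n_sites(self) -> int:
        return self.pos.size

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def sample_columns(self, sample_ids: Sequence[str]) -> np.ndarray:
        ids = self.sample_ids
        return np.array([ids.index(s) for s in sample_ids])


def build_joint_matrix(
    ref_methylomes: Sequence[MethylomeSet],
    others: Mapping[str, tuple[Sequence[MethylomeSet], ChainSet]],
    min_cov: int = 10,
    require_cpg: bool = True,
) -> JointCpGMatrix:
    """Assemble the joint CpG matrix over reference sites shared by all samples.

    ``ref_methylomes`` are coverage-filtered CpG methylomes on the
    reference genome; ``others`` maps species name to (methylomes,
    chains from reference to that species).  A reference site survives
    only if covered (>= min_cov) in every reference sample and its
    lifted coordinate is a covered CpG record in every sample of every
    other species.
    """
    if not ref_methylomes:
        raise ValidationError("need at least one reference methylome")
    ref_cpg = [m.context_subset("CpG") for m in ref_methylomes]

    # intersect reference site keys across reference samples
    keys: pd.Index | None = None
    for m in ref_cpg:
        covered = m.df[(m.df.n_meth + m.df.n_unmeth) >= min_cov]
        idx = pd.MultiIndex.from_frame(covered[["chrom", "pos", "strand"]])
        keys = idx if keys is None else keys.intersection(idx)
    assert keys is not None
    if len(keys) == 0:
        raise ValidationError(
            "no reference CpG sites pass coverage in all reference samples; "
            "check coverage filtering"
        )
    key_df = keys.to_frame(index=False).sort_values(["chrom", "pos", "strand"])
    key_df = key_df.reset_index(drop=True)

    keep = np.ones(len(key_df), dtype=bool)
    provenance: dict[str, list] = {}
    mapped_by_species: dict[str, pd.DataFrame] = {}
    for species, (msets, chainset) in others.items():
        mapped_chrom = np.empty(len(key_df), dtype=object)
        mapped_pos = np.zeros(len(key_df), dtype=np.int64)
        ok = np.zeros(len(key_df), dtype=bool)
        for chrom, group in key_df.groupby("chrom", sort=False):
            rows = group.index.to_numpy()
            pos = group["pos"].to_numpy()
            out, hit = liftover_positions(chainset, chrom, pos)
            # q_name per position: resolve via scalar path only for hits with
            # multiple chains is unnecessary here; use covering chain names
            qnames = np.empty(rows.size, dtype=object)
            if hit.any():
                # recover q_name by asking which chain covered each hit
                tree = chainset._trees.get(chrom)
                ordered = sorted(
                    ((iv.data[1].score, iv.data[0], iv.data[1]) for iv in tree),
                    key=lambda h: (-h[0], h[1]),
                )
                claimed = np.zeros(rows.size, dtype=bool)
                pos0 = pos - 1
                for _s, _o, chain in ordered:
                    sel = ~claimed & (pos0 >= chain.t_start) & (pos0 < chain.t_end)
                    qnames[sel] = chain.q_name
                    claimed |= sel
            mapped_chrom[rows] = qnames
            mapped_pos[rows] = out
            ok[rows] = hit
        keep &= ok
        mapped_by_species[species] = pd.DataFrame(
            {"chrom": mapped_chrom, "pos": mapped_pos}
        )

    key_df = key_df[keep].reset_index(drop=True)
    for species in list(mapped_by_species):
        mapped_by_species[species] = mapped_by_species[species][keep].reset_index(drop=True)

    # require the lifted coordinate to be a covered CpG in every other sample
    final_keep = np.ones(len(key_df), dtype=bool)
    for species, (msets, _cs) in others.items():
        mapped = mapped_by_species[species]
        target = pd.MultiIndex.from_arrays([mapped["chrom"], mapped["pos"]])
        for m in msets:
            df = m.context_subset("CpG") if require_cpg else m
            df = df.df if hasattr(df, "df") else df
            covered = df[(df.n_meth + df.n_unmeth) >= min_cov]
            idx = pd.MultiIndex.from_frame(covered[["chrom", "pos"]])
            final_keep &= target.isin(idx)

    key_df = key_df[final_keep].reset_index(drop=True)
    for species in list(mapped_by_species):
        mapped_by_species[species] = mapped_by_species[species][final_keep].reset_index(drop=True)
    if len(key_df) == 0:
        raise ValidationError(
            "zero shared CpG sites across species; check chains and coverage"
        )

    # assemble count matrices
    samples: list[SampleMeta] = []
    meth_cols: list[np.ndarray] = []
    cov_cols: list[np.ndarray] = []

    def _extract(mset: MethylomeSet, chroms, poss) -> tuple[np.ndarray, np.ndarray]:
        df = mset.context_subset("CpG").df
        idx = df.set_index(["chrom", "pos"])
        target = pd.MultiIndex.from_arrays([chroms, poss])
        sub = idx.reindex(target)
        return sub["n_meth"].to_numpy(dtype=float), (
            sub["n_meth"].to_numpy(dtype=float) + sub["n_unmeth"].to_numpy(dtype=float)
        )

    for m in ref_cpg:
        nm, cv = _extract(m, key_df["chrom"], key_df["pos"])
        samples.append(m.sample)
        meth_cols.append(nm)
        cov_cols.append(cv)
    prov_frames = {"ref": key_df.apply(lambda r: f"{r.chrom}:{r.pos}", axis=1)}
    for species, (msets, _cs) in others.items():
        mapped = mapped_by_species[species]
        for m in msets:
            nm, cv = _extract(m, mapped["chrom"], mapped["pos"])
            samples.append(m.sample)
            meth_cols.append(nm)
            cov_cols.append(cv)
        prov_frames[species] = mapped.apply(lambda r: f"{r.chrom}:{r.pos}", axis=1)

    meth = np.column_stack(meth_cols)
    cov = np.column_stack(cov_cols)
    if np.isnan(cov).any():
        raise ValidationError("internal error: joint matrix has missing entries")
    return JointCpGMatrix(
        chrom=key_df["chrom"].to_numpy(),
        pos=key_df["pos"].to_numpy(),
        strand=key_df["strand"].to_numpy(),
        meth=meth,
        cov=cov,
        samples=samples,
        provenance=pd.DataFrame(prov_frames),
    )
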