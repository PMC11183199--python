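"""Differential methylation: windowed DMR calling, gene-body DMG assignment,
and promoter DMG testing.

DMRs are called with a sliding-window pooled-count test (window 500 bp,
step 250 bp): within a window, read counts are pooled per group, and a
window is a candidate when (i) at least three CpG sites each show a
group-pooled per-site level difference of at least 0.1, all in the same
direction, (ii) the pooled window difference is at least 0.1, and
(iii) a two-proportion z-test on the pooled counts gives p < 1e-4.
Overlapping or adjacent same-direction candidates merge into maximal
DMRs whose statistics are recomputed on the union of sites.  This is a
deliberately simple, exactly testable region test; it consumes the same
inputs and produces the same interval/direction calls that smoothing-
based beta-binomial callers produce.

Promoter DMGs follow coverage/fold-change/rank-test criteria: a
promoter is eligible when at least two CpG sites are covered by more
than 10 reads in every sample, and called when the group mean level
ratio exceeds two-fold (strictly) and a one-tailed exact Wilcoxon
rank-sum test (direction chosen by the observed fold change, midrank
ties) gives p < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats

from .io_formats import GeneModel, ValidationError
from .crossmap import JointCpGMatrix
from .methylome import MethylomeSet, promoter_interval

__all__ = [
    "DMR",
    "GeneBodyDMG",
    "PromoterDMG",
    "call_dmrs",
    "assign_genebody_dmgs",
    "promoter_eligibility",
    "call_promoter_dmgs",
    "wilcoxon_one_tailed",
]


@dataclass
class DMR:
    chrom: str
    start: int  # 1-based inclusive
    end: int
    n_cpg: int
    level_a: float
    level_b: float
    diff: float
    pvalue: float
    direction: str  # hyper (group A above B) | hypo

    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class GeneBodyDMG:
    gene_id: str
    dmrs: list[DMR] = field(default_factory=list)
    dmg_class: str = ""  # hyper_only | hypo_only | mixed


@dataclass
class PromoterDMG:
    gene_id: str
    levels_a: list[float]
    levels_b: list[float]
    fold_change: float
    pvalue: float
    direction: str  # hyper | hypo
    n_qualifying_cpg: int = 0


def _two_proportion_z(ma: float, ta: float, mb: float, tb: float) -> float:
    """Two-sided pooled two-proportion z-test p-value."""
    if ta == 0 or tb == 0:
        return 1.0
    p1, p2 = ma / ta, mb / tb
    p = (ma + mb) / (ta + tb)
    var = p * (1 - p) * (1 / ta + 1 / tb)
    if var <= 0:
        return 1.0
    z = (p1 - p2) / np.sqrt(var)
    return float(2 * stats.norm.sf(abs(z)))


def call_dmrs(
    joint: JointCpGMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    window: int = 500,
    step: int = 250,
    p_threshold: float = 1e-4,
    min_cpg: int = 3,
    min_diff: float = 0.1,
) -> list[DMR]:
    """Sliding-window DMR calling between two sample groups.

    ``group_a``/``group_b`` are sample ids of the joint matrix.  DMR
    boundaries are the first/last CpG positions of the merged candidate
    windows; statistics are recomputed on the union of sites.
    """
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValidationError("both groups need at least one sample")
    cols_a = joint.sample_columns(group_a)
    cols_b = joint.sample_columns(group_b)
    meth_a = joint.meth[:, cols_a].sum(axis=1)
    cov_a = joint.cov[:, cols_a].sum(axis=1)
    meth_b = joint.meth[:, cols_b].sum(axis=1)
    cov_b = joint.cov[:, cols_b].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        site_diff = meth_a / cov_a - meth_b / cov_b

    dmrs: list[DMR] = []
    for chrom in pd_unique(joint.chrom):
        sel = joint.chrom == chrom
        pos = joint.pos[sel]
        order = np.argsort(pos, kind="mergesort")
        pos = pos[order]
        ma, ca = meth_a[sel][order], cov_a[sel][order]
        mb, cb = meth_b[sel][order], cov_b[sel][order]
        sd = site_diff[sel][order]

        # prefix sums for O(1) window pooling
        cum = lambda x: np.concatenate([[0.0], np.cumsum(x)])
        c_ma, c_ca, c_mb, c_cb = cum(ma), cum(ca), cum(mb), cum(cb)
        qual_pos = cum((sd >= min_diff).astype(float))
        qual_neg = cum((sd <= -min_diff).astype(float))

        last = int(pos.max())
        starts = np.arange(1, last + 1, step)
        lo = np.searchsorted(pos, starts, side="left")
        hi = np.searchsorted(pos, starts + window - 1, side="right")
        nonempty = hi > lo
        lo, hi, w_start = lo[nonempty], hi[nonempty], starts[nonempty]

        w_ma = c_ma[hi] - c_ma[lo]
        w_ca = c_ca[hi] - c_ca[lo]
        w_mb = c_mb[hi] - c_mb[lo]
        w_cb = c_cb[hi] - c_cb[lo]
        n_pos = qual_pos[hi] - qual_pos[lo]
        n_neg = qual_neg[hi] - qual_neg[lo]
        with np.errstate(invalid="ignore", divide="ignore"):
            w_diff = np.where(w_ca > 0, w_ma / np.maximum(w_ca, 1), np.nan) - np.where(
                w_cb > 0, w_mb / np.maximum(w_cb, 1), np.nan
            )
        cand_hyper = (n_pos >= min_cpg) & (n_neg == 0) & (w_diff >= min_diff)
        cand_hypo = (n_neg >= min_cpg) & (n_pos == 0) & (w_diff <= -min_diff)
        candidate = cand_hyper | cand_hypo
        if not candidate.any():
            continue
        # z-test only on surviving windows
        idx = np.where(candidate)[0]
        pvals = np.array(
            [_two_proportion_z(w_ma[i], w_ca[i], w_mb[i], w_cb[i]) for i in idx]
        )
        idx = idx[pvals < p_threshold]
        if idx.size == 0:
            continue

        # merge overlapping/adjacent same-direction candidate windows
        events = sorted(
            (int(w_start[i]), int(w_start[i]) + window - 1, "hyper" if cand_hyper[i] else "hypo")
            for i in idx
        )
        merged: list[list] = []
        for s, e, d in events:
            if merged and d == merged[-1][2] and s <= merged[-1][1] + 1:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e, d])

        for s, e, d in merged:
            a = np.searchsorted(pos, s, side="left")
            b = np.searchsorted(pos, e, side="right")
            sub = slice(a, b)
            # restrict to qualifying sites for the DMR span
            q_mask = (sd[sub] >= min_diff) if d == "hyper" else (sd[sub] <= -min_diff)
            span_pos = pos[sub][q_mask] if q_mask.any() else pos[sub]
            t_ma, t_ca = ma[sub].sum(), ca[sub].sum()
            t_mb, t_cb = mb[sub].sum(), cb[sub].sum()
            la = t_ma / t_ca if t_ca else float("nan")
            lb = t_mb / t_cb if t_cb else float("nan")
            merged_p = _two_proportion_z(t_ma, t_ca, t_mb, t_cb)
            merged_diff = float(la - lb)
            # recomputed union statistics must themselves satisfy the
            # printed constraints; rare boundary merges that lose them
            # are not emitted
            if int(q_mask.sum()) < min_cpg or abs(merged_diff) < min_diff:
                continue
            if merged_p >= p_threshold:
                continue
            dmrs.append(
                DMR(
                    chrom=str(chrom),
                    start=int(span_pos.min()),
                    end=int(span_pos.max()),
                    n_cpg=int(b - a),
                    level_a=float(la),
                    level_b=float(lb),
                    diff=merged_diff,
                    pvalue=merged_p,
                    direction=d,
                )
            )
    return dmrs


def pd_unique(values: np.ndarray) -> np.ndarray:
    """Order-preserving unique (first-occurrence order)."""
    seen: dict = {}
    for v in values:
        if v not in seen:
            seen[v] = None
    return np.array(list(seen))


def assign_genebody_dmgs(dmrs: Sequence[DMR], models: Sequence[GeneModel]) -> list[GeneBodyDMG]:
    """Assign DMRs to genes when the overlap exceeds half the DMR length.

    Overlap is in base pairs on 1-based inclusive intervals; exactly
    half does not qualify.  Genes are classified hyper_only / hypo_only
    / mixed by the directions of their assigned DMRs.
    """
    by_gene: dict[str, list[DMR]] = {}
    by_chrom: dict[str, list[GeneModel]] = {}
    for m in models:
        by_chrom.setdefault(m.chrom, []).append(m)
    for d in dmrs:
        for m in by_chrom.get(d.chrom, []):
            overlap = min(d.end, m.end) - max(d.start, m.start) + 1
            if overlap > d.length() / 2:
                by_gene.setdefault(m.gene_id, []).append(d)
    out = []
    for gene_id, assigned in by_gene.items():
        directions = {d.direction for d in assigned}
        if directions == {"hyper"}:
            cls = "hyper_only"
        elif directions == {"hypo"}:
            cls = "hypo_only"
        else:
            cls = "mixed"
        out.append(GeneBodyDMG(gene_id=gene_id, dmrs=assigned, dmg_class=cls))
    return out


def promoter_eligibility(
    methylomes: Sequence[MethylomeSet],
    chrom: str,
    start: int,
    end: int,
    min_reads: int = 10,
    rule: str = "every_sample",
) -> int:
    """Count promoter CpG positions covered by more than ``min_reads`` reads.

    ``every_sample`` (default) requires the strict >min_reads coverage
    at the position in every sample of both groups; ``pooled`` applies
    it to summed coverage across samples.
    """
    per_sample: list[dict[int, float]] = []
    for m in methylomes:
        pos, nm, nu = m.chrom_arrays(chrom, "CpG")
        lo = np.searchsorted(pos, start, side="left")
        hi = np.searchsorted(pos, end, side="right")
        per_sample.append(
            {int(p): float(c) for p, c in zip(pos[lo:hi], (nm + nu)[lo:hi])}
        )
    positions = set().union(*per_sample) if per_sample else set()
    if rule == "every_sample":
        # absent in a sample counts as coverage 0, which fails the strict test
        return sum(
            1 for p in positions if all(cov.get(p, 0.0) > min_reads for cov in per_sample)
        )
    if rule == "pooled":
        return sum(
            1 for p in positions if sum(cov.get(p, 0.0) for cov in per_sample) > min_reads
        )
    raise ValueError(f"unknown eligibility rule {rule!r}")


@lru_cache(maxsize=128)
def _subset_indices(n: int, k: int) -> tuple[tuple[int, ...], ...]:
    return tuple(combinations(range(n), k))


def wilcoxon_one_tailed(
    a: Sequence[float],
    b: Sequence[float],
    alternative: str,
    exact_max_n: int = 10,
) -> float:
    """One-tailed Wilcoxon rank-sum p-value with midrank tie handling.

    Exact by full enumeration of rank assignments when
    min(len(a), len(b)) <= ``exact_max_n`` and the total is modest;
    otherwise a tie-corrected normal approximation.  ``alternative`` is
    'greater' (a shifted above b) or 'less'.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    if a.size < 1 or b.size < 1:
        raise ValidationError("both groups need at least one observation")
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)  # midranks
    n_a, n = a.size, pooled.size
    w_obs = ranks[:n_a].sum()
    if min(a.size, b.size) <= exact_max_n and n <= 24:
        tol = 1e-9
        total = 0
        hits = 0
        for subset in _subset_indices(n, n_a):
            w = ranks[list(subset)].sum()
            total += 1
            if alternative == "greater":
                hits += w >= w_obs - tol
            else:
                hits += w <= w_obs + tol
        return hits / total
    # normal approximation with tie correction
    mean = n_a * (n + 1) / 2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / ((n) * (n - 1))
    var = n_a * b.size / 12 * ((n + 1) - tie_term)
    if var <= 0:
        return 1.0
    z = (w_obs - mean) / np.sqrt(var)
    if alternative == "greater":
        return float(stats.norm.sf(z))
    return float(stats.norm.cdf(z))


def call_promoter_dmgs(
    levels_a: Sequence[float],
    levels_b: Sequence[float],
    gene_id: str = "",
    fc_min: float = 2.0,
    alpha: float = 0.05,
    eps: float = 0.005,
    n_qualifying_cpg: int = 0,
) -> PromoterDMG | None:
    """Two-group promoter test on per-sample pooled levels.

    Fold change is (mean_a + eps) / (mean_b + eps); the one-tailed
    Wilcoxon direction follows the fold change sign; a call requires
    FC > fc_min or FC < 1/fc_min (strict) and p < alpha.
    """
    levels_a = [float(x) for x in levels_a]
    levels_b = [float(x) for x in levels_b]
    if len(levels_a) < 2 or len(levels_b) < 2:
        raise ValidationError("promoter test needs at least two samples per group")
    mean_a = float(np.mean(levels_a))
    mean_b = float(np.mean(levels_b))
    fc = (mean_a + eps) / (mean_b + eps)
    if fc == 1.0:
        return None
    direction = "hyper" if fc > 1 else "hypo"
    p = wilcoxon_one_tailed(
        levels_a, levels_b, "greater" if direction == "hyper" else "less"
    )
    if (fc > fc_min or fc < 1.0 / fc_min) and p < alpha:
        return PromoterDMG(
            gene_id=gene_id,
            levels_a=levels_a,
            levels_b=levels_b,
            fold_change=float(fc),
            pvalue=float(p),
            direction=direction,
            n_qualifying_cpg=n_qualifying_cpg,
        )
    return None
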