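"""Sample-structure analyses, methylation-expression integration, convergence
screens and gene-set enrichment.

Clustering uses 1 - Spearman rho as the between-sample distance with
complete linkage (average/single available).  The methylation-
expression integration retains genes whose linear methylation fold
change exceeds two-fold and whose expression |log2FC| exceeds 0.5,
log2-transforms both, and reports the Spearman correlation with its
t-approximation p-value.  Convergent genes are those with the same
significant call (DEG direction, or negative-correlation class) in both
panda-versus-bear comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform

from .io_formats import GeneSetCollection, ValidationError
from .differential_expression import DEGResult, bh_adjust
from .diffmeth import PromoterDMG

__all__ = [
    "IntegrationRecord",
    "ConvergentGene",
    "EnrichmentResult",
    "pca",
    "spearman_cluster",
    "species_pair_distances",
    "correlate_meth_expr",
    "negative_correlation_genes",
    "convergence_screen",
    "enrich",
]


@dataclass
class IntegrationRecord:
    gene_id: str
    region: str  # promoter | gene_body
    log2_meth_fc: float
    log2_expr_fc: float


@dataclass
class ConvergentGene:
    gene_id: str
    kind: str  # expr_up | expr_down | hypo_high | hyper_low
    evidence: dict


@dataclass
class EnrichmentResult:
    set_name: str
    k: int  # hits in query
    K: int  # set size within universe
    n: int  # query size
    N: int  # universe size
    pvalue: float
    qvalue: float = float("nan")
    significant: bool = False


def pca(matrix: np.ndarray, log_transform: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """PCA of a samples x features matrix.

    Zero-variance features are dropped, features centred, and the
    decomposition done by SVD.  Returns (scores, explained-variance
    fractions); fractions sum to one.  ``log_transform`` applies
    log2(x + 1) first (the expression convention; methylation levels
    are used untransformed).
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValidationError("PCA needs at least two samples")
    if log_transform:
        x = np.log2(x + 1.0)
    keep = x.std(axis=0) > 0
    x = x[:, keep]
    if x.shape[1] == 0:
        # fully degenerate: all samples identical
        return np.zeros((matrix.shape[0], 1)), np.array([0.0])
    x = x - x.mean(axis=0)
    u, s, _vt = np.linalg.svd(x, full_matrices=False)
    scores = u * s
    var = s**2
    evr = var / var.sum() if var.sum() > 0 else var
    return scores, evr


def spearman_cluster(
    matrix: np.ndarray,
    sample_ids: Sequence[str] | None = None,
    method: str = "complete",
) -> tuple[np.ndarray, list[int]]:
    """Agglomerative clustering of samples on 1 - Spearman rho distance.

    Returns (linkage matrix in scipy format, leaf order).  A constant
    sample vector has no defined rank correlation and raises an error
    naming the sample.
    """
    x = np.asarray(matrix, dtype=float)
    n = x.shape[0]
    if n < 3:
        raise ValidationError("clustering needs at least three samples")
    for i in range(n):
        if np.all(x[i] == x[i, 0]):
            name = sample_ids[i] if sample_ids else f"sample {i}"
            raise ValidationError(f"sample {name} is constant; Spearman rho undefined")
    ranks = np.apply_along_axis(stats.rankdata, 1, x)
    rho = np.corrcoef(ranks)
    dist = 1.0 - rho
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2
    z = linkage(squareform(dist, checks=False), method=method)
    from scipy.cluster.hierarchy import leaves_list

    return z, list(leaves_list(z))


def species_pair_distances(
    z: np.ndarray, labels: Sequence[str]
) -> dict[tuple[str, str], float]:
    """Mean cophenetic distance between every pair of label classes.

    Used to ask which two species' samples join first in a dendrogram.
    """
    coph = squareform(cophenet(z))
    labels = list(labels)
    classes = sorted(set(labels))
    out: dict[tuple[str, str], float] = {}
    for i, a in enumerate(classes):
        for b in classes[i + 1 :]:
            rows = [k for k, l in enumerate(labels) if l == a]
            cols = [k for k, l in enumerate(labels) if l == b]
            out[(a, b)] = float(np.mean([coph[r, c] for r in rows for c in cols]))
    return out


def correlate_meth_expr(
    records: Sequence[IntegrationRecord],
    meth_fc_min: float = 2.0,
    expr_log2fc_min: float = 0.5,
) -> tuple[float, float, list[IntegrationRecord]]:
    """Spearman correlation of log2 methylation FC against log2 expression FC.

    Records are retained when the linear methylation fold change is
    > meth_fc_min or < 1/meth_fc_min and |log2 expression FC| >
    expr_log2fc_min; significance is the two-tailed t-approximation
    t = rho * sqrt((n-2) / (1-rho^2)) with n-2 df.
    """
    retained = [
        r
        for r in records
        if (2.0 ** r.log2_meth_fc > meth_fc_min or 2.0 ** r.log2_meth_fc < 1.0 / meth_fc_min)
        and abs(r.log2_expr_fc) > expr_log2fc_min
    ]
    n = len(retained)
    if n < 3:
        raise ValidationError(
            f"only {n} of {len(records)} records pass the FC filters; need >= 3"
        )
    meth = np.array([r.log2_meth_fc for r in retained])
    expr = np.array([r.log2_expr_fc for r in retained])
    rho = float(
        np.corrcoef(stats.rankdata(meth), stats.rankdata(expr))[0, 1]
    )
    if abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt((n - 2) / (1 - rho**2))
        p = float(2 * stats.t.sf(abs(t), df=n - 2))
    return rho, p, retained


def negative_correlation_genes(
    promoter_dmgs: Sequence[PromoterDMG],
    degs: Sequence[DEGResult],
) -> dict[str, set[str]]:
    """Split genes into hypo+highly-expressed and hyper+lowly-expressed sets.

    hypo_high: promoter hypomethylated DMG that is an upregulated DEG;
    hyper_low: promoter hypermethylated DMG that is a downregulated DEG.
    Discordant combinations belong to neither set.
    """
    deg_status = {d.ortho_id: d.status for d in degs}
    hypo_high: set[str] = set()
    hyper_low: set[str] = set()
    for dmg in promoter_dmgs:
        status = deg_status.get(dmg.gene_id, "ns")
        if dmg.direction == "hypo" and status == "up":
            hypo_high.add(dmg.gene_id)
        elif dmg.direction == "hyper" and status == "down":
            hyper_low.add(dmg.gene_id)
    return {"hypo_high": hypo_high, "hyper_low": hyper_low}


def convergence_screen(
    results_1,
    results_2,
    mode: str = "expression",
) -> list[ConvergentGene]:
    """Genes with the same significant call in both species comparisons.

    ``expression`` mode takes two DEGResult sequences and returns genes
    whose status is non-ns and identical in both.  ``meth_expr`` mode
    takes two dicts as returned by :func:`negative_correlation_genes`
    and returns genes in the same class in both.
    """
    out: list[ConvergentGene] = []
    if mode == "expression":
        s1 = {d.ortho_id: d for d in results_1}
        s2 = {d.ortho_id: d for d in results_2}
        for gid in sorted(set(s1) & set(s2)):
            a, b = s1[gid], s2[gid]
            if a.status != "ns" and a.status == b.status:
                out.append(
                    ConvergentGene(
                        gene_id=gid,
                        kind=f"expr_{a.status}",
                        evidence={
                            "comparison1": {"log2fc": a.log2fc, "q": a.qvalue},
                            "comparison2": {"log2fc": b.log2fc, "q": b.qvalue},
                        },
                    )
                )
    elif mode == "meth_expr":
        for cls in ("hypo_high", "hyper_low"):
            for gid in sorted(results_1[cls] & results_2[cls]):
                out.append(ConvergentGene(gene_id=gid, kind=cls, evidence={}))
    else:
        raise ValueError(f"unknown convergence mode {mode!r}")
    return out


def enrich(
    query: Sequence[str],
    collection: GeneSetCollection,
    universe: Sequence[str],
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Hypergeometric upper-tail enrichment of a query gene list.

    For each set, with N the universe size, K the set size within the
    universe, n the query size and k the hits, p = P[X >= k] for
    X ~ Hypergeom(N, K, n).  BH-adjusted q-values are reported;
    significance is flagged at p < alpha.
    """
    universe_set = set(universe)
    if not universe_set:
        raise ValidationError("empty universe")
    query_set = set(query) & universe_set
    if set(query) - universe_set:
        raise ValidationError("query genes must be a subset of the universe")
    n = len(query_set)
    big_n = len(universe_set)
    results = []
    for name in collection:
        members = collection[name] & universe_set
        big_k = len(members)
        if big_k == 0:
            continue
        k = len(members & query_set)
        # P[X >= k] = survival function at k-1
        p = float(stats.hypergeom.sf(k - 1, big_n, big_k, n))
        results.append(EnrichmentResult(name, k, big_k, n, big_n, min(1.0, p)))
    if results:
        q = bh_adjust([r.pvalue for r in results])
        for r, qv in zip(results, q):
            r.qvalue = float(qv)
            r.significant = r.pvalue < alpha
    return results
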