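"""Methylation level arithmetic: pooling identities, bins, elements, metagene."""

import numpy as np
import pytest

from convergemeth.io_formats import CytosineRecord, GeneModel, SampleMeta
from convergemeth.methylome import (
    MethylomeSet,
    bin_levels,
    coverage_filter,
    gene_element_levels,
    merge_symmetric_cpgs,
    metagene_profile,
    promoter_interval,
    region_level,
    site_level,
)

from conftest import make_methylome


class TestCoverageFilter:
    def test_boundary_ten_kept_nine_removed(self):
        mset = make_methylome(
            [
                CytosineRecord("chr1", 1, "+", 4, 5, "CpG"),  # 9x
                CytosineRecord("chr1", 2, "+", 4, 6, "CpG"),  # 10x
            ]
        )
        kept = coverage_filter(mset)
        assert [r.pos for r in kept.records()] == [2]

    def test_empty_and_identity(self):
        empty = make_methylome([])
        assert len(coverage_filter(empty)) == 0
        full = make_methylome([CytosineRecord("chr1", 1, "+", 5, 6, "CpG")])
        assert coverage_filter(full).records() == full.records()

    def test_idempotent(self, rng):
        records = [
            CytosineRecord("chr1", int(p), "+", int(m), int(u), "CpG")
            for p, m, u in zip(
                np.arange(1, 200), rng.integers(0, 20, 199), rng.integers(0, 20, 199)
            )
        ]
        once = coverage_filter(make_methylome(records))
        twice = coverage_filter(once)
        assert once.records() == twice.records()


class TestSiteLevel:
    @pytest.mark.parametrize(
        "m,u,expected", [(4, 6, 0.4), (0, 10, 0.0), (10, 0, 1.0)]
    )
    def test_formula(self, m, u, expected):
        assert site_level(CytosineRecord("chr1", 1, "+", m, u, "CpG")) == expected

    def test_zero_coverage_undefined(self):
        assert np.isnan(site_level(CytosineRecord("chr1", 1, "+", 0, 0, "CpG")))


class TestBins:
    def test_pooled_level(self):
        mset = make_methylome(
            [
                CytosineRecord("chr1", 100, "+", 4, 6, "CpG"),
                CytosineRecord("chr1", 200, "+", 6, 4, "CpG"),
            ]
        )
        bins = bin_levels(mset, bin_size=10_000)
        assert bins[0].level == pytest.approx(0.5)
        assert bins[0].n_sites == 2

    def test_empty_bin_undefined(self):
        mset = make_methylome([CytosineRecord("chr1", 15_000, "+", 5, 5, "CpG")])
        bins = bin_levels(mset, bin_size=10_000)
        assert np.isnan(bins[0].level) and bins[1].level == 0.5

    def test_pooled_equals_coverage_weighted_mean(self, rng):
        n = 500
        meth = rng.integers(0, 30, n)
        unmeth = rng.integers(0, 30, n)
        pos = np.sort(rng.choice(np.arange(1, 9000), size=n, replace=False))
        records = [
            CytosineRecord("chr1", int(p), "+", int(m), int(u), "CpG")
            for p, m, u in zip(pos, meth, unmeth)
        ]
        mset = make_methylome(records)
        bins = bin_levels(mset, bin_size=10_000)
        cov = meth + unmeth
        covered = cov > 0
        weighted = (
            np.sum((meth[covered] / cov[covered]) * cov[covered]) / cov[covered].sum()
        )
        assert bins[0].level == pytest.approx(weighted)


class TestRegions:
    def test_pooled_promoter_example(self):
        mset = make_methylome(
            [
                CytosineRecord("chr1", 10, "+", 5, 5, "CpG"),
                CytosineRecord("chr1", 20, "+", 0, 10, "CpG"),
            ]
        )
        r = region_level(mset, "chr1", 1, 100, region_kind="promoter")
        assert r.level == pytest.approx(0.25)
        assert r.n_cpg_covered == 2

    def test_empty_region_undefined(self):
        mset = make_methylome([])
        r = region_level(mset, "chr1", 1, 100)
        assert np.isnan(r.level) and r.n_cpg_covered == 0

    def test_split_additivity(self, rng):
        records = [
            CytosineRecord("chr1", int(p), "+", int(m), int(u), "CpG")
            for p, m, u in zip(
                np.arange(10, 200, 7), rng.integers(0, 20, 28), rng.integers(1, 20, 28)
            )
        ]
        mset = make_methylome(records)
        whole = region_level(mset, "chr1", 10, 199)
        left = region_level(mset, "chr1", 10, 99)
        right = region_level(mset, "chr1", 100, 199)
        pooled = (left.n_meth + right.n_meth) / (left.n_total + right.n_total)
        assert whole.level == pytest.approx(pooled)


class TestPromoterInterval:
    def test_plus_strand(self):
        m = GeneModel("g", "chr1", "+", 5001, 8000)
        assert promoter_interval(m) == (4001, 5000)

    def test_minus_strand(self):
        m = GeneModel("g", "chr1", "-", 5001, 8000)
        assert promoter_interval(m) == (8001, 9000)

    def test_clipped_at_chromosome_start(self):
        m = GeneModel("g", "chr1", "+", 500, 900)
        assert promoter_interval(m) == (1, 499)


class TestElements:
    def test_exon_intron_partition(self):
        model = GeneModel("g", "chr1", "+", 1000, 1999, [(1000, 1399), (1700, 1999)])
        records = [
            CytosineRecord("chr1", p, "+", 10, 10, "CpG") for p in (1100, 1500, 1800)
        ]
        levels = {r.region_kind: r for r in gene_element_levels(make_methylome(records), [model])}
        assert levels["exon"].n_cpg_covered == 2
        assert levels["intron"].n_cpg_covered == 1
        assert levels["gene_body"].n_cpg_covered == 3


class TestMetagene:
    def make_gene(self, strand="+"):
        return GeneModel("g", "chr1", strand, 3001, 5000)

    def test_uniform_methylation_flat_profile(self):
        records = [
            CytosineRecord("chr1", p, "+", 8, 2, "CpG") for p in range(1001, 7001, 25)
        ]
        prof = metagene_profile(make_methylome(records), [self.make_gene()])
        bins = prof.all_bins()
        assert np.allclose(bins[~np.isnan(bins)], 0.8)

    def test_flank_body_separation(self):
        records = []
        for p in range(1001, 3001, 25):
            records.append(CytosineRecord("chr1", p, "+", 0, 10, "CpG"))
        for p in range(3001, 5001, 25):
            records.append(CytosineRecord("chr1", p, "+", 10, 0, "CpG"))
        for p in range(5001, 7001, 25):
            records.append(CytosineRecord("chr1", p, "+", 0, 10, "CpG"))
        prof = metagene_profile(make_methylome(records), [self.make_gene()])
        assert np.allclose(prof.upstream, 0.0)
        assert np.allclose(prof.body, 1.0)
        assert np.allclose(prof.downstream, 0.0)

    def test_minus_strand_orientation(self):
        # gradient along the chromosome: on a minus-strand gene the
        # upstream flank is the high-coordinate side
        records = [
            CytosineRecord("chr1", p, "+", (10 if p > 5000 else 0), 10, "CpG")
            for p in range(1001, 7001, 20)
        ]
        prof = metagene_profile(make_methylome(records), [self.make_gene("-")])
        assert np.nanmean(prof.upstream) > np.nanmean(prof.downstream)

    def test_single_gene_hand_pooled_bins(self, rng):
        gene = GeneModel("g", "chr1", "+", 1001, 3000)
        pos = np.sort(rng.choice(np.arange(1001, 3001), size=60, replace=False))
        meth = rng.integers(0, 15, 60)
        unmeth = rng.integers(1, 15, 60)
        records = [
            CytosineRecord("chr1", int(p), "+", int(m), int(u), "CpG")
            for p, m, u in zip(pos, meth, unmeth)
        ]
        prof = metagene_profile(make_methylome(records), [gene], n_bins=20)
        # brute-force pooling oracle
        width = 2000
        for b in range(20):
            lo = 1001 + b * width // 20
            hi = 1001 + (b + 1) * width // 20 - 1
            sel = (pos >= lo) & (pos <= hi)
            if sel.sum() == 0:
                assert np.isnan(prof.body[b])
            else:
                expected = meth[sel].sum() / (meth[sel].sum() + unmeth[sel].sum())
                assert prof.body[b] == pytest.approx(expected)


class TestSymmetricMerge:
    def test_pairs_are_summed(self):
        mset = make_methylome(
            [
                CytosineRecord("chr1", 10, "+", 3, 2, "CpG"),
                CytosineRecord("chr1", 11, "-", 1, 4, "CpG"),
                CytosineRecord("chr1", 50, "+", 2, 2, "CpG"),
            ]
        )
        merged = merge_symmetric_cpgs(mset)
        recs = {r.pos: r for r in merged.records()}
        assert recs[10].n_meth == 4 and recs[10].n_unmeth == 6
        assert recs[50].n_meth == 2
        assert len(merged) == 2


def test_context_separation_on_synthetic_bins(default_dataset):
    """CpG bins sit high and CHH bins low, per the planted baselines."""
    mset = default_dataset.methylomes["aml"][0]
    sizes = default_dataset.chrom_sizes_by_species["aml"]
    cpg = [b.level for b in bin_levels(mset, context="CpG", chrom_sizes=sizes) if b.n_sites > 0]
    chh = [b.level for b in bin_levels(mset, context="CHH", chrom_sizes=sizes) if b.n_sites > 0]
    assert np.median(cpg) > 0.5 > np.median(chh)
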