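"""GeTMM normalization against an independent straight-line oracle."""

import numpy as np
import pandas as pd
import pytest

from convergemeth.io_formats import CountTable, SampleMeta, ValidationError
from convergemeth.expression import (
    OrthoMap,
    assemble_ortho_matrix,
    coefficient_of_variation,
    filter_zero_genes,
    getmm,
    rpk,
    tmm_factors,
)


def oracle_tmm_pair(obs, ref, trim_m=0.3, trim_a=0.05):
    """Straight-line TMM factor of one column against a reference column."""
    obs = np.asarray(obs, float)
    ref = np.asarray(ref, float)
    n_o, n_r = obs.sum(), ref.sum()
    m_vals, a_vals, weights = [], [], []
    for y, yr in zip(obs, ref):
        if y > 0 and yr > 0:
            m_vals.append(np.log2((y / n_o) / (yr / n_r)))
            a_vals.append(0.5 * np.log2((y / n_o) * (yr / n_r)))
            weights.append((n_o - y) / (n_o * y) + (n_r - yr) / (n_r * yr))
    m_vals, a_vals, weights = map(np.array, (m_vals, a_vals, weights))
    if m_vals.size == 0 or np.max(np.abs(m_vals)) < 1e-6:
        return 1.0
    n = m_vals.size
    lo_m, lo_a = np.floor(n * trim_m) + 1, np.floor(n * trim_a) + 1
    hi_m, hi_a = n + 1 - lo_m, n + 1 - lo_a
    rm = pd.Series(m_vals).rank().to_numpy()
    ra = pd.Series(a_vals).rank().to_numpy()
    keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    return 2 ** (np.sum(m_vals[keep] / weights[keep]) / np.sum(1.0 / weights[keep]))


def oracle_getmm(counts, lengths):
    """Brute-force GeTMM: RPK, pairwise TMM vs UQ-chosen reference, CPM-style scale."""
    counts = np.asarray(counts, float)
    r = counts / (lengths[:, None] / 1000.0)
    lib = r.sum(axis=0)
    uq = np.array([np.quantile(r[:, j] / lib[j], 0.75) for j in range(r.shape[1])])
    ref = int(np.argmin(np.abs(uq - uq.mean())))
    f = np.array([oracle_tmm_pair(r[:, j], r[:, ref]) for j in range(r.shape[1])])
    f = f / np.exp(np.mean(np.log(f)))
    return r / (r.sum(axis=0) * f) * 1e6, f


def make_table(counts, lengths, species="aml"):
    counts = np.asarray(counts)
    return CountTable(
        gene_ids=[f"g{i}" for i in range(counts.shape[0])],
        lengths_bp=np.asarray(lengths),
        counts=counts,
        samples=[SampleMeta(f"s{j}", species) for j in range(counts.shape[1])],
    )


class TestAssembly:
    def make_inputs(self):
        rng = np.random.default_rng(0)
        tables = {}
        for sp in ("aml", "afu", "umr"):
            counts = rng.integers(0, 50, size=(4, 2))
            tables[sp] = CountTable(
                gene_ids=[f"{sp}_g{i}" for i in range(4)],
                lengths_bp=np.array([1000, 2000, 1500, 800]),
                counts=counts,
                samples=[SampleMeta(f"{sp}_{j}", sp) for j in range(2)],
            )
        ortho = OrthoMap(
            pd.DataFrame(
                {sp: [f"{sp}_g{i}" for i in range(4)] for sp in ("aml", "afu", "umr")},
                index=[f"OG{i}" for i in range(4)],
            )
        )
        return tables, ortho

    def test_shape_and_lengths(self):
        tables, ortho = self.make_inputs()
        joined = assemble_ortho_matrix(tables, ortho)
        assert joined.counts.shape == (4, 6)
        assert joined.lengths_bp.shape == (4, 6)

    def test_missing_gene_raises(self):
        tables, ortho = self.make_inputs()
        ortho.table.iloc[0, 0] = "nonexistent"
        with pytest.raises(ValidationError, match="OG0"):
            assemble_ortho_matrix(tables, ortho)

    def test_sample_permutation_only_permutes_columns(self):
        tables, ortho = self.make_inputs()
        joined = assemble_ortho_matrix(tables, ortho)
        swapped = dict(tables)
        t = tables["aml"]
        swapped["aml"] = CountTable(
            gene_ids=t.gene_ids,
            lengths_bp=t.lengths_bp,
            counts=t.counts[:, ::-1],
            samples=t.samples[::-1],
        )
        joined2 = assemble_ortho_matrix(swapped, ortho)
        assert np.array_equal(joined2.counts[:, 0], joined.counts[:, 1])
        assert np.array_equal(joined2.counts[:, 2:], joined.counts[:, 2:])


class TestRpk:
    @pytest.mark.parametrize(
        "count,length,expected", [(10, 1000, 10.0), (0, 1000, 0.0), (7, 500, 14.0)]
    )
    def test_values(self, count, length, expected):
        assert rpk(np.array([[count]]), np.array([length]))[0, 0] == expected

    def test_zero_length_rejected(self):
        with pytest.raises(ValidationError):
            rpk(np.array([[1]]), np.array([0]))


class TestTmm:
    def test_identical_columns_give_unit_factors(self):
        mat = np.tile(np.array([[5.0], [10.0], [1.0], [20.0], [3.0]]), (1, 2))
        assert np.allclose(tmm_factors(mat), [1.0, 1.0])

    def test_pure_depth_difference_absorbed(self):
        rng = np.random.default_rng(1)
        col = rng.integers(1, 200, size=50).astype(float)
        mat = np.column_stack([col, 2 * col])
        assert np.allclose(tmm_factors(mat), [1.0, 1.0], atol=1e-9)

    def test_outlier_gene_trimmed_factor_matches_oracle(self):
        rng = np.random.default_rng(2)
        base = rng.integers(10, 100, size=5).astype(float)
        mat = np.column_stack([base, base.copy()])
        mat[0, 1] *= 100.0
        ours = tmm_factors(mat, ref_sample=0)
        f = oracle_tmm_pair(mat[:, 1], mat[:, 0])
        expected = np.array([1.0, f]) / np.exp(np.mean(np.log([1.0, f])))
        assert np.allclose(ours, expected, atol=1e-12)
        assert ours[1] / ours[0] < 1  # sample 2 scaled down after trimming

    def test_all_zero_sample_is_error(self):
        mat = np.column_stack([np.arange(1, 6, dtype=float), np.zeros(5)])
        with pytest.raises(ValidationError, match="1"):
            tmm_factors(mat)


class TestGetmm:
    def test_single_sample_sums_to_one_million(self):
        t = make_table(np.array([[10], [20], [5]]), np.array([1000, 500, 2000]))
        expr = getmm(t)
        assert expr.norm_factors[0] == 1.0
        assert np.isclose(expr.values.sum(), 1e6)

    def test_duplicated_column_gives_identical_columns(self):
        rng = np.random.default_rng(3)
        counts = rng.integers(0, 100, size=(30, 1))
        t = make_table(np.hstack([counts, counts]), rng.integers(200, 3000, size=30))
        expr = getmm(t)
        assert np.allclose(expr.values[:, 0], expr.values[:, 1])

    def test_column_sum_identity(self):
        rng = np.random.default_rng(4)
        t = make_table(rng.integers(0, 300, size=(50, 6)), rng.integers(200, 5000, size=50))
        expr = getmm(t)
        expected = 1e6 / expr.norm_factors
        assert np.allclose(expr.values.sum(axis=0), expected, rtol=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 500, size=(50, 6))
        counts[rng.random(size=counts.shape) < 0.1] = 0
        lengths = rng.integers(200, 5000, size=50)
        t = make_table(counts, lengths)
        expr = getmm(t)
        oracle_vals, oracle_f = oracle_getmm(counts, lengths)
        assert np.allclose(expr.norm_factors, oracle_f, atol=1e-12)
        assert np.allclose(expr.values, oracle_vals, atol=1e-9)

    def test_scaling_one_sample_leaves_its_values_unchanged(self):
        """Depth is fully absorbed: M and A values are proportion-based, so
        with unit weights the factors (and hence GeTMM values) are exactly
        invariant to rescaling one library.  (The inverse-variance precision
        weights, on by default, depend on absolute depth and make this hold
        only approximately, which is inherent to weighted TMM.)"""
        rng = np.random.default_rng(5)
        counts = rng.integers(1, 300, size=(40, 4))
        lengths = rng.integers(200, 4000, size=40)
        expr = getmm(make_table(counts, lengths), weighting=False)
        scaled = counts.copy()
        scaled[:, 2] *= 7
        expr2 = getmm(make_table(scaled, lengths), weighting=False)
        assert np.allclose(expr.values[:, 2], expr2.values[:, 2], rtol=1e-6)
        # with precision weights on, the change stays modest
        w1 = getmm(make_table(counts, lengths))
        w2 = getmm(make_table(scaled, lengths))
        assert np.allclose(w1.values[:, 2], w2.values[:, 2], rtol=0.1)


class TestZeroFilter:
    def build(self, values):
        samples = [
            SampleMeta("a1", "aml"), SampleMeta("a2", "aml"),
            SampleMeta("u1", "umr"), SampleMeta("u2", "umr"),
        ]
        from convergemeth.expression import NormalizedExpr

        return NormalizedExpr(
            ortho_ids=[f"OG{i}" for i in range(len(values))],
            samples=samples,
            values=np.asarray(values, float),
            norm_factors=np.ones(4),
            lib_sizes=np.full(4, 100),
        )

    def test_species_all_zero_removed(self):
        expr = self.build([[0, 0, 5, 6], [1, 0, 5, 6], [0, 0, 0, 0]])
        kept = filter_zero_genes(expr)
        assert kept.ortho_ids == ["OG1"]

    def test_all_samples_policy(self):
        expr = self.build([[0, 0, 5, 6], [0, 0, 0, 0]])
        kept = filter_zero_genes(expr, policy="all_samples_zero")
        assert kept.ortho_ids == ["OG0"]


class TestCv:
    def test_constant_row_zero(self):
        assert coefficient_of_variation(np.array([[4.0, 4.0, 4.0]]))[0] == 0.0

    def test_two_point_row(self):
        # sd of (1, 3) with n-1 denominator is sqrt(2); mean 2
        assert np.isclose(coefficient_of_variation(np.array([[1.0, 3.0]]))[0], np.sqrt(2) / 2)

    def test_zero_mean_undefined(self):
        assert np.isnan(coefficient_of_variation(np.array([[0.0, 0.0]]))[0])


def test_normalization_reduces_cv_under_depth_differences(default_dataset):
    """With a 3x deeper bear library, GeTMM lowers the mean per-gene CV."""
    assembled = assemble_ortho_matrix(default_dataset.count_tables, default_dataset.ortho_map)
    raw_cv = coefficient_of_variation(assembled.counts.astype(float))
    expr = getmm(assembled)
    norm_cv = coefficient_of_variation(expr.values)
    assert np.nanmean(norm_cv) <= np.nanmean(raw_cv)
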