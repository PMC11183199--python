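"""Liftover against exhaustive per-base mapping tables; joint matrix rules."""

import numpy as np
import pytest

from convergemeth.io_formats import Chain, CytosineRecord, SampleMeta, ValidationError
from convergemeth.crossmap import (
    ChainSet,
    build_joint_matrix,
    invert_chain,
    liftover_position,
    liftover_positions,
)
from convergemeth.methylome import MethylomeSet

from conftest import make_methylome


def per_base_table(chain):
    """Exhaustive 0-based target -> query map built by walking each base."""
    table = {}
    t = chain.t_start
    q = chain.q_start
    for size, dt, dq in chain.blocks:
        for off in range(size):
            qq = q + off
            if chain.q_strand == "-":
                qq = chain.q_size - qq - 1
            table[t + off] = qq
        t += size + dt
        q += size + dq
    return table


def random_chain(rng, q_minus=False):
    n_blocks = int(rng.integers(1, 8))
    blocks = []
    for i in range(n_blocks):
        size = int(rng.integers(20, 400))
        dt = int(rng.integers(0, 120)) if i < n_blocks - 1 else 0
        dq = int(rng.integers(0, 120)) if i < n_blocks - 1 else 0
        blocks.append((size, dt, dq))
    t_start = int(rng.integers(0, 500))
    q_start = int(rng.integers(0, 500))
    t_span = sum(s + dt for s, dt, _ in blocks)
    q_span = sum(s + dq for s, _, dq in blocks)
    t_size = t_start + t_span + int(rng.integers(0, 300))
    q_size = q_start + q_span + int(rng.integers(0, 300))
    return Chain(
        score=float(rng.integers(1, 1000)),
        t_name="chrT",
        t_size=t_size,
        t_strand="+",
        t_start=t_start,
        t_end=t_start + t_span,
        q_name="chrQ",
        q_size=q_size,
        q_strand="-" if q_minus else "+",
        q_start=q_start,
        q_end=q_start + q_span,
        blocks=blocks,
        chain_id="c",
    )


def identity_chain(size=10_000, name="chr1"):
    return Chain(1000.0, name, size, "+", 0, size, name, size, "+", 0, size,
                 [(size, 0, 0)], "id")


class TestLiftover:
    def test_identity(self):
        cs = ChainSet([identity_chain()])
        assert liftover_position(cs, "chr1", 1042, "+") == ("chr1", 1042, "+")

    def test_gap_and_offset(self):
        # first block 100 bp, dt=10: 0-based target 105 is in the gap,
        # 0-based target 115 maps to 0-based query 105
        chain = Chain(10, "chrT", 1000, "+", 0, 160, "chrQ", 1000, "+", 0, 150,
                      [(100, 10, 0), (50, 0, 0)], "c")
        cs = ChainSet([chain])
        assert liftover_position(cs, "chrT", 105 + 1) is None
        assert liftover_position(cs, "chrT", 115 + 1) == ("chrQ", 105 + 1, "+")

    def test_minus_strand_reflection(self):
        chain = Chain(10, "chrT", 100, "+", 10, 20, "chrQ", 100, "-", 30, 40,
                      [(10, 0, 0)], "c")
        cs = ChainSet([chain])
        mapped = liftover_position(cs, "chrT", 11, "+")  # 0-based 10 -> q rev 30
        assert mapped == ("chrQ", 100 - 30 - 1 + 1, "-")

    @pytest.mark.parametrize("q_minus", [False, True])
    @pytest.mark.parametrize("seed", range(10))
    def test_agrees_with_per_base_oracle(self, seed, q_minus):
        rng = np.random.default_rng(seed + (1000 if q_minus else 0))
        chain = random_chain(rng, q_minus)
        chain.validate()
        cs = ChainSet([chain])
        table = per_base_table(chain)
        for pos0 in range(chain.t_start, chain.t_end):
            mapped = liftover_position(cs, "chrT", pos0 + 1, "+")
            if pos0 in table:
                expect_strand = "-" if q_minus else "+"
                assert mapped == ("chrQ", table[pos0] + 1, expect_strand)
            else:
                assert mapped is None
        # outside the chain span nothing maps
        assert liftover_position(cs, "chrT", chain.t_end + 1) is None

    @pytest.mark.parametrize("seed", range(5))
    def test_vectorised_matches_scalar(self, seed):
        rng = np.random.default_rng(seed)
        chains = [random_chain(rng) for _ in range(3)]
        cs = ChainSet(chains)
        positions = rng.integers(1, 2000, size=300)
        out, ok = liftover_positions(cs, "chrT", positions)
        for p, o, k in zip(positions, out, ok):
            scalar = liftover_position(cs, "chrT", int(p))
            if k:
                assert scalar is not None and scalar[1] == o
            else:
                assert scalar is None

    @pytest.mark.parametrize("q_minus", [False, True])
    def test_round_trip_through_inverted_chain(self, q_minus):
        rng = np.random.default_rng(42 + q_minus)
        chain = random_chain(rng, q_minus)
        cs = ChainSet([chain])
        inv = invert_chain(chain)
        inv.validate()
        cs_inv = ChainSet([inv])
        for pos0 in range(chain.t_start, chain.t_end):
            mapped = liftover_position(cs, "chrT", pos0 + 1, "+")
            if mapped is None:
                continue
            back = liftover_position(cs_inv, mapped[0].replace("chrQ", "chrQ"), mapped[1], mapped[2])
            assert back is not None
            assert back[1] == pos0 + 1
            assert back[2] == "+"

    def test_highest_score_chain_wins(self):
        low = identity_chain()
        low.score = 1.0
        shifted = Chain(999.0, "chr1", 10_000, "+", 0, 5000, "chr9", 10_000, "+", 100, 5100,
                       [(5000, 0, 0)], "hi")
        cs = ChainSet([low, shifted])
        assert liftover_position(cs, "chr1", 50) == ("chr9", 150, "+")
        # beyond the high-scoring chain the low one covers
        assert liftover_position(cs, "chr1", 6000) == ("chr1", 6000, "+")


class TestJointMatrix:
    def build_sets(self, positions, cov=20, meth=10, species="aml", n_samples=2):
        sets = []
        for j in range(n_samples):
            records = [
                CytosineRecord("chr1", int(p), "+", meth, cov - meth, "CpG")
                for p in positions
            ]
            sets.append(
                MethylomeSet(records, SampleMeta(f"{species}_{j}", species, species))
            )
        return sets

    def test_identity_chains_keep_common_sites(self):
        ref = self.build_sets([100, 200, 300])
        other = self.build_sets([100, 200, 300], species="umr")
        cs = ChainSet([identity_chain()])
        joint = build_joint_matrix(ref, {"umr": (other, cs)})
        assert joint.n_sites == 3
        assert joint.meth.shape == (3, 4)
        assert not np.isnan(joint.levels).any()

    def test_unmapped_site_dropped(self):
        chain = Chain(10, "chr1", 10_000, "+", 0, 10_000, "chr1", 9900, "+", 0, 9900,
                      [(150, 100, 0), (9750, 0, 0)], "c")
        # 0-based 199 falls in the dt gap; 0-based 299 maps to query 199,
        # where the other species does carry a covered CpG (its site 200)
        ref = self.build_sets([100, 200, 300])
        other = self.build_sets([100, 200, 300], species="umr")
        joint = build_joint_matrix(ref, {"umr": (other, ChainSet([chain]))})
        assert list(joint.pos) == [100, 300]

    def test_low_coverage_site_dropped(self):
        ref = self.build_sets([100, 200])
        records = [
            CytosineRecord("chr1", 100, "+", 10, 10, "CpG"),
            CytosineRecord("chr1", 200, "+", 2, 3, "CpG"),  # below 10x
        ]
        other = MethylomeSet(records, SampleMeta("umr_0", "umr", "umr"))
        joint = build_joint_matrix(ref, {"umr": ([other], ChainSet([identity_chain()]))})
        assert list(joint.pos) == [100]

    def test_planted_shared_sites_recovered_exactly(self, rng):
        # 5000 reference sites, of which 1000 lift and are covered everywhere
        all_pos = np.sort(rng.choice(np.arange(10, 200_000), size=5000, replace=False))
        shared = np.sort(rng.choice(all_pos, size=1000, replace=False))
        ref = self.build_sets(all_pos, n_samples=2)
        other = self.build_sets(shared, species="umr", n_samples=2)
        joint = build_joint_matrix(ref, {"umr": (other, ChainSet([identity_chain(300_000)]))})
        assert np.array_equal(joint.pos, shared)

    def test_zero_shared_sites_is_error(self):
        ref = self.build_sets([100])
        other = self.build_sets([5000], species="umr")
        with pytest.raises(ValidationError, match="shared"):
            build_joint_matrix(ref, {"umr": (other, ChainSet([identity_chain()]))})
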