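"""Differential-interaction statistics against independent oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rebel.diffint import (
    DifferentialInteraction,
    LibraryStats,
    ReplicateCall,
    adjust_fdr_distance_weighted,
    binomial_diff_test,
    call_consensus_differentials,
    match_interactions_4kb,
    overlap_mc_test,
)
from rebel.io_formats import GenomicInterval, InteractionRecord


def _binom_upper_tail(k: int, n: int, p: float) -> float:
    return sum(math.comb(n, j) * p**j * (1 - p) ** (n - j)
               for j in range(k, n + 1))


def _binom_lower_tail(k: int, n: int, p: float) -> float:
    return sum(math.comb(n, j) * p**j * (1 - p) ** (n - j)
               for j in range(0, k + 1))


def _bh_oracle(p):
    """Textbook Benjamini-Hochberg written independently of the package."""
    p = list(p)
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])
    adj = [0.0] * n
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = running
    return adj


class TestBinomialTest:
    def test_boundary_zero_counts(self):
        pg, pl = binomial_diff_test(0, 0, LibraryStats(100, 100))
        assert pg == pytest.approx(1.0)  # P[X >= 0] = 1

    def test_no_signal_when_counts_match(self):
        stats = LibraryStats(100_000, 100_000)
        pg, pl = binomial_diff_test(50, 50, stats)
        assert pg >= 0.4 and pl >= 0.4

    def test_enumeration_oracle_small_case(self):
        # p-hat = (20 + 0.5) / 205 = 0.1 exactly
        stats = LibraryStats(total_control=205, total_induced=20)
        pg, pl = binomial_diff_test(6, 20, stats)
        assert pg == pytest.approx(_binom_upper_tail(6, 20, 0.1), abs=1e-10)
        assert pl == pytest.approx(_binom_lower_tail(6, 20, 0.1), abs=1e-10)

    @pytest.mark.parametrize("seed", range(8))
    def test_enumeration_oracle_random_cases(self, seed):
        rng = np.random.default_rng(seed)
        n_ind = int(rng.integers(5, 51))
        n_ctrl = int(rng.integers(50, 500))
        o_ctrl = int(rng.integers(0, 40))
        o_ind = int(rng.integers(0, n_ind + 1))
        stats = LibraryStats(n_ctrl, n_ind)
        p_hat = (o_ctrl + 0.5) / n_ctrl
        pg, pl = binomial_diff_test(o_ind, o_ctrl, stats)
        assert pg == pytest.approx(
            _binom_upper_tail(o_ind, n_ind, p_hat), abs=1e-10)
        assert pl == pytest.approx(
            _binom_lower_tail(o_ind, n_ind, p_hat), abs=1e-10)

    def test_tails_share_atom_and_are_monotone(self):
        stats = LibraryStats(1000, 60)
        prev_gain, prev_loss = 1.0, 0.0
        for o in range(0, 61):
            pg, pl = binomial_diff_test(o, 10, stats)
            assert pg + pl >= 1.0 - 1e-12
            assert pg <= prev_gain + 1e-12
            assert pl >= prev_loss - 1e-12
            prev_gain, prev_loss = pg, pl

    def test_overflow_count_rejected(self):
        with pytest.raises(ValueError):
            binomial_diff_test(30, 0, LibraryStats(100, 20))

    @settings(derandomize=True, max_examples=80, deadline=None)
    @given(
        n_ctrl=st.integers(1, 500),
        o_ctrl=st.integers(0, 80),
        n_ind=st.integers(1, 300),
        frac=st.floats(0.0, 1.0),
    )
    def test_tails_always_cover_unit_mass(self, n_ctrl, o_ctrl, n_ind, frac):
        """The two tails share the atom at the observed count, so their sum
        is at least 1 for any counts and library sizes."""
        o_ind = min(n_ind, int(round(frac * n_ind)))
        pg, pl = binomial_diff_test(o_ind, o_ctrl,
                                    LibraryStats(n_ctrl, n_ind))
        assert 0.0 <= pg <= 1.0 and 0.0 <= pl <= 1.0
        assert pg + pl >= 1.0 - 1e-12


class TestStratifiedFdr:
    def test_single_stratum_is_plain_bh(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=25)
        d = rng.integers(0, 10_000, size=25)
        got = adjust_fdr_distance_weighted(p, d, n_strata=1)
        np.testing.assert_allclose(got, _bh_oracle(p), atol=1e-12)

    def test_all_ones_stay_one(self):
        got = adjust_fdr_distance_weighted([1.0] * 5, [10] * 5, 2)
        np.testing.assert_array_equal(got, 1.0)

    def test_matches_per_stratum_oracle(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=30)
        d = np.concatenate([
            rng.integers(0, 1000, 10),
            rng.integers(10_000, 20_000, 10),
            rng.integers(100_000, 200_000, 10),
        ])
        got = adjust_fdr_distance_weighted(p, d, n_strata=3)
        for lo, hi in ((0, 10), (10, 20), (20, 30)):
            np.testing.assert_allclose(
                got[lo:hi], _bh_oracle(p[lo:hi]), atol=1e-12
            )

    def test_never_below_raw_p(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(size=50)
        d = rng.integers(-1, 100_000, size=50)
        got = adjust_fdr_distance_weighted(p, d, n_strata=5)
        assert (got >= p - 1e-15).all()

    def test_empty_input(self):
        assert adjust_fdr_distance_weighted([], [], 3).size == 0

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        st.lists(
            st.tuples(st.floats(0.0, 1.0), st.integers(-1, 1_000_000)),
            min_size=1, max_size=50,
        ),
        st.integers(1, 5),
    )
    def test_adjusted_never_below_raw_and_bounded(self, rows, n_strata):
        p = [r[0] for r in rows]
        d = [r[1] for r in rows]
        got = adjust_fdr_distance_weighted(p, d, n_strata)
        assert (got >= np.asarray(p) - 1e-15).all()
        assert (got <= 1.0 + 1e-15).all()


def _record(gene="G1", oe_start=1000, chrom="chr1", bait_start=100_000):
    return InteractionRecord(
        bait=GenomicInterval(chrom, bait_start, bait_start + 1000),
        bait_gene=gene,
        other_end=GenomicInterval(chrom, oe_start, oe_start + 500),
        counts_control=(1, 1),
        counts_induced=(1, 1),
    )


def _call(adj_gain, adj_loss, records):
    n = len(records)
    return ReplicateCall(
        records=tuple(records),
        p_gain=np.asarray(adj_gain),
        p_loss=np.asarray(adj_loss),
        adj_p_gain=np.asarray(adj_gain),
        adj_p_loss=np.asarray(adj_loss),
    )


class TestConsensus:
    def test_two_of_three_same_direction_pass(self):
        recs = [_record()]
        calls = [
            _call([0.001], [1.0], recs),
            _call([0.002], [1.0], recs),
            _call([0.5], [0.6], recs),
        ]
        (diff,) = call_consensus_differentials(calls)
        assert diff.direction == "gained"
        assert diff.n_supporting_replicates == 2

    def test_mixed_directions_excluded(self):
        recs = [_record()]
        calls = [_call([0.001], [1.0], recs), _call([1.0], [0.001], recs)]
        assert call_consensus_differentials(calls) == []

    def test_fdr_threshold_boundary(self):
        recs = [_record()]
        passing = [_call([0.005], [1.0], recs), _call([0.005], [1.0], recs)]
        failing = [_call([0.02], [1.0], recs), _call([0.02], [1.0], recs)]
        assert len(call_consensus_differentials(passing, fdr=0.01)) == 1
        assert call_consensus_differentials(failing, fdr=0.01) == []

    def test_requires_two_replicate_comparisons(self):
        with pytest.raises(ValueError):
            call_consensus_differentials([_call([0.001], [1.0], [_record()])])


class TestMatcher:
    def test_identical_other_end_matches_at_zero(self):
        a, b = _record(), _record()
        assert match_interactions_4kb([a], [b]) == [(0, 0, 0)]

    def test_4001_bp_apart_is_no_match(self):
        a = _record(oe_start=1000)
        near = _record(oe_start=1000 + 4000)
        far = _record(oe_start=1000 + 4001)
        assert match_interactions_4kb([a], [near]) == [(0, 0, 4000)]
        assert match_interactions_4kb([a], [far]) == []

    def test_different_gene_or_chrom_never_match(self):
        a = _record(gene="G1")
        assert match_interactions_4kb([a], [_record(gene="G2")]) == []
        assert match_interactions_4kb(
            [a], [_record(chrom="chr2")]
        ) == []

    def test_equals_quadratic_oracle(self):
        rng = np.random.default_rng(7)
        genes = [f"G{i}" for i in range(5)]
        mk = lambda: _record(
            gene=genes[rng.integers(5)],
            oe_start=int(rng.integers(0, 30_000)),
        )
        set_a = [mk() for _ in range(40)]
        set_b = [mk() for _ in range(40)]
        expected = []
        for i, a in enumerate(set_a):
            best = None
            for j, b in enumerate(set_b):
                if (a.bait_gene != b.bait_gene
                        or a.other_end.chrom != b.other_end.chrom):
                    continue
                dist = abs(a.other_end.midpoint - b.other_end.midpoint)
                if dist > 4000:
                    continue
                cand = (dist, b.other_end.start, j)
                if best is None or cand < best:
                    best = cand
            if best is not None:
                expected.append((i, best[2], best[0]))
        assert match_interactions_4kb(set_a, set_b) == expected


class TestOverlapMonteCarlo:
    def test_saturated_query(self):
        target = [_record(gene=f"G{i}", oe_start=i * 20_000) for i in range(12)]
        res = overlap_mc_test(target[:6], target, universe=target,
                              n_sims=200, seed=1)
        assert res["observed"] == 6

    def test_disjoint_query_observes_zero(self):
        target = [_record(gene=f"G{i}") for i in range(5)]
        query = [_record(gene=f"H{i}") for i in range(3)]
        res = overlap_mc_test(query, target, universe=query + target,
                              n_sims=100, seed=1)
        assert res["observed"] == 0

    def test_empirical_p_matches_hypergeometric(self):
        # universe of 200 distinct interactions, 50 of them in the target:
        # the null overlap of a random 30-subset is hypergeometric.
        universe = [
            _record(gene=f"G{i}", oe_start=i * 50_000) for i in range(200)
        ]
        target = universe[:50]
        query = universe[41:71]  # observed overlap 9, near the null mean 7.5
        res = overlap_mc_test(query, target, universe=universe,
                              n_sims=4000, seed=2)
        assert res["observed"] == 9
        # exact tail P[X >= 9], X ~ Hypergeom(N=200, K=50, n=30)
        tail = sum(
            math.comb(50, k) * math.comb(150, 30 - k) / math.comb(200, 30)
            for k in range(9, 31)
        )
        assert res["empirical_p"] == pytest.approx(tail, abs=0.03)
        assert res["null_mean"] == pytest.approx(30 * 50 / 200, abs=0.2)

    def test_zero_sims_rejected(self):
        with pytest.raises(ValueError):
            overlap_mc_test([], [], n_sims=0)
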