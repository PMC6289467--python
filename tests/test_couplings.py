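import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from oracles import count_rank
from seqgnm.couplings import (
    EmptyNetworkWarning,
    percentile_rank,
    sweep_threshold,
    threshold_contacts,
)
from seqgnm.elastic import structure_gnm
from seqgnm.io import CouplingTable
from seqgnm.synthetic import make_couplings, true_contacts

# integer scores keep strictly monotone transforms exactly representable
int_scores = st.lists(st.integers(-10_000, 10_000), min_size=1, max_size=60)


class TestPercentileRank:
    def test_forced_examples(self):
        np.testing.assert_allclose(percentile_rank([10, 20, 30]), [1 / 3, 2 / 3, 1.0])
        np.testing.assert_allclose(percentile_rank([5, 5]), [1.0, 1.0])

    def test_against_counting_oracle(self):
        rng = np.random.default_rng(0)
        scores = rng.random(1000)
        ranks = percentile_rank(scores)
        np.testing.assert_allclose(ranks, count_rank(scores))
        assert ranks.max() == 1.0 and ranks.min() == 1 / 1000

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            percentile_rank([])

    @given(int_scores)
    def test_monotone_transform_invariance(self, scores):
        base = percentile_rank(scores)
        affine = percentile_rank([2.0 * s + 1.0 for s in scores])
        np.testing.assert_allclose(base, affine)
        cubed = percentile_rank([float(s) ** 3 for s in scores])
        np.testing.assert_allclose(base, cubed)


def distinct_score_table(n_pairs=100, length=300, rng_seed=0):
    """Pairs (i, i+10) with distinct scores — separation never filters."""
    rng = np.random.default_rng(rng_seed)
    scores = rng.permutation(n_pairs) + 1.0
    entries = [(k + 1, k + 11, float(s)) for k, s in enumerate(scores)]
    return CouplingTable(length=length, entries=entries)


class TestThresholdContacts:
    def test_top_two_percent_of_100(self):
        net = threshold_contacts(distinct_score_table(), tau=0.98)
        assert len(net) == 2

    def test_tau_zero_keeps_everything_past_separation(self):
        table = CouplingTable(
            length=20, entries=[(1, 3, 0.5), (1, 5, 0.6), (2, 10, 0.7)]
        )
        net = threshold_contacts(table, tau=0.0)
        assert sorted((i, j) for i, j, _ in net.contacts) == [(1, 5), (2, 10)]

    def test_weights_are_percentile_ranks(self):
        # three scores whose ranks are 1/3, 2/3, 1; tau keeps the top two
        table = CouplingTable(length=20, entries=[(1, 9, 5.0), (2, 8, 3.0), (3, 9, 1.0)])
        net = threshold_contacts(table, tau=0.5)
        weights = {(i, j): w for i, j, w in net.contacts}
        assert weights == {(1, 9): 1.0, (2, 8): pytest.approx(2 / 3)}

    def test_size_non_increasing_in_tau(self):
        table = distinct_score_table()
        sizes = [len(threshold_contacts(table, tau=t)) for t in np.linspace(0, 0.99, 25)]
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))

    def test_kept_fraction_tracks_tau_for_distinct_scores(self):
        table = distinct_score_table(n_pairs=200)
        for tau in (0.5, 0.8, 0.95):
            kept = len(threshold_contacts(table, tau=tau))
            assert abs(kept / 200 - (1 - tau)) <= 1 / 200 + 1e-12

    def test_tie_block_kept_or_dropped_together(self):
        table = CouplingTable(
            length=30, entries=[(1, 10, 1.0), (2, 11, 1.0), (3, 12, 0.0), (4, 13, 0.0)]
        )
        net = threshold_contacts(table, tau=0.6)
        assert {(i, j) for i, j, _ in net.contacts} == {(1, 10), (2, 11)}

    def test_all_pairs_rank_universe_demotes_sparse_files(self):
        table = CouplingTable(length=30, entries=[(1, 10, 9.0), (2, 20, 1.0)])
        file_net = threshold_contacts(table, tau=0.6, rank_universe="file")
        assert len(file_net) == 1  # ranks 1/2 and 1 over the file
        all_net = threshold_contacts(table, tau=0.999, rank_universe="all_pairs")
        assert [w for _, _, w in all_net.contacts] == [1.0]

    def test_empty_result_warns(self):
        table = CouplingTable(length=20, entries=[(1, 2, 1.0)])  # below separation
        with pytest.warns(EmptyNetworkWarning):
            net = threshold_contacts(table, tau=0.0)
        assert len(net) == 0

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            threshold_contacts(distinct_score_table(), tau=1.0)
        with pytest.raises(ValueError, match="no entries"):
            threshold_contacts(CouplingTable(length=5, entries=[]))


class TestSweepThreshold:
    def test_single_tau_gives_single_pair(self, walk_chain, walk_profile):
        table = make_couplings(walk_chain, p_true=1.0, sigma=0.0, seed=3)
        out = sweep_threshold(table, walk_profile, taus=[0.95])
        assert len(out) == 1 and out[0][0] == 0.95

    def test_indicator_couplings_flat_above_boundary(self, walk_chain, walk_profile):
        # sigma=0 puts every true contact in a rank-1 tie; decoys sit at 2/3
        table = make_couplings(walk_chain, p_true=1.0, sigma=0.0, seed=3)
        rs = [r for _, r in sweep_threshold(table, walk_profile)]
        assert max(rs) - min(rs) < 1e-12
        assert min(rs) > 0.9

    def test_length_mismatch_rejected(self, walk_profile):
        table = CouplingTable(length=50, entries=[(1, 10, 1.0)])
        with pytest.raises(ValueError, match="length"):
            sweep_threshold(table, walk_profile)
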