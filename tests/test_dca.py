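"""Sequence weighting, mean-field coupling estimation, APC, consensus
ranking and the elevated/reduced residue-pair test."""

import math

import numpy as np
import pytest

from coevoscan.dca import (
    apc_correct,
    compute_sequence_weights,
    consensus_rank,
    elevated_reduced,
    estimate_couplings_meanfield,
)
from coevoscan.synth import MsaSpec, make_coupled_msa
from coevoscan.types import AlignedSequenceSet, AlignmentRecord


def msa_of(*rows, ids=None):
    ids = ids or [f"s{k}" for k in range(len(rows))]
    return AlignedSequenceSet.from_records(
        AlignmentRecord(i, r) for i, r in zip(ids, rows)
    )


class TestSequenceWeights:
    def test_identical_pair_shares_weight(self):
        w = compute_sequence_weights(msa_of("ACDEF", "ACDEF"), 0.95)
        assert np.allclose(w.weights, [0.5, 0.5])
        assert w.effective_n == pytest.approx(1.0)

    def test_all_distinct_full_weight(self):
        w = compute_sequence_weights(msa_of("ACDEF", "GHIKL", "MNPQR"), 0.95)
        assert np.allclose(w.weights, 1.0)

    def test_three_identical_plus_one(self):
        w = compute_sequence_weights(
            msa_of("ACDEF", "ACDEF", "ACDEF", "GHIKL"), 0.95
        )
        assert np.allclose(w.weights, [1 / 3, 1 / 3, 1 / 3, 1.0])
        assert w.effective_n == pytest.approx(2.0)

    def test_identity_over_nongap_columns_only(self):
        # identical over the 4 shared non-gap columns -> redundant
        w = compute_sequence_weights(msa_of("ACDE-", "ACDEF"), 0.95)
        assert np.allclose(w.weights, [0.5, 0.5])

    @pytest.mark.parametrize("threshold", [0.0, -0.1, 1.5])
    def test_threshold_bounds(self, threshold):
        with pytest.raises(ValueError):
            compute_sequence_weights(msa_of("ACDEF", "GHIKL"), threshold)


class TestApcCorrect:
    def test_two_columns_forced_to_zero(self):
        raw = np.array([[0.0, 2.0], [2.0, 0.0]])
        assert np.allclose(apc_correct(raw), 0.0)

    def test_constant_matrix_zeroed(self):
        raw = np.full((5, 5), 3.0)
        np.fill_diagonal(raw, 0.0)
        assert np.allclose(apc_correct(raw), 0.0, atol=1e-12)

    def test_three_by_three_hand_expansion(self):
        raw = np.array([[0.0, 4.0, 2.0],
                        [4.0, 0.0, 2.0],
                        [2.0, 2.0, 0.0]])
        # row means (over off-diagonal): 3, 3, 2; overall mean 8/3
        mean_all = 8 / 3
        expected = raw - np.outer([3, 3, 2], [3, 3, 2]) / mean_all
        np.fill_diagonal(expected, 0.0)
        assert np.allclose(apc_correct(raw), expected)

    def test_all_zero_passes_through(self):
        assert np.allclose(apc_correct(np.zeros((4, 4))), 0.0)


def mutual_information_ranking(msa):
    """Independent oracle: rank column pairs by empirical MI."""
    mat = msa.to_matrix()
    n, L = mat.shape
    best, best_mi = None, -1.0
    for i in range(L):
        for j in range(i + 1, L):
            joint = {}
            for a, b in zip(mat[:, i], mat[:, j]):
                joint[(a, b)] = joint.get((a, b), 0) + 1
            pi, pj = {}, {}
            for (a, b), c in joint.items():
                pi[a] = pi.get(a, 0) + c
                pj[b] = pj.get(b, 0) + c
            mi = sum(
                (c / n) * math.log((c / n) / ((pi[a] / n) * (pj[b] / n)))
                for (a, b), c in joint.items()
            )
            if mi > best_mi:
                best, best_mi = (i + 1, j + 1), mi
    return best


class TestMeanfieldCouplings:
    def test_planted_pair_tops_ranking(self, coupled_msa):
        table = estimate_couplings_meanfield(coupled_msa)
        i, j, _s = table.top(1)[0]
        assert (i, j) == (3, 7)
        assert mutual_information_ranking(coupled_msa) == (3, 7)

    def test_iid_columns_within_permutation_null(self):
        msa = make_coupled_msa(MsaSpec(seed=5, n_sequences=200, n_columns=15,
                                       planted_pairs=()))
        observed = estimate_couplings_meanfield(msa).scores.max()
        rng = np.random.default_rng(5)
        mat = msa.to_matrix().copy()
        null_max = []
        for _ in range(50):
            perm = np.column_stack([
                rng.permutation(mat[:, c]) for c in range(mat.shape[1])
            ])
            shuffled = AlignedSequenceSet.from_records(
                AlignmentRecord(f"p{k}", b"".join(perm[k]).decode())
                for k in range(perm.shape[0])
            )
            null_max.append(estimate_couplings_meanfield(shuffled).scores.max())
        assert observed <= np.quantile(null_max, 0.999) * 1.05

    def test_record_order_invariance(self, coupled_msa):
        table = estimate_couplings_meanfield(coupled_msa)
        reordered = AlignedSequenceSet.from_records(
            list(coupled_msa.records)[::-1]
        )
        table_r = estimate_couplings_meanfield(reordered)
        assert np.allclose(table.scores, table_r.scores, atol=1e-8)
        assert table.entries[0][:2] == table_r.entries[0][:2]

    def test_duplication_invariance_with_reweighting(self):
        msa = make_coupled_msa(MsaSpec(seed=9, n_sequences=100, n_columns=10))
        doubled = AlignedSequenceSet.from_records(
            list(msa.records)
            + [AlignmentRecord(r.seq_id + "x", r.residues)
               for r in msa.records]
        )
        t1 = estimate_couplings_meanfield(msa)
        t2 = estimate_couplings_meanfield(doubled)
        assert np.allclose(t1.scores, t2.scores, atol=1e-8)

    def test_degenerate_single_sequence_repeated(self):
        msa = msa_of("ACDEF", "ACDEF", "ACDEF")
        # fully redundant alignment: either an explicit error or null scores
        try:
            table = estimate_couplings_meanfield(msa)
        except ValueError:
            return
        assert np.allclose(table.scores, 0.0, atol=1e-6)


class TestConsensusRank:
    def test_planted_pair_always_top20(self):
        msa = make_coupled_msa(MsaSpec(seed=2, n_sequences=300, n_columns=20))
        cr = consensus_rank(msa, n_subsamples=20, subsample_size=100, seed=0)
        assert cr.percentages[(3, 7)][20] == 100.0
        assert cr.pairs[0] == (3, 7)

    def test_full_subsample_gives_all_or_nothing(self):
        msa = make_coupled_msa(MsaSpec(seed=3, n_sequences=60, n_columns=8))
        cr = consensus_rank(msa, n_subsamples=5, subsample_size=60, seed=1)
        for pcts in cr.percentages.values():
            assert all(v in (0.0, 100.0) for v in pcts.values())

    def test_same_seed_identical(self):
        msa = make_coupled_msa(MsaSpec(seed=4, n_sequences=80, n_columns=8))
        a = consensus_rank(msa, 5, 40, seed=9)
        b = consensus_rank(msa, 5, 40, seed=9)
        assert a == b

    def test_percentages_monotone_in_k(self):
        msa = make_coupled_msa(MsaSpec(seed=6, n_sequences=80, n_columns=10))
        cr = consensus_rank(msa, 10, 40, seed=2)
        for pcts in cr.percentages.values():
            assert pcts[2] <= pcts[5] <= pcts[10] <= pcts[20]

    def test_rejects_bad_sampling_plan(self):
        msa = make_coupled_msa(MsaSpec(seed=4, n_sequences=60, n_columns=8))
        with pytest.raises(ValueError):
            consensus_rank(msa, 0, 10, seed=0)
        with pytest.raises(ValueError):
            consensus_rank(msa, 5, 61, seed=0)


def exact_upper_tail(table):
    """Exhaustive hypergeometric tail over the 2x2 support (oracle)."""
    (a, b), (c, d) = table
    N, row1, col1 = a + b + c + d, a + b, a + c
    lo, hi = max(0, row1 + col1 - N), min(row1, col1)
    total = math.comb(N, col1)
    return sum(
        math.comb(row1, k) * math.comb(N - row1, col1 - k)
        for k in range(a, hi + 1)
    ) / total


class TestElevatedReduced:
    @pytest.fixture()
    def unit_weight_msa(self):
        # 100 rows, col1/col2 engineered to the table [[30,10],[10,50]]
        rows = (
            ["RE"] * 30 + ["RA"] * 10 + ["KE"] * 10 + ["KA"] * 50
        )
        pads = "ACDEFGHIKLMNPQRSTVWY"
        # two pad columns keep all 100 rows pairwise distinct (unit weights)
        return AlignedSequenceSet.from_records(
            AlignmentRecord(f"s{k:03d}", row + pads[k % 20] + pads[k // 20])
            for k, row in enumerate(rows)
        )

    def test_tail_matches_exhaustive_enumeration(self, unit_weight_msa):
        w = compute_sequence_weights(unit_weight_msa, 1.0)
        # force unit weights: rows are engineered distinct via the pad column
        assert np.allclose(w.weights, 1.0)
        enr = elevated_reduced(unit_weight_msa, w, 1, 2, "R", "E")
        assert enr.table == ((30, 10), (10, 50))
        assert enr.p_elevated == pytest.approx(
            exact_upper_tail(((30, 10), (10, 50))), rel=1e-9
        )
        # lower tail complements the strictly-greater upper tail
        assert enr.p_reduced == pytest.approx(
            1 - exact_upper_tail(((31, 9), (9, 51))), rel=1e-9
        )

    def test_absent_residue_gives_p_one(self, unit_weight_msa):
        w = compute_sequence_weights(unit_weight_msa, 1.0)
        enr = elevated_reduced(unit_weight_msa, w, 1, 2, "W", "E")
        assert enr.table[0] == (0, 0)
        assert enr.p_elevated == 1.0

    def test_transpose_symmetry(self, unit_weight_msa):
        w = compute_sequence_weights(unit_weight_msa, 1.0)
        fwd = elevated_reduced(unit_weight_msa, w, 1, 2, "R", "E")
        swapped = AlignedSequenceSet.from_records(
            AlignmentRecord(r.seq_id, r.residues[1] + r.residues[0]
                            + r.residues[2])
            for r in unit_weight_msa.records
        )
        rev = elevated_reduced(swapped, w, 1, 2, "E", "R")
        assert fwd.p_elevated == pytest.approx(rev.p_elevated, rel=1e-12)
        assert fwd.p_reduced == pytest.approx(rev.p_reduced, rel=1e-12)

    def test_gap_rows_excluded(self):
        from coevoscan.dca import SequenceWeights

        msa = msa_of("RE", "KE", "R-", "-E", "KA")
        w = SequenceWeights(weights=np.ones(5))
        enr = elevated_reduced(msa, w, 1, 2, "R", "E")
        # the two gapped rows drop out; unit weights equal raw counts
        assert enr.table == ((1, 0), (1, 1))
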