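"""Species-matched ortholog pairing, paired-alignment construction and
cross-subunit interface scoring."""

import numpy as np
import pytest

from coevoscan.contacts import ContactParams, cross_chain_distances
from coevoscan.dca import compute_sequence_weights, estimate_couplings_meanfield
from coevoscan.hetmer import (
    build_paired_alignment,
    cross_couplings,
    hetmer_s_score,
    identity_score,
    select_orthologs,
)
from coevoscan.synth import plant_contact_scores
from coevoscan.types import AlignedSequenceSet, AlignmentRecord, CouplingTable


def aln(*entries):
    return AlignedSequenceSet.from_records(
        AlignmentRecord(seq_id, seq, taxon_id=tax)
        for seq_id, seq, tax in entries
    )


class TestSelectOrthologs:
    A = aln(
        ("1QRY_A", "ACDEF", None),
        ("a_good", "ACDEF", 562),   # identity 5 vs query
        ("a_poor", "ACWWW", 562),   # identity 2
        ("a_only", "ACDEV", 7227),
        ("a_fly", "ACDEW", 9606),
    )
    B = aln(
        ("1QRY_B", "GHIKL", None),
        ("b_ecoli", "GHIKL", 562),
        ("b_human", "GHIKV", 9606),
        ("b_extra", "GHIWW", 4932),
    )

    def test_highest_scoring_candidate_retained(self):
        pairing = select_orthologs(self.A, self.B, "1QRY_A", "1QRY_B")
        assert pairing.pairs[562][0] == "a_good"
        assert pairing.pairs[562][1] == 5.0

    def test_one_sided_taxa_listed_unpaired(self):
        pairing = select_orthologs(self.A, self.B, "1QRY_A", "1QRY_B")
        assert set(pairing.pairs) == {562, 9606}
        assert pairing.unpaired == {7227: "A", 4932: "B"}

    def test_score_ties_break_lexicographically(self):
        msa_a = aln(
            ("1QRY_A", "ACDEF", None),
            ("z_cand", "ACDEF", 562),
            ("a_cand", "ACDEF", 562),
        )
        pairing = select_orthologs(msa_a, self.B, "1QRY_A", "1QRY_B")
        assert pairing.pairs[562][0] == "a_cand"
        assert 562 in pairing.ambiguous

    def test_record_order_invariance(self):
        shuffled = AlignedSequenceSet.from_records(
            list(self.A.records)[::-1]
        )
        p1 = select_orthologs(self.A, self.B, "1QRY_A", "1QRY_B")
        p2 = select_orthologs(shuffled, self.B, "1QRY_A", "1QRY_B")
        assert p1.pairs == p2.pairs

    def test_disjoint_taxa_rejected(self):
        only_fly = aln(("1QRY_B", "GHIKL", None), ("b1", "GHIKL", 7227))
        msa_a = aln(("1QRY_A", "ACDEF", None), ("a1", "ACDEF", 562))
        with pytest.raises(ValueError, match="no taxon"):
            select_orthologs(msa_a, only_fly, "1QRY_A", "1QRY_B")

    def test_identity_score_ignores_gap_columns(self):
        q = AlignmentRecord("q", "AC-EF")
        r = AlignmentRecord("r", "ACD-F")
        assert identity_score(r, q) == 3.0


class TestBuildPairedAlignment:
    def setup_method(self):
        self.msa_a = aln(
            ("1QRY_A", "ACDE", None),
            ("a1", "ACDE", 1), ("a2", "ACDF", 2), ("a3", "ACDG", 3),
        )
        self.msa_b = aln(
            ("1QRY_B", "GHIKLM", None),
            ("b1", "GHIKLM", 1), ("b2", "GHIKLW", 2), ("b3", "GHIKLY", 3),
        )
        self.pairing = select_orthologs(self.msa_a, self.msa_b,
                                        "1QRY_A", "1QRY_B")

    def test_concatenated_shape_and_split(self):
        paired, split = build_paired_alignment(self.pairing, self.msa_a,
                                               self.msa_b)
        assert len(paired) == 3
        assert paired.n_columns == 10
        assert split == 4

    def test_records_sorted_by_taxon(self):
        paired, _ = build_paired_alignment(self.pairing, self.msa_a,
                                           self.msa_b)
        taxa = [r.taxon_id for r in paired.records]
        assert taxa == sorted(taxa) == [1, 2, 3]

    def test_both_sides_cover_same_taxa(self):
        assert set(self.pairing.pairs) == {1, 2, 3}

    def test_single_pair_rejected(self):
        msa_a = aln(("1QRY_A", "ACDE", None), ("a1", "ACDE", 1))
        msa_b = aln(("1QRY_B", "GHIK", None), ("b1", "GHIK", 1))
        pairing = select_orthologs(msa_a, msa_b, "1QRY_A", "1QRY_B")
        with pytest.raises(ValueError, match="2 paired"):
            build_paired_alignment(pairing, msa_a, msa_b)


def all_pairs_scorer(msa):
    """Cheap stand-in scorer emitting every column pair with an arbitrary
    deterministic score (tests the cross-pair bookkeeping, not DCA)."""
    L = msa.n_columns
    iu, ju = np.triu_indices(L, k=1)
    scores = ((iu * 31 + ju * 17) % 101).astype(float)
    return CouplingTable(col_i=iu + 1, col_j=ju + 1, scores=scores)


class TestCrossCouplings:
    def test_tiny_cross_product(self):
        paired = AlignedSequenceSet.from_records([
            AlignmentRecord("t1", "ACDEG", taxon_id=1),
            AlignmentRecord("t2", "ACDFG", taxon_id=2),
        ])
        table = cross_couplings(paired, 2, all_pairs_scorer)
        assert len(table) == 2 * 3
        assert all(i <= 2 < j + 2 for i, j, _ in table.entries)

    def test_cross_product_at_published_subunit_lengths(self):
        # 161- and 190-column subunits pair into 30,590 cross couplings
        len_a, len_b = 161, 190
        paired = AlignedSequenceSet.from_records([
            AlignmentRecord(f"t{k}", "A" * (len_a + len_b), taxon_id=k)
            for k in range(2)
        ])
        table = cross_couplings(paired, len_a, all_pairs_scorer)
        assert len(table) == 30590 == len_a * len_b

    def test_planted_cross_pair_ranks_first(self, het_bundle):
        from coevoscan.hetmer import select_orthologs

        pairing = select_orthologs(het_bundle["msa_a"], het_bundle["msa_b"],
                                   "1HET_A", "1HET_B")
        paired, split = build_paired_alignment(
            pairing, het_bundle["msa_a"], het_bundle["msa_b"]
        )

        def scorer(a):
            return estimate_couplings_meanfield(a,
                                                compute_sequence_weights(a))

        table = cross_couplings(paired, split, scorer)
        assert table.top(1)[0][:2] == (4, 8)

    def test_empty_cross_set_rejected(self):
        paired = AlignedSequenceSet.from_records([
            AlignmentRecord("t1", "ACD", taxon_id=1),
            AlignmentRecord("t2", "ACE", taxon_id=2),
        ])
        with pytest.raises(ValueError):
            cross_couplings(paired, 1, all_pairs_scorer,
                            mapped_a=set(), mapped_b=set())


class TestHetmerSScore:
    def planted_table(self, het_bundle, seed=5):
        dists = cross_chain_distances(het_bundle["structure"],
                                      het_bundle["map_a"],
                                      het_bundle["map_b"])
        contacts = [p for p, d in dists.items() if d <= 5.0]
        return contacts, plant_contact_scores(
            contacts, list(dists), len(contacts), seed=seed, cross=True
        )

    def test_planted_interface_couplings_score_high(self, het_bundle):
        contacts, table = self.planted_table(het_bundle)
        assert len(contacts) == 6
        row = hetmer_s_score(table, het_bundle["structure"],
                             het_bundle["map_a"], het_bundle["map_b"],
                             ContactParams(r=5.0), n_pairs=200,
                             len_a=24, len_b=20)
        assert row.result.S >= 4.0
        assert row.result.L == 24 * 20
        assert row.result.D == 6

    def test_shuffled_scores_rarely_significant(self, het_bundle):
        _contacts, table = self.planted_table(het_bundle)
        rng = np.random.default_rng(0)
        low = sum(
            hetmer_s_score(
                CouplingTable(col_i=table.col_i.copy(),
                              col_j=table.col_j.copy(),
                              scores=rng.permutation(table.scores),
                              cross=True),
                het_bundle["structure"], het_bundle["map_a"],
                het_bundle["map_b"], ContactParams(r=5.0),
            ).result.S < 2.0
            for _ in range(100)
        )
        assert low >= 99

    def test_label_swap_invariance(self, het_bundle):
        _contacts, table = self.planted_table(het_bundle)
        fwd = hetmer_s_score(table, het_bundle["structure"],
                             het_bundle["map_a"], het_bundle["map_b"],
                             ContactParams(r=5.0))
        swapped = CouplingTable(col_i=table.col_j.copy(),
                                col_j=table.col_i.copy(),
                                scores=table.scores.copy(), cross=True)
        rev = hetmer_s_score(swapped, het_bundle["structure"],
                             het_bundle["map_b"], het_bundle["map_a"],
                             ContactParams(r=5.0))
        assert fwd.result.S == pytest.approx(rev.result.S)
        assert (fwd.result.X, fwd.result.d) == (rev.result.X, rev.result.d)

    def test_separated_chains_degenerate(self, het_bundle, dimer_msa):
        from coevoscan.contacts import map_structure_to_msa
        from coevoscan.synth import StructureSpec, make_toy_structure

        _contacts, table = self.planted_table(het_bundle)
        seq_a = het_bundle["msa_a"].get("1HET_A").residues
        seq_b = het_bundle["msa_b"].get("1HET_B").residues
        far = make_toy_structure(StructureSpec(
            sequence=seq_a, sequence_b=seq_b, geometry="hetdimer",
            chain_separation=100.0, structure_id="1HET",
        ))
        ma = map_structure_to_msa(het_bundle["msa_a"], far, "1HET_A")
        mb = map_structure_to_msa(het_bundle["msa_b"], far, "1HET_B")
        row = hetmer_s_score(table, far, ma, mb, ContactParams(r=5.0))
        assert row.result.degenerate
        assert row.result.D == 0


def test_pairing_histogram_renders(het_bundle):
    pairing = select_orthologs(het_bundle["msa_a"], het_bundle["msa_b"],
                               "1HET_A", "1HET_B")
    text = pairing.histogram("A")
    assert "histogram" in text and "|" in text
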