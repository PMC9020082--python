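"""Cross-subunit coupling analysis for heteromeric complexes.

Two alignments (one per subunit), each row labeled with an NCBI taxonomy id,
are reduced to one ortholog per species per side by keeping the record most
similar to the structure-linked query row; the retained pairs are
concatenated per species, couplings are estimated on the concatenation, and
only cross-subunit column pairs are scored against inter-chain contacts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .contacts import ContactParams, StructureMsaMap, cross_chain_distances
from .ica import IcaResult, RankedDichotomy, ica_scan_safe
from .types import AlignedSequenceSet, AlignmentRecord, CouplingTable, Structure


def identity_score(record: AlignmentRecord, query: AlignmentRecord) -> float:
    """Ungapped identity-weighted similarity: the count of identical residues
    over columns where neither row is gapped."""
    return float(sum(
        1
        for a, b in zip(record.residues, query.residues)
        if a == b and a != "-" and b != "-"
    ))


@dataclass(frozen=True)
class OrthologPairing:
    """Per-taxon best ortholog pair across the two alignments."""

    pairs: dict    # taxon_id -> (id_A, score_A, id_B, score_B)
    unpaired: dict  # taxon_id -> "A" | "B" (the side present)
    ambiguous: tuple  # taxon ids where a score tie was broken lexicographically
    scores_a: tuple
    scores_b: tuple

    def histogram(self, side: str = "A", bins: int = 20, width: int = 50) -> str:
        """Fixed-width text histogram of pairing scores on one side."""
        scores = np.asarray(self.scores_a if side == "A" else self.scores_b)
        if scores.size == 0:
            return "(no scores)"
        counts, edges = np.histogram(scores, bins=bins)
        peak = max(1, counts.max())
        lines = [f"pairing-score histogram, side {side} (n={scores.size})"]
        for c, lo, hi in zip(counts, edges[:-1], edges[1:]):
            bar = "#" * int(round(width * c / peak))
            lines.append(f"{lo:8.1f}-{hi:8.1f} |{bar} {c}")
        return "\n".join(lines)


def _best_per_taxon(msa, query, scorer):
    best: dict[int, tuple] = {}
    ties: set[int] = set()
    for rec in msa.records:
        if rec.taxon_id is None or rec.seq_id == query.seq_id:
            continue
        score = scorer(rec, query)
        cur = best.get(rec.taxon_id)
        if cur is None or score > cur[1]:
            best[rec.taxon_id] = (rec.seq_id, score)
            ties.discard(rec.taxon_id)
        elif score == cur[1]:
            ties.add(rec.taxon_id)
            if rec.seq_id < cur[0]:
                best[rec.taxon_id] = (rec.seq_id, score)
    return best, ties


def select_orthologs(
    msa_a: AlignedSequenceSet,
    msa_b: AlignedSequenceSet,
    query_a: str,
    query_b: str,
    scorer=identity_score,
) -> OrthologPairing:
    """Pick, per species present in both alignments, the record on each side
    scoring highest against that side's query; ties break to the
    lexicographically smaller id and are flagged as paralog-ambiguous."""
    qa = msa_a.get(query_a)
    qb = msa_b.get(query_b)
    best_a, ties_a = _best_per_taxon(msa_a, qa, scorer)
    best_b, ties_b = _best_per_taxon(msa_b, qb, scorer)
    shared = set(best_a) & set(best_b)
    if not shared:
        raise ValueError("no taxon is present in both alignments")
    pairs = {
        tax: (best_a[tax][0], best_a[tax][1], best_b[tax][0], best_b[tax][1])
        for tax in sorted(shared)
    }
    unpaired = {tax: "A" for tax in sorted(set(best_a) - shared)}
    unpaired.update({tax: "B" for tax in sorted(set(best_b) - shared)})
    return OrthologPairing(
        pairs=pairs,
        unpaired=unpaired,
        ambiguous=tuple(sorted((ties_a | ties_b) & shared)),
        scores_a=tuple(best_a[t][1] for t in sorted(shared)),
        scores_b=tuple(best_b[t][1] for t in sorted(shared)),
    )


def build_paired_alignment(
    pairing: OrthologPairing,
    msa_a: AlignedSequenceSet,
    msa_b: AlignedSequenceSet,
) -> tuple:
    """Concatenate the retained A and B rows per species.

    Returns (paired alignment, split) where columns 1..split come from
    alignment A and split+1.. from B; records are sorted by taxon id.
    """
    if len(pairing.pairs) < 2:
        raise ValueError("need at least 2 paired taxa")
    split = msa_a.n_columns
    records = []
    for tax in sorted(pairing.pairs):
        id_a, _, id_b, _ = pairing.pairs[tax]
        records.append(AlignmentRecord(
            seq_id=f"tax{tax}|{id_a}|{id_b}",
            residues=msa_a.get(id_a).residues + msa_b.get(id_b).residues,
            taxon_id=tax,
        ))
    return AlignedSequenceSet.from_records(records), split


def cross_couplings(
    paired: AlignedSequenceSet,
    split: int,
    scorer,
    mapped_a=None,
    mapped_b=None,
) -> CouplingTable:
    """Couplings on the concatenated alignment, restricted to cross-subunit
    pairs (col_i <= split < col_j). ``col_j`` is re-indexed into alignment
    B's own 1-based columns. Optional mapped-column sets drop pairs whose
    columns are unmapped to the query structures."""
    if not 1 <= split < paired.n_columns:
        raise ValueError(f"split {split} out of bounds")
    table = scorer(paired)
    keep = []
    for i, j, s in table.entries:
        if i <= split < j:
            jb = j - split
            if mapped_a is not None and i not in mapped_a:
                continue
            if mapped_b is not None and jb not in mapped_b:
                continue
            keep.append((i, jb, s))
    if not keep:
        raise ValueError("no cross-subunit coupling pairs retained")
    return CouplingTable.from_entries(keep, cross=True)


@dataclass(frozen=True)
class HetmerRow:
    pdb_id: str
    chains: str
    result: IcaResult
    n_pairs: int   # sequence pairs used
    len_a: int
    len_b: int

    def as_dict(self) -> dict:
        r = self.result
        return {
            "pdbid": self.pdb_id, "chains": self.chains,
            "S": round(r.S, 2), "nats": round(r.nats, 2),
            "L": r.L, "D": r.D, "X": r.X, "d": r.d,
            "F": round(r.F, 2) if r.F is not None else "",
            "n_seqs": self.n_pairs, "l1": self.len_a, "l2": self.len_b,
            "degenerate": int(r.degenerate),
        }


HETMER_COLUMNS = ["pdbid", "chains", "S", "nats", "L", "D", "X", "d", "F",
                  "n_seqs", "l1", "l2", "degenerate"]


def hetmer_s_score(
    couplings: CouplingTable,
    structure: Structure,
    map_a: StructureMsaMap,
    map_b: StructureMsaMap,
    params: ContactParams = ContactParams(r=5.0),
    n_pairs: int = 0,
    len_a: int = 0,
    len_b: int = 0,
) -> HetmerRow:
    """Score cross-subunit couplings against inter-chain contacts.

    Distinguished pairs have min all-atom inter-chain distance <= r (default
    5.0 A); no sequence-separation filter applies across chains. A warning
    is logged when no inter-chain atoms lie within 2r (chains may not touch)
    but the computation proceeds.
    """
    dists = cross_chain_distances(structure, map_a, map_b,
                                  params.include_hydrogens)
    if min(dists.values(), default=np.inf) > 2 * params.r:
        import logging
        logging.getLogger(__name__).warning(
            "no inter-chain atom pairs within %.1f A; chains %s and %s may "
            "not be in contact", 2 * params.r, map_a.chain_id, map_b.chain_id,
        )
    eligible = set(dists)
    ranked = [(i, j) for i, j, _s in couplings.entries if (i, j) in eligible]
    flags = tuple(dists[pair] <= params.r for pair in ranked)
    result = ica_scan_safe(RankedDichotomy(flags)) if ranked else \
        ica_scan_safe(RankedDichotomy(()))
    if len_a:
        result = result.with_F(len_a + len_b)
    return HetmerRow(
        pdb_id=structure.structure_id,
        chains=f"{map_a.chain_id}:{map_b.chain_id}",
        result=result,
        n_pairs=n_pairs,
        len_a=len_a,
        len_b=len_b,
    )
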