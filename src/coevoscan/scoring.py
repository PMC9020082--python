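"""S-scores for structures: coupling-vs-contact correspondence, the homomeric
interface increment (delta-S), structure ranking, and spatial-cluster
significance for pattern residues."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .contacts import (
    ContactParams,
    ContactSet,
    chains_adjacent,
    contact_set,
    map_structure_to_msa,
)
from .ica import (
    IcaResult,
    RankedDichotomy,
    degenerate_result,
    ica_scan_safe,
)
from .types import AlignedSequenceSet, CouplingTable, Structure


def _ordered_pairs(couplings: CouplingTable, mapped_columns, m: int):
    """Coupling entries restricted to mapped columns and the separation
    filter, in descending-score order with deterministic (i, j) tie-break."""
    mapped = set(mapped_columns)
    return [
        (i, j)
        for i, j, _s in couplings.entries  # already sorted desc, ties (i, j)
        if i in mapped and j in mapped and abs(i - j) >= m
    ]


def s_score(
    couplings: CouplingTable,
    contact_distances: ContactSet,
    msa_length: int | None = None,
) -> IcaResult:
    """Cut-point significance of the correspondence between the coupling
    ranking and the contact set.

    The ranked list is every coupling pair that survives the contact set's
    mapping and separation filter, ordered by descending score (ties broken
    lexicographically on the column pair); a pair is distinguished when its
    effective distance is within r. Degenerate intersections (no contacts,
    or nothing but contacts) yield a flagged S = 0 result.
    """
    eligible = set(contact_distances.distances)
    ranked_pairs = [
        (i, j) for i, j, _s in couplings.entries if (i, j) in eligible
    ]
    if not ranked_pairs:
        return degenerate_result(0, 0)
    in_contact = contact_distances.contacts()
    flags = [pair in in_contact for pair in ranked_pairs]
    result = ica_scan_safe(RankedDichotomy(flags=tuple(flags)))
    if msa_length:
        result = result.with_F(msa_length)
    return result


def delta_s(internal: IcaResult, merged: IcaResult) -> float:
    """Change in S upon admitting homomeric cross-interface distances.

    Values >= ~3 suggest residue pairs directly coupled through contacts
    between identical subunits; small or negative values suggest the
    interface is not under detectable coupling constraint.
    """
    if internal.L != merged.L:
        raise ValueError(
            f"internal (L={internal.L}) and merged (L={merged.L}) runs must "
            "rank the same pair list"
        )
    return merged.S - internal.S


@dataclass(frozen=True)
class RankRow:
    pdb_id: str
    chains: str  # "A" or "A:B"
    result: IcaResult
    delta_s: float | None = None

    def as_dict(self) -> dict:
        r = self.result
        return {
            "pdbid": self.pdb_id,
            "chains": self.chains,
            "S": round(r.S, 2),
            "nats": round(r.nats, 2),
            "L": r.L,
            "D": r.D,
            "X": r.X,
            "d": r.d,
            "F": round(r.F, 2) if r.F is not None else "",
            "dS": round(self.delta_s, 2) if self.delta_s is not None else "",
            "degenerate": int(r.degenerate),
        }


RANK_COLUMNS = ["pdbid", "chains", "S", "nats", "L", "D", "X", "d", "F", "dS",
                "degenerate"]


def rank_structures(
    msa: AlignedSequenceSet,
    couplings: CouplingTable,
    structures,
    params: ContactParams = ContactParams(),
    adjacency_margin: float = 4.0,
) -> list:
    """One row per structure-linked chain, plus one per adjacent homomeric
    chain pair (with delta-S), sorted by descending S.

    Chains are adjacent when any inter-chain atom pair lies within
    r + adjacency_margin. Homomeric pairs are only merged when the partner
    chain carries the same sequence as the scored chain.
    """
    structures = list(structures)
    by_id = {s.structure_id.lower(): s for s in structures}
    rows = []
    linked = [r for r in msa.records if r.structure_linked
              and r.pdb_id.lower() in by_id]
    if not linked:
        raise ValueError("no structure-linked alignment records match the "
                         "provided structures")
    for record in linked:
        structure = by_id[record.pdb_id.lower()]
        smap = map_structure_to_msa(msa, structure, record.seq_id)
        internal = contact_set(structure, smap, params)
        res_internal = s_score(couplings, internal, msa.n_columns)
        rows.append(RankRow(pdb_id=record.pdb_id, chains=smap.chain_id,
                            result=res_internal))
        base_seq = structure.chain(smap.chain_id).sequence()
        for other in structure.chains:
            if other.chain_id == smap.chain_id:
                continue
            if other.sequence() != base_seq:
                continue
            if not chains_adjacent(structure, smap.chain_id, other.chain_id,
                                   params.r + adjacency_margin):
                continue
            smap_b = map_structure_to_msa(
                msa, structure, record.seq_id, chain_id=other.chain_id
            )
            merged = contact_set(structure, [smap, smap_b], params)
            res_merged = s_score(couplings, merged, msa.n_columns)
            rows.append(RankRow(
                pdb_id=record.pdb_id,
                chains=f"{smap.chain_id}:{other.chain_id}",
                result=res_merged,
                delta_s=delta_s(res_internal, res_merged),
            ))
    rows.sort(key=lambda row: (-row.result.S, row.pdb_id, row.chains))
    return rows


# ---------------------------------------------------------------------------
# Spatial cluster significance (pattern residues)
# ---------------------------------------------------------------------------

def cluster_significance(
    structure: Structure,
    pattern_residues,
    chain_id: str | None = None,
) -> IcaResult:
    """Significance of pattern residues forming a spatial cluster.

    From every seed residue, all residues in scope are ordered by greedy
    single-linkage growth (repeatedly appending the residue with minimum
    all-atom distance to the grown set); the cut-point scan runs on that
    ordering with pattern residues distinguished. The best seed's result is
    reported with an extra Bonferroni factor equal to the number of seeds.
    """
    pattern = {
        key if len(key) == 3 else (key[0], key[1], " ")
        for key in pattern_residues
    }
    if len(pattern) < 2:
        raise ValueError("need at least 2 pattern residues")
    scope = []
    for chain in structure.chains:
        if chain_id is not None and chain.chain_id != chain_id:
            continue
        for res in chain.polymer_residues():
            scope.append(((chain.chain_id, res.resnum, res.icode), res))
    keys = [k for k, _ in scope]
    missing = pattern - set(keys)
    if missing:
        raise ValueError(f"pattern residues not in scope: {sorted(missing)}")
    n = len(scope)
    flags_by_key = np.array([k in pattern for k in keys])
    if flags_by_key.all():
        return degenerate_result(n, n)
    coords = [res.coord_array() for _, res in scope]
    dmat = np.empty((n, n))
    for i in range(n):
        dmat[i, i] = 0.0
        for j in range(i + 1, n):
            dmat[i, j] = dmat[j, i] = cdist(coords[i], coords[j]).min()

    seeds = np.flatnonzero(flags_by_key)
    best: IcaResult | None = None
    for seed in seeds:
        order = _greedy_growth_order(dmat, int(seed))
        result = ica_scan_safe(RankedDichotomy(tuple(flags_by_key[order])))
        if best is None or result.log10_p < best.log10_p:
            best = result
    assert best is not None
    log10_p = min(0.0, best.log10_p + np.log10(len(seeds)))
    return IcaResult(
        S=-log10_p,
        log10_p=log10_p,
        X=best.X,
        d=best.d,
        D=best.D,
        L=best.L,
        n_tests=best.n_tests * len(seeds),
        degenerate=best.degenerate,
    )


def _greedy_growth_order(dmat: np.ndarray, seed: int) -> list:
    n = dmat.shape[0]
    order = [seed]
    in_set = np.zeros(n, dtype=bool)
    in_set[seed] = True
    # min distance from each outside residue to the grown set
    mindist = dmat[seed].copy()
    mindist[seed] = np.inf
    for _ in range(n - 1):
        nxt = int(np.argmin(mindist))
        order.append(nxt)
        in_set[nxt] = True
        mindist = np.minimum(mindist, dmat[nxt])
        mindist[in_set] = np.inf
    return order
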