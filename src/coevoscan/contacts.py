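"""Structure-to-alignment mapping, residue distances, contacts, hydrogen bonds.

Residue-residue distances are all-atom minimum distances (optionally
including hydrogens), contacts are distances within a cutoff r subject to a
minimum alignment-column separation m for intra-chain pairs, and hydrogen
bonds are detected from donor-hydrogen-acceptor geometry.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .types import (
    AlignedSequenceSet,
    BACKBONE_ATOMS,
    Chain,
    Residue,
    Structure,
)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContactParams:
    """Search parameters: contact cutoff r (A), minimum separation m,
    hydrogen inclusion."""

    r: float = 4.0
    m: int = 5
    include_hydrogens: bool = True

    def __post_init__(self):
        if self.r <= 0:
            raise ValueError("r must be positive")
        if self.m < 0:
            raise ValueError("m must be >= 0")


# ---------------------------------------------------------------------------
# Structure <-> MSA mapping
# ---------------------------------------------------------------------------

@dataclass
class StructureMsaMap:
    """Partial injective mapping from 1-based MSA columns to chain residues."""

    seq_id: str
    chain_id: str
    column_to_residue: dict  # column -> (resnum, icode)
    unmapped_columns: list

    @property
    def mapped_columns(self) -> list:
        return sorted(self.column_to_residue)


def map_structure_to_msa(
    msa: AlignedSequenceSet,
    structure: Structure,
    seq_id: str,
    chain_id: str | None = None,
    max_mismatch: float = 0.05,
) -> StructureMsaMap:
    """Pair the ungapped residues of a structure-linked alignment row with a
    chain's polymer residues, in order.

    Columns aligned to a gap are unmapped; if the chain is shorter than the
    ungapped row, trailing columns are unmapped with a warning. More than
    ``max_mismatch`` residue-identity disagreement raises (wrong chain).
    """
    record = msa.get(seq_id)
    if chain_id is None:
        if not record.structure_linked:
            raise ValueError(
                f"{seq_id!r} is not structure-linked; pass chain_id explicitly"
            )
        chain_id = record.chain_id
    chain = structure.chain(chain_id)
    residues = chain.polymer_residues()
    columns = [
        (col + 1, aa) for col, aa in enumerate(record.residues) if aa != "-"
    ]
    n_pairable = min(len(columns), len(residues))
    if n_pairable == 0:
        raise ValueError(f"nothing to map between {seq_id} and chain {chain_id}")
    mismatches = sum(
        1
        for (_, aa), res in zip(columns[:n_pairable], residues[:n_pairable])
        if aa != "X" and res.one_letter != "X" and aa != res.one_letter
    )
    if mismatches / n_pairable > max_mismatch:
        raise ValueError(
            f"{mismatches}/{n_pairable} residue mismatches between alignment row "
            f"{seq_id!r} and chain {chain_id}; wrong chain?"
        )
    if mismatches:
        log.warning("%d/%d residue mismatches mapping %s onto chain %s",
                    mismatches, n_pairable, seq_id, chain_id)
    if len(residues) < len(columns):
        log.warning(
            "chain %s shorter than ungapped row %s; %d trailing columns unmapped",
            chain_id, seq_id, len(columns) - len(residues),
        )
    column_to_residue = {
        col: (res.resnum, res.icode)
        for (col, _aa), res in zip(columns[:n_pairable], residues[:n_pairable])
    }
    mapped = set(column_to_residue)
    unmapped = [c for c in range(1, msa.n_columns + 1) if c not in mapped]
    return StructureMsaMap(
        seq_id=seq_id,
        chain_id=chain_id,
        column_to_residue=column_to_residue,
        unmapped_columns=unmapped,
    )


# ---------------------------------------------------------------------------
# Distances and contacts
# ---------------------------------------------------------------------------

def min_residue_distance(
    res_a: Residue, res_b: Residue, include_hydrogens: bool = True
) -> float:
    """Minimum Euclidean distance over all atom pairs of two residues (A)."""
    a = res_a.coord_array(include_hydrogens)
    b = res_b.coord_array(include_hydrogens)
    return float(cdist(a, b).min())


@dataclass(frozen=True)
class ContactSet:
    """Distances and contact flags for distinguished column pairs."""

    distances: dict  # (col_i, col_j) -> effective distance (A)
    params: ContactParams
    merged: bool = False

    def contacts(self) -> set:
        return {p for p, d in self.distances.items() if d <= self.params.r}

    def __contains__(self, pair) -> bool:
        return pair in self.contacts()


def _residue_lookup(chain: Chain) -> dict:
    return {(r.resnum, r.icode): r for r in chain.residues}


def _pairwise_min_distances(residues_a, residues_b, include_hydrogens):
    """Min all-atom distance matrix between two residue lists."""
    coords_a = [r.coord_array(include_hydrogens) for r in residues_a]
    coords_b = [r.coord_array(include_hydrogens) for r in residues_b]
    out = np.empty((len(residues_a), len(residues_b)))
    for i, ca in enumerate(coords_a):
        for j, cb in enumerate(coords_b):
            out[i, j] = cdist(ca, cb).min()
    return out


def contact_set(
    structure: Structure,
    maps,
    params: ContactParams = ContactParams(),
) -> ContactSet:
    """Distinguished (contacting) column pairs for one chain or a homomeric
    chain pair.

    With a single StructureMsaMap, pairs (i, j) of mapped columns with
    |i - j| >= m and min all-atom distance <= r are contacts. With a pair of
    maps onto two chains carrying the same sequence (homomeric merge), the
    effective distance of (i, j) is the minimum of the internal distance and
    the two cross-chain distances i_A<->j_B and j_A<->i_B.
    """
    if isinstance(maps, StructureMsaMap):
        maps = [maps]
    maps = list(maps)
    if len(maps) not in (1, 2):
        raise ValueError("contact_set takes one map or a homomeric pair of maps")
    merged = len(maps) == 2
    primary = maps[0]
    chain_a = structure.chain(primary.chain_id)
    lut_a = _residue_lookup(chain_a)
    cols = primary.mapped_columns
    res_a = [lut_a[primary.column_to_residue[c]] for c in cols]
    dmat = _pairwise_min_distances(res_a, res_a, params.include_hydrogens)
    if merged:
        secondary = maps[1]
        if set(secondary.column_to_residue) != set(primary.column_to_residue):
            raise ValueError(
                "homomeric merge requires both chains mapped to the same columns"
            )
        chain_b = structure.chain(secondary.chain_id)
        lut_b = _residue_lookup(chain_b)
        res_b = [lut_b[secondary.column_to_residue[c]] for c in cols]
        cross = _pairwise_min_distances(res_a, res_b, params.include_hydrogens)
        dmat = np.minimum(dmat, np.minimum(cross, cross.T))
    distances = {}
    for ii in range(len(cols)):
        for jj in range(ii + 1, len(cols)):
            ci, cj = cols[ii], cols[jj]
            if abs(ci - cj) < params.m:
                continue
            distances[(ci, cj)] = float(dmat[ii, jj])
    return ContactSet(distances=distances, params=params, merged=merged)


def cross_chain_distances(
    structure: Structure,
    map_a: StructureMsaMap,
    map_b: StructureMsaMap,
    include_hydrogens: bool = True,
) -> dict:
    """Min all-atom inter-chain distances keyed by (column_in_A, column_in_B).

    Used for heteromeric interfaces, where the two maps index different
    alignments and every cross pair is kept (no sequence-separation filter).
    """
    chain_a = structure.chain(map_a.chain_id)
    chain_b = structure.chain(map_b.chain_id)
    lut_a = _residue_lookup(chain_a)
    lut_b = _residue_lookup(chain_b)
    cols_a = map_a.mapped_columns
    cols_b = map_b.mapped_columns
    res_a = [lut_a[map_a.column_to_residue[c]] for c in cols_a]
    res_b = [lut_b[map_b.column_to_residue[c]] for c in cols_b]
    dmat = _pairwise_min_distances(res_a, res_b, include_hydrogens)
    return {
        (ca, cb): float(dmat[i, j])
        for i, ca in enumerate(cols_a)
        for j, cb in enumerate(cols_b)
    }


def chains_adjacent(
    structure: Structure, chain_a: str, chain_b: str, cutoff: float
) -> bool:
    """True when any inter-chain atom pair lies within the cutoff."""
    coords_a = np.concatenate([
        r.coord_array() for r in structure.chain(chain_a).residues
    ])
    coords_b = np.concatenate([
        r.coord_array() for r in structure.chain(chain_b).residues
    ])
    return bool(cdist(coords_a, coords_b).min() <= cutoff)


# ---------------------------------------------------------------------------
# Hydrogen bonds
# ---------------------------------------------------------------------------

# sidechain donor heavy atoms (hydrogen must be attached) per residue type
SIDECHAIN_DONORS = {
    "ARG": {"NE", "NH1", "NH2"},
    "ASN": {"ND2"},
    "GLN": {"NE2"},
    "HIS": {"ND1", "NE2"},
    "LYS": {"NZ"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TRP": {"NE1"},
    "TYR": {"OH"},
    "CYS": {"SG"},
}

SIDECHAIN_ACCEPTORS = {
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
    "ASN": {"OD1"},
    "GLN": {"OE1"},
    "HIS": {"ND1", "NE2"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TYR": {"OH"},
    "MET": {"SD"},
}

_H_ATTACH_CUTOFF = 1.25  # A; covalent N-H/O-H bonds are ~0.95-1.05 A

HBOND_D_A_MAX = 3.5    # A donor-acceptor
HBOND_H_A_MAX = 2.5    # A hydrogen-acceptor
HBOND_ANGLE_MIN = 120  # degrees D-H-A


@dataclass(frozen=True)
class AtomRef:
    chain_id: str
    resnum: int
    icode: str
    resname: str
    atom_name: str

    def residue_key(self):
        return (self.chain_id, self.resnum, self.icode)

    def label(self) -> str:
        return f"{self.chain_id}:{self.resnum}:{self.resname}:{self.atom_name}"


@dataclass(frozen=True)
class HBond:
    donor: AtomRef
    hydrogen: AtomRef
    acceptor: AtomRef
    d_DA: float
    d_HA: float
    angle_DHA: float
    category: str  # sc2sc | sc2bb | bb2bb | het

    def residue_pair(self):
        """Order-free residue-level identity of the interaction."""
        return tuple(sorted([self.donor.residue_key(), self.acceptor.residue_key()]))


def _atom_group(res: Residue, atom: "str | None" = None, name: str = "") -> str:
    if not res.is_polymer:
        return "het"
    return "bb" if name in BACKBONE_ATOMS else "sc"


def _pair_category(res_d: Residue, name_d: str, res_a: Residue, name_a: str) -> str:
    gd = _atom_group(res_d, name=name_d)
    ga = _atom_group(res_a, name=name_a)
    if "het" in (gd, ga):
        return "het"
    if gd == ga == "bb":
        return "bb2bb"
    if gd == ga == "sc":
        return "sc2sc"
    return "sc2bb"


def _donor_groups(res: Residue):
    """(heavy atom, attached hydrogen) donor pairs of a residue."""
    out = []
    heavies = [a for a in res.atoms if not a.is_hydrogen]
    hydrogens = [a for a in res.atoms if a.is_hydrogen]
    if not hydrogens:
        return out
    hcoords = np.array([h.xyz for h in hydrogens])
    for heavy in heavies:
        if res.is_polymer:
            is_donor = heavy.name == "N" or heavy.name in SIDECHAIN_DONORS.get(
                res.resname, ()
            )
        else:
            is_donor = heavy.element in ("N", "O")
        if not is_donor:
            continue
        dist = np.linalg.norm(hcoords - np.asarray(heavy.xyz), axis=1)
        for h, dh in zip(hydrogens, dist):
            if dh <= _H_ATTACH_CUTOFF:
                out.append((heavy, h))
    return out


def _acceptors(res: Residue):
    out = []
    for atom in res.atoms:
        if atom.is_hydrogen:
            continue
        if res.is_polymer:
            if atom.name in ("O", "OXT") or atom.name in SIDECHAIN_ACCEPTORS.get(
                res.resname, ()
            ):
                out.append(atom)
        elif atom.element in ("O", "N", "F", "CL"):
            out.append(atom)
    return out


def detect_hbonds(
    structure: Structure,
    category_filter: "str | None" = None,
    residue_filter=None,
    d_DA_max: float = HBOND_D_A_MAX,
    d_HA_max: float = HBOND_H_A_MAX,
    angle_min: float = HBOND_ANGLE_MIN,
) -> list:
    """Geometric hydrogen-bond detection over all residue pairs.

    A bond requires d(D,A) <= 3.5 A, d(H,A) <= 2.5 A and angle(D,H,A) >= 120
    degrees (all configurable). ``category_filter`` restricts to one of
    {"sc2sc", "sc2bb", "bb2bb", "het"}; ``residue_filter`` is an optional set
    of (chain_id, resnum, icode) keys at least one partner must belong to.
    Donors without modeled hydrogens are skipped (warning logged once).
    """
    entries = []  # (chain, residue, donors, acceptors)
    missing_h = 0
    for chain in structure.chains:
        for res in chain.residues:
            donors = _donor_groups(res)
            acceptors = _acceptors(res)
            if not donors and any(
                not a.is_hydrogen
                and (a.name == "N" or a.name in SIDECHAIN_DONORS.get(res.resname, ()))
                for a in res.atoms
            ):
                missing_h += 1
            entries.append((chain.chain_id, res, donors, acceptors))
    if missing_h:
        log.warning("%d residues have donor atoms without modeled hydrogens", missing_h)

    bonds = []
    for cid_d, res_d, donors, _ in entries:
        for cid_a, res_a, _, acceptors in entries:
            if res_d is res_a:
                continue
            for heavy, hyd in donors:
                hpos = np.asarray(hyd.xyz)
                dpos = np.asarray(heavy.xyz)
                for acc in acceptors:
                    apos = np.asarray(acc.xyz)
                    d_da = float(np.linalg.norm(apos - dpos))
                    if d_da > d_DA_max:
                        continue
                    d_ha = float(np.linalg.norm(apos - hpos))
                    if d_ha > d_HA_max:
                        continue
                    v1 = dpos - hpos
                    v2 = apos - hpos
                    denom = np.linalg.norm(v1) * np.linalg.norm(v2)
                    if denom == 0:
                        continue
                    cosang = float(np.dot(v1, v2) / denom)
                    angle = float(np.degrees(np.arccos(np.clip(cosang, -1, 1))))
                    if angle < angle_min:
                        continue
                    category = _pair_category(res_d, heavy.name, res_a, acc.name)
                    if category_filter and category != category_filter:
                        continue
                    if residue_filter is not None:
                        keys = {
                            (cid_d, res_d.resnum, res_d.icode),
                            (cid_a, res_a.resnum, res_a.icode),
                        }
                        if not (keys & set(residue_filter)):
                            continue
                    bonds.append(HBond(
                        donor=AtomRef(cid_d, res_d.resnum, res_d.icode,
                                      res_d.resname, heavy.name),
                        hydrogen=AtomRef(cid_d, res_d.resnum, res_d.icode,
                                         res_d.resname, hyd.name),
                        acceptor=AtomRef(cid_a, res_a.resnum, res_a.icode,
                                         res_a.resname, acc.name),
                        d_DA=d_da,
                        d_HA=d_ha,
                        angle_DHA=angle,
                        category=category,
                    ))
    return bonds
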