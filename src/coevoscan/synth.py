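"""Synthetic fixtures with planted, known signal.

Coupled alignments (a planted column pair with tunable correlation over an
i.i.d. background), toy helical structures (ideal phi/psi backbone built
from internal coordinates, amide hydrogens, pseudo-sidechain probe atoms
that realise a requested contact map), multi-chain dimer/ring geometries,
jittered trajectories with an exact hydrogen-bond schedule, and coupling
tables with contacts planted at the top of the ranking.

Every generator is a pure function of its arguments (seed included).
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .types import (
    AlignedSequenceSet,
    AlignmentRecord,
    Atom,
    Chain,
    CouplingTable,
    ONE_TO_THREE,
    Residue,
    Structure,
    TrajectoryFrames,
)

SYNTH_ALPHABET = "ACDEFG"  # 6-letter subset keeps pair tables well populated

# ideal alpha-helix internal coordinates
_PHI, _PSI, _OMEGA = -57.0, -47.0, 180.0
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O, _B_N_H, _B_CA_CB = (
    1.458, 1.525, 1.329, 1.231, 1.010, 1.530)
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O, _A_N_CA_CB = (
    111.2, 116.2, 121.7, 120.8, 110.4)


# ---------------------------------------------------------------------------
# Coupled alignments
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MsaSpec:
    seed: int = 0
    n_sequences: int = 500
    n_columns: int = 40
    planted_pairs: tuple = ((3, 7, 1.0),)  # (col_i, col_j, strength in [0,1])


def make_coupled_msa(spec: MsaSpec) -> AlignedSequenceSet:
    """I.i.d. uniform background over a 6-letter alphabet with planted
    coupled column pairs.

    Each planted pair is drawn from a two-state joint: the first column
    takes one of two letters uniformly; the second column matches the
    hidden state with probability (1 + strength)/2, so strength 1 is
    perfect correlation and strength 0 independence.
    """
    if spec.n_sequences < 50:
        raise ValueError("need at least 50 sequences")
    planted_cols = [c for i, j, _s in spec.planted_pairs for c in (i, j)]
    if len(set(planted_cols)) != len(planted_cols):
        raise ValueError("planted pairs share a column")
    for i, j, s in spec.planted_pairs:
        if not (1 <= i <= spec.n_columns and 1 <= j <= spec.n_columns):
            raise ValueError(f"planted pair ({i},{j}) outside column bounds")
        if not 0 <= s <= 1:
            raise ValueError("coupling strength must be in [0,1]")
    rng = np.random.default_rng(spec.seed)
    letters = np.frombuffer(SYNTH_ALPHABET.encode(), dtype="S1")
    mat = letters[rng.integers(0, len(letters), size=(spec.n_sequences,
                                                      spec.n_columns))]
    two_i = np.frombuffer(b"AC", dtype="S1")
    two_j = np.frombuffer(b"EG", dtype="S1")
    for i, j, strength in spec.planted_pairs:
        z = rng.integers(0, 2, size=spec.n_sequences)
        match = rng.random(spec.n_sequences) < (1 + strength) / 2
        zj = np.where(match, z, 1 - z)
        mat[:, i - 1] = two_i[z]
        mat[:, j - 1] = two_j[zj]
    records = [
        AlignmentRecord(seq_id=f"synth{k:04d}",
                        residues=mat[k].tobytes().decode("ascii"))
        for k in range(spec.n_sequences)
    ]
    return AlignedSequenceSet.from_records(records)


# ---------------------------------------------------------------------------
# Toy structures
# ---------------------------------------------------------------------------

def _place_atom(a, b, c, bond, angle_deg, torsion_deg):
    """NeRF placement of a new atom bonded to c, given predecessors a-b-c."""
    angle = math.radians(angle_deg)
    torsion = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array([
        -bond * math.cos(angle),
        bond * math.sin(angle) * math.cos(torsion),
        bond * math.sin(angle) * math.sin(torsion),
    ])
    return c + d[0] * bc + d[1] * m + d[2] * n


def _helix_backbone(n_residues: int):
    """Backbone N/CA/C/O/H coordinates of an ideal alpha helix."""
    N = [np.array([0.0, 0.0, 0.0])]
    CA = [np.array([_B_N_CA, 0.0, 0.0])]
    ang = math.radians(_A_N_CA_C)
    C = [CA[0] + _B_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])]
    for i in range(1, n_residues):
        N.append(_place_atom(N[-1], CA[-1], C[-1], _B_C_N, _A_CA_C_N, _PSI))
        CA.append(_place_atom(CA[-1], C[-1], N[-1], _B_N_CA, _A_C_N_CA, _OMEGA))
        C.append(_place_atom(C[-1], N[-1], CA[-1], _B_CA_C, _A_N_CA_C, _PHI))
    O = [
        _place_atom(N[i], CA[i], C[i], _B_C_O, _A_CA_C_O, _PSI + 180.0)
        for i in range(n_residues)
    ]
    H = [None]
    for i in range(1, n_residues):
        u = (C[i - 1] - N[i]) / np.linalg.norm(C[i - 1] - N[i])
        v = (CA[i] - N[i]) / np.linalg.norm(CA[i] - N[i])
        bis = -(u + v)
        H.append(N[i] + _B_N_H * bis / np.linalg.norm(bis))
    return N, CA, C, O, H


def _cb_position(n, ca, c):
    return _place_atom(c, n, ca, _B_CA_CB, _A_N_CA_CB, 122.6)


@dataclass(frozen=True)
class StructureSpec:
    sequence: str = "A" * 30
    sequence_b: str | None = None    # second subunit (hetdimer geometry)
    geometry: str = "helix"          # helix | dimer | hetdimer | ring
    n_chains: int = 2                # for ring
    chain_separation: float = 18.0   # dimer axis offset (A)
    ring_chord: float = 14.5         # neighbour axis separation in a ring (A)
    contact_pairs: tuple = ()        # intra-chain (resnum_i, resnum_j)
    interface_pairs: tuple = ()      # cross-chain (resnum_in_A, resnum_in_B)
    contacts_formed: bool = True     # False flips probe atoms away
    probe_gap: float = 3.0           # realised probe-probe distance (A)
    structure_id: str = "1TOY"
    verify_m: int = 5                # separation below which clashes are ignored


def _build_single_chain(spec: StructureSpec, chain_id: str = "A") -> Chain:
    seq = spec.sequence
    N, CA, C, O, H = _helix_backbone(len(seq))
    residues = []
    for i, aa in enumerate(seq):
        resname = ONE_TO_THREE.get(aa, "ALA")
        atoms = [
            Atom("N", "N", tuple(N[i])),
            Atom("CA", "C", tuple(CA[i])),
            Atom("C", "C", tuple(C[i])),
            Atom("O", "O", tuple(O[i])),
        ]
        if H[i] is not None:
            atoms.append(Atom("H", "H", tuple(H[i]), is_hydrogen=True))
        cb = _cb_position(N[i], CA[i], C[i])
        if aa != "G":
            atoms.append(Atom("CB", "C", tuple(cb)))
        if aa == "S":
            out = cb - CA[i]
            out /= np.linalg.norm(out)
            og = cb + 1.40 * out
            atoms.append(Atom("OG", "O", tuple(og)))
            atoms.append(Atom("HG", "H", tuple(og + 0.97 * out),
                              is_hydrogen=True))
        residues.append(Residue(resnum=i + 1, icode=" ", resname=resname,
                                atoms=atoms))
    return Chain(chain_id=chain_id, residues=residues)


def _translate_chain(chain: Chain, offset: np.ndarray, new_id: str) -> Chain:
    return _transform_chain(chain, np.eye(3), offset, new_id)


def _transform_chain(chain: Chain, rot: np.ndarray, offset: np.ndarray,
                     new_id: str) -> Chain:
    residues = []
    for res in chain.residues:
        atoms = [
            Atom(a.name, a.element, tuple(rot @ np.asarray(a.xyz) + offset),
                 a.is_hydrogen)
            for a in res.atoms
        ]
        residues.append(Residue(res.resnum, res.icode, res.resname, atoms,
                                res.is_polymer))
    return Chain(chain_id=new_id, residues=residues)


def _add_probe(res: Residue, pos: np.ndarray, formed: bool) -> None:
    """Append a pseudo-sidechain probe atom at an explicit position, or
    tucked against the residue's own CA when the contact is broken."""
    if not formed:
        ca = res.atom("CA").coords
        u = pos - ca
        pos = ca - 1.5 * u / np.linalg.norm(u)  # flipped: contact broken
    res.atoms.append(Atom("XP", "C", tuple(pos)))


def _helix_axis_frame(chain: Chain):
    ca = np.array([r.atom("CA").coords for r in chain.residues])
    axis = ca[-1] - ca[0]
    axis /= np.linalg.norm(axis)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, axis)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    perp = ref - np.dot(ref, axis) * axis
    perp /= np.linalg.norm(perp)
    return axis, perp


def make_toy_structure(spec: StructureSpec) -> Structure:
    """Build a helix / dimer / ring toy structure realising the requested
    contact map, then verify it by exhaustive distance computation.

    Contacts are realised by probe atoms ("XP") extended from each partner
    toward the pair midpoint, ending ``probe_gap`` apart. With
    ``contacts_formed=False`` the probes are flipped to the opposite side of
    their residue, breaking every designated contact while preserving the
    atom topology. Unsatisfiable requests (designated pairs not within 4 A,
    or stray contacts created elsewhere) raise ValueError.
    """
    base = _build_single_chain(spec)
    if spec.geometry == "helix":
        chains = [base]
        away = {"A": None}  # radially outward, computed per contact point
    elif spec.geometry == "dimer":
        _axis, perp = _helix_axis_frame(base)
        chains = [base, _translate_chain(base, spec.chain_separation * perp, "B")]
        away = {"A": -perp, "B": perp}
    elif spec.geometry == "hetdimer":
        if spec.sequence_b is None:
            raise ValueError("hetdimer geometry requires sequence_b")
        _axis, perp = _helix_axis_frame(base)
        other = _build_single_chain(
            StructureSpec(sequence=spec.sequence_b), chain_id="B")
        chains = [base, _translate_chain(other, spec.chain_separation * perp, "B")]
        away = {"A": -perp, "B": perp}
    elif spec.geometry == "ring":
        k = spec.n_chains
        if k < 3:
            raise ValueError("ring needs >= 3 chains")
        axis, perp = _helix_axis_frame(base)
        radius = spec.ring_chord / (2 * math.sin(math.pi / k))
        chains = []
        away = {}
        for c in range(k):
            theta = 2 * math.pi * c / k
            rot = _rotation_about(axis, theta)
            outward = rot @ perp
            chains.append(_transform_chain(
                base, rot, radius * outward, chr(ord("A") + c)))
            away[chr(ord("A") + c)] = outward
    else:
        raise ValueError(f"unknown geometry {spec.geometry!r}")

    for i, j in spec.contact_pairs:
        for ch in chains:
            ra, rb = ch.residue(i), ch.residue(j)
            ca_i, ca_j = ra.atom("CA").coords, rb.atom("CA").coords
            mid = 0.5 * (ca_i + ca_j)
            # move the contact point onto a ledge 8 A off the helix axis —
            # and away from any neighbouring chain — so probes clear the
            # backbone of every intervening residue
            w = away[ch.chain_id]
            if w is None:
                w = _outward(ch, mid)
            mid = _axis_projection(ch, mid) + 8.0 * w
            v = (ca_j - ca_i) / np.linalg.norm(ca_j - ca_i)
            half = spec.probe_gap / 2
            _add_probe(ra, mid - half * v, spec.contacts_formed)
            _add_probe(rb, mid + half * v, spec.contacts_formed)
    if spec.interface_pairs:
        if spec.geometry == "helix":
            raise ValueError("interface pairs require a multi-chain geometry")
        pairs = [(chains[c], chains[(c + 1) % len(chains)])
                 for c in range(len(chains) if spec.geometry == "ring" else 1)]
        for ch_a, ch_b in pairs:
            for i, j in spec.interface_pairs:
                ra, rb = ch_a.residue(i), ch_b.residue(j)
                ca_i, ca_j = ra.atom("CA").coords, rb.atom("CA").coords
                mid = 0.5 * (ca_i + ca_j)
                v = (ca_j - ca_i) / np.linalg.norm(ca_j - ca_i)
                half = spec.probe_gap / 2
                _add_probe(ra, mid - half * v, spec.contacts_formed)
                _add_probe(rb, mid + half * v, spec.contacts_formed)

    structure = Structure(structure_id=spec.structure_id, chains=chains)
    _verify_contacts(structure, spec)
    return structure


def _axis_projection(chain: Chain, point: np.ndarray) -> np.ndarray:
    ca = np.array([r.atom("CA").coords for r in chain.residues])
    origin = ca.mean(axis=0)
    axis = ca[-1] - ca[0]
    axis /= np.linalg.norm(axis)
    return origin + np.dot(point - origin, axis) * axis


def _outward(chain: Chain, point: np.ndarray) -> np.ndarray:
    """Unit vector from the chain's helix axis line through the point."""
    ca = np.array([r.atom("CA").coords for r in chain.residues])
    origin = ca.mean(axis=0)
    axis = ca[-1] - ca[0]
    axis /= np.linalg.norm(axis)
    rel = point - origin
    radial = rel - np.dot(rel, axis) * axis
    norm = np.linalg.norm(radial)
    if norm < 1e-6:
        radial = np.cross(axis, np.array([1.0, 0.0, 0.0]))
        norm = np.linalg.norm(radial)
    return radial / norm


def _rotation_about(axis, theta):
    axis = axis / np.linalg.norm(axis)
    K = np.array([
        [0, -axis[2], axis[1]],
        [axis[2], 0, -axis[0]],
        [-axis[1], axis[0], 0],
    ])
    return np.eye(3) + math.sin(theta) * K + (1 - math.cos(theta)) * K @ K


def _verify_contacts(structure: Structure, spec: StructureSpec,
                     cutoff: float = 4.0) -> None:
    """Exhaustive check that the realised contact map is exactly the
    designated one (at separations the analyses can see)."""
    chain_a = structure.chains[0]
    coords = {
        r.resnum: r.coord_array() for r in chain_a.residues
    }
    wanted = {tuple(sorted(p)) for p in spec.contact_pairs}
    n = len(chain_a.residues)
    for i in range(1, n + 1):
        for j in range(i + spec.verify_m, n + 1):
            d = cdist(coords[i], coords[j]).min()
            is_contact = d <= cutoff
            should = spec.contacts_formed and (i, j) in wanted
            if is_contact != should:
                raise ValueError(
                    f"intra-chain contact map unsatisfiable: pair ({i},{j}) "
                    f"has distance {d:.2f} A, designated={(i, j) in wanted}"
                )
    if len(structure.chains) > 1 and spec.geometry in ("dimer", "hetdimer"):
        chain_b = structure.chains[1]
        coords_b = {r.resnum: r.coord_array() for r in chain_b.residues}
        wanted_x = set(spec.interface_pairs)
        for i in range(1, n + 1):
            for j in range(1, len(chain_b.residues) + 1):
                d = cdist(coords[i], coords_b[j]).min()
                is_contact = d <= cutoff
                should = spec.contacts_formed and (i, j) in wanted_x
                if is_contact != should:
                    raise ValueError(
                        f"cross-chain contact map unsatisfiable: pair "
                        f"({i},{j}) at {d:.2f} A, designated="
                        f"{(i, j) in wanted_x}"
                    )


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BondSchedule:
    """One scheduled donor/acceptor interaction: residue A's OG-HG hydrogen
    bonds to residue B's OG during the listed (1-based, inclusive) frame
    intervals and is held out of range otherwise."""

    res_a: tuple  # (chain_id, resnum)
    res_b: tuple
    on_intervals: tuple  # ((start, end), ...)

    def active(self, frame: int) -> bool:
        return any(a <= frame <= b for a, b in self.on_intervals)


def make_trajectory(
    base: Structure,
    n_frames: int,
    schedule=(),
    seed: int = 0,
    noise_sigma: float = 0.2,
    dt_ns: float = 1.0,
) -> TrajectoryFrames:
    """Jittered copies of a base structure with an exact bond schedule.

    Each frame applies a seeded per-residue rigid displacement (sigma in A),
    then repositions every scheduled donor/acceptor group so the programmed
    hydrogen-bond geometry holds exactly: on-frames get d(D,A) = 2.9 A in a
    collinear arrangement, off-frames d(D,A) = 5.5 A.
    """
    schedule = tuple(schedule)
    for entry in schedule:
        for cid, resnum in (entry.res_a, entry.res_b):
            res = base.chain(cid).residue(resnum)
            for name in ("OG", "HG"):
                res.atom(name)  # raises KeyError when absent
        for a, b in entry.on_intervals:
            if not (1 <= a <= b <= n_frames):
                raise ValueError(
                    f"schedule interval ({a},{b}) outside 1..{n_frames}")
    rng = np.random.default_rng(seed)
    frames = []
    for f in range(1, n_frames + 1):
        st = copy.deepcopy(base)
        for chain in st.chains:
            for res in chain.residues:
                shift = rng.normal(0.0, noise_sigma, size=3)
                res.atoms = [
                    Atom(a.name, a.element, tuple(np.asarray(a.xyz) + shift),
                         a.is_hydrogen)
                    for a in res.atoms
                ]
        for entry in schedule:
            _apply_schedule(st, entry, on=entry.active(f))
        frames.append((f * dt_ns, st))
    return TrajectoryFrames(frames=tuple(frames))


def _apply_schedule(st: Structure, entry: BondSchedule, on: bool) -> None:
    res_a = st.chain(entry.res_a[0]).residue(entry.res_a[1])
    res_b = st.chain(entry.res_b[0]).residue(entry.res_b[1])
    og_a = res_a.atom("OG").coords
    u = res_b.atom("OG").coords - og_a
    u /= np.linalg.norm(u)
    d = 2.9 if on else 5.5
    new_og_b = og_a + d * u
    _set_atom(res_a, "HG", og_a + 0.97 * u)
    _set_atom(res_b, "OG", new_og_b)
    _set_atom(res_b, "HG", new_og_b + 0.97 * u)


def _set_atom(res: Residue, name: str, pos: np.ndarray) -> None:
    for idx, atom in enumerate(res.atoms):
        if atom.name == name:
            res.atoms[idx] = Atom(name, atom.element, tuple(pos),
                                  atom.is_hydrogen)
            return
    raise KeyError(name)


def interpolate_trajectory(
    start: Structure,
    end: Structure,
    n_frames: int,
    dt_ns: float = 1.0,
) -> TrajectoryFrames:
    """Linear coordinate interpolation between two same-topology structures."""
    if start.topology() != end.topology():
        raise ValueError("start and end structures differ in topology")
    end_pos = {
        (ch.chain_id, res.resnum, res.icode, a.name): np.asarray(a.xyz)
        for ch in end.chains for res in ch.residues for a in res.atoms
    }
    frames = []
    for f in range(n_frames):
        t = f / (n_frames - 1) if n_frames > 1 else 1.0
        st = copy.deepcopy(start)
        for ch in st.chains:
            for res in ch.residues:
                res.atoms = [
                    Atom(a.name, a.element, tuple(
                        (1 - t) * np.asarray(a.xyz)
                        + t * end_pos[(ch.chain_id, res.resnum, res.icode,
                                       a.name)]),
                        a.is_hydrogen)
                    for a in res.atoms
                ]
        frames.append(((f + 1) * dt_ns, st))
    return TrajectoryFrames(frames=tuple(frames))


# ---------------------------------------------------------------------------
# Planted coupling tables
# ---------------------------------------------------------------------------

def plant_contact_scores(
    contacts,
    all_pairs,
    enrichment_k: int,
    seed: int = 0,
    cross: bool = False,
) -> CouplingTable:
    """Coupling table whose top-k entries are k seeded-random contact pairs;
    every other pair scores below them (seeded uniform)."""
    contacts = sorted(set(map(tuple, contacts)))
    all_pairs = sorted(set(map(tuple, all_pairs)))
    if not set(contacts) <= set(all_pairs):
        raise ValueError("contacts must be a subset of all_pairs")
    if enrichment_k > len(contacts):
        raise ValueError(f"k={enrichment_k} exceeds {len(contacts)} contacts")
    rng = np.random.default_rng(seed)
    chosen_idx = rng.choice(len(contacts), size=enrichment_k, replace=False)
    chosen = {contacts[i] for i in chosen_idx}
    entries = []
    top = sorted(rng.uniform(1.0, 2.0, size=enrichment_k))[::-1]
    it = iter(top)
    for pair in all_pairs:
        if pair in chosen:
            entries.append((pair[0], pair[1], float(next(it))))
        else:
            entries.append((pair[0], pair[1], float(rng.uniform(0.0, 0.9))))
    return CouplingTable.from_entries(entries, cross=cross)
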