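"""Core in-memory containers shared by all analysis modules.

The containers are deliberately light: plain dataclasses over numpy
coordinates, with the invariants that every downstream statistic relies on
checked at construction time (equal-length alignment rows, unique residue
keys, strictly increasing trajectory times, constant topology).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
ALPHABET = AMINO_ACIDS + GAP + "X"

THREE_TO_ONE = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
    "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
    "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
    "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

_STRUCT_ID_RE = re.compile(r"^[0-9][0-9A-Za-z]{3}_[0-9A-Za-z]+$")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlignmentRecord:
    seq_id: str
    residues: str
    taxon_id: int | None = None

    @property
    def structure_linked(self) -> bool:
        """True when the id follows the PDB-entry_chain convention (e.g. 3M0E_A)."""
        return bool(_STRUCT_ID_RE.match(self.seq_id))

    @property
    def pdb_id(self) -> str | None:
        return self.seq_id.split("_")[0] if self.structure_linked else None

    @property
    def chain_id(self) -> str | None:
        return self.seq_id.split("_", 1)[1] if self.structure_linked else None

    def ungapped(self) -> str:
        return self.residues.replace(GAP, "")


@dataclass(frozen=True)
class AlignedSequenceSet:
    """A gapped multiple sequence alignment.

    ``n_columns`` is the alignment length (the MSA length that the cut-point
    spread statistic F is normalised by).
    """

    records: tuple[AlignmentRecord, ...]
    n_columns: int

    def __post_init__(self):
        seen: set[str] = set()
        for rec in self.records:
            if len(rec.residues) != self.n_columns:
                raise FormatError(
                    f"record {rec.seq_id!r} has {len(rec.residues)} columns, "
                    f"expected {self.n_columns}"
                )
            if rec.seq_id in seen:
                raise FormatError(f"duplicate sequence id {rec.seq_id!r}")
            seen.add(rec.seq_id)

    @classmethod
    def from_records(cls, records) -> "AlignedSequenceSet":
        records = tuple(records)
        if not records:
            raise FormatError("alignment contains no sequences")
        return cls(records=records, n_columns=len(records[0].residues))

    def __len__(self) -> int:
        return len(self.records)

    def get(self, seq_id: str) -> AlignmentRecord:
        for rec in self.records:
            if rec.seq_id == seq_id:
                return rec
        raise KeyError(seq_id)

    def to_matrix(self) -> np.ndarray:
        """Residue characters as an (n_records, n_columns) array of bytes."""
        return np.frombuffer(
            "".join(r.residues for r in self.records).encode("ascii"), dtype="S1"
        ).reshape(len(self.records), self.n_columns)


# ---------------------------------------------------------------------------
# Structures
# ---------------------------------------------------------------------------

BACKBONE_ATOMS = frozenset(
    {"N", "CA", "C", "O", "OXT", "H", "HN", "HA", "H1", "H2", "H3", "HA2", "HA3"}
)


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    xyz: tuple[float, float, float]
    is_hydrogen: bool = False

    @property
    def coords(self) -> np.ndarray:
        return np.asarray(self.xyz, dtype=float)


@dataclass
class Residue:
    resnum: int
    icode: str
    resname: str
    atoms: list[Atom] = field(default_factory=list)
    is_polymer: bool = True

    @property
    def key(self) -> tuple[int, str]:
        return (self.resnum, self.icode)

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.resname, "X")

    def coord_array(self, include_hydrogens: bool = True) -> np.ndarray:
        atoms = self.atoms if include_hydrogens else [
            a for a in self.atoms if not a.is_hydrogen
        ]
        if not atoms:
            raise ValueError(
                f"residue {self.resname}{self.resnum}{self.icode.strip()} has no atoms"
                + ("" if include_hydrogens else " after removing hydrogens")
            )
        return np.array([a.xyz for a in atoms], dtype=float)

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(name)


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def residue(self, resnum: int, icode: str = " ") -> Residue:
        for r in self.residues:
            if r.resnum == resnum and r.icode == icode:
                return r
        raise KeyError((self.chain_id, resnum, icode))

    def polymer_residues(self) -> list[Residue]:
        return [r for r in self.residues if r.is_polymer]

    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.polymer_residues())


@dataclass
class Structure:
    structure_id: str
    chains: list[Chain] = field(default_factory=list)

    def __post_init__(self):
        seen: set[tuple[str, int, str]] = set()
        for ch in self.chains:
            for res in ch.residues:
                key = (ch.chain_id, res.resnum, res.icode)
                if key in seen:
                    raise FormatError(f"duplicate residue {key} in {self.structure_id}")
                seen.add(key)
                for atom in res.atoms:
                    if not np.all(np.isfinite(atom.xyz)):
                        raise FormatError(
                            f"non-finite coordinates for atom {atom.name} of {key}"
                        )

    def chain(self, chain_id: str) -> Chain:
        for ch in self.chains:
            if ch.chain_id == chain_id:
                return ch
        raise KeyError(chain_id)

    def topology(self) -> frozenset[tuple[str, int, str, str]]:
        return frozenset(
            (ch.chain_id, res.resnum, res.icode, atom.name)
            for ch in self.chains
            for res in ch.residues
            for atom in res.atoms
        )


@dataclass(frozen=True)
class TrajectoryFrames:
    """Time-ordered structural frames with identical atom topology."""

    frames: tuple[tuple[float, Structure], ...]

    def __post_init__(self):
        if not self.frames:
            raise FormatError("trajectory contains no frames")
        times = [t for t, _ in self.frames]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise FormatError("frame times must be strictly increasing")
        topo0 = self.frames[0][1].topology()
        for t, structure in self.frames[1:]:
            if structure.topology() != topo0:
                raise FormatError(f"topology drift at frame t={t} ns")

    @property
    def times(self) -> list[float]:
        return [t for t, _ in self.frames]

    @property
    def structures(self) -> list[Structure]:
        return [s for _, s in self.frames]

    def __len__(self) -> int:
        return len(self.frames)


# ---------------------------------------------------------------------------
# Coupling scores
# ---------------------------------------------------------------------------

@dataclass(frozen=True, eq=False)
class CouplingTable:
    """Per-column-pair direct-coupling scores, sorted by descending score.

    ``col_i``/``col_j`` are 1-based alignment columns.  For cross-alignment
    (heteromer) tables ``col_i`` indexes the first alignment and ``col_j`` the
    second, and the intra-alignment ``col_i < col_j`` invariant is relaxed.
    """

    col_i: np.ndarray
    col_j: np.ndarray
    scores: np.ndarray
    cross: bool = False

    def __post_init__(self):
        ci = np.asarray(self.col_i, dtype=int)
        cj = np.asarray(self.col_j, dtype=int)
        sc = np.asarray(self.scores, dtype=float)
        if not (len(ci) == len(cj) == len(sc)):
            raise ValueError("column/score arrays must have equal length")
        if not self.cross:
            if np.any(ci >= cj):
                raise ValueError("intra-alignment pairs require col_i < col_j")
        pairs = set(zip(ci.tolist(), cj.tolist()))
        if len(pairs) != len(ci):
            raise FormatError("duplicate column pair in coupling table")
        order = np.lexsort((cj, ci, -sc))
        object.__setattr__(self, "col_i", ci[order])
        object.__setattr__(self, "col_j", cj[order])
        object.__setattr__(self, "scores", sc[order])

    @classmethod
    def from_entries(cls, entries, cross: bool = False) -> "CouplingTable":
        entries = list(entries)
        ci = np.array([e[0] for e in entries], dtype=int)
        cj = np.array([e[1] for e in entries], dtype=int)
        sc = np.array([e[2] for e in entries], dtype=float)
        return cls(col_i=ci, col_j=cj, scores=sc, cross=cross)

    @property
    def entries(self) -> list[tuple[int, int, float]]:
        return list(zip(self.col_i.tolist(), self.col_j.tolist(), self.scores.tolist()))

    def __len__(self) -> int:
        return len(self.scores)

    def top(self, n: int) -> list[tuple[int, int, float]]:
        return self.entries[:n]
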