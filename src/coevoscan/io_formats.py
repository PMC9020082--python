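"""Readers and writers for the formats the toolkit touches.

Gapped FASTA alignments (with ``taxid=<int>`` header tokens and PDB-style
``3M0E_A`` structure-linked identifiers), single- and multi-model PDB files
(one trajectory frame per MODEL), tab-separated coupling-score tables, and
PyMOL command scripts for visualising residue pairs.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import gemmi
from Bio import SeqIO

from .types import (
    AlignedSequenceSet,
    AlignmentRecord,
    Atom,
    Chain,
    CouplingTable,
    FormatError,
    Residue,
    Structure,
    TrajectoryFrames,
    THREE_TO_ONE,
)

log = logging.getLogger(__name__)

_TAXID_RE = re.compile(r"\btaxid=(\d+)\b")


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------

def read_alignment(path) -> AlignedSequenceSet:
    """Read a gapped FASTA alignment.

    Sequence ids of the form ``<pdb>_<chain>`` are recognised downstream as
    structure-linked; a ``taxid=<int>`` token anywhere in the description
    populates the record's taxonomy id.

    Raises
    ------
    FormatError
        If the file is empty or the rows are of unequal (ragged) length,
        naming the offending record.
    """
    records = []
    n_columns = None
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if n_columns is None:
            n_columns = len(seq)
        elif len(seq) != n_columns:
            raise FormatError(
                f"ragged alignment: record {rec.id!r} has length {len(seq)}, "
                f"expected {n_columns}"
            )
        m = _TAXID_RE.search(rec.description)
        taxon_id = int(m.group(1)) if m else None
        records.append(AlignmentRecord(seq_id=rec.id, residues=seq, taxon_id=taxon_id))
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    return AlignedSequenceSet.from_records(records)


def write_alignment(msa: AlignedSequenceSet, path) -> None:
    with open(path, "w") as fh:
        for rec in msa.records:
            header = rec.seq_id
            if rec.taxon_id is not None:
                header += f" taxid={rec.taxon_id}"
            fh.write(f">{header}\n{rec.residues}\n")


# ---------------------------------------------------------------------------
# Structures
# ---------------------------------------------------------------------------

def _convert_model(model: gemmi.Model, structure_id: str) -> Structure:
    chains = []
    for gchain in model:
        residues = []
        for gres in gchain:
            atoms = []
            seen_names: set[str] = set()
            for gatom in gres:
                if gatom.altloc not in ("", "\0", "A"):
                    log.warning(
                        "dropping altloc %r of atom %s in %s %s%d",
                        gatom.altloc, gatom.name, structure_id,
                        gchain.name, gres.seqid.num,
                    )
                    continue
                if gatom.name in seen_names:
                    log.warning(
                        "duplicate atom %s in %s %s%d; keeping first",
                        gatom.name, structure_id, gchain.name, gres.seqid.num,
                    )
                    continue
                seen_names.add(gatom.name)
                element = gatom.element.name
                is_h = element == "H" or gatom.name.lstrip("0123456789").startswith("H")
                atoms.append(Atom(
                    name=gatom.name,
                    element=element,
                    xyz=(gatom.pos.x, gatom.pos.y, gatom.pos.z),
                    is_hydrogen=is_h,
                ))
            if atoms:
                residues.append(Residue(
                    resnum=gres.seqid.num,
                    icode=gres.seqid.icode if gres.seqid.icode.strip() else " ",
                    resname=gres.name,
                    atoms=atoms,
                    is_polymer=gres.name in THREE_TO_ONE,
                ))
        if residues:
            chains.append(Chain(chain_id=gchain.name, residues=residues))
    return Structure(structure_id=structure_id, chains=chains)


def _structure_name(st: gemmi.Structure, path) -> str:
    entry_id = dict(st.info).get("_entry.id", "").strip()
    return entry_id or st.name or Path(path).stem


def read_structure(path) -> Structure:
    """Read a single-model PDB file into a Structure.

    HETATM records (ligands, ions, waters) are retained under their chain with
    the residue name preserved; hydrogens are flagged from the element column
    (falling back to an atom-name heuristic). Alternate locations other than
    'A'/blank are dropped with a warning.
    """
    st = gemmi.read_pdb(str(path))
    if len(st) == 0:
        raise FormatError(f"no ATOM records in {path}")
    structure = _convert_model(st[0], _structure_name(st, path))
    if not structure.chains:
        raise FormatError(f"no ATOM records in {path}")
    return structure


def read_trajectory(path, dt_ns: float = 1.0) -> TrajectoryFrames:
    """Read a multi-model PDB file as a trajectory, one frame per MODEL.

    Frame times default to 1 ns per frame (frame k at ``k * dt_ns``),
    emulating a simulation sampled every nanosecond.
    """
    st = gemmi.read_pdb(str(path))
    if len(st) == 0:
        raise FormatError(f"no models in {path}")
    name = _structure_name(st, path)
    frames = tuple(
        ((k + 1) * dt_ns, _convert_model(model, name))
        for k, model in enumerate(st)
    )
    return TrajectoryFrames(frames=frames)


def write_structure(structure: Structure, path) -> None:
    write_trajectory(TrajectoryFrames(frames=((1.0, structure),)), path,
                     single_model=True)


def write_trajectory(traj: TrajectoryFrames, path, single_model: bool = False) -> None:
    """Serialise one or more frames in PDB format (MODEL/ENDMDL per frame)."""
    first = traj.frames[0][1]
    lines = [
        f"HEADER    SYNTHETIC STRUCTURE                     01-JAN-00   "
        f"{first.structure_id[:4].upper():<4s}"
    ]
    multi = len(traj) > 1 or not single_model
    for k, (_, structure) in enumerate(traj.frames):
        if multi:
            lines.append(f"MODEL     {k + 1:4d}")
        serial = 0
        for chain in structure.chains:
            for res in chain.residues:
                record = "ATOM  " if res.is_polymer else "HETATM"
                for atom in res.atoms:
                    serial += 1
                    name = atom.name
                    # PDB column rules: 1-char elements start in column 14
                    aname = f" {name:<3s}" if len(name) < 4 and len(atom.element) == 1 else f"{name:<4s}"
                    x, y, z = atom.xyz
                    lines.append(
                        f"{record}{serial:5d} {aname}{'':1s}{res.resname:>3s} "
                        f"{chain.chain_id:1s}{res.resnum:4d}{res.icode:1s}   "
                        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                        f"          {atom.element:>2s}"
                    )
            lines.append("TER")
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Coupling tables
# ---------------------------------------------------------------------------

def read_coupling_scores(path, cross: bool = False) -> CouplingTable:
    """Read a whitespace-delimited ``i j score`` table of external DC scores.

    Rows are 1-based column indices. Self-pairs, duplicate pairs and
    non-numeric scores are format errors. Intra-alignment pairs are
    normalised to ``col_i < col_j``.
    """
    entries = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 3:
                raise FormatError(f"{path}:{lineno}: expected 'i j score', got {line!r}")
            try:
                i, j = int(fields[0]), int(fields[1])
                score = float(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if not cross and i == j:
                raise FormatError(f"{path}:{lineno}: self-pair ({i},{j})")
            if not cross and i > j:
                i, j = j, i
            entries.append((i, j, score))
    if not entries:
        raise FormatError(f"no coupling entries in {path}")
    return CouplingTable.from_entries(entries, cross=cross)


def write_coupling_scores(table: CouplingTable, path) -> None:
    with open(path, "w") as fh:
        for i, j, s in table.entries:
            fh.write(f"{i}\t{j}\t{s:.6g}\n")


# ---------------------------------------------------------------------------
# PyMOL scripts
# ---------------------------------------------------------------------------

def _check_selection(structure: Structure, sel) -> None:
    chain_id, resnum = sel[0], sel[1]
    try:
        structure.chain(chain_id).residue(resnum)
    except KeyError:
        raise ValueError(
            f"selection refers to unknown residue {chain_id}:{resnum}"
        ) from None


def write_pymol_script(
    structure_ref: str,
    highlights,
    bonds,
    path,
    structure: Structure | None = None,
) -> None:
    """Emit a PyMOL command script highlighting residues and drawing bonds.

    Parameters
    ----------
    structure_ref
        Path or object name PyMOL should load.
    highlights
        Iterable of ``((chain, resnum), color)`` residue selections.
    bonds
        Iterable of ``((chain, resnum), (chain, resnum), style)`` where style
        is ``"solid"`` or ``"dashed"`` — the rendering convention for residue
        pairs within vs beyond 10 A.
    structure
        When given, selections are validated against it; unknown residues
        raise ValueError naming the selection.
    """
    if structure is not None:
        for sel, _color in highlights:
            _check_selection(structure, sel)
        for sel_a, sel_b, _style in bonds:
            _check_selection(structure, sel_a)
            _check_selection(structure, sel_b)
    obj = Path(str(structure_ref)).stem
    lines = [
        f"load {structure_ref}, {obj}",
        "hide everything",
        f"show cartoon, {obj}",
        "color gray80, " + obj,
    ]
    for (chain_id, resnum), color in highlights:
        sel = f"{obj} and chain {chain_id} and resi {resnum}"
        lines.append(f"show sticks, ({sel})")
        lines.append(f"color {color}, ({sel})")
    for k, ((ca, ra), (cb, rb), style) in enumerate(bonds, 1):
        name = f"pair{k}"
        sel_a = f"{obj} and chain {ca} and resi {ra} and name CA"
        sel_b = f"{obj} and chain {cb} and resi {rb} and name CA"
        lines.append(f"distance {name}, ({sel_a}), ({sel_b})")
        lines.append(f"color red, {name}")
        if style == "dashed":
            lines.append(f"set dash_gap, 0.6, {name}")
        else:
            lines.append(f"set dash_gap, 0.0, {name}")
        lines.append(f"hide labels, {name}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------

def write_tsv(rows, columns, path, header_comment: str | None = None) -> None:
    """Write a list of dict rows as a TSV result table."""
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(str(row.get(c, "")) for c in columns) + "\n")
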