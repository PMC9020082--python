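"""Shared fixtures: the canonical synthetic dimer/trajectory/heteromer
bundles used across the suite. All inputs are generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from coevoscan.contacts import ContactParams, contact_set, map_structure_to_msa
from coevoscan.synth import (
    BondSchedule,
    MsaSpec,
    StructureSpec,
    make_coupled_msa,
    make_toy_structure,
    make_trajectory,
    plant_contact_scores,
)
from coevoscan.types import AlignedSequenceSet, AlignmentRecord

DIMER_SEQ = "A" * 30
DIMER_CONTACTS = ((3, 9), (13, 19), (22, 29))
DIMER_INTERFACE = ((2, 8), (6, 14), (12, 20), (18, 26), (24, 30))


def dimer_spec(formed: bool = True, structure_id: str = "1TOY") -> StructureSpec:
    return StructureSpec(
        sequence=DIMER_SEQ,
        geometry="dimer",
        contact_pairs=DIMER_CONTACTS,
        interface_pairs=DIMER_INTERFACE,
        contacts_formed=formed,
        structure_id=structure_id,
    )


@pytest.fixture(scope="session")
def dimer_structure():
    return make_toy_structure(dimer_spec())


@pytest.fixture(scope="session")
def dimer_msa():
    return AlignedSequenceSet.from_records(
        [AlignmentRecord("1TOY_A", DIMER_SEQ)]
    )


@pytest.fixture(scope="session")
def dimer_maps(dimer_msa, dimer_structure):
    map_a = map_structure_to_msa(dimer_msa, dimer_structure, "1TOY_A")
    map_b = map_structure_to_msa(
        dimer_msa, dimer_structure, "1TOY_A", chain_id="B"
    )
    return map_a, map_b


@pytest.fixture(scope="session")
def dimer_contact_sets(dimer_structure, dimer_maps):
    map_a, map_b = dimer_maps
    params = ContactParams()
    internal = contact_set(dimer_structure, map_a, params)
    merged = contact_set(dimer_structure, [map_a, map_b], params)
    return internal, merged


@pytest.fixture(scope="session")
def dimer_planted_table(dimer_contact_sets):
    _internal, merged = dimer_contact_sets
    contacts = sorted(merged.contacts())
    return plant_contact_scores(contacts, list(merged.distances),
                                len(contacts), seed=3)


# S at positions 2, 9, 21, 26 gives two schedulable donor/acceptor pairs
SCHED_SEQ = "AS" + "A" * 6 + "S" + "A" * 11 + "S" + "A" * 4 + "S" + "A" * 5
SCHEDULE = (
    BondSchedule(("A", 2), ("A", 9), ((1, 50),)),
    BondSchedule(("A", 21), ("A", 26), ((51, 100),)),
)


@pytest.fixture(scope="session")
def scheduled_trajectory():
    base = make_toy_structure(StructureSpec(sequence=SCHED_SEQ,
                                            geometry="helix"))
    return make_trajectory(base, 100, schedule=SCHEDULE, seed=7)


@pytest.fixture(scope="session")
def coupled_msa():
    return make_coupled_msa(MsaSpec(seed=1))


# heteromer bundle: two alignments sharing taxa, planted cross coupling at
# (A:4, B:8), heterodimer structure with six interface contacts
HET_LA, HET_LB = 24, 20
HET_IFACE = ((2, 2), (4, 8), (8, 12), (12, 16), (16, 20), (24, 20))


@pytest.fixture(scope="session")
def het_bundle():
    joint = make_coupled_msa(MsaSpec(
        seed=11, n_sequences=200, n_columns=HET_LA + HET_LB,
        planted_pairs=((4, HET_LA + 8, 1.0),),
    ))
    recs_a, recs_b = [], []
    for k, rec in enumerate(joint.records):
        recs_a.append(AlignmentRecord(f"a{k:03d}", rec.residues[:HET_LA],
                                      taxon_id=1000 + k))
        recs_b.append(AlignmentRecord(f"b{k:03d}", rec.residues[HET_LA:],
                                      taxon_id=1000 + k))
    seq_a = joint.records[0].residues[:HET_LA]
    seq_b = joint.records[0].residues[HET_LA:]
    recs_a.append(AlignmentRecord("1HET_A", seq_a))
    recs_b.append(AlignmentRecord("1HET_B", seq_b))
    msa_a = AlignedSequenceSet.from_records(recs_a)
    msa_b = AlignedSequenceSet.from_records(recs_b)
    structure = make_toy_structure(StructureSpec(
        sequence=seq_a, sequence_b=seq_b, geometry="hetdimer",
        interface_pairs=HET_IFACE, structure_id="1HET",
    ))
    map_a = map_structure_to_msa(msa_a, structure, "1HET_A")
    map_b = map_structure_to_msa(msa_b, structure, "1HET_B")
    return {
        "msa_a": msa_a, "msa_b": msa_b, "structure": structure,
        "map_a": map_a, "map_b": map_b,
    }
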