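"""Time-series analyses over trajectory frames.

Hydrogen-bond presence/absence matrices per interaction (sc2sc, sc2bb,
sc2sb, bb2bb), residue/ligand distance series, correlated bond switching
ranked by a two-tailed Fisher statistic (a rank score only — trajectory
frames are autocorrelated, so it is not a significance level), and
per-frame coupling-vs-contact S-scores (simul mode).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .contacts import ContactParams, contact_set, detect_hbonds
from .scoring import s_score
from .types import Structure, TrajectoryFrames

MODE_CATEGORIES = {
    "sc2sc": ("sc2sc",),
    "sc2bb": ("sc2bb",),
    "sc2sb": ("sc2sc", "sc2bb"),
    "bb2bb": ("bb2bb",),
}


@dataclass(frozen=True)
class Interaction:
    """Residue-level identity of a recurring interaction: the unordered
    residue pair plus its category, so donor-atom swaps within a residue
    count as the same persisting interaction."""

    res_1: tuple  # (chain_id, resnum, icode)
    res_2: tuple
    category: str

    def label(self) -> str:
        a = f"{self.res_1[0]}:{self.res_1[1]}"
        b = f"{self.res_2[0]}:{self.res_2[1]}"
        return f"{a}--{b}[{self.category}]"

    @property
    def trans(self) -> bool:
        """True when the partners lie on different chains."""
        return self.res_1[0] != self.res_2[0]


@dataclass(frozen=True)
class InteractionSeries:
    interactions: tuple          # Interaction, row order
    present: np.ndarray          # (n_interactions, n_frames) bool
    distances: np.ndarray        # (n_interactions, n_frames) donor-acceptor A
    times: tuple

    def present_fraction(self) -> np.ndarray:
        return self.present.mean(axis=1)

    def row(self, interaction: Interaction) -> int:
        return self.interactions.index(interaction)


def interaction_series(
    traj: TrajectoryFrames,
    mode: str,
    residue_filter=None,
    hbond_kwargs: dict | None = None,
) -> InteractionSeries:
    """Per-frame presence and distance of every hydrogen-bond interaction
    seen in any frame.

    The row set is the union over frames of detected bonds in the mode's
    categories; each row is re-evaluated in every frame. The stored distance
    is the minimum donor-acceptor distance among that frame's bonds for the
    interaction, or the residue-residue minimum distance when absent.
    """
    if mode not in MODE_CATEGORIES:
        raise ValueError(f"unknown mode {mode!r}; pick from {sorted(MODE_CATEGORIES)}")
    categories = MODE_CATEGORIES[mode]
    hbond_kwargs = hbond_kwargs or {}
    per_frame = []
    for _t, structure in traj.frames:
        bonds = [
            b
            for b in detect_hbonds(structure, residue_filter=residue_filter,
                                   **hbond_kwargs)
            if b.category in categories
        ]
        per_frame.append(bonds)
    if residue_filter is not None and not any(per_frame) and not _filter_matches(
        traj.frames[0][1], residue_filter
    ):
        raise ValueError("residue filter matches nothing in the trajectory")
    rows: list[Interaction] = []
    seen = set()
    for bonds in per_frame:
        for b in bonds:
            r1, r2 = b.residue_pair()
            key = Interaction(res_1=r1, res_2=r2, category=b.category)
            if key not in seen:
                seen.add(key)
                rows.append(key)
    rows.sort(key=lambda k: (k.res_1, k.res_2, k.category))
    n_rows, n_frames = len(rows), len(traj)
    present = np.zeros((n_rows, n_frames), dtype=bool)
    distances = np.zeros((n_rows, n_frames))
    index = {k: i for i, k in enumerate(rows)}
    for f, bonds in enumerate(per_frame):
        best: dict[Interaction, float] = {}
        for b in bonds:
            r1, r2 = b.residue_pair()
            key = Interaction(res_1=r1, res_2=r2, category=b.category)
            best[key] = min(best.get(key, np.inf), b.d_DA)
        for key, d in best.items():
            present[index[key], f] = True
            distances[index[key], f] = d
        structure = traj.frames[f][1]
        for key, i in index.items():
            if not present[i, f]:
                distances[i, f] = _residue_pair_distance(structure, key)
    return InteractionSeries(
        interactions=tuple(rows),
        present=present,
        distances=distances,
        times=tuple(traj.times),
    )


def _filter_matches(structure: Structure, residue_filter) -> bool:
    keys = {
        (ch.chain_id, res.resnum, res.icode)
        for ch in structure.chains
        for res in ch.residues
    }
    return bool(keys & set(residue_filter))


def _residue_pair_distance(structure: Structure, key: Interaction) -> float:
    res_a = structure.chain(key.res_1[0]).residue(key.res_1[1], key.res_1[2])
    res_b = structure.chain(key.res_2[0]).residue(key.res_2[1], key.res_2[2])
    return float(cdist(res_a.coord_array(), res_b.coord_array()).min())


def distance_series(traj: TrajectoryFrames, sel_a, sel_b) -> np.ndarray:
    """Per-frame minimum all-atom distance between two selections.

    A selection is a set of (chain_id, resnum) or (chain_id, resnum, icode)
    residue keys; HETATM residues (ligands, ions, waters) resolve the same
    way. A selection missing in any frame raises, naming the frame.
    """
    sel_a = [_norm_key(k) for k in sel_a]
    sel_b = [_norm_key(k) for k in sel_b]
    out = np.empty(len(traj))
    for f, (t, structure) in enumerate(traj.frames):
        try:
            coords_a = np.concatenate([
                structure.chain(c).residue(r, i).coord_array()
                for c, r, i in sel_a
            ])
            coords_b = np.concatenate([
                structure.chain(c).residue(r, i).coord_array()
                for c, r, i in sel_b
            ])
        except KeyError as exc:
            raise ValueError(
                f"selection {exc.args[0]!r} not found in frame at t={t} ns"
            ) from None
        out[f] = cdist(coords_a, coords_b).min()
    return out


def _norm_key(key):
    return key if len(key) == 3 else (key[0], key[1], " ")


# ---------------------------------------------------------------------------
# Correlated switching
# ---------------------------------------------------------------------------

def fisher_twotail(table) -> float:
    """Two-tailed Fisher exact probability of a 2x2 table.

    Defined as the sum, over all tables with the same margins, of point
    probabilities no larger than the observed table's. Computed in exact
    integer arithmetic (the point-probability comparison is on integer
    hypergeometric weights, so ties are handled exactly).
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be non-negative")
    N = a + b + c + d
    if N == 0:
        return 1.0
    r1, c1 = a + b, a + c
    lo, hi = max(0, r1 + c1 - N), min(r1, c1)
    weights = [
        math.comb(r1, k) * math.comb(N - r1, c1 - k) for k in range(lo, hi + 1)
    ]
    observed = weights[a - lo]
    total = math.comb(N, c1)
    return float(sum(w for w in weights if w <= observed) / total)


@dataclass(frozen=True)
class CorrelResult:
    interaction_1: Interaction
    interaction_2: Interaction
    table: tuple      # ((both, only_1), (only_2, neither)) frame counts
    rank_score: float  # two-tailed Fisher p, used for ranking only
    direction: str    # "positive" | "negative"


def _n_switches(series: np.ndarray) -> int:
    return int(np.sum(series[1:] != series[:-1]))


def correl_rank(series: InteractionSeries, min_switches: int = 3) -> list:
    """Rank interaction pairs by correlated formation/disruption.

    Interactions switching state fewer than ``min_switches`` times are
    excluded (always-on/off rows carry no correlation information). Each
    remaining pair is scored by a two-tailed Fisher exact test on the 2x2
    frame-count table; results are sorted by ascending rank score. The score
    orders candidates only — frames are not independent samples, so it is
    not a p-value in the significance sense.
    """
    eligible = [
        i
        for i in range(len(series.interactions))
        if _n_switches(series.present[i]) >= min_switches
    ]
    if len(eligible) < 2:
        raise ValueError(
            f"need >= 2 interactions with >= {min_switches} switches; "
            f"found {len(eligible)}"
        )
    results = []
    for a_idx in range(len(eligible)):
        for b_idx in range(a_idx + 1, len(eligible)):
            i, j = eligible[a_idx], eligible[b_idx]
            pa, pb = series.present[i], series.present[j]
            both = int(np.sum(pa & pb))
            only_a = int(np.sum(pa & ~pb))
            only_b = int(np.sum(~pa & pb))
            neither = int(np.sum(~pa & ~pb))
            table = ((both, only_a), (only_b, neither))
            p = fisher_twotail(table)
            n = both + only_a + only_b + neither
            expected = (both + only_a) * (both + only_b) / n
            results.append(CorrelResult(
                interaction_1=series.interactions[i],
                interaction_2=series.interactions[j],
                table=table,
                rank_score=float(p),
                direction="positive" if both >= expected else "negative",
            ))
    results.sort(key=lambda r: (r.rank_score,
                                r.interaction_1.label(),
                                r.interaction_2.label()))
    return results


# ---------------------------------------------------------------------------
# Per-frame S-scores (simul mode)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulSeries:
    times: tuple
    results: tuple  # IcaResult per frame

    def s_values(self) -> np.ndarray:
        return np.array([r.S for r in self.results])


def simul_series(
    traj: TrajectoryFrames,
    couplings,
    smaps,
    params: ContactParams = ContactParams(),
    msa_length: int | None = None,
) -> SimulSeries:
    """Coupling-vs-contact S-score per frame, contacts recomputed from each
    frame's coordinates. Degenerate frames (no contacts) contribute a
    flagged S = 0 and the series continues."""
    if not isinstance(smaps, (list, tuple)):
        smaps = [smaps]
    results = []
    for _t, structure in traj.frames:
        cs = contact_set(structure, list(smaps), params) if len(smaps) > 1 \
            else contact_set(structure, smaps[0], params)
        results.append(s_score(couplings, cs, msa_length))
    return SimulSeries(times=tuple(traj.times), results=tuple(results))
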