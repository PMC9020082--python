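"""Mean-field direct coupling analysis with APC correction.

Couplings are estimated by inverting the (pseudocount-regularised,
redundancy-weighted) covariance matrix of residue frequencies, scoring each
column pair by the Frobenius norm of its 20x20 coupling block in a zero-sum
gauge, and applying the average product correction. Consensus rankings over
MSA subsamples and the elevated/reduced Fisher test on specific residue
pairs live here as well.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .types import (
    AMINO_ACIDS,
    GAP,
    AlignedSequenceSet,
    CouplingTable,
)

N_AA = len(AMINO_ACIDS)  # 20
N_STATES = N_AA + 1      # amino acids + gap ('X' treated as gap/unknown)

_STATE_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
_STATE_INDEX[GAP] = N_AA
_STATE_INDEX["X"] = N_AA


def encode(msa: AlignedSequenceSet) -> np.ndarray:
    """Integer state matrix (n_records, n_columns); gap/unknown = 20."""
    lut = np.full(256, N_AA, dtype=np.int8)
    for ch, idx in _STATE_INDEX.items():
        lut[ord(ch)] = idx
    raw = msa.to_matrix().view(np.uint8)
    return lut[raw]


@dataclass(frozen=True)
class SequenceWeights:
    weights: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if np.any(w <= 0) or np.any(w > 1):
            raise ValueError("weights must lie in (0, 1]")
        object.__setattr__(self, "weights", w)

    @property
    def effective_n(self) -> float:
        return float(self.weights.sum())


def compute_sequence_weights(
    msa: AlignedSequenceSet, identity_threshold: float = 0.95
) -> SequenceWeights:
    """Down-weight redundant sequences.

    Each record's weight is 1 / (number of records, itself included, whose
    pairwise identity over mutually non-gap columns is >= the threshold).
    """
    if not 0 < identity_threshold <= 1:
        raise ValueError("identity_threshold must be in (0, 1]")
    if len(msa) < 2:
        raise ValueError("need at least 2 sequences")
    X = encode(msa)
    n = X.shape[0]
    gap = X == N_AA
    counts = np.ones(n)
    # pairwise identity over columns where neither sequence is gapped
    for i in range(n):
        both = ~gap[i] & ~gap[i + 1:]
        shared = both.sum(axis=1)
        match = ((X[i] == X[i + 1:]) & both).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            ident = np.where(shared > 0, match / np.maximum(shared, 1), 0.0)
        close = ident >= identity_threshold
        counts[i] += close.sum()
        counts[i + 1:][close] += 1
    return SequenceWeights(weights=1.0 / counts)


def apc_correct(raw: np.ndarray) -> np.ndarray:
    """Average product correction of a symmetric pair-score matrix.

    corrected(i,j) = raw(i,j) - mean_i * mean_j / mean_all, with row means
    taken over off-diagonal entries. An all-zero matrix passes through
    unchanged (no division by zero).
    """
    raw = np.asarray(raw, dtype=float)
    L = raw.shape[0]
    if raw.shape != (L, L):
        raise ValueError("raw matrix must be square")
    if not np.allclose(raw, raw.T):
        raise ValueError("raw matrix must be symmetric")
    off = ~np.eye(L, dtype=bool)
    mean_all = raw[off].mean() if L > 1 else 0.0
    if mean_all == 0.0:
        return np.zeros_like(raw)
    row_means = raw.sum(axis=1) / (L - 1)
    corrected = raw - np.outer(row_means, row_means) / mean_all
    np.fill_diagonal(corrected, 0.0)
    return corrected


def _weighted_frequencies(X, w, pseudocount):
    """Single and pair frequencies with uniform pseudocount lambda."""
    n, L = X.shape
    meff = w.sum()
    onehot = np.zeros((n, L, N_STATES))
    onehot[np.arange(n)[:, None], np.arange(L)[None, :], X] = 1.0
    fi = np.einsum("s,sla->la", w, onehot) / meff
    flat = (onehot * w[:, None, None]).reshape(n, L * N_STATES)
    fij = (onehot.reshape(n, L * N_STATES).T @ flat) / meff
    fij = fij.reshape(L, N_STATES, L, N_STATES)
    lam = pseudocount
    fi = (fi + lam / N_STATES) / (1.0 + lam)
    fij = (fij + lam / N_STATES**2) / (1.0 + lam)
    # diagonal blocks must stay consistent with single frequencies
    for i in range(L):
        fij[i, :, i, :] = np.diag(fi[i])
    return fi, fij


def coupling_matrix_meanfield(
    msa: AlignedSequenceSet,
    weights: SequenceWeights | None = None,
    pseudocount: float = 0.5,
) -> np.ndarray:
    """Raw (pre-APC) Frobenius-norm coupling matrix from mean-field inversion.

    The covariance matrix over (column x 20 amino-acid states) — the gap
    state is the reference and is excluded — is inverted; the negative
    inverse gives the coupling blocks e_ij(a,b), whose Frobenius norm in the
    zero-sum gauge scores the pair.
    """
    if msa.n_columns < 2:
        raise ValueError("need at least 2 alignment columns")
    if weights is None:
        weights = compute_sequence_weights(msa)
    w = weights.weights
    if weights.effective_n < 2:
        raise ValueError("effective number of sequences must be >= 2")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    X = encode(msa)
    L = X.shape[1]
    fi, fij = _weighted_frequencies(X, w, pseudocount)
    # covariance restricted to the 20 amino-acid states
    q = N_AA
    C = (
        fij[:, :q, :, :q]
        - np.einsum("ia,jb->iajb", fi[:, :q], fi[:, :q])
    ).reshape(L * q, L * q)
    try:
        J = -np.linalg.inv(C)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "singular covariance matrix; use a pseudocount > 0"
        ) from exc
    J = J.reshape(L, q, L, q)
    raw = np.zeros((L, L))
    for i in range(L):
        for j in range(i + 1, L):
            block = J[i, :, j, :]
            # zero-sum gauge before the Frobenius norm
            block = (
                block
                - block.mean(axis=0, keepdims=True)
                - block.mean(axis=1, keepdims=True)
                + block.mean()
            )
            raw[i, j] = raw[j, i] = float(np.sqrt((block**2).sum()))
    return raw


def estimate_couplings_meanfield(
    msa: AlignedSequenceSet,
    weights: SequenceWeights | None = None,
    pseudocount: float = 0.5,
) -> CouplingTable:
    """APC-corrected mean-field coupling scores for all column pairs."""
    raw = coupling_matrix_meanfield(msa, weights, pseudocount)
    corrected = apc_correct(raw)
    L = corrected.shape[0]
    iu, ju = np.triu_indices(L, k=1)
    return CouplingTable(col_i=iu + 1, col_j=ju + 1, scores=corrected[iu, ju])


# ---------------------------------------------------------------------------
# Consensus ranking by subsampling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConsensusRank:
    """Per-pair percentages of subsamples in which the pair ranked top-K."""

    pairs: list
    percentages: dict
    top_ks: tuple
    n_subsamples: int
    subsample_size: int

    def rows(self, query_record=None):
        """TSV-ready rows (rank, site1, res1, site2, res2, %top-K...).

        Residue letters come from the optional query alignment record."""
        ks = sorted(self.top_ks, reverse=True)
        out = []
        for rank, pair in enumerate(self.pairs, 1):
            row = {"rank": rank, "site1": pair[0], "site2": pair[1]}
            if query_record is not None:
                row["res1"] = query_record.residues[pair[0] - 1]
                row["res2"] = query_record.residues[pair[1] - 1]
            for k in ks:
                row[f"%top{k}"] = self.percentages[pair][k]
            out.append(row)
        return out


def consensus_rank(
    msa: AlignedSequenceSet,
    n_subsamples: int,
    subsample_size: int,
    top_ks=(20, 10, 5, 2),
    seed: int = 0,
    scorer=None,
) -> ConsensusRank:
    """Rank column pairs by how often they score in the top K across subsamples.

    Each subsample draws ``subsample_size`` records without replacement; the
    full pool is restored before the next draw. The injectable ``scorer``
    maps an AlignedSequenceSet to a CouplingTable (default: the mean-field
    estimator with freshly computed weights).
    """
    if n_subsamples < 1:
        raise ValueError("n_subsamples must be >= 1")
    if subsample_size > len(msa):
        raise ValueError("subsample_size exceeds number of records")
    if scorer is None:
        scorer = estimate_couplings_meanfield
    rng = np.random.default_rng(seed)
    top_ks = tuple(sorted(set(top_ks)))
    counts: dict[tuple[int, int], dict[int, int]] = {}
    for _ in range(n_subsamples):
        idx = rng.choice(len(msa), size=subsample_size, replace=False)
        sub = AlignedSequenceSet.from_records(msa.records[i] for i in sorted(idx))
        table = scorer(sub)
        for k in top_ks:
            for i, j, _s in table.top(k):
                counts.setdefault((i, j), {kk: 0 for kk in top_ks})[k] += 1
    percentages = {
        pair: {k: 100.0 * c[k] / n_subsamples for k in top_ks}
        for pair, c in counts.items()
    }
    ks_desc = sorted(top_ks, reverse=True)
    pairs = sorted(
        percentages,
        key=lambda p: tuple(-percentages[p][k] for k in ks_desc) + p,
    )
    return ConsensusRank(
        pairs=pairs,
        percentages=percentages,
        top_ks=tuple(ks_desc),
        n_subsamples=n_subsamples,
        subsample_size=subsample_size,
    )


# ---------------------------------------------------------------------------
# Elevated / reduced residue pairs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairEnrichment:
    col_i: int
    col_j: int
    res_a: str
    res_b: str
    table: tuple  # ((a&b, a&~b), (~a&b, ~a&~b)) rounded weighted counts
    p_elevated: float
    p_reduced: float


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def elevated_reduced(
    msa: AlignedSequenceSet,
    weights: SequenceWeights,
    col_i: int,
    col_j: int,
    res_a: str,
    res_b: str,
) -> PairEnrichment:
    """One-tailed Fisher tests for a specific residue pair at a column pair.

    Counts are redundancy-weighted and rounded half-up to the nearest
    integer; rows gapped at either column are excluded. ``p_elevated`` is the
    upper hypergeometric tail (co-occurrence as high or higher than
    observed), ``p_reduced`` the lower tail.
    """
    if not (1 <= col_i <= msa.n_columns and 1 <= col_j <= msa.n_columns):
        raise ValueError("column index out of range")
    X = encode(msa)
    w = weights.weights
    ci, cj = X[:, col_i - 1], X[:, col_j - 1]
    usable = (ci < N_AA) & (cj < N_AA)
    if not usable.any():
        raise ValueError("no usable (ungapped) rows at this column pair")
    a_idx = _STATE_INDEX[res_a.upper()]
    b_idx = _STATE_INDEX[res_b.upper()]
    is_a = (ci == a_idx) & usable
    is_b = (cj == b_idx) & usable
    n11 = _round_half_up(float(w[is_a & is_b].sum()))
    n10 = _round_half_up(float(w[is_a & ~is_b & usable].sum()))
    n01 = _round_half_up(float(w[~is_a & is_b & usable].sum()))
    n00 = _round_half_up(float(w[~is_a & ~is_b & usable].sum()))
    N = n11 + n10 + n01 + n00
    row1 = n11 + n10
    colsum1 = n11 + n01
    if N == 0:
        raise ValueError("zero usable weighted counts")
    p_elev = float(stats.hypergeom.sf(n11 - 1, N, row1, colsum1))
    p_red = float(stats.hypergeom.cdf(n11, N, row1, colsum1))
    return PairEnrichment(
        col_i=col_i,
        col_j=col_j,
        res_a=res_a.upper(),
        res_b=res_b.upper(),
        table=((n11, n10), (n01, n00)),
        p_elevated=min(p_elev, 1.0),
        p_reduced=min(p_red, 1.0),
    )
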