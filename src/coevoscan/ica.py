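"""Initial-cluster-analysis scoring of ranked binary lists.

Given a ranked list of L items of which D are distinguished (e.g. column
pairs ranked by coupling score, distinguished = in 3D contact), the scan
evaluates, at every candidate cut point X ending at a distinguished element,
the hypergeometric upper-tail probability of seeing d(X) or more
distinguished elements among the first X, Bonferroni-corrects the minimum
over cuts by the number of candidates, and reports S = -log10(p) together
with the optimum (X, d).  S is expressed in dits (base-10 log units);
nats = dits * ln(10).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

LN10 = math.log(10.0)


class DegenerateRankingError(ValueError):
    """The statistic is undefined: no distinguished elements, or nothing else."""


def hypergeom_tail(N: int, K: int, n: int, k: int) -> float:
    """Upper tail P(X >= k) for X ~ Hypergeometric(N, K, n), log-space safe."""
    _check_hypergeom_args(N, K, n, k)
    if k <= max(0, n + K - N):
        return 1.0
    return float(np.exp(stats.hypergeom.logsf(k - 1, N, K, n)))


def log10_hypergeom_tail(N: int, K: int, n: int, k: int) -> float:
    """log10 P(X >= k); usable far below float underflow of the tail itself."""
    _check_hypergeom_args(N, K, n, k)
    if k <= max(0, n + K - N):
        return 0.0
    return float(stats.hypergeom.logsf(k - 1, N, K, n) / LN10)


def _check_hypergeom_args(N, K, n, k):
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"invalid hypergeometric parameters N={N}, K={K}, n={n}")
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"k={k} outside [0, min(K={K}, n={n})]")


@dataclass(frozen=True)
class RankedDichotomy:
    """An ordered boolean list: True marks a distinguished element."""

    flags: tuple

    def __post_init__(self):
        object.__setattr__(self, "flags", tuple(bool(f) for f in self.flags))

    @property
    def L(self) -> int:
        return len(self.flags)

    @property
    def D(self) -> int:
        return sum(self.flags)


@dataclass(frozen=True)
class IcaResult:
    """The cut-point statistic bundle: S (dits), raw-to-corrected p, optimum
    cut X with d distinguished at or left of it, list size L with D
    distinguished, Bonferroni factor n_tests. F = X / msa_length when an
    alignment length is attached."""

    S: float
    log10_p: float
    X: int
    d: int
    D: int
    L: int
    n_tests: int
    degenerate: bool = False
    F: float | None = None

    @property
    def p(self) -> float:
        return 10.0 ** self.log10_p

    @property
    def nats(self) -> float:
        return self.S * LN10

    def with_F(self, msa_length: int) -> "IcaResult":
        return IcaResult(
            S=self.S, log10_p=self.log10_p, X=self.X, d=self.d, D=self.D,
            L=self.L, n_tests=self.n_tests, degenerate=self.degenerate,
            F=round(self.X / msa_length, 10) if msa_length else None,
        )


def degenerate_result(L: int, D: int) -> IcaResult:
    return IcaResult(S=0.0, log10_p=0.0, X=0, d=0, D=D, L=L, n_tests=0,
                     degenerate=True)


def ica_scan(ranked: RankedDichotomy) -> IcaResult:
    """Scan candidate cut points and return the corrected optimum.

    Candidate cuts are the positions immediately after each distinguished
    element (all other cuts are dominated: extending past non-distinguished
    items can only weaken the tail). Raises DegenerateRankingError when
    D = 0 or D = L.
    """
    L, D = ranked.L, ranked.D
    if D == 0 or D == L:
        raise DegenerateRankingError(f"degenerate ranking: D={D}, L={L}")
    positions = np.flatnonzero(np.asarray(ranked.flags, dtype=bool)) + 1  # 1-based
    d_values = np.arange(1, D + 1)
    log_p = stats.hypergeom.logsf(d_values - 1, L, D, positions) / LN10
    n_tests = len(positions)
    # smallest X wins on ties; exact ties can differ by float rounding, so
    # treat values within 1e-9 of the minimum as tied
    best = int(np.flatnonzero(log_p <= log_p.min() + 1e-9)[0])
    log10_p = min(0.0, float(log_p[best]) + math.log10(n_tests))
    return IcaResult(
        S=-log10_p,
        log10_p=log10_p,
        X=int(positions[best]),
        d=int(d_values[best]),
        D=D,
        L=L,
        n_tests=n_tests,
    )


def ica_scan_safe(ranked: RankedDichotomy) -> IcaResult:
    """ica_scan, but degenerate inputs yield a flagged S=0 result."""
    try:
        return ica_scan(ranked)
    except DegenerateRankingError:
        return degenerate_result(ranked.L, ranked.D)
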