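"""Affine-gap Smith-Waterman local alignment.

Scoring follows the minimap2 asm5 preset for low-divergence genome pairs:
match +1, mismatch -19, and a gap of length L costs gap_open + L*gap_extend
with O=39, E=3 (the preset's first affine component; at 50-bp flank scale
the long-gap component is unreachable).

Identity is defined against the longer input, not the alignment span, so a
short spurious local hit between two unrelated flanks scores a low identity.
"""

from __future__ import annotations

from dataclasses import dataclass

_DNA = frozenset("ACGTN")
NEG_INF = float("-inf")


@dataclass(frozen=True)
class AlignParams:
    match_score: int = 1
    mismatch_penalty: int = 19
    gap_open: int = 39
    gap_extend: int = 3

    def __post_init__(self):
        if min(self.mismatch_penalty, self.gap_open, self.gap_extend) < 0:
            raise ValueError("penalties must be non-negative")


@dataclass(frozen=True)
class LocalAlignment:
    score: float
    identity: float
    n_identical: int = 0
    aligned_cols: int = 0


def local_align(a: str, b: str, params: AlignParams | None = None) -> LocalAlignment:
    """Best local alignment of `a` vs `b` under affine-gap scoring.

    Returns the optimal score and the identity
    (identical aligned columns) / max(len(a), len(b)).  When no positive-
    scoring local alignment exists the score is 0 and identity 0.  Among
    co-optimal alignments the traceback prefers diagonal, then vertical,
    then horizontal moves, ending at the first-reached maximal cell.
    """
    if params is None:
        params = AlignParams()
    a, b = a.upper(), b.upper()
    for s in (a, b):
        if not set(s) <= _DNA:
            raise ValueError(f"non-DNA characters: {sorted(set(s) - _DNA)}")
    n, m = len(a), len(b)
    if n == 0 or m == 0:
        return LocalAlignment(0.0, 0.0)

    match = params.match_score
    mis = -params.mismatch_penalty
    go = -(params.gap_open + params.gap_extend)  # opening a length-1 gap
    ge = -params.gap_extend

    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG_INF] * (m + 1) for _ in range(n + 1)]  # gap in a (consume b)
    F = [[NEG_INF] * (m + 1) for _ in range(n + 1)]  # gap in b (consume a)

    best, bi, bj = 0.0, 0, 0
    for i in range(1, n + 1):
        ai = a[i - 1]
        Hi, Hi1 = H[i], H[i - 1]
        Ei, Fi, Fi1 = E[i], F[i], F[i - 1]
        for j in range(1, m + 1):
            e = max(Hi[j - 1] + go, Ei[j - 1] + ge)
            f = max(Hi1[j] + go, Fi1[j] + ge)
            diag = Hi1[j - 1] + (match if ai == b[j - 1] else mis)
            h = diag
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0.0
            Ei[j], Fi[j], Hi[j] = e, f, h
            if h > best:
                best, bi, bj = h, i, j

    if best <= 0:
        return LocalAlignment(0.0, 0.0)

    # traceback for identity
    i, j, state = bi, bj, "H"
    n_ident = 0
    n_cols = 0
    while True:
        if state == "H":
            if H[i][j] == 0:
                break
            diag = H[i - 1][j - 1] + (match if a[i - 1] == b[j - 1] else mis)
            if H[i][j] == diag:
                n_cols += 1
                if a[i - 1] == b[j - 1]:
                    n_ident += 1
                i, j = i - 1, j - 1
            elif H[i][j] == F[i][j]:
                state = "F"
            else:
                state = "E"
        elif state == "F":
            n_cols += 1
            opened = H[i - 1][j] + go
            closing = F[i][j] == opened
            i -= 1
            if closing:
                state = "H"
        else:  # E
            n_cols += 1
            opened = H[i][j - 1] + go
            closing = E[i][j] == opened
            j -= 1
            if closing:
                state = "H"

    return LocalAlignment(best, n_ident / max(n, m), n_ident, n_cols)
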