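"""Low-level alignment kernels: Gotoh local DP and split alignment search.

The split alignment ("alignment with gap excision") maximizes, over all ways
to split the query and the reference each into a prefix and a suffix,

    score(best local alignment of query prefix vs reference prefix)
  + score(best local alignment of query suffix vs reference suffix).

The skipped middle portions form the excised reference interval and the
inserted query interval, which give base-resolution breakpoints for one
deletion or insertion event flanked by two well-aligned blocks.

Computed with one forward and one reverse Smith-Waterman/Gotoh matrix plus
2-D running prefix maxima, so the optimum over all split points costs the
same as two ordinary alignments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

_BASE_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i

MAX_DP_CELLS = 30_000_000  # ~360 MB for the three int32 matrices


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as int8 codes (N and others -> 4)."""
    return _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@njit(cache=True)
def _gotoh_local(q, r, match, mismatch, gap_open, gap_extend):
    """Local alignment DP; returns H, E, F (scores ending at each cell).

    E = best score ending at (i, j) with a gap in the query (consuming
    reference), F = gap in the reference (consuming query).  Opening a gap of
    length L costs gap_open + L * gap_extend.  Code 4 (N) never matches.
    """
    nq, nr = len(q), len(r)
    neg = -(10 ** 9)
    H = np.zeros((nq + 1, nr + 1), dtype=np.int32)
    E = np.full((nq + 1, nr + 1), neg, dtype=np.int32)
    F = np.full((nq + 1, nr + 1), neg, dtype=np.int32)
    for i in range(1, nq + 1):
        qi = q[i - 1]
        for j in range(1, nr + 1):
            e = max(H[i, j - 1] + gap_open + gap_extend,
                    E[i, j - 1] + gap_extend)
            f = max(H[i - 1, j] + gap_open + gap_extend,
                    F[i - 1, j] + gap_extend)
            s = match if (qi == r[j - 1] and qi != 4) else mismatch
            h = H[i - 1, j - 1] + s
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            H[i, j] = h
            E[i, j] = e
            F[i, j] = f
    return H, E, F


@njit(cache=True)
def _prefix_max_arg(H):
    """2-D running prefix maxima of H with argmax cell tracking.

    PF[i, j] = max over cells (i' <= i, j' <= j) of H; ties resolved toward
    the lexicographically smallest (i', j').
    """
    nq = H.shape[0] - 1
    nr = H.shape[1] - 1
    PF = np.zeros((nq + 1, nr + 1), dtype=np.int32)
    AI = np.zeros((nq + 1, nr + 1), dtype=np.int32)
    AJ = np.zeros((nq + 1, nr + 1), dtype=np.int32)
    for i in range(nq + 1):
        for j in range(nr + 1):
            best = H[i, j]
            bi, bj = i, j
            if i > 0:
                v = PF[i - 1, j]
                if v > best or (v == best and (AI[i - 1, j] < bi or
                                               (AI[i - 1, j] == bi and AJ[i - 1, j] < bj))):
                    best, bi, bj = v, AI[i - 1, j], AJ[i - 1, j]
            if j > 0:
                v = PF[i, j - 1]
                if v > best or (v == best and (AI[i, j - 1] < bi or
                                               (AI[i, j - 1] == bi and AJ[i, j - 1] < bj))):
                    best, bi, bj = v, AI[i, j - 1], AJ[i, j - 1]
            PF[i, j] = best
            AI[i, j] = bi
            AJ[i, j] = bj
    return PF, AI, AJ


def _traceback_local(q, r, H, E, F, end_i, end_j, match, mismatch,
                     gap_open, gap_extend):
    """Trace one local alignment back from its end cell.

    Returns (start_i, start_j, matches, columns).
    """
    i, j = end_i, end_j
    matches = columns = 0
    state = "H"
    while i > 0 or j > 0:
        if state == "H":
            if H[i, j] == 0:
                break
            s = match if (q[i - 1] == r[j - 1] and q[i - 1] != 4) else mismatch
            if i > 0 and j > 0 and H[i, j] == H[i - 1, j - 1] + s:
                if q[i - 1] == r[j - 1] and q[i - 1] != 4:
                    matches += 1
                columns += 1
                i -= 1
                j -= 1
            elif H[i, j] == E[i, j]:
                state = "E"
            elif H[i, j] == F[i, j]:
                state = "F"
            else:  # pragma: no cover - DP consistency guard
                raise AssertionError("inconsistent DP traceback")
        elif state == "E":
            columns += 1
            if E[i, j] == H[i, j - 1] + gap_open + gap_extend:
                j -= 1
                state = "H"
            else:
                j -= 1
        else:
            columns += 1
            if F[i, j] == H[i - 1, j] + gap_open + gap_extend:
                i -= 1
                state = "H"
            else:
                i -= 1
    return i, j, matches, columns


@dataclass(frozen=True)
class Block:
    """One aligned flank block of a split alignment (0-based half-open)."""

    query: tuple  # (start, end) in query coordinates
    ref: tuple  # (start, end) in reference-region coordinates
    identity: float
    score: int

    @property
    def empty(self) -> bool:
        return self.query[0] == self.query[1]


@dataclass(frozen=True)
class SplitAlignment:
    left_block: Block
    right_block: Block
    excised_ref: tuple  # reference interval skipped between the blocks
    inserted_query: tuple  # query interval skipped between the blocks
    total_score: int

    @property
    def excised_len(self) -> int:
        return self.excised_ref[1] - self.excised_ref[0]

    @property
    def inserted_len(self) -> int:
        return self.inserted_query[1] - self.inserted_query[0]


def local_align_score(query: str, ref: str, match: int = 1, mismatch: int = -1,
                      gap_open: int = -2, gap_extend: int = -1) -> int:
    """Best Smith-Waterman/Gotoh local alignment score (0 if none positive)."""
    if len(query) == 0 or len(ref) == 0:
        return 0
    H, _, _ = _gotoh_local(encode(query), encode(ref), match, mismatch,
                           gap_open, gap_extend)
    return int(H.max())


def split_align(query: str, ref: str, match: int = 1, mismatch: int = -1,
                gap_open: int = -2, gap_extend: int = -1) -> SplitAlignment:
    """Optimal split alignment of ``query`` against ``ref``.

    Ties between equal-scoring solutions are broken toward the leftmost
    excision start and then the shortest excision, by preferring
    lexicographically smallest block end cells.
    """
    if len(query) == 0:
        raise ValueError("empty query")
    nq, nr = len(query), len(ref)
    if (nq + 1) * (nr + 1) > MAX_DP_CELLS:
        raise ValueError(f"split_align instance too large: {nq} x {nr}")
    qc, rc = encode(query), encode(ref)
    Hf, Ef, Ff = _gotoh_local(qc, rc, match, mismatch, gap_open, gap_extend)
    qr, rr = qc[::-1].copy(), rc[::-1].copy()
    Hr, Er, Fr = _gotoh_local(qr, rr, match, mismatch, gap_open, gap_extend)
    PF, AIf, AJf = _prefix_max_arg(Hf)
    PR, AIr, AJr = _prefix_max_arg(Hr)
    # total score for split at (i, j): PF[i, j] + PR[nq - i, nr - j]
    T = PF + PR[::-1, ::-1]
    # scan splits with j (ref split) ascending, then i: leftmost excision wins
    best = np.unravel_index(int(np.argmax(T.T)), T.T.shape)
    si, sj = int(best[1]), int(best[0])
    total = int(T[si, sj])

    # left block: argmax cell of forward prefix max at the split
    lei, lej = int(AIf[si, sj]), int(AJf[si, sj])
    if Hf[lei, lej] > 0:
        lsi, lsj, lm, lc = _traceback_local(qc, rc, Hf, Ef, Ff, lei, lej,
                                            match, mismatch, gap_open, gap_extend)
        left = Block(query=(lsi, lei), ref=(lsj, lej),
                     identity=lm / lc if lc else 0.0,
                     score=int(Hf[lei, lej]))
    else:
        left = Block(query=(0, 0), ref=(0, 0), identity=0.0, score=0)

    # right block: argmax cell of reverse prefix max, mapped back
    rei_r, rej_r = int(AIr[nq - si, nr - sj]), int(AJr[nq - si, nr - sj])
    if Hr[rei_r, rej_r] > 0:
        rsi_r, rsj_r, rm, rc_ = _traceback_local(qr, rr, Hr, Er, Fr, rei_r,
                                                 rej_r, match, mismatch,
                                                 gap_open, gap_extend)
        # reverse coords k map to forward coords n - k
        right = Block(query=(nq - rei_r, nq - rsi_r),
                      ref=(nr - rej_r, nr - rsj_r),
                      identity=rm / rc_ if rc_ else 0.0,
                      score=int(Hr[rei_r, rej_r]))
    else:
        right = Block(query=(nq, nq), ref=(nr, nr), identity=0.0, score=0)

    excised = (left.ref[1], right.ref[0])
    inserted = (left.query[1], right.query[0])
    return SplitAlignment(left_block=left, right_block=right,
                          excised_ref=excised, inserted_query=inserted,
                          total_score=total)
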