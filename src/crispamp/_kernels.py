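"""Numba JIT kernels: affine-gap DP and paired-read overlap merging.

Sequences are passed as uint8 ASCII arrays.  'N' (78) never matches
anything, including itself.  All scores are integers; the position-specific
variant elevates the base scheme by ``scalar`` and adds raw (un-elevated)
bonuses, so bonuses can only break ties between base-optimal alignments.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -(1 << 40)  # -inf sentinel that survives int64 arithmetic

_N = 78  # ord('N')


@njit(cache=True)
def nw_score(q, r, match, mismatch, gap_open, gap_extend):
    """Optimal global affine-gap score (no bonuses).

    ``match`` is a reward; ``mismatch``/``gap_open``/``gap_extend`` are
    penalty magnitudes.  A gap of length k costs open + (k-1)*extend.
    """
    m, n = len(q), len(r)
    H = np.full((2, n + 1), NEG, dtype=np.int64)
    D = np.full((2, n + 1), NEG, dtype=np.int64)
    I = np.full((2, n + 1), NEG, dtype=np.int64)
    H[0, 0] = 0
    for j in range(1, n + 1):
        D[0, j] = -gap_open - (j - 1) * gap_extend
    cur, prev = 1, 0
    for i in range(1, m + 1):
        H[cur, 0] = NEG
        D[cur, 0] = NEG
        I[cur, 0] = -gap_open - (i - 1) * gap_extend
        qc = q[i - 1]
        for j in range(1, n + 1):
            sub = match if (qc == r[j - 1] and qc != _N) else -mismatch
            vdiag = H[prev, j - 1]
            if D[prev, j - 1] > vdiag:
                vdiag = D[prev, j - 1]
            if I[prev, j - 1] > vdiag:
                vdiag = I[prev, j - 1]
            H[cur, j] = vdiag + sub
            vleft = H[cur, j - 1]
            if I[cur, j - 1] > vleft:
                vleft = I[cur, j - 1]
            do = vleft - gap_open
            de = D[cur, j - 1] - gap_extend
            D[cur, j] = do if do >= de else de
            vup = H[prev, j]
            if D[prev, j] > vup:
                vup = D[prev, j]
            io = vup - gap_open
            ie = I[prev, j] - gap_extend
            I[cur, j] = io if io >= ie else ie
        cur, prev = prev, cur
    best = H[prev, n]
    if D[prev, n] > best:
        best = D[prev, n]
    if I[prev, n] > best:
        best = I[prev, n]
    return best


@njit(cache=True)
def psnw_dp(q, r, s_match, s_mismatch, s_open, s_extend, scalar,
            open_bonus, ext_del_bonus, ext_ins_bonus, ops_out):
    """Position-specific NW: full DP + traceback.

    Scores are ``scalar``-elevated; ``open_bonus`` (len n+1, bond-indexed)
    and the two extension-bonus arrays (deletion: len n, position-indexed;
    insertion: len n+1, bond-indexed) are added raw.  ``ops_out`` must have
    length >= m+n; op codes written: 0 = diagonal, 1 = deletion (ref
    consumed), 2 = insertion (query consumed).  Returns (n_ops, total_score).
    """
    m, n = len(q), len(r)
    SM = scalar * s_match
    SX = scalar * s_mismatch
    SO = scalar * s_open
    SE = scalar * s_extend

    H = np.full((m + 1, n + 1), NEG, dtype=np.int64)
    D = np.full((m + 1, n + 1), NEG, dtype=np.int64)
    I = np.full((m + 1, n + 1), NEG, dtype=np.int64)
    H[0, 0] = 0
    for j in range(1, n + 1):
        if j == 1:
            D[0, j] = H[0, 0] - SO + open_bonus[0]
        else:
            D[0, j] = D[0, j - 1] - SE + ext_del_bonus[j - 1]
    for i in range(1, m + 1):
        if i == 1:
            I[i, 0] = H[0, 0] - SO + open_bonus[0]
        else:
            I[i, 0] = I[i - 1, 0] - SE + ext_ins_bonus[0]
    for i in range(1, m + 1):
        qc = q[i - 1]
        for j in range(1, n + 1):
            sub = SM if (qc == r[j - 1] and qc != _N) else -SX
            vdiag = H[i - 1, j - 1]
            if D[i - 1, j - 1] > vdiag:
                vdiag = D[i - 1, j - 1]
            if I[i - 1, j - 1] > vdiag:
                vdiag = I[i - 1, j - 1]
            H[i, j] = vdiag + sub

            vleft = H[i, j - 1]
            if I[i, j - 1] > vleft:
                vleft = I[i, j - 1]
            do = vleft - SO + open_bonus[j - 1]
            de = D[i, j - 1] - SE + ext_del_bonus[j - 1]
            D[i, j] = do if do >= de else de

            vup = H[i - 1, j]
            if D[i - 1, j] > vup:
                vup = D[i - 1, j]
            io = vup - SO + open_bonus[j]
            ie = I[i - 1, j] - SE + ext_ins_bonus[j]
            I[i, j] = io if io >= ie else ie

    # traceback; state 0=H 1=D 2=I, prefer H, then D, then I at ties
    best = H[m, n]
    state = 0
    if D[m, n] > best:
        best, state = D[m, n], 1
    if I[m, n] > best:
        best, state = I[m, n], 2
    total = best
    i, j = m, n
    k = 0
    while i > 0 or j > 0:
        if state == 0:
            qc = q[i - 1]
            sub = SM if (qc == r[j - 1] and qc != _N) else -SX
            want = H[i, j] - sub
            ops_out[k] = 0
            k += 1
            i -= 1
            j -= 1
            if H[i, j] == want:
                state = 0
            elif D[i, j] == want:
                state = 1
            else:
                state = 2
        elif state == 1:
            # deletion consumed r[j-1]
            do_open = D[i, j] + SO - open_bonus[j - 1]
            ops_out[k] = 1
            k += 1
            j -= 1
            if j > 0 and D[i, j] == D[i, j + 1] + SE - ext_del_bonus[j]:
                state = 1
            elif H[i, j] == do_open:
                state = 0
            elif I[i, j] == do_open:
                state = 2
            else:
                state = 1
        else:
            io_open = I[i, j] + SO - open_bonus[j]
            ops_out[k] = 2
            k += 1
            i -= 1
            if i > 0 and I[i, j] == I[i + 1, j] + SE - ext_ins_bonus[j]:
                state = 2
            elif H[i, j] == io_open:
                state = 0
            elif D[i, j] == io_open:
                state = 1
            else:
                state = 2
    # ops are reversed in place by the caller
    return k, total


@njit(cache=True)
def score_columns(codes, q, r, match, mismatch, gap_open, gap_extend,
                  open_bonus, ext_del_bonus, ext_ins_bonus):
    """(base_score, bonus_score) of an alignment given as per-column op codes
    (0 = diagonal, 1 = deletion, 2 = insertion)."""
    i = 0
    j = 0
    base = 0
    bon = 0
    prev = -1
    for k in range(len(codes)):
        c = codes[k]
        if c == 0:
            if q[i] == r[j] and q[i] != _N:
                base += match
            else:
                base -= mismatch
            i += 1
            j += 1
        elif c == 1:
            if prev == 1:
                base -= gap_extend
                bon += ext_del_bonus[j]
            else:
                base -= gap_open
                bon += open_bonus[j]
            j += 1
        else:
            if prev == 2:
                base -= gap_extend
                bon += ext_ins_bonus[j]
            else:
                base -= gap_open
                bon += open_bonus[j]
            i += 1
        prev = c
    return base, bon


@njit(cache=True)
def merge_scan(r1, rc2, min_overlap, max_mismatch_density):
    """Find the best ungapped overlap between r1 and reverse-complemented r2.

    Scans every relative offset of rc2 against r1 (both "innie" and
    read-through "outie" layouts).  Returns (offset, overlap, mismatches);
    offset is rc2's start relative to r1's start (may be negative).  Best =
    lowest mismatch fraction, ties broken by longest overlap then smallest
    |offset|.  Returns (0, -1, 0) when nothing acceptable exists.
    """
    n1, n2 = len(r1), len(rc2)
    best_off = 0
    best_ov = -1
    best_mm = 0
    best_frac = 2.0
    for off in range(-(n2 - min_overlap), n1 - min_overlap + 1):
        lo = off if off > 0 else 0
        hi = off + n2 if off + n2 < n1 else n1
        ov = hi - lo
        if ov < min_overlap:
            continue
        mm = 0
        for t in range(lo, hi):
            if r1[t] != rc2[t - off]:
                mm += 1
        frac = mm / ov
        if frac > max_mismatch_density:
            continue
        better = False
        if frac < best_frac - 1e-12:
            better = True
        elif frac < best_frac + 1e-12:
            if ov > best_ov:
                better = True
            elif ov == best_ov:
                ao = off if off >= 0 else -off
                ab = best_off if best_off >= 0 else -best_off
                if ao < ab:
                    better = True
        if better:
            best_off, best_ov, best_mm, best_frac = off, ov, mm, frac
    return best_off, best_ov, best_mm


@njit(cache=True)
def build_merged(r1, q1, rc2, rq2, off, out_seq, out_qual):
    """Assemble the merged fragment for a chosen overlap offset.

    Overlap bases take the higher-quality read's call (ties -> r1).  For
    negative offsets (read-through), overhanging tails on both sides are
    trimmed and only the overlapped fragment is returned.  Returns length.
    """
    n1, n2 = len(r1), len(rc2)
    k = 0
    if off >= 0:
        for t in range(off):
            out_seq[k] = r1[t]
            out_qual[k] = q1[t]
            k += 1
        lo = off
        hi = off + n2 if off + n2 < n1 else n1
    else:
        lo = 0
        hi = n1 if n1 < off + n2 else off + n2
    for t in range(lo, hi):
        b2 = t - off
        if r1[t] == rc2[b2]:
            out_seq[k] = r1[t]
            out_qual[k] = q1[t] if q1[t] >= rq2[b2] else rq2[b2]
        elif rq2[b2] > q1[t]:
            out_seq[k] = rc2[b2]
            out_qual[k] = rq2[b2]
        else:
            out_seq[k] = r1[t]
            out_qual[k] = q1[t]
        k += 1
    if off >= 0:
        for t in range(hi - off, n2):
            out_seq[k] = rc2[t]
            out_qual[k] = rq2[t]
            k += 1
    return k
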