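"""Numba kernels for the two hot loops: anchor chaining and gap alignment.

Both have pure-Python brute-force oracles in the test suite; these versions
only add speed (banding, rolling score rows, packed traceback).
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = np.int64(-(1 << 40))

# alignment op codes shared with align.py
OP_EQ, OP_X, OP_INS, OP_DEL = 0, 1, 2, 3


@njit(cache=True)
def chain_dp(seq_id, group, u, v, d):  # pragma: no cover - exercised via chain module
    """Anchor chaining DP: score(i) = 1 + max score(j) over precursors.

    Anchors must be sorted by (seq_id, v). A precursor j of i needs equal
    seq_id and group, 0 < v_i - v_j <= d and 0 < u_i - u_j <= d. Ties on
    score resolve to the largest j (nearest precursor). Returns
    (score, pred) with pred = -1 where no precursor exists.
    """
    n = u.size
    score = np.ones(n, dtype=np.int64)
    pred = np.full(n, -1, dtype=np.int64)
    for i in range(n):
        si = seq_id[i]
        gi = group[i]
        ui = u[i]
        vi = v[i]
        best = np.int64(0)
        bj = -1
        j = i - 1
        while j >= 0:
            if seq_id[j] != si:
                break  # sorted by seq_id first: no earlier same-seq anchors
            dv = vi - v[j]
            if dv > d:
                break  # v ascending within a sequence
            if group[j] == gi and dv > 0:
                du = ui - u[j]
                if 0 < du <= d and score[j] > best:
                    best = score[j]
                    bj = j
            j -= 1
        if bj >= 0:
            score[i] = best + 1
            pred[i] = bj
    return score, pred


@njit(cache=True)
def gotoh(a, b, match, mismatch, gap_open, gap_ext, band,
          free_b_start, free_b_end):  # pragma: no cover - exercised via align module
    """Affine-gap global alignment (Gotoh three-state DP), optionally banded.

    A gap of length L costs ``gap_open + L * gap_ext`` (both negative).
    ``band`` is the half-width of a diagonal band; the effective half-width
    is ``band + |len(a) - len(b)|`` so the corner-to-corner path always
    fits; pass band >= max(len) for a full DP. With ``free_b_start``
    (``free_b_end``) leading (trailing) unaligned reference bases cost
    nothing and are reported via j_start/j_end rather than emitted as ops.

    Returns (score, ops, n_ops, j_start, j_end): ops is a uint8 array of
    per-column op codes (OP_EQ/OP_X/OP_INS/OP_DEL) whose first ``n_ops``
    entries are valid; the alignment covers b[j_start:j_end).
    """
    n = a.size
    m = b.size
    W = band + abs(n - m)
    mx = n if n > m else m
    if W > mx:
        W = mx  # band covers the whole matrix: full DP
    width = 2 * W + 2

    # rolling score rows; packed traceback: bits 0-1 M, 2-3 I, 4-5 D
    # from-state codes: 0=M, 1=I, 2=D, 3=alignment origin
    tb = np.zeros((n + 1, width), dtype=np.uint8)
    Mprev = np.full(width, NEG, dtype=np.int64)
    Iprev = np.full(width, NEG, dtype=np.int64)
    Dprev = np.full(width, NEG, dtype=np.int64)
    Mcur = np.full(width, NEG, dtype=np.int64)
    Icur = np.full(width, NEG, dtype=np.int64)
    Dcur = np.full(width, NEG, dtype=np.int64)

    # row 0: origin at (0,0); free origins along row 0 if free_b_start;
    # D-chain open + j*ext always available.
    hi0 = m if m < W else W
    for j in range(0, hi0 + 1):
        if j == 0:
            Mprev[j] = 0
            tb[0, j] = 3
        else:
            if free_b_start:
                Mprev[j] = 0
                tb[0, j] |= np.uint8(3)
            Dprev[j] = gap_open + gap_ext * j
            tb[0, j] |= np.uint8((2 if j > 1 else 0) << 4)

    best_score = NEG
    best_state = 0
    best_j = m

    lop = 0
    for i in range(1, n + 1):
        lo = i - W
        if lo < 0:
            lo = 0
        hi = i + W
        if hi > m:
            hi = m
        for c in range(width):
            Mcur[c] = NEG
            Icur[c] = NEG
            Dcur[c] = NEG
        ai = a[i - 1]
        for j in range(lo, hi + 1):
            c = j - lo
            t = np.uint8(0)
            # I: consume a[i-1] only, from (i-1, j)
            cj = j - lop
            if 0 <= cj < width:
                sM = Mprev[cj] + gap_open + gap_ext
                sI = Iprev[cj] + gap_ext
                sD = Dprev[cj] + gap_open + gap_ext
                if sM >= sI and sM >= sD:
                    Icur[c] = sM
                elif sI >= sD:
                    Icur[c] = sI
                    t |= np.uint8(1 << 2)
                else:
                    Icur[c] = sD
                    t |= np.uint8(2 << 2)
            if j > lo:
                # D: consume b[j-1] only, from (i, j-1)
                sM = Mcur[c - 1] + gap_open + gap_ext
                sI = Icur[c - 1] + gap_open + gap_ext
                sD = Dcur[c - 1] + gap_ext
                if sM >= sI and sM >= sD:
                    Dcur[c] = sM
                elif sD >= sI:
                    Dcur[c] = sD
                    t |= np.uint8(2 << 4)
                else:
                    Dcur[c] = sI
                    t |= np.uint8(1 << 4)
            if j > 0:
                # M: consume both, from (i-1, j-1)
                cd = j - 1 - lop
                if 0 <= cd < width:
                    s = match if ai == b[j - 1] else mismatch
                    sM = Mprev[cd]
                    sI = Iprev[cd]
                    sD = Dprev[cd]
                    if sM >= sI and sM >= sD:
                        if sM > NEG:
                            Mcur[c] = sM + s
                    elif sI >= sD:
                        Mcur[c] = sI + s
                        t |= np.uint8(1)
                    else:
                        Mcur[c] = sD + s
                        t |= np.uint8(2)
            tb[i, c] = t
        Mprev, Mcur = Mcur, Mprev
        Iprev, Icur = Icur, Iprev
        Dprev, Dcur = Dcur, Dprev
        lop = lo

    # pick the end cell: (n, m), or best over the last row if free_b_end
    lon = n - W
    if lon < 0:
        lon = 0
    hin = n + W
    if hin > m:
        hin = m
    if free_b_end:
        for j in range(lon, hin + 1):
            c = j - lon
            if Mprev[c] > best_score:
                best_score = Mprev[c]
                best_state = 0
                best_j = j
            if Iprev[c] > best_score:
                best_score = Iprev[c]
                best_state = 1
                best_j = j
            if Dprev[c] > best_score:
                best_score = Dprev[c]
                best_state = 2
                best_j = j
    else:
        c = m - lon
        best_score = Mprev[c]
        best_state = 0
        best_j = m
        if Iprev[c] > best_score:
            best_score = Iprev[c]
            best_state = 1
        if Dprev[c] > best_score:
            best_score = Dprev[c]
            best_state = 2

    # traceback
    ops = np.empty(n + m + 2, dtype=np.uint8)
    p = ops.size
    i = n
    j = best_j
    st = best_state
    while True:
        lo = i - W
        if lo < 0:
            lo = 0
        t = tb[i, j - lo]
        if st == 0:
            if i == 0:
                # must be an origin cell (M[0][j] is NEG otherwise)
                break
            frm = int(t & np.uint8(3))
            p -= 1
            ops[p] = OP_EQ if a[i - 1] == b[j - 1] else OP_X
            i -= 1
            j -= 1
            st = 0 if frm == 3 else frm
        elif st == 1:
            frm = int((t >> np.uint8(2)) & np.uint8(3))
            p -= 1
            ops[p] = OP_INS
            i -= 1
            st = frm
        else:
            frm = int((t >> np.uint8(4)) & np.uint8(3))
            p -= 1
            ops[p] = OP_DEL
            j -= 1
            st = frm
    j_start = j
    n_ops = ops.size - p
    out = ops[p:].copy()
    return best_score, out, n_ops, j_start, best_j
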