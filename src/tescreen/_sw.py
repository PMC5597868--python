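"""Alignment kernels for bait screening.

Two routes are computed per read/bait pair:

* ``sw_align`` — optimal Smith–Waterman local alignment under linear gap
  scoring, with deterministic tie-breaking (smallest read start, then smallest
  bait start, then smallest ends).
* ``scan_align`` — best ungapped placement of the bait over every offset,
  with partial overlap permitted only at the read boundaries. This recovers
  full-span matches whose outermost bait positions are mismatches, which an
  optimal local alignment would trim away.

Both are numba-compiled; callers pass sequences encoded as uint8 codes
(A=0, C=1, G=2, T=3, N=4). Code 4 never matches anything, including itself.
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: sentinel for "no alignment"
NO_HIT = -1

_ENCODE_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGTN"):
    _ENCODE_LUT[_b] = _i
for _i, _b in enumerate(b"acgtn"):
    _ENCODE_LUT[_b] = _i

_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Encode an A/C/G/T/N string to uint8 codes."""
    arr = _ENCODE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if arr.max(initial=0) > 4:
        raise ValueError(f"sequence contains non-ACGTN characters: {seq[:50]!r}")
    return arr


def decode(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode("ascii")


@njit(cache=False)
def _traceback(H, read, bait, i, j, match, mismatch, gap):
    """Walk back from end cell (i, j); returns (rs, bs, matches, mismatches, gaps).

    Move preference diagonal > up > left makes the walk deterministic.
    """
    m = 0
    x = 0
    g = 0
    while H[i, j] > 0:
        s = match if (read[i - 1] == bait[j - 1] and read[i - 1] < 4) else mismatch
        if i > 0 and j > 0 and H[i, j] == H[i - 1, j - 1] + s:
            if s == match:
                m += 1
            else:
                x += 1
            i -= 1
            j -= 1
        elif i > 0 and H[i, j] == H[i - 1, j] + gap:
            g += 1
            i -= 1
        else:
            g += 1
            j -= 1
    return i, j, m, x, g


@njit(cache=False)
def sw_align(read, bait, match, mismatch, gap, H):
    """Best-scoring local alignment of ``bait`` within ``read``.

    ``H`` is a reusable workspace of shape at least
    ``(len(read)+1, len(bait)+1)`` whose first row and column stay zero.
    Returns ``(score, read_start, read_end, bait_start, bait_end, matches,
    mismatches, gaps)`` with half-open spans; score 0 means no alignment.
    """
    n = read.shape[0]
    w = bait.shape[0]
    best = 0
    for i in range(1, n + 1):
        ri = read[i - 1]
        for j in range(1, w + 1):
            s = match if (ri == bait[j - 1] and ri < 4) else mismatch
            h = H[i - 1, j - 1] + s
            if H[i - 1, j] + gap > h:
                h = H[i - 1, j] + gap
            if H[i, j - 1] + gap > h:
                h = H[i, j - 1] + gap
            if h < 0:
                h = 0
            H[i, j] = h
            if h > best:
                best = h
    if best <= 0:
        return 0, NO_HIT, NO_HIT, NO_HIT, NO_HIT, 0, 0, 0
    # among maximal end cells, pick the traceback start with the smallest
    # (read_start, bait_start), then the smallest (read_end, bait_end)
    brs = bbs = bre = bbe = -1
    bm = bx = bg = 0
    found = False
    for i in range(1, n + 1):
        for j in range(1, w + 1):
            if H[i, j] != best:
                continue
            rs, bs, m, x, g = _traceback(H, read, bait, i, j, match, mismatch, gap)
            better = False
            if not found:
                better = True
            elif rs < brs or (
                rs == brs and (bs < bbs or (bs == bbs and (i < bre or (i == bre and j < bbe))))
            ):
                better = True
            if better:
                brs, bbs, bre, bbe = rs, bs, i, j
                bm, bx, bg = m, x, g
                found = True
    return best, brs, bre, bbs, bbe, bm, bx, bg


@njit(cache=False)
def scan_align(read, bait, min_overlap, match, mismatch):
    """Best ungapped placement of ``bait`` across ``read``.

    Offsets run from ``-(len(bait) - min_overlap)`` (bait hanging off the read
    start) to ``len(read) - min_overlap`` (hanging off the read end); interior
    placements always cover the full bait. Ties prefer the smallest read
    offset, then the smallest bait offset. Returns ``(score, read_start,
    read_end, bait_start, bait_end, matches, mismatches)`` or score
    ``-2**30`` when no offset yields the minimum overlap.
    """
    n = read.shape[0]
    w = bait.shape[0]
    best_score = -(2 ** 30)
    brs = bre = bbs = bbe = NO_HIT
    bm = bx = 0
    for o in range(-(w - min_overlap), n - min_overlap + 1):
        bs = -o if o < 0 else 0
        be = w if o + w <= n else n - o
        ov = be - bs
        if ov < min_overlap:
            continue
        rs = o + bs
        m = 0
        for t in range(ov):
            a = read[rs + t]
            if a == bait[bs + t] and a < 4:
                m += 1
        x = ov - m
        score = match * m + mismatch * x
        if score > best_score or (
            score == best_score and (rs < brs or (rs == brs and bs < bbs))
        ):
            best_score = score
            brs, bre, bbs, bbe = rs, rs + ov, bs, be
            bm, bx = m, x
    return best_score, brs, bre, bbs, bbe, bm, bx


@njit(cache=False)
def screen_read(read, baits, match, mismatch, gap, min_match_len, min_identity, H, out):
    """Best bait hit for one read, applying the length and identity thresholds.

    ``baits`` is a ``(4, L)`` code matrix in fixed bait order. ``out`` is an
    int64 vector of length 10 filled with ``(bait_idx, route, score,
    read_start, read_end, bait_start, bait_end, matches, mismatches, gaps)``;
    ``bait_idx == -1`` means no passing hit. Candidates are ranked by score,
    then bait order, then route (gapped local alignment before ungapped scan).
    """
    out[0] = NO_HIT
    best_score = -(2 ** 30)
    for b in range(baits.shape[0]):
        bait = baits[b]
        score, rs, re_, bs, be, m, x, g = sw_align(read, bait, match, mismatch, gap, H)
        span = be - bs
        if score > 0 and span >= min_match_len and m >= min_identity * span - 1e-6:
            if score > best_score:
                best_score = score
                out[0] = b
                out[1] = 0
                out[2] = score
                out[3] = rs
                out[4] = re_
                out[5] = bs
                out[6] = be
                out[7] = m
                out[8] = x
                out[9] = g
        score, rs, re_, bs, be, m, x = scan_align(read, bait, min_match_len, match, mismatch)
        span = be - bs
        if rs != NO_HIT and span >= min_match_len and m >= min_identity * span - 1e-6:
            if score > best_score:
                best_score = score
                out[0] = b
                out[1] = 1
                out[2] = score
                out[3] = rs
                out[4] = re_
                out[5] = bs
                out[6] = be
                out[7] = m
                out[8] = x
                out[9] = 0


@njit(cache=False)
def screen_batch(reads, lengths, baits, match, mismatch, gap, min_match_len, min_identity, out):
    """Run :func:`screen_read` over a padded read matrix.

    ``reads`` is ``(N, maxlen)`` uint8 (padding value arbitrary; only the
    first ``lengths[r]`` codes of row ``r`` are used). ``out`` is ``(N, 10)``
    int64, filled per read as in :func:`screen_read`.
    """
    maxlen = reads.shape[1]
    H = np.zeros((maxlen + 1, baits.shape[1] + 1), dtype=np.int64)
    for r in range(reads.shape[0]):
        read = reads[r, : lengths[r]]
        screen_read(read, baits, match, mismatch, gap, min_match_len, min_identity, H, out[r])
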