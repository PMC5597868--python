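"""Independent brute-force dynamic-programming oracle for local alignment.

Plain-Python score-only Smith-Waterman with linear gaps, written separately
from (and before) the package's compiled kernel so the two can be compared.
"""

from __future__ import annotations


def sw_score_bruteforce(a: str, b: str, match: int = 2, mismatch: int = -3, gap: int = -4) -> int:
    """Best local-alignment score of ``b`` within ``a`` (N matches nothing)."""
    best = 0
    prev = [0] * (len(b) + 1)
    for i in range(1, len(a) + 1):
        cur = [0] * (len(b) + 1)
        ai = a[i - 1]
        for j in range(1, len(b) + 1):
            s = match if (ai == b[j - 1] and ai != "N") else mismatch
            v = prev[j - 1] + s
            if prev[j] + gap > v:
                v = prev[j] + gap
            if cur[j - 1] + gap > v:
                v = cur[j - 1] + gap
            if v < 0:
                v = 0
            cur[j] = v
            if v > best:
                best = v
        prev = cur
    return best
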