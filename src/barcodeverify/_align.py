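"""Semi-global (overlap) alignment for percent-identity scoring.

Barcode queries and reference records share a core region but differ in
length across primer sets, so identity is computed on an overlap alignment:
end gaps on either sequence are free and excluded from the aligned columns.

Scoring: IUPAC-compatible column +1, incompatible column -1, internal gap
column -2 (linear). Among score-optimal alignments the one with the most
matching columns is taken, and among those the one with the fewest columns,
so the reported (identity, overlap) pair is a well-defined function of the
two sequences — no dependence on traceback tie-breaking. The three-level
objective is folded into a single int64 per DP cell:

    enc = score * K^2 + matches * K + (CMAX - columns)

which orders identically to the tuple (score, matches, -columns) because
matches and columns are bounded by len(a) + len(b) < K.
"""

from __future__ import annotations

import numpy as np

from .iupac import mask_array

_K = 8192  # digit base; sequences up to ~4000 nt per side
_CMAX = _K - 1

_D_MATCH = _K * _K + _K - 1       # (+1 score, +1 match, +1 column)
_D_MISMATCH = -(_K * _K) - 1      # (-1 score, +1 column)
_D_GAP = -2 * (_K * _K) - 1       # (-2 score, +1 column)
_EMPTY = _CMAX                    # enc of (0, 0, 0)


def identity_overlap(a: str, b: str) -> tuple[float, int]:
    """(identity, overlap) of the best overlap alignment of ``a`` and ``b``.

    identity = matching columns / aligned columns (end gaps excluded);
    a column matches when the two codes' base sets intersect. overlap is
    the aligned column count. Returns (0.0, 0) when the best alignment
    is empty (completely dissimilar sequences).
    """
    if not a or not b:
        raise ValueError("pairwise identity requires two non-empty sequences")
    ma, mb = mask_array(a), mask_array(b)
    if (ma == 0).any() or (mb == 0).any():
        raise ValueError("sequences must be IUPAC DNA")
    n, m = len(a), len(b)
    if n + m >= _K:
        raise ValueError(f"sequences too long for identity scoring (>{_K} total)")

    j_idx = np.arange(1, m + 1, dtype=np.int64)
    gap_shift = j_idx * _D_GAP
    prev = np.full(m + 1, _EMPTY, dtype=np.int64)  # free leading gaps in a
    best = prev[m]
    cur = np.empty(m + 1, dtype=np.int64)
    for i in range(1, n + 1):
        compat = (mb & ma[i - 1]) != 0
        diag = prev[:-1] + np.where(compat, _D_MATCH, _D_MISMATCH)
        up = prev[1:] + _D_GAP
        base = np.maximum(diag, up)
        # left-gap dependency via prefix max: cur[j] = max(base[j], cur[j-1]+gap)
        w = np.maximum.accumulate(
            np.concatenate(([np.int64(_EMPTY)], base - gap_shift))
        )
        cur[0] = _EMPTY  # free leading gaps in b
        cur[1:] = w[1:] + gap_shift
        if cur[m] > best:  # free trailing gaps in b
            best = cur[m]
        prev, cur = cur, prev
    best = max(best, int(prev.max()))  # free trailing gaps in a (last row)

    low = int(best) % (_K * _K)
    matches = low // _K
    columns = _CMAX - (low % _K)
    if columns == 0:
        return 0.0, 0
    return matches / columns, columns
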