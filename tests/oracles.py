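"""Independent oracles used by the test suite.

These deliberately re-derive results by brute force (exhaustive DP, fine
grids, per-column vote) so that the implementations they check can never
share code with them.
"""

import numpy as np
from numba import njit


@njit(cache=False)
def _sw_affine(a, b, match, mismatch, gap_open, gap_extend):
    n, m = a.shape[0], b.shape[0]
    neg = -10 ** 9
    H = np.zeros((n + 1, m + 1), dtype=np.int64)
    E = np.full((n + 1, m + 1), neg, dtype=np.int64)
    F = np.full((n + 1, m + 1), neg, dtype=np.int64)
    best = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i, j] = max(H[i, j - 1] + gap_open, E[i, j - 1] + gap_extend)
            F[i, j] = max(H[i - 1, j] + gap_open, F[i - 1, j] + gap_extend)
            s = match if a[i - 1] == b[j - 1] else mismatch
            h = H[i - 1, j - 1] + s
            if E[i, j] > h:
                h = E[i, j]
            if F[i, j] > h:
                h = F[i, j]
            if h < 0:
                h = 0
            H[i, j] = h
            if h > best:
                best = h
    return best


def smith_waterman_score(read: str, segment: str, match=2, mismatch=-3,
                         gap_open=-5, gap_extend=-2) -> int:
    """Exhaustive affine-gap local alignment score (Gotoh); a length-k gap
    costs ``|gap_open| + |gap_extend| * (k - 1)``."""
    a = np.frombuffer(read.encode(), dtype=np.uint8).astype(np.int64)
    b = np.frombuffer(segment.encode(), dtype=np.uint8).astype(np.int64)
    return int(_sw_affine(a, b, match, mismatch, gap_open, gap_extend))


def fine_grid_auc(x, y, n_per_segment=5000) -> float:
    """Midpoint Riemann sum of the piecewise-linear interpolant of (x, y),
    with the grid aligned to the breakpoints (exact for linear pieces)."""
    x = np.asarray(x, dtype=float)
    y = np.clip(np.asarray(y, dtype=float), 0.0, None)
    order = np.argsort(x)
    x, y = x[order], y[order]
    total = 0.0
    for x0, x1 in zip(x[:-1], x[1:]):
        edges = np.linspace(x0, x1, n_per_segment + 1)
        mids = (edges[:-1] + edges[1:]) / 2
        total += float(np.interp(mids, x, y).sum() * (x1 - x0) / n_per_segment)
    return total


def majority_consensus(seqs) -> str:
    """Per-column majority vote with lexicographic tie-break."""
    out = []
    for col in zip(*seqs):
        counts = {}
        for c in col:
            counts[c] = counts.get(c, 0) + 1
        best = max(sorted(counts), key=lambda c: counts[c])
        out.append(best)
    return "".join(out)


def translate_and_scan_productive(chain_nt: str, junction: str) -> bool:
    """Independent productivity call: in-frame junction and a stop-free
    translation of the full chain from position 0."""
    from Bio.Seq import Seq

    if len(junction) % 3 != 0:
        return False
    trimmed = chain_nt[: len(chain_nt) - len(chain_nt) % 3]
    return "*" not in str(Seq(trimmed).translate())
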