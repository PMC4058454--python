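"""Independent reference implementations used only to check the package.

Each oracle takes a deliberately different computational route from the
implementation it verifies: the Otsu oracle minimizes within-class
variance over the *full* threshold space by dense enumeration; the hole
oracle flood-fills the background from the border with an explicit BFS;
the convolution oracle is a direct quadruple-loop 2-D convolution.
"""

from __future__ import annotations

from collections import deque

import numpy as np

N_BINS = 256


def exhaustive_otsu3(values) -> tuple[float, float, float]:
    """Exhaustive minimizer of within-class variance over all ordered
    256-bin threshold triples (equivalent to maximizing between-class
    variance); first occurrence in C order = lexicographically smallest."""
    bins = np.minimum(
        (np.clip(np.asarray(values, float), 0, 1) * N_BINS).astype(int), N_BINS - 1
    )
    counts = np.bincount(bins, minlength=N_BINS).astype(float)
    x = np.arange(N_BINS, dtype=float)
    P = np.concatenate([[0], np.cumsum(counts)])
    S = np.concatenate([[0], np.cumsum(counts * x)])
    Q = np.concatenate([[0], np.cumsum(counts * x * x)])

    def wcv(a, b):
        p = P[b + 1] - P[a]
        s = S[b + 1] - S[a]
        q = Q[b + 1] - Q[a]
        return np.where(p > 0, q - s * s / np.maximum(p, 1), 0.0)

    t = np.arange(N_BINS)
    t1, t2, t3 = t[:, None, None], t[None, :, None], t[None, None, :]
    tot = wcv(0, t1) + wcv(t1 + 1, t2) + wcv(t2 + 1, t3) + wcv(t3 + 1, N_BINS - 1)
    tot = np.where((t1 < t2) & (t2 < t3), tot, np.inf)
    idx = np.unravel_index(int(np.argmin(tot)), tot.shape)
    return tuple((i + 1) / N_BINS for i in idx)


def flood_fill_holes(mask: np.ndarray) -> np.ndarray:
    """Holes = background pixels not reachable from the border by
    4-connected BFS through background."""
    mask = np.asarray(mask, bool)
    h, w = mask.shape
    seen = np.zeros_like(mask)
    dq: deque = deque()
    for r in range(h):
        for c in (0, w - 1):
            if not mask[r, c] and not seen[r, c]:
                seen[r, c] = True
                dq.append((r, c))
    for c in range(w):
        for r in (0, h - 1):
            if not mask[r, c] and not seen[r, c]:
                seen[r, c] = True
                dq.append((r, c))
    while dq:
        r, c = dq.popleft()
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and not mask[rr, cc] and not seen[rr, cc]:
                seen[rr, cc] = True
                dq.append((rr, cc))
    return ~mask & ~seen


def brute_convolve2d_reflect(image: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Direct O(N^2 K^2) 2-D convolution with reflect (symmetric) borders."""
    kr = kernel.shape[0] // 2
    padded = np.pad(image, kr, mode="symmetric")
    out = np.zeros_like(image, dtype=float)
    kf = kernel[::-1, ::-1]
    h, w = image.shape
    for r in range(h):
        for c in range(w):
            out[r, c] = (padded[r : r + 2 * kr + 1, c : c + 2 * kr + 1] * kf).sum()
    return out


def best_matching_count(ious: dict, min_overlap: float) -> int:
    """Maximum one-to-one matching size by brute force over subsets."""
    import itertools

    pairs = [(g, p) for (g, p), v in ious.items() if v >= min_overlap]
    best = 0
    for k in range(len(pairs), 0, -1):
        for combo in itertools.combinations(pairs, k):
            gs = [g for g, _ in combo]
            ps = [p for _, p in combo]
            if len(set(gs)) == k and len(set(ps)) == k:
                return k
    return best
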