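"""Independent brute-force oracles used by the test suite.

Everything here is written as plain loops / set algebra, deliberately
sharing no code with the package implementation it checks.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def dsc_bruteforce(a: np.ndarray, b: np.ndarray) -> float:
    """Dice coefficient via explicit coordinate sets."""
    sa = {tuple(c) for c in np.argwhere(np.asarray(a, dtype=bool))}
    sb = {tuple(c) for c in np.argwhere(np.asarray(b, dtype=bool))}
    return 2.0 * len(sa & sb) / (len(sa) + len(sb))


def icc21_bruteforce(x: np.ndarray) -> float:
    """ICC(2,1) from the full two-way ANOVA decomposition by explicit sums."""
    x = np.asarray(x, dtype=float)
    n, k = x.shape
    grand = sum(x[i][j] for i in range(n) for j in range(k)) / (n * k)
    row = [sum(x[i][j] for j in range(k)) / k for i in range(n)]
    col = [sum(x[i][j] for i in range(n)) / n for j in range(k)]
    ss_rows = k * sum((r - grand) ** 2 for r in row)
    ss_cols = n * sum((c - grand) ** 2 for c in col)
    ss_err = sum(
        (x[i][j] - row[i] - col[j] + grand) ** 2
        for i in range(n)
        for j in range(k)
    )
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0:
        return float("nan")
    return (msr - mse) / denom


def _in_roi(L, c):
    return all(0 <= ci < si for ci, si in zip(c, L.shape)) and L[c] > 0


def glcm_bruteforce(L: np.ndarray, direction) -> np.ndarray:
    """Symmetric co-occurrence counts for one direction by voxel loops."""
    ng = int(L.max())
    P = np.zeros((ng, ng))
    for idx in np.ndindex(L.shape):
        if L[idx] == 0:
            continue
        nb = tuple(i + d for i, d in zip(idx, direction))
        if _in_roi(L, nb):
            P[L[idx] - 1, L[nb] - 1] += 1
            P[L[nb] - 1, L[idx] - 1] += 1
    return P


def glrlm_bruteforce(L: np.ndarray, direction) -> np.ndarray:
    """Run-length counts by enumerating every maximal run along a direction."""
    ng = int(L.max())
    runs = []
    for idx in np.ndindex(L.shape):
        if L[idx] == 0:
            continue
        prev = tuple(i - d for i, d in zip(idx, direction))
        if _in_roi(L, prev) and L[prev] == L[idx]:
            continue  # not a run start
        length = 1
        cur = idx
        while True:
            nxt = tuple(i + d for i, d in zip(cur, direction))
            if _in_roi(L, nxt) and L[nxt] == L[idx]:
                length += 1
                cur = nxt
            else:
                break
        runs.append((int(L[idx]), length))
    max_len = max(l for _, l in runs)
    M = np.zeros((ng, max_len))
    for g, l in runs:
        M[g - 1, l - 1] += 1
    return M


def _neighbors26(idx, shape):
    out = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if dx == dy == dz == 0:
                    continue
                nb = (idx[0] + dx, idx[1] + dy, idx[2] + dz)
                if all(0 <= c < s for c, s in zip(nb, shape)):
                    out.append(nb)
    return out


def glszm_bruteforce(L: np.ndarray) -> np.ndarray:
    """Zone sizes by breadth-first flood fill under 26-connectivity."""
    ng = int(L.max())
    seen = np.zeros(L.shape, dtype=bool)
    zones = []
    for idx in np.ndindex(L.shape):
        if L[idx] == 0 or seen[idx]:
            continue
        level = L[idx]
        size = 0
        q = deque([idx])
        seen[idx] = True
        while q:
            cur = q.popleft()
            size += 1
            for nb in _neighbors26(cur, L.shape):
                if not seen[nb] and L[nb] == level:
                    seen[nb] = True
                    q.append(nb)
        zones.append((int(level), size))
    max_size = max(s for _, s in zones)
    M = np.zeros((ng, max_size))
    for g, s in zones:
        M[g - 1, s - 1] += 1
    return M


def ngtdm_bruteforce(L: np.ndarray) -> np.ndarray:
    """Per-level neighbor-difference sums by explicit neighborhood loops."""
    ng = int(L.max())
    M = np.zeros((ng, 2))
    for idx in np.ndindex(L.shape):
        if L[idx] == 0:
            continue
        nb_levels = [L[nb] for nb in _neighbors26(idx, L.shape) if L[nb] > 0]
        if not nb_levels:
            continue
        avg = sum(nb_levels) / len(nb_levels)
        M[L[idx] - 1, 0] += 1
        M[L[idx] - 1, 1] += abs(L[idx] - avg)
    return M


def gldm_bruteforce(L: np.ndarray, alpha: int = 0) -> np.ndarray:
    """Dependence counts (column j = dependent neighbors + 1) by loops."""
    ng = int(L.max())
    counts = []
    for idx in np.ndindex(L.shape):
        if L[idx] == 0:
            continue
        dep = sum(
            1
            for nb in _neighbors26(idx, L.shape)
            if L[nb] > 0 and abs(int(L[nb]) - int(L[idx])) <= alpha
        )
        counts.append((int(L[idx]), dep))
    max_dep = max(d for _, d in counts)
    M = np.zeros((ng, max_dep + 1))
    for g, d in counts:
        M[g - 1, d] += 1
    return M


def glcm_contrast_bruteforce(P: np.ndarray) -> float:
    """Sum_{i,j} p(i,j) (i-j)^2 by direct double loop."""
    total = P.sum()
    out = 0.0
    for i in range(P.shape[0]):
        for j in range(P.shape[1]):
            out += (P[i, j] / total) * (i - j) ** 2
    return out
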