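"""Independent brute-force oracles used to validate the fast implementations.

These are written as literal, loop-based transcriptions of the defining
formulas — a double loop over pixels and window offsets for the bilateral
filter, an explicit flood fill plus direct sums for the zone matrix — and
deliberately share no code with the package.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np


def _pad(g: np.ndarray, radius: int, border_mode: str) -> np.ndarray:
    mode = {"reflect": "symmetric", "constant": "constant", "edge": "edge"}[border_mode]
    return np.pad(g, radius, mode=mode)


def bilateral_oracle(
    g: np.ndarray, sigma_d: float, sigma_r: float, radius: int, border_mode: str = "reflect"
) -> np.ndarray:
    """Literal per-pixel double loop over the window: weighted average with
    Gaussian domain and range kernels, normalised per pixel."""
    g = np.asarray(g, dtype=np.float64)
    h, w = g.shape
    padded = _pad(g, radius, border_mode)
    out = np.empty_like(g)
    for y in range(h):
        for x in range(w):
            centre = g[y, x]
            num = 0.0
            den = 0.0
            for dy in range(-radius, radius + 1):
                for dx in range(-radius, radius + 1):
                    v = padded[y + radius + dy, x + radius + dx]
                    wgt = math.exp(-(dy * dy + dx * dx) / (2.0 * sigma_d * sigma_d)) * math.exp(
                        -((v - centre) ** 2) / (2.0 * sigma_r * sigma_r)
                    )
                    num += wgt * v
                    den += wgt
            out[y, x] = num / den
    return out


def domain_oracle(
    g: np.ndarray, sigma_d: float, radius: int, border_mode: str = "reflect"
) -> np.ndarray:
    """Per-pixel weighted average with the spatial Gaussian kernel only."""
    g = np.asarray(g, dtype=np.float64)
    h, w = g.shape
    padded = _pad(g, radius, border_mode)
    out = np.empty_like(g)
    for y in range(h):
        for x in range(w):
            num = 0.0
            den = 0.0
            for dy in range(-radius, radius + 1):
                for dx in range(-radius, radius + 1):
                    wgt = math.exp(-(dy * dy + dx * dx) / (2.0 * sigma_d * sigma_d))
                    num += wgt * padded[y + radius + dy, x + radius + dx]
                    den += wgt
            out[y, x] = num / den
    return out


def glszm_oracle(levels: np.ndarray, n_levels: int, connectivity: int) -> np.ndarray:
    """Zone matrix by explicit breadth-first flood fill.

    Returns an (n_levels, n_pixels) count array trimmed to the largest
    zone size found.
    """
    levels = np.asarray(levels, dtype=int)
    h, w = levels.shape
    if connectivity == 4:
        neigh = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    elif connectivity == 8:
        neigh = [(dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1) if (dy, dx) != (0, 0)]
    else:
        raise ValueError("connectivity must be 4 or 8")
    visited = np.zeros((h, w), dtype=bool)
    counts = np.zeros((n_levels, h * w), dtype=np.int64)
    s_max = 1
    for sy in range(h):
        for sx in range(w):
            if visited[sy, sx]:
                continue
            level = levels[sy, sx]
            size = 0
            queue = deque([(sy, sx)])
            visited[sy, sx] = True
            while queue:
                y, x = queue.popleft()
                size += 1
                for dy, dx in neigh:
                    ny, nx = y + dy, x + dx
                    if 0 <= ny < h and 0 <= nx < w and not visited[ny, nx] and levels[ny, nx] == level:
                        visited[ny, nx] = True
                        queue.append((ny, nx))
            counts[level - 1, size - 1] += 1
            s_max = max(s_max, size)
    return counts[:, :s_max]


def zone_features_oracle(counts: np.ndarray) -> dict[str, float]:
    """Direct double-sum evaluation of the four zone-emphasis statistics."""
    H = float(counts.sum())
    sze = lze = lgze = hgze = 0.0
    for i0 in range(counts.shape[0]):
        for j0 in range(counts.shape[1]):
            c = float(counts[i0, j0])
            if c == 0.0:
                continue
            i, j = i0 + 1, j0 + 1
            sze += c / (j * j)
            lze += c * (j * j)
            lgze += c / (i * i)
            hgze += c * (i * i)
    return {"SZE": sze / H, "LZE": lze / H, "LGZE": lgze / H, "HGZE": hgze / H, "H": int(H)}
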