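"""Fast 3x3 lattice primitives (shift-based; hot path of the engine).

All functions treat out-of-grid territory as empty (False / zero counts),
matching a constant-zero boundary.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np


def box_sum3(grid: np.ndarray) -> np.ndarray:
    """Sum over each cell's 3x3 neighbourhood (zero-padded boundary)."""
    g = np.asarray(grid, dtype=np.float64)
    n, m = g.shape
    col = np.zeros((n, m), dtype=np.float64)
    col[:] = g
    col[:-1, :] += g[1:, :]
    col[1:, :] += g[:-1, :]
    out = col.copy()
    out[:, :-1] += col[:, 1:]
    out[:, 1:] += col[:, :-1]
    return out


@lru_cache(maxsize=8)
def window_sizes(shape: tuple) -> np.ndarray:
    """Number of in-grid patches in each 3x3 window (edge truncation)."""
    ones = np.ones(shape, dtype=np.float64)
    return box_sum3(ones)


def dilate8(mask: np.ndarray) -> np.ndarray:
    """8-connected binary dilation."""
    m = np.asarray(mask, dtype=bool)
    out = m.copy()
    out[:-1, :] |= m[1:, :]
    out[1:, :] |= m[:-1, :]
    col = out.copy()
    out[:, :-1] |= col[:, 1:]
    out[:, 1:] |= col[:, :-1]
    return out


def erode8(mask: np.ndarray) -> np.ndarray:
    """8-connected binary erosion (boundary treated as empty)."""
    m = np.asarray(mask, dtype=bool)
    out = m.copy()
    out[:-1, :] &= m[1:, :]
    out[1:, :] &= m[:-1, :]
    out[0, :] = False
    out[-1, :] = False
    col = out.copy()
    out[:, :-1] &= col[:, 1:]
    out[:, 1:] &= col[:, :-1]
    out[:, 0] = False
    out[:, -1] = False
    return out


def closing8(mask: np.ndarray) -> np.ndarray:
    """Binary closing with the 3x3 element, border treated as filled
    (erosion does not eat the grid edge)."""
    m = dilate8(mask)
    # erosion with filled border: pad with True
    p = np.pad(m, 1, constant_values=True)
    out = p[1:-1, 1:-1].copy()
    out &= p[:-2, 1:-1] & p[2:, 1:-1]
    out &= p[1:-1, :-2] & p[1:-1, 2:]
    out &= p[:-2, :-2] & p[:-2, 2:] & p[2:, :-2] & p[2:, 2:]
    return out


def chebyshev_distance_to(mask: np.ndarray, k_max: int) -> np.ndarray:
    """Chebyshev distance to the mask, exact up to ``k_max`` (larger
    distances are reported as +inf)."""
    out = np.full(mask.shape, np.inf)
    current = np.asarray(mask, dtype=bool)
    for k in range(k_max + 1):
        newly = current & np.isinf(out)
        out[newly] = k
        if k < k_max:
            current = dilate8(current)
    return out


def dilate4(mask: np.ndarray) -> np.ndarray:
    """4-connected (edge) binary dilation."""
    m = np.asarray(mask, dtype=bool)
    out = m.copy()
    out[:-1, :] |= m[1:, :]
    out[1:, :] |= m[:-1, :]
    out[:, :-1] |= m[:, 1:]
    out[:, 1:] |= m[:, :-1]
    return out


def max3(grid: np.ndarray) -> np.ndarray:
    """Maximum over each cell's 3x3 neighbourhood."""
    gr = np.asarray(grid)
    out = gr.copy()
    np.maximum(out[:-1, :], gr[1:, :], out=out[:-1, :])
    np.maximum(out[1:, :], gr[:-1, :], out=out[1:, :])
    col = out.copy()
    np.maximum(out[:, :-1], col[:, 1:], out=out[:, :-1])
    np.maximum(out[:, 1:], col[:, :-1], out=out[:, 1:])
    return out
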