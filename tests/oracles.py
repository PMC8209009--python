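"""Independent brute-force oracles for the spatial statistics.

Everything here is O(n^2) with full distance matrices and explicit
loops over grid points -- no spatial indexing, no shared code paths
with the package implementation beyond elementary numpy functions.
"""

from __future__ import annotations

import numpy as np


def brute_neighbor_counts(xy: np.ndarray, radius: float) -> np.ndarray:
    """Per-point count of other points within ``radius`` (inclusive)."""
    n = len(xy)
    d = np.hypot(xy[:, None, 0] - xy[None, :, 0], xy[:, None, 1] - xy[None, :, 1])
    within = (d <= radius)
    np.fill_diagonal(within, False)
    return within.sum(axis=1).astype(np.int64)


def _brute_isotropic_fraction(px, py, d, width, height, ox=0.0, oy=0.0):
    """Fraction of the circle of radius d centred at (px, py) inside the box."""
    d1 = min(px - ox, ox + width - px)
    d2 = min(py - oy, oy + height - py)
    a1 = np.arccos(np.clip(d1 / d, -1.0, 1.0))
    a2 = np.arccos(np.clip(d2 / d, -1.0, 1.0))
    if d1 >= d and d2 >= d:
        out = 0.0
    elif d1 < d and d2 >= d:
        out = 2 * a1
    elif d2 < d and d1 >= d:
        out = 2 * a2
    elif d1 ** 2 + d2 ** 2 >= d ** 2:
        out = 2 * a1 + 2 * a2
    else:
        out = 0.5 * np.pi + a1 + a2
    return 1.0 - out / (2 * np.pi)


def brute_ripley_k(xy: np.ndarray, width: float, height: float,
                   r_grid: np.ndarray, edge_correction: str = "isotropic") -> np.ndarray:
    """K(r) by summing every ordered pair explicitly."""
    n = len(xy)
    area = width * height
    k = np.zeros(len(r_grid))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = np.hypot(xy[i, 0] - xy[j, 0], xy[i, 1] - xy[j, 1])
            if edge_correction == "isotropic":
                w = 1.0 / _brute_isotropic_fraction(xy[i, 0], xy[i, 1], d, width, height)
            elif edge_correction == "translation":
                w = area / ((width - abs(xy[i, 0] - xy[j, 0]))
                            * (height - abs(xy[i, 1] - xy[j, 1])))
            else:
                w = 1.0
            k += w * (d <= r_grid)
    return area * k / (n * (n - 1))


def brute_cross_pair_counts(a_xy: np.ndarray, b_xy: np.ndarray,
                            edges: np.ndarray) -> np.ndarray:
    """A-B pair counts per [e_i, e_{i+1}) annulus, full distance matrix."""
    d = np.hypot(a_xy[:, None, 0] - b_xy[None, :, 0],
                 a_xy[:, None, 1] - b_xy[None, :, 1]).ravel()
    counts = np.zeros(len(edges) - 1, dtype=np.int64)
    for i in range(len(edges) - 1):
        counts[i] = np.count_nonzero((d >= edges[i]) & (d < edges[i + 1]))
    return counts


def brute_cross_correlation_toroidal(a_xy: np.ndarray, b_xy: np.ndarray,
                                     width: float, height: float,
                                     edges: np.ndarray) -> np.ndarray:
    """C(r) with toroidal wrap: counts / (uniform expectation on the torus)."""
    dx = np.abs(a_xy[:, None, 0] - b_xy[None, :, 0])
    dy = np.abs(a_xy[:, None, 1] - b_xy[None, :, 1])
    dx = np.minimum(dx, width - dx)
    dy = np.minimum(dy, height - dy)
    d = np.hypot(dx, dy).ravel()
    area = width * height
    c = np.full(len(edges) - 1, np.nan)
    for i in range(len(edges) - 1):
        obs = np.count_nonzero((d >= edges[i]) & (d < edges[i + 1]))
        annulus = np.pi * (edges[i + 1] ** 2 - edges[i] ** 2)
        expected = len(a_xy) * len(b_xy) * annulus / area
        if expected > 0:
            c[i] = obs / expected
    return c


def brute_contact_count(a: np.ndarray, b: np.ndarray, box: np.ndarray,
                        cutoff: float) -> int:
    """Minimum-image pair count within cutoff between two 3-D atom sets."""
    count = 0
    for i in range(len(a)):
        delta = b - a[i]
        delta -= box * np.round(delta / box)
        count += int(np.count_nonzero(np.linalg.norm(delta, axis=1) <= cutoff))
    return count


def thomas_k(r: np.ndarray, kappa_per_nm2: float, sigma: float) -> np.ndarray:
    """Closed-form Ripley K of the Thomas process."""
    return np.pi * r ** 2 + (1.0 / kappa_per_nm2) * (1.0 - np.exp(-r ** 2 / (4 * sigma ** 2)))


def thomas_h_argmax(kappa_per_nm2: float, sigma: float,
                    r_lo: float = 1.0, r_hi: float = 1000.0) -> float:
    """argmax of the analytic H(r) = sqrt(K/pi) - r, on a fine grid."""
    r = np.linspace(r_lo, r_hi, 200001)
    h = np.sqrt(thomas_k(r, kappa_per_nm2, sigma) / np.pi) - r
    return float(r[np.argmax(h)])
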