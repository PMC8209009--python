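"""Second-order spatial statistics for single-molecule localization data.

Localization tables (x, y in nm, optional frame/channel/precision) are
analysed inside rectangular windows with three families of statistics:

* neighbor density -- for every localization, the number of other
  localizations within a fixed radius (the classic SMLM density map);
* Ripley's K/L/H functions with analytic edge corrections for
  rectangles, and the clustering length ``r_max = argmax H(r)``;
* the two-color pair cross-correlation ``C(r)``: the probability of
  finding an A-B pair at separation r relative to independent uniform
  placement at the same intensities (C = 1 under independence).

All distances are Euclidean in nm.  Windows use a half-open
``[origin, origin + extent)`` convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import StructuralError

log = logging.getLogger(__name__)

EDGE_CORRECTIONS = ("isotropic", "translation", "none")


@dataclass(frozen=True)
class AnalysisWindow:
    """Rectangular analysis region, half-open on both axes."""

    width: float
    height: float
    origin_x: float = 0.0
    origin_y: float = 0.0

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise StructuralError("window extents must be positive")

    @property
    def area(self) -> float:
        return self.width * self.height

    def contains(self, x, y) -> np.ndarray:
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        return (
            (x >= self.origin_x)
            & (x < self.origin_x + self.width)
            & (y >= self.origin_y)
            & (y < self.origin_y + self.height)
        )


class LocalizationTable:
    """Point set of SMLM localizations.

    Thin wrapper around a :class:`pandas.DataFrame` with mandatory
    ``x``/``y`` columns (nm) and optional ``frame``, ``channel`` and
    ``precision`` columns.
    """

    REQUIRED = ("x", "y")

    def __init__(self, data: pd.DataFrame):
        for col in self.REQUIRED:
            if col not in data.columns:
                raise StructuralError(f"localization table lacks column {col!r}")
        xy = data[["x", "y"]].to_numpy(float)
        if xy.size and not np.all(np.isfinite(xy)):
            raise StructuralError("localization coordinates must be finite")
        self.data = data.reset_index(drop=True)

    @classmethod
    def from_arrays(cls, x, y, frame=None, channel=None, precision=None) -> "LocalizationTable":
        cols = {"x": np.asarray(x, float), "y": np.asarray(y, float)}
        if frame is not None:
            cols["frame"] = np.asarray(frame)
        if channel is not None:
            channel = np.asarray(channel)
            if channel.ndim == 0:
                channel = np.repeat(channel, len(cols["x"]))
            cols["channel"] = channel
        if precision is not None:
            cols["precision"] = np.asarray(precision, float)
        return cls(pd.DataFrame(cols))

    def coords(self) -> np.ndarray:
        return self.data[["x", "y"]].to_numpy(float)

    def channel(self, label: str) -> "LocalizationTable":
        if "channel" not in self.data.columns:
            raise StructuralError("table has no channel column")
        return LocalizationTable(self.data[self.data["channel"] == label])

    def channels(self) -> list:
        if "channel" not in self.data.columns:
            return []
        return sorted(self.data["channel"].unique().tolist())

    def __len__(self) -> int:
        return len(self.data)

    def __repr__(self) -> str:  # pragma: no cover
        return f"LocalizationTable(n={len(self)})"


@dataclass
class DensityResult:
    neighbor_radius: float
    per_point_counts: np.ndarray
    histogram: pd.DataFrame  # columns: count, frequency


@dataclass
class RipleyResult:
    r_grid: np.ndarray
    k_values: np.ndarray
    l_values: np.ndarray
    h_values: np.ndarray
    edge_correction: str
    n_points: int
    r_max: float = np.nan
    r_max_at_boundary: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"r": self.r_grid, "K": self.k_values, "L": self.l_values, "H": self.h_values}
        )


@dataclass
class CrossCorrelationResult:
    r_bin_centers: np.ndarray
    c_values: np.ndarray  # NaN where undefined
    n_pairs_per_bin: np.ndarray
    normalization: str
    r_bin_edges: np.ndarray = field(default=None)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"r": self.r_bin_centers, "C": self.c_values, "n_pairs": self.n_pairs_per_bin}
        )


def neighbor_density(
    points: LocalizationTable, window: AnalysisWindow, radius: float
) -> DensityResult:
    """Count, per localization, the other localizations within ``radius``.

    Self is excluded.  Distances at exactly ``radius`` count as neighbors.
    """
    if radius <= 0:
        raise StructuralError("radius must be positive")
    n = len(points)
    if n == 0:
        log.warning("neighbor_density called on an empty table")
        return DensityResult(radius, np.zeros(0, dtype=np.int64),
                             pd.DataFrame({"count": [], "frequency": []}))
    xy = points.coords()
    if not np.all(window.contains(xy[:, 0], xy[:, 1])):
        raise StructuralError("points fall outside the analysis window")
    tree = cKDTree(xy)
    pairs = tree.query_pairs(radius, output_type="ndarray")
    counts = np.zeros(n, dtype=np.int64)
    if len(pairs):
        np.add.at(counts, pairs.ravel(), 1)
    vals, freq = np.unique(counts, return_counts=True)
    hist = pd.DataFrame({"count": vals, "frequency": freq})
    return DensityResult(radius, counts, hist)


def _edge_distances(xy: np.ndarray, window: AnalysisWindow):
    dx = np.minimum(xy[:, 0] - window.origin_x, window.origin_x + window.width - xy[:, 0])
    dy = np.minimum(xy[:, 1] - window.origin_y, window.origin_y + window.height - xy[:, 1])
    return dx, dy

def _isotropic_weight(xy: np.ndarray, d: np.ndarray, window: AnalysisWindow) -> np.ndarray:
    """Ripley isotropic edge-correction weight for circles centred at ``xy``.

    Returns 1 / (fraction of the circle of radius d inside the rectangle).
    Valid for d <= min(width, height) / 2, where a circle can cross at
    most two adjacent sides.
    """
    d1, d2 = _edge_distances(xy, window)
    with np.errstate(invalid="ignore", divide="ignore"):
        a1 = np.arccos(np.clip(d1 / d, -1.0, 1.0))
        a2 = np.arccos(np.clip(d2 / d, -1.0, 1.0))
    c1 = d1 < d
    c2 = d2 < d
    both = c1 & c2
    corner_inside = both & (d1 ** 2 + d2 ** 2 < d ** 2)
    alpha_out = np.zeros_like(d)
    only1 = c1 & ~c2
    only2 = c2 & ~c1
    alpha_out[only1] = 2.0 * a1[only1]
    alpha_out[only2] = 2.0 * a2[only2]
    edge_pair = both & ~corner_inside
    alpha_out[edge_pair] = 2.0 * a1[edge_pair] + 2.0 * a2[edge_pair]
    alpha_out[corner_inside] = 0.5 * np.pi + a1[corner_inside] + a2[corner_inside]
    frac = 1.0 - alpha_out / (2.0 * np.pi)
    return 1.0 / frac


def ripley_k(
    points: LocalizationTable,
    window: AnalysisWindow,
    r_grid: Sequence[float],
    edge_correction: str = "isotropic",
) -> RipleyResult:
    """Ripley's K, L = sqrt(K/pi) and H = L - r on a rectangular window.

    K̂(r) = (A / (n(n-1))) Σ_i Σ_{j≠i} w_ij 1(d_ij <= r), with w_ij the
    chosen edge-correction weight for the circle of radius d_ij centred
    at point i.  Under complete spatial randomness E[K̂(r)] = pi r².
    """
    if edge_correction not in EDGE_CORRECTIONS:
        raise StructuralError(
            f"unknown edge correction {edge_correction!r}; choose from {EDGE_CORRECTIONS}"
        )
    r = np.asarray(r_grid, float)
    if r.ndim != 1 or len(r) < 1 or np.any(np.diff(r) <= 0) or r[0] < 0:
        raise StructuralError("r_grid must be a strictly increasing nonnegative vector")
    half_min = min(window.width, window.height) / 2.0
    if r[-1] > half_min:
        raise StructuralError(
            f"max(r_grid)={r[-1]:g} exceeds min(width,height)/2={half_min:g}"
        )
    n = len(points)
    if n < 2:
        raise StructuralError("Ripley's K needs at least two points")
    xy = points.coords()
    if not np.all(window.contains(xy[:, 0], xy[:, 1])):
        raise StructuralError("points fall outside the analysis window")

    tree = cKDTree(xy)
    pairs = tree.query_pairs(float(r[-1]), output_type="ndarray")
    wsum = np.zeros(len(r))
    if len(pairs):
        diff = xy[pairs[:, 0]] - xy[pairs[:, 1]]
        d = np.hypot(diff[:, 0], diff[:, 1])
        if edge_correction == "isotropic":
            w = _isotropic_weight(xy[pairs[:, 0]], d, window) + _isotropic_weight(
                xy[pairs[:, 1]], d, window
            )
        elif edge_correction == "translation":
            overlap = (window.width - np.abs(diff[:, 0])) * (
                window.height - np.abs(diff[:, 1])
            )
            w = 2.0 * window.area / overlap
        else:
            w = np.full(len(d), 2.0)
        idx = np.searchsorted(r, d)  # first grid point >= d (inclusive at ties)
        keep = idx < len(r)
        np.add.at(wsum, idx[keep], w[keep])
    k = window.area * np.cumsum(wsum) / (n * (n - 1))
    l = np.sqrt(k / np.pi)
    h = l - r
    result = RipleyResult(r, k, l, h, edge_correction, n)
    if len(r) >= 5:
        estimate_rmax(result)
    return result


def estimate_rmax(result: RipleyResult) -> float:
    """Clustering length: location of the maximum of H(r).

    The discrete argmax (ties broken toward smaller r) is refined by a
    parabola through the three surrounding grid points.  A maximum at
    either end of the grid sets ``r_max_at_boundary`` and returns the
    endpoint unrefined.
    """
    r, h = result.r_grid, result.h_values
    if len(r) < 5:
        raise StructuralError("r_max estimation needs H on at least 5 grid points")
    i = int(np.argmax(h))  # np.argmax takes the first of tied maxima
    if i == 0 or i == len(r) - 1:
        result.r_max = float(r[i])
        result.r_max_at_boundary = True
        return result.r_max
    coeffs = np.polyfit(r[i - 1 : i + 2], h[i - 1 : i + 2], 2)
    if coeffs[0] >= 0:  # degenerate (flat or upward) parabola
        r_hat = float(r[i])
    else:
        r_hat = float(np.clip(-coeffs[1] / (2 * coeffs[0]), r[i - 1], r[i + 1]))
    result.r_max = r_hat
    result.r_max_at_boundary = False
    return r_hat


def _pairwise_distances(a_xy: np.ndarray, b_xy: np.ndarray, r_max: float):
    """All A->B pair distances <= r_max via KD-trees (closed bound)."""
    tree_a = cKDTree(a_xy)
    tree_b = cKDTree(b_xy)
    neigh = tree_a.query_ball_tree(tree_b, r_max)
    lens = np.fromiter((len(v) for v in neigh), dtype=np.int64, count=len(neigh))
    ia = np.repeat(np.arange(len(a_xy)), lens)
    ib = np.concatenate([np.asarray(v, dtype=np.int64) for v in neigh]) if lens.sum() else np.zeros(0, np.int64)
    d = np.hypot(*(a_xy[ia] - b_xy[ib]).T) if len(ia) else np.zeros(0)
    return d


def expected_pair_counts(
    n_a: int, n_b: int, window: AnalysisWindow, edges: np.ndarray
) -> np.ndarray:
    """Expected A-B pair counts per annulus for independent uniform points.

    Uses the isotropized set covariance of the rectangle,
    gamma_bar(s) = WH - (2s/pi)(W+H) + s^2/pi (exact for s <= min(W, H)),
    integrated in closed form:  F(r) = pi W H r^2 - (4/3)(W+H) r^3 + r^4/2
    is the integral of 2 pi s gamma_bar(s) ds from 0 to r.
    """
    w_, h_ = window.width, window.height
    edges = np.asarray(edges, float)

    def F(rr):
        return np.pi * w_ * h_ * rr ** 2 - (4.0 / 3.0) * (w_ + h_) * rr ** 3 + rr ** 4 / 2.0

    return n_a * n_b / window.area ** 2 * (F(edges[1:]) - F(edges[:-1]))


def cross_correlation(
    channel_a: LocalizationTable,
    channel_b: LocalizationTable,
    window: AnalysisWindow,
    r_bins: Sequence[float],
) -> CrossCorrelationResult:
    """Two-color pair cross-correlation C(r) on a rectangular window.

    Observed A-B pair counts in each annulus ``[r_i, r_{i+1})`` are
    divided by the count expected for independent uniform points at the
    same intensities, with the rectangle's geometry (set covariance)
    providing the edge correction.  C = 1 under independence; bins whose
    expected count vanishes are reported as NaN.
    """
    edges = np.asarray(r_bins, float)
    if edges.ndim != 1 or len(edges) < 2 or np.any(np.diff(edges) <= 0) or edges[0] < 0:
        raise StructuralError("r_bins must be strictly increasing edges, starting >= 0")
    if edges[-1] > min(window.width, window.height):
        raise StructuralError("largest bin edge exceeds the window's shorter side")
    n_a, n_b = len(channel_a), len(channel_b)
    if n_a == 0 or n_b == 0:
        raise StructuralError("both channels must be nonempty")
    a_xy, b_xy = channel_a.coords(), channel_b.coords()
    for xy in (a_xy, b_xy):
        if not np.all(window.contains(xy[:, 0], xy[:, 1])):
            raise StructuralError("points fall outside the analysis window")

    d = _pairwise_distances(a_xy, b_xy, float(edges[-1]))
    idx = np.searchsorted(edges, d, side="right") - 1  # bins [e_i, e_{i+1})
    nbins = len(edges) - 1
    valid = (idx >= 0) & (idx < nbins)
    counts = np.bincount(idx[valid], minlength=nbins).astype(np.int64)

    expected = expected_pair_counts(n_a, n_b, window, edges)
    c = np.full(nbins, np.nan)
    ok = expected > 0
    c[ok] = counts[ok] / expected[ok]
    if not np.all(ok):
        log.warning("cross_correlation: %d bins with zero expected pairs flagged NaN",
                    int((~ok).sum()))
    centers = 0.5 * (edges[:-1] + edges[1:])
    return CrossCorrelationResult(centers, c, counts, "window-autocorrelation", edges)


def tile_windows(
    points: LocalizationTable,
    full_window: AnalysisWindow,
    tile: float,
    min_points: int = 1,
) -> list[tuple[AnalysisWindow, LocalizationTable]]:
    """Split a window into a grid of ``tile`` x ``tile`` sub-windows.

    Only complete tiles inside the full window are kept (floor rule);
    points are assigned half-open; tiles with fewer than ``min_points``
    localizations are dropped with a log record.
    """
    if tile <= 0 or tile > min(full_window.width, full_window.height):
        raise StructuralError("tile must be positive and fit inside the window")
    ncols = int(np.floor(full_window.width / tile))
    nrows = int(np.floor(full_window.height / tile))
    xy = points.coords()
    out = []
    for i in range(ncols):
        for j in range(nrows):
            win = AnalysisWindow(
                tile, tile,
                full_window.origin_x + i * tile,
                full_window.origin_y + j * tile,
            )
            mask = win.contains(xy[:, 0], xy[:, 1]) if len(xy) else np.zeros(0, bool)
            sub = LocalizationTable(points.data[mask])
            if len(sub) < min_points:
                log.info("dropping tile (%d,%d): %d points < min %d", i, j, len(sub), min_points)
                continue
            out.append((win, sub))
    return out


def merge_blinking(
    points: LocalizationTable, radius: float, max_frame_gap: int = 1
) -> LocalizationTable:
    """Collapse repeated localizations of one molecule across frames.

    Localizations within ``radius`` of an active molecule seen within
    ``max_frame_gap`` frames are merged into it; merged molecules are
    reported at the mean position of their localizations.  Requires a
    ``frame`` column.  This is the blinking-aware option; the default
    pipeline analyses localizations as recorded.
    """
    if "frame" not in points.data.columns:
        raise StructuralError("merge_blinking needs a frame column")
    df = points.data.sort_values("frame", kind="stable").reset_index(drop=True)
    xy = df[["x", "y"]].to_numpy(float)
    frames = df["frame"].to_numpy()
    mol_sum = []   # running [sx, sy, n]
    mol_last = []  # last frame seen
    assignment = np.empty(len(df), dtype=np.int64)
    for k in range(len(df)):
        best, best_d = -1, radius
        for m in range(len(mol_sum)):
            if frames[k] - mol_last[m] > max_frame_gap:
                continue
            mx = mol_sum[m][0] / mol_sum[m][2]
            my = mol_sum[m][1] / mol_sum[m][2]
            dd = np.hypot(xy[k, 0] - mx, xy[k, 1] - my)
            if dd <= best_d:
                best, best_d = m, dd
        if best < 0:
            mol_sum.append([xy[k, 0], xy[k, 1], 1])
            mol_last.append(frames[k])
            assignment[k] = len(mol_sum) - 1
        else:
            mol_sum[best][0] += xy[k, 0]
            mol_sum[best][1] += xy[k, 1]
            mol_sum[best][2] += 1
            mol_last[best] = frames[k]
            assignment[k] = best
    arr = np.asarray(mol_sum, float)
    if len(arr) == 0:
        return LocalizationTable(pd.DataFrame({"x": [], "y": []}))
    merged = pd.DataFrame({"x": arr[:, 0] / arr[:, 2], "y": arr[:, 1] / arr[:, 2]})
    if "channel" in df.columns:
        first = df.groupby(assignment)["channel"].first()
        merged["channel"] = first.sort_index().to_numpy()
    return LocalizationTable(merged)
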