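"""Homo-FRET fluorescence anisotropy imaging analysis.

Polarization-resolved image pairs (parallel / perpendicular emission,
``I_pa`` / ``I_pe``) are converted to steady-state anisotropy maps

    r = (I_pa - g * I_pe) / (I_pa + 2 g * I_pe),
    I_tot = I_pa + 2 g * I_pe,

where the G-factor ``g`` corrects the unequal detection efficiency of
the two channels and is calibrated on an isotropic dye solution.  Pixels
pooled over regions of interest are sorted by total intensity and
binned; the shape of the binned anisotropy-vs-intensity curve separates
two clustering regimes:

* *active clustering* -- anisotropy low and independent of intensity
  (fixed-size nanoclusters: the homo-FRET depolarization per molecule
  does not change with surface density);
* *random proximity (bystander) FRET* -- anisotropy falls with
  increasing intensity, because randomly distributed fluorophores are
  brought within transfer range by concentration alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import BinningError, InvalidReferenceError, StructuralError

log = logging.getLogger(__name__)

ANISOTROPY_MIN = -0.5
ANISOTROPY_MAX = 1.0


@dataclass
class PolarizedImagePair:
    """Registered parallel/perpendicular emission images (camera counts)."""

    parallel: np.ndarray
    perpendicular: np.ndarray
    pixel_size: float = 1.0  # nm per pixel
    background_parallel: float = 0.0
    background_perpendicular: float = 0.0

    def __post_init__(self) -> None:
        self.parallel = np.asarray(self.parallel)
        self.perpendicular = np.asarray(self.perpendicular)
        if self.parallel.shape != self.perpendicular.shape:
            raise StructuralError(
                f"channel shapes differ: {self.parallel.shape} vs {self.perpendicular.shape}"
            )
        if self.parallel.ndim != 2:
            raise StructuralError("images must be 2-D")
        if self.pixel_size <= 0:
            raise StructuralError("pixel_size must be positive")

    def corrected(self) -> tuple[np.ndarray, np.ndarray]:
        """Background-subtracted channels, clipped at zero."""
        pa = np.clip(self.parallel.astype(float) - self.background_parallel, 0.0, None)
        pe = np.clip(self.perpendicular.astype(float) - self.background_perpendicular, 0.0, None)
        return pa, pe


@dataclass
class GFactor:
    """Detection-efficiency ratio of the two polarization channels."""

    value: float
    reference_mean: float = np.nan
    reference_sd: float = np.nan
    reference_residual_anisotropy: float = np.nan

    def __post_init__(self) -> None:
        if not np.isfinite(self.value) or self.value <= 0:
            raise StructuralError("G-factor must be finite and positive")


@dataclass
class AnisotropyMaps:
    total_intensity: np.ndarray
    anisotropy: np.ndarray  # NaN on invalid pixels
    valid_mask: np.ndarray
    pixel_size: float = 1.0


@dataclass
class IntensityAnisotropyCurve:
    bin_mean_intensity: np.ndarray
    bin_mean_anisotropy: np.ndarray
    bin_sd_anisotropy: np.ndarray
    bin_pixel_count: np.ndarray
    n_rois_pooled: int = 1

    @property
    def n_bins(self) -> int:
        return len(self.bin_mean_intensity)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mean_intensity": self.bin_mean_intensity,
                "mean_anisotropy": self.bin_mean_anisotropy,
                "sd_anisotropy": self.bin_sd_anisotropy,
                "pixel_count": self.bin_pixel_count,
            }
        )


@dataclass
class ClusteringSignature:
    label: str  # active_clustered | random_proximity | indeterminate
    slope: float  # anisotropy change per decade of intensity
    slope_ci: tuple[float, float]
    mean_anisotropy: float
    monomer_reference: float
    flat_threshold: float = 0.01
    low_fraction: float = 0.8
    diagnostic: str = ""


def estimate_g_factor(reference_pair: PolarizedImagePair, mask: np.ndarray) -> GFactor:
    """Estimate g from an isotropic reference (dye freely rotating, r ~ 0).

    g is the median of the background-subtracted per-pixel I_pa / I_pe
    ratio over the foreground mask; the median resists hot pixels.  The
    residual anisotropy of the reference analysed with the estimate is
    recorded (|median r| should be < 0.01 for a good reference).
    """
    mask = np.asarray(mask, bool)
    if mask.shape != reference_pair.parallel.shape:
        raise StructuralError("mask shape does not match the reference images")
    if not mask.any():
        raise InvalidReferenceError("empty reference mask")
    pa, pe = reference_pair.corrected()
    pa_m, pe_m = pa[mask], pe[mask]
    if np.any(pe_m <= 0):
        raise InvalidReferenceError(
            "masked perpendicular intensities <= 0 after background subtraction"
        )
    ratio = pa_m / pe_m
    g = float(np.median(ratio))
    if g <= 0 or not np.isfinite(g):
        raise InvalidReferenceError("reference yielded a non-positive G-factor")
    with np.errstate(invalid="ignore", divide="ignore"):
        resid = (pa_m - g * pe_m) / (pa_m + 2 * g * pe_m)
    med_r = float(np.nanmedian(resid))
    if abs(med_r) >= 0.01:
        log.warning("reference residual anisotropy |median r| = %.4f >= 0.01", abs(med_r))
    sd = float(np.std(ratio, ddof=1)) if ratio.size > 1 else 0.0
    return GFactor(g, float(np.mean(ratio)), sd, med_r)


def compute_anisotropy_maps(pair: PolarizedImagePair, g) -> AnisotropyMaps:
    """Per-pixel anisotropy and total intensity.

    ``g`` may be a :class:`GFactor` or a bare positive float.  Pixels
    with I_tot <= 0 are masked invalid (anisotropy NaN), not dropped.
    """
    gv = g.value if isinstance(g, GFactor) else float(g)
    if gv <= 0 or not np.isfinite(gv):
        raise StructuralError("g must be finite and positive")
    pa, pe = pair.corrected()
    total = pa + 2.0 * gv * pe
    valid = total > 0
    r = np.full(total.shape, np.nan)
    np.divide(pa - gv * pe, total, out=r, where=valid)
    return AnisotropyMaps(total, r, valid, pair.pixel_size)


def roi_from_intensity(maps: AnisotropyMaps, fraction_of_max: float = 0.1) -> np.ndarray:
    """Convenience ROI: valid pixels above a fraction of the peak intensity."""
    thresh = fraction_of_max * float(np.nanmax(maps.total_intensity))
    return maps.valid_mask & (maps.total_intensity >= thresh)


def bin_intensity_anisotropy(
    maps: AnisotropyMaps | Sequence[AnisotropyMaps],
    rois=None,
    n_bins: int = 20,
) -> IntensityAnisotropyCurve:
    """Pool ROI pixels, sort by total intensity, bin into equal counts.

    ``maps`` may be a single map set or a list (pooling across cells);
    ``rois`` is a matching list of boolean-mask lists (or None for the
    whole valid mask of each map).  Per retained bin: mean intensity,
    mean anisotropy, SD of anisotropy, pixel count.
    """
    if n_bins < 3:
        raise BinningError("n_bins must be at least 3")
    maps_list = [maps] if isinstance(maps, AnisotropyMaps) else list(maps)
    if rois is None:
        rois_list = [[m.valid_mask] for m in maps_list]
    elif isinstance(maps, AnisotropyMaps):
        rois_list = [list(rois)]
    else:
        rois_list = [list(r) for r in rois]

    intensities, anisotropies, n_rois = [], [], 0
    for m, roi_masks in zip(maps_list, rois_list):
        for roi in roi_masks:
            roi = np.asarray(roi, bool)
            sel = roi & m.valid_mask
            if not sel.any():
                log.warning("ROI does not intersect the valid mask; skipped")
                continue
            intensities.append(m.total_intensity[sel])
            anisotropies.append(m.anisotropy[sel])
            n_rois += 1
    if not intensities:
        raise BinningError("no valid pixels in any ROI")
    intensity = np.concatenate(intensities)
    aniso = np.concatenate(anisotropies)
    if len(intensity) < n_bins:
        raise BinningError(f"{len(intensity)} valid pixels < {n_bins} bins")

    order = np.argsort(intensity, kind="stable")
    mean_i, mean_r, sd_r, count = [], [], [], []
    for chunk in np.array_split(order, n_bins):
        if len(chunk) == 0:
            continue
        mean_i.append(float(np.mean(intensity[chunk])))
        mean_r.append(float(np.mean(aniso[chunk])))
        sd_r.append(float(np.std(aniso[chunk], ddof=1)) if len(chunk) > 1 else 0.0)
        count.append(len(chunk))
    return IntensityAnisotropyCurve(
        np.asarray(mean_i), np.asarray(mean_r), np.asarray(sd_r),
        np.asarray(count, dtype=np.int64), n_rois,
    )


def _weighted_line_fit(x: np.ndarray, y: np.ndarray, w: np.ndarray):
    """WLS fit y = a + b x; returns (slope, slope_se)."""
    W = np.sum(w)
    xw = np.sum(w * x) / W
    yw = np.sum(w * y) / W
    sxx = np.sum(w * (x - xw) ** 2)
    if sxx <= 0:
        return np.nan, np.nan
    slope = np.sum(w * (x - xw) * (y - yw)) / sxx
    intercept = yw - slope * xw
    resid = y - intercept - slope * x
    dof = max(len(x) - 2, 1)
    s2 = np.sum(w * resid ** 2) / dof
    se = np.sqrt(s2 / sxx)
    return float(slope), float(se)


def classify_clustering_signature(
    curve: IntensityAnisotropyCurve,
    monomer_reference: float,
    flat_threshold: float = 0.01,
    low_fraction: float = 0.8,
) -> ClusteringSignature:
    """Label the intensity-anisotropy curve.

    The slope of anisotropy versus log10(intensity) is fit by weighted
    least squares (weights 1/SD^2 per bin).  Labels:

    * ``active_clustered``  -- |slope| < flat_threshold and the
      pixel-weighted mean anisotropy is below
      ``low_fraction * monomer_reference`` (concentration-independent,
      low: fixed-size nanoclusters);
    * ``random_proximity``  -- slope < -flat_threshold (anisotropy falls
      with concentration: bystander FRET between random molecules);
    * ``indeterminate`` otherwise, or when fewer than 3 bins contributed.
    """
    if curve.n_bins < 3:
        return ClusteringSignature(
            "indeterminate", np.nan, (np.nan, np.nan), np.nan, monomer_reference,
            flat_threshold, low_fraction, "fewer than 3 bins",
        )
    pos = curve.bin_mean_intensity > 0
    if pos.sum() < 3:
        return ClusteringSignature(
            "indeterminate", np.nan, (np.nan, np.nan), np.nan, monomer_reference,
            flat_threshold, low_fraction, "fewer than 3 bins with positive intensity",
        )
    x = np.log10(curve.bin_mean_intensity[pos])
    y = curve.bin_mean_anisotropy[pos]
    sd = curve.bin_sd_anisotropy[pos]
    if np.all(sd > 0):
        w = 1.0 / sd ** 2
    else:
        w = np.ones_like(y)  # constant fields carry no per-bin dispersion
    slope, se = _weighted_line_fit(x, y, w)
    ci = (slope - 1.96 * se, slope + 1.96 * se) if np.isfinite(se) else (np.nan, np.nan)
    counts = curve.bin_pixel_count[pos].astype(float)
    mean_r = float(np.sum(counts * y) / np.sum(counts))

    if not np.isfinite(slope):
        label, diag = "indeterminate", "degenerate intensity axis"
    elif abs(slope) < flat_threshold and mean_r < low_fraction * monomer_reference:
        label, diag = "active_clustered", ""
    elif slope < -flat_threshold:
        label, diag = "random_proximity", ""
    else:
        label, diag = "indeterminate", "neither flat-low nor falling"
    return ClusteringSignature(
        label, slope, ci, mean_r, monomer_reference, flat_threshold, low_fraction, diag
    )


def lo_partition_coefficient(i_lo: float, i_ld: float) -> float:
    """Ordered-phase partition coefficient, I_Lo / (I_Lo + I_Ld).

    A value > 0.5 indicates ordered-phase preference.
    """
    if i_lo < 0 or i_ld < 0:
        raise StructuralError("intensities must be nonnegative")
    total = i_lo + i_ld
    if total == 0:
        raise StructuralError("both intensities are zero; ratio undefined")
    return float(i_lo / total)
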