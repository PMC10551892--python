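"""Histogram-model segmentation of labeled vascular volumes.

The segmentation is two-staged. The gray-level histogram of a labeled,
cleared-tissue volume shows three populations: dark non-tissue voxels
(mounting medium), unlabeled tissue voxels whose gray levels follow a
Gaussian law, and a bright minority of labeled vessel voxels.

Stage 1 (object of study, OOS): the tissue is separated from the non-tissue
background at the inflexion point between the first two histogram modes.

Stage 2 (object of interest, OOI): within the tissue, the background
population is fitted with a Gaussian, and the vessel threshold is placed at
the upper confidence-interval limit ``mean + z_{alpha/2} * sd``. With
alpha = 0.05 (z = 1.96) this excludes 97.5% of background voxels, so the
vessel mask carries the same small, known background contamination in every
sample — the operator never picks a threshold by eye.

A cylinder partial-volume model quantifies how many voxels of a tubular
segment carry intermediate gray values: a cylinder of length L and radius r
sampled at voxel pitch d occupies ``L*pi*r^2/d^3`` voxels of which
``L*2*pi*r/d^2`` lie on the surface, so the intermediate-voxel proportion is
``2d/r`` — the thinner the vessel relative to the voxel, the more the
morphometry depends on where the threshold cuts the edge voxels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import optimize, stats
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

from .volio import BinaryMask, Volume3D

logger = logging.getLogger(__name__)

__all__ = [
    "GrayHistogram",
    "GaussianFitResult",
    "ThresholdDecision",
    "CylinderVoxelModel",
    "SegmentationError",
    "InflexionError",
    "GaussianFitError",
    "compute_histogram",
    "find_inflexion_threshold",
    "fit_background_gaussian",
    "auto_fit_range",
    "ci_threshold",
    "binarize",
    "partial_volume_ratio",
    "threshold_sensitivity",
]


class SegmentationError(Exception):
    pass


class InflexionError(SegmentationError):
    """No usable inflexion point; carries the histogram for diagnosis."""

    def __init__(self, message: str, histogram: "GrayHistogram | None" = None):
        super().__init__(message)
        self.histogram = histogram


class GaussianFitError(SegmentationError):
    """Gaussian fit failed; carries the optimizer diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass
class GrayHistogram:
    """Exact integer gray-level histogram (one bin per gray level)."""

    bin_centers: np.ndarray
    counts: np.ndarray
    source_voxel_count: int
    restricted_to: str | None = None

    def __post_init__(self) -> None:
        self.bin_centers = np.asarray(self.bin_centers)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.sum() != self.source_voxel_count:
            raise ValueError("histogram counts do not sum to the source voxel count")


@dataclass
class GaussianFitResult:
    """Least-squares Gaussian fit of the background voxel population."""

    mean: float
    sd: float
    amplitude: float
    r_squared: float
    fit_range: tuple[float, float]


@dataclass
class ThresholdDecision:
    """A confidence-interval threshold ``mean ± z_crit * sd``."""

    threshold: float
    alpha: float
    z_crit: float
    direction: Literal["upper", "lower"]


@dataclass
class CylinderVoxelModel:
    """Voxel bookkeeping for a cylinder of length L, radius r at pitch d (µm)."""

    L: float
    r: float
    d: float
    nv_volume: float = field(init=False)
    nv_surface: float = field(init=False)
    surface_to_volume_ratio: float = field(init=False)

    def __post_init__(self) -> None:
        if min(self.L, self.r, self.d) <= 0:
            raise ValueError("L, r and d must be positive")
        self.nv_volume = self.L * np.pi * self.r**2 / self.d**3
        self.nv_surface = self.L * 2 * np.pi * self.r / self.d**2
        self.surface_to_volume_ratio = 2 * self.d / self.r


def compute_histogram(vol: Volume3D, within: BinaryMask | None = None) -> GrayHistogram:
    """Exact gray-level histogram of a volume, optionally restricted to a mask."""
    if within is not None:
        if within.values.shape != vol.values.shape:
            raise SegmentationError(
                f"mask shape {within.values.shape} does not match volume {vol.values.shape}"
            )
        voxels = vol.values[within.values]
        if voxels.size == 0:
            raise SegmentationError("mask is empty: no voxels to histogram")
        label = "mask"
    else:
        voxels = vol.values.ravel()
        label = None
    n_bins = 2**vol.bit_depth
    counts = np.bincount(voxels.ravel().astype(np.int64), minlength=n_bins)
    return GrayHistogram(
        bin_centers=np.arange(n_bins),
        counts=counts,
        source_voxel_count=int(voxels.size),
        restricted_to=label,
    )


#: Fixed smoothing width (in gray-level bins) for second-derivative analysis.
INFLEXION_SMOOTHING_BINS = 2.0


def _dominant_modes(smooth: np.ndarray) -> tuple[int, int]:
    """Locations of the two lowest-gray prominent modes of a smoothed histogram."""
    prom = 0.01 * smooth.max()
    peaks, _ = find_peaks(smooth, prominence=prom)
    # A mode at bin 0 (clipped black level) is a peak find_peaks cannot see.
    if smooth.size > 1 and smooth[0] > smooth[1] and smooth[0] >= prom:
        peaks = np.concatenate([[0], peaks])
    if len(peaks) < 2:
        raise InflexionError(
            f"need at least two histogram modes, found {len(peaks)} "
            f"(prominence floor {prom:.1f})"
        )
    return int(peaks[0]), int(peaks[1])


def find_inflexion_threshold(
    hist: GrayHistogram, smoothing_bins: float = INFLEXION_SMOOTHING_BINS
) -> float:
    """Threshold separating the non-tissue mode from the tissue mode.

    The histogram is smoothed with a fixed Gaussian kernel and its second
    derivative examined between the two lowest-gray modes. Scanning upward
    from the inter-mode valley, the first sign change of the second
    derivative marks the inflexion at the foot of the tissue mode; its
    position is refined by linear interpolation of the zero crossing.

    Raises
    ------
    InflexionError
        If fewer than two modes exist or the second derivative never changes
        sign in the search interval; the exception carries the histogram.
    """
    counts = hist.counts.astype(float)
    smooth = gaussian_filter1d(counts, smoothing_bins, mode="nearest")
    try:
        p1, p2 = _dominant_modes(smooth)
    except InflexionError as exc:
        raise InflexionError(str(exc), histogram=hist) from None

    valley_slice = smooth[p1 : p2 + 1]
    vmin = valley_slice.min()
    flat = np.flatnonzero(valley_slice <= vmin * (1 + 1e-12))
    valley = p1 + int(round(flat.mean()))  # midpoint of a flat (empty) valley

    d2 = np.gradient(np.gradient(smooth))
    scale = np.abs(d2).max()
    tol = 1e-9 * scale if scale > 0 else 0.0

    def signum(x: float) -> int:
        if x > tol:
            return 1
        if x < -tol:
            return -1
        return 0

    prev_sign = signum(d2[valley])
    for g in range(valley + 1, p2 + 1):
        s = signum(d2[g])
        if s != 0 and prev_sign != 0 and s != prev_sign:
            # strict sign flip: interpolate the crossing
            g0, g1 = g - 1, g
            frac = d2[g0] / (d2[g0] - d2[g1])
            return float(g0 + frac)
        if s != 0 and prev_sign == 0:
            # emergence from a flat (zero-count) valley counts as the crossing
            return float(g)
        if s != 0:
            prev_sign = s
    raise InflexionError(
        f"no second-derivative sign change between modes at {p1} and {p2}",
        histogram=hist,
    )


def fit_background_gaussian(
    hist: GrayHistogram, fit_range: tuple[float, float]
) -> GaussianFitResult:
    """Non-linear least-squares Gaussian fit of the histogram in ``fit_range``.

    Fits ``amplitude * exp(-(g - mean)^2 / (2 sd^2))`` to the counts with
    moment-based initialization. Deterministic given data and range.
    """
    lo, hi = fit_range
    sel = (hist.bin_centers >= lo) & (hist.bin_centers <= hi)
    g = hist.bin_centers[sel].astype(float)
    y = hist.counts[sel].astype(float)
    if g.size < 10:
        raise GaussianFitError(f"fit range [{lo}, {hi}] spans {g.size} bins; need >= 10")
    if y.sum() <= 0:
        raise GaussianFitError(f"fit range [{lo}, {hi}] contains no counts")

    w = y / y.sum()
    m0 = float((w * g).sum())
    s0 = float(np.sqrt((w * (g - m0) ** 2).sum()))
    s0 = max(s0, 0.5)
    a0 = float(y.max())

    def model(x, a, m, s):
        return a * np.exp(-((x - m) ** 2) / (2 * s**2))

    try:
        popt, pcov = optimize.curve_fit(
            model,
            g,
            y,
            p0=(a0, m0, s0),
            bounds=((0, lo - (hi - lo), 1e-6), (np.inf, hi + (hi - lo), np.inf)),
            maxfev=20000,
        )
    except (RuntimeError, ValueError) as exc:
        raise GaussianFitError(
            f"Gaussian fit did not converge on range [{lo}, {hi}]",
            diagnostics={"error": str(exc), "p0": (a0, m0, s0)},
        ) from exc

    a, m, s = (float(v) for v in popt)
    if s <= 0:
        raise GaussianFitError(f"fit returned non-positive sd={s}")
    resid = y - model(g, *popt)
    ss_res = float((resid**2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return GaussianFitResult(mean=m, sd=s, amplitude=a, r_squared=r2, fit_range=(lo, hi))


def auto_fit_range(hist: GrayHistogram, lo: float, n_iter: int = 2) -> tuple[float, float]:
    """Automatic fit window for the background Gaussian.

    Starting from ``lo`` (normally the tissue/non-tissue inflexion threshold)
    to the last populated bin, the Gaussian is fitted and the upper limit is
    pulled back to just below the first gray level above the fitted mean
    where the observed counts exceed the fitted curve by more than three
    times the residual standard deviation (the onset of the bright vessel
    tail). The fit is repeated ``n_iter`` times with the tightened window.
    """
    populated = np.flatnonzero(hist.counts)
    if populated.size == 0:
        raise GaussianFitError("histogram is empty")
    # Initial window: locate the background (tissue) mode as the lowest-gray
    # prominent peak above `lo` — the bright vessel population can carry a
    # taller spike, so a plain argmax would capture the wrong mode — and
    # open the window four estimated sigmas above it.
    sel = hist.bin_centers >= lo
    g = hist.bin_centers[sel].astype(float)
    y = hist.counts[sel].astype(float)
    smooth = gaussian_filter1d(y, 2.0, mode="nearest")
    peaks, _ = find_peaks(smooth, prominence=0.01 * smooth.max())
    i_mode = int(peaks[0]) if len(peaks) else int(np.argmax(smooth))
    mode = float(g[i_mode])
    half = smooth[i_mode] / 2.0
    left = np.flatnonzero(smooth[: i_mode + 1] <= half)
    hwhm = (i_mode - left[-1]) if left.size else max(1.0, (mode - lo) / 3)
    sd_est = max(float(hwhm) / 1.1774, 1.0)  # half width at half max of a Gaussian
    hi = min(float(populated[-1]), mode + 4 * sd_est)
    if hi <= lo + 9:
        hi = float(populated[-1])
    for _ in range(n_iter):
        fit = fit_background_gaussian(hist, (lo, hi))
        sel = (hist.bin_centers >= lo) & (hist.bin_centers <= hi)
        g = hist.bin_centers[sel].astype(float)
        y = hist.counts[sel].astype(float)
        model = fit.amplitude * np.exp(-((g - fit.mean) ** 2) / (2 * fit.sd**2))
        resid_sd = float(np.std(y - model))
        above = g[(g > fit.mean) & (y - model > 3 * resid_sd)]
        if above.size == 0:
            break
        new_hi = float(above[0]) - 1
        if new_hi <= lo + 9 or new_hi >= hi:
            break
        hi = new_hi
    return (float(lo), float(hi))


def ci_threshold(
    fit: GaussianFitResult, alpha: float = 0.05, direction: Literal["upper", "lower"] = "upper"
) -> ThresholdDecision:
    """Confidence-interval threshold ``mean ± z_{alpha/2} * sd``.

    ``z_crit`` is the two-sided standard-normal critical score; with
    alpha = 0.05 it equals 1.96, so an upper threshold excludes 97.5% of an
    ideal Gaussian background.
    """
    if not 0 < alpha < 1:
        raise SegmentationError(f"alpha must be in (0, 1), got {alpha}")
    if direction not in ("upper", "lower"):
        raise SegmentationError(f"direction must be 'upper' or 'lower', got {direction!r}")
    z = float(stats.norm.ppf(1 - alpha / 2))
    t = fit.mean + z * fit.sd if direction == "upper" else fit.mean - z * fit.sd
    return ThresholdDecision(threshold=float(t), alpha=alpha, z_crit=z, direction=direction)


def binarize(vol: Volume3D, t: ThresholdDecision | float) -> BinaryMask:
    """Threshold a volume into a binary mask.

    Upper direction (default for a bare gray level): foreground iff
    ``gray >= threshold``; lower direction: ``gray <= threshold``. The
    real-valued threshold is compared as-is against integer gray levels.
    """
    if isinstance(t, ThresholdDecision):
        thr, direction = t.threshold, t.direction
    else:
        thr, direction = float(t), "upper"
    if direction == "upper":
        fg = vol.values >= thr
    else:
        fg = vol.values <= thr
    return BinaryMask(values=fg, spacing_um=vol.spacing_um)


def partial_volume_ratio(L: float, r: float, d: float) -> CylinderVoxelModel:
    """Cylinder voxel counts and the intermediate-voxel proportion ``2d/r``."""
    return CylinderVoxelModel(L=L, r=r, d=d)


_SENSITIVITY_DESCRIPTORS = ("segment_count", "node_count", "volume_density", "total_length")


def _descriptor_values(
    vol: Volume3D, oos_mask: BinaryMask, threshold: float, descriptors: Sequence[str]
) -> dict[str, float]:
    # Local imports: the downstream pipeline depends on this module.
    from scipy import ndimage as _ndi

    from .morphometry import volume_density
    from .skeleton import distance_map, map_radii, skeletonize
    from .vesselgraph import build_graph, default_prune_length, prune_graph

    ooi = binarize(vol, threshold)
    ooi.values &= oos_mask.values
    # same mask post-processing as the main pipeline: despeckle + majority smooth
    lab, _n = _ndi.label(ooi.values, structure=np.ones((3, 3, 3)))
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    ooi.values = (sizes >= 27)[lab]
    ooi.values = _ndi.median_filter(ooi.values.astype(np.uint8), size=3).astype(bool)
    ooi.values &= oos_mask.values
    out: dict[str, float] = {}
    if "volume_density" in descriptors:
        out["volume_density"] = volume_density(ooi, oos_mask)
    needs_graph = {"segment_count", "node_count", "total_length"} & set(descriptors)
    if needs_graph:
        skel = skeletonize(ooi)
        dm = distance_map(ooi)
        radii = map_radii(skel, dm)
        graph = prune_graph(
            build_graph(skel, radii),
            default_prune_length(vol.spacing_um),
            radius_aware=True,
        )
        if "segment_count" in descriptors:
            out["segment_count"] = float(len(graph.segments))
        if "node_count" in descriptors:
            out["node_count"] = float(sum(1 for n in graph.nodes if n.kind == "junction"))
        if "total_length" in descriptors:
            out["total_length"] = float(sum(s.real_length_um for s in graph.segments))
    return out


def threshold_sensitivity(
    vol: Volume3D,
    oos_mask: BinaryMask,
    t: ThresholdDecision | float,
    delta: float = 1.0,
    descriptors: Sequence[str] = _SENSITIVITY_DESCRIPTORS,
):
    """Signed percent change of descriptors when the threshold moves by ±delta.

    Runs the downstream pipeline (binarize, skeletonize, graph, morphometry)
    at ``t - delta``, ``t`` and ``t + delta`` gray levels and reports the
    percent change of each descriptor relative to the central threshold.
    Failures at a perturbed threshold are reported per cell as NaN with a
    logged message, never raised.
    """
    import pandas as pd

    unknown = set(descriptors) - set(_SENSITIVITY_DESCRIPTORS)
    if unknown:
        raise SegmentationError(f"unknown descriptors: {sorted(unknown)}")
    thr = t.threshold if isinstance(t, ThresholdDecision) else float(t)

    values: dict[float, dict[str, float]] = {}
    for off in (-delta, 0.0, delta):
        try:
            values[off] = _descriptor_values(vol, oos_mask, thr + off, descriptors)
        except Exception as exc:  # per-cell reporting, not fatal
            logger.warning("descriptor evaluation failed at threshold %+g: %s", off, exc)
            values[off] = {}

    base = values.get(0.0, {})
    rows = []
    for name in descriptors:
        row = {"descriptor": name, "value_at_t": base.get(name, np.nan)}
        for off, label in ((-delta, "pct_change_minus"), (delta, "pct_change_plus")):
            v = values[off].get(name, np.nan)
            b = base.get(name, np.nan)
            row[label] = 100.0 * (v - b) / b if b and np.isfinite(v) else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
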