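"""Quantitative read-outs: motility coefficient, circular hue-histogram
peaks, ROI thickness, and repeatability statistics.

The motility coefficient is the normalized temporal standard deviation
(SD / mean) of the amplitude at each ROI pixel, averaged over the ROI. Hue
analysis converts the dynamic-contrast RGB image to HSV, wraps the circular
hue axis from green to green ([120, 480) degrees, so red sits at 360, yellow
at 420 and blue at 240, all interior), and finds histogram peaks after
circular smoothing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib.colors import rgb_to_hsv

from ._core import BScanSeries, RoiMask, ValidationError
from .dyncontrast import DynamicImage

HUE_DOMAIN_DEG = (120.0, 480.0)

#: 1.96 * sqrt(2): scales within-subject SD to the coefficient of repeatability.
REPEATABILITY_FACTOR = 1.96 * float(np.sqrt(2.0))


@dataclass
class HueHistogram:
    """Histogram of wrapped hue values over [120, 480) degrees."""

    bin_edges: np.ndarray
    counts: np.ndarray
    n_pixels_used: int
    saturation_threshold: float
    value_threshold: float

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.size != self.bin_edges.size - 1:
            raise ValidationError("counts and bin_edges are inconsistent")
        if self.counts.sum() != self.n_pixels_used:
            raise ValidationError("counts must sum to n_pixels_used")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def motility_coefficient(series: BScanSeries, roi: RoiMask) -> float:
    """Mean over ROI pixels of the per-pixel temporal SD / temporal mean."""
    roi.require_grid(series.grid_shape)
    if roi.n_true == 0:
        raise ValidationError(f"ROI {roi.label!r} is empty")
    pix = series.data[:, roi.mask].astype(np.float64)  # (n_frames, n_roi)
    mean = pix.mean(axis=0)
    n_bad = int((mean <= 0).sum())
    if n_bad:
        raise ValidationError(
            f"{n_bad} ROI pixel(s) have non-positive temporal mean; "
            "motility is undefined there"
        )
    sd = pix.std(axis=0, ddof=1)
    return float((sd / mean).mean())


def wrap_hue_deg(hue_deg: np.ndarray) -> np.ndarray:
    """Map hue from [0, 360) to the green-to-green domain [120, 480)."""
    hue_deg = np.asarray(hue_deg, dtype=float)
    return np.where(hue_deg < HUE_DOMAIN_DEG[0], hue_deg + 360.0, hue_deg)


def hue_histogram(
    image: DynamicImage,
    roi: RoiMask,
    n_bins: int = 360,
    saturation_threshold: float = 0.1,
    value_threshold: float = 0.05,
) -> HueHistogram:
    """Histogram of wrapped hues of ROI pixels.

    Pixels whose HSV saturation or value falls below the thresholds are
    excluded; hue is numerically meaningless there.
    """
    roi.require_grid(image.grid_shape)
    if roi.n_true == 0:
        raise ValidationError(f"ROI {roi.label!r} is empty")
    rgb = np.clip(image.rgb[roi.mask], 0.0, 1.0)
    hsv = rgb_to_hsv(rgb)
    keep = (hsv[:, 1] >= saturation_threshold) & (hsv[:, 2] >= value_threshold)
    if not np.any(keep):
        raise ValidationError(
            "all ROI pixels fall below the saturation/value thresholds"
        )
    hue = wrap_hue_deg(hsv[keep, 0] * 360.0)
    edges = np.linspace(*HUE_DOMAIN_DEG, n_bins + 1)
    counts, _ = np.histogram(hue, bins=edges)
    return HueHistogram(
        bin_edges=edges, counts=counts, n_pixels_used=int(keep.sum()),
        saturation_threshold=saturation_threshold, value_threshold=value_threshold,
    )


def _circular_smooth(counts: np.ndarray, window: int) -> np.ndarray:
    if window % 2 != 1 or window < 1:
        raise ValidationError("smooth_window must be a positive odd integer")
    if window == 1:
        return counts.astype(float)
    half = window // 2
    padded = np.concatenate([counts[-half:], counts, counts[:half]]).astype(float)
    kernel = np.ones(window) / window
    return np.convolve(padded, kernel, mode="valid")


def find_hue_peaks(
    hist: HueHistogram,
    n_peaks: int = 1,
    smooth_window: int = 9,
    min_separation_deg: float = 30.0,
) -> list[tuple[float, float]]:
    """Up to ``n_peaks`` local maxima of the circularly smoothed histogram.

    Peaks are returned tallest first as (bin-center degrees, smoothed
    height); a peak closer than ``min_separation_deg`` (circular distance)
    to a taller one is suppressed. Ties break toward the lower wrapped
    degree. Fewer peaks than requested yields a shorter list.
    """
    if n_peaks < 1:
        raise ValidationError("n_peaks must be >= 1")
    smoothed = _circular_smooth(hist.counts, smooth_window)
    n = smoothed.size
    centers = hist.bin_centers
    left = np.roll(smoothed, 1)
    right = np.roll(smoothed, -1)
    candidates = np.nonzero((smoothed >= left) & (smoothed >= right) & (smoothed > 0))[0]
    # collapse circular runs of equal-height adjacent candidates (smoothing
    # plateaus) to their central bin
    if candidates.size > 1:
        cand = set(candidates.tolist())
        runs, seen = [], set()
        for i in candidates:
            if i in seen:
                continue
            run = [i]
            seen.add(i)
            j = (i - 1) % n
            while j in cand and j not in seen and smoothed[j] == smoothed[i]:
                run.insert(0, j)
                seen.add(j)
                j = (j - 1) % n
            j = (run[-1] + 1) % n
            while j in cand and j not in seen and smoothed[j] == smoothed[run[-1]]:
                run.append(j)
                seen.add(j)
                j = (j + 1) % n
            runs.append(run[len(run) // 2])
        candidates = np.array(sorted(runs))
    # tallest first; ties toward the lower wrapped degree
    order = sorted(candidates, key=lambda i: (-smoothed[i], centers[i]))
    span = HUE_DOMAIN_DEG[1] - HUE_DOMAIN_DEG[0]
    picked: list[int] = []
    for i in order:
        ok = True
        for j in picked:
            d = abs(centers[i] - centers[j])
            if min(d, span - d) < min_separation_deg:
                ok = False
                break
        if ok:
            picked.append(i)
        if len(picked) == n_peaks:
            break
    return [(float(centers[i]), float(smoothed[i])) for i in picked]


def thickness_from_mask(roi: RoiMask, axial_um_per_px: float) -> float:
    """Mean column-wise vertical extent of the mask, in micrometers.

    For every lateral column containing mask pixels the thickness is
    ``(max row - min row + 1) * axial_um_per_px``; the mean over such
    columns is returned. Column-wise extent is robust to small mask holes.
    """
    if axial_um_per_px <= 0:
        raise ValidationError("axial_um_per_px must be positive")
    if roi.n_true == 0:
        raise ValidationError(f"ROI {roi.label!r} is empty")
    any_col = roi.mask.any(axis=0)
    rows = np.arange(roi.mask.shape[0])[:, None]
    big = roi.mask.shape[0] + 1
    top = np.where(roi.mask, rows, big).min(axis=0)[any_col]
    bottom = np.where(roi.mask, rows, -1).max(axis=0)[any_col]
    return float(((bottom - top + 1) * axial_um_per_px).mean())


def repeatability_stats(values) -> tuple[float, float]:
    """Coefficient of variation and coefficient of repeatability.

    cv = sample SD / mean; cor = 1.96 * sqrt(2) * sample SD.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValidationError("repeatability_stats needs at least 2 values")
    sd = float(values.std(ddof=1))
    mean = float(values.mean())
    if mean == 0:
        raise ValidationError("coefficient of variation undefined for zero mean")
    return sd / mean, REPEATABILITY_FACTOR * sd
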