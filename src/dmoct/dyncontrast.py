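"""Dynamic-contrast processing of B-scan time series.

The chain turns a stack of repeated B-scans into an RGB image whose channels
encode the amplitude of temporal signal fluctuations in three frequency
bands: blue for slow, green for medium, red for fast motion. Processing
order: per-voxel temporal spectrum -> band integrals -> per-channel min-max
normalization -> histogram matching against a moving-SD reference ->
averaging of repeated acquisitions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from ._core import BScanSeries, ValidationError

NORMALIZATION_STATES = ("raw_integrals", "normalized", "histogram_matched", "averaged")

#: Default band edges in Hz: slow -> blue, medium -> green, fast -> red.
DEFAULT_BANDS_HZ = ((0.0, 0.5), (0.5, 5.0), (5.0, 25.0))


@dataclass(frozen=True)
class BandSpec:
    """Three ordered half-open frequency intervals [lo, hi) in Hz.

    Channel mapping is fixed: slow -> blue, medium -> green, fast -> red.
    """

    slow: tuple[float, float] = DEFAULT_BANDS_HZ[0]
    medium: tuple[float, float] = DEFAULT_BANDS_HZ[1]
    fast: tuple[float, float] = DEFAULT_BANDS_HZ[2]

    def __post_init__(self) -> None:
        edges = [*self.slow, *self.medium, *self.fast]
        if self.slow[0] < 0:
            raise ValidationError("band edges must be non-negative")
        for lo, hi in (self.slow, self.medium, self.fast):
            if not lo < hi:
                raise ValidationError("each band must satisfy lo < hi")
        if not (edges[1] <= edges[2] and edges[3] <= edges[4]):
            raise ValidationError("bands must be ordered slow <= medium <= fast")

    @property
    def intervals(self) -> tuple[tuple[float, float], ...]:
        return (self.slow, self.medium, self.fast)

    @property
    def names(self) -> tuple[str, str, str]:
        return ("slow", "medium", "fast")

    def validate_against_rate(self, frame_rate_hz: float) -> None:
        if self.fast[1] > frame_rate_hz / 2.0 + 1e-12:
            raise ValidationError(
                f"fast band upper edge {self.fast[1]} Hz exceeds the Nyquist "
                f"frequency {frame_rate_hz / 2.0} Hz"
            )


@dataclass
class DynamicImage:
    """Per-pixel three-channel dynamic-contrast image.

    ``rgb`` has shape (n_depth, n_ascans, 3) with channels ordered R, G, B.
    Values are in [0, 1] once ``normalization_state != 'raw_integrals'``.
    """

    rgb: np.ndarray
    bands: BandSpec
    n_frames_used: int
    normalization_state: str = "raw_integrals"

    def __post_init__(self) -> None:
        self.rgb = np.asarray(self.rgb, dtype=float)
        if self.rgb.ndim != 3 or self.rgb.shape[2] != 3:
            raise ValidationError("DynamicImage rgb must have shape (H, W, 3)")
        if self.normalization_state not in NORMALIZATION_STATES:
            raise ValidationError(
                f"unknown normalization state {self.normalization_state!r}"
            )
        if self.normalization_state != "raw_integrals":
            if self.rgb.min() < -1e-12 or self.rgb.max() > 1 + 1e-12:
                raise ValidationError("normalized channels must lie in [0, 1]")

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.rgb.shape[0], self.rgb.shape[1]


def spectrum_frequencies(n_frames: int, frame_rate_hz: float) -> np.ndarray:
    """Frequency axis of the one-sided temporal spectrum: k*rate/n, k=0..n//2."""
    return np.arange(n_frames // 2 + 1) * (frame_rate_hz / n_frames)


def temporal_spectrum(series: BScanSeries) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel magnitude of the DFT of the amplitude time series.

    No window function and no detrending are applied; the DC bin is retained.

    Returns
    -------
    spectrum : ndarray, shape (n_frames // 2 + 1, n_depth, n_ascans)
        One-sided DFT magnitudes.
    freqs : ndarray
        Bin-center frequencies ``k * frame_rate / n_frames``.
    """
    if series.n_frames < 2:
        raise ValidationError("temporal_spectrum requires at least 2 frames")
    spectrum = np.abs(np.fft.rfft(series.data.astype(np.float64), axis=0))
    freqs = spectrum_frequencies(series.n_frames, series.header.frame_rate_hz)
    return spectrum, freqs


def band_bin_indices(
    freqs: np.ndarray, bands: BandSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Assign spectral bins to bands by bin-center frequency, half-open intervals.

    The DC bin falls in the slow band whenever ``slow.lo == 0``. Bins at or
    above the fast band's upper edge are discarded.
    """
    out = []
    for name, (lo, hi) in zip(bands.names, bands.intervals):
        idx = np.nonzero((freqs >= lo) & (freqs < hi))[0]
        if idx.size == 0:
            raise ValidationError(
                f"band {name!r} [{lo}, {hi}) Hz contains no spectral bins "
                f"(bin spacing {freqs[1] - freqs[0]:.4g} Hz)"
                if freqs.size > 1
                else f"band {name!r} contains no spectral bins"
            )
        out.append(idx)
    return tuple(out)


def band_integrals(
    spectrum: np.ndarray,
    freqs: np.ndarray,
    bands: BandSpec,
    n_frames_used: int | None = None,
) -> DynamicImage:
    """Sum spectral magnitudes per voxel over each band -> raw RGB integrals.

    Channel order in the output is R (fast), G (medium), B (slow).
    """
    slow_idx, med_idx, fast_idx = band_bin_indices(freqs, bands)
    blue = spectrum[slow_idx].sum(axis=0)
    green = spectrum[med_idx].sum(axis=0)
    red = spectrum[fast_idx].sum(axis=0)
    rgb = np.stack([red, green, blue], axis=-1)
    n_used = 2 * (len(freqs) - 1) if n_frames_used is None else n_frames_used
    return DynamicImage(rgb=rgb, bands=bands, n_frames_used=n_used,
                        normalization_state="raw_integrals")


def normalize_channels(image: DynamicImage) -> DynamicImage:
    """Affine min-max rescale of each channel to [0, 1] over the whole image.

    A constant channel maps to all zeros (the "no dynamics" convention).
    """
    if image.normalization_state != "raw_integrals":
        raise ValidationError("normalize_channels expects raw_integrals state")
    out = np.empty_like(image.rgb, dtype=float)
    for c in range(3):
        ch = image.rgb[..., c]
        lo, hi = float(ch.min()), float(ch.max())
        if hi > lo:
            out[..., c] = (ch - lo) / (hi - lo)
        else:
            out[..., c] = 0.0
    return replace(image, rgb=out, normalization_state="normalized")


def moving_std_reference(series: BScanSeries, window: int = 25) -> np.ndarray:
    """Moving-SD reference image.

    Per voxel, the sample SD (ddof=1) over each contiguous run of ``window``
    frames, averaged across the ``n_frames - window + 1`` runs.
    """
    n = series.n_frames
    if not (2 <= window <= n):
        raise ValidationError(f"window must be in [2, {n}], got {window}")
    x = series.data.astype(np.float64)
    # Windowed sums via cumulative sums along the frame axis.
    zeros = np.zeros((1,) + x.shape[1:])
    c1 = np.concatenate([zeros, np.cumsum(x, axis=0)], axis=0)
    c2 = np.concatenate([zeros, np.cumsum(x * x, axis=0)], axis=0)
    s1 = c1[window:] - c1[:-window]
    s2 = c2[window:] - c2[:-window]
    var = (s2 - s1 * s1 / window) / (window - 1)
    np.clip(var, 0.0, None, out=var)  # guard tiny negative round-off
    return np.sqrt(var).mean(axis=0)


def histogram_match(
    image: DynamicImage, reference: np.ndarray, n_bins: int = 256
) -> DynamicImage:
    """Match each channel's value distribution to that of ``reference``.

    Monotone CDF matching on ``n_bins``-bin empirical histograms; a channel
    value is mapped to the lowest reference quantile whose CDF attains the
    channel's CDF value. Outputs live on the reference's min-max-rescaled
    value axis, hence in [0, 1]. Rank order within a channel is preserved.
    """
    if image.normalization_state != "normalized":
        raise ValidationError("histogram_match expects normalized state")
    reference = np.asarray(reference, dtype=float)
    if reference.shape != image.grid_shape:
        raise ValidationError(
            f"reference grid {reference.shape} does not match image grid "
            f"{image.grid_shape}"
        )
    ref_lo, ref_hi = float(reference.min()), float(reference.max())
    span = ref_hi - ref_lo if ref_hi > ref_lo else 1.0
    ref_bins = np.clip(((reference - ref_lo) / span * n_bins).astype(int), 0, n_bins - 1)
    ref_cdf = np.cumsum(np.bincount(ref_bins.ravel(), minlength=n_bins))
    ref_cdf = ref_cdf / ref_cdf[-1]
    ref_centers = (np.arange(n_bins) + 0.5) / n_bins

    out = np.empty_like(image.rgb)
    for c in range(3):
        ch = image.rgb[..., c]
        ch_bins = np.clip((ch * n_bins).astype(int), 0, n_bins - 1)
        ch_cdf = np.cumsum(np.bincount(ch_bins.ravel(), minlength=n_bins))
        ch_cdf = ch_cdf / ch_cdf[-1]
        # lowest reference bin whose CDF reaches the channel CDF value
        lut_idx = np.searchsorted(ref_cdf, ch_cdf, side="left")
        lut = ref_centers[np.clip(lut_idx, 0, n_bins - 1)]
        out[..., c] = lut[ch_bins]
    return replace(image, rgb=out, normalization_state="histogram_matched")


def average_repeats(images: list[DynamicImage]) -> DynamicImage:
    """Per-pixel, per-channel arithmetic mean of repeated acquisitions."""
    if len(images) < 1:
        raise ValidationError("average_repeats requires at least one image")
    first = images[0]
    for img in images[1:]:
        if img.grid_shape != first.grid_shape:
            raise ValidationError("images must share one spatial grid")
        if img.normalization_state != first.normalization_state:
            raise ValidationError("images must share one normalization state")
        if img.bands != first.bands:
            raise ValidationError("images must share one band specification")
    mean = np.mean([img.rgb for img in images], axis=0)
    return DynamicImage(rgb=mean, bands=first.bands,
                        n_frames_used=first.n_frames_used,
                        normalization_state="averaged")


def projection(series: BScanSeries, method: str = "max") -> np.ndarray:
    """Maximum-intensity or temporal-SD projection across frames."""
    if method == "max":
        return series.data.max(axis=0).astype(np.float64)
    if method == "std":
        if series.n_frames < 2:
            raise ValidationError("std projection requires at least 2 frames")
        return series.data.astype(np.float64).std(axis=0, ddof=1)
    raise ValidationError(f"unknown projection method {method!r}")


def process_series(
    series: BScanSeries,
    bands: BandSpec | None = None,
    window: int = 25,
    normalize: bool = True,
    histmatch: bool = True,
) -> DynamicImage:
    """Run the single-acquisition chain: spectrum -> integrals -> normalize
    -> histogram-match to the moving-SD reference."""
    bands = bands or BandSpec()
    bands.validate_against_rate(series.header.frame_rate_hz)
    spectrum, freqs = temporal_spectrum(series)
    image = band_integrals(spectrum, freqs, bands, n_frames_used=series.n_frames)
    if normalize:
        image = normalize_channels(image)
        if histmatch:
            reference = moving_std_reference(series, window=min(window, series.n_frames))
            image = histogram_match(image, reference)
    return image
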