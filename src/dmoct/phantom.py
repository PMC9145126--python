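"""Synthetic dynamic-speckle cornea phantom.

Generates B-scan time series of a layered cornea in which each layer has a
controllable mean amplitude, temporal fluctuation strength, and allocation
of fluctuation power across the three dynamic-contrast frequency bands,
plus ground-truth ROI masks and a parametric exposure time course
(epithelial swelling to a plateau, motility loss, a medium-to-fast spectral
shift of the basal cells, and delayed stromal swelling).

Band-limited dynamics are realized as sums of sinusoids at bin-centered
frequencies (k * frame_rate / n_frames) so that their spectral content
falls exactly on DFT bins; an i.i.d. Rayleigh mode provides fully dynamic
speckle with a flat fluctuation spectrum.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace

import numpy as np

from ._core import BScanSeries, ConfigurationError, RoiMask, StackHeader, ValidationError
from .dyncontrast import BandSpec, spectrum_frequencies

SPECKLE_MODES = ("sinusoid", "rayleigh")

#: Temporal coefficient of variation of i.i.d. Rayleigh-distributed amplitudes.
RAYLEIGH_CV = float(np.sqrt(4.0 / np.pi - 1.0))


@dataclass(frozen=True)
class LayerSpec:
    """One tissue layer of the phantom.

    ``band_power_fractions`` gives the fraction of temporal fluctuation power
    in the (slow, medium, fast) bands; the remainder is static. At the
    default acquisition grid the slow band contains only the DC bin, so its
    share is realized as static power. ``band_jitter`` exchanges a uniform
    per-pixel amount of power between the medium and fast bands, modelling
    cell-to-cell variability of the activity spectrum (this is what gives
    the hue histogram its width).
    """

    name: str
    z_range: tuple[int, int]
    mean_amplitude: float
    band_power_fractions: tuple[float, float, float] = (0.0, 0.0, 0.0)
    fluctuation_strength: float = 0.0
    cell_diameter_px: int = 0
    band_jitter: float = 0.0
    speckle_mode: str = "sinusoid"

    def __post_init__(self) -> None:
        z0, z1 = self.z_range
        if not (0 <= z0 < z1):
            raise ValidationError(f"layer {self.name!r}: bad z_range {self.z_range}")
        if self.mean_amplitude <= 0:
            raise ValidationError(f"layer {self.name!r}: mean_amplitude must be > 0")
        fr = self.band_power_fractions
        if len(fr) != 3 or any(f < 0 or f > 1 for f in fr):
            raise ValidationError(
                f"layer {self.name!r}: band_power_fractions must be three values in [0, 1]"
            )
        if sum(fr) > 1 + 1e-9:
            raise ValidationError(
                f"layer {self.name!r}: band_power_fractions sum to {sum(fr):.3f} > 1"
            )
        if self.fluctuation_strength < 0:
            raise ValidationError(f"layer {self.name!r}: fluctuation_strength must be >= 0")
        if self.cell_diameter_px < 0:
            raise ValidationError(f"layer {self.name!r}: cell_diameter_px must be >= 0")
        if self.band_jitter < 0:
            raise ValidationError(f"layer {self.name!r}: band_jitter must be >= 0")
        if self.speckle_mode not in SPECKLE_MODES:
            raise ValidationError(
                f"layer {self.name!r}: speckle_mode must be one of {SPECKLE_MODES}"
            )

    @property
    def thickness_px(self) -> int:
        return self.z_range[1] - self.z_range[0]


@dataclass(frozen=True)
class PhantomConfig:
    """Full description of one synthetic acquisition."""

    layers: tuple[LayerSpec, ...]
    n_frames: int = 150
    n_ascans: int = 512
    n_depth: int = 200
    frame_rate_hz: float = 111.0
    lateral_extent_mm: float = 0.5
    axial_um_per_px: float = 1.0
    noise_sigma: float = 0.0
    n_repeats: int = 5
    seed: int = 0
    bands: BandSpec = field(default_factory=BandSpec)

    def __post_init__(self) -> None:
        object.__setattr__(self, "layers", tuple(self.layers))
        if self.n_frames < 2:
            raise ValidationError("n_frames must be >= 2")
        if min(self.n_ascans, self.n_depth, self.n_repeats) < 1:
            raise ValidationError("all counts must be positive")
        if self.frame_rate_hz <= 0:
            raise ValidationError("frame_rate_hz must be positive")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be >= 0")
        self.bands.validate_against_rate(self.frame_rate_hz)
        ranges = sorted(l.z_range for l in self.layers)
        for (a0, a1), (b0, b1) in zip(ranges, ranges[1:]):
            if b0 < a1:
                raise ValidationError("layer z ranges must be disjoint")
        for layer in self.layers:
            if layer.z_range[1] > self.n_depth:
                raise ValidationError(
                    f"layer {layer.name!r} extends past n_depth={self.n_depth}"
                )

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate_hz

    @property
    def lateral_um_per_px(self) -> float:
        return self.lateral_extent_mm * 1000.0 / self.n_ascans

    def layer(self, name: str) -> LayerSpec:
        for layer in self.layers:
            if layer.name == name:
                return layer
        raise KeyError(name)

    def header(self) -> StackHeader:
        return StackHeader(
            n_frames=self.n_frames, n_depth=self.n_depth, n_ascans=self.n_ascans,
            frame_rate_hz=self.frame_rate_hz, axial_um_per_px=self.axial_um_per_px,
            lateral_um_per_px=self.lateral_um_per_px,
        )

    def summary(self) -> dict:
        """Key acquisition numbers, including the recording duration."""
        return {
            "n_frames": self.n_frames,
            "n_ascans": self.n_ascans,
            "n_depth": self.n_depth,
            "frame_rate_hz": self.frame_rate_hz,
            "duration_s": round(self.duration_s, 2),
            "nyquist_hz": self.frame_rate_hz / 2.0,
            "lateral_extent_mm": self.lateral_extent_mm,
            "n_repeats": self.n_repeats,
            "layers": [l.name for l in self.layers],
        }


@dataclass(frozen=True)
class ToxicityCourse:
    """Parametric exposure time course.

    Epithelial layers swell by a saturating factor that is exactly constant
    from ``plateau_min`` onward; the stroma swells linearly but only from
    ``stroma_onset_min``; basal fluctuation strength decays exponentially;
    basal fluctuation power is transferred from the medium to the fast band
    at ``redshift_rate_per_min`` (clamped to valid fractions).
    """

    epi_swell_max: float = 1.5
    epi_swell_tau_min: float = 60.0
    plateau_min: float = 150.0
    stroma_onset_min: float = 150.0
    stroma_swell_per_min: float = 0.006
    motility_decay_per_min: float = 0.002
    redshift_rate_per_min: float = 0.003

    def __post_init__(self) -> None:
        if self.epi_swell_max < 1:
            raise ValidationError("epi_swell_max must be >= 1")
        if self.epi_swell_tau_min <= 0:
            raise ValidationError("epi_swell_tau_min must be positive")
        if min(self.motility_decay_per_min, self.redshift_rate_per_min,
               self.stroma_swell_per_min) < 0:
            raise ValidationError("rates must be >= 0")

    def epithelium_factor(self, exposure_min: float) -> float:
        """Saturating thickness factor; constant for t >= plateau_min."""
        t = min(exposure_min, self.plateau_min)
        ramp = 1.0 - np.exp(-t / self.epi_swell_tau_min)
        full = 1.0 - np.exp(-self.plateau_min / self.epi_swell_tau_min)
        return 1.0 + (self.epi_swell_max - 1.0) * ramp / full

    def stroma_factor(self, exposure_min: float) -> float:
        if exposure_min < self.stroma_onset_min:
            return 1.0
        return 1.0 + self.stroma_swell_per_min * (exposure_min - self.stroma_onset_min)


EPITHELIAL_LAYERS = ("superficial", "basal")


def make_default_cornea(**overrides) -> PhantomConfig:
    """Baseline three-layer cornea phantom.

    The superficial epithelium has its fluctuation power mostly in the slow
    band (rendering blue), the basal epithelium splits power between the
    medium and fast bands (rendering yellow after channel mapping), and the
    stroma fluctuates weakly. Defaults: 150 frames of 512 A-scans at an
    effective B-scan rate of 111 Hz, five repeats.
    """
    layers = (
        LayerSpec(
            name="superficial", z_range=(20, 40), mean_amplitude=1.0,
            band_power_fractions=(0.80, 0.05, 0.05), fluctuation_strength=0.15,
            band_jitter=0.02,
        ),
        LayerSpec(
            name="basal", z_range=(40, 60), mean_amplitude=0.40,
            band_power_fractions=(0.04, 0.45, 0.45), fluctuation_strength=0.38,
            band_jitter=0.06, cell_diameter_px=8,
        ),
        LayerSpec(
            name="stroma", z_range=(60, 150), mean_amplitude=0.35,
            band_power_fractions=(0.70, 0.04, 0.02), fluctuation_strength=0.08,
        ),
    )
    defaults = dict(layers=layers, n_frames=150, n_ascans=512, n_depth=200,
                    frame_rate_hz=111.0, lateral_extent_mm=0.5, noise_sigma=0.01,
                    n_repeats=5, seed=0)
    valid = {f.name for f in dataclasses.fields(PhantomConfig)}
    for key in overrides:
        if key not in valid:
            raise ConfigurationError(f"unknown PhantomConfig field {key!r}")
    defaults.update(overrides)
    # Shrunken depth grids keep the default layer proportions.
    if "layers" not in overrides and defaults["n_depth"] != 200:
        scale = defaults["n_depth"] / 200.0
        scaled = []
        for layer in layers:
            z0 = int(round(layer.z_range[0] * scale))
            z1 = max(int(round(layer.z_range[1] * scale)), z0 + 1)
            scaled.append(replace(layer, z_range=(z0, z1)))
        defaults["layers"] = tuple(scaled)
    return PhantomConfig(**defaults)


def default_course() -> ToxicityCourse:
    return ToxicityCourse()


def apply_toxicity(
    config: PhantomConfig, course: ToxicityCourse, exposure_min: float
) -> PhantomConfig:
    """Exposure-adjusted copy of ``config``; the input is not mutated.

    Layer thicknesses are scaled (rounded to whole pixels) and restacked
    contiguously from the top of the uppermost layer so that z ranges stay
    disjoint.
    """
    if exposure_min < 0:
        raise ValidationError("exposure_min must be >= 0")
    t = float(exposure_min)
    epi_f = course.epithelium_factor(t)
    stroma_f = course.stroma_factor(t)
    motility_f = float(np.exp(-course.motility_decay_per_min * t))

    ordered = sorted(config.layers, key=lambda l: l.z_range[0])
    z_cursor = ordered[0].z_range[0] if ordered else 0
    new_layers = []
    for layer in ordered:
        if layer.name in EPITHELIAL_LAYERS:
            factor = epi_f
        elif layer.name == "stroma":
            factor = stroma_f
        else:
            factor = 1.0
        thickness = int(round(layer.thickness_px * factor))
        thickness = max(thickness, 1)
        changes: dict = {"z_range": (z_cursor, z_cursor + thickness)}
        if layer.name == "basal":
            slow, med, fast = layer.band_power_fractions
            shift = min(med, course.redshift_rate_per_min * t)
            changes["band_power_fractions"] = (slow, med - shift, fast + shift)
            changes["fluctuation_strength"] = layer.fluctuation_strength * motility_f
        new_layers.append(replace(layer, **changes))
        z_cursor += thickness
    n_depth = max(config.n_depth, z_cursor)
    return replace(config, layers=tuple(new_layers), n_depth=n_depth)


def ground_truth_masks(config: PhantomConfig) -> dict[str, RoiMask]:
    """ROI masks matching the layer geometry of ``config``.

    ``total_epithelium`` is the union of the superficial and basal layers;
    the per-layer masks are pairwise disjoint.
    """
    shape = (config.n_depth, config.n_ascans)
    masks: dict[str, RoiMask] = {}
    total = np.zeros(shape, dtype=bool)
    for layer in config.layers:
        m = np.zeros(shape, dtype=bool)
        m[layer.z_range[0]:layer.z_range[1], :] = True
        if layer.name in EPITHELIAL_LAYERS:
            total |= m
        if layer.name == "basal":
            masks["basal_epithelium"] = RoiMask(m, "basal_epithelium")
        elif layer.name == "superficial":
            masks["superficial_epithelium"] = RoiMask(m, "superficial_epithelium")
        elif layer.name == "stroma":
            masks["stroma"] = RoiMask(m, "stroma")
    masks["total_epithelium"] = RoiMask(total, "total_epithelium")
    return masks


def _band_sinusoid_bins(config: PhantomConfig) -> dict[str, np.ndarray]:
    """Bin-centered frequencies available for dynamic synthesis per band.

    The DC bin is excluded (it carries the static mean). A band whose
    interval contains no non-DC bin yields an empty array; its power share
    is treated as static. Up to three bins per band are used, spread across
    the interval.
    """
    freqs = spectrum_frequencies(config.n_frames, config.frame_rate_hz)
    out: dict[str, np.ndarray] = {}
    for name, (lo, hi) in zip(config.bands.names, config.bands.intervals):
        if hi > config.frame_rate_hz / 2.0 + 1e-12:
            raise ValidationError(
                f"band {name!r} requests frequencies above Nyquist "
                f"({config.frame_rate_hz / 2.0} Hz)"
            )
        idx = np.nonzero((freqs >= lo) & (freqs < hi) & (np.arange(len(freqs)) > 0))[0]
        if idx.size > 3:
            idx = idx[np.round(np.linspace(0, idx.size - 1, 3)).astype(int)]
        out[name] = freqs[idx]
    return out


def _layer_fields(
    layer: LayerSpec, config: PhantomConfig, rng: np.random.Generator
) -> np.ndarray:
    """Time series block for one layer, shape (n_frames, thickness, n_ascans)."""
    nz = layer.thickness_px
    nx = config.n_ascans
    nt = config.n_frames

    # Per-cell lateral amplitude texture (cosmetic).
    mean_map = np.full((nz, nx), layer.mean_amplitude)
    if layer.cell_diameter_px > 0:
        n_cells = -(-nx // layer.cell_diameter_px)
        cell_gain = rng.uniform(0.75, 1.25, size=n_cells)
        gain_row = np.repeat(cell_gain, layer.cell_diameter_px)[:nx]
        mean_map *= gain_row[None, :]

    if layer.speckle_mode == "rayleigh":
        # Fully dynamic speckle: i.i.d. Rayleigh per frame, mean preserved.
        scale = mean_map / np.sqrt(np.pi / 2.0)
        return rng.rayleigh(scale=np.broadcast_to(scale, (nt, nz, nx)))

    if layer.fluctuation_strength == 0:
        return np.broadcast_to(mean_map, (nt, nz, nx)).copy()

    slow_f, med_f, fast_f = layer.band_power_fractions
    # Per-pixel exchange of power between medium and fast bands. Triangular
    # (sum of two uniforms) so the pixel density peaks at the programmed
    # split and the hue-histogram mode tracks it.
    if layer.band_jitter > 0:
        u = 0.5 * (
            rng.uniform(-layer.band_jitter, layer.band_jitter, size=(nz, nx))
            + rng.uniform(-layer.band_jitter, layer.band_jitter, size=(nz, nx))
        )
        u = np.clip(u, -fast_f, med_f)
    else:
        u = np.zeros((nz, nx))
    med_px = med_f - u
    fast_px = fast_f + u

    band_bins = _band_sinusoid_bins(config)
    t = np.arange(nt) / config.frame_rate_hz
    rel = np.zeros((nt, nz, nx))
    for name, frac_px in (("slow", None), ("medium", med_px), ("fast", fast_px)):
        freqs_b = band_bins[name]
        if name == "slow":
            # At the default grid the slow interval holds only the DC bin;
            # its power share stays static. If non-DC bins exist, use them.
            frac_px = np.full((nz, nx), slow_f) if freqs_b.size else None
        if frac_px is None or freqs_b.size == 0 or np.all(frac_px <= 0):
            continue
        k = freqs_b.size
        var_px = np.clip(frac_px, 0.0, None) * layer.fluctuation_strength**2
        amp = np.sqrt(2.0 * var_px / k)  # per-sinusoid relative amplitude
        for f in freqs_b:
            phase = rng.uniform(0.0, 2.0 * np.pi, size=(nz, nx))
            rel += amp[None, :, :] * np.cos(
                2.0 * np.pi * f * t[:, None, None] + phase[None, :, :]
            )
    return mean_map[None, :, :] * (1.0 + rel)


def simulate_series(
    config: PhantomConfig,
    exposure_min: float = 0.0,
    course: ToxicityCourse | None = None,
    repeat_index: int = 0,
) -> tuple[BScanSeries, dict[str, RoiMask]]:
    """Simulate one dynamic-contrast acquisition plus ground-truth masks.

    The same ``(config.seed, exposure_min, repeat_index)`` triple always
    produces bit-identical output. Repeat streams are derived from
    ``seed + repeat_index`` so repeats are independent but reproducible.
    """
    if exposure_min < 0:
        raise ValidationError("exposure_min must be >= 0")
    if not (0 <= repeat_index < config.n_repeats):
        raise ValidationError(
            f"repeat_index must be in [0, {config.n_repeats}), got {repeat_index}"
        )
    course = course or ToxicityCourse()
    cfg = apply_toxicity(config, course, exposure_min)

    rng = np.random.default_rng(
        [config.seed + repeat_index, int(round(exposure_min * 1000))]
    )
    data = np.zeros((cfg.n_frames, cfg.n_depth, cfg.n_ascans))
    for layer in cfg.layers:
        z0, z1 = layer.z_range
        data[:, z0:z1, :] = _layer_fields(layer, cfg, rng)
    if cfg.noise_sigma > 0:
        data += rng.normal(0.0, cfg.noise_sigma, size=data.shape)
    np.clip(data, 0.0, None, out=data)  # amplitudes are non-negative

    series = BScanSeries(data=data.astype(np.float32), header=cfg.header())
    return series, ground_truth_masks(cfg)
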