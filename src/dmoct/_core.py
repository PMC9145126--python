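"""Shared data containers used across the processing modules.

Conventions: stacks are indexed (frame, depth-row, lateral-column), 0-based,
depth increasing downward; all pixel intervals are half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

ROI_LABELS = ("total_epithelium", "basal_epithelium", "stroma", "superficial_epithelium")


class ValidationError(ValueError):
    """Input violates a documented precondition."""


class FormatError(ValueError):
    """A file on disk is not something our writers could have produced."""


class ConfigurationError(ValueError):
    """Bad configuration value or unknown configuration key."""


@dataclass(frozen=True)
class StackHeader:
    """Acquisition geometry and timing of one B-scan time series."""

    n_frames: int
    n_depth: int
    n_ascans: int
    frame_rate_hz: float
    axial_um_per_px: float = 1.0
    lateral_um_per_px: float = 500.0 / 512.0
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if self.n_frames < 1 or self.n_depth < 1 or self.n_ascans < 1:
            raise ValidationError("stack dimensions must be positive")
        if self.frame_rate_hz <= 0:
            raise ValidationError("frame_rate_hz must be positive")
        if self.axial_um_per_px <= 0 or self.lateral_um_per_px <= 0:
            raise ValidationError("pixel pitches must be positive")

    @property
    def duration_s(self) -> float:
        """Total recording time of the series in seconds."""
        return self.n_frames / self.frame_rate_hz

    @property
    def nyquist_hz(self) -> float:
        """Highest analyzable fluctuation frequency."""
        return self.frame_rate_hz / 2.0

    def to_dict(self) -> dict:
        return {
            "n_frames": self.n_frames,
            "n_depth": self.n_depth,
            "n_ascans": self.n_ascans,
            "frame_rate_hz": self.frame_rate_hz,
            "axial_um_per_px": self.axial_um_per_px,
            "lateral_um_per_px": self.lateral_um_per_px,
            "dtype": self.dtype,
        }


@dataclass
class BScanSeries:
    """A 3-D stack of OCT amplitude values with its acquisition header.

    ``data`` has shape ``(n_frames, n_depth, n_ascans)`` and holds finite,
    non-negative amplitudes.
    """

    data: np.ndarray
    header: StackHeader

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValidationError(f"stack must be 3-D, got shape {self.data.shape}")
        expected = (self.header.n_frames, self.header.n_depth, self.header.n_ascans)
        if self.data.shape != expected:
            raise FormatError(
                f"stack shape {self.data.shape} does not match header {expected}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("stack contains non-finite values")
        if np.any(self.data < 0):
            raise ValidationError("stack contains negative amplitudes")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.data.shape[1], self.data.shape[2]


@dataclass
class RoiMask:
    """Boolean 2-D region-of-interest mask on the grid of one B-scan."""

    mask: np.ndarray
    label: str = "total_epithelium"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValidationError("ROI mask must be 2-D")
        if self.label not in ROI_LABELS:
            raise ValidationError(
                f"unknown ROI label {self.label!r}; expected one of {ROI_LABELS}"
            )

    @property
    def n_true(self) -> int:
        return int(self.mask.sum())

    def require_grid(self, shape: tuple[int, int]) -> None:
        if self.mask.shape != tuple(shape):
            raise ValidationError(
                f"ROI grid {self.mask.shape} does not match image grid {tuple(shape)}"
            )


@dataclass
class MetricsRecord:
    """One row of the study table."""

    sample_id: str
    group: str
    exposure_min: float
    roi: str
    motility: Optional[float] = None
    peak_hue_deg: Optional[float] = None
    second_peak_hue_deg: Optional[float] = None
    thickness_um: Optional[float] = None
    repeat: Optional[int] = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in ("control", "BAK"):
            raise ValidationError(f"unknown group {self.group!r}")
        if self.motility is not None and self.motility < 0:
            raise ValidationError("motility must be >= 0")
        for h in (self.peak_hue_deg, self.second_peak_hue_deg):
            if h is not None and not (120.0 <= h < 480.0):
                raise ValidationError("hue peaks must lie in [120, 480) degrees")
        if self.thickness_um is not None and self.thickness_um <= 0:
            raise ValidationError("thickness_um must be positive when defined")
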