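"""File formats: B-scan stacks, ROI masks, RGB images, configs, metrics tables.

Stacks are multi-page float32 TIFF (one page per frame) with a JSON sidecar
header (``<stack>.json``), or raw float32 binaries with the same sidecar.
Masks and RGB images are 8-bit PNG. Metrics go to CSV (comma separator,
"." decimal, UTF-8, no index column). All writers are deterministic
byte-for-byte for fixed input.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from ._core import (
    BScanSeries,
    FormatError,
    MetricsRecord,
    RoiMask,
    StackHeader,
    ValidationError,
)
from .dyncontrast import DynamicImage

METRICS_COLUMNS = [
    "sample_id", "group", "exposure_min", "roi", "repeat",
    "motility", "peak_hue_deg", "second_peak_hue_deg", "thickness_um",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_stack(series: BScanSeries, path: str | Path) -> None:
    """Write a stack as multi-page float32 TIFF (or .raw) plus JSON sidecar."""
    path = Path(path)
    data = series.data.astype(np.float32)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, data, photometric="minisblack")
    elif path.suffix.lower() == ".raw":
        data.tofile(path)
    else:
        raise ValidationError(f"unsupported stack extension {path.suffix!r}")
    _sidecar(path).write_text(
        json.dumps(series.header.to_dict(), indent=1, sort_keys=True) + "\n"
    )


def read_stack(path: str | Path) -> BScanSeries:
    """Read a stack written by :func:`write_stack`, validating shape and range."""
    path = Path(path)
    sidecar = _sidecar(path)
    if not sidecar.exists():
        raise FormatError(f"missing sidecar header {sidecar}")
    try:
        header = StackHeader(**json.loads(sidecar.read_text()))
    except (json.JSONDecodeError, TypeError) as exc:
        raise FormatError(f"bad sidecar header {sidecar}: {exc}") from exc
    shape = (header.n_frames, header.n_depth, header.n_ascans)
    if path.suffix.lower() in (".tif", ".tiff"):
        try:
            data = tifffile.imread(path)
        except Exception as exc:  # tifffile raises several concrete types
            raise FormatError(f"cannot read TIFF {path}: {exc}") from exc
        data = np.atleast_3d(data)
        if data.shape != shape:
            raise FormatError(
                f"pixel data shape {data.shape} does not match header {shape}"
            )
    elif path.suffix.lower() == ".raw":
        data = np.fromfile(path, dtype=header.dtype)
        if data.size != int(np.prod(shape)):
            raise FormatError(
                f"raw file holds {data.size} values, header implies {int(np.prod(shape))}"
            )
        data = data.reshape(shape)
    else:
        raise FormatError(f"unsupported stack extension {path.suffix!r}")
    if not np.all(np.isfinite(data)):
        raise ValidationError(f"{path}: stack contains non-finite values")
    if np.any(data < 0):
        raise ValidationError(f"{path}: stack contains negative amplitudes")
    return BScanSeries(data=data, header=header)


def write_rgb(image: DynamicImage, path: str | Path) -> None:
    """Write a dynamic-contrast image as 8-bit RGB PNG (round-half-up)."""
    rgb = np.asarray(image.rgb, dtype=float)
    if rgb.min() < 0 or rgb.max() > 1:
        raise ValidationError("RGB channels must lie in [0, 1] before writing")
    quantized = np.floor(rgb * 255.0 + 0.5).astype(np.uint8)
    iio.imwrite(Path(path), quantized, extension=".png")


def read_rgb(path: str | Path) -> np.ndarray:
    """Read an 8-bit RGB PNG back to float channels in [0, 1]."""
    arr = iio.imread(Path(path))
    if arr.ndim != 3 or arr.shape[2] < 3:
        raise FormatError(f"{path}: expected an RGB image")
    return arr[..., :3].astype(float) / 255.0


def write_mask(roi: RoiMask, path: str | Path) -> None:
    """Write a boolean ROI mask as single-channel 8-bit PNG (0/255)."""
    iio.imwrite(Path(path), (roi.mask.astype(np.uint8) * 255), extension=".png")


def read_mask(path: str | Path, label: str = "total_epithelium",
              grid_shape: tuple[int, int] | None = None) -> RoiMask:
    """Read a mask image, thresholding at > 0.

    If ``grid_shape`` is given the mask grid is validated against it.
    """
    arr = iio.imread(Path(path))
    if arr.ndim == 3:
        raise FormatError(f"{path}: mask image must be single-channel")
    roi = RoiMask(arr > 0, label)
    if grid_shape is not None:
        roi.require_grid(grid_shape)
    return roi


def records_to_frame(records: list[MetricsRecord]) -> pd.DataFrame:
    rows = [
        {
            "sample_id": r.sample_id, "group": r.group,
            "exposure_min": r.exposure_min, "roi": r.roi, "repeat": r.repeat,
            "motility": r.motility, "peak_hue_deg": r.peak_hue_deg,
            "second_peak_hue_deg": r.second_peak_hue_deg,
            "thickness_um": r.thickness_um,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=METRICS_COLUMNS)


def write_metrics(records: list[MetricsRecord] | pd.DataFrame, path: str | Path) -> None:
    """Write the metrics table as CSV with a fixed header, 6 significant digits."""
    frame = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    missing = [c for c in METRICS_COLUMNS if c not in frame.columns]
    if missing and not isinstance(records, pd.DataFrame):
        raise ValidationError(f"metrics table missing columns {missing}")
    frame.to_csv(path, index=False, float_format="%.6g", encoding="utf-8",
                 lineterminator="\n")


def read_metrics(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    return frame


def write_config(obj, path: str | Path) -> None:
    """Serialize a (possibly nested) dataclass config to YAML."""
    import dataclasses

    def plain(x):
        if dataclasses.is_dataclass(x) and not isinstance(x, type):
            return {f.name: plain(getattr(x, f.name)) for f in dataclasses.fields(x)}
        if isinstance(x, (list, tuple)):
            return [plain(v) for v in x]
        if isinstance(x, dict):
            return {k: plain(v) for k, v in x.items()}
        if isinstance(x, (np.floating, np.integer)):
            return x.item()
        return x

    Path(path).write_text(yaml.safe_dump(plain(obj), sort_keys=True))


def read_config(path: str | Path) -> dict:
    loaded = yaml.safe_load(Path(path).read_text())
    if not isinstance(loaded, dict):
        raise FormatError(f"{path}: config must be a mapping")
    return loaded
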