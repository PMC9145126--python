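"""Orchestration of the in-silico exposure study.

Generates control and BAK phantom series over the exposure grid, runs the
dynamic-contrast chain, computes the metrics, and writes the per-repeat
table, the per-(eye, time) aggregate, and averaged RGB images.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from ._core import MetricsRecord, ValidationError
from . import dyncontrast, io_store, metrics as metrics_mod
from .dyncontrast import BandSpec
from .phantom import PhantomConfig, ToxicityCourse, make_default_cornea, simulate_series

log = logging.getLogger("dmoct")

#: Metrics whose group summaries are reported.
METRIC_COLUMNS = ("motility", "peak_hue_deg", "second_peak_hue_deg", "thickness_um")


def percent_w_v(mass_mg: float, volume_ml: float) -> float:
    """Mass/volume percent concentration: mg -> g, divided by mL, times 100."""
    if mass_mg < 0 or volume_ml <= 0:
        raise ValidationError("mass must be >= 0 and volume > 0")
    return (mass_mg / 1000.0) / volume_ml * 100.0


@dataclass(frozen=True)
class StudyConfig:
    """Parameters of one simulated exposure study."""

    exposure_grid_min: tuple[float, ...] = (0, 30, 60, 90, 120, 150, 180, 210, 240, 270)
    n_eyes_per_group: int = 3
    n_repeats: int = 5
    phantom: PhantomConfig = field(default_factory=make_default_cornea)
    course: ToxicityCourse = field(default_factory=ToxicityCourse)
    bands: BandSpec = field(default_factory=BandSpec)
    seed: int = 0
    bak_mass_mg: float = 5.0
    bak_volume_ml: float = 100.0

    def __post_init__(self) -> None:
        grid = tuple(float(t) for t in self.exposure_grid_min)
        object.__setattr__(self, "exposure_grid_min", grid)
        if len(grid) < 1 or grid[0] != 0.0:
            raise ValidationError("exposure grid must start at 0 (baseline)")
        if any(b <= a for a, b in zip(grid, grid[1:])):
            raise ValidationError("exposure grid must be strictly increasing")
        if self.n_eyes_per_group < 1 or self.n_repeats < 1:
            raise ValidationError("counts must be positive")
        self.bands.validate_against_rate(self.phantom.frame_rate_hz)

    @property
    def bak_percent_w_v(self) -> float:
        return percent_w_v(self.bak_mass_mg, self.bak_volume_ml)


def _eye_phantom(config: StudyConfig, group: str, eye: int, t_index: int) -> PhantomConfig:
    """Phantom config with a stream seed unique to (group, eye, time point).

    Control eyes get a fresh speckle realization at every time point,
    emulating repeated imaging sessions of an unchanging tissue.
    """
    group_offset = 0 if group == "control" else 1_000_000
    seed = config.seed + group_offset + 10_000 * eye + 100 * t_index
    return replace(config.phantom, seed=seed, n_repeats=config.n_repeats)


def analyze_acquisition(
    series, masks, image, axial_um_per_px: float
) -> dict[str, dict]:
    """Metrics for one (series, masks, normalized image) triple, keyed by ROI."""
    out: dict[str, dict] = {}
    total, basal = masks["total_epithelium"], masks["basal_epithelium"]
    hist_total = metrics_mod.hue_histogram(image, total)
    peaks_total = metrics_mod.find_hue_peaks(hist_total, n_peaks=2)
    hist_basal = metrics_mod.hue_histogram(image, basal)
    peaks_basal = metrics_mod.find_hue_peaks(hist_basal, n_peaks=1)
    out["total_epithelium"] = {
        "motility": metrics_mod.motility_coefficient(series, total),
        "peak_hue_deg": peaks_total[0][0] if peaks_total else None,
        "second_peak_hue_deg": peaks_total[1][0] if len(peaks_total) > 1 else None,
        "thickness_um": metrics_mod.thickness_from_mask(total, axial_um_per_px),
    }
    out["basal_epithelium"] = {
        "motility": metrics_mod.motility_coefficient(series, basal),
        "peak_hue_deg": peaks_basal[0][0] if peaks_basal else None,
        "second_peak_hue_deg": None,
        "thickness_um": metrics_mod.thickness_from_mask(basal, axial_um_per_px),
    }
    if "stroma" in masks:
        out["stroma"] = {
            "motility": None, "peak_hue_deg": None, "second_peak_hue_deg": None,
            "thickness_um": metrics_mod.thickness_from_mask(
                masks["stroma"], axial_um_per_px
            ),
        }
    return out


def run_timecourse(config: StudyConfig, output_dir: str | Path | None = None,
                   write_images: bool = True) -> pd.DataFrame:
    """Run the full study; returns the per-repeat metrics table.

    For every (group, eye, exposure, repeat): simulate a series (control
    eyes use exposure-0 dynamics throughout), run the dynamic-contrast
    chain, and measure motility, hue peaks (basal: 1, total: 2) and
    thickness. Hue metrics are computed on the channel-normalized image;
    histogram-matched, repeat-averaged images are written for display. The
    whole run is reproducible from ``config.seed``.
    """
    outdir = Path(output_dir) if output_dir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
    records: list[MetricsRecord] = []
    for group in ("control", "BAK"):
        for eye in range(config.n_eyes_per_group):
            sample_id = f"{group}_eye{eye}"
            for t_index, exposure in enumerate(config.exposure_grid_min):
                t0 = time.perf_counter()
                phantom_cfg = _eye_phantom(config, group, eye, t_index)
                sim_exposure = 0.0 if group == "control" else exposure
                display_images = []
                try:
                    for rep in range(config.n_repeats):
                        series, masks = simulate_series(
                            phantom_cfg, sim_exposure, config.course, rep
                        )
                        image = dyncontrast.process_series(
                            series, config.bands, histmatch=False
                        )
                        roi_metrics = analyze_acquisition(
                            series, masks, image,
                            phantom_cfg.axial_um_per_px,
                        )
                        for roi, vals in roi_metrics.items():
                            records.append(MetricsRecord(
                                sample_id=sample_id, group=group,
                                exposure_min=exposure, roi=roi, repeat=rep, **vals,
                            ))
                        if write_images and outdir is not None:
                            reference = dyncontrast.moving_std_reference(
                                series, window=min(25, series.n_frames)
                            )
                            display_images.append(
                                dyncontrast.histogram_match(image, reference)
                            )
                except ValidationError as exc:
                    raise ValidationError(
                        f"stage failure at (group={group}, eye={eye}, "
                        f"exposure={exposure}, repeat={rep}): {exc}"
                    ) from exc
                if write_images and outdir is not None and display_images:
                    averaged = dyncontrast.average_repeats(display_images)
                    io_store.write_rgb(
                        averaged, outdir / f"{sample_id}_t{int(exposure):03d}.png"
                    )
                log.info("%s t=%g min done in %.2fs", sample_id, exposure,
                         time.perf_counter() - t0)
    table = io_store.records_to_frame(records)
    if outdir is not None:
        io_store.write_metrics(table, outdir / "metrics_per_repeat.csv")
        agg = aggregate_repeats(table)
        io_store.write_metrics(agg, outdir / "metrics_per_eye_time.csv")
    return table


def aggregate_repeats(table: pd.DataFrame) -> pd.DataFrame:
    """Mean across repeats per (sample, group, exposure, ROI)."""
    keys = ["sample_id", "group", "exposure_min", "roi"]
    agg = (table.groupby(keys, sort=True)[list(METRIC_COLUMNS)]
           .mean().reset_index())
    agg.insert(4, "repeat", None)
    return agg[io_store.METRICS_COLUMNS]


def summarize_groups(table: pd.DataFrame) -> pd.DataFrame:
    """Per-(group, exposure, ROI) mean and sample SD of every metric.

    Cells backed by a single record report SD as missing (no variance
    estimate), not 0.
    """
    if table.empty:
        raise ValidationError("metrics table is empty")
    required = {"group", "exposure_min", "roi", *METRIC_COLUMNS}
    missing = required - set(table.columns)
    if missing:
        raise ValidationError(f"metrics table missing columns {sorted(missing)}")
    grouped = table.groupby(["group", "exposure_min", "roi"], sort=True)
    parts = {}
    for col in METRIC_COLUMNS:
        parts[f"{col}_mean"] = grouped[col].mean()
        parts[f"{col}_sd"] = grouped[col].std(ddof=1)  # NaN for n == 1
    return pd.DataFrame(parts).reset_index()
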