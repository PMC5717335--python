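"""Background-corrected intensity measurement, line profiles and summaries."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates

from kinquant.io import ImageStack
from kinquant.segmentation import KinetochoreRegion, SegmentationParams

logger = logging.getLogger(__name__)

PHASES = ("interphase", "prophase", "prometaphase", "metaphase", "anaphase", "cytokinesis")


@dataclass
class IntensityMeasurement:
    """Per region × channel: annulus background and background-corrected sum.

    ``corrected_sum == raw_sum - background_mean * n_mask_voxels`` exactly;
    negative values are retained (clamping would bias dim conditions).
    """

    label: int
    channel: str
    background_mean: float
    raw_sum: float
    corrected_sum: float
    n_mask_voxels: int
    n_annulus_voxels: int


class EmptyAnnulusError(ValueError):
    pass


def measure_region(
    stack: ImageStack,
    region: KinetochoreRegion,
    channel: str,
    params: SegmentationParams | None = None,
) -> IntensityMeasurement:
    """Measure one region in one channel.

    background_mean = mean of channel values over the annulus;
    corrected_sum = Σ_mask(value) − background_mean × |mask|.
    """
    params = params or SegmentationParams()
    if region.annulus_mask is None or not region.annulus_mask.any():
        raise EmptyAnnulusError(f"region {region.label}: empty background annulus")
    img = np.asarray(stack.channel(channel), dtype=np.float64)[region.roi.slices]
    mask = region.measurement_mask(params)
    background_mean = float(img[region.annulus_mask].mean())
    raw_sum = float(img[mask].sum())
    n_mask = int(mask.sum())
    return IntensityMeasurement(
        label=region.label,
        channel=channel,
        background_mean=background_mean,
        raw_sum=raw_sum,
        corrected_sum=raw_sum - background_mean * n_mask,
        n_mask_voxels=n_mask,
        n_annulus_voxels=int(region.annulus_mask.sum()),
    )


def measure_cell(
    stack: ImageStack,
    regions: list[KinetochoreRegion],
    channels: list[str],
    params: SegmentationParams | None = None,
) -> list[IntensityMeasurement]:
    """Measure every non-flagged region in every requested channel."""
    out = []
    for region in regions:
        if region.flagged:
            logger.info("skipping flagged region %d (%s)", region.label, region.flag_reason)
            continue
        for ch in channels:
            out.append(measure_region(stack, region, ch, params))
    return out


def line_profile(
    stack: ImageStack,
    p0: tuple[float, float, float],
    p1: tuple[float, float, float],
    channels: list[str],
    n_samples: int = 50,
    normalize: bool = False,
) -> pd.DataFrame:
    """Trilinear-interpolated intensity along the segment p0→p1 (voxel coords).

    Returns a frame with ``distance_um`` plus one column per channel.  With
    ``normalize=True`` each channel is min-max scaled for co-plotting.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    shape = np.asarray(stack.data.shape[1:])
    for p in (p0, p1):
        if np.any(p < 0) or np.any(p > shape - 1):
            raise ValueError(f"endpoint {tuple(p)} outside grid of shape {tuple(shape)}")
    t = np.linspace(0.0, 1.0, n_samples)
    pts = p0[None, :] + t[:, None] * (p1 - p0)[None, :]
    phys = (p1 - p0) * np.asarray(stack.voxel_size)
    dist = t * float(np.linalg.norm(phys))
    out = {"distance_um": dist}
    for ch in channels:
        vals = map_coordinates(
            np.asarray(stack.channel(ch), dtype=np.float64), pts.T, order=1, mode="nearest"
        )
        if normalize:
            lo, hi = vals.min(), vals.max()
            vals = (vals - lo) / (hi - lo) if hi > lo else np.zeros_like(vals)
        out[ch] = vals
    return pd.DataFrame(out)


@dataclass
class CellRecord:
    """Per-cell aggregation of kinetochore measurements."""

    cell_id: str
    condition: str = ""
    phase: str = ""
    measurements: list[IntensityMeasurement] = field(default_factory=list)
    summary_per_channel: dict[str, float] = field(default_factory=dict)
    n_regions_per_channel: dict[str, int] = field(default_factory=dict)
    flagged: bool = False

    def __post_init__(self) -> None:
        if self.phase and self.phase not in PHASES:
            raise ValueError(f"unknown phase {self.phase!r}; expected one of {PHASES}")


def summarize_cell(
    cell_id: str,
    measurements: list[IntensityMeasurement],
    condition: str = "",
    phase: str = "",
    method: str = "mean",
) -> CellRecord:
    """Aggregate corrected sums per channel with the mean (default) or median."""
    if method not in ("mean", "median"):
        raise ValueError("method must be 'mean' or 'median'")
    record = CellRecord(cell_id=cell_id, condition=condition, phase=phase, measurements=measurements)
    by_channel: dict[str, list[float]] = {}
    for m in measurements:
        by_channel.setdefault(m.channel, []).append(m.corrected_sum)
    if not by_channel:
        record.flagged = True
        logger.warning("cell %s: zero valid regions; flagged", cell_id)
        return record
    agg = np.mean if method == "mean" else np.median
    for ch, vals in by_channel.items():
        record.summary_per_channel[ch] = float(agg(vals))
        record.n_regions_per_channel[ch] = len(vals)
    return record


def normalize_to_reference(records: list[CellRecord], reference_condition: str) -> list[CellRecord]:
    """Divide every per-cell summary by the reference group's channel mean.

    The reference group's mean maps to 1.0 per channel.  Raises if the
    reference group is empty or a reference mean is not strictly positive.
    """
    ref = [r for r in records if r.condition == reference_condition and not r.flagged]
    if not ref:
        raise ValueError(f"reference condition {reference_condition!r} has no valid cells")
    channels = sorted({ch for r in ref for ch in r.summary_per_channel})
    ref_mean = {}
    for ch in channels:
        vals = [r.summary_per_channel[ch] for r in ref if ch in r.summary_per_channel]
        mean = float(np.mean(vals))
        if mean <= 0:
            raise ValueError(f"reference mean for channel {ch!r} is {mean}; cannot normalize")
        ref_mean[ch] = mean
    out = []
    for r in records:
        scaled = {ch: v / ref_mean[ch] for ch, v in r.summary_per_channel.items() if ch in ref_mean}
        out.append(
            CellRecord(
                cell_id=r.cell_id,
                condition=r.condition,
                phase=r.phase,
                measurements=r.measurements,
                summary_per_channel=scaled,
                n_regions_per_channel=dict(r.n_regions_per_channel),
                flagged=r.flagged,
            )
        )
    return out


def measurements_frame(cell_id: str, measurements: list[IntensityMeasurement]) -> pd.DataFrame:
    """Per-kinetochore rows in the documented CSV schema."""
    return pd.DataFrame(
        [
            {
                "cell_id": cell_id,
                "label": m.label,
                "channel": m.channel,
                "background_mean": m.background_mean,
                "raw_sum": m.raw_sum,
                "corrected_sum": m.corrected_sum,
                "n_mask_voxels": m.n_mask_voxels,
                "n_annulus_voxels": m.n_annulus_voxels,
            }
            for m in measurements
        ]
    )


def cells_frame(records: list[CellRecord]) -> pd.DataFrame:
    """Per-cell rows (one row per channel) in the documented CSV schema."""
    rows = []
    for r in records:
        for ch, v in r.summary_per_channel.items():
            rows.append(
                {
                    "cell_id": r.cell_id,
                    "condition": r.condition,
                    "phase": r.phase,
                    "channel": ch,
                    "summary": v,
                    "n_regions": r.n_regions_per_channel.get(ch, 0),
                }
            )
    from kinquant.io import CELL_COLUMNS

    return pd.DataFrame(rows, columns=CELL_COLUMNS)
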