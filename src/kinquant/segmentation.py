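"""Kinetochore segmentation chain.

Pipeline: cuboid ROI around the DAPI foreground → Otsu threshold on the
reference (ACA) channel in 3D → connected components → minimum-size filter →
in-plane mask expansion (outer kinetochore) → background annulus with a gap.

Masks and dilations act in-plane (2D per z-slice) by default because the
stated radii are xy-pixel quantities while z-spacing is 2.5× coarser; a flag
enables isotropic-in-voxels 3D dilation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import ball, disk

from kinquant.io import ImageStack

logger = logging.getLogger(__name__)

REFERENCE_CHANNEL = "ACA"
DAPI_CHANNEL = "DAPI"


@dataclass
class SegmentationParams:
    min_object_voxels: int = 70
    expand_radius_px: int = 4
    annulus_gap_px: int = 1
    annulus_width_px: int = 2
    connectivity: int = 26  # one of 6, 18, 26
    roi_padding_px: int = 2
    dilate_3d: bool = False
    annulus_around_core: bool = False  # default: annulus surrounds the expanded mask
    measure_core_mask: bool = False  # default: measure within the expanded mask

    def __post_init__(self) -> None:
        if self.min_object_voxels < 1:
            raise ValueError("min_object_voxels must be >= 1")
        for name in ("expand_radius_px", "annulus_gap_px", "annulus_width_px", "roi_padding_px"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")


@dataclass
class ROI:
    """Axis-aligned cuboid, half-open bounds in (z, y, x)."""

    bounds: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]

    @property
    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(lo, hi) for lo, hi in self.bounds)

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(hi - lo for lo, hi in self.bounds)

    @property
    def offset(self) -> tuple[int, int, int]:
        return tuple(lo for lo, _ in self.bounds)


@dataclass
class KinetochoreRegion:
    """One segmented kinetochore object, masks in ROI-local coordinates."""

    label: int
    core_mask: np.ndarray  # bool, ROI-shaped
    expanded_mask: np.ndarray
    annulus_mask: np.ndarray | None
    roi: ROI
    centroid: tuple[float, float, float]  # global (z, y, x), unweighted voxel mean
    flagged: bool = False
    flag_reason: str = ""

    @property
    def voxel_count(self) -> int:
        return int(self.core_mask.sum())

    def measurement_mask(self, params: SegmentationParams) -> np.ndarray:
        return self.core_mask if params.measure_core_mask else self.expanded_mask


class EmptyForegroundError(ValueError):
    pass


def otsu_threshold(values: np.ndarray, nbins: int = 256) -> float:
    """Otsu's threshold over an ``nbins``-bin histogram of the sample.

    Returns the bin edge maximizing between-class variance; foreground is
    defined as values strictly greater than the threshold.  Ties are broken
    toward the lowest qualifying threshold.  Raises on constant input.
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    vmin, vmax = float(values.min()), float(values.max())
    if vmin == vmax:
        raise ValueError("Otsu threshold undefined for constant input")
    counts, edges = np.histogram(values, bins=nbins, range=(vmin, vmax))
    counts = counts.astype(np.float64)
    centers = 0.5 * (edges[:-1] + edges[1:])

    w0 = np.cumsum(counts)
    w1 = w0[-1] - w0
    m = np.cumsum(counts * centers)
    total_mean = m[-1]
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = m / w0
        mu1 = (total_mean - m) / w1
        between = w0 * w1 * (mu0 - mu1) ** 2
    between[~np.isfinite(between)] = -np.inf
    # candidate threshold after bin k is edges[k + 1]; last edge has empty foreground
    k = int(np.argmax(between[:-1]))
    return float(edges[k + 1])


def crop_dapi_roi(stack: ImageStack, params: SegmentationParams) -> ROI:
    """Cuboid bounding box of the Otsu-thresholded DAPI foreground, padded and clipped."""
    dapi = stack.channel(DAPI_CHANNEL)
    try:
        thr = otsu_threshold(dapi)
    except ValueError as exc:
        raise EmptyForegroundError("no nucleus detected: constant DAPI channel") from exc
    fg = dapi > thr
    if not fg.any():
        raise EmptyForegroundError("no nucleus detected: empty DAPI foreground")
    pad = params.roi_padding_px
    bounds = []
    for axis, n in enumerate(fg.shape):
        proj = np.any(fg, axis=tuple(a for a in range(3) if a != axis))
        idx = np.flatnonzero(proj)
        bounds.append((max(0, int(idx[0]) - pad), min(n, int(idx[-1]) + 1 + pad)))
    return ROI(bounds=tuple(bounds))


_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def _disk_footprint(radius: int, dilate_3d: bool) -> np.ndarray:
    if radius == 0:
        return np.ones((1, 1, 1), dtype=bool)
    if dilate_3d:
        return ball(radius).astype(bool)
    return disk(radius).astype(bool)[None, :, :]  # in-plane: no dilation across z


def expand_mask(core_mask: np.ndarray, expand_radius_px: int, dilate_3d: bool = False) -> np.ndarray:
    """Morphological dilation of the core mask by a Euclidean disk, per z-plane.

    Radius r includes lattice offsets with dy² + dx² ≤ r² (49 voxels for r=4).
    Output is clipped to the mask's own array bounds.
    """
    if expand_radius_px == 0:
        return core_mask.copy()
    return ndimage.binary_dilation(core_mask, structure=_disk_footprint(expand_radius_px, dilate_3d))


def build_annulus(
    base_mask: np.ndarray,
    exclusion_mask: np.ndarray,
    gap_px: int,
    width_px: int,
    dilate_3d: bool = False,
) -> np.ndarray:
    """Background annulus: ring of ``width_px`` at a ``gap_px`` offset from ``base_mask``.

    ``exclusion_mask`` (the union of every region's measurement mask) is
    removed so neighbouring kinetochores never contaminate the background.
    Returns a boolean mask; may be empty (caller decides how to flag).
    """
    outer = ndimage.binary_dilation(base_mask, structure=_disk_footprint(gap_px + width_px, dilate_3d))
    if gap_px > 0:
        inner = ndimage.binary_dilation(base_mask, structure=_disk_footprint(gap_px, dilate_3d))
    else:
        inner = base_mask
    return outer & ~inner & ~exclusion_mask


def segment_kinetochores(
    stack: ImageStack,
    roi: ROI,
    params: SegmentationParams,
    reference_channel: str = REFERENCE_CHANNEL,
) -> list[KinetochoreRegion]:
    """Segment reference-channel objects within the ROI.

    Otsu threshold on the ROI-restricted histogram, connected components at
    the configured connectivity, size filter at ``min_object_voxels``; labels
    are assigned in deterministic scan order; centroids are unweighted voxel
    means in global coordinates.  Regions whose annulus ends up empty after
    exclusions are flagged (not dropped from the list).
    """
    ref = stack.channel(reference_channel)[roi.slices]
    try:
        thr = otsu_threshold(ref)
    except ValueError:
        logger.warning("constant reference channel in ROI; no objects")
        return []
    binary = ref > thr
    labels, n = ndimage.label(binary, structure=_STRUCTURES[params.connectivity])
    if n == 0:
        logger.info("no objects above Otsu threshold %.3f", thr)
        return []
    counts = np.bincount(labels.ravel())[1:]
    keep = np.flatnonzero(counts >= params.min_object_voxels) + 1
    if keep.size == 0:
        logger.info("all %d objects below min size %d", n, params.min_object_voxels)
        return []

    offset = np.asarray(roi.offset, dtype=float)
    regions: list[KinetochoreRegion] = []
    for new_label, old in enumerate(keep, start=1):
        core = labels == old
        expanded = expand_mask(core, params.expand_radius_px, params.dilate_3d)
        com = ndimage.center_of_mass(core)
        regions.append(
            KinetochoreRegion(
                label=new_label,
                core_mask=core,
                expanded_mask=expanded,
                annulus_mask=None,
                roi=roi,
                centroid=tuple(float(c) for c in (np.asarray(com) + offset)),
            )
        )

    exclusion = np.zeros(roi.shape, dtype=bool)
    for r in regions:
        exclusion |= r.expanded_mask
    for r in regions:
        base = r.core_mask if params.annulus_around_core else r.expanded_mask
        ann = build_annulus(base, exclusion, params.annulus_gap_px, params.annulus_width_px, params.dilate_3d)
        r.annulus_mask = ann
        if not ann.any():
            r.flagged = True
            r.flag_reason = "empty background annulus"
            logger.warning("region %d flagged: empty annulus after exclusions", r.label)
    return regions
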