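"""Image-stack and results-table I/O.

Stacks are multi-channel 3D voxel grids stored as multi-page TIFF with a JSON
ImageDescription carrying channel names and voxel size.  Axis order is always
``(channel, z, y, x)`` in memory regardless of on-disk page layout.

Coordinates in all outputs are 0-based voxel indices in ``(z, y, x)`` order;
physical sizes are micrometres.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

_METADATA_KEY = "kinquant"


@dataclass
class ImageStack:
    """A multi-channel 3D image with physical voxel sizes.

    Parameters
    ----------
    data
        4-D array ordered ``(channel, z, y, x)``; non-negative counts.
    channel_names
        One name per channel, e.g. ``["DAPI", "ACA", "target"]``.
    voxel_size
        ``(dz, dy, dx)`` in micrometres.  Pixels must be square (dy == dx).
    """

    data: np.ndarray
    channel_names: list[str] = field(default_factory=list)
    voxel_size: tuple[float, float, float] = (0.2, 0.08, 0.08)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"stack data must be 4-D (c, z, y, x), got ndim={self.data.ndim}")
        self.channel_names = list(self.channel_names)
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for {self.data.shape[0]} channels"
            )
        dz, dy, dx = (float(v) for v in self.voxel_size)
        if not (dz > 0 and dy > 0 and dx > 0):
            raise ValueError(f"voxel_size must be strictly positive, got {self.voxel_size}")
        if not np.isclose(dy, dx):
            raise ValueError(f"non-square pixels are not supported (dy={dy}, dx={dx})")
        self.voxel_size = (dz, dy, dx)

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.data.shape

    def channel(self, name: str) -> np.ndarray:
        """Return the ``(z, y, x)`` array for a named channel."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in {self.channel_names}") from None
        return self.data[idx]

    def has_channel(self, name: str) -> bool:
        return name in self.channel_names


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write a stack as multi-page TIFF (pages ordered channel-major, then z)."""
    path = Path(path)
    tifffile.imwrite(
        path,
        stack.data,
        photometric="minisblack",
        metadata={
            _METADATA_KEY: {
                "axes": "CZYX",
                "channel_names": stack.channel_names,
                "voxel_size_um": list(stack.voxel_size),
            }
        },
    )
    return path


def read_stack(
    path: str | Path,
    channel_names: list[str] | None = None,
    voxel_size: tuple[float, float, float] | None = None,
) -> ImageStack:
    """Read a TIFF stack, normalizing axis order to ``(c, z, y, x)``.

    Metadata written by :func:`write_stack` is honoured; for foreign TIFFs the
    caller must supply ``channel_names`` and ``voxel_size``.  Supplying an
    override that conflicts with stored metadata is an error.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        shaped = tif.shaped_metadata
    meta = {}
    if shaped:
        meta = shaped[0].get(_METADATA_KEY, {})
        if isinstance(meta, str):  # tifffile may round-trip nested dicts as JSON text
            try:
                meta = json.loads(meta.replace("'", '"'))
            except json.JSONDecodeError:
                meta = {}

    stored_names = meta.get("channel_names")
    stored_vs = meta.get("voxel_size_um")
    if channel_names is not None and stored_names is not None and list(channel_names) != list(stored_names):
        raise ValueError(
            f"channel_names override {list(channel_names)} conflicts with stored {stored_names}"
        )
    if voxel_size is not None and stored_vs is not None and not np.allclose(voxel_size, stored_vs):
        raise ValueError(f"voxel_size override {voxel_size} conflicts with stored {stored_vs}")
    names = channel_names if channel_names is not None else stored_names
    vs = voxel_size if voxel_size is not None else stored_vs
    if vs is None:
        raise ValueError(f"{path}: no voxel size in metadata; pass voxel_size=")

    if data.ndim == 3:
        # single channel stored as (z, y, x)
        data = data[None]
    if data.ndim != 4:
        raise ValueError(f"{path}: cannot interpret array of ndim {data.ndim} as (c, z, y, x)")
    if names is None:
        names = [f"ch{i}" for i in range(data.shape[0])]
    return ImageStack(data=data, channel_names=list(names), voxel_size=tuple(vs))


# ---------------------------------------------------------------------------
# Results tables

RESULTS_SCHEMA_VERSION = 1

#: per-kinetochore measurement rows
REGION_COLUMNS = [
    "cell_id",
    "label",
    "channel",
    "background_mean",
    "raw_sum",
    "corrected_sum",
    "n_mask_voxels",
    "n_annulus_voxels",
]

#: per-cell summary rows
CELL_COLUMNS = [
    "cell_id",
    "condition",
    "phase",
    "channel",
    "summary",
    "n_regions",
]


def write_results_table(rows: pd.DataFrame, path: str | Path, columns: list[str]) -> Path:
    """Write result rows as RFC-4180 CSV with a fixed, versioned column order."""
    path = Path(path)
    missing = [c for c in columns if c not in rows.columns]
    if missing:
        raise ValueError(f"result rows missing required columns: {missing}")
    extra = [c for c in rows.columns if c not in columns]
    rows[columns + extra].to_csv(path, index=False)
    return path


def read_results_table(path: str | Path, columns: list[str]) -> pd.DataFrame:
    """Read a results CSV, verifying the declared schema columns are present."""
    df = pd.read_csv(path)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns: {missing}")
    return df
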