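"""Ground-truthed synthetic inputs.

Two generators:

* :func:`simulate_cell_stack` — a multi-channel 3D stack containing a nuclear
  (DAPI) ellipsoid and sister-pair spots rendered as anisotropic 3D Gaussians.
  Each voxel receives the Gaussian density *integrated over the voxel* so that
  the infinite-domain sum of a spot equals its amplitude exactly.
* :func:`simulate_lfq_table` — log-normal label-free protein-group intensities
  with a planted bait-enriched set and explicit missing values.

Everything is reproducible bit-for-bit from the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import erf

from kinquant.io import ImageStack

DEFAULT_VOXEL_SIZE = (0.2, 0.08, 0.08)  # µm; 4 px in xy == 0.32 µm


class SpotPlacementError(RuntimeError):
    """Raised when the nuclear region cannot host the requested pairs."""


@dataclass
class SpotGroundTruth:
    """One simulated kinetochore spot."""

    spot_id: int
    pair_id: int
    center: tuple[float, float, float]  # (z, y, x) continuous voxel coords
    amplitude_per_channel: dict[str, float]
    sigma_xy: float  # µm
    sigma_z: float  # µm

    def __post_init__(self) -> None:
        if any(a < 0 for a in self.amplitude_per_channel.values()):
            raise ValueError("amplitudes must be >= 0")
        if self.sigma_xy <= 0 or self.sigma_z <= 0:
            raise ValueError("sigmas must be > 0")


@dataclass
class SimImageParams:
    """Geometry, signal and noise parameters for one synthetic cell stack."""

    grid_dims: tuple[int, int, int] = (20, 96, 96)  # (nz, ny, nx)
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE
    channels: tuple[str, ...] = ("DAPI", "ACA", "target")
    n_pairs: int = 4
    pair_separation_um: float = 1.0
    min_pair_distance_um: float = 1.5
    sigma_xy_um: float = 0.10
    sigma_z_um: float = 0.30
    amplitude_mean: dict[str, float] = field(
        default_factory=lambda: {"ACA": 20000.0, "target": 20000.0}
    )
    amplitude_cv: float = 0.2
    background_level: float | dict[str, float] = 100.0
    dapi_level: float = 500.0
    read_noise_sd: float = 2.0
    shot_noise: bool = True
    nuclear_center_um: tuple[float, float, float] | None = None  # default: grid centre
    nuclear_semiaxes_um: tuple[float, float, float] = (1.5, 3.0, 3.0)
    seed: int = 0

    def __post_init__(self) -> None:
        nz, ny, nx = self.grid_dims
        if min(nz, ny, nx) < 1:
            raise ValueError("grid_dims must be positive")
        if min(self.voxel_size) <= 0:
            raise ValueError("voxel_size must be positive")
        if self.n_pairs < 0:
            raise ValueError("n_pairs must be >= 0")
        if "DAPI" not in self.channels or "ACA" not in self.channels:
            raise ValueError("channels must include 'DAPI' and 'ACA'")
        if len(self.channels) < 3:
            raise ValueError("need at least one measurement channel besides DAPI and ACA")
        center = self.nuclear_center_um
        if center is None:
            center = tuple(0.5 * n * v for n, v in zip(self.grid_dims, self.voxel_size))
            self.nuclear_center_um = center
        extent = tuple(n * v for n, v in zip(self.grid_dims, self.voxel_size))
        for c, a, e in zip(center, self.nuclear_semiaxes_um, extent):
            if c - a < 0 or c + a > e:
                raise ValueError("nuclear ellipsoid does not fit inside the grid")

    def background_of(self, channel: str) -> float:
        if isinstance(self.background_level, dict):
            return float(self.background_level.get(channel, 0.0))
        return float(self.background_level)

    @property
    def measurement_channels(self) -> list[str]:
        return [c for c in self.channels if c not in ("DAPI",)]


def _axis_integrals(n: int, center: float, sigma_vox: float) -> tuple[np.ndarray, int]:
    """Per-voxel integral of a unit 1D Gaussian along one axis.

    Voxel ``i`` spans ``[i - 0.5, i + 0.5]`` in voxel units.  Returns the
    integral for voxels in a ±6σ window and the window start index.
    """
    half = max(2, int(math.ceil(6.0 * sigma_vox)))
    lo = max(0, int(math.floor(center)) - half)
    hi = min(n, int(math.ceil(center)) + half + 1)
    idx = np.arange(lo, hi)
    s = sigma_vox * math.sqrt(2.0)
    vals = 0.5 * (erf((idx + 0.5 - center) / s) - erf((idx - 0.5 - center) / s))
    return vals, lo


def render_spot(
    image: np.ndarray,
    center: tuple[float, float, float],
    amplitude: float,
    sigma_vox: tuple[float, float, float],
) -> None:
    """Add one voxel-integrated anisotropic Gaussian spot to ``image`` in place."""
    nz, ny, nx = image.shape
    gz, z0 = _axis_integrals(nz, center[0], sigma_vox[0])
    gy, y0 = _axis_integrals(ny, center[1], sigma_vox[1])
    gx, x0 = _axis_integrals(nx, center[2], sigma_vox[2])
    block = amplitude * gz[:, None, None] * gy[None, :, None] * gx[None, None, :]
    image[z0 : z0 + len(gz), y0 : y0 + len(gy), x0 : x0 + len(gx)] += block


def _inside_ellipsoid(p_um: np.ndarray, center: np.ndarray, semi: np.ndarray) -> bool:
    return float(np.sum(((p_um - center) / semi) ** 2)) <= 1.0


def _place_pairs(params: SimImageParams, rng: np.random.Generator) -> list[np.ndarray]:
    """Sample pair centres and orientations; returns flat list of spot positions (µm).

    Spots come in consecutive pairs (2k, 2k+1).  Pair centres keep at least
    ``min_pair_distance_um`` from each other; both members must lie inside the
    nuclear ellipsoid.
    """
    center = np.asarray(params.nuclear_center_um, dtype=float)
    semi = np.asarray(params.nuclear_semiaxes_um, dtype=float)
    half_sep = 0.5 * params.pair_separation_um
    pair_centers: list[np.ndarray] = []
    positions: list[np.ndarray] = []
    max_tries = 2000
    for _ in range(params.n_pairs):
        for attempt in range(max_tries):
            # rejection-sample a point in the ellipsoid
            u = rng.uniform(-1.0, 1.0, size=3)
            if float(np.sum(u * u)) > 1.0:
                continue
            pc = center + u * semi
            if any(np.linalg.norm(pc - q) < params.min_pair_distance_um for q in pair_centers):
                continue
            # random 3D orientation
            v = rng.normal(size=3)
            v /= np.linalg.norm(v)
            a, b = pc + half_sep * v, pc - half_sep * v
            if _inside_ellipsoid(a, center, semi) and _inside_ellipsoid(b, center, semi):
                pair_centers.append(pc)
                positions.extend([a, b])
                break
        else:
            raise SpotPlacementError(
                f"could not place pair {len(pair_centers) + 1}/{params.n_pairs} "
                f"after {max_tries} attempts; nuclear region too small"
            )
    return positions


def simulate_cell_stack(
    params: SimImageParams,
) -> tuple[ImageStack, list[SpotGroundTruth]]:
    """Generate one synthetic cell stack plus per-spot ground truth.

    The DAPI channel is a smoothed indicator of the nuclear ellipsoid (it only
    needs to exercise ROI cropping).  Every other channel receives the same
    spots at the same centres, with independently drawn amplitudes, on a
    constant background, then shot and read noise.
    """
    rng = np.random.default_rng(params.seed)
    nz, ny, nx = params.grid_dims
    vz, vy, vx = params.voxel_size
    sigma_vox = (params.sigma_z_um / vz, params.sigma_xy_um / vy, params.sigma_xy_um / vx)

    positions_um = _place_pairs(params, rng)
    spots: list[SpotGroundTruth] = []
    for i, p in enumerate(positions_um):
        amps = {}
        for ch in params.measurement_channels:
            mean = params.amplitude_mean.get(ch, 0.0)
            if params.amplitude_cv > 0 and mean > 0:
                # log-normal with the requested mean and coefficient of variation
                s2 = math.log(1.0 + params.amplitude_cv**2)
                amps[ch] = float(rng.lognormal(math.log(mean) - 0.5 * s2, math.sqrt(s2)))
            else:
                amps[ch] = float(mean)
        center_vox = (p[0] / vz - 0.5, p[1] / vy - 0.5, p[2] / vx - 0.5)
        spots.append(
            SpotGroundTruth(
                spot_id=i,
                pair_id=i // 2,
                center=center_vox,
                amplitude_per_channel=amps,
                sigma_xy=params.sigma_xy_um,
                sigma_z=params.sigma_z_um,
            )
        )

    data = np.zeros((len(params.channels), nz, ny, nx), dtype=np.float64)
    # DAPI: smoothed ellipsoid indicator
    zc = (np.arange(nz) + 0.5) * vz
    yc = (np.arange(ny) + 0.5) * vy
    xc = (np.arange(nx) + 0.5) * vx
    cz, cy, cx = params.nuclear_center_um
    az, ay, ax = params.nuclear_semiaxes_um
    ell = (
        ((zc[:, None, None] - cz) / az) ** 2
        + ((yc[None, :, None] - cy) / ay) ** 2
        + ((xc[None, None, :] - cx) / ax) ** 2
    ) <= 1.0
    dapi_idx = params.channels.index("DAPI")
    data[dapi_idx] = params.background_of("DAPI") + params.dapi_level * gaussian_filter(
        ell.astype(np.float64), sigma=1.0
    )

    for ci, ch in enumerate(params.channels):
        if ch == "DAPI":
            continue
        img = data[ci]
        img += params.background_of(ch)
        for spot in spots:
            render_spot(img, spot.center, spot.amplitude_per_channel[ch], sigma_vox)

    if params.shot_noise:
        data = rng.poisson(np.clip(data, 0, None)).astype(np.float64)
    if params.read_noise_sd > 0:
        data = data + rng.normal(0.0, params.read_noise_sd, size=data.shape)
    data = np.clip(data, 0.0, None)

    stack = ImageStack(data=data, channel_names=list(params.channels), voxel_size=params.voxel_size)
    return stack, spots


@dataclass
class CellSim:
    """One simulated cell of a two-group experiment."""

    cell_id: str
    group: str
    stack: ImageStack
    ground_truth: list[SpotGroundTruth]


def simulate_depletion_experiment(
    ctrl: SimImageParams,
    depleted_fraction: float,
    n_cells_per_group: int,
    seed: int,
) -> list[CellSim]:
    """Control vs depleted cells; depletion scales measurement-channel amplitudes.

    Depleted cells are drawn from the control parameter set with every
    measurement-channel amplitude mean (ACA excluded — the reference stain is
    untouched) multiplied by ``1 - depleted_fraction``.  Per-cell seeds are
    spawned deterministically from ``seed``.
    """
    if not 0.0 <= depleted_fraction <= 1.0:
        raise ValueError("depleted_fraction must be in [0, 1]")
    if n_cells_per_group < 1:
        raise ValueError("n_cells_per_group must be >= 1")
    scaled = dict(ctrl.amplitude_mean)
    for ch in scaled:
        if ch != "ACA":
            scaled[ch] = scaled[ch] * (1.0 - depleted_fraction)
    depl = replace(ctrl, amplitude_mean=scaled)

    child_seeds = np.random.SeedSequence(seed).generate_state(2 * n_cells_per_group)
    cells: list[CellSim] = []
    for i in range(n_cells_per_group):
        for group, base in (("control", ctrl), ("depleted", depl)):
            idx = 2 * i + (0 if group == "control" else 1)
            p = replace(base, seed=int(child_seeds[idx]))
            stack, gt = simulate_cell_stack(p)
            cells.append(CellSim(cell_id=f"{group}_{i:03d}", group=group, stack=stack, ground_truth=gt))
    return cells


def ground_truth_frame(spots: list[SpotGroundTruth]) -> pd.DataFrame:
    """Tabulate ground truth (one row per spot, one amplitude column per channel)."""
    channels = sorted({ch for s in spots for ch in s.amplitude_per_channel})
    rows = []
    for s in spots:
        row = {
            "spot_id": s.spot_id,
            "pair_id": s.pair_id,
            "z": s.center[0],
            "y": s.center[1],
            "x": s.center[2],
        }
        for ch in channels:
            row[f"amplitude.{ch}"] = s.amplitude_per_channel.get(ch, 0.0)
        rows.append(row)
    cols = ["spot_id", "pair_id", "z", "y", "x"] + [f"amplitude.{c}" for c in channels]
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# LFQ tables


@dataclass
class SimLfqParams:
    """Parameters for a synthetic label-free protein-group intensity table."""

    n_proteins: int = 1000
    n_replicates_per_group: int = 4
    log2_mean: float = 25.0
    log2_sd: float = 2.0
    enriched_ids: frozenset[str] = frozenset()
    enrichment_log2fc: float = 2.0
    replicate_noise_sd_log2: float = 0.3
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        if self.n_replicates_per_group < 2:
            raise ValueError("n_replicates_per_group must be >= 2")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        self.enriched_ids = frozenset(self.enriched_ids)
        unknown = self.enriched_ids - set(protein_ids(self.n_proteins))
        if unknown:
            raise ValueError(f"enriched_ids not in protein id range: {sorted(unknown)[:5]}")


def protein_ids(n: int) -> list[str]:
    return [f"P{i:05d}" for i in range(n)]


def simulate_lfq_table(params: SimLfqParams) -> pd.DataFrame:
    """Generate an LFQ table: columns ``intensity.<group>.<replicate>``.

    Per protein per replicate, ``log2 intensity = baseline + enrichment (bait
    group of enriched proteins only) + N(0, replicate_noise_sd_log2)``.
    Missing values are NaN, never 0.
    """
    ids = protein_ids(params.n_proteins)
    rng = np.random.default_rng(params.seed)
    n, r = params.n_proteins, params.n_replicates_per_group
    baseline = rng.normal(params.log2_mean, params.log2_sd, size=n)
    enriched = np.array([pid in params.enriched_ids for pid in ids])

    table = {"protein_id": ids, "gene_name": [f"GENE{i:05d}" for i in range(n)]}
    for group in ("bait", "control"):
        shift = params.enrichment_log2fc * enriched if group == "bait" else 0.0
        for rep in range(1, r + 1):
            log2 = baseline + shift + rng.normal(0.0, params.replicate_noise_sd_log2, size=n)
            vals = np.exp2(log2)
            if params.missing_rate > 0:
                vals = np.where(rng.random(n) < params.missing_rate, np.nan, vals)
            table[f"intensity.{group}.{rep}"] = vals
    return pd.DataFrame(table)


def write_lfq_table(table: pd.DataFrame, path: str | Path) -> Path:
    """Write an LFQ table as tab-separated text; missing values are empty fields."""
    path = Path(path)
    table.to_csv(path, sep="\t", index=False)
    return path
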