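"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the code paths of the package: thresholds are scored
from raw sample values, components come from an explicit flood fill, Gaussian
voxel masses come from adaptive quadrature, and rank statistics are computed
from first principles.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import quad
from scipy.stats import norm


def brute_force_otsu(values: np.ndarray, nbins: int = 256) -> float:
    """Exhaustive search over all 256 histogram-split thresholds.

    The criterion is the textbook between-class variance of the binned sample
    (class moments from bin centers), evaluated by explicit per-candidate
    loops rather than cumulative arrays; ties go to the lowest edge.
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    counts, edges = np.histogram(values, bins=nbins, range=(values.min(), values.max()))
    centers = 0.5 * (edges[:-1] + edges[1:])
    best_t, best_score = None, -np.inf
    n = counts.sum()
    for k in range(nbins - 1):  # background = bins 0..k, threshold = edges[k + 1]
        n0 = counts[: k + 1].sum()
        n1 = n - n0
        if n0 == 0 or n1 == 0:
            continue
        mu0 = float(np.dot(counts[: k + 1], centers[: k + 1]) / n0)
        mu1 = float(np.dot(counts[k + 1 :], centers[k + 1 :]) / n1)
        score = (n0 / n) * (n1 / n) * (mu0 - mu1) ** 2
        if score > best_score * (1.0 + 1e-12) or best_t is None:
            best_score, best_t = score, float(edges[k + 1])
    return best_t


_NEIGHBORS = {
    6: [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if abs(dz) + abs(dy) + abs(dx) == 1
    ],
    26: [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ],
}


def flood_fill_label(binary: np.ndarray, connectivity: int = 26) -> np.ndarray:
    """Label connected components by iterative flood fill in raster-scan order."""
    binary = np.asarray(binary, dtype=bool)
    labels = np.zeros(binary.shape, dtype=np.int32)
    offsets = _NEIGHBORS[connectivity]
    nz, ny, nx = binary.shape
    next_label = 0
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                if binary[z, y, x] and labels[z, y, x] == 0:
                    next_label += 1
                    stack = [(z, y, x)]
                    labels[z, y, x] = next_label
                    while stack:
                        cz, cy, cx = stack.pop()
                        for dz, dy, dx in offsets:
                            pz, py, px = cz + dz, cy + dy, cx + dx
                            if 0 <= pz < nz and 0 <= py < ny and 0 <= px < nx:
                                if binary[pz, py, px] and labels[pz, py, px] == 0:
                                    labels[pz, py, px] = next_label
                                    stack.append((pz, py, px))
    return labels


def flood_fill_segment(binary: np.ndarray, min_voxels: int, connectivity: int = 26) -> np.ndarray:
    """Flood-fill labelling followed by the minimum-size filter, relabelled 1..k
    in first-encounter (scan) order."""
    labels = flood_fill_label(binary, connectivity)
    out = np.zeros_like(labels)
    new = 0
    for lab in range(1, labels.max() + 1):
        mask = labels == lab
        if mask.sum() >= min_voxels:
            new += 1
            out[mask] = new
    return out


def gaussian_voxel_mass(
    center: tuple[float, float, float],
    sigma_vox: tuple[float, float, float],
    voxels: np.ndarray,
) -> np.ndarray:
    """Adaptive-quadrature integral of a unit separable 3D Gaussian per voxel.

    ``voxels`` is an (n, 3) integer array of (z, y, x) indices; voxel i spans
    [i - 0.5, i + 0.5] along each axis.  Quadrature of the pdf, independent of
    any closed-form error-function evaluation in the package.
    """
    voxels = np.asarray(voxels)
    cache: dict[tuple[int, int], float] = {}

    def axis_mass(axis: int, idx: int) -> float:
        key = (axis, idx)
        if key not in cache:
            val, _ = quad(
                lambda u: norm.pdf(u, loc=center[axis], scale=sigma_vox[axis]),
                idx - 0.5,
                idx + 0.5,
                epsabs=1e-14,
                epsrel=1e-12,
            )
            cache[key] = val
        return cache[key]

    return np.array(
        [axis_mass(0, int(z)) * axis_mass(1, int(y)) * axis_mass(2, int(x)) for z, y, x in voxels]
    )


def lattice_disk_count(radius: int) -> int:
    """Number of 2D lattice points with dy² + dx² ≤ r²."""
    r = int(radius)
    pts = [(dy, dx) for dy in range(-r, r + 1) for dx in range(-r, r + 1) if dy * dy + dx * dx <= r * r]
    return len(pts)


def kruskal_h(groups: list[np.ndarray]) -> float:
    """H = 12/(N(N+1)) · Σ nᵢ(R̄ᵢ − R̄)², mid-ranks, no tie correction."""
    pooled = np.concatenate(groups)
    order = np.argsort(pooled, kind="stable")
    ranks = np.empty(len(pooled))
    sorted_vals = pooled[order]
    i = 0
    pos = 1.0
    while i < len(sorted_vals):
        j = i
        while j < len(sorted_vals) and sorted_vals[j] == sorted_vals[i]:
            j += 1
        ranks[order[i:j]] = (pos + (pos + (j - i) - 1)) / 2.0
        pos += j - i
        i = j
    n_total = len(pooled)
    grand = ranks.mean()
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start : start + len(g)]
        h += len(g) * (r.mean() - grand) ** 2
        start += len(g)
    return 12.0 / (n_total * (n_total + 1)) * h


def pooled_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Closed-form pooled-variance two-sample t and two-tailed p."""
    from scipy.stats import t as tdist

    a = np.asarray(a, float)
    b = np.asarray(b, float)
    n1, n2 = len(a), len(b)
    sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    p = 2 * tdist.sf(abs(t), n1 + n2 - 2)
    return float(t), float(p)
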