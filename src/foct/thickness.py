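"""ILM/RPE surface extraction and macular thickness mapping.

Surfaces are found per B-scan by dynamic programming: for each lateral
position the surface picks one depth, neighbouring depths may differ by at
most a hard smoothness bound, and the minimum-cost path is taken. The ILM
cost rewards a strong positive-going axial gradient (dark vitreous to bright
retina); the RPE cost rewards the brightest band below the ILM. Surfaces are
then median-filtered across B-scans and the ILM < RPE ordering is enforced.
Retinal thickness (RT) is the ILM-RPE separation converted to micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .io import OctVolume

__all__ = [
    "SurfacePair",
    "ThicknessMap",
    "extract_surfaces",
    "thickness_from_surfaces",
    "aggregate_rt",
]


@dataclass
class SurfacePair:
    """ILM and RPE depth maps (voxel units) on the en-face grid."""

    ilm_depth: np.ndarray
    rpe_depth: np.ndarray
    smoothness_used: int = 2

    def __post_init__(self):
        self.ilm_depth = np.asarray(self.ilm_depth, dtype=float)
        self.rpe_depth = np.asarray(self.rpe_depth, dtype=float)
        if self.ilm_depth.shape != self.rpe_depth.shape:
            raise ValueError("surface maps must share a shape")
        if not np.all(self.ilm_depth < self.rpe_depth):
            raise ValueError("ILM must lie strictly above RPE everywhere")
        # hard smoothness bound along the fast (within-B-scan) axis
        for name, surf in (("ilm", self.ilm_depth), ("rpe", self.rpe_depth)):
            step = np.abs(np.diff(surf, axis=0)).max() if surf.shape[0] > 1 else 0
            if step > self.smoothness_used + 1e-9:
                raise ValueError(
                    f"{name} surface violates the smoothness bound ({step} > "
                    f"{self.smoothness_used})")


@dataclass
class ThicknessMap:
    """Pointwise retinal thickness in micrometres and its regional mean."""

    data: np.ndarray
    mean_rt_um: float
    region: np.ndarray = field(default=None)  # analysis mask; None = full area

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if np.any(self.data < 0):
            raise ValueError("thickness cannot be negative")
        region = self.region if self.region is not None else np.ones_like(self.data, bool)
        expected = float(self.data[region].mean())
        if abs(self.mean_rt_um - expected) > 1e-9:
            raise ValueError("mean_rt_um inconsistent with map/region")


def _dp_path(cost: np.ndarray, smoothness: int) -> np.ndarray:
    """Minimum-cost monotone-in-x path through a (n_x, n_depth) cost image
    with |z(x+1) - z(x)| <= smoothness. Returns depth indices per x."""
    nx, nz = cost.shape
    size = 2 * smoothness + 1
    acc = cost[0].copy()
    steps = np.empty((nx, nz), dtype=np.int32)
    offsets = np.arange(-smoothness, smoothness + 1)
    for x in range(1, nx):
        # windowed minimum of acc and the achieving offset
        window = np.full((size, nz), np.inf)
        for j, off in enumerate(offsets):
            src = np.roll(acc, off)
            if off > 0:
                src[:off] = np.inf
            elif off < 0:
                src[off:] = np.inf
            window[j] = src
        j_best = np.argmin(window, axis=0)
        acc = window[j_best, np.arange(nz)] + cost[x]
        steps[x] = offsets[j_best]
    if not np.isfinite(acc).any():
        raise ValueError("no feasible surface path")
    path = np.empty(nx, dtype=np.int32)
    path[-1] = int(np.argmin(acc))
    for x in range(nx - 1, 0, -1):
        path[x - 1] = path[x] - steps[x, path[x]]
    return path


def extract_surfaces(volume: OctVolume, smoothness: int = 2,
                     median_size: int = 3) -> SurfacePair:
    """Extract ILM and RPE depth maps from a volume.

    ``smoothness`` is the maximum allowed depth step (voxels) between
    neighbouring lateral positions within a B-scan. Raises an error naming
    the B-scan if no feasible path exists.
    """
    data = volume.data
    nx, ny, nz = data.shape
    ilm = np.empty((nx, ny))
    rpe = np.empty((nx, ny))
    margin_vox = max(2, int(100.0 / volume.spacing_um[2]))
    for y in range(ny):
        bscan = data[:, y, :].astype(np.float64)
        grad = np.gradient(bscan, axis=1)
        # ILM: strong dark-to-bright transition with darkness above it
        cum = np.cumsum(bscan, axis=1)
        above_mean = np.zeros_like(bscan)
        above_mean[:, 1:] = cum[:, :-1] / np.arange(1, nz)[None, :]
        try:
            ilm_path = _dp_path(-np.maximum(grad, 0.0) + above_mean, smoothness)
        except ValueError as exc:
            raise ValueError(f"B-scan {y}: {exc} (ILM)") from exc
        # RPE: bright-to-dark exit edge of the outer bright band, below ILM
        cost_rpe = -np.maximum(-grad, 0.0)
        z = np.arange(nz)[None, :]
        cost_rpe[z < (ilm_path[:, None] + margin_vox)] = np.inf
        # keep at least one feasible depth per column
        cost_rpe[:, -1] = np.where(np.isinf(cost_rpe[:, -1]), 0.0, cost_rpe[:, -1])
        try:
            rpe_path = _dp_path(cost_rpe, smoothness)
        except ValueError as exc:
            raise ValueError(f"B-scan {y}: {exc} (RPE)") from exc
        ilm[:, y] = ilm_path
        rpe[:, y] = rpe_path
    if ny >= median_size:
        ilm = ndimage.median_filter(ilm, size=(1, median_size), mode="nearest")
        rpe = ndimage.median_filter(rpe, size=(1, median_size), mode="nearest")
    rpe = np.maximum(rpe, ilm + 1)  # enforce ordering
    return SurfacePair(ilm, rpe, smoothness)


def thickness_from_surfaces(surfaces: SurfacePair, spacing_um,
                            region: np.ndarray | None = None) -> ThicknessMap:
    """Pointwise (RPE - ILM) x axial spacing; mean over the analysis region
    (full scan area by default, a circular ETDRS-style region by mask)."""
    axial = spacing_um[2] if len(spacing_um) == 3 else float(spacing_um)
    data = (surfaces.rpe_depth - surfaces.ilm_depth) * axial
    mask = region if region is not None else np.ones_like(data, bool)
    return ThicknessMap(data, float(data[mask].mean()), region)


def circular_region(shape, spacing_um, radius_mm=3.0) -> np.ndarray:
    """Fovea-centred circular analysis mask (ETDRS-style)."""
    nx, ny = shape
    x = (np.arange(nx) - (nx - 1) / 2) * spacing_um[0] / 1000.0
    y = (np.arange(ny) - (ny - 1) / 2) * spacing_um[1] / 1000.0
    return (x[:, None] ** 2 + y[None, :] ** 2) <= radius_mm**2


def aggregate_rt(maps: Sequence[ThicknessMap], qualities: Sequence[float],
                 k: int = 3) -> float:
    """Mean RT (um) over the top-k maps by quality; ties break toward the
    earlier acquisition."""
    if len(maps) == 0:
        raise ValueError("no thickness maps to aggregate")
    if len(maps) != len(qualities):
        raise ValueError("one quality per map required")
    order = sorted(range(len(maps)), key=lambda i: (-qualities[i], i))
    top = order[: min(k, len(order))]
    return float(np.mean([maps[i].mean_rt_um for i in top]))
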