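"""Synthetic macular OCT volumes and physiology cohorts with known ground truth.

The generator emulates a 6 mm x 6 mm x 2 mm spectral-domain macular cube
(full resolution 512 x 128 x 1024; default half-scale depth/fast grid for
speed): a bright retinal slab bounded by two smooth surfaces (ILM above, a
thin bright RPE band below), a branching superficial vessel network just
below the ILM, multiplicative speckle, a rank-<=2 additive band-artifact
field, and circular Gaussian blobs standing in for projection artifacts.
Every stochastic element derives from an explicit seed, so a fixed seed
reproduces the volume bit for bit, and the planted vessel mask, surfaces and
vessel area fraction are returned as ground truth.

The cohort generator emulates a high-altitude sojourn: arterial blood gases
and cardiorespiratory variables measured at low altitude (day 0) and on days
2 and 9 at 3,800 m, with subject-level random intercepts, plus a planted
within-subject linear dependence of retinal vessel area fraction on PaO2.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import DEFAULT_EXTENT_MM, OctVolume, spacing_from_grid

__all__ = [
    "SceneParams",
    "SyntheticTruth",
    "CohortParams",
    "TABLE1_MEANS",
    "TABLE1_SDS",
    "generate_volume",
    "generate_cohort",
]


@dataclass(frozen=True)
class SceneParams:
    """Parameters of one synthetic macular scan.

    ``grid_shape`` defaults to 256 x 128 x 512 (half the acquisition
    resolution along x and z) for test speed; the full 512 x 128 x 1024 grid
    is available by configuration. ``extent_mm`` stays at the physical scan
    size so voxel spacing scales with the grid.
    """

    grid_shape: tuple = (256, 128, 512)
    extent_mm: tuple = DEFAULT_EXTENT_MM
    surface_smoothness_mm: float = 1.5       # correlation length of surface fields
    surface_amplitude_um: float = 25.0       # RMS height of surface undulation
    ilm_depth_um: float = 500.0              # mean ILM depth below the top of the frame
    mean_thickness_um: float = 300.0         # target ILM-RPE separation
    vessel_count: int = 3
    vessel_radius_um_range: tuple = (25.0, 60.0)
    vessel_contrast: float = 2.0             # reflectivity multiplier (<1 = dark vessels)
    vessel_depth_um: float = 40.0            # axial extent of the vessel band below ILM
    speckle_sigma: float = 0.3               # multiplicative log-normal noise scale
    band_artifact_amplitude: float = 0.10    # relative to slab reflectivity
    blob_artifact_count: int = 8
    blob_radius_um_range: tuple = (40.0, 90.0)
    target_vessel_fraction: float | None = None  # if set, vessel radii are rescaled
    seed: int = 0
    noise_seed: int | None = None  # separate stream for speckle/artifacts
                                   # (repeat scans: same anatomy, fresh noise)
    motion: tuple | None = None    # (rot_deg, dx_mm, dy_mm) rigid scene motion
                                   # about the scan centre (inter-scan motion)

    # background reflectivities (vitreous is nearly black on SD-OCT)
    vitreous_level: float = 0.005
    slab_level: float = 0.45
    rpe_level: float = 0.85
    sub_rpe_level: float = 0.12

    def __post_init__(self):
        if any(int(n) <= 0 for n in self.grid_shape) or len(self.grid_shape) != 3:
            raise ValueError(f"grid_shape must be 3 positive counts, got {self.grid_shape}")
        if self.vessel_count < 0 or self.blob_artifact_count < 0:
            raise ValueError("counts must be non-negative")
        rmin, rmax = self.vessel_radius_um_range
        if not (0 < rmin <= rmax <= 200):
            raise ValueError("vessel radii must lie in (0, 200] um")
        if rmax > 500.0 * min(self.extent_mm[:2]):
            raise ValueError("vessel radius exceeds half the scan extent")
        if self.speckle_sigma < 0 or self.band_artifact_amplitude < 0:
            raise ValueError("noise/artifact amplitudes must be non-negative")
        if self.mean_thickness_um <= 0:
            raise ValueError("mean_thickness_um must be positive")

    @property
    def spacing_um(self):
        return spacing_from_grid(self.grid_shape, self.extent_mm)


@dataclass
class SyntheticTruth:
    """Ground truth planted by :func:`generate_volume`."""

    vessel_mask: np.ndarray          # (nx, ny) bool en-face vessel footprint
    ilm_depth: np.ndarray            # (nx, ny) float, voxels
    rpe_depth: np.ndarray            # (nx, ny) float, voxels
    true_vessel_fraction: float      # exactly vessel pixels / total pixels
    artifact_low_rank: np.ndarray    # (nx, ny) additive band-artifact field
    seed: int = 0

    def __post_init__(self):
        n_vessel = int(np.count_nonzero(self.vessel_mask))
        expected = n_vessel / self.vessel_mask.size
        if self.true_vessel_fraction != expected:
            raise ValueError("true_vessel_fraction inconsistent with vessel_mask")
        if not np.all(self.ilm_depth < self.rpe_depth):
            raise ValueError("ILM must lie above RPE everywhere")


def _smooth_field(rng, shape, corr_length_px, amplitude):
    """Zero-mean Gaussian random field with unit-free RMS ``amplitude``."""
    white = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(white, corr_length_px, mode="wrap")
    smooth -= smooth.mean()  # planted means stay exact
    rms = np.sqrt(np.mean(smooth**2))
    if rms == 0:
        return np.zeros(shape)
    return amplitude * smooth / rms


def _grow_vessel_tree(rng, extent_mm, step_mm=0.05, branch_prob=0.03, max_depth=2):
    """Random branching walk in the en-face plane; returns a list of
    continuous centerline polylines (mm), one per walk run."""
    ex, ey = extent_mm[:2]
    polylines = []
    # start on a random edge, heading inward
    edge = rng.integers(4)
    if edge == 0:
        start, heading = np.array([0.0, rng.uniform(0, ey)]), 0.0
    elif edge == 1:
        start, heading = np.array([ex, rng.uniform(0, ey)]), np.pi
    elif edge == 2:
        start, heading = np.array([rng.uniform(0, ex), 0.0]), np.pi / 2
    else:
        start, heading = np.array([rng.uniform(0, ex), ey]), -np.pi / 2
    heading += rng.uniform(-0.5, 0.5)

    stack = [(start, heading, 0)]
    while stack:
        pos, ang, depth = stack.pop()
        run = [pos.copy()]
        n_steps = rng.integers(30, 90)
        for _ in range(int(n_steps)):
            pos = pos + step_mm * np.array([np.cos(ang), np.sin(ang)])
            if not (0 <= pos[0] <= ex and 0 <= pos[1] <= ey):
                break
            run.append(pos.copy())
            ang += rng.normal(0, 0.12)
            if depth < max_depth and rng.random() < branch_prob:
                stack.append((pos.copy(), ang + rng.choice([-1, 1]) * rng.uniform(0.5, 1.1), depth + 1))
        if len(run) > 1:
            polylines.append(np.array(run))
    return polylines


def _densify(polylines, step_um=10.0):
    """Resample polylines (mm) at ~``step_um`` spacing; returns points in um."""
    out = []
    for line in polylines:
        pts = line * 1000.0
        for a, b in zip(pts[:-1], pts[1:]):
            seg = np.linalg.norm(b - a)
            n = max(1, int(np.ceil(seg / step_um)))
            t = np.arange(n)[:, None] / n
            out.append(a + t * (b - a))
        out.append(pts[-1:])
    return np.concatenate(out) if out else np.empty((0, 2))


def _rasterize_tree(polylines, radius_um, shape, spacing_um):
    """Binary footprint of a tube of ``radius_um`` around a centerline tree,
    plus a Gaussian cross-section profile. Distances are exact point-to-
    centerline distances in micrometres (anisotropic pixel spacing handled),
    so the planted area varies smoothly with radius."""
    from scipy.spatial import cKDTree

    nx, ny = shape
    points_um = _densify(polylines)
    if len(points_um) == 0:
        return np.zeros(shape, bool), np.zeros(shape)
    xs = np.arange(nx) * spacing_um[0]
    ys = np.arange(ny) * spacing_um[1]
    grid = np.stack(np.meshgrid(xs, ys, indexing="ij"), axis=-1).reshape(-1, 2)
    dist_um = cKDTree(points_um).query(grid, workers=1)[0].reshape(nx, ny)
    footprint = dist_um <= radius_um
    sigma = radius_um / 1.5
    profile = np.exp(-(dist_um**2) / (2 * sigma**2))
    profile[dist_um > 2.5 * radius_um] = 0.0
    return footprint, profile


def _truncate_polylines(polylines, fraction):
    """Keep the leading ``fraction`` of a tree's total centerline length."""
    if fraction >= 1.0:
        return polylines
    lengths = [np.linalg.norm(np.diff(line, axis=0), axis=1).sum()
               for line in polylines]
    budget = fraction * sum(lengths)
    out = []
    for line, length in zip(polylines, lengths):
        if budget <= 0:
            break
        if length <= budget:
            out.append(line)
            budget -= length
        else:
            seg = np.linalg.norm(np.diff(line, axis=0), axis=1)
            cum = np.cumsum(seg)
            k = int(np.searchsorted(cum, budget)) + 1
            out.append(line[: max(2, k + 1)])
            break
    return out


def _build_vessels(params: SceneParams, radius_scale=1.0, n_trees=None,
                   last_prefix=1.0):
    """Union footprint and intensity profile of all vessel trees.

    Each tree draws from its own child stream (``SeedSequence(seed,
    spawn_key=(tree,))``) so the first k trees are unchanged when
    ``vessel_count`` grows: the planted fraction is monotone in the count.
    ``last_prefix`` truncates the final tree's centerline, giving the
    density solver a continuous knob.
    """
    nx, ny, _ = params.grid_shape
    spacing = params.spacing_um
    mask = np.zeros((nx, ny), dtype=bool)
    profile = np.zeros((nx, ny))
    rmin, rmax = params.vessel_radius_um_range
    count = params.vessel_count if n_trees is None else n_trees
    for t in range(count):
        trng = np.random.default_rng(np.random.SeedSequence(params.seed, spawn_key=(1, t)))
        polylines = _grow_vessel_tree(trng, params.extent_mm)
        radius = trng.uniform(rmin, rmax) * radius_scale
        if t == count - 1 and last_prefix < 1.0:
            polylines = _truncate_polylines(polylines, last_prefix)
        if params.motion is not None:
            polylines = [_apply_motion(line, params.motion, params.extent_mm)
                         for line in polylines]
        fp, pr = _rasterize_tree(polylines, radius, (nx, ny), spacing)
        mask |= fp
        profile = np.maximum(profile, pr)
    return mask, profile


def _apply_motion(points_mm, motion, extent_mm):
    """Rigid motion of centerline points (mm) about the scan centre."""
    rot_deg, dx, dy = motion
    c = np.array(extent_mm[:2]) / 2.0
    th = np.deg2rad(rot_deg)
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    return (points_mm - c) @ rot.T + c + np.array([dx, dy])


def generate_volume(params: SceneParams) -> tuple[OctVolume, SyntheticTruth]:
    """Generate one synthetic macular scan with ground truth.

    Returns the volume and a :class:`SyntheticTruth` holding the exact planted
    vessel footprint, surfaces (in voxels), vessel area fraction and the
    additive low-rank band-artifact field.
    """
    nx, ny, nz = params.grid_shape
    sx, sy, sz = params.spacing_um

    # --- surfaces: smooth Gaussian random fields (one stream per element) ---
    srng = np.random.default_rng(np.random.SeedSequence(params.seed, spawn_key=(0,)))
    corr_px = (1000.0 * params.surface_smoothness_mm / sx,
               1000.0 * params.surface_smoothness_mm / sy)
    ilm_um = params.ilm_depth_um + _smooth_field(srng, (nx, ny), corr_px,
                                                 params.surface_amplitude_um)
    thick_um = params.mean_thickness_um + _smooth_field(srng, (nx, ny), corr_px,
                                                        0.4 * params.surface_amplitude_um)
    rpe_band_um = 12.0
    ilm_vox = np.clip(ilm_um / sz, 2, nz - 3)
    rpe_vox = np.clip((ilm_um + thick_um) / sz, ilm_vox + 1, nz - 2)

    # --- layered reflectivity slab ---
    z = np.arange(nz)[None, None, :]
    ilm3, rpe3 = ilm_vox[..., None], rpe_vox[..., None]
    vol = np.full((nx, ny, nz), params.vitreous_level, dtype=np.float32)
    vol[(z >= ilm3) & (z < rpe3)] = params.slab_level
    vol[(z >= rpe3 - rpe_band_um / sz) & (z < rpe3)] = params.rpe_level
    vol[z >= rpe3] = params.sub_rpe_level

    # --- vessels just below the ILM ---
    radius_scale, n_trees, last_prefix = 1.0, None, 1.0
    if params.target_vessel_fraction is not None:
        n_trees, last_prefix = _solve_vessel_density(params)
    vessel_mask, vessel_profile = _build_vessels(params, radius_scale, n_trees,
                                                 last_prefix)
    vband = (z >= ilm3 + 2) & (z < ilm3 + 2 + params.vessel_depth_um / sz)
    gain = 1.0 + (params.vessel_contrast - 1.0) * vessel_profile[..., None]
    vol = np.where(vband, vol * gain.astype(np.float32), vol)

    # --- multiplicative speckle (log-normal, mean 1) ---
    nseed = params.seed if params.noise_seed is None else params.noise_seed
    if params.speckle_sigma > 0:
        nrng = np.random.default_rng(np.random.SeedSequence(nseed, spawn_key=(2,)))
        noise = np.exp(nrng.normal(-params.speckle_sigma**2 / 2, params.speckle_sigma,
                                   size=vol.shape)).astype(np.float32)
        vol *= noise

    # --- rank-<=2 band artifact: smooth row and column profiles, added to
    #     every voxel of the retinal slab (tissue signal artifact), so any
    #     depth-mean projection taken inside the slab carries exactly `band`
    band = np.zeros((nx, ny))
    if params.band_artifact_amplitude > 0:
        brng = np.random.default_rng(np.random.SeedSequence(nseed, spawn_key=(3,)))
        p = _smooth_field(brng, (nx,), 1000.0 * 0.4 / sx, 1.0)
        q = _smooth_field(brng, (ny,), 1000.0 * 0.4 / sy, 1.0)
        band = params.band_artifact_amplitude * params.slab_level * (
            np.outer(p, np.ones(ny)) + np.outer(np.ones(nx), q))
        in_slab = (z >= ilm3) & (z < rpe3)
        vol += np.where(in_slab, band[..., None], 0.0).astype(np.float32)

    # --- circular projection-artifact blobs in the vessel band ---
    if params.blob_artifact_count > 0:
        grng = np.random.default_rng(np.random.SeedSequence(nseed, spawn_key=(4,)))
        xx = np.arange(nx)[:, None] * sx
        yy = np.arange(ny)[None, :] * sy
        blobfield = np.zeros((nx, ny))
        for _ in range(params.blob_artifact_count):
            cx = grng.uniform(0, params.extent_mm[0] * 1000.0)
            cy = grng.uniform(0, params.extent_mm[1] * 1000.0)
            r = grng.uniform(*params.blob_radius_um_range)
            if params.motion is not None:  # artifacts ride with the anatomy
                cx, cy = 1000.0 * _apply_motion(
                    np.array([[cx / 1000.0, cy / 1000.0]]), params.motion,
                    params.extent_mm)[0]
            blobfield += np.exp(-(((xx - cx) ** 2) + (yy - cy) ** 2) / (2 * (r / 1.5) ** 2))
        bgain = 1.0 + (max(params.vessel_contrast, 1.5) - 1.0) * np.clip(blobfield, 0, 1)
        vol = np.where(vband, vol * bgain[..., None].astype(np.float32), vol)

    np.clip(vol, 0.0, None, out=vol)

    n_vessel = int(np.count_nonzero(vessel_mask))
    truth = SyntheticTruth(
        vessel_mask=vessel_mask,
        ilm_depth=ilm_vox,
        rpe_depth=rpe_vox,
        true_vessel_fraction=n_vessel / vessel_mask.size,
        artifact_low_rank=band,
        seed=params.seed,
    )
    volume = OctVolume(vol, params.spacing_um,
                       meta={"seed": params.seed, "synthetic": True})
    return volume, truth


def _solve_vessel_density(params: SceneParams, tol=0.01, max_trees=24,
                          max_iter=18) -> tuple[int, float]:
    """Tree count + last-tree prefix hitting ``target_vessel_fraction``.

    Full trees are added until the planted fraction reaches the target; the
    final tree's centerline length is then bisected (a continuous knob that
    leaves vessel calibres untouched) to ``tol`` relative error. Tree
    streams are child-seeded, so growing the count only adds trees.
    """
    target = params.target_vessel_fraction

    def frac_at(n, prefix):
        mask, _ = _build_vessels(params, 1.0, n, prefix)
        return np.count_nonzero(mask) / mask.size

    n = 1
    while frac_at(n, 1.0) < target and n < max_trees:
        n += 1
    if frac_at(n, 1.0) <= target:           # max_trees still short: keep all
        return n, 1.0
    lo, hi = 0.0, 1.0                        # frac_at(n, ~0) < target by choice of n
    prefix = 0.5
    for _ in range(max_iter):
        frac = frac_at(n, prefix)
        if frac > 0 and abs(frac - target) / target <= tol:
            break
        if frac < target:
            lo = prefix
        else:
            hi = prefix
        prefix = 0.5 * (lo + hi)
    return n, prefix


# ---------------------------------------------------------------------------
# physiology cohort
# ---------------------------------------------------------------------------

#: Day-wise group means emulating the study's arterial blood and
#: cardiorespiratory summary (day 0 = 1,130 m baseline; days 2 and 9 at
#: 3,800 m). SBP/DBP are chosen to reproduce the reported MAP means.
TABLE1_MEANS = {
    "PaO2":  {0: 84.8, 2: 52.5, 9: 54.5},
    "PaCO2": {0: 37.9, 2: 33.3, 9: 30.4},
    "SaO2":  {0: 96.3, 2: 87.3, 9: 88.6},
    "pH":    {0: 7.41, 2: 7.43, 9: 7.42},
    "HCO3":  {0: 24.2, 2: 22.0, 9: 19.6},
    "Hb":    {0: 150.7, 2: 153.2, 9: 165.4},
    "Hct":   {0: 43.7, 2: 43.8, 9: 46.6},
    "HR":    {0: 64.0, 2: 74.7, 9: 68.7},
    "SBP":   {0: 118.0, 2: 118.0, 9: 113.0},
    "DBP":   {0: 72.5, 2: 72.7, 9: 68.9},
    "VE":    {0: 8.9, 2: 10.3, 9: 10.2},
}

TABLE1_SDS = {
    "PaO2":  {0: 9.1, 2: 5.1, 9: 4.0},
    "PaCO2": {0: 3.7, 2: 3.2, 9: 1.9},
    "SaO2":  {0: 0.96, 2: 3.1, 9: 1.9},
    "pH":    {0: 0.02, 2: 0.02, 9: 0.01},
    "HCO3":  {0: 1.8, 2: 2.2, 9: 1.4},
    "Hb":    {0: 13.0, 2: 13.4, 9: 13.0},
    "Hct":   {0: 3.4, 2: 2.8, 9: 2.9},
    "HR":    {0: 12.4, 2: 10.1, 9: 11.4},
    "SBP":   {0: 10.3, 2: 12.7, 9: 9.2},
    "DBP":   {0: 10.3, 2: 12.7, 9: 9.2},
    "VE":    {0: 3.2, 2: 2.8, 9: 1.8},
}


@dataclass(frozen=True)
class CohortParams:
    """Parameters of a synthetic repeated-measures physiology cohort.

    Per-day value model: ``mean_d + sd_d * (sqrt(1 - w^2) * b_i + w * e_id)``
    with subject intercept ``b_i ~ N(0,1)`` shared across days and noise
    ``e_id ~ N(0,1)``, so per-day sample SDs converge to the configured SDs
    while subjects carry a repeated-measures structure. ``within_subject_sd``
    is the within-subject fraction ``w`` of each day SD.

    The retinal vessel area fraction is planted as
    ``base_i + rvpd_pao2_slope * (PaO2_id - day-0 mean PaO2) + noise`` so a
    day-2 PaO2 drop of ~32 mmHg raises the fraction by ~0.6 percentage points
    on a 4.4% base, the effect size of interest.
    """

    n_subjects: int = 18
    days: Sequence[int] = (0, 2, 9)
    means: dict = field(default_factory=lambda: TABLE1_MEANS)
    sds: dict = field(default_factory=lambda: TABLE1_SDS)
    within_subject_sd: float = 0.5
    rvpd_pao2_slope: float = -1.85e-4       # vessel fraction per mmHg PaO2
    rvpd_base_mean: float = 0.044           # day-0 mean vessel fraction
    rvpd_base_sd: float = 0.006             # between-subject SD of the base
    rvpd_resid_sd: float = 0.00476          # within-subject residual SD
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        if not (0 <= self.within_subject_sd <= 1):
            raise ValueError("within_subject_sd is a fraction in [0, 1]")
        for v, per_day in self.sds.items():
            if any(sd < 0 for sd in per_day.values()):
                raise ValueError(f"negative SD for {v}")


def generate_cohort(params: CohortParams) -> pd.DataFrame:
    """Long-format physiology table: columns (subject, day, variable, value).

    Includes a ``vessel_fraction`` variable carrying the planted PaO2
    dependence, usable as the imaging target for end-to-end simulations.
    """
    rng = np.random.default_rng(np.random.SeedSequence(params.seed, spawn_key=(10,)))
    n, days = params.n_subjects, list(params.days)
    w = params.within_subject_sd
    between = np.sqrt(1.0 - w**2)

    rows = []
    pao2 = np.zeros((n, len(days)))
    for var in params.means:
        b = rng.standard_normal(n)
        for j, d in enumerate(days):
            mu = params.means[var][d]
            sd = params.sds[var][d]
            eps = rng.standard_normal(n)
            vals = mu + sd * (between * b + w * eps)
            if var == "PaO2":
                pao2[:, j] = vals
            for i in range(n):
                rows.append((f"S{i:02d}", d, var, vals[i]))

    # planted vessel fraction tied to PaO2
    pao2_ref = params.means["PaO2"][days[0]]
    base = params.rvpd_base_mean + params.rvpd_base_sd * rng.standard_normal(n)
    for j, d in enumerate(days):
        eps = rng.standard_normal(n)
        frac = base + params.rvpd_pao2_slope * (pao2[:, j] - pao2_ref) \
            + params.rvpd_resid_sd * eps
        frac = np.clip(frac, 1e-4, 0.5)
        for i in range(n):
            rows.append((f"S{i:02d}", d, "vessel_fraction", frac[i]))

    return pd.DataFrame(rows, columns=["subject", "day", "variable", "value"])
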