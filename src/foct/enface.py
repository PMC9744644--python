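"""En-face projection, image-quality scoring, and rigid coregistration.

Repeated scans of one participant are projected between retinal surfaces,
scored on a 0-10 signal-strength scale (scans under 8 are rejected, matching
the acquisition QC rule), and rigidly aligned to a per-subject reference.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation

from .io import EnFaceImage, OctVolume

__all__ = [
    "RigidTransform",
    "QualityScore",
    "project_enface",
    "quality_score",
    "register_rigid",
    "apply_transform",
]


@dataclass(frozen=True)
class RigidTransform:
    """Rotation (degrees, about the image centre) followed by a translation
    in pixels along the (x, y) array axes."""

    rotation_deg: float = 0.0
    shift_x_px: float = 0.0
    shift_y_px: float = 0.0

    def __post_init__(self):
        if not (-180.0 < self.rotation_deg <= 180.0):
            raise ValueError("rotation must lie in (-180, 180] degrees")

    def inverse(self) -> "RigidTransform":
        """Transform undoing this one: rotate by -theta, shift by -R(-theta) s."""
        th = math.radians(-self.rotation_deg)
        c, s = math.cos(th), math.sin(th)
        sx, sy = self.shift_x_px, self.shift_y_px
        return RigidTransform(-self.rotation_deg, -(c * sx - s * sy), -(s * sx + c * sy))


@dataclass(frozen=True)
class QualityScore:
    """Signal-strength score on the scanner-style 0-10 scale with the
    underlying SNR estimate in dB."""

    score: int
    snr_db: float

    def __post_init__(self):
        if not (0 <= self.score <= 10):
            raise ValueError("score must lie in [0, 10]")


def project_enface(volume: OctVolume, surfaces, band=(0.0, 120.0),
                   reducer="mean") -> EnFaceImage:
    """Project the volume between two depth offsets below the ILM.

    Parameters
    ----------
    surfaces : SurfacePair or SyntheticTruth
        Anything with ``ilm_depth``/``rpe_depth`` maps in voxel units.
    band : (offset_top_um, offset_bottom_um)
        Half-open axial slab measured downward from the ILM. The default
        0-120 um covers the superficial vascular plexus.
    reducer : "mean" or "max"
    """
    if reducer not in ("mean", "max"):
        raise ValueError(f"unknown reducer '{reducer}'")
    sz = volume.spacing_um[2]
    nz = volume.shape[2]
    ilm = np.asarray(surfaces.ilm_depth, dtype=float)
    rpe = np.asarray(surfaces.rpe_depth, dtype=float)
    z0 = np.floor(ilm + band[0] / sz).astype(int)
    z1 = np.floor(ilm + band[1] / sz).astype(int)
    if np.any(z1 <= z0):
        bad = np.argwhere(z1 <= z0)[0]
        raise ValueError(f"empty projection slab at column (x={bad[0]}, y={bad[1]})")
    if np.any(z1 > np.ceil(rpe)) or np.any(z0 < 0) or np.any(z1 > nz):
        bad = np.argwhere((z1 > np.ceil(rpe)) | (z0 < 0) | (z1 > nz))[0]
        raise ValueError(
            f"projection band leaves the ILM-RPE slab at column (x={bad[0]}, y={bad[1]})")

    z = np.arange(nz)[None, None, :]
    inside = (z >= z0[..., None]) & (z < z1[..., None])
    data = volume.data
    if reducer == "mean":
        proj = np.where(inside, data, 0.0).sum(axis=2) / inside.sum(axis=2)
    else:
        proj = np.where(inside, data, -np.inf).max(axis=2)
    return EnFaceImage(proj, volume.enface_spacing_um,
                       provenance={"band_um": tuple(band), "reducer": reducer,
                                   **volume.meta})


def quality_score(volume: OctVolume, vitreous_frac=0.05, signal_quantile=0.9) -> QualityScore:
    """Estimate a 0-10 signal strength from the volume itself.

    SNR is the mean of the brightest decile of the mean A-scan profile (the
    retinal slab signal) over the intensity SD in the top vitreous band; the
    score is ``clamp(round(snr_db / 3), 0, 10)``. A zero noise floor yields
    score 10 with a warning.
    """
    data = volume.data
    nz = data.shape[2]
    profile = data.mean(axis=(0, 1))
    ztop = max(1, int(vitreous_frac * nz))
    noise = float(data[:, :, :ztop].std())
    tail = profile[profile >= np.quantile(profile, signal_quantile)]
    signal = float(tail.mean())
    if noise <= 1e-8:  # numerically zero noise floor
        warnings.warn("zero noise floor; reporting maximum signal strength",
                      stacklevel=2)
        return QualityScore(10, float("inf"))
    snr_db = 10.0 * math.log10(max(signal, 1e-12) / noise)
    return QualityScore(int(np.clip(round(snr_db / 3.0), 0, 10)), snr_db)


def apply_transform(image: EnFaceImage, t: RigidTransform) -> EnFaceImage:
    """Rotate about the image centre then shift, with bilinear resampling.

    Pixels pulled from outside the frame are filled with the image median and
    the fill count is recorded in provenance.
    """
    data = image.data
    fill = float(np.median(data))
    th = math.radians(t.rotation_deg)
    c, s = math.cos(th), math.sin(th)
    rot_t = np.array([[c, s], [-s, c]])  # R(theta)^T in array (x, y) coords
    centre = (np.array(data.shape) - 1) / 2.0
    shift = np.array([t.shift_x_px, t.shift_y_px])
    offset = centre - rot_t @ (centre + shift)
    out = ndimage.affine_transform(data, rot_t, offset=offset, order=1,
                                   mode="constant", cval=fill)
    # track pixels that sampled outside the frame
    inside = ndimage.affine_transform(np.ones_like(data), rot_t, offset=offset,
                                      order=1, mode="constant", cval=0.0)
    n_filled = int(np.count_nonzero(inside < 0.999))
    prov = dict(image.provenance)
    prov.update({"transform": (t.rotation_deg, t.shift_x_px, t.shift_y_px),
                 "filled_px": n_filled, "fill_value": fill})
    return EnFaceImage(out, image.spacing_um, prov)


def _ncc(a: np.ndarray, b: np.ndarray, margin=8) -> float:
    """Normalised cross-correlation on a central crop (avoids fill borders)."""
    sl = tuple(slice(margin, -margin or None) for _ in range(2))
    a, b = a[sl], b[sl]
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a**2).sum() * (b**2).sum())
    return float((a * b).sum() / denom) if denom > 0 else -1.0


def _best_shift(reference, rotated):
    shift, _, _ = phase_cross_correlation(reference, rotated,
                                          upsample_factor=20,
                                          normalization=None)
    moved = ndimage.shift(rotated, shift, order=1, mode="nearest")
    return shift, _ncc(reference, moved)


def register_rigid(reference: EnFaceImage, moving: EnFaceImage,
                   max_rotation_deg=10.0) -> RigidTransform:
    """Recover the rigid transform aligning ``moving`` to ``reference``.

    Rotation by coarse-to-fine grid search maximising normalised
    cross-correlation; translation by subpixel phase correlation at each
    candidate angle. ``apply_transform(moving, t)`` then matches the
    reference.
    """
    if reference.data.shape != moving.data.shape:
        raise ValueError("reference and moving images must share a shape")
    for name, img in (("reference", reference), ("moving", moving)):
        if img.data.std() == 0:
            raise ValueError(f"{name} image has zero variance; cannot register")

    ref = reference.data

    def evaluate(angle):
        rotated = apply_transform(moving, RigidTransform(angle, 0.0, 0.0)).data
        shift, score = _best_shift(ref, rotated)
        return shift, score

    best_angle, best_shift, best_score = 0.0, np.zeros(2), -np.inf
    for step, centre, span in ((1.0, 0.0, max_rotation_deg),
                               (0.2, None, 1.0),
                               (0.05, None, 0.2)):
        centre = best_angle if centre is None else centre
        angles = np.arange(centre - span, centre + span + step / 2, step)
        for ang in angles:
            shift, score = evaluate(float(ang))
            if score > best_score:
                best_angle, best_shift, best_score = float(ang), shift, score
    return RigidTransform(best_angle, float(best_shift[0]), float(best_shift[1]))
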