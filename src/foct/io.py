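"""Volume, image, mask and table I/O with explicit physical metadata.

Coordinate convention (shared by every module in this package): volumes are
indexed ``(x, y, z)`` = (fast scan axis, slow scan axis, depth), 0-based, with
depth increasing from the vitreous (ILM side) toward the choroid (RPE side).
Slab bounds are half-open ``[z0, z1)``. A full-resolution macular cube is
512 x 128 x 1024 voxels covering 6 mm x 6 mm x 2 mm, i.e. a voxel spacing of
(11.72, 46.88, 1.953) um.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "SchemaError",
    "OctVolume",
    "EnFaceImage",
    "BinaryVesselMask",
    "FULL_GRID",
    "DEFAULT_EXTENT_MM",
    "spacing_from_grid",
    "read_volume",
    "write_volume",
    "read_table",
    "write_results",
]

FULL_GRID = (512, 128, 1024)
DEFAULT_EXTENT_MM = (6.0, 6.0, 2.0)

#: physiology table columns that read_table requires
MANDATORY_COLUMNS = ("subject", "day")


class FormatError(ValueError):
    """A file could not be read or written in the requested format."""


class SchemaError(ValueError):
    """A table is missing mandatory columns."""


def spacing_from_grid(grid_shape, extent_mm=DEFAULT_EXTENT_MM):
    """Per-axis voxel spacing in micrometres for a grid covering ``extent_mm``."""
    return tuple(1000.0 * e / n for e, n in zip(extent_mm, grid_shape))


def _promote(data: np.ndarray) -> np.ndarray:
    """Promote integer intensities to float in [0, 1]; pass floats through."""
    data = np.asarray(data)
    if np.issubdtype(data.dtype, np.integer):
        info = np.iinfo(data.dtype)
        return data.astype(np.float32) / float(info.max)
    return data.astype(np.float32, copy=False)


@dataclass
class OctVolume:
    """A 3-D OCT reflectivity volume.

    Parameters
    ----------
    data : ndarray, shape (n_fast, n_slow, n_depth)
        Reflectivity, float. Integer input is promoted to [0, 1].
    spacing_um : tuple of float
        Voxel size along (x, y, z) in micrometres.
    meta : dict
        Free-form acquisition tags (subject, day, scanner, ...).
    """

    data: np.ndarray
    spacing_um: tuple
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = _promote(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3-D, got shape {self.data.shape}")
        self.spacing_um = tuple(float(s) for s in self.spacing_um)
        if len(self.spacing_um) != 3 or any(s <= 0 for s in self.spacing_um):
            raise ValueError(f"spacing_um must be 3 positive values, got {self.spacing_um}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume data must be finite")

    @property
    def shape(self):
        return self.data.shape

    @property
    def enface_shape(self):
        return self.data.shape[:2]

    @property
    def enface_spacing_um(self):
        return self.spacing_um[:2]


@dataclass
class EnFaceImage:
    """A 2-D frontal-plane image on the (x, y) grid of its source volume."""

    data: np.ndarray
    spacing_um: tuple
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError(f"en-face image must be 2-D, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("en-face image must be finite")
        self.spacing_um = tuple(float(s) for s in self.spacing_um)


@dataclass
class BinaryVesselMask:
    """Final binary vessel/background decision for an en-face image."""

    data: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        data = np.asarray(self.data)
        if data.dtype != bool:
            uniq = np.unique(data)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ValueError("mask must be strictly binary")
            data = data.astype(bool)
        if data.ndim != 2:
            raise ValueError("mask must be 2-D")
        self.data = data


# ---------------------------------------------------------------------------
# minimal NRRD codec (raw encoding only)
# ---------------------------------------------------------------------------

_NRRD_DTYPES = {
    "float": np.float32, "float32": np.float32,
    "double": np.float64, "float64": np.float64,
    "uint8": np.uint8, "uchar": np.uint8,
    "uint16": np.uint16, "ushort": np.uint16,
    "int16": np.int16, "short": np.int16,
}


def _write_nrrd(path: Path, data: np.ndarray, spacing_um) -> None:
    spacing_mm = [s / 1000.0 for s in spacing_um]
    header = (
        "NRRD0004\n"
        "# foct volume\n"
        f"type: float\n"
        f"dimension: {data.ndim}\n"
        f"sizes: {' '.join(str(n) for n in data.shape)}\n"
        f"spacings: {' '.join(f'{s:.9g}' for s in spacing_mm)}\n"
        "encoding: raw\n"
        "endian: little\n\n"
    )
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        fh.write(np.ascontiguousarray(data, dtype="<f4").tobytes())


def _read_nrrd(path: Path):
    with open(path, "rb") as fh:
        raw = fh.read()
    try:
        head_end = raw.index(b"\n\n")
    except ValueError:
        raise FormatError(f"{path.name}: no NRRD header terminator") from None
    fields = {}
    for line in raw[:head_end].decode("ascii", errors="replace").splitlines()[1:]:
        if line.startswith("#") or ":" not in line:
            continue
        key, val = line.split(":", 1)
        fields[key.strip().lower()] = val.strip()
    try:
        sizes = tuple(int(s) for s in fields["sizes"].split())
        dtype = _NRRD_DTYPES[fields["type"]]
    except KeyError as exc:
        raise FormatError(f"{path.name}: missing/unsupported NRRD field {exc}") from None
    if fields.get("encoding", "raw") != "raw":
        raise FormatError(f"{path.name}: only raw NRRD encoding is supported")
    spacing_um = None
    if "spacings" in fields:
        spacing_um = tuple(1000.0 * float(s) for s in fields["spacings"].split())
    buf = raw[head_end + 2:]
    expected = int(np.prod(sizes)) * np.dtype(dtype).itemsize
    if len(buf) < expected:
        raise FormatError(f"{path.name}: truncated NRRD data ({len(buf)} < {expected} bytes)")
    data = np.frombuffer(buf[:expected], dtype=np.dtype(dtype).newbyteorder("<"))
    return data.reshape(sizes), spacing_um


# ---------------------------------------------------------------------------
# volume read/write
# ---------------------------------------------------------------------------

def write_volume(volume: OctVolume, path) -> None:
    """Write a volume to TIFF (multi-page), NRRD or NIfTI, inferred from extension.

    TIFF pages run along the depth axis; spacing and the axis convention are
    stored in the ImageDescription tag as JSON.
    """
    path = Path(path)
    suffixes = "".join(path.suffixes).lower()
    if suffixes.endswith((".tif", ".tiff")):
        import tifffile

        # pages along depth; each page is the (x, y) plane
        pages = np.moveaxis(volume.data.astype(np.float32), 2, 0)
        desc = json.dumps({"spacing_um": list(volume.spacing_um), "axes": "ZXY",
                           "meta": volume.meta})
        tifffile.imwrite(path, pages, description=desc)
    elif suffixes.endswith(".nrrd"):
        _write_nrrd(path, volume.data, volume.spacing_um)
    elif suffixes.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        affine = np.diag([*(s / 1000.0 for s in volume.spacing_um), 1.0])
        img = nib.Nifti1Image(volume.data.astype(np.float32), affine)
        nib.save(img, str(path))
    else:
        raise FormatError(f"{path.name}: unknown volume extension")


def read_volume(path) -> OctVolume:
    """Read a volume written by :func:`write_volume` (or a plain file of a
    supported format). Raises :class:`FormatError` (never a bare crash) on
    unknown extensions or corrupt files."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path.name}: file does not exist")
    suffixes = "".join(path.suffixes).lower()
    if suffixes.endswith((".tif", ".tiff")):
        import tifffile

        try:
            with tifffile.TiffFile(path) as tf:
                pages = tf.asarray()
                desc = tf.pages[0].description
        except Exception as exc:
            raise FormatError(f"{path.name}: unreadable TIFF ({exc})") from exc
        spacing_um, meta = None, {}
        if desc:
            try:
                tags = json.loads(desc)
                spacing_um = tags.get("spacing_um")
                meta = tags.get("meta", {})
            except (json.JSONDecodeError, AttributeError):
                pass
        if pages.ndim != 3:
            raise FormatError(f"{path.name}: expected a 3-D TIFF stack, got {pages.shape}")
        data = np.moveaxis(pages, 0, 2)
        if spacing_um is None:
            spacing_um = spacing_from_grid(data.shape)
        return OctVolume(data, tuple(spacing_um), meta)
    if suffixes.endswith(".nrrd"):
        data, spacing_um = _read_nrrd(path)
        if spacing_um is None:
            spacing_um = spacing_from_grid(data.shape)
        return OctVolume(data, spacing_um)
    if suffixes.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        try:
            img = nib.load(str(path))
            data = np.asarray(img.dataobj)
        except Exception as exc:
            raise FormatError(f"{path.name}: unreadable NIfTI ({exc})") from exc
        zooms = img.header.get_zooms()[:3]
        return OctVolume(data, tuple(1000.0 * z for z in zooms))
    raise FormatError(f"{path.name}: unknown volume extension")


# ---------------------------------------------------------------------------
# tables and results
# ---------------------------------------------------------------------------

def read_table(path, required_columns=MANDATORY_COLUMNS) -> pd.DataFrame:
    """Read a physiology CSV.

    Missing cells stay missing (the study design allows absent arterial
    draws); extra columns are preserved with a warning; a missing mandatory
    column raises :class:`SchemaError` naming it.
    """
    df = pd.read_csv(path)
    for col in required_columns:
        if col not in df.columns:
            raise SchemaError(f"mandatory column '{col}' missing from {Path(path).name}")
    known = set(required_columns) | {
        "variable", "value", "PaO2", "PaCO2", "SaO2", "Hb", "Hct", "HCO3",
        "pH", "SBP", "DBP", "HR", "VE", "sex", "vessel_fraction",
    }
    extra = [c for c in df.columns if c not in known]
    if extra:
        warnings.warn(f"extra columns preserved: {extra}", stacklevel=2)
    return df


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.bool_,)):
            return bool(obj)
        return super().default(obj)


def write_results(results, path) -> None:
    """Write a results mapping (or DataFrame) to JSON/CSV by extension."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        pd.DataFrame(results).to_csv(path, index=False)
        return
    with open(path, "w") as fh:
        json.dump(results, fh, indent=2, sort_keys=True, cls=_NumpyEncoder)
        fh.write("\n")
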