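"""Volume and mask I/O with explicit geometry metadata.

Axis and coordinate conventions used throughout the package
-----------------------------------------------------------
* Arrays are 3-D and indexed ``(axis0, axis1, axis2)``; axis 0 is the
  slice index of a reconstructed stack.
* Voxel indices are 0-based.  World coordinates are millimetres with a
  voxel-*center* convention: ``world = origin + index * spacing``.
* A volume carries an ``intensity_scale`` tag, either ``"raw"`` (scanner
  units, pre-calibration) or ``"HU"`` (Hounsfield units).  Downstream
  stages check the tag so a volume cannot be calibrated twice or
  classified before calibration.

Supported on-disk formats: NIfTI-1 (via :mod:`nibabel`) and flat RAW
slice stacks accompanied by a small JSON sidecar describing shape,
dtype, endianness and spacing (scanners export RAW without metadata, so
the sidecar makes the file self-describing).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import nibabel as nib
import numpy as np

RAW_SCALE = "raw"
HU_SCALE = "HU"


class FormatError(ValueError):
    """A file does not match its declared geometry or encoding."""


class GridMismatchError(ValueError):
    """Two objects that must share a voxel grid do not."""


@dataclass(frozen=True)
class Grid:
    """Geometry of a voxel lattice: shape, spacing (mm) and origin (mm)."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(s <= 0 for s in self.shape):
            raise ValueError(f"grid shape must be 3 positive ints, got {self.shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"voxel spacing must be positive, got {self.spacing}")

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    @property
    def is_isotropic(self) -> bool:
        s = self.spacing
        return abs(s[0] - s[1]) < 1e-9 and abs(s[1] - s[2]) < 1e-9

    def center_world(self) -> np.ndarray:
        """World coordinates (mm) of the geometric center of the grid."""
        shape = np.asarray(self.shape, dtype=float)
        return np.asarray(self.origin) + (shape - 1.0) / 2.0 * np.asarray(self.spacing)

    def indices_to_world(self, idx: np.ndarray) -> np.ndarray:
        """Map fractional voxel indices ``(..., 3)`` to world mm."""
        idx = np.asarray(idx, dtype=float)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def world_to_indices(self, pts: np.ndarray) -> np.ndarray:
        """Map world mm coordinates ``(..., 3)`` to fractional indices."""
        pts = np.asarray(pts, dtype=float)
        return (pts - np.asarray(self.origin)) / np.asarray(self.spacing)

    def voxel_centers(self) -> np.ndarray:
        """World coordinates of every voxel center, shape ``(*shape, 3)``."""
        axes = [
            self.origin[a] + np.arange(self.shape[a]) * self.spacing[a]
            for a in range(3)
        ]
        g = np.meshgrid(*axes, indexing="ij")
        return np.stack(g, axis=-1)


@dataclass
class Volume:
    """A 3-D scalar image with voxel spacing, origin and intensity scale."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    intensity_scale: str = RAW_SCALE
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume data must be 3-D, got shape {self.data.shape}")
        if np.isscalar(self.spacing) or len(np.atleast_1d(self.spacing)) == 1:
            s = float(np.atleast_1d(self.spacing)[0])
            self.spacing = (s, s, s)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"voxel spacing must be positive, got {self.spacing}")
        if self.intensity_scale not in (RAW_SCALE, HU_SCALE):
            raise ValueError(f"unknown intensity scale {self.intensity_scale!r}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume data contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)

    @property
    def grid(self) -> Grid:
        return Grid(self.shape, self.spacing, self.origin)

    @property
    def voxel_volume(self) -> float:
        return self.grid.voxel_volume

    @property
    def is_isotropic(self) -> bool:
        return self.grid.is_isotropic

    def require_isotropic(self) -> None:
        if not self.is_isotropic:
            raise ValueError(
                f"pipeline requires isotropic voxels, got spacing {self.spacing}"
            )

    def with_data(self, data: np.ndarray, intensity_scale: str | None = None) -> "Volume":
        return replace(
            self,
            data=data,
            intensity_scale=intensity_scale or self.intensity_scale,
        )


@dataclass
class RoiMask:
    """Binary 3-D region-of-interest mask tied to a reference volume grid."""

    data: np.ndarray
    reference_id: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError(f"mask must be 3-D, got shape {arr.shape}")
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, (0, 1))):
            raise FormatError(f"mask is not binary; values found: {uniq[:10]}")
        self.data = arr.astype(bool)

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)

    @property
    def count(self) -> int:
        return int(self.data.sum())

    def require_nonempty(self) -> None:
        if self.count == 0:
            raise ValueError("defect ROI mask has no foreground voxels")

    def require_on_grid(self, vol: Volume) -> None:
        if self.shape != vol.shape:
            raise GridMismatchError(
                f"mask shape {self.shape} does not match volume shape {vol.shape}"
            )


# ---------------------------------------------------------------------------
# RAW slice stacks
# ---------------------------------------------------------------------------

_ENDIAN = {"little": "<", "big": ">"}


def read_raw_stack(
    path: str | Path,
    shape: tuple[int, int, int],
    dtype: str = "uint16",
    endianness: str = "little",
    spacing: float | tuple[float, float, float] = 0.116,
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> Volume:
    """Read a flat RAW stack of slices into a raw-scale :class:`Volume`.

    ``shape`` is ``(n_slices, ny, nx)``; the file must contain exactly
    ``prod(shape)`` samples of ``dtype`` or a :class:`FormatError` is raised
    naming the expected and actual byte counts.
    """
    path = Path(path)
    if endianness not in _ENDIAN:
        raise ValueError(f"endianness must be 'little' or 'big', got {endianness!r}")
    dt = np.dtype(dtype).newbyteorder(_ENDIAN[endianness])
    expected = int(np.prod(shape)) * dt.itemsize
    actual = path.stat().st_size
    if actual != expected:
        raise FormatError(
            f"RAW file {path.name}: expected {expected} bytes for shape "
            f"{tuple(shape)} of {dt}, found {actual}"
        )
    data = np.fromfile(path, dtype=dt).reshape(shape)
    return Volume(data.astype(np.float64), spacing, RAW_SCALE, origin)


def write_raw_stack(
    vol: Volume, path: str | Path, dtype: str = "uint16", endianness: str = "little"
) -> Path:
    """Write a volume as a flat RAW stack plus a ``<name>.json`` sidecar."""
    path = Path(path)
    dt = np.dtype(dtype).newbyteorder(_ENDIAN[endianness])
    np.ascontiguousarray(vol.data).astype(dt).tofile(path)
    sidecar = {
        "shape": list(vol.shape),
        "dtype": dtype,
        "endianness": endianness,
        "spacing_mm": list(vol.spacing),
        "origin_mm": list(vol.origin),
        "intensity_scale": vol.intensity_scale,
    }
    sidecar_path = path.with_name(path.name + ".json")
    sidecar_path.write_text(json.dumps(sidecar, indent=1))
    return sidecar_path


def read_raw_with_sidecar(path: str | Path) -> Volume:
    """Read a RAW stack using its JSON sidecar for geometry and dtype."""
    path = Path(path)
    sidecar_path = path.with_name(path.name + ".json")
    if not sidecar_path.exists():
        raise FormatError(f"missing sidecar {sidecar_path.name} for RAW file")
    meta = json.loads(sidecar_path.read_text())
    vol = read_raw_stack(
        path,
        shape=tuple(meta["shape"]),
        dtype=meta.get("dtype", "uint16"),
        endianness=meta.get("endianness", "little"),
        spacing=tuple(meta["spacing_mm"]),
        origin=tuple(meta.get("origin_mm", (0.0, 0.0, 0.0))),
    )
    vol.intensity_scale = meta.get("intensity_scale", RAW_SCALE)
    return vol


# ---------------------------------------------------------------------------
# NIfTI
# ---------------------------------------------------------------------------


def _affine(vol_or_grid) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = vol_or_grid.spacing
    aff[:3, 3] = vol_or_grid.origin
    return aff


def write_nifti(vol: Volume, path: str | Path) -> None:
    """Write a volume as NIfTI-1; spacing and origin go into the affine."""
    img = nib.Nifti1Image(np.asanyarray(vol.data), _affine(vol))
    img.header.set_zooms(vol.spacing)
    img.header["descrip"] = vol.intensity_scale.encode()
    nib.save(img, str(path))


def read_nifti(path: str | Path, intensity_scale: str | None = None) -> Volume:
    """Read a NIfTI-1 volume.

    Only axis-aligned affines are accepted: orientation handling beyond a
    diagonal scaling plus translation is out of scope for this pipeline.
    The intensity-scale tag is recovered from the header's ``descrip``
    field when present (written by :func:`write_nifti`), else defaults to
    raw; pass ``intensity_scale`` to override.
    """
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several error types
        raise FormatError(f"cannot read NIfTI file {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"expected a 3-D NIfTI volume, got shape {data.shape}")
    aff = img.affine
    if np.abs(aff[:3, :3] - np.diag(np.diag(aff[:3, :3]))).max() > 1e-6:
        raise FormatError("non-axis-aligned NIfTI affines are not supported")
    spacing = tuple(float(aff[a, a]) for a in range(3))
    if any(s <= 0 for s in spacing):
        raise FormatError(f"non-positive spacing in affine: {spacing}")
    origin = tuple(float(x) for x in aff[:3, 3])
    if intensity_scale is None:
        descrip = bytes(img.header["descrip"].tobytes()).rstrip(b"\x00").decode(errors="ignore")
        intensity_scale = descrip if descrip in (RAW_SCALE, HU_SCALE) else RAW_SCALE
    return Volume(data, spacing, intensity_scale, origin)


def write_mask(mask: RoiMask, grid: Grid, path: str | Path) -> None:
    """Write an ROI mask as a {0,1}-valued NIfTI on its reference grid."""
    if tuple(mask.shape) != tuple(grid.shape):
        raise GridMismatchError(
            f"mask shape {mask.shape} does not match grid shape {grid.shape}"
        )
    g = Volume(np.zeros(grid.shape), grid.spacing, RAW_SCALE, grid.origin)
    img = nib.Nifti1Image(mask.data.astype(np.uint8), _affine(g))
    img.header.set_zooms(grid.spacing)
    nib.save(img, str(path))


def read_mask(path: str | Path, reference_id: str = "") -> RoiMask:
    """Read a binary NIfTI mask; non-binary voxel values are rejected."""
    vol = read_nifti(path)
    return RoiMask(vol.data, reference_id=reference_id)
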