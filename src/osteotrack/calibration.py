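"""Session-wise Hounsfield-unit calibration from water and air phantoms.

Every imaging session co-scans a water tube and an air tube.  The mean
raw intensity of each anchors a two-point linear map

    HU(v) = 1000 * (v - water_mean) / (water_mean - air_mean)

so that water maps to 0 HU and air to -1000 HU by construction.  Applying
the session's map to every scan puts all timepoints on a common absolute
density scale, which is what makes longitudinal voxel classification
meaningful.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats as _sps

from .io_formats import HU_SCALE, RAW_SCALE, Volume


class CalibrationError(ValueError):
    """Degenerate or inconsistent calibration input."""


@dataclass(frozen=True)
class HuMap:
    """Affine raw-to-HU map anchored on water (0 HU) and air (-1000 HU)."""

    slope: float
    intercept: float
    source_water_mean: float
    source_air_mean: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.slope) or self.slope == 0.0:
            raise CalibrationError(f"degenerate HU map slope: {self.slope}")
        # the two anchor points must be reproduced by construction
        for v, target in ((self.source_water_mean, 0.0), (self.source_air_mean, -1000.0)):
            if abs(self.slope * v + self.intercept - target) > 1e-9:
                raise CalibrationError("HU map does not reproduce its anchor points")

    def __call__(self, raw: np.ndarray | float) -> np.ndarray | float:
        return self.slope * raw + self.intercept

    def inverse(self, hu: np.ndarray | float) -> np.ndarray | float:
        return (hu - self.intercept) / self.slope

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "slope_hu_per_raw": self.slope,
                    "intercept_hu": self.intercept,
                    "source_water_mean": self.source_water_mean,
                    "source_air_mean": self.source_air_mean,
                },
                indent=1,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "HuMap":
        d = json.loads(Path(path).read_text())
        return cls(
            d["slope_hu_per_raw"],
            d["intercept_hu"],
            d["source_water_mean"],
            d["source_air_mean"],
        )


def estimate_hu_map(
    water_region_voxels: np.ndarray,
    air_region_voxels: np.ndarray,
    robust: bool = False,
) -> HuMap:
    """Fit the two-point raw-to-HU map from phantom region intensities.

    Parameters
    ----------
    water_region_voxels, air_region_voxels
        1-D arrays of raw intensities sampled inside the water and air
        tubes.  With ``robust=True`` a 5% two-sided trimmed mean is used,
        which guards against partial-volume rim voxels and streaks in
        measured data; the plain mean is exact on noise-free input.
    """
    w = np.asarray(water_region_voxels, dtype=float).ravel()
    a = np.asarray(air_region_voxels, dtype=float).ravel()
    if w.size == 0 or a.size == 0:
        raise CalibrationError("calibration regions must be nonempty")
    if robust:
        water_mean = float(_sps.trim_mean(w, 0.05))
        air_mean = float(_sps.trim_mean(a, 0.05))
    else:
        water_mean = float(w.mean())
        air_mean = float(a.mean())
    if water_mean == air_mean:
        raise CalibrationError(
            f"water and air phantom means are equal ({water_mean}); "
            "cannot fix a linear map"
        )
    slope = 1000.0 / (water_mean - air_mean)
    intercept = -1000.0 * water_mean / (water_mean - air_mean)
    return HuMap(slope, intercept, water_mean, air_mean)


def apply_hu_map(vol: Volume, hu_map: HuMap) -> Volume:
    """Convert a raw-scale volume to HU voxelwise; geometry is unchanged."""
    if vol.intensity_scale == HU_SCALE:
        raise CalibrationError("volume is already in HU; refusing to calibrate twice")
    if vol.intensity_scale != RAW_SCALE:
        raise CalibrationError(f"unexpected intensity scale {vol.intensity_scale!r}")
    return vol.with_data(hu_map(vol.data.astype(float)), intensity_scale=HU_SCALE)


@dataclass(frozen=True)
class TubeSpec:
    """Geometry of a calibration tube: a cylinder parallel to axis 0.

    ``center_mm`` is the (axis1, axis2) world position of the tube axis;
    ``radius_mm`` is the inner (liquid/air column) radius.
    """

    center_mm: tuple[float, float]
    radius_mm: float


def extract_phantom_region(
    vol: Volume,
    tube: TubeSpec,
    erode_voxels: int = 2,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Return raw intensities from the core of a calibration tube.

    The sampled region is the tube's central cylinder eroded
    ``erode_voxels`` voxels inward from the wall so partial-volume rim
    voxels never enter the mean.  If ``mask`` is given it is honored
    verbatim instead of the analytic cylinder (for measured data where
    the tube was segmented by hand).
    """
    if mask is not None:
        vals = vol.data[np.asarray(mask, dtype=bool)]
        if vals.size == 0:
            raise CalibrationError("user-supplied phantom mask is empty")
        return vals
    vol.require_isotropic()
    r_eff = tube.radius_mm - erode_voxels * vol.spacing[1]
    if r_eff <= 0:
        raise CalibrationError(
            f"tube radius {tube.radius_mm} mm vanishes after eroding "
            f"{erode_voxels} voxels"
        )
    c1 = (np.arange(vol.shape[1]) * vol.spacing[1] + vol.origin[1]) - tube.center_mm[0]
    c2 = (np.arange(vol.shape[2]) * vol.spacing[2] + vol.origin[2]) - tube.center_mm[1]
    in_tube = (c1[:, None] ** 2 + c2[None, :] ** 2) <= r_eff**2
    if not in_tube.any():
        raise CalibrationError("phantom region empty after erosion")
    return vol.data[:, in_tube].ravel()
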