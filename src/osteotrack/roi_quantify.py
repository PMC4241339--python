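"""Tissue-band classification inside the propagated defect ROI.

Once every scan is calibrated to Hounsfield units and rigidly registered
to the day-0 reference, the day-0 defect ROI is carried to each timepoint
and its voxels are classified by absolute density:

* empty / soft-tissue reaction (e.g. hematoma): -1000 to +800 HU
* woven (immature) bone:                        +1200 to +1900 HU
* compact bone (comparable to intact cortex):   above +2700 HU

The bands deliberately leave gaps (+800..+1200 and +1900..+2700 HU);
voxels falling there are reported as an explicit ``unclassified``
fraction rather than silently re-binned, so the four fractions always
sum to one.  Healing at time t is the relative loss of soft-density
voxels, ``1 - soft(t)/soft(0)``, and summary times such as the day of
50% healing are read off the curve by linear interpolation between
scheduled scans.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.segmentation import flood

from .io_formats import Grid, GridMismatchError, HU_SCALE, RoiMask, Volume
from .registration import RigidTransform

SOFT, WOVEN, COMPACT, UNCLASSIFIED = "soft", "woven", "compact", "unclassified"
CLASS_NAMES = (SOFT, WOVEN, COMPACT, UNCLASSIFIED)


@dataclass(frozen=True)
class TissueBands:
    """HU classification bands; closed on the printed bounds, compact open-left."""

    soft: tuple[float, float] = (-1000.0, 800.0)
    woven: tuple[float, float] = (1200.0, 1900.0)
    compact_min: float = 2700.0

    def __post_init__(self) -> None:
        if not (self.soft[0] <= self.soft[1] < self.woven[0] <= self.woven[1] < self.compact_min):
            raise ValueError("tissue bands must be ordered and pairwise disjoint")

    def classify(self, hu: np.ndarray) -> np.ndarray:
        """Class codes per value: 0 soft, 1 woven, 2 compact, 3 unclassified."""
        hu = np.asarray(hu)
        cls = np.full(hu.shape, 3, dtype=np.int8)
        cls[(hu >= self.soft[0]) & (hu <= self.soft[1])] = 0
        cls[(hu >= self.woven[0]) & (hu <= self.woven[1])] = 1
        cls[hu > self.compact_min] = 2
        return cls


def classify_roi(
    vol: Volume, roi: RoiMask, bands: TissueBands | None = None
) -> tuple[int, int, int, int]:
    """Count ROI voxels per tissue band on an HU volume.

    Every ROI voxel lands in exactly one of soft/woven/compact/unclassified,
    so the four counts sum to the ROI size.
    """
    if vol.intensity_scale != HU_SCALE:
        raise ValueError("classification requires an HU-calibrated volume")
    roi.require_on_grid(vol)
    bands = bands or TissueBands()
    cls = bands.classify(vol.data[roi.data])
    counts = np.bincount(cls, minlength=4)
    return tuple(int(c) for c in counts)


@dataclass
class HealingSeries:
    """Per-timepoint tissue-class composition of the fixed day-0 ROI."""

    table: pd.DataFrame  # columns: day, n_soft..n_unclassified, frac_*, defect_volume_mm3
    roi_voxel_count: int
    voxel_volume: float  # mm^3

    @property
    def days(self) -> np.ndarray:
        return self.table["day"].to_numpy(dtype=float)

    def fractions(self, name: str) -> np.ndarray:
        return self.table[f"frac_{name}"].to_numpy(dtype=float)

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False, float_format="%.10g")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "roi_voxel_count": self.roi_voxel_count,
            "voxel_volume_mm3": self.voxel_volume,
            "timepoints": self.table.to_dict(orient="records"),
        }
        import json

        Path(path).write_text(json.dumps(payload, indent=1))


def _gather_roi_values(
    vol: Volume, roi_points_world: np.ndarray, transform: RigidTransform
) -> tuple[np.ndarray, np.ndarray]:
    """HU values at the ROI voxel centers mapped into ``vol``'s native grid.

    The day-0 ROI centers are pushed through the day-0 -> timepoint
    transform and snapped to the nearest voxel of the follow-up scan
    (nearest neighbor keeps counts integral and masks binary).  Returns
    (values, in_bounds); out-of-bounds samples carry no value.
    """
    idx = vol.grid.world_to_indices(transform.apply(roi_points_world))
    idx = np.rint(idx).astype(int)
    in_bounds = np.all((idx >= 0) & (idx < np.asarray(vol.shape)), axis=1)
    vals = vol.data[tuple(idx[in_bounds].T)]
    return vals, in_bounds


def healing_series(
    volumes_registered: list[Volume],
    roi_day0: RoiMask,
    transforms: list[RigidTransform],
    bands: TissueBands | None = None,
    days: list[float] | None = None,
    reference_grid: Grid | None = None,
) -> HealingSeries:
    """Classify the propagated day-0 ROI at every timepoint.

    Parameters
    ----------
    volumes_registered
        HU-calibrated scans in their native (unresampled) grids; the ROI
        is propagated *into* each of them, so their voxel values are
        classified untouched by interpolation.
    roi_day0
        Defect ROI delineated on the day-0 reference grid.
    transforms
        One day-0 -> timepoint rigid transform per volume (identity for
        the reference itself).
    days
        Scan days; defaults to 0..n-1 if omitted.
    reference_grid
        Grid the ROI lives on; defaults to the first volume's grid.

    The ROI voxel count is constant across timepoints — the region is
    fixed, its contents change.  Samples that land outside a scan are
    counted as unclassified and flagged in the table.
    """
    if len(volumes_registered) != len(transforms):
        raise ValueError(
            f"{len(volumes_registered)} volumes but {len(transforms)} transforms; "
            "need exactly one transform per timepoint"
        )
    if len(volumes_registered) == 0:
        raise ValueError("no volumes given")
    bands = bands or TissueBands()
    roi_day0.require_nonempty()
    grid = reference_grid or volumes_registered[0].grid
    if tuple(roi_day0.shape) != tuple(grid.shape):
        raise GridMismatchError(
            f"ROI shape {roi_day0.shape} does not match reference grid {grid.shape}"
        )
    if days is None:
        days = list(range(len(volumes_registered)))
    if len(days) != len(volumes_registered):
        raise ValueError("need one day per volume")

    roi_idx = np.argwhere(roi_day0.data)
    roi_pts = grid.indices_to_world(roi_idx)
    n_roi = roi_idx.shape[0]

    rows = []
    for day, vol, T in zip(days, volumes_registered, transforms):
        if vol.intensity_scale != HU_SCALE:
            raise ValueError("all volumes must be HU-calibrated")
        vals, in_bounds = _gather_roi_values(vol, roi_pts, T)
        counts = np.bincount(bands.classify(vals), minlength=4)
        n_oob = int(n_roi - in_bounds.sum())
        counts[3] += n_oob  # out-of-bounds voxels are unclassifiable
        frac = counts / n_roi
        rows.append(
            {
                "day": float(day),
                **{f"n_{n}": int(c) for n, c in zip(CLASS_NAMES, counts)},
                **{f"frac_{n}": f for n, f in zip(CLASS_NAMES, frac)},
                "n_out_of_bounds": n_oob,
                "defect_volume_mm3": float(counts[0]) * grid.voxel_volume,
            }
        )
    table = pd.DataFrame(rows)
    return HealingSeries(table, roi_voxel_count=n_roi, voxel_volume=grid.voxel_volume)


class DegenerateBaselineError(ValueError):
    """The day-0 soft fraction is zero, so relative healing is undefined."""


NOT_REACHED = float("nan")


def healing_curve(series: HealingSeries) -> np.ndarray:
    """Relative healing per timepoint: ``1 - soft(t) / soft(day 0)``."""
    soft = series.fractions(SOFT)
    if soft[0] <= 0:
        raise DegenerateBaselineError(
            "soft fraction at day 0 is zero; relative healing is undefined"
        )
    return 1.0 - soft / soft[0]


def time_to_healing(series: HealingSeries, level: float = 0.5) -> float:
    """First day at which relative healing crosses ``level``.

    Linear interpolation between adjacent scheduled scans; NaN when the
    level is never reached within the schedule.
    """
    if not 0 < level < 1:
        raise ValueError("healing level must be in (0, 1)")
    days = series.days
    if days[0] != 0:
        raise ValueError("healing series must start at day 0")
    h = healing_curve(series)
    if h[0] >= level:
        return float(days[0])
    for i in range(1, len(days)):
        if h[i] >= level:
            d0, d1, h0, h1 = days[i - 1], days[i], h[i - 1], h[i]
            if h1 == h0:
                return float(d1)
            return float(d0 + (level - h0) * (d1 - d0) / (h1 - h0))
    return NOT_REACHED


def suggest_defect_roi(
    vol: Volume,
    seed_index: tuple[int, int, int],
    hu_max: float = 800.0,
    max_radius_mm: float | None = None,
    reference_id: str = "",
) -> RoiMask:
    """Threshold-assisted helper for delineating the defect ROI.

    Region-grows from a seed voxel inside the freshly drilled defect over
    the connected sub-bone region (HU <= ``hu_max``), optionally clipped
    to a ball of ``max_radius_mm`` around the seed.  The result is a
    starting point meant for manual editing in an external viewer — the
    irregular contour against the cortical surface still needs an
    observer's judgment.
    """
    if vol.intensity_scale != HU_SCALE:
        raise ValueError("ROI suggestion requires an HU-calibrated volume")
    below = vol.data <= hu_max
    if not below[tuple(seed_index)]:
        raise ValueError(f"seed voxel {seed_index} is not below {hu_max} HU")
    grown = flood(below, tuple(seed_index), connectivity=1)
    if max_radius_mm is not None:
        seed_world = vol.grid.indices_to_world(np.asarray(seed_index, dtype=float))
        d = np.linalg.norm(
            vol.grid.voxel_centers() - seed_world, axis=-1
        )
        grown &= d <= max_radius_mm
    return RoiMask(grown, reference_id=reference_id)
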