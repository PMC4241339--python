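"""Synthetic longitudinal femur-defect series with exact ground truth.

No public scan data accompanies this kind of small-animal study, so the
pipeline is exercised end to end on simulated series instead.  The
generator emulates, in reconstructed image space, the features the
pipeline actually consumes:

* an idealized femoral shaft — a hollow compact-bone cylinder with a
  marrow-filled medullary cavity and a posterior longitudinal ridge
  (linea aspera analogue, which also breaks the rotational symmetry a
  plain cylinder would leave) — on an isotropic 116 um grid;
* a circular cortical defect of 1.1 mm diameter drilled through the
  anterior cortex, whose contents progress from soft-tissue density
  through woven bone to compact bone over the study;
* water and air calibration tubes co-scanned in the same field of view;
* a raw (pre-Hounsfield) detector intensity scale, additive Gaussian
  noise, and a random rigid pose perturbation per timepoint.

Everything stochastic is driven by one seeded generator, and every run
emits a :class:`GroundTruth` record (true pose per timepoint, true defect
mask, true per-class voxel fractions) so that calibration, registration,
ROI propagation and classification can each be checked for exact recovery.

Healing model
-------------
Healing of a drill defect proceeds centripetally: tissue matures at the
rim first and at the center last.  Defect voxels are ranked by distance
from the defect axis (rim first) and assigned a *conversion day* by
inverting a log-logistic filling curve

    F(t) = t^k / (t^k + t50^k)

so that the fraction of defect voxels that has left soft-tissue density
by day ``t`` is ``F(t)``: half the defect has converted at
``t = fill_halftime`` and ``F(0) = 0`` exactly (the defect is all soft
the day it is made).  Each voxel then advances soft -> woven at its
conversion day plus ``woven_onset`` and woven -> compact at conversion
day plus ``compact_onset``; staggering by conversion day produces the
rise-then-fall woven-bone transient seen in healing studies.  This
per-voxel densification path is a modeling stand-in — longitudinal CT
only observes the aggregate curves, not individual voxel trajectories.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .calibration import TubeSpec
from .io_formats import Grid, RAW_SCALE, RoiMask, Volume, write_nifti, write_mask
from .registration import RigidTransform

#: default post-surgery scan schedule (days)
DEFAULT_SCHEDULE = (0, 7, 14, 21, 30, 35, 44, 57, 78)

#: raw-intensity noise level (~= HU at the default acquisition gain) used
#: by the "moderate noise" study condition
MODERATE_NOISE_SD = 200.0


class GeometryError(ValueError):
    """Phantom geometry does not fit the requested grid."""


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry of the simulated femur, defect and calibration tubes (mm).

    The shaft axis runs along array axis 0 through the grid center; the
    defect is a cylinder along axis 1 through the anterior (+axis 1)
    cortex.  Calibration tubes run parallel to the shaft, offset along
    axis 2.
    """

    shaft_outer_radius: float = 0.9
    cortical_thickness: float = 0.25
    shaft_length: float = 8.0
    ridge_radius: float = 0.25  # posterior longitudinal ridge (linea aspera)
    defect_diameter: float = 1.1
    defect_center_offset: float = 0.0  # along the shaft axis
    voxel_spacing: float = 0.116
    grid_shape: tuple[int, int, int] = (128, 128, 128)
    tube_radius: float = 1.2
    tube_wall_thickness: float = 0.25
    tube_offset: float = 5.0  # tube axis distance from grid center, axis 2
    marrow_hu: float = 100.0
    cortical_hu: float = 3000.0
    tube_wall_hu: float = 1000.0
    margin_voxels: int = 5

    def __post_init__(self) -> None:
        if self.defect_diameter <= 0:
            raise GeometryError("defect diameter must be positive")
        if self.voxel_spacing <= 0:
            raise GeometryError("voxel spacing must be positive")
        if self.defect_diameter >= 2 * self.shaft_outer_radius:
            raise GeometryError(
                f"defect diameter {self.defect_diameter} mm does not fit a shaft "
                f"of outer radius {self.shaft_outer_radius} mm"
            )
        if self.cortical_thickness >= self.shaft_outer_radius:
            raise GeometryError("cortical thickness exceeds the shaft radius")
        half = np.asarray(self.grid_shape) / 2.0 * self.voxel_spacing
        margin = self.margin_voxels * self.voxel_spacing
        if self.shaft_length / 2.0 > half[0] - margin:
            raise GeometryError("shaft length does not fit grid axis 0 with margin")
        r_out = self.tube_radius + self.tube_wall_thickness
        if self.tube_offset + r_out > half[2] - margin:
            raise GeometryError("calibration tubes do not fit grid axis 2 with margin")
        if self.shaft_outer_radius > min(half[1], half[2]) - margin:
            raise GeometryError("shaft radius does not fit grid with margin")

    @property
    def grid(self) -> Grid:
        s = self.voxel_spacing
        return Grid(tuple(self.grid_shape), (s, s, s))

    @property
    def center(self) -> np.ndarray:
        return self.grid.center_world()

    def water_tube(self) -> TubeSpec:
        c = self.center
        return TubeSpec((float(c[1]), float(c[2] + self.tube_offset)), self.tube_radius)

    def air_tube(self) -> TubeSpec:
        c = self.center
        return TubeSpec((float(c[1]), float(c[2] - self.tube_offset)), self.tube_radius)


@dataclass(frozen=True)
class HealingTrajectory:
    """Parameters of the staged centripetal healing model (days, HU).

    ``fill_halftime`` is the day on which half the defect voxels have left
    soft-tissue density; ``fill_steepness`` is the dimensionless shape
    exponent of the log-logistic filling curve.  ``woven_onset`` /
    ``compact_onset`` are per-voxel lags (days after a voxel's conversion
    day) at which it reaches woven and compact density.  Target mean HU
    per class default to the middle of the classification bands.
    """

    fill_halftime: float = 11.0
    fill_steepness: float = 2.9
    woven_onset: float = 0.0
    compact_onset: float = 24.0
    soft_hu: float = -100.0
    woven_hu: float = 1550.0
    compact_hu: float = 3000.0

    def __post_init__(self) -> None:
        if self.fill_halftime <= 0:
            raise ValueError("fill_halftime must be positive")
        if self.fill_steepness <= 0:
            raise ValueError("fill_steepness must be positive")
        if not self.woven_onset <= self.compact_onset:
            raise ValueError("woven_onset must not exceed compact_onset")
        if not (-1000 < self.soft_hu <= 800):
            raise ValueError("soft_hu must lie in the soft-tissue band (-1000, 800]")
        if not (1200 <= self.woven_hu <= 1900):
            raise ValueError("woven_hu must lie in the woven-bone band [1200, 1900]")
        if not self.compact_hu > 2700:
            raise ValueError("compact_hu must lie in the compact-bone band (>2700)")

    @classmethod
    def unreamed(cls) -> "HealingTrajectory":
        """Drill defect healing spontaneously (50% fill ~day 11)."""
        return cls()

    @classmethod
    def reamed(cls) -> "HealingTrajectory":
        """Slower preset emulating intramedullary reaming (50% fill ~day 16)."""
        return cls(fill_halftime=16.0, fill_steepness=1.35, compact_onset=30.0)

    def fill_fraction(self, day: float | np.ndarray) -> float | np.ndarray:
        """Fraction of defect voxels no longer at soft density by ``day``."""
        t = np.asarray(day, dtype=float)
        k, t50 = self.fill_steepness, self.fill_halftime
        with np.errstate(divide="ignore"):
            out = np.where(t > 0, 1.0 / (1.0 + (t50 / np.maximum(t, 1e-300)) ** k), 0.0)
        return out if out.ndim else float(out)

    def fill_fraction_inverse(self, q: float | np.ndarray) -> float | np.ndarray:
        """Day at which the filled fraction reaches ``q`` (0 < q < 1)."""
        q = np.asarray(q, dtype=float)
        out = self.fill_halftime * (q / (1.0 - q)) ** (1.0 / self.fill_steepness)
        return out if out.ndim else float(out)


@dataclass(frozen=True)
class AcquisitionModel:
    """Detector intensity scale, noise and per-timepoint pose jitter.

    ``water_raw``/``air_raw`` are the raw intensities the scanner assigns
    to water and air; they anchor the session's two-point HU calibration.
    Pose jitter (uniform within the given bounds, drawn per timepoint)
    emulates repositioning the animal between sessions.
    """

    water_raw: float = 2000.0
    air_raw: float = 1000.0
    noise_sd: float = 0.0
    pose_jitter_max_rot: float = 0.0  # degrees
    pose_jitter_max_trans: float = 0.0  # mm
    seed: int = 0
    #: per-axis partial-volume subsampling of anatomy voxels; emulates the
    #: finite voxel integration of a real detector and keeps surface voxels
    #: from aliasing into hard steps.  Voxels whose centers lie inside the
    #: defect always carry their pure tissue-class value.
    supersample: int = 2

    def __post_init__(self) -> None:
        if self.water_raw == self.air_raw:
            raise ValueError("water_raw and air_raw must differ")
        if self.noise_sd < 0 or self.pose_jitter_max_rot < 0 or self.pose_jitter_max_trans < 0:
            raise ValueError("noise and jitter bounds must be nonnegative")

    def hu_to_raw(self, hu: np.ndarray) -> np.ndarray:
        return self.water_raw + np.asarray(hu) * (self.water_raw - self.air_raw) / 1000.0


@dataclass
class TimepointTruth:
    """Generative truth for one timepoint."""

    day: float
    transform: RigidTransform
    class_counts: tuple[int, int, int, int]  # soft, woven, compact, unclassified

    @property
    def fractions(self) -> tuple[float, float, float, float]:
        n = sum(self.class_counts)
        return tuple(c / n for c in self.class_counts)


@dataclass
class GroundTruth:
    """Full generative record for a simulated series."""

    days: list[float]
    timepoints: list[TimepointTruth]
    defect_mask: RoiMask
    spec: PhantomSpec
    trajectory: HealingTrajectory
    acquisition: AcquisitionModel

    @property
    def transforms(self) -> list[RigidTransform]:
        return [tp.transform for tp in self.timepoints]

    @property
    def fraction_table(self) -> np.ndarray:
        """Array (n_timepoints, 4) of soft/woven/compact/unclassified fractions."""
        return np.array([tp.fractions for tp in self.timepoints])

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "days": list(self.days),
                    "transforms": [tp.transform.to_dict() for tp in self.timepoints],
                    "class_counts": [list(tp.class_counts) for tp in self.timepoints],
                    "class_fractions": self.fraction_table.tolist(),
                    "defect_voxel_count": self.defect_mask.count,
                    "trajectory": vars(self.trajectory).copy(),
                    "acquisition": vars(self.acquisition).copy(),
                },
                indent=1,
            )
        )


# ---------------------------------------------------------------------------
# Geometry evaluation
# ---------------------------------------------------------------------------


def _defect_cyl_coords(
    pts: np.ndarray, spec: PhantomSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(radius, interleaved azimuth key, depth) in the defect-cylinder frame.

    The azimuth is wrapped several times around the circle before being
    used as a tie-break sort key, so voxels of equal radius convert in an
    interleaved, patchy order rather than as one contiguous arc — a
    contiguous sweep would polarize the partially healed defect
    azimuthally, which real centripetal healing does not do.
    """
    c = spec.center
    d0 = c[0] + spec.defect_center_offset
    rho = np.hypot(pts[:, 0] - d0, pts[:, 2] - c[2])
    theta = np.arctan2(pts[:, 2] - c[2], pts[:, 0] - d0)
    key = np.mod(theta * 9.5 + 1.0, 2.0 * np.pi)
    return rho, key, pts[:, 1].copy()


class _DefectModel:
    """Precomputed per-voxel conversion ranking of the defect region."""

    def __init__(self, spec: PhantomSpec):
        self.spec = spec
        grid = spec.grid
        pts = grid.voxel_centers().reshape(-1, 3)
        inside = _defect_membership(pts, spec)
        self.mask = inside.reshape(grid.shape)
        if not inside.any():
            raise GeometryError("defect region contains no voxel centers")
        self.rho, self.theta, self.depth = _defect_cyl_coords(pts[inside], spec)
        self.n = int(self.rho.size)

    def rank_fraction(self, pts: np.ndarray) -> np.ndarray:
        """Filled-fraction quantile at which each point converts.

        Rim-first ordering: a point's quantile is the fraction of defect
        voxels converting strictly before it (larger defect-axis radius;
        ties broken by azimuth, then by depth along the defect axis, so
        the per-voxel order is total) plus half a voxel.  Evaluating the
        rule at the canonical voxel centers reproduces the exact discrete
        ranking; arbitrary pose-jittered sample points interleave into
        the same ordering.
        """
        rho, theta, depth = _defect_cyl_coords(np.atleast_2d(pts), self.spec)
        before = np.zeros(rho.shape[0], dtype=np.int64)
        # chunked O(N_query x N_defect) comparison; both counts are small
        for lo in range(0, rho.shape[0], 4096):
            sl = slice(lo, lo + 4096)
            gt = self.rho[None, :] > rho[sl, None]
            eq_r = self.rho[None, :] == rho[sl, None]
            eq_rt = eq_r & (self.theta[None, :] == theta[sl, None])
            before[sl] = (
                gt
                | (eq_r & (self.theta[None, :] < theta[sl, None]))
                | (eq_rt & (self.depth[None, :] < depth[sl, None]))
            ).sum(axis=1)
        # pose-jittered samples can rank outside the canonical range;
        # clamp to the first/last voxel's quantile
        return np.clip((before + 0.5) / self.n, 0.5 / self.n, (self.n - 0.5) / self.n)

    def conversion_day(self, pts: np.ndarray, traj: HealingTrajectory) -> np.ndarray:
        return traj.fill_fraction_inverse(self.rank_fraction(pts))


def _defect_membership(pts: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    c = spec.center
    r_shaft = np.hypot(pts[:, 1] - c[1], pts[:, 2] - c[2])
    in_len = np.abs(pts[:, 0] - c[0]) <= spec.shaft_length / 2.0
    r_in = spec.shaft_outer_radius - spec.cortical_thickness
    in_cortex = (r_shaft >= r_in) & (r_shaft <= spec.shaft_outer_radius) & in_len
    d0 = c[0] + spec.defect_center_offset
    rho = np.hypot(pts[:, 0] - d0, pts[:, 2] - c[2])
    anterior = pts[:, 1] >= c[1]
    return in_cortex & anterior & (rho <= spec.defect_diameter / 2.0)


def _classify_defect_points(
    pts: np.ndarray, model: _DefectModel, traj: HealingTrajectory, day: float
) -> np.ndarray:
    """Class codes for defect points: 0 soft, 1 woven, 2 compact."""
    conv = model.conversion_day(pts, traj)
    cls = np.zeros(conv.shape, dtype=np.int8)
    cls[day >= conv + traj.woven_onset] = 1
    cls[day >= conv + traj.compact_onset] = 2
    return cls


def _tubes_hu(pts: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    """HU of the static scene: air background plus calibration tubes.

    The tubes sit in the scanner bed, so they stay in the scanner frame;
    only the animal is repositioned between sessions.
    """
    hu = np.full(pts.shape[0], -1000.0)
    # water at +axis2, air at -axis2, each with a plastic wall
    for tube, fill in ((spec.water_tube(), 0.0), (spec.air_tube(), -1000.0)):
        d = np.hypot(pts[:, 1] - tube.center_mm[0], pts[:, 2] - tube.center_mm[1])
        r_out = tube.radius_mm + spec.tube_wall_thickness
        hu[d <= r_out] = spec.tube_wall_hu
        hu[d <= tube.radius_mm] = fill
    return hu


def _anatomy_hu(
    pts: np.ndarray, spec: PhantomSpec, traj: HealingTrajectory,
    model: _DefectModel, day: float
) -> tuple[np.ndarray, np.ndarray]:
    """(HU values, membership mask) of the femur at world points ``(N, 3)``."""
    c = spec.center
    hu = np.full(pts.shape[0], -1000.0)
    inside = np.zeros(pts.shape[0], dtype=bool)

    r_shaft = np.hypot(pts[:, 1] - c[1], pts[:, 2] - c[2])
    in_len = np.abs(pts[:, 0] - c[0]) <= spec.shaft_length / 2.0
    r_in = spec.shaft_outer_radius - spec.cortical_thickness
    in_marrow = (r_shaft < r_in) & in_len
    hu[in_marrow] = spec.marrow_hu
    in_cortex = (r_shaft >= r_in) & (r_shaft <= spec.shaft_outer_radius) & in_len
    hu[in_cortex] = spec.cortical_hu
    inside |= in_marrow | in_cortex
    if spec.ridge_radius > 0:
        # posterior longitudinal ridge (linea aspera analogue): without it a
        # hollow cylinder leaves the rotation about the shaft axis
        # unconstrained for the registration stage
        r_ridge = np.hypot(
            pts[:, 1] - (c[1] - spec.shaft_outer_radius), pts[:, 2] - c[2]
        )
        in_ridge = (r_ridge <= spec.ridge_radius) & in_len
        hu[in_ridge] = spec.cortical_hu
        inside |= in_ridge

    in_defect = _defect_membership(pts, spec)
    if in_defect.any():
        cls = _classify_defect_points(pts[in_defect], model, traj, day)
        hu[in_defect] = np.choose(cls, (traj.soft_hu, traj.woven_hu, traj.compact_hu))
        inside |= in_defect
    return hu, inside


def true_class_counts(
    spec: PhantomSpec,
    traj: HealingTrajectory,
    day: float,
    model: _DefectModel | None = None,
) -> tuple[int, int, int, int]:
    """Exact (soft, woven, compact, unclassified) counts of defect voxels at ``day``."""
    model = model or _DefectModel(spec)
    grid = spec.grid
    pts = grid.voxel_centers().reshape(-1, 3)[model.mask.ravel()]
    cls = _classify_defect_points(pts, model, traj, day)
    counts = np.bincount(cls, minlength=3)
    return (int(counts[0]), int(counts[1]), int(counts[2]), 0)


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------


def _draw_jitter(acq: AcquisitionModel, rng: np.random.Generator, center) -> RigidTransform:
    rot = rng.uniform(-acq.pose_jitter_max_rot, acq.pose_jitter_max_rot, 3)
    tra = rng.uniform(-acq.pose_jitter_max_trans, acq.pose_jitter_max_trans, 3)
    return RigidTransform(tuple(rot), tuple(tra), tuple(center))


def generate_timepoint(
    spec: PhantomSpec,
    traj: HealingTrajectory,
    acq: AcquisitionModel,
    day: float,
    transform: RigidTransform | None = None,
    rng: np.random.Generator | None = None,
    _model: _DefectModel | None = None,
) -> tuple[Volume, TimepointTruth]:
    """Render one raw-intensity scan at ``day`` plus its generative truth.

    ``transform`` is the true pose of the *animal* in this scan relative
    to the canonical (day-0) frame, i.e. the transform registration
    should recover; if omitted it is drawn uniformly within the
    acquisition jitter bounds.  The calibration tubes sit in the scanner
    bed and are rendered in the static scanner frame.  The phantom is
    evaluated analytically at the pose-transformed voxel centers, so
    rendering introduces no interpolation of its own.
    """
    if day < 0:
        raise ValueError("day must be nonnegative")
    rng = rng if rng is not None else np.random.default_rng(acq.seed)
    model = _model or _DefectModel(spec)
    grid = spec.grid
    if transform is None:
        transform = _draw_jitter(acq, rng, grid.center_world())

    pts = grid.voxel_centers().reshape(-1, 3)
    hu = _tubes_hu(pts, spec)
    inv = transform.inverse() if not transform.is_identity else None

    # partial-volume anatomy rendering: average the analytic phantom over
    # a subvoxel grid so surfaces become consistent ramps instead of
    # pose-dependent hard steps
    s = max(1, int(acq.supersample))
    offsets_1d = ((np.arange(s) + 0.5) / s - 0.5) * spec.voxel_spacing
    acc = np.zeros(pts.shape[0])
    any_inside = np.zeros(pts.shape[0], dtype=bool)
    for o0 in offsets_1d:
        for o1 in offsets_1d:
            for o2 in offsets_1d:
                p = pts + np.array([o0, o1, o2])
                ap = inv.apply(p) if inv is not None else p
                sub_hu, inside = _anatomy_hu(ap, spec, traj, model, day)
                acc += np.where(inside, sub_hu, -1000.0)
                any_inside |= inside
    hu[any_inside] = acc[any_inside] / s**3

    # voxels whose centers fall in the defect keep their pure class value,
    # so ROI classification of the rendered volume matches the generative
    # truth voxel for voxel
    cp = inv.apply(pts) if inv is not None else pts
    in_defect = _defect_membership(cp, spec)
    if in_defect.any():
        cls = _classify_defect_points(cp[in_defect], model, traj, day)
        hu[in_defect] = np.choose(cls, (traj.soft_hu, traj.woven_hu, traj.compact_hu))

    raw = acq.hu_to_raw(hu)
    if acq.noise_sd > 0:
        raw = raw + rng.normal(0.0, acq.noise_sd, size=raw.shape)
    vol = Volume(raw.reshape(grid.shape), grid.spacing, RAW_SCALE, grid.origin)
    truth = TimepointTruth(
        day=day,
        transform=transform,
        class_counts=true_class_counts(spec, traj, day, model),
    )
    return vol, truth


def generate_series(
    spec: PhantomSpec,
    traj: HealingTrajectory,
    acq: AcquisitionModel,
    schedule: tuple[float, ...] = DEFAULT_SCHEDULE,
) -> tuple[list[Volume], GroundTruth]:
    """Render a full longitudinal series on a fixed scan schedule.

    The schedule must be strictly increasing and start at day 0 (the
    post-surgery reference scan, whose pose is the identity by
    definition).  A fixed ``acq.seed`` makes the output bit-identical
    across calls: pose jitters for all timepoints are drawn first, then
    noise fields in schedule order, from one seeded generator.
    """
    schedule = tuple(float(d) for d in schedule)
    if len(schedule) == 0:
        raise ValueError("scan schedule is empty")
    if schedule[0] != 0:
        raise ValueError("scan schedule must start at day 0 (the reference scan)")
    if any(b <= a for a, b in zip(schedule, schedule[1:])):
        raise ValueError("scan schedule must be strictly increasing")

    rng = np.random.default_rng(acq.seed)
    model = _DefectModel(spec)
    center = spec.grid.center_world()
    transforms = [RigidTransform(center_mm=tuple(center))]
    transforms += [_draw_jitter(acq, rng, center) for _ in schedule[1:]]

    volumes: list[Volume] = []
    timepoints: list[TimepointTruth] = []
    for day, T in zip(schedule, transforms):
        vol, truth = generate_timepoint(
            spec, traj, acq, day, transform=T, rng=rng, _model=model
        )
        volumes.append(vol)
        timepoints.append(truth)

    defect_mask = RoiMask(model.mask, reference_id="day0")
    gt = GroundTruth(
        days=list(schedule),
        timepoints=timepoints,
        defect_mask=defect_mask,
        spec=spec,
        trajectory=traj,
        acquisition=acq,
    )
    return volumes, gt


def write_series(
    volumes: list[Volume], truth: GroundTruth, outdir: str | Path
) -> dict[str, Path]:
    """Write a simulated series to disk: NIfTI volumes, defect mask, truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for day, vol in zip(truth.days, volumes):
        p = outdir / f"scan_day{int(day):03d}.nii.gz"
        write_nifti(vol, p)
        paths[f"day{int(day)}"] = p
    mask_path = outdir / "defect_mask_day0.nii.gz"
    write_mask(truth.defect_mask, volumes[0].grid, mask_path)
    paths["defect_mask"] = mask_path
    truth_path = outdir / "ground_truth.json"
    truth.to_json(truth_path)
    paths["ground_truth"] = truth_path
    return paths
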