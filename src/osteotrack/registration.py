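"""Rigid-body alignment of follow-up femur scans to the day-0 reference.

Every follow-up volume is registered to the day-0 post-surgery femur with
a 6-degree-of-freedom rigid transform (3 rotations + 3 translations), so
the 3-D ROI drawn once on day 0 stays anatomically valid at every later
timepoint.  The registration is intensity based: mean squared difference
(optionally normalized cross-correlation) minimized over a 3-level
multi-resolution pyramid with Powell's derivative-free optimizer.

Transform convention
--------------------
A :class:`RigidTransform` maps *fixed*-space (day-0) world coordinates to
*moving*-space world coordinates:

    y = R (x - c) + c + t

with ``R = R0(a0) @ R1(a1) @ R2(a2)`` (intrinsic rotations about world
axes 0, 1, 2 applied in that order, angles in degrees), rotation center
``c`` (mm, by default the fixed volume's geometric center) and
translation ``t`` (mm).  Resampling a moving volume onto the fixed grid
therefore evaluates ``moving(T(x))`` at each fixed voxel ``x``, and
propagating a day-0 ROI into a follow-up scan maps each ROI voxel center
through ``T`` directly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage, optimize

from .io_formats import Grid, HU_SCALE, RoiMask, Volume

AIR_HU = -1000.0


class EmptyExtractionError(ValueError):
    """No voxel exceeded the bone threshold during femur extraction."""


def _axis_rotation(axis: int, angle_deg: float) -> np.ndarray:
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    m = np.eye(3)
    i, j = [(1, 2), (0, 2), (0, 1)][axis]
    m[i, i] = c
    m[j, j] = c
    # sign chosen so rotations are right-handed about the +axis direction
    if axis == 1:
        m[i, j] = s
        m[j, i] = -s
    else:
        m[i, j] = -s
        m[j, i] = s
    return m


@dataclass(frozen=True)
class RigidTransform:
    """6-parameter rigid map between volume world coordinates (see module docs)."""

    rotations_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translation_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    ROTATION_ORDER = "intrinsic axes 0,1,2"

    @property
    def rotation_matrix(self) -> np.ndarray:
        r0, r1, r2 = self.rotations_deg
        return _axis_rotation(0, r0) @ _axis_rotation(1, r1) @ _axis_rotation(2, r2)

    def to_matrix(self) -> np.ndarray:
        """Homogeneous 4x4 matrix acting on world coordinates."""
        R = self.rotation_matrix
        c = np.asarray(self.center_mm)
        t = np.asarray(self.translation_mm)
        m = np.eye(4)
        m[:3, :3] = R
        m[:3, 3] = c + t - R @ c
        return m

    @classmethod
    def from_matrix(
        cls, m: np.ndarray, center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    ) -> "RigidTransform":
        R = np.asarray(m)[:3, :3]
        if abs(np.linalg.det(R) - 1.0) > 1e-6:
            raise ValueError("matrix rotation block is not a proper rotation")
        # extract intrinsic 0-1-2 angles from R = R0 R1 R2
        r1 = np.arcsin(np.clip(R[0, 2], -1.0, 1.0))
        if abs(np.cos(r1)) > 1e-9:
            r0 = np.arctan2(-R[1, 2], R[2, 2])
            r2 = np.arctan2(-R[0, 1], R[0, 0])
        else:  # gimbal lock: fold axis-2 rotation into axis-0
            r0 = np.arctan2(R[2, 1], R[1, 1])
            r2 = 0.0
        angles = tuple(np.rad2deg((r0, r1, r2)))
        c = np.asarray(center_mm, dtype=float)
        t = np.asarray(m)[:3, 3] - c + R @ c
        return cls(angles, tuple(t), tuple(c))

    def apply(self, pts: np.ndarray) -> np.ndarray:
        """Map world points, shape ``(..., 3)``."""
        pts = np.asarray(pts, dtype=float)
        c = np.asarray(self.center_mm)
        t = np.asarray(self.translation_mm)
        return (pts - c) @ self.rotation_matrix.T + c + t

    def inverse(self) -> "RigidTransform":
        return RigidTransform.from_matrix(np.linalg.inv(self.to_matrix()), self.center_mm)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform ``x -> self(other(x))``."""
        return RigidTransform.from_matrix(
            self.to_matrix() @ other.to_matrix(), self.center_mm
        )

    @property
    def is_identity(self) -> bool:
        return np.allclose(self.rotations_deg, 0, atol=1e-12) and np.allclose(
            self.translation_mm, 0, atol=1e-12
        )

    def to_dict(self) -> dict:
        return {
            "rotations_deg": list(self.rotations_deg),
            "translation_mm": list(self.translation_mm),
            "center_mm": list(self.center_mm),
            "rotation_order": self.ROTATION_ORDER,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        if d.get("rotation_order", cls.ROTATION_ORDER) != cls.ROTATION_ORDER:
            raise ValueError(f"unsupported rotation order {d['rotation_order']!r}")
        return cls(
            tuple(d["rotations_deg"]), tuple(d["translation_mm"]), tuple(d["center_mm"])
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "RigidTransform":
        return cls.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Femur extraction
# ---------------------------------------------------------------------------


def extract_femur(
    vol: Volume, bone_threshold: float = 1200.0, margin: int = 10
) -> tuple[Volume, tuple[slice, slice, slice]]:
    """Crop the largest bone-intensity connected component to a padded box.

    Thresholding at ``bone_threshold`` (HU) and keeping the largest 26-connected
    component isolates the femur from calibration tubes and soft tissue;
    the smallest axis-aligned bounding box is padded by ``margin`` voxels
    (clipped to the volume) and cropped out with an adjusted origin.
    """
    labels, n = ndimage.label(vol.data > bone_threshold, structure=np.ones((3, 3, 3)))
    if n == 0:
        raise EmptyExtractionError(
            f"no voxel above bone threshold {bone_threshold}; nothing to extract"
        )
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    largest = int(np.argmax(sizes)) + 1
    bbox = ndimage.find_objects(labels)[largest - 1]
    slices = tuple(
        slice(max(0, s.start - margin), min(dim, s.stop + margin))
        for s, dim in zip(bbox, vol.shape)
    )
    origin = tuple(
        vol.origin[a] + slices[a].start * vol.spacing[a] for a in range(3)
    )
    cropped = Volume(
        vol.data[slices].copy(), vol.spacing, vol.intensity_scale, origin
    )
    return cropped, slices


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------


def resample(
    vol: Volume,
    transform: RigidTransform,
    target: Grid | Volume,
    interpolation: str = "trilinear",
    fill_value: float | None = None,
) -> Volume:
    """Resample ``vol`` onto ``target``'s grid through ``transform``.

    ``output(x) = vol(transform(x))`` for every target voxel center ``x``.
    Voxels mapping outside the source domain are filled with air
    (-1000 HU) for image volumes and 0 otherwise; masks must use
    ``interpolation="nearest"`` to stay binary.
    """
    grid = target.grid if isinstance(target, Volume) else target
    if interpolation == "trilinear":
        order = 1
    elif interpolation == "nearest":
        order = 0
    else:
        raise ValueError(f"unknown interpolation mode {interpolation!r}")
    if fill_value is None:
        fill_value = AIR_HU if vol.intensity_scale == HU_SCALE else 0.0
    pts = grid.voxel_centers().reshape(-1, 3)
    src_idx = vol.grid.world_to_indices(transform.apply(pts))
    out = ndimage.map_coordinates(
        vol.data.astype(float),
        src_idx.T,
        order=order,
        mode="constant",
        cval=fill_value,
    ).reshape(grid.shape)
    return Volume(out, grid.spacing, vol.intensity_scale, grid.origin)


def resample_mask(
    mask: RoiMask, mask_grid: Grid, transform: RigidTransform, target: Grid | Volume
) -> RoiMask:
    """Nearest-neighbor mask resampling; output is binary by construction."""
    vol = Volume(mask.data.astype(float), mask_grid.spacing, "raw", mask_grid.origin)
    out = resample(vol, transform, target, interpolation="nearest", fill_value=0.0)
    return RoiMask(out.data > 0.5, reference_id=mask.reference_id)


# ---------------------------------------------------------------------------
# Registration
# ---------------------------------------------------------------------------


@dataclass
class RegistrationConfig:
    """Settings for intensity-based rigid registration.

    The optimizer runs coarse to fine over a ``pyramid_levels``-level
    image pyramid (local-mean downsampling by ``downsample`` per level).
    Powell line searches start with steps of ``initial_step_deg`` /
    ``initial_step_mm``, halved at each finer level, and terminate at
    ``xtol`` (in degrees/mm) per level.
    """

    metric: str = "msd"  # "msd" | "ncc"
    pyramid_levels: int = 3
    downsample: int = 2
    smoothing_sigma: float = 1.5  # Gaussian sigma in voxels, applied per level
    initial_step_deg: float = 2.0
    initial_step_mm: float = 1.0
    xtol: float = 1e-3
    ftol: float = 1e-9
    maxiter: int = 40
    fill_value: float = AIR_HU
    initial: RigidTransform | None = None
    # Long bones are nearly rotation-symmetric about their shaft (axis 0),
    # so that angle has a shallow, multi-welled cost profile along which
    # the coarsest level can drift arbitrarily.  Before the optimizer runs
    # at the first refined level the axial angle is therefore scanned over
    # the full circle, and over +/-sweep_fine_half_range_deg at later
    # levels, restarting from the best value.  Set sweep_axis=None to
    # disable.
    sweep_axis: int | None = 0
    sweep_half_range_deg: float = 180.0
    sweep_fine_half_range_deg: float = 10.0
    sweep_step_deg: float = 2.0
    # The metric is evaluated only inside a dilated neighborhood of the
    # fixed image's bone so that static off-animal structures (scanner
    # bed, calibration phantoms) never enter the fit; set
    # metric_mask_dilation_mm=None to sample the whole fixed volume.
    metric_mask_threshold: float = 1200.0  # HU
    metric_mask_dilation_mm: float | None = 0.7


@dataclass
class RegistrationResult:
    transform: RigidTransform
    final_metric: float
    converged: bool
    pyramid_levels_used: int
    metric_per_level: list = field(default_factory=list)


def _downsample_volume(vol: Volume, factor: int) -> Volume:
    """Local-mean block downsampling; trailing non-divisible voxels are trimmed."""
    if factor == 1:
        return vol
    shape = tuple((s // factor) * factor for s in vol.shape)
    if min(shape) == 0:
        return vol
    d = vol.data[: shape[0], : shape[1], : shape[2]]
    d = d.reshape(
        shape[0] // factor, factor, shape[1] // factor, factor, shape[2] // factor, factor
    ).mean(axis=(1, 3, 5))
    spacing = tuple(s * factor for s in vol.spacing)
    # block centers: origin moves to the mean position of the first block
    origin = tuple(
        vol.origin[a] + (factor - 1) / 2.0 * vol.spacing[a] for a in range(3)
    )
    return Volume(d, spacing, vol.intensity_scale, origin)


def _bump(x: np.ndarray, axis: int, delta: float) -> np.ndarray:
    out = x.copy()
    out[axis] += delta
    return out


def _metric_values(kind: str, fixed_vals: np.ndarray, moving_vals: np.ndarray) -> float:
    if kind == "msd":
        return float(np.mean((moving_vals - fixed_vals) ** 2))
    if kind == "ncc":
        f = fixed_vals - fixed_vals.mean()
        m = moving_vals - moving_vals.mean()
        denom = np.sqrt((f @ f) * (m @ m))
        if denom == 0:
            return 1.0
        return float(1.0 - (f @ m) / denom)
    raise ValueError(f"unknown metric {kind!r}")


def register_rigid(
    moving: Volume, fixed: Volume, config: RegistrationConfig | None = None
) -> RegistrationResult:
    """Estimate the rigid transform mapping fixed coordinates onto ``moving``.

    Both volumes must be HU-calibrated and isotropic.  The fixed volume —
    in this pipeline the extracted day-0 reference femur — defines the
    sample domain and the rotation center (its geometric center).  On
    success ``resample(moving, result.transform, fixed.grid)`` aligns the
    moving scan with the reference.

    Non-convergence (the optimizer failing, or the final metric exceeding
    the identity-transform metric) is flagged in the result rather than
    raised; the best transform found is still returned.
    """
    config = config or RegistrationConfig()
    for v, name in ((moving, "moving"), (fixed, "fixed")):
        if v.intensity_scale != HU_SCALE:
            raise ValueError(f"{name} volume must be HU-calibrated before registration")
        v.require_isotropic()

    center = tuple(fixed.grid.center_world())
    if config.initial is not None:
        x = np.concatenate(
            [config.initial.rotations_deg, config.initial.translation_mm]
        ).astype(float)
    else:
        x = np.zeros(6)

    levels = list(range(config.pyramid_levels - 1, -1, -1))
    metric_per_level: list[float] = []
    converged = True
    initial_full_metric: float | None = None

    for li, level in enumerate(levels):
        factor = config.downsample**level
        fx = _downsample_volume(fixed, factor)
        mv = _downsample_volume(moving, factor)
        fixed_pts = fx.grid.voxel_centers().reshape(-1, 3)
        fixed_arr = fx.data.astype(float)
        mv_data = mv.data.astype(float)
        if config.smoothing_sigma > 0:
            # band-limit both images so the metric is smooth in the pose
            # parameters; without this, edge aliasing drowns the minimum
            fixed_arr = ndimage.gaussian_filter(fixed_arr, config.smoothing_sigma)
            mv_data = ndimage.gaussian_filter(mv_data, config.smoothing_sigma)
        fixed_vals = fixed_arr.ravel()
        if config.metric_mask_dilation_mm is not None:
            bone = fx.data > config.metric_mask_threshold
            if bone.any():
                dist = ndimage.distance_transform_edt(~bone, sampling=fx.spacing)
                sel = (dist <= config.metric_mask_dilation_mm).ravel()
                fixed_pts = fixed_pts[sel]
                fixed_vals = fixed_vals[sel]
        mv_grid = mv.grid

        def cost(params: np.ndarray) -> float:
            T = RigidTransform(tuple(params[:3]), tuple(params[3:]), center)
            idx = mv_grid.world_to_indices(T.apply(fixed_pts))
            vals = ndimage.map_coordinates(
                mv_data, idx.T, order=1, mode="constant", cval=config.fill_value
            )
            return _metric_values(config.metric, fixed_vals, vals)

        if level == 0 and initial_full_metric is None:
            initial_full_metric = cost(np.zeros(6))

        def axial_sweep(x: np.ndarray, half: float) -> tuple[np.ndarray, float]:
            """Spin the anatomy about the fixed volume's symmetry axis.

            Candidates pre-compose the current transform with a rotation
            about axis ``sweep_axis`` through the fixed center; varying
            the raw Euler component instead would also tilt the shaft
            because the angle parameters interact.
            """
            offsets = np.arange(-half, half + 1e-9, config.sweep_step_deg)
            cur = RigidTransform(tuple(x[:3]), tuple(x[3:]), center)
            best_x, best_c, best_d = x, cost(x), 0.0
            for delta in offsets:
                spin = [0.0, 0.0, 0.0]
                spin[config.sweep_axis] = float(delta)
                cand = cur.compose(RigidTransform(tuple(spin), center_mm=center))
                xc = np.concatenate([cand.rotations_deg, cand.translation_mm])
                cc = cost(xc)
                if cc < best_c:
                    best_x, best_c, best_d = xc, cc, float(delta)
            return np.asarray(best_x, dtype=float), best_d

        step = 0.5**li
        direc = np.diag(
            [config.initial_step_deg * step] * 3 + [config.initial_step_mm * step] * 3
        )
        sweeping = config.sweep_axis is not None and li > 0
        # alternate sweep and local optimization: after a large spin the
        # remaining parameters need re-optimizing before the sweep can
        # judge the axial angle fairly
        for attempt in range(3 if sweeping else 1):
            moved = 0.0
            if sweeping:
                half = (
                    config.sweep_half_range_deg
                    if li == 1
                    else config.sweep_fine_half_range_deg
                )
                x, moved = axial_sweep(x, half)
            res = optimize.minimize(
                cost,
                x,
                method="Powell",
                options={
                    "direc": direc,
                    "xtol": config.xtol,
                    "ftol": config.ftol,
                    "maxiter": config.maxiter,
                },
            )
            if not res.success and res.status != 1:  # status 1 = maxiter reached
                converged = False
            x = np.asarray(res.x, dtype=float)
            if not sweeping or abs(moved) <= config.sweep_step_deg:
                break
        metric_per_level.append(float(res.fun))

    final_metric = metric_per_level[-1]
    if initial_full_metric is not None and final_metric > initial_full_metric + 1e-12:
        converged = False
    transform = RigidTransform(tuple(x[:3]), tuple(x[3:]), center)
    return RegistrationResult(
        transform=transform,
        final_metric=final_metric,
        converged=converged,
        pyramid_levels_used=len(levels),
        metric_per_level=metric_per_level,
    )
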