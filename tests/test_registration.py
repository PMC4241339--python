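"""Rigid transforms, femur extraction, resampling and registration."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from osteotrack import (
    AcquisitionModel,
    HealingTrajectory,
    extract_femur,
    generate_timepoint,
    register_rigid,
    resample,
    resample_mask,
)
from osteotrack.io_formats import Volume
from osteotrack.registration import EmptyExtractionError, RigidTransform

from conftest import calibrate_volume

angles = st.floats(-45.0, 45.0)
shifts = st.floats(-3.0, 3.0)


class TestRigidTransform:
    @given(
        r=st.tuples(angles, angles, angles),
        t=st.tuples(shifts, shifts, shifts),
    )
    def test_compose_with_inverse_is_identity(self, r, t):
        T = RigidTransform(r, t, center_mm=(1.0, 2.0, 3.0))
        I = T.compose(T.inverse())
        np.testing.assert_allclose(I.to_matrix(), np.eye(4), atol=1e-9)

    @given(
        r=st.tuples(angles, angles, angles),
        t=st.tuples(shifts, shifts, shifts),
    )
    def test_matrix_round_trip(self, r, t):
        T = RigidTransform(r, t, center_mm=(0.5, -1.0, 2.0))
        back = RigidTransform.from_matrix(T.to_matrix(), T.center_mm)
        np.testing.assert_allclose(back.to_matrix(), T.to_matrix(), atol=1e-9)

    def test_apply_matches_matrix(self):
        T = RigidTransform((10.0, -5.0, 3.0), (0.3, -0.2, 0.1), (1.0, 1.0, 1.0))
        pts = np.random.default_rng(0).normal(size=(20, 3))
        hom = np.c_[pts, np.ones(20)] @ T.to_matrix().T
        np.testing.assert_allclose(T.apply(pts), hom[:, :3], atol=1e-12)

    def test_json_round_trip(self, tmp_path):
        T = RigidTransform((1.0, 2.0, 3.0), (0.1, 0.2, 0.3), (5.0, 5.0, 5.0))
        T.to_json(tmp_path / "t.json")
        assert RigidTransform.from_json(tmp_path / "t.json") == T

    def test_identity_flag(self):
        assert RigidTransform().is_identity
        assert not RigidTransform((0.1, 0, 0)).is_identity


class TestExtractFemur:
    def test_uniform_water_volume_errors(self):
        vol = Volume(np.zeros((10, 10, 10)), 0.116, intensity_scale="HU")
        with pytest.raises(EmptyExtractionError):
            extract_femur(vol, 1200.0)

    def test_box_contains_generated_cortex(self, clean_series_hu, small_spec):
        volumes_hu, _ = clean_series_hu
        cropped, box = extract_femur(volumes_hu[0], 1200.0)
        # the cropped volume must contain every bone voxel of the original
        bone = volumes_hu[0].data > 1200.0
        assert bone[box].sum() == bone.sum()
        assert cropped.origin != volumes_hu[0].origin

    def test_larger_of_two_bones_extracted(self):
        data = np.zeros((20, 10, 10))
        data[2:5, 2:5, 2:5] = 3000.0  # small blob
        data[10:18, 2:8, 2:8] = 3000.0  # large blob
        vol = Volume(data, 0.116, intensity_scale="HU")
        _, box = extract_femur(vol, 1200.0, margin=0)
        assert box[0].start == 10 and box[0].stop == 18


class TestResample:
    def test_identity_nearest_bit_exact(self, clean_series_hu):
        vol = clean_series_hu[0][0]
        out = resample(vol, RigidTransform(), vol.grid, interpolation="nearest")
        np.testing.assert_array_equal(out.data, vol.data)

    def test_identity_trilinear_close(self, clean_series_hu):
        vol = clean_series_hu[0][0]
        out = resample(vol, RigidTransform(), vol.grid, interpolation="trilinear")
        np.testing.assert_allclose(out.data, vol.data, atol=1e-6)

    def test_unknown_interpolation(self, clean_series_hu):
        vol = clean_series_hu[0][0]
        with pytest.raises(ValueError, match="interpolation"):
            resample(vol, RigidTransform(), vol.grid, interpolation="cubic")

    def test_out_of_domain_filled_with_air(self, clean_series_hu):
        vol = clean_series_hu[0][0]
        T = RigidTransform(translation_mm=(1000.0, 0.0, 0.0))
        out = resample(vol, T, vol.grid)
        assert (out.data == -1000.0).all()

    def test_forward_then_inverse_within_blur(self, clean_series_hu):
        vol = clean_series_hu[0][0]
        T = RigidTransform((3.0, 0.0, 0.0), (0.2, 0.1, 0.0), vol.grid.center_world())
        once = resample(vol, T, vol.grid)
        back = resample(once, T.inverse(), vol.grid)
        core = (slice(10, -10),) * 3
        # interpolation blur: most voxels round-trip, edges smear
        frac_close = np.mean(np.abs(back.data[core] - vol.data[core]) < 300.0)
        assert frac_close > 0.9

    def test_mask_resample_stays_binary(self, clean_series_hu):
        vol = clean_series_hu[0][0]
        truth_mask = clean_series_hu[1].defect_mask
        T = RigidTransform((2.0, 1.0, 0.0), (0.1, 0.0, 0.05), vol.grid.center_world())
        out = resample_mask(truth_mask, vol.grid, T, vol.grid)
        assert out.data.dtype == bool


@pytest.fixture(scope="module")
def reg_reference(reg_spec):
    traj = HealingTrajectory.unreamed()
    acq = AcquisitionModel(seed=0)
    center = tuple(reg_spec.grid.center_world())
    vol, _ = generate_timepoint(
        reg_spec, traj, acq, 0.0, transform=RigidTransform(center_mm=center)
    )
    hu = calibrate_volume(vol, reg_spec)
    ref, _ = extract_femur(hu, 1200.0)
    return ref, center, traj, acq


class TestRegisterRigid:
    def test_self_registration_is_identity(self, reg_reference):
        ref, center, traj, acq = reg_reference
        res = register_rigid(ref, ref)
        assert res.converged
        assert res.final_metric < 1.0
        assert np.max(np.abs(res.transform.rotations_deg)) < 0.1
        assert np.max(np.abs(res.transform.translation_mm)) < 0.05 * 0.116

    def test_pure_translation_two_voxels(self, reg_reference, reg_spec):
        ref, center, traj, acq = reg_reference
        tru = RigidTransform(translation_mm=(0.0, 0.232, 0.0), center_mm=center)
        moving, _ = generate_timepoint(reg_spec, traj, acq, 0.0, transform=tru)
        res = register_rigid(calibrate_volume(moving, reg_spec), ref)
        est = RigidTransform.from_matrix(res.transform.to_matrix(), center)
        err = np.abs(np.array(est.translation_mm) - (0.0, 0.232, 0.0))
        assert err.max() <= 0.5 * 0.116  # within half a voxel

    def test_known_jitter_recovered(self, reg_reference, reg_spec):
        ref, center, traj, acq = reg_reference
        tru = RigidTransform((5.0, -2.0, 3.0), (0.5, -0.3, 0.2), center)
        moving, _ = generate_timepoint(reg_spec, traj, acq, 14.0, transform=tru)
        res = register_rigid(calibrate_volume(moving, reg_spec), ref)
        est = RigidTransform.from_matrix(res.transform.to_matrix(), center)
        assert np.abs(np.array(est.rotations_deg) - tru.rotations_deg).max() <= 1.0
        assert (
            np.abs(np.array(est.translation_mm) - tru.translation_mm).max()
            <= 0.5 * 0.116
        )

    def test_inverse_consistency(self, reg_reference, reg_spec):
        """Registering A to B and B to A composes to identity within
        twice the single-direction tolerance."""
        ref, center, traj, acq = reg_reference
        tru = RigidTransform((4.0, 1.5, -2.0), (0.3, 0.2, -0.4), center)
        moving, _ = generate_timepoint(reg_spec, traj, acq, 7.0, transform=tru)
        mov_hu = calibrate_volume(moving, reg_spec)
        mov_ref, _ = extract_femur(mov_hu, 1200.0)
        fwd = register_rigid(mov_hu, ref).transform
        day0, _ = generate_timepoint(
            reg_spec, traj, acq, 0.0, transform=RigidTransform(center_mm=center)
        )
        bwd = register_rigid(calibrate_volume(day0, reg_spec), mov_ref).transform
        comp = fwd.compose(bwd)
        cc = RigidTransform.from_matrix(comp.to_matrix(), center)
        assert np.abs(cc.rotations_deg).max() <= 2.0
        assert np.abs(cc.translation_mm).max() <= 0.116

    def test_requires_hu_volumes(self, reg_reference, clean_series):
        ref, *_ = reg_reference
        raw = clean_series[0][0]
        with pytest.raises(ValueError, match="HU"):
            register_rigid(raw, ref)
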