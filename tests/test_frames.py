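import numpy as np
import pytest

import copalign as ca
from copalign import frames
from copalign.errors import DataError, DegenerateGeometryError
from copalign.signal_io import ForcePlateRecording

from oracles import cop_moment_residual_grid


class TestShoeFrame:
    def test_symmetric_markers_give_canonical_axes(self):
        t = frames.shoe_frame([0, 0, 0], [-1, 10, 0], [1, 10, 0])
        np.testing.assert_allclose(t[:3, 0], [1, 0, 0], atol=1e-12)
        np.testing.assert_allclose(t[:3, 1], [0, 1, 0], atol=1e-12)
        np.testing.assert_allclose(t[:3, 2], [0, 0, 1], atol=1e-12)
        np.testing.assert_allclose(t[:3, 3], [0, 0, 0], atol=1e-12)

    def test_translation_equivariance(self):
        a = frames.shoe_frame([0, 0, 0], [-1, 10, 0], [1, 10, 0])
        b = frames.shoe_frame([5, 5, 0], [4, 15, 0], [6, 15, 0])
        np.testing.assert_allclose(b[:3, :3], a[:3, :3], atol=1e-12)
        np.testing.assert_allclose(b[:3, 3] - a[:3, 3], [5, 5, 0], atol=1e-12)

    @pytest.mark.parametrize("mt1,mt5", [
        ([0, 0, 0], [1, 10, 0]),           # heel == mt1
        ([0, 5, 0], [0, 10, 0]),           # collinear along one line
    ])
    def test_degenerate_markers_rejected(self, mt1, mt5):
        with pytest.raises(DegenerateGeometryError):
            frames.shoe_frame([0, 0, 0], mt1, mt5)

    def test_series_rotations_proper_orthonormal(self, noisy_trial):
        _, trial = noisy_trial
        pose = frames.shoe_frame_series(trial.markers)
        rots = pose.matrices[pose.valid][:, :3, :3]
        ident = np.einsum("nij,nkj->nik", rots, rots)
        assert np.max(np.abs(ident - np.eye(3))) < 1e-9
        np.testing.assert_allclose(np.linalg.det(rots), 1.0, atol=1e-9)


def _plate(force, moment, origin=(0, 0, 0)):
    n = len(force)
    return ForcePlateRecording(time_s=np.arange(n) / 60, force_n=np.asarray(force),
                               moment_nmm=np.asarray(moment), rate_hz=60,
                               origin_mm=np.asarray(origin, dtype=float))


class TestForceplateCOP:
    def test_pure_vertical_through_origin(self):
        plate = _plate([[0, 0, 500.0]], [[0, 0, 0.0]])
        cop = frames.forceplate_cop(plate, np.array([True]))
        np.testing.assert_allclose(cop.xy[0], [0, 0], atol=1e-12)

    def test_moment_offset_matches_brute_force_balance(self):
        force, moment = [0, 0, 1000.0], [50_000.0, 0, 0]
        plate = _plate([force], [moment])
        cop = frames.forceplate_cop(plate, np.array([True]))
        np.testing.assert_allclose(cop.xy[0], [0.0, 50.0], atol=1e-9)
        oracle = cop_moment_residual_grid(force, moment)
        np.testing.assert_allclose(cop.xy[0], oracle, atol=0.5)

    def test_masked_frames_not_emitted(self):
        plate = _plate([[0, 0, 100.0], [0, 0, 100.0]], [[0, 0, 0], [0, 0, 0]])
        cop = frames.forceplate_cop(plate, np.array([True, False]))
        assert cop.valid.tolist() == [True, False]
        assert np.isnan(cop.xy[1]).all()


class TestInsoleCOP:
    def test_single_active_sensor_is_its_center(self, geometry):
        p = np.zeros((1, 99))
        p[0, 42] = 120.0
        rec = ca.InsoleRecording(time_s=[0], pressure_kpa=p)
        cop = frames.insole_cop(rec, geometry)
        np.testing.assert_allclose(cop.xy[0], geometry.centers_mm[42], atol=1e-12)

    def test_equal_forces_average_to_midpoint(self, geometry):
        # two sensors in the same row share an area, so equal pressures
        # give the midpoint of their centers
        p = np.zeros((1, 99))
        p[0, [40, 44]] = 80.0
        rec = ca.InsoleRecording(time_s=[0], pressure_kpa=p)
        cop = frames.insole_cop(rec, geometry)
        mid = geometry.centers_mm[[40, 44]].mean(axis=0)
        np.testing.assert_allclose(cop.xy[0], mid, atol=1e-12)

    def test_zero_frame_masked(self, geometry):
        rec = ca.InsoleRecording(time_s=[0], pressure_kpa=np.zeros((1, 99)))
        cop = frames.insole_cop(rec, geometry)
        assert not cop.valid[0]


class TestToShoeFrame:
    def test_identity_pose_passthrough(self):
        pose = frames.ShoeFramePose(np.tile(np.eye(4), (3, 1, 1)), np.ones(3, bool))
        cop = frames.PlanarCOPSeries(np.array([[1., 2], [3, 4], [5, 6]]),
                                     np.ones(3, bool), "global")
        out = frames.to_shoe_frame(pose, cop)
        np.testing.assert_allclose(out.xy, cop.xy, atol=1e-12)

    def test_pure_translation_subtracted(self):
        mats = np.tile(np.eye(4), (2, 1, 1))
        mats[:, :2, 3] = [10.0, -5.0]
        pose = frames.ShoeFramePose(mats, np.ones(2, bool))
        cop = frames.PlanarCOPSeries(np.array([[11., -4], [0, 0]]),
                                     np.ones(2, bool), "global")
        out = frames.to_shoe_frame(pose, cop)
        np.testing.assert_allclose(out.xy, [[1, 1], [-10, 5]], atol=1e-12)

    def test_length_mismatch_rejected(self):
        pose = frames.ShoeFramePose(np.tile(np.eye(4), (2, 1, 1)), np.ones(2, bool))
        cop = frames.PlanarCOPSeries(np.zeros((3, 2)), np.ones(3, bool), "global")
        with pytest.raises(DataError):
            frames.to_shoe_frame(pose, cop)

    def test_pose_roundtrip_is_identity(self, noiseless_trial, geometry):
        # exact only while the shoe plane lies in the ground plane: mapping
        # to global and back projects out the Z coordinate
        _, trial = noiseless_trial
        pose = frames.shoe_frame_series(trial.markers)
        cop = frames.insole_cop(trial.insole, geometry)   # any planar series
        back = frames.to_shoe_frame(pose, frames.apply_pose(pose, cop))
        ok = back.valid
        np.testing.assert_allclose(back.xy[ok], cop.xy[ok], atol=1e-9)


def test_ground_plane_motion_equivariance(noiseless_trial):
    """Relocating the lab frame (yaw + in-plane shift) leaves shoe-frame COP
    unchanged: it is a pure gauge freedom of the construction."""
    _, trial = noiseless_trial
    markers = trial.markers
    pose = frames.shoe_frame_series(markers)
    contact = ca.gate_ground_contact(trial.plate)
    cop_g = frames.forceplate_cop(trial.plate, contact)
    baseline = frames.to_shoe_frame(pose, cop_g)
    rng = np.random.default_rng(3)
    for _ in range(10):
        phi = rng.uniform(-np.pi, np.pi)
        t = rng.uniform(-500, 500, size=2)
        rot = np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])

        def move(arr):
            out = arr.copy()
            out[:, :2] = arr[:, :2] @ rot.T + t
            return out

        m2 = ca.MarkerTrajectory(time_s=markers.time_s, heel=move(markers.heel),
                                 mt1=move(markers.mt1), mt5=move(markers.mt5))
        cop2 = frames.PlanarCOPSeries(cop_g.xy @ rot.T + t, cop_g.valid, "global")
        out = frames.to_shoe_frame(frames.shoe_frame_series(m2), cop2)
        ok = baseline.valid
        assert np.max(np.abs(out.xy[ok] - baseline.xy[ok])) < 1e-9
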