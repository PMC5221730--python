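"""Rotor-analysis tests against closed-form fields and synthetic streams."""

import numpy as np
import pytest

from afpom.rotor_analysis import (CoreTrajectory, compute_phase,
                                  detect_singularities, detect_termination,
                                  dominant_frequency, meandering_area,
                                  singularities_by_frame, track_cores)
from afpom.tissue_sim import VoltageMovie, build_mesh


@pytest.fixture(scope="module")
def sheet():
    return build_mesh("sheet", size=2.0, dx=0.05)


@pytest.fixture(scope="module")
def sphere():
    return build_mesh("sphere", radius=1.0, subdivisions=3)


def movie_from(frames, mesh, frame_ms=1.0):
    return VoltageMovie(np.asarray(frames, dtype=np.float32), frame_ms, mesh)


class TestComputePhase:
    def test_cosine_phase_advances_two_pi_per_period(self, sheet):
        t = np.arange(0, 1000.0)  # ms
        f = 10.0 / 1000.0  # 10 Hz in 1/ms
        v = np.cos(2 * np.pi * f * t)
        frames = np.tile(v[:, None], (1, sheet.n_nodes))
        pm = compute_phase(movie_from(frames, sheet))
        unwrapped = np.unwrap(pm.phase[:, 0])
        advance = unwrapped[-1] - unwrapped[0]
        expected = 2 * np.pi * f * (t[-1] - t[0])
        assert advance == pytest.approx(expected, rel=0.02)

    def test_constant_node_flagged_invalid(self, sheet):
        frames = np.zeros((100, sheet.n_nodes))
        frames[:, 1:] = np.sin(np.arange(100.0) / 5.0)[:, None]
        pm = compute_phase(movie_from(frames, sheet))
        assert not pm.valid[0]
        assert pm.valid[1:].all()

    def test_sign_flip_shifts_phase_by_pi(self, sheet):
        t = np.arange(0, 500.0)
        v = np.cos(2 * np.pi * 0.008 * t)
        frames = np.tile(v[:, None], (1, sheet.n_nodes))
        pa = compute_phase(movie_from(frames, sheet)).phase[:, 0]
        pb = compute_phase(movie_from(-frames, sheet)).phase[:, 0]
        diff = np.angle(np.exp(1j * (pb - pa - np.pi)))
        assert np.abs(diff).max() < 1e-6


class TestSingularities:
    def test_analytic_spiral_found_at_center(self, sheet):
        center = np.array([1.0125, 0.9875])  # off-node location
        phi = np.arctan2(sheet.points[:, 1] - center[1],
                         sheet.points[:, 0] - center[0])
        found = detect_singularities(phi, sheet)
        assert len(found) == 1
        ps = found[0]
        assert ps.charge == +1
        assert np.hypot(ps.position[0] - center[0],
                        ps.position[1] - center[1]) <= sheet.spacing

    def test_uniform_phase_has_no_singularity(self, sheet):
        assert detect_singularities(np.full(sheet.n_nodes, 0.7), sheet) == []

    def test_opposite_spiral_has_negative_charge(self, sheet):
        center = np.array([1.0125, 0.9875])
        phi = np.arctan2(sheet.points[:, 1] - center[1],
                         sheet.points[:, 0] - center[0])
        found = detect_singularities(-phi, sheet)
        assert len(found) == 1 and found[0].charge == -1

    def test_sphere_charges_sum_to_zero_on_smooth_fields(self, sphere):
        """Closed-surface topology: net winding vanishes frame by frame."""
        rng = np.random.default_rng(7)
        pts = sphere.points
        for _ in range(20):
            k = rng.normal(size=3)
            field = np.arctan2(pts @ rng.normal(size=3), pts @ k)
            ps = detect_singularities(field, sphere)
            assert sum(p.charge for p in ps) == 0

    def test_matches_bruteforce_winding_oracle(self, sheet, rng):
        """Vectorized detection equals a per-face winding-number loop."""
        from afpom.rotor_analysis import _face_winding

        nx = sheet.shape[0]
        for _ in range(100):
            # random smooth phase field: sum of a few plane/vortex terms
            a, b = rng.normal(size=2)
            cx, cy = rng.uniform(0.3, 1.7, size=2)
            phi = (a * sheet.points[:, 0] + b * sheet.points[:, 1]
                   + np.arctan2(sheet.points[:, 1] - cy,
                                sheet.points[:, 0] - cx))
            phi = np.angle(np.exp(1j * phi))
            fast = np.round(_face_winding(phi, sheet.faces)).astype(int)
            for fi in rng.choice(sheet.faces.shape[0], 40, replace=False):
                face = sheet.faces[fi]
                total = 0.0
                for e in range(len(face)):
                    d = phi[face[(e + 1) % len(face)]] - phi[face[e]]
                    while d <= -np.pi:
                        d += 2 * np.pi
                    while d > np.pi:
                        d -= 2 * np.pi
                    total += d
                assert int(round(total / (2 * np.pi))) == fast[fi]


class TestTracking:
    def make_stream(self, positions_by_frame, charges_by_frame, frame_ms=10.0):
        from afpom.rotor_analysis import PhaseSingularity

        stream = []
        for t, (pos, chg) in enumerate(zip(positions_by_frame,
                                           charges_by_frame)):
            stream.append([PhaseSingularity(t * frame_ms, tuple(p), c, 0)
                           for p, c in zip(pos, chg)])
        return stream

    def test_stationary_core_yields_single_trajectory(self):
        stream = self.make_stream([[(1.0, 1.0, 0.0)]] * 50, [[+1]] * 50)
        trajs = track_cores(stream, 10.0, gate_cm=0.2)
        assert len(trajs) == 1
        assert trajs[0].lifetime_ms == 490.0

    def test_circular_motion_tracked_without_identity_switch(self):
        t = np.linspace(0, 2 * np.pi, 80, endpoint=False)
        pos = [[(1 + 0.5 * np.cos(a), 1 + 0.5 * np.sin(a), 0.0)] for a in t]
        trajs = track_cores(self.make_stream(pos, [[+1]] * 80), 10.0,
                            gate_cm=0.2)
        assert len(trajs) == 1
        assert len(trajs[0].times) == 80

    def test_annihilating_pair_ends_together(self):
        frames_pos, frames_chg = [], []
        for k in range(20):
            x = 0.05 * (20 - k)
            frames_pos.append([(1 - x, 1.0, 0.0), (1 + x, 1.0, 0.0)])
            frames_chg.append([+1, -1])
        for _ in range(10):  # after annihilation: no PS
            frames_pos.append([])
            frames_chg.append([])
        stream = self.make_stream(frames_pos, frames_chg)
        trajs = track_cores(stream, 10.0, gate_cm=0.2)
        assert len(trajs) == 2
        death = [tr.death_ms for tr in trajs]
        assert death[0] == death[1] == 190.0
        gap = np.linalg.norm(np.asarray(trajs[0].positions[-1])
                             - np.asarray(trajs[1].positions[-1]))
        assert gap <= 0.2

    def test_same_charge_constraint(self):
        stream = self.make_stream([[(1.0, 1.0, 0.0)], [(1.02, 1.0, 0.0)]],
                                  [[+1], [-1]])
        trajs = track_cores(stream, 10.0, gate_cm=0.2)
        assert len(trajs) == 2


class TestMeandering:
    def test_stationary_core_has_zero_area(self):
        traj = CoreTrajectory(+1, [0, 1, 2],
                              [np.array([1.0, 1.0, 0.0])] * 3)
        assert meandering_area(traj) == 0.0

    def test_two_point_trajectory_degenerate(self):
        traj = CoreTrajectory(+1, [0, 1], [np.zeros(3), np.ones(3)])
        assert meandering_area(traj) == 0.0

    def test_circle_area_within_five_percent(self):
        a = np.linspace(0, 2 * np.pi, 64, endpoint=False)
        pos = [np.array([0.5 * np.cos(x), 0.5 * np.sin(x), 0.0]) for x in a]
        area = meandering_area(CoreTrajectory(+1, list(range(64)), pos))
        assert area == pytest.approx(np.pi * 0.25, rel=0.05)

    def test_sphere_trajectory_projected_to_tangent_plane(self, sphere):
        # small circle around the +z pole, radius r on the unit sphere
        r = 0.2
        a = np.linspace(0, 2 * np.pi, 64, endpoint=False)
        z = np.sqrt(1 - r ** 2)
        pos = [np.array([r * np.cos(x), r * np.sin(x), z]) for x in a]
        area = meandering_area(CoreTrajectory(+1, list(range(64)), pos),
                               sphere)
        assert area == pytest.approx(np.pi * r ** 2, rel=0.05)


class TestDominantFrequency:
    def test_periodic_pulses_recovered(self, sheet):
        t = np.arange(0, 2000.0)  # 2 s at 1 kHz
        pulse = ((t % 200.0) < 40.0).astype(float) * 100.0 - 80.0  # 5 Hz
        frames = np.tile(pulse[:, None], (1, sheet.n_nodes))
        _, df = dominant_frequency(movie_from(frames, sheet))
        assert df == pytest.approx(5.0, abs=0.5)

    def test_flat_movie_undefined(self, sheet):
        frames = np.full((2000, sheet.n_nodes), -80.0)
        df_map, df = dominant_frequency(movie_from(frames, sheet))
        assert np.isnan(df)
        assert np.all(np.isnan(df_map))

    def test_time_reversal_leaves_df_unchanged(self, sheet):
        rng = np.random.default_rng(3)
        t = np.arange(0, 2000.0)
        v = np.sin(2 * np.pi * 0.006 * t) + 0.3 * rng.normal(size=t.size)
        frames = np.tile(v[:, None], (1, 16))
        small = build_mesh("sheet", size=0.15, dx=0.05)
        a = dominant_frequency(movie_from(frames, small))[1]
        b = dominant_frequency(movie_from(frames[::-1], small))[1]
        assert a == pytest.approx(b, abs=1e-9)


class TestTermination:
    def test_decay_to_rest_detected(self, sheet):
        frames = np.full((1500, sheet.n_nodes), -80.0)
        frames[:1000] = 0.0  # active first second
        sustained, t_term, _ = detect_termination(movie_from(frames, sheet))
        assert not sustained
        assert t_term == pytest.approx(1000.0, abs=2.0)

    def test_persistent_activity_is_sustained(self, sheet):
        t = np.arange(0, 1500.0)
        v = 50.0 * np.sign(np.sin(2 * np.pi * 0.005 * t)) - 20.0
        frames = np.tile(v[:, None], (1, sheet.n_nodes))
        sustained, t_term, _ = detect_termination(movie_from(frames, sheet))
        assert sustained and t_term is None

    def test_collision_mechanism_tagged(self, sheet):
        """An annihilating opposite-charge pair is tagged core collision."""
        from afpom.rotor_analysis import PhaseSingularity

        n_frames = 1500
        frames = np.full((n_frames, sheet.n_nodes), -80.0)
        frames[:600] = 0.0
        ps = []
        for k in range(n_frames):
            if k < 600:
                x = max(0.025, 0.5 - 0.001 * k)
                ps.append([PhaseSingularity(float(k), (1 - x, 1.0, 0.0), +1, 0),
                           PhaseSingularity(float(k), (1 + x, 1.0, 0.0), -1, 0)])
            else:
                ps.append([])
        sustained, t_term, mech = detect_termination(
            movie_from(frames, sheet), ps, gate_cm=4 * sheet.spacing)
        assert not sustained
        assert mech == "core collision"


class TestMovieRoundtrip:
    def test_analysis_identical_after_hdf5_roundtrip(self, sheet, tmp_path):
        from afpom.rotor_analysis import reentry_biomarkers
        from afpom.tissue_sim import VoltageMovie

        t = np.arange(0, 1200.0)
        pulse = ((t % 150.0) < 30.0) * 100.0 - 80.0
        frames = np.tile(pulse[:, None], (1, sheet.n_nodes))
        movie = VoltageMovie(frames, 1.0, sheet)
        movie.to_hdf5(tmp_path / "m.h5")
        back = VoltageMovie.from_hdf5(tmp_path / "m.h5")
        a = reentry_biomarkers(movie, skip_ms=100.0)
        b = reentry_biomarkers(back, skip_ms=100.0)
        assert a == b
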