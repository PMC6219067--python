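import numpy as np
import pytest

from fastla import (
    DistanceCurve,
    StrainCurve,
    Trajectory,
    average_walls,
    detect_phases,
    distance_curve,
    phasic_parameters,
    reconstruct_strain,
    strain_curve,
    strain_rate_curve,
)
from fastla.errors import CalibrationError, DomainError, MonophasicCurveError
from fastla.phantom import prescribed_strain


def static_traj(point, t=10):
    return Trajectory(positions=np.tile(point, (t, 1)), scores=np.ones(t))


def triphasic_curve(t_frames=30, eps_s=35.3, eps_a=17.2):
    eps = prescribed_strain(t_frames, eps_s, eps_a, 0.40, 0.60, 0.75)
    e = StrainCurve(wall="septal", epsilon=eps)
    sr = strain_rate_curve(e, 1000.0 / t_frames)
    return e, sr


class TestDistanceCurve:
    def test_axis_aligned(self):
        d = distance_curve(static_traj([0, 0]), static_traj([0, 80]), (1.0, 1.0))
        assert np.all(d.d_mm == 80.0)

    def test_anisotropic_spacing(self):
        d = distance_curve(static_traj([0, 0]), static_traj([30, 40]), (2.0, 1.0))
        assert d.d_mm[0] == pytest.approx(np.sqrt(60**2 + 40**2), abs=1e-9)
        assert d.d_mm[0] == pytest.approx(72.111, abs=1e-3)

    def test_phantom_distances_match_programme(self, default_phantom):
        _, _, truth = default_phantom
        ja = Trajectory(positions=truth.trajectories["junction_a"],
                        scores=np.ones(len(truth.trajectories["junction_a"])))
        post = Trajectory(positions=truth.trajectories["mid_posterior"],
                          scores=np.ones(len(truth.trajectories["mid_posterior"])))
        d = distance_curve(ja, post, (1.25, 1.25), wall=truth.walls[0])
        assert np.max(np.abs(d.d_mm - truth.distance_mm[truth.walls[0]])) <= 1e-9

    def test_zero_distance_rejected(self):
        with pytest.raises(DomainError):
            distance_curve(static_traj([5, 5]), static_traj([5, 5]), (1.0, 1.0))


class TestStrainCurve:
    def test_constant_distance_gives_zero(self):
        e = strain_curve(DistanceCurve(wall="septal", d_mm=np.full(10, 42.0)))
        assert np.all(e.epsilon == 0.0)

    @pytest.mark.parametrize("d0,dt,expected", [(80.0, 100.0, 25.0), (50.0, 40.0, -20.0)])
    def test_formula(self, d0, dt, expected):
        d = DistanceCurve(wall="septal", d_mm=np.array([d0, dt, dt]))
        e = strain_curve(d)
        assert e.epsilon[0] == 0.0
        assert e.epsilon[1] == pytest.approx(expected, abs=1e-12)

    def test_scale_invariance(self, rng):
        d_mm = 50.0 + 10.0 * rng.random(20)
        e1 = strain_curve(DistanceCurve(wall="septal", d_mm=d_mm))
        e2 = strain_curve(DistanceCurve(wall="septal", d_mm=3.7 * d_mm))
        assert np.allclose(e1.epsilon, e2.epsilon, atol=1e-10)


class TestStrainRate:
    def test_constant_strain_zero_rate(self):
        e = StrainCurve(wall="septal", epsilon=np.zeros(10))
        sr = strain_rate_curve(e, 33.0)
        assert np.all(sr.sr == 0.0)

    def test_linear_ramp_interior(self):
        eps = np.arange(12, dtype=float)  # +1 % per frame
        sr = strain_rate_curve(StrainCurve(wall="septal", epsilon=eps), 33.333)
        assert np.allclose(sr.sr[1:-1], 0.01 / 0.033333, rtol=1e-4)

    def test_sinusoid_second_order_accurate(self):
        t_frames, amp = 40, 20.0
        t = np.arange(t_frames)
        omega = 2 * np.pi / t_frames
        eps = amp * np.sin(omega * t)
        eps[0] = 0.0
        dt = 0.025  # s/frame
        sr = strain_rate_curve(StrainCurve(wall="septal", epsilon=eps), dt * 1000)
        analytic = (amp / 100.0) * (omega / dt) * np.cos(omega * t)
        bound = omega**2 * amp / 100.0 / dt
        assert np.max(np.abs(sr.sr - analytic)) <= bound

    def test_nonpositive_interval_rejected(self):
        with pytest.raises(CalibrationError):
            strain_rate_curve(StrainCurve(wall="septal", epsilon=np.zeros(5)), 0.0)

    def test_integral_reconstruction(self):
        e, sr = triphasic_curve()
        recon = reconstruct_strain(sr, 1000.0 / 30)
        assert np.max(np.abs(recon.epsilon - e.epsilon)) <= 0.1

    def test_smoothing_preserves_constant(self):
        e = StrainCurve(wall="septal", epsilon=np.zeros(10))
        sr = strain_rate_curve(e, 33.0, smooth_window=3)
        assert np.all(sr.sr == 0.0)


class TestPhaseDetection:
    def test_triphasic_phases(self):
        e, sr = triphasic_curve()
        phases = detect_phases(e, sr)
        assert phases.t_es == 12  # 0.40 * 30, the prescribed strain maximum
        assert 18 <= phases.t_preA <= 22  # inside the prescribed plateau
        assert phases.t_diastasis == phases.t_preA

    def test_monophasic_curve_rejected(self):
        t = np.arange(30)
        eps = 30.0 * np.sin(np.pi * t / 30) ** 2  # single rise and decay
        e = StrainCurve(wall="septal", epsilon=eps)
        sr = strain_rate_curve(e, 33.3)
        with pytest.raises(MonophasicCurveError):
            detect_phases(e, sr)

    def test_flat_curve_rejected(self):
        e = StrainCurve(wall="septal", epsilon=np.zeros(20))
        sr = strain_rate_curve(e, 33.3)
        with pytest.raises(MonophasicCurveError):
            detect_phases(e, sr)


class TestPhasicParameters:
    def test_recovers_prescription_exactly_on_clean_curve(self):
        e, sr = triphasic_curve(eps_s=35.3, eps_a=17.2)
        res = phasic_parameters(e, sr, detect_phases(e, sr))
        assert res.eps_s == pytest.approx(35.3, abs=1e-9)
        assert res.eps_a == pytest.approx(17.2, abs=1e-9)
        assert res.eps_e == pytest.approx(18.1, abs=1e-9)
        assert res.sr_s > 0 and res.sr_e < 0 and res.sr_a < 0

    def test_additive_decomposition_is_exact(self):
        e, sr = triphasic_curve(eps_s=27.0, eps_a=14.9)
        res = phasic_parameters(e, sr, detect_phases(e, sr))
        assert res.eps_e + res.eps_a == res.eps_s  # identity by construction


class TestAverageWalls:
    def _result(self, eps_s, eps_a):
        e, sr = triphasic_curve(eps_s=eps_s, eps_a=eps_a)
        return phasic_parameters(e, sr, detect_phases(e, sr))

    def test_identical_inputs_idempotent(self):
        r = self._result(30.0, 15.0)
        avg = average_walls([r, r])
        assert avg.eps_s == pytest.approx(r.eps_s, abs=1e-12)
        assert avg.wall == "global"

    def test_mean_of_two(self):
        avg = average_walls([self._result(30.0, 15.0), self._result(40.0, 15.0)])
        assert avg.eps_s == pytest.approx(35.0, abs=1e-9)

    def test_four_walls_mean_and_decomposition(self):
        walls = [self._result(s, a) for s, a in
                 [(35.0, 17.0), (33.0, 16.0), (30.0, 15.0), (28.0, 14.0)]]
        avg = average_walls(walls)
        assert avg.eps_s == pytest.approx(np.mean([35, 33, 30, 28]), abs=1e-9)
        assert avg.eps_e + avg.eps_a == pytest.approx(avg.eps_s, abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(Exception):
            average_walls([])
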