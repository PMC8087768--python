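import numpy as np
import pytest
import sympy

from heelspring.exceptions import UndefinedResultError, ValidationError
from heelspring.inverse_dynamics import (
    MomentArmModel,
    PcsaPartition,
    StanceStep,
    external_moment_arm_ankle,
    froude_number,
    joint_angles,
    joint_power_work,
    muscle_forces,
    net_joint_moments,
)
from heelspring.pipeline import process_trial
from heelspring.signal_processing import detect_stance, downsample_force
from heelspring.synthetic_gait import (
    generate_static_trial,
    generate_trial,
    massless_inertia,
)


def _const_markers(points, n=10):
    return {k: np.tile(v, (n, 1)).astype(float) for k, v in points.items()}


class TestJointAngles:
    def test_collinear_leg_gives_straight_knee(self):
        m = _const_markers({
            "hip": [0.0, 1.0], "knee": [0.0, 0.5], "ankle": [0.0, 0.0],
            "mthead": [0.18, 0.0], "heel": [-0.05, 0.0],
        })
        a = joint_angles(m)
        np.testing.assert_allclose(a["knee"], np.pi, atol=1e-12)
        np.testing.assert_allclose(a["hip"], 0.0, atol=1e-12)

    def test_perpendicular_foot_gives_right_angle(self):
        m = _const_markers({
            "hip": [0.0, 1.0], "knee": [0.0, 0.5], "ankle": [0.0, 0.0],
            "mthead": [0.18, 0.0], "heel": [-0.05, 0.0],
        })
        np.testing.assert_allclose(joint_angles(m)["ankle"], np.pi / 2, atol=1e-12)

    def test_degenerate_segment_reports_frame(self):
        m = _const_markers({
            "hip": [0.0, 1.0], "knee": [0.0, 0.5], "ankle": [0.0, 0.0],
            "mthead": [0.18, 0.0], "heel": [-0.05, 0.0],
        })
        m["knee"][4] = m["hip"][4]
        with pytest.raises(ValidationError, match="frame 4"):
            joint_angles(m)

    def test_prescribed_angles_recovered_exactly(self, subject, noiseless_spec):
        trial, truth = generate_trial(subject, "run", noiseless_spec,
                                      np.random.default_rng(2))
        a = joint_angles(trial.markers)
        for j in ("hip", "knee", "ankle"):
            assert np.max(np.abs(a[j] - truth.angles[j])) < 1e-9


class TestNetJointMoments:
    def test_static_standing_matches_cop_lever(self, subject):
        trial, _ = generate_static_trial(subject)
        step = StanceStep("S03", "walk", 0, 500.0, trial.markers,
                          trial.fz[::2], trial.fx[::2], trial.cop_x[::2])
        m = net_joint_moments(step, massless_inertia(), subject.body_mass)
        expected = step.fz * (step.cop_x - trial.markers["ankle"][:, 0])
        np.testing.assert_allclose(m["ankle"], expected, atol=1e-9)

    def test_zero_grf_stationary_limb_zero_moments(self, subject):
        trial, _ = generate_static_trial(subject)
        n = trial.time_kinematic.size
        step = StanceStep("S03", "walk", 0, 500.0, trial.markers,
                          np.zeros(n), np.zeros(n), trial.cop_x[::2])
        m = net_joint_moments(step, massless_inertia(), subject.body_mass)
        for j in ("ankle", "knee", "hip"):
            np.testing.assert_allclose(m[j], 0.0, atol=1e-9)

    @pytest.mark.parametrize("gait", ["walk", "sprint"])
    def test_shared_equation_oracle(self, gait, subject, noiseless_spec, no_filter_config):
        trial, truth = generate_trial(subject, gait, noiseless_spec,
                                      np.random.default_rng(11), config=no_filter_config)
        res = process_trial(trial, subject, no_filter_config, keep_kinetics=True)[0]
        fz_k = downsample_force(trial.fz, 1000.0, 500.0, antialias=None)
        win = detect_stance(fz_k, 20.0, 500.0)[0]
        for j in ("ankle", "knee", "hip"):
            tm = truth.moments[j][win.slice()]
            rel = np.max(np.abs(res.kinetics.moments[j] - tm)) / np.max(np.abs(tm))
            assert rel < 1e-6


class TestMuscleForces:
    def _flat_arms(self, r_ankle=0.05, r_knee=0.05, r_hip=0.06):
        return MomentArmModel(
            ankle_coeffs=(r_ankle,), knee_coeffs=(r_knee,), hip_coeffs=(r_hip,),
            gastroc_knee_coeffs=(0.02,), hamstrings_knee_coeffs=(0.025,),
            rectus_femoris_hip_coeffs=(0.035,),
        )

    def _angles(self, n):
        return {"hip": np.full(n, 0.2), "knee": np.full(n, 2.4),
                "ankle": np.full(n, 1.6)}

    def test_pure_ankle_moment(self):
        m = {"ankle": np.full(3, 100.0), "knee": np.zeros(3), "hip": np.zeros(3)}
        f, _ = muscle_forces(m, self._angles(3), self._flat_arms(),
                             PcsaPartition(0.0, 0.0, 0.0))
        np.testing.assert_allclose(f["ankle"], 2000.0, rtol=1e-12)

    def test_zero_moments_zero_forces(self):
        m = {j: np.zeros(3) for j in ("ankle", "knee", "hip")}
        f, _ = muscle_forces(m, self._angles(3), self._flat_arms(), PcsaPartition())
        for j in f:
            np.testing.assert_allclose(f[j], 0.0, atol=1e-12)

    def test_matches_symbolic_solution(self):
        """The per-frame 2x2 elimination equals sympy's solution of the full
        bi-articular moment system."""
        arms = self._flat_arms()
        pcsa = PcsaPartition(gastroc=0.35, hamstrings=0.4, rectus_femoris=0.25)
        m = {"ankle": np.array([40.0, 90.0, 10.0]),
             "knee": np.array([60.0, -20.0, 35.0]),
             "hip": np.array([80.0, 55.0, -15.0])}
        f, _ = muscle_forces(m, self._angles(3), arms, pcsa)
        Fa, Fk, Fh = sympy.symbols("Fa Fk Fh")
        for i in range(3):
            sol = sympy.solve([
                sympy.Eq(m["ankle"][i], Fa * 0.05),
                sympy.Eq(m["knee"][i], Fk * 0.05 - 0.35 * Fa * 0.02 - 0.4 * Fh * 0.025),
                sympy.Eq(m["hip"][i], Fh * 0.06 - 0.25 * Fk * 0.035),
            ], [Fa, Fk, Fh])
            assert f["ankle"][i] == pytest.approx(float(sol[Fa]), rel=1e-10)
            assert f["knee"][i] == pytest.approx(float(sol[Fk]), rel=1e-10)
            assert f["hip"][i] == pytest.approx(float(sol[Fh]), rel=1e-10)

    def test_homogeneous_in_moments(self, rng):
        arms = self._flat_arms()
        m = {j: rng.standard_normal(5) * 50 for j in ("ankle", "knee", "hip")}
        f1, _ = muscle_forces(m, self._angles(5), arms, PcsaPartition())
        f2, _ = muscle_forces({j: 3.0 * v for j, v in m.items()},
                              self._angles(5), arms, PcsaPartition())
        for j in f1:
            np.testing.assert_allclose(f2[j], 3.0 * f1[j], rtol=1e-10)

    def test_nonpositive_arm_errors(self):
        arms = MomentArmModel(ankle_coeffs=(-0.01,))
        m = {j: np.ones(3) for j in ("ankle", "knee", "hip")}
        with pytest.raises(ValidationError, match="ankle"):
            muscle_forces(m, self._angles(3), arms, PcsaPartition())


class TestExternalMomentArm:
    def test_constants_factor_out(self):
        n = 101
        grf = np.full(n, 700.0)
        r = np.full(n, 0.04)
        f = 700.0 * 2.5 * np.ones(n)  # F = G * k with k = 2.5
        assert external_moment_arm_ankle(grf, r, f, 500.0) == pytest.approx(0.04 / 2.5)

    def test_reduces_to_weighted_mean(self, rng):
        n = 200
        grf = 1000.0 * np.abs(np.sin(np.linspace(0, np.pi, n))) + 10.0
        r = 0.04 + 0.01 * rng.random(n)
        R = external_moment_arm_ankle(grf, r, grf, 500.0)
        expected = np.trapezoid(grf * r) / np.trapezoid(grf)
        assert R == pytest.approx(expected, rel=1e-9)

    def test_zero_impulse_undefined(self):
        n = 50
        with pytest.raises(UndefinedResultError):
            external_moment_arm_ankle(np.ones(n), np.ones(n), np.zeros(n), 500.0)


class TestJointPowerWork:
    def test_constant_positive_power(self):
        n = 501  # 1 s at 500 Hz
        power, wpos, wneg = joint_power_work(np.full(n, 10.0), np.ones(n), 500.0)
        assert wpos == pytest.approx(10.0, rel=1e-9)
        assert wneg == pytest.approx(0.0, abs=1e-12)

    def test_antisymmetric_velocity_balances(self):
        n = 501
        omega = np.linspace(-1.0, 1.0, n)
        _, wpos, wneg = joint_power_work(np.full(n, 10.0), omega, 500.0)
        assert wpos == pytest.approx(-wneg, rel=1e-9)

    def test_decomposition_adds_to_total(self, rng):
        from heelspring.signal_processing import trapz_integral

        m = rng.standard_normal(300) * 30
        w = rng.standard_normal(300) * 2
        power, wpos, wneg = joint_power_work(m, w, 500.0)
        assert wpos + wneg == pytest.approx(trapz_integral(power, 500.0), abs=1e-9)
        assert wpos >= 0 >= wneg


class TestFroude:
    def test_direct_formula(self):
        assert froude_number(1.0, 1.0) == pytest.approx(0.10194, abs=1e-5)

    def test_inverse_construction(self):
        assert froude_number(3.132, 1.0) == pytest.approx(1.0, abs=1e-3)

    def test_quadratic_scaling(self):
        assert froude_number(2.0, 0.9) == pytest.approx(4.0 * froude_number(1.0, 0.9))

    def test_nonpositive_inputs_error(self):
        with pytest.raises(ValidationError):
            froude_number(0.0, 1.0)
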