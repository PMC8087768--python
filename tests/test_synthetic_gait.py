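import numpy as np
import pytest

from heelspring.exceptions import ValidationError
from heelspring.inverse_dynamics import froude_number
from heelspring.synthetic_gait import (
    ARM_MEAN,
    CohortSpec,
    generate_cohort,
    generate_static_trial,
    generate_stance_grf,
    generate_subject,
    generate_trial,
)


class TestGenerateSubject:
    def test_degenerate_ranges_pin_ranged_fields(self):
        spec = CohortSpec(seed=3, n_subjects=6,
                          at_moment_arm_range=(0.04, 0.04), mass_range=(60.0, 60.0))
        subs = [generate_subject(spec, i) for i in range(6)]
        assert all(s.body_mass == 60.0 for s in subs)
        assert all(s.at_moment_arm == 0.04 for s in subs)

    def test_same_seed_and_index_identical(self):
        spec = CohortSpec(seed=9)
        assert generate_subject(spec, 5) == generate_subject(spec, 5)

    def test_mass_moment_arm_correlation(self):
        spec = CohortSpec(seed=17, n_subjects=500)
        subs = [generate_subject(spec, i) for i in range(500)]
        r = np.corrcoef([s.body_mass for s in subs],
                        [s.at_moment_arm for s in subs])[0, 1]
        assert r == pytest.approx(0.6, abs=0.1)

    def test_morphometric_invariants_hold(self):
        spec = CohortSpec(seed=21, n_subjects=100)
        for i in range(100):
            s = generate_subject(spec, i)  # constructor validates invariants
            assert s.at_moment_arm < s.foot_length


class TestStanceGrf:
    def test_walk_has_two_peaks(self, rng):
        fz, _, _ = generate_stance_grf("walk", 70.0, 0.6, 1000.0, rng)
        interior = (fz[1:-1] > fz[:-2]) & (fz[1:-1] > fz[2:])
        # count strict local maxima above 10% of peak (plateaus excluded)
        assert int(np.sum(interior & (fz[1:-1] > 0.1 * fz.max()))) == 2

    def test_run_single_peak_in_band(self, rng):
        g = 9.81
        fz, _, _ = generate_stance_grf("run", 70.0, 0.25, 1000.0, rng)
        interior = (fz[1:-1] > fz[:-2]) & (fz[1:-1] > fz[2:])
        assert int(np.sum(interior & (fz[1:-1] > 0.1 * fz.max()))) == 1
        assert 2.2 * 70.0 * g <= fz.max() <= 2.8 * 70.0 * g

    @pytest.mark.parametrize("gait", ["walk", "fast_walk", "jog", "run", "sprint"])
    def test_waveform_contracts(self, gait, rng):
        fz, fx, cop = generate_stance_grf(gait, 65.0, 0.4, 1000.0, rng)
        assert fz.min() >= 0.0
        assert fz[0] == pytest.approx(0.0, abs=1e-9) and fz[-1] == pytest.approx(0.0, abs=1e-9)
        # near-zero net fore-aft impulse
        assert abs(np.trapezoid(fx)) < 0.02 * np.trapezoid(fz)
        # COP monotone heel -> toe over the foot
        assert np.all(np.diff(cop) > 0)
        assert cop[-1] <= 0.25

    def test_unsupported_gait_errors(self, rng):
        with pytest.raises(ValidationError, match="gait"):
            generate_stance_grf("crawl", 70.0, 0.4, 1000.0, rng)


class TestGenerateTrial:
    def test_bit_identical_regeneration(self, subject, noiseless_spec):
        t1, _ = generate_trial(subject, "jog", noiseless_spec, np.random.default_rng(7))
        t2, _ = generate_trial(subject, "jog", noiseless_spec, np.random.default_rng(7))
        np.testing.assert_array_equal(t1.fz, t2.fz)
        for name in t1.markers:
            np.testing.assert_array_equal(t1.markers[name], t2.markers[name])

    def test_cohort_bit_identical_regeneration(self):
        spec = CohortSpec(seed=13, n_subjects=2, steps_per_gait=1, gaits=("walk",))
        trials1, _, _ = generate_cohort(spec)
        trials2, _, _ = generate_cohort(spec)
        for a, b in zip(trials1, trials2):
            np.testing.assert_array_equal(a.fz, b.fz)
            np.testing.assert_array_equal(a.markers["hip"], b.markers["hip"])

    def test_sprint_froude_in_plausible_band(self, noiseless_spec):
        vals = []
        for i in range(6):
            s = generate_subject(noiseless_spec, i)
            _, truth = generate_trial(s, "sprint", noiseless_spec, np.random.default_rng(i))
            vals.append(froude_number(truth.speed, s.hip_height))
        assert 0.7 <= np.mean(vals) <= 1.5

    def test_trial_counts(self):
        spec = CohortSpec(seed=1, n_subjects=3, steps_per_gait=2, gaits=("walk", "run"))
        trials, truths, subjects = generate_cohort(spec)
        assert len(trials) == len(truths) == 3 * 2 * 2
        assert len(subjects) == 3

    def test_static_trial_ankle_moment_identity(self, subject):
        trial, truth = generate_static_trial(subject)
        fz_k = trial.fz[::2]
        expected = fz_k * (trial.cop_x[::2] - trial.markers["ankle"][:, 0])
        np.testing.assert_allclose(truth.moments["ankle"], expected, atol=1e-9)
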