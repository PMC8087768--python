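import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from heelspring.exceptions import UndefinedResultError, ValidationError
from heelspring.pipeline import process_trial
from heelspring.synthetic_gait import generate_trial
from heelspring.tendon_mechanics import (
    TendonConstants,
    assemble_outcome,
    specific_net_work,
    strain_energy,
    tendon_strain_and_dl,
    tendon_stress,
)


class TestSpecificNetWork:
    def test_perfect_spring(self):
        assert specific_net_work(5.0, -5.0) == pytest.approx(0.0)

    def test_pure_motor(self):
        assert specific_net_work(5.0, 0.0) == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        # |3 - 1| / (3 + 1)
        assert specific_net_work(3.0, -1.0) == pytest.approx(0.5)

    def test_both_zero_undefined(self):
        with pytest.raises(UndefinedResultError):
            specific_net_work(0.0, 0.0)

    @given(st.floats(1e-6, 1e6), st.floats(1e-6, 1e6), st.floats(1e-6, 1e3))
    @settings(max_examples=100, deadline=None)
    def test_scale_invariance(self, wp, wn, c):
        assert specific_net_work(c * wp, -c * wn) == pytest.approx(
            specific_net_work(wp, -wn), rel=1e-9
        )

    def test_range_on_fuzzed_inputs(self):
        rng = np.random.default_rng(99)
        wp = rng.exponential(10.0, 10_000)
        wn = -rng.exponential(10.0, 10_000)
        vals = np.array([specific_net_work(p, n) for p, n in zip(wp, wn)])
        assert np.all((vals >= 0.0) & (vals <= 1.0))


class TestTendonStress:
    def test_time_averaged_stress(self):
        mean, _ = tendon_stress(100.0, 0.5, 500.0, 1e-4)
        assert mean == pytest.approx(2.0e6)

    def test_peak_stress_from_peak_force(self):
        # peak force over the mean tendon CSA lands near ~110 MPa
        _, peak = tendon_stress(100.0, 0.5, 6746.0, 0.61e-4)
        assert peak == pytest.approx(110.6e6, rel=1e-3)

    def test_zero_impulse_zero_stress(self):
        mean, peak = tendon_stress(0.0, 0.3, 0.0, 1e-4)
        assert mean == 0.0 and peak == 0.0

    def test_raw_impulse_form(self):
        mean, _ = tendon_stress(100.0, 0.5, 500.0, 1e-4, raw_impulse=True)
        assert mean == pytest.approx(1.0e6)  # Pa*s

    def test_bad_csa_errors(self):
        with pytest.raises(ValidationError):
            tendon_stress(1.0, 0.5, 1.0, 0.0)


class TestStrainAndEnergy:
    def test_strain_from_modulus(self):
        strain, _ = tendon_strain_and_dl(81.9e6, TendonConstants(), 0.2)
        assert strain == pytest.approx(0.1)

    def test_zero_stress(self):
        assert tendon_strain_and_dl(0.0, TendonConstants(), 0.2) == (0.0, 0.0)

    def test_delta_l(self):
        _, dl = tendon_strain_and_dl(0.05 * 819e6, TendonConstants(), 0.2)
        assert dl == pytest.approx(0.01)

    def test_hookean_energy_with_resilience(self):
        assert strain_energy(1000.0, 0.01, TendonConstants()) == pytest.approx(4.65)

    def test_zero_inputs(self):
        assert strain_energy(0.0, 0.01, TendonConstants()) == 0.0
        assert strain_energy(1000.0, 0.0, TendonConstants()) == 0.0

    def test_full_resilience(self):
        c = TendonConstants(resilience=1.0)
        assert strain_energy(2000.0, 0.02, c) == pytest.approx(20.0)

    @given(st.floats(1e5, 2e8), st.floats(0.1, 0.3), st.floats(1e-5, 3e-4))
    @settings(max_examples=100, deadline=None)
    def test_energy_chain_consistency(self, stress, l0, csa):
        """W = 0.5 * resilience * (stress * CSA) * (stress / E) * L0 matches
        strain_energy applied to the equivalent force and length change."""
        c = TendonConstants()
        strain, dl = tendon_strain_and_dl(stress, c, l0)
        force = stress * csa
        direct = 0.5 * c.resilience * force * (stress / c.elastic_modulus) * l0
        assert strain_energy(force, dl, c) == pytest.approx(direct, rel=1e-12)


class TestAssembleOutcome:
    def _kwargs(self):
        return dict(
            subject_id="S00", gait="run", step_index=0, froude=0.6,
            work_pos={"hip": 10.0, "knee": 4.0, "ankle": 6.0},
            work_neg={"hip": -2.0, "knee": -4.0, "ankle": -3.0},
            force_impulse=300.0, peak_force=4000.0, stance_duration=0.25,
            r_ankle_ext=0.12, body_mass=60.0, tendon_csa=0.61e-4,
            tendon_length=0.2, constants=TendonConstants(),
        )

    def test_mass_specific_fields(self):
        o = assemble_outcome(**self._kwargs())
        assert o.energy_per_kg == pytest.approx(o.energy / 60.0)
        assert o.stress_mean_per_kg == pytest.approx(o.stress_mean / 60.0)

    def test_internal_consistency(self):
        o = assemble_outcome(**self._kwargs())
        c = TendonConstants()
        mean_force = 300.0 / 0.25
        assert o.energy == pytest.approx(strain_energy(mean_force, o.delta_l, c), rel=1e-12)
        assert o.snw_ankle == pytest.approx(specific_net_work(6.0, -3.0))

    def test_missing_upstream_value_named(self):
        kw = self._kwargs()
        kw["tendon_csa"] = 0.0
        with pytest.raises(ValidationError, match="tendon_csa"):
            assemble_outcome(**kw)

    def test_full_synthetic_step_invariants(self, subject, noiseless_spec, no_filter_config):
        trial, _ = generate_trial(subject, "run", noiseless_spec,
                                  np.random.default_rng(3), config=no_filter_config)
        for o in process_trial(trial, subject, no_filter_config):
            o.validate()
            assert 0.0 <= o.snw_ankle <= 1.0
            assert o.strain >= 0.0 and o.energy >= 0.0
            assert o.energy_per_kg == pytest.approx(o.energy / subject.body_mass)
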