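"""Generator contracts: kinematics, populations, trials, reference responses."""

import numpy as np
import pytest

from reafference import synth
from reafference.synth import (CONDITIONS, KinematicTrace, NeuronGroundTruth,
                               NoiseModel, PiecewiseChannel,
                               assign_condition_kinematics,
                               make_motion_profile, make_sinusoid_profile,
                               sample_population, simulate_mossy_fibers,
                               synthesize_rfn_reference, synthesize_trials,
                               vector_to_coeffs)


# ---------------------------------------------------------------------------
# motion profiles
# ---------------------------------------------------------------------------

class TestMotionProfile:
    def test_zero_jitter_peak_and_displacement(self):
        tr, = make_motion_profile(40.0, 500.0, 1, amplitude_jitter=0.0,
                                  onset_jitter_ms=0.0, seed=0)
        assert np.max(tr.head_vel) == pytest.approx(40.0, abs=1e-9)
        # displacement equals the integral of the velocity half-cycle
        assert tr.head_pos[-1] == pytest.approx(40.0 * 0.5 / 2.0, rel=1e-9)

    def test_displacement_capped_at_behavioural_range(self):
        for tr in make_motion_profile(140.0, 500.0, 15, seed=1):
            assert tr.displacement() <= 30.0 + 1e-9

    def test_seed_reproducibility_bit_identical(self):
        a = make_motion_profile(110.0, 500.0, 15, seed=7)
        b = make_motion_profile(110.0, 500.0, 15, seed=7)
        for x, y in zip(a, b):
            assert np.array_equal(x.head_vel, y.head_vel)
            assert np.array_equal(x.head_pos, y.head_pos)

    @pytest.mark.parametrize("peak,duration", [(0.0, 500.0), (-5.0, 500.0),
                                               (40.0, 0.0), (40.0, -1.0)])
    def test_rejects_nonpositive_inputs(self, peak, duration):
        with pytest.raises(ValueError):
            make_motion_profile(peak, duration)

    def test_velocity_is_derivative_of_position(self):
        # analytic fields are mutually consistent up to the O(dt^2)
        # discretization of the central difference
        tr, = make_motion_profile(110.0, 500.0, 1, amplitude_jitter=0.0,
                                  onset_jitter_ms=0.0, seed=0)
        num_vel = np.gradient(tr.head_pos, tr.t / 1000.0)
        err = np.max(np.abs(num_vel[2:-2] - tr.head_vel[2:-2]))
        assert err < 5e-5 * np.max(np.abs(tr.head_vel))

    def test_sinusoid_profile_peak_and_frequency(self):
        tr, = make_sinusoid_profile(40.0, 1.0, n_cycles=2)
        assert np.max(tr.head_vel) == pytest.approx(40.0, rel=1e-3)
        # one full period = 1000 ms
        assert tr.head_vel[0] == pytest.approx(tr.head_vel[1000], abs=1e-6)


class TestConditionAssignment:
    @pytest.fixture()
    def profile(self):
        return make_motion_profile(110.0, 500.0, 1, amplitude_jitter=0.0,
                                   onset_jitter_ms=0.0, seed=0)[0]

    def test_whole_body_moves_head_and_body_together(self, profile):
        tr = assign_condition_kinematics(profile, "whole_body")
        assert np.array_equal(tr.body_vel, tr.head_vel)
        assert np.all(tr.neck_vel == 0)

    def test_body_under_head_leaves_head_stationary(self, profile):
        tr = assign_condition_kinematics(profile, "body_under_head")
        assert np.all(tr.head_vel == 0)
        assert np.array_equal(tr.neck_vel, -tr.body_vel)

    def test_combined_passive_component_is_one_hz_sinusoid(self, profile):
        tr = assign_condition_kinematics(profile, "combined")
        assert np.max(np.abs(tr.passive_head_vel)) == pytest.approx(40.0,
                                                                    rel=1e-3)
        # decomposition is exact at every sample
        assert np.allclose(tr.passive_head_vel + tr.active_head_vel,
                           tr.head_vel, atol=1e-9)
        assert np.array_equal(tr.body_vel, tr.passive_head_vel)

    def test_attempted_condition_has_zero_kinematics(self, profile):
        tr = assign_condition_kinematics(profile, "attempted")
        for field in (tr.head_vel, tr.body_vel, tr.head_pos, tr.head_acc):
            assert np.all(field == 0)

    def test_unknown_condition_rejected(self, profile):
        with pytest.raises(ValueError):
            assign_condition_kinematics(profile, "sideways")


# ---------------------------------------------------------------------------
# population sampling
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def big_population():
    return sample_population(5000, seed=11)


class TestPopulation:
    @pytest.mark.parametrize("label,frac", [
        ("bimodal", 0.70), ("motor", 0.80), ("same", 0.50), ("flipped", 0.40)])
    def test_label_fractions_within_binomial_bounds(self, big_population,
                                                    label, frac):
        n = len(big_population)
        if label == "bimodal":
            count = sum(nr.modality == "bimodal" for nr in big_population)
        elif label == "motor":
            count = sum(nr.motor_responsive for nr in big_population)
        else:
            count = sum(nr.active_sign == label for nr in big_population)
        # 99% binomial bounds
        half = 2.58 * np.sqrt(frac * (1 - frac) / n)
        assert abs(count / n - frac) < half

    def test_population_mean_attenuation_matches_calibration(self,
                                                             big_population):
        same = [nr.cancellation_gain for nr in big_population
                if nr.active_sign == "same"]
        assert np.mean(same) == pytest.approx(0.92, abs=0.01)

    def test_flipped_cells_reverse_sign(self, big_population):
        prods = [np.sign(nr.active_factor) for nr in big_population
                 if nr.active_sign == "flipped"]
        assert np.mean(prods) == -1.0

    def test_unimodal_cells_have_zero_neck_channel(self, big_population):
        for nr in big_population:
            if nr.modality == "unimodal":
                assert nr.neck.is_zero()

    def test_vestibular_insensitive_cells_silent_for_whole_body(self):
        pop = sample_population(300, seed=3)
        vi = [nr for nr in pop if nr.modality == "vestibular_insensitive"]
        assert vi, "expected some vestibular-insensitive cells"
        t = np.arange(-100.0, 400.0)
        vel = np.where(t >= 0, 50.0, 0.0)
        kin = KinematicTrace(t=t, head_pos=np.zeros_like(t), head_vel=vel,
                             head_acc=np.zeros_like(t), body_pos=np.zeros_like(t),
                             body_vel=vel.copy(), body_acc=np.zeros_like(t),
                             passive_head_vel=vel.copy(),
                             active_head_vel=np.zeros_like(t))
        for nr in vi[:5]:
            assert np.allclose(nr.sensory_drive(kin), 0.0, atol=1e-9)

    def test_seed_determinism(self):
        a = sample_population(50, seed=9)
        b = sample_population(50, seed=9)
        for x, y in zip(a, b):
            assert x.vest == y.vest and x.resting_rate == y.resting_rate

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            sample_population(10, fractions={"bimodal": 0.9, "unimodal": 0.5})


# ---------------------------------------------------------------------------
# trial synthesis
# ---------------------------------------------------------------------------

def _velocity_neuron(c_v=0.4, bias=50.0):
    return NeuronGroundTruth(
        neuron_id="tv", resting_rate=bias,
        vest=PiecewiseChannel((0.0, 0.0), (c_v, c_v), (0.0, 0.0)),
        neck=PiecewiseChannel(), cancellation_gain=0.9, modality="unimodal")


class TestSynthesizeTrials:
    def test_unimodal_neuron_flat_under_body_rotation(self):
        kin = [assign_condition_kinematics(p, "body_under_head")
               for p in make_sinusoid_profile(n_trials=2)]
        ts = synthesize_trials(_velocity_neuron(), kin, "body_under_head",
                               noise_model=NoiseModel("none"))
        for tr in ts.trials:
            assert np.allclose(tr.rate, 50.0, atol=1e-9)

    def test_velocity_coding_peak_rate(self):
        # b=50, c_v=0.4, 40 deg/s peak -> peak rate 66 sp/s
        kin = [assign_condition_kinematics(p, "whole_body")
               for p in make_sinusoid_profile(40.0, n_trials=1)]
        ts = synthesize_trials(_velocity_neuron(0.4, 50.0), kin, "whole_body",
                               noise_model=NoiseModel("none"))
        assert np.max(ts.trials[0].rate) == pytest.approx(66.0, rel=1e-3)

    def test_poisson_spike_count_statistics(self):
        t = np.arange(0.0, 10_000.0)
        z = np.zeros_like(t)
        kin = KinematicTrace(t=t, head_pos=z, head_vel=z, head_acc=z,
                             body_pos=z, body_vel=z, body_acc=z,
                             passive_head_vel=z, active_head_vel=z)
        nr = _velocity_neuron(0.0, 100.0)
        ts = synthesize_trials(nr, [kin], "whole_body",
                               noise_model=NoiseModel("none"),
                               emit_spikes=True, seed=5)
        count = ts.trials[0].spikes.size
        assert abs(count - 1000) < 3 * np.sqrt(1000)

    def test_attempted_condition_torque_and_kinematics(self, transient_suite):
        entry = transient_suite[("attempted", "ipsi")]
        nr = sample_population(5, seed=2)[0]
        ts = synthesize_trials(nr, entry["trials"][:3], "attempted",
                               intended=entry["intended"], direction="ipsi",
                               seed=1)
        for tr in ts.trials:
            assert np.max(np.abs(tr.torque)) > 1.0
            assert np.all(tr.kinematics.head_vel == 0)

    def test_condition_kinematics_mismatch_rejected(self, transient_suite):
        entry = transient_suite[("head_on_body_active", "ipsi")]
        nr = sample_population(5, seed=2)[0]
        with pytest.raises(ValueError):
            synthesize_trials(nr, entry["trials"][:2], "attempted",
                              intended=entry["intended"])

    def test_rates_nonnegative_everywhere(self, small_population,
                                          transient_suite):
        entry = transient_suite[("head_on_body_passive", "contra")]
        for nr in small_population[:8]:
            ts = synthesize_trials(nr, entry["trials"][:3],
                                   "head_on_body_passive",
                                   noise_model=NoiseModel("gaussian", 30.0),
                                   direction="contra", seed=4)
            assert all(np.all(tr.rate >= 0) for tr in ts.trials)

    def test_noise_free_rates_match_forward_model(self, small_population,
                                                  transient_suite):
        """The emitted rate is exactly bias + channel responses wherever the
        rectifier is inactive."""
        entry = transient_suite[("head_on_body_passive", "ipsi")]
        kin = entry["trials"][0]
        for nr in small_population[:10]:
            ts = synthesize_trials(nr, [kin], "head_on_body_passive",
                                   noise_model=NoiseModel("none"))
            expected = nr.resting_rate + nr.sensory_drive(kin)
            got = ts.trials[0].rate
            unclipped = expected > 0
            assert np.max(np.abs(got[unclipped] - expected[unclipped])) < 1e-9


class TestReferenceTargetNeuron:
    @staticmethod
    def _matched_kin_map():
        profile = make_motion_profile(110.0, 500.0, 1, amplitude_jitter=0.0,
                                      onset_jitter_ms=0.0, seed=0)[0]
        return {
            ("head_on_body_passive", "ipsi"):
                [assign_condition_kinematics(profile, "head_on_body_passive")],
            ("head_on_body_active", "ipsi"):
                [assign_condition_kinematics(profile, "head_on_body_active")],
        }

    def test_suppression_scales_active_sensitivity(self):
        out = synthesize_rfn_reference(self._matched_kin_map(),
                                       passive_sensitivity=0.5,
                                       suppression=0.7, phase_deg=0.0,
                                       noise_model=NoiseModel("none"))
        p = out[("head_on_body_passive", "ipsi")].trials[0]
        a = out[("head_on_body_active", "ipsi")].trials[0]
        assert np.ptp(a.rate) / np.ptp(p.rate) == pytest.approx(0.3, rel=0.02)

    def test_zero_suppression_gives_identical_responses(self):
        out = synthesize_rfn_reference(self._matched_kin_map(), 0.5, 0.0,
                                       phase_deg=0.0,
                                       noise_model=NoiseModel("none"))
        p = out[("head_on_body_passive", "ipsi")].trials[0].rate
        a = out[("head_on_body_active", "ipsi")].trials[0].rate
        assert np.max(p) == pytest.approx(np.max(a), rel=1e-6)

    def test_flat_during_attempted_movement(self, transient_suite):
        kin_map = {("attempted", "ipsi"):
                   [assign_condition_kinematics(k, "attempted")
                    for k in transient_suite[("attempted", "ipsi")]["trials"][:2]]}
        out = synthesize_rfn_reference(kin_map, 0.5, 0.7,
                                       noise_model=NoiseModel("none"))
        for tr in out[("attempted", "ipsi")].trials:
            assert np.ptp(tr.rate) < 1e-9

    def test_invalid_suppression_rejected(self):
        with pytest.raises(ValueError):
            synthesize_rfn_reference({}, 0.5, 1.5)


class TestMossyFibers:
    def test_default_gain_and_phase_statistics(self):
        sims = simulate_mossy_fibers(1000, seed=3)
        gains = np.array([s.gain_vest for s in sims])
        phases = np.array([s.phase_vest for s in sims])
        assert abs(gains.mean() - 0.6) < 3 * 0.1 / np.sqrt(1000)
        assert gains.std() == pytest.approx(0.1, rel=0.15)
        assert abs(phases.mean() - 20.0) < 3 * 5.0 / np.sqrt(1000)

    @pytest.mark.parametrize("modifier,gain,phase", [
        ("gain_x2", 1.2, 20.0), ("gain_half", 0.3, 20.0),
        ("phase_x2", 0.6, 40.0), ("phase_half", 0.6, 10.0)])
    def test_modifier_distributions(self, modifier, gain, phase):
        sims = simulate_mossy_fibers(600, modifier=modifier, seed=4)
        assert np.mean([s.gain_vest for s in sims]) == pytest.approx(gain,
                                                                     rel=0.1)
        assert np.mean([s.phase_vest for s in sims]) == pytest.approx(phase,
                                                                      rel=0.1)

    def test_unknown_modifier_rejected(self):
        with pytest.raises(ValueError):
            simulate_mossy_fibers(10, modifier="gain_x3")


class TestAveragedRates:
    def test_averaged_noise_mode_matches_per_trial_statistics(self):
        pop = sample_population(6, seed=5)
        suite = synth.condition_suite(("head_on_body_passive",), 10, seed=6)
        a = synth.population_average_rates(pop, suite, n_trials=40,
                                           noise_mode="averaged", seed=1)
        b = synth.population_average_rates(pop, suite, n_trials=40,
                                           noise_mode="per_trial", seed=2)
        for nid in a[0]:
            for key in a[0][nid]:
                x, y = a[0][nid][key], b[0][nid][key]
                # same deterministic mean; residual noise ~ sd/sqrt(40)
                assert np.abs(x - y).mean() < 4 * 10.0 / np.sqrt(40)

    def test_deterministic_given_seed(self):
        pop = sample_population(3, seed=5)
        suite = synth.condition_suite(("head_on_body_active",), 5, seed=6)
        a = synth.population_average_rates(pop, suite, n_trials=30, seed=9)
        b = synth.population_average_rates(pop, suite, n_trials=30, seed=9)
        for nid in a[0]:
            for key in a[0][nid]:
                assert np.array_equal(a[0][nid][key], b[0][nid][key])


def test_vector_to_coeffs_round_trip():
    from reafference.kinfit import response_vector
    for sens, phase in [(0.5, 0.0), (-0.3, 25.0), (0.8, -40.0), (1.2, 60.0)]:
        vec = response_vector(vector_to_coeffs(sens, phase))
        assert vec.sensitivity == pytest.approx(sens, rel=1e-9)
        assert vec.phase_deg == pytest.approx(phase, abs=1e-9)
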