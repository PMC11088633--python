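"""Sign-constrained regression, gain/phase transform, tuning classification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import nnls

from reafference import synth
from reafference.kinfit import (CombinedRatios, bootstrap_prune,
                                channel_regressors, classify_tuning,
                                combined_ratios, fit_kinematic,
                                response_vector)
from reafference.synth import (KinematicTrace, NeuronGroundTruth,
                               PiecewiseChannel, NoiseModel,
                               assign_condition_kinematics,
                               make_sinusoid_profile, synthesize_trials,
                               vector_to_coeffs)

from conftest import downsample_kin


def _whole_body_kin(n_trials=4):
    """Transient whole-body rotations: unlike a single-frequency sinusoid,
    the raised-cosine profile makes position/velocity/acceleration linearly
    independent of the bias, so coefficients are identifiable."""
    kins = []
    for i in range(n_trials):
        d = "ipsi" if i % 2 == 0 else "contra"
        p = synth.make_motion_profile(80.0, 500.0, 1, direction=d,
                                      amplitude_jitter=0.1,
                                      onset_jitter_ms=10.0, seed=50 + i)[0]
        kins.append(assign_condition_kinematics(p, "whole_body"))
    return kins


# ---------------------------------------------------------------------------
# sign-constrained fitting
# ---------------------------------------------------------------------------

class TestFitKinematic:
    def test_exact_recovery_of_velocity_coding(self):
        kins = _whole_body_kin(2)
        rates = [50.0 + 0.4 * k.head_vel for k in kins]
        fit = fit_kinematic(rates, kins, channels=("head",))
        ch = fit.channel("head")
        assert fit.bias == pytest.approx(50.0, abs=1e-6)
        assert ch.c_v == pytest.approx(0.4, abs=1e-8)
        assert abs(ch.c_p) < 1e-8 and abs(ch.c_a) < 1e-8
        assert fit.vaf == pytest.approx(1.0, abs=1e-9)

    def test_negative_channel_selected_for_inhibitory_coding(self):
        kins = _whole_body_kin(2)
        rates = [60.0 - 0.3 * k.head_vel for k in kins]
        fit = fit_kinematic(rates, kins, channels=("head",))
        assert fit.channel("head").sign == -1
        assert fit.channel("head").c_v == pytest.approx(-0.3, abs=1e-8)

    def test_rank_deficient_design_rejected(self):
        kins = [assign_condition_kinematics(p, "attempted")
                for p in make_sinusoid_profile(n_trials=2)]
        rates = [np.full(k.t.size, 50.0) for k in kins]
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_kinematic(rates, kins, channels=("head",))

    def test_matches_sign_enumeration_nnls_oracle(self):
        """Small random instances against an independent solver route:
        exhaustive sign enumeration with column-flipped NNLS."""
        master = np.random.default_rng(21)
        # joint whole-body + body-under-head set dissociates the channels
        wb = [downsample_kin(k, 10) for k in _whole_body_kin(2)]
        p = synth.make_motion_profile(80.0, 500.0, 1, amplitude_jitter=0.0,
                                      onset_jitter_ms=0.0, seed=60)[0]
        bu = [downsample_kin(assign_condition_kinematics(p, "body_under_head"),
                             10)]
        kins = wb + bu
        for _ in range(30):
            rates = [master.normal(60, 20, size=k.t.size) for k in kins]
            fit = fit_kinematic(rates, kins, channels=("head", "body"))
            # oracle: per sign combination, flip columns and require all
            # coefficients non-negative; the free bias is a difference of two
            # non-negative columns (columns normalized for NNLS conditioning)
            H = np.vstack([channel_regressors(k, "head") for k in kins])
            B = np.vstack([channel_regressors(k, "body") for k in kins])
            y = np.concatenate(rates)
            ones = np.ones((y.size, 1))
            best = np.inf
            for s1 in (1, -1):
                for s2 in (1, -1):
                    A = np.hstack([s1 * H, s2 * B, ones, -ones])
                    A = A / np.linalg.norm(A, axis=0, keepdims=True)
                    _, rnorm = nnls(A, y, maxiter=100 * A.shape[1])
                    best = min(best, rnorm ** 2)
            assert fit.rss == pytest.approx(best, rel=1e-6, abs=1e-6)

    def test_constrained_never_beats_unconstrained(self):
        master = np.random.default_rng(4)
        kins = [downsample_kin(k, 10) for k in _whole_body_kin(2)]
        X = np.vstack([np.column_stack([np.ones(k.t.size),
                                        channel_regressors(k, "head")])
                       for k in kins])
        for _ in range(20):
            rates = [master.normal(60, 15, size=k.t.size) for k in kins]
            y = np.concatenate(rates)
            fit = fit_kinematic(rates, kins, channels=("head",))
            coef, res, *_ = np.linalg.lstsq(X, y, rcond=None)
            rss_unc = float(np.sum((y - X @ coef) ** 2))
            assert fit.rss >= rss_unc - 1e-6
            if np.all(coef[1:] >= 0) or np.all(coef[1:] <= 0):
                assert fit.rss == pytest.approx(rss_unc, rel=1e-9)


class TestBootstrapPrune:
    def _trials(self, seed, c_v=0.4):
        nrn = NeuronGroundTruth(
            neuron_id="x", resting_rate=60.0,
            vest=PiecewiseChannel((0.0, 0.0), (c_v, c_v), (0.0, 0.0)),
            neck=PiecewiseChannel(), cancellation_gain=0.9,
            modality="unimodal")
        kins = _whole_body_kin(8)
        ts = synthesize_trials(nrn, kins, "whole_body",
                               noise_model=NoiseModel("gaussian", 10.0),
                               seed=seed)
        step = 5
        return ([tr.rate[::step] for tr in ts.trials],
                [downsample_kin(k, step) for k in kins])

    def test_fixed_seed_gives_identical_intervals(self):
        rates, kins = self._trials(3)
        a = bootstrap_prune(rates, kins, n_boot=100, seed=42)
        b = bootstrap_prune(rates, kins, n_boot=100, seed=42)
        assert a.channel("head").ci == b.channel("head").ci

    def test_prune_keeps_true_velocity_coefficient(self):
        rates, kins = self._trials(7)
        fit = bootstrap_prune(rates, kins, n_boot=200, seed=1)
        assert fit.channel("head").c_v != 0.0

    def test_too_few_trials_rejected(self):
        rates, kins = self._trials(3)
        with pytest.raises(ValueError):
            bootstrap_prune(rates[:3], kins[:3])


# ---------------------------------------------------------------------------
# gain/phase vectorization
# ---------------------------------------------------------------------------

class TestResponseVector:
    def test_pure_velocity_coding(self):
        vec = response_vector((0.0, 0.5, 0.0))
        assert vec.sensitivity == pytest.approx(0.5)
        assert vec.phase_deg == pytest.approx(0.0)

    def test_pure_acceleration_coding(self):
        w = 2 * np.pi
        vec = response_vector((0.0, 0.0, 1.0 / w ** 2))
        assert vec.sensitivity == pytest.approx(1.0 / w, rel=1e-9)
        assert vec.phase_deg == pytest.approx(90.0)

    def test_matches_time_domain_sinusoid_oracle(self):
        """Gain/phase against direct simulation of the coefficient model's
        response to a 1 Hz velocity sinusoid."""
        master = np.random.default_rng(5)
        t = np.arange(0.0, 1000.0) / 1000.0
        w = 2 * np.pi
        pos, vel, acc = -np.cos(w * t) / w, np.sin(w * t), w * np.cos(w * t)
        for _ in range(50):
            sens = float(master.uniform(0.05, 1.5)) * master.choice([-1, 1])
            phase = float(master.uniform(-75, 75))
            c_p, c_v, c_a = vector_to_coeffs(sens, phase)
            resp = c_p * pos + c_v * vel + c_a * acc
            # amplitude and phase relative to velocity via quadrature fit
            a = 2 * np.mean(resp * np.sin(w * t))
            b = 2 * np.mean(resp * np.cos(w * t))
            amp = np.hypot(a, b)
            ph = np.degrees(np.arctan2(b, a))
            vec = response_vector((c_p, c_v, c_a))
            assert abs(vec.sensitivity) == pytest.approx(amp, rel=1e-6)
            expected_ph = ph if vec.sensitivity >= 0 else \
                (ph - 180 if ph > 0 else ph + 180)
            assert vec.phase_deg == pytest.approx(expected_ph, abs=1e-6)

    @given(st.floats(-2, 2).filter(lambda k: abs(k) > 1e-3),
           st.floats(0.05, 1.0), st.floats(-70, 70))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_one_homogeneity(self, k, sens, phase):
        c = np.array(vector_to_coeffs(sens, phase))
        base = response_vector(tuple(c))
        scaled = response_vector(tuple(k * c))
        assert abs(scaled.sensitivity) == pytest.approx(
            abs(k) * abs(base.sensitivity), rel=1e-9)
        assert np.sign(scaled.sensitivity) == np.sign(k) * np.sign(
            base.sensitivity)
        assert scaled.phase_deg == pytest.approx(base.phase_deg, abs=1e-6)

    def test_zero_velocity_coefficient_phase_limit(self):
        assert response_vector((0.5, 0.0, 0.0)).phase_deg == -90.0
        assert response_vector((0.0, 0.0, 0.1)).phase_deg == 90.0


# ---------------------------------------------------------------------------
# tuning classification
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("s_ipsi,s_contra,shape,type_label", [
    (0.5, 0.45, "linear", "I"),       # increase pref, decrease nonpref, |d|<=0.2
    (0.5, 0.1, "rectifying", "I"),    # minimal nonpreferred modulation
    (0.5, -0.4, "V_shaped", "I"),     # increases in both directions
    (-0.45, -0.5, "linear", "II"),    # contralateral-preferring mirror
    (0.8, 0.3, "other", "I"),         # asymmetric beyond threshold
    (-0.1, 0.12, "other", "II"),      # decreases in both directions
])
def test_tuning_classification_rules(s_ipsi, s_contra, shape, type_label):
    tc = classify_tuning(s_ipsi, s_contra)
    assert tc.shape == shape
    assert tc.type_label == type_label


# ---------------------------------------------------------------------------
# combined-condition ratios
# ---------------------------------------------------------------------------

class TestCombinedRatios:
    @staticmethod
    def _combined_fit(neuron):
        profile = synth.make_motion_profile(110.0, 500.0, 6,
                                            amplitude_jitter=0.05,
                                            onset_jitter_ms=0.0, seed=3)
        kins = [assign_condition_kinematics(p, "combined") for p in profile]
        ts = synthesize_trials(neuron, kins, "combined",
                               noise_model=NoiseModel("gaussian", 5.0), seed=4)
        step = 2
        return fit_kinematic([tr.rate[::step] for tr in ts.trials],
                             [downsample_kin(k, step) for k in kins],
                             channels=("passive_head", "active_head"))

    def test_selective_passive_coder(self):
        # encodes only exafference -> exafference ~ 1, reafference ~ 0
        nrn = NeuronGroundTruth(
            neuron_id="p", resting_rate=80.0,
            vest=PiecewiseChannel((0, 0), (0.5, 0.5), (0, 0)),
            neck=PiecewiseChannel(), cancellation_gain=1.0,
            modality="unimodal", motor_responsive=True)
        ratios = combined_ratios(self._combined_fit(nrn), 0.5)
        assert ratios.exafference_ratio == pytest.approx(1.0, abs=0.15)
        assert ratios.reafference_ratio < 0.15

    def test_total_head_motion_coder(self):
        # encodes head-in-space regardless of source -> both ratios ~ 1
        nrn = NeuronGroundTruth(
            neuron_id="t", resting_rate=80.0,
            vest=PiecewiseChannel((0, 0), (0.5, 0.5), (0, 0)),
            neck=PiecewiseChannel(), cancellation_gain=0.0,
            modality="unimodal", motor_responsive=False)
        ratios = combined_ratios(self._combined_fit(nrn), 0.5)
        assert ratios.exafference_ratio == pytest.approx(1.0, abs=0.15)
        assert ratios.reafference_ratio == pytest.approx(1.0, abs=0.15)

    def test_attenuated_reafference_recovered(self):
        nrn = NeuronGroundTruth(
            neuron_id="a", resting_rate=80.0,
            vest=PiecewiseChannel((0, 0), (0.5, 0.5), (0, 0)),
            neck=PiecewiseChannel(), cancellation_gain=0.8,
            modality="unimodal", motor_responsive=False)
        ratios = combined_ratios(self._combined_fit(nrn), 0.5)
        assert ratios.reafference_ratio == pytest.approx(0.2, abs=0.1)

    def test_zero_passive_sensitivity_flagged(self):
        nrn = NeuronGroundTruth(
            neuron_id="z", resting_rate=80.0,
            vest=PiecewiseChannel((0, 0), (0.3, 0.3), (0, 0)),
            neck=PiecewiseChannel(), cancellation_gain=0.5,
            modality="unimodal")
        ratios = combined_ratios(self._combined_fit(nrn), 0.0)
        assert not ratios.defined
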