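"""Synthetic head/neck kinematics, Purkinje-cell populations and firing-rate trials.

This module generates everything the downstream analyses consume: per-trial
head/body kinematics at 1 kHz for the six behavioural conditions, ground-truth
Purkinje-cell populations with heterogeneous vestibular and neck-proprioceptive
tuning, firing-rate (or spike-train) trials, neck-torque traces for attempted
movements, a reference deep-cerebellar target-neuron response, and simulated
mossy-fiber inputs.

The central construction is the forward model of a single cell's rate,

    fr(t) = max(0, b + vest(head) + neck(head - body) + motor(t) + noise),

where ``vest`` and ``neck`` are (position, velocity, acceleration) channels
that may differ between the two movement directions, and ``motor`` is an
efference-copy template.  For motor-responsive cells the template is the
negative of the cell's own predicted sensory reafference, scaled by a
cancellation gain ``k`` and advanced by a fixed motor lead.  Active responses
therefore equal the sum of the passive response and the attempted-movement
response by construction, and the active/passive sensitivity ratio is
``(1 - k)``: cells with ``k < 1`` are attenuated with the same sign, cells
with ``k > 1`` reverse sign.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d

FS_HZ = 1000.0
DT_MS = 1.0

CONDITIONS = (
    "whole_body",
    "body_under_head",
    "head_on_body_passive",
    "head_on_body_active",
    "combined",
    "attempted",
)
DIRECTIONS = ("ipsi", "contra")

#: sign convention: positive rotation = ipsilateral to the recorded side
DIRECTION_SIGN = {"ipsi": 1.0, "contra": -1.0}

# Default study conditions (see docs/methods.md for provenance of each value).
DEFAULT_ACTIVE_PEAK_DPS = 110.0     # raised-cosine peak -> 27.5 deg displacement
DEFAULT_DURATION_MS = 500.0         # half-cycle duration
DEFAULT_SINUSOID_PEAK_DPS = 40.0    # passive whole-body sinusoid
DEFAULT_SINUSOID_FREQ_HZ = 1.0
MAX_DISPLACEMENT_DEG = 30.0
DEFAULT_TORQUE_PEAK_NM = 1.5
DEFAULT_MOTOR_LEAD_MS = 0.0   # forward model compensates efferent delay


# ---------------------------------------------------------------------------
# kinematics
# ---------------------------------------------------------------------------

@dataclass
class KinematicTrace:
    """Time-aligned head/body kinematics sampled at 1 kHz.

    ``t`` is in ms with 0 at (intended) movement onset.  Positions are in
    degrees, velocities in deg/s, accelerations in deg/s^2.  For the combined
    condition the head velocity decomposes exactly into a passive and an
    active component.
    """

    t: np.ndarray
    head_pos: np.ndarray
    head_vel: np.ndarray
    head_acc: np.ndarray
    body_pos: np.ndarray
    body_vel: np.ndarray
    body_acc: np.ndarray
    passive_head_vel: np.ndarray
    active_head_vel: np.ndarray

    def __post_init__(self) -> None:
        n = self.t.size
        for name in ("head_pos", "head_vel", "head_acc", "body_pos",
                     "body_vel", "body_acc", "passive_head_vel",
                     "active_head_vel"):
            if getattr(self, name).size != n:
                raise ValueError(f"field {name!r} length mismatch")

    @property
    def neck_vel(self) -> np.ndarray:
        """Head-relative-to-body (neck) velocity."""
        return self.head_vel - self.body_vel

    @property
    def neck_pos(self) -> np.ndarray:
        return self.head_pos - self.body_pos

    @property
    def neck_acc(self) -> np.ndarray:
        return self.head_acc - self.body_acc

    def displacement(self) -> float:
        return float(np.max(np.abs(self.head_pos)))


def _zeros_like_time(t: np.ndarray) -> dict:
    z = np.zeros_like(t)
    return dict(head_pos=z.copy(), head_vel=z.copy(), head_acc=z.copy(),
                body_pos=z.copy(), body_vel=z.copy(), body_acc=z.copy(),
                passive_head_vel=z.copy(), active_head_vel=z.copy())


def _raised_cosine(t_ms: np.ndarray, peak_dps: float, duration_ms: float,
                   onset_ms: float = 0.0):
    """Analytic raised-cosine velocity half-cycle and its integrals.

    Returns (pos, vel, acc); all zero before onset, displacement plateaus
    after the half-cycle completes.
    """
    d_s = duration_ms / 1000.0
    tau = (t_ms - onset_ms) / 1000.0
    x = np.clip(tau / d_s, 0.0, 1.0)
    vel = peak_dps * 0.5 * (1.0 - np.cos(2.0 * np.pi * x))
    vel = np.where((tau >= 0) & (tau <= d_s), vel, 0.0)
    pos = peak_dps * (x * d_s / 2.0 - (d_s / (4.0 * np.pi)) * np.sin(2.0 * np.pi * x))
    pos = np.where(tau > d_s, peak_dps * d_s / 2.0, pos)
    acc = peak_dps * (np.pi / d_s) * np.sin(2.0 * np.pi * x)
    acc = np.where((tau >= 0) & (tau <= d_s), acc, 0.0)
    return pos, vel, acc


def make_motion_profile(peak_velocity: float, duration_ms: float = DEFAULT_DURATION_MS,
                        n_trials: int = 1, *,
                        direction: str = "ipsi",
                        amplitude_jitter: float = 0.1,
                        onset_jitter_ms: float = 20.0,
                        pre_ms: float = 400.0,
                        post_ms: float = 300.0,
                        seed=None) -> list[KinematicTrace]:
    """Generate active-like unidirectional motion half-cycles.

    Each trial is a smooth raised-cosine velocity half-cycle of roughly
    ``duration_ms`` reaching about ``peak_velocity`` deg/s, with seeded
    trial-to-trial jitter in amplitude and onset time.  Displacement is capped
    at 30 deg (the behavioural range of the paradigm the generator emulates).
    The motion is stored in the head channels; `assign_condition_kinematics`
    maps it onto a behavioural condition.
    """
    if duration_ms <= 0:
        raise ValueError("duration_ms must be positive")
    if peak_velocity <= 0:
        raise ValueError("peak_velocity must be positive")
    if direction not in DIRECTIONS:
        raise ValueError(f"unknown direction {direction!r}")
    rng = np.random.default_rng(seed)
    sgn = DIRECTION_SIGN[direction]
    t = np.arange(-pre_ms, duration_ms + post_ms, DT_MS)
    traces = []
    for _ in range(int(n_trials)):
        amp = 1.0 + amplitude_jitter * float(np.clip(rng.standard_normal(), -2, 2))
        onset = onset_jitter_ms * float(np.clip(rng.standard_normal(), -2, 2))
        peak = peak_velocity * max(amp, 0.1)
        # cap displacement at the paradigm's +-30 deg range
        disp = peak * duration_ms / 2000.0
        if disp > MAX_DISPLACEMENT_DEG:
            peak *= MAX_DISPLACEMENT_DEG / disp
        pos, vel, acc = _raised_cosine(t, peak, duration_ms, onset)
        traces.append(KinematicTrace(
            t=t.copy(),
            head_pos=sgn * pos, head_vel=sgn * vel, head_acc=sgn * acc,
            body_pos=np.zeros_like(t), body_vel=np.zeros_like(t),
            body_acc=np.zeros_like(t),
            passive_head_vel=np.zeros_like(t), active_head_vel=sgn * vel,
        ))
    return traces


def make_sinusoid_profile(peak_velocity: float = DEFAULT_SINUSOID_PEAK_DPS,
                          freq_hz: float = DEFAULT_SINUSOID_FREQ_HZ,
                          n_cycles: int = 2, n_trials: int = 1, *,
                          seed=None) -> list[KinematicTrace]:
    """Sinusoidal motion profile (passive rotation paradigms)."""
    if peak_velocity <= 0 or freq_hz <= 0:
        raise ValueError("peak_velocity and freq_hz must be positive")
    t = np.arange(0.0, n_cycles * 1000.0 / freq_hz, DT_MS)
    w = 2.0 * np.pi * freq_hz
    tau = t / 1000.0
    vel = peak_velocity * np.sin(w * tau)
    pos = peak_velocity / w * (1.0 - np.cos(w * tau))
    acc = peak_velocity * w * np.cos(w * tau)
    tr = KinematicTrace(t=t, head_pos=pos, head_vel=vel, head_acc=acc,
                        body_pos=np.zeros_like(t), body_vel=np.zeros_like(t),
                        body_acc=np.zeros_like(t),
                        passive_head_vel=vel.copy(),
                        active_head_vel=np.zeros_like(t))
    return [replace(tr, t=t.copy()) for _ in range(int(n_trials))]


def assign_condition_kinematics(profile: KinematicTrace, condition: str, *,
                                sinusoid_peak: float = DEFAULT_SINUSOID_PEAK_DPS,
                                sinusoid_freq: float = DEFAULT_SINUSOID_FREQ_HZ,
                                ) -> KinematicTrace:
    """Map a motion profile onto a behavioural condition.

    whole_body            head and body move together (no neck motion)
    body_under_head       body moves beneath a space-stationary head
    head_on_body_passive  head rotates on a stationary body (imposed)
    head_on_body_active   same kinematics, self-generated
    combined              active head-on-body atop a passive 1 Hz sinusoid
    attempted             intended movement withheld: all kinematics zero
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    t = profile.t
    p, v, a = profile.head_pos, profile.head_vel, profile.head_acc
    fields = _zeros_like_time(t)
    if condition == "whole_body":
        fields.update(head_pos=p, head_vel=v, head_acc=a,
                      body_pos=p.copy(), body_vel=v.copy(), body_acc=a.copy(),
                      passive_head_vel=v.copy())
    elif condition == "body_under_head":
        fields.update(body_pos=p, body_vel=v, body_acc=a)
    elif condition == "head_on_body_passive":
        fields.update(head_pos=p, head_vel=v, head_acc=a,
                      passive_head_vel=v.copy())
    elif condition == "head_on_body_active":
        fields.update(head_pos=p, head_vel=v, head_acc=a,
                      active_head_vel=v.copy())
    elif condition == "combined":
        w = 2.0 * np.pi * sinusoid_freq
        tau = t / 1000.0
        sv = sinusoid_peak * np.sin(w * tau)
        sp = sinusoid_peak / w * (1.0 - np.cos(w * tau))
        sa = sinusoid_peak * w * np.cos(w * tau)
        fields.update(head_pos=p + sp, head_vel=v + sv, head_acc=a + sa,
                      body_pos=sp, body_vel=sv, body_acc=sa,
                      passive_head_vel=sv.copy(), active_head_vel=v.copy())
    # attempted: everything stays zero
    return KinematicTrace(t=t.copy(), **fields)


# ---------------------------------------------------------------------------
# ground-truth neurons
# ---------------------------------------------------------------------------

def vector_to_coeffs(sensitivity: float, phase_deg: float, f_hz: float = 1.0):
    """Invert the gain/phase vectorization into a sign-consistent
    (c_p, c_v, c_a) triple at frequency ``f_hz``.

    The triple shares the sign of ``sensitivity`` and reproduces the requested
    gain and phase under the response-vector transform.  Requires
    ``|phase_deg| < 90``.
    """
    if not -90.0 < phase_deg < 90.0:
        raise ValueError("phase must lie strictly within (-90, 90) degrees")
    w = 2.0 * np.pi * f_hz
    s = abs(sensitivity)
    sgn = 1.0 if sensitivity >= 0 else -1.0
    phi = math.radians(phase_deg)
    c_v = s * math.cos(phi)
    a_term = w * s * math.sin(phi)       # = w^2 c_a - c_p
    if a_term >= 0:
        c_a, c_p = a_term / w ** 2, 0.0
    else:
        c_a, c_p = 0.0, -a_term
    return sgn * c_p, sgn * c_v, sgn * c_a


@dataclass(frozen=True)
class PiecewiseChannel:
    """A kinematic input channel with direction-dependent coefficients.

    Coefficient pairs are indexed by the sign of the driving velocity:
    element 0 applies where the channel velocity is >= 0 (ipsilateral),
    element 1 where it is negative.  Linear cells use identical pairs.
    """

    c_pos: tuple[float, float] = (0.0, 0.0)
    c_vel: tuple[float, float] = (0.0, 0.0)
    c_acc: tuple[float, float] = (0.0, 0.0)

    def respond(self, pos, vel, acc) -> np.ndarray:
        positive = vel >= 0
        r_pos = self.c_pos[0] * pos + self.c_vel[0] * vel + self.c_acc[0] * acc
        r_neg = self.c_pos[1] * pos + self.c_vel[1] * vel + self.c_acc[1] * acc
        return np.where(positive, r_pos, r_neg)

    def is_zero(self) -> bool:
        return all(c == (0.0, 0.0) for c in (self.c_pos, self.c_vel, self.c_acc))

    def is_linear(self) -> bool:
        return (self.c_pos[0] == self.c_pos[1] and self.c_vel[0] == self.c_vel[1]
                and self.c_acc[0] == self.c_acc[1])

    def scaled(self, k: float) -> "PiecewiseChannel":
        return PiecewiseChannel(
            (k * self.c_pos[0], k * self.c_pos[1]),
            (k * self.c_vel[0], k * self.c_vel[1]),
            (k * self.c_acc[0], k * self.c_acc[1]),
        )

    @staticmethod
    def from_vectors(vec_pos, vec_neg, f_hz: float = 1.0) -> "PiecewiseChannel":
        """Build a channel from per-side (sensitivity, phase_deg) pairs."""
        p0, v0, a0 = vector_to_coeffs(*vec_pos, f_hz)
        p1, v1, a1 = vector_to_coeffs(*vec_neg, f_hz)
        return PiecewiseChannel((p0, p1), (v0, v1), (a0, a1))


@dataclass
class NeuronGroundTruth:
    """Generator-side truth for one synthetic Purkinje cell.

    ``vest`` responds to head-in-space motion, ``neck`` to head-re-body
    motion.  ``cancellation_gain`` k sets the efference-copy template
    (motor-responsive cells) or the direct sensory attenuation (others); the
    active/passive sensitivity ratio is (1 - k).
    """

    neuron_id: str
    resting_rate: float
    vest: PiecewiseChannel
    neck: PiecewiseChannel
    cancellation_gain: float
    motor_lead_ms: float = DEFAULT_MOTOR_LEAD_MS
    modality: str = "bimodal"            # bimodal | unimodal | vestibular_insensitive
    active_sign: str = "same"            # same | flipped | other
    type_label: str = "I"                # I (ipsi-excited) | II
    tuning: str = "linear"               # linear | rectifying | V_shaped
    motor_responsive: bool = True

    def __post_init__(self) -> None:
        if self.resting_rate <= 0:
            raise ValueError("resting_rate must be positive")
        if self.modality == "unimodal" and not self.neck.is_zero():
            raise ValueError("unimodal cells must have zero neck coefficients")

    @property
    def active_factor(self) -> float:
        """Signed active/passive sensitivity ratio (1 - k)."""
        return 1.0 - self.cancellation_gain

    def eq1_head_channel(self) -> PiecewiseChannel:
        """Head-motion (i=1) coefficients in the regression basis: vest + neck."""
        return PiecewiseChannel(
            tuple(a + b for a, b in zip(self.vest.c_pos, self.neck.c_pos)),
            tuple(a + b for a, b in zip(self.vest.c_vel, self.neck.c_vel)),
            tuple(a + b for a, b in zip(self.vest.c_acc, self.neck.c_acc)),
        )

    def eq1_body_channel(self) -> PiecewiseChannel:
        """Body-motion (i=2) coefficients in the regression basis: -neck."""
        return self.neck.scaled(-1.0)

    def sensory_drive(self, kin: KinematicTrace) -> np.ndarray:
        """Unattenuated sensory response (vestibular + proprioceptive)."""
        return (self.vest.respond(kin.head_pos, kin.head_vel, kin.head_acc)
                + self.neck.respond(kin.neck_pos, kin.neck_vel, kin.neck_acc))

    def motor_template(self, intended: KinematicTrace) -> np.ndarray:
        """Efference-copy firing-rate template for an intended movement.

        The negative of the predicted sensory reafference, scaled by the
        cancellation gain and advanced by the motor lead.  Zero for cells
        without a motor response.
        """
        if not self.motor_responsive:
            return np.zeros_like(intended.t)
        pred = self.sensory_drive(intended)
        shifted = np.interp(intended.t + self.motor_lead_ms, intended.t, pred,
                            left=pred[0], right=pred[-1])
        return -self.cancellation_gain * shifted


def _draw_direction_magnitudes(rng, s_pref: float, tuning: str,
                               threshold: float = 0.2):
    """Per-side sensitivity magnitudes consistent with a tuning class."""
    if tuning == "rectifying":
        s_np = float(rng.uniform(0.02, min(0.15, threshold * 0.75)))
    else:
        s_np = max(0.05, s_pref - float(rng.uniform(0.0, 0.10)))
        # keep the class-defining |s_p| - |s_np| <= 0.2 margin
        s_np = max(s_np, s_pref - 0.9 * threshold)
        s_np = min(s_np, s_pref)
    return s_pref, s_np


def sample_population(n: int, *,
                      fractions: Mapping[str, float] | None = None,
                      sens_median: float = 0.4,
                      sens_sigma: float = 0.5,
                      phase_mean: float = 0.0,
                      phase_sd: float = 10.0,
                      attenuation_mean: float = 0.92,
                      attenuation_sd: float = 0.03,
                      flip_gain_mean: float = 1.12,
                      flip_gain_sd: float = 0.05,
                      resting_median: float = 70.0,
                      resting_sigma: float = 0.3,
                      motor_lead_ms: float = DEFAULT_MOTOR_LEAD_MS,
                      seed=None) -> list[NeuronGroundTruth]:
    """Draw a heterogeneous ground-truth Purkinje-cell population.

    Categorical axes (defaults): modality bimodal 0.70 / unimodal 0.20 /
    vestibular_insensitive 0.10; motor_responsive 0.80; active-response sign
    same 0.50 / flipped 0.40 / other 0.10; type I/II 0.5 each; tuning linear
    0.55 / rectifying 0.25 / V_shaped 0.20.  Passive sensitivities are
    lognormal (median ``sens_median``); cancellation gains are calibrated so
    the population-mean preferred-direction attenuation matches
    ``attenuation_mean`` (default 92%).
    """
    fr = {
        "bimodal": 0.70, "unimodal": 0.20, "vestibular_insensitive": 0.10,
        "motor_responsive": 0.80,
        "same": 0.50, "flipped": 0.40, "other": 0.10,
        "type_I": 0.50,
        "linear": 0.70, "rectifying": 0.15, "V_shaped": 0.15,
    }
    if fractions:
        fr.update(fractions)
    for axis in (("bimodal", "unimodal", "vestibular_insensitive"),
                 ("same", "flipped", "other"),
                 ("linear", "rectifying", "V_shaped")):
        total = sum(fr[k] for k in axis)
        if total > 1.0 + 1e-9 or any(fr[k] < 0 for k in axis):
            raise ValueError(f"fractions for axis {axis} invalid (sum {total})")

    rng = np.random.default_rng(seed)
    mu = math.log(sens_median)
    neurons = []
    for i in range(int(n)):
        modality = rng.choice(
            ["bimodal", "unimodal", "vestibular_insensitive"],
            p=[fr["bimodal"], fr["unimodal"], fr["vestibular_insensitive"]])
        active_sign = rng.choice(["same", "flipped", "other"],
                                 p=[fr["same"], fr["flipped"], fr["other"]])
        tuning = rng.choice(["linear", "rectifying", "V_shaped"],
                            p=[fr["linear"], fr["rectifying"], fr["V_shaped"]])
        type_label = "I" if rng.random() < fr["type_I"] else "II"
        motor = bool(rng.random() < fr["motor_responsive"])

        s_pref = float(np.exp(mu + sens_sigma * rng.standard_normal()))
        phase_v = float(np.clip(rng.normal(phase_mean, phase_sd), -75, 75))
        s_p, s_np = _draw_direction_magnitudes(rng, s_pref, tuning)

        # vestibular channel: type I excited by ipsilateral (positive) rotation
        pref_sign = 1.0 if type_label == "I" else -1.0
        # per-side signed velocity sensitivities; the non-preferred side keeps
        # the same sign for linear/rectifying cells and flips for V-shaped
        s_side_pref = pref_sign * s_p
        s_side_np = pref_sign * (-s_np if tuning == "V_shaped" else s_np)
        if type_label == "I":
            vec_pos, vec_neg = (s_side_pref, phase_v), (s_side_np, phase_v)
        else:
            vec_pos, vec_neg = (s_side_np, phase_v), (s_side_pref, phase_v)
        vest = PiecewiseChannel.from_vectors(vec_pos, vec_neg)
        if modality == "vestibular_insensitive":
            vest = PiecewiseChannel()

        # neck channel: linear, usually antagonistic to the vestibular channel
        if modality == "unimodal":
            neck = PiecewiseChannel()
        else:
            rho = float(rng.uniform(0.3, 1.0))
            antagonistic = rng.random() < 0.7
            base = s_pref if modality != "vestibular_insensitive" else \
                float(np.exp(mu + sens_sigma * rng.standard_normal()))
            neck_sign = -pref_sign if antagonistic else pref_sign
            phase_n = float(np.clip(rng.normal(phase_mean, phase_sd), -75, 75))
            sn = neck_sign * rho * base
            neck = PiecewiseChannel.from_vectors((sn, phase_n), (sn, phase_n))

        if active_sign == "same":
            k = float(np.clip(rng.normal(attenuation_mean, attenuation_sd),
                              0.84, 0.99))
        elif active_sign == "flipped":
            k = float(np.clip(rng.normal(flip_gain_mean, flip_gain_sd),
                              1.02, 1.30))
        else:
            k = float(rng.uniform(0.2, 0.6))

        resting = float(np.exp(math.log(resting_median)
                               + resting_sigma * rng.standard_normal()))
        neurons.append(NeuronGroundTruth(
            neuron_id=f"pc{i:04d}", resting_rate=resting, vest=vest, neck=neck,
            cancellation_gain=k, motor_lead_ms=motor_lead_ms,
            modality=str(modality), active_sign=str(active_sign),
            type_label=type_label, tuning=str(tuning), motor_responsive=motor))
    return neurons


# ---------------------------------------------------------------------------
# trials
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NoiseModel:
    """Rate-noise description.

    ``gaussian``: additive Gaussian noise on the rate with standard deviation
    ``sd`` (sp/s); ``corr_ms`` > 0 adds a Gaussian temporal correlation
    (emulating the smoothness of filtered spike-train estimates; 0 = white).
    ``poisson``: spike trains drawn as an inhomogeneous Poisson realization
    of the noise-free rate.  ``none``: deterministic rates.
    """

    kind: str = "gaussian"
    sd: float = 10.0
    corr_ms: float = 0.0

    def __post_init__(self):
        if self.kind not in ("gaussian", "poisson", "none"):
            raise ValueError(f"unknown noise kind {self.kind!r}")


def correlated_noise(rng, shape, sd: float, corr_ms: float,
                     dt_ms: float = DT_MS) -> np.ndarray:
    """Gaussian noise with a Gaussian autocorrelation of scale ``corr_ms``."""
    white = rng.standard_normal(shape)
    if corr_ms <= 0:
        return sd * white
    sigma = corr_ms / dt_ms
    smooth = gaussian_filter1d(white, sigma, axis=-1, mode="reflect")
    # restore unit variance: a unit-sum Gaussian kernel has sum(k^2) ~ 1/(2 sigma sqrt(pi))
    kernel_l2 = gaussian_filter1d(
        np.eye(1, max(int(8 * sigma) + 1, 3), max(int(4 * sigma), 1))[0],
        sigma, mode="constant")
    smooth /= math.sqrt(float(np.sum(kernel_l2 ** 2)))
    return sd * smooth


@dataclass
class Trial:
    kinematics: KinematicTrace
    rate: np.ndarray | None
    torque: np.ndarray
    direction: str
    spikes: np.ndarray | None = None


@dataclass
class TrialSet:
    """All trials of one neuron in one behavioural condition."""

    condition: str
    trials: list[Trial] = field(default_factory=list)
    neuron_id: str | None = None

    def rates(self) -> np.ndarray:
        return np.stack([tr.rate for tr in self.trials])

    def mean_rate(self) -> np.ndarray:
        return self.rates().mean(axis=0)

    def t(self) -> np.ndarray:
        return self.trials[0].kinematics.t


def torque_trace(t_ms: np.ndarray, direction: str,
                 peak_nm: float = DEFAULT_TORQUE_PEAK_NM,
                 tau_ms: float = 15.0) -> np.ndarray:
    """Stylized neck-torque waveform: a logistic rise whose 5%-of-range point
    sits at t = 0 (the intended movement onset)."""
    midpoint = tau_ms * math.log(19.0)
    return DIRECTION_SIGN[direction] * peak_nm / (
        1.0 + np.exp(-(t_ms - midpoint) / tau_ms))


def _noise_free_rate(neuron: NeuronGroundTruth, kin: KinematicTrace,
                     condition: str, intended: KinematicTrace | None):
    """Deterministic rate before rectification and noise."""
    b = neuron.resting_rate
    if condition in ("whole_body", "body_under_head", "head_on_body_passive"):
        return b + neuron.sensory_drive(kin)
    if condition == "attempted":
        if intended is None:
            raise ValueError("attempted condition requires an intended profile")
        return b + neuron.motor_template(intended)
    if condition == "head_on_body_active":
        # the efference copy predicts the trial's own movement
        if neuron.motor_responsive:
            return b + neuron.sensory_drive(kin) + neuron.motor_template(kin)
        return b + neuron.active_factor * neuron.sensory_drive(kin)
    if condition == "combined":
        # passive (exafferent) component at full gain; active component
        # attenuated by the efference copy
        passive_kin = KinematicTrace(
            t=kin.t, head_pos=kin.body_pos, head_vel=kin.body_vel,
            head_acc=kin.body_acc, body_pos=kin.body_pos, body_vel=kin.body_vel,
            body_acc=kin.body_acc,
            passive_head_vel=kin.passive_head_vel,
            active_head_vel=np.zeros_like(kin.t))
        active_kin = KinematicTrace(
            t=kin.t, head_pos=kin.head_pos - kin.body_pos,
            head_vel=kin.head_vel - kin.body_vel,
            head_acc=kin.head_acc - kin.body_acc,
            body_pos=np.zeros_like(kin.t), body_vel=np.zeros_like(kin.t),
            body_acc=np.zeros_like(kin.t),
            passive_head_vel=np.zeros_like(kin.t),
            active_head_vel=kin.active_head_vel)
        out = b + neuron.sensory_drive(passive_kin)
        if neuron.motor_responsive:
            out = (out + neuron.sensory_drive(active_kin)
                   + neuron.motor_template(active_kin))
        else:
            out = out + neuron.active_factor * neuron.sensory_drive(active_kin)
        return out
    raise ValueError(f"unknown condition {condition!r}")


def synthesize_trials(neuron: NeuronGroundTruth,
                      kinematics: Sequence[KinematicTrace],
                      condition: str,
                      n_trials: int | None = None,
                      noise_model: NoiseModel = NoiseModel(),
                      *,
                      intended: KinematicTrace | None = None,
                      direction: str = "ipsi",
                      emit_spikes: bool = False,
                      seed=None) -> TrialSet:
    """Synthesize one neuron's trials for a condition.

    ``kinematics`` supplies per-trial traces (cycled if shorter than
    ``n_trials``).  For executed movements the efference copy predicts the
    trial's own kinematics; ``intended`` supplies the stereotyped movement
    plan for the attempted condition, where no movement occurs.  Rates are
    rectified at 0 sp/s.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    if not kinematics:
        raise ValueError("at least one kinematic trace required")
    if n_trials is None:
        n_trials = len(kinematics)
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    for kin in kinematics:
        if condition == "attempted" and np.any(kin.head_vel != 0):
            raise ValueError("attempted condition requires zero head kinematics")
        if condition == "body_under_head" and np.any(kin.head_vel != 0):
            raise ValueError("body_under_head requires zero head-in-space motion")
    if intended is None and condition != "attempted":
        intended = kinematics[0]
    rng = np.random.default_rng(seed)
    trials = []
    for i in range(int(n_trials)):
        kin = kinematics[i % len(kinematics)]
        det = _noise_free_rate(neuron, kin, condition, intended)
        if noise_model.kind == "gaussian":
            rate = np.maximum(
                0.0, det + correlated_noise(rng, det.shape, noise_model.sd,
                                            noise_model.corr_ms))
        else:
            rate = np.maximum(0.0, det)
        spikes = None
        if emit_spikes or noise_model.kind == "poisson":
            spikes = poisson_spikes(np.maximum(0.0, det), kin.t, rng)
        if condition in ("head_on_body_active", "attempted", "combined"):
            torque = torque_trace(kin.t, direction)
        else:
            torque = np.zeros_like(kin.t)
        trials.append(Trial(kinematics=kin, rate=rate, torque=torque,
                            direction=direction, spikes=spikes))
    return TrialSet(condition=condition, trials=trials, neuron_id=neuron.neuron_id)


def poisson_spikes(rate: np.ndarray, t_ms: np.ndarray, rng) -> np.ndarray:
    """Inhomogeneous-Poisson spike times (ms) for a 1 kHz rate trace."""
    p = np.clip(rate * DT_MS / 1000.0, 0.0, 1.0)
    hits = rng.random(p.shape) < p
    return t_ms[hits] + rng.uniform(0.0, DT_MS, size=int(hits.sum()))


# ---------------------------------------------------------------------------
# reference target neuron and mossy fibers
# ---------------------------------------------------------------------------

def synthesize_rfn_reference(kinematics_by_condition: Mapping,
                             passive_sensitivity: float = 0.5,
                             suppression: float = 0.7, *,
                             phase_deg: float = 15.0,
                             resting_rate: float = 70.0,
                             noise_model: NoiseModel = NoiseModel(),
                             n_trials: int = 10,
                             seed=None) -> dict:
    """Reference deep-cerebellar target-neuron responses per condition.

    The reference cell encodes passive head-in-space motion with the given
    sensitivity, encodes active head motion at ``(1 - suppression)`` times
    that sensitivity (default 70% suppression), and is flat during attempted
    movements (it carries no motor-command signal).

    ``kinematics_by_condition`` maps ``(condition, direction)`` (or plain
    condition) keys to lists of KinematicTrace.
    """
    if not 0.0 <= suppression <= 1.0:
        raise ValueError("suppression must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    c_p, c_v, c_a = vector_to_coeffs(passive_sensitivity, phase_deg)
    chan = PiecewiseChannel((c_p, c_p), (c_v, c_v), (c_a, c_a))
    out = {}
    for key, kins in kinematics_by_condition.items():
        condition = key[0] if isinstance(key, tuple) else key
        direction = key[1] if isinstance(key, tuple) else "ipsi"
        trials = []
        for kin in kins:
            passive_vel = kin.passive_head_vel
            active_vel = kin.active_head_vel
            # reconstruct passive/active position & acceleration components
            dt_s = DT_MS / 1000.0
            ppos = np.cumsum(passive_vel) * dt_s
            pacc = np.gradient(passive_vel, dt_s)
            apos = np.cumsum(active_vel) * dt_s
            aacc = np.gradient(active_vel, dt_s)
            drive = (chan.respond(ppos, passive_vel, pacc)
                     + (1.0 - suppression) * chan.respond(apos, active_vel, aacc))
            det = resting_rate + drive
            if noise_model.kind == "gaussian":
                rate = np.maximum(0.0, det + correlated_noise(
                    rng, det.shape, noise_model.sd, noise_model.corr_ms))
            else:
                rate = np.maximum(0.0, det)
            torque = np.zeros_like(kin.t)
            trials.append(Trial(kinematics=kin, rate=rate, torque=torque,
                                direction=direction))
        ts = TrialSet(condition=condition, trials=trials, neuron_id="rfn_ref")
        out[key] = ts
    return out


MOSSY_MODIFIERS = {
    "none": ((0.6, 0.1), (20.0, 5.0)),
    "gain_x2": ((1.2, 0.2), (20.0, 5.0)),
    "gain_half": ((0.3, 0.05), (20.0, 5.0)),
    "phase_x2": ((0.6, 0.1), (40.0, 10.0)),
    "phase_half": ((0.6, 0.1), (10.0, 2.5)),
}


@dataclass
class MossyFiberSim:
    gain_vest: float
    phase_vest: float
    gain_neck: float
    phase_neck: float

    def respond(self, kin: KinematicTrace, f_hz: float = 1.0) -> np.ndarray:
        """Summed vestibular + neck-proprioceptive response to a movement."""
        w = 2.0 * np.pi * f_hz
        pv, pn = math.radians(self.phase_vest), math.radians(self.phase_neck)
        vest = self.gain_vest * (math.cos(pv) * kin.head_vel
                                 + math.sin(pv) * kin.head_acc / w)
        neck = self.gain_neck * (math.cos(pn) * kin.neck_vel
                                 + math.sin(pn) * kin.neck_acc / w)
        return vest + neck


def simulate_mossy_fibers(n_sim: int = 1000,
                          gain_mean_sd: tuple[float, float] | None = None,
                          phase_mean_sd: tuple[float, float] | None = None,
                          modifier: str = "none",
                          seed=None) -> list[MossyFiberSim]:
    """Draw simulated mossy-fiber inputs with vestibular-nucleus statistics.

    Gains and phases come from normal distributions (defaults
    0.6 +- 0.1 (sp/s)/(deg/s) and 20 +- 5 deg); ``modifier`` doubles or halves
    either distribution.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    if modifier not in MOSSY_MODIFIERS:
        raise ValueError(f"unknown modifier {modifier!r}")
    g_def, p_def = MOSSY_MODIFIERS[modifier]
    g_mu, g_sd = gain_mean_sd if gain_mean_sd is not None else g_def
    p_mu, p_sd = phase_mean_sd if phase_mean_sd is not None else p_def
    rng = np.random.default_rng(seed)
    sims = []
    for _ in range(int(n_sim)):
        sims.append(MossyFiberSim(
            gain_vest=float(rng.normal(g_mu, g_sd)),
            phase_vest=float(rng.normal(p_mu, p_sd)),
            gain_neck=float(rng.normal(g_mu, g_sd)),
            phase_neck=float(rng.normal(p_mu, p_sd)),
        ))
    return sims


# ---------------------------------------------------------------------------
# fast trial-averaged synthesis for population modeling
# ---------------------------------------------------------------------------

def condition_suite(conditions: Sequence[str] = CONDITIONS,
                    n_trials: int = 10, *,
                    peak_velocity: float = DEFAULT_ACTIVE_PEAK_DPS,
                    duration_ms: float = DEFAULT_DURATION_MS,
                    amplitude_jitter: float = 0.1,
                    onset_jitter_ms: float = 20.0,
                    seed=None) -> dict:
    """Trial kinematics for every (condition, direction) pair.

    Head-on-body conditions (passive playback, active, attempted) use matched
    active-like transient profiles so responses are directly comparable;
    whole-body and body-under-head rotations use the machine-driven 1 Hz,
    40 deg/s sinusoid (one cycle per trial; the "contra" block starts on the
    contraversive half-cycle).  Returns {(condition, direction): ...}.
    """
    rng = np.random.default_rng(seed)
    suite = {}
    for condition in conditions:
        for direction in DIRECTIONS:
            if condition in ("whole_body", "body_under_head"):
                base = make_sinusoid_profile(n_cycles=1, n_trials=n_trials)
                sgn = DIRECTION_SIGN[direction]
                kins = []
                for p in base:
                    kins.append(assign_condition_kinematics(KinematicTrace(
                        t=p.t, head_pos=sgn * p.head_pos,
                        head_vel=sgn * p.head_vel, head_acc=sgn * p.head_acc,
                        body_pos=p.body_pos, body_vel=p.body_vel,
                        body_acc=p.body_acc,
                        passive_head_vel=sgn * p.passive_head_vel,
                        active_head_vel=p.active_head_vel), condition))
                suite[(condition, direction)] = {"trials": kins,
                                                 "intended": kins[0]}
                continue
            profiles = make_motion_profile(
                peak_velocity, duration_ms, n_trials, direction=direction,
                amplitude_jitter=amplitude_jitter,
                onset_jitter_ms=onset_jitter_ms,
                seed=rng.integers(2 ** 31))
            if condition == "attempted":
                kins = [assign_condition_kinematics(p, "attempted")
                        for p in profiles]
                intended = assign_condition_kinematics(
                    make_motion_profile(peak_velocity, duration_ms, 1,
                                        direction=direction,
                                        amplitude_jitter=0.0,
                                        onset_jitter_ms=0.0, seed=0)[0],
                    "head_on_body_active")
            else:
                kins = [assign_condition_kinematics(p, condition)
                        for p in profiles]
                intended = assign_condition_kinematics(
                    make_motion_profile(peak_velocity, duration_ms, 1,
                                        direction=direction,
                                        amplitude_jitter=0.0,
                                        onset_jitter_ms=0.0, seed=0)[0],
                    condition)
            suite[(condition, direction)] = {"trials": kins,
                                             "intended": intended}
    return suite


def population_average_rates(neurons: Sequence[NeuronGroundTruth],
                             suite: Mapping, *,
                             n_trials: int = 100,
                             noise_model: NoiseModel = NoiseModel(),
                             downsample: int = 10,
                             n_replicates: int = 2,
                             noise_mode: str = "auto",
                             seed=None) -> list[dict]:
    """Trial-averaged (and optionally downsampled) rates for a population.

    For every neuron and every (condition, direction) in ``suite``, averages
    ``n_trials`` noisy rectified trials per replicate.  Output: one dict per
    replicate mapping neuron_id -> {(cond, dir): rate}.  Downsampling keeps
    every ``downsample``-th 1 kHz sample.

    ``noise_mode`` ``per_trial`` draws every trial's noise explicitly;
    ``averaged`` draws the trial-mean noise directly at sd/sqrt(n_trials)
    (identical in distribution up to per-trial rectification, which is
    negligible at the default operating point); ``auto`` switches to the
    averaged shortcut above 20 trials.  The deterministic response is always
    averaged over the (jittered) kinematic exemplars in the suite.
    """
    if noise_mode not in ("auto", "per_trial", "averaged"):
        raise ValueError(f"unknown noise_mode {noise_mode!r}")
    if noise_mode == "auto":
        noise_mode = "averaged" if n_trials > 20 else "per_trial"
    rng = np.random.default_rng(seed)
    out = [dict() for _ in range(n_replicates)]
    # precompute deterministic rates once per neuron; only noise differs
    for neuron in neurons:
        det_by_key = {}
        for key, entry in suite.items():
            condition = key[0]
            kins = entry["trials"]
            det = np.stack([
                _noise_free_rate(neuron, kin, condition, entry["intended"])
                for kin in kins])
            det_by_key[key] = det
        for r in range(n_replicates):
            rates = {}
            for key, det in det_by_key.items():
                if noise_model.kind != "gaussian":
                    rates[key] = np.maximum(0.0, det).mean(axis=0)[::downsample]
                elif noise_mode == "averaged":
                    mean_det = det.mean(axis=0)
                    noise = correlated_noise(
                        rng, mean_det.shape,
                        noise_model.sd / math.sqrt(n_trials),
                        noise_model.corr_ms)
                    rates[key] = np.maximum(0.0, mean_det + noise)[::downsample]
                else:
                    reps = int(np.ceil(n_trials / det.shape[0]))
                    full = np.tile(det, (reps, 1))[:n_trials]
                    noisy = np.maximum(0.0, full + correlated_noise(
                        rng, full.shape, noise_model.sd, noise_model.corr_ms))
                    rates[key] = noisy.mean(axis=0)[::downsample]
            out[r][neuron.neuron_id] = rates
    return out
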