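"""Sign-constrained kinematic regression of firing rates.

A neuron's rate is modeled as a bias plus position, velocity and acceleration
terms of one or more kinematic channels,

    fr(t) = b + sum_i  c_p,i X_i(t) + c_v,i dX_i(t) + c_a,i d2X_i(t),

with all retained coefficients of a channel sharing one sign.  The fit
enumerates the all-non-negative and all-non-positive hypotheses per channel
and keeps the combination with the lowest residual sum of squares (bias
unconstrained).  A nonparametric bootstrap over trials supplies percentile
95% confidence intervals; coefficients whose interval spans zero are pruned
to exactly zero and the model refit.  Fitted coefficient triples are
converted to a signed sensitivity and phase at the movement frequency, and
direction-resolved sensitivities are classified into linear / rectifying /
V-shaped tuning and type I/II.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import lsq_linear

from .synth import DT_MS, KinematicTrace

TERMS = ("pos", "vel", "acc")


# ---------------------------------------------------------------------------
# regressors
# ---------------------------------------------------------------------------

def channel_regressors(kin: KinematicTrace, channel: str) -> np.ndarray:
    """(n_samples, 3) array of position/velocity/acceleration for a channel.

    ``passive_head`` / ``active_head`` positions and accelerations are
    reconstructed from the stored velocity decomposition.
    """
    if channel == "head":
        cols = (kin.head_pos, kin.head_vel, kin.head_acc)
    elif channel == "body":
        cols = (kin.body_pos, kin.body_vel, kin.body_acc)
    elif channel == "neck":
        cols = (kin.neck_pos, kin.neck_vel, kin.neck_acc)
    elif channel in ("passive_head", "active_head"):
        vel = kin.passive_head_vel if channel == "passive_head" else kin.active_head_vel
        dt_s = DT_MS / 1000.0
        pos = np.cumsum(vel) * dt_s
        acc = np.gradient(vel, dt_s)
        cols = (pos, vel, acc)
    else:
        raise ValueError(f"unknown channel {channel!r}")
    return np.column_stack(cols)


@dataclass
class ChannelFit:
    c_p: float
    c_v: float
    c_a: float
    sign: int                    # +1 or -1 (chosen sign hypothesis)
    ci: dict = field(default_factory=dict)   # term -> (lo, hi)

    def coefficients(self) -> tuple[float, float, float]:
        return (self.c_p, self.c_v, self.c_a)


@dataclass
class RegressionFit:
    bias: float
    channels: dict[str, ChannelFit]
    vaf: float
    rss: float
    n_samples: int
    n_trials: int
    retained_terms: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def channel(self, name: str) -> ChannelFit:
        return self.channels[name]


def _design(trial_rates: Sequence[np.ndarray],
            trial_kins: Sequence[KinematicTrace],
            channels: Sequence[str],
            window_ms: tuple[float, float] | None,
            terms_by_channel: Mapping[str, Sequence[str]] | None = None):
    """Stack trials into a design matrix and response vector."""
    blocks, ys = [], []
    for rate, kin in zip(trial_rates, trial_kins):
        mask = np.ones(kin.t.size, bool)
        if window_ms is not None:
            mask = (kin.t >= window_ms[0]) & (kin.t <= window_ms[1])
        cols = [np.ones(mask.sum())]
        for ch in channels:
            reg = channel_regressors(kin, ch)[mask]
            keep = [TERMS.index(term) for term in
                    (terms_by_channel or {}).get(ch, TERMS)]
            cols.append(reg[:, keep])
        blocks.append(np.column_stack(cols))
        ys.append(np.asarray(rate, float)[mask])
    return np.vstack(blocks), np.concatenate(ys)


def _solve_sign_constrained(X: np.ndarray, y: np.ndarray,
                            n_terms: Sequence[int]):
    """Best sign-consistent bounded least squares over channel-sign combos.

    ``n_terms[j]`` is the number of columns belonging to channel j (column 0
    of X is the unconstrained bias).  Returns (coef, signs, rss).
    """
    best = None
    for signs in itertools.product((1, -1), repeat=len(n_terms)):
        lb, ub = [-np.inf], [np.inf]
        for s, k in zip(signs, n_terms):
            lb += [0.0 if s > 0 else -np.inf] * k
            ub += [np.inf if s > 0 else 0.0] * k
        res = lsq_linear(X, y, bounds=(np.array(lb), np.array(ub)),
                         method="bvls")
        rss = float(np.sum(res.fun ** 2))
        if best is None or rss < best[2] - 1e-12:
            best = (res.x, signs, rss)
    return best


def fit_kinematic(trial_rates: Sequence[np.ndarray],
                  trial_kins: Sequence[KinematicTrace], *,
                  channels: Sequence[str] = ("head",),
                  window_ms: tuple[float, float] | None = None,
                  terms_by_channel: Mapping[str, Sequence[str]] | None = None,
                  min_trials: int = 1) -> RegressionFit:
    """Sign-constrained least-squares fit of rate on kinematics.

    For every channel the all-non-negative and all-non-positive coefficient
    hypotheses are solved (bounded least squares) and the lowest-residual
    sign combination kept; the bias is unconstrained.  VAF is 1 minus the
    ratio of residual to total variance.
    """
    if len(trial_rates) != len(trial_kins):
        raise ValueError("one kinematic trace per rate trial required")
    if len(trial_rates) < min_trials:
        raise ValueError(f"at least {min_trials} trials required")
    X, y = _design(trial_rates, trial_kins, channels, window_ms, terms_by_channel)
    col_norm = np.linalg.norm(X[:, 1:], axis=0)
    if np.any(col_norm < 1e-10):
        raise ValueError(
            "rank-deficient design: a kinematic channel carries no motion "
            "(zero-motion condition fed with motion channels?)")
    n_terms = [len((terms_by_channel or {}).get(ch, TERMS)) for ch in channels]
    coef, signs, rss = _solve_sign_constrained(X, y, n_terms)
    vaf = 1.0 - rss / float(np.sum((y - y.mean()) ** 2))
    fits, retained = {}, {}
    pos = 1
    for ch, s, k in zip(channels, signs, n_terms):
        terms = tuple((terms_by_channel or {}).get(ch, TERMS))
        vals = dict.fromkeys(TERMS, 0.0)
        for term, c in zip(terms, coef[pos:pos + k]):
            vals[term] = float(c)
        fits[ch] = ChannelFit(vals["pos"], vals["vel"], vals["acc"], sign=s)
        retained[ch] = terms
        pos += k
    return RegressionFit(bias=float(coef[0]), channels=fits, vaf=float(vaf),
                         rss=rss, n_samples=y.size, n_trials=len(trial_rates),
                         retained_terms=retained)


def bootstrap_prune(trial_rates: Sequence[np.ndarray],
                    trial_kins: Sequence[KinematicTrace], *,
                    channels: Sequence[str] = ("head",),
                    window_ms: tuple[float, float] | None = None,
                    terms_by_channel: Mapping[str, Sequence[str]] | None = None,
                    n_boot: int = 2000, alpha: float = 0.05,
                    zero_tol: float = 1e-9,
                    seed=None) -> RegressionFit:
    """Bootstrap 95% CIs per coefficient; prune those whose CI spans zero.

    Whole trials are resampled with replacement (respecting within-trial
    autocorrelation), the model refit per resample and percentile intervals
    taken.  Non-significant coefficients are set to exactly zero and the
    model refit with the surviving terms.  ``zero_tol`` absorbs the bounded
    solver's epsilon-positive zeros when testing whether an interval excludes
    zero.
    """
    if len(trial_rates) < 5:
        raise ValueError("bootstrap pruning requires at least 5 trials")
    rng = np.random.default_rng(seed)
    base = fit_kinematic(trial_rates, trial_kins, channels=channels,
                         window_ms=window_ms, terms_by_channel=terms_by_channel)
    n = len(trial_rates)
    draws = {ch: {term: np.empty(n_boot) for term in TERMS} for ch in channels}
    for b in range(int(n_boot)):
        idx = rng.integers(0, n, size=n)
        fit_b = fit_kinematic([trial_rates[i] for i in idx],
                              [trial_kins[i] for i in idx],
                              channels=channels, window_ms=window_ms,
                              terms_by_channel=terms_by_channel)
        for ch in channels:
            cf = fit_b.channel(ch)
            for term, val in zip(TERMS, cf.coefficients()):
                draws[ch][term][b] = val
    lo_q, hi_q = 100 * alpha / 2, 100 * (1 - alpha / 2)
    fit_terms = {ch: tuple((terms_by_channel or {}).get(ch, TERMS))
                 for ch in channels}
    surviving: dict[str, list[str]] = {}
    cis: dict[str, dict[str, tuple[float, float]]] = {}
    for ch in channels:
        cis[ch] = {}
        keep = []
        for term in fit_terms[ch]:
            lo = float(np.percentile(draws[ch][term], lo_q))
            hi = float(np.percentile(draws[ch][term], hi_q))
            cis[ch][term] = (lo, hi)
            if lo > zero_tol or hi < -zero_tol:
                keep.append(term)
        surviving[ch] = keep
    kept_channels = [ch for ch in channels if surviving[ch]]
    if kept_channels:
        pruned = fit_kinematic(trial_rates, trial_kins, channels=kept_channels,
                               window_ms=window_ms,
                               terms_by_channel={ch: surviving[ch]
                                                 for ch in kept_channels})
    else:
        y = np.concatenate([np.asarray(r, float) for r in trial_rates])
        pruned = RegressionFit(bias=float(y.mean()), channels={}, vaf=0.0,
                               rss=float(np.sum((y - y.mean()) ** 2)),
                               n_samples=y.size, n_trials=n)
    for ch in channels:
        if ch not in pruned.channels:
            pruned.channels[ch] = ChannelFit(0.0, 0.0, 0.0,
                                             sign=base.channel(ch).sign)
        pruned.channels[ch].ci = cis[ch]
        pruned.retained_terms[ch] = tuple(surviving[ch])
    return pruned


# ---------------------------------------------------------------------------
# gain/phase vectorization
# ---------------------------------------------------------------------------

@dataclass
class ResponseVector:
    """Signed sensitivity ((sp/s)/(deg/s)) and phase (deg) at frequency f."""

    sensitivity: float
    phase_deg: float
    f_hz: float = 1.0
    degenerate: bool = False

    def as_complex(self) -> complex:
        return self.sensitivity * np.exp(1j * math.radians(self.phase_deg))


def response_vector(fit_or_coeffs, channel: str = "head",
                    f_hz: float = 1.0) -> ResponseVector:
    """Convert a coefficient triple to signed sensitivity and phase.

    sensitivity = sgn * sqrt(((2 pi f)^2 c_a - c_p)^2 + (2 pi f c_v)^2) / (2 pi f)
    phase       = atan(((2 pi f)^2 c_a - c_p) / (2 pi f c_v))

    where sgn is +-1 per the channel's shared coefficient sign.  A pure
    zero-velocity-coefficient response maps to a +-90 deg phase limit.
    """
    if isinstance(fit_or_coeffs, RegressionFit):
        cf = fit_or_coeffs.channel(channel)
        c_p, c_v, c_a = cf.coefficients()
        sgn = float(cf.sign)
    else:
        c_p, c_v, c_a = fit_or_coeffs
        nonzero = [c for c in (c_p, c_v, c_a) if c != 0]
        sgn = 1.0 if (not nonzero or nonzero[0] > 0) else -1.0
    w = 2.0 * np.pi * f_hz
    num = w ** 2 * c_a - c_p
    mag = math.sqrt(num ** 2 + (w * c_v) ** 2) / w
    if c_v == 0.0:
        if num == 0.0:
            return ResponseVector(0.0, 0.0, f_hz, degenerate=True)
        phase = 90.0 if (num / sgn) > 0 else -90.0
    else:
        phase = math.degrees(math.atan(num / (w * c_v)))
    return ResponseVector(sgn * mag, phase, f_hz)


# ---------------------------------------------------------------------------
# tuning classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TuningClass:
    shape: str          # linear | rectifying | V_shaped | other
    type_label: str     # I | II
    preferred: str      # ipsi | contra


def classify_tuning(sens_ipsi: float, sens_contra: float,
                    threshold: float = 0.2) -> TuningClass:
    """Classify direction-resolved velocity sensitivities.

    Inputs are the signed sensitivities fitted separately on ipsiversive
    (positive-velocity) and contraversive samples.  A positive ``sens_ipsi``
    means the rate increases for ipsilateral rotation; a negative
    ``sens_contra`` means it increases for contralateral rotation.

    linear      increase in the preferred direction, decrease in the other,
                magnitudes within ``threshold``
    rectifying  increase in the preferred direction, sub-threshold modulation
                in the other
    V_shaped    increase in both directions, magnitudes within ``threshold``
    """
    inc_ipsi, inc_contra = sens_ipsi > 0, sens_contra < 0
    m_ipsi, m_contra = abs(sens_ipsi), abs(sens_contra)
    if inc_ipsi and inc_contra:
        preferred = "ipsi" if m_ipsi >= m_contra else "contra"
    elif inc_ipsi:
        preferred = "ipsi"
    elif inc_contra:
        preferred = "contra"
    else:
        return TuningClass("other", "I" if m_ipsi >= m_contra else "II",
                           "ipsi" if m_ipsi >= m_contra else "contra")
    m_pref = m_ipsi if preferred == "ipsi" else m_contra
    m_np = m_contra if preferred == "ipsi" else m_ipsi
    both_increase = inc_ipsi and inc_contra
    if m_np < threshold and not (both_increase and abs(m_pref - m_np) <= threshold):
        shape = "rectifying"
    elif both_increase and abs(m_pref - m_np) <= threshold:
        shape = "V_shaped"
    elif not both_increase and abs(m_pref - m_np) <= threshold:
        shape = "linear"
    else:
        shape = "other"
    return TuningClass(shape, "I" if preferred == "ipsi" else "II", preferred)


# ---------------------------------------------------------------------------
# combined-condition reafference / exafference ratios
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CombinedRatios:
    exafference_ratio: float
    reafference_ratio: float
    defined: bool = True


def combined_ratios(combined_fit: RegressionFit,
                    passive_alone_sensitivity: float,
                    f_hz: float = 1.0) -> CombinedRatios:
    """Exafference and reafference encoding ratios in the combined condition.

    The combined-condition fit must use separate ``passive_head`` and
    ``active_head`` channels; each component's sensitivity is normalized by
    the sensitivity to passive rotation alone.
    """
    for ch in ("passive_head", "active_head"):
        if ch not in combined_fit.channels:
            raise ValueError("combined fit must separate passive/active channels")
    if passive_alone_sensitivity == 0 or not np.isfinite(passive_alone_sensitivity):
        return CombinedRatios(float("nan"), float("nan"), defined=False)
    s_pass = response_vector(combined_fit, "passive_head", f_hz).sensitivity
    s_act = response_vector(combined_fit, "active_head", f_hz).sensitivity
    denom = abs(passive_alone_sensitivity)
    return CombinedRatios(abs(s_pass) / denom, abs(s_act) / denom)
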