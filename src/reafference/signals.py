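"""Firing-rate estimation and response-timing statistics.

Spike trains are converted to rates by convolution with a unit-area Kaiser
window whose cutoff is twice the stimulus frequency.  Response onsets are
estimated from 4-parameter logistic fits (onset = 5%-of-range crossing), a
sliding-window correlation locates when a predicted response starts matching
the observed one, and a within-trial permutation test detects torque-locked
firing-rate changes during attempted movements, with Benjamini-Hochberg
control across neurons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal.windows import kaiser
from statsmodels.stats.multitest import multipletests

from .synth import DT_MS, TrialSet

FS_HZ = 1000.0


@dataclass
class RateTrace:
    t: np.ndarray              # ms, 1 kHz
    rate: np.ndarray           # sp/s, >= 0
    trial_id: int = 0
    alignment_event: str = "movement_onset"

    def __post_init__(self):
        if self.rate.size != self.t.size:
            raise ValueError("rate length must match time base")


@dataclass
class OnsetEstimate:
    """Sigmoid-fit onset: the time the fit reaches 5% of its range."""

    onset_ms: float | None
    floor: float = float("nan")
    range_: float = float("nan")
    midpoint_ms: float = float("nan")
    tau_ms: float = float("nan")
    residual: float = float("nan")

    @property
    def found(self) -> bool:
        return self.onset_ms is not None


# ---------------------------------------------------------------------------
# spike-train smoothing
# ---------------------------------------------------------------------------

def _kaiser_minus6db_hz(n: int, beta: float, fs: float) -> float:
    """-6 dB (half-amplitude) cutoff of a unit-area Kaiser kernel of length n."""
    win = kaiser(n, beta)
    win = win / win.sum()
    nfft = max(4096, 4 * n)
    h = np.abs(np.fft.rfft(win, nfft))
    f = np.fft.rfftfreq(nfft, d=1.0 / fs)
    idx = np.argmax(h < 0.5)
    if idx == 0:
        return f[-1]
    # linear interpolation around the crossing
    f0, f1, h0, h1 = f[idx - 1], f[idx], h[idx - 1], h[idx]
    return float(f0 + (h0 - 0.5) / (h0 - h1) * (f1 - f0))


def kaiser_kernel(cutoff_hz: float, fs: float = FS_HZ, beta: float = 6.0) -> np.ndarray:
    """Unit-area Kaiser smoothing kernel with a given -6 dB cutoff.

    The window length is solved numerically (bisection over odd lengths) so
    that the kernel's half-amplitude point lands on ``cutoff_hz``.
    """
    if cutoff_hz <= 0:
        raise ValueError("cutoff_hz must be positive")
    lo, hi = 3, 8191                       # odd lengths; longer = lower cutoff
    if _kaiser_minus6db_hz(hi, beta, fs) > cutoff_hz:
        n = hi
    else:
        while hi - lo > 2:
            mid = (lo + hi) // 2
            mid += (mid + 1) % 2           # keep odd
            if _kaiser_minus6db_hz(mid, beta, fs) > cutoff_hz:
                lo = mid
            else:
                hi = mid
        n = hi
    win = kaiser(n, beta)
    return win / win.sum()


def spikes_to_rate(spike_times_ms: np.ndarray, stimulus_freq_hz: float,
                   duration_ms: float, *, beta: float = 6.0,
                   trial_id: int = 0) -> RateTrace:
    """Estimate a firing rate by Kaiser-window smoothing of a spike train.

    The kernel cutoff is twice the stimulus frequency; the kernel has unit
    area so the rate integral preserves the spike count (away from edges).
    """
    spike_times_ms = np.asarray(spike_times_ms, dtype=float)
    if spike_times_ms.size and (spike_times_ms.min() < 0
                                or spike_times_ms.max() > duration_ms):
        raise ValueError("spike times must lie within [0, duration_ms]")
    t = np.arange(0.0, duration_ms, DT_MS)
    delta = np.zeros_like(t)
    if spike_times_ms.size:
        idx = np.clip((spike_times_ms / DT_MS).astype(int), 0, t.size - 1)
        np.add.at(delta, idx, 1.0)
    kernel = kaiser_kernel(2.0 * stimulus_freq_hz, FS_HZ, beta)
    rate = np.convolve(delta, kernel, mode="same") * FS_HZ  # spikes/bin -> sp/s
    return RateTrace(t=t, rate=rate, trial_id=trial_id)


# ---------------------------------------------------------------------------
# sigmoid onset
# ---------------------------------------------------------------------------

def _logistic(t, floor, rng, t0, tau):
    return floor + rng / (1.0 + np.exp(-(t - t0) / tau))


def sigmoid_onset(t_ms: np.ndarray, y: np.ndarray, *,
                  min_range: float | None = None) -> OnsetEstimate:
    """Fit a 4-parameter logistic and report the 5%-of-range crossing.

    Handles rising or falling transients (the range may be negative).  A
    trace whose excursion stays below ``min_range`` (default: 4 x the early
    -baseline noise SD) yields a "no onset" estimate rather than an error.
    """
    t_ms = np.asarray(t_ms, float)
    y = np.asarray(y, float)
    n_base = max(10, y.size // 10)
    noise_sd = float(np.std(y[:n_base]))
    span = float(y.max() - y.min())
    threshold = 4.0 * noise_sd if min_range is None else min_range
    if span <= max(threshold, 1e-12):
        return OnsetEstimate(onset_ms=None, floor=float(np.mean(y)), range_=0.0)

    # initialize from the 10-90% rise interval of a lightly smoothed trace
    win = max(3, y.size // 50)
    smooth = np.convolve(y, np.ones(win) / win, mode="same")
    rising = abs(smooth[-n_base:].mean() - smooth[:n_base].mean())
    sign = 1.0 if smooth[-n_base:].mean() >= smooth[:n_base].mean() else -1.0
    lo_level = smooth.min() + 0.1 * (smooth.max() - smooth.min())
    hi_level = smooth.min() + 0.9 * (smooth.max() - smooth.min())
    inside = np.where((smooth >= lo_level) & (smooth <= hi_level))[0]
    if inside.size >= 2:
        t10, t90 = t_ms[inside[0]], t_ms[inside[-1]]
    else:
        t10, t90 = t_ms[0], t_ms[-1]
    tau0 = max((t90 - t10) / 4.0, 1.0)
    p0 = [float(smooth[:n_base].mean()), sign * max(rising, span / 2), (t10 + t90) / 2.0, tau0]
    try:
        popt, _ = curve_fit(
            _logistic, t_ms, y, p0=p0,
            bounds=([-np.inf, -np.inf, t_ms[0], 1e-3],
                    [np.inf, np.inf, t_ms[-1], t_ms[-1] - t_ms[0]]),
            maxfev=5000)
    except RuntimeError:
        return OnsetEstimate(onset_ms=None)
    floor, rng_, t0, tau = (float(v) for v in popt)
    resid = float(np.sqrt(np.mean((_logistic(t_ms, *popt) - y) ** 2)))
    if abs(rng_) <= threshold:
        # fitted excursion is indistinguishable from the noise floor
        return OnsetEstimate(onset_ms=None, floor=floor, range_=rng_,
                             midpoint_ms=t0, tau_ms=tau, residual=resid)
    onset = t0 - tau * math.log(19.0)      # logistic crosses 5% of range here
    return OnsetEstimate(onset_ms=float(onset), floor=floor, range_=rng_,
                         midpoint_ms=t0, tau_ms=tau, residual=resid)


# ---------------------------------------------------------------------------
# sliding correlation
# ---------------------------------------------------------------------------

@dataclass
class SlidingCorrelation:
    t_ms: np.ndarray
    r: np.ndarray                  # Pearson r per window (NaN where undefined)
    threshold: float
    onset_ms: float | None


def sliding_correlation(t_ms: np.ndarray, observed: np.ndarray,
                        predicted: np.ndarray, *, window_ms: float = 40.0,
                        step_ms: float = 1.0,
                        baseline_ms: tuple[float, float] = (-300.0, -100.0),
                        sustain_ms: float = 10.0) -> SlidingCorrelation:
    """Windowed Pearson correlation between observed and predicted rates.

    Windows of ``window_ms`` are stepped by ``step_ms``; each window is
    causal (it ends at the reported time), so a significance onset can never
    be driven by samples that have not occurred yet.  The significance
    threshold is the upper bound of the 95% interval of baseline-epoch
    correlations; the significance onset is the first post-baseline time the
    series exceeds it for at least ``sustain_ms``.  Zero-variance windows
    yield NaN and are excluded.
    """
    t_ms = np.asarray(t_ms, float)
    observed = np.asarray(observed, float)
    predicted = np.asarray(predicted, float)
    if observed.shape != predicted.shape or observed.shape != t_ms.shape:
        raise ValueError("traces must share one time base")
    if t_ms[0] > baseline_ms[0]:
        raise ValueError("trace must cover the baseline epoch")
    width = int(round(window_ms / DT_MS))
    step = max(1, int(round(step_ms / DT_MS)))
    ends = np.arange(width, t_ms.size, step)
    r = np.full(ends.size, np.nan)
    for j, c in enumerate(ends):
        a = observed[c - width:c + 1]
        b = predicted[c - width:c + 1]
        sa, sb = a.std(), b.std()
        if sa > 0 and sb > 0:
            r[j] = float(np.corrcoef(a, b)[0, 1])
    tc = t_ms[ends]
    base = r[(tc >= baseline_ms[0]) & (tc <= baseline_ms[1]) & np.isfinite(r)]
    # upper bound of the 95% interval of baseline correlations.  The
    # mean + 1.96 sd form is more stable than an empirical percentile over
    # heavily overlapping windows, and the analytic Pearson null bound for a
    # window of this length floors the threshold when the short baseline
    # under-estimates its own variability.
    analytic = math.tanh(1.96 / math.sqrt(max(width - 2, 1)))
    if base.size:
        threshold = float(max(base.mean() + 1.96 * base.std(), analytic))
    else:
        threshold = float("nan")
    onset = None
    sustain = max(1, int(round(sustain_ms / step_ms)))
    after = np.where(tc > baseline_ms[1])[0]
    above = np.isfinite(r) & (r > threshold)
    run = 0
    for j in after:
        run = run + 1 if above[j] else 0
        if run >= sustain:
            onset = float(tc[j - sustain + 1])
            break
    return SlidingCorrelation(t_ms=tc, r=r, threshold=threshold, onset_ms=onset)


# ---------------------------------------------------------------------------
# motor-response permutation test
# ---------------------------------------------------------------------------

@dataclass
class MotorResponseResult:
    neuron_id: str | None
    statistic: float               # mean over trials of mean(post) - mean(pre)
    p_value: float
    testable: bool
    significant: bool | None = None    # set by the population BH adjustment


def motor_response_test(trials: TrialSet, *,
                        pre_ms: tuple[float, float] = (-300.0, -100.0),
                        post_ms: tuple[float, float] = (0.0, 100.0),
                        n_perm: int = 2000, min_trials: int = 5,
                        seed=None) -> MotorResponseResult:
    """Two-sided permutation test for torque-locked rate changes.

    Per trial the statistic is mean(post-epoch rate) - mean(pre-epoch rate);
    the neuron-level statistic is its trial average.  The null permutes the
    pre/post labels within each trial (equivalently flips each trial's sign).
    """
    if len(trials.trials) < min_trials:
        return MotorResponseResult(trials.neuron_id, float("nan"), float("nan"),
                                   testable=False)
    rng = np.random.default_rng(seed)
    t = trials.t()
    pre = (t >= pre_ms[0]) & (t <= pre_ms[1])
    post = (t >= post_ms[0]) & (t <= post_ms[1])
    d = np.array([tr.rate[post].mean() - tr.rate[pre].mean()
                  for tr in trials.trials])
    obs = float(d.mean())
    signs = rng.choice([-1.0, 1.0], size=(int(n_perm), d.size))
    null = (signs * d).mean(axis=1)
    p = float((1 + np.sum(np.abs(null) >= abs(obs))) / (n_perm + 1))
    return MotorResponseResult(trials.neuron_id, obs, p, testable=True)


def adjust_motor_responses(results: list[MotorResponseResult],
                           alpha: float = 0.05) -> list[MotorResponseResult]:
    """Benjamini-Hochberg adjustment across a population of neurons."""
    testable = [r for r in results if r.testable]
    if testable:
        rej, _, _, _ = multipletests([r.p_value for r in testable],
                                     alpha=alpha, method="fdr_bh")
        for r, flag in zip(testable, rej):
            r.significant = bool(flag)
    return results
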