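"""Linear-summation test: does passive + attempted predict the active response?

Each neuron's responses in the passive head-on-body, attempted-movement and
active head-on-body conditions are vectorized as (gain, phase) pairs at the
movement frequency.  The complex sum of the passive and attempted vectors is
the model's prediction for the active vector; across the population the
observed active gains and phases are regressed on the predicted ones.
"""

from __future__ import annotations

import cmath
import math
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .kinfit import ResponseVector


def vector_sum(a: ResponseVector, b: ResponseVector) -> ResponseVector:
    """Complex sum of two response vectors at the same frequency.

    The result is re-expressed in the signed-sensitivity convention (phase in
    (-90, 90], negative sensitivity for anti-phase responses).  Exact
    cancellation yields a zero-gain vector with phase 0 and a degenerate flag.
    """
    if a.f_hz != b.f_hz:
        raise ValueError("response vectors must share the stimulus frequency")
    z = a.as_complex() + b.as_complex()
    mag = abs(z)
    if mag < 1e-12:
        return ResponseVector(0.0, 0.0, a.f_hz, degenerate=True)
    phase = math.degrees(cmath.phase(z))
    sign = 1.0
    if phase > 90.0:
        phase, sign = phase - 180.0, -1.0
    elif phase <= -90.0:
        phase, sign = phase + 180.0, -1.0
    return ResponseVector(sign * mag, phase, a.f_hz)


@dataclass
class PredictionRecord:
    """Per-neuron vectors for the linear-summation prediction."""

    neuron_id: str
    passive: ResponseVector
    attempted: ResponseVector
    observed_active: ResponseVector
    predicted_active: ResponseVector = None  # filled from passive + attempted

    def __post_init__(self):
        if self.predicted_active is None:
            self.predicted_active = vector_sum(self.passive, self.attempted)

    @property
    def gain_error(self) -> float:
        return self.observed_active.sensitivity - self.predicted_active.sensitivity

    @property
    def phase_error(self) -> float:
        return self.observed_active.phase_deg - self.predicted_active.phase_deg


@dataclass
class PredictionSummary:
    gain_r2: float
    gain_slope: float
    gain_slope_ci: tuple[float, float]
    phase_r2: float
    phase_slope: float
    phase_slope_ci: tuple[float, float]
    sign_agreement: float
    n: int
    degenerate: bool = False


def _regress(observed: np.ndarray, predicted: np.ndarray):
    model = sm.OLS(observed, sm.add_constant(predicted)).fit()
    ci = model.conf_int()
    return float(model.rsquared), float(model.params[1]), \
        (float(ci[1, 0]), float(ci[1, 1]))


def evaluate_population_prediction(records: list[PredictionRecord],
                                   min_records: int = 10) -> PredictionSummary:
    """Population-level quality of the linear-summation prediction.

    Observed active gains (signed) and phases are regressed on their
    predictions; reports R-squared, the slope with its 95% CI (unity slope =
    perfect calibration), and the fraction of neurons whose observed and
    predicted gains agree in sign.
    """
    if len(records) < min_records:
        raise ValueError(f"need at least {min_records} prediction records")
    obs_g = np.array([r.observed_active.sensitivity for r in records])
    pred_g = np.array([r.predicted_active.sensitivity for r in records])
    obs_p = np.array([r.observed_active.phase_deg for r in records])
    pred_p = np.array([r.predicted_active.phase_deg for r in records])
    agree = float(np.mean(np.sign(obs_g) == np.sign(pred_g)))
    nan_stats = (float("nan"), float("nan"), (float("nan"), float("nan")))
    # each axis degenerates independently (e.g. velocity-only vectors carry
    # no phase variation): report what the data supports
    g_stats = (_regress(obs_g, pred_g) if pred_g.std() > 1e-12 else nan_stats)
    p_stats = (_regress(obs_p, pred_p) if pred_p.std() > 1e-12 else nan_stats)
    degenerate = pred_g.std() < 1e-12 or pred_p.std() < 1e-12
    return PredictionSummary(g_stats[0], g_stats[1], g_stats[2],
                             p_stats[0], p_stats[1], p_stats[2],
                             agree, len(records), degenerate=degenerate)
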