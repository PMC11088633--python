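"""Population readout: can inhibitory Purkinje-cell convergence cancel reafference?

Two linear readouts with non-positive weights (inhibitory Purkinje -> target
synapses) are fit on trial-averaged rates stacked over both movement
directions and all included conditions:

* cancellation model - the target is the *negative* of the vestibular
  afferent reafference during active movement and zero during passive
  conditions; hypothesis sweeps ask how many cells of a given composition
  (single cells, same-sign-only, or half same / half sign-flipped) are needed
  to reach a >= 70% suppression criterion;
* target-neuron model - the target is the reference deep-cerebellar neuron's
  firing rate; the goodness of fit is tracked as a function of population
  size N with bootstrap confidence intervals.

Both fits share one weight vector across all conditions.  An optional mossy
-fiber input enters as one additional non-negative column.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import nnls
from scipy.stats import kruskal

from .synth import (DIRECTIONS, KinematicTrace, MossyFiberSim,
                    NeuronGroundTruth, PiecewiseChannel, sample_population)
from .kinfit import response_vector

DEFAULT_CONDITIONS = ("whole_body", "head_on_body_passive",
                      "head_on_body_active", "attempted")
#: cancellation-signal fits: the target is defined on passive and active
#: blocks only (the attempted condition belongs to the target-neuron model)
CANCELLATION_CONDITIONS = ("whole_body", "head_on_body_passive",
                           "head_on_body_active")
ACTIVE_CONDITION = "head_on_body_active"


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

@dataclass
class DesignMatrix:
    """Stacked trial-averaged rates: rows = time samples over conditions x
    directions, columns = Purkinje cells."""

    X: np.ndarray
    neuron_ids: list[str]
    row_condition: np.ndarray
    row_direction: np.ndarray
    row_t_ms: np.ndarray

    def rows(self, condition: str) -> np.ndarray:
        return self.row_condition == condition

    def select(self, neuron_ids: Sequence[str]) -> "DesignMatrix":
        idx = [self.neuron_ids.index(nid) for nid in neuron_ids]
        return DesignMatrix(self.X[:, idx], list(neuron_ids),
                            self.row_condition, self.row_direction,
                            self.row_t_ms)


def build_design(rates: Mapping[str, Mapping], *,
                 conditions: Sequence[str] = DEFAULT_CONDITIONS,
                 directions: Sequence[str] = DIRECTIONS,
                 t_ms: Mapping | None = None) -> DesignMatrix:
    """Stack per-neuron trial-averaged rates into the readout design.

    ``rates`` maps neuron_id -> {(condition, direction): rate array}; every
    neuron must cover every requested block (cells missing a condition belong
    in `augment_population`, not here).
    """
    neuron_ids = list(rates)
    if not neuron_ids:
        raise ValueError("empty design: no neurons supplied")
    first = rates[neuron_ids[0]]
    for nid in neuron_ids:
        for c in conditions:
            for d in directions:
                if (c, d) not in rates[nid]:
                    raise ValueError(f"neuron {nid} missing block {(c, d)}")
    cols, conds, dirs, ts = [], [], [], []
    for c in conditions:
        for d in directions:
            n = first[(c, d)].size
            conds.append(np.full(n, c))
            dirs.append(np.full(n, d))
            ts.append(np.asarray(t_ms[(c, d)]) if t_ms is not None
                      else np.arange(n, dtype=float))
    X = np.column_stack([
        np.concatenate([rates[nid][(c, d)] for c in conditions
                        for d in directions])
        for nid in neuron_ids])
    return DesignMatrix(X, neuron_ids, np.concatenate(conds),
                        np.concatenate(dirs), np.concatenate(ts))


def cancellation_target(design: DesignMatrix,
                        head_vel: Mapping, *,
                        afferent_gain: float = 1.0,
                        active_condition: str = ACTIVE_CONDITION) -> np.ndarray:
    """Cancellation-signal target: -(afferent reafference) during active
    movement, zero during all other conditions.

    ``head_vel`` maps (condition, direction) to the (downsampled) mean head
    velocity; the afferent encodes head velocity context-independently with
    gain ``afferent_gain``.
    """
    y = np.zeros(design.X.shape[0])
    row = 0
    for c, d in _block_order(design):
        n = int(np.sum((design.row_condition == c) & (design.row_direction == d)))
        if c == active_condition:
            v = np.asarray(head_vel[(c, d)], float)
            if v.size != n:
                raise ValueError("head_vel block length mismatch")
            y[row:row + n] = -afferent_gain * v
        row += n
    return y


def _block_order(design: DesignMatrix):
    seen, order = set(), []
    for c, d in zip(design.row_condition, design.row_direction):
        if (c, d) not in seen:
            seen.add((c, d))
            order.append((c, d))
    return order


def rfn_target(design: DesignMatrix, rfn_rates: Mapping) -> np.ndarray:
    """Stack the reference target-neuron's trial-averaged rates to match the
    design's row blocks."""
    return np.concatenate([np.asarray(rfn_rates[(c, d)], float)
                           for c, d in _block_order(design)])


# ---------------------------------------------------------------------------
# non-positive-weight least squares
# ---------------------------------------------------------------------------

@dataclass
class PopulationFit:
    weights: np.ndarray            # <= 0, one per Purkinje cell
    intercept: float
    mossy_weight: float | None
    r2: float
    n: int
    r2_ci: tuple[float, float] | None = None
    residual: np.ndarray | None = None
    neuron_ids: list[str] = field(default_factory=list)

    def predict(self, X: np.ndarray, mossy: np.ndarray | None = None) -> np.ndarray:
        out = X @ self.weights + self.intercept
        if self.mossy_weight is not None and mossy is not None:
            out = out + self.mossy_weight * mossy
        return out


def fit_nonpositive_weights(X: np.ndarray, y: np.ndarray, *,
                            mossy: np.ndarray | None = None,
                            intercept: bool = True,
                            n_boot: int = 0,
                            seed=None,
                            neuron_ids: Sequence[str] | None = None
                            ) -> PopulationFit:
    """Least squares with all Purkinje weights constrained non-positive.

    Solved as a non-negative least-squares problem on negated columns; an
    optional mossy-fiber column is constrained non-negative and the intercept
    (if requested) is unconstrained.  ``n_boot`` > 0 adds a percentile 95% CI
    on R-squared from resampling cells with replacement.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if X.ndim != 2 or X.shape[1] == 0:
        raise ValueError("empty design")
    blocks = [-X]
    if mossy is not None:
        blocks.append(np.asarray(mossy, float).reshape(-1, 1))
    if intercept:
        ones = np.ones((X.shape[0], 1))
        blocks.extend([ones, -ones])
    A = np.hstack(blocks)
    sol, _ = nnls(A, y, maxiter=10 * A.shape[1])
    k = X.shape[1]
    w = -sol[:k]
    pos = k
    mw = None
    if mossy is not None:
        mw = float(sol[pos])
        pos += 1
    b = float(sol[pos] - sol[pos + 1]) if intercept else 0.0
    pred = A @ sol
    resid = y - pred
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else float("nan")
    fit = PopulationFit(weights=w, intercept=b, mossy_weight=mw, r2=r2,
                        n=k, residual=resid,
                        neuron_ids=list(neuron_ids or []))
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        r2s = np.empty(n_boot)
        for i in range(n_boot):
            idx = rng.integers(0, k, size=k)
            sub = fit_nonpositive_weights(X[:, idx], y, mossy=mossy,
                                          intercept=intercept)
            r2s[i] = sub.r2
        fit.r2_ci = (float(np.percentile(r2s, 2.5)),
                     float(np.percentile(r2s, 97.5)))
    return fit


# ---------------------------------------------------------------------------
# hypothesis sweeps (cancellation model)
# ---------------------------------------------------------------------------

HYPOTHESES = ("H1A", "H1B", "H2", "H3")


@dataclass(frozen=True)
class HypothesisConfig:
    """Cell-composition rule for a cancellation-signal hypothesis.

    H1A - a single same-sign attenuated cell; H1B - a single sign-flipped
    cell; H2 - same-sign cells only; H3 - half same-sign, half flipped.
    """

    label: str

    def __post_init__(self):
        if self.label not in HYPOTHESES:
            raise ValueError(f"unknown hypothesis {self.label!r}")

    @property
    def single_cell(self) -> bool:
        return self.label in ("H1A", "H1B")

    def select(self, same_ids: Sequence[str], flipped_ids: Sequence[str],
               n: int, rng) -> list[str]:
        if self.label == "H1A":
            return list(rng.choice(same_ids, size=1, replace=False))
        if self.label == "H1B":
            return list(rng.choice(flipped_ids, size=1, replace=False))
        if self.label == "H2":
            if n > len(same_ids):
                raise ValueError("hypothesis selection yields too few cells")
            return list(rng.choice(same_ids, size=n, replace=False))
        n_same = n // 2 + n % 2
        n_flip = n // 2
        if n_same > len(same_ids) or n_flip > len(flipped_ids):
            raise ValueError("hypothesis selection yields too few cells")
        ids = list(rng.choice(same_ids, size=n_same, replace=False))
        ids += list(rng.choice(flipped_ids, size=n_flip, replace=False))
        return ids


def eligible_pools(neurons: Sequence[NeuronGroundTruth]):
    """Vestibular-responsive same-sign and flipped cell id pools."""
    same = [nr.neuron_id for nr in neurons
            if nr.active_sign == "same" and not nr.vest.is_zero()]
    flipped = [nr.neuron_id for nr in neurons
               if nr.active_sign == "flipped" and not nr.vest.is_zero()]
    return same, flipped


def residual_reafference_ratio(fit: PopulationFit,
                               design_eval: DesignMatrix,
                               target_eval: np.ndarray, *,
                               active_condition: str = ACTIVE_CONDITION,
                               epoch_fraction: float = 0.05) -> float:
    """RMS residual reafference relative to the afferent reafference.

    The fitted cancellation signal (evaluated on held-out data) is added to
    the afferent reafference; the ratio of the residual RMS to the afferent
    RMS measures how much reafference survives (<= 0.3 means >= 70%
    suppression).  The ratio is evaluated over the movement epoch - active
    -condition samples where the afferent signal exceeds ``epoch_fraction``
    of its peak - since reafference exists only while the head moves.
    """
    mask = design_eval.rows(active_condition)
    pred = fit.predict(design_eval.X)
    afferent = -target_eval[mask]            # target is -(afference)
    moving = np.abs(afferent) > epoch_fraction * np.max(np.abs(afferent))
    if not np.any(moving):
        return float("nan")
    residual = afferent[moving] + pred[mask][moving]
    denom = float(np.sqrt(np.mean(afferent[moving] ** 2)))
    return float(np.sqrt(np.mean(residual ** 2)) / denom)


@dataclass
class HypothesisSweep:
    hypothesis: str
    n_grid: list[int]
    median_ratio: list[float]
    n_min: int | None              # None = not achievable within the grid

    @property
    def achievable(self) -> bool:
        return self.n_min is not None


def required_population_size(neurons: Sequence[NeuronGroundTruth],
                             design_fit: DesignMatrix,
                             design_eval: DesignMatrix,
                             target_fit: np.ndarray,
                             target_eval: np.ndarray,
                             hypothesis: HypothesisConfig | str, *,
                             criterion_ratio: float = 0.3,
                             n_seeds: int = 20,
                             n_grid: Sequence[int] = (),
                             seed=None,
                             stop_at_first: bool = True) -> HypothesisSweep:
    """Smallest population size whose median residual reafference passes.

    For each N in the ascending grid, cells are drawn per the hypothesis
    composition rule (``n_seeds`` independent draws), the non-positive
    cancellation weights are fit on one replicate of trial-averaged rates and
    the residual reafference evaluated on an independent replicate; the
    criterion is the median ratio over draws.  Single-cell hypotheses are
    evaluated at N = 1 only.
    """
    if isinstance(hypothesis, str):
        hypothesis = HypothesisConfig(hypothesis)
    same, flipped = eligible_pools(neurons)
    if not same or not flipped:
        raise ValueError("hypothesis selection yields too few eligible cells")
    grid = [1] if hypothesis.single_cell else sorted(set(int(n) for n in n_grid))
    if not grid:
        raise ValueError("empty N grid")
    # truncate the grid to what the eligible pools can supply
    if hypothesis.label == "H2":
        grid = [n for n in grid if n <= len(same)]
    elif hypothesis.label == "H3":
        grid = [n for n in grid
                if n // 2 + n % 2 <= len(same) and n // 2 <= len(flipped)]
    if not grid:
        raise ValueError("hypothesis selection yields too few eligible cells")
    rng = np.random.default_rng(seed)
    medians, n_min = [], None
    for n in grid:
        ratios = []
        for _ in range(n_seeds):
            ids = hypothesis.select(same, flipped, n, rng)
            sub_fit = design_fit.select(ids)
            fit = fit_nonpositive_weights(sub_fit.X, target_fit,
                                          neuron_ids=ids)
            ratios.append(residual_reafference_ratio(
                fit, design_eval.select(ids), target_eval))
        med = float(np.median(ratios))
        medians.append(med)
        if n_min is None and med <= criterion_ratio:
            n_min = n
            if stop_at_first:
                break
    return HypothesisSweep(hypothesis.label, grid[:len(medians)], medians, n_min)


# ---------------------------------------------------------------------------
# target-neuron model: R^2 vs N
# ---------------------------------------------------------------------------

@dataclass
class R2Curve:
    n_grid: list[int]
    r2_mean: list[float]
    r2_lo: list[float]
    r2_hi: list[float]
    n_match: int | None
    band: tuple[float, float]


def r2_vs_n_curve(design: DesignMatrix, target: np.ndarray, *,
                  n_grid: Sequence[int],
                  n_boot: int = 50,
                  band: tuple[float, float] = (0.8, 1.0),
                  mossy: np.ndarray | None = None,
                  eligible_ids: Sequence[str] | None = None,
                  seed=None) -> R2Curve:
    """Goodness of fit of the target-neuron readout versus population size.

    For each N, ``n_boot`` random cell subsets are fit and the R-squared
    summarized (mean and percentile 95% CI).  ``n_match`` is the smallest N
    whose CI overlaps the target-neuron variability band (the band stands in
    for the trial-to-trial reliability of the reference response).
    """
    rng = np.random.default_rng(seed)
    ids = list(eligible_ids) if eligible_ids is not None else design.neuron_ids
    means, los, his = [], [], []
    n_match = None
    grid = sorted(set(int(n) for n in n_grid))
    for n in grid:
        if n > len(ids):
            raise ValueError("N grid exceeds population size; augment first")
        r2s = np.empty(n_boot)
        for b in range(n_boot):
            sub = list(rng.choice(ids, size=n, replace=False))
            d = design.select(sub)
            r2s[b] = fit_nonpositive_weights(d.X, target, mossy=mossy).r2
        means.append(float(r2s.mean()))
        los.append(float(np.percentile(r2s, 2.5)))
        his.append(float(np.percentile(r2s, 97.5)))
        if n_match is None and his[-1] >= band[0] and los[-1] <= band[1]:
            n_match = n
    return R2Curve(grid, means, los, his, n_match, tuple(band))


def reliability_band(target: np.ndarray, trial_sd: float) -> tuple[float, float]:
    """R-squared band for the target response given its trial-to-trial SD.

    The lower edge is the R-squared a perfect model of the underlying
    response would score against a single trial (target +- its trial SD):
    1 - trial_sd^2 / var(target).  The band stands in for the target-neuron
    variability region of the goodness-of-fit plot.
    """
    var = float(np.var(target))
    if var <= 0:
        return (0.0, 1.0)
    return (max(0.0, 1.0 - trial_sd ** 2 / var), 1.0)


# ---------------------------------------------------------------------------
# generative augmentation
# ---------------------------------------------------------------------------

def _vest_features(neuron: NeuronGroundTruth):
    """Continuous feature vector describing a cell's response statistics."""
    pref_side = 0 if neuron.type_label == "I" else 1
    coeffs = (neuron.vest.c_pos[pref_side], neuron.vest.c_vel[pref_side],
              neuron.vest.c_acc[pref_side])
    vec = response_vector(coeffs)
    s_pref = abs(vec.sensitivity)
    neck_vec = response_vector((neuron.neck.c_pos[0], neuron.neck.c_vel[0],
                                neuron.neck.c_acc[0]))
    rho = abs(neck_vec.sensitivity) / max(s_pref, 1e-9)
    return np.array([math.log(max(s_pref, 1e-9)), vec.phase_deg,
                     math.log(max(rho, 1e-3)), neuron.cancellation_gain,
                     math.log(neuron.resting_rate)])


def augment_population(neurons: Sequence[NeuronGroundTruth], n_extra: int,
                       mode: str = "coefficient_gaussian",
                       seed=None) -> list[NeuronGroundTruth]:
    """Draw extra synthetic cells from a generative fit to an existing set.

    ``coefficient_gaussian`` fits, per active-sign class, a multivariate
    Gaussian to (log sensitivity, phase, log neck ratio, cancellation gain,
    log resting rate) and draws new coefficient sets, preserving the source's
    sensitivity and phase distributions; categorical labels are resampled
    from their empirical frequencies.  ``motor_response`` instead fills in
    motor-response parameters (cancellation gain, lead) for cells lacking
    them, drawing from a Gaussian fit to the motor-responsive cells.
    """
    if mode not in ("coefficient_gaussian", "motor_response"):
        raise ValueError(f"unknown augmentation mode {mode!r}")
    rng = np.random.default_rng(seed)
    source = [nr for nr in neurons if not nr.vest.is_zero()]
    if len(source) < 10:
        raise ValueError("need at least 10 source cells to fit the generator")
    if n_extra == 0:
        return []

    if mode == "motor_response":
        donors = [nr for nr in source if nr.motor_responsive]
        ks = np.array([nr.cancellation_gain for nr in donors])
        leads = np.array([nr.motor_lead_ms for nr in donors])
        out = []
        recipients = [nr for nr in neurons if not nr.motor_responsive][:n_extra]
        for i, nr in enumerate(recipients):
            k = float(rng.normal(ks.mean(), max(ks.std(), 1e-6)))
            lead = float(rng.normal(leads.mean(), max(leads.std(), 1e-6)))
            out.append(NeuronGroundTruth(
                neuron_id=f"{nr.neuron_id}_aug", resting_rate=nr.resting_rate,
                vest=nr.vest, neck=nr.neck, cancellation_gain=k,
                motor_lead_ms=lead, modality=nr.modality,
                active_sign=nr.active_sign, type_label=nr.type_label,
                tuning=nr.tuning, motor_responsive=True))
        return out

    out = []
    by_class: dict[str, list[NeuronGroundTruth]] = {}
    for nr in source:
        by_class.setdefault(nr.active_sign, []).append(nr)
    class_labels = list(by_class)
    class_p = np.array([len(by_class[c]) for c in class_labels], float)
    class_p /= class_p.sum()
    stats = {}
    for c, members in by_class.items():
        feats = np.stack([_vest_features(nr) for nr in members])
        mean = feats.mean(axis=0)
        if len(members) > 1 and np.all(feats.std(axis=0) > 0):
            cov = np.cov(feats.T)
        else:
            # degenerate dimensions: copy with a tiny jitter, warn via docstring contract
            cov = np.diag(np.maximum(feats.var(axis=0), 1e-12))
        stats[c] = (mean, cov, members)
    for i in range(int(n_extra)):
        c = str(rng.choice(class_labels, p=class_p))
        mean, cov, members = stats[c]
        f = rng.multivariate_normal(mean, cov)
        s_pref = float(np.exp(f[0]))
        k = float(f[3])
        resting = float(np.clip(np.exp(f[4]), 5.0, 250.0))
        # smoothed bootstrap: rescale a donor's full channel structure
        # (per-side magnitudes, phases, neck ratio) to the drawn sensitivity,
        # preserving the source's dynamics and phase distribution
        donor = members[int(rng.integers(len(members)))]
        s_donor = float(np.exp(_vest_features(donor)[0]))
        scale = s_pref / max(s_donor, 1e-9)
        out.append(NeuronGroundTruth(
            neuron_id=f"aug{i:04d}", resting_rate=resting,
            vest=donor.vest.scaled(scale), neck=donor.neck.scaled(scale),
            cancellation_gain=k, motor_lead_ms=donor.motor_lead_ms,
            modality=donor.modality, active_sign=c,
            type_label=donor.type_label, tuning=donor.tuning,
            motor_responsive=donor.motor_responsive))
    return out


# ---------------------------------------------------------------------------
# mossy-fiber robustness and subclass weights
# ---------------------------------------------------------------------------

def mossy_trace_for_design(sim: MossyFiberSim, suite: Mapping,
                           design: DesignMatrix, downsample: int) -> np.ndarray:
    """One simulated mossy-fiber input stacked to match the design rows."""
    parts = []
    for c, d in _block_order(design):
        kin = suite[(c, d)]["intended"]
        parts.append(sim.respond(kin)[::downsample])
    return np.concatenate(parts)


def mossy_robustness(design: DesignMatrix, target: np.ndarray,
                     suite: Mapping, *, downsample: int,
                     modifiers: Sequence[str] = ("none", "gain_x2", "gain_half",
                                                 "phase_x2", "phase_half"),
                     n_grid: Sequence[int],
                     band: tuple[float, float],
                     eligible_ids: Sequence[str] | None = None,
                     n_sims: int = 25, n_boot: int = 20,
                     seed=None) -> dict[str, float]:
    """Median N_match of the target-neuron model per mossy-input modifier.

    For each modifier, mossy inputs are simulated with the corresponding
    gain/phase distribution, the readout is refit with one extra non-negative
    mossy column per simulation, and the population size matching the target
    band re-estimated.
    """
    from .synth import simulate_mossy_fibers
    rng = np.random.default_rng(seed)
    out = {}
    for mod in modifiers:
        sims = simulate_mossy_fibers(n_sims, modifier=mod,
                                     seed=rng.integers(2 ** 31))
        n_matches = []
        for sim in sims:
            mossy = mossy_trace_for_design(sim, suite, design, downsample)
            curve = r2_vs_n_curve(design, target, n_grid=n_grid,
                                  n_boot=n_boot, band=band, mossy=mossy,
                                  eligible_ids=eligible_ids,
                                  seed=rng.integers(2 ** 31))
            n_matches.append(curve.n_match if curve.n_match is not None
                             else max(n_grid))
        out[mod] = float(np.median(n_matches))
    return out


DEFAULT_N_GRID = (10, 15, 20, 25, 30, 35, 40, 45, 50, 55, 60, 70, 80,
                  100, 130, 170, 220, 280, 340, 400)


def cancellation_study(pool_size: int = 1200, *,
                       hypotheses: Sequence[str] = HYPOTHESES,
                       n_trials: int = 100,
                       n_seeds: int = 20,
                       n_grid: Sequence[int] = DEFAULT_N_GRID,
                       downsample: int = 10,
                       afferent_gain: float = 1.0,
                       criterion_ratio: float = 0.3,
                       seed=None) -> dict:
    """End-to-end hypothesis study of the cancellation-signal model.

    Generates a default synthetic population and matched condition suite,
    averages trial rates (two independent replicates for out-of-sample
    evaluation), builds the passive + active design with the cancellation
    target, and sweeps every requested hypothesis.  Returns
    {label: HypothesisSweep} plus the pool under key ``"neurons"``.
    """
    rng = np.random.default_rng(seed)
    neurons = sample_population(pool_size, seed=rng.integers(2 ** 31))
    from .synth import NoiseModel, condition_suite, population_average_rates
    suite = condition_suite(CANCELLATION_CONDITIONS, 10,
                            seed=rng.integers(2 ** 31))
    reps = population_average_rates(neurons, suite, n_trials=n_trials,
                                    noise_model=NoiseModel(),
                                    downsample=downsample, n_replicates=2,
                                    seed=rng.integers(2 ** 31))
    designs = [build_design(r, conditions=CANCELLATION_CONDITIONS)
               for r in reps]
    head_vel = {key: entry["intended"].head_vel[::downsample]
                for key, entry in suite.items()}
    y = cancellation_target(designs[0], head_vel, afferent_gain=afferent_gain)
    out = {"neurons": neurons}
    for label in hypotheses:
        out[label] = required_population_size(
            neurons, designs[0], designs[1], y, y, label,
            criterion_ratio=criterion_ratio, n_seeds=n_seeds, n_grid=n_grid,
            seed=rng.integers(2 ** 31))
    return out


@dataclass(frozen=True)
class WeightComparison:
    statistic: float
    p_value: float
    groups: tuple[str, ...]


def compare_weight_distributions(weights: np.ndarray,
                                 labels: Sequence[str]) -> WeightComparison:
    """Kruskal-Wallis rank test of |weight| across cell subclasses."""
    labels = np.asarray(labels)
    groups = [np.abs(weights[labels == g]) for g in np.unique(labels)]
    groups = [g for g in groups if g.size > 0]
    if len(groups) < 2:
        return WeightComparison(float("nan"), float("nan"),
                                tuple(np.unique(labels)))
    stat, p = kruskal(*groups)
    return WeightComparison(float(stat), float(p), tuple(np.unique(labels)))
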