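"""End-to-end orchestration: generate -> fit neurons -> summation -> population.

`run_pipeline` executes the configured stages on synthetic data, writing every
stage artifact (JSON/CSV) plus a machine-readable `summary.json` into a run
directory; `report` renders tables and figures from a completed run.  All
randomness derives from the single config seed, so identical configs produce
byte-identical summaries.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io, kinfit, popmodel, signals, summation, synth

log = logging.getLogger("reafference")

STAGES = ("synthesize", "fit_neurons", "summation", "population",
          "hypotheses", "mossy")

#: analysis window around (attempted-)movement onset for response vectors
SUMMATION_WINDOW = (-50.0, 100.0)


@dataclass
class RunConfig:
    """Configuration of one pipeline run (YAML-serializable).

    Defaults are sized for a complete desk-scale run; every stochastic stage
    derives its seed from ``seed``.
    """

    seed: int = 0
    out_dir: str = "runs/default"
    stages: tuple = ("synthesize", "fit_neurons", "summation", "population",
                     "hypotheses")
    # generator
    n_neurons: int = 100
    n_trials: int = 10                  # sinusoid trials per condition
    n_trials_transient: int = 100       # head-on-body passive/active/combined
    n_trials_attempted: int = 10        # brake trials are a small subset
    noise_sd: float = 10.0
    noise_corr_ms: float = 0.0
    peak_velocity: float = synth.DEFAULT_ACTIVE_PEAK_DPS
    duration_ms: float = synth.DEFAULT_DURATION_MS
    conditions: tuple = synth.CONDITIONS
    write_trials: bool = False
    # per-neuron fitting
    fit_downsample: int = 5
    n_boot_prune: int = 200
    n_perm: int = 500
    alpha: float = 0.05
    min_trials_per_direction: int = 10
    # population model
    pool_size: int = 600
    n_trials_population: int = 100      # sessions contribute ~100 movements/direction
    rfn_n_trials: int = 20              # trial budget of the reference recordings
    downsample: int = 5
    afferent_gain: float = 1.0
    rfn_sensitivity: float = 0.5
    rfn_suppression: float = 0.7
    criterion_ratio: float = 0.3
    hypothesis_grid: tuple = popmodel.DEFAULT_N_GRID
    hypothesis_seeds: int = 10
    r2_grid: tuple = (1, 2, 5, 10, 20, 40, 60, 90, 140, 200)
    r2_boot: int = 30
    model_n: int = 200                  # full-population contract model
    mossy_n_sims: int = 10

    @staticmethod
    def from_yaml(path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        valid = {f.name for f in dataclasses.fields(RunConfig)}
        unknown = set(data) - valid
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("stages", "conditions", "hypothesis_grid", "r2_grid"):
            if key in data:
                data[key] = tuple(data[key])
        return RunConfig(**data)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        for key in ("stages", "conditions", "hypothesis_grid", "r2_grid"):
            d[key] = list(d[key])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    def validate(self) -> None:
        for s in self.stages:
            if s not in STAGES:
                raise ValueError(f"unknown stage {s!r}")
        if self.n_trials < 1 or self.n_neurons < 1:
            raise ValueError("n_neurons and n_trials must be positive")


def _noise(cfg: RunConfig) -> synth.NoiseModel:
    return synth.NoiseModel("gaussian", cfg.noise_sd, cfg.noise_corr_ms)


# ---------------------------------------------------------------------------
# stage: synthesize
# ---------------------------------------------------------------------------

def _trials_per_condition(cfg: RunConfig, condition: str) -> int:
    return (cfg.n_trials_attempted if condition == "attempted"
            else cfg.n_trials_transient)


def _synthesize(cfg: RunConfig, rng, out: Path):
    """Generate trials at 1 kHz per neuron (optionally serialized), keeping a
    downsampled copy in memory for the fitting stages."""
    neurons = synth.sample_population(cfg.n_neurons,
                                      seed=rng.integers(2 ** 31))
    n_max = max(cfg.n_trials_transient, cfg.n_trials_attempted)
    suite = synth.condition_suite(
        [c for c in cfg.conditions if c != "whole_body"
         and c != "body_under_head"],
        n_max, peak_velocity=cfg.peak_velocity,
        duration_ms=cfg.duration_ms, seed=rng.integers(2 ** 31))
    sinus = {}
    for condition in ("whole_body", "body_under_head"):
        if condition in cfg.conditions:
            profiles = synth.make_sinusoid_profile(
                n_trials=cfg.n_trials, seed=rng.integers(2 ** 31))
            sinus[condition] = [
                synth.assign_condition_kinematics(p, condition)
                for p in profiles]
    trials = {}
    noise = _noise(cfg)
    index = []
    for nr in neurons:
        per = {}
        for (condition, direction), entry in suite.items():
            full = synth.synthesize_trials(
                nr, entry["trials"][:_trials_per_condition(cfg, condition)],
                condition, noise_model=noise,
                intended=entry["intended"], direction=direction,
                seed=rng.integers(2 ** 31))
            if cfg.write_trials:
                rel = f"trials/{nr.neuron_id}_{condition}_{direction}.csv"
                io.write_trialset(full, out / rel)
                index.append({"neuron_id": nr.neuron_id,
                              "condition": condition, "direction": direction,
                              "path": rel, "n_trials": len(full.trials)})
            per[(condition, direction)] = _downsampled_set(
                full, cfg.fit_downsample)
            if condition in ("head_on_body_passive", "head_on_body_active",
                             "attempted"):
                # full-rate copy of the short onset window for vectorization
                per[("window", condition, direction)] = _window_set(
                    full, *SUMMATION_WINDOW)
        for condition, kins in sinus.items():
            full = synth.synthesize_trials(
                nr, kins, condition, noise_model=noise,
                seed=rng.integers(2 ** 31))
            if cfg.write_trials:
                rel = f"trials/{nr.neuron_id}_{condition}_both.csv"
                io.write_trialset(full, out / rel)
                index.append({"neuron_id": nr.neuron_id,
                              "condition": condition, "direction": "both",
                              "path": rel, "n_trials": len(full.trials)})
            per[(condition, "both")] = _downsampled_set(
                full, cfg.fit_downsample)
        trials[nr.neuron_id] = per
    io.write_population(neurons, out / "ground_truth.json",
                        seeds={"seed": cfg.seed})
    if cfg.write_trials:
        io.write_trials_index(index, out / "trials_index.csv")
    return neurons, suite, sinus, trials


# ---------------------------------------------------------------------------
# stage: per-neuron fitting
# ---------------------------------------------------------------------------

def _downsample_kin(k: synth.KinematicTrace, step: int) -> synth.KinematicTrace:
    return synth.KinematicTrace(
        t=k.t[::step], head_pos=k.head_pos[::step],
        head_vel=k.head_vel[::step], head_acc=k.head_acc[::step],
        body_pos=k.body_pos[::step], body_vel=k.body_vel[::step],
        body_acc=k.body_acc[::step],
        passive_head_vel=k.passive_head_vel[::step],
        active_head_vel=k.active_head_vel[::step])


def _downsampled_set(ts: synth.TrialSet, step: int) -> synth.TrialSet:
    out = []
    for tr in ts.trials:
        out.append(synth.Trial(
            kinematics=_downsample_kin(tr.kinematics, step),
            rate=np.asarray(tr.rate[::step], dtype=np.float32),
            torque=tr.torque[::step], direction=tr.direction))
    return synth.TrialSet(ts.condition, out, ts.neuron_id)


def _trial_data(ts: synth.TrialSet, proxy: synth.KinematicTrace | None = None):
    rates = [np.asarray(tr.rate, float) for tr in ts.trials]
    kins = [proxy if proxy is not None else tr.kinematics
            for tr in ts.trials]
    return rates, kins


def _crop_kin(k: synth.KinematicTrace, lo: float, hi: float) -> synth.KinematicTrace:
    m = (k.t >= lo) & (k.t <= hi)
    return synth.KinematicTrace(
        t=k.t[m], head_pos=k.head_pos[m], head_vel=k.head_vel[m],
        head_acc=k.head_acc[m], body_pos=k.body_pos[m], body_vel=k.body_vel[m],
        body_acc=k.body_acc[m], passive_head_vel=k.passive_head_vel[m],
        active_head_vel=k.active_head_vel[m])


def _window_set(ts: synth.TrialSet, lo: float, hi: float) -> synth.TrialSet:
    """Full-rate copy of a trial set cropped to the analysis window."""
    out = []
    for tr in ts.trials:
        m = (tr.kinematics.t >= lo) & (tr.kinematics.t <= hi)
        out.append(synth.Trial(kinematics=_crop_kin(tr.kinematics, lo, hi),
                               rate=np.asarray(tr.rate[m], dtype=np.float32),
                               torque=tr.torque[m], direction=tr.direction))
    return synth.TrialSet(ts.condition, out, ts.neuron_id)


def _fit_neurons(cfg: RunConfig, rng, neurons, suite, trials, out: Path):
    """Kinematic regression per neuron with QC exclusions; returns fit records."""
    records = []
    motor_results = []
    mean_active = {d: suite[("head_on_body_active", d)]["intended"]
                   for d in synth.DIRECTIONS
                   if ("head_on_body_active", d) in suite}
    for nr in neurons:
        per = trials[nr.neuron_id]
        rec = {"neuron_id": nr.neuron_id, "excluded": None}
        # QC: trial counts
        n_ipsi = len(per.get(("head_on_body_active", "ipsi"),
                             synth.TrialSet("x")).trials)
        n_contra = len(per.get(("head_on_body_active", "contra"),
                               synth.TrialSet("x")).trials)
        if min(n_ipsi, n_contra) < cfg.min_trials_per_direction:
            rec["excluded"] = "fewer than 10 movements per direction"
            records.append(rec)
            continue
        # passive sinusoid fit (vestibular + proprioceptive channels)
        if ("whole_body", "both") in per and ("body_under_head", "both") in per:
            r1, k1 = _trial_data(per[("whole_body", "both")])
            r2, k2 = _trial_data(per[("body_under_head", "both")])
            fit_pass = kinfit.bootstrap_prune(
                r1 + r2, k1 + k2, channels=("head", "body"),
                n_boot=cfg.n_boot_prune, seed=rng.integers(2 ** 31))
            vec = kinfit.response_vector(fit_pass, "head")
            rec["passive_sinusoid"] = {
                "bias": fit_pass.bias, "vaf": fit_pass.vaf,
                "sensitivity": vec.sensitivity, "phase_deg": vec.phase_deg,
                "retained": {c: list(t) for c, t
                             in fit_pass.retained_terms.items()}}
            if not fit_pass.retained_terms.get("head"):
                rec["excluded"] = "not responsive to vestibular stimulation"
                records.append(rec)
                continue
            passive_alone_sens = vec.sensitivity
        else:
            passive_alone_sens = None
        # direction-resolved passive/active transient fits
        for condition, key in (("head_on_body_passive", "passive_hob"),
                               ("head_on_body_active", "active")):
            vecs = {}
            for d in synth.DIRECTIONS:
                if (condition, d) not in per:
                    continue
                r, k = _trial_data(per[(condition, d)])
                fit_d = kinfit.fit_kinematic(
                    r, k, channels=("head",),
                    window_ms=(0.0, cfg.duration_ms))
                vecs[d] = kinfit.response_vector(fit_d, "head")
            if vecs:
                rec[key] = {d: {"sensitivity": v.sensitivity,
                                "phase_deg": v.phase_deg}
                            for d, v in vecs.items()}
        if "passive_hob" in rec and set(rec["passive_hob"]) == set(synth.DIRECTIONS):
            tc = kinfit.classify_tuning(
                rec["passive_hob"]["ipsi"]["sensitivity"],
                rec["passive_hob"]["contra"]["sensitivity"])
            rec["tuning"] = {"shape": tc.shape, "type": tc.type_label,
                             "preferred": tc.preferred}
        # summation-window vectors (passive, attempted, active): full-rate
        # windowed data, velocity regressor (the attempted condition is fit
        # against the mean active head velocity per protocol)
        vecs_sum = {}
        for condition, label in (("head_on_body_passive", "passive"),
                                 ("head_on_body_active", "active"),
                                 ("attempted", "attempted")):
            for d in synth.DIRECTIONS:
                if ("window", condition, d) not in per:
                    continue
                ts = per[("window", condition, d)]
                if condition == "attempted":
                    proxy = mean_active.get(d)
                    if proxy is None:
                        continue
                    r, k = _trial_data(ts, _crop_kin(proxy, *SUMMATION_WINDOW))
                else:
                    r, k = _trial_data(ts)
                fit_v = kinfit.fit_kinematic(
                    r, k, channels=("head",),
                    terms_by_channel={"head": ("vel",)})
                vecs_sum[(label, d)] = kinfit.response_vector(fit_v, "head")
        rec["summation_vectors"] = {
            f"{label}_{d}": {"sensitivity": v.sensitivity,
                             "phase_deg": v.phase_deg}
            for (label, d), v in vecs_sum.items()}
        # combined-condition reafference/exafference ratios
        if ("combined", "ipsi") in per and passive_alone_sens:
            r, k = _trial_data(per[("combined", "ipsi")])
            try:
                fit_c = kinfit.fit_kinematic(
                    r, k, channels=("passive_head", "active_head"))
                ratios = kinfit.combined_ratios(fit_c, passive_alone_sens)
                rec["combined"] = {
                    "exafference_ratio": ratios.exafference_ratio,
                    "reafference_ratio": ratios.reafference_ratio,
                    "defined": ratios.defined}
            except ValueError:
                pass
        # motor-response permutation test per direction (a neuron is
        # motor-related if it responds to torque in at least one direction)
        for d in synth.DIRECTIONS:
            if ("attempted", d) not in per:
                continue
            ts_att = synth.TrialSet("attempted", per[("attempted", d)].trials,
                                    f"{nr.neuron_id}:{d}")
            res = signals.motor_response_test(
                ts_att, n_perm=cfg.n_perm, seed=rng.integers(2 ** 31))
            motor_results.append(res)
            rec.setdefault("motor", {})[d] = {
                "statistic": res.statistic, "p": res.p_value,
                "testable": res.testable}
        rec["_vectors"] = vecs_sum
        records.append(rec)
    signals.adjust_motor_responses(motor_results, alpha=cfg.alpha)
    by_key = {r.neuron_id: r for r in motor_results}
    for rec in records:
        if "motor" not in rec:
            continue
        flags = [by_key[f"{rec['neuron_id']}:{d}"].significant
                 for d in synth.DIRECTIONS
                 if f"{rec['neuron_id']}:{d}" in by_key]
        rec["motor"]["significant"] = any(f is True for f in flags)
    serializable = [{k: v for k, v in rec.items() if not k.startswith("_")}
                    for rec in records]
    io.write_json(serializable, out / "neuron_fits.json")
    return records


# ---------------------------------------------------------------------------
# stage: summation
# ---------------------------------------------------------------------------

def _summation(cfg: RunConfig, records, out: Path):
    if "attempted" not in cfg.conditions:
        io.write_json({"skipped": "attempted condition not configured"},
                      out / "summation.json")
        log.info("summation stage skipped: no attempted condition")
        return None
    prediction_records = []
    for rec in records:
        if rec.get("excluded") or "_vectors" not in rec:
            continue
        # the summation hypothesis concerns cells with a motor-related
        # response; cells without one have nothing to sum
        if not rec.get("motor", {}).get("significant"):
            continue
        vecs = rec["_vectors"]
        # evaluate in the direction with the largest motor-related response
        best_d, best = None, -1.0
        for d in synth.DIRECTIONS:
            v = vecs.get(("attempted", d))
            if v is not None and abs(v.sensitivity) > best:
                best_d, best = d, abs(v.sensitivity)
        if best_d is None:
            continue
        needed = [("passive", best_d), ("active", best_d), ("attempted", best_d)]
        if not all(k in vecs for k in needed):
            continue
        prediction_records.append(summation.PredictionRecord(
            neuron_id=rec["neuron_id"],
            passive=vecs[("passive", best_d)],
            attempted=vecs[("attempted", best_d)],
            observed_active=vecs[("active", best_d)]))
    rows = [{
        "neuron_id": r.neuron_id,
        "predicted_gain": r.predicted_active.sensitivity,
        "observed_gain": r.observed_active.sensitivity,
        "predicted_phase": r.predicted_active.phase_deg,
        "observed_phase": r.observed_active.phase_deg,
    } for r in prediction_records]
    pd.DataFrame(rows).to_csv(out / "summation_records.csv", index=False)
    if len(prediction_records) < 10:
        io.write_json({"skipped": "fewer than 10 prediction records"},
                      out / "summation.json")
        return None
    summary = summation.evaluate_population_prediction(prediction_records)
    payload = dataclasses.asdict(summary)
    io.write_json(payload, out / "summation.json")
    return summary


# ---------------------------------------------------------------------------
# stages: population model and hypotheses
# ---------------------------------------------------------------------------

def _population_data(cfg: RunConfig, rng, neurons):
    """Pool, trial-averaged replicate rates and designs for the readouts.

    Returns the (augmented) pool, the kinematic suite, designs for the
    target-neuron model (all conditions; replicates 0/1 noisy, 2 noise-free),
    cancellation designs (passive + active conditions only) and the
    cancellation target.
    """
    pool = [nr for nr in neurons if not nr.vest.is_zero()]
    if len(pool) < cfg.pool_size:
        pool = pool + popmodel.augment_population(
            pool, cfg.pool_size - len(pool), seed=rng.integers(2 ** 31))
    suite = synth.condition_suite(
        popmodel.DEFAULT_CONDITIONS, cfg.n_trials,
        peak_velocity=cfg.peak_velocity, duration_ms=cfg.duration_ms,
        seed=rng.integers(2 ** 31))
    reps = synth.population_average_rates(
        pool, suite, n_trials=cfg.n_trials_population,
        noise_model=_noise(cfg), downsample=cfg.downsample, n_replicates=2,
        seed=rng.integers(2 ** 31))
    clean = synth.population_average_rates(
        pool, suite, n_trials=1, noise_model=synth.NoiseModel("none"),
        downsample=cfg.downsample, n_replicates=1, seed=0)
    designs = [popmodel.build_design(r) for r in reps + clean]
    designs_cancel = [
        popmodel.build_design(r, conditions=popmodel.CANCELLATION_CONDITIONS)
        for r in reps]
    head_vel = {key: entry["intended"].head_vel[::cfg.downsample]
                for key, entry in suite.items()}
    y_cancel = popmodel.cancellation_target(
        designs_cancel[0], head_vel, afferent_gain=cfg.afferent_gain)
    return pool, suite, designs, designs_cancel, y_cancel


def _rfn_reference(cfg: RunConfig, rng, suite):
    """Trial-averaged reference target-neuron rates at its own trial budget."""
    kin_map = {key: [kin for kin in entry["trials"]]
               for key, entry in suite.items()}
    noise = synth.NoiseModel(
        "gaussian", cfg.noise_sd / np.sqrt(cfg.rfn_n_trials),
        cfg.noise_corr_ms)
    ts_map = synth.synthesize_rfn_reference(
        kin_map, cfg.rfn_sensitivity, cfg.rfn_suppression,
        noise_model=noise, seed=rng.integers(2 ** 31))
    return {key: ts.mean_rate()[::cfg.downsample]
            for key, ts in ts_map.items()}


def _model_suppression(fit, design, head_vel_by_key, downsample):
    """Active-vs-passive velocity sensitivity of the fitted model output."""
    pred = fit.predict(design.X)
    gains = {}
    for condition in ("head_on_body_passive", "head_on_body_active"):
        num = den = 0.0
        row = 0
        for c, d in popmodel._block_order(design):
            n = int(np.sum((design.row_condition == c)
                           & (design.row_direction == d)))
            if c == condition:
                v = head_vel_by_key[(c, d)]
                seg = pred[row:row + n] - pred[row:row + n].mean()
                num += float(np.dot(seg, v - v.mean()))
                den += float(np.dot(v - v.mean(), v - v.mean()))
            row += n
        gains[condition] = num / den if den else float("nan")
    g_pass = gains["head_on_body_passive"]
    g_act = gains["head_on_body_active"]
    supp = 1.0 - abs(g_act) / abs(g_pass) if g_pass else float("nan")
    return supp, gains


def _attempted_output_fraction(fit, design):
    pred = fit.predict(design.X)
    att = design.rows("attempted")
    pas = design.rows("head_on_body_passive")
    mod_att = float(np.sqrt(np.mean((pred[att] - pred[att].mean()) ** 2)))
    mod_pas = float(np.sqrt(np.mean((pred[pas] - pred[pas].mean()) ** 2)))
    return mod_att / mod_pas if mod_pas else float("nan")


def _population(cfg: RunConfig, rng, pool, suite, designs, out: Path):
    rfn_rates = _rfn_reference(cfg, rng, suite)
    y_rfn = popmodel.rfn_target(designs[0], rfn_rates)
    band = popmodel.reliability_band(
        y_rfn, cfg.noise_sd / np.sqrt(cfg.rfn_n_trials))
    eligible = [nr.neuron_id for nr in pool]
    curve = popmodel.r2_vs_n_curve(
        designs[0], y_rfn, n_grid=cfg.r2_grid, n_boot=cfg.r2_boot,
        band=band, eligible_ids=eligible, seed=rng.integers(2 ** 31))
    pd.DataFrame({"N": curve.n_grid, "r2_mean": curve.r2_mean,
                  "r2_lo": curve.r2_lo, "r2_hi": curve.r2_hi}
                 ).to_csv(out / "r2_vs_n.csv", index=False)
    # full-population contract model: suppression, motor negation, weights
    # (medians over independent cell draws; single fits are noisy)
    head_vel = {key: entry["intended"].head_vel[::cfg.downsample]
                for key, entry in suite.items()}
    draw_rng = np.random.default_rng(rng.integers(2 ** 31))
    supps, att_fracs = [], []
    fit = ids = d_clean = None
    for _ in range(5):
        ids = list(draw_rng.choice(eligible,
                                   size=min(cfg.model_n, len(eligible)),
                                   replace=False))
        d_fit = designs[0].select(ids)
        d_clean = designs[2].select(ids)
        fit = popmodel.fit_nonpositive_weights(d_fit.X, y_rfn,
                                               neuron_ids=ids)
        s_, gains = _model_suppression(fit, d_clean, head_vel,
                                       cfg.downsample)
        supps.append(s_)
        att_fracs.append(_attempted_output_fraction(fit, d_clean))
    supp = float(np.median(supps))
    att_frac = float(np.median(att_fracs))
    fit.r2_ci = fit.r2_ci or None
    boot = popmodel.fit_nonpositive_weights(d_fit.X, y_rfn, n_boot=50,
                                            seed=rng.integers(2 ** 31),
                                            neuron_ids=ids)
    fit.r2_ci = boot.r2_ci
    by_id = {nr.neuron_id: nr for nr in pool}
    labels = {
        "modality": [by_id[i].modality for i in ids],
        "type": [by_id[i].type_label for i in ids],
        "tuning": [by_id[i].tuning for i in ids],
        "motor": [str(by_id[i].motor_responsive) for i in ids],
    }
    weight_tests = {
        axis: dataclasses.asdict(
            popmodel.compare_weight_distributions(fit.weights, labs))
        for axis, labs in labels.items()}
    top_share = float(np.max(np.abs(fit.weights))
                      / max(np.sum(np.abs(fit.weights)), 1e-12))
    payload = {
        "band": list(band), "n_match": curve.n_match,
        "r2_at_model_n": fit.r2, "r2_ci": list(fit.r2_ci),
        "model_suppression": supp, "model_gains": gains,
        "attempted_output_fraction": att_frac,
        "largest_weight_share": top_share,
        "weight_subclass_tests": weight_tests,
        "model_n": len(ids),
    }
    io.write_json(payload, out / "population_model.json")
    return payload, (y_rfn, band, eligible)


def _hypotheses(cfg: RunConfig, rng, pool, designs_cancel, y_cancel, out: Path):
    rows = []
    for label in popmodel.HYPOTHESES:
        sweep = popmodel.required_population_size(
            pool, designs_cancel[0], designs_cancel[1], y_cancel, y_cancel,
            label,
            criterion_ratio=cfg.criterion_ratio,
            n_seeds=cfg.hypothesis_seeds, n_grid=cfg.hypothesis_grid,
            seed=rng.integers(2 ** 31))
        rows.append({"hypothesis": label,
                     "n_min": sweep.n_min if sweep.achievable else None,
                     "achievable": sweep.achievable,
                     "grid_max": max(sweep.n_grid),
                     "median_ratio_at_max": sweep.median_ratio[-1]})
    df = pd.DataFrame(rows)
    df.to_csv(out / "hypotheses.csv", index=False)
    return rows


def _mossy(cfg: RunConfig, rng, pool, suite, designs, rfn_bits, out: Path):
    y_rfn, band, eligible = rfn_bits
    table = popmodel.mossy_robustness(
        designs[0], y_rfn, suite, downsample=cfg.downsample,
        n_grid=cfg.r2_grid, band=band, eligible_ids=eligible,
        n_sims=cfg.mossy_n_sims, n_boot=max(5, cfg.r2_boot // 3),
        seed=rng.integers(2 ** 31))
    io.write_json(table, out / "mossy_robustness.json")
    return table


# ---------------------------------------------------------------------------
# entry points
# ---------------------------------------------------------------------------

def run_pipeline(cfg: RunConfig) -> Path:
    """Execute the configured stages; returns the run directory."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    cfg.to_yaml(out / "config.yaml")
    rng = np.random.default_rng(cfg.seed)
    summary = {"config_seed": cfg.seed, "stages_run": []}
    state: dict = {}
    try:
        for stage in ("synthesize", "fit_neurons", "summation",
                      "population", "hypotheses", "mossy"):
            if stage not in cfg.stages:
                # keep the seed chain aligned regardless of stage selection
                rng_stage = np.random.default_rng(rng.integers(2 ** 31))
                del rng_stage
                continue
            rng_stage = np.random.default_rng(rng.integers(2 ** 31))
            log.info("stage %s", stage)
            try:
                if stage == "synthesize":
                    neurons, suite, sinus, trials = _synthesize(
                        cfg, rng_stage, out)
                    state.update(neurons=neurons, suite=suite, trials=trials)
                    summary["n_neurons"] = len(neurons)
                elif stage == "fit_neurons":
                    records = _fit_neurons(cfg, rng_stage, state["neurons"],
                                           state["suite"], state["trials"], out)
                    state["records"] = records
                    excluded = sum(1 for r in records if r.get("excluded"))
                    sig = [r["motor"].get("significant") for r in records
                           if "motor" in r and not r.get("excluded")]
                    summary["fit_neurons"] = {
                        "n_fit": len(records) - excluded,
                        "n_excluded": excluded,
                        "motor_responsive_fraction":
                            float(np.mean([s is True for s in sig]))
                            if sig else None}
                elif stage == "summation":
                    s = _summation(cfg, state.get("records", []), out)
                    if s is not None:
                        summary["summation"] = {
                            "gain_r2": s.gain_r2, "gain_slope": s.gain_slope,
                            "gain_slope_ci": list(s.gain_slope_ci),
                            "phase_r2": s.phase_r2,
                            "sign_agreement": s.sign_agreement, "n": s.n}
                elif stage == "population":
                    (pool, psuite, designs, designs_cancel,
                     y_cancel) = _population_data(cfg, rng_stage,
                                                  state["neurons"])
                    state.update(pool=pool, psuite=psuite, designs=designs,
                                 designs_cancel=designs_cancel,
                                 y_cancel=y_cancel)
                    payload, rfn_bits = _population(cfg, rng_stage, pool,
                                                    psuite, designs, out)
                    state["rfn_bits"] = rfn_bits
                    summary["population"] = {
                        k: payload[k] for k in
                        ("n_match", "model_suppression",
                         "attempted_output_fraction", "largest_weight_share",
                         "r2_at_model_n")}
                elif stage == "hypotheses":
                    if "pool" not in state:
                        (pool, psuite, designs, designs_cancel,
                         y_cancel) = _population_data(cfg, rng_stage,
                                                      state["neurons"])
                        state.update(pool=pool, psuite=psuite,
                                     designs=designs,
                                     designs_cancel=designs_cancel,
                                     y_cancel=y_cancel)
                    rows = _hypotheses(cfg, rng_stage, state["pool"],
                                       state["designs_cancel"],
                                       state["y_cancel"], out)
                    summary["hypotheses"] = {
                        r["hypothesis"]:
                            (r["n_min"] if r["achievable"] else "not achievable")
                        for r in rows}
                elif stage == "mossy":
                    table = _mossy(cfg, rng_stage, state["pool"],
                                   state["psuite"], state["designs"],
                                   state["rfn_bits"], out)
                    summary["mossy_n_match"] = table
                summary["stages_run"].append(stage)
            except Exception as exc:
                log.exception("stage %s failed", stage)
                summary["failed_stage"] = stage
                summary["error"] = f"{type(exc).__name__}: {exc}"
                io.write_json(summary, out / "summary.json")
                raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    finally:
        log.removeHandler(handler)
        handler.close()
    io.write_json(summary, out / "summary.json")
    return out


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

EXPECTED_ARTIFACTS = ("summary.json", "ground_truth.json", "neuron_fits.json",
                      "summation.json", "summation_records.csv",
                      "r2_vs_n.csv", "population_model.json", "hypotheses.csv")


def report(run_dir) -> Path:
    """Render a human-readable report (markdown + figures) from a run.

    Missing artifacts are listed but do not abort the rendering; regeneration
    is idempotent.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    run = Path(run_dir)
    missing = [a for a in EXPECTED_ARTIFACTS if not (run / a).exists()]
    lines = ["# Pipeline report", ""]
    if missing:
        lines += ["## Missing artifacts", ""]
        lines += [f"- {m}" for m in missing]
        lines.append("")
    figdir = run / "figures"
    figdir.mkdir(exist_ok=True)
    if (run / "summary.json").exists():
        summary = io.read_json(run / "summary.json")
        lines += ["## Headline statistics", "", "```json",
                  json.dumps(summary, indent=1, sort_keys=True), "```", ""]
    if (run / "neuron_fits.json").exists():
        fits = io.read_json(run / "neuron_fits.json")
        sens = [f["passive_sinusoid"]["sensitivity"] for f in fits
                if f.get("passive_sinusoid")]
        if sens:
            fig, ax = plt.subplots(figsize=(4, 3))
            ax.hist(np.abs(sens), bins=20, color="0.4")
            ax.set_xlabel("vestibular sensitivity ((sp/s)/(deg/s))")
            ax.set_ylabel("cells")
            fig.tight_layout()
            fig.savefig(figdir / "sensitivity_hist.png", dpi=120)
            plt.close(fig)
            lines.append("![sensitivities](figures/sensitivity_hist.png)")
        pairs = [(f["passive_hob"]["ipsi"]["sensitivity"],
                  f["active"]["ipsi"]["sensitivity"]) for f in fits
                 if f.get("passive_hob") and f.get("active")
                 and "ipsi" in f.get("passive_hob", {})
                 and "ipsi" in f.get("active", {})]
        if pairs:
            p = np.array(pairs)
            lim = float(np.abs(p).max()) * 1.05 + 1e-9
            fig, ax = plt.subplots(figsize=(4, 4))
            ax.scatter(p[:, 0], p[:, 1], s=12, color="k")
            ax.plot([-lim, lim], [-lim, lim], "k-", lw=1)     # unity
            ax.plot([-lim, lim], [lim, -lim], "k-", lw=1)     # sign-flip unity
            ax.axhline(0, color="0.7", lw=0.5)
            ax.axvline(0, color="0.7", lw=0.5)
            ax.set_xlabel("passive sensitivity")
            ax.set_ylabel("active sensitivity")
            fig.tight_layout()
            fig.savefig(figdir / "active_vs_passive.png", dpi=120)
            plt.close(fig)
            lines.append("![active vs passive](figures/active_vs_passive.png)")
    if (run / "r2_vs_n.csv").exists():
        df = pd.read_csv(run / "r2_vs_n.csv")
        fig, ax = plt.subplots(figsize=(4, 3))
        ax.plot(df["N"], df["r2_mean"], "k-o", ms=3)
        ax.fill_between(df["N"], df["r2_lo"], df["r2_hi"], alpha=0.3,
                        color="0.5")
        ax.set_xlabel("population size N")
        ax.set_ylabel(r"$R^2$")
        fig.tight_layout()
        fig.savefig(figdir / "r2_vs_n.png", dpi=120)
        plt.close(fig)
        lines.append("![r2 vs n](figures/r2_vs_n.png)")
    if (run / "hypotheses.csv").exists():
        df = pd.read_csv(run / "hypotheses.csv")
        lines += ["", "## Hypothesis table", "", df.to_markdown(index=False), ""]
    out_path = run / "report.md"
    out_path.write_text("\n".join(lines))
    return out_path
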