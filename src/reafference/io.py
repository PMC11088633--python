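"""Serialization of trials, ground truth and fits (CSV + JSON)."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .synth import NeuronGroundTruth, PiecewiseChannel, Trial, TrialSet

SCHEMA_VERSION = 1

TRIAL_COLUMNS = ["t_ms", "head_pos_deg", "head_vel_dps", "head_acc_dps2",
                 "body_pos_deg", "body_vel_dps", "body_acc_dps2",
                 "passive_head_vel_dps", "active_head_vel_dps", "torque_Nm",
                 "rate_sps"]


def trialset_to_frame(ts: TrialSet) -> pd.DataFrame:
    """One row per sample, all trials stacked with a trial_id column."""
    frames = []
    for i, tr in enumerate(ts.trials):
        k = tr.kinematics
        frames.append(pd.DataFrame({
            "trial_id": i, "direction": tr.direction,
            "t_ms": k.t, "head_pos_deg": k.head_pos, "head_vel_dps": k.head_vel,
            "head_acc_dps2": k.head_acc, "body_pos_deg": k.body_pos,
            "body_vel_dps": k.body_vel, "body_acc_dps2": k.body_acc,
            "passive_head_vel_dps": k.passive_head_vel,
            "active_head_vel_dps": k.active_head_vel,
            "torque_Nm": tr.torque, "rate_sps": tr.rate,
        }))
    return pd.concat(frames, ignore_index=True)


def write_trialset(ts: TrialSet, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    trialset_to_frame(ts).to_csv(path, index=False)
    return path


def write_trials_index(entries: Sequence[dict], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(entries).to_csv(path, index=False)
    return path


def write_spikes(spike_times_by_trial: dict[int, np.ndarray],
                 path: str | Path) -> Path:
    rows = [{"trial_id": tid, "spike_ms": float(s)}
            for tid, times in spike_times_by_trial.items() for s in times]
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows, columns=["trial_id", "spike_ms"]).to_csv(path, index=False)
    return path


def _channel_dict(ch: PiecewiseChannel) -> dict:
    return {"c_pos": list(ch.c_pos), "c_vel": list(ch.c_vel),
            "c_acc": list(ch.c_acc)}


def neuron_to_dict(n: NeuronGroundTruth) -> dict:
    return {
        "neuron_id": n.neuron_id, "resting_rate": n.resting_rate,
        "vest": _channel_dict(n.vest), "neck": _channel_dict(n.neck),
        "cancellation_gain": n.cancellation_gain,
        "motor_lead_ms": n.motor_lead_ms, "modality": n.modality,
        "active_sign": n.active_sign, "type": n.type_label,
        "tuning": n.tuning, "motor_responsive": n.motor_responsive,
    }


def neuron_from_dict(d: dict) -> NeuronGroundTruth:
    def chan(c):
        return PiecewiseChannel(tuple(c["c_pos"]), tuple(c["c_vel"]),
                                tuple(c["c_acc"]))
    return NeuronGroundTruth(
        neuron_id=d["neuron_id"], resting_rate=d["resting_rate"],
        vest=chan(d["vest"]), neck=chan(d["neck"]),
        cancellation_gain=d["cancellation_gain"],
        motor_lead_ms=d["motor_lead_ms"], modality=d["modality"],
        active_sign=d["active_sign"], type_label=d["type"],
        tuning=d["tuning"], motor_responsive=d["motor_responsive"])


def write_population(neurons: Sequence[NeuronGroundTruth], path: str | Path,
                     *, seeds: dict | None = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {"schema_version": SCHEMA_VERSION, "seeds": seeds or {},
               "neurons": [neuron_to_dict(n) for n in neurons]}
    path.write_text(json.dumps(payload, indent=1, sort_keys=True))
    return path


def read_population(path: str | Path) -> list[NeuronGroundTruth]:
    payload = json.loads(Path(path).read_text())
    return [neuron_from_dict(d) for d in payload["neurons"]]


def _jsonable(obj):
    """Recursively convert numpy scalars/arrays; NaN/inf become null."""
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if np.isfinite(v) else None
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(_jsonable(obj), indent=1, sort_keys=True,
                               allow_nan=False))
    return path


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
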