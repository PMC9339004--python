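"""Reading and writing the pipeline's file formats.

Tables are CSV (one row per trial; per-neuron counts with one row per trial
and one column per 10-ms bin, ragged rows padded with blanks), fitted
objects are JSON, task/agent configuration is YAML, and an HDF5 container
is offered for spike counts as an alternative to per-neuron CSVs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import glm, synth
from .task import (
    N_EPOCHS,
    ShapeSet,
    StimulusEvent,
    TaskConfig,
    Trial,
    derive_stimulus_vars,
)

__all__ = [
    "SchemaError",
    "TRIAL_COLUMNS",
    "trials_to_frame",
    "frame_to_trials",
    "write_trials_csv",
    "read_trials_csv",
    "write_counts_csv",
    "read_counts_csv",
    "write_counts_h5",
    "read_counts_h5",
    "write_dataset",
    "read_dataset",
    "write_results",
    "load_task_yaml",
    "save_task_yaml",
    "write_manifest",
    "config_hash",
]


class SchemaError(ValueError):
    """A file does not match the expected schema."""


TRIAL_COLUMNS = (
    ["trial_id"]
    + [f"shape_{k}" for k in range(1, N_EPOCHS + 1)]
    + [f"color_{k}" for k in range(1, N_EPOCHS + 1)]
    + ["tin_color", "end_delay_ms", "choice", "chosen_color", "reward", "p_red", "p_green"]
)


def trials_to_frame(trials: Sequence[Trial]) -> pd.DataFrame:
    rows = []
    for t in trials:
        row = {"trial_id": t.trial_id}
        for s in t.stimuli:
            row[f"shape_{s.epoch}"] = s.shape_id
            row[f"color_{s.epoch}"] = s.color
        row.update(
            tin_color=t.tin_color,
            end_delay_ms=t.end_delay_ms,
            choice=t.choice if t.choice is not None else "",
            chosen_color=t.chosen_color if t.chosen_color is not None else "",
            reward=t.reward if t.reward is not None else "",
            p_red=t.p_red,
            p_green=t.p_green,
        )
        rows.append(row)
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def frame_to_trials(df: pd.DataFrame, task_config: Optional[TaskConfig] = None) -> List[Trial]:
    task_config = task_config or TaskConfig()
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"trial table is missing columns: {missing}")
    trials = []
    for i, row in df.iterrows():
        try:
            stimuli = tuple(
                StimulusEvent(
                    epoch=k,
                    shape_id=int(row[f"shape_{k}"]),
                    color=str(row[f"color_{k}"]),
                    onset_ms=task_config.stim_onset_ms(k),
                )
                for k in range(1, N_EPOCHS + 1)
            )

            def _opt(name):
                v = row[name]
                return None if (pd.isna(v) or v == "") else str(v)

            trials.append(
                Trial(
                    trial_id=int(row["trial_id"]),
                    stimuli=stimuli,
                    tin_color=str(row["tin_color"]),
                    end_delay_ms=int(row["end_delay_ms"]),
                    p_red=float(row["p_red"]),
                    p_green=float(row["p_green"]),
                    choice=_opt("choice"),
                    chosen_color=_opt("chosen_color"),
                    reward=_opt("reward"),
                )
            )
        except (ValueError, KeyError) as exc:
            raise SchemaError(f"trial table row {i}: {exc}") from exc
    return trials


def write_trials_csv(trials: Sequence[Trial], path) -> None:
    # %.17g keeps the probabilities exact under write -> read
    trials_to_frame(trials).to_csv(path, index=False, float_format="%.17g")


def read_trials_csv(path, task_config: Optional[TaskConfig] = None) -> List[Trial]:
    path = Path(path)
    try:
        df = pd.read_csv(
            path, keep_default_na=False, na_values=[""],
            float_precision="round_trip",
        )
    except OSError as exc:
        raise SchemaError(f"cannot read trial table {path}: {exc}") from exc
    return frame_to_trials(df, task_config)


def write_counts_csv(counts: Sequence[np.ndarray], path) -> None:
    """One row per trial, one column per bin; rows padded with blanks."""
    width = max(len(c) for c in counts)
    with open(path, "w") as fh:
        for c in counts:
            vals = [str(int(v)) for v in c]
            fh.write(",".join(vals + [""] * (width - len(vals))) + "\n")


def read_counts_csv(path) -> List[np.ndarray]:
    path = Path(path)
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh):
            fields = [f for f in line.strip().split(",") if f != ""]
            try:
                row = np.array([float(f) for f in fields])
            except ValueError as exc:
                raise SchemaError(f"{path} row {ln}: non-numeric count") from exc
            if np.any(row < 0):
                raise SchemaError(f"{path} row {ln}: negative count")
            if np.any(row != np.floor(row)):
                raise SchemaError(f"{path} row {ln}: non-integer count")
            out.append(row.astype(np.int64))
    if not out:
        raise SchemaError(f"{path}: empty counts file")
    return out


def write_counts_h5(counts_by_neuron: Sequence[Sequence[np.ndarray]], path) -> None:
    """Single container with datasets ``neuron_<id>/counts`` (ragged rows)."""
    import h5py

    with h5py.File(path, "w") as f:
        vlen = h5py.vlen_dtype(np.int64)
        for ni, per_trial in enumerate(counts_by_neuron):
            g = f.create_group(f"neuron_{ni:03d}")
            d = g.create_dataset("counts", (len(per_trial),), dtype=vlen)
            for ti, c in enumerate(per_trial):
                d[ti] = np.asarray(c, dtype=np.int64)


def read_counts_h5(path) -> List[List[np.ndarray]]:
    import h5py

    out = []
    with h5py.File(path, "r") as f:
        for name in sorted(f.keys()):
            d = f[name]["counts"]
            per_trial = [np.asarray(row, dtype=np.int64) for row in d]
            for ti, c in enumerate(per_trial):
                if np.any(c < 0):
                    raise SchemaError(f"{path} {name} trial {ti}: negative count")
            out.append(per_trial)
    return out


def write_dataset(ds: synth.SyntheticDataset, out_dir) -> Dict[str, str]:
    """Write a synthetic session: trial table, per-neuron count CSVs, and the
    ground-truth record. Returns the paths written."""
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        paths = {"trials": str(out / "trials.csv")}
        write_trials_csv(ds.trials, paths["trials"])
        for ni, per_trial in enumerate(ds.counts):
            p = out / f"neuron_{ni:03d}.csv"
            write_counts_csv(per_trial, p)
            paths[f"neuron_{ni:03d}"] = str(p)
        truth = {
            "master_seed": ds.master_seed,
            "agent": {
                "subjective_weights": list(ds.agent.subjective_weights),
                "bias": ds.agent.bias,
            },
            "shape_weights": list(ds.shape_set.weights),
            "neurons": [
                {
                    "template": s.template,
                    "baseline_log_rate": s.baseline_log_rate,
                    "variable_set": s.variable_set,
                    "kernels": {v: k.tolist() for v, k in s.kernels.items()},
                }
                for s in ds.neuron_specs
            ],
        }
        paths["ground_truth"] = str(out / "ground_truth.json")
        write_results(truth, paths["ground_truth"])
        return paths
    except OSError as exc:
        raise OSError(f"writing dataset under {out}: {exc}") from exc


def read_dataset(trials_path, counts_paths: Sequence, task_config=None):
    """Trial table plus per-neuron spike containers (CSV or HDF5)."""
    trials = read_trials_csv(trials_path, task_config)
    counts: List[List[np.ndarray]] = []
    for p in counts_paths:
        p = Path(p)
        if p.suffix in (".h5", ".hdf5"):
            counts.extend(read_counts_h5(p))
        else:
            counts.append(read_counts_csv(p))
    for ni, per_trial in enumerate(counts):
        if len(per_trial) != len(trials):
            raise SchemaError(
                f"neuron {ni} has {len(per_trial)} trials of counts; "
                f"trial table has {len(trials)}"
            )
    return trials, counts


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, (np.bool_,)):
            return bool(o)
        return super().default(o)


def write_results(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, cls=_NumpyEncoder, indent=2, sort_keys=True)
        fh.write("\n")


def save_task_yaml(shape_set: ShapeSet, task_config: TaskConfig, path) -> None:
    doc = {
        "shapes": {
            "weights": list(shape_set.weights),
            "subjective_weights": (
                list(shape_set.subjective_weights)
                if shape_set.subjective_weights is not None
                else None
            ),
        },
        "task": {
            "t_targets_ms": task_config.t_targets_ms,
            "t_first_stim_ms": task_config.t_first_stim_ms,
            "stim_on_ms": task_config.stim_on_ms,
            "stim_gap_ms": task_config.stim_gap_ms,
            "end_delay_choices_ms": list(task_config.end_delay_choices_ms),
            "reward_scheme": task_config.reward_scheme,
            "large_reward_ul": task_config.large_reward_ul,
            "small_reward_ul": task_config.small_reward_ul,
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_task_yaml(path):
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    try:
        shapes = doc["shapes"]
        ss = ShapeSet(
            tuple(shapes["weights"]),
            tuple(shapes["subjective_weights"]) if shapes.get("subjective_weights") else None,
        )
        t = doc["task"]
        tc = TaskConfig(
            t_targets_ms=t["t_targets_ms"],
            t_first_stim_ms=t["t_first_stim_ms"],
            stim_on_ms=t["stim_on_ms"],
            stim_gap_ms=t["stim_gap_ms"],
            end_delay_choices_ms=tuple(t["end_delay_choices_ms"]),
            reward_scheme=t.get("reward_scheme", "probabilistic"),
            large_reward_ul=t.get("large_reward_ul", 240.0),
            small_reward_ul=t.get("small_reward_ul", 60.0),
        )
    except (KeyError, TypeError) as exc:
        raise SchemaError(f"task YAML {path}: {exc}") from exc
    return ss, tc


def config_hash(obj) -> str:
    blob = json.dumps(obj, cls=_NumpyEncoder, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(path, seed, config: dict, inputs: Optional[Dict[str, str]] = None) -> None:
    """Run manifest written beside every command's outputs."""
    from . import __version__

    hashes = {}
    for name, p in (inputs or {}).items():
        p = Path(p)
        if p.exists():
            hashes[name] = hashlib.sha256(p.read_bytes()).hexdigest()[:16]
    write_results(
        {
            "seed": seed,
            "config": config,
            "config_hash": config_hash(config),
            "input_hashes": hashes,
            "version": __version__,
        },
        path,
    )
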