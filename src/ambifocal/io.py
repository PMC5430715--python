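"""Readers and writers: gaze traces (HDF5/TSV), event tables (TSV),
model parameters and configuration (YAML/JSON)."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .classify import LabeledFixation, SaccadeType, TypedSaccade
from .descriptive import ClassifiedTrial, RatioByOrderCurves
from .detection import FixationEvent, SaccadeEvent
from .model import SACCADE_TYPES, ModelParams
from .trace import GazeTrace

__all__ = [
    "write_trace",
    "read_trace",
    "write_events",
    "read_events",
    "write_ratio_curves",
    "read_ratio_curves",
    "save_params",
    "load_params",
]

EVENT_COLUMNS = [
    "trial_id", "event_type", "onset_s", "offset_s", "x_on", "y_on",
    "x_off", "y_off", "amplitude_deg", "duration_s", "order",
    "shortest_obj_dist_deg", "fix_kind", "fixated_object", "saccade_type",
]

_VALID_TYPES = set(SACCADE_TYPES) | {""}


def write_trace(trace: GazeTrace, path: str | Path) -> None:
    """Write a trace as HDF5 (.h5/.hdf5) or 3-column TSV with a metadata
    header, chosen by file extension."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            f.create_dataset("t", data=trace.t)
            f.create_dataset("x", data=trace.x)
            f.create_dataset("y", data=trace.y)
            f.attrs["sampling_rate"] = trace.sampling_rate
            f.attrs["stimulus_onset"] = trace.stimulus_onset
    else:
        with open(path, "w") as f:
            f.write(f"# sampling_rate: {trace.sampling_rate!r}\n")
            f.write(f"# stimulus_onset: {trace.stimulus_onset!r}\n")
            f.write("t\tx\ty\n")
            np.savetxt(f, np.column_stack([trace.t, trace.x, trace.y]),
                       delimiter="\t", fmt="%.9g")


def read_trace(path: str | Path) -> GazeTrace:
    """Read a trace written by :func:`write_trace`; validates metadata and
    uniform, strictly increasing time stamps."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            for key in ("sampling_rate", "stimulus_onset"):
                if key not in f.attrs:
                    raise ValueError(f"{path} is missing the {key!r} attribute")
            return GazeTrace(
                t=f["t"][:], x=f["x"][:], y=f["y"][:],
                sampling_rate=float(f.attrs["sampling_rate"]),
                stimulus_onset=float(f.attrs["stimulus_onset"]),
            )
    meta: dict[str, float] = {}
    with open(path) as f:
        pos = f.tell()
        line = f.readline()
        while line.startswith("#"):
            key, _, val = line[1:].partition(":")
            meta[key.strip()] = float(val)
            pos = f.tell()
            line = f.readline()
        f.seek(pos)
        data = pd.read_csv(f, sep="\t")
    for key in ("sampling_rate", "stimulus_onset"):
        if key not in meta:
            raise ValueError(f"{path} is missing {key!r} metadata")
    return GazeTrace(
        t=data["t"].to_numpy(), x=data["x"].to_numpy(), y=data["y"].to_numpy(),
        sampling_rate=meta["sampling_rate"], stimulus_onset=meta["stimulus_onset"],
    )


def events_to_frame(trials: list[ClassifiedTrial]) -> pd.DataFrame:
    rows = []
    for trial in trials:
        for fix in trial.fixations:
            rows.append({
                "trial_id": trial.trial_id,
                "event_type": "fixation",
                "onset_s": fix.base.onset,
                "offset_s": fix.base.offset,
                "x_on": fix.base.position[0],
                "y_on": fix.base.position[1],
                "x_off": fix.base.position[0],
                "y_off": fix.base.position[1],
                "amplitude_deg": np.nan,
                "duration_s": fix.base.duration,
                "order": fix.base.order_in_trial,
                "shortest_obj_dist_deg": fix.shortest_object_distance,
                "fix_kind": fix.kind,
                "fixated_object": "" if fix.fixated_object is None else fix.fixated_object,
                "saccade_type": "",
                "stimulus_onset": trial.stimulus_onset,
            })
        for sac in trial.saccades:
            rows.append({
                "trial_id": trial.trial_id,
                "event_type": "saccade",
                "onset_s": sac.base.onset,
                "offset_s": sac.base.offset,
                "x_on": sac.base.start_pos[0],
                "y_on": sac.base.start_pos[1],
                "x_off": sac.base.end_pos[0],
                "y_off": sac.base.end_pos[1],
                "amplitude_deg": sac.base.amplitude,
                "duration_s": sac.base.offset - sac.base.onset,
                "order": sac.base.order_in_trial,
                "shortest_obj_dist_deg": np.nan,
                "fix_kind": "",
                "fixated_object": "",
                "saccade_type": "" if sac.saccade_type is None else sac.saccade_type.value,
                "stimulus_onset": trial.stimulus_onset,
            })
    frame = pd.DataFrame(rows, columns=EVENT_COLUMNS + ["stimulus_onset"])
    return frame.sort_values(["trial_id", "onset_s"], kind="stable").reset_index(drop=True)


def write_events(trials: list[ClassifiedTrial], path: str | Path) -> None:
    """Write labelled events of one or more trials as a TSV table."""
    events_to_frame(trials).to_csv(path, sep="\t", index=False, float_format="%.9g")


def read_events(path: str | Path) -> list[ClassifiedTrial]:
    """Read a TSV event table back into classified trials.

    Unknown saccade-type values raise a schema error.  Object-distance
    vectors are not stored in the table, so they come back as a length-1
    array holding the shortest distance.
    """
    frame = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=["nan"])
    missing = set(EVENT_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"{path} is missing columns: {sorted(missing)}")
    bad = set(frame["saccade_type"].astype(str)) - _VALID_TYPES
    if bad:
        raise ValueError(f"{path} contains unknown saccade_type values: {sorted(bad)}")

    trials = []
    for trial_id, group in frame.groupby("trial_id", sort=True):
        fixations: list[LabeledFixation] = []
        saccades: list[TypedSaccade] = []
        for _, row in group.iterrows():
            if row["event_type"] == "fixation":
                base = FixationEvent(
                    onset=row["onset_s"], offset=row["offset_s"],
                    position=(row["x_on"], row["y_on"]),
                    duration=row["duration_s"], order_in_trial=int(row["order"]),
                )
                fixated = row["fixated_object"]
                fixations.append(LabeledFixation(
                    base=base,
                    object_distances=np.array([row["shortest_obj_dist_deg"]]),
                    shortest_object_distance=row["shortest_obj_dist_deg"],
                    kind=row["fix_kind"],
                    fixated_object=None if fixated == "" else int(fixated),
                ))
            elif row["event_type"] == "saccade":
                base = SaccadeEvent(
                    onset=row["onset_s"], offset=row["offset_s"],
                    start_pos=(row["x_on"], row["y_on"]),
                    end_pos=(row["x_off"], row["y_off"]),
                    amplitude=row["amplitude_deg"], peak_velocity=np.nan,
                    order_in_trial=int(row["order"]),
                )
                stype = row["saccade_type"]
                saccades.append(TypedSaccade(
                    base=base,
                    saccade_type=None if stype == "" else SaccadeType(stype),
                ))
            else:
                raise ValueError(f"unknown event_type {row['event_type']!r}")
        onset0 = group["stimulus_onset"].iloc[0] if "stimulus_onset" in group else 0.0
        trials.append(ClassifiedTrial(
            trial_id=int(trial_id), stimulus_onset=float(onset0),
            fixations=fixations, saccades=saccades,
        ))
    return trials


def write_ratio_curves(curves, path: str | Path) -> None:
    """Write per-order type curves (empirical or model) as TSV."""
    ratios = np.asarray(getattr(curves, "ratios", getattr(curves, "probs", curves)))
    frame = pd.DataFrame(ratios, columns=list(SACCADE_TYPES))
    frame.insert(0, "order", np.arange(1, len(frame) + 1))
    n = getattr(curves, "n_at_order", None)
    if n is not None:
        frame["n_at_order"] = n
    frame.to_csv(path, sep="\t", index=False, float_format="%.9g")


def read_ratio_curves(path: str | Path) -> RatioByOrderCurves:
    frame = pd.read_csv(path, sep="\t")
    ratios = frame[list(SACCADE_TYPES)].to_numpy(dtype=float)
    n = (
        frame["n_at_order"].to_numpy(dtype=int)
        if "n_at_order" in frame
        else np.full(len(frame), -1)
    )
    return RatioByOrderCurves(ratios=ratios, n_at_order=n)


def save_params(params: ModelParams, path: str | Path) -> None:
    """Serialize model parameters as YAML (.yml/.yaml) or JSON."""
    payload = dataclasses.asdict(params)
    path = Path(path)
    if path.suffix in (".yml", ".yaml"):
        path.write_text(yaml.safe_dump(payload, sort_keys=False))
    else:
        path.write_text(json.dumps(payload, indent=2) + "\n")


def load_params(path: str | Path) -> ModelParams:
    path = Path(path)
    text = path.read_text()
    payload = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") else json.loads(text)
    known = {f.name for f in dataclasses.fields(ModelParams)}
    unknown = set(payload) - known
    if unknown:
        raise ValueError(f"{path} contains unknown parameter keys: {sorted(unknown)}")
    return ModelParams(**payload)
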