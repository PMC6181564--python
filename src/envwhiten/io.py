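"""Plain-text readers/writers for stimuli, spike trains, traces and tables.

Stimuli travel as 2-column CSV (time_s, value) with a JSON sidecar holding
the StimulusSpec; spike trains as one ascending spike time (seconds) per
line; EOD/behavior traces as CSV; tuning and whitening results as tidy CSV
plus a JSON summary.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .behavior import BehaviorTrace
from .spikes import SpikeTrain
from .synthetic import StimulusSet, StimulusSpec

__all__ = [
    "write_stimulus", "read_stimulus",
    "write_spike_train", "read_spike_train",
    "write_behavior_trace", "read_behavior_trace",
    "write_tidy_table", "write_json_summary",
]


def _spec_to_jsonable(spec: StimulusSpec) -> dict:
    d = dataclasses.asdict(spec)
    d["natural_band"] = list(d["natural_band"])
    return d


def write_stimulus(stim: StimulusSet, path) -> Path:
    """Write a stimulus as CSV plus a ``<stem>.spec.json`` sidecar."""
    path = Path(path)
    pd.DataFrame({"time_s": stim.time, "am": stim.am,
                  "envelope": stim.envelope}).to_csv(path, index=False)
    sidecar = path.with_suffix(".spec.json")
    sidecar.write_text(json.dumps(_spec_to_jsonable(stim.spec), indent=1))
    return path


def read_stimulus(path) -> StimulusSet:
    path = Path(path)
    df = pd.read_csv(path)
    raw = json.loads(path.with_suffix(".spec.json").read_text())
    raw["natural_band"] = tuple(raw["natural_band"])
    spec = StimulusSpec(**raw)
    return StimulusSet(time=df["time_s"].to_numpy(), am=df["am"].to_numpy(),
                       envelope=df["envelope"].to_numpy(), spec=spec)


def write_spike_train(spikes: SpikeTrain, path) -> Path:
    """One spike time (s) per line; duration recorded on a header comment."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# duration_s={float(spikes.duration)!r}\n")
        for t in spikes.times:
            fh.write(f"{float(t)!r}\n")
    return path


def read_spike_train(path) -> SpikeTrain:
    path = Path(path)
    duration = None
    times = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            key, _, val = line.lstrip("# ").partition("=")
            if key == "duration_s":
                duration = float(val)
            continue
        times.append(float(line))
    if duration is None:
        duration = times[-1] + 1e-9 if times else 1.0
    return SpikeTrain(times=np.asarray(times), duration=duration)


def write_behavior_trace(trace: BehaviorTrace, path) -> Path:
    path = Path(path)
    pd.DataFrame({"time_s": trace.time,
                  "eod_frequency_hz": trace.eod_frequency}).to_csv(path,
                                                                   index=False)
    meta = {"sample_rate": trace.sample_rate,
            "lowpass_cutoff": trace.lowpass_cutoff}
    path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=1))
    return path


def read_behavior_trace(path) -> BehaviorTrace:
    path = Path(path)
    df = pd.read_csv(path)
    meta = json.loads(path.with_suffix(".meta.json").read_text())
    return BehaviorTrace(time=df["time_s"].to_numpy(),
                         eod_frequency=df["eod_frequency_hz"].to_numpy(),
                         sample_rate=meta["sample_rate"],
                         lowpass_cutoff=meta["lowpass_cutoff"])


def write_tidy_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def write_json_summary(obj: dict, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def _default(x):
        if isinstance(x, (np.floating, np.integer)):
            return x.item()
        if isinstance(x, np.ndarray):
            return x.tolist()
        raise TypeError(f"not JSON serializable: {type(x)}")

    path.write_text(json.dumps(obj, indent=1, default=_default))
    return path
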