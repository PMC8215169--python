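"""Session persistence and structured logs.

Raw sessions round-trip through HDF5 (`/baseline/segment_i`,
`/run_k/trial_j/segment_i` datasets with label/artifact attributes);
replay results export the gate log as JSONL and the frame history as CSV
(point_id, class, x, y, frame_index).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List

import h5py
import numpy as np
import pandas as pd

from .engine import SessionResult
from .geometry import EEGSegment
from .synth import GeneratorConfig, Run, Session, Trial

__all__ = [
    "save_session_hdf5",
    "load_session_hdf5",
    "events_to_jsonl",
    "frames_to_csv",
]


def save_session_hdf5(session: Session, path: str | Path) -> None:
    cfg = session.config
    with h5py.File(path, "w") as f:
        f.attrs["fs"] = cfg.fs
        f.attrs["channels"] = json.dumps(cfg.channel_names)
        f.attrs["config"] = json.dumps(
            {k: v for k, v in cfg.__dict__.items() if k != "channel_names"}
        )
        g = f.create_group("baseline")
        for i, seg in enumerate(session.baseline):
            d = g.create_dataset(f"segment_{i:03d}", data=seg.samples,
                                 track_times=False)
            d.attrs["label"] = seg.label
            d.attrs["artifact"] = bool(seg.is_artifact)
        for run in session.runs:
            gr = f.create_group(f"run_{run.run_id:02d}")
            for j, trial in enumerate(run.trials):
                gt = gr.create_group(f"trial_{j:02d}")
                gt.attrs["label"] = trial.label
                for k, seg in enumerate(trial.segments):
                    d = gt.create_dataset(f"segment_{k}", data=seg.samples,
                                          track_times=False)
                    d.attrs["label"] = seg.label
                    d.attrs["artifact"] = bool(seg.is_artifact)


def load_session_hdf5(path: str | Path) -> Session:
    with h5py.File(path, "r") as f:
        cfg_dict = json.loads(f.attrs["config"])
        cfg_dict["channel_names"] = json.loads(f.attrs["channels"])
        cfg = GeneratorConfig(**cfg_dict)
        baseline: List[EEGSegment] = []
        g = f["baseline"]
        for name in sorted(g):
            d = g[name]
            baseline.append(
                EEGSegment(samples=d[()], fs=cfg.fs, label=d.attrs["label"],
                           run_id=-1, trial_id=-1,
                           segment_index=len(baseline),
                           is_artifact=bool(d.attrs["artifact"]))
            )
        runs: List[Run] = []
        for rname in sorted(n for n in f if n.startswith("run_")):
            rid = int(rname.split("_")[1])
            trials: List[Trial] = []
            gr = f[rname]
            for tname in sorted(gr):
                tid = int(tname.split("_")[1])
                gt = gr[tname]
                segs = []
                for sname in sorted(gt):
                    d = gt[sname]
                    sid = int(sname.split("_")[1])
                    segs.append(
                        EEGSegment(samples=d[()], fs=cfg.fs,
                                   label=d.attrs["label"], run_id=rid,
                                   trial_id=tid, segment_index=sid,
                                   is_artifact=bool(d.attrs["artifact"]))
                    )
                trials.append(Trial(label=gt.attrs["label"], segments=segs))
            runs.append(Run(run_id=rid, trials=trials))
    return Session(config=cfg, baseline=baseline, runs=runs)


def events_to_jsonl(result: SessionResult, path: str | Path) -> None:
    """Gate decisions as one JSON object per line (machine-parseable log)."""
    with open(path, "w") as fh:
        for ev in result.events:
            fh.write(json.dumps(ev, sort_keys=True) + "\n")


def frames_to_csv(result: SessionResult, path: str | Path) -> pd.DataFrame:
    """Frame history as tidy CSV: run, frame_index, point_id, class, x, y."""
    rows = []
    for run in result.runs:
        label_of = {rec["point_id"]: rec["label"] for rec in run.records}
        for frame in run.frames:
            for pid, (x, y) in zip(frame.point_ids, frame.coordinates):
                cls = label_of.get(pid, pid.split(":")[-1] if ":" in pid else "")
                rows.append(
                    {"run": run.run_id, "frame_index": frame.frame_index,
                     "point_id": pid, "class": cls,
                     "x": x, "y": y, "warm_up": frame.warm_up}
                )
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False, float_format="%.10g")
    return df
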