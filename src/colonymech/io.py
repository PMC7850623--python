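"""File formats: mesh/trajectory JSON, tracked-cell CSV, YAML configs.

The tracked-cell table is the exchange format between the simulator and
the kinematics pipeline (and the target schema for converted Tissue
Analyzer / Tissue Miner exports): delimited text with columns

    frame, time, cell_id, x, y, neighbor_ids, tag

where ``neighbor_ids`` is a semicolon-joined id list and ``tag`` is one of
``none``, ``divided:<mother_id>`` or ``extruded``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .kinematics import Frame, TrackedFrames
from .mesh import TissueMesh

SCHEMA_VERSION = 1


def mesh_to_dict(mesh: TissueMesh, polarity=None, params=None, events=None) -> dict:
    d = {
        "schema_version": SCHEMA_VERSION,
        "time": mesh.time,
        "vertices": mesh.vertices.tolist(),
        "cells": [list(map(int, loop)) for loop in mesh.cells],
        "preferred_areas": mesh.preferred_areas.tolist(),
    }
    if polarity is not None:
        d["polarity_angles"] = np.asarray(polarity.angles).tolist()
    if params is not None:
        d["params"] = params.to_dict()
    if events is not None:
        d["t1_events"] = [
            {
                "time": e.time,
                "cells": list(e.cells),
                "pre_length": e.pre_length,
                "vertices": list(e.vertices),
            }
            for e in events
        ]
    return d


def save_mesh(path, mesh: TissueMesh, polarity=None, params=None, events=None) -> None:
    Path(path).write_text(json.dumps(mesh_to_dict(mesh, polarity, params, events)))


def load_mesh(path) -> TissueMesh:
    d = json.loads(Path(path).read_text())
    mesh = TissueMesh(
        np.array(d["vertices"]),
        [np.array(c, dtype=np.int64) for c in d["cells"]],
        preferred_areas=np.array(d["preferred_areas"]),
        time=d["time"],
    )
    return mesh


def tracked_frames_to_df(frames: TrackedFrames) -> pd.DataFrame:
    rows = []
    for k, (t, f) in enumerate(zip(frames.times, frames.frames)):
        for idx, cid in enumerate(f.ids):
            cid = int(cid)
            rows.append(
                {
                    "frame": k,
                    "time": t,
                    "cell_id": cid,
                    "x": f.positions[idx, 0],
                    "y": f.positions[idx, 1],
                    "neighbor_ids": ";".join(
                        str(n) for n in sorted(f.neighbors.get(cid, set()))
                    ),
                    "tag": f.tags.get(cid, "none"),
                }
            )
    return pd.DataFrame(rows)


def save_tracked_frames(path, frames: TrackedFrames) -> None:
    tracked_frames_to_df(frames).to_csv(path, index=False)


def tracked_frames_from_df(df: pd.DataFrame) -> TrackedFrames:
    times, frame_objs = [], []
    for k, sub in df.groupby("frame"):
        ids = sub["cell_id"].to_numpy(dtype=np.int64)
        pos = sub[["x", "y"]].to_numpy(dtype=float)
        neigh = {}
        tags = {}
        for _, row in sub.iterrows():
            cid = int(row["cell_id"])
            raw = row["neighbor_ids"]
            neigh[cid] = (
                {int(s) for s in str(raw).split(";") if s not in ("", "nan")}
                if pd.notna(raw)
                else set()
            )
            tag = row.get("tag", "none")
            if isinstance(tag, str) and tag != "none":
                tags[cid] = tag
        times.append(float(sub["time"].iloc[0]))
        frame_objs.append(Frame(ids=ids, positions=pos, neighbors=neigh, tags=tags))
    return TrackedFrames(times=np.array(times), frames=frame_objs)


def load_tracked_frames(path) -> TrackedFrames:
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - message formatting only
        raise ValueError(f"cannot parse tracked-cell CSV {path}: {exc}") from exc
    required = {"frame", "cell_id", "x", "y", "neighbor_ids"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if "time" not in df.columns:
        df["time"] = df["frame"].astype(float)
    return tracked_frames_from_df(df)


def convert_neighbor_changes_to_t1_tags(frames: TrackedFrames) -> TrackedFrames:
    """Converter stub for TA/TM-style exports without explicit event tags.

    Neighbour-list changes between persisting cells are T1s by exclusion
    and need no tag; cells that appear or disappear without a lineage tag
    are left untagged, which the shear decomposition reports and folds into
    the correlation closure.
    """
    return frames


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def save_config(path, config: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
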