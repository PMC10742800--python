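"""Reading and writing trajectories, events and result tables.

Trajectories travel as comma-delimited text with a header
(``frame,fish_id,x_m,y_m`` by default; a column mapping adapts other
exports).  Events are JSON.  Read/write round-trips are lossless.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ArenaConfig
from .errors import DataError, FormatError
from .events import TurnEvent
from .trajectory import Trajectory

__all__ = [
    "read_trajectories",
    "write_trajectories",
    "write_events",
    "read_events",
]

DEFAULT_COLUMNS = {"frame": "frame", "fish_id": "fish_id", "x": "x_m", "y": "y_m"}


def read_trajectories(
    path: str | Path,
    arena: ArenaConfig | None = None,
    columns: dict | None = None,
) -> tuple[Trajectory, Trajectory]:
    """Read a two-fish trajectory file.

    Parameters
    ----------
    path : path
        Delimited-text file with columns frame, fish_id, x, y (header
        names configurable through ``columns``).
    arena : ArenaConfig, optional
        Supplies the sampling rate; defaults to the standard arena.
    columns : dict, optional
        Mapping from logical names (``frame``, ``fish_id``, ``x``, ``y``)
        to the column names used in the file.

    Returns
    -------
    (Trajectory, Trajectory)
        One trajectory per fish, both restricted to the intersection of
        their frame ranges and ordered by fish id.

    Raises
    ------
    FormatError
        If a required column is missing.
    DataError
        If there are not exactly two fish ids, a coordinate is not
        finite, or frames are non-monotone.
    """
    arena = arena or ArenaConfig()
    cols = {**DEFAULT_COLUMNS, **(columns or {})}
    df = pd.read_csv(path)
    missing = [c for c in cols.values() if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    df = df.rename(columns={v: k for k, v in cols.items()})

    ids = sorted(df["fish_id"].astype(str).unique())
    if len(ids) != 2:
        raise DataError(f"{path}: expected exactly 2 fish ids, found {ids}")

    bad = df[~np.isfinite(df["x"]) | ~np.isfinite(df["y"])]
    if len(bad):
        where = ", ".join(
            f"frame {int(r.frame)} fish {r.fish_id}" for r in bad.head(5).itertuples())
        raise DataError(f"{path}: non-finite coordinates ({where})")

    trajs = []
    per_fish = {fid: df[df["fish_id"].astype(str) == fid] for fid in ids}
    common = np.intersect1d(
        per_fish[ids[0]]["frame"].to_numpy(), per_fish[ids[1]]["frame"].to_numpy())
    for fid in ids:
        sub = per_fish[fid]
        frames = sub["frame"].to_numpy(dtype=np.int64)
        if np.any(np.diff(frames) <= 0):
            raise DataError(f"{path}: non-monotone frames for fish {fid}")
        keep = np.isin(frames, common)
        trajs.append(Trajectory(
            fish_id=fid,
            frames=frames[keep],
            xy=sub[["x", "y"]].to_numpy(dtype=np.float64)[keep],
            fs=arena.fs,
        ))
    return trajs[0], trajs[1]


def write_trajectories(
    trajs: tuple[Trajectory, Trajectory] | list,
    path: str | Path,
    columns: dict | None = None,
) -> None:
    """Write trajectories as delimited text (inverse of :func:`read_trajectories`)."""
    cols = {**DEFAULT_COLUMNS, **(columns or {})}
    parts = []
    for traj in trajs:
        parts.append(pd.DataFrame({
            cols["frame"]: traj.frames,
            cols["fish_id"]: traj.fish_id,
            cols["x"]: traj.xy[:, 0],
            cols["y"]: traj.xy[:, 1],
        }))
    out = pd.concat(parts).sort_values([cols["frame"], cols["fish_id"]])
    out.to_csv(path, index=False)


def write_events(events: list[TurnEvent], path: str | Path) -> None:
    """Write a list of turn events to a JSON file (order preserved)."""
    payload = [ev.to_dict() for ev in events]
    Path(path).write_text(json.dumps(payload, indent=1))


def read_events(path: str | Path) -> list[TurnEvent]:
    """Read back a JSON event file written by :func:`write_events`."""
    payload = json.loads(Path(path).read_text())
    return [TurnEvent.from_dict(d) for d in payload]
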