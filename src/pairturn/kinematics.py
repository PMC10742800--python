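"""Per-frame kinematic and geometric state parameters of a fish pair.

Given smoothed, frame-aligned trajectories of two fish in the annular
arena this module computes, per frame:

* heading(t) = c(t) - c(t-1) and its change dheading(t), where c(t) is
  the position vector from the tank centre;
* speed = |heading| * fs (the inter-frame path is treated as linear);
* Roa, the position rotation angle: the signed angle between c(t) and
  the +x axis, range (-pi, pi], counterclockwise positive, plus its
  unwrapped (continuous) version whose slope encodes swim direction;
* ald, the alignment degree: |sin(theta)| of the angle theta between
  heading and the radial vector -- 1 when swimming along the wall,
  0 when heading straight at it;
* Wdis, the shortest wall distance in body lengths;
* Fdis, the inter-individual distance in body lengths;
* Rpa, the relative position angle: the angle at the follower between
  its heading and the bearing to the leader, range [0, pi];
* Los, the line-of-sight angle: the angular size of the leader
  (eye to tail) in the follower's visual field;
* the leader identity under the position-rotation-angle rule: when the
  pair swims counterclockwise the fish with the larger unwrapped Roa
  leads; clockwise, the smaller.

The ten-channel multivariate series fed to time-series clustering uses
the frozen channel order of :data:`CHANNELS`; Los and the leader
identity ride along as auxiliaries and are not clustered.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ArenaConfig
from .errors import TooShortError, UndefinedAngleError
from .trajectory import Trajectory

__all__ = [
    "CHANNELS",
    "FishKinematics",
    "PairStateSeries",
    "compute_heading",
    "compute_roa",
    "unwrap_roa",
    "compute_fdis",
    "compute_wdis",
    "compute_ald",
    "compute_rpa",
    "estimate_eye_tail",
    "compute_los",
    "assign_leader",
    "compute_fish_kinematics",
    "build_pair_state_series",
]

#: Frozen channel order of the pair state series.  Downstream centrality
#: tables and cluster compositions depend on these indices.
CHANNELS = (
    "Fdis",       # 1  inter-individual distance [BL]
    "Wldis",      # 2  leader wall distance [BL]
    "Wfdis",      # 3  follower wall distance [BL]
    "Rpa",        # 4  relative position angle [rad]
    "Lald",       # 5  leader alignment degree [-]
    "Fald",       # 6  follower alignment degree [-]
    "Lspeed",     # 7  leader speed [m/s]
    "Fspeed",     # 8  follower speed [m/s]
    "DlHeading",  # 9  |leader heading change| [m]
    "DfHeading",  # 10 |follower heading change| [m]
)


# ---------------------------------------------------------------------------
# elementary constructions


def compute_heading(traj: Trajectory) -> tuple[np.ndarray, np.ndarray]:
    """Displacement-based heading and heading-change vectors.

    Returns
    -------
    heading : ndarray (n, 2)
        heading[t] = c[t] - c[t-1]; heading[0] is undefined and copies
        heading[1].  Zero-displacement frames keep magnitude 0 (the
        direction carried for unit-vector uses is handled downstream).
    dheading : ndarray (n, 2)
        dheading[t] = heading[t] - heading[t-1]; entries 0 and 1 copy
        dheading[2].
    """
    if len(traj) < 3:
        raise TooShortError("need at least 3 frames for heading/dheading")
    xy = traj.xy
    heading = np.empty_like(xy)
    heading[1:] = xy[1:] - xy[:-1]
    heading[0] = heading[1]
    dheading = np.empty_like(xy)
    dheading[2:] = heading[2:] - heading[1:-1]
    dheading[:2] = dheading[2]
    return heading, dheading


def compute_roa(pos: np.ndarray) -> np.ndarray:
    """Position rotation angle: signed angle of c(t) against +x, in (-pi, pi].

    Increases while the fish swims counterclockwise and wraps when the
    trajectory crosses the branch cut of the angle range.
    """
    pos = np.asarray(pos, dtype=np.float64)
    r = np.hypot(*(pos.T if pos.ndim == 2 else pos))
    if np.any(r == 0):
        raise UndefinedAngleError("Roa undefined at the tank centre")
    if pos.ndim == 1:
        return float(np.arctan2(pos[1], pos[0]))
    return np.arctan2(pos[:, 1], pos[:, 0])


def unwrap_roa(roa: np.ndarray) -> np.ndarray:
    """Remove the +-2*pi jumps of a wrapped Roa series.

    The slope of the result has the sign of the swim direction.  At 50 Hz
    successive angular steps are far below pi, so unwrapping is exact; a
    post-unwrap step of magnitude >= pi indicates undersampling and
    raises a warning.
    """
    out = np.unwrap(np.asarray(roa, dtype=np.float64))
    if len(out) > 1 and np.any(np.abs(np.diff(out)) >= np.pi):
        import warnings

        warnings.warn("angular step >= pi after unwrap; sampling too sparse",
                      stacklevel=2)
    return out


def compute_fdis(pos_l: np.ndarray, pos_f: np.ndarray, body_length: float) -> np.ndarray:
    """Inter-individual distance in body lengths."""
    d = np.linalg.norm(np.asarray(pos_l) - np.asarray(pos_f), axis=-1)
    return d / body_length


def compute_wdis(pos: np.ndarray, arena: ArenaConfig) -> np.ndarray:
    """Shortest wall distance in body lengths, clamped at 0 outside the annulus."""
    pos = np.asarray(pos, dtype=np.float64)
    rho = np.hypot(*(pos.T if pos.ndim == 2 else pos))
    w = np.minimum(rho - arena.inner_radius, arena.outer_radius - rho)
    if np.any(w < 0):
        import warnings

        warnings.warn("position outside the annulus; wall distance clamped at 0",
                      stacklevel=2)
        w = np.maximum(w, 0.0)
    return w / arena.body_length


def compute_ald(pos: np.ndarray, heading: np.ndarray) -> np.ndarray:
    """Alignment degree: |sin| of the angle between heading and the radial vector.

    1 means tangential (wall-aligned) motion, 0 means heading straight
    at (or away from) a wall.  Zero-heading frames are returned as NaN;
    the series builder carries the previous value.
    """
    pos = np.atleast_2d(np.asarray(pos, dtype=np.float64))
    heading = np.atleast_2d(np.asarray(heading, dtype=np.float64))
    cross = pos[:, 0] * heading[:, 1] - pos[:, 1] * heading[:, 0]
    norm = np.linalg.norm(pos, axis=1) * np.linalg.norm(heading, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ald = np.abs(cross) / norm
    ald = np.where(norm == 0, np.nan, ald)
    ald = np.clip(ald, 0.0, 1.0)
    return ald[0] if ald.shape == (1,) else ald


def _angle_between(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Unsigned angle between row vectors, in [0, pi], via atan2 (stable near 0/pi)."""
    cross = u[:, 0] * v[:, 1] - u[:, 1] * v[:, 0]
    dot = np.einsum("ij,ij->i", u, v)
    return np.arctan2(np.abs(cross), dot)


def compute_rpa(pos_l: np.ndarray, pos_f: np.ndarray, heading_f: np.ndarray) -> np.ndarray:
    """Relative position angle: angle between (Lc - Fc) and the follower heading."""
    scalar = np.asarray(pos_l).ndim == 1
    pos_l = np.atleast_2d(np.asarray(pos_l, dtype=np.float64))
    pos_f = np.atleast_2d(np.asarray(pos_f, dtype=np.float64))
    heading_f = np.atleast_2d(np.asarray(heading_f, dtype=np.float64))
    bearing = pos_l - pos_f
    if np.any(np.linalg.norm(bearing, axis=1) == 0):
        raise UndefinedAngleError("Rpa undefined for coincident positions")
    if np.any(np.linalg.norm(heading_f, axis=1) == 0):
        raise UndefinedAngleError("Rpa undefined for zero follower heading")
    ang = _angle_between(bearing, heading_f)
    return float(ang[0]) if scalar else ang


def estimate_eye_tail(
    pos: np.ndarray, heading: np.ndarray, body_length: float
) -> tuple[np.ndarray, np.ndarray]:
    """Eye and tail points at +-BL/2 along the unit heading.

    The fish is treated as a rigid rod of length BL centred on the
    tracked position; the eye sits at the top of the head.
    """
    pos = np.atleast_2d(np.asarray(pos, dtype=np.float64))
    heading = np.atleast_2d(np.asarray(heading, dtype=np.float64))
    norm = np.linalg.norm(heading, axis=1, keepdims=True)
    if np.any(norm == 0):
        raise UndefinedAngleError("eye/tail undefined for zero heading")
    unit = heading / norm
    eye = pos + 0.5 * body_length * unit
    tail = pos - 0.5 * body_length * unit
    if eye.shape[0] == 1:
        return eye[0], tail[0]
    return eye, tail


def compute_los(eye_l: np.ndarray, tail_l: np.ndarray, eye_f: np.ndarray) -> np.ndarray:
    """Line-of-sight angle: angular size of the leader in the follower's view.

    The unsigned angle between (Le - Fe) and (Lt - Fe), in [0, pi].
    """
    eye_l = np.atleast_2d(np.asarray(eye_l, dtype=np.float64))
    tail_l = np.atleast_2d(np.asarray(tail_l, dtype=np.float64))
    eye_f = np.atleast_2d(np.asarray(eye_f, dtype=np.float64))
    u = eye_l - eye_f
    v = tail_l - eye_f
    if np.any(np.linalg.norm(u, axis=1) == 0) or np.any(np.linalg.norm(v, axis=1) == 0):
        raise UndefinedAngleError("Los undefined: follower eye coincides with leader")
    ang = _angle_between(u, v)
    return float(ang[0]) if len(ang) == 1 else ang


def assign_leader(
    roa_u_a: np.ndarray,
    roa_u_b: np.ndarray,
    direction: np.ndarray,
    ids: tuple[str, str] = ("A", "B"),
) -> np.ndarray:
    """Per-frame leader identity from unwrapped Roa and swim direction.

    Counterclockwise (direction +1): the fish with the larger unwrapped
    Roa leads; clockwise (-1): the smaller.  Exact ties carry the
    previous frame's leader (the first frame of a tie run defaults to
    the first id).
    """
    roa_u_a = np.atleast_1d(np.asarray(roa_u_a, dtype=np.float64))
    roa_u_b = np.atleast_1d(np.asarray(roa_u_b, dtype=np.float64))
    direction = np.atleast_1d(np.asarray(direction, dtype=np.float64))
    delta = (roa_u_a - roa_u_b) * np.sign(direction)
    leader = np.empty(len(delta), dtype=object)
    prev = ids[0]
    for i, d in enumerate(delta):
        if d > 0:
            prev = ids[0]
        elif d < 0:
            prev = ids[1]
        leader[i] = prev
    return leader


# ---------------------------------------------------------------------------
# per-fish bundle


@dataclass
class FishKinematics:
    """All per-frame kinematic quantities of one fish."""

    fish_id: str
    heading: np.ndarray        # (n, 2) m
    dheading: np.ndarray       # (n, 2) m
    speed: np.ndarray          # (n,) m/s
    roa: np.ndarray            # (n,) rad, wrapped to (-pi, pi]
    roa_unwrapped: np.ndarray  # (n,) rad, continuous
    ald: np.ndarray            # (n,) in [0, 1]
    wdis: np.ndarray           # (n,) body lengths
    eye: np.ndarray            # (n, 2) m
    tail: np.ndarray           # (n, 2) m


def _carry_heading_direction(heading: np.ndarray) -> np.ndarray:
    """Unit heading directions with zero-displacement frames carrying the
    last nonzero direction (first frames fall back to the first nonzero)."""
    norm = np.linalg.norm(heading, axis=1)
    unit = np.zeros_like(heading)
    nz = norm > 0
    unit[nz] = heading[nz] / norm[nz, None]
    if not nz.all():
        idx = np.where(nz, np.arange(len(norm)), -1)
        idx = np.maximum.accumulate(idx)
        first = np.argmax(nz) if nz.any() else -1
        if first == -1:
            raise UndefinedAngleError("trajectory never moves; headings undefined")
        idx[idx < 0] = first
        unit = unit[idx]
    return unit


def compute_fish_kinematics(traj: Trajectory, arena: ArenaConfig) -> FishKinematics:
    """Compute the full per-fish kinematic bundle from a smoothed trajectory."""
    heading, dheading = compute_heading(traj)
    unit = _carry_heading_direction(heading)
    speed = np.linalg.norm(heading, axis=1) * arena.fs
    roa = compute_roa(traj.xy)
    roa_u = unwrap_roa(roa)
    # ald with the carried direction at zero-displacement frames
    ald = compute_ald(traj.xy, unit)
    wdis = compute_wdis(traj.xy, arena)
    eye = traj.xy + 0.5 * arena.body_length * unit
    tail = traj.xy - 0.5 * arena.body_length * unit
    return FishKinematics(
        fish_id=traj.fish_id, heading=heading, dheading=dheading, speed=speed,
        roa=roa, roa_unwrapped=roa_u, ald=ald, wdis=wdis, eye=eye, tail=tail)


# ---------------------------------------------------------------------------
# pair state series


@dataclass
class PairStateSeries:
    """The ten-channel multivariate state series of a fish pair.

    Attributes
    ----------
    frames : ndarray (n,)
        Frame indices (the first two frames of the recording are dropped
        because heading changes are undefined there).
    data : DataFrame (n, 10)
        Channels in the frozen :data:`CHANNELS` order.
    leader : ndarray (n,) of str
        Leader identity per frame.
    direction : ndarray (n,)
        Group swim direction sign per frame (+1 ccw, -1 cw).
    los : ndarray (n,)
        Line-of-sight angle (auxiliary; not clustered).
    ald : dict of str -> ndarray (n,)
        Per-fish alignment degree, aligned with ``frames``.
    roa : dict of str -> ndarray (n,)
        Per-fish wrapped position rotation angle, aligned with ``frames``.
    arena : ArenaConfig
    fish_ids : tuple of str
    """

    frames: np.ndarray
    data: pd.DataFrame
    leader: np.ndarray
    direction: np.ndarray
    los: np.ndarray
    ald: dict
    roa: dict
    arena: ArenaConfig
    fish_ids: tuple

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def values(self) -> np.ndarray:
        """(n, 10) channel matrix in frozen order."""
        return self.data.to_numpy()

    def ald_of(self, fish_id: str) -> np.ndarray:
        """Alignment-degree series of one fish, aligned with ``frames``."""
        return self.ald[fish_id]

    def window(self, lo: int, hi: int) -> "PairStateSeries":
        """Slice to frames in [lo, hi] (inclusive; clipped to the record)."""
        mask = (self.frames >= lo) & (self.frames <= hi)
        return PairStateSeries(
            frames=self.frames[mask], data=self.data.iloc[mask].reset_index(drop=True),
            leader=self.leader[mask], direction=self.direction[mask],
            los=self.los[mask],
            ald={fid: a[mask] for fid, a in self.ald.items()},
            roa={fid: r[mask] for fid, r in self.roa.items()},
            arena=self.arena, fish_ids=self.fish_ids)

    def to_csv(self, path) -> None:
        """Write the channel series (plus frame, leader, direction, Los) as CSV."""
        out = self.data.copy()
        out.insert(0, "frame", self.frames)
        out["leader"] = self.leader
        out["direction"] = self.direction
        out["Los"] = self.los
        out.to_csv(path, index=False)


def _interpolate_nans(x: np.ndarray) -> tuple[np.ndarray, bool]:
    """Linearly interpolate interior NaNs (edge NaNs take nearest value)."""
    x = x.astype(np.float64, copy=True)
    bad = ~np.isfinite(x)
    if not bad.any():
        return x, False
    good = np.where(~bad)[0]
    if len(good) == 0:
        raise UndefinedAngleError("channel is entirely undefined")
    x[bad] = np.interp(np.where(bad)[0], good, x[good])
    return x, True


def build_pair_state_series(
    traj_a: Trajectory,
    traj_b: Trajectory,
    arena: ArenaConfig,
    direction_window_s: float = 0.5,
) -> PairStateSeries:
    """Assemble the ten-channel pair state series from aligned trajectories.

    The group swim direction at frame t is the sign of the mean unwrapped
    Roa increment of the pair over a trailing window
    (``direction_window_s``); leader and follower roles are resolved per
    frame with the position-rotation-angle rule.  Frames with degenerate
    geometry (zero heading) are interpolated and flagged with a warning
    by the underlying operations.
    """
    if len(traj_a) != len(traj_b) or np.any(traj_a.frames != traj_b.frames):
        raise ValueError("trajectories must be frame-aligned; intersect them first")
    if len(traj_a) < max(5, int(direction_window_s * arena.fs) + 3):
        raise TooShortError("recording too short for a pair state series")

    kin = {
        traj_a.fish_id: compute_fish_kinematics(traj_a, arena),
        traj_b.fish_id: compute_fish_kinematics(traj_b, arena),
    }
    ka, kb = kin[traj_a.fish_id], kin[traj_b.fish_id]
    n = len(traj_a)

    # each unwrapped series starts from its own wrapped value, so the two
    # fish can differ by a spurious multiple of 2*pi when the recording
    # opens with the pair straddling the branch cut; align them to the
    # physical separation (< pi) at the first frame
    offset = 2 * np.pi * np.round(
        (ka.roa_unwrapped[0] - kb.roa_unwrapped[0]) / (2 * np.pi))
    kb = FishKinematics(
        fish_id=kb.fish_id, heading=kb.heading, dheading=kb.dheading,
        speed=kb.speed, roa=kb.roa, roa_unwrapped=kb.roa_unwrapped + offset,
        ald=kb.ald, wdis=kb.wdis, eye=kb.eye, tail=kb.tail)
    kin[traj_b.fish_id] = kb

    # group direction: trailing mean of the pair's unwrapped Roa increments
    mean_u = 0.5 * (ka.roa_unwrapped + kb.roa_unwrapped)
    inc = np.diff(mean_u, prepend=mean_u[0])
    win = max(1, int(round(direction_window_s * arena.fs)))
    kernel = np.ones(win)
    trailing = np.convolve(inc, kernel, mode="full")[: n]
    direction = np.sign(trailing)
    # fill leading zeros / undecided start with the first decided sign
    nz = np.nonzero(direction)[0]
    first = direction[nz[0]] if len(nz) else 1.0
    direction[direction == 0] = first
    for i in range(1, n):
        if direction[i] == 0:
            direction[i] = direction[i - 1]

    leader = assign_leader(
        ka.roa_unwrapped, kb.roa_unwrapped, direction,
        ids=(traj_a.fish_id, traj_b.fish_id))

    is_a = leader == traj_a.fish_id

    def pick(arr_a, arr_b):
        arr_a, arr_b = np.asarray(arr_a), np.asarray(arr_b)
        if arr_a.ndim == 1:
            return np.where(is_a, arr_a, arr_b)
        return np.where(is_a[:, None], arr_a, arr_b)

    pos_l = pick(traj_a.xy, traj_b.xy)
    pos_f = pick(traj_b.xy, traj_a.xy)
    head_f = pick(kb.heading, ka.heading)
    eye_l, tail_l = pick(ka.eye, kb.eye), pick(ka.tail, kb.tail)
    eye_f = pick(kb.eye, ka.eye)

    fdis = compute_fdis(pos_l, pos_f, arena.body_length)
    wldis = pick(ka.wdis, kb.wdis)
    wfdis = pick(kb.wdis, ka.wdis)
    # Rpa/Los with degenerate frames interpolated rather than raised
    bearing = pos_l - pos_f
    with np.errstate(invalid="ignore", divide="ignore"):
        rpa = _angle_between(bearing, head_f)
        rpa[np.linalg.norm(bearing, axis=1) == 0] = np.nan
        rpa[np.linalg.norm(head_f, axis=1) == 0] = np.nan
        u = eye_l - eye_f
        v = tail_l - eye_f
        los = _angle_between(u, v)
        los[(np.linalg.norm(u, axis=1) == 0) | (np.linalg.norm(v, axis=1) == 0)] = np.nan

    lald = pick(ka.ald, kb.ald)
    fald = pick(kb.ald, ka.ald)
    lspeed = pick(ka.speed, kb.speed)
    fspeed = pick(kb.speed, ka.speed)
    dl = np.linalg.norm(pick(ka.dheading, kb.dheading), axis=1)
    df_ = np.linalg.norm(pick(kb.dheading, ka.dheading), axis=1)

    cols = [fdis, wldis, wfdis, rpa, lald, fald, lspeed, fspeed, dl, df_]
    interped = False
    for i, c in enumerate(cols):
        cols[i], did = _interpolate_nans(c)
        interped = interped or did
    los, _ = _interpolate_nans(los)
    if interped:
        import warnings

        warnings.warn("degenerate frames interpolated in the state series",
                      stacklevel=2)

    # drop the first two frames (heading change undefined there)
    sl = slice(2, None)
    data = pd.DataFrame(
        {name: col[sl] for name, col in zip(CHANNELS, cols)}, columns=list(CHANNELS))
    return PairStateSeries(
        frames=traj_a.frames[sl].copy(),
        data=data,
        leader=leader[sl],
        direction=direction[sl],
        los=los[sl],
        ald={traj_a.fish_id: ka.ald[sl], traj_b.fish_id: kb.ald[sl]},
        roa={traj_a.fish_id: ka.roa[sl], traj_b.fish_id: kb.roa[sl]},
        arena=arena,
        fish_ids=(traj_a.fish_id, traj_b.fish_id),
    )
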