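"""U-turn event extraction, pairing, classification and timing.

A U-turn shows up as a '∧' or '∨' extremum in the position rotation
angle (Roa).  The detector works per fish in four steps:

1. Segment the record at the frames where the wrapped Roa jumps by
   ~2*pi (the trajectory crossing the branch cut of the angle range);
   a segment Ln spans the frames between consecutive crossings.
2. Compare the extrema of Roa over Ln with the extrema over the core
   Sn = Ln trimmed by p frames at both ends.
3. If the maximum (or minimum) over Ln is attained inside Sn, the
   segment contains a turn and the extremum frame is the Epoint — the
   turning midpoint, where the fish moves perpendicular to the wall.
   A segment shorter than 2p cannot be tested (the method's documented
   failure mode when a turn happens too close to a crossing).
4. The output window [Epoint - q, Epoint + q] is the turn interval.

Per-fish Epoints are then greedily paired (nearest first, within a
maximum lag); the pairwise turning moment is the midpoint of the two
Epoints.  A paired turn is *dominated* when the same fish leads, almost
without interruption, both before and after the manoeuvre, and
*non-dominated* otherwise.  The group turning time spans the first to
the last fish's wall-perpendicular moment (alignment-degree minimum).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import TooShortError
from .events import DOMINATED, NON_DOMINATED, UNPAIRED, TurnEvent
from .kinematics import PairStateSeries

__all__ = [
    "Segment",
    "segment_by_axis_crossings",
    "detect_single_turn",
    "detect_turns",
    "pair_turns",
    "classify_turn",
    "group_turning_time",
    "extract_turn_window",
    "extract_events",
]

#: reason codes for detect_single_turn
REASON_OK = "ok"
REASON_TOO_SHORT = "Ln <= 2p"
REASON_NO_TURN = "no extremum in core"


@dataclass
class Segment:
    """A frame interval between consecutive Roa wrap crossings.

    ``start``/``stop`` index into the Roa series (half-open, 0-based
    array indices, not recording frames).  Partial segments at the
    record edges carry ``partial=True``.
    """

    start: int
    stop: int
    partial: bool = False

    def __len__(self) -> int:
        return self.stop - self.start


def segment_by_axis_crossings(roa: np.ndarray) -> list[Segment]:
    """Partition a wrapped Roa series at its ~2*pi jump frames.

    A crossing is a step with ``|delta Roa| > pi``.  The first and last
    segments are flagged partial (the record starts/ends mid-lap).  With
    no crossings a single flagged segment spans the record.
    """
    roa = np.asarray(roa, dtype=np.float64)
    jumps = np.where(np.abs(np.diff(roa)) > np.pi)[0] + 1
    bounds = np.concatenate([[0], jumps, [len(roa)]])
    segments = []
    for i, (a, b) in enumerate(zip(bounds[:-1], bounds[1:])):
        if b <= a:
            continue
        partial = i == 0 or i == len(bounds) - 2
        segments.append(Segment(int(a), int(b), partial))
    return segments


def detect_single_turn(
    segment: Segment, roa: np.ndarray, p: int = 20
) -> tuple[int | None, str]:
    """Test one segment for a U-turn.

    Returns ``(epoint, reason)``; ``epoint`` is the array index of the
    qualifying Roa extremum or None.  ``p`` trims the segment ends: it
    should exceed half a single turning time and stay below a full one.
    Plateau ties resolve to the earliest frame.
    """
    epoints = detect_turns(segment, roa, p)
    if isinstance(epoints, str):
        return None, epoints
    if not epoints:
        return None, REASON_NO_TURN
    return epoints[0], REASON_OK


def detect_turns(segment: Segment, roa: np.ndarray, p: int = 20):
    """All qualifying extrema of one segment (0, 1 or 2 Epoints).

    Returns the reason string ``"Ln <= 2p"`` when the segment is too
    short to test, else a list of array indices.
    """
    ln = np.asarray(roa[segment.start: segment.stop], dtype=np.float64)
    if len(ln) <= 2 * p:
        return REASON_TOO_SHORT
    sn = ln[p:-p]
    out = []
    # '∧': the segment maximum attained inside the trimmed core
    if np.max(ln) == np.max(sn):
        out.append(segment.start + p + int(np.argmax(sn)))
    # '∨': likewise for the minimum
    if np.min(ln) == np.min(sn):
        out.append(segment.start + p + int(np.argmin(sn)))
    return sorted(out)


def _detect_all(roa: np.ndarray, p: int) -> tuple[list[int], list[dict]]:
    """Run the detector over every segment of one fish's Roa series."""
    epoints, log = [], []
    for seg in segment_by_axis_crossings(roa):
        res = detect_turns(seg, roa, p)
        if isinstance(res, str):
            log.append({"segment": (seg.start, seg.stop), "reason": res,
                        "partial": seg.partial})
            continue
        epoints.extend(res)
        log.append({"segment": (seg.start, seg.stop),
                    "reason": REASON_OK if res else REASON_NO_TURN,
                    "partial": seg.partial, "epoints": res})
    return sorted(epoints), log


def pair_turns(
    epoints_a: list[int],
    epoints_b: list[int],
    max_lag: int,
    ids: tuple[str, str] = ("A", "B"),
    q: int = 150,
    n_frames: int | None = None,
) -> list[TurnEvent]:
    """Greedily pair per-fish Epoints into pairwise turn events.

    The closest A/B Epoint pairs (within ``max_lag`` frames) are matched
    first; the pairwise turning moment is the rounded midpoint.
    Unmatched Epoints become unpaired events.  Events whose +-q windows
    overlap another event are dropped (single-manoeuvre focus).
    """
    a = sorted(epoints_a)
    b = sorted(epoints_b)
    cand = sorted(
        (abs(ea - eb), i, j) for i, ea in enumerate(a) for j, eb in enumerate(b)
        if abs(ea - eb) <= max_lag)
    used_a, used_b = set(), set()
    events = []
    for _, i, j in cand:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pe = int(round((a[i] + b[j]) / 2))
        events.append(TurnEvent(
            epoints={ids[0]: a[i], ids[1]: b[j]}, pair_epoint=pe,
            window=(pe - q, pe + q)))
    for i, ea in enumerate(a):
        if i not in used_a:
            events.append(TurnEvent(
                epoints={ids[0]: ea}, pair_epoint=ea, window=(ea - q, ea + q),
                turn_type=UNPAIRED, flags=["unpaired"]))
    for j, eb in enumerate(b):
        if j not in used_b:
            events.append(TurnEvent(
                epoints={ids[1]: eb}, pair_epoint=eb, window=(eb - q, eb + q),
                turn_type=UNPAIRED, flags=["unpaired"]))
    events.sort(key=lambda ev: ev.pair_epoint)

    # drop events whose windows overlap another turn
    keep = []
    for i, ev in enumerate(events):
        lo, hi = ev.window
        overlaps = any(
            not (other.window[1] < lo or other.window[0] > hi)
            for k, other in enumerate(events) if k != i)
        if not overlaps:
            keep.append(ev)
    if n_frames is not None:
        for ev in keep:
            lo, hi = ev.window
            if lo < 0 or hi > n_frames - 1:
                ev.window = (max(lo, 0), min(hi, n_frames - 1))
                ev.flags.append("window_truncated")
    return keep


def classify_turn(
    event: TurnEvent,
    leader: np.ndarray,
    frames: np.ndarray,
    q: int = 150,
    tau_frames: int = 20,
    fix_frac: float = 0.9,
) -> str:
    """Classify a paired event as dominated or non-dominated.

    The manoeuvre interval — from the first fish's Epoint to the last
    fish's, padded by half a reversal (``tau_frames/2``) — is excluded;
    the modal leader is computed over the remaining pre and post halves
    of the +-q window.  The turn is *dominated* when the same fish is
    modal in both halves and leads at least ``fix_frac`` of the frames
    in each; otherwise *non-dominated*.
    """
    if len(event.epoints) < 2:
        return UNPAIRED
    pe = event.pair_epoint
    e_first = min(event.epoints.values())
    e_last = max(event.epoints.values())
    half = tau_frames // 2
    pre_mask = (frames >= pe - q) & (frames <= e_first - half)
    post_mask = (frames >= e_last + half) & (frames <= pe + q)
    if not pre_mask.any() or not post_mask.any():
        warnings.warn("classification window truncated at the record edge",
                      stacklevel=2)
        event.flags.append("classification_window_truncated")
        if not pre_mask.any() or not post_mask.any():
            return NON_DOMINATED
    out = []
    for mask in (pre_mask, post_mask):
        ids, counts = np.unique(leader[mask], return_counts=True)
        top = ids[np.argmax(counts)]
        out.append((top, counts.max() / counts.sum()))
    (pre_id, pre_frac), (post_id, post_frac) = out
    if pre_id == post_id and pre_frac >= fix_frac and post_frac >= fix_frac:
        return DOMINATED
    return NON_DOMINATED


def group_turning_time(
    event: TurnEvent,
    series: PairStateSeries,
    ald_perp_max: float = 0.2,
    search_halfwidth: int | None = None,
) -> float | None:
    """Time between the two fish's wall-perpendicular moments (seconds).

    Per fish, the perpendicular moment is the alignment-degree local
    minimum nearest its Epoint (within the turn window) with
    ``ald < ald_perp_max``.  Undefined (None) for unpaired events or
    when a fish shows no qualifying minimum; the event is flagged.
    """
    if len(event.epoints) < 2:
        event.flags.append("no_group_turning_time")
        return None
    fs = series.arena.fs
    lo, hi = event.window
    perp_frames = []
    for fid, ep in event.epoints.items():
        ald = series.ald_of(fid)
        frames = series.frames
        if search_halfwidth is not None:
            mask = (frames >= ep - search_halfwidth) & (frames <= ep + search_halfwidth)
        else:
            mask = (frames >= lo) & (frames <= hi)
        idx = np.where(mask)[0]
        if len(idx) < 3:
            event.flags.append("no_ald_minimum")
            return None
        a = ald[idx]
        local = np.where((a[1:-1] <= a[:-2]) & (a[1:-1] <= a[2:])
                         & (a[1:-1] < ald_perp_max))[0] + 1
        if len(local) == 0:
            event.flags.append("no_ald_minimum")
            return None
        cand = frames[idx[local]]
        perp_frames.append(cand[np.argmin(np.abs(cand - ep))])
    return float(abs(perp_frames[1] - perp_frames[0]) / fs)


def extract_turn_window(
    event: TurnEvent, series: PairStateSeries, q: int = 150
) -> PairStateSeries:
    """Slice the pair state series to [pair_epoint - q, pair_epoint + q]."""
    lo = event.pair_epoint - q
    hi = event.pair_epoint + q
    if lo < series.frames[0] or hi > series.frames[-1]:
        warnings.warn("turn window truncated at the record edge", stacklevel=2)
        if "window_truncated" not in event.flags:
            event.flags.append("window_truncated")
    return series.window(lo, hi)


def extract_events(
    series: PairStateSeries,
    p: int = 20,
    q: int = 150,
    max_lag_s: float = 2.0,
    tau_s: float = 0.4,
    fix_frac: float = 0.9,
    ald_perp_max: float = 0.2,
) -> list[TurnEvent]:
    """Full extraction pipeline on a pair state series.

    Detects per-fish turns from the wrapped Roa series, pairs them,
    classifies each paired event and computes its group turning time.
    Epoints are reported as recording frames.
    """
    fs = series.arena.fs
    ids = series.fish_ids
    if len(series) <= 2 * p:
        raise TooShortError("record shorter than the detector trim window")
    eps = {}
    for fid in ids:
        idx, _ = _detect_all(series.roa[fid], p)
        eps[fid] = [int(series.frames[i]) for i in idx]
    tau_frames = int(round(tau_s * fs))
    events = pair_turns(
        eps[ids[0]], eps[ids[1]], max_lag=int(round(max_lag_s * fs)),
        ids=ids, q=q, n_frames=int(series.frames[-1]) + 1)
    for ev in events:
        if len(ev.epoints) == 2:
            ev.turn_type = classify_turn(
                ev, series.leader, series.frames, q=q,
                tau_frames=tau_frames, fix_frac=fix_frac)
            # leader identities on the classification halves
            pe = ev.pair_epoint
            e_first, e_last = min(ev.epoints.values()), max(ev.epoints.values())
            half = tau_frames // 2
            for attr, mlo, mhi in (
                ("leader_pre", pe - q, e_first - half),
                ("leader_post", e_last + half, pe + q),
            ):
                mask = (series.frames >= mlo) & (series.frames <= mhi)
                if mask.any():
                    vals, counts = np.unique(series.leader[mask], return_counts=True)
                    setattr(ev, attr, str(vals[np.argmax(counts)]))
            ev.group_turning_time_s = group_turning_time(
                ev, series, ald_perp_max=ald_perp_max)
            # direction change across the turn
            pre = series.direction[(series.frames >= pe - q) & (series.frames < e_first)]
            post = series.direction[(series.frames > e_last) & (series.frames <= pe + q)]
            if len(pre) and len(post):
                d_pre = 1 if np.median(pre) > 0 else -1
                d_post = 1 if np.median(post) > 0 else -1
                names = {1: "ccw", -1: "cw"}
                ev.direction_change = f"{names[d_pre]}->{names[d_post]}"
    return events
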