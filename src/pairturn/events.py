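"""The TurnEvent record: one extracted single-fish or pairwise U-turn."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

__all__ = ["TurnEvent", "DOMINATED", "NON_DOMINATED", "UNPAIRED"]

DOMINATED = "dominated"
NON_DOMINATED = "non_dominated"
UNPAIRED = "unpaired"


@dataclass
class TurnEvent:
    """One U-turn of a pair (or of a single fish if unpaired).

    Attributes
    ----------
    epoints : dict
        Per-fish turning moment: ``{fish_id: frame}``.  The Epoint is the
        frame of the position-rotation-angle extremum, where the fish's
        motion is approximately perpendicular to the wall.
    pair_epoint : int
        Turning moment of the pairwise U-turn: the intermediate moment
        between the two per-fish Epoints (rounded).  Equals the single
        Epoint for unpaired events.
    window : tuple of int
        Analysis interval ``[pair_epoint - q, pair_epoint + q]``, clipped
        to the recording.
    direction_change : str
        ``"ccw->cw"`` or ``"cw->ccw"``.
    turn_type : str
        ``"dominated"`` (fixed leader), ``"non_dominated"`` (leadership
        switches across the turn) or ``"unpaired"``.
    leader_pre, leader_post : str or None
        Modal leader identity before / after the turn.
    group_turning_time_s : float or None
        Time between the first and the last fish's velocity becoming
        perpendicular to the wall; None when undefined.
    flags : list of str
        Diagnostics, e.g. ``"window_truncated"`` or ``"no_ald_minimum"``.
    """

    epoints: dict
    pair_epoint: int
    window: tuple
    direction_change: str = ""
    turn_type: str = UNPAIRED
    leader_pre: str | None = None
    leader_post: str | None = None
    group_turning_time_s: float | None = None
    flags: list = field(default_factory=list)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["window"] = list(d["window"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TurnEvent":
        d = dict(d)
        d["epoints"] = {str(k): int(v) for k, v in d["epoints"].items()}
        d["window"] = tuple(d["window"])
        return cls(**d)
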