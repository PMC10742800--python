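"""Synthetic two-fish annular-tank trajectories with scripted U-turns.

The generator produces ground-truthed data for every downstream stage:
two fish circle the annulus with burst-glide speed modulation and
perform scripted pairwise U-turns of two behavioural templates.

* In a **dominated** turn the pair keeps a fixed leader.  The leader
  reverses its swim direction first, the follower a lag later; at the
  comfortable spacing of a few body lengths the relative angular motion
  during the lag carries the pair past each other, so the same fish is
  ahead in the new direction of travel and leadership (defined through
  the position rotation angle) is preserved.
* In a **non-dominated** turn the fish travel about one body length
  apart and nearly stop during the manoeuvre ("stop and go").  Because
  hardly any relative angular motion accumulates, the angular order of
  the pair is preserved and leadership switches across the turn.

Each fish's direction reversal is a raised-cosine angular-velocity
reversal of duration ``turn_duration_s`` centred exactly on its scripted
turning moment; during the reversal a radial velocity pulse makes the
fish's motion pass through the wall-normal direction, so the alignment
degree dips to zero exactly at the turning moment.  After each turn a
gentle angular-speed asymmetry between the fish (a station-keeping
nudge) restores the pair spacing required by the next scripted turn;
the nudge is solved exactly on the frame grid, so template leadership
and spacing are guaranteed by construction.

Measurement degradation is applied last: i.i.d. Gaussian position
jitter plus sparse single-frame outliers displaced 3-6 body lengths
(the "Z"-shaped tracking artefact).  Output is bit-reproducible for a
given seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .config import ArenaConfig
from .errors import ConfigError
from .events import DOMINATED, NON_DOMINATED
from .trajectory import Trajectory

__all__ = ["SimConfig", "TurnTruth", "GroundTruth", "simulate_pair",
           "inject_noise", "simulate_regime_series"]

#: group turning times observed for the two templates (s); used as the
#: default leader-follower reversal lag per template
DEFAULT_LAG_S = {DOMINATED: 0.8496, NON_DOMINATED: 1.6775}
#: default pair spacing per template (body lengths)
DEFAULT_SPACING_BL = {DOMINATED: 2.5, NON_DOMINATED: 1.0}


@dataclass
class SimConfig:
    """Study conditions for one simulated recording.

    The defaults emulate the annular-tank experiment: 12.5/17.5 cm
    walls, 33.3 mm fish sampled at 50 Hz, cruising at ~4 body lengths
    per second with burst-glide modulation, turning spontaneously a few
    times per minute.
    """

    arena: ArenaConfig = field(default_factory=ArenaConfig)
    duration_s: float = 120.0
    turn_times_s: tuple = (20.0, 50.0, 80.0, 110.0)
    turn_types: tuple | None = None        # None -> alternate starting dominated
    leader_lag_s: float | tuple | None = None  # None -> per-template default
    turn_duration_s: float = 0.4           # single-fish reversal duration tau
    mean_speed: float = 0.14               # m/s (~4.2 BL/s)
    burst_period_s: float = 0.8
    burst_depth: float = 0.35              # glide speed = (1-depth) * mean
    fdis_target_BL: dict | float | None = None  # None -> per-template default
    stop_go_depth: float = 0.95            # non-dominated speed dip, fraction of mean
    stop_go_dips: int = 2                  # "stop and go": repeated stops
    noise_sigma_m: float = 0.0005
    spike_prob: float = 0.001
    phi0: float = 1.0                      # initial centroid angle (rad)
    initial_leader: str = "A"
    initial_direction: int = 1             # +1 ccw, -1 cw
    seed: int = 0

    # internal motion constants (exposed for completeness)
    radial_excursion_frac: float = 0.10    # radial pulse speed / mean_speed
    radial_relax_rate: float = 1.2         # 1/s mean reversion of radius
    correction_duration_s: float = 2.0     # station-keeping nudge length

    def __post_init__(self) -> None:
        if not 0 <= self.burst_depth < 1:
            raise ConfigError("burst_depth must be in [0, 1)")
        if not 0 <= self.spike_prob <= 0.01:
            raise ConfigError("spike_prob must be in [0, 0.01]")
        if not 0 < self.stop_go_depth < 1:
            raise ConfigError("stop_go_depth must be in (0, 1)")
        if self.initial_leader not in ("A", "B"):
            raise ConfigError("initial_leader must be 'A' or 'B'")
        if self.initial_direction not in (-1, 1):
            raise ConfigError("initial_direction must be +1 or -1")

    # -- resolved per-turn schedules -------------------------------------
    def resolved_types(self) -> tuple:
        if self.turn_types is not None:
            if len(self.turn_types) != len(self.turn_times_s):
                raise ConfigError("turn_types length must match turn_times_s")
            bad = set(self.turn_types) - {DOMINATED, NON_DOMINATED}
            if bad:
                raise ConfigError(f"unknown turn types {bad}")
            return tuple(self.turn_types)
        return tuple(
            DOMINATED if j % 2 == 0 else NON_DOMINATED
            for j in range(len(self.turn_times_s)))

    def resolved_lags(self) -> tuple:
        types = self.resolved_types()
        if self.leader_lag_s is None:
            return tuple(DEFAULT_LAG_S[t] for t in types)
        if np.isscalar(self.leader_lag_s):
            return tuple(float(self.leader_lag_s) for _ in types)
        if len(self.leader_lag_s) != len(types):
            raise ConfigError("leader_lag_s length must match turn_times_s")
        return tuple(float(v) for v in self.leader_lag_s)

    def resolved_spacing(self) -> dict:
        if self.fdis_target_BL is None:
            return dict(DEFAULT_SPACING_BL)
        if np.isscalar(self.fdis_target_BL):
            v = float(self.fdis_target_BL)
            return {DOMINATED: v, NON_DOMINATED: v}
        return {**DEFAULT_SPACING_BL, **self.fdis_target_BL}


@dataclass
class TurnTruth:
    """Ground truth for one scripted pairwise U-turn."""

    time_s: float
    pair_epoint: int           # frame of the pairwise turning moment
    epoints: dict              # fish id -> frame of the per-fish reversal centre
    turn_type: str
    leader_pre: str
    leader_post: str
    lag_s: float
    direction_change: str      # "ccw->cw" or "cw->ccw"


@dataclass
class GroundTruth:
    """Per-turn and per-frame ground truth of a simulated recording."""

    turns: list
    direction: np.ndarray      # per frame, +1 ccw / -1 cw (steps at pair epoints)
    leader: np.ndarray         # per frame leader id under the Roa rule
    delta_phi: np.ndarray      # per frame angular separation phi_A - phi_B (rad)


def _reversal_factor(t: np.ndarray, centre: float, tau: float) -> np.ndarray:
    """Smooth direction factor: +1 before, -1 after, 0 exactly at centre.

    A cubed cosine keeps the zero crossing flat, so the tangential
    velocity lingers near zero for a few frames around the turning
    moment and the sampled heading passes visibly through the
    wall-normal direction (the apex of a C-turn).
    """
    out = np.ones_like(t)
    out[t >= centre + tau / 2] = -1.0
    inside = (t > centre - tau / 2) & (t < centre + tau / 2)
    out[inside] = np.cos(np.pi * (t[inside] - centre + tau / 2) / tau) ** 3
    return out


def _bump(t: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Smooth raised-cosine bump, 0 outside [lo, hi], peak 1 at the midpoint."""
    out = np.zeros_like(t)
    inside = (t > lo) & (t < hi)
    out[inside] = 0.5 * (1 - np.cos(2 * np.pi * (t[inside] - lo) / (hi - lo)))
    return out


def _plateau(t: np.ndarray, lo: float, hi: float, ramp: float) -> np.ndarray:
    """Profile rising 0->1 over [lo-ramp, lo], 1 on [lo, hi], falling over [hi, hi+ramp]."""
    out = np.zeros_like(t)
    out[(t >= lo) & (t <= hi)] = 1.0
    up = (t > lo - ramp) & (t < lo)
    out[up] = 0.5 * (1 - np.cos(np.pi * (t[up] - lo + ramp) / ramp))
    dn = (t > hi) & (t < hi + ramp)
    out[dn] = 0.5 * (1 + np.cos(np.pi * (t[dn] - hi) / ramp))
    return out


def simulate_pair(cfg: SimConfig) -> tuple[Trajectory, Trajectory, GroundTruth]:
    """Simulate a two-fish recording with scripted pairwise U-turns.

    Returns the two trajectories (fish ids ``"A"`` and ``"B"``) and the
    :class:`GroundTruth`.  Deterministic given ``cfg.seed``.
    """
    arena = cfg.arena
    fs = arena.fs
    dt = 1.0 / fs
    n = int(round(cfg.duration_s * fs))
    t = np.arange(n) * dt
    tau = cfg.turn_duration_s
    rho_mid = arena.mid_radius
    bl = arena.body_length

    types = cfg.resolved_types()
    lags = cfg.resolved_lags()
    times = tuple(float(v) for v in cfg.turn_times_s)
    spacing = cfg.resolved_spacing()
    if any(tt <= 0 or tt >= cfg.duration_s for tt in times):
        raise ConfigError("turn times must lie inside the recording")
    order = np.argsort(times)
    times = tuple(times[i] for i in order)
    types = tuple(types[i] for i in order)
    lags = tuple(lags[i] for i in order)
    for j in range(len(times) - 1):
        gap = times[j + 1] - times[j]
        need = max(
            2 * (lags[j] + tau),
            lags[j] / 2 + tau + 0.2 + cfg.correction_duration_s + lags[j + 1] / 2 + 0.5,
        )
        if gap <= need:
            raise ConfigError(
                f"turns at {times[j]}s and {times[j+1]}s too close (need > {need:.2f}s)")
    for j, (tt, lag) in enumerate(zip(times, lags)):
        margin = lag / 2 + tau / 2 + 0.5
        if tt < margin or tt > cfg.duration_s - margin:
            raise ConfigError(f"turn at {tt}s too close to the record edge")

    # ---- per-turn bookkeeping ------------------------------------------
    leader = cfg.initial_leader
    d = cfg.initial_direction
    turns: list[TurnTruth] = []
    centres = {"A": [], "B": []}
    for j, (tt, ty, lag) in enumerate(zip(times, types, lags)):
        follower = "B" if leader == "A" else "A"
        centres[leader].append(tt - lag / 2)
        centres[follower].append(tt + lag / 2)
        leader_post = leader if ty == DOMINATED else follower
        turns.append(TurnTruth(
            time_s=tt,
            pair_epoint=int(round(tt * fs)),
            epoints={leader: int(round((tt - lag / 2) * fs)),
                     follower: int(round((tt + lag / 2) * fs))},
            turn_type=ty,
            leader_pre=leader,
            leader_post=leader_post,
            lag_s=lag,
            direction_change="ccw->cw" if d > 0 else "cw->ccw",
        ))
        leader = leader_post
        d = -d

    # ---- direction factors ---------------------------------------------
    D = {}
    for fid in ("A", "B"):
        f = np.full(n, float(cfg.initial_direction))
        for c in centres[fid]:
            f = f * _reversal_factor(t, c, tau)
        D[fid] = f

    # ---- speed profiles -------------------------------------------------
    sq = ((t / cfg.burst_period_s) % 1.0 < 0.5).astype(float)  # shared burst phase
    glide = cfg.burst_depth * sq
    dip_len, dip_gap = 0.45, 0.4  # stop-and-go cadence (s)
    v = {}
    for fid in ("A", "B"):
        vi = cfg.mean_speed * (1.0 - glide)
        for tr in turns:
            lo = min(tr.epoints.values()) / fs - tau / 2
            hi = max(tr.epoints.values()) / fs + tau / 2
            if tr.turn_type == NON_DOMINATED:
                # The complex manoeuvre unfolds in heterogeneous phases
                # while the pair still shares a direction (so no relative
                # angular drift accrues): stop-and-go hesitation dips, a
                # moderate-speed leg while the pair drifts toward the
                # outer wall, then a sustained near-stop across the
                # reversal core, which preserves the angular order and
                # hence realises the leadership switch.
                ndip = max(1, int(cfg.stop_go_dips))
                wall_lo, wall_hi = lo - 1.0, lo - 0.4
                start = wall_lo - ndip * (dip_len + dip_gap)
                m = _plateau(t, start, hi, tau / 2)
                vi = vi * (1 - m) + cfg.mean_speed * m
                for idip in range(ndip):
                    a = wall_lo - (idip + 1) * (dip_len + dip_gap)
                    vi = vi * (1.0 - cfg.stop_go_depth * _bump(t, a, a + dip_len + 0.2))
                vi = vi * (1.0 - 0.45 * _plateau(t, wall_lo, wall_hi, 0.15))
                vi = vi * (1.0 - cfg.stop_go_depth * _plateau(t, lo, hi, tau / 2))
            else:
                # dominated: swift manoeuvre at full speed (burst-glide
                # suspended over the reversal span)
                m = _plateau(t, lo, hi, tau / 2)
                vi = vi * (1 - m) + cfg.mean_speed * m
        v[fid] = vi

    # ---- radial dynamics (independent of phi) ---------------------------
    rho = {}
    amp_r = cfg.radial_excursion_frac * cfg.mean_speed
    lo_r = arena.inner_radius + bl / 2 + 5e-4
    hi_r = arena.outer_radius - bl / 2 - 5e-4
    wobble_period = {"A": 13.0, "B": 17.0}
    wobble_sign = {"A": 1.0, "B": -1.0}
    for fid in ("A", "B"):
        target = rho_mid + wobble_sign[fid] * 0.002 * np.sin(
            2 * np.pi * t / wobble_period[fid])
        for tr in turns:
            if tr.turn_type == NON_DOMINATED:
                # the pair drifts toward the outer wall while hesitating,
                # motivating the about-turn at close wall range
                lo = min(tr.epoints.values()) / fs - tau / 2
                target = target + 0.004 * _bump(t, lo - 1.05, lo - 0.25)
        exc = np.zeros(n)
        for c in centres[fid]:
            inside = (t > c - tau / 2) & (t < c + tau / 2)
            exc[inside] += amp_r * np.cos(np.pi * (t[inside] - c) / tau)
        r = np.empty(n)
        r[0] = np.clip(target[0], lo_r, hi_r)
        for i in range(1, n):
            drdt = cfg.radial_relax_rate * (target[i - 1] - r[i - 1]) + exc[i - 1]
            r[i] = np.clip(r[i - 1] + drdt * dt, lo_r, hi_r)
        rho[fid] = r

    # ---- base angular integration ---------------------------------------
    d0 = cfg.initial_direction
    pre_leader = cfg.initial_leader
    delta0 = spacing[types[0]] * bl / rho_mid if turns else \
        DEFAULT_SPACING_BL[DOMINATED] * bl / rho_mid
    s0 = d0 if pre_leader == "A" else -d0
    phi = {}
    for fid in ("A", "B"):
        omega = D[fid] * v[fid] / rho[fid]
        base = cfg.phi0 + (0.5 if fid == "A" else -0.5) * s0 * delta0
        phi[fid] = base + np.concatenate([[0.0], np.cumsum(omega[:-1]) * dt])

    # ---- station-keeping corrections after each turn ---------------------
    cruise = spacing[DOMINATED]
    for j, tr in enumerate(turns):
        e_late = max(tr.epoints.values()) / fs
        lo = e_late + tau / 2 + 0.2
        hi = lo + cfg.correction_duration_s
        next_spacing = spacing[types[j + 1]] if j + 1 < len(turns) else cruise
        d_post = cfg.initial_direction * (-1) ** (j + 1)
        sign = d_post if tr.leader_post == "A" else -d_post
        target = sign * next_spacing * bl / rho_mid
        g = _bump(t, lo, hi)
        cum_g = np.concatenate([[0.0], np.cumsum(g[:-1]) * dt])
        idx_end = min(n - 1, int(round(hi * fs)) + 1)
        current = (phi["A"][idx_end] - phi["B"][idx_end])
        a = (target - current) / cum_g[idx_end] if cum_g[idx_end] > 0 else 0.0
        # keep the nudge well below the base angular speed so no spurious
        # direction reversal is introduced
        base_omega = cfg.mean_speed * (1 - cfg.burst_depth) / rho_mid
        if abs(a) * 0.5 > 0.8 * base_omega:
            warnings.warn(
                f"station-keeping nudge after turn {j} is large "
                f"({abs(a):.2f} rad/s); spacing change may be aggressive",
                stacklevel=2)
        phi["A"] = phi["A"] + 0.5 * a * cum_g
        phi["B"] = phi["B"] - 0.5 * a * cum_g

    # ---- ground truth per frame ------------------------------------------
    direction = np.full(n, float(cfg.initial_direction))
    for j, tr in enumerate(turns):
        direction[tr.pair_epoint:] = cfg.initial_direction * (-1) ** (j + 1)
    delta_phi = phi["A"] - phi["B"]
    leader_series = np.where(delta_phi * direction > 0, "A", "B")

    gt = GroundTruth(
        turns=turns, direction=direction, leader=leader_series, delta_phi=delta_phi)

    frames = np.arange(n, dtype=np.int64)
    trajs = {}
    for fid in ("A", "B"):
        xy = np.column_stack([
            rho[fid] * np.cos(phi[fid]), rho[fid] * np.sin(phi[fid])])
        trajs[fid] = Trajectory(fish_id=fid, frames=frames, xy=xy, fs=fs)

    if cfg.noise_sigma_m > 0 or cfg.spike_prob > 0:
        root = np.random.SeedSequence(cfg.seed)
        seeds = root.spawn(2)
        for i, fid in enumerate(("A", "B")):
            trajs[fid] = inject_noise(
                trajs[fid], cfg.noise_sigma_m, cfg.spike_prob,
                seed=seeds[i], body_length=bl)

    return trajs["A"], trajs["B"], gt


def simulate_regime_series(
    seed,
    n_segments: int = 4,
    segment_len: int = 200,
    d: int = 3,
    corr: float = 0.8,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian series alternating between two covariance regimes.

    Regime 0 is equicorrelated at ``+corr``; regime 1 carries a chain of
    ``-corr`` correlations (ridge-stabilised).  Used to validate the
    clustering stage against known change-points.

    Returns ``(series, truth)`` with ``series`` of shape
    ``(n_segments * segment_len, d)`` and ``truth`` the per-frame regime
    index (0 or 1).
    """
    rng = np.random.default_rng(seed)
    cov_a = np.full((d, d), corr)
    np.fill_diagonal(cov_a, 1.0)
    cov_b = np.eye(d)
    for i in range(d - 1):
        cov_b[i, i + 1] = cov_b[i + 1, i] = -corr
    for i in range(d - 2):
        cov_b[i, i + 2] = cov_b[i + 2, i] = corr * corr
    cov_b = cov_b + 0.2 * np.eye(d)
    parts, truth = [], []
    for i in range(n_segments):
        cov = cov_a if i % 2 == 0 else cov_b
        parts.append(rng.multivariate_normal(np.zeros(d), cov, size=segment_len))
        truth.extend([i % 2] * segment_len)
    return np.vstack(parts), np.asarray(truth)


def inject_noise(
    traj: Trajectory,
    sigma: float,
    spike_prob: float,
    seed,
    body_length: float = 0.0333,
) -> Trajectory:
    """Add Gaussian jitter and sparse single-frame outliers to a trajectory.

    Every coordinate receives i.i.d. N(0, sigma^2) noise; independently,
    each frame is displaced with probability ``spike_prob`` by 3-6 body
    lengths in a uniform random direction (the "Z" tracking artefact).
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if not 0 <= spike_prob <= 1:
        raise ValueError("spike_prob must be a probability")
    rng = np.random.default_rng(seed)
    xy = traj.xy.copy()
    if sigma > 0:
        xy = xy + rng.normal(0.0, sigma, size=xy.shape)
    if spike_prob > 0:
        hit = rng.random(len(xy)) < spike_prob
        k = int(hit.sum())
        if k:
            dist = rng.uniform(3.0, 6.0, size=k) * body_length
            ang = rng.uniform(0.0, 2 * np.pi, size=k)
            xy[hit, 0] += dist * np.cos(ang)
            xy[hit, 1] += dist * np.sin(ang)
    return traj.with_xy(xy)
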