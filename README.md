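# pairturn

Pairwise U-turn analysis for fish swimming in annular tanks.

Rummy-nose tetra (*Hemigrammus rhodostomus*) pairs circling a ring-shaped
tank spontaneously reverse their swim direction. These pairwise U-turns come
in two behavioural flavours: **dominated** turns, where one fish leads
throughout a fast, smooth manoeuvre, and **non-dominated** turns, where
leadership switches across the turning moment and the pair stops and goes at
close range. `pairturn` turns raw two-fish trajectory recordings into an
interpreted account of this behaviour, and ships a ground-truthed simulator
so every stage is testable without any recorded data.

The pipeline:

1. **Preprocessing** — five-point cubic (degree-3 least-squares) smoothing
   removes tracking noise and "Z"-shaped error points while preserving
   burst-glide speed structure.
2. **U-turn extraction** — the position rotation angle
   `Roa(t) = atan2(y, x) ∈ (−π, π]` of each fish drifts monotonically while
   it circles and forms a '∧'/'∨' extremum at a reversal. The record is
   segmented at the angle wraps; an extremum that survives trimming `p`
   frames off the segment ends is a turning moment (*Epoint*). Per-fish
   Epoints are paired (midpoint = the pairwise turning moment), classified
   dominated/non-dominated from the leader identity before and after the
   manoeuvre, and timed (group turning time = first-to-last
   wall-perpendicular moment, located at alignment-degree minima).
3. **State parameters** — per frame, the ten-channel pair state series in a
   frozen order: `Fdis` (inter-fish distance, body lengths), `Wldis`/`Wfdis`
   (leader/follower wall distance), `Rpa` (bearing of the leader in the
   follower's heading frame), `Lald`/`Fald` (alignment degree,
   |sin| of the heading-to-radial angle), `Lspeed`/`Fspeed`, and
   `|ΔHeading|` for both fish; plus the line-of-sight angle `Los` as an
   auxiliary.
4. **Clustering** — Toeplitz inverse-covariance clustering (TICC),
   implemented from scratch: each behavioural state is a Gaussian Markov
   random field over a `w`-frame window whose `(d·w)×(d·w)` precision matrix
   is block-Toeplitz and L1-sparsified
   (`argmin −logdet Θ + tr(SΘ) + λ‖Θ‖₁`, solved by ADMM with a
   block-Toeplitz projection), while a dynamic program assigns labels under
   a switching penalty `β`. BIC selects the cluster count.
5. **Interpretation** — each cluster's MRF collapses to a 10-node channel
   dependency graph; betweenness centrality (normalised to max 1 per
   cluster) ranks which state parameter drives each state. Turn windows
   become run-length-encoded **state compositions** (e.g. `5-2-5`), and
   per-state statistics (segment-averaged `Fdis`, quartiles per channel)
   characterise each state.

## Worked example

```python
from pairturn import (SimConfig, simulate_pair, smooth_trajectory,
                      build_pair_state_series, extract_events)

cfg = SimConfig(duration_s=120.0, seed=42)          # tracking noise on
fish_a, fish_b, truth = simulate_pair(cfg)
series = build_pair_state_series(
    smooth_trajectory(fish_a), smooth_trajectory(fish_b), cfg.arena)
events = [e for e in extract_events(series) if len(e.epoints) == 2]
for ev in events:
    gtt = f"{ev.group_turning_time_s:.2f} s" if ev.group_turning_time_s else "undefined"
    print(f"turn @ frame {ev.pair_epoint:5d}  {ev.direction_change}  "
          f"{ev.turn_type:<13s}  leader {ev.leader_pre}->{ev.leader_post}  "
          f"group turning time {gtt}")
```

prints

```
turn @ frame  1002  ccw->cw  dominated      leader A->A  group turning time 0.84 s
turn @ frame  2496  cw->ccw  non_dominated  leader A->B  group turning time 1.60 s
turn @ frame  4000  ccw->cw  dominated      leader B->B  group turning time undefined
turn @ frame  5502  cw->ccw  non_dominated  leader B->A  group turning time 1.82 s
```

All four scripted turns are recovered at their true frames with the correct
template, leadership and timing; the third event's timing is flagged
undefined because noise hides its wall-perpendicular moment (a fish that is
nearly stopped has no reliable displacement-based heading) — the event
carries a `no_ald_minimum` flag rather than a fabricated number.

Clustering the four ±3 s turn windows and printing the fit:

```python
import numpy as np
from pairturn import fit_ticc, extract_turn_window

x = np.vstack([extract_turn_window(ev, series, q=150).values for ev in events])
res = fit_ticc(x, k=4, w=5, lam=0.11, beta=150, seed=0)
print(res.summary())
```

```
Toeplitz inverse-covariance clustering
======================================================
channels (d):        10
window length (w):   5
clusters (k):        4
lambda (sparsity):   0.11
beta (switching):    150
windows:             1200
label switches:      19
log-likelihood:      -1509.67
BIC:                 11619.61
seed:                0
------------------------------------------------------
cluster  frames  share
      1     524   43.5%
      2      58    4.8%
      3     248   20.6%
      4     374   31.1%
```

`res.thetas` holds the per-cluster block-Toeplitz precision matrices; feed
them to `mrf_adjacency` + `betweenness_scores` to rank the channels driving
each state, and `state_composition` to express each turn as a label string.

A `pairturn` console script exposes the same pipeline as subcommands
(`simulate`, `preprocess`, `states`, `extract`, `cluster`, `interpret`);
each stage reads and writes plain CSV/JSON.

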