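# Methods

This note records the models, conventions and design choices behind
`pairturn`, in the spirit of a statistical package's model documentation:
what is computed, under which assumptions, and what the synthetic data do
and do not establish.

## Coordinate and unit conventions

All positions are tank-centred Cartesian metres; frames are 0-based at
`fs = 50` Hz. The default arena is an annulus with inner radius 0.125 m,
outer radius 0.175 m, holding fish of mean body length `BL = 33.3` mm.
Distances reported in body lengths are divided by `BL`.

The position rotation angle is the signed angle of the centre-to-fish
vector against +x, `Roa = atan2(y, x) ∈ (−π, π]`, counterclockwise
positive. Its branch cut therefore sits on the negative x-semi-axis; the
U-turn detector is invariant to where the cut sits (it only needs *a* cut),
but turns whose apex falls within `p` frames of the cut are undetectable —
the method's documented failure mode. Unwrapped Roa series of the two fish
are aligned so their difference at the first frame lies in `(−π, π]`;
without this alignment a recording that opens with the pair straddling the
branch cut acquires a spurious 2π offset that inverts the leader rule.

## Per-frame kinematics

Headings are inter-frame displacements, `heading(t) = c(t) − c(t−1)`, with
the inter-frame path treated as linear, so `speed = |heading|·fs`. The
first frame has no heading and the first two no heading change; the pair
state series therefore starts at frame 2. Zero-displacement frames carry
the last nonzero heading *direction* (for the alignment degree and the
eye/tail construction) while keeping magnitude zero. The fish is treated as
a rigid rod: eye and tail sit at `±BL/2` along the unit heading.

The alignment degree is `ald = |sin θ|` with `θ` the angle between heading
and the radial vector — 1 when wall-aligned, 0 when heading at a wall. It
is unsigned: the analysis never needs the side. The relative position angle
`Rpa` and line-of-sight angle `Los` are unsigned angles in `[0, π]`,
computed via `atan2(|cross|, dot)` (stable near 0 and π, unlike `arccos` of
a clipped cosine).

Leader rule: with the pair's direction `d` (+1 ccw, −1 cw, estimated as
the sign of the trailing 0.5 s mean of the pair's unwrapped-Roa increment),
the fish with the larger unwrapped Roa leads when `d = +1`, the smaller
when `d = −1`. Exact ties carry the previous frame's leader.

The ten clustered channels, in frozen order:
`Fdis, Wldis, Wfdis, Rpa, Lald, Fald, Lspeed, Fspeed, |DlHeading|,
|DfHeading|`. Heading-change channels enter as magnitudes (the clustering
needs scalar channels). Channels are z-scored per recording before
clustering because they mix metres, radians and body lengths; `Los` and
the leader identity ride along as auxiliaries and are not clustered.

## Smoothing

The five-point cubic smoother replaces each sample with the centre value of
the degree-3 least-squares fit over the centred five-point window
(weights `(−3, 12, 17, 12, −3)/35`); the two samples at each edge use the
one-sided degree-3 fit. It is exact on cubics, linear, and
shift-equivariant in the interior, and equals a five-point cubic
Savitzky–Golay filter with polynomial edge handling (used as the
independent oracle in tests). One pass scales an isolated spike by exactly
17/35 ≈ 0.486 at its centre frame — and, a small identity, a second pass
leaves the centre residual at Σk² = 595/1225 = 17/35 again, though it
spreads and thereby flattens the artefact further. Default: one pass.
There is no separate despiking stage.

## U-turn extraction

Detection runs per fish on the wrapped Roa series: segments between
consecutive wraps (`|ΔRoa| > π`); within a segment `Ln`, the extrema over
`Ln` are compared with the extrema over the trimmed core `Sn`
(`p = 20` frames off each end). A shared extremum is a turning moment.
Segments with `|Ln| ≤ 2p` are untestable and return the reason code
`"Ln <= 2p"`. Plateau ties resolve to the earliest frame. `p` should
exceed half a single-fish reversal and stay below a full one.

Pairing is greedy nearest-first within `max_lag = 2 s`; the pairwise
turning moment is the rounded midpoint of the two per-fish Epoints.
Events whose `±q` windows (default `q = 150` frames = 3 s) overlap another
turn are dropped — the analysis targets isolated single manoeuvres.

Classification: the manoeuvre interval — from the first per-fish Epoint to
the last, padded by half a reversal duration (`τ/2`, `τ = 0.4` s) — is
excluded, and the modal leader is computed over the remaining pre and post
halves of the `±q` window. *Dominated* requires the same fish to be modal
in both halves with at least `fix_frac = 0.9` of the frames in each;
anything else is *non-dominated*. The exclusion is anchored to the
per-fish Epoints rather than the pairwise midpoint because the manoeuvre
occupies the full leader-to-follower lag (0.8–1.7 s in practice): a
fixed-width exclusion around the midpoint would leave transition frames
inside the post half and push every turn below the `fix_frac` bar.

Group turning time: per fish, the wall-perpendicular moment is the
alignment-degree local minimum (below `ald_perp_max = 0.2`) nearest its
Epoint within the turn window; the group turning time spans the first to
the last such moment. When a fish shows no qualifying minimum — typical
for noisy recordings of stop-and-go turns, where a nearly stopped fish has
no reliable displacement-based heading — the event is flagged
(`no_ald_minimum`) instead of receiving a fabricated time.

## Toeplitz inverse-covariance clustering

Each cluster is a Gaussian MRF over a forward-looking window of `w` frames
of the d-channel series; window `t` (frames `t..t+w−1`) labels frame `t`,
and the trailing `w−1` frames inherit the last window's label. The cluster
parameter `Θ` is the `(d·w)×(d·w)` precision of the stacked window,
constrained block-Toeplitz (the `d×d` block coupling frame offsets `i, j`
depends only on `j−i`): within a state, cross-time dependencies are
time-invariant, and `w` bounds the temporal depth of the dependency
network.

Fitting alternates:

* **Assignment.** Given per-window negative log-likelihoods
  `nll(t, c) = ½(s_t−μ_c)ᵀΘ_c(s_t−μ_c) − ½ log det Θ_c`, a forward dynamic
  program minimises `Σ_t nll(t, z_t) + β·#{z_t ≠ z_{t+1}}` exactly, with
  backtracking; ties prefer continuing the current label, then the smaller
  cluster index. `β = 0` reduces to the pointwise argmin; large `β` forces
  a single global label.
* **M-step.** Per cluster, `μ` is the stack mean and `Θ` solves
  `argmin −log det Θ + tr(SΘ) + λ‖Θ‖₁(off-diagonal)` over block-Toeplitz
  positive-definite matrices, by ADMM: a closed-form eigenvalue update for
  the smooth part, a consensus step that averages entries along each
  Toeplitz block diagonal and soft-thresholds off-diagonal entries, and a
  scaled dual update with residual balancing (the penalty parameter doubles
  or halves whenever the primal and dual residuals diverge by 10×, which
  prevents stalls at extreme `λ`). Convergence: both residual norms below
  1e-5, cap 1000 iterations. The returned matrix is the consensus iterate
  — exactly block-Toeplitz — ridge-shifted to a minimum eigenvalue of 1e-6
  if needed (the identity is block-Toeplitz, so the shift preserves
  structure). The empirical covariance receives a ~1e-6 relative ridge so
  clusters holding fewer windows than dimensions remain workable.

Labels are initialised by a diagonal-covariance Gaussian mixture on the
stacked windows (seeded; the seed is the fit's only randomness). Empty
clusters are reseeded deterministically from the worst-fitting windows.
Because the inner ADMM is inexact, a late EM step can raise the penalised
objective by ~1e-4 relative; the fitter treats any uphill step as
convergence and rolls back to the previous iterate, so the reported
objective path is non-increasing by construction.

Model selection: `BIC = −2·loglik + κ·log(#windows)` with `κ` the number
of upper-triangle precision entries exceeding 1e-4 in magnitude plus the
`d·w` means per cluster, minimised over candidate `k`.

Defaults are `k = 5`, `w = 20` (the study conditions) with
`λ = 0.11` and `β = 400·d`. Neither `λ` nor `β` is anchored by a published
value; both are mandatory, logged settings. `β` trades temporal coherence
against responsiveness and must be scaled to the problem: on short turn
windows at 50 Hz the `400·d` default effectively forbids switching, and
the validation runs use `β` in the 50–250 range with `w = 5`.

## Interpretation

A cluster's channel-level dependency graph takes
`weight(u, v) = max_lag |Θ_block(lag)[u, v]|` and keeps edges above
`edge_eps = 1e-3` of the maximum weight — the MRF lives on `d·w` nodes, so
a lag-aggregation rule is unavoidable; max-over-lags is the most
conservative (an interaction at any depth counts). Node importance is
unweighted shortest-path betweenness divided by the per-cluster maximum,
so each cluster's top channel scores exactly 1; a graph with no
betweenness mass (complete or edgeless) scores all zeros. Ranking ties
follow the frozen channel order.

State compositions run-length-encode the cluster labels across a turn
window; the *early* phase is `[pair_epoint − q, pair_epoint]` — the first
half of the manoeuvre, where the behavioural decision is made (the second
half of a C-shaped turn is largely unpowered gliding). Per-state `Fdis`
is averaged per maximal single-label segment first, then across segments,
so long dwells do not swamp the statistic.

## The synthetic two-fish generator

The simulator scripts two fish on the annulus in polar coordinates:
tangential speed `v̄ = 0.14 m/s` (≈4.2 BL/s) with square-wave burst-glide
modulation (period 0.8 s, glide depth 0.35, shared phase — schooling fish
synchronise bursts), radial position mean-reverting to the centreline with
small per-fish wobble, and hard clipping at `BL/2` off either wall.

Each scripted pairwise turn gives the leader and follower raised-cosine-
family angular-velocity reversals of duration `τ = 0.4` s centred
`lag/2` before and after the pair turning moment, so per-fish Epoints,
the pairwise Epoint and the reversal lag are exact by construction. The
direction factor is a *cubed* cosine: its flat zero crossing keeps the
tangential velocity near zero for a few frames around the turning moment,
so the sampled heading visibly passes through the wall normal (a plain
raised cosine at full speed sweeps through in under one frame at 50 Hz and
the sampled alignment degree never reaches its dip). A radial velocity
pulse during the reversal makes the mid-turn motion exactly wall-normal.
Default lags are the two templates' observed group turning times
(0.8496 s dominated, 1.6775 s non-dominated), since the group turning
time equals the reversal lag by construction.

Leadership geometry follows from the leader rule: across a direction
reversal, a *fixed* leader requires the pair's angular order to swap, and
a leadership *switch* requires it to be preserved. The dominated template
(spacing ≈ 2.5 BL, full speed, leader reverses first) lets the natural
counter-rotation during the lag carry the pair past each other; the
non-dominated template (spacing ≈ 1 BL) sustains a near-stop (5% of
cruise) across the reversal core so almost no relative angular motion
accrues and the order — hence the switch — is preserved. Before the core,
while the pair is still co-directional (relative drift-free), the
non-dominated manoeuvre unfolds in heterogeneous phases: repeated
stop-and-go hesitation dips, then a moderate-speed leg during which both
fish drift ~4 mm toward the outer wall — the close-range, multi-factor
adjustment that makes these turns complex. After each turn a gentle
antisymmetric angular-speed nudge (solved exactly on the frame grid, and
bounded well below the cruise angular speed so it can never create a
spurious reversal) restores the spacing required by the next scripted
turn.

Measurement degradation is applied last: i.i.d. Gaussian jitter
(default σ = 0.5 mm per coordinate) and, with probability 0.001 per frame,
a single-frame outlier displaced 3–6 BL in a uniform direction (the "Z"
tracking artefact). Output is bit-reproducible given the seed.

**What the simulator does not emulate:** body bending (fish are rigid
rods), hydrodynamic interaction, identity swaps or tracking gaps, the
trapezoidal tank's perspective distortion, more than two fish, and any
behavioural variability beyond the scripted templates — real turns vary in
shape and timing where the templates are exact. Passing tests therefore
establish that the *analysis* is correct on data whose ground truth is
known, not that real fish behave like the templates.

## Validation problem sizes

The test-suite and acceptance-script runs use sizes chosen to exercise
every code path at interactive cost: detector recall over 100 noise-free
40 s single-turn recordings with uniformly random starting angles
(turns landing within `2p` frames of the branch cut are excluded from
recall and reported separately, with ten steered-onto-the-cut
constructions verifying the `"Ln <= 2p"` reason code); classification over
~220 turns spanning lags 0.6–1.0 s / 1.4–1.9 s and spacings 2–4 BL /
0.8–1.3 BL; clustering validation on a three-channel two-regime Gaussian
series (equicorrelated +0.8 vs a −0.8 chain, four 200-frame segments,
`w = 5`) with BIC selection over `k ∈ {1..4}` across 20 replicates; and
end-to-end compositions from two 120 s recordings (eight turns), fitted
at `k = 4, w = 5, β = 150` with a three-seed multi-start keeping the best
penalised objective. The 32-turn census is scripted with 14 dominated and
18 non-dominated manoeuvres.

## Known limitations

* Displacement-based headings make `ald` unreliable when a fish is nearly
  stopped under noise; group turning times of noisy stop-and-go turns are
  sometimes flagged undefined rather than estimated.
* TICC is non-convex: different initialisations can reach different local
  optima, which is why fits are seeded, multi-start is available, and the
  penalised objective is reported.
* The detector cannot test segments shorter than `2p` frames; turns whose
  apex falls that close to the angle branch cut are missed by design.
* `λ` and `β` have no published anchors; conclusions that depend on them
  should be checked across a range, and both are logged with every run.
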