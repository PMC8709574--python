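# Methods

`neurophen` implements four analysis stages used in developmental /
behavioral phenotyping of mice, plus seeded generators that produce inputs
with known ground truth for each stage. This note records the models, the
conventions and tie-breaks, the parameters that matter, and what the
synthetic data do and do not emulate.

## Coordinate and unit conventions

Swim trajectories are pool-centered Cartesian centimetres, y up, time in
seconds with t[0] shifted to 0. The water maze is a 170 cm circular pool
with a 12 cm platform, an 8 cm outer (thigmotaxis) ring along the wall, and
a 30 cm focal zone centered on the platform. Points up to 1 cm outside the
pool are tolerated as tracking jitter; beyond that the reader raises rather
than clipping silently. SWC reconstructions are in micrometres,
whitespace-delimited, 1-based ids, `#` comments, unknown structure codes
accepted. Milestone scores are integers on P1–P21.

## Swim-strategy classification

Each trial is resampled to a uniform grid no coarser than 0.2 s and reduced
to distance-weighted zone fractions: every path step's length is attributed
to the zone containing its **start** point, with boundary points belonging
to the inner / left-closed zone. This attribution makes the conservation
identities exact (outer + inner ring fractions sum to 1; the four quadrant
fractions sum to 1), which the tests assert to 1e-9.

Features per trial:

* `frac_outer_ring`, `frac_inner_area` — distance shares inside/outside the
  8 cm wall ring (boundary at r = 77 cm for the default pool);
* `frac_corridor` — share inside the *goal corridor*: the angular sector of
  half-angle 20° from the release point toward the platform centre,
  truncated at the platform distance plus the focal-zone radius. The
  truncation matters: an infinite wedge seen from a release point on the
  far wall covers much of the pool interior and stops discriminating
  goal-directed swimming;
* `frac_focal_zone`, and the post-entry statistics: the fraction of total
  distance swum after the first entry into the focal zone, and the in-focal
  share of that stretch;
* `frac_per_quadrant` (time-ordered, left-closed quadrant boundaries; a
  sample exactly on an axis belongs to the counter-clockwise quadrant);
* `heading_efficiency` — net radial progress toward the platform divided by
  path length, clipped at 0;
* `circularity` — |net angular sweep| / total angular sweep about the pool
  centre: 1 for consistent circling, near 0 for a random walk;
* `end_platform_distance` — distance from the final sample to the platform
  centre (whether the trial ended in an escape).

Classification applies the most specific rule first — DSw, FS, DS, Tt, Ch,
Sc, RS, else Unclassified — because a direct swim trivially satisfies the
looser inner-area rules. The rules at default thresholds:

| label | rule |
|---|---|
| DSw (direct swim) | corridor fraction > 0.80 **and** heading efficiency > 0.70 |
| FS (focal search) | after first focal-zone entry: > 50% of the remaining distance is in-zone **and** that stretch covers > 50% of total distance |
| DS (directed search) | corridor fraction > 0.60 **and** the trial ends on the platform (within platform radius + 2 cm) |
| Tt (thigmotaxis) | outer-ring fraction > 0.70 |
| Ch (chaining) | circularity > 0.70 and mean swim radius within 25% of pool radius of the platform's distance from the centre |
| Sc (scanning) | inner-area fraction > 0.80, no quadrant > 0.50, circularity ≤ 0.70, focal-zone fraction > 0.10 |
| RS (random swim) | inner-area fraction > 0.80 (balanced-but-unstructured remainder) |

Design choices that resolve ambiguities in the published rule set:

* **FS dominance guard.** A bare "post-approach distance mostly in the
  focal zone" rule captures *every* trajectory that ends on the platform,
  because the final approach is trivially in-zone; requiring the post-entry
  stretch to dominate the trial restricts FS to genuine focal searching.
* **DS goal gate.** With the truncated 20° corridor, release points far
  from the platform still yield corridor fractions above 0.6 for scanning
  paths; requiring the escape to have actually happened separates directed
  search (a goal-reaching strategy) from exploration.
* **DSw heading gate.** The corridor contains the focal zone near its far
  end, so focal search can exceed 0.8 corridor fraction; direct swims are
  additionally required to be efficient (heading efficiency > 0.7).
* **Sc/RS split.** Both require > 0.80 inner-area distance. Scanning
  additionally requires quadrant balance (no quadrant above 0.50 —
  resolving the garbled double negative in the published wording as "no
  quadrant exceeds half the distance"), a non-circular trajectory, and
  focal-zone coverage above 0.10, i.e. clearly above the ~3% areal chance
  level. All four cut-offs are `StrategyThresholds` fields.
* Chaining is excluded from both strategy blocks; the block definition
  names six strategies and chaining is not among them.

**Blocks.** Block 1 = {Tt, RS, Sc}, Block 2 = {DS, FS, DSw}. A block is
*established* at the first run of ≥ `min_block_run` (default 3) consecutive
same-block trials, applies from the first trial of that run, and persists —
through block-less trials and relapses shorter than a qualifying run —
until the other block is established by the same rule. Equivalently: the
block in force at trial *t* is that of the qualifying run with the largest
start index ≤ *t*. The implementation uses an event scan; the test oracle
uses the window formulation; they agree on every sequence over
{Block 1, Block 2, none} up to length 8 (9 840 sequences, exhaustive).

**Zone occupancy.** Reversal-probe quadrant times, open-field centre
occupancy (11 × 11 cm centre of a 43.2 cm arena) and plus-maze arm times
all use the same step-start attribution; occupancy is reported as percent
time and percent distance per named zone plus mean velocity.

## LFP multitaper spectra and coherence

Recordings (nominally 1000 Hz, 100 s per site) are cut into non-overlapping
1-s segments, each demeaned (no further detrending or notch; acquisition
filtering is assumed done upstream). Each segment is multiplied by K = 5
unit-energy DPSS tapers with time–bandwidth NW = 3 (the common toolbox
default; the resolution half-bandwidth is NW / T = 3 Hz). Auto- and
cross-spectra are averaged over **all tapers and segments**, then

    C_ab(f) = |S_ab(f)|² / (S_aa(f) · S_bb(f)).

This pooled estimator has a null bias of ≈ 1/(segments × tapers) = 0.002 at
the protocol size. The variant that forms a coherence per segment and
averages those (`average="per_segment"`) is retained as an option but
carries a ≈ 1/K = 0.2 bias under independence and is not the default. The
cross-spectrum is accumulated in explicit real arithmetic so that
`mt_coherence(a, b)` and `mt_coherence(b, a)` are bit-identical.

PSD is 10·log10 of the taper- and segment-averaged power, with one-sided
scaling chosen so the linear-scale PSD sums to the demeaned signal's mean
square (discrete Parseval; verified to 5%). A 1e-20 floor (with a warning)
prevents −∞ on near-silent bins; an all-zero signal is an error. Absolute
PSD level depends on amplifier gain and referencing; coherence is invariant
to per-channel scaling (asserted to 1e-9).

Frequency grid: 1 Hz spacing (1-s segments, no zero padding), restricted to
1–90 Hz. Bands: delta 1–4, theta 4–12, beta 12–20, low gamma 20–40, high
gamma 40–90 Hz, half-open [low, high) with the final band closed at 90 Hz,
so each shared edge belongs to exactly one band. PSD band means are
averaged on the linear scale, then converted to dB.

**Resolution caveat.** With a 3 Hz bandwidth, coherence estimates within
3 Hz of a spectral edge are smeared: for a source confined to 4–12 Hz at
per-bin SNR 1 (true in-band MSC = 0.25) the bins at 4–6 and 10–11 Hz are
biased low and the adjacent out-of-band bins slightly high, while the
resolved interior (7–9 Hz) recovers 0.25. Closed-form recovery is therefore
validated on the resolved interior of the source band; band summaries are
reported with the literal band convention.

## Neurite morphometry

* **Total length** — sum of Euclidean parent–child segment lengths;
  segments with both endpoints soma-coded are excluded unless requested.
* **Sholl profile** — spheres (for planar traces with constant z these are
  the classical circles) centered on the soma node, radii at multiples of
  20 µm extending one increment past the maximal extent (so the profile
  ends in a 0 unless an intersection falls at the last radius). A segment
  is counted once per transversal crossing. Distance to a fixed centre is
  convex along a straight segment, so a segment with both endpoints outside
  may dip inside and cross **twice**; this case is solved geometrically
  (interior minimum vs radius). Tie rules: an endpoint exactly on the
  sphere counts with the outward-going segment only; tangency never counts.
  Sholl circles are centered on the soma node (the root for multi-node
  somas) — the alternative, the primary-dendrite origin, is not used.
  Agreement with a dense-sampling oracle (sign changes of d − r at 0.01 µm
  steps) is exact on random trees; rigid motions leave profiles unchanged.
* **Branching complexity** — branch points (≥ 2 children), tips (leaves),
  and maximal branch order (bifurcations passed from the root; an
  unbranched cable has order 0).
* **Laminar reach** — a DCX⁺ cell is *long* iff its maximal radial node
  distance from the soma strictly exceeds the IML / M-OML boundary, else
  *short*; exactly on the boundary is short. Cells not reaching past the
  GCL/IML boundary are flagged unclassifiable. Boundaries are supplied per
  cell as radial distances (they are read from the image in practice, not
  inferred from the trace).
* **Density** — marker-positive count divided by region area (cells/mm²).

## Milestone scoring

Daily scores (binary 0/1 or graded 0–3, eye opening 0–2) per animal × test
over P1–P21; a gap inside an animal's observation window is an error. A day
qualifies when its score reaches the test's criterion; maturity is
registered on the **final** day of the first run of the required length
(the day the criterion is first satisfied in full; `run_convention="first"`
gives the run's first day instead). Tests whose protocol demands "3
consecutive days" (surface righting, negative geotaxis, cliff aversion, air
righting, rooting, ear twitch, auditory startle, open-field traversal) use
a 3-day rule; walking, grasping, postural reflex, wire suspension and eye
opening (criterion: both eyes open, score 2) register on the first
qualifying day. All rules are data (`MaturityRule`) and overridable via the
CLI rules file.

Group summaries report the median maturity day (even-n convention: mean of
the middle pair) over animals that reached maturity, with non-reachers
counted separately. The Mann-Whitney U statistic is computed by direct pair
counting (a < b pairs plus half the ties), reported as
min(U, n₁n₂ − U); p-values are left to standard statistical software. The
raw statistic satisfies U(a,b) + U(b,a) = n₁n₂ exactly, and the
implementation is cross-checked against an independent library routine in
the tests.

## Synthetic data: what it emulates, and what it does not

Every generator is a pure function of (parameters, seed) — one fresh
pseudorandom stream per call, no global state — and attaches the ground
truth the analysis stage should recover.

* **Swim paths** (0.1 s steps, 20 cm/s, 120 s trial limit, release 5 cm off
  the wall at a compass point): thigmotaxis = mean-reverting wall-following
  with occasional direction reversals; random swim = reflected correlated
  random walk over the central area; scanning = waypoint tours of the four
  quadrants in randomised order, the platform quadrant's waypoint being a
  2 s visit to the focal zone; chaining = consistent circling at the
  platform's distance from the pool centre; directed search = zigzag whose
  angular offset oscillates slightly beyond the corridor edge (corridor
  share lands between the 0.6 and 0.8 cut-offs); focal search = direct
  approach then a mean-reverting search inside the focal zone; direct swim
  = near-straight path with small heading noise. Goal strategies terminate
  on the platform; exploratory ones run the full trial. These are
  geometric signatures, not locomotor dynamics: no swim-speed variability,
  floating, or wall-climbing, so classifier recovery on them bounds only
  the geometry of the rules, not tracker noise robustness.
* **LFP pairs**: x = s + n₁, y = α·s + n₂ with s white Gaussian noise
  shaped in the frequency domain to the source band (half-open on the FFT
  grid) and n independent unit-variance white noise; the source's per-bin
  in-band power is SNR × the noise's per-bin power, so the
  magnitude-squared coherence has the closed form
  α²γ_aγ_b / ((1+γ_a)(1+α²γ_b)) in-band — (γ/(1+γ))² = 0.25 at α = 1,
  γ = 1 — and 0 outside. No 1/f spectrum, line noise, or nonstationarity.
* **Neuron trees**: a straight radial trunk plus branches fanning outward
  (directions constrained to a positive radial component, so soma distance
  is monotone along every branch); total length is exact by construction
  and the Sholl profile of the planned geometry is analytic. A separate
  generic random-tree generator (no ground truth) exercises the oracles,
  including re-entrant double crossings.
* **Milestone tables**: per-animal maturity days drawn from a base
  distribution (default mass on P6–P10), the second group shifted by a
  whole number of days; base days are shared across groups so the median
  difference recovers the shift exactly in the noise-free case. Scores are
  built so the first qualifying run ends exactly on the drawn day; the
  noise model adds isolated premature successes that can never form a
  qualifying run under multi-day rules.

## Problem sizes and numerical choices

Default validation sizes: 100 × 1-s segments per coherence estimate, 200
generated trials per strategy, exhaustive block sequences to length 8,
100 random trees against the 0.01 µm Sholl oracle, 500 random sample pairs
for the U statistic — sizes at which every stochastic check has a wide
margin while the whole suite runs in seconds. Numerical guards: PSD floor
1e-20 before log; coherence clipped to [0, 1] against round-off; zero-power
segments, stationary trials, zero-duration paths, empty groups and
degenerate (all-zero) signals are errors, not NaNs.

## Known limitations

* The strategy thresholds beyond the four published cut-offs (corridor
  half-angle, chaining radius tolerance, scanning focal minimum, FS/DSw
  gates) are package choices; on real tracker exports they may need
  adjustment, which is why they are all explicit `StrategyThresholds`
  fields.
* Coherence group statistics (per-frequency inference across animals) are
  out of scope; the package computes the estimator only.
* PSD absolute level is gain-dependent; only relative/band structure is
  meaningful without amplifier calibration.
* SWC input is trusted to be a faithful trace; no image processing or
  tracing correction is attempted.
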