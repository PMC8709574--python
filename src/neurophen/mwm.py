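"""Swim-strategy classification for the Morris water maze.

Each trial's trajectory is reduced to a vector of geometric features
(distance fractions in pool zones, corridor occupancy, heading efficiency,
angular-progression circularity) and classified by a deterministic rule
cascade into one of seven named search strategies:

====  =======================  =====
code  strategy                 block
====  =======================  =====
Tt    thigmotaxis              1
RS    random swim              1
Sc    scanning                 1
Ch    chaining                 --
DS    directed search          2
FS    focal search             2
DSw   directed swim            2
====  =======================  =====

Block 1 groups the non-hippocampal-dependent strategies, Block 2 the
hippocampal-dependent ones; across a trial sequence a block is *established*
by the first run of at least ``min_block_run`` consecutive same-block trials
and persists until the other block is established the same way.

Rule thresholds follow the published scheme: thigmotaxis when >70% of swim
distance falls in the 8-cm outer ring; random swim / scanning when >80%
falls in the inner area; directed search when >60% of distance lies in the
platform corridor; direct swim when >80% does.  Because a direct swim also
satisfies the looser rules, classification applies the most specific rule
first: DSw, FS, DS, Tt, Ch, Sc, RS, else Unclassified.

Zone attribution convention: every path step's length is attributed to the
zone containing its *start* point; boundary points belong to the inner /
left-closed zone.  This makes all fractions exactly conserved
(outer + inner = 1; quadrant fractions sum to 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from shapely.geometry import Point

from .datamodel import ArenaGeometry, PoolGeometry, SwimTrial, resample_path

STRATEGY_LABELS = ("Tt", "RS", "Sc", "Ch", "DS", "FS", "DSw", "Unclassified")
BLOCK1_LABELS = frozenset({"Tt", "RS", "Sc"})
BLOCK2_LABELS = frozenset({"DS", "FS", "DSw"})


def block_of(label: str) -> int | None:
    """Strategy-block membership: 1, 2 or None (Ch / Unclassified)."""
    if label in BLOCK1_LABELS:
        return 1
    if label in BLOCK2_LABELS:
        return 2
    return None


@dataclass(frozen=True)
class StrategyThresholds:
    """Decision thresholds of the strategy cascade.

    The first four fractions are the published cut-offs (>70% outer ring for
    thigmotaxis, >80% inner area for random swim / scanning, >60% / >80%
    corridor distance for directed search / direct swim).  The remaining
    parameters resolve rule overlaps the published scheme leaves open and
    are documented in the methods note.
    """

    thigmotaxis_outer_fraction: float = 0.70
    inner_area_fraction: float = 0.80
    corridor_fraction_directed: float = 0.60
    corridor_fraction_direct: float = 0.80
    corridor_half_angle: float = 20.0
    quadrant_balance_max: float = 0.50
    min_block_run: int = 3
    # cascade disambiguation parameters
    dsw_min_heading_efficiency: float = 0.70
    focal_post_entry_fraction: float = 0.50
    focal_dominance_fraction: float = 0.50
    chaining_circularity: float = 0.70
    chaining_radius_rel_tol: float = 0.25
    scanning_focal_min: float = 0.10
    platform_reach_tolerance: float = 2.0

    def __post_init__(self) -> None:
        for name in (
            "thigmotaxis_outer_fraction",
            "inner_area_fraction",
            "corridor_fraction_directed",
            "corridor_fraction_direct",
            "quadrant_balance_max",
        ):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        if self.min_block_run < 1:
            raise ValueError("min_block_run must be >= 1")


@dataclass(frozen=True)
class TrialFeatures:
    """Per-trial geometric feature vector.

    All ``frac_*`` quantities are proportions of total swim distance.
    ``heading_efficiency`` is the net progress toward the platform divided
    by path length (clipped at 0).  ``circularity`` is |net angular sweep| /
    total angular sweep about the pool centre, 1 for consistent circling.
    ``post_entry_*`` describe the stretch after the first entry into the
    focal zone and feed the focal-search rule.
    """

    frac_outer_ring: float
    frac_inner_area: float
    frac_corridor: float
    frac_focal_zone: float
    frac_per_quadrant: tuple[float, float, float, float]
    heading_efficiency: float
    circularity: float
    path_length: float
    latency: float
    mean_radius: float = 0.0
    post_entry_focal_frac: float = 0.0
    post_entry_dist_frac: float = 0.0
    end_platform_distance: float = 0.0


@dataclass(frozen=True)
class StrategyCall:
    """A classified trial: label, block membership, and its features."""

    label: str
    block: int | None
    features: TrialFeatures

    def __post_init__(self) -> None:
        if self.label not in STRATEGY_LABELS:
            raise ValueError(f"unknown strategy label {self.label!r}")
        if self.block != block_of(self.label):
            raise ValueError(f"label {self.label} cannot carry block {self.block}")


# --------------------------------------------------------------------------
# Feature extraction
# --------------------------------------------------------------------------


def zone_fractions(
    trial: SwimTrial,
    geometry: PoolGeometry | None = None,
    max_dt: float = 0.2,
    corridor_half_angle: float = 20.0,
) -> TrialFeatures:
    """Compute the full feature vector for one trial.

    The trial is resampled to a uniform grid no coarser than ``max_dt``
    seconds first, so fractions are robust to the tracker's frame rate.
    Raises ``ValueError`` for a stationary trial (zero path length).
    """
    geometry = geometry or trial.geometry
    dts = np.diff(trial.t)
    if dts.size == 0:
        raise ValueError("stationary trial: no movement samples")
    if dts.max() > max_dt + 1e-9:
        trial = resample_path(trial, max_dt)

    x, y = trial.x, trial.y
    step = np.hypot(np.diff(x), np.diff(y))
    total = float(step.sum())
    if total <= 0:
        raise ValueError("stationary trial: zero total path length")

    # start point of each step carries its length
    sx, sy = x[:-1], y[:-1]
    r = np.hypot(sx, sy)

    inner = r <= geometry.inner_radius  # boundary belongs to the inner area
    frac_inner = float(step[inner].sum() / total)
    frac_outer = float(step[~inner].sum() / total)

    px, py = geometry.platform_center
    d_platform = np.hypot(sx - px, sy - py)
    in_focal = d_platform <= geometry.focal_zone_radius
    frac_focal = float(step[in_focal].sum() / total)

    # platform corridor: angular sector of half-angle `corridor_half_angle`
    # from the release point toward the platform centre, truncated at the
    # platform distance plus the focal-zone radius (the goal corridor, not
    # an infinite wedge); the release point itself counts as inside
    x0, y0 = x[0], y[0]
    bearing = math.atan2(py - y0, px - x0)
    ang = np.arctan2(sy - y0, sx - x0) - bearing
    ang = np.abs((ang + np.pi) % (2 * np.pi) - np.pi)
    dist_from_start = np.hypot(sx - x0, sy - y0)
    at_start = dist_from_start < 1e-9
    reach = math.hypot(px - x0, py - y0) + geometry.focal_zone_radius
    in_corridor = (
        (ang <= math.radians(corridor_half_angle)) & (dist_from_start <= reach)
    ) | at_start
    frac_corridor = float(step[in_corridor].sum() / total)

    quad = geometry.quadrant_of(sx, sy)
    frac_quad = tuple(float(step[quad == q].sum() / total) for q in range(4))

    d0 = math.hypot(x0 - px, y0 - py)
    d_end = math.hypot(x[-1] - px, y[-1] - py)
    heading_eff = max(0.0, (d0 - d_end) / total)

    theta = np.unwrap(np.arctan2(y, x))
    dtheta = np.diff(theta)
    sweep = float(np.abs(dtheta).sum())
    circ = float(abs(dtheta.sum()) / sweep) if sweep > 1e-12 else 0.0

    # focal-search evidence: distance after the first focal-zone entry
    entry = np.nonzero(in_focal)[0]
    if entry.size:
        i0 = int(entry[0])
        post = float(step[i0:].sum())
        post_focal = float(step[i0:][in_focal[i0:]].sum())
        post_entry_dist_frac = post / total
        post_entry_focal_frac = post_focal / post if post > 0 else 0.0
    else:
        post_entry_dist_frac = 0.0
        post_entry_focal_frac = 0.0

    mean_radius = float((r * step).sum() / total)

    return TrialFeatures(
        frac_outer_ring=frac_outer,
        frac_inner_area=frac_inner,
        frac_corridor=frac_corridor,
        frac_focal_zone=frac_focal,
        frac_per_quadrant=frac_quad,
        heading_efficiency=heading_eff,
        circularity=circ,
        path_length=total,
        latency=trial.duration,
        mean_radius=mean_radius,
        post_entry_focal_frac=post_entry_focal_frac,
        post_entry_dist_frac=post_entry_dist_frac,
        end_platform_distance=d_end,
    )


# --------------------------------------------------------------------------
# Classification cascade
# --------------------------------------------------------------------------


def classify_trial(
    features: TrialFeatures,
    thresholds: StrategyThresholds | None = None,
    geometry: PoolGeometry | None = None,
) -> StrategyCall:
    """Label one trial by the most-specific-first rule cascade.

    Order: DSw, FS, DS, Tt, Ch, Sc, RS, Unclassified.  Total function: every
    valid feature vector receives exactly one label.
    """
    th = thresholds or StrategyThresholds()
    geo = geometry or PoolGeometry()
    f = features

    label = "Unclassified"
    if (
        f.frac_corridor > th.corridor_fraction_direct
        and f.heading_efficiency > th.dsw_min_heading_efficiency
    ):
        label = "DSw"
    elif (
        f.post_entry_dist_frac > th.focal_dominance_fraction
        and f.post_entry_focal_frac > th.focal_post_entry_fraction
    ):
        label = "FS"
    elif (
        f.frac_corridor > th.corridor_fraction_directed
        and f.end_platform_distance <= geo.platform_radius + th.platform_reach_tolerance
    ):
        label = "DS"
    elif f.frac_outer_ring > th.thigmotaxis_outer_fraction:
        label = "Tt"
    elif (
        f.circularity > th.chaining_circularity
        and abs(f.mean_radius - _platform_radius_from_center(geo))
        <= th.chaining_radius_rel_tol * geo.pool_radius
    ):
        label = "Ch"
    elif f.frac_inner_area > th.inner_area_fraction:
        balanced = max(f.frac_per_quadrant) <= th.quadrant_balance_max
        if (
            balanced
            and f.circularity <= th.chaining_circularity
            and f.frac_focal_zone > th.scanning_focal_min
        ):
            label = "Sc"
        else:
            label = "RS"
    return StrategyCall(label=label, block=block_of(label), features=f)


def _platform_radius_from_center(geometry: PoolGeometry) -> float:
    px, py = geometry.platform_center
    return math.hypot(px, py)


def classify_trials(
    trials: Iterable[SwimTrial],
    thresholds: StrategyThresholds | None = None,
) -> list[StrategyCall]:
    """Feature extraction + classification over an ordered trial sequence."""
    th = thresholds or StrategyThresholds()
    return [
        classify_trial(
            zone_fractions(t, corridor_half_angle=th.corridor_half_angle),
            th,
            t.geometry,
        )
        for t in trials
    ]


# --------------------------------------------------------------------------
# Block segmentation
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class BlockTimeline:
    """Result of block segmentation across an ordered trial sequence.

    ``established`` holds, per trial, the block in force (1, 2 or None);
    ``onsets`` maps each block to the 0-based index of the first trial of
    its first qualifying run (absent if never established); ``lengths``
    counts trials spent under each established block.
    """

    established: tuple[int | None, ...]
    onsets: dict[int, int]
    lengths: dict[int, int]


def assign_blocks(
    calls: Sequence[StrategyCall | str | int | None],
    thresholds: StrategyThresholds | None = None,
) -> BlockTimeline:
    """Segment a trial sequence into strategy blocks.

    A block is established at the first run of >= ``min_block_run``
    consecutive trials belonging to the same block, and then persists —
    through block-less trials and short relapses — until the *other* block
    is established by the same run rule.  The established block is applied
    from the first trial of the qualifying run onward.

    ``calls`` may hold :class:`StrategyCall` objects, strategy labels, or
    block values (1, 2, None) directly.
    """
    th = thresholds or StrategyThresholds()
    blocks = [_as_block(c) for c in calls]
    if not blocks:
        raise ValueError("need at least one trial")
    k = th.min_block_run
    n = len(blocks)

    timeline: list[int | None] = []
    onsets: dict[int, int] = {}
    current: int | None = None
    # establishment events: run of >= k same-block trials for a block other
    # than the current one
    events: list[tuple[int, int]] = []  # (start index, block)
    for s in range(n):
        b = blocks[s]
        if b is None:
            continue
        if s + k <= n and all(blocks[j] == b for j in range(s, s + k)):
            if not events or events[-1][1] != b:
                events.append((s, b))
    # events are only switches if they change the in-force block
    pos = 0
    current = None
    for start, b in events:
        if b == current:
            continue
        timeline.extend([current] * (start - pos))
        pos = start
        current = b
        if b not in onsets:
            onsets[b] = start
    timeline.extend([current] * (n - pos))

    lengths = {
        1: sum(1 for b in timeline if b == 1),
        2: sum(1 for b in timeline if b == 2),
    }
    return BlockTimeline(established=tuple(timeline), onsets=onsets, lengths=lengths)


def _as_block(call) -> int | None:
    if call is None or isinstance(call, int):
        return call
    if isinstance(call, StrategyCall):
        return call.block
    if isinstance(call, str):
        if call in STRATEGY_LABELS:
            return block_of(call)
        raise ValueError(f"unknown strategy label {call!r}")
    raise TypeError(f"cannot interpret {call!r} as a block")


# --------------------------------------------------------------------------
# Zone occupancy (reversal quadrants, open field, plus maze)
# --------------------------------------------------------------------------


def reversal_quadrant_times(
    trial: SwimTrial,
    geometry: PoolGeometry,
    old_platform: tuple[float, float],
    new_platform: tuple[float, float],
) -> tuple[float, float]:
    """Percent time in the new- and old-platform quadrants (reversal probe).

    Occupancy is time-weighted: each inter-sample interval is attributed to
    the quadrant of its start sample.  The four quadrant percentages sum to
    100.  Raises ``ValueError`` if both platforms sit in the same quadrant.
    """
    q_old = int(geometry.quadrant_of(*old_platform))
    q_new = int(geometry.quadrant_of(*new_platform))
    if q_old == q_new:
        raise ValueError("old and new platform lie in the same quadrant")
    dt = np.diff(trial.t)
    quad = geometry.quadrant_of(trial.x[:-1], trial.y[:-1])
    total = float(dt.sum())
    if total <= 0:
        raise ValueError("zero-duration trial")
    pct = [100.0 * float(dt[quad == q].sum()) / total for q in range(4)]
    return pct[q_new], pct[q_old]


def zone_occupancy(
    t: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    arena: ArenaGeometry,
    tolerance: float = 1.0,
) -> dict:
    """Per-zone occupancy (percent time, percent distance) and mean velocity.

    Works for any polygonal arena with named zones (open-field centre,
    plus-maze arms...).  Points are attributed by step start; the path must
    stay within the arena boundary plus ``tolerance`` cm.
    """
    t = np.asarray(t, float)
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if t.size < 2:
        raise ValueError("need at least two samples")
    duration = float(t[-1] - t[0])
    if duration <= 0:
        raise ValueError("zero-duration path")
    boundary = arena.arena_polygon.buffer(tolerance)
    for i in range(t.size):
        if not boundary.covers(Point(x[i], y[i])):
            raise ValueError(f"sample {i} lies outside the arena (beyond tolerance)")

    dt = np.diff(t)
    step = np.hypot(np.diff(x), np.diff(y))
    total_dist = float(step.sum())
    out = {
        "average_velocity": total_dist / duration,
        "total_distance": total_dist,
        "total_time": duration,
        "zones": {},
    }
    for label in arena.named_zones:
        poly = arena.zone_polygon(label)
        inside = np.array(
            [poly.covers(Point(x[i], y[i])) for i in range(t.size - 1)]
        )
        out["zones"][label] = {
            "pct_time": 100.0 * float(dt[inside].sum()) / duration,
            "pct_distance": (
                100.0 * float(step[inside].sum()) / total_dist if total_dist > 0 else 0.0
            ),
        }
    return out
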