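"""Seeded generators for every pipeline stage, with ground truth attached.

Each generator is a pure function of its parameters and an explicit seed
(one fresh ``numpy.random.Generator`` per call, no global state), and
returns both the simulated input and a :class:`GroundTruth` record carrying
the quantity the corresponding analysis stage should recover:

* swim paths with the geometric signature of a named search strategy,
* LFP channel pairs built as shared band-limited source plus independent
  white noise, so magnitude-squared coherence has the closed form
  C = alpha^2 Ss^2 / ((Ss + N1)(alpha^2 Ss + N2)) in-band and 0 outside,
* SWC neuron trees with exactly known total length and an analytic Sholl
  profile,
* milestone score tables with a known maturity day per animal and an
  optional group shift.

Swim-path defaults emulate the standard mouse protocol: a 170-cm pool,
120-s trial limit, ~20 cm/s swim speed, 0.1-s sampling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    DEFAULT_MILESTONE_RULES,
    LFPRecording,
    MaturityRule,
    MilestoneTable,
    NeuronTree,
    PoolGeometry,
    SwimTrial,
    WEANING_DAY,
)

#: Trial time limit (s) and sampling step (s) for generated swim paths.
TRIAL_LIMIT_S = 120.0
SWIM_DT = 0.1
#: Cruise swim speed for a mouse, cm/s.
SWIM_SPEED = 20.0

GENERATED_STRATEGIES = ("Tt", "RS", "Sc", "Ch", "DS", "FS", "DSw")


@dataclass(frozen=True)
class GroundTruth:
    """What the generator intended, for parameter-recovery testing."""

    generator: str
    seed: int
    labels: dict[str, Any] = field(default_factory=dict)


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


# --------------------------------------------------------------------------
# Swim paths
# --------------------------------------------------------------------------


def gen_swim_path(
    strategy: str,
    geometry: PoolGeometry | None = None,
    seed: int = 0,
    start_position: str = "N",
    speed: float = SWIM_SPEED,
    dt: float = SWIM_DT,
) -> tuple[SwimTrial, GroundTruth]:
    """Generate one trial with the geometric signature of ``strategy``.

    Strategies that find the platform (DS, FS, DSw) terminate on reaching
    it; exploratory strategies (Tt, RS, Sc, Ch) swim for the full 120-s
    trial.  Signatures are generated well inside the classification
    thresholds so that label recovery is expected for almost every seed.
    """
    geometry = geometry or PoolGeometry()
    if strategy not in GENERATED_STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}")
    rng = _rng(seed)
    start = np.array(geometry.start_xy(start_position))
    plat = np.array(geometry.platform_center)

    builders = {
        "Tt": _path_thigmotaxis,
        "RS": _path_random_swim,
        "Sc": _path_scanning,
        "Ch": _path_chaining,
        "DS": _path_directed_search,
        "FS": _path_focal_search,
        "DSw": _path_direct_swim,
    }
    xy = builders[strategy](rng, geometry, start, plat, speed, dt)
    xy = _clip_to_pool(xy, geometry)
    t = dt * np.arange(len(xy))
    trial = SwimTrial(
        trial_id=f"{strategy}-{seed}",
        animal_id=f"sim-{seed}",
        t=t,
        x=xy[:, 0],
        y=xy[:, 1],
        start_position=start_position,
        geometry=geometry,
    )
    gt = GroundTruth("gen_swim_path", seed, {"strategy": strategy})
    return trial, gt


def _clip_to_pool(xy: np.ndarray, geometry: PoolGeometry) -> np.ndarray:
    r = np.hypot(xy[:, 0], xy[:, 1])
    lim = geometry.pool_radius - 0.5
    over = r > lim
    if over.any():
        scale = np.where(over, lim / r, 1.0)
        xy = xy * scale[:, None]
    return xy


def _n_steps(dt: float) -> int:
    return int(round(TRIAL_LIMIT_S / dt))


def _path_thigmotaxis(rng, geo, start, plat, speed, dt):
    """Wall-following: angular drift at a radius deep inside the outer ring,
    with meandering direction reversals so the path is not circular."""
    r_target = geo.pool_radius - 4.0
    n = _n_steps(dt)
    theta = math.atan2(start[1], start[0])
    r = float(np.hypot(*start))
    direction = rng.choice([-1.0, 1.0])
    pts = [start.copy()]
    for i in range(n):
        if rng.random() < 0.01:  # occasional reversal breaks circularity
            direction = -direction
        dtheta = direction * (speed * dt) / r_target * (1 + 0.2 * rng.standard_normal())
        theta += dtheta
        r += 0.5 * (r_target - r) + 0.5 * rng.standard_normal()
        r = min(max(r, geo.inner_radius + 1.0), geo.pool_radius - 0.5)
        pts.append(np.array([r * math.cos(theta), r * math.sin(theta)]))
    return np.array(pts)


def _path_random_swim(rng, geo, start, plat, speed, dt):
    """Reflected correlated random walk over the inner area."""
    n = _n_steps(dt)
    lim = geo.inner_radius - 14.0  # clear of the outer ring and focal zone
    p = start * min(1.0, (lim - 1.0) / max(1e-9, float(np.hypot(*start))))
    heading = rng.uniform(0, 2 * math.pi)
    pts = [p.copy()]
    for _ in range(n):
        heading += 0.6 * rng.standard_normal()
        step = speed * dt * np.array([math.cos(heading), math.sin(heading)])
        q = p + step
        rr = float(np.hypot(*q))
        if rr > lim:  # reflect at the inner-area boundary
            normal = q / rr
            v = step - 2 * (step @ normal) * normal
            q = p + v
            heading = math.atan2(v[1], v[0])
            rr = float(np.hypot(*q))
            if rr > lim:
                q = q * (lim / rr)
        p = q
        pts.append(p.copy())
    return np.array(pts)


def _path_scanning(rng, geo, start, plat, speed, dt):
    """Waypoint walk cycling the four quadrants in randomised order; each
    cycle includes a dwell inside the platform's focal zone, so central
    coverage sits clearly above the area-chance level."""
    n = _n_steps(dt)
    lim = geo.inner_radius - 6.0
    quad_centers = []
    for q in range(4):
        a = math.radians(45 + 90 * q + geo.quadrant_axes_deg)
        quad_centers.append(0.6 * lim * np.array([math.cos(a), math.sin(a)]))
    # focal waypoint: just inside the focal zone, pulled toward the pool
    # centre so it stays within the reflection boundary
    focal_wp = plat * 0.88
    platform_quadrant = int(geo.quadrant_of(*plat))
    p = start * min(1.0, (lim - 1.0) / max(1e-9, float(np.hypot(*start))))
    pts = [p.copy()]
    waypoints: list[tuple[np.ndarray, bool]] = []
    dwell_steps = int(round(2.0 / dt))
    while len(pts) <= n:
        if not waypoints:
            # the platform quadrant's waypoint IS the focal-zone visit, so
            # quadrant coverage stays balanced
            waypoints = [
                (focal_wp + rng.uniform(-3, 3, 2), True)
                if q == platform_quadrant
                else (quad_centers[q] + 5.0 * rng.standard_normal(2), False)
                for q in rng.permutation(4)
            ]
        target, is_focal = waypoints.pop(0)
        guard = 0
        while len(pts) <= n:
            d = target - p
            dist = float(np.hypot(*d))
            guard += 1
            if dist < 3.0 or guard > 400:
                break
            heading = math.atan2(d[1], d[0]) + 0.25 * rng.standard_normal()
            p = p + speed * dt * np.array([math.cos(heading), math.sin(heading)])
            rr = float(np.hypot(*p))
            if rr > lim:
                p = p * (lim / rr)
            pts.append(p.copy())
        if is_focal:
            # brief scan of the focal zone before moving on
            for _ in range(dwell_steps):
                if len(pts) > n:
                    break
                jitter = rng.standard_normal(2)
                p = p + speed * dt * jitter / max(1e-9, float(np.hypot(*jitter)))
                dpf = float(np.hypot(*(p - plat)))
                if dpf > geo.focal_zone_radius - 3.0:
                    p = plat + (p - plat) * (geo.focal_zone_radius - 3.0) / dpf
                pts.append(p.copy())
    return np.array(pts[: n + 1])


def _path_chaining(rng, geo, start, plat, speed, dt):
    """Consistent circling at the platform's distance from the pool centre."""
    n = _n_steps(dt)
    r_target = float(np.hypot(*plat))
    theta = math.atan2(start[1], start[0])
    direction = rng.choice([-1.0, 1.0])
    r = float(np.hypot(*start))
    pts = [start.copy()]
    for i in range(n):
        dtheta = direction * (speed * dt) / max(r_target, 1.0)
        theta += dtheta * (1 + 0.05 * rng.standard_normal())
        r += 0.4 * (r_target - r) + 0.4 * rng.standard_normal()
        pts.append(np.array([r * math.cos(theta), r * math.sin(theta)]))
    return np.array(pts)


def _path_directed_search(rng, geo, start, plat, speed, dt):
    """Zigzag progress toward the platform: the angular offset from the
    start->platform bearing oscillates slightly beyond the corridor edge, so
    corridor occupancy lands between the directed (>60%) and direct (>80%)
    cut-offs."""
    bearing = math.atan2(plat[1] - start[1], plat[0] - start[0])
    dist = float(np.hypot(*(plat - start)))
    amp = math.radians(22.0 + rng.normal(0, 0.5))
    omega = 2 * math.pi / rng.uniform(2.5, 4.0)  # several sweeps per approach
    phase = rng.uniform(0, 2 * math.pi)
    pts = [start.copy()]
    rho = 0.0
    i = 0
    while True:
        i += 1
        # radial progress is slowed by the zigzag detour
        rho = min(dist, rho + 0.25 * speed * dt)
        alpha = amp * math.sin(omega * i * dt + phase)
        a = bearing + alpha
        p = start + rho * np.array([math.cos(a), math.sin(a)])
        pts.append(p)
        if float(np.hypot(*(p - plat))) <= geo.platform_radius or i * dt >= TRIAL_LIMIT_S:
            break
    return np.array(pts)


def _path_focal_search(rng, geo, start, plat, speed, dt):
    """Approach, then a mean-reverting search confined to the focal zone."""
    # approach leg: straight toward the platform
    pts = [start.copy()]
    p = start.copy()
    while float(np.hypot(*(p - plat))) > geo.focal_zone_radius * 0.5:
        d = plat - p
        d = d / float(np.hypot(*d))
        p = p + speed * dt * d
        pts.append(p.copy())
    # focal phase: Ornstein-Uhlenbeck around the platform centre
    n_focal = int(round(30.0 / dt))
    v = np.zeros(2)
    for _ in range(n_focal):
        v = 0.8 * v + 0.6 * speed * dt * rng.standard_normal(2)
        p = p + v + 0.15 * (plat - p) * dt * 10
        d = float(np.hypot(*(p - plat)))
        if d > geo.focal_zone_radius - 2.0:
            p = plat + (p - plat) * (geo.focal_zone_radius - 2.0) / d
        pts.append(p.copy())
    pts.append(plat + np.array([geo.platform_radius * 0.5, 0.0]))
    return np.array(pts)


def _path_direct_swim(rng, geo, start, plat, speed, dt):
    """Near-straight swim to the platform with small heading noise."""
    pts = [start.copy()]
    p = start.copy()
    i = 0
    while float(np.hypot(*(p - plat))) > geo.platform_radius and i * dt < TRIAL_LIMIT_S:
        i += 1
        d = plat - p
        heading = math.atan2(d[1], d[0]) + 0.12 * rng.standard_normal()
        p = p + speed * dt * np.array([math.cos(heading), math.sin(heading)])
        pts.append(p.copy())
    return np.array(pts)


# --------------------------------------------------------------------------
# LFP pairs
# --------------------------------------------------------------------------


def gen_lfp_pair(
    source_band: tuple[float, float] = (4.0, 12.0),
    snr_a: float = 1.0,
    snr_b: float = 1.0,
    alpha: float = 1.0,
    fs: float = 1000.0,
    duration: float = 100.0,
    seed: int = 0,
) -> tuple[tuple[LFPRecording, LFPRecording], GroundTruth]:
    """Two channels sharing a band-limited source: x = s + n1, y = alpha*s + n2.

    The source is white Gaussian noise shaped in the frequency domain so its
    power is confined exactly to ``source_band`` (half-open [low, high) on
    the FFT grid) and its per-bin in-band power equals ``snr`` times the
    per-bin power of each channel's independent unit-variance white noise.
    The ground truth carries the closed-form in-band magnitude-squared
    coherence alpha^2 Ss^2 / ((Ss + N1)(alpha^2 Ss + N2)) — for alpha = 1
    and equal SNRs gamma this is (gamma / (1 + gamma))^2 — and zero
    out-of-band, on a 1-Hz grid over 1-90 Hz.
    """
    if snr_a <= 0 or snr_b <= 0:
        raise ValueError("snr must be positive")
    if fs < 200:
        raise ValueError("fs must be at least 200 Hz")
    if duration < 2:
        raise ValueError("duration must be at least 2 s")
    rng = _rng(seed)
    n = int(round(fs * duration))

    # frequency-domain shaping of white noise onto the source band
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    lo, hi = source_band
    in_band = (freqs >= lo) & (freqs < hi)
    if not in_band.any():
        raise ValueError("source band contains no FFT bins")
    W = np.fft.rfft(rng.standard_normal(n))
    W[~in_band] = 0.0
    s = np.fft.irfft(W, n=n)
    # unit-variance white noise has flat per-bin power; scale the source so
    # its per-bin in-band power is snr times that level
    n_bins = freqs.size
    band_count = int(in_band.sum())
    var_target_a = snr_a * band_count / n_bins  # total source power for channel a
    s = s / s.std()

    sa = s * math.sqrt(var_target_a)
    n1 = rng.standard_normal(n)
    n2 = rng.standard_normal(n)
    # channel b shares the same source waveform; alpha scales the coupling
    # and snr_b fixes the source-to-noise ratio seen by b before alpha
    sb = s * math.sqrt(snr_b * band_count / n_bins)
    x = sa + n1
    y = alpha * sb + n2

    # closed-form coherence on the 1-90 Hz, 1-Hz analysis grid
    grid = np.arange(1.0, 91.0)
    gamma_a = np.where((grid >= lo) & (grid < hi), snr_a, 0.0)
    gamma_b = np.where((grid >= lo) & (grid < hi), snr_b, 0.0)
    a2 = alpha**2
    num = a2 * gamma_a * gamma_b
    den = (gamma_a + 1.0) * (a2 * gamma_b + 1.0)
    theory = np.where(num > 0, num / den, 0.0)

    rec_a = LFPRecording("dHip", x, fs)
    rec_b = LFPRecording("mPFC", y, fs)
    gt = GroundTruth(
        "gen_lfp_pair",
        seed,
        {
            "freqs": grid,
            "coherence": theory,
            "source_band": source_band,
            "alpha": alpha,
            "snr_a": snr_a,
            "snr_b": snr_b,
        },
    )
    return (rec_a, rec_b), gt


# --------------------------------------------------------------------------
# Neuron trees
# --------------------------------------------------------------------------


def gen_neuron_tree(
    n_branches: int = 2,
    trunk_length: float = 50.0,
    branch_length: float | Sequence[float] = 40.0,
    seed: int = 0,
    increment: float = 20.0,
    node_spacing: float = 5.0,
) -> tuple[NeuronTree, GroundTruth]:
    """A soma, a straight radial trunk, and ``n_branches`` straight branches
    fanning outward from the trunk tip.

    Branch directions keep a positive radial component, so the distance from
    the soma is monotone along every branch and the Sholl profile of the
    planned geometry is analytic: 1 crossing per radius within the trunk,
    then one per branch whose tip extends past the radius.  The ground truth
    carries the exact planned total length and that profile.
    """
    if trunk_length <= 0:
        raise ValueError("trunk_length must be positive")
    if n_branches < 0:
        raise ValueError("n_branches cannot be negative")
    lengths = (
        [float(branch_length)] * n_branches
        if np.isscalar(branch_length)
        else [float(v) for v in branch_length]
    )
    if len(lengths) != n_branches:
        raise ValueError("branch_length list must match n_branches")
    if any(v <= 0 for v in lengths):
        raise ValueError("branch lengths must be positive")
    rng = _rng(seed)

    trunk_dir = _random_unit(rng)
    rows = [(1, 1, 0.0, 0.0, 0.0, 1.0, -1)]  # soma at origin
    next_id = 2

    def add_cable(start_xyz, direction, length, parent_id, structure=3):
        nonlocal next_id
        n_seg = max(1, int(math.ceil(length / node_spacing)))
        for k in range(1, n_seg + 1):
            p = start_xyz + direction * (length * k / n_seg)
            rows.append((next_id, structure, p[0], p[1], p[2], 0.5, parent_id))
            parent_id = next_id
            next_id += 1
        return parent_id, start_xyz + direction * length

    tip_id, tip_xyz = add_cable(np.zeros(3), trunk_dir, trunk_length, 1)

    branch_extents = []
    for L in lengths:
        # outward direction: positive component along the soma->tip axis
        d = _random_unit(rng)
        radial = tip_xyz / np.linalg.norm(tip_xyz)
        d = d + 1.2 * radial
        d = d / np.linalg.norm(d)
        _, end = add_cable(tip_xyz, d, L, tip_id)
        branch_extents.append(float(np.linalg.norm(end)))

    df = pd.DataFrame(rows, columns=["id", "structure", "x", "y", "z", "radius", "parent"])
    tree = NeuronTree(nodes=df)

    total = trunk_length + sum(lengths)
    extent = max([trunk_length] + branch_extents)
    n_radii = max(1, int(math.ceil(extent / increment)))
    if abs(extent - n_radii * increment) < 1e-9:
        n_radii += 1
    radii = [increment * (k + 1) for k in range(n_radii)]
    profile = []
    for r in radii:
        if r < trunk_length:
            profile.append(1)
        elif n_branches == 0:
            profile.append(1 if r < trunk_length else 0)
        else:
            profile.append(sum(1 for e in branch_extents if e > r))
    gt = GroundTruth(
        "gen_neuron_tree",
        seed,
        {
            "total_length": total,
            "sholl_radii": radii,
            "sholl_profile": profile,
            "extent": extent,
        },
    )
    return tree, gt


def gen_random_tree(n_nodes: int = 50, seed: int = 0, step: float = 12.0) -> NeuronTree:
    """A generic random tree for oracle-based testing (no ground truth):
    each new node attaches to a uniformly chosen existing node at a random
    offset.  Coordinates are continuous, so sphere tangencies and on-sphere
    endpoints have probability zero."""
    if n_nodes < 1:
        raise ValueError("need at least one node")
    rng = _rng(seed)
    rows = [(1, 1, 0.0, 0.0, 0.0, 1.0, -1)]
    coords = [np.zeros(3)]
    for i in range(2, n_nodes + 1):
        parent = int(rng.integers(1, i))
        p = coords[parent - 1] + rng.normal(0, step, 3)
        rows.append((i, 3, p[0], p[1], p[2], 0.5, parent))
        coords.append(p)
    df = pd.DataFrame(rows, columns=["id", "structure", "x", "y", "z", "radius", "parent"])
    return NeuronTree(nodes=df)


def _random_unit(rng) -> np.ndarray:
    v = rng.standard_normal(3)
    return v / np.linalg.norm(v)


# --------------------------------------------------------------------------
# Milestone tables
# --------------------------------------------------------------------------


def gen_milestone_table(
    n_per_group: int = 9,
    base_day_distribution: Sequence[float] | None = None,
    group_shift_days: int = 0,
    noise: float = 0.0,
    seed: int = 0,
    test_name: str = "surface_righting",
    groups: tuple[str, str] = ("WT", "KO"),
    first_day: int = 1,
) -> tuple[MilestoneTable, GroundTruth]:
    """Daily-score table for one milestone test with known maturity days.

    Per-animal maturity days are drawn from ``base_day_distribution`` (a
    probability vector over postnatal days, default centred near P7-P9 as in
    a typical righting-reflex battery); the second group's days are shifted
    by ``group_shift_days``.  Scores are built so that the first qualifying
    run of the test's rule ends exactly on the drawn day; ``noise`` is the
    probability of an isolated premature success on any earlier day (never
    two adjacent, so it cannot create a spurious qualifying run for rules
    requiring >= 2 consecutive days; under such rules maturity days are
    recovered exactly even with noise).
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    rule = DEFAULT_MILESTONE_RULES[test_name]
    rng = _rng(seed)
    if base_day_distribution is None:
        days_support = np.array([6, 7, 8, 9, 10])
        probs = np.array([0.1, 0.3, 0.3, 0.2, 0.1])
    else:
        probs = np.asarray(base_day_distribution, float)
        days_support = np.arange(first_day, first_day + probs.size)
        probs = probs / probs.sum()

    need = rule.consecutive_days_required
    records = []
    truth_days: dict[str, int] = {}
    # base days are drawn once per animal index and shared across groups, so
    # a group shift moves every matched pair — and hence the median — by
    # exactly ``group_shift_days``
    base_days = [int(rng.choice(days_support, p=probs)) for _ in range(n_per_group)]
    for gi, group in enumerate(groups):
        shift = group_shift_days if gi == 1 else 0
        for a in range(n_per_group):
            animal = f"{group}-{a + 1}"
            day = base_days[a] + shift
            if not first_day + need - 1 <= day <= WEANING_DAY:
                raise ValueError(
                    f"maturity day {day} (shift {shift}) falls outside the "
                    f"P{first_day}-P{WEANING_DAY} observation window"
                )
            truth_days[animal] = day
            run_start = day - need + 1
            scores = {}
            for d in range(first_day, WEANING_DAY + 1):
                if d >= run_start:
                    scores[d] = rule.criterion
                else:
                    scores[d] = 0
            # isolated premature successes (noise); never adjacent to each
            # other or to the qualifying run
            if noise > 0:
                prev_hit = False
                for d in range(first_day, run_start - 1):
                    if not prev_hit and rng.random() < noise:
                        scores[d] = rule.criterion
                        prev_hit = True
                    else:
                        prev_hit = False
            for d, s in scores.items():
                records.append(
                    {
                        "animal_id": animal,
                        "group": group,
                        "test_name": test_name,
                        "postnatal_day": d,
                        "score": s,
                    }
                )
    table = MilestoneTable(records=pd.DataFrame(records), rule_set={test_name: rule})
    gt = GroundTruth(
        "gen_milestone_table",
        seed,
        {
            "maturity_days": truth_days,
            "group_shift_days": group_shift_days,
            "test_name": test_name,
        },
    )
    return table, gt
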