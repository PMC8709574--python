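"""Core data types and text-format readers/writers.

Containers for the four kinds of raw input the analysis stages consume:

* swim trajectories (timestamped planar paths inside a circular pool),
* local field potential traces (uniformly sampled voltage),
* neuron reconstructions (SWC trees),
* developmental-milestone daily-score tables.

Coordinate conventions: pool-centered Cartesian centimetres with y pointing
up; trial time in seconds with t[0] shifted to 0.  SWC coordinates are in
micrometres.  All readers accept comma- or tab-delimited text with a header
row and ignore unknown extra columns.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon


class FormatError(ValueError):
    """Input file does not conform to the expected schema."""


class InputError(ValueError):
    """Input file parses but violates a physical/semantic invariant."""


# --------------------------------------------------------------------------
# Geometry
# --------------------------------------------------------------------------

#: Tolerance (cm) for points nominally outside the pool, absorbing tracking
#: jitter.  Beyond it the reader raises rather than silently clipping.
OUT_OF_POOL_TOLERANCE_CM = 1.0

#: Compass start positions used in the water maze protocol.
START_POSITIONS = ("N", "E", "S", "W")


@dataclass(frozen=True)
class PoolGeometry:
    """Circular-pool geometry for the Morris water maze.

    Defaults follow the standard mouse protocol: a 170 cm pool with a 12 cm
    hidden platform, an 8 cm thigmotaxis ring along the wall, and a 30 cm
    focal zone around the platform.  ``quadrant_axes_deg`` rotates the two
    axes that split the pool into four quadrants (0 = axes aligned with x/y).
    """

    pool_diameter: float = 170.0
    platform_diameter: float = 12.0
    platform_center: tuple[float, float] = (42.5, 42.5)
    outer_ring_width: float = 8.0
    focal_zone_diameter: float = 30.0
    quadrant_axes_deg: float = 0.0

    def __post_init__(self) -> None:
        r = self.pool_radius
        px, py = self.platform_center
        if math.hypot(px, py) + self.platform_diameter / 2 > r:
            raise ValueError("platform must lie fully inside the pool")
        if not 0 < self.outer_ring_width < r:
            raise ValueError("outer_ring_width must be in (0, pool radius)")
        if self.focal_zone_diameter < self.platform_diameter:
            raise ValueError("focal zone cannot be smaller than the platform")

    @property
    def pool_radius(self) -> float:
        return self.pool_diameter / 2.0

    @property
    def platform_radius(self) -> float:
        return self.platform_diameter / 2.0

    @property
    def focal_zone_radius(self) -> float:
        return self.focal_zone_diameter / 2.0

    @property
    def inner_radius(self) -> float:
        """Radius of the boundary between the inner area and the outer ring."""
        return self.pool_radius - self.outer_ring_width

    def quadrant_of(self, x, y) -> np.ndarray:
        """Quadrant index (0..3, counter-clockwise from the rotated +x/+y
        quadrant) for each point.

        The boundary is left-closed: a point exactly on a quadrant axis
        belongs to the counter-clockwise quadrant whose angular interval
        starts there.  The pool centre itself maps to quadrant 0.
        """
        ang = np.degrees(np.arctan2(np.asarray(y, float), np.asarray(x, float)))
        ang = np.mod(ang - self.quadrant_axes_deg, 360.0)
        return np.minimum((ang // 90.0).astype(int), 3)

    def start_xy(self, start_position: str, margin: float = 5.0) -> tuple[float, float]:
        """Release point for a compass start position, ``margin`` cm off the wall."""
        bearing = {"E": 0.0, "N": 90.0, "W": 180.0, "S": 270.0}
        try:
            a = math.radians(bearing[start_position])
        except KeyError:
            raise ValueError(f"unknown start position {start_position!r}") from None
        r = self.pool_radius - margin
        return (r * math.cos(a), r * math.sin(a))


@dataclass(frozen=True)
class ArenaGeometry:
    """Polygonal arena with named zones (open field, elevated plus maze...).

    ``named_zones`` maps labels to polygons given as vertex sequences in the
    arena's coordinate frame.  Zones must lie inside the arena boundary and
    labels must be unique (enforced by the mapping type).
    """

    boundary: tuple[tuple[float, float], ...]
    named_zones: Mapping[str, tuple[tuple[float, float], ...]]

    def __post_init__(self) -> None:
        arena = Polygon(self.boundary)
        if not arena.is_valid or arena.area <= 0:
            raise ValueError("arena boundary is not a valid polygon")
        for label, verts in self.named_zones.items():
            zone = Polygon(verts)
            if not arena.buffer(1e-9).contains(zone):
                raise ValueError(f"zone {label!r} extends outside the arena")

    @property
    def arena_polygon(self) -> Polygon:
        return Polygon(self.boundary)

    def zone_polygon(self, label: str) -> Polygon:
        return Polygon(self.named_zones[label])

    @staticmethod
    def open_field(side: float = 43.2, center_side: float = 11.0) -> "ArenaGeometry":
        """Square open-field arena with a central square zone.

        Defaults: 43.2 cm box with an 11 x 11 cm centre region, the standard
        anxiety readout geometry.  Coordinates are arena-centered.
        """
        h, c = side / 2.0, center_side / 2.0
        return ArenaGeometry(
            boundary=((-h, -h), (h, -h), (h, h), (-h, h)),
            named_zones={"center": ((-c, -c), (c, -c), (c, c), (-c, c))},
        )


# --------------------------------------------------------------------------
# Swim trials
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SwimTrial:
    """One water-maze trial: a timestamped planar path plus pool context.

    ``t`` is in seconds (shifted so t[0] = 0), ``x``/``y`` in pool-centered
    centimetres.  Invariants: strictly increasing time, at least two samples,
    every point within the pool radius plus a 1 cm jitter tolerance.
    """

    trial_id: str
    animal_id: str
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    start_position: str = "N"
    geometry: PoolGeometry = field(default_factory=PoolGeometry)

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if not (t.shape == x.shape == y.shape) or t.ndim != 1:
            raise ValueError("t, x, y must be 1-D arrays of equal length")
        if t.size < 2:
            raise InputError("a trial needs at least 2 samples")
        if not np.all(np.diff(t) > 0):
            raise InputError("non-monotone timestamps")
        r = np.hypot(x, y)
        limit = self.geometry.pool_radius + OUT_OF_POOL_TOLERANCE_CM
        bad = np.nonzero(r > limit)[0]
        if bad.size:
            i = int(bad[0])
            raise InputError(
                f"sample {i} at ({x[i]:.2f}, {y[i]:.2f}) lies {r[i] - self.geometry.pool_radius:.2f} cm "
                "outside the pool (beyond the 1 cm tolerance)"
            )
        object.__setattr__(self, "t", t - t[0])
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    @property
    def n_samples(self) -> int:
        return int(self.t.size)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    @property
    def xy(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])

    def path_length(self) -> float:
        """Total swim distance in cm."""
        return float(np.hypot(np.diff(self.x), np.diff(self.y)).sum())


def read_trajectory(
    path: str | Path | io.TextIOBase,
    geometry: PoolGeometry | None = None,
    trial_id: str = "",
    animal_id: str = "",
    start_position: str = "N",
) -> SwimTrial:
    """Read a swim trajectory from delimited text with columns t, x, y.

    Comma or tab delimiters are autodetected; extra columns are ignored.
    Raises :class:`FormatError` for missing columns and :class:`InputError`
    for non-monotone timestamps or points outside the pool.
    """
    geometry = geometry or PoolGeometry()
    df = _read_table(path)
    for col in ("t", "x", "y"):
        if col not in df.columns:
            raise FormatError(f"trajectory file is missing required column {col!r}")
    name = trial_id or (Path(path).stem if isinstance(path, (str, Path)) else "trial")
    return SwimTrial(
        trial_id=name,
        animal_id=animal_id or name,
        t=df["t"].to_numpy(float),
        x=df["x"].to_numpy(float),
        y=df["y"].to_numpy(float),
        start_position=start_position,
        geometry=geometry,
    )


def write_trajectory(trial: SwimTrial, path: str | Path) -> None:
    """Write a trial back to CSV at full round-trip precision."""
    df = pd.DataFrame({"t": trial.t, "x": trial.x, "y": trial.y})
    df.to_csv(path, index=False, float_format="%.10g")


def resample_path(trial: SwimTrial, dt: float) -> SwimTrial:
    """Linearly interpolate a trial onto a uniform time grid of step ``dt``.

    Endpoints (first and last sample) are preserved exactly; the final grid
    point is the original end time even when the duration is not a multiple
    of ``dt``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if dt > trial.duration:
        raise ValueError(f"dt={dt} exceeds trial duration {trial.duration}")
    n_steps = int(math.floor(trial.duration / dt + 1e-9))
    grid = trial.t[0] + dt * np.arange(n_steps + 1)
    if grid[-1] < trial.t[-1] - 1e-9:
        grid = np.append(grid, trial.t[-1])
    else:
        grid[-1] = trial.t[-1]
    x = np.interp(grid, trial.t, trial.x)
    y = np.interp(grid, trial.t, trial.y)
    # pin endpoints exactly
    x[0], y[0], x[-1], y[-1] = trial.x[0], trial.y[0], trial.x[-1], trial.y[-1]
    return replace(trial, t=grid, x=x, y=y)


# --------------------------------------------------------------------------
# LFP recordings
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class LFPRecording:
    """A uniformly sampled local field potential trace.

    ``samples`` are in arbitrary voltage units; ``fs`` in Hz.  The recording
    protocol this models acquires 100 s at 1000 Hz per site, but any length
    compatible with the analysis (>= one 1-s segment, fs above twice the
    highest analysed frequency) is accepted.
    """

    channel_id: str
    samples: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=float).ravel()
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if s.size < 2:
            raise InputError("recording too short for 1-s segmentation")
        object.__setattr__(self, "samples", s)

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


def read_lfp(path: str | Path | io.TextIOBase, fs: float, channel_id: str = "") -> LFPRecording:
    """Read an LFP trace from delimited text.

    Accepts a single value column (header ``value`` or any single column) or
    two columns ``t,value``; with a time column, sampling uniformity at
    ``fs`` is verified to 1e-6 relative tolerance.
    """
    df = _read_table(path)
    if df.shape[0] == 0:
        raise InputError("empty LFP file")
    if "t" in df.columns:
        value_cols = [c for c in df.columns if c != "t"]
        if not value_cols:
            raise FormatError("LFP file has a t column but no value column")
        t = df["t"].to_numpy(float)
        dt = np.diff(t)
        if dt.size and not np.allclose(dt, 1.0 / fs, rtol=1e-6, atol=1e-6 / fs):
            raise InputError("non-uniform sampling: t column inconsistent with fs")
        values = df[value_cols[0]].to_numpy(float)
    else:
        values = df[df.columns[0]].to_numpy(float)
    name = channel_id or (Path(path).stem if isinstance(path, (str, Path)) else "lfp")
    return LFPRecording(channel_id=name, samples=values, fs=fs)


def write_lfp(rec: LFPRecording, path: str | Path) -> None:
    pd.DataFrame({"value": rec.samples}).to_csv(path, index=False, float_format="%.10g")


# --------------------------------------------------------------------------
# Neuron reconstructions (SWC)
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class NeuronTree:
    """A rooted neurite reconstruction with SWC node semantics.

    ``nodes`` is a DataFrame with columns id, structure, x, y, z, radius,
    parent (coordinates in µm).  Exactly one root (parent -1) is required;
    connectivity must be acyclic with unique ids.  The soma is the first
    node with structure code 1, else the root.
    """

    nodes: pd.DataFrame
    soma_id: int = -1

    def __post_init__(self) -> None:
        df = self.nodes.reset_index(drop=True)
        required = ["id", "structure", "x", "y", "z", "radius", "parent"]
        if list(df.columns[:7]) != required:
            df = df[required]
        ids = df["id"].to_numpy(int)
        if len(set(ids)) != len(ids):
            raise FormatError("duplicate node ids in reconstruction")
        parents = df["parent"].to_numpy(int)
        roots = np.nonzero(parents == -1)[0]
        if roots.size != 1:
            raise InputError(f"expected exactly one root node, found {roots.size}")
        id_set = set(ids)
        for nid, pid in zip(ids, parents):
            if pid != -1 and pid not in id_set:
                raise InputError(f"node {nid} references missing parent {pid}")
        # acyclicity + connectivity: walk each node up to the root
        parent_of = dict(zip(ids, parents))
        root_id = int(ids[roots[0]])
        for nid in ids:
            seen = set()
            cur = int(nid)
            while cur != -1:
                if cur in seen:
                    raise InputError(f"cycle detected at node {cur}")
                seen.add(cur)
                cur = int(parent_of[cur])
        soma = self.soma_id
        if soma == -1:
            soma_rows = df.index[df["structure"] == 1]
            soma = int(df.loc[soma_rows[0], "id"]) if len(soma_rows) else root_id
        if soma not in id_set:
            raise ValueError(f"soma id {soma} not among node ids")
        object.__setattr__(self, "nodes", df)
        object.__setattr__(self, "soma_id", int(soma))

    @property
    def root_id(self) -> int:
        return int(self.nodes.loc[self.nodes["parent"] == -1, "id"].iloc[0])

    @property
    def n_nodes(self) -> int:
        return int(len(self.nodes))

    def coords(self) -> dict[int, np.ndarray]:
        """Map node id -> xyz coordinate (µm)."""
        return {
            int(r.id): np.array([r.x, r.y, r.z], dtype=float)
            for r in self.nodes.itertuples(index=False)
        }

    def segments(self) -> list[tuple[int, int]]:
        """All (parent_id, child_id) edges, root excluded as a child of -1."""
        return [
            (int(r.parent), int(r.id))
            for r in self.nodes.itertuples(index=False)
            if int(r.parent) != -1
        ]

    def soma_xyz(self) -> np.ndarray:
        row = self.nodes.loc[self.nodes["id"] == self.soma_id].iloc[0]
        return np.array([row.x, row.y, row.z], dtype=float)


def read_swc(path: str | Path | io.TextIOBase) -> NeuronTree:
    """Read a whitespace-delimited 7-column SWC reconstruction.

    Comment lines start with ``#``.  Unknown structure codes are accepted.
    """
    if isinstance(path, (str, Path)):
        text = Path(path).read_text()
    else:
        text = path.read()
    rows = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 7:
            raise FormatError(f"SWC line {lineno}: expected 7 columns, got {len(parts)}")
        try:
            rows.append(
                (
                    int(parts[0]),
                    int(parts[1]),
                    float(parts[2]),
                    float(parts[3]),
                    float(parts[4]),
                    float(parts[5]),
                    int(parts[6]),
                )
            )
        except ValueError as e:
            raise FormatError(f"SWC line {lineno}: {e}") from None
    if not rows:
        raise InputError("SWC file contains no nodes")
    df = pd.DataFrame(rows, columns=["id", "structure", "x", "y", "z", "radius", "parent"])
    return NeuronTree(nodes=df)


def write_swc(tree: NeuronTree, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# id structure x y z radius parent\n")
        for r in tree.nodes.itertuples(index=False):
            fh.write(
                f"{int(r.id)} {int(r.structure)} {r.x:.10g} {r.y:.10g} {r.z:.10g} "
                f"{r.radius:.10g} {int(r.parent)}\n"
            )


# --------------------------------------------------------------------------
# Milestone tables
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class MaturityRule:
    """Maturity criterion for one developmental-milestone test.

    ``score_type`` is "binary" (0/1) or "graded" (0..max_score); maturity is
    reached on the final day of the first run of ``consecutive_days_required``
    days with score >= ``criterion``.  ``time_limit`` (s) documents the
    behavioural cut-off where the protocol has one; it does not enter the
    scoring, which consumes already-scored tables.
    """

    test_name: str
    score_type: str = "binary"
    criterion: int = 1
    consecutive_days_required: int = 1
    max_score: int = 1
    time_limit: float | None = None

    def __post_init__(self) -> None:
        if self.score_type not in ("binary", "graded"):
            raise ValueError("score_type must be 'binary' or 'graded'")
        if self.consecutive_days_required < 1:
            raise ValueError("consecutive_days_required must be >= 1")
        if not 0 <= self.criterion <= self.max_score:
            raise ValueError("criterion outside the declared score range")


#: Per-test defaults for the early-postnatal milestone battery (P1-P21).
#: Tests with a "3 consecutive days" clause in the protocol use a 3-day rule;
#: the rest register maturity on the first qualifying day.
DEFAULT_MILESTONE_RULES: dict[str, MaturityRule] = {
    r.test_name: r
    for r in [
        MaturityRule("surface_righting", "graded", 3, 3, 3, time_limit=1.0),
        MaturityRule("negative_geotaxis", "graded", 3, 3, 3, time_limit=30.0),
        MaturityRule("cliff_aversion", "graded", 3, 3, 3, time_limit=30.0),
        MaturityRule("air_righting", "binary", 1, 3, 1),
        MaturityRule("rooting", "binary", 1, 3, 1),
        MaturityRule("ear_twitch", "binary", 1, 3, 1),
        MaturityRule("auditory_startle", "binary", 1, 3, 1),
        MaturityRule("open_field", "binary", 1, 3, 1, time_limit=30.0),
        MaturityRule("walking", "graded", 3, 1, 3),
        MaturityRule("grasping", "graded", 3, 1, 3),
        MaturityRule("postural_reflex", "binary", 1, 1, 1),
        MaturityRule("wire_suspension", "binary", 1, 1, 1),
        MaturityRule("eye_opening", "graded", 2, 1, 2),
    ]
}

#: Last observable postnatal day of the protocol.
WEANING_DAY = 21


@dataclass(frozen=True)
class MilestoneTable:
    """Long-format daily milestone scores.

    ``records`` columns: animal_id, group, test_name, postnatal_day, score.
    Scores must lie within each test's declared range and days within P1-P21.
    """

    records: pd.DataFrame
    rule_set: Mapping[str, MaturityRule] = field(
        default_factory=lambda: dict(DEFAULT_MILESTONE_RULES)
    )

    def __post_init__(self) -> None:
        df = self.records.reset_index(drop=True)
        required = {"animal_id", "group", "test_name", "postnatal_day", "score"}
        missing = required - set(df.columns)
        if missing:
            raise FormatError(f"milestone table missing columns: {sorted(missing)}")
        days = df["postnatal_day"].to_numpy(int)
        if days.size and (days.min() < 1 or days.max() > WEANING_DAY):
            raise InputError("postnatal days must lie within 1..21")
        for test, sub in df.groupby("test_name"):
            rule = self.rule_set.get(str(test))
            if rule is None:
                raise InputError(f"no maturity rule for test {test!r}")
            s = sub["score"].to_numpy(int)
            if s.size and (s.min() < 0 or s.max() > rule.max_score):
                raise InputError(
                    f"test {test!r}: scores outside declared range 0..{rule.max_score}"
                )
        object.__setattr__(self, "records", df)
        object.__setattr__(self, "rule_set", dict(self.rule_set))


def read_milestone_table(
    path: str | Path | io.TextIOBase,
    rule_set: Mapping[str, MaturityRule] | None = None,
) -> MilestoneTable:
    """Read a long-format milestone score table from delimited text."""
    df = _read_table(path)
    return MilestoneTable(
        records=df, rule_set=dict(rule_set or DEFAULT_MILESTONE_RULES)
    )


def write_milestone_table(table: MilestoneTable, path: str | Path) -> None:
    table.records.to_csv(path, index=False)


# --------------------------------------------------------------------------
# helpers
# --------------------------------------------------------------------------


def _read_table(path: str | Path | io.TextIOBase) -> pd.DataFrame:
    """Delimited-text reader with comma/tab autodetection and a header row."""
    import csv

    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except pd.errors.EmptyDataError:
        raise InputError("empty input file") from None
    except csv.Error as e:
        # delimiter sniffing fails on empty/one-column-no-delimiter files;
        # retry as plain single-column CSV before giving up
        try:
            if hasattr(path, "seek"):
                path.seek(0)
            df = pd.read_csv(path)
        except pd.errors.EmptyDataError:
            raise InputError("empty input file") from None
        except (ValueError, OSError):
            raise FormatError(str(e)) from None
    except (ValueError, OSError) as e:
        raise FormatError(str(e)) from None
    return df
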