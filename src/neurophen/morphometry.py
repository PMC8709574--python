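"""Neurite morphometry on traced reconstructions.

Operates on SWC trees (:class:`~neurophen.datamodel.NeuronTree`): total
dendritic length, Sholl intersection profiles at a fixed radius increment,
branching complexity, laminar-reach classification of immature (DCX+)
neurons, and areal cell-density normalisation.

Sholl convention: spheres (SWC is 3-D; for planar reconstructions with
constant z this reduces to the classical circles) centered on the soma node,
radii at successive multiples of the increment (20 µm by default).  A
segment is counted once per transversal crossing of the sphere; because the
distance to a fixed centre is convex along a straight segment, a segment
with both endpoints outside the sphere may dip inside and cross twice.  Tie
rules: an endpoint lying exactly on the sphere counts with the outward-going
segment only, and tangency does not count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .datamodel import NeuronTree


class UnclassifiableCellError(ValueError):
    """The reconstruction does not reach past the first laminar boundary."""


@dataclass(frozen=True)
class ShollProfile:
    """Sholl intersection counts at evenly incremented radii (µm)."""

    radii: tuple[float, ...]
    intersections: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.radii) != len(self.intersections):
            raise ValueError("radii and intersections must align")
        if any(c < 0 for c in self.intersections):
            raise ValueError("intersection counts cannot be negative")
        if len(self.radii) > 1:
            diffs = np.diff(self.radii)
            if not np.all(diffs > 0):
                raise ValueError("radii must be strictly increasing")


@dataclass(frozen=True)
class LaminarBounds:
    """Laminar landmarks as radial distances (µm) from the soma.

    ``gcl_iml_boundary`` marks the granule-cell-layer / inner-molecular-layer
    transition; ``iml_moml_boundary`` the inner / medial-outer molecular
    layer transition.  A DCX+ cell is "short" when its dendritic tree stops
    within the IML and "long" when it reaches strictly beyond into the
    M/OML.
    """

    gcl_iml_boundary: float
    iml_moml_boundary: float

    def __post_init__(self) -> None:
        if not 0 < self.gcl_iml_boundary < self.iml_moml_boundary:
            raise ValueError("need 0 < gcl_iml_boundary < iml_moml_boundary")


@dataclass(frozen=True)
class CellCount:
    """A marker-positive cell count over a measured region area (mm²)."""

    n_cells: int
    region_area: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ValueError("n_cells cannot be negative")
        if self.region_area <= 0:
            raise ValueError("region_area must be positive")


# --------------------------------------------------------------------------
# Length and branching
# --------------------------------------------------------------------------


def total_length(tree: NeuronTree, include_soma: bool = False) -> float:
    """Total neurite length (µm): sum of Euclidean parent-child segment
    lengths.  Segments internal to a multi-node soma (both endpoints with
    structure code 1) are excluded unless ``include_soma``.
    """
    coords = tree.coords()
    structure = dict(
        zip(tree.nodes["id"].astype(int), tree.nodes["structure"].astype(int))
    )
    length = 0.0
    for parent, child in tree.segments():
        if not include_soma and structure[parent] == 1 and structure[child] == 1:
            continue
        length += float(np.linalg.norm(coords[child] - coords[parent]))
    return length


def branching_complexity(tree: NeuronTree) -> tuple[int, int, int]:
    """(n_branch_points, n_tips, max_branch_order).

    Branch points are nodes with >= 2 children; tips are leaves; the branch
    order of a node counts the bifurcations passed on the path from the
    root, so an unbranched cable has maximal order 0.
    """
    ids = tree.nodes["id"].astype(int).tolist()
    parent = dict(zip(ids, tree.nodes["parent"].astype(int)))
    children: dict[int, list[int]] = {i: [] for i in ids}
    for i in ids:
        p = parent[i]
        if p != -1:
            children[p].append(i)
    n_branch = sum(1 for i in ids if len(children[i]) >= 2)
    n_tips = sum(1 for i in ids if not children[i])

    order: dict[int, int] = {}
    root = tree.root_id
    stack = [(root, 0)]
    max_order = 0
    while stack:
        node, o = stack.pop()
        order[node] = o
        max_order = max(max_order, o)
        bump = 1 if len(children[node]) >= 2 else 0
        for c in children[node]:
            stack.append((c, o + bump))
    return n_branch, n_tips, max_order


# --------------------------------------------------------------------------
# Sholl analysis
# --------------------------------------------------------------------------


def sholl_profile(
    tree: NeuronTree,
    increment: float = 20.0,
    max_radius: float | None = None,
) -> ShollProfile:
    """Sholl intersection profile at radii increment, 2*increment, ...

    Radii extend to the first multiple of ``increment`` at or beyond the
    maximal neurite extent (so the final count is 0 whenever the extent is
    not itself a crossing), or to ``max_radius`` when given.  An empty tree
    (single node) yields an all-zero profile of length 1.
    """
    if increment <= 0:
        raise ValueError("increment must be positive")
    coords = tree.coords()
    soma = tree.soma_xyz()
    dist = {nid: float(np.linalg.norm(p - soma)) for nid, p in coords.items()}
    extent = max(dist.values()) if dist else 0.0

    if max_radius is None:
        n_radii = max(1, int(math.ceil((extent + 1e-12) / increment)))
        if extent > 0 and abs(extent - n_radii * increment) < 1e-9:
            n_radii += 1  # ensure a trailing zero beyond the extent
    else:
        n_radii = max(1, int(math.floor(max_radius / increment + 1e-9)))
    radii = [increment * (k + 1) for k in range(n_radii)]

    segs = tree.segments()
    counts = []
    for r in radii:
        c = 0
        for parent, child in segs:
            c += _crossings(coords[parent], coords[child], soma, r)
        counts.append(c)
    return ShollProfile(radii=tuple(radii), intersections=tuple(counts))


def _crossings(p1: np.ndarray, p2: np.ndarray, center: np.ndarray, r: float, tol: float = 1e-9) -> int:
    """Transversal crossings of the sphere |p - center| = r by segment p1->p2.

    Distance to the centre is convex along the segment: its maximum is at an
    endpoint and it has at most one interior minimum, so there are 0, 1 or 2
    crossings.  Endpoint exactly on the sphere counts only at the segment
    start and only when the segment leaves outward; tangency never counts.
    """
    d1 = float(np.linalg.norm(p1 - center))
    d2 = float(np.linalg.norm(p2 - center))
    on1 = abs(d1 - r) <= tol
    on2 = abs(d2 - r) <= tol

    if on1:
        return 1 if d2 > r + tol else 0
    if on2:
        # attributed to the outward continuation (next segment's start)
        return 0
    if (d1 < r) != (d2 < r):
        return 1
    if d1 < r and d2 < r:
        return 0
    # both endpoints outside: crossings iff the interior minimum dips below r
    v = p2 - p1
    vv = float(v @ v)
    if vv == 0.0:
        return 0
    t = float((center - p1) @ v) / vv
    if not 0.0 < t < 1.0:
        return 0
    dmin = float(np.linalg.norm(p1 + t * v - center))
    return 2 if dmin < r - tol else 0


# --------------------------------------------------------------------------
# Laminar reach and density
# --------------------------------------------------------------------------


def classify_dcx_extent(tree: NeuronTree, bounds: LaminarBounds) -> str:
    """Short/long classification of a DCX+ cell by laminar dendritic reach.

    "long" iff the maximal radial node distance from the soma strictly
    exceeds the IML / M-OML boundary, else "short".  Raises
    :class:`UnclassifiableCellError` for trees confined below the GCL/IML
    boundary (not a classifiable DCX+ cell under the inclusion rule).
    """
    soma = tree.soma_xyz()
    coords = tree.coords()
    extent = max(float(np.linalg.norm(p - soma)) for p in coords.values())
    if extent <= bounds.gcl_iml_boundary:
        raise UnclassifiableCellError(
            f"maximal dendritic extent {extent:.1f} µm does not reach past the "
            f"GCL/IML boundary at {bounds.gcl_iml_boundary:.1f} µm"
        )
    return "long" if extent > bounds.iml_moml_boundary else "short"


def cell_density(count: CellCount) -> float:
    """Cells per mm²: marker-positive count normalised by region area."""
    return count.n_cells / count.region_area
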