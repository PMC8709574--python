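"""Dendritic length, Sholl profiles, branching, laminar reach, density."""

import io

import numpy as np
import pandas as pd
import pytest

from neurophen import (
    CellCount,
    LaminarBounds,
    NeuronTree,
    UnclassifiableCellError,
    branching_complexity,
    cell_density,
    classify_dcx_extent,
    read_swc,
    sholl_profile,
    total_length,
)
from neurophen.synthetic import gen_neuron_tree, gen_random_tree


def tree_from(rows):
    df = pd.DataFrame(rows, columns=["id", "structure", "x", "y", "z", "radius", "parent"])
    return NeuronTree(nodes=df)


def radial_cable(length, n_nodes=10):
    rows = [(1, 1, 0.0, 0.0, 0.0, 1.0, -1)]
    for k in range(1, n_nodes + 1):
        rows.append((k + 1, 3, 0.0, 0.0, length * k / n_nodes, 0.5, k))
    return tree_from(rows)


class TestTotalLength:
    def test_single_segment(self):
        t = tree_from([(1, 1, 0, 0, 0, 1, -1), (2, 3, 0, 0, 30, 0.5, 1)])
        assert total_length(t) == pytest.approx(30.0)

    def test_trunk_plus_two_branches(self):
        t = tree_from(
            [
                (1, 1, 0, 0, 0, 1, -1),
                (2, 3, 0, 0, 50, 0.5, 1),
                (3, 3, 0, 40, 50, 0.5, 2),
                (4, 3, 0, -40, 50, 0.5, 2),
            ]
        )
        assert total_length(t) == pytest.approx(130.0)

    def test_soma_internal_segments_excluded_by_default(self):
        t = tree_from(
            [
                (1, 1, 0, 0, 0, 1, -1),
                (2, 1, 5, 0, 0, 1, 1),  # soma-soma segment
                (3, 3, 5, 0, 30, 0.5, 2),
            ]
        )
        assert total_length(t) == pytest.approx(30.0)
        assert total_length(t, include_soma=True) == pytest.approx(35.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_tree_matches_bruteforce_sum(self, seed):
        tree = gen_random_tree(50, seed=seed)
        coords = tree.coords()
        expected = sum(
            float(np.linalg.norm(coords[c] - coords[p])) for p, c in tree.segments()
        )
        assert total_length(tree) == pytest.approx(expected, abs=1e-9)

    def test_invariant_under_reindexing(self):
        tree = gen_random_tree(30, seed=1)
        df = tree.nodes.copy()
        mapping = {old: new for new, old in enumerate(reversed(df["id"].tolist()), start=1)}
        df["id"] = df["id"].map(mapping)
        df["parent"] = df["parent"].map(lambda p: -1 if p == -1 else mapping[p])
        df = df.sort_values("id").reset_index(drop=True)
        assert total_length(NeuronTree(nodes=df)) == pytest.approx(total_length(tree), abs=1e-9)


def sholl_dense_oracle(tree, radii, ds=0.01):
    """Count sign changes of (distance to soma) - r along a dense sampling
    of every segment, walking root-to-leaf so shared endpoints are handled
    once, in path order."""
    coords = tree.coords()
    soma = tree.soma_xyz()
    counts = []
    for r in radii:
        c = 0
        for p, ch in tree.segments():
            a, b = coords[p], coords[ch]
            n = max(2, int(np.ceil(np.linalg.norm(b - a) / ds)))
            t = np.linspace(0.0, 1.0, n + 1)  # endpoints included: a sign
            # change at a shared node lands inside exactly one segment
            pts = a + t[:, None] * (b - a)
            d = np.linalg.norm(pts - soma, axis=1) - r
            c += int(np.sum(np.sign(d[:-1]) != np.sign(d[1:])))
        counts.append(c)
    return counts


class TestShollProfile:
    def test_straight_radial_cable(self):
        profile = sholl_profile(radial_cable(95.0))
        assert profile.radii == (20.0, 40.0, 60.0, 80.0, 100.0)
        assert profile.intersections == (1, 1, 1, 1, 0)

    def test_trunk_with_two_branches(self):
        tree, gt = gen_neuron_tree(n_branches=2, trunk_length=50.0, branch_length=40.0, seed=0)
        profile = sholl_profile(tree)
        assert profile.intersections[:4] == (1, 1, 2, 2)

    def test_increment_must_be_positive(self):
        with pytest.raises(ValueError):
            sholl_profile(radial_cable(50.0), increment=0.0)

    def test_single_node_tree_all_zero(self):
        t = tree_from([(1, 1, 0, 0, 0, 1, -1)])
        profile = sholl_profile(t)
        assert sum(profile.intersections) == 0

    def test_node_exactly_on_sphere_counts_outward_only(self):
        # chain passes through a node at exactly r = 20: one crossing
        t = tree_from(
            [
                (1, 1, 0, 0, 0, 1, -1),
                (2, 3, 0, 0, 20, 0.5, 1),
                (3, 3, 0, 0, 35, 0.5, 2),
            ]
        )
        assert sholl_profile(t).intersections[0] == 1

    def test_reentrant_segment_counts_twice(self):
        # both endpoints outside r=20 but the segment dips inside
        t = tree_from(
            [
                (1, 1, 0, 0, 0, 1, -1),
                (2, 3, 25, 0, 0, 0.5, 1),
                (3, 3, -25, 1, 0, 0.5, 2),
            ]
        )
        # segment 2->3 passes within 1 µm of the soma: in and out again
        assert sholl_profile(t).intersections[0] == 1 + 2

    @pytest.mark.parametrize("seed", range(8))
    def test_random_trees_match_dense_sampling_oracle(self, seed):
        tree = gen_random_tree(40, seed=seed)
        profile = sholl_profile(tree)
        oracle = sholl_dense_oracle(tree, profile.radii)
        assert list(profile.intersections) == oracle

    @pytest.mark.parametrize("seed", range(4))
    def test_invariant_under_rigid_motion(self, seed):
        rng = np.random.default_rng(seed)
        tree = gen_random_tree(30, seed=seed)
        # random rotation (QR of a gaussian matrix) + translation
        q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        shift = rng.uniform(-100, 100, 3)
        df = tree.nodes.copy()
        xyz = df[["x", "y", "z"]].to_numpy() @ q.T + shift
        df[["x", "y", "z"]] = xyz
        moved = NeuronTree(nodes=df)
        assert sholl_profile(moved).intersections == sholl_profile(tree).intersections

    def test_trailing_radius_beyond_extent_is_zero(self):
        profile = sholl_profile(radial_cable(95.0))
        assert profile.intersections[-1] == 0
        assert profile.radii[-1] >= 95.0


class TestBranchingComplexity:
    def test_unbranched_cable(self):
        assert branching_complexity(radial_cable(50.0, n_nodes=5)) == (0, 1, 0)

    def test_single_bifurcation(self):
        t = tree_from(
            [
                (1, 1, 0, 0, 0, 1, -1),
                (2, 3, 0, 0, 50, 0.5, 1),
                (3, 3, 0, 40, 50, 0.5, 2),
                (4, 3, 0, -40, 50, 0.5, 2),
            ]
        )
        assert branching_complexity(t) == (1, 2, 1)

    @pytest.mark.parametrize("n_branch", [1, 2, 3, 5, 8])
    def test_binary_tree_tip_identity(self, n_branch):
        # a tree built by n successive bifurcations has n+1 tips
        rows = [(1, 1, 0.0, 0.0, 0.0, 1.0, -1)]
        tips = [1]
        next_id = 2
        z = 10.0
        rng = np.random.default_rng(n_branch)
        for _ in range(n_branch):
            parent = tips.pop(int(rng.integers(len(tips))))
            for dx in (-1.0, 1.0):
                rows.append((next_id, 3, dx * z, 0.0, z, 0.5, parent))
                tips.append(next_id)
                next_id += 1
            z += 10.0
        t = tree_from(rows)
        n_bp, n_tips, _ = branching_complexity(t)
        assert n_bp == n_branch
        assert n_tips == n_branch + 1


class TestLaminarReachAndDensity:
    bounds = LaminarBounds(gcl_iml_boundary=50.0, iml_moml_boundary=100.0)

    @pytest.mark.parametrize(
        "extent, expected", [(60.0, "short"), (120.0, "long"), (100.0, "short")]
    )
    def test_reach_classification(self, extent, expected):
        # exactly at the boundary counts as short (strict inequality)
        assert classify_dcx_extent(radial_cable(extent), self.bounds) == expected

    def test_confined_tree_unclassifiable(self):
        with pytest.raises(UnclassifiableCellError):
            classify_dcx_extent(radial_cable(40.0), self.bounds)

    @pytest.mark.parametrize(
        "n, area, expected", [(10, 0.5, 20.0), (0, 1.0, 0.0), (7, 0.35, 20.0)]
    )
    def test_density(self, n, area, expected):
        assert cell_density(CellCount(n, area)) == pytest.approx(expected)

    def test_zero_area_rejected(self):
        with pytest.raises(ValueError):
            CellCount(5, 0.0)
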