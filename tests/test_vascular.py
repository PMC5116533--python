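import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from carposim.errors import InvalidGeometryError, StateError
from carposim.mesh import _in_tet
from carposim.vascular import (
    SCAParams,
    VascularTree,
    assign_radii_murray,
    contact_areas,
    grow_network,
    read_tree,
    sample_attractors,
    write_tree,
)


def y_junction():
    nodes = np.array([[0, 0, 0], [0, 0, 1], [1, 0, 2], [-1, 0, 2]], float)
    return VascularTree(nodes=nodes, parents=np.array([-1, 0, 1, 1]))


def random_tree(rng, n_nodes=40):
    nodes = [np.zeros(3)]
    parents = [-1]
    for i in range(1, n_nodes):
        p = int(rng.integers(0, i))
        nodes.append(nodes[p] + rng.normal(size=3) * 0.3)
        parents.append(p)
    return VascularTree(nodes=np.array(nodes), parents=np.array(parents))


class TestMurray:
    def test_symmetric_bifurcation_n1_parent_is_double(self):
        t = assign_radii_murray(y_junction(), 1.0, tip_radius=1.0)
        assert t.radii[1] == pytest.approx(2.0, abs=1e-14)

    def test_large_exponent_limit_parent_equals_daughter(self):
        t = assign_radii_murray(y_junction(), 64.0, tip_radius=1.0)
        assert t.radii[1] == pytest.approx(1.0, rel=0.02)

    def test_binary_tree_depth3_root_is_cbrt8(self):
        # brute-force recursion oracle: 8 tips of radius 1, n=3 -> root 8^(1/3)
        nodes = [np.zeros(3)]
        parents = [-1]
        frontier = [0]
        for d in range(3):
            nxt = []
            for f in frontier:
                for s in (-1, 1):
                    nodes.append(nodes[f] + np.array([s * 0.5**d, 0, 1.0]))
                    parents.append(f)
                    nxt.append(len(nodes) - 1)
            frontier = nxt
        t = VascularTree(nodes=np.array(nodes), parents=np.array(parents))
        assign_radii_murray(t, 3.0, tip_radius=1.0)
        assert t.radii[0] == pytest.approx(2.0, abs=1e-12)

    @given(st.integers(0, 2**31 - 1), st.floats(0.5, 4.0))
    @settings(max_examples=25, deadline=None)
    def test_junction_identity_on_random_trees(self, seed, n):
        tree = random_tree(np.random.default_rng(seed))
        assign_radii_murray(tree, n, tip_radius=0.5)
        for parent, kids in enumerate(tree.children()):
            if len(kids) >= 1 and parent != 0:
                lhs = tree.radii[parent] ** n
                rhs = sum(tree.radii[k] ** n for k in kids)
                assert lhs == pytest.approx(rhs, rel=1e-12)

    def test_pedicel_rescaling(self):
        t = assign_radii_murray(y_junction(), 2.0, tip_radius=1.0, pedicel_radius=0.1)
        assert t.radii[0] == pytest.approx(0.1)
        # relative structure preserved
        assert t.radii[1] / t.radii[2] == pytest.approx(np.sqrt(2.0))

    def test_invalid_exponent(self):
        with pytest.raises(ValueError):
            assign_radii_murray(y_junction(), 0.0)


class TestAttractors:
    def test_deterministic_for_fixed_seed(self, sphere_mesh):
        a = sample_attractors(sphere_mesh, ["flesh"], 300, seed=7)
        b = sample_attractors(sphere_mesh, ["flesh"], 300, seed=7)
        assert np.array_equal(a, b)

    def test_points_inside_selected_tissue(self, two_tissue_mesh):
        pts = sample_attractors(two_tissue_mesh, ["pericarp"], 400, seed=1)
        # no point may fall deep inside the core (labeling is by centroid,
        # so pericarp tets can straddle the faceted radius-1 inner surface)
        assert np.linalg.norm(pts, axis=1).min() > 0.8

    def test_uniform_density_per_octant(self, cube_mesh):
        pts = sample_attractors(cube_mesh, ["flesh"], 1000, seed=3)
        oct_idx = (
            (pts[:, 0] > 0.5).astype(int) * 4
            + (pts[:, 1] > 0.5).astype(int) * 2
            + (pts[:, 2] > 0.5).astype(int)
        )
        counts = np.bincount(oct_idx, minlength=8)
        sigma = np.sqrt(1000 * (1 / 8) * (7 / 8))
        assert np.all(np.abs(counts - 125) < 3 * sigma)

    def test_empty_tissue_selection(self, sphere_mesh):
        with pytest.raises(ValueError):
            sample_attractors(sphere_mesh, [], 10, seed=0)


class TestSpaceColonization:
    def bundle(self):
        return [np.array([[0, 0, -0.9], [0, 0, 0.0]])]

    def test_far_attractors_leave_bundles_unchanged(self, sphere_mesh):
        params = SCAParams(influence_radius=0.2, kill_radius=0.1, step_length=0.1)
        tree = grow_network(
            sphere_mesh, self.bundle(), np.array([[0.0, 0.9, 0.0]]), params
        )
        # only the resampled bundle itself
        assert tree.n_segments == pytest.approx(9, abs=1)

    def test_colinear_attractor_hand_trace(self, sphere_mesh):
        # attractor at 3 x step_length: three colinear extension segments,
        # then the attractor is killed
        params = SCAParams(influence_radius=0.5, kill_radius=0.1, step_length=0.1)
        base = grow_network(sphere_mesh, self.bundle(), np.zeros((0, 3)), params)
        tree = grow_network(
            sphere_mesh, self.bundle(), np.array([[0.0, 0.0, 0.3 + 1e-7]]), params
        )
        added = tree.n_segments - base.n_segments
        assert added == 3
        assert np.allclose(tree.nodes[-1], [0, 0, 0.3], atol=1e-6)
        assert np.allclose(tree.nodes[-3:][:, :2], 0.0, atol=1e-9)

    def test_attractor_count_non_increasing_and_halts(self, sphere_mesh):
        params = SCAParams(
            influence_radius=0.4, kill_radius=0.2, step_length=0.1, max_iterations=500
        )
        att = sample_attractors(sphere_mesh, ["flesh"], 500, seed=2)
        tree = grow_network(sphere_mesh, self.bundle(), att, params)
        assert tree.n_segments < 5000  # terminated well before max blowup
        # acyclic by construction (validated in __post_init__)
        assert tree.parents[0] == -1

    def test_zero_attractors_returns_main_bundles(self, sphere_mesh):
        params = SCAParams(influence_radius=0.4, kill_radius=0.2, step_length=0.1)
        tree = grow_network(sphere_mesh, self.bundle(), np.zeros((0, 3)), params)
        assert tree.n_segments <= 10

    def test_bundle_outside_mesh_raises(self, sphere_mesh):
        params = SCAParams(influence_radius=0.4, kill_radius=0.2, step_length=0.1)
        with pytest.raises(InvalidGeometryError):
            grow_network(
                sphere_mesh,
                [np.array([[0, 0, 0], [0, 0, 3.0]])],
                np.zeros((0, 3)),
                params,
            )


class TestContactAreas:
    def test_single_segment_inside_one_tet(self, single_tet_mesh):
        tree = VascularTree(
            nodes=np.array([[1, 1, 1], [1, 1, 2.0]]),
            parents=np.array([-1, 0]),
            radii=np.array([0.0, 0.1]),
        )
        cm = contact_areas(tree, single_tet_mesh)
        assert cm.A_x[0] == pytest.approx(2 * np.pi * 0.1 * 1.0, rel=1e-12)

    def test_split_matches_dense_sampling_oracle(self, two_tet_mesh):
        a = np.array([0.1, 0.1, 0.1])
        b = np.array([0.6, 0.6, 0.6])
        tree = VascularTree(
            nodes=np.array([a, b]), parents=np.array([-1, 0]),
            radii=np.array([0.0, 0.05]),
        )
        cm = contact_areas(tree, two_tet_mesh)
        total = 2 * np.pi * 0.05 * np.linalg.norm(b - a)
        ts = (np.arange(10000) + 0.5) / 10000
        pts = a + ts[:, None] * (b - a)
        for i in range(2):
            tet_v = np.repeat(
                two_tet_mesh.vertices[two_tet_mesh.tets[i]][None], 10000, axis=0
            )
            frac = _in_tet(pts, tet_v).mean()
            assert cm.A_x[i] == pytest.approx(frac * total, rel=1e-3)
        assert cm.A_x.sum() == pytest.approx(total, rel=1e-9)

    def test_total_equals_clipped_lateral_area(self, sphere_mesh):
        params = SCAParams(influence_radius=0.4, kill_radius=0.2, step_length=0.1)
        att = sample_attractors(sphere_mesh, ["flesh"], 400, seed=5)
        tree = grow_network(
            sphere_mesh, [np.array([[0, 0, -0.9], [0, 0, 0.0]])], att, params
        )
        assign_radii_murray(tree, 2.0, tip_radius=0.01)
        cm = contact_areas(tree, sphere_mesh)
        assert cm.A_x.sum() == pytest.approx(tree.total_lateral_area(), rel=1e-6)

    def test_total_area_monotone_in_pipe_exponent(self, sphere_mesh):
        params = SCAParams(influence_radius=0.4, kill_radius=0.2, step_length=0.1)
        att = sample_attractors(sphere_mesh, ["flesh"], 400, seed=5)
        tree = grow_network(
            sphere_mesh, [np.array([[0, 0, -0.9], [0, 0, 0.0]])], att, params
        )
        totals = []
        for n in (1.0, 2.0, 3.0, 4.0):
            assign_radii_murray(tree, n, tip_radius=0.01, pedicel_radius=0.05)
            totals.append(contact_areas(tree, sphere_mesh).A_x.sum())
        assert np.all(np.diff(totals) >= -1e-12)

    def test_requires_radii(self, single_tet_mesh):
        tree = VascularTree(
            nodes=np.array([[1, 1, 1], [1, 1, 2.0]]), parents=np.array([-1, 0])
        )
        with pytest.raises(StateError):
            contact_areas(tree, single_tet_mesh)


class TestTreeIO:
    def test_roundtrip(self, tmp_path):
        t = assign_radii_murray(y_junction(), 2.0, tip_radius=0.3)
        p = tmp_path / "t.json"
        write_tree(t, p)
        t2 = read_tree(p)
        assert np.array_equal(t2.nodes, t.nodes)
        assert np.array_equal(t2.parents, t.parents)
        assert np.allclose(t2.radii, t.radii)

    def test_roundtrip_preserves_lateral_area(self, tmp_path):
        rng = np.random.default_rng(1)
        t = assign_radii_murray(random_tree(rng), 2.5, tip_radius=0.01)
        p = tmp_path / "t.json"
        write_tree(t, p)
        assert read_tree(p).total_lateral_area() == pytest.approx(
            t.total_lateral_area(), rel=1e-9
        )

    def test_cycle_detected(self, tmp_path):
        p = tmp_path / "cyclic.json"
        p.write_text(
            '{"kind": "xylem", "nodes": [[0,0,0],[0,0,1],[0,0,2]],'
            ' "parents": [-1, 2, 1], "radii": null}'
        )
        with pytest.raises(InvalidGeometryError):
            read_tree(p)

    def test_malformed_file(self, tmp_path):
        p = tmp_path / "bad.json"
        p.write_text("{not json")
        with pytest.raises(InvalidGeometryError):
            read_tree(p)
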