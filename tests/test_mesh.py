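"""Geometry primitives against independent oracles."""

import heapq

import numpy as np
import pytest
import trimesh

import fcdsurf as fs
from fcdsurf.mesh import MeshError, SurfaceMesh

from conftest import random_blob


def brute_force_edges(triangles):
    edges = set()
    for a, b, c in triangles:
        edges |= {tuple(sorted(e)) for e in ((a, b), (b, c), (c, a))}
    return edges


def dijkstra_oracle(mesh, seeds):
    """Plain heapq Dijkstra on the cortex edge graph."""
    adj = {v: [] for v in range(mesh.n_vertices)}
    for (u, v), w in zip(mesh.edges, mesh.edge_lengths):
        if mesh.cortex_mask[u] and mesh.cortex_mask[v]:
            adj[u].append((v, w))
            adj[v].append((u, w))
    dist = np.full(mesh.n_vertices, np.inf)
    heap = [(0.0, int(s)) for s in seeds]
    for _, s in heap:
        dist[s] = 0.0
    heapq.heapify(heap)
    while heap:
        d, u = heapq.heappop(heap)
        if d > dist[u]:
            continue
        for v, w in adj[u]:
            nd = d + w
            if nd < dist[v]:
                dist[v] = nd
                heapq.heappush(heap, (nd, v))
    dist[~mesh.cortex_mask] = np.inf
    return dist


def flood_fill_oracle(mesh, flag):
    """Iterative flood fill partition of flagged vertices."""
    adj = fs.build_adjacency(mesh)
    labels = np.zeros(mesh.n_vertices, dtype=int)
    nxt = 0
    for start in np.flatnonzero(flag):
        if labels[start]:
            continue
        nxt += 1
        stack = [start]
        labels[start] = nxt
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if flag[v] and not labels[v]:
                    labels[v] = nxt
                    stack.append(v)
    return labels


def random_mesh(seed):
    rng = np.random.default_rng(seed)
    level = int(rng.integers(1, 4))
    ico = trimesh.creation.icosphere(subdivisions=level, radius=float(rng.uniform(20, 80)))
    verts = np.asarray(ico.vertices) * rng.uniform(0.8, 1.2, size=(1, 3))
    cortex = np.ones(len(verts), dtype=bool)
    if rng.random() < 0.5:  # carve a small polar cap off the cortex
        cortex = verts[:, 2] < np.percentile(verts[:, 2], 95)
    return SurfaceMesh(verts, np.asarray(ico.faces), cortex)


class TestAdjacency:
    def test_single_triangle(self):
        mesh = SurfaceMesh(np.eye(3), [[0, 1, 2]])
        adj = fs.build_adjacency(mesh)
        assert [sorted(a) for a in adj] == [[1, 2], [0, 2], [0, 1]]

    def test_icosahedron_degree_five(self):
        ico = trimesh.creation.icosphere(subdivisions=0)
        mesh = SurfaceMesh(ico.vertices, ico.faces)
        assert all(len(a) == 5 for a in fs.build_adjacency(mesh))

    def test_matches_brute_force_edge_scan(self):
        mesh = random_mesh(7)
        adj = fs.build_adjacency(mesh)
        got = {(u, int(v)) for u, nbrs in enumerate(adj) for v in nbrs if u < v}
        assert got == brute_force_edges(mesh.triangles)

    def test_duplicate_triangles_rejected(self):
        with pytest.raises(MeshError, match="duplicate"):
            SurfaceMesh(np.eye(3), [[0, 1, 2], [2, 1, 0]])


class TestGeodesicDistance:
    def test_all_seeds_zero(self, template2):
        mesh = template2.left
        seeds = np.flatnonzero(mesh.cortex_mask)
        d = fs.geodesic_distance(mesh, seeds)
        assert np.all(d[mesh.cortex_mask] == 0)

    def test_path_strip_unit_edges(self):
        # 5 collinear unit-spaced vertices braced by distant apex vertices:
        # the shortest path runs along the line, distances 0..4
        line = [(i, 0.0, 0.0) for i in range(5)]
        apex = [(i + 0.5, 5.0, 0.0) for i in range(4)]
        tris = [(i, i + 1, 5 + i) for i in range(4)]
        mesh = SurfaceMesh(np.array(line + apex), np.array(tris))
        d = fs.geodesic_distance(mesh, [0])
        np.testing.assert_allclose(d[:5], [0, 1, 2, 3, 4])

    def test_equals_dijkstra_oracle(self):
        for seed in range(5):
            mesh = random_mesh(seed)
            rng = np.random.default_rng(seed)
            cortex = np.flatnonzero(mesh.cortex_mask)
            seeds = rng.choice(cortex, size=rng.integers(1, 6), replace=False)
            np.testing.assert_array_equal(
                fs.geodesic_distance(mesh, seeds), dijkstra_oracle(mesh, seeds)
            )

    def test_triangle_inequality(self, template2):
        mesh = template2.left
        cortex = np.flatnonzero(mesh.cortex_mask)
        a, b = int(cortex[0]), int(cortex[50])
        da = fs.geodesic_distance(mesh, [a])
        db = fs.geodesic_distance(mesh, [b])
        fin = np.isfinite(da) & np.isfinite(db)
        assert np.all(da[fin] <= da[b] + db[fin] + 1e-9)

    def test_max_dist_caps(self, template2):
        mesh = template2.left
        v0 = int(np.flatnonzero(mesh.cortex_mask)[0])
        d = fs.geodesic_distance(mesh, [v0], max_dist=30.0)
        assert np.all(d[np.isfinite(d)] <= 30.0)

    def test_errors(self, template2):
        mesh = template2.left
        with pytest.raises(MeshError):
            fs.geodesic_distance(mesh, [])
        wall = int(np.flatnonzero(~mesh.cortex_mask)[0])
        with pytest.raises(MeshError, match="cortex"):
            fs.geodesic_distance(mesh, [wall])


class TestConnectedComponents:
    def test_empty_flag(self, template2):
        labels, sizes = fs.connected_components(
            template2.left, np.zeros(template2.n_vertices, bool)
        )
        assert labels.sum() == 0 and len(sizes) == 0

    def test_two_separated_patches(self, template3):
        mesh = template3.left
        flag = random_blob(mesh, 1, 20) | random_blob(mesh, 2, 20)
        # only accept the construction when the blobs are disjoint and apart
        labels, sizes = fs.connected_components(mesh, flag)
        assert len(sizes) == 2
        assert sizes.sum() == flag.sum()

    def test_matches_flood_fill_oracle(self):
        for seed in range(5):
            mesh = random_mesh(seed + 20)
            rng = np.random.default_rng(seed)
            flag = (rng.random(mesh.n_vertices) < 0.3) & mesh.cortex_mask
            labels, sizes = fs.connected_components(mesh, flag)
            oracle = flood_fill_oracle(mesh, flag)
            # identical partition: label images agree up to renaming
            assert len(np.unique(labels[flag])) == len(np.unique(oracle[flag]))
            pairs = set(zip(labels[flag], oracle[flag]))
            assert len(pairs) == len(np.unique(labels[flag]))
            np.testing.assert_array_equal(np.bincount(labels)[1:].sum(), flag.sum())

    def test_permutation_equivariance(self):
        mesh = random_mesh(3)
        rng = np.random.default_rng(3)
        flag = (rng.random(mesh.n_vertices) < 0.3) & mesh.cortex_mask
        perm = rng.permutation(mesh.n_vertices)
        inv = np.argsort(perm)
        pmesh = SurfaceMesh(
            mesh.vertices[perm], inv[mesh.triangles], mesh.cortex_mask[perm]
        )
        l1, _ = fs.connected_components(mesh, flag)
        l2, _ = fs.connected_components(pmesh, flag[perm])
        # same partition: co-membership must be preserved under relabeling
        pairs1 = {frozenset(c) for c in _components_as_sets(l1)}
        pairs2 = {frozenset(perm_indexed(c, inv)) for c in _components_as_sets(l2)}
        assert pairs1 == pairs2


def _components_as_sets(labels):
    return [
        set(np.flatnonzero(labels == lab)) for lab in np.unique(labels) if lab > 0
    ]


def perm_indexed(component, inv):
    # component holds permuted-space indices; map back via the permutation
    perm = np.argsort(inv)
    return {int(perm[v]) for v in component}


class TestGaussianSmooth:
    def test_constant_preserved(self, template2):
        mesh = template2.left
        f = np.full(mesh.n_vertices, 3.3)
        s = fs.gaussian_smooth(mesh, f, 15.0)
        np.testing.assert_allclose(s[mesh.cortex_mask], 3.3)

    def test_impulse_peak_at_source(self, template2):
        mesh = template2.left
        v0 = int(np.flatnonzero(mesh.cortex_mask)[10])
        f = np.zeros(mesh.n_vertices)
        f[v0] = 1.0
        s = fs.gaussian_smooth(mesh, f, 25.0)
        assert np.argmax(s) == v0
        assert s[v0] > 0

    def test_matches_dense_pairwise_oracle(self, template3):
        mesh = template3.left
        rng = np.random.default_rng(0)
        f = rng.standard_normal(mesh.n_vertices)
        kernel, sigma = 10.0, 10.0 / fs.mesh.FWHM_TO_SIGMA
        got = fs.gaussian_smooth(mesh, f, kernel)
        cortex = np.flatnonzero(mesh.cortex_mask)
        want = np.zeros(mesh.n_vertices)
        for v in cortex[::7]:  # dense oracle on a subsample of vertices
            d = dijkstra_oracle(mesh, [v])
            w = np.exp(-0.5 * (d / sigma) ** 2)
            w[d > 3 * sigma] = 0.0
            w[~mesh.cortex_mask] = 0.0
            want[v] = (w * f).sum() / w.sum()
            assert got[v] == pytest.approx(want[v], abs=1e-10)

    def test_linear_in_field(self, template2):
        mesh = template2.left
        rng = np.random.default_rng(1)
        f, g = rng.standard_normal((2, mesh.n_vertices))
        lhs = fs.gaussian_smooth(mesh, 2 * f + 3 * g, 20.0)
        rhs = 2 * fs.gaussian_smooth(mesh, f, 20.0) + 3 * fs.gaussian_smooth(mesh, g, 20.0)
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)

    def test_variance_contraction(self, template2):
        mesh = template2.left
        rng = np.random.default_rng(2)
        f = rng.standard_normal(mesh.n_vertices)
        f[mesh.cortex_mask] -= f[mesh.cortex_mask].mean()
        s = fs.gaussian_smooth(mesh, f, 20.0)
        assert s[mesh.cortex_mask].var() <= f[mesh.cortex_mask].var()

    def test_tiny_kernel_warns_and_passes_through(self, template2):
        mesh = template2.left
        f = np.random.default_rng(3).standard_normal(mesh.n_vertices)
        with pytest.warns(UserWarning, match="kernel"):
            s = fs.gaussian_smooth(mesh, f, 0.5)
        np.testing.assert_array_equal(s[mesh.cortex_mask], f[mesh.cortex_mask])


class TestSymmetricTemplate:
    def test_mismatched_hemispheres_rejected(self, template2):
        ico = trimesh.creation.icosphere(subdivisions=1)
        other = SurfaceMesh(ico.vertices, ico.faces)
        with pytest.raises(MeshError):
            fs.SymmetricTemplate(template2.left, other)
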