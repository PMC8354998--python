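"""Shared fixtures and independent oracles for the surfseed test suite.

The oracles here are deliberately written with different data structures and
code paths than the library (plain-dict adjacency scanned from faces, list
queues, per-triangle loops via trimesh) so that agreement is evidence, not
tautology.
"""

import math

import numpy as np
import pytest
import trimesh

from surfseed import FixtureSpec, TriangleMesh, generate_chain, two_cube_fixture


# ------------------------------------------------------------ mesh builders


def make_grid(n: int = 10, spacing: float = 1.0, z: float = 0.0) -> TriangleMesh:
    """Planar (n x n cells) triangulated grid in the z=const plane."""
    g = np.arange(n + 1) * spacing
    xx, yy = np.meshgrid(g, g, indexing="ij")
    vertices = np.column_stack([xx.ravel(), yy.ravel(), np.full(xx.size, z)])
    faces = []
    for i in range(n):
        for j in range(n):
            v00 = i * (n + 1) + j
            v10 = (i + 1) * (n + 1) + j
            faces.append((v00, v10, v10 + 1))
            faces.append((v00, v10 + 1, v00 + 1))
    return TriangleMesh(vertices, np.array(faces))


def make_icosphere(subdivisions: int = 3, radius: float = 1.0) -> TriangleMesh:
    src = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return TriangleMesh(np.asarray(src.vertices), np.asarray(src.faces))


def random_small_mesh(rng: np.random.Generator) -> TriangleMesh:
    """A random fixture below 500 vertices: jittered icosphere, random convex
    hull, or a coarse noisy lobe chain."""
    kind = rng.integers(3)
    if kind == 0:
        base = make_icosphere(2, radius=10.0)
        jitter = rng.normal(0, 0.5, size=base.vertices.shape)
        return TriangleMesh(base.vertices + jitter, base.faces)
    if kind == 1:
        pts = rng.normal(0, 10.0, size=(60, 3))
        hull = trimesh.convex.convex_hull(pts)
        return TriangleMesh(np.asarray(hull.vertices), np.asarray(hull.faces))
    spec = FixtureSpec(n_lobes=2, mesh_resolution=3.5,
                       noise_sd=float(rng.uniform(0, 0.5)),
                       random_seed=int(rng.integers(2 ** 31)))
    return generate_chain(spec).mesh


# ----------------------------------------------------------------- fixtures


@pytest.fixture(scope="session")
def chain3():
    """Noise-free default chain: 3 spindle lobes, 60 deg crease."""
    return generate_chain(FixtureSpec())


@pytest.fixture(scope="session")
def two_cubes():
    return two_cube_fixture()


@pytest.fixture(scope="session")
def icosphere():
    return make_icosphere(3)


# ------------------------------------------------------------------ oracles


def oracle_region_grow(mesh: TriangleMesh, seeds, theta: float) -> np.ndarray:
    """Brute-force breadth-first reachability over the consecutive-normal-angle
    relation, with the library's tie rules (frontier sorted by vertex, FIFO,
    neighbours ascending).  Independent implementation: adjacency from a plain
    face scan, list-based queue, per-edge angle computation."""
    adjacency: dict[int, set[int]] = {v: set() for v in range(mesh.n_vertices)}
    for f in mesh.faces:
        fa, fb, fc = int(f[0]), int(f[1]), int(f[2])
        adjacency[fa].update((fb, fc))
        adjacency[fb].update((fa, fc))
        adjacency[fc].update((fa, fb))
    normals = mesh.vertex_normals
    labels = [0] * mesh.n_vertices
    queue = sorted((int(v), int(lab)) for v, lab in seeds)
    for v, lab in queue:
        labels[v] = lab
    limit = math.cos(math.radians(theta)) - 1e-12
    while queue:
        u, lab = queue.pop(0)
        if float(np.dot(normals[u], normals[u])) < 0.25:
            continue
        for v in sorted(adjacency[u]):
            if labels[v] == 0 and float(np.dot(normals[v], normals[v])) > 0.25:
                if float(np.dot(normals[u], normals[v])) >= limit:
                    labels[v] = lab
                    queue.append((v, lab))
    return np.array(labels)


def oracle_closest_points(points: np.ndarray, mesh: TriangleMesh):
    """Exhaustive nearest point on a mesh via trimesh's per-triangle closest
    point over *every* triangle (no pruning, independent kernel)."""
    tris = mesh.vertices[mesh.faces]
    best_d = np.full(len(points), np.inf)
    best_p = np.zeros((len(points), 3))
    for k in range(len(tris)):
        cand = trimesh.triangles.closest_point(
            np.broadcast_to(tris[k], (len(points), 3, 3)), points)
        d = np.linalg.norm(points - cand, axis=1)
        better = d < best_d
        best_d[better] = d[better]
        best_p[better] = cand[better]
    return best_d, best_p
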