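"""Deterministic synthetic fixtures: chains of convex lobes that touch at
small contact patches, emulating adjacent vertebrae on a thresholded bone
surface.

The default lobe is a "spindle" barrel: a solid of revolution whose meridian
is a circular arc, so normals vary smoothly *within* a lobe while adjacent
lobes meet at a contact ring across which the angle between vertex normals
equals ``crease_angle`` exactly (by construction, ``crease = 2*arctan(s)``
where ``s`` is the meridian slope at the ring).  This reproduces the
geometric situation the segmenter exploits: smooth intra-segment surfaces
separated by sharp normal discontinuities at the contacts.  End lobes close
with hemispherical caps (tangent-continuous, no spurious crease).

A fine band of rings is inserted just *above* each contact ring so that the
shared ring's area-weighted vertex normals lean toward the lower lobe; the
ring is then deterministically claimed by the lower lobe (which also owns it
in the ground truth) and never acts as a stepping stone across the crease.

``lobe_shape="cube"`` builds stacked grid-subdivided cubes joined by small
square necks (all creases at 90 degrees) as a minimal worked example.

Every output is a pure function of (spec, random_seed); randomness is used
only for contact-hole punching and, in :func:`perturb_mesh`, vertex jitter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import InvalidSpecError
from .mesh import TriangleMesh, clean_mesh
from .volume import Volume


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic lobe-chain fixture (lengths in mm, angles in
    degrees).  ``crease_angle`` is the angle between vertex normals across
    each contact ring; ``contact_radius`` the radius of the contact patch;
    ``mesh_resolution`` the target edge length."""

    n_lobes: int = 3
    lobe_shape: str = "spindle"          # "spindle" | "cube"
    crease_angle: float = 60.0
    contact_radius: float = 2.0
    lobe_radius: float = 8.0
    noise_sd: float = 0.0
    hole_fraction: float = 0.0
    random_seed: int = 0
    mesh_resolution: float = 1.0

    def __post_init__(self) -> None:
        if self.n_lobes < 1:
            raise InvalidSpecError("n_lobes must be >= 1")
        if not (0.0 < self.crease_angle < 180.0):
            raise InvalidSpecError("crease_angle must lie strictly in (0, 180)")
        if self.noise_sd < 0:
            raise InvalidSpecError("noise_sd must be >= 0")
        if not (0.0 <= self.hole_fraction <= 1.0):
            raise InvalidSpecError("hole_fraction must lie in [0, 1]")
        if self.mesh_resolution <= 0:
            raise InvalidSpecError("mesh_resolution must be positive")
        if self.lobe_shape not in ("spindle", "cube"):
            raise InvalidSpecError(f"unknown lobe_shape {self.lobe_shape!r}")
        if not (0.0 < self.contact_radius < self.lobe_radius):
            raise InvalidSpecError(
                "contact_radius must be positive and smaller than lobe_radius "
                "to keep lobes separable")


@dataclass
class ChainFixture:
    """A generated chain: mesh, per-vertex ground-truth labels (1-based lobe
    of origin) and suggested seed layouts mirroring a 5- and a 12-seed
    clinical placement (near-contact plus body-centre positions)."""

    mesh: TriangleMesh
    labels: np.ndarray
    seeds_5pt: list[tuple[tuple[float, float, float], int]]
    seeds_12pt: list[tuple[tuple[float, float, float], int]]
    spec: FixtureSpec
    lobe_centers: np.ndarray
    joint_zs: np.ndarray
    n_holes: int = 0


# ------------------------------------------------------------- spindle lobe


def _spindle_geometry(spec: FixtureSpec):
    phi = math.radians(spec.crease_angle) / 2.0
    R, a = spec.lobe_radius, spec.contact_radius
    r_arc = (R - a) / (1.0 - math.cos(phi))
    c_r = a - r_arc * math.cos(phi)      # arc centre offset from the axis
    h = r_arc * math.sin(phi)            # half barrel height
    centers = np.arange(spec.n_lobes) * 2.0 * h
    joints = centers[:-1] + h
    return phi, r_arc, c_r, h, centers, joints


def _build_spindle_chain(spec: FixtureSpec):
    phi, r_arc, c_r, h, centers, joints = _spindle_geometry(spec)
    R, a = spec.lobe_radius, spec.contact_radius
    res = spec.mesh_resolution
    n = spec.n_lobes
    m = max(12, int(math.ceil(2.0 * math.pi * R / res)))
    n_hemi = max(3, int(math.ceil(R * math.pi / 2.0 / res)))
    n_barrel = max(3, int(math.ceil(r_arc * phi / res)))
    eps_beta = (res / 50.0) / r_arc      # refinement band above each joint

    # meridian rings: (z, rho, lobe_label); poles handled separately
    rings: list[tuple[float, float, int]] = []
    ring_tags: dict[tuple, int] = {}     # semantic tag -> ring index

    def add_ring(z, rho, label, tag=None):
        rings.append((z, rho, label))
        if tag is not None:
            ring_tags[tag] = len(rings) - 1

    for i in range(n):
        c = centers[i]
        lab = i + 1
        # ---- lower half
        if i == 0:
            for k in range(1, n_hemi):                    # pole handled later
                beta = -math.pi / 2 + (math.pi / 2) * k / n_hemi
                add_ring(c + R * math.sin(beta), R * math.cos(beta), lab,
                         tag=("hemi_lo", i, k))
        else:
            beta0 = -phi + eps_beta
            add_ring(c + r_arc * math.sin(beta0), c_r + r_arc * math.cos(beta0),
                     lab, tag=("eps", i))
            for k in range(1, n_barrel):
                beta = beta0 + (0.0 - beta0) * k / n_barrel
                tag = ("near_above", i) if k == 1 else None
                add_ring(c + r_arc * math.sin(beta), c_r + r_arc * math.cos(beta),
                         lab, tag=tag)
        add_ring(c, (c_r + r_arc) if n > 1 else R, lab, tag=("equator", i))
        # ---- upper half
        if i == n - 1:
            for k in range(1, n_hemi):
                beta = (math.pi / 2) * k / n_hemi
                add_ring(c + R * math.sin(beta), R * math.cos(beta), lab,
                         tag=("hemi_hi", i, k))
        else:
            for k in range(1, n_barrel):
                beta = phi * k / n_barrel
                tag = ("near_below", i) if k == n_barrel - 2 else None
                add_ring(c + r_arc * math.sin(beta), c_r + r_arc * math.cos(beta),
                         lab, tag=tag)
            # the shared contact ring; owned by the lower lobe
            add_ring(c + r_arc * math.sin(phi), a, lab, tag=("joint", i))

    theta = 2.0 * np.pi * np.arange(m) / m
    cos_t, sin_t = np.cos(theta), np.sin(theta)

    n_rings = len(rings)
    vertices = np.empty((2 + n_rings * m, 3))
    labels = np.empty(2 + n_rings * m, dtype=np.int64)
    pole_bot, pole_top = 0, 1
    vertices[pole_bot] = (0.0, 0.0, centers[0] - R)
    vertices[pole_top] = (0.0, 0.0, centers[-1] + R)
    labels[pole_bot] = 1
    labels[pole_top] = n

    def ring_vertex(r, j):
        return 2 + r * m + j

    for r, (z, rho, lab) in enumerate(rings):
        sl = slice(2 + r * m, 2 + (r + 1) * m)
        vertices[sl, 0] = rho * cos_t
        vertices[sl, 1] = rho * sin_t
        vertices[sl, 2] = z
        labels[sl] = lab

    faces: list[tuple[int, int, int]] = []
    for j in range(m):
        j2 = (j + 1) % m
        faces.append((pole_bot, ring_vertex(0, j2), ring_vertex(0, j)))
        faces.append((pole_top, ring_vertex(n_rings - 1, j),
                      ring_vertex(n_rings - 1, j2)))
    for r in range(n_rings - 1):
        for j in range(m):
            j2 = (j + 1) % m
            a0, b0 = ring_vertex(r, j), ring_vertex(r, j2)
            c1, d1 = ring_vertex(r + 1, j2), ring_vertex(r + 1, j)
            faces.append((a0, b0, c1))
            faces.append((a0, c1, d1))
    faces_arr = np.array(faces, dtype=np.int64)

    joint_ring_indices = [ring_tags[("joint", i)] for i in range(n - 1)]
    return vertices, faces_arr, labels, ring_tags, m, joint_ring_indices, ring_vertex


def _spindle_seed_layouts(spec: FixtureSpec, vertices, ring_tags, m, ring_vertex):
    """Deterministic 5- and 12-seed layouts: body-centre plus near-contact
    vertices, mirroring the clinical placement logic."""
    n = spec.n_lobes

    def at(tag, fractions):
        r = ring_tags[tag]
        return [tuple(vertices[ring_vertex(r, int(round(f * m)) % m)])
                for f in fractions]

    quarter = (0.0, 0.25, 0.5, 0.75)
    eighth = tuple(k / 8.0 for k in range(8))
    seeds5, seeds12 = [], []
    for i in range(n):
        lab = i + 1
        near_tags = []
        if i > 0:
            near_tags.append(("near_above", i))
        if i < n - 1:
            near_tags.append(("near_below", i))
        body1 = at(("equator", i), (0.0,))
        body4 = at(("equator", i), quarter)
        if not near_tags:                     # single closed lobe: no contacts
            hi_mid = ("hemi_hi", i, _mid_hemi(ring_tags, i, "hemi_hi"))
            lo_mid = ("hemi_lo", i, _mid_hemi(ring_tags, i, "hemi_lo"))
            five = body4 + at(hi_mid, (0.0,))
            twelve = body4 + at(hi_mid, quarter) + at(lo_mid, quarter)
        elif len(near_tags) == 1:
            five = body1 + at(near_tags[0], quarter)
            twelve = body4 + at(near_tags[0], eighth)
        else:
            five = body1 + at(near_tags[0], (0.0, 0.5)) + at(near_tags[1], (0.25, 0.75))
            twelve = body4 + at(near_tags[0], quarter) + at(near_tags[1], quarter)
        seeds5.extend((p, lab) for p in five)
        seeds12.extend((p, lab) for p in twelve)
    return seeds5, seeds12


def _mid_hemi(ring_tags, i, which):
    ks = sorted(t[2] for t in ring_tags if t[0] == which and t[1] == i)
    return ks[len(ks) // 2]


# ---------------------------------------------------------------- cube lobe


def _build_cube_chain(spec: FixtureSpec):
    """Stacked cubes of side 2*lobe_radius joined by square necks of half-width
    ~contact_radius; emitted as a triangle soup and welded by deduplication."""
    R, a = spec.lobe_radius, spec.contact_radius
    L = 2.0 * R
    ncell = max(2, int(round(L / spec.mesh_resolution)))
    ncell += ncell % 2
    cell = L / ncell
    hw = int(np.clip(round(a / cell), 1, ncell // 2 - 1))   # neck half-width in cells
    neck_h = cell
    n = spec.n_lobes
    centers = np.arange(n) * (L + neck_h)
    joints = centers[:-1] + R + neck_h / 2.0

    tris: list[np.ndarray] = []

    def emit_grid(origin, du, dv, nu, nv, skip=None):
        """Rectangular grid of nu x nv cells; ``skip(iu, iv)`` drops a cell.
        Winding follows (du, dv) so the normal is du x dv."""
        origin = np.asarray(origin, float)
        du, dv = np.asarray(du, float), np.asarray(dv, float)
        for iu in range(nu):
            for iv in range(nv):
                if skip is not None and skip(iu, iv):
                    continue
                p00 = origin + iu * du + iv * dv
                p10, p01, p11 = p00 + du, p00 + dv, p00 + du + dv
                tris.append(np.array([p00, p10, p11]))
                tris.append(np.array([p00, p11, p01]))

    lo_c, hi_c = ncell // 2 - hw, ncell // 2 + hw

    def central(iu, iv):
        return lo_c <= iu < hi_c and lo_c <= iv < hi_c

    ex, ey, ez = np.eye(3)
    for i, c in enumerate(centers):
        zlo, zhi = c - R, c + R
        # side walls (normals +-x, +-y)
        emit_grid((R, -R, zlo), ey * cell, ez * cell, ncell, ncell)            # +x
        emit_grid((-R, R, zlo), -ey * cell, ez * cell, ncell, ncell)           # -x
        emit_grid((R, R, zlo), -ex * cell, ez * cell, ncell, ncell)            # +y
        emit_grid((-R, -R, zlo), ex * cell, ez * cell, ncell, ncell)           # -y
        # top face (+z): central block removed when a neck sits above
        emit_grid((-R, -R, zhi), ex * cell, ey * cell, ncell, ncell,
                  skip=central if i < n - 1 else None)
        # bottom face (-z): winding flipped; central removed when neck below
        emit_grid((-R, R, zlo), ex * cell, -ey * cell, ncell, ncell,
                  skip=(lambda iu, iv: central(iu, ncell - 1 - iv)) if i > 0 else None)
        # neck above this cube
        if i < n - 1:
            w = hw * cell
            emit_grid((w, -w, zhi), ey * cell, ez * neck_h, 2 * hw, 1)         # +x wall
            emit_grid((-w, w, zhi), -ey * cell, ez * neck_h, 2 * hw, 1)        # -x wall
            emit_grid((w, w, zhi), -ex * cell, ez * neck_h, 2 * hw, 1)         # +y wall
            emit_grid((-w, -w, zhi), ex * cell, ez * neck_h, 2 * hw, 1)        # -y wall

    soup = np.concatenate(tris).reshape(-1, 3)
    faces = np.arange(len(soup)).reshape(-1, 3)
    mesh = clean_mesh(soup, faces, tolerance=1e-9)
    dz = np.abs(mesh.vertices[:, 2][:, None] - centers[None, :])
    labels = np.argmax(dz <= dz.min(axis=1)[:, None] + 1e-9, axis=1) + 1
    return mesh, labels.astype(np.int64), centers, joints


def _cube_seed_layouts(spec: FixtureSpec, mesh, labels, centers, joints):
    """Geometric seed picker for the cube chain: nearest own-lobe vertex to
    body-centre and near-contact target points."""
    R, a = spec.lobe_radius, spec.contact_radius
    off = 1.5 * spec.mesh_resolution
    seeds5, seeds12 = [], []
    quarter = (0.0, 90.0, 180.0, 270.0)
    eighth = tuple(45.0 * k for k in range(8))

    def nearest_own(lab, targets):
        idx = np.flatnonzero(labels == lab)
        tree = cKDTree(mesh.vertices[idx])
        out, used = [], set()
        for t in targets:
            _, j = tree.query(np.asarray(t, float))
            v = int(idx[j])
            if v not in used:
                used.add(v)
                out.append(tuple(mesh.vertices[v]))
        return out

    for i, c in enumerate(centers):
        lab = i + 1
        body = [(R * math.cos(math.radians(t)), R * math.sin(math.radians(t)), c)
                for t in quarter]
        near = []
        if i > 0:
            near.append((joints[i - 1] + off, quarter))
        if i < len(centers) - 1:
            near.append((joints[i] - off, quarter))
        if not near:
            contact5 = [(0.0, 0.0, c + R)]
            contact12 = [(R * 0.7 * math.cos(math.radians(t)),
                          R * 0.7 * math.sin(math.radians(t)), c + s * R * 0.7)
                         for s in (-1, 1) for t in quarter]
        elif len(near) == 1:
            z, _ = near[0]
            contact5 = [(a * math.cos(math.radians(t)), a * math.sin(math.radians(t)), z)
                        for t in quarter]
            contact12 = [(a * math.cos(math.radians(t)), a * math.sin(math.radians(t)), z)
                         for t in eighth]
        else:
            (z0, _), (z1, _) = near
            contact5 = [(a * math.cos(math.radians(t)), a * math.sin(math.radians(t)), z)
                        for z, ts in ((z0, (0.0, 180.0)), (z1, (90.0, 270.0)))
                        for t in ts]
            contact12 = [(a * math.cos(math.radians(t)), a * math.sin(math.radians(t)), z)
                         for z in (z0, z1) for t in quarter]
        seeds5.extend((p, lab) for p in nearest_own(lab, [body[0]] + contact5))
        seeds12.extend((p, lab) for p in nearest_own(lab, body + contact12))
    return seeds5, seeds12


# ----------------------------------------------------------------- chains


def generate_chain(spec: FixtureSpec) -> ChainFixture:
    """Generate a labelled lobe chain with suggested seed layouts.

    Output is bit-identical for identical specs.  ``hole_fraction`` > 0
    punches that fraction of the contact-zone faces (pairwise non-adjacent,
    so each punched face opens exactly one boundary loop); ``noise_sd`` > 0
    applies :func:`perturb_mesh` with the spec's random seed.
    """
    if spec.lobe_shape == "cube":
        mesh, labels, centers, joints = _build_cube_chain(spec)
        seeds5, seeds12 = _cube_seed_layouts(spec, mesh, labels, centers, joints)
        fixture = ChainFixture(mesh, labels, seeds5, seeds12, spec,
                               centers, joints)
    else:
        vertices, faces, labels, ring_tags, m, joint_rings, ring_vertex = \
            _build_spindle_chain(spec)
        mesh = TriangleMesh(vertices, faces)
        seeds5, seeds12 = _spindle_seed_layouts(spec, vertices, ring_tags, m,
                                                ring_vertex)
        _, _, _, h, centers, joints = _spindle_geometry(spec)
        fixture = ChainFixture(mesh, labels, seeds5, seeds12, spec,
                               centers, joints)
        if spec.hole_fraction > 0:
            _punch_contact_holes(fixture, ring_tags, m, ring_vertex)
    if spec.noise_sd > 0:
        fixture.mesh = perturb_mesh(fixture.mesh, spec.noise_sd, spec.random_seed)
    fixture.mesh.vertex_labels = fixture.labels
    return fixture


def _punch_contact_holes(fixture: ChainFixture, ring_tags, m, ring_vertex) -> None:
    spec = fixture.spec
    mesh, n = fixture.mesh, fixture.spec.n_lobes
    joint_vertices = set()
    for i in range(n - 1):
        r = ring_tags[("joint", i)]
        joint_vertices.update(ring_vertex(r, j) for j in range(m))
    touches = np.array([any(v in joint_vertices for v in f) for f in mesh.faces])
    candidates = np.flatnonzero(touches)
    k = int(round(spec.hole_fraction * len(candidates)))
    rng = np.random.default_rng(spec.random_seed)
    order = rng.permutation(len(candidates))
    chosen, used_vertices = [], set()
    for idx in order:
        f = mesh.faces[candidates[idx]]
        if used_vertices.isdisjoint(f):
            chosen.append(candidates[idx])
            used_vertices.update(int(v) for v in f)
            if len(chosen) == k:
                break
    keep = np.ones(mesh.n_faces, dtype=bool)
    keep[chosen] = False
    fixture.mesh = TriangleMesh(mesh.vertices, mesh.faces[keep])
    fixture.n_holes = len(chosen)


def two_cube_fixture(resolution: float = 0.5, lobe_radius: float = 1.0,
                     contact_radius: float = 0.4) -> ChainFixture:
    """Minimal worked example: two grid-subdivided cubes joined by a small
    square neck; every crease is 90 degrees."""
    return generate_chain(FixtureSpec(
        n_lobes=2, lobe_shape="cube", crease_angle=90.0,
        contact_radius=contact_radius, lobe_radius=lobe_radius,
        mesh_resolution=resolution))


# ------------------------------------------------------------------ noise


def perturb_mesh(mesh: TriangleMesh, noise_sd: float, random_seed: int) -> TriangleMesh:
    """Displace vertices along their (area-weighted) normals by zero-mean
    Gaussian noise; topology unchanged, seeded and reproducible."""
    if noise_sd < 0:
        raise InvalidSpecError("noise_sd must be >= 0")
    if noise_sd == 0:
        return TriangleMesh(mesh.vertices.copy(), mesh.faces.copy(),
                            vertex_labels=None if mesh.vertex_labels is None
                            else mesh.vertex_labels.copy())
    rng = np.random.default_rng(random_seed)
    eps = rng.normal(0.0, noise_sd, size=mesh.n_vertices)
    moved = mesh.vertices + eps[:, None] * mesh.vertex_normals
    return TriangleMesh(moved, mesh.faces.copy(),
                        vertex_labels=None if mesh.vertex_labels is None
                        else mesh.vertex_labels.copy())


# ---------------------------------------------------------------- phantoms


def _spindle_profile(spec: FixtureSpec):
    """Vectorised radius-of-z for the union of spindle lobes."""
    phi, r_arc, c_r, h, centers, _ = _spindle_geometry(spec)
    R = spec.lobe_radius
    n = spec.n_lobes

    def rho_of_z(z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, dtype=np.float64)
        rho = np.full(z.shape, -np.inf)
        for i, c in enumerate(centers):
            dz = z - c
            with np.errstate(invalid="ignore"):
                barrel = c_r + np.sqrt(np.maximum(r_arc ** 2 - dz ** 2, 0.0))
            sphere = np.sqrt(np.maximum(R ** 2 - dz ** 2, 0.0))
            # lower half: barrel down to the joint below, else a spherical cap
            lower = barrel if i > 0 else sphere
            span_lo = (dz >= (-h if i > 0 else -R)) & (dz <= 0)
            rho = np.where(span_lo, np.maximum(rho, lower), rho)
            # upper half: barrel up to the joint above, else a spherical cap
            upper = barrel if i < n - 1 else sphere
            span_hi = (dz > 0) & (dz <= (h if i < n - 1 else R))
            rho = np.where(span_hi, np.maximum(rho, upper), rho)
        return rho

    z_min = centers[0] - R
    z_max = centers[-1] + R
    return rho_of_z, z_min, z_max, centers


def generate_phantom_volume(spec: FixtureSpec, spacing=(0.5, 0.5, 0.5),
                            bone_hu: float = 300.0,
                            background_hu: float = 0.0) -> Volume:
    """Voxelise the chain solid on an axis-aligned grid.

    The returned :class:`Volume` records its interior voxel count
    (``interior_count``) so thresholding can be validated against the
    generator's own bookkeeping.
    """
    if bone_hu <= background_hu:
        raise InvalidSpecError("bone_hu must exceed background_hu")
    if spec.lobe_shape != "spindle":
        raise InvalidSpecError("phantom volumes are defined for spindle chains")
    spacing = np.asarray(spacing, dtype=np.float64)
    if (spacing <= 0).any():
        raise InvalidSpecError("spacing must be strictly positive")
    rho_of_z, z_min, z_max, centers = _spindle_profile(spec)
    R = spec.lobe_radius
    margin = 2.0 * spacing
    origin = np.array([-R - margin[0], -R - margin[1], z_min - margin[2]])
    extent = np.array([2 * R + 2 * margin[0], 2 * R + 2 * margin[1],
                       (z_max - z_min) + 2 * margin[2]])
    shape = np.maximum(np.ceil(extent / spacing).astype(int) + 1, 2)

    xs = origin[0] + spacing[0] * np.arange(shape[0])
    ys = origin[1] + spacing[1] * np.arange(shape[1])
    zs = origin[2] + spacing[2] * np.arange(shape[2])
    rho_z = rho_of_z(zs)                                  # (nz,)
    r_xy = np.hypot(xs[:, None], ys[None, :])             # (nx, ny)
    inside = r_xy[:, :, None] <= rho_z[None, None, :]

    # a lobe must survive voxelisation
    half = 0.5 * (centers[1] - centers[0]) if len(centers) > 1 else R
    for c in centers:
        zsel = (zs >= c - half) & (zs <= c + half)
        if not inside[:, :, zsel].any():
            raise InvalidSpecError(
                f"spacing {tuple(spacing)} too coarse: lobe at z={c:.1f} vanished")

    data = np.where(inside, float(bone_hu), float(background_hu))
    affine = np.eye(4)
    affine[:3, :3] = np.diag(spacing)
    affine[:3, 3] = origin
    return Volume(data, affine, interior_count=int(inside.sum()))
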