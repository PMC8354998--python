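"""Triangle-mesh data model, I/O and connectivity queries.

The central object is :class:`TriangleMesh`: indexed vertex/face arrays in
world millimetres with per-vertex unit normals, edge adjacency and optional
per-vertex integer labels.  Everything downstream (region growing, distance
metrics, fixture generation) consumes this type.

Conventions
-----------
* indices are 0-based everywhere;
* coordinates are world millimetres;
* vertex normals are the area-weighted mean of incident face normals,
  renormalised to unit length (marching-cubes output has highly nonuniform
  triangle sizes, so area weighting beats a plain mean);
* a vertex with no incident face gets a zero normal and is flagged
  unsegmentable rather than raising at construction time.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh
from scipy.spatial import cKDTree

from .errors import InvalidInputError, MeshFormatError, UnsegmentableVertexError

#: vertices closer than this (mm) are merged on ingestion
MERGE_TOLERANCE_MM = 1e-6

_FORMATS = ("stl", "ply", "obj")


@dataclass
class TriangleMesh:
    """An indexed triangle surface mesh in world millimetres.

    Parameters
    ----------
    vertices : (n, 3) float array
    faces : (m, 3) int array of 0-based vertex indices
    vertex_labels : optional (n,) int array, 0 = unassigned

    Derived quantities (normals, areas, adjacency) are computed lazily and
    cached; mutate ``vertices``/``faces`` only through construction of a new
    mesh.
    """

    vertices: np.ndarray
    faces: np.ndarray
    vertex_labels: np.ndarray | None = None

    _face_normals: np.ndarray | None = field(default=None, repr=False, compare=False)
    _face_areas: np.ndarray | None = field(default=None, repr=False, compare=False)
    _vertex_normals: np.ndarray | None = field(default=None, repr=False, compare=False)
    _adjacency: list | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise InvalidInputError("vertices must be an (n, 3) array")
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= len(self.vertices)):
            raise InvalidInputError("face indices out of range")
        if self.vertex_labels is not None:
            self.vertex_labels = np.asarray(self.vertex_labels, dtype=np.int64)
            if self.vertex_labels.shape != (len(self.vertices),):
                raise InvalidInputError("vertex_labels must have one entry per vertex")

    # ------------------------------------------------------------------ sizes
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    # ---------------------------------------------------------------- normals
    @property
    def face_normals(self) -> np.ndarray:
        if self._face_normals is None:
            self._compute_face_geometry()
        return self._face_normals

    @property
    def face_areas(self) -> np.ndarray:
        if self._face_areas is None:
            self._compute_face_geometry()
        return self._face_areas

    def _compute_face_geometry(self) -> None:
        tri = self.vertices[self.faces]
        cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        norms = np.linalg.norm(cross, axis=1)
        areas = 0.5 * norms
        with np.errstate(invalid="ignore", divide="ignore"):
            normals = np.where(norms[:, None] > 0, cross / np.where(norms == 0, 1, norms)[:, None], 0.0)
        self._face_normals = normals
        self._face_areas = areas

    @property
    def vertex_normals(self) -> np.ndarray:
        """Unit vertex normals; zero for isolated (unsegmentable) vertices."""
        if self._vertex_normals is None:
            self._vertex_normals = compute_vertex_normals(self)
        return self._vertex_normals

    @property
    def segmentable(self) -> np.ndarray:
        """Boolean mask of vertices with a well-defined (nonzero) normal."""
        return np.linalg.norm(self.vertex_normals, axis=1) > 0.5

    # -------------------------------------------------------------- adjacency
    @property
    def adjacency(self) -> list:
        """Per-vertex neighbour index arrays, each sorted ascending."""
        if self._adjacency is None:
            self._adjacency = vertex_adjacency(self)
        return self._adjacency

    def edges_unique(self) -> np.ndarray:
        """Unique undirected edges as an (e, 2) array with u < v."""
        e = np.sort(self.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
        return np.unique(e, axis=0)

    # ------------------------------------------------------------------ misc
    def signed_volume(self) -> float:
        """Signed enclosed volume (divergence theorem); positive for outward winding."""
        tri = self.vertices[self.faces]
        return float(np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])).sum() / 6.0)

    def bounds(self) -> np.ndarray:
        return np.array([self.vertices.min(axis=0), self.vertices.max(axis=0)])

    def to_trimesh(self) -> trimesh.Trimesh:
        mesh = trimesh.Trimesh(self.vertices.copy(), self.faces.copy(), process=False)
        if self.vertex_labels is not None:
            mesh.vertex_attributes["label"] = self.vertex_labels.astype(np.int32)
        return mesh


@dataclass
class BoundaryLoop:
    """An ordered closed cycle of vertex indices along edges with exactly one face."""

    vertices: np.ndarray

    def __len__(self) -> int:
        return len(self.vertices)


# --------------------------------------------------------------------- build


def clean_mesh(vertices: np.ndarray, faces: np.ndarray,
               vertex_labels: np.ndarray | None = None,
               tolerance: float = MERGE_TOLERANCE_MM) -> TriangleMesh:
    """Merge duplicate vertices within ``tolerance`` mm and drop degenerate faces.

    STL stores three loose vertices per facet, so deduplication is required
    before edge adjacency is meaningful.  Merging is transitive (union-find on
    all pairs closer than the tolerance); the surviving representative is the
    lowest index of each cluster.
    """
    vertices = np.asarray(vertices, dtype=np.float64)
    faces = np.asarray(faces, dtype=np.int64)
    if len(vertices) == 0 or len(faces) == 0:
        raise InvalidInputError("mesh is empty")

    tree = cKDTree(vertices)
    pairs = tree.query_pairs(r=tolerance, output_type="ndarray")
    parent = np.arange(len(vertices))

    def find(i: int) -> int:
        root = i
        while parent[root] != root:
            root = parent[root]
        while parent[i] != root:
            parent[i], i = root, parent[i]
        return root

    for a, b in pairs:
        ra, rb = find(int(a)), find(int(b))
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)
    roots = np.array([find(int(i)) for i in range(len(vertices))])
    kept, inverse = np.unique(roots, return_inverse=True)
    new_vertices = vertices[kept]
    new_faces = inverse[faces]
    labels = None if vertex_labels is None else np.asarray(vertex_labels)[kept]

    # drop faces with a repeated index or (numerically) zero area
    distinct = (
        (new_faces[:, 0] != new_faces[:, 1])
        & (new_faces[:, 1] != new_faces[:, 2])
        & (new_faces[:, 0] != new_faces[:, 2])
    )
    new_faces = new_faces[distinct]
    tri = new_vertices[new_faces]
    areas = 0.5 * np.linalg.norm(np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1)
    new_faces = new_faces[areas > 1e-14]
    if len(new_faces) == 0:
        raise InvalidInputError("mesh has no non-degenerate faces")
    return TriangleMesh(new_vertices, new_faces, vertex_labels=labels)


def compute_vertex_normals(mesh: TriangleMesh) -> np.ndarray:
    """Area-weighted mean of incident face normals, renormalised to unit length.

    The cross product of two triangle edges has magnitude 2*area and the
    direction of the face normal, so accumulating raw cross products performs
    the area weighting implicitly.  Isolated vertices get the zero vector.
    """
    tri = mesh.vertices[mesh.faces]
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    acc = np.zeros_like(mesh.vertices)
    for k in range(3):
        np.add.at(acc, mesh.faces[:, k], cross)
    norms = np.linalg.norm(acc, axis=1)
    out = np.zeros_like(acc)
    nz = norms > 1e-300
    out[nz] = acc[nz] / norms[nz, None]
    return out


def vertex_adjacency(mesh: TriangleMesh) -> list:
    """Neighbour map: ``adjacency[u]`` = sorted array of vertices sharing an edge with u.

    Sorting ascending by index is part of the determinism contract of the
    region-growing traversal.
    """
    edges = mesh.edges_unique()
    both = np.vstack([edges, edges[:, ::-1]])
    order = np.lexsort((both[:, 1], both[:, 0]))
    both = both[order]
    counts = np.bincount(both[:, 0], minlength=mesh.n_vertices)
    offsets = np.concatenate([[0], np.cumsum(counts)])
    return [both[offsets[u]:offsets[u + 1], 1] for u in range(mesh.n_vertices)]


def normal_angle(mesh: TriangleMesh, u: int, v: int) -> float:
    """Angle in degrees between the vertex normals of u and v, in [0, 180]."""
    nu = mesh.vertex_normals[u]
    nv = mesh.vertex_normals[v]
    if np.linalg.norm(nu) < 0.5 or np.linalg.norm(nv) < 0.5:
        raise UnsegmentableVertexError(f"vertex {u if np.linalg.norm(nu) < 0.5 else v} has no normal")
    return float(np.degrees(np.arccos(np.clip(np.dot(nu, nv), -1.0, 1.0))))


def normal_angles(normals: np.ndarray, u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Vectorised :func:`normal_angle` over index arrays (no zero-normal check)."""
    dots = np.einsum("ij,ij->i", normals[u], normals[v])
    return np.degrees(np.arccos(np.clip(dots, -1.0, 1.0)))


# ------------------------------------------------------------ boundary loops


def find_boundary_loops(mesh: TriangleMesh) -> list[BoundaryLoop]:
    """Return one :class:`BoundaryLoop` per hole; empty list for a watertight mesh.

    A boundary edge is incident to exactly one face.  Loops follow the
    orientation induced by the adjacent face's winding.  Edges with more than
    two incident faces are non-manifold; they are reported with a warning and
    excluded (marching cubes can emit them, so this is not fatal).
    """
    # directed edges as they appear in faces
    directed = mesh.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2)
    und = np.sort(directed, axis=1)
    uniq, inverse, counts = np.unique(und, axis=0, return_inverse=True, return_counts=True)
    n_nonmanifold = int((counts > 2).sum())
    if n_nonmanifold:
        warnings.warn(f"{n_nonmanifold} non-manifold edges (more than 2 incident faces)")
    boundary_mask = counts[inverse] == 1
    # boundary half-edge (a, b): traverse b -> a so loops run counter to the
    # face winding, which makes hole rims consistently oriented
    successors: dict[int, list[int]] = {}
    for a, b in directed[boundary_mask]:
        successors.setdefault(int(b), []).append(int(a))
    for v in successors:
        successors[v].sort()

    loops: list[BoundaryLoop] = []
    while successors:
        start = min(successors)
        loop = [start]
        current = start
        while True:
            nxts = successors.get(current)
            if not nxts:
                break  # open chain (non-manifold boundary); emit as-is
            nxt = nxts.pop(0)
            if not nxts:
                del successors[current]
            if nxt == start:
                break
            loop.append(nxt)
            current = nxt
        loops.append(BoundaryLoop(np.array(loop, dtype=np.int64)))
    return loops


# ------------------------------------------------------------------------ IO


def _infer_format(path: Path, fmt: str) -> str:
    if fmt != "auto":
        if fmt not in _FORMATS:
            raise MeshFormatError(f"unsupported format {fmt!r}; expected one of {_FORMATS}")
        return fmt
    suffix = path.suffix.lower().lstrip(".")
    if suffix not in _FORMATS:
        raise MeshFormatError(f"cannot infer mesh format from suffix {path.suffix!r}")
    return suffix


def load_mesh(path: str | Path, fmt: str = "auto") -> TriangleMesh:
    """Load an STL/PLY/OBJ mesh, deduplicate vertices and drop degenerate faces.

    A PLY per-vertex integer property named ``label`` is preserved into
    ``vertex_labels``.
    """
    path = Path(path)
    if not path.exists():
        raise MeshFormatError(f"mesh file not found: {path}")
    fmt_resolved = _infer_format(path, fmt)
    try:
        raw = trimesh.load(str(path), file_type=fmt_resolved, process=False, force="mesh")
    except Exception as exc:  # trimesh raises assorted types for bad files
        raise MeshFormatError(f"could not read {path} as {fmt_resolved}: {exc}") from exc
    if not isinstance(raw, trimesh.Trimesh) or len(raw.vertices) == 0 or len(raw.faces) == 0:
        raise InvalidInputError(f"{path} contains no triangle geometry")

    labels = None
    va = raw.vertex_attributes.get("label") if hasattr(raw, "vertex_attributes") else None
    if va is not None:
        labels = np.asarray(va).ravel().astype(np.int64)
    else:
        ply_raw = raw.metadata.get("_ply_raw") if hasattr(raw, "metadata") else None
        if ply_raw is not None and "vertex" in ply_raw:
            data = ply_raw["vertex"].get("data")
            names = (data.dtype.names if isinstance(data, np.ndarray)
                     else data.keys() if isinstance(data, dict) else ())
            if names and "label" in names:
                labels = np.asarray(data["label"]).ravel().astype(np.int64)
    return clean_mesh(np.asarray(raw.vertices), np.asarray(raw.faces), vertex_labels=labels)


def save_mesh(mesh: TriangleMesh, path: str | Path, fmt: str = "auto") -> Path:
    """Write a mesh to STL (binary), PLY or OBJ.

    Labels ride along only in PLY (as a per-vertex int32 ``label`` property);
    writing a labelled mesh to STL/OBJ silently drops the labels, which those
    formats cannot carry.
    """
    path = Path(path)
    fmt_resolved = _infer_format(path, fmt)
    tm = mesh.to_trimesh()
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt_resolved == "ply":
        from trimesh.exchange.ply import export_ply

        data = export_ply(tm, encoding="binary", include_attributes=True)
        path.write_bytes(data)
    else:
        tm.export(str(path), file_type=fmt_resolved)
    return path


def submesh_for_mask(mesh: TriangleMesh, vertex_mask: np.ndarray) -> tuple[TriangleMesh, int]:
    """Submesh of faces whose three vertices are all inside ``vertex_mask``.

    Returns the submesh (reindexed, unreferenced vertices dropped) and the
    number of faces that straddle the mask boundary (omitted faces that touch
    at least one in-mask vertex).
    """
    vertex_mask = np.asarray(vertex_mask, dtype=bool)
    inside = vertex_mask[mesh.faces]
    keep = inside.all(axis=1)
    spanning = int((inside.any(axis=1) & ~keep).sum())
    faces = mesh.faces[keep]
    if len(faces) == 0:
        raise InvalidInputError("mask selects no whole face")
    used = np.unique(faces)
    remap = np.full(mesh.n_vertices, -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    labels = None if mesh.vertex_labels is None else mesh.vertex_labels[used]
    return TriangleMesh(mesh.vertices[used], remap[faces], vertex_labels=labels), spanning
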