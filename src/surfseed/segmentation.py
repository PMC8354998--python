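"""Seed-point surface region growing with iterative threshold adaptation.

The core method: the user marks each bone segment with one or more seed
points on the extracted surface; regions grow outward from the seeds in
breadth-first order, crossing an edge only when the angle between the two
vertex normals stays below a connectivity threshold.  Smooth surface patches
are flooded like an oil spill while sharp creases (where touching segments
meet) act as natural barriers.  The threshold starts low and is raised
between passes, so smooth interiors are claimed early and tighter corners
are conquered later; the pass history supports undo so a user (or a
programmatic hook) can retract a pass that leaked and add seeds instead.

Determinism contract
--------------------
* the frontier is enqueued sorted ascending by vertex index;
* traversal is strict FIFO (breadth-first);
* a dequeued vertex visits its unlabelled neighbours in ascending index
  order;
* a vertex is never relabelled once assigned.

Under these rules the output is a pure function of (mesh, seeds, schedule),
independent of hash ordering or platform.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .errors import InvalidInputError, InvalidSeedError
from .mesh import TriangleMesh, save_mesh, submesh_for_mask


@dataclass(frozen=True)
class SeedPoint:
    """A world-coordinate seed with a segment label, snapped to its nearest vertex."""

    position: tuple[float, float, float]
    label: int
    snapped_vertex: int

    def __post_init__(self) -> None:
        if self.label < 1:
            raise InvalidSeedError(f"segment label must be >= 1, got {self.label}")


@dataclass(frozen=True)
class ThresholdSchedule:
    """Connectivity-angle schedule: start at ``theta_init`` degrees, raise by
    ``theta_step`` after each pass, never exceed ``theta_max``."""

    theta_init: float = 5.0
    theta_step: float = 5.0
    theta_max: float = 60.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.theta_init <= self.theta_max <= 180.0):
            raise InvalidInputError("require 0 <= theta_init <= theta_max <= 180")
        if self.theta_step <= 0:
            raise InvalidInputError("theta_step must be positive")

    def thetas(self) -> list[float]:
        out = []
        theta = self.theta_init
        while theta <= self.theta_max + 1e-12:
            out.append(min(theta, self.theta_max))
            theta += self.theta_step
        return out


@dataclass
class PassRecord:
    """One region-growing pass: threshold used, vertices newly labelled (with
    their labels), and any seeds added just before the pass."""

    theta: float
    newly_labeled: np.ndarray          # vertex indices
    newly_labels: np.ndarray           # label per newly labelled vertex
    seeds_added: list[SeedPoint] = field(default_factory=list)


@dataclass
class LabelState:
    """Per-vertex segment assignment (0 = unassigned) plus replayable history.

    ``seeds`` holds every planted seed (seed vertices are labelled directly,
    outside any pass, and survive an undo); ``pass_log`` holds one record per
    region-growing pass.  ``replay`` reconstructs the labels from history.
    """

    labels: np.ndarray
    pass_log: list[PassRecord] = field(default_factory=list)
    seeds: list[SeedPoint] = field(default_factory=list)

    @classmethod
    def empty(cls, n_vertices: int) -> "LabelState":
        return cls(labels=np.zeros(n_vertices, dtype=np.int64))

    @property
    def n_labeled(self) -> int:
        return int((self.labels > 0).sum())

    def replay(self) -> np.ndarray:
        """Reconstruct the label array from the seed list and pass log."""
        labels = np.zeros_like(self.labels)
        for rec in self.pass_log:
            for s in rec.seeds_added:
                labels[s.snapped_vertex] = s.label
            labels[rec.newly_labeled] = rec.newly_labels
        for s in self.seeds:
            labels[s.snapped_vertex] = s.label
        return labels


# ------------------------------------------------------------------- seeding


def snap_seeds(mesh: TriangleMesh, raw_seeds: list[tuple]) -> list[SeedPoint]:
    """Snap (position, label) pairs to their nearest mesh vertices.

    Ties (several vertices exactly nearest) break to the lowest vertex index.
    Two seeds may share a vertex only if they agree on the label.
    """
    if mesh.n_vertices == 0:
        raise InvalidInputError("cannot snap seeds onto an empty mesh")
    if len(raw_seeds) == 0:
        raise InvalidInputError("at least one seed point is required")
    tree = cKDTree(mesh.vertices)
    seeds: list[SeedPoint] = []
    taken: dict[int, SeedPoint] = {}
    for pos, label in raw_seeds:
        pos = np.asarray(pos, dtype=np.float64)
        d, idx = tree.query(pos)
        # resolve exact/near ties deterministically to the lowest index
        cands = tree.query_ball_point(pos, d + 1e-9)
        dists = np.linalg.norm(mesh.vertices[cands] - pos, axis=1)
        dmin = dists.min()
        snapped = min(c for c, dd in zip(cands, dists) if dd <= dmin + 1e-12)
        seed = SeedPoint(tuple(float(x) for x in pos), int(label), int(snapped))
        prev = taken.get(snapped)
        if prev is not None and prev.label != seed.label:
            raise InvalidSeedError(
                f"seeds {prev.position} (label {prev.label}) and {seed.position} "
                f"(label {seed.label}) snap to the same vertex {snapped}"
            )
        if prev is None:
            taken[snapped] = seed
            seeds.append(seed)
    return seeds


# ------------------------------------------------------------------- growing


def region_grow_pass(mesh: TriangleMesh, state: LabelState,
                     frontier: list[tuple[int, int]], theta: float,
                     seeds_added: list[SeedPoint] | None = None) -> LabelState:
    """One breadth-first region-growing pass at fixed threshold ``theta`` degrees.

    ``frontier`` is a list of (vertex, label) pairs, all already labelled in
    ``state``.  A dequeued vertex labels and enqueues each of its unlabelled
    neighbours (ascending index) whose normal lies within ``theta`` degrees of
    its own.  Existing labels are never overwritten.  The newly labelled set
    is appended to the pass log; the state is extended in place and returned.
    """
    if not (0.0 <= theta <= 180.0):
        raise InvalidInputError("theta must lie in [0, 180] degrees")
    labels = state.labels
    for v, lab in frontier:
        if labels[v] != lab:
            raise InvalidInputError(f"frontier vertex {v} is not labelled {lab}")

    normals = mesh.vertex_normals
    segmentable = mesh.segmentable
    adjacency = mesh.adjacency
    cos_limit = np.cos(np.radians(theta)) - 1e-12  # dot >= cos_limit <=> angle <= theta

    queue = deque(sorted(frontier))
    newly: list[int] = []
    while queue:
        u, lab = queue.popleft()
        nu = normals[u]
        for v in adjacency[u]:
            if labels[v] == 0 and segmentable[v]:
                if float(nu @ normals[v]) >= cos_limit:
                    labels[v] = lab
                    newly.append(int(v))
                    queue.append((int(v), lab))
    newly_arr = np.array(newly, dtype=np.int64)
    state.pass_log.append(PassRecord(
        theta=float(theta),
        newly_labeled=newly_arr,
        newly_labels=labels[newly_arr].copy(),
        seeds_added=list(seeds_added or []),
    ))
    return state


def _compute_frontier(mesh: TriangleMesh, labels: np.ndarray) -> list[tuple[int, int]]:
    """Labelled vertices that still border an unlabelled segmentable vertex."""
    segmentable = mesh.segmentable
    adjacency = mesh.adjacency
    frontier = []
    for v in np.flatnonzero(labels > 0):
        nbrs = adjacency[v]
        if np.any((labels[nbrs] == 0) & segmentable[nbrs]):
            frontier.append((int(v), int(labels[v])))
    return frontier


@dataclass
class HookAction:
    """What an interactive hook may request after a pass: undo it and/or add seeds."""

    undo: bool = False
    add_seeds: list[tuple] = field(default_factory=list)  # raw (position, label)


def iterative_segment(mesh: TriangleMesh, seeds: list[SeedPoint],
                      schedule: ThresholdSchedule = ThresholdSchedule(),
                      interactive_hook=None) -> LabelState:
    """Run the full iterative schedule: grow at theta_init, then raise the
    threshold by theta_step and re-grow from the current boundary until every
    segmentable vertex is labelled or the schedule ceiling is exceeded.

    ``interactive_hook(state, theta)`` is called after each pass and may
    return a :class:`HookAction` to undo the pass and/or add seeds, mirroring
    interactive use; when it undoes a pass the same threshold is retried.
    Terminates with a warning (not an error) if unreachable vertices remain
    at theta_max.
    """
    if len(seeds) == 0:
        raise InvalidInputError("at least one seed point is required")
    state = LabelState.empty(mesh.n_vertices)
    pending = _apply_seeds(mesh, state, seeds)

    thetas = schedule.thetas()
    i = 0
    while i < len(thetas):
        theta = thetas[i]
        if int((mesh.segmentable & (state.labels == 0)).sum()) == 0:
            break
        frontier = _compute_frontier(mesh, state.labels)
        if not frontier and not pending:
            break  # unlabelled vertices exist but are unreachable from any label
        state = region_grow_pass(mesh, state, frontier, theta, seeds_added=pending)
        pending = []
        remaining = int((mesh.segmentable & (state.labels == 0)).sum())
        if interactive_hook is not None:
            action = interactive_hook(state, theta)
            if action is not None:
                if action.undo:
                    undone = state.pass_log[-1] if state.pass_log else None
                    undo_last_pass(state)
                    if undone is not None:
                        pending = list(undone.seeds_added)
                if action.add_seeds:
                    new = snap_seeds(mesh, action.add_seeds)
                    pending = pending + _apply_seeds(mesh, state, new)
                if action.undo:
                    continue  # retry the same threshold after intervention
                remaining = int((mesh.segmentable & (state.labels == 0)).sum())
        if remaining == 0:
            break
        i += 1
    remaining = int((mesh.segmentable & (state.labels == 0)).sum())
    if remaining:
        warnings.warn(f"{remaining} vertices remain unlabelled at theta_max")
    return state


def _apply_seeds(mesh: TriangleMesh, state: LabelState, seeds: list[SeedPoint]) -> list[SeedPoint]:
    """Label seed vertices directly; returns the seeds for pass-log bookkeeping."""
    for s in seeds:
        existing = state.labels[s.snapped_vertex]
        if existing not in (0, s.label):
            raise InvalidSeedError(
                f"seed {s.position} (label {s.label}) snaps to vertex "
                f"{s.snapped_vertex} already labelled {existing}"
            )
        state.labels[s.snapped_vertex] = s.label
        state.seeds.append(s)
    return list(seeds)


def undo_last_pass(state: LabelState) -> LabelState:
    """Revert every vertex labelled in the most recent pass; planted seeds are
    user input, not growth, and keep their labels.  No-op with a warning when
    the log is empty."""
    if not state.pass_log:
        warnings.warn("undo requested but no pass has been run")
        return state
    rec = state.pass_log.pop()
    state.labels[rec.newly_labeled] = 0
    return state


# ------------------------------------------------------------------- export


@dataclass
class ExportReport:
    """Outcome of :func:`export_segments`: written files and omitted-face count."""

    files: dict[int, Path]
    omitted_faces: int
    skipped_labels: list[int]


def export_segments(mesh: TriangleMesh, state: LabelState, out_dir: str | Path,
                    fmt: str = "ply") -> ExportReport:
    """Write one mesh file per label: the submesh of faces whose three vertices
    share that label.  Faces spanning labels or touching unlabelled vertices
    are omitted and counted; segments are exported as-is (holes included)."""
    labels = state.labels
    if not (labels > 0).any():
        raise InvalidInputError("no labelled vertices to export")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    face_labels = labels[mesh.faces]
    whole = (face_labels[:, 0] == face_labels[:, 1]) \
        & (face_labels[:, 1] == face_labels[:, 2]) & (face_labels[:, 0] > 0)
    omitted = int((~whole).sum())

    files: dict[int, Path] = {}
    skipped: list[int] = []
    for lab in sorted(int(x) for x in np.unique(labels[labels > 0])):
        try:
            sub, _ = submesh_for_mask(mesh, labels == lab)
        except InvalidInputError:
            warnings.warn(f"label {lab} has no whole face; skipping its file")
            skipped.append(lab)
            continue
        path = out_dir / f"segment_{lab:03d}.{fmt}"
        save_mesh(sub, path, fmt=fmt)
        files[lab] = path
    return ExportReport(files=files, omitted_faces=omitted, skipped_labels=skipped)


def extract_segment(mesh: TriangleMesh, labels: np.ndarray, label: int) -> TriangleMesh:
    """In-memory counterpart of :func:`export_segments` for a single label."""
    sub, _ = submesh_for_mask(mesh, np.asarray(labels) == label)
    return sub
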