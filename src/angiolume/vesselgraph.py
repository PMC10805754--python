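"""Vascular graph extraction and per-segment morphology features.

A binary vessel segmentation is converted into a spatial graph: 3D
thinning yields a one-voxel centerline; skeleton voxels with three or
more skeleton neighbors cluster into branch nodes and voxels with a
single neighbor become end nodes; skeleton paths between nodes become
vessel segments. Each centerline point carries the local radius (the
Euclidean distance transform of the segmentation evaluated on the
skeleton), every foreground voxel is assigned to the segment owning its
nearest centerline voxel, and spur branches shorter than
``bulge_size × local radius`` are treated as surface bulges and pruned.

Per-segment features are the standard vascular descriptors: arc length,
volume (assigned voxels × voxel volume), average cross-section area
(volume / length), radius statistics, and curveness — arc length over
endpoint chord, the classic tortuosity ratio (≥ 1, = 1 for a straight
vessel).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize

_STRUCT26 = np.ones((3, 3, 3), bool)


@dataclass
class SegmentFeatures:
    length: float
    volume: float
    avg_cross_section: float
    avg_radius: float
    min_radius: float
    max_radius: float
    curveness: float

    def as_dict(self) -> dict:
        return dict(vars(self))


@dataclass
class Node:
    id: int
    position_um: np.ndarray
    degree: int = 0


@dataclass
class Segment:
    id: int
    node_a: int
    node_b: int
    centerline_um: np.ndarray        # (N, 3) physical coordinates
    radii_um: np.ndarray             # (N,)
    skeleton_voxels: np.ndarray      # (N, 3) integer grid coordinates
    voxel_count: int = 0
    features: SegmentFeatures | None = None
    degenerate: bool = False


@dataclass
class VesselGraph:
    nodes: list[Node]
    segments: list[Segment]
    spacing: tuple[float, float, float]
    shape: tuple[int, int, int] = (0, 0, 0)

    def to_networkx(self):
        import networkx as nx

        g = nx.MultiGraph()
        for n in self.nodes:
            g.add_node(n.id, position_um=n.position_um, degree=n.degree)
        for s in self.segments:
            g.add_edge(s.node_a, s.node_b, key=s.id, segment=s)
        return g

    def feature_table(self):
        """Per-segment feature rows (non-degenerate segments only)."""
        import pandas as pd

        rows = []
        for s in self.segments:
            if s.degenerate or s.features is None:
                continue
            row = {"segment_id": s.id, "node_a": s.node_a, "node_b": s.node_b,
                   "voxel_count": s.voxel_count}
            row.update(s.features.as_dict())
            rows.append(row)
        return pd.DataFrame(rows)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "spacing": list(self.spacing),
            "shape": list(self.shape),
            "nodes": [
                {"id": int(n.id), "position_um": n.position_um.tolist(), "degree": int(n.degree)}
                for n in self.nodes
            ],
            "segments": [
                {
                    "id": int(s.id),
                    "node_a": int(s.node_a),
                    "node_b": int(s.node_b),
                    "centerline_um": s.centerline_um.tolist(),
                    "radii_um": s.radii_um.tolist(),
                    "voxel_count": int(s.voxel_count),
                    "degenerate": bool(s.degenerate),
                    "features": s.features.as_dict() if s.features else None,
                }
                for s in self.segments
            ],
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "VesselGraph":
        payload = json.loads(Path(path).read_text())
        nodes = [Node(d["id"], np.asarray(d["position_um"]), d["degree"]) for d in payload["nodes"]]
        segments = []
        for d in payload["segments"]:
            feats = SegmentFeatures(**d["features"]) if d["features"] else None
            segments.append(
                Segment(
                    d["id"], d["node_a"], d["node_b"],
                    np.asarray(d["centerline_um"]), np.asarray(d["radii_um"]),
                    np.zeros((0, 3), int), d["voxel_count"], feats, d["degenerate"],
                )
            )
        return cls(nodes, segments, tuple(payload["spacing"]), tuple(payload["shape"]))


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------

def to_isotropic(
    seg: np.ndarray, spacing: tuple[float, float, float]
) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Nearest-neighbor super-sampling along z to the in-plane spacing.

    Light-sheet stacks are coarser along z; replicating each slice
    ``round(dz/dx)`` times preserves foreground topology while making the
    grid isotropic, which the distance-based radius estimates require.
    """
    if spacing is None:
        raise ValueError("spacing metadata is required for isotropic resampling")
    dz, dy, dx = spacing
    if not np.isclose(dy, dx):
        raise ValueError(f"in-plane spacing must be isotropic, got dy={dy}, dx={dx}")
    if dz < dx - 1e-9:
        raise ValueError("z spacing must be ≥ in-plane spacing")
    factor = int(round(dz / dx))
    if factor == 1:
        return np.asarray(seg), (dx, dy, dx)
    out = np.repeat(np.asarray(seg), factor, axis=0)
    return out, (dz / factor, dy, dx)


# ---------------------------------------------------------------------------
# graph extraction
# ---------------------------------------------------------------------------

_OFFSETS = np.array(
    [(dz, dy, dx) for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
     if (dz, dy, dx) != (0, 0, 0)]
)


def _neighbors(coord, skel):
    out = []
    for off in _OFFSETS:
        c = coord + off
        if np.all(c >= 0) and np.all(c < skel.shape) and skel[tuple(c)]:
            out.append(tuple(c))
    return out


def extract_graph(
    seg: np.ndarray,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    bulge_size: float = 1.0,
) -> VesselGraph:
    """Build the vascular graph of an isotropic binary segmentation.

    See the module docstring for the algorithm. An empty segmentation
    yields an empty graph; closed loops without branch points receive one
    artificial anchor node carrying a single self-segment.
    """
    seg = np.asarray(seg) > 0
    sp = np.asarray(spacing, float)
    if not (np.isclose(sp[0], sp[1]) and np.isclose(sp[1], sp[2])):
        raise ValueError("extract_graph requires an isotropic grid; call to_isotropic first")
    graph = VesselGraph([], [], tuple(spacing), seg.shape)
    if not seg.any():
        return graph

    skel = skeletonize(seg).astype(bool)
    if not skel.any():
        # segmentation too small/thin to skeletonize: no graph
        return graph
    edt = ndimage.distance_transform_edt(seg)

    # neighbor counts within the skeleton (26-connectivity)
    ncount = ndimage.convolve(skel.astype(np.uint8), _STRUCT26.astype(np.uint8), mode="constant") - 1
    ncount[~skel] = 0

    is_branch = skel & (ncount >= 3)
    is_end = skel & (ncount == 1)
    is_isolated = skel & (ncount == 0)

    node_id_at = np.full(seg.shape, -1, dtype=np.int32)
    nodes: list[Node] = []

    if is_branch.any():
        blab, nb = ndimage.label(is_branch, structure=_STRUCT26)
        for i in range(1, nb + 1):
            coords = np.argwhere(blab == i)
            nid = len(nodes)
            nodes.append(Node(nid, coords.mean(axis=0) * sp))
            node_id_at[tuple(coords.T)] = nid
    for coord in np.argwhere(is_end | is_isolated):
        nid = len(nodes)
        nodes.append(Node(nid, coord * sp))
        node_id_at[tuple(coord)] = nid

    visited = np.zeros(seg.shape, bool)
    segments: list[Segment] = []

    def add_segment(na: int, nb: int, path_voxels: list[tuple[int, int, int]]) -> None:
        pv = np.asarray(path_voxels)
        segments.append(
            Segment(
                id=len(segments),
                node_a=na,
                node_b=nb,
                centerline_um=pv * sp,
                radii_um=edt[tuple(pv.T)] * sp[0],
                skeleton_voxels=pv,
            )
        )

    node_voxels = np.argwhere(node_id_at >= 0)
    direct_pairs = set()
    for nv in node_voxels:
        nid = node_id_at[tuple(nv)]
        for nb_coord in _neighbors(nv, skel):
            other = node_id_at[nb_coord]
            if other >= 0:
                if other != nid:
                    key = tuple(sorted((tuple(nv), nb_coord)))
                    if key not in direct_pairs:
                        direct_pairs.add(key)
                        add_segment(nid, other, [tuple(nv), nb_coord])
                continue
            if visited[nb_coord]:
                continue
            # walk the degree-≤2 chain until the next node voxel
            path = [tuple(nv)]
            prev = tuple(nv)
            cur = nb_coord
            end_node = None
            while True:
                path.append(cur)
                visited[cur] = True
                nxt = None
                for cand in _neighbors(np.asarray(cur), skel):
                    if cand == prev:
                        continue
                    if node_id_at[cand] >= 0:
                        end_node = node_id_at[cand]
                        nxt = None
                        break
                    if not visited[cand]:
                        nxt = cand
                if end_node is not None or nxt is None:
                    break
                prev, cur = cur, nxt
            if end_node is not None:
                path.append(min(
                    (c for c in _neighbors(np.asarray(path[-1]), skel) if node_id_at[c] == end_node),
                ))
                add_segment(nid, end_node, path)
            else:
                # dead end without an end node (rare voxel pattern): anchor one
                anchor = len(nodes)
                nodes.append(Node(anchor, np.asarray(path[-1]) * sp))
                node_id_at[path[-1]] = anchor
                add_segment(nid, anchor, path)

    # pure cycles: unvisited degree-2 voxels not adjacent to any node
    remaining = skel & ~visited & (node_id_at < 0) & (ncount == 2)
    if remaining.any():
        clab, nc = ndimage.label(remaining, structure=_STRUCT26)
        for i in range(1, nc + 1):
            coords = [tuple(c) for c in np.argwhere(clab == i)]
            start = coords[0]
            anchor = len(nodes)
            nodes.append(Node(anchor, np.asarray(start) * sp))
            node_id_at[start] = anchor
            path = [start]
            prev, cur = start, None
            nbrs = [c for c in _neighbors(np.asarray(start), skel) if clab[c] == i]
            if not nbrs:
                continue
            cur = nbrs[0]
            while cur is not None and cur != start:
                path.append(cur)
                visited[cur] = True
                nxt = None
                for cand in _neighbors(np.asarray(cur), skel):
                    if cand != prev and clab[cand] == i and not visited[cand]:
                        nxt = cand
                        break
                prev, cur = cur, nxt
            path.append(start)
            add_segment(anchor, anchor, path)

    _prune_spurs(nodes, segments, bulge_size)
    _merge_degree2(nodes, segments)
    _assign_voxels(seg, segments)
    _finalize(nodes, segments, sp)
    graph.nodes = [n for n in nodes if n.degree > 0]
    graph.segments = segments
    return graph


def _degrees(nodes, segments):
    deg = {n.id: 0 for n in nodes}
    for s in segments:
        deg[s.node_a] += 1
        if s.node_b != s.node_a:
            deg[s.node_b] += 1
    return deg


def _arc_length(points_um: np.ndarray) -> float:
    if len(points_um) < 2:
        return 0.0
    return float(np.linalg.norm(np.diff(points_um, axis=0), axis=1).sum())


def _prune_spurs(nodes, segments, bulge_size: float) -> None:
    """Drop terminal segments shorter than bulge_size × attachment radius."""
    if bulge_size <= 0:
        return
    deg = _degrees(nodes, segments)
    keep = []
    for s in segments:
        terminal_a = deg[s.node_a] == 1 and deg[s.node_b] > 1
        terminal_b = deg[s.node_b] == 1 and deg[s.node_a] > 1
        if terminal_a or terminal_b:
            r_attach = s.radii_um[-1] if terminal_a else s.radii_um[0]
            if _arc_length(s.centerline_um) < bulge_size * r_attach:
                continue
        keep.append(s)
    segments[:] = keep


def _merge_degree2(nodes, segments) -> None:
    """Dissolve pass-through nodes by concatenating their two segments."""
    changed = True
    while changed:
        changed = False
        deg = _degrees(nodes, segments)
        incident: dict[int, list[Segment]] = {}
        for s in segments:
            incident.setdefault(s.node_a, []).append(s)
            if s.node_b != s.node_a:
                incident.setdefault(s.node_b, []).append(s)
        for n in nodes:
            if deg.get(n.id, 0) != 2:
                continue
            inc = incident.get(n.id, [])
            if len(inc) != 2 or inc[0] is inc[1]:
                continue
            s1, s2 = inc
            if s1.node_a == s1.node_b or s2.node_a == s2.node_b:
                continue
            # orient s1 to end at n and s2 to start at n
            c1, r1, v1 = s1.centerline_um, s1.radii_um, s1.skeleton_voxels
            if s1.node_a == n.id:
                c1, r1, v1 = c1[::-1], r1[::-1], v1[::-1]
                far1 = s1.node_b
            else:
                far1 = s1.node_a
            c2, r2, v2 = s2.centerline_um, s2.radii_um, s2.skeleton_voxels
            if s2.node_b == n.id:
                c2, r2, v2 = c2[::-1], r2[::-1], v2[::-1]
                far2 = s2.node_a
            else:
                far2 = s2.node_b
            merged = Segment(
                id=s1.id,
                node_a=far1,
                node_b=far2,
                centerline_um=np.vstack([c1, c2[1:]]),
                radii_um=np.concatenate([r1, r2[1:]]),
                skeleton_voxels=np.vstack([v1, v2[1:]]),
            )
            segments[:] = [s for s in segments if s is not s1 and s is not s2] + [merged]
            changed = True
            break
    for i, s in enumerate(segments):
        s.id = i


def _assign_voxels(seg: np.ndarray, segments) -> None:
    """Partition foreground voxels by nearest centerline voxel."""
    if not segments:
        return
    seg_id_at = np.full(seg.shape, -1, dtype=np.int32)
    for s in segments:
        for v in s.skeleton_voxels:
            t = tuple(v)
            if seg_id_at[t] < 0:
                seg_id_at[t] = s.id
    has_id = seg_id_at >= 0
    if not has_id.any():
        return
    inds = ndimage.distance_transform_edt(~has_id, return_indices=True)[1]
    fg = np.argwhere(seg)
    owners = seg_id_at[tuple(inds[:, fg[:, 0], fg[:, 1], fg[:, 2]])]
    counts = np.bincount(owners, minlength=len(segments))
    for s in segments:
        s.voxel_count = int(counts[s.id])


def _finalize(nodes, segments, sp) -> None:
    deg = _degrees(nodes, segments)
    for n in nodes:
        n.degree = deg.get(n.id, 0)
    voxel_volume = float(np.prod(sp))
    for s in segments:
        s.features = compute_features(s, voxel_volume)
        s.degenerate = s.features is None


def compute_features(segment: Segment, voxel_volume: float) -> SegmentFeatures | None:
    """Morphological descriptors of one vessel segment.

    Returns ``None`` (degenerate) for zero-length centerlines or segments
    that own no voxels; such segments are excluded from feature tables.
    """
    pts = segment.centerline_um
    if len(pts) < 2 or segment.voxel_count <= 0:
        return None
    length = _arc_length(pts)
    if length <= 0:
        return None
    volume = segment.voxel_count * voxel_volume
    chord = float(np.linalg.norm(pts[-1] - pts[0]))
    # closed loops have ~zero chord; bound it below by one voxel length
    chord = max(chord, voxel_volume ** (1.0 / 3.0))
    radii = segment.radii_um
    return SegmentFeatures(
        length=length,
        volume=volume,
        avg_cross_section=volume / length,
        avg_radius=float(radii.mean()),
        min_radius=float(radii.min()),
        max_radius=float(radii.max()),
        curveness=max(length / chord, 1.0),
    )
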