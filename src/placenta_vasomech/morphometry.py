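"""Vascular-tree morphometry: generations, radii, branching angles and ratios.

A vessel tree is a rooted, acyclic set of centerline nodes (x, y, z in mm,
radius in mm) connected by parent->child edges.  Segments are maximal
unbranched chains; the root segment is generation 1 and every branching
event increments the generation of all daughters, i.e. the generation is
the number of branchings traversed from the root plus one.

Reported quantities per branch point:

* branching ratio  — daughter / mother segment-representative radius
  (median of node radii along the segment, robust to junction artifacts);
* branching angle  — angle in degrees between the mother's incoming and
  each daughter's outgoing direction, each estimated by a least-squares
  line fit to centerline points within an arc-length window of the branch
  point (default 5 mm).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class VesselTree:
    """Rooted branching tree of centerline nodes with radii."""

    nodes: pd.DataFrame  # columns: id, x, y, z, radius
    edges: pd.DataFrame  # columns: parent, child
    root_id: int

    def __post_init__(self) -> None:
        need = {"id", "x", "y", "z", "radius"}
        if not need.issubset(self.nodes.columns):
            raise ValueError(f"nodes must have columns {sorted(need)}")
        if not {"parent", "child"}.issubset(self.edges.columns):
            raise ValueError("edges must have columns parent, child")
        if (self.nodes["radius"] <= 0).any():
            raise ValueError("all radii must be positive")
        ids = set(self.nodes["id"])
        if self.root_id not in ids:
            raise ValueError("root_id not among node ids")
        if len(ids) != len(self.nodes):
            raise ValueError("duplicate node ids")
        children = self.edges["child"]
        if children.duplicated().any():
            raise ValueError("a node has more than one parent")
        if self.root_id in set(children):
            raise ValueError("root must not have a parent")
        # connectivity + acyclicity by traversal
        adj = self.children_map()
        seen = set()
        stack = [self.root_id]
        while stack:
            n = stack.pop()
            if n in seen:
                raise ValueError("cycle detected in vessel tree")
            seen.add(n)
            stack.extend(adj.get(n, ()))
        if seen != ids:
            raise ValueError("tree is not connected: unreachable nodes exist")

    def children_map(self) -> dict[int, list[int]]:
        adj: dict[int, list[int]] = {}
        for p, c in zip(self.edges["parent"], self.edges["child"]):
            adj.setdefault(int(p), []).append(int(c))
        return adj

    def coords(self) -> dict[int, np.ndarray]:
        return {
            int(i): np.array([x, y, z])
            for i, x, y, z in zip(self.nodes["id"], self.nodes["x"],
                                  self.nodes["y"], self.nodes["z"])
        }

    def radii(self) -> dict[int, float]:
        return dict(zip(self.nodes["id"].astype(int), self.nodes["radius"]))


@dataclass
class Segment:
    """Maximal unbranched chain of nodes.

    ``node_ids[0]`` is the anchor (the mother's junction node for non-root
    segments); the remaining nodes belong to the segment itself.
    """

    id: int
    node_ids: list = field(default_factory=list)
    parent_segment: int | None = None
    generation: int = 1

    @property
    def own_node_ids(self) -> list:
        """Nodes owned by this segment (anchor excluded for non-root)."""
        if self.parent_segment is None:
            return self.node_ids
        return self.node_ids[1:] if len(self.node_ids) > 1 else self.node_ids


def extract_segments(tree: VesselTree) -> list[Segment]:
    """Decompose the tree into segments between branch points."""
    adj = tree.children_map()
    segments: list[Segment] = []
    # stack entries: (anchor node, first own node or None, parent seg, gen)
    stack: list[tuple[int, int | None, int | None, int]] = [
        (tree.root_id, None, None, 1)
    ]
    while stack:
        anchor, first, parent_seg, gen = stack.pop()
        seg = Segment(id=len(segments), node_ids=[anchor],
                      parent_segment=parent_seg, generation=gen)
        node = anchor if first is None else first
        if first is not None:
            seg.node_ids.append(first)
        while len(adj.get(node, [])) == 1:
            node = adj[node][0]
            seg.node_ids.append(node)
        segments.append(seg)
        kids = adj.get(node, [])
        if len(kids) >= 2:
            for kid in reversed(kids):
                stack.append((node, kid, seg.id, gen + 1))
    return segments


def assign_generations(tree: VesselTree) -> dict[int, int]:
    """Generation index per segment id (root segment = 1)."""
    return {s.id: s.generation for s in extract_segments(tree)}


def segment_radius(tree: VesselTree, seg: Segment) -> float:
    """Representative radius: median of node radii along the segment."""
    radii = tree.radii()
    return float(np.median([radii[i] for i in seg.own_node_ids]))


def branching_ratio(tree: VesselTree,
                    segments: list[Segment] | None = None) -> pd.DataFrame:
    """Daughter/mother radius ratio per daughter at every branch point."""
    if segments is None:
        segments = extract_segments(tree)
    by_id = {s.id: s for s in segments}
    rows = []
    for s in segments:
        if s.parent_segment is None:
            continue
        mother = by_id[s.parent_segment]
        rm = segment_radius(tree, mother)
        if rm <= 0:
            raise ValueError(f"mother segment {mother.id} has zero radius")
        rows.append({
            "branch_node": s.node_ids[0],
            "mother_segment": mother.id,
            "daughter_segment": s.id,
            "generation": s.generation,
            "ratio": segment_radius(tree, s) / rm,
        })
    if not rows:
        raise ValueError("tree has no branch points")
    return pd.DataFrame(rows)


def _fit_direction(points: np.ndarray) -> np.ndarray:
    """Least-squares line direction of ordered centerline points.

    First principal axis of the centered points, oriented from the first
    towards the last point.  Degenerate (coincident) points raise.
    """
    pts = np.asarray(points, dtype=float)
    chord = pts[-1] - pts[0]
    if pts.shape[0] < 2 or np.linalg.norm(chord) == 0:
        raise ValueError("degenerate (zero-length) direction")
    if pts.shape[0] == 2:
        return chord / np.linalg.norm(chord)
    centered = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    d = vt[0]
    if np.dot(d, chord) < 0:
        d = -d
    return d / np.linalg.norm(d)


def _window_points(coords: dict[int, np.ndarray], node_ids: list,
                   window: float, from_end: bool) -> np.ndarray:
    """Centerline points within an arc-length window of a segment end."""
    pts = np.array([coords[i] for i in node_ids], dtype=float)
    if from_end:
        pts = pts[::-1]
    keep = [pts[0]]
    s = 0.0
    for q in pts[1:]:
        s += float(np.linalg.norm(q - keep[-1]))
        keep.append(q)
        if s >= window:
            break
    out = np.array(keep)
    return out[::-1] if from_end else out


def branching_angle(tree: VesselTree, window: float = 5.0,
                    segments: list[Segment] | None = None) -> pd.DataFrame:
    """Mother-daughter branching angle (degrees) per daughter segment."""
    if segments is None:
        segments = extract_segments(tree)
    by_id = {s.id: s for s in segments}
    coords = tree.coords()
    rows = []
    for s in segments:
        if s.parent_segment is None:
            continue
        mother = by_id[s.parent_segment]
        m_pts = _window_points(coords, mother.node_ids, window, from_end=True)
        d_pts = _window_points(coords, s.node_ids, window, from_end=False)
        dm = _fit_direction(m_pts)
        dd = _fit_direction(d_pts)
        cosang = float(np.clip(np.dot(dm, dd), -1.0, 1.0))
        rows.append({
            "branch_node": s.node_ids[0],
            "daughter_segment": s.id,
            "generation": s.generation,
            "angle_deg": float(np.degrees(np.arccos(cosang))),
        })
    if not rows:
        raise ValueError("tree has no branch points")
    return pd.DataFrame(rows)


def summarize_by_generation(trees, window: float = 5.0) -> pd.DataFrame:
    """Pool segments of one or more trees and report mean +/- SE per
    generation of radius, branching angle and branching ratio.

    SE is NaN where a generation holds a single measurement.  Angles and
    ratios are attributed to the daughter's generation; generation 1 has
    neither (no branching above it).
    """
    if isinstance(trees, VesselTree):
        trees = [trees]
    if not trees:
        raise ValueError("no trees given")
    rad_rows, angle_frames, ratio_frames = [], [], []
    for tree in trees:
        segs = extract_segments(tree)
        for s in segs:
            rad_rows.append({"generation": s.generation,
                             "radius": segment_radius(tree, s)})
        if any(s.parent_segment is not None for s in segs):
            angle_frames.append(branching_angle(tree, window, segs))
            ratio_frames.append(branching_ratio(tree, segs))
    radii = pd.DataFrame(rad_rows)

    def _stats(df, col):
        g = df.groupby("generation")[col]
        out = g.agg(["mean", "std", "count"])
        out["se"] = out["std"] / np.sqrt(out["count"])
        return out

    rs = _stats(radii, "radius")
    result = pd.DataFrame({
        "generation": rs.index,
        "n": rs["count"].to_numpy(),
        "mean_radius": rs["mean"].to_numpy(),
        "se_radius": rs["se"].to_numpy(),
    }).set_index("generation")
    if angle_frames:
        ast = _stats(pd.concat(angle_frames), "angle_deg")
        result["mean_branch_angle"] = ast["mean"]
        result["se_branch_angle"] = ast["se"]
        rst = _stats(pd.concat(ratio_frames), "ratio")
        result["mean_branch_ratio"] = rst["mean"]
        result["se_branch_ratio"] = rst["se"]
    else:
        for col in ("mean_branch_angle", "se_branch_angle",
                    "mean_branch_ratio", "se_branch_ratio"):
            result[col] = np.nan
    return result.reset_index()
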