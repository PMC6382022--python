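"""Octree-accelerated region-growing segmentation of individual leaves.

After cleaning, the cloud contains plant surface only, and individual
leaves are (to a good approximation) the connected components of the
graph that joins any two points closer than a neighbour radius.  Region
growing recovers exactly those components: the lowest-index unvisited
point seeds a region automatically, the region absorbs every point
within the radius of any member, and the process repeats until all
points are visited.  Labels are assigned in seed order starting at 1,
so the partition is deterministic for a given point order — and as a
set partition it is independent of point order altogether.

Neighbour queries go through an octree — a recursive 8-way spatial
subdivision — so each growth step inspects a block of points instead of
the whole cloud.  The octree is purely an accelerator: its radius
queries return exactly the brute-force result set.

Components smaller than ``min_segment_size`` are residue (stray returns,
partially seen leaves) and are dropped from the output, reported
separately on request.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .errors import ParameterError
from .geometry import PointCloud

__all__ = ["OctreeIndex", "LeafSegment", "build_octree", "region_grow",
           "segmentation_rate"]


@dataclass
class LeafSegment:
    """One segmented leaf: a positive label and the indices of its
    member points in the source cloud."""

    label: int
    point_indices: np.ndarray

    def __post_init__(self):
        self.point_indices = np.asarray(self.point_indices, dtype=np.intp)
        if self.label < 1:
            raise ValueError("segment labels start at 1")
        if self.point_indices.size == 0:
            raise ValueError("segments are non-empty")

    def __len__(self) -> int:
        return int(self.point_indices.size)


class _Node:
    __slots__ = ("center", "half", "children", "indices")

    def __init__(self, center, half):
        self.center = center          # (3,) box centre
        self.half = half              # scalar half side (cubic nodes)
        self.children = None          # list of 8 or None for a leaf
        self.indices = None           # point indices for a leaf node


class OctreeIndex:
    """Cubic octree over a point set supporting exact radius queries.

    Each leaf node holds at most ``leaf_capacity`` points (a node that
    cannot subdivide further — all points coincident — may exceed it).
    Node boxes tile their parent; every point lives in exactly one leaf.
    """

    def __init__(self, points: np.ndarray, leaf_capacity: int = 32):
        if leaf_capacity < 1:
            raise ParameterError("leaf_capacity must be a positive integer")
        self.points = np.asarray(points, dtype=float).reshape(-1, 3)
        if self.points.shape[0] == 0:
            raise ParameterError("cannot build an octree over an empty cloud")
        self.leaf_capacity = int(leaf_capacity)
        lo = self.points.min(axis=0)
        hi = self.points.max(axis=0)
        center = (lo + hi) / 2.0
        half = float(max(np.max(hi - lo) / 2.0, 1e-12)) * (1 + 1e-9)
        self.root = self._build(np.arange(self.points.shape[0]), center, half,
                                depth=0)

    _MAX_DEPTH = 48  # coincident points would otherwise recurse forever

    def _build(self, idx, center, half, depth):
        node = _Node(center, half)
        if idx.size <= self.leaf_capacity or depth >= self._MAX_DEPTH:
            node.indices = idx
            return node
        pts = self.points[idx]
        octant = ((pts[:, 0] >= center[0]).astype(np.int8)
                  | ((pts[:, 1] >= center[1]).astype(np.int8) << 1)
                  | ((pts[:, 2] >= center[2]).astype(np.int8) << 2))
        node.children = []
        q = half / 2.0
        for o in range(8):
            sub = idx[octant == o]
            off = np.array([q if o & 1 else -q,
                            q if o & 2 else -q,
                            q if o & 4 else -q])
            if sub.size:
                node.children.append(self._build(sub, center + off, q, depth + 1))
            else:
                node.children.append(None)
        return node

    def query_radius(self, center, radius: float) -> np.ndarray:
        """Indices of all points within Euclidean ``radius`` of ``center``
        (boundary inclusive), in ascending index order."""
        center = np.asarray(center, dtype=float)
        out = []
        stack = [self.root]
        r2 = radius * radius
        while stack:
            node = stack.pop()
            # distance from the query point to the node's cube
            d = np.maximum(np.abs(center - node.center) - node.half, 0.0)
            if d @ d > r2:
                continue
            if node.children is None:
                pts = self.points[node.indices]
                diff = pts - center
                hit = node.indices[np.einsum("ij,ij->i", diff, diff) <= r2]
                if hit.size:
                    out.append(hit)
            else:
                stack.extend(c for c in node.children if c is not None)
        if not out:
            return np.empty(0, dtype=np.intp)
        return np.sort(np.concatenate(out))

    def leaf_count(self) -> int:
        n = 0
        stack = [self.root]
        while stack:
            node = stack.pop()
            if node.children is None:
                n += 1
            else:
                stack.extend(c for c in node.children if c is not None)
        return n


def build_octree(cloud: PointCloud, leaf_capacity: int = 32) -> OctreeIndex:
    """Index a cloud for radius queries."""
    return OctreeIndex(cloud.xyz, leaf_capacity)


def region_grow(
    cloud: PointCloud,
    neighbor_radius_cm: float,
    min_segment_size: int = 30,
    leaf_capacity: int = 32,
    return_residue: bool = False,
):
    """Partition a cloud into leaves by radius-connectivity region growing.

    Returns the list of :class:`LeafSegment` (labels 1, 2, ... in order
    of their seed index); with ``return_residue`` also the indices of
    points in components smaller than ``min_segment_size``.
    """
    if neighbor_radius_cm <= 0:
        raise ParameterError("neighbor_radius_cm must be positive")
    n = len(cloud)
    if n == 0:
        return ([], np.empty(0, dtype=np.intp)) if return_residue else []
    tree = build_octree(cloud, leaf_capacity)
    visited = np.zeros(n, dtype=bool)
    segments: List[LeafSegment] = []
    residue = []
    label = 1
    for seed in range(n):
        if visited[seed]:
            continue
        # grow the region: absorb everything radius-connected to the seed
        visited[seed] = True
        member = [seed]
        frontier = [seed]
        while frontier:
            nxt = []
            for p in frontier:
                hits = tree.query_radius(tree.points[p], neighbor_radius_cm)
                fresh = hits[~visited[hits]]
                if fresh.size:
                    visited[fresh] = True
                    nxt.extend(fresh.tolist())
            member.extend(nxt)
            frontier = nxt
        member = np.sort(np.asarray(member, dtype=np.intp))
        if member.size >= min_segment_size:
            segments.append(LeafSegment(label, member))
            label += 1
        else:
            residue.append(member)
    res = (np.sort(np.concatenate(residue)) if residue
           else np.empty(0, dtype=np.intp))
    return (segments, res) if return_residue else segments


def segmentation_rate(n_detected: int, n_annotated: int) -> float:
    """Detected leaves over annotated leaves.

    May exceed 1 under over-segmentation; no cap is imposed.
    """
    if n_annotated < 1:
        raise ParameterError("n_annotated must be a positive integer")
    if n_detected < 0:
        raise ParameterError("n_detected must be non-negative")
    return n_detected / n_annotated
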