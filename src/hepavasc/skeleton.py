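"""Skeletonization of vessel masks into a branch graph.

The binary mask is thinned to a one-voxel-wide medial axis and decomposed
following the ImageJ AnalyzeSkeleton classification: slab voxels have
exactly two 26-neighbours on the skeleton, end voxels one, junction voxels
three or more.  Adjacent junction voxels form a single junction; a branch is
a maximal ordered voxel path connecting two non-slab voxels (or a closed
loop of slabs).  Each branch carries a radius estimate from the Euclidean
distance transform of the parent mask sampled along its path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import skeletonize as _skeletonize_3d

from .volume import VesselMask

__all__ = ["Branch", "SkeletonGraph", "skeletonize", "diameter_distribution"]

_OFFSETS = np.array([
    (dz, dy, dx)
    for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
    if (dz, dy, dx) != (0, 0, 0)
])


@dataclass
class Branch:
    """One skeleton branch: an ordered 26-connected voxel path."""

    path: np.ndarray          # (n, 3) int voxel coordinates, ordered
    radius: float             # µm, median local radius along the path
    closed: bool = False      # True for an isolated loop

    def __len__(self) -> int:
        return len(self.path)


@dataclass
class SkeletonGraph:
    """Branches plus junction/end nodes of a thinned vessel mask."""

    branches: list[Branch]
    nodes: np.ndarray         # (m, 3) int voxel coordinates of non-slab voxels
    node_degree: np.ndarray   # (m,) int
    voxel_size: float

    @property
    def n_branches(self) -> int:
        return len(self.branches)

    def branch_radii(self) -> np.ndarray:
        return np.array([b.radius for b in self.branches])


def _adjacency(coords: np.ndarray, shape: tuple[int, int, int]) -> list[list[int]]:
    """26-connectivity adjacency lists for skeleton voxels."""
    index = np.full(shape, -1, dtype=np.int64)
    index[tuple(coords.T)] = np.arange(len(coords))
    pad = np.pad(index, 1, constant_values=-1)
    adj: list[list[int]] = [[] for _ in range(len(coords))]
    base = coords + 1
    for off in _OFFSETS:
        nb = pad[tuple((base + off).T)]
        hit = nb >= 0
        for i, j in zip(np.nonzero(hit)[0], nb[hit]):
            adj[i].append(int(j))
    return adj


def skeletonize(mask: VesselMask, prune_spurs_um: float = 3.5) -> SkeletonGraph:
    """Medial-axis thinning followed by branch-graph extraction.

    Thinning of noisy tube surfaces produces short terminal twigs whose
    junctions artificially split branches; terminal branches shorter than
    ``prune_spurs_um`` that hang off a junction are pruned and the graph
    re-extracted (isolated branches are never pruned).  An empty mask
    yields an empty graph; a single isolated voxel yields one degenerate
    branch of length zero.
    """
    data = mask.data
    vs = mask.voxel_size
    if not data.any():
        return SkeletonGraph([], np.empty((0, 3), int), np.empty(0, int), vs)

    skel = _skeletonize_3d(data).astype(bool)
    if not skel.any():
        # parallel thinning can annihilate objects with an even-width
        # symmetric core; breaking the symmetry by one dilation recovers
        # the medial axis (which lies inside the original mask)
        grown = ndi.binary_dilation(data, structure=np.ones((3, 3, 3), bool))
        skel = _skeletonize_3d(grown).astype(bool) & data
    if not skel.any():
        # a tiny blob may still vanish; keep its innermost voxel
        edt0 = ndi.distance_transform_edt(data, sampling=vs)
        peak = np.unravel_index(int(np.argmax(edt0)), data.shape)
        skel[peak] = True

    for _ in range(3):
        graph = _extract_graph(skel, data, vs)
        if prune_spurs_um <= 0:
            return graph
        pruned = False
        junctions = {tuple(c) for c, d in zip(graph.nodes, graph.node_degree)
                     if d >= 3}
        for br in graph.branches:
            if br.closed or len(br.path) < 2:
                continue
            a, b = tuple(br.path[0]), tuple(br.path[-1])
            a_j, b_j = a in junctions, b in junctions
            if a_j == b_j:  # isolated (free-free) or junction-junction branch
                continue
            length = float(np.linalg.norm(np.diff(br.path, axis=0), axis=1).sum()) * vs
            if length >= prune_spurs_um:
                continue
            # drop the branch voxels except its junction-side terminal
            for p in map(tuple, br.path):
                if p in junctions:
                    continue
                skel[p] = False
                pruned = True
        if not pruned:
            return graph
    return _extract_graph(skel, data, vs)


def _extract_graph(skel: np.ndarray, data: np.ndarray, vs: float) -> SkeletonGraph:
    coords = np.argwhere(skel)
    adj = _adjacency(coords, data.shape)
    degree = np.array([len(a) for a in adj])
    edt = ndi.distance_transform_edt(data, sampling=vs)
    radius_at = edt[tuple(coords.T)]

    is_node = degree != 2
    # merge adjacent junction voxels into single junctions
    cluster = np.full(len(coords), -1, dtype=np.int64)
    n_clusters = 0
    for i in np.nonzero(degree >= 3)[0]:
        if cluster[i] >= 0:
            continue
        stack = [int(i)]
        cluster[i] = n_clusters
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if degree[v] >= 3 and cluster[v] < 0:
                    cluster[v] = n_clusters
                    stack.append(v)
        n_clusters += 1

    branches: list[Branch] = []
    visited_slab = np.zeros(len(coords), dtype=bool)
    seen_pairs: set[tuple[int, int]] = set()

    def _emit(path_idx: list[int], closed: bool = False) -> None:
        path = coords[np.asarray(path_idx)]
        rad = float(np.median(radius_at[np.asarray(path_idx)]))
        branches.append(Branch(path=path, radius=max(rad, 0.5 * vs), closed=closed))

    for i in np.nonzero(is_node)[0]:
        if degree[i] == 0:
            _emit([int(i)])
            continue
        for j in adj[i]:
            if is_node[j]:
                # zero-slab branch between distinct junction clusters / ends
                same_cluster = (cluster[i] >= 0 and cluster[i] == cluster[j])
                key = (min(int(i), int(j)), max(int(i), int(j)))
                if same_cluster or key in seen_pairs:
                    continue
                seen_pairs.add(key)
                _emit([int(i), int(j)])
                continue
            if visited_slab[j]:
                continue
            path = [int(i), int(j)]
            visited_slab[j] = True
            prev, cur = int(i), int(j)
            while True:
                nxt = [v for v in adj[cur] if v != prev]
                if not nxt:
                    break  # dead-end slab (shouldn't happen; degree==2)
                v = int(nxt[0])
                path.append(v)
                if is_node[v]:
                    break
                visited_slab[v] = True
                prev, cur = cur, v
            _emit(path)

    # isolated cycles: slabs never reached from any node
    for i in np.nonzero(~is_node & ~visited_slab)[0]:
        if visited_slab[i]:
            continue
        path = [int(i)]
        visited_slab[i] = True
        prev, cur = int(i), int(i)
        while True:
            nxt = [v for v in adj[cur] if v != prev and not visited_slab[v]]
            if not nxt:
                break
            v = int(nxt[0])
            path.append(v)
            visited_slab[v] = True
            prev, cur = cur, v
        path.append(int(i))  # close the loop
        _emit(path, closed=True)

    nodes = coords[is_node]
    return SkeletonGraph(branches, nodes, degree[is_node], vs)


def diameter_distribution(graph: SkeletonGraph, bin_width: float = 0.5,
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of per-branch diameters (2 × median local radius), in µm.

    Returns ``(counts, bin_edges)`` with bins of ``bin_width`` µm anchored at
    zero.  An empty graph yields empty arrays.
    """
    if not graph.branches:
        return np.empty(0, int), np.empty(0, float)
    diam = 2.0 * graph.branch_radii()
    hi = (np.floor(diam.max() / bin_width) + 1) * bin_width
    edges = np.arange(0.0, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(diam, bins=edges)
    return counts, edges


def modal_bin_center(counts: np.ndarray, edges: np.ndarray) -> float:
    """Centre of the most populated histogram bin (first on ties)."""
    if counts.size == 0:
        raise ValueError("empty histogram has no mode")
    i = int(np.argmax(counts))
    return float(0.5 * (edges[i] + edges[i + 1]))
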