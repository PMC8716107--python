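"""Geometry on skeleton trees.

Cable length, geodesic (along-the-tree) distances, branch counts, varicosity
detection from the node-radius profile, mitochondrial polyline lengths and
per-micrometre event densities.  All distances are computed in nanometres
after voxel-to-nm conversion and reported in the unit stated per function.
"""

from __future__ import annotations

import heapq
import warnings
from collections import deque
from dataclasses import dataclass

import numpy as np

from .types import AxonRecord, Skeleton, ValidationError

NM_PER_UM = 1000.0


def _edge_lengths(skeleton: Skeleton) -> dict[tuple[int, int], float]:
    """Vectorized nm length of every edge, keyed by the sorted id pair."""
    if not skeleton.edges:
        return {}
    ids = list(skeleton.nodes)
    pos = np.array([[skeleton.nodes[i].x, skeleton.nodes[i].y, skeleton.nodes[i].z]
                    for i in ids]) * skeleton.scale.as_array()
    index = {nid: k for k, nid in enumerate(ids)}
    edges = sorted(skeleton.edges)
    a = np.array([index[e[0]] for e in edges])
    b = np.array([index[e[1]] for e in edges])
    lengths = np.linalg.norm(pos[a] - pos[b], axis=1)
    return dict(zip(edges, lengths))


# ---------------------------------------------------------------------------
# Tree traversal primitives
# ---------------------------------------------------------------------------

def tree_path(skeleton: Skeleton, node_a: int, node_b: int) -> list[int]:
    """Node ids along the unique tree path from ``node_a`` to ``node_b``."""
    if node_a not in skeleton.nodes or node_b not in skeleton.nodes:
        raise ValidationError(f"unknown node in path query ({node_a}, {node_b})")
    if node_a == node_b:
        return [node_a]
    adj = skeleton.adjacency()
    parent: dict[int, int] = {node_a: node_a}
    queue = deque([node_a])
    while queue:
        u = queue.popleft()
        if u == node_b:
            break
        for v in adj[u]:
            if v not in parent:
                parent[v] = u
                queue.append(v)
    if node_b not in parent:
        raise ValidationError(f"nodes {node_a} and {node_b} are not connected")
    path = [node_b]
    while path[-1] != node_a:
        path.append(parent[path[-1]])
    path.reverse()
    return path


def geodesic_distance(skeleton: Skeleton, node_a: int, node_b: int) -> float:
    """Path length in nm along the unique tree path between two nodes."""
    path = tree_path(skeleton, node_a, node_b)
    return sum(skeleton.edge_length_nm(a, b) for a, b in zip(path, path[1:]))


def distances_from(skeleton: Skeleton, source: int) -> dict[int, float]:
    """Geodesic distance in nm from ``source`` to every node (single BFS)."""
    if source not in skeleton.nodes:
        raise ValidationError(f"unknown source node {source}")
    adj = skeleton.adjacency()
    lengths = _edge_lengths(skeleton)
    dist = {source: 0.0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + lengths[(u, v) if u < v else (v, u)]
                queue.append(v)
    return dist


# ---------------------------------------------------------------------------
# Whole-skeleton measures
# ---------------------------------------------------------------------------

def cable_length(skeleton: Skeleton) -> float:
    """Total cable length in µm: sum of Euclidean edge lengths (nm) / 1000."""
    if not skeleton.nodes:
        raise ValidationError("cannot measure an empty skeleton")
    return float(sum(_edge_lengths(skeleton).values())) / NM_PER_UM


def count_branches(skeleton: Skeleton) -> int:
    """Number of branch events: sum over nodes of max(0, degree - 2)."""
    deg: dict[int, int] = {nid: 0 for nid in skeleton.nodes}
    for a, b in skeleton.edges:
        deg[a] += 1
        deg[b] += 1
    return sum(max(0, d - 2) for d in deg.values())


def linear_density(count: int, cable_length_um: float) -> float:
    """Events per µm of cable."""
    if cable_length_um <= 0:
        raise ValidationError("cable length must be positive for a density")
    return count / cable_length_um


# ---------------------------------------------------------------------------
# Radius profiles and varicosity detection
# ---------------------------------------------------------------------------

@dataclass
class PathProfile:
    """Diameter profile along one maximal unbranched run of the tree.

    ``arclength_nm`` is cumulative from the first node (first entry 0, strictly
    non-decreasing); ``diameter_nm`` is twice the node radius.
    """

    node_ids: list[int]
    arclength_nm: np.ndarray
    diameter_nm: np.ndarray

    def __post_init__(self) -> None:
        if len(self.node_ids) != len(self.arclength_nm) or len(self.node_ids) != len(
            self.diameter_nm
        ):
            raise ValidationError("profile arrays must align with node ids")
        if len(self.arclength_nm) and self.arclength_nm[0] != 0:
            raise ValidationError("profile arclength must start at 0")
        if np.any(np.diff(self.arclength_nm) < 0):
            raise ValidationError("profile arclength must be non-decreasing")


def path_profiles(skeleton: Skeleton) -> list[PathProfile]:
    """Decompose the tree into maximal unbranched segments.

    Segments run between 'break' nodes (degree != 2); interior nodes all have
    degree 2.  A single chain yields one profile; an isolated node none.
    """
    adj = skeleton.adjacency()
    deg = {nid: len(nb) for nid, nb in adj.items()}
    breaks = [nid for nid, d in deg.items() if d != 2]
    if not breaks:  # cannot happen in a tree with >= 1 edge
        return []
    profiles: list[PathProfile] = []
    visited_edges: set[tuple[int, int]] = set()
    for start in sorted(breaks):
        for nxt in sorted(adj[start]):
            e0 = (min(start, nxt), max(start, nxt))
            if e0 in visited_edges:
                continue
            chain = [start, nxt]
            visited_edges.add(e0)
            while deg[chain[-1]] == 2:
                a, b = adj[chain[-1]]
                step = b if a == chain[-2] else a
                visited_edges.add((min(chain[-1], step), max(chain[-1], step)))
                chain.append(step)
            arclen = np.zeros(len(chain))
            for i in range(1, len(chain)):
                arclen[i] = arclen[i - 1] + skeleton.edge_length_nm(chain[i - 1], chain[i])
            diam = np.array([2.0 * skeleton.nodes[nid].radius for nid in chain])
            profiles.append(PathProfile(chain, arclen, diam))
    return profiles


def detect_varicosities(
    profile: PathProfile,
    fold: float = 2.0,
    window_um: float = 1.0,
    min_separation_um: float = 0.5,
) -> list[tuple[int, float]]:
    """Flag diameter peaks that exceed ``fold`` x the local minimum diameter.

    A node is flagged when its diameter is at least ``fold`` times the minimum
    diameter within the trailing+leading ``window_um`` of arclength.  Maximal
    flagged runs closer than ``min_separation_um`` are merged; the peak node of
    each run is reported as ``(node_id, peak_diameter_nm)``.
    """
    if fold <= 1:
        raise ValidationError("fold must exceed 1")
    if window_um <= 0:
        raise ValidationError("window must be positive")
    s = profile.arclength_nm
    d = profile.diameter_nm
    if len(s) == 0 or s[-1] < window_um * NM_PER_UM:
        warnings.warn("profile shorter than detection window; no varicosities reported")
        return []
    win = window_um * NM_PER_UM
    flagged = np.zeros(len(s), dtype=bool)
    lo = 0
    hi = 0
    for i in range(len(s)):
        while s[i] - s[lo] > win:
            lo += 1
        while hi < len(s) - 1 and s[hi + 1] - s[i] <= win:
            hi += 1
        base = d[lo : hi + 1].min()
        flagged[i] = base > 0 and d[i] >= fold * base
    # maximal runs of flagged nodes
    runs: list[tuple[int, int]] = []
    i = 0
    while i < len(flagged):
        if flagged[i]:
            j = i
            while j + 1 < len(flagged) and flagged[j + 1]:
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1
    # merge runs separated by less than min_separation
    sep = min_separation_um * NM_PER_UM
    merged: list[tuple[int, int]] = []
    for run in runs:
        if merged and s[run[0]] - s[merged[-1][1]] < sep:
            merged[-1] = (merged[-1][0], run[1])
        else:
            merged.append(run)
    out = []
    for i0, i1 in merged:
        k = i0 + int(np.argmax(d[i0 : i1 + 1]))
        out.append((profile.node_ids[k], float(d[k])))
    return out


def detect_varicosities_skeleton(
    skeleton: Skeleton,
    fold: float = 2.0,
    window_um: float = 1.0,
    min_separation_um: float = 0.5,
) -> list[tuple[int, float]]:
    """Run the profile detector over every unbranched segment of a skeleton."""
    hits: dict[int, float] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for profile in path_profiles(skeleton):
            for nid, diam in detect_varicosities(
                profile, fold=fold, window_um=window_um, min_separation_um=min_separation_um
            ):
                hits[nid] = max(diam, hits.get(nid, 0.0))
    return sorted(hits.items())


# ---------------------------------------------------------------------------
# Structure-level measures
# ---------------------------------------------------------------------------

def mito_length(skeleton: Skeleton, node_chain: list[int] | tuple[int, ...]) -> float:
    """Polyline length of a mitochondrion's annotated node chain, in µm."""
    chain = list(node_chain)
    if len(set(chain)) != len(chain):
        raise ValidationError("duplicate node in mitochondrion chain")
    for nid in chain:
        if nid not in skeleton.nodes:
            raise ValidationError(f"mitochondrion chain hits missing node {nid}")
    if len(chain) < 2:
        warnings.warn("mitochondrion chain has fewer than 2 nodes; length 0")
        return 0.0
    total = sum(skeleton.edge_length_nm(a, b) if (min(a, b), max(a, b)) in skeleton.edges
                else float(np.linalg.norm(
                    skeleton.nodes[a].position_nm(skeleton.scale)
                    - skeleton.nodes[b].position_nm(skeleton.scale)))
                for a, b in zip(chain, chain[1:]))
    return total / NM_PER_UM


def dendrite_diameter(chords_nm: tuple[float, float, float]) -> float:
    """Dendrite diameter as the mean of three orthogonal chord lengths (nm)."""
    if len(chords_nm) != 3:
        raise ValidationError("exactly three chord lengths required")
    if any(c <= 0 for c in chords_nm):
        raise ValidationError("chord lengths must be positive")
    return float(np.mean(chords_nm))


def intervaricosity_distances(axon: AxonRecord, all_pairs: bool = False) -> list[float]:
    """Geodesic distances (nm) between varicosities in axon order.

    Default is consecutive pairs along the axon; ``all_pairs`` returns every
    unordered pair.  Fewer than two varicosities yields an empty list.
    """
    nodes = [v.node_id for v in axon.varicosities]
    if len(nodes) < 2:
        return []
    if all_pairs:
        return [
            geodesic_distance(axon.skeleton, nodes[i], nodes[j])
            for i in range(len(nodes))
            for j in range(i + 1, len(nodes))
        ]
    return [geodesic_distance(axon.skeleton, a, b) for a, b in zip(nodes, nodes[1:])]


def order_varicosity_nodes(skeleton: Skeleton, root: int, node_ids: list[int]) -> list[int]:
    """Sort varicosity nodes by geodesic distance from the root (ties by id)."""
    dist = distances_from(skeleton, root)
    return sorted(node_ids, key=lambda nid: (dist[nid], nid))


def mito_within_flags(
    skeleton: Skeleton,
    varicosity_nodes: list[int],
    mito_segments: list[tuple[int, ...]],
    radius_um: float = 1.0,
) -> list[bool]:
    """Whether any mitochondrion node lies within ``radius_um`` (geodesic) of
    each varicosity node."""
    mito_nodes = {nid for chain in mito_segments for nid in chain}
    if not mito_nodes:
        return [False] * len(varicosity_nodes)
    cutoff = radius_um * NM_PER_UM
    # multi-source Dijkstra from every mitochondrion node, pruned at cutoff
    adj = skeleton.adjacency()
    lengths = _edge_lengths(skeleton)
    dist: dict[int, float] = {m: 0.0 for m in mito_nodes}
    heap = [(0.0, m) for m in mito_nodes]
    heapq.heapify(heap)
    while heap:
        d, u = heapq.heappop(heap)
        if d > dist.get(u, np.inf) or d > cutoff:
            continue
        for v in adj[u]:
            nd = d + lengths[(u, v) if u < v else (v, u)]
            if nd <= cutoff and nd < dist.get(v, np.inf):
                dist[v] = nd
                heapq.heappush(heap, (nd, v))
    return [bool(dist.get(v, np.inf) <= cutoff) for v in varicosity_nodes]


def measure_axon(axon: AxonRecord) -> dict[str, float]:
    """Per-axon summary: cable, branch count and event densities."""
    length_um = cable_length(axon.skeleton)
    branches = count_branches(axon.skeleton)
    return {
        "axon_id": axon.axon_id,
        "group": axon.group,
        "compartment": axon.compartment,
        "cable_length_um": length_um,
        "n_branches": branches,
        "branch_density_per_um": linear_density(branches, length_um),
        "n_varicosities": len(axon.varicosities),
        "n_mitochondria": len(axon.mito_segments),
        "mito_density_per_um": linear_density(len(axon.mito_segments), length_um),
        "n_contact_points": len(axon.contact_points),
        "contact_density_per_um": linear_density(len(axon.contact_points), length_um),
        "n_swellings": len(axon.swellings),
        "swelling_density_per_um": linear_density(len(axon.swellings), length_um),
    }
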