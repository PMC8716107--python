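"""Core domain types for EM-traced axon skeletons and their annotations.

A traced neurite is an undirected tree of 3D nodes in voxel coordinates with a
per-node radius in nanometres; the voxel scale carries the anisotropic sampling
of serial-section EM (40 nm section thickness, 6 or 20 nm in plane).  All
geometry downstream of the scale is done in nanometres.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

#: Controlled vocabulary for node-comment annotation tags.
ANNOTATION_KEYS = frozenset(
    {
        "varicosity",
        "vesicle_diam_nm",
        "mito_start",
        "mito_end",
        "contact_point",
        "swelling",
        "soma",
    }
)

GROUPS = ("saline", "cocaine", "none")
COMPARTMENTS = ("DA_axon", "CS_axon", "MSN_dendrite", "DA_dendrite", "DA_soma")
VTYPES = ("I", "II", "III", "IV")
PARTNER_CLASSES = ("axo_axonic", "axo_dendritic")


class ValidationError(ValueError):
    """A record violates a structural invariant (cycle, dangling edge, ...)."""


@dataclass(frozen=True)
class VoxelScale:
    """Nanometres per voxel along x, y, z.  All entries strictly positive."""

    sx: float
    sy: float
    sz: float

    def __post_init__(self) -> None:
        if not all(math.isfinite(s) and s > 0 for s in (self.sx, self.sy, self.sz)):
            raise ValidationError(f"voxel scale must be strictly positive, got {self}")

    def as_array(self) -> np.ndarray:
        return np.array([self.sx, self.sy, self.sz], dtype=float)


@dataclass(frozen=True)
class SkeletonNode:
    """One skeleton node: voxel coordinates plus radius in nm (0 = unknown)."""

    node_id: int
    x: float
    y: float
    z: float
    radius: float = 0.0

    def __post_init__(self) -> None:
        if self.node_id <= 0:
            raise ValidationError(f"node_id must be a positive integer, got {self.node_id}")
        if not all(math.isfinite(v) for v in (self.x, self.y, self.z)):
            raise ValidationError(f"non-finite coordinate on node {self.node_id}")
        if not (math.isfinite(self.radius) and self.radius >= 0):
            raise ValidationError(f"negative or non-finite radius on node {self.node_id}")

    def position_nm(self, scale: VoxelScale) -> np.ndarray:
        return np.array([self.x * scale.sx, self.y * scale.sy, self.z * scale.sz])


def _norm_edge(a: int, b: int) -> tuple[int, int]:
    return (a, b) if a < b else (b, a)


@dataclass
class Skeleton:
    """An undirected tree of nodes with a voxel scale.

    Edges are stored as sorted (low, high) id pairs.  ``validate`` enforces the
    tree invariant: every edge endpoint exists, no self loops or duplicates,
    connected and acyclic.
    """

    nodes: dict[int, SkeletonNode]
    edges: set[tuple[int, int]]
    scale: VoxelScale

    def __init__(
        self,
        nodes: Iterable[SkeletonNode],
        edges: Iterable[tuple[int, int]],
        scale: VoxelScale,
    ) -> None:
        self.nodes = {}
        for n in nodes:
            if n.node_id in self.nodes:
                raise ValidationError(f"duplicate node id {n.node_id}")
            self.nodes[n.node_id] = n
        self.edges = set()
        for a, b in edges:
            if a == b:
                raise ValidationError(f"self-loop on node {a}")
            e = _norm_edge(int(a), int(b))
            if e in self.edges:
                raise ValidationError(f"duplicate edge {e}")
            self.edges.add(e)
        self.scale = scale

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        for a, b in self.edges:
            if a not in self.nodes or b not in self.nodes:
                raise ValidationError(f"edge ({a},{b}) references a missing node")
        n = len(self.nodes)
        if n == 0:
            raise ValidationError("empty skeleton")
        if len(self.edges) != n - 1:
            raise ValidationError(
                f"not a tree: {n} nodes but {len(self.edges)} edges (cycle or disconnection)"
            )
        # connectivity check; with |E| = |V|-1, connected <=> acyclic
        adj = self.adjacency()
        seen: set[int] = set()
        start = next(iter(self.nodes))
        stack = [start]
        while stack:
            u = stack.pop()
            if u in seen:
                continue
            seen.add(u)
            stack.extend(v for v in adj[u] if v not in seen)
        if len(seen) != n:
            raise ValidationError("not a tree: graph is disconnected (implies a cycle elsewhere)")

    # -- helpers ---------------------------------------------------------
    def adjacency(self) -> dict[int, list[int]]:
        adj: dict[int, list[int]] = {nid: [] for nid in self.nodes}
        for a, b in self.edges:
            adj[a].append(b)
            adj[b].append(a)
        return adj

    def degree(self, node_id: int) -> int:
        return sum(1 for a, b in self.edges if a == node_id or b == node_id)

    def edge_length_nm(self, a: int, b: int) -> float:
        pa = self.nodes[a].position_nm(self.scale)
        pb = self.nodes[b].position_nm(self.scale)
        return float(np.linalg.norm(pa - pb))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Skeleton):
            return NotImplemented
        return (
            self.nodes == other.nodes
            and self.edges == other.edges
            and self.scale == other.scale
        )


@dataclass(frozen=True)
class AnnotationTag:
    """One key=value annotation bound to a node (controlled vocabulary)."""

    node_id: int
    key: str
    value: str = ""


@dataclass
class VaricosityRecord:
    """One varicosity: its node, vesicle diameters, assigned type and mito flag.

    ``vtype`` is one of I (empty), II (small vesicles only), III (large only),
    IV (mixed), or None while unassigned.
    """

    axon_id: str
    index: int
    node_id: int
    vesicle_diameters: tuple[float, ...] = ()
    vtype: str | None = None
    mito_within_1um: bool = False


@dataclass
class AxonRecord:
    """A skeleton plus its ordered annotations and group/compartment metadata."""

    skeleton: Skeleton
    axon_id: str
    thing_id: int = 1
    group: str = "none"
    compartment: str = "DA_axon"
    varicosities: list[VaricosityRecord] = field(default_factory=list)
    mito_segments: list[tuple[int, ...]] = field(default_factory=list)
    contact_points: list[tuple[int, str]] = field(default_factory=list)
    swellings: list[tuple[int, float]] = field(default_factory=list)
    soma_node: int | None = None
    extra_tags: list[AnnotationTag] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(f"unknown group {self.group!r}")
        if self.compartment not in COMPARTMENTS:
            raise ValidationError(f"unknown compartment {self.compartment!r}")

    def validate(self) -> None:
        self.skeleton.validate()
        ids = self.skeleton.nodes.keys()
        for v in self.varicosities:
            if v.node_id not in ids:
                raise ValidationError(f"varicosity at missing node {v.node_id}")
        for chain in self.mito_segments:
            if len(chain) < 1:
                raise ValidationError("empty mitochondrion chain")
            for nid in chain:
                if nid not in ids:
                    raise ValidationError(f"mitochondrion chain hits missing node {nid}")
        for nid, partner in self.contact_points:
            if nid not in ids:
                raise ValidationError(f"contact point at missing node {nid}")
            if partner not in PARTNER_CLASSES:
                raise ValidationError(f"unknown contact partner class {partner!r}")
        for nid, diam in self.swellings:
            if nid not in ids:
                raise ValidationError(f"swelling at missing node {nid}")
            if diam <= 0:
                raise ValidationError(f"non-positive swelling diameter at node {nid}")
        if self.soma_node is not None and self.soma_node not in ids:
            raise ValidationError(f"soma tag at missing node {self.soma_node}")

    @property
    def root_node(self) -> int:
        """Designated root for traversal order: soma-tagged node, else lowest id."""
        if self.soma_node is not None:
            return self.soma_node
        return min(self.skeleton.nodes)

    def type_sequence(self) -> list[str | None]:
        return [v.vtype for v in self.varicosities]


def type_counts(sequence: Sequence[str | None]) -> np.ndarray:
    """Counts of classified types (I..IV) in a sequence; unassigned ignored."""
    out = np.zeros(4, dtype=int)
    for t in sequence:
        if t in VTYPES:
            out[VTYPES.index(t)] += 1
    return out
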