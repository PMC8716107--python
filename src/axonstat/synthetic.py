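"""Synthetic axon populations with known ground truth.

The generator emulates the statistical structure of EM-traced dopaminergic
axons so that every downstream stage (parsing, morphometry, classification,
null model, group comparison) can be exercised without any imaging data:

* the skeleton backbone is a persistent 3D random walk (1 µm steps) with
  branch events from a Poisson process per µm of grown cable; branch subtrees
  draw their length from the same length distribution scaled by 0.3 per
  generation, keeping trees compact;
* varicosities are placed sequentially along the trunk with log-normal
  spacing; their types follow a first-order Markov chain over the four
  vesicle-content types (iid when the persistence rho is 0), or a mixture
  mode where each axon tilts the type frequencies toward a dominant type;
* vesicle diameters are truncated normals confined to the small (26-67 nm)
  and large (90-238 nm) bins, so classification can recover the true type;
* mitochondria, swellings and contact points are Poisson events per µm over
  all cable, with group-dependent length/diameter distributions.

Event nodes (varicosity peaks, swellings, mitochondrion endpoints, contact
points) are inserted at their exact arclengths by splitting walk edges, so
sub-micrometre structures keep exact lengths on the skeleton.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import morphometry, skeleton_io
from .types import (
    AxonRecord,
    Skeleton,
    SkeletonNode,
    ValidationError,
    VaricosityRecord,
    VoxelScale,
    VTYPES,
)

#: Pooled varicosity-type counts (empty / small / large / mixed) of the
#: reference EM dataset; their fractions are the default type frequencies.
DEFAULT_TYPE_COUNTS = (156, 101, 78, 75)

NM_PER_UM = 1000.0


def lognormal_params_from_mean_sd(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) on the log scale for a log-normal with given mean and SD."""
    if mean <= 0 or sd < 0:
        raise ValidationError("log-normal mean must be positive and sd non-negative")
    sigma2 = math.log1p((sd / mean) ** 2)
    return math.log(mean) - sigma2 / 2, math.sqrt(sigma2)


@dataclass
class TypeProcessParams:
    """Varicosity-type process: population frequencies + dependence knob.

    ``rho`` is the Markov persistence (probability that a varicosity repeats
    the previous type; 0 = iid).  ``mode='mixture'`` instead draws a dominant
    type per axon and tilts f toward it with weight ``mixture_weight``; both
    modes reduce to iid sampling at rho = 0 / weight = 0.
    """

    f: np.ndarray = field(
        default_factory=lambda: np.asarray(DEFAULT_TYPE_COUNTS, dtype=float)
        / sum(DEFAULT_TYPE_COUNTS)
    )
    rho: float = 0.0
    mode: str = "markov"
    mixture_weight: float = 0.0

    def __post_init__(self) -> None:
        self.f = np.asarray(self.f, dtype=float)
        if self.f.shape != (4,) or (self.f < 0).any() or abs(self.f.sum() - 1) > 1e-12:
            raise ValidationError(f"type frequencies must be a probability 4-vector, got {self.f}")
        if not 0 <= self.rho <= 1:
            raise ValidationError("rho must lie in [0, 1]")
        if self.mode not in ("markov", "mixture"):
            raise ValidationError(f"unknown type-process mode {self.mode!r}")
        if not 0 <= self.mixture_weight <= 1:
            raise ValidationError("mixture weight must lie in [0, 1]")


@dataclass
class AxonGenParams:
    """All tunable generator rates and distributions (rates per µm of cable)."""

    length_range_um: tuple[float, float] = (50.0, 250.0)
    step_um: float = 1.0
    walk_persistence: float = 0.9
    branch_rate_per_um: float = 0.01
    branch_length_factor: float = 0.3
    place_varicosities: bool = True
    spacing_mu_log_nm: float = math.log(4000.0)  # median spacing 4 µm
    spacing_sigma_log: float = 0.8
    mito_rate_per_um: float = 0.14
    mito_len_mean_um: float = 0.36
    mito_len_sd_um: float = 0.13
    mito_ratio_mean: float | None = None  # dendrites: mito length / diameter
    mito_ratio_sd: float = 1.0
    swelling_rate_per_um: float = 0.0
    swelling_diam_mean_um: float = 2.2
    swelling_diam_sd_um: float = 1.4
    swelling_diam_min_um: float = 0.5
    contact_rate_per_um: float = 0.2
    p_axo_axonic: float = 0.83
    baseline_diam_nm: float = 100.0
    baseline_diam_sd_nm: float = 0.0
    varic_peak_diam_nm: float = 300.0
    # vesicle content per type (counts are truncated-normal, min 1)
    small_count_mean: float = 30.1
    small_count_sd: float = 32.2
    large_count_mean: float = 9.2
    large_count_sd: float = 7.1
    mixed_small_count_mean: float = 28.2
    mixed_small_count_sd: float = 41.6
    mixed_large_count_mean: float = 6.9
    mixed_large_count_sd: float = 7.8
    small_diam_mean_nm: float = 48.0
    small_diam_sd_nm: float = 8.0
    large_diam_mean_nm: float = 133.0
    large_diam_sd_nm: float = 25.0
    small_bin: tuple[float, float] = (26.0, 67.0)
    large_bin: tuple[float, float] = (90.0, 238.0)
    scale: VoxelScale = field(default_factory=lambda: VoxelScale(20.0, 20.0, 40.0))

    def __post_init__(self) -> None:
        lo, hi = self.length_range_um
        if not (0 < lo <= hi):
            raise ValidationError(f"invalid length range {self.length_range_um}")
        for name in (
            "branch_rate_per_um", "mito_rate_per_um", "swelling_rate_per_um",
            "contact_rate_per_um", "step_um",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        if self.step_um <= 0:
            raise ValidationError("step_um must be positive")
        for name in ("p_axo_axonic", "walk_persistence"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValidationError(f"{name} must lie in [0, 1]")


@dataclass
class GroundTruth:
    """Generator-side record of every planted structure in one axon."""

    axon_id: str
    seed: int
    group: str
    compartment: str
    trunk_length_um: float
    total_cable_um: float
    n_branch_events: int
    varicosity_node_ids: list[int] = field(default_factory=list)
    varicosity_arclengths_nm: list[float] = field(default_factory=list)
    varicosity_types: list[str] = field(default_factory=list)
    mito_lengths_um: list[float] = field(default_factory=list)
    swelling_diams_nm: list[float] = field(default_factory=list)
    contact_partners: list[str] = field(default_factory=list)
    dendrite_diameter_nm: float | None = None


# ---------------------------------------------------------------------------
# Type-sequence sampling (shared by the generator and calibration studies)
# ---------------------------------------------------------------------------

def _inv_cdf(f: np.ndarray, u: float) -> int:
    return int(np.searchsorted(np.cumsum(f), u, side="right").clip(0, 3))


def sample_type_sequence(n: int, types: TypeProcessParams, rng: np.random.Generator) -> list[int]:
    """Draw a length-n sequence of type indices (0..3).

    Two uniforms are consumed per position regardless of rho, so sequences
    generated from the same seed are coupled across rho values (common random
    numbers): raising rho only converts fresh draws into repeats.
    """
    if n < 0:
        raise ValidationError("sequence length must be non-negative")
    u = rng.random((max(n, 1), 2))
    if n == 0:
        return []
    if types.mode == "mixture":
        dominant = _inv_cdf(types.f, float(rng.random()))
        w = types.mixture_weight
        tilted = (1 - w) * types.f
        tilted[dominant] += w
        return [_inv_cdf(tilted, u[i, 1]) for i in range(n)]
    seq = [_inv_cdf(types.f, u[0, 1])]
    for i in range(1, n):
        if u[i, 0] < types.rho:
            seq.append(seq[-1])
        else:
            seq.append(_inv_cdf(types.f, u[i, 1]))
    return seq


def sample_axon_sizes(
    n_axons: int,
    rng: np.random.Generator,
    mean_extra: float = 2.5,
    min_varicosities: int = 3,
) -> np.ndarray:
    """Per-axon varicosity counts for sequence-level studies.

    ``min_varicosities + Poisson(mean_extra)`` gives a mean of ~5.5
    varicosities per axon, the composition typical of the reference dataset
    (410 varicosities over 75 axons).
    """
    return min_varicosities + rng.poisson(mean_extra, size=n_axons)


# ---------------------------------------------------------------------------
# Vesicle content
# ---------------------------------------------------------------------------

def _trunc_normal(rng, mean, sd, lo, hi, size):
    """Truncated-normal draws by rejection (bounds are a few SDs wide here)."""
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(mean, sd, size=size - filled)
        keep = draw[(draw >= lo) & (draw <= hi)]
        out[filled : filled + len(keep)] = keep
        filled += len(keep)
    return out


def _count(rng, mean, sd) -> int:
    return max(1, int(round(rng.normal(mean, sd))))


def sample_vesicle_diameters(
    vtype: str, params: AxonGenParams, rng: np.random.Generator
) -> tuple[float, ...]:
    """Vesicle diameter list for a varicosity of the given type.

    Diameters are truncated to their bin by construction, so classification
    from diameters recovers the generating type exactly.
    """
    def small(n):
        return _trunc_normal(rng, params.small_diam_mean_nm, params.small_diam_sd_nm,
                             *params.small_bin, size=n)

    def large(n):
        return _trunc_normal(rng, params.large_diam_mean_nm, params.large_diam_sd_nm,
                             *params.large_bin, size=n)

    if vtype == "I":
        return ()
    if vtype == "II":
        return tuple(small(_count(rng, params.small_count_mean, params.small_count_sd)))
    if vtype == "III":
        return tuple(large(_count(rng, params.large_count_mean, params.large_count_sd)))
    if vtype == "IV":
        ns = _count(rng, params.mixed_small_count_mean, params.mixed_small_count_sd)
        nl = _count(rng, params.mixed_large_count_mean, params.mixed_large_count_sd)
        return tuple(np.concatenate([small(ns), large(nl)]))
    raise ValidationError(f"unknown varicosity type {vtype!r}")


# ---------------------------------------------------------------------------
# Skeleton assembly
# ---------------------------------------------------------------------------

@dataclass
class _Segment:
    parent: int | None          # parent segment index
    parent_arclength: float     # attachment arclength on the parent (nm)
    points: np.ndarray          # walk vertices in nm, (n_steps+1, 3); [0] = origin
    length_nm: float
    events: list[tuple[float, str, object]] = field(default_factory=list)


def _random_unit(rng) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _walk(rng, origin, length_nm, step_nm, persistence) -> np.ndarray:
    n = max(1, int(round(length_nm / step_nm)))
    pts = np.empty((n + 1, 3))
    pts[0] = origin
    direction = _random_unit(rng)
    for i in range(n):
        direction = persistence * direction + (1 - persistence) * _random_unit(rng)
        direction /= np.linalg.norm(direction)
        pts[i + 1] = pts[i] + direction * step_nm
    return pts


def _grow_segments(rng, params: AxonGenParams) -> tuple[list[_Segment], int]:
    """Trunk plus Poisson branch subtrees; returns (segments, n branch events)."""
    step_nm = params.step_um * NM_PER_UM
    lo, hi = params.length_range_um
    trunk_len = rng.uniform(lo, hi) * NM_PER_UM
    segments = [_Segment(None, 0.0, _walk(rng, np.zeros(3), trunk_len, step_nm,
                                          params.walk_persistence),
                         0.0)]
    segments[0].length_nm = (len(segments[0].points) - 1) * step_nm
    n_branches = 0
    queue = [(0, 1)]  # (segment index, depth of its children)
    while queue:
        seg_idx, depth = queue.pop(0)
        seg = segments[seg_idx]
        lam = params.branch_rate_per_um * seg.length_nm / NM_PER_UM
        for _ in range(rng.poisson(lam)):
            s = rng.uniform(0.0, seg.length_nm)
            child_len = (params.branch_length_factor ** depth) * rng.uniform(lo, hi) * NM_PER_UM
            if child_len < step_nm:
                child_len = step_nm
            origin = _interp(seg.points, step_nm, s)
            child = _Segment(seg_idx, s,
                             _walk(rng, origin, child_len, step_nm, params.walk_persistence),
                             0.0)
            child.length_nm = (len(child.points) - 1) * step_nm
            seg.events.append((s, "branch", len(segments)))
            segments.append(child)
            queue.append((len(segments) - 1, depth + 1))
            n_branches += 1
    return segments, n_branches


def _interp(points: np.ndarray, step_nm: float, s: float) -> np.ndarray:
    i = min(int(s // step_nm), len(points) - 2)
    frac = (s - i * step_nm) / step_nm
    return points[i] + frac * (points[i + 1] - points[i])


class _NodeTable:
    """Assign global node ids to (segment, arclength) positions, splitting
    walk edges for event positions; snaps arclengths within 1e-6 nm."""

    def __init__(self) -> None:
        self.next_id = 1
        self.nodes: list[tuple[int, np.ndarray, float]] = []  # id, pos nm, radius
        self.edges: list[tuple[int, int]] = []
        self._by_segment: dict[int, list[tuple[float, int]]] = {}

    def build_segment(self, seg_idx: int, seg: _Segment, step_nm: float,
                      baseline_radius: float, attach_node: int | None) -> None:
        base_s = [k * step_nm for k in range(len(seg.points))]
        event_s = sorted({s for s, _, _ in seg.events})
        all_s: list[float] = []
        for s in sorted(base_s + event_s):
            if all_s and abs(s - all_s[-1]) < 1e-6:
                continue
            all_s.append(s)
        entries: list[tuple[float, int]] = []
        prev_id = attach_node
        for s in all_s:
            if seg.parent is not None and s < 1e-6:
                # the attachment vertex lives on the parent segment
                entries.append((0.0, attach_node))
                continue
            nid = self.next_id
            self.next_id += 1
            self.nodes.append((nid, _interp(seg.points, step_nm, s), baseline_radius))
            entries.append((s, nid))
            if prev_id is not None:
                self.edges.append((prev_id, nid))
            prev_id = nid
        self._by_segment[seg_idx] = entries

    def node_at(self, seg_idx: int, s: float) -> int:
        for s_e, nid in self._by_segment[seg_idx]:
            if abs(s_e - s) < 1e-6:
                return nid
        raise KeyError(f"no node at arclength {s} on segment {seg_idx}")

    def nodes_between(self, seg_idx: int, s0: float, s1: float) -> list[int]:
        return [nid for s, nid in self._by_segment[seg_idx] if s0 - 1e-6 <= s <= s1 + 1e-6]

    def set_radius(self, node_id: int, radius: float) -> None:
        for i, (nid, pos, _) in enumerate(self.nodes):
            if nid == node_id:
                self.nodes[i] = (nid, pos, radius)
                return
        raise KeyError(node_id)


# ---------------------------------------------------------------------------
# Main generator
# ---------------------------------------------------------------------------

def generate_axon(
    params: AxonGenParams,
    types: TypeProcessParams | None = None,
    seed: int = 0,
    axon_id: str = "axon_1",
    thing_id: int = 1,
    group: str = "none",
    compartment: str = "DA_axon",
) -> tuple[AxonRecord, GroundTruth]:
    """Generate one synthetic axon with ground truth, reproducible from seed."""
    types = types or TypeProcessParams()
    rng = np.random.default_rng(seed)
    step_nm = params.step_um * NM_PER_UM

    segments, n_branches = _grow_segments(rng, params)
    trunk = segments[0]
    total_cable_nm = sum(seg.length_nm for seg in segments)

    # dendrite compartments carry a per-cell diameter; mito length scales on it
    dendrite_diam_nm: float | None = None
    baseline_diam = params.baseline_diam_nm
    if params.baseline_diam_sd_nm > 0:
        baseline_diam = float(
            _trunc_normal(rng, params.baseline_diam_nm, params.baseline_diam_sd_nm,
                          0.2 * params.baseline_diam_nm, 5 * params.baseline_diam_nm, 1)[0]
        )
    if params.mito_ratio_mean is not None:
        dendrite_diam_nm = baseline_diam

    # --- varicosities along the trunk (sequential log-normal spacing) ------
    varic_s: list[float] = []
    s = rng.lognormal(params.spacing_mu_log_nm, params.spacing_sigma_log)
    while params.place_varicosities and s < trunk.length_nm:
        varic_s.append(s)
        s += rng.lognormal(params.spacing_mu_log_nm, params.spacing_sigma_log)
    type_idx = sample_type_sequence(len(varic_s), types, rng)
    varic_types = [VTYPES[t] for t in type_idx]
    vesicles = [sample_vesicle_diameters(t, params, rng) for t in varic_types]
    for s_v in varic_s:
        trunk.events.append((s_v, "varicosity", None))

    # --- mitochondria, swellings, contacts over all cable -------------------
    if params.mito_ratio_mean is not None:
        mito_mean_um = params.mito_ratio_mean * baseline_diam / NM_PER_UM
        mito_sd_um = params.mito_ratio_sd * baseline_diam / NM_PER_UM
    else:
        mito_mean_um, mito_sd_um = params.mito_len_mean_um, params.mito_len_sd_um
    mito_mu, mito_sigma = lognormal_params_from_mean_sd(mito_mean_um, max(mito_sd_um, 1e-9))

    mito_spans: list[tuple[int, float, float]] = []
    swell_info: list[tuple[int, float, float]] = []
    contact_info: list[tuple[int, float, str]] = []
    for seg_idx, seg in enumerate(segments):
        seg_um = seg.length_nm / NM_PER_UM
        for _ in range(rng.poisson(params.mito_rate_per_um * seg_um)):
            m_len = rng.lognormal(mito_mu, mito_sigma) * NM_PER_UM
            m_len = min(m_len, seg.length_nm)
            start = rng.uniform(0.0, seg.length_nm - m_len) if seg.length_nm > m_len else 0.0
            mito_spans.append((seg_idx, start, start + m_len))
            seg.events.append((start, "mito", None))
            seg.events.append((start + m_len, "mito", None))
        if params.swelling_rate_per_um > 0:
            sw_mu, sw_sigma = lognormal_params_from_mean_sd(
                params.swelling_diam_mean_um, params.swelling_diam_sd_um)
        for _ in range(rng.poisson(params.swelling_rate_per_um * seg_um)):
            s_w = rng.uniform(0.0, seg.length_nm)
            # log-normal: positive support without truncation bias on the mean
            diam_um = max(float(rng.lognormal(sw_mu, sw_sigma)),
                          params.swelling_diam_min_um)
            swell_info.append((seg_idx, s_w, diam_um * NM_PER_UM))
            seg.events.append((s_w, "swelling", None))
        for _ in range(rng.poisson(params.contact_rate_per_um * seg_um)):
            s_c = rng.uniform(0.0, seg.length_nm)
            partner = "axo_axonic" if rng.random() < params.p_axo_axonic else "axo_dendritic"
            contact_info.append((seg_idx, s_c, partner))
            seg.events.append((s_c, "contact", None))

    # --- assemble the node table --------------------------------------------
    table = _NodeTable()
    baseline_radius = baseline_diam / 2.0
    table.build_segment(0, trunk, step_nm, baseline_radius, attach_node=None)
    for seg_idx, seg in enumerate(segments):
        if seg_idx == 0:
            continue
        attach = table.node_at(seg.parent, seg.parent_arclength)
        table.build_segment(seg_idx, seg, step_nm, baseline_radius, attach_node=attach)

    varic_nodes = [table.node_at(0, s_v) for s_v in varic_s]
    for nid in varic_nodes:
        table.set_radius(nid, params.varic_peak_diam_nm / 2.0)
    swellings = []
    for seg_idx, s_w, diam_nm in swell_info:
        nid = table.node_at(seg_idx, s_w)
        table.set_radius(nid, diam_nm / 2.0)
        swellings.append((nid, diam_nm))
    contacts = [(table.node_at(seg_idx, s_c), partner) for seg_idx, s_c, partner in contact_info]
    mito_segments = [
        tuple(table.nodes_between(seg_idx, s0, s1)) for seg_idx, s0, s1 in mito_spans
    ]

    # --- shift to non-negative voxel coordinates ----------------------------
    positions = np.array([pos for _, pos, _ in table.nodes])
    positions -= positions.min(axis=0)
    scale_arr = params.scale.as_array()
    skeleton = Skeleton(
        (
            SkeletonNode(nid, *(pos / scale_arr), radius=rad)
            for (nid, _, rad), pos in zip(table.nodes, positions)
        ),
        table.edges,
        params.scale,
    )

    record = AxonRecord(
        skeleton=skeleton,
        axon_id=axon_id,
        thing_id=thing_id,
        group=group,
        compartment=compartment,
        mito_segments=mito_segments,
        contact_points=sorted(contacts),
        swellings=sorted(swellings),
    )
    flags = morphometry.mito_within_flags(skeleton, varic_nodes, mito_segments)
    for idx, (nid, vtype, diams, flag) in enumerate(
        zip(varic_nodes, varic_types, vesicles, flags)
    ):
        record.varicosities.append(
            VaricosityRecord(
                axon_id=axon_id, index=idx, node_id=nid,
                vesicle_diameters=tuple(float(d) for d in diams),
                vtype=vtype, mito_within_1um=flag,
            )
        )
    record.validate()

    truth = GroundTruth(
        axon_id=axon_id,
        seed=int(seed),
        group=group,
        compartment=compartment,
        trunk_length_um=trunk.length_nm / NM_PER_UM,
        total_cable_um=total_cable_nm / NM_PER_UM,
        n_branch_events=n_branches,
        varicosity_node_ids=list(varic_nodes),
        varicosity_arclengths_nm=[float(sv) for sv in varic_s],
        varicosity_types=list(varic_types),
        mito_lengths_um=[(s1 - s0) / NM_PER_UM for _, s0, s1 in mito_spans],
        swelling_diams_nm=[float(d) for _, d in swellings],
        contact_partners=[p for _, p in contacts],
        dendrite_diameter_nm=dendrite_diam_nm,
    )
    return record, truth


def generate_group(
    n_axons: int,
    group_label: str,
    params: AxonGenParams,
    types: TypeProcessParams | None = None,
    seed: int = 0,
    compartment: str = "DA_axon",
    start_thing_id: int = 1,
) -> list[tuple[AxonRecord, GroundTruth]]:
    """Independent axons with per-axon seeds spawned from the master seed."""
    if n_axons < 0:
        raise ValidationError("n_axons must be >= 0")
    child_seeds = np.random.SeedSequence(seed).generate_state(max(n_axons, 1))
    out = []
    for i in range(n_axons):
        thing_id = start_thing_id + i
        record, truth = generate_axon(
            params, types, seed=int(child_seeds[i]),
            axon_id=f"{group_label}_{compartment}_{thing_id}",
            thing_id=thing_id, group=group_label, compartment=compartment,
        )
        out.append((record, truth))
    return out


# ---------------------------------------------------------------------------
# Group presets
# ---------------------------------------------------------------------------

def study_defaults(group: str, compartment: str = "DA_axon") -> AxonGenParams:
    """Generator defaults reproducing each study condition.

    Saline vs cocaine dopaminergic axons differ in branch rate (0.01 vs 0.04
    /µm), swelling rate (0 vs 0.04 /µm), mitochondrial mean length (0.36 vs
    0.79 µm) and mitochondrion density (0.14 vs 0.16 /µm); contact-point rate
    (0.2 /µm) is shared.  Chemical-synapse (CS) axons and VTA compartments
    keep group-invariant or near-invariant mitochondria.
    """
    cocaine = group == "cocaine"
    if compartment == "DA_axon":
        return AxonGenParams(
            branch_rate_per_um=0.04 if cocaine else 0.01,
            swelling_rate_per_um=0.04 if cocaine else 0.0,
            mito_rate_per_um=0.16 if cocaine else 0.14,
            mito_len_mean_um=0.79 if cocaine else 0.36,
            mito_len_sd_um=0.64 if cocaine else 0.13,
            p_axo_axonic=0.77 if cocaine else 0.83,
        )
    if compartment == "CS_axon":
        # CS-axon mitochondria do not change with cocaine; both groups share
        # the pooled mean length
        return AxonGenParams(
            branch_rate_per_um=0.01,
            mito_len_mean_um=0.72,
            mito_len_sd_um=0.51,
            contact_rate_per_um=0.0,
        )
    if compartment == "MSN_dendrite":
        return AxonGenParams(
            length_range_um=(20.0, 60.0),
            branch_rate_per_um=0.0,
            place_varicosities=False,
            contact_rate_per_um=0.0,
            mito_rate_per_um=0.1,
            mito_ratio_mean=3.0 if cocaine else 1.39,
            mito_ratio_sd=2.9 if cocaine else 1.3,
            baseline_diam_nm=600.0,
            baseline_diam_sd_nm=100.0,
        )
    if compartment == "DA_dendrite":
        return AxonGenParams(
            length_range_um=(20.0, 60.0),
            branch_rate_per_um=0.0,
            place_varicosities=False,
            contact_rate_per_um=0.0,
            mito_rate_per_um=0.1,
            mito_ratio_mean=1.85 if cocaine else 1.74,
            mito_ratio_sd=1.6 if cocaine else 1.5,
            baseline_diam_nm=800.0,
            baseline_diam_sd_nm=150.0,
        )
    if compartment == "DA_soma":
        return AxonGenParams(
            length_range_um=(15.0, 30.0),
            branch_rate_per_um=0.0,
            place_varicosities=False,
            contact_rate_per_um=0.0,
            mito_rate_per_um=1.0,
            mito_len_mean_um=2.78 if cocaine else 2.46,
            mito_len_sd_um=2.7 if cocaine else 2.0,
            baseline_diam_nm=8000.0,
        )
    raise ValidationError(f"unknown compartment {compartment!r}")


# ---------------------------------------------------------------------------
# Whole-study generation
# ---------------------------------------------------------------------------

def default_study_config() -> dict:
    """Two-group dopaminergic-axon study at the reference group sizes."""
    return {
        "scale_nm": [20.0, 20.0, 40.0],
        "groups": [
            {"label": "saline", "compartment": "DA_axon", "n_axons": 44,
             "params": {}, "types": {"rho": 0.0}},
            {"label": "cocaine", "compartment": "DA_axon", "n_axons": 41,
             "params": {}, "types": {"rho": 0.0}},
        ],
    }


def _apply_overrides(params: AxonGenParams, overrides: dict) -> AxonGenParams:
    for key, value in overrides.items():
        if not hasattr(params, key):
            raise ValidationError(f"unknown generator parameter {key!r}")
        if key in ("length_range_um", "small_bin", "large_bin"):
            value = tuple(value)
        if key == "scale":
            value = VoxelScale(*value)
        setattr(params, key, value)
    params.__post_init__()
    return params


def build_study(config: dict, seed: int) -> tuple[list[AxonRecord], list[GroundTruth]]:
    """Generate every group of a study config in memory."""
    records: list[AxonRecord] = []
    truths: list[GroundTruth] = []
    group_seeds = np.random.SeedSequence(seed).generate_state(len(config["groups"]))
    thing_id = 1
    for gi, grp in enumerate(config["groups"]):
        params = study_defaults(grp["label"], grp.get("compartment", "DA_axon"))
        if "scale_nm" in config:
            params.scale = VoxelScale(*config["scale_nm"])
        params = _apply_overrides(params, grp.get("params", {}))
        types = TypeProcessParams(**grp.get("types", {}))
        pairs = generate_group(
            grp["n_axons"], grp["label"], params, types,
            seed=int(group_seeds[gi]), compartment=grp.get("compartment", "DA_axon"),
            start_thing_id=thing_id,
        )
        thing_id += grp["n_axons"]
        records.extend(r for r, _ in pairs)
        truths.extend(t for _, t in pairs)
    return records, truths


def config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True).encode()).hexdigest()[:16]


def generate_study(config: dict, seed: int, outdir) -> dict:
    """Generate a study to disk: NML per group + manifest + ground truth.

    Returns the study manifest, which links every emitted file and axon to
    its ground truth and records the master seed and config hash.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records, truths = build_study(config, seed)
    files = []
    for grp in config["groups"]:
        label, comp = grp["label"], grp.get("compartment", "DA_axon")
        grp_records = [r for r in records if r.group == label and r.compartment == comp]
        if grp_records:
            nml_path = outdir / f"{label}_{comp}.nml"
            nml_path.write_text(skeleton_io.write_nml(grp_records))
        else:
            nml_path = None
        files.append(
            {
                "label": label,
                "compartment": comp,
                "nml": nml_path.name if nml_path else None,
                "thing_ids": [r.thing_id for r in grp_records],
            }
        )
    manifest = {
        "seed": int(seed),
        "config": config,
        "config_hash": config_hash(config),
        "scale_nm": config.get("scale_nm", [20.0, 20.0, 40.0]),
        "files": files,
        "axons": skeleton_io.make_manifest(records),
    }
    skeleton_io.save_manifest(manifest, outdir / "study_manifest.json")
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump([asdict(t) for t in truths], fh, indent=1)
    return manifest


def load_study(outdir) -> list[AxonRecord]:
    """Parse a generated study back from disk via the NML reader."""
    outdir = Path(outdir)
    manifest = skeleton_io.load_manifest(outdir / "study_manifest.json")
    scale = VoxelScale(*manifest["scale_nm"])
    records: list[AxonRecord] = []
    for entry in manifest["files"]:
        if entry["nml"] is None:
            continue
        text = (outdir / entry["nml"]).read_text()
        records.extend(skeleton_io.parse_nml(text, scale, manifest=manifest["axons"]))
    return records
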