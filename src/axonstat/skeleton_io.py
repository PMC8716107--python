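"""Read and write skeleton annotations.

Two on-disk forms are supported: a pinned Knossos-style NML XML dialect and a
flat JSON interchange.  The NML dialect is::

    <things>
      <thing id="1">
        <nodes><node id="1" x="0" y="0" z="0" radius="50"/>...</nodes>
        <edges><edge source="1" target="2"/>...</edges>
        <comments><comment node="1" content="varicosity=II;vesicle_diam_nm=48;50"/></comments>
      </thing>
    </things>

Coordinates are 0-based voxel indices; radii are stored in nm.  Node comments
carry annotation tags as ``key=value`` pairs joined by ``;``; a ``;``-separated
token without ``=`` continues the previous value (so vesicle diameter lists
stay readable).  Group/compartment metadata travels in a sidecar JSON manifest
keyed by thing id, since NML has no standard slot for it.
"""

from __future__ import annotations

import json
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from lxml import etree

from . import morphometry
from .types import (
    ANNOTATION_KEYS,
    AnnotationTag,
    AxonRecord,
    Skeleton,
    SkeletonNode,
    ValidationError,
    VaricosityRecord,
    VoxelScale,
    VTYPES,
)


class ParseError(ValueError):
    """Malformed input file (XML syntax, missing attributes, bad numbers)."""


# Deterministic key order used when serializing a node's tags into one comment.
_KEY_ORDER = ["soma", "varicosity", "vesicle_diam_nm", "mito_start", "mito_end",
              "contact_point", "swelling"]


# ---------------------------------------------------------------------------
# Comment tag syntax
# ---------------------------------------------------------------------------

def parse_comment(content: str) -> list[tuple[str, str]]:
    """Split a comment string into (key, value) tags.

    Tokens are ``;``-separated; a token containing ``=`` starts a new tag, a
    bare token either opens a valueless tag (if no tag is pending) or extends
    the previous tag's value (rejoined with ``;``).
    """
    tags: list[tuple[str, str]] = []
    for token in content.split(";"):
        token = token.strip()
        if not token:
            continue
        if "=" in token:
            key, value = token.split("=", 1)
            tags.append((key.strip(), value.strip()))
        elif not tags:
            tags.append((token, ""))
        else:
            key, value = tags[-1]
            tags[-1] = (key, f"{value};{token}" if value else token)
    return tags


def format_comment(tags: list[tuple[str, str]]) -> str:
    parts = []
    for key, value in tags:
        parts.append(f"{key}={value}" if value else key)
    return ";".join(parts)


def _parse_diameters(value: str, node_id: int) -> tuple[float, ...]:
    try:
        diams = tuple(float(tok) for tok in value.split(";") if tok.strip())
    except ValueError as exc:
        raise ParseError(f"bad vesicle diameter list {value!r} on node {node_id}") from exc
    if any(d <= 0 for d in diams):
        raise ParseError(f"non-positive vesicle diameter on node {node_id}")
    return diams


# ---------------------------------------------------------------------------
# Record assembly from raw parts (shared by NML and JSON paths)
# ---------------------------------------------------------------------------

def _build_record(
    thing_id: int,
    skeleton: Skeleton,
    node_tags: list[AnnotationTag],
    manifest: Mapping[str, Mapping[str, str]] | None,
) -> AxonRecord:
    try:
        skeleton.validate()
    except ValidationError as exc:
        raise ValidationError(f"thing {thing_id}: {exc}") from exc

    soma_node: int | None = None
    varic: dict[int, dict[str, str]] = {}
    mito_start: dict[str, int] = {}
    mito_end: dict[str, int] = {}
    contacts: list[tuple[int, str]] = []
    swellings: list[tuple[int, float]] = []
    extra: list[AnnotationTag] = []

    for tag in node_tags:
        if tag.node_id not in skeleton.nodes:
            raise ValidationError(f"thing {thing_id}: comment on missing node {tag.node_id}")
        if tag.key not in ANNOTATION_KEYS:
            extra.append(tag)  # unknown keys preserved but ignored
            continue
        if tag.key == "soma":
            soma_node = tag.node_id if soma_node is None else soma_node
        elif tag.key == "varicosity":
            varic.setdefault(tag.node_id, {})["vtype"] = tag.value
        elif tag.key == "vesicle_diam_nm":
            varic.setdefault(tag.node_id, {})["diams"] = tag.value
        elif tag.key == "mito_start":
            if tag.value in mito_start:
                raise ValidationError(
                    f"thing {thing_id}: duplicate mito_start id {tag.value!r}")
            mito_start[tag.value] = tag.node_id
        elif tag.key == "mito_end":
            if tag.value in mito_end:
                raise ValidationError(
                    f"thing {thing_id}: duplicate mito_end id {tag.value!r}")
            mito_end[tag.value] = tag.node_id
        elif tag.key == "contact_point":
            contacts.append((tag.node_id, tag.value))
        elif tag.key == "swelling":
            try:
                swellings.append((tag.node_id, float(tag.value)))
            except ValueError as exc:
                raise ParseError(
                    f"thing {thing_id}: bad swelling diameter {tag.value!r}") from exc

    if set(mito_start) != set(mito_end):
        missing = set(mito_start) ^ set(mito_end)
        raise ValidationError(
            f"thing {thing_id}: unpaired mitochondrion segment ids {sorted(missing)}")

    def _seg_key(k: str):
        return (0, int(k)) if k.isdigit() else (1, k)

    mito_segments = [
        tuple(morphometry.tree_path(skeleton, mito_start[k], mito_end[k]))
        for k in sorted(mito_start, key=_seg_key)
    ]

    meta = (manifest or {}).get(str(thing_id), {})
    record = AxonRecord(
        skeleton=skeleton,
        axon_id=str(meta.get("axon_id", f"axon_{thing_id}")),
        thing_id=thing_id,
        group=meta.get("group", "none"),
        compartment=meta.get("compartment", "DA_axon"),
        mito_segments=mito_segments,
        contact_points=sorted(contacts),
        swellings=sorted(swellings),
        soma_node=soma_node,
        extra_tags=extra,
    )

    ordered = morphometry.order_varicosity_nodes(skeleton, record.root_node, sorted(varic))
    flags = morphometry.mito_within_flags(skeleton, ordered, mito_segments)
    for idx, (nid, flag) in enumerate(zip(ordered, flags)):
        info = varic[nid]
        vtype = info.get("vtype", "")
        record.varicosities.append(
            VaricosityRecord(
                axon_id=record.axon_id,
                index=idx,
                node_id=nid,
                vesicle_diameters=_parse_diameters(info.get("diams", ""), nid),
                vtype=vtype if vtype in VTYPES else None,
                mito_within_1um=flag,
            )
        )
    record.validate()
    return record


# ---------------------------------------------------------------------------
# NML
# ---------------------------------------------------------------------------

def parse_nml(
    xml_text: str | bytes,
    scale: VoxelScale,
    manifest: Mapping[str, Mapping[str, str]] | None = None,
) -> list[AxonRecord]:
    """Parse NML text into one ``AxonRecord`` per ``<thing>``.

    Raises ``ParseError`` (naming the line) on malformed XML and
    ``ValidationError`` (naming the thing) on cyclic/disconnected skeletons or
    edges to missing nodes.
    """
    data = xml_text.encode() if isinstance(xml_text, str) else xml_text
    try:
        root = etree.fromstring(data)
    except etree.XMLSyntaxError as exc:
        raise ParseError(f"XML parse error at line {exc.lineno}: {exc.msg}") from exc
    if root.tag != "things":
        raise ParseError(f"expected <things> root element, found <{root.tag}>")

    records = []
    for thing in root.findall("thing"):
        try:
            thing_id = int(thing.get("id"))
        except (TypeError, ValueError) as exc:
            raise ParseError("thing without a valid integer id") from exc
        nodes = []
        for el in thing.findall("nodes/node"):
            try:
                nodes.append(
                    SkeletonNode(
                        node_id=int(el.get("id")),
                        x=float(el.get("x")),
                        y=float(el.get("y")),
                        z=float(el.get("z")),
                        radius=float(el.get("radius", 0.0)),
                    )
                )
            except (TypeError, ValueError) as exc:
                raise ParseError(
                    f"thing {thing_id}: bad node attributes at line {el.sourceline}") from exc
        edges = []
        for el in thing.findall("edges/edge"):
            try:
                edges.append((int(el.get("source")), int(el.get("target"))))
            except (TypeError, ValueError) as exc:
                raise ParseError(
                    f"thing {thing_id}: bad edge attributes at line {el.sourceline}") from exc
        tags = []
        for el in thing.findall("comments/comment"):
            try:
                nid = int(el.get("node"))
            except (TypeError, ValueError) as exc:
                raise ParseError(
                    f"thing {thing_id}: comment without node id at line {el.sourceline}") from exc
            for key, value in parse_comment(el.get("content", "")):
                tags.append(AnnotationTag(node_id=nid, key=key, value=value))
        skeleton = Skeleton(nodes, edges, scale)
        records.append(_build_record(thing_id, skeleton, tags, manifest))
    return records


def _node_tags(record: AxonRecord) -> dict[int, list[tuple[str, str]]]:
    """Collect each node's annotation tags in deterministic key order."""
    per_node: dict[int, dict[str, list[str]]] = {}

    def add(nid: int, key: str, value: str) -> None:
        per_node.setdefault(nid, {}).setdefault(key, []).append(value)

    if record.soma_node is not None:
        add(record.soma_node, "soma", "")
    for v in record.varicosities:
        add(v.node_id, "varicosity", v.vtype or "")
        if v.vesicle_diameters:
            add(v.node_id, "vesicle_diam_nm", ";".join(repr(d) for d in v.vesicle_diameters))
    for seg_idx, chain in enumerate(record.mito_segments):
        add(chain[0], "mito_start", str(seg_idx))
        add(chain[-1], "mito_end", str(seg_idx))
    for nid, partner in record.contact_points:
        add(nid, "contact_point", partner)
    for nid, diam in record.swellings:
        add(nid, "swelling", repr(float(diam)))
    for tag in record.extra_tags:
        add(tag.node_id, tag.key, tag.value)

    out: dict[int, list[tuple[str, str]]] = {}
    for nid, by_key in per_node.items():
        tags: list[tuple[str, str]] = []
        for key in _KEY_ORDER:
            for value in by_key.get(key, []):
                tags.append((key, value))
        for key in by_key:
            if key not in _KEY_ORDER:
                for value in by_key[key]:
                    tags.append((key, value))
        out[nid] = tags
    return out


def write_nml(records: Iterable[AxonRecord]) -> str:
    """Serialize records to NML with deterministic ordering (ascending ids).

    Round-trip contract: ``parse_nml(write_nml(R), scale)`` reproduces ``R``
    exactly (ids, coordinates, radii, annotations).
    """
    root = etree.Element("things")
    for record in sorted(records, key=lambda r: r.thing_id):
        record.validate()
        thing = etree.SubElement(root, "thing", id=str(record.thing_id))
        nodes_el = etree.SubElement(thing, "nodes")
        for nid in sorted(record.skeleton.nodes):
            n = record.skeleton.nodes[nid]
            etree.SubElement(
                nodes_el, "node", id=str(n.node_id),
                x=repr(float(n.x)), y=repr(float(n.y)), z=repr(float(n.z)),
                radius=repr(float(n.radius)),
            )
        edges_el = etree.SubElement(thing, "edges")
        for a, b in sorted(record.skeleton.edges):
            etree.SubElement(edges_el, "edge", source=str(a), target=str(b))
        comments_el = etree.SubElement(thing, "comments")
        tags = _node_tags(record)
        for nid in sorted(tags):
            etree.SubElement(
                comments_el, "comment", node=str(nid), content=format_comment(tags[nid])
            )
    return etree.tostring(root, pretty_print=True, encoding="unicode")


# ---------------------------------------------------------------------------
# JSON interchange
# ---------------------------------------------------------------------------

def records_to_json(records: Iterable[AxonRecord]) -> str:
    """Flat JSON form of the same content as NML + manifest, self-contained."""
    payload = []
    for r in sorted(records, key=lambda rec: rec.thing_id):
        r.validate()
        sc = r.skeleton.scale
        payload.append(
            {
                "thing_id": r.thing_id,
                "axon_id": r.axon_id,
                "group": r.group,
                "compartment": r.compartment,
                "scale_nm": [sc.sx, sc.sy, sc.sz],
                "nodes": [
                    [n.node_id, n.x, n.y, n.z, n.radius]
                    for n in (r.skeleton.nodes[i] for i in sorted(r.skeleton.nodes))
                ],
                "edges": sorted(map(list, r.skeleton.edges)),
                "soma_node": r.soma_node,
                "varicosities": [
                    {
                        "index": v.index,
                        "node_id": v.node_id,
                        "vesicle_diameters_nm": list(v.vesicle_diameters),
                        "vtype": v.vtype,
                        "mito_within_1um": v.mito_within_1um,
                    }
                    for v in r.varicosities
                ],
                "mito_segments": [list(chain) for chain in r.mito_segments],
                "contact_points": [[nid, partner] for nid, partner in r.contact_points],
                "swellings": [[nid, diam] for nid, diam in r.swellings],
                "extra_tags": [[t.node_id, t.key, t.value] for t in r.extra_tags],
            }
        )
    return json.dumps(payload, indent=1)


def records_from_json(text: str) -> list[AxonRecord]:
    try:
        payload = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ParseError(f"JSON parse error at line {exc.lineno}: {exc.msg}") from exc
    records = []
    for item in payload:
        scale = VoxelScale(*item["scale_nm"])
        skeleton = Skeleton(
            (SkeletonNode(int(n[0]), n[1], n[2], n[3], n[4]) for n in item["nodes"]),
            ((int(a), int(b)) for a, b in item["edges"]),
            scale,
        )
        record = AxonRecord(
            skeleton=skeleton,
            axon_id=item["axon_id"],
            thing_id=int(item["thing_id"]),
            group=item["group"],
            compartment=item["compartment"],
            mito_segments=[tuple(chain) for chain in item["mito_segments"]],
            contact_points=[(int(n), p) for n, p in item["contact_points"]],
            swellings=[(int(n), float(d)) for n, d in item["swellings"]],
            soma_node=item["soma_node"],
            extra_tags=[AnnotationTag(int(n), k, v) for n, k, v in item["extra_tags"]],
        )
        for v in item["varicosities"]:
            record.varicosities.append(
                VaricosityRecord(
                    axon_id=record.axon_id,
                    index=int(v["index"]),
                    node_id=int(v["node_id"]),
                    vesicle_diameters=tuple(float(d) for d in v["vesicle_diameters_nm"]),
                    vtype=v["vtype"],
                    mito_within_1um=bool(v["mito_within_1um"]),
                )
            )
        record.validate()
        records.append(record)
    return records


# ---------------------------------------------------------------------------
# Flat tables
# ---------------------------------------------------------------------------

def to_table(records: Iterable[AxonRecord]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flatten records to (nodes, annotations) DataFrames.

    The node table has one row per skeleton node with both voxel and
    nm-converted coordinates; the annotation table has one row per annotated
    structure (varicosity, mitochondrion segment, contact point, swelling).
    """
    node_rows = []
    ann_rows = []
    for r in records:
        sc = r.skeleton.scale
        for nid in sorted(r.skeleton.nodes):
            n = r.skeleton.nodes[nid]
            node_rows.append(
                {
                    "axon_id": r.axon_id, "thing_id": r.thing_id, "node_id": n.node_id,
                    "x_vox": n.x, "y_vox": n.y, "z_vox": n.z,
                    "x_nm": n.x * sc.sx, "y_nm": n.y * sc.sy, "z_nm": n.z * sc.sz,
                    "radius_nm": n.radius,
                }
            )
        for v in r.varicosities:
            ann_rows.append(
                {
                    "axon_id": r.axon_id, "kind": "varicosity", "node_id": v.node_id,
                    "index": v.index, "vtype": v.vtype,
                    "n_vesicles": len(v.vesicle_diameters),
                    "vesicle_diameters_nm": ";".join(repr(d) for d in v.vesicle_diameters),
                    "mito_within_1um": v.mito_within_1um,
                }
            )
        for i, chain in enumerate(r.mito_segments):
            ann_rows.append(
                {
                    "axon_id": r.axon_id, "kind": "mito_segment", "node_id": chain[0],
                    "index": i, "length_um": morphometry.mito_length(r.skeleton, chain),
                }
            )
        for nid, partner in r.contact_points:
            ann_rows.append(
                {"axon_id": r.axon_id, "kind": "contact_point", "node_id": nid,
                 "partner_class": partner}
            )
        for nid, diam in r.swellings:
            ann_rows.append(
                {"axon_id": r.axon_id, "kind": "swelling", "node_id": nid,
                 "diameter_nm": diam}
            )
    return pd.DataFrame(node_rows), pd.DataFrame(ann_rows)


# ---------------------------------------------------------------------------
# Sidecar manifest
# ---------------------------------------------------------------------------

def make_manifest(records: Iterable[AxonRecord]) -> dict[str, dict[str, str]]:
    return {
        str(r.thing_id): {
            "axon_id": r.axon_id, "group": r.group, "compartment": r.compartment,
        }
        for r in records
    }


def save_manifest(manifest: Mapping, path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)


def load_manifest(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
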