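"""Deterministic 3D layout: concentric depth rings, CNV elevation, family planes.

Nodes sit on a base plane (z = 0) at a radius fixed by their pathway depth,
evenly spaced in angle within each ring.  Copy-number elevation then moves
nodes above (gains) or below (losses) the plane; expanding a gene-family
node places its members on a small elevated plane above the family sphere.
Everything is a pure function of its inputs — identical inputs give
bit-identical coordinates.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field

from .config import CNVConfig, LayoutConfig
from .datamodel import Pathway, ValidationError
from .stats import CohortGeneSummary

Vec3 = tuple[float, float, float]


@dataclass
class LayoutModel:
    positions: dict[str, Vec3] = field(default_factory=dict)
    depths: dict[str, int] = field(default_factory=dict)
    cones: dict[str, tuple[float, str]] = field(default_factory=dict)
    guide_rings: list[float] = field(default_factory=list)
    family_planes: dict[str, dict[str, Vec3]] = field(default_factory=dict)

    def copy(self) -> "LayoutModel":
        return copy.deepcopy(self)


def compute_depths(pathway: Pathway) -> dict[str, int]:
    """Integer pathway depth for every collapsed-view node.

    Depth is the length of the shortest directed path from any root
    (in-degree 0 counting directed edges only); family members are folded
    into their family node first.  A graph with no in-degree-0 node (a pure
    cycle) designates the lexicographically smallest node id as root.
    Nodes unreachable from every root sit one level beyond the deepest
    reachable node.
    """
    g = pathway.to_networkx(collapsed=True)
    nodes = sorted(g.nodes)
    if not nodes:
        return {}

    def directed_preds(n):
        return [p for p in g.predecessors(n) if g.edges[p, n].get("directed", True)]

    def directed_succs(n):
        return [s for s in g.successors(n) if g.edges[n, s].get("directed", True)]

    roots = [n for n in nodes if not directed_preds(n)]
    if not roots:
        roots = [min(nodes)]
    # multi-source BFS over directed edges
    depths: dict[str, int] = {r: 0 for r in roots}
    frontier = list(roots)
    while frontier:
        nxt = []
        for n in frontier:
            for s in directed_succs(n):
                if s not in depths:
                    depths[s] = depths[n] + 1
                    nxt.append(s)
        frontier = nxt
    max_reached = max(depths.values())
    for n in nodes:
        if n not in depths:
            depths[n] = max_reached + 1
    return depths


def radial_layout(pathway: Pathway, depths: dict[str, int] | None = None,
                  config: LayoutConfig | None = None) -> LayoutModel:
    """Place collapsed-view nodes on concentric rings by depth.

    A node at depth d sits at radius ``d * ring_spacing``; a sole depth-0
    root sits at the origin.  When several nodes share depth 0 (multi-root
    pathway) every ring is pushed one level outward so roots get a ring of
    their own instead of colliding at the origin.  Nodes sharing a ring are
    evenly spaced in angle, ordered alphabetically by label (or by input
    order per config).
    """
    config = config or LayoutConfig()
    if depths is None:
        depths = compute_depths(pathway)
    model = LayoutModel(depths=dict(depths))
    if not depths:
        return model
    by_depth: dict[int, list[str]] = {}
    for n, d in depths.items():
        by_depth.setdefault(d, []).append(n)

    label = {n.id: n.label for n in pathway.nodes}
    input_rank = {nid: i for i, nid in enumerate(pathway.node_ids)}

    def order(ids: list[str]) -> list[str]:
        if config.angular_tiebreak == "alphabetical":
            return sorted(ids, key=lambda i: (label[i], i))
        return sorted(ids, key=lambda i: input_rank[i])

    root_offset = 0 if len(by_depth.get(0, [])) <= 1 else 1
    ring_radii: set[float] = set()
    for d, ids in sorted(by_depth.items()):
        radius = (d + root_offset) * config.ring_spacing
        ids = order(ids)
        if radius == 0.0:
            model.positions[ids[0]] = (0.0, 0.0, 0.0)
            continue
        ring_radii.add(radius)
        n = len(ids)
        for i, nid in enumerate(ids):
            theta = 2.0 * math.pi * i / n
            model.positions[nid] = (radius * math.cos(theta), radius * math.sin(theta), 0.0)
    model.guide_rings = sorted(ring_radii)
    return model


def apply_cnv_elevation(layout: LayoutModel, summaries: dict[str, CohortGeneSummary],
                        pathway: Pathway, cnv_cfg: CNVConfig | None = None) -> LayoutModel:
    """Raise gained genes above the plane and lower lost ones below it.

    Relative mode: ``z = mean_deviation * height_scale``.  Boolean mode: a
    constant flag height (one ``height_scale`` unit) in the direction of
    the mean deviation, applied only when some sample deviates from neutral
    by more than epsilon.  A cone record (gain = red tag, loss = green tag)
    is attached whenever the node leaves the plane.
    """
    cnv_cfg = cnv_cfg or CNVConfig()
    out = layout.copy()
    label = {n.id: n.label for n in pathway.nodes}
    for nid, pos in layout.positions.items():
        summary = summaries.get(label.get(nid, nid))
        if summary is None or summary.cnv is None:
            continue
        cs = summary.cnv
        if cnv_cfg.mode == "relative":
            z = cs.mean_deviation * cnv_cfg.height_scale
        else:
            sign = 1.0 if cs.direction == "gain" else (-1.0 if cs.direction == "loss" else 0.0)
            z = sign * cnv_cfg.height_scale if cs.boolean_flag else 0.0
        if z != 0.0:
            out.positions[nid] = (pos[0], pos[1], z)
            out.cones[nid] = (z, "gain" if z > 0 else "loss")
    return out


def expand_family(layout: LayoutModel, pathway: Pathway, family_id: str,
                  config: LayoutConfig | None = None) -> LayoutModel:
    """Place a family's member genes on an elevated plane above its node.

    Members are spread evenly on a circle of diameter ``child_spread`` at
    ``family_plane_height`` above the family sphere; a single member sits
    directly above it.  ``collapse_family`` inverts this exactly.
    """
    config = config or LayoutConfig()
    if family_id not in pathway.families:
        raise ValidationError(f"{family_id!r} is not a family node in pathway {pathway.name!r}")
    if family_id in layout.family_planes:
        raise ValidationError(f"family {family_id!r} is already expanded")
    if family_id not in layout.positions:
        raise ValidationError(f"family {family_id!r} has no layout position")
    fx, fy, fz = layout.positions[family_id]
    members = list(pathway.families[family_id])
    label = {n.id: n.label for n in pathway.nodes}
    if config.angular_tiebreak == "alphabetical":
        members = sorted(members, key=lambda i: (label[i], i))
    out = layout.copy()
    z = fz + config.family_plane_height
    plane: dict[str, Vec3] = {}
    if len(members) == 1:
        plane[members[0]] = (fx, fy, z)
    else:
        r = config.child_spread / 2.0
        for i, m in enumerate(members):
            theta = 2.0 * math.pi * i / len(members)
            plane[m] = (fx + r * math.cos(theta), fy + r * math.sin(theta), z)
    out.family_planes[family_id] = plane
    out.positions.update(plane)
    return out


def collapse_family(layout: LayoutModel, family_id: str) -> LayoutModel:
    """Remove an expanded family's member plane (exact inverse of expand)."""
    if family_id not in layout.family_planes:
        raise ValidationError(f"family {family_id!r} is not expanded")
    out = layout.copy()
    plane = out.family_planes.pop(family_id)
    for m in plane:
        out.positions.pop(m, None)
        out.cones.pop(m, None)
    return out
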