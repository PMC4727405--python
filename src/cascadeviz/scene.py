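"""Renderer-independent scene graph and its three export backends.

The scene is an ordered list of typed primitives (spheres, edges, bars,
splicing annuli, CNV cones, guide rings, text labels) with positions and
RGB colors, assembled from a pathway, a layout and the per-gene cohort
summaries.  The canonical JSON export is byte-stable for fixed inputs and
is the contract consumed by the bundled HTML renderer, the matplotlib
raster backend, or any other 3D-capable backend.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

from .config import ColorScheme, ViewConfig, RGB
from .datamodel import DataType, Pathway, ValidationError
from .layout import LayoutModel, Vec3
from .stats import CohortGeneSummary

KINDS = ("sphere", "line_edge", "bar", "ring_annulus", "cone", "guide_ring", "text_label")


@dataclass
class Primitive:
    kind: str
    node: str | None = None
    position: Vec3 | None = None
    end: Vec3 | None = None          # second endpoint for line_edge / bar
    size: float = 1.0
    color: RGB = (0, 0, 0)
    text: str | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValidationError(f"unknown primitive kind {self.kind!r}")


@dataclass
class SceneGraph:
    primitives: list[Primitive] = field(default_factory=list)
    view: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def count(self, kind: str) -> int:
        return sum(1 for p in self.primitives if p.kind == kind)

    def of_kind(self, kind: str) -> list[Primitive]:
        return [p for p in self.primitives if p.kind == kind]


def color_for_summary(summary: CohortGeneSummary | None, data_type: DataType | None,
                      scheme: ColorScheme) -> RGB:
    """Sphere/annulus color for one gene: bin color, or the no-data color
    when the gene is restricted out or carries no frequency for the type."""
    if summary is None or summary.restricted_out or data_type is None:
        return scheme.no_data_color
    fs = summary.frequencies.get(DataType(data_type))
    if fs is None or fs.frequency is None or fs.bin is None:
        return scheme.no_data_color
    return scheme.bin_colors[fs.bin]


def _bar_height(value: float, view: ViewConfig) -> float:
    return min(value * view.expression_bar_scale, view.expression_bar_max)


def build_scene(pathway: Pathway, layout: LayoutModel,
                summaries: dict[str, CohortGeneSummary],
                view: ViewConfig | None = None,
                scheme: ColorScheme | None = None,
                provenance: dict | None = None) -> SceneGraph:
    """Assemble the drawable scene for one pathway view.

    Emits, in a fixed deterministic order: guide rings (when enabled), one
    line per pathway edge between visible nodes, one sphere and one name
    label per visible node, then per active layer: green expression bars
    (with a red numeric label on outlier-flagged genes), splicing annuli
    colored by splicing bin, and CNV cones matching the layout elevation.
    """
    view = view or ViewConfig()
    scheme = scheme or ColorScheme()
    label = {n.id: n.label for n in pathway.nodes}
    is_family = {n.id: n.is_family for n in pathway.nodes}
    for nid in layout.positions:
        if nid not in label:
            raise ValidationError(
                f"layout node {nid!r} is not part of pathway {pathway.name!r}")

    scene = SceneGraph(
        view={"expression": view.expression, "splicing": view.splicing,
              "cnv": view.cnv, "show_guide_rings": view.show_guide_rings,
              "node_color_type": None if view.node_color_type is None
              else str(view.node_color_type)},
        provenance=dict(provenance or {}),
    )
    prims = scene.primitives

    if view.show_guide_rings:
        for r in layout.guide_rings:
            prims.append(Primitive("guide_ring", position=(0.0, 0.0, 0.0), size=r,
                                   color=scheme.guide_ring_color))

    member_to_fam = {m: f for f, ms in pathway.families.items() for m in ms}

    def resolve(nid: str) -> str | None:
        if nid in layout.positions:
            return nid
        fam = member_to_fam.get(nid)
        return fam if fam in layout.positions else None

    for e in pathway.edges:
        s, t = resolve(e.source), resolve(e.target)
        if s is None or t is None or s == t:
            continue
        prims.append(Primitive("line_edge", position=layout.positions[s],
                               end=layout.positions[t], color=scheme.edge_color,
                               metadata={"source": s, "target": t,
                                         "directed": e.directed}))

    visible = sorted(layout.positions)
    for nid in visible:
        pos = layout.positions[nid]
        summary = summaries.get(label[nid])
        if is_family.get(nid):
            color = scheme.family_color
        else:
            color = color_for_summary(summary, view.node_color_type, scheme)
        prims.append(Primitive("sphere", node=nid, position=pos, size=1.0, color=color,
                               metadata={"label": label[nid],
                                         "is_family": bool(is_family.get(nid))}))
        prims.append(Primitive("text_label", node=nid,
                               position=(pos[0], pos[1], pos[2] + 1.5),
                               text=label[nid], color=(0, 0, 0)))

    if view.expression:
        for nid in visible:
            summary = summaries.get(label[nid])
            if is_family.get(nid) or summary is None or summary.expression is None \
                    or summary.expression.summary is None:
                continue
            pos = layout.positions[nid]
            h = _bar_height(summary.expression.summary, view)
            top = (pos[0], pos[1], pos[2] + h)
            prims.append(Primitive("bar", node=nid, position=pos, end=top, size=h,
                                   color=scheme.expression_bar_color,
                                   metadata={"value": summary.expression.summary}))
            if summary.expression.is_outlier_gene:
                prims.append(Primitive(
                    "text_label", node=nid, position=(top[0], top[1], top[2] + 0.5),
                    text=f"{summary.expression.summary:g}",
                    color=scheme.outlier_marker_color,
                    metadata={"outlier_gene": True}))

    if view.splicing:
        for nid in visible:
            summary = summaries.get(label[nid])
            if is_family.get(nid) or summary is None:
                continue
            fs = summary.frequencies.get(DataType.SPLICING)
            if fs is None or fs.frequency is None:
                continue
            color = color_for_summary(summary, DataType.SPLICING, scheme)
            prims.append(Primitive("ring_annulus", node=nid,
                                   position=layout.positions[nid], size=1.6,
                                   color=color, metadata={"frequency": fs.frequency,
                                                          "bin": fs.bin}))

    if view.cnv:
        for nid in sorted(layout.cones):
            if nid not in layout.positions:
                continue
            z, tag = layout.cones[nid]
            base = layout.positions[nid]
            color = scheme.gain_cone_color if tag == "gain" else scheme.loss_cone_color
            prims.append(Primitive("cone", node=nid,
                                   position=(base[0], base[1], 0.0),
                                   end=base, size=abs(z), color=color,
                                   metadata={"direction": tag, "apex_height": z}))
    return scene


# ---------------------------------------------------------------------------
# canonical JSON

def _round_floats(obj, ndigits: int = 9):
    if isinstance(obj, float):
        r = round(obj, ndigits)
        return 0.0 if r == 0 else r
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def scene_to_dict(scene: SceneGraph) -> dict:
    return _round_floats({
        "primitives": [asdict(p) for p in scene.primitives],
        "view": scene.view,
        "provenance": scene.provenance,
    })


def scene_to_json(scene: SceneGraph) -> str:
    """Canonical serialization: sorted keys, fixed float rounding."""
    return json.dumps(scene_to_dict(scene), sort_keys=True, separators=(",", ":"))


def export_scene_json(scene: SceneGraph, path: str | Path) -> None:
    Path(path).write_text(scene_to_json(scene) + "\n", encoding="utf-8")


def scene_from_json(path: str | Path) -> SceneGraph:
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    prims = []
    for p in doc.get("primitives", []):
        prims.append(Primitive(
            kind=p["kind"], node=p.get("node"),
            position=None if p.get("position") is None else tuple(p["position"]),
            end=None if p.get("end") is None else tuple(p["end"]),
            size=p.get("size", 1.0), color=tuple(p.get("color", (0, 0, 0))),
            text=p.get("text"), metadata=p.get("metadata", {})))
    return SceneGraph(primitives=prims, view=doc.get("view", {}),
                      provenance=doc.get("provenance", {}))


# ---------------------------------------------------------------------------
# HTML backend (self-contained canvas renderer; the scene JSON is the contract)

_HTML_TEMPLATE = """<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>{title}</title>
<style>body{{margin:0;background:#111;overflow:hidden;font-family:sans-serif}}
#hud{{position:fixed;top:8px;left:8px;color:#ccc;font-size:12px}}</style></head>
<body><div id="hud">{title} &mdash; drag to rotate, wheel to zoom</div>
<canvas id="c"></canvas>
<script id="scene-data" type="application/json">{scene_json}</script>
<script>
const scene = JSON.parse(document.getElementById("scene-data").textContent);
const canvas = document.getElementById("c"), ctx = canvas.getContext("2d");
let yaw = 0.6, pitch = 0.9, dist = {camera_dist};
function rgb(c) {{ return `rgb(${{c[0]}},${{c[1]}},${{c[2]}})`; }}
function project(p) {{
  const cy = Math.cos(yaw), sy = Math.sin(yaw), cp = Math.cos(pitch), sp = Math.sin(pitch);
  const x = p[0]*cy - p[1]*sy, y = p[0]*sy + p[1]*cy;
  const yy = y*cp - p[2]*sp, zz = y*sp + p[2]*cp;
  const f = dist/(dist + yy + 1e-6);
  return [canvas.width/2 + x*f*12, canvas.height/2 - zz*f*12, f];
}}
function circle3d(cx, r, n) {{
  const pts = [];
  for (let i = 0; i <= n; i++) {{
    const t = 2*Math.PI*i/n;
    pts.push(project([cx[0]+r*Math.cos(t), cx[1]+r*Math.sin(t), cx[2]]));
  }}
  return pts;
}}
function draw() {{
  canvas.width = innerWidth; canvas.height = innerHeight;
  ctx.fillStyle = "#111"; ctx.fillRect(0, 0, canvas.width, canvas.height);
  for (const prim of scene.primitives) {{
    ctx.strokeStyle = ctx.fillStyle = rgb(prim.color);
    if (prim.kind === "guide_ring") {{
      ctx.beginPath();
      for (const [i, q] of circle3d(prim.position, prim.size, 64).entries())
        i ? ctx.lineTo(q[0], q[1]) : ctx.moveTo(q[0], q[1]);
      ctx.stroke();
    }} else if (prim.kind === "line_edge" || prim.kind === "bar") {{
      const a = project(prim.position), b = project(prim.end);
      ctx.lineWidth = prim.kind === "bar" ? 3 : 1;
      ctx.beginPath(); ctx.moveTo(a[0], a[1]); ctx.lineTo(b[0], b[1]); ctx.stroke();
      ctx.lineWidth = 1;
    }} else if (prim.kind === "sphere") {{
      const q = project(prim.position);
      ctx.beginPath(); ctx.arc(q[0], q[1], 7*q[2], 0, 2*Math.PI); ctx.fill();
      ctx.strokeStyle = "#000"; ctx.stroke();
    }} else if (prim.kind === "ring_annulus") {{
      ctx.lineWidth = 3;
      ctx.beginPath();
      for (const [i, q] of circle3d(prim.position, prim.size, 32).entries())
        i ? ctx.lineTo(q[0], q[1]) : ctx.moveTo(q[0], q[1]);
      ctx.stroke(); ctx.lineWidth = 1;
    }} else if (prim.kind === "cone") {{
      const a = project(prim.position), b = project(prim.end);
      ctx.globalAlpha = 0.6;
      ctx.beginPath(); ctx.moveTo(a[0]-6, a[1]); ctx.lineTo(a[0]+6, a[1]);
      ctx.lineTo(b[0], b[1]); ctx.closePath(); ctx.fill();
      ctx.globalAlpha = 1;
    }} else if (prim.kind === "text_label") {{
      const q = project(prim.position);
      ctx.font = "11px sans-serif"; ctx.textAlign = "center";
      ctx.fillText(prim.text || "", q[0], q[1]);
    }}
  }}
}}
let dragging = false, px = 0, py = 0;
canvas.addEventListener("mousedown", e => {{ dragging = true; px = e.clientX; py = e.clientY; }});
addEventListener("mouseup", () => dragging = false);
addEventListener("mousemove", e => {{
  if (!dragging) return;
  yaw += (e.clientX - px)*0.01; pitch += (e.clientY - py)*0.01;
  px = e.clientX; py = e.clientY; draw();
}});
canvas.addEventListener("wheel", e => {{ dist *= e.deltaY > 0 ? 1.1 : 0.9; draw(); }});
addEventListener("resize", draw);
draw();
</script></body></html>
"""


def render_html(scene: SceneGraph, path: str | Path, title: str | None = None) -> None:
    """Write a self-contained interactive HTML view (no plugins, no CDN).

    The scene JSON is embedded verbatim in a ``<script type="application/
    json">`` block and drawn by a small canvas renderer with mouse rotate
    and wheel zoom.
    """
    title = title or scene.provenance.get("pathway", "cascade scene")
    html = _HTML_TEMPLATE.format(title=title, scene_json=scene_to_json(scene),
                                 camera_dist=60.0)
    Path(path).write_text(html, encoding="utf-8")


# ---------------------------------------------------------------------------
# raster backend

@dataclass
class Camera:
    elev: float = 35.0
    azim: float = -60.0
    width: float = 8.0    # inches
    height: float = 6.0
    dpi: int = 100


def render_image(scene: SceneGraph, path: str | Path, camera: Camera | None = None) -> None:
    """Rasterize the scene to PNG/JPEG at a fixed camera (matplotlib 3D)."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    camera = camera or Camera()
    fig = plt.figure(figsize=(camera.width, camera.height), dpi=camera.dpi)
    ax = fig.add_subplot(projection="3d")
    ax.view_init(elev=camera.elev, azim=camera.azim)
    ax.set_axis_off()

    def c01(color: RGB) -> tuple[float, float, float]:
        return tuple(ch / 255.0 for ch in color)

    for p in scene.primitives:
        if p.kind == "guide_ring":
            t = [2 * math.pi * i / 128 for i in range(129)]
            ax.plot([p.size * math.cos(a) for a in t],
                    [p.size * math.sin(a) for a in t],
                    [p.position[2]] * len(t), color=c01(p.color), lw=0.8)
        elif p.kind in ("line_edge", "bar"):
            ax.plot([p.position[0], p.end[0]], [p.position[1], p.end[1]],
                    [p.position[2], p.end[2]], color=c01(p.color),
                    lw=2.5 if p.kind == "bar" else 1.0)
        elif p.kind == "sphere":
            ax.scatter([p.position[0]], [p.position[1]], [p.position[2]],
                       s=90, color=c01(p.color), edgecolors="black", depthshade=False)
        elif p.kind == "ring_annulus":
            t = [2 * math.pi * i / 64 for i in range(65)]
            ax.plot([p.position[0] + p.size * math.cos(a) for a in t],
                    [p.position[1] + p.size * math.sin(a) for a in t],
                    [p.position[2]] * len(t), color=c01(p.color), lw=2.0)
        elif p.kind == "cone":
            ax.plot([p.position[0], p.end[0]], [p.position[1], p.end[1]],
                    [p.position[2], p.end[2]], color=c01(p.color), lw=4.0, alpha=0.6)
        elif p.kind == "text_label":
            ax.text(p.position[0], p.position[1], p.position[2], p.text or "",
                    color=c01(p.color), fontsize=7, ha="center")
    if not scene.primitives:
        ax.set_xlim(-1, 1), ax.set_ylim(-1, 1), ax.set_zlim(-1, 1)
    fig.savefig(path, bbox_inches=None)
    plt.close(fig)
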