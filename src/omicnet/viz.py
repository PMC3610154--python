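"""Layouts and static rendering of data-enriched networks.

Node glyphs approximate SBGN: circles for simple chemicals, rounded
rectangles for macromolecules, small squares for processes.  Mapped
measurements are drawn as bar charts inside the glyphs (one bar per
condition, in declared condition order); correlation coefficients are
color-coded on a diverging red-white-blue scale; flux values scale edge
thickness linearly.  Output formats: PNG and SVG (each node's chart is an
SVG group ``chart-<node>``), plus a clickable HTML image map.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
from matplotlib.collections import LineCollection, PolyCollection
from matplotlib.patches import Circle, FancyBboxPatch, Rectangle

from .graph import AttributedGraph, GraphStructureError
from .mapping import mapped_nodes, node_measurements

LAYOUTS = ("force_directed", "circle", "grid", "tree", "pathway_circles")


# ---------------------------------------------------------------------------
# color coding


def color_scale(r: float) -> str:
    """Diverging correlation color: -1 pure red, 0 white, +1 pure blue.

    Clamped at the endpoints; odd-symmetric (the color of -r is the
    red/blue mirror of the color of r).
    """
    r = max(-1.0, min(1.0, float(r)))
    if r >= 0:
        rgb = (1.0 - r, 1.0 - r, 1.0)
    else:
        rgb = (1.0, 1.0 + r, 1.0 + r)
    return "#{:02x}{:02x}{:02x}".format(*(int(round(255 * c)) for c in rgb))


@dataclass
class ChartSpec:
    """What to draw inside node glyphs."""

    kind: str = "bar"                  # bar | pie | line | heatmap
    source: str = "mapping"            # attribute path prefix of the data
    color: str = "#4878a8"

    def __post_init__(self):
        if self.kind not in ("bar", "pie", "line", "heatmap"):
            raise ValueError(f"unknown chart kind {self.kind!r}")


# ---------------------------------------------------------------------------
# layouts


def layout(g: AttributedGraph, algorithm: str = "force_directed",
           seed: int = 0, scale: float = 400.0,
           pathway_attr: str = "pathway") -> AttributedGraph:
    """Assign x/y coordinates to every node (screen convention, y down)."""
    import networkx as nx

    out = g.copy()
    nodes = out.nodes
    if not nodes:
        return out
    if algorithm == "force_directed":
        pos = nx.spring_layout(out.nx, seed=seed, scale=scale / 2)
        pos = {n: (p[0] + scale / 2, p[1] + scale / 2) for n, p in pos.items()}
        _jitter_collisions(pos)
    elif algorithm == "circle":
        pos = _circle_positions(nodes, (scale / 2, scale / 2), scale / 2 * 0.9)
    elif algorithm == "grid":
        cols = max(1, math.ceil(math.sqrt(len(nodes))))
        step = scale / cols
        pos = {n: ((i % cols + 0.5) * step, (i // cols + 0.5) * step)
               for i, n in enumerate(nodes)}
    elif algorithm == "tree":
        pos = _tree_positions(out, scale)
    elif algorithm == "pathway_circles":
        pos = _pathway_circle_positions(out, pathway_attr, scale)
    else:
        raise ValueError(f"unknown layout {algorithm!r} (known: {LAYOUTS})")
    for n, (x, y) in pos.items():
        out.set_position(n, float(x), float(y))
    return out


def _jitter_collisions(pos: dict) -> None:
    seen = {}
    for n in sorted(pos):
        key = (round(pos[n][0], 9), round(pos[n][1], 9))
        if key in seen:
            k = seen[key]
            seen[key] += 1
            pos[n] = (pos[n][0] + 1e-3 * k, pos[n][1] + 1e-3 * k)
        else:
            seen[key] = 1


def _circle_positions(nodes, center, radius) -> dict:
    cx, cy = center
    n = len(nodes)
    return {node: (cx + radius * math.cos(2 * math.pi * i / n),
                   cy + radius * math.sin(2 * math.pi * i / n))
            for i, node in enumerate(nodes)}


def _tree_positions(g: AttributedGraph, scale: float) -> dict:
    import networkx as nx

    h = nx.DiGraph(g.nx)
    if not nx.is_directed_acyclic_graph(h):
        raise GraphStructureError("tree layout requires an acyclic graph when rooted")
    roots = [n for n in h if h.in_degree(n) == 0] or list(h.nodes)[:1]
    depth = {}
    for r in roots:
        for n, d in nx.single_source_shortest_path_length(h, r).items():
            depth[n] = min(depth.get(n, d), d)
    for n in h:
        depth.setdefault(n, 0)
    levels: dict[int, list] = {}
    for n in g.nodes:
        levels.setdefault(depth[n], []).append(n)
    max_d = max(levels)
    pos = {}
    for d, members in levels.items():
        y = (d + 0.5) / (max_d + 1) * scale
        for i, n in enumerate(members):
            pos[n] = ((i + 0.5) / len(members) * scale, y)
    return pos


def _pathway_circle_positions(g: AttributedGraph, attr: str, scale: float) -> dict:
    groups: dict[str, list] = {}
    for n in g.nodes:
        groups.setdefault(str(g.get_attr("node", n, attr, "unassigned")), []).append(n)
    names = sorted(groups)
    k = len(names)
    ring_r = scale / 2 * 0.9 if k > 1 else 0.0
    sub_r = scale / (2.5 * max(k, 1)) + scale * 0.05
    pos = {}
    for gi, name in enumerate(names):
        cx = scale / 2 + ring_r * math.cos(2 * math.pi * gi / k) if k > 1 else scale / 2
        cy = scale / 2 + ring_r * math.sin(2 * math.pi * gi / k) if k > 1 else scale / 2
        pos.update(_circle_positions(groups[name], (cx, cy), sub_r))
    return pos


# ---------------------------------------------------------------------------
# rendering


@dataclass
class RenderResult:
    path: Path
    node_bounds: dict[str, tuple[float, float, float, float]]  # px, origin top-left
    width_px: int
    height_px: int


def _flux_widths(g: AttributedGraph, attr: str, t_min=0.8, t_max=6.0) -> dict:
    vals = {}
    for e in g.edges:
        v = g.get_attr("edge", e, attr)
        if isinstance(v, (int, float)):
            vals[e] = abs(float(v))
    vmax = max(vals.values(), default=0.0)
    widths = {}
    for e in g.edges:
        if vmax > 0 and e in vals:
            widths[e] = t_min + (t_max - t_min) * vals[e] / vmax
        else:
            widths[e] = t_min
    return widths


def render(
    g: AttributedGraph,
    charts: ChartSpec | None = None,
    out: str | Path = "network.svg",
    format: str | None = None,
    flux_attr: str | None = None,
    dpi: int = 100,
) -> RenderResult:
    """Draw the network to PNG or SVG; the graph itself is left unchanged.

    Requires coordinates; nodes without any fall back to an automatic
    force-directed layout (with a warning).  When ``charts`` is given,
    every mapped node gets an embedded chart of its measurements grouped
    by condition.
    """
    out = Path(out)
    fmt = (format or out.suffix.lstrip(".")).lower()
    if fmt not in ("png", "svg"):
        raise ValueError(f"unsupported image format {fmt!r}")
    if not any(("graphics.x" in g.attrs("node", n)) for n in g.nodes):
        import logging
        logging.getLogger(__name__).warning("render: no layout present, "
                                            "applying force-directed fallback")
        g = layout(g, "force_directed")

    xs = [g.position(n)[0] for n in g.nodes] or [0.0]
    ys = [g.position(n)[1] for n in g.nodes] or [0.0]
    margin = 60.0
    x0, x1 = min(xs) - margin, max(xs) + margin
    y0, y1 = min(ys) - margin, max(ys) + margin
    fig_w, fig_h = (x1 - x0) / dpi, (y1 - y0) / dpi
    fig = plt.figure(figsize=(fig_w, fig_h), dpi=dpi)
    ax = fig.add_axes([0, 0, 1, 1])
    ax.set_xlim(x0, x1)
    ax.set_ylim(y1, y0)  # y grows downward (screen convention)
    ax.axis("off")

    widths = _flux_widths(g, flux_attr) if flux_attr else None
    for e in g.edges:
        (ux, uy), (vx, vy) = g.position(e[0]), g.position(e[1])
        lw = widths[e] if widths else float(g.get_attr("edge", e, "thickness", 1.0))
        color = str(g.get_attr("edge", e, "color", "#606060"))
        ax.plot([ux, vx], [uy, vy], color=color, linewidth=lw, zorder=1)

    cond_order = [c for c in str(g.graph_attrs.get("mapping_conditions", "")).split("|") if c]
    bounds = {}
    for n in g.nodes:
        x, y = g.position(n)
        w, h = g.size(n)
        fill = str(g.get_attr("node", n, "graphics.fill", "#e8e8e8"))
        frame = str(g.get_attr("node", n, "graphics.frame", "#303030"))
        cls = g.sbgn_class(n)
        if cls == "simple_chemical":
            patch = Circle((x, y), radius=max(w, h) / 2, facecolor=fill,
                           edgecolor=frame, zorder=2)
        elif cls == "process":
            s = min(w, h) / 2
            patch = Rectangle((x - s / 2, y - s / 2), s, s, facecolor=fill,
                              edgecolor=frame, zorder=2)
        else:
            patch = FancyBboxPatch((x - w / 2, y - h / 2), w, h,
                                   boxstyle="round,pad=0,rounding_size=4",
                                   facecolor=fill, edgecolor=frame, zorder=2)
        ax.add_patch(patch)
        ax.text(x, y + h / 2 + 9, g.label(n), ha="center", va="top",
                fontsize=6, zorder=4)
        if charts is not None:
            _draw_chart(ax, g, n, x, y, w, h, charts, cond_order)
        bounds[n] = (x - w / 2, y - h / 2, x + w / 2, y + h / 2)

    fig.savefig(out, format=fmt, dpi=dpi)
    plt.close(fig)

    # pixel-space bounds for the HTML image map (origin top-left)
    px = {}
    for n, (bx0, by0, bx1, by1) in bounds.items():
        px[n] = (bx0 - x0, by0 - y0, bx1 - x0, by1 - y0)
    return RenderResult(out, px, int(round(x1 - x0)), int(round(y1 - y0)))


def _draw_chart(ax, g, n, x, y, w, h, charts: ChartSpec, cond_order) -> None:
    m = node_measurements(g, n)
    if m.empty:
        return
    means = m.groupby("condition")["value"].mean()
    order = [c for c in cond_order if c in means.index] or sorted(means.index)
    vals = np.array([means[c] for c in order], dtype=float)
    vmax = np.nanmax(np.abs(vals)) or 1.0
    cw, ch = w * 0.8, h * 0.6
    bx0, by0 = x - cw / 2, y + ch / 2  # chart baseline (y down)
    k = len(vals)
    bw = cw / max(k, 1)
    if charts.kind == "line":
        pts = [(bx0 + (i + 0.5) * bw, by0 - ch * (v / vmax)) for i, v in enumerate(vals)]
        coll = LineCollection([pts], colors=charts.color, linewidths=1.2, zorder=3)
    elif charts.kind == "pie":
        total = np.abs(vals).sum() or 1.0
        polys, a = [], 0.0
        for v in vals:
            frac = abs(v) / total
            arc = np.linspace(a, a + 2 * math.pi * frac, max(3, int(24 * frac) + 2))
            fan = [(x, y)] + [(x + cw / 2 * math.cos(t), y + cw / 2 * math.sin(t))
                              for t in arc]
            polys.append(fan)
            a += 2 * math.pi * frac
        coll = PolyCollection(polys, facecolors=[
            plt.cm.tab20(i % 20) for i in range(k)], edgecolors="white",
            linewidths=0.3, zorder=3)
    elif charts.kind == "heatmap":
        polys = [[(bx0 + i * bw, y - ch / 2), (bx0 + (i + 1) * bw, y - ch / 2),
                  (bx0 + (i + 1) * bw, y + ch / 2), (bx0 + i * bw, y + ch / 2)]
                 for i in range(k)]
        coll = PolyCollection(polys, facecolors=[
            color_scale(v / vmax) for v in vals], edgecolors="none", zorder=3)
    else:  # bar
        polys = []
        for i, v in enumerate(vals):
            bh = ch * (v / vmax)
            polys.append([(bx0 + i * bw, by0), (bx0 + (i + 0.9) * bw, by0),
                          (bx0 + (i + 0.9) * bw, by0 - bh), (bx0 + i * bw, by0 - bh)])
        coll = PolyCollection(polys, facecolors=charts.color, edgecolors="none", zorder=3)
    coll.set_gid(f"chart-{n}")
    ax.add_collection(coll)


# ---------------------------------------------------------------------------
# HTML export


def export_html(
    g: AttributedGraph,
    out_dir: str | Path,
    title: str = "omicnet network",
    charts: ChartSpec | None = None,
) -> Path:
    """Browsable page: rendered PNG plus a client-side image map.

    One clickable region per node; nodes carrying a ``url`` attribute get
    a hyperlink, the rest a tooltip with the node label.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rr = render(g, charts=charts, out=out_dir / "network.png", format="png")
    areas = []
    for n in g.nodes:
        x0, y0, x1, y1 = (int(round(v)) for v in rr.node_bounds[n])
        url = g.get_attr("node", n, "url")
        href = f' href="{url}"' if url else ""
        areas.append(f'    <area shape="rect" coords="{x0},{y0},{x1},{y1}"'
                     f'{href} title="{g.label(n)}" alt="{g.label(n)}">')
    html = (
        "<!DOCTYPE html>\n<html>\n<head><meta charset=\"utf-8\">"
        f"<title>{title}</title></head>\n<body>\n"
        f"  <h1>{title}</h1>\n"
        "  <img src=\"network.png\" usemap=\"#netmap\" "
        f"width=\"{rr.width_px}\" height=\"{rr.height_px}\">\n"
        "  <map name=\"netmap\">\n" + "\n".join(areas) + "\n  </map>\n"
        "</body>\n</html>\n"
    )
    path = out_dir / "index.html"
    path.write_text(html)
    return path
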