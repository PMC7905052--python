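"""Self-contained HTML merge report with a static circular DAG.

The report shows the merge statistics table, a donut of the name- vs
structure-matched shares, and a circular layout of the merged DAG.  Colour
code: orange nodes are unmatched contributions from ontology A, blue from
ontology B; green and red nodes carry name and structure matches,
respectively.  Labels appear as native hover titles on the SVG nodes.
Every number printed in the report comes from the stats dictionary.
"""

from __future__ import annotations

import html
import math

from .align import Alignment, NAME, STRUCTURE
from .merge import MergeResult

COLORS = {
    "A": "#e67e22",        # unmatched from A: orange
    "B": "#2980b9",        # unmatched from B: blue
    "name": "#27ae60",     # name match: green
    "structure": "#c0392b",  # structure match: red
}

DEFAULT_NODE_CAP = 2000


def _node_colors(res: MergeResult, al: Alignment) -> dict[str, str]:
    match_type: dict[str, str] = {}
    for rec in al.records:
        if rec.match_type == NAME:
            match_type[rec.native_id] = "name"
        elif rec.match_type == STRUCTURE:
            match_type[rec.native_id] = "structure"
    colors = {}
    for cid, src in res.provenance.items():
        if cid in match_type:
            colors[cid] = COLORS[match_type[cid]]
        elif src == "B":
            colors[cid] = COLORS["B"]
        else:
            colors[cid] = COLORS["A"]
    return colors


def _donut_svg(name_pct: float, struct_pct: float, size: int = 180) -> str:
    """Two-segment donut of the match-type shares (percent of matches)."""
    cx = cy = size / 2
    r, width = size / 2 - 12, 22

    def arc(start_frac: float, end_frac: float, color: str) -> str:
        if end_frac - start_frac <= 0:
            return ""
        if end_frac - start_frac >= 0.999:
            return (f'<circle cx="{cx}" cy="{cy}" r="{r}" fill="none" '
                    f'stroke="{color}" stroke-width="{width}"/>')
        a0 = 2 * math.pi * start_frac - math.pi / 2
        a1 = 2 * math.pi * end_frac - math.pi / 2
        x0, y0 = cx + r * math.cos(a0), cy + r * math.sin(a0)
        x1, y1 = cx + r * math.cos(a1), cy + r * math.sin(a1)
        large = 1 if end_frac - start_frac > 0.5 else 0
        return (f'<path d="M {x0:.2f} {y0:.2f} A {r} {r} 0 {large} 1 '
                f'{x1:.2f} {y1:.2f}" fill="none" stroke="{color}" '
                f'stroke-width="{width}"/>')

    total = name_pct + struct_pct
    nf = name_pct / 100.0 if total else 0.0
    sf = struct_pct / 100.0 if total else 0.0
    parts = [f'<svg width="{size}" height="{size}" class="donut">',
             arc(0.0, nf, COLORS["name"]),
             arc(nf, nf + sf, COLORS["structure"]),
             "</svg>"]
    return "".join(parts)


def _dag_svg(res: MergeResult, al: Alignment, size: int = 720,
             node_cap: int = DEFAULT_NODE_CAP) -> str:
    merged = res.merged
    ids = merged.class_ids
    if len(ids) > node_cap:
        return (f'<p class="notice">Graph with {len(ids)} classes exceeds '
                f'the rendering cap of {node_cap}; summary only.</p>')
    colors = _node_colors(res, al)
    cx = cy = size / 2
    r = size / 2 - 20
    pos = {}
    n = max(len(ids), 1)
    for k, cid in enumerate(ids):
        a = 2 * math.pi * k / n - math.pi / 2
        pos[cid] = (cx + r * math.cos(a), cy + r * math.sin(a))
    parts = [f'<svg width="{size}" height="{size}" class="dag">']
    for p, c in merged.edges:
        (x0, y0), (x1, y1) = pos[p], pos[c]
        parts.append(f'<path d="M {x0:.1f} {y0:.1f} Q {cx:.1f} {cy:.1f} '
                     f'{x1:.1f} {y1:.1f}" fill="none" stroke="#999" '
                     f'stroke-opacity="0.25" stroke-width="0.7"/>')
    for cid in ids:
        x, y = pos[cid]
        label = html.escape(merged.get(cid).label)
        parts.append(f'<circle cx="{x:.1f}" cy="{y:.1f}" r="3.2" '
                     f'fill="{colors[cid]}"><title>{label}</title></circle>')
    parts.append("</svg>")
    return "".join(parts)


def render_report(res: MergeResult, al: Alignment, stats: dict, path: str,
                  node_cap: int = DEFAULT_NODE_CAP) -> None:
    """Write the self-contained HTML merge report to ``path``."""
    rows = "".join(
        f"<tr><td>{html.escape(str(k))}</td><td>{v}</td></tr>"
        for k, v in stats.items())
    legend = "".join(
        f'<span class="chip" style="background:{color}"></span>{text} '
        for color, text in (
            (COLORS["name"], "name match"),
            (COLORS["structure"], "structure match"),
            (COLORS["A"], "unmatched from A"),
            (COLORS["B"], "added from B"),
        ))
    doc = f"""<!DOCTYPE html>
<html lang="en"><head><meta charset="utf-8">
<title>Ontology fusion report</title>
<style>
body {{ font-family: sans-serif; margin: 2em; color: #222; }}
table {{ border-collapse: collapse; }}
td {{ border: 1px solid #ccc; padding: 4px 10px; }}
.chip {{ display:inline-block; width:0.9em; height:0.9em;
        margin:0 0.3em 0 0.8em; border-radius:50%; }}
.notice {{ color: #a33; }}
</style></head><body>
<h1>Ontology fusion report</h1>
<h2>Merge statistics</h2>
<table>{rows}</table>
<h2>Match breakdown</h2>
<p>Name matches: {stats["name_match_pct"]}% &mdash; structure matches:
{stats["structure_match_pct"]}% of all matched classes.</p>
{_donut_svg(stats["name_match_pct"], stats["structure_match_pct"])}
<h2>Merged ontology (circular DAG)</h2>
<p>{legend}</p>
{_dag_svg(res, al, node_cap=node_cap)}
</body></html>
"""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(doc)
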