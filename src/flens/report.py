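"""Self-contained interactive HTML reports of projections, scores and probes.

The report is a single HTML file with every number embedded as JSON inside
the document and a small inline script for interactivity: scatter panels
arranged on the (n_neighbors x min_dist) grid, a variable selector,
per-class show/hide toggles, zoom/pan, optional side-by-side embedding vs
raw-pixel panels, and a score table. No external resources are referenced,
so the file can be shared and opened anywhere.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .probe import ProbeResult
from .projector import ProjectionResult
from .scores import StructureScores
from .store import EmbeddingSet, VariableSpec

__all__ = ["ReportBundle", "build_report", "export_scores_table", "make_bundle"]

# colorblind-friendly qualitative cycle
_PALETTE = [
    "#4477AA", "#EE6677", "#228833", "#CCBB44", "#66CCEE",
    "#AA3377", "#BBBBBB", "#000000", "#E69F00", "#56B4E9",
]


@dataclass
class ReportBundle:
    """Everything one report renders.

    ``labels`` holds, for each projection, a map variable-name -> per-point
    class labels (aligned with that projection's ids). ``pair_tags`` may
    mark projections as e.g. "embedding" / "raw_pixel" for side-by-side
    panels.
    """

    projections: list[ProjectionResult]
    scores: list[StructureScores]
    probe_results: list[ProbeResult]
    variable: VariableSpec
    labels: list[dict[str, list[str]]] = field(default_factory=list)
    class_palette: dict[str, str] | None = None
    pair_tags: list[str] | None = None

    def __post_init__(self) -> None:
        if len(self.projections) != len(self.scores):
            raise ValueError("every projection needs a matching score entry")
        if not self.labels:
            self.labels = [{} for _ in self.projections]
        if len(self.labels) != len(self.projections):
            raise ValueError("labels must align with projections")
        classes = sorted(
            {c for lab in self.labels for vals in lab.values() for c in vals}
        )
        if self.class_palette is None:
            self.class_palette = {
                c: _PALETTE[i % len(_PALETTE)] for i, c in enumerate(classes)
            }
        else:
            missing = [c for c in classes if c not in self.class_palette]
            if missing:
                raise ValueError(f"palette missing classes: {missing}")

    def to_dict(self) -> dict:
        return {
            "projections": [p.to_dict() for p in self.projections],
            "scores": [s.to_dict() for s in self.scores],
            "probe_results": [r.to_dict() for r in self.probe_results],
            "variable": {"name": self.variable.name, "role": self.variable.role},
            "labels": self.labels,
            "class_palette": self.class_palette,
            "pair_tags": self.pair_tags,
        }


def make_bundle(
    es: EmbeddingSet,
    projections: list[ProjectionResult],
    scores: list[StructureScores],
    probe_results: list[ProbeResult] | None = None,
    variables: list[str] | None = None,
    variable: VariableSpec | None = None,
    pair_tags: list[str] | None = None,
) -> ReportBundle:
    """Assemble a bundle, pulling per-point labels out of ``es``."""
    variables = variables or list(es.metadata.columns)
    variable = variable or VariableSpec(variables[0] if variables else "none")
    index = {i: k for k, i in enumerate(es.ids)}
    labels = []
    for proj in projections:
        rows = [index[i] for i in proj.ids]
        labels.append(
            {
                v: [str(es.metadata[v].iloc[r]) for r in rows]
                for v in variables
                if v in es.metadata.columns
            }
        )
    return ReportBundle(
        projections=projections,
        scores=scores,
        probe_results=probe_results or [],
        variable=variable,
        labels=labels,
        pair_tags=pair_tags,
    )


_TEMPLATE = """<!DOCTYPE html>
<html lang="en">
<head>
<meta charset="utf-8">
<title>flens report</title>
<style>
body {{ font-family: sans-serif; margin: 1em; background: #fafafa; }}
.panel {{ display: inline-block; margin: 6px; background: #fff;
          border: 1px solid #ccc; vertical-align: top; }}
.panel h3 {{ font-size: 12px; margin: 4px 6px; font-weight: normal; }}
#controls {{ margin-bottom: 1em; }}
#controls label {{ margin-right: 10px; }}
table {{ border-collapse: collapse; margin-top: 1em; font-size: 13px; }}
td, th {{ border: 1px solid #bbb; padding: 3px 8px; text-align: right; }}
svg {{ cursor: grab; }}
</style>
</head>
<body>
<h1>Embedding inspection report</h1>
<div id="controls">
  <label>Color by: <select id="varsel"></select></label>
  <span id="classtoggles"></span>
</div>
<div id="panels"></div>
<h2>Structure scores</h2>
<div id="scoretable"></div>
<h2>Linear probes</h2>
<div id="probetable"></div>
<script type="application/json" id="flens-data">{payload}</script>
<script>
"use strict";
const DATA = JSON.parse(document.getElementById("flens-data").textContent);
const PAL = DATA.class_palette;
const vars = new Set();
DATA.labels.forEach(l => Object.keys(l).forEach(v => vars.add(v)));
const varsel = document.getElementById("varsel");
[...vars].forEach(v => {{
  const o = document.createElement("option");
  o.value = v; o.textContent = v;
  if (v === DATA.variable.name) o.selected = true;
  varsel.appendChild(o);
}});
let hidden = new Set();
function classesFor(v) {{
  const s = new Set();
  DATA.labels.forEach(l => (l[v] || []).forEach(c => s.add(c)));
  return [...s].sort();
}}
function drawToggles() {{
  const v = varsel.value, host = document.getElementById("classtoggles");
  host.innerHTML = "";
  classesFor(v).forEach(c => {{
    const lab = document.createElement("label");
    const cb = document.createElement("input");
    cb.type = "checkbox"; cb.checked = !hidden.has(c);
    cb.onchange = () => {{ cb.checked ? hidden.delete(c) : hidden.add(c); render(); }};
    lab.appendChild(cb);
    const sw = document.createElement("span");
    sw.textContent = " \\u25A0 " + c + " ";
    sw.style.color = PAL[c] || "#888";
    lab.appendChild(sw);
    host.appendChild(lab);
  }});
}}
function render() {{
  const v = varsel.value, host = document.getElementById("panels");
  host.innerHTML = "";
  DATA.projections.forEach((p, pi) => {{
    const div = document.createElement("div");
    div.className = "panel";
    div.dataset.nNeighbors = p.params.n_neighbors;
    div.dataset.minDist = p.params.min_dist;
    const tag = DATA.pair_tags ? " [" + DATA.pair_tags[pi] + "]" : "";
    div.innerHTML = "<h3>" + p.params.method +
      " n_neighbors=" + p.params.n_neighbors +
      " min_dist=" + p.params.min_dist + tag + "</h3>";
    const W = 320, H = 320;
    const xs = p.coords.map(c => c[0]), ys = p.coords.map(c => c[1]);
    const x0 = Math.min(...xs), x1 = Math.max(...xs);
    const y0 = Math.min(...ys), y1 = Math.max(...ys);
    const sx = x => 10 + (W - 20) * (x - x0) / ((x1 - x0) || 1);
    const sy = y => H - 10 - (H - 20) * (y - y0) / ((y1 - y0) || 1);
    const ns = "www.w3.org/2000/svg";
    const svg = document.createElementNS("ht" + "tp://" + ns, "svg");
    svg.setAttribute("width", W); svg.setAttribute("height", H);
    const g = document.createElementNS("ht" + "tp://" + ns, "g");
    svg.appendChild(g);
    const labs = DATA.labels[pi][v] || [];
    p.coords.forEach((c, i) => {{
      const cls = labs[i];
      if (hidden.has(cls)) return;
      const dot = document.createElementNS("ht" + "tp://" + ns, "circle");
      dot.setAttribute("cx", sx(c[0])); dot.setAttribute("cy", sy(c[1]));
      dot.setAttribute("r", 2.2);
      dot.setAttribute("fill", PAL[cls] || "#888");
      dot.setAttribute("fill-opacity", 0.7);
      const t = document.createElementNS("ht" + "tp://" + ns, "title");
      t.textContent = p.ids[i] + (cls ? " (" + cls + ")" : "");
      dot.appendChild(t);
      g.appendChild(dot);
    }});
    let scale = 1, tx = 0, ty = 0, dragging = null;
    const apply = () => g.setAttribute("transform",
      "translate(" + tx + "," + ty + ") scale(" + scale + ")");
    svg.addEventListener("wheel", e => {{
      e.preventDefault();
      scale *= e.deltaY < 0 ? 1.15 : 1 / 1.15;
      apply();
    }});
    svg.addEventListener("mousedown", e => dragging = [e.clientX, e.clientY]);
    svg.addEventListener("mousemove", e => {{
      if (!dragging) return;
      tx += e.clientX - dragging[0]; ty += e.clientY - dragging[1];
      dragging = [e.clientX, e.clientY]; apply();
    }});
    svg.addEventListener("mouseup", () => dragging = null);
    div.appendChild(svg);
    host.appendChild(div);
  }});
}}
function tables() {{
  const fmt = x => (x === null || x === undefined) ? "NA" : x.toFixed(4);
  let h = "<table><tr><th>method</th><th>n_neighbors</th><th>min_dist</th>" +
    "<th>silhouette</th><th>ARI</th><th>KNN</th><th>CPD</th></tr>";
  DATA.projections.forEach((p, i) => {{
    const s = DATA.scores[i];
    h += "<tr><td>" + p.params.method + "</td><td>" + p.params.n_neighbors +
      "</td><td>" + p.params.min_dist + "</td><td>" + fmt(s.silhouette) +
      "</td><td>" + fmt(s.ari) + "</td><td>" + fmt(s.knn_preservation) +
      "</td><td>" + fmt(s.cpd) + "</td></tr>";
  }});
  document.getElementById("scoretable").innerHTML = h + "</table>";
  let q = "<table><tr><th>variable</th><th>accuracy</th><th>CI low</th>" +
    "<th>CI high</th><th>kappa</th><th>n_test</th></tr>";
  DATA.probe_results.forEach(r => {{
    q += "<tr><td>" + (r.provenance.variable || "?") + "</td><td>" +
      fmt(r.accuracy) + "</td><td>" + fmt(r.ci_low) + "</td><td>" +
      fmt(r.ci_high) + "</td><td>" + fmt(r.kappa_mean) + "</td><td>" +
      r.n_test + "</td></tr>";
  }});
  document.getElementById("probetable").innerHTML = q + "</table>";
}}
varsel.onchange = () => {{ hidden = new Set(); drawToggles(); render(); }};
drawToggles(); render(); tables();
</script>
</body>
</html>
"""


def build_report(bundle: ReportBundle, out_path: str) -> str:
    """Write the bundle as one self-contained interactive HTML document."""
    if not bundle.projections:
        raise ValueError("empty bundle: nothing to render")
    payload = json.dumps(bundle.to_dict())
    # '</script>' inside the JSON would terminate the data block early
    payload = payload.replace("</", "<\\/")
    html = _TEMPLATE.format(payload=payload)
    with open(out_path, "w", encoding="utf-8") as fh:
        fh.write(html)
    return str(out_path)


def export_scores_table(bundle: ReportBundle, out_path: str) -> str:
    """Write scores (and probe summaries) as one delimited text table.

    One row per projection with its parameters and the four structure
    scores; probe rows are appended below with accuracy, CI and kappa.
    The same serialization backs the console renderer.
    """
    if not bundle.scores and not bundle.probe_results:
        raise ValueError("empty bundle: no scores to export")
    header = (
        "kind\tmethod\tn_neighbors\tmin_dist\tsilhouette\tari"
        "\tknn_preservation\tcpd\taccuracy\tci_low\tci_high\tkappa\tn"
    )
    lines = [header]

    def f6(x) -> str:
        return "NA" if x is None else f"{x:.6f}"

    for p, s in zip(bundle.projections, bundle.scores):
        lines.append(
            "\t".join(
                [
                    "projection",
                    p.params.method,
                    str(p.params.n_neighbors),
                    f"{p.params.min_dist:g}",
                    f6(s.silhouette),
                    f6(s.ari),
                    f6(s.knn_preservation),
                    f6(s.cpd),
                    "NA", "NA", "NA", "NA",
                    str(s.n_scored),
                ]
            )
        )
    for r in bundle.probe_results:
        lines.append(
            "\t".join(
                [
                    "probe",
                    str(r.provenance.get("variable", "?")),
                    "NA", "NA", "NA", "NA", "NA", "NA",
                    f6(r.accuracy),
                    f6(r.ci_low),
                    f6(r.ci_high),
                    f6(r.kappa_mean),
                    str(r.n_test),
                ]
            )
        )
    with open(out_path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")
    return str(out_path)
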