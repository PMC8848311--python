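"""Interactive exploration plot data: scatter, sunburst, world map.

The three builders aggregate six-rank taxonomy paths (and geographic
references) into plot datasets; :func:`export_html` writes each dataset as
a self-contained HTML file that renders offline with inline JavaScript/SVG
and embeds the full dataset as JSON, so the counts remain machine-
recoverable from the exported file (see :func:`extract_embedded_data`).

A frequency filter can be applied before plotting: taxonomic units (species
level) whose record count falls below the chosen threshold are moved to an
overflow TSV whose filename embeds the threshold; a threshold of 0 keeps
all data and writes nothing.
"""

from __future__ import annotations

import csv
import html
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .errors import TaxonomyFileError
from .records import GeoKind, GeoRef
from .taxonomy import MAIN_RANKS, LineagePath

logger = logging.getLogger(__name__)

OVERFLOW_PATTERN = "filtered_out_min{threshold}.tsv"

#: Marker styling carried as plot-data metadata: sampling coordinates render
#: as green crosses, bare country names as red circles.
COORD_MARKER = {"symbol": "cross", "color": "green"}
COUNTRY_MARKER = {"symbol": "circle", "color": "red"}


def _as_ranks(path) -> tuple[str, ...]:
    if isinstance(path, LineagePath):
        return path.ranks()
    ranks = tuple(path)
    if len(ranks) != 6:
        raise ValueError(f"expected a 6-rank path, got {len(ranks)} fields")
    return ranks


def load_taxonomy_file(path: str | Path) -> list[LineagePath]:
    """Read six-rank taxonomy paths from a TSV/CSV list file.

    Accepts the database module's two-column output (accession, path) as
    well as headerless single-column files of ``;``-joined paths; the path
    is taken from the last column containing a ``;``, or the sole column.
    Short paths are right-padded by repeating the last available name;
    rows flagged unresolved are skipped with a warning.  A row whose path
    has more than six fields is a parse error naming the line.
    """
    path = Path(path)
    delim = "," if path.suffix.lower() == ".csv" else "\t"
    out: list[LineagePath] = []
    skipped = 0
    with open(path, newline="", encoding="utf-8") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter=delim), start=1):
            if not row or not any(cell.strip() for cell in row):
                continue
            cell = None
            for candidate in reversed(row):
                if ";" in candidate:
                    cell = candidate.strip()
                    break
            if cell is None:
                cell = row[-1].strip() if len(row) == 1 else row[1].strip()
            if cell.lower() == "unresolved":
                skipped += 1
                continue
            fields = [f.strip() for f in cell.split(";")]
            if len(fields) > 6:
                raise TaxonomyFileError(path, lineno,
                                        f"taxonomy path has {len(fields)} fields (max 6)")
            while len(fields) < 6:
                fields.append(fields[-1])
            out.append(LineagePath(0, *fields, source_rank=""))
    if skipped:
        logger.warning("skipped %d unresolved rows in %s", skipped, path)
    return out


@dataclass
class FilterResult:
    """Partition of input paths by the species-level frequency threshold."""

    kept: list[LineagePath]
    discarded: list[tuple[str, int]]
    threshold: int
    overflow_file: Path | None


def apply_filter(paths: Sequence[LineagePath], threshold: int,
                 workdir: str | Path) -> FilterResult:
    """Drop species whose record count is below ``threshold``.

    Counts are taken at the terminal (species) level and removal propagates
    upward, since dropping the paths removes their contribution at every
    rank.  Discarded units are written to
    ``filtered_out_min{threshold}.tsv`` under ``workdir``.  Threshold 0 is
    the identity: everything kept, no overflow file.
    """
    if threshold < 0:
        raise ValueError(f"threshold must be >= 0, got {threshold}")
    paths = list(paths)
    if threshold == 0:
        return FilterResult(paths, [], 0, None)
    counts: dict[str, int] = {}
    for p in paths:
        species = _as_ranks(p)[5]
        counts[species] = counts.get(species, 0) + 1
    low = {s for s, c in counts.items() if c < threshold}
    kept = [p for p in paths if _as_ranks(p)[5] not in low]
    discarded = sorted(((s, counts[s]) for s in low), key=lambda e: (-e[1], e[0]))
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    overflow = workdir / OVERFLOW_PATTERN.format(threshold=threshold)
    with open(overflow, "w", encoding="utf-8") as fh:
        for unit, count in discarded:
            fh.write(f"{unit}\t{count}\n")
    return FilterResult(kept, discarded, threshold, overflow)


@dataclass(frozen=True)
class ScatterPoint:
    taxon: str
    count: int
    parent: str


@dataclass
class ScatterData:
    """Per-rank count series; at every rank the counts sum to the corpus size."""

    series: dict[str, list[ScatterPoint]]
    n_paths: int

    def to_payload(self) -> dict:
        return {
            "kind": "scatter",
            "n_paths": self.n_paths,
            "ranks": {
                rank: [{"taxon": p.taxon, "count": p.count, "parent": p.parent}
                       for p in pts]
                for rank, pts in self.series.items()
            },
        }


def build_scatter(paths: Sequence[LineagePath]) -> ScatterData:
    """Count taxa at each of the six ranks, annotated with the parent taxon.

    Same-named taxa under different parents are kept as separate points, so
    each rank's counts always sum to the number of input paths.  Points are
    ordered by count descending, ties lexicographic.
    """
    series: dict[str, list[ScatterPoint]] = {}
    for level, rank in enumerate(MAIN_RANKS):
        counts: dict[tuple[str, str], int] = {}
        for p in paths:
            ranks = _as_ranks(p)
            parent = ranks[level - 1] if level > 0 else ""
            key = (ranks[level], parent)
            counts[key] = counts.get(key, 0) + 1
        pts = sorted(
            (ScatterPoint(taxon, c, parent) for (taxon, parent), c in counts.items()),
            key=lambda p: (-p.count, p.taxon, p.parent),
        )
        series[rank] = pts
    return ScatterData(series, len(paths))


@dataclass(frozen=True)
class SunburstNode:
    id: str
    label: str
    parent_id: str
    level: int  # 1..6 = phylum..species
    count: int


@dataclass
class TaxonCountTree:
    """Hierarchical taxon counts: each internal node's count equals the sum
    of its children; node ids are full path prefixes, so a genus name that
    occurs under two families yields two distinct nodes."""

    nodes: dict[str, SunburstNode]
    total: int

    def children(self, node_id: str) -> list[SunburstNode]:
        return [n for n in self.nodes.values() if n.parent_id == node_id and n.id != node_id]

    def roots(self) -> list[SunburstNode]:
        return [n for n in self.nodes.values() if n.parent_id == ""]

    def to_payload(self) -> dict:
        return {
            "kind": "sunburst",
            "total": self.total,
            "nodes": [
                {"id": n.id, "label": n.label, "parent": n.parent_id,
                 "level": n.level, "count": n.count}
                for n in self.nodes.values()
            ],
        }


def build_sunburst(paths: Sequence[LineagePath]) -> TaxonCountTree:
    """Aggregate paths into the nested-ring taxonomy hierarchy."""
    nodes: dict[str, SunburstNode] = {}
    counts: dict[str, int] = {}
    meta: dict[str, tuple[str, str, int]] = {}
    for p in paths:
        ranks = _as_ranks(p)
        parent_id = ""
        for level, name in enumerate(ranks, start=1):
            node_id = "|".join(ranks[:level])
            counts[node_id] = counts.get(node_id, 0) + 1
            meta[node_id] = (name, parent_id, level)
            parent_id = node_id
    for node_id, (label, parent_id, level) in meta.items():
        nodes[node_id] = SunburstNode(node_id, label, parent_id, level,
                                      counts[node_id])
    return TaxonCountTree(nodes, len(paths))


@dataclass(frozen=True)
class CoordinatePoint:
    lat: float
    lon: float
    label: str
    count: int


@dataclass(frozen=True)
class CountryPoint:
    country_name: str
    label: str
    count: int


@dataclass
class GeoArrays:
    """The world-map split: resolved coordinates vs bare country names."""

    coordinate_points: list[CoordinatePoint] = field(default_factory=list)
    country_points: list[CountryPoint] = field(default_factory=list)
    n_unlocated: int = 0

    def to_payload(self) -> dict:
        return {
            "kind": "worldmap",
            "n_unlocated": self.n_unlocated,
            "coordinate_marker": COORD_MARKER,
            "country_marker": COUNTRY_MARKER,
            "coordinates": [
                {"lat": p.lat, "lon": p.lon, "label": p.label, "count": p.count}
                for p in self.coordinate_points
            ],
            "countries": [
                {"country": p.country_name, "label": p.label, "count": p.count}
                for p in self.country_points
            ],
        }


def _summarize(labels: list[str], count: int) -> str:
    uniq: list[str] = []
    for lab in labels:
        if lab and lab not in uniq:
            uniq.append(lab)
    body = "; ".join(uniq) if uniq else "n/a"
    return f"{body} ({count} records)"


def build_worldmap(georefs: Sequence[GeoRef],
                   labels: Sequence[str] | None = None) -> GeoArrays:
    """Aggregate geographic references into the two world-map arrays.

    Coordinate-kind references aggregate on (lat, lon) rounded to 4 decimal
    places (merging trivially different encodings of one site); country-kind
    on the country name.  Each point carries a legend label concatenating
    the distinct record labels (taxa/genes) plus the record count.  Records
    of kind none contribute to neither array.
    """
    if labels is None:
        labels = [""] * len(georefs)
    if len(labels) != len(georefs):
        raise ValueError("labels must parallel georefs")
    coord_groups: dict[tuple[float, float], list[str]] = {}
    country_groups: dict[str, list[str]] = {}
    unlocated = 0
    for ref, label in zip(georefs, labels):
        if ref.kind is GeoKind.COORDINATES:
            key = (round(ref.lat, 4), round(ref.lon, 4))
            coord_groups.setdefault(key, []).append(label)
        elif ref.kind is GeoKind.COUNTRY:
            country_groups.setdefault(ref.country_name, []).append(label)
        else:
            unlocated += 1
    coords = [
        CoordinatePoint(lat, lon, _summarize(labs, len(labs)), len(labs))
        for (lat, lon), labs in sorted(coord_groups.items())
    ]
    countries = [
        CountryPoint(name, _summarize(labs, len(labs)), len(labs))
        for name, labs in sorted(country_groups.items())
    ]
    return GeoArrays(coords, countries, unlocated)


_DATA_ID = "extaxsi-data"

_PAGE = """<!DOCTYPE html>
<html lang="en">
<head>
<meta charset="utf-8">
<title>{title}</title>
<style>
body {{ font-family: sans-serif; margin: 2em; }}
svg {{ border: 1px solid #ccc; }}
.bar {{ fill: #2a6f97; }}
.bar:hover {{ fill: #e76f51; }}
text {{ font-size: 11px; }}
ul.tree {{ list-style: none; }}
</style>
</head>
<body>
<h1>{title}</h1>
<div id="plot"></div>
<script type="application/json" id="{data_id}">{data_json}</script>
<script>
const data = JSON.parse(document.getElementById("{data_id}").textContent);
const plot = document.getElementById("plot");
function esc(s) {{ const d = document.createElement("div"); d.textContent = s; return d.innerHTML; }}
function bars(items, nameOf, hintOf) {{
  if (!items.length) {{ plot.innerHTML += "<p>(no data)</p>"; return; }}
  const w = 700, bh = 18, max = Math.max(...items.map(i => i.count));
  let svg = `<svg width="${{w}}" height="${{items.length * (bh + 4) + 10}}">`;
  items.forEach((it, i) => {{
    const bw = Math.max(1, (it.count / max) * (w - 260));
    const y = i * (bh + 4) + 5;
    svg += `<rect class="bar" x="250" y="${{y}}" width="${{bw}}" height="${{bh}}"><title>${{esc(hintOf(it))}}</title></rect>`;
    svg += `<text x="245" y="${{y + 13}}" text-anchor="end">${{esc(nameOf(it))}}</text>`;
    svg += `<text x="${{252 + bw}}" y="${{y + 13}}">${{it.count}}</text>`;
  }});
  plot.innerHTML += svg + "</svg>";
}}
if (data.kind === "scatter") {{
  const sel = document.createElement("select");
  Object.keys(data.ranks).forEach(r => {{ const o = document.createElement("option"); o.value = r; o.textContent = r; sel.appendChild(o); }});
  document.body.insertBefore(sel, plot);
  const render = () => {{ plot.innerHTML = ""; bars(data.ranks[sel.value].slice(0, 50), i => i.taxon, i => `${{i.taxon}} (parent: ${{i.parent || "-"}}): ${{i.count}}`); }};
  sel.onchange = render; render();
}} else if (data.kind === "sunburst") {{
  if (!data.nodes.length) {{ plot.innerHTML = "<p>(no data)</p>"; }}
  else {{
    const byParent = {{}};
    data.nodes.forEach(n => {{ (byParent[n.parent] = byParent[n.parent] || []).push(n); }});
    const list = (pid) => {{
      const kids = (byParent[pid] || []).sort((a, b) => b.count - a.count);
      if (!kids.length) return "";
      return "<ul class=\\"tree\\">" + kids.map(k =>
        `<li><details><summary>${{esc(k.label)}} — ${{k.count}}</summary>${{list(k.id)}}</details></li>`).join("") + "</ul>";
    }};
    plot.innerHTML = `<p>${{data.total}} records</p>` + list("");
  }}
}} else if (data.kind === "worldmap") {{
  const w = 720, h = 360;
  let svg = `<svg width="${{w}}" height="${{h}}"><rect width="${{w}}" height="${{h}}" fill="#eef6fb"/>`;
  svg += `<line x1="0" y1="${{h / 2}}" x2="${{w}}" y2="${{h / 2}}" stroke="#bbb"/>`;
  svg += `<line x1="${{w / 2}}" y1="0" x2="${{w / 2}}" y2="${{h}}" stroke="#bbb"/>`;
  data.coordinates.forEach(p => {{
    const x = (p.lon + 180) / 360 * w, y = (90 - p.lat) / 180 * h;
    svg += `<g stroke="green" stroke-width="2"><line x1="${{x - 4}}" y1="${{y}}" x2="${{x + 4}}" y2="${{y}}"/><line x1="${{x}}" y1="${{y - 4}}" x2="${{x}}" y2="${{y + 4}}"/><title>${{esc(p.label)}}</title></g>`;
  }});
  plot.innerHTML = svg + "</svg>";
  bars(data.countries.map(c => ({{count: c.count, country: c.country, label: c.label}})).slice(0, 50), i => i.country, i => i.label);
  plot.innerHTML += `<p>${{data.coordinates.length}} coordinate sites (green crosses), ${{data.countries.length}} countries (red circles), ${{data.n_unlocated}} records without geography.</p>`;
}}
</script>
</body>
</html>
"""


def export_html(plot_data, out: str | Path, title: str = "ExTaxsI plot") -> Path:
    """Write plot data as a self-contained, offline-openable HTML file.

    The dataset is embedded verbatim as JSON in a ``<script
    type="application/json">`` block, so every count shown in the rendered
    figure can be recovered from the file (:func:`extract_embedded_data`).
    Accepts any ``build_*`` result (or an equivalent payload dict).
    """
    payload = plot_data.to_payload() if hasattr(plot_data, "to_payload") else dict(plot_data)
    if _payload_is_empty(payload):
        logger.warning("exporting an empty %s figure", payload.get("kind", "plot"))
    out = Path(out)
    text = _PAGE.format(
        title=html.escape(title),
        data_id=_DATA_ID,
        data_json=json.dumps(payload).replace("</", "<\\/"),
    )
    out.write_text(text, encoding="utf-8")
    return out


def _payload_is_empty(payload: dict) -> bool:
    kind = payload.get("kind")
    if kind == "scatter":
        return all(not v for v in payload.get("ranks", {}).values())
    if kind == "sunburst":
        return not payload.get("nodes")
    if kind == "worldmap":
        return not payload.get("coordinates") and not payload.get("countries")
    return not payload


def extract_embedded_data(path: str | Path) -> dict:
    """Recover the JSON dataset embedded in an exported HTML file."""
    text = Path(path).read_text(encoding="utf-8")
    marker = f'<script type="application/json" id="{_DATA_ID}">'
    start = text.index(marker) + len(marker)
    end = text.index("</script>", start)
    return json.loads(text[start:end].replace("<\\/", "</"))
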