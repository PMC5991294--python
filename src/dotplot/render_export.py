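"""Static outputs: SVG/PNG dot plots, summary bar graphs, FASTA exports,
and the three-file backup archive.

The dot plot is drawn as one line per visible match, colored by identity
class, over the concatenated axis layouts; sequence borders and margin
labels (grayed for super-sequences) frame the scene.  Unless strong
precision is requested, matches shorter than one pixel are padded to stay
visible; with strong precision they are drawn at true scale and sub-pixel
matches vanish.
"""

from __future__ import annotations

import gzip
import io
import os
import tarfile
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field

from Bio import SeqIO
from PIL import Image, ImageDraw

from .alignment_io import (
    FormatError,
    open_text_auto,
    parse_paf,
    read_catalog,
    read_fasta_records,
)
from .core import (
    DEFAULT_CAP,
    DEFAULT_MERGE_FRACTION,
    AxisLayout,
    DotPlot,
    IdentityClass,
    PlottedSegment,
    build_dotplot,
    global_coordinates,
    layout_axis,
    visible_matches,
)
from .model import REVERSE, Match, SequenceCatalog
from .sort_orient import SortPlan
from .summary import SummaryProfile

# Palettes map the four identity classes (low to high) to colors; the
# "colorblind" schema uses a deuteranopia-safe set.
COLOR_SCHEMAS: dict[str, dict[IdentityClass, str]] = {
    "default": {
        IdentityClass.CLASS1: "#f7b267",
        IdentityClass.CLASS2: "#f4845f",
        IdentityClass.CLASS3: "#3c8dbc",
        IdentityClass.CLASS4: "#094074",
    },
    "colorblind": {
        IdentityClass.CLASS1: "#fee090",
        IdentityClass.CLASS2: "#fc8d59",
        IdentityClass.CLASS3: "#91bfdb",
        IdentityClass.CLASS4: "#4575b4",
    },
    "viridis": {
        IdentityClass.CLASS1: "#fde725",
        IdentityClass.CLASS2: "#35b779",
        IdentityClass.CLASS3: "#31688e",
        IdentityClass.CLASS4: "#440154",
    },
    "heat": {
        IdentityClass.CLASS1: "#ffffb2",
        IdentityClass.CLASS2: "#fecc5c",
        IdentityClass.CLASS3: "#fd8d3c",
        IdentityClass.CLASS4: "#e31a1c",
    },
    "greens": {
        IdentityClass.CLASS1: "#edf8e9",
        IdentityClass.CLASS2: "#bae4b3",
        IdentityClass.CLASS3: "#74c476",
        IdentityClass.CLASS4: "#238b45",
    },
    "grays": {
        IdentityClass.CLASS1: "#d9d9d9",
        IdentityClass.CLASS2: "#969696",
        IdentityClass.CLASS3: "#525252",
        IdentityClass.CLASS4: "#000000",
    },
}

GRAY_MARGIN = "#c8c8c8"
MARGIN = 60  # pixels reserved for labels on each side


@dataclass
class RenderOptions:
    width: int = 800
    height: int = 800
    color_schema: str = "default"
    line_width: float = 1.5
    border_lines: bool = True
    strong_precision: bool = False
    min_visual_length: float = 1.0
    cap: int = DEFAULT_CAP
    merge_fraction: float = DEFAULT_MERGE_FRACTION

    def palette(self) -> dict[IdentityClass, str]:
        try:
            return COLOR_SCHEMAS[self.color_schema]
        except KeyError:
            raise ValueError(
                f"unknown color schema {self.color_schema!r}; "
                f"available: {', '.join(sorted(COLOR_SCHEMAS))}"
            ) from None


@dataclass
class _Scene:
    """Resolution-independent drawing instructions shared by SVG and PNG."""

    width: int
    height: int
    plot_x: float
    plot_y: float
    plot_w: float
    plot_h: float
    match_lines: list[tuple[float, float, float, float, str]] = field(default_factory=list)
    border_x: list[float] = field(default_factory=list)
    border_y: list[float] = field(default_factory=list)
    gray_x: list[tuple[float, float]] = field(default_factory=list)
    gray_y: list[tuple[float, float]] = field(default_factory=list)
    labels_x: list[tuple[float, str, bool]] = field(default_factory=list)
    labels_y: list[tuple[float, str, bool]] = field(default_factory=list)


def _ellipsize(name: str, max_chars: int) -> str:
    if len(name) <= max_chars or max_chars < 4:
        return name if len(name) <= max_chars else name[: max(1, max_chars)]
    half = (max_chars - 1) // 2
    return name[:half] + "…" + name[-(max_chars - 1 - half):]


def _build_scene(plot: DotPlot, options: RenderOptions) -> _Scene:
    layout_t = layout_axis(plot.target, options.merge_fraction)
    layout_q = layout_axis(plot.query, options.merge_fraction)
    if layout_t.total_length == 0 or layout_q.total_length == 0:
        raise ValueError("cannot render a zero-length axis")

    scene = _Scene(
        width=options.width, height=options.height,
        plot_x=MARGIN, plot_y=MARGIN,
        plot_w=options.width - 2 * MARGIN, plot_h=options.height - 2 * MARGIN,
    )
    sx = scene.plot_w / layout_t.total_length
    sy = scene.plot_h / layout_q.total_length
    palette = options.palette()

    segments = global_coordinates(
        plot, layout_q, layout_t, matches=visible_matches(plot, options.cap)
    )
    for seg in segments:
        x1 = scene.plot_x + seg.x1 * sx
        x2 = scene.plot_x + seg.x2 * sx
        y1 = scene.plot_y + seg.y1 * sy
        y2 = scene.plot_y + seg.y2 * sy
        if not options.strong_precision:
            length = ((x2 - x1) ** 2 + (y2 - y1) ** 2) ** 0.5
            if length < options.min_visual_length:
                # Pad around the midpoint so tiny matches stay visible.
                cx, cy = (x1 + x2) / 2, (y1 + y2) / 2
                if length > 0:
                    ux, uy = (x2 - x1) / length, (y2 - y1) / length
                else:
                    ux, uy = 0.7071067811865476, 0.7071067811865476
                half = options.min_visual_length / 2
                x1, y1 = cx - ux * half, cy - uy * half
                x2, y2 = cx + ux * half, cy + uy * half
        from .core import identity_class

        scene.match_lines.append((x1, y1, x2, y2, palette[identity_class(seg.identity)]))

    for layout, borders, grays, labels, scale, origin in (
        (layout_t, scene.border_x, scene.gray_x, scene.labels_x, sx, scene.plot_x),
        (layout_q, scene.border_y, scene.gray_y, scene.labels_y, sy, scene.plot_y),
    ):
        for group in layout.groups:
            start = origin + group.offset * scale
            end = start + group.length * scale
            borders.append(end)
            if group.grayed:
                grays.append((start, end))
            label = _ellipsize(group.label, max(4, int((end - start) / 7)))
            labels.append(((start + end) / 2, label, group.grayed))
    return scene


def render_svg(plot: DotPlot, options: RenderOptions | None = None) -> str:
    """Render the dot plot as an SVG 1.1 document (one line per match)."""
    options = options or RenderOptions()
    scene = _build_scene(plot, options)

    svg = ET.Element(
        "svg",
        xmlns="http://www.w3.org/2000/svg",
        width=str(scene.width), height=str(scene.height),
        viewBox=f"0 0 {scene.width} {scene.height}",
        version="1.1",
    )
    ET.SubElement(svg, "rect", x="0", y="0", width=str(scene.width),
                  height=str(scene.height), fill="white")
    for x0, x1 in scene.gray_x:
        ET.SubElement(svg, "rect", x=f"{x0:.2f}", y="0", width=f"{x1 - x0:.2f}",
                      height=f"{scene.plot_y:.2f}", fill=GRAY_MARGIN,
                      **{"class": "super-margin"})
    for y0, y1 in scene.gray_y:
        ET.SubElement(svg, "rect", x=f"{scene.plot_x + scene.plot_w:.2f}",
                      y=f"{y0:.2f}", width=f"{MARGIN:.2f}", height=f"{y1 - y0:.2f}",
                      fill=GRAY_MARGIN, **{"class": "super-margin"})
    ET.SubElement(svg, "rect", x=f"{scene.plot_x:.2f}", y=f"{scene.plot_y:.2f}",
                  width=f"{scene.plot_w:.2f}", height=f"{scene.plot_h:.2f}",
                  fill="none", stroke="black", **{"stroke-width": "1", "class": "frame"})
    if options.border_lines:
        for x in scene.border_x[:-1]:
            ET.SubElement(svg, "line", x1=f"{x:.2f}", y1=f"{scene.plot_y:.2f}",
                          x2=f"{x:.2f}", y2=f"{scene.plot_y + scene.plot_h:.2f}",
                          stroke="#cccccc", **{"stroke-width": "0.5", "class": "border"})
        for y in scene.border_y[:-1]:
            ET.SubElement(svg, "line", x1=f"{scene.plot_x:.2f}", y1=f"{y:.2f}",
                          x2=f"{scene.plot_x + scene.plot_w:.2f}", y2=f"{y:.2f}",
                          stroke="#cccccc", **{"stroke-width": "0.5", "class": "border"})
    for x1, y1, x2, y2, color in scene.match_lines:
        ET.SubElement(svg, "line", x1=f"{x1:.3f}", y1=f"{y1:.3f}",
                      x2=f"{x2:.3f}", y2=f"{y2:.3f}", stroke=color,
                      **{"stroke-width": f"{options.line_width:g}", "class": "match"})
    for cx, label, grayed in scene.labels_x:
        el = ET.SubElement(svg, "text", x=f"{cx:.2f}", y=f"{scene.plot_y - 8:.2f}",
                          fill="#555555" if grayed else "black",
                          **{"text-anchor": "middle", "font-size": "10", "class": "label"})
        el.text = label
    for cy, label, grayed in scene.labels_y:
        el = ET.SubElement(
            svg, "text",
            x=f"{scene.plot_x + scene.plot_w + 8:.2f}", y=f"{cy:.2f}",
            fill="#555555" if grayed else "black",
            transform=f"rotate(90 {scene.plot_x + scene.plot_w + 8:.2f} {cy:.2f})",
            **{"text-anchor": "middle", "font-size": "10", "class": "label"},
        )
        el.text = label
    return ET.tostring(svg, encoding="unicode")


def render_png(plot: DotPlot, options: RenderOptions | None = None) -> bytes:
    """Render the same scene as deterministic PNG bytes."""
    options = options or RenderOptions()
    scene = _build_scene(plot, options)
    img = Image.new("RGB", (scene.width, scene.height), "white")
    draw = ImageDraw.Draw(img)
    for x0, x1 in scene.gray_x:
        draw.rectangle([x0, 0, x1, scene.plot_y], fill=GRAY_MARGIN)
    for y0, y1 in scene.gray_y:
        draw.rectangle([scene.plot_x + scene.plot_w, y0,
                        scene.plot_x + scene.plot_w + MARGIN, y1], fill=GRAY_MARGIN)
    draw.rectangle(
        [scene.plot_x, scene.plot_y, scene.plot_x + scene.plot_w, scene.plot_y + scene.plot_h],
        outline="black",
    )
    if options.border_lines:
        for x in scene.border_x[:-1]:
            draw.line([x, scene.plot_y, x, scene.plot_y + scene.plot_h], fill="#cccccc")
        for y in scene.border_y[:-1]:
            draw.line([scene.plot_x, y, scene.plot_x + scene.plot_w, y], fill="#cccccc")
    lw = max(1, round(options.line_width))
    for x1, y1, x2, y2, color in scene.match_lines:
        draw.line([x1, y1, x2, y2], fill=color, width=lw)
    for cx, label, grayed in scene.labels_x:
        draw.text((cx, scene.plot_y - 16), label,
                  fill="#555555" if grayed else "black", anchor="ma")
    for cy, label, grayed in scene.labels_y:
        draw.text((scene.plot_x + scene.plot_w + 6, cy), label,
                  fill="#555555" if grayed else "black", anchor="lm")
    buf = io.BytesIO()
    img.save(buf, format="PNG")
    return buf.getvalue()


def render_summary_svg(profile: SummaryProfile, options: RenderOptions | None = None) -> str:
    """Bar graph of the reference identity profile."""
    options = options or RenderOptions()
    palette = options.palette()
    width, height = options.width, options.height // 2
    svg = ET.Element(
        "svg", xmlns="http://www.w3.org/2000/svg",
        width=str(width), height=str(height),
        viewBox=f"0 0 {width} {height}", version="1.1",
    )
    ET.SubElement(svg, "rect", x="0", y="0", width=str(width), height=str(height), fill="white")
    bars = [(f"class{int(c)}", profile.fractions[c], palette[c]) for c in IdentityClass]
    bars.append(("no match", profile.no_match, "#bbbbbb"))
    bw = width / (len(bars) + 1)
    baseline = height - 30
    for i, (label, frac, color) in enumerate(bars):
        h = frac * (baseline - 20)
        x = (i + 0.6) * bw
        ET.SubElement(svg, "rect", x=f"{x:.2f}", y=f"{baseline - h:.2f}",
                      width=f"{bw * 0.8:.2f}", height=f"{h:.2f}", fill=color,
                      **{"class": "bar"})
        t = ET.SubElement(svg, "text", x=f"{x + bw * 0.4:.2f}", y=f"{baseline + 14:.2f}",
                          **{"text-anchor": "middle", "font-size": "10"})
        t.text = label
        v = ET.SubElement(svg, "text", x=f"{x + bw * 0.4:.2f}", y=f"{baseline - h - 4:.2f}",
                          **{"text-anchor": "middle", "font-size": "10"})
        v.text = f"{100 * frac:.1f}%"
    return ET.tostring(svg, encoding="unicode")


# ---------------------------------------------------------------------------
# FASTA exports


def export_sorted_fasta(query_fasta: str | os.PathLike, plan: SortPlan,
                        out: str | os.PathLike) -> None:
    """Write the query records in plan order, reverse-complementing reversed ones.

    Reverse complementing is IUPAC-aware (N stays N, R pairs with Y, ...);
    reversed records carry a note in their description.
    """
    records = {rec.id: rec for rec in read_fasta_records(query_fasta)}
    missing = [a.query for a in plan.assignments if a.query not in records]
    if missing:
        raise KeyError(f"sequences missing from {query_fasta}: {', '.join(missing)}")
    with open(out, "wt", encoding="ascii") as fh:
        for a in plan.assignments:
            rec = records[a.query]
            if a.orientation == REVERSE:
                rec = rec.reverse_complement(id=rec.id, description="reversed")
            SeqIO.write([rec], fh, "fasta")


def export_unaligned(catalog: SequenceCatalog, matches: list[Match],
                     fasta: str | os.PathLike, out: str | os.PathLike) -> int:
    """Write catalog sequences that appear in no match; returns the count.

    Works for either axis: a sequence is considered aligned when it occurs
    as query or target of any match in the raw (pre-filter) list.
    """
    aligned = {m.qname for m in matches} | {m.tname for m in matches}
    wanted = [name for name in catalog.names if name not in aligned]
    records = {rec.id: rec for rec in read_fasta_records(fasta)}
    with open(out, "wt", encoding="ascii") as fh:
        for name in wanted:
            if name in records:
                SeqIO.write([records[name]], fh, "fasta")
    return len(wanted)


# ---------------------------------------------------------------------------
# Backup archive

_CANONICAL = {"query": "query.fasta", "target": "target.fasta", "alignment": "alignment.paf"}


def make_backup(query_fasta: str | os.PathLike, target_fasta: str | os.PathLike,
                paf: str | os.PathLike, out_archive: str | os.PathLike) -> None:
    """Bundle the three inputs into a tar.gz with canonical member names.

    Gzipped FASTA members keep a .gz suffix so they can be stored verbatim.
    """
    def _is_gz(path):
        with open(path, "rb") as fh:
            return fh.read(2) == b"\x1f\x8b"

    with tarfile.open(out_archive, "w:gz") as tar:
        for path, member in (
            (query_fasta, _CANONICAL["query"]),
            (target_fasta, _CANONICAL["target"]),
            (paf, _CANONICAL["alignment"]),
        ):
            name = member + ".gz" if member.endswith(".fasta") and _is_gz(path) else member
            tar.add(os.fspath(path), arcname=name)


def load_backup(archive: str | os.PathLike, workdir: str | os.PathLike) -> DotPlot:
    """Extract a backup archive and rebuild the dot plot from its members."""
    os.makedirs(workdir, exist_ok=True)
    with tarfile.open(archive, "r:gz") as tar:
        members = {m.name: m for m in tar.getmembers()}
        paths = {}
        for key, canonical in _CANONICAL.items():
            name = canonical if canonical in members else canonical + ".gz"
            if name not in members:
                raise FormatError(f"backup archive is missing member {canonical!r}")
            tar.extract(members[name], path=workdir, filter="data")
            paths[key] = os.path.join(workdir, name)
    query = read_catalog(paths["query"])
    target = read_catalog(paths["target"])
    with open_text_auto(paths["alignment"]) as fh:
        matches = parse_paf(fh)
    return build_dotplot(matches, query, target)
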