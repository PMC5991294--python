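"""SVG/PNG rendering, FASTA exports and the backup archive."""

import io
import xml.etree.ElementTree as ET

import pytest
from PIL import Image

from dotplot.alignment_io import write_paf
from dotplot.core import Filters, IdentityClass, build_dotplot
from dotplot.model import REVERSE, SequenceCatalog
from dotplot.render_export import (
    COLOR_SCHEMAS,
    RenderOptions,
    export_sorted_fasta,
    export_unaligned,
    load_backup,
    make_backup,
    render_png,
    render_summary_svg,
    render_svg,
)
from dotplot.sort_orient import compute_sort_plan
from dotplot.summary import summary_profile
from tests.conftest import make_match, small_catalogs

SVGNS = "{http://www.w3.org/2000/svg}"


def match_lines(svg_text):
    root = ET.fromstring(svg_text)
    return [el for el in root.iter(f"{SVGNS}line") if el.get("class") == "match"]


@pytest.fixture
def simple_plot():
    query, target = small_catalogs()
    matches = [
        make_match(qname="q0", tname="t0", qstart=0, qend=500, tstart=0, tend=500,
                   nmatch=450, blocklen=500),
        make_match(qname="q1", tname="t0", qstart=100, qend=300, tstart=400, tend=600,
                   nmatch=60, blocklen=200),
        make_match(qname="q2", tname="t1", strand=REVERSE, qstart=0, qend=400,
                   tstart=0, tend=400, nmatch=150, blocklen=400),
    ]
    return build_dotplot(matches, query, target)


class TestRenderSvg:
    def test_one_line_element_per_visible_match(self, simple_plot):
        svg = render_svg(simple_plot)
        assert len(match_lines(svg)) == 3

    def test_hidden_classes_remove_lines_but_keep_frame(self, simple_plot):
        simple_plot.filters = Filters(hidden_classes=frozenset(IdentityClass))
        svg = render_svg(simple_plot)
        assert len(match_lines(svg)) == 0
        root = ET.fromstring(svg)
        assert any(el.get("class") == "frame" for el in root.iter(f"{SVGNS}rect"))

    def test_cap_limits_drawn_matches(self, simple_plot):
        svg = render_svg(simple_plot, RenderOptions(cap=2))
        assert len(match_lines(svg)) == 2

    def test_strong_precision_drops_subpixel_padding(self):
        query = SequenceCatalog([("q", 10_000_000)])
        target = SequenceCatalog([("t", 10_000_000)])
        tiny = make_match(qname="q", qlen=10_000_000, qstart=0, qend=1,
                          tname="t", tlen=10_000_000, tstart=0, tend=1,
                          nmatch=1, blocklen=1)
        plot = build_dotplot([tiny], query, target)

        def drawn_length(svg):
            (line,) = match_lines(svg)
            dx = float(line.get("x2")) - float(line.get("x1"))
            dy = float(line.get("y2")) - float(line.get("y1"))
            return (dx * dx + dy * dy) ** 0.5

        padded = drawn_length(render_svg(plot, RenderOptions(strong_precision=False)))
        true_scale = drawn_length(render_svg(plot, RenderOptions(strong_precision=True)))
        assert padded >= 1.0
        assert true_scale < 0.01

    def test_super_sequence_margins_are_grayed(self):
        target = SequenceCatalog(
            [("big", 100_000), ("tiny1", 10), ("tiny2", 10), ("big2", 100_000)]
        )
        query = SequenceCatalog([("q", 1000)])
        plot = build_dotplot([], query, target)
        root = ET.fromstring(render_svg(plot))
        grays = [el for el in root.iter(f"{SVGNS}rect") if el.get("class") == "super-margin"]
        assert len(grays) == 1

    def test_unknown_color_schema_rejected(self, simple_plot):
        with pytest.raises(ValueError, match="schema"):
            render_svg(simple_plot, RenderOptions(color_schema="nope"))

    def test_six_schemas_with_distinct_class_colors(self):
        assert len(COLOR_SCHEMAS) >= 6
        assert "colorblind" in COLOR_SCHEMAS
        for palette in COLOR_SCHEMAS.values():
            assert len(set(palette.values())) == 4


class TestRenderPng:
    def test_decodable_with_requested_dimensions(self, simple_plot):
        png = render_png(simple_plot, RenderOptions(width=400, height=300))
        img = Image.open(io.BytesIO(png))
        assert img.size == (400, 300)

    def test_deterministic_bytes(self, simple_plot):
        opts = RenderOptions()
        assert render_png(simple_plot, opts) == render_png(simple_plot, opts)

    def test_empty_plot_renders_blank_canvas(self):
        query, target = small_catalogs()
        png = render_png(build_dotplot([], query, target))
        Image.open(io.BytesIO(png)).verify()


class TestSummaryGraph:
    def test_bar_per_class_plus_no_match(self, simple_plot):
        profile = summary_profile(simple_plot)
        root = ET.fromstring(render_summary_svg(profile))
        bars = [el for el in root.iter(f"{SVGNS}rect") if el.get("class") == "bar"]
        assert len(bars) == 5


class TestFastaExports:
    def _write_query_fasta(self, tmp_path):
        path = tmp_path / "q.fasta"
        path.write_text(">q1\nAACG\n>q2\nTTTT\n")
        return path

    def test_reversed_query_written_as_reverse_complement(self, tmp_path):
        fasta = tmp_path / "q.fasta"
        fasta.write_text(">q1\nAACG\n")
        m = make_match(qname="q1", qlen=4, qstart=0, qend=4, strand=REVERSE,
                       tstart=0, tend=4, nmatch=4, blocklen=4)
        plot = build_dotplot(
            [m], SequenceCatalog([("q1", 4)]), SequenceCatalog([("t1", 2000)])
        )
        plan = compute_sort_plan(plot)
        assert plan.assignment("q1").orientation == REVERSE
        out = tmp_path / "sorted.fasta"
        export_sorted_fasta(fasta, plan, out)
        assert "CGTT" in out.read_text()

    def test_iupac_codes_complemented(self, tmp_path):
        fasta = tmp_path / "q.fasta"
        fasta.write_text(">q1\nNRYA\n")
        m = make_match(qname="q1", qlen=4, qstart=0, qend=4, strand=REVERSE,
                       tstart=0, tend=4, nmatch=4, blocklen=4)
        plot = build_dotplot(
            [m], SequenceCatalog([("q1", 4)]), SequenceCatalog([("t1", 2000)])
        )
        out = tmp_path / "sorted.fasta"
        export_sorted_fasta(fasta, compute_sort_plan(plot), out)
        assert "TRYN" in out.read_text()

    def test_forward_plan_reorders_without_editing_residues(self, tmp_path):
        fasta = self._write_query_fasta(tmp_path)
        m = make_match(qname="q2", qlen=4, qstart=0, qend=4, tstart=0, tend=4,
                       nmatch=4, blocklen=4)
        plot = build_dotplot(
            [m], SequenceCatalog([("q1", 4), ("q2", 4)]), SequenceCatalog([("t1", 2000)])
        )
        out = tmp_path / "sorted.fasta"
        export_sorted_fasta(fasta, compute_sort_plan(plot), out)
        text = out.read_text()
        assert text.index(">q2") < text.index(">q1")  # aligned query first
        assert "TTTT" in text and "AACG" in text

    def test_missing_sequence_rejected(self, tmp_path):
        fasta = tmp_path / "q.fasta"
        fasta.write_text(">other\nAC\n")
        plot = build_dotplot(
            [], SequenceCatalog([("q1", 4)]), SequenceCatalog([("t1", 2000)])
        )
        with pytest.raises(KeyError, match="q1"):
            export_sorted_fasta(fasta, compute_sort_plan(plot), tmp_path / "out.fasta")

    def test_unaligned_export_counts(self, tmp_path):
        fasta = self._write_query_fasta(tmp_path)
        catalog = SequenceCatalog([("q1", 4), ("q2", 4)])
        m = make_match(qname="q1", qlen=4, qstart=0, qend=4, tstart=0, tend=4,
                       nmatch=4, blocklen=4)
        out = tmp_path / "unaligned.fasta"
        assert export_unaligned(catalog, [m], fasta, out) == 1
        assert out.read_text().startswith(">q2")
        assert export_unaligned(catalog, [], fasta, out) == 2
        m2 = make_match(qname="q2", qlen=4, qstart=0, qend=4, tstart=0, tend=4,
                        nmatch=4, blocklen=4)
        assert export_unaligned(catalog, [m, m2], fasta, out) == 0


class TestBackupArchive:
    def _inputs(self, tmp_path):
        q = tmp_path / "query.fa"
        t = tmp_path / "target.fa"
        p = tmp_path / "aln.paf"
        q.write_text(">q1\n" + "ACGT" * 250 + "\n")
        t.write_text(">t1\n" + "ACGT" * 500 + "\n")
        m = make_match(qname="q1", qlen=1000, tname="t1", tlen=2000)
        with open(p, "wt") as fh:
            write_paf([m], fh)
        return q, t, p, [m]

    def test_round_trip_reconstructs_plot(self, tmp_path):
        q, t, p, matches = self._inputs(tmp_path)
        archive = tmp_path / "backup.tar.gz"
        make_backup(q, t, p, archive)
        plot = load_backup(archive, tmp_path / "extracted")
        assert plot.matches == matches
        assert list(plot.query) == [("q1", 1000)]
        assert list(plot.target) == [("t1", 2000)]

    def test_missing_member_named_in_error(self, tmp_path):
        import tarfile

        q, t, p, _ = self._inputs(tmp_path)
        archive = tmp_path / "broken.tar.gz"
        with tarfile.open(archive, "w:gz") as tar:
            tar.add(q, arcname="query.fasta")
            tar.add(t, arcname="target.fasta")
        with pytest.raises(Exception, match="alignment.paf"):
            load_backup(archive, tmp_path / "x")

    def test_gzipped_fasta_members_accepted(self, tmp_path):
        import gzip

        q, t, p, matches = self._inputs(tmp_path)
        qgz = tmp_path / "query.fa.gz"
        qgz.write_bytes(gzip.compress(q.read_bytes()))
        archive = tmp_path / "backup.tar.gz"
        make_backup(qgz, t, p, archive)
        plot = load_backup(archive, tmp_path / "extracted")
        assert plot.matches == matches
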