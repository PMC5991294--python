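"""Chunk splitting, coordinate restoration and boundary stitching."""

import random

import pytest

from dotplot.alignment_io import read_fasta_records
from dotplot.chunking import (
    ChunkMap,
    chunk_name,
    merge_contiguous,
    project_to_chunks,
    split_catalog,
    split_fasta,
    unchunk,
)
from dotplot.fixtures import simulate_catalogs
from dotplot.model import FORWARD, REVERSE, SequenceCatalog
from tests.conftest import make_match

MB = 1_000_000


class TestSplitCatalog:
    def test_25mb_sequence_becomes_three_chunks(self):
        catalog = SequenceCatalog([("chr1", 25 * MB)])
        chunked, cmap = split_catalog(catalog, 10 * MB)
        assert [l for _, l in chunked] == [10 * MB, 10 * MB, 5 * MB]
        assert chunked.names == [chunk_name("chr1", i) for i in range(3)]
        assert cmap.lookup(chunk_name("chr1", 2)) == ("chr1", 20 * MB, 25 * MB)

    @pytest.mark.parametrize("length", [1, 9_999_999, 10 * MB])
    def test_sequences_within_one_chunk_keep_their_name(self, length):
        chunked, cmap = split_catalog(SequenceCatalog([("s", length)]), 10 * MB)
        assert list(chunked) == [("s", length)]
        assert len(cmap) == 0

    def test_total_length_conserved(self):
        catalog = SequenceCatalog([("a", 25 * MB), ("b", 3 * MB), ("c", 40 * MB)])
        chunked, _ = split_catalog(catalog, 10 * MB)
        assert chunked.total_length == catalog.total_length

    def test_name_colliding_with_separator_rejected(self):
        with pytest.raises(ValueError, match="separator"):
            split_catalog(SequenceCatalog([("x_###_0", 5)]), 10)


class TestSplitFasta:
    def test_chunk_records_concatenate_to_original(self, tmp_path):
        seq = "".join(random.Random(7).choices("ACGT", k=25))
        src = tmp_path / "in.fasta"
        src.write_text(f">s\n{seq}\n>short\nACGT\n")
        out = tmp_path / "out.fasta"
        cmap = split_fasta(src, out, chunk_size=10)
        records = list(read_fasta_records(out))
        assert [r.id for r in records] == [
            chunk_name("s", 0), chunk_name("s", 1), chunk_name("s", 2), "short",
        ]
        assert [len(r.seq) for r in records[:3]] == [10, 10, 5]
        assert "".join(str(r.seq) for r in records[:3]) == seq
        assert len(cmap) == 3

    def test_short_sequence_record_unchanged(self, tmp_path):
        src = tmp_path / "in.fasta"
        src.write_text(">s\nACGTACGT\n")
        out = tmp_path / "out.fasta"
        split_fasta(src, out, chunk_size=100)
        (rec,) = read_fasta_records(out)
        assert (rec.id, str(rec.seq)) == ("s", "ACGTACGT")

    def test_empty_fasta_rejected(self, tmp_path):
        src = tmp_path / "empty.fasta"
        src.write_text("")
        with pytest.raises(Exception, match="no sequences|empty"):
            split_fasta(src, tmp_path / "out.fasta", chunk_size=10)


class TestUnchunk:
    def test_offset_is_added_back(self):
        cmap = ChunkMap(10 * MB)
        cmap.add(chunk_name("c", 1), "c", 10 * MB, 25 * MB)
        m = make_match(qname=chunk_name("c", 1), qlen=10 * MB, qstart=5, qend=50)
        (u,) = unchunk([m], cmap)
        assert (u.qname, u.qlen) == ("c", 25 * MB)
        assert (u.qstart, u.qend) == (10 * MB + 5, 10 * MB + 50)
        assert (u.tname, u.tstart, u.tend) == (m.tname, m.tstart, m.tend)

    def test_chunk_zero_keeps_coordinates(self):
        cmap = ChunkMap(10 * MB)
        cmap.add(chunk_name("c", 0), "c", 0, 25 * MB)
        m = make_match(qname=chunk_name("c", 0), qlen=10 * MB, qstart=5, qend=50)
        (u,) = unchunk([m], cmap)
        assert (u.qname, u.qstart, u.qend) == ("c", 5, 50)

    def test_unsplit_names_pass_through(self):
        cmap = ChunkMap(10 * MB)
        m = make_match()
        assert unchunk([m], cmap) == [m]

    def test_unknown_chunk_name_rejected(self):
        cmap = ChunkMap(10 * MB)
        m = make_match(qname=chunk_name("ghost", 3), qlen=1000)
        with pytest.raises(KeyError, match="ghost"):
            unchunk([m], cmap)

    def test_idempotent_on_restored_matches(self):
        cmap = ChunkMap(10 * MB)
        cmap.add(chunk_name("c", 1), "c", 10 * MB, 25 * MB)
        m = make_match(qname=chunk_name("c", 1), qlen=10 * MB, qstart=5, qend=50)
        once = unchunk([m], cmap)
        assert unchunk(once, cmap) == once


class TestProjectAndRoundTrip:
    @pytest.mark.parametrize("seed", range(5))
    def test_projection_round_trip_restores_query_intervals(self, seed):
        query, target, matches = simulate_catalogs(seed)
        chunked, cmap = split_catalog(query, 10 * MB)
        for m in matches:
            pieces = project_to_chunks([m], cmap)
            for p in pieces:  # pieces live inside the chunked catalog
                assert p.qend <= chunked.length(p.qname)
            parts = sorted(unchunk(pieces, cmap), key=lambda p: p.qstart)
            assert parts[0].qstart == m.qstart
            assert parts[-1].qend == m.qend
            for a, b in zip(parts, parts[1:]):
                assert a.qend == b.qstart  # contiguous, no overlap
            assert sum(p.nmatch for p in parts) == m.nmatch
            assert sum(p.blocklen for p in parts) == m.blocklen

    def test_tsv_round_trip(self, tmp_path):
        _, cmap = split_catalog(SequenceCatalog([("a", 25 * MB), ("b", 12 * MB)]), 10 * MB)
        path = tmp_path / "map.tsv"
        with open(path, "wt") as fh:
            cmap.write_tsv(fh)
        with open(path) as fh:
            loaded = ChunkMap.read_tsv(fh, 10 * MB)
        for i in range(3):
            assert loaded.lookup(chunk_name("a", i)) == cmap.lookup(chunk_name("a", i))


class TestMergeContiguous:
    def test_forward_boundary_pieces_rejoin(self):
        a = make_match(qname="c", qlen=15 * MB, qstart=0, qend=10 * MB,
                       tname="t", tlen=20 * MB, tstart=0, tend=10 * MB,
                       nmatch=9 * MB, blocklen=10 * MB)
        b = make_match(qname="c", qlen=15 * MB, qstart=10 * MB, qend=15 * MB,
                       tname="t", tlen=20 * MB, tstart=10 * MB, tend=15 * MB,
                       nmatch=4 * MB, blocklen=5 * MB)
        (merged,) = merge_contiguous([a, b], gap_tolerance=0)
        assert (merged.qstart, merged.qend) == (0, 15 * MB)
        assert (merged.tstart, merged.tend) == (0, 15 * MB)
        assert merged.nmatch == 13 * MB
        assert merged.blocklen == 15 * MB

    def test_reverse_strand_target_runs_backwards(self):
        a = make_match(qname="c", qlen=20 * MB, qstart=0, qend=10 * MB, strand=REVERSE,
                       tname="t", tlen=20 * MB, tstart=10 * MB, tend=20 * MB,
                       nmatch=10 * MB, blocklen=10 * MB)
        b = make_match(qname="c", qlen=20 * MB, qstart=10 * MB, qend=20 * MB, strand=REVERSE,
                       tname="t", tlen=20 * MB, tstart=0, tend=10 * MB,
                       nmatch=10 * MB, blocklen=10 * MB)
        (merged,) = merge_contiguous([a, b], gap_tolerance=0)
        assert (merged.qstart, merged.qend) == (0, 20 * MB)
        assert (merged.tstart, merged.tend) == (0, 20 * MB)

    def test_opposite_strands_not_merged(self):
        a = make_match(qend=10, qstart=0, tstart=0, tend=10, nmatch=10, blocklen=10)
        b = make_match(qstart=10, qend=20, strand=REVERSE, tstart=10, tend=20,
                       nmatch=10, blocklen=10)
        assert len(merge_contiguous([a, b], 0)) == 2

    def test_different_targets_not_merged(self):
        a = make_match(qstart=0, qend=10, tstart=0, tend=10, nmatch=10, blocklen=10)
        b = make_match(qstart=10, qend=20, tname="t2", tstart=10, tend=20,
                       nmatch=10, blocklen=10)
        assert len(merge_contiguous([a, b], 0)) == 2

    def test_gap_beyond_tolerance_not_merged(self):
        a = make_match(qstart=0, qend=10, tstart=0, tend=10, nmatch=10, blocklen=10)
        b = make_match(qstart=15, qend=25, tstart=15, tend=25, nmatch=10, blocklen=10)
        assert len(merge_contiguous([a, b], gap_tolerance=0)) == 2
        assert len(merge_contiguous([a, b], gap_tolerance=5)) == 1

    def test_transitive_merge_of_three_pieces(self):
        pieces = [
            make_match(qstart=i * 10, qend=(i + 1) * 10, tstart=i * 10, tend=(i + 1) * 10,
                       nmatch=8, blocklen=10)
            for i in (2, 0, 1)  # shuffled input order
        ]
        (merged,) = merge_contiguous(pieces, 0)
        assert (merged.qstart, merged.qend) == (0, 30)
        assert merged.nmatch == 24

    def test_total_nmatch_never_decreases(self):
        rng = random.Random(3)
        from tests.conftest import random_matches

        matches = random_matches(rng, 100)
        merged = merge_contiguous(matches, gap_tolerance=50)
        assert sum(m.nmatch for m in merged) == sum(m.nmatch for m in matches)
        for m in merged:
            assert 0 <= m.qstart < m.qend <= m.qlen
            assert 0 <= m.tstart < m.tend <= m.tlen
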