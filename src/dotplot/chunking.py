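"""Query chunking: split long sequences before alignment, stitch afterwards.

Long query sequences (chromosomes) are split into fixed-size chunks —
10 Mb by default — so the aligner's memory stays bounded.  After alignment
the chunk coordinates are shifted back onto the original sequences
(:func:`unchunk`), and alignments that continue each other across chunk
boundaries are rejoined (:func:`merge_contiguous`).  Only the query axis is
ever chunked.

Chunk names are ``<original>_###_<i>`` (i from 0); sequences that fit in a
single chunk keep their original name.
"""

from __future__ import annotations

import math
import os
import re
from typing import Iterable, TextIO

from Bio import SeqIO

from .alignment_io import FormatError, read_fasta_records
from .model import FORWARD, Match, SequenceCatalog

DEFAULT_CHUNK_SIZE = 10_000_000
CHUNK_SEP = "_###_"
_CHUNK_RE = re.compile(re.escape(CHUNK_SEP) + r"(\d+)$")


class ChunkMap:
    """Mapping from chunk names back to (original name, offset).

    Only sequences that were actually split appear in the map; unsplit
    sequences pass through aligners under their own names and are left
    untouched by :func:`unchunk`.
    """

    def __init__(self, chunk_size: int):
        if chunk_size < 1:
            raise ValueError("chunk_size must be >= 1")
        self.chunk_size = int(chunk_size)
        self._entries: dict[str, tuple[str, int]] = {}
        self._original_length: dict[str, int] = {}

    def add(self, chunk_name: str, original_name: str, offset: int, original_length: int) -> None:
        if chunk_name in self._entries:
            raise ValueError(f"duplicate chunk name {chunk_name!r}")
        if offset % self.chunk_size != 0:
            raise ValueError(f"offset {offset} is not a multiple of chunk_size")
        self._entries[chunk_name] = (original_name, offset)
        self._original_length[original_name] = original_length

    def __contains__(self, chunk_name: str) -> bool:
        return chunk_name in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    def lookup(self, chunk_name: str) -> tuple[str, int, int]:
        """Return (original name, offset, original length) for a chunk."""
        original, offset = self._entries[chunk_name]
        return original, offset, self._original_length[original]

    def chunks_of(self, original_name: str) -> list[tuple[str, int]]:
        return sorted(
            ((c, off) for c, (orig, off) in self._entries.items() if orig == original_name),
            key=lambda t: t[1],
        )

    def write_tsv(self, stream: TextIO) -> None:
        for chunk, (orig, off) in sorted(self._entries.items(), key=lambda kv: (kv[1][0], kv[1][1])):
            stream.write(f"{chunk}\t{orig}\t{off}\t{self._original_length[orig]}\n")

    @classmethod
    def read_tsv(cls, stream: Iterable[str], chunk_size: int = DEFAULT_CHUNK_SIZE) -> "ChunkMap":
        cmap = cls(chunk_size)
        for line in stream:
            if not line.strip():
                continue
            chunk, orig, off, olen = line.rstrip("\n").split("\t")
            cmap.add(chunk, orig, int(off), int(olen))
        return cmap


def chunk_name(original: str, index: int) -> str:
    return f"{original}{CHUNK_SEP}{index}"


def split_catalog(
    catalog: SequenceCatalog, chunk_size: int = DEFAULT_CHUNK_SIZE
) -> tuple[SequenceCatalog, ChunkMap]:
    """Split every sequence longer than ``chunk_size`` into fixed-size chunks.

    Chunk i of a sequence of length L covers [i*chunk_size,
    min((i+1)*chunk_size, L)).  Sequences that fit in one chunk keep their
    name and do not enter the map.
    """
    cmap = ChunkMap(chunk_size)
    entries: list[tuple[str, int]] = []
    for name, length in catalog:
        if CHUNK_SEP in name:
            raise ValueError(f"sequence name {name!r} collides with the chunk separator")
        if length <= chunk_size:
            entries.append((name, length))
            continue
        n_chunks = math.ceil(length / chunk_size)
        for i in range(n_chunks):
            start = i * chunk_size
            clen = min(chunk_size, length - start)
            cname = chunk_name(name, i)
            cmap.add(cname, name, start, length)
            entries.append((cname, clen))
    return SequenceCatalog(entries), cmap


def split_fasta(
    in_path: str | os.PathLike, out_path: str | os.PathLike,
    chunk_size: int = DEFAULT_CHUNK_SIZE,
) -> ChunkMap:
    """Materialize :func:`split_catalog` on a FASTA file.

    Concatenating the chunk records of a sequence in offset order reproduces
    the original residues exactly.
    """
    records = list(read_fasta_records(in_path))
    if not records:
        raise FormatError(f"{in_path}: no sequences found")
    catalog = SequenceCatalog((r.id, len(r.seq)) for r in records)
    _, cmap = split_catalog(catalog, chunk_size)
    with open(out_path, "wt", encoding="ascii") as out:
        for rec in records:
            if len(rec.seq) <= chunk_size:
                SeqIO.write([rec], out, "fasta")
                continue
            for i in range(math.ceil(len(rec.seq) / chunk_size)):
                piece = rec[i * chunk_size : (i + 1) * chunk_size]
                piece.id = chunk_name(rec.id, i)
                piece.description = ""
                SeqIO.write([piece], out, "fasta")
    return cmap


def unchunk(matches: Iterable[Match], cmap: ChunkMap) -> list[Match]:
    """Restore original query names, lengths and coordinates after alignment.

    Matches whose qname is not a chunk name are assumed to be unsplit
    originals and pass through untouched; an unknown name carrying the chunk
    separator is an error.
    """
    out: list[Match] = []
    for m in matches:
        if m.qname in cmap:
            orig, offset, olen = cmap.lookup(m.qname)
            out.append(
                m.replace(
                    qname=orig, qlen=olen,
                    qstart=m.qstart + offset, qend=m.qend + offset,
                )
            )
        elif _CHUNK_RE.search(m.qname):
            raise KeyError(f"unknown chunk name {m.qname!r}")
        else:
            out.append(m)
    return out


def project_to_chunks(matches: Iterable[Match], cmap: ChunkMap) -> list[Match]:
    """Express matches in chunk coordinates (the inverse view of unchunk).

    A match crossing chunk boundaries is split into one piece per chunk;
    nmatch is apportioned proportionally to piece length (remainder on the
    last piece) and the target interval is sliced assuming a collinear
    alignment, so that re-unchunking followed by contiguous merging restores
    the original match exactly.
    """
    out: list[Match] = []
    for m in matches:
        chunks = cmap.chunks_of(m.qname)
        if not chunks:
            out.append(m)
            continue
        size = cmap.chunk_size
        first = m.qstart // size
        last = (m.qend - 1) // size
        pieces = []
        for i in range(first, last + 1):
            lo = max(m.qstart, i * size)
            hi = min(m.qend, (i + 1) * size)
            pieces.append((i, lo, hi))
        qspan = m.qend - m.qstart
        tspan = m.tend - m.tstart
        K = len(pieces)
        # Apportion block length and target span proportionally (remainder on
        # the last piece), then distribute nmatch within per-piece capacity so
        # every piece keeps nmatch <= blocklen and the totals are exact.
        blocks, tlens = [], []
        for k, (i, lo, hi) in enumerate(pieces):
            frac_len = hi - lo
            if k == K - 1:
                blocks.append(m.blocklen - sum(blocks))
                tlens.append(tspan - sum(tlens))
            else:
                blocks.append(max(1, m.blocklen * frac_len // qspan))
                tlens.append(tspan * frac_len // qspan)
        nmatches = [min(b, m.nmatch * b // m.blocklen) for b in blocks]
        deficit = m.nmatch - sum(nmatches)
        for k in range(K - 1, -1, -1):
            if deficit == 0:
                break
            room = blocks[k] - nmatches[k]
            add = min(room, deficit)
            nmatches[k] += add
            deficit -= add

        t_cursor = m.tstart if m.strand == FORWARD else m.tend
        for k, (i, lo, hi) in enumerate(pieces):
            t_len = tlens[k]
            if m.strand == FORWARD:
                tlo, thi = t_cursor, t_cursor + t_len
                t_cursor = thi
            else:
                tlo, thi = t_cursor - t_len, t_cursor
                t_cursor = tlo
            _, offset, olen = cmap.lookup(chunk_name(m.qname, i))
            clen = min(cmap.chunk_size, olen - i * size)
            out.append(
                m.replace(
                    qname=chunk_name(m.qname, i), qlen=clen,
                    qstart=lo - i * size, qend=hi - i * size,
                    tstart=tlo, tend=thi,
                    nmatch=nmatches[k], blocklen=blocks[k],
                )
            )
    return out


def merge_contiguous(matches: Iterable[Match], gap_tolerance: int = 0) -> list[Match]:
    """Rejoin alignments that continue each other across chunk boundaries.

    Two matches merge when they share qname, tname and strand and the second
    continues the first within ``gap_tolerance`` bases on both axes; on the
    reverse strand the target continuation runs in decreasing coordinates.
    Merging is transitive after sorting candidates by query start; nmatch and
    blocklen are summed, so identity is recomputed from the merged totals.
    """
    groups: dict[tuple[str, str, str], list[Match]] = {}
    order: list[tuple[str, str, str]] = []
    for m in matches:
        key = (m.qname, m.tname, m.strand)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(m)

    out: list[Match] = []
    for key in order:
        group = sorted(groups[key], key=lambda m: (m.qstart, m.qend))
        current = group[0]
        for nxt in group[1:]:
            q_gap = nxt.qstart - current.qend
            if current.strand == FORWARD:
                t_gap = nxt.tstart - current.tend
            else:
                t_gap = current.tstart - nxt.tend
            if abs(q_gap) <= gap_tolerance and abs(t_gap) <= gap_tolerance:
                current = current.replace(
                    qstart=min(current.qstart, nxt.qstart),
                    qend=max(current.qend, nxt.qend),
                    tstart=min(current.tstart, nxt.tstart),
                    tend=max(current.tend, nxt.tend),
                    nmatch=current.nmatch + nxt.nmatch,
                    blocklen=current.blocklen + nxt.blocklen,
                )
            else:
                out.append(current)
                current = nxt
        out.append(current)
    return out
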