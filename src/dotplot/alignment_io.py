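"""Readers and writers for the standard formats: PAF, MAF, FASTA and .fai.

PAF records use 0-based half-open coordinates and 12 mandatory columns;
extra SAM-style tag columns are kept as opaque text and written back
verbatim.  MAF pairwise blocks are converted to the same internal
:class:`~dotplot.model.Match` representation at parse time, including the
minus-strand coordinate transform (MAF minus-strand coordinates are given
relative to the reverse-complemented source), so downstream code only ever
sees one convention.

A small extension registry maps file extensions to (validator, converter)
pairs so additional alignment formats can be plugged in without touching
the loader.
"""

from __future__ import annotations

import gzip
import io
import os
from typing import Callable, Iterable, TextIO

from Bio import SeqIO

from .model import FORWARD, REVERSE, Match, SequenceCatalog


class FormatError(ValueError):
    """Raised when an input file violates its format."""


# ---------------------------------------------------------------------------
# PAF


def parse_paf(stream: Iterable[str]) -> list[Match]:
    """Parse a PAF stream into a list of matches, preserving input order.

    Identity is computed as column 10 / column 11 (residue matches over
    alignment block length).  Columns beyond the 12 mandatory ones are
    preserved as opaque tags.
    """
    matches: list[Match] = []
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 12:
            raise FormatError(
                f"PAF line {lineno}: expected >= 12 tab-separated fields, got {len(fields)}"
            )
        try:
            qlen, qstart, qend = int(fields[1]), int(fields[2]), int(fields[3])
            tlen, tstart, tend = int(fields[6]), int(fields[7]), int(fields[8])
            nmatch, blocklen = int(fields[9]), int(fields[10])
            mapq = int(fields[11])
        except ValueError as exc:
            raise FormatError(f"PAF line {lineno}: non-integer coordinate field: {exc}") from None
        if qend <= qstart:
            raise FormatError(f"PAF line {lineno}: query end {qend} <= start {qstart}")
        if tend <= tstart:
            raise FormatError(f"PAF line {lineno}: target end {tend} <= start {tstart}")
        try:
            matches.append(
                Match(
                    qname=fields[0], qlen=qlen, qstart=qstart, qend=qend,
                    strand=fields[4],
                    tname=fields[5], tlen=tlen, tstart=tstart, tend=tend,
                    nmatch=nmatch, blocklen=blocklen, mapq=mapq,
                    tags=tuple(fields[12:]),
                )
            )
        except ValueError as exc:
            raise FormatError(f"PAF line {lineno}: {exc}") from None
    return matches


def write_paf(matches: Iterable[Match], stream: TextIO) -> None:
    """Write matches as PAF; ``parse_paf(write_paf(m))`` reproduces ``m``."""
    for m in matches:
        fields = [
            m.qname, str(m.qlen), str(m.qstart), str(m.qend), m.strand,
            m.tname, str(m.tlen), str(m.tstart), str(m.tend),
            str(m.nmatch), str(m.blocklen), str(m.mapq),
        ]
        fields.extend(m.tags)
        stream.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# MAF


def _maf_s_fields(line: str, lineno: int):
    parts = line.split()
    if len(parts) != 7:
        raise FormatError(f"MAF line {lineno}: s-line must have 7 fields, got {len(parts)}")
    _, src, start, size, strand, srcsize, text = parts
    try:
        return src, int(start), int(size), strand, int(srcsize), text
    except ValueError as exc:
        raise FormatError(f"MAF line {lineno}: non-integer coordinate: {exc}") from None


def parse_maf(stream: Iterable[str]) -> list[Match]:
    """Convert pairwise MAF blocks to matches.

    Within a block the first s-line is the target, the second the query
    (the convention of pairwise aligners).  ``nmatch`` counts identical
    aligned non-gap column pairs (case-insensitive); ``blocklen`` counts all
    aligned columns.  Minus-strand coordinates are converted to forward
    coordinates via ``start_fwd = srcSize - start - size``.
    """
    matches: list[Match] = []
    block: list[tuple[int, str]] = []
    in_block = False

    def flush(block: list[tuple[int, str]]) -> None:
        s_lines = [(no, ln) for no, ln in block if ln.startswith("s")]
        if not s_lines:
            return
        if len(s_lines) != 2:
            raise FormatError(
                f"MAF block at line {block[0][0]}: expected exactly 2 s-lines, got {len(s_lines)}"
            )
        (tno, tline), (qno, qline) = s_lines
        tsrc, tstart, tsize, tstrand, tsrcsize, ttext = _maf_s_fields(tline, tno)
        qsrc, qstart, qsize, qstrand, qsrcsize, qtext = _maf_s_fields(qline, qno)
        if len(ttext) != len(qtext):
            raise FormatError(
                f"MAF block at line {tno}: aligned texts have different lengths"
            )
        nmatch = sum(
            1
            for a, b in zip(ttext.upper(), qtext.upper())
            if a != "-" and b != "-" and a == b
        )
        blocklen = len(ttext)
        if tstrand == "-":
            tstart = tsrcsize - tstart - tsize
        if qstrand == "-":
            qstart = qsrcsize - qstart - qsize
        strand = FORWARD if tstrand == qstrand else REVERSE
        matches.append(
            Match(
                qname=qsrc, qlen=qsrcsize, qstart=qstart, qend=qstart + qsize,
                strand=strand,
                tname=tsrc, tlen=tsrcsize, tstart=tstart, tend=tstart + tsize,
                nmatch=nmatch, blocklen=blocklen,
            )
        )

    for lineno, line in enumerate(stream, start=1):
        stripped = line.strip()
        if stripped.startswith("#"):
            continue
        if stripped.startswith("a") and (len(stripped) == 1 or stripped[1].isspace() or stripped[1] == "="):
            if in_block:
                flush(block)
            block, in_block = [], True
            continue
        if not stripped:
            if in_block:
                flush(block)
                block, in_block = [], False
            continue
        if in_block:
            block.append((lineno, stripped))
    if in_block:
        flush(block)
    return matches


# ---------------------------------------------------------------------------
# FASTA / .fai catalogs


def _is_gzip(path: str | os.PathLike) -> bool:
    with open(path, "rb") as fh:
        return fh.read(2) == b"\x1f\x8b"


def open_text_auto(path: str | os.PathLike) -> TextIO:
    """Open a text file, transparently decompressing gzip (detected by magic)."""
    if _is_gzip(path):
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="ascii")
    return open(path, "rt", encoding="ascii")


def read_catalog(path: str | os.PathLike) -> SequenceCatalog:
    """Read sequence names and lengths from FASTA, gzip-FASTA or a .fai index.

    FASTA lengths are residue counts ignoring whitespace.  Gzip is detected
    by magic bytes, not by extension.  Only columns 1-2 of a .fai are used.
    """
    with open_text_auto(path) as fh:
        first = fh.read(1)
        if not first:
            raise FormatError(f"{path}: empty file")
        fh.seek(0)
        if first == ">":
            entries = [(rec.id, len(rec.seq)) for rec in SeqIO.parse(fh, "fasta")]
        else:
            entries = []
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                fields = line.split("\t") if "\t" in line else line.split()
                if len(fields) < 2:
                    raise FormatError(f"{path} line {lineno}: not a FASTA index line")
                try:
                    entries.append((fields[0], int(fields[1])))
                except ValueError:
                    raise FormatError(
                        f"{path} line {lineno}: non-integer sequence length"
                    ) from None
    if not entries:
        raise FormatError(f"{path}: no sequences found")
    try:
        return SequenceCatalog(entries)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from None


def read_fasta_records(path: str | os.PathLike):
    """Yield Bio.SeqRecord objects from a plain or gzipped FASTA."""
    with open_text_auto(path) as fh:
        yield from SeqIO.parse(fh, "fasta")


# ---------------------------------------------------------------------------
# Extension registry

Validator = Callable[[str], bool]
Converter = Callable[[Iterable[str]], list[Match]]

_FORMATS: dict[str, tuple[Validator, Converter]] = {}


def _validate_paf(path: str) -> bool:
    try:
        with open_text_auto(path) as fh:
            parse_paf(fh)
        return True
    except (FormatError, UnicodeDecodeError):
        return False


def _validate_maf(path: str) -> bool:
    try:
        with open_text_auto(path) as fh:
            parse_maf(fh)
        return True
    except (FormatError, UnicodeDecodeError):
        return False


def register_format(extension: str, validator: Validator, converter: Converter) -> None:
    """Register a new alignment format keyed by file extension.

    The validator receives the file path and returns True when the file is
    well-formed; the converter receives a text line stream and returns the
    match list.  Built-in registrations are "paf" and "maf".
    """
    extension = extension.lower().lstrip(".")
    if extension in _FORMATS:
        raise ValueError(f"format {extension!r} already registered")
    _FORMATS[extension] = (validator, converter)


def registered_formats() -> list[str]:
    return sorted(_FORMATS)


def load_alignment(path: str | os.PathLike) -> list[Match]:
    """Load an alignment file, dispatching on its extension."""
    name = os.fspath(path)
    base = name[:-3] if name.endswith(".gz") else name
    ext = os.path.splitext(base)[1].lower().lstrip(".")
    if ext not in _FORMATS:
        raise FormatError(
            f"unsupported format {ext!r}; known extensions: {', '.join(registered_formats())}"
        )
    validator, converter = _FORMATS[ext]
    if not validator(name):
        raise FormatError(f"{name}: rejected by the {ext!r} format validator")
    with open_text_auto(name) as fh:
        return converter(fh)


_FORMATS["paf"] = (_validate_paf, parse_paf)
_FORMATS["maf"] = (_validate_maf, parse_maf)
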