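"""Core in-memory model: pairwise matches and sequence catalogs.

A :class:`Match` is one local alignment between a query and a target
sequence, in PAF conventions: 0-based half-open coordinates on the forward
strand of both sequences, with ``strand`` recording whether the query aligns
to the reverse complement of the target.  ``identity`` is the fraction of
matching residues over the alignment block length (PAF columns 10/11).

A :class:`SequenceCatalog` is the ordered list of (name, length) pairs for
one plot axis; the order is the axis order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator

FORWARD = "+"
REVERSE = "-"


@dataclass(frozen=True)
class Match:
    """One pairwise local alignment (PAF record semantics)."""

    qname: str
    qlen: int
    qstart: int
    qend: int
    strand: str  # "+" or "-"
    tname: str
    tlen: int
    tstart: int
    tend: int
    nmatch: int
    blocklen: int
    mapq: int = 255  # PAF mapping quality, preserved on round-trip, otherwise unused
    tags: tuple[str, ...] = ()  # opaque extra PAF columns, preserved on round-trip

    def __post_init__(self) -> None:
        if self.strand not in (FORWARD, REVERSE):
            raise ValueError(f"invalid strand {self.strand!r}")
        if not (0 <= self.qstart < self.qend <= self.qlen):
            raise ValueError(
                f"query interval [{self.qstart}, {self.qend}) out of bounds "
                f"for {self.qname!r} (length {self.qlen})"
            )
        if not (0 <= self.tstart < self.tend <= self.tlen):
            raise ValueError(
                f"target interval [{self.tstart}, {self.tend}) out of bounds "
                f"for {self.tname!r} (length {self.tlen})"
            )
        if self.blocklen < 1:
            raise ValueError("blocklen must be >= 1")
        if not (0 <= self.nmatch <= self.blocklen):
            raise ValueError("nmatch must lie in [0, blocklen]")

    @property
    def identity(self) -> float:
        """Fraction of matching residues over the alignment block length."""
        return self.nmatch / self.blocklen

    @property
    def size(self) -> int:
        """Match size used by size-based filters: the alignment block length."""
        return self.blocklen

    def replace(self, **changes) -> "Match":
        return replace(self, **changes)


class SequenceCatalog:
    """Ordered, name-unique collection of sequence lengths for one axis."""

    def __init__(self, entries: Iterable[tuple[str, int]]):
        self._names: list[str] = []
        self._lengths: dict[str, int] = {}
        for name, length in entries:
            if name in self._lengths:
                raise ValueError(f"duplicate sequence name {name!r}")
            if length < 1:
                raise ValueError(f"sequence {name!r} has non-positive length {length}")
            self._names.append(name)
            self._lengths[name] = int(length)

    @property
    def names(self) -> list[str]:
        return list(self._names)

    def length(self, name: str) -> int:
        return self._lengths[name]

    def __contains__(self, name: str) -> bool:
        return name in self._lengths

    def __len__(self) -> int:
        return len(self._names)

    def __iter__(self) -> Iterator[tuple[str, int]]:
        for name in self._names:
            yield name, self._lengths[name]

    def __eq__(self, other) -> bool:
        if not isinstance(other, SequenceCatalog):
            return NotImplemented
        return list(self) == list(other)

    def __repr__(self) -> str:
        return f"SequenceCatalog({list(self)!r})"

    @property
    def total_length(self) -> int:
        return sum(self._lengths.values())

    def index(self, name: str) -> int:
        return self._names.index(name)

    def reordered(self, names: Iterable[str]) -> "SequenceCatalog":
        """New catalog with the same lengths in the given order."""
        names = list(names)
        if sorted(names) != sorted(self._names):
            raise ValueError("reordering must be a permutation of the catalog names")
        return SequenceCatalog((n, self._lengths[n]) for n in names)
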