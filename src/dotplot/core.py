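"""Dot-plot state: matches, catalogs, identity classes and axis layout.

The plot binds a match list to a query catalog (y axis) and a target
catalog (x axis).  Match identities are binned into four classes
(< 25%, 25-50%, 50-75%, >= 75%) which drive coloring and the summary
profile.  The axis layout concatenates the catalog sequences, merging runs
of successive tiny sequences (< 0.2% of the axis by default) into grayed
super-sequences, and only the 100,000 largest alignments are ever plotted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import IntEnum
from typing import Iterable, Optional, Sequence

from .model import FORWARD, REVERSE, Match, SequenceCatalog

DEFAULT_CAP = 100_000
DEFAULT_MERGE_FRACTION = 0.002


class IdentityClass(IntEnum):
    """Similarity bins: <25%, 25-50%, 50-75%, >=75%."""

    CLASS1 = 1  # identity < 0.25
    CLASS2 = 2  # 0.25 <= identity < 0.50
    CLASS3 = 3  # 0.50 <= identity < 0.75
    CLASS4 = 4  # identity >= 0.75


def identity_class(identity: float) -> IdentityClass:
    """Bin an identity ratio; boundaries belong to the upper class."""
    if not 0.0 <= identity <= 1.0:
        raise ValueError(f"identity {identity} outside [0, 1]")
    if identity < 0.25:
        return IdentityClass.CLASS1
    if identity < 0.50:
        return IdentityClass.CLASS2
    if identity < 0.75:
        return IdentityClass.CLASS3
    return IdentityClass.CLASS4


@dataclass
class Filters:
    """Active match-level display filters."""

    min_identity: Optional[float] = None
    min_size: Optional[int] = None
    hidden_classes: frozenset[IdentityClass] = frozenset()


@dataclass
class DotPlot:
    """A validated dot plot: matches plus the catalogs of both axes."""

    matches: list[Match]
    query: SequenceCatalog
    target: SequenceCatalog
    sorted: bool = False
    noise_filtered: bool = False
    filters: Filters = field(default_factory=Filters)

    def with_matches(self, matches: list[Match]) -> "DotPlot":
        return replace(self, matches=list(matches))


def build_dotplot(
    matches: Iterable[Match], query: SequenceCatalog, target: SequenceCatalog
) -> DotPlot:
    """Validate matches against both catalogs and assemble the plot."""
    checked: list[Match] = []
    for m in matches:
        if m.qname not in query:
            raise ValueError(f"unknown query sequence {m.qname!r}")
        if m.tname not in target:
            raise ValueError(f"unknown target sequence {m.tname!r}")
        if m.qend > query.length(m.qname):
            raise ValueError(
                f"match on {m.qname!r} ends at {m.qend}, beyond catalog length "
                f"{query.length(m.qname)}"
            )
        if m.tend > target.length(m.tname):
            raise ValueError(
                f"match on {m.tname!r} ends at {m.tend}, beyond catalog length "
                f"{target.length(m.tname)}"
            )
        checked.append(m)
    return DotPlot(matches=checked, query=query, target=target)


def cap_largest(matches: Sequence[Match], cap: int = DEFAULT_CAP) -> list[Match]:
    """Keep the ``cap`` largest matches by block length, in input order.

    Ties at the threshold are broken by input order (stable), so re-running
    on the output is the identity.
    """
    if cap < 0:
        raise ValueError("cap must be >= 0")
    if len(matches) <= cap:
        return list(matches)
    ranked = sorted(range(len(matches)), key=lambda i: (-matches[i].blocklen, i))
    keep = sorted(ranked[:cap])
    return [matches[i] for i in keep]


def remove_self_matches(matches: Iterable[Match]) -> list[Match]:
    """Drop trivial self-alignment diagonals (same sequence, same positions).

    Only forward-strand identity matches are trivial; a reverse-strand match
    over the same positions marks an inverted repeat and is kept.
    """
    return [
        m
        for m in matches
        if not (
            m.strand == FORWARD
            and m.qname == m.tname
            and m.qstart == m.tstart
            and m.qend == m.tend
        )
    ]


@dataclass(frozen=True)
class AxisGroup:
    """One axis tick group: a sequence or a grayed super-sequence."""

    names: tuple[str, ...]
    offset: int
    length: int
    grayed: bool

    @property
    def label(self) -> str:
        return self.names[0] if len(self.names) == 1 else f"[{len(self.names)} seqs]"


@dataclass(frozen=True)
class AxisLayout:
    groups: tuple[AxisGroup, ...]
    total_length: int
    offsets: dict[str, int]  # per-sequence cumulative offset on the axis

    def offset(self, name: str) -> int:
        return self.offsets[name]


def layout_axis(
    catalog: SequenceCatalog, merge_fraction: float = DEFAULT_MERGE_FRACTION
) -> AxisLayout:
    """Lay out one axis, merging runs of successive tiny sequences.

    Maximal runs of >= 2 successive sequences each shorter than
    ``merge_fraction`` of the axis total become a single grayed
    super-sequence group; all other sequences are singleton groups.
    Within-group and between-group order follows the catalog.
    """
    if len(catalog) == 0:
        raise ValueError("cannot lay out an empty catalog")
    total = catalog.total_length
    threshold = merge_fraction * total
    entries = list(catalog)

    runs: list[tuple[list[tuple[str, int]], bool]] = []
    current: list[tuple[str, int]] = []
    for name, length in entries:
        small = length < threshold
        if small:
            current.append((name, length))
        else:
            if current:
                runs.append((current, True))
                current = []
            runs.append(([(name, length)], False))
    if current:
        runs.append((current, True))

    groups: list[AxisGroup] = []
    offsets: dict[str, int] = {}
    pos = 0
    for members, small in runs:
        if small and len(members) >= 2:
            glen = sum(l for _, l in members)
            inner = pos
            for name, length in members:
                offsets[name] = inner
                inner += length
            groups.append(
                AxisGroup(names=tuple(n for n, _ in members), offset=pos, length=glen, grayed=True)
            )
            pos += glen
        else:
            for name, length in members:
                offsets[name] = pos
                groups.append(AxisGroup(names=(name,), offset=pos, length=length, grayed=False))
                pos += length
    return AxisLayout(groups=tuple(groups), total_length=total, offsets=offsets)


@dataclass(frozen=True)
class PlottedSegment:
    """A match placed in concatenated-axis coordinates (x = target, y = query)."""

    x1: float
    y1: float
    x2: float
    y2: float
    identity: float
    match: Match


def global_coordinates(
    plot: DotPlot, layout_q: AxisLayout, layout_t: AxisLayout,
    matches: Optional[Sequence[Match]] = None,
) -> list[PlottedSegment]:
    """Map matches to line segments on the concatenated axes.

    Forward matches run diagonally (x and y both increasing); reverse
    matches anti-diagonally (x decreasing as y increases).
    """
    segments = []
    for m in plot.matches if matches is None else matches:
        ox = layout_t.offset(m.tname)
        oy = layout_q.offset(m.qname)
        if m.strand == FORWARD:
            x1, x2 = m.tstart + ox, m.tend + ox
        else:
            x1, x2 = m.tend + ox, m.tstart + ox
        segments.append(
            PlottedSegment(
                x1=x1, y1=m.qstart + oy, x2=x2, y2=m.qend + oy,
                identity=m.identity, match=m,
            )
        )
    return segments


def visible_matches(plot: DotPlot, cap: int = DEFAULT_CAP) -> list[Match]:
    """Matches surviving the active filters and the largest-alignment cap."""
    from .filters import filter_identity, filter_min_size  # cycle-free at call time

    kept = plot.matches
    f = plot.filters
    if f.min_identity is not None or f.hidden_classes:
        kept = filter_identity(kept, f.min_identity or 0.0, f.hidden_classes)
    if f.min_size is not None:
        kept = filter_min_size(kept, f.min_size)
    return cap_largest(kept, cap)
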