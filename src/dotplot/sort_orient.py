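"""Order and orient query sequences along the reference.

Each query contig is assigned to the reference sequence carrying the
largest share of its aligned bases, oriented to the strand carrying the
majority of those bases, and placed at the block-length-weighted mean
midpoint of its matches on that reference.  Sorting the query axis by
(reference order, position) maximizes the visual diagonal; the derived
association table links each query to its reference.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, TextIO

from .core import DotPlot
from .model import FORWARD, REVERSE, Match, SequenceCatalog


@dataclass(frozen=True)
class QueryAssignment:
    query: str
    target: str | None  # None for unaligned queries
    orientation: str  # "+" or "-"
    order_key: tuple[int, float] | None  # (target catalog index, weighted midpoint)


@dataclass(frozen=True)
class SortPlan:
    assignments: tuple[QueryAssignment, ...]  # in final sorted order
    original_order: tuple[str, ...]  # query catalog order before sorting

    @property
    def sorted_names(self) -> list[str]:
        return [a.query for a in self.assignments]

    def assignment(self, qname: str) -> QueryAssignment:
        for a in self.assignments:
            if a.query == qname:
                return a
        raise KeyError(qname)


def compute_sort_plan(plot: DotPlot) -> SortPlan:
    """Assign, orient and order every query sequence against the reference.

    Assignment maximizes summed block length per target (ties to the first
    target in catalog order); orientation is reverse iff reverse-strand
    matches to the assigned target carry more aligned bases than forward
    ones; position is the block-length-weighted mean of target-interval
    midpoints.  Queries without matches follow all assigned queries in
    their original relative order.
    """
    by_query: dict[str, list[Match]] = {name: [] for name in plot.query.names}
    for m in plot.matches:
        by_query[m.qname].append(m)

    target_index = {name: i for i, name in enumerate(plot.target.names)}
    assigned: list[QueryAssignment] = []
    unaligned: list[QueryAssignment] = []
    for qname in plot.query.names:
        ms = by_query[qname]
        if not ms:
            unaligned.append(QueryAssignment(qname, None, FORWARD, None))
            continue
        weight: dict[str, int] = {}
        for m in ms:
            weight[m.tname] = weight.get(m.tname, 0) + m.blocklen
        best = min(weight, key=lambda t: (-weight[t], target_index[t]))
        on_best = [m for m in ms if m.tname == best]
        fwd = sum(m.blocklen for m in on_best if m.strand == FORWARD)
        rev = sum(m.blocklen for m in on_best if m.strand == REVERSE)
        orientation = REVERSE if rev > fwd else FORWARD
        total = sum(m.blocklen for m in on_best)
        position = sum(m.blocklen * (m.tstart + m.tend) / 2 for m in on_best) / total
        assigned.append(
            QueryAssignment(qname, best, orientation, (target_index[best], position))
        )

    assigned.sort(key=lambda a: a.order_key)
    return SortPlan(
        assignments=tuple(assigned + unaligned),
        original_order=tuple(plot.query.names),
    )


def _mirror(m: Match) -> Match:
    return m.replace(
        qstart=m.qlen - m.qend,
        qend=m.qlen - m.qstart,
        strand=REVERSE if m.strand == FORWARD else FORWARD,
    )


def apply_sort(plot: DotPlot, plan: SortPlan) -> DotPlot:
    """Reorder the query catalog per the plan and mirror reversed queries."""
    if sorted(plan.sorted_names) != sorted(plot.query.names):
        raise ValueError("sort plan does not cover the plot's query catalog")
    reversed_queries = {a.query for a in plan.assignments if a.orientation == REVERSE}
    matches = [_mirror(m) if m.qname in reversed_queries else m for m in plot.matches]
    return replace(
        plot,
        matches=matches,
        query=plot.query.reordered(plan.sorted_names),
        sorted=True,
    )


def unsort(plot: DotPlot, plan: SortPlan) -> DotPlot:
    """Restore the original catalog order and orientations exactly."""
    reversed_queries = {a.query for a in plan.assignments if a.orientation == REVERSE}
    matches = [_mirror(m) if m.qname in reversed_queries else m for m in plot.matches]
    return replace(
        plot,
        matches=matches,
        query=plot.query.reordered(plan.original_order),
        sorted=False,
    )


def reverse_query(plot: DotPlot, qname: str) -> DotPlot:
    """Mirror one query's matches in place; catalog order is unchanged."""
    if qname not in plot.query:
        raise KeyError(f"unknown query sequence {qname!r}")
    matches = [_mirror(m) if m.qname == qname else m for m in plot.matches]
    return replace(plot, matches=matches)


def association_table(plan: SortPlan) -> list[tuple[str, str]]:
    """One (query, reference-or-None) row per query, in plan order."""
    return [(a.query, a.target if a.target is not None else "None") for a in plan.assignments]


def write_association_table(plan: SortPlan, stream: TextIO) -> None:
    stream.write("Query\tTarget\n")
    for query, target in association_table(plan):
        stream.write(f"{query}\t{target}\n")
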