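"""Reference identity profile: fraction of reference bases per similarity class.

The profile sums match projections on the reference per identity class and
divides by the total reference length.  It is computed on a working copy of
the plot after sorting the query along the reference, removing matches whose
reference interval is contained in another match's interval, and noise
filtering; the displayed plot itself is untouched.  Where surviving matches
overlap, each reference base counts once, for its highest covering class.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Sequence, TextIO

from .core import DotPlot, IdentityClass, identity_class
from .filters import noise_filter
from .model import Match
from .sort_orient import apply_sort, compute_sort_plan


def remove_included(matches: Sequence[Match]) -> list[Match]:
    """Drop matches whose reference interval lies inside another's.

    Containment is judged on the reference axis only, per reference
    sequence.  Equal intervals keep the highest-identity match (first on
    tie).  Input order is preserved in the output.
    """
    by_target: dict[str, list[int]] = {}
    for i, m in enumerate(matches):
        by_target.setdefault(m.tname, []).append(i)

    drop: set[int] = set()
    for idxs in by_target.values():
        # Collapse duplicated intervals first: keep max identity, first on tie.
        best_for_interval: dict[tuple[int, int], int] = {}
        for i in idxs:
            key = (matches[i].tstart, matches[i].tend)
            j = best_for_interval.get(key)
            if j is None or matches[i].identity > matches[j].identity:
                if j is not None:
                    drop.add(j)
                best_for_interval[key] = i
            else:
                drop.add(i)
        survivors = [i for i in idxs if i not in drop]
        # Sweep in (start asc, end desc) order: any interval ending at or
        # before the running max end is contained in an earlier interval.
        survivors.sort(key=lambda i: (matches[i].tstart, -matches[i].tend))
        max_end = -1
        for i in survivors:
            if matches[i].tend <= max_end:
                drop.add(i)
            else:
                max_end = matches[i].tend
    return [m for i, m in enumerate(matches) if i not in drop]


@dataclass(frozen=True)
class SummaryProfile:
    """Per-class reference coverage fractions plus the uncovered fraction."""

    fractions: dict[IdentityClass, float]
    no_match: float
    total_reference: int

    def to_json(self) -> str:
        payload = {f"class{int(c)}": self.fractions[c] for c in IdentityClass}
        payload["no_match"] = self.no_match
        payload["total_reference"] = self.total_reference
        return json.dumps(payload, indent=2)

    def write_tsv(self, stream: TextIO) -> None:
        labels = {
            IdentityClass.CLASS1: "<25%",
            IdentityClass.CLASS2: "25-50%",
            IdentityClass.CLASS3: "50-75%",
            IdentityClass.CLASS4: ">75%",
        }
        stream.write("class\tpercent\n")
        for c in IdentityClass:
            stream.write(f"{labels[c]}\t{100 * self.fractions[c]:.6g}\n")
        stream.write(f"no match\t{100 * self.no_match:.6g}\n")


def _class_base_counts(
    matches: Iterable[Match], target
) -> dict[IdentityClass, int]:
    """Count reference bases per class, each base once at its highest class."""
    by_target: dict[str, list[Match]] = {}
    for m in matches:
        by_target.setdefault(m.tname, []).append(m)

    covered = {c: 0 for c in IdentityClass}
    for tname, ms in by_target.items():
        events: list[tuple[int, int, IdentityClass]] = [
            (m.tstart, m.tend, identity_class(m.identity)) for m in ms
        ]
        points = sorted({p for s, e, _ in events for p in (s, e)})
        for lo, hi in zip(points, points[1:]):
            best = None
            for s, e, c in events:
                if s <= lo and hi <= e and (best is None or c > best):
                    best = c
            if best is not None:
                covered[best] += hi - lo
    return covered


def summary_profile(plot: DotPlot) -> SummaryProfile:
    """Compute the reference identity profile on a working copy of the plot.

    Pipeline: sort the query along the reference, remove included matches,
    noise-filter, then count each reference base once for the highest
    identity class covering it.  Fractions divide the integer base counts by
    the total reference length once at the end, so they sum to 1 exactly.
    """
    working = apply_sort(plot, compute_sort_plan(plot))
    kept = remove_included(working.matches)
    kept, _ = noise_filter(kept)

    total = plot.target.total_length
    covered = _class_base_counts(kept, plot.target)
    covered_total = sum(covered.values())
    fractions = {c: covered[c] / total for c in IdentityClass}
    return SummaryProfile(
        fractions=fractions,
        no_match=(total - covered_total) / total,
        total_reference=total,
    )
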