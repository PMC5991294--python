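"""Match-level filters: the size-histogram noise filter plus simple cutoffs.

A match is considered noise when it is small and its size is very frequent.
The noise filter bins matches by block length into floor(N/10) equal-width
bins, finds the most represented bin scanning in increasing size order, then
scans upward for the first bin whose count has fallen to 1% of the modal
count; every match in a bin strictly below that cutoff is discarded.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Iterable, Optional, Sequence

from .core import IdentityClass, identity_class
from .model import Match


@dataclass(frozen=True)
class NoiseFilterReport:
    """Diagnostics from one noise-filter run."""

    n_bins: int
    bin_edges: tuple[float, ...]
    modal_bin: Optional[int]
    cutoff_bin: Optional[int]
    removed: int
    kept: int

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def _no_op_report(n: int, n_bins: int = 0) -> NoiseFilterReport:
    return NoiseFilterReport(
        n_bins=n_bins, bin_edges=(), modal_bin=None, cutoff_bin=None, removed=0, kept=n
    )


def noise_filter(matches: Sequence[Match]) -> tuple[list[Match], NoiseFilterReport]:
    """Remove abundant small matches below a data-driven size cutoff.

    Procedure: (1) bin block lengths into floor(N/10) equal-width bins over
    [min, max]; (2) take the first bin of maximal count, scanning in
    increasing size order, as the modal bin; (3) from there scan upward for
    the first bin with count <= 1% of the modal count; (4) drop every match
    in bins strictly below that one.  With fewer than 20 matches (fewer than
    2 bins), a degenerate size range, or no bin satisfying step 3, nothing
    is removed.
    """
    matches = list(matches)
    n = len(matches)
    n_bins = n // 10
    if n_bins < 2:
        return matches, _no_op_report(n, max(1, n_bins))

    sizes = [m.blocklen for m in matches]
    lo, hi = min(sizes), max(sizes)
    if lo == hi:
        return matches, _no_op_report(n, n_bins)

    width = (hi - lo) / n_bins
    edges = tuple(lo + i * width for i in range(n_bins + 1))

    def bin_of(size: int) -> int:
        return min(n_bins - 1, int((size - lo) / width))

    counts = [0] * n_bins
    for s in sizes:
        counts[bin_of(s)] += 1

    modal = max(range(n_bins), key=lambda i: (counts[i], -i))
    threshold = 0.01 * counts[modal]
    cutoff = None
    for i in range(modal + 1, n_bins):
        if counts[i] <= threshold:
            cutoff = i
            break
    if cutoff is None:
        return matches, NoiseFilterReport(
            n_bins=n_bins, bin_edges=edges, modal_bin=modal, cutoff_bin=None,
            removed=0, kept=n,
        )

    kept = [m for m in matches if bin_of(m.blocklen) >= cutoff]
    return kept, NoiseFilterReport(
        n_bins=n_bins, bin_edges=edges, modal_bin=modal, cutoff_bin=cutoff,
        removed=n - len(kept), kept=len(kept),
    )


def filter_identity(
    matches: Iterable[Match],
    min_identity: float = 0.0,
    hidden_classes: frozenset[IdentityClass] | set[IdentityClass] = frozenset(),
) -> list[Match]:
    """Keep matches with identity >= min_identity whose class is not hidden."""
    if not 0.0 <= min_identity <= 1.0:
        raise ValueError("min_identity must lie in [0, 1]")
    return [
        m
        for m in matches
        if m.identity >= min_identity and identity_class(m.identity) not in hidden_classes
    ]


def filter_min_size(matches: Iterable[Match], min_size: int) -> list[Match]:
    """Keep matches whose block length is at least ``min_size``."""
    if min_size < 0:
        raise ValueError("min_size must be >= 0")
    return [m for m in matches if m.blocklen >= min_size]
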