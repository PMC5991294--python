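"""Synthetic genome pairs with planted rearrangements and exact ground truth.

The generator builds a reference from random nucleotide fragments and a
query by permuting those fragments, reverse-complementing a subset, and
applying point substitutions at rate 1 - identity.  Because every edit is a
substitution, ground-truth match coordinates are exact: each query contig
aligns to its source fragment's reference interval end to end, on the
planted strand, with nmatch equal to the number of unmutated positions.

An optional thin wrapper runs minimap2 (or any aligner declared in a
tools.yaml-style file) on the generated FASTA files; the aligner itself is
never reimplemented.
"""

from __future__ import annotations

import os
import shlex
import subprocess
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import yaml
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import FORWARD, REVERSE, Match, SequenceCatalog

_ALPHABET = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class RearrangementPlan:
    """Recipe for one synthetic genome pair.

    Defaults describe a mid-size assembly comparison: a dozen 50 kb
    fragments at 95% identity, no planted noise.
    """

    seed: int = 0
    n_fragments: int = 12
    fragment_length: int = 50_000
    permutation: Optional[tuple[int, ...]] = None  # None = random
    reversed_set: Optional[frozenset[int]] = None  # None = random subset
    identity: float = 0.95
    noise_matches: int = 0
    noise_size_range: tuple[int, int] = (20, 200)

    def __post_init__(self):
        if not 0.0 < self.identity <= 1.0:
            raise ValueError("identity must lie in (0, 1]")
        if self.permutation is not None and sorted(self.permutation) != list(
            range(self.n_fragments)
        ):
            raise ValueError("permutation must be a bijection over fragments")


@dataclass
class SimulatedPair:
    reference: list[SeqRecord]
    query: list[SeqRecord]
    truth: list[Match]
    plan: RearrangementPlan
    permutation: tuple[int, ...]
    reversed_set: frozenset[int]

    @property
    def reference_catalog(self) -> SequenceCatalog:
        return SequenceCatalog((r.id, len(r.seq)) for r in self.reference)

    @property
    def query_catalog(self) -> SequenceCatalog:
        return SequenceCatalog((r.id, len(r.seq)) for r in self.query)

    def write(self, ref_path, query_path) -> None:
        from Bio import SeqIO

        with open(ref_path, "wt") as fh:
            SeqIO.write(self.reference, fh, "fasta")
        with open(query_path, "wt") as fh:
            SeqIO.write(self.query, fh, "fasta")


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return _ALPHABET[rng.integers(0, 4, size=length)]


def _mutate(rng: np.random.Generator, seq: np.ndarray, rate: float) -> tuple[np.ndarray, int]:
    """Substitute bases at the given rate; returns (mutated copy, n changed)."""
    if rate <= 0:
        return seq.copy(), 0
    mask = rng.random(len(seq)) < rate
    idx = np.flatnonzero(mask)
    out = seq.copy()
    for i in idx:
        choices = _ALPHABET[_ALPHABET != out[i]]
        out[i] = choices[rng.integers(0, 3)]
    return out, len(idx)


_COMPLEMENT = bytes.maketrans(b"ACGT", b"TGCA")


def _revcomp(seq: np.ndarray) -> np.ndarray:
    return np.frombuffer(seq.tobytes().translate(_COMPLEMENT), dtype=np.uint8)[::-1].copy()


def generate_pair(plan: RearrangementPlan) -> SimulatedPair:
    """Generate (reference, query, ground-truth matches) from a plan.

    The reference is one sequence, "ref", of ``n_fragments`` concatenated
    fragments; the query has one contig per fragment, named after its
    position in the query ("q<k>").  Optional noise matches with small
    block lengths emulate spurious aligner hits.
    """
    rng = np.random.default_rng(plan.seed)
    n, L = plan.n_fragments, plan.fragment_length
    fragments = [_random_seq(rng, L) for _ in range(n)]
    reference = np.concatenate(fragments)

    if plan.permutation is None:
        permutation = tuple(int(i) for i in rng.permutation(n))
    else:
        permutation = plan.permutation
    if plan.reversed_set is None:
        reversed_set = frozenset(int(i) for i in range(n) if rng.random() < 0.5)
    else:
        reversed_set = frozenset(plan.reversed_set)

    ref_record = SeqRecord(Seq(reference.tobytes().decode("ascii")), id="ref", description="")
    query_records: list[SeqRecord] = []
    truth: list[Match] = []
    rate = 1.0 - plan.identity
    for k, frag_idx in enumerate(permutation):
        mutated, n_mut = _mutate(rng, fragments[frag_idx], rate)
        strand = REVERSE if frag_idx in reversed_set else FORWARD
        if strand == REVERSE:
            mutated = _revcomp(mutated)
        qname = f"q{k}"
        query_records.append(
            SeqRecord(Seq(mutated.tobytes().decode("ascii")), id=qname, description="")
        )
        truth.append(
            Match(
                qname=qname, qlen=L, qstart=0, qend=L,
                strand=strand,
                tname="ref", tlen=n * L, tstart=frag_idx * L, tend=(frag_idx + 1) * L,
                nmatch=L - n_mut, blocklen=L,
            )
        )

    for _ in range(plan.noise_matches):
        size = int(rng.integers(plan.noise_size_range[0], plan.noise_size_range[1] + 1))
        k = int(rng.integers(0, n))
        qpos = int(rng.integers(0, L - size))
        tpos = int(rng.integers(0, n * L - size))
        truth.append(
            Match(
                qname=f"q{k}", qlen=L, qstart=qpos, qend=qpos + size,
                strand=FORWARD if rng.random() < 0.5 else REVERSE,
                tname="ref", tlen=n * L, tstart=tpos, tend=tpos + size,
                nmatch=max(1, int(size * 0.3)), blocklen=size,
            )
        )

    return SimulatedPair(
        reference=[ref_record], query=query_records, truth=truth,
        plan=plan, permutation=permutation, reversed_set=reversed_set,
    )


def simulate_catalogs(
    seed: int,
    n_query: int = 5,
    n_target: int = 3,
    min_length: int = 1_000_000,
    max_length: int = 30_000_000,
    matches_per_query: int = 4,
) -> tuple[SequenceCatalog, SequenceCatalog, list[Match]]:
    """Random catalogs plus consistent diagonal matches, without residues.

    Useful for exercising chunking and coordinate arithmetic at
    chromosome scale where materializing sequence would be wasteful.
    """
    rng = np.random.default_rng(seed)
    query = SequenceCatalog(
        (f"q{i}", int(rng.integers(min_length, max_length + 1))) for i in range(n_query)
    )
    target = SequenceCatalog(
        (f"t{i}", int(rng.integers(min_length, max_length + 1))) for i in range(n_target)
    )
    matches: list[Match] = []
    for qname, qlen in query:
        for _ in range(matches_per_query):
            span = int(rng.integers(1_000, max(2_000, qlen // 2)))
            qstart = int(rng.integers(0, qlen - span))
            tname = f"t{int(rng.integers(0, n_target))}"
            tlen = target.length(tname)
            tspan = min(span, tlen - 1)
            tstart = int(rng.integers(0, tlen - tspan))
            blocklen = span
            matches.append(
                Match(
                    qname=qname, qlen=qlen, qstart=qstart, qend=qstart + span,
                    strand=FORWARD if rng.random() < 0.5 else REVERSE,
                    tname=tname, tlen=tlen, tstart=tstart, tend=tstart + tspan,
                    nmatch=int(blocklen * 0.9), blocklen=blocklen,
                )
            )
    return query, target, matches


# ---------------------------------------------------------------------------
# External aligner wrapper


@dataclass(frozen=True)
class ToolConfig:
    name: str
    exec_path: str
    command_line: str  # skeleton with {exe} {target} {query} {out} {threads} placeholders
    threads: int = 1
    max_memory: Optional[int] = None  # advisory, recorded only

    @classmethod
    def from_yaml(cls, path: str | os.PathLike, name: str = "minimap2") -> "ToolConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if name not in data:
            raise KeyError(f"tool {name!r} not declared in {path}")
        entry = data[name]
        return cls(
            name=name,
            exec_path=entry["exec"],
            command_line=entry["command_line"],
            threads=int(entry.get("threads", 1)),
            max_memory=entry.get("max_memory"),
        )


DEFAULT_MINIMAP2 = ToolConfig(
    name="minimap2",
    exec_path="minimap2",
    command_line="{exe} -t {threads} {target} {query}",
    threads=1,
)


def run_minimap2(
    query: str | os.PathLike, target: str | os.PathLike, out_paf: str | os.PathLike,
    tool: ToolConfig = DEFAULT_MINIMAP2,
) -> str:
    """Run the external aligner with its default parameters, writing PAF.

    Raises a clear error when the executable is missing or exits non-zero.
    """
    cmd = shlex.split(
        tool.command_line.format(
            exe=tool.exec_path, query=os.fspath(query), target=os.fspath(target),
            threads=tool.threads, out=os.fspath(out_paf),
        )
    )
    try:
        proc = subprocess.run(cmd, capture_output=True, text=True)
    except FileNotFoundError:
        raise RuntimeError(
            f"aligner executable {tool.exec_path!r} not found on PATH; install it "
            "or point a tools.yaml entry at it"
        ) from None
    if proc.returncode != 0:
        raise RuntimeError(
            f"{tool.name} exited with status {proc.returncode}: {proc.stderr[:500]}"
        )
    with open(out_paf, "wt") as fh:
        fh.write(proc.stdout)
    return os.fspath(out_paf)
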