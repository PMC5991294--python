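import random

import pytest

from dotplot.model import FORWARD, Match, SequenceCatalog


def make_match(
    qname="q1", qlen=1000, qstart=0, qend=500, strand=FORWARD,
    tname="t1", tlen=2000, tstart=100, tend=600, nmatch=450, blocklen=500,
    **kw,
):
    return Match(
        qname=qname, qlen=qlen, qstart=qstart, qend=qend, strand=strand,
        tname=tname, tlen=tlen, tstart=tstart, tend=tend,
        nmatch=nmatch, blocklen=blocklen, **kw,
    )


@pytest.fixture
def mk():
    return make_match


def random_matches(rng: random.Random, n: int, tlen: int = 10_000, qlen: int = 10_000,
                   n_targets: int = 2, n_queries: int = 3, max_span: int = 2_000):
    """Random valid matches over small catalogs, for property tests."""
    out = []
    for _ in range(n):
        span = rng.randint(1, max_span)
        qstart = rng.randint(0, qlen - span)
        tspan = rng.randint(1, max_span)
        tstart = rng.randint(0, tlen - tspan)
        blocklen = max(span, tspan)
        out.append(
            Match(
                qname=f"q{rng.randrange(n_queries)}", qlen=qlen,
                qstart=qstart, qend=qstart + span,
                strand=rng.choice("+-"),
                tname=f"t{rng.randrange(n_targets)}", tlen=tlen,
                tstart=tstart, tend=tstart + tspan,
                nmatch=rng.randint(0, blocklen), blocklen=blocklen,
            )
        )
    return out


def small_catalogs(n_queries: int = 3, n_targets: int = 2, qlen: int = 10_000,
                   tlen: int = 10_000):
    query = SequenceCatalog((f"q{i}", qlen) for i in range(n_queries))
    target = SequenceCatalog((f"t{i}", tlen) for i in range(n_targets))
    return query, target


@pytest.fixture
def toy_fasta(tmp_path):
    path = tmp_path / "toy.fasta"
    path.write_text(">a\nACGT\n>b\nAC\n")
    return path
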