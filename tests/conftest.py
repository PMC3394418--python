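"""Shared fixtures and instance generators for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from hapweave.alignment import AlignedRead, MultipleAlignment
from hapweave.snps import SnpSet


def make_aln(reads, length=None, name="aln"):
    """Build an alignment from (id, start, bases) triples."""
    rs = [AlignedRead(i, s, b) for i, s, b in reads]
    if length is None:
        length = max((r.end for r in rs), default=0)
    return MultipleAlignment(length, rs, name=name)


def random_snp_instance(rng, n_cols=None, n_reads=None, n_alleles=2):
    """A random alignment whose columns are all SNP columns.

    Reads are gapless random spans with random alleles drawn from the first
    ``n_alleles`` bases per column, giving dense conflict structure.
    """
    m = int(n_cols if n_cols is not None else rng.integers(3, 8))
    n = int(n_reads if n_reads is not None else rng.integers(4, 15))
    alphabet = "ACGT"[:n_alleles]
    reads = []
    for i in range(n):
        start = int(rng.integers(0, m))
        length = int(rng.integers(1, m - start + 1))
        bases = "".join(rng.choice(list(alphabet), size=length))
        reads.append((f"r{i}", start, bases))
    aln = make_aln(reads, length=m)
    return aln, SnpSet(tuple(range(m)))


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def figure_dag():
    """A 4-node transitive DAG with two minimum path covers, only one of
    which isolates a singleton: arcs a->b, b->c, a->c, a->d.

    Both {a,b,c}+{d} and {a,d}+{b,c} are 2-chain covers, but only the first
    has a single-node chain — the weighted matching must return it.
    """
    from hapweave.haplotyping import CompatibilityDag, SnpProfile

    # profiles over 4 SNP columns reproducing exactly those arcs:
    # a=cols0-3:AAAA, b=cols0-1:AA, c=cols2-3:AA, d=cols1-2:AT
    # conflicts: b-d (col1 A vs A?) ... build adjacency directly instead.
    prof = [
        SnpProfile("a", np.array([0, 0, 0, 0], dtype=np.int8), 0, 3),
        SnpProfile("b", np.array([0, 0, -1, -1], dtype=np.int8), 0, 1),
        SnpProfile("c", np.array([-1, -1, 0, 0], dtype=np.int8), 2, 3),
        SnpProfile("d", np.array([-1, 3, 3, -1], dtype=np.int8), 1, 2),
    ]
    adj = np.zeros((4, 4), dtype=bool)
    order = {"a": 0, "b": 1, "c": 2, "d": 3}
    for x, y in [("a", "b"), ("b", "c"), ("a", "c"), ("a", "d")]:
        adj[order[x], order[y]] = True
    return CompatibilityDag(prof, adj)
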