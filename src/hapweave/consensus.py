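"""Minimum-chimerism consensus reconstruction and chimerism evaluation.

A full-length consensus is stitched from the assembled haplotype regions:
non-SNP loci take the whole-alignment majority vote, and at SNP loci a
dynamic program chooses, for each SNP in order, the region providing the
allele. A "possible crossover" is a pair of adjacent SNPs that no single
region supports (covers and agrees with) at both — the consensus must
switch source haplotypes somewhere in between. The DP therefore charges a
transition only when the adjacent allele pair has no joint supporter, and
optimizes three criteria of decreasing importance: fewest possible
crossovers, largest total supporting read coverage of the alleles used,
fewest distinct regions.

The same accounting evaluates the chimerism of *any* consensus against a
reference set (true haplotypes or assembled regions): with the consensus
fixed, the minimum number of crossovers is simply the number of adjacent
evaluation-SNP pairs that no single reference covers and agrees with at
both. An allele no reference explains is charged on both sides (two
crossovers at interior loci, one at a boundary).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .alignment import GAP, HaplotypeSet, MultipleAlignment
from .haplotyping import HaplotypeRegion, majority_string
from .snps import SnpSet

__all__ = [
    "SupportTable",
    "ConsensusResult",
    "ChimerismReport",
    "build_support_table",
    "reconstruct_consensus",
    "evaluate_consensus",
    "true_vs_estimated_crossovers",
    "majority_vote_consensus",
]

# criterion-3 exact pass falls back to min-cardinality pruning above this
_STATE_CAP = 100_000


@dataclass
class SupportTable:
    """Per-SNP support: which regions cover each SNP, with what allele and
    how many member reads backing that allele."""

    snp_cols: list[int]
    # per SNP: list of (region index, allele, supporting read count)
    entries: list[list[tuple[int, str, int]]]
    # per adjacent SNP pair (i-1, i): allele pairs some single region covers
    # and carries at both columns
    pair_support: list[set[tuple[str, str]]]


def build_support_table(
    regions: Sequence[HaplotypeRegion], snps: SnpSet
) -> SupportTable:
    cols = list(snps)
    entries = []
    for col in cols:
        row = []
        for ri, reg in enumerate(regions):
            if reg.covers(col):
                allele = reg.allele(col)
                row.append((ri, allele, reg.support(col, allele)))
        entries.append(row)
    pair_support: list[set[tuple[str, str]]] = []
    for prev, cur in zip(cols, cols[1:]):
        pairs = {
            (reg.allele(prev), reg.allele(cur))
            for reg in regions
            if reg.covers(prev) and reg.covers(cur)
        }
        pair_support.append(pairs)
    return SupportTable(cols, entries, pair_support)


@dataclass
class ConsensusResult:
    """A reconstructed consensus with its chimerism accounting.

    ``crossover_pairs`` lists the adjacent SNP column pairs where the chosen
    path switches region and no single region supports the consensus at
    both; ``score`` is (possible crossovers, total SNP-allele coverage,
    distinct regions used) and its first component always equals
    ``len(crossover_pairs)``.
    """

    sequence: str
    crossover_pairs: list[tuple[int, int, str, str]]
    path: list[str]  # chosen region name per SNP, in SNP order
    score: tuple[int, int, int]
    snp_cols: list[int]


def reconstruct_consensus(
    regions: Sequence[HaplotypeRegion],
    aln: MultipleAlignment,
    snps: SnpSet,
    universal: HaplotypeRegion | None = None,
) -> ConsensusResult:
    """Reconstruct the full consensus with minimum possible chimerism.

    ``regions`` are the non-universal haplotype regions; the universal
    haplotype never enters the DP (switching through reads common to all
    haplotypes is not a crossover) — it is accepted for interface symmetry
    only. Every SNP must be covered by at least one region.
    """
    table = build_support_table(regions, snps)
    for col, row in zip(table.snp_cols, table.entries):
        if not row:
            raise ValueError(
                f"SNP at column {col} is covered by no haplotype region; "
                f"inconsistent inputs"
            )
    m = len(table.snp_cols)
    base = majority_string(aln)
    if m == 0:
        return ConsensusResult(base, [], [], (0, 0, 0), [])

    path_idx, crossovers, coverage, distinct = _lexicographic_dp(
        table.entries, table.pair_support
    )

    seq = list(base)
    allele_of = []
    for i, col in enumerate(table.snp_cols):
        allele = next(a for r, a, _ in table.entries[i] if r == path_idx[i])
        seq[col] = allele
        allele_of.append(allele)
    sequence = "".join(seq)

    pairs: list[tuple[int, int, str, str]] = []
    for i in range(m - 1):
        if (allele_of[i], allele_of[i + 1]) in table.pair_support[i]:
            continue
        pairs.append(
            (
                table.snp_cols[i],
                table.snp_cols[i + 1],
                regions[path_idx[i]].name,
                regions[path_idx[i + 1]].name,
            )
        )
    assert len(pairs) == crossovers
    return ConsensusResult(
        sequence=sequence,
        crossover_pairs=pairs,
        path=[regions[r].name for r in path_idx],
        score=(crossovers, coverage, distinct),
        snp_cols=table.snp_cols,
    )


def _lexicographic_dp(entries, pair_support):
    """DP over SNPs; returns (path, crossovers, total coverage, distinct).

    A transition between SNPs i-1 and i is free iff the chosen allele pair
    is jointly supported by a single region; criteria 1-2 (fewest
    crossovers, then max coverage) are Markovian in the providing region.
    Criterion 3 (fewest distinct regions) is resolved exactly by a second
    pass over the criteria-1/2-optimal transition graph carrying
    used-region sets (small: at most crossovers+1 new regions per path).
    """
    m = len(entries)
    allele = [
        {q: a for q, a, _ in row} for row in entries
    ]
    cover = [
        {q: c for q, _, c in row} for row in entries
    ]

    def step_cost(i, r, q):
        return 0 if (allele[i - 1][r], allele[i][q]) in pair_support[i - 1] else 1

    best: list[dict[int, tuple[int, int]]] = [
        {q: (0, -cov) for q, _, cov in entries[0]}
    ]
    for i in range(1, m):
        cur: dict[int, tuple[int, int]] = {}
        for q in allele[i]:
            cur[q] = min(
                (s + step_cost(i, r, q), negc - cover[i][q])
                for r, (s, negc) in best[i - 1].items()
            )
        best.append(cur)

    opt_final = min(best[m - 1].values())
    # backward-mark states on some criteria-1/2-optimal path
    marked: list[set[int]] = [set() for _ in range(m)]
    marked[m - 1] = {q for q, v in best[m - 1].items() if v == opt_final}
    for i in range(m - 1, 0, -1):
        for q in marked[i]:
            s, negc = best[i][q]
            for r, (ps, pnegc) in best[i - 1].items():
                if (ps + step_cost(i, r, q), pnegc - cover[i][q]) == (s, negc):
                    marked[i - 1].add(r)

    n_regions = len({q for row in entries for q, _, _ in row})
    if m <= 16 and n_regions <= 12:
        path = _min_distinct_path(entries, best, marked, step_cost, cover, m)
    else:
        # large instances: criterion 3 applied greedily (prefer staying in
        # the current region, then the lowest region index); the exact
        # used-set search is exponential when many zero-cost transitions
        # exist and the tie-break is immaterial at this scale
        path = _greedy_backtrack(best, marked, step_cost, cover, m)
    switches, negcov = opt_final
    return path, switches, -negcov, len(set(path))


def _greedy_backtrack(best, marked, step_cost, cover, m):
    q = min(marked[m - 1])
    path = [q]
    for i in range(m - 1, 0, -1):
        s, negc = best[i][q]
        preds = [
            r
            for r in marked[i - 1]
            if (best[i - 1][r][0] + step_cost(i, r, q),
                best[i - 1][r][1] - cover[i][q]) == (s, negc)
        ]
        q = q if q in preds else min(preds)
        path.append(q)
    path.reverse()
    return path


def _pref_parent(cand, incumbent, q):
    """Deterministic parent preference: staying in the same region, then
    lowest region index, then lexicographically smallest used-set."""
    (rc, uc), (ri, ui) = cand, incumbent
    return ((rc != q), rc, sorted(uc)) < ((ri != q), ri, sorted(ui))


def _min_distinct_path(entries, best, marked, step_cost, cover, m):
    """Choose one optimal path minimizing the number of distinct regions."""
    layers: list[dict[tuple[int, frozenset], tuple | None]] = [
        {(q, frozenset([q])): None for q in marked[0]}
    ]
    for i in range(1, m):
        nxt: dict[tuple[int, frozenset], tuple | None] = {}
        for q in marked[i]:
            s, negc = best[i][q]
            for (r, used) in layers[i - 1]:
                ps, pnegc = best[i - 1][r]
                if (ps + step_cost(i, r, q), pnegc - cover[i][q]) != (s, negc):
                    continue
                key = (q, used | {q})
                prev = nxt.get(key)
                if prev is None or _pref_parent((r, used), prev, q):
                    nxt[key] = (r, used)
        # prune used-sets dominated by a subset for the same region
        pruned: dict[tuple[int, frozenset], tuple | None] = {}
        by_q: dict[int, list[frozenset]] = {}
        for (q, used) in sorted(nxt, key=lambda k: (len(k[1]), sorted(k[1]), k[0])):
            kept = by_q.setdefault(q, [])
            if any(other < used for other in kept):
                continue
            kept.append(used)
            pruned[(q, used)] = nxt[(q, used)]
        if len(pruned) > _STATE_CAP:
            min_len = min(len(u) for _, u in pruned)
            pruned = {k: v for k, v in pruned.items() if len(k[1]) == min_len}
        layers.append(pruned)

    key = min(layers[m - 1], key=lambda k: (len(k[1]), sorted(k[1]), k[0]))
    path = [key[0]]
    for i in range(m - 1, 0, -1):
        key = layers[i][key]
        path.append(key[0])
    path.reverse()
    return path


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

@dataclass
class ChimerismReport:
    """Minimum crossovers needed to explain a consensus with a reference
    haplotype set, plus the SNP loci no reference explains."""

    min_crossovers: int
    error_loci: list[int]
    eval_snps: list[int]


def _reference_entries(refs) -> tuple[list[tuple[str, str]], int]:
    """Normalize a HaplotypeSet or a region list to (name, sequence) pairs
    (sequences may contain '~' for uncovered loci) plus the common length."""
    if isinstance(refs, HaplotypeSet):
        seqs = list(refs.sequences)
        if not seqs:
            raise ValueError("empty reference haplotype set")
        return seqs, refs.length
    seqs = [(reg.name, reg.consensus) for reg in refs]
    if not seqs:
        raise ValueError("empty reference region list")
    return seqs, len(seqs[0][1])


def evaluate_consensus(
    c: str,
    refs: HaplotypeSet | Sequence[HaplotypeRegion],
    snp_override: SnpSet | Sequence[int] | None = None,
) -> ChimerismReport:
    """Minimum number of crossovers through ``refs`` explaining ``c``.

    Evaluation SNPs are the polymorphic loci among the references (ignoring
    ``'~'``) unless ``snp_override`` is given. A crossover is charged for
    every adjacent evaluation-SNP pair that no single reference covers and
    agrees with at both; a locus no reference explains is reported in
    ``error_loci`` and is charged on both sides. Mismatches at non-SNP loci
    are ignored (they cannot be phasing errors); a ``'~'`` in ``c`` at a
    SNP agrees with nothing.
    """
    entries, ref_len = _reference_entries(refs)
    if len(c) != ref_len:
        raise ValueError(
            f"consensus length {len(c)} != reference length {ref_len}"
        )
    if snp_override is not None:
        cols = list(snp_override)
    else:
        cols = _polymorphic_among(entries, ref_len)

    def agrees(seq: str, col: int) -> bool:
        return seq[col] != GAP and c[col] != GAP and seq[col] == c[col]

    error_loci = [
        col for col in cols if not any(agrees(seq, col) for _, seq in entries)
    ]
    crossovers = 0
    for prev, cur in zip(cols, cols[1:]):
        if not any(agrees(s, prev) and agrees(s, cur) for _, s in entries):
            crossovers += 1
    return ChimerismReport(crossovers, error_loci, list(cols))


def _polymorphic_among(entries, length: int) -> list[int]:
    arr = np.array([list(seq) for _, seq in entries])
    cols = []
    for i in range(length):
        alleles = {a for a in arr[:, i] if a != GAP}
        if len(alleles) > 1:
            cols.append(i)
    return cols


def true_vs_estimated_crossovers(
    c: str,
    truth: HaplotypeSet,
    regions: Sequence[HaplotypeRegion],
) -> tuple[ChimerismReport, ChimerismReport]:
    """Chimerism of ``c`` against the true haplotypes ("true" crossovers)
    and against the assembled regions ("estimated" crossovers).

    The estimate is conservative: assembled regions are shorter than true
    haplotypes, so it generally overestimates — unless the regions are
    themselves long chimeras (e.g. single-repetition colorings), when it
    can undercount.
    """
    return (
        evaluate_consensus(c, truth),
        evaluate_consensus(c, regions),
    )


def majority_vote_consensus(aln: MultipleAlignment) -> str:
    """Plain per-column majority-vote consensus (the approach this package
    improves on); ties break A < C < G < T < '-', zero-depth columns 'N'."""
    return majority_string(aln)
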