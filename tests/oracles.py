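"""Independent brute-force oracles used to validate the optimizers.

These deliberately share no code with the implementation: chain covers are
found by exhaustive set-partition search, consensus paths by enumerating
every per-SNP region assignment, and binomial quantiles by direct CDF
summation with exact integer combinatorics.
"""

from __future__ import annotations

import itertools
from math import comb


def brute_chain_cover(n: int, comparable) -> tuple[int, int]:
    """Exhaustive minimum chain partition of a transitive DAG.

    ``comparable[i][j]`` must be True iff an arc joins i and j (either
    direction); in a transitive DAG a set of pairwise-comparable nodes is a
    chain. Returns (minimum number of chains, maximum number of single-node
    chains over all minimum partitions).
    """
    best_size = n + 1
    best_singles = -1

    def rec(item: int, blocks: list[list[int]]):
        nonlocal best_size, best_singles
        if len(blocks) > best_size:
            return
        if item == n:
            size = len(blocks)
            singles = sum(1 for b in blocks if len(b) == 1)
            if (size, -singles) < (best_size, -best_singles):
                best_size, best_singles = size, singles
            return
        for b in blocks:
            if all(comparable[item][j] for j in b):
                b.append(item)
                rec(item + 1, blocks)
                b.pop()
        blocks.append([item])
        rec(item + 1, blocks)
        blocks.pop()

    rec(0, [])
    return best_size, best_singles


def brute_consensus(entries, pair_support):
    """Exhaustive lexicographic optimum over all per-SNP region assignments.

    ``entries[i]`` lists ``(region, allele, coverage)`` options at SNP i;
    ``pair_support[i]`` is the set of allele pairs some single region
    carries at SNPs i and i+1 (a junction choosing such a pair is not a
    crossover). Returns the best (crossovers, -total_coverage,
    distinct_regions) triple.
    """
    best = None
    for assign in itertools.product(*entries):
        path = [region for region, _, _ in assign]
        alleles = [a for _, a, _ in assign]
        crossings = sum(
            1
            for i in range(len(assign) - 1)
            if (alleles[i], alleles[i + 1]) not in pair_support[i]
        )
        cov = sum(c for _, _, c in assign)
        key = (crossings, -cov, len(set(path)))
        if best is None or key < best:
            best = key
    return best


def binomial_cdf(q: int, n: int, p: float) -> float:
    """Exact-arithmetic binomial CDF by direct summation."""
    return sum(comb(n, k) * p**k * (1 - p) ** (n - k) for k in range(q + 1))


def brute_binomial_quantile(prob: float, n: int, p: float) -> int:
    """Smallest integer q with CDF(q) >= prob."""
    for q in range(n + 1):
        if binomial_cdf(q, n, p) >= prob:
            return q
    return n


def brute_min_switches(candidate_sets) -> int:
    """Minimum adjacent-pair switches over all per-SNP candidate choices."""
    best = None
    for assign in itertools.product(*candidate_sets):
        s = sum(1 for a, b in zip(assign, assign[1:]) if a != b)
        best = s if best is None else min(best, s)
    return best
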