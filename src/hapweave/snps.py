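"""Variant-locus (SNP) callers over pileup columns of a multiple alignment.

Haplotyping only uses columns declared variant here, so the caller choice
trades sensitivity against robustness to sequencing error:

* ``simple`` — every polymorphic column, regardless of allele frequency.
* ``simple_strict`` — a polymorphic column where a minority allele occurs at
  least twice, or where fewer than 10 reads cover the locus (low-coverage
  columns are conservatively kept so that haplotyping, not the caller,
  resolves them).
* ``c454`` — tailored to pyrosequencing indel noise: the majority allele
  must not be a deletion, and minority support must either be repeated or
  fall outside a homopolymer run.
* ``binomial`` — a Bonferroni-corrected binomial test against the expected
  second-allele count under a uniform substitution-error model.
* user-provided positions.

Deletion alleles (``'-'``) are real alleles that can conflict; ``N`` never
counts toward tallies or depth.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np
from scipy.stats import binom

from .alignment import ALLELES, MultipleAlignment

__all__ = [
    "SnpSet",
    "ColumnProfile",
    "call_simple",
    "call_simple_strict",
    "call_454",
    "call_binomial",
    "load_user_snps",
    "binomial_threshold",
    "CALLERS",
]


class Caller(str, Enum):
    simple = "simple"
    simple_strict = "simple_strict"
    c454 = "c454"
    binomial = "binomial"
    user = "user"


@dataclass(frozen=True)
class SnpSet:
    """Ordered variant columns used for haplotyping."""

    columns: tuple[int, ...]
    caller: Caller = Caller.user

    def __post_init__(self):
        cols = self.columns
        if any(b <= a for a, b in zip(cols, cols[1:])):
            raise ValueError("SNP columns must be strictly increasing")

    def __len__(self) -> int:
        return len(self.columns)

    def __iter__(self):
        return iter(self.columns)

    def __contains__(self, col: int) -> bool:
        return col in set(self.columns)


@dataclass(frozen=True)
class ColumnProfile:
    """Informative allele counts at one column (A, C, G, T, ``-``)."""

    counts: dict[str, int]

    @property
    def depth(self) -> int:
        return sum(self.counts.values())

    @property
    def n_alleles(self) -> int:
        return sum(1 for v in self.counts.values() if v > 0)

    def ranked(self) -> list[tuple[str, int]]:
        """Alleles by descending count; ties broken A < C < G < T < ``-``."""
        return sorted(
            ((a, c) for a, c in self.counts.items() if c > 0),
            key=lambda ac: (-ac[1], ALLELES.index(ac[0])),
        )


def column_profile(aln: MultipleAlignment, col: int) -> ColumnProfile:
    row = aln.counts[col]
    return ColumnProfile({a: int(row[i]) for i, a in enumerate(ALLELES)})


def _variant_mask(aln: MultipleAlignment) -> np.ndarray:
    """Boolean mask of columns with >= 2 distinct informative alleles."""
    return (aln.counts[:, :5] > 0).sum(axis=1) >= 2


def call_simple(aln: MultipleAlignment) -> SnpSet:
    """Every polymorphic column is a SNP, regardless of allele frequency."""
    cols = np.flatnonzero(_variant_mask(aln))
    return SnpSet(tuple(int(c) for c in cols), Caller.simple)


def call_simple_strict(aln: MultipleAlignment) -> SnpSet:
    """Polymorphic columns where a minority allele occurs >= 2 times, or the
    locus is covered by fewer than 10 reads."""
    counts = aln.counts[:, :5]
    variant = _variant_mask(aln)
    depth = counts.sum(axis=1)
    second = np.sort(counts, axis=1)[:, -2]
    keep = variant & ((second >= 2) | (depth < 10))
    return SnpSet(tuple(int(c) for c in np.flatnonzero(keep)), Caller.simple_strict)


def call_454(
    aln: MultipleAlignment, literal_two_alleles: bool = False
) -> SnpSet:
    """Pyrosequencing-aware caller.

    A polymorphic column is a SNP iff (1) the majority allele is not ``'-'``
    and (2) either (a) a minority non-``'-'`` allele occurs at least twice
    (set ``literal_two_alleles=True`` for the alternative reading: at least
    two distinct non-``'-'`` alleles exist), or (b) some read carries a
    minority non-``'-'`` allele that is not inside a homopolymer run of
    length >= 3 in that read's own sequence.
    """
    out = []
    for col in np.flatnonzero(_variant_mask(aln)):
        col = int(col)
        prof = column_profile(aln, col)
        ranked = prof.ranked()
        majority = ranked[0][0]
        if majority == "-":
            continue
        if literal_two_alleles:
            cond_a = sum(1 for a, c in ranked if a != "-") >= 2
        else:
            cond_a = any(c >= 2 for a, c in ranked[1:] if a != "-")
        if cond_a or _minority_outside_homopolymer(aln, col, majority):
            out.append(col)
    return SnpSet(tuple(out), Caller.c454)


def _minority_outside_homopolymer(aln, col, majority, min_run=3) -> bool:
    for r in aln.reads:
        if not r.covers(col):
            continue
        a = r.bases[col - r.start]
        if a in ("-", "N") or a == majority:
            continue
        if _run_length(r.bases, col - r.start) < min_run:
            return True
    return False


def _run_length(bases: str, i: int) -> int:
    """Length of the maximal equal-character run containing position i."""
    c = bases[i]
    lo = i
    while lo > 0 and bases[lo - 1] == c:
        lo -= 1
    hi = i
    while hi + 1 < len(bases) and bases[hi + 1] == c:
        hi += 1
    return hi - lo + 1


def binomial_threshold(
    d: int, length: int, e: float = 0.005, alpha: float = 0.05
) -> int:
    """Count threshold t at depth ``d``: call a SNP iff the second most
    frequent allele count is strictly greater than t.

    t is the inverse binomial CDF at probability ``1 - alpha/length`` with
    ``d`` trials and per-base success probability ``e/3`` (a substitution
    error turns a base into one of the three others uniformly), i.e. the
    smallest integer q with ``CDF(q) >= 1 - alpha/length``.
    """
    if d <= 0:
        return 0
    return int(binom.ppf(1.0 - alpha / length, d, e / 3.0))


def call_binomial(
    aln: MultipleAlignment, e: float = 0.005, alpha: float = 0.05
) -> SnpSet:
    """Bonferroni-corrected binomial test per column.

    Under a uniform substitution-error model with error rate ``e``, the
    second most frequent character at a non-polymorphic locus occurs at rate
    ``e/(|A|-1)`` with ``|A| = 4``. A column is a SNP iff its observed
    second-allele count exceeds the ``1 - alpha/L`` binomial quantile at the
    locus depth, ``L`` being the alignment length.
    """
    if not 0 < e < 1:
        raise ValueError(f"error rate must be in (0, 1), got {e}")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    counts = aln.counts[:, :5]
    depth = counts.sum(axis=1)
    second = np.sort(counts, axis=1)[:, -2]
    L = max(aln.length, 1)
    out = []
    # quantiles depend only on depth: evaluate once per distinct depth
    thresholds = {
        int(d): binomial_threshold(int(d), L, e, alpha)
        for d in np.unique(depth[second > 0])
    }
    for col in np.flatnonzero(second > 0):
        if second[col] > thresholds[int(depth[col])]:
            out.append(int(col))
    return SnpSet(tuple(out), Caller.binomial)


def load_user_snps(path: str | Path, aln: MultipleAlignment) -> SnpSet:
    """Load 0-based SNP positions from a text file.

    Lines are either ``alignment_name<TAB>position`` (only rows matching
    ``aln.name`` are used) or a bare integer position applying to any
    alignment. Duplicates are removed; positions are validated against the
    alignment bounds.
    """
    positions: set[int] = set()
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        fields = line.split()
        if not fields or line.lstrip().startswith("#"):
            continue
        if len(fields) == 1:
            name, pos_s = aln.name, fields[0]
        else:
            name, pos_s = fields[0], fields[1]
        if name != aln.name:
            continue
        try:
            pos = int(pos_s)
        except ValueError as exc:
            raise ValueError(f"line {lineno}: not an integer position: {pos_s!r}") from exc
        if not 0 <= pos < aln.length:
            raise ValueError(
                f"line {lineno}: position {pos} out of range for alignment "
                f"{aln.name!r} of length {aln.length}"
            )
        positions.add(pos)
    return SnpSet(tuple(sorted(positions)), Caller.user)


CALLERS = {
    "simple": call_simple,
    "simple-strict": call_simple_strict,
    "454": call_454,
    "binomial": call_binomial,
}
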