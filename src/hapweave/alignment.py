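"""In-memory model of a padded multiple alignment of gapless reads.

The alignment is a rectangle of columns indexed ``0 .. length-1``. Each read
occupies a contiguous run of columns (reads are gapless: they may carry
deletion alleles ``'-'`` inside their span, but never a coverage gap).
Outside its span a read implicitly shows ``'~'`` — "no information" — which
is distinct from a deletion: a ``'-'`` allele can conflict with a base,
a ``'~'`` cannot conflict with anything.

``N`` is accepted in read bases as an uninformative fifth character: it never
counts toward allele tallies or depth and conflicts with nothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Alphabet of informative alleles, in tie-break order (A < C < G < T < -).
ALLELES = "ACGT-"
#: Integer codes: A=0 C=1 G=2 T=3 -=4 N=5; '~' is never stored in a read.
CODES = {c: i for i, c in enumerate(ALLELES + "N")}
GAP = "~"

_VALID = frozenset(ALLELES + "N")


@dataclass(frozen=True)
class AlignedRead:
    """A gapless read placed at a fixed column offset in the alignment.

    ``bases`` covers columns ``[start, start + len(bases))``; the read is
    ``'~'`` everywhere else.
    """

    id: str
    start: int
    bases: str

    def __post_init__(self) -> None:
        if not self.bases:
            raise ValueError(f"read {self.id!r}: empty sequence")
        if self.start < 0:
            raise ValueError(f"read {self.id!r}: negative start {self.start}")
        bad = set(self.bases) - _VALID
        if bad:
            raise ValueError(
                f"read {self.id!r}: invalid characters {sorted(bad)} "
                f"(allowed: {ALLELES}N; '~' may not occur inside a read)"
            )

    @property
    def end(self) -> int:
        """One past the last covered column (half-open)."""
        return self.start + len(self.bases)

    def covers(self, col: int) -> bool:
        return self.start <= col < self.end

    def at(self, col: int) -> str:
        """Allele at ``col``, or ``'~'`` outside the read's span."""
        if self.covers(col):
            return self.bases[col - self.start]
        return GAP


class MultipleAlignment:
    """A padded multiple alignment: a set of reads over a shared column axis."""

    def __init__(self, length: int, reads: list[AlignedRead], name: str = "aln"):
        if length < 0:
            raise ValueError("alignment length must be non-negative")
        for r in reads:
            if r.end > length:
                raise ValueError(
                    f"read {r.id!r} spans columns [{r.start}, {r.end}) beyond "
                    f"alignment length {length}"
                )
        self.length = length
        self.reads = list(reads)
        self.name = name
        self._counts: np.ndarray | None = None

    def __len__(self) -> int:
        return self.length

    def __repr__(self) -> str:
        return (
            f"MultipleAlignment(name={self.name!r}, length={self.length}, "
            f"reads={len(self.reads)})"
        )

    @property
    def counts(self) -> np.ndarray:
        """Per-column allele counts, shape ``(length, 6)`` (A,C,G,T,-,N)."""
        if self._counts is None:
            counts = np.zeros((self.length, 6), dtype=np.int64)
            for r in self.reads:
                codes = np.frombuffer(r.bases.encode(), dtype=np.uint8)
                cols = np.arange(r.start, r.end)
                np.add.at(counts, (cols, _CODE_LUT[codes]), 1)
            self._counts = counts
        return self._counts

    def column(self, col: int) -> list[str]:
        """Multiset (as list) of alleles of reads covering ``col`` (incl. N)."""
        if not 0 <= col < self.length:
            raise IndexError(f"column {col} out of range [0, {self.length})")
        return [r.bases[col - r.start] for r in self.reads if r.covers(col)]

    def depth(self, col: int) -> int:
        """Number of informative (non-N) covering reads at ``col``."""
        return int(self.counts[col, :5].sum())

    def depth_profile(self) -> np.ndarray:
        """Informative read depth at every column, shape ``(length,)``."""
        return self.counts[:, :5].sum(axis=1)


# uint8 byte value -> allele code lookup (invalid bytes impossible post-validation)
_CODE_LUT = np.zeros(256, dtype=np.int64)
for _c, _i in CODES.items():
    _CODE_LUT[ord(_c)] = _i


@dataclass
class HaplotypeSet:
    """An ordered set of equal-length, ungapped haplotype sequences.

    Serves both as simulator ground truth and as the reference set for
    chimerism evaluation.
    """

    sequences: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        lengths = {(name, len(seq)) for name, seq in self.sequences}
        if len({l for _, l in lengths}) > 1:
            by_len = sorted(lengths, key=lambda t: t[1])
            a, b = by_len[0], by_len[-1]
            raise ValueError(
                f"haplotypes must be equal length: {a[0]!r} has {a[1]} bp "
                f"but {b[0]!r} has {b[1]} bp"
            )

    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self):
        return iter(self.sequences)

    @property
    def length(self) -> int:
        return len(self.sequences[0][1]) if self.sequences else 0

    @property
    def ids(self) -> list[str]:
        return [name for name, _ in self.sequences]

    def seq(self, name: str) -> str:
        for n, s in self.sequences:
            if n == name:
                return s
        raise KeyError(name)

    def polymorphic_columns(self) -> list[int]:
        """Columns where at least two sequences differ."""
        if len(self.sequences) < 2:
            return []
        arr = np.array([list(s) for _, s in self.sequences])
        return [i for i in range(arr.shape[1]) if len(set(arr[:, i])) > 1]

    def pairwise_diversity(self) -> float:
        """Mean pairwise Hamming distance divided by sequence length."""
        n = len(self.sequences)
        if n < 2 or self.length == 0:
            return 0.0
        arr = np.array(
            [np.frombuffer(s.encode(), dtype=np.uint8) for _, s in self.sequences]
        )
        total = 0
        for i in range(n):
            total += int((arr[i + 1 :] != arr[i]).sum())
        return total / (n * (n - 1) / 2) / self.length
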