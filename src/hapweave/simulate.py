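"""Synthetic population, read-sequencing and scoring harness.

Emulates the study design the haplotyping method targets: a small set of
gene-sized haplotypes from a natural population (low pairwise diversity,
SNPs at scattered, non-adjacent columns), shotgun-sequenced to shallow
fold-coverage with a uniform substitution-error model, and "perfectly
assembled" — reads placed at their true coordinates. Indels, homopolymer
noise, quality values and alignment error are deliberately out of scope.

The letter-swap expansion (``expand_sequence``) quadruples a haplotype by
concatenating it with its T<->C, A<->G and A<->T swapped variants — a
diversity-preserving trick for testing Sanger-length reads on full
gene-length alignments.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .alignment import GAP, AlignedRead, HaplotypeSet, MultipleAlignment
from .haplotyping import HaplotypeRegion

__all__ = [
    "SimulationConfig",
    "ReadProvenance",
    "SimulatedAlignment",
    "generate_population",
    "expand_sequence",
    "expand_population",
    "simulate_reads",
    "score_regions",
    "aggregate_by_coverage",
    "write_simulation",
]

_BASES = "ACGT"
_SWAPS = [
    str.maketrans("TC", "CT"),  # T <-> C
    str.maketrans("AG", "GA"),  # A <-> G
    str.maketrans("AT", "TA"),  # A <-> T
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated sequencing experiment.

    Defaults are the low-diversity scenario: four haplotypes of a 600 bp
    gene region at 1.16% mean pairwise diversity, each sequenced to 6X with
    400 bp error-free reads (the expansion step, applied separately,
    quadruples the length before sequencing). ``multiplicities`` skews the
    population (e.g. ``(3, 1, 1, 1)``: one haplotype at three copies).
    """

    n_haplotypes: int = 4
    length: int = 600
    diversity: float = 0.0116
    per_hap_coverage: float = 6.0
    read_length: int = 400
    error_rate: float = 0.0
    seed: int = 0
    min_snp_spacing: int = 2
    multiplicities: tuple[int, ...] | None = None

    def __post_init__(self):
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")
        if self.per_hap_coverage <= 0:
            raise ValueError("per_hap_coverage must be positive")
        if self.multiplicities is not None and (
            len(self.multiplicities) != self.n_haplotypes
            or any(m < 1 for m in self.multiplicities)
        ):
            raise ValueError("multiplicities must give a count >= 1 per haplotype")


def generate_population(cfg: SimulationConfig) -> HaplotypeSet:
    """Draw a random haplotype set hitting the target diversity.

    Diversity is measured as the proportion of polymorphic (segregating)
    columns — e.g. 7 SNPs in a 600 bp gene region give 1.16% — so
    ``round(diversity * length)`` biallelic SNPs are placed at random
    columns (no two closer than ``min_snp_spacing``), each with a random
    derived allele carried by a random nonempty proper subset of the
    haplotypes. The realized diversity must land within 10% of the target
    or the configuration is rejected as infeasible.
    """
    rng = np.random.default_rng([cfg.seed, 0])
    n, L = cfg.n_haplotypes, cfg.length
    ancestral = rng.choice(list(_BASES), size=L)
    seqs = np.tile(ancestral, (n, 1))
    target = cfg.diversity
    if n == 1 or target == 0:
        return HaplotypeSet([(f"hap{i}", "".join(seqs[i])) for i in range(n)])

    n_snps = round(target * L)
    if n_snps < 1 or abs(n_snps / L - target) > 0.1 * target:
        raise ValueError(
            f"diversity {target} is not representable on length {L}: "
            f"nearest SNP count {n_snps} gives {n_snps / L:.5f}"
        )
    available = np.ones(L, dtype=bool)
    for _ in range(n_snps):
        cand = np.flatnonzero(available)
        if len(cand) == 0:
            raise ValueError(
                f"cannot place {n_snps} SNPs on length {L} with "
                f"min_snp_spacing {cfg.min_snp_spacing}: ran out of columns"
            )
        col = int(rng.choice(cand))
        lo = max(0, col - cfg.min_snp_spacing + 1)
        available[lo : col + cfg.min_snp_spacing] = False
        # random nonempty proper subset carries a random derived allele
        d = int(rng.integers(1, n))
        carriers = rng.choice(n, size=d, replace=False)
        anc = seqs[0, col]
        derived = rng.choice([b for b in _BASES if b != anc])
        seqs[carriers, col] = derived
    return HaplotypeSet([(f"hap{i}", "".join(seqs[i])) for i in range(n)])


def expand_sequence(s: str) -> str:
    """Quadruple a sequence by concatenating letter-swapped variants.

    Output = s + s(T<->C) + s(A<->G) + s(A<->T). Each swap is a bijection on
    the alphabet, so pairwise Hamming distances — hence diversity — scale
    exactly with length and the expanded set keeps the input's diversity.
    """
    return s + s.translate(_SWAPS[0]) + s.translate(_SWAPS[1]) + s.translate(_SWAPS[2])


def expand_population(haps: HaplotypeSet) -> HaplotypeSet:
    """Apply the 4x letter-swap expansion to every haplotype."""
    return HaplotypeSet([(name, expand_sequence(seq)) for name, seq in haps])


@dataclass(frozen=True)
class ReadProvenance:
    """Where a simulated read came from and where errors were injected."""

    source: str
    start: int
    error_cols: tuple[int, ...]


class SimulatedAlignment(MultipleAlignment):
    """A simulated multiple alignment carrying ground truth and provenance."""

    def __init__(self, length, reads, name, truth, provenance):
        super().__init__(length, reads, name=name)
        self.truth: HaplotypeSet = truth
        self.provenance: dict[str, ReadProvenance] = provenance


def simulate_reads(haps: HaplotypeSet, cfg: SimulationConfig) -> SimulatedAlignment:
    """Simulate shotgun sequencing with perfect assembly.

    Per haplotype (times its multiplicity), read windows of ``read_length``
    are dropped uniformly over all positions overlapping the sequence and
    truncated at the sequence ends (so expected coverage is uniform along
    the whole alignment), until ``per_hap_coverage x L`` bases have been
    emitted per copy; each base is then substituted with one of the other
    three (uniformly) with probability ``error_rate``. Reads are placed at
    their true offsets, so the alignment is error-free apart from the
    injected substitutions.
    """
    rng = np.random.default_rng([cfg.seed, 1])
    L = haps.length
    rl = cfg.read_length
    if rl > L:
        raise ValueError(f"read_length {rl} exceeds haplotype length {L}")
    mults = cfg.multiplicities or tuple([1] * len(haps))
    reads: list[AlignedRead] = []
    prov: dict[str, ReadProvenance] = {}
    for (name, seq), mult in zip(haps, mults):
        target = cfg.per_hap_coverage * mult * L
        emitted = 0
        i = 0
        while emitted < target:
            raw = int(rng.integers(-(rl - 1), L))
            start = max(0, raw)
            stop = min(L, raw + rl)
            bases = np.array(list(seq[start:stop]))
            err_cols: tuple[int, ...] = ()
            if cfg.error_rate > 0:
                hits = np.flatnonzero(rng.random(len(bases)) < cfg.error_rate)
                for h in hits:
                    h = int(h)
                    bases[h] = rng.choice([b for b in _BASES if b != bases[h]])
                err_cols = tuple(start + int(h) for h in hits)
            rid = f"{name}_r{i}"
            reads.append(AlignedRead(rid, start, "".join(bases)))
            prov[rid] = ReadProvenance(name, start, err_cols)
            emitted += stop - start
            i += 1
    return SimulatedAlignment(L, reads, f"sim_seed{cfg.seed}", haps, prov)


def score_regions(
    regions: list[HaplotypeRegion], truth: HaplotypeSet
) -> pd.DataFrame:
    """Score assembled regions against the true haplotypes.

    A region is *correct* iff some single haplotype matches every contiguous
    covered segment of its consensus exactly at the right offsets (exact
    subsequence criterion, extended segment-wise for the rare non-contiguous
    region). Returns one row per region with the correctness flag, covered
    bases and mean coverage.
    """
    rows = []
    for reg in regions:
        segments = _segments(reg.consensus)
        correct = any(
            all(seq[s:e] == reg.consensus[s:e] for s, e in segments)
            for _, seq in truth
        ) if segments else True
        rows.append(
            {
                "region": reg.name,
                "correct": bool(correct),
                "covered_bases": reg.covered_bases,
                "mean_coverage": reg.mean_coverage,
                "n_members": len(reg.members),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["region", "correct", "covered_bases", "mean_coverage", "n_members"],
    )


def _segments(consensus: str) -> list[tuple[int, int]]:
    """Half-open runs of non-'~' columns."""
    segs = []
    start = None
    for i, ch in enumerate(consensus):
        if ch != GAP and start is None:
            start = i
        elif ch == GAP and start is not None:
            segs.append((start, i))
            start = None
    if start is not None:
        segs.append((start, len(consensus)))
    return segs


def aggregate_by_coverage(scores: pd.DataFrame, bin_width: float = 1.0) -> pd.DataFrame:
    """Bin region scores by mean coverage: counts and percent correct."""
    df = scores.copy()
    df["coverage_bin"] = (df["mean_coverage"] // bin_width) * bin_width
    out = (
        df.groupby("coverage_bin")
        .agg(
            n=("correct", "size"),
            n_correct=("correct", "sum"),
        )
        .reset_index()
    )
    out["pct_correct"] = 100.0 * out["n_correct"] / out["n"]
    return out


def write_simulation(sim: SimulatedAlignment, outdir: str | Path) -> dict[str, Path]:
    """Write a simulation as SAM + truth FASTA + provenance TSV."""
    from . import io as _io

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "sam": outdir / "reads.sam",
        "truth": outdir / "truth.fasta",
        "provenance": outdir / "provenance.tsv",
    }
    _io.write_sam(sim, paths["sam"])
    with open(paths["truth"], "w") as fh:
        for name, seq in sim.truth:
            fh.write(f">{name}\n{seq}\n")
    with open(paths["provenance"], "w") as fh:
        fh.write("read\tsource\tstart\terror_cols\n")
        for rid, p in sim.provenance.items():
            cols = ",".join(map(str, p.error_cols))
            fh.write(f"{rid}\t{p.source}\t{p.start}\t{cols}\n")
    return paths
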