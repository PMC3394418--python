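"""End-to-end orchestration: SNP calling -> haplotyping -> consensus -> reports."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import io as _io
from .alignment import HaplotypeSet, MultipleAlignment
from .consensus import (
    ChimerismReport,
    ConsensusResult,
    evaluate_consensus,
    reconstruct_consensus,
    true_vs_estimated_crossovers,
)
from .haplotyping import HaplotypingResult, assemble_haplotypes
from .snps import CALLERS, SnpSet, load_user_snps

logger = logging.getLogger(__name__)

__all__ = ["PipelineResult", "run_alignment", "write_outputs"]


@dataclass
class PipelineResult:
    alignment: MultipleAlignment
    snps: SnpSet
    haplotyping: HaplotypingResult
    consensus: ConsensusResult
    true_report: ChimerismReport | None = None
    estimated_report: ChimerismReport | None = None


def run_alignment(
    aln: MultipleAlignment,
    snp_caller: str = "binomial",
    error_rate: float = 0.005,
    alpha: float = 0.05,
    snp_file: str | Path | None = None,
    snps: SnpSet | None = None,
    min_reps: int = 20,
    max_reps: int = 1000,
    seed: int = 0,
    rng: np.random.Generator | None = None,
    truth: HaplotypeSet | None = None,
) -> PipelineResult:
    """Run the full method on one multiple alignment.

    ``snps`` (pre-computed) or ``snp_file`` (user positions) override the
    caller. With ``truth`` given, the reconstructed consensus is additionally
    scored for true vs estimated crossovers.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if snps is None:
        if snp_file is not None:
            snps = load_user_snps(snp_file, aln)
        else:
            if snp_caller == "binomial":
                snps = CALLERS["binomial"](aln, e=error_rate, alpha=alpha)
            else:
                snps = CALLERS[snp_caller](aln)
    logger.info(
        "%s: %d reads, %d columns, %d SNPs (%s)",
        aln.name, len(aln.reads), aln.length, len(snps),
        getattr(snps.caller, "value", snps.caller),
    )
    hap = assemble_haplotypes(aln, snps, rng, min_reps=min_reps, max_reps=max_reps)
    logger.info(
        "%s: %d blocks, %d irredundant reads, %d regions (+universal), "
        "repetitions per block: %s",
        aln.name, hap.n_blocks, hap.n_irredundant, len(hap.regions),
        [r.n_repetitions for r in hap.repetitions],
    )
    cons = reconstruct_consensus(hap.regions, aln, snps, universal=hap.universal)
    logger.info(
        "%s: consensus with %d possible crossovers (coverage %d, %d regions used)",
        aln.name, cons.score[0], cons.score[1], cons.score[2],
    )
    true_rep = est_rep = None
    if truth is not None:
        true_rep, est_rep = true_vs_estimated_crossovers(
            cons.sequence, truth, hap.regions
        )
        logger.info(
            "%s: true crossovers %d, estimated %d",
            aln.name, true_rep.min_crossovers, est_rep.min_crossovers,
        )
    return PipelineResult(aln, snps, hap, cons, true_rep, est_rep)


def write_outputs(
    result: PipelineResult,
    outdir: str | Path,
    evaluate: str | None = None,
) -> None:
    """Write per-alignment reports: SNP list, region FASTA+TSV, consensus
    FASTA, crossover TSV, and (when available) chimerism TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    name = result.alignment.name

    with open(outdir / f"{name}.snps.txt", "w") as fh:
        for col in result.snps:
            fh.write(f"{name}\t{col}\n")

    _io.write_regions(
        result.haplotyping.regions,
        result.haplotyping.universal,
        outdir / f"{name}.regions.fasta",
        outdir / f"{name}.regions.tsv",
    )

    with open(outdir / f"{name}.consensus.fasta", "w") as fh:
        fh.write(f">{name}.consensus crossovers={result.consensus.score[0]}\n")
        fh.write(result.consensus.sequence + "\n")

    with open(outdir / f"{name}.crossovers.tsv", "w") as fh:
        fh.write("left_snp_col\tright_snp_col\tleft_region\tright_region\n")
        for cj, ck, rl, rr in result.consensus.crossover_pairs:
            fh.write(f"{cj}\t{ck}\t{rl}\t{rr}\n")

    reports = []
    if result.true_report is not None:
        reports.append(("reconstructed_vs_truth", result.true_report))
    if result.estimated_report is not None:
        reports.append(("reconstructed_vs_regions", result.estimated_report))
    if evaluate is not None:
        ext = evaluate_consensus(
            _single_fasta_sequence(evaluate), result.haplotyping.regions
        )
        reports.append(("given_vs_regions", ext))
    if reports:
        with open(outdir / f"{name}.chimerism.tsv", "w") as fh:
            fh.write("comparison\tmin_crossovers\tn_error_loci\tn_eval_snps\n")
            for label, rep in reports:
                fh.write(
                    f"{label}\t{rep.min_crossovers}\t{len(rep.error_loci)}\t"
                    f"{len(rep.eval_snps)}\n"
                )


def _single_fasta_sequence(path: str | Path) -> str:
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"expected exactly one sequence in {path}")
    return str(records[0].seq).upper()
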