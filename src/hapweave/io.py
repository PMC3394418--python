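"""Readers and writers for the alignment and sequence formats the tool touches.

SAM is read through :mod:`pysam`; the TIGR Assembler ``.contig`` dialect has
no maintained Python reader, so a tolerant parser is implemented here. All
coordinates are converted to the internal convention (0-based, half-open) at
the parsing boundary.
"""

from __future__ import annotations

import logging
import re
import sys
from collections import defaultdict
from pathlib import Path

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alignment import AlignedRead, HaplotypeSet, MultipleAlignment

logger = logging.getLogger(__name__)

__all__ = [
    "read_sam",
    "read_tigr",
    "read_tigr_contigs",
    "read_fasta_haplotypes",
    "write_regions",
    "write_sam",
    "write_tigr",
]


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------

def read_sam(path: str | Path) -> MultipleAlignment:
    """Read a single-reference SAM file into a padded multiple alignment.

    Alignment columns are the union of reference positions and columns
    inserted by reads with ``I`` CIGAR operations. Deletions (``D``) become
    ``'-'`` alleles; soft clips are trimmed; each mate of a pair becomes an
    independent read (mate phasing is deliberately not used: joining mates
    would create gapped reads, which break the polynomial-time guarantees
    of the haplotyping stage). Unmapped reads are skipped with a logged
    count. Reads mapped to more than one reference are rejected.
    """
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        records = []
        n_unmapped = 0
        refname: str | None = None
        ref_len = 0
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                n_unmapped += 1
                continue
            if refname is None:
                refname = rec.reference_name
            elif rec.reference_name != refname:
                raise ValueError(
                    f"SAM contains alignments to multiple references: "
                    f"{refname!r} and {rec.reference_name!r}; one multiple "
                    f"alignment per contig is required"
                )
            records.append(
                (rec.query_name, _mate_tag(rec), rec.reference_start,
                 rec.cigartuples, rec.query_sequence)
            )
        if refname is not None:
            try:
                ref_len = sam.get_reference_length(refname)
            except (KeyError, ValueError):
                ref_len = 0
    if n_unmapped:
        logger.info("skipped %d unmapped/secondary records", n_unmapped)

    name = refname if refname is not None else "aln"

    # Insertion slots: max inserted length before each reference position.
    ins_len: dict[int, int] = defaultdict(int)
    for _, _, pos, cig, seq in records:
        p = pos
        for op, ln in cig or []:
            if op in (0, 7, 8):  # M, =, X
                p += ln
            elif op == 2:  # D
                p += ln
            elif op == 1:  # I: occurs before reference position p
                ins_len[p] = max(ins_len[p], ln)
            elif op == 3:  # N: would create an internal coverage gap
                raise ValueError(
                    "CIGAR 'N' (reference skip) is unsupported: reads must be "
                    "gapless"
                )
    ins_keys = sorted(ins_len)

    max_end = max((_ref_end(pos, cig) for _, _, pos, cig, _ in records), default=0)
    ref_cols = max(ref_len, max_end)

    def refcol(p: int) -> int:
        """Padded column of reference position p."""
        return p + sum(ins_len[k] for k in ins_keys if k <= p)

    reads: list[AlignedRead] = []
    seen: dict[str, int] = defaultdict(int)
    for qname, mate, pos, cig, seq in records:
        start, bases = _apply_cigar(pos, cig or [], seq or "", ins_len, refcol)
        if not bases:
            continue
        rid = qname + mate
        seen[rid] += 1
        if seen[rid] > 1:
            rid = f"{rid}.{seen[qname + mate]}"
        reads.append(AlignedRead(rid, start, bases))

    length = ref_cols + sum(ins_len.values())
    return MultipleAlignment(length, reads, name=name)


def _mate_tag(rec: pysam.AlignedSegment) -> str:
    if rec.is_paired:
        return "/1" if rec.is_read1 else "/2"
    return ""


def _ref_end(pos: int, cig) -> int:
    p = pos
    for op, ln in cig or []:
        if op in (0, 2, 7, 8):
            p += ln
    return p


def _apply_cigar(pos, cig, seq, ins_len, refcol):
    """Project one SAM record onto padded columns -> (start_col, bases).

    Insertion slots created by *any* read sit just before their reference
    position. A read crossing a slot it did not create shows ``'-'`` there;
    a read whose own insertion is shorter than the slot is left-aligned and
    '-'-padded; a leading insertion is right-aligned against its reference
    column; a trailing insertion is left-aligned and the read simply ends.
    """
    parts: list[str] = []
    p, q = pos, 0
    start_col: int | None = None
    started = False
    own_slot: set[int] = set()

    def fill_slot():
        # '-'-fill the slot before ref position p unless this read's own
        # insertion already occupied it
        if started and p in ins_len and p not in own_slot:
            parts.append("-" * ins_len[p])

    last_consuming = max(
        (i for i, (op, _) in enumerate(cig) if op in (0, 1, 2, 7, 8)), default=-1
    )
    for idx, (op, ln) in enumerate(cig):
        if op == 4:  # soft clip: present in SEQ, absent from the alignment
            q += ln
        elif op in (5, 6):  # hard clip / pad
            continue
        elif op in (0, 2, 7, 8):  # reference-consuming: bases or deletions
            for _ in range(ln):
                fill_slot()
                if start_col is None:
                    start_col = refcol(p)
                started = True
                if op == 2:
                    parts.append("-")
                else:
                    parts.append(seq[q].upper())
                    q += 1
                p += 1
        elif op == 1:  # insertion owned by this read
            slot = ins_len[p]
            ins_seq = seq[q : q + ln].upper()
            q += ln
            own_slot.add(p)
            if not started:
                # leading insertion: right-align against the reference column
                start_col = refcol(p) - ln
                started = True
                parts.append(ins_seq)
            elif idx == last_consuming:
                parts.append(ins_seq)  # trailing: left-align, read ends
            else:
                parts.append(ins_seq + "-" * (slot - ln))
        else:
            raise ValueError(f"unsupported CIGAR op code {op}")
    return (start_col if start_col is not None else refcol(pos), "".join(parts))


# ---------------------------------------------------------------------------
# TIGR .contig
# ---------------------------------------------------------------------------

_CONTIG_RE = re.compile(r"^##(\S+)")
_READ_RE = re.compile(r"^#(\S+?)\((\d+)\)")


def read_tigr_contigs(path: str | Path) -> list[MultipleAlignment]:
    """Parse a TIGR Assembler ``.contig`` file (possibly multi-contig).

    Layout per contig: a ``##name ...`` header followed by the gapped
    consensus, then for each read a ``#name(offset) ...`` header followed by
    its gapped sequence. Offsets are 0-based columns into the padded contig;
    read-internal pads (``-``) are kept as deletion alleles. ``'-'`` as the
    path reads from stdin.
    """
    if str(path) == "-":
        text = sys.stdin.read()
    else:
        text = Path(path).read_text()
    contigs: list[MultipleAlignment] = []
    cur_name: str | None = None
    consensus_parts: list[str] = []
    pending: list[tuple[str, int, list[str]]] = []

    def flush():
        if cur_name is None:
            return
        length = len("".join(consensus_parts))
        reads = []
        for rid, off, parts in pending:
            bases = "".join(parts).upper()
            if off + len(bases) > length:
                raise ValueError(
                    f"read {rid!r} at offset {off} (length {len(bases)}) "
                    f"extends past contig {cur_name!r} length {length}"
                )
            reads.append(AlignedRead(rid, off, bases))
        contigs.append(MultipleAlignment(length, reads, name=cur_name))

    target: list[str] | None = None
    for line in text.splitlines():
        m = _CONTIG_RE.match(line)
        if m:
            flush()
            cur_name = m.group(1)
            consensus_parts = []
            pending = []
            target = consensus_parts
            continue
        m = _READ_RE.match(line)
        if m:
            if cur_name is None:
                raise ValueError("read header before any contig header")
            pending.append((m.group(1), int(m.group(2)), []))
            target = pending[-1][2]
            continue
        if line.startswith("#"):
            raise ValueError(f"unparseable header line: {line!r}")
        if target is not None and line.strip():
            target.append(line.strip())
    flush()
    return contigs


def read_tigr(path: str | Path) -> MultipleAlignment:
    """Read a TIGR ``.contig`` file containing exactly one contig."""
    contigs = read_tigr_contigs(path)
    if not contigs:
        raise ValueError("no contigs found in TIGR input")
    if len(contigs) > 1:
        raise ValueError(
            f"expected one contig, found {len(contigs)}: "
            f"{[c.name for c in contigs]}; use read_tigr_contigs()"
        )
    return contigs[0]


def write_tigr(aln: MultipleAlignment, handle) -> None:
    """Write an alignment in TIGR ``.contig`` layout (lossless round-trip)."""
    close = False
    if isinstance(handle, (str, Path)):
        handle = open(handle, "w")
        close = True
    try:
        cons = _column_majority_string(aln)
        handle.write(
            f"##{aln.name} {len(aln.reads)} {aln.length} bases, 00000000 checksum.\n"
        )
        for chunk in _wrap(cons):
            handle.write(chunk + "\n")
        for r in aln.reads:
            handle.write(
                f"#{r.id}({r.start}) [] {len(r.bases)} bases, 00000000 checksum. "
                f"{{1 {len(r.bases)}}} <{r.start + 1} {r.end}>\n"
            )
            for chunk in _wrap(r.bases):
                handle.write(chunk + "\n")
    finally:
        if close:
            handle.close()


def _column_majority_string(aln: MultipleAlignment) -> str:
    import numpy as np

    if aln.length == 0:
        return ""
    counts = aln.counts[:, :5]
    best = counts.argmax(axis=1)
    chars = np.array(list("ACGT-"))
    out = chars[best]
    out[counts.sum(axis=1) == 0] = "N"
    return "".join(out)


def _wrap(s: str, width: int = 60):
    return [s[i : i + width] for i in range(0, len(s), width)] or [""]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta_haplotypes(path: str | Path) -> HaplotypeSet:
    """Load equal-length ungapped haplotype sequences from FASTA."""
    records = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]
    if records:
        ref_id, ref_seq = records[0]
        for rid, seq in records[1:]:
            if len(seq) != len(ref_seq):
                raise ValueError(
                    f"haplotypes must be equal length: {ref_id!r} has "
                    f"{len(ref_seq)} bp but {rid!r} has {len(seq)} bp"
                )
    return HaplotypeSet(records)


def write_regions(regions, universal, fasta_path, tsv_path=None) -> None:
    """Write assembled haplotype regions as FASTA plus a TSV summary.

    The FASTA keeps ``'~'`` at loci no member read covers; headers carry the
    region id, member-read count and mean coverage. The universal haplotype
    (reads consistent with every haplotype) is written last.
    """
    fasta_path = Path(fasta_path)
    if tsv_path is None:
        tsv_path = fasta_path.with_suffix(".tsv")
    entries = list(regions)
    if universal is not None:
        entries.append(universal)
    recs = [
        SeqRecord(
            Seq(reg.consensus),
            id=reg.name,
            description=(
                f"reads={len(reg.members)} covered_bases={reg.covered_bases} "
                f"mean_coverage={reg.mean_coverage:.3f}"
            ),
        )
        for reg in entries
    ]
    with open(fasta_path, "w") as fh:
        SeqIO.write(recs, fh, "fasta-2line")
    with open(tsv_path, "w") as fh:
        fh.write("region\tcovered_bases\tmean_coverage\tmember_reads\n")
        for reg in entries:
            fh.write(
                f"{reg.name}\t{reg.covered_bases}\t{reg.mean_coverage:.4f}\t"
                + ",".join(reg.members)
                + "\n"
            )


# ---------------------------------------------------------------------------
# SAM writing (simulator output; alignments without inserted columns)
# ---------------------------------------------------------------------------

def write_sam(aln: MultipleAlignment, handle) -> None:
    """Write an alignment as SAM text (columns = reference positions).

    ``'-'`` runs inside reads become ``D`` CIGAR operations. Only valid for
    alignments whose columns are all reference positions (no insertions) —
    true of simulator output and of anything parsed from pure-match SAM.
    """
    close = False
    if isinstance(handle, (str, Path)):
        handle = open(handle, "w")
        close = True
    try:
        handle.write("@HD\tVN:1.6\tSO:coordinate\n")
        handle.write(f"@SQ\tSN:{aln.name}\tLN:{aln.length}\n")
        for r in sorted(aln.reads, key=lambda r: (r.start, r.id)):
            cigar, seq = _to_cigar(r.bases)
            handle.write(
                f"{r.id}\t0\t{aln.name}\t{r.start + 1}\t60\t{cigar}\t*\t0\t0\t"
                f"{seq}\t*\n"
            )
    finally:
        if close:
            handle.close()


def _to_cigar(bases: str) -> tuple[str, str]:
    ops: list[tuple[str, int]] = []
    for ch in bases:
        op = "D" if ch == "-" else "M"
        if ops and ops[-1][0] == op:
            ops[-1] = (op, ops[-1][1] + 1)
        else:
            ops.append((op, 1))
    cigar = "".join(f"{n}{op}" for op, n in ops)
    seq = bases.replace("-", "")
    return cigar, seq
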