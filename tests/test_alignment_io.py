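"""Alignment model and format I/O."""

import numpy as np
import pysam
import pytest

from hapweave.alignment import AlignedRead, MultipleAlignment
from hapweave.io import (
    read_fasta_haplotypes,
    read_sam,
    read_tigr,
    write_regions,
    write_sam,
    write_tigr,
)
from hapweave.haplotyping import HaplotypeRegion

from conftest import make_aln

SAM_HEADER = "@HD\tVN:1.6\n@SQ\tSN:ref\tLN:50\n"


def _sam(tmp_path, records, header=SAM_HEADER):
    p = tmp_path / "t.sam"
    p.write_text(header + "".join(records))
    return p


def _rec(name, pos, cigar, seq, flag=0, rname="ref"):
    return f"{name}\t{flag}\t{rname}\t{pos}\t60\t{cigar}\t*\t0\t0\t{seq}\t*\n"


class TestReadSam:
    def test_plain_match_is_identity(self, tmp_path):
        aln = read_sam(_sam(tmp_path, [_rec("r1", 1, "5M", "ACGTA")]))
        (r,) = aln.reads
        assert (r.start, r.bases) == (0, "ACGTA")
        assert aln.length == 50

    def test_deletion_becomes_dash_allele(self, tmp_path):
        aln = read_sam(_sam(tmp_path, [_rec("r1", 1, "2M1D2M", "ACGT")]))
        (r,) = aln.reads
        assert r.bases == "AC-GT"
        assert r.end - r.start == 5

    def test_soft_clip_is_trimmed(self, tmp_path):
        aln = read_sam(_sam(tmp_path, [_rec("r1", 5, "3S4M", "TTTACGT")]))
        (r,) = aln.reads
        assert (r.start, r.bases) == (4, "ACGT")

    def test_insertion_columns_are_shared(self, tmp_path):
        # r1 inserts GG after ref pos 2; r2 spans the same point without an
        # insertion and must show '-' at the two inserted columns
        aln = read_sam(
            _sam(
                tmp_path,
                [_rec("r1", 1, "2M2I2M", "ACGGTA"), _rec("r2", 1, "4M", "ACTA")],
            )
        )
        r1, r2 = sorted(aln.reads, key=lambda r: r.id)
        assert r1.bases == "ACGGTA"
        assert r2.bases == "AC--TA"
        assert aln.length == 52

    def test_unmapped_reads_skipped(self, tmp_path):
        aln = read_sam(
            _sam(tmp_path, [_rec("r1", 1, "3M", "ACG"), _rec("r2", 0, "*", "AAA", flag=4)])
        )
        assert [r.id for r in aln.reads] == ["r1"]

    def test_multi_reference_rejected_by_name(self, tmp_path):
        header = "@HD\tVN:1.6\n@SQ\tSN:ref\tLN:50\n@SQ\tSN:other\tLN:50\n"
        p = _sam(
            tmp_path,
            [_rec("r1", 1, "3M", "ACG"), _rec("r2", 1, "3M", "ACG", rname="other")],
            header,
        )
        with pytest.raises(ValueError, match="other"):
            read_sam(p)

    def test_mates_become_independent_reads(self, tmp_path):
        recs = [
            _rec("p", 1, "3M", "ACG", flag=0x1 | 0x40),
            _rec("p", 10, "3M", "TTT", flag=0x1 | 0x80),
        ]
        aln = read_sam(_sam(tmp_path, recs))
        ids = sorted(r.id for r in aln.reads)
        assert ids == ["p/1", "p/2"]
        spans = sorted((r.start, r.end) for r in aln.reads)
        assert spans == [(0, 3), (9, 12)]

    def test_depth_profile_matches_independent_pileup(self, tmp_path):
        rng = np.random.default_rng(7)
        recs = []
        for i in range(30):
            pos = int(rng.integers(1, 40))
            ln = int(rng.integers(1, min(10, 51 - pos)))
            seq = "".join(rng.choice(list("ACGT"), size=ln))
            recs.append(_rec(f"r{i}", pos, f"{ln}M", seq))
        path = _sam(tmp_path, recs)
        aln = read_sam(path)
        # independent pileup from pysam's own per-record reference positions
        depth = np.zeros(50, dtype=int)
        with pysam.AlignmentFile(str(path), "r") as sam:
            for rec in sam:
                for p in rec.get_reference_positions():
                    depth[p] += 1
        assert np.array_equal(aln.depth_profile(), depth)


TIGR_TEXT = """##ctg1 2 10 bases, 00000000 checksum.
ACGTACGTAC
#readA(0) [] 10 bases, 00000000 checksum. {1 10} <1 10>
ACGTACGTAC
#readB(3) [] 5 bases, 00000000 checksum. {1 5} <4 8>
TAC-T
"""


class TestTigr:
    def test_single_read_contig(self, tmp_path):
        p = tmp_path / "c.contig"
        p.write_text(
            "##c 1 4 bases, 0 checksum.\nACGT\n#only(0) [] 4 bases, 0 checksum.\nACGT\n"
        )
        aln = read_tigr(p)
        assert aln.name == "c" and aln.length == 4
        assert aln.reads[0].bases == "ACGT" and aln.reads[0].start == 0

    def test_offsets_and_depth(self, tmp_path):
        p = tmp_path / "c.contig"
        p.write_text(TIGR_TEXT)
        aln = read_tigr(p)
        assert aln.length == 10
        # readB spans cols 3..7; its '-' at col 6 is a deletion allele and
        # still counts as informative coverage
        assert [aln.depth(i) for i in range(10)] == [1, 1, 1, 2, 2, 2, 2, 2, 1, 1]
        rb = next(r for r in aln.reads if r.id == "readB")
        assert rb.bases == "TAC-T"  # internal pad kept as deletion allele

    def test_read_past_contig_end_rejected(self, tmp_path):
        p = tmp_path / "c.contig"
        p.write_text(
            "##c 1 4 bases, 0 checksum.\nACGT\n#r(2) [] 4 bases, 0 checksum.\nACGT\n"
        )
        with pytest.raises(ValueError, match="extends past"):
            read_tigr(p)

    def test_stdin_dash_equivalent_to_file(self, tmp_path, monkeypatch):
        import io as _stdio

        p = tmp_path / "c.contig"
        p.write_text(TIGR_TEXT)
        from_file = read_tigr(p)
        monkeypatch.setattr("sys.stdin", _stdio.StringIO(TIGR_TEXT))
        from_stdin = read_tigr("-")
        assert from_file.length == from_stdin.length
        assert [(r.id, r.start, r.bases) for r in from_file.reads] == [
            (r.id, r.start, r.bases) for r in from_stdin.reads
        ]

    def test_write_read_round_trip_is_lossless(self, tmp_path):
        rng = np.random.default_rng(11)
        reads = []
        for i in range(20):
            start = int(rng.integers(0, 30))
            ln = int(rng.integers(1, 15))
            bases = "".join(rng.choice(list("ACGT-"), size=ln))
            reads.append((f"r{i}", start, bases))
        aln = make_aln(reads, length=45, name="rt")
        p = tmp_path / "rt.contig"
        write_tigr(aln, p)
        back = read_tigr(p)
        assert back.length == aln.length
        assert {(r.id, r.start, r.bases) for r in back.reads} == {
            (r.id, r.start, r.bases) for r in aln.reads
        }


class TestSamRoundTrip:
    def test_sam_write_read_preserves_alleles(self, tmp_path):
        aln = make_aln(
            [("a", 0, "ACGT-ACG"), ("b", 3, "T-AC"), ("c", 6, "GGGG")],
            length=12,
            name="ctg",
        )
        p = tmp_path / "rt.sam"
        write_sam(aln, p)
        back = read_sam(p)
        assert back.length == 12
        assert {(r.id, r.start, r.bases) for r in back.reads} == {
            (r.id, r.start, r.bases) for r in aln.reads
        }


class TestFastaAndRegions:
    def test_haplotypes_uppercased_order_preserved(self, tmp_path):
        p = tmp_path / "h.fasta"
        p.write_text(">h2\nacgt\n>h1\nTTTT\n")
        hs = read_fasta_haplotypes(p)
        assert hs.sequences == [("h2", "ACGT"), ("h1", "TTTT")]

    def test_unequal_lengths_rejected_naming_both(self, tmp_path):
        p = tmp_path / "h.fasta"
        p.write_text(">one\nACGTACGTAC\n>two\nACGTACGTACG\n")
        with pytest.raises(ValueError, match="one.*two"):
            read_fasta_haplotypes(p)

    def _region(self, name="reg"):
        return HaplotypeRegion(
            name=name,
            core=["x"],
            members=["x", "y"],
            consensus="~~~ACGTA~~",
            covered_bases=5,
            mean_coverage=1.6,
        )

    def test_region_fasta_keeps_tildes_and_round_trips(self, tmp_path):
        from Bio import SeqIO

        universal = HaplotypeRegion("uni", [], [], "AC~~~~~~GT", 4, 1.0)
        fa = tmp_path / "regions.fasta"
        write_regions([self._region()], universal, fa)
        recs = {r.id: str(r.seq) for r in SeqIO.parse(str(fa), "fasta")}
        assert recs == {"reg": "~~~ACGTA~~", "uni": "AC~~~~~~GT"}
        tsv = (tmp_path / "regions.tsv").read_text().splitlines()
        assert tsv[0].startswith("region\t")
        assert tsv[1].split("\t")[:2] == ["reg", "5"]

    def test_empty_region_list_writes_universal_only(self, tmp_path):
        from Bio import SeqIO

        universal = HaplotypeRegion("uni", [], [], "ACGT", 4, 2.0)
        fa = tmp_path / "u.fasta"
        write_regions([], universal, fa)
        assert [r.id for r in SeqIO.parse(str(fa), "fasta")] == ["uni"]


class TestInvariants:
    def test_read_validation(self):
        with pytest.raises(ValueError):
            AlignedRead("r", 0, "")
        with pytest.raises(ValueError):
            AlignedRead("r", -1, "ACG")
        with pytest.raises(ValueError):
            AlignedRead("r", 0, "AC~G")  # '~' may not occur inside a read
        with pytest.raises(ValueError):
            MultipleAlignment(3, [AlignedRead("r", 1, "ACG")])

    def test_column_and_depth(self):
        aln = make_aln([("a", 0, "ACGT"), ("b", 2, "GNAA")], length=6)
        assert sorted(aln.column(2)) == ["G", "G"]
        assert sorted(aln.column(3)) == ["N", "T"]
        assert aln.depth(3) == 1  # N is not informative
        assert aln.depth(5) == 1 and aln.depth(1) == 1
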