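"""End-to-end per-read mapping: record geometry, CIGAR round-trips, SAM."""

import io

import numpy as np
import pysam
import pytest

from invmap import RunConfig, map_read, map_reads
from invmap.io import revcomp


@pytest.fixture(scope="module")
def refseqs(genome):
    return [genome]


def reconstruct_check(rec, genome):
    """Applying the CIGAR to the reference must reproduce the read bases."""
    qpos, gpos = 0, rec.pos
    for op, n in rec.cigar:
        if op == "=":
            assert rec.seq[qpos:qpos + n] == genome[gpos:gpos + n]
            qpos += n
            gpos += n
        elif op == "X":
            assert all(rec.seq[qpos + i] != genome[gpos + i] for i in range(n))
            qpos += n
            gpos += n
        elif op in "IS":
            qpos += n
        elif op == "D":
            gpos += n
        else:
            raise AssertionError(f"unexpected op {op}")
    assert qpos == len(rec.seq)


def query_bases(rec):
    return sum(n for op, n in rec.cigar if op in "=XIS")


class TestSvFreeReads:
    def test_forward_read_single_clean_record(self, genome, index_w5, refseqs):
        read = genome[4000:10000]
        rm = map_read("r", read, index_w5, RunConfig(), refseqs)
        assert len(rm.records) == 1 and not rm.calls
        rec = rm.records[0]
        assert rec.flag & 16 == 0
        assert not any(op == "S" and n > 20 for op, n in rec.cigar)
        reconstruct_check(rec, genome)

    def test_reverse_read_flag16(self, genome, index_w5, refseqs):
        read = revcomp(genome[4000:10000])
        rm = map_read("r", read, index_w5, RunConfig(), refseqs)
        rec = rm.records[0]
        assert rec.flag & 16
        assert rec.seq == revcomp(read)
        reconstruct_check(rec, genome)

    def test_junk_read_unmapped(self, index_w5, refseqs):
        junk = "".join(np.array(list("ACGT"))[
            np.random.default_rng(5).integers(0, 4, 400)])
        rm = map_read("junk", junk, index_w5, RunConfig(), refseqs)
        assert rm.is_unmapped


class TestInversionReads:
    def read_with_middle_inversion(self, genome):
        return genome[4000:8000] + revcomp(genome[8000:9000]) + genome[9000:13000]

    def test_three_records_for_middle_inversion(self, genome, index_w5, refseqs):
        read = self.read_with_middle_inversion(genome)
        rm = map_read("r", read, index_w5, RunConfig(), refseqs)
        assert len(rm.records) == 3
        assert len(rm.calls) == 1
        c = rm.calls[0]
        assert abs(c.ps_ref - 8000) <= 14 and abs(c.pe_ref - 9000) <= 14
        flags = sorted(r.flag for r in rm.records)
        # one primary forward, one supplementary forward, one supplementary
        # reverse (the inverted part)
        assert flags == [0, 2048, 2048 | 16]
        for rec in rm.records:
            reconstruct_check(rec, genome)
            assert query_bases(rec) == len(read)

    def test_reverse_sampled_inversion_symmetric(self, genome, index_w5, refseqs):
        read = revcomp(self.read_with_middle_inversion(genome))
        rm = map_read("r", read, index_w5, RunConfig(), refseqs)
        assert len(rm.calls) == 1
        c = rm.calls[0]
        assert abs(c.ps_ref - 8000) <= 14 and abs(c.pe_ref - 9000) <= 14
        # read-interval coordinates are in the read's own orientation
        assert abs(c.ps_read - 4000) <= 14 and abs(c.pe_read - 5000) <= 14
        flags = sorted(r.flag for r in rm.records)
        assert flags == [16, 2048, 2048 | 16]

    def test_boundary_inversion_detected(self, genome, index_w5, refseqs):
        read = revcomp(genome[6000:6700]) + genome[6700:12000]
        rm = map_read("r", read, index_w5, RunConfig(), refseqs)
        assert len(rm.calls) == 1
        c = rm.calls[0]
        assert abs(c.ps_ref - 6000) <= 14 and abs(c.pe_ref - 6700) <= 14

    def test_sa_tags_cross_reference(self, genome, index_w5, refseqs):
        read = self.read_with_middle_inversion(genome)
        rm = map_read("r", read, index_w5, RunConfig(), refseqs)
        for rec in rm.records:
            assert rec.tags["SA"].count(";") == len(rm.records) - 1


class TestSamOutput:
    def make_sam(self, genome, index_w5, refseqs, reads):
        buf = io.StringIO()
        map_reads(reads, index_w5, refseqs, RunConfig(), sam_out=buf)
        return buf.getvalue()

    def test_sam_parses_and_validates(self, genome, index_w5, refseqs, tmp_path):
        reads = [
            ("fwd", genome[2000:9000]),
            ("rev", revcomp(genome[2000:9000])),
            ("inv", genome[2000:6000] + revcomp(genome[6000:6800])
             + genome[6800:10000]),
            ("junk", "ACGT" * 100),
        ]
        text = self.make_sam(genome, index_w5, refseqs, reads)
        p = tmp_path / "out.sam"
        p.write_text(text)
        with pysam.AlignmentFile(str(p), "r") as fh:
            recs = list(fh)
        names = {r.query_name for r in recs}
        assert names == {"fwd", "rev", "inv", "junk"}
        for r in recs:
            if r.is_unmapped:
                continue
            assert r.infer_read_length() == len(r.query_sequence)
            # aligned reference slice agrees with the =-runs
            assert r.reference_end > r.reference_start

    def test_zero_reads_header_only(self, index_w5, refseqs, tmp_path):
        buf = io.StringIO()
        map_reads([], index_w5, refseqs, RunConfig(), sam_out=buf)
        lines = buf.getvalue().strip().splitlines()
        assert lines and all(l.startswith("@") for l in lines)

    def test_byte_identical_reruns(self, genome, index_w5, refseqs):
        reads = [("a", genome[1000:7000]), ("b", revcomp(genome[8000:14000]))]
        assert (self.make_sam(genome, index_w5, refseqs, reads)
                == self.make_sam(genome, index_w5, refseqs, reads))

    def test_samtools_accepts_output(self, genome, index_w5, refseqs, tmp_path):
        import subprocess
        reads = [("inv", genome[2000:6000] + revcomp(genome[6000:6800])
                  + genome[6800:10000])]
        p = tmp_path / "out.sam"
        p.write_text(self.make_sam(genome, index_w5, refseqs, reads))
        res = subprocess.run(["samtools", "view", "-c", str(p)],
                             capture_output=True, text=True)
        assert res.returncode == 0
        assert int(res.stdout.strip()) >= 1


def test_noisy_read_round_trip(genome, index_w5, refseqs):
    """10% error read: every record's CIGAR still reconstructs exactly."""
    rng = np.random.default_rng(31)
    from invmap.simulate import SimConfig, _apply_errors
    template = genome[3000:11000]
    cfg = SimConfig(error_rate=0.10, seed=0)
    read, _ = _apply_errors(template, rng, cfg)
    rm = map_read("noisy", read, index_w5, RunConfig(), refseqs)
    assert not rm.is_unmapped
    for rec in rm.records:
        reconstruct_check(rec, genome)
        assert query_bases(rec) == len(read)
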