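"""Simulator: determinism, SV implanting, error channel calibration."""

import edlib
import numpy as np
import pytest

from invmap.io import revcomp
from invmap.simulate import (SimConfig, implant_svs, make_genome,
                             read_truth, simulate, simulate_reads,
                             write_truth)


class TestMakeGenome:
    def test_deterministic(self):
        a = make_genome(10_000, seed=1)
        b = make_genome(10_000, seed=1)
        assert a.sequences == b.sequences

    def test_length(self):
        assert len(make_genome(10_000, seed=2)[0][1]) == 10_000

    def test_gc_fraction_near_half(self):
        seq = make_genome(100_000, seed=3)[0][1]
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert abs(gc - 0.5) < 0.02

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            make_genome(500, seed=0)


class TestImplantSvs:
    def test_single_inversion_revcomps_interval(self):
        ref = make_genome(10_000, seed=4)
        cfg = SimConfig(genome_len=10_000, n_inv=1, inv_len=(200, 200), seed=4)
        alt, svs = implant_svs(ref, cfg)
        (sv,) = svs
        orig = ref[0][1]
        new = alt[0][1]
        s, e = sv.orig_start, sv.orig_end
        assert new[s:e] == revcomp(orig[s:e])
        assert new[:s] == orig[:s] and new[e:] == orig[e:]

    def test_zero_svs_identity(self):
        ref = make_genome(5_000, seed=5)
        cfg = SimConfig(genome_len=5_000, n_inv=0, seed=5)
        alt, svs = implant_svs(ref, cfg)
        assert alt.sequences == ref.sequences and svs == []

    def test_100_disjoint_inversions(self):
        ref = make_genome(1_000_000, seed=6)
        cfg = SimConfig(genome_len=1_000_000, n_inv=100, seed=6)
        alt, svs = implant_svs(ref, cfg)
        assert len(svs) == 100
        ivs = sorted((sv.orig_start, sv.orig_end) for sv in svs)
        assert all(a_end <= b_start for (_, a_end), (b_start, _)
                   in zip(ivs, ivs[1:]))

    def test_infeasible_spec_errors(self):
        ref = make_genome(2_000, seed=7)
        cfg = SimConfig(genome_len=2_000, n_inv=50, inv_len=(500, 500), seed=7)
        with pytest.raises(ValueError, match="disjoint"):
            implant_svs(ref, cfg)

    def test_indels_shift_coordinates(self):
        ref = make_genome(20_000, seed=8)
        cfg = SimConfig(genome_len=20_000, n_inv=0, n_del=2, n_ins=2, seed=8)
        alt, svs = implant_svs(ref, cfg)
        delta = sum((sv.alt_end - sv.alt_start) - (sv.orig_end - sv.orig_start)
                    for sv in svs)
        assert len(alt[0][1]) == len(ref[0][1]) + delta


class TestSimulateReads:
    def test_error_free_reads_are_substrings(self):
        cfg = SimConfig(genome_len=20_000, n_inv=0, coverage=2.0,
                        error_rate=0.0, read_len=3_000, seed=9)
        _, alt, _, reads, truth = simulate(cfg)
        seq = alt[0][1]
        for (name, read), t in zip(reads, truth):
            window = seq[t.start:t.end]
            assert read == (window if t.strand == "+" else revcomp(window))

    def test_deterministic_per_seed(self):
        cfg = SimConfig(genome_len=20_000, coverage=2.0, seed=10)
        out1 = simulate(cfg)
        out2 = simulate(cfg)
        assert out1[3] == out2[3]
        assert [t.__dict__ for t in out1[4]] == [t.__dict__ for t in out2[4]]

    def test_coverage_total_bases(self):
        cfg = SimConfig(genome_len=50_000, n_inv=0, coverage=10.0,
                        error_rate=0.0, read_len=5_000, seed=11)
        _, _, _, reads, _ = simulate(cfg)
        total = sum(len(s) for _, s in reads)
        assert abs(total - 10.0 * 50_000) / (10.0 * 50_000) < 0.1

    def test_empirical_error_rate(self):
        """Edit distance of noisy reads vs their true windows ~ 15%."""
        cfg = SimConfig(genome_len=100_000, n_inv=0, coverage=12.0,
                        error_rate=0.15, read_len=10_000, seed=12)
        _, alt, svs, reads, truth = simulate(cfg)
        seq = alt[0][1]
        dist = bases = 0
        for (name, read), t in zip(reads, truth):
            window = seq[t.start:t.end]
            if t.strand == "-":
                window = revcomp(window)
            dist += edlib.align(read, window)["editDistance"]
            bases += len(window)
        assert bases >= 1_000_000
        assert abs(dist / bases - 0.15) < 0.01

    def test_read_inside_inversion_no_quad_strand_flipped(self):
        cfg = SimConfig(genome_len=30_000, n_inv=1, inv_len=(5_000, 5_000),
                        coverage=8.0, error_rate=0.0, read_len=1_500, seed=13)
        ref, alt, svs, reads, truth = simulate(cfg)
        (sv,) = svs
        inside = [t for t in truth
                  if sv.alt_start <= t.start and t.end <= sv.alt_end]
        assert inside, "expected some reads fully inside the 5 kb inversion"
        for t in inside:
            assert t.quads == []
        # strand is flipped relative to the sampling strand, so the
        # original-genome content matches the reported strand
        orig = ref[0][1]
        by_name = dict(reads)
        for t in inside:
            window = orig[t.start:t.end]
            read = by_name[t.name]
            assert read == (window if t.strand == "+" else revcomp(window))

    def test_quadruples_for_spanning_reads(self):
        cfg = SimConfig(genome_len=50_000, n_inv=2, inv_len=(800, 800),
                        coverage=6.0, error_rate=0.0, read_len=6_000, seed=14)
        ref, alt, svs, reads, truth = simulate(cfg)
        orig = ref[0][1]
        by_name = dict(reads)
        quads = [(t, q) for t in truth for q in t.quads]
        assert quads
        for t, q in quads:
            # the read segment [ps_read, pe_read) is the revcomp of the
            # original genome at [ps_ref, pe_ref) (error-free case)
            seg = by_name[t.name][q.ps_read:q.pe_read]
            expect = orig[q.ps_ref:q.pe_ref]
            assert seg == (revcomp(expect) if t.strand == "+"
                           else expect), "quadruple coordinates inconsistent"


def test_truth_tsv_roundtrip(tmp_path):
    cfg = SimConfig(genome_len=30_000, n_inv=2, coverage=3.0, seed=15)
    ref, alt, svs, reads, truth = simulate(cfg)
    p = tmp_path / "truth.tsv"
    write_truth(truth, ref.names, p)
    loaded = read_truth(p, ref.names)
    assert [t.__dict__ for t in loaded] == [t.__dict__ for t in truth]
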