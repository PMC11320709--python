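"""Region extension, the strand transform, and inversion re-chaining."""

import numpy as np
import pytest

from conftest import random_dna
from invmap import (Reference, best_chain, build_index, chain_scores,
                    collect_anchors, compute_d, find_inversion_chains,
                    locate_region, transform_anchors)
from invmap.anchors import Anchor, AnchorSet
from invmap.chain import Chain
from invmap.io import revcomp


def chain_for(read, index, k=15):
    anchors = collect_anchors(read, index)
    scores = chain_scores(anchors, compute_d(len(read)))
    return anchors, best_chain(anchors, scores, k)


def fake_chain(read_span, ref_span, strand="+"):
    return Chain(indices=np.array([0]), score_gain=0, strand=strand,
                 read_span=read_span, ref_span=ref_span, seq_id=0)


class TestLocateRegion:
    def test_no_prefix_no_extension(self):
        r = locate_region(fake_chain((0, 900), (5000, 5900)), 1000, 100000)
        assert r.ext_start == r.p_start == 5000

    def test_prefix_100_extends_120(self):
        r = locate_region(fake_chain((100, 1000), (5000, 5900)), 1000, 100000)
        assert r.ext_start == 5000 - 120

    def test_prefix_40_below_threshold(self):
        r = locate_region(fake_chain((40, 1000), (5000, 5960)), 1000, 100000)
        assert r.ext_start == 5000

    def test_prefix_exactly_50_not_extended(self):
        r = locate_region(fake_chain((50, 1000), (5000, 5950)), 1000, 100000)
        assert r.ext_start == 5000

    def test_suffix_extends_end(self):
        r = locate_region(fake_chain((0, 900), (5000, 5900)), 1000, 100000)
        assert r.ext_end == 5900 + 120

    def test_reverse_chain_swaps_roles(self):
        # read prefix of a '-' chain lies beyond the region end
        r = locate_region(fake_chain((100, 1000), (5000, 5900), "-"),
                          1000, 100000)
        assert r.ext_start == 5000 and r.ext_end == 5900 + 120

    def test_clamped_to_sequence(self):
        r = locate_region(fake_chain((500, 1000), (100, 600)), 1000, 5000)
        assert r.ext_start == 0


class TestTransform:
    def test_opposite_anchor_mirrored(self):
        a = AnchorSet.from_anchors([Anchor(pr=30, pg=70, dr=0, dg=1)])
        t = transform_anchors(a, read_len=100)
        assert t[0].mpr == 70 and t[0].mpg == 70 and t[0].r == "-"

    def test_same_anchor_identity(self):
        a = AnchorSet.from_anchors([Anchor(pr=30, pg=70, dr=1, dg=1)])
        t = transform_anchors(a, read_len=100)
        assert t[0].mpr == 30 and t[0].r == "+"

    def test_involution_on_minus_anchors(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            L = int(rng.integers(100, 10000))
            pr = int(rng.integers(0, L))
            once = L - pr
            twice = L - once
            assert twice == pr

    def test_inverted_block_linearized(self, genome, index_w1):
        """Anchors of an inverted block are anti-diagonal before the
        transform and jointly monotone (chainable) after."""
        read = genome[4000:5000] + revcomp(genome[5000:6000]) + genome[6000:7000]
        anchors, main = chain_for(read, index_w1)
        inv = anchors.take(np.nonzero(~anchors.same_orientation())[0])
        assert len(inv) > 10
        order = np.argsort(inv.pg)
        # before: read coordinate decreases as reference increases
        assert (np.diff(inv.pr[order]) < 0).all()
        t = transform_anchors(inv, len(read))
        # after: sorted by (mpg, mpr), both coordinates strictly increase
        assert (np.diff(t.mpg) > 0).all() and (np.diff(t.mpr) > 0).all()
        scores = chain_scores_transformed(t, compute_d(len(read)))
        assert int(scores.max()) == len(t)  # one chain takes all anchors


def chain_scores_transformed(t, d):
    from invmap._kernels import chain_dp
    score, _ = chain_dp(t.seq_id, t.neg.astype(np.int64), t.mpr, t.mpg,
                        np.int64(d))
    return score


class TestFindInversionChains:
    def residual(self, genome, index, read):
        anchors, main = chain_for(read, index)
        on_main = np.zeros(len(anchors), dtype=bool)
        on_main[main.indices] = True
        region = locate_region(main, len(read), len(genome))
        inside = (anchors.pg >= region.ext_start) & (anchors.pg < region.ext_end)
        res = anchors.take(np.nonzero(~on_main & inside)[0])
        return transform_anchors(res, len(read), main.strand), main

    def test_sv_free_read_no_calls(self, genome, index_w1):
        t, _ = self.residual(genome, index_w1, genome[2000:5000])
        calls = find_inversion_chains(t, compute_d(3000), k=15)
        assert calls == []

    def test_single_inverted_block_found(self, genome, index_w1):
        read = genome[4000:5000] + revcomp(genome[5000:5500]) + genome[5500:6500]
        t, _ = self.residual(genome, index_w1, read)
        calls = find_inversion_chains(t, compute_d(len(read)), k=15)
        assert len(calls) == 1
        c = calls[0]
        assert abs(c.ps_ref - 5000) <= 14 and abs(c.pe_ref - 5500) <= 14
        assert abs(c.ps_read - 1000) <= 14 and abs(c.pe_read - 1500) <= 14

    def test_two_anchor_chain_rejected(self):
        # 2 anchors spanning 400 bp on both axes: fails the anchor-count rule
        t = transformed_from([(100, 1000), (500, 1400)])
        assert find_inversion_chains(t, d=10000, k=15) == []

    def test_short_span_rejected(self):
        # 5 anchors spanning only ~30 bp: fails the span rule
        t = transformed_from([(100 + 4 * i, 1000 + 4 * i) for i in range(5)])
        assert find_inversion_chains(t, d=10000, k=15) == []

    def test_three_anchors_wide_span_accepted(self):
        t = transformed_from([(100, 1000), (140, 1040), (180, 1080)])
        calls = find_inversion_chains(t, d=10000, k=15)
        assert len(calls) == 1 and calls[0].n_anchors == 3


def transformed_from(pairs, read_len=2000):
    """Build '-' residual anchors whose transform lands on the given
    (mpr, mpg) pairs."""
    anchors = AnchorSet.from_anchors(
        [Anchor(pr=read_len - mpr, pg=mpg, dr=0, dg=1) for mpr, mpg in pairs])
    return transform_anchors(anchors, read_len)


def test_calls_disjoint_on_reference(genome, index_w1):
    read = (genome[2000:3000] + revcomp(genome[3000:3400])
            + genome[3400:4400] + revcomp(genome[4400:5000])
            + genome[5000:6000])
    anchors = collect_anchors(read, index_w1)
    scores = chain_scores(anchors, compute_d(len(read)))
    main = best_chain(anchors, scores, 15)
    on_main = np.zeros(len(anchors), dtype=bool)
    on_main[main.indices] = True
    res = anchors.take(np.nonzero(~on_main)[0])
    t = transform_anchors(res, len(read), main.strand)
    calls = find_inversion_chains(t, compute_d(len(read)), k=15)
    assert len(calls) == 2
    calls.sort(key=lambda c: c.ps_ref)
    assert calls[0].pe_ref <= calls[1].ps_ref
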