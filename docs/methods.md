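# Methods

## Model and assumptions

invmap is a seed-chain-extend mapper specialized for inversions. Its core
assumption is the standard one: outside of structural variants a long read
is co-linear with the reference up to a ~15% error rate, so exact k-mer
matches (anchors) concentrate near one diagonal of the read-vs-reference
dot plot. Inversions violate co-linearity in a specific, recoverable way —
their anchors lie on an anti-diagonal — and the method's contribution is a
second chaining pass over coordinate-transformed residual anchors rather
than a ranking of multiple candidate chains.

The pipeline per read:

1. **Seeding.** Canonical minimizers (k = 15, window w = 5) of the read
   are looked up in a hash index of the reference. Each hit yields an
   anchor (pr, pg, dr, dg); only the predicate dr = dg ("same
   orientation") is consumed downstream.
2. **Main chain.** A DP over anchors sorted by (reference, read) position
   awards +1 per chained anchor. A precursor must share both strand bits,
   advance strictly on the reference, advance on the read along the
   orientation's diagonal (forward for same-orientation anchors, backward
   for opposite-orientation ones, so reverse-strand reads chain without
   any transform), and lie within d = ceil(1.15 · read length) on both
   axes. The path with the maximal score increase is the main chain;
   with a +1-per-anchor reward this is exactly the path ending at the
   globally maximal score, since every path origin scores 1.
3. **Region extension.** The reference interval covered by the main chain
   is extended by ceil(1.2 · flank length) on a side whose unchained read
   flank exceeds 50 bp, so anchors of a boundary inversion fall inside
   the region. For reverse-oriented main chains the read prefix extends
   the region end and vice versa.
4. **Inversion re-chaining.** Residual anchors inside the extended region
   get the mirror transform mpr = pr if dr = dg else read_len − pr,
   mpg = pg, with an orientation label that is *relative to the main
   chain*: anchors opposing the main chain are labelled '−'. (With a
   forward main chain this is the printed transform; with a reverse main
   chain the labels swap while the mirrored coordinate is still applied
   to absolute-opposite anchors — both cases leave candidate inversion
   chains jointly monotone in (mpr, mpg).) The same chaining DP runs on
   the transformed residuals; the best chain is extracted and its anchors
   removed, repeating up to 5 rounds. A chain of uniformly '−' anchors
   with at least 3 anchors and both spans strictly greater than 50 bp
   becomes an inversion call; uniform '+' chains (duplication-like
   signals) are detected but discarded unclassified.
5. **Call/chain reconciliation.** Chance k-mer matches crossing an
   inversion breakpoint can extend a raw call a few bases into the
   flanking main-chain anchors. Supporting anchors are trimmed to the
   enclosing main-chain gap (located by the call's median anchor on both
   axes) and the quadruple is recomputed; the call survives if it still
   meets the anchor-count and span rules. Accepted calls are mutually
   disjoint on both read and reference.
6. **Base-level alignment.** Chains partition read and reference into
   paired segments: anchor k-mers are exact-match runs (overlapping
   anchors clipped symmetrically), inner gaps get affine-gap global
   alignment, and the read's unchained prefix/suffix is paired with
   ceil(1.15 · flank) reference bases inside the extended region and
   aligned with the distal reference end free, so no spurious terminal
   deletions appear. A boundary alignment with identity below 30% is
   soft-clipped instead — at reference edges or over junk flanks a forced
   global alignment is worse than an honest clip.
7. **Records.** SAM has no internal soft clips, so a read with a middle
   inversion cannot be one record per chain: the read is split into
   parts — main-chain flanks and each inverted block — and each part is
   emitted as one record (the inverted part on the opposite strand). The
   largest main part is primary; the rest are supplementary (flag 2048)
   with SA tags. Records never begin or end with a deletion; the POS
   shifts instead.

## Parameters

| parameter | default | meaning |
|---|---|---|
| k | 15 | k-mer length (canonical, 2-bit packed) |
| w | 5 | minimizer window; w = 1 indexes/samples every k-mer |
| max_occ | 500 | drop index keys with more hits (repeat masking) |
| d_factor | 1.15 | chaining distance bound as a fraction of read length |
| extend_factor | 1.2 | aligned-region extension per unchained flank |
| min_flank | 50 bp | flank length that triggers the extension |
| min_inv_anchors | 3 | anchors required for an inversion chain |
| min_inv_span | 50 bp | read- and reference-span an inversion must exceed |
| match/mismatch | +2 / −4 | alignment scores |
| gap | −4 − 2·L | affine gap cost for a gap of length L |

The span rule is applied to **both** the read span and the reference span,
exclusively (> 50). k = 15 with w = 5 keeps anchor density high (on
average one minimizer per 3 positions); `-w 1` reproduces dense all-k-mer
seeding at higher cost. The minimizer hash is an invertible 64-bit mix
(splitmix-style finalizer) of the packed canonical k-mer; ties within a
window break to the smallest hash, then the leftmost position. K-mers
containing N are never seeded.

MAPQ is 60·(1 − second_gain/best_gain) clamped to [0, 60], where
second_gain is the best DP gain among anchors off the main chain; a
single-anchor chain gets 0.

## Numerical and degenerate-case choices

- Chaining ties (equal-score precursors) resolve to the nearest precursor;
  equal-gain chains to the smallest reference start, then read start.
  Determinism everywhere: identical inputs give byte-identical SAM.
- The Gotoh DP keeps three states with gap opening allowed from any state;
  segments above 1 kb use a diagonal band of half-width
  max(64, 0.15·len) + |length difference|, which contains any path whose
  extra indels stay within the error model; full DP below. Banded and
  full scores are asserted equal on random noisy pairs in the tests.
- Empty-vs-nonempty gap segments become pure I/D runs; empty-vs-empty
  segments vanish. Segments are capped at 20 kb (configurable).
- Anchors overlapping on read or reference are clipped by the larger of
  the two deficits so the match run stays length-consistent on both axes.

## The simulator, and what passing tests do not show

The generator produces uniform-random ACGT genomes, implants
non-overlapping inversions (reverse-complemented in place; deletions and
insertions also supported) with a 500 bp separation margin, and samples
reads uniformly in position and strand until coverage × genome length
bases. Errors are i.i.d. per base, split 50% substitution / 40% deletion /
10% insertion of the total rate (0.15 default); read lengths are fixed or
log-normal (8 kb median, truncated to [1, 30] kb). Each read carries its
true original-genome interval and strand, plus a quadruple
(PS_ref, PE_ref, PS_read, PE_read) for every inversion breakpoint the read
crosses, with the read-side coordinates projected through the error
channel. A read sampled entirely inside an inverted block is locally
co-linear, so it gets a flipped truth strand and no quadruple.

Real genomes are not uniform-random: repeats create ambiguous anchors,
error processes are context-dependent (homopolymers), and real inversions
carry flanking repeats that defeat k-mer seeding. Passing the bundled
benchmarks therefore demonstrates the correctness of the chaining,
transform and alignment machinery under the stated error model — not
mapping accuracy on human data.

Benchmark problem sizes were chosen at desk scale as the package's own
evaluation conditions: 100 kb genomes, five inversions of 200–2000 bp,
10 kb reads, 20× error-free and 40× at 10% error. Under the error-free
condition every inversion fully spanned by a read is recovered and every
read is located correctly; under the noisy condition pooled sensitivity
sits near 0.9 with precision at 1.0, the residual misses being reads that
clip an inversion edge by less than the span an anchor chain needs.

## Evaluation metric conventions

- Location accuracy: a read counts when its primary record is on the true
  strand and the union of aligned (non-clipped) reference intervals over
  its records covers ≥ 90% of the true interval — with per-part records a
  read spanning an inversion cannot reach 90% from any single record, and
  clipped portions are excluded by definition. The criterion is one-way
  (relative to the true interval's length), and intervals are half-open
  with "overlap" meaning ≥ 1 shared base.
- Inversion recovery: a call is correct when it shares ≥ 1 base with a
  truth quadruple of the same read on both the reference and the read
  axis. A truth recovered by several calls counts once for sensitivity;
  each matching call counts for precision. Zero predictions report
  precision 0 with an explicit degenerate flag.

## Known limitations

- One main chain per read: no multi-locus candidate ranking, so chimeric
  or split reads spanning distant loci are not modelled.
- Only inversions are classified among residual chains; duplications and
  translocations are detected as '+' chains and dropped.
- No base-quality awareness, no BAM/CRAM output, no multithreading.
- Inversions shorter than ~60 bp rarely retain three anchors at k = 15
  and go undetected, consistent with the span thresholds.
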