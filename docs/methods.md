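# Methods

This note documents the models, defaults, and numerical choices behind
`pistop`, and what the synthetic benchmarks do and do not establish about
real small-RNA data.

## The 5′ end definition score

For a transcript position *x* within a scored region, with *f(x)* the number
of read 5′ ends mapping exactly to *x* (strand-matched to the region),

    s(x) = f(x) / Σ_{i = x−10}^{x+20} f(i).

Conventions:

* The summation bounds are inclusive, so the window spans 31 positions
  including *x* itself. The window is transcript-oriented: upstream means
  toward the transcript's 5′ end, so on minus-strand regions the genomic
  direction flips.
* The coverage gate (`min_local_reads`, default 100) applies to the window
  sum (the denominator), not to *f(x)*; a position with *f(x) = 0* inside a
  well-covered window is a legitimate, covered score of 0.
* Positions whose window is truncated by a region edge are scored with the
  truncated denominator and flagged `truncated`.
* In the 3′ variant (`end='downstream_of_three_prime'`), *f(x)* counts reads
  whose 3′ end is at *x − 1* in transcript orientation — the next expected
  5′ end under tail-to-head phased processing.

**Binning.** Covered positions with *s* = 0 form bin 0. The remaining
positions are stable-sorted by (*s*, contig, position) and split into
`n_bins` (default 20) contiguous groups whose sizes differ by at most one,
ordered from lowest to highest score. Equal bin sizes take precedence over
keeping tied scores together; the deterministic tie-break makes the
assignment independent of input order, which the tests rely on.

**Oracle.** The engine is verified against a literal per-position window sum
on small fixtures to 1e−12 relative error (cumulative-sum implementation vs
naive loop).

## The phased-biogenesis simulator

The generator emulates Zucchini/PLD6-style processing so downstream
statistics can be validated against injected ground truth.

**Cluster sequences.** A first-order chain with marginal base probabilities
(default A/C/G/T = 0.30/0.20/0.20/0.30, mildly AT-rich as piRNA clusters
are) and a CpG-depletion factor (default 0.25) that scales the C→G
transition before row renormalisation, mimicking the methylation-driven CpG
deficit of non-coding DNA. The stationary trinucleotide distribution
π(a)·P(b|a)·P(c|b) is available in closed form and serves as the oracle for
empirical 3-mer content. An optional explicit 3-mer target table switches
the generator to a second-order chain.

**Cleavage model.** Each position *i* on the sense strand gets a relative
cut propensity

    w(i) = weight(seq[i..i+2]) × penalty[seq[i−1] = G] × (1 + (bonus − 1)·GC(i)),

where `weight` is a 64-entry table keyed by the trinucleotide that becomes
the new 5′ end, the −1G penalty (default 0.25 in the in-vivo-like model)
reproduces the observed depletion of G immediately upstream of preferred
cleavage sites, and GC(i) is the GC fraction of the 10 bases at
[i−20, i−10), rewarding the GC-rich region further upstream of preferred
sites (bonus default 2.0). The exact upstream-window offsets are a simulator
choice, recorded with the simulation truth. Two stock models:
`uniform_u()` (weight 1 on all 16 Unn, 0 elsewhere — the 1U-only null) and
`stop_preference(fold=4)` (additionally `fold`× weight on UAA, UAG, UGA,
UAC — the in-vivo-like preference).

**Chains.** Each of `n_initiations` chains starts at a site drawn
proportionally to w (so even the first fragment's 5′ end respects the weight
support), then repeatedly samples the next cut among candidates 28–50 nt
downstream with probability ∝ w, emitting fragments tail-to-head
(`next.start == prev.end`) for up to 25 fragments. The 28 nt floor keeps
every pre-piRNA longer than mature length, so the trimming toggle cleanly
creates (`untrimmed`) or destroys (`trimmed`, truncation to 26–27 nt from
the 3′ side, 5′ end untouched — the trimmer exonuclease works 3′→5′) the
3′-end/5′-end adjacency that the downstream-profile analysis detects. Cut
choice and trim lengths use independent seeded streams, so the same seed
yields identical pre-piRNA chains in both trimming modes.

**A deliberate, documented bias.** Window-normalised competition means a
candidate's win rate depends on how many rival U positions share its
windows. Trinucleotides with no U at +1/+2 — the three stop codons and UAC —
face on average one fewer adjacent competitor and win ~15% more often per
occurrence even at uniform Unn weights, putting the null stop-codon ratio
near 1.09 rather than exactly 1. This is not a defect: it is the same
neighbouring-U competition visible in real data (multi-U sequences
concentrate in lower score bins), and it spontaneously elevates UAC, the
fourth in-vivo-preferred sequence. Analyses that need an exact null should
use the composition-normalised ratio or compare against a matched simulated
null rather than against 1.0.

## End profiling

* Length windows are inclusive (typical choices: 26–32 nt adult mouse,
  23–32 nt prenatal, 24–31 nt cross-species).
* The duplicate cap treats identical (contig, start, end, strand) tuples as
  interchangeable: surplus removal at random is equivalent to truncating the
  pooled count at the cap, which is what the implementation does (the seed
  parameter is kept for interface stability).
* The 10A exclusion indexes position 10 1-based from the 5′ end
  (the ping-pong cleavage register) and is strand-aware.
* The stop-codon ratio divides the mean frequency of the three stop
  trinucleotides by the mean frequency of the 13 other Unn trinucleotides;
  it is invariant to count rescaling and to any change confined to non-U
  cells. Whether frequencies are normalised over all 64 cells or within Unn
  cancels in the ratio; both normalisations are exposed for reporting.
* The replicate-level enrichment test is a two-sided one-sample t test of
  raw per-replicate ratios against 1; a log-scale variant (log-ratios
  against 0) is available. Zero-variance inputs are flagged rather than
  raised.
* Reads whose interrogated window leaves the sequence or contains N are
  excluded from that statistic only.

## ORF analysis

Stop codons are every TAA/TAG/TGA occurrence on the sense strand, any frame,
overlaps allowed. Membership in an ORF is decided by walking upstream
codon-by-codon in the stop's frame: the first in-frame ATG met before any
in-frame stop defines the ORF, whose length counts codons from that ATG up
to but excluding the stop; lengths of 3–100 aa qualify. Size strata for
matching and grouping are 3–8, 9–19, and 20–100 aa.

The size-matched empirical test draws, per confirmed site and per resample,
one control score from the site's size stratum (with replacement;
`n_resamples` default 10,000), and reports p as the fraction of resampled
control means at or below the observed mean — the one-sided direction that
is coherent with a low observed score yielding a small p. A calibration
subtlety: p values are uniform under the null only marginally over control
pools; conditioning many replicates on one finite pool induces shared shifts,
so the calibration tests regenerate the pool per replicate.

## Conservation

Track values join to binned positions by exact (contig, position) match;
unmatched positions are dropped and counted. Per-bin summaries use t-based
confidence intervals on per-position values (default 95%). Acceleration
calls use a strict inequality against −1.30103 (the −log10(0.05) convention
of phyloP-style scores). Each bin's accelerated fraction is compared against
the pooled *remaining* bins (bin excluded from the pool) with a two-sided
two-proportion Z test. Subsetting restricts bins to U positions or to U
positions opening a stop codon before summarising.

## Cross-species analysis

Expressed clusters require ≥ 100 uniquely mapped reads, ≥ 80% of reads on
the preferred strand, and ≥ 40% 1U (all inclusive). Library-level thresholds
are ≥ 10,000 cluster-mapped reads (refined analysis) or ≥ 100,000 total
reads (global), a 24–31 nt read window, and a per-position cap of 100
(applied before expressed-cluster statistics).

Robustness classes: *robust* requires every stop codon's 5′-end frequency to
strictly exceed every non-stop sequence's; *near-robust* requires all three
stop codons within the top five by frequency, with ties ranked against the
stop codons (max-rank), keeping the tie semantics of the strict robust rule;
robust implies near-robust. Under a uniform random ranking of the 16 Unn
sequences the chance of a robust configuration is (3/16)(2/15)(1/14) ≈
0.18% — the analytic null, cross-checked by permutation enumeration. Group
comparisons of robust-library counts use the two-sided Fisher exact test,
verified against full hypergeometric enumeration.

Composition normalisation divides each Unn sequence's observed 5′-end
frequency by its expected frequency from the expressed clusters' sliding
3-mer content (sense strand, no windows across record boundaries, N windows
skipped); the normalised stop ratio is the mean of stop ratios over the mean
of other-Unn ratios. Group summaries average library frequencies within a
(species, tissue) pair first, then weight species equally within each
class × tissue group.

## What the synthetic benchmarks show — and what they do not

Passing tests establish that the score engine computes its definition
exactly, that injected cleavage preferences are recovered as the top-ranked
per-3-mer mean scores, that binning, normalisation, classification, and all
statistical tests behave as specified on data with known truth, and that the
trimming toggle reproduces the presence/absence of the downstream phasing
signal. The generator does not model ping-pong amplification, RNA secondary
structure, sequencing error, ligation bias, multimapping, or annotation
contamination, so agreement on synthetic data does not by itself validate
conclusions on any particular real library. Published full-scale statistics
that require external data retrieval (for example the 2.14-fold stop-codon
enrichment with 95% CI 2.04–2.23 in adult mouse control libraries, the
genome-wide mean score of 0.0329, the 92,481 precursor stop codons, or the
995,160-position empty bin) are out of scope for the offline test suite;
with the corresponding aligned reads, cluster FASTA/BED, and tracks supplied,
the same functions reproduce those analyses end to end.

## Problem sizes

Simulated benchmarks use 10–20 kb clusters, 600–10,000 processing chains
(≈ 15,000–250,000 reads), 10 replicate simulations for null calibration,
150 replicates for empirical-p calibration, and 200,000 permutation draws
for the analytic-null cross-check — sizes at which every tested effect is
resolved with comfortable margins while the whole suite stays quick on a
single CPU.
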