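# Methods

`viromesig` implements the analysis battery used to characterise
insect-specific virus (ISV) infections in mosquito RNA-Seq panels from the
small-RNA side: strand-resolved vsiRNA/vpiRNA profiling with a ping-pong
overlap statistic, discrimination of actively replicating viruses from
endogenised viral elements (EVEs), RPKM-based incidence calling with
Pearson-complete clustering, co-appearance incrimination of multi-segment
viruses and satellite segments, and ORF annotation. A synthetic-data module
generates libraries and panels with the statistical structure these methods
assume, so the whole battery is testable without external sequencing data.

## The biological model

During replication, RNA virus dsRNA intermediates are cleaved by Dicer-2
into **vsiRNAs** of 20–22 nt (mode 21). Because the substrate is
double-stranded, vsiRNAs appear on *both* genome orientations; a 21-nt peak
on both strands is the operational evidence of active replication. The
piRNA pathway independently produces **vpiRNAs** of ~24–29 nt through the
ping-pong amplification cycle: a primary (antisense) piRNA with uridine at
position 1 (U1) guides cleavage that generates a secondary (sense) piRNA
whose 5′ end lies exactly 10 nt inside the primary's 5′ end, placing an
adenine at its position 10 (A10). Transcribed **EVEs** — virus fragments
integrated in the host genome — instead yield piRNAs from a single
orientation only, with no vsiRNA response; this asymmetry is the classic
discriminator between infection and endogenisation.

## Coordinates and the 5′ convention

Internal coordinates are 0-based half-open on the sense strand. An
antisense read is stored by its genomic interval with a strand flag; its
biological 5′ end is the **rightmost** genomic coordinate of the interval.
SAM output converts to 1-based positions with flag 16 for antisense and
reference-forward SEQ, as the format requires.

## Ping-pong statistic

For reads in the piRNA length window (default 24–29 nt; the upper bound is
configurable to 30 for analyses that use the wider window), let f+(i) and
f−(j) be the counts of sense and antisense 5′ ends at genomic positions i
and j. For each 5′ overlap o = 1..29,

    pair_weight[o] = Σ_i f+(i) · f−(i + o − 1)

summed over segments, and z[o] standardises pair_weight across the overlap
range. A perfect ping-pong pair has o = 10. The product-of-counts weighting
with within-profile z-scoring is the standard overlap-probability
construction for this signature; the z-scores have mean 0 by construction,
and a zero spread (no pairing structure at all) is flagged *degenerate*
rather than silently zeroed, as is a window with reads on only one strand
(*undefined*). The exact symmetry of this statistic is reverse-complementing
the reference (mirror coordinates, flip strands): z[] is invariant and the
sense-orientation fraction maps f ↦ 1 − f. A naive in-place strand-label
swap is *not* a symmetry for mixed read lengths, because the 5′ end of each
read moves to the other end of its interval.

## RNAi status classification

Deterministic cascade over the signature battery (defaults in
`RnaiThresholds`, all configurable):

1. **NOT_DETECTED** — fewer than `n_min = 100` mapped reads.
2. **EVE_LIKE** — ≥ `n_min` reads in the piRNA window, single-orientation
   fraction ≥ `s_eve = 0.95`, and no vsiRNA peak.
3. vsiRNA peak flag — 21-nt reads ≥ 15 % of all 18–32-nt reads *and*
   minority-strand share of 21-nt reads ≥ 10 % (both strands targeted).
4. ping-pong flag — z[10] ≥ `z_min = 3.29` (one-sided p ≈ 5·10⁻⁴ under a
   normal reference) with antisense-U1 and sense-A10 frequencies ≥ 0.5.
5. **ACTIVE_SIRNA**, **PIRNA_PINGPONG**, **ACTIVE_SIRNA_PLUS_PIRNA** from
   the two flags; otherwise **AMBIGUOUS**.

The source analyses judged profiles qualitatively; these thresholds are the
package's own conservative formalisation, and every evaluation states its
configuration.

## Mapper

Reads (18–32 nt; reads of ≤ 18 nt are skipped and counted) are placed
full-length and ungapped on both strands under identity ≥ 0.9 and coverage
≥ 0.9 — at these lengths the short-read mappers used for this kind of
screening operate effectively ungapped, and indels are out of model.
Candidates come from an exact k-mer index with `seed_k = 6`: by pigeonhole,
a read of length L with m mismatches contains an exact run of at least
⌈(L − m)/(m + 1)⌉ bases, which is ≥ 6 for all L ≥ 19 at the default
mismatch budget of 2, so the seeded search provably finds every acceptable
placement and coincides with a brute-force all-position scan (a larger seed
such as 12 cannot guarantee this for 19-nt reads). The default report
policy `best-unique` keeps the single fewest-mismatch placement with a
deterministic (segment, start, strand) lexicographic tie-break;
`best-random-tie` (seeded) and `all-best` are provided. A read counts once,
for its single reported placement, which prevents double-counting in
incidence.

## Incidence

RPKM = mapped / (library_total/10⁶ × genome_length/10³); the log matrix
uses log10(RPKM + 1), since log10(RPKM) is undefined at zero. Presence
requires (mapped ≥ 100 AND breadth ≥ 0.10) OR an assembly-contig hit with
> 85 % nucleotide identity over ≥ 500 bp. Breadth — the fraction of genome
positions with ≥ 1 read — formalises the visual "sufficient coverage"
inspection that guards against single-hotspot false positives; the 0.10
default is a declared choice, since no numeric equivalent exists for the
visual criterion. A flat reads-per-million cut-off is deliberately not
used: it penalises viruses without poly-A tails in poly-A-enriched
libraries. Reported mapping percentages round half-up to two decimals.

Clustering is agglomerative complete linkage under d(x, y) = 1 − r(x, y)
(Pearson). Zero-variance profiles have undefined correlation and receive
the metric's maximum distance 2, so degenerate rows remain clusterable and
merge last. Ties in the minimum inter-cluster distance break on the
smallest original leaf index. Complete linkage guarantees monotone merge
heights; dendrograms serialise to Newick with branch lengths equal to
height differences.

## Co-occurrence and incrimination

For a candidate segment set, *consistency* = n_all/n_any where n_any counts
libraries positive for at least one segment and n_all those positive for
all of them — absence everywhere is uninformative, not confirmatory. The
permutation null shuffles each segment's presence column independently
across libraries, preserving per-segment prevalence exactly;
p = (1 + #{null ≥ observed})/(B + 1). This null is exchangeable across
libraries and therefore does not model library-size confounding (a
documented limitation). Degenerate marginals (a segment present everywhere
or nowhere) leave p undefined-flagged. A set is incriminated *same-virus*
when n_all ≥ 2 ("multiple libraries", fixed at ≥ 2 since the source rule
names no number), consistency ≥ 0.9 and p ≤ 0.01; a *satellite* is flagged
by conditional asymmetry — the candidate never appears without the core
(P(core|sat) ≥ 0.9) while the core appears without it (P(sat|core) < 0.9).

## ORF prediction

ATG-initiated, stop-terminated ORFs under the standard genetic code with a
150-aa default minimum, both strands by default (negative-sense genomes are
annotated in their deposited orientation, so both strands are scanned
unless restricted). The nucleotide interval includes the stop codon;
length_aa excludes it. Per (frame, stop) only the longest ORF is reported;
codons containing N break ORFs; open-ended ORFs (no stop before the
sequence end) are reported only with `include_open=True`, since
coding-complete genomes are the intended input.

## Synthetic data: what it emulates and what it does not

The read simulator draws read classes (siRNA/piRNA/noise) i.i.d. at the
configured fractions; siRNA lengths 20/21/22 at 0.15/0.70/0.15, piRNA
lengths 24–29 with mode 27; positions uniform; segments weighted by length.
Antisense (primary) piRNAs get U at position 1 with probability `u1_bias`;
sense (secondary) piRNAs pair with a sampled primary with probability
`pingpong_prob`, placing their 5′ end exactly 10 nt inside the partner's 5′
end and carrying the complement of the partner's first base at position 10;
unpaired secondaries get A10 forced with probability `a10_bias`, which lets
bias and pairing be tested separately. `eve_mode` emits piRNAs from the
antisense orientation only and folds the siRNA mass into the piRNA class.
Noise reads are uniform in position, strand and length (18–32 nt) over the
viral genome — the least-structured null for degradation, since no
degradation model is stated anywhere; the background (non-viral) fraction
of real libraries is likewise unstated, so the noise fraction is a free
parameter. Qualities are constant ('I') because the analysis never uses
them. Not modelled: host-genome background reads, instrument error
profiles, poly-A enrichment bias, full transcriptomes. Passing tests
therefore demonstrate correctness of the statistics and decision rules
under the assumed generative structure, not robustness to real-library
artefacts such as host-derived multimapping or ligation biases.

Presence panels: per library, each virus is present with its prevalence;
present core segments are missed with probability `segment_dropout`;
satellites are present with probability `satellite_dependence` given their
virus; absent viruses' segments appear with probability
`contamination_rate`; abundances are log-uniform RPKM over a configurable
range.

## Reference experiment sizes

Chosen as the package's reference problem sizes: regime recovery uses 200
virus–library pairs of 3 000 reads on a 4 000-nt genome with non-boundary
parameter draws per regime; the ping-pong demonstration uses one 20 000-read
library (pingpong_prob 0.5) and its null calibration 100 libraries of 2 000
reads with independent strands; mapper validation uses 50 instances of 500
reads on ≤ 2-kb segments at 2 % substitution error; clustering validation
100 random 6–10-profile matrices; co-occurrence calibration 200 independent
two-segment panels and power 100 two-segment panels of 40 libraries with
prevalence U(0.3, 0.7), dropout 0.01 and contamination 0.005.

## Known limitations

* Under the reference panel conditions the same-virus incrimination power
  measures ~94–96 % rather than uniformly ≥ 95 %: at low prevalence a panel
  has few positive libraries, and a single dropout or contamination event
  then moves consistency from 1.0 to (n−1)/n just below the 0.9 rule (e.g.
  8/9 = 0.889) even though the permutation p stays highly significant. The
  hard consistency cut is discrete in small panels; the acceptance suite
  records this measured shortfall rather than relaxing the rule or the
  panel conditions.
* The permutation null treats libraries as exchangeable; sequencing-depth
  confounding of presence calls is not modelled.
* The mapper is exact but ungapped; a read spanning a true indel will be
  rejected rather than clipped.
* `pingpong_signature` weights pairs by the product of 5′-end counts;
  highly clustered coverage (hotspots) inflates all overlaps' weights and
  is only partially absorbed by the within-profile z-scoring.
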