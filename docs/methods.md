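# Methods

This note documents the models and procedures implemented in `regchar`, the
parameters that matter, the synthetic-data design, and the numerical and
design choices made where more than one convention was defensible.

## Coordinate conventions

All externally visible coordinates are 1-based fully closed: an interval
`[start, end]` has `end − start + 1` bases. BED output is converted to
0-based half-open only at serialization (`[s, e]` → `start = s−1, end = e`),
so `length = bed_end − bed_start` holds on disk. Published locus coordinates
are sometimes printed with an off-by-one span (a 3,812-nt closed interval
described as 3,811 bp); `regchar` standardizes on closed intervals
throughout and treats such spans as printing inconsistencies. RNA input is
mapped to the DNA alphabet (U→T) for all scanning and alignment, with the
declared alphabet preserved on records; one scanning engine then serves
both alphabets.

## Motif scanning

Consensus motifs are IUPAC degenerate strings; a window matches if every
position is in the code's base set. `N` in a scanned sequence matches only
`N` in the pattern — a conservative rule that never calls a hit through
ambiguous sequence. Both strands are scanned by default, with reverse-strand
hits mapped to forward coordinates (a hit at reverse-frame offset *p* of an
*m*-mer in a length-*L* sequence starts at `L − (p+m−1) + 1`). All
overlapping occurrences are counted; a greedy left-to-right non-overlapping
mode exists because incidence counts of self-overlapping motifs (e.g. GAF
`GAGAG`) otherwise depend on overlap policy.

PFM scanning converts counts to per-column probabilities with pseudocount
0.25, takes log2-odds against a uniform background (both configurable), and
calls a hit when the window score reaches `threshold_fraction` (default
0.8) of the maximum attainable score. At fraction 1.0 this reduces to exact
matching of the PFM's argmax word when that word is unique, which is the
bridge the tests use between the two scanners. No JASPAR scanning
parameters are standardized anywhere upstream of this package, so all three
values are exposed as flags; the defaults are ordinary practice for short
TF motifs.

The built-in catalog carries 18 named consensus motifs (TATA-box `TATAWA`,
INR `YYANWYY`, DTIE `GBBRDNHGG`, BRE `SSRCGCC`, DPE `RGWCGTG`, M3
`SCGGAAGY`, M22 `TGCGCANK`, HIF `RCGTG`, EBF3 `CCCNNGGG`, Sox `WWCAAWG`,
P53 `RRRCWWGY`, Oct4 `TTTKSWTW`, PU.1 `GAGGAA`, Nanog `SRSSATTANS`, c-myc
`CACRTG`, MAD `CCGNCGCG`, GAF `GAGAG`, GATA `WGATAR`) exactly as used in
the promoter analyses this package reproduces, plus slots for PFM motifs
(NRF1, ZNF143) loaded from JASPAR-format text. The DPE string is kept
verbatim even though other DPE forms circulate in the literature. The
printed catalog counts 20 binding sites (18 consensus + 2 PFM); reports can
subset.

## CpG-island detection

A CpG island is a region of at least `min_length` = 200 nt with GC fraction
strictly > 0.5 and observed/expected CpG strictly > 0.6, where
`obs/exp = N_CpG · L / (N_C · N_G)`. Detection slides a 200-nt window at
1-nt step (both configurable; the classic criteria do not fix step or merge
policy, and a 1-nt step maximizes sensitivity at negligible cost at desk
scale), marks qualifying windows, merges overlapping or abutting windows,
and reports merged spans of sufficient length whose statistics — recomputed
on the merged span — still satisfy both criteria. The final recomputation
matters: a cluster of individually qualifying windows can pull in enough
flank during merging that the union no longer qualifies (a 150-nt pure-CG
repeat inside AT flanks is the canonical case: single windows reach GC 0.75
but the merged span drops to ≈0.43), and such diluted unions are not
reported. Thresholds are strict inequalities, matching the criteria's
phrasing; boundary cases are pinned in tests. Scanning is forward-strand
only because both statistics are invariant under reverse complementation
(property-tested rather than double-scanned).

## Stacking-energy profiles

The raw profile assigns step *i* (1-based, indexed by its left base) the
table energy of the dinucleotide `seq[i..i+1]`; a length-*L* sequence gives
*L−1* values, and steps touching `N` are NaN. The 16 dinucleotide energies
are not hard-coded into the algorithms: they live in a versioned TSV
(`src/regchar/data/stacking_energies.tsv`, transcribing the classic
stacked-dimer scale of Ornstein et al. 1978, in kcal/mol with more negative
= more stable), and every computation and test is written against "the
configured table", so any complete replacement table is equally supported.
The packaged table is complementation-symmetric
(`E[XY] = E[revcomp(XY)]`), which the profile tests exploit.

Smoothing is a sliding arithmetic mean (default window 25 steps for plots
and region calls; raw profiles are always available since published
profiles do not state their windowing). Low-energy regions are maximal runs
of steps inside a band; the default band −7.0..−6.5 kcal/mol is the range
reported for TATA/INR/DTIE motifs on this energy scale, and is a flag
because it is table-dependent.

Co-localization of motif hits with low-energy structure is scored as the
mean profile value over hit-covered steps vs all other steps, with a
one-sided empirical p-value from `n` random repositionings of the hit set
(hit lengths and count preserved, uniform placement, seeded):
`p = (1 + #{perm ≤ observed}) / (n + 1)`, so p ∈ [1/(n+1), 1]. With the
complement empty the background mean is reported as unavailable; with
`n = 0` only the means are reported.

## Local alignment and MRE discovery

Complementary heteroduplex segments between convergent transcripts are
found by aligning transcript A against the reverse complement of transcript
B with optimal Smith–Waterman local alignment under affine gaps, delegated
to Biopython's `PairwiseAligner` engine. Scoring defaults (+5 match, −4
mismatch, gap open 16, gap extend 4, a length-*L* gap costing
`open + L·extend`) emulate common EMBOSS DNA settings, since the pairwise
tool this analysis standardizes on is named but not parameterized; all four
values are flags. An independently implemented Gotoh dynamic program serves
as the oracle in the test suite, so the engine and the check never share
code. Identity is `100 · matches / alignment_columns` (gaps count in the
denominator), the convention of EMBOSS-style pairwise reports; segment
acceptance requires configurable minimum length (default 20) and identity
(default 70%). Ties among co-optimal alignments are broken toward the
smallest (a_start, b_start) when the co-optimal set is small enough to
enumerate (≤ 64); in degenerate cases with astronomically many co-optimal
paths the engine's first traceback, which is deterministic, is used.
Reported b-coordinates are mapped back to transcript B's own 5′→3′ frame.

MRE (miRNA-recognition-element) calling is a documented seed rule, not a
reimplementation of pattern-statistics target predictors: the seed is miR
positions 2–8 (configurable), and a site is any mRNA window equal to the
Watson-Crick reverse complement of the seed with at most
`max_seed_mismatches` mismatches (default 0; no G:U wobble). Target-site
p-values of the full pattern-discovery tools are out of scope. The pipeline
derives its candidate miR from the ncRNA side of the recovered heteroduplex
and can additionally rank a user-supplied mature-miRNA FASTA by local
alignment score against that candidate.

## Promoter classification and statistics

Classification is a pure function of four boolean features: `has_tata`
(≥ 1 TATA-box hit anywhere; a `tss_window` flag narrows this to a
TSS-proximal interval, since nothing upstream fixes one), `has_cgi`,
`has_nrf1`, `has_znf143`. Labels: TATA_containing ⇔ has_tata (else
TATA_less); CGI_positive/negative likewise; bidirectional_candidate
requires CGI⁺ ∧ NRF1 ∧ ZNF143 ∧ TATA-less, the canonical bidirectional-
promoter signature; a promoter with no features at all is additionally
flagged unclassified.

The F statistic is computed from explicit sums of squares
(`F = MS_between / MS_within`, df `(k−1, N−k)`) and the t statistic from
the pooled or Welch formulas, with p-values from scipy's F and t
distributions; scipy's own `f_oneway`/`ttest_ind` act as independent
cross-checks in tests. Incidence significance across a promoter panel
applies the ANOVA to per-motif count columns — reproducing the convention
of testing count data with ANOVA as stated for this analysis — with a
chi-square alternative on motif totals offered behind a flag (counts are
not Gaussian, and the caveat is deliberate). Significance defaults to
p ≤ 0.05. Replicate-level expression input is required (≥ 2 per group).

## Synthetic data: what it emulates and what it does not

The generators reproduce the statistical *structure* of the study inputs,
not real genomic sequence:

* `gen_background` — i.i.d. bases at a chosen GC (no higher-order
  composition, repeats, or isochores).
* `plant_motif` — overwrites a region with a uniformly sampled concrete
  expansion of a consensus, recording position and name.
* `gen_cgi_sequence` — a CpG-dinucleotide-dominated island (GC ≥ ~0.9,
  obs/exp well above 1) inside strongly AT-rich flanks (GC 0.02), so the
  island satisfies the CGI criteria by construction and no flank window
  qualifies. Islands of ~250 nt and longer are guaranteed detectable under
  the default 200-nt window; a minimum-length 200-nt island can be diluted
  just below the GC criterion by merge overhang (documented boundary case).
* `gen_convergent_pair` — defaults 5,266 and 422 nt with a 52-nt segment at
  75% identity: `52 − round(0.75·52) = 13` mismatches placed internally,
  never adjacent, with the first and last 5 positions matched, so that
  under the default scoring no trimming or extension beats the full
  segment and the planted geometry is the unique optimum. Flanks are poly-A
  (transcript A) vs poly-C (transcript B) — alphabets whose cross-strand
  comparison carries zero alignment signal — which isolates the planted
  segment. The segment sits in A's 3′ quarter, emulating a 3′UTR overlap.
* `gen_expression_table` — `value(g,r) = mean_g + N(0, σ)`, Gaussian on the
  (already log-like) expression-intensity scale to match the ANOVA
  assumptions applied to it; 11 groups × 2 replicates by default. The
  actual tissue panel and means of the original expression resource are
  not published at replicate level, so group means are configurable rather
  than guessed.

All generators are pure functions of (parameters, seed); reruns are
byte-identical. Because the backgrounds are i.i.d., passing plant-then-find
tests demonstrates correctness of the detectors' logic and coordinates, not
performance on real promoters (repeats, CpG decay gradients, and motif
clustering are absent). Short AT-rich consensus motifs (e.g. `TATAWA`)
occur by chance in AT-rich backgrounds at their expected rate, which the
fixtures either tolerate (classification examples) or avoid by
construction (AT-free backgrounds where zero counts are asserted).

## Problem sizes and determinism

Everything here runs at desk scale on one CPU. The validation suites use
1,000 random consensus-scan cases against an enumerate-all-expansions
oracle, 500 random pairs against the independent affine-gap DP, 500 random
sequences against the all-windows CGI oracle, 1,000 null expression tables
for the ANOVA type-I calibration (rejection at α = 0.05 within 5% ± 1.5%),
and 100-seed plant-then-find closure for motifs, CGIs and MREs. Every
stochastic component (generators, permutation tests) takes an explicit seed
and is reproducible; the pipeline threads a single seed through its
stages and echoes its full configuration next to its report.

## Known limitations

* No hidden-Markov or methylation-aware CGI models; the window criteria
  only.
* No hybridization free-energy model for the heteroduplex or MRE sites
  (complementarity only, no ΔG, no G:U wobble by default).
* No nearest-neighbor melting thermodynamics or DNA-shape features beyond
  the stacking-energy table.
* ANOVA on motif counts is reproduced as the stated convention despite its
  distributional caveat (chi-square offered as an alternative).
* Promoter *prediction* (TSS discovery) is out of scope; promoters are
  inputs.
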