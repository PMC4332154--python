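# Methods

## The measurement being modeled

A mini-transposon inserts once per clone at quasi-random genomic
positions. Sequencing transposon–genome junctions across a pooled
library maps every insertion; clones disrupted in an essential
sequence stop dividing, so after serial passaging their insertions
fade from the library. Essential sequence therefore shows up as
*insertion-free gaps*, dispensable sequence as dense insertion
coverage. Two practical complications drive the design: low-read
"noise" insertions inside essential genes (PCR and mapping artifacts,
dying clones), handled by a calibrated read-count threshold; and the
fact that gaps of moderate length arise by chance, handled by an
explicit null model.

## Insertion calling

Reads are authenticated by their inverted-repeat (IR) prefix (allowing
`max_mismatch` substitutions, default 1), trimmed, and mapped by their
first `k` bases (default 20) against an exact k-mer index of both
strands of the circular reference. Only uniquely matching seeds yield
calls; multi-locus seeds are counted ambiguous, and every input read
lands in exactly one provenance bucket (no-IR / unmapped / ambiguous /
mapped). The site coordinate is the first genomic base downstream of
the IR on the read's orientation; opposite-orientation sites at one
position stay distinct in the table (the transposon carries an
internal promoter, so orientation can matter biologically) and are
merged only for scoring. `k < 12` is rejected: shorter seeds are not
reliably unique on genomes near 1 Mb. Gapped alignment, quality
trimming and PCR-duplicate modeling are out of scope; the mapper is
deliberately minimal because read mapping is not the analytical
contribution.

Insertion composition bias is quantified per quadruplet: the 4-mer
centred on the junction (bases p−2..p+1 of site p), observed versus
expected under uniform insertion, with a chi-square goodness-of-fit
and a summary ratio for the G/C-rich class (≥ 3 G/C of 4).

## Timepoint selection and threshold calibration

The analysis day is the earliest on which the gold-essential genes
have lost their insertions — mean insertions per gold-E gene at or
below `max(0.1 × day-0 value, 0.5)` — while gold-non-essential genes
retain at least 80% of their day-0 mean (guarding against library
bottlenecks, which raise an error instead).

Read thresholds come from the bimodal reads-per-insertion
distribution: for every integer t, `error(t)` counts gold-essential
insertions kept (reads ≥ t) plus gold-non-essential insertions lost
(reads < t). The relaxed and stringent thresholds are the smallest and
largest minimizers of this curve; a completely flat curve (no
separation) sets both to 1 with a warning. The stringent threshold is
the default for scoring; both are always reported.

## The gap null model and P_E / P_NE

With `N` threshold-passing (orientation-merged) insertions on a
circular genome of length `G`, a span of length `L` escapes all of
them with probability `P_N(L) = (1 − L/G)^N`, evaluated in log space.
Maximal insertion-free intervals (computed circularly, wrapping the
origin) with `P_N(L) ≤ α` are significant; α = 0.01 corresponds to 99%
confidence. Per region:

* `P_E` — fraction of the region covered by significant insertion-free
  intervals (the intervals are genome-wide objects; coverage is
  clipped to the region);
* `P_NE` — fraction covered by the ±w neighborhoods of insertions
  *inside* the region, with `w = ⌈G/2N⌉`, half the mean
  inter-insertion spacing, so that neighborhoods tile the genome at
  the observed density. Restricting to internal insertions keeps a
  neighboring gene's insertions from bleeding across the boundary;
  with genome-wide neighborhoods nearly every essential gene would
  pick up `P_NE ≥ 0.01` from sites just outside its edges.

Both are rounded half-up to two decimals using integer arithmetic
(0.005 → 0.01; 0.004999… → 0.00), and the E/NE/F rule is applied to
the rounded values: E iff `P_E > 0` and `P_NE = 0`; NE iff `P_E = 0`
and `P_NE > 0`; F otherwise. The F (fitness) category deliberately
absorbs both mixed evidence (`P_E > 0, P_NE > 0` — typically
multi-domain proteins, or genes adjacent to an essential gap whose
margin reaches a few bases in) and no evidence (`0, 0` — regions too
short for a significant gap). Under this null, chance alone produces
significant gaps at a known rate, so a few percent of genuinely
dispensable genes land in F; that is a property of the statistic, not
a defect, and it is why the package reports the strict NE-recovery
rate separately from the specificity of the essential call.

Scores are invariant under genome rotation (regions crossing the
origin are handled by rotating coordinates) and under strand
reflection; both are property-tested, and region scoring is tested for
exact equality against an independent brute-force per-base labeling
oracle.

The essentiality landscape is the union of significant insertion-free
intervals (BED export), summarized as essential bp and fraction plus
per-class E/NE/F percentages for ORFs, smORFs, ncRNAs, 5′-UTRs,
conventional RNAs, and intergenic regions > 100 bp. ncRNAs overlapping
an essential-called ORF on either strand are reported "unassignable":
their insertion-free state may only reflect the host gene.

## Domain-level essentiality

Domain amino-acid coordinates (1-based, stop codon belongs to no
domain) are projected onto the genome — plus strand:
`nt = orf_start + 3(aa−1) … orf_start + 3·aa_end − 1`; minus strand
mirrored from `orf_end` — and each domain is scored like any region.
Overlapping input domains are trimmed at the midpoint of the overlap;
nested domains are dropped. Inter-domain linkers and termini are
scored but reported unassigned and never drive the `differential`
flag, which is set when at least two assigned domains receive
different categories.

## ncRNA co-expression and smORFs

Association over the expression time course uses CLR. With ~10
timepoints a binned MI estimator is unstable, so mutual information
comes from the Gaussian identity `MI = −½ ln(1 − r²)` (monotone in
|r|, zero iff r = 0). Each pair's MI is z-scored against the
background MI distribution of both partners (negative z clamped to
zero); the pair score is the **mean** of the two clamped z-scores.
The mean combination was chosen over the root-sum-square variant
because, at the fixed significance threshold of 2.5, it keeps the
null false-positive rate below 5% for 50-feature × 10-timepoint
studies (measured ≈ 3.6%) while detecting planted |r| ≈ 0.9 pairs in
≈ 98% of studies; the root-sum-square variant exceeds 7% false
positives at the same threshold. Zero-variance features get MI 0 with
a warning. Significant pairs are signed by Pearson's r
(anti-correlated / correlated; r = 0 is undetermined and excluded).

Enrichment of essential partners among anti-correlated pairs is
tested per ncRNA: the percentage of its anti-correlated partners
called E versus the percentage of its correlated partners called E,
compared across ncRNAs by Welch's two-sample t-test (two-sided,
Welch–Satterthwaite degrees of freedom; zero pooled variance with
equal means returns p = 1 by convention). The implementation follows
the textbook formulas and is cross-checked against
`scipy.stats.ttest_ind(equal_var=False)` in the tests.

smORF candidates are maximal start-to-stop spans in the three forward
frames of each ncRNA's annotated strand, under genetic code 4: TGA
codes tryptophan, only TAA/TAG terminate. Start codons default to
{ATG, GTG, TTG}; peptide length is bounded to < 100 residues.
Conservation filtering of candidates is out of scope; the scanner
emits all candidates for external filtering.

## The synthetic generator

`simulate_genome` packs non-overlapping ORFs, smORFs and conventional
RNAs around a circular chromosome with random intergenic gaps, placing
~95% of ncRNAs antisense within host ORFs, 5′-UTRs upstream of a
quarter of ORFs, and one large intergenic region marked essential (an
oriC-like structural element). All coding sequence is valid under
genetic code 4 (ATG start, no internal TAA/TAG, TAA/TAG stop). Truth
categories are assigned per `frac_essential`; fitness genes are
generated as mixed-domain ORFs with one essential and one
non-essential domain — purely stochastic intermediate fitness is not
modeled.

`simulate_insertions` is Bernoulli per position at `insertion_rate_ne`
(default 0.05/bp) in dispensable sequence and `noise_rate_e` (default
5 × 10⁻⁴/bp) in essential sequence, optionally thinned by
`quadruplet_bias` at G/C-rich quadruplets. Read counts are negative
binomial in the NB1 sense — variance `(1 + d)·mean` with dispersion
d = 0.5 — around means of 100 (dispensable) and 3 (noise); the NB1
parameterization keeps the two read-count modes separable, which the
calibration procedure requires, while still being overdispersed
relative to Poisson. Essential-class read means decay exponentially
across passage days (half-life 1.5 days by default, relative to the
earliest day); sites whose redrawn read count reaches zero drop out of
that day's table, reproducing the decay of gold-essential insertion
counts that drives timepoint selection. Defaults (200-kb genome, 120
ORFs of 600–1800 nt, 40% essential, 8% fitness) put the essential
fraction of the genome near one third.

`simulate_expression` gives each planted ncRNA a latent profile copied
exactly (sign flipped for anti-correlation) to its host ORF and any
extra planted partners, then adds iid Gaussian noise
(`expression_noise_sd`, default 0.3 — attenuating planted |r| to ≈
0.9); with zero noise a planted anti-correlated pair has sample
r = −1 exactly. Partner ORFs can be drawn preferentially from
essential truth (`p_essential_anti` / `p_essential_corr`) to emulate
repressive regulation of essential genes; partner sets are disjoint
across ncRNAs, so planting is cluster-structured and unplanted pairs
remain independent. What the generator does **not** emulate: base-call
errors beyond an optional uniform substitution view, PCR duplicates,
growth competition beyond exponential decay, transcription-unit
structure in expression, or any mass-spectrometry observables — so
passing tests demonstrate correctness of the statistical machinery
under the stated generative assumptions, not robustness to every
artifact of real libraries.

## Benchmark problem sizes

The recovery benchmark runs the full pipeline on the default 200-kb
conditions for 10 seeds (~6,600 threshold-passing sites each);
sensitivity/specificity are defined on the essential call (truth-E
called E; truth-NE not called E), with the strict truth-NE → NE rate
reported alongside (~0.93–0.98; the shortfall is the chance-gap F
behavior described above). Threshold calibration is checked on 50
seeds of a 100-kb experiment with 20+20 gold genes. CLR null and power
use 100 studies of 50 features × 10 timepoints. The enrichment power
study uses 140 ncRNAs with ~13 planted partners each over 2,600 short
ORFs — a pre-study power analysis (per-sign partner count ≈ 5.7,
per-ncRNA percentage SD ≈ 22, effect 50% vs 37%) gives Welch t ≈ 5,
so p < 0.01 is expected in ≈ 99% of replicates. These sizes are the
package's benchmark conditions; they were chosen for tight statistics
at desk-scale runtimes.

## Numerical and degenerate-input choices

* `P_N(L)` is computed as `exp(N·log1p(−L/G))`; `L = 0` or `N = 0`
  give 1, `L = G` gives 0.
* Two-decimal rounding is exact integer arithmetic, round-half-up.
* Zero threshold-passing insertions (N = 0) is an error, not a call:
  a library with no surviving insertions cannot distinguish essential
  from dead.
* Ties in the calibration argmin resolve to (smallest, largest) for
  (relaxed, stringent); a flat curve is flagged degenerate.
* Orientation-merged read sums are thresholded (two sub-threshold
  opposite-orientation sites at one position can jointly pass).
* Wrapping regions are scored by rotating coordinates; scores are
  rotation- and reflection-invariant by construction.
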