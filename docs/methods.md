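# Methods

This note documents the models and procedures implemented in
`chlamirna`, the reasoning behind the tunable parameters, what the
synthetic-data generator does and does not emulate, and the numerical
choices that make the pipeline deterministic.

## Read handling and coordinates

All genomic coordinates are 0-based half-open in memory; BED output is
native and GFF3 is converted to 1-based closed only at write time.
Sequences are DNA on disk and in genome space, RNA inside the duplex
and folding logic, with conversion at module boundaries.

The built-in mapper places collapsed reads at every exact-match locus
on either strand; reads mapping nowhere or to more than `max_loci`
(default 5, boundary inclusive) locations are discarded, emulating the
usual multi-mapper removal in sRNA profiling. Reads overlapping an
exclusion annotation (organellar genomes, structural ncRNAs) by at
least 1 bp at any locus are removed entirely. A retained multi-locus
read contributes its full abundance to every cluster it touches, but is
counted once in the library total N and once in a cluster's local
total when several of its loci fall inside the same cluster (a mature
read that also matches the star arm of a perfect-duplex precursor is
one molecule population, not two).

## Clustering and hairpin calling

Reads are grouped strand-agnostically: walking coordinate-sorted loci,
a new cluster opens when the end-to-start gap exceeds `max_gap`
(default 200 nt). The gap is measured end-to-start between sorted
loci, the most literal reading of an "adjacent reads no more than
200 nt apart" rule. Each cluster's genomic sequence, extended by
`flank` (default 20 nt) and truncated at chromosome edges, is taken on
both strands; any non-ACGT base marks the cluster as ambiguous and
disqualifies it before folding, since secondary structure over
unsequenced gaps is undefined.

### Two folding primitives

`fold_sequence` is a maximum-base-pairing dynamic program (Watson-Crick
plus G:U, minimum hairpin loop 3) with a stack-preferring, strictly
deterministic traceback. Its pair count is provably optimal and is
cross-checked in the tests against an independent brute-force
recursion. It answers "how much pairing is possible", which is the
right primitive for short-sequence structure questions and for the
optimality oracle — but the *global* maximum-pairing structure of a
~90-nt cluster window is generically dense and multibranched (even a
perfect precursor window acquires a couple dozen scattered pairs), so
it cannot answer "is this window a hairpin".

`fold_hairpin` answers that question: it computes the best single-stem
structure — a chain of mutually nested pairs maximising
`pairs − 0.5 × (unpaired bases between consecutive pairs)`, with at
most 6 skipped bases per arm between consecutive pairs. This is the
optimal gap-penalised inverted-repeat alignment of the window against
itself, which is what a thermodynamic folder effectively returns for a
genuine precursor (stacking dominates; isolated pairs are penalised).
A real precursor scores its near-contiguous stem; random or
low-complexity windows cannot assemble a long chain. An
`RNAfold`-compatible executable can be substituted as an external
backend, in which case its MFE structure feeds the same downstream
geometry checks.

`detect_hairpin` accepts a fold only if its pairs form one nested chain
(hence exactly one terminal loop and no multibranch junction) with at
least `min_stem_pairs` pairs. The default 15 follows from the calling
criteria themselves: a 20–24-nt mature with at most four arm mismatches
implies roughly ≥ 16 paired positions; 15 leaves one pair of slack for
end breathing. `star_mismatch_count` counts mature positions that are
unpaired or paired non-complementarily (G:U counts as paired, matching
what folding engines pair); mature ends dangling past the stem — past
its outer end or a base or two into the terminal loop — are tolerated
and simply count as unpaired, because a register shift of one at a stem
end moves the stem boundary without changing the biology. An interval
spanning the loop from arm to arm belongs to no arm and is an error.

### Acceptance criteria

A cluster becomes an accepted miRNA when, in order: it has no ambiguous
bases; the main (highest-abundance, ties broken by lexicographically
smallest sequence) read's strand folds into a hairpin containing the
main read within one arm; at most `max_5p_sites` (default 2) 5′
processing sites each hold ≥ `min_site_fraction` (default 10 %) of the
cluster abundance; the main read holds ≥ `predominance_min` (default
90 %) of the locally mapped abundance; and the main read has ≤
`max_star_mismatches` (default 4) unmatched positions against the
complementary arm. The first two checks short-circuit (later criteria
are undefined without a hairpin); the rest all run, so a rejection
records every failing reason. "Predominant site" is quantified as ≥
10 % of cluster abundance — a threshold that cleanly separates
processing sites from degradation noise in the synthetic model; it is
configurable because no canonical value exists. Note that with the
default thresholds the three-predominant-site failure mode necessarily
co-occurs with low predominance (three sites ≥ 10 % cap the main read
at 80 %), which is why rejection reasons are ordered and the first
failing criterion is reported as primary.

MicroRNAs are matched across libraries by exact mature genomic locus
(chromosome, interval, strand); a miRNA counts as identified in a
condition when accepted in at least one of its libraries, and
"condition-prevalent" when identified in exactly one condition.

## Expression

CPM = 10⁶·C/N with C the abundance of the exact mature sequence in a
library and N the library's total mapped reads; the mean CPM over all
configured libraries feeds an inclusive 500-CPM low/high split and a
500-CPM-binned histogram (half-open bins, boundary values to the
right). RPKM = 10⁹·C/(N·L). Differential flags use
log2(RPKM ratio) with a pseudo-RPKM of 0.1 added to both sides when
either is zero, Benjamini-Hochberg q-values, and the q ≤ 0.05 plus
≥ 2-fold-change rule. The built-in per-gene test is an exact
two-sided binomial comparison of a count pair against the library-size
ratio — deliberately simple; externally computed p/q-values (e.g. from
a negative-binomial model) can be supplied instead.

## Target prediction

miRNA positions are numbered 1-based from the 5′ end: seed 2–8
(perfect Watson-Crick required), catalytic center 9–12, remainder
{1, 13..L}. Budgets in the remainder — at most three G:U wobbles AND
at most three mismatches AND at most a single 1-nt bulge — are read as
three separate constraints, since a pooled "mismatches or a gap"
budget cannot express a bulge-length limit. Position 1 is budgeted,
not required perfect. Catalytic perfection yields the cleavage class;
one to three catalytic wobbles/mismatches the translational class; the
two are disjoint by construction. The single bulge may sit on either
strand, only outside the seed and catalytic regions, placed to
minimise the mismatch count and then the position index.

The scanner slides windows of length L−1, L, L+1, prescreened by the
seed heptamer (a classified site must contain the exact reverse
complement of miRNA positions 2–8, at one of a handful of offsets
determined by the gap placement); the test-suite's independent oracle
enumerates every window without the prescreen. Overlapping windows
describing the same duplex are deduplicated by (miRNA, transcript,
window 3′-end), keeping the fewest-gap, then fewest-mismatch
alignment — gap first, because a 1-nt bulge can masquerade as one
fewer mismatch and would otherwise displace the exact ungapped window.
A perfect site retains up to two "satellite" representations at
neighbouring 3′ ends (its L±1 sub/super-windows also satisfy the
grammar); target counts are per distinct transcript, so satellites
never inflate them. Sites on a miRNA's own precursor transcript are
flagged and excluded from counts by default; miRNAs with no remaining
target are flagged for exclusion from expression comparisons, since
they carry no constraint on their expression level.

## Group comparison

Per-miRNA target counts (one class at a time) are split at the 500-CPM
mean-expression cutoff after removing no-target/self-only miRNAs, and
compared with a two-sided Wilcoxon rank-sum test plus Cohen's *d*
(classic pooled-SD form, n−1 variances, sign = low-group mean minus
high-group mean). The rank-sum test uses the exact null distribution
when n·m ≤ 400 and the pooled sample is tie-free, otherwise the normal
approximation with midranks, tie correction and continuity correction
(the semantics of R's `wilcox.test`); identical constant data returns
p = 1 by convention. The exact path is validated against full
permutation enumeration for all n = m ≤ 6, and the approximate path's
type-I error under a discrete null (Poisson counts, n = 25 per group,
2000 replicates) is required to land in [0.03, 0.07] at α = 0.05.

## The synthetic-data generator

The generator builds what the calling criteria are designed to detect,
and records everything it plants.

* **Precursors** place a user-given mature sequence on one arm and its
  reverse complement, mutated at exactly `star_mismatches` positions,
  on the other, joined by a poly-C terminal loop (≥ 3 nt). Mutated
  positions sit ≥ 2 pairs from both stem ends and ≥ 2 apart, and the
  substitute base pairs neither its mature partner nor the partner's
  neighbours — otherwise the stem fold could truncate at, absorb, or
  overshoot a planted mismatch through register shifts. Because a rare
  mature sequence still admits such a shift, construction verifies its
  own postcondition (fold → hairpin → counted mismatches = planted) and
  redraws the assignment; the benchmark additionally verifies each
  precursor embedded in its future genomic flanks over the window sizes
  the caller will see.
* **Genomes** separate precursors by > 200-nt spacers drawn from a
  single A/C stream in which every 18-mer is unique. A/C sequence
  cannot base-pair with itself (no A:C, A:A or C:C pairs exist), so
  non-precursor clusters never fold; k-mer uniqueness guarantees
  spacer-derived reads map to exactly one locus, which matters because
  a multi-mapping background read can bridge otherwise well-separated
  clusters. Junction-crossing k-mers that happen to be pure A/C are
  excluded from background sampling for the same reason.
* **Reads**: a fraction `predominance` (default 0.95) of each
  precursor's reads is the exact mature sequence, a small
  `star_fraction` (default 0.02) comes from the star arm — real AGO
  libraries retain miRNA* reads, and they let the cluster span both
  arms — and the rest are 5′-jittered copies (±`offset_jitter`,
  default 2 nt, constant length, since the criteria concern 5′
  processing sites). Background reads are 18–26-nt spacer substrings
  kept > 200 nt from all loci. Integer allocation uses largest-remainder
  rounding, so abundance-weighted totals equal the requested library
  sizes exactly. Per-precursor site profiles can be overridden, which
  is how defective loci (three predominant sites: 0.39/0.295/0.295;
  low predominance: 0.85 with sub-threshold jitter) are planted.
* **The standard benchmark** plants 20 valid precursors (mature
  lengths 20–22, 1–4 star mismatches, both arms, variable loops) and
  two precursors per defect kind — five star mismatches, three
  predominant 5′ sites, 0.85 predominance, an N in the loop, and an
  unfoldable A/C locus — each carrying exactly one defect. Expression
  weights are log-normal (σ = 1.5, clipped); with several libraries,
  60 % of valid precursors are expressed everywhere and the rest are
  condition-exclusive. One mature sequence is additionally copied into
  a reserved spacer to exercise multi-mapping. Reported runs use
  300 000 reads per library with 90 % background, which yields
  per-precursor depths of roughly 10²–10⁴ reads and mean CPMs
  straddling the 500-CPM cutoff.
* **Transcriptomes** carry one engineered window per transcript:
  cleavage windows are perfect over positions 1–12 with up to two
  remainder wobbles/mismatches (at positions ≥ 14, which stay in the
  remainder under a ±1 register shift); translational windows add one
  catalytic imperfection at position 10 or 11 (catalytic under ±1
  shifts); decoys break seed positions 4 and 6 (inside the seed under
  ±1 shifts). Backgrounds are redrawn until they contain no accidental
  site for any miRNA in the set, so the truth table is exhaustive.
* **Two-group target counts** for the statistics stage are
  1 + negative-binomial draws. The defaults — 47 low-expression miRNAs
  with mean 5.11 cleavage targets (dispersion 0.35, i.e. a heavy right
  tail reaching tens of targets) against 18 high-expression miRNAs with
  mean 1.78 (dispersion 0.7) — reproduce the observed contrast between
  condition-prevalent lowly expressed and universally detected highly
  expressed miRNAs, with an expected pooled-SD effect size near 0.54.

What the generator does **not** emulate: sequencing errors, adapter
contamination, ligation bias, isomiR 3′ heterogeneity beyond the
co-shifted jitter, genuine degradome structure (background is uniform
within spacers), multi-chromosome genomes, or intron-containing
precursor transcripts. Passing the planted-truth tests therefore
demonstrates the correctness of the decision rules and their
composition, not robustness to those real-data artifacts.

## Problem sizes and determinism

Reported runs use: 30 planted precursors over three single-library
conditions at 300 000 reads each; target planting with class-dependent
per-miRNA counts capped at 12 transcripts of 300 nt; 1000 (test) or
300 (report) random miRNA/transcript pairs with transcripts up to
500 nt for the scanner/enumeration equivalence; 200 random sequences up
to 25 nt for fold optimality; and 2000 null replicates for Wilcoxon
calibration. Every random choice flows from a single integer seed
through `numpy.random.default_rng`; identical seeds give byte-identical
FASTA/FASTQ/TSV outputs. All tie-breaks (traceback order, main-read
selection, site deduplication, apportionment) are deterministic and
documented at the point of implementation.

## Known limitations

* The built-in folder family does no thermodynamics: a stem of
  energetically implausible pairs scores like a plausible one. The
  external RNAfold backend is the remedy where that matters.
* `star_mismatch_count` is exact for the planted constructs by
  verification; for arbitrary hand-built precursors with ≥ 5 mismatches
  a register shift can occasionally change the count by one.
* The simple binomial count test ignores biological overdispersion;
  its q-values are honest only for technical-replicate-like data.
  Supply external p-values for anything else.
* With default thresholds, `TOO_MANY_5P_SITES` cannot occur without
  `LOW_PREDOMINANCE` (see above); consumers should use the ordered
  primary reason, not the reason set, to attribute a failure mode.
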