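# Methods

This note records the models behind `hpmut`, the defaults and why they were
chosen, what the simulator does and does not emulate, and the numerical
decisions that matter for reproducing its output.

## Homopolymer catalog

A locus is a maximal run of one base on the reference strand, stored
0-based half-open (BED convention) to avoid the off-by-one ambiguity that
plagues 1-based inclusive interval handling. Sequence is uppercased before
scanning; any character outside {A,C,G,T} terminates a run, so no locus
ever spans unknown or ambiguous sequence. The catalog default of
`min_len = 5` is deliberately below the 7–16 nt analysis window used for
rate estimation: the catalog is the reusable superset, and windows are
applied downstream, so changing the analysis window never requires
re-scanning the genome. Only mononucleotide runs are catalogued;
dinucleotide and compound microsatellites are out of scope.

## Read-level run-length extraction

A read contributes an observation at a locus only if it aligns across the
full anchor window — `min_anchor = 3` reference-matching, non-clipped
positions on each side of the run. This prevents partially aligned or
clipped reads from reporting truncated run lengths, the dominant artifact
mode when extraction is naive. The observed length is the number of
consecutive run-base characters between the two anchors in the read, so
inserted extra copies count and deleted positions do not; a non-run base
inserted inside the run stops counting at the 5'-anchored segment
(conservative: an interrupted run is not evidence for a longer allele).
Unmapped, secondary, supplementary, duplicate-flagged and MAPQ < 20 reads
are excluded, mirroring a duplicate-marked, uniqueness-filtered alignment
pipeline without re-implementing one. Base qualities are ignored; at ~50×
depth the binomial cohort test dominates any per-base quality signal, but
per-base quality gating would be a natural extension.

## The cohort caller

### Null model

The leave-one-out profile averages the *frequency* distributions of the
other samples, unweighted: a depth-weighted average would let one deep
sample impose its stutter realization on the cohort null (the weighted
variant is available behind a flag). Samples with zero depth are excluded
and the number actually used is recorded. The test statistic is the
sample's read count at the profile mode L₀, with lower-tail exact binomial
probability at p₀ = profile mass at L₀, clamped to [10⁻⁶, 1−10⁻⁶] so the
null stays proper when the profile is a point mass. No per-bin
pseudocounts are added; the clamp alone keeps the test exact and
conservative. The CDF is evaluated through the regularized incomplete beta
function, which equals direct pmf summation to ~10⁻¹⁵; the test suite
checks agreement to 10⁻¹² against brute-force summation for all n ≤ 200.

A variant call additionally requires that the sample's own modal length
differ from L₀. Depletion at the cohort mode alone (without a coherent
alternate allele) is left as `reference`/`no_call` because it is the
signature of a dirty locus, not a genotype.

### Gates and defaults

| parameter | default | rationale |
|---|---|---|
| `p_threshold` | 1e-6 | ~6×10⁵ locus-sample tests genome-wide ⇒ <1 expected FP |
| `min_depth` | 8 | below this the lower-tail test has essentially no power |
| `max_depth` | 250 | ~5× the 50× design depth; flags collapsed repeats |
| `min_lq` | 0.5 | locus quality: cohort fraction of reads at own-sample modes |
| `min_modal_fraction` | 0.5 | a genotype call needs a majority allele in-sample |
| `min_consensus_support` | 0.5 (strict `>`) | cohort consensus must be a strict majority of per-sample modes |
| `min_data_fraction` | 44/47 | data-availability rule reused from point-mutation filtering |

Gate order: locus-level first (data fraction, LQ, consensus), then
per-sample (depth window, modal fraction), then the binomial test. Every
sample receives a record with a reason code, so callability is computable
from the call table itself. Note one consequence of the 44/47 data
fraction: in an 8-line cohort it requires all 8 lines to have usable
depth; a single thin sample no-calls the whole locus. In the 16-line and
47-line settings the rule behaves as a ≤3-missing allowance.

Modal lengths break ties toward the length closest to the reference, then
toward the shorter length — deterministic and biased toward the least
surprising allele.

## Unique-mutation filtering

A mutation shared by many lines is ancestral polymorphism or systematic
artifact, not an MA event; alleles in more than 3 lines are dropped, with
identity (chrom, pos, alt) for points and (locus, Δ) for indels. Loci with
data in fewer than ⌈0.936·n⌉ lines are dropped entirely. Clustered
same-line point mutations within 20 bp are removed as putative alignment
artifacts; the chain rule is transitive (a 100/118/135 chain is one
cluster — the graph-component reading of "within 20 bp of one another"),
with a strict-pairwise alternative behind a flag. The default filter order
is qual → cluster → unique; the qual and uniqueness filters commute
whenever QUAL is a property of the site, so the order only matters in
pathological inputs, and it is configurable.

## Rate estimation

Frequency = events / exposure; rate = frequency / generations (default
1000 per line, overridable per line in the exposure ledger). Exposure is
per-line callable loci (indel windows) or per-line callable bp by
base-pair class (points); per-class denominators are required to make the
A:T and G:C blocks of a point-rate table internally consistent. All
intervals are Clopper–Pearson from Beta quantiles; with genome-scale
exposures (n ~ 10¹⁰) and small k these coincide with Poisson (χ²)
intervals to three significant figures, which the tests verify. Table
rendering is two significant figures with round-half-even.

Pairwise rate comparisons pool counts into 2×2 event/exposure tables for
Fisher's exact test; the two-sided definition is the minimum-likelihood
convention (sum of all same-margin tables no more probable than the
observed one). The Mann–Whitney U test is exact — full enumeration, ties
handled by the ½-score convention — for combined sample size ≤ 20 (a
typical copy-number comparison of a handful of strains), and falls back to
the tie-corrected normal approximation above that. Copy number itself is
the ratio of median per-base depth in the target region to that of the
background, invariant to overall coverage scale.

## Fluctuation analysis

The Ma–Sandri–Sarkar recursion gives the Luria–Delbrück pmf; the
log-likelihood of the culture counts is maximized over m by bounded 1-D
search on [10⁻⁸, 2·max(1, mean count)], with geometric bracket expansion
if the optimum presses the upper bound, `xatol = 1e-12`. All-zero counts
return m̂ = 0 exactly. The distribution is compound Poisson (Poisson(m)
events; clone sizes K with P(K=k) = 1/(k(k+1)), the size distribution of a
clone founded at a uniformly random division during exponential growth),
so for maximum counts above 4096 — jackpot cultures, where the O(n²)
recursion becomes the bottleneck — the same pmf is evaluated through its
generating function exp(m(Q(x)−1)) on a 32×-padded Fourier grid; the two
routes agree to better than 10⁻⁸ absolute where both are feasible, and the
recursion remains the reference implementation. The standard error is the
inverse square root of a central-difference observed information at m̂;
it is reported, never used for gating. Plating fraction < 1 is not
modeled (whole-culture plating semantics); counts above 10⁵ are rejected
as implausible rather than fed to the recursion.

## The simulator

The generator emulates a haploid MA study design: 8 lines, 1000
generations, ~50× depth, 100 bp reads, a catalog of 1000 A-runs spanning
lengths 7–16 (100 per length), per-locus indel rate 5×10⁻⁷ per generation
and 75% deletion bias, and background point rates of 3×10⁻¹⁰ per bp per
generation. Indels arrive per line per locus with probability
1−exp(−μ·g); mutations accumulate linearly in total generations — the
20–22-generation bottleneck structure is not modeled at the population
level, matching how MA studies convert counts to rates.

Stutter: each read spanning a run of template length L slips with
probability 0.01·(L−4), capped at 0.30, split 2:1 in favor of −1. This is
deletion-biased and length-increasing, qualitatively matching real
mononucleotide stutter; real instrument error profiles are not published
for the target platform, so the three parameters are explicit knobs and
the caller acceptance results should be read as conditional on them.

Reads are emitted pre-aligned (MAPQ 60, no mapping error), with the
allele's indel encoded in the CIGAR at the 3' end of the run; alignment is
out of scope and this isolates caller behavior from mapper behavior. Runs
are separated by at least one read length so no read spans two loci, and
background sequence is scrubbed online so scanning the synthetic genome
recovers exactly the planted catalog. Randomness is split into keyed
streams per component and line, so adding a line never perturbs the
genomes or reads of the others, and everything is reproducible under
(config, seed).

A histogram-level path (`simulate_histograms`) draws per-sample depths
Poisson(50) and allocates reads to {allele−1, allele, allele+1} with the
same stutter probabilities, bypassing SAM text. It is marginally
equivalent to the read path at spanning loci and orders of magnitude
faster; replicated studies (e.g. the 100-replicate coverage check in the
acceptance suite) use it, while the SAM path is exercised end-to-end at
smaller scale (8 lines × 60 loci). What the simulator does **not**
emulate — mapping error, paired-end structure, quality scores, selection,
ploidy changes, locus-specific stutter idiosyncrasies — bounds what
passing tests show about real data: they validate the statistical
machinery, not robustness to alignment artifacts.

## Problem sizes used in the test and acceptance runs

Analytic interval checks run at the published exposures (up to ~10¹¹
bp-generations) — these are closed-form and instant. Simulation-based
checks use 1000-locus × 8-line cohorts (histogram path, 100 replicates for
coverage; 5 seeds for the zero-false-positive check), a 60-locus × 8-line
full SAM cohort, 10⁴ cultures for fluctuation recovery and 10⁶ cultures
for the pmf Monte-Carlo check.

## Known limitations

* The binomial mode test and the LQ score are principled stand-ins for the
  original cohort-caller's unpublished internals; both are parameterized.
* The uniqueness filter's ≤3-lines rule assumes independent lines; shared
  ancestry deeper than the experiment start would violate it.
* Exposure bookkeeping takes callable loci/bp as given (from the call
  table or a ledger); it does not model reference regions that are
  systematically unmappable.
* The fluctuation likelihood assumes equal final population sizes across
  cultures and complete plating.
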