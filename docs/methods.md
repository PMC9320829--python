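# Methods

`antdiv` reconstructs the divergence history of the wood ants *Formica
polyctena* and *F. aquilonia* from whole-genome SNP data. This note
records the models, estimators, numerical choices and limitations of
the implementation, and the scales at which the test suite exercises
it.

## Structured-coalescent engine

Demographies are backward-time models over demes with haploid effective
sizes. Within a deme of haploid size `N`, `k` lineages coalesce at
total rate `k(k-1)/(2N)` per generation (pairwise rate `1/N`; all sizes
are haploid gene-copy counts throughout, matching the haplodiploid
study system in which reported sizes are numbers of haploids). Each
lineage in deme `i` migrates backward in time to deme `j` at rate
`m[i][j]`. Gene flow reported as "from A into B" (forward time) is
implemented as backward lineage movement B→A at rate `2Nm / N_B` with
`N_B` the recipient's haploid size in the relevant epoch. Demographic
events — deme joins, instantaneous resizes, migration-matrix switches —
are applied at their scheduled times, ties in listed order. Waiting
times are exponential (continuous-time approximation, not
generation-discrete Wright–Fisher): this matches the coalescent
framework of standard SFS-based inference tools and is orders of
magnitude faster.

The expected joint site-frequency spectrum uses the branch-length
method: each branch contributes its length to the unfolded entry given
by its descendant copy counts per sampled deme; with per-site mutation
rate `mu` the probability of a configuration is `mu × mean contributed
length`, and the monomorphic probability is `1 − mu × mean total
length`. This is the linear infinite-sites approximation; the engine
refuses regimes with `mu × E[total length] ≥ 1`. Compared to throwing
Poisson mutations, the branch-length estimator has strictly lower Monte
Carlo variance at identical cost. Probabilities sum to 1 by
construction (checked to 1e-12).

Kernels are numba-compiled (~1–4 µs per genealogy for 8–21 tips), and
are bit-reproducible given one integer seed per call; multi-genealogy
calls consume a documented sequential substream of a generator seeded
once at entry.

Constants: `mu = 3.5e-9` per bp per generation (social-insect
estimate); generation time 2.5 years (overlapping queen generations).

## Synthetic data generator

The generator emulates the shape of the study data so the whole
pipeline runs without the archived reads: 20 diploid workers (10 per
species over 6 sampling locations), mean individual depth 15.6× with
lognormal dispersion, 15.49% missing genotypes per site (per-individual
rates jittered so the "least missing data" ordering used by window
resampling is meaningful), genome-wide biallelic SNPs, and a
configurable fraction of all-heterozygote artifact sites mimicking
collapsed paralogs.

Linkage is modelled at the resolution the analysis uses: one genealogy
per 50-kb window, shared by all SNPs in the window. A window's chance
of carrying SNPs is proportional to its physical length times its total
tree length (length-biased allocation). This matters: assigning a fixed
number of SNPs per window regardless of tree length produces a spectrum
shaped like `E[A_e/L]` instead of the infinite-sites expectation
`E[A_e]/E[L]`, a systematic distortion large enough (hundreds of
composite log-likelihood units at 2×10⁵ sites) to bias demographic
fits toward shorter divergence and less migration.

Callable-site counts are derived from the simulated tree lengths:
`C = round(S / (mu × mean tree length))` is the number of callable
sites implied by `S` SNPs at rate `mu`, with a small per-individual
jitter. This keeps the SNP-to-callable ratio consistent with the
mutation rate assumed downstream.

Not modelled: read-level errors, indels, mapping artifacts other than
the all-heterozygote proxy, recombination within windows. Passing tests
therefore demonstrate correctness of the analysis machinery under the
model's own assumptions, not robustness to real-data artifacts.

## Filter cascade

Fixed order: biallelic + site QUAL ≥ 30 → genotype masking (GQ < 30 or
DP < 8 → missing) → missingness (site dropped if missing in strictly
more than half the samples; 10/20 retained) → one-sided exact
Hardy–Weinberg heterozygote-excess test on all pooled genotyped
individuals (p < 0.01 dropped; pooling deliberately creates a Wahlund
effect so paralog-collapse artifacts stand out) → per-individual depth
envelope (genotypes outside [mean/2, 2×mean] masked; missingness rule
re-applied, both counts logged) → region exclusion (whole chromosomes,
e.g. the supergene-carrying chromosome 3, and gene features ± 10 kb,
closed intervals). Thinning keeps every k-th SNP in genome order
(1-based ordinals). Every stage is site- or individual-local, so the
cascade commutes with partitioning by chromosome (given fixed mean
depths).

The exact heterozygote-excess test conditions on the observed allele
counts; all placements of the minor copies into the 2n gene-copy slots
are equally likely under the null, giving
`P(h) ∝ n!/(n_AA! h! n_aa!) · 2^h`. Exact integer arithmetic is used.
Being an exact conditional test it is conservative: its null rejection
rate is below the nominal alpha. Indel-adjacency and strand-support
filters require caller-level annotations and are upstream
responsibilities.

## Summary statistics

Per locus, `H_o` is the heterozygote fraction among genotyped
individuals and `H_e = 2p(1−p)·n/(n−1)` (unbiased form, `n` genotyped
haploids). Group means are unweighted over counted loci. `F_IS = 1 −
mean(H_o)/mean(H_e)` (ratio of means — stable at low-diversity loci),
with a percentile bootstrap over loci. Pairwise `F_ST` is the Weir &
Cockerham (1984) estimator from the a/b/c variance components summed
over loci (`Σa / Σ(a+b+c)`); estimates may be negative and are not
clamped. Note the estimator's known small-sample behaviour: two samples
with *identical* genotype counts give a slightly negative estimate of
order `−1/(2(n−1))`, because the forced zero between-group variance
sits below its panmictic sampling expectation.

## Folded joint SFS

Missing data are eliminated by downsampling individuals in 50-kb
windows: a dataset-wide target `k_p` per population (population size
minus the maximum per-site missing count in that population, floored at
2), per window the `k_p` individuals with least missing data at that
window's SNPs (ties by sample order), windows with mean inter-SNP
distance < 2 bp discarded, residually incomplete sites dropped and
counted. `k_p` is computed per population of the specific pair being
analysed. Folding uses the pooled minor allele; exact half-frequency
ties go to the lexicographically smaller member of the mirror pair
(split weights are not used; folding is idempotent). The monomorphic
count is `round(L_callable × S_kept/S_dataset) − S_kept`, isolated in
one function so alternative readings are one-line swaps; total mass
then equals the scaled sequence length exactly. Export uses a
fastsimcoal2-style `.obs` text dialect (monomorphic mass in the [0,0]
cell) plus a native TSV with a JSON provenance sidecar.

## Demographic inference

Ten scenario templates (allopatry; sympatry with one or two
migration-rate epochs; isolation-after-migration; migration-after-
isolation; a 10-parameter allopatry control with asynchronous recent
resizes and an extra mid-divergence resize; four ghost-introgression
topologies with an unsampled deme) map parameter vectors to
demographies. Search ranges: sizes log-uniform 10³–10⁷ haploids, times
uniform 10²–10⁶ generations with machine-checked orderings, migration
as scaled 2Nm log-uniform 10⁻¹⁰–20.

The objective is the composite log10-likelihood `Σ m_e log10 p̂_e` over
folded entries with the monomorphic mass pooled into the (0,0) cell;
expected probabilities for observed-but-unsimulated entries are floored
at 10⁻²⁰. Composite likelihoods on linked sites support point
estimation and likelihood ranking but not AIC-style penalties, so model
comparison reports raw Δ composite-log-likelihood only.

Optimisation is multi-start coordinate-cycling multiplicative line
search with common random numbers (one kernel seed per run makes each
run's objective deterministic). Two refinements of plain multi-start
proved necessary and are part of the design:

* **Data-anchored starts.** Random starts over 4–11 orders of magnitude
  almost never place gene flow in a meaningful regime. Initial points
  are centred on a Watterson-style size scale computed from the
  observed spectrum, the divergence-time start additionally uses a
  fixed-difference moment anchor (`T ≈ f_fix × E[L]/2`, so deep
  divergences are reachable), and starts cycle through qualitative
  gene-flow regimes (none / each direction /
  each-direction-ancestral-only / all).
* **Staged precision with common-random-number comparisons.** All
  candidate starts are polished on a cheap objective (coordinate line
  search for travel, then a Nelder–Mead simplex in log space whose
  diagonal moves traverse correlated ridges), leaders are re-optimised
  at higher genealogy counts, and the final few are compared and
  polished with a small-simplex Nelder–Mead under one shared kernel
  seed at high precision.
  Near-tied modes (e.g. swapped migration direction, or the classic
  divergence-time–migration ridge) are thereby ranked at a resolution
  where the spread of the objective across kernel seeds (~1 log10 unit
  at 2.5×10⁵ genealogies for the test-scale configurations) is far
  below the mode separation.

Protocol defaults mirror the full-scale analysis (100 runs × 80
iterations × 2×10⁵ genealogies); the test suite uses reduced
configurations (4–6 runs, 8–18 iterations, 3×10³–6×10⁴ genealogies with
a 2×10⁵-genealogy final polish) chosen as the package's desk-scale
operating point.

Identifiability at desk scale: with a folded 12-tip joint spectrum and
2×10⁵ sites the profile composite likelihood along the divergence-time
versus migration ridge is flat to within ~10 log10 units across a
ten-fold parameter range; at 20 tips the same ridge is ~200 units deep
and point recovery within a factor of two becomes reliable. Parameter
recovery tests therefore sample five diploids per species.

## Block bootstrap

Confidence intervals resample 50-kb windows with replacement from the
complete-data table, rebuild the spectrum (monomorphic count rescaled
proportionally to the resampled SNP total), and refit from the MLE
(first run) and lognormally jittered copies (σ = 0.25 on the log scale
by default). Each replicate's refit seed is derived from the resampled
window multiset itself: identical resamples give bit-identical
estimates (so degenerate one-window data yields exactly zero-width
intervals), while distinct resamples get fresh search randomness — on
nearly flat likelihood ridges this lets replicate estimates spread the
way independent full fits would, which percentile intervals need in
order to attain their nominal coverage. Percentile intervals
(0.5th/99.5th percentiles at the 99% level); runs with fewer than 1000
replicates are flagged as indicative, as in the original protocol.

## Test scales

The suite generates all data programmatically. Representative sizes:
engine calibration 1–2×10⁵ genealogies per check and 3×10³ replicates
for the independent-simulator cross-validation; parameter recovery
2×10⁵ effectively unlinked SNPs (one genealogy per 50-kb window, ~1 SNP
per window) from 5 + 5 diploids; model discrimination twenty 3×10⁴-SNP
datasets from 3 + 3 diploids generated under strong asymmetric gene
flow (ancestral 2Nm = 5); bootstrap coverage twenty meta-replicates of
7.5×10³ SNPs in ~750 dense 50-kb windows from 3 + 3 diploids under a
deep-divergence history (T ≈ 4 coalescent units), where the divergence
time is sharply identified by fixed differences — the regime in which
the original analysis also reported its tightest intervals. Fits at
these scales recover parameters within the tolerances asserted in the
tests, with the measured exception discussed above (the no-gene-flow
mode ties the truth mode within ~14 log10 units at 2×10⁵ sites, so
point recovery of a weak migration rate is realisation-dependent);
they do not reproduce the study's point estimates, which would require
the archived sequencing data.
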