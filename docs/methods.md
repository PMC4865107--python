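# Methods

This note documents the models and numerical choices behind `topomap`: what
each stage computes, the parameters that matter, what the synthetic data
emulate (and do not), and the design decisions taken where the problem was
genuinely open.

## Coverage model and normalization

All tracks are per-base read signals on a circular genome, 0-based and
half-open; every window operation wraps. The pipeline follows the standard
bacterial ChIP-seq recipe:

1. scale each library to reads-per-million (`rpm_normalize`);
2. smooth each strand with a **200 bp** centered circular moving average
   (`smooth_circular`; even windows take ⌊w/2⌋ positions on the left; the
   track total is conserved exactly);
3. add strands and form the IP/input ratio with a pseudocount of **1 read
   per smoothing window** (0.005/bp at w=200) in both numerator and
   denominator — enough to stabilize near-zero-coverage bins without biasing
   covered ones;
4. rescale the ratio so its genome-wide **median** is 1. The median rather
   than the mean, because a handful of very strong peaks would drag a mean.

Non-specific signal (rRNA operons, tRNA clusters, IS elements) appears in
mock immunoprecipitations as well; `mask_from_mock` masks every position
whose smoothed mock/input ratio is ≥ 2, and every downstream statistic
ignores masked positions. GC normalization fits a straight line of ratio
vs GC fraction on 60 kb bins and divides it out (lowess was rejected for
determinism); the genome-wide mean is preserved. Copy-number normalization
is an elementwise division by a dosage track.

## Cleavage-site calling (NorflIP)

A quinolone-poisoned type II topoisomerase is trapped covalently on the 5′
ends of its cleavage site. Sequencing such IPs yields, around each cleavage
point: forward-read enrichment on roughly [c−235, c−65), reverse-read
enrichment on [c+65, c+235), a non-enriched **130 bp** gap between the
smoothed blocks, and a **100 bp** central window with almost no raw reads
(the blocked 5′ ends fail ligation). The caller turns this geometry into a
matched filter:

* `differential_track` = smooth(fwd) − smooth(rev), after RPM scaling.
  A cleavage site becomes a positive lobe followed by a negative lobe with
  a zero crossing at the cleavage point.
* `scan_cleavage` slides a template over the genome at **100 bp** steps and
  computes the Pearson correlation of each **600 bp** window (2 kb
  supported as the wide-probe variant) with the template, via FFT
  cross-correlation plus prefix sums (O(L log L) genome-wide). Windows with
  r ≥ **0.72** are merged within 300 bp keeping the maximum-r window (ties
  to the smaller coordinate). Negative correlations are never calls: the
  template's sign convention is forward-lobe-first.
* `validate_sites` keeps candidates whose maximum unmasked IP/input ratio
  within the template window is ≥ **2**, and drops candidates in masked
  regions.
* `estimate_cleavage_point` finds the forward and reverse read blocks at
  half maximum and returns the center of the gap between them; on canonical
  noise-free input this is exact and sits **150 bp** downstream of the
  forward-peak center ((170+130)/2). When the two blocks cannot be resolved
  (e.g. a symmetric binding peak) it falls back to the differential-signal
  zero crossing and flags the site.
* `measure_shape` reports the realized spans at half maximum, the gap, and
  the width of the region where combined raw signal falls below half the
  local background.

The template is synthesized from canonical shape parameters by default; a
"data" mode rebuilds it from the two strongest sites of the experiment
itself, mimicking a pipeline bootstrapped from its own best peaks. Block
edges are located on raw signal (`smooth=1`, exact for rate tracks) or on
~51 bp-smoothed signal for Poisson data (`NorflipPeakModel.from_experiment`
selects this automatically).

**A note on the r threshold.** After 200 bp smoothing, a 600 bp window
retains only ~3–6 effective degrees of freedom, so pure-noise windows
exceed r = 0.72 regularly (measured: a few thousand raw candidates on a
background-only 4.6 Mb genome). The correlation filter is therefore a
*shape* filter, not a significance filter; specificity comes from the
fold ≥ 2 validation, which removes all background candidates at realistic
depths. Mirror-image (reverse-lobe-first) shapes anticorrelate at alignment
and are never called at their center, though single-lobe partial matches
can pass the r filter ~300 bp away.

## Binding-site calling (ChIP)

Binding peaks are symmetric ~200 bp enrichments. The caller extracts a
600 bp template from the ratio track at a trusted reference site (the
strongest unmasked peak by default, playing the role of *dif*), scans the
genome at 100 bp steps, and keeps merged windows with r ≥ **0.7** and
fold ≥ **2**. Calls are invariant to global library scaling and to reversal
of scan order. `ori_ter_bias` reports the mean dosage-normalized ratio over
a 3 Mb origin-centered arc vs the complement, and the longest run of 60 kb
bins below the genome-wide mean as the terminus-depleted span.

## Marker frequency and fork localization

`marker_frequency` bins (10 kb) the ratio of a replicating sample's
coverage to a non-replicating reference, masks empty reference bins, and
rescales so the lowest-decile bins average 1. A flat track is flagged
`fully_replicated`: after library normalization a uniformly doubled (G2)
genome is indistinguishable from an unreplicated one — only fork structure
is observable.

Fork positions are slope changes of this profile. The track is cut at the
origin (a slope change known a priori) and at the terminus (profile
minimum) into its two replichore arcs; each arc is fitted with a continuous
3-segment piecewise-linear function whose two knots are grid-searched
coarse-to-fine at bin resolution, and the knot at which the profile reaches
the unreplicated baseline — the fork foot — is that replichore's
breakpoint. A single whole-circle fit with two free knots was tried first
and is not identifiable for plateau–ramp–plateau profiles; the
per-replichore decomposition is. Step profiles localize within one bin,
Poisson-noise profiles within two. `fork_distances` converts two breakpoints
into arc distances from the origin along the two replichores (bp), raising
an error if both fall on one replichore.

## The comet null model

The null model asks whether occupancy could be explained by the enzyme
simply tracking replication forks. Assumptions: forks move deterministically
at v = L/C down each replichore; each fork trails a comet of fixed genomic
length `comet_len`; optionally every locus stays marked for a fixed
`persistence` time after the comet passes; the population is in steady
exponential growth, so cell ages follow f(a) = (2 ln2/T)·2^(−a/T) on [0,T).
With τ = comet_len/v + persistence (capped at one doubling time, to avoid
double-counting marks across divisions), a locus at distance s from the
origin has

    D(s) = 2^((C + D − s/v)/T)        mean copy number (Cooper–Helmstetter)
    O(s) = 2·(1 − 2^(−τ/T))·D(s)      mean marked copies

so **O/D is constant in s** for every parameterization, including
overlapping rounds (C + D > T, handled by carrying the completed doublings
as a 2^m baseline). That flatness is the model's testable content: the
coefficient of variation of O/D is ~10⁻¹⁶ for the analytic solution, and a
mechanistic Monte-Carlo (cells sampled from the age distribution, fork
positions and mark windows reconstructed per cell) agrees within 3 standard
errors at 10⁵ cells. Conversely, halving O over a terminus-sized arc drives
the CV above 0.1 — occupancy data with a terminus gap reject the model.

Parameter defaults: L = 2.32 Mb (one replichore), C = 40 min, D = 20 min,
T = 60 min, comet_len = 200 kb, persistence = 0.

## Genomic-context statistics

Distances to intervals are circular and 0 inside. "Highly expressed"
transcription units are those with ≥ **500** RNA-seq reads (a top-decile
selector is available). The TU-proximity comparison against a seeded
uniform random control uses a one-way ANOVA F-test by design, with a
rank-based Mann–Whitney alternative offered for the skewed distance
distributions; under the null the ANOVA p-value is conservative
(super-uniform), which the tests verify. Overlap enrichment is computed at
the **gene level** (does a gene carry a site midpoint? does it overlap a
feature?) with a one-sided Fisher exact test; on universes ≤ 50 genes it
matches brute-force hypergeometric enumeration to 10⁻⁹ relative.
GATC-motif spacing is reported per rank (−k..k−1) around each site; note
the interval straddling a random site is size-biased (~2× the ~256 bp
mean spacing of an i.i.d. GC=0.5 sequence) — comparisons must be made
rank-wise against the random control, never pooled.

## Synthetic data: what it emulates, and what it does not

The generator plants per-base Poisson **rates**, not reads: cleavage sites
with the canonical strand-asymmetric geometry (enrichment as a
multiplicative fold on the strand blocks, raw rates forced to zero on the
central 100 bp), symmetric binding peaks, artifact regions multiplying IP
and mock alike, dosage gradients (asynchronous exponential-growth gradients
with ori:ter = 2^(C/T), or synchronized fork pairs with an optional linear
front ramp emulating fork dispersion), i.i.d. genome sequence at a chosen
GC fraction, and annotation sets with non-overlapping genes (~85% genic),
heavy-tailed TU expression, Fis points and H-NS intervals. A noise-free
mode returns the rate tracks so geometric assertions are exact; seeded runs
are byte-reproducible. Defaults are 5 reads/bp/strand for IP background and
input — at which a planted fold-10 site stands ≫10σ above background after
200 bp smoothing — and a 2 kb minimum planted spacing (violations warn, as
real genomes do cluster sites).

Deliberately not modeled: read-level artifacts (PCR duplicates, sequencing
error, mappability), fragment-end geometry linking the 130 bp smoothed gap
to the 100 bp raw-read gap (both are independent parameters, as the two
numbers are reported independently), chromatin-driven background structure,
and correlated noise between strands. Passing tests therefore demonstrate
correctness of the *computations* on data with the assumed statistical
structure, not robustness to every pathology of real libraries.

## Numerical choices and limitations

* Correlation scans: FFT cross-correlation on the wrapped-extended track
  (padded to fast FFT sizes), window variance by prefix sums; constant
  windows get r = 0 by convention. Merging keeps the max-r window, ties to
  the smaller coordinate; clusters wrap across the origin.
* Problem sizes: the planted-truth recovery checks run 20 seeded 4.6 Mb
  genomes with 25 sites each for the cleavage caller and one 19-site genome
  for the binding caller; module-level recall tests use 1 Mb genomes. The
  Monte-Carlo comet oracle uses 10⁵ cells on a 200-bin grid.
* Cross-experiment site matching pools and clusters positions with a 250 bp
  tolerance; with well-separated sites this equals greedy nearest matching,
  but adjacent true sites < 250 bp apart would merge.
* `detect_slope_breaks` assumes exactly one fork per replichore (one
  synchronized round); multi-fork profiles need a different segmentation.
* The comet model's persistence is capped at one doubling time; longer
  memory would require tracking marks across multiple divisions.
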