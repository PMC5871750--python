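# Methods

This note records the statistical model, the numerical choices, and the
design decisions behind `dhrcall`, together with what the synthetic-data
validation does and does not establish.

## Windowing and counting

The genome is tiled exhaustively into fixed windows (default 100 bp,
0-based half-open coordinates; the last window of a chromosome may be
short). A fragment increments **every** window it overlaps by at least one
base — region-coverage semantics, matching window-based enrichment tooling;
a midpoint-assignment mode is available as a config option but is not the
default. Strand is ignored: retention is occupancy, not transcription.
Fragments exceeding chromosome bounds are an error by default (they signal
upstream mapping problems) with an opt-in clip mode. The global window index
is ordered by chromosome order in the `chrom.sizes` file, then start, and is
the join key across samples.

## Differential coverage test

The per-window test is a re-implementation of the classic two-group
conditional NB exact test for sequencing counts, defined so that every step
is deterministic and oracle-verifiable:

* **Normalization.** Effective library size = total fragment count per
  sample (default), or a trimmed mean of per-window count ratios against a
  reference sample ("trimmed-mean" mode, trim fraction 0.3) when a few
  extreme windows would otherwise distort the totals.
* **Pseudo-counts.** Samples are scaled to the geometric mean of the
  effective sizes and rounded half-up to integers (the exact test needs
  integer support; the rounding error is bounded by half a count and is
  covered by the oracle-equivalence tests).
* **Common dispersion.** A single `φ` (Var = μ + φμ²) is estimated by
  maximizing the summed conditional log-likelihood of each group's
  pseudo-counts given their row sums — the conditional law is free of the
  window means, so only `φ` remains. The search is a coarse geometric grid
  on [0, 2] refined by bounded scalar minimization to 10⁻⁴, with the Poisson
  boundary (`φ = 0`, multinomial conditional law) checked explicitly.
  All-zero windows contribute a constant and are dropped; with more than
  2 × 10⁵ windows a deterministic even stride is used.
* **Exact test.** Group pseudo-count totals `(y_A, y_B)` are compared
  conditionally on `n = y_A + y_B`: `P(Y_A = k | n)` is proportional to
  `C(k + r_A − 1, k) C(n − k + r_B − 1, n − k)` with `r_g = w_g/φ` and `w_g`
  the group's summed effective size in common-library units. The two-sided
  p-value is the minimum-likelihood rule: the total probability of outcomes
  whose probability is at most that of the observed outcome. Outcomes
  within a relative factor 1 + 10⁻⁷ of the observed probability count as
  ties (the same convention scipy's binomial test uses), so float noise
  cannot split exact ties. For `n` beyond 10⁵ the enumeration is truncated
  to the central mass (≥ 1 − ~10⁻¹³), computed as the complement of the
  more-likely outcomes so the truncated tails are implicitly counted as
  "less likely"; the approximation error is below 10⁻¹².
* **Degenerate windows.** All-zero (or below `min_total_count`) windows get
  p = 1 and log₂FC 0 so window indices stay aligned; one-sided-zero groups
  get ±∞ fold-change sentinels.

No multiple-testing adjustment is applied: the method thresholds raw
p-values, and the thresholds (10⁻⁷ / 10⁻⁶) are part of the procedure.

## Site calling

DHR seeds are maximal runs of windows below the stringent cutoff. Extension
absorbs whole windows only: a candidate window with `p < 0.1` is absorbed
when the gap between its nearer edge and the region edge is **strictly less
than** 1000 bp (the "within 1000 bp" rule; a closed-comparison variant is a
config switch), repeated to a fixpoint — extension can therefore chain
across long runs of sub-0.1 windows, which the fixpoint wording requires.
Regions that touch or overlap merge (half-open adjacency is zero gap).

Because the seed set is a subset of the extension-qualifying set, the
fixpoint equals the single-linkage clustering of qualifying windows at the
extension distance, restricted to clusters containing a seed; the
implementation uses that closed form, and the test suite checks it against
a deliberately naive re-scanning implementation on random genomes, together
with the fixpoint certificate (no qualifying window within 1000 bp of any
final edge) and seed-set monotonicity in the threshold.

Depth-based sites (conserved / individual) use the same machinery with
"qualifying" = raw count ≥ 150 (alternate 25) in every sample of the group
(or the single sample); qualifying windows are their own seeds. Raw counts
are used deliberately — the threshold is stated in reads, not normalized
units. The universal core takes a representative group's conserved sites
and keeps those overlapping (≥ 1 bp, as everywhere) at least one site in
every other group, reporting the representative's intervals verbatim.

Site scores: −log₁₀ of the minimum seed p-value (DHRs) or the weakest
qualifying window's group-minimum depth (depth sites).

The comparison-level "all treatment or all control" wording is implemented
as per-group site sets; both are reported and the core intersection
consumes them directly. "Multiple-window" DHR counts require ≥ 2 seed
windows per final region (not adjacency of the seeds).

## Gene association

Genes come from a local BED6/TSV table. A gene is associated with a site
when the gap between the half-open intervals, `max(0, max(a,c) − min(b,d))`,
is at most 10 kb (0 = overlap). The gene body, not the TSS, is used — the
distance is stated to the site/gene edges — and strand is ignored.
Functional categorization (pathways, curated groups) is out of scope.

## Synthetic data generator

The generator plants truth directly in window coordinates and then
materializes fragments, because the pipeline only ever sees window counts.

* **Geometry.** Default genome 2 × 5 Mb; 50 core sites and 20 differential
  sites per exposure, placed uniformly, window-aligned, with a minimum
  separation of 3 kb so that sub-window edge effects plus the 1000 bp
  extension can never fuse two planted sites. Lengths are lognormal around
  1 kb (σ = 0.6) clipped to [0.3, 10] kb and rounded to whole windows —
  predominantly ~1 kb with a tail to 10 kb.
* **Rates.** Rates are expected per-window *coverage* — the quantity the
  count matrix and the 150-read threshold see. Background 30, retention
  sites 250. Differential sites are exposure-gained: background in
  controls, background × fold-change (default 4) in exposure samples; a
  "reduced" mode plants retention in both lineages with the control at
  `retained/fold` instead. The fold change is the effect size: at
  fold → 1 the differential signal vanishes, and recovery must degrade
  accordingly.
* **Materialization.** Each window draws `NB(rate/3, φ)` fragments
  (φ = 0.05 by default; φ = 0 gives Poisson). A fragment homed at a window
  has length uniform on 200–250 bp and is jittered so it covers exactly the
  home window and its two neighbours (clipped only at chromosome ends).
  Window coverage is then the sum of three adjacent draws: its mean equals
  the declared rate exactly and its replicate-to-replicate dispersion is
  ≈ φ/3 — the smoothing a fragment footprint spanning several windows
  produces in real data too. The intensity profile of each planted site is
  widened by one window per side so realized coverage plateaus across the
  whole truth interval; the soft shoulder outside the truth is one window
  wide, which is why called boundaries land within one window of truth.
* **Determinism.** One seeded generator stream per stage (placement,
  fragments, individuals) with a fixed draw order; identical seeds give
  byte-identical BED output.

What the generator does **not** emulate: sequence content, mappability, GC
bias, PCR duplicates, chromatin accessibility structure, or any
window-to-window rate autocorrelation beyond the fragment footprint.
Passing the recovery tests shows the pipeline implements its stated rules
correctly under its own model assumptions; it does not show the thresholds
are optimal for any real library.

## Problem sizes and runtime choices

The validation suite runs the full pipeline at the default scale
(2 × 5 Mb genome, ~10⁶ fragments per sample, 3 + 3 pools — a deliberate
desk-scale reduction of a ~35 M-read rat library), three independently
re-drawn comparisons for the six-way core intersection, five simulated
individuals for the reproducibility fraction, 10⁵ windows for the null
check, all grand totals ≤ 200 for the exact-test oracle, and 200 random
small genomes for the interval oracle. p-value vectors are cached per grand
total, which makes the 10⁵-window runs take seconds.

## Known limitations

* The exact test is a defined surrogate for the cited R tooling: library
  size (or trimmed-mean) normalization, conditional-likelihood common
  dispersion, and group-summed exact test. It does not reproduce
  quantile-adjusted pseudo-counts, tagwise dispersion, or GLM variants, so
  p-values on real data will differ in detail from the original stack even
  though the procedure is structurally the same.
* Whether the original window counting used plain or extended-fragment
  overlap is unknowable from the text; plain overlap counting is adopted
  and flagged, with midpoint assignment as the alternative.
* The dispersion estimate is a single common φ; strongly heterogeneous
  windows (e.g. retention sites vs background) are pooled, which biases φ
  toward the dominant background class. For DHR calling this is
  conservative in the direction that matters (sites are tested with a
  background-driven dispersion).
* Depth thresholds compare raw counts, so they are sensitive to sequencing
  depth; the 150/25 values are assay constants, not estimates.
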