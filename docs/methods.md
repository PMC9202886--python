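# Methods

## Data model and conventions

All coordinates are 0-based half-open, the native convention of the
BED/bedGraph files the package reads and writes; 1-based sources must
be converted at the boundary.  Count tracks are keyed on an ordered,
non-overlapping restriction-fragment grid; counts are stored as floats
because normalized counts are fractional.  Sample metadata (condition,
replicate) travels in a sidecar table or explicit arguments — it is
never inferred from filenames.  Distances are measured from the integer
midpoint of the viewpoint fragment, `floor((start+end)/2)`.

In-silico digestion cuts at every occurrence of the recognition motif
(default GATC with cut offset 0, i.e. a blunt cut at the start of the
site, so every fragment after the first begins with the motif).
Matching is case-insensitive, `N` never matches, overlapping
occurrences each contribute a cut, and zero-width fragments at the
sequence ends are dropped.  Fragments always tile the input exactly.

## Normalization and the difference track

Size factors use the median-of-ratios estimator: for sample `j`,
`s_j = median_i ( K_ij / g_i )` over fragments `i` with strictly
positive counts in all samples, where `g_i` is the row geometric mean.
Rows containing zeros are excluded from the median (the geometric mean
is undefined there) but are still rescaled.  The estimator is
scale-equivariant: multiplying one sample by `c` multiplies its factor
by `c^(1-1/m)` and every other factor by `c^(-1/m)`.  The test suite
verifies the implementation against DESeq2's
`estimateSizeFactorsForMatrix` on a random matrix.

Replicates enter the count matrix as separate columns and are combined
only when the difference track is formed: `Δ_i` is the mean normalized
count over condition-A replicates minus the mean over condition-B
replicates, so `Δ(A,B) = −Δ(B,A)` exactly.

## Binning

The difference track is trimmed to a region of interest (default
±500 kb around the viewpoint midpoint; straddling fragments are kept
whole), then binned.  The bin origin is anchored at `midpoint − radius`
so the midpoint falls on a fine-bin boundary and both flanks hold
equally many whole bins.  A fragment's value is split across the bins
it overlaps *proportionally to overlap width*.  This rule is a design
choice (midpoint assignment would be the alternative); it was chosen
because it conserves the total exactly, which makes re-binning
(default 1 kb → 10 kb, trailing partial groups summed as-is and
flagged) an exact sum and gives the test statistic a clean conservation
invariant.  The caveat it introduces is discussed under Limitations.

## Meso-scale constant-sign-run test

On the coarse (10 kb) track, maximal runs of strictly-positive or
strictly-negative bins are enumerated; zero bins carry no sign and
break runs, as do excluded bins.  The statistic is the largest run
total absolute value.  The null is built by uniformly permuting the
fine (1 kb) bins outside a ±50 kb exclusion zone around the viewpoint;
exclusion-zone bins are frozen in place rather than removed, so the
coarse-bin geometry is identical in observed and permuted data, and
the coarse bins overlapping the zone are excluded from the statistic on
both sides of the comparison.  The p-value is `exceedances / n_perm`
with ties counted as exceedances; a bias-corrected
`(exceedances+1)/(n_perm+1)` variant is available behind a flag.  The
observed run may abut the exclusion zone; permutation covers the full
region of interest minus the zone.  Only the single maximal run is
tested — no multiplicity adjustment across runs is attempted.

## Near-viewpoint asymmetry test

Counts close to the viewpoint correlate strongly with distance, so
arbitrary shuffling is invalid there.  The test uses the group of
distance-preserving permutations: swapping a fine bin with its mirror
image on the opposite flank.  With `n` mirror pairs (default 50; the
viewpoint's own bin belongs to neither flank) and pair differences
`x_i`, the statistic `T = Σ x_i` is compared with the `2^n` values of
`Σ ±x_i`.  For `n ≤ 20` (~10^6 assignments) the distribution is
enumerated exactly; otherwise `n_perm` (default 10 000) seeded draws
are used.  The test is two-sided on `|T|` by default — remodelling can
favour either flank — with a one-sided option; ties count as
exceedances.  Exactness of the sign-flip null requires the `(up_i,
down_i)` pairs to be independent across `i` and exchangeable within a
pair under the null; both hold when fragments are small relative to
bins (see Limitations).

## Peak-overlap enrichment

A query set of interacting fragments is compared against a universe of
candidate fragments (default: all fragments in the region of interest).
Each permutation redraws `|query|` fragments uniformly without
replacement and counts how many intersect at least one peak (half-open
semantics; abutting intervals do not overlap).  Resampling fragments —
rather than shuffling peak positions — preserves the fragment-grid
structure capture data lives on; with binary per-fragment overlap the
null is exactly hypergeometric, and the implementation is cross-checked
against that closed form.

## Significance bookkeeping

Per-fragment p/q tables from an upstream interaction caller are
consumed, never computed, here.  Replicate q values merge by geometric
mean (`sqrt(q1·q2)` for two replicates — the mean of −log10 q on the
log scale; `(Π q)^(1/n)` generally).  A fragment is
replicated-significant for a cell type iff `q < 0.1` in every replicate
of that cell type; the global set is the union over cell types.
Curation keeps fragments whose `−log10(merged q)` exceeds the curation
threshold (`q < 0.05`) and strictly beats every neighbour within a
window of 2 fragments per side, with coordinate ties resolved leftward,
so no two curated fragments fall within one window.  The local-maximum
rule is this package's operational definition of "highest local
significance"; both thresholds and the window are configurable.

## Synthetic data generator

The generator emulates what fragment-level processing of a capture
library yields: per-fragment counts with expected value
`μ(d) = depth · A · (1 + d/d₀)^(−α)` at near-edge distance `d` from the
viewpoint midpoint, drawn from a negative binomial with size
(dispersion) `r`, `var = μ + μ²/r`.  Defaults: `A = 1000` expected
counts at the viewpoint, `d₀ = 5 kb`, `α = 1` (contact probability
falling roughly as 1/distance across the 50–500 kb range), `r = 5`
(strong overdispersion typical of capture counts), per-sample depth
factors uniform on [0.5, 2] so normalization is genuinely exercised.
The synthetic chromosome is a seeded random sequence with 58% AT —
mammal-like composition giving the ~270 bp mean GATC-fragment length a
4-cutter actually produces (~4000 fragments across the ±500 kb region).
Differential structure is injected multiplicatively: the default
scenario raises one condition's means 5-fold over a 100 kb domain
starting 350 kb downstream of the viewpoint; near-viewpoint asymmetry
is injected by scaling one 50 kb flank's amplitude (1.5-fold in the
asymmetry example, at which the sign-flip test has power ~1).
Emulated significance tables draw `q ~ U(0, 0.05)` inside designated
true-interaction regions and `q ~ U(0.2, 1)` elsewhere, making the
replication filter's behaviour analytically forced.

What the generator does *not* emulate: ligation-junction artefacts,
mappability gaps, undigested or self-ligated fragments, trans contacts,
domain boundaries/TAD structure beyond the injected effects, and any
correlation between replicates beyond shared means.  Passing tests
therefore demonstrate correctness of the statistical machinery under a
clean distance-decay + overdispersion model, not robustness to every
artefact of real libraries.

## Numerical and design choices

- Zeros break sign runs: the sign of 0 is neither + nor −, which keeps
  the run statistic well-defined on sparse tracks.
- Ties count as exceedances in every permutation p-value, and the
  plain `exceedances/n_perm` estimator is the default.
- Exact enumeration threshold for the sign-flip test: 20 pairs (2^20 ≈
  10^6 sums, enumerated by doubling) — exactness whenever it is cheap.
- Every source of randomness takes a mandatory seed; absent seeds are
  errors, not silent defaults.
- Degenerate inputs: all-zero tracks give statistic 0 and p = 1; an
  exclusion zone covering the whole region, empty universes, and
  single-replicate cell types are rejected with validation errors.
- CLI exit codes: 0 success, 2 validation failure, 3 I/O failure;
  logs to stderr, results only to files/stdout.

## Limitations

**The meso-scale null is anti-conservative under strong distance
decay.**  Uniform permutation of fine bins assumes they are
exchangeable, but the variance of the per-bin difference decays with
distance along with the mean counts.  The observed track concentrates
its high-variance bins just outside the exclusion zone, whereas
permutation spreads them across the region, so the observed maximal
run total is stochastically larger than its permutation null.  Under
the default generator the test rejects ~20% of effect-free datasets at
p ≤ 0.05; flattening the decay restores the nominal rate, isolating
distance heterogeneity as the cause.  The test suite records this
honestly (the null-calibration check fails for the meso-scale test and
passes for the asymmetry test, which is exactly calibrated by
construction).  In practice this means meso-scale p-values should be
read as enrichment scores unless the difference track is approximately
distance-flat, effects are large (the default scenario's domain is
detected with p ≈ 0 against either null), or a distance-stratified
permutation scheme — not implemented here — is used.

**Fragment width vs bin width.**  Proportional allocation writes
correlated shares of one fragment's count into adjacent bins.  With
realistic ~270 bp fragments and 1 kb bins the effect is minor, but if
fragments approach the bin width the induced adjacent-bin correlation
invalidates both permutation nulls; choose bins comfortably wider than
the fragment grid.

**Other limits.**  Per-run p-values are not multiplicity-adjusted;
the overlap test's fragment-resampling null ignores peak clustering
along the genome; the curation rule is a reasonable operational
definition, not a canonical one.
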