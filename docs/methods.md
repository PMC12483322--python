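# Methods

This note documents the models, conventions, and numerical choices behind
`septorg`, and what the synthetic-data tests do and do not establish about
real imaging data.

## Coordinate and normalization conventions

A line scan is an ordered vector of intensity samples along the cell
perimeter, two channels per cell-timepoint (polarity marker, septin), at a
fixed spacing (default 0.1 µm, 100 samples, i.e. a 10 µm perimeter).  The
perimeter is treated as circular; positions are signed µm from the polar-cap
center, negative left.  The center index of an n-grid is `n // 2` (odd grids
have a unique center; even grids use index n/2, and the index-0 sample — the
cap's antipode — is its own mirror image under reflection).

Alignment finds the polarity peak as the argmax after a 3-sample circular
moving average (raw argmax is noise-sensitive), remaining ties to the lowest
index, and circularly shifts the septin channel so the peak is central.  A
constant polarity channel has no peak and the scan is rejected.  Whether
real acquisitions smooth before peak-finding varies; smoothing is a flag.

Normalization subtracts the per-profile minimum and scales to unit sum, so a
profile is a spatial distribution of septin signal (min 0, sum 1).  This
makes cells of different brightness comparable but discards absolute
intensity; constant profiles are rejected as uninformative.  Profiles of
unequal length are never warped onto a common grid — mixed-length ensembles
are an error.

## Bootstrap confidence bands

`average_with_ci` resamples whole profiles (cell-timepoints) with
replacement — respecting within-profile spatial correlation — and reports
percentile intervals of the per-position mean (default n_boot = 1000, level
0.95).  Non-overlap of two 95% bands is the significance criterion
(conservative relative to a direct two-sample test).  Percentile intervals
at small ensemble sizes can fail to bracket the sample mean by a hair; bounds
are clipped so `lower ≤ mean ≤ upper` always holds.  Coverage is verified
empirically in the test suite: ~95% ± 3 points for Gaussian ensembles of 100
profiles.

## Shape classification

Orientation ("symmetry removal") compares the half-sums left and right of the
center (center sample excluded on both sides, plus the antipode sample on
even grids, which reflection maps to itself — without that exclusion an
exactly symmetric profile on an even grid would spuriously flip).  Exact ties
do not flip, so orientation is deterministic and idempotent.

PCA is center-only (no variance scaling): profiles share units, and scaling
would inflate low-signal positions.  The retained score count is the smallest
whose cumulative explained variance reaches 95%, capped at 12 (both
configurable); on synthetic data a handful of scores usually suffices, and
the cap only binds for richer data.

K-means uses the squared-Euclidean objective with k-means++ seeding, best of
10 restarts per K, fixed seed.  "Within-cluster sum of differences" is the
sum of squared point-to-centroid distances (the clustering objective itself),
so the sweep curve W(K) is the quantity the clusterer minimizes.  K is chosen
at the strict local maximum of the discrete second derivative
`d2(K) = W(K−1) − 2W(K) + W(K+1)` with the largest value, ties toward larger
K; if no strict local maximum exists (e.g. a linear curve) the global
interior maximum is used with a warning.

The curvature rule is well-posed when class separations are comparable: for
six equidistant, equal-mass, well-separated clusters W(K) falls linearly to
K = 6 and then flattens, putting the unique curvature spike at 6.  If one
coarse split dominates (very unequal separations or masses), the spike moves
to that split — the rule then reports the dominant partition, not the finest
one.  Two design consequences:

- The default synthetic templates are engineered near-equidistant: multi-bump
  classes use bumps of mass 1/k and width σ/k (which leaves the
  post-normalization L2 norm unchanged) with mutually disjoint supports, so
  all pairwise distances agree to ~30%.
- The classifier is meant to be fitted once on the pooled profiles of all
  strains (which balances class masses) and then applied per strain; fitting
  on a single strain with very skewed usage can merge rare classes.

Class ids are arbitrary; `relabel_by_reference` renames the two classes whose
frequencies differ most between two reference strains to 1 and 2 (larger
difference first) and orders the rest by the leaf order of an average-linkage
dendrogram of their centroids.

## Strain similarity

Distances between strains are Euclidean distances between overall class-usage
frequency vectors (the referenced distance routine's default metric; overall
rather than per-timepoint frequencies).  Trees are average-linkage (UPGMA);
clade support is the fraction of bootstrap trees — profiles resampled within
strain, usage and tree recomputed — containing the clade, with 0.95 the
conventional confidence flag.

The two-reference projection solves the circle intersection in the stable
product form `y² = ((r1+r2)² − d²)(d² − (r1−r2)²) / 4d²`, which avoids
cancellation when a strain lies on the reference axis (the references
themselves land at exactly (±d/2, 0)).  Non-intersecting circles — possible
for bootstrap resamples — clamp y to 0 and flag the point degenerate rather
than fail.  Position CIs re-derive the axis (and d) within every resample, so
reference uncertainty propagates into every strain's interval; the price is
that the references' own x-intervals have nonzero width around ±d/2.

## Trafficking model

State: a linear (non-periodic) membrane of `n_bins` bins of 0.1 µm, each
cargo an agent with a forward-only state chain naive → phosphorylated →
ubiquitinated, a bin index, and a trapped flag; a fixed pool of `n_pits`
endocytic pits with ages.  Defaults: 100 initial bins, dt = 0.01 s, 200,000
steps (2000 s ≈ 33 min), p_phos = 5e-5 × multiplier, p_ubiq = 0.01,
p_move = 0.0024, exocytosis 8 events/min, endocytosis at 2× that rate,
two-bin exocytic insertions vs single-bin endocytic removals (rates and sizes
roughly conserve membrane area; the bin count performs an unbiased random
walk around its initial value).

Per step, in order: (1) exocytosis and endocytosis are drawn as independent
Bernoulli events at p = rate × dt (the rates are given; the scheduling law is
a modeling choice, and both events may fire in one step, exo first);
(2) state transitions; (3) diffusion and trapping; (4) pits age.  Per-cargo
Bernoulli trials are realized as a binomial count plus a uniform choice of
which cargo transitions — statistically identical and much cheaper.  A cargo
phosphorylated in a step is not eligible for ubiquitination until the next.

Diffusion: each untrapped cargo moves with total probability p_move; the
direction is drawn from weights `w_side = 1/(1 + occupancy of that neighbor)`
normalized over existing neighbors (end bins offer only the inward option).
Uniform occupancy gives an even split, crowded neighbors are avoided, and the
total move probability stays exactly p_move — so the configured 0.0024 is
interpreted as the total per-step move probability, not per-direction.
Occupancy is evaluated at the start of the sub-step (simultaneous moves).
After moving, any untrapped ubiquitinated cargo in a pit bin becomes trapped;
this covers both a cargo diffusing into a pit and a cargo ubiquitinated while
already inside one.

Exocytosis: the location distribution [Bem1]²×[Exo84] lives on a fixed
signed-µm grid anchored at the membrane midpoint and is re-interpolated onto
the current bins at every event, keeping the polarity site centered as the
membrane grows and shrinks.  The measured Bem1/Exo84 distributions are not
available in portable form, so bell-shaped surrogates stand in (Gaussians of
σ 0.8 and 1.2 µm — the exocyst footprint slightly broader than the polarity
cap; both configurable, and measured two-column profiles can be supplied).
Each event inserts two empty bins at the sampled location, shifting flanking
bins (and pits) outward, and delivers 10 naive cargo uniformly into the new
bins.  Delivery size and the initial load (10 cargo/bin) are not constrained
by measurement; they were chosen so delivery and internalization roughly
balance at steady state.

Endocytosis: the most mature pit is consumed; its bin is removed with all
cargo in it (trapped or not — the membrane patch itself is internalized), and
a replacement pit forms at the pit-free bin with the most ubiquitinated
cargo, ties uniform at random with the run RNG.  Pits start at distinct
uniform-random bins.  If the membrane is at minimum length the event is
skipped with a warning.  Event positions are recorded as signed µm from the
membrane midpoint at event time.

Kymographs of total and ubiquitinated cargo are recorded every 100 steps
(1 s) on a fixed ±10 µm grid to bound memory.  Every run is reproducible from
its config and seed; exposure counters (cargo-steps at risk, transition and
move counts) allow the realized hazards to be compared against the configured
probabilities.

## Synthetic data: what it emulates, what it does not

The generator emulates micrograph-derived line scans at the line-scan level:
a polar-cap polarity bump at a known, optionally rotated perimeter position;
a septin channel drawn from one of six planted class templates placed
relative to the cap; additive zero-mean Gaussian noise clipped at zero
(preserving nonnegativity); per-strain class frequencies, optionally drifting
over timepoints.  Determinism: identical seeds give bit-identical datasets.

It does not emulate optics (PSF, depth attenuation), segmentation error,
perimeter-length variation between cells, within-class shape variability
beyond additive noise, or temporal autocorrelation of a single cell's class
membership.  Passing tests therefore establish that the pipeline's
*operations* are correct (alignment undoes rotation exactly, planted classes
and frequencies are recovered, K selection finds the planted class count
under comparable separations) — not that six classes, or any particular
class shapes, are a property of real septin data.

## Problem sizes

Default verification scales: one full-length simulator run for rate
recovery; 3 replicates × 3 multipliers at full length for the
centralization ordering; 3000 profiles for K-selection; 5000 for frequency
recovery; 10⁶ single-cargo steps for the move-probability estimate; 500
replicate ensembles × 1000 bootstrap draws for coverage; 100 random 5-leaf
fixtures for the average-linkage cross-check.  These sizes put Monte-Carlo
error comfortably inside the asserted tolerances while keeping the whole
suite in a few minutes.

## Known limitations

- The 1-D membrane has no explicit septin agents; endocytic-event locations
  are the model's proxy for where septin structures assemble.
- Percentile bootstrap (not BCa); adequate at the ensemble sizes used.
- The K-selection rule inherits the elbow heuristic's blind spots (documented
  above); K can always be fixed explicitly.
- Usage distances ignore per-timepoint structure; two strains with equal
  overall usage but different time courses are indistinguishable to the
  similarity stage.
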