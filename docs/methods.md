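# Methods

This note documents the models, numerical choices and limitations behind
`towcam`. It is written for users deciding whether the package's defaults
apply to their survey.

## Data model

The sampling unit is the annotated video **frame**: transect id, 1-based
frame index, a taxon → count map, optional per-frame sediment percentages,
and a `usable` flag. Frames that could not be annotated (hardware dropouts,
poor visibility) stay in the sequence but are excluded from all analysis
denominators and from subsample selection, which always operates on the
usable-frame sequence. Annotation files are wide CSV (one row per frame,
one column per taxon, sediment columns prefixed `sed_`), chosen for
portability over any binary format.

Sediment labels are normalized on read to the canonical vocabulary
{clay, silt, sand, gravel, shell}; the synonym table (default
"shells" → shell, "boulders" → gravel) is configurable because field
annotations commonly mix vocabularies. A default species/order/class
taxonomy for all packaged taxa ships with the package; the published survey
grouped its counts into seven classes without enumerating the grouping, so
these are standard assignments and overridable.

The three packaged tables preserve the published survey's numbers *as
printed*, including their internal inconsistencies (a test-set column
summing to 343 where the text says 339 organisms in 13 species while the
column has 14 nonzero entries; 22 nonzero transect taxa against a stated 23
groups; 15 beam-trawl taxa with ≥ 5 individuals against a stated 14). The
package documents these rather than repairing them.

## Diversity

Shannon's H′ = −Σ p log p (0·log 0 ≡ 0) and Hill's N2 = 1/Σ p². The default
logarithm is natural: the source formulas are written without a base, nats
is the common ecology convention, and it makes the Hill ordering
exp(H′) ≥ N2 ≥ 1 hold directly. Zero-count taxa are dropped before forming
proportions. A vector with no organisms yields NaN with a warning rather
than an exception, so empty subsamples propagate through replicate tables.

Pooled ("All") rows of group tables are computed from pooled counts by
default. A mean-of-groups mode exists because published "All" summaries of
this kind are sometimes not reproducible from pooled printed counts (a
catch pooled under 82.6% sand-dollar dominance caps pooled H′ well below
the published overall value in any log base, so that summary was evidently
computed some other way); neither mode is asserted to match such rows.

## Subsampling designs

- **Systematic**: indices {start, start+k, …} ∩ [1, N]; realized size is
  ⌊(N−start)/k⌋+1. Each replicate redraws the start uniformly from [1, k],
  which removes phase bias; over all starts the samples partition the
  frames, so pooled composition is exactly the full-set composition.
- **Random**: n distinct indices, uniform without replacement.
- The default systematic grid is 40 unique integers approximately
  log-spaced over [5, 300], matching the log₁₀ axis on which stabilization
  is judged (the published study used 40 intervals in that range without
  enumerating them). The default random grid is the published one: 36 sizes
  rounded from an even log₁₀ grid between 31 and 1778, endpoints exact.
- Replicates default to 10 per interval/size.

## Sufficiency rules

LOWESS defaults are the classic ones: local linear fits, tricube weights,
span 2/3, no robustness iterations (the smoothing is done by
`statsmodels`' lowess behind the package's interface). The plateau size n\*
converts the smoothed curve to piecewise slopes per decade of sample size
(replicates at the same size are averaged first) and returns 10^x for the
smallest x from which every later slope stays below the tolerance. The
default tolerance is 0.05 diversity units per decade: the published
analysis read its plateau visually, so a numeric rule is required; 0.05 is
small relative to the N2 range of these data (1–4) and is configurable.
Signed (not absolute) slopes are used, so a declining tail counts as
plateaued — the question is whether the estimate is still *rising*.

The CV rule fits ordinary least squares of size-level CV (one CV per size
across replicates, sd/mean) on log₁₀ n and inverts the line for the
smallest integer n with predicted CV ≤ 0.25. The 25% threshold is taken as
a pure configuration constant, as in the source study. If the fitted line
is already below the threshold at the smallest observed size, that size is
returned; if the slope is non-negative the rule returns none.

The final recommendation takes the more conservative (larger) of n\* and
n_CV and converts it to a frame interval ⌊N/max(n\*, n_CV)⌋.

## Survey geometry

Layback L = √(R²−D²) treats the tow cable as a straight line — an
overestimate of the true catenary layback, accepted here as in the source
survey. Position correction applies only to latitude (tows are meridional):
minus L/m° for northward tows, plus for southward, with m° = 111 120 m per
degree of latitude (1852 m × 60; the constant is configurable). Swept area
is width × speed × duration.

## Community structure

Counts are standardized per taxon to mean 0, sample sd 1 (n−1 denominator);
zero-variance columns are dropped with a warning. Ward clustering minimizes
the increase in total within-cluster sum of squares; heights are reported
on that sum-of-squares scale, Δ(A,B) = n_A n_B/(n_A+n_B)·‖c_A−c_B‖². Two
Ward height conventions circulate (the other reports √(2Δ)); the orderings
are identical, and the scipy linkage that performs the merges is converted
to the Δ scale. Ties are resolved deterministically. The cluster count k is
user-specified — the source study chose k = 3 by eye — and no automatic
selection is attempted. Clustering on raw per-transect counts despite
unequal annotation effort mirrors the source workflow; a per-frame-rate
mode is provided for effort-corrected analyses.

Dendrograms export to Newick with branch lengths h_parent − h_child, so
every root-to-leaf path length equals the final merge height.

## Synthetic stream generator

The generator is a first-class module, not a test fixture. Per-frame
organism *arrivals* are negative binomial — Poisson with a Gamma-mixed rate
of mean `organism_rate` and dispersion θ (smaller θ = patchier seafloor;
θ = ∞ is the Poisson limit). Each arrival gets a taxon from a fixed
composition and a persistence drawn uniformly from `persistence_range`,
incrementing that many consecutive frames.

**Calibration.** Given an observed organism total, frame count and occupied
-frame fraction, the rate is total/frames and θ solves
(θ/(θ+rate))^θ = 1 − occupancy by bracketed root finding (residual < 10⁻⁶).
The published transect-level targets (3035 organisms / 4393 frames, 33.3%
occupancy) *require* overdispersion: Poisson arrivals at that rate would
occupy 49.9% of frames. Occupancy targets above the Poisson limit are
rejected with an explanation, since a Gamma mixture can only lower
occupancy. The zero-probability equation describes arrivals, so generated
occupancy matches the target exactly when persistence is one frame — the
correct emulation of interval-subsampled annotation data, and the default.
`expected_occupancy` gives the closed-form occupied fraction for any
persistence range (a product of arrival-pgf evaluations over lags) for
users generating raw-video-like streams.

**Study conditions.** Two stock configurations are used in tests and
examples, chosen once from the published totals:

- *dense / interval-subsampled*: 0.691 arrivals·frame⁻¹, θ = 0.410
  (calibrated), persistence 1 — the seven-transect annotation set;
- *sparse / raw video*: 343 expected organisms over 9155 frames
  (0.0375 arrivals·frame⁻¹), persistence 3–5, Poisson arrivals — the fully
  annotated single-transect test set. Poisson is used here because the
  published occupancy for that stream (27%) is unattainable under *any*
  arrival model at that organism count (343 organisms × ≤ 5 frames each
  can occupy at most 18.7% of 9155 frames), leaving no feasible occupancy
  target to calibrate θ against; this inconsistency is inherited from the
  printed numbers and documented rather than resolved.

**What the generator does not model.** Arrivals are independent between
frames beyond the 3–5-frame persistence window. Real seafloors have
longer-range structure (sand-dollar beds span many metres, i.e. tens of
frames), which inflates the variance of small subsamples. Consequently the
plateau sizes measured on synthetic streams are expected to sit *below*
field-derived ones: repeated runs of the sparse configuration across twenty
seeds gave systematic-design plateaus of 74–286 frames (frozen as the test
envelope), whereas the field study reported stabilization at 316–398
frames. Passing tests therefore demonstrate correct machinery and
calibration, not that any particular real survey stabilizes at a given
size. There is also no between-transect spatial model and no
sediment-conditioned abundance: synthetic sediment profiles are decorative.

Trawl catches are per-station multinomial draws from a composition, with an
optional single-station "jackpot" multiplier emulating a tow through a
dense monospecific bed.

## Problem sizes in the test suite

Tests run the full published design shapes (40 systematic intervals + 36
random sizes × 10 replicates on a 9155-frame stream), law-of-large-numbers
checks at 30–60 k frames, and 20-seed Monte-Carlo envelopes; the whole
suite completes in well under a minute on one CPU. Exhaustive oracles
(all systematic starts; all Ward merge orders) are used at small n where
enumeration is exact.

## Known limitations

- Diversity is the only community metric; no rarefaction/extrapolation
  estimators (Chao, jackknife) and no Hill numbers beyond N2.
- The CV model is linear in log₁₀ n; monotone nonlinear decays are out of
  scope.
- Only north/south tow headings are supported in the layback correction.
- Systematic-sampling variance under serial autocorrelation is not modeled;
  CV envelopes from the generator understate field variance for patchy
  seafloors.
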