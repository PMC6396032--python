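# Methods

This note documents the statistical procedures implemented in
`macrofacets`, the defaults and why they were chosen, the numerical
edge-case policies, and what the synthetic-data generator does and does
not emulate.

## Diversity indices

All indices are computed from presence/absence data with equal species
weights (w = 1/S for a site of richness S).

**Taxonomic richness (TRic)** is the per-site species count.

**Taxonomic distinctness (TDis)** is the presence/absence form Δ⁺: the
mean rank-hierarchy distance over all unordered pairs of species present.
Distances come from a six-rank hierarchy (genus, family, order, subclass,
class, phylum) with equal branch lengths: the distance between two
species is the height of their lowest shared rank, counting unit steps
species → genus → … → phylum → root, and the matrix is rescaled so that
the *maximum realized* distance is 100.  This is the convention of the
standard distinctness tooling in community ecology, and our matrices
reproduce that tool's output exactly on reference tables (frozen in the
test suite).  A consequence worth knowing: congeners sit at 100/7 only
when the table contains a cross-phylum pair; in a single-phylum table the
deepest realized divergence is rescaled to 100 instead.  TDis is
undefined (NaN) for S < 2.  Note that adding a congeneric duplicate of a
present species does not always lower Δ⁺ — twinning an *outlying*
species can raise the mean pairwise distance; the dilution guarantee
holds when the twinned species has at most average mean distance to the
rest, and that is the property the tests assert.

**Functional trait space.**  Species dissimilarity is the Gower
coefficient over four categorical traits (life form, life cycle,
morphology, sexual propagation; simple matching) and one quantitative
trait (adult weight in grams, range-normalized within the supplied
species pool, optionally log-transformed first), averaged with equal
variable weights.  Gower is the de facto metric for mixed trait data and
the documented default of the functional-diversity tooling this analysis
follows.  A zero-range quantitative trait contributes 0 with a warning.
The trait space is the principal coordinates (PCoA) ordination of this
matrix.  Gower matrices on categorical data are generally non-Euclidean,
so a correction is applied before ordination: the default takes the
element-wise square root of the dissimilarities (which makes simple
matching Euclidean and is the default of the cited tooling); the
Cailliez additive constant and no correction are available.  Remaining
negative eigenvalues beyond 1e-6 of the largest raise an error
suggesting the alternative correction.  Retained axes have eigenvalues
above 1e-9 of the largest; coordinates are scaled U√λ, so inter-point
distances reproduce the corrected dissimilarities when all axes are kept.

**Functional indices** on the ordinated space:

* FRic — convex-hull volume of the community in the first `n_axes` axes.
  Default axis policy: `min(3, min_site(S) − 1)`, bounded below by 2, so
  hulls are computable at every site that can have one; sites with
  S ≤ n_axes are undefined.  Degenerate (collinear/coplanar) communities
  get volume 0 with a warning.
* FEve — with equal weights the branch evenness reduces to branch length
  over total MST length; FEve = (Σ min(PEWₗ, 1/(S−1)) − 1/(S−1)) /
  (1 − 1/(S−1)).  Undefined for S < 3, and for communities of
  functionally identical species (zero total tree length).
* FDiv — gravity center G of the convex-hull vertices; with dGᵢ the
  distances of all present species to G, FDiv = (Δd + d̄) / (Δ|d| + d̄).
  Undefined for S < 3 or when every species sits exactly at G.  When the
  hull is degenerate all present species are treated as hull vertices
  (they all lie on the degenerate hull).
* FDis — mean distance to the equal-weight community centroid; 0 for a
  single species.

All four are invariant to species relabeling and to rigid rotation of
the trait space, which the tests verify.

## Spatial eigenvectors (dbMEM / PCNM)

From the planar Euclidean distance matrix of site centroids (users must
supply projected coordinates; the package never touches geographic CRS
logic), the truncation threshold t is the longest edge of the minimum
spanning tree of the complete site graph.  Distances above t are
replaced by 4t — the classic PCNM constant; the multiplier is
configurable.  The truncated matrix is Gower-centered (−½ J D² J) and
eigendecomposed; eigenvectors with eigenvalues above 1e-9 of the largest
are retained, scaled to norm √λ, and ordered by decreasing eigenvalue,
so dbMEM1 carries the broadest spatial pattern.  Scaling only affects
reported loadings — every regression downstream is scale-invariant.
Duplicate centroids are rejected (they make the MST threshold
degenerate).  Retention follows the positive-eigenvalue rule rather than
a Moran-criterion filter.

**Moran's I** uses the standard cross-product form with expectation
−1/(n−1).  The default test permutes the values over sites (seeded;
p = (exceedances + 1)/(n_perm + 1), two-sided around the expectation); a
normal approximation under randomization is available.  Correlograms use
equal-width distance classes over (0, d_max] (default 10) with binary
membership weights, and progressive Bonferroni significance (class k
tested at α/k).  Empty classes are reported as NaN with a warning.

## Modeling

Each diversity index is a univariate response, so redundancy analysis
reduces exactly to OLS with an intercept; the test suite cross-checks
the partition against the reference RDA-based implementation on a frozen
dataset.  Adjusted R² is Ezekiel's 1 − (1 − R²)(n − 1)/(n − p − 1) — the
standard for variation partitioning; negative values (including a
negative shared fraction b) are reported, never clipped.

**Forward selection** implements the double stopping rule: the global
(all-candidate) model must be significant before anything is selected;
then candidates enter greedily by R² gain (ties broken by lowest column
index, deterministic), each entry requiring (i) a permutation p ≤ α for
its marginal contribution and (ii) the growing model's adjusted R² not
to exceed the global model's.  The entry test permutes the residuals of
the current reduced model (Freedman–Lane style), which is exact for the
first step and standard thereafter.  The marginal test is calibrated for
a fixed candidate; the familywise behavior of best-of-m selection is
governed by the global-model gate and the R² ceiling, not by the entry
test itself.

**Variation partitioning** uses the adjusted-R² algebra
(a = adjR²(E∪S) − adjR²(S), etc.) with the union model's degrees of
freedom taken from the *rank* of the combined predictor matrix, so
duplicated predictors across sets do not inflate the penalty.  Marginal
fractions are tested by permuting the response; semipartial fractions
(a, c) by permuting the residuals of the conditioning model.  An empty
selected set contributes adjR² = 0 and is flagged in the output.

**VIF** is 1/(1 − R²ⱼ) per predictor, reported (perfect collinearity as
∞) with a configurable warning threshold of 10; predictors are never
auto-dropped.

## Congruence

The top-percentile set of an index contains the k = max(1, ⌊p·n⌋) sites
with the largest values among sites where the index is defined (for
n = 214 and p = 0.10, k = 21); boundary ties are broken by the original
site-label order, deterministically.  Congruence of a pair is
100·|overlap|/k on the sites where both indices are defined.  The null
draws two independent uniform k-subsets per iteration — the minimal
exchangeable null consistent with unconstrained randomization; permuting
one ranking against a fixed other is distributionally equivalent.  The
analytic overlap expectation k²/n (hypergeometric) is reported beside
the Monte Carlo null mean as a cross-check.  Because the overlap is a
small integer, the randomization test is conservative at small (n, k):
the exact rejection rate at nominal α = 0.05 is ≈ 0.027 at n = 40,
k = 10 and rises toward 0.05 as the atoms get finer; the calibration
test therefore uses n = 500, k = 200, where the exact expected rate is
0.041.

## Synthetic data

The generator emulates the statistical structure the analysis assumes,
with defaults mirroring the emulated study system's dimensions: 214
sites, 469 species (93 submerged, 40 floating-leaved, 25 free-floating,
311 emergent).

* **Coordinates** — uniform scatter on a 100×100 square by default; a
  regular grid and a 5-blob clustered layout are available.
* **Environment** — each continuous predictor is β_s · (combination of
  the first 8 dbMEM eigenvectors with geometrically decaying weights and
  random signs) + (1 − β_s) · N(0, noise_sd), standardized.  Default
  β_s = 0.8: a strongly spatially structured environment, the regime the
  analysis is about.  LANDVAR is the Shannon index of six land-cover
  proportions drawn from a Dirichlet whose concentration varies
  spatially.
* **Species** — life forms fixed by the count mix; the other categorical
  traits, the log-normal adult weight and the niche optima depend
  stochastically on life form, so traits are ecologically structured.
  The taxonomy is random nested grouping with configurable counts per
  rank.
* **Occurrence** — P(species j at site i) = p_max ·
  exp(−(eᵢ − μⱼ)²/(2σⱼ²)) on a composite environmental axis
  e = standardized weighted sum of MAP, MAT and SOLAR (weights 1.0, 0.7,
  0.5 — strong enough that the generative predictors are recoverable by
  forward selection).  Defaults p_max = 0.85 and niche breadth σ = 2
  give mean per-site richness near 60% of the pool, matching the
  high-occupancy character of the emulated system.  Optima center at
  +1.0 on the axis so richness responds monotonically over most of the
  observed range.  Empty sites/species are redrawn up to 10 times, then
  dropped by validation with a logged warning.

All randomness flows from one scenario seed through four named
substreams (coordinates, environment, species, occurrence).

**What recovery tests do and do not show.**  With β_s high, the shared
fraction b dominates the explained variation in richness — the headline
qualitative behavior — and with β_s = 0 the pure-environment fraction a
does; both hold in ≥ 80% of seeded replicates at 100 sites × 150
species.  Forward-selection recovery of the generative predictors
(sensitivity ≥ 0.8, false-selection ≤ 0.2) is tested at moderate
structuring (β_s = 0.4): when the environment is strongly spatially
structured, *every* predictor shares dbMEM structure with the response,
non-generative predictors become genuinely informative spatial proxies,
and a false-selection rate stops being a meaningful error measure.  The
generator emulates gradients and niche filtering only; it has no
mechanistic dispersal (river connectivity, hydrochory kernels), no
sampling-effort heterogeneity, and no trait–phylogeny covariance beyond
the life-form channel, so passing recovery tests demonstrate the
statistical machinery, not fidelity to any particular real region.

## Problem sizes and runtime policy

The test suite exercises oracle equivalence on 1,000 random small
instances per statistic, calibration on 1,000 null replicates × 199
permutations, and recovery on 20 seeds at 100 × 150; the acceptance
script runs the full pipeline at 214 × 469 with 199 permutations.  These
sizes keep a complete run in the minutes range on one CPU while leaving
every Monte Carlo tolerance comfortably wider than the simulation error.

## Known limitations

* Coordinates are treated as planar; supply projected coordinates.
* Only presence/absence index variants are implemented; no
  abundance-weighted versions.
* The rank hierarchy stands in for a phylogeny; no tree input.
* Which environmental variables receive log/sqrt transforms is left to
  configuration (default none) rather than guessed.
* No spatially constrained congruence nulls; the randomization is
  unconstrained by design.
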