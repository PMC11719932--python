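# Methods

## The question the toolkit answers

Particles in a colloidal suspension interact — electrostatically, through
solvent structure, sterically. When they adsorb onto a flat, homogeneous
substrate and are imaged by AFM, the 2D point pattern of their positions
retains a signature of those interactions: non-interacting particles land
as a homogeneous Poisson (CSR) pattern, mutually repulsive particles keep a
minimum distance and produce quasi-periodic (sub-Poisson) patterns with an
exclusion zone in g(r), and attractive or aggregating particles produce
clusters (super-Poisson). `colloid2d` implements the full inference chain
from raw height map to regime verdict, plus the simulators needed to
validate every stage against known ground truth.

The chain assumes the substrate is neutral — free of preferred adsorption
sites — and that the particles are immobilized where they land (or have
equilibrated before drying). If the surface templates the pattern, the
statistics describe the surface, not the solution.

## Detection

Grain marking is a level-set operation: pixels with height above a
threshold are grouped into 8-connected components; each component becomes
one particle with an intensity-weighted centroid (weights are the heights
in excess of the threshold, giving sub-pixel positions), its maximum raw
height, and its footprint area. Options: a least-squares plane subtraction
(off by default — rendered fixtures are flat, and real flattening is
usually done upstream), Gaussian pre-smoothing (off by default), and a
minimum footprint area to reject single-pixel specks.

The default threshold is **0.5 nm** because control scans of bare mica
show no objects above that height: anything taller is a particle, not
noise. Detection is deterministic.

Border-touching components are kept but flagged; discarding them would
bias the density estimate downward, and the pair-correlation edge
corrections already account for the window boundary.

A note on thresholds: the detected component count is *not* globally
monotone in the threshold. Lowering the level grows every footprint and can
merge two nearby blobs into one component, and below ~3 noise standard
deviations the noise floor itself fragments into spurious specks.
Monotonicity holds for isolated bumps, which is how the tests probe it.

## The g(r) estimator

For N points in a window of area A, with pair distances d_ij binned into
annuli of width Δr,

    ĝ(r) = A / (N(N−1)) · Σ_{i≠j} w_ij · 1[d_ij ∈ [r, r+Δr)] / a(r),

with a(r) = π((r+Δr)² − r²). The N(N−1) normalization makes ĝ exactly
unbiased under CSR. Bins are half-open; a distance equal to r_max is
excluded. Edge handling:

- **periodic** — minimum-image distances; exact for patterns generated in
  a periodic box; r_max is capped at half the shorter window side.
- **isotropic** — Ripley weights w_ij = 1/p_i(d_ij), where p_i(d) is the
  fraction of the circle of radius d centred on point i lying inside the
  window, computed in closed form for a rectangle (per-edge exterior arcs
  2·arccos(d_edge/r) minus per-corner overlaps arccos(d_i/r) −
  arcsin(d_j/r)); validated against numerical arc integration.
- **none** — raw annulus areas, for comparison only.

Distances are Euclidean between centroids in the plane; particle heights
never enter. g is never smoothed. The default bin width is
max(pixel size, r_max/200): no finer than the positional resolution, at
most 200 bins.

The **exclusion radius** is read from ĝ by a plateau-relative rule: the
plateau is the mean of g over the top quartile of r; scanning from r = 0,
the first bin where g reaches half the plateau (threshold configurable)
marks the minimum-approach distance, reported as that bin's left edge.
`None` is returned when g is already at level in the first bin (no
exclusion zone, e.g. CSR) or identically zero. The rule is deliberately
scale-free so it works for both protein-sized and nanoparticle-sized
patterns without tuning.

## Quadrat analysis

The window is tiled by the largest k×m grid of equal-area rectangles (near
square preferred) such that the mean count N/(k·m) ≥ 25 — small enough
regions to resolve heterogeneity, large enough expected counts for the χ²
machinery. Region edges are left/top-inclusive with the last row/column
closed, so each particle is counted exactly once and counts sum to N.

Two tests run on the counts:

1. **Pearson χ² goodness of fit** against Poisson(λ̂), λ̂ = mean count.
   Expected frequencies are pooled inward from both tails until ≥ 5; df =
   (pooled bins − 1 − 1), the extra −1 paying for the estimated mean. The
   pattern is "consistent" with Poisson when p > 1 − confidence (default
   confidence 0.95). Measured size of the test at the null: ≈ 5%
   rejections, as it should be.
2. **Index of dispersion**: D = (n_regions − 1)·s²/λ̂ is χ²(n−1) under the
   null; two-sided bounds at the configured confidence split the verdict
   into sub_poisson / poisson / super_poisson.

The density-precision helper returns the Poisson relative standard error
1/√N of a single-region count (10% at 100 particles, 1% at 10,000) — the
reason a single AFM frame with a few thousand objects already pins the
surface density to a percent.

## Simulators

All simulators are pure functions of (config, seed), seeded through
`numpy.random.default_rng`.

- **CSR**: n iid uniform points.
- **Hard core**: sequential random placement (dart throwing / RSA) with a
  cell list; a proposal is accepted only if ≥ R (periodic minimum-image)
  from all accepted points, so the constraint holds *exactly*. If the
  target count is unreachable (the nominal guideline n·πR² < 0.3·A is
  far inside the RSA jamming limit, but arbitrarily dense requests will
  exhaust proposals), the achievable pattern is returned with a warning.
- **Soft repulsive**: Metropolis Monte Carlo of U(d) = 4ε[(σ/d)¹² −
  (σ/d)⁶] + ε_c·e^(−κd)/d, truncated at a cutoff ≤ half the box,
  periodic boundaries, started from CSR (coincident points jittered).
  Monte Carlo rather than molecular dynamics because only the equilibrium
  structure matters for g(r); Yukawa screening rather than bare Coulomb
  keeps the truncation well defined in a periodic box. The step size is
  auto-tuned toward 30–50% acceptance during the first half of the run.
  Temperature is in reduced units (ε/k_B = 1). The `fig1_like` preset
  (400 particles, σ = 250 nm, ε_c = 2000, κ⁻¹ = 250 nm in a 10 µm box)
  produces the canonical repulsive-monolayer phenomenology: g = 0 below
  σ, a first-shell peak g > 1, and sub-Poisson counts.
- **Cluster**: Thomas process — uniform parents, Poisson-distributed
  offspring counts, Gaussian scatter, wrapped periodically so the
  intensity stays homogeneous.

**Renderer**: each particle contributes height·exp(−d²/2σ²) (per-particle
heights if the pattern carries them), accumulated on ±4σ patches, plus iid
Gaussian pixel noise. It emulates flat-substrate AFM frames with compact,
roughly isotropic objects; it does **not** model tip convolution, line
artifacts, drift, or height-dependent footprints, so passing round-trip
tests demonstrates the statistics pipeline, not robustness to instrument
artifacts — real images should be flattened upstream.

## Validation conditions and problem sizes

The test suite and acceptance script use conditions chosen to mirror a
typical analyzed frame (a 10–50 µm window holding 500–2,000 objects, i.e.
≥ 40 quadrats at the default mean-25 rule):

- CSR calibration: 2,000 points in a 10×10 µm periodic window, 50 nm
  bins; mean g beyond 200 nm within [0.95, 1.05] averaged over 20 seeds.
- Regime recovery: 50 seeds per process at N ≈ 2,000. Hard-core uses
  R = 90 nm (exclusion-disc coverage ≈ 0.5 — moderate packing whose
  dispersion index ≈ 0.65 is detectably sub-Poisson at 80 quadrats
  without being trivially jammed); clusters use 40 parents × 50 offspring
  with 200 nm scatter.
- Round trip: 10 rendered frames per process at 20 nm/pixel (500×500
  pixels), 2 nm × 30 nm Gaussian bumps, 0.1 nm noise — protein-like
  contrast at a 6:1 peak-to-threshold ratio. Detection recall/precision
  are scored on the hard-core frames, where bumps are well separated by
  construction; in CSR and clustered frames overlapping bumps merge, which
  is a physical property of level-set detection, not an error, and does
  not flip the regime verdicts.
- The brute-force g(r) oracle is an explicit per-pair double loop sharing
  no code path with the chunked production estimator.

## Numerical choices and degenerate inputs

- Poisson PMF in log space via log-gamma; normalization, mean, and
  variance verified to < 1e−9 at λ up to 100.
- Empty annuli give g = 0, not NaN; patterns with < 2 points return an
  all-zero flagged result rather than raising.
- Quadrat tie-break: a point exactly on an interior region edge belongs to
  the region on its right/below (floor division), the last row/column is
  closed; conservation is exact.
- The χ² GOF needs ≥ 5 regions and ≥ 3 pooled bins; identical counts
  (zero variance) are not an error — the fit simply rejects, which is the
  correct sub-Poisson reading of a degenerate pattern.
- All coordinates and the g(r) pipeline are scale-equivariant: scaling
  positions, window, and bins by a common factor leaves g unchanged
  (property-tested).

## Known limitations

- The isotropic correction's closed form assumes a rectangular window and
  r ≤ half the shorter side; masks or irregular windows are out of scope.
- Quadrat analysis assumes a homogeneous intensity; a density gradient
  (e.g. drying fronts) reads as super-Poisson even without particle
  attraction. Inspect g(r) and the image before trusting the verdict.
- Aggregate morphologies (merged blobs) are detected as single objects;
  cluster-shape analysis is out of scope.
- The soft-repulsive simulator is O(N²) per sweep and intended for
  hundreds of particles, which is ample for generating reference
  structure; hard-core and CSR handle tens of thousands.
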