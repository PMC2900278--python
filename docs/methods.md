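# Methods

## Data model: sparsity about the median

A gene's expression profile x ∈ ℝⁿ across n samples is modelled as a
shared baseline b plus at most k *spikes* — samples where expression
deviates strongly from the gene's median. Subtracting the median leaves
a k-sparse vector. Spikes may be up- or down-regulated; intensities are
nonnegative, so a down-spike's magnitude is bounded by the baseline
(it cannot push expression below zero), which makes large down-spikes
intrinsically harder to resolve than up-spikes.

## Pooling designs

The design Φ ∈ {0,1}^{m×n} assigns each of n samples to exactly d of m
pools; each pool is hybridized on one chip. Φ is the adjacency matrix
of a left-d-regular bipartite graph, and decoding quality rests on its
expansion: every set X of ≤ k samples must touch ≥ (1 − ε)·d·|X|
distinct pools.

- **Construction** (`build_design`): each column is a uniformly random
  d-subset of the m pools, redrawn on collision with an existing
  column, so supports are pairwise distinct. Seeded and reproducible.
  The construction is randomized because no deterministic recipe is
  imposed; any matrix passing certification is equivalent for the
  guarantee, and an externally supplied design file can be used instead
  for exact replication of a particular experiment.
- **Certification** (`verify_expansion`): exhaustive enumeration of all
  subsets up to size k, with a hard budget (default 10⁶ subsets) —
  the function refuses rather than silently sampling. The report
  carries the smallest achievable slack ε and the worst subset.
- **ε default 1/4**: for d = 2, two distinct columns share at most one
  pool, so every pair has ≥ 3 neighbours, i.e. ratio 3/4 — ε = 1/4 is
  the smallest slack a d = 2 design with any overlapping column pair
  can achieve, and it suffices for the single-spike guarantee.
  Configurable.
- **Sizing** (`chips_needed`): m ≈ k·ln(n/k), rounded half away from
  zero. Natural log and this rounding reproduce the canonical worked
  value 23 at (n, k) = (100, 10). The rule ignores noise and is a lower
  bound, not the m of any constructed design.
- `design_for_guarantee` searches m upward and returns the first
  certified (2k, ε) design; for n = 15, k = 1, d = 2 this can be as
  small as m = 6 (any distinct-column d = 2 design expands at ε = 1/4),
  smaller than the 12 chips a conservative experiment might use.

## Forward model and decoder

Pooling is additive in **linear** intensity: y = Φx per gene. Published
expression tables are often log2-transformed, so `DecodeOptions.scale`
declares the input scale and log2 inputs are exponentiated before
pooling arithmetic; decoded matrices are returned in both scales (the
log2 view floors linear values at 2⁻²⁰ since decoded backgrounds can be
exactly zero). Mixing weights default to the unweighted binary matrix;
a row-normalized variant (equal total mRNA mass per chip) is available
via `pool_weights_equal_mass`, the difference being absorbed in
practice by per-chip normalization.

Decoding is basis pursuit, gene by gene:

    minimize ‖z‖₁  subject to  Φz = y,

recast as an LP over split positive/negative parts and solved with
scipy's HiGHS backend (feasibility/optimality tolerance 10⁻⁸ by
default; entries below the tolerance are snapped to zero). Options:

- **δ-relaxation** (`noise_tolerance`): replaces equality with
  Σᵢ|Φz − y|ᵢ ≤ δ for noisy measurements. Default δ = 0 (equality),
  matching the exact-fit formulation.
- **Nonnegativity**: off by default (the program imposes only
  ℓ1-minimality and consistency) but available since intensities are
  physically nonnegative.
- **Ties**: the ℓ1 optimum value is unique; the argmin need not be.
  Correctness is asserted on the optimum value and residual, and the
  solver's vertex choice is accepted.
- **Infeasibility** (possible only when y leaves Φ's column space, e.g.
  a nonzero measurement in an empty pool) is reported in the result
  status, never zero-filled.

### Baseline centering

For a left-d-regular binary Φ and nonnegative x, Σᵢyᵢ = d·Σⱼxⱼ, so
*every* nonnegative feasible z has the same ℓ1 norm: plain basis
pursuit cannot identify a dense baseline-plus-spike profile — only
profiles sparse about zero. Since the data model is sparse about the
median, the decoder offers opt-in centering
(`DecodeOptions.baseline_centering`): estimate the gene's baseline as
the median of yᵢ/(pool size)ᵢ over occupied pools (robust because a
single spike perturbs only d pools), subtract b·Φ1 from y, decode the
now-sparse signed deviation without the nonnegativity constraint, and
add b back (clipping at zero if nonnegativity was requested). The
standalone `estimate_baseline` follows the same median-of-ratios rule
but raises on designs with empty pools; the centered decode path
skips empty pools instead, since a random design can leave a chip
unused and an empty pool carries no information. The simulation
harness enables centering by default; decoding of zero-background
sparse profiles needs no centering and the default remains off.

## Recovery guarantee

If Φ is a (2k, ε)-expander and S indexes the k largest-magnitude
entries of x, then ‖x − x̂‖₁ ≤ C(ε)·‖x − x_S‖₁. Exactly k-sparse
profiles decode exactly; approximately sparse ones with error
proportional to the ℓ1 tail. The constant C(ε) has no closed form
exposed here, so `check_error_bound` takes C as an argument and the
test suite calibrates it empirically: over 500 seeded 2-spike
simulations on a (2, 1/4)-certified design, C is taken as the maximum
observed error/tail ratio and then verified across the same set — a
calibration demonstrating the ratio is finite and stable, not an
independent validation of a theoretical constant. Measurement noise
enters the error the same way tail mass does: more noise, more error,
with no cliff.

## Synthetic-data generator

`SimulationConfig` defaults (all log2 scale, chosen once to resemble
RMA-summarized microarray intensities):

| parameter | default | meaning |
|---|---|---|
| n_samples, n_genes | 15, 500 | experiment shape |
| k_spikes | 1 | spikes per gene |
| baseline_log2_mean, _sd | 8, 2 | per-gene baseline ~ Normal(8, 2) in log2 |
| spike_log2_magnitude | 3 | 8-fold spikes |
| down_spike_fraction | 0.5 | sign of each spike |
| noise_log2_sd | 0.25 | multiplicative noise: entry × 2^N(0, sd) |
| low_intensity_noise_boost | 0 | extra sd below the intensity threshold |
| low_intensity_threshold | 64 | linear intensity below which noise inflates |
| seed | 0 | all stages reproduce bit-identically |

The generator emulates: near-constant profiles with spikes (sparsity
about the median), nonnegative intensities, multiplicative noise whose
relative magnitude can grow at low expression (the threshold field
accompanies the boost because a boost needs a changeover point; 64 ≈ 2⁶
sits below typical baselines). It does **not** emulate probe-level
effects, chip normalization artifacts, spatial defects, or gene–gene
correlation — so passing simulations show the decoder behaves as the
theory predicts under the model's assumptions, not that any particular
real experiment satisfies those assumptions.

`run_experiment` chains simulate → pool → (noise) → decode → score and
reports exact-recovery rate (relative ℓ1 error < 10⁻⁴, a
solver-tolerance-driven convention), mean/median ℓ1 error, and
spike-call precision/recall (call threshold 1.0 log2 unit about the
median — an evaluation convention, recorded in outputs, not a claim
about what "differentially expressed" means).

## Numerical conventions

- Median: lower median for even lengths (deterministic tie rule),
  everywhere a median is taken.
- `sparsity_tail` ties: equal magnitudes resolve to the lowest index.
- Spike calls use log2(x + 1) so zero intensities stay finite.
- Exact-recovery and bound checks use relative tolerances (10⁻⁴
  simulation convention, 10⁻⁶ for guarantee checks) anchored to the
  profile's ℓ1 mass.
- Monte-Carlo sizes: 200 genes per condition for monotonicity checks,
  500 for exact-recovery and bound calibration; enough for stable means
  at these effect sizes while keeping the suite quick.

## Limitations

- Exhaustive expansion certification is exponential in k; the subset
  budget restricts certification to small k (k ≤ 3–4 at n in the
  hundreds). Deterministic expander constructions are out of scope.
- Random designs can waste chips (empty pools) at small m; the
  constructor does not forbid this since certification judges the
  result.
- Baseline centering assumes one shared baseline per gene; profiles
  with drifting baselines violate it and surface as tail error.
- The decoder treats genes independently; correlation-aware or
  group-sparse decoding is not implemented.
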