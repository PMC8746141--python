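# Methods

## Model

The propagation model is a network Fisher–KPP (reaction–diffusion)
equation for seed-competent protein `p`, coupled to a saturating
accumulation law for the tangle marker `q`:

    dp_i/dt = −β Σ_j L_ij p_j + p_i (1 − p_i)
    dq_i/dt = δ p_i (1 − q_i)

Assumptions: transport occurs only along connectome edges; local growth is
logistic with carrying capacity 1; tangle formation is irreversible and
driven by the local seed concentration; time is nondimensionalized so the
growth rate is 1 (no physical-time conversion is attempted). On a connected
graph with β > 0, every `p_i → 1`, so every finite threshold below the
asymptote is eventually crossed.

## Parameters

| parameter | meaning | units | default |
|---|---|---|---|
| β | transmission / growth ratio | dimensionless | swept; worked example uses ln β = 3.897 |
| δ | tangle accumulation rate | 1 / nondimensional time | 1 |
| seed mass | total initial concentration | dimensionless | 0.005, split evenly over the seed region |
| seed region | where pathology starts | — | region I (entorhinal cortex in the packaged config) |
| T | biomarker threshold | fraction of capacity | grid 1%…100% in 1% steps |

Graph-side choices: edge weighting LW (`n`), BW (`n/ℓ`), DW (`n/ℓ²`);
Laplacian family `L_{a,b} = D^{1−a−b} − D^{−a} W D^{−b}` with
`a, b ∈ [0, 1]`, `a + b ≤ 1`. The transport axioms (zero column sums —
mass conservation; zero row sums — Fick's condition) are checked on
row/column sums scaled by `max|L|` with default tolerance 1e-10, so the
verdict is invariant under rescaling the weights. Only `(0, 0)` passes
both on degree-heterogeneous graphs; on equal-strength (regular) graphs
the whole family passes, which the scan reports as such.

## Numerics

- **Integrator.** `scipy.integrate.solve_ivp`, LSODA with an analytic
  Jacobian, dense output enabled, rtol 1e-8 / atol 1e-10. The tolerances
  are deliberately tighter than trajectory accuracy requires: staging is
  decided by races between near-identical crossing times, and the ordering
  must not be an artifact of integration error.
- **Horizon.** Adaptive: integrate to t = 10 and double until every
  region's average has crossed the largest requested threshold, capped at
  t = 1e6. Thresholds uncrossed at the cap are recorded as ∞. A threshold
  of exactly 100% is never reached (the state only approaches 1
  asymptotically), so the default grid's last row is the all-unreached
  pattern; sweeps that need completed patterns should stop at 99%.
- **Crossing localization.** The first stored solver step at or above the
  threshold brackets the crossing; `brentq` on the dense output refines it
  to relative time tolerance 1e-8. Crossings are closed (≥): a region
  whose initial average already meets T crosses at time 0.
- **Clamping.** Solver state is never clamped; reported and averaged
  outputs clip tiny undershoots/overshoots to [0, 1].
- **Ties.** Crossing times equal within 1e-9 (absolute, nondimensional
  time) are flagged as ties and broken by ascending region index. Silent
  tie-breaking is dangerous exactly where braid surfaces are interesting,
  so ties are carried on the pattern object.
- **Unreached regions.** A pattern with unreached regions is a distinct
  identity from any completed pattern (the unreached set participates in
  equality); a surface cell where region V never appears is a different
  observation from one where it appears last.
- **Registry determinism.** Surface cells are scanned ascending in the
  swept parameter, then ascending in threshold; pattern ids are assigned
  after all cells are collected, so parallel execution (joblib) is
  bitwise-identical to serial.
- **Dispersion.** `staging_time_std` uses the population convention
  (divisor J); it is undefined (None) when any region never crossed. On
  few-region fixtures the spread is dominated by the seeded region's early
  crossing, so the sharper per-cell race diagnostic is the minimum
  inter-crossing gap; the test suite uses that gap to verify that ±1%
  perturbations of β flip patterns only where crossings race.

## Regional averaging

Regional averages divide by the region's own node count `N_j` (a true
mean). The seeded region's average at t = 0 therefore equals
`seed_mass / N_1` only when the partition is the singleton layout of the
worked example; in general it is `seed_mass / N_1` by construction of the
initial condition.

## Backbone thresholding

Two filters ship built in. The naive cutoff removes edges with fiber count
below a level and warns when the result disconnects. The disparity filter
keeps edge (i, j) when its closed-form p-value
`α_ij = (1 − w_ij / s_i)^{k_i − 1}` falls below α at *either* endpoint,
and always keeps edges at degree-1 endpoints (the null model is undefined
there); weights default to raw fiber counts (LW). The literature using the
DF abbreviation is not fully consistent about the method's name
("disparity" vs "density" filtering); this package implements the
disparity filter. Doubly stochastic, high-salience-skeleton and
noise-corrected backbones are published external algorithms and are
exposed only as a registry hook (`register_backbone_filter`), not
reimplemented.

Asymmetric input edge lists are symmetrized by averaging the two
directions (the model assumes an undirected network); self-loops are
dropped. Both are reported.

## Synthetic data

The generator provides: the deterministic four-node worked example (its
DW matrix fixed entrywise, fiber counts back-computed as `n = W ℓ²` so LW
and BW variants of the same network are well defined); random geometric
graphs with lognormal fiber counts and uniform 10–120 mm lengths
(heavy-tailed weights and heterogeneous degrees, like tractography
output); d-regular rings with constant weights (the degenerate
equal-strength case); and stars (the extreme hub case for the disparity
filter). These fixtures emulate the degree heterogeneity and weight
skew of real connectomes but none of their spatial organization,
community structure, or hemispheric symmetry — so passing tests establish
correctness of the machinery, not that any particular staging pattern
would be observed on human connectome data (which requires restricted
HCP/ADNI inputs and is out of scope). Problem sizes in the test and
acceptance runs (10–30 nodes, 151-point parameter grids, 100 random
fixtures) were chosen so each check isolates one property at full solver
tolerance.

## Known limitations

- No clearance term, alternative growth laws, or directed transport.
- The Fick condition generalization to regions of unequal volumes is not
  implemented.
- The worked example's parameter sweep range for the braid surface is this
  package's choice (ln β ∈ [−5, 10] for the fixture; the CLI defaults to
  [−10, 2]); the fixture's two-pattern repertoire is insensitive to it.
- Crossing detection scans stored solver steps for the first bracketing
  interval; a crossing that rises above and falls back below a threshold
  entirely inside one accepted step would be missed. At rtol 1e-8 the
  accepted steps are dense enough that the dense-sampling oracle test
  (10⁵-point grid over 100 random fixtures) finds no such case.
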