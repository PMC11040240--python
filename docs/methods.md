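# Methods

## Dispersal model and its assumptions

Post-sunset movement is modelled as isotropic diffusion on an unbounded
plane: all bats start the night at the roost (a point source), and the
population density at time `t` is the Gaussian heat kernel with variance
`2Dt` per axis. The assumptions this buys, and their cost:

* **Isotropy and homogeneity.** `D` is a single constant; hedgerows, roads,
  rivers and other landscape structure that channel real bat movement are
  ignored. Detectors sitting on flight corridors will record more passes
  than the model expects, which biases the estimate toward them.
* **Fixed window.** Only the first 90 minutes after sunset are modelled
  (`T = 5400 s`); after that the population begins returning to the roost
  and the diffusive description breaks down. Input counts must already be
  restricted to this window.
* **One roost.** The source is a single point. If a second roost contributes
  calls, the surface will be pulled between them.
* **Colony-size independence.** Only call *proportions* are compared, so the
  number of bats cancels and need not be known.

## Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| `D` | 80 | m²/s | diffusion coefficient (search default, from independent radio-tracking MSD fits for greater horseshoe bats) |
| `T` | 5400 | s | post-sunset integration horizon (90 min of diffusive movement) |
| `detector_radius` | 15 | m | acoustic footprint radius; species- and habitat-dependent (10–30 m is typical, horseshoe bats at the low end) |
| `time_steps` | 501 | – | Simpson nodes on [0, T] |
| `radial_nodes × angular_nodes` | 16 × 32 | – | disk quadrature for the exact detection integral |
| grid | 500 × 500 | cells | evaluation grid over the detector extent (tests and examples use 100 × 100) |
| `exponent` | 2 | – | mismatch exponent in ρ; 2 emphasises the busy detectors nearest the roost (1 and 3 are supported) |

The simulator defaults to `D = 81.7 m²/s` — deliberately *not* the search
default — so that validation never hands the estimator the exact generating
parameter.

## Detection probability: exact and approximate

The exact detection probability is the kernel integrated over the detector
disk, computed with a tensor polar rule (Gauss–Legendre in radius with the
Jacobian folded into the weights, uniform in angle). It is validated against
the centred-disk closed form `1 − exp(−r²/4Dt)` (agreement to 1e−10), against
adaptive 2-D quadrature, and against Monte-Carlo sampling of the Gaussian.

Because the kernel is nearly constant across a 15 m disk, the disk integral
is approximated by the kernel value at the detector centre times the disk
area, `P̃ = r²/(4Dt)·exp(−d²/4Dt)`, clamped to [0, 1] since the unclamped
expression diverges as `t → 0` at `d = 0`. This clamp is the package's
choice; the approximation itself is only derived for detectors away from the
roost, and the clamp keeps grid cells at or near detectors finite.

Numerical facts worth knowing about the approximation, all established by
the test suite:

* the absolute error |P − P̃| at fixed `t` decays away from the roost, but
  not strictly monotonically: the signed error crosses zero at
  `d = √(4Dt)` (≈ 1314 m at `t = T`), where the disk-average correction —
  proportional to the kernel's Laplacian — changes sign. The decay holds as
  an envelope (every error beyond 50 m is below the 50 m error).
* relative error is below 1e−3 at 1 km and the two expected-proportion
  vectors agree to ~3e−4 componentwise for all detectors farther than
  ~100 m from the candidate roost.
* the single place the approximation is materially wrong is a detector
  *at* the candidate roost: there the clamped kernel overstates the expected
  passes by a few percent, worth about 1.2e−3 in absolute proportion terms
  on a 30-detector transect. Since a grid scan evaluates every cell,
  including cells on top of detectors, this is a known, bounded artefact of
  approx mode; `mode="exact"` is available when it matters.

## Time integration

`E_i` has no elementary antiderivative (the integrand behaves like
`e^{−a/t}/t`), so composite Simpson's rule on a uniform grid of 501 nodes is
used in both modes. The `t = 0` endpoint is set to the integrand's analytic
limit: 0 for any detector away from the roost, 1 for a detector centred on
it. Convergence, not a node count, is the contract: doubling the nodes
changes `E_i` by under 0.1% for `d ≥ 200 m` (and under 1% at `d = 100 m`,
where the kernel's arrival spike near `t = 0` is hardest to resolve).

## The ρ surface

ρ is evaluated at **cell centres** of an `n_x × n_y` grid spanning the
detector bounding box (centres make the area statistics exact cell-count
multiples). Key choices:

* **Normalisation is grid-relative.** The denominator is the maximum raw
  squared error over the evaluated cells, so `max(ρ) = 1` exactly but ρ
  values — including `ρ_c`, the value at a known roost — change if the grid
  extent changes. Search-area percentages are likewise relative to the
  mapped area.
* **Argmin ties** break to the first cell in row-major order (north-to-south,
  west-to-east) and are logged.
* **`ρ_c` is read from the cell containing the roost**, without
  interpolation, matching the cell-count basis of the area statistics.
* Cells are independent; any evaluation order gives a bit-identical surface
  (asserted in the tests).
* A degenerate detector extent (all detectors collinear) is widened to half
  the other axis' span so a grid always exists.
* Zero-call detectors are retained with `C_i = 0`: silence is informative.
  Detectors with zero active nights are dropped.

The centre of calls `CC = Σ C_i X_i` is exact and instantaneous but is a
convex combination of detector positions, so it cannot indicate a roost
outside the array. The separation |z_p − CC| doubles as a confidence
heuristic: under 500 m is flagged `high`, under 1000 m `moderate`, beyond
that `low` (configurable; when the two estimators disagree by a kilometre
the point prediction is usually poor even though the surface still ranks
search areas usefully).

## The simulator

Agents perform planar Brownian motion, `x ← x + √(2DΔt)·ξ` per axis with
`Δt = 1 s` by default. For pure diffusion this scheme is *exact in
distribution* at the step times, so `Δt` only affects how finely disk
crossings are resolved (and the far-field checks deliberately use coarse
steps). A detector records one **pass** per entry event — an agent moving
from outside to inside its disk — with a 30 s refractory period per
agent–detector pair so that boundary jitter is not double-counted; the
refractory window is configurable, including 0. The exact pass-counting rule
of real acoustic hardware differs between devices; entry events with a short
refractory are a reasonable stand-in for "bat pass" semantics and the
Spearman agreement between simulated counts and the deterministic
expectations exceeds 0.9 on random layouts.

Every night is seeded by the pair (scenario seed, night index), so nights
are independently reproducible and whole surveys are bit-identical across
runs and platforms.

Detector dropout is modelled geometrically: each detector survives each
night with probability `p` and stays silent after its first failure;
detectors that fail before night one are excluded downstream by survey
loading, mirroring what happens to real detectors that never power up.

**What the simulator does and does not emulate.** It reproduces the
diffusive null model exactly — which is the point: it validates the
estimator's machinery (grid scan, normalisation, search statistics) under
conditions where the truth is known. It does not contain landscape
heterogeneity, corridor-following, male bats roosting separately, weather
nights, multiple roosts, or the return-to-roost phase. Passing the recovery
tests therefore demonstrates correctness of the method, not field accuracy:
on real surveys the dominant errors come precisely from the un-modelled
landscape effects.

## Validation problem sizes

The recovery experiments use a 20-detector ring of 3 km extent, 600 agents
per night for 5 nights, a 100 × 100 grid, and 10 independent seeds — a scale
at which the whole validation runs in minutes on one core while keeping
per-survey counts (~2000 passes) in the range of a strong field survey.
With the roost inside the array the grid scan recovers it to well under 500 m
(typically one or two cells) and beats the centre of calls on average; with
the roost 1 km outside the array and the grid padded 3 km, the centre of
calls stays trapped in the detector hull while the ρ argmin tracks the true
roost.

## Known limitations

* ρ values are only comparable between runs that used the same grid extent.
* approx mode's clamp region (cells within ~100 m of a detector placed at
  the candidate roost) carries a small systematic error; use exact mode for
  final refinement if the argmin lands on a detector.
* The confidence heuristic thresholds are calibrated to horseshoe-bat
  survey scales (kilometres); other species/geometries may need different
  cut-offs.
* No multi-roost support: a second source produces a misleading single-roost
  surface rather than an error.
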