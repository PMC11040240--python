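# roostfinder

Estimate the location of a bat roost from static acoustic detector surveys.

Finding roosts — especially summer maternity roosts — is one of the most
labour-intensive tasks in bat conservation. `roostfinder` turns a passive
acoustic survey (an array of ultrasound detectors, each reporting how many
bat passes it recorded in the first 90 minutes after sunset) into:

* a **likelihood-style error surface** ρ over the landscape, whose low
  values flag where the roost is likely to be;
* two **point estimates** — the surface minimum `z_p` and the *centre of
  calls* `CC` (call-weighted mean detector position);
* **search-effort statistics**: how much area must be searched, in order of
  increasing ρ, before the roost is reached.

It also ships a stochastic agent-based simulator of dispersing bats, used to
generate synthetic surveys with known ground truth for validation.

## The model

Bats are assumed to leave the roost `z = (z_x, z_y)` at sunset and disperse
diffusively, so the position density at time `t` is the 2-D heat kernel

    φ(x, y; z, t) = 1/(4πDt) · exp(−((x−z_x)² + (y−z_y)²) / (4Dt)),

with diffusion coefficient `D ≈ 80 m²/s` for greater horseshoe bats (fitted
independently from radio-tracking mean-squared-displacement data). A detector
at `X_i` with circular footprint `Ω_i` of radius `r ≈ 15 m` detects a bat with
probability `P_i(z, t) = ∫_{Ω_i} φ dA`, well approximated away from the roost
by the algebraic kernel

    P̃_i(z, t) = r²/(4Dt) · exp(−|X_i − z|² / (4Dt)),

clamped to [0, 1]. Integrating over the 90-minute window `[0, T]` by
Simpson's rule gives expected pass counts `E_i(z)`, and the colony size
cancels in the expected proportions `F̃_i(z) = E_i / Σ_j E_j`. These are
compared with the observed call proportions `C_i = c_i / Σ_j c_j` (where
`c_i` is detector `i`'s calls per active night) via

    ρ(z) = Σ_i (F̃_i(z) − C_i)² / max_z' Σ_i (F̃_i(z') − C_i)²,

evaluated at every cell centre of a grid spanning the detector extent. The
argmin of ρ is the point prediction `z_p`; the whole surface ranks the
landscape into optimal search regions. The centre of calls `CC = Σ_i C_i X_i`
is a cheap companion estimate, but being a convex combination of detector
positions it can never leave the detector hull — the ρ surface has no such
restriction, which matters when the roost lies outside the surveyed area.

## Worked example

Simulate a five-night survey of 600 diffusing bats around a 20-detector ring
(3 km extent), with the roost at (300, 200) m, then recover it:

```python
import numpy as np
from roostfinder import RoostModel, SimScenario, simulate_survey

theta = 2 * np.pi * np.arange(20) / 20
detectors = 1500 * np.stack([np.cos(theta), np.sin(theta)], axis=1)
scenario = SimScenario(roost=(300.0, 200.0), detector_positions=detectors,
                       n_agents=600, n_nights=5, seed=1)
survey, _ = simulate_survey(scenario)

results = RoostModel(survey, n_x=100, n_y=100).fit()
print(results.summary())
```

```
Roost location estimate (diffusion grid scan)
=====================================================
detectors: 20   grid: 100 x 100   mapped area: 9.00 km^2
D = 80 m^2/s   T = 5400 s   r = 15 m
-----------------------------------------------------
z_p (argmin rho)     : (285.0, 225.0)
centre of calls (CC) : (560.1, 417.7)
|z_p - CC|           : 0.34 km (confidence: high)
|z_R - z_p|          : 0.03 km
|z_R - CC|           : 0.34 km
rho_c (rho at roost) : 0.00
area with rho <= rho_c: 0.01 km^2 (0.07% of mapped area)
-----------------------------------------------------
percentage of mapped area below rho thresholds:
  rho <= 0.1 :  10.16%  (0.91 km^2)
  rho <= 0.2 :  22.50%  (2.02 km^2)
  rho <= 0.3 :  38.19%  (3.44 km^2)
```

The grid-scan estimate lands 30 m from the true roost (one grid cell), while
the centre of calls is 340 m off — and a searcher expanding outward from
min(ρ) would cover only 0.07% of the mapped area before reaching the roost.
`results.plot()` draws the ρ heatmap with contours and all three markers;
`results.save("outdir/")` writes the surface as CSV and the summary as JSON.

The same pipeline is available from the shell:

```sh
roostfinder simulate --scenario scenario.yaml --out simdir/
roostfinder estimate --survey simdir/survey.csv --roost 300,200 \
    --grid 100 --out estdir/
roostfinder validate-approx          # exact vs algebraic kernel report
```

Surveys are plain CSV (`id,easting,northing,nights_active,total_calls`) in
planar metric coordinates (e.g. UK Ordnance Survey eastings/northings);
detectors that failed part-way through a survey are handled by per-detector
night averaging, and detectors that never ran are dropped.

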