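# Methods

## The model

`fillfrac` rests on a preload-recruitable stroke-work (PRSW) description of
left-ventricular function: stroke work is linear in preload,

    SW = M_W · (EDV − V_W),

with slope `M_W` (a contractility index, work per volume) and volume-axis
intercept `V_W`, the dead-space or absolute minimum volume (AMV) — the cavity
volume below which the ventricle can perform no work. Writing SW = MAP·SV and
dividing by EDV gives the three-factor decomposition

    EF = FF · M_W / MAP,      FF = (EDV − AMV) / EDV,

so the ejection fraction separates exactly into a preload factor (the filling
fraction FF, which is also EF's ceiling), a contractility factor and an
afterload factor. FF is dimensionless and BSA-indexing cancels in it.

Classically V_W requires preload manipulation and extrapolation. The package's
core is a single-beat estimator of AMV from one echocardiographic beat:

1. **Cubic law.** For an axis-symmetric ellipsoidal shell whose axial motion
   is proportional to its hoop motion, cavity volume is linear in the cube of
   the mid-wall perimeter, `LVV = a·PMW³ − b`, with `b` the muscle volume
   inside the mid-wall surface. `a` and `b` are fitted exactly through the
   measured ED and ES states (two-point interpolation), capturing
   patient-specific size and motion without specifying the shape factors.
   For a hemispherical cavity the coefficient has the closed form
   `a = 1/(12π²) ≈ 0.008443`.
2. **Stress pathway to PMW_AM.** End-systolic myocyte stress is taken linear
   in mid-wall stretch with x-intercept at stretch 1:
   `ESS = G_C · M_N · (λ_ES − 1)`. With normal contractility (`G_C = 1`),
   λ_ES ≈ 1.12 at ESS ≈ 60 g/cm², fixing the normal slope `M_N ≈ 500 g/cm²`.
   The gain is `G_C = C₁·Z_C + sqrt((C₁·Z_C)² + 1)` (reciprocal-symmetric,
   1 at Z_C = 0), with the contractility Z-score taken from the V_CFC-vs-ESS
   population relation `Z_C = (V_CFC + 0.0044·ESS − 1.23)/0.06`. Inverting
   gives `λ_ES = 1 + ESS/(G_C·M_N)` and `PMW_AM = PMW_ES / λ_ES`.
3. **AMV.** Evaluate the fitted cubic at PMW_AM: `AMV = a·PMW_AM³ − b`, then
   `FF = (EDV − AMV)/EDV` and, with MAP, `M_W = EF·MAP/FF`.

### Parameters that matter

| parameter | meaning | default | rationale |
|---|---|---|---|
| `M_N` | normal stress–stretch slope | 500 g/cm² | 60 g/cm² / 0.12 |
| `C_1` | gain-relation slope | 0.2 | population-level estimate; acknowledged as a gross approximation, hence configurable |
| mmHg→g/cm² | pressure conversion | 1.35951 | mercury density 13.5951 g/cm³ × 0.1 cm |

ESS is consumed in g/cm², lengths in cm, volumes in mL. Pressures carry an
explicit unit tag (`mmHg` or `g/cm2`); mixing tags raises an error rather
than converting silently, since M_W/MAP is only meaningful in common units.

## The synthetic-heart generator

The verification cohort models the LV as a truncated prolate-ellipsoid shell
with uniform radial wall thickness. With minor semi-axis `B` (half of LVID),
major semi-axis `A = k·B` and truncation ratio `L` (shell height `T = A(1+L)`;
`L=0` half shell, `L=1` full ellipsoid):

    LVV = (2/3)·π·A·B²·(1 + L + L² − L³)
    V_M = (2/3)·π·A·H·(1 + L + L² − L³)·(H + 2B)
    PMW = π·(2B + H)

`V_M` is algebraically the cavity of the outer surface (semi-axes `A`, `B+H`)
minus the inner cavity — i.e. "uniform thickness" is radial-only. Note the
truncation polynomial is a smooth shape factor, not the literal
solid-of-revolution integral of a spherically-capped ellipsoid: the two agree
exactly at `L = 0` and `L = 1` and within a few percent between; the
polynomial is the model.

Each heart keeps `k`, `L` and `V_M` constant (incompressible myocardium,
constant shape) and is inflated from its fully contracted AM state by
prescribing the mid-wall stretch λ = PMW/PMW_AM. Because `H + 2B = PMW/π` is
then fixed, conservation of `V_M = C·B·H·(H+2B)` (with
`C = (2/3)πk(1+L+L²−L³)`) is a quadratic in `B`, solved in closed form; of
the two roots (`B` and `H/2` mirror each other) we always take the larger,
i.e. enforce `H ≤ 2B`, which holds throughout the sampled ranges and is
preserved as inflation raises `B` and lowers `H`. No iterative solver is
needed; a bracketed bisection solver exists in the test suite purely as an
independent oracle.

### Study conditions

The cohort defaults are the verification conditions: 10,000 hearts, all six
parameters drawn independently and uniformly from

    LVID_AM ∈ [2.6, 4.6] cm   H_AM ∈ [1.0, 2.0] cm   k ∈ [1.0, 2.0]
    L ∈ [0, 0.375]            λ_ES ∈ [1.06, 1.18]    λ_ED ∈ [1.24, 1.36]

(the `L` upper bound is configurable up to 0.75). The RNG is numpy's
`default_rng` (PCG64); the default seed is 42 and every exported table
records the seed in a `#`-comment header. Two estimator modes exist:
`true_pmw_am` evaluates the fitted cubic at the heart's known PMW_AM,
isolating the cubic-law extrapolation; `ess_pathway` synthesizes
`ESS = G_C·M_N·(λ_ES−1)` and recovers PMW_AM through the stress relation —
with the same gain the inversion is exact and the modes agree to floating
precision, which the tests assert at 1e−9.

### What the generator does and does not emulate

It reproduces the geometric diversity of the verification experiment — sizes,
wall thicknesses, elongations, truncations and contraction amplitudes — under
exact incompressibility and exact shape constancy. It does not emulate
measurement noise, image-plane obliquity, regional heterogeneity, pressure
dynamics or correlations between parameters (deliberately sampled
independently). Passing cohort tests therefore demonstrates the estimator's
mathematical fidelity to the shell model, not its robustness to clinical
measurement error.

## Verification results and frozen bounds

On the reference cohort (n = 10,000, seed 42) the estimator is tightly but
not perfectly matched to the truth: the cubic law is exact only in the
thin-wall limit, and thick-walled small hearts are overestimated. Measured
once on the reference run and frozen as regression bounds:

- median |relative error| 0.0396 (bound < 0.05); max 0.3305 (bound < 0.35);
- OLS of V_W on AMV: slope 0.9944 (bound 0.97–1.02), R² 0.99690
  (bound > 0.995);
- every per-heart (PMW³, LVV) inflation trajectory has R² > 0.99
  (minimum observed 0.99907);
- the estimate never exceeds ESV (PMW_AM < PMW_ES and a > 0).

The full cohort runs in about a second on one CPU, so the default problem
size is used everywhere, including the acceptance tests.

## Numerical choices and edge cases

- Wall-volume conservation is asserted at 1e−9 relative, perimeter exactness
  and state identities at 1e−12; λ = 1 returns the AM state object itself.
- A degenerate beat (ED and ES perimeters equal to within 1e−9 relative on
  the cubes) raises an error instead of producing infinities.
- Negative AMV or AMV above ESV is returned raw with a diagnostic flag
  (`NEGATIVE_AMV`, `AMV_ABOVE_ESV`), never clamped: the estimate is a
  measurement and downstream users decide.
- V_CFC is computed as `(PMW_ED − PMW_ES)/PMW_ED/RR^(1/3)` from the beat by
  default; an override field accepts literature values.
- CSV output uses 6 significant digits; JSON summaries keep full precision.

## Known limitations

- **V_CFC conventions.** The chain defines V_CFC as fractional mid-wall
  shortening divided by ∛RR, which for real beats has magnitude ~0.15–0.2
  s⁻¹, whereas the Z-score's normal line (intercept 1.23 s⁻¹, SD 0.06 s⁻¹)
  was established for the conventional ejection-time-normalized V_CFC of
  magnitude ~1 s⁻¹. Feeding the perimeter-derived value into the Z-score
  therefore yields extreme negative scores; supply an ejection-time-based
  value through `vcfc_override` (the `vcfc_s1` CSV column) when using the
  contractility pathway on clinical data. The two-point cubic fit and the
  true-perimeter verification mode are unaffected.
- Because ESS enters the Z-score (+0.0044·ESS) as well as the stretch law,
  the inferred gain rises with stress and AMV is *not* globally monotone in
  ESS at fixed V_CFC; it is monotone at fixed contractility gain. This is a
  property of the published chain, not an implementation artifact.
- The EF decomposition inherits the PRSW assumption; departures from linear
  PRSW make EF nonlinear in FF.
- The model is static (three states), axisymmetric and regionally
  homogeneous; no pressure–volume mechanics are simulated and no ESPVR-based
  dead-space estimate is attempted.
- The half-sphere cubic coefficient is reported in the source literature as
  0.00845 while the closed form gives 0.008443; tests accept the printed
  value at 0.2% relative.
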