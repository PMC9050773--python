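# Methods

## Constitutive models

The package models the uniaxial stress–strain response of collagen-fiber
tissues (tendon, ligament) as two regimes separated by a transition
(critical) strain ε_c: a *heel* region in which crimped/twisted collagen
structures straighten, and a *linear* region in which the collagen backbones
stretch. Stress is engineering stress in MPa, strain is dimensionless
engineering strain; there is no unit-conversion layer, and viscoelasticity,
hysteresis, rate dependence and the failure region are out of scope.

**Piecewise model** (five parameters):

    σ(ε) = k₁ ε^{n+1}          for ε < ε_c
    σ(ε) = E (ε − ε_th)        for ε ≥ ε_c

k₁ (MPa) and n (dimensionless, exponent stored as the *offset* n so the
evaluator raises strain to n+1) describe the heel power law; E (MPa) is the
linear-region modulus; ε_th is the strain-axis intercept of the extrapolated
linear region (the threshold strain). ε_th exists to make the relation
continuous at ε_c — it is exactly continuous when
ε_th = ε_c − k₁ ε_c^{n+1}/E — but fitted or rounded parameter sets are
generally only approximately continuous, so the *continuity gap*
k₁ε_c^{n+1} − E(ε_c − ε_th) is always reported and both a free 5-parameter
fit (default) and a constrained 4-parameter fit (ε_th eliminated) are
offered.

Formally both switching factors are Heaviside steps, which under the strict
H(0)=0 convention would zero the stress at ε = ε_c exactly; the evaluator
therefore assigns the boundary sample to the linear branch by explicit
logic (heel on [0, ε_c), linear on [ε_c, ∞)), consistent with ε_c being the
strain *above which* the fibers are fully stretched. ε^{n+1} at ε = 0 is
defined as its limit, 0.

**Combined model** (four parameters): σ = k₁ε^{n+1} + H(ε−ε_c)·E·(ε−ε_c).
The power-law term stays active at all strains, so the tangent modulus above
ε_c is k₁(n+1)ε^n + E, strictly greater than E: the combined model's fitted
E is *not* the linear-region modulus. The package exposes the analytic
slope (`eval_combined_slope`) so this can be checked numerically; fitting
both models to the same data quantifies the understatement.

**Bilinear model**: two straight lines, switching at their intersection
strain ε_c = (b_heel − b_lin)/(E − E_heel). Parallel lines leave ε_c
undefined and are rejected (with a relative slope tolerance of 1e-8, since
two sub-fits of data on one global line agree only to floating-point error).

`critical_strain_from_ratio(a, b) = a/b − 1` is a small utility for the
helical-spring estimate of ε_c from the ratio of the fully-stretched to the
linear-region modulus; the full helical-spring model itself is not
implemented, since only those two scalars feed the comparison.

## Parameter identification

All fitters minimize the sum of squared stress residuals (ordinary least
squares; noise is assumed additive on stress with exact strains). The
breakpoint makes the problem non-smooth, so a two-stage *profiled
breakpoint* strategy is used:

1. **Profile stage.** Candidate ε_c values (default 101, evenly spaced over
   the 5th–95th percentile of the observed strains) are mapped to the
   splits of the sample they induce; duplicates are merged and splits
   leaving fewer than `min_points_per_branch` (default 3) samples on either
   side are discarded. For the piecewise model each split gets a heel
   power-law fit (log–log OLS initializer, slope = n+1, intercept = log k₁,
   refined by bounded least squares in stress space) and a linear-region OLS
   line (E from the slope, ε_th = −intercept/slope); for the bilinear model,
   an OLS line on each side. The split with the smallest total SSR wins,
   ties broken toward smaller ε_c. A hill-climb over neighbouring split
   indices then runs until no neighbour improves, which makes the selected
   split identical to an exhaustive enumeration of all admissible splits
   whenever the candidate grid reaches the best split's basin — this is
   asserted against a brute-force oracle in the tests — and heals candidate
   grids coarser than the sample spacing.
2. **Refinement stage.** Bounded trust-region least squares
   (`scipy.optimize.least_squares`, TRF, `x_scale="jac"`, tolerances
   `refine_tol`, default 1e-10) polishes the smooth parameters from the
   profile solution. Bounds: k₁ ∈ (0, 1e7] MPa, n ∈ (0, 10], E ∈ (0, 1e5]
   MPa, ε_th ∈ [0, ε_c], ε_c within the observed strain range. If
   refinement fails to improve the profile objective, the profile solution
   is kept and `converged=False` reported.

No random starts are used; a fit is a deterministic function of
(curve, options). The `seed` option is reserved for an optional multi-start
mode and is never consumed by the default path.

**Identifiability of ε_c.** For the free piecewise fit the SSR is constant
in ε_c between two adjacent strain samples (ε_c only assigns samples to
branches), so ε_c is identifiable only up to that interval; the reported
value is the interval midpoint. The alternative — the intersection of the
two fitted branches — was rejected as the default because it inherits the
bias of any continuity gap in the underlying material response. With
`enforce_continuity=True`, ε_th is eliminated and ε_c becomes a smooth
parameter refined continuously within the split interval. In the combined
model ε_c enters the residuals continuously everywhere and is refined
jointly; its profile stage eliminates (k₁, E) exactly by non-negative least
squares and profiles n by a bounded scalar search (variable projection).

**Goodness of fit.** The default R² is the standard coefficient of
determination 1 − SS_res/SS_tot. The regression-sum-of-squares variant
SS_reg/SS_tot is also exposed (`r_squared(..., kind="regression")`); the two
coincide for OLS linear fits with intercept but not for nonlinear fits.
Reports state the standard definition was used.

## Synthetic data

`generate_curve` forward-evaluates any model on a strain grid and optionally
adds zero-mean Gaussian noise to stress (absolute sd in MPa, or relative to
the maximum noiseless stress), seeded through `numpy.random.default_rng` so
curves are reproducible. The default validation protocol is 200 uniform
points on (0, 0.06] for the tendon parameter set and (0, 0.08] for the
ligament set (whose linear region extends to higher strain), giving ≥ 30
points on each branch. These sizes keep every fit under ~2 s on one CPU
while leaving the breakpoint localized to ±half the sample spacing.

What the generator does *not* emulate: strain measurement error, serially
correlated or heteroscedastic noise, preconditioning/hysteresis loops,
specimen-to-specimen variability, and the failure region. Passing the
recovery tests therefore shows the estimator is correct and well-behaved
under idealized tensile-test conditions, not that real experimental curves
will yield parameters of comparable accuracy.

## Known limitations

- Under realistic noise the heel parameters are intrinsically poorly
  determined on a uniform strain grid: (log k₁, n) are nearly collinear, and
  the Cramér–Rao bound for the heel sub-fit with stress noise at 1% of the
  maximum stress puts the *floor* of the median relative error of k₁ near
  25% (n near 4%), while E, ε_th and ε_c remain well determined. The
  Monte-Carlo recovery test reports this honestly (it currently fails its
  5% bound for k₁ and marginally for n, at the estimator's information
  floor). Log-spaced grids concentrate points in the heel and improve the
  conditioning.
- Uncertainty quantification (bootstrap, profile confidence intervals) and
  weighted least squares are not provided.
- CSV line numbers in reader diagnostics count data rows; with interleaved
  comment lines they can be offset from physical file lines.
- The `--plot` pathway is intentionally absent; plotting is left to the
  caller (curves are plain arrays / CSV).
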