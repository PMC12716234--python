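# Methods

## Physical model and scope

A GUV in an RT-DC channel is a fluid-filled, freely-shearable elastic
surface: the lipid bilayer has no shear modulus, its bending rigidity
κ ~ 10⁻¹⁹ N·m is irrelevant at RT-DC stresses (η·γ̇·r³/κ > 10⁵), and the
stationary bullet shape is therefore controlled by a single parameter, the
area expansion modulus *K* (N/m). The quasi-stationary state depends on the
channel only through the dimensionless group K̂ = K·L²/(ηQ), and on the
vesicle through the relative projected area Â = A/L². All calibrated
relations in this package are functions of (K̂, Â, D) alone; dimensional
moduli transfer between setups with the factor
(η·Q·L_from²)/(η_from·Q_from·L_to²)·(…), implemented in
`scaling.rescale_K`/`rescale_area`, and every estimator is exactly
equivariant under that transformation (tested to 10⁻⁹).

The phase-field simulations that produced the calibration constants are out
of scope; the constants ship as data. So are membrane rupture, shear-thinning
rheology models (effective viscosities enter via a lookup table for the
standard MC-PBS buffer, or explicitly), and image segmentation.

## The calibrated laws and their transcription

Direct surface: K̂ = Γ·D^(−β·Â^α)·Â^(−δ) with α = 0.5, β = 2.16, δ = 1.
Slope law: K̂ = â·s^(−b) with s = dD/dÂ and b = 1.75.

The published prefactors are γ ≈ 3.40·10⁻⁴ and a ≈ 0.0015. Treated as
dimensionless they are inconsistent with every other stated property of the
calibration (the deformation range of the simulations, the near-equality of
D and the capillary number, the residual scale of the surface fit, and the
sign of ∂D/∂Â). They are consistent with all of those properties when read
as *dimensional* prefactors in N/m at the reference setup — note that
a = 0.0015 N/m equals the reference modulus scale η′Q′/L′² = 1.5·10⁻³ N/m
exactly. The package therefore stores γ and a in N/m and uses
Γ = γ/(η′Q′/L′²) ≈ 0.2267 and â = a/(η′Q′/L′²) = 1.0 internally. Under
this transcription the surface maps the calibrated domain
(D ≤ 0.06, Â ∈ [0.12, 0.56]) onto K ≈ 0.1–1 N/m at the reference setup,
deformation grows with area at fixed modulus (provided K̂·Â > e²·Γ, which
holds throughout the domain), and typical DOPC-scale events give
K ≈ 0.18 N/m.

**Residual inconsistency of the two laws.** Both laws are least-squares
fits with finite residuals to the same simulations, so they do not agree
exactly with each other: converting noise-free direct-surface data through
the slope law overestimates K by ~14% at K̂ = 133 and ~7% at K̂ = 1667
(measured once by a brute-force oracle and frozen as the regression band
1.00 < K_slope/K_direct < 1.35 over K̂ ∈ [67, 1667]). This band is a
property of the published constant pairs, not of the implementation, and it
sets the accuracy floor of the combined estimator on synthetic data
generated from the direct surface: ~+12% at 0.2 N/m, ~+5% at 2.5 N/m.

## Fitting procedures

* `calibration.fit_direct_surface` reproduces the two-step procedure:
  α = 0.5 and δ = 1 are fixed (a four-parameter fit is available) and
  (β, γ) are solved by Levenberg–Marquardt (`scipy.optimize.least_squares`,
  method "lm") starting from the built-in constants, with residuals on K̂
  expressed on the reference N/m scale so reported SSR values are
  comparable across setups. Start-value sensitivity is mild: the
  self-consistency tests recover synthetic (β, γ) to 10⁻⁶ from the default
  start even when the truth differs by ~10%.
* `calibration.fit_slope_law` computes per-modulus OLS slopes of D vs Â
  (groups with fewer than two distinct areas are excluded with a warning)
  and fits the power law as a straight line in log–log space for
  conditioning; the parameterization is algebraically equivalent.
* Collective fits use ordinary least squares with a free intercept; a
  non-positive slope is an estimation failure (the power law is undefined),
  raised rather than silently clamped.

## Mixture modelling on ln K

Measurement error on the non-negative deformation is multiplicative, hence
approximately lognormal; through the power-law surface the per-event
modulus is then lognormal too, and populations are modelled as Gaussian
mixtures on ln K. The EM implementation is one-dimensional and purpose-built
so its internals are explicit and testable: quantile-based initialization
(component means at evenly spaced sample quantiles), 10 restarts with
seeded jitter keeping the best likelihood, convergence at a relative
log-likelihood change of 10⁻⁸, at most 500 iterations, and a variance floor
of 10⁻⁶ (flagged when hit). All of these are arguments of
`fit_lnK_mixture`; the per-iteration log-likelihood trace is retained and is
non-decreasing by construction. The test suite cross-checks the fit against
scikit-learn's `GaussianMixture` on well-separated blends. Component count
is user-chosen (2 for a single population plus outliers, 3 for a suspected
two-type blend); a BIC scan is deliberately not auto-applied. Component
summaries use the geometric-mean convention exp(μ). Classification is the
hard posterior argmax with ties broken to the lower-index (lower-mean)
component.

The outlier class is the lowest-mean component: doublets and misplaced
contour lines inflate D and therefore deflate the apparent modulus. This
rule is reliable for single populations, where every inflated event moves
down-scale. **Known limitation:** in a blend of a soft and a stiff
population, inflated events from the stiff class land *between* the class
modes, the maximum-likelihood three-component solution places a wide,
low-weight component co-centred with the soft class, and the ascending-mean
ordering of {soft bulk, outlier component} becomes data-dependent — the
lowest-mean rule can then discard the soft bulk. Side-grouped quantities
(top-component weight for the stiff class, the two lower components for the
soft side) remain accurate to ±0.01 and are what the mixed-set checks use.

## Synthetic data generator

`synthetic.generate_events` is the forward model of the analysis: areas
uniform on the gated range [60, 225] µm² (a truncated-lognormal option
exists), noise-free deformation from the direct surface at the population's
true K, observed deformation D·exp(ε) with ε ~ N(0, σ_D²), σ_D = 0.15 by
default — a level chosen to produce the scatter typical of GUV
measurements; the source data do not quantify their noise magnitude, so
this default cannot be validated against a printed number. Outliers
(default 5%) have D multiplied by a factor ~ U(1.5, 3), mimicking doublets
and missegmentation, and carry porosity > 1.03 when porosity emission is
requested. The generator seeds every draw from the spec seed and is
bitwise reproducible. It emulates the *statistical* structure the analysis
assumes — it does not emulate hydrodynamic interactions, focus drift,
absolute-D outlier mechanics, or image-level noise, so passing recovery
tests demonstrates correctness of the inference chain under its own noise
model, not instrument-grade accuracy on real data.

`synthetic.rasterize_contour` emits capsule (stadium) shapes on the pixel
grid. Vertices are sampled at about one-pixel spacing, snapped to the
lattice and convexified — matching how RT-DC deformation is computed from
convexified contours; a naive staircase polygon would carry a
non-vanishing perimeter excess. Measured features match the request within
|ΔD| ≤ 0.02 and |ΔA|/A ≤ 5% (pixel-grid oracle bound; the D excess is the
pixelation offset, positive and size-decreasing). `doublet_contour`
overlays two discs (centre distance 1.5 r) for a porosity ≈ 1.07 doublet.

## Pixelation correction

Contours on a pixel grid make even perfect circles appear deformed.
`geometry.pixelation_correct` subtracts a configurable offset model and
clamps at zero. The shipped `GridOffsetCorrection` is **synthetic**: its
double-exponential coefficients (c₁ = 3.507·10⁻³, τ₁ = 9934 px²,
c₂ = 1.337·10⁻², τ₂ = 519.2 px², zero asymptote) were fitted against this
package's own rasterized circles at 0.34 µm/px, so correction and
rasterizer form a closed, self-consistent loop. They are not the
instrument-calibrated coefficients of the published correction for real
RT-DC cameras; users with such coefficients should supply their own
strategy object. With no strategy configured the correction is the
identity, with a one-time logged warning.

## Quality gates

Defaults follow standard RT-DC post-processing: A ∈ [60, 225] µm²,
D ≤ 0.1, porosity ≤ 1.03. Gating is idempotent and annotates rejected
events with the failing gate. The stricter calibration-validity range
(D ≤ 0.06, Â ∈ [0.12, 0.56]) is deliberately a warning, not a gate —
analyses legitimately mix both ranges, and the surface extrapolates
smoothly.

## Problem sizes and numerical choices

The shipped checks use n = 5000 events for recovery runs, 1000 + 1000 for
the mixed-set deconvolution, 24-seed oracle ensembles behind the frozen
tolerance bands, and sub-minute runtimes throughout; these sizes give
binomial/Monte-Carlo uncertainties comfortably below the asserted bands
(e.g. mixing-weight SE ≈ 0.011 at n = 2000 against a ±0.02 band).
Degenerate inputs fail loudly: D ≤ 0 events are undefined under the power
law and are excluded with a logged count (scalar calls raise), empty
post-gate datasets produce explicit failure reports, and degenerate
polygons raise `InvalidContourError`.
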