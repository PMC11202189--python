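# Methods

## Model

Released mass is modelled as order-one kinetics with a time-varying
residence lifetime,

    dm/dt = (m_∞ − m(t)) / τ_exp(t),        τ_exp(t) = B·t^(1−σ),

whose solution with m(0) = 0 is the compressed/stretched exponential
χ(t) = m(t)/m_∞ = 1 − exp(−(t/τ₀)^σ) with τ₀ = (σB)^(1/σ). The power-law
lifetime is a phenomenological summary of everything that changes the escape
timescale during a run — osmotic swelling of the wall, slow hydrolysis of
the polyester, changing sorption sites. None of those mechanisms is
simulated; the model's claim is only that their aggregate effect on the
lifetime is a power law in time. Consequences worth keeping in mind:

- σ > 1: lifetime decreases with time (accelerating release), zero initial
  rate, sigmoidal curve. σ = 1: constant lifetime, simple exponential.
  σ < 1: decelerating (stretched) release with a singular initial rate.
- The membrane-frame lifetime is τ(t) = φ·τ_exp(t) with φ = V_m/V. φ only
  rescales lifetimes; it does not enter the fit.
- χ is strictly increasing with sup χ = 1; in double precision χ saturates
  to exactly 1.0 once (t/τ₀)^σ ≳ 37, which is handled throughout (such
  points carry no parameter information and contribute zero residuals and
  zero Jacobian rows).

## Parameters and units

| quantity | units | default / convention |
|---|---|---|
| m_∞ | µg | fitted; plateau released mass in the bath |
| τ₀ | h | fitted; characteristic time |
| σ | – | fitted; shape exponent, positivity enforced |
| bath volume V | dm³ | 0.015 |
| geometry | m | cylinder d_i = 0.01, L = 0.01, wall 410 µm |
| c₀ | g dm⁻³ | initial load; presets 0.03763 ("low") and 37.63 ("high") |
| concentrations | mg dm⁻³ | calibration and instrument switching scale |
| LOD/LOQ | µg dm⁻³ | trace scale they are conventionally quoted on |

Masses are µg because that is the only choice placing the plateau bath
concentrations of both presets (3.0 µg/0.015 dm³ = 0.2 mg dm⁻³;
147 µg/0.015 dm³ = 9.8 mg dm⁻³) inside the two instruments' working ranges.

The membrane volume V_m counts the lateral shell only (the top is sealed,
the bottom glued to the vessel, so the end disks do not transport);
`SystemGeometry(include_bases=True)` overrides this. The loaded mass uses
the nominal inner cylinder volume π(d_i/2)²·L = 7.854·10⁻⁴ dm³.

Derived descriptors are closed-form: t₀.₅ = τ₀(ln 2)^(1/σ),
B = τ₀^σ/σ, yield = 100·m_∞/(c₀·V_inner). "Infinite time" in reports is
the time at χ = 0.999. For the two preset triples the closed forms give
t₀.₅ = 618.3 h (low) and 369.6 h (high) and yields 10.15 % and 0.50 %;
figures sometimes quoted for comparable systems from graphical readings of
normalized curves (e.g. t₀.₅ ≈ 656/395 h, yields 12 %/0.8 %) differ from
the closed-form values of these triples — when comparing, state which
procedure produced the number.

## Calibration

Curves are fitted by ordinary least squares on replicate means (standards
are read in triplicate): a line for the fluorimeter, a parabola for the
spectrophotometer. The parabola's negative curvature reflects dye–dye
association at high concentration; a fit that is not strictly increasing
over the calibrated range is rejected because inversion would be ambiguous
(the derivative is linear in c, so checking the range endpoints suffices).

Inverse prediction: line algebraically; parabola via the numerically stable
quadratic formula, keeping the root on the increasing branch inside the
range. Signals within 2 residual-sd outside the range image are clamped to
the nearest endpoint with a warning (noise at range edges); farther signals
raise an error naming the instrument to switch to.

Detection limits use the regression-residual formulation LOD = 3.3·s/S and
LOQ = 10·s/S (s = residual sd of the means regression, S = slope), so
LOQ/LOD ≡ 10/3.3. The reported calibration RMSE is computed against the
individual replicate signals — the scatter a single bath reading carries —
while s, R² and the detection limits stay on the means regression.

Instrument switching partitions the concentration axis with no gap or
overlap: fluorimeter for c ≤ 0.06 mg dm⁻³, spectrophotometer for
0.06 < c ≤ 14, mandatory decade dilution above 14.

## Fitting

Levenberg–Marquardt on the damped normal equations
(JᵀJ + µ·diag(JᵀJ))δ = Jᵀr with Nielsen's gain-ratio update for µ. The
Jacobian is analytic (∂f/∂m_∞ = χ; ∂f/∂τ₀ = −m_∞e^(−u)uσ/τ₀;
∂f/∂σ = m_∞e^(−u)u·ln(t/τ₀), u = (t/τ₀)^σ), with all derivatives set to
their limit 0 at t = 0 so the origin point can stay in the fit. Positivity
is enforced by optimizing log-parameters (chain rule ∂f/∂ln p = p·∂f/∂p);
this matters for near-step shapes (σ ≈ 9) that approach the boundary of
useful parameter space.

Convergence: relative SSR decrease < 1e−10 on an accepted step, gradient
∞-norm < 1e−10, or a damped step below 1e−14 relative (the numerical floor
reached on noiseless data). Default cap 200 iterations; a non-converged fit
is returned flagged, not raised. Covariance is s²(JᵀJ)⁻¹ in the original
parameter space, s² = SSR/(n−k); with σ frozen (`sigma_fixed`) its row and
column are zero. Initialization inflates the largest observed mass by 1.05
and linearizes ln(−ln(1−χ̂)) = σ·ln t − σ·ln τ₀ over 0.01 < χ̂ < 0.99,
falling back to (σ = 1, τ₀ = median t) below 3 usable points.

Caveat: for near-step releases (σ of order 9) the SSR surface is almost
flat in σ once the sampling grid straddles the step, so the σ standard
error is large and only loosely interpretable; the package reports it as
computed. R²/RMSE are reported on the mass scale (µg) and RMSE additionally
on the normalized χ scale, where it is dimensionless and comparable across
loads — a normalized RMSE of a few 0.01 corresponds to a visually excellent
fit.

Fitting operates on masses, not normalized curves; normalization by the
fitted m_∞ is applied afterwards for reporting and comparison. Points below
the LOD are retained at their point estimates (flagged): the early sub-LOD
points are precisely the ones carrying the lag information, and censoring-
aware fitting is out of scope.

## Synthetic generator

`relkin.synthetic` simulates the whole measurement chain per scheduled time:
true mass from the model → bath concentration at fixed V → instrument
selection (with decade dilution above the ceiling) → forward calibration
curve → additive Gaussian signal noise; seeded, byte-reproducible. Sample
withdrawal is modelled as volume-neutral (withdrawn aliquots are returned
after reading), so no volume-correction term is generated.

Defaults are the study conditions: geometry above, 2200 h horizon (> 12
weeks), an irregular schedule (2-hourly over the first half-day, 12-hourly
over the first week, then daily; ~104 points), and the two preset truths.
Forward curves: fluorimeter signal = 2.0 + 8000·c counts; spectrophotometer
A = 0.01 + 0.155·c − 0.0025·c² (monotone up to its vertex at 31 mg dm⁻³,
well above the 14 mg dm⁻³ ceiling). Per-read noise: 0.56 counts
(fluorimeter — via 3.3·s/S this reproduces trace detection limits of a few
tenths of a µg dm⁻³) and 0.001 A photometric noise (spectrophotometer),
which give the low-load run a fit quality of R² ≈ 0.99 and normalized
RMSE ≈ 0.03, the regime the analysis is designed for. Calibration standards
prepared by serial dilution scatter more than a repeated read (~0.01 A,
preparation plus read error); the standards generator takes that value
explicitly when emulating a standards series. A proportional-noise option
exists for robustness checks.

What the generator does **not** emulate: membrane swelling dynamics and
photographic data, hydrolysis chemistry, dye-aggregation equilibria (only
their net effect, the saturating calibration curve and the preset contrast
in σ and yield), drift or autocorrelated instrument error, and any
volume-loss effects of sampling. Passing tests therefore demonstrate that
the pipeline recovers parameters under the model's own assumptions plus
realistic instrument noise — not that the compressed-exponential model is
correct for any particular polymer.

## Verification design

- Closed forms are cross-checked against independent numerics: t₀.₅ against
  bisection on χ, the release rate against central finite differences, the
  lifetime power law against quadrature of 1/τ_exp, the LM optimizer
  against both an exhaustive grid search and an independent trust-region
  least-squares implementation.
- Noiseless round trips (generate → calibrate → invert → fit) recover
  generating parameters to ≤ 1e−6 relative for both presets and for random
  valid triples with adequate time coverage (t_max ≥ 2.5·t₀.₅, 50–60
  points — these sizes keep the whole suite under a few seconds without
  affecting the conclusions).
- Under 2 % mass-scale noise, ±2-stderr intervals cover the truth for
  ~95 % of 500 seeded replicates (accepted band 90–99 %).
- The brute-force localization check (grid optimum within one grid step of
  the LM optimum on an 11³ bracketing grid) is run at 1 % noise: there each
  grid step is about three parameter standard errors, so the discrete
  optimum should land on the node nearest the continuous one; at larger
  noise the displacement of the optimum exceeds the σ grid step and the
  one-step property is no longer a fair test of either optimizer. The SSR
  ordering SSR(grid) ≥ SSR(LM) is checked at 2 % noise as well.

## Known limitations

- No censoring-aware treatment of sub-LOD points and no weighted/
  heteroscedastic fitting (the chain converts all points to masses and fits
  unweighted least squares).
- The quadratic calibration is empirical; it extrapolates badly outside the
  calibrated range, which is why inversion refuses to.
- σ estimates for near-step releases are ill-conditioned (flat SSR in σ);
  compare such fits via t₀.₅, which stays well-determined.
- The model forces χ(0) = 0 and a monotone curve; burst release or
  biphasic profiles need a different model.
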