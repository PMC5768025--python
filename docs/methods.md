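# Methods

## Scope and model structure

`titrkin` models a pressurized tube-in-tube membrane reactor used to
measure oxygen-dependent enzyme kinetics, and the statistical pipeline
that turns its output into parameter estimates. The chain is:

gas condition → dissolved-O₂ saturation (Henry) → plug-flow reactor with
membrane O₂ supply → flow-ramp concentration–residence-time series →
initial rates → nonlinear fit of the ping-pong bi-bi law → uncertainty and
design analysis. Each stage is an independent module with its own
contract, so any stage can be fed real data in the documented CSV schemas
instead of simulated data.

## Oxygen equilibrium

Dissolved O₂ at equilibrium is linear in the O₂ partial pressure
(Henry's law), calibrated through one anchor point. Two anchors are
built in: air-saturated water at 1 atm (0.276 mM) and pure O₂ at 6 bar
(7.13 mM). These imply Henry constants of 1.300 and 1.188 mM/bar
respectively — a ~9 % inconsistency that a single linear law cannot
absorb (plausibly buffer salting-out or a different tabulated constant
behind the pressurized figure). The package deliberately keeps both as
first-class calibrations, never averages them, and requires each
computation to pick one; an explicit-constant mode covers everything else.
Consequences:

* the pressurized-over-air fold ratio is computed with each condition
  under its own anchor (7.13/0.276 ≈ 25.8);
* a calibration is valid only at its anchor temperature — querying another
  temperature is an error, not an extrapolation;
* water-vapor correction of the partial pressure (the feed gas is wetted)
  is available but **off** by default, since the anchor measurements'
  handling of vapor is unknown.

## Rate law and stoichiometry

The ping-pong bi-bi law
r_E = k_cat·S·O/(S·O + K_MO·S + K_MS·O)
is implemented with rates per mg of *liquid enzyme formulation*, not per
mg pure protein — the basis on which the reference parameter triples
(k_cat = 17.82 μmol·min⁻¹·mg⁻¹, K_MO = 0.52 mM, K_MS = 74.57 mM for the
combined-design estimate) are defined. The S=O=0 point is defined as rate
0 by continuity. Catalase is modeled as instantaneous: H₂O₂ is held at
zero and the net O₂ demand halves; product inhibition and the reverse
reaction are omitted because peroxide removal renders the reaction
unidirectional. At fixed O the law collapses *exactly* to a hyperbola
with V_max,app = k_cat·O/(O+K_MO) and K_MS,app = K_MS·O/(O+K_MO); this
identity is enforced to 1e-12 in the tests and is the algebraic reason a
single-oxygen-level design cannot identify all three parameters.

## Reactor twin

The solute balance is 1-D plug flow in residence time τ ∈ [0, V/Q] with
the membrane term kLa·(c_sat − O) in the oxygen equation, integrated with
LSODA at rtol 1e-8 / atol 1e-10. Axial dispersion is a *diagnostic*, not
part of the transport model: Taylor–Aris
(D_ax = D_m + u²a²/48D_m) classifies the operating point as plug-flow-like
when the vessel dispersion number D_ax/(uL) < 0.01, a standard
small-dispersion criterion. At default geometry and flows the criterion
gives ~1.5e-3 for small molecules (plug flow holds) and ~0.15 for the
enzyme (D = 1e-11 vs 1e-9 m²/s — plug flow fails). The twin therefore
never transports the enzyme: its concentration is clamped spatially
uniform, mirroring the operating practice of holding the enzyme feed
concentration constant and independent of liquid flow.

The flow-ramp method is implemented as a quasi-steady mapping: each
sampled clock time t is assigned τ(t) = V/Q(t) and the steady plug-flow
outlet at that τ. Validity requires the relative change of residence time
per residence time, |dQ/dt|·V/Q², to stay below 0.1; the series carries
this as `attrs['quasi_steady_valid']`. Because the criterion scales as
1/Q², a *linear* flow ramp always fails at its slow end; the
`FlowProgram.tau_ramp` schedule (residence time linear in clock time,
i.e. hyperbolic flow) holds the criterion constant and is the default
ramp. A full transient PDE solution is out of scope — the quasi-steady
assumption is exactly what the slow-ramp operating mode is designed to
satisfy, and the flag surfaces its limit.

RTD: tracer responses use the closed-form small-dispersion Gaussian
exit-age curve (pulse) or its running integral (step), adequate for
dispersion numbers < 0.01 where the curve is effectively symmetric.
Volume is estimated as flow × first moment of the normalized E-curve
(steps are differentiated first); a truncation guard rejects curves whose
E-curve has not returned to ≤10 % of peak at either end, and the reported
uncertainty propagates the baseline noise level through the moment
quadrature. The moment estimator is unbiased under additive noise, which
the Monte-Carlo test (20 seeded pulses at 1 % of peak) confirms.

## Defaults and key parameters

| Parameter | Default | Why |
|---|---|---|
| reactor volume | 155 μL | RTD-calibrated volume of the reference instrument |
| inner radius | 115 μm | I.D. 230 μm membrane tubing |
| kLa | 6 min⁻¹ | chosen so the *fastest* default flow (τ = 1.55 min) still reaches ≥99 % of saturation enzyme-free (1 − e⁻⁹·³); the true membrane coefficient is instrument-specific and configurable |
| flow range | 10–100 μL/min | residence times 1.55–15.5 min over 155 μL; a practical window for initial-rate work |
| diffusivities | 1e-9 / 1e-11 m²/s | small molecule vs enzyme, the two-orders-of-magnitude gap that motivates the constant-enzyme-feed design |
| enzyme feed | 0.05 mg/mL | keeps the reactor differential: O₂ stays within ~1–4 % of saturation at the highest rates and conversions stay in the initial-rate window; configurable |
| integrator | rtol 1e-8, atol 1e-10 | validated to 1e-6 against a Richardson-extrapolated fixed-step Euler oracle |

## Synthetic campaigns

`paper_design()` reproduces the study structure: glucose
{25, 100, 200, 400} mM crossed with six log-spaced dissolved-O₂ levels per
pressure window, 0.14–1.3 mM (1 atm, 5–100 % O₂) and 0.9–7.13 mM (6 bar).
The exact number and placement of O₂ levels in the original campaigns is
not published; six log-spaced levels preserve the printed ranges and give
even fold-change coverage. The design satisfies the Michaelis-bracketing
rule at the reference parameters (O from K_MO/3.7 to 13.7·K_MO; S from
K_MS/3 to 5.4·K_MS). Measurement noise is multiplicative Gaussian with
3 % CV by default (the original work reports only fitted ± values, so the
CV is an assumption, stated as the noise model everywhere it matters);
rates are truncated at zero. Enzyme degradation between campaigns enters
as a single static factor on k_cat (default 0.79 where a degraded
campaign is simulated) — equivalent under the rate law to scaling the
measured rates. Every generator is a pure function of (config, seed).

What the generator does **not** emulate: detector/flow-injection peak
shapes, calibration-chemistry errors, systematic drifts within a
campaign, pump pulsation, or enzyme deactivation *during* a run. Passing
tests therefore demonstrate correctness of the estimation machinery under
the stated noise model, not robustness to every artifact of real
instrument data.

## Estimation

Initial rates: through-origin least-squares slope of product vs residence
time over the rows with conversion ≤ 10 % (product is zero at τ = 0 by
construction), divided by the enzyme concentration; the observation's O
is the mean dissolved O₂ over the retained rows. Requiring ≥3 eligible
rows guards against fitting outside the initial-rate window.

Fitting: multi-start nonlinear least squares in log-parameters
(positivity by construction), 20 starts log-uniform over ±2 decades
around an automatic scale guess (max rate, median O, median S), analytic
Jacobian, Levenberg–Marquardt, best converged start wins. The default
objective is absolute (unit-weight) least squares — the conventional
choice for initial-rate fitting; relative weighting (residuals scaled by
the observed rate) is available and is the variance-consistent choice
under the multiplicative noise model, so the Monte-Carlo coverage and
Fisher-consistency studies use it. Covariance is σ²(JᵀJ)⁻¹ with
σ² = RSS/(n−3); intervals are t-based at 95 %. A fit is flagged
ill-identified when the normal-matrix condition number exceeds 1e8 or any
relative CI half-width exceeds 100 % — the signature of a single-O-level
design. Bootstrap CIs resample residuals with replacement (seeded) and
refit from the point estimate; >20 % refit failures aborts.

Activity scaling: a four-parameter joint fit (campaign-specific k_cat,
shared K_MO and K_MS) whose k_cat ratio is the degradation factor; the
ratio inverts exactly under label swap.

Design comparison: Fisher information under the relative-noise model,
F = Σ n_i g_i g_iᵀ/(cv·r_i)², inverted for linearized relative SEs at the
true parameters; numerically singular information (condition > 1e15) is
reported as infinite SEs rather than raised. The combined two-pressure
design roughly halves the K_MO SE versus the atmospheric-only design, and
a design with all O ≥ 20·K_MO leaves K_MO effectively unidentifiable
(relative SE > 1).

## Numerical and testing choices

* The plug-flow integrator is validated against an independent fixed-step
  explicit-Euler oracle, Richardson-extrapolated from 50k and 100k steps
  (the extrapolation cancels the O(h) error, reaching ~1e-8 so the 1e-6
  comparison is meaningful at desk-scale runtime), over 20 random
  parameter draws.
* The optimizer is validated against a brute-force 2-D log-grid search on
  the (k_cat, K_MO) profile with K_MS pinned at its fitted value; the
  grid contains the fitted point (odd point count) so the argmin lands on
  it iff the fit is a genuine minimum among ~40k alternatives.
* Monte-Carlo studies (CI coverage over 50 seeds, recovery over 20 seeds,
  Fisher-vs-Monte-Carlo SE consistency over 30 seeds) run at the default
  48-observation design and complete in seconds; all seeds are fixed.
* Degenerate inputs: zero enzyme, zero residence time, zero O₂ fraction,
  truncated tracer curves, single-O designs and sub-vapor pressures all
  have defined behavior (closed-form limits, errors, or flags) covered by
  tests.

## Known limitations

* The quasi-steady ramp mapping cannot represent genuinely fast ramps;
  the validity flag warns but the twin does not solve the transient PDE.
* The small-dispersion Gaussian RTD is inadequate beyond dispersion
  numbers of ~0.01–0.25 (the constructor rejects ≥0.25).
* Temperature dependence of solubility and kinetics is out of scope; all
  defaults describe 25 °C operation.
* kLa is a single lumped, user-set constant — membrane permeability
  physics, pressure drop and radial profiles are not modeled.
* Enzyme deactivation is a static between-campaign factor, not a
  time-resolved decay.
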