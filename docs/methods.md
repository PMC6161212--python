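# Methods

This note records the models implemented in `meltflow`, the defaults and
numerical choices behind them, what the synthetic generators do and do
not emulate, and the known limitations. Nothing here states a result the
test suite or `scripts/acceptance.py` does not itself compute.

## Glass-transition mixing

**Couchman–Karasz (CK).** The ideal-mixing prediction
Tg = (w₁Tg₁ + k(1−w₁)Tg₂)/(w₁ + k(1−w₁)), k = ΔCp₂/ΔCp₁, is evaluated
on the absolute temperature scale (Kelvin) and converted back to °C.
The thermodynamic derivation demands Kelvin; for the temperature ranges
of pharmaceutical melts a Celsius evaluation happens to land within
about a degree, but Kelvin is canonical here. Component 1 is the drug,
2 the polymer. ΔCp ≤ 0 is rejected. For k > 0 the prediction is
monotone in composition between the endpoint Tgs, and k = 1 reduces to
the linear Kelvin mean — both are property-tested.

**BCKV polynomial.** Tg(w₁) = w₁Tg₁ + (1−w₁)Tg₂ +
w₁(1−w₁)[a₀ + a₁u + a₂u²], u = 2w₁−1. The correction vanishes at the
endpoints, so the pure-component Tgs are pinned, never fitted; the
coefficients enter linearly and are solved by linear least squares
(exact, no iteration). With fewer than three interior compositions the
order drops (a₂ = 0, then a₁ = a₂ = 0). Goodness of fit is reported as
adjusted r²; on measured-like data it is a diagnostic, not an assertion.

**Deviation diagnostics.** The signed gap measured-Tg − CK-prediction is
reported per blend; because a quoted deviation can also refer to the
largest gap between the fitted BCKV curve and the CK curve, an extremum
diagnostic over w ∈ [0, 1] (0.001 grid) is provided as well.

## Solubility from annealing DSC

A supersaturated blend annealed ~60 °C above its predicted Tg
equilibrates its dissolved drug fraction; the Tg measured afterwards is
converted to that fraction by inverting the BCKV curve. Inversion scans
a 2001-point grid for sign changes and polishes each bracket with
Brent's method (tolerance 1e-9). BCKV curves with strong corrections
can be non-monotone, so when several roots exist the one nearest the
nominal loading is returned and the multiplicity flagged. Records whose
recovered fraction equals the nominal loading (within 0.02) were fully
dissolved and are excluded from boundary fitting — they bound the curve
from below but do not lie on it.

The boundary T(x) = y₀ + A·e^(R₀x) is fitted by
`scipy.optimize.curve_fit`, seeding y₀ at the drug's melting point when
supplied. Both sign branches are physically usable; for a boundary that
rises toward the melting point at full drug fraction, A and R₀ are both
negative and y₀ is the w→1 (melting) asymptote. Ambient solubility is
the inverse x = ln((T−y₀)/A)/R₀ at 25 °C, clipped to [0, 1] with a
flag; a non-positive argument means the boundary never reaches that
temperature and the drug is reported insoluble (fraction 0, flagged)
rather than raising — the meaningful answer for screening.

## Rheology

**Cox–Merz** is assumed throughout: |η*|(ω) from SAOS is used as η(γ̇)
with γ̇ ≡ ω, so oscillatory data can drive steady-shear process models.
Frequencies in Hz are converted to rad/s on ingestion.

**Master curves.** Shifting is horizontal only (no vertical/density
correction): the master curve stores (ω·a_T, |η*|) pairs with the
viscosity values untouched, and off-reference evaluation applies a_T to
the relaxation time, η(γ̇, T) = η_ref(a_T γ̇). Sweeps are merged
nearest-temperature-first against the growing master; each shift
minimises the mean squared log–log distance over the overlap window
(801-point bracketing grid, then bounded scalar minimisation to 1e-12).
The master is interpolated with a monotone cubic (PCHIP): a piecewise
linear interpolant biases shifts by several 10⁻³ decades on the curved
knee of the flow curve, an order more than the noise-free recovery the
test suite requires. One Gauss–Seidel refinement pass re-optimises every
shift against the master assembled from all other sweeps, removing most
of the sequential order dependence; noise-free recovery is then better
than 1e-3 decades at every temperature. Sweeps whose viscosity ranges do
not intersect cannot be superposed horizontally and raise an overlap
error naming the offending pair.

**Carreau–Yasuda.** The reduced form (no infinite-shear viscosity term)
is fitted in log viscosity by `scipy.optimize.least_squares` with
η₀, λ, a parameterised on the log scale and n bounded in (0, 1].
Initial values: η₀ = max η, λ = 1/median rate, a = 2, n = 0.3. Data
with fewer than five points or spanning less than a factor 2 in
viscosity cannot resolve the transition; these trigger a warning and a
reduced fit with a fixed at 2. Standard errors come from the Jacobian at
the solution (basis: ln η₀, ln λ, ln a, n); confidence intervals must
use t-quantiles at the reported residual degrees of freedom.

**WLF.** log₁₀ a_T = −C₁(T−T₀)/(C₂+T−T₀) is fitted to the shift-factor
map with positivity bounds, starting from (C₁, C₂) = (8, 120). At the
default five-temperature design the fit keeps only two residual degrees
of freedom, so its 95 % intervals are t₂-based (quantile ≈ 4.3) — using
a normal quantile there undercovers badly, which the recovery tests
verify by replicate coverage counting.

## The Tg–viscosity correlation and model-based flow curves

ln η₀ = ln a + b·Tg is a plain linear least-squares fit (Tg in °C); at
least two distinct Tgs are required. The prefactor a is temperature
specific — the shipped default calibration is computed on demand from
the five packaged (Tg, η₀-estimated) pairs at 150 °C; for another
polymer or reference temperature, recalibrate. b > 0 is enforced:
a stiffer (higher-Tg) blend must be more viscous.

`generate_model_flow_curve` refuses mismatched reference temperatures,
copies n and a bit-identically, and rescales (η₀, λ) by the common
ratio r. The correlation ignores specific drug–polymer interactions;
at drug loadings ≥ 30 % of a drug that dissolves in the polymer the
prediction is known to drift, so such calls emit a `HighLoadingWarning`
when the caller supplies the loading and solubility flags. Treating the
drift itself is future work for the correlation, not this package.

## Extrusion energy

`compute_sme` is the exact telemetry formula SME = 2πn(τ−τ_idle)/(60ṁ)
with the idle torque defaulting to 1.2 N·m (small 12 mm lab extruder);
W/(kg/h) ≡ kWh/t, so no unit factor appears. Net torque below zero
clamps to zero with a warning.

`simulate_energy_1d` is a demonstrator, deliberately simple and labelled
as such in every report it writes: fully filled channels, melt
isothermal at barrel temperature, no pressure or die back-flow coupling,
no backward iteration from the die, zero melting enthalpy (the blend's
glass transition stands in wherever a softening point is demanded).
Per element the mean channel shear rate is γ̇ = πDN/h and the dissipated
power η(γ̇, T)·γ̇²·V with V ≈ πDhL; the barrel conducts whatever part of
the feed-heating duty ṁ·cp·ΔT dissipation does not cover, capped by a
film-conduction estimate (k/h)·A·ΔT using the 0.18 W/(m·K) melt
conductivity approximation. The reported breakdown is
SME = dissipated + conduction; a commercial 1D solver partitions energy
differently (specific/dissipated/melting) and computes partially filled,
non-isothermal channels, so only orderings and sensitivities — more
viscous melt ⇒ more dissipation; 10 % blends out-consuming their 30 %
counterparts — are claimable, and those are what the tests assert.
Default geometry: 12 mm screw, 25:1 L/D, channel depth 2.4 mm (0.2·D, a
documented assumption), a conveying/kneading layout totalling 300 mm.

## Synthetic data: what passing tests show

Generators are pure functions of (spec, seed) via
`numpy.random.default_rng`; identical seeds give identical bytes.

- SAOS: |η*|(ω, T) = CY(ω·a_T) on a 10→0.1 Hz grid (9 points) at five
  temperatures in 10 K steps, with multiplicative log-normal noise
  (default σ = 2 %). This matches the horizontal-only TTS model exactly;
  real melts also show vertical (ρT) shifts, thermorheological
  complexity and instrument compliance errors that are not emulated.
- Tg-vs-composition: BCKV truth plus additive Gaussian noise
  (default 0.5 K).
- Annealing: dissolved fraction = min(nominal, boundary value at the
  hold temperature); Tg from the BCKV curve at that fraction plus noise.
  Real annealing adds equilibration kinetics, recrystallization during
  the re-scan and moisture effects; none are modelled.

Default ground truths, chosen once as realistic for a copovidone system
at 150 °C: CY (η₀ = 10⁴ Pa·s, λ = 0.5 s, a = 2, n = 0.3), WLF
(C₁ = 8, C₂ = 120 K), and a celecoxib-like boundary anchored at the
melting point 160.9 °C with R₀ = −8 and A solved so ambient solubility
is 33 %. Recovery tests therefore demonstrate correctness of the
estimators under the stated noise model — not instrument-grade accuracy
on real measurements.

Problem sizes used by the recovery suites (8 replicates × 45 SAOS
points; 9 compositions; 8 annealing holds) are the study designs above;
they run in seconds.

## Known limitations

- The correlation prefactor a(T) is only available by recalibration at
  each reference temperature; no functional temperature dependence is
  asserted for it.
- Horizontal-only TTS makes the zero-shear plateau formally
  temperature-independent; within the measured frequency window this is
  inconsequential, but extrapolated plateaus at far-off temperatures
  inherit the assumption.
- The energy demonstrator must not be used for absolute SME prediction,
  scale-up, residence-time or pressure work.
- Physical stability of the dispersions (recrystallization on storage)
  is out of scope; the solubility module describes the melt-state
  boundary only.
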