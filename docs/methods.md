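# Methods

## Scope and model

`gilltep` analyses sodium balance across the gill of a freshwater fish as
the interplay of a chemical gradient (water vs. plasma Na⁺ concentrations)
and an electrical gradient (the transepithelial potential, TEP, blood side
relative to external water = 0 mV). The central physical assumption is
that the TEP is a pure diffusion potential: it arises from the differential
passive permeability of the gill epithelium to plasma cations (mainly Na⁺)
versus anions (mainly Cl⁻), with no electrogenic (charge-separating pump)
term. The empirical signature of that assumption — abolition of the TEP in
a bath isotonic to plasma — corresponds exactly to the model property that
symmetric solutions give 0 mV for any permeability set, which the test
suite asserts bit-exactly.

### Nernst and GHK

Single-ion equilibrium potentials are computed as
E = (RT/zF)·ln(c_out/c_in), with T entering only through T_K = T_C + 273.15
(R = 8.314 J mol⁻¹ K⁻¹, F = 96485 C mol⁻¹). Activities are taken equal to
concentrations: the waters of interest are ≤ ~2.5 mmol/L ionic strength,
where activity coefficients for monovalent ions deviate from 1 by under
~5%; a Debye–Hückel correction is deliberately out of scope.

The diffusion potential is the Goldman–Hodgkin–Katz (GHK) voltage
equation over monovalent ions (Na⁺, K⁺, NH₄⁺, H⁺, Cl⁻):

V = (RT/F)·ln[(Σ_cat P_i[i]_out + Σ_an P_j[j]_in) /
(Σ_cat P_i[i]_in + Σ_an P_j[j]_out)]

Divalent ions (Ca²⁺, Mg²⁺) are rejected with an explicit error rather than
silently dropped: the constant-field derivation for mixed valences is a
different equation, and in these waters the divalents contribute little to
the diffusion potential in any case. Permeabilities are relative, with
P_Cl ≡ 1 as the reference.

Because the GHK equation is linear in any single unknown permeability, the
inverse problem (measured TEP → P_Na/P_Cl) has the closed form
P_Na = (E·b − a)/([Na]_out − E·[Na]_in) with E = exp(VF/RT) and a, b the
fixed permeability-weighted terms. Feasible potentials lie strictly
between the Nernst potentials of the ions involved; outside that interval
the solver raises an infeasible-potential error naming the offending TEP,
and for symmetric solutions (where any ratio reproduces 0 mV) it raises a
degenerate-solution error instead of returning an arbitrary number. The
fit∘forward round trip is held to ≤ 1e−9 mV in the tests.

### Gradient partitioning

For a measured TEP the outward driving force on an ion is
TEP − E_ion (mV); the *electrical fraction* |TEP|/|E_ion| is the share of
the chemical gradient that the TEP offsets (defined when the two have the
same sign; NaN sentinel when E_ion = 0 with TEP ≠ 0). The *equivalent
internal concentration* re-expresses the reduced gradient as the
fictitious plasma concentration that would produce the same driving force
at TEP = 0: c_eq = c_out·exp((TEP − E_ion)·zF/RT). Percent values are
carried at full precision with a nearest-integer convenience property,
since the field reports them as integers.

Default plasma composition: Na⁺ 158 mmol/L (the measured species value),
Cl⁻ 130 mmol/L and K⁺ 3 mmol/L (generic teleost values). The latter two
are labelled assumptions and are overridable everywhere they appear.

## Radiotracer flux calculus

With a ²²Na dose mixed into the chamber water, unidirectional influx is
estimated from the tracer drawdown,
J_in = ([R]_i − [R]_f)·V/(SA·t·M), net flux from the chemical drawdown,
J_net = ([Na]_i − [Na]_f)·V/(t·M), and efflux by difference,
J_out = J_net − J_in (≤ 0 by convention). SA is the *mean external
specific activity*, taken as the arithmetic mean of the start and end
R/[Na] ratios: the alternative (ratio of means) differs by well under 1%
at realistic drawdowns and is not symmetric under time reversal. No decay
correction is applied (²²Na t½ ≈ 2.6 y ≫ 1 h) and cpm are treated as
proportional to dpm (constant quench). No backflux correction is applied
either; instead the simulator quantifies the resulting bias (below).

Q10 coefficients use the conventional form Q10 = (R2/R1)^(10/(T2−T1)),
defined for two nonzero rates of common sign (signed efflux rates work
naturally). Adjacent-interval Q10s combine into the full-range value by
the span-weighted geometric composition
((q₁^Δ₁·q₂^Δ₂)^(1/(Δ₁+Δ₂))), which is exactly what Q10 applied to the end
points of a piecewise log-linear rate curve gives, and is associative.

## Water chemistry

Waters are stored in µmol/L with pH, DOC and DIC. The charge balance
(Σz·c cations − Σ|z|·c anions, µeq/L) is reported as a diagnostic; the
reference waters all show a positive gap attributable to unmeasured HCO₃⁻
and organic anions, which the package reports but does not impute.
Salt amendments (NaCl, NH₄Cl) increment both constituent ions;
`required_addition` is the exact inverse.

Conductivity is predicted by the Kohlrausch infinite-dilution sum
Σλ°ᵢ|zᵢ|cᵢ using tabulated 25 °C limiting equivalent conductances. This is
a plausibility check, not a fit: no ionic-strength or temperature
correction is applied, and agreement within ±20% of measurement is the
design expectation. When checking an amended water against its measured
conductivity, the amendment's predicted contribution is added to the
*measured* background of the base water (delta form); stacking the full
amended-ion prediction on top of the measured background would count the
base water's own ions twice.

## Paired-design statistics

TEP measurements are triplicates per fish per condition; `collapse`
averages the three readings and subtracts the junction-potential offset
(default 0 — the offset magnitude is instrument-specific and configurable).
The inferential tools mirror the design: paired t (two-tailed) on per-fish
condition-minus-control differences; one-sample and two-sample t-tests
from summary statistics (mean ± SEM, n), Welch by default for the
two-sample case (both variants agree to two decimals at the group sizes in
play); and a subject-blocked one-way repeated-measures ANOVA followed by
Tukey's HSD on the within-subject error mean square, with q referred to
the studentized-range distribution at (k, df_error). No sphericity
correction is applied. The compact letter display uses the
insert-and-absorb algorithm at α = 0.05; no multiplicity correction is
applied across series (Tukey operates within a series only).

The omnibus F/p comes from `statsmodels.stats.anova.AnovaRM`; the test
suite cross-checks it against an independent long-hand sums-of-squares
computation, and the t machinery against `scipy.stats.ttest_*`.

## Synthetic experiments

No public repository holds raw TEP or two-sample flux data of this design,
so the package generates its own, with the structure the analysis assumes.

**TEP generator.** Fish baselines ~ Normal(control_mean, fish_sd);
condition values add a fixed effect; replicates add
Normal(0, replicate_sd). Defaults: control_mean −22.3 mV; fish_sd 7.1 mV,
back-calculated from the published grand control SEM (0.8 mV at n = 78:
0.8·√78 ≈ 7.1) — the true inter- vs. intra-fish variance partition is not
published, so all fish-level spread is assigned to the baseline;
replicate_sd 1.0 mV (instrument-level repeatability, an assumption).
Per-series condition effects (e.g. +14.4 mV for acid exposure, −15.5/+12.5
mV for 21/33 °C) are shipped as a data table. What the generator does
*not* emulate: order effects, settling-time dynamics, non-Gaussian tails,
fish-by-condition interaction. Passing tests therefore show that the
statistical machinery is correct under the stated model, not that real
gills obey it.

**Flux simulator.** Explicit two-pool bookkeeping at dt = duration/n_steps
(default 3600 steps/h; a convergence test shows halving dt moves the
noise-free estimate by ≪ the bias being measured): water and fish each
hold labelled and unlabelled Na; influx moves Na water→fish carrying
tracer at the water's instantaneous SA; efflux moves Na fish→water
carrying tracer at the fish's SA (initially 0). Total Na and total tracer
are conserved to machine precision at every step (asserted in tests).
Observables are only the four numbers of the real protocol, optionally
with multiplicative Gaussian sampling noise (default CV 2%). Defaults:
J_in 600, J_out −650 nmol g⁻¹ h⁻¹ (slightly negative net, matching the
acclimation-temperature balance), 2 g fish, 70 mL, 1.11×10⁶ cpm dose
(0.5 µCi at unit counting efficiency), 63 µmol/L water Na, 40 µmol/g
exchangeable internal pool (literature-typical; an explicit assumption,
overridable). cpm are continuous — Poisson counting noise is not
simulated.

Because the simulator implements backflux and the estimator ignores it,
the estimator's bias is an emergent quantity: `estimator_bias_curve` runs
the model noise-free over a list of durations and reports the relative
shortfall of the influx estimate. It is nonnegative and nondecreasing in
duration (~1.6% at 1 h, ~4.7% at 2 h at defaults). With an effectively
infinite internal pool the *backflux* component vanishes, but a
second-order residual (~0.7% at 1 h) remains from the arithmetic-mean-SA
approximation under a time-varying specific activity; the tests assert
exactly that decomposition.

Stochastic checks are seeded and sized explicitly: estimator recovery uses
100 replicates at defaults and compares the median J_in estimate to truth
(< 5%); the type-I-error check uses 400 null replicates at n = 6 and
accepts a rejection rate in a ~3σ band around 0.05; the power check uses
200 replicates with a 3×SEM effect and requires detection > 0.8.

## Numerical and interface choices

* All potentials mV; water ions µmol/L; plasma mmol/L; fluxes
  nmol g⁻¹ h⁻¹. CSV schemas embed units in column names.
* Randomness always flows through an explicit integer seed
  (`numpy.random.default_rng`); the `simulate` CLI command is
  byte-deterministic per seed.
* Run configuration is schema-validated (unknown keys rejected) and hashed
  into the run log.
* Degenerate inputs raise typed errors from a single exception hierarchy;
  sign-reversal in `driving_force_shift` is flagged in the result rather
  than raised, since an overshooting TEP change is physically meaningful.

## Known limitations

* The GHK treatment is monovalent-only and ideal-dilute; H⁺ permeability
  effects at low pH are representable only through the permeability ratio,
  not mechanistically.
* The conductivity predictor ignores ion pairing and DOC contributions.
* The flux design has two time points; no compartmental time-series
  fitting or Michaelis–Menten uptake kinetics is attempted.
* The generator's variance partition and the fish internal Na pool are
  assumptions (see above), so absolute bias/power numbers should be read
  as model properties, not measurements.
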