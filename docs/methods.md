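# Methods

## Models

Four deterministic compartment models describe a well-mixed virus–microbe
system. Densities are per ml, time is in hours. All share: logistic host
division at maximal rate *b* (susceptibles) or *b*′ (infected cells),
crowded by the total cell density *N*; adsorption of virions to
susceptible cells at rate constant φ (ml/h), each new infection consuming
one virion; per-capita cell washout (*d*, *d*′); and first-order virion
decay *m*.

* **lytic** (S, I, V): infections lyse at rate η (mean latent period 1/η),
  releasing β virions. Infected cells do not divide.
* **latent, implicit** (S, L, V): one lysogen class that divides at *qb*′
  and lyses at *p*η, with scaling factors *p*, *q* ∈ [0, 1] interpolating
  between strictly lytic (*q*=0, *p*=1) and strictly lysogenic
  (*q*=1, *p*=0) strategies; N = S + L.
* **latent, explicit** (S, I, L, V): a new infection integrates with
  probability *q*ₗ (becoming a lysogen that divides at *b*′) and enters
  the lytic pathway otherwise; lysogens induce to the lytic class at rate
  γ; N = S + I + L.
* **chronic** (S, C, V): infected cells divide at *b*′ and continuously
  bud virions at per-capita rate α without lysing; N = S + C.

The models exclude adsorption of virions to already-infected or latent
cells, prophage curing, partial-fidelity vertical transmission, and any
explicit nutrient dynamics.

**Logistic N in the lytic model.** Infected cells do not divide in the
lytic model, so whether they crowd susceptible growth is a genuine
modeling choice. The package defaults to N = S + I, counting all cells as
competitors consistently with the other three models; `lytic_rhs` exposes
`logistic_includes_infected=False` for the N = S variant. The choice does
not affect any R0 result: the linearization at (S\*, 0, 0) is identical
either way.

**Negative densities.** Right-hand sides and trajectories tolerate
compartment values down to −10⁻⁹·K (adaptive integrators undershoot zero
by tiny amounts) and reject anything more negative.

**Burst size** is any positive real, not an integer: it is a population
mean.

## Linearization and R0

Stability of the virus-free equilibrium S\* = K(1 − d/b) is governed by
the infected subsystem — every compartment carrying an infectious viral
genome (infected cells of any kind plus free virions). Its linearized
dynamics ẋ = (T + Σ)x are split into transmission events T
(epidemiological births: new infections φS\*, lysis bursts, divisions of
infected cells) and transitions Σ (lysis, washout, decay, adsorption
loss). −Σ⁻¹ is the expected-duration matrix, and R0 is the spectral
radius of the next-generation matrix −TΣ⁻¹. With the compartments ordered
cells-then-virions, Σ is lower triangular for all four models (virions
never feed a cell state at γ = 0), so the duration matrix is computed by
a triangular solve that preserves structural zeros exactly.

The closed-form expressions (see README) are hand-coded, decomposed into
a horizontal component (transmission through free virions) and a vertical
component (transmission through division of infected cells). The numeric
spectral-radius route reports totals only: the decomposition is defined
by the algebra, not by the matrix. The two routes are implemented
independently and agreement to 10⁻⁹ relative is enforced by the test
ensemble (1000 random life histories per model).

**Induction.** The nonlinear explicit-latency model supports any γ ≥ 0,
but every R0 operation requires γ = 0. Induction couples the lysogen and
lytic classes and changes the structure of the calculation; requesting an
NGM with γ ≠ 0 raises `UnsupportedConfigurationError` rather than
silently approximating.

**Mixed pathways.** For 0 < *q*ₗ < 1 the explicit-latency NGM is
reducible — the lysogenic and lytic pathways are both seeded but do not
feed each other at γ = 0 — and R0 is the maximum of the two branch
values. `R0Report.reducible` flags this case.

**Vertical fitness as a life-history ratio.** At the virus-free
equilibrium the vertical component collapses to
R_ver = (b′/d′)/(b/d): vertical transmission pays exactly when the
infected cell's lifetime reproduction ratio beats the susceptible one.
The value is invariant under scaling b′ and d′ by a common factor (R0
counts generations, not elapsed time), which is also why R0 and the
Malthusian growth rate rank strategies differently in general.

## Invasion analyses

**Thresholds.** `threshold_density` locates R0(S\*) = 1 by Brent's method
on a user bracket (default (10⁻⁶K, K)), to relative tolerance 10⁻¹² in
S. Two criteria are supported — the closed-form root and the zero of the
dominant eigenvalue of T + Σ — because their coincidence (the NGM
threshold theorem) is the package's standard end-to-end cross-check and
the basis of the acceptance script. An absent sign change raises
`NoThresholdError` rather than returning a boundary value.

**Crossover.** The horizontal branch (lytic closed form) is nondecreasing
in S\* and the vertical branch b′(1 − S\*/K)/d′ is decreasing, so their
difference crosses zero at most once on (0, K); monotonicity of the
difference is verified on a 1000-point grid before root-finding and the
crossing S꜀ is then bracketed on (10⁻⁹K, K).

**Winner maps and grids.** `strategy_map` evaluates the lytic, chronic,
and pure-vertical closed forms on a density grid and records the argmax;
values within 10⁻⁹ relative of the maximum are reported jointly as ties,
never broken silently. `r0_grid` tabulates log₁₀ of the lytic R0 over a
(β, S\*) grid with the lysis-survival fraction η/(η + d′) exposed as a
single `eta_factor`; R0 = 0 points are recorded as −∞.

**S\* as a free axis.** All sweep analyses treat susceptible density as
an environmental axis, decoupled from the K(1 − d/b) equilibrium formula;
the equilibrium helper exists for when *b* and *d* are known.

## Built-in fixtures

The `fig2`/`fig3_*`/`fig4_*` bundles carry the parameter sets of the
package's three canonical analyses (the R0 contour sweep, the
horizontal/vertical crossover, and the three-strategy winner map); K =
7.5×10⁷ ml⁻¹ throughout. Two conventions fill rates those analyses leave
unconstrained, and both are explicit, overridable assumptions rather than
hidden defaults:

* lytic bundles set d′ = 0 with η = 1 h⁻¹, the fast-lysis limit
  η/(η + d′) = 1;
* the crossover analysis reuses m = 1/24 h⁻¹ from the sweep bundle
  (`fig3_horizontal` holds the horizontal-branch parameters; the three
  curve bundles hold the lysogen life histories b′/d′ = 0.427, 1.227,
  4.167).

Susceptible growth is b = 1 h⁻¹, d = 0, so the virus-free equilibrium
sits at carrying capacity and S\* is swept freely. The `fig4_chronic`
bundle's β and η are inert placeholders (the chronic model uses neither).

## Simulation and invasion trials

`integrate` wraps `scipy.integrate.solve_ivp` with LSODA (stiff-capable)
at rtol 10⁻⁸ and atol 10⁻³ ml⁻¹ by default; solver failures and negative
excursions beyond tolerance raise instead of being swallowed.

`invasion_trial` seeds the virus-free equilibrium with a rare inoculum
(default one infected cell per ml) and classifies the outcome from the
total infected-genome density Y (infected cells of all kinds plus
virions, mirroring the linearized subsystem):

* **invade** — integration stopped because infected cells reached 1% of
  S\* or susceptibles drifted 2% from S\* (the linear regime is ending),
  and Y grew at least 10-fold from its post-transient minimum;
* **extinct** — Y fell below 10⁻⁶ of the inoculum;
* **indeterminate** — neither bound within the horizon (default 2000 h).

All bounds are exposed as configuration. Trials integrate at rtol 10⁻⁹
with an absolute tolerance far below the extinction threshold, locate the
stopping time with a cheap event-driven pass, then resample 1500 points
for the rate fit.

**Growth-rate estimation.** The early exponential rate is the slope of a
least-squares line through log Y over the asymptotic tail: after the
transient extremum (minimum for growing, maximum for decaying
trajectories), restricted to the final four e-foldings and the second
half of the post-extremum span. Two error sources bound its accuracy, and
the verification ensemble is designed around them:

* *Mode mixing.* A single slope identifies the dominant eigenvalue of
  T + Σ only when the subdominant modes have died within the window. The
  simulation-consistency tests therefore seed all infected compartments
  (`inoculum_type="mixed"`, so every mode is excited even in reducible
  systems) and assert the 5% rate match only where the relative spectral
  gap (λ₁ − λ₂)/|λ₁| is at least 0.5. Near-degenerate subsystems mix
  modes for longer than the linear regime lasts — lysis bursts can
  amplify a subdominant mode by 10²–10³ — and no finite-window fit can
  separate them; outcome classification is asserted unconditionally.
* *Logistic crowding.* In a growing trial the infected cells themselves
  begin to crowd the logistic term near the end of the window, biasing
  the slope by about b′·(cells/K). Rate-fit trials therefore use a small
  inoculum (10⁻⁴ ml⁻¹) and stop at 10⁻⁴ of S\*, keeping this bias well
  under the 5% tolerance while retaining ~12 e-foldings of growth.

The verification ensemble draws per-capita rates log-uniform on
[10⁻³, 10] h⁻¹, adsorption rates log-uniform on [10⁻¹², 10⁻⁸] ml/h,
burst sizes log-uniform on [1, 10³], and probabilities uniform on [0, 1]
(γ = 0) — the ranges typical of aquatic phage–bacteria systems. These
draws exercise the mathematics across realistic orders of magnitude; they
do not emulate correlations between traits (e.g. burst size versus latent
period trade-offs) present in real virus populations, so passing tests
certify the framework's internal consistency, not any empirical
prediction for a particular system.

## Scope and limitations

* All R0 analyses assume no induction (γ = 0); induction feedback is out
  of scope.
* R0 is an invasion measure at a fixed environment: it ignores feedback
  of viral proliferation on susceptible density, long-term coexistence,
  oscillations, and evolutionary dynamics (R0 maximization is not implied
  for mixed transmission modes).
* The models are deterministic; demographic stochasticity at the
  single-genome densities the trials use is not represented — trial
  inocula are numerical probes of the linearized dynamics, not counts of
  discrete virions.
* Units are fixed (hours, ml); there is no unit-conversion layer.
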