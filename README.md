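# virofit

Cell-centric invasion fitness for viruses of microbes.

Most ecological theory for phage and other microbial viruses counts free
virus particles. But the unit of selection is the viral *genome*, which can
proliferate without ever leaving a cell — integrated as a prophage, or
persisting episomally in a chronically producing cell. `virofit` implements
a basic reproduction number R0 that counts **infected cells**: the average
number of new infected cells produced by a single infected cell and its
progeny virions in an otherwise susceptible population. On this common
scale, obligately lytic, temperate (latent), and chronic strategies can be
compared directly, and the winning strategy becomes a function of the
environment — chiefly the susceptible host density S\*.

The package is for quantitative microbial ecologists and modelers: it
provides the nonlinear population models, the linearized theory, and the
analyses connecting them, as both a Python library and a `virofit` CLI.

## What it computes

Four ODE models of virus–microbe dynamics (densities in ml⁻¹, rates in
h⁻¹), sharing logistic host growth *bS*(1 − *N*/*K*), adsorption φ*SV*,
washout, and virion decay *mV*:

* **lytic** — susceptible S, infected I, virions V; infected cells lyse at
  rate η releasing β virions;
* **latent, implicit** — S, lysogens L, V; lysogens grow at *qb*′ and lyse
  at *p*η;
* **latent, explicit** — S, I, L, V; an infection integrates with
  probability *q*ₗ, lysogens induce at rate γ (γ = 0 for all R0 analyses);
* **chronic** — S, chronically infected C, V; C cells bud virions at rate
  α without lysing.

For each model the infected subsystem linearized at the virus-free
equilibrium (S\*, 0, …, 0) is split as ẋ = (T + Σ)x into transmission
(T) and transition (Σ) matrices, and

> R0 = ρ(−TΣ⁻¹),

the spectral radius of the next-generation matrix. Closed forms and their
horizontal/vertical decomposition:

| strategy | R0 |
|---|---|
| lytic | β · φS\*/(φS\* + m) · η/(η + d′) |
| latent (implicit) | qb′(1 − S\*/K)/(d′ + pη) + β · φS\*/(φS\* + m) · pη/(pη + d′) |
| latent (explicit, γ = 0) | max{ b′(1 − S\*/K)/d′, (1 − qₗ) · β · φS\*/(φS\* + m) · η/(η + d′) } |
| chronic | α/d′ · φS\*/(φS\* + m) + b′(1 − S\*/K)/d′ |

On top of these: invasion thresholds in S\* (where R0 = 1, equivalently
where the dominant eigenvalue of T + Σ crosses zero), the
horizontal/vertical crossover density S꜀, winner maps across strategies,
log₁₀ R0 contour grids, and nonlinear invasion trials that verify the
linearized predictions by direct simulation.

## Worked example

A burst size of 50, adsorption rate 6.7×10⁻¹⁰ ml/h, virion decay 1/24 h⁻¹,
and 10⁷ susceptible cells/ml, in the fast-lysis limit:

```bash
$ virofit --quiet r0 --model lytic --fixture fig2 --S-star 1e7 --beta 50
{
  "closed_form": {
    "model": "lytic",
    "method": "closed_form",
    "S_star": 10000000.0,
    "R0_total": 6.926257753273604,
    "R0_horizontal": 6.926257753273604,
    "R0_vertical": 0.0
  },
  "ngm_numeric": {
    "model": "lytic",
    "method": "ngm_numeric",
    "S_star": 10000000.0,
    "R0_total": 6.926257753273604,
    "R0_horizontal": null,
    "R0_vertical": null
  }
}
```

R0 ≈ 6.93 > 1: each virion is adsorbed before decaying with probability
φS\*/(φS\* + m) ≈ 0.139, every infection lyses, and the burst of 50
virions therefore yields ~6.9 new infected cells — the virus invades.
The closed form and the independent spectral-radius computation agree to
machine precision.

Where does lysing stop paying? The crossover densities S꜀ between
horizontal (always lyse) and vertical (always integrate) transmission for
three lysogen life histories:

```bash
$ virofit --quiet sweep --kind fig3
curve,b_prime,d_prime,ratio,S_c
fig3_curve1,0.32,0.75,0.4266666666666667,531422.4034741804
fig3_curve2,0.54,0.44,1.2272727272727273,1532114.0378657107
fig3_curve3,1.0,0.24,4.166666666666667,5226465.696459112
```

Fitter lysogens (larger b′/d′) keep vertical transmission competitive up
to higher host densities: S꜀ rises from ~5.3×10⁵ to ~5.2×10⁶ cells/ml.
Below S꜀ integration wins; above it lysis wins. `sweep --kind fig4`
extends the comparison to a chronic strategy, producing contiguous
vertical → chronic → lytic winner bands along increasing S\*.

Library use mirrors the CLI:

```python
import virofit as vf

params = vf.fixture("fig4_chronic")        # b'=0.68, d'=0.63, alpha=20, ...
report = vf.r0_chronic_closed(params, 2e7)
print(report.total, report.horizontal, report.vertical)
```

## Documentation

`docs/methods.md` describes the models and their assumptions, the
linearization, the parameter conventions of the built-in fixtures, the
numerical choices (root-finding, integration tolerances, growth-rate
estimation), and known limitations.
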