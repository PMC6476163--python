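"""Built-in reference parameter sets for the standard analyses.

These bundles carry the life-history values used by the package's three
canonical analyses:

* ``fig2`` — obligately lytic contour sweep of R0 over burst size and
  susceptible density.
* ``fig3_curve1..3`` / ``fig3_horizontal`` — horizontal-vs-vertical
  crossover for temperate strategies, three lysogen life histories ordered
  by increasing b'/d'.
* ``fig4_lytic`` / ``fig4_chronic`` / ``fig4_temperate`` — three-strategy
  map of the winning strategy along the susceptible-density axis.

Where an analysis leaves a rate unconstrained, the bundles adopt explicit
conventions rather than hidden defaults: the lytic bundles for the sweep,
crossover, and strategy map set d' = 0 with eta = 1 h^-1, i.e. the
fast-lysis limit eta/(eta + d') = 1 (every adsorbed virion's infection
lyses); the crossover analysis reuses m = 1/24 h^-1 from the sweep bundle.
Both are package assumptions, overridable via ``replace``.  Susceptible
growth is fixed at b = 1 h^-1, d = 0 so that the virus-free equilibrium
sits at carrying capacity; S* is then swept as a free environmental axis.
"""

from __future__ import annotations

import dataclasses

from .parameters import (
    ChronicParameters,
    CommonParameters,
    LatentImplicitParameters,
    StrategyParameters,
)

__all__ = ["fixture", "fixture_names", "FIXTURES"]

_K = 7.5e7  # cells/ml, shared carrying capacity


def _temperate(b_prime: float, d_prime: float) -> LatentImplicitParameters:
    # Pure lysogeny (q=1, p=0); beta/m/eta retained from the sweep bundle
    # but inert since p = 0.
    return LatentImplicitParameters(
        b=1.0, b_prime=b_prime, K=_K, phi=6.7e-10, d=0.0, d_prime=d_prime,
        beta=50.0, m=1.0 / 24.0, eta=1.0, p=0.0, q=1.0,
    )


FIXTURES: dict = {
    # Lytic sweep bundle: beta is the swept axis, default 50.
    "fig2": CommonParameters(
        b=1.0, b_prime=1.0, K=_K, phi=6.7e-10, d=0.0, d_prime=0.0,
        beta=50.0, m=1.0 / 24.0, eta=1.0,
    ),
    # Horizontal branch of the crossover analysis (fast-lysis limit).
    "fig3_horizontal": CommonParameters(
        b=1.0, b_prime=1.0, K=_K, phi=6.7e-10, d=0.0, d_prime=0.0,
        beta=50.0, m=1.0 / 24.0, eta=1.0,
    ),
    # Three lysogen life histories, bottom to top by b'/d'.
    "fig3_curve1": _temperate(0.32, 0.75),
    "fig3_curve2": _temperate(0.54, 0.44),
    "fig3_curve3": _temperate(1.0, 0.24),
    # Strategy-map bundles.
    "fig4_lytic": CommonParameters(
        b=1.0, b_prime=1.0, K=_K, phi=6.7e-10, d=0.0, d_prime=0.0,
        beta=100.0, m=0.13, eta=1.0,
    ),
    "fig4_chronic": ChronicParameters(
        b=1.0, b_prime=0.68, K=_K, phi=3.4e-10, d=0.0, d_prime=0.63,
        beta=1.0, m=0.04, eta=0.0, alpha=20.0,
    ),
    "fig4_temperate": LatentImplicitParameters(
        b=1.0, b_prime=0.54, K=_K, phi=6.7e-10, d=0.0, d_prime=0.44,
        beta=50.0, m=1.0 / 24.0, eta=1.0, p=0.0, q=1.0,
    ),
}


def fixture_names() -> tuple:
    return tuple(FIXTURES)


def fixture(name: str, **overrides) -> StrategyParameters:
    """Return a copy of the named bundle, optionally with fields replaced."""
    try:
        base = FIXTURES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(FIXTURES)}"
        ) from None
    if overrides:
        return dataclasses.replace(base, **overrides)
    return base
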