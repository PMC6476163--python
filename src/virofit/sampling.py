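"""Random life-history ensembles for property checking and sweeps.

Draws span the ranges typical of virus-microbe systems: per-capita rates
log-uniform over [1e-3, 10] h^-1, adsorption rates log-uniform over
[1e-12, 1e-8] ml/h, burst sizes log-uniform over [1, 1000], probabilities
and scaling factors uniform on [0, 1], carrying capacity fixed at
7.5e7 ml^-1 unless overridden.  Induction is held at gamma = 0 so every
draw is valid for the R0 machinery.
"""

from __future__ import annotations

import numpy as np

from .parameters import (
    ChronicParameters,
    CommonParameters,
    LatentExplicitParameters,
    LatentImplicitParameters,
    StrategyParameters,
    parameter_class,
)

__all__ = ["sample_parameters", "sample_invasion_setting"]

RATE_RANGE = (1e-3, 1e1)
PHI_RANGE = (1e-12, 1e-8)
BETA_RANGE = (1e0, 1e3)
DEFAULT_K = 7.5e7


def _log_uniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def sample_parameters(model_id: str, rng: np.random.Generator, *,
                      K: float = DEFAULT_K) -> StrategyParameters:
    """Draw one random valid parameter bundle for ``model_id``."""
    rate = lambda: _log_uniform(rng, *RATE_RANGE)
    common = dict(
        b=rate(), b_prime=rate(), K=K,
        phi=_log_uniform(rng, *PHI_RANGE),
        d=rate(), d_prime=rate(),
        beta=_log_uniform(rng, *BETA_RANGE),
        m=rate(), eta=rate(),
    )
    cls = parameter_class(model_id)
    if cls is CommonParameters:
        return CommonParameters(**common)
    if cls is LatentImplicitParameters:
        return LatentImplicitParameters(
            **common, p=float(rng.uniform()), q=float(rng.uniform())
        )
    if cls is LatentExplicitParameters:
        return LatentExplicitParameters(
            **common, q_l=float(rng.uniform()), gamma=0.0
        )
    return ChronicParameters(**common, alpha=rate())


def sample_invasion_setting(model_id: str, rng: np.random.Generator, *,
                            K: float = DEFAULT_K) -> StrategyParameters:
    """Draw a bundle with b > d, so a positive virus-free equilibrium
    S* = K(1 - d/b) exists for seeding invasion trials."""
    params = sample_parameters(model_id, rng, K=K)
    d = params.b * float(rng.uniform(0.05, 0.95))
    return params.replace(d=d)
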