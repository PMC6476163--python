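"""Right-hand sides of the four nonlinear virus-microbe ODE systems.

All models share the structural motifs: logistic cell growth b*X*(1 - N/K)
with N counting all cells, horizontal infection phi*S*V (which removes one
free virion per new infection), per-capita washout, and first-order virion
decay m*V.  They differ in how the infected class propagates the viral
genome:

* lytic: infected cells I lyse at rate eta, releasing beta virions.
* latent_implicit: lysogens L grow at q*b', lyse at p*eta.
* latent_explicit: infections split q_l : (1-q_l) into lysogens L and
  lytic infections I; lysogens induce to I at rate gamma.
* chronic: infected cells C grow and continuously bud virions at rate
  alpha without lysing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import (
    COMPARTMENTS,
    ChronicParameters,
    CommonParameters,
    LatentExplicitParameters,
    LatentImplicitParameters,
    StrategyParameters,
    parameter_class,
)

__all__ = [
    "InvalidStateError",
    "ModelState",
    "NEGATIVE_TOLERANCE",
    "lytic_rhs",
    "latent_implicit_rhs",
    "latent_explicit_rhs",
    "chronic_rhs",
    "rhs",
    "rhs_function",
]

#: Compartments may undershoot zero by at most this fraction of K before the
#: state is considered invalid (adaptive integrators routinely produce tiny
#: negative excursions).
NEGATIVE_TOLERANCE = 1e-9


class InvalidStateError(ValueError):
    """A compartment density is negative beyond integrator tolerance."""


@dataclass(frozen=True)
class ModelState:
    """Compartment densities (ml^-1) for one model variant."""

    model_id: str
    compartments: tuple

    def __post_init__(self) -> None:
        labels = COMPARTMENTS.get(self.model_id)
        if labels is None:
            raise InvalidStateError(f"unknown model {self.model_id!r}")
        if len(self.compartments) != len(labels):
            raise InvalidStateError(
                f"{self.model_id} expects {len(labels)} compartments "
                f"{labels}, got {len(self.compartments)}"
            )

    @property
    def labels(self) -> tuple:
        return COMPARTMENTS[self.model_id]

    def asarray(self) -> np.ndarray:
        return np.asarray(self.compartments, dtype=float)


def _as_array(state, model_id: str) -> np.ndarray:
    if isinstance(state, ModelState):
        if state.model_id != model_id:
            raise InvalidStateError(
                f"state is for model {state.model_id!r}, expected {model_id!r}"
            )
        y = state.asarray()
    else:
        y = np.asarray(state, dtype=float)
    n = len(COMPARTMENTS[model_id])
    if y.shape != (n,):
        raise InvalidStateError(
            f"{model_id} expects {n} compartments, got shape {y.shape}"
        )
    return y


def _check_nonnegative(y: np.ndarray, K: float) -> None:
    floor = -NEGATIVE_TOLERANCE * K
    if np.min(y) < floor:
        raise InvalidStateError(
            f"negative compartment density {np.min(y)!r} below tolerance {floor!r}"
        )


def lytic_rhs(state, params: CommonParameters, *,
              logistic_includes_infected: bool = True,
              check: bool = True) -> np.ndarray:
    """Time derivatives (dS, dI, dV) of the obligately lytic model.

    The logistic crowding term counts N = S + I by default, treating
    infected cells as competitors even though they do not divide; pass
    ``logistic_includes_infected=False`` for the N = S variant.
    """
    y = _as_array(state, "lytic")
    if check:
        _check_nonnegative(y, params.K)
    S, I, V = y
    N = S + I if logistic_includes_infected else S
    infection = params.phi * S * V
    dS = params.b * S * (1.0 - N / params.K) - infection - params.d * S
    dI = infection - params.eta * I - params.d_prime * I
    dV = params.beta * params.eta * I - infection - params.m * V
    return np.array([dS, dI, dV])


def latent_implicit_rhs(state, params: LatentImplicitParameters, *,
                        check: bool = True) -> np.ndarray:
    """Time derivatives (dS, dL, dV) of the implicit latency model, N = S + L."""
    y = _as_array(state, "latent_implicit")
    if check:
        _check_nonnegative(y, params.K)
    S, L, V = y
    N = S + L
    crowding = 1.0 - N / params.K
    infection = params.phi * S * V
    lysis = params.p * params.eta * L
    dS = params.b * S * crowding - infection - params.d * S
    dL = params.q * params.b_prime * L * crowding + infection - lysis - params.d_prime * L
    dV = params.beta * lysis - infection - params.m * V
    return np.array([dS, dL, dV])


def latent_explicit_rhs(state, params: LatentExplicitParameters, *,
                        check: bool = True) -> np.ndarray:
    """Time derivatives (dS, dI, dL, dV) of the explicit latency model.

    N = S + I + L.  The infection flux phi*S*V splits exactly into
    (1 - q_l) -> I and q_l -> L; induction moves lysogens to the lytic
    class at rate gamma.
    """
    y = _as_array(state, "latent_explicit")
    if check:
        _check_nonnegative(y, params.K)
    S, I, L, V = y
    N = S + I + L
    crowding = 1.0 - N / params.K
    infection = params.phi * S * V
    induction = params.gamma * L
    dS = params.b * S * crowding - infection - params.d * S
    dI = (1.0 - params.q_l) * infection - params.eta * I + induction - params.d_prime * I
    dL = params.q_l * infection + params.b_prime * L * crowding - induction - params.d_prime * L
    dV = params.beta * params.eta * I - infection - params.m * V
    return np.array([dS, dI, dL, dV])


def chronic_rhs(state, params: ChronicParameters, *,
                check: bool = True) -> np.ndarray:
    """Time derivatives (dS, dC, dV) of the chronic model, N = S + C.

    Chronically infected cells divide (logistic, rate b') and bud virions
    at per-capita rate alpha without lysing.
    """
    y = _as_array(state, "chronic")
    if check:
        _check_nonnegative(y, params.K)
    S, C, V = y
    N = S + C
    crowding = 1.0 - N / params.K
    infection = params.phi * S * V
    dS = params.b * S * crowding - infection - params.d * S
    dC = params.b_prime * C * crowding + infection - params.d_prime * C
    dV = params.alpha * C - infection - params.m * V
    return np.array([dS, dC, dV])


_RHS = {
    "lytic": lytic_rhs,
    "latent_implicit": latent_implicit_rhs,
    "latent_explicit": latent_explicit_rhs,
    "chronic": chronic_rhs,
}


def rhs(model_id: str, state, params: StrategyParameters, **kwargs) -> np.ndarray:
    """Evaluate the RHS of ``model_id`` at ``state``."""
    parameter_class(model_id)  # validates model_id
    if not isinstance(params, parameter_class(model_id)):
        raise TypeError(
            f"expected {parameter_class(model_id).__name__} for {model_id!r}, "
            f"got {type(params).__name__}"
        )
    return _RHS[model_id](state, params, **kwargs)


def rhs_function(model_id: str, params: StrategyParameters, **kwargs):
    """Return ``f(t, y)`` suitable for :func:`scipy.integrate.solve_ivp`.

    State validity is not re-checked inside the integrator loop; callers
    check the returned trajectory instead.
    """
    fn = _RHS[model_id]

    def f(t, y):
        return fn(y, params, check=False, **kwargs)

    return f
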