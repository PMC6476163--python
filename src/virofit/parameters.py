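"""Life-history parameter bundles for virus-microbe population models.

Four model variants share a common core of rates (all in h^-1), densities
(ml^-1), and dimensionless quantities (burst size, probabilities):

``lytic``
    Obligately lytic infection: susceptible cells S, lytically infected
    cells I, free virions V.
``latent_implicit``
    Latency with implicit infection bookkeeping: S, lysogens L, V.  The
    scaling factors ``p`` (lysis) and ``q`` (lysogen growth) interpolate
    between purely lytic (q=0, p=1) and purely lysogenic (q=1, p=0)
    strategies.
``latent_explicit``
    Latency with an explicit lytically infected class: S, I, L, V.  A new
    infection integrates (becomes a lysogen) with probability ``q_l`` and
    enters the lytic pathway otherwise; lysogens induce at rate ``gamma``.
``chronic``
    Chronic (productive, non-lysing) infection: S, chronically infected
    cells C, V; virions bud from C at rate ``alpha``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import ClassVar, Mapping, Union

__all__ = [
    "MODEL_IDS",
    "PARAM_KEYS",
    "COMPARTMENTS",
    "ParameterError",
    "CommonParameters",
    "LatentImplicitParameters",
    "LatentExplicitParameters",
    "ChronicParameters",
    "StrategyParameters",
    "parameter_class",
    "validate_parameters",
    "virus_free_equilibrium",
    "params_from_dict",
    "params_to_dict",
]

MODEL_IDS = ("lytic", "latent_implicit", "latent_explicit", "chronic")

#: Flat config-file key order.  Keys absent for a given model are null.
PARAM_KEYS = (
    "b", "b_prime", "K", "phi", "d", "d_prime", "beta", "m", "eta",
    "p", "q", "q_l", "gamma", "alpha",
)

#: Ordered compartment labels per model.
COMPARTMENTS = {
    "lytic": ("S", "I", "V"),
    "latent_implicit": ("S", "L", "V"),
    "latent_explicit": ("S", "I", "L", "V"),
    "chronic": ("S", "C", "V"),
}


class ParameterError(ValueError):
    """A life-history parameter violates a model invariant."""


@dataclass(frozen=True)
class CommonParameters:
    """Parameters shared by all model variants (the obligately lytic set).

    Parameters
    ----------
    b, b_prime : float
        Maximal growth rates of susceptible and infected cells (h^-1).
    K : float
        Cell carrying capacity (ml^-1).
    phi : float
        Adsorption rate constant (ml h^-1).
    d, d_prime : float
        Death/washout rates of susceptible and infected cells (h^-1).
    beta : float
        Burst size (virions released per lysis, dimensionless, > 0).
    m : float
        Virion decay rate (h^-1).
    eta : float
        Lysis rate (h^-1); 1/eta is the mean latent period.
    """

    b: float
    b_prime: float
    K: float
    phi: float
    d: float
    d_prime: float
    beta: float
    m: float
    eta: float

    model_id: ClassVar[str] = "lytic"

    def __post_init__(self) -> None:
        validate_parameters(self)

    def _check(self) -> None:
        for name in ("b", "b_prime", "phi", "d", "d_prime", "m", "eta"):
            value = getattr(self, name)
            if not value >= 0.0:
                raise ParameterError(f"{name} must be nonnegative, got {value!r}")
        if not self.K > 0.0:
            raise ParameterError(f"K must be positive, got {self.K!r}")
        if not self.beta > 0.0:
            raise ParameterError(f"beta must be positive, got {self.beta!r}")

    def virus_free_equilibrium(self) -> float:
        """Susceptible density S* = K(1 - d/b) of the virus-free state."""
        return virus_free_equilibrium(self.b, self.d, self.K)

    def replace(self, **changes) -> "CommonParameters":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return params_to_dict(self)


@dataclass(frozen=True)
class LatentImplicitParameters(CommonParameters):
    """Latency with implicit infections: adds lysis/latency scaling factors.

    ``p`` scales the lysis rate of lysogens (effective rate p*eta) and
    ``q`` scales lysogen growth (effective rate q*b_prime); both lie in
    [0, 1].  (q=0, p=1) recovers the obligately lytic model; (q=1, p=0)
    is pure lysogeny.
    """

    p: float = 1.0
    q: float = 0.0

    model_id: ClassVar[str] = "latent_implicit"

    def _check(self) -> None:
        super()._check()
        if not 0.0 <= self.p <= 1.0:
            raise ParameterError(f"p outside [0,1], got {self.p!r}")
        if not 0.0 <= self.q <= 1.0:
            raise ParameterError(f"q outside [0,1], got {self.q!r}")


@dataclass(frozen=True)
class LatentExplicitParameters(CommonParameters):
    """Latency with explicit lytic infections: integration and induction.

    ``q_l`` is the probability that a new infection integrates (lysogeny);
    ``gamma`` is the induction rate of lysogens (h^-1).  The nonlinear
    dynamics support any gamma >= 0; the R0 machinery requires gamma = 0.
    """

    q_l: float = 0.0
    gamma: float = 0.0

    model_id: ClassVar[str] = "latent_explicit"

    def _check(self) -> None:
        super()._check()
        if not 0.0 <= self.q_l <= 1.0:
            raise ParameterError(f"q_l outside [0,1], got {self.q_l!r}")
        if not self.gamma >= 0.0:
            raise ParameterError(f"gamma must be nonnegative, got {self.gamma!r}")


@dataclass(frozen=True)
class ChronicParameters(CommonParameters):
    """Chronic (productive) infection: adds the virion budding rate alpha."""

    alpha: float = 0.0

    model_id: ClassVar[str] = "chronic"

    def _check(self) -> None:
        super()._check()
        if not self.alpha >= 0.0:
            raise ParameterError(f"alpha must be nonnegative, got {self.alpha!r}")


StrategyParameters = Union[
    CommonParameters,
    LatentImplicitParameters,
    LatentExplicitParameters,
    ChronicParameters,
]

_PARAM_CLASSES = {
    "lytic": CommonParameters,
    "latent_implicit": LatentImplicitParameters,
    "latent_explicit": LatentExplicitParameters,
    "chronic": ChronicParameters,
}


def parameter_class(model_id: str) -> type:
    """Parameter dataclass for ``model_id``."""
    try:
        return _PARAM_CLASSES[model_id]
    except KeyError:
        raise ParameterError(
            f"unknown model {model_id!r}; expected one of {MODEL_IDS}"
        ) from None


def validate_parameters(params: StrategyParameters) -> StrategyParameters:
    """Validate a parameter bundle, raising on the first violated invariant.

    Returns the bundle unchanged when every invariant holds, so it can be
    used inline: ``p = validate_parameters(p)``.
    """
    if not isinstance(params, CommonParameters):
        raise ParameterError(f"not a parameter bundle: {params!r}")
    params._check()
    return params


def virus_free_equilibrium(b: float, d: float, K: float) -> float:
    """Susceptible density of the virus-free equilibrium, S* = K(1 - d/b).

    Returns 0 when d >= b (growth cannot balance washout, so the only
    nonnegative equilibrium is extinction).  Raises for b = 0, where the
    expression is undefined.
    """
    if b <= 0.0:
        raise ParameterError("virus-free equilibrium undefined for b = 0")
    if d < 0.0:
        raise ParameterError(f"d must be nonnegative, got {d!r}")
    if K <= 0.0:
        raise ParameterError(f"K must be positive, got {K!r}")
    if d >= b:
        return 0.0
    return K * (1.0 - d / b)


def params_to_dict(params: StrategyParameters) -> dict:
    """Flatten a bundle to the full config key set (missing keys -> None)."""
    raw = dataclasses.asdict(params)
    return {key: raw.get(key) for key in PARAM_KEYS}


def params_from_dict(model_id: str, mapping: Mapping) -> StrategyParameters:
    """Build a bundle for ``model_id`` from a flat key-value mapping.

    Keys irrelevant to the model must be absent or null; unknown keys are
    rejected so that typos in config files fail loudly.
    """
    cls = parameter_class(model_id)
    field_names = {f.name for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in mapping.items():
        if key not in PARAM_KEYS:
            raise ParameterError(f"unknown parameter key {key!r}")
        if value is None:
            continue
        if key not in field_names:
            raise ParameterError(
                f"parameter {key!r} does not apply to model {model_id!r}"
            )
        kwargs[key] = float(value)
    missing = {
        f.name
        for f in dataclasses.fields(cls)
        if f.default is dataclasses.MISSING
    } - set(kwargs)
    if missing:
        raise ParameterError(
            f"missing required parameter(s) for {model_id!r}: {sorted(missing)}"
        )
    return cls(**kwargs)
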