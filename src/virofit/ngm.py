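"""Next-generation-matrix computation of the basic reproduction number R0.

For each model the dynamics of the infected subsystem (every class that
carries an infectious viral genome: infected cells, lysogens, chronically
infected cells, and free virions), linearized about the virus-free
equilibrium (S*, 0, ..., 0), take the form ``x_dot = (T + Sigma) x``.

T holds transmission rates ("epidemiological births" of infected classes):
new infections of cells by virions (horizontal, rate phi*S*), lysis bursts
creating virions, and divisions of infected cells (vertical).  Sigma holds
transitions and losses: lysis, washout, virion decay and adsorption.  R0 is
the spectral radius of the next-generation matrix -T Sigma^{-1}; the entries
of -Sigma^{-1} are expected state durations, so each row of the NGM reads as
"births per unit time x expected time in state".

R0 is cell-centric: it counts the average number of new infected cells
produced by a single infected cell and its progeny virions in an otherwise
susceptible population, which makes lytic, latent, and chronic strategies
directly comparable.  Closed-form R0 expressions per model decompose into a
horizontal component (via free virions) and a vertical component (via
division of infected cells).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.linalg import solve_triangular

from .parameters import (
    ChronicParameters,
    CommonParameters,
    LatentExplicitParameters,
    LatentImplicitParameters,
    StrategyParameters,
    parameter_class,
    validate_parameters,
)

__all__ = [
    "NGMError",
    "DegenerateModelError",
    "UnsupportedConfigurationError",
    "NGMDecomposition",
    "R0Report",
    "INFECTED_COMPARTMENTS",
    "build_ngm",
    "expected_durations",
    "dominant_eigenvalue",
    "spectral_gap",
    "r0_numeric",
    "r0_closed",
    "r0_lytic_closed",
    "r0_latent_implicit_closed",
    "r0_latent_explicit_closed",
    "r0_chronic_closed",
    "r0_vertical_identity",
]

#: Infected-subsystem labels (order of rows/columns in T and Sigma).
INFECTED_COMPARTMENTS = {
    "lytic": ("I", "V"),
    "latent_implicit": ("L", "V"),
    "latent_explicit": ("I", "L", "V"),
    "chronic": ("C", "V"),
}


class NGMError(ValueError):
    """Base class for next-generation-matrix failures."""


class DegenerateModelError(NGMError):
    """Parameters make the infected subsystem non-dissipative or a closed
    form's denominator vanish (e.g. immortal lysogens with d' = p*eta = 0)."""


class UnsupportedConfigurationError(NGMError):
    """Configuration outside the scope of the R0 machinery (gamma != 0)."""


@dataclass(frozen=True)
class NGMDecomposition:
    """Transmission/transition split of the linearized infected subsystem.

    Attributes
    ----------
    model_id : str
    S_star : float
        Susceptible density (ml^-1) at which the system is linearized.
    T : ndarray
        Transmission matrix (entrywise nonnegative).
    Sigma : ndarray
        Transition matrix (negative diagonal, nonnegative off-diagonal).
    compartment_labels : tuple of str
    """

    model_id: str
    S_star: float
    T: np.ndarray
    Sigma: np.ndarray
    compartment_labels: tuple


@dataclass(frozen=True)
class R0Report:
    """Basic reproduction number with its transmission-route decomposition.

    ``horizontal``/``vertical`` are populated only by the closed-form
    routes; the numeric spectral-radius route reports the total alone.
    For the explicit latency model with mixed pathways (0 < q_l < 1) the
    NGM is reducible and the total is the maximum of the two routes;
    ``reducible`` flags that case.
    """

    model_id: str
    total: float
    method: str  # "closed_form" | "ngm_numeric"
    S_star: float
    horizontal: Optional[float] = None
    vertical: Optional[float] = None
    reducible: bool = False

    def to_dict(self) -> dict:
        return {
            "model": self.model_id,
            "method": self.method,
            "S_star": self.S_star,
            "R0_total": self.total,
            "R0_horizontal": self.horizontal,
            "R0_vertical": self.vertical,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def _check_s_star(S_star: float) -> float:
    S_star = float(S_star)
    if not np.isfinite(S_star) or S_star < 0.0:
        raise NGMError(f"S_star must be finite and nonnegative, got {S_star!r}")
    return S_star


def build_ngm(model_id: str, params: StrategyParameters, S_star: float) -> NGMDecomposition:
    """Build the (T, Sigma) decomposition at susceptible density ``S_star``.

    For the explicit latency model this requires gamma = 0 (no induction);
    induction feedback couples the lysogen and lytic classes in a way the
    present R0 analysis does not cover, so gamma != 0 is an error rather
    than a silent approximation.
    """
    validate_parameters(params)
    cls = parameter_class(model_id)
    if not isinstance(params, cls):
        raise NGMError(
            f"expected {cls.__name__} for model {model_id!r}, "
            f"got {type(params).__name__}"
        )
    S_star = _check_s_star(S_star)
    p = params
    phiS = p.phi * S_star
    if model_id == "lytic":
        T = np.array([[0.0, phiS],
                      [0.0, 0.0]])
        Sigma = np.array([[-p.eta - p.d_prime, 0.0],
                          [p.beta * p.eta, -phiS - p.m]])
    elif model_id == "latent_implicit":
        headroom = 1.0 - S_star / p.K
        T = np.array([[p.q * p.b_prime * headroom, phiS],
                      [0.0, 0.0]])
        Sigma = np.array([[-p.p * p.eta - p.d_prime, 0.0],
                          [p.beta * p.p * p.eta, -phiS - p.m]])
    elif model_id == "latent_explicit":
        if p.gamma != 0.0:
            raise UnsupportedConfigurationError(
                "R0 via NGM requires gamma = 0 (no induction); "
                f"got gamma = {p.gamma!r}"
            )
        headroom = 1.0 - S_star / p.K
        T = np.array([
            [0.0, 0.0, (1.0 - p.q_l) * phiS],
            [0.0, p.b_prime * headroom, p.q_l * phiS],
            [0.0, 0.0, 0.0],
        ])
        Sigma = np.array([
            [-(p.eta + p.d_prime), 0.0, 0.0],
            [0.0, -p.d_prime, 0.0],
            [p.beta * p.eta, 0.0, -(p.m + phiS)],
        ])
    elif model_id == "chronic":
        headroom = 1.0 - S_star / p.K
        T = np.array([[p.b_prime * headroom, phiS],
                      [0.0, 0.0]])
        Sigma = np.array([[-p.d_prime, 0.0],
                          [p.alpha, -phiS - p.m]])
    else:  # pragma: no cover - parameter_class already rejects this
        raise NGMError(f"unknown model {model_id!r}")
    return NGMDecomposition(
        model_id=model_id,
        S_star=S_star,
        T=T,
        Sigma=Sigma,
        compartment_labels=INFECTED_COMPARTMENTS[model_id],
    )


def expected_durations(decomp: NGMDecomposition) -> np.ndarray:
    """Expected-duration matrix -Sigma^{-1}.

    Entry (i, j) is the expected time a viral genome starting in state j
    spends in state i; all entries are nonnegative for a dissipative
    subsystem.
    """
    Sigma = decomp.Sigma
    if np.any(np.diag(Sigma) == 0.0):
        raise DegenerateModelError(
            "infected subsystem is non-dissipative (a state has no loss term)"
        )
    eye = np.eye(Sigma.shape[0])
    try:
        if np.all(np.triu(Sigma, 1) == 0.0):
            # all four models are sequential in the chosen ordering (cells
            # feed virions, never the reverse), so Sigma is lower triangular
            # and the triangular solve preserves the structural zeros exactly
            durations = -solve_triangular(Sigma, eye, lower=True)
        else:  # pragma: no cover - kept for user-supplied decompositions
            durations = -np.linalg.solve(Sigma, eye)
    except np.linalg.LinAlgError as exc:
        raise DegenerateModelError(f"singular transition matrix: {exc}") from exc
    return durations


def dominant_eigenvalue(decomp: NGMDecomposition) -> float:
    """Largest real part among the eigenvalues of T + Sigma (h^-1).

    Its sign matches the sign of R0 - 1 (the NGM threshold theorem), so
    the zero crossing in S* locates the invasion threshold.
    """
    return float(np.max(np.real(np.linalg.eigvals(decomp.T + decomp.Sigma))))


def spectral_gap(decomp: NGMDecomposition) -> float:
    """Relative gap between the two largest real parts of eig(T + Sigma).

    (lambda_1 - lambda_2) / |lambda_1|.  A trajectory-based estimate of
    the dominant growth rate is reliable only when this gap is
    substantial; near-degenerate or strongly non-normal subsystems mix
    modes for longer than the linear regime lasts.
    """
    real_parts = np.sort(np.real(np.linalg.eigvals(decomp.T + decomp.Sigma)))[::-1]
    lam1 = real_parts[0]
    return float((lam1 - real_parts[1]) / max(abs(lam1), 1e-300))


def r0_numeric(decomp: NGMDecomposition) -> R0Report:
    """R0 as the spectral radius of the next-generation matrix -T Sigma^{-1}.

    The NGM is entrywise nonnegative, so by Perron-Frobenius its dominant
    eigenvalue is real and nonnegative; a complex dominant eigenvalue
    indicates a malformed decomposition and raises.  The numeric route
    reports the total only — the horizontal/vertical split is defined by
    the closed-form algebra, not by the matrix.
    """
    ngm_matrix = decomp.T @ expected_durations(decomp)
    eigenvalues = np.linalg.eigvals(ngm_matrix)
    idx = int(np.argmax(np.abs(eigenvalues)))
    dominant = eigenvalues[idx]
    scale = max(1.0, float(np.max(np.abs(eigenvalues))))
    if abs(dominant.imag) > 1e-9 * scale:
        raise NGMError(
            f"dominant NGM eigenvalue is not real: {dominant!r}"
        )
    return R0Report(
        model_id=decomp.model_id,
        total=float(abs(dominant)),
        method="ngm_numeric",
        S_star=decomp.S_star,
    )


def _horizontal_factor(phi: float, S_star: float, m: float) -> float:
    """Probability phi*S*/(phi*S* + m) that a virion adsorbs before decay."""
    phiS = phi * S_star
    if phiS + m == 0.0:
        raise DegenerateModelError(
            "phi*S* + m = 0: virions neither adsorb nor decay"
        )
    return phiS / (phiS + m)


def r0_lytic_closed(params: CommonParameters, S_star: float) -> R0Report:
    """Closed-form R0 of the obligately lytic model (purely horizontal).

    R0 = beta * phi*S*/(phi*S* + m) * eta/(eta + d'): burst size times the
    probability a virion adsorbs before decaying times the probability an
    infected cell lyses before washout.
    """
    validate_parameters(params)
    S_star = _check_s_star(S_star)
    if params.eta + params.d_prime == 0.0:
        raise DegenerateModelError("eta + d' = 0: infected cells never resolve")
    horizontal = (
        params.beta
        * _horizontal_factor(params.phi, S_star, params.m)
        * params.eta / (params.eta + params.d_prime)
    )
    return R0Report(
        model_id="lytic",
        total=horizontal,
        method="closed_form",
        S_star=S_star,
        horizontal=horizontal,
        vertical=0.0,
    )


def r0_latent_implicit_closed(params: LatentImplicitParameters, S_star: float) -> R0Report:
    """Closed-form R0 of the implicit latency model.

    R0 = q*b'*(1 - S*/K)/(d' + p*eta)                      [vertical]
       + beta * phi*S*/(phi*S* + m) * p*eta/(p*eta + d')   [horizontal]
    """
    validate_parameters(params)
    S_star = _check_s_star(S_star)
    loss = params.d_prime + params.p * params.eta
    if loss == 0.0:
        raise DegenerateModelError("d' + p*eta = 0: lysogens are immortal")
    headroom = 1.0 - S_star / params.K
    vertical = params.q * params.b_prime * headroom / loss
    horizontal = (
        params.beta
        * _horizontal_factor(params.phi, S_star, params.m)
        * params.p * params.eta / loss
    )
    return R0Report(
        model_id="latent_implicit",
        total=vertical + horizontal,
        method="closed_form",
        S_star=S_star,
        horizontal=horizontal,
        vertical=vertical,
    )


def r0_latent_explicit_closed(params: LatentExplicitParameters, S_star: float) -> R0Report:
    """Closed-form R0 of the explicit latency model (gamma = 0).

    With no induction the lysogen and lytic pathways decouple, and
    R0 = max{ b'/d' * (1 - S*/K),
              (1 - q_l) * beta * phi*S*/(phi*S* + m) * eta/(eta + d') }.
    For 0 < q_l < 1 the NGM is reducible (both pathways are seeded but do
    not feed each other), flagged via ``reducible``.
    """
    validate_parameters(params)
    if params.gamma != 0.0:
        raise UnsupportedConfigurationError(
            "closed-form R0 requires gamma = 0 (no induction); "
            f"got gamma = {params.gamma!r}"
        )
    S_star = _check_s_star(S_star)
    if params.d_prime == 0.0:
        raise DegenerateModelError("d' = 0: lysogens are immortal")
    if params.eta + params.d_prime == 0.0:
        raise DegenerateModelError("eta + d' = 0: infected cells never resolve")
    vertical = params.b_prime / params.d_prime * (1.0 - S_star / params.K)
    horizontal = (
        (1.0 - params.q_l)
        * params.beta
        * _horizontal_factor(params.phi, S_star, params.m)
        * params.eta / (params.eta + params.d_prime)
    )
    return R0Report(
        model_id="latent_explicit",
        total=max(vertical, horizontal),
        method="closed_form",
        S_star=S_star,
        horizontal=horizontal,
        vertical=vertical,
        reducible=0.0 < params.q_l < 1.0,
    )


def r0_chronic_closed(params: ChronicParameters, S_star: float) -> R0Report:
    """Closed-form R0 of the chronic model.

    R0 = alpha/d' * phi*S*/(phi*S* + m)   [horizontal: virions budded over
         the cell's lifetime that adsorb before decaying]
       + b'*(1 - S*/K)/d'                 [vertical: daughter cells over
         the cell's lifetime]
    """
    validate_parameters(params)
    S_star = _check_s_star(S_star)
    if params.d_prime == 0.0:
        raise DegenerateModelError("d' = 0: chronically infected cells are immortal")
    horizontal = (
        params.alpha / params.d_prime
        * _horizontal_factor(params.phi, S_star, params.m)
    )
    vertical = params.b_prime * (1.0 - S_star / params.K) / params.d_prime
    return R0Report(
        model_id="chronic",
        total=horizontal + vertical,
        method="closed_form",
        S_star=S_star,
        horizontal=horizontal,
        vertical=vertical,
    )


_CLOSED_FORMS = {
    "lytic": r0_lytic_closed,
    "latent_implicit": r0_latent_implicit_closed,
    "latent_explicit": r0_latent_explicit_closed,
    "chronic": r0_chronic_closed,
}


def r0_closed(model_id: str, params: StrategyParameters, S_star: float) -> R0Report:
    """Dispatch to the closed-form R0 of ``model_id``."""
    parameter_class(model_id)
    return _CLOSED_FORMS[model_id](params, S_star)


def r0_vertical_identity(params: StrategyParameters) -> float:
    """Vertical R0 at the virus-free equilibrium as a life-history ratio.

    At S* = K(1 - d/b) the vertical component b'(1 - S*/K)/d' collapses to
    (b'/d') / (b/d): infected cells spread vertically exactly when their
    lifetime reproduction ratio beats that of susceptible cells.  The value
    is invariant under scaling b' and d' by a common factor (R0 counts
    generations, not time).
    """
    validate_parameters(params)
    if params.d <= 0.0:
        raise DegenerateModelError("vertical identity undefined for d = 0")
    if params.b <= params.d:
        raise DegenerateModelError(
            "vertical identity requires b > d (positive virus-free equilibrium)"
        )
    if params.d_prime <= 0.0:
        raise DegenerateModelError("vertical identity undefined for d' = 0")
    return (params.b_prime / params.d_prime) / (params.b / params.d)
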