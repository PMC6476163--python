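"""Invasion-threshold and strategy-comparison analyses built on R0.

Susceptible density S* is treated throughout as a free environmental axis
(decoupled from the K(1 - d/b) equilibrium formula, which remains available
via :func:`virofit.parameters.virus_free_equilibrium` when b and d are
known).  The analyses are:

* invasion thresholds in S*, where R0 crosses 1 — equivalently where the
  dominant eigenvalue of the linearized infected subsystem crosses 0;
* the horizontal/vertical crossover density S_c above which lysing beats
  integrating for a temperate virus;
* winner maps comparing lytic, chronic, and purely vertical strategies
  along a density grid;
* log10 R0 contour grids over (burst size, density) for the lytic model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import ngm
from .ngm import (
    NGMError,
    R0Report,
    build_ngm,
    dominant_eigenvalue,
    r0_closed,
    r0_lytic_closed,
    r0_numeric,
)
from .parameters import StrategyParameters, validate_parameters

__all__ = [
    "NoThresholdError",
    "SweepResult",
    "ConsistencyReport",
    "vertical_r0",
    "threshold_density",
    "crossover_density",
    "strategy_map",
    "r0_grid",
    "invasion_consistency_check",
]

#: Relative tolerance on S for bracketed root-finding.
ROOT_RTOL = 1e-12

#: Relative tolerance within which strategy R0 values are reported as tied.
TIE_RTOL = 1e-9


class NoThresholdError(ValueError):
    """R0 - 1 (or the strategy difference) does not change sign on the bracket."""


@dataclass
class SweepResult:
    """Tabulated R0 (or winner) values over one or more named grid axes.

    ``table`` is a tidy frame with one row per grid point: the axis
    columns, one value column per quantity, and a ``winner`` column for
    strategy maps (ties reported as ``"tie:<a>|<b>"``, never broken
    silently).
    """

    kind: str
    axes: dict
    table: pd.DataFrame
    winner_column: Optional[str] = None

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @property
    def winners(self) -> Optional[pd.Series]:
        if self.winner_column is None:
            return None
        return self.table[self.winner_column]


@dataclass(frozen=True)
class ConsistencyReport:
    """Three-way invasion diagnosis at one (model, parameters, S*) point."""

    model_id: str
    S_star: float
    r0_closed_form: float
    r0_numeric: float
    growth_eigenvalue: float
    consistent: bool

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        verdict = "consistent" if self.consistent else "INCONSISTENT"
        return (
            f"{self.model_id} @ S*={self.S_star:g}: "
            f"closed={self.r0_closed_form:.6g}, numeric={self.r0_numeric:.6g}, "
            f"lambda={self.growth_eigenvalue:.6g}/h [{verdict}]"
        )


def vertical_r0(params: StrategyParameters, S_star: float) -> float:
    """Purely vertical reproduction number b'(1 - S*/K)/d'."""
    validate_parameters(params)
    if params.d_prime <= 0.0:
        raise ngm.DegenerateModelError("vertical R0 undefined for d' = 0")
    return params.b_prime * (1.0 - S_star / params.K) / params.d_prime


def _brentq(f: Callable[[float], float], lo: float, hi: float,
            what: str) -> tuple:
    f_lo, f_hi = f(lo), f(hi)
    if f_lo == 0.0:
        return lo, 2
    if f_hi == 0.0:
        return hi, 2
    if np.sign(f_lo) == np.sign(f_hi):
        raise NoThresholdError(
            f"no {what} on bracket ({lo:g}, {hi:g}): "
            f"f({lo:g})={f_lo:.6g}, f({hi:g})={f_hi:.6g}"
        )
    root, info = brentq(f, lo, hi, rtol=ROOT_RTOL, full_output=True)
    return float(root), int(info.function_calls) + 2


def threshold_density(model_id: str, params: StrategyParameters,
                      bracket: Optional[tuple] = None, *,
                      criterion: str = "closed_form") -> float:
    """Susceptible density at which the virus sits exactly at the invasion
    boundary.

    With ``criterion="closed_form"`` the root of R0(S*) - 1 is located;
    with ``criterion="eigenvalue"`` the root of the dominant eigenvalue of
    T + Sigma.  By the NGM threshold theorem the two coincide; computing
    both is the package's standard cross-check.  The default bracket is
    (1e-6 K, K).

    Raises :class:`NoThresholdError` when the criterion does not change
    sign on the bracket (the virus invades everywhere or nowhere on it).
    """
    validate_parameters(params)
    if bracket is None:
        bracket = (1e-6 * params.K, params.K)
    lo, hi = float(bracket[0]), float(bracket[1])
    if not (np.isfinite(lo) and np.isfinite(hi) and 0.0 <= lo < hi):
        raise ValueError(f"invalid bracket {bracket!r}")

    if criterion == "closed_form":
        def f(S):
            return r0_closed(model_id, params, S).total - 1.0
    elif criterion == "eigenvalue":
        def f(S):
            return dominant_eigenvalue(build_ngm(model_id, params, S))
    else:
        raise ValueError(f"unknown criterion {criterion!r}")

    root, _ = _brentq(f, lo, hi, what=f"invasion threshold ({criterion})")
    return root


def crossover_density(lytic_params: StrategyParameters,
                      vertical_params: StrategyParameters,
                      K: Optional[float] = None) -> float:
    """Density S_c where horizontal and vertical reproduction numbers cross.

    The horizontal branch is the lytic closed form under ``lytic_params``
    (increasing in S*); the vertical branch is b'(1 - S*/K)/d' under
    ``vertical_params`` (decreasing in S*).  Their difference is strictly
    increasing, so the crossing on (0, K) is unique when it exists; the
    monotonicity is verified on a 1000-point grid before root-finding.
    For S > S_c horizontal transmission is favored, for S < S_c vertical.

    Raises :class:`NoThresholdError` when one mode dominates everywhere on
    (0, K) — e.g. b' = 0 makes the vertical branch identically zero.
    """
    validate_parameters(lytic_params)
    validate_parameters(vertical_params)
    if K is None:
        K = vertical_params.K

    def diff(S):
        return (r0_lytic_closed(lytic_params, S).total
                - vertical_r0(vertical_params, S))

    grid = np.linspace(K * 1e-9, K, 1000)
    values = np.array([diff(S) for S in grid])
    increments = np.diff(values)
    scale = max(np.max(np.abs(values)), 1.0)
    if np.any(increments < -1e-12 * scale):
        raise NGMError(
            "horizontal - vertical difference is not monotone on (0, K); "
            "crossover may not be unique"
        )

    root, _ = _brentq(diff, grid[0], K, what="horizontal/vertical crossover")
    return root


def strategy_map(S_grid: Sequence[float],
                 lytic_params: StrategyParameters,
                 chronic_params: StrategyParameters,
                 vertical_params: StrategyParameters) -> SweepResult:
    """Winning strategy (argmax R0) at each density of ``S_grid``.

    Compares the lytic closed form, the chronic closed form, and a purely
    vertical strategy b'(1 - S*/K)/d'.  R0 values within ``TIE_RTOL``
    relative of the maximum are reported jointly as a tie.
    """
    S_grid = np.asarray(S_grid, dtype=float)
    if S_grid.size == 0:
        raise ValueError("empty density grid")
    labels = ("lytic", "chronic", "vertical")
    rows = []
    for S in S_grid:
        values = (
            r0_lytic_closed(lytic_params, S).total,
            ngm.r0_chronic_closed(chronic_params, S).total,
            vertical_r0(vertical_params, S),
        )
        best = max(values)
        tol = TIE_RTOL * max(best, 1e-300)
        winners = [lab for lab, v in zip(labels, values) if best - v <= tol]
        winner = winners[0] if len(winners) == 1 else "tie:" + "|".join(winners)
        rows.append((S, *values, winner))
    table = pd.DataFrame(
        rows, columns=["S_star", "R0_lytic", "R0_chronic", "R0_vertical", "winner"]
    )
    return SweepResult(
        kind="strategy_map",
        axes={"S_star": S_grid},
        table=table,
        winner_column="winner",
    )


def r0_grid(beta_grid: Sequence[float], S_grid: Sequence[float],
            phi: float, m: float, eta_factor: float = 1.0) -> SweepResult:
    """log10 of the horizontal R0 over a (burst size, density) grid.

    R0_hor = beta * phi*S/(phi*S + m) * eta_factor, where ``eta_factor``
    stands in for eta/(eta + d') (1.0 is the fast-lysis limit).  The zero
    contour of the returned log10 values separates viral extinction from
    proliferation; grid points with R0 = 0 are recorded as -inf.
    """
    beta_grid = np.asarray(beta_grid, dtype=float)
    S_grid = np.asarray(S_grid, dtype=float)
    if beta_grid.size == 0 or S_grid.size == 0:
        raise ValueError("empty grid")
    if np.any(~np.isfinite(beta_grid)) or np.any(~np.isfinite(S_grid)):
        raise ValueError("grids must be finite")
    if not 0.0 <= eta_factor <= 1.0:
        raise ValueError(f"eta_factor must lie in [0,1], got {eta_factor!r}")
    B, S = np.meshgrid(beta_grid, S_grid, indexing="ij")
    r0 = B * (phi * S) / (phi * S + m) * eta_factor
    with np.errstate(divide="ignore"):
        log10_r0 = np.log10(r0)
    table = pd.DataFrame({
        "beta": B.ravel(),
        "S_star": S.ravel(),
        "log10_R0": log10_r0.ravel(),
    })
    return SweepResult(
        kind="r0_grid",
        axes={"beta": beta_grid, "S_star": S_grid},
        table=table,
    )


def invasion_consistency_check(model_id: str, params: StrategyParameters,
                               S_star: float, *, rtol: float = 1e-9,
                               boundary_tol: float = 1e-8) -> ConsistencyReport:
    """Cross-check the three invasion diagnostics at one point.

    Computes (a) the closed-form R0, (b) the numeric spectral-radius R0,
    and (c) the dominant eigenvalue of T + Sigma, then verifies that
    (a) and (b) agree to ``rtol`` relative and that the sign of (c)
    matches the sign of (a) - 1.  Within ``boundary_tol`` of the R0 = 1
    boundary the sign comparison is waived (both quantities vanish there).
    """
    closed = r0_closed(model_id, params, S_star)
    decomp = build_ngm(model_id, params, S_star)
    numeric = r0_numeric(decomp)
    eigenvalue = dominant_eigenvalue(decomp)

    agree = math.isclose(closed.total, numeric.total,
                         rel_tol=rtol, abs_tol=1e-12)
    near_boundary = abs(closed.total - 1.0) <= boundary_tol
    signs_match = near_boundary or (
        np.sign(eigenvalue) == np.sign(closed.total - 1.0)
    )
    return ConsistencyReport(
        model_id=model_id,
        S_star=float(S_star),
        r0_closed_form=closed.total,
        r0_numeric=numeric.total,
        growth_eigenvalue=eigenvalue,
        consistent=bool(agree and signs_match),
    )
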