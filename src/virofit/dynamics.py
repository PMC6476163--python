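"""Numerical integration of the nonlinear models and invasion trials.

An invasion trial seeds the virus-free equilibrium with a rare inoculum
(a single infected cell, or a single virion, per ml by default) and
classifies the outcome by tracking the total infected-genome density: the
sum of all infected-cell compartments plus free virions, mirroring the
infected subclasses of the linearized analysis.  While the infected
classes remain rare the trajectory grows (or decays) at the dominant
eigenvalue of T + Sigma, which the trial estimates by a log-linear fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .models import NEGATIVE_TOLERANCE, rhs_function
from .ngm import INFECTED_COMPARTMENTS, build_ngm, dominant_eigenvalue
from .parameters import (
    COMPARTMENTS,
    StrategyParameters,
    validate_parameters,
    virus_free_equilibrium,
)

__all__ = [
    "IntegrationError",
    "Trajectory",
    "InvasionOutcome",
    "integrate",
    "invasion_trial",
    "infected_genome_density",
]


class IntegrationError(RuntimeError):
    """The ODE solver failed or the solution left the feasible region."""


@dataclass
class Trajectory:
    """Solution of one model over time.

    ``states`` has shape (n_times, n_compartments) in the model's
    compartment order; ``metadata`` records the integrator settings.
    """

    model_id: str
    times: np.ndarray
    states: np.ndarray
    labels: tuple
    metadata: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.states, columns=list(self.labels))
        frame.insert(0, "time", self.times)
        return frame

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def compartment(self, label: str) -> np.ndarray:
        return self.states[:, self.labels.index(label)]


def integrate(model_id: str, params: StrategyParameters, initial_state,
              t_span, *, rtol: float = 1e-8, atol: float = 1e-3,
              method: str = "LSODA", t_eval=None, events=None,
              **rhs_options) -> Trajectory:
    """Integrate the model over ``t_span`` (hours) with stiff-capable
    adaptive stepping.

    Defaults: relative tolerance 1e-8 and absolute tolerance 1e-3 ml^-1
    (cell densities are O(1e7)).  Solver failure raises; so does any
    output state more negative than the integrator-undershoot tolerance.
    A zero-length span returns the (validated) initial state as a
    single-row trajectory.
    """
    validate_parameters(params)
    labels = COMPARTMENTS[model_id]
    y0 = np.asarray(initial_state, dtype=float)
    if y0.shape != (len(labels),):
        raise ValueError(
            f"{model_id} expects {len(labels)} compartments {labels}, "
            f"got shape {y0.shape}"
        )
    if np.min(y0) < -NEGATIVE_TOLERANCE * params.K:
        raise IntegrationError(f"negative initial state {y0!r}")
    t0, t1 = float(t_span[0]), float(t_span[1])
    if not (np.isfinite(t0) and np.isfinite(t1)):
        raise ValueError(f"t_span must be finite, got {t_span!r}")
    metadata = {"rtol": rtol, "atol": atol, "method": method,
                "params": params}
    if t1 == t0:
        return Trajectory(model_id, np.array([t0]), y0[None, :], labels, metadata)

    sol = solve_ivp(
        rhs_function(model_id, params, **rhs_options),
        (t0, t1), y0, method=method, rtol=rtol, atol=atol,
        t_eval=t_eval, events=events, dense_output=False,
    )
    if not sol.success:
        raise IntegrationError(
            f"integrator failed at t={sol.t[-1] if sol.t.size else t0:g} h: "
            f"{sol.message}"
        )
    states = sol.y.T
    if np.min(states) < -NEGATIVE_TOLERANCE * params.K:
        raise IntegrationError(
            f"trajectory left the nonnegative region "
            f"(min density {np.min(states)!r})"
        )
    metadata["t_events"] = sol.t_events
    traj = Trajectory(model_id, sol.t.copy(), states, labels, metadata)
    return traj


def infected_genome_density(model_id: str, states: np.ndarray) -> np.ndarray:
    """Total density of infectious viral genomes: infected cells + virions."""
    labels = COMPARTMENTS[model_id]
    infected = INFECTED_COMPARTMENTS[model_id]
    idx = [labels.index(lab) for lab in infected]
    return np.asarray(states)[..., idx].sum(axis=-1)


def _infected_cell_density(model_id: str, states: np.ndarray) -> np.ndarray:
    labels = COMPARTMENTS[model_id]
    idx = [labels.index(lab) for lab in INFECTED_COMPARTMENTS[model_id]
           if lab != "V"]
    return np.asarray(states)[..., idx].sum(axis=-1)


@dataclass
class InvasionOutcome:
    """Result of a rare-inoculum invasion trial.

    ``outcome`` is ``"invade"`` (infected-genome density grew by the
    required factor from its post-transient minimum while still rare),
    ``"extinct"`` (it collapsed below the extinction fraction of the
    inoculum), or ``"indeterminate"`` (neither bound reached within the
    horizon).  ``growth_rate`` (h^-1) is the log-linear fit over the
    linear-regime window, or None when too few points were available.
    """

    model_id: str
    outcome: str
    growth_rate: Optional[float]
    trajectory: Trajectory
    S_star: float
    inoculum_size: float

    @property
    def infected_genomes(self) -> np.ndarray:
        return infected_genome_density(self.model_id, self.trajectory.states)


def _fit_log_linear_rate(times: np.ndarray, genome: np.ndarray,
                         efolds: float = 4.0) -> Optional[float]:
    """Slope of log(genome) vs time over the asymptotic tail.

    The fit window starts after the transient extremum (the minimum for a
    growing trajectory, the maximum for a decaying one) and keeps only the
    final ``efolds`` e-foldings, where the dominant mode has taken over.
    """
    positive = genome > 0.0
    if np.count_nonzero(positive) < 4:
        return None
    t = times[positive]
    logy = np.log(genome[positive])
    growing = logy[-1] >= logy[0]
    i_ext = int(np.argmin(logy)) if growing else int(np.argmax(logy))
    t, logy = t[i_ext:], logy[i_ext:]
    if t.size < 4:
        return None
    window = np.abs(logy - logy[-1]) <= efolds
    # also drop the first half of the post-extremum span: transient mixing
    # of subdominant modes decays there
    window &= t >= t[0] + 0.5 * (t[-1] - t[0])
    if np.count_nonzero(window) < 4:
        window = np.abs(logy - logy[-1]) <= 2.0 * efolds
    if np.count_nonzero(window) < 4:
        window = np.ones_like(t, dtype=bool)
    slope = np.polyfit(t[window], logy[window], 1)[0]
    return float(slope)


def invasion_trial(model_id: str, params: StrategyParameters, *,
                   inoculum_type: str = "cell", inoculum_size: float = 1.0,
                   horizon: float = 2000.0, S_star: Optional[float] = None,
                   growth_factor: float = 10.0,
                   extinction_fraction: float = 1e-6,
                   rare_fraction: float = 0.01,
                   rtol: float = 1e-9, n_points: int = 1500) -> InvasionOutcome:
    """Simulate the fate of a rare inoculum in a susceptible population.

    The susceptible compartment starts at ``S_star`` (default: the
    virus-free equilibrium K(1 - d/b)); the inoculum is placed in the
    first infected-cell compartment (``inoculum_type="cell"``), in the
    virion compartment (``"virion"``), or split evenly over all infected
    classes (``"mixed"``, which guarantees every linearized mode is
    excited even when pathways are decoupled).  Integration stops as soon
    as the infected-cell density reaches ``rare_fraction`` of S* or the
    susceptible density drifts more than 2% from S* (the trajectory is
    leaving the linear regime: invasion if the genome density also grew by
    ``growth_factor`` from its post-transient minimum), or the
    infected-genome density falls below ``extinction_fraction`` of the
    inoculum (extinction).

    A zero inoculum leaves the system at equilibrium and is classified
    extinct by convention.
    """
    validate_parameters(params)
    labels = COMPARTMENTS[model_id]
    if S_star is None:
        S_star = virus_free_equilibrium(params.b, params.d, params.K)
    S_star = float(S_star)
    if S_star <= 0.0:
        raise ValueError("invasion trial requires a positive susceptible density")
    if inoculum_size < 0.0:
        raise ValueError(f"inoculum_size must be nonnegative, got {inoculum_size!r}")

    y0 = np.zeros(len(labels))
    y0[0] = S_star
    infected = INFECTED_COMPARTMENTS[model_id]
    if inoculum_type == "cell":
        y0[labels.index(infected[0])] = inoculum_size
    elif inoculum_type == "virion":
        y0[labels.index("V")] = inoculum_size
    elif inoculum_type == "mixed":
        for lab in infected:
            y0[labels.index(lab)] = inoculum_size / len(infected)
    else:
        raise ValueError(
            f"inoculum_type must be 'cell', 'virion', or 'mixed', "
            f"got {inoculum_type!r}"
        )

    metadata_extra = {
        "inoculum_type": inoculum_type, "inoculum_size": inoculum_size,
        "horizon": horizon, "growth_factor": growth_factor,
        "extinction_fraction": extinction_fraction,
        "rare_fraction": rare_fraction,
    }

    if inoculum_size == 0.0:
        traj = integrate(model_id, params, y0, (0.0, horizon),
                         rtol=rtol, atol=1e-6,
                         t_eval=np.linspace(0.0, horizon, 11))
        traj.metadata.update(metadata_extra)
        return InvasionOutcome(model_id, "extinct", None, traj,
                               S_star, inoculum_size)

    atol = max(inoculum_size * extinction_fraction * 1e-4, 1e-300)
    collapse_level = extinction_fraction * inoculum_size
    rare_level = rare_fraction * S_star

    def cells(y):
        return _infected_cell_density(model_id, y)

    def genome(y):
        return infected_genome_density(model_id, y)

    def event_rare(t, y):
        return cells(y) - rare_level
    event_rare.terminal = True
    event_rare.direction = 1.0

    def event_collapse(t, y):
        return genome(y) - collapse_level
    event_collapse.terminal = True
    event_collapse.direction = -1.0

    def event_depletion(t, y):
        return abs(y[0] - S_star) - 0.02 * S_star
    event_depletion.terminal = True
    event_depletion.direction = 1.0

    events = (event_rare, event_collapse, event_depletion)

    # First pass: locate the stopping time with minimal output, then
    # resample densely on [0, t_stop] for the log-linear fit.
    probe = integrate(model_id, params, y0, (0.0, horizon),
                      rtol=rtol, atol=atol, events=events,
                      t_eval=np.array([0.0, horizon]))
    t_events = probe.metadata["t_events"]
    stop_times = [te[0] for te in t_events if te.size]
    t_stop = min(stop_times) if stop_times else horizon

    traj = integrate(model_id, params, y0, (0.0, t_stop),
                     rtol=rtol, atol=atol,
                     t_eval=np.linspace(0.0, t_stop, n_points))
    traj.metadata.update(metadata_extra)

    genome_series = genome(traj.states)
    rate = _fit_log_linear_rate(traj.times, genome_series)

    hit_rare = t_events[0].size > 0 and t_events[0][0] <= t_stop
    hit_collapse = t_events[1].size > 0 and t_events[1][0] <= t_stop
    hit_depletion = t_events[2].size > 0 and t_events[2][0] <= t_stop

    positive = genome_series[genome_series > 0.0]
    post_minimum = float(np.min(positive)) if positive.size else 0.0
    grew_enough = (positive.size > 0
                   and genome_series[-1] >= growth_factor * post_minimum)

    if (hit_rare or hit_depletion) and grew_enough:
        outcome = "invade"
    elif hit_collapse:
        outcome = "extinct"
    else:
        outcome = "indeterminate"
    return InvasionOutcome(model_id, outcome, rate, traj, S_star, inoculum_size)


def linearized_growth_rate(model_id: str, params: StrategyParameters,
                           S_star: float) -> float:
    """Dominant eigenvalue of T + Sigma: the independent prediction for the
    early exponential growth rate of a rare inoculum."""
    return dominant_eigenvalue(build_ngm(model_id, params, S_star))


__all__.append("linearized_growth_rate")
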