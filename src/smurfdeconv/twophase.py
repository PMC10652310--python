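"""Two-phase demographic model of ageing.

Individuals live through a healthy, zero-mortality phase, irreversibly
transition into the frail "Smurf" phase with hazard ``lambda(t)``, and then
die with a constant force of mortality ``h`` (so the median remaining
lifespan after the transition is ``ln(2)/h`` regardless of the age at which
it happened).  At the population level the Smurf prevalence among live
individuals rises roughly linearly with age, and the population survival
curve is fully determined by that prevalence line and ``h``:

    S(t) = exp(-h * (a*t^2/2 + b*t))        for p(t) = a*t + b (clipped)

Two transition-hazard shapes are supported: ``lambda(t) = c*t`` (default,
age-accelerating) and a constant ``lambda(t) = c``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = [
    "TwoPhaseParams",
    "CohortState",
    "closed_form_survival",
    "simulate_cohort",
    "prevalence_curve",
]

#: Median remaining lifespan (days) of a Smurf used to calibrate the default
#: mortality rate; reproduced empirically by :func:`simulate_cohort`.
DEFAULT_SMURF_T50 = 2.04

_LN2 = float(np.log(2.0))


@dataclass(frozen=True)
class TwoPhaseParams:
    """Demographic parameters of the two-phase model.

    Parameters
    ----------
    c:
        Transition-hazard coefficient.  With ``hazard_mode="linear"`` the
        Smurf-transition hazard is ``lambda(t) = c * t`` (units: day^-2);
        with ``hazard_mode="constant"`` it is ``lambda(t) = c`` (day^-1).
    h:
        Constant force of mortality in the Smurf phase (day^-1).  The median
        Smurf remaining lifespan is ``ln(2)/h``.
    a, b:
        Slope (day^-1) and intercept of the linear prevalence approximation
        ``p(t) = a*t + b``, clipped to [0, 1].  Used by the closed-form
        survival; ignored by the mechanistic simulation.
    t0:
        Age (days) at which the prevalence line first becomes positive; the
        closed-form hazard is zero before ``max(t0, -b/a)``.
    hazard_mode:
        ``"linear"`` or ``"constant"`` transition hazard.
    """

    c: float = 0.0015
    h: float = _LN2 / DEFAULT_SMURF_T50
    a: float = 0.0044
    b: float = 0.0
    t0: float = 0.0
    hazard_mode: Literal["linear", "constant"] = "linear"

    def __post_init__(self) -> None:
        if self.c < 0:
            raise ValueError(f"transition hazard coefficient c must be >= 0, got {self.c}")
        if self.h <= 0:
            raise ValueError(f"Smurf mortality h must be > 0, got {self.h}")
        if self.a < 0:
            raise ValueError(f"prevalence slope a must be >= 0, got {self.a}")
        if self.t0 < 0:
            raise ValueError(f"t0 must be >= 0, got {self.t0}")
        if self.hazard_mode not in ("linear", "constant"):
            raise ValueError(f"unknown hazard_mode {self.hazard_mode!r}")

    @property
    def smurf_t50(self) -> float:
        """Median remaining lifespan after the Smurf transition (days)."""
        return _LN2 / self.h

    def transition_hazard(self, t: np.ndarray | float) -> np.ndarray:
        """Smurf-transition hazard ``lambda(t)``."""
        t = np.asarray(t, dtype=float)
        if self.hazard_mode == "linear":
            return self.c * t
        return np.full_like(t, self.c)

    def prevalence_line(self, t: np.ndarray | float) -> np.ndarray:
        """Clipped linear prevalence approximation ``p(t)``."""
        t = np.asarray(t, dtype=float)
        p = self.a * t + self.b
        p = np.where(t < self.t0, np.minimum(p, 0.0), p)
        return np.clip(p, 0.0, 1.0)


@dataclass
class CohortState:
    """Result of a stochastic cohort simulation.

    ``individuals`` has one row per fly (id, smurf_entry_age, death_age,
    status at the observation horizon); ``by_day`` daily population
    summaries (day, n_alive, n_smurf, survival, prevalence).
    """

    individuals: pd.DataFrame
    by_day: pd.DataFrame
    params: TwoPhaseParams = field(repr=False)
    horizon: float = 0.0

    @property
    def n(self) -> int:
        return len(self.individuals)


def closed_form_survival(params: TwoPhaseParams, t: np.ndarray | float) -> np.ndarray | float:
    """Population survival under the linear-prevalence approximation.

    The population death hazard is ``h * p(t)`` with ``p`` the clipped
    prevalence line, hence ``S(t) = exp(-h * int_0^t p(u) du)``; on the
    un-clipped stretch this is ``exp(-h*(a*t^2/2 + b*t))``.

    Raises ``ValueError`` for negative times.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("negative times are not allowed")
    start = max(params.t0, -params.b / params.a if params.a > 0 else params.t0)
    start = max(start, 0.0)
    # integral of the clipped line from `start` up to t, capped where p hits 1
    a, b, h = params.a, params.b, params.h
    if a > 0:
        t_cap = (1.0 - b) / a  # age at which p(t) reaches 1
    else:
        t_cap = np.inf
    tt = np.maximum(t_arr, start)
    lo = np.minimum(tt, t_cap)
    integral = a * (lo**2 - start**2) / 2.0 + b * (lo - start)
    integral = integral + np.maximum(tt - t_cap, 0.0)  # p == 1 beyond the cap
    s = np.exp(-h * integral)
    if np.isscalar(t) or t_arr.ndim == 0:
        return float(s)
    return s


def _sample_transition_ages(params: TwoPhaseParams, n: int, rng: np.random.Generator) -> np.ndarray:
    """Inverse-CDF sampling of transition ages from the cumulative hazard.

    Linear hazard: Lambda(t) = c*t^2/2, so t = sqrt(2 E / c) with E ~ Exp(1).
    Constant hazard: t = E / c.  c == 0 means the transition never happens.
    """
    if params.c == 0:
        return np.full(n, np.inf)
    e = rng.exponential(1.0, size=n)
    if params.hazard_mode == "linear":
        return np.sqrt(2.0 * e / params.c)
    return e / params.c


def simulate_cohort(
    params: TwoPhaseParams,
    n: int,
    horizon: float,
    seed: int,
    grid_step: float = 1.0,
) -> CohortState:
    """Simulate ``n`` individuals through the two-phase model up to ``horizon``.

    Each individual draws a Smurf-transition age from the transition hazard
    and an independent Smurf-phase duration from ``Exponential(h)``; death
    always occurs in the Smurf state.  Identical seeds give identical
    cohorts.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if horizon <= 0:
        raise ValueError("horizon must be > 0")
    rng = np.random.default_rng(seed)
    entry = _sample_transition_ages(params, n, rng)
    duration = rng.exponential(1.0 / params.h, size=n)
    death = entry + duration

    status = np.where(
        death <= horizon,
        "dead",
        np.where(entry <= horizon, "alive-smurf", "alive-nonsmurf"),
    )
    individuals = pd.DataFrame(
        {
            "id": np.arange(n),
            "smurf_entry_age": np.where(np.isfinite(entry), entry, np.nan),
            "death_age": np.where(death <= horizon, death, np.nan),
            "status": status,
        }
    )

    days = np.arange(0.0, horizon + grid_step / 2, grid_step)
    # vectorised daily summaries
    alive = days[None, :] < np.where(np.isfinite(death), death, np.inf)[:, None]
    smurf = alive & (entry[:, None] <= days[None, :])
    n_alive = alive.sum(axis=0)
    n_smurf = smurf.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        prevalence = np.where(n_alive > 0, n_smurf / np.maximum(n_alive, 1), np.nan)
    by_day = pd.DataFrame(
        {
            "day": days,
            "n_alive": n_alive,
            "n_smurf": n_smurf,
            "survival": n_alive / n,
            "prevalence": prevalence,
        }
    )
    return CohortState(individuals=individuals, by_day=by_day, params=params, horizon=horizon)


def two_compartment_ode(
    params: TwoPhaseParams, grid: np.ndarray, rtol: float = 1e-9, atol: float = 1e-12
) -> pd.DataFrame:
    """Deterministic compartment solution n_NS' = -lambda n_NS, n_S' = lambda n_NS - h n_S.

    Returns fractions (of the initial population) of non-Smurfs and Smurfs
    on ``grid`` plus the implied survival and prevalence.  This is the
    mechanistic counterpart of :func:`simulate_cohort` and the oracle the
    stochastic simulation is checked against.
    """
    grid = np.asarray(grid, dtype=float)

    def rhs(t: float, y: np.ndarray) -> list[float]:
        lam = float(params.transition_hazard(t))
        n_ns, n_s = y
        return [-lam * n_ns, lam * n_ns - params.h * n_s]

    sol = solve_ivp(
        rhs, (float(grid[0]), float(grid[-1])), [1.0, 0.0], t_eval=grid, rtol=rtol, atol=atol
    )
    n_ns, n_s = sol.y
    survival = n_ns + n_s
    with np.errstate(invalid="ignore", divide="ignore"):
        prevalence = np.where(survival > 0, n_s / survival, np.nan)
    return pd.DataFrame(
        {"day": grid, "nonsmurf": n_ns, "smurf": n_s, "survival": survival, "prevalence": prevalence}
    )


def prevalence_curve(params: TwoPhaseParams, grid: np.ndarray) -> pd.Series:
    """Smurf prevalence p(t) among live individuals from the compartment ODE.

    Monotone non-decreasing whenever the transition hazard is, and close to
    linear on the mid-life observation window for the default parameters
    (the regime the linear approximation targets).
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or len(grid) < 1:
        raise ValueError("grid must be a non-empty 1-D array")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")
    if grid[0] > 0:
        full = np.concatenate([[0.0], grid])
        ode = two_compartment_ode(params, full).iloc[1:]
    else:
        ode = two_compartment_ode(params, grid)
    return pd.Series(ode["prevalence"].to_numpy(), index=grid, name="prevalence")


def write_cohort_csvs(state: CohortState, individuals_path, summary_path) -> None:
    """Write per-individual and per-day summary CSVs of a simulated cohort."""
    state.individuals.to_csv(individuals_path, index=False)
    state.by_day.to_csv(summary_path, index=False)
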