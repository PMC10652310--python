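"""Longevity-screen statistics: lifespans and Smurf-prevalence regression.

Death-event tables (condition, day, deaths) give mean/median lifespans
and percent change against a designated control; Smurf-prevalence tables
(condition, day, n_alive, n_smurf) are fitted with per-condition linear
regressions of the Smurf proportion on age, plus a joint model with a
condition x age interaction — the test for delayed entry into the Smurf
phase.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "LifespanSummary",
    "PrevalenceFit",
    "mean_lifespan",
    "percent_change",
    "fit_prevalence",
    "survival_curve",
]


@dataclass
class LifespanSummary:
    """Per-condition mean/median lifespan and percent change vs control."""

    table: pd.DataFrame  # condition, n, mean_lifespan, median_lifespan, pct_change
    control: str | None = None


@dataclass
class PrevalenceFit:
    """Per-condition prevalence slopes and the joint interaction model."""

    per_condition: pd.DataFrame     # condition, slope, intercept, r2, f_p
    interaction: pd.DataFrame | None  # condition, interaction_coef, interaction_p (vs reference)
    reference: str | None = None

    def predict(self, condition: str, days: np.ndarray) -> np.ndarray:
        row = self.per_condition.set_index("condition").loc[condition]
        return np.clip(row["intercept"] + row["slope"] * np.asarray(days, float), 0.0, 1.0)


def percent_change(ml_control: float, ml_treated: float) -> float:
    """Mean-lifespan percent change vs control, rounded to one decimal."""
    return round((ml_treated - ml_control) / ml_control * 100.0, 1)


def _weighted_median(days: np.ndarray, deaths: np.ndarray) -> float:
    order = np.argsort(days)
    days, deaths = days[order], deaths[order]
    cum = np.cumsum(deaths)
    total = cum[-1]
    return float(days[np.searchsorted(cum, total / 2.0)])


def mean_lifespan(events: pd.DataFrame, control: str | None = None) -> LifespanSummary:
    """Mean lifespan per condition from a complete death-event table.

    ML = sum(day * deaths) / sum(deaths); percent change is reported
    against ``control`` when one is designated.
    """
    required = {"condition", "day", "deaths"}
    missing = required - set(events.columns)
    if missing:
        raise ValueError(f"event table missing columns: {sorted(missing)}")
    rows = []
    for cond, grp in events.groupby("condition"):
        days = grp["day"].to_numpy(dtype=float)
        deaths = grp["deaths"].to_numpy(dtype=float)
        total = deaths.sum()
        if total <= 0:
            raise ValueError(f"condition {cond!r} has zero deaths")
        ml = float((days * deaths).sum() / total)
        rows.append(
            {
                "condition": cond,
                "n": int(total),
                "mean_lifespan": ml,
                "median_lifespan": _weighted_median(days, deaths),
            }
        )
    table = pd.DataFrame(rows)
    if control is not None:
        if control not in set(table["condition"]):
            raise ValueError(f"control condition {control!r} not in event table")
        ml_c = float(table.loc[table["condition"] == control, "mean_lifespan"].iloc[0])
        table["pct_change"] = [
            percent_change(ml_c, ml) if cond != control else 0.0
            for cond, ml in zip(table["condition"], table["mean_lifespan"])
        ]
    return LifespanSummary(table=table, control=control)


def fit_prevalence(
    obs: pd.DataFrame,
    reference: str | None = None,
    weighted: bool = False,
) -> PrevalenceFit:
    """Linear regression of the Smurf proportion on chronological age.

    Per condition: unweighted OLS of proportion (n_smurf / n_alive) on
    day, with the slope's F-test (equivalently the squared-t test).  When
    several conditions are present, a joint OLS with condition dummies and
    condition x day interactions quantifies whether a condition's
    prevalence rises more slowly than the reference (a significant
    negative interaction).  ``weighted=True`` weights observations by
    n_alive.
    """
    required = {"condition", "day", "n_alive", "n_smurf"}
    missing = required - set(obs.columns)
    if missing:
        raise ValueError(f"prevalence table missing columns: {sorted(missing)}")
    obs = obs.copy()
    obs["proportion"] = obs["n_smurf"] / obs["n_alive"]

    rows = []
    for cond, grp in obs.groupby("condition"):
        if grp["day"].nunique() < 3:
            raise ValueError(f"condition {cond!r} has fewer than 3 observation days")
        X = sm.add_constant(grp["day"].to_numpy(dtype=float))
        w = grp["n_alive"].to_numpy(dtype=float) if weighted else None
        model = sm.WLS(grp["proportion"].to_numpy(), X, weights=w) if weighted else sm.OLS(
            grp["proportion"].to_numpy(), X
        )
        fit = model.fit()
        f_p = float(fit.f_pvalue)
        if not np.isfinite(f_p):  # zero residual variance (e.g. exactly constant data)
            f_p = 1.0 if abs(fit.params[1]) < 1e-12 else 0.0
        rows.append(
            {
                "condition": cond,
                "slope": float(fit.params[1]),
                "intercept": float(fit.params[0]),
                "r2": float(fit.rsquared) if np.isfinite(fit.rsquared) else 0.0,
                "f_p": f_p,
            }
        )
    per_condition = pd.DataFrame(rows)

    interaction = None
    conditions = sorted(obs["condition"].unique())
    if len(conditions) >= 2:
        ref = reference if reference is not None else conditions[0]
        if ref not in conditions:
            raise ValueError(f"reference condition {ref!r} not present")
        others = [c for c in conditions if c != ref]
        day = obs["day"].to_numpy(dtype=float)
        cols = [np.ones(len(obs)), day]
        names = ["intercept", "day"]
        for c in others:
            dummy = (obs["condition"] == c).to_numpy(dtype=float)
            cols += [dummy, dummy * day]
            names += [f"cond_{c}", f"day:cond_{c}"]
        X = np.column_stack(cols)
        w = obs["n_alive"].to_numpy(dtype=float) if weighted else None
        model = sm.WLS(obs["proportion"].to_numpy(), X, weights=w) if weighted else sm.OLS(
            obs["proportion"].to_numpy(), X
        )
        fit = model.fit()
        inter_rows = []
        for c in others:
            j = names.index(f"day:cond_{c}")
            inter_rows.append(
                {
                    "condition": c,
                    "interaction_coef": float(fit.params[j]),
                    "interaction_p": float(fit.pvalues[j]),
                }
            )
        interaction = pd.DataFrame(inter_rows)
        reference = ref
    return PrevalenceFit(per_condition=per_condition, interaction=interaction, reference=reference)


def survival_curve(events: pd.DataFrame, n_initial: int | None = None) -> pd.DataFrame:
    """Right-continuous stepwise survival S(day) per condition.

    ``n_initial`` defaults to the total number of recorded deaths
    (complete follow-up, no censoring).
    """
    curves = []
    for cond, grp in events.groupby("condition"):
        grp = grp.sort_values("day")
        deaths = grp["deaths"].to_numpy(dtype=float)
        if (deaths < 0).any():
            raise ValueError("negative death counts")
        n0 = float(n_initial if n_initial is not None else deaths.sum())
        cum = np.cumsum(deaths)
        if cum[-1] > n0:
            raise ValueError("cumulative deaths exceed initial population")
        curves.append(
            pd.DataFrame(
                {
                    "condition": cond,
                    "day": grp["day"].to_numpy(dtype=float),
                    "survival": 1.0 - cum / n0,
                }
            )
        )
    return pd.concat(curves, ignore_index=True)


def prevalence_observations_from_cohort(by_day: pd.DataFrame, days: np.ndarray,
                                        condition: str) -> pd.DataFrame:
    """Turn a simulated cohort's daily summary into a prevalence table."""
    sel = by_day[by_day["day"].isin(np.asarray(days, dtype=float)) & (by_day["n_alive"] > 0)]
    return pd.DataFrame(
        {
            "condition": condition,
            "day": sel["day"].to_numpy(dtype=float),
            "n_alive": sel["n_alive"].to_numpy(dtype=int),
            "n_smurf": sel["n_smurf"].to_numpy(dtype=int),
        }
    )
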