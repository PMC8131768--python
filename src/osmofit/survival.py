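"""Kaplan-Meier product-limit estimation of time-to-death.

Adults removed alive at the end of the 30-day window are censored at day
30; F1 offspring followed to maturity are censored at day 90.  Individuals
are pooled across boxes within a population x treatment group.  Deaths are
processed before censorings at tied times (the standard convention).  The
median is the first event day at which the survivor curve drops to 0.5 or
below; curves that never reach 0.5 have an undefined median.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .data import ADULT_WINDOW_DAYS, F1_WINDOW_DAYS, Dataset


@dataclass
class KMCurve:
    """Product-limit survivor curve with Greenwood standard errors."""

    times: np.ndarray  # event/censoring days, increasing
    s_hat: np.ndarray  # survival probability after each time
    at_risk: np.ndarray
    deaths: np.ndarray
    censored: np.ndarray
    greenwood_se: np.ndarray
    median_day: float | None

    def survival_at(self, day: float) -> float:
        """Step-function value S(day)."""
        idx = np.searchsorted(self.times, day, side="right") - 1
        return 1.0 if idx < 0 else float(self.s_hat[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "day": self.times,
                "at_risk": self.at_risk,
                "deaths": self.deaths,
                "censored": self.censored,
                "s_hat": self.s_hat,
                "se": self.greenwood_se,
            }
        )

    def plot(self, ax=None, label: str | None = None):
        """Survivor step function with a pointwise ±1.96 SE band."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = np.concatenate([[0.0], self.times])
        s = np.concatenate([[1.0], self.s_hat])
        se = np.concatenate([[0.0], self.greenwood_se])
        ax.step(t, s, where="post", label=label)
        ax.fill_between(t, np.clip(s - 1.96 * se, 0, 1), np.clip(s + 1.96 * se, 0, 1),
                        step="post", alpha=0.15)
        ax.set_xlabel("day")
        ax.set_ylabel("S(t)")
        ax.set_ylim(0, 1.02)
        if label:
            ax.legend()
        return ax


def kaplan_meier(events) -> KMCurve:
    """Product-limit estimate from (day, status) pairs (status True = death)."""
    events = list(events)
    if not events:
        raise ValueError("no survival records supplied")
    days = np.array([d for d, _ in events], dtype=float)
    observed = np.array([bool(s) for _, s in events])
    if np.any(days < 0):
        raise ValueError("event days must be non-negative")

    kmf = KaplanMeierFitter()
    kmf.fit(days, event_observed=observed)
    # drop lifelines' synthetic t=0 row when nothing happens there
    tbl = kmf.event_table
    tbl = tbl[(tbl["observed"] > 0) | (tbl["censored"] > 0)]

    times = tbl.index.to_numpy(dtype=float)
    at_risk = tbl["at_risk"].to_numpy(dtype=float)
    deaths = tbl["observed"].to_numpy(dtype=float)
    censored = tbl["censored"].to_numpy(dtype=float)

    # survivor value *after* each listed time, from the fitted step function
    s_hat = np.array([float(kmf.predict(t)) for t in times])

    # Greenwood: Var[S(t)] = S(t)^2 * sum_{t_i<=t, deaths} d_i / (n_i (n_i - d_i))
    terms = np.where(
        (deaths > 0) & (at_risk > deaths),
        deaths / (at_risk * (at_risk - deaths)),
        np.where((deaths > 0) & (at_risk == deaths), np.nan, 0.0),
    )
    cum = np.nancumsum(terms)
    greenwood_se = s_hat * np.sqrt(cum)
    greenwood_se = np.where(s_hat == 0, 0.0, greenwood_se)

    below = np.where(s_hat <= 0.5)[0]
    median = float(times[below[0]]) if below.size else None

    return KMCurve(
        times=times,
        s_hat=s_hat,
        at_risk=at_risk,
        deaths=deaths,
        censored=censored,
        greenwood_se=greenwood_se,
        median_day=median,
    )


def median_survival_time(curve: KMCurve) -> float | None:
    """Smallest event day with S <= 0.5; None when the curve never gets there."""
    return curve.median_day


def adult_events(box, window: int = ADULT_WINDOW_DAYS):
    """Individual (day, death) records from a box's daily adult censuses.

    A death is assigned to the day the census count dropped; adults alive at
    the end of the observed window are censored there.
    """
    out = []
    for sex, series in sorted(box.daily_alive.items()):
        horizon = min(window, len(series) - 1)
        for d in range(1, horizon + 1):
            for _ in range(int(series[d - 1] - series[d])):
                out.append((d, True))
        for _ in range(int(series[horizon])):
            out.append((horizon, False))
    return out


def group_km_curves(ds: Dataset, cohort: str = "adults") -> dict[tuple[str, float], KMCurve]:
    """KM curve per population x treatment, pooling individuals across boxes.

    ``cohort`` selects the 30-day adult censuses or the F1 longevity records
    (followed to day 90).
    """
    groups: dict[tuple[str, float], list] = {}
    for box in ds.records:
        key = (box.origin, box.treatment)
        if cohort == "adults":
            ev = adult_events(box)
        elif cohort == "f1":
            ev = [(min(d, F1_WINDOW_DAYS), s) for d, s in box.f1_longevity]
        else:
            raise ValueError("cohort must be 'adults' or 'f1'")
        groups.setdefault(key, []).extend(ev)
    return {k: kaplan_meier(v) for k, v in sorted(groups.items()) if v}
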