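"""Fitness surrogates per common-garden box and their population x treatment summaries.

Four surrogates of reproductive success are computed per box: adult
survival (survivors at the 30-day horizon over initial adults), fecundity
(total eggs), oviposition rate (eggs per observed day), and number of
immatures (F1 juveniles counted before wing development).  Sex-specific
survival divides sex-specific survivors by the SAME whole-box denominator,
so male + female survival equals overall survival within a box.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import ADULT_WINDOW_DAYS, Dataset, GardenBox

TRAITS = ("survival", "survival_male", "survival_female", "fecundity", "oviposition_rate", "n_immatures")
#: the four surrogates entering adaptation indices (sex-specific survival excluded)
CORE_TRAITS = ("survival", "fecundity", "oviposition_rate", "n_immatures")


@dataclass(frozen=True)
class FitnessSummary:
    """Mean ± SE of one fitness surrogate for one population x treatment cell."""

    population: str
    treatment: float
    trait: str
    n_boxes: int
    mean: float
    se: float


def survival_ratio(box: GardenBox, horizon_day: int = ADULT_WINDOW_DAYS, by_sex: str | None = None) -> float:
    """Survivors at *horizon_day* divided by total initial adults in the box.

    ``by_sex`` restricts the numerator to one sex ("M"/"F"); the
    denominator stays the whole box so that sex-specific ratios add up to
    the overall ratio.
    """
    if box.n_initial == 0:
        raise ValueError(f"box {box.box_id} has no initial adults")
    alive = box.alive_on(horizon_day, sex=by_sex)
    return alive / box.n_initial


def oviposition_rate(box: GardenBox) -> float:
    """Eggs laid per observed day (box total over the observation window)."""
    if box.days_observed <= 0:
        raise ValueError(f"box {box.box_id}: days_observed must be positive")
    return box.eggs_total / box.days_observed


def box_traits(box: GardenBox, horizon_day: int = ADULT_WINDOW_DAYS) -> dict[str, float]:
    """All six surrogate values for one box."""
    return {
        "survival": survival_ratio(box, horizon_day),
        "survival_male": survival_ratio(box, horizon_day, by_sex="M"),
        "survival_female": survival_ratio(box, horizon_day, by_sex="F"),
        "fecundity": float(box.eggs_total),
        "oviposition_rate": oviposition_rate(box),
        "n_immatures": float(box.n_offspring),
    }


def trait_frame(ds: Dataset, horizon_day: int = ADULT_WINDOW_DAYS) -> pd.DataFrame:
    """Long per-box trait table (box_id, population, treatment, trait, value)."""
    rows = []
    for box in ds.records:
        if not isinstance(box, GardenBox):
            raise TypeError("fitness summaries require a common-garden (GardenBox) dataset")
        for trait, value in box_traits(box, horizon_day).items():
            rows.append(
                {
                    "box_id": box.box_id,
                    "population": box.origin,
                    "treatment": box.treatment,
                    "trait": trait,
                    "value": value,
                }
            )
    return pd.DataFrame(rows, columns=["box_id", "population", "treatment", "trait", "value"])


def summarize_traits(ds: Dataset, horizon_day: int = ADULT_WINDOW_DAYS) -> pd.DataFrame:
    """Mean and SE of every surrogate per population x treatment cell.

    SE is the sample standard deviation over boxes divided by sqrt(n_boxes);
    a single-box cell reports SE 0 with a degenerate-cell warning.  Rows are
    deterministically ordered by (population, treatment, trait).
    """
    long = trait_frame(ds, horizon_day)
    if long.empty:
        return pd.DataFrame(columns=["population", "treatment", "trait", "n_boxes", "mean", "se"])
    out = []
    for (pop, treat, trait), g in long.groupby(["population", "treatment", "trait"], sort=True):
        vals = g["value"].to_numpy(dtype=float)
        n = len(vals)
        if n == 1:
            warnings.warn(f"degenerate cell ({pop}, {treat}, {trait}): single box, SE reported as 0")
            se = 0.0
        else:
            se = float(np.std(vals, ddof=1) / np.sqrt(n))
        out.append(
            {
                "population": pop,
                "treatment": treat,
                "trait": trait,
                "n_boxes": n,
                "mean": float(np.mean(vals)),
                "se": se,
            }
        )
    df = pd.DataFrame(out)
    trait_order = {t: i for i, t in enumerate(TRAITS)}
    df = df.sort_values(
        ["population", "treatment", "trait"],
        key=lambda s: s.map(trait_order) if s.name == "trait" else s,
    ).reset_index(drop=True)
    return df


def summaries_from_records(records) -> pd.DataFrame:
    """Build a summary table directly from FitnessSummary records or dicts."""
    df = pd.DataFrame([r.__dict__ if isinstance(r, FitnessSummary) else dict(r) for r in records])
    return df[["population", "treatment", "trait", "n_boxes", "mean", "se"]]
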