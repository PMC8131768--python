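"""Local-adaptation (LA) and maladaptation-magnitude (MA) indices.

The LA index compares the mean fitness W of the native population at a
site against the foreign population at the same site, normalised by the
site mean:

    LA = (W_native - W_foreign) / mean(W_native, W_foreign)

Positive LA indicates local adaptation of the focal (native) population at
that site, negative LA maladaptation; for non-negative fitness LA is
bounded in [-2, 2], the extremes reached when one population's fitness is
zero.  LA is undefined (flagged, not 0) when both fitness values are zero.

The MA index measures the proportional fitness shortfall of a derived
population in its own home environment relative to the ancestral
population's home-environment fitness standardised to 1.0:

    MA = 1 - W_realized / W_ideal

MA is 0 when the derived population matches the ancestral benchmark and 1
when its fitness is zero.  MA < 0 (realized exceeding ideal) is reported
as-is with a flag rather than clipped.

A population's fitness advantage at home versus away classifies each trait
into a trade-off quadrant: advantage only at home (trade-off), only away
(inverse trade-off), both, or neither.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import pandas as pd

from .fitness import CORE_TRAITS

#: default home treatments: ancestral freshwater population at 0 ppt,
#: derived brackish population at 1 ppt (its lagoon-water treatment)
DEFAULT_HOME_MAP = {"FW": 0.0, "BW": 1.0}

QUADRANTS = ("tradeoff_home", "inverse_tradeoff", "no_tradeoff_both", "no_tradeoff_neither", "boundary")


@dataclass(frozen=True)
class LAEstimate:
    focal_population: str
    site: float | str
    trait: str
    w_native: float
    w_foreign: float
    la: float  # NaN when undefined
    defined: bool


@dataclass(frozen=True)
class MAEstimate:
    trait: str
    w_ideal: float
    w_realized: float
    ma: float
    defined: bool
    exceeds_ideal: bool = False  # realized > ideal, so ma < 0


@dataclass(frozen=True)
class TradeoffClass:
    trait: str
    la_home: float
    la_foreign: float
    quadrant: str


def local_adaptation_index(
    w_native: float,
    w_foreign: float,
    focal_population: str = "",
    site: float | str = "",
    trait: str = "",
) -> LAEstimate:
    """Normalised home-vs-foreign fitness difference at one site."""
    if w_native < 0 or w_foreign < 0:
        raise ValueError("fitness values must be non-negative")
    if not (math.isfinite(w_native) and math.isfinite(w_foreign)):
        raise ValueError("fitness values must be finite")
    avg = (w_native + w_foreign) / 2.0
    if avg == 0:
        return LAEstimate(focal_population, site, trait, w_native, w_foreign, float("nan"), False)
    return LAEstimate(focal_population, site, trait, w_native, w_foreign, (w_native - w_foreign) / avg, True)


def trait_average_la(estimates, exclude: set[str] | None = None) -> float:
    """Arithmetic mean of defined LA values across traits at one site.

    ``exclude`` drops named traits explicitly (e.g. averaging reproduction
    surrogates while leaving survival out); exclusion is never implicit.
    """
    exclude = exclude or set()
    vals = [e.la for e in estimates if e.defined and e.trait not in exclude]
    if not vals:
        raise ValueError("no defined LA estimates to average")
    return sum(vals) / len(vals)


def maladaptation_magnitude(w_ideal: float, w_realized: float, trait: str = "") -> MAEstimate:
    """Proportional fitness shortfall of the derived population at home."""
    if w_ideal <= 0:
        raise ValueError("ideal (ancestral home) fitness must be positive to standardise to 1.0")
    if w_realized < 0:
        raise ValueError("realized fitness must be non-negative")
    ma = 1.0 - w_realized / w_ideal
    return MAEstimate(trait, w_ideal, w_realized, ma, True, exceeds_ideal=ma < 0)


def classify_tradeoff(la_home: float, la_foreign: float, tol: float = 1e-9, trait: str = "") -> TradeoffClass:
    """Quadrant classification of home-vs-away fitness advantage by LA signs."""
    if abs(la_home) <= tol or abs(la_foreign) <= tol:
        quadrant = "boundary"
    elif la_home > 0 and la_foreign < 0:
        quadrant = "tradeoff_home"
    elif la_home < 0 and la_foreign > 0:
        quadrant = "inverse_tradeoff"
    elif la_home > 0 and la_foreign > 0:
        quadrant = "no_tradeoff_both"
    else:
        quadrant = "no_tradeoff_neither"
    return TradeoffClass(trait, la_home, la_foreign, quadrant)


def _cell_mean(summaries: pd.DataFrame, population: str, treatment: float, trait: str):
    sub = summaries[
        (summaries["population"] == population)
        & (summaries["treatment"] == treatment)
        & (summaries["trait"] == trait)
    ]
    if sub.empty:
        return None
    return float(sub["mean"].iloc[0])


def adaptation_report(
    summaries: pd.DataFrame,
    home_map: dict[str, float] | None = None,
    traits=CORE_TRAITS,
    ancestral: str = "FW",
    derived: str = "BW",
) -> dict[str, pd.DataFrame]:
    """Full LA / MA / trade-off analysis from a fitness-summary table.

    Parameters
    ----------
    summaries : DataFrame with columns population, treatment, trait, mean
        Population x treatment cell means of the fitness surrogates
        (typically :func:`osmofit.fitness.summarize_traits` output, or a
        hand-entered table of published means).
    home_map : mapping population -> home treatment (ppt).
    traits : surrogates to analyse (default the four core ones).

    Returns a dict of tidy tables: ``la`` (per population x site x trait),
    ``la_average`` (trait-averaged LA per population x site), ``ma`` (per
    trait, derived population at home vs ancestral at home), and
    ``tradeoff`` (quadrant per population x trait, home vs each foreign
    site).  Missing cells are skipped with a warning.
    """
    home_map = dict(DEFAULT_HOME_MAP if home_map is None else home_map)
    populations = sorted(summaries["population"].unique())
    sites = sorted(summaries["treatment"].unique())

    la_rows = []
    for pop in populations:
        others = [p for p in populations if p != pop]
        if len(others) != 1:
            raise ValueError("the LA report requires exactly two populations")
        other = others[0]
        for site in sites:
            for trait in traits:
                w_nat = _cell_mean(summaries, pop, site, trait)
                w_for = _cell_mean(summaries, other, site, trait)
                if w_nat is None or w_for is None:
                    warnings.warn(f"missing cell for ({pop} vs {other}, {site} ppt, {trait}); skipped")
                    continue
                est = local_adaptation_index(w_nat, w_for, pop, site, trait)
                la_rows.append(
                    {
                        "population": pop,
                        "site": site,
                        "trait": trait,
                        "w_native": w_nat,
                        "w_foreign": w_for,
                        "la": est.la,
                        "defined": est.defined,
                        "is_home": math.isclose(site, home_map.get(pop, float("nan"))),
                    }
                )
    la = pd.DataFrame(
        la_rows,
        columns=["population", "site", "trait", "w_native", "w_foreign", "la", "defined", "is_home"],
    )

    avg_rows = []
    for (pop, site), g in la.groupby(["population", "site"], sort=True):
        ests = [
            LAEstimate(pop, site, r.trait, r.w_native, r.w_foreign, r.la, r.defined)
            for r in g.itertuples()
        ]
        try:
            avg_rows.append(
                {
                    "population": pop,
                    "site": site,
                    "la_average": trait_average_la(ests),
                    "n_traits": sum(e.defined for e in ests),
                }
            )
        except ValueError:
            warnings.warn(f"no defined LA estimates for ({pop}, {site}); average skipped")
    la_average = pd.DataFrame(avg_rows, columns=["population", "site", "la_average", "n_traits"])

    ma_rows = []
    ideal_site = home_map.get(ancestral)
    realized_site = home_map.get(derived)
    for trait in traits:
        w_ideal = _cell_mean(summaries, ancestral, ideal_site, trait)
        w_real = _cell_mean(summaries, derived, realized_site, trait)
        if w_ideal is None or w_real is None or w_ideal <= 0:
            warnings.warn(f"MA for {trait} skipped (missing or non-positive ideal cell)")
            continue
        est = maladaptation_magnitude(w_ideal, w_real, trait)
        ma_rows.append(
            {
                "trait": trait,
                "w_ideal": est.w_ideal,
                "w_realized": est.w_realized,
                "ma": est.ma,
                "exceeds_ideal": est.exceeds_ideal,
            }
        )
    ma = pd.DataFrame(ma_rows, columns=["trait", "w_ideal", "w_realized", "ma", "exceeds_ideal"])

    trade_rows = []
    for pop in populations:
        home = home_map.get(pop)
        if home is None:
            continue
        for site in sites:
            if math.isclose(site, home):
                continue
            for trait in traits:
                sub_home = la[(la["population"] == pop) & (la["site"] == home) & (la["trait"] == trait)]
                sub_for = la[(la["population"] == pop) & (la["site"] == site) & (la["trait"] == trait)]
                if sub_home.empty or sub_for.empty:
                    continue
                if not (sub_home["defined"].iloc[0] and sub_for["defined"].iloc[0]):
                    continue
                cls = classify_tradeoff(sub_home["la"].iloc[0], sub_for["la"].iloc[0], trait=trait)
                trade_rows.append(
                    {
                        "population": pop,
                        "home_site": home,
                        "foreign_site": site,
                        "trait": trait,
                        "la_home": cls.la_home,
                        "la_foreign": cls.la_foreign,
                        "quadrant": cls.quadrant,
                    }
                )
    tradeoff = pd.DataFrame(
        trade_rows,
        columns=["population", "home_site", "foreign_site", "trait", "la_home", "la_foreign", "quadrant"],
    )

    return {"la": la, "la_average": la_average, "ma": ma, "tradeoff": tradeoff}
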