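"""Supporting statistical tests: ANOVA, Tukey HSD, factorial fixed-effects
models, binomial survival regression, and Welch's t-test.

Responses are box-level aggregates throughout, so the experimental box is
the independent unit and all models are fixed-effects; no random box term
is fitted.  Factorial tables use sequential (Type I) sums of squares with
factors entered treatment, sex, origin, treatment:origin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from scipy.special import expit as _expit
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

from .data import Dataset
from .fitness import trait_frame


@dataclass
class AnovaTable:
    """Sequential ANOVA decomposition: term rows + residual, SS adding to total."""

    terms: list[tuple[str, float, int, float, float]]  # (name, sum_sq, df, F, p)
    residual: tuple[float, int]
    total_sum_sq: float
    chi2: dict[str, tuple[float, float]] | None = None  # term -> (LR chi2, p)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"term": name, "sum_sq": ss, "df": df, "F": F, "p": p}
            for name, ss, df, F, p in self.terms
        ]
        rows.append(
            {"term": "residual", "sum_sq": self.residual[0], "df": self.residual[1],
             "F": np.nan, "p": np.nan}
        )
        df = pd.DataFrame(rows)
        if self.chi2:
            df["lr_chi2"] = df["term"].map(lambda t: self.chi2.get(t, (np.nan, np.nan))[0])
            df["p_chi2"] = df["term"].map(lambda t: self.chi2.get(t, (np.nan, np.nan))[1])
        return df


@dataclass
class TukeyResult:
    """All pairwise studentized-range comparisons at one alpha."""

    pairs: list[tuple[str, str, float, float, float, bool]]
    # (group_a, group_b, mean_diff, q_statistic, adjusted_p, significant)
    alpha: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.pairs,
            columns=["group_a", "group_b", "mean_diff", "q_statistic", "adjusted_p", "significant"],
        )


def anova_oneway(groups) -> AnovaTable:
    """Classical one-way fixed-effects ANOVA on a list of numeric samples.

    Returns the full between/within decomposition; all observations
    identical across >=2 groups yields F = 0 (not an error).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("one-way ANOVA requires at least two groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("every group needs at least one observation")
    all_vals = np.concatenate(groups)
    n_total = len(all_vals)
    k = len(groups)
    if n_total - k < 1:
        raise ValueError("no residual degrees of freedom")
    grand = all_vals.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b, df_w = k - 1, n_total - k
    msb, msw = ssb / df_b, ssw / df_w
    if msw == 0:
        F = 0.0 if msb == 0 else np.inf
    else:
        F = msb / msw
    p = float(scipy.stats.f.sf(F, df_b, df_w)) if np.isfinite(F) else 0.0
    if F == 0:
        p = 1.0
    return AnovaTable(
        terms=[("between", float(ssb), df_b, float(F), p)],
        residual=(float(ssw), df_w),
        total_sum_sq=float(ssb + ssw),
    )


def tukey_hsd(samples: dict[str, np.ndarray], alpha: float = 0.05) -> TukeyResult:
    """Tukey honestly-significant-difference pairwise comparisons.

    Adjusted p-values come from the studentized range distribution
    (scipy's numerical integration); ``q = |mean diff| / sqrt(MSW/2 * (1/na+1/nb))``.
    """
    labels = sorted(samples)
    arrays = [np.asarray(samples[l], dtype=float) for l in labels]
    if len(labels) < 2:
        raise ValueError("Tukey HSD requires at least two groups")
    df_w = sum(len(a) - 1 for a in arrays)
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    if df_w <= 0 or ssw == 0:
        raise ValueError("pooled within-group variance must be positive")
    msw = ssw / df_w
    res = scipy.stats.tukey_hsd(*arrays)
    pairs = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            diff = arrays[i].mean() - arrays[j].mean()
            se_q = np.sqrt(msw / 2 * (1 / len(arrays[i]) + 1 / len(arrays[j])))
            q = abs(diff) / se_q
            p = float(res.pvalue[i, j])
            pairs.append((labels[i], labels[j], float(diff), float(q), p, p < alpha))
    return TukeyResult(pairs=pairs, alpha=alpha)


def _sequential_tables(df: pd.DataFrame, response: str, terms: list[str]):
    """OLS fit + Type I ANOVA + per-term likelihood-ratio chi-square."""
    rhs = " + ".join(terms)
    fit = smf.ols(f"{response} ~ {rhs}", data=df).fit()
    table = anova_lm(fit, typ=1)
    # LR chi2 by comparing nested sequential fits
    chi2: dict[str, tuple[float, float]] = {}
    prev = smf.ols(f"{response} ~ 1", data=df).fit()
    for i in range(len(terms)):
        cur = smf.ols(f"{response} ~ {' + '.join(terms[: i + 1])}", data=df).fit()
        lr = 2 * (cur.llf - prev.llf)
        ddf = cur.df_model - prev.df_model
        p = float(scipy.stats.chi2.sf(lr, ddf)) if ddf > 0 else np.nan
        chi2[terms[i]] = (float(lr), p)
        prev = cur
    return fit, table, chi2


def factorial_lm(
    df: pd.DataFrame,
    response: str,
    factors: list[str],
    with_interaction: bool = True,
) -> AnovaTable:
    """Fixed-effects factorial model on box-level responses.

    Sequential (Type I) sums of squares in the order given; the interaction
    of the first and last factor is appended when ``with_interaction``.
    Raises on rank-deficient designs, naming the aliased terms.
    """
    terms = [f"C({f})" for f in factors]
    if with_interaction and len(factors) >= 2:
        terms.append(f"C({factors[0]}):C({factors[-1]})")
    fit, table, chi2 = _sequential_tables(df, response, terms)
    if np.linalg.matrix_rank(fit.model.exog) < fit.model.exog.shape[1]:
        raise ValueError(f"rank-deficient design; aliased terms among {terms}")
    pretty = {f"C({f})": f for f in factors}
    if with_interaction and len(factors) >= 2:
        pretty[f"C({factors[0]}):C({factors[-1]})"] = f"{factors[0]}:{factors[-1]}"
    out_terms = []
    for name in table.index:
        if name == "Residual":
            continue
        row = table.loc[name]
        out_terms.append(
            (pretty.get(name, name), float(row["sum_sq"]), int(row["df"]), float(row["F"]), float(row["PR(>F)"]))
        )
    resid = table.loc["Residual"]
    chi2_pretty = {pretty.get(k, k): v for k, v in chi2.items()}
    return AnovaTable(
        terms=out_terms,
        residual=(float(resid["sum_sq"]), int(resid["df"])),
        total_sum_sq=float(table["sum_sq"].sum()),
        chi2=chi2_pretty,
    )


def logistic_survival_model(ds: Dataset, predictors=("salinity",)) -> dict:
    """Binomial-logit regression of box survival proportion on salinity (± sex).

    Shares the GLM engine with the dose-response module; survival (not
    mortality) is the modelled outcome here, so coefficients flip sign
    relative to a mortality fit on the same data.  Returns the coefficient
    table plus a callable producing fitted curves with pointwise 95% bands
    on the probability scale.
    """
    rows = []
    for box in ds.records:
        horizon = min(box.days_observed, min(len(s) for s in box.daily_alive.values()) - 1)
        if "sex" in predictors:
            for sex, n0 in (("M", box.n_males), ("F", box.n_females)):
                if n0 > 0:
                    rows.append(
                        {"salinity": box.treatment, "sex": sex,
                         "alive": box.alive_on(horizon, sex=sex), "n": n0}
                    )
        else:
            rows.append({"salinity": box.treatment, "alive": box.alive_on(horizon), "n": box.n_initial})
    df = pd.DataFrame(rows)
    if "sex" in predictors:
        exog = pd.DataFrame(
            {
                "const": 1.0,
                "salinity": df["salinity"],
                "sex_M": (df["sex"] == "M").astype(float),
                "salinity:sex_M": df["salinity"] * (df["sex"] == "M"),
            }
        )
    else:
        exog = pd.DataFrame({"const": 1.0, "salinity": df["salinity"]})
    endog = np.column_stack([df["alive"], df["n"] - df["alive"]])
    res = sm.GLM(endog, exog, family=sm.families.Binomial()).fit(maxiter=100, tol=1e-8)
    separated = bool(np.max(np.abs(res.params)) > 30) or not np.all(np.isfinite(res.bse))
    coef = pd.DataFrame(
        {"coef": res.params, "se": res.bse, "z": res.tvalues, "p": res.pvalues,
         "ci_lo": res.conf_int()[0], "ci_hi": res.conf_int()[1]}
    )

    def predict(salinity, sex: str | None = None, level: float = 0.95):
        salinity = np.atleast_1d(np.asarray(salinity, dtype=float))
        if "sex" in predictors:
            is_m = 1.0 if sex == "M" else 0.0
            X = np.column_stack([np.ones_like(salinity), salinity, np.full_like(salinity, is_m), salinity * is_m])
        else:
            X = np.column_stack([np.ones_like(salinity), salinity])
        eta = X @ res.params.to_numpy()
        se_eta = np.sqrt(np.einsum("ij,jk,ik->i", X, res.cov_params().to_numpy(), X))
        z = scipy.stats.norm.ppf(0.5 + level / 2)
        return pd.DataFrame(
            {"salinity": salinity, "p_survival": _expit(eta),
             "lo": _expit(eta - z * se_eta), "hi": _expit(eta + z * se_eta)}
        )

    return {"coefficients": coef, "predict": predict, "separated": separated, "results": res}


def welch_t_test(x, y) -> tuple[float, float, float]:
    """Welch's unequal-variance two-sample t-test with Satterthwaite df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs n >= 2")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        if x.mean() == y.mean():
            return 0.0, float(len(x) + len(y) - 2), 1.0
        return float(np.inf) * np.sign(x.mean() - y.mean()), float(len(x) + len(y) - 2), 0.0
    t, p = scipy.stats.ttest_ind(x, y, equal_var=False)
    sx2, sy2 = vx / len(x), vy / len(y)
    df = (sx2 + sy2) ** 2 / (sx2**2 / (len(x) - 1) + sy2**2 / (len(y) - 1))
    return float(t), float(df), float(p)


def trait_anova(ds: Dataset, trait: str, treatments=None) -> tuple[AnovaTable, TukeyResult]:
    """One-way ANOVA + Tukey HSD of one fitness surrogate across treatments."""
    long = trait_frame(ds)
    long = long[long["trait"] == trait]
    if treatments is not None:
        long = long[long["treatment"].isin(treatments)]
    samples = {f"{t:g} ppt": g["value"].to_numpy() for t, g in long.groupby("treatment")}
    table = anova_oneway(list(samples.values()))
    tukey = tukey_hsd(samples)
    return table, tukey
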