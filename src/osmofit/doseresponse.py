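"""Dose-response modelling of acute salinity mortality and LC50 estimation.

The model is a binomial GLM with logit link fitted to per-replicate death
counts against untransformed salinity (ppt):

    logit Pr(death) = beta0 + beta1 * dose

LC50, the dose at which modelled mortality is 50%, is the logit zero
crossing ``-beta0/beta1``.  Its standard error comes from the delta method
applied to the coefficient covariance (a Fieller interval is available as
an alternative).  Mortality — not survival — is modelled so that LC50 is
the 0.5 point of the fitted curve directly.

Dose stays on the natural scale (no log transform) because the designs of
interest include a true 0 ppt (freshwater) treatment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

from .data import Dataset, TolCensus

#: logit-scale coefficient magnitude beyond which the fit is flagged as separated
SEPARATION_THRESHOLD = 30.0
MAX_ITER = 100
DEVIANCE_TOL = 1e-8


class UndefinedLC50Error(ZeroDivisionError):
    """Raised when the fitted slope is zero and LC50 is undefined."""


def lc50_from_fit(beta0: float, beta1: float) -> float:
    """Dose at which modelled mortality is 0.5, i.e. ``-beta0/beta1``."""
    if beta1 == 0:
        raise UndefinedLC50Error("slope is zero: the mortality curve never crosses 0.5")
    return -beta0 / beta1


def _tolerance_frame(ds: Dataset, exposure_hr: int, population: str | None = None) -> pd.DataFrame:
    rows = []
    for rec in ds.records:
        if not isinstance(rec, TolCensus):
            raise TypeError("dose-response fitting requires a tolerance (TolCensus) dataset")
        if population is not None and rec.population != population:
            continue
        rows.append(
            {
                "replicate_id": rec.replicate_id,
                "population": rec.population,
                "dose": rec.salinity,
                "deaths": rec.deaths(exposure_hr),
                "n": rec.n_initial,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class DoseResponseResults:
    """Fitted mortality curve for one population x exposure time.

    ``r2`` is the squared Pearson correlation between observed and fitted
    replicate mortality proportions (the model is binomial, so no unique R²
    exists; the definition used is recorded in ``r2_definition``).
    """

    beta0: float
    beta1: float
    cov: np.ndarray
    lc50: float
    lc50_se: float
    r2: float
    exposure_hr: int
    population: str
    converged: bool
    separated: bool
    n_iter: int
    deviance: float
    model: "DoseResponseModel" = field(repr=False, default=None)
    r2_definition: str = "squared correlation of observed vs fitted replicate proportions"

    @property
    def params(self) -> np.ndarray:
        return np.array([self.beta0, self.beta1])

    def predict(self, dose) -> np.ndarray:
        """Modelled mortality probability at *dose* (ppt)."""
        eta = self.beta0 + self.beta1 * np.asarray(dose, dtype=float)
        return scipy.stats.logistic.cdf(eta)

    def lc50_confidence_interval(self, level: float = 0.95, method: str = "delta"):
        """Confidence interval for LC50 on the dose scale.

        ``method="delta"`` (default) is symmetric: lc50 ± z * SE with the
        delta-method SE of -beta0/beta1.  ``method="fieller"`` inverts the
        ratio test and can be asymmetric or unbounded near beta1 = 0.
        """
        if not np.all(np.isfinite(self.cov)):
            raise np.linalg.LinAlgError("coefficient covariance is not finite")
        z = scipy.stats.norm.ppf(0.5 + level / 2)
        if method == "delta":
            return self.lc50 - z * self.lc50_se, self.lc50 + z * self.lc50_se
        if method == "fieller":
            b0, b1 = self.beta0, self.beta1
            v00, v11 = self.cov[0, 0], self.cov[1, 1]
            v01 = self.cov[0, 1]
            # the interval is {d : (b0 + b1 d)^2 <= z^2 Var(b0 + b1 d)},
            # a quadratic in d that is bounded only when the slope is
            # significantly non-zero (a > 0)
            a = b1**2 - z**2 * v11
            b = 2 * (b0 * b1 - z**2 * v01)
            c = b0**2 - z**2 * v00
            disc = b**2 - 4 * a * c
            if a <= 0 or disc < 0:
                return -np.inf, np.inf
            lo = (-b - np.sqrt(disc)) / (2 * a)
            hi = (-b + np.sqrt(disc)) / (2 * a)
            return lo, hi
        raise ValueError(f"unknown CI method {method!r}")

    def plot(self, ax=None, dose_grid=None, ci_level: float = 0.95):
        """Observed replicate mortality, fitted curve and the LC50 marker."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if dose_grid is None:
            hi = max(self.model.dose.max(), self.lc50) * 1.05 if self.model is not None else 35
            dose_grid = np.linspace(0, hi, 200)
        if self.model is not None:
            ax.scatter(self.model.dose, self.model.deaths / self.model.n, s=18, alpha=0.6,
                       label="replicate boxes")
        ax.plot(dose_grid, self.predict(dose_grid), label="fitted mortality")
        if np.isfinite(self.lc50):
            ax.axvline(self.lc50, linestyle=":", label=f"LC50 = {self.lc50:.2f} ppt")
            if np.isfinite(self.lc50_se):
                lo, hi_ci = self.lc50_confidence_interval(ci_level)
                ax.axvspan(lo, hi_ci, alpha=0.15)
        ax.set_xlabel("salinity (ppt)")
        ax.set_ylabel("mortality probability")
        ax.set_ylim(-0.02, 1.02)
        ax.legend()
        return ax

    def summary(self) -> str:
        lines = [
            f"Dose-response logistic fit  [{self.population or 'pooled'} @ {self.exposure_hr} hr]",
            "=" * 58,
            f"  intercept (logit)   {self.beta0: .4f}  (SE {np.sqrt(self.cov[0,0]):.4f})",
            f"  slope (per ppt)     {self.beta1: .4f}  (SE {np.sqrt(self.cov[1,1]):.4f})",
            f"  LC50 (ppt)          {self.lc50: .3f}  ± {self.lc50_se:.3f} (delta SE)",
            f"  R2 (obs~fit props)  {self.r2: .3f}",
            f"  converged={self.converged}  separated={self.separated}  iter={self.n_iter}",
        ]
        return "\n".join(lines)


class DoseResponseModel:
    """Binomial-logit mortality model for one exposure time.

    Parameters
    ----------
    deaths, n, dose : array-like
        Replicate-level death counts, group sizes, and salinity (ppt).
    """

    def __init__(self, deaths, n, dose, exposure_hr: int = 48, population: str = ""):
        self.deaths = np.asarray(deaths, dtype=float)
        self.n = np.asarray(n, dtype=float)
        self.dose = np.asarray(dose, dtype=float)
        if len(np.unique(self.dose)) < 2:
            raise ValueError("at least two distinct doses are required to fit a curve")
        self.exposure_hr = exposure_hr
        self.population = population

    @classmethod
    def from_dataset(cls, ds: Dataset, exposure_hr: int, population: str | None = None):
        df = _tolerance_frame(ds, exposure_hr, population)
        if df.empty:
            raise ValueError(f"no tolerance records for population {population!r}")
        return cls(
            df["deaths"], df["n"], df["dose"],
            exposure_hr=exposure_hr,
            population=population if population is not None else "",
        )

    def fit(self) -> DoseResponseResults:
        endog = np.column_stack([self.deaths, self.n - self.deaths])
        exog = sm.add_constant(self.dose)
        glm = sm.GLM(endog, exog, family=sm.families.Binomial())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = glm.fit(maxiter=MAX_ITER, tol=DEVIANCE_TOL)
        beta0, beta1 = res.params
        # degenerate outcomes (every replicate all-dead, or all-alive) admit
        # no finite MLE even though the IRLS deviance flattens out
        degenerate = bool(np.all(self.deaths == self.n) or np.all(self.deaths == 0))
        separated = (
            degenerate
            or bool(np.max(np.abs(res.params)) > SEPARATION_THRESHOLD)
            or not np.all(np.isfinite(res.bse))
        )
        converged = bool(res.converged) and not separated
        cov = np.asarray(res.cov_params())
        if beta1 != 0:
            lc50 = lc50_from_fit(beta0, beta1)
            # delta method on g(b) = -b0/b1: grad = (-1/b1, b0/b1^2)
            grad = np.array([-1.0 / beta1, beta0 / beta1**2])
            var = float(grad @ cov @ grad)
            lc50_se = float(np.sqrt(var)) if var >= 0 and np.isfinite(var) else np.nan
        else:
            lc50, lc50_se = np.nan, np.nan
        obs = np.divide(self.deaths, self.n)
        fitted = scipy.stats.logistic.cdf(beta0 + beta1 * self.dose)
        if np.std(obs) > 0 and np.std(fitted) > 0:
            r2 = float(np.corrcoef(obs, fitted)[0, 1] ** 2)
        else:
            r2 = 0.0
        return DoseResponseResults(
            beta0=float(beta0),
            beta1=float(beta1),
            cov=cov,
            lc50=float(lc50),
            lc50_se=lc50_se,
            r2=r2,
            exposure_hr=self.exposure_hr,
            population=self.population,
            converged=converged,
            separated=separated,
            n_iter=int(getattr(res, "fit_history", {}).get("iteration", MAX_ITER))
            if hasattr(res, "fit_history")
            else MAX_ITER,
            deviance=float(res.deviance),
            model=self,
        )


def fit_mortality_curve(ds: Dataset, exposure_hr: int, population: str | None = None) -> DoseResponseResults:
    """Fit the logistic mortality curve for one exposure time.

    Convenience wrapper over :class:`DoseResponseModel`; a completely
    separated dataset (e.g. all-dead everywhere above some dose, all-alive
    below) is returned with ``converged=False`` and ``separated=True``
    rather than raising.
    """
    return DoseResponseModel.from_dataset(ds, exposure_hr, population).fit()


def lc50_comparison_model(ds: Dataset, exposure_hr: int) -> pd.DataFrame:
    """Compare tolerance between populations via ANCOVA on replicate survival.

    Fits a linear model of replicate-level survival proportion on dose
    (covariate), population (factor) and their interaction, and reports
    sequential F-tests plus the full-model R².  The replicate box is the
    unit of analysis.
    """
    df = _tolerance_frame(ds, exposure_hr)
    pops = sorted(df["population"].unique())
    if len(pops) < 2:
        raise ValueError("two populations are required for a tolerance comparison")
    shared = set(df[df["population"] == pops[0]]["dose"]) & set(
        df[df["population"] == pops[1]]["dose"]
    )
    if len(shared) < 2:
        raise ValueError("populations share fewer than two common doses")
    df = df.assign(survival=1.0 - df["deaths"] / df["n"])
    fit = smf.ols("survival ~ dose + C(population) + dose:C(population)", data=df).fit()
    table = anova_lm(fit, typ=1)
    table = table.rename(
        index={
            "dose": "dose",
            "C(population)": "population",
            "dose:C(population)": "dose:population",
            "Residual": "residual",
        }
    )
    table.attrs["r2"] = float(fit.rsquared)
    return table
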