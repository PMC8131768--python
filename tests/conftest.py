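import numpy as np
import pytest

from osmofit.data import Dataset, GardenBox, TolCensus
from osmofit.simulate import load_published_fitness_means


@pytest.fixture(scope="session")
def published_means():
    return load_published_fitness_means()


def make_box(
    box_id="b1",
    origin="FW",
    treatment=0.0,
    alive_m=(5, 3),
    alive_f=(5, 2),
    eggs=78,
    days=30,
    n_offspring=10,
    f1=(),
):
    """GardenBox with a two-point daily series padded flat to `days`."""
    series_m = list(alive_m) + [alive_m[-1]] * (days - len(alive_m) + 1)
    series_f = list(alive_f) + [alive_f[-1]] * (days - len(alive_f) + 1)
    return GardenBox(
        box_id=box_id,
        origin=origin,
        treatment=treatment,
        n_males=alive_m[0],
        n_females=alive_f[0],
        daily_alive={"M": series_m, "F": series_f},
        eggs_total=eggs,
        days_observed=days,
        n_offspring=n_offspring,
        f1_longevity=list(f1),
    )


@pytest.fixture
def simple_box():
    return make_box()


@pytest.fixture
def tol_dataset():
    """Deterministic tolerance dataset: 5 doses, death counts rising with dose."""
    deaths_by_dose = {0.0: 0, 5.0: 1, 10.0: 5, 15.0: 9, 20.0: 10}
    records = []
    for dose, deaths in deaths_by_dose.items():
        records.append(
            TolCensus(
                replicate_id=f"d{dose:g}",
                salinity=dose,
                n_initial=10,
                alive_at={48: 10 - deaths, 72: 10 - deaths, 96: 10 - deaths},
                population="FW",
            )
        )
    return Dataset(records)


def binomial_logit_nll(params, dose, deaths, n):
    """Independent negative log-likelihood for the mortality logit model."""
    b0, b1 = params
    eta = b0 + b1 * np.asarray(dose, dtype=float)
    # log(p) = eta - log(1+e^eta); log(1-p) = -log(1+e^eta)
    log1pe = np.logaddexp(0.0, eta)
    return -float(np.sum(deaths * (eta - log1pe) + (n - deaths) * (-log1pe)))
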