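"""Shared fixtures: synthetic hazards, rate-matrix pairs, file fixtures."""

import numpy as np
import pandas as pd
import pytest

import lifegap as lg
from lifegap.io import MORTALITY_COLUMNS, POPULATION_COLUMNS


@pytest.fixture(scope="session")
def five_cause_mix():
    return {
        "treatable": 0.15,
        "preventable": 0.25,
        "treatable_and_preventable": 0.10,
        "ihd": 0.20,
        "non_avoidable": 0.30,
    }


@pytest.fixture(scope="session")
def base_hazard(five_cause_mix):
    return lg.HazardSpec(cause_mix=five_cause_mix)


@pytest.fixture(scope="session")
def gompertz_rate_pair(base_hazard, five_cause_mix):
    """Two rate matrices differing smoothly in every cell (10% level shift
    in the comparator's senescent component)."""
    ref = lg.make_rates(base_hazard, country="REF", sex="male", period="2015-2016")
    cmp_hazard = lg.HazardSpec(
        makeham=base_hazard.makeham,
        gompertz_level=base_hazard.gompertz_level * 0.9,
        gompertz_slope=base_hazard.gompertz_slope,
        infant_excess=base_hazard.infant_excess * 0.5,
        cause_mix=five_cause_mix,
    )
    cmp_ = lg.make_rates(cmp_hazard, country="CMP", sex="male", period="2015-2016")
    return ref, cmp_


@pytest.fixture(scope="session")
def injected_scenario(base_hazard):
    """Reference with doubled 'preventable' rates in ages 15-49, else
    identical to the comparator."""
    return lg.ScenarioSpec(
        base=base_hazard,
        countries=("REF", "CMP"),
        perturbations=[lg.Perturbation("REF", "preventable", 15, 45, 2.0)],
        seed=11,
    )


@pytest.fixture(scope="session")
def injected_pair(injected_scenario):
    return lg.make_country_pair(injected_scenario)


def random_long_table(seed: int, n_causes: int = 3, countries=("AAA", "BBB"),
                      years=(2015, 2016)) -> pd.DataFrame:
    """Deterministic random long-format mortality table on the full ladder."""
    rng = np.random.default_rng(seed)
    causes = [f"A{10 + i:02d}" for i in range(n_causes)]
    rows = []
    for country in countries:
        for year in years:
            for sex in ("male", "female"):
                for lower in lg.LADDER_LOWER:
                    for cause in causes:
                        rows.append(dict(
                            country=country, year=year, sex=sex,
                            age_lower=lower, age_width=np.nan, cause=cause,
                            deaths=int(rng.integers(0, 50)),
                        ))
    return pd.DataFrame(rows, columns=MORTALITY_COLUMNS)


def uniform_population(countries=("AAA",), years=(2015, 2016),
                       size: float = 50_000.0) -> pd.DataFrame:
    rows = [
        dict(country=c, year=y, sex=s, age_lower=lo, age_width=np.nan,
             population=size)
        for c in countries for y in years for s in ("male", "female")
        for lo in lg.LADDER_LOWER
    ]
    return pd.DataFrame(rows, columns=POPULATION_COLUMNS)


@pytest.fixture()
def long_table():
    return random_long_table(7)


@pytest.fixture(scope="session")
def external_table():
    """Strictly positive external all-cause schedule on the ladder."""
    h = lg.HazardSpec(cause_mix={"all": 1.0})
    rates = lg.make_rates(h).rates["all"] * 1.25
    return lg.ExternalLifeTable(rates=rates, source="synthetic-external")
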