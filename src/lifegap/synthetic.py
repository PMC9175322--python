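"""Synthetic WHO-style mortality fixtures with known structure.

The generator builds two-country scenarios from a Gompertz–Makeham hazard

    h(x) = makeham + level * exp(slope * x)   (+ infant excess on [0,1))

evaluated at age-group midpoints (the open 85+ group at 90), split across
causes by an age-dependent share mix, optionally perturbed in named
(country, cause, age-range) cells by a multiplicative factor, and finally
realised as Poisson death counts against supplied person-years. The exact
(noise-free) rate matrices are returned alongside the counts so
decomposition recovery can be checked against known injected differences.

Randomness is reproducible and cell-local: each (country, year, age,
cause) count draws from its own RNG substream derived from the master
seed, so adding a cause or year never shifts the draws of other cells.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .ages import LADDER, LADDER_LOWER, validate_lower_bounds
from .io import (
    MORTALITY_COLUMNS,
    POPULATION_COLUMNS,
    RateMatrix,
    ValidationError,
    validate_mortality,
    validate_population,
)

ShareSpec = float | Sequence[float] | Callable[[float], float]


@dataclass
class HazardSpec:
    """Gompertz–Makeham all-cause hazard with an age-dependent cause mix.

    Parameters
    ----------
    makeham : float
        Age-independent background rate (per person-year), >= 0.
    gompertz_level, gompertz_slope : float
        Senescent component level * exp(slope * age); both > 0.
    infant_excess : float
        Extra rate added to the [0,1) group only, >= 0 (crude infant
        mortality hump).
    cause_mix : mapping
        Cause label -> share of the all-cause hazard: a constant, a
        sequence of 19 per-age-group shares, or a callable of age
        (midpoint, years). Shares must be >= 0 and sum to 1 at every age.
    """

    makeham: float = 5e-4
    gompertz_level: float = 3e-5
    gompertz_slope: float = 0.095
    infant_excess: float = 0.012
    cause_mix: Mapping[str, ShareSpec] = field(
        default_factory=lambda: {"all": 1.0}
    )

    def all_cause_at(self, age: float, *, infant: bool = False) -> float:
        h = self.makeham + self.gompertz_level * np.exp(self.gompertz_slope * age)
        if infant:
            h += self.infant_excess
        return float(h)

    def shares_at(self, age: float, group_index: int) -> dict[str, float]:
        out = {}
        for cause, spec in self.cause_mix.items():
            if callable(spec):
                out[cause] = float(spec(age))
            elif np.isscalar(spec):
                out[cause] = float(spec)
            else:
                out[cause] = float(spec[group_index])
        total = sum(out.values())
        if any(v < 0 for v in out.values()) or abs(total - 1.0) > 1e-12:
            raise ValidationError(
                f"cause shares at age {age} must be >= 0 and sum to 1 "
                f"(got sum {total!r})"
            )
        return out


def make_rates(
    h: HazardSpec, *, country: str = "", sex: str = "male", period: str = ""
) -> RateMatrix:
    """Exact age x cause rate matrix for one hazard specification."""
    rows = []
    for i, grp in enumerate(LADDER):
        mid = grp.midpoint
        total = h.all_cause_at(mid, infant=(grp.lower == 0 and not grp.is_open))
        if total <= 0:
            raise ValidationError(f"all-cause hazard non-positive at age {mid}")
        shares = h.shares_at(mid, i)
        rows.append({c: total * s for c, s in shares.items()})
    rates = pd.DataFrame(rows, index=list(LADDER_LOWER))
    return RateMatrix(rates=rates, country=country, sex=sex, period=period)


def _cell_rng(seed: int, country: str, year: int, age_lower: int, cause: str):
    entropy = [
        int(seed),
        zlib.crc32(country.encode()),
        int(year),
        int(age_lower),
        zlib.crc32(cause.encode()),
    ]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def simulate_counts(
    r: RateMatrix,
    pop: pd.DataFrame,
    seed: int,
) -> pd.DataFrame:
    """Poisson death counts deaths[a,c] ~ Poisson(rate * person-years).

    ``pop`` is a population table for the same stratum (one row per year
    and age group); counts are drawn independently per (year, age, cause)
    cell from seed-derived substreams, so repeated calls with one seed are
    identical.
    """
    popv = validate_population(pop)
    if (popv["population"] < 0).any():  # validate_population already rejects <= 0
        raise ValidationError("person-years must be non-negative")
    records = []
    for _, prow in popv.iterrows():
        lower = int(prow["age_lower"])
        for cause in r.causes:
            rate = float(r.rates.at[lower, cause])
            lam = rate * float(prow["population"])
            rng = _cell_rng(seed, str(prow["country"]), int(prow["year"]),
                            lower, cause)
            deaths = int(rng.poisson(lam)) if lam > 0 else 0
            records.append(
                dict(country=prow["country"], year=prow["year"],
                     sex=prow["sex"], age_lower=lower,
                     age_width=prow["age_width"], cause=cause, deaths=deaths)
            )
    out = pd.DataFrame(records, columns=MORTALITY_COLUMNS)
    return validate_mortality(out)


@dataclass
class Perturbation:
    country: str
    cause: str
    age_lo: int  # inclusive lower bound of first affected group
    age_hi: int  # affected groups have lower bound <= age_hi
    factor: float

    def __post_init__(self) -> None:
        if self.factor <= 0:
            raise ValidationError(f"perturbation factor must be > 0, got {self.factor}")
        validate_lower_bounds([self.age_lo])


@dataclass
class ScenarioSpec:
    """A two-country scenario with known injected rate differences."""

    base: HazardSpec
    countries: tuple[str, str] = ("REF", "CMP")
    sex: str = "male"
    perturbations: list[Perturbation] = field(default_factory=list)
    populations: Mapping[int, float] = field(
        default_factory=lambda: {lo: 100_000.0 for lo in LADDER_LOWER}
    )
    years: Sequence[int] = (2015, 2016)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "ScenarioSpec":
        doc = yaml.safe_load(open(path, encoding="utf-8"))
        base = HazardSpec(
            makeham=float(doc.get("makeham", 5e-4)),
            gompertz_level=float(doc.get("gompertz_level", 3e-5)),
            gompertz_slope=float(doc.get("gompertz_slope", 0.095)),
            infant_excess=float(doc.get("infant_excess", 0.012)),
            cause_mix={str(k): float(v)
                       for k, v in doc.get("cause_mix", {"all": 1.0}).items()},
        )
        perts = [
            Perturbation(
                country=str(p["country"]), cause=str(p["cause"]),
                age_lo=int(p["age_lo"]), age_hi=int(p["age_hi"]),
                factor=float(p["factor"]),
            )
            for p in doc.get("perturbations", [])
        ]
        pops = {int(k): float(v) for k, v in doc.get("populations", {}).items()} \
            or {lo: 100_000.0 for lo in LADDER_LOWER}
        return cls(
            base=base,
            countries=tuple(doc.get("countries", ("REF", "CMP"))),
            sex=str(doc.get("sex", "male")),
            perturbations=perts,
            populations=pops,
            years=[int(y) for y in doc.get("years", (2015, 2016))],
            seed=int(doc.get("seed", 0)),
        )


@dataclass
class CountryPair:
    """Simulated counts, populations and the exact underlying rates."""

    mortality: dict[str, pd.DataFrame]
    population: dict[str, pd.DataFrame]
    exact_rates: dict[str, RateMatrix]


def make_country_pair(s: ScenarioSpec) -> CountryPair:
    """Realise a scenario: exact rates per country, then Poisson counts."""
    period = (f"{min(s.years)}-{max(s.years)}"
              if len(set(s.years)) > 1 else str(s.years[0]))
    exact: dict[str, RateMatrix] = {}
    for country in s.countries:
        rm = make_rates(s.base, country=country, sex=s.sex, period=period)
        for p in s.perturbations:
            if p.country != country:
                continue
            if p.cause not in rm.causes:
                raise ValidationError(
                    f"perturbation names unknown cause {p.cause!r}; "
                    f"scenario causes: {rm.causes}"
                )
            mask = [(p.age_lo <= lo <= p.age_hi) for lo in LADDER_LOWER]
            rm.rates.loc[mask, p.cause] *= p.factor
        exact[country] = rm

    mortality: dict[str, pd.DataFrame] = {}
    population: dict[str, pd.DataFrame] = {}
    for country in s.countries:
        pop_records = [
            dict(country=country, year=year, sex=s.sex, age_lower=lo,
                 age_width=np.nan, population=float(s.populations[lo]))
            for year in s.years for lo in LADDER_LOWER
        ]
        pop = validate_population(pd.DataFrame(pop_records, columns=POPULATION_COLUMNS))
        population[country] = pop
        mortality[country] = simulate_counts(exact[country], pop, s.seed)
    return CountryPair(mortality=mortality, population=population, exact_rates=exact)
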