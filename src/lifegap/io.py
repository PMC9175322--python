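"""Reading, validating, pooling and rate conversion for cause-of-death data.

Two on-disk dialects are supported:

* the canonical long CSV with columns
  ``country,year,sex,age_lower,age_width,cause,deaths`` (one row per
  stratum-cause), and
* the WHO mortality-database wide dialect, one row per
  (country, year, sex, cause) with numbered ``Deaths1..DeathsN`` age-bucket
  columns whose meaning is supplied by an age-format mapping.

In memory both become a tidy :class:`pandas.DataFrame` on the canonical
19-group age ladder. Central death rates are deaths divided by person-years
of exposure; for a multi-year pooled period the person-years are the sum of
the annual mid-year populations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .ages import LADDER_LOWER, LADDER_WIDTH, OPEN, validate_lower_bounds

logger = logging.getLogger("lifegap")

MORTALITY_COLUMNS = ["country", "year", "sex", "age_lower", "age_width", "cause", "deaths"]
POPULATION_COLUMNS = ["country", "year", "sex", "age_lower", "age_width", "population"]

_SEX_SYNONYMS = {
    "1": "male", "m": "male", "male": "male", "males": "male",
    "2": "female", "f": "female", "female": "female", "females": "female",
}


class FormatError(ValueError):
    """Structural problem with an input file (missing/unknown columns)."""


class ValidationError(ValueError):
    """Content problem with otherwise well-formed data."""


def normalize_sex(value) -> str:
    key = str(value).strip().lower()
    try:
        return _SEX_SYNONYMS[key]
    except KeyError:
        raise ValidationError(
            f"unrecognized sex code {value!r}; accepted: 1/2, male/female"
        ) from None


def _width_for(lowers: pd.Series) -> pd.Series:
    widths = {lo: w for lo, w in zip(LADDER_LOWER, LADDER_WIDTH)}
    return lowers.map(widths)


def validate_mortality(df: pd.DataFrame, *, allow_real_deaths: bool = False) -> pd.DataFrame:
    """Validate and normalize a long-format mortality table.

    Checks the canonical ladder, non-negative deaths (integral unless
    ``allow_real_deaths``, for post-recalibration tables), sex codes, and
    key uniqueness. Returns a normalized copy.
    """
    missing = [c for c in MORTALITY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"mortality table missing columns: {missing}")
    out = df.loc[:, MORTALITY_COLUMNS].copy()
    out["sex"] = out["sex"].map(normalize_sex)
    out["age_lower"] = pd.to_numeric(out["age_lower"], errors="raise").astype(int)
    validate_lower_bounds(out["age_lower"])
    out["age_width"] = _width_for(out["age_lower"])
    out["deaths"] = pd.to_numeric(out["deaths"], errors="raise").astype(float)
    if (out["deaths"] < 0).any():
        bad = out.loc[out["deaths"] < 0].iloc[0]
        raise ValidationError(
            f"negative deaths ({bad['deaths']}) for "
            f"{bad['country']}/{bad['year']}/{bad['sex']}/"
            f"age {bad['age_lower']}/{bad['cause']}"
        )
    if not allow_real_deaths:
        nonint = out["deaths"] % 1 != 0
        if nonint.any():
            bad = out.loc[nonint].iloc[0]
            raise ValidationError(
                f"non-integer deaths ({bad['deaths']}) in pre-pooling table "
                f"at {bad['country']}/age {bad['age_lower']}/{bad['cause']}"
            )
    key = ["country", "year", "sex", "age_lower", "cause"]
    dup = out.duplicated(subset=key, keep=False)
    if dup.any():
        first = out.loc[dup, key].iloc[0].to_dict()
        raise ValidationError(f"duplicate mortality key: {first}")
    return out.reset_index(drop=True)


def validate_population(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in POPULATION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"population table missing columns: {missing}")
    out = df.loc[:, POPULATION_COLUMNS].copy()
    out["sex"] = out["sex"].map(normalize_sex)
    out["age_lower"] = pd.to_numeric(out["age_lower"], errors="raise").astype(int)
    validate_lower_bounds(out["age_lower"])
    out["age_width"] = _width_for(out["age_lower"])
    out["population"] = pd.to_numeric(out["population"], errors="raise").astype(float)
    if (out["population"] <= 0).any():
        bad = out.loc[out["population"] <= 0].iloc[0]
        raise ValidationError(
            f"non-positive population at {bad['country']}/{bad['year']}/"
            f"{bad['sex']}/age {bad['age_lower']}"
        )
    key = ["country", "year", "sex", "age_lower"]
    if out.duplicated(subset=key).any():
        dup = out.loc[out.duplicated(subset=key), key].iloc[0].to_dict()
        raise ValidationError(f"duplicate population key: {dup}")
    return out.reset_index(drop=True)


def read_long(path) -> pd.DataFrame:
    """Read the canonical long CSV into a validated mortality table."""
    df = pd.read_csv(path, dtype={"country": str, "sex": str, "cause": str})
    return validate_mortality(df)


def write_long(df: pd.DataFrame, path, *, allow_real_deaths: bool = False) -> None:
    """Write a mortality table as canonicalized long CSV.

    Canonical form: key-sorted rows, fixed column order, open-group width
    written as ``inf``, integral deaths written without a decimal point.
    ``write_long(read_long(f))`` reproduces a canonical file byte-for-byte.
    """
    out = validate_mortality(df, allow_real_deaths=allow_real_deaths)
    out = out.sort_values(
        ["country", "year", "sex", "age_lower", "cause"], kind="mergesort"
    ).reset_index(drop=True)
    out["age_width"] = out["age_width"].map(lambda w: "inf" if np.isinf(w) else int(w))
    out["deaths"] = out["deaths"].map(
        lambda d: str(int(d)) if float(d).is_integer() else repr(float(d))
    )
    out.to_csv(path, index=False, lineterminator="\n")


def read_population(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"country": str, "sex": str})
    return validate_population(df)


def write_population(df: pd.DataFrame, path) -> None:
    out = validate_population(df)
    out = out.sort_values(
        ["country", "year", "sex", "age_lower"], kind="mergesort"
    ).reset_index(drop=True)
    out["age_width"] = out["age_width"].map(lambda w: "inf" if np.isinf(w) else int(w))
    out.to_csv(path, index=False, lineterminator="\n")


def read_who_wide(path, age_format: Mapping[str, object]) -> pd.DataFrame:
    """Read the WHO wide dialect (``Deaths1..DeathsN`` age columns).

    Parameters
    ----------
    path : path-like
        CSV with columns country, year, sex, cause and numbered death
        columns.
    age_format : mapping
        Maps each death-column name to the lower bound (years) of the age
        group its deaths belong to, or to ``"unknown"`` for
        unspecified-age buckets (dropped with a logged count). Buckets
        finer than the canonical ladder (e.g. single years 1,2,3,4) are
        summed into their canonical group. Sub-ladder bounds such as 2 or
        3 are accepted and rolled up; bounds that do not fall inside any
        canonical group are rejected.

    Missing mapped columns are treated as all-zero with a warning; empty
    cells become zero deaths with a warning.
    """
    df = pd.read_csv(path, dtype={"country": str, "sex": str, "cause": str})
    id_cols = ["country", "year", "sex", "cause"]
    missing_id = [c for c in id_cols if c not in df.columns]
    if missing_id:
        raise FormatError(f"WHO wide file missing columns: {missing_id}")

    death_cols = [c for c in df.columns if c not in id_cols]
    unmapped = [c for c in death_cols if c not in age_format]
    if unmapped:
        raise FormatError(f"age columns without an age-format entry: {unmapped}")
    absent = [c for c in age_format if c not in death_cols]
    if absent:
        logger.warning(
            "age-format columns absent from file, treated as zero deaths: %s",
            absent,
        )

    # Roll each mapped bucket bound up to its canonical group.
    edges = list(LADDER_LOWER) + [np.inf]
    canon_of: dict[str, object] = {}
    for col, bound in age_format.items():
        if isinstance(bound, str) and bound.lower() in {"unknown", "unk", "na"}:
            canon_of[col] = "unknown"
            continue
        b = float(bound)
        if b < 0 or not float(b).is_integer():
            raise FormatError(f"age-format bound for {col!r} invalid: {bound!r}")
        idx = int(np.searchsorted(edges, b, side="right")) - 1
        canon_of[col] = LADDER_LOWER[idx]

    empties = 0
    records = []
    for _, row in df.iterrows():
        sums: dict[int, float] = {}
        unknown = 0.0
        for col in death_cols:
            cell = row[col]
            if pd.isna(cell) or (isinstance(cell, str) and cell.strip() == ""):
                empties += 1
                val = 0.0
            else:
                try:
                    val = float(cell)
                except (TypeError, ValueError):
                    raise ValidationError(
                        f"non-numeric deaths cell {cell!r} in column {col} "
                        f"for {row['country']}/{row['year']}/{row['sex']}/{row['cause']}"
                    ) from None
            target = canon_of[col]
            if target == "unknown":
                unknown += val
            else:
                sums[target] = sums.get(target, 0.0) + val
        if unknown:
            logger.warning(
                "dropped %g unknown-age deaths for %s/%s/%s/%s",
                unknown, row["country"], row["year"], row["sex"], row["cause"],
            )
        for lower in LADDER_LOWER:
            if lower in sums:
                records.append(
                    dict(country=row["country"], year=row["year"], sex=row["sex"],
                         age_lower=lower, age_width=np.nan, cause=row["cause"],
                         deaths=sums[lower])
                )
    if empties:
        logger.warning("treated %d empty deaths cells as zero", empties)
    long = pd.DataFrame(records, columns=MORTALITY_COLUMNS)
    return validate_mortality(long)


def pool_years(table: pd.DataFrame, years: Iterable[int]) -> pd.DataFrame:
    """Sum deaths over the given years within each stratum-cause cell.

    The output ``year`` column carries a pooled period label such as
    ``"2015-2016"``.
    """
    table = validate_mortality(table, allow_real_deaths=True)
    years = sorted(set(int(y) for y in years))
    present = set(pd.to_numeric(table["year"]).astype(int))
    absent = [y for y in years if y not in present]
    if absent:
        raise ValidationError(
            f"requested years absent: {absent}; available: {sorted(present)}"
        )
    sub = table[pd.to_numeric(table["year"]).astype(int).isin(years)]
    grouped = (
        sub.groupby(["country", "sex", "age_lower", "age_width", "cause"],
                    as_index=False, sort=True)["deaths"].sum()
    )
    label = str(years[0]) if len(years) == 1 else f"{years[0]}-{years[-1]}"
    grouped.insert(1, "year", label)
    return grouped.loc[:, MORTALITY_COLUMNS]


def pool_population(pop: pd.DataFrame, years: Iterable[int]) -> pd.DataFrame:
    """Sum annual mid-year populations into person-years for the period."""
    pop = validate_population(pop)
    years = sorted(set(int(y) for y in years))
    present = set(pd.to_numeric(pop["year"]).astype(int))
    absent = [y for y in years if y not in present]
    if absent:
        raise ValidationError(
            f"requested years absent from population table: {absent}; "
            f"available: {sorted(present)}"
        )
    sub = pop[pd.to_numeric(pop["year"]).astype(int).isin(years)]
    grouped = (
        sub.groupby(["country", "sex", "age_lower", "age_width"],
                    as_index=False, sort=True)["population"].sum()
    )
    label = str(years[0]) if len(years) == 1 else f"{years[0]}-{years[-1]}"
    grouped.insert(1, "year", label)
    return grouped.loc[:, POPULATION_COLUMNS]


@dataclass
class RateMatrix:
    """Age x cause central death rates for one population stratum.

    ``rates`` is indexed by canonical age-group lower bound (all 19 rows,
    in ladder order) with one column per cause; entries are deaths per
    person-year. Row sums are the all-cause age schedule, the covariate
    vector of the decomposition.
    """

    rates: pd.DataFrame
    country: str = ""
    sex: str = ""
    period: str = ""
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if list(self.rates.index) != list(LADDER_LOWER):
            raise ValidationError(
                "RateMatrix must be indexed by the full canonical ladder"
            )
        vals = self.rates.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValidationError("RateMatrix entries must be finite")
        if (vals < 0).any():
            raise ValidationError("RateMatrix entries must be non-negative")
        self.rates = self.rates.astype(float)

    @property
    def causes(self) -> list[str]:
        return list(self.rates.columns)

    def all_cause(self) -> np.ndarray:
        """All-cause rate per age group (row sums), ladder order."""
        return self.rates.to_numpy(dtype=float).sum(axis=1)

    def flatten(self) -> np.ndarray:
        """Row-major (age-major) flattening used by the decomposition."""
        return self.rates.to_numpy(dtype=float).ravel()


def to_rate_matrix(table: pd.DataFrame, pop: pd.DataFrame) -> RateMatrix:
    """Convert a pooled single-stratum table pair to central death rates.

    m[a, c] = pooled deaths / pooled person-years. Causes absent from an
    age group get rate 0. Any age group with deaths but zero/missing
    population is an error naming the stratum.
    """
    mort = validate_mortality(table, allow_real_deaths=True)
    popv = validate_population(pop)
    for df, what in ((mort, "mortality"), (popv, "population")):
        strata = df[["country", "year", "sex"]].drop_duplicates()
        if len(strata) != 1:
            raise ValidationError(
                f"{what} table must hold a single (country, year, sex) "
                f"stratum; found {len(strata)}"
            )
    mkey = mort[["country", "year", "sex"]].iloc[0]
    pkey = popv[["country", "year", "sex"]].iloc[0]
    if not (mkey == pkey).all():
        raise ValidationError(
            f"mortality stratum {tuple(mkey)} != population stratum {tuple(pkey)}"
        )

    pop_by_age = popv.set_index("age_lower")["population"]
    deaths_by_age = mort.groupby("age_lower")["deaths"].sum()
    for lower, d in deaths_by_age.items():
        if d > 0 and (lower not in pop_by_age.index or pop_by_age[lower] <= 0):
            raise ValidationError(
                f"zero or missing population for age group {lower} of "
                f"{mkey['country']}/{mkey['year']}/{mkey['sex']} "
                f"which has {d} deaths"
            )

    causes = sorted(mort["cause"].unique())
    grid = (
        mort.pivot_table(index="age_lower", columns="cause", values="deaths",
                         aggfunc="sum", fill_value=0.0)
        .reindex(index=list(LADDER_LOWER), columns=causes, fill_value=0.0)
    )
    exposure = pop_by_age.reindex(list(LADDER_LOWER))
    rates = grid.divide(exposure, axis=0)
    rates = rates.fillna(0.0)  # ages with no population had no deaths
    return RateMatrix(
        rates=rates,
        country=str(mkey["country"]),
        sex=str(mkey["sex"]),
        period=str(mkey["year"]),
    )
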