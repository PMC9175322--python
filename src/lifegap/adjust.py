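"""Recalibration of cause-specific rates to an external life table.

Cause-of-death registries with incomplete vital-registration coverage can
understate all-cause mortality. As a sensitivity analysis, the observed
cause *mix* is kept but the all-cause level is taken from an external life
table (e.g. IHME / UN / WHO): the implied population of each age group is
the registry's all-cause deaths divided by the external rate,

    P[a] = D[a] / m*[a],

and each cause-specific rate becomes r[a,c] = D[a,c] / P[a]
= m*[a] * D[a,c] / D[a]. Row sums then equal the external rates exactly
wherever deaths were recorded, and within-age cause shares are preserved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ages import LADDER_LOWER, LADDER_WIDTH, validate_lower_bounds
from .io import RateMatrix, ValidationError, validate_mortality

logger = logging.getLogger("lifegap")


@dataclass
class ExternalLifeTable:
    """All-cause mortality rates by canonical age group, from one source."""

    rates: pd.Series  # index: age lower bounds (full ladder)
    source: str = ""

    def __post_init__(self) -> None:
        self.rates = self.rates.astype(float)
        validate_lower_bounds(self.rates.index)
        if list(self.rates.index) != list(LADDER_LOWER):
            raise ValidationError(
                "external life table must cover the full canonical ladder; "
                "coarser ladders are rejected, not interpolated"
            )
        vals = self.rates.to_numpy()
        if not np.all(np.isfinite(vals)) or (vals <= 0).any():
            raise ValidationError(
                f"external life-table rates must be strictly positive and "
                f"finite (source {self.source!r})"
            )

    @classmethod
    def from_csv(cls, path) -> "ExternalLifeTable":
        """Read ``age_lower,age_width,mx`` CSV with a ``# source,<label>``
        header line."""
        source = ""
        with open(path, encoding="utf-8") as fh:
            first = fh.readline()
            if first.startswith("# source,"):
                source = first[len("# source,"):].strip()
                df = pd.read_csv(fh)
            else:
                import io as _io
                df = pd.read_csv(_io.StringIO(first + fh.read()))
        for col in ("age_lower", "mx"):
            if col not in df.columns:
                raise ValidationError(f"external life table missing column {col!r}")
        rates = df.set_index(df["age_lower"].astype(int))["mx"]
        return cls(rates=rates, source=source)

    def to_csv(self, path) -> None:
        widths = ["inf" if np.isinf(w) else int(w) for w in LADDER_WIDTH]
        out = pd.DataFrame(
            dict(age_lower=list(LADDER_LOWER), age_width=widths,
                 mx=self.rates.to_numpy())
        )
        with open(path, "w", encoding="utf-8", newline="") as fh:
            fh.write(f"# source,{self.source}\n")
            out.to_csv(fh, index=False, lineterminator="\n")


def implied_population(
    all_cause_deaths: pd.Series, ext: ExternalLifeTable
) -> pd.Series:
    """Person-years P[a] = D[a] / m*[a] implied by the external rates.

    Age groups with zero deaths get P = 0, flagged in the log as an
    undefined denominator and excluded downstream.
    """
    deaths = all_cause_deaths.astype(float)
    validate_lower_bounds(deaths.index)
    if (deaths < 0).any():
        raise ValidationError("death counts must be non-negative")
    rates = ext.rates
    missing = [a for a in deaths.index[deaths > 0] if a not in rates.index]
    if missing:
        raise ValidationError(
            f"external life table lacks rates for age groups with "
            f"deaths: {missing}"
        )
    bad = [a for a in deaths.index[deaths > 0] if rates[a] <= 0]
    if bad:
        raise ValidationError(
            f"external rate must be > 0 where deaths > 0; offending age "
            f"groups: {bad}"
        )
    pop = pd.Series(0.0, index=deaths.index)
    pos = deaths > 0
    pop[pos] = deaths[pos] / rates.reindex(deaths.index)[pos]
    zero_ages = list(deaths.index[~pos])
    if zero_ages:
        logger.info(
            "implied population undefined (0/denominator) for zero-death "
            "age groups %s; set to 0", zero_ages,
        )
    return pop


def recalibrate(table: pd.DataFrame, ext: ExternalLifeTable) -> RateMatrix:
    """Rate matrix whose all-cause level matches the external life table.

    ``table`` must be a pooled single-stratum mortality table by cause.
    Ages with zero recorded deaths yield a row of zeros (the cause mix is
    undefined there) with a logged note.
    """
    mort = validate_mortality(table, allow_real_deaths=True)
    strata = mort[["country", "year", "sex"]].drop_duplicates()
    if len(strata) != 1:
        raise ValidationError(
            f"recalibrate expects a single (country, year, sex) stratum; "
            f"found {len(strata)}"
        )
    key = strata.iloc[0]

    causes = sorted(mort["cause"].unique())
    grid = (
        mort.pivot_table(index="age_lower", columns="cause", values="deaths",
                         aggfunc="sum", fill_value=0.0)
        .reindex(index=list(LADDER_LOWER), columns=causes, fill_value=0.0)
    )
    all_cause = grid.sum(axis=1)
    implied_population(all_cause, ext)  # raises on D>0 with bad m*

    shares = grid.divide(all_cause.replace(0.0, np.nan), axis=0)
    rates = shares.multiply(ext.rates.reindex(grid.index), axis=0)
    empty = all_cause[all_cause == 0].index.tolist()
    if empty:
        logger.info(
            "age groups %s have no recorded deaths; recalibrated rates set "
            "to 0 there (cause mix undefined)", empty,
        )
    rates = rates.fillna(0.0)
    return RateMatrix(
        rates=rates,
        country=str(key["country"]),
        sex=str(key["sex"]),
        period=str(key["year"]),
        extra={"recalibrated_to": ext.source},
    )
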