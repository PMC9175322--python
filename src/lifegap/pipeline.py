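"""End-to-end orchestration: config in, summary + contribution bundle out.

A run reads long-format mortality and population data, pools the requested
years, collapses ICD-10 causes into the five avoidability categories,
builds sex-specific rate matrices per country, and for every
(comparator, sex, measure) writes a summary row (levels and signed
reference-minus-comparator gap) and an age x cause contribution matrix.
With an external life table configured, a parallel sensitivity bundle is
produced from recalibrated rates. Outputs are deterministic: identical
config and seed give byte-identical CSVs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .adjust import ExternalLifeTable, recalibrate
from .ages import LADDER_LOWER
from .causes import collapse_causes, load_scheme
from .decompose import (
    DEFAULT_N_STEPS,
    ContributionMatrix,
    decompose_gap,
    residual_report,
)
from .io import (
    ValidationError,
    pool_population,
    pool_years,
    read_long,
    read_population,
    to_rate_matrix,
)
from .lifetable import build_lifetable, gap, life_expectancy, lifespan_sd

logger = logging.getLogger("lifegap")


@dataclass
class RunConfig:
    reference: str
    comparators: list[str]
    years: list[int]
    sexes: list[str] = field(default_factory=lambda: ["male", "female"])
    mortality_path: str = "mortality.csv"
    population_path: str = "population.csv"
    scheme_path: str | None = None  # None -> shipped default scheme
    external_lifetable_path: str | None = None
    measures: list[str] = field(default_factory=lambda: ["LE", "LI"])
    n_steps: int = DEFAULT_N_STEPS
    output_dir: str = "output"
    seed: int = 0
    age_bins: list[tuple[int, int]] | None = None
    ax_rule: str = "standard"

    def __post_init__(self) -> None:
        if self.reference in self.comparators:
            raise ValidationError(
                f"reference {self.reference!r} must not appear in comparators"
            )
        if not self.years:
            raise ValidationError("years must be non-empty")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        doc = yaml.safe_load(open(path, encoding="utf-8"))
        bins = doc.get("age_bins")
        if bins is not None:
            bins = [tuple(int(v) for v in b) for b in bins]
        return cls(
            reference=str(doc["reference"]),
            comparators=[str(c) for c in doc["comparators"]],
            years=[int(y) for y in doc["years"]],
            sexes=[str(s) for s in doc.get("sexes", ["male", "female"])],
            mortality_path=str(doc.get("mortality_path", "mortality.csv")),
            population_path=str(doc.get("population_path", "population.csv")),
            scheme_path=doc.get("scheme_path"),
            external_lifetable_path=doc.get("external_lifetable_path"),
            measures=[str(m) for m in doc.get("measures", ["LE", "LI"])],
            n_steps=int(doc.get("n_steps", DEFAULT_N_STEPS)),
            output_dir=str(doc.get("output_dir", "output")),
            seed=int(doc.get("seed", 0)),
            age_bins=bins,
            ax_rule=str(doc.get("ax_rule", "standard")),
        )


def _stratum_rates(mort, pop, country, sex, years, scheme, ax_sex):
    sub_m = mort[(mort["country"] == country) & (mort["sex"] == sex)]
    sub_p = pop[(pop["country"] == country) & (pop["sex"] == sex)]
    if sub_m.empty:
        raise ValidationError(f"no mortality data for {country}/{sex}")
    pooled_m = pool_years(sub_m, years)
    pooled_p = pool_population(sub_p, years)
    collapsed = collapse_causes(pooled_m, scheme)
    return collapsed, pooled_p, to_rate_matrix(collapsed, pooled_p)


def _values(rm, ax_rule, sex):
    lt = build_lifetable(rm.all_cause(), ax_rule=ax_rule, sex=sex)
    return {"LE": life_expectancy(lt), "LI": lifespan_sd(lt)}


def run(config: RunConfig) -> dict:
    """Execute the full analysis; returns a dict of output paths and
    residual diagnostics. Any stage error aborts with the stage and
    stratum named, and files written by this run are removed."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _write_cm(cm: ContributionMatrix, path: Path) -> None:
        cm.to_csv(path)
        written.append(path)
        display = cm.contributions.round(1).rename_axis("age_lower")
        dpath = path.with_name("display_" + path.name)
        display.to_csv(dpath, lineterminator="\n")
        written.append(dpath)

    stage = "load"
    try:
        mort = read_long(config.mortality_path)
        pop = read_population(config.population_path)
        if config.scheme_path:
            scheme = load_scheme(config.scheme_path)
        else:
            from .causes import default_scheme
            scheme = default_scheme()
        ext = (ExternalLifeTable.from_csv(config.external_lifetable_path)
               if config.external_lifetable_path else None)

        summary_rows = []
        residuals = []
        for sex in config.sexes:
            stage = f"rates[{config.reference}/{sex}]"
            _, _, rm_ref = _stratum_rates(
                mort, pop, config.reference, sex, config.years, scheme, sex)
            vals_ref = _values(rm_ref, config.ax_rule, sex)
            for measure in config.measures:
                summary_rows.append(dict(
                    country=config.reference, sex=sex, measure=measure,
                    value=vals_ref[measure], gap=""))
            for cmp_country in config.comparators:
                stage = f"rates[{cmp_country}/{sex}]"
                collapsed_cmp, _, rm_cmp = _stratum_rates(
                    mort, pop, cmp_country, sex, config.years, scheme, sex)
                vals_cmp = _values(rm_cmp, config.ax_rule, sex)
                for measure in config.measures:
                    g = gap(measure, vals_ref[measure], vals_cmp[measure])
                    summary_rows.append(dict(
                        country=cmp_country, sex=sex, measure=measure,
                        value=vals_cmp[measure], gap=g.gap))
                    stage = f"decompose[{measure}/{cmp_country}/{sex}]"
                    cm = decompose_gap(measure, rm_ref, rm_cmp,
                                       config.n_steps,
                                       ax_rule=config.ax_rule, sex=sex)
                    residuals.append(residual_report(cm) | dict(
                        comparator=cmp_country, sex=sex))
                    _write_cm(cm, out_dir /
                              f"contributions_{measure}_{cmp_country}_{sex}.csv")

        stage = "summary"
        summary = pd.DataFrame(summary_rows,
                               columns=["country", "sex", "measure", "value", "gap"])
        spath = out_dir / "summary.csv"
        summary.to_csv(spath, index=False, lineterminator="\n")
        written.append(spath)

        if ext is not None:
            sens_dir = out_dir / "sensitivity"
            sens_dir.mkdir(exist_ok=True)
            sens_rows = []
            for sex in config.sexes:
                stage = f"recalibrate[{config.reference}/{sex}]"
                collapsed_ref, _, _ = _stratum_rates(
                    mort, pop, config.reference, sex, config.years, scheme, sex)
                rm_ref = recalibrate(collapsed_ref, ext)
                vals_ref = _values(rm_ref, config.ax_rule, sex)
                for cmp_country in config.comparators:
                    stage = f"recalibrate[{cmp_country}/{sex}]"
                    collapsed_cmp, _, _ = _stratum_rates(
                        mort, pop, cmp_country, sex, config.years, scheme, sex)
                    rm_cmp = recalibrate(collapsed_cmp, ext)
                    vals_cmp = _values(rm_cmp, config.ax_rule, sex)
                    for measure in config.measures:
                        g = gap(measure, vals_ref[measure], vals_cmp[measure])
                        sens_rows.append(dict(
                            country=cmp_country, sex=sex, measure=measure,
                            value=vals_cmp[measure], gap=g.gap,
                            source=ext.source))
                        stage = f"sens-decompose[{measure}/{cmp_country}/{sex}]"
                        cm = decompose_gap(measure, rm_ref, rm_cmp,
                                           config.n_steps,
                                           ax_rule=config.ax_rule, sex=sex)
                        residuals.append(residual_report(cm) | dict(
                            comparator=cmp_country, sex=sex,
                            sensitivity=ext.source))
                        _write_cm(cm, sens_dir /
                                  f"contributions_{measure}_{cmp_country}_{sex}.csv")
            sp = sens_dir / "summary.csv"
            pd.DataFrame(sens_rows).to_csv(sp, index=False, lineterminator="\n")
            written.append(sp)

        stage = "run-log"
        log = dict(
            version=__version__, seed=config.seed, n_steps=config.n_steps,
            reference=config.reference, comparators=config.comparators,
            years=config.years, sexes=config.sexes,
            measures=config.measures, ax_rule=config.ax_rule,
            residuals=residuals,
        )
        lpath = out_dir / "run_log.json"
        lpath.write_text(json.dumps(log, indent=2, sort_keys=True) + "\n")
        written.append(lpath)
        return dict(output_dir=str(out_dir),
                    files=[str(p) for p in written],
                    residuals=residuals)
    except Exception as err:
        for p in written:
            p.unlink(missing_ok=True)
        raise type(err)(f"stage {stage}: {err}") from err


def aggregate_contributions(
    cm: ContributionMatrix,
    age_bins: Sequence[tuple[int, int]],
    cause_groups: Mapping[str, str],
) -> pd.DataFrame:
    """Sum contributions into presentation bins and cause groups.

    ``age_bins`` are inclusive (lower, upper) bounds on age-group lower
    bounds and must partition the ladder; ``cause_groups`` maps every
    cause to its group and must cover the cause axis. The grand total
    (hence total gap minus residual) is unchanged by aggregation.
    """
    covered: list[int] = []
    for lo, hi in age_bins:
        covered.extend(a for a in LADDER_LOWER if lo <= a <= hi)
    if sorted(covered) != list(LADDER_LOWER) or len(covered) != len(set(covered)):
        raise ValidationError(
            "age_bins must partition the canonical ladder exactly"
        )
    missing = set(cm.contributions.columns) - set(cause_groups)
    if missing:
        raise ValidationError(f"cause_groups does not cover causes: {sorted(missing)}")

    rows = {}
    for lo, hi in age_bins:
        label = f"{lo}-{hi}" if lo != hi else str(lo)
        mask = [(lo <= a <= hi) for a in cm.contributions.index]
        binned = cm.contributions.loc[mask].sum(axis=0)
        rows[label] = binned.groupby(
            binned.index.map(cause_groups.__getitem__)).sum()
    out = pd.DataFrame(rows).T
    out.index.name = "age_bin"
    return out.fillna(0.0)
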