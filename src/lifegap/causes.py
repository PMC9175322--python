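"""Avoidable-mortality classification of ICD-10 coded deaths.

Deaths are assigned to five mutually exclusive groups — only treatable,
only preventable, both treatable and preventable, ischaemic heart disease
(IHD), and non-avoidable — by an ordered table of inclusive ICD-10 range
rules (first match wins, terminal catch-all maps to non-avoidable). An age
cap (default 75) makes every death in an age group whose lower bound
reaches the cap non-avoidable regardless of cause: avoidability is a
statement about premature death.

The shipped default rule file covers the major avoidable-cause families
(injuries, drug- and alcohol-related deaths, maternal/perinatal causes,
diabetes, hypertensive disease, lung cancer, IHD, infectious and
respiratory diseases); it is a synthetic working default, not a
reproduction of the official OECD/Eurostat list, and can be replaced by a
user-supplied file with the full classification.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .ages import AgeGroup
from .io import MORTALITY_COLUMNS, ValidationError, validate_mortality

logger = logging.getLogger("lifegap")

CATEGORIES = (
    "treatable",
    "preventable",
    "treatable_and_preventable",
    "ihd",
    "non_avoidable",
)

AVOIDABLE_CATEGORIES = CATEGORIES[:4]

_STEM_RE = re.compile(r"^[A-Z][0-9]{2}$")
_CODE_RE = re.compile(r"^[A-Z][0-9]{2}(?:\.?[0-9]{1,2})?$")


def code_stem(code: str) -> str:
    """Normalize an ICD-10 code to its 3-character stem (e.g. E10.1 -> E10)."""
    c = str(code).strip().upper()
    if not _CODE_RE.match(c):
        raise ValidationError(f"syntactically invalid ICD-10 code: {code!r}")
    return c.replace(".", "")[:3]


@dataclass(frozen=True)
class Rule:
    start: str  # 3-char stem, inclusive
    end: str    # 3-char stem, inclusive
    category: str

    def matches(self, stem: str) -> bool:
        return self.start <= stem <= self.end


@dataclass
class AvoidabilityScheme:
    """Ordered ICD-10 range rules plus the avoidability age cap."""

    rules: list[Rule]
    age_cap: int = 75

    def __post_init__(self) -> None:
        if not self.rules or self.rules[-1].category != "non_avoidable" or (
            self.rules[-1].start != "A00" or self.rules[-1].end != "Z99"
        ):
            self.rules = list(self.rules) + [Rule("A00", "Z99", "non_avoidable")]


def _validate_rule(start, end, category, index: int) -> Rule:
    for label, value in (("range_start", start), ("range_end", end)):
        v = str(value).strip().upper()
        if not _STEM_RE.match(v):
            raise ValidationError(
                f"rule {index}: malformed ICD-10 {label} {value!r} "
                "(expected letter + two digits, e.g. A15)"
            )
    s, e = str(start).strip().upper(), str(end).strip().upper()
    if s > e:
        raise ValidationError(f"rule {index}: range start {s} > end {e}")
    cat = str(category).strip().lower()
    if cat not in CATEGORIES:
        raise ValidationError(
            f"rule {index}: unknown category {category!r}; "
            f"valid categories: {CATEGORIES}"
        )
    return Rule(s, e, cat)


def load_scheme(path) -> AvoidabilityScheme:
    """Load an ordered rule file (CSV with range_start,range_end,category
    columns, or a YAML list of such mappings with optional ``age_cap``)."""
    path = Path(path)
    age_cap = 75
    if path.suffix.lower() in {".yaml", ".yml"}:
        doc = yaml.safe_load(path.read_text())
        if isinstance(doc, dict):
            age_cap = int(doc.get("age_cap", 75))
            raw = doc["rules"]
        else:
            raw = doc
        rows = [(r["range_start"], r["range_end"], r["category"]) for r in raw]
    else:
        df = pd.read_csv(path, comment="#", dtype=str)
        needed = {"range_start", "range_end", "category"}
        if not needed.issubset(df.columns):
            raise ValidationError(
                f"scheme file must have columns {sorted(needed)}; "
                f"found {list(df.columns)}"
            )
        rows = list(df[["range_start", "range_end", "category"]].itertuples(index=False))

    rules = [_validate_rule(s, e, c, i) for i, (s, e, c) in enumerate(rows)]
    for i, a in enumerate(rules):
        for j, b in enumerate(rules[i + 1:], start=i + 1):
            if a.start <= b.end and b.start <= a.end:
                logger.info(
                    "scheme rules %d (%s-%s) and %d (%s-%s) overlap; "
                    "order resolves the overlap", i, a.start, a.end, j, b.start, b.end,
                )
    return AvoidabilityScheme(rules=rules, age_cap=age_cap)


def default_scheme() -> AvoidabilityScheme:
    """The scheme shipped with the package (see module docstring)."""
    with resources.as_file(
        resources.files("lifegap").joinpath("data/default_scheme.csv")
    ) as p:
        return load_scheme(p)


def classify(code: str, age_group: AgeGroup | int, scheme: AvoidabilityScheme) -> str:
    """Category for one (ICD-10 code, age group) pair.

    Age groups at or above the cap are non-avoidable whatever the code.
    """
    stem = code_stem(code)
    lower = age_group.lower if isinstance(age_group, AgeGroup) else int(age_group)
    if lower >= scheme.age_cap:
        return "non_avoidable"
    for rule in scheme.rules:
        if rule.matches(stem):
            return rule.category
    raise AssertionError("catch-all rule guarantees a match")  # pragma: no cover


def collapse_causes(table: pd.DataFrame, scheme: AvoidabilityScheme) -> pd.DataFrame:
    """Replace the ICD-10 cause axis by the five avoidability categories.

    Deaths are summed within (country, year, sex, age group, category);
    totals are conserved exactly.
    """
    t = validate_mortality(table, allow_real_deaths=True)
    try:
        t["cause"] = [
            classify(code, lower, scheme)
            for code, lower in zip(t["cause"], t["age_lower"])
        ]
    except ValidationError as err:
        raise ValidationError(f"collapse_causes: {err}") from err
    out = (
        t.groupby(["country", "year", "sex", "age_lower", "age_width", "cause"],
                  as_index=False, sort=True)["deaths"].sum()
    )
    return out.loc[:, MORTALITY_COLUMNS]
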