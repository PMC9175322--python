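"""End-to-end run: simulate a two-country fixture, classify causes,
decompose, and print the summary table.

The fixture uses real ICD-10 codes so the shipped avoidability scheme can
sort them into the five groups (treatable / preventable / both / IHD /
non-avoidable, capped at age 75). Outputs land in a temporary directory
as the same CSVs the command-line interface writes.
"""

import tempfile
from pathlib import Path

import pandas as pd

import lifegap as lg

mix = {"V43": 0.20, "E10": 0.10, "I21": 0.20, "O15": 0.05, "C50": 0.45}
scenario = lg.ScenarioSpec(
    base=lg.HazardSpec(cause_mix=mix),
    countries=("IRN", "KWT"),
    sex="male",
    perturbations=[lg.Perturbation("IRN", "V43", 15, 45, 2.0)],
    populations={lo: 300_000.0 for lo in lg.LADDER_LOWER},
    seed=42,
)
pair = lg.make_country_pair(scenario)

workdir = Path(tempfile.mkdtemp())
lg.write_long(pd.concat(pair.mortality.values(), ignore_index=True),
              workdir / "mortality.csv")
lg.write_population(pd.concat(pair.population.values(), ignore_index=True),
                    workdir / "population.csv")

config = lg.RunConfig(
    reference="IRN", comparators=["KWT"], years=[2015, 2016],
    sexes=["male"],
    mortality_path=str(workdir / "mortality.csv"),
    population_path=str(workdir / "population.csv"),
    output_dir=str(workdir / "out"), n_steps=20,
)
result = lg.run(config)

summary = pd.read_csv(workdir / "out" / "summary.csv")
print(summary.round(2).to_string(index=False))

cm = lg.ContributionMatrix.from_csv(
    workdir / "out" / "contributions_LE_KWT_male.csv")
agg = lg.aggregate_contributions(
    cm, [(0, 0), (1, 10), (15, 45), (50, 70), (75, 85)],
    {c: c for c in cm.contributions.columns})
print("\nLE contributions by presentation age bin (years):")
print(agg.round(3).to_string())
print(f"\ntotal gap {cm.total_gap:+.3f}, residual {cm.residual:+.2e} "
      f"at n_steps={cm.n_steps}")
print("The preventable (injury) column carries the gap at ages 15-49;")
print("Poisson noise puts small contributions elsewhere.")
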