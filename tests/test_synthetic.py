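"""Synthetic-data generator: construction identities, Poisson sampling,
seed discipline, and the noise-free pathway."""

import numpy as np
import pandas as pd
import pytest

import lifegap as lg
from lifegap.io import POPULATION_COLUMNS, ValidationError
from lifegap.synthetic import _cell_rng

from conftest import uniform_population


def small_population(ages=(30, 35, 40), size=20_000.0, years=(2015,)):
    rows = [
        dict(country="SYN", year=y, sex="male", age_lower=lo,
             age_width=np.nan, population=size)
        for y in years for lo in ages
    ]
    return pd.DataFrame(rows, columns=POPULATION_COLUMNS)


class TestMakeRates:
    def test_row_sums_equal_hazard_at_midpoints(self, base_hazard):
        rm = lg.make_rates(base_hazard)
        for i, grp in enumerate(lg.LADDER):
            infant = grp.lower == 0 and not grp.is_open
            want = base_hazard.all_cause_at(grp.midpoint, infant=infant)
            assert rm.all_cause()[i] == pytest.approx(want, rel=1e-12)

    def test_makeham_dominates_when_level_vanishes(self):
        h = lg.HazardSpec(makeham=0.004, gompertz_level=1e-12,
                          infant_excess=0.0, cause_mix={"all": 1.0})
        rm = lg.make_rates(h)
        np.testing.assert_allclose(rm.all_cause(), 0.004, rtol=2e-5)

    def test_bad_shares_rejected(self):
        h = lg.HazardSpec(cause_mix={"a": 0.6, "b": 0.6})
        with pytest.raises(ValidationError, match="sum to 1"):
            lg.make_rates(h)

    def test_le_matches_quadrature_of_same_hazard(self):
        h = lg.HazardSpec(makeham=0.001, gompertz_level=1e-4,
                          gompertz_slope=0.1, infant_excess=0.0,
                          cause_mix={"all": 1.0})
        rm = lg.make_rates(h)
        lt = lg.build_lifetable(rm.all_cause(), ax_rule="midpoint")
        t = np.arange(0, 130, 0.01)
        haz = 0.001 + 1e-4 * np.exp(0.1 * t)
        H = np.concatenate([[0.0], np.cumsum((haz[1:] + haz[:-1]) / 2 * 0.01)])
        e0 = np.trapezoid(np.exp(-H), t)
        assert lg.life_expectancy(lt) == pytest.approx(e0, abs=0.3)


class TestSimulateCounts:
    def test_same_seed_identical(self, base_hazard):
        rm = lg.make_rates(base_hazard, country="SYN")
        pop = small_population()
        a = lg.simulate_counts(rm, pop, seed=5)
        b = lg.simulate_counts(rm, pop, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_different_seed_differs(self, base_hazard):
        rm = lg.make_rates(base_hazard, country="SYN")
        pop = small_population(size=100_000.0)
        a = lg.simulate_counts(rm, pop, seed=5)
        b = lg.simulate_counts(rm, pop, seed=6)
        assert not a["deaths"].equals(b["deaths"])

    def test_zero_rates_zero_deaths(self):
        rm = lg.RateMatrix(
            rates=pd.DataFrame({"a": np.zeros(19)}, index=list(lg.LADDER_LOWER)),
            country="SYN")
        out = lg.simulate_counts(rm, small_population(), seed=1)
        assert (out["deaths"] == 0).all()

    def test_monte_carlo_means(self, base_hazard):
        """Over 500 replicates, empirical cell means sit within 3 standard
        errors of rate * person-years."""
        mix = {"a": 0.4, "b": 0.6}
        rm = lg.make_rates(lg.HazardSpec(cause_mix=mix), country="SYN")
        pop = small_population(ages=(30, 60), size=50_000.0)
        n_rep = 500
        sums = None
        for s in range(n_rep):
            t = lg.simulate_counts(rm, pop, seed=1000 + s)
            cell = t.set_index(["age_lower", "cause"])["deaths"]
            sums = cell if sums is None else sums + cell
        means = sums / n_rep
        for (lo, cause), mean in means.items():
            lam = rm.rates.at[lo, cause] * 50_000.0
            se = np.sqrt(lam / n_rep)
            assert abs(mean - lam) < 3 * se + 1e-9

    def test_substream_per_cell_is_stable(self, base_hazard):
        """Adding a cause must not shift the draws of existing cells."""
        rm2 = lg.make_rates(lg.HazardSpec(cause_mix={"a": 0.4, "b": 0.6}),
                            country="SYN")
        rm3 = lg.make_rates(
            lg.HazardSpec(cause_mix={"a": 0.4, "b": 0.3, "c": 0.3}),
            country="SYN")
        # cause "a" has identical rates in both matrices
        np.testing.assert_allclose(rm2.rates["a"], rm3.rates["a"])
        pop = small_population()
        t2 = lg.simulate_counts(rm2, pop, seed=7)
        t3 = lg.simulate_counts(rm3, pop, seed=7)
        a2 = t2[t2["cause"] == "a"].set_index("age_lower")["deaths"]
        a3 = t3[t3["cause"] == "a"].set_index("age_lower")["deaths"]
        pd.testing.assert_series_equal(a2, a3)

    def test_cell_rng_depends_on_all_keys(self):
        base = _cell_rng(1, "A", 2015, 30, "x").integers(1 << 30)
        assert _cell_rng(1, "A", 2015, 30, "x").integers(1 << 30) == base
        for other in (_cell_rng(2, "A", 2015, 30, "x"),
                      _cell_rng(1, "B", 2015, 30, "x"),
                      _cell_rng(1, "A", 2016, 30, "x"),
                      _cell_rng(1, "A", 2015, 35, "x"),
                      _cell_rng(1, "A", 2015, 30, "y")):
            assert other.integers(1 << 30) != base


class TestCountryPair:
    def test_no_perturbations_identical_rates(self, base_hazard):
        s = lg.ScenarioSpec(base=base_hazard, seed=1)
        pair = lg.make_country_pair(s)
        np.testing.assert_allclose(
            pair.exact_rates["REF"].rates.to_numpy(),
            pair.exact_rates["CMP"].rates.to_numpy())

    def test_perturbation_confined_to_named_cells(self, injected_pair):
        ref = injected_pair.exact_rates["REF"].rates
        cmp_ = injected_pair.exact_rates["CMP"].rates
        ratio = ref / cmp_
        for lo in lg.LADDER_LOWER:
            for cause in ref.columns:
                want = 2.0 if (cause == "preventable" and 15 <= lo <= 45) else 1.0
                assert ratio.at[lo, cause] == pytest.approx(want, rel=1e-12)

    def test_unknown_cause_in_perturbation(self, base_hazard):
        s = lg.ScenarioSpec(
            base=base_hazard,
            perturbations=[lg.Perturbation("REF", "nosuch", 15, 45, 2.0)])
        with pytest.raises(ValidationError, match="nosuch"):
            lg.make_country_pair(s)

    def test_scenario_yaml_round_trip(self, tmp_path):
        p = tmp_path / "scenario.yaml"
        p.write_text(
            "countries: [IRN, KWT]\nsex: female\nyears: [2015, 2016]\n"
            "seed: 3\ncause_mix: {preventable: 0.3, other: 0.7}\n"
            "perturbations:\n"
            "  - {country: IRN, cause: preventable, age_lo: 15, age_hi: 45,"
            " factor: 1.5}\n"
        )
        s = lg.ScenarioSpec.from_yaml(p)
        assert s.countries == ("IRN", "KWT")
        assert s.perturbations[0].factor == 1.5
        pair = lg.make_country_pair(s)
        assert set(pair.mortality) == {"IRN", "KWT"}
        assert set(pair.mortality["IRN"]["sex"]) == {"female"}

    def test_noise_free_limit_matches_exact_rates(self, base_hazard):
        """With enormous populations the count pathway reproduces the
        exact-rate LE to within 0.05 years."""
        s = lg.ScenarioSpec(
            base=base_hazard, years=[2015], seed=2,
            populations={lo: 1e9 for lo in lg.LADDER_LOWER})
        pair = lg.make_country_pair(s)
        rm_exact = pair.exact_rates["REF"]
        rm_counts = lg.to_rate_matrix(pair.mortality["REF"],
                                      pair.population["REF"])
        le_exact = lg.life_expectancy(lg.build_lifetable(rm_exact.all_cause()))
        le_counts = lg.life_expectancy(
            lg.build_lifetable(rm_counts.all_cause()))
        assert le_counts == pytest.approx(le_exact, abs=0.05)
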