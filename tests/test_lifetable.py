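"""Life-table construction, LE, lifespan SD, and the gap convention.

Oracles: closed forms for constant (exponential) hazards, and trapezoidal
quadrature of the survival curve on a 0.01-year grid for Gompertz
schedules.
"""

import numpy as np
import pandas as pd
import pytest

import lifegap as lg
from lifegap.lifetable import measure_from_rates


def fine_ladder(top: int = 110):
    x = np.arange(0, top + 1, dtype=float)
    n = np.r_[np.ones(top), np.inf]
    return x, n


def quadrature_e0_sd(hazard, top: float = 130.0, dt: float = 0.01):
    """Independent oracle: survival from cumulative hazard on a fine grid;
    e0 = integral of S, SD from the density f = h*S (trapezoid rule)."""
    t = np.arange(0.0, top + dt, dt)
    h = hazard(t)
    H = np.concatenate([[0.0], np.cumsum((h[1:] + h[:-1]) / 2 * dt)])
    S = np.exp(-H)
    e0 = np.trapezoid(S, t)
    f = h * S
    mass = np.trapezoid(f, t)
    mean = np.trapezoid(t * f, t) / mass
    var = np.trapezoid((t - mean) ** 2 * f, t) / mass
    return e0, np.sqrt(var)


class TestConstruction:
    def test_zero_mortality_until_open_group(self):
        mu = 0.1
        m = np.zeros(19)
        m[-1] = mu
        lt = lg.build_lifetable(m)
        assert lg.life_expectancy(lt) == pytest.approx(85 + 1 / mu, abs=1e-9)

    def test_open_rate_zero_cannot_close(self):
        with pytest.raises(ValueError, match="cannot close"):
            lg.build_lifetable(np.zeros(19))

    def test_negative_rate_rejected(self):
        m = np.full(19, 0.01)
        m[3] = -0.001
        with pytest.raises(ValueError, match="negative"):
            lg.build_lifetable(m)

    def test_column_invariants(self):
        rm = lg.make_rates(lg.HazardSpec())
        lt = lg.build_lifetable(rm.all_cause())
        assert (np.diff(lt["l"]) <= 0).all()
        assert lt["l"].iloc[0] == 100_000
        assert lt["d"].sum() == pytest.approx(100_000)
        assert ((lt["q"] >= 0) & (lt["q"] <= 1)).all()
        assert lt["q"].iloc[-1] == 1.0
        assert (np.diff(lt["T"]) <= 0).all()
        assert lt["L"].sum() == pytest.approx(lt["T"].iloc[0])
        assert lt["e"].iloc[0] == pytest.approx(lt["T"].iloc[0] / 100_000)

    def test_q_clamped_with_warning(self, caplog):
        m = np.full(19, 0.01)
        m[10] = 5.0  # Greville overshoots 1 here
        with caplog.at_level("WARNING", logger="lifegap"):
            lt = lg.build_lifetable(m)
        assert lt["q"].iloc[10] == 1.0
        assert any("clamped" in r.message for r in caplog.records)


class TestClosedForms:
    def test_exponential_e0(self):
        mu = 0.02
        x, n = fine_ladder()
        lt = lg.build_lifetable(np.full(len(x), mu), x=x, n=n,
                                ax_rule="midpoint")
        assert lg.life_expectancy(lt) == pytest.approx(1 / mu, rel=0.01)

    def test_exponential_sd(self):
        mu = 0.02
        x, n = fine_ladder()
        lt = lg.build_lifetable(np.full(len(x), mu), x=x, n=n,
                                ax_rule="midpoint")
        assert lg.lifespan_sd(lt) == pytest.approx(1 / mu, rel=0.02)

    @pytest.mark.parametrize("level,slope,makeham", [
        (1e-4, 0.1, 1e-3),
        (3e-5, 0.095, 5e-4),
    ])
    def test_gompertz_e0_matches_quadrature(self, level, slope, makeham):
        def hazard(t):
            return makeham + level * np.exp(slope * t)
        x, n = fine_ladder(120)
        m = hazard(np.where(np.isinf(n), x + 1.0, x + n / 2))
        lt = lg.build_lifetable(m, x=x, n=n, ax_rule="midpoint")
        e0_oracle, sd_oracle = quadrature_e0_sd(hazard)
        assert lg.life_expectancy(lt) == pytest.approx(e0_oracle, abs=0.1)
        assert lg.lifespan_sd(lt) == pytest.approx(sd_oracle, abs=0.25)


class TestMeasures:
    def test_all_die_in_infancy(self):
        m = np.zeros(19)
        m[0] = 1e9
        m[-1] = 0.1
        lt = lg.build_lifetable(m, ax_rule="midpoint")  # a0 = 0.5
        assert lg.life_expectancy(lt) == pytest.approx(0.5)
        assert lg.lifespan_sd(lt) == pytest.approx(0.0, abs=1e-6)

    def test_le_equals_column_identity(self):
        rm = lg.make_rates(lg.HazardSpec())
        lt = lg.build_lifetable(rm.all_cause())
        assert lg.life_expectancy(lt) == pytest.approx(
            lt["T"].iloc[0] / lt["l"].iloc[0], rel=1e-14)

    def test_sd_translation_invariance(self):
        mu = 0.05
        x, n = fine_ladder(60)
        m = np.full(len(x), mu)
        lt = lg.build_lifetable(m, x=x, n=n, ax_rule="midpoint")
        lt_shift = lg.build_lifetable(m, x=x + 30, n=n, ax_rule="midpoint")
        assert lg.lifespan_sd(lt_shift) == pytest.approx(
            lg.lifespan_sd(lt), rel=1e-12)

    def test_radix_invariance(self):
        rm = lg.make_rates(lg.HazardSpec())
        m = rm.all_cause()
        lt1 = lg.build_lifetable(m, radix=100_000)
        lt2 = lg.build_lifetable(m, radix=1.0)
        assert lg.life_expectancy(lt1) == pytest.approx(
            lg.life_expectancy(lt2), rel=1e-12)
        assert lg.lifespan_sd(lt1) == pytest.approx(
            lg.lifespan_sd(lt2), rel=1e-12)

    def test_fast_path_matches_dataframe_path(self):
        rm = lg.make_rates(lg.HazardSpec())
        m = rm.all_cause()
        lt = lg.build_lifetable(m)
        assert measure_from_rates("LE", m) == lg.life_expectancy(lt)
        assert measure_from_rates("LI", m) == lg.lifespan_sd(lt)

    def test_csv_round_trip(self, tmp_path):
        rm = lg.make_rates(lg.HazardSpec())
        lt = lg.build_lifetable(rm.all_cause())
        p = tmp_path / "lt.csv"
        lt.to_csv(p, index=False)
        back = pd.read_csv(p)
        pd.testing.assert_frame_equal(lt, back, check_exact=False)


class TestSensitivities:
    def test_le_strictly_decreases_in_any_rate(self):
        m = lg.make_rates(lg.HazardSpec()).all_cause()
        base = measure_from_rates("LE", m)
        for i in range(19):
            bumped = m.copy()
            bumped[i] *= 1.05
            assert measure_from_rates("LE", bumped) < base

    def test_sd_sensitivity_changes_sign_once(self):
        """Raising mortality at young ages raises the SD, at old ages
        lowers it; the sign flips exactly once along the age axis."""
        m = lg.make_rates(lg.HazardSpec()).all_cause()
        base = measure_from_rates("LI", m)
        signs = []
        for i in range(19):
            bumped = m.copy()
            bumped[i] *= 1.05
            signs.append(np.sign(measure_from_rates("LI", bumped) - base))
        flips = sum(1 for a, b in zip(signs, signs[1:]) if a != b)
        assert flips == 1
        assert signs[0] > 0 and signs[-1] < 0


class TestGap:
    @pytest.mark.parametrize("measure,ref,cmp_,expected", [
        ("LE", 76.2, 80.2, -4.0),
        ("LI", 18.5, 14.0, +4.5),
        ("LE", 80.0, 85.2, -5.2),
    ])
    def test_signed_reference_minus_comparator(self, measure, ref, cmp_, expected):
        g = lg.gap(measure, ref, cmp_)
        assert round(g.gap, 1) == expected

    def test_equal_inputs_zero(self):
        assert lg.gap("LE", 70.0, 70.0).gap == 0.0

    def test_invalid_measure(self):
        with pytest.raises(ValueError, match="measure"):
            lg.gap("e-dagger", 1.0, 2.0)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            lg.gap("LE", float("nan"), 2.0)
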