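import math

import numpy as np
import pytest

from metrodose.dose_response import HillParams, viability
from metrodose.dynamics import DosingRegimen, GrowthParams, PopulationState
from metrodose.regimen import (
    NoCrossoverError,
    UnreachableCriticalDoseError,
    collateral_tradeoff,
    critical_concentration,
    crossover_dose,
    dose_sweep,
)


def grid_scan_crossover(n, curve, lo, hi, points=200_000):
    """Brute-force oracle: finest sign change of V(x/n)^n - V(x) on a grid."""
    x = np.linspace(lo, hi, points)
    diff = viability(x / n, curve) ** n - viability(x, curve)
    idx = np.flatnonzero(np.sign(diff[:-1]) != np.sign(diff[1:]))
    assert idx.size == 1, "expected exactly one sign change"
    return 0.5 * (x[idx[0]] + x[idx[0] + 1])


class TestDoseSweep:
    def test_gain_is_one_at_single_dose(self, mixed_state, growth, tumor_curve):
        df = dose_sweep(
            [mixed_state], np.geomspace(0.1, 30, 12), [1, 2, 4], growth, tumor_curve
        )
        base = df[df.n_doses == 1]
        assert np.all(base.gain_total == 1.0)
        assert np.all(base.gain_frac == 1.0)

    def test_zero_dose_rows_are_pure_growth(self, mixed_state, growth, tumor_curve):
        df = dose_sweep([mixed_state], [0.0], [1, 2, 5], growth, tumor_curve)
        expect = 5e4 * math.exp(growth.a_sensitive) + 5e4 * math.exp(
            growth.a_resistant
        )
        assert np.allclose(df.total, expect)

    def test_row_count_is_exhaustive(self, growth, tumor_curve):
        states = [PopulationState(5e4, 10**k) for k in range(4)]
        df = dose_sweep(states, np.linspace(0, 10, 7), [1, 2, 3], growth, tumor_curve)
        assert len(df) == 4 * 7 * 3

    def test_matches_stepped_oracle_row(self, tumor_curve):
        growth = GrowthParams(0.2, 0.04)
        state = PopulationState(5e4, 5e4)
        df = dose_sweep([state], [2.0], [1, 2], growth, tumor_curve)
        row = df[(df.n_doses == 2)].iloc[0]
        ns = 5e4
        for _ in range(2):
            ns *= viability(1.0, tumor_curve)
        ns *= math.exp(0.2)
        assert row.ns_final == pytest.approx(ns, rel=1e-12)
        assert row.nr_final == pytest.approx(5e4 * math.exp(0.04), rel=1e-12)

    def test_gains_require_single_dose_row(self, mixed_state, growth, tumor_curve):
        with pytest.raises(ValueError, match="n=1"):
            dose_sweep([mixed_state], [1.0], [2, 3], growth, tumor_curve)


class TestCrossoverDose:
    def test_analytic_root_for_two_doses(self, tumor_curve):
        # (1 + u/4)^2 = 1 + u  =>  u = (x/ec50)^2 = 8
        expect = tumor_curve.ec50 * math.sqrt(8.0)
        assert crossover_dose(2, tumor_curve) == pytest.approx(expect, rel=1e-8)

    def test_matches_brute_force_grid(self, tumor_curve):
        for n in (2, 3, 5):
            x_root = crossover_dose(n, tumor_curve)
            x_grid = grid_scan_crossover(n, tumor_curve, 0.1, 100.0)
            assert x_root == pytest.approx(x_grid, rel=1e-3)

    def test_independent_of_resistant_population(self, tumor_curve, growth):
        # gain_total = 1 at x* regardless of the resistant seed: the
        # resistant term cancels in the total-cell ratio
        x_star = crossover_dose(2, tumor_curve)
        for nr0 in (0.0, 1e4):
            state = PopulationState(5e4, nr0)
            df = dose_sweep([state], [x_star], [1, 2], growth, tumor_curve)
            gain = df[df.n_doses == 2].gain_total.iloc[0]
            assert gain == pytest.approx(1.0, rel=1e-6)

    def test_independent_of_growth_rates(self, tumor_curve):
        rng = np.random.default_rng(4)
        x_star = crossover_dose(3, tumor_curve)
        for _ in range(5):
            g = GrowthParams(rng.uniform(0, 1), rng.uniform(0, 1))
            state = PopulationState(5e4, rng.uniform(1, 1e5))
            df = dose_sweep([state], [x_star], [1, 3], g, tumor_curve)
            # sensitive survival ratio is 1 at x*, so total gain depends
            # only on the (cancelling) resistant term when nr=0
            ns = df.set_index("n_doses").ns_final
            assert ns[3] == pytest.approx(ns[1], rel=1e-6)

    def test_shallow_curve_has_no_crossover(self):
        # h = 1: (1 + u/n)^n >= 1 + u, fractionation never kills more
        with pytest.raises(NoCrossoverError):
            crossover_dose(2, HillParams(ec50=3.2, hill_coeff=1.0))

    def test_single_dose_rejected(self, tumor_curve):
        with pytest.raises(ValueError):
            crossover_dose(1, tumor_curve)


class TestCriticalConcentration:
    def test_equal_seed_equal_growth_is_zero(self, tumor_curve):
        state = PopulationState(1e4, 1e4)
        g = GrowthParams(0.2, 0.2)
        assert critical_concentration(state, g, tumor_curve) == 0.0

    def test_closed_form_equal_seed(self, tumor_curve):
        # V(x) = e^{-delta}  =>  x = ec50 * sqrt(e^delta - 1) for h = 2
        delta = 0.16
        g = GrowthParams(0.2, 0.2 - delta)
        state = PopulationState(5e4, 5e4)
        expect = tumor_curve.ec50 * math.sqrt(math.exp(delta) - 1.0)
        got = critical_concentration(state, g, tumor_curve, n=1)
        assert got == pytest.approx(expect, rel=1e-6)

    def test_monotone_in_initial_resistant_share(self, tumor_curve, growth):
        # a larger resistant seed needs less drug to reach half-resistant
        doses = [
            critical_concentration(
                PopulationState(1e5 - nr, nr), growth, tumor_curve
            )
            for nr in (1e3, 1e4, 5e4, 9e4)
        ]
        assert all(a > b for a, b in zip(doses, doses[1:]))

    def test_no_resistant_cells_unreachable(self, tumor_curve, growth):
        with pytest.raises(UnreachableCriticalDoseError):
            critical_concentration(PopulationState(1e4, 0.0), growth, tumor_curve)

    def test_protective_bottom_plateau_unreachable(self, growth):
        # bottom = 0.5 keeps half the sensitive cells alive at any dose
        curve = HillParams(ec50=3.2, hill_coeff=2.0, top=1.0, bottom=0.5)
        state = PopulationState(1e6, 10.0)
        with pytest.raises(UnreachableCriticalDoseError):
            critical_concentration(state, growth, curve)


class TestRegimeStructure:
    def test_objectives_antagonistic_around_crossover(self, tumor_curve):
        """Below x*: fractionation gives more cells but fewer resistant;
        above x*: fewer cells but a more resistant colony. The two
        objectives can never be optimised together."""
        growth = GrowthParams(0.2, 0.04)
        state = PopulationState(5e4, 5e4)
        for n in (2, 3, 4, 5):
            x_star = crossover_dose(n, tumor_curve)
            below = np.geomspace(0.05, 0.95, 8) * x_star
            above = np.geomspace(1.05, 5.0, 8) * x_star
            df = dose_sweep(
                [state], np.concatenate([below, above]), [1, n], growth, tumor_curve
            )
            dfn = df[df.n_doses == n].set_index("dose_uM")
            assert np.all(dfn.loc[below].gain_total > 1.0)
            assert np.all(dfn.loc[below].gain_frac < 1.0)
            assert np.all(dfn.loc[above].gain_total < 1.0)
            assert np.all(dfn.loc[above].gain_frac > 1.0)


class TestCollateralTradeoff:
    def test_symmetry_with_identical_curves(self, tumor_curve):
        g0 = GrowthParams(0.0, 0.0)
        tumor = PopulationState(1e4, 0.0)
        regs = [DosingRegimen(4.0, n) for n in (1, 2, 3)]
        df = collateral_tradeoff(
            tumor, g0, tumor_curve, tumor_curve, g0, regs
        )
        np.testing.assert_allclose(
            df.tumor_total_rel_diff, df.healthy_rel_diff, rtol=1e-12
        )

    def test_zero_dose_has_no_differences(self, tumor_curve, healthy_curve, growth):
        regs = [DosingRegimen(0.0, n) for n in (1, 2, 5)]
        df = collateral_tradeoff(
            PopulationState(1e4, 1e3), growth, tumor_curve, healthy_curve,
            GrowthParams(0.1, 0.0), regs,
        )
        assert np.allclose(df.tumor_total_rel_diff, 0.0)
        assert np.allclose(df.healthy_rel_diff, 0.0)

    def test_closed_form_healthy_survival(self, tumor_curve, healthy_curve):
        dose, n = 0.3, 3
        df = collateral_tradeoff(
            PopulationState(5e4, 5e4), GrowthParams(0.2, 0.04), tumor_curve,
            healthy_curve, GrowthParams(0.0, 0.0),
            [DosingRegimen(dose, 1), DosingRegimen(dose, n)],
        )
        row = df[df.n_doses == n].iloc[0]
        assert row.healthy_surviving_fraction == pytest.approx(
            viability(dose / n, healthy_curve) ** n, rel=1e-12
        )

    def test_empty_regimen_list_rejected(self, tumor_curve, healthy_curve, growth):
        with pytest.raises(ValueError):
            collateral_tradeoff(
                PopulationState(1, 1), growth, tumor_curve, healthy_curve,
                growth, [],
            )

    def test_missing_baseline_rejected(self, tumor_curve, healthy_curve, growth):
        with pytest.raises(ValueError, match="baseline"):
            collateral_tradeoff(
                PopulationState(1, 1), growth, tumor_curve, healthy_curve,
                growth, [DosingRegimen(1.0, 2)],
            )
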