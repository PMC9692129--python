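"""Survival/IIF statistics, lifetime mixture, and the small exact conversions."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neutroflow import tether_analysis as ta
from neutroflow import tether_sim as ts


class TestSurvivalCurve:
    def test_counting_example(self):
        grid = np.array([0.0, 0.5, 1.0, 1.5, 2.0, 2.5])
        c = ta.survival_curve([0.5, 1.0, 1.5, 2.0], grid)
        assert c.at(1.0) == pytest.approx(0.75)
        assert c.S[0] == 1.0
        assert c.n_total == 4

    def test_starts_at_one_for_positive_lifetimes(self, rng):
        c = ta.survival_curve(rng.exponential(1.0, 500))
        assert c.S[0] == 1.0

    def test_exponential_closed_form_oracle(self, rng):
        life = rng.exponential(0.5, 10_000)  # rate 2
        c = ta.survival_curve(life)
        assert np.max(np.abs(c.S - np.exp(-2.0 * c.grid))) < 0.02

    def test_row_order_invariance(self, rng):
        life = rng.exponential(1.0, 1000)
        a = ta.survival_curve(life)
        b = ta.survival_curve(life[rng.permutation(1000)])
        np.testing.assert_array_equal(a.S, b.S)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ta.survival_curve([])

    def test_bad_grid_rejected(self):
        with pytest.raises(ValueError):
            ta.survival_curve([1.0], grid=np.array([0.5, 1.0]))

    @given(st.lists(st.floats(0.01, 10.0), min_size=1, max_size=50))
    @settings(max_examples=50, deadline=None)
    def test_non_increasing_and_bounded(self, lifetimes):
        c = ta.survival_curve(lifetimes)
        assert np.all(np.diff(c.S) <= 1e-12)
        assert np.all((c.S >= 0) & (c.S <= 1))


def _curve(S, n=1000, grid=None):
    grid = ta.DEFAULT_GRID if grid is None else grid
    return ta.SurvivalCurve(grid=grid, S=np.asarray(S, float), n_total=n)


class TestIIF:
    def test_defining_formula(self):
        g = ta.DEFAULT_GRID
        c = ta.iif_curve(_curve(np.full(g.size, 0.8)), _curve(np.full(g.size, 0.2)))
        np.testing.assert_allclose(c.raw, 0.75)

    def test_identical_cohorts_give_zero(self):
        g = ta.DEFAULT_GRID
        s = np.exp(-g)
        c = ta.iif_curve(_curve(s), _curve(s), pe_floor=1e-6)
        np.testing.assert_allclose(c.raw[~np.isnan(c.raw)], 0.0, atol=1e-12)

    def test_exponential_closed_form(self):
        """S_without = e^{-2t}, S_with = e^{-t}  =>  IIF(t) = 1 - e^{-t}."""
        g = ta.DEFAULT_GRID
        c = ta.iif_curve(_curve(np.exp(-g)), _curve(np.exp(-2 * g)))
        ok = ~np.isnan(c.raw)
        np.testing.assert_allclose(c.raw[ok], 1 - np.exp(-g[ok]), atol=1e-9)
        assert ta.iif_crossing_time(c, 0.5) == pytest.approx(np.log(2), abs=0.01)

    def test_mismatched_grids_rejected(self):
        g2 = np.round(np.arange(0.0, 3.0, 0.01), 2)
        with pytest.raises(ValueError):
            ta.iif_curve(
                _curve(np.exp(-g2), grid=g2), _curve(np.exp(-ta.DEFAULT_GRID))
            )

    def test_small_cohorts_rejected(self):
        g = ta.DEFAULT_GRID
        with pytest.raises(ValueError, match="cohort"):
            ta.iif_curve(_curve(np.exp(-g), n=50), _curve(np.exp(-2 * g)))

    def test_adjusted_is_monotone_and_bounded_under_noise(self, rng):
        g = ta.DEFAULT_GRID
        noisy_e = np.clip(np.exp(-g) + rng.normal(0, 0.02, g.size), 0, 1)
        noisy_0 = np.clip(np.exp(-2 * g) + rng.normal(0, 0.02, g.size), 0, 1)
        noisy_e[0] = noisy_0[0] = 1.0
        c = ta.iif_curve(_curve(noisy_e), _curve(noisy_0))
        adj = c.iif[~np.isnan(c.iif)]
        assert np.all(np.diff(adj) >= -1e-12)
        assert np.all((adj >= 0) & (adj <= 1))


class TestCrossingTimes:
    def test_already_crossed_at_first_point(self):
        g = ta.DEFAULT_GRID
        c = ta.IIFCurve(grid=g, raw=np.full(g.size, 0.2),
                        iif=np.full(g.size, 0.2), adjusted=True)
        assert ta.iif_crossing_time(c, 0.10) == g[0]

    def test_never_crossed_reports_nan(self):
        g = ta.DEFAULT_GRID
        c = ta.IIFCurve(grid=g, raw=np.full(g.size, 0.2),
                        iif=np.full(g.size, 0.2), adjusted=True)
        assert np.isnan(ta.iif_crossing_time(c, 0.95))

    def test_threshold_ordering_on_monotone_curve(self):
        g = ta.DEFAULT_GRID
        y = 1 - np.exp(-g)
        c = ta.IIFCurve(grid=g, raw=y, iif=y, adjusted=True)
        t10 = ta.iif_crossing_time(c, 0.10)
        t50 = ta.iif_crossing_time(c, 0.50)
        t95 = ta.iif_crossing_time(c, 0.95)
        assert t10 <= t50 <= t95

    def test_unadjusted_curve_rejected(self):
        g = ta.DEFAULT_GRID
        c = ta.IIFCurve(grid=g, raw=g * 0, iif=g * 0, adjusted=False)
        with pytest.raises(ValueError):
            ta.iif_crossing_time(c, 0.5)

    def test_threshold_domain(self):
        g = ta.DEFAULT_GRID
        c = ta.IIFCurve(grid=g, raw=g * 0, iif=g * 0, adjusted=True)
        for bad in (0.0, 1.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                ta.iif_crossing_time(c, bad)

    def test_crossings_shrink_with_faster_activation(self):
        """A faster local-activation clock pulls every crossing earlier."""
        crossing = {}
        for lam in (8.0, 40.0):
            ap = ts.ActivationParams(lam, 0.55, 0.528, 100.0)
            sub1 = ts.SubstrateCondition(ligand="ICAM1")
            cond = ts.FlowCondition(0.2)
            rng = np.random.default_rng(10)
            le, _ = ts.sample_tether_events(20_000, sub1, cond,
                                            ts.DEFAULT_SELECTIN_PARAMS, ap, rng)
            l0 = ts.sample_selectin_lifetimes(20_000, cond,
                                              ts.DEFAULT_SELECTIN_PARAMS, rng)
            c = ta.iif_curve(ta.survival_curve(le), ta.survival_curve(l0))
            crossing[lam] = ta.iif_crossing_time(c, 0.5)
        assert crossing[40.0] < crossing[8.0]


class TestIIFAgainstTruth:
    def test_iif_matches_holder_fraction_from_hidden_state(self):
        """IIF from paired survival curves equals the integrin-held fraction.

        Independent oracle: simulate the three clocks directly, record
        which bond holds each surviving event at time t (the selectin
        bond holds iff T_s > t), and compare with the paired-curve
        statistic computed by the package.
        """
        rng = np.random.default_rng(99)
        n = 40_000
        k, lam, p, mu = 1.48, 40.0, 0.55, 0.68
        t_s = rng.exponential(1 / k, n)
        t_a = rng.exponential(1 / lam, n)
        engaged = (t_a < t_s) & (rng.random(n) < p)
        t_i = rng.exponential(1 / mu, n)
        life = np.where(engaged, np.maximum(t_s, t_a + t_i), t_s)
        t_s0 = rng.exponential(1 / k, n)

        c = ta.iif_curve(ta.survival_curve(life), ta.survival_curve(t_s0))
        for t in (0.5, 1.0, 2.0, 3.0):
            alive = life >= t
            truth = 1.0 - (t_s[alive] >= t).mean()
            i = np.searchsorted(c.grid, t)
            assert c.iif[i] == pytest.approx(truth, abs=0.04)


class TestMeanLifetimeVsWss:
    @staticmethod
    def _events(wss_to_lifetime, n=40):
        rows = []
        for w, lt in wss_to_lifetime.items():
            rows += [(w, lt)] * n
        return pd.DataFrame(rows, columns=["wss_dyn_cm2", "lifetime_s"])

    def test_flat_data_gives_zero_curvature(self):
        res = ta.mean_lifetime_vs_wss(self._events({0.1: 1.0, 0.2: 1.0, 0.3: 1.0}))
        assert res["coeffs"][0] == pytest.approx(0.0, abs=1e-9)

    def test_quadratic_interpolates_three_exact_points(self):
        # means lie exactly on 1 + 2w - 4w^2
        vals = {w: 1 + 2 * w - 4 * w**2 for w in (0.1, 0.25, 0.4)}
        res = ta.mean_lifetime_vs_wss(self._events(vals))
        np.testing.assert_allclose(res["coeffs"], [-4.0, 2.0, 1.0], atol=1e-9)
        assert res["apex_wss"] == pytest.approx(0.25, abs=1e-9)

    def test_sparse_level_excluded_with_warning(self, caplog):
        df = pd.concat(
            [self._events({0.1: 1.0, 0.2: 1.2, 0.3: 1.0}),
             pd.DataFrame([(0.4, 9.9)], columns=["wss_dyn_cm2", "lifetime_s"])]
        )
        with caplog.at_level("WARNING"):
            res = ta.mean_lifetime_vs_wss(df)
        assert 0.4 not in set(res["table"]["wss_dyn_cm2"])
        assert any("excluding" in r.message for r in caplog.records)

    def test_default_ligand_simulation_has_interior_apex(self):
        """The ligand-reinforced mean-lifetime curve is biphasic too."""
        df = ts.generate_tether_dataset(
            [ts.SubstrateCondition(ligand="GPIbalpha")], ts.DEFAULT_WSS_GRID,
            20_000, seed=8,
        )
        res = ta.mean_lifetime_vs_wss(df)
        means = res["table"].set_index("wss_dyn_cm2")["mean_s"]
        apex = means.idxmax()
        assert ts.DEFAULT_WSS_GRID[0] < apex < ts.DEFAULT_WSS_GRID[-1]
        assert res["coeffs"][0] < 0  # concave fit


class TestLifetimeMixture:
    def test_recovers_known_two_component_mixture(self, rng):
        x = np.concatenate(
            [rng.normal(0.7, 0.1, 1000), rng.normal(1.5, 0.2, 1000)]
        )
        mix = ta.lifetime_mixture_fit(x, seed=0)
        assert mix.means[0] == pytest.approx(0.7, abs=0.05)
        assert mix.means[1] == pytest.approx(1.5, abs=0.05)
        assert mix.weights.sum() == pytest.approx(1.0)

    def test_single_component_data_degenerates(self, rng):
        x = rng.normal(1.0, 0.1, 1000)
        mix = ta.lifetime_mixture_fit(x, seed=0)
        assert (mix.weights.min() < 0.05) or (mix.means[1] - mix.means[0] < 0.15)

    def test_input_order_invariance(self, rng):
        x = np.concatenate([rng.normal(0.7, 0.1, 500), rng.normal(1.5, 0.2, 500)])
        a = ta.lifetime_mixture_fit(x, seed=0)
        b = ta.lifetime_mixture_fit(x[rng.permutation(x.size)], seed=0)
        np.testing.assert_allclose(a.means, b.means)
        np.testing.assert_allclose(a.weights, b.weights)

    def test_too_few_lifetimes_rejected(self):
        with pytest.raises(ValueError):
            ta.lifetime_mixture_fit(np.ones(50))


class TestExactConversions:
    @pytest.mark.parametrize("wss,force", [(0.0, 0.0), (0.2, 25.0), (1.0, 125.0)])
    def test_wss_to_force(self, wss, force):
        assert ta.wss_to_force(wss) == force

    def test_negative_wss_rejected(self):
        with pytest.raises(ValueError):
            ta.wss_to_force(-0.1)

    @pytest.mark.parametrize("tethered,total,ratio", [(0, 50, 0.0), (50, 50, 1.0),
                                                      (12, 48, 0.25)])
    def test_tethering_adhesion_ratio(self, tethered, total, ratio):
        assert ta.tethering_adhesion_ratio(tethered, total) == ratio

    def test_adhesion_ratio_validation(self):
        with pytest.raises(ValueError):
            ta.tethering_adhesion_ratio(5, 0)
        with pytest.raises(ValueError):
            ta.tethering_adhesion_ratio(10, 5)


class TestRateRecovery:
    def test_selectin_only_defaults_recover_off_rate(self, default_tether_events_02):
        """log-survival slope of the generated cohort matches the model off-rate.

        The detection floor conditions the exponential but leaves its
        log-slope untouched.
        """
        df = default_tether_events_02
        life = df.loc[df["ligand"] == "none", "lifetime_s"].to_numpy()
        c = ta.survival_curve(life)
        sel = (c.S > 0.05) & (c.S < 0.95)
        slope = np.polyfit(c.grid[sel], np.log(c.S[sel]), 1)[0]
        k_true = ts.off_rate(25.0, ts.DEFAULT_SELECTIN_PARAMS)
        assert -slope == pytest.approx(k_true, rel=0.05)


def test_bootstrap_mean_ci_brackets_the_mean(rng):
    x = rng.exponential(1.0, 400)
    lo, hi = ta.bootstrap_mean_ci(x, seed=2)
    assert lo < x.mean() < hi
    assert hi - lo < 0.5
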