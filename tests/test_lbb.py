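"""LBB model: catch-composition oracle, reference-point chain against the
published assessment table, posterior recovery, indicators and status."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lbstock import (ConvergenceWarning, DataError, LBBModel, LBBPriors,
                     LengthFrequencyTable, ParameterError, PopulationScenario,
                     b_over_bmsy, bmsy_proxy, classify_status,
                     compute_reference_points, expected_catch_proportions,
                     l_opt, lc_opt, length_indicators,
                     relative_yield_per_recruit, simulate_length_frequency)

# Published per-year LBB outputs: year -> (Linf, Lc, M/K, F/K) and the
# derived values printed with them.
TABLE = {
    2016: (39.7, 19.8, 1.58, 0.52),
    2017: (36.8, 20.5, 1.48, 0.58),
    2018: (39.5, 24.4, 1.24, 0.26),
    2019: (36.2, 22.4, 1.64, 0.47),
    2020: (41.3, 20.4, 1.71, 0.57),
    2021: (38.9, 22.0, 1.27, 0.61),
}
LOPT_PRINTED = {2016: 26, 2017: 25, 2018: 28, 2019: 23, 2020: 26, 2021: 27}
LCOPT_PRINTED = {2016: 19, 2017: 19, 2018: 20, 2019: 17, 2020: 20, 2021: 21}
BB0_PRINTED = {2016: 0.65, 2017: 0.62, 2018: 0.77, 2019: 0.71, 2020: 0.64,
               2021: 0.57}
BBMSY_PRINTED = {2016: 1.8, 2017: 1.7, 2018: 2.0, 2019: 1.9, 2020: 1.8,
                 2021: 1.5}


class TestExpectedProportions:
    EDGES = np.arange(10.0, 38.0, 1.0)

    def test_sums_to_one(self):
        p = expected_catch_proportions(40.0, 20.0, 2.0, 1.5, 0.5, self.EDGES)
        assert p.sum() == pytest.approx(1.0)
        assert (p >= 0).all()

    def test_pure_survivorship_oracle(self):
        """F=0 with full selection reduces to the survivorship recursion,
        recomputed independently bin by bin."""
        p = expected_catch_proportions(40.0, 0.0, np.inf, 1.5, 0.0, self.EDGES)
        n, expected = 1.0, []
        for lo, hi in zip(self.EDGES[:-1], self.EDGES[1:]):
            expected.append(n)
            n *= ((40.0 - hi) / (40.0 - lo)) ** 1.5
        expected = np.array(expected)
        np.testing.assert_allclose(p, expected / expected.sum(), rtol=1e-12)

    def test_fishing_erodes_the_large_fish_tail(self):
        top = self.EDGES[:-1] >= np.quantile(self.EDGES[:-1], 0.75)
        masses = [expected_catch_proportions(40.0, 20.0, 2.0, 1.5, fk,
                                             self.EDGES)[top].sum()
                  for fk in (0.2, 0.6, 1.2)]
        assert masses[0] > masses[1] > masses[2]

    def test_edges_at_or_above_linf_rejected(self):
        with pytest.raises(ParameterError):
            expected_catch_proportions(30.0, 20.0, 2.0, 1.5, 0.5, self.EDGES)


class TestReferencePoints:
    @pytest.mark.parametrize("year", sorted(TABLE))
    def test_optimum_lengths_match_printed_integers(self, year):
        linf, _, mk, fk = TABLE[year]
        assert round(l_opt(linf, mk)) == LOPT_PRINTED[year]
        assert round(lc_opt(linf, fk / mk, mk)) == LCOPT_PRINTED[year]

    @pytest.mark.parametrize("year", sorted(TABLE))
    def test_biomass_ratios_match_printed_values(self, year):
        linf, lc, mk, fk = TABLE[year]
        rp = compute_reference_points(linf, lc, mk, fk)
        assert rp.bb0 == pytest.approx(BB0_PRINTED[year], abs=0.01)
        assert rp.bbmsy == pytest.approx(BBMSY_PRINTED[year], abs=0.1)

    def test_2018_and_2021_chains_at_two_decimals(self):
        assert round(relative_yield_per_recruit(39.5, 24.4, 1.24, 0.26).bb0,
                     2) == 0.77
        assert round(relative_yield_per_recruit(38.9, 22.0, 1.27, 0.61).bb0,
                     2) == 0.57

    def test_bmsy_proxy_direct_value(self):
        assert bmsy_proxy(39.5, 1.24) == pytest.approx(0.377, abs=5e-4)

    def test_bmsy_proxy_decreases_with_relative_natural_mortality(self):
        values = [bmsy_proxy(40.0, mk) for mk in np.linspace(0.5, 2.5, 9)]
        assert (np.diff(values) < 0).all()

    def test_unfished_stock_has_bb0_of_one(self):
        for lc in (5.0, 15.0, 25.0):
            assert relative_yield_per_recruit(40.0, lc, 1.5, 0.0).bb0 == \
                pytest.approx(1.0, abs=1e-12)

    def test_bb0_monotone_in_fishing_and_selectivity(self):
        bb0_fk = [relative_yield_per_recruit(40.0, 20.0, 1.5, fk).bb0
                  for fk in np.linspace(0.1, 2.0, 8)]
        assert (np.diff(bb0_fk) < 0).all()
        bb0_lc = [relative_yield_per_recruit(40.0, lc, 1.5, 0.5).bb0
                  for lc in np.linspace(5.0, 35.0, 8)]
        assert (np.diff(bb0_lc) > 0).all()

    @settings(max_examples=200, derandomize=True)
    @given(linf=st.floats(5.0, 100.0), mk=st.floats(0.1, 5.0),
           fm=st.floats(0.01, 5.0))
    def test_length_optima_ordering(self, linf, mk, fm):
        assert lc_opt(linf, fm, mk) < l_opt(linf, mk) < linf

    def test_exploitation_identity(self):
        for mk, fk in [(1.5, 0.5), (1.24, 0.26), (2.0, 1.3)]:
            fm = fk / mk
            assert fk / (mk + fk) == pytest.approx(fm / (1 + fm), rel=1e-12)

    def test_closed_form_special_case(self):
        assert lc_opt(12.0, 1.0, 3.0) == pytest.approx(5.0)  # 5/12 * Linf

    def test_b_over_bmsy_quotient(self):
        assert b_over_bmsy(0.4, 0.4) == pytest.approx(1.0)
        with pytest.raises(ParameterError):
            b_over_bmsy(0.5, 0.0)


class TestPosterior:
    def test_recovers_generating_parameters(self, lbb_recovery):
        """Posterior medians within 10% of the generating values at 5,000
        fish under analyst-style priors."""
        scen, _, res = lbb_recovery
        assert res.converged
        assert res.linf == pytest.approx(scen.linf_mean, rel=0.10)
        assert res.lc == pytest.approx(scen.lc, rel=0.10)
        assert res.mk == pytest.approx(scen.m_over_k, rel=0.10)
        assert res.fk == pytest.approx(scen.f_over_k, rel=0.10)

    def test_biomass_ratio_recovered_end_to_end(self, lbb_recovery):
        scen, _, res = lbb_recovery
        truth = relative_yield_per_recruit(scen.linf_mean, scen.lc,
                                           scen.m_over_k, scen.f_over_k).bb0
        assert res.reference_points().bb0 == pytest.approx(truth, abs=0.1)

    def test_fit_is_deterministic_given_seed(self, lbb_recovery):
        _, table, _ = lbb_recovery
        priors = LBBPriors.from_table(table)
        kwargs = dict(chains=2, iterations=2000, burn_in=800, seed=5,
                      ess_floor=0.0)
        a = LBBModel(table, priors).fit(**kwargs)
        b = LBBModel(table, priors).fit(**kwargs)
        assert (a.linf, a.lc, a.alpha, a.mk, a.fk) == \
            (b.linf, b.lc, b.alpha, b.mk, b.fk)

    def test_zero_variance_priors_pin_posterior_at_prior(self, lbb_recovery):
        _, table, _ = lbb_recovery
        priors = LBBPriors(linf_prior=41.0, lc_prior=20.0, alpha_prior=2.0,
                           mk_prior=1.5, fk_prior=0.5, linf_cv=0.0, lc_cv=0.0,
                           alpha_cv=0.0, mk_cv=0.0, fk_cv=0.0)
        res = LBBModel(table, priors).fit(seed=1)
        assert (res.linf, res.lc, res.alpha, res.mk, res.fk) == \
            (41.0, 20.0, 2.0, 1.5, 0.5)

    def test_short_chains_flagged_as_unconverged(self, lbb_recovery):
        _, table, _ = lbb_recovery
        with pytest.warns(ConvergenceWarning):
            res = LBBModel(table).fit(chains=2, iterations=700, burn_in=600,
                                      seed=2)
        assert not res.converged

    def test_derived_ratio_identities(self, lbb_recovery):
        _, _, res = lbb_recovery
        assert res.zk == pytest.approx(res.mk + res.fk, rel=1e-12)
        assert res.e == pytest.approx(res.fm / (1 + res.fm), rel=1e-12)

    def test_summary_mentions_status_and_interval(self, lbb_recovery):
        _, _, res = lbb_recovery
        text = res.summary()
        assert "B/B0" in text and "95%" in text and "status" in text

    def test_too_few_bins_rejected(self):
        table = LengthFrequencyTable(2020, 10.0 * np.arange(5),
                                     np.array([1, 2, 3, 2, 1]), 10.0)
        with pytest.raises(DataError):
            LBBModel(table)


class TestIndicators:
    def test_hand_built_table_matches_brute_force_percentile(self):
        table = LengthFrequencyTable(
            2020, np.array([200.0, 210, 220, 230, 240]),
            np.array([10, 40, 30, 15, 5]), 10.0)
        ind = length_indicators(table, linf=30.0, lc=21.0, lcopt=22.0)
        # brute force: spread every fish uniformly inside its bin
        rng = np.random.default_rng(1)
        sample = np.concatenate([
            lo / 10.0 + rng.random(c)
            for lo, c in zip(table.bin_lower, table.counts * 2000)])
        assert ind.l95th == pytest.approx(np.quantile(sample, 0.95), abs=0.02)
        mids = table.mid_cm
        keep = mids > 21.0
        lmean = np.average(mids[keep], weights=table.counts[keep])
        assert ind.lmean == pytest.approx(lmean)
        assert ind.lc_over_lcopt == pytest.approx(21.0 / 22.0)

    def test_all_fish_near_linf_gives_ratio_near_one(self):
        table = LengthFrequencyTable(2020, np.array([95.0, 395.0]),
                                     np.array([1, 9999]), 10.0)
        ind = length_indicators(table, linf=40.0, lc=20.0, lcopt=22.0)
        assert ind.l95_over_linf == pytest.approx(1.0, abs=0.02)

    def test_percentile_bounded_by_table_support(self, lbb_recovery):
        _, table, _ = lbb_recovery
        ind = length_indicators(table, linf=40.0, lc=20.0, lcopt=21.0)
        assert ind.l95th <= table.edges_cm[-1]


class TestStatus:
    @pytest.mark.parametrize("bb0,bbmsy,fm,label", [
        (0.65, 1.8, 0.33, "healthy"),
        (1.0, 1.0, 1.0, "healthy"),        # boundary inclusive
        (0.5, 1.2, 1.5, "fully exploited"),  # high biomass, F above M
        (0.4, 0.7, 0.5, "fully exploited"),
        (0.2, 0.3, 0.5, "overfished"),
        (0.05, 0.1, 0.5, "collapsed"),
    ])
    def test_classification_rules(self, bb0, bbmsy, fm, label):
        assert classify_status(bb0, bbmsy, fm) == label

    def test_non_finite_inputs_rejected(self):
        with pytest.raises(ParameterError):
            classify_status(float("nan"), 1.0, 0.5)
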