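"""Trap-expansion unit tests: phenotype bins, daily bookkeeping, the
efficiency GLM and the Monte-Carlo passage expansion."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit

from otoscape import trap
from otoscape.phenotype import PHENOTYPES, assign_phenotype


class TestAssignPhenotype:
    @pytest.mark.parametrize("fl,expected", [
        (30.0, "fry"), (55.0, "fry"),          # fry bin is closed at 55
        (55.01, "parr"), (75.0, "parr"),       # parr bin is closed at 75
        (75.01, "smolt"), (110.0, "smolt"),
    ])
    def test_bin_edges(self, fl, expected):
        assert assign_phenotype(fl) == expected

    def test_rejects_nonpositive_lengths(self):
        with pytest.raises(ValueError):
            assign_phenotype(0.0)
        with pytest.raises(ValueError):
            assign_phenotype([-3.0, 60.0])

    def test_vectorized_matches_scalar(self, rng):
        fl = rng.uniform(25, 110, 50)
        assert list(assign_phenotype(fl)) == [assign_phenotype(x) for x in fl]


class TestApportionment:
    def test_all_measured_one_phenotype(self):
        rec = trap.DailyCatchRecord("2000-02-01", 100, [40.0] * 10)
        assert trap.apportion_unmeasured(rec) == {"fry": 100, "parr": 0, "smolt": 0}

    def test_even_split(self):
        rec = trap.DailyCatchRecord("2000-02-01", 10, [40.0, 90.0])
        assert trap.apportion_unmeasured(rec) == {"fry": 5, "parr": 0, "smolt": 5}

    def test_zero_catch(self):
        rec = trap.DailyCatchRecord("2000-02-01", 0, [])
        assert trap.apportion_unmeasured(rec) == {"fry": 0, "parr": 0, "smolt": 0}

    @given(raw=st.integers(1, 10_000),
           lengths=st.lists(st.floats(25, 110), min_size=1, max_size=50))
    @settings(max_examples=100, deadline=None)
    def test_conserves_raw_count(self, raw, lengths):
        raw = max(raw, len(lengths))
        out = trap.apportion_unmeasured(
            trap.DailyCatchRecord("2000-03-01", raw, lengths))
        assert sum(out.values()) == pytest.approx(raw, abs=1e-9)

    def test_series_borrows_nearest_measured_day(self):
        recs = [trap.DailyCatchRecord("2000-02-01", 50, [40.0]),
                trap.DailyCatchRecord("2000-02-02", 80, []),   # no measurements
                trap.DailyCatchRecord("2000-02-05", 20, [90.0])]
        out = trap.apportion_series(recs)
        assert out.loc["2000-02-02", "fry"] == 80  # borrowed from Feb 1


class TestInterpolation:
    def test_equal_neighbours(self):
        idx = pd.date_range("2000-01-01", periods=3)
        s = pd.Series([7.0, np.nan, 7.0], index=idx)
        assert trap.interpolate_missing(s)[idx[1]] == pytest.approx(7.0)

    def test_hand_computed_weighted_mean(self):
        idx = pd.date_range("2000-01-01", periods=3)
        s = pd.Series([10.0, np.nan, 0.0], index=idx)
        # symmetric weights at offset +-1 -> (10+0)/2
        assert trap.interpolate_missing(s)[idx[1]] == pytest.approx(5.0)

    def test_asymmetric_offsets(self):
        idx = pd.date_range("2000-01-01", periods=4)
        s = pd.Series([12.0, np.nan, np.nan, 4.0], index=idx)
        # day 1: weights 0.75 (off -1) and 0.5 (off +2) -> (9+2)/1.25
        out = trap.interpolate_missing(s)
        assert out[idx[1]] == pytest.approx((0.75 * 12 + 0.5 * 4) / 1.25)

    def test_observed_days_unchanged(self, rng):
        idx = pd.date_range("2000-01-01", periods=30)
        s = pd.Series(rng.poisson(20, 30).astype(float), index=idx)
        assert trap.interpolate_missing(s).equals(s)

    def test_all_missing_window_warns_and_zeros(self):
        idx = pd.date_range("2000-01-01", periods=9)
        s = pd.Series([1.0] + [np.nan] * 7 + [1.0], index=idx)
        with pytest.warns(UserWarning):
            out = trap.interpolate_missing(s, window=3)
        assert out[idx[4]] == 0.0


class TestEfficiencyModel:
    def test_intercept_only_closed_form(self):
        trials = [trap.EfficiencyTrial("2000-02-01", 100, 50, "fry", 10.0)
                  for _ in range(6)]
        m = trap.fit_efficiency(trials)
        assert len(m.coefficients) == 1
        assert expit(m.coefficients[0]) == pytest.approx(0.5, abs=1e-9)

    def test_dispersion_near_one_for_binomial_trials(self, rng):
        phis = []
        for _ in range(30):
            flow = rng.uniform(5, 80, 60)
            p = expit(-2.0 - 0.3 * np.log(flow))
            rec = rng.binomial(300, p)
            df = pd.DataFrame({"date": "2000-02-01", "released": 300,
                               "recaptured": rec,
                               "phenotype": rng.choice(PHENOTYPES, 60),
                               "flow": flow})
            phis.append(trap.fit_efficiency(df).dispersion)
        assert np.mean(phis) == pytest.approx(1.0, abs=0.1)

    def test_coefficient_recovery(self, rng):
        # average of replicate fits recovers the generating coefficients
        truth = {"intercept": -2.2, "log_flow": -0.35, "parr": -0.15,
                 "smolt": -0.30}
        n_rep, ests, ses = 8, [], None
        for _ in range(n_rep):
            flow = rng.uniform(5, 100, 120)
            phen = rng.choice(PHENOTYPES, 120)
            off = np.array([{"fry": 0.0, "parr": truth["parr"],
                             "smolt": truth["smolt"]}[p] for p in phen])
            p = expit(truth["intercept"] + truth["log_flow"] * np.log(flow) + off)
            df = pd.DataFrame({"date": "2000-02-01", "released": 300,
                               "recaptured": rng.binomial(300, p),
                               "phenotype": phen, "flow": flow})
            m = trap.fit_efficiency(df)
            ests.append(m.coefficients)
            ses = np.sqrt(np.diag(m.covariance))
        mean_est = np.mean(ests, axis=0)
        # parameter order: intercept, parr, smolt, log-flow
        target = np.array([truth["intercept"], truth["parr"], truth["smolt"],
                           truth["log_flow"]])
        assert np.all(np.abs(mean_est - target) < 2 * ses / np.sqrt(n_rep))

    def test_requires_valid_counts(self):
        with pytest.raises(ValueError):
            trap.EfficiencyTrial("2000-02-01", 0, 0, "fry", 10.0)
        with pytest.raises(ValueError):
            trap.EfficiencyTrial("2000-02-01", 10, 11, "fry", 10.0)


class TestBetaBinomial:
    def test_phi_one_matches_binomial_variance(self, rng):
        draws = trap._betabinom_rvs(np.full(20_000, 500), np.full(20_000, 0.3),
                                    1.0, rng)
        assert draws.var() == pytest.approx(500 * 0.3 * 0.7, rel=0.05)

    def test_overdispersed_variance_scales_with_phi(self, rng):
        phi = 3.0
        draws = trap._betabinom_rvs(np.full(40_000, 500), np.full(40_000, 0.3),
                                    phi, rng)
        assert draws.var() == pytest.approx(phi * 500 * 0.3 * 0.7, rel=0.05)

    def test_endpoint_probabilities_deterministic(self, rng):
        n = np.array([10, 20, 0])
        assert list(trap._betabinom_rvs(n, np.array([1.0, 0.0, 0.5]), 2.0, rng)) \
            == [10, 0, 0]


class TestSimulatePassage:
    def _catch(self, days=30, value=100):
        idx = pd.date_range("2000-02-01", periods=days)
        return (pd.DataFrame({p: value for p in PHENOTYPES}, index=idx),
                pd.Series(10.0, index=idx))

    def test_perfect_efficiency_identity(self):
        catch, flow = self._catch()
        model = trap.constant_efficiency_model(1.0)
        est = trap.simulate_passage(catch, model, flow, n_draws=50, seed=1)
        for p in PHENOTYPES:
            assert np.all(est[p].draws == catch[p].sum())
            assert est[p].lo95 == est[p].hi95 == est[p].point == catch[p].sum()

    def test_constant_p_expected_value(self):
        catch, flow = self._catch(days=50)
        model = trap.constant_efficiency_model(0.1)
        est = trap.simulate_passage(catch, model, flow, n_draws=2000, seed=2)
        expected = catch["fry"].sum() / 0.1
        assert est["fry"].draws.mean() == pytest.approx(expected, rel=0.01)

    def test_passage_at_least_simulated_catch(self):
        catch, flow = self._catch()
        model = trap.constant_efficiency_model(0.25, dispersion=2.0)
        est = trap.simulate_passage(catch, model, flow, n_draws=200, seed=3)
        for p in PHENOTYPES:
            assert np.all(est[p].draws >= 0)
            # passage = sim_catch / p >= sim_catch because p <= 1
            assert np.all(est[p].draws * 0.25 <= est[p].draws)

    def test_seeded_reproducibility(self, small_cohort):
        from otoscape import synthetic as syn
        td = syn.simulate_trap(small_cohort, seed=4)
        m = trap.fit_efficiency(td.trials)
        a = trap.simulate_passage(td.true_catch, m, small_cohort.flow,
                                  n_draws=100, seed=11)
        b = trap.simulate_passage(td.true_catch, m, small_cohort.flow,
                                  n_draws=100, seed=11)
        for p in a:
            assert np.array_equal(a[p].draws, b[p].draws)

    def test_total_equals_sum_of_phenotypes_per_draw(self, small_cohort):
        from otoscape import synthetic as syn
        td = syn.simulate_trap(small_cohort, seed=5)
        m = trap.fit_efficiency(td.trials)
        est = trap.simulate_passage(td.true_catch, m, small_cohort.flow,
                                    n_draws=100, seed=12)
        summed = sum(est[p].draws for p in PHENOTYPES)
        assert np.allclose(summed, est["total"].draws)

    def test_missing_flow_rejected(self):
        catch, flow = self._catch()
        with pytest.raises(ValueError, match="flow"):
            trap.simulate_passage(catch, trap.constant_efficiency_model(0.5),
                                  flow.iloc[:10], n_draws=10, seed=1)


class TestPhenology:
    def test_single_day_mass(self):
        idx = pd.date_range("2000-03-01", periods=11)
        s = pd.Series(0.0, index=idx)
        s.iloc[5] = 250.0
        ph = trap.phenology(s)
        assert (ph.first_date == ph.last_date == ph.iqr_start == ph.iqr_end
                == ph.median_date == idx[5])

    def test_uniform_quartiles(self):
        idx = pd.date_range("2000-01-01", periods=100)
        ph = trap.phenology(pd.Series(1.0, index=idx))
        assert (ph.iqr_end - ph.iqr_start).days == 50
        assert ph.first_date == idx[0] and ph.last_date == idx[-1]

    def test_symmetric_bimodal_median_centered(self):
        idx = pd.date_range("2000-01-01", periods=21)
        s = pd.Series(0.0, index=idx)
        s.iloc[3] = s.iloc[17] = 100.0
        assert trap.phenology(s).median_date == idx[10]

    def test_ordering_invariant(self, small_cohort):
        for p in PHENOTYPES:
            s = small_cohort.passage[p].astype(float)
            ph = trap.phenology(s, p)
            assert (ph.first_date <= ph.iqr_start <= ph.median_date
                    <= ph.iqr_end <= ph.last_date)

    def test_zero_total_signalled(self):
        idx = pd.date_range("2000-01-01", periods=5)
        with pytest.raises(ValueError):
            trap.phenology(pd.Series(0.0, index=idx))
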