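"""ΔBW/ΔCoM tests, stability classification, subsampling, group comparisons."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from whiskmap.data_model import AnalysisConfig
from whiskmap.responsiveness import WHISKER_LABELS
from whiskmap.stability import (
    classify_stability,
    delta_bw_test,
    delta_com_bootstrap,
    group_compare,
    interval_subsample,
    predict_change,
    within_session_control,
)


def _trials(rng, means, n=20, sd=0.08):
    return {w: rng.normal(means.get(w, 0.0), sd, n) for w in WHISKER_LABELS}


FAST = AnalysisConfig(n_permutations=1000, n_bootstrap=500,
                      subsample_reps=300, seed=3)


class TestDeltaBwTest:
    def test_identical_distributions_stable(self):
        rng = np.random.default_rng(0)
        t2 = _trials(rng, {"D2": 0.5, "D1": 0.2})
        res = delta_bw_test(t2, "D2", FAST, rng=np.random.default_rng(1))
        assert not res.changed

    def test_swap_with_large_margin_changed(self):
        rng = np.random.default_rng(2)
        t2 = _trials(rng, {"D1": 0.8, "D2": 0.1})
        res = delta_bw_test(t2, "D2", FAST, significant_s2=["D1", "D2"],
                            rng=np.random.default_rng(3))
        assert res.changed
        assert res.new_bw == "D1"

    def test_statistically_equivalent_top_whiskers_stable(self):
        rng = np.random.default_rng(4)
        t2 = _trials(rng, {"D2": 0.5, "D1": 0.52})
        res = delta_bw_test(t2, "D2", FAST, rng=np.random.default_rng(5))
        assert not res.changed

    def test_unsampled_prior_bw_rejected(self):
        with pytest.raises(ValueError):
            delta_bw_test({"D1": np.ones(5)}, "D2", FAST)

    def test_new_bw_restricted_to_significant_whiskers(self):
        rng = np.random.default_rng(6)
        t2 = _trials(rng, {"D1": 0.9, "C1": 1.5, "D2": 0.1})
        res = delta_bw_test(t2, "D2", FAST, significant_s2=["D1", "D2"],
                            rng=np.random.default_rng(7))
        assert res.changed
        assert res.new_bw == "D1"  # C1 not significant in session 2


class TestDeltaComBootstrap:
    def test_identical_sessions_stable(self):
        rng = np.random.default_rng(8)
        t1 = _trials(rng, {"D2": 0.5, "D1": 0.2})
        t2 = {w: v.copy() for w, v in t1.items()}
        res = delta_com_bootstrap(t1, t2, FAST, np.random.default_rng(9),
                                  n_iter=500)
        assert res.observed == pytest.approx(0.0)
        assert not res.changed

    def test_large_injected_shift_changed(self):
        rng = np.random.default_rng(10)
        t1 = _trials(rng, {"D2": 0.6, "D1": 0.1})
        t2 = _trials(rng, {"D2": 0.6, "D3": 0.55})
        res = delta_com_bootstrap(t1, t2, FAST, np.random.default_rng(11),
                                  n_iter=500)
        assert res.changed
        assert res.observed > res.null_threshold

    def test_split_halves_false_positive_near_alpha(self):
        # alternate halves of one stationary session → changed rate ≈ α
        rng = np.random.default_rng(12)
        flags = []
        for _ in range(120):
            full = _trials(rng, {"D2": 0.5, "D1": 0.2, "C2": 0.1}, n=40)
            t1 = {w: v[::2] for w, v in full.items()}
            t2 = {w: v[1::2] for w, v in full.items()}
            res = delta_com_bootstrap(t1, t2, FAST, rng, n_iter=400)
            flags.append(res.changed)
        rate = np.mean(flags)
        assert rate < 0.125  # ≈ 0.05 within Monte-Carlo error

    def test_whisker_in_one_session_only_excluded(self):
        rng = np.random.default_rng(13)
        t1 = _trials(rng, {"D2": 0.5})
        t2 = {w: v.copy() for w, v in t1.items()}
        del t1["C1"]
        res = delta_com_bootstrap(t1, t2, FAST, np.random.default_rng(14),
                                  n_iter=300)
        assert np.isfinite(res.observed)


class TestClassifyStability:
    def test_nonresponsive_both(self):
        rec = classify_stability("k", 0, 1, False, False, None, None)
        assert rec.transition == "stable_nonresponsive"
        assert rec.tuning_class is None

    def test_lost_and_gained(self):
        assert classify_stability("k", 0, 1, True, False, None,
                                  None).transition == "lost"
        assert classify_stability("k", 0, 2, False, True, None,
                                  None).transition == "gained"
        assert classify_stability("k", 0, 2, False, True, None,
                                  None).interval == 2

    def test_stable_responsive_runs_tuning_cascade(self):
        rng = np.random.default_rng(15)
        t1 = _trials(rng, {"D2": 0.6, "D1": 0.2})
        t2 = _trials(rng, {"D2": 0.6, "D1": 0.2})
        rec = classify_stability("k", 0, 1, True, True, t1, t2,
                                 prior_bw="D2", significant_j=["D2", "D1"],
                                 config=FAST, rng=np.random.default_rng(16),
                                 n_iter=400)
        assert rec.transition == "stable_responsive"
        assert rec.tuning_class in ("stable", "delta_com")
        assert np.isfinite(rec.delta_com_magnitude)


class TestWithinSessionControl:
    def test_zero_noise_data_never_flagged(self):
        from whiskmap.synthetic import (SimulationConfig, make_barrel_map,
                                        sample_cells, simulate_session)
        from whiskmap.data_model import filter_analysis_trials

        cfg = SimulationConfig(cells_per_column=4, blank_noise_sd=1e-6,
                               trial_gain_sd=0.0, lick_prob=0.0,
                               responsive_fraction=1.0,
                               suppressed_fraction=0.0, seed=30)
        m = make_barrel_map(cfg)
        rois, truth = sample_cells(cfg, m, cfg.rng())
        table = filter_analysis_trials(
            simulate_session(rois, truth, cfg, 0, np.random.default_rng(31)))
        res = within_session_control(table, "alternate_trials", FAST,
                                     np.random.default_rng(32), n_iter=300)
        assert res["n_tested"] > 0
        assert res["fraction_flagged"] == 0.0

    def test_modes_split_all_trials(self):
        from whiskmap.stability import _split_table
        from conftest import make_table

        rows = [("single_whisker", "D2", False)] * 10 + \
            [("blank", None, False)] * 6
        table = make_table(rows, {"r1": np.arange(16.0)})
        for mode in ("alternate_trials", "halves"):
            a, b = _split_table(table, mode)
            assert a.n_trials + b.n_trials == 16
            assert (a.trials["stimulus_kind"] == "blank").sum() == 3


class TestIntervalSubsample:
    def test_single_record_per_cell_gives_plain_mean(self):
        records = pd.DataFrame({
            "cross_session_key": ["a", "b", "c"],
            "interval": [1, 1, 1],
            "changed": [1.0, 0.0, 1.0],
        })
        est = interval_subsample(records, "changed", FAST,
                                 np.random.default_rng(17))
        assert est[1].mean == pytest.approx(2.0 / 3.0)
        assert est[1].ci_lo == est[1].ci_hi == est[1].mean

    def test_two_cell_toy_matches_enumeration(self):
        # cells A and B each contribute three Δ1 values; the estimate support
        # is the 3×3 grid of (a_i + b_j)/2
        records = pd.DataFrame({
            "cross_session_key": list("AAABBB"),
            "interval": [1] * 6,
            "changed": [0.0, 1.0, 1.0, 0.0, 0.0, 1.0],
        })
        est = interval_subsample(records, "changed", FAST,
                                 np.random.default_rng(18))
        enumerated = {(a + b) / 2 for a in (0, 1, 1) for b in (0, 0, 1)}
        assert est[1].ci_lo in enumerated and est[1].ci_hi in enumerated
        # E[mean] = (2/3 + 1/3)/2 = 0.5
        assert est[1].mean == pytest.approx(0.5, abs=0.06)

    def test_four_session_record_counts(self):
        # a cell present in 4 sessions has 3 Δ1, 2 Δ2, 1 Δ3 records
        pairs = [(i, j) for i in range(4) for j in range(i + 1, 4)]
        intervals = [j - i for i, j in pairs]
        assert intervals.count(1) == 3
        assert intervals.count(2) == 2
        assert intervals.count(3) == 1
        records = pd.DataFrame({
            "cross_session_key": "a",
            "interval": intervals,
            "changed": np.zeros(len(pairs)),
        })
        est = interval_subsample(records, "changed", FAST,
                                 np.random.default_rng(19))
        assert set(est) == {1, 2, 3}

    def test_ci_contains_mean(self):
        rng = np.random.default_rng(20)
        records = pd.DataFrame({
            "cross_session_key": np.repeat([f"c{i}" for i in range(40)], 3),
            "interval": 1,
            "changed": rng.random(120),
        })
        est = interval_subsample(records, "changed", FAST, rng)[1]
        assert est.ci_lo <= est.mean <= est.ci_hi


class TestGroupCompare:
    def test_identical_proportions_p_one(self):
        _, p = group_compare((10, 50), (10, 50), "fisher_exact")
        assert p == pytest.approx(1.0)

    def test_two_by_two_matches_hypergeometric_tail_sum(self):
        # {{2,8},{8,2}}: enumerate P(X=k) for k successes in the first row
        _, p = group_compare((2, 10), (8, 10), "fisher_exact")
        pmf = sps.hypergeom(20, 10, 10).pmf(np.arange(11))
        p_exact = pmf[pmf <= pmf[2] * (1 + 1e-9)].sum()
        assert p == pytest.approx(p_exact, rel=1e-9)

    def test_ranksum_and_ks_dispatch(self):
        rng = np.random.default_rng(21)
        a = rng.normal(0, 1, 60)
        b = rng.normal(1.2, 1, 60)
        for test in ("ranksum", "ks"):
            _, p = group_compare(a, b, test)
            assert p < 0.01

    def test_chi2_warns_on_tiny_expected_counts(self):
        with pytest.warns(UserWarning):
            group_compare((1, 2), (0, 2), "chi2")


class TestPredictChange:
    def _records(self, rng, n=400, signal=0.0):
        location = rng.uniform(0, 2, n)
        sharp = rng.uniform(0.2, 1.0, n)
        mag = rng.lognormal(-1, 0.4, n)
        cidx = np.where(rng.random(n) < 0.3, np.nan, rng.normal(0.2, 0.2, n))
        logit = -1.0 + signal * location
        p = 1 / (1 + np.exp(-logit))
        outcome = rng.random(n) < p
        return pd.DataFrame({
            "location": location, "sharpness": sharp, "magnitude": mag,
            "cluster_index": cidx, "tuning_change": outcome.astype(float),
        })

    def test_null_covariates_give_chance_discrimination(self):
        rng = np.random.default_rng(22)
        res = predict_change(self._records(rng), "tuning_change", folds=5,
                             rng_seed=0)
        assert abs(res.cv_auc - 0.5) < 0.12

    def test_location_signal_recovered(self):
        rng = np.random.default_rng(23)
        res = predict_change(self._records(rng, n=800, signal=2.0),
                             "tuning_change", folds=5, rng_seed=0)
        coefs = res.coefficients.drop("cluster_index_missing",
                                      errors="ignore").abs()
        assert coefs.idxmax() == "location"
        assert res.coefficients["location"] > 0
        assert res.cv_auc > 0.6

    def test_single_class_outcome_rejected(self):
        rng = np.random.default_rng(24)
        records = self._records(rng)
        records["tuning_change"] = 0.0
        with pytest.raises(ValueError):
            predict_change(records, "tuning_change")

    def test_perfect_separation_flagged(self):
        n = 80
        rng = np.random.default_rng(25)
        records = pd.DataFrame({
            "location": np.r_[np.zeros(40), np.ones(40)],
            "sharpness": rng.random(n),
            "magnitude": rng.random(n),
            "cluster_index": rng.random(n),
            "tuning_change": np.r_[np.zeros(40), np.ones(40)],
        })
        with pytest.raises(ValueError, match="separation"):
            predict_change(records, "tuning_change", folds=4)
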