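import numpy as np
import pandas as pd
import pytest

from panelscan import clinical_relevance as cr
from panelscan.containers import InputError, OmicsMatrix
from panelscan.synthetic_data import SimulationConfig, gen_clinical
from tests.conftest import make_mutations


class TestAlterationStatus:
    def _cnv(self, data, samples):
        meta = pd.DataFrame({"cancer_type": "C1"}, index=samples)
        return OmicsMatrix(values=pd.DataFrame(data, index=["GX"], columns=samples),
                           role="cnv", col_meta=meta)

    def test_patient_without_records_unaltered(self, one_gene_panel):
        muts = make_mutations([5], sample=["p1"])
        status = cr.alteration_status(muts, None, one_gene_panel, patients=["p1", "p2"])
        assert bool(status["p1"]) and not bool(status["p2"])

    def test_silent_mutation_does_not_alter(self, one_gene_panel):
        muts = make_mutations([5], sample=["p1"], variant_class="silent")
        status = cr.alteration_status(muts, None, one_gene_panel, patients=["p1"])
        assert not status["p1"]

    def test_high_level_cnv_alters_low_level_does_not_by_default(self, one_gene_panel):
        cnv = self._cnv([[2, 1, 0]], ["p1", "p2", "p3"])
        muts = make_mutations([]).iloc[:0]
        status = cr.alteration_status(muts, cnv, one_gene_panel, patients=["p1", "p2", "p3"])
        assert status.tolist() == [True, False, False]

    def test_any_mode_is_superset_of_high_mode(self, one_gene_panel):
        rng = np.random.default_rng(2)
        samples = [f"p{i}" for i in range(50)]
        cnv = self._cnv([rng.integers(-2, 3, size=50)], samples)
        muts = make_mutations([5, 6], sample=["p0", "p7"])
        high = cr.alteration_status(muts, cnv, one_gene_panel, patients=samples, cnv_mode="high")
        any_ = cr.alteration_status(muts, cnv, one_gene_panel, patients=samples, cnv_mode="any")
        assert (any_ | high).equals(any_)  # high-altered set is contained in any-altered

    def test_empty_patient_universe_rejected(self, one_gene_panel):
        with pytest.raises(InputError):
            cr.alteration_status(make_mutations([]).iloc[:0], None, one_gene_panel, patients=[])


class TestCompareClinicalFeatures:
    def _cohort(self, seed, **config_kwargs):
        config = SimulationConfig(seed=seed, **config_kwargs)
        ids = [f"P{i}" for i in range(400)]
        status = pd.Series([True] * 200 + [False] * 200, index=ids)
        return gen_clinical(ids, status, config), status

    def test_null_groups_not_significant(self):
        clin, status = self._cohort(40, hazard_multiplier_altered=1.0, hypoxia_shift=0.0,
                                    tmb_multiplier_altered=1.0, stage_log_odds_shift=0.0)
        res = cr.compare_clinical_features(clin, status)
        tested = res[res["p_value"].notna()]
        assert (tested["adjusted_p"] >= 0.05).all()

    def test_planted_hypoxia_shift_detected(self):
        clin, status = self._cohort(41, hypoxia_shift=1.0)
        res = cr.compare_clinical_features(clin, status).set_index("feature")
        assert res.loc["hypoxia_score", "p_value"] < 1e-3
        assert res.loc["tmb", "p_value"] < 1e-3

    def test_fisher_branch_for_sparse_2x2(self):
        clin = pd.DataFrame(
            {
                "sex": ["female"] * 3 + ["male"] * 17,
                "hypoxia_score": np.arange(20, dtype=float),
            },
            index=[f"P{i}" for i in range(20)],
        )
        status = pd.Series([True] * 10 + [False] * 10, index=clin.index)
        res = cr.compare_clinical_features(clin, status, features=["sex", "hypoxia_score"])
        assert res.set_index("feature").loc["sex", "test"] == "fisher"

    def test_missing_feature_reported_untested(self):
        clin = pd.DataFrame({"hypoxia_score": [1.0, 2.0, 3.0, 4.0]},
                            index=[f"P{i}" for i in range(4)])
        status = pd.Series([True, True, False, False], index=clin.index)
        res = cr.compare_clinical_features(clin, status, features=["weight", "hypoxia_score"])
        assert res.set_index("feature").loc["weight", "test"] == "untested"

    def test_type_one_error_controlled_over_replicates(self):
        # null cohorts: fraction of feature tests at p < 0.05 stays near nominal
        flags, total = 0, 0
        for rep in range(200):
            config = SimulationConfig(seed=1000 + rep, hazard_multiplier_altered=1.0,
                                      hypoxia_shift=0.0, tmb_multiplier_altered=1.0,
                                      stage_log_odds_shift=0.0)
            ids = [f"P{i}" for i in range(80)]
            status = pd.Series([True] * 40 + [False] * 40, index=ids)
            clin = gen_clinical(ids, status, config)
            res = cr.compare_clinical_features(clin, status)
            tested = res[res["p_value"].notna()]
            flags += int((tested["p_value"] < 0.05).sum())
            total += len(tested)
        assert flags / total <= 0.075


class TestLogrank:
    def test_identical_groups_chi2_zero(self):
        times = [5, 8, 12, 5, 8, 12]
        events = [1, 1, 0, 1, 1, 0]
        groups = ["a", "a", "a", "b", "b", "b"]
        chi2, p = cr.logrank_test(times, events, groups)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_six_patient_hand_computation(self):
        # A: events at 1, 3, censored 4; B: event at 5, censored 2, 6.
        # Hand tabulation over event times 1, 3, 5:
        #  t=1: n=6, nA=3, d=1, dA=1 -> e=0.5, v=0.25
        #  t=3: n=4, nA=2, d=1, dA=1 -> e=0.5, v=0.25
        #  t=5: n=2, nA=0, d=1, dA=0 -> e=0,   v=0
        # chi2 = (2 - 1.0)^2 / 0.5 = 2
        times = [1, 3, 5, 2, 4, 6]
        events = [1, 1, 1, 0, 0, 0]
        groups = ["A", "A", "B", "B", "A", "B"]
        chi2, _ = cr.logrank_test(times, events, groups)
        assert chi2 == pytest.approx(2.0, abs=1e-12)

    def test_label_swap_invariance(self):
        rng = np.random.default_rng(5)
        times = rng.exponential(1, 60)
        events = rng.integers(0, 2, 60)
        events[0] = 1
        groups = np.array(["x"] * 30 + ["y"] * 30)
        chi2_a, _ = cr.logrank_test(times, events, groups)
        chi2_b, _ = cr.logrank_test(times, events, np.where(groups == "x", "y", "x"))
        assert chi2_a == pytest.approx(chi2_b)

    def test_agrees_with_lifelines(self):
        from lifelines.statistics import logrank_test as ll_logrank

        rng = np.random.default_rng(6)
        times = rng.exponential(1.0 / np.r_[np.ones(40), 2 * np.ones(40)])
        cens = rng.uniform(0, 2, 80)
        obs = np.minimum(times, cens)
        events = (times <= cens).astype(int)
        groups = np.array([0] * 40 + [1] * 40)
        chi2, p = cr.logrank_test(obs, events, groups)
        ref = ll_logrank(obs[groups == 0], obs[groups == 1],
                         events[groups == 0], events[groups == 1])
        assert chi2 == pytest.approx(ref.test_statistic, rel=1e-9)
        assert p == pytest.approx(ref.p_value, rel=1e-9)

    def test_all_censored_rejected(self):
        with pytest.raises(InputError):
            cr.logrank_test([1, 2, 3, 4], [0, 0, 0, 0], ["a", "a", "b", "b"])

    def test_three_groups_rejected(self):
        with pytest.raises(InputError):
            cr.logrank_test([1, 2, 3], [1, 1, 1], ["a", "b", "c"])


class TestOptimalCutpoint:
    def test_perfect_bimodal_separation(self):
        x = np.array([1.0] * 10 + [10.0] * 10)
        times = np.r_[np.full(10, 100.0), np.full(10, 5.0)]
        events = np.ones(20, dtype=int)
        res = cr.optimal_cutpoint(x, times, events)
        assert 1.0 < res["cutpoint"] < 10.0
        assert res["selection_biased_p"]

    def test_minprop_honored(self):
        rng = np.random.default_rng(8)
        x = np.arange(20, dtype=float)
        times = rng.exponential(1, 20)
        events = np.ones(20, dtype=int)
        res = cr.optimal_cutpoint(x, times, events, minprop=0.1)
        n_high = (x > res["cutpoint"]).sum()
        assert 2 <= n_high <= 18

    def test_matches_exhaustive_oracle(self):
        from panelscan.benchmarks import cutpoint_oracle_agreement

        assert cutpoint_oracle_agreement(seed=9, n_instances=3, n=80) == 1.0

    def test_constant_expression_rejected(self):
        with pytest.raises(InputError):
            cr.optimal_cutpoint(np.ones(20), np.arange(1, 21, dtype=float), np.ones(20, dtype=int))


class TestHazardRatio:
    def test_identical_groups_hr_near_one(self):
        times = np.tile([3.0, 6.0, 9.0, 12.0, 15.0], 4)
        events = np.tile([1, 1, 0, 1, 0], 4)
        groups = np.array(["altered"] * 10 + ["unaltered"] * 10)
        fit = cr.hazard_ratio(groups, times, events)
        assert fit.ci_low <= 1.0 <= fit.ci_high
        assert fit.classification == "ns"

    def test_exponential_arms_recover_true_hr(self):
        config = SimulationConfig(seed=50, hazard_multiplier_altered=2.0)
        ids = [f"P{i}" for i in range(400)]
        status = pd.Series([True] * 200 + [False] * 200, index=ids)
        clin = gen_clinical(ids, status, config)
        fit = cr.hazard_ratio(np.where(status, "altered", "unaltered"),
                              clin["os_time"], clin["os_event"])
        assert 1.6 <= fit.hr <= 2.5
        assert fit.classification == "risky"

    def test_zero_expression_filter(self):
        rng = np.random.default_rng(10)
        x = np.r_[np.zeros(60), rng.uniform(1, 5, 40)]
        times = rng.exponential(1, 100)
        events = np.ones(100, dtype=int)
        fit = cr.hazard_ratio(x, times, events, label="gene_z")
        assert fit.skipped == "zero-expression filter"

    def test_agrees_with_logrank_direction(self):
        config = SimulationConfig(seed=51, hazard_multiplier_altered=2.0)
        ids = [f"P{i}" for i in range(600)]
        status = pd.Series([True] * 300 + [False] * 300, index=ids)
        clin = gen_clinical(ids, status, config)
        fit = cr.hazard_ratio(status.to_numpy(), clin["os_time"], clin["os_event"])
        _, p = cr.logrank_test(clin["os_time"], clin["os_event"], status)
        assert (fit.p_value < 0.05) == (p < 0.05)
        assert fit.hr > 1
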