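"""Concordance index, feature table rules, selection and Cox network."""

import numpy as np
import pandas as pd
import pytest
from sksurv.metrics import concordance_index_censored

from hccpipe import survival as SV
from tests.conftest import make_survival_table


class TestConcordance:
    def test_perfect_and_reversed_ordering(self):
        t = np.array([5, 4, 3, 2, 1.0])
        e = np.ones(5, int)
        risk = np.array([1, 2, 3, 4, 5.0])
        assert SV.concordance_index(risk, t, e) == 1.0
        assert SV.concordance_index(-risk, t, e) == 0.0

    def test_five_patient_censored_case_by_hand(self):
        # times 1,2,3,4,5; patient 3 (t=3) censored; risk 5,4,1,2,3
        # comparable pairs: (1,*)x4, (2,*)x3, (4,5)
        # concordant: 1 vs all (risk 5 highest) = 4; 2 vs {3,4,5} = 3; 4 vs 5 risk 2<3 -> 0
        risk = np.array([5, 4, 1, 2, 3.0])
        t = np.array([1, 2, 3, 4, 5.0])
        e = np.array([1, 1, 0, 1, 1])
        assert SV.concordance_index(risk, t, e) == pytest.approx(7 / 8)

    def test_matches_independent_library_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 21))
            t = rng.integers(1, 10, n).astype(float)  # ties on purpose
            e = rng.integers(0, 2, n)
            risk = rng.integers(0, 5, n).astype(float)  # risk ties too
            if e.sum() == 0:
                e[0] = 1
            try:
                ours = SV.concordance_index(risk, t, e)
            except ValueError:
                continue
            ref = concordance_index_censored(e.astype(bool), t, risk)[0]
            assert ours == pytest.approx(ref, abs=1e-12)

    def test_no_comparable_pairs_raises(self):
        with pytest.raises(ValueError):
            SV.concordance_index([1, 2], [5, 5], [0, 0])


class TestFeatureTable:
    def _inputs(self, n=40):
        rng = np.random.default_rng(1)
        sids = [f"s{i}" for i in range(n)]
        clinical = pd.DataFrame({
            "sample_id": sids,
            "cohort": ["A"] * (n // 2) + ["B"] * (n // 2),
            "age": rng.normal(60, 8, n),
            "sex": rng.choice(["male", "female"], n),
            "viral_status": rng.choice(["HBV", "HCV", "none"], n),
            "stage": rng.choice(["I", "II", "III", "IV"], n),
            "grade": rng.choice(["G1", "G2", "G3", "G4"], n),
            "os_time": rng.uniform(1, 60, n),
            "os_event": rng.integers(0, 2, n),
        })
        molecular = pd.DataFrame({"purity": rng.uniform(0.4, 0.9, n)}, index=sids)
        ith = pd.DataFrame(rng.uniform(0, 1, (n, 3)), index=sids,
                           columns=["plm", "math", "shannon"])
        return clinical, molecular, ith, sids, rng

    def test_signature_mean_rule(self):
        clinical, molecular, ith, sids, rng = self._inputs()
        sigs = pd.DataFrame({"SBS5": 0.5, "SBSlow": 0.04}, index=sids)
        sigs["SBS5"] += rng.normal(0, 0.01, len(sids))
        sigs["SBSlow"] += rng.normal(0, 0.005, len(sids))
        drv = pd.DataFrame(index=sids)
        X, cats = SV.build_feature_table(clinical, molecular, drv, ith,
                                         signature_exposures=sigs)
        assert "sig_SBS5" in X.columns and "sig_SBSlow" not in X.columns

    def test_cnv_either_cohort_rule(self):
        clinical, molecular, ith, sids, rng = self._inputs()
        cohort = clinical.set_index("sample_id")["cohort"]
        cnv = pd.DataFrame(0, index=sids, columns=["armX", "armY"])
        cnv.loc[cohort == "A", "armX"] = (rng.random((cohort == "A").sum()) < 0.45).astype(int)
        cnv.loc[cohort == "B", "armX"] = (rng.random((cohort == "B").sum()) < 0.10).astype(int)
        cnv["armY"] = (rng.random(len(sids)) < 0.05).astype(int)
        X, _ = SV.build_feature_table(clinical, molecular, pd.DataFrame(index=sids),
                                      ith, cnv_events=cnv, cohort=cohort)
        assert "cnv_armX" in X.columns and "cnv_armY" not in X.columns

    def test_driver_mutation_count_rule(self):
        clinical, molecular, ith, sids, _ = self._inputs()
        drv = pd.DataFrame(0, index=sids, columns=["G14", "G15"])
        drv.iloc[:14, 0] = 1
        drv.iloc[:15, 1] = 1
        X, cats = SV.build_feature_table(clinical, molecular, drv, ith)
        assert "drv_G15" in X.columns and "drv_G14" not in X.columns
        assert cats["drv_G15"] == "driver"

    def test_missing_survival_columns_rejected(self):
        clinical, molecular, ith, sids, _ = self._inputs()
        with pytest.raises(ValueError):
            SV.build_feature_table(clinical.drop(columns=["os_time"]),
                                   molecular, pd.DataFrame(index=sids), ith)


class TestSelection:
    def test_deterministic_given_seed(self, rng):
        tab = make_survival_table(rng, n=80, coef=0.9, n_noise=4)
        factory = lambda s: SV.RSFLearner(n_estimators=40, seed=s)
        a = SV.select_features(tab, factory, n_repeats=6, threshold=3, seed=5)
        b = SV.select_features(tab, factory, n_repeats=6, threshold=3, seed=5)
        assert a.times_selected.equals(b.times_selected)

    def test_threshold_monotonicity(self, rng):
        tab = make_survival_table(rng, n=80, coef=0.9, n_noise=4)
        factory = lambda s: SV.RSFLearner(n_estimators=40, seed=s)
        res = SV.select_features(tab, factory, n_repeats=8, threshold=4, seed=2)
        low = set(res.times_selected[res.times_selected >= 2].index)
        high = set(res.times_selected[res.times_selected >= 6].index)
        assert high <= low

    def test_planted_feature_dominates(self, rng):
        tab = make_survival_table(rng, n=150, coef=np.log(2.5), n_noise=6)
        factory = lambda s: SV.RSFLearner(n_estimators=80, seed=s)
        res = SV.select_features(tab, factory, n_repeats=10, threshold=9, seed=3)
        assert res.times_selected["signal"] >= 9
        assert res.selected["signal"]

    def test_too_few_events_rejected(self, rng):
        tab = make_survival_table(rng, n=30, censor_scale=5)
        tab["os_event"] = 0
        tab.loc[:4, "os_event"] = 1
        with pytest.raises(ValueError):
            SV.select_features(tab, n_repeats=1, seed=0)


class TestEvaluation:
    def test_category_with_no_features_rejected(self, rng):
        tab = make_survival_table(rng, n=60)
        cats = pd.Series("molecular", index=[c for c in tab.columns
                                             if c not in ("os_time", "os_event")])
        with pytest.raises(ValueError):
            SV.evaluate_categories(tab, cats, n_splits=2, which=("ith",))

    def test_informative_beats_noise_category(self, rng):
        tab = make_survival_table(rng, n=150, coef=1.2, n_noise=5)
        cols = [c for c in tab.columns if c not in ("os_time", "os_event")]
        cats = pd.Series(["molecular"] + ["clinical"] * 5, index=cols)
        ev = SV.evaluate_categories(
            tab, cats, lambda s: SV.RSFLearner(n_estimators=60, seed=s),
            n_splits=8, seed=4, which=("molecular", "clinical"))
        mean = ev.groupby("category")["cindex"].mean()
        assert mean["molecular"] > mean["clinical"]


class TestImportanceAndNetwork:
    def test_dominant_feature_ranks_first(self, rng):
        tab = make_survival_table(rng, n=120, coef=1.2, n_noise=5)
        ranks = SV.importance_ranking(
            tab, lambda s: SV.RSFLearner(n_estimators=60, seed=s),
            n_repeats=5, seed=0)
        assert ranks.index[0] == "signal"

    def test_single_feature_rank_one(self, rng):
        tab = make_survival_table(rng, n=60, coef=0.8, n_noise=0)
        ranks = SV.importance_ranking(
            tab, lambda s: SV.RSFLearner(n_estimators=40, seed=s),
            n_repeats=3, seed=1)
        assert ranks["signal"] == 1.0

    def test_cox_hr_direction_matches_generator(self, rng):
        tab = make_survival_table(rng, n=200, coef=0.9, n_noise=2)
        nodes, edges = SV.univariate_cox_network(tab)
        assert nodes.loc["signal", "hr"] > 1
        assert nodes.loc["signal", "p"] < 0.01
        assert nodes.loc["signal", "shape"] == "circle"

    def test_protective_feature_is_diamond(self, rng):
        tab = make_survival_table(rng, n=200, coef=-0.9, n_noise=1)
        nodes, _ = SV.univariate_cox_network(tab)
        assert nodes.loc["signal", "hr"] < 1
        assert nodes.loc["signal", "shape"] == "diamond"

    def test_constant_feature_dropped_with_warning(self, rng):
        tab = make_survival_table(rng, n=50, n_noise=1)
        tab["const"] = 1.0
        with pytest.warns(UserWarning):
            nodes, _ = SV.univariate_cox_network(tab)
        assert "const" not in nodes.index

    def test_independent_features_edge_rate_near_nominal(self, rng):
        tab = make_survival_table(rng, n=100, n_noise=9)
        _, edges = SV.univariate_cox_network(tab, edge_p=0.05)
        n_pairs = 10 * 9 / 2
        assert len(edges) <= n_pairs * 0.05 + 3
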