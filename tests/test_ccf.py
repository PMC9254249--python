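"""CCF estimation, timing, subclone clustering and ITH metrics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hccpipe import ccf as C


def _calls(rows):
    return pd.DataFrame(rows, columns=["t_depth", "t_alt_count"])


class TestFilter:
    def test_read_support_thresholds(self):
        df = _calls([(9, 5), (100, 2), (100, 3), (10, 3), (100, 30)])
        # VAF for row 2 is 0.03 < 0.05; row 3 is the all-boundaries case
        kept = C.filter_mutations(df)
        assert list(kept.index) == [3, 4]

    def test_missing_columns_raise(self):
        with pytest.raises(ValueError):
            C.filter_mutations(pd.DataFrame({"t_depth": [10]}))

    def test_order_preserved(self):
        df = _calls([(50, 20), (9, 9), (60, 30)])
        assert list(C.filter_mutations(df).index) == [0, 2]


class TestExpectedVaf:
    @pytest.mark.parametrize(
        "ccf,purity,cn_n,cn_m,expected",
        [
            (1.0, 1.0, 2, 2, 0.5),
            (1.0, 0.6, 2, 2, 0.3),
            (0.0, 0.37, 2, 3, 0.0),
            (0.5, 0.6, 2, 2, 0.15),
        ],
    )
    def test_formula_values(self, ccf, purity, cn_n, cn_m, expected):
        assert C.expected_vaf(ccf, purity, cn_n, cn_m) == pytest.approx(expected)

    def test_clamped_to_unit_interval(self):
        assert 0 <= C.expected_vaf(1.0, 1.0, 1, 1) <= 1


class TestEstimate:
    @pytest.mark.parametrize(
        "alt,depth,purity,cn,expected",
        [(30, 100, 0.6, 2, 1.0), (15, 100, 0.6, 2, 0.5), (50, 100, 1.0, 2, 1.0)],
    )
    def test_known_optima(self, alt, depth, purity, cn, expected):
        est = C.estimate_ccf(alt, depth, purity, cn)
        assert est.ccf == pytest.approx(expected, abs=1e-3)

    def test_grid_oracle_agreement(self, rng):
        """Brent minimum matches an exhaustive 1e-3 grid search."""
        grid = np.linspace(0.0, 1.0, 1001)
        for _ in range(30):
            depth = int(rng.integers(15, 250))
            alt = int(rng.integers(1, depth + 1))
            purity = float(rng.uniform(0.2, 1.0))
            cn = int(rng.integers(1, 6))
            est = C.estimate_ccf(alt, depth, purity, cn)
            dev = C.binomial_deviance(grid, alt, depth, purity, 2, cn)
            assert abs(est.ccf - grid[np.argmin(dev)]) <= 1e-3

    def test_vectorized_table_matches_scalar_path(self, rng):
        rows = []
        for _ in range(40):
            depth = int(rng.integers(15, 250))
            rows.append({"chrom": "chr1", "pos": 10, "t_depth": depth,
                         "t_alt_count": int(rng.integers(1, depth + 1))})
        calls = pd.DataFrame(rows)
        prof = C.SampleProfile("s", 0.62)
        tab = C.estimate_ccf_table(calls, prof)
        for (i, row) in calls.iterrows():
            est = C.estimate_ccf(row["t_alt_count"], row["t_depth"], 0.62, 2)
            assert tab.loc[i, "ccf"] == pytest.approx(est.ccf, abs=1e-5)

    def test_male_x_uses_haploid_normal(self):
        est = C.estimate_ccf(30, 100, 0.6, 2, chrom="chrX", sex="male")
        assert est.cn_normal == 1
        est_f = C.estimate_ccf(30, 100, 0.6, 2, chrom="chrX", sex="female")
        assert est_f.cn_normal == 2

    def test_timing_threshold_tie_is_early(self):
        # alt/depth chosen so the MLE lands exactly on 0.8: vaf = 0.8*p/2
        est = C.estimate_ccf(24, 100, 0.6, 2)
        assert est.ccf == pytest.approx(0.8, abs=1e-6)
        assert est.timing == "early"

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            C.estimate_ccf(5, 0, 0.5)
        with pytest.raises(ValueError):
            C.SampleProfile("s", 0.0)


class TestSubclones:
    def test_degenerate_single_cluster(self):
        m = C.cluster_subclones(np.ones(30))
        assert m.n_clusters == 1 and m.means[0] == pytest.approx(1.0)

    def test_two_planted_clusters_recovered(self, rng):
        x = np.concatenate([
            np.clip(rng.normal(1.0, 0.03, 50), 0, 1),
            rng.normal(0.4, 0.03, 50),
        ])
        m = C.cluster_subclones(x, seed=0)
        assert m.n_clusters == 2
        assert abs(m.means[0] - 1.0) < 0.05 and abs(m.means[1] - 0.4) < 0.05

    def test_too_few_mutations_warns(self):
        with pytest.warns(UserWarning):
            m = C.cluster_subclones([0.5, 0.6, 0.7])
        assert m.n_clusters == 1

    def test_counts_sum_to_mutations(self, rng):
        x = rng.uniform(0.1, 1.0, 80)
        m = C.cluster_subclones(x, seed=1)
        assert m.counts.sum() == 80


class TestITH:
    def test_math_hand_value(self):
        assert C.math_score([0.1, 0.2, 0.3, 0.4, 0.5]) == pytest.approx(49.42, abs=0.01)

    def test_math_zero_for_identical_vafs(self):
        assert C.math_score([0.3] * 10) == 0.0

    def test_math_zero_median_raises(self):
        with pytest.raises(ValueError):
            C.math_score([0.0, 0.0, 0.0])

    def test_shannon_symmetric_and_degenerate(self):
        assert C.shannon_index([50, 50]) == pytest.approx(np.log(2), abs=1e-9)
        assert C.shannon_index([100]) == 0.0

    @given(st.lists(st.integers(min_value=1, max_value=500), min_size=2, max_size=6))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_shannon_maximal_for_equal_sizes(self, counts):
        k = len(counts)
        assert C.shannon_index(counts) <= C.shannon_index([1] * k) + 1e-12
        assert C.shannon_index(counts) <= np.log(k) + 1e-12

    def test_plm_complements_early_fraction(self, rng):
        ccfs = rng.uniform(0, 1, 200)
        model = C.cluster_subclones(ccfs, seed=0)
        m = C.ith_metrics(ccfs, rng.uniform(0.05, 0.5, 200), model)
        assert m.plm + (ccfs >= 0.8).mean() == pytest.approx(1.0)

    def test_all_clonal_sample_has_zero_plm(self):
        ccfs = np.ones(40)
        model = C.cluster_subclones(ccfs)
        m = C.ith_metrics(ccfs, np.full(40, 0.35), model)
        assert m.plm == 0.0 and m.shannon == 0.0 and m.math_score == 0.0

    def test_mean_ccf_shannon_variant(self):
        model = C.SubcloneModel(np.zeros(4, int), np.array([1.0, 0.5]), np.array([2, 2]))
        m = C.ith_metrics([1, 1, 0.5, 0.5], [0.3, 0.3, 0.2, 0.2], model,
                          shannon_on_mean_ccf=True)
        p = np.array([1.0, 0.5]) / 1.5
        assert m.shannon == pytest.approx(float(-(p * np.log(p)).sum()))
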