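"""Signature catalog, deconvolution, retention rule, grouping, timing."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import nnls
from sklearn.metrics import adjusted_rand_score

from hccpipe import signatures as S


@pytest.fixture(scope="module")
def catalog():
    return S.synthetic_catalog()


class TestCatalog:
    def test_bundled_catalog_shape_and_simplex(self, catalog):
        assert catalog.matrix.shape == (10, 96)
        assert np.allclose(catalog.matrix.sum(axis=1), 1.0, atol=1e-8)
        assert (catalog.matrix >= 0).all()

    def test_tsv_roundtrip(self, catalog, tmp_path):
        p = tmp_path / "cat.tsv"
        catalog.to_tsv(p)
        back = S.SignatureCatalog.from_tsv(p)
        assert back.names == catalog.names
        assert np.allclose(back.matrix, catalog.matrix)

    def test_context_labels_canonical(self):
        assert len(S.CONTEXTS_96) == 96
        assert S.CONTEXTS_96[0] == "A[C>A]A" and S.CONTEXTS_96[-1] == "T[T>G]T"


class TestCounting:
    def test_concentrated_sample(self):
        calls = pd.DataFrame({"sample_id": ["s"] * 10, "context96": ["A[C>A]A"] * 10})
        tab = S.count_contexts(calls)
        assert tab.loc["s", "A[C>A]A"] == 10 and tab.loc["s"].sum() == 10

    def test_conservation_and_empty_sample(self):
        calls = pd.DataFrame({
            "sample_id": ["a", "a", "b"],
            "context96": ["A[C>A]A", "T[T>G]T", "C[C>T]G"],
        })
        tab = S.count_contexts(calls, samples=["a", "b", "c"])
        assert tab.to_numpy().sum() == 3
        assert tab.loc["c"].sum() == 0

    def test_unknown_context_rejected(self):
        calls = pd.DataFrame({"sample_id": ["s"], "context96": ["bogus"]})
        with pytest.raises(ValueError):
            S.count_contexts(calls)


class TestDeconvolution:
    def test_identity_profile(self, catalog):
        ev = S.deconvolute(catalog.matrix[3] * 5000, catalog)
        assert ev.weights["SBS6"] == pytest.approx(1.0, abs=1e-6)
        assert ev.residual < 1e-10

    def test_two_signature_mixture_recovery(self, catalog, rng):
        mix = 0.7 * catalog.matrix[2] + 0.3 * catalog.matrix[7]
        counts = rng.multinomial(10_000, mix)
        ev = S.deconvolute(counts, catalog)
        assert abs(ev.weights["SBS5"] - 0.7) < 0.05
        assert abs(ev.weights["SBS22"] - 0.3) < 0.05

    def test_scaling_invariance(self, catalog, rng):
        counts = rng.multinomial(3000, catalog.matrix[0] * 0.5 + catalog.matrix[4] * 0.5)
        a = S.deconvolute(counts, catalog).weights
        b = S.deconvolute(counts * 10, catalog).weights
        assert np.allclose(a, b, atol=1e-9)

    def test_zero_profile_rejected(self, catalog):
        with pytest.raises(ValueError):
            S.deconvolute(np.zeros(96), catalog)

    def test_objective_beats_nnls_projection_oracle(self, catalog, rng):
        """Solver objective must not exceed an independent NNLS-then-project
        oracle (tolerance 1e-6) on random profiles."""
        Smat = catalog.matrix
        for _ in range(100):
            x = rng.dirichlet(np.full(96, 0.3))
            ev = S.deconvolute(x, catalog, min_weight=0.0)
            w_o, _ = nnls(Smat.T, x)
            if w_o.sum() > 1:
                w_o = w_o / w_o.sum()
            obj_ours = ((x - Smat.T @ ev.weights.to_numpy()) ** 2).sum()
            obj_oracle = ((x - Smat.T @ w_o) ** 2).sum()
            assert obj_ours <= obj_oracle + 1e-6

    def test_residual_reported_for_unfittable_profile(self, catalog):
        ev = S.deconvolute(np.ones(96), catalog, min_weight=0.0)
        assert ev.residual > 0


class TestRetention:
    def _counts_from_exposures(self, catalog, exposures, n=20_000, seed=0):
        rng = np.random.default_rng(seed)
        rows = {}
        for sid, w in exposures.iterrows():
            mix = w.to_numpy() @ catalog.matrix
            rows[sid] = rng.multinomial(n, mix / mix.sum())
        return pd.DataFrame(rows, index=S.CONTEXTS_96).T

    def test_rule_drops_and_keeps_exactly(self, catalog):
        names = catalog.names
        # SBS29 mean ~0.1% max 5% -> dropped; SBS24 mean 1% but max 25% -> kept
        exposures = pd.DataFrame(0.0, index=[f"s{i}" for i in range(10)], columns=names)
        exposures["SBS5"] = 0.85
        exposures["SBS1"] = 0.10
        exposures.loc["s0", "SBS29"] = 0.05
        exposures.loc["s0", "SBS5"] = 0.80
        exposures.loc["s1", "SBS24"] = 0.25
        exposures.loc["s1", "SBS5"] = 0.60
        exposures = exposures.div(exposures.sum(axis=1), axis=0)
        counts = self._counts_from_exposures(catalog, exposures)
        reduced, refit = S.iterative_retention(counts, catalog)
        assert "SBS29" not in reduced.names
        assert "SBS24" in reduced.names
        assert set(refit.columns) == set(reduced.names)

    def test_rule_idempotent(self, catalog):
        exposures = pd.DataFrame(
            {"SBS5": [0.6] * 6, "SBS22": [0.4] * 6},
            index=[f"s{i}" for i in range(6)],
        ).reindex(columns=catalog.names, fill_value=0.0)
        counts = self._counts_from_exposures(catalog, exposures)
        red1, _ = S.iterative_retention(counts, catalog)
        red2, refit2 = S.iterative_retention(counts, red1)
        assert red1.names == red2.names

    def test_needs_two_samples(self, catalog):
        counts = pd.DataFrame([np.ones(96)], index=["s"], columns=S.CONTEXTS_96)
        with pytest.raises(ValueError):
            S.iterative_retention(counts, catalog)


class TestGroups:
    def test_two_archetypes_recovered(self, rng):
        a = rng.dirichlet([50, 5, 5], size=20)
        b = rng.dirichlet([5, 50, 5], size=20)
        exposures = pd.DataFrame(np.vstack([a, b]), columns=["x", "y", "z"],
                                 index=[f"s{i}" for i in range(40)])
        groups = S.signature_groups(exposures, k=2)
        truth = [0] * 20 + [1] * 20
        assert adjusted_rand_score(truth, groups.to_numpy()) == 1.0

    def test_k_equals_n_gives_singletons(self, rng):
        exposures = pd.DataFrame(rng.dirichlet([1, 1, 1], size=5),
                                 index=[f"s{i}" for i in range(5)])
        groups = S.signature_groups(exposures, k=5)
        assert groups.nunique() == 5

    def test_k_beyond_n_rejected(self, rng):
        exposures = pd.DataFrame(rng.dirichlet([1, 1], size=3))
        with pytest.raises(ValueError):
            S.signature_groups(exposures, k=4)


class TestTiming:
    def _cohort(self, catalog, rng, n_samples, early_mix, late_mix, n_mut=120):
        rows, ccfs = [], []
        for i in range(n_samples):
            for mix, ccf in ((early_mix, 0.95), (late_mix, 0.3)):
                ctx = rng.choice(96, size=n_mut, p=mix)
                for c in ctx:
                    rows.append({"sample_id": f"s{i}", "context96": S.CONTEXTS_96[c]})
                    ccfs.append(ccf)
        calls = pd.DataFrame(rows)
        return calls, pd.Series(ccfs, index=calls.index)

    def test_planted_late_enrichment_detected(self, catalog, rng):
        early = 0.1 * catalog.matrix[7] + 0.9 * catalog.matrix[2]
        late = 0.4 * catalog.matrix[7] + 0.6 * catalog.matrix[2]
        calls, ccfs = self._cohort(catalog, rng, 30, early, late)
        res = S.timing_of_signatures(calls, ccfs, catalog)
        assert res.tests.loc["SBS22", "q"] < 0.1
        assert res.tests.loc["SBS22", "mean_late"] > res.tests.loc["SBS22", "mean_early"]

    def test_single_sample_skips_test_with_warning(self, catalog, rng):
        mix = catalog.matrix[2]
        calls, ccfs = self._cohort(catalog, rng, 1, mix, mix)
        with pytest.warns(UserWarning):
            res = S.timing_of_signatures(calls, ccfs, catalog)
        assert res.tests.empty

    def test_min_mutation_rule_excludes_sample(self, catalog, rng):
        mix = catalog.matrix[2]
        calls, ccfs = self._cohort(catalog, rng, 3, mix, mix, n_mut=10)
        with pytest.raises(ValueError):
            S.timing_of_signatures(calls, ccfs, catalog, min_mutations=20)
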