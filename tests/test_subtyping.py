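"""Variable-gene selection, consensus NMF, NTP transfer, gene-set scores."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from hccpipe import subtyping as SB


def block_matrix(rng, n_blocks=3, genes_per_block=80, samples_per_block=20,
                 shift=2.0, baseline=6.0):
    n_genes = n_blocks * genes_per_block
    n_samples = n_blocks * samples_per_block
    labels = np.repeat(np.arange(n_blocks), samples_per_block)
    X = rng.normal(baseline, 1.0, (n_genes, n_samples))
    for b in range(n_blocks):
        X[b * genes_per_block:(b + 1) * genes_per_block, labels == b] += shift
    expr = pd.DataFrame(np.clip(X, 0, None),
                        index=[f"g{i:03d}" for i in range(n_genes)],
                        columns=[f"s{i:02d}" for i in range(n_samples)])
    return expr, labels


class TestVariableGenes:
    def test_low_count_filter(self, rng):
        expr = pd.DataFrame(rng.normal(5, 1, (3, 20)), index=["a", "b", "c"])
        counts = pd.DataFrame(0, index=["a", "b", "c"], columns=expr.columns)
        counts.loc["a", counts.columns[:10]] = 10  # exactly 10 patients
        counts.loc["b", counts.columns[:9]] = 10  # only 9 -> dropped
        counts.loc["c"] = 50
        out = SB.select_variable_genes(expr, n=2, counts=counts)
        assert "b" not in out.index and {"a", "c"} >= set(out.index)

    def test_constant_gene_never_beats_variable(self, rng):
        expr = pd.DataFrame(
            np.vstack([np.full(30, 5.0), rng.normal(5, 1, (4, 30))]),
            index=["const", "v1", "v2", "v3", "v4"],
        )
        out = SB.select_variable_genes(expr, n=4)
        assert "const" not in out.index

    def test_planted_programs_captured(self, small_bundle):
        """MAD selection captures the strongly bimodal planted programs.

        Program genes carry more biological variance than the housekeeping
        background, so a top-k cut the size of the planted program space
        recovers nearly all of them.
        """
        expr = small_bundle.expression
        progs = small_bundle.truth.program_genes
        planted = [g for p, gl in progs.items() if p != "BACKGROUND" for g in gl]
        top = SB.select_variable_genes(expr, n=len(planted))
        captured = len(set(planted) & set(top.index)) / len(planted)
        assert captured >= 0.95

    def test_requesting_too_many_genes(self, rng):
        expr = pd.DataFrame(rng.normal(size=(5, 10)))
        with pytest.raises(ValueError):
            SB.select_variable_genes(expr, n=6)


class TestNMF:
    def test_kl_objective_non_increasing_every_iteration(self, rng):
        V = rng.poisson(5, (30, 15)).astype(float) + 0.1
        for seed in range(3):
            _, _, trace = SB.nmf_brunet(V, 3, np.random.default_rng(seed),
                                        max_iter=120, tol=0.0, track_objective=True)
            diffs = np.diff(trace)
            assert (diffs <= 1e-8).all()

    def test_negative_input_rejected(self, rng):
        with pytest.raises(ValueError):
            SB.nmf_brunet(-np.ones((4, 4)), 2, rng)

    def test_consensus_selects_planted_rank(self, rng):
        expr, labels = block_matrix(rng)
        model = SB.nmf_consensus(expr, ranks=range(2, 7), n_runs=20, seed=1)
        assert model.rank == 3
        assert adjusted_rand_score(labels, model.labels.to_numpy()) >= 0.9

    def test_consensus_matrix_symmetric_unit_diagonal(self, rng):
        expr, _ = block_matrix(rng, n_blocks=2, samples_per_block=10, genes_per_block=40)
        model = SB.nmf_consensus(expr, ranks=[2, 3], n_runs=8, seed=2)
        C = model.consensus.to_numpy()
        assert np.allclose(C, C.T)
        assert np.allclose(np.diag(C), 1.0)
        assert ((model.metrics["cophenetic"] >= -1) & (model.metrics["cophenetic"] <= 1)).all()

    def test_duplicate_samples_get_identical_labels(self, rng):
        expr, _ = block_matrix(rng, n_blocks=2, samples_per_block=8, genes_per_block=40)
        dup = pd.concat([expr, expr.add_suffix("_dup")], axis=1)
        model = SB.nmf_consensus(dup, ranks=[2], n_runs=10, seed=3)
        for s in expr.columns:
            assert model.labels[s] == model.labels[s + "_dup"]

    def test_templates_are_upregulated_block_genes(self, rng):
        expr, labels = block_matrix(rng)
        model = SB.nmf_consensus(expr, ranks=[3], n_runs=10, seed=4)
        for sub, genes in model.templates.items():
            assert 0 < len(genes) <= 100
            blocks = {g[:1] == "g" and int(g[1:]) // 80 for g in genes}
            assert len(blocks) == 1  # each template drawn from one planted block


class TestNTP:
    def _model(self, rng):
        expr, labels = block_matrix(rng)
        model = SB.nmf_consensus(expr, ranks=[3], n_runs=10, seed=5)
        return expr, labels, model

    def test_centroid_plus_noise_assigned(self, rng):
        """Centroid-plus-noise probes embedded in a heterogeneous query
        cohort (NTP standardizes genes across the queried samples) are
        confidently assigned to their subtype."""
        expr, labels, model = self._model(rng)
        centroid = expr.loc[:, labels == 0].mean(axis=1)
        probe = pd.DataFrame({
            f"p{i}": centroid + rng.normal(0, 0.3, len(centroid)) for i in range(5)
        })
        query = pd.concat([expr, probe], axis=1)
        res = SB.ntp_assign(query, model.templates, n_permutations=500, seed=0)
        ref = model.labels[expr.columns[labels == 0][0]]
        probes = res.loc[probe.columns]
        assert (probes["subtype"] == ref).all()
        assert (probes["q"] < 0.1).all()

    def test_pure_noise_goes_ns(self, rng):
        expr, _, model = self._model(rng)
        noise = pd.DataFrame(rng.normal(6, 1, (expr.shape[0], 20)),
                             index=expr.index, columns=[f"n{i}" for i in range(20)])
        res = SB.ntp_assign(noise, model.templates, n_permutations=500, seed=1)
        assert (res["subtype"] == "NS").mean() >= 0.9

    def test_deterministic_and_gene_order_invariant(self, rng):
        expr, labels, model = self._model(rng)
        r1 = SB.ntp_assign(expr, model.templates, n_permutations=200, seed=7)
        r2 = SB.ntp_assign(expr, model.templates, n_permutations=200, seed=7)
        assert r1.equals(r2)
        shuffled = expr.sample(frac=1.0, random_state=0)
        r3 = SB.ntp_assign(shuffled, model.templates, n_permutations=200, seed=7)
        assert (r3["subtype"] == r1["subtype"]).all()

    def test_missing_templates_rejected(self, rng):
        expr, _, model = self._model(rng)
        other = pd.DataFrame(rng.normal(size=(10, 4)), index=[f"zz{i}" for i in range(10)])
        with pytest.raises(ValueError):
            SB.ntp_assign(other, model.templates)


class TestCorrespondence:
    def test_identical_cohorts_map_to_identity(self, rng):
        expr, labels = block_matrix(rng)
        m1 = SB.nmf_consensus(expr, ranks=[3], n_runs=10, seed=8)
        expr2 = expr.add_suffix("_b")
        m2 = SB.SubtypeModel(m1.rank, m1.labels.set_axis(expr2.columns),
                             m1.consensus, m1.templates)
        res = SB.subtype_correspondence(m1, m2, expr, expr2,
                                        n_permutations=200, seed=0)
        matched = res[res["matched"]]
        assert len(matched) == 3
        assert (matched["subtype_a"] == matched["subtype_b"]).all()

    def test_label_permuted_cohort_fails_to_match(self, rng):
        expr, labels = block_matrix(rng)
        m1 = SB.nmf_consensus(expr, ranks=[3], n_runs=10, seed=9)
        noise = pd.DataFrame(rng.normal(6, 1, expr.shape), index=expr.index,
                             columns=[f"n{i}" for i in range(expr.shape[1])])
        m2 = SB.SubtypeModel(3, pd.Series(rng.integers(1, 4, expr.shape[1]),
                                          index=noise.columns),
                             m1.consensus, SB.cohens_d_templates(
                                 noise, pd.Series(rng.integers(1, 4, expr.shape[1]),
                                                  index=noise.columns)))
        res = SB.subtype_correspondence(m1, m2, expr, noise,
                                        n_permutations=200, seed=1)
        assert res["matched"].sum() == 0


class TestGeneSetScore:
    def test_constant_genes_score_zero(self):
        expr = pd.DataFrame(5.0, index=["a", "b", "c"], columns=["s1", "s2", "s3"])
        score = SB.gene_set_score(expr, ["a", "b", "c"])
        assert (score == 0).all()

    def test_planted_program_highest_in_its_subtype(self, small_bundle):
        from scipy.stats import mannwhitneyu
        expr = small_bundle.expression
        progs = small_bundle.truth.program_genes
        labs = small_bundle.truth.samples["subtype"]
        score = SB.gene_set_score(expr, progs["PROLIF"], "prolif")
        prolif_like = labs.isin(["P", "P1", "P2"])
        p = mannwhitneyu(score[prolif_like], score[~prolif_like],
                         alternative="greater").pvalue
        assert p < 0.01

    def test_too_few_members(self, rng):
        expr = pd.DataFrame(rng.normal(size=(5, 4)), index=list("abcde"))
        with pytest.raises(ValueError):
            SB.gene_set_score(expr, ["a", "zz"])
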