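"""End-to-end recovery benchmarks on synthetic cohorts.

Each routine regenerates its inputs from a seed, runs the relevant
pipeline stage, and returns the measured quantity (an RMSE, a power, an
agreement gap, a c-index contrast).  They back both the acceptance test
suite and ``scripts/acceptance.py``; problem sizes are the package's
benchmark defaults and are documented in the methods note.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, mannwhitneyu

from . import ccf as ccf_mod
from . import cnv as cnv_mod
from . import signatures as sig_mod
from . import stats as stats_mod
from . import subtyping as sub_mod
from . import survival as surv_mod
from .pipeline import assemble_features, run_layers
from .simulate import DELETION_ARMS, SimulationConfig, simulate_cohorts


def _spawn(seed: int, k: int) -> int:
    """Derived child seed, kept below 2**31."""
    return int(np.random.default_rng([seed, k]).integers(0, 2**31 - 1))


# ---------------------------------------------------------------- CCF layer

def ccf_recovery(seed: int, n_per_cohort: int = 25, depth_mean: float = 100.0) -> dict:
    """RMSE between estimated and planted clone CCFs over a 50-sample run."""
    bundle = simulate_cohorts(SimulationConfig(
        n_a=n_per_cohort, n_b=n_per_cohort, seed=seed, depth_mean=depth_mean))
    maf = ccf_mod.filter_mutations(bundle.maf)
    errs = []
    for sid, sub in maf.groupby("sample_id"):
        prof = ccf_mod.SampleProfile(sid, float(bundle.truth.samples.loc[sid, "purity"]))
        seg = bundle.segments[bundle.segments["sample_id"] == sid]
        est = ccf_mod.estimate_ccf_table(sub, prof, seg)
        truth = bundle.truth.mutations.iloc[sub.index]
        errs.append(est["ccf"].to_numpy() - truth["true_ccf"].to_numpy())
    e = np.concatenate(errs)
    return {"rmse": float(np.sqrt((e**2).mean())), "n": int(len(e))}


def ccf_grid_oracle_gap(seed: int, n_cases: int = 100) -> dict:
    """Max |Brent - exhaustive 1e-3 grid| over random read-count cases."""
    rng = np.random.default_rng(seed)
    grid = np.linspace(0.0, 1.0, 1001)
    worst = 0.0
    for _ in range(n_cases):
        depth = int(rng.integers(15, 250))
        alt = int(rng.integers(1, depth + 1))
        purity = float(rng.uniform(0.2, 1.0))
        cn = int(rng.integers(1, 6))
        est = ccf_mod.estimate_ccf(alt, depth, purity, cn)
        dev = ccf_mod.binomial_deviance(grid, alt, depth, purity, 2, cn)
        worst = max(worst, abs(est.ccf - grid[np.argmin(dev)]))
    return {"max_abs_gap": float(worst), "n": n_cases}


def subclone_k_recovery(seed: int, n_reps: int = 20, depth: int = 200,
                        purity: float = 0.7, per_clone: int = 100) -> dict:
    """Fraction of replicates where BIC recovers the planted 3-clone model
    (CCFs 1.0 / 0.6 / 0.2) from binomial read counts."""
    hits = 0
    for r in range(n_reps):
        rng = np.random.default_rng(_spawn(seed, r))
        ccfs = np.repeat([1.0, 0.6, 0.2], per_clone)
        vaf = ccf_mod.expected_vaf(ccfs, purity, 2.0, 2.0)
        alt = rng.binomial(depth, vaf)
        est = np.array([
            ccf_mod.estimate_ccf(int(a), depth, purity, 2).ccf for a in alt
        ])
        model = ccf_mod.cluster_subclones(est, seed=r)
        hits += model.n_clusters == 3
    return {"recovery_rate": hits / n_reps, "n": n_reps}


# --------------------------------------------------------- signature layer

def signature_mixture_recovery(seed: int, n_mutations: int = 10_000,
                               w=(0.7, 0.3), idx=(2, 7)) -> dict:
    """L1 exposure error on a two-signature multinomial mixture."""
    catalog = sig_mod.synthetic_catalog()
    rng = np.random.default_rng(seed)
    mix = w[0] * catalog.matrix[idx[0]] + w[1] * catalog.matrix[idx[1]]
    counts = rng.multinomial(n_mutations, mix)
    ev = sig_mod.deconvolute(counts, catalog)
    truth = np.zeros(catalog.k)
    truth[list(idx)] = w
    return {"l1_error": float(np.abs(ev.weights.to_numpy() - truth).sum()),
            "n": n_mutations}


def deconvolution_oracle_gap(seed: int, n_profiles: int = 100) -> dict:
    """Max (solver - NNLS-project oracle) objective gap on random profiles."""
    from scipy.optimize import nnls

    catalog = sig_mod.synthetic_catalog()
    rng = np.random.default_rng(seed)
    worst = -np.inf
    for _ in range(n_profiles):
        x = rng.dirichlet(np.full(96, 0.3))
        ev = sig_mod.deconvolute(x, catalog, min_weight=0.0)
        w, _ = nnls(catalog.matrix.T, x)
        if w.sum() > 1:
            w = w / w.sum()
        ours = ((x - catalog.matrix.T @ ev.weights.to_numpy()) ** 2).sum()
        oracle = ((x - catalog.matrix.T @ w) ** 2).sum()
        worst = max(worst, float(ours - oracle))
    return {"max_objective_gap": worst, "n": n_profiles}


def _timing_cohort(rng, catalog, n_samples, early_mix, late_mix, n_mut=100):
    """Vectorized early/late call table for the paired timing test."""
    n = n_samples * n_mut
    rows = {
        "sample_id": np.repeat([f"s{i}" for i in range(n_samples)], 2 * n_mut),
        "context96": np.empty(2 * n, dtype=object),
    }
    ccf = np.empty(2 * n)
    ctx = np.asarray(sig_mod.CONTEXTS_96, dtype=object)
    e = rng.choice(96, size=n, p=early_mix)
    l = rng.choice(96, size=n, p=late_mix)
    per = np.empty((n_samples, 2 * n_mut), dtype=object)
    per[:, :n_mut] = ctx[e].reshape(n_samples, n_mut)
    per[:, n_mut:] = ctx[l].reshape(n_samples, n_mut)
    rows["context96"] = per.ravel()
    cc = np.empty((n_samples, 2 * n_mut))
    cc[:, :n_mut] = 0.95
    cc[:, n_mut:] = 0.3
    calls = pd.DataFrame(rows)
    return calls, pd.Series(cc.ravel(), index=calls.index)


def timing_test_calibration(seed: int, n_cohorts: int = 200,
                            n_samples: int = 60) -> dict:
    """Fraction of null cohorts (identical early/late mixtures) with any
    signature flagged at BH q < 0.1."""
    catalog = sig_mod.synthetic_catalog()
    false_pos = 0
    for r in range(n_cohorts):
        rng = np.random.default_rng(_spawn(seed, r))
        mix = rng.dirichlet(np.full(catalog.k, 1.0)) @ catalog.matrix
        calls, ccfs = _timing_cohort(rng, catalog, n_samples, mix, mix)
        res = sig_mod.timing_of_signatures(calls, ccfs, catalog)
        false_pos += bool((res.tests["q"] < 0.1).any())
    return {"type_i_rate": false_pos / n_cohorts, "n": n_cohorts}


def timing_test_power(seed: int, n_reps: int = 30, n_samples: int = 60,
                      early_w: float = 0.1, late_w: float = 0.4) -> dict:
    """Power to flag a planted late-enriched signature at q < 0.1."""
    catalog = sig_mod.synthetic_catalog()
    target = "SBS22"
    j = catalog.names.index(target)
    base = catalog.names.index("SBS5")
    hits = 0
    for r in range(n_reps):
        rng = np.random.default_rng(_spawn(seed, 10_000 + r))
        early = early_w * catalog.matrix[j] + (1 - early_w) * catalog.matrix[base]
        late = late_w * catalog.matrix[j] + (1 - late_w) * catalog.matrix[base]
        calls, ccfs = _timing_cohort(rng, catalog, n_samples, early, late)
        res = sig_mod.timing_of_signatures(calls, ccfs, catalog)
        hits += bool(res.tests.loc[target, "q"] < 0.1
                     and res.tests.loc[target, "mean_late"] > res.tests.loc[target, "mean_early"])
    return {"power": hits / n_reps, "n": n_reps}


# --------------------------------------------------------------- CNV layer

def arm_call_accuracy(seed: int, n_per_cohort: int = 30) -> dict:
    """Arm-call agreement with the planted truth on a simulated bundle."""
    bundle = simulate_cohorts(SimulationConfig(n_a=n_per_cohort, n_b=n_per_cohort, seed=seed))
    _, calls = cnv_mod.instability_table(bundle.segments)
    truth = bundle.truth.arm_calls
    acc = (calls.sort_index() == truth.sort_index()).to_numpy().mean()
    return {"accuracy": float(acc), "n": int(truth.size)}


def _arm_matrix(rng, n, del_freq, bg):
    arms = list(cnv_mod.default_arm_table()["arm"])
    mat = {}
    for a in arms:
        if a in DELETION_ARMS:
            hit = rng.random(n) < del_freq
            mat[a] = np.where(hit, "del", "neutral")
        else:
            hit = rng.random(n) < bg
            kind = np.where(rng.random(n) < 0.5, "amp", "del")
            mat[a] = np.where(hit, kind, "neutral")
    return pd.DataFrame(mat)


def arm_frequency_power(seed: int, n_reps: int = 100, n: int = 150,
                        freq_a: float = 0.4, freq_b: float = 0.1,
                        background: float = 0.1) -> dict:
    """Power of the per-arm Fisher/BH comparison to flag the planted
    deletion arm (generated from the arm layer of the cohort model)."""
    hits = 0
    for r in range(n_reps):
        rng = np.random.default_rng(_spawn(seed, 20_000 + r))
        a = _arm_matrix(rng, n, freq_a, background)
        b = _arm_matrix(rng, n, freq_b, background)
        calls = pd.concat([a, b], ignore_index=True)
        calls.index = [f"s{i}" for i in range(2 * n)]
        cohort = pd.Series(["A"] * n + ["B"] * n, index=calls.index)
        res = cnv_mod.compare_arm_frequencies(calls, cohort)
        hits += bool(res.loc[list(DELETION_ARMS), "significant"].all())
    return {"power": hits / n_reps, "n": n_reps}


def scna_score_contrast(seed: int, n_per_cohort: int = 150) -> dict:
    """One-sided rank-sum p for cohort A carrying a higher arm SCNA burden."""
    bundle = simulate_cohorts(SimulationConfig(n_a=n_per_cohort, n_b=n_per_cohort, seed=seed))
    scores, _ = cnv_mod.instability_table(bundle.segments)
    cohort = bundle.truth.samples["cohort"].reindex(scores.index)
    a = scores.loc[cohort == "A", "arm_scna_score"]
    b = scores.loc[cohort == "B", "arm_scna_score"]
    p = mannwhitneyu(a, b, alternative="greater").pvalue
    return {"p_one_sided": float(p), "mean_a": float(a.mean()),
            "mean_b": float(b.mean()), "n": int(len(scores))}


# ------------------------------------------------------- association layer

def fisher_oracle_gap(max_total: int = 30) -> dict:
    """Max |package p - hypergeometric enumeration| over every 2x2 table
    with at most ``max_total`` observations and no zero margin."""
    worst = 0.0
    n_tables = 0
    for n in range(1, max_total + 1):
        for a in range(n + 1):
            for b in range(n - a + 1):
                for c in range(n - a - b + 1):
                    d = n - a - b - c
                    if min(a + b, c + d, a + c, b + d) == 0:
                        continue
                    n_tables += 1
                    p_pkg, _ = stats_mod._fisher_2x2(a, b, c, d)
                    r1, c1 = a + b, a + c
                    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
                    ks = np.arange(lo, hi + 1)
                    pmf = hypergeom.pmf(ks, n, r1, c1)
                    p_obs = hypergeom.pmf(a, n, r1, c1)
                    p_or = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
                    worst = max(worst, abs(p_pkg - min(p_or, 1.0)))
    return {"max_abs_gap": worst, "n": n_tables}


def null_pairwise_fpr(seed: int, n_reps: int = 200, n_samples: int = 100,
                      n_events: int = 8) -> dict:
    """Fraction of independent-event matrices with any pair flagged at
    q < 0.1."""
    hits = 0
    for r in range(n_reps):
        rng = np.random.default_rng(_spawn(seed, 30_000 + r))
        events = pd.DataFrame(
            (rng.random((n_samples, n_events)) < 0.3).astype(int),
            columns=[f"g{i}" for i in range(n_events)],
        )
        res = stats_mod.fisher_pairwise(events)
        hits += bool(res["significant"].any())
    return {"false_positive_rate": hits / n_reps, "n": n_reps}


# ---------------------------------------------------------- subtyping layer

def nmf_block_recovery(seed: int, n_runs: int = 20) -> dict:
    """Rank and label recovery on a 3-block planted matrix (60 samples)."""
    from sklearn.metrics import adjusted_rand_score

    rng = np.random.default_rng(seed)
    labels = np.repeat(np.arange(3), 20)
    X = rng.normal(6.0, 1.0, (240, 60))
    for blk in range(3):
        X[blk * 80:(blk + 1) * 80, labels == blk] += 2.0
    expr = pd.DataFrame(np.clip(X, 0, None),
                        index=[f"g{i}" for i in range(240)],
                        columns=[f"s{i}" for i in range(60)])
    model = sub_mod.nmf_consensus(expr, ranks=range(2, 7), n_runs=n_runs, seed=seed)
    ari = adjusted_rand_score(labels, model.labels.to_numpy())
    return {"rank": model.rank, "ari": float(ari), "n": 60}


def ntp_noise_ns_rate(seed: int, n_noise: int = 20) -> dict:
    """Fraction of pure-noise query samples sent to "NS"."""
    rng = np.random.default_rng(seed)
    labels = np.repeat(np.arange(3), 20)
    X = rng.normal(6.0, 1.0, (240, 60))
    for blk in range(3):
        X[blk * 80:(blk + 1) * 80, labels == blk] += 2.0
    expr = pd.DataFrame(np.clip(X, 0, None),
                        index=[f"g{i}" for i in range(240)],
                        columns=[f"s{i}" for i in range(60)])
    model = sub_mod.nmf_consensus(expr, ranks=[3], n_runs=10, seed=seed)
    noise = pd.DataFrame(rng.normal(6, 1, (240, n_noise)), index=expr.index,
                         columns=[f"n{i}" for i in range(n_noise)])
    res = sub_mod.ntp_assign(noise, model.templates, n_permutations=500, seed=seed)
    return {"ns_rate": float((res["subtype"] == "NS").mean()), "n": n_noise}


def correspondence_topology(seed: int, n_per_cohort: int = 60,
                            n_runs: int = 20) -> dict:
    """Cross-cohort subtype matching on the planted A-has-4 / B-has-3 design.

    Each cohort is fitted at its design rank (4 for A, 3 for B); mutual NTP
    matching should find three shared subtypes and leave the planted P2-like
    subtype A-specific.
    """
    bundle = simulate_cohorts(SimulationConfig(n_a=n_per_cohort, n_b=n_per_cohort, seed=seed))
    models, exprs = {}, {}
    for cohort, rank in (("A", 4), ("B", 3)):
        ids = [s for s in bundle.expression.columns if s.startswith(cohort)]
        expr = bundle.expression[ids]
        sel = sub_mod.select_variable_genes(expr, n=400)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            models[cohort] = sub_mod.nmf_consensus(sel, ranks=[rank], n_runs=n_runs, seed=seed)
        exprs[cohort] = expr
    res = sub_mod.subtype_correspondence(models["A"], models["B"],
                                         exprs["A"], exprs["B"],
                                         n_permutations=300, seed=seed)
    matched = res[res["matched"]]
    a_specific = res[(~res["matched"]) & res["subtype_a"].notna()]
    # is the unmatched A subtype the planted P2-like one?
    truth = bundle.truth.samples["subtype"]
    p2_flag = 0.0
    if len(a_specific) == 1:
        sub = a_specific.iloc[0]["subtype_a"]
        members = models["A"].labels[models["A"].labels == sub].index
        p2_flag = float((truth[members] == "P2").mean())
    return {"n_matched": int(len(matched)),
            "n_a_specific": int(len(a_specific)),
            "a_specific_p2_purity": p2_flag, "n": 2 * n_per_cohort}


# ----------------------------------------------------------- survival layer

def cindex_oracle_gap(seed: int, n_cases: int = 100) -> dict:
    """Max |package c-index - library oracle| on small random datasets."""
    from sksurv.metrics import concordance_index_censored

    rng = np.random.default_rng(seed)
    worst = 0.0
    done = 0
    while done < n_cases:
        n = int(rng.integers(4, 21))
        t = rng.integers(1, 10, n).astype(float)
        e = rng.integers(0, 2, n)
        risk = rng.integers(0, 5, n).astype(float)
        if e.sum() == 0:
            continue
        try:
            ours = surv_mod.concordance_index(risk, t, e)
        except ValueError:
            continue
        ref = concordance_index_censored(e.astype(bool), t, risk)[0]
        worst = max(worst, abs(ours - ref))
        done += 1
    return {"max_abs_gap": float(worst), "n": n_cases}


def _survival_table(rng, n, coef, n_noise):
    X = pd.DataFrame(rng.normal(size=(n, 1 + n_noise)),
                     columns=["signal"] + [f"noise{i}" for i in range(n_noise)])
    eta = coef * X["signal"].to_numpy()
    t = rng.exponential(1.0 / (0.03 * np.exp(eta)))
    c = rng.uniform(0, 100, n)
    X["os_time"] = np.minimum(t, c)
    X["os_event"] = (t <= c).astype(int)
    return X


def noise_model_cindex(seed: int, n_datasets: int = 5, n_splits: int = 10,
                       n: int = 150) -> dict:
    """Mean test c-index of forests trained on pure-noise features.

    Averaged over several independent noise datasets as well as splits: a
    single finite dataset carries chance feature-survival correlations
    that shift its own split distribution coherently, so the expectation
    is only visible across dataset draws.
    """
    vals = []
    for d in range(n_datasets):
        rng = np.random.default_rng(_spawn(seed, 40_000 + d))
        tab = _survival_table(rng, n, 0.0, 9)
        cats = pd.Series("molecular", index=[c for c in tab.columns
                                             if c not in ("os_time", "os_event")])
        ev = surv_mod.evaluate_categories(
            tab, cats, lambda s: surv_mod.RSFLearner(n_estimators=100, seed=s),
            n_splits=n_splits, seed=seed, which=("all",))
        vals.append(ev["cindex"].mean())
    return {"mean_cindex": float(np.mean(vals)), "n": n_datasets * n_splits}


def planted_feature_selection(seed: int, hr: float = 2.5, n: int = 150,
                              n_repeats: int = 50) -> dict:
    """Runs selected / 50 for a planted HR-per-SD prognostic feature."""
    rng = np.random.default_rng(seed)
    tab = _survival_table(rng, n, np.log(hr), 9)
    res = surv_mod.select_features(
        tab, lambda s: surv_mod.RSFLearner(n_estimators=100, seed=s),
        n_repeats=n_repeats, threshold=n_repeats // 2, seed=seed)
    return {"times_selected": int(res.times_selected["signal"]),
            "selected": bool(res.selected["signal"]), "n": n_repeats}


def p2_ablation(seed: int, n_per_cohort: int = 150, n_splits: int = 50,
                n_estimators: int = 100) -> dict:
    """Cohort-A c-index with vs without the planted A-specific subtype.

    Reproduces the ablation design: the full cohort-A feature table is
    evaluated over repeated 75/25 splits, then the P2 patients are removed
    and the evaluation repeated; the drop is tested one-sided.
    """
    bundle = simulate_cohorts(SimulationConfig(n_a=n_per_cohort, n_b=n_per_cohort, seed=seed))
    layers = run_layers(bundle, seed=seed)
    table, cats = assemble_features(bundle, layers,
                                    subtype_labels=bundle.truth.samples["subtype"])
    is_a = bundle.truth.samples["cohort"] == "A"
    a_ids = list(bundle.truth.samples.index[is_a])
    tab_a = table.loc[a_ids].drop(columns=["cohort_a"], errors="ignore")
    tab_a = tab_a.loc[:, tab_a.std(axis=0) > 0]
    not_p2 = [s for s in a_ids if bundle.truth.samples.loc[s, "subtype"] != "P2"]
    tab_ablated = tab_a.loc[not_p2]
    tab_ablated = tab_ablated.loc[:, tab_ablated.std(axis=0) > 0]
    factory = lambda s: surv_mod.RSFLearner(n_estimators=n_estimators, seed=s)
    cats_a = pd.Series("all", index=tab_a.columns)
    full = surv_mod.evaluate_categories(tab_a, cats_a, factory,
                                        n_splits=n_splits, seed=seed, which=("all",))
    cats_ab = pd.Series("all", index=tab_ablated.columns)
    ablated = surv_mod.evaluate_categories(tab_ablated, cats_ab, factory,
                                           n_splits=n_splits, seed=seed, which=("all",))
    a = full["cindex"].to_numpy()
    b = ablated["cindex"].to_numpy()
    p = mannwhitneyu(a, b, alternative="greater").pvalue
    return {"cindex_full": float(a.mean()), "cindex_ablated": float(b.mean()),
            "drop": float(a.mean() - b.mean()), "p_one_sided": float(p),
            "n": n_splits}


def cohort_cindex_contrast(seed: int, table: pd.DataFrame, cats: pd.Series,
                           cohorts: pd.Series, n_splits: int = 50,
                           n_estimators: int = 100) -> dict:
    """All-features c-index distributions per cohort, A as reference."""
    factory = lambda s: surv_mod.RSFLearner(n_estimators=n_estimators, seed=s)
    out = {}
    for label in sorted(cohorts.unique()):
        ids = list(cohorts.index[cohorts == label])
        sub = table.loc[ids].drop(columns=["cohort_a"], errors="ignore")
        sub = sub.loc[:, sub.std(axis=0) > 0]
        c = pd.Series("all", index=[x for x in sub.columns
                                    if x not in ("os_time", "os_event")])
        ev = surv_mod.evaluate_categories(sub, c, factory, n_splits=n_splits,
                                          seed=seed, which=("all",))
        out[label] = ev["cindex"].to_numpy()
    labels = sorted(out)
    p = mannwhitneyu(out[labels[0]], out[labels[1]], alternative="greater").pvalue
    return {f"mean_{labels[0].lower()}": float(out[labels[0]].mean()),
            f"mean_{labels[1].lower()}": float(out[labels[1]].mean()),
            "p_a_greater": float(p), "n": n_splits}
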