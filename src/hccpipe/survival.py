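"""Integrative survival modelling over the 44-feature patient table.

The harness assembles clinical, molecular, driver and ITH features
(7/22/12/3 by default), runs a repeated random-survival-forest feature
selection (50 seeded 75% subsamples; a feature survives a run when its
permutation importance exceeds the best of five injected shadow-noise
copies, and is kept overall when selected in at least 25 runs), evaluates
c-index distributions over 50 seeded 75/25 train/test splits per feature
category and cohort, ranks variable importance by mean VIMP rank, and fits
univariate Cox models for the feature correlation / hazard-ratio network.

The survival learner is a thin contract (fit / predict_risk / vimp); the
default backend is a random survival forest, with a penalized Cox model as
fallback.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from scipy.stats import mannwhitneyu, pearsonr, spearmanr, wilcoxon
from sksurv.ensemble import RandomSurvivalForest
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

FEATURE_CATEGORIES = ("clinical", "molecular", "driver", "ith")


def concordance_index(risk, time, event) -> float:
    """Harrell's c-index.

    Among comparable pairs (the earlier time is an observed event), counts
    the fraction where the higher risk score fails earlier; risk ties score
    0.5.  Raises when no pair is comparable.
    """
    risk = np.asarray(risk, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    n = len(risk)
    num = den = 0.0
    for i in range(n):
        if not event[i]:
            continue
        for j in range(n):
            if j == i:
                continue
            # i is the earlier observed event of the pair; a censored j at
            # the same time is known to survive at least as long
            if time[j] > time[i] or (time[j] == time[i] and not event[j]):
                den += 1
                if risk[i] > risk[j]:
                    num += 1
                elif risk[i] == risk[j]:
                    num += 0.5
    if den == 0:
        raise ValueError("no comparable pairs")
    return num / den


@dataclass
class RSFLearner:
    """Random-survival-forest backend satisfying the learner contract.

    Defaults mirror the tuned forest configuration (1500 trees, node size
    10, 3 candidate features per split); smaller forests are used for quick
    runs via ``n_estimators``.
    """

    n_estimators: int = 1500
    min_samples_leaf: int = 10
    max_features: int | float | str = 3
    seed: int = 0
    model: RandomSurvivalForest | None = None
    columns: list[str] = field(default_factory=list)

    def fit(self, X: pd.DataFrame, time, event) -> "RSFLearner":
        mf = self.max_features
        if isinstance(mf, int):
            mf = min(mf, X.shape[1])
        self.model = RandomSurvivalForest(
            n_estimators=self.n_estimators,
            min_samples_leaf=self.min_samples_leaf,
            max_features=mf,
            random_state=self.seed,
            n_jobs=1,
        )
        self.columns = list(X.columns)
        self.model.fit(X.to_numpy(float), Surv.from_arrays(np.asarray(event, bool), np.asarray(time, float)))
        return self

    def predict_risk(self, X: pd.DataFrame) -> np.ndarray:
        return self.model.predict(X[self.columns].to_numpy(float))

    def vimp(self, X: pd.DataFrame, time, event, rng: np.random.Generator) -> pd.Series:
        """Permutation importance: c-index drop when one feature is shuffled."""
        base = concordance_index(self.predict_risk(X), time, event)
        out = {}
        Xp = X.copy()
        for col in self.columns:
            saved = Xp[col].to_numpy().copy()
            Xp[col] = rng.permutation(saved)
            out[col] = base - concordance_index(self.predict_risk(Xp), time, event)
            Xp[col] = saved
        return pd.Series(out)


@dataclass
class CoxnetLearner:
    """Penalized Cox fallback with coefficient-magnitude importance."""

    l1_ratio: float = 0.5
    seed: int = 0
    model: CoxnetSurvivalAnalysis | None = None
    columns: list[str] = field(default_factory=list)

    def fit(self, X: pd.DataFrame, time, event) -> "CoxnetLearner":
        self.model = CoxnetSurvivalAnalysis(l1_ratio=self.l1_ratio, alpha_min_ratio=0.01)
        self.columns = list(X.columns)
        Xs = (X - X.mean()) / X.std().replace(0, 1.0)
        self._scale = (X.mean(), X.std().replace(0, 1.0))
        self.model.fit(Xs.to_numpy(float), Surv.from_arrays(np.asarray(event, bool), np.asarray(time, float)))
        return self

    def predict_risk(self, X: pd.DataFrame) -> np.ndarray:
        mu, sd = self._scale
        Xs = (X[self.columns] - mu) / sd
        return self.model.predict(Xs.to_numpy(float))

    def vimp(self, X, time, event, rng) -> pd.Series:
        return pd.Series(np.abs(self.model.coef_[:, -1]), index=self.columns)


def build_feature_table(
    clinical: pd.DataFrame,
    molecular: pd.DataFrame,
    driver_events: pd.DataFrame,
    ith: pd.DataFrame,
    signature_exposures: pd.DataFrame | None = None,
    cnv_events: pd.DataFrame | None = None,
    cohort: pd.Series | None = None,
    min_signature_mean: float = 0.05,
    min_cnv_freq: float = 0.40,
    min_driver_mutations: int = 15,
    max_missing: float = 0.20,
) -> tuple[pd.DataFrame, pd.Series]:
    """Assemble the per-patient feature matrix with the inclusion rules.

    Signature exposures enter when their cohort mean proportion is at least
    ``min_signature_mean`` (5%); CNV events when altered in at least
    ``min_cnv_freq`` (40%) of either cohort; drivers with at least
    ``min_driver_mutations`` (15) mutated patients overall.  Categorical
    clinical columns are dummy/ordinal encoded, features missing in more
    than ``max_missing`` of patients are dropped and the rest median
    imputed.  Returns (features, category labels per feature column).
    """
    if not {"os_time", "os_event"} <= set(clinical.columns):
        raise ValueError("clinical table must carry os_time and os_event")
    clin = clinical.set_index("sample_id") if "sample_id" in clinical.columns else clinical.copy()
    idx = clin.index
    parts, cats = [], {}

    cf = pd.DataFrame(index=idx)
    cf["age"] = clin["age"].astype(float)
    cf["sex_male"] = (clin["sex"].astype(str).str.lower().str.startswith("m")).astype(float)
    cf["stage"] = clin["stage"].map({"I": 1, "II": 2, "III": 3, "IV": 4}).astype(float)
    cf["grade"] = clin["grade"].map({"G1": 1, "G2": 2, "G3": 3, "G4": 4}).astype(float)
    cf["hbv"] = (clin["viral_status"] == "HBV").astype(float)
    cf["hcv"] = (clin["viral_status"] == "HCV").astype(float)
    if "cohort" in clin.columns and clin["cohort"].nunique() > 1:
        cf["cohort_a"] = (clin["cohort"] == sorted(clin["cohort"].unique())[0]).astype(float)
    parts.append(cf)
    cats.update({c: "clinical" for c in cf.columns})

    mol = molecular.reindex(idx).astype(float)
    if signature_exposures is not None:
        keep = signature_exposures.mean(axis=0) >= min_signature_mean
        sig = signature_exposures.loc[:, keep].reindex(idx)
        sig.columns = [f"sig_{c}" for c in sig.columns]
        mol = pd.concat([mol, sig], axis=1)
    if cnv_events is not None:
        cnv = cnv_events.reindex(idx).astype(float)
        if cohort is not None and cohort.reindex(idx).nunique() == 2:
            co = cohort.reindex(idx)
            keep_cols = []
            for c in cnv.columns:
                freqs = cnv.groupby(co)[c].mean()
                if (freqs >= min_cnv_freq).any():
                    keep_cols.append(c)
            cnv = cnv[keep_cols]
        else:
            cnv = cnv.loc[:, cnv.mean(axis=0) >= min_cnv_freq]
        cnv.columns = [f"cnv_{c}" for c in cnv.columns]
        mol = pd.concat([mol, cnv], axis=1)
    parts.append(mol)
    cats.update({c: "molecular" for c in mol.columns})

    drv = driver_events.reindex(idx).fillna(0).astype(float)
    drv = drv.loc[:, drv.sum(axis=0) >= min_driver_mutations]
    drv.columns = [f"drv_{c}" for c in drv.columns]
    parts.append(drv)
    cats.update({c: "driver" for c in drv.columns})

    ith_t = ith.reindex(idx).astype(float)
    parts.append(ith_t)
    cats.update({c: "ith" for c in ith_t.columns})

    X = pd.concat(parts, axis=1)
    missing = X.isna().mean(axis=0)
    X = X.loc[:, missing <= max_missing]
    X = X.fillna(X.median(numeric_only=True))
    X = X.loc[:, X.std(axis=0) > 0]  # constant features carry no signal
    X["os_time"] = clin["os_time"].astype(float)
    X["os_event"] = clin["os_event"].astype(int)
    categories = pd.Series({c: cats[c] for c in X.columns if c in cats})
    return X, categories


def _split_xy(table: pd.DataFrame):
    X = table.drop(columns=["os_time", "os_event"])
    return X, table["os_time"].to_numpy(float), table["os_event"].to_numpy(int)


@dataclass
class SelectionResult:
    times_selected: pd.Series
    selected: pd.Series
    n_repeats: int
    threshold: int


def select_features(
    table: pd.DataFrame,
    learner_factory=None,
    n_repeats: int = 50,
    subsample: float = 0.75,
    threshold: int = 25,
    n_shadow: int = 5,
    seed: int = 0,
) -> SelectionResult:
    """Repeated subsample feature selection with a shadow-feature rule.

    Each of ``n_repeats`` runs fits the learner on a ``subsample`` fraction
    of patients augmented with ``n_shadow`` permuted copies of randomly
    chosen real features; a feature is selected in that run when its VIMP
    exceeds the largest shadow VIMP.  Features selected in at least
    ``threshold`` runs pass.
    """
    X, time, event = _split_xy(table)
    if learner_factory is None:
        learner_factory = lambda s: RSFLearner(n_estimators=150, seed=s)
    rng = np.random.default_rng(seed)
    counts = pd.Series(0, index=X.columns, dtype=int)
    n = len(X)
    for _ in range(n_repeats):
        idx = rng.choice(n, size=int(round(subsample * n)), replace=False)
        Xi, ti, ei = X.iloc[idx].copy(), time[idx], event[idx]
        if ei.sum() < 10:
            raise ValueError("subsample holds fewer than 10 events")
        shadows = []
        for s in range(n_shadow):
            src = X.columns[rng.integers(0, X.shape[1])]
            Xi[f"_shadow_{s}"] = rng.permutation(Xi[src].to_numpy())
            shadows.append(f"_shadow_{s}")
        lr = learner_factory(int(rng.integers(0, 2**31 - 1)))
        lr.fit(Xi, ti, ei)
        imp = lr.vimp(Xi, ti, ei, rng)
        cut = imp[shadows].max()
        picked = imp.drop(index=shadows)
        counts[picked[picked > cut].index] += 1
    selected = counts >= threshold
    return SelectionResult(counts, selected, n_repeats, threshold)


def tune_learner(
    table: pd.DataFrame,
    n_iter: int = 100,
    n_folds: int = 5,
    seed: int = 0,
    n_estimators: int = 150,
) -> dict:
    """Random-search hyperparameter tuning with k-fold cross-validated
    c-index; the tuned forest configuration (node size 10, 3 features per
    split) seeds the search space."""
    X, time, event = _split_xy(table)
    rng = np.random.default_rng(seed)
    space = {
        "min_samples_leaf": [5, 10, 15, 20],
        "max_features": [2, 3, 5, "sqrt"],
    }
    folds = np.array_split(rng.permutation(len(X)), n_folds)
    best = ({"min_samples_leaf": 10, "max_features": 3}, -np.inf)
    tried = set()
    for _ in range(n_iter):
        params = {k: v[rng.integers(0, len(v))] for k, v in space.items()}
        key = tuple(sorted(params.items()))
        if key in tried:
            continue
        tried.add(key)
        scores = []
        for f in range(n_folds):
            test = folds[f]
            train = np.concatenate([folds[g] for g in range(n_folds) if g != f])
            if event[test].sum() == 0 or event[train].sum() == 0:
                continue
            lr = RSFLearner(n_estimators=n_estimators, seed=seed, **params)
            lr.fit(X.iloc[train], time[train], event[train])
            scores.append(concordance_index(lr.predict_risk(X.iloc[test]), time[test], event[test]))
        mean = float(np.mean(scores)) if scores else -np.inf
        if mean > best[1]:
            best = (params, mean)
    return {**best[0], "cv_cindex": best[1]}


def evaluate_categories(
    table: pd.DataFrame,
    categories: pd.Series,
    learner_factory=None,
    n_splits: int = 50,
    train_fraction: float = 0.75,
    seed: int = 0,
    which: tuple[str, ...] = ("all",) + FEATURE_CATEGORIES,
) -> pd.DataFrame:
    """c-index distributions over repeated 75/25 splits per feature category.

    Returns a long table (category, split, cindex).  The same split
    sequence is reused across categories so distributions are paired.
    """
    X, time, event = _split_xy(table)
    if learner_factory is None:
        learner_factory = lambda s: RSFLearner(n_estimators=150, seed=s)
    rng = np.random.default_rng(seed)
    col_sets = {}
    for cat in which:
        cols = list(X.columns) if cat == "all" else list(categories[categories == cat].index)
        cols = [c for c in cols if c in X.columns]
        if not cols:
            raise ValueError(f"category {cat!r} has no features")
        col_sets[cat] = cols
    rows = []
    n = len(X)
    for split in range(n_splits):
        perm = rng.permutation(n)
        k = int(round(train_fraction * n))
        train, test = perm[:k], perm[k:]
        if event[train].sum() == 0 or event[test].sum() == 0:
            continue
        lseed = int(rng.integers(0, 2**31 - 1))
        for cat, cols in col_sets.items():
            lr = learner_factory(lseed)
            lr.fit(X.iloc[train][cols], time[train], event[train])
            c = concordance_index(lr.predict_risk(X.iloc[test][cols]), time[test], event[test])
            rows.append({"category": cat, "split": split, "cindex": c})
    return pd.DataFrame(rows)


def compare_cindex_distributions(
    eval_a: pd.DataFrame, eval_b: pd.DataFrame, category: str = "all"
) -> dict:
    """Two-cohort comparison of paired-split c-index distributions
    (cohort A as the reference group)."""
    a = eval_a.loc[eval_a["category"] == category, "cindex"].to_numpy()
    b = eval_b.loc[eval_b["category"] == category, "cindex"].to_numpy()
    u = mannwhitneyu(a, b, alternative="greater")
    return {"mean_a": float(a.mean()), "mean_b": float(b.mean()),
            "p_a_greater": float(u.pvalue)}


def importance_ranking(
    table: pd.DataFrame,
    learner_factory=None,
    n_repeats: int = 50,
    seed: int = 0,
) -> pd.Series:
    """Mean VIMP rank per feature across repeated full-model fits
    (rank 1 = most important)."""
    X, time, event = _split_xy(table)
    if learner_factory is None:
        learner_factory = lambda s: RSFLearner(n_estimators=150, seed=s)
    rng = np.random.default_rng(seed)
    ranks = []
    for _ in range(n_repeats):
        lr = learner_factory(int(rng.integers(0, 2**31 - 1)))
        lr.fit(X, time, event)
        imp = lr.vimp(X, time, event, rng)
        ranks.append(imp.rank(ascending=False))
    return pd.concat(ranks, axis=1).mean(axis=1).sort_values()


def univariate_cox_network(
    table: pd.DataFrame, edge_p: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Univariate Cox HRs per feature plus a feature-correlation edge list.

    Nodes carry the hazard ratio and its p-value (diamond/circle shape by
    HR direction in the downstream plot); edges connect feature pairs whose
    correlation (Spearman numeric/numeric, phi binary/binary, point-
    biserial mixed) has p below ``edge_p``, with width -log10(p).
    Degenerate (constant) features are dropped with a warning and
    non-converging fits flagged rather than fatal.
    """
    X, time, event = _split_xy(table)
    keep = [c for c in X.columns if X[c].nunique() > 1]
    dropped = set(X.columns) - set(keep)
    if dropped:
        warnings.warn(f"dropping constant features: {sorted(dropped)}")
    X = X[keep]
    nodes = []
    for c in keep:
        df = pd.DataFrame({"t": time, "e": event, "x": (X[c] - X[c].mean()) / (X[c].std() or 1.0)})
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph = CoxPHFitter().fit(df, duration_col="t", event_col="e")
            hr = float(np.exp(cph.params_["x"]))
            p = float(cph.summary.loc["x", "p"])
            ok = True
        except Exception:
            hr, p, ok = np.nan, np.nan, False
        nodes.append({"feature": c, "hr": hr, "p": p, "converged": ok,
                      "shape": "diamond" if (ok and hr < 1) else "circle"})
    nodes = pd.DataFrame(nodes).set_index("feature")

    def _is_binary(s: pd.Series) -> bool:
        return set(np.unique(s.dropna())) <= {0.0, 1.0}

    edges = []
    cols = list(X.columns)
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            a, b = X[cols[i]], X[cols[j]]
            if _is_binary(a) == _is_binary(b) and _is_binary(a):
                r, p = pearsonr(a, b)  # phi coefficient
            elif _is_binary(a) != _is_binary(b):
                r, p = pearsonr(a, b)  # point-biserial
            else:
                r, p = spearmanr(a, b)
            if np.isfinite(p) and p < edge_p:
                edges.append({"feature_a": cols[i], "feature_b": cols[j],
                              "r": float(r), "p": float(p),
                              "width": float(-np.log10(max(p, 1e-300)))})
    return nodes, pd.DataFrame(edges, columns=["feature_a", "feature_b", "r", "p", "width"])
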