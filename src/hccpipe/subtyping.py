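"""Transcriptomic subtype discovery and cross-cohort transfer.

Subtypes are found per cohort by consensus non-negative matrix
factorization: KL-divergence multiplicative updates (the Brunet variant)
are run from many random initializations at each candidate rank, samples
are co-clustered by their dominant metagene, and the rank is chosen where
both the cophenetic correlation of the consensus matrix and the mean
silhouette on 1 - consensus sit at (or within 0.02 of) their maxima.
Subtypes transfer to an external cohort by nearest-template prediction:
each sample is correlated against per-subtype template gene sets, with
significance from a seeded gene-label permutation test and a BH cutoff
(q < 0.1) below which samples fall back to "NS".  Cross-cohort subtype
correspondence is scored by mutual template assignment rates with
one-to-one maximum-weight matching.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, fcluster, linkage
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_score

from .stats import bh_adjust


def select_variable_genes(
    expr: pd.DataFrame,
    n: int = 3000,
    counts: pd.DataFrame | None = None,
    min_count: int = 5,
    min_patients: int = 10,
) -> pd.DataFrame:
    """Low-count filter then top-``n`` genes by median absolute deviation.

    When a raw ``counts`` matrix is supplied, genes must reach
    ``min_count`` reads in at least ``min_patients`` patients to survive;
    MAD is then computed on the (normalized) ``expr`` rows and ties broken
    by gene identifier.
    """
    keep = expr
    if counts is not None:
        ok = (counts.ge(min_count).sum(axis=1) >= min_patients)
        keep = expr.loc[[g for g in expr.index if ok.get(g, False)]]
    if n > keep.shape[0]:
        raise ValueError(f"requested {n} genes but only {keep.shape[0]} available")
    med = keep.median(axis=1)
    mad = (keep.sub(med, axis=0)).abs().median(axis=1)
    order = sorted(keep.index, key=lambda g: (-mad[g], g))
    return keep.loc[order[:n]]


def kl_divergence(V: np.ndarray, W: np.ndarray, H: np.ndarray) -> float:
    """Generalized KL divergence D(V || WH)."""
    WH = W @ H
    mask = V > 0
    return float((V[mask] * np.log(V[mask] / WH[mask])).sum() - V.sum() + WH.sum())


def nmf_brunet(
    V: np.ndarray,
    rank: int,
    rng: np.random.Generator,
    max_iter: int = 500,
    tol: float = 1e-5,
    track_objective: bool = False,
):
    """KL multiplicative-update NMF (Brunet).

    Returns (W, H[, objective trace]).  The update rules monotonically
    decrease the KL divergence; the trace allows asserting that per run.
    """
    V = np.asarray(V, dtype=float)
    if (V < 0).any():
        raise ValueError("NMF input must be nonnegative")
    m, n = V.shape
    eps = 1e-12
    W = rng.uniform(eps, 1.0, (m, rank))
    H = rng.uniform(eps, 1.0, (rank, n))
    trace = []
    prev = np.inf
    for it in range(max_iter):
        WH = W @ H + eps
        H *= (W.T @ (V / WH)) / (W.sum(axis=0)[:, None] + eps)
        WH = W @ H + eps
        W *= ((V / WH) @ H.T) / (H.sum(axis=1)[None, :] + eps)
        if track_objective or it % 10 == 9 or it == max_iter - 1:
            obj = kl_divergence(V, W, H + eps)
            if track_objective:
                trace.append(obj)
            if prev - obj < tol * max(abs(prev), 1.0):
                break
            prev = obj
    if track_objective:
        return W, H, trace
    return W, H


@dataclass
class SubtypeModel:
    """Consensus-NMF subtyping of one cohort."""

    rank: int
    labels: pd.Series  # sample -> subtype id (1..k)
    consensus: pd.DataFrame  # samples x samples co-assignment frequency
    templates: dict  # subtype id -> top-100 up-regulated gene list
    metrics: pd.DataFrame = field(default_factory=pd.DataFrame)  # rank-selection curves


def _consensus_for_rank(V, rank, n_runs, rng) -> np.ndarray:
    n = V.shape[1]
    C = np.zeros((n, n))
    for _ in range(n_runs):
        _, H = nmf_brunet(V, rank, rng)
        lab = H.argmax(axis=0)
        C += lab[None, :] == lab[:, None]
    return C / n_runs


def _consensus_scores(C: np.ndarray, k: int) -> tuple[float, float, np.ndarray]:
    """Cophenetic correlation, mean silhouette and labels at cut k."""
    D = 1.0 - C
    np.fill_diagonal(D, 0.0)
    D = (D + D.T) / 2.0
    cond = squareform(D, checks=False)
    Z = linkage(cond, method="average")
    coph = cophenet(Z, cond)[0]
    labels = fcluster(Z, t=k, criterion="maxclust")
    if len(np.unique(labels)) < 2:
        sil = -1.0
    else:
        sil = float(silhouette_score(D, labels, metric="precomputed"))
    return float(coph) if np.isfinite(coph) else 1.0, sil, labels


def cohens_d_templates(
    expr: pd.DataFrame, labels: pd.Series, n_top: int = 100
) -> dict:
    """Per-subtype top-``n_top`` up-regulated genes by one-vs-rest Cohen's d."""
    templates = {}
    X = expr.to_numpy(float)
    for sub in sorted(labels.unique()):
        mask = (labels == sub).to_numpy()
        if mask.sum() == 0 or (~mask).sum() == 0:
            templates[sub] = []
            continue
        a, b = X[:, mask], X[:, ~mask]
        pooled = np.sqrt((a.var(axis=1, ddof=1) * (a.shape[1] - 1)
                          + b.var(axis=1, ddof=1) * (b.shape[1] - 1))
                         / max(a.shape[1] + b.shape[1] - 2, 1))
        d = (a.mean(axis=1) - b.mean(axis=1)) / np.where(pooled > 0, pooled, np.inf)
        up = pd.Series(d, index=expr.index)
        up = up[up > 0].sort_values(ascending=False)
        templates[sub] = list(up.index[:n_top])
    return templates


def nmf_consensus(
    expr: pd.DataFrame,
    ranks: range | list[int] = range(2, 7),
    n_runs: int = 200,
    seed: int = 0,
    tie_window: float = 0.02,
    n_template_genes: int = 100,
) -> SubtypeModel:
    """Consensus NMF subtyping with joint cophenetic/silhouette rank choice.

    For each rank, ``n_runs`` seeded random initializations are clustered
    by dominant metagene into a consensus matrix.  The chosen rank is the
    largest k whose cophenetic correlation and mean silhouette both lie
    within ``tie_window`` of their respective maxima (the two criteria can
    otherwise disagree); both curves are returned in ``metrics``.
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    V = expr.to_numpy(float)
    if (V < 0).any():
        raise ValueError("expression matrix must be nonnegative")
    rng = np.random.default_rng(seed)
    results = {}
    rows = []
    for k in ranks:
        C = _consensus_for_rank(V, k, n_runs, rng)
        coph, sil, labels = _consensus_scores(C, k)
        results[k] = (C, labels)
        rows.append({"rank": k, "cophenetic": coph, "silhouette": sil})
    metrics = pd.DataFrame(rows).set_index("rank")
    best_c = metrics["cophenetic"].max()
    best_s = metrics["silhouette"].max()
    ok = metrics[(metrics["cophenetic"] >= best_c - tie_window)
                 & (metrics["silhouette"] >= best_s - tie_window)]
    chosen = int(ok.index.max()) if len(ok) else int(metrics["silhouette"].idxmax())
    C, labels = results[chosen]
    label_ser = pd.Series(labels, index=expr.columns, name="subtype")
    templates = cohens_d_templates(expr, label_ser, n_template_genes)
    consensus = pd.DataFrame(C, index=expr.columns, columns=expr.columns)
    return SubtypeModel(chosen, label_ser, consensus, templates, metrics)


def ntp_assign(
    expr: pd.DataFrame,
    templates: dict,
    n_permutations: int = 1000,
    seed: int = 0,
    fdr: float = 0.1,
    max_missing: float = 0.5,
) -> pd.DataFrame:
    """Nearest-template prediction with permutation FDR and "NS" fallback.

    Expression rows are standardized across samples; each sample's distance
    to a template is 1 - Pearson correlation between its standardized
    values over the union of template genes and the template's 0/1
    indicator vector.  Null distances come from permuting gene labels
    (``n_permutations`` seeded draws); per-sample p-values are BH adjusted
    and samples with q >= ``fdr`` are assigned "NS".
    """
    names = sorted(templates)
    union = sorted({g for n_ in names for g in templates[n_]})
    present = [g for g in union if g in expr.index]
    if len(union) == 0 or len(present) / len(union) < max_missing:
        raise ValueError("more than half the template genes are missing")
    E = expr.loc[present]
    mu = E.mean(axis=1)
    sd = E.std(axis=1).replace(0, np.nan)
    Z = E.sub(mu, axis=0).div(sd, axis=0).fillna(0.0).to_numpy(float)  # genes x samples
    T = np.stack([np.isin(present, templates[n_]).astype(float) for n_ in names], axis=1)

    def _corr(zmat: np.ndarray) -> np.ndarray:
        # columns of zmat vs columns of T, Pearson over genes
        zc = zmat - zmat.mean(axis=0)
        tc = T - T.mean(axis=0)
        denom = np.sqrt((zc**2).sum(axis=0))[:, None] * np.sqrt((tc**2).sum(axis=0))[None, :]
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(denom > 0, (zc.T @ tc) / denom, 0.0)

    corr = _corr(Z)  # samples x templates
    dist = 1.0 - corr
    best = dist.argmin(axis=1)
    best_dist = dist.min(axis=1)

    rng = np.random.default_rng(seed)
    n_samples = Z.shape[1]
    exceed = np.zeros(n_samples)
    for _ in range(n_permutations):
        perm = rng.permutation(Z.shape[0])
        pd_ = 1.0 - _corr(Z[perm])
        exceed += pd_.min(axis=1) <= best_dist
    pvals = (exceed + 1.0) / (n_permutations + 1.0)
    qvals = bh_adjust(pvals)
    assigned = [names[b] if q < fdr else "NS" for b, q in zip(best, qvals)]
    return pd.DataFrame(
        {"subtype": assigned, "nearest": [names[b] for b in best],
         "distance": best_dist, "p": pvals, "q": qvals},
        index=expr.columns,
    )


def subtype_correspondence(
    model_a: SubtypeModel,
    model_b: SubtypeModel,
    expr_a: pd.DataFrame,
    expr_b: pd.DataFrame,
    match_threshold: float = 0.25,
    **ntp_kwargs,
) -> pd.DataFrame:
    """Mutual nearest-template correspondence between two cohorts' subtypes.

    B samples are assigned to A's templates and vice versa; the
    correspondence score of (a, b) is the geometric mean of the two
    cross-assignment rates.  Pairs are matched one-to-one by maximum-weight
    assignment; rows flag matches above ``match_threshold``, and subtypes
    left unmatched are cohort-specific.
    """
    b_to_a = ntp_assign(expr_b, model_a.templates, **ntp_kwargs)
    a_to_b = ntp_assign(expr_a, model_b.templates, **ntp_kwargs)
    subs_a = sorted(model_a.templates)
    subs_b = sorted(model_b.templates)
    score = pd.DataFrame(0.0, index=subs_a, columns=subs_b)
    for sa in subs_a:
        for sb in subs_b:
            in_b = model_b.labels == sb
            rate_b = float((b_to_a.loc[in_b[in_b].index, "subtype"] == sa).mean()) if in_b.any() else 0.0
            in_a = model_a.labels == sa
            rate_a = float((a_to_b.loc[in_a[in_a].index, "subtype"] == sb).mean()) if in_a.any() else 0.0
            score.loc[sa, sb] = np.sqrt(rate_a * rate_b)
    ri, ci = linear_sum_assignment(-score.to_numpy())
    rows = []
    matched_a, matched_b = set(), set()
    for i, j in zip(ri, ci):
        s = float(score.iloc[i, j])
        if s >= match_threshold:
            rows.append({"subtype_a": subs_a[i], "subtype_b": subs_b[j],
                         "score": s, "matched": True})
            matched_a.add(subs_a[i])
            matched_b.add(subs_b[j])
    for sa in subs_a:
        if sa not in matched_a:
            rows.append({"subtype_a": sa, "subtype_b": None,
                         "score": float(score.loc[sa].max()), "matched": False})
    for sb in subs_b:
        if sb not in matched_b:
            rows.append({"subtype_a": None, "subtype_b": sb,
                         "score": float(score[sb].max()), "matched": False})
    out = pd.DataFrame(rows)
    out.attrs["score_matrix"] = score
    return out


def gene_set_score(expr: pd.DataFrame, genes: list[str], name: str = "set") -> pd.Series:
    """Mean per-gene z-score over the member genes, per sample.

    A rank-free activity proxy: each gene is z-scored across samples
    (constant genes contribute 0) and member z-scores averaged.  Requires
    at least 3 member genes present in the matrix.
    """
    present = [g for g in genes if g in expr.index]
    if len(present) < 3:
        raise ValueError("fewer than 3 member genes present")
    E = expr.loc[present]
    sd = E.std(axis=1)
    z = E.sub(E.mean(axis=1), axis=0).div(sd.replace(0, np.nan), axis=0).fillna(0.0)
    return z.mean(axis=0).rename(name)
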