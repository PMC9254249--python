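"""Cohort-level categorical statistics shared across the pipeline.

Fisher exact tests for driver-frequency comparison and mutual
exclusivity / co-occurrence, Benjamini-Hochberg correction, the
hypermutation and low-frequency cohort filters, and a covariate-adjusted
tumor-mutation-burden comparison.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from itertools import combinations
from scipy.stats import fisher_exact, mannwhitneyu
from statsmodels.stats.multitest import multipletests


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, order-preserving."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any():
        raise ValueError("NaN p-values are not allowed")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def apply_cohort_filters(
    maf: pd.DataFrame,
    clinical: pd.DataFrame,
    hypermutation_cutoff: int = 1000,
    min_gene_freq: float = 0.01,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Standardize a cohort for driver association testing.

    Samples with more than ``hypermutation_cutoff`` coding mutations are
    excluded, a gene x sample binary mutation matrix is built from the
    retained samples, and genes mutated in fewer than ``min_gene_freq`` of
    retained samples are dropped.  Returns (filtered maf, samples x genes
    0/1 event matrix over all clinical samples).
    """
    samples = list(clinical["sample_id"])
    if maf.empty:
        return maf.copy(), pd.DataFrame(index=samples, dtype=int)
    coding = maf[maf["coding"].astype(int) == 1]
    counts = coding.groupby("sample_id").size().reindex(samples, fill_value=0)
    keep_samples = counts[counts <= hypermutation_cutoff].index
    if len(keep_samples) == 0:
        raise ValueError("all samples excluded as hypermutated")
    fmaf = maf[maf["sample_id"].isin(keep_samples)].copy()
    if "gene" not in fmaf.columns:
        return fmaf, pd.DataFrame(index=list(keep_samples), dtype=int)
    genic = fmaf[(fmaf["gene"].notna()) & (fmaf["gene"] != ".") & (fmaf["coding"].astype(int) == 1)]
    events = (
        pd.crosstab(genic["sample_id"], genic["gene"])
        .reindex(index=list(keep_samples), fill_value=0)
        .gt(0)
        .astype(int)
    )
    freq = events.mean(axis=0)
    events = events.loc[:, freq >= min_gene_freq]
    return fmaf, events


def _fisher_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-sided Fisher exact p and odds ratio for table [[a, b], [c, d]].

    Degenerate tables (a zero margin) carry no information and return p=1.
    """
    if min(a + b, c + d, a + c, b + d) == 0:
        if b * c == 0:
            odds = np.inf if a * d > 0 else np.nan
        else:
            odds = a * d / (b * c)
        return 1.0, odds
    odds, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(p), float(odds)


def fisher_pairwise(events: pd.DataFrame, fdr: float = 0.1) -> pd.DataFrame:
    """Mutual exclusivity / co-occurrence over all event pairs.

    A single two-sided Fisher exact test per pair; direction is read off the
    odds ratio (>1 co-occurring, <1 mutually exclusive) -- the two tails of
    the test.  BH correction over all pairs, significance at q < ``fdr``.
    """
    cols = list(events.columns)
    if len(cols) < 2:
        raise ValueError("need at least 2 events")
    X = events.to_numpy(int)
    rows = []
    for i, j in combinations(range(len(cols)), 2):
        x, y = X[:, i], X[:, j]
        a = int(((x == 1) & (y == 1)).sum())
        b = int(((x == 1) & (y == 0)).sum())
        c = int(((x == 0) & (y == 1)).sum())
        d = int(((x == 0) & (y == 0)).sum())
        p, odds = _fisher_2x2(a, b, c, d)
        rows.append(
            {
                "event_a": cols[i],
                "event_b": cols[j],
                "odds_ratio": odds,
                "p": p,
                "direction": "co-occur" if odds > 1 else "exclusive",
            }
        )
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = out["q"] < fdr
    return out


def compare_event_frequencies(
    events: pd.DataFrame, cohort: pd.Series, fdr: float = 0.1
) -> pd.DataFrame:
    """Per-event two-cohort frequency comparison by Fisher exact + BH.

    ``cohort`` maps sample -> label (exactly two labels).  Direction labels
    which cohort is enriched; significance at q < ``fdr``.
    """
    cohort = cohort.reindex(events.index)
    labels = sorted(cohort.dropna().unique())
    if len(labels) != 2:
        raise ValueError("exactly two cohorts required")
    in_a = (cohort == labels[0]).to_numpy()
    rows = []
    for name in events.columns:
        x = events[name].to_numpy(int)
        a = int(x[in_a].sum())
        b = int(in_a.sum() - a)
        c = int(x[~in_a].sum())
        d = int((~in_a).sum() - c)
        p, odds = _fisher_2x2(a, b, c, d)
        fa = a / max(a + b, 1)
        fb = c / max(c + d, 1)
        rows.append(
            {
                "event": name,
                "freq_a": fa,
                "freq_b": fb,
                "odds_ratio": odds,
                "p": p,
                "direction": f"enriched-{labels[0]}" if fa >= fb else f"enriched-{labels[1]}",
            }
        )
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = out["q"] < fdr
    return out


def adjusted_tmb_comparison(
    tmb: pd.Series,
    cohort: pd.Series,
    covariates: pd.DataFrame | None = None,
) -> dict:
    """TMB difference between cohorts, with and without covariate adjustment.

    Fits OLS of log10(TMB + 1) on a cohort indicator plus covariates
    (categorical covariates are dummy-coded) and reports the cohort
    coefficient with its CI and p-value, alongside the unadjusted two-sided
    Wilcoxon rank-sum test.
    """
    labels = sorted(cohort.dropna().unique())
    if len(labels) != 2:
        raise ValueError("exactly two cohorts required")
    y = np.log10(tmb.astype(float) + 1.0)
    ind = (cohort == labels[0]).astype(float).rename("cohort_a")
    X = pd.DataFrame({"cohort_a": ind})
    if covariates is not None:
        X = pd.concat([X, pd.get_dummies(covariates, drop_first=True, dtype=float)], axis=1)
    X = sm.add_constant(X.astype(float))
    fit = sm.OLS(y, X).fit()
    ci = fit.conf_int().loc["cohort_a"]
    a = tmb[cohort == labels[0]]
    b = tmb[cohort == labels[1]]
    u = mannwhitneyu(a, b, alternative="two-sided")
    return {
        "reference": labels[0],
        "coef": float(fit.params["cohort_a"]),
        "ci_low": float(ci[0]),
        "ci_high": float(ci[1]),
        "p_adjusted_model": float(fit.pvalues["cohort_a"]),
        "p_wilcoxon": float(u.pvalue),
        "condition_number": float(np.linalg.cond(X.to_numpy(float))),
    }
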