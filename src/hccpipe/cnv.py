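"""Genome instability scoring from integer copy-number segments.

The genome instability index (GII) is the fraction of the covered genome
whose integer copy number differs from the sample's (length-weighted)
median ploidy.  Arm-level calls compare each arm's copy state against the
rounded median ploidy, the arm SCNA score counts altered arms, and cohort
arm frequencies are compared with per-arm Fisher exact tests under BH
correction.  Coordinates are 1-based inclusive (SEG convention).

A bundled miniature genome of 22 named arms over 11 chromosomes (3 Mb
total, a desk-scale stand-in for the 3 Gb genome) backs the synthetic
cohorts; real cytoband-derived arm tables load from TSV.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .stats import _fisher_2x2, bh_adjust

# (chrom, arm, length in bp) -- lengths loosely proportional to the real
# chromosomes they are named after, summing to ~3 Mb.
_MINI_ARMS = [
    ("chr1", "p", 125_000), ("chr1", "q", 125_000),
    ("chr2", "p", 95_000), ("chr2", "q", 150_000),
    ("chr4", "p", 50_000), ("chr4", "q", 140_000),
    ("chr5", "p", 48_000), ("chr5", "q", 133_000),
    ("chr6", "p", 60_000), ("chr6", "q", 110_000),
    ("chr8", "p", 45_000), ("chr8", "q", 100_000),
    ("chr11", "p", 53_000), ("chr11", "q", 82_000),
    ("chr13", "p", 18_000), ("chr13", "q", 98_000),
    ("chr16", "p", 37_000), ("chr16", "q", 55_000),
    ("chr17", "p", 25_000), ("chr17", "q", 58_000),
    ("chr20", "p", 28_000), ("chr20", "q", 35_000),
]


def default_arm_table() -> pd.DataFrame:
    """The bundled miniature-genome arm table (arm, chrom, start, end)."""
    rows = []
    offset: dict[str, int] = {}
    for chrom, arm, length in _MINI_ARMS:
        start = offset.get(chrom, 0) + 1
        end = start + length - 1
        offset[chrom] = end
        rows.append({"arm": f"{chrom}{arm}", "chrom": chrom, "start": start, "end": end})
    return pd.DataFrame(rows)


def read_arm_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = {"arm", "chrom", "start", "end"}
    if not need <= set(df.columns):
        raise ValueError(f"arm table needs columns {sorted(need)}")
    return df


def _weighted_median_cn(cn: np.ndarray, bp: np.ndarray) -> float:
    """bp-length-weighted median integer copy number, ties broken toward 2."""
    order = np.argsort(cn)
    cn, bp = cn[order], bp[order].astype(float)
    cum = np.cumsum(bp)
    half = cum[-1] / 2.0
    i = int(np.searchsorted(cum, half))
    if np.isclose(cum[i], half) and i + 1 < len(cn) and cn[i] != cn[i + 1]:
        lo, hi = cn[i], cn[i + 1]
        return float(lo if abs(lo - 2) <= abs(hi - 2) else hi)
    return float(cn[i])


def genome_instability_index(segments: pd.DataFrame) -> float:
    """Fraction of covered bp at an integer CN different from the median
    ploidy (whole-genome doubling therefore scores 0)."""
    if segments.empty:
        raise ValueError("no segments")
    bp = (segments["end"] - segments["start"] + 1).to_numpy(float)
    if bp.sum() <= 0:
        raise ValueError("segments cover no bases")
    cn = segments["integer_cn"].to_numpy(float)
    med = _weighted_median_cn(cn, bp)
    return float(bp[cn != med].sum() / bp.sum())


def arm_calls(
    segments: pd.DataFrame,
    arms: pd.DataFrame | None = None,
    ploidy: float | None = None,
    min_coverage: float = 0.5,
) -> pd.Series:
    """Per-arm alteration calls for one sample.

    An arm is called ``amp`` when segments at CN >= ploidy+1 cover at least
    ``min_coverage`` of its length, ``del`` when CN <= ploidy-1 does, and
    ``neutral`` otherwise.  ``ploidy`` defaults to the sample's rounded
    bp-weighted median CN.
    """
    if arms is None:
        arms = default_arm_table()
    if ploidy is None:
        bp = (segments["end"] - segments["start"] + 1).to_numpy(float)
        ploidy = _weighted_median_cn(segments["integer_cn"].to_numpy(float), bp)
    base = int(round(ploidy))
    calls = {}
    for _, arm in arms.iterrows():
        seg = segments[
            (segments["chrom"] == arm["chrom"])
            & (segments["end"] >= arm["start"])
            & (segments["start"] <= arm["end"])
        ]
        if seg.empty:
            warnings.warn(f"arm {arm['arm']} has no overlapping segments; neutral")
            calls[arm["arm"]] = "neutral"
            continue
        ov = (
            np.minimum(seg["end"], arm["end"]) - np.maximum(seg["start"], arm["start"]) + 1
        ).to_numpy(float)
        cn = seg["integer_cn"].to_numpy(float)
        arm_len = arm["end"] - arm["start"] + 1
        amp_frac = ov[cn >= base + 1].sum() / arm_len
        del_frac = ov[cn <= base - 1].sum() / arm_len
        if amp_frac >= min_coverage and amp_frac >= del_frac:
            calls[arm["arm"]] = "amp"
        elif del_frac >= min_coverage:
            calls[arm["arm"]] = "del"
        else:
            calls[arm["arm"]] = "neutral"
    return pd.Series(calls, name="call")


def arm_scna_score(calls: pd.Series, weight_magnitude: bool = False,
                   deviations: pd.Series | None = None) -> dict:
    """Arm SCNA burden: the count of non-neutral arms, amp/del split.

    ``weight_magnitude`` switches to the sum of |CN deviation| over altered
    arms (requires ``deviations``), an optional variant for score flavors
    that also weight alteration size.
    """
    n_amp = int((calls == "amp").sum())
    n_del = int((calls == "del").sum())
    if weight_magnitude:
        if deviations is None:
            raise ValueError("magnitude weighting needs per-arm deviations")
        score = float(deviations[calls != "neutral"].abs().sum())
    else:
        score = float(n_amp + n_del)
    return {"score": score, "n_amp": n_amp, "n_del": n_del}


def instability_table(
    segments: pd.DataFrame, arms: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample GII + arm SCNA scores and the samples x arms call matrix."""
    if arms is None:
        arms = default_arm_table()
    rows, call_rows = [], {}
    for sid, seg in segments.groupby("sample_id"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            calls = arm_calls(seg, arms)
        sc = arm_scna_score(calls)
        rows.append({
            "sample_id": sid, "gii": genome_instability_index(seg),
            "arm_scna_score": sc["score"], "n_amp": sc["n_amp"], "n_del": sc["n_del"],
        })
        call_rows[sid] = calls
    scores = pd.DataFrame(rows).set_index("sample_id")
    call_matrix = pd.DataFrame(call_rows).T
    call_matrix.index.name = "sample_id"
    return scores, call_matrix


def compare_arm_frequencies(
    call_matrix: pd.DataFrame, cohort: pd.Series, fdr: float = 0.1
) -> pd.DataFrame:
    """Per-arm altered-vs-not x cohort Fisher exact tests with BH."""
    cohort = cohort.reindex(call_matrix.index)
    labels = sorted(cohort.dropna().unique())
    if len(labels) != 2:
        raise ValueError("exactly two cohorts required")
    in_a = (cohort == labels[0]).to_numpy()
    rows = []
    for arm in call_matrix.columns:
        altered = (call_matrix[arm] != "neutral").to_numpy()
        a = int(altered[in_a].sum())
        b = int(in_a.sum() - a)
        c = int(altered[~in_a].sum())
        d = int((~in_a).sum() - c)
        p, odds = _fisher_2x2(a, b, c, d)
        rows.append({
            "arm": arm,
            "freq_a": a / max(a + b, 1),
            "freq_b": c / max(c + d, 1),
            "odds_ratio": odds,
            "p": p,
        })
    out = pd.DataFrame(rows).set_index("arm")
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = out["q"] < fdr
    return out


def arm_mean_cn(segments: pd.DataFrame, arms: pd.DataFrame | None = None) -> pd.DataFrame:
    """samples x arms bp-weighted mean integer copy number."""
    if arms is None:
        arms = default_arm_table()
    rows = {}
    for sid, seg in segments.groupby("sample_id"):
        vals = {}
        for _, arm in arms.iterrows():
            sub = seg[
                (seg["chrom"] == arm["chrom"])
                & (seg["end"] >= arm["start"])
                & (seg["start"] <= arm["end"])
            ]
            if sub.empty:
                vals[arm["arm"]] = np.nan
                continue
            ov = (
                np.minimum(sub["end"], arm["end"]) - np.maximum(sub["start"], arm["start"]) + 1
            ).to_numpy(float)
            vals[arm["arm"]] = float((sub["integer_cn"].to_numpy(float) * ov).sum() / ov.sum())
        rows[sid] = vals
    out = pd.DataFrame(rows).T
    out.index.name = "sample_id"
    return out


def cnv_expression_correlation(
    arm_cn: pd.DataFrame, expression: pd.DataFrame, fdr: float = 0.1
) -> pd.DataFrame:
    """Spearman correlation of per-arm mean CN with every gene's expression.

    ``expression`` is genes x samples; returns a long table (arm, gene, rho,
    p, q, significant) for the cis/trans correlation map.  Constant
    expression rows are skipped.
    """
    common = [s for s in arm_cn.index if s in expression.columns]
    if len(common) < 3:
        raise ValueError("need >= 3 matched samples")
    E = expression[common]
    E = E.loc[E.std(axis=1) > 0]
    rows = []
    for arm in arm_cn.columns:
        x = arm_cn.loc[common, arm].to_numpy(float)
        if np.ptp(x[~np.isnan(x)]) == 0:
            continue
        rho, p = spearmanr(x, E.to_numpy(float).T, nan_policy="omit")
        rho = np.atleast_2d(rho)[0, 1:]
        p = np.atleast_2d(p)[0, 1:]
        for g, r_, p_ in zip(E.index, rho, p):
            rows.append({"arm": arm, "gene": g, "rho": float(r_), "p": float(p_)})
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].fillna(1.0).to_numpy())
    out["significant"] = out["q"] < fdr
    return out
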