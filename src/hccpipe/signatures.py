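"""Single-base-substitution (SBS) signature deconvolution and grouping.

Per-sample 96-context mutation profiles are expressed as nonnegative
mixtures of a fixed signature catalog (the liver-cancer relevant subset of
the COSMIC SBS catalog, or any user-supplied catalog in the COSMIC TSV
layout).  Exposures are estimated by constrained least squares on the
normalized profile, signatures with negligible cohort contribution are
dropped by a mean>2% / max>=20% retention rule and the fit repeated, and
patients are grouped by Ward clustering of their exposure vectors.
Early (clonal) and late (subclonal) mutation subsets can be deconvoluted
separately and compared per signature with a paired Wilcoxon signed-rank
test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import minimize, nnls
from scipy.stats import wilcoxon

from .stats import bh_adjust

# Canonical SBS-96 category order: substitution-major (C>A, C>G, C>T, T>A,
# T>C, T>G), then 5' and 3' flanking base lexicographically -- the COSMIC
# column convention, written here as e.g. "A[C>A]A".
_SUBS = ["C>A", "C>G", "C>T", "T>A", "T>C", "T>G"]
_BASES = ["A", "C", "G", "T"]
CONTEXTS_96 = [
    f"{five}[{sub}]{three}" for sub in _SUBS for five in _BASES for three in _BASES
]
_CONTEXT_INDEX = {c: i for i, c in enumerate(CONTEXTS_96)}

# Liver-cancer associated signature labels carried by the bundled synthetic
# catalog (clock-like SBS1/SBS5, smoking SBS4, MSI SBS6, liver-associated
# SBS12/SBS16, ROS SBS18, aristolochic acid SBS22, aflatoxin SBS24, SBS29).
DEFAULT_SIGNATURE_NAMES = [
    "SBS1", "SBS4", "SBS5", "SBS6", "SBS12",
    "SBS16", "SBS18", "SBS22", "SBS24", "SBS29",
]


@dataclass
class SignatureCatalog:
    """K reference signatures over the 96 trinucleotide-substitution contexts.

    ``matrix`` is K x 96, rows nonnegative and summing to 1, columns in the
    canonical :data:`CONTEXTS_96` order.
    """

    names: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.names), 96):
            raise ValueError("catalog matrix must be K x 96")
        if (self.matrix < 0).any():
            raise ValueError("catalog entries must be nonnegative")
        rows = self.matrix.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-8):
            raise ValueError("catalog rows must sum to 1")

    @property
    def k(self) -> int:
        return len(self.names)

    def subset(self, names: list[str]) -> "SignatureCatalog":
        idx = [self.names.index(n) for n in names]
        return SignatureCatalog(list(names), self.matrix[idx])

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.matrix, index=self.names, columns=CONTEXTS_96)
        df.to_csv(path, sep="\t", index_label="signature")

    @classmethod
    def from_tsv(cls, path) -> "SignatureCatalog":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df = df[CONTEXTS_96]  # enforce canonical column order
        return cls(list(df.index), df.to_numpy(float))


def synthetic_catalog(names: list[str] | None = None, seed: int = 1729) -> SignatureCatalog:
    """Bundled synthetic stand-in catalog of 10 liver-cancer signatures.

    The rows are synthetic: mutually distinct sparse profiles generated from
    a fixed seed and labelled with the field's signature names, not
    redistributed COSMIC data.  Real COSMIC v3.x TSVs load through
    :meth:`SignatureCatalog.from_tsv` and are preferred when available.
    """
    names = list(names or DEFAULT_SIGNATURE_NAMES)
    rng = np.random.default_rng(seed)
    rows = rng.dirichlet(np.full(96, 0.08), size=len(names))
    # guard against accidental near-duplicates from the sparse draw
    rows += 1e-6
    rows /= rows.sum(axis=1, keepdims=True)
    return SignatureCatalog(names, rows)


def count_contexts(calls: pd.DataFrame, samples: list[str] | None = None) -> pd.DataFrame:
    """Tabulate per-sample SBS-96 context counts.

    Returns a samples x 96 integer DataFrame whose row sums equal each
    sample's mutation count.  Unknown context labels raise.
    """
    bad = set(calls["context96"]) - set(CONTEXTS_96)
    if bad:
        raise ValueError(f"unknown context96 labels: {sorted(bad)[:5]}")
    if samples is None:
        samples = list(pd.unique(calls["sample_id"]))
    tab = pd.crosstab(calls["sample_id"], calls["context96"])
    tab = tab.reindex(index=samples, columns=CONTEXTS_96, fill_value=0)
    return tab.astype(int)


@dataclass
class ExposureVector:
    """Nonnegative per-sample signature weights with sum <= 1."""

    sample_id: str
    weights: pd.Series
    residual: float = 0.0

    def __post_init__(self) -> None:
        w = self.weights.to_numpy(float)
        if (w < -1e-12).any():
            raise ValueError("negative exposure weight")
        if w.sum() > 1 + 1e-8:
            raise ValueError("exposure weights sum above 1")


def _solve_simplex_lsq(x: np.ndarray, S: np.ndarray) -> np.ndarray:
    """argmin_w ||x - S.T w||^2 subject to w >= 0, sum(w) <= 1.

    NNLS solves the relaxed problem; when its solution is infeasible the
    optimum lies on the sum(w)=1 face and is polished with SLSQP.
    """
    w, _ = nnls(S.T, x)
    if w.sum() <= 1 + 1e-12:
        return w
    w0 = w / w.sum()
    res = minimize(
        lambda v: float(((x - S.T @ v) ** 2).sum()),
        w0,
        jac=lambda v: 2.0 * (S @ (S.T @ v) - S @ x),
        bounds=[(0.0, 1.0)] * len(w0),
        constraints=[{"type": "ineq", "fun": lambda v: 1.0 - v.sum()}],
        method="SLSQP",
        options={"maxiter": 200, "ftol": 1e-14},
    )
    return np.clip(res.x, 0.0, None)


def deconvolute(
    profile: np.ndarray | pd.Series,
    catalog: SignatureCatalog,
    min_weight: float = 0.06,
    sample_id: str = "",
) -> ExposureVector:
    """Deconvolute one 96-context profile into catalog exposures.

    The profile is normalized to proportions and fit by nonnegative least
    squares under the simplex constraint sum(w) <= 1.  Weights below
    ``min_weight`` (the conventional 6% cutoff) are zeroed and the remainder
    rescaled to the pre-zeroing total; ``residual`` is the squared-error
    objective at the returned weights.
    """
    x = np.asarray(profile, dtype=float).ravel()
    if x.shape != (96,):
        raise ValueError("profile must have 96 context entries")
    total = x.sum()
    if total <= 0:
        raise ValueError("cannot deconvolute a zero-count profile")
    x = x / total
    w = _solve_simplex_lsq(x, catalog.matrix)
    if min_weight > 0:
        kept = w >= min_weight
        pre = w.sum()
        w = np.where(kept, w, 0.0)
        if w.sum() > 0:
            w *= pre / w.sum()
    residual = float(((x - catalog.matrix.T @ w) ** 2).sum())
    return ExposureVector(sample_id, pd.Series(w, index=catalog.names), residual)


def deconvolute_cohort(
    counts: pd.DataFrame, catalog: SignatureCatalog, min_weight: float = 0.06
) -> pd.DataFrame:
    """Per-sample exposures for a samples x 96 count table (rows with zero
    mutations get all-zero weights)."""
    rows = {}
    for sid, row in counts.iterrows():
        if row.sum() == 0:
            rows[sid] = pd.Series(0.0, index=catalog.names)
        else:
            rows[sid] = deconvolute(row.to_numpy(), catalog, min_weight, str(sid)).weights
    return pd.DataFrame(rows).T.reindex(counts.index)


def iterative_retention(
    counts: pd.DataFrame,
    catalog: SignatureCatalog,
    mean_cut: float = 0.02,
    max_cut: float = 0.20,
    min_weight: float = 0.06,
) -> tuple[SignatureCatalog, pd.DataFrame]:
    """Drop cohort-negligible signatures and refit once.

    A signature is retained when its cohort mean exposure exceeds
    ``mean_cut`` (2%) or its maximum exposure in any sample reaches
    ``max_cut`` (20%); deconvolution is then repeated against the reduced
    catalog exactly once.
    """
    if counts.shape[0] < 2:
        raise ValueError("retention rule needs at least 2 samples")
    exposures = deconvolute_cohort(counts, catalog, min_weight)
    keep = (exposures.mean(axis=0) > mean_cut) | (exposures.max(axis=0) >= max_cut)
    kept = [n for n in catalog.names if keep[n]]
    if not kept:
        raise ValueError("retention rule dropped every signature")
    reduced = catalog.subset(kept)
    refit = deconvolute_cohort(counts, reduced, min_weight)
    return reduced, refit


def signature_groups(exposures: pd.DataFrame, k: int = 5) -> pd.Series:
    """Ward-linkage hierarchical clustering of exposure vectors into k
    signature groups (labels "SG1".."SGk", ordered by cluster mean TMB-free
    first-appearance).

    Five groups (SG1-SG5), the convention in liver-cancer signature
    analyses, is the default ``k``.
    """
    if k < 1 or k > exposures.shape[0]:
        raise ValueError("k must be in [1, n_samples]")
    Z = linkage(exposures.to_numpy(float), method="ward", metric="euclidean")
    raw = fcluster(Z, t=k, criterion="maxclust")
    # relabel deterministically by first appearance
    order: dict[int, int] = {}
    labels = []
    for c in raw:
        if c not in order:
            order[c] = len(order) + 1
        labels.append(f"SG{order[c]}")
    return pd.Series(labels, index=exposures.index, name="signature_group")


@dataclass
class SignatureTimingResult:
    early: pd.DataFrame
    late: pd.DataFrame
    tests: pd.DataFrame = field(default_factory=pd.DataFrame)


def timing_of_signatures(
    calls: pd.DataFrame,
    ccf: pd.Series,
    catalog: SignatureCatalog,
    min_mutations: int = 20,
    early_threshold: float = 0.8,
    min_weight: float = 0.06,
) -> SignatureTimingResult:
    """Separate early/late deconvolution with a paired signed-rank test.

    Mutations with CCF >= ``early_threshold`` are early (clonal), the rest
    late.  Samples contribute only when both subsets hold at least
    ``min_mutations`` mutations (bounds the variance of either fit).  Per
    signature, a two-sided paired Wilcoxon signed-rank test compares early
    vs late exposures across samples; p-values are BH adjusted.
    """
    ccf = ccf.reindex(calls.index)
    early_calls = calls[ccf >= early_threshold]
    late_calls = calls[ccf < early_threshold]
    samples = list(pd.unique(calls["sample_id"]))
    ec = count_contexts(early_calls, samples)
    lc = count_contexts(late_calls, samples)
    ok = (ec.sum(axis=1) >= min_mutations) & (lc.sum(axis=1) >= min_mutations)
    use = [s for s in samples if ok[s]]
    if not use:
        raise ValueError("no sample passes the minimum early/late mutation rule")
    early = deconvolute_cohort(ec.loc[use], catalog, min_weight)
    late = deconvolute_cohort(lc.loc[use], catalog, min_weight)
    if len(use) < 2:
        warnings.warn("fewer than 2 eligible samples; paired test skipped")
        return SignatureTimingResult(early, late)
    rows = []
    for name in catalog.names:
        d = late[name] - early[name]
        if np.allclose(d, 0.0):
            p = 1.0
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                p = float(wilcoxon(early[name], late[name], zero_method="wilcox").pvalue)
        rows.append({"signature": name, "mean_early": float(early[name].mean()),
                     "mean_late": float(late[name].mean()), "p": p})
    tests = pd.DataFrame(rows).set_index("signature")
    tests["q"] = bh_adjust(tests["p"].to_numpy())
    return SignatureTimingResult(early, late, tests)
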