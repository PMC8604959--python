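"""Count-matrix statistics shared by the RNA-seq and ATAC-seq analyses.

CPM/TPM/FPKM transforms, TMM and background-bin composition normalization,
median-CPM low-signal filtering, a negative-binomial exact differential
test with moment-estimated common dispersion, and the six-cluster
expression-trajectory assignment.

Counts are pandas DataFrames with feature row ids and sample column ids.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.special import logsumexp
from statsmodels.stats.multitest import multipletests

__all__ = [
    "cpm",
    "tpm",
    "fpkm",
    "NormFactors",
    "tmm_factors",
    "background_bin_factors",
    "filter_by_median_cpm",
    "DifferentialResult",
    "differential_test",
    "ExpressionClusters",
    "cluster_de_genes",
    "bh_fdr",
]


def _lib_sizes(counts: pd.DataFrame, lib_sizes: pd.Series | None) -> pd.Series:
    if lib_sizes is None:
        lib_sizes = counts.sum(axis=0)
    lib_sizes = pd.Series(lib_sizes, index=counts.columns).astype(float)
    if (lib_sizes <= 0).any():
        bad = lib_sizes.index[lib_sizes <= 0].tolist()
        raise ValueError(f"non-positive library size for samples: {bad}")
    return lib_sizes


def cpm(counts: pd.DataFrame, lib_sizes: pd.Series | None = None) -> pd.DataFrame:
    """Counts per million mapped reads: 1e6 * c / N."""
    N = _lib_sizes(counts, lib_sizes)
    return counts.astype(float).div(N, axis=1) * 1e6


def tpm(counts: pd.DataFrame, lengths_bp: pd.Series) -> pd.DataFrame:
    """Transcripts per million: length-normalized rates rescaled to 1e6 per column."""
    lengths_kb = pd.Series(lengths_bp, index=counts.index).astype(float) / 1e3
    if (lengths_kb <= 0).any():
        raise ValueError("feature lengths must be positive")
    rate = counts.astype(float).div(lengths_kb, axis=0)
    colsum = rate.sum(axis=0)
    if (colsum <= 0).any():
        raise ValueError("all-zero sample column; TPM undefined")
    return rate.div(colsum, axis=1) * 1e6


def fpkm(
    counts: pd.DataFrame,
    lengths_bp: pd.Series,
    lib_sizes: pd.Series | None = None,
) -> pd.DataFrame:
    """Fragments per kilobase per million mapped reads: c / (L_kb * N_millions)."""
    lengths_kb = pd.Series(lengths_bp, index=counts.index).astype(float) / 1e3
    if (lengths_kb <= 0).any():
        raise ValueError("feature lengths must be positive")
    N = _lib_sizes(counts, lib_sizes)
    return counts.astype(float).div(lengths_kb, axis=0).div(N / 1e6, axis=1)


@dataclass
class NormFactors:
    """Per-sample composition scaling factors, geometric mean 1."""

    factors: pd.Series
    method: str

    def __post_init__(self) -> None:
        gm = float(np.exp(np.mean(np.log(self.factors))))
        if abs(gm - 1.0) > 1e-9:
            raise ValueError(f"factors must have geometric mean 1 (got {gm})")

    def effective_lib_sizes(self, counts: pd.DataFrame, lib_sizes: pd.Series | None = None) -> pd.Series:
        return _lib_sizes(counts, lib_sizes) * self.factors


def tmm_factors(
    counts: pd.DataFrame,
    lib_sizes: pd.Series | None = None,
    ref_sample: str | None = None,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> NormFactors:
    """Trimmed mean of M-values normalization factors.

    For each sample against a reference, per-gene log ratios
    M = log2((c_k/N_k)/(c_r/N_r)) and abundances
    A = 0.5*log2((c_k/N_k)*(c_r/N_r)) are computed over genes with positive
    counts in both samples, doubly trimmed (``trim_m`` of the M tails,
    ``trim_a`` of the A tails), and combined as a precision-weighted mean of
    M with inverse asymptotic binomial variances as weights. The factor is
    2**(weighted mean M); factors are re-centered to geometric mean 1.

    The reference defaults to the sample whose 75th CPM percentile is
    closest to the mean of the samples' 75th percentiles.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM requires >= 2 samples")
    N = _lib_sizes(counts, lib_sizes)
    X = counts.to_numpy(dtype=float)
    n = N.to_numpy()
    if ref_sample is None:
        q75 = np.array([
            np.quantile(X[:, j][X[:, j] > 0] / n[j], 0.75) if (X[:, j] > 0).any() else 0.0
            for j in range(X.shape[1])
        ])
        ref_idx = int(np.argmin(np.abs(q75 - q75.mean())))
    else:
        ref_idx = counts.columns.get_loc(ref_sample)

    factors = np.ones(X.shape[1])
    cr, Nr = X[:, ref_idx], n[ref_idx]
    for j in range(X.shape[1]):
        if j == ref_idx:
            continue
        ck, Nk = X[:, j], n[j]
        keep = (ck > 0) & (cr > 0)
        if keep.sum() < 1:
            warnings.warn(f"sample {counts.columns[j]}: no genes shared with reference; factor 1")
            continue
        pk, pr = ck[keep] / Nk, cr[keep] / Nr
        M = np.log2(pk / pr)
        A = 0.5 * np.log2(pk * pr)
        w = 1.0 / ((Nk - ck[keep]) / (Nk * ck[keep]) + (Nr - cr[keep]) / (Nr * cr[keep]))
        m = len(M)
        rank_m = stats.rankdata(M)
        rank_a = stats.rankdata(A)
        lo_m = np.floor(m * trim_m) + 1
        hi_m = m + 1 - lo_m
        lo_a = np.floor(m * trim_a) + 1
        hi_a = m + 1 - lo_a
        sel = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
        if sel.sum() < 1:
            warnings.warn(f"sample {counts.columns[j]}: no genes survive trimming; factor 1")
            continue
        factors[j] = 2.0 ** (np.sum(w[sel] * M[sel]) / np.sum(w[sel]))
    factors = factors / np.exp(np.mean(np.log(factors)))
    return NormFactors(pd.Series(factors, index=counts.columns), method="TMM")


def background_bin_factors(bin_counts: pd.DataFrame, lib_sizes: pd.Series | None = None) -> NormFactors:
    """TMM on genome-wide background bin counts (composition normalization
    for accessibility data, where peak counts are dominated by signal).

    All-zero bins are removed first; the resulting factors are meant to be
    attached to the OCR-level analysis of the same samples.
    """
    kept = bin_counts.loc[bin_counts.sum(axis=1) > 0]
    if kept.empty:
        raise ValueError("all background bins are zero")
    nf = tmm_factors(kept, lib_sizes=lib_sizes)
    return NormFactors(nf.factors, method="background_bins")


def filter_by_median_cpm(
    counts: pd.DataFrame,
    threshold: float,
    lib_sizes: pd.Series | None = None,
) -> pd.DataFrame:
    """Keep rows whose median CPM across all samples is >= threshold."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    med = cpm(counts, lib_sizes).median(axis=1)
    return counts.loc[med >= threshold]


@dataclass
class DifferentialResult:
    row_id: str
    log2fc: float
    p: float
    fdr: float
    call: str  # up / down / ns


def bh_fdr(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    return multipletests(pvals, method="fdr_bh")[1]


def _common_dispersion(norm: np.ndarray, group_idx: list[np.ndarray]) -> float:
    """Method-of-moments common NB dispersion from within-group variability.

    For each row the pooled within-group variance s2 satisfies
    E[s2] ~ mbar + phi*qbar where mbar/qbar are df-weighted means of the
    group means / squared group means; phi is the ratio estimator over rows.
    """
    num = 0.0
    den = 0.0
    dfs = np.array([len(ix) - 1 for ix in group_idx], dtype=float)
    for g in range(norm.shape[0]):
        ss = 0.0
        mbar = 0.0
        qbar = 0.0
        for ix, df in zip(group_idx, dfs):
            x = norm[g, ix]
            mu = x.mean()
            ss += np.sum((x - mu) ** 2)
            mbar += df * mu
            qbar += df * mu**2
        tot_df = dfs.sum()
        s2 = ss / tot_df
        num += s2 - mbar / tot_df
        den += qbar / tot_df
    if den <= 0:
        return 0.0
    return max(0.0, num / den)


def _nb_exact_p(ya: int, yb: int, na: int, nb: int, phi: float) -> float:
    """Exact conditional two-sided p for NB group sums given their total.

    Sum of n iid NB(m, phi) is NB(n*m, phi/n); conditioning on the total,
    the p-value aggregates all splits at most as likely as the observed one
    (the standard small-probability-mass exact test).
    """
    t = ya + yb
    if t == 0:
        return 1.0
    m = t / (na + nb)
    a = np.arange(t + 1)
    if phi < 1e-10:
        # Poisson limit: conditional distribution is binomial
        logp = stats.binom.logpmf(a, t, na / (na + nb))
    else:
        ra, rb = na / phi, nb / phi
        mua, mub = na * m, nb * m
        pa, pb = ra / (ra + mua), rb / (rb + mub)
        logp = stats.nbinom.logpmf(a, ra, pa) + stats.nbinom.logpmf(t - a, rb, pb)
    logp = logp - logsumexp(logp)
    obs = logp[ya]
    mask = logp <= obs + 1e-12
    return float(min(1.0, np.exp(logsumexp(logp[mask]))))


def differential_test(
    counts: pd.DataFrame,
    groups: pd.Series,
    factors: NormFactors | None = None,
    lib_sizes: pd.Series | None = None,
    alpha: float = 0.05,
    lfc_min: float = 1.0,
    prior_count: float = 0.5,
    dispersion: float | None = None,
) -> pd.DataFrame:
    """Two-group negative-binomial exact test per row.

    ``groups`` maps sample id -> group label (exactly two labels, each with
    >= 2 samples). Counts are scaled to a common effective library size
    (the geometric mean), a common dispersion is moment-estimated from
    within-group variability unless supplied, and each row is tested with
    the conditional NB exact test on rounded group sums. log2FC is the
    second group over the first (labels in sorted order) from
    factor-normalized means with ``prior_count`` added. BH FDR across rows;
    calls require fdr < alpha and |log2FC| > lfc_min.
    """
    groups = pd.Series(groups).reindex(counts.columns)
    if groups.isna().any():
        raise ValueError("every sample column needs a group label")
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise ValueError(f"exactly two groups required, got {labels}")
    group_cols = [counts.columns[groups == lab] for lab in labels]
    if any(len(c) < 2 for c in group_cols):
        raise ValueError("each group needs >= 2 samples")

    N = _lib_sizes(counts, lib_sizes)
    f = factors.factors if factors is not None else pd.Series(1.0, index=counts.columns)
    eff = (N * f).astype(float)
    common = float(np.exp(np.mean(np.log(eff))))
    norm = counts.astype(float).div(eff, axis=1) * common

    cols = list(counts.columns)
    group_idx = [np.array([cols.index(c) for c in gc]) for gc in group_cols]
    norm_arr = norm.to_numpy()
    phi = _common_dispersion(norm_arr, group_idx) if dispersion is None else dispersion

    na, nb = len(group_idx[0]), len(group_idx[1])
    mu_a = norm_arr[:, group_idx[0]].mean(axis=1)
    mu_b = norm_arr[:, group_idx[1]].mean(axis=1)
    log2fc = np.log2(mu_b + prior_count) - np.log2(mu_a + prior_count)

    ya = np.rint(norm_arr[:, group_idx[0]].sum(axis=1)).astype(int)
    yb = np.rint(norm_arr[:, group_idx[1]].sum(axis=1)).astype(int)
    pvals = np.array([_nb_exact_p(int(a), int(b), na, nb, phi) for a, b in zip(ya, yb)])
    fdr = bh_fdr(pvals)

    call = np.where(
        (fdr < alpha) & (log2fc > lfc_min), "up",
        np.where((fdr < alpha) & (log2fc < -lfc_min), "down", "ns"),
    )
    return pd.DataFrame(
        {"log2fc": log2fc, "p": pvals, "fdr": fdr, "call": call},
        index=counts.index,
    )


@dataclass
class ExpressionClusters:
    """Gene -> cluster assignment (clusters 1..k) with per-stage mean z profiles."""

    assignments: pd.Series
    cluster_means: pd.DataFrame
    k: int = 6
    zscores: pd.DataFrame = field(repr=False, default=None)


def zscore_rows(mat: pd.DataFrame) -> pd.DataFrame:
    """Per-row z-scores; constant rows become zeros (with a warning)."""
    arr = mat.to_numpy(dtype=float)
    mu = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=1, keepdims=True)
    flat = (sd == 0).ravel()
    if flat.any():
        warnings.warn(f"{int(flat.sum())} constant rows z-scored to 0")
        sd = np.where(sd == 0, 1.0, sd)
    return pd.DataFrame((arr - mu) / sd, index=mat.index, columns=mat.columns)


def cluster_de_genes(
    tpm_matrix: pd.DataFrame,
    k: int = 6,
    stage_map: dict[str, str] | None = None,
    method: str = "complete",
    metric: str = "euclidean",
) -> ExpressionClusters:
    """Cluster standardized expression trajectories and cut into k branches.

    Rows (genes) are z-scored across samples, clustered by agglomerative
    hierarchical clustering (complete linkage, Euclidean distance by
    default) and the tree is cut into ``k`` clusters. Cluster ids are
    relabelled 1..k in order of first appearance in the input for
    determinism.
    """
    if tpm_matrix.shape[0] < k:
        raise ValueError(f"need >= {k} genes to form {k} clusters")
    z = zscore_rows(tpm_matrix)
    Z = linkage(z.to_numpy(), method=method, metric=metric)
    raw = fcluster(Z, t=k, criterion="maxclust")
    relabel: dict[int, int] = {}
    lab = np.empty_like(raw)
    for i, r in enumerate(raw):
        if r not in relabel:
            relabel[r] = len(relabel) + 1
        lab[i] = relabel[r]
    assignments = pd.Series(lab, index=tpm_matrix.index, name="cluster")

    if stage_map is not None:
        stages = pd.Series({s: stage_map[s] for s in z.columns})
        prof = z.T.groupby(stages).mean().T
    else:
        prof = z
    cluster_means = prof.groupby(assignments).mean()
    return ExpressionClusters(assignments=assignments, cluster_means=cluster_means, k=k, zscores=z)
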