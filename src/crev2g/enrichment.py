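"""Enrichment statistics.

Hypergeometric gene-set tests, Fisher 2x2 marker enrichment, a
length-preserving permutation test for genomic region overlap, and a
GC/read-count decile-matched permutation test for TF-binding-site
enrichment in cREs versus non-PIR OCRs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .countstats import bh_fdr
from .genome import GenomicInterval

__all__ = [
    "GeneSetResult",
    "hypergeom_test",
    "hypergeom_test_sets",
    "fisher_2x2",
    "RegionOverlapResult",
    "permutation_region_overlap",
    "TFEnrichResult",
    "tf_site_enrichment",
    "read_gmt",
]


@dataclass
class GeneSetResult:
    set_id: str
    overlap_k: int
    query_n: int
    set_K: int
    universe_N: int
    p: float
    fdr: float = float("nan")


def hypergeom_test(
    query: set[str], gene_set: set[str], universe: set[str], set_id: str = ""
) -> GeneSetResult:
    """Upper-tail hypergeometric test P(X >= k) for gene-set overlap.

    Query and set are intersected with the universe first; k is the size
    of the query/set overlap within the universe.
    """
    if not universe:
        raise ValueError("empty universe")
    q = query & universe
    s = gene_set & universe
    N, K, n = len(universe), len(s), len(q)
    k = len(q & s)
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return GeneSetResult(set_id=set_id, overlap_k=k, query_n=n, set_K=K, universe_N=N, p=min(1.0, p))


def hypergeom_test_sets(
    query: set[str], gene_sets: dict[str, set[str]], universe: set[str]
) -> pd.DataFrame:
    """Hypergeometric test per set with BH FDR across sets."""
    results = [hypergeom_test(query, s, universe, set_id=sid) for sid, s in gene_sets.items()]
    df = pd.DataFrame([r.__dict__ for r in results])
    df["fdr"] = bh_fdr(df["p"].to_numpy())
    return df


def fisher_2x2(a: int, b: int, c: int, d: int, alternative: str = "greater") -> float:
    """Fisher's exact test on the 2x2 table [[a, b], [c, d]]."""
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be non-negative")
    if a + b + c + d == 0:
        raise ValueError("all-zero table")
    return float(stats.fisher_exact([[a, b], [c, d]], alternative=alternative)[1])


def read_gmt(path) -> dict[str, set[str]]:
    """GMT gene-set reader: set name, description, member genes per line."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = set(g for g in parts[2:] if g)
    return sets


@dataclass
class RegionOverlapResult:
    observed_overlap: int
    permuted_overlaps: np.ndarray = field(repr=False)
    z: float = 0.0
    p_perm: float = 1.0
    n_perm: int = 0


def _exclude_top_length(regions: list[GenomicInterval], pct: float) -> list[GenomicInterval]:
    if not regions:
        return regions
    lengths = np.array([len(r) for r in regions])
    cut = np.quantile(lengths, 1 - pct / 100.0)
    return [r for r, L in zip(regions, lengths) if L <= cut]


def _reference_index(reference: list[GenomicInterval]) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per chromosome: independently sorted reference starts and ends."""
    idx: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for r in reference:
        by_chrom.setdefault(r.chrom, []).append(r)
    for chrom, regs in by_chrom.items():
        starts = np.sort(np.array([r.start for r in regs]))
        ends = np.sort(np.array([r.end for r in regs]))
        idx[chrom] = (starts, ends)
    return idx

def _count_overlapping(starts: np.ndarray, lengths: np.ndarray,
                       ref: tuple[np.ndarray, np.ndarray]) -> np.ndarray:
    """Number of (query, reference) overlapping pairs; vectorized over a
    trailing permutation axis.

    A reference interval overlaps query [s, s+L) iff ref_start < s+L and
    ref_end > s, so the pair count per query is
    #(ref_start < s+L) - #(ref_end <= s).
    """
    r_starts, r_ends = ref
    n_before = np.searchsorted(r_starts, starts + lengths, side="left")
    n_ended = np.searchsorted(r_ends, starts, side="right")
    return np.sum(n_before - n_ended, axis=-1)


def permutation_region_overlap(
    query: list[GenomicInterval],
    reference: list[GenomicInterval],
    genome_extents: dict[str, int],
    n_perm: int = 10000,
    seed: int = 0,
    exclude_top_length_pct: float | None = None,
) -> RegionOverlapResult:
    """Permutation test for overlap between two region sets.

    The statistic is the number of overlapping (query, reference) region
    pairs. Each permutation re-places every query region
    uniformly within its own chromosome, preserving its length;
    p = (1 + #{perm >= observed}) / (n_perm + 1), and z is the observed
    count standardized by the permutation mean and sd. With
    ``exclude_top_length_pct`` the longest regions of each set (top pct%)
    are removed first, independently per set.
    """
    if exclude_top_length_pct is not None:
        query = _exclude_top_length(query, exclude_top_length_pct)
        reference = _exclude_top_length(reference, exclude_top_length_pct)
    for q in query:
        if q.chrom not in genome_extents:
            raise ValueError(f"query chromosome {q.chrom!r} has no extent")
        if len(q) > genome_extents[q.chrom]:
            raise ValueError(f"query region longer than chromosome {q.chrom}")

    ref_idx = _reference_index(reference)
    rng = np.random.default_rng(seed)

    observed = 0
    null = np.zeros(n_perm, dtype=int)
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for q in query:
        by_chrom.setdefault(q.chrom, []).append(q)
    for chrom, regs in sorted(by_chrom.items()):
        ref = ref_idx.get(chrom)
        starts = np.array([r.start for r in regs])
        lengths = np.array([len(r) for r in regs])
        if ref is not None:
            observed += int(_count_overlapping(starts, lengths, ref))
        max_start = genome_extents[chrom] - lengths + 1
        rand_starts = rng.integers(0, max_start, size=(n_perm, len(regs)))
        if ref is not None:
            null += _count_overlapping(rand_starts, lengths, ref).astype(int)

    ge = int(np.sum(null >= observed))
    p_perm = (1 + ge) / (n_perm + 1)
    sd = float(null.std())
    z = float((observed - null.mean()) / sd) if sd > 0 else 0.0
    return RegionOverlapResult(
        observed_overlap=observed, permuted_overlaps=null, z=z, p_perm=p_perm, n_perm=n_perm
    )


@dataclass
class TFEnrichResult:
    tf_id: str
    fg_sites: int
    expected_bg_sites: float
    p: float
    fdr: float
    direction: str


def _decile_bins(values: np.ndarray, n_bins: int = 10) -> np.ndarray:
    edges = np.quantile(values, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.searchsorted(edges, values, side="right")


def _region_site_counts(
    regions: pd.DataFrame, sites: pd.DataFrame, tf_ids: list[str]
) -> np.ndarray:
    """(n_regions x n_tfs) matrix of binding sites overlapping each region."""
    tf_index = {t: j for j, t in enumerate(tf_ids)}
    M = np.zeros((len(regions), len(tf_ids)), dtype=int)
    by_chrom_sites: dict[str, pd.DataFrame] = {c: g for c, g in sites.groupby("chrom")}
    for i, reg in enumerate(regions.itertuples(index=False)):
        sub = by_chrom_sites.get(reg.chrom)
        if sub is None:
            continue
        hit = sub[(sub["start"] < reg.end) & (sub["end"] > reg.start)]
        for t in hit["tf_id"]:
            M[i, tf_index[t]] += 1
    return M


def tf_site_enrichment(
    sites: pd.DataFrame,
    foreground: pd.DataFrame,
    background: pd.DataFrame,
    purity_min: float = 0.7,
    n_perm: int = 1000,
    seed: int = 0,
    n_bins: int | None = None,
) -> pd.DataFrame:
    """Covariate-matched permutation test for TF-site enrichment in cREs.

    ``sites``: tf_id, chrom, start, end, purity. ``foreground`` (cREs) and
    ``background`` (non-PIR OCRs): chrom, start, end, gc, read_count.
    Sites below purity (<= purity_min) are discarded. Regions are binned
    into GC-decile x read-count-decile cells (edges from the pooled
    regions); each permutation draws, for every foreground region, one
    background region from the same cell (nearest non-empty cell if the
    exact cell has no background regions), and counts sites per TF. The
    one-sided p per TF is (1 + #{null >= observed}) / (n_perm + 1), with
    BH FDR across TFs.

    ``n_bins`` defaults to deciles when the background is large, coarsening
    automatically so the expected cell occupancy stays near ten regions
    (degenerate cells would understate the null variance).
    """
    sites = sites[sites["purity"] > purity_min]
    tf_ids = sorted(sites["tf_id"].unique())
    if not tf_ids:
        return pd.DataFrame(
            columns=["tf_id", "fg_sites", "expected_bg_sites", "p", "fdr", "direction"]
        )

    if n_bins is None:
        n_bins = int(np.clip(np.sqrt(len(background) / 10), 1, 10))

    pooled_gc = np.concatenate([foreground["gc"].to_numpy(), background["gc"].to_numpy()])
    pooled_rc = np.concatenate(
        [foreground["read_count"].to_numpy(), background["read_count"].to_numpy()]
    )
    gc_edges = np.quantile(pooled_gc, np.linspace(0, 1, n_bins + 1)[1:-1])
    rc_edges = np.quantile(pooled_rc, np.linspace(0, 1, n_bins + 1)[1:-1])

    def cell_of(df: pd.DataFrame) -> np.ndarray:
        gbin = np.searchsorted(gc_edges, df["gc"].to_numpy(), side="right")
        rbin = np.searchsorted(rc_edges, df["read_count"].to_numpy(), side="right")
        return gbin * n_bins + rbin

    fg_cells = cell_of(foreground)
    bg_cells = cell_of(background)
    bg_by_cell: dict[int, np.ndarray] = {
        int(c): np.flatnonzero(bg_cells == c) for c in np.unique(bg_cells)
    }

    # nearest-cell fallback for foreground cells with no background members
    def candidates(cell: int) -> np.ndarray:
        if cell in bg_by_cell:
            return bg_by_cell[cell]
        g0, r0 = divmod(cell, n_bins)
        best, best_d = None, None
        for c, idx in sorted(bg_by_cell.items()):
            g1, r1 = divmod(c, n_bins)
            d = abs(g1 - g0) + abs(r1 - r0)
            if best_d is None or d < best_d:
                best, best_d = idx, d
        return best

    fg_counts = _region_site_counts(foreground, sites, tf_ids)
    bg_counts = _region_site_counts(background, sites, tf_ids)
    observed = fg_counts.sum(axis=0)

    rng = np.random.default_rng(seed)
    fg_candidates = [candidates(int(c)) for c in fg_cells]
    null = np.zeros((n_perm, len(tf_ids)), dtype=int)
    for p in range(n_perm):
        picks = np.array([cand[rng.integers(len(cand))] for cand in fg_candidates])
        null[p] = bg_counts[picks].sum(axis=0)

    pvals = (1 + np.sum(null >= observed, axis=0)) / (n_perm + 1)
    fdr = bh_fdr(pvals)
    expected = null.mean(axis=0)
    out = pd.DataFrame(
        {
            "tf_id": tf_ids,
            "fg_sites": observed,
            "expected_bg_sites": expected,
            "p": pvals,
            "fdr": fdr,
            "direction": np.where(observed >= expected, "enriched", "depleted"),
        }
    )
    return out
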