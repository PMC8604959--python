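"""Variant-to-gene mapping.

The filter chain: GWAS sentinel -> LD proxies (r^2 > 0.6) -> proxies in
open chromatin -> promoter contact (distal PIR fragment or baited promoter
OCR) -> expressed gene (TPM > 1), with Table-1-style per-trait summaries
and cross-trait exclusive gene overlaps.

Proxy positions are 1-based (VCF-style) in input files and converted to
0-based points internally.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import pandas as pd

from .atlas import ConsensusOCR
from .genome import FragmentMap, GenomicInterval

__all__ = [
    "TraitSignalTable",
    "expand_proxies",
    "find_open_proxies",
    "map_to_genes",
    "filter_expressed",
    "TraitSummary",
    "summarize_trait",
    "cross_trait_overlap",
]

RECORD_COLUMNS = ["trait", "sentinel", "proxy", "stage", "ocr_id", "gene_id", "route", "gene_tpm"]


@dataclass
class TraitSignalTable:
    """Sentinels with their LD proxies for one trait (internal 0-based pos)."""

    trait: str
    proxies: pd.DataFrame  # sentinel, proxy, chrom, pos0, r2
    n_signals: int
    n_in_panel: int

    @property
    def n_unique_proxies(self) -> int:
        return int(self.proxies["proxy"].nunique())


def expand_proxies(
    raw: pd.DataFrame,
    r2_min: float = 0.6,
    sentinels: pd.DataFrame | None = None,
) -> list[TraitSignalTable]:
    """Apply the LD filter (r^2 > r2_min) and assemble per-trait tables.

    ``raw`` has columns trait, sentinel, proxy, chrom, pos (1-based), r2.
    Each sentinel's self-row (proxy == sentinel, r2 = 1) marks it as found
    in the reference panel; sentinels listed in ``sentinels`` (columns
    trait, sentinel) but absent from ``raw`` are counted as not-in-panel
    and contribute no proxies.
    """
    if ((raw["r2"] < 0) | (raw["r2"] > 1)).any():
        raise ValueError("r2 values must lie in [0, 1]")
    out = []
    all_traits = sorted(set(raw["trait"]) | (set(sentinels["trait"]) if sentinels is not None else set()))
    for trait in all_traits:
        sub = raw[raw["trait"] == trait].copy()
        in_panel = set(sub["sentinel"])
        if sentinels is not None:
            declared = set(sentinels.loc[sentinels["trait"] == trait, "sentinel"])
            all_sent = declared | in_panel
        else:
            all_sent = in_panel
        is_self = sub["proxy"] == sub["sentinel"]
        kept = sub[(sub["r2"] > r2_min) | is_self].copy()
        kept["pos0"] = kept["pos"].astype(int) - 1
        kept = kept[["sentinel", "proxy", "chrom", "pos0", "r2"]].reset_index(drop=True)
        out.append(
            TraitSignalTable(
                trait=trait,
                proxies=kept,
                n_signals=len(all_sent),
                n_in_panel=len(in_panel),
            )
        )
    return out


def find_open_proxies(
    table: TraitSignalTable,
    ocrs: list[ConsensusOCR],
    stages: list[str] | None = None,
) -> pd.DataFrame:
    """Proxies falling inside an OCR open in a stage (half-open containment).

    Returns one row per (proxy, OCR, stage) hit.
    """
    by_chrom: dict[str, list[ConsensusOCR]] = {}
    for o in ocrs:
        by_chrom.setdefault(o.interval.chrom, []).append(o)
    rows = []
    for rec in table.proxies.itertuples(index=False):
        for o in by_chrom.get(rec.chrom, []):
            if o.interval.contains_point(rec.chrom, rec.pos0):
                for stage, is_open in o.open_in.items():
                    if stages is not None and stage not in stages:
                        continue
                    if is_open:
                        rows.append((table.trait, rec.sentinel, rec.proxy,
                                     rec.chrom, rec.pos0, o.ocr_id, stage))
    return pd.DataFrame(
        rows, columns=["trait", "sentinel", "proxy", "chrom", "pos0", "ocr_id", "stage"]
    )


def map_to_genes(
    hits: pd.DataFrame,
    sig: pd.DataFrame,
    fm: FragmentMap,
    promoter_windows: dict[str, GenomicInterval],
    ocrs: list[ConsensusOCR],
    baited_promoters: set[str] | None = None,
) -> pd.DataFrame:
    """Assign open proxies to genes via the two contact evidence routes.

    distal_PIR: the proxy's OCR overlaps an other-end fragment of a
    stage-significant interaction -> the interaction's bait gene(s).
    bait_OCR: the proxy's OCR overlaps a baited promoter fragment -> that
    fragment's gene(s). The same (trait, proxy, gene, stage) can carry
    both routes.
    """
    ocr_by_id = {o.ocr_id: o for o in ocrs}

    # stage -> oe fragment -> bait genes
    oe_genes: dict[tuple[str, int], set[str]] = {}
    for rec in sig.itertuples(index=False):
        bait_iv = GenomicInterval(rec.bait_chrom, rec.bait_start, rec.bait_end)
        for gid, win in promoter_windows.items():
            if baited_promoters is not None and gid not in baited_promoters:
                continue
            if bait_iv.overlaps(win):
                oe_genes.setdefault((rec.stage, rec.oe_frag_id), set()).add(gid)

    # baited promoter fragments -> genes (stage-independent bait design)
    bait_frag_genes: dict[int, set[str]] = {}
    for gid, win in promoter_windows.items():
        if baited_promoters is not None and gid not in baited_promoters:
            continue
        for fid in fm.overlapping_fragment_ids(win):
            bait_frag_genes.setdefault(fid, set()).add(gid)

    rows = []
    for h in hits.itertuples(index=False):
        frag_ids = fm.overlapping_fragment_ids(ocr_by_id[h.ocr_id].interval)
        for fid in frag_ids:
            for gid in sorted(oe_genes.get((h.stage, fid), set())):
                rows.append((h.trait, h.sentinel, h.proxy, h.stage, h.ocr_id, gid, "distal_PIR"))
            for gid in sorted(bait_frag_genes.get(fid, set())):
                rows.append((h.trait, h.sentinel, h.proxy, h.stage, h.ocr_id, gid, "bait_OCR"))
    records = pd.DataFrame(
        rows, columns=["trait", "sentinel", "proxy", "stage", "ocr_id", "gene_id", "route"]
    ).drop_duplicates()
    records["gene_tpm"] = float("nan")
    return records


def filter_expressed(
    records: pd.DataFrame,
    tpm_matrix: pd.DataFrame,
    stage_map: dict[str, str],
    tpm_min: float = 1.0,
) -> pd.DataFrame:
    """Keep records whose gene is expressed (stage-mean TPM > tpm_min) in
    the record's stage; genes missing from the table are dropped."""
    stages = pd.Series({s: stage_map[s] for s in tpm_matrix.columns})
    stage_tpm = tpm_matrix.T.groupby(stages).mean().T
    kept = []
    for rec in records.itertuples(index=False):
        if rec.gene_id not in stage_tpm.index or rec.stage not in stage_tpm.columns:
            continue
        val = float(stage_tpm.loc[rec.gene_id, rec.stage])
        if val > tpm_min:
            kept.append(rec._replace(gene_tpm=val))
    return pd.DataFrame(kept, columns=records.columns)


@dataclass
class TraitSummary:
    """Per-trait variant-to-gene summary (the Table-1-style columns)."""

    trait: str
    n_signals: int
    n_in_panel: int
    n_unique_proxies: int
    n_open_proxies_with_cis: dict[str, int]
    n_sentinels_with_cis: dict[str, int]
    n_contacted_genes: dict[str, int]
    n_unique_contacted_genes: int

    def to_row(self, stages: list[str]) -> dict:
        row = {
            "trait": self.trait,
            "n_signals": self.n_signals,
            "n_in_panel": self.n_in_panel,
            "n_unique_proxies": self.n_unique_proxies,
        }
        for s in stages:
            row[f"open_proxies_cis_{s}"] = self.n_open_proxies_with_cis.get(s, 0)
        for s in stages:
            row[f"sentinels_cis_{s}"] = self.n_sentinels_with_cis.get(s, 0)
        for s in stages:
            row[f"contacted_genes_{s}"] = self.n_contacted_genes.get(s, 0)
        row["unique_contacted_genes"] = self.n_unique_contacted_genes
        return row


def summarize_trait(records: pd.DataFrame, table: TraitSignalTable) -> TraitSummary:
    """Count proxies, sentinels and genes surviving the full filter chain,
    per stage and deduplicated across stages."""
    sub = records[records["trait"] == table.trait]
    per_stage_proxies = sub.groupby("stage")["proxy"].nunique().to_dict()
    per_stage_sent = sub.groupby("stage")["sentinel"].nunique().to_dict()
    per_stage_genes = sub.groupby("stage")["gene_id"].nunique().to_dict()
    return TraitSummary(
        trait=table.trait,
        n_signals=table.n_signals,
        n_in_panel=table.n_in_panel,
        n_unique_proxies=table.n_unique_proxies,
        n_open_proxies_with_cis=per_stage_proxies,
        n_sentinels_with_cis=per_stage_sent,
        n_contacted_genes=per_stage_genes,
        n_unique_contacted_genes=int(sub["gene_id"].nunique()),
    )


def cross_trait_overlap(gene_sets: dict[str, set[str]]) -> pd.DataFrame:
    """Exclusive (upset-style) gene intersection counts.

    For every non-empty subset of traits, counts the genes implicated in
    exactly that subset of traits and no others.
    """
    if len(gene_sets) < 2:
        raise ValueError("cross-trait overlap needs >= 2 traits")
    traits = sorted(gene_sets)
    membership: dict[str, frozenset[str]] = {}
    for t in traits:
        for g in gene_sets[t]:
            membership[g] = membership.get(g, frozenset()) | {t}
    rows = []
    for r in range(1, len(traits) + 1):
        for subset in combinations(traits, r):
            fs = frozenset(subset)
            n = sum(1 for m in membership.values() if m == fs)
            rows.append({"traits": "+".join(subset), "n_traits": r, "n_genes": n})
    return pd.DataFrame(rows)
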