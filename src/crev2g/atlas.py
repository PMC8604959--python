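"""Consensus open-chromatin atlas and cRE classification.

Replicate ATAC-seq peak sets are merged (1-bp rule) into consensus OCRs,
filtered for reproducibility in at least half the replicates, quantified as
FPKM per stage (open = mean FPKM > 1), and the open OCRs of each stage are
partitioned into promoter OCRs, PIR-OCRs (contacting a baited gene promoter
through a significant capture interaction) and non-PIR-OCRs.
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .countstats import fpkm as fpkm_transform
from .genome import FragmentMap, GeneModel, GenomicInterval, promoter_window

__all__ = [
    "PeakReplicate",
    "ConsensusOCR",
    "build_consensus",
    "quantify_openness",
    "significant_interactions",
    "classify_ocrs",
    "gene_cre_map",
    "CLASS_PROMOTER",
    "CLASS_PIR",
    "CLASS_NONPIR",
]

CLASS_PROMOTER = "PromoterOCR"
CLASS_PIR = "PIR_OCR"
CLASS_NONPIR = "NonPIR_OCR"


@dataclass
class PeakReplicate:
    sample_id: str
    cell_stage: str
    peaks: list[GenomicInterval]

    def __post_init__(self) -> None:
        self.peaks = sorted(self.peaks, key=lambda p: (p.chrom, p.start, p.end))


@dataclass
class ConsensusOCR:
    ocr_id: str
    interval: GenomicInterval
    support: dict[str, int] = field(default_factory=dict)   # stage -> n replicates
    fpkm: dict[str, float] = field(default_factory=dict)    # stage -> mean FPKM
    open_in: dict[str, bool] = field(default_factory=dict)  # stage -> open flag
    cre_class: dict[str, str] = field(default_factory=dict)  # stage -> class (open stages only)

    @property
    def length(self) -> int:
        return len(self.interval)


def _merge_1bp(intervals: list[GenomicInterval]) -> list[GenomicInterval]:
    """Transitive merge of all intervals overlapping by >= 1 bp."""
    merged: list[GenomicInterval] = []
    for iv in sorted(intervals, key=lambda p: (p.chrom, p.start, p.end)):
        if merged and merged[-1].chrom == iv.chrom and iv.start < merged[-1].end:
            if iv.end > merged[-1].end:
                merged[-1] = GenomicInterval(iv.chrom, merged[-1].start, iv.end)
        else:
            merged.append(iv)
    return merged


def build_consensus(
    replicates: list[PeakReplicate],
    min_fraction: float = 0.5,
    per_stage: bool = True,
) -> list[ConsensusOCR]:
    """Merge replicate peaks into consensus OCRs and apply the
    reproducibility filter.

    All peaks from all replicates are merged transitively at >= 1 bp
    overlap. A consensus region is kept if it overlaps peaks from at least
    ``ceil(min_fraction * R)`` replicates — with R the replicate count of
    some stage (``per_stage=True``, each stage's atlas self-contained) or
    the total replicate count (``per_stage=False``). Support counts per
    stage are recorded on every kept OCR.
    """
    if not replicates:
        raise ValueError("at least one replicate required")
    merged = _merge_1bp([p for r in replicates for p in r.peaks])

    stages = sorted({r.cell_stage for r in replicates})
    n_reps = {s: sum(1 for r in replicates if r.cell_stage == s) for s in stages}
    n_total = len(replicates)

    # support per merged region: replicates contributing >= 1 overlapping peak
    support: list[dict[str, int]] = [dict.fromkeys(stages, 0) for _ in merged]
    by_chrom: dict[str, list[tuple[int, GenomicInterval]]] = {}
    for i, iv in enumerate(merged):
        by_chrom.setdefault(iv.chrom, []).append((i, iv))
    for rep in replicates:
        hit: set[int] = set()
        for chrom, items in by_chrom.items():
            starts = [iv.start for _, iv in items]
            peaks = [p for p in rep.peaks if p.chrom == chrom]
            for p in peaks:
                j = bisect.bisect_right(starts, p.start) - 1
                j = max(j, 0)
                while j < len(items) and items[j][1].start < p.end:
                    if items[j][1].end > p.start:
                        hit.add(items[j][0])
                    j += 1
        for i in hit:
            support[i][rep.cell_stage] += 1

    out: list[ConsensusOCR] = []
    for iv, sup in zip(merged, support):
        if per_stage:
            keep = any(
                sup[s] >= math.ceil(min_fraction * n_reps[s]) for s in stages
            )
        else:
            keep = sum(sup.values()) >= math.ceil(min_fraction * n_total)
        if keep:
            out.append(ConsensusOCR(ocr_id=f"ocr_{len(out)}", interval=iv, support=dict(sup)))
    return out


def quantify_openness(
    ocrs: list[ConsensusOCR],
    counts: pd.DataFrame,
    stage_map: dict[str, str],
    lib_sizes: pd.Series | None = None,
    fpkm_open: float = 1.0,
) -> list[ConsensusOCR]:
    """Attach per-stage mean FPKM and the open flag (mean FPKM > threshold).

    ``counts`` rows must align with ``ocrs`` (by ocr_id index); FPKM uses
    per-replicate library sizes and the OCR length in kb.
    """
    if list(counts.index) != [o.ocr_id for o in ocrs]:
        raise ValueError("count matrix rows must align with OCR list (by ocr_id)")
    lengths = pd.Series({o.ocr_id: o.length for o in ocrs})
    if (lengths <= 0).any():
        raise ValueError("zero-length OCR")
    fk = fpkm_transform(counts, lengths, lib_sizes)
    stages = pd.Series({s: stage_map[s] for s in counts.columns})
    stage_mean = fk.T.groupby(stages).mean().T
    for o in ocrs:
        o.fpkm = {s: float(stage_mean.loc[o.ocr_id, s]) for s in stage_mean.columns}
        o.open_in = {s: v > fpkm_open for s, v in o.fpkm.items()}
    return ocrs


def significant_interactions(
    ibed: pd.DataFrame,
    fm: FragmentMap,
    score_min: float = 5.0,
) -> pd.DataFrame:
    """Filter capture interactions at score > score_min and expand to
    1-fragment resolution.

    Input is an ibed-style frame (bait/other-end coordinates, score,
    resolution frag1|frag4, stage). 4-fragment calls are projected onto
    their member 1-fragment other-ends; the union over resolutions and
    stages is returned with one row per (stage, bait, oe fragment id).
    """
    required = {"bait_chrom", "bait_start", "bait_end", "oe_chrom", "oe_start", "oe_end",
                "score", "resolution", "stage"}
    missing = required - set(ibed.columns)
    if missing:
        raise ValueError(f"interaction table missing columns: {sorted(missing)}")
    sig = ibed[ibed["score"] > score_min]
    rows = []
    for rec in sig.itertuples(index=False):
        oe_iv = GenomicInterval(rec.oe_chrom, int(rec.oe_start), int(rec.oe_end))
        if rec.resolution == "frag1":
            oe_ids = [fm.fragment_id_at(rec.oe_chrom, int(rec.oe_start))]
        else:
            oe_ids = [
                fid for fid in fm.overlapping_fragment_ids(oe_iv)
                if fm.fragment(fid).start >= oe_iv.start and fm.fragment(fid).end <= oe_iv.end
            ] or fm.overlapping_fragment_ids(oe_iv)
        for fid in oe_ids:
            rows.append(
                (rec.stage, rec.bait_chrom, int(rec.bait_start), int(rec.bait_end),
                 getattr(rec, "bait_name", ""), fid, float(rec.score), rec.resolution)
            )
    out = pd.DataFrame(
        rows,
        columns=["stage", "bait_chrom", "bait_start", "bait_end", "bait_name",
                 "oe_frag_id", "score", "resolution"],
    )
    return out.drop_duplicates(subset=["stage", "bait_chrom", "bait_start", "bait_end", "oe_frag_id"])


def _bait_gene_index(
    sig: pd.DataFrame,
    promoter_windows: dict[str, GenomicInterval],
    baited_promoters: set[str] | None,
) -> pd.DataFrame:
    """Expand each significant interaction row to its bait gene(s).

    A bait fragment maps to every baited gene whose promoter window
    overlaps it; rows with no baited gene are dropped.
    """
    rows = []
    for rec in sig.itertuples(index=False):
        bait_iv = GenomicInterval(rec.bait_chrom, rec.bait_start, rec.bait_end)
        for gid, win in promoter_windows.items():
            if baited_promoters is not None and gid not in baited_promoters:
                continue
            if bait_iv.overlaps(win):
                rows.append((rec.stage, gid, rec.oe_frag_id))
    return pd.DataFrame(rows, columns=["stage", "gene_id", "oe_frag_id"]).drop_duplicates()


def classify_ocrs(
    ocrs: list[ConsensusOCR],
    promoter_windows: dict[str, GenomicInterval],
    sig: pd.DataFrame,
    fm: FragmentMap,
    baited_promoters: set[str] | None = None,
    stage_specific: bool = True,
) -> list[ConsensusOCR]:
    """Assign each open OCR one class per stage: promoter > PIR > non-PIR.

    Promoter OCRs overlap a gene promoter window; PIR-OCRs overlap (>= 1
    bp) an other-end fragment of a significant interaction whose bait
    fragment carries a baited gene promoter; everything else open is
    non-PIR. With ``stage_specific`` the contact set of each stage is used
    for that stage; otherwise contacts are pooled across stages.
    """
    bait_gene = _bait_gene_index(sig, promoter_windows, baited_promoters)
    contacted: dict[str, set[int]] = {}
    all_oe = set(bait_gene["oe_frag_id"])
    for stage, sub in bait_gene.groupby("stage"):
        contacted[stage] = set(sub["oe_frag_id"])

    prom_by_chrom: dict[str, list[GenomicInterval]] = {}
    for win in promoter_windows.values():
        prom_by_chrom.setdefault(win.chrom, []).append(win)

    for o in ocrs:
        frag_ids = set(fm.overlapping_fragment_ids(o.interval))
        if not frag_ids:
            raise ValueError(f"OCR {o.ocr_id} outside fragment map")
        in_promoter = any(
            o.interval.overlaps(w) for w in prom_by_chrom.get(o.interval.chrom, [])
        )
        o.cre_class = {}
        for stage, is_open in o.open_in.items():
            if not is_open:
                continue
            oe_set = contacted.get(stage, set()) if stage_specific else all_oe
            if in_promoter:
                o.cre_class[stage] = CLASS_PROMOTER
            elif frag_ids & oe_set:
                o.cre_class[stage] = CLASS_PIR
            else:
                o.cre_class[stage] = CLASS_NONPIR
    return ocrs


def gene_cre_map(
    ocrs: list[ConsensusOCR],
    sig: pd.DataFrame,
    promoter_windows: dict[str, GenomicInterval],
    genes: list[GeneModel],
    fm: FragmentMap,
    baited_promoters: set[str] | None = None,
    stage_specific: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Link classified cREs to genes and summarize per gene.

    Promoter OCRs link to every gene whose promoter window they overlap
    (route 'promoter'); PIR-OCRs link to the bait gene(s) of the
    interactions whose other-end fragment they overlap (route 'contact').
    Returns (links, per-gene summary with count and mean |midpoint - TSS|).
    """
    tss = {g.gene_id: g.tss for g in genes}
    bait_gene = _bait_gene_index(sig, promoter_windows, baited_promoters)
    oe_to_genes: dict[tuple[str, int], set[str]] = {}
    for rec in bait_gene.itertuples(index=False):
        oe_to_genes.setdefault((rec.stage, rec.oe_frag_id), set()).add(rec.gene_id)
    pooled_oe_to_genes: dict[int, set[str]] = {}
    for (_, fid), gids in oe_to_genes.items():
        pooled_oe_to_genes.setdefault(fid, set()).update(gids)

    rows = []
    for o in ocrs:
        frag_ids = fm.overlapping_fragment_ids(o.interval)
        for stage, klass in o.cre_class.items():
            if klass == CLASS_PROMOTER:
                for gid, win in promoter_windows.items():
                    if o.interval.overlaps(win):
                        rows.append((stage, gid, o.ocr_id, "promoter",
                                     abs(o.interval.midpoint - tss[gid])))
            elif klass == CLASS_PIR:
                gids: set[str] = set()
                for fid in frag_ids:
                    if stage_specific:
                        gids |= oe_to_genes.get((stage, fid), set())
                    else:
                        gids |= pooled_oe_to_genes.get(fid, set())
                for gid in sorted(gids):
                    rows.append((stage, gid, o.ocr_id, "contact",
                                 abs(o.interval.midpoint - tss[gid])))
    links = pd.DataFrame(rows, columns=["stage", "gene_id", "ocr_id", "route", "distance_bp"])
    if links.empty:
        summary = pd.DataFrame(columns=["stage", "gene_id", "n_cres", "mean_distance_bp"])
    else:
        summary = (
            links.groupby(["stage", "gene_id"])
            .agg(n_cres=("ocr_id", "nunique"), mean_distance_bp=("distance_bp", "mean"))
            .reset_index()
        )
    return links, summary


def class_counts(ocrs: list[ConsensusOCR]) -> pd.DataFrame:
    """Per-stage counts of each cRE class (the atlas partition table)."""
    rows: dict[str, dict[str, int]] = {}
    for o in ocrs:
        for stage, klass in o.cre_class.items():
            rows.setdefault(stage, {}).setdefault(klass, 0)
            rows[stage][klass] += 1
    return (
        pd.DataFrame(rows)
        .T.reindex(columns=[CLASS_PROMOTER, CLASS_PIR, CLASS_NONPIR])
        .fillna(0)
        .astype(int)
        .rename_axis("stage")
    )
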