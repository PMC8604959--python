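"""Self-consistent synthetic differentiation dataset with a ground truth.

Generates everything the pipeline consumes — genome FASTA, gene models,
restriction-fragment map, replicate ATAC peak sets, OCR / background-bin /
RNA count matrices, capture interactions, LD proxy tables and TF binding
sites — around planted effects: reproducible consensus OCRs with known
promoter/PIR/non-PIR classes, six stage-restricted expression archetypes,
differentially accessible regions, significant promoter contacts (score in
[6, 12] vs decoys in [0, 5]) and sentinel->proxy->cRE->gene links with one
decoy proxy class per variant-to-gene filter. All randomness flows from a
single seed; generation is bit-reproducible.

The emulated study design is a three-stage in vitro differentiation (ESC ->
hypothalamic progenitor -> hypothalamic neuron) with 4/4/6 ATAC replicates.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from .atlas import PeakReplicate, build_consensus
from .countstats import tpm as tpm_transform
from .genome import (
    FragmentMap,
    GeneModel,
    GenomicInterval,
    bin_fragments,
    digest_genome,
    promoter_window,
)

__all__ = ["SyntheticConfig", "generate", "ld_from_haplotypes", "validate_manifest"]

ARCHETYPES = [
    ("ESC", "up"), ("HP", "up"), ("HN", "up"),
    ("ESC", "down"), ("HP", "down"), ("HN", "down"),
]


@dataclass
class SyntheticConfig:
    seed: int = 0
    n_chrom: int = 2
    chrom_length: int = 400_000
    motif: str = "GATC"
    n_genes: int = 160
    stages: dict[str, int] = field(default_factory=lambda: {"ESC": 4, "HP": 4, "HN": 6})
    # planted atlas structure
    n_promoter_ocrs: int = 25
    n_pir_ocrs: int = 30
    n_nonpir_ocrs: int = 30
    n_closed_ocrs: int = 5
    n_da_regions: int = 15
    n_decoy_peaks: int = 30
    # planted expression structure
    n_de_per_cluster: int = 20
    n_low_tpm_genes: int = 5
    # planted GWAS structure
    n_traits: int = 3
    sentinels_per_trait: int = 4
    links_per_trait: int = 2
    # planted TF structure
    n_tfs_enriched: int = 3
    n_tfs_null: int = 3
    sites_per_tf: int = 60
    # noise / scale
    nb_dispersion: float = 0.05
    peak_dropout: float = 0.1
    atac_depth: float = 1e7
    rna_depth: float = 2e6
    open_fpkm: float = 8.0
    closed_fpkm: float = 0.1
    # planted means are on the TPM scale itself: with n_genes genes the
    # flat baseline is chosen so per-stage totals land near 1e6
    base_tpm: float = 6000.0
    low_tpm: float = 0.2
    de_fold: float = 6.0
    da_fold: float = 4.0
    score_sig: tuple[float, float] = (6.0, 12.0)
    score_decoy: tuple[float, float] = (0.5, 4.9)
    frag4_fraction: float = 0.25

    def samples(self) -> list[tuple[str, str]]:
        """(sample_id, stage) pairs, stable order."""
        out = []
        for stage, n in self.stages.items():
            out.extend((f"{stage}_r{i + 1}", stage) for i in range(n))
        return out


def _nb_draw(rng: np.random.Generator, mean, dispersion: float):
    """Negative-binomial draw with var = mu + phi mu^2 (Poisson at phi=0)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p)


def ld_from_haplotypes(haplotypes: np.ndarray) -> np.ndarray:
    """Pairwise r^2 from a binary haplotype matrix (haplotypes x variants).

    r^2 = (p_AB - p_A p_B)^2 / (p_A (1-p_A) p_B (1-p_B)); monomorphic
    variants yield NaN rows/columns.
    """
    H = np.asarray(haplotypes, dtype=float)
    if H.ndim != 2 or H.shape[1] < 2:
        raise ValueError("need a 2-D matrix with >= 2 variants")
    p = H.mean(axis=0)
    pAB = (H.T @ H) / H.shape[0]
    num = (pAB - np.outer(p, p)) ** 2
    var = p * (1 - p)
    den = np.outer(var, var)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(den > 0, num / den, np.nan)
    return r2


# ---------------------------------------------------------------------------
# generation


def _random_genome(rng: np.random.Generator, cfg: SyntheticConfig) -> dict[str, str]:
    bases = np.array(list("ACGT"))
    return {
        f"chr{i + 1}": "".join(bases[rng.integers(0, 4, size=cfg.chrom_length)])
        for i in range(cfg.n_chrom)
    }


def _place_genes(rng: np.random.Generator, cfg: SyntheticConfig,
                 chroms: list[str]) -> list[GeneModel]:
    """Genes on a jittered grid; 3 exons, ~1.3 kb span, strand random."""
    per_chrom = cfg.n_genes // len(chroms)
    genes = []
    gi = 0
    for chrom in chroms:
        lo, hi = 4000, cfg.chrom_length - 4000
        step = (hi - lo) / per_chrom
        for j in range(per_chrom):
            tss = int(lo + j * step + rng.integers(-400, 401))
            strand = "+" if rng.integers(2) == 0 else "-"
            gid = f"G{gi:03d}"
            gi += 1
            if strand == "+":
                e1 = GenomicInterval(chrom, tss, tss + 200)
                e2 = GenomicInterval(chrom, tss + 600, tss + 750)
                e3 = GenomicInterval(chrom, tss + 1050, tss + 1300)
                utr5 = [GenomicInterval(chrom, tss, tss + 100)]
                cds = [GenomicInterval(chrom, tss + 100, tss + 200), e2,
                       GenomicInterval(chrom, tss + 1050, tss + 1150)]
                utr3 = [GenomicInterval(chrom, tss + 1150, tss + 1300)]
            else:
                e3 = GenomicInterval(chrom, tss - 1299, tss - 1049)
                e2 = GenomicInterval(chrom, tss - 749, tss - 599)
                e1 = GenomicInterval(chrom, tss - 199, tss + 1)
                utr5 = [GenomicInterval(chrom, tss - 99, tss + 1)]
                cds = [GenomicInterval(chrom, tss - 199, tss - 99), e2,
                       GenomicInterval(chrom, tss - 1149, tss - 1049)]
                utr3 = [GenomicInterval(chrom, tss - 1299, tss - 1149)]
            genes.append(GeneModel(gid, chrom, strand, [e1, e2, e3],
                                   cds=cds, utr5=utr5, utr3=utr3))
    return genes


def _candidate_fragments(fm: FragmentMap, windows: list[GenomicInterval],
                         margin: int = 500, min_len: int = 200) -> list[int]:
    """Fragment ids long enough to host an OCR and clear of promoter windows."""
    padded = [GenomicInterval(w.chrom, max(0, w.start - margin), w.end + margin)
              for w in windows]
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for w in padded:
        by_chrom.setdefault(w.chrom, []).append(w)
    out = []
    for fid, chrom, frag in fm.iter_fragments():
        if len(frag) < min_len:
            continue
        if any(frag.overlaps(w) for w in by_chrom.get(chrom, [])):
            continue
        out.append(fid)
    return out


def _bin_id(fm: FragmentMap, fid: int, k: int = 4) -> tuple[str, int]:
    """Bin key matching bin_fragments' anchoring (first fragment, groups of k)."""
    chrom = fm.fragment_chrom(fid)
    offset = fid - fm._id_offset[chrom]  # noqa: SLF001
    return (chrom, offset // k)


def generate(cfg: SyntheticConfig, out_dir: str | Path) -> dict:
    """Emit the full synthetic input directory plus the ground-truth manifest.

    Returns the manifest dict (also written to ``manifest.json``).
    """
    out = cio.ensure_dir(out_dir)
    rng = np.random.default_rng(cfg.seed)
    stages = list(cfg.stages)
    samples = cfg.samples()

    # --- genome, fragments, genes -----------------------------------------
    genome = _random_genome(rng, cfg)
    fm = digest_genome(genome, cfg.motif)
    genes = _place_genes(rng, cfg, list(genome))
    windows = {g.gene_id: promoter_window(g) for g in genes}
    baited = sorted(windows)  # every promoter is baited in the toy design

    cio.write_fasta(out / "genome.fa", genome)
    cio.write_gtf_genes(out / "genes.gtf", genes)
    cio.write_fragment_bed(out / "fragments.bed", fm)

    # --- expression: archetypes, low-TPM decoy genes ----------------------
    gene_ids = [g.gene_id for g in genes]
    n_de = 6 * cfg.n_de_per_cluster
    if n_de + cfg.n_low_tpm_genes >= len(gene_ids):
        raise ValueError("config infeasible: more planted genes than genes")
    perm = rng.permutation(len(gene_ids))
    de_genes = [gene_ids[i] for i in perm[:n_de]]
    low_genes = [gene_ids[i] for i in perm[n_de : n_de + cfg.n_low_tpm_genes]]
    flat_genes = [gene_ids[i] for i in perm[n_de + cfg.n_low_tpm_genes :]]

    de_cluster = {g: 1 + i // cfg.n_de_per_cluster for i, g in enumerate(de_genes)}
    tpm_mean = pd.DataFrame(cfg.base_tpm, index=gene_ids, columns=stages, dtype=float)
    for g, c in de_cluster.items():
        stage, direction = ARCHETYPES[c - 1]
        tpm_mean.loc[g, stage] = (
            cfg.base_tpm * cfg.de_fold if direction == "up" else cfg.base_tpm / cfg.de_fold
        )
    for g in low_genes:
        tpm_mean.loc[g, :] = cfg.low_tpm

    gene_len = pd.Series({g.gene_id: sum(len(e) for e in g.exons) for g in genes})
    rna_counts = pd.DataFrame(index=gene_ids, dtype=int)
    for sample, stage in samples:
        lam = tpm_mean[stage].to_numpy() * gene_len.to_numpy() / 1e3
        lam = lam / lam.sum() * cfg.rna_depth
        rna_counts[f"rna_{sample}"] = _nb_draw(rng, lam, cfg.nb_dispersion)
    tpm_obs = tpm_transform(rna_counts, gene_len)
    cio.write_count_matrix(out / "rna_counts.tsv", rna_counts)
    cio.write_count_matrix(out / "tpm.tsv", tpm_obs.round(4))
    cio.write_stage_map(out / "rna_stage_map.yaml",
                        {f"rna_{s}": st for s, st in samples})

    # --- plant OCRs --------------------------------------------------------
    candidates = _candidate_fragments(fm, list(windows.values()))
    cand = list(rng.permutation(np.array(candidates)))

    used_bins: set[tuple[str, int]] = set()

    def take_fragment(reserve_bin: bool) -> int:
        while cand:
            fid = int(cand.pop())
            b = _bin_id(fm, fid)
            if b in used_bins:
                continue
            if reserve_bin:
                used_bins.add(b)
            return fid
        raise ValueError("config infeasible: not enough clear fragments")

    def ocr_in_fragment(fid: int) -> GenomicInterval:
        frag = fm.fragment(fid)
        width = min(300, len(frag) - 120)
        start = frag.start + 60
        return GenomicInterval(fm.fragment_chrom(fid), start, start + width)

    def random_open_pattern() -> list[str]:
        k = int(rng.integers(1, len(stages) + 1))
        return sorted(rng.choice(stages, size=k, replace=False).tolist())

    planted: list[dict] = []
    expressed_pool = [g for g in flat_genes]  # flat genes have TPM > 1 everywhere

    # promoter OCRs: centered on a gene TSS
    prom_genes = list(rng.choice(np.array(sorted(set(gene_ids))), size=cfg.n_promoter_ocrs,
                                 replace=False))
    tss_of = {g.gene_id: (g.chrom, g.tss) for g in genes}
    for i, gid in enumerate(prom_genes):
        chrom, tss = tss_of[gid]
        iv = GenomicInterval(chrom, tss - 150, tss + 150)
        planted.append({
            "name": f"p_prom_{i}", "kind": "promoter", "chrom": iv.chrom,
            "start": iv.start, "end": iv.end, "open_stages": random_open_pattern(),
            "gene": gid,
        })

    # PIR OCRs: distal fragment + significant contact to a bait gene
    n_low_pir = min(3, cfg.n_pir_ocrs)  # contacts to low-TPM genes (decoy route d)
    pir_records = []
    for i in range(cfg.n_pir_ocrs):
        fid = take_fragment(reserve_bin=True)
        iv = ocr_in_fragment(fid)
        if i < cfg.n_pir_ocrs - n_low_pir:
            gid = expressed_pool[int(rng.integers(len(expressed_pool)))]
        else:
            gid = low_genes[int(rng.integers(len(low_genes)))]
        open_st = random_open_pattern()
        use_frag4 = bool(rng.random() < cfg.frag4_fraction)
        rec = {
            "name": f"p_pir_{i}", "kind": "pir", "chrom": iv.chrom,
            "start": iv.start, "end": iv.end, "open_stages": open_st,
            "gene": gid, "oe_frag_id": fid, "frag4": use_frag4,
        }
        planted.append(rec)
        pir_records.append(rec)

    # non-PIR OCRs (incl. differentially accessible subset) and closed OCRs
    for i in range(cfg.n_nonpir_ocrs):
        fid = take_fragment(reserve_bin=True)
        iv = ocr_in_fragment(fid)
        planted.append({
            "name": f"p_nonpir_{i}", "kind": "nonpir", "chrom": iv.chrom,
            "start": iv.start, "end": iv.end, "open_stages": random_open_pattern(),
        })
    for i in range(cfg.n_da_regions):
        fid = take_fragment(reserve_bin=True)
        iv = ocr_in_fragment(fid)
        direction = "up" if rng.random() < 0.5 else "down"  # HP vs ESC
        planted.append({
            "name": f"p_da_{i}", "kind": "da", "chrom": iv.chrom,
            "start": iv.start, "end": iv.end, "open_stages": ["ESC", "HP"],
            "da_direction": direction, "da_contrast": ["ESC", "HP"],
        })
    for i in range(cfg.n_closed_ocrs):
        fid = take_fragment(reserve_bin=True)
        iv = ocr_in_fragment(fid)
        planted.append({
            "name": f"p_closed_{i}", "kind": "closed", "chrom": iv.chrom,
            "start": iv.start, "end": iv.end, "open_stages": [],
        })

    # expected cRE class per open stage
    for rec in planted:
        if rec["kind"] == "promoter":
            rec["expected_class"] = {s: "PromoterOCR" for s in rec["open_stages"]}
        elif rec["kind"] == "pir":
            rec["expected_class"] = {s: "PIR_OCR" for s in rec["open_stages"]}
        elif rec["kind"] in ("nonpir", "da"):
            rec["expected_class"] = {s: "NonPIR_OCR" for s in rec["open_stages"]}
        else:
            rec["expected_class"] = {}

    # --- replicate peaks ----------------------------------------------------
    rep_peaks: dict[str, list[GenomicInterval]] = {s: [] for s, _ in samples}
    by_stage_samples = {st: [s for s, s_st in samples if s_st == st] for st in stages}
    for rec in planted:
        peak_stages = stages if rec["kind"] == "closed" else rec["open_stages"]
        for st in peak_stages:
            reps = by_stage_samples[st]
            need = math.ceil(len(reps) / 2)
            n_in = len(reps) - int(rng.binomial(len(reps), cfg.peak_dropout))
            n_in = max(need, n_in)
            chosen = rng.choice(len(reps), size=n_in, replace=False)
            for ri in sorted(chosen):
                j0 = int(rng.integers(0, 21))
                j1 = int(rng.integers(0, 21))
                rep_peaks[reps[ri]].append(
                    GenomicInterval(rec["chrom"], rec["start"] - j0, rec["end"] + j1)
                )
    # decoy peaks: one replicate each, never reproducible
    for i in range(cfg.n_decoy_peaks):
        fid = take_fragment(reserve_bin=True)
        iv = ocr_in_fragment(fid)
        sample = samples[int(rng.integers(len(samples)))][0]
        rep_peaks[sample].append(iv)

    peaks_dir = cio.ensure_dir(out / "peaks")
    for sample, _ in samples:
        ivs = sorted(rep_peaks[sample], key=lambda p: (p.chrom, p.start, p.end))
        cio.write_bed(peaks_dir / f"{sample}.bed", ivs)

    # --- consensus (the pipeline's own merge) and OCR counts ---------------
    replicates = [PeakReplicate(s, st, rep_peaks[s]) for s, st in samples]
    consensus = build_consensus(replicates, per_stage=True)
    # match each consensus OCR to exactly one planted OCR
    match: dict[str, dict] = {}
    for o in consensus:
        hits = [r for r in planted
                if r["chrom"] == o.interval.chrom
                and o.interval.start < r["end"] and r["start"] < o.interval.end]
        if len(hits) != 1:
            raise ValueError("config infeasible: consensus/planted mismatch")
        match[o.ocr_id] = hits[0]
        hits[0]["consensus_id"] = o.ocr_id
    if len(match) != len(planted):
        # decoy peaks must not survive; every planted OCR must survive
        raise ValueError("config infeasible: consensus size mismatch")

    atac_lib = pd.Series(
        {s: cfg.atac_depth * (1 + 0.1 * rng.standard_normal()) for s, _ in samples}
    ).round(0)
    ocr_counts = pd.DataFrame(index=[o.ocr_id for o in consensus], dtype=int)
    fpkm_target: dict[tuple[str, str], float] = {}
    for o in consensus:
        rec = match[o.ocr_id]
        for st in stages:
            f = cfg.open_fpkm if st in rec["open_stages"] else cfg.closed_fpkm
            if rec["kind"] == "da" and st in rec.get("da_contrast", []):
                hi = cfg.open_fpkm * cfg.da_fold
                if rec["da_direction"] == "up":
                    f = hi if st == "HP" else cfg.open_fpkm
                else:
                    f = hi if st == "ESC" else cfg.open_fpkm
            fpkm_target[(o.ocr_id, st)] = f
    for sample, st in samples:
        lam = np.array([
            fpkm_target[(o.ocr_id, st)] * (o.length / 1e3) * (atac_lib[sample] / 1e6)
            for o in consensus
        ])
        ocr_counts[sample] = _nb_draw(rng, lam, cfg.nb_dispersion)
    cio.write_count_matrix(out / "ocr_counts.tsv", ocr_counts)
    atac_lib.rename("lib_size").to_csv(out / "atac_lib_sizes.tsv", sep="\t")
    cio.write_stage_map(out / "atac_stage_map.yaml", dict(samples))

    # --- background 10-kb bins ---------------------------------------------
    bin_rows = []
    bin_index = []
    for chrom in genome:
        for b0 in range(0, cfg.chrom_length, 10_000):
            bin_index.append(f"{chrom}:{b0}")
            bin_rows.append((chrom, b0))
    bin_counts = pd.DataFrame(index=bin_index, dtype=int)
    for sample, _ in samples:
        depth = atac_lib[sample] / cfg.atac_depth
        bin_counts[sample] = _nb_draw(
            rng, np.full(len(bin_index), 200.0 * depth), cfg.nb_dispersion
        )
    cio.write_count_matrix(out / "bin_counts.tsv", bin_counts)

    # --- interactions -------------------------------------------------------
    fm4 = None
    ibed_rows = []
    bait_frag = {g.gene_id: fm.fragment_id_at(g.chrom, g.tss) for g in genes}
    for rec in pir_records:
        bf = bait_frag[rec["gene"]]
        b_iv = fm.fragment(bf)
        if rec["frag4"]:
            if fm4 is None:
                fm4 = bin_fragments(fm, 4)
            chrom = rec["chrom"]
            oe_iv = fm4.fragment(fm4.fragment_id_at(chrom, rec["start"]))
            resolution = "frag4"
        else:
            oe_iv = fm.fragment(rec["oe_frag_id"])
            resolution = "frag1"
        scores = {}
        for st in rec["open_stages"]:
            score = float(rng.uniform(*cfg.score_sig))
            scores[st] = round(score, 3)
            ibed_rows.append((
                fm.fragment_chrom(bf), b_iv.start, b_iv.end, rec["gene"],
                rec["chrom"], oe_iv.start, oe_iv.end, scores[st], resolution, st,
            ))
        rec["contact_scores"] = scores
    # decoy sub-threshold interactions to non-PIR fragments
    nonpir = [r for r in planted if r["kind"] in ("nonpir", "da")]
    for i in range(min(20, len(nonpir))):
        rec = nonpir[i]
        gid = expressed_pool[int(rng.integers(len(expressed_pool)))]
        bf = bait_frag[gid]
        b_iv = fm.fragment(bf)
        oe_iv = fm.fragment(fm.fragment_id_at(rec["chrom"], rec["start"]))
        st = stages[int(rng.integers(len(stages)))]
        ibed_rows.append((
            fm.fragment_chrom(bf), b_iv.start, b_iv.end, gid,
            rec["chrom"], oe_iv.start, oe_iv.end,
            round(float(rng.uniform(*cfg.score_decoy)), 3), "frag1", st,
        ))
    ibed = pd.DataFrame(ibed_rows, columns=cio.IBED_COLUMNS)
    cio.write_ibed(out / "interactions.ibed.tsv", ibed)

    # --- traits: sentinels, proxies, planted links and decoys ---------------
    stage_tpm = tpm_obs.T.groupby(pd.Series({f"rna_{s}": st for s, st in samples})).mean().T
    good_pirs = [r for r in pir_records
                 if r["open_stages"] and r["gene"] in set(flat_genes)
                 and (stage_tpm.loc[r["gene"], r["open_stages"]] > 1).all()]
    low_pirs = [r for r in pir_records if r["gene"] in set(low_genes) and r["open_stages"]]
    open_nonpirs = [r for r in planted if r["kind"] == "nonpir" and r["open_stages"]]
    closed_ocrs = [r for r in planted if r["kind"] == "closed"]
    need = cfg.n_traits * (cfg.links_per_trait + 1) + 1
    if len(good_pirs) < need or not low_pirs or not open_nonpirs or not closed_ocrs:
        raise ValueError("config infeasible: not enough planted regions for traits")

    def pos_in(rec: dict) -> int:
        return int(rng.integers(rec["start"], rec["end"]))

    def boring_position() -> tuple[str, int]:
        fid = take_fragment(reserve_bin=True)
        frag = fm.fragment(fid)
        return fm.fragment_chrom(fid), (frag.start + frag.end) // 2

    proxy_rows = []
    sentinel_rows = []
    planted_links = []
    decoys: dict[str, list[dict]] = {"low_r2": [], "closed": [], "no_contact": [], "low_tpm": []}
    pir_cursor = 0
    # the first link gene is shared between the first two traits
    shared_rec = good_pirs[pir_cursor]
    for t in range(cfg.n_traits):
        trait = f"trait{t + 1}"
        sents = [f"rs{t + 1}{k + 1}00" for k in range(cfg.sentinels_per_trait)]
        for s in sents:
            sentinel_rows.append((trait, s))
        # last sentinel is not in the reference panel: no rows at all
        in_panel = sents[:-1]
        for s in in_panel:
            chrom, pos0 = boring_position()
            proxy_rows.append((trait, s, s, chrom, pos0 + 1, 1.0))
        # planted links on the first sentinels
        for k in range(cfg.links_per_trait):
            if t < 2 and k == 0:
                rec = shared_rec
            else:
                pir_cursor += 1
                rec = good_pirs[pir_cursor]
            proxy = f"rs{t + 1}{k + 1}01"
            pos0 = pos_in(rec)
            r2 = round(float(rng.uniform(0.7, 0.99)), 3)
            proxy_rows.append((trait, in_panel[k], proxy, rec["chrom"], pos0 + 1, r2))
            planted_links.append({
                "trait": trait, "sentinel": in_panel[k], "proxy": proxy,
                "chrom": rec["chrom"], "pos": pos0 + 1, "ocr": rec["name"],
                "gene": rec["gene"], "stages": rec["open_stages"], "r2": r2,
            })
        # one decoy of each class on the last in-panel sentinel
        s = in_panel[-1]
        pir_cursor += 1
        rec = good_pirs[pir_cursor]
        pos0 = pos_in(rec)
        proxy_rows.append((trait, s, f"rs{t + 1}d1", rec["chrom"], pos0 + 1, 0.4))
        decoys["low_r2"].append({"trait": trait, "sentinel": s, "proxy": f"rs{t + 1}d1",
                                 "ocr": rec["name"], "r2": 0.4})
        rec = closed_ocrs[t % len(closed_ocrs)]
        pos0 = pos_in(rec)
        proxy_rows.append((trait, s, f"rs{t + 1}d2", rec["chrom"], pos0 + 1, 0.85))
        decoys["closed"].append({"trait": trait, "sentinel": s, "proxy": f"rs{t + 1}d2",
                                 "ocr": rec["name"]})
        rec = open_nonpirs[t % len(open_nonpirs)]
        pos0 = pos_in(rec)
        proxy_rows.append((trait, s, f"rs{t + 1}d3", rec["chrom"], pos0 + 1, 0.85))
        decoys["no_contact"].append({"trait": trait, "sentinel": s, "proxy": f"rs{t + 1}d3",
                                     "ocr": rec["name"]})
        rec = low_pirs[t % len(low_pirs)]
        pos0 = pos_in(rec)
        proxy_rows.append((trait, s, f"rs{t + 1}d4", rec["chrom"], pos0 + 1, 0.85))
        decoys["low_tpm"].append({"trait": trait, "sentinel": s, "proxy": f"rs{t + 1}d4",
                                  "ocr": rec["name"], "gene": rec["gene"]})

    proxies = pd.DataFrame(proxy_rows, columns=cio.PROXY_COLUMNS)
    cio.write_proxy_table(out / "traits.tsv", proxies)
    pd.DataFrame(sentinel_rows, columns=["trait", "sentinel"]).to_csv(
        out / "sentinels.tsv", sep="\t", index=False
    )

    # --- TF binding sites ----------------------------------------------------
    cre_recs = [r for r in planted if r["kind"] in ("promoter", "pir") and r["open_stages"]]
    all_open = [r for r in planted if r["open_stages"]]
    site_rows = []
    for t in range(cfg.n_tfs_enriched):
        tf = f"TF_enr_{t + 1}"
        for _ in range(cfg.sites_per_tf):
            rec = cre_recs[int(rng.integers(len(cre_recs)))]
            s0 = pos_in(rec)
            site_rows.append((tf, rec["chrom"], s0, min(s0 + 10, rec["end"]),
                              round(float(rng.uniform(0.75, 0.99)), 3)))
        # low-purity sites land anywhere; they must be ignored by the filter
        for _ in range(cfg.sites_per_tf // 2):
            rec = all_open[int(rng.integers(len(all_open)))]
            s0 = pos_in(rec)
            site_rows.append((tf, rec["chrom"], s0, min(s0 + 10, rec["end"]),
                              round(float(rng.uniform(0.3, 0.7)), 3)))
    for t in range(cfg.n_tfs_null):
        tf = f"TF_null_{t + 1}"
        for _ in range(cfg.sites_per_tf):
            rec = all_open[int(rng.integers(len(all_open)))]
            s0 = pos_in(rec)
            site_rows.append((tf, rec["chrom"], s0, min(s0 + 10, rec["end"]),
                              round(float(rng.uniform(0.75, 0.99)), 3)))
    pd.DataFrame(site_rows, columns=["tf_id", "chrom", "start", "end", "purity"]).to_csv(
        out / "tf_sites.tsv", sep="\t", index=False
    )

    # --- manifest ------------------------------------------------------------
    manifest = {
        "config": {k: (v if not isinstance(v, tuple) else list(v))
                   for k, v in asdict(cfg).items()},
        "stages": stages,
        "baited_promoters": baited,
        "planted_ocrs": planted,
        "planted_de": de_cluster,
        "low_tpm_genes": low_genes,
        "planted_da": [
            {"name": r["name"], "direction": r["da_direction"],
             "contrast": r["da_contrast"], "consensus_id": r["consensus_id"]}
            for r in planted if r["kind"] == "da"
        ],
        "planted_links": planted_links,
        "decoys": decoys,
        "planted_tfs": [f"TF_enr_{t + 1}" for t in range(cfg.n_tfs_enriched)],
        "null_tfs": [f"TF_null_{t + 1}" for t in range(cfg.n_tfs_null)],
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


# ---------------------------------------------------------------------------
# validation


def validate_manifest(out_dir: str | Path, manifest: dict | None = None) -> dict:
    """Cross-check every manifest entry against the emitted files.

    Returns {"ok": bool, "failures": [...]}; a missing file raises.
    """
    out = Path(out_dir)
    if manifest is None:
        with open(out / "manifest.json") as fh:
            manifest = json.load(fh)
    failures: list[str] = []

    stage_map = cio.read_stage_map(out / "atac_stage_map.yaml")
    by_stage: dict[str, list[str]] = {}
    for s, st in stage_map.items():
        by_stage.setdefault(st, []).append(s)
    peaks = {s: cio.read_bed(out / "peaks" / f"{s}.bed") for s in stage_map}

    def n_reps_with_peak(rec: dict, stage: str) -> int:
        n = 0
        for s in by_stage[stage]:
            if any(p.chrom == rec["chrom"] and p.start < rec["end"] and rec["start"] < p.end
                   for p in peaks[s]):
                n += 1
        return n

    for rec in manifest["planted_ocrs"]:
        check_stages = rec["open_stages"] or (
            list(by_stage) if rec["kind"] == "closed" else []
        )
        ok = any(
            n_reps_with_peak(rec, st) >= math.ceil(len(by_stage[st]) / 2)
            for st in check_stages
        )
        if not ok:
            failures.append(f"planted OCR {rec['name']} not reproducible in any stage")

    ibed = cio.read_ibed(out / "interactions.ibed.tsv")
    for rec in manifest["planted_ocrs"]:
        if rec["kind"] != "pir":
            continue
        for st, score in rec["contact_scores"].items():
            hit = ibed[
                (ibed["stage"] == st)
                & (ibed["bait_name"] == rec["gene"])
                & (ibed["oe_chrom"] == rec["chrom"])
                & (ibed["oe_start"] <= rec["start"])
                & (ibed["oe_end"] >= rec["end"])
                & (ibed["score"] > 5)
            ]
            if hit.empty:
                failures.append(f"planted contact missing: {rec['name']} stage {st}")

    proxies = cio.read_proxy_table(out / "traits.tsv")
    tpm_obs = cio.read_count_matrix(out / "tpm.tsv")
    rna_stage = cio.read_stage_map(out / "rna_stage_map.yaml")
    stage_tpm = tpm_obs.T.groupby(pd.Series(rna_stage)).mean().T
    ocr_by_name = {r["name"]: r for r in manifest["planted_ocrs"]}
    for link in manifest["planted_links"]:
        row = proxies[(proxies["trait"] == link["trait"]) & (proxies["proxy"] == link["proxy"])]
        if row.empty:
            failures.append(f"planted proxy {link['proxy']} missing from traits.tsv")
            continue
        if not (row["r2"] > 0.6).all():
            failures.append(f"planted proxy {link['proxy']} has r2 <= 0.6")
        rec = ocr_by_name[link["ocr"]]
        pos0 = int(row["pos"].iloc[0]) - 1
        if not (rec["start"] <= pos0 < rec["end"]):
            failures.append(f"planted proxy {link['proxy']} outside its OCR")
        if not (stage_tpm.loc[link["gene"], link["stages"]] > 1).all():
            failures.append(f"planted link gene {link['gene']} not expressed")

    for d in manifest["decoys"]["low_r2"]:
        row = proxies[(proxies["trait"] == d["trait"]) & (proxies["proxy"] == d["proxy"])]
        if row.empty or not (row["r2"] <= 0.6).all():
            failures.append(f"low_r2 decoy {d['proxy']} mislabelled")
    for d in manifest["decoys"]["closed"]:
        if ocr_by_name[d["ocr"]]["open_stages"]:
            failures.append(f"closed decoy {d['proxy']} points at an open OCR")
    for d in manifest["decoys"]["no_contact"]:
        rec = ocr_by_name[d["ocr"]]
        hit = ibed[(ibed["oe_chrom"] == rec["chrom"]) & (ibed["oe_start"] <= rec["start"])
                   & (ibed["oe_end"] >= rec["end"]) & (ibed["score"] > 5)]
        if not hit.empty:
            failures.append(f"no_contact decoy {d['proxy']} has a significant contact")
    for d in manifest["decoys"]["low_tpm"]:
        if (stage_tpm.loc[d["gene"]] > 1).any():
            failures.append(f"low_tpm decoy gene {d['gene']} is expressed somewhere")

    return {"ok": not failures, "failures": failures}
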