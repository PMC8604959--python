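"""End-to-end orchestration of the atlas -> differential -> clustering ->
variant-to-gene -> enrichment pipeline.

A single RunConfig carries every input path and threshold (the printed
defaults: r2 > 0.6, CHiCAGO-style score > 5, TPM > 1, FPKM > 1 openness,
median-CPM filters 0.7 / 1.2, FDR < 0.05, |log2FC| > 1, purity > 0.7,
10,000 permutations, 6 clusters); no stage hard-codes a threshold.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as cio
from .atlas import (
    ConsensusOCR,
    PeakReplicate,
    build_consensus,
    class_counts,
    classify_ocrs,
    gene_cre_map,
    quantify_openness,
    significant_interactions,
)
from .countstats import (
    background_bin_factors,
    cluster_de_genes,
    differential_test,
    filter_by_median_cpm,
    tmm_factors,
)
from .enrichment import hypergeom_test_sets, read_gmt, tf_site_enrichment
from .genome import promoter_window
from .simulate import SyntheticConfig, generate, validate_manifest
from .v2g import (
    cross_trait_overlap,
    expand_proxies,
    filter_expressed,
    find_open_proxies,
    map_to_genes,
    summarize_trait,
)

log = logging.getLogger("crev2g")

__all__ = ["RunConfig", "run_atlas", "run_differential", "run_cluster",
           "run_v2g", "run_enrich", "run_all"]


@dataclass
class RunConfig:
    """All inputs and thresholds for one pipeline run."""

    input_dir: str
    out_dir: str
    seed: int = 0
    # thresholds (defaults are the published conventions)
    r2_min: float = 0.6
    score_min: float = 5.0
    tpm_min: float = 1.0
    fpkm_open: float = 1.0
    cpm_filter_rna: float = 0.7
    cpm_filter_atac: float = 1.2
    fdr: float = 0.05
    lfc: float = 1.0
    purity_min: float = 0.7
    n_perm: int = 10000
    n_perm_tf: int = 500
    k_clusters: int = 6
    # behaviour switches
    per_stage_reproducibility: bool = True
    stage_specific_contacts: bool = True
    drop_bait_to_bait: bool = False
    # optional extras
    gene_sets: str | None = None
    # file names inside input_dir
    files: dict[str, str] = field(default_factory=lambda: {
        "genome": "genome.fa",
        "genes": "genes.gtf",
        "fragments": "fragments.bed",
        "peaks_dir": "peaks",
        "atac_stage_map": "atac_stage_map.yaml",
        "ocr_counts": "ocr_counts.tsv",
        "atac_lib_sizes": "atac_lib_sizes.tsv",
        "bin_counts": "bin_counts.tsv",
        "interactions": "interactions.ibed.tsv",
        "rna_counts": "rna_counts.tsv",
        "rna_stage_map": "rna_stage_map.yaml",
        "tpm": "tpm.tsv",
        "traits": "traits.tsv",
        "sentinels": "sentinels.tsv",
        "tf_sites": "tf_sites.tsv",
    })

    def path(self, key: str) -> Path:
        p = Path(self.input_dir) / self.files[key]
        if not p.exists():
            raise FileNotFoundError(f"required input {key!r} missing: {p}")
        return p

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in data.items() if k in known})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _checksum(path: Path) -> str:
    h = hashlib.md5()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_atlas_inputs(cfg: RunConfig):
    fm = cio.read_fragment_bed(cfg.path("fragments"))
    genes = cio.read_gtf_genes(cfg.path("genes"))
    windows = {g.gene_id: promoter_window(g) for g in genes}
    return fm, genes, windows


def _stage_pairs(stage_map: dict[str, str]) -> list[tuple[str, str]]:
    stages = sorted(set(stage_map.values()))
    order = {"ESC": 0, "HP": 1, "HN": 2}
    stages.sort(key=lambda s: (order.get(s, 99), s))
    return list(zip(stages, stages[1:]))


def run_atlas(cfg: RunConfig) -> dict:
    """Consensus OCRs, openness, cRE classes and gene-cRE links."""
    out = cio.ensure_dir(Path(cfg.out_dir) / "atlas")
    stage_map = cio.read_stage_map(cfg.path("atac_stage_map"))
    peaks_dir = cfg.path("peaks_dir")
    replicates = [
        PeakReplicate(s, st, cio.read_bed(peaks_dir / f"{s}.bed"))
        for s, st in sorted(stage_map.items())
    ]
    ocrs = build_consensus(replicates, per_stage=cfg.per_stage_reproducibility)
    log.info("consensus OCRs: %d", len(ocrs))

    counts = cio.read_count_matrix(cfg.path("ocr_counts"))
    lib = pd.read_csv(cfg.path("atac_lib_sizes"), sep="\t", index_col=0)["lib_size"]
    ocrs = quantify_openness(ocrs, counts, stage_map, lib_sizes=lib,
                             fpkm_open=cfg.fpkm_open)

    fm, genes, windows = _load_atlas_inputs(cfg)
    ibed = cio.read_ibed(cfg.path("interactions"))
    sig = significant_interactions(ibed, fm, score_min=cfg.score_min)
    ocrs = classify_ocrs(ocrs, windows, sig, fm,
                         stage_specific=cfg.stage_specific_contacts)
    links, summary = gene_cre_map(ocrs, sig, windows, genes, fm,
                                  stage_specific=cfg.stage_specific_contacts)

    stages = sorted(set(stage_map.values()))
    rows = []
    for o in ocrs:
        row = {"ocr_id": o.ocr_id, "chrom": o.interval.chrom,
               "start": o.interval.start, "end": o.interval.end}
        for s in stages:
            row[f"support_{s}"] = o.support.get(s, 0)
            row[f"fpkm_{s}"] = round(o.fpkm.get(s, 0.0), 4)
            row[f"open_{s}"] = o.open_in.get(s, False)
            row[f"class_{s}"] = o.cre_class.get(s, "")
        rows.append(row)
    ocr_table = pd.DataFrame(rows)
    ocr_table.to_csv(out / "ocrs.tsv", sep="\t", index=False)
    cio.write_bed(out / "ocrs.bed", [o.interval for o in ocrs],
                  names=[o.ocr_id for o in ocrs])
    links.to_csv(out / "gene_cre_links.tsv", sep="\t", index=False)
    summary.to_csv(out / "gene_cre_summary.tsv", sep="\t", index=False)
    cc = class_counts(ocrs)
    cc.to_csv(out / "class_counts.tsv", sep="\t")
    log.info("class counts:\n%s", cc)
    return {"ocrs": ocrs, "sig": sig, "fm": fm, "genes": genes,
            "windows": windows, "links": links, "class_counts": cc,
            "stage_map": stage_map}


def run_differential(cfg: RunConfig) -> dict:
    """Differential expression (TMM) and accessibility (background bins)."""
    out = cio.ensure_dir(Path(cfg.out_dir) / "differential")
    results: dict[str, pd.DataFrame] = {}

    rna = cio.read_count_matrix(cfg.path("rna_counts"))
    rna_stage = cio.read_stage_map(cfg.path("rna_stage_map"))
    rna_f = filter_by_median_cpm(rna, cfg.cpm_filter_rna)
    for a, b in _stage_pairs(rna_stage):
        cols = [s for s in rna_f.columns if rna_stage[s] in (a, b)]
        sub = rna_f[cols]
        groups = pd.Series({s: rna_stage[s] for s in cols})
        nf = tmm_factors(sub)
        res = differential_test(sub, groups, factors=nf,
                                alpha=cfg.fdr, lfc_min=cfg.lfc)
        key = f"rna_{a}_vs_{b}"
        res.to_csv(out / f"{key}.tsv", sep="\t")
        results[key] = res

    atac = cio.read_count_matrix(cfg.path("ocr_counts"))
    bins = cio.read_count_matrix(cfg.path("bin_counts"))
    atac_stage = cio.read_stage_map(cfg.path("atac_stage_map"))
    atac_f = filter_by_median_cpm(atac, cfg.cpm_filter_atac)
    for a, b in _stage_pairs(atac_stage):
        cols = [s for s in atac_f.columns if atac_stage[s] in (a, b)]
        sub = atac_f[cols]
        groups = pd.Series({s: atac_stage[s] for s in cols})
        nf = background_bin_factors(bins[cols])
        res = differential_test(sub, groups, factors=nf,
                                lib_sizes=atac[cols].sum(axis=0),
                                alpha=cfg.fdr, lfc_min=cfg.lfc)
        key = f"atac_{a}_vs_{b}"
        res.to_csv(out / f"{key}.tsv", sep="\t")
        results[key] = res
    return results


def run_cluster(cfg: RunConfig, differential: dict[str, pd.DataFrame] | None = None) -> dict:
    """Six-branch trajectory clustering of differentially expressed genes."""
    out = cio.ensure_dir(Path(cfg.out_dir) / "cluster")
    if differential is None:
        differential = run_differential(cfg)
    de_genes: set[str] = set()
    for key, res in differential.items():
        if key.startswith("rna_"):
            de_genes |= set(res.index[res["call"] != "ns"])
    tpm_obs = cio.read_count_matrix(cfg.path("tpm"))
    rna_stage = cio.read_stage_map(cfg.path("rna_stage_map"))
    de_tpm = tpm_obs.loc[sorted(de_genes & set(tpm_obs.index))]
    clusters = cluster_de_genes(de_tpm, k=cfg.k_clusters, stage_map=rna_stage)
    clusters.assignments.to_csv(out / "clusters.tsv", sep="\t")
    clusters.cluster_means.round(4).to_csv(out / "cluster_means.tsv", sep="\t")
    return {"clusters": clusters, "n_de_genes": len(de_genes)}


def run_v2g(cfg: RunConfig, atlas: dict | None = None) -> dict:
    """Variant-to-gene mapping from the built atlas."""
    out = cio.ensure_dir(Path(cfg.out_dir) / "v2g")
    if atlas is None:
        atlas = run_atlas(cfg)
    ocrs: list[ConsensusOCR] = atlas["ocrs"]

    raw = cio.read_proxy_table(cfg.path("traits"))
    sent_path = Path(cfg.input_dir) / cfg.files.get("sentinels", "sentinels.tsv")
    sentinels = pd.read_csv(sent_path, sep="\t") if sent_path.exists() else None
    tables = expand_proxies(raw, r2_min=cfg.r2_min, sentinels=sentinels)

    tpm_obs = cio.read_count_matrix(cfg.path("tpm"))
    rna_stage = cio.read_stage_map(cfg.path("rna_stage_map"))

    all_records = []
    summaries = []
    for table in tables:
        hits = find_open_proxies(table, ocrs)
        records = map_to_genes(hits, atlas["sig"], atlas["fm"], atlas["windows"], ocrs)
        records = filter_expressed(records, tpm_obs, rna_stage, tpm_min=cfg.tpm_min)
        all_records.append(records)
        summaries.append(summarize_trait(records, table))
    records = pd.concat(all_records, ignore_index=True) if all_records else pd.DataFrame()
    records.to_csv(out / "v2g_records.tsv", sep="\t", index=False)

    stages = sorted({s for o in ocrs for s in o.open_in})
    summary_df = pd.DataFrame([s.to_row(stages) for s in summaries])
    summary_df.to_csv(out / "trait_summary.tsv", sep="\t", index=False)

    overlap = None
    if len(tables) >= 2 and not records.empty:
        gene_sets = {
            t.trait: set(records.loc[records["trait"] == t.trait, "gene_id"])
            for t in tables
        }
        overlap = cross_trait_overlap(gene_sets)
        overlap.to_csv(out / "cross_trait_overlap.tsv", sep="\t", index=False)
    return {"records": records, "summaries": summaries, "summary_table": summary_df,
            "overlap": overlap}


def _gc_content(seq: str) -> float:
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)


def run_enrich(cfg: RunConfig, atlas: dict | None = None,
               cluster: dict | None = None) -> dict:
    """TF-binding-site enrichment in cREs and optional gene-set enrichment."""
    out = cio.ensure_dir(Path(cfg.out_dir) / "enrich")
    if atlas is None:
        atlas = run_atlas(cfg)
    ocrs: list[ConsensusOCR] = atlas["ocrs"]
    genome = cio.read_fasta(cfg.path("genome"))
    counts = cio.read_count_matrix(cfg.path("ocr_counts"))

    def region_row(o: ConsensusOCR) -> dict:
        seq = genome[o.interval.chrom][o.interval.start:o.interval.end]
        return {"chrom": o.interval.chrom, "start": o.interval.start,
                "end": o.interval.end, "gc": _gc_content(seq),
                "read_count": float(counts.loc[o.ocr_id].sum())}

    fg = [region_row(o) for o in ocrs
          if any(c in ("PromoterOCR", "PIR_OCR") for c in o.cre_class.values())]
    bg = [region_row(o) for o in ocrs
          if o.cre_class and all(c == "NonPIR_OCR" for c in o.cre_class.values())]
    results: dict = {}
    sites_path = Path(cfg.input_dir) / cfg.files["tf_sites"]
    if sites_path.exists() and fg and bg:
        sites = pd.read_csv(sites_path, sep="\t")
        tf = tf_site_enrichment(
            sites, pd.DataFrame(fg), pd.DataFrame(bg),
            purity_min=cfg.purity_min, n_perm=cfg.n_perm_tf, seed=cfg.seed,
        )
        tf.to_csv(out / "tf_enrichment.tsv", sep="\t", index=False)
        results["tf"] = tf

    if cfg.gene_sets and cluster is not None:
        gene_sets = read_gmt(cfg.gene_sets)
        tpm_obs = cio.read_count_matrix(cfg.path("tpm"))
        rna_stage = cio.read_stage_map(cfg.path("rna_stage_map"))
        stage_tpm = tpm_obs.T.groupby(pd.Series(rna_stage)).mean().T
        universe = set(stage_tpm.index[(stage_tpm > cfg.tpm_min).any(axis=1)])
        assignments = cluster["clusters"].assignments
        gs_rows = []
        for cid in sorted(assignments.unique()):
            query = set(assignments.index[assignments == cid])
            df = hypergeom_test_sets(query, gene_sets, universe)
            df.insert(0, "cluster", cid)
            gs_rows.append(df)
        gs = pd.concat(gs_rows, ignore_index=True)
        gs.to_csv(out / "geneset_enrichment.tsv", sep="\t", index=False)
        results["gene_sets"] = gs
    return results


def run_all(cfg: RunConfig, simulate: SyntheticConfig | None = None) -> dict:
    """simulate (optional) -> atlas -> differential -> cluster -> v2g ->
    enrich, with a machine-readable JSON report."""
    out = cio.ensure_dir(cfg.out_dir)
    report: dict = {"config": cfg.to_dict(), "stages": {}}
    if simulate is not None:
        generate(simulate, cfg.input_dir)
        check = validate_manifest(cfg.input_dir)
        if not check["ok"]:
            raise RuntimeError(f"synthetic data failed validation: {check['failures']}")
        report["stages"]["simulate"] = {"ok": True}

    report["input_checksums"] = {
        key: _checksum(Path(cfg.input_dir) / name)
        for key, name in cfg.files.items()
        if (Path(cfg.input_dir) / name).is_file()
    }

    stage = "atlas"
    try:
        atlas = run_atlas(cfg)
        report["stages"]["atlas"] = {
            "n_ocrs": len(atlas["ocrs"]),
            "class_counts": {
                s: row.to_dict() for s, row in atlas["class_counts"].iterrows()
            },
        }
        stage = "differential"
        diff = run_differential(cfg)
        report["stages"]["differential"] = {
            key: {"n_tested": int(len(res)),
                  "n_significant": int((res["call"] != "ns").sum())}
            for key, res in diff.items()
        }
        stage = "cluster"
        cl = run_cluster(cfg, differential=diff)
        report["stages"]["cluster"] = {
            "n_de_genes": cl["n_de_genes"],
            "cluster_sizes": cl["clusters"].assignments.value_counts().sort_index().to_dict(),
        }
        stage = "v2g"
        v2g_out = run_v2g(cfg, atlas=atlas)
        report["stages"]["v2g"] = {
            "n_records": int(len(v2g_out["records"])),
            "trait_summary": v2g_out["summary_table"].to_dict(orient="records"),
        }
        stage = "enrich"
        enr = run_enrich(cfg, atlas=atlas, cluster=cl)
        if "tf" in enr:
            report["stages"]["enrich"] = {
                "n_tf_tested": int(len(enr["tf"])),
                "tf_significant": enr["tf"].loc[enr["tf"]["fdr"] < cfg.fdr, "tf_id"].tolist(),
            }
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=str)
    return report
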