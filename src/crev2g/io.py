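"""Readers and writers for the standard formats the pipeline consumes.

BED is 0-based half-open and passes through unchanged; GTF is 1-based
inclusive and is converted to the internal 0-based half-open convention at
the reader. Count matrices are TSV with a header row of sample ids and a
YAML sidecar mapping sample id -> cell stage.
"""

from __future__ import annotations

import os
from pathlib import Path

import pandas as pd
import yaml
from pyfaidx import Fasta

from .genome import FragmentMap, GeneModel, GenomicInterval

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_bed",
    "write_bed",
    "read_gtf_genes",
    "write_gtf_genes",
    "write_fragment_bed",
    "read_fragment_bed",
    "read_ibed",
    "write_ibed",
    "read_count_matrix",
    "write_count_matrix",
    "read_stage_map",
    "write_stage_map",
    "read_proxy_table",
    "write_proxy_table",
]


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    with Fasta(str(path), as_raw=True, sequence_always_upper=True) as fa:
        return {name: str(fa[name][:]) for name in fa.keys()}


def write_fasta(path: str | os.PathLike, sequences: dict[str, str], width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_bed(path: str | os.PathLike) -> list[GenomicInterval]:
    """BED3+ reader; narrowPeak and other extra columns are ignored."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end = line.split("\t")[:3]
            out.append(GenomicInterval(chrom, int(start), int(end)))
    return out


def write_bed(path: str | os.PathLike, intervals: list[GenomicInterval], names: list[str] | None = None) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            if names is not None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{names[i]}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def write_fragment_bed(path: str | os.PathLike, fm: FragmentMap) -> None:
    """Fragment map as BED4, name = integer fragment id."""
    with open(path, "w") as fh:
        fh.write(f"#motif={fm.motif}\n")
        for fid, chrom, frag in fm.iter_fragments():
            fh.write(f"{chrom}\t{frag.start}\t{frag.end}\t{fid}\n")


def read_fragment_bed(path: str | os.PathLike) -> FragmentMap:
    motif = ""
    frags: dict[str, list[GenomicInterval]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#motif="):
                motif = line.split("=", 1)[1]
                continue
            if not line or line.startswith("#"):
                continue
            chrom, start, end, _fid = line.split("\t")[:4]
            frags.setdefault(chrom, []).append(GenomicInterval(chrom, int(start), int(end)))
    return FragmentMap(frags, motif)


def _parse_gtf_attributes(attr: str) -> dict[str, str]:
    out = {}
    for field in attr.strip().split(";"):
        field = field.strip()
        if not field:
            continue
        key, _, value = field.partition(" ")
        out[key] = value.strip().strip('"')
    return out


def read_gtf_genes(path: str | os.PathLike) -> list[GeneModel]:
    """Build gene models from GTF exon/CDS/UTR records keyed by gene_id.

    GTF coordinates (1-based inclusive) are converted to 0-based half-open.
    The attribute key ``gene_id`` is required on every feature line.
    """
    buckets: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, _src, feature, start, end, _score, strand, _frame, attr = f[:9]
            attrs = _parse_gtf_attributes(attr)
            if "gene_id" not in attrs:
                raise ValueError(f"GTF line missing gene_id attribute: {line!r}")
            gid = attrs["gene_id"]
            iv = GenomicInterval(chrom, int(start) - 1, int(end))
            rec = buckets.setdefault(
                gid, {"chrom": chrom, "strand": strand, "exon": [], "CDS": [],
                      "five_prime_utr": [], "three_prime_utr": []}
            )
            key = {"exon": "exon", "CDS": "CDS", "five_prime_utr": "five_prime_utr",
                   "three_prime_utr": "three_prime_utr", "5UTR": "five_prime_utr",
                   "3UTR": "three_prime_utr"}.get(feature)
            if key is not None:
                rec[key].append(iv)
    genes = []
    for gid, rec in buckets.items():
        genes.append(
            GeneModel(
                gene_id=gid,
                chrom=rec["chrom"],
                strand=rec["strand"],
                exons=rec["exon"],
                cds=sorted(rec["CDS"], key=lambda e: e.start),
                utr5=sorted(rec["five_prime_utr"], key=lambda e: e.start),
                utr3=sorted(rec["three_prime_utr"], key=lambda e: e.start),
            )
        )
    return genes


def write_gtf_genes(path: str | os.PathLike, genes: list[GeneModel]) -> None:
    def line(chrom, feature, iv, strand, gid):
        return (f"{chrom}\tcrev2g\t{feature}\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{strand}\t.\tgene_id \"{gid}\";\n")

    with open(path, "w") as fh:
        for g in genes:
            for iv in g.exons:
                fh.write(line(g.chrom, "exon", iv, g.strand, g.gene_id))
            for iv in g.cds:
                fh.write(line(g.chrom, "CDS", iv, g.strand, g.gene_id))
            for iv in g.utr5:
                fh.write(line(g.chrom, "five_prime_utr", iv, g.strand, g.gene_id))
            for iv in g.utr3:
                fh.write(line(g.chrom, "three_prime_utr", iv, g.strand, g.gene_id))


IBED_COLUMNS = [
    "bait_chrom", "bait_start", "bait_end", "bait_name",
    "oe_chrom", "oe_start", "oe_end", "score", "resolution", "stage",
]


def read_ibed(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(IBED_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"ibed file {path} missing columns: {sorted(missing)}")
    return df


def write_ibed(path: str | os.PathLike, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False, columns=IBED_COLUMNS)


def read_count_matrix(path: str | os.PathLike) -> pd.DataFrame:
    """TSV with row ids in the first column, sample ids in the header."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_count_matrix(path: str | os.PathLike, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t")


def read_stage_map(path: str | os.PathLike) -> dict[str, str]:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return {str(k): str(v) for k, v in data.items()}


def write_stage_map(path: str | os.PathLike, stage_map: dict[str, str]) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dict(stage_map), fh, sort_keys=True)


PROXY_COLUMNS = ["trait", "sentinel", "proxy", "chrom", "pos", "r2"]


def read_proxy_table(path: str | os.PathLike) -> pd.DataFrame:
    """LD proxy TSV; positions are 1-based (VCF-style) in the file."""
    df = pd.read_csv(path, sep="\t")
    missing = set(PROXY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"proxy table {path} missing columns: {sorted(missing)}")
    return df


def write_proxy_table(path: str | os.PathLike, df: pd.DataFrame) -> None:
    cols = PROXY_COLUMNS + [c for c in df.columns if c not in PROXY_COLUMNS]
    df.to_csv(path, sep="\t", index=False, columns=cols)


def ensure_dir(path: str | os.PathLike) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
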