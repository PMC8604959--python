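"""Genome coordinate model.

Intervals, restriction-fragment maps, gene models, promoter windows and the
hierarchical feature annotator. All coordinates are 0-based half-open (BED
convention); readers for 1-based formats convert on input.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "FragmentMap",
    "FEATURE_HIERARCHY",
    "digest_genome",
    "promoter_window",
    "annotate_feature",
    "intersect",
    "bin_fragments",
]

# Feature labels in priority order: an interval touching several features
# receives the highest-priority (lowest-rank) label.
FEATURE_HIERARCHY = (
    "Promoter",
    "5UTR",
    "CDS",
    "3UTR",
    "FirstIntron",
    "OtherIntron",
    "Intergenic",
)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains_point(self, chrom: str, pos: int) -> bool:
        """Half-open containment of a 0-based point."""
        return chrom == self.chrom and self.start <= pos < self.end


@dataclass
class GeneModel:
    """A gene with its TSS, strand, and exon structure.

    Exons are sorted by coordinate and non-overlapping. The TSS is the 5'
    end of the first exon on the annotated strand: ``exons[0].start`` on
    ``+``, ``exons[-1].end - 1`` on ``-`` (as a 0-based base position).
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[GenomicInterval]
    cds: list[GenomicInterval] = field(default_factory=list)
    utr5: list[GenomicInterval] = field(default_factory=list)
    utr3: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")
        if not self.exons:
            raise ValueError(f"gene {self.gene_id}: at least one exon required")
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if a.end > b.start:
                raise ValueError(f"gene {self.gene_id}: overlapping exons")

    @property
    def tss(self) -> int:
        if self.strand == "+":
            return self.exons[0].start
        return self.exons[-1].end - 1

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.exons[0].start, self.exons[-1].end)

    def introns(self) -> list[GenomicInterval]:
        """Gaps between consecutive exons, in genomic order."""
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:
                out.append(GenomicInterval(self.chrom, a.end, b.start))
        return out

    def first_intron(self) -> GenomicInterval | None:
        """The intron between exon 1 and exon 2 on the annotated strand."""
        gaps = self.introns()
        if not gaps:
            return None
        return gaps[0] if self.strand == "+" else gaps[-1]


class FragmentMap:
    """A gap-free restriction-fragment tiling of each chromosome.

    Fragments carry consecutive integer ids in emission order (per
    chromosome, left to right, chromosomes in insertion order).
    """

    def __init__(self, fragments_by_chrom: dict[str, list[GenomicInterval]], motif: str):
        self.motif = motif
        self.fragments_by_chrom = fragments_by_chrom
        self._starts: dict[str, list[int]] = {}
        self._id_offset: dict[str, int] = {}
        self._index: list[tuple[str, GenomicInterval]] = []
        for chrom, frags in fragments_by_chrom.items():
            if not frags:
                raise ValueError(f"{chrom}: empty fragment list")
            for a, b in zip(frags, frags[1:]):
                if a.end != b.start:
                    raise ValueError(f"{chrom}: fragments not adjacent at {a.end}")
            self._id_offset[chrom] = len(self._index)
            self._starts[chrom] = [f.start for f in frags]
            self._index.extend((chrom, f) for f in frags)

    def __len__(self) -> int:
        return len(self._index)

    def fragment(self, frag_id: int) -> GenomicInterval:
        return self._index[frag_id][1]

    def fragment_chrom(self, frag_id: int) -> str:
        return self._index[frag_id][0]

    def iter_fragments(self) -> Iterable[tuple[int, str, GenomicInterval]]:
        for fid, (chrom, frag) in enumerate(self._index):
            yield fid, chrom, frag

    def fragment_id_at(self, chrom: str, pos: int) -> int:
        """Id of the fragment containing 0-based position ``pos``."""
        if chrom not in self._starts:
            raise KeyError(f"chromosome {chrom!r} not in fragment map")
        starts = self._starts[chrom]
        i = bisect.bisect_right(starts, pos) - 1
        frags = self.fragments_by_chrom[chrom]
        if i < 0 or pos >= frags[i].end:
            raise ValueError(f"position {chrom}:{pos} outside fragment map")
        return self._id_offset[chrom] + i

    def overlapping_fragment_ids(self, iv: GenomicInterval) -> list[int]:
        """Ids of all fragments overlapping ``iv`` by >= 1 bp."""
        if iv.chrom not in self._starts:
            raise KeyError(f"chromosome {iv.chrom!r} not in fragment map")
        starts = self._starts[iv.chrom]
        frags = self.fragments_by_chrom[iv.chrom]
        off = self._id_offset[iv.chrom]
        i = max(0, bisect.bisect_right(starts, iv.start) - 1)
        out = []
        while i < len(frags) and frags[i].start < iv.end:
            if frags[i].end > iv.start:
                out.append(off + i)
            i += 1
        return out


def digest_genome(sequence_by_chrom: dict[str, str], motif: str) -> FragmentMap:
    """In-silico restriction digest.

    The cut is placed immediately 5' of each motif occurrence, so each
    fragment except the first begins with the motif (DpnII-style blunt
    ^GATC cutting). Overlapping motif occurrences each produce a cut.
    """
    if not motif:
        raise ValueError("motif must be non-empty")
    motif = motif.upper()
    frag_map: dict[str, list[GenomicInterval]] = {}
    for chrom, seq in sequence_by_chrom.items():
        if not seq:
            raise ValueError(f"{chrom}: empty sequence")
        seq = seq.upper()
        cuts = [0]
        i = seq.find(motif)
        while i != -1:
            if i > 0:
                cuts.append(i)
            i = seq.find(motif, i + 1)
        cuts.append(len(seq))
        frag_map[chrom] = [
            GenomicInterval(chrom, a, b) for a, b in zip(cuts, cuts[1:])
        ]
    return FragmentMap(frag_map, motif)


def promoter_window(
    gene: GeneModel, upstream: int = 1500, downstream: int = 500
) -> GenomicInterval:
    """Strand-aware promoter window around the TSS, clipped at 0.

    On ``+`` the window is ``[tss - upstream, tss + downstream)``; on ``-``
    it is mirrored around the TSS base.
    """
    tss = gene.tss
    if gene.strand == "+":
        start, end = tss - upstream, tss + downstream
    else:
        start, end = tss - downstream, tss + upstream
    return GenomicInterval(gene.chrom, max(0, start), end)


def annotate_feature(
    interval: GenomicInterval,
    genes: Sequence[GeneModel],
    upstream: int = 1500,
    downstream: int = 500,
) -> str:
    """Assign one feature label by the promoter-first hierarchy.

    The interval receives the highest-priority label among all gene
    features it overlaps by >= 1 bp: Promoter > 5UTR > CDS > 3UTR >
    FirstIntron > OtherIntron; Intergenic if it touches nothing.
    Interval strand is ignored; promoter windows are gene-strand-aware.
    """
    best = len(FEATURE_HIERARCHY) - 1  # Intergenic
    for gene in genes:
        if gene.chrom != interval.chrom:
            continue
        candidates: list[tuple[int, Iterable[GenomicInterval]]] = [
            (0, [promoter_window(gene, upstream, downstream)]),
            (1, gene.utr5),
            (2, gene.cds),
            (3, gene.utr3),
        ]
        fi = gene.first_intron()
        introns = gene.introns()
        if fi is not None:
            candidates.append((4, [fi]))
            candidates.append((5, [iv for iv in introns if iv != fi]))
        for rank, ivs in candidates:
            if rank >= best:
                continue
            if any(interval.overlaps(iv) for iv in ivs):
                best = rank
    return FEATURE_HIERARCHY[best]


def intersect(
    a: Sequence[GenomicInterval],
    b: Sequence[GenomicInterval],
    min_overlap: int = 1,
) -> list[tuple[int, int, int]]:
    """All pairs (i, j, overlap_bp) with a[i] and b[j] overlapping.

    Sorted-sweep join per chromosome; each qualifying pair is reported
    exactly once, in no guaranteed order. ``min_overlap`` is the minimum
    overlap in bp (>= 1).
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    by_chrom_a: dict[str, list[tuple[int, int, int]]] = {}
    by_chrom_b: dict[str, list[tuple[int, int, int]]] = {}
    for store, ivs in ((by_chrom_a, a), (by_chrom_b, b)):
        for idx, iv in enumerate(ivs):
            store.setdefault(iv.chrom, []).append((iv.start, iv.end, idx))
    out: list[tuple[int, int, int]] = []
    for chrom, lefts in by_chrom_a.items():
        rights = by_chrom_b.get(chrom)
        if not rights:
            continue
        lefts = sorted(lefts)
        rights = sorted(rights)
        r_starts = np.array([r[0] for r in rights])
        # active window of b intervals ordered by start; prune by max end seen
        for a_start, a_end, ai in lefts:
            # all b starting before a_end may overlap
            hi = int(np.searchsorted(r_starts, a_end - min_overlap + 1))
            for b_start, b_end, bi in rights[:hi]:
                ov = min(a_end, b_end) - max(a_start, b_start)
                if ov >= min_overlap:
                    out.append((ai, bi, ov))
    return out


def bin_fragments(fm: FragmentMap, k: int = 4) -> FragmentMap:
    """Merge consecutive groups of ``k`` fragments into super-fragments.

    Binning is anchored at the first fragment of each chromosome; a
    trailing remainder group of fewer than ``k`` fragments is kept.
    """
    if k <= 0:
        raise ValueError("k must be >= 1")
    if k == 1:
        return fm
    binned: dict[str, list[GenomicInterval]] = {}
    for chrom, frags in fm.fragments_by_chrom.items():
        merged = []
        for i in range(0, len(frags), k):
            group = frags[i : i + k]
            merged.append(GenomicInterval(chrom, group[0].start, group[-1].end))
        binned[chrom] = merged
    return FragmentMap(binned, fm.motif)


def member_fragment_ids(fm_fine: FragmentMap, fm_binned: FragmentMap, binned_id: int) -> list[int]:
    """Fine-resolution fragment ids whose spans fall inside a binned fragment."""
    chrom = fm_binned.fragment_chrom(binned_id)
    span = fm_binned.fragment(binned_id)
    return [
        fid
        for fid in fm_fine.overlapping_fragment_ids(span)
        if fm_fine.fragment(fid).start >= span.start
        and fm_fine.fragment(fid).end <= span.end
    ]
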