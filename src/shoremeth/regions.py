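"""Genomic region classes and bin/region mapping.

Coordinates are 0-based half-open (BED convention) throughout.  A gene's
TSS is its interval start on the + strand and its interval end on the -
strand.  CpG-island shores are the immediate flanks of an island, shelves
the next band outward; islands subtract from shores, and islands+shores
subtract from shelves, so the three classes are pairwise disjoint even
when neighbouring islands are close.

The methylation matrix is addressed through a fixed non-overlapping grid
of ``bin_size`` bp windows (:class:`BinIndex`); bin/interval overlap is
therefore plain integer arithmetic and needs no interval index.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

#: Closed vocabulary of region class labels.
REGION_LABELS = frozenset(
    {
        "CpGI",
        "shore",
        "shelf",
        "promoter",
        "exon",
        "intron",
        "UTR5",
        "UTR3",
        "TFBS",
        "gene",
        "intergenic",
    }
)

#: Derived intersection labels emitted by :func:`assign_bins`.
PROMOTER_CPGI = "promoter_CpGI"
PROMOTER_SHORE = "promoter_shore"


@dataclass(frozen=True)
class GenomicInterval:
    """A labelled genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    label: str = "intergenic"
    gene_id: str | None = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start in {self}")
        if self.end <= self.start:
            raise ValueError(f"empty or inverted interval {self}")
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"bad strand {self.strand!r}")
        if self.label not in REGION_LABELS:
            raise ValueError(f"unknown region label {self.label!r}")

    def __len__(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# Interval set arithmetic on plain (start, end) tuples, per chromosome.
# ---------------------------------------------------------------------------

def merge_intervals(ivs: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping/abutting (start, end) tuples into a disjoint sorted list."""
    ivs = sorted(ivs)
    out: list[tuple[int, int]] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def subtract_intervals(
    a: Sequence[tuple[int, int]], b: Sequence[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Set difference a \\ b; both inputs arbitrary, output disjoint sorted."""
    a = merge_intervals(a)
    b = merge_intervals(b)
    out: list[tuple[int, int]] = []
    j = 0
    for s, e in a:
        cur = s
        while j < len(b) and b[j][1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k][0] < e:
            bs, be = b[k]
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            if be >= e:
                break
            k += 1
        if cur < e:
            out.append((cur, e))
    return out


def intersect_intervals(
    a: Sequence[tuple[int, int]], b: Sequence[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Set intersection of two interval collections, disjoint sorted output."""
    a = merge_intervals(a)
    b = merge_intervals(b)
    out: list[tuple[int, int]] = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            out.append((s, e))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


@dataclass
class RegionSet:
    """A collection of labelled intervals plus chromosome sizes."""

    intervals: list[GenomicInterval] = field(default_factory=list)
    chrom_sizes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for iv in self.intervals:
            size = self.chrom_sizes.get(iv.chrom)
            if size is None:
                raise ValueError(f"interval on unknown chromosome {iv.chrom!r}")
            if iv.end > size:
                raise ValueError(
                    f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds "
                    f"chromosome length {size}"
                )

    def by_label(self, label: str) -> list[GenomicInterval]:
        return [iv for iv in self.intervals if iv.label == label]

    def labels(self) -> set[str]:
        return {iv.label for iv in self.intervals}

    def merged(self, label: str) -> dict[str, list[tuple[int, int]]]:
        """Canonicalized per-chromosome disjoint view of one label."""
        per_chrom: dict[str, list[tuple[int, int]]] = {}
        for iv in self.by_label(label):
            per_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        return {c: merge_intervals(v) for c, v in per_chrom.items()}

    def extend(self, other: "RegionSet") -> None:
        if other.chrom_sizes != self.chrom_sizes:
            raise ValueError("chromosome sizes differ between region sets")
        self.intervals.extend(other.intervals)


@dataclass(frozen=True)
class BinIndex:
    """Fixed non-overlapping genome tiling addressing methylation-matrix rows.

    Bin k of a chromosome covers [k*bin_size, min((k+1)*bin_size, chrom_len)).
    Rows are ordered by chromosome (insertion order of ``chrom_sizes``) then
    position.
    """

    chrom_sizes: dict[str, int]
    bin_size: int = 100

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        offsets: dict[str, int] = {}
        total = 0
        for chrom, size in self.chrom_sizes.items():
            offsets[chrom] = total
            total += -(-size // self.bin_size)
        object.__setattr__(self, "_offsets", offsets)
        object.__setattr__(self, "_n_bins", total)

    @property
    def n_bins(self) -> int:
        return self._n_bins

    @property
    def bins(self) -> list[tuple[str, int]]:
        out = []
        for chrom, size in self.chrom_sizes.items():
            out.extend((chrom, s) for s in range(0, size, self.bin_size))
        return out

    def bin_bounds(self, row: int) -> tuple[str, int, int]:
        for chrom, size in self.chrom_sizes.items():
            n = -(-size // self.bin_size)
            off = self._offsets[chrom]
            if off <= row < off + n:
                s = (row - off) * self.bin_size
                return chrom, s, min(s + self.bin_size, size)
        raise IndexError(row)

    def overlapping(self, chrom: str, start: int, end: int) -> range:
        """Row indices of bins overlapping [start, end) by >= 1 bp."""
        if chrom not in self._offsets or end <= start:
            return range(0)
        size = self.chrom_sizes[chrom]
        start = max(0, start)
        end = min(size, end)
        if end <= start:
            return range(0)
        off = self._offsets[chrom]
        return range(off + start // self.bin_size, off + (end - 1) // self.bin_size + 1)


# ---------------------------------------------------------------------------
# Derivations
# ---------------------------------------------------------------------------

def derive_shores_shelves(
    cpgi: RegionSet, shore_width: int = 2000, shelf_width: int = 2000
) -> RegionSet:
    """Derive CpG-island shores and shelves from island intervals.

    Shores are the ``shore_width`` bp flanks of each island minus any
    island; shelves the next ``shelf_width`` bp outward minus islands and
    shores.  Everything is clipped to chromosome bounds.
    """
    if shore_width <= 0 or shelf_width <= 0:
        raise ValueError("shore_width and shelf_width must be positive")
    extra = cpgi.labels() - {"CpGI"}
    if extra:
        raise ValueError(f"input must contain only CpGI intervals, found {extra}")
    out: list[GenomicInterval] = []
    islands = cpgi.merged("CpGI")
    for chrom, isl in islands.items():
        size = cpgi.chrom_sizes[chrom]
        clip = lambda s, e: (max(0, s), min(size, e))  # noqa: E731
        shore_cand = []
        shelf_cand = []
        for s, e in isl:
            shore_cand.append(clip(s - shore_width, s))
            shore_cand.append(clip(e, e + shore_width))
            shelf_cand.append(clip(s - shore_width - shelf_width, s - shore_width))
            shelf_cand.append(clip(e + shore_width, e + shore_width + shelf_width))
        shore_cand = [(s, e) for s, e in shore_cand if e > s]
        shelf_cand = [(s, e) for s, e in shelf_cand if e > s]
        shores = subtract_intervals(shore_cand, isl)
        shelves = subtract_intervals(subtract_intervals(shelf_cand, isl), shores)
        out.extend(GenomicInterval(chrom, s, e, label="shore") for s, e in shores)
        out.extend(GenomicInterval(chrom, s, e, label="shelf") for s, e in shelves)
    return RegionSet(out, dict(cpgi.chrom_sizes))


def tss(gene: GenomicInterval) -> int:
    """Transcription start site of a stranded gene interval."""
    if gene.strand == "+":
        return gene.start
    if gene.strand == "-":
        return gene.end
    raise ValueError(f"gene {gene.gene_id!r} has no strand; cannot locate TSS")


def derive_promoters(genes: RegionSet, promoter_len: int = 2000) -> RegionSet:
    """Promoters as the ``promoter_len`` bp immediately upstream of each TSS."""
    if promoter_len <= 0:
        raise ValueError("promoter_len must be positive")
    out: list[GenomicInterval] = []
    for g in genes.intervals:
        if g.label != "gene":
            continue
        t = tss(g)  # raises naming the gene when strand is missing
        size = genes.chrom_sizes[g.chrom]
        if g.strand == "+":
            s, e = max(0, t - promoter_len), t
        else:
            s, e = t, min(size, t + promoter_len)
        if e > s:
            out.append(
                GenomicInterval(g.chrom, s, e, g.strand, "promoter", g.gene_id)
            )
    return RegionSet(out, dict(genes.chrom_sizes))


def derive_introns(genes: RegionSet) -> RegionSet:
    """Introns = gene body minus that gene's exons, per gene."""
    exons_by_gene: dict[str | None, list[GenomicInterval]] = {}
    for iv in genes.by_label("exon"):
        exons_by_gene.setdefault(iv.gene_id, []).append(iv)
    out: list[GenomicInterval] = []
    for g in genes.by_label("gene"):
        ex = [(e.start, e.end) for e in exons_by_gene.get(g.gene_id, [])]
        for s, e in subtract_intervals([(g.start, g.end)], ex):
            out.append(GenomicInterval(g.chrom, s, e, g.strand, "intron", g.gene_id))
    return RegionSet(out, dict(genes.chrom_sizes))


def assign_bins(bins: BinIndex, regions: RegionSet) -> list[set[str]]:
    """Label every bin with the region classes it overlaps by >= 1 bp.

    Also emits the derived base-pair-level intersection labels
    ``promoter_CpGI`` and ``promoter_shore``.  Bins overlapping nothing are
    labelled ``intergenic``.
    """
    labels: list[set[str]] = [set() for _ in range(bins.n_bins)]

    def mark(chrom: str, ivs: Iterable[tuple[int, int]], label: str) -> None:
        for s, e in ivs:
            for row in bins.overlapping(chrom, s, e):
                labels[row].add(label)

    present = regions.labels()
    for label in present:
        for chrom, ivs in regions.merged(label).items():
            mark(chrom, ivs, label)
    prom = regions.merged("promoter") if "promoter" in present else {}
    for other, derived in (("CpGI", PROMOTER_CPGI), ("shore", PROMOTER_SHORE)):
        if other not in present:
            continue
        oth = regions.merged(other)
        for chrom in set(prom) & set(oth):
            mark(chrom, intersect_intervals(prom[chrom], oth[chrom]), derived)
    for lab in labels:
        if not lab:
            lab.add("intergenic")
    return labels


def reflect(regions: RegionSet) -> RegionSet:
    """Mirror every interval through its chromosome (x -> L - x), flipping strand."""
    flip = {"+": "-", "-": "+", ".": "."}
    out = []
    for iv in regions.intervals:
        size = regions.chrom_sizes[iv.chrom]
        out.append(
            replace(
                iv,
                start=size - iv.end,
                end=size - iv.start,
                strand=flip[iv.strand],
            )
        )
    return RegionSet(out, dict(regions.chrom_sizes))
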