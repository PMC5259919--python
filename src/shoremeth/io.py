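"""Readers and writers for the plain-text formats the pipeline consumes.

Everything is TSV or BED; coordinates are BED-style 0-based half-open.
The methylation matrix carries ``chrom, start, end`` then one RMS column
per sample, in the row order of the :class:`~shoremeth.regions.BinIndex`
derived from the accompanying chromosome-sizes file.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .regions import BinIndex, GenomicInterval, RegionSet

SUBTYPES = ("luminal", "basalA", "basalB")


# -- chromosome sizes -------------------------------------------------------

def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"])
    return dict(zip(df["chrom"].astype(str), df["size"].astype(int)))


def write_chrom_sizes(sizes: dict[str, int], path: str | Path) -> None:
    pd.DataFrame(sizes.items(), columns=["chrom", "size"]).to_csv(
        path, sep="\t", header=False, index=False
    )


# -- BED --------------------------------------------------------------------

def write_bed(regions: RegionSet, path: str | Path) -> None:
    """BED6; name column = ``label`` or ``label|gene_id`` when gene-linked."""
    rows = []
    for iv in regions.intervals:
        name = iv.label if iv.gene_id is None else f"{iv.label}|{iv.gene_id}"
        rows.append((iv.chrom, iv.start, iv.end, name, 0, iv.strand))
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def read_bed(
    path: str | Path, chrom_sizes: dict[str, int], default_label: str = "CpGI"
) -> RegionSet:
    """Read BED3/BED6.  BED6 name columns written by :func:`write_bed` round-trip."""
    df = pd.read_csv(path, sep="\t", header=None)
    ivs = []
    for row in df.itertuples(index=False):
        chrom, start, end = str(row[0]), int(row[1]), int(row[2])
        label, gene_id, strand = default_label, None, "."
        if len(row) >= 4 and isinstance(row[3], str):
            label, _, gid = row[3].partition("|")
            gene_id = gid or None
        if len(row) >= 6:
            strand = str(row[5])
        ivs.append(GenomicInterval(chrom, start, end, strand, label, gene_id))
    return RegionSet(ivs, dict(chrom_sizes))


# -- gene models ------------------------------------------------------------

def write_gene_models(genes: RegionSet, path: str | Path) -> None:
    """Minimal gene-model TSV: one row per gene with comma-joined exon bounds."""
    exons: dict[str, list[GenomicInterval]] = {}
    for iv in genes.by_label("exon"):
        exons.setdefault(iv.gene_id or "", []).append(iv)
    rows = []
    for g in genes.by_label("gene"):
        ex = sorted(exons.get(g.gene_id or "", []), key=lambda e: e.start)
        rows.append(
            {
                "chrom": g.chrom,
                "start": g.start,
                "end": g.end,
                "strand": g.strand,
                "gene_id": g.gene_id,
                "exon_starts": ",".join(str(e.start) for e in ex),
                "exon_ends": ",".join(str(e.end) for e in ex),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_gene_models(path: str | Path, chrom_sizes: dict[str, int]) -> RegionSet:
    df = pd.read_csv(path, sep="\t", dtype={"exon_starts": str, "exon_ends": str})
    ivs: list[GenomicInterval] = []
    for r in df.itertuples(index=False):
        ivs.append(
            GenomicInterval(str(r.chrom), int(r.start), int(r.end), r.strand, "gene", r.gene_id)
        )
        if isinstance(r.exon_starts, str) and r.exon_starts:
            starts = [int(x) for x in r.exon_starts.split(",")]
            ends = [int(x) for x in r.exon_ends.split(",")]
            for s, e in zip(starts, ends):
                ivs.append(GenomicInterval(str(r.chrom), s, e, r.strand, "exon", r.gene_id))
    return RegionSet(ivs, dict(chrom_sizes))


# -- matrices ---------------------------------------------------------------

def write_methylation(meth: pd.DataFrame, bins: BinIndex, path: str | Path) -> None:
    coords = pd.DataFrame(
        [bins.bin_bounds(i) for i in range(bins.n_bins)],
        columns=["chrom", "start", "end"],
    )
    pd.concat([coords, meth.reset_index(drop=True)], axis=1).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def read_methylation(path: str | Path) -> pd.DataFrame:
    """Sample columns only; rows in file order (must match the BinIndex)."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return df.drop(columns=["chrom", "start", "end"])


def write_matrix(df: pd.DataFrame, path: str | Path, index_name: str) -> None:
    df.to_csv(path, sep="\t", index=True, index_label=index_name, float_format="%.17g")


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")


# -- tables -----------------------------------------------------------------

def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", float_precision="round_trip")


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", dtype=str)
    validate_sample_sheet(sheet)
    return sheet


def validate_sample_sheet(sheet: pd.DataFrame) -> None:
    missing = {"sample", "subtype"} - set(sheet.columns)
    if missing:
        raise ValueError(f"sample sheet lacks columns {sorted(missing)}")
    bad = sheet.loc[~sheet["subtype"].isin(SUBTYPES)]
    if len(bad):
        pairs = ", ".join(f"{r.sample}={r.subtype}" for r in bad.itertuples())
        raise ValueError(f"unknown subtype for sample(s): {pairs}")
    if sheet["sample"].duplicated().any():
        dups = sheet.loc[sheet["sample"].duplicated(), "sample"].tolist()
        raise ValueError(f"duplicate sample ids: {dups}")


def subtype_groups(sheet: pd.DataFrame) -> dict[str, list[str]]:
    """Map subtype -> list of sample ids, in sheet order."""
    validate_sample_sheet(sheet)
    return {
        st: sheet.loc[sheet["subtype"] == st, "sample"].tolist()
        for st in SUBTYPES
        if (sheet["subtype"] == st).any()
    }
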