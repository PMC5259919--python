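"""Per-bin differential methylation between subtype pairs.

Each 100-bp bin's RMS is compared between two subtypes with a Welch
two-sample t-test; P-values are Bonferroni-adjusted over the bins
actually tested in that pair (significant when adjusted P < alpha).
Runs of adjacent significant bins with the same hypomethylated subtype
are merged into differentially methylated regions (DMRs); significant
bins are counted per genomic region class, and the hypomethylation
ratio of a region gives the fraction of its significant bins whose
lower group mean belongs to each subtype.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import subtype_groups
from .regions import BinIndex


@dataclass
class PairwiseResult:
    """Per-bin Welch t-test results for one subtype pair."""

    pair: tuple[str, str]
    table: pd.DataFrame          # bin, mean_a, mean_b, t_stat, p, p_adj, significant, hypo_in
    alpha: float
    n_tested: int
    n_skipped_zero_var: int
    n_skipped_nan: int


def pairwise_bin_test(
    meth: pd.DataFrame,
    sheet: pd.DataFrame,
    pair: tuple[str, str],
    alpha: float = 0.05,
) -> PairwiseResult:
    """Welch t-test per bin between the two subtypes of ``pair``.

    Bins with any NaN cell, or with zero variance in both groups, are
    skipped and counted; the Bonferroni multiplier is the number of bins
    actually tested.
    """
    groups = subtype_groups(sheet)
    for st in pair:
        if len(groups.get(st, [])) < 2:
            raise ValueError(f"subtype {st!r} has fewer than 2 samples")
    a = meth[groups[pair[0]]].to_numpy(dtype=float)
    b = meth[groups[pair[1]]].to_numpy(dtype=float)
    nan_mask = np.isnan(a).any(axis=1) | np.isnan(b).any(axis=1)
    with np.errstate(invalid="ignore"):
        # exact constantness check (float variance of a constant row can be ~1e-17)
        zero_var = (
            (~nan_mask)
            & (np.ptp(a, axis=1) == 0)
            & (np.ptp(b, axis=1) == 0)
        )
    tested = ~(nan_mask | zero_var)
    m = int(tested.sum())

    n_bins = meth.shape[0]
    t_stat = np.full(n_bins, np.nan)
    p = np.full(n_bins, np.nan)
    if m:
        t_stat[tested], p[tested] = stats.ttest_ind(
            a[tested], b[tested], axis=1, equal_var=False
        )
    p_adj = np.minimum(p * m, 1.0)
    mean_a = a.mean(axis=1)  # NaN rows propagate NaN means
    mean_b = b.mean(axis=1)
    significant = np.zeros(n_bins, dtype=bool)
    significant[tested] = p_adj[tested] < alpha
    hypo = np.where(mean_a < mean_b, pair[0], np.where(mean_b < mean_a, pair[1], "tie"))
    table = pd.DataFrame(
        {
            "bin": np.arange(n_bins),
            "mean_a": mean_a,
            "mean_b": mean_b,
            "t_stat": t_stat,
            "p": p,
            "p_adj": p_adj,
            "significant": significant,
            "hypo_in": hypo,
            "tested": tested,
        }
    )
    return PairwiseResult(
        pair=pair,
        table=table,
        alpha=alpha,
        n_tested=m,
        n_skipped_zero_var=int(zero_var.sum()),
        n_skipped_nan=int(nan_mask.sum()),
    )


@dataclass(frozen=True)
class DMR:
    chrom: str
    start: int
    end: int
    bins: tuple[int, ...]        # significant member bins only
    pair: tuple[str, str]
    hypo_in: str
    min_p_adj: float


def merge_bins_to_dmrs(
    result: PairwiseResult, bin_index: BinIndex, max_gap_bins: int = 0
) -> list[DMR]:
    """Merge runs of significant same-direction bins into DMRs.

    Up to ``max_gap_bins`` consecutive non-significant bins may sit inside
    a run; chromosome boundaries and direction changes always split.
    """
    tab = result.table
    sig = tab["significant"].to_numpy()
    hypo = tab["hypo_in"].to_numpy()
    chroms = np.array([bin_index.bin_bounds(i)[0] for i in range(bin_index.n_bins)])

    dmrs: list[DMR] = []
    members: list[int] = []

    def flush() -> None:
        if not members:
            return
        c, s0, _ = bin_index.bin_bounds(members[0])
        _, _, e1 = bin_index.bin_bounds(members[-1])
        dmrs.append(
            DMR(
                chrom=c,
                start=s0,
                end=e1,
                bins=tuple(members),
                pair=result.pair,
                hypo_in=hypo[members[0]],
                min_p_adj=float(tab.loc[members, "p_adj"].min()),
            )
        )
        members.clear()

    gap = 0
    for i in range(len(sig)):
        if not sig[i]:
            gap += 1
            if gap > max_gap_bins:
                flush()
            continue
        if members and (
            chroms[i] != chroms[members[-1]]
            or hypo[i] != hypo[members[0]]
            or gap > max_gap_bins
        ):
            flush()
        members.append(i)
        gap = 0
    flush()
    return dmrs


def count_by_region(
    result: PairwiseResult, bin_labels: list[set[str]]
) -> pd.DataFrame:
    """Significant-bin counts per region class (multi-labelled bins count in each)."""
    counts: dict[str, int] = {}
    for i in result.table.index[result.table["significant"]]:
        for lab in bin_labels[i]:
            counts[lab] = counts.get(lab, 0) + 1
    return pd.DataFrame(
        sorted(counts.items()), columns=["region", "n_significant_bins"]
    )


def hypomethylation_ratio(
    result: PairwiseResult, bin_labels: list[set[str]], region: str
) -> dict[str, float]:
    """Fraction of significant ``region`` bins hypomethylated in each pair member.

    Tie-direction bins are excluded from numerator and denominator; with no
    qualifying bins both ratios are NaN.
    """
    tab = result.table
    rows = [
        i
        for i in tab.index[tab["significant"]]
        if region in bin_labels[i] and tab.at[i, "hypo_in"] != "tie"
    ]
    if not rows:
        return {result.pair[0]: float("nan"), result.pair[1]: float("nan")}
    hypo = tab.loc[rows, "hypo_in"]
    n = len(rows)
    return {st: float((hypo == st).sum()) / n for st in result.pair}


def dmrs_to_bed(dmrs: list[DMR]) -> pd.DataFrame:
    """BED6-shaped frame: name = pair, score = -log10 of the best adjusted P."""
    rows = []
    for d in dmrs:
        score = -np.log10(max(d.min_p_adj, 1e-300))
        rows.append(
            (d.chrom, d.start, d.end, f"{d.pair[0]}-{d.pair[1]}|hypo_{d.hypo_in}", round(score, 3), ".")
        )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])
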