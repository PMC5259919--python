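"""TFBS methylation scoring and methylation–expression coupling.

A TFBS's methylation per sample is the unweighted mean RMS of all
100-bp bins overlapping the site.  Candidate sites are screened in
three steps: Kruskal–Wallis differential methylation across subtypes
(Benjamini–Hochberg FDR < 0.1), Spearman anti-correlation with the
downstream target gene's expression (rho < -0.5), and a TF-expression
similarity filter that discards TFs whose own expression differs
across subtypes (so that expression differences are attributable to
TFBS methylation rather than TF abundance).  Passing sites are rolled
up to a gene-level table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import subtype_groups
from .regions import BinIndex


@dataclass
class TFBSScreen:
    hits: pd.DataFrame            # one row per TFBS with all screen columns
    excluded_no_bins: list[str]   # tfbs_ids overlapping no methylation bin
    n_kw_na: int                  # TFBS with undefined KW (constant data)


def tfbs_methylation(
    meth: pd.DataFrame, bin_index: BinIndex, links: pd.DataFrame
) -> tuple[pd.DataFrame, list[str]]:
    """TFBS × sample mean RMS matrix; TFBS overlapping no bin are dropped.

    ``links`` needs columns tfbs_id, chrom, start, end.
    Returns (matrix indexed by tfbs_id, list of excluded tfbs_ids).
    """
    rows = {}
    excluded = []
    for r in links.itertuples(index=False):
        idx = list(bin_index.overlapping(r.chrom, int(r.start), int(r.end)))
        if not idx:
            excluded.append(r.tfbs_id)
            continue
        rows[r.tfbs_id] = meth.iloc[idx].mean(axis=0)
    mat = pd.DataFrame(rows).T
    mat.index.name = "tfbs_id"
    return mat, excluded


def _kw_by_group(values: pd.DataFrame, groups: dict[str, list[str]]) -> np.ndarray:
    """Kruskal–Wallis P per row of ``values`` across sample groups; NaN if constant."""
    p = np.full(len(values), np.nan)
    arrs = [values[m].to_numpy(dtype=float) for m in groups.values()]
    for i in range(len(values)):
        samples = [a[i] for a in arrs]
        flat = np.concatenate(samples)
        if np.ptp(flat) == 0:
            continue
        p[i] = stats.kruskal(*samples).pvalue
    return p


def differential_tfbs(
    tfbs_meth: pd.DataFrame, sheet: pd.DataFrame, fdr_threshold: float = 0.1
) -> pd.DataFrame:
    """Kruskal–Wallis across subtypes per TFBS with BH FDR across TFBS.

    TFBS with constant methylation across all samples have no defined test
    and are reported NA (excluded from the FDR family).
    """
    groups = subtype_groups(sheet)
    kw_p = _kw_by_group(tfbs_meth, groups)
    kw_fdr = np.full_like(kw_p, np.nan)
    ok = np.isfinite(kw_p)
    if ok.any():
        kw_fdr[ok] = multipletests(kw_p[ok], method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "tfbs_id": tfbs_meth.index,
            "kw_p": kw_p,
            "kw_fdr": kw_fdr,
            "kw_significant": ok & (kw_fdr < fdr_threshold),
        }
    ).set_index("tfbs_id")


def expression_correlation(
    tfbs_meth: pd.DataFrame, expr: pd.DataFrame, links: pd.DataFrame
) -> pd.Series:
    """Spearman rho between each TFBS's methylation and its target's expression.

    Computed over all samples (ties mid-ranked); NaN when the target gene
    is missing from the expression matrix or either vector is constant.
    """
    target = links.set_index("tfbs_id")["target_gene"]
    samples = [s for s in tfbs_meth.columns if s in expr.columns]
    rho = {}
    for tid in tfbs_meth.index:
        gene = target.get(tid)
        if gene is None or gene not in expr.index:
            rho[tid] = np.nan
            continue
        x = tfbs_meth.loc[tid, samples].to_numpy(dtype=float)
        y = expr.loc[gene, samples].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            rho[tid] = np.nan
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rho[tid] = stats.spearmanr(x, y).statistic
    return pd.Series(rho, name="rho")


def tf_expression_filter(
    expr: pd.DataFrame, tf_id: str, sheet: pd.DataFrame, p_threshold: float = 0.05
) -> bool:
    """True when the TF's own expression is similar across subtypes.

    Operationalized as Kruskal–Wallis P >= ``p_threshold`` on the TF's
    expression; a TF absent from the matrix, or with constant expression,
    counts as similar.
    """
    if tf_id not in expr.index:
        return True
    groups = subtype_groups(sheet)
    samples_by_group = [
        expr.loc[tf_id, m].to_numpy(dtype=float) for m in groups.values()
    ]
    flat = np.concatenate(samples_by_group)
    if np.ptp(flat) == 0:
        return True
    return bool(stats.kruskal(*samples_by_group).pvalue >= p_threshold)


def screen_tfbs(
    meth: pd.DataFrame,
    bin_index: BinIndex,
    links: pd.DataFrame,
    expr: pd.DataFrame,
    sheet: pd.DataFrame,
    fdr_threshold: float = 0.1,
    rho_threshold: float = -0.5,
    tf_p_threshold: float = 0.05,
) -> TFBSScreen:
    """Full per-TFBS screen combining all filters into a ``passes`` flag."""
    tm, excluded = tfbs_methylation(meth, bin_index, links)
    kw = differential_tfbs(tm, sheet, fdr_threshold)
    rho = expression_correlation(tm, expr, links)
    tf_ok = {
        tf: tf_expression_filter(expr, tf, sheet, tf_p_threshold)
        for tf in links["tf_id"].unique()
    }
    info = links.set_index("tfbs_id")
    hits = kw.join(rho).join(info[["tf_id", "target_gene", "validated"]])
    hits["tf_expression_similar"] = hits["tf_id"].map(tf_ok)
    hits["mean_meth"] = tm.mean(axis=1)
    groups = subtype_groups(sheet)
    for st, members in groups.items():
        hits[f"mean_meth_{st}"] = tm[members].mean(axis=1)
    hits["hypo_subtype"] = (
        hits[[f"mean_meth_{st}" for st in groups]]
        .idxmin(axis=1)
        .str.replace("mean_meth_", "", regex=False)
    )
    hits["passes"] = (
        hits["kw_significant"]
        & (hits["rho"] < rho_threshold)
        & hits["tf_expression_similar"]
        & hits["validated"].astype(bool)
    )
    return TFBSScreen(
        hits=hits.reset_index(),
        excluded_no_bins=excluded,
        n_kw_na=int((~np.isfinite(kw["kw_p"])).sum()),
    )


def integrate(screen: TFBSScreen) -> tuple[pd.DataFrame, dict]:
    """Gene-level roll-up of passing TFBS.

    One row per gene with >= 1 passing TFBS: the most negative rho, the
    smallest KW FDR, and the hypomethylated subtype of the best TFBS.
    The summary reports the fraction of genes hypomethylated in basal B.
    """
    passing = screen.hits[screen.hits["passes"]]
    if passing.empty:
        cols = ["gene", "tfs", "n_tfbs", "best_rho", "min_kw_fdr", "hypo_subtype"]
        return pd.DataFrame(columns=cols), {"n_genes": 0, "frac_hypo_basalB": float("nan")}
    rows = []
    for gene, grp in passing.groupby("target_gene"):
        best = grp.loc[grp["rho"].idxmin()]
        rows.append(
            {
                "gene": gene,
                "tfs": ",".join(sorted(grp["tf_id"].unique())),
                "n_tfbs": len(grp),
                "best_rho": float(grp["rho"].min()),
                "min_kw_fdr": float(grp["kw_fdr"].min()),
                "hypo_subtype": best["hypo_subtype"],
            }
        )
    table = pd.DataFrame(rows).sort_values("best_rho").reset_index(drop=True)
    summary = {
        "n_genes": len(table),
        "frac_hypo_basalB": float((table["hypo_subtype"] == "basalB").mean()),
    }
    return table, summary
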