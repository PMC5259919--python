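"""CpG mutation calling, methylation-stratified rates, subtype-specific sites.

Mutation calls come from an explicit one-sided binomial test on per-site
per-sample (coverage, mismatch) counts: a site-sample is called mutated
when P[X >= mismatches | coverage, seq_error] falls below ``call_alpha``
and coverage is adequate.  The mutation rate of a methylation stratum is
the fraction of eligible site-sample observations called mutated; a
one-way ANOVA on per-sample rates compares subtypes per stratum with
Bonferroni correction over strata.  A site is subtype-specific when its
carrier fraction reaches >= 30% in one subtype but stays < 10% in each of
the other two; specific sites are counted per genomic region class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import subtype_groups
from .regions import BinIndex


def call_mutations(
    obs: pd.DataFrame,
    seq_error: float = 0.002,
    call_alpha: float = 1e-6,
    min_coverage: int = 10,
    max_reads: int = 250,
) -> pd.DataFrame:
    """Binomial-tail mutation calls on a (chrom, pos, sample, coverage, mismatches[, rms]) table.

    Coverage above ``max_reads`` is capped with proportional mismatch
    subsampling.  ``p_error`` = P[X >= mismatches | coverage, seq_error];
    zero mismatches give p_error = 1.  A call requires p_error < call_alpha
    and coverage >= min_coverage (``eligible``).
    """
    if not 0.0 < seq_error < 0.5:
        raise ValueError("seq_error must lie in (0, 0.5)")
    out = obs.copy()
    cov = out["coverage"].to_numpy(dtype=np.int64)
    mm = out["mismatches"].to_numpy(dtype=np.int64)
    if (mm > cov).any():
        bad = out.loc[mm > cov].iloc[0]
        raise ValueError(
            f"mismatches exceed coverage at {bad['chrom']}:{bad['pos']} "
            f"sample {bad['sample']}"
        )
    if (mm < 0).any() or (cov < 0).any():
        raise ValueError("negative counts")
    over = cov > max_reads
    if over.any():
        mm = mm.copy()
        mm[over] = np.rint(mm[over] * max_reads / cov[over]).astype(np.int64)
        cov = np.where(over, max_reads, cov)
    # survival function at mm-1 gives P[X >= mm]; sf(-1) = 1 for mm = 0
    p_error = stats.binom.sf(mm - 1, cov, seq_error)
    eligible = cov >= min_coverage
    out["coverage"] = cov
    out["mismatches"] = mm
    out["p_error"] = p_error
    out["eligible"] = eligible
    out["is_mutated"] = eligible & (p_error < call_alpha)
    return out


def _stratum_edges(width: float) -> np.ndarray:
    edges = np.arange(0.0, 1.0, width)
    return np.append(edges, 1.0)


def _stratum_of(rms: np.ndarray, width: float) -> np.ndarray:
    """Stratum index for each RMS; [k*w, (k+1)*w) with the last stratum closed at 1."""
    # pre-round so a boundary value like 0.3/0.05 = 5.999...9 lands in its stratum
    idx = np.floor(np.round(np.asarray(rms, dtype=float) / width, 9)).astype(int)
    n = len(_stratum_edges(width)) - 1
    return np.clip(idx, 0, n - 1)


def mutation_rate_by_methylation(
    calls: pd.DataFrame, sheet: pd.DataFrame, stratum_width: float = 0.05
) -> pd.DataFrame:
    """Per-subtype per-stratum mutation rate table.

    n_sites counts eligible site-sample observations whose containing-bin
    RMS falls in the stratum; n_mutated counts calls among them; the rate
    is their ratio (NA for empty strata, not 0).
    """
    edges = _stratum_edges(stratum_width)
    subtype_of = dict(zip(sheet["sample"], sheet["subtype"]))
    df = calls[calls["eligible"]].copy()
    df["subtype"] = df["sample"].map(subtype_of)
    df["stratum"] = _stratum_of(df["rms"].to_numpy(), stratum_width)
    rows = []
    grouped = df.groupby(["subtype", "stratum"], sort=False)
    agg = grouped["is_mutated"].agg(["size", "sum"])
    for st in subtype_groups(sheet):
        for k in range(len(edges) - 1):
            if (st, k) in agg.index:
                n, m = int(agg.loc[(st, k), "size"]), int(agg.loc[(st, k), "sum"])
                rate = m / n
            else:
                n, m, rate = 0, 0, float("nan")
            rows.append(
                {
                    "stratum_lo": round(float(edges[k]), 6),
                    "stratum_hi": round(float(edges[k + 1]), 6),
                    "subtype": st,
                    "n_sites": n,
                    "n_mutated": m,
                    "rate": rate,
                }
            )
    return pd.DataFrame(rows)


def per_sample_stratum_rates(
    calls: pd.DataFrame, stratum_width: float = 0.05
) -> pd.DataFrame:
    """Stratum × sample matrix of per-sample mutation rates (ANOVA units)."""
    df = calls[calls["eligible"]].copy()
    df["stratum"] = _stratum_of(df["rms"].to_numpy(), stratum_width)
    rates = df.groupby(["stratum", "sample"])["is_mutated"].mean().unstack("sample")
    n_strata = len(_stratum_edges(stratum_width)) - 1
    return rates.reindex(range(n_strata))


def stratum_anova(
    per_sample_rates: pd.DataFrame, sheet: pd.DataFrame, stratum_width: float = 0.05
) -> pd.DataFrame:
    """One-way ANOVA of per-sample rates across subtypes, Bonferroni over strata.

    Strata where any subtype has < 2 samples with data are NA and excluded
    from the multiplicity count.
    """
    groups = subtype_groups(sheet)
    edges = _stratum_edges(stratum_width)
    p_raw = np.full(len(per_sample_rates), np.nan)
    for i, (_, row) in enumerate(per_sample_rates.iterrows()):
        vals = []
        ok = True
        for members in groups.values():
            v = row.reindex(members).to_numpy(dtype=float)
            v = v[np.isfinite(v)]
            if len(v) < 2:
                ok = False
                break
            vals.append(v)
        if not ok:
            continue
        if np.ptp(np.concatenate(vals)) == 0:
            p_raw[i] = 1.0
            continue
        p_raw[i] = stats.f_oneway(*vals).pvalue
    m = int(np.isfinite(p_raw).sum())
    p_adj = np.minimum(p_raw * m, 1.0)
    return pd.DataFrame(
        {
            "stratum_lo": edges[:-1][: len(p_raw)],
            "stratum_hi": edges[1:][: len(p_raw)],
            "p": p_raw,
            "p_adj": p_adj,
        }
    )


@dataclass(frozen=True)
class SubtypeSpecificMutation:
    chrom: str
    pos: int
    assigned_subtype: str
    freq_in: dict[str, float]


def classify_subtype_specific(
    calls: pd.DataFrame,
    sheet: pd.DataFrame,
    min_in: float = 0.30,
    max_out: float = 0.10,
) -> pd.DataFrame:
    """Assign sites to a subtype by the >=30% / <10% carrier-fraction rule.

    The carrier fraction of a subtype is the share of its samples whose
    observation at the site is a mutation call (samples without an
    eligible observation count as non-carriers).  With min_in > max_out a
    site can match at most one subtype.
    """
    if min_in <= max_out:
        raise ValueError("min_in must exceed max_out (assignment would be ambiguous)")
    groups = subtype_groups(sheet)
    subtype_of = dict(zip(sheet["sample"], sheet["subtype"]))
    df = calls.copy()
    df["subtype"] = df["sample"].map(subtype_of)
    carriers = (
        df.groupby(["chrom", "pos", "subtype"])["is_mutated"].sum().unstack("subtype")
    ).fillna(0)
    n_per = {st: len(m) for st, m in groups.items()}
    freq = carriers.copy()
    for st in freq.columns:
        freq[st] = freq[st] / n_per[st]
    rows = []
    for (chrom, pos), fr in freq.iterrows():
        for st in groups:
            others = [o for o in groups if o != st]
            if fr.get(st, 0.0) >= min_in and all(fr.get(o, 0.0) < max_out for o in others):
                rows.append(
                    {
                        "chrom": chrom,
                        "pos": pos,
                        "assigned_subtype": st,
                        **{f"freq_{o}": float(fr.get(o, 0.0)) for o in groups},
                    }
                )
                break
    cols = ["chrom", "pos", "assigned_subtype"] + [f"freq_{st}" for st in groups]
    return pd.DataFrame(rows, columns=cols)


def regional_mutation_counts(
    specific: pd.DataFrame,
    calls: pd.DataFrame,
    bin_index: BinIndex,
    bin_labels: list[set[str]],
    sheet: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Region × subtype counts of specific sites, plus per-region ANOVA.

    The ANOVA unit is the per-sample count of specific-site mutation calls
    carried in the region; Bonferroni over the regions tested.
    """
    groups = subtype_groups(sheet)
    region_of_site: dict[tuple[str, int], set[str]] = {}
    for r in specific.itertuples(index=False):
        rows = bin_index.overlapping(r.chrom, int(r.pos), int(r.pos) + 1)
        labs: set[str] = set()
        for b in rows:
            labs |= bin_labels[b]
        region_of_site[(r.chrom, int(r.pos))] = labs

    all_regions = sorted(set().union(*region_of_site.values())) if region_of_site else []
    counts = pd.DataFrame(0, index=all_regions, columns=list(groups))
    for r in specific.itertuples(index=False):
        for lab in region_of_site[(r.chrom, int(r.pos))]:
            counts.loc[lab, r.assigned_subtype] += 1
    counts.index.name = "region"

    # per-sample carried specific-site counts per region
    spec_keys = set(zip(specific["chrom"], specific["pos"]))
    if len(calls):
        key_idx = pd.MultiIndex.from_frame(calls[["chrom", "pos"]])
        carried = calls.loc[calls["is_mutated"].to_numpy() & key_idx.isin(list(spec_keys))]
    else:
        carried = calls
    per_sample = {s: {reg: 0 for reg in all_regions} for s in sheet["sample"]}
    for r in carried.itertuples(index=False):
        labs = region_of_site.get((r.chrom, int(r.pos)))
        if labs is None:
            continue
        for lab in labs:
            per_sample[r.sample][lab] += 1

    p_raw = {}
    for reg in all_regions:
        vals = []
        for members in groups.values():
            vals.append(np.array([per_sample[s][reg] for s in members], dtype=float))
        flat = np.concatenate(vals)
        p_raw[reg] = 1.0 if np.ptp(flat) == 0 else stats.f_oneway(*vals).pvalue
    m = len(p_raw)
    anova = pd.DataFrame(
        {
            "region": all_regions,
            "p": [p_raw[r] for r in all_regions],
            "p_adj": [min(1.0, p_raw[r] * m) for r in all_regions],
        }
    )
    return counts.reset_index(), anova
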