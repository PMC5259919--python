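"""Cross-technology methylation concordance over 2-kb windows.

Single-CpG bisulfite-style beta values and binned affinity-capture RMS
are both averaged over non-overlapping 2-kb windows tiling the targeted
regions (windows anchored at each region's start); Pearson correlation
of the paired window means measures agreement between the two
technologies, per sample and averaged across samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .regions import BinIndex


@dataclass
class WindowPairs:
    pairs: pd.DataFrame      # chrom, start, end, mean_beta, mean_rms
    n_windows: int
    n_dropped: int


def bin_2kb(
    betas: pd.DataFrame,
    meth: pd.DataFrame,
    bin_index: BinIndex,
    target_regions: pd.DataFrame,
    sample: str,
    window: int = 2000,
) -> WindowPairs:
    """Paired (mean beta, mean RMS) per 2-kb window of the target regions.

    Windows are anchored at each target region's start; a trailing
    remainder shorter than ``window`` is kept.  Windows lacking CpGs or
    bins on either side are dropped and counted.
    """
    b = betas[betas["sample"] == sample]
    rows = []
    total = 0
    for reg in target_regions.itertuples(index=False):
        for ws in range(int(reg.start), int(reg.end), window):
            we = min(ws + window, int(reg.end))
            total += 1
            in_win = b[(b["chrom"] == reg.chrom) & (b["pos"] >= ws) & (b["pos"] < we)]
            bins = list(bin_index.overlapping(reg.chrom, ws, we))
            if in_win.empty or not bins or sample not in meth.columns:
                continue
            rows.append(
                {
                    "chrom": reg.chrom,
                    "start": ws,
                    "end": we,
                    "mean_beta": float(in_win["beta"].mean()),
                    "mean_rms": float(meth.loc[bins, sample].mean()),
                }
            )
    pairs = pd.DataFrame(rows, columns=["chrom", "start", "end", "mean_beta", "mean_rms"])
    return WindowPairs(pairs=pairs, n_windows=total, n_dropped=total - len(pairs))


def pearson_concordance(pairs: pd.DataFrame) -> float:
    """Pearson r of paired window means; requires >= 3 pairs with variance."""
    if len(pairs) < 3:
        raise ValueError("need at least 3 paired windows")
    x = pairs["mean_beta"].to_numpy(dtype=float)
    y = pairs["mean_rms"].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance on one side; correlation undefined")
    if np.array_equal(x, y):
        return 1.0  # exact fast path: identical readouts correlate perfectly
    return float(stats.pearsonr(x, y).statistic)


def per_sample_concordance(
    betas: pd.DataFrame,
    meth: pd.DataFrame,
    bin_index: BinIndex,
    target_regions: pd.DataFrame,
    window: int = 2000,
) -> pd.DataFrame:
    """Per-sample Pearson r plus the cross-sample average (sample = 'average')."""
    out = []
    for sample in sorted(betas["sample"].unique()):
        wp = bin_2kb(betas, meth, bin_index, target_regions, sample, window)
        out.append(
            {
                "sample": sample,
                "r": pearson_concordance(wp.pairs),
                "n_windows": len(wp.pairs),
                "n_dropped": wp.n_dropped,
            }
        )
    df = pd.DataFrame(out)
    avg = {
        "sample": "average",
        "r": float(df["r"].mean()),
        "n_windows": int(df["n_windows"].sum()),
        "n_dropped": int(df["n_dropped"].sum()),
    }
    return pd.concat([df, pd.DataFrame([avg])], ignore_index=True)


def predicted_attenuation(var_signal: float, var_a: float, var_b: float) -> float:
    """Closed-form Pearson r for two noisy readouts of a shared signal."""
    return var_signal / np.sqrt((var_signal + var_a) * (var_signal + var_b))
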