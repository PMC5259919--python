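"""CpG-island-relative methylation meta-profiles.

Every island is rescaled to ``k_internal`` equal slices (percent
coordinates) with ``flank_bp`` of absolute-coordinate flank on each
side in bin-size steps; a slice or flank window's value per sample is
the length-weighted mean RMS of the 100-bp bins it overlaps.  Islands
contribute with equal weight to the profile.  Position-wise one-way
ANOVA across subtypes (on per-sample island-averaged values, avoiding
pseudo-replication across islands) with Bonferroni correction over
axis positions localizes where the subtypes diverge.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import subtype_groups
from .regions import BinIndex, RegionSet


@dataclass
class MetaProfile:
    axis: list[str]               # e.g. -500 .. -100, 0% .. 95%, +100 .. +500
    per_sample: pd.DataFrame      # samples × positions, island-averaged
    subtype_curves: pd.DataFrame  # positions × subtypes
    island_matrix: dict[str, np.ndarray]  # subtype -> islands × positions
    flank_bp: int
    k_internal: int


def _axis_labels(flank_bp: int, bin_size: int, k_internal: int) -> list[str]:
    left = [str(-off) for off in range(flank_bp, 0, -bin_size)]
    internal = [f"{100 * i // k_internal}%" for i in range(k_internal)]
    right = [f"+{off}" for off in range(bin_size, flank_bp + bin_size, bin_size)]
    return left + internal + right


def _windows(
    island: tuple[str, int, int], flank_bp: int, bin_size: int, k_internal: int
) -> list[tuple[float, float]]:
    chrom, s, e = island
    win: list[tuple[float, float]] = []
    for off in range(flank_bp, 0, -bin_size):
        win.append((s - off, s - off + bin_size))
    L = e - s
    for i in range(k_internal):
        win.append((s + L * i / k_internal, s + L * (i + 1) / k_internal))
    for off in range(0, flank_bp, bin_size):
        win.append((e + off, e + off + bin_size))
    return win


def _weighted_window_value(
    meth_arr: np.ndarray,
    bin_index: BinIndex,
    chrom: str,
    a: float,
    b: float,
) -> np.ndarray:
    """Length-weighted mean RMS over bins overlapping [a, b); NaN outside genome."""
    size = bin_index.chrom_sizes.get(chrom, 0)
    if b <= 0 or a >= size or b <= a:
        return np.full(meth_arr.shape[1], np.nan)
    rows = bin_index.overlapping(chrom, int(np.floor(max(a, 0))), int(np.ceil(min(b, size))))
    w = []
    idx = []
    for r in rows:
        _, bs, be = bin_index.bin_bounds(r)
        ov = min(b, be) - max(a, bs)
        if ov > 0:
            w.append(ov)
            idx.append(r)
    if not idx:
        return np.full(meth_arr.shape[1], np.nan)
    w_arr = np.asarray(w)
    return (w_arr @ meth_arr[idx]) / w_arr.sum()


def compute_metaprofile(
    meth: pd.DataFrame,
    islands: RegionSet,
    bin_index: BinIndex,
    sheet: pd.DataFrame,
    flank_bp: int = 500,
    k_internal: int = 20,
) -> MetaProfile:
    """Island-relative profile with per-subtype mean curves and heatmap matrices."""
    isl = [(c, s, e) for c, ivs in islands.merged("CpGI").items() for s, e in ivs]
    if not isl:
        raise ValueError("no CpG islands supplied")
    if flank_bp % bin_index.bin_size:
        raise ValueError("flank_bp must be a multiple of bin_size")
    short = [i for i in isl if i[2] - i[1] < k_internal]
    if short:
        warnings.warn(
            f"{len(short)} island(s) shorter than {k_internal} bp: slices share bins",
            stacklevel=2,
        )
    samples = sheet["sample"].tolist()
    meth_arr = meth[samples].to_numpy(dtype=float)
    axis = _axis_labels(flank_bp, bin_index.bin_size, k_internal)
    P = len(axis)
    cube = np.empty((len(isl), P, len(samples)))
    for ii, island in enumerate(isl):
        for pi, (a, b) in enumerate(_windows(island, flank_bp, bin_index.bin_size, k_internal)):
            cube[ii, pi] = _weighted_window_value(meth_arr, bin_index, island[0], a, b)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN positions
        per_sample = pd.DataFrame(
            np.nanmean(cube, axis=0).T, index=samples, columns=axis
        )
    groups = subtype_groups(sheet)
    curves = {}
    heat = {}
    for st, members in groups.items():
        j = [samples.index(m) for m in members]
        curves[st] = per_sample.loc[members].mean(axis=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            heat[st] = np.nanmean(cube[:, :, j], axis=2)
    return MetaProfile(
        axis=axis,
        per_sample=per_sample,
        subtype_curves=pd.DataFrame(curves),
        island_matrix=heat,
        flank_bp=flank_bp,
        k_internal=k_internal,
    )


def positionwise_anova(
    per_sample: pd.DataFrame, sheet: pd.DataFrame
) -> pd.DataFrame:
    """One-way ANOVA across subtypes per axis position, Bonferroni over positions.

    The analysis unit is the per-sample island-averaged value at the
    position.  Positions where any group has < 2 finite values are NA and
    do not enter the multiplicity count.
    """
    groups = subtype_groups(sheet)
    if len(groups) < 2:
        raise ValueError("need at least two subtypes with samples")
    p_raw = np.full(per_sample.shape[1], np.nan)
    for pi, pos in enumerate(per_sample.columns):
        vals = []
        ok = True
        for members in groups.values():
            v = per_sample.loc[members, pos].to_numpy(dtype=float)
            v = v[np.isfinite(v)]
            if len(v) < 2:
                ok = False
                break
            vals.append(v)
        if not ok:
            continue
        if np.ptp(np.concatenate(vals)) == 0:
            p_raw[pi] = 1.0  # constant data: no evidence against the null
            continue
        p_raw[pi] = stats.f_oneway(*vals).pvalue
    m = int(np.isfinite(p_raw).sum())
    p_adj = np.minimum(p_raw * m, 1.0)
    return pd.DataFrame(
        {"position": per_sample.columns, "p": p_raw, "p_adj": p_adj}
    )


def profile_table(profile: MetaProfile, anova: pd.DataFrame | None = None) -> pd.DataFrame:
    """Long-format (position, subtype, mean[, p_adj]) table for export."""
    long = (
        profile.subtype_curves.reset_index(names="position")
        .melt(id_vars="position", var_name="subtype", value_name="mean_rms")
    )
    if anova is not None:
        long = long.merge(anova[["position", "p_adj"]], on="position", how="left")
    return long
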