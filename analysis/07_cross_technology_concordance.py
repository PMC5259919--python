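"""Concordance between bisulfite-style betas and binned affinity RMS.

Averages both readouts over 2-kb windows tiling the targeted regions
and reports per-sample and mean Pearson correlation between the
technologies.
"""

from _common import get_dataset, outdir

from shoremeth import concordance as conc
from shoremeth import io as sio


def main() -> None:
    ds = get_dataset()
    out = outdir()
    table = conc.per_sample_concordance(
        ds.betas, ds.meth, ds.genome.bin_index, ds.bs_regions
    )
    sio.write_table(table, out / "concordance.tsv")
    per = table[table["sample"] != "average"]
    avg = table.loc[table["sample"] == "average", "r"].iloc[0]
    print(f"per-sample Pearson r: {per['r'].min():.2f}-{per['r'].max():.2f}; "
          f"average {avg:.2f} over {per['n_windows'].iloc[0]} windows/sample")


if __name__ == "__main__":
    main()
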