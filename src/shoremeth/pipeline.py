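"""End-to-end orchestration: simulate/load → DMR → metaprofile → TFBS →
mutation → concordance → report, with a reproducibility manifest.

Every stage writes plain-text tables under the output directory; the
manifest echoes the configuration, the seed and per-stage row counts.
Given the same seed a run is byte-for-byte reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from . import concordance as conc
from . import dmr as dmr_mod
from . import io as sio
from . import metaprofile as mp
from . import mutation as mut
from . import simulate as sim
from . import tfbs as tfbs_mod
from .regions import BinIndex

PAIRS = (("luminal", "basalA"), ("luminal", "basalB"), ("basalA", "basalB"))
RATIO_REGIONS = ("shore", "intron")


@dataclass
class PipelineConfig:
    """All thresholds of the analysis, with the study's values as defaults."""

    outdir: str = "results/run"
    seed: int = 0
    sim: sim.SimConfig | None = None    # exactly one of sim / input_dir
    input_dir: str | None = None

    alpha: float = 0.05                 # Bonferroni-adjusted t-test / ANOVA level
    fdr: float = 0.1                    # BH FDR on TFBS Kruskal-Wallis
    rho_cut: float = -0.5               # Spearman anti-correlation cut
    tf_p: float = 0.05                  # TF-expression similarity KW level
    min_in: float = 0.30                # subtype-specific carrier floor
    max_out: float = 0.10               # subtype-specific carrier ceiling (others)
    stratum_width: float = 0.05         # methylation stratum width
    call_alpha: float = 1e-6            # binomial caller level
    min_coverage: int = 10
    max_reads: int = 250
    seq_error: float = 0.002
    flank_bp: int = 500                 # metaprofile flank
    k_internal: int = 20                # metaprofile island slices
    max_gap_bins: int = 0               # DMR merging gap tolerance
    concordance_window: int = 2000

    def validate(self) -> None:
        if (self.sim is None) == (self.input_dir is None):
            raise ValueError("exactly one of sim config or input_dir must be given")
        if not (0 < self.alpha < 1 and 0 < self.fdr < 1):
            raise ValueError("alpha and fdr must lie in (0, 1)")
        if self.rho_cut >= 0:
            raise ValueError("rho_cut must be negative")
        if not (0 < self.max_out < self.min_in <= 1):
            raise ValueError("need 0 < max_out < min_in <= 1")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"] = self.sim.to_dict() if self.sim else None
        # paths are environment, not results: keep the manifest location-independent
        d.pop("outdir", None)
        d.pop("input_dir", None)
        return d


def default_config(seed: int = 0, outdir: str = "results/run") -> PipelineConfig:
    return PipelineConfig(outdir=outdir, seed=seed, sim=sim.SimConfig(seed=seed))


def _load_dataset(config: PipelineConfig) -> sim.SimulatedDataset:
    if config.sim is not None:
        cfg = dataclasses.replace(config.sim, seed=config.seed)
        return sim.generate(cfg)
    indir = Path(config.input_dir)
    sizes = sio.read_chrom_sizes(indir / "chrom_sizes.tsv")
    regions = sio.read_bed(indir / "regions.bed", sizes)
    islands = sio.read_bed(indir / "cpg_islands.bed", sizes, default_label="CpGI")
    genes = sio.read_gene_models(indir / "gene_models.tsv", sizes)
    links = sio.read_table(indir / "tfbs_links.tsv")
    bin_index = BinIndex(sizes)
    from .regions import assign_bins

    labels = assign_bins(bin_index, regions)
    boundary: list[int] = []
    genome = sim.SimGenome(sizes, regions, islands, genes, links, bin_index, labels, boundary)
    sheet = sio.read_sample_sheet(indir / "sample_sheet.tsv")
    meth = sio.read_methylation(indir / "methylation.tsv")
    expr = sio.read_matrix(indir / "expression.tsv")
    sites = sio.read_table(indir / "cpg_sites.tsv")
    betas = sio.read_table(indir / "bisulfite_betas.tsv")
    bs_regions = sio.read_table(indir / "bs_target_regions.tsv")
    truth = sim.TruthTables([], [], pd.DataFrame(), pd.DataFrame(), [])
    cfg = sim.SimConfig(seed=config.seed)
    return sim.SimulatedDataset(cfg, genome, sheet, meth, expr, sites, betas, bs_regions, truth)


def run(config: PipelineConfig) -> dict:
    """Execute all stages and return the manifest (also written as JSON)."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "stages": {},
    }

    ds = _load_dataset(config)
    if config.sim is not None:
        sim.write_dataset(ds, out / "inputs")
    manifest["stages"]["simulate"] = {
        "n_bins": ds.genome.bin_index.n_bins,
        "n_samples": len(ds.samples),
        "n_sites": int(ds.sites[["chrom", "pos"]].drop_duplicates().shape[0]),
    }

    # regions stage: derived classes as BED
    sio.write_bed(ds.genome.regions, out / "region_classes.bed")
    manifest["stages"]["regions"] = {"n_intervals": len(ds.genome.regions.intervals)}

    # DMR stage
    ratio_rows = []
    dmr_counts = {}
    for pair in PAIRS:
        res = dmr_mod.pairwise_bin_test(ds.meth, ds.samples, pair, config.alpha)
        tag = f"{pair[0]}-{pair[1]}"
        sio.write_table(res.table, out / f"bin_tests_{tag}.tsv")
        dmrs = dmr_mod.merge_bins_to_dmrs(res, ds.genome.bin_index, config.max_gap_bins)
        sio.write_table(dmr_mod.dmrs_to_bed(dmrs), out / f"dmrs_{tag}.bed")
        sio.write_table(
            dmr_mod.count_by_region(res, ds.genome.bin_labels),
            out / f"dmr_region_counts_{tag}.tsv",
        )
        for region in RATIO_REGIONS:
            ratios = dmr_mod.hypomethylation_ratio(res, ds.genome.bin_labels, region)
            for st, val in ratios.items():
                ratio_rows.append(
                    {"pair": tag, "region": region, "subtype": st, "hypo_ratio": val}
                )
        dmr_counts[tag] = {
            "n_significant_bins": int(res.table["significant"].sum()),
            "n_dmrs": len(dmrs),
        }
    ratio_df = pd.DataFrame(ratio_rows)
    sio.write_table(ratio_df, out / "hypomethylation_ratios.tsv")
    manifest["stages"]["dmr"] = dmr_counts

    # metaprofile stage
    profile = mp.compute_metaprofile(
        ds.meth, ds.genome.islands, ds.genome.bin_index, ds.samples,
        config.flank_bp, config.k_internal,
    )
    anova = mp.positionwise_anova(profile.per_sample, ds.samples)
    sio.write_table(mp.profile_table(profile, anova), out / "metaprofile.tsv")
    for st, matrix in profile.island_matrix.items():
        pd.DataFrame(matrix, columns=profile.axis).to_csv(
            out / f"metaprofile_heatmap_{st}.tsv", sep="\t", index=False, float_format="%.6g"
        )
    manifest["stages"]["metaprofile"] = {
        "n_positions": len(profile.axis),
        "min_p_adj_position": str(anova.loc[anova["p_adj"].idxmin(), "position"]),
    }

    # TFBS stage
    screen = tfbs_mod.screen_tfbs(
        ds.meth, ds.genome.bin_index, ds.genome.tfbs_links, ds.expr, ds.samples,
        config.fdr, config.rho_cut, config.tf_p,
    )
    gene_table, tf_summary = tfbs_mod.integrate(screen)
    sio.write_table(screen.hits, out / "tfbs_hits.tsv")
    sio.write_table(gene_table, out / "tfbs_gene_table.tsv")
    manifest["stages"]["tfbs"] = {
        "n_tfbs": len(screen.hits),
        "n_passing_genes": tf_summary["n_genes"],
        "frac_hypo_basalB": tf_summary["frac_hypo_basalB"],
    }

    # mutation stage
    calls = mut.call_mutations(
        ds.sites, config.seq_error, config.call_alpha, config.min_coverage, config.max_reads
    )
    rates = mut.mutation_rate_by_methylation(calls, ds.samples, config.stratum_width)
    psr = mut.per_sample_stratum_rates(calls, config.stratum_width)
    anova_strata = mut.stratum_anova(psr, ds.samples, config.stratum_width)
    specific = mut.classify_subtype_specific(calls, ds.samples, config.min_in, config.max_out)
    counts, region_anova = mut.regional_mutation_counts(
        specific, calls, ds.genome.bin_index, ds.genome.bin_labels, ds.samples
    )
    sio.write_table(rates, out / "mutation_rates_by_stratum.tsv")
    sio.write_table(anova_strata, out / "mutation_stratum_anova.tsv")
    sio.write_table(specific, out / "subtype_specific_mutations.tsv")
    sio.write_table(counts, out / "specific_mutation_region_counts.tsv")
    sio.write_table(region_anova, out / "specific_mutation_region_anova.tsv")
    manifest["stages"]["mutation"] = {
        "n_calls": int(calls["is_mutated"].sum()),
        "n_specific_sites": len(specific),
    }

    # concordance stage
    conc_df = conc.per_sample_concordance(
        ds.betas, ds.meth, ds.genome.bin_index, ds.bs_regions, config.concordance_window
    )
    sio.write_table(conc_df, out / "concordance.tsv")
    manifest["stages"]["concordance"] = {
        "mean_r": float(conc_df.loc[conc_df["sample"] == "average", "r"].iloc[0]),
    }

    # report stage
    report_path = out / "summary.md"
    report_path.write_text(report(manifest, ratio_df, gene_table, rates, counts))
    manifest["stages"]["report"] = {"path": report_path.name}

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def report(
    manifest: dict,
    ratios: pd.DataFrame,
    gene_table: pd.DataFrame,
    rates: pd.DataFrame,
    region_counts: pd.DataFrame,
) -> str:
    """Human-readable markdown summary of the run's main result surfaces."""
    lines = ["# Pipeline summary", ""]
    lines.append(f"Seed: {manifest['seed']}  |  package {manifest['package_version']}")
    lines.append("")
    lines.append("## Differential methylation (per pair)")
    for tag, d in manifest["stages"]["dmr"].items():
        lines.append(f"- {tag}: {d['n_significant_bins']} significant bins, {d['n_dmrs']} DMRs")
    lines.append("")
    lines.append("## Hypomethylation ratios (shore / intron)")
    for r in ratios.itertuples(index=False):
        if pd.notna(r.hypo_ratio):
            lines.append(f"- {r.pair} {r.region}: {r.subtype} = {r.hypo_ratio:.2f}")
    lines.append("")
    tf = manifest["stages"]["tfbs"]
    lines.append("## TFBS–expression coupling")
    lines.append(
        f"- {tf['n_passing_genes']} genes with differentially methylated promoter "
        f"TFBS and inversely correlated expression "
        f"({100 * tf['frac_hypo_basalB']:.0f}% hypomethylated in basal B)"
        if tf["n_passing_genes"]
        else "- no passing genes"
    )
    lines.append("")
    lines.append("## Mutation analysis")
    mu = manifest["stages"]["mutation"]
    lines.append(f"- {mu['n_calls']} mutation calls; {mu['n_specific_sites']} subtype-specific sites")
    lines.append("")
    lines.append("## Concordance")
    lines.append(f"- mean cross-technology Pearson r = {manifest['stages']['concordance']['mean_r']:.3f}")
    lines.append("")
    return "\n".join(lines)
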