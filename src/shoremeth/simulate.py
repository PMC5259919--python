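"""Synthetic study generator.

Emulates the statistical structure of a 30-cell-line affinity-capture
methylome study of three breast-cancer subtypes (luminal, basal A,
basal B), at desk scale:

* a toy genome with non-overlapping CpG islands, stranded genes with
  exon/intron/UTR structure, promoters anchored on island shores, and
  TFBS planted inside promoter∩shore;
* a 100-bp binned relative-methylation-score (RMS) matrix in which
  luminal and basal A carry a methylation peak on island-boundary shore
  bins while basal B is flat there, and a planted subset of shore bins
  is hypomethylated in basal B;
* an expression matrix in which planted genes are inversely coupled to
  the methylation of their promoter TFBS, while the TFs' own expression
  is subtype-invariant;
* a per-CpG-site pileup table whose mutation probability depends on the
  site's methylation level and subtype, with planted subtype-specific
  mutations regionally biased (basal A to CpGI/shore/shelf, basal B to
  introns);
* per-CpG bisulfite-style beta values over target regions, for the
  cross-technology concordance stage.

Everything is deterministic given ``SimConfig.seed``: independent child
generators are spawned per stage, so two runs emit byte-identical files.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as sio
from .regions import (
    BinIndex,
    GenomicInterval,
    RegionSet,
    assign_bins,
    derive_introns,
    derive_promoters,
    derive_shores_shelves,
)

SUBTYPES = ("luminal", "basalA", "basalB")
_PREFIX = {"luminal": "Lu", "basalA": "BaA", "basalB": "BaB"}


# ---------------------------------------------------------------------------
# Mutation-rate models (serializable callables)
# ---------------------------------------------------------------------------

@dataclass
class LinearRateModel:
    """Mutation probability rising linearly with methylation.

    Basal A gets a bonus below ``basalA_low_threshold`` (higher rates at
    low/intermediate methylation), basal B above ``basalB_high_threshold``
    (higher rates at hypermethylated sites).
    """

    intercept: float = 0.005
    slope: float = 0.02
    basalA_low_bonus: float = 0.02
    basalA_low_threshold: float = 0.5
    basalB_high_bonus: float = 0.03
    basalB_high_threshold: float = 0.7

    kind = "linear"

    def rate(self, subtype: str, rms: np.ndarray) -> np.ndarray:
        rms = np.asarray(rms, dtype=float)
        r = self.intercept + self.slope * rms
        if subtype == "basalA":
            r = r + self.basalA_low_bonus * (rms < self.basalA_low_threshold)
        elif subtype == "basalB":
            r = r + self.basalB_high_bonus * (rms >= self.basalB_high_threshold)
        return np.clip(r, 0.0, 1.0)

    def to_dict(self) -> dict:
        return {"kind": self.kind, **dataclasses.asdict(self)}


@dataclass
class StepRateModel:
    """Two-level step rate: ``low`` below ``threshold``, ``high`` at/above.

    Per-subtype multiplicative scales can differ below and above the
    threshold, e.g. a 3x basal A excess confined to low-methylation sites.
    """

    low: float = 0.01
    high: float = 0.05
    threshold: float = 0.5
    scale_low: dict[str, float] = field(default_factory=dict)
    scale_high: dict[str, float] = field(default_factory=dict)

    kind = "step"

    def rate(self, subtype: str, rms: np.ndarray) -> np.ndarray:
        rms = np.asarray(rms, dtype=float)
        base = np.where(rms < self.threshold, self.low, self.high)
        scale = np.where(
            rms < self.threshold,
            self.scale_low.get(subtype, 1.0),
            self.scale_high.get(subtype, 1.0),
        )
        return np.clip(base * scale, 0.0, 1.0)

    def to_dict(self) -> dict:
        return {"kind": self.kind, **dataclasses.asdict(self)}


def rate_model_from_dict(d: dict) -> LinearRateModel | StepRateModel:
    d = dict(d)
    kind = d.pop("kind")
    if kind == "linear":
        return LinearRateModel(**d)
    if kind == "step":
        return StepRateModel(**d)
    raise ValueError(f"unknown rate model kind {kind!r}")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Study conditions for the synthetic dataset.

    Defaults: 10 samples per subtype; 50 islands whose 2-kb flanks give
    2,000 shore-labelled 100-bp bins; 200 of them hypomethylated by
    -0.3 RMS in every basal B sample; truncated-normal RMS noise sd 0.1;
    20 of 30 genes inversely coupled to promoter-TFBS methylation.
    """

    seed: int = 0

    # genome geometry
    n_chroms: int = 2
    chrom_len: int = 300_000
    bin_size: int = 100
    n_islands: int = 50
    island_len_range: tuple[int, int] = (500, 1000)
    shore_width: int = 2000
    shelf_width: int = 2000
    promoter_len: int = 2000
    n_genes: int = 30
    gene_len: int = 3000
    n_tfbs_per_promoter: int = 2
    tfbs_len: int = 150
    n_tfs: int = 8

    # samples
    samples_per_subtype: dict[str, int] = field(
        default_factory=lambda: {"luminal": 10, "basalA": 10, "basalB": 10}
    )

    # methylation
    region_mean_rms: dict[str, float] = field(
        default_factory=lambda: {
            "CpGI": 0.25,     # islands largely methyl-protected
            "shore": 0.45,
            "shelf": 0.40,
            "gene": 0.70,     # gene bodies heavily methylated
            "intergenic": 0.35,
        }
    )
    boundary_peak_effect: float = 0.25
    shore_hypo_effect: float = -0.3
    n_affected_shore_bins: int = 200
    noise_sd: float = 0.1

    # expression
    n_coupled_genes: int = 20
    expr_baseline_mean: float = 8.0
    expr_baseline_sd: float = 1.0
    coupling_strength: float = 5.0
    expr_noise_sd: float = 0.3

    # mutations
    n_cpg_sites: int = 4000
    coverage_mean: float = 30.0
    max_reads: int = 250
    seq_error: float = 0.002
    het_fraction: float = 0.5
    mutation_rate_model: LinearRateModel | StepRateModel = field(
        default_factory=LinearRateModel
    )
    n_specific_per_subtype: int = 25
    specific_carrier_range: tuple[float, float] = (0.3, 0.6)

    # bisulfite concordance
    n_bs_regions: int = 20
    bs_region_len: int = 4000
    bs_cpg_spacing: int = 200
    bs_noise_sd: float = 0.1
    bs_samples_per_subtype: int = 2

    def validate(self) -> None:
        for k, v in self.samples_per_subtype.items():
            if k not in SUBTYPES:
                raise ValueError(f"unknown subtype {k!r}")
            if v <= 0:
                raise ValueError("sample counts must be positive")
        for m in self.region_mean_rms.values():
            if not 0.0 <= m <= 1.0:
                raise ValueError("region mean RMS must lie in [0, 1]")
        if self.n_islands < 0 or self.n_genes < 0:
            raise ValueError("counts must be non-negative")
        if self.n_genes > self.n_islands:
            raise ValueError("each gene is anchored to a distinct island")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["mutation_rate_model"] = self.mutation_rate_model.to_dict()
        d["island_len_range"] = list(self.island_len_range)
        d["specific_carrier_range"] = list(self.specific_carrier_range)
        return d


def sample_sheet(config: SimConfig) -> pd.DataFrame:
    rows = [
        {"sample": f"{_PREFIX[st]}{i + 1:02d}", "subtype": st}
        for st in SUBTYPES
        if st in config.samples_per_subtype
        for i in range(config.samples_per_subtype[st])
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------

@dataclass
class SimGenome:
    chrom_sizes: dict[str, int]
    regions: RegionSet            # all labels incl. derived shores/shelves etc.
    islands: RegionSet
    genes: RegionSet              # gene + exon + UTR intervals
    tfbs_links: pd.DataFrame      # tfbs_id, tf_id, target_gene, validated, coords
    bin_index: BinIndex
    bin_labels: list[set[str]]
    boundary_bins: list[int]      # first shore bin on each side of each island


def generate_genome(config: SimConfig, rng: np.random.Generator | None = None) -> SimGenome:
    """Lay out islands, genes, and TFBS on a toy genome, deterministically.

    Each island occupies one slot of its chromosome; genes are anchored so
    that their 2-kb promoter coincides with one shore of the island (the
    right shore for + genes, the left for - genes), guaranteeing non-empty
    promoter∩shore for TFBS planting.
    """
    config.validate()
    rng = rng or np.random.default_rng(config.seed)
    bs = config.bin_size
    chrom_sizes = {f"chr{i + 1}": config.chrom_len for i in range(config.n_chroms)}

    # feasibility: a slot must hold margins for flanks + promoter + gene body
    margin = max(config.shore_width + config.shelf_width,
                 config.promoter_len + config.gene_len)
    max_island = config.island_len_range[1]
    jitter = 1000
    per_chrom = [config.n_islands // config.n_chroms] * config.n_chroms
    for i in range(config.n_islands % config.n_chroms):
        per_chrom[i] += 1
    island_ivs: list[GenomicInterval] = []
    slots: list[tuple[str, int, int]] = []  # (chrom, slot_start, slot_len)
    for ci, (chrom, n_isl) in enumerate(zip(chrom_sizes, per_chrom)):
        if n_isl == 0:
            continue
        slot_len = (config.chrom_len // n_isl) // bs * bs
        if slot_len < 2 * margin + jitter + max_island:
            raise ValueError(
                "infeasible geometry: islands+genes do not fit "
                f"(slot {slot_len} bp < required {2 * margin + jitter + max_island} bp)"
            )
        for k in range(n_isl):
            slot_start = k * slot_len
            off = int(rng.integers(margin // bs, (margin + jitter) // bs + 1)) * bs
            ilen = (
                int(
                    rng.integers(
                        config.island_len_range[0] // bs,
                        config.island_len_range[1] // bs + 1,
                    )
                )
                * bs
            )
            s = slot_start + off
            island_ivs.append(GenomicInterval(chrom, s, s + ilen, label="CpGI"))
            slots.append((chrom, slot_start, slot_len))
    islands = RegionSet(island_ivs, dict(chrom_sizes))

    # genes anchored to a random subset of islands, alternating strand
    gene_ivs: list[GenomicInterval] = []
    order = rng.permutation(len(island_ivs))[: config.n_genes]
    gene_anchor: dict[str, GenomicInterval] = {}
    for gi, isl_idx in enumerate(sorted(order)):
        isl = island_ivs[isl_idx]
        gene_id = f"G{gi + 1:03d}"
        strand = "+" if gi % 2 == 0 else "-"
        if strand == "+":
            tss_pos = isl.end + config.promoter_len
            g = GenomicInterval(
                isl.chrom, tss_pos, tss_pos + config.gene_len, "+", "gene", gene_id
            )
        else:
            tss_pos = isl.start - config.promoter_len
            g = GenomicInterval(
                isl.chrom, tss_pos - config.gene_len, tss_pos, "-", "gene", gene_id
            )
        gene_ivs.append(g)
        gene_anchor[gene_id] = isl
        # three exons at fixed offsets within the body; UTRs at the ends
        L = config.gene_len
        rel_exons = [(0, 500), (L // 2 - 250, L // 2 + 250), (L - 500, L)]
        for s_rel, e_rel in rel_exons:
            gene_ivs.append(
                GenomicInterval(g.chrom, g.start + s_rel, g.start + e_rel, strand, "exon", gene_id)
            )
        if strand == "+":
            u5 = (g.start, g.start + 200)
            u3 = (g.end - 200, g.end)
        else:
            u5 = (g.end - 200, g.end)
            u3 = (g.start, g.start + 200)
        gene_ivs.append(GenomicInterval(g.chrom, *u5, strand, "UTR5", gene_id))
        gene_ivs.append(GenomicInterval(g.chrom, *u3, strand, "UTR3", gene_id))
    genes = RegionSet(gene_ivs, dict(chrom_sizes))

    # TFBS inside each promoter (== one shore of the anchor island)
    promoters = derive_promoters(genes, config.promoter_len)
    tf_pool = [f"TF{i + 1}" for i in range(config.n_tfs)]
    links = []
    tfbs_ivs: list[GenomicInterval] = []
    for p in promoters.intervals:
        span = (p.end - p.start) - config.tfbs_len
        starts = sorted(
            int(rng.integers(0, span + 1)) for _ in range(config.n_tfbs_per_promoter)
        )
        for j, off in enumerate(starts):
            iv = GenomicInterval(
                p.chrom, p.start + off, p.start + off + config.tfbs_len,
                p.strand, "TFBS", p.gene_id,
            )
            tfbs_ivs.append(iv)
            links.append(
                {
                    "tfbs_id": f"tfbs_{p.gene_id}_{j + 1}",
                    "tf_id": tf_pool[int(rng.integers(0, len(tf_pool)))],
                    "target_gene": p.gene_id,
                    "validated": True,
                    "chrom": iv.chrom,
                    "start": iv.start,
                    "end": iv.end,
                }
            )
    tfbs_links = pd.DataFrame(
        links, columns=["tfbs_id", "tf_id", "target_gene", "validated", "chrom", "start", "end"]
    )

    flanks = derive_shores_shelves(islands, config.shore_width, config.shelf_width)
    introns = derive_introns(genes)
    full = RegionSet(list(island_ivs), dict(chrom_sizes))
    full.extend(flanks)
    full.extend(genes)
    full.extend(introns)
    full.extend(promoters)
    full.extend(RegionSet(tfbs_ivs, dict(chrom_sizes)))

    bin_index = BinIndex(chrom_sizes, bs)
    bin_labels = assign_bins(bin_index, full)

    boundary = []
    for isl in island_ivs:
        left = bin_index.overlapping(isl.chrom, isl.start - bs, isl.start)
        right = bin_index.overlapping(isl.chrom, isl.end, isl.end + bs)
        boundary.extend(left)
        boundary.extend(right)
    return SimGenome(
        chrom_sizes, full, islands, genes, tfbs_links, bin_index, bin_labels, sorted(boundary)
    )


# ---------------------------------------------------------------------------
# Methylation
# ---------------------------------------------------------------------------

# gene-body methylation outranks shelf so intragenic flank bins read as gene body
_MEAN_PRIORITY = ("CpGI", "shore", "gene", "shelf", "intergenic")


def _bin_base_means(genome: SimGenome, config: SimConfig) -> np.ndarray:
    means = np.empty(genome.bin_index.n_bins)
    fallback = config.region_mean_rms.get("intergenic", 0.35)
    for i, labs in enumerate(genome.bin_labels):
        for lab in _MEAN_PRIORITY:
            if lab in labs and lab in config.region_mean_rms:
                means[i] = config.region_mean_rms[lab]
                break
        else:
            means[i] = fallback
    return means


def _tfbs_shore_bins(genome: SimGenome, gene_ids: set[str]) -> list[int]:
    rows: set[int] = set()
    sub = genome.tfbs_links[genome.tfbs_links["target_gene"].isin(gene_ids)]
    for r in sub.itertuples(index=False):
        rows.update(genome.bin_index.overlapping(r.chrom, int(r.start), int(r.end)))
    return sorted(rows)


def simulate_methylation(
    genome: SimGenome,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    coupled_genes: list[str] | None = None,
) -> tuple[pd.DataFrame, list[int]]:
    """Bins × samples RMS matrix; returns (matrix, planted hypo-bin rows).

    RMS = clamp(region mean + subtype effect + N(0, noise_sd)) to [0, 1].
    Luminal and basal A receive ``boundary_peak_effect`` on island-boundary
    shore bins; basal B receives ``shore_hypo_effect`` on the planted bins
    (which always include the TFBS bins of coupled genes).
    """
    rng = rng or np.random.default_rng(config.seed)
    sheet = sample_sheet(config)
    base = _bin_base_means(genome, config)

    shore_rows = [i for i, labs in enumerate(genome.bin_labels) if "shore" in labs]
    coupled = coupled_genes if coupled_genes is not None else _default_coupled(genome, config)
    tfbs_rows = _tfbs_shore_bins(genome, set(coupled))
    affected = list(tfbs_rows)
    remaining = [r for r in shore_rows if r not in set(affected)]
    n_fill = max(0, config.n_affected_shore_bins - len(affected))
    if n_fill and remaining:
        pick = rng.choice(len(remaining), size=min(n_fill, len(remaining)), replace=False)
        affected.extend(remaining[i] for i in sorted(pick))
    affected = sorted(affected)

    n_bins = genome.bin_index.n_bins
    cols = {}
    boundary = np.zeros(n_bins)
    boundary[genome.boundary_bins] = config.boundary_peak_effect
    hypo = np.zeros(n_bins)
    hypo[affected] = config.shore_hypo_effect
    for r in sheet.itertuples(index=False):
        mu = base.copy()
        if r.subtype in ("luminal", "basalA"):
            mu = mu + boundary
        else:
            mu = mu + hypo
        cols[r.sample] = np.clip(mu + rng.normal(0.0, config.noise_sd, n_bins), 0.0, 1.0)
    return pd.DataFrame(cols), affected


def _default_coupled(genome: SimGenome, config: SimConfig) -> list[str]:
    gene_ids = sorted({g.gene_id for g in genome.genes.by_label("gene")})
    return gene_ids[: config.n_coupled_genes]


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def tfbs_mean_methylation(
    meth: pd.DataFrame, genome: SimGenome
) -> pd.DataFrame:
    """Per-TFBS mean RMS over overlapping bins (tfbs_id × samples)."""
    rows = {}
    for r in genome.tfbs_links.itertuples(index=False):
        idx = list(genome.bin_index.overlapping(r.chrom, int(r.start), int(r.end)))
        rows[r.tfbs_id] = meth.iloc[idx].mean(axis=0)
    return pd.DataFrame(rows).T


def simulate_expression(
    meth: pd.DataFrame,
    genome: SimGenome,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    coupled_genes: list[str] | None = None,
) -> pd.DataFrame:
    """Genes (targets + TFs) × samples expression matrix.

    Coupled genes: baseline − coupling_strength · (mean promoter-TFBS RMS)
    + noise.  Uncoupled targets and TF genes: baseline + noise, identical
    across subtypes by construction.
    """
    rng = rng or np.random.default_rng(config.seed)
    sheet = sample_sheet(config)
    samples = sheet["sample"].tolist()
    coupled = set(
        coupled_genes if coupled_genes is not None else _default_coupled(genome, config)
    )
    tf_meth = tfbs_mean_methylation(meth, genome)
    per_gene = tf_meth.join(genome.tfbs_links.set_index("tfbs_id")["target_gene"]).groupby(
        "target_gene"
    ).mean()

    gene_ids = sorted({g.gene_id for g in genome.genes.by_label("gene")})
    tf_ids = sorted(genome.tfbs_links["tf_id"].unique())
    rows = {}
    for gid in gene_ids:
        a = rng.normal(config.expr_baseline_mean, config.expr_baseline_sd)
        noise = rng.normal(0.0, config.expr_noise_sd, len(samples))
        if gid in coupled and gid in per_gene.index:
            rows[gid] = a - config.coupling_strength * per_gene.loc[gid, samples].to_numpy() + noise
        else:
            rows[gid] = a + noise
    for tid in tf_ids:
        a = rng.normal(config.expr_baseline_mean, config.expr_baseline_sd)
        rows[tid] = a + rng.normal(0.0, config.expr_noise_sd, len(samples))
    return pd.DataFrame(rows, index=samples).T


# ---------------------------------------------------------------------------
# Mutations
# ---------------------------------------------------------------------------

def simulate_mutations(
    meth: pd.DataFrame,
    bin_index: BinIndex,
    bin_labels: list[set[str]],
    sheet: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-site per-sample pileup table and the planted-specific truth table.

    Sites are scattered over bins; per site and sample the mutation
    probability is ``mutation_rate_model.rate(subtype, rms)`` with the
    sample's RMS of the containing bin.  Planted subtype-specific sites
    carry the mutation in 30–60% of one subtype's samples and are kept
    free of background mutations elsewhere.  Coverage ~ Poisson(mean
    ``coverage_mean``); mutated site-samples draw mismatches at VAF 0.5
    (het) or 1.0 (hom), others at the sequencing error rate.
    """
    rng = rng or np.random.default_rng(config.seed)
    n_bins = bin_index.n_bins
    n_sites = min(config.n_cpg_sites, n_bins * (bin_index.bin_size // 2))
    bin_rows = np.sort(rng.choice(n_bins, size=n_sites, replace=n_sites > n_bins))
    offsets = rng.integers(0, bin_index.bin_size, size=n_sites)
    coords = []
    seen = set()
    for b, off in zip(bin_rows, offsets):
        chrom, s, e = bin_index.bin_bounds(int(b))
        pos = min(s + int(off), e - 1)
        while (chrom, pos) in seen:
            pos = s + int(rng.integers(0, e - s))
        seen.add((chrom, pos))
        coords.append((chrom, pos, int(b)))
    site_df = pd.DataFrame(coords, columns=["chrom", "pos", "bin"])

    samples = sheet["sample"].tolist()
    subtype_of = dict(zip(sheet["sample"], sheet["subtype"]))
    rms = meth.loc[site_df["bin"].to_numpy(), samples].to_numpy()  # sites × samples

    mutated = np.zeros((n_sites, len(samples)), dtype=bool)
    planted = np.zeros(n_sites, dtype=bool)

    # planted subtype-specific sites with regional bias; pools are kept
    # disjoint in region space (island-related bins outside gene bodies for
    # basal A, intronic bins outside island flanks for basal B) so the
    # regional count table reflects the planted enrichment cleanly
    island_related = {"CpGI", "shore", "shelf"}
    region_pool = {
        "basalA": [
            i for i, b in enumerate(site_df["bin"])
            if bin_labels[b] & island_related and "gene" not in bin_labels[b]
        ],
        "basalB": [
            i for i, b in enumerate(site_df["bin"])
            if "intron" in bin_labels[b] and not bin_labels[b] & island_related
        ],
    }
    region_pool["luminal"] = [
        i for i in range(n_sites)
        if i not in set(region_pool["basalA"]) | set(region_pool["basalB"])
    ]
    truth_rows = []
    lo, hi = config.specific_carrier_range
    for st in SUBTYPES:
        members = [j for j, s in enumerate(samples) if subtype_of[s] == st]
        if not members or config.n_specific_per_subtype == 0:
            continue
        pool = [i for i in region_pool.get(st, []) if not planted[i]]
        take = min(config.n_specific_per_subtype, len(pool))
        if take == 0:
            continue
        chosen = rng.choice(len(pool), size=take, replace=False)
        for c in sorted(chosen):
            i = pool[c]
            planted[i] = True
            k_min = int(np.ceil(lo * len(members)))
            k_max = max(k_min, int(np.floor(hi * len(members))))
            k = int(rng.integers(k_min, k_max + 1))
            carriers = rng.choice(members, size=k, replace=False)
            mutated[i, carriers] = True
            truth_rows.append(
                {
                    "chrom": site_df.at[i, "chrom"],
                    "pos": int(site_df.at[i, "pos"]),
                    "subtype": st,
                    "n_carriers": k,
                }
            )
    truth = pd.DataFrame(truth_rows, columns=["chrom", "pos", "subtype", "n_carriers"])

    # background sporadic mutations on non-planted sites
    for j, s in enumerate(samples):
        p = config.mutation_rate_model.rate(subtype_of[s], rms[:, j])
        bg = rng.random(n_sites) < p
        mutated[~planted, j] |= bg[~planted]

    cov = rng.poisson(config.coverage_mean, size=(n_sites, len(samples)))
    cov = np.clip(cov, 1, config.max_reads)
    het = rng.random((n_sites, len(samples))) < config.het_fraction
    vaf = np.where(het, 0.5, 1.0)
    mm = rng.binomial(cov, np.where(mutated, vaf, config.seq_error))

    long = pd.DataFrame(
        {
            "chrom": np.repeat(site_df["chrom"].to_numpy(), len(samples)),
            "pos": np.repeat(site_df["pos"].to_numpy(), len(samples)),
            "sample": np.tile(np.array(samples, dtype=object), n_sites),
            "coverage": cov.ravel(),
            "mismatches": mm.ravel(),
            "rms": rms.ravel(),
        }
    )
    return long, truth


# ---------------------------------------------------------------------------
# Bisulfite betas for concordance
# ---------------------------------------------------------------------------

def simulate_bisulfite(
    meth: pd.DataFrame,
    genome: SimGenome,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-CpG beta values over target regions centred on island boundaries.

    beta = clamp(bin RMS + N(0, bs_noise_sd)); a few samples per subtype
    are profiled, mirroring a targeted validation experiment.
    Returns (betas long table, target regions table).
    """
    rng = rng or np.random.default_rng(config.seed)
    sheet = sample_sheet(config)
    chosen = (
        sheet.groupby("subtype", sort=False)
        .head(config.bs_samples_per_subtype)["sample"]
        .tolist()
    )
    islands = genome.islands.intervals[: config.n_bs_regions]
    regions = []
    for isl in islands:
        half = config.bs_region_len // 2
        s = max(0, isl.start - half)
        regions.append({"chrom": isl.chrom, "start": s, "end": s + config.bs_region_len})
    regions_df = pd.DataFrame(regions)

    rows = []
    for reg in regions_df.itertuples(index=False):
        for pos in range(reg.start + 1, reg.end, config.bs_cpg_spacing):
            rs = list(genome.bin_index.overlapping(reg.chrom, pos, pos + 1))
            if not rs:
                continue
            base = meth.loc[rs[0], chosen].to_numpy()
            betas = np.clip(base + rng.normal(0.0, config.bs_noise_sd, len(chosen)), 0, 1)
            covs = rng.poisson(config.coverage_mean, len(chosen))
            for s_name, b, c in zip(chosen, betas, covs):
                rows.append((reg.chrom, pos, s_name, b, int(max(1, c))))
    betas_df = pd.DataFrame(rows, columns=["chrom", "pos", "sample", "beta", "coverage"])
    return betas_df, regions_df


# ---------------------------------------------------------------------------
# Whole-dataset orchestration and round-trip I/O
# ---------------------------------------------------------------------------

@dataclass
class TruthTables:
    dmr_bins: list[int]
    coupled_genes: list[str]
    stratum_rates: pd.DataFrame      # subtype × stratum midpoint planted probability
    specific_sites: pd.DataFrame     # chrom, pos, subtype, n_carriers
    boundary_bins: list[int]


@dataclass
class SimulatedDataset:
    config: SimConfig
    genome: SimGenome
    samples: pd.DataFrame
    meth: pd.DataFrame
    expr: pd.DataFrame
    sites: pd.DataFrame
    betas: pd.DataFrame
    bs_regions: pd.DataFrame
    truth: TruthTables


def _planted_stratum_rates(config: SimConfig, width: float = 0.05) -> pd.DataFrame:
    mids = np.arange(width / 2, 1.0, width)
    rows = []
    for st in SUBTYPES:
        for m in mids:
            rows.append(
                {
                    "subtype": st,
                    "stratum_mid": round(float(m), 6),
                    "rate": float(config.mutation_rate_model.rate(st, np.array([m]))[0]),
                }
            )
    return pd.DataFrame(rows)


def generate(config: SimConfig) -> SimulatedDataset:
    """Generate the full synthetic study, deterministically from the seed."""
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    r_genome, r_meth, r_expr, r_mut, r_bs = (
        np.random.default_rng(c) for c in ss.spawn(5)
    )
    genome = generate_genome(config, r_genome)
    coupled = _default_coupled(genome, config)
    meth, affected = simulate_methylation(genome, config, r_meth, coupled)
    expr = simulate_expression(meth, genome, config, r_expr, coupled)
    sheet = sample_sheet(config)
    sites, specific = simulate_mutations(
        meth, genome.bin_index, genome.bin_labels, sheet, config, r_mut
    )
    betas, bs_regions = simulate_bisulfite(meth, genome, config, r_bs)
    truth = TruthTables(
        dmr_bins=affected,
        coupled_genes=coupled,
        stratum_rates=_planted_stratum_rates(config),
        specific_sites=specific,
        boundary_bins=genome.boundary_bins,
    )
    return SimulatedDataset(
        config, genome, sheet, meth, expr, sites, betas, bs_regions, truth
    )


def write_dataset(ds: SimulatedDataset, outdir: str | Path) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    sio.write_chrom_sizes(ds.genome.chrom_sizes, out / "chrom_sizes.tsv")
    sio.write_bed(ds.genome.regions, out / "regions.bed")
    sio.write_bed(ds.genome.islands, out / "cpg_islands.bed")
    sio.write_gene_models(ds.genome.genes, out / "gene_models.tsv")
    sio.write_table(ds.genome.tfbs_links, out / "tfbs_links.tsv")
    sio.write_methylation(ds.meth, ds.genome.bin_index, out / "methylation.tsv")
    sio.write_matrix(ds.expr, out / "expression.tsv", "gene")
    sio.write_table(ds.sites, out / "cpg_sites.tsv")
    sio.write_table(ds.samples, out / "sample_sheet.tsv")
    sio.write_table(ds.betas, out / "bisulfite_betas.tsv")
    sio.write_table(ds.bs_regions, out / "bs_target_regions.tsv")
    sio.write_table(ds.truth.specific_sites, out / "truth_specific_sites.tsv")
    sio.write_table(ds.truth.stratum_rates, out / "truth_stratum_rates.tsv")
    pd.DataFrame({"bin": ds.truth.dmr_bins}).to_csv(out / "truth_dmr_bins.tsv", sep="\t", index=False)
    pd.DataFrame({"gene": ds.truth.coupled_genes}).to_csv(out / "truth_coupled_genes.tsv", sep="\t", index=False)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(ds.config.to_dict(), fh, sort_keys=True)


def load_methylation(outdir: str | Path) -> tuple[pd.DataFrame, BinIndex]:
    out = Path(outdir)
    sizes = sio.read_chrom_sizes(out / "chrom_sizes.tsv")
    meth = sio.read_methylation(out / "methylation.tsv")
    return meth, BinIndex(sizes)
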