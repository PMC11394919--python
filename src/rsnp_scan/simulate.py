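"""Synthetic study generator with known ground truth.

Emulates the statistical structure of a paired ChIP-seq / RNA-seq
allele-specific study on a single synthetic chromosome: beta-binomially
overdispersed allele counts at heterozygous sites, planted allelic imbalance
at a known subset of regulated genes, multi-SNP genes with alternative
transcription start sites, variant catalogs with planted overlap enrichment,
negative-binomial expression counts with planted log-fold-changes, and a
protein-interaction graph with planted dense modules.

Reads and alignment are not simulated; the dual-genome remapping protocol
that removes reference-mapping bias is represented by a counting-mode
switch (``mode="dual_genome"`` draws unbiased counts, ``mode="naive"``
shifts the reference-allele probability by ``ref_bias_delta``).

All generators are deterministic functions of ``SimConfig.seed``: the same
configuration yields bit-identical outputs regardless of call order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

ASSAYS_CHIP = ("H3K4me3", "H3K27ac")
ASSAY_RNA = "RNA"
ASSAYS = ASSAYS_CHIP + (ASSAY_RNA,)

_BASES = np.array(list("ACGT"))

# fixed sub-seed offsets so each generator draws an independent,
# call-order-independent stream from the master seed
_SS_LAYOUT = 1
_SS_DEPTHS = 2
_SS_CATALOG = 3
_SS_COUNTS = 4
_SS_PPI = 5
_SS_IDMAP = 6
_SS_GENESETS = 7


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study.

    Counts are per the unit named; ``(lo, hi)`` pairs are inclusive ranges
    sampled uniformly.  ``overdispersion_rho`` is the beta-binomial
    intra-class correlation (0 reduces to binomial).  ``imbalance_fraction``
    is the fraction of genes with a planted regulatory event: their promoter
    sites carry allelic imbalance in both chromatin marks and their gene-body
    sites carry the same-magnitude imbalance in RNA.  ``imbalanced_maf`` is
    the true major-allele frequency at planted sites.  ``ref_bias_delta``
    shifts the reference-allele probability upward at every site, but only
    in "naive" counting mode; dual-genome mode is unbiased.
    """

    seed: int = 0
    n_individuals: int = 9
    n_genes: int = 200
    n_transcripts_per_gene: tuple[int, int] = (1, 3)
    n_het_sites_per_promoter: tuple[int, int] = (1, 3)
    n_het_sites_per_gene_body: tuple[int, int] = (2, 4)
    het_rate: float = 0.8
    mean_depth: float = 60.0
    overdispersion_rho: float = 0.02
    imbalance_fraction: float = 0.1
    imbalanced_maf: float = 0.75
    ref_bias_delta: float = 0.05
    # differential expression
    de_fraction: float = 0.1
    de_log2fc: float = 1.0
    nb_dispersion: float = 0.05
    de_n_per_group: tuple[int, int] = (10, 10)
    # protein-interaction graph
    n_graph_nodes: int = 120
    n_modules: int = 3
    module_size: int = 8
    background_edge_p: float = 0.05
    # catalogs
    catalog_base_p: float = 0.05
    catalog_overlap_enrichment: float = 8.0
    trait_sizes: tuple[int, ...] = (60, 90, 150, 250, 400)
    rs_id_coverage: float = 0.7

    def __post_init__(self) -> None:
        for name in ("n_individuals", "n_genes", "n_graph_nodes", "n_modules", "module_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("n_transcripts_per_gene", "n_het_sites_per_promoter",
                     "n_het_sites_per_gene_body"):
            lo, hi = getattr(self, name)
            if lo < 1 or hi < lo:
                raise ValueError(f"{name} must be an inclusive range with lo >= 1")
        for name in ("het_rate", "imbalance_fraction", "de_fraction",
                     "background_edge_p", "catalog_base_p", "rs_id_coverage",
                     "ref_bias_delta"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0.0 <= self.overdispersion_rho < 1.0:
            raise ValueError("overdispersion_rho must lie in [0, 1)")
        if not 0.5 < self.imbalanced_maf <= 1.0:
            raise ValueError("imbalanced_maf must lie in (0.5, 1]")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be non-negative")


@dataclass
class GroundTruth:
    """Planted truth for scoring pipeline output.

    ``true_imbalanced_sites`` maps assay name to the set of (chrom, pos)
    with planted imbalance in that assay; ``true_rsnps`` are the promoter
    sites of regulated genes (a subset of every ChIP assay's imbalanced
    sites); every true rSNP's target gene is in ``true_ase_genes``.
    """

    true_imbalanced_sites: dict[str, set[tuple[str, int]]] = field(default_factory=dict)
    true_ase_genes: set[str] = field(default_factory=set)
    true_rsnps: set[tuple[str, int]] = field(default_factory=set)
    true_rsnp_genes: dict[tuple[str, int], str] = field(default_factory=dict)
    true_de_genes: dict[str, float] = field(default_factory=dict)
    true_modules: list[set[str]] = field(default_factory=list)

    def to_json(self) -> str:
        payload = {
            "true_imbalanced_sites": {
                a: sorted([c, int(p)] for c, p in s)
                for a, s in self.true_imbalanced_sites.items()
            },
            "true_ase_genes": sorted(self.true_ase_genes),
            "true_rsnps": sorted([c, int(p)] for c, p in self.true_rsnps),
            "true_rsnp_genes": {f"{c}:{p}": g for (c, p), g in sorted(self.true_rsnp_genes.items())},
            "true_de_genes": dict(sorted(self.true_de_genes.items())),
            "true_modules": [sorted(m) for m in self.true_modules],
        }
        return json.dumps(payload, indent=1)


@dataclass
class SimulatedStudy:
    """Bundle of every input the pipeline consumes, plus the planted truth."""

    config: SimConfig
    depths: pd.DataFrame
    transcripts: pd.DataFrame
    catalogs: pd.DataFrame
    counts: pd.DataFrame
    condition_labels: pd.Series
    edges: pd.DataFrame
    gene_sets: dict[str, set[str]]
    id_map: pd.DataFrame
    truth: GroundTruth


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(cfg.seed), stream]))


# ---------------------------------------------------------------------------
# genome layout (shared between annotation and depth simulation)
# ---------------------------------------------------------------------------

def _layout(cfg: SimConfig) -> dict:
    """Deterministic chromosome layout: gene intervals, strands, transcripts,
    het-site positions and planted regulatory assignments.

    Genes are non-overlapping with intergenic gaps > 2100 bp so a +/-1000 bp
    promoter never reaches a neighbouring gene.  Promoter het sites are
    placed strictly upstream of the primary TSS (inside its +/-1000 bp
    promoter but outside the gene body) and gene-body het sites inside the
    gene, so every site is covered by either the two ChIP assays (promoter)
    or RNA (gene body), never both.
    """
    rng = _rng(cfg, _SS_LAYOUT)
    n = cfg.n_genes

    lengths = rng.integers(2000, 6001, size=n)
    gaps = rng.integers(2101, 4001, size=n)
    starts = np.empty(n, dtype=np.int64)
    pos = 2000  # leave room for the first gene's upstream promoter
    for i in range(n):
        starts[i] = pos + gaps[i]
        pos = starts[i] + lengths[i]
    ends = starts + lengths - 1
    strands = rng.choice(["+", "-"], size=n)
    gene_ids = np.array([f"G{i:04d}" for i in range(n)])

    # transcripts: first spans the gene; extras get a TSS shifted into the body
    tx_rows = []
    lo, hi = cfg.n_transcripts_per_gene
    n_tx = rng.integers(lo, hi + 1, size=n)
    for i in range(n):
        tx_rows.append((gene_ids[i], f"{gene_ids[i]}.t0", "chrS", strands[i],
                        int(starts[i]), int(ends[i])))
        for t in range(1, n_tx[i]):
            shift = int(rng.integers(200, max(201, lengths[i] // 2)))
            if strands[i] == "+":
                tx_rows.append((gene_ids[i], f"{gene_ids[i]}.t{t}", "chrS", strands[i],
                                int(starts[i] + shift), int(ends[i])))
            else:
                tx_rows.append((gene_ids[i], f"{gene_ids[i]}.t{t}", "chrS", strands[i],
                                int(starts[i]), int(ends[i] - shift)))
    transcripts = pd.DataFrame(
        tx_rows, columns=["gene_id", "transcript_id", "chrom", "strand", "start", "end"]
    )
    transcripts["tss"] = np.where(
        transcripts["strand"] == "+", transcripts["start"], transcripts["end"]
    )

    # primary TSS per gene and het-site placement
    tss0 = np.where(strands == "+", starts, ends)
    plo, phi = cfg.n_het_sites_per_promoter
    blo, bhi = cfg.n_het_sites_per_gene_body
    n_prom = rng.integers(plo, phi + 1, size=n)
    n_body = rng.integers(blo, bhi + 1, size=n)

    site_rows = []
    for i in range(n):
        if strands[i] == "+":
            window = np.arange(tss0[i] - 1000, tss0[i])  # upstream of + gene
        else:
            window = np.arange(tss0[i] + 1, tss0[i] + 1001)  # upstream of - gene
        prom_pos = rng.choice(window, size=n_prom[i], replace=False)
        body_pos = rng.choice(np.arange(starts[i], ends[i] + 1),
                              size=n_body[i], replace=False)
        for p in sorted(prom_pos):
            site_rows.append((gene_ids[i], "promoter", int(p)))
        for p in sorted(body_pos):
            site_rows.append((gene_ids[i], "gene_body", int(p)))
    sites = pd.DataFrame(site_rows, columns=["gene_id", "site_class", "pos"])
    sites["chrom"] = "chrS"
    ref_idx = rng.integers(0, 4, size=len(sites))
    alt_shift = rng.integers(1, 4, size=len(sites))
    sites["ref"] = _BASES[ref_idx]
    sites["alt"] = _BASES[(ref_idx + alt_shift) % 4]

    n_reg = int(round(cfg.imbalance_fraction * n))
    regulated = set(rng.choice(gene_ids, size=n_reg, replace=False)) if n_reg else set()
    sites["planted"] = sites["gene_id"].isin(regulated)
    # the planted major allele: ref or alt, fixed per site (a haplotype)
    sites["major_is_ref"] = rng.random(len(sites)) < 0.5

    return {
        "genes": pd.DataFrame({
            "gene_id": gene_ids, "chrom": "chrS", "strand": strands,
            "start": starts, "end": ends, "tss0": tss0,
        }),
        "transcripts": transcripts,
        "sites": sites,
        "regulated_genes": regulated,
    }


def simulate_annotation(cfg: SimConfig) -> pd.DataFrame:
    """Transcript models on one synthetic chromosome (1-based inclusive).

    Columns: gene_id, transcript_id, chrom, strand, start, end, tss.
    At least 10% of multi-transcript configurations produce alternative TSSs
    (every extra transcript of a gene gets a distinct shifted TSS).
    """
    return _layout(cfg)["transcripts"].copy()


# ---------------------------------------------------------------------------
# allele depths
# ---------------------------------------------------------------------------

def _beta_binomial(rng: np.random.Generator, n: np.ndarray, p: np.ndarray,
                   rho: float) -> np.ndarray:
    """Draw from BetaBinomial(n, p, rho); rho = 0 reduces to Binomial."""
    p = np.clip(p, 0.0, 1.0)
    if rho == 0.0:
        return rng.binomial(n, p)
    a = p * (1.0 - rho) / rho
    b = (1.0 - p) * (1.0 - rho) / rho
    out = np.empty(len(n), dtype=np.int64)
    degen = (p <= 0.0) | (p >= 1.0)
    if degen.any():
        out[degen] = rng.binomial(n[degen], p[degen])
    ok = ~degen
    if ok.any():
        pp = rng.beta(a[ok], b[ok])
        out[ok] = rng.binomial(n[ok], pp)
    return out


def simulate_allele_depths(
    cfg: SimConfig, mode: str = "dual_genome"
) -> tuple[pd.DataFrame, GroundTruth]:
    """Per-individual, per-assay ref/alt read depths at candidate het sites.

    Depth at each individual x assay x site is Poisson(``mean_depth``); the
    reference-allele count is beta-binomial with success probability 0.5 at
    null sites and the planted major-allele frequency at regulated sites.
    Promoter sites are covered by both ChIP marks, gene-body sites by RNA.
    ``mode="naive"`` adds ``ref_bias_delta`` to the reference-allele
    probability at every site, emulating reference-mapping bias that the
    dual-genome protocol removes.
    """
    if mode not in ("dual_genome", "naive"):
        raise ValueError("mode must be 'dual_genome' or 'naive'")
    lay = _layout(cfg)
    sites = lay["sites"]
    rng = _rng(cfg, _SS_DEPTHS)

    rows = []
    for ind in range(cfg.n_individuals):
        ind_id = f"I{ind:02d}"
        het = rng.random(len(sites)) < cfg.het_rate
        sub = sites[het]
        for assay in ASSAYS:
            covered = sub[sub["site_class"] == ("gene_body" if assay == ASSAY_RNA
                                                else "promoter")]
            if covered.empty:
                continue
            depth = rng.poisson(cfg.mean_depth, size=len(covered))
            p_ref = np.where(
                covered["planted"],
                np.where(covered["major_is_ref"], cfg.imbalanced_maf,
                         1.0 - cfg.imbalanced_maf),
                0.5,
            )
            if mode == "naive":
                p_ref = np.clip(p_ref + cfg.ref_bias_delta, 0.0, 1.0)
            ref_count = _beta_binomial(rng, depth, p_ref, cfg.overdispersion_rho)
            rows.append(pd.DataFrame({
                "individual": ind_id,
                "assay": assay,
                "chrom": covered["chrom"].to_numpy(),
                "pos": covered["pos"].to_numpy(),
                "ref": covered["ref"].to_numpy(),
                "alt": covered["alt"].to_numpy(),
                "ref_count": ref_count,
                "alt_count": depth - ref_count,
            }))
    depths = pd.concat(rows, ignore_index=True)

    truth = GroundTruth()
    prom_planted = sites[(sites["site_class"] == "promoter") & sites["planted"]]
    body_planted = sites[(sites["site_class"] == "gene_body") & sites["planted"]]
    chip_sites = set(zip(prom_planted["chrom"], prom_planted["pos"].astype(int)))
    rna_sites = set(zip(body_planted["chrom"], body_planted["pos"].astype(int)))
    for assay in ASSAYS_CHIP:
        truth.true_imbalanced_sites[assay] = set(chip_sites)
    truth.true_imbalanced_sites[ASSAY_RNA] = rna_sites
    truth.true_ase_genes = set(lay["regulated_genes"])
    truth.true_rsnps = set(chip_sites)
    truth.true_rsnp_genes = {
        (c, int(p)): g
        for c, p, g in zip(prom_planted["chrom"], prom_planted["pos"],
                           prom_planted["gene_id"])
    }
    return depths, truth


# ---------------------------------------------------------------------------
# id map and catalogs
# ---------------------------------------------------------------------------

def simulate_id_map(cfg: SimConfig) -> pd.DataFrame:
    """Synthetic rs-ID lookup covering ``rs_id_coverage`` of all het sites."""
    sites = _layout(cfg)["sites"]
    rng = _rng(cfg, _SS_IDMAP)
    keep = rng.random(len(sites)) < cfg.rs_id_coverage
    mapped = sites[keep]
    rs_numbers = rng.choice(np.arange(10_000, 99_000_000), size=len(mapped),
                            replace=False)
    return pd.DataFrame({
        "chrom": mapped["chrom"].to_numpy(),
        "pos": mapped["pos"].astype(int).to_numpy(),
        "rs_id": [f"rs{n}" for n in rs_numbers],
    })


def simulate_catalogs(cfg: SimConfig, truth: GroundTruth) -> pd.DataFrame:
    """GWAS-like, eQTL-like and TF-ASB-like variant catalogs.

    Membership probability for a het site is ``catalog_base_p``, multiplied
    by ``catalog_overlap_enrichment`` (capped at 1) for true rSNP positions,
    so a downstream Fisher test recovers OR > 1.  Each catalog also carries
    background variants at random intergenic-ish positions.  GWAS trait
    labels come from a fixed trait list whose per-trait sizes straddle the
    100-variant filter; catalog entries at true rSNP sites concentrate on
    the first large trait, planting a trait-level enrichment.
    """
    lay = _layout(cfg)
    sites = lay["sites"]
    rng = _rng(cfg, _SS_CATALOG)
    chrom_end = int(lay["genes"]["end"].max() + 5000)

    trait_names = [f"trait_{i:02d}_{'big' if s >= 100 else 'small'}"
                   for i, s in enumerate(cfg.trait_sizes)]
    enriched_trait = next(n for n, s in zip(trait_names, cfg.trait_sizes) if s >= 100)

    frames = []
    for catalog, labels in (
        ("GWAS", trait_names),
        ("eQTL", ["whole_blood", "pancreas", "liver", "muscle"]),
        ("TF_ASB", ["CTCF", "YY1", "STAT1", "ANDR", "ESR1"]),
    ):
        p_member = np.where(
            [(c, int(p)) in truth.true_rsnps
             for c, p in zip(sites["chrom"], sites["pos"])],
            min(1.0, cfg.catalog_base_p * cfg.catalog_overlap_enrichment),
            cfg.catalog_base_p,
        )
        member = sites[rng.random(len(sites)) < p_member]
        if catalog == "GWAS":
            site_labels = np.where(
                [(c, int(p)) in truth.true_rsnps
                 for c, p in zip(member["chrom"], member["pos"])],
                enriched_trait,
                rng.choice(labels, size=len(member)),
            )
        else:
            site_labels = rng.choice(labels, size=len(member))
        frames.append(pd.DataFrame({
            "catalog": catalog,
            "chrom": member["chrom"].to_numpy(),
            "pos": member["pos"].astype(int).to_numpy(),
            "label": site_labels,
        }))
        # background entries fill each label up to its nominal size
        if catalog == "GWAS":
            for name, size in zip(trait_names, cfg.trait_sizes):
                n_have = int((frames[-1]["label"] == name).sum())
                n_extra = max(0, size - n_have)
                frames.append(pd.DataFrame({
                    "catalog": catalog,
                    "chrom": "chrS",
                    "pos": rng.integers(1, chrom_end, size=n_extra),
                    "label": name,
                }))
        else:
            n_extra = max(0, 4 * len(labels) * 25 - len(member))
            frames.append(pd.DataFrame({
                "catalog": catalog,
                "chrom": "chrS",
                "pos": rng.integers(1, chrom_end, size=n_extra),
                "label": rng.choice(labels, size=n_extra),
            }))
    cat = pd.concat(frames, ignore_index=True)
    cat["rs_id"] = [f"cat_{c}_{p}" for c, p in zip(cat["chrom"], cat["pos"])]
    cat["fdr"] = np.where(cat["catalog"] == "TF_ASB",
                          rng.uniform(0.0, 0.1, size=len(cat)), np.nan)
    return cat


# ---------------------------------------------------------------------------
# expression counts
# ---------------------------------------------------------------------------

def simulate_counts(
    cfg: SimConfig,
) -> tuple[pd.DataFrame, pd.Series, dict[str, float]]:
    """Negative-binomial count matrix for two conditions with planted DE.

    counts_gj ~ NB(mean = mu_g * s_j * 2^(x_j * beta_g), dispersion alpha)
    where beta_g = 0 except for ``de_fraction`` of genes (|beta| =
    ``de_log2fc``, sign random) and size factors s_j are log-uniform.
    Returns (genes x samples counts, condition labels, gene -> log2fc map).
    """
    lay = _layout(cfg)
    gene_ids = lay["genes"]["gene_id"].to_numpy()
    rng = _rng(cfg, _SS_COUNTS)
    n1, n2 = cfg.de_n_per_group
    n_samples = n1 + n2
    labels = pd.Series(
        ["control"] * n1 + ["disease"] * n2,
        index=[f"S{j:02d}" for j in range(n_samples)],
        name="condition",
    )
    x = np.array([0] * n1 + [1] * n2)

    mu = rng.lognormal(mean=np.log(200.0), sigma=1.0, size=len(gene_ids))
    n_de = int(round(cfg.de_fraction * len(gene_ids)))
    de_idx = rng.choice(len(gene_ids), size=n_de, replace=False)
    beta = np.zeros(len(gene_ids))
    beta[de_idx] = cfg.de_log2fc * rng.choice([-1.0, 1.0], size=n_de)
    s = np.exp(rng.uniform(-0.3, 0.3, size=n_samples))

    mean = mu[:, None] * s[None, :] * np.power(2.0, x[None, :] * beta[:, None])
    if cfg.nb_dispersion == 0.0:
        counts = rng.poisson(mean)
    else:
        size = 1.0 / cfg.nb_dispersion
        counts = rng.negative_binomial(size, size / (size + mean))
    counts_df = pd.DataFrame(counts, index=gene_ids, columns=labels.index)
    true_de = {gene_ids[i]: float(beta[i]) for i in de_idx}
    return counts_df, labels, true_de


# ---------------------------------------------------------------------------
# protein-interaction graph and gene sets
# ---------------------------------------------------------------------------

def simulate_ppi(cfg: SimConfig) -> tuple[pd.DataFrame, list[set[str]]]:
    """Edge list of an Erdos-Renyi background with planted near-clique modules.

    Nodes are the first ``n_graph_nodes`` gene symbols of the universe;
    the first ``n_modules * module_size`` of them form disjoint planted
    cliques.  Simple undirected graph: no self-loops, no duplicate edges.
    """
    lay = _layout(cfg)
    nodes = list(lay["genes"]["gene_id"].to_numpy()[: cfg.n_graph_nodes])
    if cfg.n_modules * cfg.module_size > len(nodes):
        raise ValueError("n_modules * module_size exceeds n_graph_nodes")
    rng = _rng(cfg, _SS_PPI)

    edges: set[tuple[str, str]] = set()
    modules: list[set[str]] = []
    for m in range(cfg.n_modules):
        members = nodes[m * cfg.module_size: (m + 1) * cfg.module_size]
        modules.append(set(members))
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                edges.add((members[i], members[j]))
    n = len(nodes)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < cfg.background_edge_p:
                edges.add((nodes[i], nodes[j]))
    edge_df = pd.DataFrame(sorted(edges), columns=["node_a", "node_b"])
    return edge_df, modules


def simulate_gene_sets(cfg: SimConfig) -> dict[str, set[str]]:
    """GMT-style gene sets over the gene universe; the first set is the first
    planted PPI module (so module ORA has a recoverable enriched term)."""
    lay = _layout(cfg)
    genes = list(lay["genes"]["gene_id"].to_numpy())
    rng = _rng(cfg, _SS_GENESETS)
    nodes = genes[: cfg.n_graph_nodes]
    sets: dict[str, set[str]] = {
        "module_pathway": set(nodes[: cfg.module_size]),
    }
    for k in range(5):
        size = int(rng.integers(10, max(11, min(40, len(genes)))))
        sets[f"random_set_{k}"] = set(rng.choice(genes, size=size, replace=False))
    return sets


# ---------------------------------------------------------------------------
# bundle and writers
# ---------------------------------------------------------------------------

def simulate_all(cfg: SimConfig, mode: str = "dual_genome") -> SimulatedStudy:
    """Generate every pipeline input plus ground truth under one seed."""
    depths, truth = simulate_allele_depths(cfg, mode=mode)
    transcripts = simulate_annotation(cfg)
    catalogs = simulate_catalogs(cfg, truth)
    counts, labels, true_de = simulate_counts(cfg)
    edges, modules = simulate_ppi(cfg)
    gene_sets = simulate_gene_sets(cfg)
    id_map = simulate_id_map(cfg)
    truth.true_de_genes = true_de
    truth.true_modules = modules
    return SimulatedStudy(
        config=cfg, depths=depths, transcripts=transcripts, catalogs=catalogs,
        counts=counts, condition_labels=labels, edges=edges,
        gene_sets=gene_sets, id_map=id_map, truth=truth,
    )


def annotation_to_bed6(transcripts: pd.DataFrame) -> pd.DataFrame:
    """BED6 export of transcript models (0-based half-open)."""
    return pd.DataFrame({
        "chrom": transcripts["chrom"],
        "start": transcripts["start"] - 1,
        "end": transcripts["end"],
        "name": transcripts["transcript_id"],
        "score": 0,
        "strand": transcripts["strand"],
    })


def write_study(study: SimulatedStudy, out_dir: str | Path) -> None:
    """Write every simulated table as flat TSV/JSON under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    study.depths.to_csv(out / "allele_depths.tsv", sep="\t", index=False)
    study.transcripts.to_csv(out / "transcripts.tsv", sep="\t", index=False)
    annotation_to_bed6(study.transcripts).to_csv(
        out / "transcripts.bed", sep="\t", index=False, header=False)
    study.catalogs.to_csv(out / "catalogs.tsv", sep="\t", index=False)
    study.counts.to_csv(out / "counts.tsv", sep="\t")
    study.condition_labels.rename_axis("sample").to_frame().to_csv(
        out / "condition_labels.tsv", sep="\t")
    study.edges.to_csv(out / "ppi_edges.tsv", sep="\t", index=False)
    study.id_map.to_csv(out / "id_map.tsv", sep="\t", index=False)
    with open(out / "gene_sets.gmt", "w") as fh:
        for name, members in study.gene_sets.items():
            fh.write("\t".join([name, "synthetic"] + sorted(members)) + "\n")
    (out / "ground_truth.json").write_text(study.truth.to_json())
    (out / "sim_config.json").write_text(json.dumps(asdict(study.config), indent=1))
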