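"""Gene-level allele-specific expression calls.

A gene with one ASE-informative SNV inherits that SNV's decision.  Genes
with several SNVs are aggregated with an MBASED-style pseudo-phasing
Monte-Carlo test: the major allele at each SNV is assigned to a nominal
haplotype and the count-weighted aggregate major-haplotype frequency is
compared with a null that re-applies the same pseudo-phasing to symmetric
binomial draws.  Re-phasing inside the null is the essential bias
correction - picking the larger count at every SNV inflates the aggregate
frequency above 0.5 even without any true imbalance.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .allelic import bh_adjust, DEFAULT_ALPHA

DEFAULT_N_SIM = 9999


def genes_from_transcripts(transcripts: pd.DataFrame) -> pd.DataFrame:
    """Collapse transcript models to one genomic span per gene."""
    g = transcripts.groupby("gene_id", as_index=False).agg(
        chrom=("chrom", "first"), start=("start", "min"), end=("end", "max"),
        strand=("strand", "first"))
    return g


def snvs_in_gene(sites: pd.DataFrame, gene_models: pd.DataFrame) -> pd.DataFrame:
    """Assign sites to genes by 1-based inclusive span overlap.

    A site inside two overlapping genes is assigned to both.  ``sites``
    needs chrom and pos columns; ``gene_models`` needs gene_id, chrom,
    start, end.  Returns gene_id plus the site columns, one row per
    (gene, site) assignment.
    """
    pieces = []
    for _, g in gene_models.iterrows():
        hit = sites[(sites["chrom"] == g["chrom"])
                    & (sites["pos"] >= g["start"]) & (sites["pos"] <= g["end"])]
        if not hit.empty:
            hit = hit.copy()
            hit.insert(0, "gene_id", g["gene_id"])
            pieces.append(hit)
    if not pieces:
        return pd.DataFrame(columns=["gene_id", *sites.columns])
    return pd.concat(pieces, ignore_index=True)


def gene_ase_single(ref_count: int, alt_count: int, p_value: float,
                    p_adj: float, significant: bool) -> dict:
    """Gene-level record for a gene carrying exactly one informative SNV."""
    total = ref_count + alt_count
    if total < 1:
        raise ValueError("SNV has zero coverage")
    return {
        "n_snvs": 1,
        "aggregate_maf": max(ref_count, alt_count) / total,
        "p_value": float(p_value),
        "p_adj": float(p_adj),
        "is_ase": bool(significant),
    }


def mbased_gene_ase(
    snv_counts: list[tuple[int, int]],
    n_sim: int = DEFAULT_N_SIM,
    seed: int = 0,
    rho: float = 0.0,
) -> tuple[float, float]:
    """Pseudo-phasing Monte-Carlo gene-level ASE test.

    T = sum_i major_i / sum_i total_i where major_i = max(ref_i, alt_i).
    The null draws k_i ~ Binomial(total_i, 0.5) (beta-binomial when
    ``rho`` > 0), re-applies max(k_i, total_i - k_i), and the p-value is
    (1 + #{T* >= T}) / (n_sim + 1).  Deterministic under a fixed seed.
    Returns (aggregate_maf, p_value).
    """
    if len(snv_counts) == 0:
        raise ValueError("empty SNV list")
    if n_sim < 999:
        warnings.warn(f"n_sim={n_sim} < 999: p-value resolution is coarse",
                      stacklevel=2)
    totals = np.array([r + a for r, a in snv_counts], dtype=np.int64)
    if np.any(totals < 1):
        raise ValueError("every SNV needs total count >= 1")
    major = np.array([max(r, a) for r, a in snv_counts], dtype=np.int64)
    obs_major = int(major.sum())
    grand = int(totals.sum())

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 7]))
    if rho > 0.0:
        a = 0.5 * (1.0 - rho) / rho
        pp = rng.beta(a, a, size=(n_sim, len(totals)))
        k = rng.binomial(totals[None, :], pp)
    else:
        k = rng.binomial(totals[None, :], 0.5, size=(n_sim, len(totals)))
    sim_major = np.maximum(k, totals[None, :] - k).sum(axis=1)
    # integer comparison: T* >= T  <=>  sum(major*) >= sum(major)
    p = (1 + int((sim_major >= obs_major).sum())) / (n_sim + 1)
    return obs_major / grand, float(p)


def call_ase_genes(
    gene_sites: pd.DataFrame,
    calls: pd.DataFrame,
    n_sim: int = DEFAULT_N_SIM,
    seed: int = 0,
    alpha: float = DEFAULT_ALPHA,
    rule: str = "mbased",
    rho: float = 0.0,
) -> pd.DataFrame:
    """Gene-level ASE table across individuals.

    ``gene_sites`` maps sites to genes (from :func:`snvs_in_gene`);
    ``calls`` is the SNP-level asymmetry table, of which only RNA (ASE
    event-class) rows are used.  Single-SNV genes inherit the SNP decision.
    Multi-SNV genes are tested with :func:`mbased_gene_ase` and BH-adjusted
    within each individual (``rule="mbased"``, default), or called when any
    SNV is significant (``rule="any_snv"``).  Genes without RNA-covered
    SNVs are absent.
    """
    if rule not in ("mbased", "any_snv"):
        raise ValueError("rule must be 'mbased' or 'any_snv'")
    rna = calls[calls["event_class"] == "ASE"]
    merged = rna.merge(gene_sites[["gene_id", "chrom", "pos"]],
                       on=["chrom", "pos"], how="inner")
    rows = []
    for (ind, gene), grp in sorted(
            merged.groupby(["individual", "gene_id"]), key=lambda kv: kv[0]):
        if len(grp) == 1:
            r = grp.iloc[0]
            rec = gene_ase_single(int(r["ref_count"]), int(r["alt_count"]),
                                  r["p_value"], r["p_adj"], r["significant"])
            rec.update(gene_id=gene, individual=ind, multi=False)
        else:
            counts = list(zip(grp["ref_count"].astype(int),
                              grp["alt_count"].astype(int)))
            gene_seed = int(np.random.SeedSequence(
                [int(seed), len(rows), 11]).generate_state(1)[0] % (2**31))
            maf, p = mbased_gene_ase(counts, n_sim=n_sim, seed=gene_seed, rho=rho)
            rec = {
                "gene_id": gene, "individual": ind, "n_snvs": len(grp),
                "aggregate_maf": maf, "p_value": p, "p_adj": np.nan,
                "is_ase": bool(grp["significant"].any()), "multi": True,
            }
        rows.append(rec)
    if not rows:
        return pd.DataFrame(columns=["gene_id", "individual", "n_snvs",
                                     "aggregate_maf", "p_value", "p_adj",
                                     "is_ase"])
    table = pd.DataFrame(rows)
    if rule == "mbased":
        multi = table["multi"]
        for ind in table.loc[multi, "individual"].unique():
            fam = multi & (table["individual"] == ind)
            adj = bh_adjust(table.loc[fam, "p_value"].to_numpy())
            table.loc[fam, "p_adj"] = adj
            table.loc[fam, "is_ase"] = adj < alpha
    cols = ["gene_id", "individual", "n_snvs", "aggregate_maf", "p_value",
            "p_adj", "is_ase"]
    return (table[cols].sort_values(["individual", "gene_id"])
                 .reset_index(drop=True))
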