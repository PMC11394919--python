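"""Promoter construction and rSNP panel assembly.

Promoters are the +/-1000 bp windows around every distinct transcription
start site (strand-aware, 1-based inclusive, clipped at position 1).
Significant ASB SNPs falling inside a promoter whose gene shows
allele-specific expression in the same individual are regulatory SNPs
(rSNPs); evidence is merged across individuals by position with a
union rule (supported in >= ``min_individuals``, default 1).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

PROMOTER_FLANK = 1000


def promoters(transcripts: pd.DataFrame) -> pd.DataFrame:
    """One promoter interval per distinct (gene, TSS).

    TSS = start on the + strand, end on the - strand; the interval is
    [max(1, tss - 1000), tss + 1000], identical TSSs deduplicated.
    """
    t = transcripts.copy()
    if "tss" not in t.columns:
        t["tss"] = np.where(t["strand"] == "+", t["start"], t["end"])
    uniq = t.drop_duplicates(["gene_id", "chrom", "tss"])
    out = pd.DataFrame({
        "gene_id": uniq["gene_id"].to_numpy(),
        "chrom": uniq["chrom"].to_numpy(),
        "start": np.maximum(1, uniq["tss"].to_numpy() - PROMOTER_FLANK),
        "end": uniq["tss"].to_numpy() + PROMOTER_FLANK,
        "source_tss": uniq["tss"].to_numpy(),
    })
    return out.sort_values(["chrom", "start", "gene_id"]).reset_index(drop=True)


def promoters_to_bed(prom: pd.DataFrame) -> pd.DataFrame:
    """BED export (0-based half-open) of promoter intervals."""
    return pd.DataFrame({
        "chrom": prom["chrom"], "start": prom["start"] - 1, "end": prom["end"],
        "name": prom["gene_id"],
    })


def promoter_asb(calls: pd.DataFrame, prom: pd.DataFrame) -> pd.DataFrame:
    """Significant ASB sites inside promoters (inclusive both ends).

    One row per (site, gene) hit; a SNP in the promoters of two genes
    yields two rows.  Duplicate promoters of one gene (alternative TSSs
    covering the same SNP) collapse to one hit row per gene.
    """
    asb = calls[(calls["event_class"] == "ASB") & calls["significant"]]
    pieces = []
    for _, p in prom.iterrows():
        hit = asb[(asb["chrom"] == p["chrom"])
                  & (asb["pos"] >= p["start"]) & (asb["pos"] <= p["end"])]
        if not hit.empty:
            hit = hit.copy()
            hit["gene_id"] = p["gene_id"]
            pieces.append(hit)
    if not pieces:
        return pd.DataFrame(columns=list(calls.columns) + ["gene_id"])
    out = pd.concat(pieces, ignore_index=True)
    return (out.drop_duplicates(["individual", "assay", "chrom", "pos", "gene_id"])
               .sort_values(["chrom", "pos", "gene_id"]).reset_index(drop=True))


def assemble_panel(
    hits: pd.DataFrame,
    gene_ase_table: pd.DataFrame,
    min_individuals: int = 1,
    same_individual: bool = True,
) -> pd.DataFrame:
    """Intersect promoter ASB hits with ASE genes to form the rSNP panel.

    By default a hit counts only when its target gene is ASE in the same
    individual (``same_individual=False`` accepts ASE evidence from any
    individual).  Hits are merged by (chrom, pos); a position enters the
    panel when supported in >= ``min_individuals``.  Output columns:
    rs_id (if present on hits), chrom, pos, ref, alt, target_genes
    (sorted ;-joined), individuals, assays, n_individuals.
    """
    ase = gene_ase_table[gene_ase_table["is_ase"]]
    if same_individual:
        keep = hits.merge(ase[["gene_id", "individual"]].drop_duplicates(),
                          on=["gene_id", "individual"], how="inner")
    else:
        keep = hits[hits["gene_id"].isin(set(ase["gene_id"]))]
    if keep.empty:
        return pd.DataFrame(columns=["rs_id", "chrom", "pos", "ref", "alt",
                                     "target_genes", "individuals", "assays",
                                     "n_individuals"])
    agg = {
        "ref": ("ref", "first"),
        "alt": ("alt", "first"),
        "target_genes": ("gene_id", lambda s: ";".join(sorted(set(s)))),
        "individuals": ("individual", lambda s: ";".join(sorted(set(s)))),
        "assays": ("assay", lambda s: ";".join(sorted(set(s)))),
        "n_individuals": ("individual", "nunique"),
    }
    if "rs_id" in keep.columns:
        agg["rs_id"] = ("rs_id", "first")
    panel = keep.groupby(["chrom", "pos"], as_index=False).agg(**agg)
    panel = panel[panel["n_individuals"] >= min_individuals]
    cols = (["rs_id"] if "rs_id" in panel.columns else []) + \
        ["chrom", "pos", "ref", "alt", "target_genes", "individuals",
         "assays", "n_individuals"]
    return panel[cols].sort_values(["chrom", "pos"]).reset_index(drop=True)


def panel_to_bed(panel: pd.DataFrame) -> pd.DataFrame:
    """BED export (0-based half-open) of panel positions."""
    name = panel["rs_id"] if "rs_id" in panel.columns else (
        panel["chrom"].astype(str) + ":" + panel["pos"].astype(str))
    return pd.DataFrame({
        "chrom": panel["chrom"], "start": panel["pos"] - 1, "end": panel["pos"],
        "name": name,
    })
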