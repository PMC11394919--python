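"""Negative-binomial Wald differential expression and rSNP intersection.

A deliberately compact NB-Wald core in the style of count-based RNA-seq
engines: median-of-ratios size factors, per-gene method-of-moments
dispersion on normalised counts (floored at 1e-8), a Wald test on the
log group-mean ratio with delta-method standard errors, BH adjustment
across genes, and the differential-expression gate |log2FC| > 0.2 and
adjusted p < 0.05.  Dispersion shrinkage, outlier filtering and LFC
shrinkage are intentionally absent; the downstream contribution is the
thresholds and the promoter-rSNP intersection, not the DE engine.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .allelic import bh_adjust

DEG_MIN_ABS_LOG2FC = 0.2
DEG_ALPHA = 0.05
MIN_DISPERSION = 1e-8


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    factor_j = median over genes with positive geometric mean of
    count_gj / geometric_mean_g.  Columns are samples.
    """
    mat = counts.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        log_geo = np.log(mat).mean(axis=1)
    ok = np.isfinite(log_geo)
    if not ok.any():
        raise ValueError("no gene has all-positive counts")
    ratios = mat[ok] / np.exp(log_geo[ok])[:, None]
    return pd.Series(np.median(ratios, axis=0), index=counts.columns,
                     name="size_factor")


def _group_masks(labels: pd.Series, reference: str | None) -> tuple[np.ndarray, np.ndarray, str, str]:
    groups = sorted(labels.unique())
    if len(groups) != 2:
        raise ValueError("exactly two condition labels required")
    ref = reference if reference is not None else groups[0]
    if ref not in groups:
        raise ValueError(f"reference {ref!r} not among labels {groups}")
    other = groups[1] if ref == groups[0] else groups[0]
    return (labels == ref).to_numpy(), (labels == other).to_numpy(), ref, other


def nb_wald_test(
    counts: pd.DataFrame,
    labels: pd.Series,
    factors: pd.Series | None = None,
    reference: str | None = None,
    lfc_threshold: float = DEG_MIN_ABS_LOG2FC,
    alpha: float = DEG_ALPHA,
) -> pd.DataFrame:
    """Per-gene NB Wald test of the second group against the reference.

    log2fc is the base-2 log ratio of normalised group means (second group
    over reference; reference defaults to the alphabetically first label).
    Dispersion alpha_g is method-of-moments on normalised counts, pooled
    within groups and floored at 1e-8.  z = ln-ratio / se with
    se^2 = sum_groups Var(mean_g)/mean_g^2 under NB variance
    mu/s_j + alpha mu^2.  Genes with all-zero counts are excluded.
    Returns gene_id, base_mean, log2fc, se, z, p_value, p_adj, is_deg,
    direction, n_excluded recorded in ``attrs``.
    """
    labels = labels.loc[counts.columns]
    if factors is None:
        factors = size_factors(counts)
    m_ref, m_alt, ref, other = _group_masks(labels, reference)
    if m_ref.sum() < 2 or m_alt.sum() < 2:
        raise ValueError("each group needs >= 2 samples")

    mat = counts.to_numpy(dtype=float)
    nonzero = mat.sum(axis=1) > 0
    n_excluded = int((~nonzero).sum())
    mat = mat[nonzero]
    genes = counts.index.to_numpy()[nonzero]
    s = factors.to_numpy(dtype=float)
    norm = mat / s[None, :]

    pseudo = 0.5  # guards the log for a group with an all-zero mean
    mu1 = norm[:, m_ref].mean(axis=1)
    mu2 = norm[:, m_alt].mean(axis=1)
    log2fc = np.log2(np.maximum(mu2, pseudo) / np.maximum(mu1, pseudo))

    # method-of-moments dispersion pooled within groups:
    # Var(K/s) = mu/s + alpha mu^2  =>  alpha = (Var - mu mean(1/s)) / mu^2
    resid_var = np.zeros(len(mat))
    mean_inv_s = np.zeros(len(mat))
    dof = 0
    for mask, mu in ((m_ref, mu1), (m_alt, mu2)):
        dev = norm[:, mask] - mu[:, None]
        resid_var += dev.var(axis=1, ddof=1) * (mask.sum() - 1)
        mean_inv_s += mu * (1.0 / s[mask]).mean() * (mask.sum() - 1)
        dof += mask.sum() - 1
    resid_var /= dof
    mean_inv_s /= dof
    grand = (mu1 + mu2) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = (resid_var - mean_inv_s) / np.maximum(grand, pseudo) ** 2
    disp = np.maximum(disp, MIN_DISPERSION)

    def mean_var(mask: np.ndarray, mu: np.ndarray) -> np.ndarray:
        nj = mask.sum()
        per_sample = mu[:, None] / s[None, mask] + disp[:, None] * mu[:, None] ** 2
        return per_sample.sum(axis=1) / nj**2

    v1 = mean_var(m_ref, np.maximum(mu1, pseudo))
    v2 = mean_var(m_alt, np.maximum(mu2, pseudo))
    se = np.sqrt(v1 / np.maximum(mu1, pseudo) ** 2
                 + v2 / np.maximum(mu2, pseudo) ** 2)
    z = log2fc * np.log(2.0) / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    p_adj = bh_adjust(p)

    out = pd.DataFrame({
        "gene_id": genes,
        "base_mean": norm.mean(axis=1),
        "log2fc": log2fc,
        "se": se,
        "z": z,
        "p_value": p,
        "p_adj": p_adj,
    })
    out["is_deg"] = (np.abs(out["log2fc"]) > lfc_threshold) & (out["p_adj"] < alpha)
    out["direction"] = np.where(out["log2fc"] > 0, "up", "down")
    out = out.sort_values("gene_id").reset_index(drop=True)
    out.attrs["n_excluded_all_zero"] = n_excluded
    out.attrs["reference"] = ref
    out.attrs["contrast"] = f"{other}_vs_{ref}"
    return out


def deg_rsnp_intersection(
    de_results: pd.DataFrame,
    panel: pd.DataFrame,
    prom: pd.DataFrame,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """rSNPs of the panel lying in promoters of differentially expressed genes.

    Returns (table, totals): the table has one row per (DEG, rSNP in one of
    its promoter intervals) with the gene's direction; the totals dict
    gives per-direction and grand counts of genes and rSNPs.  DEGs with no
    promoter rSNP are absent from the table.
    """
    degs = de_results[de_results["is_deg"]][["gene_id", "direction"]]
    deg_prom = prom.merge(degs, on="gene_id", how="inner")
    rows = []
    for _, p in deg_prom.iterrows():
        hit = panel[(panel["chrom"] == p["chrom"])
                    & (panel["pos"] >= p["start"]) & (panel["pos"] <= p["end"])]
        for _, r in hit.iterrows():
            rows.append({
                "gene_id": p["gene_id"], "direction": p["direction"],
                "chrom": r["chrom"], "pos": int(r["pos"]),
                "rs_id": r.get("rs_id", f"{r['chrom']}:{r['pos']}"),
            })
    table = (pd.DataFrame(rows, columns=["gene_id", "direction", "chrom",
                                         "pos", "rs_id"])
               .drop_duplicates(["gene_id", "chrom", "pos"])
               .sort_values(["gene_id", "chrom", "pos"]).reset_index(drop=True))
    # totals are additive over direction: an rSNP is counted once per
    # direction it appears in, so up + down always equals the grand total
    totals = {}
    for direction in ("up", "down"):
        sub = table[table["direction"] == direction]
        totals[f"n_genes_{direction}"] = int(sub["gene_id"].nunique())
        totals[f"n_rsnps_{direction}"] = int(
            sub.drop_duplicates(["chrom", "pos"]).shape[0])
    totals["n_genes_total"] = totals["n_genes_up"] + totals["n_genes_down"]
    totals["n_rsnps_total"] = totals["n_rsnps_up"] + totals["n_rsnps_down"]
    return table, totals
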