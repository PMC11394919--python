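"""Heterozygote calling and SNP-level allelic-asymmetry tests.

Per individual, read depths from every assay are pooled to call heterozygous
sites (total depth > 20 and minor-allele fraction >= 0.2), then each het
site is tested per assay with an exact two-sided binomial test against an
equal-coverage null, with Benjamini-Hochberg control within each
(individual, assay) family.  Significant ChIP-mark sites are allele-specific
binding (ASB) events; significant RNA sites are allele-specific expression
(ASE) events.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

HET_MIN_DEPTH = 20       # pooled depth must be strictly greater
HET_MIN_MINOR_FRAC = 0.2  # pooled minor-allele fraction, inclusive
DEFAULT_ALPHA = 0.1       # BH threshold for ASB/ASE significance

CHIP_ASSAYS = frozenset({"H3K4me3", "H3K27ac"})


def pool_and_call_het(depths: pd.DataFrame, individual: str) -> pd.DataFrame:
    """Pool ref/alt counts across assays for one individual and call het sites.

    Keeps sites with pooled depth > 20 and pooled minor-allele fraction
    >= 0.2.  Raises if one position carries conflicting ref/alt annotations.
    Returns columns: individual, chrom, pos, ref, alt, pooled_depth,
    pooled_minor_fraction.
    """
    sub = depths[depths["individual"] == individual]
    if sub.empty:
        return pd.DataFrame(columns=["individual", "chrom", "pos", "ref", "alt",
                                     "pooled_depth", "pooled_minor_fraction"])
    alleles = sub.groupby(["chrom", "pos"])[["ref", "alt"]].nunique()
    bad = alleles[(alleles["ref"] > 1) | (alleles["alt"] > 1)]
    if not bad.empty:
        c, p = bad.index[0]
        raise ValueError(
            f"conflicting ref/alt annotations at {c}:{p} for {individual}")
    pooled = (sub.groupby(["chrom", "pos", "ref", "alt"], as_index=False)
                 [["ref_count", "alt_count"]].sum())
    total = pooled["ref_count"] + pooled["alt_count"]
    minor = np.minimum(pooled["ref_count"], pooled["alt_count"])
    with np.errstate(invalid="ignore"):
        minor_frac = np.where(total > 0, minor / total, 0.0)
    keep = (total > HET_MIN_DEPTH) & (minor_frac >= HET_MIN_MINOR_FRAC)
    out = pooled[keep].copy()
    out.insert(0, "individual", individual)
    out["pooled_depth"] = total[keep].astype(int)
    out["pooled_minor_fraction"] = minor_frac[keep]
    return (out.drop(columns=["ref_count", "alt_count"])
               .sort_values(["chrom", "pos"]).reset_index(drop=True))


def binomial_asymmetry_p(ref_count, alt_count):
    """Exact two-sided binomial p-value under a symmetric (p = 0.5) null.

    Uses the "minlike" two-sided definition: the sum of P(X = k) over all k
    whose point probability does not exceed that of the observation.  For a
    symmetric null this is min(1, 2 * P(X <= min(ref, alt))).  Accepts
    scalars or arrays; symmetric in (ref, alt).
    """
    ref = np.asarray(ref_count)
    alt = np.asarray(alt_count)
    total = ref + alt
    if np.any(total < 1):
        raise ValueError("ref_count + alt_count must be >= 1")
    m = np.minimum(ref, alt)
    p = np.minimum(1.0, 2.0 * stats.binom.cdf(m, total, 0.5))
    # the exactly balanced observation is the mode: p = 1
    p = np.where(ref == alt, 1.0, p)
    if np.ndim(ref_count) == 0 and np.ndim(alt_count) == 0:
        return float(p)
    return p


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    q_(i) = p_(i) * n / i on the ascending sort, made monotone from the
    largest rank down and capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_events(
    het_sites: pd.DataFrame,
    depths: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    bh_family: str = "per_individual_assay",
) -> pd.DataFrame:
    """Test each het site for allelic asymmetry in every assay covering it.

    A site enters an assay's test family when that assay has depth >= 1
    there.  BH adjustment is applied within each (individual, assay) family
    by default, or globally with ``bh_family="global"``.  ChIP-mark events
    are classed ASB, RNA events ASE; ``significant`` means p_adj < alpha.
    Ties in allele counts record preferred_allele="ref" with a tie flag.
    """
    if bh_family not in ("per_individual_assay", "global"):
        raise ValueError("bh_family must be 'per_individual_assay' or 'global'")
    key = ["individual", "chrom", "pos"]
    merged = depths.merge(het_sites[key], on=key, how="inner")
    merged = merged[(merged["ref_count"] + merged["alt_count"]) >= 1].copy()
    if merged.empty:
        return pd.DataFrame(columns=key + ["assay", "ref", "alt", "ref_count",
                                           "alt_count", "event_class", "p_value",
                                           "p_adj", "preferred_allele", "tie",
                                           "significant"])
    merged["event_class"] = np.where(merged["assay"].isin(CHIP_ASSAYS),
                                     "ASB", "ASE")
    merged["p_value"] = binomial_asymmetry_p(
        merged["ref_count"].to_numpy(), merged["alt_count"].to_numpy())
    merged["tie"] = merged["ref_count"] == merged["alt_count"]
    merged["preferred_allele"] = np.where(
        merged["alt_count"] > merged["ref_count"], "alt", "ref")
    if bh_family == "global":
        merged["p_adj"] = bh_adjust(merged["p_value"].to_numpy())
    else:
        merged["p_adj"] = (merged.groupby(["individual", "assay"])["p_value"]
                                 .transform(lambda s: bh_adjust(s.to_numpy())))
    merged["significant"] = merged["p_adj"] < alpha
    cols = key + ["assay", "ref", "alt", "ref_count", "alt_count", "event_class",
                  "p_value", "p_adj", "preferred_allele", "tie", "significant"]
    return (merged[cols].sort_values(key + ["assay"]).reset_index(drop=True))


def assign_rs_ids(calls: pd.DataFrame, id_map: pd.DataFrame) -> pd.DataFrame:
    """Left-join rs IDs on (chrom, pos); unmapped sites get ``novel_<chrom>_<pos>``.

    The join is total: every input row is returned exactly once.
    """
    out = calls.merge(id_map[["chrom", "pos", "rs_id"]], on=["chrom", "pos"],
                      how="left")
    novel = "novel_" + out["chrom"].astype(str) + "_" + out["pos"].astype(str)
    out["rs_id"] = out["rs_id"].fillna(pd.Series(novel, index=out.index))
    return out
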