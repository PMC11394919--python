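"""Catalog characterisation of the rSNP panel.

Window matching against GWAS-like, eQTL-like and TF-ASB-like variant
catalogs (direct identity or +/-1000 bp proximity), 2x2 enrichment with
odds ratio, Woolf 95% CI, Pearson chi-square and Fisher exact p-values,
per-trait ranking with a >= 100-variant catalog-size filter, percentage
reporting, and three-way overlap (Venn) counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
from scipy import stats

from .allelic import bh_adjust

DEFAULT_WINDOW = 1000
TF_ASB_FDR_MAX = 0.05
TRAIT_MIN_CATALOG = 100


def _prepare_catalog(catalog: pd.DataFrame) -> pd.DataFrame:
    """Apply the FDR < 0.05 gate to TF-ASB entries when an fdr column exists."""
    if "fdr" in catalog.columns and "catalog" in catalog.columns:
        drop = (catalog["catalog"] == "TF_ASB") & catalog["fdr"].notna() \
            & (catalog["fdr"] >= TF_ASB_FDR_MAX)
        return catalog[~drop]
    return catalog


def window_match(
    panel: pd.DataFrame, catalog: pd.DataFrame, window: int = DEFAULT_WINDOW
) -> pd.Series:
    """Match status per panel row against one catalog: direct, proximal, none.

    Direct: identical (chrom, pos), or identical rs_id when both tables
    carry one.  Proximal: some catalog variant within ``window`` bp on the
    same chromosome.  Direct takes precedence; window 0 reduces to direct
    matching only.
    """
    catalog = _prepare_catalog(catalog)
    cat_pos: dict[str, np.ndarray] = {
        c: np.sort(g["pos"].to_numpy())
        for c, g in catalog.groupby("chrom")
    }
    cat_keys = set(zip(catalog["chrom"], catalog["pos"].astype(int)))
    cat_ids = set(catalog["rs_id"]) if "rs_id" in catalog.columns else set()

    status = []
    has_id = "rs_id" in panel.columns
    for _, r in panel.iterrows():
        key = (r["chrom"], int(r["pos"]))
        if key in cat_keys or (has_id and r["rs_id"] in cat_ids):
            status.append("direct")
            continue
        pos_arr = cat_pos.get(r["chrom"])
        if pos_arr is not None and len(pos_arr):
            i = np.searchsorted(pos_arr, r["pos"])
            near = min(
                abs(int(pos_arr[j]) - int(r["pos"]))
                for j in (i - 1, i) if 0 <= j < len(pos_arr)
            )
            if near <= window:
                status.append("proximal")
                continue
        status.append("none")
    return pd.Series(status, index=panel.index, name="match")


@dataclass(frozen=True)
class EnrichmentResult:
    """2x2 contingency summary: a=panel&catalog, b=panel-only,
    c=background&catalog, d=background-only."""

    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_chi2: float
    p_fisher: float


def enrichment_2x2(a: int, b: int, c: int, d: int) -> EnrichmentResult:
    """Odds ratio with Haldane correction, Woolf CI, chi-square and Fisher p.

    OR = (a d)/(b c); when any cell is zero, 0.5 is added to every cell for
    the OR and its CI.  CI = exp(ln OR +/- 1.96 sqrt(1/a+1/b+1/c+1/d)) on
    the (possibly corrected) cells.  Fisher is exact two-sided (minlike);
    chi-square is Pearson with 1 df, no continuity correction.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("cell counts must be non-negative")
    cells = np.array([a, b, c, d], dtype=float)
    if np.any(cells == 0):
        cells = cells + 0.5
    aa, bb, cc, dd = cells
    oratio = (aa * dd) / (bb * cc)
    se = np.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    ci_low = float(np.exp(np.log(oratio) - 1.96 * se))
    ci_high = float(np.exp(np.log(oratio) + 1.96 * se))
    table = [[a, b], [c, d]]
    _, p_fisher = stats.fisher_exact(table, alternative="two-sided")
    try:
        p_chi2 = float(stats.chi2_contingency(table, correction=False)[1])
    except ValueError:  # a zero margin: no association testable
        p_chi2 = 1.0
    return EnrichmentResult(int(a), int(b), int(c), int(d), float(oratio),
                            ci_low, ci_high, p_chi2, float(p_fisher))


def trait_enrichment(
    panel: pd.DataFrame,
    gwas_catalog: pd.DataFrame,
    background_sites: pd.DataFrame,
    min_catalog: int = TRAIT_MIN_CATALOG,
    alpha: float = 0.1,
) -> pd.DataFrame:
    """Per-trait Fisher enrichment of the panel against background het sites.

    Traits with fewer than ``min_catalog`` catalog variants are excluded.
    Membership is direct (chrom, pos) identity with the trait's variants.
    Rows are ranked by the number of directly-matching rSNPs; BH adjustment
    is applied across tested traits.
    """
    panel_keys = set(zip(panel["chrom"], panel["pos"].astype(int)))
    bg_keys = set(zip(background_sites["chrom"],
                      background_sites["pos"].astype(int))) - panel_keys
    rows = []
    for trait, grp in gwas_catalog.groupby("label"):
        n_total = len(grp)
        if n_total < min_catalog:
            continue
        trait_keys = set(zip(grp["chrom"], grp["pos"].astype(int)))
        a = len(panel_keys & trait_keys)
        b = len(panel_keys) - a
        c = len(bg_keys & trait_keys)
        d = len(bg_keys) - c
        res = enrichment_2x2(a, b, c, d)
        rows.append({
            "trait": trait, "n_catalog_total": n_total, "n_rsnp_direct": a,
            "odds_ratio": res.odds_ratio, "ci_low": res.ci_low,
            "ci_high": res.ci_high, "p_fisher": res.p_fisher,
        })
    if not rows:
        return pd.DataFrame(columns=["trait", "n_catalog_total", "n_rsnp_direct",
                                     "odds_ratio", "ci_low", "ci_high",
                                     "p_fisher", "p_adj", "significant"])
    out = pd.DataFrame(rows)
    out["p_adj"] = bh_adjust(out["p_fisher"].to_numpy())
    out["significant"] = out["p_adj"] < alpha
    return (out.sort_values(["n_rsnp_direct", "trait"],
                            ascending=[False, True])
               .reset_index(drop=True))


def report_fractions(numerator: int, denominator: int) -> tuple[float, str]:
    """Percentage 100*num/den rounded half-up to one decimal, plus a string."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    pct = Decimal(100 * numerator) / Decimal(denominator)
    rounded = float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
    return rounded, f"{rounded:.1f}%"


def three_way_overlap(flags: pd.DataFrame) -> dict[str, int]:
    """Venn counts over three boolean membership columns.

    ``flags`` must have boolean columns GWAS, eQTL and TF_ASB, one row per
    panel rSNP.  The eight returned regions partition the panel.
    """
    g = flags["GWAS"].astype(bool)
    e = flags["eQTL"].astype(bool)
    t = flags["TF_ASB"].astype(bool)
    return {
        "GWAS_only": int((g & ~e & ~t).sum()),
        "eQTL_only": int((~g & e & ~t).sum()),
        "TF_ASB_only": int((~g & ~e & t).sum()),
        "GWAS_eQTL": int((g & e & ~t).sum()),
        "GWAS_TF_ASB": int((g & ~e & t).sum()),
        "eQTL_TF_ASB": int((~g & e & t).sum()),
        "all_three": int((g & e & t).sum()),
        "none": int((~g & ~e & ~t).sum()),
    }
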