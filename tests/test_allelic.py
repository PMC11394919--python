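"""Het calling, exact binomial asymmetry, BH adjustment, event calling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from rsnp_scan import (
    SimConfig,
    assign_rs_ids,
    bh_adjust,
    binomial_asymmetry_p,
    call_events,
    pool_and_call_het,
)
from rsnp_scan.simulate import simulate_allele_depths

from conftest import depths_frame


# --- independent oracles ---------------------------------------------------

def minlike_binom_p(k: int, n: int) -> float:
    """Brute-force minlike two-sided binomial p at p0 = 0.5."""
    pmf = stats.binom.pmf(np.arange(n + 1), n, 0.5)
    return float(pmf[pmf <= pmf[k] * (1 + 1e-9)].sum())


def bh_stepup(p):
    """Hand step-up: q_(i) = p_(i) n/i, monotone from the top, capped at 1."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    q = p[order] * n / np.arange(1, n + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(q, 1.0)
    return out


# --- heterozygote calling --------------------------------------------------

def test_het_call_pools_assays_and_applies_thresholds():
    depths = depths_frame([
        # pooled (15, 10): depth 25 > 20, minor 0.4 -> kept
        ("I0", "H3K4me3", "c1", 100, "A", "G", 10, 5),
        ("I0", "RNA", "c1", 100, "A", "G", 5, 5),
        # pooled (17, 4): depth 21 > 20 but minor 4/21 < 0.2 -> dropped
        ("I0", "H3K4me3", "c1", 200, "C", "T", 17, 4),
        # pooled (10, 10): depth 20 not > 20 -> dropped (strict inequality)
        ("I0", "H3K27ac", "c1", 300, "G", "T", 10, 10),
    ])
    het = pool_and_call_het(depths, "I0")
    assert list(het["pos"]) == [100]
    assert het.loc[0, "pooled_depth"] == 25
    assert het.loc[0, "pooled_minor_fraction"] == pytest.approx(0.4)


def test_het_call_rejects_conflicting_allele_annotations():
    depths = depths_frame([
        ("I0", "H3K4me3", "c1", 100, "A", "G", 30, 20),
        ("I0", "RNA", "c1", 100, "A", "T", 30, 20),
    ])
    with pytest.raises(ValueError, match="c1:100"):
        pool_and_call_het(depths, "I0")


# --- exact binomial test ---------------------------------------------------

@pytest.mark.parametrize("ref,alt,expected", [
    (5, 5, 1.0),
    (10, 0, 2 * 0.5**10),
    (15, 5, 0.04138946533203125),  # enumeration of Binomial(20, 1/2)
])
def test_binomial_p_known_values(ref, alt, expected):
    assert binomial_asymmetry_p(ref, alt) == pytest.approx(expected, rel=1e-12)


def test_binomial_p_matches_enumeration_exhaustively():
    """Equality with the pmf-enumeration oracle for all totals 1..60."""
    for n in range(1, 61):
        ks = np.arange(n + 1)
        ours = binomial_asymmetry_p(ks, n - ks)
        oracle = np.array([minlike_binom_p(k, n) for k in ks])
        np.testing.assert_allclose(ours, oracle, rtol=1e-10)


def test_binomial_p_matches_scipy_binomtest():
    for n, k in [(7, 2), (40, 13), (61, 61), (100, 50)]:
        assert binomial_asymmetry_p(k, n - k) == pytest.approx(
            stats.binomtest(k, n, 0.5).pvalue, rel=1e-9)


@given(st.integers(0, 120), st.integers(0, 120))
@settings(max_examples=200, deadline=None)
def test_binomial_p_symmetry_and_range(ref, alt):
    if ref + alt == 0:
        with pytest.raises(ValueError):
            binomial_asymmetry_p(ref, alt)
        return
    p = binomial_asymmetry_p(ref, alt)
    assert 0.0 < p <= 1.0
    assert p == binomial_asymmetry_p(alt, ref)


def test_binomial_p_decreases_with_imbalance():
    n = 50
    ps = [binomial_asymmetry_p(k, n - k) for k in range(n // 2, n + 1)]
    assert all(a >= b for a, b in zip(ps, ps[1:]))


def test_binomial_p_zero_total_errors():
    with pytest.raises(ValueError):
        binomial_asymmetry_p(0, 0)


# --- Benjamini-Hochberg ----------------------------------------------------

@pytest.mark.parametrize("p,expected", [
    ([0.5], [0.5]),
    ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
    ([1.0, 1.0], [1.0, 1.0]),
])
def test_bh_known_vectors(p, expected):
    np.testing.assert_allclose(bh_adjust(p), expected, rtol=1e-12)


@given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
@settings(max_examples=200, deadline=None)
def test_bh_matches_stepup_oracle_and_invariants(p):
    adj = bh_adjust(p)
    np.testing.assert_allclose(adj, bh_stepup(p), rtol=1e-10, atol=1e-12)
    assert np.all(adj >= np.asarray(p) - 1e-12)
    assert np.all(adj <= 1.0)
    # adjusted order respects raw order
    order = np.argsort(p, kind="stable")
    assert np.all(np.diff(adj[order]) >= -1e-12)


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.5])


# --- event calling ---------------------------------------------------------

def _planted_panel(rng, n_null=500, n_planted=50, depth=60, maf=0.9):
    """Het sites with known truth for one individual, one ChIP assay."""
    rows = []
    for i in range(n_null + n_planted):
        p = maf if i < n_planted else 0.5
        d = rng.poisson(depth)
        while d == 0:
            d = rng.poisson(depth)
        ref = rng.binomial(d, p)
        rows.append(("I0", "H3K4me3", "c1", 1000 + i, "A", "G", ref, d - ref))
    depths = depths_frame(rows)
    het = depths.rename(columns={})[["individual", "chrom", "pos", "ref", "alt"]]
    truth = set(range(1000, 1000 + n_planted))
    return depths, het, truth


def test_event_calling_recovers_planted_imbalance():
    """maf 0.9 at depth 60: sensitivity > 0.8, realized FDP near/below 0.1,
    averaged over 20 seeds."""
    sens, fdp = [], []
    for seed in range(20):
        rng = np.random.default_rng(seed)
        depths, het, truth = _planted_panel(rng)
        calls = call_events(het, depths)
        sig = set(calls.loc[calls["significant"], "pos"])
        tp = len(sig & truth)
        sens.append(tp / len(truth))
        fdp.append((len(sig) - tp) / max(1, len(sig)))
    assert np.mean(sens) > 0.8
    assert np.mean(fdp) <= 0.1 + 0.05


def test_pure_null_rejection_fraction_controlled():
    """With no planted imbalance the significant fraction stays below the
    BH level plus Monte-Carlo slack (20 seeds)."""
    fracs = []
    for seed in range(20):
        cfg = SimConfig(seed=100 + seed, n_genes=60, imbalance_fraction=0.0,
                        overdispersion_rho=0.0, n_individuals=2)
        depths, _ = simulate_allele_depths(cfg)
        het = pd.concat([pool_and_call_het(depths, i)
                         for i in sorted(depths["individual"].unique())],
                        ignore_index=True)
        calls = call_events(het, depths)
        fracs.append(calls["significant"].mean())
    assert np.mean(fracs) <= 0.1 + 0.03


def test_event_classes_and_family_structure():
    depths = depths_frame([
        ("I0", "H3K4me3", "c1", 100, "A", "G", 40, 8),
        ("I0", "RNA", "c1", 100, "A", "G", 0, 0),     # no RNA coverage
        ("I0", "RNA", "c1", 200, "C", "T", 25, 25),   # balanced RNA
        ("I1", "H3K27ac", "c1", 100, "A", "G", 30, 22),
    ])
    het = pd.DataFrame({
        "individual": ["I0", "I0", "I1"],
        "chrom": ["c1", "c1", "c1"],
        "pos": [100, 200, 100],
        "ref": ["A", "C", "A"], "alt": ["G", "T", "G"],
    })
    calls = call_events(het, depths)
    # zero-coverage assay rows produce no test
    assert len(calls) == 3
    by = calls.set_index(["individual", "pos", "assay"])
    assert by.loc[("I0", 100, "H3K4me3"), "event_class"] == "ASB"
    assert by.loc[("I0", 200, "RNA"), "event_class"] == "ASE"
    assert not by.loc[("I0", 200, "RNA"), "significant"]
    assert bool(by.loc[("I0", 200, "RNA"), "tie"])
    assert by.loc[("I0", 200, "RNA"), "preferred_allele"] == "ref"
    # site significant in a ChIP mark but absent from RNA -> no ASE record
    assert ("I0", 100, "RNA") not in by.index
    # preferred allele is the larger count
    assert by.loc[("I0", 100, "H3K4me3"), "preferred_allele"] == "ref"


def test_rs_id_assignment_total_join():
    calls = pd.DataFrame({"chrom": ["c1", "c1", "c2"], "pos": [5, 9, 5],
                          "p_value": [0.1, 0.2, 0.3]})
    id_map = pd.DataFrame({"chrom": ["c1"], "pos": [5], "rs_id": ["rs42"]})
    out = assign_rs_ids(calls, id_map)
    assert len(out) == len(calls)
    assert list(out["rs_id"]) == ["rs42", "novel_c1_9", "novel_c2_5"]
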