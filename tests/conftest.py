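import numpy as np
import pandas as pd
import pytest

from rsnp_scan import SimConfig, simulate_all
from rsnp_scan.pipeline import run_on_study

SMALL_CFG = SimConfig(seed=11, n_genes=80)


@pytest.fixture(scope="session")
def small_study():
    """One modest synthetic study shared across tests."""
    return simulate_all(SMALL_CFG)


@pytest.fixture(scope="session")
def small_discovery(small_study):
    """Full discovery run on the shared study (reduced Monte-Carlo reps)."""
    return run_on_study(small_study, n_sim=999)


def toy_transcripts():
    """Hand-built transcript table exercising strands and alternative TSSs."""
    return pd.DataFrame({
        "gene_id": ["gA", "gA", "gB", "gC"],
        "transcript_id": ["gA.t0", "gA.t1", "gB.t0", "gC.t0"],
        "chrom": ["chr1"] * 4,
        "strand": ["+", "+", "-", "+"],
        "start": [5000, 5400, 2000, 10_500],
        "end": [9000, 9000, 5000, 12_000],
    })


def depths_frame(rows):
    """Rows of (individual, assay, chrom, pos, ref, alt, ref_count, alt_count)."""
    return pd.DataFrame(rows, columns=["individual", "assay", "chrom", "pos",
                                       "ref", "alt", "ref_count", "alt_count"])
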