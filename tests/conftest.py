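"""Shared fixtures: small simulated study designs reused across test modules."""

import numpy as np
import pandas as pd
import pytest

import sweepscan as ss
from sweepscan.experiments import combined_matrix


def make_snp_map(positions, chrom=1, alleles=("A", "G")):
    n = len(positions)
    return ss.SnpMap(
        pd.DataFrame(
            {
                "snp_id": [f"s{i}" for i in range(n)],
                "chrom": chrom,
                "pos": list(positions),
                "allele1": alleles[0],
                "allele2": alleles[1],
            }
        )
    )


@pytest.fixture(scope="session")
def sweep_sim():
    """Two-chromosome design with a moderate sweep on each, active both phases."""
    cfg = ss.SimConfig(
        n_chrom=2,
        snps_per_chrom=400,
        chrom_length_bp=20_000_000,
        pop_size=300,
        n_founder_haplotypes=600,
        cohort_sizes=(80, 80, 80),
        sweep_loci=(ss.SweepLocus(0, 200, 0.15), ss.SweepLocus(1, 100, 0.15)),
        seed=42,
    )
    return ss.simulate(cfg)


@pytest.fixture(scope="session")
def neutral_sim():
    cfg = ss.SimConfig(
        n_chrom=2,
        snps_per_chrom=200,
        chrom_length_bp=10_000_000,
        pop_size=150,
        n_founder_haplotypes=300,
        cohort_sizes=(60, 60, 60),
        sweep_loci=(),
        seed=7,
    )
    return ss.simulate(cfg)


@pytest.fixture(scope="session")
def sweep_combined(sweep_sim):
    """Stacked genotype matrix + groups + per-group frequency table."""
    matrix, groups = combined_matrix(sweep_sim)
    freqs = ss.group_frequencies(matrix, groups, labels=["I", "II", "III"])
    return matrix, groups, freqs
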