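import numpy as np
import pandas as pd
import pytest

from gwamaqc import (
    CohortSpec,
    CohortSummary,
    PopulationSpec,
    SimConfig,
    run_simulation,
)


def make_cohort(
    m=200, n=500, seed=0, cohort_id="c1", chrom_count=4, spacing=250_000,
    palindromic=False,
):
    """Small hand-rolled cohort table with controllable allele content."""
    rng = np.random.default_rng(seed)
    pairs = (
        [("A", "T"), ("C", "G")] if palindromic
        else [("A", "C"), ("A", "G"), ("T", "C"), ("T", "G"), ("C", "A"), ("G", "A")]
    )
    alleles = [pairs[i % len(pairs)] for i in range(m)]
    freq = rng.uniform(0.05, 0.95, m)
    table = pd.DataFrame(
        {
            "snp_id": [f"rs{i}" for i in range(m)],
            "chrom": [str(1 + i % chrom_count) for i in range(m)],
            "bp": [1 + (i // chrom_count) * spacing for i in range(m)],
            "a1": [a for a, _ in alleles],
            "a2": [b for _, b in alleles],
            "freq_a1": freq,
            "beta": rng.standard_normal(m) * 0.05,
            "se": rng.uniform(0.02, 0.08, m),
            "n": n,
        }
    )
    return CohortSummary(cohort_id=cohort_id, table=table)


@pytest.fixture(scope="session")
def small_pair_sim():
    """Two 400-sample cohorts sharing 40 individuals, 3000 unlinked SNPs."""
    config = SimConfig(
        m_snps=3000,
        populations=[PopulationSpec("POP")],
        cohorts=[
            CohortSpec("cohort1", "POP", 400, h2=0.25),
            CohortSpec("cohort2", "POP", 400, h2=0.25, overlap_with=("cohort1", 40)),
        ],
        n_qtl=100,
        seed=42,
    )
    return run_simulation(config)
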