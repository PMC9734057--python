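import numpy as np
import pandas as pd
import pytest

from circpath.simulate import ScenarioConfig, simulate_cohort


@pytest.fixture(scope="session")
def mediation_cohort():
    """One MEDIATION cohort at the reference cohort size (n=105)."""
    return simulate_cohort(
        ScenarioConfig(
            n_samples=105,
            n_snps=8,
            n_circ=2,
            n_genes=2,
            n_mirna=2,
            theta_trait=1.5,
            scenario="MEDIATION",
            seed=101,
        )
    )


@pytest.fixture(scope="session")
def null_cohort():
    return simulate_cohort(
        ScenarioConfig(
            n_samples=105, n_snps=40, n_circ=20, n_genes=5, scenario="NULL", seed=77
        )
    )


def snp_frame(positions):
    """Helper: build a positions DataFrame from (id, chrom, pos) triples."""
    ids, chroms, pos = zip(*positions)
    return pd.DataFrame(
        {"chrom": chroms, "pos": pos}, index=pd.Index(ids, name="snp_id")
    )
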