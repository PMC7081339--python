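import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import haploscan as hs

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_matrix(calls, strains=None, chrom="chr1", spacing=100):
    """GenotypeMatrix from a (n_variants, n_strains) array of {0,1,-1}."""
    calls = np.asarray(calls, dtype=np.int8)
    n_var, n_str = calls.shape
    strains = strains or [f"s{i}" for i in range(n_str)]
    variants = [
        hs.Variant(chrom, (i + 1) * spacing, "A", "G") for i in range(n_var)
    ]
    return hs.GenotypeMatrix(strains, variants, calls)


def make_phenotypes(rows):
    """PhenotypeTable from (strain, timepoint, replicate, value) tuples."""
    return hs.PhenotypeTable(
        pd.DataFrame(rows, columns=["strain", "timepoint", "replicate", "value"])
    )


@pytest.fixture(scope="session")
def causal_panel():
    """16-strain panel with a 2-group causal block active at 3 of 6 timepoints."""
    cfg = hs.SimulationConfig(
        seed=11,
        causal_spec=hs.CausalSpec(
            active_timepoints=("0", "4", "24"), variance_explained=0.8, n_groups=2
        ),
    )
    genotypes, phenotypes, truth = hs.simulate_panel(cfg)
    return cfg, genotypes, phenotypes, truth


@pytest.fixture(scope="session")
def small_panel():
    """Small noisy panel for I/O round trips."""
    cfg = hs.SimulationConfig(
        seed=3,
        n_chromosomes=2,
        snps_per_chromosome=40,
        missing_rate=0.1,
        flip_rate=0.01,
    )
    genotypes, phenotypes, truth = hs.simulate_panel(cfg)
    return genotypes, phenotypes, truth
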