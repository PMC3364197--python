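import numpy as np
import pytest

from amdgrs import (CaseControlStudy, SnpDefinition, SnpPanel, amd13_panel,
                    default_config, simulate_cohort)


@pytest.fixture(scope="session")
def panel13():
    return amd13_panel()


@pytest.fixture(scope="session")
def tiny_panel():
    return SnpPanel((
        SnpDefinition("rsA", "GENE1", "L1", "A", "G"),
        SnpDefinition("rsB", "GENE2", "L2", "T", "C"),
    ))


@pytest.fixture(scope="session")
def study_cohort():
    """Study-sized cohort (986 cases / 796 controls) from the default
    13-SNP disease model; shared across read-only tests."""
    return simulate_cohort(default_config(seed=11))


@pytest.fixture(scope="session")
def small_cohort():
    """Small cohort for cheap structural tests."""
    return simulate_cohort(default_config(seed=7, n_cases=250,
                                          n_controls=250))


def make_study_from_counts(control_counts, case_counts, snp="rs1"):
    """Study with one SNP whose genotype counts are given per arm."""
    dosages, status = [], []
    for g, n in enumerate(control_counts):
        dosages += [g] * n
        status += [0] * n
    for g, n in enumerate(case_counts):
        dosages += [g] * n
        status += [1] * n
    import pandas as pd
    return CaseControlStudy(
        subjects=[f"S{i}" for i in range(len(status))],
        status=np.array(status),
        dosage=pd.DataFrame({snp: dosages}),
    )
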