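import numpy as np
import pandas as pd
import pytest

from iescape import CohortSpec, ExpressionMatrix, GeneSet, GroupSpec, simulate_cohort


@pytest.fixture
def ranked_matrix() -> ExpressionMatrix:
    """5 genes strictly ordered g1 > g2 > ... > g5 in a single sample."""
    return ExpressionMatrix(
        pd.DataFrame({"s1": [5.0, 4.0, 3.0, 2.0, 1.0]},
                     index=["g1", "g2", "g3", "g4", "g5"])
    )


@pytest.fixture
def random_matrix() -> ExpressionMatrix:
    rng = np.random.default_rng(11)
    genes = [f"G{i:03d}" for i in range(60)]
    samples = [f"s{i}" for i in range(8)]
    return ExpressionMatrix(
        pd.DataFrame(rng.normal(6, 1, (60, 8)), index=genes, columns=samples)
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A modest synthetic cohort reused across modules (seeded)."""
    spec = CohortSpec(
        groups={
            "cHL": GroupSpec(30, (0.0, 0.0, 1.0, 0.0)),
            "DLBCL": GroupSpec(50, (0.3, 0.3, 0.2, 0.2)),
        },
        n_genes=800,
        noise_sd=0.5,
        seed=13,
    )
    return simulate_cohort(spec)


@pytest.fixture
def iegs_like_set() -> GeneSet:
    return GeneSet("toy", frozenset(["G000", "G005", "G010", "G015"]))
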