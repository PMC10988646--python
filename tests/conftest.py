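import numpy as np
import pandas as pd
import pytest

from mirnet import (
    AnalysisConfig,
    CohortTable,
    ExpressionMatrix,
    SimulationSpec,
    default_domain_map,
    simulate_cohort,
    simulate_counts,
)


@pytest.fixture(scope="session")
def domain_map():
    return default_domain_map()


@pytest.fixture(scope="session")
def default_spec():
    return SimulationSpec(seed=11)


@pytest.fixture(scope="session")
def cohort(default_spec):
    return simulate_cohort(default_spec)


@pytest.fixture(scope="session")
def counts(default_spec, cohort):
    return simulate_counts(default_spec, cohort)


@pytest.fixture(scope="session")
def fitted(counts, cohort):
    from mirnet import MiRNAPhenotypeModel

    return MiRNAPhenotypeModel(counts, cohort, config=AnalysisConfig()).fit()


@pytest.fixture()
def tiny_cohort(domain_map):
    """Hand-sized 8-subject cohort with a deterministic battery."""
    rng = np.random.default_rng(5)
    n = 8
    df = pd.DataFrame(
        {
            "subject_id": [f"T{i}" for i in range(n)],
            "age_at_death": np.linspace(76, 95, n),
            "sex": ["male", "female"] * (n // 2),
            "education": np.linspace(12, 24, n),
            "apoe": ["e3/e3"] * n,
            "mmse": [26, 27, 28, 29, 30, 28, 27, 29],
            "braak": ["I", "I", "II", "II", "III", "III", "IV", "IV"],
            "cerad": ["No AD", "No AD", "Possible", "Probable", "No AD", "Probable", "Definite", "No AD"],
            "nia_reagan": ["Low", "Low", "Low", "Intermediate", "Low", "Intermediate", "Intermediate", "Low"],
            "amyloid_load_6e10": [0, 1, 2, 2, 3, 3, 4, 5],
            "tangle_load_at8": [0, 0, 1, 1, 1, 2, 3, 3],
        }
    )
    for t in domain_map.tests:
        df[t] = rng.normal(size=n)
    z = (df[domain_map.tests] - df[domain_map.tests].mean()) / df[domain_map.tests].std(ddof=1)
    df["gcs"] = z.mean(axis=1)
    return CohortTable(df, tests=domain_map.tests)


@pytest.fixture()
def tiny_counts(tiny_cohort):
    rng = np.random.default_rng(6)
    ids = [f"miR-t{i}" for i in range(12)]
    mat = rng.integers(0, 200, size=(12, tiny_cohort.n_subjects)).astype(float)
    mat[0, :3] = 0.0  # sparse miRNA
    df = pd.DataFrame(mat, index=pd.Index(ids, name="mirna"), columns=tiny_cohort.subject_ids)
    return ExpressionMatrix(df)


@pytest.fixture()
def example_records():
    """Small association-record set covering both signs and a highlight."""
    return pd.DataFrame(
        {
            "mirna": ["miR-a", "miR-b", "miR-a", "miR-c", "miR-d"],
            "phenotype": ["age", "age", "sem.mem", "sem.mem", "age"],
            "statistic_kind": ["spearman_rho"] * 5,
            "rho": [0.5, 0.72, -0.44, -0.6, 0.39],
            "p": [0.01, 0.0001, 0.03, 0.004, 0.049],
            "q": [np.nan] * 5,
            "n_used": [26] * 5,
            "sign": ["positive", "positive", "negative", "negative", "positive"],
            "highlight": [False, True, False, False, False],
        }
    )
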