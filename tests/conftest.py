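"""Shared fixtures: tiny hand-checkable matrices and seeded simulated cohorts."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from gradesig import SimConfig, simulate_expression
from gradesig.core_io import ExpressionMatrix, PhenotypeTable, GRADE2, GRADE3


def make_cohort(
    n_features: int,
    n_samples: int,
    seed: int,
    separating: int = 0,
    shift: float = 3.0,
    noise: float = 0.1,
) -> tuple[ExpressionMatrix, PhenotypeTable]:
    """Gaussian noise cohort with the first ``separating`` features class-shifted."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n_features, n_samples))
    grades = np.array([GRADE2] * (n_samples // 2) + [GRADE3] * (n_samples - n_samples // 2))
    for i in range(separating):
        X[i] = np.where(grades == GRADE3, shift, 0.0) + rng.normal(0, noise, n_samples)
    genes = [f"G{i:03d}" for i in range(n_features)]
    samples = [f"S{j:03d}" for j in range(n_samples)]
    expr = ExpressionMatrix(genes, samples, X)
    pheno = PhenotypeTable(pd.DataFrame({"sample_id": samples, "grade": grades}))
    return expr, pheno


@pytest.fixture
def tiny_expr() -> ExpressionMatrix:
    return ExpressionMatrix(
        ["g1", "g2", "g3"], ["s1", "s2"], np.array([[1.0, 4.0], [2.0, 5.0], [3.0, 6.0]])
    )


@pytest.fixture
def cohort_factory():
    return make_cohort


@pytest.fixture(scope="session")
def default_sim():
    """One cohort drawn at the default study conditions, shared across tests."""
    return simulate_expression(SimConfig(seed=11))


def two_class_pheno(sample_ids, grades) -> PhenotypeTable:
    return PhenotypeTable(pd.DataFrame({"sample_id": sample_ids, "grade": grades}))
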