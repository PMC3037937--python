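import numpy as np
import pandas as pd
import pytest

from dige_biomarker import (
    ExpressionMatrix,
    SyntheticParams,
    assemble_matrix,
    generate_study,
    normalize_internal_standard,
)


def make_matrix(values: np.ndarray, n_tumor: int, feature_prefix: str = "F",
                sample_prefix: str = "s") -> ExpressionMatrix:
    """Wrap a raw array as an ExpressionMatrix with the first columns tumor."""
    n_features, n_samples = values.shape
    features = [f"{feature_prefix}{i:03d}" for i in range(n_features)]
    samples = [f"{sample_prefix}{i:02d}" for i in range(n_samples)]
    labels = pd.Series(
        ["tumor"] * n_tumor + ["benign"] * (n_samples - n_tumor),
        index=samples, name="class")
    return ExpressionMatrix(pd.DataFrame(values, index=features, columns=samples),
                            labels)


def default_study(seed: int, **overrides):
    """Full default synthetic study -> (design, truth, assembled matrix)."""
    params = SyntheticParams(seed=seed, **overrides)
    design, truth, tables = generate_study(params)
    matrix = assemble_matrix(normalize_internal_standard(tables), design)
    return design, truth, matrix


@pytest.fixture(scope="session")
def study_seed1():
    return default_study(1)


@pytest.fixture(scope="session")
def matrix_seed1(study_seed1):
    return study_seed1[2]
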