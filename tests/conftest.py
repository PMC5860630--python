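import numpy as np
import pandas as pd
import pytest

from deltami import (
    Column,
    ImputationConfig,
    RoleMap,
    Schema,
    StudyTable,
)
from deltami import synthgen


def make_table(df: pd.DataFrame, schema: Schema) -> StudyTable:
    return StudyTable(df.reset_index(drop=True), schema)


@pytest.fixture(scope="session")
def synth_small():
    """One synthetic survey of n=5,000 with its exact truth (session-cached)."""
    params = synthgen.default_params(n=5_000, seed=42)
    table, truth = synthgen.generate(params)
    return table, truth, synthgen.default_roles()


@pytest.fixture(scope="session")
def synth_big():
    """A large synthetic survey (n=50,000) for recovery tests (session-cached)."""
    params = synthgen.default_params(n=50_000, seed=7)
    table, truth = synthgen.generate(params)
    return table, truth, synthgen.default_roles()


@pytest.fixture(scope="session")
def synth_roles():
    return synthgen.default_roles()


@pytest.fixture
def binary_schema():
    return Schema([Column("y", "binary"), Column("x", "binary")])


@pytest.fixture
def simple_config():
    return ImputationConfig(predictors=("x",), M=5, seed=7)


def counts_table(n_pos: int, n_neg: int, n_missing: int = 0) -> StudyTable:
    """Single-column binary table with given observed counts and missing rows."""
    vals = [1.0] * n_pos + [0.0] * n_neg + [np.nan] * n_missing
    return StudyTable(
        pd.DataFrame({"y": vals}), Schema([Column("y", "binary")])
    )
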