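import numpy as np
import pandas as pd
import pytest

from opinionet.cohort import SyntheticConfig, generate_cohort
from opinionet.network import StanceMatrix
from opinionet.survey import ItemSpec, LikertScale, ResponseMatrix


@pytest.fixture(scope="session")
def default_cohort():
    """One default planted-faction cohort, shared across tests."""
    return generate_cohort(SyntheticConfig(seed=42))


def make_matrix(values, scale=(1, 7), wave_id="T1", block="attitude", ids=None):
    """ResponseMatrix from a nested list / array (NaN = missing)."""
    arr = np.asarray(values, dtype=float)
    n, k = arr.shape
    items = [ItemSpec(f"item{j + 1}", LikertScale(*scale), block) for j in range(k)]
    ids = ids or [f"P{i + 1}" for i in range(n)]
    return ResponseMatrix(wave_id, items, pd.DataFrame(arr, index=ids,
                                                       columns=[s.item_id for s in items]))


def make_stances(values, wave_id="T1", ids=None, item_ids=None):
    """StanceMatrix from a nested list over {-1, 0, 1, nan}."""
    arr = np.asarray(values, dtype=float)
    n, k = arr.shape
    ids = ids or [f"P{i + 1}" for i in range(n)]
    item_ids = item_ids or [f"item{j + 1}" for j in range(k)]
    return StanceMatrix(wave_id, pd.DataFrame(arr, index=ids, columns=item_ids))


@pytest.fixture
def stance_factory():
    return make_stances


@pytest.fixture
def matrix_factory():
    return make_matrix


def random_stances(rng, n=20, k=8, p_missing=0.1, p_neutral=0.15):
    """Random stance matrix with missing cells and neutral stances."""
    signs = rng.choice([-1.0, 1.0], size=(n, k))
    u = rng.uniform(size=(n, k))
    signs[u < p_neutral] = 0.0
    signs[u > 1 - p_missing] = np.nan
    return make_stances(signs)
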