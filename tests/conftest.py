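"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import leda
from leda.synthetic_data import _bundled_segments

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def segments():
    return _bundled_segments()


@pytest.fixture(scope="session")
def cqa_table():
    return leda.load_bundled_ratio_table("CQAs")


@pytest.fixture(scope="session")
def dicqa_table():
    return leda.load_bundled_ratio_table("diCQAs")


@pytest.fixture(scope="session")
def cqa_matrix(cqa_table):
    return leda.assemble_leda_matrix(cqa_table)


@pytest.fixture(scope="session")
def dicqa_matrix(dicqa_table):
    return leda.assemble_leda_matrix(dicqa_table)


# ---------------------------------------------------------------------------
# Independent oracle: exhaustive grid search over the 3-simplex


def simplex_grid(resolution: float = 0.001) -> np.ndarray:
    """All 3-component compositions at the given resolution (rows sum to 1)."""
    n = int(round(1.0 / resolution))
    i, j = np.meshgrid(np.arange(n + 1), np.arange(n + 1), indexing="ij")
    mask = i + j <= n
    i, j = i[mask], j[mask]
    return np.column_stack([i, j, n - i - j]) / n


class SimplexSearchOracle:
    """Brute-force least-squares minimizer over the gridded simplex.

    Precomputes the design's image of every grid composition so each query
    is a single matrix-vector product plus an argmin.
    """

    def __init__(self, design: np.ndarray, resolution: float = 0.001):
        self.grid = simplex_grid(resolution)
        self._image = design @ self.grid.T
        self._colnorms = np.einsum("ij,ij->j", self._image, self._image)

    def best_fractions(self, measured: np.ndarray) -> np.ndarray:
        scores = self._colnorms - 2.0 * (np.asarray(measured, float) @ self._image)
        return self.grid[int(np.argmin(scores))]
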