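"""Composite cognitive-domain scores from the 12-test battery.

Each participant's 12 test scores are z-scored across the analysis sample
and projected onto three domain axes (working memory, verbal, reasoning)
with the regression-scores formula

    Y = X (Ar+)^T,

where ``Ar`` is a 12 x 3 matrix of varimax-rotated principal-component
weights and ``Ar+`` its Moore-Penrose pseudo-inverse.  Row i of Y is the
least-squares solution of ``Ar y ~ x_i``: the domain-score triple that best
reconstructs that participant's test profile.  A weight matrix is normally
supplied (the battery's published factor structure); ``derive_weights``
re-derives one from data via PCA plus varimax when none is available.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from statsmodels.multivariate.factor_rotation import rotate_factors

from .cohort import DOMAINS, TEST_COLUMNS, CohortTable

__all__ = [
    "WeightMatrix",
    "DEFAULT_WEIGHTS",
    "zscore_tests",
    "compute_domain_scores",
    "derive_weights",
]


@dataclass
class WeightMatrix:
    """12 x 3 test-to-domain component-weight matrix.

    Rows are tests in declared order, columns are the domains
    (wm, verbal, reasoning).  Must be full column rank, with every row and
    every column carrying at least one nonzero entry (every test informs
    every domain score through the pseudo-inverse).
    """

    entries: pd.DataFrame
    provenance: str = "user-supplied"

    def __post_init__(self) -> None:
        e = self.entries
        if e.shape != (12, 3):
            raise ValueError(f"weight matrix must be 12x3, got {e.shape}")
        vals = e.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError("weight matrix entries must be finite")
        if np.linalg.matrix_rank(vals) < 3:
            raise ValueError("weight matrix must have full column rank")
        if np.any(np.all(vals == 0, axis=1)) or np.any(np.all(vals == 0, axis=0)):
            raise ValueError("every row and column needs a nonzero entry")

    @property
    def values(self) -> np.ndarray:
        return self.entries.to_numpy(dtype=float)

    def write_csv(self, path: str | Path) -> None:
        self.entries.to_csv(path)

    @classmethod
    def read_csv(cls, path: str | Path, provenance: str = "user-supplied"
                 ) -> "WeightMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(df, provenance=provenance)


# Default loading pattern: each test loads chiefly on its home domain with
# modest cross-loadings, so every test contributes to every domain score.
_DEFAULT = np.array([
    # wm    verbal reasoning
    [0.72, 0.08, 0.18],  # monkey_ladder
    [0.10, 0.75, 0.22],  # grammatical_reasoning
    [0.15, 0.55, 0.35],  # double_trouble
    [0.12, 0.10, 0.70],  # odd_one_out
    [0.75, 0.06, 0.15],  # spatial_span
    [0.10, 0.05, 0.68],  # rotations
    [0.20, 0.12, 0.60],  # feature_match
    [0.55, 0.45, 0.08],  # digit_span
    [0.35, 0.10, 0.58],  # spatial_planning
    [0.65, 0.12, 0.20],  # paired_associates
    [0.18, 0.35, 0.55],  # interlocking_polygons
    [0.70, 0.10, 0.25],  # token_search
])

DEFAULT_WEIGHTS = WeightMatrix(
    pd.DataFrame(_DEFAULT, index=list(TEST_COLUMNS), columns=list(DOMAINS)),
    provenance="package-default",
)


def zscore_tests(table: CohortTable | pd.DataFrame) -> pd.DataFrame:
    """Z-score each test column (sample SD) over the analysis sample.

    Returns the N x 12 matrix X with column means 0 and SDs 1.
    """
    scores = table.scores() if isinstance(table, CohortTable) else table
    if len(scores) < 2:
        raise ValueError("need at least 2 rows to z-score")
    sd = scores.std(ddof=1)
    zero = sd[sd == 0]
    if len(zero):
        raise ValueError(f"zero-variance test column: {zero.index[0]!r}")
    return (scores - scores.mean()) / sd


def compute_domain_scores(
    X: pd.DataFrame | np.ndarray, weights: WeightMatrix
) -> pd.DataFrame:
    """Project z-scored tests onto the three domains: ``Y = X (Ar+)^T``."""
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 12:
        raise ValueError("X must be N x 12")
    pinv = np.linalg.pinv(weights.values)  # 3 x 12
    Y = arr @ pinv.T
    index = X.index if isinstance(X, pd.DataFrame) else None
    return pd.DataFrame(Y, columns=list(weights.entries.columns), index=index)


def _varimax_kaiser(A: np.ndarray, tol: float = 1e-8, max_iter: int = 1000
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Varimax with Kaiser row normalisation; returns (rotated, rotation)."""
    h = np.sqrt(np.sum(A**2, axis=1))
    h[h == 0] = 1.0
    L, T = rotate_factors(A / h[:, None], "varimax", tol=tol, max_tries=max_iter)
    return L * h[:, None], T


def derive_weights(
    X: pd.DataFrame | np.ndarray, n_components: int = 3
) -> WeightMatrix:
    """Derive a weight matrix from data: PCA loadings, varimax-rotated.

    The first ``n_components`` principal-component loading vectors
    (eigenvectors scaled by the root eigenvalue of the correlation
    structure of X) are varimax-rotated with Kaiser normalisation.  The
    rotation is unique only up to column order and sign; these are fixed
    by ordering columns by explained variance (descending) and choosing
    the sign that makes each column's largest-magnitude loading positive.
    """
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 12:
        raise ValueError("X must be N x 12")
    if arr.shape[0] < 13:
        raise ValueError("need at least 13 rows to derive weights")
    C = np.cov(arr, rowvar=False, ddof=1)
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if np.sum(evals > 1e-12) < n_components:
        raise ValueError("fewer than 3 positive eigenvalues")
    loadings = evecs[:, :n_components] * np.sqrt(evals[:n_components])
    rotated, _ = _varimax_kaiser(loadings)
    # deterministic column order and sign
    var_explained = np.sum(rotated**2, axis=0)
    col_order = np.argsort(var_explained)[::-1]
    rotated = rotated[:, col_order]
    for j in range(rotated.shape[1]):
        i = np.argmax(np.abs(rotated[:, j]))
        if rotated[i, j] < 0:
            rotated[:, j] = -rotated[:, j]
    df = pd.DataFrame(rotated, index=list(TEST_COLUMNS), columns=list(DOMAINS))
    return WeightMatrix(df, provenance="derived")
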