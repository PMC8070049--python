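import numpy as np
import pytest

import cogspan as cs


@pytest.fixture(scope="session")
def small_cohort() -> cs.CohortTable:
    """Clean default cohort, 800 per sex, reused by read-only tests."""
    return cs.generate_cohort(cs.default_config(n_per_sex=800, seed=101))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)


def one_break_data(rng, n=200, psi=10.0, slopes=(0.5, -0.2), noise=1.0,
                   span=(0.0, 20.0)):
    """Noisy one-breakpoint dataset for fitter tests."""
    x = rng.uniform(*span, size=n)
    y = 1.0 + slopes[0] * x + (slopes[1] - slopes[0]) * np.maximum(x - psi, 0)
    y = y + rng.normal(0, noise, size=n)
    return x, y


def profile_rss_grid(x, y, step=0.01, qlo=0.05, qhi=0.95):
    """Independent dense-grid profile least squares for one breakpoint.

    Returns (best_rss, best_psi) over a regular grid of candidate
    breakpoints, solving the 3-parameter least-squares problem at each by
    normal equations.
    """
    lo, hi = np.quantile(x, [qlo, qhi])
    grid = np.arange(lo, hi, step)
    ones = np.ones_like(x)
    # batched normal equations over the grid
    hinges = np.maximum(x[None, :] - grid[:, None], 0.0)  # G x n
    G = grid.size
    X0 = np.column_stack([ones, x])
    A = np.empty((G, 3, 3))
    b = np.empty((G, 3))
    A[:, :2, :2] = X0.T @ X0
    A[:, 2, 2] = np.einsum("gn,gn->g", hinges, hinges)
    cross = hinges @ X0  # G x 2
    A[:, 2, :2] = cross
    A[:, :2, 2] = cross
    b[:, :2] = X0.T @ y
    b[:, 2] = hinges @ y
    coef = np.linalg.solve(A, b[..., None])[..., 0]
    yy = float(y @ y)
    rss = yy - np.einsum("gi,gi->g", coef, b)
    k = int(np.argmin(rss))
    return float(rss[k]), float(grid[k])
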