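"""Between-sex comparisons of questionnaire covariates.

Each covariate is compared between women and men with the test matching
its variable type — Welch's t (continuous), Wilcoxon rank-sum (ordinal),
Pearson chi-square (categorical) — with Benjamini-Hochberg FDR correction
applied jointly across the battery and a standardised effect size attached
(Cohen's d, rank-shift r, Cramer's V).  Sign convention throughout is
women minus men.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohort import CohortTable

__all__ = [
    "GroupComparison",
    "welch_t",
    "welch_t_from_stats",
    "wilcoxon_rank_sum",
    "chi_square_test",
    "fdr_adjust",
    "compare_demographics",
    "describe_distribution",
    "comparisons_to_frame",
]


@dataclass
class GroupComparison:
    """One row of a sex-comparison table."""

    variable: str
    var_type: str
    statistic: float
    df: float | tuple[int, int]
    p_raw: float
    p_adjusted: float
    effect_size: float
    effect_kind: str
    significant: bool = False

    def to_dict(self) -> dict:
        return {
            "variable": self.variable,
            "var_type": self.var_type,
            "statistic": float(self.statistic),
            "df": self.df if np.isscalar(self.df) else list(self.df),
            "p_raw": float(self.p_raw),
            "p_adjusted": float(self.p_adjusted),
            "effect_size": float(self.effect_size),
            "effect_kind": self.effect_kind,
            "significant": bool(self.significant),
        }


def welch_t_from_stats(
    m1: float, s1: float, n1: int, m2: float, s2: float, n2: int
) -> tuple[float, float, float, float]:
    """Welch's t from summary statistics; returns (t, df, p, cohens_d).

    Cohen's d uses the pooled SD with the classical
    ``((n1-1)s1^2 + (n2-1)s2^2) / (n1+n2-2)`` pooled variance.
    """
    if min(n1, n2) < 2:
        raise ValueError("each sample needs n >= 2")
    v1, v2 = s1 * s1, s2 * s2
    if v1 == 0 and v2 == 0:
        if m1 == m2:
            return 0.0, float(n1 + n2 - 2), 1.0, 0.0
        raise ValueError("zero variance in both samples with unequal means")
    se2 = v1 / n1 + v2 / n2
    t = (m1 - m2) / np.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    pooled = np.sqrt(((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2))
    d = (m1 - m2) / pooled if pooled > 0 else 0.0
    return float(t), float(df), float(p), float(d)


def welch_t(x, y) -> tuple[float, float, float, float]:
    """Welch's unequal-variance t test; returns (t, df, p, cohens_d)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return welch_t_from_stats(
        x.mean(), x.std(ddof=1), x.size, y.mean(), y.std(ddof=1), y.size
    )


def _exact_rank_sum_p(x: np.ndarray, y: np.ndarray, u_obs: float) -> float:
    """Two-sided exact p by enumerating all group labelings (small n)."""
    pooled = np.concatenate([x, y])
    n1 = x.size
    mu = n1 * y.size / 2.0
    obs_dev = abs(u_obs - mu)
    count = 0
    total = comb(pooled.size, n1)
    idx = np.arange(pooled.size)
    for chosen in combinations(idx, n1):
        mask = np.zeros(pooled.size, dtype=bool)
        mask[list(chosen)] = True
        xa, ya = pooled[mask], pooled[~mask]
        u = float(np.sum(xa[:, None] > ya[None, :])
                  + 0.5 * np.sum(xa[:, None] == ya[None, :]))
        if abs(u - mu) >= obs_dev - 1e-12:
            count += 1
    return count / total


def wilcoxon_rank_sum(x, y) -> tuple[float, float, float, float]:
    """Wilcoxon rank-sum (Mann-Whitney) test; returns (U, z, p, rank_r).

    Midranks handle ties; the normal approximation uses the tie-corrected
    variance and a continuity correction, with
    ``r = |z| / sqrt(n1 + n2)``.  When ``n1 + n2 <= 10`` the p-value comes
    from exact enumeration of all labelings instead.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("each sample needs n >= 1")
    n1, n2 = x.size, y.size
    N = n1 + n2
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    mu = n1 * n2 / 2.0

    _, counts = np.unique(pooled, return_counts=True)
    if counts.size <= 1:  # everything tied across both groups
        return u1, 0.0, 1.0, 0.0
    tie_term = float(np.sum(counts**3 - counts))
    var = n1 * n2 / 12.0 * ((N + 1) - tie_term / (N * (N - 1)))
    if var <= 0:
        return u1, 0.0, 1.0, 0.0
    dev = u1 - mu
    cc = min(0.5, abs(dev))  # continuity correction toward the mean
    z = (dev - np.sign(dev) * cc) / np.sqrt(var)
    if N <= 10:
        p = _exact_rank_sum_p(x, y, u1)
    else:
        p = 2.0 * stats.norm.sf(abs(z))
    r = abs(z) / np.sqrt(N)
    return u1, float(z), float(min(1.0, p)), float(r)


def chi_square_test(table) -> tuple[float, int, float, float]:
    """Pearson chi-square on a contingency table; returns (chi2, df, p, V).

    No continuity correction.  Rows or columns with a zero margin are
    dropped with a warning.  ``V = sqrt(chi2 / (N * min(r-1, c-1)))``.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or min(obs.shape) < 2:
        raise ValueError("need a contingency table with >= 2 rows and columns")
    if np.any(obs < 0) or not np.allclose(obs, np.round(obs)):
        raise ValueError("counts must be non-negative integers")
    row_ok = obs.sum(axis=1) > 0
    col_ok = obs.sum(axis=0) > 0
    if not row_ok.all() or not col_ok.all():
        warnings.warn("dropping zero-margin rows/columns", UserWarning,
                      stacklevel=2)
        obs = obs[row_ok][:, col_ok]
        if min(obs.shape) < 2:
            raise ValueError("table degenerate after dropping zero margins")
    chi2, p, df, _ = stats.chi2_contingency(obs, correction=False)
    n = obs.sum()
    k = min(obs.shape[0] - 1, obs.shape[1] - 1)
    v = float(np.sqrt(chi2 / (n * k))) if chi2 > 0 else 0.0
    return float(chi2), int(df), float(p), v


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, original order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def describe_distribution(values) -> tuple[float, float, float, float]:
    """Sample mean, SD, skew and excess kurtosis (bias-corrected)."""
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        raise ValueError("need at least 4 observations")
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance: skew and kurtosis undefined")
    return (
        float(v.mean()),
        float(sd),
        float(stats.skew(v, bias=False)),
        float(stats.kurtosis(v, fisher=True, bias=False)),
    )


def compare_demographics(
    table: CohortTable,
    type_map: dict[str, str] | None = None,
    alpha: float = 0.01,
) -> list[GroupComparison]:
    """Compare women and men on every covariate; FDR-adjust jointly.

    Continuous covariates get Welch's t (effect: Cohen's d), ordinal
    covariates the Wilcoxon rank-sum test (effect: r), categorical
    covariates the chi-square test on the sex-by-level table (effect:
    Cramer's V).  A comparison is flagged significant when its adjusted
    p-value falls below ``alpha`` (default 0.01).
    """
    type_map = dict(type_map or table.covariate_types)
    if not type_map:
        raise ValueError("no covariates to compare")
    df = table.data
    women = df[df["sex"] == "female"]
    men = df[df["sex"] == "male"]
    rows: list[GroupComparison] = []
    for name, vt in type_map.items():
        if name not in df.columns:
            raise KeyError(f"covariate {name!r} absent from table")
        if vt == "continuous":
            t, dof, p, d = welch_t(women[name].dropna(), men[name].dropna())
            rows.append(GroupComparison(name, vt, t, dof, p, np.nan, d,
                                        "cohens_d"))
        elif vt == "ordinal":
            u, z, p, r = wilcoxon_rank_sum(
                women[name].dropna(), men[name].dropna()
            )
            # signed effect: women - men rank shift
            rows.append(GroupComparison(name, vt, u,
                                        (len(women), len(men)), p,
                                        np.nan, float(np.sign(z) * r),
                                        "rank_r"))
        elif vt == "categorical":
            ct = pd.crosstab(df["sex"], df[name]).to_numpy()
            chi2, dof, p, v = chi_square_test(ct)
            rows.append(GroupComparison(name, vt, chi2, dof, p, np.nan, v,
                                        "cramers_v"))
        else:
            raise ValueError(f"unknown variable type {vt!r} for {name!r}")
    adj = fdr_adjust([r.p_raw for r in rows])
    for r, a in zip(rows, adj):
        r.p_adjusted = float(a)
        r.significant = bool(a < alpha)
    return rows


def comparisons_to_frame(rows: list[GroupComparison]) -> pd.DataFrame:
    """Tabulate comparisons in the style of a demographics table."""
    return pd.DataFrame([r.to_dict() for r in rows])
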