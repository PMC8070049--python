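"""Propensity-score matched sex samples.

A logistic regression of sex-group membership on the questionnaire
covariates gives each participant a propensity score; the smaller sex
group ("treated") is then matched 1:1 to the other by greedy
nearest-neighbour matching without replacement.  Treated units are
processed in descending propensity order; ties in propensity or distance
break on the lowest participant id, making the procedure fully
deterministic.  Standardised mean differences before/after matching
provide the balance diagnostics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import (
    PerfectSeparationError,
    PerfectSeparationWarning,
)

from .cohort import CohortTable

__all__ = [
    "PropensityModel",
    "MatchResult",
    "estimate_propensity",
    "nearest_neighbor_match",
    "balance_report",
]


@dataclass
class PropensityModel:
    """Fitted logistic model of treated-sex membership."""

    treatment_sex: str
    coefficients: pd.Series  # includes "const"
    propensity: pd.Series    # indexed by participant_id
    design_columns: list[str]
    n_iterations: int

    def __post_init__(self) -> None:
        p = self.propensity.to_numpy()
        if np.any(p <= 0) or np.any(p >= 1):
            raise ValueError("fitted propensities must lie strictly in (0, 1)")


@dataclass
class MatchResult:
    """1:1 matched pairs and balance diagnostics."""

    pairs: list[tuple[str, str]]  # (treated_id, control_id)
    unmatched_treated: list[str]
    balance: pd.DataFrame = field(default_factory=pd.DataFrame)
    treatment_sex: str = ""

    def matched_ids(self) -> list[str]:
        out: list[str] = []
        for t, c in self.pairs:
            out.append(t)
            out.append(c)
        return out

    def write_pairs(self, path, sep: str = ",") -> None:
        pd.DataFrame(self.pairs, columns=["treated_id", "control_id"]).to_csv(
            path, sep=sep, index=False
        )


def _design_matrix(table: CohortTable, covariates: list[str]) -> pd.DataFrame:
    """Numeric design: continuous/ordinal as-is, categorical as indicators
    (reference level = first in sorted order)."""
    df = table.data
    parts = []
    for name in covariates:
        if name not in df.columns:
            raise KeyError(f"covariate {name!r} absent from table")
        vt = table.covariate_types.get(name, "continuous")
        if vt == "categorical":
            dummies = pd.get_dummies(df[name], prefix=name, dtype=float)
            dummies = dummies.reindex(sorted(dummies.columns), axis=1)
            parts.append(dummies.iloc[:, 1:])  # drop reference level
        else:
            parts.append(df[[name]].astype(float))
    X = pd.concat(parts, axis=1)
    # constant columns carry no information and break the MLE
    const = [c for c in X.columns if X[c].nunique() <= 1]
    if const:
        warnings.warn(f"dropping constant design columns: {const}",
                      UserWarning, stacklevel=3)
        X = X.drop(columns=const)
    return X


def estimate_propensity(
    table: CohortTable, covariates: list[str] | None = None
) -> PropensityModel:
    """Logistic regression of treated-sex membership on the covariates.

    The treated group is the smaller sex group (maximising the number of
    possible pairs).  Fitting uses Newton-Raphson (equivalently IRLS) with
    tolerance 1e-8 and at most 100 iterations; perfect separation and
    non-convergence raise informative errors.
    """
    df = table.data
    counts = df["sex"].value_counts()
    if len(counts) < 2 or counts.min() < 2:
        raise ValueError("need at least 2 participants of each sex")
    treatment_sex = counts.idxmin() if counts.iloc[0] != counts.iloc[1] \
        else "female"
    covariates = list(covariates or table.covariate_columns)
    X = _design_matrix(table, covariates)
    y = (df["sex"] == treatment_sex).astype(float)
    design = sm.add_constant(X, has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            res = sm.Logit(y, design).fit(
                method="newton", tol=1e-8, maxiter=100, disp=0
            )
    except (PerfectSeparationError, PerfectSeparationWarning) as exc:
        raise ValueError(
            "perfect separation in propensity model; remove the offending "
            "covariate"
        ) from exc
    if not res.mle_retvals.get("converged", False):
        raise RuntimeError(
            f"propensity model did not converge in "
            f"{res.mle_retvals.get('iterations', '?')} iterations"
        )
    prop = pd.Series(np.asarray(res.predict(design)),
                     index=df["participant_id"].to_numpy())
    eps = 1e-12
    prop = prop.clip(eps, 1 - eps)
    return PropensityModel(
        treatment_sex=treatment_sex,
        coefficients=res.params,
        propensity=prop,
        design_columns=list(design.columns),
        n_iterations=int(res.mle_retvals.get("iterations", 0)),
    )


def _find_alive(start: int, alive: np.ndarray, step: int) -> int:
    """Nearest alive index at or beyond ``start`` in direction ``step``."""
    i = start
    n = alive.size
    while 0 <= i < n and not alive[i]:
        i += step
    return i if 0 <= i < n else -1


def nearest_neighbor_match(
    model: PropensityModel, table: CohortTable, seed: int | None = None
) -> MatchResult:
    """Greedy 1:1 nearest-neighbour matching without replacement.

    Treated units (the designated treatment sex) are processed in
    descending propensity order (ties: lowest participant id); each is
    paired with the not-yet-used control whose propensity is closest
    (distance ties: lowest control id).  If the control pool empties,
    remaining treated units are recorded unmatched.  The ``seed`` argument
    is accepted for interface symmetry; the procedure is deterministic.
    """
    df = table.data
    ids = df["participant_id"].to_numpy()
    prop = model.propensity.reindex(ids).to_numpy()
    if np.any(np.isnan(prop)):
        raise ValueError("propensity missing for some participants")
    treated_mask = (df["sex"] == model.treatment_sex).to_numpy()

    t_ids, t_p = ids[treated_mask], prop[treated_mask]
    c_ids, c_p = ids[~treated_mask], prop[~treated_mask]
    t_order = np.lexsort((t_ids, -t_p))
    c_order = np.lexsort((c_ids, c_p))
    c_ids, c_p = c_ids[c_order], c_p[c_order]

    alive = np.ones(c_ids.size, dtype=bool)
    n_alive = c_ids.size
    pairs: list[tuple[str, str]] = []
    unmatched: list[str] = []
    for ti in t_order:
        if n_alive == 0:
            unmatched.append(t_ids[ti])
            continue
        p = t_p[ti]
        j = int(np.searchsorted(c_p, p))
        left = _find_alive(j - 1, alive, -1)
        right = _find_alive(j, alive, +1)
        if left < 0:
            pick = right
        elif right < 0:
            pick = left
        else:
            dl, dr = abs(p - c_p[left]), abs(c_p[right] - p)
            if abs(dl - dr) <= 1e-15:
                pick = left if c_ids[left] < c_ids[right] else right
            else:
                pick = left if dl < dr else right
        pairs.append((t_ids[ti], c_ids[pick]))
        alive[pick] = False
        n_alive -= 1

    assert len({c for _, c in pairs}) == len(pairs), "control reused"
    result = MatchResult(pairs=pairs, unmatched_treated=unmatched,
                         treatment_sex=model.treatment_sex)
    result.balance = balance_report(result, table)
    return result


def _smd(a: np.ndarray, b: np.ndarray) -> float:
    """Standardised mean difference with the pooled-SD denominator."""
    va, vb = a.var(ddof=1), b.var(ddof=1)
    denom = np.sqrt((va + vb) / 2.0)
    if denom == 0:
        return 0.0
    return float((a.mean() - b.mean()) / denom)


def balance_report(result: MatchResult, table: CohortTable) -> pd.DataFrame:
    """Per-covariate balance before vs. after matching.

    Continuous and ordinal covariates report the standardised mean
    difference (treated minus control); categorical covariates report the
    maximum absolute difference in level proportions.
    """
    if not result.pairs:
        raise ValueError("no matched pairs to report on")
    df = table.data.set_index("participant_id")
    treated_all = df[df["sex"] == result.treatment_sex]
    control_all = df[df["sex"] != result.treatment_sex]
    t_ids = [t for t, _ in result.pairs]
    c_ids = [c for _, c in result.pairs]
    rows = []
    for name, vt in table.covariate_types.items():
        if vt == "categorical":
            def maxdiff(a: pd.Series, b: pd.Series) -> float:
                pa = a.value_counts(normalize=True)
                pb = b.value_counts(normalize=True)
                lv = pa.index.union(pb.index)
                return float((pa.reindex(lv, fill_value=0)
                              - pb.reindex(lv, fill_value=0)).abs().max())
            before = maxdiff(treated_all[name], control_all[name])
            after = maxdiff(df.loc[t_ids, name], df.loc[c_ids, name])
            metric = "max_prop_diff"
        else:
            before = _smd(treated_all[name].to_numpy(dtype=float),
                          control_all[name].to_numpy(dtype=float))
            after = _smd(df.loc[t_ids, name].to_numpy(dtype=float),
                         df.loc[c_ids, name].to_numpy(dtype=float))
            metric = "smd"
        rows.append({"covariate": name, "metric": metric,
                     "before": before, "after": after})
    return pd.DataFrame(rows)
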