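"""End-to-end lifespan analysis: filter, score, (match), fit, compare.

``run_pipeline`` chains the exclusion cascade, composite scoring,
optional propensity matching, the demographic battery, per-sex/per-domain
segmented fits with BIC breakpoint selection and Davies' test, and
bootstrapped between-sex differences of the trajectory parameters
(peak age, peak score, increasing and decreasing slope).  Differences are
summarised by percentile bootstrap confidence intervals (2.5% / 97.5%
quantiles); an interval excluding zero is read as a significant
difference — no p-values are computed for these comparisons.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import (
    DOMAINS,
    SEX_LEVELS,
    CohortTable,
    filter_age,
    filter_complete,
    filter_outliers_two_pass,
    read_cohort,
)
from .composites import DEFAULT_WEIGHTS, WeightMatrix, compute_domain_scores, \
    zscore_tests
from .demographics import compare_demographics, comparisons_to_frame
from .matching import estimate_propensity, nearest_neighbor_match
from .segmented import (
    PeakEstimate,
    SegmentedFit,
    SlopeSummary,
    davies_test,
    fit_segmented,
    peak_from_fit,
    select_n_breakpoints,
    side_slope,
)

__all__ = [
    "AnalysisConfig",
    "ComparisonResult",
    "SexFit",
    "fit_by_sex",
    "bootstrap_differences",
    "run_pipeline",
    "load_analysis_config",
]

PARAMETERS = ("peak_age", "peak_score", "increasing_slope", "decreasing_slope")


@dataclass
class AnalysisConfig:
    """Configuration of one matched or unmatched analysis run."""

    mode: str = "unmatched"
    n_bootstrap: int = 10000
    max_breakpoints: int = 3
    subsample_male_n: int | None = None
    seed: int = 0
    weights: WeightMatrix | None = None
    type_map: dict[str, str] | None = None
    match_covariates: list[str] | None = None
    reselect_breakpoints: bool = False  # re-run BIC selection per replicate

    def __post_init__(self) -> None:
        if self.mode not in ("matched", "unmatched"):
            raise ValueError("mode must be 'matched' or 'unmatched'")
        if self.n_bootstrap < 1:
            raise ValueError("n_bootstrap must be >= 1")

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "n_bootstrap": self.n_bootstrap,
            "max_breakpoints": self.max_breakpoints,
            "subsample_male_n": self.subsample_male_n,
            "seed": self.seed,
            "reselect_breakpoints": self.reselect_breakpoints,
        }


def load_analysis_config(path: str | Path) -> AnalysisConfig:
    """Read an :class:`AnalysisConfig` from a YAML key-value file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return AnalysisConfig(
        mode=raw.get("mode", "unmatched"),
        n_bootstrap=int(raw.get("n_bootstrap", 10000)),
        max_breakpoints=int(raw.get("max_breakpoints", 3)),
        subsample_male_n=raw.get("subsample_male_n"),
        seed=int(raw.get("seed", 0)),
        reselect_breakpoints=bool(raw.get("reselect_breakpoints", False)),
    )


@dataclass
class SexFit:
    """Everything estimated for one domain in one sex."""

    fit: SegmentedFit
    davies_statistic: float
    davies_p: float
    peak: PeakEstimate
    increasing: SlopeSummary
    decreasing: SlopeSummary

    def parameters(self) -> dict[str, float]:
        return _parameters(self.fit, self.peak, self.increasing,
                           self.decreasing)

    def to_dict(self) -> dict:
        return {
            "fit": self.fit.to_dict(),
            "davies": {"statistic": float(self.davies_statistic),
                       "p": float(self.davies_p)},
            "peak": {
                "peak_age": float(self.peak.peak_age),
                "peak_score": float(self.peak.peak_score),
                "at_boundary": bool(self.peak.at_boundary),
                "which_breakpoint": self.peak.which_breakpoint,
            },
            "slopes": {
                s.side: {
                    "value": None if not s.defined else float(s.value),
                    "ci": list(s.ci) if s.ci else None,
                    "combined": bool(s.combined),
                    "defined": bool(s.defined),
                }
                for s in (self.increasing, self.decreasing)
            },
        }


def _parameters(fit, peak, inc, dec) -> dict[str, float]:
    return {
        "peak_age": float(peak.peak_age),
        "peak_score": float(peak.peak_score),
        "increasing_slope": float(inc.value) if inc.defined else np.nan,
        "decreasing_slope": float(dec.value) if dec.defined else np.nan,
    }


@dataclass
class ComparisonResult:
    """Bootstrapped between-sex difference in one trajectory parameter."""

    domain: str
    parameter: str
    value_women: float
    value_men: float
    point_difference: float  # women - men
    ci: tuple[float, float] | None
    significant: bool | None
    n_bootstrap: int
    n_failed: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "domain": self.domain,
            "parameter": self.parameter,
            "value_women": _num(self.value_women),
            "value_men": _num(self.value_men),
            "point_difference": _num(self.point_difference),
            "ci": None if self.ci is None else [_num(self.ci[0]),
                                                _num(self.ci[1])],
            "significant": self.significant,
            "n_bootstrap": self.n_bootstrap,
            "n_failed": self.n_failed,
            "seed": self.seed,
        }


def _num(v):
    v = float(v)
    return None if np.isnan(v) else v


def _analyse_one(x: np.ndarray, y: np.ndarray, max_breakpoints: int) -> SexFit:
    fit, _ = select_n_breakpoints(x, y, max_breakpoints)
    stat, p = davies_test(x, y)
    peak = peak_from_fit(fit)
    inc = side_slope(fit, peak, "left")
    dec = side_slope(fit, peak, "right")
    return SexFit(fit, stat, p, peak, inc, dec)


def fit_by_sex(
    table: CohortTable,
    scores: pd.DataFrame,
    config: AnalysisConfig,
    domains: tuple[str, ...] = DOMAINS,
) -> dict[str, dict[str, SexFit]]:
    """Model each domain score on age, separately per sex (3 x 2 fits)."""
    out: dict[str, dict[str, SexFit]] = {}
    sex = table.data["sex"].to_numpy()
    age = table.data["age"].to_numpy(dtype=float)
    for domain in domains:
        y_all = scores[domain].to_numpy(dtype=float)
        out[domain] = {}
        for s in SEX_LEVELS:
            mask = sex == s
            try:
                out[domain][s] = _analyse_one(
                    age[mask], y_all[mask], config.max_breakpoints
                )
            except Exception as exc:
                raise RuntimeError(
                    f"segmented analysis failed for domain={domain!r} "
                    f"sex={s!r}: {exc}"
                ) from exc
    return out


def _refit_parameters(
    x: np.ndarray, y: np.ndarray, n_breakpoints: int,
    init: np.ndarray | None,
) -> dict[str, float]:
    fit = fit_segmented(x, y, n_breakpoints,
                        init=init if n_breakpoints else None)
    peak = peak_from_fit(fit)
    inc = side_slope(fit, peak, "left")
    dec = side_slope(fit, peak, "right")
    return _parameters(fit, peak, inc, dec)


def bootstrap_differences(
    table: CohortTable,
    scores: pd.DataFrame,
    config: AnalysisConfig,
    fits: dict[str, dict[str, SexFit]] | None = None,
    domains: tuple[str, ...] = DOMAINS,
) -> list[ComparisonResult]:
    """Percentile-bootstrap CIs for women-minus-men parameter differences.

    Each replicate resamples participants with replacement within sex and
    refits both sexes with the full-sample breakpoint count held fixed
    (initialised at the full-sample breakpoint ages).  In unmatched mode
    with ``subsample_male_n`` set, the male resample is instead a random
    subsample of that size drawn without replacement, equalising the
    effective sample sizes.  Replicate seeds are derived counter-style
    from the master seed, so results do not depend on execution order.
    Failed refits are dropped and counted (> 5% failures: warning flag;
    > 50%: error).
    """
    if fits is None:
        fits = fit_by_sex(table, scores, config, domains)
    sex = table.data["sex"].to_numpy()
    age = table.data["age"].to_numpy(dtype=float)
    idx = {s: np.flatnonzero(sex == s) for s in SEX_LEVELS}
    B = config.n_bootstrap
    results: list[ComparisonResult] = []

    for domain in domains:
        di = DOMAINS.index(domain)
        y = scores[domain].to_numpy(dtype=float)
        full = {s: fits[domain][s] for s in SEX_LEVELS}
        diffs = {p: np.full(B, np.nan) for p in PARAMETERS}
        n_failed = 0
        for b in range(B):
            rng = np.random.default_rng([config.seed, di, b])
            try:
                reps: dict[str, dict[str, float]] = {}
                for s in SEX_LEVELS:
                    pool = idx[s]
                    if (s == "male" and config.subsample_male_n
                            and config.subsample_male_n < pool.size):
                        take = rng.choice(pool, size=config.subsample_male_n,
                                          replace=False)
                    else:
                        take = rng.choice(pool, size=pool.size, replace=True)
                    if config.reselect_breakpoints:
                        f, _ = select_n_breakpoints(
                            age[take], y[take], config.max_breakpoints)
                        peak = peak_from_fit(f)
                        reps[s] = _parameters(
                            f, peak, side_slope(f, peak, "left"),
                            side_slope(f, peak, "right"))
                    else:
                        reps[s] = _refit_parameters(
                            age[take], y[take],
                            full[s].fit.n_breakpoints,
                            full[s].fit.psi if full[s].fit.n_breakpoints
                            else None,
                        )
                for p in PARAMETERS:
                    diffs[p][b] = reps["female"][p] - reps["male"][p]
            except Exception:
                n_failed += 1

        if n_failed > 0.5 * B:
            raise RuntimeError(
                f"{n_failed}/{B} bootstrap replicates failed for {domain!r}"
            )
        if n_failed > 0.05 * B:
            warnings.warn(
                f"{n_failed}/{B} bootstrap replicates failed for {domain!r}",
                UserWarning, stacklevel=2,
            )
        pw = full["female"].parameters()
        pm = full["male"].parameters()
        for p in PARAMETERS:
            d = diffs[p][~np.isnan(diffs[p])]
            defined = np.isfinite(pw[p]) and np.isfinite(pm[p]) and d.size > 0
            if defined:
                lo, hi = np.percentile(d, [2.5, 97.5])
                ci = (float(lo), float(hi))
                sig = bool(not (lo <= 0.0 <= hi))
                point = pw[p] - pm[p]
            else:
                ci, sig, point = None, None, np.nan
            results.append(ComparisonResult(
                domain=domain, parameter=p,
                value_women=pw[p], value_men=pm[p],
                point_difference=point, ci=ci, significant=sig,
                n_bootstrap=B, n_failed=n_failed, seed=config.seed,
            ))
    return results


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_pipeline(
    source: str | Path | CohortTable,
    config: AnalysisConfig,
    out_dir: str | Path | None = None,
) -> dict:
    """Run the full cascade and return (and optionally write) the reports.

    Stages: read -> completeness filter -> two-pass outlier screen -> age
    window -> [matched mode: propensity matching, keeping matched pairs]
    -> z-score + domain scores -> demographic battery -> per-sex segmented
    fits -> bootstrap comparisons.  Scoring happens on the sample being
    analysed, after matching when applicable.
    """
    table = source if isinstance(source, CohortTable) else read_cohort(source)
    stage_log: list[dict] = []
    reports = []

    table, rep = filter_complete(table)
    reports.append(rep)
    table, rep = filter_outliers_two_pass(table)
    reports.append(rep)
    table, rep = filter_age(table)
    reports.append(rep)
    for r in reports:
        stage_log.append(r.to_dict())

    bundle: dict = {
        "config": config.to_dict(),
        "filter_reports": stage_log,
    }

    demographics_pre = compare_demographics(table, config.type_map)
    bundle["demographics"] = [r.to_dict() for r in demographics_pre]

    if config.mode == "matched":
        model = estimate_propensity(table, config.match_covariates)
        match = nearest_neighbor_match(model, table)
        keep = set(match.matched_ids())
        table = table.subset(table.data["participant_id"].isin(keep))
        bundle["matching"] = {
            "treatment_sex": match.treatment_sex,
            "n_pairs": len(match.pairs),
            "n_unmatched_treated": len(match.unmatched_treated),
            "balance": match.balance.to_dict(orient="records"),
        }
        post = compare_demographics(table, config.type_map)
        bundle["demographics_post_match"] = [r.to_dict() for r in post]

    weights = config.weights or DEFAULT_WEIGHTS
    X = zscore_tests(table)
    scores = compute_domain_scores(X, weights)

    fits = fit_by_sex(table, scores, config)
    bundle["fits"] = {
        d: {s: fits[d][s].to_dict() for s in SEX_LEVELS} for d in DOMAINS
    }
    comparisons = bootstrap_differences(table, scores, config, fits=fits)
    bundle["comparisons"] = [c.to_dict() for c in comparisons]
    bundle["n_analyzed"] = {
        s: int((table.data["sex"] == s).sum()) for s in SEX_LEVELS
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        _write_json(bundle["config"], out / "config.json")
        _write_json(stage_log, out / "filter_reports.json")
        _write_json(bundle["demographics"], out / "demographics.json")
        comparisons_to_frame(demographics_pre).to_csv(
            out / "demographics.csv", index=False)
        _write_json(bundle["fits"], out / "fits.json")
        _write_json(bundle["comparisons"], out / "comparisons.json")
        pd.DataFrame([c.to_dict() for c in comparisons]).to_csv(
            out / "comparisons.csv", index=False)
        _write_json({"n_analyzed": bundle["n_analyzed"]}, out / "summary.json")
    return bundle
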