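"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator draws, per participant, an age (uniform on the study window
by default), evaluates three latent piecewise-linear domain trajectories
(working memory, verbal, reasoning; sex-specific), mixes them through a
12 x 3 weight matrix into 12 test-score means, and adds independent
Gaussian noise per test.  Questionnaire covariates are drawn with
controllable standardised sex effects: Cohen's d for continuous variables,
a rank-shift r for ordinal variables (generated by thresholding a shifted
latent normal) and Cramer's V for categorical variables (generated by
exponential tilting of the level probabilities).  Extreme score outliers
and participant-level missingness can be injected at configurable rates.

Defaults reproduce the study conditions: ages 12-69, sex-specific domain
trajectories matching the matched-sample estimates (e.g. working memory
rising at ~0.04 SD/year to a peak near age 20 then declining at ~0.02
SD/year), residual SD 1 per test, and covariate sex effects of d = 0.10
(sleep), d = -0.19 (caffeine), r = 0.15 (anxiety) and V = 0.24 (tech
savviness), with null effects on education and exercise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, stats

from .cohort import DEFAULT_COVARIATE_TYPES, DOMAINS, SEX_LEVELS, CohortTable
from .composites import DEFAULT_WEIGHTS, WeightMatrix

__all__ = [
    "TrajectorySpec",
    "CovariateSpec",
    "SyntheticConfig",
    "trajectory_value",
    "generate_cohort",
    "inject_outliers",
    "default_trajectories",
    "default_covariates",
    "default_config",
    "load_config",
]


@dataclass(frozen=True)
class TrajectorySpec:
    """Ground-truth piecewise-linear mean trajectory of a domain score.

    ``intercept`` is the score at the left end of ``age_range``;
    ``slopes`` has one entry per segment (``len(breakpoints) + 1``).  The
    implied mean function is continuous.
    """

    intercept: float
    breakpoints: tuple[float, ...]
    slopes: tuple[float, ...]
    age_range: tuple[float, float] = (12.0, 69.0)

    def __post_init__(self) -> None:
        bp = np.asarray(self.breakpoints, dtype=float)
        lo, hi = self.age_range
        if not lo < hi:
            raise ValueError("age_range must be increasing")
        if len(self.slopes) != len(bp) + 1:
            raise ValueError("need len(breakpoints) + 1 slopes")
        if bp.size and (np.any(np.diff(bp) <= 0) or bp[0] <= lo or bp[-1] >= hi):
            raise ValueError(
                "breakpoints must be strictly increasing and inside age_range"
            )

    def value(self, age):
        return trajectory_value(self, age)


def trajectory_value(spec: TrajectorySpec, age):
    """Evaluate the trajectory mean at ``age`` (scalar or array).

    Raises a domain error for ages outside ``spec.age_range``.
    """
    a = np.asarray(age, dtype=float)
    lo, hi = spec.age_range
    if np.any(a < lo) or np.any(a > hi):
        raise ValueError(f"age outside trajectory range [{lo}, {hi}]")
    out = spec.intercept + spec.slopes[0] * (a - lo)
    for bp, ds in zip(spec.breakpoints,
                      np.diff(np.asarray(spec.slopes, dtype=float))):
        out = out + ds * np.maximum(a - bp, 0.0)
    return float(out) if np.isscalar(age) else out


@dataclass(frozen=True)
class CovariateSpec:
    """One questionnaire covariate and its standardised sex effect.

    ``sex_effect`` is signed women-minus-men: Cohen's d (continuous),
    asymptotic Wilcoxon rank-shift r (ordinal) or Cramer's V
    (categorical; V is non-negative, women tilted toward higher levels
    for positive values).  ``sex_effect = 0`` yields identical marginal
    distributions for both sexes.
    """

    name: str
    var_type: str
    sex_effect: float = 0.0
    levels: tuple[str, ...] = ()
    probabilities: tuple[float, ...] = ()
    mean: float = 0.0
    sd: float = 1.0

    def __post_init__(self) -> None:
        if self.var_type not in ("continuous", "ordinal", "categorical"):
            raise ValueError(f"unknown var_type {self.var_type!r}")
        if self.var_type in ("ordinal", "categorical"):
            if not self.levels:
                raise ValueError(f"{self.name}: levels must be non-empty")
            p = np.asarray(self.probabilities, dtype=float)
            if p.size != len(self.levels):
                raise ValueError(f"{self.name}: one probability per level")
            if abs(p.sum() - 1.0) > 1e-12:
                raise ValueError(f"{self.name}: probabilities must sum to 1")
        elif self.sd <= 0:
            raise ValueError(f"{self.name}: sd must be positive")


def _ordinal_latent_shift(probs: np.ndarray, r: float) -> float:
    """Latent-normal mean shift giving asymptotic rank-shift r.

    Categories come from thresholding N(mu, 1) at the base quantile cuts;
    the two sexes get means +/- delta/2.  For equal group sizes the
    large-sample Wilcoxon effect size is r = (theta - 1/2) * sqrt(3/tf),
    with theta = P(W > M) + P(W = M)/2 and tie factor
    tf = 1 - sum(pooled_prob^3); delta solves this for the target r.
    """
    if r == 0:
        return 0.0
    cuts = stats.norm.ppf(np.cumsum(probs)[:-1])

    def cat_probs(mu: float) -> np.ndarray:
        cdf = np.concatenate([[0.0], stats.norm.cdf(cuts - mu), [1.0]])
        return np.diff(cdf)

    def asymptotic_r(delta: float) -> float:
        pw = cat_probs(delta / 2.0)   # women: latent mean +delta/2
        pm = cat_probs(-delta / 2.0)
        cum_m = np.concatenate([[0.0], np.cumsum(pm)[:-1]])
        theta = float(np.sum(pw * (cum_m + 0.5 * pm)))
        pooled = (pw + pm) / 2.0
        tf = 1.0 - float(np.sum(pooled**3))
        return (theta - 0.5) * np.sqrt(3.0 / tf)

    target = abs(r)
    delta = optimize.brentq(lambda d: asymptotic_r(d) - target, 0.0, 12.0,
                            xtol=1e-10)
    return float(np.sign(r) * delta)


def _categorical_tilt(probs: np.ndarray, v: float) -> float:
    """Exponential-tilt strength giving population Cramer's V = v.

    Sexes get level probabilities proportional to ``p * exp(+/- t*u/2)``
    with centred level scores u; for a 2 x L table with equal sexes,
    V^2 = sum_j (pw_j - pm_j)^2 / (4 * pooled_j).
    """
    if v == 0:
        return 0.0
    if not 0 <= v < 1:
        raise ValueError("Cramer's V effect must be in [0, 1)")
    u = np.arange(len(probs), dtype=float)
    u -= u.mean()

    def pop_v(t: float) -> float:
        pw = probs * np.exp(u * t / 2.0)
        pw /= pw.sum()
        pm = probs * np.exp(-u * t / 2.0)
        pm /= pm.sum()
        pooled = (pw + pm) / 2.0
        return float(np.sqrt(np.sum((pw - pm) ** 2 / (4.0 * pooled))))

    return float(optimize.brentq(lambda t: pop_v(t) - abs(v), 0.0, 50.0,
                                 xtol=1e-10) * np.sign(v))


@dataclass
class SyntheticConfig:
    """Full recipe for one synthetic cohort."""

    n_per_sex: dict[str, int]
    trajectories: dict[str, dict[str, TrajectorySpec]]
    weights: WeightMatrix
    noise_sd: float = 1.0
    covariates: tuple[CovariateSpec, ...] = ()
    outlier_rate: float = 0.0
    outlier_magnitude_sd: float = 7.0
    missing_rate: float = 0.0
    age_range: tuple[float, float] = (12.0, 69.0)
    age_dist: str = "study"  # "study" (truncated normal) or "uniform"
    seed: int = 0

    def __post_init__(self) -> None:
        for rate, label in ((self.outlier_rate, "outlier_rate"),
                            (self.missing_rate, "missing_rate")):
            if not 0 <= rate <= 1:
                raise ValueError(f"{label} must be in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        for sex in SEX_LEVELS:
            if self.n_per_sex.get(sex, 0) < 1:
                raise ValueError(f"n_per_sex[{sex!r}] must be >= 1")
        for d in DOMAINS:
            for sex in SEX_LEVELS:
                if not isinstance(self.trajectories[d][sex], TrajectorySpec):
                    raise TypeError("trajectories must hold TrajectorySpec")

    @property
    def covariate_types(self) -> dict[str, str]:
        return {c.name: c.var_type for c in self.covariates}


def default_trajectories() -> dict[str, dict[str, TrajectorySpec]]:
    """Sex-specific domain trajectories used as the generator's truth.

    Working memory peaks near age 20 for both sexes; verbal ability rises
    steeply in adolescence, more slowly to a peak in the mid/late twenties,
    then declines gently; reasoning declines from the start of the window
    in women (gradual then steeper after the late thirties) and plateaus
    to about age 20 before declining in men.
    """
    return {
        "wm": {
            "female": TrajectorySpec(-0.25712, (20.42,), (0.036, -0.023)),
            "male": TrajectorySpec(-0.11585, (19.65,), (0.049, -0.025)),
        },
        "verbal": {
            "female": TrajectorySpec(-0.80077, (16.49, 24.89),
                                     (0.153, 0.022, -0.006)),
            "male": TrajectorySpec(-0.81826, (17.16, 28.42),
                                   (0.146, 0.015, -0.008)),
        },
        "reasoning": {
            "female": TrajectorySpec(0.223, (38.12,), (-0.014, -0.029)),
            "male": TrajectorySpec(0.01670, (19.62,), (0.015, -0.025)),
        },
    }


def default_covariates() -> tuple[CovariateSpec, ...]:
    """Covariate battery with the study's largest reported sex effects."""
    return (
        CovariateSpec("sleep_hours", "continuous", sex_effect=0.10,
                      mean=7.0, sd=1.6),
        CovariateSpec("caffeine_units", "continuous", sex_effect=-0.19,
                      mean=3.5, sd=4.8),
        CovariateSpec(
            "anxiety", "ordinal", sex_effect=0.15,
            levels=("never", "occasionally", "quite_often",
                    "nearly_every_day", "all_the_time"),
            probabilities=(0.142, 0.509, 0.203, 0.101, 0.045),
        ),
        CovariateSpec(
            "education", "ordinal", sex_effect=0.0,
            levels=("some_high_school", "high_school", "some_post_secondary",
                    "post_secondary_degree", "professional_degree"),
            probabilities=(0.10, 0.085, 0.28, 0.275, 0.26),
        ),
        CovariateSpec(
            "exercise", "ordinal", sex_effect=0.0,
            levels=("never", "infrequently", "weekly",
                    "several_times_a_week", "every_day"),
            probabilities=(0.105, 0.365, 0.198, 0.262, 0.07),
        ),
        CovariateSpec(
            "tech_savvy", "categorical", sex_effect=0.24,
            levels=("no", "yes"), probabilities=(0.23, 0.77),
        ),
    )


def default_config(
    n_per_sex: int | dict[str, int] = 13444,
    seed: int = 0,
    *,
    noise_sd: float = 1.0,
    outlier_rate: float = 0.0,
    missing_rate: float = 0.0,
) -> SyntheticConfig:
    """The study-condition configuration (13,444 per sex, noise SD 1)."""
    if isinstance(n_per_sex, int):
        n_per_sex = {"female": n_per_sex, "male": n_per_sex}
    return SyntheticConfig(
        n_per_sex=dict(n_per_sex),
        trajectories=default_trajectories(),
        weights=DEFAULT_WEIGHTS,
        noise_sd=noise_sd,
        covariates=default_covariates(),
        outlier_rate=outlier_rate,
        missing_rate=missing_rate,
        seed=seed,
    )


# Truncated-normal age density calibrated so that ages on [12, 69] have
# mean 28.2 years and SD 10.8 years, the moments of the study cohort; the
# online sample skews young.
_AGE_TRUNCNORM_LOC = 21.6495476
_AGE_TRUNCNORM_SCALE = 15.0333568


def _draw_ages(config: SyntheticConfig, n: int,
               rng: np.random.Generator) -> np.ndarray:
    lo, hi = config.age_range
    if config.age_dist == "uniform":
        return rng.uniform(lo, hi, size=n)
    if config.age_dist != "study":
        raise ValueError(f"unknown age_dist {config.age_dist!r}")
    a = (lo - _AGE_TRUNCNORM_LOC) / _AGE_TRUNCNORM_SCALE
    b = (hi - _AGE_TRUNCNORM_LOC) / _AGE_TRUNCNORM_SCALE
    return stats.truncnorm.rvs(
        a, b, loc=_AGE_TRUNCNORM_LOC, scale=_AGE_TRUNCNORM_SCALE,
        size=n, random_state=rng,
    )


def _draw_covariate(
    spec: CovariateSpec, sex: str, n: int, rng: np.random.Generator
):
    sign = 1.0 if sex == "female" else -1.0
    if spec.var_type == "continuous":
        mu = spec.mean + sign * spec.sex_effect * spec.sd / 2.0
        return rng.normal(mu, spec.sd, size=n)
    probs = np.asarray(spec.probabilities, dtype=float)
    if spec.var_type == "ordinal":
        delta = _ordinal_latent_shift(probs, spec.sex_effect)
        cuts = stats.norm.ppf(np.cumsum(probs)[:-1])
        z = rng.normal(sign * delta / 2.0, 1.0, size=n)
        return np.searchsorted(cuts, z).astype(np.int64)
    t = _categorical_tilt(probs, spec.sex_effect)
    u = np.arange(len(probs), dtype=float)
    u -= u.mean()
    p = probs * np.exp(sign * u * t / 2.0)
    p /= p.sum()
    return rng.choice(np.asarray(spec.levels, dtype=object), size=n, p=p)


def generate_cohort(config: SyntheticConfig) -> CohortTable:
    """Generate a cohort table from the configuration; deterministic in the seed."""
    rng = np.random.default_rng([config.seed, 0])
    frames = []
    offset = 0
    Ar = config.weights.values  # 12 x 3
    test_names = list(config.weights.entries.index)
    lo, hi = config.age_range
    for sex in SEX_LEVELS:
        n = config.n_per_sex[sex]
        ages = _draw_ages(config, n, rng)
        domain_vals = np.column_stack([
            trajectory_value(config.trajectories[d][sex], ages)
            for d in DOMAINS
        ])  # n x 3
        means = domain_vals @ Ar.T  # n x 12
        tests = means + rng.normal(0.0, config.noise_sd, size=means.shape)
        df = pd.DataFrame(tests, columns=test_names)
        df.insert(0, "sex", sex)
        df.insert(0, "age", ages)
        df.insert(0, "participant_id",
                  [f"P{offset + i:06d}" for i in range(n)])
        for cov in config.covariates:
            df[cov.name] = _draw_covariate(cov, sex, n, rng)
        frames.append(df)
        offset += n
    data = pd.concat(frames, ignore_index=True)
    table = CohortTable(data, covariate_types=config.covariate_types)

    if config.outlier_rate > 0:
        table, _ = inject_outliers(
            table, config.outlier_rate, config.outlier_magnitude_sd,
            seed_key=(config.seed, 1),
        )
    if config.missing_rate > 0:
        table = _inject_missing(table, config.missing_rate, (config.seed, 2))
    return table


def _inject_missing(
    table: CohortTable, rate: float, seed_key: tuple[int, int]
) -> CohortTable:
    """Blank one random test or questionnaire item for a fraction of rows."""
    rng = np.random.default_rng(list(seed_key))
    df = table.data.copy()
    cols = [*table.test_columns, *table.covariate_columns]
    hit = rng.random(len(df)) < rate
    which = rng.integers(0, len(cols), size=len(df))
    for i in np.flatnonzero(hit):
        col = cols[which[i]]
        if df[col].dtype.kind in "iu":
            df[col] = df[col].astype(float)
        df.loc[df.index[i], col] = np.nan
    return CohortTable(df, covariate_types=dict(table.covariate_types),
                       test_columns=table.test_columns)


def inject_outliers(
    table: CohortTable,
    rate: float,
    magnitude_sd: float = 7.0,
    seed: int | None = None,
    seed_key: tuple[int, int] | None = None,
) -> tuple[CohortTable, list[tuple[str, str]]]:
    """Replace a fraction of test-score cells with extreme values.

    ``round(rate * n_cells)`` cells, drawn uniformly without replacement
    over the N x 12 score block, are set to the column mean plus or minus
    ``magnitude_sd`` column SDs (random sign).  Returns the modified copy
    and the altered cells as ``(participant_id, test)`` pairs.

    ``magnitude_sd`` must exceed 4 so injected cells are outside the
    outlier screen's tighter pass.
    """
    if not 0 <= rate <= 1:
        raise ValueError("rate must be in [0, 1]")
    if magnitude_sd <= 4:
        raise ValueError("magnitude_sd must exceed 4 SDs")
    rng = np.random.default_rng(list(seed_key) if seed_key is not None
                                else seed)
    df = table.data.copy()
    tests = list(table.test_columns)
    n_cells = len(df) * len(tests)
    n_alter = int(round(rate * n_cells))
    altered: list[tuple[str, str]] = []
    if n_alter:
        flat = rng.choice(n_cells, size=n_alter, replace=False)
        signs = rng.choice([-1.0, 1.0], size=n_alter)
        rows, cols = np.divmod(flat, len(tests))
        col_mean = {c: df[c].mean() for c in tests}
        col_sd = {c: df[c].std(ddof=1) for c in tests}
        for r, c, s in zip(rows, cols, signs):
            col = tests[c]
            df.loc[df.index[r], col] = col_mean[col] + s * magnitude_sd * col_sd[col]
            altered.append((df["participant_id"].iloc[r], col))
    out = CohortTable(df, covariate_types=dict(table.covariate_types),
                      test_columns=table.test_columns)
    return out, altered


def load_config(path: str | Path) -> SyntheticConfig:
    """Build a :class:`SyntheticConfig` from a YAML key-value file.

    Recognised keys: ``n_per_sex`` (int or per-sex map), ``seed``,
    ``noise_sd``, ``outlier_rate``, ``missing_rate``.  Trajectories,
    weights and covariates use the package defaults; supply them in code
    for full control.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return default_config(
        n_per_sex=raw.get("n_per_sex", 13444),
        seed=int(raw.get("seed", 0)),
        noise_sd=float(raw.get("noise_sd", 1.0)),
        outlier_rate=float(raw.get("outlier_rate", 0.0)),
        missing_rate=float(raw.get("missing_rate", 0.0)),
    )
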