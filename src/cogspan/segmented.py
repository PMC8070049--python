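"""Broken-line (segmented) regression of a score on age.

Fits piecewise-linear mean functions with continuity at estimated
breakpoints using the iterative-linearisation scheme of Muggeo: at the
current breakpoint guesses ``psi`` the model

    y = a + b*x + sum_k beta_k * (x - psi_k)_+ + gamma_k * (-1{x > psi_k})

is linear in its coefficients; the reparameterisation term ``gamma_k``
measures the gap left by a wrong ``psi_k`` and drives the update
``psi_k <- psi_k + gamma_k / beta_k``.  At convergence ``gamma ~ 0`` and the
fitted mean is continuous.  The number of breakpoints is chosen by BIC, and
Davies' bound tests for the existence of any slope change.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "SegmentedFit",
    "PeakEstimate",
    "SlopeSummary",
    "fit_segmented",
    "select_n_breakpoints",
    "davies_test",
    "peak_from_fit",
    "side_slope",
    "predict",
    "BreakpointCollisionWarning",
    "ConvergenceWarning",
]

_Z95 = 1.959963984540054


class BreakpointCollisionWarning(UserWarning):
    """Two breakpoint estimates collided; the model was refit with fewer."""


class ConvergenceWarning(UserWarning):
    """Breakpoint iteration did not converge within the iteration cap."""


@dataclass
class SegmentedFit:
    """A fitted broken-line model of score on age.

    Attributes
    ----------
    n_breakpoints : int
        Number of breakpoints in the fitted model (0 = ordinary line).
    psi, psi_se : ndarray
        Breakpoint ages (strictly increasing) and delta-method standard
        errors.
    intercept : float
        Intercept of the leftmost segment extrapolated to x = 0.
    segment_slopes, slope_se : ndarray
        Per-segment slopes, left to right, with standard errors.
    slope_ci : ndarray, shape (n_segments, 2)
        95% Wald confidence intervals for the segment slopes.
    slope_changes : ndarray
        ``segment_slopes[k+1] - segment_slopes[k]`` for each breakpoint;
        the "change in age coefficient after the breakpoint".
    """

    n_breakpoints: int
    psi: np.ndarray
    psi_se: np.ndarray
    intercept: float
    segment_slopes: np.ndarray
    slope_se: np.ndarray
    slope_ci: np.ndarray
    slope_changes: np.ndarray
    resid_var: float
    loglik: float
    bic: float
    n: int
    converged: bool
    n_iter: int
    x_range: tuple[float, float]
    requested_breakpoints: int = 0
    # t statistic and SE of the base (leftmost) slope, for report tables
    base_slope_t: float = field(default=np.nan)

    def to_dict(self) -> dict:
        return {
            "n_breakpoints": int(self.n_breakpoints),
            "psi": [float(v) for v in self.psi],
            "psi_se": [float(v) for v in self.psi_se],
            "intercept": float(self.intercept),
            "segment_slopes": [float(v) for v in self.segment_slopes],
            "slope_se": [float(v) for v in self.slope_se],
            "slope_ci": [[float(a), float(b)] for a, b in self.slope_ci],
            "slope_changes": [float(v) for v in self.slope_changes],
            "resid_var": float(self.resid_var),
            "loglik": float(self.loglik),
            "bic": float(self.bic),
            "n": int(self.n),
            "converged": bool(self.converged),
            "n_iter": int(self.n_iter),
            "x_range": [float(self.x_range[0]), float(self.x_range[1])],
        }


@dataclass
class PeakEstimate:
    """Age of maximal fitted score and the fitted score there."""

    peak_age: float
    peak_score: float
    at_boundary: bool
    which_breakpoint: int | None


@dataclass
class SlopeSummary:
    """Summary slope on one side of the peak.

    ``combined`` is set when two or more segments flank the peak on that
    side and the value is their length-weighted average (equivalently the
    chord slope of the fitted line across the side).  ``defined`` is False
    when the peak sits at the range boundary and no segment exists on the
    requested side.
    """

    side: str
    value: float
    ci: tuple[float, float] | None
    combined: bool
    defined: bool = True
    n_segments: int = 0


def _design(x: np.ndarray, psi: np.ndarray, with_gap: bool) -> np.ndarray:
    cols = [np.ones_like(x), x]
    for p in psi:
        cols.append(np.maximum(x - p, 0.0))
    if with_gap:
        for p in psi:
            cols.append(-(x > p).astype(float))
    return np.column_stack(cols)


def _validate_xy(x, y, n_breakpoints) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    if not np.all(np.isfinite(x)) or not np.all(np.isfinite(y)):
        raise ValueError("x and y must be finite")
    if x.size < 10 + 3 * n_breakpoints:
        raise ValueError(
            f"need at least {10 + 3 * n_breakpoints} observations for "
            f"{n_breakpoints} breakpoint(s), got {x.size}"
        )
    if np.ptp(x) <= 0:
        raise ValueError("x must span a positive range")
    return x, y


def _linear_fit(x: np.ndarray, y: np.ndarray) -> SegmentedFit:
    n = x.size
    X = np.column_stack([np.ones_like(x), x])
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    rss = float(resid @ resid)
    dof = n - 2
    sigma2 = rss / dof if dof > 0 else np.nan
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se_b = float(np.sqrt(cov[1, 1]))
    ll = _gauss_loglik(rss, n)
    p = 3  # intercept, slope, error variance
    slope = float(coef[1])
    return SegmentedFit(
        n_breakpoints=0,
        psi=np.empty(0),
        psi_se=np.empty(0),
        intercept=float(coef[0]),
        segment_slopes=np.array([slope]),
        slope_se=np.array([se_b]),
        slope_ci=np.array([[slope - _Z95 * se_b, slope + _Z95 * se_b]]),
        slope_changes=np.empty(0),
        resid_var=rss / n,
        loglik=ll,
        bic=-2.0 * ll + p * np.log(n),
        n=n,
        converged=True,
        n_iter=0,
        x_range=(float(x.min()), float(x.max())),
        requested_breakpoints=0,
        base_slope_t=slope / se_b if se_b > 0 else np.nan,
    )


def _gauss_loglik(rss: float, n: int) -> float:
    sigma2 = max(rss / n, 1e-300)
    return -0.5 * n * (np.log(2.0 * np.pi * sigma2) + 1.0)


def _coarse_init(
    x: np.ndarray, y: np.ndarray, K: int, lo: float, hi: float, min_sep: float
) -> np.ndarray:
    """Best breakpoint start by coarse profile least squares.

    Evaluates the profile RSS at every admissible K-combination of a
    quantile grid and returns the minimiser; the iterative refinement then
    starts inside the right basin of attraction rather than at arbitrary
    quantiles (the update is only locally convergent).
    """
    from itertools import combinations

    n_grid = {1: 30, 2: 14}.get(K, 12)
    grid = np.unique(np.quantile(x, np.linspace(0.06, 0.94, n_grid)))
    grid = grid[(grid >= lo) & (grid <= hi)]
    if grid.size < K:
        return np.quantile(x, (np.arange(K) + 1.0) / (K + 1.0))
    best_rss, best = np.inf, None
    ones = np.ones_like(x)
    for combo in combinations(grid, K):
        psi = np.asarray(combo)
        if K > 1 and np.any(np.diff(psi) < min_sep):
            continue
        X = np.column_stack([ones, x] + [np.maximum(x - p, 0.0) for p in psi])
        coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ coef
        rss = float(r @ r)
        if rss < best_rss:
            best_rss, best = rss, psi
    if best is None:
        return np.quantile(x, (np.arange(K) + 1.0) / (K + 1.0))
    return best


def fit_segmented(
    x: Sequence[float],
    y: Sequence[float],
    n_breakpoints: int,
    init: Sequence[float] | None = None,
    *,
    max_iter: int = 100,
    tol_scale: float = 1e-6,
) -> SegmentedFit:
    """Fit a continuous piecewise-linear regression with ``n_breakpoints``.

    Parameters
    ----------
    x, y : array-like
        Ages and scores.
    n_breakpoints : int
        Number of slope changes to fit.  0 gives an ordinary linear fit.
    init : sequence of float, optional
        Starting breakpoint ages.  Defaults to evenly spaced quantiles of
        ``x``.

    Notes
    -----
    Breakpoints are constrained to the 5th-95th percentile window of ``x``
    with a minimum mutual separation of 2% of the x-range; if two estimates
    collide, the model is refit with one fewer breakpoint and a
    :class:`BreakpointCollisionWarning` is issued.  Convergence is declared
    when the largest gap coefficient falls below ``tol_scale * SD(y)``.
    The model BIC counts ``2 + 2K + 1`` free parameters (intercept, base
    slope, one slope change and one location per breakpoint, and the error
    variance).
    """
    if n_breakpoints < 0:
        raise ValueError("n_breakpoints must be >= 0")
    x, y = _validate_xy(x, y, n_breakpoints)
    if n_breakpoints == 0:
        return _linear_fit(x, y)

    K = n_breakpoints
    lo, hi = np.quantile(x, [0.05, 0.95])
    min_sep = 0.02 * np.ptp(x)
    if init is not None:
        psi = np.sort(np.asarray(init, dtype=float))
        if psi.size != K:
            raise ValueError("init must supply one guess per breakpoint")
    else:
        psi = _coarse_init(x, y, K, lo, hi, min_sep)
    psi = np.clip(psi, lo, hi)

    tol = tol_scale * np.std(y)
    sd_y = np.std(y)
    if sd_y == 0:
        raise ValueError("y has zero variance")

    def profile_rss(p: np.ndarray) -> float:
        Xp = _design(x, p, with_gap=False)
        c, _, _, _ = np.linalg.lstsq(Xp, y, rcond=None)
        r = y - Xp @ c
        return float(r @ r)

    converged = False
    it = 0
    rss_cur = profile_rss(psi)
    for it in range(1, max_iter + 1):
        X = _design(x, psi, with_gap=True)
        coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        beta = coef[2 : 2 + K]
        gamma = coef[2 + K :]
        if np.max(np.abs(gamma)) < tol:
            converged = True
            break
        with np.errstate(divide="ignore", invalid="ignore"):
            step = np.where(np.abs(beta) > 1e-12, gamma / beta, 0.0)
        # step-halving on the profile RSS keeps the update from oscillating
        h = 1.0
        psi_new, rss_new = psi, rss_cur
        while h >= 1.0 / 64.0:
            cand = np.sort(np.clip(psi + h * step, lo, hi))
            rss_c = profile_rss(cand)
            if rss_c <= rss_cur + 1e-12 * max(rss_cur, 1.0):
                psi_new, rss_new = cand, rss_c
                break
            h /= 2.0
        if np.max(np.abs(psi_new - psi)) < 1e-10 * np.ptp(x):
            # stuck (update rejected or negligible): the profile optimum
            # is reached to numerical precision
            converged = True
            psi = psi_new
            break
        psi, rss_cur = psi_new, rss_new
        if K > 1 and np.any(np.diff(psi) < min_sep):
            warnings.warn(
                f"breakpoints collided (separation < {min_sep:.3g}); "
                f"refitting with {K - 1}",
                BreakpointCollisionWarning,
                stacklevel=2,
            )
            sub = fit_segmented(x, y, K - 1, max_iter=max_iter, tol_scale=tol_scale)
            sub.requested_breakpoints = n_breakpoints
            return sub

    if not converged:
        warnings.warn(
            f"breakpoint iteration did not converge in {max_iter} iterations",
            ConvergenceWarning,
            stacklevel=2,
        )

    # Coordinate-wise polish: the linearised update lands near, but not
    # exactly on, the profile-RSS optimum; a bounded scalar search over
    # each psi_k pins it down.
    from scipy.optimize import minimize_scalar

    for _ in range(2):
        moved = False
        for k in range(K):
            lo_k = max(lo, (psi[k - 1] + min_sep) if k else lo)
            hi_k = min(hi, (psi[k + 1] - min_sep) if k < K - 1 else hi)
            if hi_k - lo_k <= 0:
                continue
            span = hi_k - lo_k
            a = max(lo_k, psi[k] - 0.05 * span)
            b = min(hi_k, psi[k] + 0.05 * span)

            def rss_at(p: float, k=k) -> float:
                trial = psi.copy()
                trial[k] = p
                return profile_rss(trial)

            res = minimize_scalar(rss_at, bounds=(a, b), method="bounded",
                                  options={"xatol": 1e-7})
            if res.fun < rss_cur - 1e-12:
                psi[k] = float(res.x)
                rss_cur = res.fun
                moved = True
        psi = np.sort(psi)
        if not moved:
            break

    # Final refit at the converged psi; the gap columns supply the
    # delta-method SE for psi (SE(gamma)/|beta|) and first-order covariance.
    X = _design(x, psi, with_gap=True)
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    rss = float(resid @ resid)
    p_design = X.shape[1]
    dof = max(x.size - p_design, 1)
    sigma2 = rss / dof
    XtX = X.T @ X
    try:
        cov = sigma2 * np.linalg.inv(XtX)
    except np.linalg.LinAlgError:
        cov = sigma2 * np.linalg.pinv(XtX)

    beta = coef[2 : 2 + K]
    gamma = coef[2 + K :]
    slopes = np.concatenate([[coef[1]], coef[1] + np.cumsum(beta)])
    # slope_j = b + sum_{k<=j} beta_k : linear combination over coef vector
    slope_se = np.empty(K + 1)
    slope_ci = np.empty((K + 1, 2))
    for j in range(K + 1):
        c = np.zeros(p_design)
        c[1] = 1.0
        c[2 : 2 + j] = 1.0
        var = float(c @ cov @ c)
        slope_se[j] = np.sqrt(max(var, 0.0))
        slope_ci[j] = (
            slopes[j] - _Z95 * slope_se[j],
            slopes[j] + _Z95 * slope_se[j],
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        gamma_se = np.sqrt(np.maximum(np.diag(cov)[2 + K :], 0.0))
        psi_se = np.where(np.abs(beta) > 1e-12, gamma_se / np.abs(beta), np.nan)

    n = x.size
    ll = _gauss_loglik(rss, n)
    p = 2 + 2 * K + 1
    b_se = float(np.sqrt(max(cov[1, 1], 0.0)))
    return SegmentedFit(
        n_breakpoints=K,
        psi=psi,
        psi_se=psi_se,
        intercept=float(coef[0]),
        segment_slopes=slopes,
        slope_se=slope_se,
        slope_ci=slope_ci,
        slope_changes=np.diff(slopes),
        resid_var=rss / n,
        loglik=ll,
        bic=-2.0 * ll + p * np.log(n),
        n=n,
        converged=converged,
        n_iter=it,
        x_range=(float(x.min()), float(x.max())),
        requested_breakpoints=n_breakpoints,
        base_slope_t=coef[1] / b_se if b_se > 0 else np.nan,
    )


def select_n_breakpoints(
    x: Sequence[float],
    y: Sequence[float],
    max_breakpoints: int = 3,
    init: dict[int, Sequence[float]] | None = None,
) -> tuple[SegmentedFit, list[dict]]:
    """Fit 0..max_breakpoints models and return the lowest-BIC fit.

    Returns the winning :class:`SegmentedFit` and a BIC table (one row per
    converged candidate).  Candidates that fail, do not converge, or whose
    breakpoints collide down to a smaller model are excluded.
    """
    table: list[dict] = []
    fits: list[SegmentedFit] = []
    for k in range(max_breakpoints + 1):
        guess = init.get(k) if init else None
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("error", BreakpointCollisionWarning)
                warnings.simplefilter("error", ConvergenceWarning)
                fit = fit_segmented(x, y, k, init=guess)
        except (BreakpointCollisionWarning, ConvergenceWarning, ValueError,
                np.linalg.LinAlgError):
            continue
        fits.append(fit)
        table.append({"n_breakpoints": k, "bic": fit.bic, "loglik": fit.loglik})
    if not fits:
        raise RuntimeError("no candidate segmented model converged")
    best = min(fits, key=lambda f: f.bic)
    return best, table


def davies_test(
    x: Sequence[float], y: Sequence[float], n_points: int = 10
) -> tuple[float, float]:
    """Test for a change in slope at an unknown age (Davies' bound).

    Adds a hinge term ``(x - psi)_+`` to the linear model at ``n_points``
    candidate locations evenly spaced between the 10th and 90th percentiles
    of ``x``, takes the maximum absolute t statistic M, and bounds the
    two-sided p-value by ``2*Phi(-M) + V*exp(-M^2/2)/sqrt(8*pi)`` where V is
    the total variation of the t sequence.  The bound is conservative.

    Returns ``(M, p_value)``.
    """
    x, y = _validate_xy(x, y, 0)
    if x.size < 20:
        raise ValueError("davies_test requires at least 20 observations")
    lin = np.column_stack([np.ones_like(x), x])
    coef, _, _, _ = np.linalg.lstsq(lin, y, rcond=None)
    rss0 = float(np.sum((y - lin @ coef) ** 2))
    if rss0 <= 1e-12 * max(1.0, float(y @ y)):
        warnings.warn("perfect linear fit; Davies' test undefined, p = 1",
                      UserWarning, stacklevel=2)
        return 0.0, 1.0

    qs = np.quantile(x, [0.10, 0.90])
    candidates = np.linspace(qs[0], qs[1], n_points)
    tstats = np.empty(n_points)
    n = x.size
    for i, p0 in enumerate(candidates):
        X = np.column_stack([np.ones_like(x), x, np.maximum(x - p0, 0.0)])
        coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
        rss = float(resid @ resid)
        dof = n - X.shape[1]
        sigma2 = rss / dof
        cov = sigma2 * np.linalg.pinv(X.T @ X)
        se = np.sqrt(max(cov[2, 2], 1e-300))
        tstats[i] = coef[2] / se
    M = float(np.max(np.abs(tstats)))
    V = float(np.sum(np.abs(np.diff(tstats))))
    p = 2.0 * stats.norm.sf(M) + V * np.exp(-0.5 * M * M) / np.sqrt(8.0 * np.pi)
    return M, float(min(1.0, p))


def predict(fit: SegmentedFit, ages: Sequence[float]) -> np.ndarray:
    """Evaluate the fitted piecewise-linear mean at the given ages.

    Extrapolation outside the training range is allowed (the boundary
    segments are extended).
    """
    a = np.asarray(ages, dtype=float)
    out = fit.intercept + fit.segment_slopes[0] * a
    for k, p in enumerate(fit.psi):
        out = out + fit.slope_changes[k] * np.maximum(a - p, 0.0)
    return out


def peak_from_fit(
    fit: SegmentedFit, age_range: tuple[float, float] | None = None
) -> PeakEstimate:
    """Locate the age of maximal fitted score.

    Candidates are the two endpoints of ``age_range`` (default: the
    observed range) and every breakpoint.  Exact ties take the earliest
    candidate age.
    """
    if age_range is None:
        age_range = fit.x_range
    lo, hi = float(age_range[0]), float(age_range[1])
    cand_ages = np.concatenate([[lo], fit.psi, [hi]])
    cand_vals = predict(fit, cand_ages)
    # stable preference: among near-equal maxima take the earliest age
    best = int(np.argmax(cand_vals))
    peak_age = float(cand_ages[best])
    at_boundary = best == 0 or best == cand_ages.size - 1
    which = None if at_boundary else best - 1
    return PeakEstimate(
        peak_age=peak_age,
        peak_score=float(cand_vals[best]),
        at_boundary=at_boundary,
        which_breakpoint=which,
    )


def side_slope(fit: SegmentedFit, peak: PeakEstimate, side: str) -> SlopeSummary:
    """Summarise the slope left ("increasing") or right ("decreasing") of the peak.

    A single flanking segment returns that segment's slope with its Wald
    CI.  Two or more flanking segments return the length-weighted average
    slope (the chord slope of the fitted function over that side) with
    ``combined=True``; its CI is left to the bootstrap and reported as
    ``None``.  If the peak sits at the boundary and no segment exists on the
    requested side, the result is flagged undefined.
    """
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")
    lo, hi = fit.x_range
    edges = np.concatenate([[lo], fit.psi, [hi]])
    label = "increasing" if side == "left" else "decreasing"
    if side == "left":
        a, b = lo, peak.peak_age
    else:
        a, b = peak.peak_age, hi
    if b - a <= 0:
        return SlopeSummary(side=label, value=np.nan, ci=None, combined=False,
                            defined=False, n_segments=0)
    # segments wholly inside [a, b]
    seg_idx = [
        j for j in range(fit.n_breakpoints + 1)
        if edges[j] >= a - 1e-12 and edges[j + 1] <= b + 1e-12
    ]
    if not seg_idx:
        return SlopeSummary(side=label, value=np.nan, ci=None, combined=False,
                            defined=False, n_segments=0)
    if len(seg_idx) == 1:
        j = seg_idx[0]
        return SlopeSummary(
            side=label,
            value=float(fit.segment_slopes[j]),
            ci=(float(fit.slope_ci[j, 0]), float(fit.slope_ci[j, 1])),
            combined=False,
            n_segments=1,
        )
    lengths = np.array([edges[j + 1] - edges[j] for j in seg_idx])
    vals = fit.segment_slopes[seg_idx]
    value = float(np.sum(lengths * vals) / np.sum(lengths))
    return SlopeSummary(side=label, value=value, ci=None, combined=True,
                        n_segments=len(seg_idx))
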