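"""Over/under-responsive mutant detection from a telomere-length screen.

For each deletion/hypomorphic mutant, a screen records the initial telomere
length and the length after ~100 generations under a stress. The length
change is strongly linear in the initial length (long mutants respond more),
so responsiveness outliers are defined against a robust linear fit of
delta on initial length: iteratively reweighted least squares with Tukey's
bisquare weights, residual scale from the median absolute deviation, and a
normal-quantile cut on standardized residuals — the most extreme 5% of an
assumed-normal residual distribution, 2.5% from each side, by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ScreenTable",
    "RegressionFit",
    "OutlierCalls",
    "CorrelationReport",
    "pearson",
    "robust_fit",
    "call_outliers",
    "response_ratio",
    "TUKEY_C",
]

TUKEY_C = 4.685  # bisquare tuning constant, ~95% Gaussian efficiency
MAD_SCALE = 1.4826  # consistency factor: MAD -> SD under normality


@dataclass(frozen=True)
class ScreenTable:
    """Per-mutant (initial, final) telomere lengths for one stress, in bp."""

    table: pd.DataFrame  # columns: mutant, initial, final, delta
    stress: str

    def __post_init__(self) -> None:
        required = {"mutant", "initial", "final", "delta"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"screen table needs columns {sorted(required)}")
        if self.table["mutant"].duplicated().any():
            dup = self.table.loc[self.table["mutant"].duplicated(), "mutant"].tolist()
            raise ValueError(f"duplicate mutant rows: {dup}")
        mismatch = np.abs(
            self.table["delta"] - (self.table["final"] - self.table["initial"])
        )
        if (mismatch > 1.0).any():
            bad = self.table.loc[mismatch > 1.0, "mutant"].tolist()
            raise ValueError(f"delta disagrees with final - initial by > 1 bp: {bad}")

    @classmethod
    def from_columns(cls, mutant, initial, final, stress: str) -> "ScreenTable":
        initial = np.asarray(initial, dtype=float)
        final = np.asarray(final, dtype=float)
        return cls(
            table=pd.DataFrame(
                {
                    "mutant": list(mutant),
                    "initial": initial,
                    "final": final,
                    "delta": final - initial,
                }
            ),
            stress=stress,
        )


@dataclass(frozen=True)
class RegressionFit:
    """Robust linear fit of delta on initial length."""

    slope: float
    intercept: float
    scale: float
    weights: np.ndarray
    residuals: np.ndarray
    converged: bool
    n_iter: int

    def predict(self, initial):
        return self.slope * np.asarray(initial, dtype=float) + self.intercept


@dataclass(frozen=True)
class CorrelationReport:
    r: float
    p: float
    n: int


def pearson(x, y) -> CorrelationReport:
    """Pearson product-moment correlation with the two-sided t-transform p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    if x.size < 3:
        raise ValueError("need >= 3 points for a finite p-value")
    for name, v in (("x", x), ("y", y)):
        if np.ptp(v) == 0:
            raise ValueError(f"variable {name} is constant; correlation undefined")
    res = stats.pearsonr(x, y)
    return CorrelationReport(r=float(res.statistic), p=float(res.pvalue), n=x.size)


def _tukey_weights(u: np.ndarray) -> np.ndarray:
    w = np.zeros_like(u)
    inside = np.abs(u) < TUKEY_C
    w[inside] = (1.0 - (u[inside] / TUKEY_C) ** 2) ** 2
    return w


def robust_fit(
    initial,
    delta,
    tol: float = 1e-8,
    max_iter: int = 50,
    tuning: float = TUKEY_C,
) -> RegressionFit:
    """IRLS robust line fit: delta ~ slope * initial + intercept.

    Starts from ordinary least squares, then alternates (i) residual scale =
    1.4826 * MAD of residuals and (ii) weighted least squares with Tukey
    bisquare weights at the given tuning constant, until the relative change
    in coefficients drops below `tol` or `max_iter` iterations.
    """
    x = np.asarray(initial, dtype=float)
    y = np.asarray(delta, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("initial and delta must be 1-D and of equal length")
    if x.size < 3:
        raise ValueError("need >= 3 points to fit a line")
    if x.size < 10:
        warnings.warn(f"only {x.size} points; robust fit may be unstable", stacklevel=2)

    X = np.column_stack([x, np.ones_like(x)])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    weights = np.ones_like(x)
    scale = 0.0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        resid = y - X @ beta
        scale = MAD_SCALE * float(np.median(np.abs(resid - np.median(resid))))
        if scale == 0:  # perfect fit (or >50% of points on one line)
            converged = True
            weights = np.ones_like(x)
            break
        w = _tukey_weights(resid / scale)
        if w.sum() == 0:
            warnings.warn("all points downweighted to zero; keeping last fit", stacklevel=2)
            break
        sw = np.sqrt(w)
        beta_new, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
        change = np.max(
            np.abs(beta_new - beta) / np.maximum(np.abs(beta), 1e-12)
        )
        beta, weights = beta_new, w
        if change < tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"robust fit did not converge in {max_iter} iterations", stacklevel=2)
    resid = y - X @ beta
    return RegressionFit(
        slope=float(beta[0]),
        intercept=float(beta[1]),
        scale=float(scale),
        weights=weights,
        residuals=resid,
        converged=converged,
        n_iter=it,
    )


@dataclass(frozen=True)
class OutlierCalls:
    """Standardized residuals and over/under-responsive flags per mutant."""

    table: pd.DataFrame  # columns: mutant, z, flagged, direction
    alpha: float
    cutoff: float
    stress_direction: str


def call_outliers(
    fit: RegressionFit,
    alpha: float = 0.05,
    stress_direction: str = "elongating",
    mutants=None,
    method: str = "normal",
    scale_estimator: str = "classical",
) -> OutlierCalls:
    """Flag responsiveness outliers from a robust fit.

    method='normal' (default): z = residual / residual SD; flag |z| above the
    standard-normal upper alpha/2 quantile (1.960 at alpha=0.05) — the most
    extreme 5% of an assumed-normal residual distribution, 2.5% per side.
    method='rank': flag the literal most-extreme round(alpha*n) residuals,
    split evenly between the two sides.

    scale_estimator='classical' (default) standardizes by the ordinary SD of
    the residuals — a normal distribution fitted to all residuals, so gross
    outliers widen it and only points far outside the bulk are flagged.
    'robust' standardizes by the fit's MAD scale instead, which keeps the
    cut calibrated to the clean bulk regardless of contamination.

    Direction: under an elongating stress a positive residual (more elongation
    than the trend predicts) is over-responsive; under a shortening stress a
    negative residual is over-responsive.
    """
    if not (0.0 < alpha < 0.5):
        raise ValueError("alpha must be in (0, 0.5)")
    if stress_direction not in ("elongating", "shortening"):
        raise ValueError(f"unknown stress_direction {stress_direction!r}")
    resid = fit.residuals
    if scale_estimator == "classical":
        scale = float(np.std(resid, ddof=2))  # 2 fitted coefficients
    elif scale_estimator == "robust":
        scale = fit.scale
    else:
        raise ValueError(f"unknown scale_estimator {scale_estimator!r}")
    if scale <= 0:
        raise ValueError("degenerate fit: residual scale is zero")
    z = resid / scale
    n = z.size
    if method == "normal":
        cutoff = float(stats.norm.ppf(1.0 - alpha / 2.0))
        flagged = np.abs(z) > cutoff
    elif method == "rank":
        k_side = int(round(alpha * n / 2.0))
        cutoff = float("nan")
        flagged = np.zeros(n, dtype=bool)
        if k_side:
            order = np.argsort(z)
            flagged[order[:k_side]] = True
            flagged[order[-k_side:]] = True
    else:
        raise ValueError(f"unknown method {method!r}")

    over_sign = 1.0 if stress_direction == "elongating" else -1.0
    direction = np.where(
        z * over_sign > 0, "over_responsive", "under_responsive"
    )
    if mutants is None:
        mutants = [f"m{i}" for i in range(n)]
    table = pd.DataFrame(
        {"mutant": list(mutants), "z": z, "flagged": flagged, "direction": direction}
    )
    return OutlierCalls(
        table=table, alpha=alpha, cutoff=cutoff, stress_direction=stress_direction
    )


def response_ratio(initial, delta):
    """Per-mutant ratio initial / delta; infinite (flagged NaN->inf) where delta = 0.

    Used for the grouping of very short mutants by relative response. Returns
    (ratio array, finite mask).
    """
    initial = np.asarray(initial, dtype=float)
    delta = np.asarray(delta, dtype=float)
    finite = delta != 0
    ratio = np.full_like(initial, np.inf)
    np.divide(initial, delta, out=ratio, where=finite)
    return ratio, finite
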