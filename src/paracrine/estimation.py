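"""Empirical PCD estimation: Gaussian fit to response versus source distance.

The communication distance is measured directly as the sigma of
mean(r) = A exp(-r^2/(2 sigma^2)) + c fitted to the binned mean response of
neighbor cells around a single secreting cell.  A baseline c is included
because cells far from the source keep basal activity.  ``compare_pcd`` then
tests whether these direct estimates agree with the sweep-derived optima.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .fields import CellField


def gaussian_profile(r: np.ndarray, a: float, sigma: float, c: float) -> np.ndarray:
    return a * np.exp(-(r**2) / (2.0 * sigma**2)) + c


@dataclass
class PcdFit:
    """Gaussian fit to one point-source field; ``sigma`` is the PCD estimate."""

    a: float
    sigma: float
    c: float
    r_centers: np.ndarray
    bin_means: np.ndarray
    bin_counts: np.ndarray
    residual_norm: float
    sigma_stderr: float
    wide_ci: bool  # sigma poorly identified (flat or noisy profile)

    def to_dict(self) -> dict:
        return {
            "a": self.a,
            "sigma": self.sigma,
            "c": self.c,
            "residual_norm": self.residual_norm,
            "sigma_stderr": self.sigma_stderr,
            "wide_ci": self.wide_ci,
            "n_bins": len(self.r_centers),
        }


class FitConvergenceError(RuntimeError):
    """Nonlinear fit failed; carries the initialization and a data summary."""


def fit_point_source(
    field: CellField,
    bin_width: float = 20.0,
    r_max: float = 400.0,
    per_cell: bool = False,
) -> PcdFit:
    """Fit a Gaussian-plus-baseline profile to a single-source field.

    Neighbor (non-source) cells within ``r_max`` of the source are binned by
    distance (``bin_width`` um); the fit runs on the bin means by default
    (``per_cell=True`` fits all cells directly instead).  Initialization:
    A0 = max bin mean - min bin mean, sigma0 = quarter of the covered radial
    range, c0 = min bin mean.

    Requires >= 30 neighbor cells in range.  A fit whose sigma standard error
    exceeds sigma itself (e.g. a flat profile) is flagged ``wide_ci`` rather
    than trusted silently.
    """
    mask = (field.group != "source") & (field.covariate > 0) & (field.covariate <= r_max)
    r = field.covariate[mask]
    resp = field.responses[mask]
    if len(r) < 30:
        raise ValueError(f"only {len(r)} neighbor cells within r_max={r_max}; need >= 30")

    edges = np.arange(0.0, r_max + bin_width / 2.0, bin_width)
    idx = np.clip(np.digitize(r, edges) - 1, 0, len(edges) - 2)
    centers, means, counts = [], [], []
    for b in np.unique(idx):
        sel = idx == b
        if sel.sum() < 2:
            continue
        centers.append(r[sel].mean())
        means.append(resp[sel].mean())
        counts.append(int(sel.sum()))
    centers = np.asarray(centers)
    means = np.asarray(means)
    counts = np.asarray(counts)
    if len(centers) < 4:
        raise ValueError(f"only {len(centers)} usable distance bins; need >= 4")

    a0 = float(means.max() - means.min())
    sigma0 = float((centers.max() - centers.min()) / 4.0)
    c0 = float(means.min())
    p0 = (a0, sigma0, c0)
    x, y = (r, resp) if per_cell else (centers, means)
    try:
        popt, pcov = optimize.curve_fit(
            gaussian_profile,
            x,
            y,
            p0=p0,
            bounds=([0.0, 1e-6, 0.0], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
    except (RuntimeError, optimize.OptimizeWarning) as exc:
        raise FitConvergenceError(
            f"Gaussian fit failed: {exc}; init (A0, sigma0, c0)={p0}, "
            f"{len(centers)} bins, mean response range "
            f"[{means.min():.4g}, {means.max():.4g}]"
        ) from exc
    a_hat, sigma_hat, c_hat = (float(v) for v in popt)
    perr = np.sqrt(np.diag(pcov))
    sigma_se = float(perr[1]) if np.isfinite(perr[1]) else math.inf
    a_se = float(perr[0]) if np.isfinite(perr[0]) else math.inf
    wide = (
        (not math.isfinite(sigma_se))
        or sigma_se > sigma_hat
        or a_hat < 2.0 * a_se          # amplitude indistinguishable from flat
        or sigma_hat < bin_width       # narrower than one distance bin
        or sigma_hat > r_max           # wider than the fitted range
    )
    if wide:
        warnings.warn(
            f"sigma poorly identified (sigma={sigma_hat:.3g} +/- {sigma_se:.3g})",
            stacklevel=2,
        )
    resid = gaussian_profile(x, *popt) - y
    return PcdFit(
        a=a_hat,
        sigma=sigma_hat,
        c=c_hat,
        r_centers=centers,
        bin_means=means,
        bin_counts=counts,
        residual_norm=float(np.linalg.norm(resid)),
        sigma_stderr=sigma_se,
        wide_ci=wide,
    )


@dataclass(frozen=True)
class PcdSummary:
    sigmas: tuple[float, ...]
    mean: float
    sem: Optional[float]


def summarize_fits(fits: Sequence[PcdFit]) -> PcdSummary:
    """Mean +/- SEM of the per-source sigma estimates."""
    sigmas = np.array([f.sigma for f in fits], dtype=float)
    if len(sigmas) == 0:
        raise ValueError("no fits to summarize")
    sem = float(sigmas.std(ddof=1) / math.sqrt(len(sigmas))) if len(sigmas) > 1 else None
    return PcdSummary(sigmas=tuple(sigmas), mean=float(sigmas.mean()), sem=sem)


@dataclass(frozen=True)
class PcdComparison:
    t: float
    p_value: float
    mean_optima: float
    mean_fits: float


def compare_pcd(optima: Sequence[float], fits: Sequence[float]) -> PcdComparison:
    """Two-sided two-sample t-test: sweep optima versus direct sigma estimates."""
    optima = np.asarray(optima, dtype=float)
    fits = np.asarray(fits, dtype=float)
    if len(optima) < 2 or len(fits) < 2:
        raise ValueError("each group needs at least 2 values")
    if optima.std(ddof=1) == 0 and fits.std(ddof=1) == 0:
        if optima.mean() == fits.mean():
            return PcdComparison(0.0, 1.0, float(optima.mean()), float(fits.mean()))
        raise ValueError("degenerate zero-variance groups with unequal means")
    res = stats.ttest_ind(optima, fits)
    return PcdComparison(
        t=float(res.statistic),
        p_value=float(res.pvalue),
        mean_optima=float(optima.mean()),
        mean_fits=float(fits.mean()),
    )


__all__ = [
    "FitConvergenceError",
    "PcdComparison",
    "PcdFit",
    "PcdSummary",
    "compare_pcd",
    "fit_point_source",
    "gaussian_profile",
    "summarize_fits",
]
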