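"""Response-fidelity statistics: binning, SNR, CV-by-bin, and mutual information.

The signal-to-noise ratio follows the variance-decomposition definition used
throughout wound-response analysis: cells are binned by a covariate (ATP dose
well, or distance from the wound), the signal S is the variance across bins of
the bin-mean responses, the noise N is the mean across bins of the within-bin
response variances, and SNR = S/N.

Mutual information between covariate bin and response is estimated with a
k-nearest-neighbor (k = 10 by default) density estimate of the response
distribution, I_B = H[R] - sum_b (n_b/n) H[R | bin b] for each bin count B,
followed by a linear extrapolation of I_B to B = 0 to remove the dependence
on the number of bins.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree

from .fields import CellField

DEFAULT_BIN_COUNTS = (4, 6, 8, 10, 12, 16, 20)

Scheme = Union[str, tuple[str, int]]


class ZeroNoiseError(ValueError):
    """All responses identical within every bin: the SNR denominator is zero."""


@dataclass
class BinSummary:
    """Per-bin statistics over a covariate binning.

    ``table`` has one row per retained bin with columns
    ``n, mean, var, sd, cv, lo, hi`` (lo/hi are covariate ranges; NaN for
    group bins).  ``assignments`` maps each cell to its bin index (-1 for
    cells in dropped bins).
    """

    table: pd.DataFrame
    scheme: str
    assignments: np.ndarray
    n_total: int

    @property
    def k(self) -> int:
        return len(self.table)

    @property
    def counts(self) -> np.ndarray:
        return self.table["n"].to_numpy()

    @property
    def means(self) -> np.ndarray:
        return self.table["mean"].to_numpy()

    @property
    def variances(self) -> np.ndarray:
        return self.table["var"].to_numpy()

    @property
    def cvs(self) -> np.ndarray:
        return self.table["cv"].to_numpy()


@dataclass
class FidelityResult:
    """Fidelity of one field at one PCD: SNR pieces and/or mutual information."""

    signal: Optional[float] = None
    noise: Optional[float] = None
    snr: Optional[float] = None
    mi_bits: Optional[float] = None
    mi_nats: Optional[float] = None
    mi_curve: Optional[list[tuple[int, float]]] = None
    mi_slope: Optional[float] = None
    pcd: Optional[float] = None
    n_cells: int = 0
    scheme: str = ""
    warnings: list[str] = dc_field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "signal": self.signal,
            "noise": self.noise,
            "snr": self.snr,
            "mi_bits": self.mi_bits,
            "mi_nats": self.mi_nats,
            "mi_curve": self.mi_curve,
            "mi_slope": self.mi_slope,
            "pcd": self.pcd,
            "n_cells": self.n_cells,
            "scheme": self.scheme,
            "warnings": self.warnings,
        }


def _parse_scheme(scheme: Scheme) -> tuple[str, Optional[int]]:
    if isinstance(scheme, tuple):
        kind, k = scheme
        return kind, int(k)
    if scheme == "by-group":
        return "by-group", None
    for kind in ("equal-count", "equal-width"):
        if scheme.startswith(kind + ":"):
            return kind, int(scheme.split(":", 1)[1])
    raise ValueError(
        f"unrecognized binning scheme {scheme!r}; expected 'by-group', "
        "'equal-count:K' or 'equal-width:K'"
    )


def bin_assignments(field: CellField, scheme: Scheme) -> tuple[np.ndarray, str]:
    """Deterministic bin index per cell (before small-bin dropping)."""
    kind, k = _parse_scheme(scheme)
    if kind == "by-group":
        groups = field.group
        labels = pd.unique(groups)
        index = {g: i for i, g in enumerate(labels)}
        return np.array([index[g] for g in groups]), "by-group"
    if k is None or k < 2:
        raise ValueError("covariate schemes need k >= 2 bins")
    cov = field.covariate
    if np.unique(cov).size < 2:
        raise ValueError("all covariates identical: cannot form 2 bins")
    if kind == "equal-count":
        # stable rank split; ties broken by cell order so assignment is
        # deterministic and bin sizes differ by at most one
        order = np.lexsort((np.arange(len(cov)), cov))
        assign = np.empty(len(cov), dtype=int)
        for b, chunk in enumerate(np.array_split(order, k)):
            assign[chunk] = b
        return assign, f"equal-count:{k}"
    edges = np.linspace(cov.min(), cov.max(), k + 1)
    assign = np.clip(np.searchsorted(edges, cov, side="right") - 1, 0, k - 1)
    return assign, f"equal-width:{k}"


def bin_cells(field: CellField, scheme: Scheme) -> BinSummary:
    """Bin cells by covariate or group and summarize each bin.

    Bins with fewer than 2 cells are dropped with a warning (their variance is
    undefined); fewer than 2 usable bins is an error.
    """
    assign, name = bin_assignments(field, scheme)
    cov = field.covariate
    resp = field.responses
    rows = []
    final = np.full(len(assign), -1, dtype=int)
    for b in np.unique(assign):
        mask = assign == b
        n = int(mask.sum())
        if n < 2:
            warnings.warn(f"dropping bin {b} with n={n} < 2", stacklevel=2)
            continue
        r = resp[mask]
        mean = float(r.mean())
        var = float(r.var(ddof=1))
        sd = math.sqrt(var)
        rows.append(
            {
                "bin": int(b),
                "n": n,
                "mean": mean,
                "var": var,
                "sd": sd,
                "cv": sd / mean if mean != 0 else (0.0 if sd == 0 else math.inf),
                "lo": float(cov[mask].min()) if name != "by-group" else math.nan,
                "hi": float(cov[mask].max()) if name != "by-group" else math.nan,
            }
        )
        final[mask] = len(rows) - 1
    if len(rows) < 2:
        raise ValueError(f"only {len(rows)} usable bin(s); need at least 2")
    table = pd.DataFrame(rows)
    return BinSummary(table=table, scheme=name, assignments=final, n_total=int((final >= 0).sum()))


def snr(field: CellField, scheme: Scheme, weighted: bool = False) -> FidelityResult:
    """Signal-to-noise ratio of a binned field.

    S = sample variance (ddof=1) across bins of the bin means;
    N = mean across bins of the within-bin sample variances (unweighted by
    default; ``weighted=True`` weights by bin counts); SNR = S/N.
    """
    summary = bin_cells(field, scheme)
    s = float(np.var(summary.means, ddof=1))
    if weighted:
        n_noise = float(np.average(summary.variances, weights=summary.counts))
    else:
        n_noise = float(np.mean(summary.variances))
    if n_noise == 0.0:
        raise ZeroNoiseError(
            "zero noise: all responses identical within every bin"
        )
    return FidelityResult(
        signal=s,
        noise=n_noise,
        snr=s / n_noise,
        n_cells=summary.n_total,
        scheme=summary.scheme,
    )


def cv_by_bin(field: CellField, scheme: Scheme) -> BinSummary:
    """Coefficient of variation (sd/mean) per covariate bin."""
    return bin_cells(field, scheme)


@dataclass(frozen=True)
class CvComparison:
    t: float
    p_value: float
    mean_cv_a: float
    mean_cv_b: float


def cv_compare(a: BinSummary, b: BinSummary) -> CvComparison:
    """Two-sample t-test on per-bin CVs of two summaries (same scheme)."""
    if a.scheme != b.scheme:
        raise ValueError(f"schemes differ: {a.scheme!r} vs {b.scheme!r}")
    if a.k < 2 or b.k < 2:
        raise ValueError("need at least 2 bins on each side")
    res = stats.ttest_ind(a.cvs, b.cvs)
    return CvComparison(
        t=float(res.statistic),
        p_value=float(res.pvalue),
        mean_cv_a=float(a.cvs.mean()),
        mean_cv_b=float(b.cvs.mean()),
    )


# ---------------------------------------------------------------------------
# kNN density / entropy / mutual information
# ---------------------------------------------------------------------------

def knn_density(values: np.ndarray, k: int = 10) -> np.ndarray:
    """k-nearest-neighbor density estimate for 1-D samples.

    p_hat(v_i) = k / (n * w_i), where w_i = 2 * (distance from v_i to its k-th
    nearest neighbor among the other values).  If a value has >= k exact
    duplicates (w_i = 0), half the smallest nonzero width is substituted with
    a warning.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n <= k:
        raise ValueError(f"need more than k={k} values, got {n}")
    tree = cKDTree(values[:, None])
    dist, _ = tree.query(values[:, None], k=k + 1)
    w = 2.0 * dist[:, k]
    if (w == 0).any():
        nz = w[w > 0]
        if nz.size == 0:
            raise ValueError("all values identical: density undefined")
        warnings.warn(
            f"{int((w == 0).sum())} values have >= {k} duplicates; "
            "substituting half the smallest nonzero width",
            stacklevel=2,
        )
        w = np.where(w == 0, 0.5 * nz.min(), w)
    return k / (n * w)


def knn_entropy_bits(values: np.ndarray, k: int = 10) -> float:
    """Plug-in entropy (bits) from the kNN density: -(1/n) sum log2 p_hat."""
    p = knn_density(values, k=k)
    return float(-np.mean(np.log2(p)))


def mutual_information(
    field: CellField,
    bin_counts: Sequence[int] = DEFAULT_BIN_COUNTS,
    k_nn: int = 10,
    pcd: Optional[float] = None,
) -> FidelityResult:
    """Mutual information (bits) between covariate bin and response, with
    bin-count extrapolation.

    For each bin count B the field is split into B equal-count covariate bins
    and I_B = H[R] - sum_b (n_b/n) H[R | bin b] is estimated with kNN
    entropies; the reported MI is the intercept of an ordinary least-squares
    line of I_B on B (extrapolation to zero bins removes the estimator's
    dependence on B).  Negative intercepts are clamped to 0 with a warning.
    """
    resp = field.responses
    n = len(resp)
    warns: list[str] = []
    h_r = knn_entropy_bits(resp, k=k_nn)
    curve = []
    for b_count in bin_counts:
        assign, _ = bin_assignments(field, ("equal-count", int(b_count)))
        h_cond = 0.0
        for b in np.unique(assign):
            r_b = resp[assign == b]
            if len(r_b) <= k_nn:
                raise ValueError(
                    f"bin {b} of {b_count} has n={len(r_b)} <= k_nn={k_nn}"
                )
            h_cond += (len(r_b) / n) * knn_entropy_bits(r_b, k=k_nn)
        curve.append((int(b_count), h_r - h_cond))
    bs = np.array([c[0] for c in curve], dtype=float)
    ivals = np.array([c[1] for c in curve])
    slope, intercept = np.polyfit(bs, ivals, 1)
    mi = float(intercept)
    if mi < 0:
        warns.append(f"negative MI intercept {mi:.4f} clamped to 0")
        warnings.warn(warns[-1], stacklevel=2)
        mi = 0.0
    return FidelityResult(
        mi_bits=mi,
        mi_nats=mi * math.log(2.0),
        mi_curve=curve,
        mi_slope=float(slope),
        pcd=pcd,
        n_cells=n,
        scheme=f"equal-count extrapolated over {list(bin_counts)}",
        warnings=warns,
    )


__all__ = [
    "DEFAULT_BIN_COUNTS",
    "BinSummary",
    "CvComparison",
    "FidelityResult",
    "ZeroNoiseError",
    "bin_assignments",
    "bin_cells",
    "cv_by_bin",
    "cv_compare",
    "knn_density",
    "knn_entropy_bits",
    "mutual_information",
    "snr",
]
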