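"""Spatial cluster analysis: density versus response variability.

Cells are grouped by single-linkage hierarchical clustering on center-to-center
distance, cut at the maximal communication distance (MCD, 200 um) so that
cells in different clusters cannot communicate.  Per cluster, the longest
cell-to-cell distance d defines an effective circular area EA = pi (d/2)^2 and
a local density n/EA; clusters wider than d_max (150 um, above the measured
~100 um communication distance) are flagged and excluded.  The
density-variability test asks whether the within-cluster response SD drops
with density — the signature of paracrine coordination.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .fields import CellField

DEFAULT_MCD = 200.0
DEFAULT_D_MAX = 150.0


@dataclass
class ClusterTable:
    """Per-cluster geometry and response statistics.

    ``table`` columns: ``cluster, n, d, ea, density, resp_mean, resp_sd,
    filtered, singleton``; ``members`` maps cluster index to member cell ids;
    ``labels`` is the per-cell cluster index in field order.
    """

    table: pd.DataFrame
    members: dict[int, np.ndarray]
    labels: np.ndarray
    mcd: float
    d_max: float

    @property
    def n_clusters(self) -> int:
        return len(self.table)

    def retained(self) -> pd.DataFrame:
        """Clusters usable for SD statistics: not filtered, not singletons."""
        t = self.table
        return t[~t["filtered"] & ~t["singleton"]]


def cluster_cells(
    field: CellField, mcd: float = DEFAULT_MCD, d_max: float = DEFAULT_D_MAX
) -> ClusterTable:
    """Single-linkage clustering of cell centers cut at the MCD.

    Cutting a single-linkage dendrogram at ``mcd`` is exactly the connected
    components of the graph whose edges join cells within ``mcd``.  Clusters
    whose maximum pairwise distance d exceeds ``d_max`` are flagged
    ``filtered``; singletons are flagged (their SD is undefined).
    """
    if field.n < 2:
        raise ValueError("need at least 2 cells to cluster")
    xy = field.positions
    resp = field.responses
    z = linkage(xy, method="single")
    labels = fcluster(z, t=mcd, criterion="distance") - 1

    rows = []
    members: dict[int, np.ndarray] = {}
    ids = field.cells["id"].to_numpy()
    for k in np.unique(labels):
        mask = labels == k
        n = int(mask.sum())
        members[int(k)] = ids[mask]
        if n > 1:
            d = float(pdist(xy[mask]).max())
        else:
            d = 0.0
        ea = math.pi * (d / 2.0) ** 2
        density = n / ea if ea > 0 else math.nan
        r = resp[mask]
        rows.append(
            {
                "cluster": int(k),
                "n": n,
                "d": d,
                "ea": ea,
                "density": density,
                "resp_mean": float(r.mean()),
                "resp_sd": float(r.std(ddof=1)) if n > 1 else math.nan,
                "filtered": d > d_max,
                "singleton": n == 1,
            }
        )
    return ClusterTable(
        table=pd.DataFrame(rows), members=members, labels=labels, mcd=mcd, d_max=d_max
    )


@dataclass(frozen=True)
class DensityVariabilityResult:
    r: float
    p_value: float
    n_clusters: int
    statistic: str


def density_variability_test(
    table: ClusterTable, statistic: str = "sd"
) -> DensityVariabilityResult:
    """Pearson correlation of per-cluster response SD (or mean) with density.

    Uses only unfiltered, non-singleton clusters; a negative correlation with
    p < 0.05 on the SD is the paracrine-coordination signature.
    """
    if statistic not in ("sd", "mean"):
        raise ValueError(f"statistic must be 'sd' or 'mean', got {statistic!r}")
    t = table.retained()
    t = t[np.isfinite(t["density"]) & np.isfinite(t["resp_sd" if statistic == "sd" else "resp_mean"])]
    if len(t) < 3:
        raise ValueError(
            f"only {len(t)} usable clusters (need >= 3 unfiltered, non-singleton)"
        )
    col = "resp_sd" if statistic == "sd" else "resp_mean"
    if np.std(t[col]) == 0 or np.std(t["density"]) == 0:
        # no variability on one axis: no detectable trend by construction
        return DensityVariabilityResult(
            r=0.0, p_value=1.0, n_clusters=len(t), statistic=statistic
        )
    res = stats.pearsonr(t["density"], t[col])
    return DensityVariabilityResult(
        r=float(res.statistic),
        p_value=float(res.pvalue),
        n_clusters=len(t),
        statistic=statistic,
    )


__all__ = [
    "DEFAULT_D_MAX",
    "DEFAULT_MCD",
    "ClusterTable",
    "DensityVariabilityResult",
    "cluster_cells",
    "density_variability_test",
]
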