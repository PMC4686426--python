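"""PCD sweeps: fidelity as a function of communication distance, with the
optimum located per replicate and aggregated as mean +/- SEM.

A replicate is either a single wound field or a list of per-well dose fields
(wells are averaged independently — paracrine communication does not cross
wells — and then pooled with the dose as the group label).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .fields import CellField, make_cell_table, FieldGeometry
from .fidelity import Scheme, mutual_information, snr
from .kernel import DiffusionCap, KernelSpec, paracrine_average_grid

Replicate = Union[CellField, Sequence[CellField]]


def combine_wells(wells: Sequence[CellField]) -> CellField:
    """Pool per-well fields into one field binned ``by-group`` (one bin per well)."""
    if not wells:
        raise ValueError("no wells to combine")
    tables = []
    offset = 0
    for w in wells:
        t = w.cells.copy()
        t["id"] = t["id"].to_numpy() + offset
        offset += int(t["id"].max()) + 1 if len(t) else 0
        tables.append(t)
    cells = pd.concat(tables, ignore_index=True)
    g = wells[0].geometry
    return CellField(cells, FieldGeometry(width=g.width, height=g.height))


def _parabolic_refine(x: np.ndarray, y: np.ndarray, i: int) -> float:
    """Vertex of the parabola through grid points i-1, i, i+1 (clipped to
    that bracket); falls back to x[i] on degenerate curvature."""
    if i == 0 or i == len(x) - 1:
        return float(x[i])
    x0, x1, x2 = x[i - 1], x[i], x[i + 1]
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = (x1 - x0) * (y1 - y2) - (x1 - x2) * (y1 - y0)
    if denom == 0 or not np.isfinite(denom):
        return float(x1)
    num = (x1 - x0) ** 2 * (y1 - y2) - (x1 - x2) ** 2 * (y1 - y0)
    vertex = x1 - 0.5 * num / denom
    return float(np.clip(vertex, x0, x2))


@dataclass
class SweepResult:
    """Fidelity curves over a PCD grid for several replicate fields."""

    pcd_grid: np.ndarray
    curves: np.ndarray  # (n_replicates, n_grid), NaN where the statistic failed
    argmax_per_replicate: np.ndarray  # refined optimum per replicate, um
    mean_argmax: float
    sem_argmax: Optional[float]  # None for a single replicate
    statistic: str
    mode: str  # "free" | "diffusion-capped"
    failures: list[tuple[int, float, str]] = dc_field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "pcd_grid": self.pcd_grid.tolist(),
            "curves": self.curves.tolist(),
            "argmax_per_replicate": self.argmax_per_replicate.tolist(),
            "mean_argmax": self.mean_argmax,
            "sem_argmax": self.sem_argmax,
            "statistic": self.statistic,
            "mode": self.mode,
            "failures": [list(f) for f in self.failures],
        }

    @property
    def mean_curve(self) -> np.ndarray:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.curves, axis=0)


def sweep_pcd(
    replicates: Sequence[Replicate],
    grid: Sequence[float],
    statistic: str = "snr",
    scheme: Scheme = "equal-count:15",
    include_self: bool = True,
    cap: Optional[DiffusionCap] = None,
    convention: str = "sigma",
    bin_counts: Optional[Sequence[int]] = None,
    k_nn: int = 10,
) -> SweepResult:
    """Sweep the PCD over ``grid`` and locate the fidelity-maximizing value.

    For every replicate and every grid PCD the field is paracrine-averaged and
    the fidelity statistic ("snr" or "mi") computed; the per-replicate optimum
    is the best grid point refined by a 3-point parabola (the curves are
    smooth near their peak, so the optimum is reported at sub-grid
    resolution).  Aggregation is the mean of the per-replicate optima with
    SEM = sd/sqrt(N).  The sweep itself is deterministic given its inputs.

    Statistic failures on a (replicate, pcd) pair are recorded, excluded, and
    warned about; if every evaluation fails the sweep errors out.
    """
    grid = np.asarray(sorted(float(g) for g in grid))
    if len(grid) < 3:
        raise ValueError("grid needs at least 3 points")
    if (grid < 0).any():
        raise ValueError("grid PCDs must be >= 0")
    if statistic not in ("snr", "mi"):
        raise ValueError(f"unknown statistic {statistic!r}")
    if not replicates:
        raise ValueError("need at least one replicate")

    specs = [
        KernelSpec(pcd=pcd, include_self=include_self, cap=cap, convention=convention)
        for pcd in grid
    ]
    curves = np.full((len(replicates), len(grid)), np.nan)
    failures: list[tuple[int, float, str]] = []
    for ri, rep in enumerate(replicates):
        wells = [rep] if isinstance(rep, CellField) else list(rep)
        rep_scheme = scheme if isinstance(rep, CellField) else "by-group"
        # pairwise distances are shared across the whole grid per well
        responses_per_well = [paracrine_average_grid(w, specs) for w in wells]
        for gi, pcd in enumerate(grid):
            try:
                averaged = [
                    w.with_responses(resp[gi])
                    for w, resp in zip(wells, responses_per_well)
                ]
                pooled = averaged[0] if len(averaged) == 1 else combine_wells(averaged)
                if statistic == "snr":
                    val = snr(pooled, rep_scheme).snr
                else:
                    val = mutual_information(
                        pooled,
                        bin_counts=bin_counts or (4, 6, 8, 10, 12, 16, 20),
                        k_nn=k_nn,
                        pcd=pcd,
                    ).mi_bits
                curves[ri, gi] = val
            except Exception as exc:  # noqa: BLE001 — recorded, not swallowed silently
                failures.append((ri, float(pcd), str(exc)))
                warnings.warn(
                    f"statistic failed for replicate {ri} at pcd={pcd}: {exc}",
                    stacklevel=2,
                )
    if np.isnan(curves).all():
        raise RuntimeError("statistic failed for every (replicate, pcd) pair")

    argmaxes = np.empty(len(replicates))
    for ri in range(len(replicates)):
        y = curves[ri]
        if np.isnan(y).all():
            argmaxes[ri] = np.nan
            continue
        i = int(np.nanargmax(y))
        if i > 0 and i < len(grid) - 1 and np.isfinite(y[i - 1 : i + 2]).all():
            argmaxes[ri] = _parabolic_refine(grid, y, i)
        else:
            argmaxes[ri] = grid[i]
    valid = argmaxes[np.isfinite(argmaxes)]
    mean_arg = float(valid.mean())
    sem = float(valid.std(ddof=1) / math.sqrt(len(valid))) if len(valid) > 1 else None
    return SweepResult(
        pcd_grid=grid,
        curves=curves,
        argmax_per_replicate=argmaxes,
        mean_argmax=mean_arg,
        sem_argmax=sem,
        statistic=statistic,
        mode="diffusion-capped" if cap is not None else "free",
        failures=failures,
    )


def default_grid(start: float = 0.0, stop: float = 600.0, step: float = 10.0) -> np.ndarray:
    """The study's sweep grid: 0-600 um in 10 um steps."""
    return np.arange(start, stop + step / 2.0, step)


__all__ = ["SweepResult", "combine_wells", "default_grid", "sweep_pcd"]
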