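"""Core containers: cell fields, geometry, and the multiplicative noise model.

A :class:`CellField` is the in-memory currency of the whole package: a table of
cells, each with a planar position in micrometers, a scalar response
(max-over-time reporter activity, arbitrary units), and a covariate (ATP dose
in uM, distance to the wound center in um, or distance to a source cell in um).
Positions live in a y-down planar frame; there are no pixel units anywhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

#: canonical CSV column order for on-disk cell tables
CSV_COLUMNS = ["id", "x_um", "y_um", "response", "covariate", "group"]


@dataclass(frozen=True)
class FieldGeometry:
    """Rectangular field geometry, with optional wound disk and source cell.

    ``width``/``height`` are the field extents in um; cells live in
    ``[0, width] x [0, height]``.  ``wound_center``/``wound_radius`` describe a
    circular wound (cells never lie inside the wound disk).  ``source_id`` is
    the id of a designated secreting cell in point-source fields.
    """

    width: float
    height: float
    wound_center: Optional[tuple[float, float]] = None
    wound_radius: Optional[float] = None
    source_id: Optional[int] = None
    min_spacing: float = 0.0

    def to_dict(self) -> dict:
        return {
            "width": self.width,
            "height": self.height,
            "wound_center": list(self.wound_center) if self.wound_center else None,
            "wound_radius": self.wound_radius,
            "source_id": self.source_id,
            "min_spacing": self.min_spacing,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FieldGeometry":
        wc = d.get("wound_center")
        return cls(
            width=float(d["width"]),
            height=float(d["height"]),
            wound_center=tuple(wc) if wc else None,
            wound_radius=d.get("wound_radius"),
            source_id=d.get("source_id"),
            min_spacing=float(d.get("min_spacing", 0.0)),
        )


@dataclass
class CellField:
    """A set of cells with positions, responses and a covariate.

    ``cells`` is a DataFrame with columns ``id, x_um, y_um, response,
    covariate, group`` (extra columns are preserved through I/O).
    """

    cells: pd.DataFrame
    geometry: FieldGeometry
    rng_seed: Optional[int] = None
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in CSV_COLUMNS if c not in self.cells.columns]
        if missing:
            raise ValueError(f"cell table is missing columns {missing}")

    # -- accessors -------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.cells)

    @property
    def positions(self) -> np.ndarray:
        """(n, 2) array of cell centers in um."""
        return self.cells[["x_um", "y_um"]].to_numpy(dtype=float)

    @property
    def responses(self) -> np.ndarray:
        return self.cells["response"].to_numpy(dtype=float)

    @property
    def covariate(self) -> np.ndarray:
        return self.cells["covariate"].to_numpy(dtype=float)

    @property
    def group(self) -> np.ndarray:
        return self.cells["group"].to_numpy(dtype=object)

    def with_responses(self, responses: np.ndarray) -> "CellField":
        """Copy of the field with new responses, everything else unchanged."""
        responses = np.asarray(responses, dtype=float)
        if responses.shape != (self.n,):
            raise ValueError("response vector length does not match cell count")
        cells = self.cells.copy()
        cells["response"] = responses
        return CellField(cells, self.geometry, self.rng_seed, dict(self.params))

    def copy(self) -> "CellField":
        return CellField(
            self.cells.copy(), self.geometry, self.rng_seed, dict(self.params)
        )

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        """Assert the structural invariants of a well-formed field.

        Positions inside the rectangle, no cell inside the wound disk,
        pairwise spacing >= the stated minimum, responses finite and >= 0.
        """
        g = self.geometry
        xy = self.positions
        if self.n:
            if xy[:, 0].min() < -1e-9 or xy[:, 0].max() > g.width + 1e-9:
                raise ValueError("cell x position outside field rectangle")
            if xy[:, 1].min() < -1e-9 or xy[:, 1].max() > g.height + 1e-9:
                raise ValueError("cell y position outside field rectangle")
        r = self.responses
        if not np.all(np.isfinite(r)) or (r < 0).any():
            raise ValueError("responses must be finite and non-negative")
        if g.wound_center is not None and g.wound_radius:
            d = np.hypot(xy[:, 0] - g.wound_center[0], xy[:, 1] - g.wound_center[1])
            if (d < g.wound_radius - 1e-9).any():
                raise ValueError("cell inside the wound disk")
        if g.min_spacing > 0 and self.n > 1:
            from scipy.spatial import cKDTree

            tree = cKDTree(xy)
            dmin = tree.query(xy, k=2)[0][:, 1].min()
            if dmin < g.min_spacing - 1e-9:
                raise ValueError(
                    f"pairwise spacing {dmin:.3f} um below stated minimum "
                    f"{g.min_spacing} um"
                )


@dataclass(frozen=True)
class NoiseModel:
    """Mean-one multiplicative lognormal cell-to-cell noise.

    ``cv`` is the coefficient of variation of the multiplicative factor; the
    lognormal is parameterized so that E[factor] = 1 exactly
    (sigma^2 = ln(1 + cv^2), mu = -sigma^2/2).  ``cv = 0`` is the noiseless
    limit (all factors 1).
    """

    cv: float
    kind: str = "lognormal-multiplicative"

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError("noise cv must be >= 0")
        if self.kind != "lognormal-multiplicative":
            raise ValueError(f"unknown noise kind {self.kind!r}")

    def factors(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """Draw ``n`` iid mean-one factors."""
        if self.cv == 0:
            return np.ones(n)
        sigma2 = math.log1p(self.cv**2)
        mu = -sigma2 / 2.0
        return rng.lognormal(mean=mu, sigma=math.sqrt(sigma2), size=n)


def make_cell_table(
    x: np.ndarray,
    y: np.ndarray,
    response: np.ndarray | float = 0.0,
    covariate: np.ndarray | float = 0.0,
    group: np.ndarray | str = "",
    ids: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Assemble a canonical cell table from column vectors."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if ids is None:
        ids = np.arange(n)
    return pd.DataFrame(
        {
            "id": np.asarray(ids, dtype=int),
            "x_um": x,
            "y_um": np.asarray(y, dtype=float),
            "response": np.broadcast_to(np.asarray(response, dtype=float), (n,)).copy(),
            "covariate": np.broadcast_to(
                np.asarray(covariate, dtype=float), (n,)
            ).copy(),
            "group": np.broadcast_to(np.asarray(group, dtype=object), (n,)).copy(),
        }
    )


__all__ = [
    "CSV_COLUMNS",
    "CellField",
    "FieldGeometry",
    "NoiseModel",
    "make_cell_table",
    "replace",
]
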