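"""Synthetic single-cell fields with the statistical structure of wound-signaling data.

Four generators cover the study conditions every downstream stage assumes:

* :func:`dose_response_field` — multi-well ATP dose response with a saturating
  Hill mean and large multiplicative cell-to-cell noise (pre-averaging SNR
  near 0.9 under the default ladder);
* :func:`wound_field` — a decreasing radial mean response around a circular
  wound (default 300 um diameter) with a >500 um gradient;
* :func:`point_source_field` — mean response decaying as a Gaussian of the
  distance to one designated secreting cell;
* :func:`clustered_field` — spatially clustered layouts whose within-cluster
  response variability decreases with cluster density when responses are
  paracrine-coordinated.

Positions come from :func:`scatter_cells`, a jittered hexagonal lattice that
hits the requested density exactly while guaranteeing a minimum center-to-center
spacing; epithelial monolayers are far closer to such a jittered lattice than
to an ideal Poisson scatter, and the default density (2e-3 cells/um^2, spacing
20 um, about three cell diameters per 100 um) exceeds what sequential random
packing can reach.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .fields import CellField, FieldGeometry, NoiseModel, make_cell_table

#: default monolayer parameters (um, cells/um^2)
DEFAULT_MIN_SPACING = 20.0
DEFAULT_DENSITY = 2e-3

#: default wound scenario
DEFAULT_WOUND = dict(wound_radius=150.0, lam=500.0, amplitude=3.0, baseline=0.3)
DEFAULT_WOUND_CV = 0.6
DEFAULT_WOUND_FIELD_SIZE = 3000.0
#: spatially correlated heterogeneity of wound fields (patchy cell state)
DEFAULT_WOUND_PATCH_CV = 0.3
DEFAULT_WOUND_PATCH_SCALE = 300.0

#: default dose ladder (uM) and Hill curve for the multi-well experiment
DEFAULT_DOSES = (0.1, 0.3, 1.0, 3.0, 10.0, 30.0)
DEFAULT_HILL = dict(rmax=1.0, k=2.0, h=1.2)
#: pre-averaging SNR the default dose experiment is calibrated to
DEFAULT_DOSE_SNR = 0.9


# ---------------------------------------------------------------------------
# positions
# ---------------------------------------------------------------------------

def hex_packing_density(min_spacing: float) -> float:
    """Maximum cell density (cells/um^2) at a given minimum spacing
    (hexagonal close packing of centers)."""
    return 2.0 / (math.sqrt(3.0) * min_spacing**2)


def scatter_cells(
    width: float,
    height: float,
    target_density: float,
    min_spacing: float = DEFAULT_MIN_SPACING,
    seed: int = 0,
) -> CellField:
    """Scatter cell centers at ``target_density`` with pairwise spacing >= ``min_spacing``.

    Centers sit on a hexagonal lattice whose density equals the target, with a
    random global offset and an independent uniform-in-disk jitter per cell.
    The jitter radius is (a - min_spacing)/2 for lattice constant a, so any two
    neighbors remain at least ``min_spacing`` apart by construction.

    Raises
    ------
    ValueError
        if the requested density exceeds 92% of the hexagonal packing bound
        2/(sqrt(3)*min_spacing^2), which leaves no room for jitter.
    """
    if min_spacing <= 0:
        raise ValueError("min_spacing must be > 0")
    if target_density <= 0:
        raise ValueError("target_density must be > 0")
    dmax = hex_packing_density(min_spacing)
    if target_density > 0.92 * dmax:
        raise ValueError(
            f"target density {target_density:g} cells/um^2 infeasible: the "
            f"hexagonal packing bound at spacing {min_spacing} um is "
            f"2/(sqrt(3)*s^2) = {dmax:.3g}, and jitter requires <= 92% of it"
        )
    rng = np.random.default_rng(seed)
    a = math.sqrt(2.0 / (math.sqrt(3.0) * target_density))  # lattice constant
    jitter = (a - min_spacing) / 2.0
    dy = a * math.sqrt(3.0) / 2.0

    # lattice covering the rectangle with one extra ring, random global offset
    off = rng.uniform(0.0, a, size=2)
    rows = np.arange(-1, int(math.ceil(height / dy)) + 2)
    cols = np.arange(-1, int(math.ceil(width / a)) + 2)
    cc, rr = np.meshgrid(cols, rows)
    x = cc * a + (rr % 2) * (a / 2.0) + off[0]
    y = rr * dy + off[1]
    x = x.ravel()
    y = y.ravel()

    theta = rng.uniform(0.0, 2.0 * math.pi, size=x.size)
    rad = jitter * np.sqrt(rng.uniform(0.0, 1.0, size=x.size))
    x = x + rad * np.cos(theta)
    y = y + rad * np.sin(theta)

    keep = (x >= 0) & (x <= width) & (y >= 0) & (y <= height)
    x, y = x[keep], y[keep]
    order = np.lexsort((x, y))
    x, y = x[order], y[order]

    geometry = FieldGeometry(width=width, height=height, min_spacing=min_spacing)
    cells = make_cell_table(x, y)
    return CellField(
        cells,
        geometry,
        rng_seed=seed,
        params={
            "generator": "scatter_cells",
            "target_density": target_density,
            "min_spacing": min_spacing,
            "seed": seed,
        },
    )


# ---------------------------------------------------------------------------
# dose response
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HillCurve:
    """Saturating Hill dose-response mean: rmax * dose^h / (k^h + dose^h)."""

    rmax: float = DEFAULT_HILL["rmax"]
    k: float = DEFAULT_HILL["k"]
    h: float = DEFAULT_HILL["h"]

    def __post_init__(self) -> None:
        if self.rmax <= 0 or self.k <= 0 or self.h <= 0:
            raise ValueError("Hill parameters rmax, k, h must all be > 0")

    def mean(self, dose: float) -> float:
        if dose < 0:
            raise ValueError("dose must be >= 0")
        if dose == 0:
            return 0.0
        dh = dose**self.h
        return self.rmax * dh / (self.k**self.h + dh)


def dose_response_field(
    positions: CellField,
    dose: float,
    hill: HillCurve,
    noise: NoiseModel,
    seed: int = 0,
) -> CellField:
    """Assign Hill-mean responses with multiplicative noise to a positions field.

    response_i = hill.mean(dose) * f_i with f_i iid mean-one lognormal of the
    stated CV; the covariate is the dose and the group label the dose string
    (one well = one dose).
    """
    if dose < 0:
        raise ValueError("dose must be >= 0")
    rng = np.random.default_rng(seed)
    mean = hill.mean(dose)
    f = noise.factors(rng, positions.n)
    out = positions.copy()
    out.cells["response"] = mean * f
    out.cells["covariate"] = float(dose)
    out.cells["group"] = f"dose={dose:g}"
    out.rng_seed = seed
    out.params = dict(
        positions.params,
        generator="dose_response_field",
        dose=dose,
        hill=vars(hill),
        noise_cv=noise.cv,
        seed=seed,
    )
    return out


def calibrated_dose_cv(
    doses: Sequence[float] = DEFAULT_DOSES,
    hill: HillCurve = HillCurve(),
    target_snr: float = DEFAULT_DOSE_SNR,
) -> float:
    """Noise CV that makes the expected pre-averaging SNR of a dose ladder
    equal ``target_snr``.

    With per-dose mean m_d and multiplicative noise of coefficient of
    variation cv, the between-bin variance of means is var_d(m_d) and the
    mean within-bin variance is cv^2 * mean_d(m_d^2), so
    cv = sqrt(var_d(m_d) / (target_snr * mean_d(m_d^2))).
    """
    m = np.array([hill.mean(d) for d in doses])
    return float(math.sqrt(np.var(m, ddof=1) / (target_snr * np.mean(m**2))))


def dose_response_experiment(
    doses: Sequence[float] = DEFAULT_DOSES,
    hill: HillCurve = HillCurve(),
    cv: Optional[float] = None,
    well_size: float = 1000.0,
    density: float = DEFAULT_DENSITY,
    min_spacing: float = DEFAULT_MIN_SPACING,
    seed: int = 0,
) -> list[CellField]:
    """One independently scattered well per dose (the multi-well experiment).

    ``cv=None`` calibrates the noise so the expected pre-averaging SNR of the
    ladder is 0.9, the study's dose-response regime.
    """
    if cv is None:
        cv = calibrated_dose_cv(doses, hill)
    noise = NoiseModel(cv=cv)
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(2 * len(doses))]
    wells = []
    for i, dose in enumerate(doses):
        pos = scatter_cells(well_size, well_size, density, min_spacing, seeds[2 * i])
        wells.append(dose_response_field(pos, dose, hill, noise, seeds[2 * i + 1]))
    return wells


# ---------------------------------------------------------------------------
# wound fields
# ---------------------------------------------------------------------------

def correlated_lognormal_field(
    xy: np.ndarray,
    width: float,
    height: float,
    cv: float,
    corr_length: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Mean-one lognormal factors with Gaussian spatial correlation.

    A white-noise grid (spacing corr_length/3) is smoothed with a Gaussian of
    sigma = ``corr_length``, re-standardized, sampled at the cell positions by
    bilinear interpolation, and exponentiated with the mean-one correction.
    Models patchy cell-state heterogeneity that local averaging cannot remove
    (unlike iid per-cell noise).
    """
    if cv == 0:
        return np.ones(len(xy))
    from scipy.ndimage import gaussian_filter

    h = corr_length / 3.0
    pad = int(math.ceil(3.0 * corr_length / h))
    nx = int(math.ceil(width / h)) + 2 * pad + 1
    ny = int(math.ceil(height / h)) + 2 * pad + 1
    z = gaussian_filter(rng.standard_normal((ny, nx)), sigma=corr_length / h, mode="wrap")
    z = (z - z.mean()) / z.std()
    # bilinear interpolation at cell positions
    gx = np.clip(xy[:, 0] / h + pad, 0, nx - 1.001)
    gy = np.clip(xy[:, 1] / h + pad, 0, ny - 1.001)
    ix, iy = gx.astype(int), gy.astype(int)
    fx, fy = gx - ix, gy - iy
    vals = (
        z[iy, ix] * (1 - fx) * (1 - fy)
        + z[iy, ix + 1] * fx * (1 - fy)
        + z[iy + 1, ix] * (1 - fx) * fy
        + z[iy + 1, ix + 1] * fx * fy
    )
    s = math.sqrt(math.log1p(cv**2))
    return np.exp(vals * s - s**2 / 2.0)

@dataclass(frozen=True)
class GradientProfile:
    """Radial mean-response profile around the wound edge.

    mean(r) = amplitude * shape((r - wound_radius)/lam) + baseline, where
    shape is exp(-u) (default), exp(-u^2/2) ("gaussian"), or (1+u)^-2
    ("power").  ``lam`` sets the gradient extent (>500 um in the study).
    """

    amplitude: float = DEFAULT_WOUND["amplitude"]
    lam: float = DEFAULT_WOUND["lam"]
    baseline: float = DEFAULT_WOUND["baseline"]
    form: str = "exponential"

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("gradient length scale lam must be > 0")
        if self.amplitude < 0 or self.baseline < 0:
            raise ValueError("amplitude and baseline must be >= 0")
        if self.form not in ("exponential", "gaussian", "power"):
            raise ValueError(f"unknown profile form {self.form!r}")

    def mean(self, r: np.ndarray, wound_radius: float) -> np.ndarray:
        u = np.maximum(np.asarray(r, dtype=float) - wound_radius, 0.0) / self.lam
        if self.form == "exponential":
            shape = np.exp(-u)
        elif self.form == "gaussian":
            shape = np.exp(-(u**2) / 2.0)
        else:
            shape = (1.0 + u) ** -2.0
        return self.amplitude * shape + self.baseline


def wound_field(
    positions: CellField,
    wound_center: tuple[float, float],
    wound_radius: float,
    gradient: GradientProfile,
    noise: NoiseModel,
    seed: int = 0,
    patch_cv: float = DEFAULT_WOUND_PATCH_CV,
    patch_scale: float = DEFAULT_WOUND_PATCH_SCALE,
) -> CellField:
    """Radial wound-response field: cells in the wound disk are removed,
    the covariate is the raw distance to the wound CENTER, and
    response_i = mean(covariate_i) * f_i * g(x_i).

    The noise has two mean-one lognormal components: the iid per-cell factor
    f_i (``noise``), and a spatially correlated factor g (``patch_cv``,
    ``patch_scale``) modeling patchy cell-state heterogeneity — the component
    of wound-response variability that paracrine averaging cannot remove.
    ``patch_cv=0`` switches it off.
    """
    if wound_radius < 0:
        raise ValueError("wound_radius must be >= 0")
    rng = np.random.default_rng(seed)
    xy = positions.positions
    r = np.hypot(xy[:, 0] - wound_center[0], xy[:, 1] - wound_center[1])
    keep = r >= wound_radius
    cells = positions.cells.loc[keep].reset_index(drop=True).copy()
    r = r[keep]
    mean = gradient.mean(r, wound_radius)
    f = noise.factors(rng, len(cells))
    g = correlated_lognormal_field(
        xy[keep],
        positions.geometry.width,
        positions.geometry.height,
        patch_cv,
        patch_scale,
        rng,
    )
    cells["response"] = mean * f * g
    cells["covariate"] = r
    cells["group"] = "wound"
    geometry = FieldGeometry(
        width=positions.geometry.width,
        height=positions.geometry.height,
        wound_center=tuple(wound_center),
        wound_radius=float(wound_radius),
        min_spacing=positions.geometry.min_spacing,
    )
    return CellField(
        cells,
        geometry,
        rng_seed=seed,
        params=dict(
            positions.params,
            generator="wound_field",
            wound_center=list(wound_center),
            wound_radius=wound_radius,
            gradient=vars(gradient),
            noise_cv=noise.cv,
            patch_cv=patch_cv,
            patch_scale=patch_scale,
            seed=seed,
        ),
    )


def default_wound_replicate(
    seed: int,
    field_size: float = DEFAULT_WOUND_FIELD_SIZE,
    density: float = DEFAULT_DENSITY,
    cv: float = DEFAULT_WOUND_CV,
    gradient: Optional[GradientProfile] = None,
    patch_cv: float = DEFAULT_WOUND_PATCH_CV,
    patch_scale: float = DEFAULT_WOUND_PATCH_SCALE,
) -> CellField:
    """One wound replicate under the default study conditions
    (square field, centered circular wound of radius 150 um)."""
    ss = np.random.SeedSequence(seed)
    s_pos, s_resp = (int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(2))
    pos = scatter_cells(field_size, field_size, density, DEFAULT_MIN_SPACING, s_pos)
    grad = gradient or GradientProfile()
    return wound_field(
        pos,
        wound_center=(field_size / 2.0, field_size / 2.0),
        wound_radius=DEFAULT_WOUND["wound_radius"],
        gradient=grad,
        noise=NoiseModel(cv=cv),
        seed=s_resp,
        patch_cv=patch_cv,
        patch_scale=patch_scale,
    )


# ---------------------------------------------------------------------------
# point-source fields
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PointSourceProfile:
    """Gaussian mean profile around a secreting cell:
    mean(r) = amplitude * exp(-r^2/(2 sigma^2)) + baseline."""

    amplitude: float = 1.0
    sigma: float = 99.5
    baseline: float = 0.2

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")

    def mean(self, r: np.ndarray) -> np.ndarray:
        r = np.asarray(r, dtype=float)
        return self.amplitude * np.exp(-(r**2) / (2.0 * self.sigma**2)) + self.baseline


def point_source_field(
    positions: CellField,
    source_cell: int,
    profile: PointSourceProfile,
    noise: NoiseModel,
    seed: int = 0,
) -> CellField:
    """Field with one designated secreting cell; the covariate is the distance
    to that cell and the mean response decays as a Gaussian of it.

    The source cell is flagged with group ``"source"`` (everything else gets
    ``"neighbor"``)."""
    ids = positions.cells["id"].to_numpy()
    match = np.flatnonzero(ids == source_cell)
    if match.size != 1:
        raise ValueError(f"unknown source cell id {source_cell!r}")
    rng = np.random.default_rng(seed)
    xy = positions.positions
    src = xy[match[0]]
    r = np.hypot(xy[:, 0] - src[0], xy[:, 1] - src[1])
    mean = profile.mean(r)
    f = noise.factors(rng, positions.n)
    out = positions.copy()
    out.cells["response"] = mean * f
    out.cells["covariate"] = r
    group = np.full(positions.n, "neighbor", dtype=object)
    group[match[0]] = "source"
    out.cells["group"] = group
    out.geometry = FieldGeometry(
        width=positions.geometry.width,
        height=positions.geometry.height,
        source_id=int(source_cell),
        min_spacing=positions.geometry.min_spacing,
    )
    out.rng_seed = seed
    out.params = dict(
        positions.params,
        generator="point_source_field",
        source_cell=int(source_cell),
        profile=vars(profile),
        noise_cv=noise.cv,
        seed=seed,
    )
    return out


def default_point_source_replicate(
    seed: int,
    sigma: float = 99.5,
    amplitude: float = 1.0,
    baseline: float = 0.2,
    cv: float = 0.25,
    field_size: float = 1000.0,
    density: float = DEFAULT_DENSITY,
) -> CellField:
    """A single-source field under the study's point-source conditions
    (~2000 neighbor cells, source at the cell nearest the field center)."""
    ss = np.random.SeedSequence(seed)
    s_pos, s_resp = (int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(2))
    pos = scatter_cells(field_size, field_size, density, DEFAULT_MIN_SPACING, s_pos)
    xy = pos.positions
    center = np.array([field_size / 2.0, field_size / 2.0])
    src = int(pos.cells["id"].iloc[np.argmin(np.hypot(*(xy - center).T))])
    profile = PointSourceProfile(amplitude=amplitude, sigma=sigma, baseline=baseline)
    return point_source_field(pos, src, profile, NoiseModel(cv=cv), seed=s_resp)


# ---------------------------------------------------------------------------
# clustered fields
# ---------------------------------------------------------------------------

def clustered_field(
    n_clusters: int = 60,
    cells_per_cluster_mean: float = 16.0,
    cluster_spread: float = 35.0,
    inter_cluster_min: float = 400.0,
    alpha: float = 0.8,
    cell_cv: float = 0.5,
    comm_distance: float = 20.0,
    mu: float = 1.0,
    seed: int = 0,
) -> CellField:
    """Spatially clustered layout with paracrine-coordinated responses.

    Cluster centers sit on a jittered grid with pairwise separation
    > ``inter_cluster_min`` (must exceed the 200 um maximal communication
    distance so clusters cannot talk to each other).  Member counts are
    uniform in [0.85, 1.15] * ``cells_per_cluster_mean`` and member positions
    Gaussian around the center with a per-cluster spread drawn log-uniformly
    in [0.25, 1.6] * ``cluster_spread`` — the spread variation is what
    produces the wide range of cluster densities.

    Responses interpolate between an uncoordinated per-cell factor f_i and a
    paracrine-coordinated component: response_i = mu * (alpha * a_i +
    (1 - alpha) * f_i), where a_i is the Gaussian-kernel
    (sigma = ``comm_distance``) local average of the per-cell factors.
    Dense, tight clusters average strongly (a_i nearly the cluster mean, so
    the within-cluster SD collapses toward (1-alpha)*cv); sparse clusters
    barely average, keeping full per-cell variability.  alpha = 0 reproduces
    an uncoordinated, Ca2+-like response whose within-cluster SD is
    independent of density.

    The default coordination scale is one cell diameter (20 um), deliberately
    far below the cluster-retention diameter (d_max = 150 um in the cluster
    analysis): retained clusters then span the full range from uncoordinated
    to fully coordinated, which is what gives the density-variability
    signature teeth.  With a coordination scale at the ~100 um communication
    distance, every cluster narrow enough to be retained would already be
    fully coordinated and the signature would be invisible at this cluster
    size.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    if inter_cluster_min <= 200.0:
        raise ValueError(
            "inter_cluster_min must exceed the 200 um maximal communication "
            "distance so clusters are communication-isolated"
        )
    if n_clusters < 1:
        raise ValueError("need at least one cluster")
    rng = np.random.default_rng(seed)

    # cluster centers: jittered grid, spacing 1.5*s and jitter <= 0.25*s keeps
    # center separation >= s = inter_cluster_min
    g = int(math.ceil(math.sqrt(n_clusters)))
    pitch = 1.5 * inter_cluster_min
    margin = 4.0 * cluster_spread * 1.6 + 0.25 * inter_cluster_min
    side = g * pitch + 2 * margin
    idx = rng.permutation(g * g)[:n_clusters]
    cx = (idx % g) * pitch + margin + pitch / 2.0
    cy = (idx // g) * pitch + margin + pitch / 2.0
    cx = cx + rng.uniform(-0.25, 0.25, n_clusters) * inter_cluster_min
    cy = cy + rng.uniform(-0.25, 0.25, n_clusters) * inter_cluster_min

    xs, ys, labels = [], [], []
    for k in range(n_clusters):
        # narrow count range: cluster density is then driven by spatial
        # spread, which is also what sets the coordination strength
        n_k = int(rng.integers(max(2, round(0.85 * cells_per_cluster_mean)),
                               max(2, round(1.15 * cells_per_cluster_mean)) + 1))
        spread_k = cluster_spread * math.exp(
            rng.uniform(math.log(0.25), math.log(1.6))
        )
        xs.append(rng.normal(cx[k], spread_k, n_k))
        ys.append(rng.normal(cy[k], spread_k, n_k))
        labels.extend([f"cluster{k}"] * n_k)
    x = np.clip(np.concatenate(xs), 0.0, side)
    y = np.clip(np.concatenate(ys), 0.0, side)
    n = len(x)

    noise = NoiseModel(cv=cell_cv)
    f = noise.factors(rng, n)
    if alpha > 0:
        from .kernel import KernelSpec, paracrine_average

        carrier = CellField(
            make_cell_table(x, y, response=f),
            FieldGeometry(width=side, height=side),
        )
        averaged = paracrine_average(carrier, KernelSpec(pcd=comm_distance))
        a = averaged.responses
    else:
        a = f
    response = mu * (alpha * a + (1.0 - alpha) * f)

    cells = make_cell_table(x, y, response=response, covariate=0.0, group=np.array(labels, dtype=object))
    return CellField(
        cells,
        FieldGeometry(width=side, height=side),
        rng_seed=seed,
        params={
            "generator": "clustered_field",
            "n_clusters": n_clusters,
            "cells_per_cluster_mean": cells_per_cluster_mean,
            "cluster_spread": cluster_spread,
            "inter_cluster_min": inter_cluster_min,
            "alpha": alpha,
            "cell_cv": cell_cv,
            "comm_distance": comm_distance,
            "mu": mu,
            "seed": seed,
        },
    )


__all__ = [
    "DEFAULT_DENSITY",
    "DEFAULT_MIN_SPACING",
    "DEFAULT_DOSES",
    "DEFAULT_WOUND",
    "GradientProfile",
    "HillCurve",
    "PointSourceProfile",
    "calibrated_dose_cv",
    "clustered_field",
    "default_point_source_replicate",
    "default_wound_replicate",
    "dose_response_experiment",
    "dose_response_field",
    "hex_packing_density",
    "point_source_field",
    "scatter_cells",
    "wound_field",
]
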