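import numpy as np
import pytest

from paracrine.fields import CellField, FieldGeometry, make_cell_table


def make_field(x, y, response=0.0, covariate=0.0, group="", width=None, height=None):
    """Small helper: build a CellField straight from arrays."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    geom = FieldGeometry(
        width=float(width if width is not None else max(x.max(initial=1.0), 1.0)),
        height=float(height if height is not None else max(y.max(initial=1.0), 1.0)),
    )
    return CellField(make_cell_table(x, y, response, covariate, group), geom)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture(scope="session")
def wound_replicates():
    """Shared scaled-down wound replicates for the sweep-based tests."""
    from paracrine.synthetic import default_wound_replicate

    return [default_wound_replicate(seed, field_size=1800.0) for seed in range(6)]


@pytest.fixture(scope="session")
def wound_snr_sweep(wound_replicates):
    from paracrine.sweep import sweep_pcd

    grid = np.arange(0.0, 401.0, 25.0)
    return sweep_pcd(wound_replicates, grid, statistic="snr")


@pytest.fixture(scope="session")
def wound_mi_sweep(wound_replicates):
    from paracrine.sweep import sweep_pcd

    grid = np.arange(0.0, 401.0, 25.0)
    return sweep_pcd(wound_replicates, grid, statistic="mi")
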