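import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

import reportdelay as rd


@pytest.fixture(scope="session")
def null_data():
    """One realisation of the null scenario (no spatial or covariate effects)."""
    return rd.generate(rd.preset("null", seed=11))


@pytest.fixture(scope="session")
def spatial_data():
    """One realisation of the spatial scenario (district effect SD 0.5,
    holiday/survivor/poverty effects, 100 districts, n=3000)."""
    return rd.generate(rd.preset("spatial", seed=7))


@pytest.fixture
def unit_grid():
    """3x3 grid of unit-square 'tracts' with ids 0..8, row-major from the
    bottom-left corner."""
    geoms = [box(c, r, c + 1, r + 1) for r in range(3) for c in range(3)]
    return pd.DataFrame({"tract_id": np.arange(9), "geometry": geoms})


def brute_force_global_moran(values, w_dense):
    """Independent double-sum evaluation of global Moran's I."""
    v = np.asarray(values, dtype=float)
    m = len(v)
    zbar = v.mean()
    num = 0.0
    s0 = 0.0
    for j in range(m):
        for l in range(m):
            s0 += w_dense[j, l]
            num += w_dense[j, l] * (v[j] - zbar) * (v[l] - zbar)
    den = ((v - zbar) ** 2).sum()
    return m / s0 * num / den


def brute_force_local_moran(values, w_dense):
    """Independent direct evaluation of the (m-1)-prefactor local Moran's I."""
    v = np.asarray(values, dtype=float)
    m = len(v)
    zbar = v.mean()
    out = np.zeros(m)
    for j in range(m):
        denom = sum((v[l] - zbar) ** 2 for l in range(m) if l != j)
        lag = sum(w_dense[j, l] * (v[l] - zbar) for l in range(m) if l != j)
        if w_dense[j].sum() == 0:
            out[j] = 0.0
        else:
            out[j] = (m - 1) * (v[j] - zbar) / denom * lag
    return out
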