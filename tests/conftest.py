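import numpy as np
import pytest

from oximsi import (
    AcquisitionSpec,
    build_design,
    default_grid,
    load_extinction_table,
    make_phantom,
    render_cube,
    to_reflectance,
)


@pytest.fixture(scope="session")
def table():
    return load_extinction_table()


@pytest.fixture(scope="session")
def grid():
    return default_grid()


@pytest.fixture(scope="session")
def design(grid):
    return build_design(grid)


@pytest.fixture(scope="session")
def truth():
    """Small post-transplant phantom scene used across modules."""
    return make_phantom((64, 64), "post_utx", seed=1)


@pytest.fixture(scope="session")
def noiseless_acq(grid):
    return AcquisitionSpec(grid=grid, shot_noise=False, read_noise_sd=0.0, seed=2)


@pytest.fixture(scope="session")
def noiseless_bundle(truth, design, noiseless_acq):
    return render_cube(truth, design, noiseless_acq)


@pytest.fixture(scope="session")
def noiseless_cube(noiseless_bundle, grid):
    b = noiseless_bundle
    return to_reflectance(b.raw, b.white, b.dark, grid)


def isosbestic_crossings(table, lo=500.0, hi=620.0):
    """Wavelengths where the packaged oxy/deoxy extinctions cross, by linear
    interpolation between table knots (independent of the design pipeline)."""
    oxy, deoxy = table["oxyhemoglobin"], table["deoxyhemoglobin"]
    w = oxy.wavelengths
    diff = oxy.values - deoxy.values
    sel = (w >= lo) & (w <= hi)
    idx = np.where(np.diff(np.sign(diff)) != 0)[0]
    out = []
    for i in idx:
        if not (sel[i] and sel[i + 1]):
            continue
        frac = diff[i] / (diff[i] - diff[i + 1])
        out.append(float(w[i] + frac * (w[i + 1] - w[i])))
    return out
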