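import warnings

import numpy as np
import pytest

from billclim import gamm, morphometry
from billclim import synthetic_data as sd
from billclim.climate_covariates import SummerSeries

# a reduced-extent, reduced-n study used by most model-level tests
SMALL = dict(
    n=200,
    first_year=1932,
    last_year=1950,
    lat_min=35.5,
    lat_max=38.5,
    lon_min=-122.0,
    lon_max=-119.0,
)


@pytest.fixture(scope="session")
def small_params():
    return sd.GenerativeParams(**SMALL)


@pytest.fixture(scope="session")
def small_sim(small_params):
    """(grid, specimens, info) for a 200-specimen reduced study."""
    return sd.simulate_dataset(small_params, seed=7)


@pytest.fixture(scope="session")
def small_designs(small_sim):
    grid, spec, info = small_sim
    return gamm.build_design(info["covariates"], spec, gamm.ModelSpec(k=15))


@pytest.fixture(scope="session")
def small_response(small_sim):
    _, spec, _ = small_sim
    return morphometry.bill_surface_area(
        spec["bill_length_mm"].to_numpy(),
        spec["bill_width_mm"].to_numpy(),
        spec["bill_depth_mm"].to_numpy(),
    )


@pytest.fixture(scope="session")
def small_fit(small_designs, small_response):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return gamm.fit_gamm(small_designs, small_response)


def make_series(tmin=None, tmax=None, tmean=None, precip=None, years_back=5, n_months=5):
    """Hand-built SummerSeries; unspecified variables default to constants."""
    shape = (years_back, n_months)
    data = {
        "tmin": np.full(shape, 10.0) if tmin is None else np.asarray(tmin, float),
        "tmax": np.full(shape, 20.0) if tmax is None else np.asarray(tmax, float),
        "tmean": np.full(shape, 15.0) if tmean is None else np.asarray(tmean, float),
        "precip": np.full(shape, 5.0) if precip is None else np.asarray(precip, float),
    }
    return SummerSeries(
        collection_year=1930,
        years=np.array([1930 - i for i in range(1, years_back + 1)]),
        months=tuple(range(4, 4 + n_months)),
        data=data,
    )
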