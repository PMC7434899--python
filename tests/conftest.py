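import numpy as np
import pandas as pd
import pytest

from watneeds import (
    CropParameters,
    EngineConfig,
    GrowingSeason,
    SoilProfile,
    WaterCapacity,
    make_preset,
    preset_crops,
)


@pytest.fixture(scope="session")
def crops():
    return preset_crops()


@pytest.fixture
def wheat(crops):
    return crops["wheat"]


@pytest.fixture
def quarter_crop():
    """A crop with equal stage quarters and simple kc values."""
    return CropParameters(
        crop_id="test", kc_ini=0.3, kc_mid=1.2, kc_end=0.6,
        stage_fractions=(0.25, 0.25, 0.25, 0.25),
        zr_rainfed=1.0, zr_irrigated=1.0, p=0.5,
    )


@pytest.fixture
def profile():
    return SoilProfile(theta_diff=200.0, f_max=20.0)


@pytest.fixture
def cap():
    return WaterCapacity(taw=200.0, raw=100.0)


@pytest.fixture
def season():
    return GrowingSeason(planting_doy=100, harvest_doy=219, harvested_area=50.0)


@pytest.fixture
def year_span():
    return pd.date_range("2001-01-01", "2001-12-31", freq="D")


@pytest.fixture(scope="session")
def small_seasonal():
    """A 3x3 seasonal bundle with two forcing years, shared across tests."""
    inputs, cfg = make_preset("seasonal", n_rows=3, n_cols=3,
                              years=[2001, 2002], seed=11)
    return inputs, cfg


def random_point_scenario(rng, n_days):
    """A random but valid point forcing/soil scenario for property tests."""
    precip = np.where(rng.random(n_days) < 0.35,
                      rng.exponential(7.0, n_days), 0.0)
    et0 = rng.uniform(0.0, 8.0, n_days)
    kc = rng.uniform(0.2, 1.3, n_days)
    theta = rng.uniform(100.0, 250.0)
    zr = rng.uniform(0.4, 1.8)
    p = rng.uniform(0.2, 0.7)
    taw = theta * zr
    return dict(
        precip=precip, et0=et0, kc=kc,
        taw=taw, raw=p * taw, f_max=rng.uniform(5.0, 50.0),
        s0=rng.uniform(0.0, taw),
    )
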