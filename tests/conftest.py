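import numpy as np
import pandas as pd
import pytest

from reefstress import DailySeries, LoggerSeries, MMMThreshold, SiteMetadata


@pytest.fixture
def site():
    return SiteMetadata(
        site_id="PH23",
        island="PearlHermes",
        region="NWHI",
        latitude=27.8,
        longitude=-175.8,
        depth_m=23.0,
    )


@pytest.fixture
def equator_site():
    return SiteMetadata(
        site_id="EQ01", island="I0", region="EQ", latitude=0.0, longitude=0.0, depth_m=10.0
    )


def make_daily(values, start="2014-01-01", site=None, kind="temperature"):
    idx = pd.date_range(start, periods=len(values), freq="D")
    return DailySeries(values=pd.Series(np.asarray(values, float), index=idx), kind=kind, site=site)


def make_logger(site, temps, start="2014-01-01", freq="30min"):
    idx = pd.date_range(start, periods=len(temps), freq=freq, tz="UTC")
    return LoggerSeries(site=site, samples=pd.Series(np.asarray(temps, float), index=idx))


@pytest.fixture
def surface_mmm():
    return MMMThreshold(mmm_c=28.0, warmest_month=9)
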