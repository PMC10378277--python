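import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import stcoreg as sc
from stcoreg.covariance import ExponentialMarginal, ProductSumComponent

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def ps(k1, k2, k3, a, b) -> ProductSumComponent:
    return ProductSumComponent(
        k1, k2, k3, ExponentialMarginal(a), ExponentialMarginal(b)
    )


def make_table(records, role="raw") -> sc.ObservationTable:
    df = pd.DataFrame(
        records, columns=["station", "x", "y", "t", "variable", "value"]
    )
    return sc.ObservationTable(df, role=role)


@pytest.fixture(scope="session")
def two_scale_truth() -> sc.STLCM:
    from stcoreg.experiments import default_truth

    return default_truth()


@pytest.fixture(scope="session")
def small_world(two_scale_truth):
    """30 stations x 36 months drawn from the two-scale truth, with mean and
    seasonality, plus the matching residual table."""
    coords = sc.make_station_layout(30, (200.0, 200.0), "uniform", seed=7)
    spec = sc.SimulationSpec(
        model=two_scale_truth,
        coords=coords,
        n_months=36,
        mean={"rn_flux": 20.0, "tm": 12.0},
        seasonal_amplitude={"rn_flux": 5.0, "tm": 8.0},
        seed=2,
    )
    raw, res = sc.STLCMSimulator(spec).simulate()
    return {"raw": raw, "residuals": res, "coords": coords, "truth": two_scale_truth}
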