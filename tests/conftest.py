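import numpy as np
import pandas as pd
import pytest

from ovizip.study_design import TrapObservation
from ovizip.synthetic import ScenarioConfig, simulate_study


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


def make_trap(site="s1", season="early", trap=1, counts=None, status="ok", **kw):
    return TrapObservation(
        city_id=kw.get("city", "tampa"),
        site_id=site,
        site_class=kw.get("site_class", "urban"),
        season=season,
        trap_index=trap,
        counts={"ALB": 0, "AEG": 0, "CQ": 0, "OTHER": 0, **(counts or {})},
        status=status,
    )


@pytest.fixture(scope="session")
def small_study():
    """A compact trap-level synthetic study exercising the full design."""
    cfg = ScenarioConfig(
        urban_sites_per_city=(10, 10, 10),
        cemeteries_per_city=(2, 2, 2),
        grid_size=60,
        seed=77,
    )
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def site_level_study():
    """200 site-seasons drawn directly at the site level (fast fits)."""
    cfg = ScenarioConfig(
        urban_sites_per_city=(34, 33, 33),
        cemeteries_per_city=(0, 0, 0),
        site_level=True,
        seed=5,
    )
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def records_frame(small_study):
    return small_study.records_frame()


@pytest.fixture
def intercept_only_design():
    """Single-city Poisson-style design for oracle comparisons."""
    from ovizip.zip_model import DesignMatrix

    rng = np.random.default_rng(42)
    y = rng.poisson(3.0, size=30)
    n = len(y)
    return DesignMatrix(
        y=y,
        X=np.ones((n, 1)),
        W=np.column_stack([np.ones(n), np.zeros(n)]),
        city_index=np.zeros(n, dtype=int),
        x_names=["intercept"],
        w_names=["zi_intercept", "zi_month"],
        row_meta=pd.DataFrame(
            {
                "site_id": [f"s{i}" for i in range(n)],
                "city_id": "c",
                "site_class": "urban",
                "season": "early",
            }
        ),
        cities=["c"],
    )
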