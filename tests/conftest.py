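import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import loonlakes as ll

settings.register_profile(
    "default",
    settings(derandomize=True, deadline=None,
             suppress_health_check=[HealthCheck.too_slow]),
)
settings.load_profile("default")


def make_lake(lake_id, lat=45.7, lon=-89.5, **kw):
    """A valid lake with all five basic traits, overridable per test."""
    defaults = dict(area_ha=100.0, perimeter_km=4.0, shape_index=0.4,
                    max_depth=10.0, secchi=3.0, ph=7.0, trophic_class="CCC",
                    loon_suitable=True)
    defaults.update(kw)
    return ll.Lake(lake_id=lake_id, name=lake_id, lat=lat, lon=lon, **defaults)


@pytest.fixture
def grid_lakes():
    """25 complete lakes on a ~5x5 grid spanning ~40 km."""
    lakes = []
    rng = np.random.default_rng(7)
    for i in range(5):
        for j in range(5):
            lakes.append(make_lake(
                f"G{i}{j}",
                lat=45.5 + 0.09 * i,
                lon=-89.5 + 0.13 * j,
                ph=float(rng.uniform(5, 9)),
                area_ha=float(rng.uniform(20, 500)),
                secchi=float(rng.uniform(1, 6)),
                max_depth=float(rng.uniform(3, 40)),
                shape_index=float(rng.uniform(0.4, 3.0)),
            ))
    return lakes


@pytest.fixture
def three_lake_instance():
    """Worked pool example: natal pH 7, pool pH {6, 7, 8}, one visit to the
    pH-7 lake (observed difference 0)."""
    lakes = [
        make_lake("N", lat=45.70, lon=-89.50, ph=7.0),
        make_lake("A", lat=45.72, lon=-89.50, ph=6.0),
        make_lake("B", lat=45.74, lon=-89.50, ph=7.0),
        make_lake("C", lat=45.76, lon=-89.50, ph=8.0),
    ]
    visits = [ll.VisitRecord("J1", "N", "B")]
    return lakes, visits
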