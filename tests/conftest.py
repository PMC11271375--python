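import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from pseudosurvey import (GrtsEngine, SampleFrame, clip_grid, default_surface,
                          make_estuary, make_hex_grid)


@pytest.fixture(scope="session")
def square_frame():
    """10 km x 10 km square frame."""
    return SampleFrame.from_polygons([box(0, 0, 10, 10)])


@pytest.fixture(scope="session")
def estuary():
    """Shared synthetic estuary (multi-lobed, with river arms)."""
    return make_estuary(seed=1)


@pytest.fixture(scope="session")
def surface():
    return default_surface()


@pytest.fixture(scope="session")
def estuary_grid(estuary):
    return clip_grid(make_hex_grid(estuary.frame, 45), estuary.frame)


@pytest.fixture(scope="session")
def square_engine(square_frame):
    return GrtsEngine(square_frame, n_max=45)


@pytest.fixture(scope="session")
def estuary_engine(estuary):
    return GrtsEngine(estuary.frame, n_max=45)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def make_record(**kw):
    """A clean in-window record; override fields per test."""
    base = dict(site_id="S1", source="STATE", x=5.0, y=5.0,
                datetime="2015-07-10T10:00:00", parameter="CHLA", value=3.0,
                unit="ug/L", qualifiers="", mdl=np.nan, pql=np.nan, depth_m=0.5)
    base.update(kw)
    return base


@pytest.fixture()
def record_factory():
    return make_record


@pytest.fixture(scope="session")
def two_source_records(estuary, surface):
    """Targeted multi-year + probabilistic single-year record tables."""
    from pseudosurvey import SamplingScript, sample_records

    targeted = SamplingScript(source="STATE", mode="targeted", n_sites=40,
                              years=(2015, 2016, 2017, 2018, 2019),
                              alt_unit_fraction=0.1, seed=11)
    prob = SamplingScript(source="NATIONAL", mode="probabilistic", n_sites=30,
                          years=(2015,), dropout=0.0, seed=12)
    return pd.concat([sample_records(estuary, surface, targeted),
                      sample_records(estuary, surface, prob)], ignore_index=True)
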