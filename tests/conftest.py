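import numpy as np
import pytest

from isocanopy import pipeline as pl
from isocanopy import stand_structure as ss
from isocanopy import synthetic_data as sd
from isocanopy.leaf_gas_exchange import PhotosynthesisParams


@pytest.fixture(scope="session")
def week_weather():
    """One mid-summer week of half-hourly forcing (deterministic)."""
    cfg = sd.WeatherConfig(start_year=2012, end_year=2012, seed=7)
    w = sd.generate_weather(cfg)
    return w[(w.timestamp >= "2012-07-01") & (w.timestamp < "2012-07-08")].reset_index(drop=True)


@pytest.fixture(scope="session")
def year_weather():
    """One full synthetic year (deterministic)."""
    return sd.generate_weather(sd.WeatherConfig(start_year=2012, end_year=2012, seed=7))


@pytest.fixture(scope="session")
def stand_grids():
    """(pre-thinning, post-thinning) canopy grids of the default harvest plot."""
    pre_df, post_df = sd.generate_stand(sd.make_harvest_config(seed=1))
    grid_pre = ss.build_lad(ss.inventory_from_frame(pre_df))
    grid_post = ss.build_lad(ss.inventory_from_frame(post_df))
    return grid_pre, grid_post


@pytest.fixture(scope="session")
def target_tree(stand_grids):
    """A suppressed spruce that survives the thinning."""
    pre_df, post_df = sd.generate_stand(sd.make_harvest_config(seed=1))
    spruce = [t for t in ss.inventory_from_frame(post_df) if t.species == "spruce"][0]
    return pl.target_tree_from_record(spruce, stand_grids[0])


@pytest.fixture
def leaf_params():
    return PhotosynthesisParams()


@pytest.fixture
def fixed_leaf_state():
    """A hand-specified leaf state for term-by-term discrimination checks."""
    from isocanopy.leaf_gas_exchange import LeafState

    def arr(x):
        return np.asarray(float(x))

    return LeafState(
        an=arr(10.0), rd=arr(1.0), gamma_star=arr(40.0),
        gs_co2=arr(0.1), gs_h2o=arr(0.16), gb_co2=arr(1.0), gb_h2o=arr(1.37),
        ca=arr(400.0), cs=arr(380.0), ci=arr(300.0), cc=arr(250.0),
        dl=arr(1.0), tleaf=arr(20.0), e=arr(0.002), w_i=arr(0.023),
        converged=np.asarray(True),
    )
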