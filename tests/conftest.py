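import datetime as dt

import numpy as np
import pytest

from trophlink.data_io import (
    Dataset,
    PreyItem,
    SpecimenRecord,
    StationRecord,
    StomachRecord,
    TrawlEvent,
)


@pytest.fixture(scope="session")
def survey():
    """Default synthetic survey, shared read-only across tests."""
    from trophlink.synthetic_data import make_survey

    return make_survey(seed=1)


@pytest.fixture()
def toy_dataset():
    """Three linked records per table: the smallest valid survey."""
    stations = [StationRecord(
        station_id="ST01", latitude=-3.8, longitude=-32.4,
        date=dt.date(2017, 4, 20), sunrise=dt.time(5, 40), sunset=dt.time(17, 30))]
    t0 = dt.datetime(2017, 4, 20, 12, 0)
    trawls = [TrawlEvent(
        trawl_id="TR01", station_id="ST01", start_time=t0,
        end_time=t0 + dt.timedelta(minutes=30), depth_min_m=700,
        depth_max_m=780, mouth_area_m2=120.0, diel_period="day")]
    specimens = [
        SpecimenRecord(specimen_id=f"VP{i}", trawl_id="TR01",
                       taxon="Chauliodus sloani",
                       standard_length_cm=sl, total_weight_g=tw)
        for i, (sl, tw) in enumerate([(12.0, 6.0), (17.5, 18.0), (14.9, 10.0)])]
    stomachs = [
        StomachRecord(specimen_id="VP0", is_empty=False, items=[
            PreyItem(category="Myctophidae", count=2, weight_g=0.5)]),
        StomachRecord(specimen_id="VP1", is_empty=True, items=[]),
        StomachRecord(specimen_id="VP2", is_empty=False, items=[
            PreyItem(category="Euphausiidae", count=1, weight_g=0.1)]),
    ]
    return Dataset(stations=stations, trawls=trawls, specimens=specimens,
                   stomachs=stomachs)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
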