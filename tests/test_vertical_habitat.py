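import datetime as dt

import numpy as np
import pytest

from trophlink.data_io import CTDProfile, Dataset, SpecimenRecord, TrawlEvent
from trophlink.vertical_habitat import (
    classify_diel,
    cpue,
    default_strata,
    habitat_envelope,
    label_trawls,
    mean_profile,
    occupied_intervals,
    size_by_depth,
    stratify,
)

SUNRISE, SUNSET = dt.time(6, 0), dt.time(18, 0)


def at(hhmm):
    h, m = divmod(hhmm, 100)
    return dt.datetime(2017, 4, 20, h, m)


class TestDielRule:
    @pytest.mark.parametrize("time,expected", [
        (1200, "day"),
        (630, "twilight"),     # dawn, discarded downstream
        (2300, "night"),
        (700, "day"),          # exactly sunrise + 1 h
        (1700, "day"),         # exactly sunset - 1 h
        (1730, "twilight"),    # dusk window
        (1900, "night"),       # exactly sunset + 1 h
        (500, "night"),        # exactly sunrise - 1 h
    ])
    def test_windows(self, time, expected):
        assert classify_diel(at(time), SUNRISE, SUNSET) == expected

    def test_missing_solar_times_error(self):
        with pytest.raises(ValueError):
            classify_diel(at(1200), None, SUNSET)


class TestCPUE:
    @pytest.mark.parametrize("count,w,dur,area,expected", [
        (30, 0.3, 0.5, 120.0, (60.0, 0.6)),
        (30, 0.3, 1.0, 60.0, (60.0, 0.6)),   # area standardization x2
        (0, 0.0, 1.0, 120.0, (0.0, 0.0)),
    ])
    def test_standardization(self, count, w, dur, area, expected):
        n, kg = cpue(count, w, dur, area)
        assert (n, kg) == pytest.approx(expected)

    def test_invalid_effort_rejected(self):
        with pytest.raises(ValueError):
            cpue(1, 0.1, 0.0, 120.0)
        with pytest.raises(ValueError):
            cpue(1, 0.1, 1.0, -5.0)

    def test_split_invariance(self):
        """Splitting one trawl into two half-duration halves preserves the mean."""
        whole = cpue(30, 0.3, 1.0, 120.0)
        half_a = cpue(15, 0.15, 0.5, 120.0)
        half_b = cpue(15, 0.15, 0.5, 120.0)
        assert np.mean([half_a, half_b], axis=0) == pytest.approx(whole)


def _mini_survey(toy_station):
    t0 = dt.datetime(2017, 4, 20, 12, 0)
    trawls = [
        TrawlEvent(trawl_id="T1", station_id="ST01", start_time=t0,
                   end_time=t0 + dt.timedelta(minutes=30),
                   depth_min_m=610, depth_max_m=690, mouth_area_m2=120.0),
        TrawlEvent(trawl_id="T2", station_id="ST01",
                   start_time=dt.datetime(2017, 4, 20, 23, 0),
                   end_time=dt.datetime(2017, 4, 20, 23, 30),
                   depth_min_m=420, depth_max_m=480, mouth_area_m2=60.0),
    ]
    specimens = (
        [SpecimenRecord(specimen_id=f"a{i}", trawl_id="T1",
                        taxon="Chauliodus sloani",
                        standard_length_cm=15.0, total_weight_g=10.0)
         for i in range(30)]
        + [SpecimenRecord(specimen_id=f"b{i}", trawl_id="T2",
                          taxon="Chauliodus sloani",
                          standard_length_cm=10.0, total_weight_g=5.0)
           for i in range(4)])
    return Dataset(stations=[toy_station], trawls=trawls, specimens=specimens)


@pytest.fixture()
def mini_survey(toy_dataset):
    return _mini_survey(toy_dataset.stations[0])


class TestStratify:
    def test_single_cell_arithmetic(self, mini_survey):
        label_trawls(mini_survey)
        table = stratify(mini_survey)
        cell = table[(table.stratum_lower_m == 600) & (table.period == "day")].iloc[0]
        assert cell.n_trawls == 1
        assert cell.cpue_n == pytest.approx(60.0)   # 30 fish / 0.5 h at 120 m2
        cell2 = table[(table.stratum_lower_m == 400) & (table.period == "night")].iloc[0]
        assert cell2.cpue_n == pytest.approx(4 / 0.5 * 2)  # 60 m2 mouth doubles

    def test_unsampled_cells_missing_not_zero(self, mini_survey):
        label_trawls(mini_survey)
        table = stratify(mini_survey)
        empty = table[(table.stratum_lower_m == 800) & (table.period == "night")]
        assert empty.iloc[0].n_trawls == 0
        assert np.isnan(empty.iloc[0].cpue_n)

    def test_stratum_tiling_conserves_specimens(self, survey):
        label_trawls(survey)
        table = size_by_depth(survey)
        labeled = {t.trawl_id for t in survey.trawls
                   if t.diel_period in ("day", "night")}
        n_specimens = sum(1 for s in survey.specimens if s.trawl_id in labeled)
        assert table["n"].sum() == n_specimens

    def test_every_trawl_maps_to_one_stratum(self, survey):
        label_trawls(survey)
        strata = default_strata()
        for t in survey.trawls:
            hits = [(lo, hi) for lo, hi in strata
                    if lo <= t.midpoint_depth_m < hi]
            assert len(hits) == 1

    def test_modal_daytime_stratum_in_peak_band(self, survey):
        label_trawls(survey)
        table = stratify(survey)
        day = table[(table.period == "day") & table.cpue_n.notna()]
        lo = day.loc[day.cpue_n.idxmax(), "stratum_lower_m"]
        assert 700 <= lo <= 800   # stratum within the 700-900 m daytime band

    def test_survey_without_night_trawls(self, mini_survey):
        mini_survey.trawls = [t for t in mini_survey.trawls if t.trawl_id == "T1"]
        mini_survey.specimens = [s for s in mini_survey.specimens
                                 if s.trawl_id == "T1"]
        label_trawls(mini_survey)
        table = stratify(mini_survey)
        night = table[table.period == "night"]
        assert (night.n_trawls == 0).all()


class TestSizeByDepth:
    def test_generator_trend_day_large_deeper(self, survey):
        label_trawls(survey)
        table = size_by_depth(survey)
        day = table[(table.period == "day") & (table.n > 0)]
        shallow = day[day.stratum_upper_m <= 500]
        deep = day[day.stratum_lower_m >= 500]
        mean_shallow = np.average(shallow.mean_SL_cm, weights=shallow.n)
        mean_deep = np.average(deep.mean_SL_cm, weights=deep.n)
        assert mean_deep > mean_shallow

    def test_single_specimen_cell_median(self, mini_survey):
        mini_survey.specimens = mini_survey.specimens[:1]
        label_trawls(mini_survey)
        table = size_by_depth(mini_survey)
        cell = table[(table.stratum_lower_m == 600) & (table.period == "day")].iloc[0]
        assert cell.n == 1 and cell.median_SL_cm == 15.0

    def test_empty_cell_has_missing_stats(self, mini_survey):
        label_trawls(mini_survey)
        table = size_by_depth(mini_survey)
        cell = table[(table.stratum_lower_m == 100) & (table.period == "day")].iloc[0]
        assert cell.n == 0 and np.isnan(cell.mean_SL_cm)


def linear_profile(station_id="ST01"):
    z = np.arange(0.0, 1001.0, 10.0)
    return CTDProfile(
        station_id=station_id, depth_m=z.tolist(),
        temperature_C=(30 - 0.025 * z).tolist(),
        oxygen_ml_l=np.full_like(z, 3.0).tolist(),
        salinity=np.full_like(z, 35.0).tolist(),
        fluorescence=np.zeros_like(z).tolist())


class TestEnvelope:
    def test_linear_profile_envelope(self):
        env = habitat_envelope([(400.0, 1000.0)], [linear_profile()])
        assert env.temp_min == pytest.approx(5.0, abs=1e-6)
        assert env.temp_max == pytest.approx(20.0, abs=1e-6)

    def test_single_depth_min_equals_max(self):
        env = habitat_envelope([(500.0, 500.0)], [linear_profile()])
        assert env.temp_min == env.temp_max == pytest.approx(17.5, abs=1e-6)

    def test_out_of_coverage_interval_rejected(self):
        with pytest.raises(ValueError, match="coverage"):
            habitat_envelope([(900.0, 1500.0)], [linear_profile()])

    def test_envelope_monotone_under_interval_growth(self):
        small = habitat_envelope([(500.0, 700.0)], [linear_profile()])
        big = habitat_envelope([(400.0, 900.0)], [linear_profile()])
        assert big.temp_min <= small.temp_min
        assert big.temp_max >= small.temp_max

    def test_default_generator_envelope_in_observed_band(self, survey):
        """Occupancy at 400-1000 m sits inside 4-13 degC, as observed at sea."""
        env = habitat_envelope([(400.0, 1000.0)], survey.ctd)
        assert 4.0 <= env.temp_min and env.temp_max <= 13.0
        assert 2.0 <= env.oxy_min and env.oxy_max <= 4.2

    def test_truncated_casts_contribute_over_their_range(self):
        full = linear_profile("A")
        z = np.arange(0.0, 501.0, 10.0)
        shallow = CTDProfile(
            station_id="B", depth_m=z.tolist(),
            temperature_C=(20 - 0.01 * z).tolist(),
            oxygen_ml_l=np.full_like(z, 2.0).tolist(),
            salinity=np.full_like(z, 35.0).tolist(),
            fluorescence=np.zeros_like(z).tolist())
        prof = mean_profile([full, shallow])
        assert prof[prof.depth_m == 400].iloc[0].n_casts == 2
        assert prof[prof.depth_m == 800].iloc[0].n_casts == 1
        # above 500 m the mean blends both casts
        t400 = prof[prof.depth_m == 400].iloc[0].temperature_C
        assert t400 == pytest.approx(((30 - 10) + (20 - 4)) / 2, abs=1e-9)


class TestOccupiedIntervals:
    def test_contiguous_merge(self, survey):
        label_trawls(survey)
        intervals = occupied_intervals(stratify(survey))
        assert intervals == [(400.0, 1000.0)]
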