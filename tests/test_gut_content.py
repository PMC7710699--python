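import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trophlink.data_io import PreyItem, SpecimenRecord, StomachRecord
from trophlink.gut_content import (
    EmptyInputError,
    StomachSummary,
    diet_indices,
    diet_table,
    levins_index,
    split_size_classes,
    summarize_stomachs,
    vacuity_index,
)


def stomach(sid, *items):
    return StomachRecord(specimen_id=sid, is_empty=not items, items=list(items))


def prey(cat, count=1, w=0.1):
    return PreyItem(category=cat, count=count, weight_g=w)


def specimen(sid, sl, trawl="TR01"):
    return SpecimenRecord(specimen_id=sid, trawl_id=trawl,
                          taxon="Chauliodus sloani",
                          standard_length_cm=sl, total_weight_g=1 + sl)


class TestVacuity:
    @pytest.mark.parametrize("ne,nv,expected_pct,rounded", [
        (197, 121, 61.42, 61),   # pooled sizes
        (55, 39, 70.91, 71),     # small size class
        (142, 82, 57.75, 58),    # large size class
        (10, 0, 0.0, 0),
    ])
    def test_vacuity_values(self, ne, nv, expected_pct, rounded):
        vi = vacuity_index(StomachSummary(Ne=ne, Nv=nv))
        assert vi == pytest.approx(expected_pct, abs=0.01)
        assert round(vi) == rounded

    def test_zero_examined_undefined(self):
        with pytest.raises(EmptyInputError):
            vacuity_index(StomachSummary(Ne=0, Nv=0))

    def test_pooled_vi_is_count_weighted_mean_of_periods(self, rng):
        """VI(pooled)*Ne == VI(day)*Ne_day + VI(night)*Ne_night exactly."""
        day = [stomach(f"d{i}", *( [prey("Myctophidae")] if rng.uniform() > 0.7 else []))
               for i in range(37)]
        night = [stomach(f"n{i}", *( [prey("Myctophidae")] if rng.uniform() > 0.5 else []))
                 for i in range(23)]
        vi_d = vacuity_index(summarize_stomachs(day))
        vi_n = vacuity_index(summarize_stomachs(night))
        vi_p = vacuity_index(summarize_stomachs(day + night))
        assert vi_p * 60 == pytest.approx(vi_d * 37 + vi_n * 23, abs=1e-9)


class TestDietIndices:
    def test_hand_computed_toy_set(self):
        stomachs = [
            stomach("S1", prey("Myctophidae", count=2, w=0.5)),
            stomach("S2", prey("Euphausiidae", count=1, w=0.1)),
            stomach("S3", prey("Myctophidae", count=1, w=0.4)),
        ]
        rows = diet_indices(stomachs).set_index("category")
        myct = rows.loc["Myctophidae"]
        assert myct["FO_pct"] == pytest.approx(100 * 2 / 3, abs=0.01)
        assert myct["N_pct"] == pytest.approx(75.0)
        assert myct["W_pct"] == pytest.approx(90.0)

    def test_single_category_is_100_everywhere(self):
        rows = diet_indices([stomach("S1", prey("Myctophidae", 3, 0.7))])
        assert rows.iloc[0][["FO_pct", "N_pct", "W_pct"]].tolist() == [100, 100, 100]

    def test_absent_category_row_omitted(self):
        rows = diet_indices([stomach("S1", prey("Myctophidae"))])
        assert "Euphausiidae" not in rows["category"].tolist()

    def test_percentages_sum_to_100(self, rng):
        cats = ["A", "B", "C", "D"]
        stomachs = [
            stomach(f"S{i}", *[prey(rng.choice(cats), int(rng.integers(1, 4)),
                                    float(rng.uniform(0.05, 2)))
                               for _ in range(rng.integers(1, 5))])
            for i in range(30)]
        rows = diet_indices(stomachs)
        assert rows["N_pct"].sum() == pytest.approx(100, abs=1e-6)
        assert rows["W_pct"].sum() == pytest.approx(100, abs=1e-6)

    def test_all_empty_is_an_error(self):
        with pytest.raises(EmptyInputError):
            diet_indices([stomach("S1"), stomach("S2")])


class TestLevins:
    def test_uniform_diet_upper_bound(self):
        assert levins_index([0.2] * 5) == pytest.approx(1.0)

    def test_single_item_lower_bound(self):
        assert levins_index([1.0, 0, 0, 0, 0], n=5) == pytest.approx(0.0)

    def test_hand_computed_value(self):
        assert levins_index([0.5, 0.3, 0.2]) == pytest.approx(
            (1 / 0.38 - 1) / 2, abs=1e-9)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(st.floats(0.01, 1.0), min_size=2, max_size=8))
    def test_permutation_invariance_and_bounds(self, raw):
        p = np.array(raw) / np.sum(raw)
        b = levins_index(p)
        assert -1e-12 <= b <= 1 + 1e-12
        perm = np.random.default_rng(0).permutation(p)
        assert levins_index(perm) == pytest.approx(b, abs=1e-12)

    def test_concentration_strictly_lowers_breadth(self):
        """Shifting mass onto the largest component (majorization) lowers Bj."""
        p = np.array([0.4, 0.3, 0.2, 0.1])
        for eps in (0.05, 0.1, 0.2):
            q = p.copy()
            q[0] += eps
            q[3] -= eps
            if q[3] < 0:
                continue
            assert levins_index(q) < levins_index(p)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            levins_index([0.6, 0.3])          # not normalized
        with pytest.raises(ValueError):
            levins_index([1.0], n=1)           # n < 2
        with pytest.raises(ValueError):
            levins_index([0.5, 0.3, 0.2], n=2)  # n below nonzero categories


class TestSizeClasses:
    def test_boundary_and_membership(self):
        specs = [specimen("a", 14.9), specimen("b", 15.0), specimen("c", 20.0)]
        part = split_size_classes(specs)
        assert [s.specimen_id for s in part["small"]] == ["a"]
        assert [s.specimen_id for s in part["large"]] == ["b", "c"]
        assert len(part["pooled"]) == 3

    def test_empty_input(self):
        part = split_size_classes([])
        assert part == {"small": [], "large": [], "pooled": []}


class TestDietTable:
    def test_tables_match_component_functions(self):
        specs = [specimen("S1", 12.0), specimen("S2", 18.0), specimen("S3", 13.0)]
        stomachs = [
            stomach("S1", prey("Myctophidae", 2, 0.5)),
            stomach("S2", prey("Diaphus sp.", 1, 0.8)),
            stomach("S3"),
        ]
        tables = diet_table(stomachs, specs)
        assert tables["pooled"].VI_pooled == pytest.approx(100 / 3)
        assert tables["small"].summary.Ne == 2
        assert tables["large"].summary.Nv == 0
        small_rows = tables["small"].rows.set_index("category")
        assert small_rows.loc["Myctophidae", "W_pct"] == pytest.approx(100.0)

    def test_group_without_stomachs_flagged_empty(self):
        specs = [specimen("S1", 12.0), specimen("S2", 18.0)]
        stomachs = [stomach("S1", prey("Myctophidae"))]
        tables = diet_table(stomachs, specs)
        assert tables["large"].is_empty
        assert tables["large"].Bj is None

    def test_missing_night_vi_is_none_not_zero(self):
        specs = [specimen("S1", 12.0), specimen("S2", 13.0)]
        stomachs = [stomach("S1", prey("Myctophidae")), stomach("S2")]
        tables = diet_table(stomachs, specs,
                            diel_by_specimen={"S1": "day", "S2": "day"})
        assert tables["pooled"].VI_day is not None
        assert tables["pooled"].VI_night is None

    def test_synthetic_survey_is_myctophid_dominated(self, survey):
        tables = diet_table(survey.stomachs, survey.specimens)
        rows = tables["pooled"].rows.sort_values("W_pct", ascending=False)
        top3 = set(rows["category"].head(3))
        fish_categories = {"Myctophidae", "Diaphus sp.", "Unidentified Teleostei",
                           "Hygophum sp.", "Chauliodus sloani"}
        assert top3 <= fish_categories
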