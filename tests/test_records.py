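import datetime as dt

import numpy as np
import pytest

from herdlife.records import (MISSING, CullingGroup, apply_quality_control,
                              assign_culling_group, build_longevity_panel,
                              read_records, summarize_life_histories,
                              write_records)
from tests.conftest import make_record


class TestQualityControl:
    def test_toy_set_removal_counts_match_manual_filtering(self, toy_records):
        kept, report = apply_quality_control(toy_records)
        assert len(kept) == 7
        assert report.removed["first_calving_window"] == 1
        assert report.removed["birth_before_1990"] == 1
        assert report.removed["culling_age_over_20"] == 1
        assert report.removed["missing_fields"] == 0
        assert report.n_retained == 7
        report.check()

    def test_first_calving_at_18_months_removed(self):
        kept, report = apply_quality_control(
            [make_record(1, fca=18.0, calv=[18.0])])
        assert kept == []
        assert report.removed["first_calving_window"] == 1

    def test_empty_input(self):
        kept, report = apply_quality_control([])
        assert kept == []
        assert report.n_input == 0
        assert all(v == 0 for v in report.removed.values())

    def test_missing_fields_and_duplicates(self):
        recs = [
            make_record(1),
            make_record(2, herd=None),
            make_record(3), make_record(3),  # two culling records
        ]
        kept, report = apply_quality_control(recs)
        assert [r.cow_id for r in kept] == [1]
        assert report.removed["missing_fields"] == 1
        assert report.removed["duplicate_culling"] == 2


class TestCullingGroups:
    @pytest.mark.parametrize(
        "code, age, expected",
        [
            ("unknown_reason", 16.0, CullingGroup.NATURAL_DEATH),
            ("unknown_reason", 10.0, CullingGroup.MISCELLANEOUS),
            ("feet_conformation", 6.0, CullingGroup.STRUCTURAL_PROBLEMS),
            ("fertility", 15.5, CullingGroup.NATURAL_DEATH),  # age override
            ("illness_disease", 5.0, CullingGroup.DISEASE),
            ("temperament", 7.0, CullingGroup.PERFORMANCE),
        ],
    )
    def test_group_assignment(self, code, age, expected):
        assert assign_culling_group(code, age) is expected

    def test_unmapped_code_raises_listing_code(self):
        with pytest.raises(KeyError, match="not_a_code"):
            assign_culling_group("not_a_code", 5.0)


class TestLongevityPanels:
    def cow(self):
        # culled at 5.6 y, calvings assigned to ages 2, 3, 4
        return make_record(1, fca=24.0, calv=[24.0, 36.0, 48.0], cull=5.6)

    def test_hand_coded_example_all_three_definitions(self):
        rec = [self.cow()]
        tl = build_longevity_panel(rec, "TL").codes[0]
        fla = build_longevity_panel(rec, "FLa").codes[0]
        flb = build_longevity_panel(rec, "FLb").codes[0]
        assert list(tl) == [1, 1, 1, 1] + [0] * 10
        assert list(fla) == [1, 1, 1] + [0] * 11
        assert list(flb) == [1, 1, 1, MISSING] + [0] * 10

    def test_boundary_cow_culled_at_exactly_two(self):
        rec = [make_record(1, calv=[24.0], cull=2.0)]
        for d in ("TL", "FLa", "FLb"):
            codes = build_longevity_panel(rec, d).codes[0]
            assert list(codes) == [1] + [0] * 13

    def test_panel_has_14_age_columns(self, toy_records):
        kept, _ = apply_quality_control(toy_records)
        panel = build_longevity_panel(kept, "TL")
        assert panel.codes.shape == (len(kept), 14)
        assert list(panel.ages) == list(range(2, 16))

    def test_tl_monotone_and_no_missing(self, toy_records):
        kept, _ = apply_quality_control(toy_records)
        for d in ("TL", "FLa"):
            codes = build_longevity_panel(kept, d).codes
            assert not np.any(codes == MISSING)
        tl = build_longevity_panel(kept, "TL").codes
        assert np.all(np.diff(tl.astype(int), axis=1) <= 0)

    def test_flb_never_missing_after_culling(self, toy_records):
        kept, _ = apply_quality_control(toy_records)
        panel = build_longevity_panel(kept, "FLb")
        for i, r in enumerate(kept):
            after = panel.ages > r.completed_culling_age
            assert not np.any(panel.codes[i, after] == MISSING)

    def test_recoding_is_idempotent(self, toy_records):
        kept, _ = apply_quality_control(toy_records)
        a = build_longevity_panel(kept, "FLb").codes
        b = build_longevity_panel(kept, "FLb").codes
        assert np.array_equal(a, b)

    def test_missing_culling_age_raises(self):
        rec = make_record(1)
        rec.culling_age = None
        with pytest.raises(ValueError, match="culling age"):
            build_longevity_panel([rec], "TL")

    def test_subset_group(self):
        recs = [make_record(1, reason="fertility"),
                make_record(2, reason="illness_disease")]
        panel = build_longevity_panel(recs, "TL")
        sub = panel.subset_group("disease")
        assert list(sub.cow_ids) == [2]
        assert panel.subset_group("all_reasons").n_cows == 2


class TestSummaries:
    def test_single_cow(self):
        out = summarize_life_histories([make_record(1, cull=8.0)])
        row = out["by_group"].iloc[0]
        assert row["mean_culling_age"] == pytest.approx(8.0)
        # sample SD of one value is undefined (NaN), reported as such
        assert np.isnan(row["sd_culling_age"])

    def test_toy_mean_and_sample_sd(self):
        recs = [make_record(i, cull=c, reason="fertility")
                for i, c in enumerate([4.0, 6.0, 8.0])]
        out = summarize_life_histories(recs)
        grp = out["by_group"]
        fert = grp[grp["group"] == "fertility"].iloc[0]
        assert fert["mean_culling_age"] == pytest.approx(6.0)
        assert fert["sd_culling_age"] == pytest.approx(2.0)

    def test_all_reasons_row_equals_sum_of_groups(self):
        recs = [make_record(1, reason="fertility"),
                make_record(2, reason="temperament"),
                make_record(3, reason="died_unknown")]
        grp = summarize_life_histories(recs)["by_group"]
        total = grp[grp["group"] == "all_reasons"]["n"].iloc[0]
        assert total == grp[grp["group"] != "all_reasons"]["n"].sum() == 3


def test_records_roundtrip_through_delimited_text(tmp_path, toy_records):
    path = tmp_path / "records.csv"
    write_records(toy_records, path)
    back, errors = read_records(path)
    assert errors == []
    assert len(back) == len(toy_records)
    for a, b in zip(toy_records, back):
        assert a.cow_id == b.cow_id
        assert a.birth_date == b.birth_date
        assert a.calving_ages == b.calving_ages
        assert a.culling_age == b.culling_age
        assert a.culling_reason == b.culling_reason


def test_panel_long_format_uses_na_for_missing(tmp_path):
    rec = [make_record(1, calv=[24.0], cull=5.6)]
    panel = build_longevity_panel(rec, "FLb")
    path = tmp_path / "panel.csv"
    panel.write(path)
    text = path.read_text()
    assert "NA" in text
    assert text.splitlines()[0] == "cow_id,age,code"
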