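"""Time-point parsing, age-frame conversion and table aggregation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import agealign as aa
from agealign.events import EventTable, write_timepoints
from agealign.synthetic import gen_study_timepoints

CSV_HEADER = "species,event_id,event_type,age_value,age_frame,sex,population,environment,provenance\n"


def _csv(tmp_path, rows, header=CSV_HEADER):
    p = tmp_path / "tps.csv"
    p.write_text(header + "".join(r + "\n" for r in rows))
    return p


class TestReadTimepoints:
    def test_well_formed_rows_parse_cleanly(self, tmp_path, species_cfg):
        path = _csv(
            tmp_path,
            [
                "human,eyes_open,behavior,100,days_post_conception,pooled,,unknown,individual",
                "chimpanzee,eyes_open,behavior,90,days_post_conception,M,,captive,individual",
                "gorilla,menarche,life_history,8.1,years_postnatal,F,,wild,individual",
            ],
        )
        parsed = aa.read_timepoints(path, species_cfg)
        assert len(parsed) == 3 and parsed.errors == []
        assert [tp.species for tp in parsed] == ["human", "chimpanzee", "gorilla"]

    def test_bad_rows_are_flagged_not_fatal(self, tmp_path, species_cfg):
        path = _csv(
            tmp_path,
            [
                "human,a,behavior,100,days_post_conception,pooled,,unknown,individual",
                "human,b,behavior,-1,days_post_conception,pooled,,unknown,individual",
                "dodo,c,behavior,50,days_postnatal,pooled,,unknown,individual",
                "human,d,not_a_type,50,days_post_conception,pooled,,unknown,individual",
            ],
        )
        parsed = aa.read_timepoints(path, species_cfg)
        assert len(parsed) == 1
        assert sorted(e.row for e in parsed.errors) == [2, 3, 4]

    def test_missing_mandatory_column_is_a_format_error(self, tmp_path, species_cfg):
        p = tmp_path / "bad.csv"
        p.write_text("species,event_id\nhuman,a\n")
        with pytest.raises(ValueError, match="mandatory column"):
            aa.read_timepoints(p, species_cfg)

    def test_extra_columns_kept_as_metadata(self, tmp_path, species_cfg):
        path = _csv(
            tmp_path,
            ["human,a,behavior,100,days_post_conception,pooled,,unknown,individual,src1"],
            header=CSV_HEADER.rstrip("\n") + ",source\n",
        )
        parsed = aa.read_timepoints(path, species_cfg)
        assert dict(parsed.timepoints[0].metadata)["source"] == "src1"

    def test_study_scale_bundle_round_trips_573_rows(self, tmp_path, species_cfg):
        tps, _ = gen_study_timepoints(seed=0)
        assert len(tps) == 573
        path = tmp_path / "study.csv"
        write_timepoints(tps, path)
        parsed = aa.read_timepoints(path, species_cfg)
        assert len(parsed) == 573 and not parsed.errors


class TestAgeConversion:
    def test_days_post_conception_is_identity(self, species_cfg):
        tp = aa.TimePoint("human", "e", "behavior", 100.0)
        assert aa.to_days_post_conception(tp, species_cfg) == 100.0

    def test_postnatal_days_add_gestation(self, species_cfg):
        tp = aa.TimePoint("human", "birth", "life_history", 0.0, age_frame="days_postnatal")
        assert aa.to_days_post_conception(tp, species_cfg) == pytest.approx(270.0)

    def test_organoid_incubation_uses_configured_offset(self, species_cfg):
        tp = aa.TimePoint(
            "gorilla", "org_d25", "transcription", 25.0,
            age_frame="days_post_incubation", provenance="organoid", environment="in_vitro",
        )
        assert aa.to_days_post_conception(tp, species_cfg) == 25.0
        shifted = aa.SpeciesConfig(species_cfg.gestation_days, organoid_offset_days=30.0)
        assert aa.to_days_post_conception(tp, shifted) == 55.0

    @given(
        a1=st.floats(1.0, 1e4), delta=st.floats(0.1, 1e3),
        frame=st.sampled_from(["days_post_conception", "days_postnatal", "years_postnatal"]),
    )
    @settings(max_examples=50, deadline=None)
    def test_conversion_strictly_increasing_in_age(self, a1, delta, frame):
        cfg = aa.default_species_config()
        tp1 = aa.TimePoint("human", "e", "behavior", a1, age_frame=frame)
        tp2 = aa.TimePoint("human", "e", "behavior", a1 + delta, age_frame=frame)
        assert aa.to_days_post_conception(tp2, cfg) > aa.to_days_post_conception(tp1, cfg)

    def test_organoid_must_use_incubation_frame(self):
        with pytest.raises(ValueError, match="incubation"):
            aa.TimePoint("human", "e", "transcription", 10.0, provenance="organoid")


def _tp(species, event, age_days, event_type="behavior", sex="pooled"):
    return aa.TimePoint(species, event, event_type, age_days, sex=sex)


class TestBuildEventTable:
    def test_cell_is_mean_of_log_ages(self, species_cfg):
        tps = [
            _tp("human", "a", math.exp(2.0)),
            _tp("human", "a", math.exp(4.0)),
            _tp("chimpanzee", "a", math.exp(3.0)),
            _tp("human", "b", 100.0),
            _tp("chimpanzee", "b", 90.0),
            _tp("human", "c", 200.0),
            _tp("chimpanzee", "c", 220.0),
        ]
        table = aa.build_event_table(tps, species_cfg)
        assert table.values.loc["a", "human"] == pytest.approx(3.0)

    def test_unobserved_cells_are_masked(self, species_cfg):
        tps = [
            _tp("human", "only_h", 100.0),
            _tp("human", "both", 150.0),
            _tp("chimpanzee", "both", 140.0),
            _tp("human", "b2", 300.0),
            _tp("chimpanzee", "b2", 280.0),
        ]
        table = aa.build_event_table(tps, species_cfg)
        assert not table.mask.loc["only_h", "human"]
        assert bool(table.mask.loc["only_h", "chimpanzee"])

    def test_row_order_permutation_invariant(self, species_cfg):
        tps, _ = gen_study_timepoints(seed=3)
        t1 = aa.build_event_table(tps, species_cfg)
        rng = np.random.default_rng(0)
        shuffled = [tps[i] for i in rng.permutation(len(tps))]
        t2 = aa.build_event_table(shuffled, species_cfg)
        t2_aligned = t2.values.loc[t1.values.index, t1.values.columns]
        assert np.allclose(t1.values.to_numpy(), t2_aligned.to_numpy(), equal_nan=True)

    def test_by_sex_aggregation_splits_events(self, species_cfg):
        tps = [
            _tp("human", "gm", 1000.0, sex="M"), _tp("human", "gm", 900.0, sex="F"),
            _tp("chimpanzee", "gm", 800.0, sex="M"), _tp("chimpanzee", "gm", 700.0, sex="F"),
            _tp("human", "x", 100.0), _tp("chimpanzee", "x", 100.0),
            _tp("human", "y", 300.0), _tp("chimpanzee", "y", 300.0),
        ]
        table = aa.build_event_table(tps, species_cfg, aggregation="by_sex")
        assert {"gm:M", "gm:F"}.issubset(table.events)

    def test_csv_round_trip_bit_identical(self, tmp_path, study_table):
        table, _ = study_table
        p = tmp_path / "table.csv"
        table.to_csv(p)
        back = EventTable.read_csv(p)
        assert back.values.equals(table.values)
        assert back.event_types.equals(table.event_types)
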