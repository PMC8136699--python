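"""Domain types: stage clock, frequency tables, ladder, validation."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import testiquant as tq
from testiquant.core import Stage, STAGES, ValidationError


class TestStage:
    def test_roman_round_trip(self):
        for stage in STAGES:
            assert Stage.from_label(stage.roman) is stage
            assert Stage.from_label(stage.value) is stage

    def test_cycle_is_periodic(self):
        assert Stage.XII.advance() is Stage.I
        assert Stage.VII.advance(12) is Stage.VII
        assert Stage.I.advance(-1) is Stage.XII

    @pytest.mark.parametrize("bad", ["XIII", 0, 13, "stage 7"])
    def test_unknown_stage_rejected(self, bad):
        with pytest.raises(ValidationError):
            Stage.from_label(bad)


class TestMakeStageTable:
    def test_published_column_normalizes(self, reference):
        sft = tq.make_stage_table(reference["a_cursor"]["stage_frequencies_percent"])
        assert sum(sft.freq.values()) == pytest.approx(1.0, abs=1e-12)
        assert sft.fraction("VII") == pytest.approx(0.204, abs=1e-12)
        assert sft.original_total == pytest.approx(100.0)

    def test_uniform_table(self):
        sft = tq.make_stage_table({s.roman: 100.0 / 12 for s in STAGES})
        for s in STAGES:
            assert sft.fraction(s) == pytest.approx(1.0 / 12)

    def test_forced_normalization(self):
        values = {s.roman: 0.0 for s in STAGES}
        values["I"] = 50.0
        values["II"] = 50.0
        sft = tq.make_stage_table(values)
        assert sft.fraction("I") == sft.fraction("II") == pytest.approx(0.5)

    def test_missing_stage_named_in_error(self):
        values = {s.roman: 1.0 for s in STAGES if s is not Stage.IX}
        with pytest.raises(ValidationError, match="IX"):
            tq.make_stage_table(values)

    def test_negative_value_named_in_error(self):
        values = {s.roman: 1.0 for s in STAGES}
        values["IV"] = -0.1
        with pytest.raises(ValidationError, match="IV"):
            tq.make_stage_table(values)

    @settings(max_examples=50, derandomize=True)
    @given(
        scale=st.floats(min_value=1e-3, max_value=1e3),
        raw=st.lists(
            st.floats(min_value=0.0, max_value=100.0), min_size=12, max_size=12
        ).filter(lambda v: sum(v) > 1.0),
    )
    def test_normalization_scale_invariant(self, scale, raw):
        """Scaling every tally by the same k > 0 leaves the fractions unchanged."""
        base = tq.make_stage_table({s.roman: v for s, v in zip(STAGES, raw)})
        scaled = tq.make_stage_table({s.roman: scale * v for s, v in zip(STAGES, raw)})
        for s in STAGES:
            assert scaled.fraction(s) == pytest.approx(base.fraction(s), rel=1e-9, abs=1e-12)

    def test_cumulative_positions(self, cursor_sft):
        assert cursor_sft.cumulative_before(Stage.I) == 0.0
        assert cursor_sft.cumulative_through(Stage.XII) == pytest.approx(1.0, abs=1e-12)
        assert cursor_sft.cumulative_through(Stage.VII) == pytest.approx(0.622, abs=1e-9)


class TestBiometryAndMorphometry:
    def test_biometry_invariants(self):
        with pytest.raises(ValidationError):
            tq.Biometry(body_weight_g=0.0, testis_weight_mg=100.0)
        with pytest.raises(ValidationError):
            tq.Biometry(body_weight_g=50.0, testis_weight_mg=100.0, n_testes=3)
        assert tq.Biometry(54.0, 288.0).testis_weight_g == pytest.approx(0.288)

    def test_epithelium_cannot_exceed_radius(self):
        with pytest.raises(ValidationError):
            tq.TubuleMorphometry(diameter_um=180.0, epithelium_height_um=95.0)

    def test_volume_density_hierarchy_is_derived(self):
        leaves = dict(
            tunica_propria=0.031,
            seminiferous_epithelium=0.867,
            lumen=0.057,
            leydig=0.020,
            blood_vessels=0.010,
            lymphatic=0.005,
            other=0.010,
        )
        vd = tq.VolumeDensityTable(components=leaves, albuginea_fraction=0.041)
        assert vd["tubule_compartment"] == pytest.approx(0.955)
        assert vd["intertubular"] == pytest.approx(0.045)

    def test_inconsistent_aggregate_rejected(self):
        leaves = dict(
            tunica_propria=0.031,
            seminiferous_epithelium=0.867,
            lumen=0.057,
            leydig=0.020,
            blood_vessels=0.010,
            lymphatic=0.005,
            other=0.010,
            tubule_compartment=0.90,
        )
        with pytest.raises(ValidationError):
            tq.VolumeDensityTable(components=leaves)


class TestGermCellLadder:
    def test_anchor_and_rows(self, cursor_ladder):
        assert cursor_ladder.lookup("Pl/L", "VII").cycle_ordinal == 0
        assert cursor_ladder.lookup("E", "XII").cycle_ordinal == 2
        assert cursor_ladder.lookup("E", "III").cycle_ordinal == 3
        assert cursor_ladder.release_stage is Stage.VII

    def test_species_variants_differ_at_anchor(self):
        other = tq.GermCellLadder.for_species("n_lasiurus")
        assert other.lookup("Pl/L", "IX").cycle_ordinal == 0
        with pytest.raises(ValidationError, match="VII"):
            other.lookup("Pl/L", "VII")

    def test_lookup_conflict_names_pair(self, cursor_ladder):
        with pytest.raises(ValidationError, match="'R'.*XII"):
            cursor_ladder.lookup("R", "XII")  # R ends at VIII

    def test_position_keys_give_total_order(self, cursor_ladder):
        keys = [
            cursor_ladder.position_key("Pl/L", "VII"),
            cursor_ladder.position_key("L", "VIII"),
            cursor_ladder.position_key("P", "I"),
            cursor_ladder.position_key("MII", "XII"),
            cursor_ladder.position_key("R", "I"),
            cursor_ladder.position_key("E", "IX"),
            cursor_ladder.position_key("E", "VII"),
        ]
        assert keys == sorted(keys)

    def test_overlapping_row_rejected(self):
        records = [
            {"cell_class": "Pl/L", "stages": ["I", "XII"], "cycle_ordinal": 0},
            {"cell_class": "L", "stages": ["V", "VI"], "cycle_ordinal": 0},
        ]
        with pytest.raises(ValidationError):
            tq.GermCellLadder.from_records(records)

    def test_gapped_row_rejected(self):
        records = [
            {"cell_class": "Pl/L", "stages": ["I", "X"], "cycle_ordinal": 0},
            {"cell_class": "E", "stages": ["I", "VII"], "cycle_ordinal": 1},
        ]
        with pytest.raises(ValidationError, match="tile"):
            tq.GermCellLadder.from_records(records)


class TestLabelingObservation:
    def test_stage_and_class_validated(self):
        obs = tq.LabelingObservation(19.8, "E", "XII")
        assert obs.stage is Stage.XII
        with pytest.raises(ValidationError):
            tq.LabelingObservation(19.8, "Q", "XII")
        with pytest.raises(ValidationError):
            tq.LabelingObservation(-1.0, "E", "XII")
        with pytest.raises(ValidationError):
            tq.LabelingObservation(19.8, "E", "XII", within_stage_fraction=1.5)
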