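"""Ground-truth generator: determinism, noise models, label transport."""

import dataclasses

import numpy as np
import pytest

import testiquant as tq
from testiquant import io as tio
from testiquant.core import Stage, ValidationError
from testiquant.synthetic import (
    TruthParams,
    generate_animal,
    generate_grid_counts,
    generate_labeling,
    generate_leydig,
    generate_stage8_counts,
    generate_stage_tallies,
)


class TestDeterminism:
    def test_same_seed_bit_identical(self, cursor_truth):
        a = generate_animal(cursor_truth, seed=7)
        b = generate_animal(cursor_truth, seed=7)
        assert a.grid_counts == b.grid_counts
        assert np.array_equal(a.tubule_diameters_um, b.tubule_diameters_um)
        assert a.stage_tallies == b.stage_tallies
        assert a.labeling == b.labeling
        assert a.stage8 == b.stage8
        assert a.leydig == b.leydig

    def test_different_seeds_differ(self, cursor_truth):
        a = generate_animal(cursor_truth, seed=7)
        b = generate_animal(cursor_truth, seed=8)
        assert a.grid_counts != b.grid_counts


class TestGridCounts:
    def test_default_design_scores_6615_points(self, cursor_truth, rng):
        counts = generate_grid_counts(cursor_truth, rng=rng)
        assert sum(counts.values()) == 6615

    def test_degenerate_truth_puts_all_points_on_one_component(self, cursor_truth, rng):
        leaves = {k: 0.0 for k in cursor_truth.leaf_fractions}
        leaves["seminiferous_epithelium"] = 1.0
        truth = dataclasses.replace(cursor_truth, leaf_fractions=leaves, albuginea_fraction=0.0)
        counts = generate_grid_counts(truth, rng=rng)
        assert counts["seminiferous_epithelium"] == 6615

    def test_estimated_fraction_within_three_se(self, cursor_truth, rng):
        counts = generate_grid_counts(cursor_truth, rng=rng)
        p = (1 - cursor_truth.albuginea_fraction) * cursor_truth.leaf_fractions[
            "seminiferous_epithelium"
        ]
        se = np.sqrt(p * (1 - p) / 6615)
        assert abs(counts["seminiferous_epithelium"] / 6615 - p) <= 3 * se


class TestStageTallies:
    def test_expected_stage_vii_tally(self, cursor_truth, rng):
        tallies = generate_stage_tallies(cursor_truth, rng=rng)
        expected = 0.204 * 250
        se = np.sqrt(250 * 0.204 * (1 - 0.204))
        assert abs(tallies[Stage.VII] - expected) <= 3 * se

    def test_degenerate_truth(self, cursor_truth, rng):
        freq = {s.roman: 0.0 for s in tq.STAGES}
        freq["I"] = 100.0
        truth = dataclasses.replace(
            cursor_truth, stage_frequencies=tq.make_stage_table(freq)
        )
        tallies = generate_stage_tallies(truth, rng=rng)
        assert tallies[Stage.I] == 250


class TestLabelTransport:
    def test_published_design_reaches_elongated_at_xii(self, cursor_truth):
        start, end = generate_labeling(cursor_truth)
        assert (start.cell_class, start.stage) == ("Pl/L", Stage.VII)
        assert (end.cell_class, end.stage) == ("E", Stage.XII)
        true_cycles = cursor_truth.chase_days / cursor_truth.cycle_length_days
        assert true_cycles == pytest.approx(2.3515, abs=5e-4)
        # the true position is inside stage XII, not at its end
        assert 0.0 < end.within_stage_fraction < 1.0

    def test_chase_of_one_cycle_moves_to_next_ladder_row(self, cursor_truth):
        start, end = generate_labeling(cursor_truth, chase_days=cursor_truth.cycle_length_days)
        assert end.stage is start.stage
        assert end.cell_class == "P"  # the row after Pl/L at the same stage
        assert end.within_stage_fraction == pytest.approx(1.0)

    def test_chase_beyond_spermiation_raises(self, cursor_truth):
        with pytest.raises(ValidationError, match="released"):
            generate_labeling(cursor_truth, chase_days=3.1 * cursor_truth.cycle_length_days)

    def test_kinetics_inverts_transport_exactly(self, cursor_truth, cursor_ladder):
        from testiquant import kinetics

        start, end = generate_labeling(cursor_truth)
        cycles = kinetics.cycles_traversed(
            start, end, cursor_truth.stage_frequencies, cursor_ladder
        )
        estimate = kinetics.cycle_length(cursor_truth.chase_days, cycles)
        assert estimate == pytest.approx(cursor_truth.cycle_length_days, rel=1e-12)


class TestStageVIIIGeneration:
    def test_raw_counts_carry_abercrombie_inflation(self, cursor_truth, rng):
        s8 = generate_stage8_counts(cursor_truth, n_sections=20_000, rng=rng)
        t = cursor_truth.section_thickness_um
        expected_raw = (
            cursor_truth.sertoli_corr_per_section
            * (t + cursor_truth.sertoli_nucleolus_diameter_um)
            / t
        )
        assert s8.sertoli_nucleoli_raw == pytest.approx(expected_raw, rel=0.02)

    def test_correction_recovers_truth_at_large_n(self, cursor_truth, rng):
        from testiquant import cellquant

        s8 = generate_stage8_counts(cursor_truth, n_sections=10_000, rng=rng)
        corrected = cellquant.abercrombie_correct(
            s8.sertoli_nucleoli_raw,
            s8.section_thickness_um,
            s8.sertoli_nucleolus_diameter_um,
        )
        assert corrected == pytest.approx(cursor_truth.sertoli_corr_per_section, rel=0.05)

    def test_meiotic_index_round_trip(self, cursor_truth, rng):
        from testiquant import cellquant

        s8 = generate_stage8_counts(cursor_truth, n_sections=5_000, rng=rng)
        pach = cellquant.abercrombie_correct(
            s8.pachytene_raw, s8.section_thickness_um, s8.pachytene_diameter_um
        )
        rnd = cellquant.abercrombie_correct(
            s8.round_spermatid_raw, s8.section_thickness_um, s8.round_spermatid_diameter_um
        )
        truth_index = (
            cursor_truth.round_spermatid_corr_per_section
            / cursor_truth.pachytene_corr_per_section
        )
        assert cellquant.meiotic_index(rnd, pach) == pytest.approx(truth_index, rel=0.05)


class TestLeydigGeneration:
    def test_zero_sd_gives_exact_mean(self, cursor_truth, rng):
        truth = dataclasses.replace(cursor_truth, leydig_nuclear_diameter_sd_um=0.0)
        ley = generate_leydig(truth, rng=rng)
        assert ley.nuclear_diameter_um == pytest.approx(
            truth.leydig_nuclear_diameter_um, rel=1e-12
        )

    def test_point_fraction_within_binomial_se(self, cursor_truth, rng):
        ley = generate_leydig(cursor_truth, rng=rng)
        p = cursor_truth.leydig_nucleus_fraction
        se = np.sqrt(p * (1 - p) / 1000)
        assert abs(ley.nucleus_point_fraction - p) <= 3 * se

    def test_cell_volume_round_trip_at_defaults(self, cursor_truth, rng):
        from testiquant import cellquant

        ley = generate_leydig(cursor_truth, rng=rng)
        nuc = cellquant.leydig_nuclear_volume(ley.nuclear_diameter_um)
        cell = cellquant.leydig_cell_volume(nuc, ley.nucleus_point_fraction)
        assert cell == pytest.approx(cursor_truth.true_leydig_cell_volume(), rel=0.10)


class TestPipelineRoundTrip:
    def test_single_animal_recovery(self, cursor_truth):
        animal = generate_animal(cursor_truth, seed=3)
        result = tio.analyze_animal(animal.to_observations())
        assert result.gsi_percent == pytest.approx(cursor_truth.true_gsi(), rel=1e-12)
        assert result.tubule_length_per_gram_m == pytest.approx(
            cursor_truth.true_tubule_length_per_gram(), rel=0.05
        )
        assert result.cycle_length_days == pytest.approx(
            cursor_truth.cycle_length_days, rel=0.03
        )
        assert result.dsp_per_testis == pytest.approx(
            cursor_truth.true_dsp_per_testis(), rel=0.10
        )
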