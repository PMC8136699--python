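"""Abercrombie correction, cell ratios, DSP and Leydig quantification."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import testiquant as tq
from testiquant import cellquant
from testiquant.core import ValidationError


class TestAbercrombie:
    def test_direct_formula(self):
        assert cellquant.abercrombie_correct(10.0, 4.0, 6.0) == pytest.approx(4.0)

    def test_point_objects_unchanged(self):
        assert cellquant.abercrombie_correct(7.0, 4.0, 0.0) == 7.0

    @settings(max_examples=50, derandomize=True)
    @given(
        raw=st.floats(min_value=0.0, max_value=1e3),
        t=st.floats(min_value=0.5, max_value=20.0),
        d=st.floats(min_value=0.0, max_value=20.0),
    )
    def test_never_exceeds_raw(self, raw, t, d):
        corrected = cellquant.abercrombie_correct(raw, t, d)
        assert corrected <= raw
        if raw > 0 and d > 1e-9 * t:  # strict once D is resolvable in floats
            assert corrected < raw

    def test_recovers_density_of_sectioned_spheres(self, rng):
        """Geometric oracle: spheres of diameter D cut by slabs of thickness T.

        A slab [z, z+T) intersects every sphere whose centre lies within D/2
        of it, so raw profile counts overcount centres by (T+D)/T; the
        correction must recover the true number of centres per slab.
        """
        t, d, density = 4.0, 6.0, 10.0  # centres per um of depth
        n_sections = 10_000
        depth = n_sections * t
        centres = rng.uniform(0.0, depth, size=int(density * depth))
        edges = np.arange(n_sections + 1) * t
        # profile in slab k iff centre in (edges[k]-d/2, edges[k+1]+d/2)
        starts = np.searchsorted(np.sort(centres), edges[:-1] - d / 2.0)
        stops = np.searchsorted(np.sort(centres), edges[1:] + d / 2.0)
        raw_counts = stops - starts
        corrected = cellquant.abercrombie_correct(float(raw_counts.mean()), t, d)
        true_per_section = density * t
        assert corrected == pytest.approx(true_per_section, rel=0.05)


class TestRatiosAndLoss:
    def test_meiotic_index_examples(self):
        assert cellquant.meiotic_index(30.0, 10.0) == pytest.approx(3.0)
        assert cellquant.meiotic_index(5.0, 5.0) == 1.0
        with pytest.raises(ValidationError):
            cellquant.meiotic_index(10.0, 0.0)

    def test_meiotic_index_recovery_from_noisy_sections(self, rng):
        truth = 2.6
        pach = rng.poisson(40.0, size=10).mean()
        rnd = rng.poisson(40.0 * truth, size=10).mean()
        estimate = cellquant.meiotic_index(rnd, pach)
        se = truth * math.sqrt(1 / 400.0 + 1 / (400.0 * truth))
        assert abs(estimate - truth) <= 3 * se

    @pytest.mark.parametrize(
        "index, loss", [(2.6, 35.0), (3.0, 25.0), (4.0, 0.0)]
    )
    def test_meiotic_loss(self, index, loss):
        assert cellquant.meiotic_loss(index) == pytest.approx(loss)

    def test_supra_theoretical_index_warns(self):
        with pytest.warns(UserWarning):
            value = cellquant.meiotic_loss(4.4)
        assert value == pytest.approx(-10.0)

    def test_sertoli_efficiency(self):
        assert cellquant.sertoli_efficiency(132.0, 10.0) == pytest.approx(13.2)
        with pytest.raises(ValidationError):
            cellquant.sertoli_efficiency(10.0, 0.0)


class TestSertoliAndDsp:
    def test_sections_along_tubule(self):
        # 4 m of tubule cut into 4-um sections -> 1e6 sections
        assert cellquant.sertoli_per_testis(10.0, 4.0, 4.0) == pytest.approx(1.0e7)

    def test_inversion_against_published_sertoli_number(self):
        """The printed Sertoli number implies ~10 corrected nucleoli/section."""
        implied = 14.4e6 * 4.0 / 5.7e6
        assert implied == pytest.approx(10.1, abs=0.05)
        assert cellquant.sertoli_per_testis(implied, 5.7, 4.0) == pytest.approx(14.4e6, rel=1e-9)

    def test_dsp_published_means(self):
        value = cellquant.dsp(1.13e7, 10.3, 0.091, 0.091 * 8.89)
        assert value == pytest.approx(1.309e7, rel=1e-3)
        assert value == pytest.approx(13.2e6, rel=0.01)

    @settings(max_examples=50, derandomize=True)
    @given(
        sc=st.floats(min_value=1e6, max_value=1e8),
        eff=st.floats(min_value=1.0, max_value=20.0),
        freq=st.floats(min_value=0.01, max_value=0.3),
        c=st.floats(min_value=6.0, max_value=14.0),
    )
    def test_four_factor_formula_reduces_to_cycle_length(self, sc, eff, freq, c):
        """DSP via frequency/duration is exactly SC x efficiency / cycle length."""
        assert cellquant.dsp(sc, eff, freq, freq * c) == pytest.approx(
            sc * eff / c, rel=1e-12
        )

    def test_per_gram_route_matches_published_within_ratio_caveat(self):
        per_gram = 47.9e6 * 13.2 / 7.8
        assert per_gram == pytest.approx(8.106e7, rel=1e-3)
        assert per_gram == pytest.approx(79.0e6, rel=0.03)

    def test_per_gram_times_grams_is_per_testis(self):
        bio = tq.Biometry(54.0, 288.0)
        dsp_testis = 1.85e7
        per_gram = cellquant.dsp_per_gram(dsp_testis, bio)
        assert per_gram * bio.testis_weight_g == pytest.approx(dsp_testis, rel=1e-12)
        assert cellquant.dsp_per_gram(0.0, bio) == 0.0


class TestLeydig:
    @pytest.mark.parametrize(
        "diameter, volume, printed, sem",
        [(8.0, 268.1, 275.0, 17.0), (6.5, 143.8, 146.0, 4.0)],
    )
    def test_nuclear_sphere_volume(self, diameter, volume, printed, sem):
        value = cellquant.leydig_nuclear_volume(diameter)
        assert value == pytest.approx(volume, abs=0.05)
        assert abs(value - printed) <= sem  # published per-animal means

    def test_tiny_nucleus(self):
        assert cellquant.leydig_nuclear_volume(2.0) == pytest.approx(4.0 * math.pi / 3.0)

    def test_cell_volume_from_point_fraction(self):
        # published nucleus 275 + cytoplasm 817 -> cell 1092
        assert cellquant.leydig_cell_volume(275.0, 275.0 / 1092.0) == pytest.approx(1092.0)
        assert cellquant.leydig_cell_volume(146.0, 146.0 / 393.0) == pytest.approx(393.0)
        assert cellquant.leydig_cell_volume(100.0, 0.5) == pytest.approx(200.0)
        with pytest.raises(ValidationError):
            cellquant.leydig_cell_volume(100.0, 1.0)

    def test_numbers_per_gram_and_testis(self):
        bio = tq.Biometry(23.0, 63.0)
        per_gram, per_testis = cellquant.leydig_numbers(0.014, 393.0, bio, 0.067)
        assert per_gram == pytest.approx(33.2e6, rel=0.005)
        assert per_testis == pytest.approx(per_gram * 0.063, rel=1e-12)

    def test_montensis_number_reflects_mean_of_ratios_gap(self):
        bio = tq.Biometry(37.0, 217.0)
        per_gram, _ = cellquant.leydig_numbers(0.011, 807.0, bio, 0.040)
        assert per_gram == pytest.approx(1.31e7, rel=0.005)
        assert per_gram == pytest.approx(14.6e6, rel=0.11)

    def test_zero_density_zero_cells(self):
        per_gram, per_testis = cellquant.leydig_numbers(0.0, 393.0, tq.Biometry(23.0, 63.0), 0.067)
        assert per_gram == 0.0 and per_testis == 0.0
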