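import math

import numpy as np
import pytest

from ctlensdose import beam_quality as bq
from ctlensdose.reference_data import AL_DENSITY, TableRangeError, load_table


def spectrum_at(kvp, filtration=()):
    return bq.simulate_spectrum(bq.TubeSetting(tube_voltage=kvp, filtration=filtration))


def near_mono(energy, bin_width=0.5):
    """Two-bin spectrum with all fluence in the bin nearest `energy`."""
    energies = np.array([energy - bin_width, energy])
    fluence = np.array([0.0, 1.0])
    return bq.Spectrum(energies=energies, fluence=fluence)


class TestSimulateSpectrum:
    def test_no_fluence_at_or_above_tube_voltage(self):
        spec = spectrum_at(120)
        assert np.all(spec.fluence[spec.energies >= 120.0] == 0)
        assert np.any(spec.fluence > 0)

    def test_k_lines_only_above_tungsten_k_edge(self):
        low = spectrum_at(60)
        # below the K-edge the continuum is smooth: no bin towers over the
        # mean of its neighbours
        interior = low.fluence[1:-1]
        neighbours = 0.5 * (low.fluence[:-2] + low.fluence[2:])
        assert np.all(interior[neighbours > 0] <= 1.05 * neighbours[neighbours > 0])

        high = spectrum_at(120)
        ka1_bin = int(np.argmin(np.abs(high.energies - 59.32)))
        local = 0.5 * (high.fluence[ka1_bin - 1] + high.fluence[ka1_bin + 1])
        assert high.fluence[ka1_bin] > 1.2 * local

    def test_unknown_filtration_material_lists_supported(self):
        with pytest.raises(ValueError, match="supported"):
            spectrum_at(120, filtration=(("Pb", 1.0),))

    def test_bad_bin_width_rejected(self):
        with pytest.raises(ValueError):
            bq.simulate_spectrum(bq.TubeSetting(tube_voltage=120), bin_width=5.0)


class TestApplyFiltration:
    def test_zero_thickness_is_identity(self):
        spec = spectrum_at(100)
        out = bq.apply_filtration(spec, "Al", 0.0)
        assert np.array_equal(out.fluence, spec.fluence)

    def test_two_one_mm_layers_equal_one_two_mm_layer(self):
        spec = spectrum_at(100)
        twice = bq.apply_filtration(bq.apply_filtration(spec, "Al", 1.0), "Al", 1.0)
        once = bq.apply_filtration(spec, "Al", 2.0)
        assert np.allclose(twice.fluence, once.fluence, rtol=1e-12)

    @pytest.mark.parametrize("thickness", [0.5, 2.0, 10.0])
    def test_aluminum_filtration_raises_mean_energy(self, thickness):
        spec = spectrum_at(100)
        assert bq.apply_filtration(spec, "Al", thickness).mean_energy() > spec.mean_energy()

    def test_negative_thickness_rejected(self):
        with pytest.raises(ValueError):
            bq.apply_filtration(spectrum_at(100), "Al", -1.0)


class TestAirKerma:
    def test_linearity_in_fluence(self):
        spec = spectrum_at(120)
        doubled = bq.Spectrum(energies=spec.energies, fluence=2 * spec.fluence)
        assert bq.air_kerma_of(doubled) == pytest.approx(2 * bq.air_kerma_of(spec), rel=1e-12)

    def test_single_positive_bin_is_three_factor_product(self):
        spec = near_mono(60.0)
        muen = float(load_table("air_mu_en_rho")(60.0))
        assert bq.air_kerma_of(spec) == pytest.approx(1.0 * 60.0 * muen, rel=1e-12)

    def test_mono_60_vs_30_ratio_matches_table_arithmetic(self):
        """Kerma ratio of equal-fluence monoenergetic beams equals the
        hand-computed E*(mu_en/rho) ratio from the bundled air table."""
        k60 = bq.air_kerma_of(near_mono(60.0))
        k30 = bq.air_kerma_of(near_mono(30.0))
        expected = (60.0 * 0.03041) / (30.0 * 0.1537)  # node values
        assert k60 / k30 == pytest.approx(expected, rel=1e-12)


class TestHvl:
    @pytest.mark.parametrize("energy", [40.0, 60.0, 100.0])
    def test_monoenergetic_hvl_matches_closed_form(self, energy):
        spec = near_mono(energy)
        mu = float(load_table("al_mu_rho")(energy)) * AL_DENSITY
        assert bq.hvl_al(spec) == pytest.approx(math.log(2) / mu * 10, abs=1e-3)

    def test_transmission_through_hvl_is_half(self):
        spec = spectrum_at(120, filtration=(("Al", 5.0),))
        t = bq.hvl_al(spec)
        ratio = bq.air_kerma_of(bq.apply_filtration(spec, "Al", t)) / bq.air_kerma_of(spec)
        assert ratio == pytest.approx(0.5, abs=1e-3)

    def test_prefiltration_hardens_beam(self):
        assert bq.hvl_al(spectrum_at(120, (("Al", 5.0),))) > bq.hvl_al(spectrum_at(120))


class TestEffectiveEnergy:
    @pytest.mark.parametrize("energy", [40.0, 60.0, 80.0, 100.0])
    def test_round_trip_through_closed_form_hvl(self, energy):
        assert bq.effective_energy_from_hvl(bq.hvl_monoenergetic(energy)) == pytest.approx(
            energy, abs=0.01
        )

    def test_monotone_in_hvl(self):
        hvls = np.linspace(2.5, 18.0, 25)
        effs = [bq.effective_energy_from_hvl(h) for h in hvls]
        assert np.all(np.diff(effs) > 0)

    def test_out_of_range_hvl_raises(self):
        with pytest.raises((TableRangeError, ValueError)):
            bq.effective_energy_from_hvl(0.5)
        with pytest.raises((TableRangeError, ValueError)):
            bq.effective_energy_from_hvl(30.0)

    def test_hardening_monotonicity_of_effective_energy(self):
        effs = [
            bq.effective_energy_of_spectrum(spectrum_at(120, (("Al", t),)))
            for t in (3.0, 6.0, 10.0, 14.0)
        ]
        assert np.all(np.diff(effs) > 0)


class TestCalibration:
    def test_default_beams_reproduce_per_fov_anchors(self):
        beams = bq.default_beam_qualities()
        for key, anchor in bq.TABLE3_EFFECTIVE_ENERGIES_KEV.items():
            assert beams[key].effective_energy == pytest.approx(anchor, abs=0.05)

    def test_default_beams_within_plausible_window(self):
        for beam in bq.default_beam_qualities().values():
            assert 54.0 <= beam.effective_energy <= 58.5


class TestSummarize:
    def test_mean_and_population_sd_of_fov_values(self):
        mean, sd = bq.summarize_effective_energy([55.74, 57.97, 54.87, 57.30])
        assert mean == 56.47
        assert sd == 1.23  # divisor n; divisor n-1 would print 1.42

    def test_sample_divisor_would_disagree(self):
        sample_sd = np.std([55.74, 57.97, 54.87, 57.30], ddof=1)
        assert round(float(sample_sd), 2) == 1.42

    def test_constant_values_have_zero_sd(self):
        assert bq.summarize_effective_energy([56.0, 56.0, 56.0]) == (56.0, 0.0)

    def test_singleton_rejected(self):
        with pytest.raises(ValueError):
            bq.summarize_effective_energy([56.0])


def test_tube_setting_validation():
    with pytest.raises(ValueError):
        bq.TubeSetting(tube_voltage=30)
    with pytest.raises(ValueError):
        bq.TubeSetting(tube_voltage=120, filtration=(("Al", -1.0),))
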