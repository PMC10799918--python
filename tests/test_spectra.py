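import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from quenchbind import (
    Spectrum,
    SpectrumKind,
    ShiftDirection,
    SimulationConfig,
    EmissionBand,
    TitrationSeries,
    ValidationError,
    inner_filter_correct,
    intensity_at,
    load_titration,
    peak_position,
    simulate_titration,
    subtract_background,
    synchronous_shift,
    write_titration,
)
from conftest import gaussian_spectrum


class TestSpectrumValidation:
    def test_rejects_non_monotone_grid(self):
        with pytest.raises(ValidationError):
            Spectrum(SpectrumKind.EMISSION, [300, 299, 301], [1, 2, 3])

    def test_rejects_length_mismatch_and_single_point(self):
        with pytest.raises(ValidationError):
            Spectrum(SpectrumKind.EMISSION, [300, 301], [1, 2, 3])
        with pytest.raises(ValidationError):
            Spectrum(SpectrumKind.EMISSION, [300], [1])

    def test_negative_absorbance_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clipped"):
            sp = Spectrum(SpectrumKind.ABSORBANCE, [300, 301, 302], [0.1, -0.01, 0.2])
        assert sp.values[1] == 0.0


class TestLoadWrite:
    def test_csv_metadata_roundtrip_is_bit_identical(self, tmp_path):
        cfg = SimulationConfig(
            quenching_model="stern_volmer_linear", K_sv_M=1.92e4, noise_rel=0.01, seed=7
        )
        series = simulate_titration(cfg)
        write_titration(series, tmp_path / "s.csv", tmp_path / "s.json")
        back = load_titration(tmp_path / "s.csv", tmp_path / "s.json")
        assert np.array_equal(back.wavelengths_nm, series.wavelengths_nm)
        for a, b in zip(back.spectra, series.spectra):
            assert np.array_equal(a.values, b.values)
        assert np.array_equal(back.quencher_concs_M, series.quencher_concs_M)
        assert back.temperature_K == series.temperature_K
        assert back.excitation_nm == series.excitation_nm
        assert back.fluorophore_conc_M == series.fluorophore_conc_M

    def test_micromolar_design_converts_to_molar(self, tmp_path):
        concs_uM = [0, 1, 5, 10, 20, 30, 40, 50, 60, 80]
        wl = np.arange(285.0, 451.0)
        header = "wavelength_nm," + ",".join(f"I_{c}" for c in concs_uM)
        rows = [header] + [
            ",".join([str(w)] + ["1.0"] * len(concs_uM)) for w in wl
        ]
        (tmp_path / "s.csv").write_text("\n".join(rows))
        meta = {
            "temperature_K": 310,
            "excitation_nm": 280,
            "fluorophore_conc": 2,
            "quencher_concs": concs_uM,
            "units": "uM",
            "competitor": None,
        }
        (tmp_path / "s.json").write_text(json.dumps(meta))
        series = load_titration(tmp_path / "s.csv", tmp_path / "s.json")
        assert len(series.spectra) == 10
        np.testing.assert_allclose(
            series.quencher_concs_M, np.array(concs_uM) * 1e-6, rtol=0, atol=0
        )
        assert series.fluorophore_conc_M == 2e-6

    def test_single_spectrum_reference_series_is_valid(self, tmp_path):
        wl = np.arange(285.0, 451.0)
        rows = ["wavelength_nm,I_0"] + [f"{w},1.0" for w in wl]
        (tmp_path / "s.csv").write_text("\n".join(rows))
        meta = {
            "temperature_K": 310,
            "excitation_nm": 280,
            "fluorophore_conc": 2,
            "quencher_concs": [0],
            "units": "uM",
        }
        (tmp_path / "s.json").write_text(json.dumps(meta))
        series = load_titration(tmp_path / "s.csv", tmp_path / "s.json")
        assert series.has_reference and len(series.spectra) == 1

    @pytest.mark.parametrize(
        "broken",
        ["column_count", "missing_units", "missing_wavelength", "bad_grid"],
    )
    def test_malformed_inputs_rejected(self, tmp_path, broken):
        concs = [0, 1, 5]
        wl = [300.0, 301.0, 302.0]
        names = concs if broken != "column_count" else concs[:-1]
        header = "wavelength_nm," + ",".join(f"I_{c}" for c in names)
        if broken == "missing_wavelength":
            header = header.replace("wavelength_nm", "wl")
        if broken == "bad_grid":
            wl = [300.0, 302.0, 301.0]
        rows = [header] + [
            ",".join([str(w)] + ["1.0"] * len(names)) for w in wl
        ]
        (tmp_path / "s.csv").write_text("\n".join(rows))
        meta = {
            "temperature_K": 310,
            "excitation_nm": 280,
            "fluorophore_conc": 2,
            "quencher_concs": concs,
            "units": "uM",
        }
        if broken == "missing_units":
            del meta["units"]
        (tmp_path / "s.json").write_text(json.dumps(meta))
        with pytest.raises(ValidationError):
            load_titration(tmp_path / "s.csv", tmp_path / "s.json")


def _flat_absorbance(series, a):
    grid = series.wavelengths_nm
    return [
        Spectrum(SpectrumKind.ABSORBANCE, grid, np.full(grid.size, a))
        for _ in series.spectra
    ]


class TestInnerFilter:
    def test_zero_absorbance_is_identity(self, linear_series):
        out = inner_filter_correct(
            linear_series,
            np.zeros(10),
            _flat_absorbance(linear_series, 0.0),
        )
        for a, b in zip(out.spectra, linear_series.spectra):
            np.testing.assert_array_equal(a.values, b.values)
        assert out.corrected

    def test_total_absorbance_two_scales_by_e(self, linear_series):
        out = inner_filter_correct(
            linear_series, np.full(10, 1.0), _flat_absorbance(linear_series, 1.0)
        )
        ratio = out.spectra[0].values / linear_series.spectra[0].values
        np.testing.assert_allclose(ratio, np.e, rtol=1e-12)

    def test_correction_factor_matches_direct_evaluation(self, linear_series):
        out = inner_filter_correct(
            linear_series, np.full(10, 0.10), _flat_absorbance(linear_series, 0.05)
        )
        ratio = out.spectra[3].values / linear_series.spectra[3].values
        np.testing.assert_allclose(ratio, 1.0778841508846442, rtol=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        a_ex=st.floats(0, 2),
        a_em=st.floats(0, 2),
    )
    def test_correction_never_decreases_intensity(self, a_ex, a_em):
        cfg = SimulationConfig(quenching_model="stern_volmer_linear", K_sv_M=1e4)
        series = simulate_titration(cfg)
        out = inner_filter_correct(
            series, np.full(10, a_ex), _flat_absorbance(series, a_em)
        )
        for corr, orig in zip(out.spectra, series.spectra):
            assert np.all(corr.values >= orig.values)

    def test_double_correction_rejected(self, linear_series):
        once = inner_filter_correct(
            linear_series, np.zeros(10), _flat_absorbance(linear_series, 0.0)
        )
        with pytest.raises(ValidationError):
            inner_filter_correct(once, np.zeros(10), _flat_absorbance(once, 0.0))

    def test_negative_absorbance_rejected(self, linear_series):
        with pytest.raises(ValidationError):
            inner_filter_correct(
                linear_series, np.full(10, -0.1), _flat_absorbance(linear_series, 0.0)
            )


class TestBackgroundSubtraction:
    def test_spectrum_minus_itself_is_zero(self, gauss340):
        out = subtract_background(gauss340, gauss340)
        np.testing.assert_array_equal(out.values, 0.0)

    def test_recovers_addend_from_synthetic_sum(self):
        protein = gaussian_spectrum(center=278, width=12, amplitude=0.5,
                                    kind=SpectrumKind.ABSORBANCE)
        ligand = gaussian_spectrum(center=300, width=20, amplitude=0.2,
                                   kind=SpectrumKind.ABSORBANCE)
        total = protein.with_values(protein.values + ligand.values)
        out = subtract_background(total, ligand)
        np.testing.assert_allclose(out.values, protein.values, rtol=1e-12, atol=1e-15)

    def test_zero_background_is_identity(self, gauss340):
        zero = gauss340.with_values(np.zeros_like(gauss340.values))
        out = subtract_background(gauss340, zero)
        np.testing.assert_array_equal(out.values, gauss340.values)

    def test_disjoint_ranges_rejected(self, gauss340):
        other = gaussian_spectrum(start=500, stop=600)
        with pytest.raises(ValidationError):
            subtract_background(gauss340, other)


class TestIntensityAt:
    def test_exact_on_grid_points(self, gauss340):
        assert intensity_at(gauss340, 340.0) == gauss340.values[55]

    def test_linear_midpoint(self):
        sp = Spectrum(SpectrumKind.EMISSION, [339.0, 341.0], [1.0, 3.0])
        assert intensity_at(sp, 340.0) == 2.0

    def test_gaussian_center_amplitude(self, gauss340):
        assert intensity_at(gauss340, 340.0) == pytest.approx(1000.0, rel=1e-6)

    def test_out_of_range_rejected(self, gauss340):
        with pytest.raises(ValidationError):
            intensity_at(gauss340, 200.0)


class TestPeakPosition:
    def test_gaussian_peak(self, gauss340):
        assert peak_position(gauss340, (285, 450)) == 340.0

    def test_flat_spectrum_ties_to_shortest_wavelength(self):
        sp = Spectrum(SpectrumKind.EMISSION, np.arange(300.0, 310.0), np.ones(10))
        assert peak_position(sp, (302, 308)) == 302.0

    def test_taller_band_wins_within_window(self):
        a = gaussian_spectrum(center=301, width=8, amplitude=800)
        b = gaussian_spectrum(center=342, width=15, amplitude=600)
        sp = a.with_values(a.values + b.values)
        assert peak_position(sp, (285, 320)) == 301.0

    def test_empty_window_rejected(self, gauss340):
        with pytest.raises(ValidationError):
            peak_position(gauss340, (200, 210))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(scale=st.floats(1e-6, 1e6))
    def test_invariant_under_positive_scaling(self, scale):
        a = gaussian_spectrum(center=301, width=8, amplitude=800)
        b = gaussian_spectrum(center=342, width=15, amplitude=600)
        sp = a.with_values(a.values + b.values)
        scaled = sp.with_values(sp.values * scale)
        assert peak_position(scaled, (285, 450)) == peak_position(sp, (285, 450))


class TestSynchronousShift:
    def _drift_series(self, drift):
        cfg = SimulationConfig(
            quenching_model="stern_volmer_linear",
            K_sv_M=1.92e4,
            band=EmissionBand(center_nm=342.0, center_drift_nm=drift),
            spectrum_kind=SpectrumKind.SYNCHRONOUS,
            synchronous_offset_nm=60.0,
        )
        return simulate_titration(cfg)

    def test_programmed_blueshift_detected(self):
        res = synchronous_shift(self._drift_series(-2.0), 60)
        assert res.shift_nm == -2.0
        assert res.direction is ShiftDirection.BLUESHIFT

    def test_no_drift_classified_none(self):
        res = synchronous_shift(self._drift_series(0.0), 60)
        assert res.shift_nm == 0.0
        assert res.direction is ShiftDirection.NONE

    def test_programmed_redshift_detected(self):
        res = synchronous_shift(self._drift_series(3.0), 15)
        assert res.shift_nm == 3.0
        assert res.direction is ShiftDirection.REDSHIFT

    def test_subresolution_shift_is_not_a_claim(self):
        # 0.4 nm total drift on a 1 nm grid stays below the 0.5-step threshold
        res = synchronous_shift(self._drift_series(0.4), 60)
        assert res.direction is ShiftDirection.NONE

    def test_single_concentration_rejected(self, gauss340):
        series = TitrationSeries(
            spectra=(gauss340,),
            quencher_concs_M=[0.0],
            temperature_K=310.0,
            excitation_nm=280.0,
            fluorophore_conc_M=2e-6,
        )
        with pytest.raises(ValidationError):
            synchronous_shift(series, 60)
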