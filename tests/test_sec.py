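"""Multi-detector SEC: calibration, deconvolution, quantification."""

import math

import numpy as np
import pytest

from abaffinity.errors import CalibrationError, FitError, ValidationError
from abaffinity.sec import (
    BOLTZMANN,
    Chromatogram,
    absorption_coefficient,
    calibrate,
    deconvolve,
    extinction_from_sequence,
    molar_mass,
    quantify_peaks,
    simulate_chromatogram,
    stokes_einstein,
)
from abaffinity.synthetic import (
    pertuzumab_like_scenario,
    trastuzumab_like_scenario,
)

K_CONST = dict(k_ri=2.0, k_uv=3.0, k_ls=0.05)


def _standard(noise=0.0, conc=1.0, seed=0):
    return simulate_chromatogram(
        [dict(name="BSA", mass_kDa=66.4, conc_gL=conc, dA_dc=0.66)],
        noise_sigma_rel=noise, seed=seed, **K_CONST,
    )


class TestCalibration:
    def test_constants_recovered_from_standard_run(self):
        cal = calibrate(_standard(), 66.4, 1.0, 0.185, 0.66)
        assert cal.k_ri == pytest.approx(2.0, rel=1e-3)
        assert cal.k_uv == pytest.approx(3.0, rel=1e-3)
        assert cal.k_ls == pytest.approx(0.05, rel=1e-3)

    def test_scale_invariance_in_injected_concentration(self):
        a = calibrate(_standard(conc=1.0), 66.4, 1.0, 0.185, 0.66)
        b = calibrate(_standard(conc=2.0), 66.4, 2.0, 0.185, 0.66)
        assert a.k_ri == pytest.approx(b.k_ri, rel=1e-9)
        assert a.k_ls == pytest.approx(b.k_ls, rel=1e-9)

    def test_zero_signal_and_multi_peak_errors(self):
        flat = Chromatogram(
            np.arange(10.0, 20.0, 0.01),
            {d: np.zeros(1000) for d in ("RI", "UV", "RALS")},
        )
        with pytest.raises(CalibrationError):
            calibrate(flat, 66.4, 1.0)
        double = simulate_chromatogram(
            [dict(name="a", mass_kDa=66.4, conc_gL=1.0),
             dict(name="b", mass_kDa=300.0, conc_gL=1.0)],
            noise_sigma_rel=0.0, **K_CONST,
        )
        with pytest.raises(CalibrationError):
            calibrate(double, 66.4, 1.0)


class TestDeconvolution:
    def test_single_gaussian_recovered(self):
        chrom = _standard()
        res = deconvolve(chrom, n_peaks=1)
        pk = res.peaks[0]
        true_center = 38.05 - 9.56 * math.log10(66.4)
        assert pk.center == pytest.approx(true_center, abs=0.005)
        assert pk.sigma == pytest.approx(0.25, rel=0.005)
        # injected 0.1 mg at dn/dc 0.185, k_RI = 2
        assert pk.areas["RI"] == pytest.approx(2.0 * 0.185 * 0.1, rel=0.005)

    def test_two_close_peaks_at_snr_100(self):
        """Two Gaussians 2.5 sigma apart, 1% noise: areas within 2%."""
        chrom = simulate_chromatogram(
            [dict(name="a", mass_kDa=150.0, conc_gL=1.0, center_mL=16.0),
             dict(name="b", mass_kDa=300.0, conc_gL=0.5, center_mL=16.0 - 2.5 * 0.25)],
            noise_sigma_rel=0.01, seed=5, **K_CONST,
        )
        res = deconvolve(chrom, n_peaks=2)
        areas = sorted(p.areas["RI"] for p in res.peaks)
        expected = sorted([2.0 * 0.185 * 0.1, 2.0 * 0.185 * 0.05])
        for got, want in zip(areas, expected):
            assert got == pytest.approx(want, rel=0.02)

    def test_four_species_mixture_fractions(self):
        """The solution-mixture emulation (heterodimer 0.31 C_T,
        heterotrimer 0.10 C_T) deconvolves back to its composition."""
        scn = trastuzumab_like_scenario(seed=3, **K_CONST)
        res = deconvolve(scn.chromatogram, n_peaks=4)
        truth = scn.truth["mass_fractions"]
        got = {p.center: p.fraction_ct for p in res.peaks}
        want_sorted = [truth["complex2"], truth["complex1"],
                       truth["free_ab"], truth["free_ag"]]
        for (center, frac), want in zip(sorted(got.items()), want_sorted):
            assert frac == pytest.approx(want, abs=0.02)

    def test_emg_shape_supported(self):
        chrom = simulate_chromatogram(
            [dict(name="a", mass_kDa=150.0, conc_gL=1.0, tau_mL=0.15)],
            shape="emg", noise_sigma_rel=0.0, **K_CONST,
        )
        res = deconvolve(chrom, n_peaks=1, shape="emg")
        assert res.peaks[0].areas["RI"] == pytest.approx(2.0 * 0.185 * 0.1, rel=0.01)
        assert res.peaks[0].tau == pytest.approx(0.15, rel=0.05)

    def test_bad_inputs(self):
        chrom = _standard()
        with pytest.raises(ValidationError):
            deconvolve(chrom, n_peaks=0)
        with pytest.raises(ValidationError):
            deconvolve(chrom, n_peaks=1, shape="lorentzian")


class TestQuantities:
    @pytest.fixture()
    def cal(self):
        return calibrate(_standard(), 66.4, 1.0, 0.185, 0.66)

    def test_molar_masses_of_mixture_species(self, cal):
        """Absolute Mw from LS/RI recovers the species masses within 1%:
        the 147 kDa antibody, 234/320 kDa complexes, 86.4 kDa antigen."""
        scn = trastuzumab_like_scenario(seed=3, **K_CONST)
        res = deconvolve(scn.chromatogram, n_peaks=4)
        masses = sorted(molar_mass(p, cal) for p in res.peaks)
        for got, want in zip(masses, [86.4, 147.0, 234.0, 320.0]):
            assert got == pytest.approx(want, rel=0.01)

    def test_standard_self_consistency(self, cal):
        res = deconvolve(_standard(), n_peaks=1)
        assert molar_mass(res.peaks[0], cal) == pytest.approx(66.4, rel=1e-3)

    def test_mw_invariant_to_concentration_scaling(self, cal):
        for conc in (0.5, 2.0):
            chrom = simulate_chromatogram(
                [dict(name="x", mass_kDa=147.0, conc_gL=conc, dA_dc=1.38)],
                noise_sigma_rel=0.0, **K_CONST,
            )
            res = deconvolve(chrom, n_peaks=1)
            assert molar_mass(res.peaks[0], cal) == pytest.approx(147.0, rel=1e-3)

    @pytest.mark.parametrize("dadc", [1.38, 0.90, 0.0])
    def test_absorption_coefficient_recovery(self, cal, dadc):
        chrom = simulate_chromatogram(
            [dict(name="x", mass_kDa=147.0, conc_gL=1.0, dA_dc=dadc)],
            noise_sigma_rel=0.0, **K_CONST,
        )
        res = deconvolve(chrom, n_peaks=1)
        assert absorption_coefficient(res.peaks[0], cal) == pytest.approx(
            dadc, abs=0.01 if dadc == 0 else dadc * 0.01
        )

    def test_mass_conservation_of_deconvolved_peaks(self, cal):
        """Sum of per-peak mass concentrations equals the injected total
        within 2% (noise-free)."""
        scn = pertuzumab_like_scenario(seed=0, noise_sigma_rel=0.0, **K_CONST)
        res = quantify_peaks(deconvolve(scn.chromatogram, n_peaks=4), cal)
        total = sum(p.conc_gL for p in res.peaks)
        assert total == pytest.approx(scn.truth["total_mass_conc_gL"], rel=0.02)

    def test_vanishing_ri_area_guard(self, cal):
        res = deconvolve(_standard(), n_peaks=1)
        res.peaks[0].areas["RI"] = 0.0
        with pytest.raises(FitError):
            molar_mass(res.peaks[0], cal)


class TestStokesEinstein:
    def test_round_trip(self):
        h = stokes_einstein(d_s=5.81e-11)
        back = stokes_einstein(r_h=h.r_h)
        assert back.d_s == pytest.approx(5.81e-11, rel=1e-12)

    def test_antibody_sized_radius(self):
        """D = 5.81e-11 m^2/s at 309 K in a 7.0e-4 Pa s buffer is a
        ~5.5 nm hydrodynamic radius (an IgG)."""
        h = stokes_einstein(d_s=5.81e-11, temperature=309.0, viscosity=7.0e-4)
        assert h.r_h_nm == pytest.approx(5.5, abs=0.1)
        assert h.d_s * h.r_h == pytest.approx(
            BOLTZMANN * 309.0 / (6 * math.pi * 7.0e-4), rel=1e-12
        )

    def test_viscosity_proportionality(self):
        a = stokes_einstein(r_h=5.5e-9, viscosity=7.0e-4)
        b = stokes_einstein(r_h=5.5e-9, viscosity=1.4e-3)
        assert a.d_s == pytest.approx(2 * b.d_s, rel=1e-12)

    def test_input_validation(self):
        with pytest.raises(ValidationError):
            stokes_einstein()
        with pytest.raises(ValidationError):
            stokes_einstein(d_s=1e-11, r_h=5e-9)
        with pytest.raises(ValidationError):
            stokes_einstein(d_s=-1.0)


class TestExtinction:
    def test_no_chromophores(self):
        assert extinction_from_sequence(0, 0, 0, 10000.0).epsilon_280 == 0.0

    def test_single_tryptophan_unit_identity(self):
        opt = extinction_from_sequence(1, 0, 0, 5690.0)
        assert opt.epsilon_280 == 5690.0
        assert opt.dA_dc == pytest.approx(1.0)

    def test_toy_sequence_hand_sum(self):
        opt = extinction_from_sequence(2, 3, 1, 20 * 110.0)
        assert opt.epsilon_280 == pytest.approx(2 * 5690 + 3 * 1280 + 120)
        assert opt.epsilon_280 == pytest.approx(15340.0)


def test_chromatogram_csv_round_trip(tmp_path):
    chrom = _standard(noise=0.01, seed=9)
    path = tmp_path / "run.csv"
    chrom.to_csv(path)
    back = Chromatogram.from_csv(path)
    np.testing.assert_allclose(back.volume, chrom.volume)
    for d in chrom.traces:
        np.testing.assert_allclose(back.traces[d], chrom.traces[d], rtol=1e-12)
    assert back.metadata["injection_volume_uL"] == 100.0


def test_chromatogram_grid_validation():
    with pytest.raises(ValidationError):
        Chromatogram(np.array([1.0, 0.5]), {"RI": np.zeros(2)})
    with pytest.raises(ValidationError):
        Chromatogram(np.array([0.0, 0.5, 1.0]), {"RI": np.zeros(2)})
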