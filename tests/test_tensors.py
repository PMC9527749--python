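"""Displacement weights, tensor fits, Morse scan fits, and scan-table I/O."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import lmvcd as L
from lmvcd.errors import FitError, InvalidParameterError
from lmvcd.synthetic import ENERGY_SCAN_POINTS


class TestDisplacementWeights:
    def test_ch_reference_values(self):
        t_c, t_h = L.displacement_weights(12.0, 1.0)
        assert t_h == pytest.approx(12.0 / 13.0, abs=1e-15)
        assert t_c == pytest.approx(-1.0 / 13.0, abs=1e-15)

    def test_equal_masses_split_evenly(self):
        assert L.displacement_weights(5.0, 5.0) == pytest.approx((-0.5, 0.5))

    def test_clamped_heavy_atom(self):
        assert L.displacement_weights(math.inf, 1.0) == (0.0, 1.0)

    @settings(max_examples=200, deadline=None)
    @given(
        m_heavy=st.floats(0.5, 300.0),
        m_h=st.floats(0.5, 300.0),
    )
    def test_identities_hold_for_any_masses(self, m_heavy, m_h):
        t_heavy, t_h = L.displacement_weights(m_heavy, m_h)
        assert t_h - t_heavy == pytest.approx(1.0, abs=1e-12)
        assert m_heavy * t_heavy + m_h * t_h == pytest.approx(0.0, abs=1e-9)

    def test_invalid_masses(self):
        with pytest.raises(InvalidParameterError):
            L.displacement_weights(-1.0, 1.0)


class TestTensorFit:
    def test_exact_quadratic_recovered(self, synthetic_bond):
        _, tensor_scan, truth = synthetic_bond
        fit = L.fit_tensor_expansion(tensor_scan, order=2)
        np.testing.assert_allclose(
            fit.expansion.apt, truth.bond.tensors.apt, atol=1e-10
        )
        np.testing.assert_allclose(
            fit.expansion.aat, truth.bond.tensors.aat, atol=1e-16
        )
        assert all(r < 1e-10 for r in fit.rms.values())

    def test_constant_profile_has_zero_derivatives(self):
        z = np.linspace(-0.2, 0.2, 9)
        scan = L.ScanTable(
            displacements=z, tensor_samples={"apt_h_1": np.full(9, 0.25)}
        )
        fit = L.fit_tensor_expansion(scan, order=2)
        assert fit.expansion.apt[1, 0, 0] == pytest.approx(0.25, abs=1e-12)
        assert abs(fit.expansion.apt[1, 0, 1]) < 1e-10
        assert abs(fit.expansion.apt[1, 0, 2]) < 1e-10

    def test_noisy_recovery_within_tolerance(self):
        # 1% of each profile's spread, 9 points on +-0.2 A, fixed seed.
        # Value and slope are recoverable to a few percent of their
        # generating ranges; the curvature carries the design's full noise
        # amplification, so it is checked against the propagated
        # least-squares standard error (4 sigma).
        _, tensor_scan, truth = L.make_synthetic_bond(42, noise_tensor=0.01)
        fit = L.fit_tensor_expansion(tensor_scan, order=2)
        from lmvcd.synthetic import _APT_SCALE, TENSOR_SCAN_POINTS

        z = TENSOR_SCAN_POINTS
        design = np.vander(z, 3, increasing=True)
        cov_unit = np.linalg.inv(design.T @ design)  # x sigma_noise^2
        deriv_scale = np.array([1.0, 1.0, 2.0])  # k! per order
        for atom in range(2):
            for j in range(3):
                profile = tensor_scan.tensor_samples[
                    f"apt_{'x' if atom == 0 else 'h'}_{j + 1}"
                ]
                sigma_noise = 0.01 * max(np.ptp(profile), np.abs(profile).max())
                sigma_k = deriv_scale * np.sqrt(np.diag(cov_unit)) * sigma_noise
                err = np.abs(
                    fit.expansion.apt[atom, j] - truth.bond.tensors.apt[atom, j]
                )
                for order in range(3):
                    bound = max(0.05 * _APT_SCALE[order], 4.0 * sigma_k[order])
                    assert err[order] < bound, (atom, j, order)

    def test_rank_deficient_design_raises(self):
        scan = L.ScanTable(
            displacements=np.array([-0.1, 0.1]),
            tensor_samples={"apt_h_1": np.array([0.1, 0.2])},
        )
        with pytest.raises(FitError):
            L.fit_tensor_expansion(scan, order=2)

    def test_scan_without_tensors_raises(self):
        scan = L.ScanTable(
            displacements=np.linspace(-0.1, 0.1, 5), energies=np.ones(5)
        )
        with pytest.raises(FitError):
            L.fit_tensor_expansion(scan)

    def test_unit_rescaling_equivariance(self):
        z = np.linspace(-0.2, 0.2, 9)
        y = 0.1 + 0.3 * z - 0.8 * z**2
        fit1 = L.fit_tensor_expansion(
            L.ScanTable(displacements=z, tensor_samples={"apt_h_1": y})
        )
        fit2 = L.fit_tensor_expansion(
            L.ScanTable(displacements=z, tensor_samples={"apt_h_1": 10.0 * y})
        )
        np.testing.assert_allclose(
            fit2.expansion.apt[1, 0], 10.0 * fit1.expansion.apt[1, 0], rtol=1e-12
        )


class TestMorseScanFit:
    def test_noiseless_round_trip(self, synthetic_bond):
        energy_scan, _, truth = synthetic_bond
        osc = truth.bond.oscillator
        fit = L.fit_morse_scan(energy_scan, osc.reduced_mass)
        assert not fit.chi_ill_determined
        assert fit.omega0 == pytest.approx(osc.omega0, rel=1e-6)
        assert fit.chi == pytest.approx(osc.chi, rel=1e-6)
        assert fit.oscillator.omega0 == pytest.approx(osc.omega0, rel=1e-6)

    def test_printed_well_recovered_to_0p1_wavenumbers(self, c5h6):
        z = ENERGY_SCAN_POINTS
        e = c5h6.well_depth * (1 - np.exp(-c5h6.steepness * z)) ** 2
        fit = L.fit_morse_scan(
            L.ScanTable(displacements=z, energies=e), c5h6.reduced_mass
        )
        assert abs(fit.omega0 - c5h6.omega0) < 0.1
        assert abs(fit.chi - c5h6.chi) < 0.1

    def test_energy_offset_invariance(self, synthetic_bond):
        energy_scan, _, truth = synthetic_bond
        m = truth.bond.oscillator.reduced_mass
        shifted = L.ScanTable(
            displacements=energy_scan.displacements,
            energies=energy_scan.energies + 1234.5,
        )
        fit0 = L.fit_morse_scan(energy_scan, m)
        fit1 = L.fit_morse_scan(shifted, m)
        assert fit1.omega0 == pytest.approx(fit0.omega0, rel=1e-6)
        assert fit1.chi == pytest.approx(fit0.chi, rel=1e-6)
        assert fit1.energy_offset - fit0.energy_offset == pytest.approx(
            1234.5, abs=1e-3
        )

    def test_harmonic_scan_flags_ill_determined_chi(self):
        z = np.linspace(-0.05, 0.05, 11)
        e = 0.5 * 1.2e6 * z**2  # pure parabola, CH-like curvature
        fit = L.fit_morse_scan(L.ScanTable(displacements=z, energies=e), 12.0 / 13.0)
        assert fit.chi_ill_determined
        with pytest.raises(FitError):
            _ = fit.oscillator

    def test_degenerate_scans_raise(self):
        z = np.linspace(-0.1, 0.4, 11)
        with pytest.raises(FitError):  # no energies
            L.fit_morse_scan(L.ScanTable(displacements=z), 1.0)
        with pytest.raises(FitError):  # minimum at the edge
            L.fit_morse_scan(
                L.ScanTable(displacements=z, energies=np.linspace(0, 1e4, 11)), 1.0
            )
        with pytest.raises(FitError):  # negative curvature
            L.fit_morse_scan(
                L.ScanTable(displacements=z, energies=-1e4 * (z - 0.15) ** 2), 1.0
            )

    def test_noisy_recovery_single_seed(self):
        energy_scan, _, truth = L.make_synthetic_bond(7, noise_energy=0.005)
        osc = truth.bond.oscillator
        fit = L.fit_morse_scan(energy_scan, osc.reduced_mass)
        assert abs(fit.omega0 - osc.omega0) / osc.omega0 < 0.01
        assert abs(fit.chi - osc.chi) / osc.chi < 0.10

    def test_recovery_study_median_over_50_seeds(self):
        d_omega, d_chi = [], []
        for seed in range(50):
            energy_scan, _, truth = L.make_synthetic_bond(seed, noise_energy=0.005)
            osc = truth.bond.oscillator
            fit = L.fit_morse_scan(energy_scan, osc.reduced_mass)
            d_omega.append(abs(fit.omega0 - osc.omega0) / osc.omega0)
            d_chi.append(abs(fit.chi - osc.chi) / osc.chi)
        assert np.median(d_omega) < 0.005
        assert np.median(d_chi) < 0.05


class TestScanTableIO:
    def test_bit_exact_round_trip(self, tmp_path, synthetic_bond):
        energy_scan, tensor_scan, _ = synthetic_bond
        for i, scan in enumerate((energy_scan, tensor_scan)):
            path = tmp_path / f"scan{i}.tsv"
            scan.write(path, comment="round-trip fixture")
            back = L.ScanTable.read(path)
            assert np.array_equal(back.displacements, scan.displacements)
            if scan.energies is not None:
                assert np.array_equal(back.energies, scan.energies)
            assert set(back.tensor_samples) == set(scan.tensor_samples)
            for key in scan.tensor_samples:
                assert np.array_equal(back.tensor_samples[key], scan.tensor_samples[key])

    def test_validation(self):
        with pytest.raises(InvalidParameterError):  # not increasing
            L.ScanTable(displacements=np.array([0.1, 0.0, -0.1]))
        with pytest.raises(InvalidParameterError):  # zero not bracketed
            L.ScanTable(displacements=np.array([0.1, 0.2, 0.3]))
        with pytest.raises(InvalidParameterError):  # mismatched energies
            L.ScanTable(displacements=np.array([-0.1, 0.1]), energies=np.ones(3))


class TestBondGeometry:
    def test_direction_must_be_unit(self, c5h6):
        with pytest.raises(InvalidParameterError):
            L.LocalModeBond(
                label="bad",
                direction=np.array([1.0, 1.0, 0.0]),
                oscillator=c5h6,
                t_heavy=-1 / 13,
                t_hydrogen=12 / 13,
            )

    def test_create_normalizes_and_sets_weights(self):
        bond = L.LocalModeBond.create("b", [3.0, 4.0, 0.0], 3100.0, 60.0)
        np.testing.assert_allclose(bond.direction, [0.6, 0.8, 0.0], atol=1e-15)
        assert bond.t_hydrogen == pytest.approx(12 / 13)
        assert bond.oscillator.reduced_mass == pytest.approx(12 / 13)

    def test_reflection_is_involutive(self):
        _, _, truth = L.make_synthetic_bond(3)
        bond = truth.bond
        normal = np.array([0.3, -0.5, 0.81])
        twice = bond.reflected(normal).reflected(normal)
        np.testing.assert_allclose(twice.direction, bond.direction, atol=1e-14)
        np.testing.assert_allclose(twice.tensors.apt, bond.tensors.apt, atol=1e-14)
        np.testing.assert_allclose(twice.tensors.aat, bond.tensors.aat, atol=1e-20)
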