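"""Morse energetics and transition integrals against independent oracles."""

import math

import numpy as np
import pytest

import lmvcd as L
from lmvcd.errors import (
    ConvergenceError,
    InvalidParameterError,
    UnboundStateError,
)

from conftest import ALL_INTEGRAL_SPECS, integral_tolerance

ALL_REFERENCE_ROWS = [
    row for rows in L.REFERENCE_CH_PARAMETERS.values() for row in rows
]


class TestWellConversions:
    @pytest.mark.parametrize("label,omega0,chi,_r", ALL_REFERENCE_ROWS)
    def test_round_trip_is_identity(self, label, omega0, chi, _r):
        depth, steep = L.well_from_wavenumbers(omega0, chi, 12.0 / 13.0)
        om_back, chi_back = L.wavenumbers_from_well(depth, steep, 12.0 / 13.0)
        assert om_back == pytest.approx(omega0, rel=1e-9)
        assert chi_back == pytest.approx(chi, rel=1e-9)

    def test_well_depth_identity(self, c5h6):
        # D = omega0^2 / (4 chi), and the DVR ladder of that exact well
        # reproduces the Birge-Sponer energies (checked below), closing the loop
        assert c5h6.well_depth == pytest.approx(3115.01**2 / (4 * 62.28), rel=1e-12)
        assert c5h6.well_depth == pytest.approx(38950.0, rel=1e-4)

    def test_harmonic_limit_chi_vanishes(self):
        # alpha -> 0 with D*alpha^2 fixed: omega0 fixed, chi -> 0
        d0, a0 = 4.0e4, 1.8
        m = 12.0 / 13.0
        chis = []
        for scale in (1.0, 0.25, 0.0625):
            omega0, chi = L.wavenumbers_from_well(d0 / scale, a0 * math.sqrt(scale), m)
            assert omega0 == pytest.approx(
                L.wavenumbers_from_well(d0, a0, m)[0], rel=1e-12
            )
            chis.append(chi)
        assert chis[0] > chis[1] > chis[2]
        assert chis[2] == pytest.approx(chis[0] / 16.0, rel=1e-12)

    def test_degenerate_inputs_raise(self):
        with pytest.raises(InvalidParameterError):
            L.well_from_wavenumbers(3100.0, 0.0, 1.0)
        with pytest.raises(InvalidParameterError):
            L.wavenumbers_from_well(-1.0, 1.8, 1.0)
        with pytest.raises(InvalidParameterError):
            L.MorseOscillator(3100.0, 1600.0)  # chi/omega0 >= 0.5


class TestTransitionWavenumbers:
    def test_frozen_birge_sponer_values(self, c5h6):
        # frozen against DVR eigenvalue differences of the same well
        assert L.transition_wavenumber(c5h6, 1) == pytest.approx(2990.45, abs=1e-9)
        assert L.transition_wavenumber(c5h6, 2) == pytest.approx(5856.34, abs=1e-9)

    def test_harmonic_limit_is_n_omega(self):
        osc = L.MorseOscillator(3100.0, 1.0e-9)
        for n in (1, 2, 3):
            assert L.transition_wavenumber(osc, n) == pytest.approx(
                n * 3100.0, rel=1e-10
            )

    def test_unbound_state_raises(self):
        shallow = L.MorseOscillator(3100.0, 500.0)  # lambda = 3.1 -> 3 bound levels
        assert shallow.n_bound == 3
        L.transition_wavenumber(shallow, 2)
        with pytest.raises(UnboundStateError):
            L.transition_wavenumber(shallow, 3)

    @pytest.mark.parametrize("label,omega0,chi,_r", ALL_REFERENCE_ROWS)
    def test_matches_numeric_eigenvalues(self, label, omega0, chi, _r, oracle_cache):
        osc = L.MorseOscillator(omega0, chi)
        energies = oracle_cache(osc).eigenvalues()
        for n in (1, 2, 3):
            assert energies[n] - energies[0] == pytest.approx(
                L.transition_wavenumber(osc, n), abs=0.01
            )

    def test_fig1_window_containment_methyloxirane(self, reference_bonds):
        windows = {1: (2750.0, 3050.0), 2: (5550.0, 6250.0), 3: (8100.0, 9100.0)}
        for bond in reference_bonds["methyloxirane"]:
            for n, (lo, hi) in windows.items():
                nu = L.transition_wavenumber(bond.oscillator, n)
                assert lo <= nu <= hi


class TestCharacteristicLength:
    def test_ch_value_is_about_0p2_angstrom(self):
        d = L.characteristic_length(3100.0, 12.0 / 13.0)
        assert round(d, 1) == 0.2
        assert 0.15 < d < 0.25

    def test_scaling_laws(self):
        d = L.characteristic_length(3100.0, 1.0)
        assert L.characteristic_length(4 * 3100.0, 1.0) == pytest.approx(d / 2, rel=1e-12)
        assert L.characteristic_length(3100.0, 4.0) == pytest.approx(d / 2, rel=1e-12)
        assert L.characteristic_length(3100.0, 1.0e9) < 1.0e-4

    def test_invalid_inputs(self):
        with pytest.raises(InvalidParameterError):
            L.characteristic_length(-3100.0, 1.0)


class TestNumericOracle:
    def test_normalization_and_orthogonality(self, c5h6, oracle_cache):
        oracle = oracle_cache(c5h6)
        wf, dx = oracle.wavefunctions, oracle.dx
        overlap = wf.T @ wf * dx
        assert np.allclose(np.diag(overlap), 1.0, atol=1e-10)
        assert np.abs(overlap - np.eye(overlap.shape[0])).max() < 1e-8

    def test_bound_state_count(self):
        # shallow well: lambda = 3100/600 ~ 5.17 -> 5 bound levels
        osc = L.MorseOscillator(3100.0, 300.0)
        assert osc.n_bound == int(math.floor(osc.lam - 0.5)) + 1 == 5
        oracle = L.MorseOracle(
            osc, n_max=8, npts=1501, window=(-1.0, 6.0), allow_unbound=True
        )
        n_below = int(np.sum(oracle.eigenvalues() < osc.well_depth - 1.0))
        assert n_below == 5

    def test_grid_doubling_convergence_flag(self, c5h6):
        spec = L.IntegralSpec(z_power=1, final_state=1)
        val = L.numeric_oracle_integral(spec, c5h6, npts=601, check_convergence=True)
        assert val.real == pytest.approx(0.0773287, abs=1e-5)
        with pytest.raises(ConvergenceError):
            L.numeric_oracle_integral(spec, c5h6, npts=25, check_convergence=True)


class TestTransitionIntegrals:
    def test_harmonic_column_zeros(self, c5h6):
        zero_specs = [
            (2, 1, False), (1, 2, False), (3, 2, False), (1, 3, False), (2, 3, False),
            (1, 1, True), (0, 2, True), (2, 2, True), (0, 3, True), (1, 3, True),
        ]
        for k, v, mom in zero_specs:
            spec = L.IntegralSpec(
                z_power=k, final_state=v, includes_momentum=mom,
                mechanical_anharmonicity=False,
            )
            assert L.analytic_integral(spec, c5h6) == 0

    def test_phase_convention(self, c5h6):
        for spec in ALL_INTEGRAL_SPECS:
            val = L.analytic_integral(spec, c5h6)
            if spec.includes_momentum:
                assert val.real == 0.0
            else:
                assert val.imag == 0.0

    @pytest.mark.parametrize("ratio", [0.005, 0.01, 0.019, 0.025])
    def test_closed_forms_match_oracle(self, ratio, oracle_cache):
        osc = L.MorseOscillator(3100.0, 3100.0 * ratio)
        oracle = oracle_cache(osc)
        for spec in ALL_INTEGRAL_SPECS:
            ana = L.analytic_integral(spec, osc)
            num = oracle.integral(spec)
            assert abs(ana - num) <= integral_tolerance(spec, osc, num), spec.label

    def test_anharmonic_tends_to_harmonic(self):
        # relative deviation from the harmonic value decreases monotonically
        # over chi/omega0 = 1e-2 -> 1e-4 and is tiny at 1e-6
        for spec in ALL_INTEGRAL_SPECS:
            harm = L.harmonic_integral(spec, L.MorseOscillator(3100.0, 31.0))
            if harm == 0:
                continue
            devs = []
            for ratio in (1e-2, 1e-3, 1e-4, 1e-6):
                osc = L.MorseOscillator(3100.0, 3100.0 * ratio)
                ana = L.analytic_integral(spec, osc)
                href = L.harmonic_integral(
                    L.IntegralSpec(
                        spec.z_power, spec.final_state, spec.includes_momentum, False
                    ),
                    osc,
                )
                devs.append(abs(ana - href) / abs(href))
            assert devs[0] > devs[1] > devs[2] > devs[3], spec.label
            assert devs[3] < 1e-4, spec.label

    def test_frozen_regression_value(self, c5h6):
        # <0|z^2|2> of the printed C5-H6 well, frozen from the DVR oracle
        spec = L.IntegralSpec(z_power=2, final_state=2)
        assert L.analytic_integral(spec, c5h6).real == pytest.approx(
            7.9208010e-3, abs=1e-9
        )

    def test_spec_validation(self):
        with pytest.raises(InvalidParameterError):
            L.IntegralSpec(z_power=4, final_state=1)
        with pytest.raises(InvalidParameterError):
            L.IntegralSpec(z_power=0, final_state=1, includes_momentum=False)
        with pytest.raises(InvalidParameterError):
            L.IntegralSpec(z_power=3, final_state=1, includes_momentum=True)
        with pytest.raises(InvalidParameterError):
            L.IntegralSpec(z_power=1, final_state=4)

    def test_unbound_final_state_raises(self):
        shallow = L.MorseOscillator(3100.0, 700.0)  # 2 bound levels: v = 0, 1
        with pytest.raises(UnboundStateError):
            L.analytic_integral(L.IntegralSpec(z_power=1, final_state=2), shallow)
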