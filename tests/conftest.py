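import pytest

import lmvcd as L

#: all 18 transition-integral specs: z, z^2, z^3, p, zp, z^2 p against v = 1..3
ALL_INTEGRAL_SPECS = [
    L.IntegralSpec(z_power=k, final_state=v, includes_momentum=mom)
    for v in (1, 2, 3)
    for mom in (False, True)
    for k in ((0, 1, 2) if mom else (1, 2, 3))
]


@pytest.fixture(scope="session")
def c5h6():
    """The reference methyloxirane C5-H6 well (printed parameters)."""
    return L.MorseOscillator(3115.01, 62.28)


@pytest.fixture(scope="session")
def oracle_cache():
    """Memoized DVR oracles so each well is diagonalized once per session."""
    cache: dict = {}

    def get(osc: L.MorseOscillator, n_max: int = 3, npts: int = 1201) -> L.MorseOracle:
        key = (osc.omega0, osc.chi, osc.reduced_mass, n_max, npts)
        if key not in cache:
            cache[key] = L.MorseOracle(osc, n_max=n_max, npts=npts)
        return cache[key]

    return get


@pytest.fixture(scope="session")
def reference_bonds():
    return L.reference_molecules()


@pytest.fixture(scope="session")
def reference_bonds_with_tensors():
    return L.reference_molecules(with_placeholder_tensors=True)


@pytest.fixture()
def synthetic_bond():
    """A noiseless synthetic bond with recorded truth (fixed seed)."""
    energy_scan, tensor_scan, truth = L.make_synthetic_bond(20240101)
    return energy_scan, tensor_scan, truth


def integral_tolerance(spec: L.IntegralSpec, osc: L.MorseOscillator, reference: complex):
    """0.5% relative with an absolute floor of 1e-6 d^k for near-zero values."""
    floor = 1.0e-6 * osc.d_length ** max(spec.z_power, 1)
    return max(5.0e-3 * abs(reference), floor)
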