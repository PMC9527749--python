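"""Seeded synthetic fixtures with recorded ground truth.

Every generator here emulates the inputs of the CH local-mode workflow --
Morse energy scans, tensor-profile scans, and full bond sets -- from known
generating parameters, so each pipeline stage can be tested against exact
truth without external electronic-structure data.

Generated wells fall in the envelope of the printed CH parameter sets
(omega0 in [3060, 3185] cm^-1, chi in [59, 63] cm^-1) unless overridden.
Tensor profiles are exact quadratics; APT magnitudes (tenths of e) give
CH-typical dipole strengths of order 10^-39 esu^2 cm^2, and AAT magnitudes
are set so dissymmetry ratios land in the 10^-4..10^-3 range reported for
CH stretches.  Noise, when requested, is applied only after the truth is
recorded.

The printed parameter tables of the two reference molecules,
(R)-2-methyloxirane and (R)-2-methylthiirane, are exposed by
:func:`reference_molecules`; their tensor expansions are arbitrary-but-fixed
placeholders (the underlying scan ordinates are not published), so
intensity-level assertions should use synthetic bonds with known truth
instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .morse import MorseOscillator
from .tensors import LocalModeBond, ScanTable, TensorExpansion, displacement_weights

__all__ = [
    "FixtureTruth",
    "make_synthetic_bond",
    "random_tensor_expansion",
    "reference_molecules",
    "REFERENCE_CH_PARAMETERS",
]

#: default scan designs: 11 energy points on the asymmetric interval
#: [-0.3, +0.6] angstrom (to capture the anharmonic tail), 9 tensor points
#: on +-0.2 angstrom (enough for a quadratic fit)
ENERGY_SCAN_POINTS = np.linspace(-0.3, 0.6, 11)
TENSOR_SCAN_POINTS = np.linspace(-0.2, 0.2, 9)

_APT_SCALE = (0.3, 0.8, 2.0)  # e, e/A, e/A^2
_AAT_SCALE = (2.0e-7, 1.0e-6, 5.0e-6)  # tagged AAT units per order


@dataclass(frozen=True)
class FixtureTruth:
    """The generating parameters of one synthetic bond fixture."""

    seed: int
    bond: LocalModeBond
    noise_energy: float
    noise_tensor: float

    def to_dict(self) -> dict[str, float | str]:
        osc = self.bond.oscillator
        out: dict[str, float | str] = {
            "seed": self.seed,
            "label": self.bond.label,
            "omega0_cm1": osc.omega0,
            "chi_cm1": osc.chi,
            "reduced_mass_u": osc.reduced_mass,
            "well_depth_cm1": osc.well_depth,
            "steepness_per_angstrom": osc.steepness,
            "t_heavy": self.bond.t_heavy,
            "t_hydrogen": self.bond.t_hydrogen,
            "noise_energy": self.noise_energy,
            "noise_tensor": self.noise_tensor,
        }
        for j, axis in enumerate("123"):
            out[f"direction_{axis}"] = self.bond.direction[j]
        tensors = self.bond.tensors
        if tensors is not None:
            for kind in ("apt", "aat"):
                arr = getattr(tensors, kind)
                for atom, tok in enumerate(("x", "h")):
                    for j in range(3):
                        for order in range(3):
                            out[f"{kind}_{tok}_{j + 1}_d{order}"] = arr[atom, j, order]
        return out

    def write(self, path: str | Path) -> None:
        """Key-value sidecar (one ``key = value`` per line, '#' comments)."""
        rows = ["# lmvcd synthetic fixture truth"]
        for key, val in self.to_dict().items():
            if isinstance(val, float):
                rows.append(f"{key} = {val!r}")
            else:
                rows.append(f"{key} = {val}")
        Path(path).write_text("\n".join(rows) + "\n")


def random_tensor_expansion(rng: np.random.Generator) -> TensorExpansion:
    """Random APT/AAT expansion in the documented magnitude ranges."""
    apt = np.zeros((2, 3, 3))
    aat = np.zeros((2, 3, 3))
    for order in range(3):
        apt[:, :, order] = rng.uniform(-_APT_SCALE[order], _APT_SCALE[order], (2, 3))
        aat[:, :, order] = rng.uniform(-_AAT_SCALE[order], _AAT_SCALE[order], (2, 3))
    return TensorExpansion(apt=apt, aat=aat)


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    vec = rng.normal(size=3)
    return vec / np.linalg.norm(vec)


def make_synthetic_bond(
    seed: int,
    noise_energy: float = 0.0,
    noise_tensor: float = 0.0,
    overrides: dict | None = None,
    energy_points: np.ndarray = ENERGY_SCAN_POINTS,
    tensor_points: np.ndarray = TENSOR_SCAN_POINTS,
) -> tuple[ScanTable, ScanTable, FixtureTruth]:
    """One synthetic bond: (energy scan, tensor scan, truth record).

    The energy scan is sampled exactly from the generating Morse well and
    the tensor scan exactly from the generating quadratics; Gaussian noise
    (relative to the local energy value, and to each profile's spread,
    respectively) is added afterwards.  Identical seeds reproduce identical
    tables bit for bit.
    """
    overrides = overrides or {}
    rng = np.random.default_rng(seed)
    omega0 = float(overrides.get("omega0", rng.uniform(3060.0, 3185.0)))
    chi = float(overrides.get("chi", rng.uniform(59.0, 63.0)))
    direction = np.asarray(overrides.get("direction", _random_unit(rng)), dtype=float)
    m_heavy = float(overrides.get("m_heavy", 12.0))
    m_hydrogen = float(overrides.get("m_hydrogen", 1.0))
    tensors = overrides.get("tensors") or random_tensor_expansion(rng)

    bond = LocalModeBond.create(
        label=overrides.get("label", f"synthetic-{seed}"),
        direction=direction,
        omega0=omega0,
        chi=chi,
        m_heavy=m_heavy,
        m_hydrogen=m_hydrogen,
        tensors=tensors,
    )
    osc = bond.oscillator

    z_e = np.asarray(energy_points, dtype=float)
    energies = osc.well_depth * (1.0 - np.exp(-osc.steepness * z_e)) ** 2
    if noise_energy > 0.0:
        energies = energies * (1.0 + noise_energy * rng.standard_normal(z_e.size))
    energy_scan = ScanTable(displacements=z_e, energies=energies)

    z_t = np.asarray(tensor_points, dtype=float)
    samples: dict[str, np.ndarray] = {}
    for kind in ("apt", "aat"):
        arr = getattr(tensors, kind)
        for atom, tok in enumerate(("x", "h")):
            for j in range(3):
                c0, c1, c2 = arr[atom, j, :]
                profile = c0 + c1 * z_t + 0.5 * c2 * z_t**2
                if noise_tensor > 0.0:
                    scale = max(np.ptp(profile), abs(profile).max(), 1.0e-300)
                    profile = profile + noise_tensor * scale * rng.standard_normal(
                        z_t.size
                    )
                samples[f"{kind}_{tok}_{j + 1}"] = profile
    tensor_scan = ScanTable(displacements=z_t, tensor_samples=samples)

    truth = FixtureTruth(
        seed=seed, bond=bond, noise_energy=noise_energy, noise_tensor=noise_tensor
    )
    return energy_scan, tensor_scan, truth


# ---------------------------------------------------------------------------
# printed reference parameter sets
# ---------------------------------------------------------------------------

#: (bond label, omega0 cm^-1, chi cm^-1, r_eq angstrom) per molecule, as printed
REFERENCE_CH_PARAMETERS: dict[str, list[tuple[str, float, float, float]]] = {
    "methyloxirane": [
        ("C5-H6", 3115.01, 62.28, 1.0872),
        ("C2-H4", 3145.23, 61.17, 1.0848),
        ("C2-H3", 3139.60, 61.26, 1.0855),
        ("C7-H8", 3089.49, 59.39, 1.0928),
        ("C7-H9", 3107.14, 59.34, 1.0911),
        ("C7-H10", 3091.87, 59.91, 1.0920),
    ],
    "methylthiirane": [
        ("C5-H6", 3156.26, 61.66, 1.0850),
        ("C2-H4", 3182.67, 60.81, 1.0829),
        ("C2-H3", 3173.53, 60.68, 1.0839),
        ("C7-H8", 3066.17, 60.78, 1.0944),
        ("C7-H9", 3106.46, 59.13, 1.0913),
        ("C7-H10", 3106.40, 59.75, 1.0911),
    ],
}

# Arbitrary-but-fixed placeholder bond directions (normalized in code):
# roughly tetrahedral CH orientations; only used where geometry matters
# (moment vectors), never for wavenumbers.
_PLACEHOLDER_DIRECTIONS = np.array(
    [
        [0.0, 0.82, 0.57],
        [0.94, -0.23, 0.25],
        [0.41, -0.41, -0.82],
        [-0.82, 0.41, 0.41],
        [-0.41, -0.82, 0.41],
        [-0.57, 0.0, -0.82],
    ]
)

_PLACEHOLDER_TENSOR_SEED = 20230515


def reference_molecules(
    with_placeholder_tensors: bool = False,
) -> dict[str, list[LocalModeBond]]:
    """The two printed 6-oscillator CH parameter sets as bond lists.

    Wavenumber parameters (omega0, chi) and equilibrium bond lengths are
    exactly the printed values; masses are (12, 1) u.  With
    ``with_placeholder_tensors=True`` each bond carries an
    arbitrary-but-fixed synthetic tensor expansion (the published tensor
    scans exist only as figures), which is sufficient for intensity
    plumbing but carries no physical meaning.
    """
    rng = np.random.default_rng(_PLACEHOLDER_TENSOR_SEED)
    out: dict[str, list[LocalModeBond]] = {}
    for molecule, rows in REFERENCE_CH_PARAMETERS.items():
        bonds = []
        for i, (label, omega0, chi, r_eq) in enumerate(rows):
            direction = _PLACEHOLDER_DIRECTIONS[i]
            direction = direction / np.linalg.norm(direction)
            tensors = random_tensor_expansion(rng) if with_placeholder_tensors else None
            heavy_idx = int(label[1])
            hyd_idx = int(label.split("H")[1])
            bonds.append(
                LocalModeBond.create(
                    label=label,
                    direction=direction,
                    omega0=omega0,
                    chi=chi,
                    m_heavy=12.0,
                    m_hydrogen=1.0,
                    tensors=tensors,
                    r_eq=r_eq,
                    heavy_index=heavy_idx,
                    hydrogen_index=hyd_idx,
                )
            )
        out[molecule] = bonds
    return out
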