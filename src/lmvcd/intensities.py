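"""Transition moments, dipole/rotational strengths, and line lists.

The electric transition moment of the 0->v transition of one bond combines
the Taylor-expanded APT with the position transition integrals,

    mu_j = sum_alpha t_alpha [ P_j(0) <0|z|v> + (1/2) P_j' <0|z^2|v>
                               + (1/6) P_j'' <0|z^3|v> ],

and the magnetic moment mirrors it with the AAT against the
momentum-containing integrals <0|p|v>, <0|zp|v>, <0|z^2 p|v> (p on the
right).  The 1/k! factors of the expanded operator are owned by this
module; :class:`~lmvcd.tensors.TensorExpansion` stores raw derivatives.

Observables per line: dipole strength D = |mu|^2 (10^-40 esu^2 cm^2),
rotational strength R = Im(mu . m*) (10^-44 esu^2 cm^2), and the
dissymmetry ratio g = 4R/D = delta_eps/eps for an isolated line.

In the doubly harmonic limit (electrical_order=0, mechanical=False) every
overtone (v >= 2) moment vanishes identically: anharmonicity, mechanical
or electrical, is what switches the overtones on.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import EA2_TO_1E40_ESU2CM2, EA2_TO_1E44_ESU2CM2
from .errors import ConfigError, InvalidParameterError
from .morse import IntegralSpec, MorseOracle, analytic_integral, transition_wavenumber
from .tensors import LocalModeBond

__all__ = [
    "TransitionLine",
    "electric_moment",
    "magnetic_moment",
    "electric_moment_quadrature",
    "magnetic_moment_quadrature",
    "dipole_strength",
    "rotational_strength",
    "g_ratio",
    "line_list",
    "mirror_lines",
    "lines_to_dataframe",
    "write_line_list",
    "read_line_list",
    "cluster_wavenumbers",
]

#: Taylor factors 1/k! of the assembled operator, order k = 0, 1, 2
_TAYLOR = (1.0, 0.5, 1.0 / 6.0)


@dataclass(frozen=True)
class TransitionLine:
    """One 0->v local-mode transition."""

    wavenumber: float  # cm^-1
    dipole_strength: float  # 10^-40 esu^2 cm^2
    rotational_strength: float  # 10^-44 esu^2 cm^2
    g_ratio: float  # dimensionless, 4R/D
    bond_label: str
    quanta: int
    mechanical: bool = True
    electrical_order: int = 2

    def __post_init__(self) -> None:
        if self.dipole_strength < 0:
            raise InvalidParameterError("dipole strength must be >= 0")

    @property
    def assignment(self) -> str:
        return f"{self.bond_label} v=0->{self.quanta}"


def _check_order(bond: LocalModeBond, electrical_order: int) -> None:
    if electrical_order not in (0, 1, 2):
        raise ConfigError(f"electrical_order must be 0, 1 or 2, got {electrical_order}")
    if bond.tensors is None:
        raise ConfigError(f"bond {bond.label!r} has no tensor expansion attached")


def electric_moment(
    bond: LocalModeBond,
    v: int,
    electrical_order: int = 2,
    mechanical: bool = True,
) -> np.ndarray:
    """Electric transition moment <0|mu|v>, real 3-vector in e*angstrom."""
    _check_order(bond, electrical_order)
    tw = (bond.t_heavy, bond.t_hydrogen)
    mu = np.zeros(3)
    for k in range(electrical_order + 1):
        integral = analytic_integral(
            IntegralSpec(
                z_power=k + 1,
                final_state=v,
                includes_momentum=False,
                mechanical_anharmonicity=mechanical,
            ),
            bond.oscillator,
        ).real
        if integral == 0.0:
            continue
        eff = sum(tw[atom] * bond.tensors.apt[atom, :, k] for atom in range(2))
        mu += _TAYLOR[k] * eff * integral
    return mu


def magnetic_moment(
    bond: LocalModeBond,
    v: int,
    electrical_order: int = 2,
    mechanical: bool = True,
) -> np.ndarray:
    """Magnetic transition moment <0|m|v>, purely imaginary 3-vector.

    Units: e*angstrom after the hbar of the momentum integral cancels the
    1/hbar of the tagged AAT unit.
    """
    _check_order(bond, electrical_order)
    tw = (bond.t_heavy, bond.t_hydrogen)
    m_vec = np.zeros(3, dtype=complex)
    for k in range(electrical_order + 1):
        integral = analytic_integral(
            IntegralSpec(
                z_power=k,
                final_state=v,
                includes_momentum=True,
                mechanical_anharmonicity=mechanical,
            ),
            bond.oscillator,
        )
        if integral == 0.0:
            continue
        eff = sum(tw[atom] * bond.tensors.aat[atom, :, k] for atom in range(2))
        m_vec += _TAYLOR[k] * eff * integral
    return m_vec


def electric_moment_quadrature(
    bond: LocalModeBond,
    v: int,
    electrical_order: int = 2,
    oracle: MorseOracle | None = None,
) -> np.ndarray:
    """Independent route: quadrature of the expanded dipole operator.

    Samples sum_k (1/k!) P_eff_k z^(k+1) on the oracle grid and integrates
    against DVR wavefunctions; cross-checks :func:`electric_moment`.
    """
    _check_order(bond, electrical_order)
    oracle = oracle or MorseOracle(bond.oscillator, n_max=v)
    tw = (bond.t_heavy, bond.t_hydrogen)
    z = oracle.grid
    mu = np.zeros(3)
    for j in range(3):
        op = np.zeros_like(z)
        for k in range(electrical_order + 1):
            eff = sum(tw[atom] * bond.tensors.apt[atom, j, k] for atom in range(2))
            op += _TAYLOR[k] * eff * z ** (k + 1)
        mu[j] = oracle.expectation(op, v)
    return mu


def magnetic_moment_quadrature(
    bond: LocalModeBond,
    v: int,
    electrical_order: int = 2,
    oracle: MorseOracle | None = None,
) -> np.ndarray:
    """Quadrature route for the magnetic moment (p applied on the right)."""
    _check_order(bond, electrical_order)
    oracle = oracle or MorseOracle(bond.oscillator, n_max=v)
    tw = (bond.t_heavy, bond.t_hydrogen)
    z = oracle.grid
    m_vec = np.zeros(3, dtype=complex)
    for j in range(3):
        for k in range(electrical_order + 1):
            eff = sum(tw[atom] * bond.tensors.aat[atom, j, k] for atom in range(2))
            if eff == 0.0:
                continue
            m_vec[j] += 1j * _TAYLOR[k] * eff * oracle.momentum_expectation(z**k, v)
    return m_vec


def dipole_strength(mu: np.ndarray) -> float:
    """|mu|^2 in 10^-40 esu^2 cm^2, for mu in e*angstrom."""
    mu = np.asarray(mu)
    return float(np.sum(np.abs(mu) ** 2)) * EA2_TO_1E40_ESU2CM2


def rotational_strength(mu: np.ndarray, m_vec: np.ndarray) -> float:
    """Im(mu . m*) in 10^-44 esu^2 cm^2 (Rosenfeld form, m* = <v|m|0>)."""
    dot = np.sum(np.asarray(mu, dtype=complex) * np.conj(np.asarray(m_vec, dtype=complex)))
    return float(dot.imag) * EA2_TO_1E44_ESU2CM2


def g_ratio(dip: float, rot: float) -> float:
    """Dissymmetry ratio g = 4R/D for strengths in their 10^-40/10^-44 units."""
    if dip <= 0.0:
        raise InvalidParameterError("g-ratio undefined for vanishing dipole strength")
    return 4.0e-4 * rot / dip


def line_list(
    bonds: list[LocalModeBond],
    quanta: tuple[int, ...] = (1, 2, 3),
    electrical_order: int = 2,
    mechanical: bool = True,
) -> list[TransitionLine]:
    """All 0->v lines for every bond: exactly len(bonds) * len(quanta) entries.

    The purely local-mode model predicts one line per bond per overtone
    region and no combination bands, so each region always carries the
    same number of transitions.
    """
    if not bonds:
        raise ConfigError("bond list is empty")
    lines: list[TransitionLine] = []
    for bond in bonds:
        for v in sorted(set(quanta)):
            nu = transition_wavenumber(bond.oscillator, v)
            mu = electric_moment(bond, v, electrical_order, mechanical)
            m_vec = magnetic_moment(bond, v, electrical_order, mechanical)
            dip = dipole_strength(mu)
            rot = rotational_strength(mu, m_vec)
            g = g_ratio(dip, rot) if dip > 0 else 0.0
            lines.append(
                TransitionLine(
                    wavenumber=nu,
                    dipole_strength=dip,
                    rotational_strength=rot,
                    g_ratio=g,
                    bond_label=bond.label,
                    quanta=v,
                    mechanical=mechanical,
                    electrical_order=electrical_order,
                )
            )
    return lines


def mirror_lines(lines: list[TransitionLine]) -> list[TransitionLine]:
    """The enantiomer's line list: every R and g negated, D and nu kept."""
    return [
        TransitionLine(
            wavenumber=ln.wavenumber,
            dipole_strength=ln.dipole_strength,
            rotational_strength=-ln.rotational_strength,
            g_ratio=-ln.g_ratio,
            bond_label=ln.bond_label,
            quanta=ln.quanta,
            mechanical=ln.mechanical,
            electrical_order=ln.electrical_order,
        )
        for ln in lines
    ]


_LINE_COLS = [
    "wavenumber_cm1",
    "dipole_strength_1e-40",
    "rotational_strength_1e-44",
    "g_ratio",
    "bond_id",
    "quanta",
    "flags",
]


def lines_to_dataframe(lines: list[TransitionLine]) -> pd.DataFrame:
    rows = [
        {
            "wavenumber_cm1": ln.wavenumber,
            "dipole_strength_1e-40": ln.dipole_strength,
            "rotational_strength_1e-44": ln.rotational_strength,
            "g_ratio": ln.g_ratio,
            "bond_id": ln.bond_label,
            "quanta": ln.quanta,
            "flags": f"mechanical={int(ln.mechanical)};electrical_order={ln.electrical_order}",
        }
        for ln in lines
    ]
    return pd.DataFrame(rows, columns=_LINE_COLS)


def write_line_list(lines: list[TransitionLine], path: str | Path) -> None:
    lines_to_dataframe(lines).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_line_list(path: str | Path) -> list[TransitionLine]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    out = []
    for _, row in df.iterrows():
        flags = dict(item.split("=") for item in str(row["flags"]).split(";"))
        out.append(
            TransitionLine(
                wavenumber=float(row["wavenumber_cm1"]),
                dipole_strength=float(row["dipole_strength_1e-40"]),
                rotational_strength=float(row["rotational_strength_1e-44"]),
                g_ratio=float(row["g_ratio"]),
                bond_label=str(row["bond_id"]),
                quanta=int(row["quanta"]),
                mechanical=bool(int(flags.get("mechanical", 1))),
                electrical_order=int(flags.get("electrical_order", 2)),
            )
        )
    return out


def cluster_wavenumbers(values: np.ndarray, gap: float = 50.0) -> list[np.ndarray]:
    """Single-linkage 1-D clustering: split sorted values at gaps > ``gap`` cm^-1.

    With the default 50 cm^-1 threshold, the second-overtone lines of the
    printed methyloxirane parameters group into two clusters and those of
    methylthiirane into four, matching the predicted absorption band counts.
    """
    values = np.sort(np.asarray(values, dtype=float))
    if values.size == 0:
        return []
    splits = np.where(np.diff(values) > gap)[0]
    return np.split(values, splits + 1)
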