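"""Bond geometry, tensor Taylor expansions, and scan fitting.

The electric and magnetic response of one XH local mode is carried by the
jz-components (j = molecular Cartesian axis, z = bond-stretch coordinate)
of the atomic polar tensor (APT, electric-dipole derivative, units of e)
and the atomic axial tensor (AAT, magnetic coupling to the atomic momentum,
carried as an opaque tagged unit), for the two atoms of the bond.  Each
component is Taylor-expanded to second order in the bond elongation z:

    P(z) = P(0) + P' z + (1/2) P'' z^2

The zeroth-order terms are the electrically harmonic response; the first
and second derivatives are the electrical anharmonicities that switch on
the overtone intensities.

Atoms displace by t_alpha * z along the bond axis, with dimensionless
weights satisfying t_H - t_heavy = 1 (unit relative elongation) and
m_heavy t_heavy + m_H t_H = 0 (fixed centre of mass); for a 12C-1H bond
t_H = 12/13 and t_C = -1/13.

Scan tables (displacement vs energy and/or tensor components) are the
input format for parameter fitting: a Morse well is fit to the energy
profile and polynomials to the tensor profiles.
"""

from __future__ import annotations

import io as _io
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from numpy.polynomial import Polynomial
from scipy.optimize import curve_fit

from .constants import reduced_mass_u
from .errors import FitError, InvalidParameterError
from .morse import MorseOscillator, wavenumbers_from_well

__all__ = [
    "displacement_weights",
    "TensorExpansion",
    "LocalModeBond",
    "ScanTable",
    "TensorFitResult",
    "MorseFitResult",
    "fit_tensor_expansion",
    "fit_morse_scan",
]

#: unit tags recorded with the stored tensor derivatives, order 0..2
APT_UNITS = ("e", "e/angstrom", "e/angstrom^2")
AAT_UNITS = (
    "e*angstrom^2/hbar",
    "e*angstrom/hbar",
    "e/hbar",
)


def displacement_weights(m_heavy: float, m_hydrogen: float) -> tuple[float, float]:
    """Dimensionless displacement weights (t_heavy, t_hydrogen).

    A unit bond elongation moves the hydrogen by t_H and the heavy atom by
    t_heavy = t_H - 1, partitioned so the centre of mass stays fixed:
    t_H = m_heavy / (m_heavy + m_H).  For (12, 1): (-1/13, 12/13).
    An infinite heavy mass clamps the heavy atom: (0, 1).
    """
    if m_hydrogen <= 0 or m_heavy <= 0:
        raise InvalidParameterError("masses must be positive")
    if math.isinf(m_heavy):
        return 0.0, 1.0
    t_h = m_heavy / (m_heavy + m_hydrogen)
    return t_h - 1.0, t_h


@dataclass(frozen=True)
class TensorExpansion:
    """APT and AAT jz-components and their z-derivatives for one bond.

    ``apt`` and ``aat`` have shape (2, 3, 3): [atom, j, order] with atom 0
    the heavy atom and atom 1 the hydrogen, j the molecular Cartesian
    component, and order the z-derivative order (0 = equilibrium value,
    1 = first, 2 = second derivative).  Values beyond ``order`` are zero.
    """

    apt: np.ndarray
    aat: np.ndarray
    apt_units: tuple[str, ...] = APT_UNITS
    aat_units: tuple[str, ...] = AAT_UNITS

    def __post_init__(self) -> None:
        for name in ("apt", "aat"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (2, 3, 3):
                raise InvalidParameterError(
                    f"{name} must have shape (2, 3, 3), got {arr.shape}"
                )
            if not np.all(np.isfinite(arr)):
                raise InvalidParameterError(f"{name} contains non-finite entries")
            object.__setattr__(self, name, arr)

    @classmethod
    def zeros(cls) -> "TensorExpansion":
        return cls(apt=np.zeros((2, 3, 3)), aat=np.zeros((2, 3, 3)))

    def scaled(self, apt_factor: float = 1.0, aat_factor: float = 1.0) -> "TensorExpansion":
        return replace(self, apt=self.apt * apt_factor, aat=self.aat * aat_factor)

    def reflected(self, normal: np.ndarray) -> "TensorExpansion":
        """Mirror image through the plane with unit ``normal``.

        APT components transform as polar vectors in j, AAT components as
        axial vectors (extra sign flip), which is what makes the mirror
        image an enantiomer with negated rotational strengths.
        """
        m = _mirror_matrix(normal)
        apt = np.einsum("jk,akd->ajd", m, self.apt)
        aat = -np.einsum("jk,akd->ajd", m, self.aat)
        return replace(self, apt=apt, aat=aat)


def _mirror_matrix(normal: np.ndarray) -> np.ndarray:
    n = np.asarray(normal, dtype=float)
    n = n / np.linalg.norm(n)
    return np.eye(3) - 2.0 * np.outer(n, n)


@dataclass(frozen=True)
class LocalModeBond:
    """One XH bond: geometry, displacement weights, well, and tensors.

    ``direction`` is the unit vector from the heavy atom to the hydrogen in
    the molecular frame (the local +z of the stretch).  Atom indices are
    1-based for user-facing labels.
    """

    label: str
    direction: np.ndarray
    oscillator: MorseOscillator
    t_heavy: float
    t_hydrogen: float
    tensors: TensorExpansion | None = None
    heavy_index: int | None = None
    hydrogen_index: int | None = None

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        if d.shape != (3,):
            raise InvalidParameterError("direction must be a 3-vector")
        if abs(np.linalg.norm(d) - 1.0) > 1.0e-10:
            raise InvalidParameterError("direction must be a unit vector (|d|-1 > 1e-10)")
        object.__setattr__(self, "direction", d)
        if abs((self.t_hydrogen - self.t_heavy) - 1.0) > 1.0e-12:
            raise InvalidParameterError("t_hydrogen - t_heavy must equal 1")

    @classmethod
    def create(
        cls,
        label: str,
        direction: np.ndarray,
        omega0: float,
        chi: float,
        m_heavy: float = 12.0,
        m_hydrogen: float = 1.0,
        tensors: TensorExpansion | None = None,
        r_eq: float = 1.09,
        heavy_index: int | None = None,
        hydrogen_index: int | None = None,
    ) -> "LocalModeBond":
        """Build a bond from wavenumber parameters and atomic masses."""
        d = np.asarray(direction, dtype=float)
        d = d / np.linalg.norm(d)
        t_heavy, t_h = displacement_weights(m_heavy, m_hydrogen)
        osc = MorseOscillator(
            omega0=omega0,
            chi=chi,
            reduced_mass=reduced_mass_u(m_heavy, m_hydrogen)
            if not math.isinf(m_heavy)
            else m_hydrogen,
            r_eq=r_eq,
        )
        return cls(
            label=label,
            direction=d,
            oscillator=osc,
            t_heavy=t_heavy,
            t_hydrogen=t_h,
            tensors=tensors,
            heavy_index=heavy_index,
            hydrogen_index=hydrogen_index,
        )

    def with_tensors(self, tensors: TensorExpansion) -> "LocalModeBond":
        return replace(self, tensors=tensors)

    def reflected(self, normal: np.ndarray) -> "LocalModeBond":
        """The bond of the mirror-image molecule (enantiomer)."""
        m = _mirror_matrix(normal)
        tensors = self.tensors.reflected(normal) if self.tensors is not None else None
        return replace(self, direction=m @ self.direction, tensors=tensors)


# ---------------------------------------------------------------------------
# scan tables
# ---------------------------------------------------------------------------

_Z_COL = "z_angstrom"
_E_COL = "energy_cm1"


@dataclass
class ScanTable:
    """A bond-displacement scan: z grid plus energies and/or tensor samples.

    ``displacements`` are in angstrom relative to equilibrium (positive =
    elongation), strictly increasing and containing or bracketing zero.
    ``tensor_samples`` maps column names ``(apt|aat)_(x|h)_(1|2|3)`` (x =
    heavy atom, h = hydrogen, digit = molecular Cartesian component) to the
    sampled profile.
    """

    displacements: np.ndarray
    energies: np.ndarray | None = None
    tensor_samples: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        z = np.asarray(self.displacements, dtype=float)
        if z.ndim != 1 or z.size < 2:
            raise InvalidParameterError("displacements must be a 1-D grid of >= 2 points")
        if not np.all(np.diff(z) > 0):
            raise InvalidParameterError("displacements must be strictly increasing")
        if not (z[0] <= 0.0 <= z[-1]):
            raise InvalidParameterError("displacements must contain or bracket z = 0")
        self.displacements = z
        if self.energies is not None:
            e = np.asarray(self.energies, dtype=float)
            if e.shape != z.shape:
                raise InvalidParameterError("energies must match the displacement grid")
            self.energies = e
        clean: dict[str, np.ndarray] = {}
        for key, col in self.tensor_samples.items():
            col = np.asarray(col, dtype=float)
            if col.shape != z.shape:
                raise InvalidParameterError(f"column {key} must match the grid")
            clean[key] = col
        self.tensor_samples = clean

    def to_dataframe(self) -> pd.DataFrame:
        data: dict[str, np.ndarray] = {_Z_COL: self.displacements}
        if self.energies is not None:
            data[_E_COL] = self.energies
        data.update(self.tensor_samples)
        return pd.DataFrame(data)

    def write(self, path: str | Path, comment: str | None = None) -> None:
        """Write as tab-delimited text; floats use %.17g for bit-exact round trips."""
        buf = _io.StringIO()
        if comment:
            for line in comment.splitlines():
                buf.write(f"# {line}\n")
        self.to_dataframe().to_csv(buf, sep="\t", index=False, float_format="%.17g")
        Path(path).write_text(buf.getvalue())

    @classmethod
    def read(cls, path: str | Path) -> "ScanTable":
        # round_trip parsing: the default fast parser can be 1 ulp off,
        # breaking the bit-exact round-trip contract
        df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
        if _Z_COL not in df.columns:
            raise InvalidParameterError(f"scan table lacks required column {_Z_COL!r}")
        energies = df[_E_COL].to_numpy() if _E_COL in df.columns else None
        tensor_cols = {
            c: df[c].to_numpy()
            for c in df.columns
            if c.startswith("apt_") or c.startswith("aat_")
        }
        return cls(
            displacements=df[_Z_COL].to_numpy(),
            energies=energies,
            tensor_samples=tensor_cols,
        )


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TensorFitResult:
    """Polynomial tensor fit: the derivative expansion plus residual RMS per column."""

    expansion: TensorExpansion
    rms: dict[str, float]
    order: int


def _column_key(kind: str, atom: int, j: int) -> str:
    return f"{kind}_{'x' if atom == 0 else 'h'}_{j + 1}"


def fit_tensor_expansion(scan: ScanTable, order: int = 2) -> TensorFitResult:
    """Least-squares polynomial fit of tensor profiles along the scan.

    Coefficients of z^k are rescaled by k! so the stored values are the
    derivatives of the Taylor expansion.  Columns absent from the scan are
    fitted as zero.  Raises :class:`FitError` on a rank-deficient design
    (fewer distinct displacements than order + 1).
    """
    if order not in (0, 1, 2):
        raise InvalidParameterError(f"order must be 0, 1 or 2, got {order}")
    if not scan.tensor_samples:
        raise FitError("scan table contains no tensor columns")
    z = scan.displacements
    if np.unique(z).size < order + 1:
        raise FitError(
            f"need at least {order + 1} distinct displacements for order {order}"
        )
    apt = np.zeros((2, 3, 3))
    aat = np.zeros((2, 3, 3))
    rms: dict[str, float] = {}
    for kind, target in (("apt", apt), ("aat", aat)):
        for atom in range(2):
            for j in range(3):
                key = _column_key(kind, atom, j)
                if key not in scan.tensor_samples:
                    continue
                y = scan.tensor_samples[key]
                poly = Polynomial.fit(z, y, deg=order).convert()
                coeffs = poly.coef
                for k in range(min(order, 2) + 1):
                    if k < coeffs.size:
                        target[atom, j, k] = coeffs[k] * math.factorial(k)
                resid = y - poly(z)
                rms[key] = float(np.sqrt(np.mean(resid**2)))
    return TensorFitResult(
        expansion=TensorExpansion(apt=apt, aat=aat), rms=rms, order=order
    )


@dataclass(frozen=True)
class MorseFitResult:
    """Nonlinear Morse fit of an energy scan.

    ``omega0``/``chi`` are the Birge-Sponer constants implied by the fitted
    well; ``z_min`` is the fitted minimum position relative to the scan's
    zero, ``energy_offset`` the fitted energy at the minimum.  When the scan
    carries no usable anharmonic information (e.g. a narrow, effectively
    harmonic scan) ``chi_ill_determined`` is set and ``oscillator`` access
    raises.
    """

    omega0: float
    chi: float
    well_depth: float
    steepness: float
    z_min: float
    energy_offset: float
    reduced_mass: float
    rms: float
    chi_ill_determined: bool
    chi_stderr: float

    @property
    def oscillator(self) -> MorseOscillator:
        if self.chi_ill_determined:
            raise FitError(
                "anharmonicity is ill-determined by this scan "
                f"(chi = {self.chi:.3g} +- {self.chi_stderr:.3g} cm^-1)"
            )
        return MorseOscillator(
            omega0=self.omega0, chi=self.chi, reduced_mass=self.reduced_mass
        )


def _morse_model(z: np.ndarray, depth: float, alpha: float, z0: float, e0: float):
    return e0 + depth * (1.0 - np.exp(-alpha * (z - z0))) ** 2


def fit_morse_scan(scan: ScanTable, reduced_mass: float) -> MorseFitResult:
    """Fit a Morse well (D, alpha, z_min, offset) to an energy scan.

    Initialization is a parabola through the three lowest-energy points;
    the converted (omega0, chi) follow from the fitted well.  Raises
    :class:`FitError` for scans without curvature, with an exterior
    minimum, or on optimizer failure.
    """
    if scan.energies is None:
        raise FitError("scan table has no energy column")
    z, e = scan.displacements, scan.energies
    if z.size < 5:
        raise FitError("a Morse fit needs at least 5 scan points")
    i_min = int(np.argmin(e))
    if i_min == 0 or i_min == z.size - 1:
        raise FitError("scan minimum must be interior to the displacement range")
    # parabolic initial guess from the three points around the minimum
    sel = slice(i_min - 1, i_min + 2)
    c2 = np.polyfit(z[sel], e[sel], 2)[0]
    if c2 <= 0:
        raise FitError("scan has no positive curvature at its minimum")
    depth0 = max(4.0 * (e.max() - e.min()), 1.0)
    alpha0 = math.sqrt(c2 / depth0)  # from f = 2 D alpha^2
    # a finite depth ceiling keeps the optimizer out of the flat
    # harmonic valley (D -> inf, alpha -> 0 at fixed curvature); hitting
    # it marks the anharmonicity as ill-determined below
    depth_cap = 5.0e6
    p0 = [depth0, alpha0, z[i_min], e.min()]
    bounds = (
        [0.0, 1.0e-4, z[0], -np.inf],
        [depth_cap, 100.0, z[-1], np.inf],
    )
    try:
        popt, pcov = curve_fit(
            _morse_model, z, e, p0=p0, bounds=bounds, maxfev=20000
        )
    except RuntimeError as exc:
        raise FitError(f"Morse fit did not converge: {exc}") from exc
    depth, alpha, z0, e0 = popt
    omega0, chi = wavenumbers_from_well(depth, alpha, reduced_mass)
    resid = e - _morse_model(z, *popt)
    rms = float(np.sqrt(np.mean(resid**2)))
    # chi is quadratic in alpha: propagate the alpha standard error
    alpha_var = float(pcov[1, 1]) if np.all(np.isfinite(pcov)) else np.inf
    chi_stderr = (
        2.0 * chi * math.sqrt(alpha_var) / alpha if np.isfinite(alpha_var) else np.inf
    )
    ill = (
        (not np.isfinite(chi_stderr))
        or chi_stderr > 0.5 * chi
        or chi < 0.5
        or depth > 0.9 * depth_cap
    )
    return MorseFitResult(
        omega0=float(omega0),
        chi=float(chi),
        well_depth=float(depth),
        steepness=float(alpha),
        z_min=float(z0),
        energy_offset=float(e0),
        reduced_mass=float(reduced_mass),
        rms=rms,
        chi_ill_determined=bool(ill),
        chi_stderr=float(chi_stderr),
    )
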