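"""Band-shape synthesis: line lists -> molar absorptivity and CD curves.

Each transition line contributes an area-normalized Lorentzian

    L(nu) = (1/pi) * gamma / ((nu - nu0)^2 + gamma^2),

parameterized by its half-width at half-maximum gamma (HWHM, not FWHM).
The absorptivity and CD traces are

    eps(nu)       = kappa * nu0 * D * L(nu),
    delta_eps(nu) = 4 kappa * nu0 * R * L(nu),

with kappa = 8 pi^3 N_A / (3000 h c ln10) the cgs integrated-absorption
constant, so that the areas of eps/nu and delta_eps/nu recover kappa*D and
4*kappa*R exactly, and the band-level delta_eps/eps of an isolated line
equals its g = 4R/D.

Region-specific default widths follow spectroscopic practice for these
molecules: 7 cm^-1 in the mid-IR, 10/15/40 cm^-1 in the fundamental /
first-overtone / second-overtone CH-stretching regions, 30 cm^-1 in the
stretch-bend combination region.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import EPS_INTEGRAL_PER_D
from .errors import ConfigError, InvalidParameterError
from .intensities import TransitionLine, mirror_lines

__all__ = [
    "Spectrum",
    "REGION_HWHM",
    "region_defaults",
    "default_grid",
    "lorentzian_convolve",
    "mirror_enantiomer",
    "write_spectrum_text",
    "read_spectrum_text",
    "write_jcamp",
]

REGION_HWHM: dict[str, float] = {
    "mid_ir": 7.0,
    "fundamental": 10.0,
    "first_overtone": 15.0,
    "combination": 30.0,
    "second_overtone": 40.0,
}

#: the spectral windows (cm^-1) of the three CH-stretching regions
REGION_WINDOWS: dict[str, tuple[float, float]] = {
    "fundamental": (2750.0, 3050.0),
    "first_overtone": (5550.0, 6250.0),
    "second_overtone": (8100.0, 9100.0),
}

QUANTA_REGION = {1: "fundamental", 2: "first_overtone", 3: "second_overtone"}


def region_defaults(region: str) -> float:
    """Default Lorentzian HWHM (cm^-1) for a named spectral region."""
    try:
        return REGION_HWHM[region]
    except KeyError:
        raise ConfigError(
            f"unknown region {region!r}; known: {sorted(REGION_HWHM)}"
        ) from None


@dataclass
class Spectrum:
    """A simulated spectrum on a uniform wavenumber grid.

    ``epsilon`` is the decadic molar absorptivity (L mol^-1 cm^-1),
    ``delta_epsilon`` the circular-dichroism trace in the same units.
    """

    grid: np.ndarray
    epsilon: np.ndarray
    delta_epsilon: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        g = np.asarray(self.grid, dtype=float)
        steps = np.diff(g)
        if g.size < 2 or not np.all(steps > 0):
            raise InvalidParameterError("grid must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=1.0e-9):
            raise InvalidParameterError("grid must be uniformly spaced")
        self.grid = g
        self.epsilon = np.asarray(self.epsilon, dtype=float)
        self.delta_epsilon = np.asarray(self.delta_epsilon, dtype=float)
        if self.epsilon.shape != g.shape or self.delta_epsilon.shape != g.shape:
            raise InvalidParameterError("traces must match the grid")

    @property
    def step(self) -> float:
        return float(self.grid[1] - self.grid[0])

    def mirrored(self) -> "Spectrum":
        """The enantiomer's spectrum: delta_eps negated, eps unchanged."""
        meta = dict(self.metadata)
        meta["mirrored"] = not meta.get("mirrored", False)
        return replace(self, delta_epsilon=-self.delta_epsilon, metadata=meta)

    def __add__(self, other: "Spectrum") -> "Spectrum":
        if not np.array_equal(self.grid, other.grid):
            raise InvalidParameterError("cannot add spectra on different grids")
        return Spectrum(
            grid=self.grid,
            epsilon=self.epsilon + other.epsilon,
            delta_epsilon=self.delta_epsilon + other.delta_epsilon,
            metadata={"sum": True},
        )


def default_grid(lines: list[TransitionLine], hwhm: float, step: float | None = None) -> np.ndarray:
    """Uniform grid spanning all lines +- 10*HWHM with step HWHM/10."""
    if not lines:
        raise ConfigError("no lines to place on a grid")
    step = hwhm / 10.0 if step is None else step
    lo = min(ln.wavenumber for ln in lines) - 10.0 * hwhm
    hi = max(ln.wavenumber for ln in lines) + 10.0 * hwhm
    n = int(np.ceil((hi - lo) / step)) + 1
    return lo + step * np.arange(n)


def lorentzian_convolve(
    lines: list[TransitionLine],
    hwhm: float,
    grid: np.ndarray | None = None,
    metadata: dict | None = None,
) -> Spectrum:
    """Convolve a line list into eps / delta_eps traces.

    Emits a truncation warning (with the largest lost area fraction) when
    the grid does not span every line by at least 10 HWHM.
    """
    if hwhm <= 0:
        raise InvalidParameterError("hwhm must be > 0")
    if grid is None:
        grid = default_grid(lines, hwhm)
    grid = np.asarray(grid, dtype=float)
    eps = np.zeros_like(grid)
    deps = np.zeros_like(grid)
    worst_loss = 0.0
    for ln in lines:
        if ln.wavenumber - grid[0] < 10 * hwhm or grid[-1] - ln.wavenumber < 10 * hwhm:
            # fraction of a Lorentzian outside the covered interval
            a = np.arctan((grid[0] - ln.wavenumber) / hwhm)
            b = np.arctan((grid[-1] - ln.wavenumber) / hwhm)
            worst_loss = max(worst_loss, 1.0 - (b - a) / np.pi)
        shape = (hwhm / np.pi) / ((grid - ln.wavenumber) ** 2 + hwhm**2)
        eps += EPS_INTEGRAL_PER_D * ln.wavenumber * ln.dipole_strength * 1.0e-40 * shape
        deps += (
            4.0
            * EPS_INTEGRAL_PER_D
            * ln.wavenumber
            * ln.rotational_strength
            * 1.0e-44
            * shape
        )
    if worst_loss > 0.0:
        warnings.warn(
            f"grid truncates at least one line; up to {100 * worst_loss:.2f}% "
            "of its band area falls outside the grid",
            stacklevel=2,
        )
    meta = {"hwhm_cm1": hwhm, "n_lines": len(lines)}
    if metadata:
        meta.update(metadata)
    return Spectrum(grid=grid, epsilon=eps, delta_epsilon=deps, metadata=meta)


def mirror_enantiomer(obj):
    """Mirror a :class:`Spectrum` or a line list into its enantiomer."""
    if isinstance(obj, Spectrum):
        return obj.mirrored()
    return mirror_lines(obj)


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------


def write_spectrum_text(spectrum: Spectrum, path: str | Path) -> None:
    """Three-column delimited text: wavenumber, eps, delta_eps."""
    df = pd.DataFrame(
        {
            "wavenumber_cm1": spectrum.grid,
            "epsilon": spectrum.epsilon,
            "delta_epsilon": spectrum.delta_epsilon,
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_spectrum_text(path: str | Path) -> Spectrum:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return Spectrum(
        grid=df["wavenumber_cm1"].to_numpy(),
        epsilon=df["epsilon"].to_numpy(),
        delta_epsilon=df["delta_epsilon"].to_numpy(),
    )


def write_jcamp(
    spectrum: Spectrum,
    path: str | Path,
    title: str = "lmvcd simulated spectrum",
    trace: str = "epsilon",
) -> None:
    """Minimal JCAMP-DX 4.24 export (AFFN XYDATA, cm^-1 abscissa).

    ``trace`` selects ``"epsilon"`` or ``"delta_epsilon"``.
    """
    if trace not in ("epsilon", "delta_epsilon"):
        raise ConfigError(f"unknown trace {trace!r}")
    y = getattr(spectrum, trace)
    x = spectrum.grid
    lines = [
        f"##TITLE={title}",
        "##JCAMP-DX=4.24",
        "##DATA TYPE=INFRARED SPECTRUM",
        "##ORIGIN=lmvcd",
        "##OWNER=",
        "##XUNITS=1/CM",
        f"##YUNITS={'MOLAR ABSORPTIVITY' if trace == 'epsilon' else 'DELTA MOLAR ABSORPTIVITY'}",
        f"##FIRSTX={x[0]:.6f}",
        f"##LASTX={x[-1]:.6f}",
        f"##DELTAX={spectrum.step:.6f}",
        "##XFACTOR=1.0",
        "##YFACTOR=1.0",
        f"##NPOINTS={x.size}",
        f"##FIRSTY={y[0]:.8e}",
        "##XYDATA=(X++(Y..Y))",
    ]
    per_row = 4
    for i in range(0, x.size, per_row):
        ys = " ".join(f"{v:.8e}" for v in y[i : i + per_row])
        lines.append(f"{x[i]:.4f} {ys}")
    lines.append("##END=")
    Path(path).write_text("\n".join(lines) + "\n")
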