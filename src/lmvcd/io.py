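"""Run configuration, XYZ geometry I/O, and the end-to-end pipeline.

The pipeline ties the stages together: resolve each bond's Morse well
(given directly or fit from an energy scan) and tensor expansion (fit from
a tensor scan, or a seeded synthetic placeholder), assemble the line list,
and convolve one spectrum per requested overtone region.  Outputs are
deterministic text artifacts: a line list, per-region spectra (optionally
also JCAMP-DX), and a log echoing every toggle and physical constant used.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import constants
from .errors import ConfigError
from .intensities import TransitionLine, line_list, write_line_list
from .spectra import (
    QUANTA_REGION,
    REGION_HWHM,
    lorentzian_convolve,
    write_jcamp,
    write_spectrum_text,
)
from .synthetic import random_tensor_expansion
from .tensors import (
    LocalModeBond,
    ScanTable,
    fit_morse_scan,
    fit_tensor_expansion,
)

__all__ = [
    "Atom",
    "read_xyz",
    "write_xyz",
    "bond_direction",
    "RunConfig",
    "load_config",
    "run_pipeline",
]


@dataclass(frozen=True)
class Atom:
    element: str
    position: tuple[float, float, float]


def read_xyz(path: str | Path) -> list[Atom]:
    """Read a standard XYZ file (count line, comment line, element x y z).

    Atoms are returned in file order; user-facing indices are 1-based to
    match conventional atom numbering.  Malformed counts or records raise
    :class:`ConfigError` with the offending line number.
    """
    text = Path(path).read_text().splitlines()
    if not text:
        raise ConfigError(f"{path}: empty XYZ file")
    try:
        count = int(text[0].strip())
    except ValueError:
        raise ConfigError(f"{path}:1: first line must be the atom count") from None
    records = [ln for ln in text[2 : 2 + count + 1] if ln.strip()]
    if len(records) != count:
        raise ConfigError(
            f"{path}: count line says {count} atoms but found {len(records)} records"
        )
    atoms: list[Atom] = []
    for i, line in enumerate(records, start=3):
        parts = line.split()
        if len(parts) < 4:
            raise ConfigError(f"{path}:{i}: expected 'element x y z', got {line!r}")
        try:
            xyz = tuple(float(p) for p in parts[1:4])
        except ValueError:
            raise ConfigError(f"{path}:{i}: non-numeric coordinate in {line!r}") from None
        atoms.append(Atom(element=parts[0], position=xyz))
    return atoms


def write_xyz(atoms: list[Atom], path: str | Path, comment: str = "") -> None:
    lines = [str(len(atoms)), comment.replace("\n", " ")]
    for atom in atoms:
        x, y, z = atom.position
        lines.append(f"{atom.element} {x:.10f} {y:.10f} {z:.10f}")
    Path(path).write_text("\n".join(lines) + "\n")


def bond_direction(atoms: list[Atom], heavy_index: int, hydrogen_index: int) -> np.ndarray:
    """Unit vector heavy -> hydrogen from 1-based atom indices."""
    for idx in (heavy_index, hydrogen_index):
        if not (1 <= idx <= len(atoms)):
            raise ConfigError(f"atom index {idx} outside 1..{len(atoms)}")
    a = np.asarray(atoms[heavy_index - 1].position)
    b = np.asarray(atoms[hydrogen_index - 1].position)
    vec = b - a
    norm = np.linalg.norm(vec)
    if norm == 0:
        raise ConfigError("coincident atoms define no bond direction")
    return vec / norm


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Validated pipeline configuration (usually loaded from YAML)."""

    bonds: list[dict]
    quanta: tuple[int, ...] = (1, 2, 3)
    mechanical: bool = True
    electrical_order: int = 2
    hwhm: dict[str, float] = field(default_factory=dict)
    output_dir: str = "."
    prefix: str = "lmvcd"
    jcamp: bool = False
    xyz: str | None = None
    seed: int = 0
    base_dir: Path = field(default_factory=Path)

    def __post_init__(self) -> None:
        if not self.bonds:
            raise ConfigError("config defines no bonds")
        if self.electrical_order not in (0, 1, 2):
            raise ConfigError(f"electrical_order must be 0..2, got {self.electrical_order}")
        bad = [q for q in self.quanta if q not in (1, 2, 3)]
        if bad:
            raise ConfigError(f"quanta must be within {{1,2,3}}, got {bad}")
        for region in self.hwhm:
            if region not in REGION_HWHM:
                raise ConfigError(f"unknown region {region!r} in hwhm overrides")
        for path in self._referenced_files():
            if not path.exists():
                raise ConfigError(f"referenced file does not exist: {path}")

    def _referenced_files(self) -> list[Path]:
        paths = []
        if self.xyz:
            paths.append(self.base_dir / self.xyz)
        for spec in self.bonds:
            for key in ("energy_scan", "tensor_scan"):
                if spec.get(key):
                    paths.append(self.base_dir / spec[key])
        return paths


def load_config(path: str | Path) -> RunConfig:
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    out = raw.get("output", {})
    return RunConfig(
        bonds=raw.get("bonds", []),
        quanta=tuple(raw.get("quanta", [1, 2, 3])),
        mechanical=bool(raw.get("mechanical", True)),
        electrical_order=int(raw.get("electrical_order", 2)),
        hwhm={k: float(v) for k, v in raw.get("hwhm", {}).items()},
        output_dir=out.get("directory", "."),
        prefix=out.get("prefix", "lmvcd"),
        jcamp=bool(out.get("jcamp", False)),
        xyz=raw.get("xyz"),
        seed=int(raw.get("seed", 0)),
        base_dir=path.parent,
    )


def _resolve_bond(spec: dict, config: RunConfig, atoms: list[Atom] | None) -> LocalModeBond:
    label = spec.get("label", "bond")
    m_heavy = float(spec.get("m_heavy", 12.0))
    m_hydrogen = float(spec.get("m_hydrogen", 1.0))

    if "direction" in spec:
        direction = np.asarray(spec["direction"], dtype=float)
    elif "atoms" in spec:
        if atoms is None:
            raise ConfigError(f"bond {label!r} uses atom indices but no xyz file is set")
        direction = bond_direction(atoms, int(spec["atoms"][0]), int(spec["atoms"][1]))
    else:
        raise ConfigError(f"bond {label!r} needs 'direction' or 'atoms'")

    if "omega0" in spec and "chi" in spec:
        omega0, chi = float(spec["omega0"]), float(spec["chi"])
    elif spec.get("energy_scan"):
        scan = ScanTable.read(config.base_dir / spec["energy_scan"])
        fit = fit_morse_scan(scan, reduced_mass=m_heavy * m_hydrogen / (m_heavy + m_hydrogen))
        omega0, chi = fit.omega0, fit.chi
    else:
        raise ConfigError(f"bond {label!r} needs (omega0, chi) or an energy_scan")

    if spec.get("tensor_scan"):
        scan = ScanTable.read(config.base_dir / spec["tensor_scan"])
        tensors = fit_tensor_expansion(scan, order=2).expansion
    elif "tensors_seed" in spec:
        tensors = random_tensor_expansion(
            np.random.default_rng(int(spec["tensors_seed"]))
        )
    else:
        raise ConfigError(f"bond {label!r} needs 'tensor_scan' or 'tensors_seed'")

    return LocalModeBond.create(
        label=label,
        direction=direction,
        omega0=omega0,
        chi=chi,
        m_heavy=m_heavy,
        m_hydrogen=m_hydrogen,
        tensors=tensors,
    )


@dataclass(frozen=True)
class PipelineResult:
    lines: list[TransitionLine]
    line_list_path: Path
    spectrum_paths: dict[str, Path]
    log_path: Path


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Fit -> line list -> spectra, writing deterministic text artifacts.

    Outputs land in ``config.output_dir``: ``<prefix>_lines.tsv``, one
    ``<prefix>_<region>.tsv`` per requested quanta (plus ``.jdx`` when
    JCAMP export is enabled), and ``<prefix>_log.txt``.  Identical configs
    produce byte-identical artifacts (the log carries no timestamps).
    """
    out_dir = config.base_dir / config.output_dir
    out_dir.mkdir(parents=True, exist_ok=True)
    atoms = read_xyz(config.base_dir / config.xyz) if config.xyz else None
    bonds = [_resolve_bond(spec, config, atoms) for spec in config.bonds]

    lines = line_list(
        bonds,
        quanta=config.quanta,
        electrical_order=config.electrical_order,
        mechanical=config.mechanical,
    )
    line_path = out_dir / f"{config.prefix}_lines.tsv"
    write_line_list(lines, line_path)

    spectrum_paths: dict[str, Path] = {}
    for v in sorted(set(config.quanta)):
        region = QUANTA_REGION[v]
        hwhm = config.hwhm.get(region, REGION_HWHM[region])
        region_lines = [ln for ln in lines if ln.quanta == v]
        spectrum = lorentzian_convolve(
            region_lines, hwhm=hwhm, metadata={"region": region}
        )
        spath = out_dir / f"{config.prefix}_{region}.tsv"
        write_spectrum_text(spectrum, spath)
        spectrum_paths[region] = spath
        if config.jcamp:
            write_jcamp(
                spectrum,
                out_dir / f"{config.prefix}_{region}.jdx",
                title=f"{config.prefix} {region}",
            )

    log_path = out_dir / f"{config.prefix}_log.txt"
    log_path.write_text(_render_log(config, bonds, lines))
    return PipelineResult(
        lines=lines,
        line_list_path=line_path,
        spectrum_paths=spectrum_paths,
        log_path=log_path,
    )


def _render_log(config: RunConfig, bonds: list[LocalModeBond], lines) -> str:
    import importlib.metadata

    try:
        version = importlib.metadata.version("lmvcd")
    except importlib.metadata.PackageNotFoundError:  # pragma: no cover
        version = "unknown"
    rows = [
        f"lmvcd version: {version}",
        f"seed: {config.seed}",
        f"mechanical anharmonicity: {config.mechanical}",
        f"electrical order: {config.electrical_order}",
        f"quanta: {sorted(set(config.quanta))}",
        "",
        "constants (cgs):",
        f"  hbar = {constants.HBAR!r} erg s",
        f"  c = {constants.C_LIGHT!r} cm/s",
        f"  amu = {constants.AMU!r} g",
        f"  e = {constants.E_ESU!r} esu",
        f"  eps integral per D = {constants.EPS_INTEGRAL_PER_D!r}",
        "",
        "bonds:",
    ]
    for bond in bonds:
        osc = bond.oscillator
        rows.append(
            f"  {bond.label}: omega0={osc.omega0!r} chi={osc.chi!r} "
            f"m_R={osc.reduced_mass!r} d={osc.d_length!r}"
        )
    rows.append("")
    rows.append(f"lines computed: {len(lines)}")
    return "\n".join(rows) + "\n"
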