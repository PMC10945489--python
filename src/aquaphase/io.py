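"""File formats and run configuration.

Readers accept the two text configuration formats the pipeline consumes
(GRO, with nm coordinates converted to Å, and XYZ with the box on the
comment line) plus CSV tables for coexistence points, phase observables
and density traces.  Reports are written as JSON (single results) or CSV
(tables), round-trip stable.  Coordinate parsing is delegated to
MDAnalysis; parse failures surface as :class:`ParseError` with file
context.

Internal units are fixed (Å, K, bar, g/L, kJ/mol); conversions happen
only here, at the boundary.
"""

from __future__ import annotations

import dataclasses
import json
import re
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .critical import CoexistencePoint, CriticalPointFit
from .npt import DensityTrace
from .slab import Configuration
from .thermo import PhaseObservables

__all__ = [
    "ParseError",
    "RunConfig",
    "load_config",
    "read_configuration",
    "read_configurations",
    "write_xyz",
    "write_gro",
    "read_coexistence_csv",
    "write_coexistence_csv",
    "read_phase_observables_csv",
    "read_trace",
    "write_trace",
    "write_profile_csv",
    "write_report",
    "read_report",
]

_SUPPORTED_LENGTH_UNITS = {"A", "nm"}
_SUPPORTED_ENERGY_UNITS = {"kJ/mol", "kcal/mol"}


class ParseError(ValueError):
    """A file did not parse as the expected format."""


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Validated run-wide settings (units, bin width, thresholds, seed)."""

    length_unit: str = "A"
    energy_unit: str = "kJ/mol"
    bin_width: float = 0.5
    beta: float = 0.326
    collapse_fraction: float = 0.5
    recovery_fraction: float = 0.8
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.length_unit not in _SUPPORTED_LENGTH_UNITS:
            raise ValueError(f"length unit must be one of {_SUPPORTED_LENGTH_UNITS}")
        if self.energy_unit not in _SUPPORTED_ENERGY_UNITS:
            raise ValueError(f"energy unit must be one of {_SUPPORTED_ENERGY_UNITS}")
        for name in ("collapse_fraction", "recovery_fraction"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML run configuration; unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ParseError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def _detect_format(path: Path, fmt: str | None) -> str:
    if fmt:
        return fmt.lower()
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("gro", "xyz"):
        return suffix
    raise ParseError(f"cannot infer format of {path}; pass fmt='gro' or 'xyz'")


def _xyz_box_from_comment(path: Path) -> tuple[float, float, float] | None:
    """Box lengths [Å] from the XYZ comment line, if present.

    Accepts either three whitespace-separated floats or an extended-XYZ
    ``Lattice="lx 0 0 0 ly 0 0 0 lz"`` entry.
    """
    with open(path) as fh:
        fh.readline()
        comment = fh.readline()
    m = re.search(r'Lattice="([^"]+)"', comment)
    if m:
        vals = [float(v) for v in m.group(1).split()]
        if len(vals) == 9:
            return vals[0], vals[4], vals[8]
    floats = re.findall(r"[-+]?\d*\.?\d+(?:[eE][-+]?\d+)?", comment)
    if len(floats) >= 3:
        return float(floats[0]), float(floats[1]), float(floats[2])
    return None


def read_configuration(
    path: str | Path,
    fmt: str | None = None,
    box: tuple[float, float, float] | None = None,
    oxygen_only: bool = True,
) -> Configuration:
    """Read one configuration from a GRO or XYZ file, coordinates in Å.

    GRO coordinates (nm) are converted to Å by MDAnalysis; the box record
    must be orthorhombic.  XYZ files carry the box on the comment line
    (three lengths in Å, or an extended-XYZ ``Lattice``); alternatively
    pass ``box=`` explicitly.  By default only atoms whose name starts
    with "O" are kept (molecule reference = oxygen site); if none match,
    all atoms are used.
    """
    import MDAnalysis as mda

    path = Path(path)
    fmt = _detect_format(path, fmt)
    if not path.exists():
        raise ParseError(f"{path}: no such file")
    try:
        with np.errstate(all="ignore"):
            universe = mda.Universe(str(path), format=fmt.upper())
        positions = universe.atoms.positions.astype(float)
        names = universe.atoms.names
    except Exception as exc:  # MDAnalysis raises many exception types
        raise ParseError(f"{path}: failed to parse as {fmt.upper()}: {exc}") from exc
    if fmt == "gro":
        dims = universe.dimensions
        if dims is None or np.any(np.asarray(dims[:3]) <= 0):
            raise ParseError(f"{path}: missing or invalid box record")
        if not np.allclose(dims[3:], 90.0):
            raise ParseError(f"{path}: only orthorhombic boxes are supported")
        file_box = (float(dims[0]), float(dims[1]), float(dims[2]))
    else:
        file_box = _xyz_box_from_comment(path)
    box = box or file_box
    if box is None:
        raise ParseError(
            f"{path}: XYZ file has no box on the comment line; pass box=(Lx, Ly, Lz)"
        )
    if oxygen_only:
        mask = np.array([str(n).upper().startswith("O") for n in names])
        if mask.any():
            positions = positions[mask]
    if len(positions) == 0:
        raise ParseError(f"{path}: no atoms")
    return Configuration(box=tuple(box), positions=positions)


def read_configurations(paths, **kwargs) -> list[Configuration]:
    """Read several single-frame configuration files."""
    return [read_configuration(p, **kwargs) for p in sorted(map(str, paths))]


def write_xyz(config: Configuration, path: str | Path, element: str = "O") -> None:
    """Write a configuration as XYZ with the box on the comment line (Å)."""
    lx, ly, lz = config.box
    lines = [str(config.n_molecules), f"{lx:.6f} {ly:.6f} {lz:.6f}"]
    for x, y, z in config.positions:
        lines.append(f"{element} {x:.6f} {y:.6f} {z:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_gro(config: Configuration, path: str | Path) -> None:
    """Write a configuration as a GRO file (oxygen sites only, nm)."""
    import MDAnalysis as mda

    n = config.n_molecules
    universe = mda.Universe.empty(
        n, n_residues=n, atom_resindex=np.arange(n), trajectory=True
    )
    universe.add_TopologyAttr("names", ["OW"] * n)
    universe.add_TopologyAttr("resnames", ["SOL"] * n)
    universe.add_TopologyAttr("resids", np.arange(1, n + 1))
    universe.atoms.positions = config.positions
    universe.dimensions = [*config.box, 90.0, 90.0, 90.0]
    universe.atoms.write(str(path))


def read_coexistence_csv(path: str | Path) -> list[CoexistencePoint]:
    """Read a coexistence table CSV (T, rho_l, rho_v[, sd_l, sd_v])."""
    frame = pd.read_csv(path)
    required = {"T", "rho_l", "rho_v"}
    if not required.issubset(frame.columns):
        raise ParseError(f"{path}: need columns {sorted(required)}")
    points = []
    for _, row in frame.iterrows():
        points.append(
            CoexistencePoint(
                T=float(row["T"]),
                rho_l=float(row["rho_l"]),
                rho_v=float(row["rho_v"]),
                sd_rho_l=float(row["sd_l"]) if "sd_l" in frame.columns and pd.notna(row.get("sd_l")) else None,
                sd_rho_v=float(row["sd_v"]) if "sd_v" in frame.columns and pd.notna(row.get("sd_v")) else None,
            )
        )
    return points


def write_coexistence_csv(points, path: str | Path) -> None:
    """Write coexistence points with the canonical header."""
    frame = pd.DataFrame(
        {
            "T": [p.T for p in points],
            "rho_l": [p.rho_l for p in points],
            "rho_v": [p.rho_v for p in points],
            "sd_l": [p.sd_rho_l for p in points],
            "sd_v": [p.sd_rho_v for p in points],
        }
    )
    frame.to_csv(path, index=False)


def read_phase_observables_csv(path: str | Path) -> list[PhaseObservables]:
    """Read phase observables (T, phase, u, rho[, p, n])."""
    frame = pd.read_csv(path)
    required = {"T", "phase", "u", "rho"}
    if not required.issubset(frame.columns):
        raise ParseError(f"{path}: need columns {sorted(required)}")
    out = []
    for _, row in frame.iterrows():
        out.append(
            PhaseObservables(
                T=float(row["T"]),
                phase=str(row["phase"]),
                u=float(row["u"]),
                rho=float(row["rho"]),
                p=float(row["p"]) if "p" in frame.columns and pd.notna(row.get("p")) else None,
                n_molecules=int(row["n"]) if "n" in frame.columns and pd.notna(row.get("n")) else 1,
            )
        )
    return out


def read_trace(csv_path: str | Path, metadata: dict | str | Path) -> DensityTrace:
    """Read a density trace CSV (time_ns, density_gL) plus sidecar metadata.

    ``metadata`` is a dict or the path of a YAML file with at least ``T``
    and ``pressure`` plus optional ``barostat`` and ``pre_equilibrated``.
    """
    if not isinstance(metadata, dict):
        with open(metadata) as fh:
            metadata = yaml.safe_load(fh)
    frame = pd.read_csv(csv_path)
    if not {"time_ns", "density_gL"}.issubset(frame.columns):
        raise ParseError(f"{csv_path}: need columns time_ns, density_gL")
    return DensityTrace(
        T=float(metadata["T"]),
        pressure_setpoint=float(metadata.get("pressure", 1.0)),
        times=frame["time_ns"].to_numpy(float),
        density=frame["density_gL"].to_numpy(float),
        barostat_label=str(metadata.get("barostat", "synthetic")),
        pre_equilibrated=bool(metadata.get("pre_equilibrated", True)),
    )


def write_trace(trace: DensityTrace, csv_path: str | Path, meta_path: str | Path | None = None) -> None:
    """Write a density trace CSV and (optionally) its YAML sidecar."""
    pd.DataFrame({"time_ns": trace.times, "density_gL": trace.density}).to_csv(
        csv_path, index=False
    )
    if meta_path is not None:
        meta = {
            "T": trace.T,
            "pressure": trace.pressure_setpoint,
            "barostat": trace.barostat_label,
            "pre_equilibrated": trace.pre_equilibrated,
        }
        Path(meta_path).write_text(yaml.safe_dump(meta))


def write_profile_csv(profile, path: str | Path) -> None:
    """Write a density profile as (z, density) CSV."""
    pd.DataFrame({"z": profile.bin_centers, "density": profile.density}).to_csv(
        path, index=False
    )


def _jsonable(value):
    if isinstance(value, np.ndarray):
        return value.tolist()
    if isinstance(value, (np.floating, np.integer)):
        return value.item()
    if isinstance(value, frozenset):
        return sorted(value)
    if dataclasses.is_dataclass(value) and not isinstance(value, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(value).items()}
    if isinstance(value, dict):
        return {k: _jsonable(v) for k, v in value.items()}
    if isinstance(value, (list, tuple)):
        return [_jsonable(v) for v in value]
    if isinstance(value, float) and not np.isfinite(value):
        return None
    return value


def write_report(results, path: str | Path, fmt: str = "json") -> None:
    """Serialize a result (dataclass, dict, or list of either) to JSON/CSV."""
    path = Path(path)
    if fmt == "json":
        path.write_text(json.dumps(_jsonable(results), indent=2) + "\n")
    elif fmt == "csv":
        rows = results if isinstance(results, (list, tuple)) else [results]
        pd.DataFrame([_jsonable(r) for r in rows]).to_csv(path, index=False)
    else:
        raise ValueError(f"unsupported report format {fmt!r}")


def read_report(path: str | Path, cls=None):
    """Read a JSON report back; with ``cls`` a dataclass, reconstruct it."""
    data = json.loads(Path(path).read_text())
    if cls is None:
        return data
    names = {f.name for f in dataclasses.fields(cls)}

    def build(entry):
        kwargs = {k: v for k, v in entry.items() if k in names}
        for f in dataclasses.fields(cls):
            if f.name in kwargs and isinstance(kwargs[f.name], list):
                if f.name == "flags":
                    kwargs[f.name] = frozenset(kwargs[f.name])
                else:
                    kwargs[f.name] = np.asarray(kwargs[f.name])
        return cls(**kwargs)

    if isinstance(data, list):
        return [build(e) for e in data]
    return build(data)
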