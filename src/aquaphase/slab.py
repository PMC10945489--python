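"""Slab-geometry density profiles and tanh interface fitting.

A liquid-vapor coexistence simulation places a liquid slab in an
elongated periodic box (z is the long axis), exposing two planar
interfaces to the surrounding vapor.  The analysis chain is

1. re-center the slab at Lz/2 (the slab may diffuse across the periodic
   boundary, so the center is a *circular* mean along z),
2. histogram the molecule positions into a mass-density profile ρ(z),
3. fit the double hyperbolic-tangent profile

   ρ(z) = ρ_v + (ρ_l − ρ_v)/2 · [tanh((z − z_lo)/w) − tanh((z − z_hi)/w)]

   to read off the coexistence densities ρ_l and ρ_v.

Near the critical temperature the two phases blur together; fits whose
density gap is not resolved against its own standard error are flagged
``indistinct_phases`` rather than trusted silently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import curve_fit

from .constants import A3_TO_L, M_WATER, N_AVOGADRO

__all__ = [
    "Configuration",
    "DensityProfile",
    "InterfaceFit",
    "center_slab",
    "density_profile",
    "fit_interfaces",
    "tanh_profile",
]

#: circular-mean resultant length below which a z-distribution is treated
#: as uniform (no slab to center)
UNIFORM_RESULTANT_THRESHOLD = 0.05


@dataclass(frozen=True)
class Configuration:
    """One frame of molecule reference positions in an orthorhombic box.

    ``positions`` holds the oxygen-site coordinates, shape (N, 3), in Å;
    coordinates are wrapped into [0, L) per axis on construction.
    """

    box: tuple[float, float, float]
    positions: np.ndarray
    mass_per_molecule: float = M_WATER
    temperature_label: float | None = None

    def __post_init__(self) -> None:
        box = np.asarray(self.box, dtype=float)
        if box.shape != (3,) or np.any(box <= 0):
            raise ValueError("box must be three positive edge lengths")
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise ValueError("positions must have shape (N, 3)")
        object.__setattr__(self, "box", tuple(box))
        object.__setattr__(self, "positions", np.mod(pos, box))

    @property
    def n_molecules(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class DensityProfile:
    """Frame-averaged mass density along z, in g/L."""

    bin_centers: np.ndarray
    density: np.ndarray
    n_frames: int
    bin_width: float
    box: tuple[float, float, float]
    n_molecules: int
    mass_per_molecule: float = M_WATER


@dataclass(frozen=True)
class InterfaceFit:
    """Parameters of the double-tanh interface fit.

    ``rho_l``/``rho_v`` in g/L; ``z_lo``/``z_hi`` interface midpoints and
    shared width ``w`` in Å.  ``indistinct_phases`` is set when the fitted
    density gap is below 3x its standard error (near-critical guard);
    ``converged`` is False when the optimizer failed, in which case
    ``message`` carries the diagnostics.
    """

    rho_l: float
    rho_v: float
    z_lo: float
    z_hi: float
    w: float
    rmse: float
    converged: bool = True
    indistinct_phases: bool = False
    message: str = ""
    sd_rho_l: float = math.nan
    sd_rho_v: float = math.nan


def _circular_center(z: np.ndarray, lz: float) -> tuple[float, float]:
    """Periodic mean position along z and the resultant length in [0, 1]."""
    angles = 2.0 * np.pi * z / lz
    vec = np.exp(1j * angles).mean()
    resultant = float(np.abs(vec))
    center = float(np.angle(vec)) / (2.0 * np.pi) * lz
    return center % lz, resultant


def center_slab(config: Configuration) -> Configuration:
    """Translate the slab along z so its periodic mass center sits at Lz/2.

    The center is the circular mean of the z coordinates (map z to an angle
    2πz/Lz, average on the unit circle, map back), which is well defined
    even when the slab straddles the periodic boundary.  If the resultant
    length of the circular mean falls below 0.05 the z-distribution is
    essentially uniform (single phase filling the box); the configuration
    is then returned unchanged.
    """
    if config.n_molecules == 0:
        raise ValueError("cannot center an empty configuration")
    lz = config.box[2]
    center, resultant = _circular_center(config.positions[:, 2], lz)
    if resultant < UNIFORM_RESULTANT_THRESHOLD:
        return config
    shifted = config.positions.copy()
    shifted[:, 2] = np.mod(shifted[:, 2] + (lz / 2.0 - center), lz)
    return replace(config, positions=shifted)


def density_profile(
    configs: list[Configuration] | tuple[Configuration, ...],
    bin_width: float = 0.5,
    center: bool = True,
) -> DensityProfile:
    """Mean mass-density profile ρ(z) over frames, in g/L.

    Each frame is re-centered first (``center=False`` skips that, e.g. for
    already-centered synthetic data).  The bin width is adjusted to the
    nearest divisor of Lz so the bins tile the box exactly; per-bin density
    is ``count · M / (N_A · Lx · Ly · Δz)`` converted from g/Å³ to g/L.
    """
    if not configs:
        raise ValueError("no configurations given")
    box = configs[0].box
    mass = configs[0].mass_per_molecule
    for cfg in configs:
        if not np.allclose(cfg.box, box) or cfg.mass_per_molecule != mass:
            raise ValueError("all configurations must share box and molecule mass")
    lx, ly, lz = box
    n_bins = max(1, round(lz / bin_width))
    width = lz / n_bins
    edges = np.linspace(0.0, lz, n_bins + 1)
    counts = np.zeros(n_bins)
    for cfg in configs:
        frame = center_slab(cfg) if center else cfg
        counts += np.histogram(frame.positions[:, 2], bins=edges)[0]
    counts /= len(configs)
    bin_volume_l = lx * ly * width * A3_TO_L
    density = counts * mass / N_AVOGADRO / bin_volume_l
    centers = 0.5 * (edges[:-1] + edges[1:])
    return DensityProfile(
        bin_centers=centers,
        density=density,
        n_frames=len(configs),
        bin_width=width,
        box=box,
        n_molecules=configs[0].n_molecules,
        mass_per_molecule=mass,
    )


def tanh_profile(
    z: np.ndarray, rho_v: float, rho_l: float, z_lo: float, z_hi: float, w: float
) -> np.ndarray:
    """Double-tanh slab profile with shared interface width."""
    return rho_v + 0.5 * (rho_l - rho_v) * (
        np.tanh((z - z_lo) / w) - np.tanh((z - z_hi) / w)
    )


def fit_interfaces(profile: DensityProfile) -> InterfaceFit:
    """Least-squares fit of the double-tanh profile to a centered slab.

    Shares ρ_l, ρ_v and the width w between the two interfaces.  Returns a
    flagged (never raising) :class:`InterfaceFit`: ``converged=False`` with
    diagnostics on optimizer failure, ``indistinct_phases=True`` when the
    fitted gap ρ_l − ρ_v is smaller than 3x its propagated standard error.
    """
    z = profile.bin_centers
    rho = profile.density
    lz = profile.box[2]
    lo, hi = float(rho.min()), float(rho.max())
    span = hi - lo
    if span <= 0:
        return InterfaceFit(
            rho_l=hi, rho_v=lo, z_lo=lz / 4, z_hi=3 * lz / 4, w=1.0,
            rmse=0.0, converged=True, indistinct_phases=True,
            message="profile is exactly flat",
        )
    # initial interface guesses: outermost crossings of the half height
    above = rho > lo + 0.5 * span
    idx = np.flatnonzero(above)
    z_lo0 = z[idx[0]] if idx.size else lz / 4
    z_hi0 = z[idx[-1]] if idx.size else 3 * lz / 4
    if z_hi0 - z_lo0 < 2 * profile.bin_width:
        z_lo0, z_hi0 = lz / 4, 3 * lz / 4
    p0 = [lo, hi, z_lo0, z_hi0, 2.0]
    bounds = ([0.0, 0.0, 0.0, 0.0, 1e-6], [np.inf, np.inf, lz, lz, lz])
    try:
        popt, pcov = curve_fit(
            tanh_profile, z, rho, p0=p0, bounds=bounds, maxfev=20000
        )
    except (RuntimeError, ValueError) as exc:
        return InterfaceFit(
            rho_l=hi, rho_v=lo, z_lo=z_lo0, z_hi=z_hi0, w=2.0,
            rmse=float(np.sqrt(np.mean((rho - np.mean(rho)) ** 2))),
            converged=False, indistinct_phases=True,
            message=f"tanh fit did not converge: {exc}",
        )
    rho_v, rho_l, z_lo, z_hi, w = popt
    resid = rho - tanh_profile(z, *popt)
    rmse = float(np.sqrt(np.mean(resid**2)))
    sd = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
    gap = rho_l - rho_v
    # var(gap) = var(l) + var(v) - 2 cov(l, v)
    gap_var = pcov[1, 1] + pcov[0, 0] - 2.0 * pcov[0, 1]
    gap_sd = math.sqrt(max(gap_var, 0.0))
    indistinct = bool(gap <= 0 or (gap_sd > 0 and gap < 3.0 * gap_sd))
    return InterfaceFit(
        rho_l=float(rho_l), rho_v=float(rho_v),
        z_lo=float(z_lo), z_hi=float(z_hi), w=float(w),
        rmse=rmse, converged=True, indistinct_phases=indistinct,
        message="density gap below 3 sigma" if indistinct else "",
        sd_rho_l=float(sd[1]), sd_rho_v=float(sd[0]),
    )
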