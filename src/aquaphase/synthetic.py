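"""Synthetic inputs with known ground truth for every analysis stage.

The analyses in this package normally consume molecular-dynamics output
(slab configurations, coexistence tables, NPT density traces).  The
generators here emulate those inputs statistically — no force field, no
dynamics — so the whole pipeline can be exercised and validated against
exact ground truth:

* :func:`gen_slab_frames` draws molecule positions from a double-tanh
  slab density profile (independent samples, no excluded volume), with
  optional per-frame drift to exercise periodic re-centering;
* :func:`gen_coexistence_table` inverts the scaling law and the
  rectilinear diameter to produce coexistence points with multiplicative
  noise;
* :func:`gen_npt_ladder` produces mean-reverting (discrete
  Ornstein-Uhlenbeck) density traces on a heating ladder that collapse
  to vapor after an exponential waiting time above a true T_evap.

Every generator is deterministic under its seed and returns its ground
truth in a sidecar record.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import A3_TO_L, M_WATER, N_AVOGADRO
from .critical import CoexistencePoint
from .npt import DensityTrace, HeatingLadder
from .slab import Configuration, tanh_profile
from .thermo import EvapThermoPoint, PhaseObservables

__all__ = [
    "SlabSpec",
    "SlabTruth",
    "LadderSpec",
    "LadderTruth",
    "gen_slab_frames",
    "gen_coexistence_table",
    "gen_coexistence_blocks",
    "gen_npt_ladder",
    "gen_collapse_trace",
    "gen_density_vs_T",
    "gen_evap_thermo_point",
]

#: below this interface width [Å] the slab profile is sampled as an exact
#: step-function mixture instead of a numeric inverse CDF
_STEP_WIDTH = 1e-3


@dataclass(frozen=True)
class SlabSpec:
    """Specification of a synthetic liquid-vapor slab.

    Geometry mirrors a 20 x 20 x 100 Å coexistence box with ~500
    molecules; ``n_molecules=None`` derives the count from the target
    densities (mass consistency).  ``drift_per_frame`` translates the
    whole slab along z every frame to exercise periodic wrapping.
    """

    rho_l: float = 1000.0
    rho_v: float = 10.0
    z_lo: float = 30.0
    z_hi: float = 70.0
    w: float = 2.0
    box: tuple[float, float, float] = (20.0, 20.0, 100.0)
    n_molecules: int | None = None
    n_frames: int = 200
    drift_per_frame: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.z_lo < self.z_hi < self.box[2]):
            raise ValueError("require 0 < z_lo < z_hi < Lz")
        if self.rho_v < 0 or self.rho_l <= self.rho_v:
            raise ValueError("require rho_l > rho_v >= 0")
        if self.w < 0:
            raise ValueError("w must be non-negative")


@dataclass(frozen=True)
class SlabTruth:
    """Ground truth of a generated slab (effective densities after the
    molecule count is fixed to an integer)."""

    rho_l: float
    rho_v: float
    z_lo: float
    z_hi: float
    w: float
    n_molecules: int


def _slab_shape(z: np.ndarray, spec: SlabSpec) -> np.ndarray:
    if spec.w <= _STEP_WIDTH:
        inside = (z >= spec.z_lo) & (z <= spec.z_hi)
        return np.where(inside, spec.rho_l, spec.rho_v)
    return tanh_profile(z, spec.rho_v, spec.rho_l, spec.z_lo, spec.z_hi, spec.w)


def _expected_count(spec: SlabSpec) -> float:
    """Expected molecule count implied by the target density profile."""
    lx, ly, lz = spec.box
    z = np.linspace(0.0, lz, 20001)
    integral = np.trapezoid(_slab_shape(z, spec), z)  # g/L * Å
    return lx * ly * integral * A3_TO_L * N_AVOGADRO / M_WATER


def gen_slab_frames(spec: SlabSpec) -> tuple[list[Configuration], SlabTruth]:
    """Draw slab configurations from the double-tanh density profile.

    Molecule z-coordinates are iid inverse-CDF samples from the profile
    (step-function mixture in the w -> 0 limit); x, y are uniform.  The
    whole slab is translated by the cumulative drift each frame and
    wrapped.  The sidecar truth carries the *effective* densities after
    rounding the molecule count to an integer; a requested count that is
    off the implied mass by more than 10% is an infeasible spec.
    """
    n_exp = _expected_count(spec)
    n = round(n_exp) if spec.n_molecules is None else spec.n_molecules
    if n <= 0:
        raise ValueError("spec implies no molecules")
    scale = n / n_exp
    if abs(scale - 1.0) > 0.10:
        raise ValueError(
            f"infeasible spec: target profile mass implies {n_exp:.1f} molecules "
            f"but {n} were requested (off by {abs(scale - 1) * 100:.0f}%)"
        )
    truth = SlabTruth(
        rho_l=spec.rho_l * scale, rho_v=spec.rho_v * scale,
        z_lo=spec.z_lo, z_hi=spec.z_hi, w=spec.w, n_molecules=n,
    )
    lx, ly, lz = spec.box
    rng = np.random.default_rng(spec.seed)
    frames = []
    if spec.w <= _STEP_WIDTH:
        slab_len = spec.z_hi - spec.z_lo
        mass_slab = (spec.rho_l - spec.rho_v) * slab_len
        p_slab = mass_slab / (mass_slab + spec.rho_v * lz)

        def draw_z(u: np.ndarray, rng: np.random.Generator) -> np.ndarray:
            in_slab = rng.random(u.size) < p_slab
            z = np.where(in_slab, spec.z_lo + u * slab_len, u * lz)
            return z
    else:
        grid = np.linspace(0.0, lz, 8001)
        pdf = _slab_shape(grid, spec)
        cdf = np.concatenate([[0.0], np.cumsum((pdf[1:] + pdf[:-1]) / 2 * np.diff(grid))])
        cdf /= cdf[-1]

        def draw_z(u: np.ndarray, rng: np.random.Generator) -> np.ndarray:
            return np.interp(u, cdf, grid)

    for k in range(spec.n_frames):
        u = rng.random(n)
        z = draw_z(u, rng)
        z = np.mod(z + k * spec.drift_per_frame, lz)
        xy = rng.random((n, 2)) * np.array([lx, ly])
        positions = np.column_stack([xy, z])
        frames.append(Configuration(box=spec.box, positions=positions))
    return frames, truth


def gen_coexistence_table(
    T: np.ndarray,
    T_C: float = 640.0,
    rho_C: float = 300.0,
    A: float = 750.0,
    B: float = 0.85,
    beta: float = 0.326,
    noise_frac: float = 0.0,
    seed: int = 0,
) -> list[CoexistencePoint]:
    """Coexistence points from the closed-form inversion of the two laws.

    ρ_l/ρ_v are the diameter ± half the scaling-law gap, each multiplied
    by (1 + ε) with ε ~ Normal(0, noise_frac).  All temperatures must lie
    strictly below T_C.
    """
    T = np.asarray(T, dtype=float)
    if np.any(T >= T_C):
        raise ValueError("all temperatures must be strictly below T_C")
    tau = 1.0 - T / T_C
    diameter = rho_C + B * (T_C - T)
    gap = A * tau**beta
    rho_l = diameter + gap / 2
    rho_v = diameter - gap / 2
    if np.any(rho_v < 0):
        raise ValueError("parameters produce negative vapor densities")
    rng = np.random.default_rng(seed)
    if noise_frac:
        rho_l = rho_l * (1.0 + noise_frac * rng.standard_normal(T.size))
        rho_v = rho_v * (1.0 + noise_frac * rng.standard_normal(T.size))
    return [
        CoexistencePoint(T=float(t), rho_l=float(max(l, v)), rho_v=float(max(min(l, v), 0.0)))
        for t, l, v in zip(T, rho_l, rho_v)
    ]


def gen_coexistence_blocks(
    T: np.ndarray,
    n_blocks: int = 4,
    seed: int = 0,
    **kwargs,
) -> list[list[CoexistencePoint]]:
    """Independent noisy coexistence tables on one grid, one per block."""
    seeds = np.random.SeedSequence(seed).spawn(n_blocks)
    return [
        gen_coexistence_table(T, seed=int(s.generate_state(1)[0] % 2**31), **kwargs)
        for s in seeds
    ]


def _rho_eq_linear(T: np.ndarray | float, rho_ref: float, T_ref: float, slope: float):
    return rho_ref - slope * (np.asarray(T, dtype=float) - T_ref)


@dataclass(frozen=True)
class LadderSpec:
    """Specification of a synthetic NPT heating ladder.

    Densities fluctuate around a linearly declining equilibrium
    ``rho_eq(T) = rho_ref − slope (T − T_ref)`` as a discrete
    Ornstein-Uhlenbeck process (relaxation ``ou_tau`` ns, stationary sd
    ``ou_sigma`` g/L).  Steps above ``T_evap_true`` collapse to
    ``rho_vapor`` after an exponential waiting time of mean
    ``mean_wait`` ns, over ``collapse_duration`` ns.
    """

    T_start: float = 580.0
    T_end: float = 620.0
    dT: float = 1.0
    tau_per_step: float = 5.0
    dt: float = 0.01
    rho_ref: float = 1000.0
    T_ref: float = 300.0
    slope: float = 0.8
    ou_tau: float = 0.1
    ou_sigma: float = 15.0
    T_evap_true: float = 600.0
    mean_wait: float = 1.0
    rho_vapor: float = 5.0
    collapse_duration: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.T_end <= self.T_start or self.dT <= 0:
            raise ValueError("need T_end > T_start and dT > 0")
        if not self.T_start <= self.T_evap_true <= self.T_end:
            raise ValueError("T_evap_true must lie inside the ladder grid")
        if self.mean_wait <= 0 or self.tau_per_step <= 0 or self.dt <= 0:
            raise ValueError("waiting time and durations must be positive")

    @property
    def temperatures(self) -> np.ndarray:
        n = int(math.floor((self.T_end - self.T_start) / self.dT + 1e-9)) + 1
        return self.T_start + self.dT * np.arange(n)

    def rho_eq(self, T: np.ndarray | float):
        """Equilibrium liquid density at temperature T [g/L]."""
        return _rho_eq_linear(T, self.rho_ref, self.T_ref, self.slope)


@dataclass(frozen=True)
class LadderTruth:
    """Ground truth of a generated heating ladder."""

    T_evap_true: float
    rho_ref_by_T: dict = field(repr=False, default=None)


def gen_npt_ladder(spec: LadderSpec) -> tuple[HeatingLadder, LadderTruth]:
    """Heating ladder of OU density traces with collapse above T_evap_true."""
    rng = np.random.default_rng(spec.seed)
    n_samples = max(2, int(round(spec.tau_per_step / spec.dt)))
    times = spec.dt * (1 + np.arange(n_samples))
    a = math.exp(-spec.dt / spec.ou_tau)
    kick = spec.ou_sigma * math.sqrt(1.0 - a * a)
    steps = []
    for T in spec.temperatures:
        mu = float(spec.rho_eq(T))
        noise = rng.standard_normal(n_samples)
        rho = np.empty(n_samples)
        x = mu + spec.ou_sigma * noise[0]
        for i in range(n_samples):
            rho[i] = x
            x = mu + a * (x - mu) + kick * noise[i]
        if spec.ou_sigma == 0:
            rho[:] = mu
        if T > spec.T_evap_true:
            wait = rng.exponential(spec.mean_wait)
            if wait < times[-1]:
                ramp = (times - wait) / spec.collapse_duration
                ramp = np.clip(ramp, 0.0, 1.0)
                rho = rho * (1.0 - ramp) + spec.rho_vapor * ramp
        rho = np.clip(rho, 0.1, None)
        steps.append(
            DensityTrace(
                T=float(T), pressure_setpoint=1.0, times=times, density=rho,
                barostat_label="synthetic", pre_equilibrated=True,
            )
        )
    ladder = HeatingLadder(steps=tuple(steps), dT=spec.dT, tau_per_step=spec.tau_per_step)
    truth = LadderTruth(
        T_evap_true=spec.T_evap_true,
        rho_ref_by_T={float(T): float(spec.rho_eq(T)) for T in spec.temperatures},
    )
    return ladder, truth


def gen_collapse_trace(
    T: float = 610.0,
    rho_liquid: float = 700.0,
    rho_vapor: float = 5.0,
    onset_time: float = 2.0,
    collapse_duration: float = 0.2,
    total_time: float = 5.0,
    dt: float = 0.01,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> DensityTrace:
    """Single trace that collapses from liquid to vapor at a known time."""
    rng = np.random.default_rng(seed)
    times = dt * (1 + np.arange(int(round(total_time / dt))))
    ramp = np.clip((times - onset_time) / collapse_duration, 0.0, 1.0)
    rho = rho_liquid * (1.0 - ramp) + rho_vapor * ramp
    if noise_sd:
        rho = rho + noise_sd * rng.standard_normal(times.size)
    return DensityTrace(
        T=T, pressure_setpoint=1.0, times=times,
        density=np.clip(rho, 0.1, None), barostat_label="synthetic",
    )


def gen_density_vs_T(
    T: np.ndarray,
    T_MD: float = 277.0,
    rho_MD: float = 1000.0,
    curvature: float = 0.007,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Parabolic ρ(T) samples around a known density maximum.

    Returns ``(T, rho, sd)`` with sd set to the noise level (or 1 g/L for
    noiseless data, so weighted fits stay defined).
    """
    T = np.asarray(T, dtype=float)
    rng = np.random.default_rng(seed)
    rho = rho_MD - curvature * (T - T_MD) ** 2
    if noise_sd:
        rho = rho + noise_sd * rng.standard_normal(T.size)
    sd = np.full(T.size, noise_sd if noise_sd else 1.0)
    return T, rho, sd


def gen_evap_thermo_point(
    T: float = 450.0,
    dU: float = 35.0,
    p_sat: float = 10.0,
    rho_l: float = 900.0,
    rho_v: float = 5.0,
    u_liquid: float = -40.0,
) -> tuple[PhaseObservables, PhaseObservables, EvapThermoPoint]:
    """Pure-phase observable pair with the closed-form ΔH it must yield.

    The expected point is assembled here from the defining arithmetic
    (ΔH = ΔU + p·(M/ρ_v − M/ρ_l)·0.1), independent of the thermo module.
    """
    liquid = PhaseObservables(T=T, phase="liquid", u=u_liquid, rho=rho_l, n_molecules=512)
    vapor = PhaseObservables(T=T, phase="vapor", u=u_liquid + dU, rho=rho_v, p=p_sat, n_molecules=128)
    pdv = p_sat * (M_WATER / rho_v - M_WATER / rho_l) * 0.1
    expected = EvapThermoPoint(T=T, dH=dU + pdv, dU=dU, pdV=pdv, p_sat=p_sat)
    return liquid, vapor, expected
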