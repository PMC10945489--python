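"""Isobaric-isothermal (NPT) density analysis.

Two phenomena are extracted from NPT density time series at 1 bar:

* **Spontaneous evaporation.**  A superheated liquid held above a
  model-dependent temperature T_evap collapses to vapor — the box
  expands explosively and the density drops by orders of magnitude.
  ``detect_evaporation`` applies a hysteresis rule (fall below half the
  liquid reference density and never recover above 80% of it) to a
  single trace; ``estimate_T_evap`` scans a heating ladder of such
  traces and reports the lowest evaporating temperature.

* **Maximum density.**  Liquid water's isobaric density peaks at T_MD
  (experimentally near 277 K).  ``fit_density_maximum`` interpolates
  mean densities over temperature with a quartic polynomial and locates
  the stationary point analytically.

Statistical errors use trajectory splitting: a long trace is cut into
equal blocks (by default six, the first discarded as residual
equilibration) and the spread of block means is reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DensityTrace",
    "HeatingLadder",
    "MaxDensityFit",
    "BlockStats",
    "TevapResult",
    "detect_evaporation",
    "estimate_T_evap",
    "heating_schedule",
    "fit_density_maximum",
    "split_trace",
    "split_uncertainty",
    "NoMaximumError",
]

#: density must fall below this fraction of the liquid reference to count
#: as evaporated
COLLAPSE_FRACTION = 0.5
#: ... and never afterwards recover above this fraction (hysteresis)
RECOVERY_FRACTION = 0.8
#: fraction of the trace tail used for the evaporated/liquid verdict
TAIL_FRACTION = 0.2


class NoMaximumError(RuntimeError):
    """The fitted density curve has no interior maximum."""


@dataclass(frozen=True)
class DensityTrace:
    """Density time series at fixed temperature and pressure setpoint."""

    T: float
    pressure_setpoint: float
    times: np.ndarray
    density: np.ndarray
    barostat_label: str = "synthetic"
    pre_equilibrated: bool = True

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        rho = np.asarray(self.density, dtype=float)
        if t.shape != rho.shape or t.ndim != 1:
            raise ValueError("times and density must be matching 1-D arrays")
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(rho <= 0):
            raise ValueError("density must be positive")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "density", rho)

    @property
    def n_samples(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class HeatingLadder:
    """Sequence of NPT traces at equally spaced, increasing temperatures."""

    steps: tuple[DensityTrace, ...]
    dT: float
    tau_per_step: float

    def __post_init__(self) -> None:
        if self.dT <= 0 or self.tau_per_step <= 0:
            raise ValueError("dT and tau_per_step must be positive")
        temps = np.array([s.T for s in self.steps])
        if temps.size >= 2:
            spacing = np.diff(temps)
            if np.any(spacing <= 0) or not np.allclose(spacing, self.dT, rtol=1e-9, atol=1e-9):
                raise ValueError("step temperatures must increase with constant spacing dT")
        object.__setattr__(self, "steps", tuple(self.steps))

    @property
    def temperatures(self) -> np.ndarray:
        return np.array([s.T for s in self.steps])

    @property
    def heating_rate(self) -> float:
        """Average heating rate dT/τ [K/ns]."""
        return self.dT / self.tau_per_step


@dataclass(frozen=True)
class MaxDensityFit:
    """Quartic-fit location of the density maximum."""

    T_MD: float
    rho_MD: float
    poly_coeffs: np.ndarray
    sd_T_MD: float | None = None
    sd_rho_MD: float | None = None


@dataclass(frozen=True)
class BlockStats:
    """Per-block means and their spread from trajectory splitting."""

    block_means: np.ndarray
    mean: float
    sd: float
    n_blocks_retained: int


@dataclass(frozen=True)
class TevapResult:
    """Outcome of the heating-ladder scan for spontaneous evaporation."""

    T_evap: float | None
    reached: bool
    consistent: bool
    evaporated_mask: np.ndarray = field(repr=False, default=None)


def detect_evaporation(
    trace: DensityTrace,
    rho_liquid_ref: float,
    collapse_fraction: float = COLLAPSE_FRACTION,
    recovery_fraction: float = RECOVERY_FRACTION,
) -> tuple[bool, float | None]:
    """Decide whether a trace has evaporated and locate the onset.

    The verdict is based on the tail: evaporated iff the mean density over
    the final 20% of samples lies below ``collapse_fraction`` times the
    liquid reference.  The onset is the first time the density falls below
    the collapse threshold *and never again recovers* above
    ``recovery_fraction`` times the reference, so a transient dip does not
    count.  Returns ``(evaporated, onset_time_or_None)``.
    """
    if rho_liquid_ref <= 0:
        raise ValueError("rho_liquid_ref must be positive")
    if trace.n_samples < 50:
        raise ValueError("trace too short: need at least 50 samples")
    rho = trace.density
    n_tail = max(1, int(np.ceil(TAIL_FRACTION * rho.size)))
    evaporated = bool(np.mean(rho[-n_tail:]) < collapse_fraction * rho_liquid_ref)
    if not evaporated:
        return False, None
    above_recovery = np.flatnonzero(rho > recovery_fraction * rho_liquid_ref)
    start = int(above_recovery[-1]) + 1 if above_recovery.size else 0
    below = np.flatnonzero(rho[start:] < collapse_fraction * rho_liquid_ref)
    if below.size == 0:  # tail mean below threshold but no single sample is
        return True, None
    return True, float(trace.times[start + below[0]])


def estimate_T_evap(
    ladder: HeatingLadder,
    rho_ref_by_T,
    collapse_fraction: float = COLLAPSE_FRACTION,
    recovery_fraction: float = RECOVERY_FRACTION,
) -> TevapResult:
    """Lowest ladder temperature at which the liquid spontaneously evaporates.

    ``rho_ref_by_T`` maps a step temperature to its liquid reference
    density: a scalar, a mapping, or a callable.  The result is flagged
    ``consistent=False`` (with a warning) when some step above the
    detected T_evap stayed liquid — physically the transition should be
    monotone in temperature.  When no step evaporates, ``reached`` is
    False and ``T_evap`` is None (not an exception: a ladder may simply
    end below the transition).
    """
    if callable(rho_ref_by_T):
        ref = rho_ref_by_T
    elif isinstance(rho_ref_by_T, dict):
        ref = rho_ref_by_T.__getitem__
    else:
        ref = lambda _t: float(rho_ref_by_T)  # noqa: E731
    mask = np.array(
        [
            detect_evaporation(s, ref(s.T), collapse_fraction, recovery_fraction)[0]
            for s in ladder.steps
        ]
    )
    if not mask.any():
        return TevapResult(T_evap=None, reached=False, consistent=True, evaporated_mask=mask)
    first = int(np.argmax(mask))
    consistent = bool(mask[first:].all())
    if not consistent:
        warnings.warn(
            "non-monotone evaporation along the ladder: some step above the "
            "detected T_evap stayed liquid",
            stacklevel=2,
        )
    return TevapResult(
        T_evap=float(ladder.steps[first].T),
        reached=True,
        consistent=consistent,
        evaporated_mask=mask,
    )


def heating_schedule(
    T_start: float, T_end: float, dT: float, tau_per_step: float
) -> HeatingLadder:
    """Skeleton heating ladder: empty traces on the requested grid.

    Useful to lay out a simulation campaign; the reported heating rate is
    dT/τ (e.g. 1 K per 5 ns step -> 0.2 K/ns).
    """
    if dT <= 0 or tau_per_step <= 0:
        raise ValueError("dT and tau_per_step must be positive")
    if T_end <= T_start:
        raise ValueError("T_end must exceed T_start")
    n_steps = int(np.floor((T_end - T_start) / dT + 1e-9)) + 1
    steps = tuple(
        DensityTrace(
            T=T_start + i * dT,
            pressure_setpoint=1.0,
            times=np.empty(0),
            density=np.empty(0),
        )
        for i in range(n_steps)
    )
    return HeatingLadder(steps=steps, dT=dT, tau_per_step=tau_per_step)


def fit_density_maximum(
    T: np.ndarray, rho: np.ndarray, sd: np.ndarray | None = None
) -> MaxDensityFit:
    """Locate the temperature of maximum density by a weighted quartic fit.

    ρ(T) is fitted with a degree-4 polynomial (weights 1/sd when given);
    T_MD is the real stationary point inside the sampled range with
    negative curvature, ρ_MD the fitted density there.  Raises
    :class:`NoMaximumError` when no interior maximum exists (e.g. strictly
    monotonic data).
    """
    T = np.asarray(T, dtype=float)
    rho = np.asarray(rho, dtype=float)
    if T.size < 5:
        raise ValueError("need at least 5 temperatures to fit a quartic")
    w = None if sd is None else 1.0 / np.asarray(sd, dtype=float)
    # center T for conditioning
    t0 = T.mean()
    coeffs = np.polyfit(T - t0, rho, deg=4, w=w)
    poly = np.poly1d(coeffs)
    crit = poly.deriv().roots
    crit = crit[np.isreal(crit)].real + t0
    curv = poly.deriv(2)
    maxima = [
        t for t in crit
        if T.min() < t < T.max() and curv(t - t0) < 0
    ]
    if not maxima:
        raise NoMaximumError("no maximum in range: fitted curve has no interior peak")
    t_md = max(maxima, key=lambda t: poly(t - t0))
    return MaxDensityFit(T_MD=float(t_md), rho_MD=float(poly(t_md - t0)), poly_coeffs=coeffs)


def split_trace(trace: DensityTrace, n_blocks: int = 6) -> list[DensityTrace]:
    """Cut a trace into ``n_blocks`` consecutive equal-length blocks."""
    if n_blocks < 2:
        raise ValueError("need at least 2 blocks")
    idx = np.array_split(np.arange(trace.n_samples), n_blocks)
    return [
        DensityTrace(
            T=trace.T,
            pressure_setpoint=trace.pressure_setpoint,
            times=trace.times[i],
            density=trace.density[i],
            barostat_label=trace.barostat_label,
            pre_equilibrated=trace.pre_equilibrated,
        )
        for i in idx
    ]


def split_uncertainty(
    blocks: list[DensityTrace], discard_first: bool = True
) -> BlockStats:
    """Mean density and its block-splitting uncertainty.

    Default convention: six 5-ns blocks from a 30-ns trace, first block
    discarded as residual equilibration; the quoted sd is the standard
    deviation of the retained block means.
    """
    retained = blocks[1:] if discard_first else list(blocks)
    if len(retained) < 2:
        raise ValueError("need at least 2 retained blocks")
    means = np.array([float(np.mean(b.density)) for b in retained])
    return BlockStats(
        block_means=means,
        mean=float(means.mean()),
        sd=float(means.std(ddof=1)),
        n_blocks_retained=len(retained),
    )
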