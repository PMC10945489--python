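"""Critical-point estimation from liquid-vapor coexistence densities.

Close to (but below) the critical temperature the coexistence densities
obey two empirical laws with the 3D-Ising critical exponent β = 0.326:

* universal scaling law of the density gap
      ρ_l − ρ_v = A (1 − T/T_C)^β
* law of rectilinear diameters
      (ρ_l + ρ_v)/2 = ρ_C + B (T_C − T)

Both are fitted *jointly* with a shared T_C (weighted least squares when
per-point uncertainties are available), which makes the intersection of
the two fitted branches at (T_C, ρ_C) exact by construction.  Statistical
uncertainties come from refitting trajectory blocks ("splits") and taking
the spread of the block estimates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "CoexistencePoint",
    "CriticalPointFit",
    "fit_critical_point",
    "block_estimates",
    "coexistence_curves",
    "CriticalFitError",
    "DomainError",
]

#: default critical exponent of the universal scaling law (3D Ising)
BETA_ISING = 0.326


class CriticalFitError(RuntimeError):
    """The critical-point fit could not be carried out."""


class DomainError(CriticalFitError):
    """Input temperatures incompatible with the fitted (or assumed) T_C."""


@dataclass(frozen=True)
class CoexistencePoint:
    """Coexistence densities (ρ_l, ρ_v) at one temperature, in g/L and K."""

    T: float
    rho_l: float
    rho_v: float
    sd_rho_l: float | None = None
    sd_rho_v: float | None = None
    flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.T > 0:
            raise ValueError("T must be positive")
        if not self.rho_l >= self.rho_v >= 0:
            raise ValueError("require rho_l >= rho_v >= 0")


@dataclass(frozen=True)
class CriticalPointFit:
    """Joint fit of the scaling law and the rectilinear diameter."""

    T_C: float
    rho_C: float
    amplitude_A: float
    amplitude_B: float
    beta: float
    n_points_used: int
    sd_T_C: float | None = None
    sd_rho_C: float | None = None
    n_blocks: int | None = None
    residual_rms: float = math.nan

    def rho_liquid(self, T: np.ndarray | float) -> np.ndarray | float:
        """Fitted liquid branch ρ_l(T) for T <= T_C."""
        t = 1.0 - np.asarray(T) / self.T_C
        return self.rho_C + self.amplitude_B * (self.T_C - np.asarray(T)) + 0.5 * self.amplitude_A * t**self.beta

    def rho_vapor(self, T: np.ndarray | float) -> np.ndarray | float:
        """Fitted vapor branch ρ_v(T) for T <= T_C."""
        t = 1.0 - np.asarray(T) / self.T_C
        return self.rho_C + self.amplitude_B * (self.T_C - np.asarray(T)) - 0.5 * self.amplitude_A * t**self.beta


def _usable(points: list[CoexistencePoint], include_flagged: bool) -> list[CoexistencePoint]:
    if include_flagged:
        return list(points)
    return [p for p in points if not p.flags]


def fit_critical_point(
    points: list[CoexistencePoint] | tuple[CoexistencePoint, ...],
    beta: float = BETA_ISING,
    include_flagged: bool = False,
    fit_beta: bool = False,
) -> CriticalPointFit:
    """Estimate (T_C, ρ_C) from coexistence points by the joint fit.

    Points carrying flags (e.g. the near-critical ``indistinct_phases``
    guard) are excluded unless ``include_flagged`` is set.  Requires at
    least 4 usable points spanning at least 50 K.  Weights are 1/sd per
    residual when per-point uncertainties are present on every point,
    otherwise the fit is unweighted.  β is fixed by default; ``fit_beta``
    releases it as a fifth parameter.

    Raises :class:`DomainError` when the fitted T_C does not exceed every
    input temperature, and :class:`CriticalFitError` on non-convergence
    (the message carries the initial guesses for diagnosis).
    """
    pts = _usable(list(points), include_flagged)
    n_params = 5 if fit_beta else 4
    if len(pts) < max(4, n_params):
        raise CriticalFitError(
            f"need at least {max(4, n_params)} unflagged points, got {len(pts)}"
        )
    T = np.array([p.T for p in pts])
    if T.max() - T.min() < 50.0:
        raise CriticalFitError(
            f"temperature span {T.max() - T.min():.1f} K < 50 K; fit ill-conditioned"
        )
    rho_l = np.array([p.rho_l for p in pts])
    rho_v = np.array([p.rho_v for p in pts])
    have_sd = all(p.sd_rho_l is not None and p.sd_rho_v is not None for p in pts)
    if have_sd:
        sd_l = np.array([p.sd_rho_l for p in pts])
        sd_v = np.array([p.sd_rho_v for p in pts])
        # residuals below are on the gap and the diameter; propagate
        w_gap = 1.0 / np.sqrt(sd_l**2 + sd_v**2)
        w_dia = 2.0 / np.sqrt(sd_l**2 + sd_v**2)
    else:
        w_gap = w_dia = np.ones_like(T)

    gap = rho_l - rho_v
    diameter = 0.5 * (rho_l + rho_v)

    # deterministic initial guesses
    t_c0 = 1.05 * T.max()
    b0, rho_at_tc0 = np.polyfit(t_c0 - T, diameter, 1)
    i_min = int(np.argmin(T))
    a0 = gap[i_min] / (1.0 - T[i_min] / t_c0) ** beta
    p0 = [t_c0, rho_at_tc0, a0, b0] + ([beta] if fit_beta else [])

    def residuals(params: np.ndarray) -> np.ndarray:
        t_c, rho_c, a, b = params[:4]
        b_exp = params[4] if fit_beta else beta
        tau = 1.0 - T / t_c
        tau = np.clip(tau, 1e-12, None)  # keep the power real while iterating
        r1 = w_gap * (gap - a * tau**b_exp)
        r2 = w_dia * (diameter - (rho_c + b * (t_c - T)))
        return np.concatenate([r1, r2])

    lower = [T.max() * (1 + 1e-9), 0.0, 0.0, -np.inf] + ([0.05] if fit_beta else [])
    upper = [np.inf] * 4 + ([1.0] if fit_beta else [])
    result = least_squares(residuals, p0, bounds=(lower, upper), xtol=1e-14, ftol=1e-14, gtol=1e-14)
    if not result.success:
        raise CriticalFitError(
            f"critical-point fit did not converge (status {result.status}); "
            f"initial guesses T_C={t_c0:.2f}, rho_C={rho_at_tc0:.2f}, A={a0:.2f}, B={b0:.4f}"
        )
    t_c, rho_c, a, b = result.x[:4]
    beta_out = float(result.x[4]) if fit_beta else beta
    # a fit pinned against the T_C > max(T) bound means some input sits at
    # or above the critical temperature the data imply; at tau = 1e-3 the
    # scaling-law gap is still ~10% of A, so no credible fit lands there
    if t_c <= T.max() * (1.0 + 1e-3):
        raise DomainError(
            f"fitted T_C={t_c:.2f} K does not exceed the highest input temperature "
            f"{T.max():.2f} K; points at or above T_C are outside the scaling-law domain"
        )
    rms = float(np.sqrt(np.mean(residuals(result.x) ** 2)))
    return CriticalPointFit(
        T_C=float(t_c), rho_C=float(rho_c), amplitude_A=float(a),
        amplitude_B=float(b), beta=beta_out, n_points_used=len(pts),
        residual_rms=rms,
    )


def block_estimates(
    blocks: list[list[CoexistencePoint]],
    beta: float = BETA_ISING,
    include_flagged: bool = False,
) -> CriticalPointFit:
    """Critical-point fit with block-splitting ("trajectory split") errors.

    Each block is one independently analyzed stretch of trajectory,
    yielding a coexistence table on the *same* temperature grid.  The
    central value is the fit on the pooled points; the quoted standard
    deviations are the spread of the per-block fits.
    """
    if len(blocks) < 2:
        raise CriticalFitError("need at least 2 blocks for a split uncertainty")
    grids = [tuple(sorted(p.T for p in blk)) for blk in blocks]
    if len(set(grids)) != 1:
        raise CriticalFitError("all blocks must share the same temperature grid")
    pooled = [p for blk in blocks for p in blk]
    central = fit_critical_point(pooled, beta=beta, include_flagged=include_flagged)
    fits = [fit_critical_point(blk, beta=beta, include_flagged=include_flagged) for blk in blocks]
    sd_t = float(np.std([f.T_C for f in fits], ddof=1))
    sd_r = float(np.std([f.rho_C for f in fits], ddof=1))
    return CriticalPointFit(
        T_C=central.T_C, rho_C=central.rho_C,
        amplitude_A=central.amplitude_A, amplitude_B=central.amplitude_B,
        beta=central.beta, n_points_used=central.n_points_used,
        sd_T_C=sd_t, sd_rho_C=sd_r, n_blocks=len(blocks),
        residual_rms=central.residual_rms,
    )


def coexistence_curves(fit: CriticalPointFit, T: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate the fitted liquid and vapor branches on a temperature grid."""
    T = np.asarray(T, dtype=float)
    if np.any(T > fit.T_C):
        raise DomainError("curves are defined only for T <= T_C")
    return np.asarray(fit.rho_liquid(T)), np.asarray(fit.rho_vapor(T))
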