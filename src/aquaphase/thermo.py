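"""Evaporation thermodynamics from pure-phase canonical observables.

The enthalpy of evaporation at temperature T is assembled from two
constant-volume (NVT) simulations, one of pure liquid and one of pure
vapor, held at the coexistence densities:

    ΔU  = U_v − U_l                      (per molecule, kJ/mol)
    pΔV = p_sat (v_v − v_l)              (molar volumes v = M/ρ)
    ΔH  = ΔU + pΔV

The saturation pressure p_sat is the mean pressure reported by the vapor
simulation when available; otherwise the vapor is treated as an ideal
gas, p = (ρ_v/M) R T.  Volume work is converted with 1 L·bar = 0.1 kJ,
so the identity ΔH = ΔU + pΔV holds to machine precision by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass

from .constants import KCAL_TO_KJ, LBAR_TO_KJ, M_WATER, R_LBAR

__all__ = [
    "PhaseObservables",
    "EvapThermoPoint",
    "saturation_pressure",
    "enthalpy_of_evaporation",
    "kcal_to_kj",
]

#: matching tolerance for the liquid/vapor temperatures [K]
_T_MATCH_TOL = 1e-6


@dataclass(frozen=True)
class PhaseObservables:
    """Mean canonical observables of one pure phase at temperature T.

    ``u`` is the mean internal energy per molecule [kJ/mol], ``rho`` the
    mean density [g/L], ``p`` the mean pressure [bar] if the simulation
    reported one.
    """

    T: float
    phase: str
    u: float
    rho: float
    p: float | None = None
    n_molecules: int = 1

    def __post_init__(self) -> None:
        if self.phase not in ("liquid", "vapor"):
            raise ValueError(f"phase must be 'liquid' or 'vapor', got {self.phase!r}")
        if not self.rho > 0:
            raise ValueError("rho must be positive")
        if not self.n_molecules > 0:
            raise ValueError("n_molecules must be positive")


@dataclass(frozen=True)
class EvapThermoPoint:
    """Evaporation thermodynamics at one temperature, all in kJ/mol and bar."""

    T: float
    dH: float
    dU: float
    pdV: float
    p_sat: float


def saturation_pressure(vapor: PhaseObservables, molar_mass: float = M_WATER) -> float:
    """Saturation vapor pressure [bar] for a pure-vapor observation.

    Returns the simulation-reported mean pressure verbatim when present;
    otherwise falls back to the ideal-gas estimate p = (ρ/M) R T.
    """
    if vapor.phase != "vapor":
        raise ValueError("saturation pressure requires a vapor-phase observation")
    if vapor.p is not None:
        return vapor.p
    return vapor.rho / molar_mass * R_LBAR * vapor.T


def enthalpy_of_evaporation(
    liquid: PhaseObservables,
    vapor: PhaseObservables,
    molar_mass: float = M_WATER,
) -> EvapThermoPoint:
    """ΔH of evaporation and its ΔU / pΔV decomposition at one temperature.

    The liquid molar volume enters pΔV exactly (it is small against the
    vapor's but not neglected), so ΔH = ΔU + pΔV is an identity of the
    returned fields.
    """
    if liquid.phase != "liquid" or vapor.phase != "vapor":
        raise ValueError("need one liquid-phase and one vapor-phase observation")
    if abs(liquid.T - vapor.T) > _T_MATCH_TOL:
        raise ValueError(
            f"temperature mismatch: liquid at {liquid.T} K, vapor at {vapor.T} K"
        )
    du = vapor.u - liquid.u
    p_sat = saturation_pressure(vapor, molar_mass)
    v_vap = molar_mass / vapor.rho  # L/mol
    v_liq = molar_mass / liquid.rho
    pdv = p_sat * (v_vap - v_liq) * LBAR_TO_KJ
    return EvapThermoPoint(T=liquid.T, dH=du + pdv, dU=du, pdV=pdv, p_sat=p_sat)


def kcal_to_kj(u_kcal: float) -> float:
    """Convert an energy from kcal/mol to the internal kJ/mol convention."""
    return u_kcal * KCAL_TO_KJ
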