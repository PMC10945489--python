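"""Registry of rigid three-point water models and their electrostatic moments.

A rigid three-point water model is fully specified by its geometry
(O-H bond length ``d_OH``, H-O-H angle ``phi_HOH``), one Lennard-Jones
site on the oxygen (``sigma_O``, ``epsilon_O``) and the hydrogen partial
charge ``q_H`` (the oxygen carries ``-2 q_H`` so the molecule is neutral).

From the charge arrangement two scalar electrostatic moments follow in
closed form, with θ = ϕ_HOH / 2:

* dipole moment        μ   = 2 q_H d_OH cos θ
* tetrahedral
  quadrupole moment    Q_T = (3/2) q_H d_OH² sin² θ

both converted from e·Å (resp. e·Å²) to Debye (resp. D·Å) with
1 e·Å = 4.80320 D.  ``point_charge_moments`` provides the brute-force
point-charge evaluation of the same quantities, used as an independent
cross-check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .constants import EA_TO_DEBYE

__all__ = [
    "WaterModel",
    "DerivedMoments",
    "load_registry",
    "get_model",
    "dipole_moment",
    "quadrupole_moment",
    "derived_moments",
    "charge_sites",
    "point_charge_moments",
    "moments_table",
    "RegistryError",
]


class RegistryError(RuntimeError):
    """Bundled registry resource missing or corrupted."""


@dataclass(frozen=True)
class WaterModel:
    """Parameters of one rigid three-point water model.

    Units: ``d_OH`` and ``sigma_O`` in Å, ``phi_HOH`` in degrees,
    ``epsilon_O`` in kcal/mol, ``q_H`` in elementary charges.
    ``extra_h_site`` flags an additional weak repulsive site on the
    hydrogens (sTIP3P); it does not enter the moment formulas.
    """

    name: str
    d_OH: float
    phi_HOH: float
    sigma_O: float
    epsilon_O: float
    q_H: float
    year: int
    extra_h_site: bool = False

    def __post_init__(self) -> None:
        if not self.d_OH > 0:
            raise ValueError(f"{self.name}: d_OH must be positive")
        if not 0 < self.phi_HOH < 180:
            raise ValueError(f"{self.name}: phi_HOH must lie in (0, 180) deg")
        if not self.sigma_O > 0:
            raise ValueError(f"{self.name}: sigma_O must be positive")
        if not self.epsilon_O > 0:
            raise ValueError(f"{self.name}: epsilon_O must be positive")
        if not 0 < self.q_H < 1:
            raise ValueError(f"{self.name}: q_H must lie in (0, 1) e")

    @property
    def q_O(self) -> float:
        """Oxygen partial charge [e], fixed by neutrality."""
        return -2.0 * self.q_H


@dataclass(frozen=True)
class DerivedMoments:
    """Scalar electrostatic moments of a model: μ [D], Q_T [D·Å], θ [deg]."""

    mu: float
    Q_T: float
    theta: float


def load_registry() -> list[WaterModel]:
    """Load the bundled table of 11 rigid three-point water models.

    Raises :class:`RegistryError` if the bundled CSV resource is absent or
    does not parse.
    """
    try:
        ref = resources.files("aquaphase.data").joinpath("water_models.csv")
        with ref.open("r") as fh:
            frame = pd.read_csv(fh)
    except (FileNotFoundError, pd.errors.ParserError, ModuleNotFoundError) as exc:
        raise RegistryError(f"cannot load bundled water-model registry: {exc}") from exc
    required = {"name", "d_OH", "phi_HOH", "sigma_O", "epsilon_O", "q_H", "year", "extra_h_site"}
    if not required.issubset(frame.columns):
        raise RegistryError(
            f"registry is missing columns: {sorted(required - set(frame.columns))}"
        )
    return [
        WaterModel(
            name=row["name"],
            d_OH=float(row["d_OH"]),
            phi_HOH=float(row["phi_HOH"]),
            sigma_O=float(row["sigma_O"]),
            epsilon_O=float(row["epsilon_O"]),
            q_H=float(row["q_H"]),
            year=int(row["year"]),
            extra_h_site=bool(row["extra_h_site"]),
        )
        for _, row in frame.iterrows()
    ]


def get_model(name: str) -> WaterModel:
    """Return the registry entry called ``name`` (exact match)."""
    for model in load_registry():
        if model.name == name:
            return model
    raise KeyError(f"unknown water model {name!r}")


def dipole_moment(model: WaterModel) -> float:
    """Dipole moment μ = 2 q_H d_OH cos(θ) in Debye."""
    theta = math.radians(model.phi_HOH / 2.0)
    return 2.0 * model.q_H * model.d_OH * math.cos(theta) * EA_TO_DEBYE


def quadrupole_moment(model: WaterModel) -> float:
    """Tetrahedral quadrupole moment Q_T = (3/2) q_H d_OH² sin²(θ) in D·Å."""
    theta = math.radians(model.phi_HOH / 2.0)
    return 1.5 * model.q_H * model.d_OH**2 * math.sin(theta) ** 2 * EA_TO_DEBYE


def derived_moments(model: WaterModel) -> DerivedMoments:
    """Closed-form μ and Q_T for one model."""
    return DerivedMoments(
        mu=dipole_moment(model),
        Q_T=quadrupole_moment(model),
        theta=model.phi_HOH / 2.0,
    )


def charge_sites(model: WaterModel) -> tuple[np.ndarray, np.ndarray]:
    """Explicit charge coordinates of a model.

    The molecule sits in the xz-plane with the oxygen at the origin and the
    dipole along +z: hydrogens at (±d sinθ, 0, d cosθ).  Returns
    ``(charges [e], positions [Å])`` with shapes (3,), (3, 3).
    """
    theta = math.radians(model.phi_HOH / 2.0)
    x, z = model.d_OH * math.sin(theta), model.d_OH * math.cos(theta)
    positions = np.array([[0.0, 0.0, 0.0], [x, 0.0, z], [-x, 0.0, z]])
    charges = np.array([model.q_O, model.q_H, model.q_H])
    return charges, positions


def point_charge_moments(model: WaterModel) -> DerivedMoments:
    """Brute-force μ and Q_T from the explicit point charges.

    μ is the magnitude of Σ qᵢ rᵢ.  Q_T is ½(Θ_xx − Θ_yy) of the traceless
    quadrupole tensor Θ_αβ = ½ Σ q (3 r_α r_β − r² δ_αβ) about the oxygen.
    Serves as the independent oracle for the closed-form expressions.
    """
    q, r = charge_sites(model)
    mu_vec = (q[:, None] * r).sum(axis=0)
    r2 = (r**2).sum(axis=1)
    theta_t = 0.5 * np.einsum("i,iab->ab", q, 3.0 * r[:, :, None] * r[:, None, :])
    theta_t -= 0.5 * np.diag([np.dot(q, r2)] * 3)
    q_t = 0.5 * (theta_t[0, 0] - theta_t[1, 1])
    return DerivedMoments(
        mu=float(np.linalg.norm(mu_vec)) * EA_TO_DEBYE,
        Q_T=float(q_t) * EA_TO_DEBYE,
        theta=model.phi_HOH / 2.0,
    )


def moments_table(models: list[WaterModel] | None = None) -> pd.DataFrame:
    """μ and Q_T for every model, as a DataFrame indexed by model name."""
    models = load_registry() if models is None else models
    rows = []
    for m in models:
        dm = derived_moments(m)
        rows.append({"name": m.name, "mu_D": dm.mu, "Q_T_DA": dm.Q_T, "year": m.year})
    return pd.DataFrame(rows).set_index("name")
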