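"""Cross-model correlations between phase-diagram points and model parameters.

Given per-model characteristic points (critical point, density maximum,
spontaneous-evaporation temperature) and the model parameters and
electrostatic moments, this module quantifies how well one quantity
predicts another across the 11 water models:

* ``linear_fit``  — ordinary least squares y = a x + b, R² = squared
  Pearson correlation;
* ``offset_fit``  — the one-parameter model y = x + c with
  c = mean(y − x) and R² = 1 − SS_res/SS_tot about mean(y), the natural
  score for "the two temperatures differ by a constant";
* ``property_scan`` — one linear fit of a target (typically T_evap)
  against each model parameter / moment, ranked by R².

The bundled characteristic-point table carries an experimental reference
row; it is excluded from all cross-model fits and kept only for
reference deltas (e.g. the experimental T_C − T_MD gap).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .registry import RegistryError, dipole_moment, load_registry, quadrupole_moment

__all__ = [
    "CorrelationResult",
    "load_characteristic_points",
    "model_summaries",
    "linear_fit",
    "offset_fit",
    "property_scan",
    "experimental_gap",
]

logger = logging.getLogger(__name__)

#: predictors scanned against the target in property_scan
SCAN_PREDICTORS = ("d_OH", "phi_HOH", "sigma_O", "epsilon_O", "q_H", "mu", "Q_T")


@dataclass(frozen=True)
class CorrelationResult:
    """Outcome of one pairwise fit across models."""

    x_name: str
    y_name: str
    n: int
    slope: float
    intercept: float
    r2: float
    fit_kind: str


def load_characteristic_points(include_experiment: bool = False) -> pd.DataFrame:
    """Bundled per-model characteristic points (T_C, ρ_C, T_MD, ρ_MD, T_evap).

    Temperatures in K, densities in g/L; ``sd_*`` columns carry the
    published block-splitting uncertainties.  The experimental reference
    row is dropped unless ``include_experiment`` is set.
    """
    try:
        ref = resources.files("aquaphase.data").joinpath("characteristic_points.csv")
        with ref.open("r") as fh:
            frame = pd.read_csv(fh)
    except (FileNotFoundError, pd.errors.ParserError) as exc:
        raise RegistryError(f"cannot load characteristic-point table: {exc}") from exc
    if not include_experiment:
        frame = frame[frame["source"] != "experiment"].reset_index(drop=True)
    return frame


def model_summaries() -> pd.DataFrame:
    """Characteristic points joined with model parameters and moments.

    One row per water model; columns include the Table-style phase-diagram
    points plus d_OH, phi_HOH, sigma_O, epsilon_O, q_H, mu and Q_T.
    """
    points = load_characteristic_points(include_experiment=False)
    params = []
    for m in load_registry():
        params.append(
            {
                "name": m.name,
                "d_OH": m.d_OH,
                "phi_HOH": m.phi_HOH,
                "sigma_O": m.sigma_O,
                "epsilon_O": m.epsilon_O,
                "q_H": m.q_H,
                "year": m.year,
                "mu": dipole_moment(m),
                "Q_T": quadrupole_moment(m),
            }
        )
    return points.merge(pd.DataFrame(params), on="name", validate="1:1")


def _paired(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be matching 1-D sequences")
    keep = np.isfinite(x) & np.isfinite(y)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("dropping %d pairs with missing values", dropped)
    return x[keep], y[keep]


def linear_fit(x, y, x_name: str = "x", y_name: str = "y") -> CorrelationResult:
    """Ordinary least squares y = slope·x + intercept with R² = Pearson r².

    Degenerate inputs: zero variance in x raises (no slope is defined);
    constant y is scored R² = 0 by convention.
    """
    x, y = _paired(x, y)
    if x.size < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.ptp(x) == 0 or np.var(x) == 0:
        raise ValueError(f"zero variance in x ({x_name}); slope undefined")
    slope, intercept = np.polyfit(x, y, 1)
    if np.var(y) == 0:
        r2 = 0.0
    else:
        r2 = float(np.corrcoef(x, y)[0, 1] ** 2)
    return CorrelationResult(
        x_name=x_name, y_name=y_name, n=int(x.size),
        slope=float(slope), intercept=float(intercept),
        r2=r2, fit_kind="full-linear",
    )


def offset_fit(x, y, x_name: str = "x", y_name: str = "y") -> CorrelationResult:
    """Offset-only fit y = x + c with c = mean(y − x).

    R² = 1 − SS_res/SS_tot with SS_tot taken about mean(y); clipped at 0
    for pathologically bad data so the score stays in [0, 1].
    """
    x, y = _paired(x, y)
    if x.size < 2:
        raise ValueError("need at least 2 complete pairs")
    c = float(np.mean(y - x))
    ss_res = float(np.sum((y - x - c) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    r2 = 1.0 if ss_tot == 0 and ss_res == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    return CorrelationResult(
        x_name=x_name, y_name=y_name, n=int(x.size),
        slope=1.0, intercept=c, r2=r2, fit_kind="offset-only",
    )


def property_scan(
    summaries: pd.DataFrame | None = None,
    target: str = "T_evap",
    predictors: tuple[str, ...] = SCAN_PREDICTORS,
) -> list[CorrelationResult]:
    """Linear fit of ``target`` against each model parameter, ranked by R².

    Zero-variance predictors are skipped with a warning; pairs with
    missing values are dropped per predictor with a logged count.
    """
    frame = model_summaries() if summaries is None else summaries
    if target not in frame.columns:
        raise KeyError(f"target column {target!r} absent from summaries")
    results = []
    for name in predictors:
        if name not in frame.columns:
            raise KeyError(f"predictor column {name!r} absent from summaries")
        try:
            results.append(linear_fit(frame[name], frame[target], name, target))
        except ValueError as exc:
            warnings.warn(f"skipping predictor {name}: {exc}", stacklevel=2)
    return sorted(results, key=lambda r: r.r2, reverse=True)


def experimental_gap(column_high: str = "T_C", column_low: str = "T_MD") -> float:
    """Difference of two experimental reference values from the bundled table."""
    frame = load_characteristic_points(include_experiment=True)
    row = frame[frame["source"] == "experiment"]
    if row.empty:
        raise RegistryError("no experimental row in the characteristic-point table")
    return float(row[column_high].iloc[0] - row[column_low].iloc[0])
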