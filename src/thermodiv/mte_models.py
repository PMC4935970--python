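"""Boltzmann-Arrhenius fitting of diversity against temperature.

The metabolic theory of ecology predicts ln S = a - E_a * (1/kT): log
richness declines linearly with inverse thermal energy 1/(kT), where k is
Boltzmann's constant in eV/K and T the absolute temperature.  The fitted
slope, sign-reversed, is the activation energy E_a (eV).  A quadratic
polynomial and a continuous two-segment (hinge) model are fitted to the
same points as alternatives, and models are compared by AIC: fits within
two AIC units of the best are "competitive".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BOLTZMANN_EV_PER_K",
    "ArrheniusPoint",
    "MteFit",
    "arrhenius_points",
    "fit_linear",
    "fit_quadratic",
    "fit_piecewise",
    "select_model",
    "q10_from_ea",
]

#: Boltzmann's constant in electron-volts per kelvin.
BOLTZMANN_EV_PER_K = 8.617e-5

# Residual variances below this are treated as exact fits: keeps the
# Gaussian likelihood finite and makes AIC comparisons between two
# interpolating models depend only on their parameter counts.
_SIGMA2_FLOOR = 1e-12


@dataclass
class ArrheniusPoint:
    """One unit on the Arrhenius plot: x = 1/(kT) in 1/eV, y = ln richness."""

    unit: str
    temperature_k: float
    x: float
    y: float


@dataclass
class MteFit:
    """A fitted diversity-temperature model.

    ``aic`` is -2 ln L + 2 * n_params with a Gaussian likelihood evaluated
    at the MLE residual variance SS_res / n_obs; n_params counts the
    residual variance as a parameter (3 linear, 4 quadratic, 5 piecewise).
    ``ea`` (activation energy, eV) is the sign-reversed slope and is only
    defined for the linear form.
    """

    form: str
    coefficients: dict[str, float]
    ea: float | None
    r2: float
    aic: float
    log_likelihood: float
    n_obs: int
    n_params: int
    ss_res: float
    ss_tot: float
    x: np.ndarray = field(repr=False, default=None)
    y: np.ndarray = field(repr=False, default=None)

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        c = self.coefficients
        if self.form == "linear":
            return c["intercept"] + c["slope"] * x
        if self.form == "quadratic":
            return c["a"] + c["b"] * x + c["c"] * x**2
        if self.form == "piecewise":
            t = c["breakpoint"]
            return (
                c["intercept"]
                + c["left_slope"] * np.minimum(x - t, 0)
                + c["right_slope"] * np.maximum(x - t, 0)
            )
        raise ValueError(f"unknown form {self.form!r}")


def arrhenius_points(richness, temps_c, units=None) -> list[ArrheniusPoint]:
    """Convert richness estimates and Celsius temperatures to Arrhenius
    coordinates (x = 1/(kT), y = ln S)."""
    s = np.asarray(richness, dtype=float)
    tc = np.asarray(temps_c, dtype=float)
    if s.size != tc.size:
        raise ValueError("richness and temperature vectors differ in length")
    if np.any(~np.isfinite(tc)):
        raise ValueError("temperatures must be finite")
    if np.any(s < 1):
        raise ValueError("richness must be >= 1 (ln S would be negative)")
    if units is None:
        units = [f"unit{i}" for i in range(s.size)]
    out = []
    for u, si, ti in zip(units, s, tc):
        tk = ti + 273.15
        out.append(
            ArrheniusPoint(
                unit=str(u),
                temperature_k=tk,
                x=1.0 / (BOLTZMANN_EV_PER_K * tk),
                y=math.log(si),
            )
        )
    return out


def _xy(points) -> tuple[np.ndarray, np.ndarray]:
    if points and isinstance(points[0], ArrheniusPoint):
        x = np.array([p.x for p in points], dtype=float)
        y = np.array([p.y for p in points], dtype=float)
    else:
        x, y = (np.asarray(v, dtype=float) for v in points)
    return x, y


def _gaussian_ll(ss_res: float, n: int) -> float:
    sigma2 = max(ss_res / n, _SIGMA2_FLOOR)
    return -0.5 * n * (math.log(2 * math.pi * sigma2) + 1.0)


def _finish(form, coeffs, ea, x, y, fitted, n_params) -> MteFit:
    resid = y - fitted
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    r2 = min(max(r2, 0.0), 1.0)
    ll = _gaussian_ll(ss_res, y.size)
    return MteFit(
        form=form,
        coefficients=coeffs,
        ea=ea,
        r2=r2,
        aic=-2.0 * ll + 2.0 * n_params,
        log_likelihood=ll,
        n_obs=y.size,
        n_params=n_params,
        ss_res=ss_res,
        ss_tot=ss_tot,
        x=x,
        y=y,
    )


def fit_linear(points) -> MteFit:
    """OLS of y = a + b x; activation energy E_a = -b."""
    x, y = _xy(points)
    if x.size < 3:
        raise ValueError("linear fit needs at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; slope undefined")
    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    coeffs = {"intercept": float(beta[0]), "slope": float(beta[1])}
    return _finish("linear", coeffs, -coeffs["slope"], x, y, X @ beta, 3)


def fit_quadratic(points) -> MteFit:
    """OLS of y = a + b x + c x^2.  No activation energy is reported."""
    x, y = _xy(points)
    if x.size < 4:
        raise ValueError("quadratic fit needs at least 4 points")
    X = np.column_stack([np.ones_like(x), x, x * x])
    if np.linalg.matrix_rank(X) < 3:
        raise ValueError("rank-deficient design (fewer than 3 distinct x values)")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    coeffs = {"a": float(beta[0]), "b": float(beta[1]), "c": float(beta[2])}
    return _finish("quadratic", coeffs, None, x, y, X @ beta, 4)


def fit_piecewise(points) -> MteFit:
    """Continuous two-segment (hinge) regression with one breakpoint.

    The breakpoint is chosen by grid search over interior observed x values
    leaving at least two points strictly on each side, minimising SS_res.
    """
    x, y = _xy(points)
    if x.size < 6:
        raise ValueError("piecewise fit needs at least 6 points")
    candidates = [t for t in np.unique(x) if (x < t).sum() >= 2 and (x > t).sum() >= 2]
    if not candidates:
        raise ValueError("no breakpoint candidate leaves two points per side")
    best = None
    for t in candidates:
        X = np.column_stack(
            [np.ones_like(x), np.minimum(x - t, 0), np.maximum(x - t, 0)]
        )
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        ssr = float(resid @ resid)
        if best is None or ssr < best[0]:
            best = (ssr, t, beta, X @ beta)
    _, t, beta, fitted = best
    coeffs = {
        "intercept": float(beta[0]),
        "left_slope": float(beta[1]),
        "right_slope": float(beta[2]),
        "breakpoint": float(t),
    }
    return _finish("piecewise", coeffs, None, x, y, fitted, 5)


@dataclass
class ModelSelection:
    """AIC ranking of candidate fits over the same data."""

    table: pd.DataFrame  # form, aic, delta_aic, r2, n_params, competitive
    best: str
    competitive: list[str]


def select_model(fits: list[MteFit], competitive_delta: float = 2.0) -> ModelSelection:
    """Rank fits by AIC; fits within ``competitive_delta`` of the best are
    competitive.  AIC ties break by higher r2, then fewer parameters."""
    if len(fits) < 2:
        raise ValueError("model selection needs at least 2 fits")
    ref = fits[0]
    for f in fits[1:]:
        if f.n_obs != ref.n_obs or not (
            np.allclose(f.x, ref.x) and np.allclose(f.y, ref.y)
        ):
            raise ValueError("fits were made on different data")
    rows = sorted(fits, key=lambda f: (f.aic, -f.r2, f.n_params))
    best_aic = rows[0].aic
    table = pd.DataFrame(
        {
            "form": [f.form for f in rows],
            "aic": [f.aic for f in rows],
            "delta_aic": [f.aic - best_aic for f in rows],
            "r2": [f.r2 for f in rows],
            "n_params": [f.n_params for f in rows],
        }
    )
    table["competitive"] = table["delta_aic"] < competitive_delta
    return ModelSelection(
        table=table,
        best=rows[0].form,
        competitive=table.loc[table["competitive"], "form"].tolist(),
    )


def q10_from_ea(ea: float, t1: float, t2: float) -> float:
    """Rate multiplier between absolute temperatures t1 < t2 implied by an
    activation energy (eV): exp(ea (t2 - t1) / (k t1 t2)).  For a 10 K step
    this is the familiar Q10."""
    if t1 <= 0 or t2 <= 0:
        raise ValueError("temperatures must be positive (kelvin)")
    if t2 <= t1:
        raise ValueError("t2 must exceed t1")
    return math.exp(ea * (t2 - t1) / (BOLTZMANN_EV_PER_K * t1 * t2))
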