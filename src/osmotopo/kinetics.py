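"""Mass-transfer bookkeeping and Peleg equilibrium kinetics.

During osmotic dehydration a tissue cube immersed in a hypertonic
solution loses water and gains solutes (and dissolved bioactives).  The
increase of any transferred quantity j over time, Y_j(t), follows the
two-parameter Peleg sorption model

    Y(t) = Y0 + t / (k1 + k2·t),

whose equilibrium value is Y_e = Y0 + 1/k2.  k1 (s per substance unit)
is the reciprocal initial rate and k2 (1 per substance unit) the
capacity constant.  This module provides the mass-balance primitives
(water loss, solute gain, wet/dry basis, dimensionless volume) and a
nonlinear least-squares Peleg fit with diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "KineticSeries",
    "PelegFit",
    "ShrinkageSeries",
    "DegenerateSeriesError",
    "dimensionless_volume",
    "wet_to_dry_basis",
    "water_loss",
    "solute_gain",
    "peleg_fit",
    "equilibrium_value",
]


class DegenerateSeriesError(ValueError):
    """Raised when a kinetic series carries no usable signal for a fit."""


@dataclass(frozen=True)
class KineticSeries:
    """Timestamped increases Y_j(t) of a transferred substance.

    ``substance`` is a free label (e.g. ``"water loss"``, ``"solute
    gain"``, ``"AA"``, ``"TPC"``, ``"TMA"``); ``values`` are in the
    substance's own units (g/g fresh product for WL/SG, mg per 100 g
    dry basis for bioactives).
    """

    substance: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or t.shape != y.shape:
            raise ValueError("times and values must be equal-length 1D arrays")
        if t.size and t[0] < 0:
            raise ValueError("first time must be nonnegative")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", y)


@dataclass(frozen=True)
class ShrinkageSeries:
    """Dimensionless volume V/V0 over time; V/V0(0) must be ≈ 1."""

    times: np.ndarray
    v_ratio: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.v_ratio, dtype=float)
        if t.shape != v.shape or t.ndim != 1:
            raise ValueError("times and v_ratio must be equal-length 1D arrays")
        if np.any(v <= 0):
            raise ValueError("v_ratio must be positive")
        if t.size and t[0] == 0 and abs(v[0] - 1.0) > 1e-6:
            raise ValueError("v_ratio at t=0 must be 1")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "v_ratio", v)


@dataclass(frozen=True)
class PelegFit:
    """Fitted Peleg parameters with diagnostics.

    ``Ye`` always equals ``Y0 + 1/k2``; ``se_k1``/``se_k2`` are
    Jacobian-based standard errors at the optimum.
    """

    substance: str
    Y0: float
    k1: float
    k2: float
    Ye: float = field(init=False)
    r_squared: float = np.nan
    rmse: float = np.nan
    se_k1: float = np.nan
    se_k2: float = np.nan

    def __post_init__(self) -> None:
        if self.k2 <= 0:
            raise ValueError("k2 must be positive")
        object.__setattr__(self, "Ye", self.Y0 + 1.0 / self.k2)

    def predict(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.Y0 + t / (self.k1 + self.k2 * t)


def dimensionless_volume(
    L1: float, L2: float, L3: float, L1_0: float, L2_0: float, L3_0: float
) -> float:
    """V/V0 of a (possibly shrunken) cuboid from its edge lengths (m)."""
    lengths = (L1, L2, L3, L1_0, L2_0, L3_0)
    if any(x <= 0 for x in lengths):
        raise ValueError("all lengths must be positive")
    return (L1 * L2 * L3) / (L1_0 * L2_0 * L3_0)


def wet_to_dry_basis(wb: float) -> float:
    """Convert moisture from wet basis (g water/g fresh) to dry basis."""
    if not 0 <= wb < 1:
        raise ValueError("wet-basis moisture must lie in [0, 1)")
    return wb / (1.0 - wb)


def water_loss(m_p0: float, m_OP: float, M0: float, M_OP: float) -> float:
    """Water loss per gram of fresh product.

    WL = (m_p0·M0 − m_OP·M_OP) / m_p0 with m the sample masses (g) and
    M the wet-basis moisture fractions before and after treatment.
    """
    _check_mass_balance_inputs(m_p0, m_OP, M0, M_OP)
    return (m_p0 * M0 - m_OP * M_OP) / m_p0


def solute_gain(m_p0: float, m_OP: float, M0: float, M_OP: float) -> float:
    """Solute gain per gram of fresh product.

    SG = (m_OP·(1 − M_OP) − m_p0·(1 − M0)) / m_p0.  Together with
    water_loss this satisfies the mass balance
    WL − (m_p0 − m_OP)/m_p0 − SG = 0.
    """
    _check_mass_balance_inputs(m_p0, m_OP, M0, M_OP)
    return (m_OP * (1.0 - M_OP) - m_p0 * (1.0 - M0)) / m_p0


def _check_mass_balance_inputs(m_p0: float, m_OP: float, M0: float, M_OP: float) -> None:
    if m_p0 <= 0 or m_OP <= 0:
        raise ValueError("masses must be positive")
    for M in (M0, M_OP):
        if not 0 <= M < 1:
            raise ValueError("moisture fractions must lie in [0, 1)")


def peleg_fit(series: KineticSeries, Y0: float | None = None) -> PelegFit:
    """Fit the Peleg model to a kinetic series by nonlinear least squares.

    Y0 is a datum, not a fitted parameter: it defaults to the t = 0
    observation (or the first observation when no t = 0 point exists),
    which is 0 for water loss and solute gain by construction.  Starting
    values for (k1, k2) come from ordinary least squares on the
    linearization t/(Y − Y0) = k1 + k2·t, making the fit insensitive to
    solver initialization.

    Raises
    ------
    DegenerateSeriesError
        If the series is flat (k2 unidentifiable) or the fitted k2 is
        not positive (data incompatible with a saturating uptake).
    """
    t = series.times
    y = series.values
    if t.size < 4:
        raise ValueError("need at least 4 points to fit the Peleg model")
    if Y0 is None:
        Y0 = float(y[0]) if t[0] == 0 else float(y[0])
    dy = y - Y0
    if np.allclose(dy, dy[0]):
        raise DegenerateSeriesError("flat series: k2 is unidentifiable")

    # linearized initialization on points with genuine uptake
    use = (t > 0) & (dy != 0)
    if use.sum() < 2:
        raise DegenerateSeriesError("too few nonzero increments to initialize")
    x_lin = t[use]
    z = x_lin / dy[use]
    k2_0, k1_0 = np.polyfit(x_lin, z, 1)
    if k1_0 <= 0:
        k1_0 = abs(k1_0) or 1.0
    if k2_0 <= 0:
        k2_0 = abs(k2_0) or 1.0

    def model(tt: np.ndarray, k1: float, k2: float) -> np.ndarray:
        return Y0 + tt / (k1 + k2 * tt)

    popt, pcov = curve_fit(
        model, t, y, p0=[k1_0, k2_0], maxfev=20000, bounds=([0, 0], [np.inf, np.inf])
    )
    k1, k2 = float(popt[0]), float(popt[1])
    if k2 <= 0:
        raise DegenerateSeriesError("fitted k2 is not positive: data are not Peleg-shaped")
    resid = y - model(t, k1, k2)
    sse = float(resid @ resid)
    sst = float(((y - y.mean()) ** 2).sum())
    r_squared = 1.0 - sse / sst if sst > 0 else np.nan
    rmse = float(np.sqrt(sse / t.size))
    se = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else (np.nan, np.nan)
    return PelegFit(
        substance=series.substance,
        Y0=Y0,
        k1=k1,
        k2=k2,
        r_squared=r_squared,
        rmse=rmse,
        se_k1=float(se[0]),
        se_k2=float(se[1]),
    )


def equilibrium_value(fit: PelegFit) -> float:
    """Equilibrium increase Y_e = Y0 + 1/k2 (the t → ∞ limit of the model)."""
    if fit.k2 <= 0:
        raise ValueError("k2 must be positive")
    return fit.Y0 + 1.0 / fit.k2
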