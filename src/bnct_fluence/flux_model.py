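"""Empirical neutron-flux degradation model for solid-state Li targets.

In accelerator-based BNCT with a ``7Li(p,n)7Be`` neutron source, proton
bombardment degrades the lithium layer and the neutron flux per unit proton
current falls with the cumulative proton charge *m* delivered to the target.
The degradation is described by the three-coefficient exponential

    F(m) = a * exp(-b * m) + c        [Bq/mA/atom]

where ``a`` is the decaying amplitude, ``b`` the decay constant per mC, and
``c`` the asymptotic flux of the worn target.  The coefficients are purely
empirical and are fitted per target from activation-foil flux measurements.

The neutron *fluence* delivered between cumulative charges ``d`` and ``e``
is the integral of F over that charge interval; it has the closed form

    NF(d, e) = (a/b) * (exp(-b d) - exp(-b e)) + c * (e - d)

with the limit ``(a + c) * (e - d)`` as ``b -> 0``.

The canonical charge unit throughout this package is the millicoulomb (mC);
the model is often written against charge in mAh elsewhere, and
``MC_PER_MAH`` converts at the boundary (1 mAh = 3600 mC).
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Optional

import numpy as np
from scipy.optimize import least_squares

if TYPE_CHECKING:  # pragma: no cover
    from .measurement_io import MeasurementSeries

__all__ = [
    "MC_PER_MAH",
    "N_MIN_DEFAULT",
    "FitDiagnostics",
    "FluxModel",
    "InsufficientDataError",
    "FitFailureError",
    "evaluate_flux",
    "integrate_flux",
    "fit_flux_model",
]

#: 1 mAh of proton charge expressed in mC.
MC_PER_MAH = 3600.0

#: Minimum number of measurements required to fit the 3-coefficient model
#: (3 coefficients + 2 residual degrees of freedom).
N_MIN_DEFAULT = 5

#: b * (e - d) below this threshold switches the fluence integral to its
#: b -> 0 limit, avoiding catastrophic cancellation in exp(-bd) - exp(-be).
_B_SMALL = 1e-12

#: Floor for the asymptotic flux c during fitting (Bq/mA/atom); keeps the
#: fitted flux strictly positive.
_C_FLOOR = 1e-30


class InsufficientDataError(ValueError):
    """Fewer measurements than the minimum needed to constrain the fit."""


class FitFailureError(RuntimeError):
    """Nonlinear fit did not converge; carries the diagnostics record."""

    def __init__(self, message: str, diagnostics: "FitDiagnostics"):
        super().__init__(message)
        self.diagnostics = diagnostics


@dataclass(frozen=True)
class FitDiagnostics:
    """Bookkeeping attached to a fitted :class:`FluxModel`."""

    n_points: int
    residual_rms: float  # RMS of relative residuals (dimensionless)
    converged: bool
    message: str = ""


@dataclass(frozen=True)
class FluxModel:
    """Coefficients of the per-target flux degradation curve.

    Parameters
    ----------
    a : float
        Decaying flux amplitude, Bq/mA/atom.  ``a >= 0``.
    b : float
        Decay constant per mC of cumulative proton charge.  ``b >= 0``.
    c : float
        Asymptotic flux of the fully degraded target, Bq/mA/atom. ``c > 0``.
    fit_diagnostics : FitDiagnostics, optional
        Present when the model came from :func:`fit_flux_model`.
    """

    a: float
    b: float
    c: float
    fit_diagnostics: Optional[FitDiagnostics] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not (self.a >= 0.0):
            raise ValueError(f"amplitude a must be >= 0, got {self.a}")
        if not (self.b >= 0.0):
            raise ValueError(f"decay constant b must be >= 0, got {self.b}")
        if not (self.c > 0.0):
            raise ValueError(f"asymptotic flux c must be > 0, got {self.c}")

    # -- convenience -------------------------------------------------------

    def __call__(self, m):
        return evaluate_flux(self, m)

    def to_text(self) -> str:
        """Serialize to a small key-value record (see :meth:`from_text`)."""
        buf = io.StringIO()
        buf.write("# flux degradation model F(m) = a*exp(-b*m) + c\n")
        buf.write("charge_unit = mC\n")
        buf.write(f"a_Bq_per_mA_per_atom = {self.a!r}\n")
        buf.write(f"b_per_mC = {self.b!r}\n")
        buf.write(f"c_Bq_per_mA_per_atom = {self.c!r}\n")
        d = self.fit_diagnostics
        if d is not None:
            buf.write(f"fit_n_points = {d.n_points}\n")
            buf.write(f"fit_residual_rms = {d.residual_rms!r}\n")
            buf.write(f"fit_converged = {d.converged}\n")
        return buf.getvalue()

    @classmethod
    def from_text(cls, text: str) -> "FluxModel":
        kv = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            kv[key.strip()] = value.strip()
        if kv.get("charge_unit", "mC") != "mC":
            raise ValueError(f"unsupported charge unit {kv.get('charge_unit')!r}")
        diag = None
        if "fit_n_points" in kv:
            diag = FitDiagnostics(
                n_points=int(kv["fit_n_points"]),
                residual_rms=float(kv["fit_residual_rms"]),
                converged=kv["fit_converged"] == "True",
            )
        return cls(
            a=float(kv["a_Bq_per_mA_per_atom"]),
            b=float(kv["b_per_mC"]),
            c=float(kv["c_Bq_per_mA_per_atom"]),
            fit_diagnostics=diag,
        )


def evaluate_flux(model: FluxModel, m):
    """Neutron flux F(m) = a exp(-b m) + c at cumulative charge ``m`` (mC).

    ``m`` may be a scalar or array; negative charges are a domain error.
    The result is strictly positive and non-increasing in ``m``.
    """
    m_arr = np.asarray(m, dtype=float)
    if np.any(m_arr < 0.0):
        raise ValueError("cumulative charge m must be >= 0")
    out = model.a * np.exp(-model.b * m_arr) + model.c
    return float(out) if np.isscalar(m) or m_arr.ndim == 0 else out


def integrate_flux(model: FluxModel, d: float, e: float) -> float:
    """Neutron fluence delivered between cumulative charges ``d`` and ``e``.

    Closed form of the integral of the degradation curve, in atom^-1
    (Bq/mA/atom integrated over mC of charge).  Requires ``0 <= d <= e``;
    the result is >= 0 and vanishes iff ``d == e``.
    """
    if d < 0.0:
        raise ValueError("lower charge limit d must be >= 0")
    if e < d:
        raise ValueError(f"upper charge limit e={e} below lower limit d={d}")
    span = e - d
    if model.b * span < _B_SMALL:
        # b -> 0 limit; also covers d == e exactly.
        return (model.a + model.c) * span
    # expm1 keeps exp(-bd) - exp(-be) accurate when b*span is small.
    exp_term = -(model.a / model.b) * math.exp(-model.b * d) * math.expm1(
        -model.b * span
    )
    return exp_term + model.c * span


def _initial_guess(charge: np.ndarray, flux: np.ndarray) -> tuple[float, float, float]:
    """Deterministic, scale-aware starting point for the bounded fit.

    c0 is the smallest observed flux, a0 the first observation's excess over
    it, and b0 comes from a log-linear regression of log(flux - 0.99 c0)
    against charge (clamped to >= 0).
    """
    c0 = float(flux.min())
    a0 = max(float(flux[0]) - c0, 1e-3 * c0)
    excess = flux - 0.99 * c0  # > 0 by construction
    design = np.column_stack([np.ones_like(charge), -charge])
    coef, *_ = np.linalg.lstsq(design, np.log(excess), rcond=None)
    b0 = max(float(coef[1]), 0.0)
    return a0, b0, c0


def fit_flux_model(
    series: "MeasurementSeries",
    n_min: int = N_MIN_DEFAULT,
) -> FluxModel:
    """Fit the degradation curve to one target's measurement series.

    Bounded nonlinear least squares (trust-region reflective) with
    ``a >= 0``, ``b >= 0``, ``c > 0``.  When the series carries relative
    measurement uncertainties the residuals are weighted by
    ``1 / (rel_uncertainty * flux)``; otherwise the fit is unweighted.
    Charges and fluxes are rescaled internally so the optimizer works near
    unit magnitude (raw fluxes are ~1e-15 Bq/mA/atom).

    Raises
    ------
    InsufficientDataError
        Fewer than ``n_min`` points.
    FitFailureError
        Optimizer reported non-convergence; diagnostics attached.
    """
    charge = np.asarray([p.cumulative_charge for p in series.measurements], float)
    flux = np.asarray([p.flux for p in series.measurements], float)
    if len(charge) < n_min:
        raise InsufficientDataError(
            f"target {series.target_id!r}: {len(charge)} points < n_min={n_min}"
        )
    rel_unc = np.asarray(
        [p.rel_uncertainty if p.rel_uncertainty is not None else np.nan
         for p in series.measurements],
        float,
    )
    weighted = not np.any(np.isnan(rel_unc))

    m_scale = float(charge.max()) if charge.max() > 0 else 1.0
    f_scale = float(np.median(flux))
    x = charge / m_scale
    y = flux / f_scale
    sigma = (rel_unc * y) if weighted else np.ones_like(y)

    a0, b0, c0 = _initial_guess(x, y)

    def residuals(p):
        a, b, c = p
        return (a * np.exp(-b * x) + c - y) / sigma

    result = least_squares(
        residuals,
        x0=[a0, b0, max(c0, _C_FLOOR / f_scale)],
        bounds=([0.0, 0.0, _C_FLOOR / f_scale], [np.inf, np.inf, np.inf]),
        method="trf",
        xtol=1e-13,
        ftol=1e-13,
        gtol=1e-13,
        max_nfev=5000,
    )
    a, b, c = result.x
    pred = a * np.exp(-b * x) + c
    rms = float(np.sqrt(np.mean(((pred - y) / y) ** 2)))
    diag = FitDiagnostics(
        n_points=len(charge),
        residual_rms=rms,
        converged=bool(result.success),
        message=result.message,
    )
    if not result.success:
        raise FitFailureError(
            f"target {series.target_id!r}: fit did not converge "
            f"({result.message})",
            diag,
        )
    return FluxModel(
        a=float(a * f_scale),
        b=float(b / m_scale),
        c=float(c * f_scale),
        fit_diagnostics=diag,
    )
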