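"""Binodal curve of the ethanol–ammonium-sulfate aqueous two-phase system.

An aqueous two-phase system (ATPS) forms when a short-chain alcohol and a
kosmotropic salt compete for water strongly enough that the mixture splits
into an alcohol-rich top phase and a salt-rich bottom phase.  The binodal
curve is the boundary in the (salt mass fraction ``w2``, alcohol mass
fraction ``w1``) plane separating the one-phase region (below) from the
two-phase region (above).  For small-alcohol/salt systems the binodal is
well described by the four-parameter empirical form

    w1 = exp(a + b·√w2 + c·w2 + d·w2²)

This module fits that relation to measured node points, evaluates it, and
classifies compositions into the one- or two-phase region.  Mass fractions
are stored as fractions in [0, 1] throughout; the CLI converts percents.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math

import numpy as np
from scipy.optimize import least_squares

from .exceptions import ConvergenceError, DomainError, InsufficientDataError
from .metrics import fit_metrics

__all__ = [
    "BinodalCoefficients",
    "PhaseComposition",
    "BinodalFitReport",
    "ETHANOL_AMMONIUM_SULFATE",
    "eval_binodal",
    "fit_binodal",
    "classify_region",
]


@dataclass(frozen=True)
class BinodalCoefficients:
    """The four fitting constants (a, b, c, d) of the empirical binodal."""

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self):
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise DomainError(f"binodal coefficient {name!r} must be finite, got {v}")

    def as_array(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c, self.d], dtype=float)


#: Fitted constants for the ethanol–ammonium-sulfate system at ambient
#: temperature, the working system for grape-pomace polyphenol extraction.
ETHANOL_AMMONIUM_SULFATE = BinodalCoefficients(-0.1408, -2.882, -0.3998, -5.608)


@dataclass(frozen=True)
class PhaseComposition:
    """A point in the phase plane: salt fraction ``w2``, alcohol fraction ``w1``."""

    w2: float
    w1: float

    def __post_init__(self):
        if not (0.0 <= self.w2 and 0.0 <= self.w1):
            raise DomainError(f"mass fractions must be non-negative: w2={self.w2}, w1={self.w1}")
        if self.w1 + self.w2 > 1.0 + 1e-12:
            raise DomainError(
                f"mass fractions exceed unity: w1 + w2 = {self.w1 + self.w2:.6f}"
            )


@dataclass(frozen=True)
class BinodalFitReport:
    coefficients: BinodalCoefficients
    r_squared: float
    aad_percent: float
    residuals: tuple = field(repr=False)  # signed deviations in w1 (fit − data)
    n_points: int = 0
    method: str = "nonlinear"

    def to_dict(self) -> dict:
        c = self.coefficients
        return {
            "a": c.a,
            "b": c.b,
            "c": c.c,
            "d": c.d,
            "r_squared": self.r_squared,
            "aad_percent": self.aad_percent,
            "n_points": self.n_points,
            "method": self.method,
        }


def _basis(w2: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones_like(w2), np.sqrt(w2), w2, w2**2])


def eval_binodal(w2, coeffs: BinodalCoefficients):
    """Alcohol mass fraction on the binodal at salt fraction ``w2``.

    Accepts a scalar or array; ``w2`` must lie in [0, 1].
    """
    w2_arr = np.asarray(w2, dtype=float)
    if np.any(w2_arr < 0.0) or np.any(w2_arr > 1.0):
        raise DomainError("salt mass fraction w2 must lie in [0, 1]")
    exponent = coeffs.a + coeffs.b * np.sqrt(w2_arr) + coeffs.c * w2_arr + coeffs.d * w2_arr**2
    out = np.exp(exponent)
    return float(out) if np.isscalar(w2) or w2_arr.ndim == 0 else out


def _points_to_arrays(points) -> tuple[np.ndarray, np.ndarray]:
    w2 = np.array([p.w2 for p in points], dtype=float)
    w1 = np.array([p.w1 for p in points], dtype=float)
    return w2, w1


def fit_binodal(points, method: str = "nonlinear") -> BinodalFitReport:
    """Fit the four-parameter binodal to node-point data.

    Two fitting spaces are exposed. ``log-linear`` solves the exact linear
    least-squares problem for ln w1 against the basis (1, √w2, w2, w2²);
    ``nonlinear`` (default) refines that solution by nonlinear least
    squares on w1 itself, which matches the R²/AAD conventions that are
    reported on w1.  On noiseless data the two coincide.

    Raises
    ------
    InsufficientDataError
        Fewer than 5 points (the 4-parameter fit would be under-determined
        with no residual degree of freedom).
    DomainError
        Any w1 ≤ 0 (the log transform must exist), or all w2 identical.
    ConvergenceError
        Nonlinear refinement failed; carries the log-linear fit as
        ``fallback``.
    """
    points = list(points)
    if len(points) < 5:
        raise InsufficientDataError(
            f"binodal fit needs at least 5 points, got {len(points)}"
        )
    if method not in ("log-linear", "nonlinear"):
        raise DomainError(f"unknown fitting method {method!r}")
    w2, w1 = _points_to_arrays(points)
    if np.any(w1 <= 0.0):
        raise DomainError("all alcohol fractions w1 must be positive to fit the binodal")
    if np.ptp(w2) == 0.0:
        raise DomainError("salt fractions w2 are all identical; design is singular")

    X = _basis(w2)
    beta_log, *_ = np.linalg.lstsq(X, np.log(w1), rcond=None)

    if method == "log-linear":
        beta = beta_log
    else:
        def resid(beta):
            return np.exp(X @ beta) - w1

        sol = least_squares(resid, beta_log, method="lm", xtol=1e-15, ftol=1e-15)
        if not sol.success or not np.all(np.isfinite(sol.x)):
            raise ConvergenceError(
                f"nonlinear binodal fit did not converge: {sol.message}",
                fallback=_report(beta_log, w2, w1, "log-linear"),
            )
        beta = sol.x

    return _report(beta, w2, w1, method)


def _report(beta: np.ndarray, w2: np.ndarray, w1: np.ndarray, method: str) -> BinodalFitReport:
    coeffs = BinodalCoefficients(*map(float, beta))
    pred = np.exp(_basis(w2) @ beta)
    m = fit_metrics(w1, pred)
    return BinodalFitReport(
        coefficients=coeffs,
        r_squared=m.r_squared if m.r_squared is not None else float("nan"),
        aad_percent=m.aad_percent if m.aad_percent is not None else float("nan"),
        residuals=tuple(np.asarray(pred - w1, dtype=float)),
        n_points=len(w1),
        method=method,
    )


def classify_region(comp: PhaseComposition, coeffs: BinodalCoefficients) -> str:
    """Classify a composition as ``"one-phase"`` or ``"two-phase"``.

    The two-phase region lies above the binodal; a composition exactly on
    the curve is classified two-phase (the curve is the first composition
    at which phase separation is observed in practice).
    """
    boundary = eval_binodal(comp.w2, coeffs)
    return "two-phase" if comp.w1 >= boundary else "one-phase"
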