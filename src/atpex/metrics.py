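"""Goodness-of-fit metrics shared by every fitting stage.

Three statistics summarise agreement between observed and predicted
values throughout the toolkit:

* the coefficient of determination  R² = 1 − SSE/SST,
* the root-mean-square error        RMSE = sqrt(SSE/n)  (no degrees-of-
  freedom correction: n is the full vector length),
* the average absolute relative deviation in percent
  AAD = 100 · mean(|pred − obs| / obs).

R² is undefined when the observations have zero variance and AAD is
undefined when any observation is exactly zero; both cases are flagged by
returning ``None`` for the affected statistic rather than raising, so a
fit report can still carry the remaining metrics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ValidationError

__all__ = ["FitMetrics", "fit_metrics"]


@dataclass(frozen=True)
class FitMetrics:
    """Container for the shared fit statistics.

    ``r_squared`` and ``aad_percent`` are ``None`` when undefined (zero
    observed variance / a zero observation respectively).
    """

    r_squared: float | None
    rmse: float
    aad_percent: float | None
    n: int

    def to_dict(self) -> dict:
        return {
            "r_squared": self.r_squared,
            "rmse": self.rmse,
            "aad_percent": self.aad_percent,
            "n": self.n,
        }


def fit_metrics(observed, predicted) -> FitMetrics:
    """Compute R², RMSE and AAD% for paired observed/predicted vectors.

    Parameters
    ----------
    observed, predicted
        Equal-length one-dimensional sequences of finite reals.

    Returns
    -------
    FitMetrics
        With ``r_squared=None`` if the observed variance is zero and
        ``aad_percent=None`` if any observed value is exactly zero.
    """
    obs = np.asarray(observed, dtype=float).ravel()
    pred = np.asarray(predicted, dtype=float).ravel()
    if obs.size == 0:
        raise ValidationError("fit_metrics requires at least one pair")
    if obs.shape != pred.shape:
        raise ValidationError(
            f"length mismatch: {obs.size} observed vs {pred.size} predicted"
        )
    if not (np.all(np.isfinite(obs)) and np.all(np.isfinite(pred))):
        raise ValidationError("fit_metrics requires finite values")

    resid = pred - obs
    sse = float(np.dot(resid, resid))
    rmse = float(np.sqrt(sse / obs.size))

    sst = float(np.sum((obs - obs.mean()) ** 2))
    r_squared = 1.0 - sse / sst if sst > 0.0 else None

    if np.any(obs == 0.0):
        aad = None
    else:
        # near-denormal observations can push a ratio past the float range;
        # the resulting inf is the honest value of the statistic
        with np.errstate(over="ignore"):
            aad = float(100.0 * np.mean(np.abs(resid) / np.abs(obs)))

    return FitMetrics(r_squared=r_squared, rmse=rmse, aad_percent=aad, n=obs.size)
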