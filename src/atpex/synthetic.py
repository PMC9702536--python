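"""Seeded synthetic-data generators for every pipeline input.

The study's raw measurements (binodal node points, full-factorial
extraction kinetics, phase-concentration pairs) were published only as
figures, so the toolkit is exercised on synthetic data that emulate the
experimental design:

* binodal points scattered around the fitted ethanol–ammonium-sulfate
  curve over the working salt-fraction range;
* a full-factorial kinetics grid — 4 AED levels (41.1, 63.5, 96.1,
  111.2 W/L) × 3 temperatures (20, 30, 40 °C) × a 9-point time grid up to
  60 min — generated by the spherical-diffusion forward model with De
  taken from the quadratic De(AED, T) response surface;
* top/bottom phase-concentration pairs with a prescribed partition
  coefficient and volume ratio.

Noise is multiplicative Gaussian on positive quantities (truncated at
zero): assay error on yields and concentrations is roughly proportional
to the measured value, and an additive model could produce negative
readings.  Every generator is a pure function of (config, truth
parameters); identical seeds give identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .binodal import BinodalCoefficients, eval_binodal
from .diffusion import (
    DeSurfaceCoefficients,
    KineticsCurve,
    ParticleSystem,
    eval_de_surface,
    solve_diffusion,
)
from .exceptions import DomainError
from .partition import PhasePartition

__all__ = ["SynthConfig", "gen_binodal", "gen_kinetics_grid", "gen_partition"]

#: Factorial design of the extraction experiments.
DEFAULT_AED_LEVELS = (41.1, 63.5, 96.1, 111.2)       # W/L
DEFAULT_TEMPERATURES = (20.0, 30.0, 40.0)            # °C
DEFAULT_TIMES_MIN = (2.5, 5.0, 10.0, 15.0, 20.0, 30.0, 40.0, 50.0, 60.0)


@dataclass(frozen=True)
class SynthConfig:
    """Configuration shared by all generators.

    ``noise_rel`` is the relative standard deviation of the
    multiplicative Gaussian noise; ``noise_model="none"`` disables it.
    """

    seed: int = 0
    noise_model: str = "multiplicative-gaussian"
    noise_rel: float = 0.03
    aed_levels: tuple = DEFAULT_AED_LEVELS
    temperatures: tuple = DEFAULT_TEMPERATURES
    times_min: tuple = DEFAULT_TIMES_MIN
    w2_range: tuple = (0.02, 0.35)
    n_binodal: int = 20

    def __post_init__(self):
        if self.noise_model not in ("none", "multiplicative-gaussian"):
            raise DomainError(f"unknown noise model {self.noise_model!r}")
        if self.noise_rel < 0.0:
            raise DomainError("noise_rel must be non-negative")
        if not (self.aed_levels and self.temperatures and self.times_min):
            raise DomainError("factorial grids must be non-empty")
        if self.n_binodal < 2:
            raise DomainError("need at least 2 binodal points")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _perturb(values: np.ndarray, cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    if cfg.noise_model == "none" or cfg.noise_rel == 0.0:
        return values
    eps = rng.normal(0.0, cfg.noise_rel, size=values.shape)
    return np.clip(values * (1.0 + eps), 0.0, None)


def gen_binodal(cfg: SynthConfig, truth: BinodalCoefficients) -> pd.DataFrame:
    """Node points scattered around a known binodal curve.

    Returns a ``(w2, w1)`` DataFrame with ``cfg.n_binodal`` points, w2
    evenly spaced over ``cfg.w2_range``; with noise off the points lie
    exactly on the truth curve.
    """
    lo, hi = cfg.w2_range
    if not (0.0 < lo < hi <= 0.5):
        raise DomainError("w2_range must satisfy 0 < lo < hi <= 0.5")
    rng = cfg.rng()
    w2 = np.linspace(lo, hi, cfg.n_binodal)
    w1 = eval_binodal(w2, truth)
    w1 = _perturb(w1, cfg, rng)
    return pd.DataFrame({"w2": w2, "w1": w1})


def gen_kinetics_grid(
    cfg: SynthConfig,
    system: ParticleSystem,
    surface: DeSurfaceCoefficients,
    n_radial: int = 60,
) -> tuple[pd.DataFrame, dict]:
    """Full-factorial extraction kinetics from the diffusion forward model.

    For each (AED, T) cell the effective diffusivity comes from the
    response surface, a noiseless curve from :func:`solve_diffusion`, and
    the observed yields from the configured noise model.

    Returns
    -------
    (DataFrame, dict)
        A long-format table with columns ``aed_w_per_l, temp_c, time_min,
        yield_mg_per_g`` plus a ``{(aed, temp): KineticsCurve}`` map.
    """
    rng = cfg.rng()
    times_s = np.asarray(cfg.times_min, dtype=float) * 60.0
    rows = []
    curves: dict[tuple, KineticsCurve] = {}
    for aed in cfg.aed_levels:
        for temp in cfg.temperatures:
            de = eval_de_surface(aed, temp, surface)
            if de <= 0.0:
                raise DomainError(
                    f"response surface gives non-positive De at (AED={aed}, T={temp})"
                )
            sol = solve_diffusion(system, de, times_s, n_radial=n_radial)
            y = _perturb(sol.curve.yields, cfg, rng)
            curves[(aed, temp)] = KineticsCurve(
                times=times_s, yields=y, aed=aed, temperature=temp
            )
            for t_min, yi in zip(cfg.times_min, y):
                rows.append((aed, temp, t_min, yi))
    df = pd.DataFrame(
        rows, columns=["aed_w_per_l", "temp_c", "time_min", "yield_mg_per_g"]
    )
    return df, curves


def gen_partition(
    cfg: SynthConfig,
    k_true: float,
    volume_ratio: float,
    c_total: float = 100.0,
    n_samples: int = 1,
) -> list[PhasePartition]:
    """Phase-concentration pairs with a prescribed partition coefficient.

    Before noise, concentrations satisfy C_top/C_bottom = ``k_true``
    exactly with C_bottom = c_total/(1+K); volumes are (``volume_ratio``,
    1) litres.  Noise perturbs the two concentrations independently.
    """
    if k_true <= 0.0 or volume_ratio <= 0.0:
        raise DomainError("k_true and volume_ratio must be positive")
    if c_total <= 0.0:
        raise DomainError("c_total must be positive")
    rng = cfg.rng()
    out = []
    for _ in range(n_samples):
        c_bottom = c_total / (1.0 + k_true)
        c_top = k_true * c_bottom
        c = _perturb(np.array([c_top, c_bottom]), cfg, rng)
        out.append(
            PhasePartition(
                c_top=float(c[0]),
                c_bottom=float(c[1]),
                v_top=float(volume_ratio),
                v_bottom=1.0,
            )
        )
    return out
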