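"""Partition, recovery, purity and ratio statistics for two-phase extracts.

For a solute distributed between the alcohol-rich top phase (concentration
C_T, volume V_T) and the salt-rich bottom phase (C_B, V_B):

    K     = C_T / C_B                              partition coefficient
    Y_T % = 100 · C_T·V_T / (C_T·V_T + C_B·V_B)    top-phase recovery
    Y_B % = 100 − Y_T                              bottom-phase recovery

Purity of a dried extract is the mass ratio of assayed phenolics to total
extract, in percent.  All statistics are computed at full precision;
rounding to report-style decimals belongs to the presentation layer.
"""

from __future__ import annotations

from dataclasses import dataclass

from .exceptions import DomainError

__all__ = [
    "PhasePartition",
    "PurityRecord",
    "partition_coefficient",
    "recoveries",
    "implied_volume_ratio",
    "purity_percent",
    "percent_increase",
    "yield_fraction",
]


@dataclass(frozen=True)
class PhasePartition:
    """Top/bottom concentrations (mg/L) and volumes (L) of one partition."""

    c_top: float
    c_bottom: float
    v_top: float
    v_bottom: float

    def __post_init__(self):
        if self.c_top < 0.0 or self.c_bottom < 0.0:
            raise DomainError("phase concentrations must be non-negative")
        if self.v_top <= 0.0 or self.v_bottom <= 0.0:
            raise DomainError("phase volumes must be strictly positive")

    @property
    def volume_ratio(self) -> float:
        """R = V_top / V_bottom."""
        return self.v_top / self.v_bottom


@dataclass(frozen=True)
class PurityRecord:
    """Assayed phenolic mass and total dried-extract mass, in mg."""

    phenolic_mass: float
    extract_mass: float

    def __post_init__(self):
        if self.extract_mass <= 0.0:
            raise DomainError("extract mass must be positive")
        if not (0.0 <= self.phenolic_mass <= self.extract_mass):
            raise DomainError("phenolic mass must lie in [0, extract mass]")


def partition_coefficient(p: PhasePartition) -> float:
    """K = C_top / C_bottom (dimensionless, ≥ 0).

    Raises DomainError when C_bottom is zero — the solute partitions
    entirely into the top phase and K is unbounded.
    """
    if p.c_bottom == 0.0:
        raise DomainError(
            "partition coefficient is unbounded: bottom-phase concentration is zero"
        )
    return p.c_top / p.c_bottom


def recoveries(p: PhasePartition) -> tuple[float, float]:
    """(Y_top %, Y_bottom %) — mass-weighted phase recoveries.

    Y_bottom is returned as 100 − Y_top so the pair sums to 100 exactly.
    """
    m_top = p.c_top * p.v_top
    m_bottom = p.c_bottom * p.v_bottom
    total = m_top + m_bottom
    if total <= 0.0:
        raise DomainError("total solute mass is zero; recoveries undefined")
    y_top = 100.0 * m_top / total
    return y_top, 100.0 - y_top


def implied_volume_ratio(k: float, y_top_percent: float) -> float:
    """Volume ratio R = V_top/V_bottom consistent with a (K, Y_top) pair.

    From Y_top = 100·K·R/(K·R + 1):  R = [Y/(100−Y)] / K.  Used to check
    the mutual consistency of published partition/recovery pairs when the
    phase volumes themselves are not reported.
    """
    if k <= 0.0:
        raise DomainError("partition coefficient must be positive")
    if not (0.0 < y_top_percent < 100.0):
        raise DomainError("recovery must lie strictly between 0 and 100%")
    return (y_top_percent / (100.0 - y_top_percent)) / k


def purity_percent(rec: PurityRecord) -> float:
    """Extract purity: 100 · phenolic mass / extract mass, in [0, 100]."""
    return 100.0 * rec.phenolic_mass / rec.extract_mass


def percent_increase(new_value: float, reference_value: float) -> float:
    """Relative increase of ``new_value`` over ``reference_value`` in percent."""
    if reference_value <= 0.0:
        raise DomainError("reference value must be positive")
    return 100.0 * (new_value / reference_value - 1.0)


def yield_fraction(extracted: float, raw_content: float) -> float:
    """Extracted amount as a percentage of the raw-material content."""
    if raw_content <= 0.0:
        raise DomainError("raw-material content must be positive")
    if extracted < 0.0:
        raise DomainError("extracted amount must be non-negative")
    return 100.0 * extracted / raw_content
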