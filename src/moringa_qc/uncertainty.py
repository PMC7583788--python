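"""Top-down expanded measurement uncertainty from precision and recovery.

The budget treats run-to-run precision and recovery bias as the dominant
contributions. At each of the two bracketing spike levels

    U_x = √( RSD² + ((100 − R) / d)² )

where RSD is the percent relative standard deviation, R the percent
recovery and d a bias divisor (default √3, the rectangular-distribution
convention for converting a bias bound into a standard uncertainty).
The two level uncertainties combine in quadrature,

    U_c = √( U₃² + U₁₀² )

and the expanded uncertainty is U = K · U_c with coverage factor K = 2
(≈95% confidence).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .errors import ValidationError

#: Default bias divisor: rectangular-distribution convention.
DEFAULT_BIAS_DIVISOR = math.sqrt(3.0)
DEFAULT_COVERAGE_K = 2.0


@dataclass
class UncertaintyBudget:
    compound_id: int
    matrix: str
    u_low: float       # U at the low spike level (%)
    u_high: float      # U at the high spike level (%)
    u_combined: float  # U_c (%)
    coverage_k: float = DEFAULT_COVERAGE_K
    u_expanded: float = float("nan")  # U (%)

    def __post_init__(self) -> None:
        if math.isnan(self.u_expanded):
            self.u_expanded = expanded_uncertainty(self.u_combined, self.coverage_k)


def level_uncertainty(rsd: float, recovery: float, bias_divisor: float = DEFAULT_BIAS_DIVISOR) -> float:
    """Single-level uncertainty U_x; reduces to RSD at 100% recovery."""
    if rsd < 0:
        raise ValidationError(f"RSD must be ≥ 0, got {rsd}")
    if bias_divisor <= 0:
        raise ValidationError(f"bias divisor must be positive, got {bias_divisor}")
    return math.sqrt(rsd**2 + ((100.0 - recovery) / bias_divisor) ** 2)


def combined_uncertainty(u_low: float, u_high: float) -> float:
    """Quadrature combination of the two bracketing-level uncertainties."""
    if u_low < 0 or u_high < 0:
        raise ValidationError("level uncertainties must be ≥ 0")
    return math.hypot(u_low, u_high)


def expanded_uncertainty(u_c: float, k: float = DEFAULT_COVERAGE_K) -> float:
    """Expanded uncertainty U = K · U_c."""
    if u_c < 0:
        raise ValidationError(f"combined uncertainty must be ≥ 0, got {u_c}")
    if k <= 0:
        raise ValidationError(f"coverage factor must be positive, got {k}")
    return u_c * k


def budget(
    compound_id: int,
    matrix: str,
    *,
    rsd_low: float,
    recovery_low: float,
    rsd_high: float,
    recovery_high: float,
    bias_divisor: float = DEFAULT_BIAS_DIVISOR,
    coverage_k: float = DEFAULT_COVERAGE_K,
) -> UncertaintyBudget:
    """Full chain for one compound × matrix from the two bracketing levels."""
    u_low = level_uncertainty(rsd_low, recovery_low, bias_divisor)
    u_high = level_uncertainty(rsd_high, recovery_high, bias_divisor)
    u_c = combined_uncertainty(u_low, u_high)
    return UncertaintyBudget(compound_id, matrix, u_low, u_high, u_c, coverage_k)


def budgets_from_validation(
    frame: pd.DataFrame,
    *,
    low_level: float = 3.0,
    high_level: float = 10.0,
    rsd_column: str = "rsd_inter",
    bias_divisor: float = DEFAULT_BIAS_DIVISOR,
    coverage_k: float = DEFAULT_COVERAGE_K,
) -> pd.DataFrame:
    """Budgets for every compound × matrix in a validation-summary table.

    ``frame`` has the layout of the bundled ``table2_validation`` fixture
    (compound, medium, level, recovery, rsd_intra, rsd_inter); solvent
    rows (no recovery) are skipped. ``rsd_column`` selects which RSD
    feeds the level uncertainties (inter-day by default).
    """
    rows = []
    matrices = frame.loc[frame["recovery"].notna(), "medium"].unique()
    for medium in matrices:
        sub = frame[frame["medium"] == medium]
        for comp in sorted(sub["compound"].unique()):
            lo = sub[(sub["compound"] == comp) & (sub["level"] == low_level)]
            hi = sub[(sub["compound"] == comp) & (sub["level"] == high_level)]
            if lo.empty or hi.empty:
                continue
            b = budget(
                int(comp),
                str(medium),
                rsd_low=float(lo[rsd_column].iloc[0]),
                recovery_low=float(lo["recovery"].iloc[0]),
                rsd_high=float(hi[rsd_column].iloc[0]),
                recovery_high=float(hi["recovery"].iloc[0]),
                bias_divisor=bias_divisor,
                coverage_k=coverage_k,
            )
            rows.append(
                {
                    "compound": b.compound_id,
                    "medium": b.matrix,
                    "u_low": b.u_low,
                    "u_high": b.u_high,
                    "u_combined": b.u_combined,
                    "coverage_k": b.coverage_k,
                    "u_expanded": b.u_expanded,
                }
            )
    return pd.DataFrame(rows)
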