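"""Spike recovery, repeatability and intermediate precision (%RSD).

Recovery of a spiked amount:

    %R = 100 · (C_found − C_original) / C_spiked

Repeatability (intra-day) is the %RSD of replicate found concentrations
within a single day; intermediate precision (inter-day) is the %RSD of
the per-day mean concentrations across consecutive days. Acceptability
follows the EU 2002/657/EC-style limits: intra-day RSD strictly below
10%, inter-day strictly below 20%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, ValidationError


@dataclass(frozen=True)
class PrecisionThresholds:
    intra_max: float = 10.0
    inter_max: float = 20.0

    def __post_init__(self) -> None:
        if self.intra_max <= 0 or self.inter_max <= 0:
            raise ValidationError("precision thresholds must be positive")


@dataclass
class SpikeLevelResult:
    """Recovery and precision for one compound × matrix × spike level."""

    compound_id: int
    matrix: str
    spike_level: float
    c_original: float
    c_spiked: float
    c_found: list[float] = field(default_factory=list)  # per-replicate means kept for audit
    recovery: float = float("nan")
    rsd_intra: float = float("nan")
    rsd_inter: float = float("nan")


def percent_recovery(c_found: float, c_original: float, c_spiked: float) -> float:
    if c_spiked <= 0:
        raise ValidationError(f"spiked amount must be positive, got {c_spiked}")
    if c_found < 0:
        raise ValidationError(f"found concentration must be ≥ 0, got {c_found}")
    return 100.0 * (c_found - c_original) / c_spiked


def rsd(values) -> float:
    """Percent relative standard deviation (sample SD, n−1 denominator)."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise InsufficientDataError(f"RSD needs ≥ 2 values, got {arr.size}")
    mean = arr.mean()
    if mean == 0:
        raise ValidationError("RSD undefined for zero mean")
    return 100.0 * arr.std(ddof=1) / mean


def precision_summary(
    frame: pd.DataFrame,
    *,
    value_col: str = "found",
    day_col: str = "day",
    reference_day: int | None = None,
) -> tuple[float, float | None]:
    """(intra-day RSD, inter-day RSD) from replicate measurements keyed by day.

    Intra-day uses the replicates of ``reference_day`` (default: first day
    present); inter-day is the RSD of per-day means and is ``None`` when
    only one day is available (never silently zero).
    """
    days = sorted(frame[day_col].unique())
    if not days:
        raise InsufficientDataError("no measurements supplied")
    ref = days[0] if reference_day is None else reference_day
    within = frame.loc[frame[day_col] == ref, value_col]
    if len(within) < 2:
        raise InsufficientDataError(f"need ≥ 2 replicates within day {ref}, got {len(within)}")
    rsd_intra = rsd(within)
    if len(days) < 2:
        return rsd_intra, None
    day_means = frame.groupby(day_col)[value_col].mean()
    return rsd_intra, rsd(day_means)


def check_thresholds(result: SpikeLevelResult, thresholds: PrecisionThresholds = PrecisionThresholds()) -> dict:
    """Strict pass/fail flags against the repeatability/reproducibility limits."""
    return {
        "intra_ok": bool(result.rsd_intra < thresholds.intra_max),
        "inter_ok": bool(result.rsd_inter < thresholds.inter_max),
        "intra_max": thresholds.intra_max,
        "inter_max": thresholds.inter_max,
    }


def evaluate_spike_table(
    frame: pd.DataFrame,
    *,
    reference_day: int | None = None,
) -> list[SpikeLevelResult]:
    """Per compound × matrix × spike-level results from a tidy recovery table.

    Required columns: compound, matrix, spike_level, c_original, c_spiked,
    replicate, day, found (found concentration per replicate). Recovery is
    computed from the mean found concentration across all replicates.
    """
    required = {"compound", "matrix", "spike_level", "c_original", "c_spiked", "replicate", "day", "found"}
    missing = required - set(frame.columns)
    if missing:
        raise ValidationError(f"spike table missing column(s): {sorted(missing)}")
    results = []
    for (comp, matrix, level), grp in frame.groupby(["compound", "matrix", "spike_level"], sort=True):
        c_orig = float(grp["c_original"].iloc[0])
        c_spk = float(grp["c_spiked"].iloc[0])
        c_found_mean = float(grp["found"].mean())
        intra, inter = precision_summary(grp, reference_day=reference_day)
        results.append(
            SpikeLevelResult(
                compound_id=int(comp),
                matrix=str(matrix),
                spike_level=float(level),
                c_original=c_orig,
                c_spiked=c_spk,
                c_found=grp["found"].tolist(),
                recovery=percent_recovery(c_found_mean, c_orig, c_spk),
                rsd_intra=intra,
                rsd_inter=float("nan") if inter is None else inter,
            )
        )
    return results


def results_frame(results: list[SpikeLevelResult]) -> pd.DataFrame:
    """Table-2-style block: recovery and RSDs per compound × matrix × level."""
    return pd.DataFrame(
        {
            "compound": [r.compound_id for r in results],
            "matrix": [r.matrix for r in results],
            "spike_level": [r.spike_level for r in results],
            "recovery": [r.recovery for r in results],
            "rsd_intra": [r.rsd_intra for r in results],
            "rsd_inter": [r.rsd_inter for r in results],
        }
    )
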