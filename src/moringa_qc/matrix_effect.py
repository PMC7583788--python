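"""Percent matrix effect from paired calibration slopes, with severity classes.

The matrix effect compares the matrix-matched slope against the solvent
slope for the same compound:

    %ME = 100 · (S_matrix − S_solvent) / S_solvent

A positive value means signal enhancement, a negative one suppression.
Severity uses the conventional bands on |%ME|: mild below 20%, medium
from 20% up to (but excluding) 50%, strong at 50% and above.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .data_model import MATRICES, load_fixture
from .errors import InsufficientDataError, ValidationError

SEVERITY_MILD = "mild"
SEVERITY_MEDIUM = "medium"
SEVERITY_STRONG = "strong"

#: |%ME| band edges; the lower edge of each band is inclusive.
MEDIUM_BOUNDARY = 20.0
STRONG_BOUNDARY = 50.0


@dataclass(frozen=True)
class MatrixEffectRecord:
    compound_id: int
    matrix: str
    s_solvent: float
    s_matrix: float
    percent_me: float
    direction: str  # enhanced / suppressed / none
    severity: str


def percent_me(s_matrix: float, s_solvent: float) -> float:
    """Eq.-style slope-ratio matrix effect in percent."""
    if not (s_solvent > 0):
        raise ValidationError(f"solvent slope must be positive, got {s_solvent}")
    return 100.0 * (s_matrix - s_solvent) / s_solvent


def classify_me(value: float) -> str:
    """Severity class of a %ME value (bands on |%ME|, lower edge inclusive)."""
    if not math.isfinite(value):
        raise ValidationError(f"%ME must be finite, got {value}")
    mag = abs(value)
    if mag < MEDIUM_BOUNDARY:
        return SEVERITY_MILD
    if mag < STRONG_BOUNDARY:
        return SEVERITY_MEDIUM
    return SEVERITY_STRONG


def round_half_away(value: float, ndigits: int = 0) -> float:
    """Round to ``ndigits`` decimals with halves away from zero (44.5 → 45)."""
    scale = 10.0**ndigits
    out = math.floor(abs(value) * scale + 0.5) / scale * (1 if value >= 0 else -1)
    return int(out) if ndigits == 0 else out


def report_rounded(value: float) -> int:
    """Integer %ME for reporting, via the one-decimal intermediate.

    Summary percentages are rounded the way the tabulated values are
    presented: first to the one-decimal working precision, then to the
    integer, halves away from zero at both stages (44.499 → 44.5 → 45).
    """
    return int(round_half_away(round_half_away(value, 1)))


def make_record(compound_id: int, matrix: str, s_matrix: float, s_solvent: float) -> MatrixEffectRecord:
    me = percent_me(s_matrix, s_solvent)
    direction = "enhanced" if me > 0 else ("suppressed" if me < 0 else "none")
    return MatrixEffectRecord(
        compound_id=compound_id,
        matrix=matrix,
        s_solvent=s_solvent,
        s_matrix=s_matrix,
        percent_me=me,
        direction=direction,
        severity=classify_me(me),
    )


def records_from_table1(frame: pd.DataFrame | None = None) -> list[MatrixEffectRecord]:
    """All compound × matrix records from a regression-summary table.

    The table must hold one ``solvent`` row per compound plus one row per
    product matrix (the bundled ``table1_regressions`` fixture layout).
    """
    if frame is None:
        frame = load_fixture("table1_regressions")
    solvent = frame[frame["medium"] == "solvent"].set_index("compound")["slope"]
    records = []
    for row in frame[frame["medium"] != "solvent"].itertuples(index=False):
        records.append(
            make_record(int(row.compound), str(row.medium), float(row.slope), float(solvent[row.compound]))
        )
    return records


def summarize_me(records: list[MatrixEffectRecord]) -> dict:
    """Panel summary: extremes, per-matrix severity counts, sign proportions."""
    if not records:
        raise InsufficientDataError("empty matrix-effect panel")
    lo = min(records, key=lambda r: r.percent_me)
    hi = max(records, key=lambda r: r.percent_me)
    per_matrix: dict[str, dict[str, int]] = {}
    for rec in records:
        counts = per_matrix.setdefault(rec.matrix, {SEVERITY_MILD: 0, SEVERITY_MEDIUM: 0, SEVERITY_STRONG: 0})
        counts[rec.severity] += 1
    n = len(records)
    n_enh = sum(r.direction == "enhanced" for r in records)
    n_sup = sum(r.direction == "suppressed" for r in records)
    return {
        "min": {"percent_me": lo.percent_me, "rounded": report_rounded(lo.percent_me),
                "compound": lo.compound_id, "matrix": lo.matrix},
        "max": {"percent_me": hi.percent_me, "rounded": report_rounded(hi.percent_me),
                "compound": hi.compound_id, "matrix": hi.matrix},
        "per_matrix_severity": per_matrix,
        "fraction_enhanced": n_enh / n,
        "fraction_suppressed": n_sup / n,
        "n_records": n,
        "records": records,
    }


def records_frame(records: list[MatrixEffectRecord]) -> pd.DataFrame:
    frame = pd.DataFrame([r.__dict__ for r in records])
    frame["percent_me_rounded"] = frame["percent_me"].map(report_rounded)
    return frame


def matrices_in(records: list[MatrixEffectRecord]) -> list[str]:
    seen = {r.matrix for r in records}
    return [m for m in MATRICES if m in seen] + sorted(seen - set(MATRICES))
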