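"""Domain types, CSV I/O and bundled fixture tables.

The package works with three kinds of tables:

* tidy replicate tables (one row per injection) feeding calibration and
  precision statistics,
* per-curve regression summaries (slope, intercept, r², LOD, LOQ) for one
  compound in one medium,
* wide sample × compound quantification matrices with detection-status
  coding (0.0 = not detected, 0.1 = detected but below the LOQ).

Concentration units follow the medium: mg L⁻¹ for the pure solvent,
mg kg⁻¹ for every product matrix. The unit is a property of the medium,
never of an individual row, so mixed-unit tables cannot be constructed.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import FixtureLookupError, SchemaError, ValidationError

#: All media in which calibration curves exist. ``solvent`` is the neat
#: standard solution; the rest are product matrices.
MEDIA: tuple[str, ...] = ("solvent", "leaves", "porridge", "pill", "seeds", "teabag")

#: Product matrices only (everything except the solvent).
MATRICES: tuple[str, ...] = MEDIA[1:]

#: Replicate-table column order.
REPLICATE_COLUMNS = ("compound", "medium", "level", "replicate", "day", "response")

#: Below-LOQ sentinel used in quantification tables.
BELOW_LOQ_CODE = 0.1
#: Not-detected sentinel used in quantification tables.
NOT_DETECTED_CODE = 0.0


def unit_for_medium(medium: str) -> str:
    """Concentration unit implied by the medium (mg/L for solvent, mg/kg else)."""
    if medium not in MEDIA:
        raise ValidationError(f"unknown medium {medium!r}; expected one of {MEDIA}")
    return "mg/L" if medium == "solvent" else "mg/kg"


class DetectionStatus(enum.IntEnum):
    """Per-cell detection status, totally ordered by information content."""

    NOT_DETECTED = 0
    BELOW_LOQ = 1
    QUANTIFIED = 2


@dataclass(frozen=True)
class Compound:
    id: int
    name: str = ""
    retention_time_min: float | None = None  # metadata only


@dataclass(frozen=True)
class CompoundPanel:
    """Ordered panel of target compounds with chromatographic metadata."""

    compounds: tuple[Compound, ...]
    detection_wavelength_nm: float = 254.0

    def __post_init__(self) -> None:
        ids = [c.id for c in self.compounds]
        if len(set(ids)) != len(ids):
            raise ValidationError("compound identifiers must be unique")

    @property
    def ids(self) -> list[int]:
        return [c.id for c in self.compounds]


#: The ten-compound panel, in elution order, with retention times in minutes.
DEFAULT_PANEL = CompoundPanel(
    compounds=tuple(
        Compound(id=i, retention_time_min=rt)
        for i, rt in enumerate((1.4, 2.1, 3.8, 4.5, 4.8, 6.5, 7.0, 7.6, 7.8, 8.7), start=1)
    )
)


@dataclass
class ReplicateTable:
    """Tidy table of replicate peak-area responses.

    One row per injection: (compound, medium, level, replicate, day,
    response). ``level`` is the nominal concentration in the unit implied
    by the medium.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in REPLICATE_COLUMNS if c not in self.frame.columns]
        if missing:
            raise SchemaError(f"replicate table missing column(s): {', '.join(missing)}")
        bad_media = set(self.frame["medium"]) - set(MEDIA)
        if bad_media:
            raise ValidationError(f"unknown medium value(s): {sorted(bad_media)}")
        neg = self.frame.index[self.frame["response"] < 0].tolist()
        if neg:
            raise ValidationError(f"negative response in row(s) {neg}")

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ReplicateTable):
            return NotImplemented
        return self.frame.reset_index(drop=True).equals(other.frame.reset_index(drop=True))

    @property
    def units(self) -> pd.Series:
        """Per-row concentration unit, derived from the medium column."""
        return self.frame["medium"].map(unit_for_medium)

    def slice(self, compound: int, medium: str) -> pd.DataFrame:
        sub = self.frame[(self.frame["compound"] == compound) & (self.frame["medium"] == medium)]
        return sub.reset_index(drop=True)


def read_replicate_table(path: str | Path) -> ReplicateTable:
    """Read a tidy replicate CSV, rejecting malformed rows with row numbers."""
    frame = pd.read_csv(path)
    missing = [c for c in REPLICATE_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s): {', '.join(missing)}")
    for col in ("level", "response"):
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = frame.index[coerced.isna() & frame[col].notna()].tolist()
        if bad:
            raise ValidationError(f"{path}: non-numeric {col!r} in row(s) {bad}")
        frame[col] = coerced
    if frame[["level", "response"]].isna().any().any():
        bad = frame.index[frame[["level", "response"]].isna().any(axis=1)].tolist()
        raise ValidationError(f"{path}: missing numeric value(s) in row(s) {bad}")
    frame["compound"] = frame["compound"].astype(int)
    frame[["replicate", "day"]] = frame[["replicate", "day"]].astype(int)
    return ReplicateTable(frame[list(REPLICATE_COLUMNS)])


def write_replicate_table(table: ReplicateTable, path: str | Path) -> None:
    table.frame.to_csv(path, index=False)


@dataclass
class CalibrationCurve:
    """Fitted line ``response = slope · concentration + intercept`` with limits.

    ``s_residual`` is the residual standard deviation of the per-level mean
    responses about the fitted line; LOD/LOQ are in concentration units of
    the medium.
    """

    compound_id: int
    medium: str
    slope: float
    intercept: float
    r_squared: float
    s_residual: float = float("nan")
    n_levels: int = 0
    lod: float = float("nan")
    loq: float = float("nan")

    def __post_init__(self) -> None:
        if np.isfinite(self.r_squared) and not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValidationError(f"r_squared {self.r_squared} outside [0, 1]")

    @property
    def has_limits(self) -> bool:
        return np.isfinite(self.lod) and np.isfinite(self.loq)


class QuantTable:
    """Wide sample × compound concentration matrix with status coding.

    Mirrors the published layout: samples as rows, compounds 1–10 as
    columns, concentrations in mg kg⁻¹ with sentinel codes 0.0 (not
    detected) and 0.1 (detected but below the LOQ).
    """

    def __init__(self, values: pd.DataFrame, labels: pd.DataFrame | None = None):
        if labels is None:
            labels = pd.DataFrame(index=values.index)
        if not values.index.equals(labels.index):
            raise SchemaError("values and labels must share the same sample index")
        if (values.to_numpy(dtype=float) < 0).any():
            raise ValidationError("concentrations must be non-negative")
        self.values = values.astype(float)
        self.labels = labels

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def compounds(self) -> list[int]:
        return list(self.values.columns)

    def status(self) -> pd.DataFrame:
        """Decode each cell's sentinel into a :class:`DetectionStatus`."""
        vals = self.values
        out = pd.DataFrame(DetectionStatus.QUANTIFIED, index=vals.index, columns=vals.columns)
        out = out.mask(vals == BELOW_LOQ_CODE, DetectionStatus.BELOW_LOQ)
        out = out.mask(vals == NOT_DETECTED_CODE, DetectionStatus.NOT_DETECTED)
        return out

    def matrix(self) -> np.ndarray:
        """Numeric matrix with coded cells entered as their printed values."""
        return self.values.to_numpy(dtype=float)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, QuantTable):
            return NotImplemented
        return self.values.equals(other.values) and self.labels.equals(other.labels)


_LABEL_COLUMNS = ("product_type", "region")


def read_quant_table(path: str | Path) -> QuantTable:
    frame = pd.read_csv(path)
    if "sample" not in frame.columns:
        raise SchemaError(f"{path}: missing column(s): sample")
    frame = frame.set_index("sample")
    label_cols = [c for c in _LABEL_COLUMNS if c in frame.columns]
    comp_cols = [c for c in frame.columns if c not in label_cols]
    try:
        compounds = [int(str(c).lstrip("c")) for c in comp_cols]
    except ValueError as exc:
        raise SchemaError(f"{path}: unrecognized compound column among {comp_cols}") from exc
    values = frame[comp_cols].astype(float)
    values.columns = compounds
    return QuantTable(values, frame[label_cols])


def write_quant_table(table: QuantTable, path: str | Path) -> None:
    out = table.labels.copy()
    for comp in table.compounds:
        out[f"c{comp}"] = table.values[comp]
    out.index.name = "sample"
    out.to_csv(path)


_FIXTURES = {
    "table1_regressions": "table1_regressions.csv",
    "table2_validation": "table2_validation.csv",
    "table2_uncertainty": "table2_uncertainty.csv",
    "table3_quant": "table3_quant.csv",
}


def fixture_path(name: str) -> Path:
    if name not in _FIXTURES:
        raise FixtureLookupError(
            f"unknown fixture {name!r}; available: {sorted(_FIXTURES)}"
        )
    return Path(str(resources.files("moringa_qc.fixtures") / _FIXTURES[name]))


def load_fixture(name: str):
    """Load a bundled published table.

    ``table1_regressions`` → DataFrame of per-curve regression summaries;
    ``table2_validation`` → DataFrame of recoveries and intra/inter-day
    %RSD per compound × medium × level (recovery empty for the solvent);
    ``table2_uncertainty`` → DataFrame of published expanded-uncertainty
    percentages (metadata; not reproducible from the printed summaries);
    ``table3_quant`` → :class:`QuantTable` of the 32 products.
    """
    path = fixture_path(name)
    if name == "table3_quant":
        return read_quant_table(path)
    frame = pd.read_csv(path)
    frame["compound"] = frame["compound"].astype(int)
    return frame


def calibration_curves_from_table1(frame: pd.DataFrame | None = None) -> list[CalibrationCurve]:
    """Build :class:`CalibrationCurve` objects from the published regression table."""
    if frame is None:
        frame = load_fixture("table1_regressions")
    return [
        CalibrationCurve(
            compound_id=int(row.compound),
            medium=str(row.medium),
            slope=float(row.slope),
            intercept=float(row.intercept),
            r_squared=float(row.r_squared),
            n_levels=7 if row.medium == "solvent" else 5,
            lod=float(row.lod),
            loq=float(row.loq),
        )
        for row in frame.itertuples(index=False)
    ]
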