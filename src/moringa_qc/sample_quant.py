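"""Quantification of product samples and detection-status summaries.

Concentrations are read back through the matrix-matched calibration line
and coded by the curve's limits: below the LOD the cell is reported as
0.0 (not detected); between LOD and LOQ as 0.1 (detected but not
quantifiable); at or above the LOQ the concentration itself is reported.
Boundary convention is lower-inclusive: c = LOD codes as below-LOQ,
c = LOQ as quantified.
"""

from __future__ import annotations

import pandas as pd

from .calibration import inverse_predict
from .data_model import (
    BELOW_LOQ_CODE,
    NOT_DETECTED_CODE,
    CalibrationCurve,
    DetectionStatus,
    QuantTable,
)
from .errors import InvalidCurveError

__all__ = [
    "DetectionStatus",
    "quantify",
    "encode",
    "sample_summary",
    "compound_summary",
]


def quantify(curve: CalibrationCurve, response: float) -> tuple[float, DetectionStatus]:
    """Inverse-predict a concentration and assign its detection status.

    Returns the *encoded* value (0.0 / 0.1 / concentration) together with
    the status.
    """
    if not curve.has_limits:
        raise InvalidCurveError(
            f"curve for compound {curve.compound_id} in {curve.medium!r} has no LOD/LOQ"
        )
    conc = inverse_predict(curve, response)
    if conc < curve.lod:
        return NOT_DETECTED_CODE, DetectionStatus.NOT_DETECTED
    if conc < curve.loq:
        return BELOW_LOQ_CODE, DetectionStatus.BELOW_LOQ
    return conc, DetectionStatus.QUANTIFIED


def encode(status: DetectionStatus, concentration: float) -> float:
    """Coded cell value for a status/concentration pair."""
    if status == DetectionStatus.NOT_DETECTED:
        return NOT_DETECTED_CODE
    if status == DetectionStatus.BELOW_LOQ:
        return BELOW_LOQ_CODE
    return concentration


def sample_summary(table: QuantTable) -> pd.DataFrame:
    """Per-sample detection counts (detected = below-LOQ or quantified)."""
    status = table.status()
    out = pd.DataFrame(
        {
            "n_detected": (status != DetectionStatus.NOT_DETECTED).sum(axis=1),
            "n_below_loq": (status == DetectionStatus.BELOW_LOQ).sum(axis=1),
            "n_quantified": (status == DetectionStatus.QUANTIFIED).sum(axis=1),
        },
        index=status.index,
    )
    return out


def compound_summary(table: QuantTable) -> pd.DataFrame:
    """Per-compound stats over quantified cells only.

    Below-LOQ cells count as detections but are excluded from min/max
    (0.1 is a code, not a measurement). Ties at the maximum report every
    argmax sample, in table order.
    """
    status = table.status()
    rows = []
    for comp in table.compounds:
        col = table.values[comp]
        quant = col[status[comp] == DetectionStatus.QUANTIFIED]
        detected = int((status[comp] != DetectionStatus.NOT_DETECTED).sum())
        if quant.empty:
            rows.append(
                {
                    "compound": comp,
                    "n_detected": detected,
                    "n_quantified": 0,
                    "max_value": float("nan"),
                    "max_samples": [],
                    "min_value": float("nan"),
                }
            )
            continue
        vmax = quant.max()
        rows.append(
            {
                "compound": comp,
                "n_detected": detected,
                "n_quantified": int(len(quant)),
                "max_value": float(vmax),
                "max_samples": list(quant.index[quant == vmax]),
                "min_value": float(quant.min()),
            }
        )
    return pd.DataFrame(rows).set_index("compound")


def quantify_samples(
    responses: pd.DataFrame,
    curves: dict[tuple[int, str], CalibrationCurve],
    sample_matrix: pd.Series,
    labels: pd.DataFrame | None = None,
) -> QuantTable:
    """Build a coded quantification table from raw sample responses.

    ``responses`` is samples × compounds (peak areas); ``sample_matrix``
    maps each sample to its calibration medium; ``curves`` is keyed by
    (compound, medium).
    """
    values = pd.DataFrame(index=responses.index, columns=responses.columns, dtype=float)
    for sample in responses.index:
        medium = sample_matrix[sample]
        for comp in responses.columns:
            key = (int(comp), str(medium))
            if key not in curves:
                raise InvalidCurveError(f"no calibration curve for compound {comp} in {medium!r}")
            values.loc[sample, comp], _ = quantify(curves[key], float(responses.loc[sample, comp]))
    return QuantTable(values, labels)
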