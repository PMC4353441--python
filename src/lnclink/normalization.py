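"""Log2 transform and per-sample percentile-shift normalization.

Each array (sample column) is normalized to its 75th percentile: after log2
transformation the column's 75th percentile is subtracted, which equals
division by that percentile in linear intensity space.  No per-probe
(baseline) transformation is applied.  Percentiles use the linear
interpolation between order statistics in which percentile q of sorted
x1..xn sits at rank 1+(n-1)q/100 (numpy's default, the "type 7" convention),
so results are reproducible bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import LINEAR, LOG2, ExpressionMatrix, ValidationError


@dataclass
class NormalizationReport:
    """Per-sample record of the shift applied.

    ``shifts`` holds each sample's percentile-th percentile before the shift,
    in log2 units; that value is what was subtracted from the column.
    """

    shifts: pd.Series
    percentile: float
    floor: float | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.shifts.index,
                "percentile_log2": self.shifts.to_numpy(),
                "percentile": self.percentile,
            }
        )


def log2_transform(m: ExpressionMatrix, floor: float = 1.0) -> ExpressionMatrix:
    """Return log2(max(value, floor)) of a linear-scale matrix.

    The floor guards against near-zero intensities; the default of 1.0
    linear maps to 0.0 in log2 space.  Applying the transform to an already
    log2-scaled matrix is an error (double-transform guard).
    """
    if m.scale == LOG2:
        raise ValidationError("matrix is already log2-scaled")
    if not floor > 0:
        raise ValidationError("floor must be > 0")
    values = np.log2(np.maximum(m.values, floor))
    data = pd.DataFrame(values, index=m.data.index, columns=m.data.columns)
    return ExpressionMatrix(data, scale=LOG2)


def percentile_shift_normalize(
    m: ExpressionMatrix, percentile: float = 75.0
) -> tuple[ExpressionMatrix, NormalizationReport]:
    """Subtract each sample column's percentile-th percentile (log2 space).

    Postcondition: every column's percentile-th percentile is 0 to within
    1e-12.  The operation is idempotent and preserves ranks within columns.
    """
    if m.scale != LOG2:
        raise ValidationError("percentile-shift normalization expects a log2-scaled matrix")
    if not 0 < percentile < 100:
        raise ValidationError("percentile must lie in (0, 100)")
    if m.data.shape[0] < 2:
        raise ValidationError("need at least 2 values per sample column to normalize")
    shifts = np.percentile(m.values, percentile, axis=0)  # type-7 linear interpolation
    data = m.data - shifts
    report = NormalizationReport(
        shifts=pd.Series(shifts, index=m.data.columns, name="percentile_log2"),
        percentile=percentile,
    )
    return ExpressionMatrix(data, scale=LOG2), report


def normalize(
    m: ExpressionMatrix, percentile: float = 75.0, floor: float = 1.0
) -> tuple[ExpressionMatrix, NormalizationReport]:
    """Convenience: log2 transform (if needed) then percentile-shift."""
    if m.scale == LINEAR:
        m = log2_transform(m, floor=floor)
        normed, report = percentile_shift_normalize(m, percentile=percentile)
        report.floor = floor
        return normed, report
    return percentile_shift_normalize(m, percentile=percentile)
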