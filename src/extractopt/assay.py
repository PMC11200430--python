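"""Calibration lines of the four antioxidant assays.

The colorimetric assays report absorbance; a linear standard curve
y = slope * x + intercept converts absorbance y into analyte amount x.
TPC uses a gallic-acid standard (Folin-Ciocalteu), TFC a catechin standard
(aluminum chloride), and DPPH/ABTS use ascorbic acid.  Radical-scavenging
activity is reported as percent inhibition of the radical's absorbance
relative to an extract-free control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CalibrationLine",
    "CALIBRATIONS",
    "concentration_from_absorbance",
    "percent_inhibition",
]


@dataclass(frozen=True)
class CalibrationLine:
    assay: str
    slope: float  # absorbance per concentration unit
    intercept: float  # absorbance
    r2: float  # of the standard curve, as reported
    output_unit: str

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValueError("calibration slope must be nonzero")
        if not 0 < self.r2 <= 1:
            raise ValueError("calibration r2 must lie in (0, 1]")


#: Standard-curve regressions of the packaged study.  The ABTS line's printed
#: form dropped the 'x' typographically; it is the slope of the linear term.
CALIBRATIONS: dict[str, CalibrationLine] = {
    "tpc": CalibrationLine("tpc", 0.0526, 0.0020, 0.9856, "mg GAE/g"),
    "tfc": CalibrationLine("tfc", 0.0336, 0.0021, 0.9894, "mg CAE/g"),
    "dpph": CalibrationLine("dpph", 0.0555, 0.0123, 0.9879, "% inhibition"),
    "abts": CalibrationLine("abts", 0.0369, 0.0133, 0.9823, "% inhibition"),
}


def concentration_from_absorbance(line: CalibrationLine, absorbance):
    """Invert the standard curve: x = (y - intercept) / slope.

    Returns ``(concentration, negative_flag)``; a negative concentration
    (absorbance below the blank intercept) is physically impossible and is
    flagged rather than silently clipped.
    """
    y = np.asarray(absorbance, dtype=float)
    x = (y - line.intercept) / line.slope
    flag = x < 0
    if np.isscalar(absorbance):
        return float(x), bool(flag)
    return x, flag


def percent_inhibition(control_absorbance: float, sample_absorbance):
    """Radical scavenging as 100 * (A_control - A_sample) / A_control.

    Values outside [0, 100] (sample more colored than control, or negative
    readings) are clipped for reporting and flagged.
    """
    if control_absorbance <= 0:
        raise ValueError("control absorbance must be positive")
    a = np.asarray(sample_absorbance, dtype=float)
    raw = 100.0 * (control_absorbance - a) / control_absorbance
    flag = (raw < 0) | (raw > 100)
    clipped = np.clip(raw, 0.0, 100.0)
    if np.isscalar(sample_absorbance):
        return float(clipped), bool(flag)
    return clipped, flag
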