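"""Estimated glomerular filtration rate (MDRD) and window aggregation.

The 4-variable MDRD study equation estimates GFR (mL/min/1.73 m^2) from
serum creatinine, age and sex:

    eGFR = k * (Scr_mg/dL)^(-1.154) * age^(-0.203) * 0.742[if female]

Creatinine is accepted in umol/L (the unit clinical laboratories in this
setting report) and converted internally by dividing by 88.4.  The race
term is omitted; the calibration constant ``k`` defaults to 186 (original
MDRD) with 175 (IDMS-traceable) available via the ``constant`` argument,
since laboratory calibration varies between centers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pk_features import InsufficientDataError, WindowSpec

__all__ = ["EgfrValue", "mdrd_egfr", "egfr_period_mean", "UMOL_PER_MG_DL"]

UMOL_PER_MG_DL = 88.4


@dataclass(frozen=True)
class EgfrValue:
    value: float  # mL/min/1.73 m^2
    time_months: float


def mdrd_egfr(
    creatinine_umol_l: float,
    age_years: float,
    sex: str,
    *,
    constant: float = 186.0,
) -> float:
    """4-variable MDRD eGFR in mL/min/1.73 m^2.

    Strictly decreasing in creatinine and age; female predictions are
    exactly 0.742 times the male prediction at equal inputs.
    """
    if creatinine_umol_l <= 0:
        raise ValueError(f"creatinine must be > 0, got {creatinine_umol_l}")
    if age_years <= 0:
        raise ValueError(f"age must be > 0, got {age_years}")
    if sex not in ("male", "female"):
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")
    scr_mg_dl = creatinine_umol_l / UMOL_PER_MG_DL
    egfr = constant * scr_mg_dl ** (-1.154) * age_years ** (-0.203)
    if sex == "female":
        egfr *= 0.742
    return float(egfr)


def egfr_period_mean(egfr_series, window: WindowSpec) -> float:
    """Arithmetic mean of eGFR values with time in ``[start, end]`` (closed)."""
    vals = [e.value for e in egfr_series if window.contains(e.time_months)]
    if not vals:
        raise InsufficientDataError(
            f"no eGFR values in window [{window.start_months:g}, {window.end_months:g}]"
        )
    return float(np.mean(vals))
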