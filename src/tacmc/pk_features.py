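"""Tacrolimus pharmacokinetic-variability features.

Three quantities drive the downstream outcome model:

* **C0/D** — the dose-normalized trough concentration (trough C0 in ng/mL
  divided by total daily dose in mg/day), a surrogate for metabolism
  rate / bioavailability.
* **IPV (CV%)** — intrapatient variability, the coefficient of variation
  of a patient's C0/D values across monitoring visits in a fixed window
  (by default months 6-12 post-transplant), in percent:
  ``CV% = SD(C0/D) / mean(C0/D) * 100``.
* **Metabolizer class** — fast / intermediate / slow, from the C0/D at
  month 3 with cut points 1.05 and 1.55 ng/mL/mg.

The sample (n-1) standard deviation is the default for CV%, the usual
convention for therapeutic-drug-monitoring IPV; population SD is
available via ``ddof=0`` for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .cohort_io import Cohort, PatientRecord

__all__ = [
    "WindowSpec",
    "PKSummary",
    "InsufficientDataError",
    "concentration_dose_ratio",
    "ipv_cv_percent",
    "window_features",
    "metabolizer_class",
    "PKFeatureExtractor",
    "DEFAULT_METABOLIZER_CUTOFFS",
]

DEFAULT_METABOLIZER_CUTOFFS = (1.05, 1.55)


class InsufficientDataError(ValueError):
    """Too few usable observations to compute the requested feature."""


@dataclass(frozen=True)
class WindowSpec:
    """A closed time window ``[start_months, end_months]`` post-transplant."""

    start_months: float
    end_months: float

    def __post_init__(self) -> None:
        if not (0 <= self.start_months < self.end_months):
            raise ValueError(
                f"window requires 0 <= start < end, got [{self.start_months}, {self.end_months}]"
            )

    def contains(self, t: float) -> bool:
        return self.start_months <= t <= self.end_months


@dataclass(frozen=True)
class PKSummary:
    """Per-patient derived pharmacokinetic features over a window."""

    patient_id: str
    c0d_series: tuple[tuple[float, float], ...]  # (time_months, c0d)
    mean_c0d_window: float
    sd_c0d_window: float
    ipv_percent: float
    n_samples: int
    metabolizer: str  # fast | intermediate | slow | undetermined


def concentration_dose_ratio(c0: float, tdd: float) -> float:
    """Dose-normalized trough: ``c0 / tdd`` in ng/mL per mg/day.

    Raises ``ValueError`` for non-positive dose or negative trough.
    """
    if tdd <= 0:
        raise ValueError(f"total daily dose must be > 0, got {tdd}")
    if c0 < 0:
        raise ValueError(f"trough concentration must be >= 0, got {c0}")
    return c0 / tdd


def ipv_cv_percent(c0d_values, *, ddof: int = 1) -> float:
    """Intrapatient variability as the coefficient of variation, in %.

    ``CV% = SD / mean * 100`` over a patient's windowed C0/D values.
    ``ddof=1`` (sample SD) is the default; ``ddof=0`` gives the population
    SD.  Requires at least two positive values.
    """
    x = np.asarray(list(c0d_values), dtype=float)
    if x.size < 2:
        raise InsufficientDataError(f"CV%% needs >= 2 values, got {x.size}")
    if np.any(x <= 0):
        raise ValueError("CV% requires strictly positive C0/D values")
    mean = x.mean()
    return float(x.std(ddof=ddof) / mean * 100.0)


def metabolizer_class(
    c0d_month3: float,
    cutoffs: tuple[float, float] = DEFAULT_METABOLIZER_CUTOFFS,
) -> str:
    """Classify metabolism rate from the month-3 C0/D.

    fast: C0/D < 1.05; intermediate: 1.05 <= C0/D < 1.55; slow: C0/D >= 1.55
    (ng/mL/mg; cut points configurable).  The three classes partition
    [0, inf) with no gaps or overlaps.
    """
    if c0d_month3 < 0:
        raise ValueError(f"C0/D must be >= 0, got {c0d_month3}")
    lo, hi = cutoffs
    if not 0 < lo < hi:
        raise ValueError(f"cutoffs must satisfy 0 < low < high, got {cutoffs}")
    if c0d_month3 < lo:
        return "fast"
    if c0d_month3 < hi:
        return "intermediate"
    return "slow"


def _month3_c0d(patient: PatientRecord, center: float = 3.0, halfwidth: float = 1.0) -> float | None:
    """C0/D of the visit nearest month 3 within +/- 1 month, else None."""
    candidates = [v for v in patient.visits if abs(v.time_months - center) <= halfwidth]
    if not candidates:
        return None
    best = min(candidates, key=lambda v: abs(v.time_months - center))
    return concentration_dose_ratio(best.c0, best.tdd)


def window_features(
    patient: PatientRecord,
    window: WindowSpec = WindowSpec(6.0, 12.0),
    *,
    ddof: int = 1,
    metabolizer_cutoffs: tuple[float, float] = DEFAULT_METABOLIZER_CUTOFFS,
) -> PKSummary:
    """Derive the per-patient PK feature set over ``window``.

    Both window boundaries are included.  Raises
    :class:`InsufficientDataError` with fewer than two usable visits.
    """
    in_window = patient.visits_in_window(window.start_months, window.end_months)
    series = tuple(
        (v.time_months, concentration_dose_ratio(v.c0, v.tdd)) for v in in_window
    )
    if len(series) < 2:
        raise InsufficientDataError(
            f"patient {patient.patient_id}: {len(series)} usable visit(s) in "
            f"[{window.start_months:g}, {window.end_months:g}]; need >= 2"
        )
    values = np.array([c for _, c in series])
    m3 = _month3_c0d(patient)
    return PKSummary(
        patient_id=patient.patient_id,
        c0d_series=series,
        mean_c0d_window=float(values.mean()),
        sd_c0d_window=float(values.std(ddof=ddof)),
        ipv_percent=ipv_cv_percent(values, ddof=ddof),
        n_samples=len(series),
        metabolizer="undetermined" if m3 is None else metabolizer_class(m3, metabolizer_cutoffs),
    )


class PKFeatureExtractor(BaseEstimator, TransformerMixin):
    """Cohort -> per-patient feature table, as a scikit-learn transformer.

    ``transform`` maps a :class:`~tacmc.cohort_io.Cohort` (or list of
    :class:`~tacmc.cohort_io.PatientRecord`) to a DataFrame with one row
    per patient: ``patient_id, sex, age_years, genotype, acute_rejection,
    mean_c0d, sd_c0d, ipv_percent, n_samples, metabolizer, c0d_month3``.
    Stateless (``fit`` is a no-op), so it slots into sklearn pipelines
    ahead of the outcome model.

    Parameters
    ----------
    window : (float, float)
        Feature window in months post-transplant, boundaries included.
    ddof : int
        0 for population SD, 1 (default) for sample SD in CV%.
    metabolizer_cutoffs : (float, float)
        Fast/intermediate and intermediate/slow C0/D cut points.
    on_insufficient : {"skip", "raise"}
        Patients with <2 windowed visits are dropped (default) or raise.
    """

    def __init__(
        self,
        window: tuple[float, float] = (6.0, 12.0),
        ddof: int = 1,
        metabolizer_cutoffs: tuple[float, float] = DEFAULT_METABOLIZER_CUTOFFS,
        on_insufficient: str = "skip",
    ):
        self.window = window
        self.ddof = ddof
        self.metabolizer_cutoffs = metabolizer_cutoffs
        self.on_insufficient = on_insufficient

    def fit(self, X, y=None):
        if self.on_insufficient not in ("skip", "raise"):
            raise ValueError("on_insufficient must be 'skip' or 'raise'")
        self.n_features_in_ = 1
        return self

    def transform(self, X):
        import pandas as pd

        self.fit(X)
        patients = X.patients if isinstance(X, Cohort) else list(X)
        spec = WindowSpec(*self.window)
        rows = []
        skipped = []
        for p in patients:
            try:
                s = window_features(
                    p, spec, ddof=self.ddof, metabolizer_cutoffs=tuple(self.metabolizer_cutoffs)
                )
            except InsufficientDataError:
                if self.on_insufficient == "raise":
                    raise
                skipped.append(p.patient_id)
                continue
            rows.append(
                {
                    "patient_id": p.patient_id,
                    "sex": p.sex,
                    "age_years": p.age_years,
                    "genotype": p.genotype,
                    "acute_rejection": int(p.acute_rejection),
                    "mean_c0d": s.mean_c0d_window,
                    "sd_c0d": s.sd_c0d_window,
                    "ipv_percent": s.ipv_percent,
                    "n_samples": s.n_samples,
                    "metabolizer": s.metabolizer,
                    "c0d_month3": _month3_c0d(p),
                }
            )
        self.skipped_ids_ = skipped
        return pd.DataFrame(rows)
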