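"""The linear eGFR outcome model and auxiliary cohort statistics.

The central object is a five-predictor linear model for the mean eGFR in
months 13-36 after kidney transplantation:

    y = b0 + b1*eGFR6 + b2*IPV% + b3*Sex + b4*C0D + b5*AR

with eGFR6 the month-6 eGFR (mL/min/1.73 m^2), IPV% the intrapatient
variability of C0/D over months 6-12, Sex coded male=1 / female=0, C0D
the mean dose-normalized trough over months 6-12 (ng/mL/mg), and AR an
acute-rejection indicator coded yes=1 / no=0.

The published coefficient set is

    (11.256, 0.764, -0.103, 1.439, 1.676, -10.112)

**Sign conventions matter**: male=1 and AR=1 are fixed; flipping either
coding silently corrupts every downstream simulation.

:class:`EgfrLinearModel` is a scikit-learn estimator: construct it with
``coef="published"`` to evaluate the fixed model, or call ``fit`` on a
feature table to re-estimate the same specification by ordinary least
squares (statsmodels OLS underneath, so 95% CIs, standardized betas and
R^2 come along).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "PREDICTORS",
    "PUBLISHED_COEFFICIENTS",
    "ModelCoefficients",
    "ModelInputs",
    "evaluate_model",
    "EgfrLinearModel",
    "fit_linear_model",
    "compare_groups_mannwhitney",
    "compare_freq_chisq",
    "correlate_c0d",
]

#: Predictor order used everywhere: column names of the design matrix.
PREDICTORS = ("egfr6", "ipv_percent", "sex", "c0d", "ar")


@dataclass(frozen=True)
class ModelCoefficients:
    """Intercept and slopes of the five-predictor eGFR model.

    Units: ``b_egfr6`` per mL/min/1.73 m^2, ``b_ipv`` per IPV percentage
    point, ``b_sex`` for the male indicator, ``b_c0d`` per ng/mL/mg,
    ``b_ar`` for the acute-rejection indicator.
    """

    intercept: float
    b_egfr6: float
    b_ipv: float
    b_sex: float
    b_c0d: float
    b_ar: float
    conf_int: dict = field(default_factory=dict, compare=False)
    standardized_beta: dict = field(default_factory=dict, compare=False)
    r_squared: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        for name, v in self.as_dict().items():
            if not np.isfinite(v):
                raise ValueError(f"coefficient {name} is not finite: {v}")

    def as_dict(self) -> dict[str, float]:
        return {
            "intercept": self.intercept,
            "egfr6": self.b_egfr6,
            "ipv_percent": self.b_ipv,
            "sex": self.b_sex,
            "c0d": self.b_c0d,
            "ar": self.b_ar,
        }

    def as_array(self) -> np.ndarray:
        """(intercept, slopes...) in :data:`PREDICTORS` order."""
        d = self.as_dict()
        return np.array([d["intercept"]] + [d[p] for p in PREDICTORS])


#: The fixed published coefficient set.
PUBLISHED_COEFFICIENTS = ModelCoefficients(
    intercept=11.256,
    b_egfr6=0.764,
    b_ipv=-0.103,
    b_sex=1.439,
    b_c0d=1.676,
    b_ar=-10.112,
    conf_int={
        "intercept": (8.205, 14.306),
        "egfr6": (0.729, 0.799),
        "ipv_percent": (-0.165, -0.040),
        "sex": (0.297, 2.581),
        "c0d": (1.061, 2.290),
        "ar": (-12.664, -7.559),
    },
    standardized_beta={"egfr6": 0.706, "ipv_percent": -0.054, "sex": 0.042, "c0d": 0.096, "ar": -0.133},
    r_squared=0.574,
)


@dataclass(frozen=True)
class ModelInputs:
    """One input vector for the model; indicators must be 0/1."""

    egfr6: float
    ipv_percent: float
    sex: int
    c0d: float
    ar: int

    def __post_init__(self) -> None:
        if self.sex not in (0, 1):
            raise ValueError(f"sex indicator must be 0 (female) or 1 (male), got {self.sex}")
        if self.ar not in (0, 1):
            raise ValueError(f"AR indicator must be 0 (no) or 1 (yes), got {self.ar}")
        if self.egfr6 <= 0:
            raise ValueError(f"egfr6 must be > 0, got {self.egfr6}")
        if self.ipv_percent < 0:
            raise ValueError(f"ipv_percent must be >= 0, got {self.ipv_percent}")
        if self.c0d <= 0:
            raise ValueError(f"c0d must be > 0, got {self.c0d}")


def evaluate_model(coeffs: ModelCoefficients, x) -> float | np.ndarray:
    """Evaluate the linear model at one input vector or a feature table.

    ``x`` may be a :class:`ModelInputs`, a mapping, or a DataFrame with the
    :data:`PREDICTORS` columns.  The map is affine, so evaluating at the
    mean of a set of inputs equals the mean of the evaluations exactly.
    """
    if isinstance(x, ModelInputs):
        vals = {"egfr6": x.egfr6, "ipv_percent": x.ipv_percent, "sex": x.sex, "c0d": x.c0d, "ar": x.ar}
    elif isinstance(x, pd.DataFrame):
        missing = [p for p in PREDICTORS if p not in x.columns]
        if missing:
            raise ValueError(f"feature table is missing column(s): {missing}")
        vals = {p: x[p].to_numpy(dtype=float) for p in PREDICTORS}
    else:
        vals = {p: x[p] for p in PREDICTORS}
    y = (
        coeffs.intercept
        + coeffs.b_egfr6 * np.asarray(vals["egfr6"])
        + coeffs.b_ipv * np.asarray(vals["ipv_percent"])
        + coeffs.b_sex * np.asarray(vals["sex"])
        + coeffs.b_c0d * np.asarray(vals["c0d"])
        + coeffs.b_ar * np.asarray(vals["ar"])
    )
    return float(y) if np.ndim(y) == 0 else y


class EgfrLinearModel(BaseEstimator, RegressorMixin):
    """Five-predictor linear eGFR model as a scikit-learn regressor.

    Parameters
    ----------
    coef : "published" or ModelCoefficients or None
        With ``"published"`` (or an explicit coefficient set) the model is
        fixed and ``fit`` only validates the design; ``predict`` works
        without fitting.  With ``None`` (default) ``fit`` estimates the
        coefficients by OLS.
    include_age : bool
        Add ``age_years`` as a covariate when fitting, mirroring the wider
        multivariable analysis; the default five-predictor specification
        excludes it.

    Attributes (after ``fit``)
    --------------------------
    coef_ : ModelCoefficients   estimated (or fixed) coefficients
    results_ : statsmodels RegressionResults (refit mode only)
    """

    def __init__(self, coef=None, include_age: bool = False):
        self.coef = coef
        self.include_age = include_age

    # -- helpers -----------------------------------------------------------
    def _fixed_coefficients(self) -> ModelCoefficients | None:
        if self.coef is None:
            return None
        if isinstance(self.coef, str):
            if self.coef != "published":
                raise ValueError(f"coef must be None, 'published' or ModelCoefficients, got {self.coef!r}")
            return PUBLISHED_COEFFICIENTS
        return self.coef

    @staticmethod
    def _design(X: pd.DataFrame, columns) -> pd.DataFrame:
        missing = [c for c in columns if c not in X.columns]
        if missing:
            raise ValueError(f"feature table is missing column(s): {missing}")
        return X[list(columns)].astype(float)

    def fit(self, X: pd.DataFrame, y=None):
        """Estimate by OLS (refit mode) or adopt the fixed coefficients.

        ``X`` is a per-patient feature table with columns
        ``egfr6, ipv_percent, sex, c0d, ar`` (plus ``age_years`` when
        ``include_age``); ``y`` the observed window-mean eGFR.
        """
        fixed = self._fixed_coefficients()
        if fixed is not None:
            self.coef_ = fixed
            self.results_ = None
            self.n_features_in_ = len(PREDICTORS)
            return self
        if y is None:
            raise ValueError("y is required to fit the model")
        cols = list(PREDICTORS) + (["age_years"] if self.include_age else [])
        design = self._design(X, cols)
        yv = np.asarray(y, dtype=float)
        if len(design) < len(cols) + 1:
            raise ValueError(f"need at least {len(cols) + 1} rows, got {len(design)}")
        const_cols = [c for c in cols if design[c].nunique() <= 1]
        if const_cols:
            raise ValueError(f"singular design: constant column(s) {const_cols}")
        exog = sm.add_constant(design, has_constant="add")
        if np.linalg.matrix_rank(exog.to_numpy()) < exog.shape[1]:
            corr = design.corr().abs()
            np.fill_diagonal(corr.values, 0)
            worst = corr.stack().idxmax()
            raise ValueError(f"singular design: collinear columns {worst}")
        res = sm.OLS(yv, exog).fit()
        ci = res.conf_int(alpha=0.05)
        conf = {("intercept" if c == "const" else c): tuple(ci.loc[c]) for c in exog.columns}
        sd_y = yv.std(ddof=1)
        betas = {c: float(res.params[c] * design[c].std(ddof=1) / sd_y) for c in cols}
        self.coef_ = ModelCoefficients(
            intercept=float(res.params["const"]),
            b_egfr6=float(res.params["egfr6"]),
            b_ipv=float(res.params["ipv_percent"]),
            b_sex=float(res.params["sex"]),
            b_c0d=float(res.params["c0d"]),
            b_ar=float(res.params["ar"]),
            conf_int=conf,
            standardized_beta=betas,
            r_squared=float(res.rsquared),
        )
        self.results_ = res
        self.n_features_in_ = len(cols)
        return self

    def predict(self, X) -> np.ndarray:
        """Predict window-mean eGFR for a feature table (or ModelInputs)."""
        if not hasattr(self, "coef_"):
            fixed = self._fixed_coefficients()
            if fixed is None:
                check_is_fitted(self)
            self.coef_ = fixed
        y = evaluate_model(self.coef_, X)
        return np.atleast_1d(np.asarray(y, dtype=float)) if not np.isscalar(y) else np.array([y])


def fit_linear_model(features: pd.DataFrame, y=None, *, include_age: bool = False) -> ModelCoefficients:
    """OLS fit of the five-predictor specification on a feature table.

    ``features`` must contain the :data:`PREDICTORS` columns; the outcome is
    taken from ``y`` or from a ``y`` column of the table.
    """
    if y is None:
        if "y" not in features.columns:
            raise ValueError("outcome must be passed as `y` or as a 'y' column")
        y = features["y"]
    return EgfrLinearModel(include_age=include_age).fit(features, y).coef_


# -- auxiliary cohort statistics ------------------------------------------


def compare_groups_mannwhitney(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U; returns (Z, p) via the normal approximation.

    Uses the tie-corrected normal approximation (group sizes in this
    setting are far beyond the exact-enumeration regime).  The Z sign
    follows the first group: negative when ``a`` tends below ``b``.
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    n1, n2 = a.size, b.size
    mu = n1 * n2 / 2.0
    # tie-corrected variance of U
    combined = np.concatenate([a, b])
    _, counts = np.unique(combined, return_counts=True)
    n = n1 + n2
    tie_term = ((counts**3 - counts).sum()) / (n * (n - 1)) if n > 1 else 0.0
    sigma = np.sqrt(n1 * n2 / 12.0 * ((n + 1) - tie_term))
    z = 0.0 if sigma == 0 else (res.statistic - mu) / sigma
    return float(z), float(res.pvalue)


def compare_freq_chisq(counts) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, without continuity correction."""
    table = np.asarray(counts)
    if table.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {table.shape}")
    if np.any(table < 0):
        raise ValueError("counts must be non-negative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("table has a zero margin")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def correlate_c0d(x, y, *, method: str = "spearman") -> tuple[float, float]:
    """Correlation between month-3 C0/D and months 6-12 mean C0/D.

    Spearman rank correlation by default (the cohort summaries here are
    nonparametric throughout); ``method="pearson"`` is available.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size != y.size:
        raise ValueError(f"paired series differ in length: {x.size} vs {y.size}")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if method == "spearman":
        r, p = stats.spearmanr(x, y)
    elif method == "pearson":
        r, p = stats.pearsonr(x, y)
    else:
        raise ValueError(f"method must be 'spearman' or 'pearson', got {method!r}")
    return float(r), float(p)
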