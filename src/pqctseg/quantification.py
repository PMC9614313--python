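"""Tissue quantification and age-trend regression.

From a segmented cross-section we compute, per tissue, the cross-sectional
area ``CSA = (pixel count) * spacing^2`` in mm² and the average calibrated
density over the tissue's pixels.  Cohort-level age trends are estimated by
ordinary least squares of a tissue property on age, reported with slope,
intercept, R², a two-sided slope p-value, and the coefficient of variation
of the root-mean-squared difference between observed and fitted values:

    CV-RMSD = sqrt(mean((y - yhat)^2)) / mean(y)

Analyses can be stratified by sex; on data with sex-offset means the
stratified fits show lower CV-RMSD than the pooled fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .core_raster import TISSUE_NAMES, LabelMap2D, Raster2D

__all__ = [
    "QuantRecord",
    "RegressionResult",
    "tissue_csa",
    "tissue_density",
    "quantify_subject",
    "cv_rmsd",
    "regress_age",
]


@dataclass
class QuantRecord:
    """Per-subject tissue measurements."""

    subject_id: str
    age: float
    sex: str
    site: int
    csa: dict[int, float]       # tissue code -> mm^2
    density: dict[int, float]   # tissue code -> mean calibrated density

    def to_row(self) -> dict:
        row = {"subject_id": self.subject_id, "age": self.age,
               "sex": self.sex, "site": self.site}
        for code, value in self.csa.items():
            row[f"{TISSUE_NAMES[code]}_csa"] = value
        for code, value in self.density.items():
            row[f"{TISSUE_NAMES[code]}_density"] = value
        return row


@dataclass
class RegressionResult:
    """OLS fit of a tissue property against age."""

    slope: float
    intercept: float
    r_squared: float
    cv_rmsd: float
    p_value: float
    n: int
    stratum: str = "total"
    slope_ci: tuple[float, float] = (float("nan"), float("nan"))


def tissue_csa(labels: LabelMap2D, tissue: int, spacing: float | None = None) -> float:
    """Cross-sectional area of one tissue in mm² (0 if absent)."""
    if tissue not in TISSUE_NAMES:
        raise ValueError(f"unknown tissue code {tissue}")
    spacing = labels.spacing if spacing is None else spacing
    return float((labels.labels == tissue).sum()) * spacing ** 2


def tissue_density(image: Raster2D, labels: LabelMap2D, tissue: int) -> float:
    """Mean calibrated density over one tissue's pixels (NaN if absent)."""
    if tissue not in TISSUE_NAMES:
        raise ValueError(f"unknown tissue code {tissue}")
    if image.shape != labels.shape:
        raise ValueError("image and label grids differ")
    mask = labels.labels == tissue
    if not mask.any():
        return float("nan")
    return float(image.values[mask].mean())


def quantify_subject(image: Raster2D, labels: LabelMap2D, subject_id: str = "",
                     age: float = float("nan"), sex: str = "", site: int = 66
                     ) -> QuantRecord:
    """CSA and mean density for every tissue present in the label map."""
    tissues = sorted(labels.present_tissues() - {0})
    return QuantRecord(
        subject_id=subject_id, age=age, sex=sex, site=site,
        csa={t: tissue_csa(labels, t) for t in tissues},
        density={t: tissue_density(image, labels, t) for t in tissues},
    )


def cv_rmsd(y, yhat) -> float:
    """Root-mean-squared difference between ``y`` and ``yhat`` divided by
    the mean of ``y``.  Undefined (raises) when ``mean(y) == 0``."""
    y = np.asarray(y, dtype=np.float64)
    yhat = np.asarray(yhat, dtype=np.float64)
    if y.shape != yhat.shape:
        raise ValueError("y and yhat must have equal length")
    mu = y.mean()
    if mu == 0:
        raise ValueError("CV-RMSD undefined: mean(y) is zero")
    return float(np.sqrt(np.mean((y - yhat) ** 2)) / mu)


def regress_age(
    records,
    property: str,
    stratum: str = "total",
    correlation: str = "pearson",
) -> RegressionResult:
    """OLS regression of a tissue property on age, optionally sex-stratified.

    ``records`` is a DataFrame (or sequence of :class:`QuantRecord`) with
    ``age``, ``sex`` and the property column.  ``stratum`` is ``'total'``,
    ``'male'`` or ``'female'``.  R² is the squared Pearson correlation by
    default (identical to the OLS R² for a single predictor); set
    ``correlation='spearman'`` for a rank-based R².  The slope p-value comes
    from the t distribution of the OLS slope.
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        df = pd.DataFrame([r.to_row() for r in records])
    if stratum != "total":
        df = df[df["sex"] == stratum]
    df = df[["age", property]].dropna()
    if len(df) < 3:
        raise ValueError(f"need >= 3 records in stratum {stratum!r}, got {len(df)}")
    age = df["age"].to_numpy(dtype=np.float64)
    y = df[property].to_numpy(dtype=np.float64)
    if np.ptp(age) == 0:
        raise ValueError("zero age variance in stratum")
    X = sm.add_constant(age)
    fit = sm.OLS(y, X).fit()
    yhat = fit.fittedvalues
    if correlation == "spearman":
        r2 = float(stats.spearmanr(age, y).statistic ** 2)
    else:
        r2 = float(fit.rsquared)
    ci = fit.conf_int(alpha=0.05)
    return RegressionResult(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        r_squared=r2,
        cv_rmsd=cv_rmsd(y, yhat),
        p_value=float(fit.pvalues[1]),
        n=int(len(df)),
        stratum=stratum,
        slope_ci=(float(ci[1, 0]), float(ci[1, 1])),
    )
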