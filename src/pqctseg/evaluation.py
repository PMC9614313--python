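"""Segmentation scoring and motion-stratified comparison.

Per-tissue overlap metrics between a predicted and a reference label map:
Dice similarity coefficient ``DSC = 2|P∩R| / (|P|+|R|)``, sensitivity
``TPR = |P∩R| / |R|`` and precision ``PR = |P∩R| / |P|``.  Metrics with an
empty denominator are *missing* (NaN), never zero.  Group differences are
tested with two-sided Wilcoxon rank-sum tests, and
:func:`motion_stratified_report` tabulates mean performance in low
(grades 1-3) versus high (grades 4-5) subject-motion strata with relative
differences and p-values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_raster import LabelMap2D

__all__ = [
    "PerformanceRecord",
    "overlap_metrics",
    "wilcoxon_rank_sum",
    "motion_stratified_report",
    "records_to_frame",
]


@dataclass
class PerformanceRecord:
    """Scores of one method on one tissue of one subject."""

    subject_id: str
    tissue: int
    dsc: float
    tpr: float
    pr: float
    motion_grade: int = 1
    method: str = ""


def overlap_metrics(pred: LabelMap2D, ref: LabelMap2D, tissue: int
                    ) -> tuple[float, float, float]:
    """Return ``(DSC, TPR, PR)`` for one tissue code.

    If both masks are empty all three are NaN; an empty reference makes TPR
    NaN and an empty prediction makes PR NaN (missing, not zero).
    """
    if pred.shape != ref.shape:
        raise ValueError(f"grid mismatch: {pred.shape} vs {ref.shape}")
    P = pred.labels == tissue
    R = ref.labels == tissue
    np_, nr = int(P.sum()), int(R.sum())
    inter = int((P & R).sum())
    dsc = 2.0 * inter / (np_ + nr) if (np_ + nr) > 0 else float("nan")
    tpr = inter / nr if nr > 0 else float("nan")
    pr = inter / np_ if np_ > 0 else float("nan")
    return dsc, tpr, pr


def wilcoxon_rank_sum(a, b) -> float:
    """Two-sided Wilcoxon rank-sum p-value between two samples.

    Uses exact null enumeration when the pooled size is at most 20 and the
    data are tie-free, and the normal approximation with tie correction
    otherwise.  Two identical constant samples give p = 1.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size < 3 or b.size < 3:
        raise ValueError("each sample needs at least 3 values")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=False)
    return float(min(res.pvalue, 1.0))


def records_to_frame(records) -> pd.DataFrame:
    """Normalize a sequence of records (dataclasses or dicts) or a DataFrame."""
    if isinstance(records, pd.DataFrame):
        return records
    rows = [r.__dict__ if isinstance(r, PerformanceRecord) else dict(r)
            for r in records]
    return pd.DataFrame(rows)


def motion_stratified_report(
    records,
    metric: str = "dsc",
    low_grades: tuple[int, ...] = (1, 2, 3),
    high_grades: tuple[int, ...] = (4, 5),
) -> pd.DataFrame:
    """Mean metric per motion stratum, relative difference and Wilcoxon p.

    One row per (tissue, method): mean over subjects in the low-motion
    stratum, in the high-motion stratum, the relative difference
    ``(high - low) / low * 100`` in percent, and the two-sided rank-sum
    p-value between the strata.  A row whose stratum is empty (or too small
    to test) is flagged ``complete=False`` with NaN where undefined.
    """
    df = records_to_frame(records)
    rows = []
    for (tissue, method), grp in df.groupby(["tissue", "method"], sort=True):
        low = grp.loc[grp["motion_grade"].isin(low_grades), metric].dropna()
        high = grp.loc[grp["motion_grade"].isin(high_grades), metric].dropna()
        mean_low = float(low.mean()) if len(low) else float("nan")
        mean_high = float(high.mean()) if len(high) else float("nan")
        if len(low) and mean_low != 0 and len(high):
            diff_pct = (mean_high - mean_low) / mean_low * 100.0
        else:
            diff_pct = float("nan")
        if len(low) >= 3 and len(high) >= 3:
            p = wilcoxon_rank_sum(low.to_numpy(), high.to_numpy())
        else:
            p = float("nan")
        rows.append({
            "tissue": tissue, "method": method, "metric": metric,
            "mean_low": mean_low, "mean_high": mean_high,
            "diff_pct": diff_pct, "p_value": p,
            "n_low": int(len(low)), "n_high": int(len(high)),
            "complete": bool(len(low) and len(high)),
        })
    return pd.DataFrame(rows)
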