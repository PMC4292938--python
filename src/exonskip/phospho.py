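"""Antibody-array differential pipeline.

Spot-level processing follows the platform's normalization: per array the
mean blank signal is subtracted from every antibody spot (clipped to a small
positive floor), replicate spots are averaged per antibody, every antibody
value is divided by the array's median over all antibodies, and the result
is log10 transformed.  Downstream: mean-centering to the reference samples,
Welch (unequal-variance) t-tests, joint fold-change / P filtering, and the
naive expected-false-positives FDR estimate ``m * alpha / k``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .signature import mean_center_to_reference as center_to_reference  # shared

__all__ = [
    "process_spots",
    "center_to_reference",
    "WelchResult",
    "welch_test",
    "differential_analysis",
    "filter_differential",
    "FdrEstimate",
    "estimate_fdr",
]


def process_spots(
    spots: pd.DataFrame,
    *,
    floor: float = 1.0,
    intensity: str = "intensity",
    sample: str = "sample_id",
    antibody: str = "antibody_id",
    spot_type: str = "spot_type",
) -> pd.DataFrame:
    """Reduce a spot table to a protein x sample matrix of log10 levels.

    Per array (sample): subtract the mean blank intensity from every
    antibody spot, clip at ``floor`` (> 0), average replicate spots per
    antibody, divide by the median over all antibodies, log10 transform.
    Control spots (anything whose ``spot_type`` is not ``"antibody"``) are
    excluded from the matrix and from the median.
    """
    if floor <= 0:
        raise ValueError("floor must be strictly positive")
    required = {intensity, sample, antibody, spot_type}
    if not required <= set(spots.columns):
        raise ValueError(f"spot table needs columns {sorted(required)}")
    cols = {}
    for sid, sub in spots.groupby(sample, sort=False):
        blanks = sub.loc[sub[spot_type] == "blank", intensity]
        ab = sub[sub[spot_type] == "antibody"]
        if ab.empty:
            raise ValueError(f"array {sid!r} has no antibody spots")
        if blanks.empty:
            raise ValueError(f"array {sid!r} has no blank spots")
        corrected = np.maximum(ab[intensity] - float(blanks.mean()), floor)
        per_ab = corrected.groupby(ab[antibody], sort=False).mean()
        med = float(per_ab.median())
        if med <= 0:
            raise ValueError(f"array {sid!r} has non-positive median signal")
        cols[sid] = np.log10(per_ab / med)
    return pd.DataFrame(cols)


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p_value: float
    degenerate: bool = False


def welch_test(group_a, group_b) -> WelchResult:
    """Two-sample t-test with unequal-variance (Satterthwaite) correction.

    Degenerate inputs (zero variance in both groups) follow the convention
    P = 1 for equal means and P -> 0 (flagged) for unequal means.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("Welch test needs n >= 2 per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return WelchResult(0.0, float(a.size + b.size - 2), 1.0, degenerate=True)
        return WelchResult(
            np.inf if a.mean() > b.mean() else -np.inf,
            float(a.size + b.size - 2),
            0.0,
            degenerate=True,
        )
    sa, sb = va / a.size, vb / b.size
    t = (a.mean() - b.mean()) / np.sqrt(sa + sb)
    df = (sa + sb) ** 2 / (sa**2 / (a.size - 1) + sb**2 / (b.size - 1))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return WelchResult(float(t), float(df), p)


def differential_analysis(
    log10_matrix: pd.DataFrame,
    groups: pd.Series,
    case_label: str,
    reference_label: str,
) -> pd.DataFrame:
    """Per-protein Welch tests of case vs reference on log10 levels.

    Returns a DataFrame indexed by protein with the mean log10 difference,
    the linear fold change (``max(ratio, 1/ratio)`` of the group means of
    the unlogged normalized values), direction, Welch t, df and P.
    """
    groups = pd.Series(groups)
    case_ids = groups.index[groups == case_label]
    ref_ids = groups.index[groups == reference_label]
    if len(case_ids) < 2 or len(ref_ids) < 2:
        raise ValueError("need >= 2 samples per group")
    case_m = log10_matrix[case_ids]
    ref_m = log10_matrix[ref_ids]
    rows = []
    for protein in log10_matrix.index:
        a = case_m.loc[protein].to_numpy(dtype=float)
        b = ref_m.loc[protein].to_numpy(dtype=float)
        res = welch_test(a, b)
        lin_case = float(np.mean(10.0**a))
        lin_ref = float(np.mean(10.0**b))
        ratio = lin_case / lin_ref
        rows.append(
            {
                "protein": protein,
                "mean_diff_log10": float(a.mean() - b.mean()),
                "fold": max(ratio, 1.0 / ratio),
                "direction": "up" if a.mean() >= b.mean() else "down",
                "t": res.t,
                "df": res.df,
                "p_value": res.p_value,
                "degenerate": res.degenerate,
            }
        )
    return pd.DataFrame(rows).set_index("protein")


def filter_differential(
    results: pd.DataFrame, p_threshold: float = 0.02, fold_threshold: float = 1.1
) -> pd.DataFrame:
    """Flag proteins passing both the P and the fold filter.

    A protein passes iff ``p_value < p_threshold`` and ``fold >
    fold_threshold``; direction comes from the sign of the centered
    difference.  Adds boolean columns ``pass_p``, ``pass_fold``,
    ``significant``.
    """
    out = results.copy()
    out["pass_p"] = out["p_value"] < p_threshold
    out["pass_fold"] = out["fold"] > fold_threshold
    out["significant"] = out["pass_p"] & out["pass_fold"]
    return out


@dataclass(frozen=True)
class FdrEstimate:
    """Naive FDR: expected false positives ``m * alpha`` over observed hits ``k``."""

    raw_percent: float
    percent: int  # truncated to whole percent, capped at 100

    def __str__(self) -> str:
        return f"{self.percent}%"


def estimate_fdr(m: int, alpha: float, k: int) -> FdrEstimate:
    """Estimate the false discovery rate among k of m tests significant at alpha.

    ``100 * m * alpha / k`` percent, capped at 100 and reported truncated to
    an integer (the raw value is retained).
    """
    if k < 1:
        raise ValueError("FDR is undefined with zero significant results")
    if m < k:
        raise ValueError("m must be >= k")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    raw = min(100.0 * m * alpha / k, 100.0)
    return FdrEstimate(raw_percent=raw, percent=int(raw))
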