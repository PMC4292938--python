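"""The exon-skipping index and its cohort statistics.

Given probe-level log2 expression for one probeset whose probes interrogate a
target exon and its flanking exons, the per-sample index is

    index(s) = mean(centered target-exon probes) - mean(centered flanking probes)

where "centered" means the per-sample median over *all* probes of the
probeset has been subtracted.  A sample whose target exon is skipped loses
signal on the target-exon probes only, so its index drops below the
reference range; samples are called positive when their index falls strictly
below the lower bound of the t-based 95% confidence interval of the
reference-group mean.

Group comparisons use one-way ANOVA with a Dunnett many-to-one post hoc
whose family-wise adjustment is estimated by seeded Monte Carlo sampling of
the max-|t| null distribution.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ParseError",
    "ProbeAlignmentRecord",
    "parse_probe_alignments",
    "ExonMap",
    "build_exon_map",
    "median_center_sample",
    "compute_delta_index",
    "reference_interval",
    "IndexResult",
    "call_incidence",
    "AnovaResult",
    "one_way_anova",
    "dunnett_posthoc",
]


class ParseError(ValueError):
    """A text record did not match the expected format."""


@dataclass(frozen=True)
class ProbeAlignmentRecord:
    """Genomic alignment of one probe, with its exon designation.

    Coordinates are 1-based inclusive as printed in alignment reports; they
    are treated as trusted labels and never recomputed.
    """

    probe_id: str
    chrom: str
    start: int
    end: int
    exon_label: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.probe_id}: start {self.start} > end {self.end}")

    def to_bed6(self, score: int = 0, strand: str = ".") -> str:
        """BED6 line (0-based half-open) for genome-browser export."""
        return "\t".join(
            [self.chrom, str(self.start - 1), str(self.end), self.probe_id, str(score), strand]
        )


# "PROBE aligned to chrN:START-END (Exon k)"; tolerates a space after the
# colon and en/em dashes in the coordinate span.
_ALIGNMENT_RE = re.compile(
    r"^\s*(?P<probe>\S+)\s+aligned\s+to\s+(?P<chrom>\S+?):\s*"
    r"(?P<start>\d+)\s*[–—-]\s*(?P<end>\d+)\s*"
    r"\(\s*(?P<exon>[^)]+?)\s*\)\s*;?\s*$"
)


def parse_probe_alignments(records) -> list[ProbeAlignmentRecord]:
    """Parse verbatim "probe aligned to chrN:start-end (Exon k)" lines.

    ``records`` may be a single string (split on newlines/semicolons between
    records) or an iterable of lines.  Blank lines are skipped; a malformed
    line raises :class:`ParseError` naming it.
    """
    if isinstance(records, str):
        lines = records.splitlines()
    else:
        lines = list(records)
    out: list[ProbeAlignmentRecord] = []
    for i, line in enumerate(lines, start=1):
        if not str(line).strip():
            continue
        m = _ALIGNMENT_RE.match(str(line))
        if m is None:
            raise ParseError(f"line {i} is not a probe alignment record: {line!r}")
        out.append(
            ProbeAlignmentRecord(
                probe_id=m.group("probe"),
                chrom=m.group("chrom"),
                start=int(m.group("start")),
                end=int(m.group("end")),
                exon_label=m.group("exon"),
            )
        )
    return out


@dataclass(frozen=True)
class ExonMap:
    """Assignment of probes to {target, flanking}; unlisted probes are unassigned.

    Unassigned probes still participate in the per-sample median centering but
    contribute to neither group mean.
    """

    target_exon: str
    target_probes: tuple[str, ...]
    flanking_probes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.target_probes or not self.flanking_probes:
            raise ValueError(
                "index computation needs at least one target and one flanking probe"
            )
        overlap = set(self.target_probes) & set(self.flanking_probes)
        if overlap:
            raise ValueError(f"probes in both groups: {sorted(overlap)}")

    def group_of(self, probe_id: str) -> str:
        if probe_id in self.target_probes:
            return "target"
        if probe_id in self.flanking_probes:
            return "flanking"
        return "unassigned"


def build_exon_map(alignments, target_exon: str) -> ExonMap:
    """Split aligned probes into target-exon vs flanking-exon groups."""
    target, flanking = [], []
    for rec in alignments:
        if rec.exon_label == target_exon:
            target.append(rec.probe_id)
        else:
            flanking.append(rec.probe_id)
    if not target:
        raise ValueError(f"no probe is labeled {target_exon!r}")
    if not flanking:
        raise ValueError(f"all probes are labeled {target_exon!r}; no flanking probes")
    return ExonMap(
        target_exon=target_exon,
        target_probes=tuple(target),
        flanking_probes=tuple(flanking),
    )


def median_center_sample(values) -> np.ndarray:
    """Subtract the median from one sample's probe values (log2 scale)."""
    v = np.asarray(values, dtype=float)
    finite = np.isfinite(v)
    if finite.sum() < 2:
        raise ValueError("median centering needs at least 2 finite values")
    return v - float(np.median(v[finite]))


def compute_delta_index(
    log2_matrix: pd.DataFrame, exon_map: ExonMap, aggregator: str = "mean"
) -> pd.Series:
    """Per-sample exon-skipping index from a probes x samples log2 matrix.

    Every probe in the matrix enters the per-sample median centering; only
    probes named in the exon map enter the two group aggregates.  A sample
    with no finite target or no finite flanking value gets NaN (flagged for
    exclusion downstream).

    ``aggregator`` is ``"mean"`` (default) or ``"median"``.
    """
    if aggregator not in ("mean", "median"):
        raise ValueError(f"unknown aggregator {aggregator!r}")
    agg = np.nanmean if aggregator == "mean" else np.nanmedian
    groups = np.array([exon_map.group_of(p) for p in log2_matrix.index])
    t_mask = groups == "target"
    f_mask = groups == "flanking"
    if not t_mask.any() or not f_mask.any():
        raise ValueError("matrix contains no target or no flanking probes from the map")
    vals = log2_matrix.to_numpy(dtype=float)
    out = np.full(vals.shape[1], np.nan)
    for j in range(vals.shape[1]):
        col = vals[:, j]
        if np.isfinite(col).sum() < 2:
            continue
        centered = col - float(np.nanmedian(col))
        t_vals = centered[t_mask]
        f_vals = centered[f_mask]
        if np.isfinite(t_vals).any() and np.isfinite(f_vals).any():
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                out[j] = float(agg(t_vals)) - float(agg(f_vals))
    return pd.Series(out, index=log2_matrix.columns, name="exon_index")


def reference_interval(reference_values, level: float = 0.95) -> tuple[float, float]:
    """t-based confidence interval for the reference-group mean.

    Returns ``mean +/- t_{(1+level)/2, n-1} * SE``.  A zero-variance input
    yields the degenerate interval (mean, mean) with a warning.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    v = np.asarray(reference_values, dtype=float)
    v = v[np.isfinite(v)]
    n = v.size
    if n < 2:
        raise ValueError("reference interval needs at least 2 values")
    m = float(np.mean(v))
    sd = float(np.std(v, ddof=1))
    if sd == 0:
        warnings.warn("zero-variance reference group: degenerate interval", RuntimeWarning)
        return (m, m)
    se = sd / np.sqrt(n)
    half = float(stats.t.ppf((1 + level) / 2, n - 1)) * se
    return (m - half, m + half)


@dataclass
class IndexResult:
    """Incidence of index suppression in a case group vs a reference interval."""

    reference_interval: tuple[float, float]
    below_lower: pd.Series  # boolean per evaluable case sample
    n_cases: int
    n_below: int
    incidence: float  # proportion in [0, 1]
    incidence_ci: tuple[float, float]  # exact binomial 95% CI
    n_excluded: int = 0  # cases dropped for undefined index

    @property
    def percent(self) -> float:
        return 100.0 * self.incidence


def call_incidence(case_values, interval: tuple[float, float]) -> IndexResult:
    """Classify case samples strictly below the reference lower bound."""
    lower, upper = interval
    if not np.isfinite(lower) or not np.isfinite(upper) or lower > upper:
        raise ValueError(f"invalid reference interval {interval}")
    cases = pd.Series(case_values, dtype=float)
    evaluable = cases[np.isfinite(cases.to_numpy())]
    if evaluable.empty:
        raise ValueError("no evaluable case samples")
    below = evaluable < lower
    k = int(below.sum())
    n = int(below.size)
    ci = stats.binomtest(k, n).proportion_ci(confidence_level=0.95, method="exact")
    return IndexResult(
        reference_interval=(float(lower), float(upper)),
        below_lower=below,
        n_cases=n,
        n_below=k,
        incidence=k / n,
        incidence_ci=(float(ci.low), float(ci.high)),
        n_excluded=int(cases.size - n),
    )


@dataclass(frozen=True)
class AnovaResult:
    f_statistic: float
    p_value: float
    df_between: int
    df_within: int
    defined: bool = True


def one_way_anova(groups) -> AnovaResult:
    """Classical between/within decomposition across >= 2 groups.

    Zero within-group variance with equal means leaves F undefined
    (``defined=False``); with unequal means F is infinite and P zero.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2:
        raise ValueError("one-way ANOVA needs at least 2 groups")
    for g in arrs:
        if g.size < 2:
            raise ValueError("each group needs at least 2 observations")
    n_total = sum(g.size for g in arrs)
    grand = sum(g.sum() for g in arrs) / n_total
    ssb = sum(g.size * (g.mean() - grand) ** 2 for g in arrs)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in arrs)
    df_b = len(arrs) - 1
    df_w = n_total - len(arrs)
    if ssw == 0:
        if ssb == 0:
            return AnovaResult(np.nan, np.nan, df_b, df_w, defined=False)
        return AnovaResult(np.inf, 0.0, df_b, df_w)
    f = (ssb / df_b) / (ssw / df_w)
    p = float(stats.f.sf(f, df_b, df_w))
    return AnovaResult(float(f), p, df_b, df_w)


def dunnett_posthoc(
    groups,
    control_index: int = 0,
    n_mc: int = 100_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Many-to-one comparisons against a control group.

    The family-wise adjusted two-sided P for each comparison is
    ``P(max_j |T_j| >= |t_obs|)`` under the joint null, estimated by Monte
    Carlo: group means are drawn as independent normals scaled by 1/sqrt(n),
    the pooled variance as chi-square(df)/df, reproducing the equicorrelated
    multivariate-t structure of the Dunnett statistics.

    Returns a DataFrame (one row per non-control group) with the mean
    difference, t statistic, adjusted P and its Monte Carlo standard error.
    """
    if n_mc < 1000:
        raise ValueError("n_mc < 1000 gives too little precision; refuse to run")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    k = len(arrs)
    if k < 2:
        raise ValueError("Dunnett post hoc needs at least 2 groups")
    if not 0 <= control_index < k:
        raise ValueError(f"control_index {control_index} out of range")
    ns = np.array([g.size for g in arrs])
    if (ns < 2).any():
        raise ValueError("each group needs at least 2 observations")
    means = np.array([g.mean() for g in arrs])
    df = int(ns.sum() - k)
    ss = sum(((g - g.mean()) ** 2).sum() for g in arrs)
    others = [i for i in range(k) if i != control_index]

    if ss == 0:
        # all groups constant
        degenerate_p = np.where(means[others] == means[control_index], 1.0, 0.0)
        return pd.DataFrame(
            {
                "group": others,
                "estimate": means[others] - means[control_index],
                "t": np.where(degenerate_p == 1.0, 0.0, np.inf),
                "p_adjusted": degenerate_p,
                "mc_se": 0.0,
            }
        )

    s2 = ss / df
    sed = np.sqrt(s2 * (1.0 / ns[others] + 1.0 / ns[control_index]))
    t_obs = (means[others] - means[control_index]) / sed

    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_mc, k)) / np.sqrt(ns)
    s2_null = rng.chisquare(df, n_mc) / df
    t_null = (z[:, others] - z[:, [control_index]]) / np.sqrt(
        s2_null[:, None] * (1.0 / ns[others] + 1.0 / ns[control_index])
    )
    max_abs = np.max(np.abs(t_null), axis=1)

    p_adj = np.array([float(np.mean(max_abs >= abs(t))) for t in t_obs])
    mc_se = np.sqrt(p_adj * (1 - p_adj) / n_mc)
    return pd.DataFrame(
        {
            "group": others,
            "estimate": means[others] - means[control_index],
            "t": t_obs,
            "p_adjusted": p_adj,
            "mc_se": mc_se,
        }
    )
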