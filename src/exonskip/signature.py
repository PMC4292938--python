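"""Cross-cohort signature scoring.

Implements the statistics used to carry a gene-expression signature from a
discovery cohort to validation cohorts:

* mean-centering of log-scale expression to a reference sample set;
* a two-factor mixed-model ANOVA (fixed probeset, fixed diagnostic group,
  their interaction, and a random intercept per sample) fitted by REML;
* per-probeset linear contrasts reported as linear-scale fold differences;
* index-expression correlation tests (Pearson r with its F(1, n-2));
* expansion of a signature through an ortholog map onto a target platform.

The mixed model is restricted to this exact balanced design (every sample
measured on every probeset, each sample in one group).  In the cell-means
parameterization the GLS fixed effects reduce to the per-cell sample means
for *any* value of the variance ratio, so REML estimation reduces to a
one-dimensional profile over lambda = sigma2_sample / sigma2_resid:

    -2 REML(lambda) = (n - p) log( SSR - c * Q ) + (S - G) log(1 + lambda P) + const

with c = lambda / (1 + lambda P), SSR the within-cell residual sum of
squares, Q the sum over samples of the squared residual totals, S samples,
G groups, P probesets.  The profile is optimized over log lambda.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "mean_center_to_reference",
    "MixedModelFit",
    "fit_signature_mixed_model",
    "ContrastResult",
    "per_probeset_contrast",
    "CorrelationResult",
    "index_expression_correlation",
    "SignatureSet",
    "map_signature_across_species",
    "adjust_bh",
]


def mean_center_to_reference(matrix: pd.DataFrame, reference_sample_ids) -> pd.DataFrame:
    """Subtract each feature's reference-group mean (features x samples).

    After centering the reference-group mean of every feature is zero;
    applying the operation twice is a no-op.
    """
    ref = [s for s in reference_sample_ids]
    if not ref:
        raise ValueError("reference sample set is empty")
    missing = [s for s in ref if s not in matrix.columns]
    if missing:
        raise ValueError(f"reference samples absent from matrix: {missing}")
    return matrix.sub(matrix[ref].mean(axis=1), axis=0)


@dataclass
class MixedModelFit:
    """REML fit of the probeset x group model with a random sample intercept."""

    lsmeans: pd.DataFrame  # columns: probeset, group, estimate, se
    sigma2_sample: float
    sigma2_resid: float
    lambda_: float
    group_f: float
    group_df: tuple[int, int]
    group_p: float
    group_sizes: dict
    probesets: list
    groups: list
    converged: bool
    reml_criterion: float

    def lsmean(self, probeset, group) -> float:
        sel = self.lsmeans[
            (self.lsmeans["probeset"] == probeset) & (self.lsmeans["group"] == group)
        ]
        if sel.empty:
            raise KeyError((probeset, group))
        return float(sel["estimate"].iloc[0])

    @property
    def interaction_effects(self) -> pd.DataFrame:
        """Cell means minus additive (probeset + group) structure."""
        wide = self.lsmeans.pivot(index="probeset", columns="group", values="estimate")
        overall = wide.to_numpy().mean()
        row = wide.mean(axis=1)
        col = wide.mean(axis=0)
        return wide.sub(row, axis=0).sub(col, axis=1) + overall


def _reml_profile(lam: float, ssr: float, q: float, n: int, p: int, s: int, g: int, m: int):
    """-2 REML criterion (up to a constant) and sigma2_resid at lambda."""
    c = lam / (1.0 + lam * m)
    rvr = ssr - c * q
    if rvr <= 0:
        return np.inf, np.nan
    sigma2 = rvr / (n - p)
    crit = (n - p) * np.log(sigma2) + (s - g) * np.log1p(lam * m)
    return crit, sigma2


def fit_signature_mixed_model(
    data: pd.DataFrame,
    value: str = "value",
    probeset: str = "probeset",
    group: str = "group",
    sample: str = "sample_id",
) -> MixedModelFit:
    """Fit the two-factor mixed model to long-format data by profiled REML.

    Requires a balanced layout: every sample measured once on every
    probeset, every sample in exactly one group, >= 2 probesets and >= 2
    groups.  Least-squares means and SEs come from the interaction (cell)
    parameterization; the group-effect F uses the between-sample denominator
    degrees of freedom (samples - groups).
    """
    df = data[[value, probeset, group, sample]].copy()
    if df[value].isna().any():
        raise ValueError("missing values are not supported in the mixed model")
    g_of_sample = df.groupby(sample)[group].nunique()
    if (g_of_sample != 1).any():
        raise ValueError("each sample must belong to exactly one group")
    wide = df.pivot_table(index=sample, columns=probeset, values=value, aggfunc="first")
    if wide.isna().any().any() or len(df) != wide.size:
        raise ValueError("design must be balanced: one value per sample x probeset")
    probesets = list(wide.columns)
    P = len(probesets)
    samples = list(wide.index)
    S = len(samples)
    sample_groups = df.drop_duplicates(sample).set_index(sample)[group].loc[samples]
    groups = sorted(sample_groups.unique())
    G = len(groups)
    if P < 2 or G < 2:
        raise ValueError("need >= 2 probesets and >= 2 groups")
    n = S * P
    p_fixed = P * G
    if S <= G:
        raise ValueError("need more samples than groups to estimate the sample variance")

    y = wide.to_numpy(dtype=float)  # S x P
    cell_means = np.empty((G, P))
    n_g = {}
    for gi, grp in enumerate(groups):
        mask = (sample_groups == grp).to_numpy()
        n_g[grp] = int(mask.sum())
        cell_means[gi] = y[mask].mean(axis=0)

    # residuals from the cell means (GLS fixed effects for every lambda)
    fitted = np.vstack([cell_means[groups.index(g)] for g in sample_groups])
    r = y - fitted
    ssr = float(np.sum(r**2))
    q = float(np.sum(r.sum(axis=1) ** 2))

    if ssr <= 0:
        lam_hat, sigma2, crit, converged = 0.0, 0.0, -np.inf, True
    else:
        def objective(log_lam: float) -> float:
            return _reml_profile(np.exp(log_lam), ssr, q, n, p_fixed, S, G, P)[0]

        res = optimize.minimize_scalar(
            objective, bounds=(-20.0, 20.0), method="bounded",
            options={"xatol": 1e-10},
        )
        crit0, _ = _reml_profile(0.0, ssr, q, n, p_fixed, S, G, P)
        if res.fun < crit0:
            lam_hat = float(np.exp(res.x))
            crit = float(res.fun)
        else:  # boundary solution: no between-sample variance
            lam_hat = 0.0
            crit = float(crit0)
        converged = bool(getattr(res, "success", True))
        sigma2 = _reml_profile(lam_hat, ssr, q, n, p_fixed, S, G, P)[1]
    if not converged:
        warnings.warn("REML profile optimization did not converge", RuntimeWarning)

    sigma2_sample = lam_hat * sigma2

    rows = []
    for gi, grp in enumerate(groups):
        se = float(np.sqrt((sigma2 + sigma2_sample) / n_g[grp])) if sigma2 > 0 else 0.0
        for pi, ps in enumerate(probesets):
            rows.append(
                {"probeset": ps, "group": grp, "estimate": cell_means[gi, pi], "se": se}
            )
    lsmeans = pd.DataFrame(rows)

    # group effect: contrast of group marginal means; whole-plot variance
    # (sigma2_resid + P * sigma2_sample) / P per sample
    marg = cell_means.mean(axis=1)
    w = np.array([n_g[grp] for grp in groups], dtype=float)
    var_unit = (sigma2 + P * sigma2_sample) / P  # var of a sample's probeset average
    grand = float(np.sum(w * marg) / w.sum())
    ss_group = float(np.sum(w * (marg - grand) ** 2))
    df_num = G - 1
    df_den = S - G
    if var_unit > 0:
        group_f = (ss_group / df_num) / var_unit
        group_p = float(stats.f.sf(group_f, df_num, df_den))
    else:
        group_f, group_p = np.inf if ss_group > 0 else np.nan, 0.0 if ss_group > 0 else np.nan

    return MixedModelFit(
        lsmeans=lsmeans,
        sigma2_sample=float(sigma2_sample),
        sigma2_resid=float(sigma2),
        lambda_=float(lam_hat),
        group_f=float(group_f),
        group_df=(df_num, df_den),
        group_p=group_p,
        group_sizes=n_g,
        probesets=probesets,
        groups=groups,
        converged=converged,
        reml_criterion=crit,
    )


@dataclass(frozen=True)
class ContrastResult:
    probeset: object
    group_a: object
    group_b: object
    log2_difference: float
    fold: float
    se: float
    t: float
    df: int
    p_value: float
    degenerate: bool = False


def per_probeset_contrast(
    fit: MixedModelFit, probeset, group_a, group_b
) -> ContrastResult:
    """Linear contrast of two groups at one probeset.

    The estimate is the LS-mean difference on the log2 scale; the reported
    fold is ``2**difference``.  The SE uses both variance components (a
    between-group cell difference involves distinct samples) and the
    between-sample degrees of freedom.
    """
    est = fit.lsmean(probeset, group_a) - fit.lsmean(probeset, group_b)
    var = (fit.sigma2_resid + fit.sigma2_sample) * (
        1.0 / fit.group_sizes[group_a] + 1.0 / fit.group_sizes[group_b]
    )
    df = fit.group_df[1]
    if var <= 0:
        return ContrastResult(
            probeset, group_a, group_b, est, float(2.0**est), 0.0,
            np.inf if est != 0 else 0.0, df, 0.0 if est != 0 else 1.0, degenerate=True,
        )
    se = float(np.sqrt(var))
    t = est / se
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return ContrastResult(probeset, group_a, group_b, float(est), float(2.0**est), se, float(t), df, p)


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    f_statistic: float
    df: tuple[int, int]
    p_value: float
    n: int
    degenerate: bool = False


def index_expression_correlation(index_values, expression_values) -> CorrelationResult:
    """Pearson correlation with its regression-ANOVA F test.

    ``F = r**2 (n - 2) / (1 - r**2)`` on (1, n-2) degrees of freedom; a
    perfectly linear relation gives infinite F and zero P.
    """
    x = np.asarray(index_values, dtype=float)
    y = np.asarray(expression_values, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("index and expression must be equal-length vectors")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise ValueError("correlation needs at least 3 paired finite values")
    if np.std(x) == 0 or np.std(y) == 0:
        return CorrelationResult(np.nan, np.nan, (1, n - 2), np.nan, n, degenerate=True)
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) >= 1.0:
        return CorrelationResult(r, np.inf, (1, n - 2), 0.0, n)
    f = r**2 * (n - 2) / (1.0 - r**2)
    p = float(stats.f.sf(f, 1, n - 2))
    return CorrelationResult(r, float(f), (1, n - 2), p, n)


@dataclass
class SignatureSet:
    """A signature as probesets on a platform, with unmapped source genes."""

    probesets: list
    unmapped_genes: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.probesets and not self.unmapped_genes:
            raise ValueError("signature set is empty")

    def __len__(self) -> int:
        return len(self.probesets)


def map_signature_across_species(signature_genes, ortholog_map: pd.DataFrame) -> SignatureSet:
    """Expand source genes to target-platform probesets via an ortholog table.

    ``ortholog_map`` needs columns ``source_gene`` and ``target_probeset``.
    Genes without any mapping are returned in ``unmapped_genes`` (with a
    warning, not an error).
    """
    required = {"source_gene", "target_probeset"}
    if not required <= set(ortholog_map.columns):
        raise ValueError(f"ortholog map needs columns {sorted(required)}")
    by_gene = ortholog_map.groupby("source_gene")["target_probeset"].apply(list)
    probesets: list = []
    unmapped: list = []
    for gene in signature_genes:
        hits = by_gene.get(gene)
        if hits:
            for h in hits:
                if h not in probesets:
                    probesets.append(h)
        else:
            unmapped.append(gene)
    if unmapped:
        warnings.warn(f"{len(unmapped)} signature gene(s) had no ortholog mapping")
    return SignatureSet(probesets=probesets, unmapped_genes=unmapped)


def adjust_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted P-values (optional; raw P is the default filter)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(p_values, dtype=float), method="fdr_bh")[1]
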