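"""Differential abundance via a negative-binomial Wald log2-fold-change test.

Counts are normalized with median-of-ratios size factors, then each feature
(taxon, gene or pathway) is tested between two groups: the log2 ratio of
group means (with a 0.5 pseudocount on the means) is referred to a standard
normal after dividing by a delta-method standard error built from a
method-of-moments negative-binomial dispersion. P-values are
Benjamini-Hochberg adjusted across features. This is a transparent
simplification of the shrinkage-based estimators used by dedicated RNA-seq
packages: no dispersion sharing across features and no outlier filtering.

A Kruskal-Wallis alternative on clr-transformed values is provided for
pathway-style comparisons where a rank test is preferred.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import CountTable, ValidationError

__all__ = [
    "size_factors",
    "wald_lfc_test",
    "clr_transform",
    "volcano_table",
]

_DISPERSION_FLOOR = 1e-8


def size_factors(counts: CountTable | pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, normalized to geometric mean 1.

    Features with any zero are excluded from the geometric-mean reference;
    if none remain the geometric means are computed over positive counts only
    (zero-heavy fallback).
    """
    df = counts.counts if isinstance(counts, CountTable) else counts
    arr = df.to_numpy(float)
    if np.any(arr.sum(axis=0) == 0):
        bad = [df.columns[j] for j in np.flatnonzero(arr.sum(axis=0) == 0)]
        raise ValidationError(f"sample(s) with all-zero counts: {bad}")
    with np.errstate(divide="ignore"):
        log_arr = np.where(arr > 0, np.log(arr), np.nan)
    all_positive = ~np.isnan(log_arr).any(axis=1)
    if all_positive.sum() >= 1:
        ref = np.exp(np.nanmean(log_arr[all_positive], axis=1))
        ratios = arr[all_positive] / ref[:, None]
        factors = np.median(ratios, axis=0)
    else:
        # positive-count geometric means; ratios only where the count is positive
        ref = np.exp(np.nanmean(log_arr, axis=1))
        usable = (arr > 0) & np.isfinite(ref)[:, None]
        factors = np.array(
            [
                np.median(arr[usable[:, j], j] / ref[usable[:, j]])
                for j in range(arr.shape[1])
            ]
        )
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=df.columns, name="size_factor")


def wald_lfc_test(
    counts: CountTable,
    groups: pd.Series | None = None,
    reference_group: str | None = None,
    method: str = "wald",
) -> pd.DataFrame:
    """Per-feature LFC test of (other group) vs ``reference_group``.

    Exactly two groups must be present. LFC = log2((m_T + 0.5)/(m_R + 0.5))
    of size-factor-normalized group means; SE via the delta method with a
    pooled method-of-moments NB dispersion alpha = max((s2-mu)/mu^2, 1e-8).
    Features that are all-zero in both groups are excluded and reported via
    the ``excluded`` attribute of the returned frame.

    ``method="kruskal"`` keeps the same LFC but takes the p-value from a
    Kruskal-Wallis test on the normalized counts instead of the Wald z.
    """
    labels = counts.group_labels() if groups is None else pd.Series(groups, index=counts.samples)
    uniq = sorted(labels.unique())
    if len(uniq) != 2:
        raise ValidationError(f"need exactly 2 groups, got {uniq}")
    if reference_group is None:
        reference_group = uniq[0]
    if reference_group not in uniq:
        raise ValidationError(f"reference group {reference_group!r} not in {uniq}")
    treatment_group = next(g for g in uniq if g != reference_group)

    sf = size_factors(counts)
    norm = counts.counts / sf
    in_ref = (labels == reference_group).to_numpy()
    in_trt = (labels == treatment_group).to_numpy()
    n_ref, n_trt = int(in_ref.sum()), int(in_trt.sum())
    if min(n_ref, n_trt) < 2:
        raise ValidationError("need >= 2 samples per group")

    nz = counts.counts.sum(axis=1) > 0
    excluded = list(counts.counts.index[~nz])
    norm_nz = norm.loc[nz]
    x_ref = norm_nz.loc[:, in_ref].to_numpy()
    x_trt = norm_nz.loc[:, in_trt].to_numpy()

    m_ref = x_ref.mean(axis=1)
    m_trt = x_trt.mean(axis=1)
    lfc = np.log2(m_trt + 0.5) - np.log2(m_ref + 0.5)

    # pooled within-group method-of-moments dispersion
    s2 = ((x_ref.var(axis=1, ddof=1) * (n_ref - 1)) + (x_trt.var(axis=1, ddof=1) * (n_trt - 1))) / (
        n_ref + n_trt - 2
    )
    mu = (m_ref * n_ref + m_trt * n_trt) / (n_ref + n_trt)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(mu > 0, (s2 - mu) / mu**2, 0.0)
    alpha = np.maximum(alpha, _DISPERSION_FLOOR)

    ln2 = np.log(2.0)
    var_mean_ref = (m_ref + alpha * m_ref**2) / n_ref
    var_mean_trt = (m_trt + alpha * m_trt**2) / n_trt
    se = np.sqrt(
        var_mean_ref / ((m_ref + 0.5) ** 2) + var_mean_trt / ((m_trt + 0.5) ** 2)
    ) / ln2
    se = np.maximum(se, 1e-12)
    z = lfc / se
    if method == "wald":
        p = 2.0 * stats.norm.sf(np.abs(z))
    elif method == "kruskal":
        p = np.array(
            [
                stats.kruskal(x_trt[i], x_ref[i]).pvalue
                if np.ptp(np.concatenate([x_trt[i], x_ref[i]])) > 0
                else 1.0
                for i in range(x_ref.shape[0])
            ]
        )
    else:
        raise ValidationError(f"unknown test method {method!r}")
    padj = multipletests(p, method="fdr_bh")[1]

    result = pd.DataFrame(
        {
            "base_mean": norm_nz.mean(axis=1),
            "lfc": lfc,
            "se": se,
            "wald_z": z,
            "pvalue": p,
            "padj": padj,
        },
        index=norm_nz.index,
    )
    result.attrs["excluded"] = excluded
    result.attrs["reference_group"] = reference_group
    result.attrs["treatment_group"] = treatment_group
    return result


def clr_transform(counts: CountTable | pd.DataFrame, pseudocount: float = 0.5) -> pd.DataFrame:
    """Centered log-ratio transform per sample: log(x+pc) minus its mean.

    Columns (samples) each sum to zero; the transform is invariant to
    rescaling a sample's counts by a constant only up to the pseudocount,
    and exactly scale-invariant when applied to fractions.
    """
    df = counts.counts if isinstance(counts, CountTable) else counts
    logged = np.log(df.to_numpy(float) + pseudocount)
    centered = logged - logged.mean(axis=0, keepdims=True)
    return pd.DataFrame(centered, index=df.index, columns=df.columns)


def volcano_table(
    result: pd.DataFrame, lfc_cutoff: float = 1.0, alpha: float = 0.05
) -> pd.DataFrame:
    """Features with |LFC| >= cutoff and BH p < alpha, labeled by direction."""
    if result.empty:
        return result.assign(direction=pd.Series(dtype=str))
    hits = result[(result["lfc"].abs() >= lfc_cutoff) & (result["padj"] < alpha)].copy()
    hits["direction"] = np.where(hits["lfc"] > 0, "increased", "decreased")
    return hits.sort_values("padj")
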