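"""Rarefaction, alpha/beta diversity and nonparametric group comparisons.

Alpha diversity uses Faith's phylogenetic diversity (total branch length of
the minimal rooted subtree spanning the observed taxa) and Pielou's evenness
J = H'/ln(S) with Shannon entropy H' in nats. Beta diversity uses Bray-Curtis
dissimilarity compared between groups with a permutational ANOVA
(pseudo-F over among/within sums of squared distances, p by label
permutation). Group comparisons of scalar indices use Kruskal-Wallis and
Mann-Whitney U tests.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import skbio
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from skbio.diversity.alpha import faith_pd as _skbio_faith_pd

from .containers import CountTable, ValidationError

__all__ = [
    "rarefy",
    "faith_pd",
    "shannon",
    "pielou",
    "alpha_diversity_table",
    "bray_curtis",
    "permanova",
    "kruskal_wallis",
    "mann_whitney",
    "pcoa_coordinates",
]


def rarefy(
    counts: CountTable, depth: int | None = None, seed: int | None = None
) -> CountTable:
    """Subsample each sample to exactly ``depth`` reads without replacement.

    ``depth=None`` uses the minimum sample sum. Samples shallower than the
    depth are dropped with a warning. A single draw is performed (not an
    average over draws).
    """
    totals = counts.counts.sum(axis=0)
    if depth is None:
        depth = int(totals.min())
    if depth <= 0:
        raise ValidationError("rarefaction depth must be positive")
    shallow = list(totals.index[totals < depth])
    if shallow:
        warnings.warn(
            f"dropping {len(shallow)} sample(s) below depth {depth}: {shallow[:5]}",
            stacklevel=2,
        )
    keep = [s for s in counts.samples if s not in set(shallow)]
    rng = np.random.default_rng(seed)
    out = {}
    for s in keep:
        col = counts.counts[s].to_numpy()
        out[s] = col if col.sum() == depth else rng.multivariate_hypergeometric(col, depth)
    df = pd.DataFrame(out, index=counts.counts.index)
    meta = counts.metadata.loc[keep] if counts.metadata is not None else None
    return CountTable(df, meta)


def faith_pd(sample: pd.Series, tree: skbio.TreeNode) -> float:
    """Faith's PD: branch length of the minimal subtree over observed taxa.

    Includes the path to the root of the (rooted) tree. Raises a descriptive
    error listing any observed taxon missing from the tree's tips.
    """
    observed = [t for t, c in sample.items() if c > 0]
    if not observed:
        raise ValidationError("Faith PD undefined for an empty sample")
    tips = {t.name for t in tree.tips()}
    missing = [t for t in observed if t not in tips]
    if missing:
        raise ValidationError(f"taxa absent from tree: {missing[:10]}")
    values = sample.loc[list(sample.index)].to_numpy()
    return float(_skbio_faith_pd(values, taxa=list(sample.index), tree=tree))


def shannon(sample: pd.Series | np.ndarray) -> float:
    """Shannon entropy H' in nats over nonzero counts."""
    x = np.asarray(sample, float)
    x = x[x > 0]
    if x.size == 0:
        raise ValidationError("Shannon entropy undefined for an empty sample")
    p = x / x.sum()
    return float(-(p * np.log(p)).sum())


def pielou(sample: pd.Series | np.ndarray) -> float:
    """Pielou evenness J = H'/ln(S_obs); NaN (with warning) when S_obs = 1."""
    x = np.asarray(sample, float)
    s_obs = int((x > 0).sum())
    if s_obs == 0:
        raise ValidationError("Pielou evenness undefined for an empty sample")
    if s_obs == 1:
        warnings.warn("Pielou evenness undefined for a single-taxon sample", stacklevel=2)
        return float("nan")
    return shannon(x) / np.log(s_obs)


def alpha_diversity_table(counts: CountTable, tree: skbio.TreeNode | None = None) -> pd.DataFrame:
    """Per-sample Faith PD (if a tree is given), Shannon H' and Pielou J."""
    rows = {}
    for s in counts.samples:
        col = counts.counts[s]
        rows[s] = {
            "shannon": shannon(col),
            "pielou": pielou(col),
        }
        if tree is not None:
            rows[s]["faith_pd"] = faith_pd(col, tree)
    return pd.DataFrame(rows).T.rename_axis("sample")


def bray_curtis(counts: CountTable) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarities between samples."""
    arr = counts.values().T.astype(float)
    if np.any(arr.sum(axis=1) == 0):
        empty = [counts.samples[i] for i in np.flatnonzero(arr.sum(axis=1) == 0)]
        raise ValidationError(f"empty sample(s): {empty}")
    d = squareform(pdist(arr, metric="braycurtis"))
    return pd.DataFrame(d, index=counts.samples, columns=counts.samples)


def permanova(
    dist: pd.DataFrame | np.ndarray,
    labels,
    n_perm: int = 999,
    seed: int | None = None,
) -> tuple[float, float]:
    """PERMANOVA pseudo-F and permutation p-value.

    F = (SS_among/(a-1)) / (SS_within/(N-a)) computed from squared
    dissimilarities; the p-value permutes raw labels (no strata):
    p = (1 + #{F_perm >= F_obs}) / (1 + n_perm).
    """
    d = np.asarray(dist, float)
    labels = np.asarray(labels)
    n = d.shape[0]
    if labels.shape[0] != n:
        raise ValidationError("labels length must match distance matrix")
    groups, inverse = np.unique(labels, return_inverse=True)
    a = len(groups)
    if a < 2 or np.min(np.bincount(inverse)) < 2:
        raise ValidationError("need >= 2 groups with >= 2 samples each")
    d2 = d**2
    ss_total = d2[np.triu_indices(n, 1)].sum() / n

    def f_stat(inv: np.ndarray) -> float:
        ss_within = 0.0
        for g in range(a):
            idx = np.flatnonzero(inv == g)
            ss_within += d2[np.ix_(idx, idx)][np.triu_indices(len(idx), 1)].sum() / len(idx)
        ss_among = ss_total - ss_within
        return (ss_among / (a - 1)) / (ss_within / (n - a))

    f_obs = f_stat(inverse)
    rng = np.random.default_rng(seed)
    exceed = sum(f_stat(inverse[rng.permutation(n)]) >= f_obs for _ in range(n_perm))
    return float(f_obs), (1.0 + exceed) / (1.0 + n_perm)


def kruskal_wallis(values, labels) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and p; degenerate data -> (0, 1) + warning."""
    values = np.asarray(values, float)
    labels = np.asarray(labels)
    samples = [values[labels == g] for g in np.unique(labels)]
    if len(samples) < 2:
        raise ValidationError("Kruskal-Wallis needs >= 2 groups")
    if np.ptp(values) == 0:
        warnings.warn("all values identical; Kruskal-Wallis degenerate", stacklevel=2)
        return 0.0, 1.0
    h, p = stats.kruskal(*samples)
    return float(h), float(p)


def mann_whitney(a, b, method: str = "auto") -> tuple[float, float]:
    """Two-sided Mann-Whitney U for group ``a`` (exact for small samples)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("Mann-Whitney needs non-empty groups")
    u, p = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(u), float(p)


def pcoa_coordinates(dist: pd.DataFrame, n_axes: int = 2) -> pd.DataFrame:
    """Principal-coordinate (classical MDS) sample coordinates."""
    res = skbio.stats.ordination.pcoa(
        skbio.DistanceMatrix(np.asarray(dist, float), ids=list(dist.index))
    )
    coords = res.samples.iloc[:, :n_axes]
    coords.index = list(dist.index)
    return coords
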