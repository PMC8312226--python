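"""Compositionally robust co-occurrence network inference (SparCC).

Relative-abundance data are compositional: correlations of raw fractions are
distorted by the unit-sum constraint. SparCC works instead from log-ratio
variances

    t_ij = Var_samples[ log(x_i / x_j) ]
         = omega_i + omega_j - 2 rho_ij sqrt(omega_i omega_j),

where omega_i are the variances of the unobserved log *basis* abundances and
rho_ij their correlations. Under the sparsity approximation (most rho_ij ~ 0)
the row sums of t give a linear system for omega, from which

    rho_ij = (omega_i + omega_j - t_ij) / (2 sqrt(omega_i omega_j)).

The full procedure repeats this over several Dirichlet resamplings of the
count table (to propagate count uncertainty), iteratively excluding the most
strongly correlated pair from the omega system (so the sparsity assumption is
not broken by genuinely coupled taxa), and aggregates by the element-wise
median. Edge significance uses permutation pseudo-p-values obtained by
independently shuffling each taxon's counts across samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from numba import njit
from statsmodels.stats.multitest import multipletests

from .containers import CountTable, ValidationError

__all__ = [
    "CorrelationModel",
    "SignedNetwork",
    "to_fractions",
    "log_ratio_variance",
    "basis_correlation",
    "sparcc",
    "permutation_pvalues",
    "build_network",
]

MIN_TAXA = 4  # below this the omega system is under-determined


@dataclass
class CorrelationModel:
    """Output of SparCC inference, all matrices in one taxon order."""

    taxa: list[str]
    t: np.ndarray
    omega: np.ndarray
    rho: np.ndarray
    pvals: np.ndarray | None = None
    excluded_pairs: list[tuple[str, str]] = field(default_factory=list)


@dataclass
class SignedNetwork:
    """Signed weighted co-occurrence network plus the build thresholds."""

    graph: nx.Graph
    r_min: float
    alpha: float

    @property
    def taxa(self) -> list[str]:
        return list(self.graph.nodes)


def to_fractions(
    counts: CountTable | np.ndarray,
    method: str = "dirichlet_draw",
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Convert counts (taxa x samples) to strictly positive fractions.

    ``dirichlet_draw`` samples each sample's composition from
    Dirichlet(counts + 1); ``pseudocount`` returns the deterministic
    (counts + 0.5) / column-sum fractions.
    """
    arr = counts.values() if isinstance(counts, CountTable) else np.asarray(counts, float)
    if isinstance(counts, CountTable):
        names = counts.samples
    else:
        names = [str(j) for j in range(arr.shape[1])]
    zero = np.flatnonzero(arr.sum(axis=0) == 0)
    if zero.size:
        raise ValidationError(f"all-zero sample column(s): {[names[j] for j in zero]}")
    if method == "pseudocount":
        shifted = arr + 0.5
        return shifted / shifted.sum(axis=0)
    if method == "dirichlet_draw":
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        gamma = rng.standard_gamma(arr + 1.0)
        return gamma / gamma.sum(axis=0)
    raise ValueError(f"unknown fraction method {method!r}")


def log_ratio_variance(fractions: np.ndarray) -> np.ndarray:
    """Pairwise variance of log ratios, t_ij = Var[log(x_i/x_j)].

    Computed through the covariance of log fractions:
    t_ij = v_i + v_j - 2 c_ij, which equals the per-pair definition exactly.
    """
    fractions = np.asarray(fractions, float)
    if fractions.shape[1] < 2:
        raise ValidationError("log-ratio variance needs at least 2 samples")
    if np.any(fractions <= 0):
        raise ValidationError("fractions must be strictly positive")
    logf = np.log(fractions)
    cov = np.cov(logf, ddof=1)
    v = np.diag(cov)
    t = v[:, None] + v[None, :] - 2.0 * cov
    np.fill_diagonal(t, 0.0)
    return np.maximum(t, 0.0)


def basis_correlation(
    t: np.ndarray, excluded_pairs: set[tuple[int, int]] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Solve the sparsity approximation for basis variances and correlations.

    With partner sets S_i (all j != i minus excluded pairs), omega solves

        sum_{j in S_i} t_ij = |S_i| omega_i + sum_{j in S_i} omega_j.

    Negative omega estimates (possible in the linear solve) are clamped to the
    smallest positive estimate with a warning so rho stays defined.
    """
    t = np.asarray(t, float)
    d = t.shape[0]
    if d < MIN_TAXA:
        raise ValidationError(f"basis correlation needs >= {MIN_TAXA} taxa, got {d}")
    active = np.ones((d, d), bool)
    np.fill_diagonal(active, False)
    for i, j in excluded_pairs or ():
        active[i, j] = active[j, i] = False
    m = active.astype(float)
    m[np.diag_indices(d)] = active.sum(axis=1)
    b = (t * active).sum(axis=1)
    return _solve_omega_rho(t, m, b)


def _solve_omega_rho(
    t: np.ndarray, m: np.ndarray, b: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Shared omega solve + rho formula for a prepared linear system."""
    try:
        omega = np.linalg.solve(m, b)
    except np.linalg.LinAlgError:
        omega = np.linalg.lstsq(m, b, rcond=None)[0]
    if np.any(omega <= 0):
        positive = omega[omega > 0]
        floor = positive.min() if positive.size else 1e-6
        warnings.warn(
            f"{int((omega <= 0).sum())} non-positive basis variance(s) clamped",
            RuntimeWarning,
            stacklevel=3,
        )
        omega = np.where(omega <= 0, floor, omega)
    denom = 2.0 * np.sqrt(np.outer(omega, omega))
    rho = (omega[:, None] + omega[None, :] - t) / denom
    rho = np.clip(rho, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    return omega, rho


@njit(cache=True)
def _exclusion_solve(
    t: np.ndarray, n_exclusion_iter: int, exclusion_threshold: float
):  # pragma: no cover - exercised via _one_inference
    """Omega solve with iterative strong-pair exclusion (compiled hot path).

    The omega linear system is updated incrementally as pairs are excluded.
    At each round the single most strongly correlated remaining pair with
    |rho| above the threshold is removed (row-major scan order: ties resolve
    to the lexicographically smallest index pair); a taxon is never left with
    fewer than 2 active partners. Non-positive omega estimates are clamped to
    the smallest positive estimate; the clamp count is returned.
    """
    d = t.shape[0]
    m = np.ones((d, d))
    for i in range(d):
        m[i, i] = d - 1
    b = t.sum(axis=1)
    partners = np.full(d, d - 1)
    mask = np.zeros((d, d), np.bool_)
    for i in range(d):
        for j in range(i + 1):
            mask[i, j] = True
    excluded = np.empty((n_exclusion_iter, 2), np.int64)
    n_excluded = 0
    n_clamped = 0
    omega = np.zeros(d)
    rho = np.zeros((d, d))
    for round_ in range(n_exclusion_iter + 1):
        omega = np.linalg.solve(m, b)
        n_bad = int((omega <= 0).sum())
        if n_bad:
            n_clamped += n_bad
            floor = np.inf
            for i in range(d):
                if 0 < omega[i] < floor:
                    floor = omega[i]
            if not np.isfinite(floor):
                floor = 1e-6
            for i in range(d):
                if omega[i] <= 0:
                    omega[i] = floor
        sq = np.sqrt(omega)
        for i in range(d):
            for j in range(d):
                r = (omega[i] + omega[j] - t[i, j]) / (2.0 * sq[i] * sq[j])
                rho[i, j] = min(1.0, max(-1.0, r))
            rho[i, i] = 1.0
        if round_ == n_exclusion_iter:
            break
        best = exclusion_threshold
        bi = -1
        bj = -1
        for i in range(d):
            if partners[i] <= 2:
                continue
            for j in range(i + 1, d):
                if mask[i, j] or partners[j] <= 2:
                    continue
                a = abs(rho[i, j])
                if a > best:
                    best = a
                    bi, bj = i, j
        if bi < 0:
            break
        excluded[n_excluded, 0] = bi
        excluded[n_excluded, 1] = bj
        n_excluded += 1
        mask[bi, bj] = True
        m[bi, bj] = 0.0
        m[bj, bi] = 0.0
        m[bi, bi] -= 1.0
        m[bj, bj] -= 1.0
        b[bi] -= t[bi, bj]
        b[bj] -= t[bi, bj]
        partners[bi] -= 1
        partners[bj] -= 1
    return omega, rho, excluded[:n_excluded], n_clamped


def _one_inference(
    t: np.ndarray, n_exclusion_iter: int, exclusion_threshold: float
) -> tuple[np.ndarray, np.ndarray, set[tuple[int, int]]]:
    """Basis correlation with iterative strong-pair exclusion on one t matrix."""
    d = t.shape[0]
    if d < MIN_TAXA:
        raise ValidationError(f"basis correlation needs >= {MIN_TAXA} taxa, got {d}")
    omega, rho, excluded, n_clamped = _exclusion_solve(
        np.ascontiguousarray(t, dtype=np.float64), n_exclusion_iter, exclusion_threshold
    )
    if n_clamped:
        warnings.warn(
            f"{n_clamped} non-positive basis variance estimate(s) clamped",
            RuntimeWarning,
            stacklevel=3,
        )
    return omega, rho, {(int(i), int(j)) for i, j in excluded}


def sparcc(
    counts: CountTable | np.ndarray,
    n_inference_iter: int = 20,
    n_exclusion_iter: int = 10,
    exclusion_threshold: float = 0.1,
    seed: int | np.random.Generator | None = None,
) -> CorrelationModel:
    """Full SparCC estimate: Dirichlet resampling + exclusion + median.

    ``exclusion_threshold >= 1`` disables exclusion entirely, making the
    result the element-wise median of plain basis correlations.
    """
    taxa = counts.taxa if isinstance(counts, CountTable) else [
        str(i) for i in range(np.asarray(counts).shape[0])
    ]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ts, omegas, rhos = [], [], []
    excluded_union: set[tuple[int, int]] = set()
    for _ in range(n_inference_iter):
        frac = to_fractions(counts, method="dirichlet_draw", seed=rng)
        t = log_ratio_variance(frac)
        omega, rho, excl = _one_inference(t, n_exclusion_iter, exclusion_threshold)
        ts.append(t)
        omegas.append(omega)
        rhos.append(rho)
        excluded_union |= excl
    rho_med = np.median(rhos, axis=0)
    np.fill_diagonal(rho_med, 1.0)
    return CorrelationModel(
        taxa=taxa,
        t=np.median(ts, axis=0),
        omega=np.median(omegas, axis=0),
        rho=rho_med,
        excluded_pairs=sorted((taxa[i], taxa[j]) for i, j in excluded_union),
    )


def permutation_pvalues(
    counts: CountTable | np.ndarray,
    rho_obs: np.ndarray,
    n_perm: int = 100,
    seed: int | np.random.Generator | None = None,
    **sparcc_kwargs,
) -> np.ndarray:
    """Two-sided permutation pseudo-p-values for SparCC correlations.

    Each permutation shuffles every taxon's counts independently across
    samples (destroying all between-taxon association while keeping marginal
    distributions), reruns ``sparcc`` with the same settings, and counts how
    often |rho_perm| >= |rho_obs| element-wise:

        p = (1 + #exceedances) / (1 + n_perm)  in [1/(n_perm+1), 1].
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    arr = counts.values() if isinstance(counts, CountTable) else np.asarray(counts)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    abs_obs = np.abs(np.asarray(rho_obs))
    exceed = np.zeros_like(abs_obs)
    for _ in range(n_perm):
        perm = rng.permuted(arr, axis=1)
        model = sparcc(perm, seed=rng, **sparcc_kwargs)
        exceed += np.abs(model.rho) >= abs_obs
    pvals = (1.0 + exceed) / (1.0 + n_perm)
    np.fill_diagonal(pvals, 1.0)
    return pvals


def build_network(
    model: CorrelationModel,
    counts: CountTable,
    r_min: float = 0.3,
    alpha: float = 0.05,
    p_adjust: str = "bh",
) -> SignedNetwork:
    """Declare signed edges where |rho| >= r_min and (BH-adjusted) p <= alpha.

    All taxa are retained as nodes (isolated taxa count toward the node total,
    as in the study's topology tables), annotated with mean relative abundance
    and ubiquity. Edge weight is the basis correlation; sign follows weight.
    """
    if not 0.0 <= r_min <= 1.0:
        raise ValidationError("r_min must be in [0, 1]")
    if model.pvals is None:
        raise ValidationError("CorrelationModel has no p-values; run permutation_pvalues")
    if model.taxa != counts.taxa:
        raise ValidationError("model and counts disagree on taxa")
    d = len(model.taxa)
    iu = np.triu_indices(d, k=1)
    raw = model.pvals[iu]
    if p_adjust == "bh":
        padj = multipletests(raw, method="fdr_bh")[1]
    elif p_adjust == "none":
        padj = raw
    else:
        raise ValueError(f"unknown p_adjust {p_adjust!r}")

    mean_rel = counts.mean_relative_abundance()
    presence = (counts.counts > 0).mean(axis=1)
    g = nx.Graph()
    for taxon in model.taxa:
        g.add_node(taxon, abundance=float(mean_rel[taxon]), ubiquity=float(presence[taxon]))
    for (i, j), p_raw, p_corr in zip(zip(*iu), raw, padj):
        w = float(model.rho[i, j])
        if abs(w) >= r_min and p_corr <= alpha:
            g.add_edge(
                model.taxa[i],
                model.taxa[j],
                weight=w,
                absweight=abs(w),
                sign="positive" if w > 0 else "negative",
                p=float(p_raw),
                padj=float(p_corr),
            )
    return SignedNetwork(graph=g, r_min=r_min, alpha=alpha)
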