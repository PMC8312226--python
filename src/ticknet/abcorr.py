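"""Taxon-abundance vs covariate correlation with Dirichlet Monte-Carlo clr.

Mirrors the ALDEx2-style ``aldex.cor`` analysis: technical count uncertainty
is propagated by drawing many Monte-Carlo instances of each sample's
composition from Dirichlet(counts + 0.5), clr-transforming each instance, and
computing per-taxon Spearman correlations against a continuous covariate
(e.g. antibody OD). Reported values are expected values over instances;
Benjamini-Hochberg adjustment is applied within each instance before
averaging the adjusted p-values.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import CountTable, ValidationError

__all__ = ["mc_instances", "correlate"]


def mc_instances(
    counts: CountTable | pd.DataFrame,
    n_instances: int = 128,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Stack of clr-transformed Dirichlet instances, (n_instances, taxa, samples)."""
    if n_instances < 2:
        raise ValidationError("need at least 2 Monte-Carlo instances")
    df = counts.counts if isinstance(counts, CountTable) else counts
    arr = df.to_numpy(float) + 0.5
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = np.empty((n_instances, *arr.shape))
    for k in range(n_instances):
        gamma = rng.standard_gamma(arr)
        frac = gamma / gamma.sum(axis=0)
        logf = np.log(frac)
        out[k] = logf - logf.mean(axis=0, keepdims=True)
    return out


def correlate(
    instances: np.ndarray,
    covariate,
    taxa: list[str] | None = None,
) -> pd.DataFrame:
    """Expected Spearman correlation of each taxon's clr with the covariate.

    Per instance and taxon: Spearman r_s and its p-value against the
    covariate; BH adjustment across taxa within the instance; all three
    quantities averaged across instances.
    """
    instances = np.asarray(instances, float)
    n_inst, n_taxa, n_samples = instances.shape
    cov = np.asarray(covariate, float)
    if cov.shape[0] != n_samples:
        raise ValidationError("covariate length must equal the number of samples")
    if not np.all(np.isfinite(cov)):
        raise ValidationError("covariate contains non-finite values")
    if np.ptp(cov) == 0:
        raise ValidationError("constant covariate: correlation undefined")
    rs = np.empty((n_inst, n_taxa))
    pv = np.empty((n_inst, n_taxa))
    padj = np.empty((n_inst, n_taxa))
    for k in range(n_inst):
        res = stats.spearmanr(instances[k].T, cov)
        # spearmanr on a (samples, taxa+1) stack: last row/col is the covariate
        rs[k] = np.atleast_2d(res.statistic)[-1, :n_taxa]
        pv[k] = np.atleast_2d(res.pvalue)[-1, :n_taxa]
        padj[k] = multipletests(pv[k], method="fdr_bh")[1]
    index = pd.Index(taxa, name="taxon") if taxa is not None else pd.RangeIndex(n_taxa)
    return pd.DataFrame(
        {
            "expected_rs": rs.mean(axis=0),
            "expected_p": pv.mean(axis=0),
            "expected_padj": padj.mean(axis=0),
            "n_instances": n_inst,
        },
        index=index,
    )
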