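"""Copy-number-based functional prediction and qPCR relative quantification.

Gene-family abundances per sample are predicted by weighting each taxon's
abundance by its inverse 16S rRNA copy number and multiplying by a
taxon-by-gene copy-number table (the deterministic multiplication step of
16S-based metagenome prediction; phylogenetic placement and hidden-state
inference happen upstream and are taken as given). Pathway abundances
aggregate member genes (mean by default). qPCR fold changes use the
2^-ddCt method against a housekeeping gene and a control-group baseline.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import CountTable, ValidationError

__all__ = [
    "predict_metagenome",
    "pathway_abundance",
    "ddct_fold_change",
]


def predict_metagenome(
    counts: CountTable | pd.DataFrame,
    gene_content: pd.DataFrame,
    rrna_copies: pd.Series | None = None,
    exclude_taxa: list[str] | None = None,
) -> pd.DataFrame:
    """Predicted gene abundances per sample (genes x samples).

    Each taxon's abundance is divided by its 16S copy number (default 1) and
    multiplied through the taxon x gene copy-number table. ``exclude_taxa``
    drops taxa before prediction (e.g. a placement-quality exclusion list
    from a real prediction pipeline).
    """
    df = counts.counts if isinstance(counts, CountTable) else counts
    if exclude_taxa:
        df = df.drop(index=[t for t in exclude_taxa if t in df.index])
    missing = [t for t in df.index if t not in gene_content.index]
    if missing:
        raise ValidationError(f"taxa missing from gene content: {missing[:10]}")
    if (gene_content.to_numpy() < 0).any():
        raise ValidationError("gene copy numbers must be non-negative")
    if rrna_copies is None:
        rrna = pd.Series(1.0, index=df.index)
    else:
        rrna = rrna_copies.reindex(df.index)
        if rrna.isna().any():
            raise ValidationError(
                f"taxa missing 16S copy number: {list(rrna.index[rrna.isna()])[:10]}"
            )
        if (rrna < 1).any():
            raise ValidationError("16S copy numbers must be >= 1")
    adjusted = df.div(rrna, axis=0)
    content = gene_content.loc[df.index]
    return content.T @ adjusted


def pathway_abundance(
    predicted_genes: pd.DataFrame,
    pathway_map: pd.DataFrame,
    aggregator: str = "mean",
) -> pd.DataFrame:
    """Aggregate predicted gene abundances into pathways (pathways x samples).

    ``pathway_map`` has columns ``gene`` and ``pathway``; a gene may belong to
    several pathways. Aggregator is ``mean`` (default) or ``sum`` over member
    genes.
    """
    if aggregator not in ("mean", "sum"):
        raise ValidationError(f"unknown aggregator {aggregator!r}")
    required = {"gene", "pathway"}
    if not required.issubset(pathway_map.columns):
        raise ValidationError(f"pathway map needs columns {sorted(required)}")
    unknown = [g for g in pathway_map["gene"].unique() if g not in predicted_genes.index]
    if unknown:
        raise ValidationError(f"mapped gene(s) absent from predictions: {unknown[:10]}")
    rows = {}
    for pwy, sub in pathway_map.groupby("pathway"):
        members = sub["gene"].tolist()
        if not members:
            raise ValidationError(f"pathway {pwy!r} has no member genes")
        block = predicted_genes.loc[members]
        rows[pwy] = block.mean(axis=0) if aggregator == "mean" else block.sum(axis=0)
    out = pd.DataFrame(rows).T
    out.index.name = "pathway"
    return out


def ddct_fold_change(
    ct_table: pd.DataFrame,
    target: str,
    housekeeping: str,
    control_group: str,
) -> pd.DataFrame:
    """2^-ddCt per-sample fold changes of ``target`` vs the control group.

    dCt = Ct_target - Ct_housekeeping per sample; ddCt subtracts the control
    group's mean dCt; fold = 2^-ddCt. The geometric mean of control-group
    folds is exactly 1 by construction. Tidy input: columns
    ``sample, group, gene, ct``.
    """
    required = {"sample", "group", "gene", "ct"}
    if not required.issubset(ct_table.columns):
        raise ValidationError(f"Ct table needs columns {sorted(required)}")
    wide = ct_table.pivot_table(index="sample", columns="gene", values="ct")
    groups = ct_table.drop_duplicates("sample").set_index("sample")["group"]
    for gene in (target, housekeeping):
        if gene not in wide.columns:
            raise ValidationError(f"gene {gene!r} absent from Ct table")
        if wide[gene].isna().any():
            bad = list(wide.index[wide[gene].isna()])
            raise ValidationError(f"missing Ct for {gene!r} in sample(s): {bad[:5]}")
    dct = wide[target] - wide[housekeeping]
    in_control = groups.loc[dct.index] == control_group
    if not in_control.any():
        raise ValidationError(f"control group {control_group!r} has no samples")
    ddct = dct - dct[in_control].mean()
    out = pd.DataFrame(
        {
            "group": groups.loc[dct.index],
            "delta_ct": dct,
            "delta_delta_ct": ddct,
            "fold_change": np.power(2.0, -ddct),
        }
    )
    out.index.name = "sample"
    out.attrs["target"] = target
    out.attrs["control_group"] = control_group
    return out
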