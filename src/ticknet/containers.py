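"""Core in-memory containers shared by every pipeline stage.

The universal input is a :class:`CountTable`: a taxa-by-sample matrix of
non-negative integer counts (typically genus-collapsed 16S amplicon counts,
one column per pooled-tick or fecal sample) together with optional sample
metadata carrying group labels, antibody OD readings and collection days.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CountTable", "ValidationError"]


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


@dataclass
class CountTable:
    """Taxa x samples count matrix plus sample metadata.

    Parameters
    ----------
    counts:
        DataFrame with taxa as the index and samples as columns. Entries must
        be non-negative and integer-valued (within a small float tolerance).
    metadata:
        Optional DataFrame indexed by sample ID. A ``group`` column, when
        present, provides the experimental group labels used by downstream
        statistics.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        self.counts = _coerce_counts(self.counts)
        if self.metadata is not None:
            missing = [s for s in self.counts.columns if s not in self.metadata.index]
            if missing:
                raise ValidationError(
                    f"metadata missing {len(missing)} sample(s): {missing[:5]}"
                )

    # -- basic accessors ---------------------------------------------------

    @property
    def taxa(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def values(self) -> np.ndarray:
        return self.counts.to_numpy()

    def group_labels(self) -> pd.Series:
        """Group label per sample, aligned to the column order."""
        if self.metadata is None or "group" not in self.metadata.columns:
            raise ValidationError("count table has no 'group' metadata column")
        return self.metadata.loc[self.samples, "group"]

    # -- derived quantities ------------------------------------------------

    def relative_abundance(self) -> pd.DataFrame:
        """Per-sample relative abundances (columns sum to 1)."""
        sums = self.counts.sum(axis=0)
        zero = sums[sums == 0]
        if len(zero):
            raise ValidationError(f"sample(s) with zero total counts: {list(zero.index)}")
        return self.counts / sums

    def mean_relative_abundance(self) -> pd.Series:
        return self.relative_abundance().mean(axis=1)

    # -- manipulation ------------------------------------------------------

    def select_samples(self, samples: list[str]) -> "CountTable":
        meta = self.metadata.loc[samples] if self.metadata is not None else None
        return CountTable(self.counts[samples].copy(), meta)

    def select_group(self, *groups: str) -> "CountTable":
        labels = self.group_labels()
        keep = [s for s in self.samples if labels[s] in groups]
        if not keep:
            raise ValidationError(f"no samples in group(s) {groups}")
        return self.select_samples(keep)

    def collapse(self, taxon_map: dict[str, str] | pd.Series) -> "CountTable":
        """Sum counts over taxa sharing a label (e.g. ASVs to genus)."""
        mapping = pd.Series(taxon_map)
        missing = [t for t in self.taxa if t not in mapping.index]
        if missing:
            raise ValidationError(f"taxon map missing: {missing[:5]}")
        grouped = self.counts.groupby(mapping.loc[self.taxa].to_numpy()).sum()
        grouped.index.name = self.counts.index.name
        return CountTable(grouped, self.metadata)


def _coerce_counts(df: pd.DataFrame) -> pd.DataFrame:
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate taxon IDs: {dups[:5]}")
    if df.columns.has_duplicates:
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate sample IDs: {dups[:5]}")
    arr = df.to_numpy(dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValidationError("counts contain non-finite values")
    if (arr < 0).any():
        i, j = np.argwhere(arr < 0)[0]
        raise ValidationError(
            f"negative count at taxon {df.index[i]!r}, sample {df.columns[j]!r}"
        )
    rounded = np.rint(arr)
    if np.abs(arr - rounded).max(initial=0.0) > 1e-6:
        i, j = np.argwhere(np.abs(arr - rounded) > 1e-6)[0]
        raise ValidationError(
            f"non-integer count at taxon {df.index[i]!r}, sample {df.columns[j]!r}"
        )
    return pd.DataFrame(rounded.astype(np.int64), index=df.index, columns=df.columns)
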