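"""Synthetic datasets with the statistical structure the pipeline assumes.

The generator emulates a host-immunization tick-feeding study: genus-level
16S count tables for four groups of pooled tick samples (unfed ticks, ticks
fed on mock/PBS-immunized mice, on mice immunized against a keystone taxon,
and on mice immunized against a non-keystone taxon), with

* a planted *hub* taxon of high abundance and ubiquity,
* a block of *satellite* taxa whose latent abundances correlate with the hub
  (one-factor structure, so the implied correlation matrix is always PSD),
* a multiplicative depletion of the hub in the keystone-vaccinated group,
* per-sample antibody OD values negatively and monotonically coupled to the
  realized hub abundance,
* a random coalescent phylogeny over the taxa,
* a taxon-by-gene copy-number table in which only the hub carries two marker
  genes of a single pathway, and a qPCR Ct table whose 2^-ddCt fold change
  of those markers tracks the hub depletion.

Latent abundances are log-normal and observed counts are multinomial draws of
the implied compositions — the same generative family the basis-correlation
inference itself assumes. All randomness descends from one master seed via
``numpy.random.SeedSequence.spawn``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
import skbio

from .containers import CountTable, ValidationError

__all__ = [
    "SimConfig",
    "SyntheticBundle",
    "generate_counts",
    "generate_antibody",
    "generate_tree",
    "generate_gene_content",
    "generate_bundle",
    "GROUPS",
    "MARKER_GENES",
    "MARKER_PATHWAY",
    "HOUSEKEEPING_GENE",
]

GROUPS = ("unfed", "mock", "keystone_vax", "nonkeystone_vax")
#: study design: number of pooled-tick samples per group
DEFAULT_GROUP_SIZES = {"unfed": 6, "mock": 7, "keystone_vax": 9, "nonkeystone_vax": 5}
ANTIBODY_DAYS = (0, 14, 30, 46)
MARKER_GENES = ("atoB_like", "eutD_like")
MARKER_PATHWAY = "lysine_fermentation"
HOUSEKEEPING_GENE = "rsp4"


class ConfigurationError(ValueError):
    """Raised when a simulation configuration violates an invariant."""


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    ``n_samples_per_group`` may be a single int (applied to every group) or a
    mapping group -> count; the default is the study design (6/7/9/5 pools).
    ``depletion_factor`` multiplies the hub's latent abundance in the
    keystone-vaccinated group (0.25 = 4-fold depletion; 1.0 = null).
    """

    n_taxa: int = 50
    n_samples_per_group: int | Mapping[str, int] | None = None
    groups: tuple[str, ...] = GROUPS
    depth: int = 20_000
    hub_index: int = 0
    n_satellites: int = 8
    hub_satellite_rho: float = 0.8
    depletion_factor: float = 0.25
    od_noise_sd: float = 0.05
    seed: int = 0
    # secondary knobs (defaults are the package's standing choices)
    log_sd: float = 1.0
    hub_log_boost: float = 2.0
    od_base: float = 0.2
    od_gain: float = 1.5
    antibody_coupled: bool = True
    ct_noise_sd: float = 0.1

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ConfigurationError("depth must be positive")
        if self.n_taxa < 2:
            raise ConfigurationError("need at least 2 taxa")
        if not -1.0 <= self.hub_satellite_rho <= 1.0:
            raise ConfigurationError("hub_satellite_rho must be in [-1, 1]")
        if self.n_satellites >= self.n_taxa:
            raise ConfigurationError("n_satellites must be < n_taxa")
        if self.depletion_factor <= 0:
            raise ConfigurationError("depletion_factor must be > 0")
        if not 0 <= self.hub_index < self.n_taxa:
            raise ConfigurationError("hub_index out of range")
        if self.od_noise_sd < 0 or self.ct_noise_sd < 0:
            raise ConfigurationError("noise standard deviations must be >= 0")

    def group_sizes(self) -> dict[str, int]:
        spg = self.n_samples_per_group
        if spg is None:
            return {g: DEFAULT_GROUP_SIZES.get(g, 7) for g in self.groups}
        if isinstance(spg, Mapping):
            return {g: int(spg[g]) for g in self.groups}
        return {g: int(spg) for g in self.groups}

    def taxon_names(self) -> list[str]:
        names = [f"genus_{i:03d}" for i in range(self.n_taxa)]
        names[self.hub_index] = "hub_genus"
        for k, j in enumerate(self.satellite_indices()):
            names[j] = f"satellite_{k:02d}"
        return names

    def satellite_indices(self) -> list[int]:
        idx = [i for i in range(self.n_taxa) if i != self.hub_index]
        return idx[: self.n_satellites]

    def _child_rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence(self.seed).spawn(8)[stream])


def _latent_log_abundance(cfg: SimConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    """Latent per-sample log abundances, taxa x samples, before group effects."""
    # fixed taxon baselines, deterministic given the seed
    mu = rng.normal(0.0, 1.0, size=cfg.n_taxa)
    mu[cfg.hub_index] = mu.max() + cfg.hub_log_boost
    sats = cfg.satellite_indices()
    mu[sats] = np.maximum(mu[sats], np.median(mu))  # keep satellites detectable
    rho = cfg.hub_satellite_rho
    z = rng.standard_normal((cfg.n_taxa, n))
    z_hub = z[cfg.hub_index].copy()
    # one-factor coupling: corr(hub, sat) = rho, corr(sat, sat') = rho^2
    z[sats] = rho * z_hub + np.sqrt(1.0 - rho**2) * z[sats]
    return mu[:, None] + cfg.log_sd * z


def generate_counts(cfg: SimConfig) -> CountTable:
    """Simulate the genus-level count table for all groups.

    Latent log-normal abundances with a hub–satellite correlation block are
    depleted (hub only) in the keystone-vaccinated group, normalized to
    compositions, and sampled with a multinomial at ``cfg.depth`` reads so
    every sample's counts sum to the depth exactly.
    """
    rng = cfg._child_rng(0)
    sizes = cfg.group_sizes()
    n_total = sum(sizes.values())
    latent = _latent_log_abundance(cfg, rng, n_total)

    sample_ids, group_of = [], []
    for g in cfg.groups:
        for k in range(sizes[g]):
            sample_ids.append(f"{g}_{k + 1:02d}")
            group_of.append(g)
    group_arr = np.array(group_of)
    latent[cfg.hub_index, group_arr == "keystone_vax"] += np.log(cfg.depletion_factor)

    frac = np.exp(latent - latent.max(axis=0))
    frac /= frac.sum(axis=0)
    counts = np.column_stack(
        [rng.multinomial(cfg.depth, frac[:, j]) for j in range(n_total)]
    )
    meta = pd.DataFrame(
        {
            "group": group_of,
            "day": [0 if g == "unfed" else 46 for g in group_of],
        },
        index=pd.Index(sample_ids, name="sample"),
    )
    df = pd.DataFrame(counts, index=pd.Index(cfg.taxon_names(), name="taxon"),
                      columns=sample_ids)
    return CountTable(df, meta)


def generate_antibody(cfg: SimConfig, counts: CountTable) -> pd.DataFrame:
    """Per-sample IgM/IgG OD values by bleed day.

    For mock and keystone-vaccinated samples the day-46 OD is a strictly
    decreasing function of the realized hub relative abundance (so with zero
    noise the pooled mock+keystone_vax Spearman correlation of OD against hub
    abundance is exactly -1); other groups and earlier days carry baseline OD
    plus noise, ramped over the immunization schedule. With
    ``antibody_coupled=False`` every sample is baseline-only (null scenario).
    OD values are non-negative by construction.
    """
    rng = cfg._child_rng(1)
    rel = counts.relative_abundance()
    hub = rel.iloc[[cfg.hub_index]].to_numpy().ravel()
    groups = counts.group_labels().to_numpy()
    # strictly decreasing, bounded signal in [0, 1]
    span = np.log(hub.max() + 1e-12) - np.log(hub.min() + 1e-12)
    signal = (np.log(hub.max() + 1e-12) - np.log(hub + 1e-12)) / max(span, 1e-12)
    coupled = np.isin(groups, ["mock", "keystone_vax"]) & cfg.antibody_coupled

    ramp = {0: 0.0, 14: 0.25, 30: 0.8, 46: 1.0}
    rows = []
    for day in ANTIBODY_DAYS:
        for iso, gain_scale in (("IgM", 1.0), ("IgG", 0.8)):
            od = np.full(counts.n_samples, cfg.od_base)
            od = od + np.where(coupled, ramp[day] * gain_scale * cfg.od_gain * signal, 0.0)
            od = od + rng.normal(0.0, cfg.od_noise_sd, size=od.shape)
            rows.append(
                pd.DataFrame(
                    {
                        "sample": counts.samples,
                        "group": groups,
                        "day": day,
                        "isotype": iso,
                        "od": np.maximum(od, 0.0),
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


def generate_tree(cfg: SimConfig) -> skbio.TreeNode:
    """Random coalescent-style rooted binary tree over the taxa.

    Lineages are merged uniformly at random with exponentially distributed
    waiting times, giving positive branch lengths throughout; tip labels equal
    the count-table taxon names.
    """
    if cfg.n_taxa < 2:
        raise ConfigurationError("a tree needs at least 2 taxa")
    rng = cfg._child_rng(2)
    nodes = [skbio.TreeNode(name=name, length=None) for name in cfg.taxon_names()]
    heights = [0.0] * len(nodes)
    t = 0.0
    while len(nodes) > 1:
        k = len(nodes)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        parent = skbio.TreeNode(length=None)
        for child, h in ((nodes[i], heights[i]), (nodes[j], heights[j])):
            child.length = t - h
            parent.append(child)
        nodes = [n for m, n in enumerate(nodes) if m not in (i, j)] + [parent]
        heights = [h for m, h in enumerate(heights) if m not in (i, j)] + [t]
    return nodes[0]


def generate_gene_content(
    cfg: SimConfig, counts: CountTable | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Taxon x gene copy numbers, gene->pathway map, and a qPCR Ct table.

    The hub taxon is the sole carrier (copy number 1) of the two marker genes,
    both members of one pathway; background genes are scattered over the other
    taxa with small copy numbers, each belonging to exactly one background
    pathway. Ct values are simulated so that each sample's target-gene delta-Ct
    tracks -log2(hub relative abundance): the 2^-ddCt fold change of the
    markers in the keystone-vaccinated group then approximates the planted
    depletion factor (< 1).
    """
    rng = cfg._child_rng(3)
    taxa = cfg.taxon_names()
    background = [f"gene_{i:02d}" for i in range(8)]
    genes = list(MARKER_GENES) + background
    content = pd.DataFrame(0, index=pd.Index(taxa, name="taxon"),
                           columns=pd.Index(genes, name="gene"))
    for g in MARKER_GENES:
        content.loc[taxa[cfg.hub_index], g] = 1
    non_hub = [t for i, t in enumerate(taxa) if i != cfg.hub_index]
    for g in background:
        carriers = rng.choice(len(non_hub), size=max(2, len(non_hub) // 4), replace=False)
        content.loc[[non_hub[c] for c in carriers], g] = rng.integers(1, 4)

    pathway_map = pd.DataFrame(
        {
            "gene": genes,
            "pathway": [MARKER_PATHWAY] * len(MARKER_GENES)
            + [f"background_pwy_{i % 4}" for i in range(len(background))],
        }
    )

    if counts is None:
        counts = generate_counts(cfg)
    rel = counts.relative_abundance()
    hub_rel = rel.iloc[[cfg.hub_index]].to_numpy().ravel()
    groups = counts.group_labels().to_numpy()
    rows = []
    for j, sample in enumerate(counts.samples):
        ct_hk = 20.0 + rng.normal(0.0, cfg.ct_noise_sd)
        rows.append((sample, groups[j], HOUSEKEEPING_GENE, ct_hk))
        for g in MARKER_GENES:
            ct = ct_hk + 6.0 - np.log2(hub_rel[j] + 1e-12) / 1.0
            rows.append((sample, groups[j], g, ct + rng.normal(0.0, cfg.ct_noise_sd)))
    ct_table = pd.DataFrame(rows, columns=["sample", "group", "gene", "ct"])
    if not np.all(np.isfinite(ct_table["ct"])):
        raise ConfigurationError("non-finite Ct simulated; hub absent from a sample")
    return content, pathway_map, ct_table


@dataclass
class SyntheticBundle:
    """Everything the downstream pipeline consumes, generated coherently."""

    config: SimConfig
    counts: CountTable
    tree: skbio.TreeNode
    antibody: pd.DataFrame
    gene_content: pd.DataFrame
    pathway_map: pd.DataFrame
    ct_table: pd.DataFrame

    @property
    def hub_taxon(self) -> str:
        return self.counts.taxa[self.config.hub_index]


def generate_bundle(cfg: SimConfig) -> SyntheticBundle:
    counts = generate_counts(cfg)
    tree = generate_tree(cfg)
    antibody = generate_antibody(cfg, counts)
    gene_content, pathway_map, ct_table = generate_gene_content(cfg, counts)
    return SyntheticBundle(cfg, counts, tree, antibody, gene_content, pathway_map, ct_table)
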