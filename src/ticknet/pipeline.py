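"""End-to-end orchestration of the analysis on synthetic or supplied inputs.

Stage order mirrors the study's analysis sequence: simulate (optional) ->
co-occurrence network -> topology / keystones / attack tolerance ->
diversity -> differential abundance -> antibody correlation -> functional
prediction -> qPCR fold changes. A manifest JSON records parameters, seeds
and package version so a rerun with the same config is reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__, abcorr, compnet, diffab, diversity, funcpred, io_tables, syndata, topology
from .containers import ValidationError
from .syndata import SimConfig

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    outdir: str = "ticknet_run"
    seed: int = 0
    # either simulate, or read counts/metadata/tree/... from these paths
    simulate: bool = True
    sim: dict = field(default_factory=dict)
    counts_path: str | None = None
    metadata_path: str | None = None
    tree_path: str | None = None
    gene_content_path: str | None = None
    pathway_map_path: str | None = None
    ct_path: str | None = None
    # network stage
    network_group: str = "mock"
    r_min: float = 0.3
    alpha: float = 0.05
    n_inference_iter: int = 20
    n_exclusion_iter: int = 10
    exclusion_threshold: float = 0.1
    n_perm: int = 100
    # attack stage
    attack_iterations: int = 100
    loss_target: float = 0.90
    # stats
    rarefaction_depth: int | None = None
    permanova_permutations: int = 999
    contrast: tuple[str, str] = ("mock", "keystone_vax")
    lfc_cutoff: float = 1.0
    diffab_alpha: float = 0.05
    abcorr_instances: int = 128
    abcorr_covariate: tuple[str, int] = ("IgM", 46)
    qpcr_target: str = syndata.MARKER_GENES[0]
    qpcr_housekeeping: str = syndata.HOUSEKEEPING_GENE
    qpcr_control: str = "mock"

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        payload = json.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        for key in ("contrast", "abcorr_covariate"):  # JSON has no tuples
            if key in payload:
                payload[key] = tuple(payload[key])
        return cls(**payload)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _load_inputs(cfg: PipelineConfig):
    if cfg.simulate:
        sim_cfg = SimConfig(seed=cfg.seed, **cfg.sim)
        return syndata.generate_bundle(sim_cfg)
    for name in ("counts_path", "metadata_path"):
        p = getattr(cfg, name)
        if p is None or not Path(p).exists():
            raise ValidationError(f"pre-flight: missing input {name}={p}")
    counts = io_tables.read_counts(cfg.counts_path)
    meta = io_tables.read_metadata(cfg.metadata_path)
    counts = type(counts)(counts.counts, meta)
    tree = io_tables.read_newick(cfg.tree_path) if cfg.tree_path else None
    import pandas as pd

    gene_content = (
        io_tables.read_matrix_tsv(cfg.gene_content_path) if cfg.gene_content_path else None
    )
    pathway_map = (
        pd.read_csv(cfg.pathway_map_path, sep="\t", comment="#")
        if cfg.pathway_map_path
        else None
    )
    ct = pd.read_csv(cfg.ct_path, sep="\t", comment="#") if cfg.ct_path else None
    return syndata.SyntheticBundle(
        SimConfig(seed=cfg.seed), counts, tree, None, gene_content, pathway_map, ct
    )


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Execute every stage, writing results and a manifest under ``outdir``."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    rng_seed = int(cfg.seed)
    bundle = _load_inputs(cfg)
    counts = bundle.counts

    io_tables.write_counts(counts, out / "counts.tsv")
    if counts.metadata is not None:
        io_tables.write_metadata(counts.metadata, out / "metadata.tsv")
    if bundle.tree is not None:
        io_tables.write_newick(bundle.tree, out / "tree.nwk")

    # --- network on the control (mock-fed) samples ------------------------
    net_counts = counts.select_group(cfg.network_group) if cfg.network_group else counts
    model = compnet.sparcc(
        net_counts,
        n_inference_iter=cfg.n_inference_iter,
        n_exclusion_iter=cfg.n_exclusion_iter,
        exclusion_threshold=cfg.exclusion_threshold,
        seed=rng_seed,
    )
    model.pvals = compnet.permutation_pvalues(
        net_counts,
        model.rho,
        n_perm=cfg.n_perm,
        seed=rng_seed + 1,
        n_inference_iter=cfg.n_inference_iter,
        n_exclusion_iter=cfg.n_exclusion_iter,
        exclusion_threshold=cfg.exclusion_threshold,
    )
    net = compnet.build_network(model, net_counts, r_min=cfg.r_min, alpha=cfg.alpha)
    io_tables.write_correlation_model(model, out)
    io_tables.write_edge_list(net, out / "network_edges.tsv")
    io_tables.write_network_gexf(net, out / "network.gexf")

    report = topology.summarize_topology(net)
    io_tables.write_json(report.to_dict(), out / "topology.json")
    keystones = topology.keystoneness(net, net_counts)
    keystones.to_csv(out / "keystones.tsv", sep="\t")
    curves = {}
    for strategy in ("random", "directed"):
        curve = topology.attack(
            net, strategy, n_iterations=cfg.attack_iterations, seed=rng_seed + 2
        )
        curves[strategy] = curve
        np.savetxt(
            out / f"attack_{strategy}.tsv",
            np.column_stack([curve.fractions, curve.cl]),
            delimiter="\t",
            header="fraction_removed\tconnectivity_loss",
        )
    attack_summary = {
        s: topology.removal_fraction_at_loss(c, cfg.loss_target) for s, c in curves.items()
    }
    io_tables.write_json(attack_summary, out / "attack_summary.json")

    # --- diversity ---------------------------------------------------------
    rare = diversity.rarefy(counts, cfg.rarefaction_depth, seed=rng_seed + 3)
    alpha_tbl = diversity.alpha_diversity_table(rare, bundle.tree)
    alpha_tbl.to_csv(out / "alpha_diversity.tsv", sep="\t")
    bc = diversity.bray_curtis(rare)
    io_tables.write_matrix_tsv(bc, list(bc.index), out / "bray_curtis.tsv",
                               "Bray-Curtis dissimilarities")
    labels = rare.group_labels().to_numpy()
    f_stat, p_perm = diversity.permanova(
        bc, labels, n_perm=cfg.permanova_permutations, seed=rng_seed + 4
    )
    tests = {"permanova": {"F": f_stat, "p": p_perm}}
    for col in [c for c in alpha_tbl.columns]:
        h, p = diversity.kruskal_wallis(alpha_tbl[col].to_numpy(), labels)
        tests[f"kruskal_{col}"] = {"H": h, "p": p}
    io_tables.write_json(tests, out / "diversity_tests.json")

    # --- differential abundance -------------------------------------------
    ref, trt = cfg.contrast
    sub = counts.select_group(ref, trt)
    result = diffab.wald_lfc_test(sub, reference_group=ref)
    result.to_csv(out / "diffab_taxa.tsv", sep="\t")
    diffab.volcano_table(result, cfg.lfc_cutoff, cfg.diffab_alpha).to_csv(
        out / "diffab_taxa_hits.tsv", sep="\t"
    )

    # --- antibody correlation ----------------------------------------------
    if bundle.antibody is not None:
        iso, day = cfg.abcorr_covariate
        ab = bundle.antibody
        ab = ab[(ab["isotype"] == iso) & (ab["day"] == day)].set_index("sample")
        ab_samples = [s for s in sub.samples if s in ab.index]
        ab_counts = sub.select_samples(ab_samples)
        inst = abcorr.mc_instances(ab_counts, cfg.abcorr_instances, seed=rng_seed + 5)
        corr = abcorr.correlate(inst, ab.loc[ab_samples, "od"].to_numpy(), taxa=ab_counts.taxa)
        corr.to_csv(out / "antibody_correlation.tsv", sep="\t")

    # --- functional prediction + qPCR ---------------------------------------
    if bundle.gene_content is not None:
        genes = funcpred.predict_metagenome(counts, bundle.gene_content)
        pwys = funcpred.pathway_abundance(genes, bundle.pathway_map)
        genes.to_csv(out / "predicted_genes.tsv", sep="\t")
        pwys.to_csv(out / "predicted_pathways.tsv", sep="\t")
        from .containers import CountTable

        pwy_counts = CountTable(pwys.round().astype(int).loc[:, sub.samples], sub.metadata)
        pwy_result = diffab.wald_lfc_test(pwy_counts, reference_group=ref)
        pwy_result.to_csv(out / "diffab_pathways.tsv", sep="\t")
    if bundle.ct_table is not None:
        folds = funcpred.ddct_fold_change(
            bundle.ct_table, cfg.qpcr_target, cfg.qpcr_housekeeping, cfg.qpcr_control
        )
        folds.to_csv(out / "qpcr_fold_changes.tsv", sep="\t")

    manifest = {
        "package": "ticknet",
        "version": __version__,
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "stages": [p.name for p in sorted(out.iterdir())],
    }
    io_tables.write_json(manifest, out / "manifest.json")
    return out
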