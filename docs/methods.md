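# Methods

This note records the models, parameter choices, numerical conventions and
known limitations behind `ticknet`. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Synthetic study generator (`syndata`)

The generator emulates a host-immunization tick-feeding experiment at the
level of the data the analysis actually consumes: a genus-by-sample count
table over four groups (unfed ticks; ticks fed on mock-, keystone- and
non-keystone-immunized hosts; default group sizes 6/7/9/5 pooled samples),
plus antibody OD kinetics, a phylogeny, gene copy numbers and qPCR Ct values.

**Latent abundance model.** Per-taxon baselines `μ_i ~ N(0, 1)` with the hub
raised `hub_log_boost = 2.0` above the maximum (high abundance and full
ubiquity, as expected of a keystone); per-sample latent log abundances
`L_i = μ_i + σ z_i` with `σ = log_sd = 1.0`. Hub–satellite dependence uses a
one-factor construction, `z_sat = ρ z_hub + √(1−ρ²) ε`, giving
`corr(hub, sat) = ρ` and `corr(sat, sat′) = ρ²` with a guaranteed PSD
correlation matrix; default `ρ = 0.8` with 8 satellites. The
keystone-vaccinated group multiplies the hub's latent abundance by
`depletion_factor = 0.25` (a 4-fold depletion). Compositions
`exp(L)/Σexp(L)` are sampled by a multinomial at `depth = 20 000` reads, so
each sample's counts sum to the depth exactly. Log-normal bases are the same
generative family the basis-correlation inference assumes, which is the
point: the planted parameters are recoverable in principle.

**Antibody coupling.** For mock and keystone-vaccinated samples the OD at the
final bleed day is a single strictly decreasing affine function of
log(hub relative abundance), scaled into a bounded signal, ramped over the
immunization schedule (days 0/14/30/46) and perturbed by
`N(0, od_noise_sd²)`; other groups receive baseline + noise. Using one
monotone function across both coupled groups makes the noise-free pooled
Spearman correlation exactly −1, the limit the tests pin down.
`antibody_coupled=False` produces the baseline-only null.

**Phylogeny.** A random coalescent: lineages merge uniformly at random with
exponential waiting times, yielding a rooted binary tree with strictly
positive branch lengths, serialized as Newick.

**Genes and qPCR.** Only the hub carries the two marker genes (copy number
1), both mapped to one pathway; background genes are scattered over other
taxa. Target-gene ΔCt tracks −log2(hub relative abundance) plus
`N(0, ct_noise_sd²)`, so the 2^−ΔΔCt fold change of the markers in the
keystone-vaccinated group approximates the planted depletion factor.

**Seeds.** One master seed; every sub-generator draws from a child of
`numpy.random.SeedSequence(seed)`, so bundles are bitwise reproducible.

**What the generator does not emulate.** Read-level error, chimeras and
denoising artifacts; variable library sizes (all samples share one depth);
taxonomic misassignment; overdispersion beyond log-normal×multinomial; tick
biology (pooling is represented only as "a sample is a pool"). Passing tests
therefore demonstrate statistical correctness of the estimators under their
own generative assumptions, not robustness to real amplicon pathologies.

## SparCC inference (`compnet`)

Defaults follow the published convention: 20 Dirichlet-resampling inference
iterations, up to 10 exclusion rounds per iteration, exclusion threshold 0.1,
median aggregation. The ω linear system is solved exactly (LAPACK via a
compiled numba kernel; `basis_correlation` keeps a plain NumPy path used by
the formula-level tests). Non-positive ω estimates are clamped to the
smallest positive estimate with a warning — this keeps ρ defined without
discarding taxa, at the cost of occasional |ρ| ≈ 1 artifacts on small
tables (see below). Exclusion ties resolve to the lexicographically smallest
index pair; a taxon is never left with fewer than two active partners.

Permutation pseudo-p-values shuffle each taxon's counts independently across
samples, rerun the full SparCC estimate per permutation, and report
`p = (1 + #{|ρ_perm| ≥ |ρ_obs|}) / (1 + n_perm)` per pair. Edges require
`|ρ| ≥ r_min = 0.3` and Benjamini–Hochberg-adjusted `p ≤ α = 0.05` over all
pairs (both exposed as parameters; the original study does not state its
thresholds, so published edge counts are not reproducible and are used only
as worked-example arithmetic).

**Small-table instability.** With few taxa (D ≲ 30) and a compositionally
dominant taxon, the ω solve can yield tiny variances under permutation,
producing clipped |ρ| ≈ 1 null outliers. Because the BH step-up over
`m = D(D−1)/2` pairs can only admit an edge whose pseudo-p floor satisfies
`1/(n_perm+1) ≤ α·k/m`, scenarios at this scale need `n_perm ≈ 1000`. The
keystone-recovery scenario (25 taxa, one group of 100 samples, 999
permutations) was sized by this arithmetic, and sample size chosen where the
solve is stable; the originating study operated at 525 genera, a far more
stable regime for the sparsity approximation.

## Topology, keystones, attack (`topology`)

Eigenvector centrality is computed by power iteration on the absolute-weight
adjacency shifted by a spectral-radius bound (`A + cI`), which converges on
bipartite graphs too; tolerance 1e−10, max-normalized. Hub scores on an
undirected graph coincide with eigenvector centrality (the symmetric-case
identity of HITS) and are exposed for report parity. Keystone criteria:
centrality ≥ its 0.9 quantile; ubiquity ≥ 0.8; abundance ≥ its 0.75 quantile
combined with the centrality criterion; the composite requires all three.
The study says only "high" for each, so the quantiles are package defaults,
exposed as parameters.

Connectivity loss is the pair-reachability ratio
`CL = 1 − (reachable pairs after removal)/(N(N−1)/2)`, the convention of the
attack-tolerance package family; the originating study never defines CL
explicitly. Whole curves are computed by reverse union-find (add nodes in
reverse removal order), exact and near-linear. The directed attack uses
betweenness centrality ranked once on the intact graph ("the highest, the
first"), ties by node ID; `recompute=True` re-ranks after every removal.
Random attacks average 100 (default) independent uniform orders. The removal
fraction at a loss target uses step semantics (smallest k/N with CL ≥
target), no interpolation.

Modularity is greedy modularity maximization on |weight| at resolution 1.
Published modularity values above 1 are incompatible with the Newman
definition (range ≤ 1) and are treated as non-reproducible; our value is
validated against the closed form `1 − 1/k` for k disjoint equal cliques.

## Diversity (`diversity`)

Rarefaction subsamples without replacement (multivariate hypergeometric) to
the minimum sample sum by default, one draw, seed logged; shallower samples
are dropped with a warning. Faith PD (scikit-bio) includes the root
connection. Pielou uses natural logs and observed richness; single-taxon
samples return NaN with a warning. PERMANOVA is implemented in-package
(pseudo-F from among/within sums of squared distances, raw-label
permutations, default 999) so the permutation stream is explicitly seeded;
scikit-bio's implementation serves as the cross-check oracle for the
statistic in the tests. Note that at the default depth a 50-genus table is
dense — every genus present in every sample — so Faith PD is flat across
samples and carries no group signal; evenness does.

## Differential abundance (`diffab`)

Median-of-ratios size factors (zero-free reference features; positive-count
fallback for zero-heavy tables), normalized to geometric mean 1. The Wald
test models each feature as negative-binomial with a pooled within-group
method-of-moments dispersion `α = max((s² − μ)/μ², 1e−8)`;
`LFC = log2((m_T + 0.5)/(m_R + 0.5))` of normalized group means; the
standard error comes from the delta method and the z statistic is referred
to the standard normal (the convention of the dedicated RNA-seq tools this
simplifies). No dispersion shrinkage across features, no outlier filtering.
BH across features. The clr transform uses pseudocount 0.5; note that with a
pseudocount, rescaling raw counts changes clr values by a vanishing amount
(exact invariance holds only in the limit of large counts).

Two properties measured by the suite are worth stating: the test's type-I
error for the hub under a null depletion at n = 10/group is ≈ 5–6%
(within the ±3-point band, checked over 1000 replicates); and the LFC
estimand under the compositional pipeline is ≈ −1.95 rather than −2.00 for
a planted 4-fold depletion (a small residual from median-based size-factor
correction of a skewed compositional shift). The recovery check runs at
n = 150/group, sized so the estimator's sampling spread (≈ 0.62 log2 units
at n = 10, scaling as 1/√n) fits the ±0.5 recovery band with margin. At the
study's own pool counts (5–9 per group) the Wald test has power only for
large effects — which is consistent with how such studies report them.

## Antibody correlation (`abcorr`)

128 Monte-Carlo instances (Dirichlet(counts + 0.5) per sample, clr per
instance), Spearman correlation per taxon per instance against the
covariate, expected values across instances; BH within each instance before
averaging the adjusted p-values, matching the expected-value reporting
convention of the dedicated tool. Doubling the instance count moves expected
correlations by < 0.05 on the default scenario (checked).

## Functional prediction and qPCR (`funcpred`)

Metagenome prediction is the deterministic copy-number step only: taxon
abundances divided by 16S copy number (default 1) times the taxon×gene
table; phylogenetic placement and hidden-state prediction are upstream
concerns, represented only by an optional per-taxon exclusion list. Pathway
abundance aggregates member genes by mean (default) or sum. 2^−ΔΔCt
normalizes ΔCt per sample against the housekeeping gene and centers on the
control group's mean ΔCt, so the control group's geometric-mean fold change
is exactly 1; per-group summaries report both arithmetic and geometric
means implicitly via the per-sample table.

## Problem sizes used by the checks

Scenario sizes are the package's own choices, set by the power arithmetic
described above: keystone recovery 25 taxa × 100 samples × 999 permutations
× 50 seeds; LFC recovery 50 taxa × 150 samples/group × 50 seeds; null
calibrations 1000 replicates (PERMANOVA at 16 samples; Wald at 10/group);
SparCC pseudo-p uniformity at 10 taxa × 50 samples × 200 permutations.

## Known limitations

* SparCC at few taxa is fragile when one taxon dominates the composition;
  results at D < ~30 should be read with the instability note above in mind.
* The Wald LFC test is slightly anticonservative at very small groups
  (normal reference for a variance estimated with few degrees of freedom).
* Published network edge counts, modularity values and attack-tolerance
  fractions from the originating study depend on unstated thresholds and
  accession-scale data; the package reproduces their arithmetic and their
  qualitative structure (directed attacks dominate random ones on hub-heavy
  networks), not the printed values themselves.
* The BIOM reader implements only the minimal JSON dialect
  (rows/columns/data triplets), not HDF5 BIOM.
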