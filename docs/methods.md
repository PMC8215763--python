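# Methods

This note records the models, conventions and design choices behind
`rumennet`, in the order the pipeline runs. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself compute.

## Synthetic data: what the generator emulates

The generator (`rumennet.synthetic_data`) produces annotated gene × sample
count bundles with the structure the analysis assumes, so that every stage can
be tested against known ground truth.

**Study design.** Default: 3 animals × 5 incubation timepoints (1, 2, 4, 6,
8 h), one sample per animal-timepoint, plus a single pooled 0 h baseline
sample under a reserved animal id — 16 samples. The baseline is drawn from a
flat "epiphyte" profile unrelated to the colonisation trajectories and is
excluded from every analysis stage by default, mirroring how pre-incubation
plant-surface communities differ from rumen colonisers.

**Latent trajectories.** Each taxonomic family has a mean trajectory over the
timepoints, built from fixed templates (log-linear interpolation between
anchor hours for non-default designs, normalised to mean 1, then scaled by
`family_mean_total`, default 3000 expected family counts per sample):

| role | template (1, 2, 4, 6, 8 h) | rank profile |
|---|---|---|
| primary consensus | 8, 10, 6, 2.5, 1 | peak at 2 h, declining after 4 h |
| primary facet A | 6, 10, 8, 2.5, 1 | one adjacent rank swap from consensus |
| primary facet B | 10, 8, 6, 2.5, 1 | the opposite adjacent swap |
| secondary consensus | 2.5, 1, 4, 7, 10 | non-decreasing from 4 h |
| secondary facets A/B | 1, 2.5, 4, 7, 10 / 4, 1, 2.5, 7, 10 | pre-4 h variants |

The rank geometry is deliberate: within a block, each facet has trajectory
Spearman 0.9 with the consensus but only 0.7 with the other facet, while every
primary-vs-secondary template pair sits at −0.7 to −1.0. Block members
alternate between facets A and B and receive per-(family, timepoint) lognormal
jitter (sd 0.1, small enough that rank correlations are stable at n = 15
samples). **Keystone families** (default 2 per block) follow the block
consensus *exactly*, scaled by `keystone_abundance_fraction` (default 0.05):
low-abundance families that correlate strongly with members of both facets.
In the resulting network the facets form two sub-cliques with sparse
cross-links, and the keystones are the hubs bridging them — the "connector"
topology the keystone procedure is designed to detect. Keystones are planted
as consensus-tracking hubs, not as degree-2 bridges: on toy graphs a bare
bridge between two cliques does not win the five-measure Borda ranking (the
transitivity and density directions reward clique members, and disconnection
*lowers* the reachable-pair average path length).

**Independent and rare families.** Independents (default 4) are
high-expression families with flat trajectories plus jitter; they correlate
with nothing and end up isolated in the network, emulating dominant
non-cooperative families. Rare families (default 10) are flat at
`rare_abundance_fraction` (default 0.01) of a member family's abundance. They
model the low-abundance tail of a real community and exist so that the IQR
variable filter has something realistic to remove: absolute IQR scales with
abundance, so without a rare tail the 25% IQR cut would always eliminate the
planted keystones (the least-variable retained nodes). Ten rare families give
the cut margin even when one or two of them already fall to the 10-expressed-
genes floor (their Dirichlet gene weights can leave individual genes
unexpressed).

**Counts.** Gene g of family f in sample s (animal a, timepoint t) is drawn
negative-binomial with mean `trajectory(f, t) · w_g · animal(f, a) ·
library(s)` and shape `nb_dispersion` (default 5; a Poisson mode covers the
infinite-dispersion limit). `w_g` are Dirichlet(1) weights within the family
(the within-family weight distribution is not identified by the emulated
design; any heavy-tailed choice would do and the choice is documented here).
Animal effects are lognormal per (family, animal) (sd 0.1 on the log scale),
library factors lognormal per sample (sd 0.3). Genes get uniform lengths in
300–3000 bp, a functional cluster out of 6, and enzyme tags (a handful of GH
families, MEROPS-style peptidase codes, LuxS) by fixed per-tag fractions,
independent of block membership unless `gh_tags_secondary_bias` ties GH tags
to secondary-block families. Equal configs and seeds give byte-identical
bundles; all randomness flows from `numpy.random.default_rng` seeded from
`GeneratorConfig.seed`.

**What the generator does not emulate** — and hence what passing tests do not
show about real data: read-level noise and mapping artefacts, annotation
error, compositional coupling between families (families are sampled
independently given the latent trajectories), phylogenetic correlation,
unbalanced or missing samples, and communities with hundreds of families. The
generator demonstrates that the *procedures* recover planted structure under
the stated noise model, not that the biology of any particular rumen data set
is recoverable.

## Pre-processing

Fixed order, enforced by a stage tag: family aggregation → minimum-gene
filter → sample-sum scaling → IQR filter → regularized log.

* "Genes expressed" for the 10-gene floor counts genes with ≥1 read in ≥1
  retained sample.
* Scaling divides each sample column by its sum and multiplies by the median
  of all column sums; afterwards every column sums to that median (tested to
  1e-9 relative).
* The IQR filter removes families whose IQR across samples is *strictly
  below* the 25th percentile (numpy default, type-7 linear interpolation — the
  boundary depends on the quantile convention, so it is pinned) of all family
  IQRs. The underlying description is ambiguous between filtering on IQR and
  on total expression; both are implemented (`mode="iqr"` default,
  `mode="total"`), matching the usual reading of IQR-based variable filtering.
* The regularized log is `log2(x + 1)` on the scaled values. Reference
  shrinkage estimators differ, but the only downstream consumer is a
  rank-based correlation, and any strictly monotone transform yields an
  identical edge set (asserted as a cross-module test), so re-deriving a
  shrinkage fit would change nothing.

## Network construction

Spearman ρ uses mid-rank ties; p-values come from the t approximation
`t = ρ√((n−2)/(1−ρ²))` on n−2 df (n = 15 in the emulated design), with an
exact permutation option for n ≤ 8. Constant families have undefined
correlations and never form edges. BH adjustment runs over the strict upper
triangle. An edge requires |ρ| > 0.7 **and** adjusted p < 0.1 (both strict).
The magnitude rule is used because negative associations between the two
colonisation phases are as informative as positive ones and appear as
negative edges in the displayed network; a `threshold_on="positive"` switch
restricts to positive correlations.

**Clustering.** Greedy modularity agglomeration (networkx CNM, made
deterministic by sorted node insertion) on the **positive-edge subgraph**.
With biphasic data the negative edges run *between* the two sub-microbiomes;
a near-complete unsigned skeleton (two positive cliques plus a dense negative
bipartite layer) has a single-community max-modularity partition, so
clustering the unsigned skeleton would fuse exactly the clusters the negative
edges separate. Restricting the community skeleton to positive edges is the
standard treatment of signed co-occurrence networks; `edges="all"` restores
the unsigned behaviour. Communities of ≥2 nodes get cluster ids; isolated
and singleton nodes stay unclustered. Whether edge weights should enter is
not identified by the emulated analysis; the default is unweighted.

**The five measures.**

* transitivity = 3·triangles / connected triples (0 without triples);
* density = 2E/(N(N−1)) (0 for N < 2);
* modularity Q = Σ_c [e_c/m − (d_c/2m)²]; Q := 0 when the graph has no edges;
* average path length = mean shortest-path distance over *reachable* ordered
  pairs (0 if none; disconnected graphs arise constantly during node removal).
  A `penalize` mode counts unreachable pairs at distance N instead;
* eigenvector centralization = Σ_i (c_max − c_i)/(N−1) with centralities
  scaled to max 1. The centrality vector is pinned to a deterministic
  representative of the dominant eigenspace of the adjacency matrix: the
  projection of the all-ones vector, with absolute values. On connected
  graphs this is the ordinary leading eigenvector; on disconnected graphs,
  where the leading eigenvalue can be degenerate, it remains well defined
  (per-component Perron vectors weighted by their overlap with the ones
  vector). Edgeless graphs and single nodes get centralization 0.

All five agree with independent brute-force recomputation (triple
enumeration, hand BFS, pair-sum modularity, power iteration on A+I) on 200
random graphs of ≤12 nodes in the acceptance suite.

## Keystone identification

For each clustered node, the five measures are computed on the full network
and on the network minus that node, with the partition held fixed (minus the
removed node). No re-clustering: re-detection after each removal would
confound the node's structural contribution with algorithmic instability of
the community search. Deltas (removed − full) are rounded to 9 decimals so
that ties between structurally equivalent nodes are exact, then ranked within
the node's cluster: most *negative* first for transitivity and density, most
*positive* first for modularity, average path length and eigenvector
centralization (a disruptive removal degrades cohesion and fragments the
graph). Ties take average ranks. The Borda score is the exact sum of the five
ranks; the per-cluster ordering is ascending Borda with node-id tie-break for
output only, equal scores are flagged, and the top-k (default 2) are reported
as putative keystones. Measures are evaluated on the full network by default
because cluster membership only scopes the *candidate set*; a
`scope="subgraph"` mode evaluates them on the cluster subgraph instead.
Ranking is within-cluster throughout (candidates never compete across
clusters).

## Temporal differential expression

Counts are summed per (family, functional cluster) feature; genes without a
cluster go to a reserved `unclustered` id with a warning. The default testing
engine is a linear-model surrogate on regularized-log feature values: an
additive `animal + time` fixed-effects model per feature, with the time
(animal) p-value from the F-test of the full model against the animal-only
(time-only) reduction, vectorised over features via least squares. The
bespoke content of this stage is the contrast enumeration and letter
construction, not the GLM fit, so the stage's contract is defined on the
p-value tables and `engine="external"` accepts externally computed tables
(e.g. from a negative-binomial likelihood-ratio engine) unchanged. The
surrogate is verified against statsmodels OLS/anova_lm in the unit tests.

Features with a BH-significant animal effect are excluded (threshold BH < 0.1,
matching the time cutoff; the emulated analysis excluded cow-confounded
features without stating its cutoff). Significant-time features (BH < 0.1
across features) proceed to all C(5,2) = 10 pairwise timepoint contrasts —
t-tests on the fitted time coefficients — BH-adjusted within feature at 0.1.

**Letters.** Build the non-significance graph on timepoints (edge where
adjusted p ≥ α), enumerate maximal cliques (networkx Bron–Kerbosch; ≤5
nodes), assign one letter per clique ordered by the clique's earliest
timepoint, and label each timepoint with the letters of all cliques containing
it. Two timepoints share a letter iff they lie in a common maximal clique —
verified exhaustively against subset search for all 1024 possible 5-point
graphs. Pattern keys canonicalise letters by first appearance in time order,
so keys are invariant to clique naming; whether real analyses counted letter
patterns or sign trajectories is not recoverable, and this operationalisation
is ours. Pattern grouping restricts to the most-expressed features — by
default the descending-total prefix holding 90% of summed expression
(`mode="cumulative"`); a quantile reading is switchable — and reports feature
counts, per-timepoint expression and per-family contribution shares.

## Enzyme profiling

TPM(g, s) = (count/length_kb) / Σ_g(count/length_kb) × 1e6, over the entire
table, so each sample sums to 1e6 (tested; TPM is invariant to uniform count
scaling of a sample). Summed TPM per GH or peptidase family, per taxonomic
family for LuxS. The 95% filter keeps, per enzyme type separately, the
minimal descending-total prefix reaching 95% of that type's TPM (the same
cumulative-mass reading as the DE stage's 90% cut); LuxS taxa pass
unfiltered. The two-way fixed-effects ANOVA (time + animal, no interaction;
replicate unit = animal × timepoint summed TPM, n = 3 per timepoint; baseline
excluded) is computed in closed form on the balanced design, where
SS_total = SS_time + SS_animal + SS_residual exactly; unbalanced designs are
rejected. Zero-variance families return F = 0, p = 1. BH runs across all
tested units with significance at adjusted p < 0.1.

Tukey letters use the Tukey–Kramer statistic
q = |m_i − m_j| / √((MSE/2)(1/n_i + 1/n_j)) with MSE and residual df from the
additive model and p from the studentized range distribution (k = number of
timepoints). For k = 2 this reduces to the blocked t-test via q = √2·|t|
(tested to 1e-6, the accuracy pinned for scipy's studentized-range CDF at
small df). The letter display itself reuses the maximal-clique routine, at
α = 0.05 by default (the R-convention HSD level; the BH screen stays at 0.1).
Taxon contributions are per-sample shares within (enzyme family, sample),
averaged over the animals of each timepoint, so shares per (enzyme family,
timepoint) sum to 1; silent combinations are emitted as missing.

## Problem sizes and determinism

Default synthetic runs use 34 families (~700 genes, 16 samples); the full
pipeline completes in about a second, the complete test suite in well under a
minute, and `scripts/acceptance.py` (5 replicate bundles plus a 10-replicate
keystone-recovery check shared with the test suite) in seconds. The brute-
force oracle suites use 200 random graphs of ≤12 nodes and all 1024 five-point
letter graphs; the null ANOVA calibration uses 500 replicates of 20 families.
Every stochastic step is seeded; identical configs and seeds reproduce outputs
byte for byte, and each pipeline run echoes its effective config next to its
outputs.

## Known limitations

* The linear-model DE surrogate has different power characteristics from a
  negative-binomial likelihood-ratio engine at low counts; the external-engine
  adapter exists precisely so the downstream contrast/letter machinery can be
  reused with such an engine.
* The IQR filter operates on absolute scaled expression, so its behaviour
  depends on the abundance structure of the input; the generator's rare tail
  reproduces the intended regime (rare families absorb the cut) but real data
  with different tails may filter differently.
* Eigenvector centralization has no single canonical normalisation; the
  convention above is used consistently on full and perturbed graphs, and only
  rank differences of its deltas feed the keystone stage.
* With 5 timepoints, trajectory rank space is coarse: facet templates can sit
  at Spearman 0.9 from the consensus and 0.7 from each other, but not farther
  apart, so facet sub-cliques in the synthetic network retain some cross-links.
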