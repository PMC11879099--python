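# Methods

## Scope and data model

The package implements the statistical chain commonly applied to multi-year
rhizosphere amplicon surveys: community structure (alpha/beta diversity,
ordination, multivariate permutation tests), correlation-threshold
co-occurrence networks benchmarked against degree-preserving null models,
two network-stability indices (robustness under random node loss,
efficiency-based vulnerability), niche breadth, phylogenetic assembly
stochasticity (pNST), the AVD stability index, and regressions linking
stochasticity to soil-nutrient structure.

Communities are samples × taxa count tables (`CommunityTable`); sample
metadata carries the design factors (plant ∈ {grass, legume}, year 1–4,
replicate 1–6) and seven soil covariates (TN, TP, NH₄⁺-N, NO₃⁻-N, AP in
mg/kg; OM in %; AK in mg/kg). Distance matrices use
`skbio.DistanceMatrix`; trees are `skbio.TreeNode` (Newick on disk).

## Synthetic community generator

The generator exists to give every inference stage a ground truth. It
emulates the 2 × 4 × 6 factorial design at a reduced scale chosen for test
throughput (defaults: 200 taxa, 5 000 reads/sample, 48 samples); the
reduced scale preserves every qualitative contrast the inference stages are
asked to recover.

**Regional pool.** Relative abundances are lognormal
(σ = 1.5 by default), normalized to a simplex. Each taxon gets an
environmental optimum and a niche width.

**Phylogeny.** A Kingman coalescent over the taxon set (uniform random
pair merges, exponential waiting times with rate C(k,2)); branch lengths
strictly positive, Newick-serializable, bit-identical per seed.

**Phylogenetically conserved optima.** Environmental optima are produced by
simulating a Brownian trait root-to-tip on the phylogeny and rank-mapping
the tip values onto a uniform grid over the NO₃⁻-N range (2–9 mg/kg). The
marginal distribution of optima is uniform, but close relatives get close
optima. This conservatism is essential, not cosmetic: environmental
filtering leaves a signature in *phylogenetic* turnover only if the
filtered trait is heritable on the tree. Without it, tip-shuffling null
models cannot distinguish filtered from neutral communities at all.

**Soil covariates.** Per-year means and standard deviations follow a
four-year grass–legume trial preset in which NH₄⁺, NO₃⁻, AP and OM decline
from year 1 to year 4 while TN, TP and AK stay roughly flat (e.g. NO₃⁻-N:
7.82 ± 2.65 → 2.81 ± 0.10 mg/kg). Replicate noise is Gaussian with the
preset's per-year sd scaled by `noise_sd` (a multiplier, because the
covariates span three orders of magnitude); covariate noises share a
common per-sample factor with loading 0.6, so the multivariate nutrient
matrix co-varies with any single driver the way field soil chemistry does.
Values are floored at 0.01 to stay physical.

**Community assembly.** Per sample, a local pool is drawn from a Dirichlet
perturbation of the regional abundances with concentration
`dispersal × reads_per_sample`; the pool is then reweighted by the niche
kernel `exp(−s·(optimum − env)²/(2σ²))` where `s` is the filter strength
and `env` the sample's NO₃⁻-N value, renormalized, and sampled as a
multinomial. The random stream is consumed identically at every strength,
so `s = 0` reproduces the neutral table bit-for-bit under the same seed,
and `mixed` mode interpolates continuously.

**Defaults and why.** `dispersal = 0.01` (concentration 50 at 5 000 reads)
produces replicate-to-replicate compositional variability in the range
real amplicon replicates show — far more overdispersed than a multinomial.
`niche_sd = 0.2` makes specialists occupy ≈3 % of the simulated gradient,
sharp enough that strength-1 filtering confines communities to a clade.
These two values jointly realize the two endpoints the generator is
required to produce: neutral data read as stochastic (mean group
pNST ≈ 0.73–0.80 across seeds) and strength-1 filtered data as
deterministic (≈ 0.31–0.40). One covariate (NO₃⁻-N) drives filtering;
the others are correlated noise, so recovery tests have a single known
driver.

**What the generator does not emulate.** No read-level error model, no
chimeras, no taxonomic realism, no spatial autocorrelation between
replicates, no year-to-year carryover of communities (years are
independent draws given the soil preset). Passing recovery tests therefore
demonstrates that the inference chain responds correctly to assembly
mechanism and nutrient structure — not that it is robust to sequencing
artifacts or temporal autocorrelation in real data.

## Diversity and ordination

Shannon uses the natural logarithm (recorded in output metadata). Faith's
PD is the rooted variant: total branch length of the subtree spanning the
observed taxa *including the path to the root*. Bray–Curtis is computed on
counts. PCoA double-centers −D²/2 and eigendecomposes; coordinates are
returned for positive eigenvalues only, negative eigenvalues are reported
but excluded from the `proportion_explained` denominator. PERMANOVA's
pseudo-F uses the within/among decomposition of squared distances; MRPP's
observed δ is the group-size-weighted mean within-group distance with the
chance-corrected effect A = 1 − δ/E[δ] estimated from the permutation
distribution. All permutation p-values use (1 + exceedances)/(1 + n_perm)
and an explicit seed. Diversity is computed on raw counts by default (the
relative-abundance conversions happen inside the indices that need them);
no rarefaction is performed anywhere.

## Co-occurrence networks

Taxa present in ≥ 50 % of a group's samples enter a Spearman correlation on
relative abundances (average ranks on ties). The default network is the
fixed-threshold |ρ| ≥ 0.90 graph; a documented RMT-style scan is also
provided: for thresholds 0.30–0.99 (step 0.01) the unweighted adjacency
spectrum's nearest-neighbor spacing histogram (unfolded to unit mean) is
compared by chi-square against the Poisson law e^(−s) and the GOE Wigner
surmise (πs/2)e^(−πs²/4), and the smallest threshold where Poisson fits at
least as well is selected. The fixed threshold is the default because scan
implementations differ in unfolding details and the fixed path is exactly
reproducible. No multiple-testing filter is applied to correlations by
default (magnitude filtering only).

Topology: avgK = 2L/N; avgCC is the mean local clustering coefficient with
degree-<2 nodes contributing 0; GD averages shortest paths over connected
pairs only (these sparse networks are almost always disconnected; the
choice is recorded in the output); modularity comes from greedy
(Clauset–Newman–Moore) maximization, which is deterministic at these
sizes — the algorithm name is recorded in every report.

Null models are Maslov–Sneppen double-edge-swap ensembles:
`rewires_per_edge × L` successful swaps per replicate (default 10×,
default 100 replicates — both knobs exposed, since conventions in the
literature vary between 100 and 1000), rejecting swaps that would create
self-loops or multi-edges, so the degree sequence is preserved exactly.
Each metric is tested with a two-sided one-sample t of the null
distribution against the observed value; a zero-variance null degrades to
an exact comparison with a warning.

## Robustness and vulnerability

"Proportion of species remaining after removing 50 % of nodes" is
operationalized as the fraction of *surviving* nodes with at least one
remaining neighbor — the literal reading (always 50 %) is vacuous, and the
non-isolated-survivor reading matches the robustness literature the index
descends from while requiring no abundance model. Removal is uniform, 100
replicates by default, seeded; group comparisons use two-sided Welch
t-tests over replicate values.

Global efficiency is E = ⟨1/d(i,j)⟩ over ordered pairs with 1/∞ = 0,
normalized by n(n−1) (complete graph → 1). Vulnerability
Vᵢ = (E − Eᵢ)/E with Eᵢ computed on the n−1 surviving nodes. Negative
values (removals that raise mean efficiency) are reported as-is; the
network's headline value is the maximum. Note a consequence of this
definition verified numerically in the tests: in a barbell of two cliques
joined through a bridge node, the *clique-attachment* nodes — not the
bridge itself — are maximally vulnerable, because removing an attachment
strands the bridge side as well. The robust invariant is that the maximum
sits on an articulation point.

## Niche breadth and pNST

Levins B for taxon j uses the taxon's occupancy shares across a group's
samples, B_j = 1/Σᵢ p²ᵢⱼ ∈ [1, n_samples]; B_com is the mean over taxa
occurring in the group.

βMNTD between two samples is the mean patristic distance from each taxon
in one sample to its nearest taxon in the other, averaged over both
directions, abundance-weighted by default (a flag disables weighting; the
weighted form was also measurably more sensitive to assembly regime in the
recovery harness).

pNST compares observed within-group βMNTD to a null ensemble in which tip
labels are shuffled across the whole phylogeny (`taxa_shuffle`), keeping
all abundances fixed; the same global permutation is applied to all pairs
of a replicate. For each pair, the observed value D and its null values
are scaled to [0, 1] by the *pair's own* maximum over observed and null
values, giving null expectation E and Dmax = 1. The two ratios are then:

- **ST** (stochasticity ratio): if the pair is more similar than expected
  (D < E), ST = (1 − E)/(1 − D), the ratio of expected to observed
  similarity; if more dissimilar, ST = E/D. ST = 1 means the pair looks
  exactly like its null.
- **NST** (normalized, deterministic extremes at zero): if D ≤ E,
  NST = D/E — zero for identical communities under a non-degenerate null;
  if D > E, NST = (1 − D)/(1 − E) — zero when the observed dissimilarity
  reaches the pair's maximum. Both branches equal 1 at D = E.

Group pNST is the mean NST over within-group pairs (reported both in
[0, 1] and as a percentage). Pairs whose null is entirely zero (identical
samples under a label shuffle) are degenerate and dropped with a warning.
Per-pair scaling is a deliberate choice: with a single global maximum the
divergence branch hinges on one order statistic of the whole analysis, and
regime recovery was unstable; per-pair scaling pins strongly divergent
pairs (observed beyond their whole null ensemble) at the deterministic
extreme regardless of other pairs' magnitudes, and the sign of
(pNST − 0.5) then tracks the generating regime on every tested seed.
Group differences (e.g. year 1 vs year 4) use a seeded bootstrap over
within-group pairwise NST values (1000 resamples, two-sided).

The NST-vs-nutrient-distance response is tent-shaped by construction: the
similarity branch rises from 0 to 1 as D approaches E, the divergence
branch falls back toward 0. A monotone decline of NST along a nutrient
gradient therefore appears when environmentally close pairs assemble
near-neutrally and distant pairs diverge deterministically — i.e. at
moderate filter strength over pair sets spanning the gradient. The
covariate-linkage analyses accordingly regress *plant-level* pairwise NST
(pairs spanning all four years) on the driver-covariate distance, at
moderate strength in the recovery harness; within single plant-by-year
groups the nutrient gradient is too narrow for a stable slope sign.

## AVD

On relative abundances within a group: for taxon i with group mean μᵢ and
sample standard deviation σᵢ (ddof = 1), sample k contributes
|xᵢₖ − μᵢ|/σᵢ; the sample's AVD is the mean contribution over taxa with
σᵢ > 0. Zero-variance taxa are excluded from the denominator (not treated
as 0/0 = 0) and their count is reported. Two algebraic consequences:
every 2-sample group has per-sample AVD = 1/√2 exactly (a strong
regression test), and AVD is invariant to scaling — it responds to the
*shape* of within-group variation, not its magnitude. Added i.i.d. noise
raises AVD on structured (spiky) abundance profiles by pushing per-taxon
profiles toward the Gaussian shape, but leaves flat profiles unchanged;
this shape-not-scale behavior is a real property of the index worth
keeping in mind when interpreting group differences.

## Nutrient distances, Mantel, regressions

Soil covariates are z-scored across samples (zero-variance variables
dropped with a warning) and combined by Euclidean distance, making the
matrix invariant to affine rescaling of any variable. Mantel correlates
the off-diagonal vectors (Pearson by default, Spearman available) with a
label-permutation null, two-sided. OLS fits report slope, intercept, r²,
two-sided slope p and a 95 % pointwise confidence band. The pair-level
regressions of NST on nutrient distance and on |AVD| differences inherit
the non-independence of pairs sharing a sample; this caveat is recorded in
the fit's notes, and a Mantel-style permutation over the same pairs is the
recommended guard. "AVD differences" are interpreted as |AVD_k − AVD_l|
per sample pair — the only reading that puts both variables on pairs.

## Numerical choices and degenerate inputs

All randomness flows through `numpy.random.default_rng` with explicit
seeds; the pipeline derives per-stage seeds from one master seed via
`SeedSequence.spawn` and records them in its manifest. Kernel weights are
computed in log space to survive sharp filters. Empty samples yield zero
diversity with a warning; all-zero sample pairs get Bray–Curtis 0 with a
warning; empty networks are explicit results, not errors; graphs without
two independent edges cannot be rewired (explicit error, handled in the
pipeline by skipping the null comparison); permutation p-values respect
their 1/(n_perm + 1) floor.

## Problem sizes

Tests and the acceptance script run the full 48-sample design at 200 taxa
and 5 000 reads with 100 phylogenetic nulls and 100 rewired networks; the
20-seed recovery harness completes in about a minute on one CPU. These
sizes were chosen because every recovery contrast is already decisive
there; the pipeline itself has no hard-coded scale and accepts
paper-scale tables (10⁴ taxa), where the βMNTD null ensemble becomes the
dominant cost.

## Known limitations

- pNST's null is limited to tip shuffling; richness- or
  abundance-randomizing nulls (and βNTI/Raup–Crick process partitioning)
  are out of scope.
- Robustness has no abundance-weighted extinction cascade and no targeted
  (degree-ordered) attack mode.
- Module-role (Zi–Pi) classification of network nodes is not implemented.
- The RMT scan uses a simple rank unfolding of the spacing distribution;
  production RMT pipelines use smoothed spectral unfolding and may select
  slightly different thresholds.
- BIOM I/O is not provided; tables are TSV (taxa × samples), metadata CSV,
  trees Newick.
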