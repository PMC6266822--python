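# Methods

This note documents the statistical procedures, the synthetic-data model,
the numerical choices and the known limitations of `dcenet`.

## Study design assumptions

The pipeline expects a repeated-measures design: every sample belongs to one
individual, every individual to exactly one group, and each individual is
profiled at the same T ≥ 3 time points (complete series; incomplete series
are an error, not silently dropped). Expression values are assumed already
normalised, on a log2 scale, with no missing entries. Gene identifiers are
opaque strings; no identifier mapping is performed.

## Background filtering

Y-chromosome genes carry no true signal in female samples, so their measured
female expression estimates the platform noise floor. The default threshold
pools every (Y gene, female sample) value into one vector and takes its
median. The phrase "median Y-gene expression in females" admits a second
reading — the median of per-gene medians — which is available via
`method="per_gene"`; pooling was chosen as the default because it is a
single order statistic of the raw values and therefore insensitive to how
values are grouped into genes. Filtering then removes every gene whose
median over *all* samples of both groups is equal to or lower than the
threshold (the boundary is removed). Consequence worth knowing: genes with
strong expression in only half the samples (e.g. truly male-specific genes
in a half-male cohort) have an all-sample median between floor and
baseline and will *survive* the filter; the filter targets genes that are
background everywhere.

## Paired differential expression

Within one group, gene-wise differences d_i = x(t_B, i) − x(t_A, i) are
formed per individual (≥ 3 individuals required), so each individual serves
as its own control. log2FC is the mean of d_i, and the signed linear fold
change is +2^log2FC for up- and −2^(−log2FC) for down-regulation, so a
single gate |FC| ≥ 1.2 treats both directions identically. The boundary
semantics are asymmetric by design: |FC| exactly at the threshold passes
(≥), p exactly at the threshold fails (<).

Two tests are offered:

* `paired_t` — one-sample t on d_i with df = n − 1. Zero-variance genes get
  p = NaN, are flagged, and can never be significant.
* `moderated_paired_t` (default) — the same statistic with the per-gene
  variance replaced by the empirical-Bayes posterior
  s̃²_g = (d₀·s₀² + df·s²_g)/(d₀ + df), and df + d₀ degrees of freedom.
  The prior (d₀, s₀²) is fitted by method of moments on log sample
  variances: with z_g = log s²_g, E[z] and Var[z] under
  s²_g ~ s₀²·F(df, d₀) are matched using digamma/trigamma identities, and
  d₀ is recovered with a Newton inversion of the trigamma function. When
  the observed spread of log variances does not exceed the sampling
  expectation, d₀ = ∞ and all genes share s₀² (the reference distribution
  becomes normal). d₀ = 0 reproduces the plain paired t exactly, which the
  tests assert to machine precision. Genes with zero sample variance are
  excluded from the prior fit but still receive a posterior variance
  (d₀·s₀²/(d₀+df)) when d₀ > 0.

Multiple testing uses Storey q-values: π₀(λ) = #{p > λ}/(m(1−λ)) on
λ ∈ {0.05, …, 0.95}, smoothed with a cubic polynomial and evaluated at
λ = 0.95, clipped to [1/m, 1]; the q-value of the i-th ordered p is
min_{j≥i} π₀·m·p_(j)/j capped at 1, so ties share a q. With π₀ = 1
(`pi0_method="fixed"`) this is exactly Benjamini–Hochberg, which the tests
verify against an independent step-up implementation. With fewer than 30
p-values the smoother is unstable and π₀ falls back to 1 (conservative).
The significance gate is stated on raw p (q-values are reported alongside),
matching the workflow this package operationalises.

## Within-individual correlation networks

For each individual, Pearson correlations of all gene pairs across that
individual's time-ordered values; a gene with zero variance across its T
points yields NaN correlations (including its own diagonal). For each pair,
the qualifying set Q holds the individuals with defined |r_i| ≥ cutoff
(default 0.6). The pair becomes an edge iff

* |Q| / n_individuals ≥ support fraction (default 0.25) — the denominator is
  always the full group, so NaNs count against support (conservative), and
* every r_i, i ∈ Q, has the same sign.

The edge weight is the mean r over Q only, which guarantees
|weight| ≥ cutoff and makes the edge sign stable; averaging over all
individuals is deliberately not used because near-zero non-qualifying
correlations would wash out the sign that the overlap stage depends on.
"Support" is read as a fraction of *individuals*, not arrays: one
correlation series exists per individual, so individuals are the natural
sampling unit.

A subtlety the property tests document: the edge rule is monotone in the
support fraction, but *not* in the cutoff — raising the cutoff can remove
the single conflicting qualifier of a sign-discordant pair and thereby
newly admit it. This is an unavoidable consequence of combining a qualifier
threshold with a sign-consistency veto.

The overlap network intersects two group networks edge-wise, keeping pairs
present in both with equal sign; weight = mean of parent weights,
support = min of parent supports. The operation is commutative, idempotent
and associative in edge set.

## Frobenius variability diagnostic

The distance between two correlation matrices is the Frobenius norm of
their difference, summed over the full matrix (both triangles and the
diagonal). Undefined entries are excluded pairwise by default
(`on_nan="error"` available). Each individual's matrix is compared against
the entry-wise NaN-aware mean matrix of its group; the resulting profile,
sorted descending, ranks individuals by how atypical their co-expression
structure is and is the in-package analogue of manual outlier screening.
On fully-defined matrices the distance is a true metric (non-negativity,
symmetry, triangle inequality — property-tested on random triples).

## Clustering and over-representation

Communities are computed on the unweighted topology of the network.
Connected components smaller than `min_cluster_size` (default 3) are
labelled "unclustered" — isolated correlated pairs are real signal but not
clusters — and the rest is partitioned by greedy modularity maximization
(Girvan–Newman with the best-modularity cut is available behind the same
interface; the algorithm is a deterministic choice, and any community that
ends up smaller than `min_cluster_size` is also labelled unclustered so
every numbered cluster honours the size floor). Cluster ids are dense from
1 in order of decreasing size, ties broken by smallest member id, so runs
are reproducible without randomness.

ORA: for each gene set, K = |S ∩ universe|, k = |S ∩ query|, and
p = P(X ≥ k) under Hypergeom(N, K, n). Default gates follow common
pathway-tool practice: minimum overlap 2, p ≤ 0.01, plus an optional
"number OR percentage" gate (k ≥ min_genes or k/K ≥ min_fraction).
Benjamini–Hochberg adjustment runs over all tested sets (every set with
K > 0), not just reported rows. The universe defaults to the
background-filtered gene list rather than the whole genome — testing
enrichment against genes that could never have been observed inflates
significance. Gene-ontology hierarchy traversal is out of scope; GMT files
carry whatever granularity the user supplies.

## Synthetic study generator

Per module m active in a group and per individual i, a latent trajectory
z_i(1) = 0, z_i(t+1) = z_i(t) + shift_t + N(0, 1), with shift applied only
between the first two time points (default −1.0 log2 units) — group-level
change concentrated between the first two visits, individual variation as a
unit-step random walk. A member gene reads
baseline_g + sign_g·loading·z_i(t) + N(0, noise_sd). Defaults: 2 groups of
12 individuals, T = 3, five 8-gene modules (three shared, one unique per
group), 25 % mirrored members, loading 1.0, noise 0.25, 200 background
genes at a flat 4.0 log2 floor, 20 Y genes (baseline in males), female
fraction 0.5, baselines N(8.0, 0.5).

Y genes in females sit at the floor plus a small offset (0.3 log2 units,
`y_female_offset`), emulating cross-hybridization residue; this places the
filter threshold strictly above the background genes' own median so the
filter's behaviour on background genes is deterministic rather than a coin
flip at the boundary. Sexes are assigned deterministically (first
⌈f·n⌉ individuals per group female, at least one female overall). One RNG
stream per study, consumed in a fixed documented order, makes studies
bit-reproducible; the truth object records every gene's role and sign and
the planted edge sets per group and shared across groups.

What the generator does **not** emulate: probe-level noise, batch effects,
missing time points, heavy-tailed intensity distributions, correlated
noise between modules, and realistic chromosome structure. Passing the
planted-recovery tests therefore demonstrates that the machinery recovers
the structure it is designed for under its own assumptions, not that any
particular real dataset would yield comparable recall.

## Numerical and scale choices

* All simulation-based tests and the acceptance script run the default
  study (260 genes, 24 individuals, 72 samples) or a 2000-gene null study;
  the full pipeline completes in about a second, chosen so the whole suite
  stays interactive.
* Correlations are clipped to [−1, 1] and symmetrised after `corrcoef` to
  absorb float round-off; matrices are validated for symmetry and range.
* Expression TSVs are written with shortest round-trip float repr and read
  with `float_precision="round_trip"`, so write→read is bit-exact; edge
  lists store weights via `repr` for the same reason.
* Storey's smoother uses a cubic polynomial fit (a deterministic,
  dependency-light stand-in for a smoothing spline with similar df).

## Known limitations

* With T = 3 time points the per-individual Pearson null is U-shaped
  (density ∝ (1−r²)^(−1/2)), so |r| ≥ 0.6 is weak evidence per individual;
  the support and sign-consistency rules recover precision only partially.
  Under the default generator settings, within-module edge recall per group
  is typically 0.7–0.85 with false-edge rates well above a few percent, and
  the overlap network is a conservative subset of the planted shared edges
  — the acceptance report computes the exact values for a given seed. The
  shared group-level trajectory shift also induces genuine positive
  cross-module correlation; such edges are "false" against the planted
  modules but are not artefacts of the implementation.
* The background filter keys on an all-sample median, so sex-specific genes
  in mixed cohorts survive it (see above); they are subsequently inert in
  the paired contrasts because their expression is time-constant.
* Variance moderation assumes exchangeable gene variances around one prior;
  strong variance structure (e.g. intensity-dependent) is not modelled.
* The community algorithm is a modularity heuristic; it is deterministic
  but not guaranteed optimal beyond the small exhaustively-verified cases
  in the test suite.
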