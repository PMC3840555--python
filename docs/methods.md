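# Methods

## Effective-number diversity profiles

The central quantity is the similarity-sensitive effective diversity of
order q of a community with relative abundance vector p over its S present
taxa and similarity matrix Z (S × S, entries in [0, 1], unit diagonal):

    qD_Z(p) = ( Σ_i p_i (Zp)_i^(q−1) )^(1/(1−q)),   (Zp)_i = Σ_j Z_ij p_j.

(Zp)_i — the "ordinariness" of taxon i — is the expected similarity of a
randomly drawn individual to taxon i; it always lies in [p_i, 1]. The
formula has removable singularities at q = 1 and q = ∞, evaluated by their
limits exp(−Σ p_i ln (Zp)_i) and 1/max(Zp)_i. The result is an effective
number in [1, S]: the size of a community of equally abundant, completely
dissimilar taxa with the same diversity. Key consequences, all enforced
as tests:

* non-increasing in q (larger q discounts rare taxa);
* with Z = I the profile is the classical Hill-number family, so q = 0 is
  richness, q = 1 is exp(Shannon H), q = 2 is inverse Simpson, and q → ∞
  is the reciprocal Berger-Parker index;
* adding similarity can only lower diversity ((Zp)_i ≥ p_i);
* the all-ones Z collapses every community to diversity 1; consequently
  "no similarity information" must be modelled by the *identity* matrix,
  not by Z_ij ≡ 1 — the package's naïve case is Z = I;
* doubling: two completely dissimilar copies of a community at half
  abundance have exactly twice the diversity.

Numerics: the q = 1 branch engages within |q − 1| < 1e-9; communities
larger than 1000 taxa are evaluated in log space (log-sum-exp) so profiles
of tens of thousands of OTUs cannot underflow; q = ∞ is a sentinel
(`math.inf`). Default grid: 0 ≤ q ≤ 5 in steps of 0.05, dense enough to
cover the conventional 1 ≤ q ≤ 2 inset without re-evaluation. Taxa with
zero abundance are dropped (logged) before any profile computation.

## Phylogenetic similarity

Trees are rooted, tips uniquely labelled, branch lengths non-negative
(Newick I/O via dendropy; explicitly unrooted input is midpoint-rooted and
logged, since the balance and UniFrac statistics need a root). Taxon
similarity comes from patristic distance d_ij through

* exponential (default): Z_ij = exp(−d_ij/s), s > 0 a decay scale;
  s = "auto" sets s to the mean off-diagonal patristic distance, making a
  typical pair's similarity 1/e independent of the tree's depth units;
* linear: Z_ij = max(0, 1 − d_ij/d_max).

Both transforms map zero distance to similarity 1 and are monotone
decreasing; the choice and scale are recorded in run configs. The
patristic matrix is computed by a single post-order pass (d_ij = depth_i +
depth_j − 2·depth(LCA), merging tip blocks with vectorized outer sums), so
a 2048-tip matrix takes seconds. Pruning a tree to a taxon subset
preserves pairwise path lengths exactly (unifurcations collapsed, lengths
summed) — therefore the similarity matrix of a pruned tree equals the
exponential transform of the corresponding distance sub-matrix, a fact the
simulation engine exploits and a test asserts.

## Tree balance

Colless' I sums |L − R| over internal nodes of a strictly bifurcating
rooted tree (polytomies are an error unless a random-resolution seed is
supplied, which is then recorded). The Yule normalization
(I_C − E_Yule)/n with E_Yule = n·ln n + n·(γ − 1 − ln 2) (γ the
Euler–Mascheroni constant) centres the statistic at its pure-birth
expectation and makes values comparable across tree sizes; real microbial
OTU trees in the motivating datasets range from about 0.3 to about 35 on
this scale. The statistic is topology-only and affine in I_C at fixed n.

## Community dissimilarity

Four pairwise metrics, all symmetric, zero on identical samples and
bounded by [0, 1] so dendrogram heights are comparable:

* unweighted Jaccard, 1 − |A∩B|/|A∪B| on presence sets;
* abundance-weighted Jaccard in the min/max (Ružička) generalization,
  which reduces to classical Jaccard on binary data;
* unweighted UniFrac: unique / observed branch length over the edges
  leading to either sample's taxa;
* weighted UniFrac in the normalized form Σ l_e|p^A_e − p^B_e| /
  Σ l_e(p^A_e + p^B_e), with p^X_e the fraction of sample X's abundance
  below edge e.

On an equal-branch star tree unweighted UniFrac equals unweighted Jaccard
exactly (both reduce to set overlap). Hierarchical clustering uses Ward's
minimum-variance linkage in the ward.D2 convention (Lance–Williams on
squared dissimilarities, via scipy); a hand-coded agglomeration oracle
cross-checks merge order and heights in the tests, and dendrograms export
to Newick with merge heights as branch lengths.

## Synthetic communities and trees

The generator reproduces the statistical structure of the simulation
study; its defaults are the study conditions.

Rank-abundance families (parameters recorded per run):

| family | realization | default |
| --- | --- | --- |
| uniform | all abundances equal | — |
| geometric | rank r gets k(1−k)^(r−1) | k = 0.01 |
| log normal | i.i.d. exp(N(meanlog, sdlog)) | meanlog 0, sdlog 1.5 |
| log series | i.i.d. logarithmic(x), x = N/(N+α) | α = 1, N = 10⁵ |

The geometric retention k = 0.01 keeps all 2048 ranks above ~1e-9 of the
total (k = 0.5 would underflow beyond rank ~1000); sdlog 1.5 is a typical
fitted spread for microbial abundance data; α = 1 is the study's stated
log-series diversity, with N = 10⁵ reads a typical deep-sequencing library
size. For the log series, a fixed richness S is obtained by S i.i.d.
logarithmic draws (a 2048-taxon pool at α = 1 is impossible under the full
Fisher ensemble, which ties S to α and N); with `n_taxa=None` the full
ensemble is realized instead (Poisson species count, mean α·ln(1 + N/α)),
and a parameter-recovery test confirms the realized Fisher's alpha —
obtained by solving S = α·ln(1 + N/α) with bracketed Brent iteration —
matches the generating value within 10% at N = 10⁴.

Topologies use Aldous beta-splitting: a clade of m tips splits (i, m−i)
with weight Γ(β+1+i)Γ(β+1+m−i)/(i!(m−i)!). β → ∞ is the deterministic
balanced split, β = 0 Yule-like, β = −2 the caterpillar limit; one
parameter thus spans the full balance range, and the *realized*
Colless-Yule value is always recorded and reported, since tree shape, not
the nominal parameter, is the scientifically meaningful covariate. At
2048 tips, β = {10, 0, −1} realize roughly {−4, 0, +9} and β = −1.8
roughly +360 on the Colless-Yule scale.

Branch lengths: `ultrametric` draws each internal node's age uniformly on
(0, parent age) below a root at age 1 — every root-to-tip path is exactly
1, so the exponential similarity scale is comparable across trees;
`nonultrametric` draws i.i.d. Exponential(1) lengths per edge. Every
stochastic operation is a pure function of (inputs, seed), with seeds
spawned from a master seed through `numpy.random.SeedSequence` at fixed
child indices, so any sub-run reproduces independently.

## The agreement experiment

One pool pair per condition: a shared 2048-tip tree and two independent
abundance draws from the same family (deterministic families are randomly
permuted across tips so the two communities differ in placement). Per
iteration (100 per condition), one subsample is drawn from each community
and the naïve and tree-similarity effective diversities are compared at
q ∈ {0, 1.1, 3.1, 5.1}; the per-q agreement proportion is the fraction of
iterations in which both metrics pick the same winner. Ties in both
metrics count as agreement; a tie in only one counts as disagreement.

Subsampling draws n reads multinomially from the community's relative
abundances, as sequencing does, so observed richness varies between
subsamples. Drawing n *distinct* OTUs uniformly instead (available as
`sampling="otus"`) fixes both subsamples' richness at n, which makes the
naïve side tie identically at q = 0 (and at every q for the uniform
family) and turns those comparisons into guaranteed disagreements under
the tie rule — a degenerate design that cannot produce the observed
near-50% agreement structure; it is kept for comparison but is not the
default. Each subsample's similarity matrix is rebuilt from its own
pruned tree with the per-sample "auto" scale (computed equivalently, and
much faster, from the pool distance sub-matrix).

The default grid is 4 families × {ultrametric, non-ultrametric} ×
3 imbalance levels (β = 10, 0, −1.8) × sample sizes {64, 128, 256, 512} =
96 conditions. Summaries: the pooled mean of the 384 condition-by-q
agreement proportions and their empirical 2.5th/97.5th percentiles (the
"95% interval" is read as this empirical spread across experiments — a
parametric CI of a mean over hundreds of proportions would be far
narrower than the tens-of-points spread observed).

Trend analyses mirror the four panels of the simulation figure: sample
size and ultrametricity from grid marginals; skew and imbalance as
within-log-series sweeps (agreement vs Fisher's alpha at fixed moderate
imbalance, and vs realized Colless-Yule over β ∈ {10, 0, −0.5, −1, −1.3},
spanning roughly −4 to +30 — the range real OTU trees occupy) with 10
replicate pool pairs per level, summarized by the sign of the Spearman
correlation of level means. Cross-family marginals are *not* used for the
skew trend: family identity confounds it (the uniform family's naïve
rankings are near-ties, depressing its agreement for reasons unrelated to
skew).

The two-proportion Z test (pooled standard error, two-sided normal
p-value) quantifies when two agreement proportions differ significantly;
at 100 trials each near p̄ = 0.5 the minimal significant difference at
α = 0.05 is ≈ 0.139.

## Problem sizes and runtime

The full grid (96 conditions × 100 iterations, 2048-OTU pools) runs in
about half a minute; the trend sweeps add about a minute; the complete
test suite, including the grid, runs in under three minutes on one CPU.
These sizes reproduce the study's stated conditions exactly (pool size,
sample sizes, iteration count, q values); only the number of imbalance
levels and sweep replicates are choices of this package, recorded above.

## Known limitations

* The exact tree-to-similarity transform behind the original analysis is
  not published; the exponential/auto choice here is recorded per run, and
  conclusions are restricted to ranking behaviour and simulation
  summaries, not exact profile values on the original datasets.
* The four environmental datasets (and hence their profile figures,
  Colless values and dendrograms) are not redistributed; the pipeline
  reproduces those computations on simulated data only.
* Simulated pools are abstract OTU communities: no sequencing error, no
  chimeras, no clustering artifacts, no compositional bias — agreement
  rates on real libraries may differ for those reasons.
* The skew and imbalance effects on agreement are small (a few points
  across realistic parameter ranges); their signs are stable under the
  recorded seeds but individual re-randomizations can wobble.
* No coverage-corrected (rarefaction-extrapolated) diversity estimation:
  profiles are computed on observed abundances.
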