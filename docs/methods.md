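# Methods

## Model and scope

`fibergraph` analyzes white-matter structural connectivity as a weighted,
undirected graph on the 90 cerebral regions of the AAL parcellation. The
input contract begins *after* tractography: each streamline is already
resolved to an unordered pair of atlas regions (how a streamline is assigned
to a pair — endpoint vs. traversal rules — belongs to the tractography
pipeline and is out of scope). The edge weight is the streamline count, and
a pair is considered anatomically connected only when joined by at least
`min_fibers = 4` streamlines, the usual guard against false-positive
connections; surviving edges keep their raw count (the network is weighted,
not binarized).

## Graph measures and conventions

* **Lengths.** The field reports fiber counts as connection *strength*
  without fixing a strength-to-distance map; we use the standard reciprocal
  convention, edge length `1/w`, so path-based measures reward strong
  connections. A `binary` flag computes hop-count paths instead; weighted
  is the default everywhere. Because edge lengths are reciprocal counts,
  efficiencies are on the scale of counts (a network with typical weight 40
  has `E_glob` of order 30), and per-node efficiencies lie in `[0, max w]`.
* **Disconnection.** `1/∞ = 0` in every efficiency sum; the characteristic
  path length `L` averages over connected ordered pairs only and reports
  the number of excluded pairs. This is the only convention that keeps all
  measures finite and monotone under edge addition.
* **Clustering.** `C_i = E_i / (K_i(K_i−1)/2)` counts edges among node
  *i*'s neighbors against the possible maximum — an inherently binary
  formula — so it is evaluated on the thresholded binary adjacency, while
  path measures stay weighted. Nodes with fewer than two neighbors score 0,
  as do such nodes in local efficiency.
* **Local efficiency.** The subgraph `G_i` contains exactly node *i*'s
  direct neighbors (not *i* itself); paths are recomputed strictly inside
  it, so a route through an outside node does not count.
* **Hubs.** A node is a hub when its nodal efficiency is at least (`≥`,
  inclusive) one *sample* standard deviation (denominator n−1) above the
  network mean. A numerically constant efficiency vector yields no hubs.
* **Null model.** Degree-preserving Maslov–Sneppen double-edge swaps; the
  two edges' weights travel with them, so every null has the input's exact
  binary degree sequence and weight multiset. Per null network the swap
  budget is `ceil(swap_fraction × E)` attempted swaps per sweep (default
  `swap_fraction = 0.5`) over `n_iter = 1000` sweeps — the "rewire half the
  edge pairs, iterated 1,000 times" recipe common in this literature, which
  is far past mixing. The ensemble size is configurable (default 100
  nulls). `C_rand` and `L_rand` are ensemble means, and
  `σ = γ/λ = (C/C_rand)/(L/L_rand)` exactly. The swap kernel is
  numba-compiled; the ensemble is deterministic given a seed.

Shortest paths use Dijkstra (scipy's `csgraph`) on the reciprocal-length
graph; the test suite cross-checks every path-based measure against an
independent plain-Python Floyd–Warshall oracle at 1e-10 on hundreds of
random graphs.

## Statistical inference

The group comparison follows the regress-then-permute order: covariates
(age in years, gender as a 0/1 indicator with female = 1, education in
years, intracranial volume in mm³) are removed once by OLS — residuals are
exactly orthogonal to the design — and group labels are then permuted on
the residuals. The statistic is the difference of residual group means
(first group minus second, AD − NC by default, so deficits are negative);
the two-tailed p-value uses the add-one convention
`p = (1 + #{|T_perm| ≥ |T_obs|})/(n_perm + 1)`, which cannot reach zero.
Default `n_perm = 5000`. All tests at one level (5 global measures, 90
nodes, the tested edges) share the same label permutations and form one
Benjamini–Hochberg FDR family at q = 0.05. Edge-level tests additionally
report the uncorrected p < 0.05 flag, since edge-level findings in this
literature are often reported uncorrected; an edge is tested only when
present in at least half the subjects of at least one group (degenerate
all-zero edges would make the permutation distribution a point mass).
Reported group means ± SD are of the *raw* measures; the `difference`
column and p-value come from the regressed residuals.

Measurement of a subject's small-world ratios uses that subject's own null
ensemble with a per-subject seed spawned from the comparison seed, so the
whole pipeline is bit-reproducible for a fixed seed.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, at
the matrix level:

* **Topology.** One template per cohort: a Watts–Strogatz ring lattice
  (`lattice_k = 36` neighbors, rewiring probability 0.1) giving ≈40%
  connection density — the range reported for ≥4-fiber thresholded
  networks — and small-world organization (σ well above 1); or a
  density-matched uniform random graph (σ ≈ 1) as a negative control.
* **Weights.** Present edges draw integer counts from a negative binomial
  with mean 40 and dispersion 8 (SD ≈ 15, the overdispersion typical of
  count data), floored at the 4-fiber threshold.
* **Subjects.** Each subject multiplies the template edgewise by lognormal
  noise (`noise_sd = 0.1`) and by a global covariate factor
  `exp(Σ_c β_c (c − c̄))` with small default slopes (age −0.004/yr,
  education +0.005/yr, ICV +2e−7/mm³), so the nuisance regression has real
  structure to remove. Covariates sample around a typical elderly cohort:
  age ≈ 70 ± 7 yr, education ≈ 10 ± 3 yr, ICV ≈ 1.45e6 ± 1.3e5 mm³,
  gender Bernoulli(½). Default group sizes are 26 patients vs 16 controls,
  matching the cohort scale this analysis is designed for.
* **Planted effect.** In the patient group only, weights of edges incident
  to `affected_nodes` (plus explicit `affected_edges`) are multiplied by
  `effect_multiplier ∈ (0, 1]`, re-rounded, and present edges are floored
  at the threshold. The floor means the planted effect never changes the
  binary topology: the clustering coefficient and γ are therefore identical
  between groups by construction, the deficit expresses itself in weighted
  measures (`E_glob`, `E_loc`, `E_i`, edge counts, λ), and thresholding
  cannot interact with noise in effect-free cohorts — which keeps the
  type-I calibration clean. A consequence worth knowing: with a planted
  deficit, σ falls in the patient group (γ flat, λ up), whereas real
  degeneration that also removes connections can raise γ and σ.

What the generator does *not* emulate: tractography biases (path-length and
curvature effects, crossing-fiber failures), site/scanner effects,
region-specific covariate structure, or topology differences between
groups. Passing tests therefore certify the pipeline's statistical
behavior under its own assumptions, not robustness to imaging artifacts.

## Problem sizes and numerical choices

The test suite exercises oracle equivalence on 500 random graphs of ≤15
nodes; calibration uses 200 effect-free cohorts of 26+16 subjects with
1,000 permutations (empirical type-I at nominal 0.05 within [0.02, 0.09];
power ≥ 0.8 for a one-pooled-SD global-efficiency deficit, planted at the
measure level so no generator knob needs tuning); recovery uses a 30/30
cohort with a 0.5 multiplier on 10 nodes, 5,000 permutations. Small-world
discrimination uses 20 seeded ring lattices (4 neighbors per side) against
100 nulls each. Ties in the permutation test are counted with a 1e-12
relative tolerance; residual vectors within 1e-10 (relative) of zero are
snapped to exact zero so constant measures give p = 1.

## Limitations

Betweenness, modularity, rich-club and FA/MD-weighted variants are out of
scope. The package analyzes 90-node networks by contract; the metric
functions themselves are size-agnostic and are tested on small graphs.
Edge-level FDR is applied within the prevalence-filtered edge family;
families are never pooled across levels.
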