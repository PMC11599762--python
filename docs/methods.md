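# Methods

## Signals and co-fluctuations

Panels are `N × T` real matrices, one row per parcellated region. All
z-scoring uses the population standard deviation (`ddof = 0`); this choice
makes the temporal-unwrapping identity exact: the time mean of the raw
product of two z-scored rows equals their Pearson correlation to machine
precision. For every strictly increasing tuple of `k + 1` regions the raw
product series is standardized over time and given a parity sign: +1 when
the instantaneous values are all positive or all negative, −1 when signs are
mixed. Zeros break concordance only when both a positive and a negative
value are present at the same frame; an all-zero or zeros-with-one-sign
frame counts as concordant (a measure-zero event that needs a deterministic
rule). Orders are capped at `k = 2` by default (edges and triangles);
higher orders are accepted but combinatorially expensive.

Edge functional connectivity (eFC) correlates the *raw* edge product series
(the classic edge time signals), not the parity-signed weights; the signed
variant is available via `efc_matrix(..., use="signed")`. Because the eFC
matrix is `C(N,2) × C(N,2)`, it is guarded by a configurable region cap
(default 60).

## Per-frame topology

At each frame the edge and triangle weights form a weighted complex. A
triangle is *violating* when its weight strictly exceeds the minimum of its
three edge weights; ties do not violate, so a retained triangle never
precedes its slowest edge in the descending filtration and every filtration
step is a valid simplicial complex. Violating triangles are excluded from
the complex and logged with their signed weights.

H1 persistence is computed by the standard Z/2 column reduction,
implemented in two passes: a union-find pass classifies edges as
tree-forming or cycle-creating and records each creator's birth cycle (the
edge plus the tree path between its endpoints — the standard birth-cycle
representative; representatives are not unique, and scaffolds inherit this
choice); triangle boundary columns are then reduced against each other with
bitset arithmetic, pairing each with the cycle-creating edge at its final
pivot. Conventions the persistence literature leaves open are fixed as
follows:

* bars live on the weight scale with `birth ≥ death` and persistence
  `π = birth − death ≥ 0` (a descending filtration);
* sort ties break by dimension (edges before triangles) and then
  lexicographic tuple order; vertices are present from the start;
* essential cycles (never filled) die at the frame's minimum simplex
  weight, which keeps every diagram functional finite;
* generators of essential and finite bars alike enter the frequency
  scaffold, whose edge weight counts the generators containing that edge.

Hyper-coherence is the fraction of coherent (positive-weight) triangles
that violate closure, averaged over frames; a frame without coherent
triangles contributes zero. Hyper-complexity is the sliced Wasserstein
distance between the H1 diagram and the empty diagram: every bar is matched
to its orthogonal projection on the diagonal, the matching cost is averaged
over equally spaced directions (default 50, configurable) and rescaled by
π/2 so that the value converges to the exact diagonal-matching cost
`Σ |b − d| / √2` (Euclidean ground metric) as directions grow; the exact
cost is also implemented and serves as the test oracle. Cycle classes
weight each bar by its persistence: full coherence (`b, d > 0`), coherence
transition (`b > 0 ≥ d`), full decoherence (`b ≤ 0`); if all bars have zero
persistence the shares fall back to counts, and an empty diagram is
reported as undefined rather than all-zero.

## Applications

**Task decoding.** Per-frame indicator vectors (z-scored BOLD, signed edge
weights, violating-triangle weights embedded densely over all `C(N,3)`
triples, scaffold frequencies) are correlated frame against frame,
binarized at the 95th percentile of the upper-triangular off-diagonal
values (ties pass, diagonal removed), clustered with Louvain at resolution
1.0 (best modularity of 10 restarts with consecutive seeds), and scored
against the ground-truth blocks with the element-centric similarity (ECS),
damping α = 0.9. For hard partitions the ECS affinity has the closed form
`(1 − α)δ_ij + α/|c_i|` inside clusters, which the implementation uses; a
brute-force personalized-PageRank inversion is kept as a test oracle. The
decoding score reports the mean ECS over the Louvain restarts.

**Fingerprinting.** Static features per subject and session (FC upper
triangle, eFC upper triangle, time-mean violating triangles, time-mean
scaffold) enter an `S × S` matrix of test-against-retest Pearson
correlations; `I_diff = 100 · (mean diagonal − mean off-diagonal)` in
percentage points. Network-restricted scores mask features whose node sets
intersect (`at_least_one`) or are contained in (`within`) one of the eight
canonical functional systems; eFC features pool the nodes of both edges.
The subsampled variant draws subject subsets without replacement.

**PLSC.** Columns of the feature matrix and the score table are
standardized (the usual PLSC practice) before the SVD of the
cross-covariance `YᵀX/(S−1)`. Permutation significance permutes subject
rows of `Y` and, by default, compares every observed singular value with
the null distribution of the *largest* permuted singular value: because the
observed values are ordered, the probability of declaring any component
significant on null data is then exactly the nominal level (measured 0.06
at α = 0.05 over 200 replicates), while the test for the first component is
identical to the per-rank test. The per-rank ("marginal") reference is
available but inflates the family-wise rate to ≈ 0.3 with ten score
columns. Later components are assessed marginally, without sequential
conditioning or Procrustes rotation. Bootstrap salience reliability
resamples subjects with replacement, matches bootstrap components to the
original by maximal absolute correlation, aligns signs, and reports the
original salience over the bootstrap standard deviation; entries are
conventionally reliable at |z| > 2. Covariance explained sums the squared
singular values of significant components over the total. The robustness
loop repeats PLSC plus permutation on subject subsamples (defaults 80 of
100, 100 repetitions) and flags salience entries reliable in more than 60%
of repetitions. Cognitive subdomains with several raw instruments are
summarized by the first principal component of their z-scored columns,
sign-aligned so the mean loading is positive.

## Synthetic cohorts

The generator plants the statistical structure each stage is designed to
detect; its defaults are the study conditions of the validation suite.

* **Pairs** share a white Gaussian latent whose variance share equals the
  coupling, so the planted Pearson correlation equals the coupling.
* **Shared triads** use a concordant construction: a shared per-frame sign
  drawn from the fully coherent patterns times independent per-region
  magnitudes `|N(0,1)|`. This elevates positive (coherent) triple weights
  while leaking only `2c/π` pairwise correlation; the validation suite uses
  couplings ≤ 0.15 where the leak stays within ±0.1.
* **Task states** split frames into contiguous blocks. Shared triads are
  assigned round-robin to states; each state can also own a coherent
  *assembly* (default for decoding cohorts: 12 of 20 regions, coupling 0.9)
  whose magnitudes are sustained (`|N(0,1)|` offset by 4 standard
  deviations), making its edge and triangle weights nearly block-constant —
  the synthetic analogue of a sustained task-locked coherence topography.
  No pair-specific couplings are planted and overlapping assembly pairs
  keep identical couplings in every state where both members are active.
* **Identity** is planted as node-disjoint subject-specific triads with an
  amplitude-compensated concordant construction: concordant frames
  (probability 1/2, amplitude A, shared sign) alternate with mixed-pattern
  frames of amplitude `√3·A`. Mixed sign patterns have pairwise sign
  expectation −1/3, so this amplitude ratio cancels the planted pairwise
  covariance exactly: the fingerprint lives purely in third-order
  (concordance) statistics, where the signed triangle weights carry a
  strong stable offset and node FC sees nothing. Test and retest reuse the
  structural draw with fresh noise; `identity_strength` scales the
  coupling, so strength 0 makes subjects exchangeable.
* **Behavior** scores are noisy linear read-outs of the per-subject feature
  matrix along planted unit salience directions, rotated into the score
  columns by deterministic orthonormal loadings; the planted directions,
  strengths and latents are returned for recovery tests.

Randomness is split into a structural stream (cohort seed, subject id) and
a session stream, both through `numpy.random.SeedSequence`; identical specs
and seeds reproduce outputs bit for bit, and no stage touches global random
state.

### What the generator does and does not emulate

It reproduces the *statistical signatures* the indicators target — planted
pairwise correlation, coherent triadic excess beyond pairwise margins,
test/retest identity, low-rank brain–behavior covariance, block-structured
task states — with temporally white (or block-sustained) latents and
Gaussian noise. It does not model hemodynamics, temporal autocorrelation,
spatial maps, physiological confounds or realistic network topology, so
green tests certify the pipeline's correctness and sensitivity under these
idealized conditions, not performance on real recordings.

### Design notes on the validation conditions

Two structural facts shaped the validation cohorts and are worth recording
because they constrain what any synthetic test of this pipeline can show.

First, concordance and pairwise dependence are coupled: if the three signs
of a triple are pairwise independent, the probability of a fully concordant
pattern is exactly 1/4 — chance level. Planting coherent (concordance-
based) triadic structure therefore always either leaks pairwise covariance
or must compensate it through amplitude coupling (the identity
construction). A consequence for task decoding is that any cohort strong
enough to push the triangle indicator's block recovery toward ECS 1 also
hands the edge indicator a usable state signature; conversely, cohorts in
which pairwise information is matched across states cap the triangle ECS
near 0.86 at N = 20 (between-state assembly overlap shares coherent
triples, and the per-series standardization of the weights erases all
state-invariant structure, so the leak cannot be masked). The validation
suite asserts the method ordering (triangles ≥ edges ≥ BOLD), which is
robust across cohorts, at the spec'd recovery threshold.

Second, PLSC salience recovery at `F > S` requires structured features:
with isotropic Gaussian features the cosine between the recovered and
planted salience is bounded by `1/√(1 + F/S)` even for noise-free scores,
because the latent correlates with every feature through the sample
covariance. The recovery tests therefore generate factor-structured
features (five latent factors, residual 0.3) and plant the salience along a
factor loading — the regime real connectivity features live in — where
recovery reaches ≈ 0.94. The exact noise-free identity is exercised
separately with column-orthonormal features.

## Numerical choices and degenerate inputs

Constant signals, constant product series, constant feature vectors and
constant score columns raise explicit degenerate-input errors naming the
offending region, tuple, subject or column; near-constant columns are
caught with a relative tolerance because exact zero variance is not
guaranteed in floating point. Correlation matrices are symmetrized and
clipped into [−1, 1]. Frames with no coherent triangles contribute zero
hyper-coherence; empty graphs yield singleton Louvain communities;
degenerate bootstrap resamples are redrawn up to a capped number of
attempts. Validation problem sizes (N ≤ 20, T ≤ 400, 20-seed replications,
200 permutations / 200 replicates for the Type-I check) were chosen so the
whole suite runs in a few minutes on one core while keeping every
statistical assertion comfortably powered.

## Known limitations

* Generator representatives of H1 classes are not unique; scaffolds depend
  on the birth-cycle convention above and may differ from other valid
  implementations at equal bar structure.
* The essential-bar death convention (frame minimum weight) is one of
  several defensible choices and affects hyper-complexity additively.
* eFC memory grows as `C(N,2)²`; the cap exists for safety, not science.
* The per-rank permutation scheme is retained for comparability but is
  anti-conservative family-wise; the max-statistic default is exact for
  the any-component error rate and conservative for later components.
* Louvain is stochastic; determinism is provided by fixed seed sequences
  and best-of-restarts, not by the algorithm itself.
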