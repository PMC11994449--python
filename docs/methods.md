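# Methods

## The evaluation model

A single-sample subclonal reconstruction is represented as a rooted clone
tree. The germline "normal" root is a sentinel (cluster id 0) holding no
somatic SNVs; truths have exactly one clonal (truncal) node beneath it whose
cellular prevalence (CP — the fraction of all sampled cells carrying the
clone's mutations) equals the tumor purity ρ. Trees must satisfy the
pigeonhole principle: the CPs of a node's children may not sum beyond the
node's own CP, because in a single sample sibling clones occupy disjoint cell
populations inside their parent. Predictions are allowed to be multi-rooted;
every parentless cluster is treated as a child of the germline sentinel.

The internal prevalence scale is CP throughout. Cancer cell fractions
(CCF = CP/ρ) appear only at I/O boundaries (the random profile baseline draws
CCFs, as its reference definition does, and converts on output).

## Metrics and their conventions

Where the metric definitions leave freedom, this package pins the following
conventions, each backed by an oracle test:

* **sc1C / EMD.** The earth mover's distance is the first Wasserstein
  distance between the two SNV-mass distributions over CP with ground
  distance |x − y| on the unit interval, computed by the CDF-area identity
  (`scipy.stats.wasserstein_distance`). On [0, 1] this is automatically
  bounded by 1, so `1 − EMD ∈ [0, 1]` with no extra scaling constant. The
  test suite checks the fast path against a transport linear program on a
  thousand random profiles to 1e−9.
* **sc2 / AUPR.** Computed on the unordered off-diagonal SNV pairs, true
  copairings as positives, predicted coclustering probabilities as scores,
  using step-wise average precision (no interpolation). Degenerate truths
  (no positive or no negative pair) pin the component to 1 for an exact
  prediction and 0 otherwise, and are flagged.
* **sc2 / AJSD.** The per-pair Jensen–Shannon divergence, base 2, between
  Bernoulli(p_pred) and Bernoulli(p_true), averaged over unordered pairs.
* **sc2 normalization.** Each component is affinely rescaled so a perfect
  prediction maps to 1 and the worse of the two extreme references (all SNVs
  in one cluster; each SNV its own cluster) maps to 0, clamped below at 0.
  The extremes are recomputed per tumor; they depend only on the truth.
* **sc3 / PCC.** One Pearson correlation over the concatenation of the
  off-diagonal entries of the four relation matrices (cocluster, cousin,
  ancestor–descendant, its transpose) — not an average of four per-matrix
  correlations, since the definition names a single coefficient. The
  diagonal is excluded: self-relations carry no information and would only
  dilute variance. Zero variance in either stacked vector (e.g. a
  single-cluster truth) yields score 0, flagged as degenerate.
* **Reconciliation.** False-negative SNVs form one new cluster at CP 0
  attached to the germline root — for sc3 purposes its SNVs are cousins of
  every somatic SNV ("derived from the normal"). False positives are removed
  (matrix rows/columns dropped, profile masses decremented; when per-SNV
  labels are unavailable for a profile, the removed mass is spread
  proportionally with largest-remainder rounding). sc3B matrices are taken
  as submitted; the cousin matrix is derived as `1 − CC − AD − ADᵀ` clamped
  to [0, 1] because participants submit only cocluster and
  ancestor–descendant probabilities.

## Baselines

The random baselines draw purity ~ U[0.2, 0.99]; subclone count from
{1, 2, 3, 4} with probabilities {0.2, 0.3, 0.3, 0.2}; profile clusters at
CCF 1 (clonal) plus U[0.2, 0.9] others with U{1..10} SNVs each; hard
assignments from per-cluster weights U{1..10}; and a cocluster matrix as the
coassignment fraction over 100 stored random assignment vectors (the stored
vectors make the matrix recountable in tests). The one-cluster method places
all SNVs in a single clonal cluster at CP = min(1, 2·mode(VAF)), the diploid
heterozygous mapping; the mode is a Gaussian kernel density maximum
(Silverman bandwidth, 512-point grid on [0, 1]) since the reference
definition names the mode but not an estimator.

## Normalization, ranking, significance

Raw scores are min–max normalized within each {tumor, subchallenge} group; a
titration series (one tumor at several depths) forms a single group. A
degenerate group (all scores equal) maps to 1 — everyone is equally best,
and the alternative (0 or NaN) would penalize a tie. Leaderboards rank by
median normalized score over the tumors an algorithm produced output for;
ties share the minimum rank; missing outputs are excluded, not zeroed, with
an opt-in zero-fill flag. The bootstrap test resamples tumors with
replacement (default 10,000 resamples, seeded), recomputes medians and ranks
per resample, and reports the fraction of resamples in which an entry ranks
at least as well as the original best; entries with P > 0.1 are flagged
indistinguishable from the best. The resample count is a package choice —
the procedure, not the count, is specified by its source.

The decision analysis builds the algorithm × subchallenge matrix of
(tumor-weighted) mean normalized scores, projects algorithms and
subchallenge axes onto the first two principal components, and projects a
decision axis — the direction of the weighted mean across subchallenges.
The decision ranking itself is computed in the full space (it is exactly the
weighted-mean ranking); the 2-D coordinates are for visualization. Axis
stability is probed with relative weight perturbations drawn uniformly from
±50%, and rank distributions with 200 × 200 independent uniform tumor and
subchallenge weight draws (40,000 rankings), weights renormalized to sum 1.

## Ensembles

sc1A: median. sc1B: floor of the median. sc1C (WeMe): each profile's
quantile function (CP at cumulative SNV-mass fraction) is evaluated on 1,001
evenly spaced mass quantiles; the consensus is the pointwise weighted median
across methods, with half-mass ties averaged between the two bracketing
order statistics; the steps of the consensus quantile function become the
consensus clusters, with masses converted to counts by largest-remainder
rounding. The grid makes the median of step functions well defined; 1,001
points bound the mass discretization error at 0.1%. sc2A (CICC): the
coassignment distance 1 − (fraction of methods coassigning a pair) is
clustered by average-linkage agglomeration and cut at k clusters, k
defaulting to the floor-of-median of the input methods' cluster counts.
Average linkage is the natural choice for proportion-valued distances;
being greedy, it is not guaranteed to minimize the mean intra-cluster
distance globally, but it does on the low-disagreement inputs consensus is
meant for, which is what the oracle tests pin. Soft (sc2B) and phylogeny
(sc3) ensembles are out of scope. When more subsets of methods exist than
the cap (default 200), subsets are sampled without replacement.

## Synthetic cohort

`simulate_tree` draws CPs by stick-breaking within each parent's CP budget,
enforcing a minimum CP gap of 0.05 between parent/child and sibling
clusters; without the gap, truths can be unresolvable in principle and rank
recovery becomes meaningless. SNVs are distributed with a Dirichlet weight
of 3 on the clonal node versus 1 elsewhere (truncal mutations typically
dominate), at least one SNV per node. Read sampling is binomial: coverage ~
Poisson(depth), alt reads ~ Binomial(coverage, CP/2) for diploid
heterozygous SNVs.

Cohort defaults span the benchmark design space: 1–5 subclones, purity
0.3–0.95, depths {8, 16, 32, 64, 128}×, 500–5,000 SNVs, half branching
topologies, whole-genome doubling probability 0.25 (a typical pan-cancer
fraction; WGD enters only as a ploidy flag for feature computation). The
first tumor is replicated across all depth levels as a titration series
sharing one truth and one normalization group.

Emulated algorithms degrade the truth with seven independent noise channels
(cluster merges and splits, CP jitter, SNV misassignment, purity jitter,
false-negative and false-positive SNV rates). A zero-noise spec reproduces
the truth exactly and scores 1 on all seven metrics — the anchor for every
monotonicity test. The generator emulates cluster-level structure and
read-count noise only; it does not model copy-number aberrations within the
genome, mutation phasing, caller-specific artifact spectra or neutral-tail
mutations, so passing rank-recovery tests demonstrates that the harness
orders algorithms by reconstruction fidelity, not that any particular real
algorithm would achieve a particular score on real tumors.

## Numerical and scale choices

* Tolerances: soft assignment rows sum to 1 within 1e−8; 2B symmetry and
  unit diagonal within 1e−6; perfect-score assertions at 1e−12; EMD
  fast-path versus LP at 1e−9.
* Dense pairwise matrices are refused beyond 20,000 SNVs (O(N²) memory), and
  the cohort writer skips 2B/3B files above 2,000 SNVs; prediction bundles
  derive their dense matrices from hard outputs on demand rather than
  storing them per prediction.
* Test and acceptance cohorts use 8–20 tumors with 80–400 SNVs per tumor:
  large enough for stable rank recovery (Spearman ≥ 0.9 margins), small
  enough that the full suite runs in well under a minute of scoring time.
  These sizes are package defaults for testing, chosen for statistical
  sufficiency; the library itself handles cohorts at the full design scale.
* Ties in the WeMe weighted median average the bracketing values; ranking
  ties share the minimum rank; CICC consensus labels are canonicalized to
  1-based contiguous integers in order of first appearance.

## Known limitations

* The original challenge harness's exact PR-curve interpolation and EMD
  scaling constants are not restated in its description; this package's
  conventions (step-wise AP, unit-interval EMD) are pinned by its own oracle
  tests and may differ from the historical implementation in the second or
  third decimal on adversarial inputs.
* sc2B scoring accepts a full cocluster matrix; per-SNV soft assignment
  matrices are converted via row dot products, which assumes cluster
  independence between SNVs.
* The bootstrap compares ranks within resamples (not raw medians); with few
  tumors the resample distribution is coarse, so P values are conservative
  near 0.1.
* Peak overlap integrates the second-largest density envelope, which
  generalizes the two-subclone "shared CCF space" notion to k subclones but
  is not the only possible reading (min-density is the common alternative
  for k = 2, where the two agree).
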