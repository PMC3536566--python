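# Methods

## Tree vectorization

A leaf-labeled tree with n taxa and non-negative branch lengths is mapped
to ℝ^{n(n−1)/2} by flattening the upper triangle of its dissimilarity
matrix in lexicographic pair order [(1,2), (1,3), …, (n−1,n)].  Two maps
are provided: path-length sums (`branch-length`) and path edge counts
(`topological`).  The topological map equals the branch-length map of the
same topology with every branch set to length 1.

Both maps depend only on the unrooted weighted topology, so rooted inputs
are treated as unrooted: a bifurcating root is a subdivision point of one
edge — path lengths sum its two segments, edge counts count it once.
Taxon order defaults to lexicographic sorting of the labels; any fixed
order gives an equivalent test, since the SVM statistic is invariant to a
coordinate permutation applied to both samples.  Zero-length branches are
legal (NJ emits them): they add 0 to path sums and 1 to edge counts.

## Separation percentage

`train_separator` fits a linear-kernel soft-margin SVM (scikit-learn SVC);
cost parameter c defaults to 1.0 and is exposed because no principled
value exists for tree vectors — the statistic is calibrated against its
own permutation null, so moderate changes in c wash out.  No per-feature
standardization is applied (both maps put all coordinates on one scale
within a run), but the training data are divided by a single pooled
scalar (their mean absolute value) before the fit and the hyperplane is
mapped back to original coordinates afterwards.  This makes c = 1 refer
to unit data scale whatever the branch-length units are; without it,
vectors in units of generations (~10⁶) turn the soft margin into an
effectively hard one and stall the optimizer on non-separable draws.
Points exactly on the hyperplane count as the positive half-space
(deterministic; measure-zero otherwise).

Two scoring conventions are implemented and agree whenever the test sets
are equally sized (every protocol run here is balanced):

* `class-average` (default): δ = ½·frac(X₊ in H⁺) + ½·frac(X₋ in H⁻) —
  the formal definition;
* `pooled`: correct points over total points — the convention of the
  classic 9/12-and-16/20 illustration, (9+16)/32 = 0.78125.

On unbalanced test sets they differ (0.775 vs 0.78125 in that example);
which one the original description intends for unbalanced data is
undetermined, so neither is guessed — both are first-class options.

## The hypothesis test

H₀: both tree collections are drawn from one distribution.

**Direct-tree mode** (`geneout_trees`): the observed statistic averages
`obs_repeats` train/test resamples (M = 168 training and N = 336 testing
trees per set, drawn disjointly without replacement when the pools allow,
with replacement plus a warning otherwise).  The null is approximated by
k replicates in which *both* pseudo-samples are drawn from a designated
null pool — the second input set by default, mirroring the asymmetric
"sample only from T₂" protocol; a pooled option exists.  Because the
observed statistic is an average of 100 resamples while each null draw is
a single δ\*, the null spread dominates under H₀ and the test is
conservative — observed null p-values concentrate well above 0.36, and
measured false-positive rates sit far below the nominal α.

**Alignment mode** (`geneout_alignments`): per set, ceil(M/|set|) bootstrap
NJ trees per alignment form the training pool and ceil(N/|set|) the testing
pool; δ₀ trains on the full training pools and scores the full testing
pools (with `obs_repeats` > 1, M/N-sized resamples of those pools are
averaged instead).  Each null replicate (i) permutes the set-membership
labels of the pooled alignments into pseudo-sets of the original sizes,
(ii) replaces every pseudo-set alignment by a column-bootstrap replicate of
itself (same length — no cross-alignment column pooling), and (iii) re-runs
reconstruction, training and testing from scratch.

**P-value direction.**  The standard permutation convention is the
default: p = #{δ\* ≥ δ₀}/k, ties counting toward the null.  The pseudo-code
form of the algorithm literally counts δ\* ≤ δ₀, which assigns p ≈ 1 to the
strongest separations and contradicts the documented usage (rejection at
p < 0.05 when separation is strong); that literal rule is preserved behind
`pvalue_mode="literal"` for comparison.  With k = 100 the p-value
granularity is 0.01; p is reported as count/k.

**Seeding.**  One master seed spawns an independent child stream for the
observed statistic and one per null replicate (numpy `SeedSequence`), so
results are bit-reproducible and enlarging k never perturbs earlier
replicates.  Every CLI run writes a manifest (config, seed, input digests)
sufficient for bit-exact replay.

## Reconstruction

Pairwise distances: JC69, and F84 via the closed-form distance with base
frequencies pooled over all sequences of the alignment (the choice of
pooling is conventional; per-pair frequencies change nothing material).
Columns with a gap or ambiguity in either member of a pair are skipped for
that pair (pairwise deletion).  Distances are capped at d_max = 5.0
substitutions/site when the log arguments vanish (saturation), keeping
vectors finite; the cap only ever binds on pathological pairs.  With equal
base frequencies and transitions at one third of observed differences, the
F84 distance reduces exactly to JC69 (both collapse to −¾·ln(1 − 4p/3)).

Neighbor joining uses the Studier–Keppler Q-criterion with ties broken by
the smallest index pair in node-creation order (determinism), and clamps
negative estimated branch lengths to 0 rather than redistributing them —
the simplest convention that preserves the non-negativity the vectorizer
requires.  On additive matrices the output reproduces the generating
weighted tree exactly; scikit-bio's independent implementation is used as
a cross-check oracle in the test suite.  Replicate trees are NJ applied to
independent column bootstraps of the alignment.  For speed, the replicate
path precomputes per-pair mismatch-type indicator matrices once per
alignment, so each bootstrap replicate costs one bincount and three
matrix–vector products before the O(n³) NJ agglomeration; this path is
exercised against the plain `bootstrap_columns` → `f84_distances` →
`neighbor_joining` composition in the tests.

Maximum-likelihood and Bayesian reconstruction are deliberately external:
a command-template hook receives the alignment and must print Newick to
stdout (for posterior samples, every j-th tree is taken).  They are not
reimplemented.

## Simulators

The validation data emulate a fixed design: pairs of 8-taxon pure-birth
(Yule) species trees rescaled so the root-to-tip depth equals an exact
multiple (0.1–10) of a haploid effective population size Ne = 100,000
generations; neutral censored-coalescent gene trees (one copy per species,
pairwise rate C(j,2)/Ne inside each branch, forced coalescence above the
root); and 1,000-nt alignments under HKY+Γ with ts/tv flux ratio R = 3.0
(κ = R·π_Rπ_Y/(π_Aπ_G + π_Cπ_T) = 6.25), shape 0.8, four equal-probability
discrete-gamma categories (category means normalized to average exactly
1), stationary frequencies Π = (0.3, 0.2, 0.2, 0.3), and a branch scaling
of 3×10⁻⁸ substitutions/site/generation applied to generation-scaled
branches.  That unit interpretation is validated by the resulting mean
pairwise uncorrected divergences (≈4.4% at depth 10 Ne ≈ 2·(τ̄+Ne)·3×10⁻⁸),
which land inside the published per-depth table.  The divergence check
spreads its 100 genes over ten independent species trees rather than one:
the shape of a single 8-taxon Yule draw shifts the 100-gene mean by more
than the within-study spread, so averaging over trees is what actually
estimates the design's expected divergence at a depth.

Choices worth noting:

* Yule trees are rescaled multiplicatively to the exact target depth —
  depth is the controlled variable of the whole study, so it is treated as
  binding rather than the birth rate.
* Tip labels are attached by a uniform random permutation.  Tips of a Yule
  tree are exchangeable, but any deterministic labeling scheme tied to the
  split order imprints the same label/shape correlation on every draw,
  which would make "independent" species trees spuriously similar.
* Sequence evolution uses exact HKY transition matrices (matrix
  exponential per branch × rate category), not an approximation.

What the simulators do **not** emulate: migration, recombination,
non-constant Ne, indels/missing data, selection, or rate variation across
branches.  Passing tests therefore demonstrate correct behavior under the
multispecies coalescent with clock-like HKY+Γ evolution — not robustness
to alignment error, model misspecification, or non-neutral processes.

## Evaluation

Fisher's linear discriminant is computed after projecting the pooled cloud
onto the leading principal components (default 2, matching the usual
visualization practice; configurable): FLD = (μ₁−μ₂)ᵀ(S₁+S₂)⁻¹(μ₁−μ₂)
with S the within-class covariance; 1 marks between-class separation equal
to within-class spread.  A singular scatter is ridge-regularized
(1e−8·trace/dim) with a warning — 28-dimensional vectors from few trees
are routinely rank-deficient.

ROC curves treat a battery of GeneOut runs as a classifier with α as the
boundary: TPR(α) over runs whose generating processes differ, FPR(α) over
runs where they coincide, evaluated on the grid of all observed p-values
plus {0, 1} (no binning).  Points are joined by the **lower staircase**
(horizontal then vertical), the most conservative interpolation: its AUC
never exceeds the trapezoidal value, and the bare diagonal {(0,0),(1,1)}
scores 0.

## Scaled-down replication study

The full published study (fifteen depths, three reconstruction methods,
three sampling designs, 100 permutations per test, hundreds of tests) is
hours of compute.  The bundled replication (`geneout.study`,
`scripts/acceptance.py`) keeps every fixed protocol constant — M = 168,
N = 336, NJ with F84 distances, 1,000-nt HKY+Γ alignments, both
dissimilarity maps scored from the same reconstructions — and scales the
breadth: five depths (0.6, 2, 4, 6, 10 Ne), the 10v10 and 1v10 sampling
designs (1v50 is supported by the code path but omitted from the bundled
study), five tests per depth per condition, and k = 20 permutations
(p-value granularity 0.05).  The test suite runs a further-reduced
two-tests-per-condition version of the same design.  AUCs from pools this
small carry sampling noise of several hundredths, which is why the
replication targets are checked to scaled-down tolerances rather than to
the printed third decimal.

## Known limitations

* The permutation null bootstraps alignments that the observed statistic
  uses un-bootstrapped, so null trees carry slightly more reconstruction
  variance than observed ones; the effect is conservative and is most
  visible for the branch-length map on shallow species trees.
* The test is two-sample only; scanning many single-locus comparisons for
  outliers multiplies the false-positive rate and requires an explicit
  multiplicity correction, which is intentionally out of scope.
* k = 20 in the reduced study bounds attainable p-values at 0.05
  granularity; power comparisons at small α need the full k = 100.
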