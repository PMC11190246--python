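# Methods

## The problem

Amplicon (16S rRNA gene) surveys report read fractions, but prokaryotes carry
between 1 and 21 copies of the 16S gene per genome, so a taxon's read share
is proportional to `cells x GCN` (gene copy number), not to cells. Recovering
cell fractions requires dividing each taxon's reads by an estimate of its
GCN. This package provides (i) a sequence-based GCN regressor, (ii) the
classical taxonomy- and phylogeny-based estimators it is compared against,
(iii) the correction arithmetic and its mock-community evaluation, (iv) a
SHAP-based positional interpretation pipeline, and (v) seeded synthetic-data
generators that make all of it testable without any database download.

## The stacked-ensemble regressor

A sequence is represented by its vector of 6-mer counts over a vocabulary
fitted on the training corpus (sorted union of observed 6-mers; ambiguous
bases are kept as literal tokens; prediction-time sequences are counted
against the training vocabulary, unseen 6-mers dropped). Two base learners
read this vector:

- an MLP with hidden layers 489-926-645-929-582-82, activations
  GELU/ReLU/ReLU/ELU/GELU/Linear, a single linear output unit, trained by
  Adam on the RMSE loss `sqrt(mean((y_hat - y)^2))` with early stopping on a
  10% validation split (patience 20); the output bias is initialized at the
  training-label mean;
- an epsilon-insensitive SVR (RBF kernel, C = 11, gamma = 'auto' = 1/100,
  epsilon = 0.1) on the top-100 PCA scores of the count matrix.

A ridge regression (alpha = 49, unpenalized intercept, closed-form solution
on the centered design) aggregates `[mlp_pred, svr_pred, 100 PCA scores]`
into the final estimate, which is clamped to >= 1 copy/genome and never
rounded. Two stacking modes exist: in-sample (base models predict their own
training data; the default, matching the large-data regime where base-model
overfitting is mild) and out-of-fold (bases are re-trained per fold and the
ridge sees only out-of-fold outputs). The desk-scale runs in this repository
use out-of-fold stacking: at a few hundred training sequences, in-sample
stacking lets the ridge trust memorized base outputs and amplifies noise.

`SEMConfig.desk()` is the laptop-sized preset used throughout the tests:
hidden layers 128-64 (GELU/ReLU), 80 epochs, batch 32, learning rate 1e-3.
It changes capacity and budget only; every other architectural element
(6-mers, PCA-100, SVR settings, ridge alpha, clamping) is identical to the
full configuration.

Training is a pure function of its seed: identical seeds give bit-identical
loss traces and predictions on one machine.

## Baseline estimators

**Taxonomy aggregation.** Training lineages (domain -> species) build a tree
whose node value is the unweighted mean of its child taxa (sequences sharing
a terminal taxon are pooled by mean first; a leaf-weighted mode exists for
comparison). Queries descend while ranks match and return the deepest
matched node's value, so unassigned or novel ranks fall back to the nearest
known ancestor; nodes are keyed by full path, so homonymous taxa under
different parents never pool.

**Phylogenetic hidden-state prediction** on a Newick tree with labeled and
query tips:

- *Subtree averaging (SA)*: nearest ancestor's mean over known descendants.
- *Empirical probabilities (EP)*: nearest informative ancestor's state
  frequency vector over integer states 1..S_max; the scalar prediction is
  its expectation (argmax optional). S_max defaults to the largest observed
  state.
- *Sankoff maximum parsimony (MPR)*: min-sum dynamic programming with an
  all-equal transition cost matrix (configurable); known tips cost 0/inf,
  query tips are free. Each query is scored with the tree re-rooted at the
  query via undirected message passing; tied minimal states are averaged.
- *Weighted squared-change parsimony (WSCP)*: values minimizing
  `sum (delta x)^2 / branch_length`; each unknown node's optimum is the
  inverse-branch-length weighted mean of its neighbors, solved as one sparse
  linear system.
- *Independent contrasts (PIC)*: Felsenstein's pruning pass with branch
  inflation `b' = b + b_L' b_R' / (b_L' + b_R')`, run toward each query;
  equivalent to the Brownian-motion ML (GLS) conditional mean, which the
  test suite verifies directly.

Zero-length branches are collapsed into polytomies before WSCP/PIC (an
epsilon-floor mode exists); both methods treat the tree as unrooted, and
their predictions are re-rooting invariant. All continuous predictions are
convex combinations of known values, so they stay inside the observed range,
and a query at zero distance from a known tip returns that tip's value.

## Community correction

`reads_from_cells` maps cells to read fractions (`reads_i ∝ cells_i g_i`);
`correct_composition` inverts it with estimated GCNs
(`corrected_i ∝ reads_i / g_hat_i`); the two are exact inverses on the
simplex. Mock communities of ten strains at 1e5 total cells come in an
"even" (10% each) and a "staggered" (log-spaced fractions spanning three
orders of magnitude) preset. Accuracy is the Bray-Curtis dissimilarity
`sum|u - v| / sum(u + v)` between true and estimated cell fractions; an
oracle row (true GCNs) scores 0 by construction and an uncorrected row
anchors the other end. Fractions below 1e-12 are floored to zero before
normalization.

## Interpretation

Kernel SHAP treats each 6-mer of a record as a player; masked players take
background values (averaged over a seeded set of training count vectors,
default 100). With at most 12 active features all coalitions are enumerated
and the exact Shapley formula applied; otherwise coalitions are sampled from
the Shapley kernel and solved by constrained weighted least squares, so the
efficiency axiom `phi_0 + sum phi = f(x)` holds in both modes. The attributed
output is the pre-clamp ensemble prediction. Per-record attributions are
computed on a seeded 10% subsample by default.

Positional mapping adds the full phi of a 6-mer occurrence to each of the 6
covered positions (a split mode divides by 6 instead); positions translate
through the alignment to 1-based reference coordinates, with insertion
columns attached to the preceding reference position (a leading insertion to
position 1). Aggregation reports both mean(|sum phi|) and RMS per position.
Mutation rates per reference position are computed over non-reference rows:
substitutions among non-gap bases, deletions over all rows, insertions as
the fraction of rows occupying the reference-gap stretch after the position.

The SHAP-vs-insertion-rate upper bound clusters insertion rates into 50
ranks by 1-D k-means (seeded k-means++), takes each rank's mean rate and max
SHAP, drops zero rates before log10 (no pseudocount — one would manufacture
structure), and fits `y = a*ELU(b(x - x0)) + c` by Adam (learning rate 0.01,
2000 iterations, 5 seeded restarts from data-scaled initializations, best
MSE kept). At those budget settings the optimizer reaches R^2 > 0.99 on
noiseless self-generated data; exact parameter recovery needs ~8000
iterations, which the recovery test uses.

## Synthetic data: what it emulates, and what it does not

All generators are pure functions of their seed and share one id namespace.

- **Tree**: Yule pure-birth process grown to `n_tips` (ultrametric).
- **Sequences**: Jukes-Cantor substitutions (probability
  `3/4 (1 - exp(-4 mu t / 3))` per site per branch) plus Poisson indel
  events with geometric lengths. Sequences are lists of global column ids,
  so the exact multiple alignment (including insertion columns) is emitted
  alongside the FASTA — positional statistics therefore have a ground-truth
  oracle. The ancestral (root) row is included as the natural reference.
- **Traits** (copies/genome, clamped to [1, 21]): either clamped-rounded
  Brownian motion, or the motif-determined model: each of `n_motifs` random
  motifs is written onto one mid-sized clade (re-imposed at every node of
  the clade, as purifying selection would), and the trait is
  `base + sum(effect_m * motif_m present) + N(0, noise_sd)`. A per-tip
  `motif_flip_rate` scrambles the locus in some clade members, modeling the
  documented deviations of real copy numbers from strict phylogenetic
  conservation — with zero decay the true tree is an oracle and no
  sequence-based method can beat tree smoothing; with decay the sequence
  carries strictly more information than the tree.
- **Lineages**: monophyletic depth cuts of the same tree; the deepest cut
  sits at 60% of tip depth so that genera pool multiple sequences, matching
  the coarseness of real reference taxonomies (~15 sequences per genus).
- **Mock communities**: the even/staggered presets above with seeded
  integer GCNs in 1..15.

Two frozen condition sets are used by the tests and the acceptance script:
`SimulationConfig.recovery()` (2000 tips, 300 nt, 5 motifs with effects
2.0-3.5 so the trait spread approaches the empirical copies/genome SD of
~2.7, noise SD 0.25) for parameter recovery, and
`SimulationConfig.benchmark()` (300 tips, 400 nt, substitution rate 0.02, 12
motifs with effects 0.7-1.4 on clades of 5-50% of tips, 15% locus decay,
noise SD 0.25) for the cross-validated method comparison. The benchmark
trait varies at many phylogenetic scales; a trait constant over a few large
clades makes coarse taxonomic averaging near-optimal, which is not how real
copy numbers behave.

The generator does not emulate: 16S secondary-structure constraints,
amplicon sequencing error, chimeras, compositional database bias, or
alignment/tree estimation error (trees and alignments are exact). Passing
tests therefore demonstrate correctness of the algorithms and the claimed
orderings *under the stated generative model*, not performance on real
amplicon data; full-scale training on a copy-number database is the
intended production use and is out of desk scope.

## Numerical choices and degenerate inputs

- Orientation detection is a simplified seed-and-extend local aligner
  (word size 11, match +2 / mismatch -3, X-drop 20) with the Karlin-Altschul
  E-value `E = K m n exp(-lambda S)` (lambda = 1.28, K = 0.46); both strands
  are scored and a record is `unrecognized` if neither clears E < 0.01.
  Strand semantics (which strand carries the template) define the label; a
  config switch inverts the mapping for corpora labeled the other way.
- Degenerate primer matching uses IUPAC set intersection (N matches all);
  ties break leftmost for forward and rightmost for reverse primers; primers
  are excluded from the extracted region by default (amplicon insert).
- Ridge never becomes singular for alpha > 0; PCA components are capped at
  `min(n_samples, n_features) - 1`.
- Empty or all-gap inputs, zero-sum compositions, missing references, and
  negative costs raise informative errors rather than propagating NaNs.

## Known limitations

- The MLP trainer is plain numpy on one CPU; the full 489-926-... stack on a
  database-sized corpus is feasible but slow (hours, not minutes).
- Kernel SHAP sampling cost grows with the active-feature count times the
  background size; full-length 16S records (~1500 distinct 6-mers) need
  either the subsampled protocol used here or a GPU-backed predictor.
- The taxonomy estimator assumes consistent nomenclature between training
  and query lineages; reconciling different reference taxonomies is out of
  scope.
- Queries must already be tips of the supplied tree; placement of novel
  sequences into a reference tree is not implemented.
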