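# Methods

## Descriptors

A conformer with atoms at positions **r**ᵢ ∈ ℝ³ is condensed, per reference
point *c*, into the first three moments of the distance distribution
{‖**p**ᵢ − *c*‖}:

* m₁ — the mean distance,
* m₂ — the square root of the *population* (1/n) second central moment,
* m₃ — the signed cube root of the population third central moment.

The root normalisation puts all three on the same length scale as m₁; the
*signed* cube root preserves whether the distribution is skewed towards or
away from the reference point. A single-atom cloud yields (d, 0, 0) per
block. We use central moments (not standardised skewness): only on central
moments does the square/cube-root normalisation have the dimensional effect
it is meant to have — standardised skewness is already dimensionless.

**USR** uses the four reference points ctd/cst/fct/ftf in ℝ³ (12 values).
Selected reference points (cst, fct, ftf) break ties by lowest atom index,
so descriptors are deterministic and stable under input order on tie-free
clouds. USR is by construction invariant under rotation, translation *and*
mirror reflection — enantiomers are indistinguishable.

**ElectroShape** embeds atom *i* as
(**r**ᵢ, Q·qᵢ[, s·logPᵢ]) ∈ ℝ⁴ or ℝ⁵ and computes all distances in the full
augmented space. Defaults Q = 25 Å/e and s = 25 Å per ALogP unit follow the
published ElectroShape convention of scaling the extra dimensions to
magnitudes comparable with molecular dimensions; both are configuration
fields so sensitivity can be probed. Reference points: c1 = augmented
centroid, c2 = furthest point from c1, c3 = furthest point from c2; c4 and
c5 share the spatial part c1₃ + (‖a₃‖ / 2‖a₃×b₃‖)·(a₃×b₃) with a = c2−c1,
b = c3−c1 (making the descriptor chirality-sensitive), carry the maximum
and minimum scaled charge as their 4th coordinates, and inherit c1's 5th
coordinate in 5D. If the spatial parts of a and b are collinear the cross
product is degenerate and c4 = c5 = c1 (logged). Correctness of this recipe
is asserted through invariance properties (rigid motion, permutation,
oracle equivalence against an independent loop-based implementation) rather
than external ground truth.

Hydrogens are included by default — charges on polar hydrogens materially
shape the augmented cloud — and can be excluded via the scheme when a
conformer carries an element mask.

## Conformers

Molecules are standardised with RDKit's MolStandardize (cleanup + largest
fragment; the rule set that absorbed MolVS) and embedded with ETKDG, whose
experimental torsion knowledge yields geometries close to minimised, so no
force-field minimisation is applied; each conformer gets a *single-point*
MMFF94 energy. Conformers with energy ≥ LEC + window are removed; the
window defaults to 5 kcal/mol and the boundary is exclusive-keep (a
conformer exactly at the window is discarded). The LEC is always retained;
LEC ties break by lowest conformer index. Defaults: up to 200 conformers
requested per molecule (generous relative to the 28–158 per molecule
typical of drug-like screening libraries), 3 embedding retries with
incremented seeds, MMFF94 partial charges (Gasteiger selectable), Crippen
atomic logP contributions. Embedding failure excludes the molecule with a
warning rather than aborting a library run.

## Screening models

All model families share one ranking convention (higher score = more
active-like) and one aggregation rule (a molecule's score is the max over
its conformer scores, mirroring the max-over-conformer-pairs rule of
classical template screening).

* **GMM** — full-covariance Gaussian mixture fitted by EM
  (scikit-learn `GaussianMixture`, reg_covar 10⁻⁶, max 500 iterations) to
  active-conformer descriptors only; scoring is the log mixture density.
  Default grid M ∈ {1, 2, 4, 8, 16}.
* **Isolation forest** — fitted to active descriptors only
  (scikit-learn, subsample 256); scoring is the negated anomaly score.
  Default grid: 100 or 200 trees.
* **ANN** — scikit-learn `MLPRegressor` with exactly one hidden layer
  (ReLU) and a linear output, trained by Adam on active=1/decoy=0 targets
  under squared-error loss with early stopping on a validation split;
  ranking uses the raw output. Default grid: hidden size 100 or 500.
  Optionally the active rows are oversampled (whole copies plus a sampled
  remainder) until the active:decoy row counts balance.

### Protocol

1. Hold out 20% of *molecules* as test set T, stratified by label. Splits
   are always at molecule level: conformers of one molecule are
   near-duplicates and conformer-level splits would leak.
2. 5-fold cross-validated grid search on the remaining 80% (L), also at
   molecule level. One-class families fit on the active conformers of the
   training folds and are scored on the actives *and* decoys of the
   held-out fold; selection metric is validation ROC AUC by default (more
   stable than EF₁% at small fold sizes; EF₁% selectable).
3. Ties between grid points go to the first in grid order.
4. Refit on all of L with the winning hyperparameters; score and rank T
   (descending score, lexicographic mol_id tie-break so rankings are
   bit-reproducible).

Degenerate inputs: when a label class has fewer than 3 molecules (or folds
cannot be formed), the grid search is skipped with a warning and the first
grid point is used — below that size cross-validation folds can contain a
single molecule and validation scores are meaningless. A class with < 2
molecules cannot be stratified at all and is a fatal error at the split.

One-class hygiene is auditable: a recording context (`record_fits`)
captures the labels of every row reaching GMM/isolation-forest fitting, and
the test suite asserts they are all active.

### Fraction sweep

The training set is subsampled at 100, 80, 60, 50, 30, 10 and 5% of the
training actives plus an absolute 10-molecule cell, each in full-ensemble
and LEC mode: 16 retrain/evaluate cells. Only actives are subsampled for
one-class models (decoys never enter their fits); for the ANN the decoys
are subsampled proportionally so the class ratio is preserved. The test set
is fixed across all cells of a mode. Cells whose subsample cannot support
training are reported as unavailable (NaN metrics), not fatal. Per-cell
seeds are derived deterministically from the protocol seed.

In LEC mode the whole frame (training and test) is reduced to one conformer
per molecule — lowest energy when energies are present, lowest conformer
index otherwise — so the mode describes the data regime end to end.

## Evaluation

* **EF_x%** with cut size c_x = ⌈x/100 · N⌉, floored at one compound so the
  selection is never empty at 0.25% on small sets; ties at the boundary
  resolve by the list's deterministic order. EF and AUC always consume one
  score per molecule (post-aggregation).
* **ROC AUC** via the Mann–Whitney construction (ties half-credit).
* **Improvement ratios** 100·EF_model/EF_baseline; a zero baseline is
  reported as unavailable rather than infinite.
* **Wilcoxon rank-sum**, two-sided: for combined n ≤ 10 the p-value is an
  exhaustive enumeration over assignments of the tie-averaged pooled ranks
  (exact even with ties); larger samples use the normal approximation with
  tie correction. Comparisons are single pairwise tests; no
  multiple-comparison correction is applied, which report consumers should
  note when scanning many cells.

## Synthetic scenarios

`make_screening_scenario` draws active-conformer descriptors from
`active_modes` Gaussian clusters (σ = noise_sd) whose centres sit along
randomly chosen orthogonal axes at distance `separation` from the origin
(hence ≥ separation apart pairwise), emulating the descriptor-space shape
clusters that distinct binding modes produce; decoys come from one broad
Gaussian at the origin (σ = 3×noise_sd by default — a Gaussian rather than
uniform background keeps densities finite and the one-mode limit
analytically predictable; a factor of 1 with separation 0 gives an exactly
exchangeable null). Each molecule's conformer draws come from its own
cluster. Descriptor-space scenarios isolate the learning and evaluation
machinery from conformer-generation variance; point-cloud fixtures cover
the descriptor geometry itself.

What the scenarios do **not** emulate: real descriptor marginals (moments
of bounded distance distributions are correlated and non-Gaussian),
property-matched decoys that overlap the actives in shape,
conformer-ensemble redundancy, or dataset sizes of real benchmarks. Passing
synthetic screens therefore demonstrates that the machinery is correct and
well-calibrated, not that any particular enrichment will transfer to a real
target.

## Problem sizes and determinism

The default experiment sizes (20 actives / 1000 decoys / 5 conformers for
the headline screen; 40 actives / 200 decoys / 3 conformers for the sweep,
sized like the smallest common real targets so every sweep cell stays
trainable) were chosen to exercise every code path at desk scale. Every
stochastic component (scenario generation, splits, folds, EM and forest
initialisation, network training) is seeded from a single integer;
identical seeds give bit-identical rankings, and the ANN relies on
scikit-learn's deterministic single-threaded Adam path.

## Known limitations

* Eq-level similarity screening is O(|templates|·|library|) over conformer
  pairs; no nearest-neighbour indexing is provided.
* The ElectroShape c4/c5 construction is one published convention among
  several; alternatives differ in the displacement constant.
* GMMs with full covariance degrade when the number of active conformers is
  close to the descriptor dimension (12/15); the covariance regulariser
  keeps fits defined but small-sample LEC cells can rank poorly — visible
  in sweep cells with few actives, and a faithful property of the method
  rather than an artefact.
* One-class scores are not calibrated probabilities; only their ranking is
  meaningful.
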