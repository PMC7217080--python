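# Methods

## The classification problem

Chimeric virus-like particles (cVLPs) are built by inserting a foreign
epitope into a capsid scaffold protein (hepatitis B core antigen in the
motivating application). Insertion frequently destroys soluble expression:
the scaffold's assembly into capsids is an entropy-driven, hydrophobicity-
mediated aggregation process, and an unfortunate insert tips it from
ordered capsid formation into insoluble aggregation. The task is binary
classification — soluble (1) versus insoluble (0) — from the amino-acid
sequence alone, over a grid of constructs formed by crossing peptide
inserts with insertion strategies (rules fixing the insertion site and the
scaffold residues deleted).

## The soft ensemble vote classifier (sEVC)

**Features.** A hydrophobicity scale *h* assigns a real value *h(a)* to
each of the 20 canonical amino acids. The feature of construct *s* under
scale *h* is the plain sum

    x_h(s) = Σ_{i = trim_n + 1 .. |s| - trim_c} h(s_i),

i.e. the summed hydrophobicity of the variable window of the sequence.
The first `trim_n` and last `trim_c` residues are constant across all
constructs of a design series and carry no class information, so they are
omitted (defaults `trim_n = 73`, `trim_c = 71`, both configurable). The
window convention is 1-based inclusive; the sum is position-free, so the
feature is invariant under permutations within the window and linear in
the scale values.

**Scale preprocessing.** Every scale is centered and scaled to unit
variance before use. The population convention (divisor 20) is used
because a scale enumerates all 20 residues rather than sampling them;
only self-consistency is asserted. After normalization each scale is
sign-oriented so that aspartic acid is non-positive, making "more
hydrophobic" point the same way in every scale. Exact reversed duplicates
(Pearson r = −1 after normalization) can be filtered, keeping the earlier
scale of each pair. Library order is significant: it is the deterministic
tie-break everywhere downstream.

**Classifiers.** Each scale contributes one decision stump — a one-level
CART tree on the scalar feature, split by minimizing the weighted Gini
diversity index over midpoints between consecutive distinct sorted
feature values. Each child predicts its majority class with the majority
fraction as the class probability. Conventions, all deterministic:
feature < threshold goes left; the boundary value goes right; Gini ties
take the smallest threshold (numerical ties within 1e-12 are treated as
ties); a child's 50/50 majority tie predicts class 0 — the conservative
call in a solubility screen — with probability 0.5; if no split beats the
root impurity the stump degenerates to the root majority leaf. The stump
is implemented here, rather than delegated to a library tree, precisely
so these conventions are pinned down; tests cross-check the attained
impurity against scikit-learn's depth-1 CART and against exhaustive
enumeration.

**Feature importance and selection.** A stump's importance is its
accuracy on its own training set. (MCC would be less biased, but it is
undefined whenever a denominator factor vanishes, which happens routinely
on small training sets; accuracy is always defined.) Stumps are sorted by
descending importance with a stable sort, and the model with *k* included
classifiers uses the top *k*. Importance is recomputed for every training
draw — feature selection is embedded, never done once globally.

**Voting.** Each included stump contributes its class probability to its
*decided class only* (score0 or score1); the class with the larger summed
score wins, ties electing class 0. A hard-vote variant replaces all
probabilities with 1. The decided-class-only semantics is the primary
reading of the method; summing full two-class probability vectors would
be a different aggregation and is not what the vote of a tree means here.

## Evaluation machinery

**Metrics.** MCC = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN)),
raising an explicit error when undefined; accuracy = (TP+TN)/total.
For a *balanced, symmetric* classifier (TP = TN, FP = FN) the identity
MCC = 2·accuracy − 1 holds, which converts published accuracies
0.62–0.83 into MCC 0.24–0.66. Replicate spread is summarized by the
median and the unscaled MAD, median(|x − median(x)|).

**Stratified sampling.** A training set of size *n* is drawn without
replacement under per-stratum caps: each insert may appear at most
⌈n / n_inserts⌉ times and each strategy at most ⌈n / n_strategies⌉ times
(the ceil convention is applied to both strata; for strategy counts
divisible into *n* the cap is exact). Records are drawn uniformly one at
a time; saturating a stratum removes its remaining members from the pool.
A draw that dead-ends restarts with the next child seed; persistent
failure raises an infeasible-sampling error.

**Monte Carlo cross-validation.** Each of `n_folds` folds draws
⌊n·train_frac⌋ records at random without replacement (default 50%),
trains the full ensemble — including feature selection — inside the fold,
and scores MCC on the held-out remainder for every candidate *k*. Folds
with undefined MCC are recorded as NaN, excluded from medians, and
counted.

**Learning experiment.** From a stratified pool (the analogue of the
study's 384-construct training set) training sets of increasing size are
drawn at random *without* stratification, `reps` times per size; each
model is evaluated on its own training draw and on the fixed external
test set for *k* = 1..n_scales. Default sizes are ⌊0.05·i·n_pool⌋ for
i = 1..18 plus the full pool (19, 38, 57, …, 345, 384 for a pool of
384) — floor is used because it reproduces the intermediate sizes the
study quotes (57, 249) while the two endpoints are the printed ones.
All replicate MCCs are stored; medians and MADs are always recomputable
from them.

**Misclassification analysis.** Across all models of a learning grid,
each prediction is assigned to TP/TN/FP/FN and counted per insertion
strategy; each strategy's four counts are normalized by its total
occurrences, so rows sum to 1. A strategy with excess FP mass is one
whose solubility the ensemble systematically overestimates.

**Baselines.** Two single-stump baselines: the net-charge feature
(scale D = E = −1, R = K = +1, others 0, used raw) and the K/R ratio
(lysine count / arginine count; undefined with zero arginines, an error
by default since the motivating constructs always contain arginine).
With solubility concentrated at low K/R the fitted stump's left child
predicts soluble, reproducing the orientation reported for this family.

## Synthetic data generator

Real construct sequences in this problem family are confidential, so the
generator emulates their structure: constant N-flank (length = trim_n) +
a scaffold core deterministically edited per strategy (insertion
position, 0–4 deleted residues, and for the last, designated "bad"
strategy an arginine-rich RRRR edit with a large negative oriented-scale
offset) + a uniform-random peptide insert of 15–25 residues + constant
C-flank (length = trim_c). The latent score is

    latent = w_insert · x_true(insert) + w_strategy · x_true(edited core)

with x_true the feature under a designated true scale (default:
normalized, oriented Kyte–Doolittle). Because strategy effects are
realized as sequence edits, at the default weights (1, 1) the latent
score equals *exactly* the true scale's feature of the trimmed window, so
the noise-free grid is perfectly separable by that feature — the anchor
property every recovery test builds on. Insert dominance is structural:
a 15–25-residue random insert has far larger feature variance than a
few-residue strategy edit.

Labels are 1 when the latent score falls below the decision threshold
(low hydrophobicity favors solubility). The default threshold sits at the
midpoint of the widest latent-score gap between the 45th and 55th
percentiles: the percentile band keeps the soluble fraction within
0.45–0.55, and the widest-gap placement leaves a margin around the class
boundary so that thresholds learned from finite training draws generalize
to held-out constructs. Optional corruptions, both recorded in the
returned ground truth: independent label noise ε ∈ [0, 0.5), and an
adversarial flip of one strategy's labels (to exercise the
misclassification analysis).

What the generator does **not** emulate: biophysically realistic residue
composition, insert–scaffold structural interactions, correlated label
noise, and strategy effects that are invisible in sequence. Passing
recovery tests therefore demonstrates the machinery — separable signal
in, correct scale and threshold out — not field performance on real
constructs, whose headline numbers depend on confidential data.

## Randomness and reproducibility

All randomness flows through `numpy.random.Generator`. A single master
seed is expanded into per-fold / per-repetition / per-attempt child seeds
by drawing integers below 2³¹ from a generator seeded with the master
seed; child seeds are stored in result objects, and rerunning with the
same seed is bit-reproducible.

## Problem sizes in the bundled experiments

The packaged scale table is a fixture set of 10 well-known published
scales (the original study used 91); scaled-down experiments therefore
screen k = 1..10. The default synthetic grid is the full 71 × 8 = 568;
the bundled learning-experiment configuration runs 5 sizes × 10 k-values
× 3 repetitions from a stratified pool of 384 with a 184-construct
external test set. All sizes are package defaults chosen to exercise
every code path at comfortable cost; every experiment accepts the full-
scale settings through its parameters.

## Known limitations

* MCC-undefined folds are excluded from medians (with a count) rather
  than imputed; on very small validation splits this can thin a cell.
* The PCA audit fixes amino acids as observations and scales as
  variables; the alternative orientation is not computed.
* Non-canonical residues (B, Z, X, U, O) have no scale values and are a
  hard error inside the feature window unless the caller opts into
  `zero`/`skip` handling.
* The stump's tie conventions (smallest threshold, class 0 on 50/50
  children) are deliberate conventions of this implementation; other
  tree routines may break ties differently.
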