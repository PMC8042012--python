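# Methods

## The question the package addresses

How many annotated single-cell images does a convolutional classifier need
before its performance on leukocyte-morphology tasks saturates?  The package
implements the full machinery to answer this with learning curves: a fixed
small sequential CNN, a nested incremental cross-validation protocol,
augmentation and balancing rules, ROC/F1 evaluation, and model-introspection
tools (saliency, layer-wise relevance propagation, penultimate-layer
embeddings).  Because the clinical image collections it was designed around
are not redistributable, a seeded synthetic cytomorphology generator stands
in for them; every claim the test suite makes is therefore about the
behavior of the method, not about clinical accuracy.

## Network

The architecture is fixed up to input size and class count: six pairs of 3x3
valid-padding convolutions (filter counts 4, 8, 8, 8, 16, 16, rectified) and
2x2 stride-2 max-pooling, then flatten, a 32-unit rectified dense layer, and
a softmax output.  For a 257x257 RGB input the shape recurrence

    257 -> 255 -> 127 -> 125 -> 62 -> 60 -> 30 -> 28 -> 14 -> 12 -> 6 -> 4 -> 2

leaves a 2x2x16 feature map (flatten width 64) and a total of exactly 7210
trainable parameters for two classes, 7342 for six.  These totals pin the
design: 'same' padding, a different hidden width, or a grayscale input all
break them, so valid padding, floor pooling, width 32 and 3 input channels
are forced.  The smallest input the six-stage stack supports is 190x190
(each stage inverts to s -> 2s + 2 from a 1-pixel output).  For smaller test
images `build_network(..., n_stages=k)` uses the first k conv/pool pairs —
65-px fixtures use four stages — leaving the rest of the pipeline unchanged.

The compute backend is plain NumPy in float64.  At ~7k parameters this is
faster to set up than a GPU framework, bit-reproducible, and gives the
relevance-propagation code direct access to every intermediate activation.
Weights are initialized U(-sqrt(1/fan_in), +sqrt(1/fan_in)) with zero
biases, from a seeded generator.

## Protocol

* Ten folds; every image appears in the test set of exactly one fold (for
  250 images: ten disjoint test sets of 25).
* Per fold, 25 validation images are drawn once and held fixed across all
  training-set sizes, keeping within-fold size comparisons paired.
* The remaining pool is permuted once; training subsets are its prefixes
  (10, 20, ..., 200 by default), so each subset contains the previous one.
* Each (fold, size) cell trains a freshly initialized network and evaluates
  on the fold's fixed test set.
* Training minimizes softmax cross-entropy with Adam (lr 1e-3, batch 16 —
  standard small-CNN defaults, exposed in `ProtocolConfig`), with per-epoch
  augmentation and early stopping: stop when the validation loss has not
  strictly improved for `patience` (50) epochs, restore the weights of the
  best epoch (earliest epoch wins ties).
* Augmentation: independent horizontal/vertical flips (p = 0.5 each) and a
  rotation drawn uniformly from [0, 359) degrees, bilinear with constant
  fill (default: the image's mean border color).  The default mode
  re-augments every training image once per epoch; an alternative `append`
  mode adds a random number of augmented copies per epoch instead — both
  readings of "adding a random number of augmented images" are available
  because the phrase is ambiguous.
* Multiclass runs balance each training subset to 150 images per class:
  classes below target keep all originals plus augmented copies, classes
  above target are subsampled.  Test sets are never augmented, hence macro
  F1 as the multiclass metric.
* A large-dataset variant draws class-balanced fixed-size test sets (e.g.
  600 images), disjoint across folds on the test side only.
* Seeding: a master seed drives fold planning; each (fold, size) cell
  derives a stable child seed (SeedSequence, < 2^31) for initialization,
  shuffling and augmentation, making the whole results table reproducible.

## Evaluation conventions

ROC-AUC is computed as the Mann-Whitney probability (ties count one half),
identical to the trapezoidal area under the empirical ROC.  Fold-mean ROC
curves are vertically averaged on a 101-point FPR grid; vertical jumps in an
individual curve are resolved to their upper envelope first, so a single
curve averages to itself exactly.  Both mean-of-AUCs and AUC-of-mean-curve
are reported, since summary values in the literature use either.  Boxplot
summaries use linearly interpolated quartiles and 1.5*IQR whisker fences.
Confusion matrices report row percentages with the per-class n; empty rows
are NaN-flagged rather than silently zero.

## Interpretability

Saliency is the gradient of the target class's pre-softmax score with
respect to the input, reduced over RGB by max of absolute values (sum-abs
available).  LRP uses the stabilized epsilon rule (eps = 1e-6) at every
conv/dense layer, winner-take-all routing through max-pooling, and channel
summation at the input; the alpha-beta rule (alpha=1, beta=0) is available.
The decomposed quantity is the pre-softmax logit, the standard choice for
both methods.  Bias neurons absorb their relevance share, so exact
conservation (tested at 1%) holds for zero-bias networks; trained networks
leak a small bias-proportional amount.  Penultimate 32-d activations are
embedded with seeded t-SNE (PCA initialization, so fixed seeds give fixed
coordinates); class separation is quantified by the mean silhouette
coefficient, which turns the qualitative "clusters separate with more
training data" claim into a testable number.

## Synthetic generator: what it does and does not establish

Each class is a distribution over interpretable morphology parameters:
nucleus:cytoplasm area fraction, nuclear lobe count, chromatin texture
contrast, stain colors, and cell size; thrombocyte-like classes are
anucleate fragments.  Defaults follow standard cytology descriptions —
blasts: N:C ~0.75, round nucleus, fine chromatin; typical lymphocytes: N:C
~0.45, coarser chromatin; segmented neutrophils: 2-5 lobes, N:C ~0.35;
monocytes: large, indented nucleus; thrombocytes: small, anucleate.  Cells
are rendered as ellipse lobes with low-pass-filtered chromatin noise on a
smear-colored background with optional red-cell-like distractor discs
(default on, so classifiers must localize and attribution maps have
something to find).  `effect_size` interpolates every parameter between the
pooled across-class mean (0: classes identical by construction) and the full
class values (1).

The generator gives ground-truth masks, so its own output is validated by
measurement (area fractions, connected-component lobe counts) rather than by
assumption.  What it does not emulate: real stain variability, focus and
illumination artifacts, touching cells, patient-level correlation (the
reference data had none available either), or the hard intra-class
ambiguity of real smears.  A green learning-curve test therefore
establishes that the protocol measures what it should on a controllable
world — not that any particular clinical accuracy would be reached.

## Numerical and design choices

* float64 everywhere; softmax is max-shifted; cross-entropy clamps
  probabilities at 1e-12.
* Pooling drops odd trailing rows/columns (floor), matching the parameter
  accounting.
* Early-stopping ties keep the earliest epoch; `early_stop_epoch` exposes
  the rule for direct testing.
* Quartiles: linear interpolation of order statistics (affects small-n
  boxplots only).
* The acceptance-grade synthetic learning-curve run (250 images, 65 px,
  5 folds, sizes 10/30/60/100, patience 50) caps `max_epochs` at 150 rather
  than 500 purely to fit CI time budgets; on this easy, well-separated data
  early stopping triggers long before the cap matters.

## Known limitations

* The NumPy backend is single-threaded BLAS-bound; 257-px ten-fold runs at
  the full 10x20 grid take hours, not minutes.  The protocol is
  size-parametric, so methodological tests run at 34-65 px.
* t-SNE determinism is guaranteed per seed and library version, not across
  library versions.
* The exact-duplicate finder matches bytes only; it is a curation utility,
  not a perceptual-duplicate detector.
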