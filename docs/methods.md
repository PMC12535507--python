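# Methods

This note records the scientific and numerical choices behind `nscl`: the
model and its assumptions, the defaults and why they were chosen, what the
synthetic generator does and does not emulate, and the limitations a user
should know before trusting a green test suite.

## Hierarchy construction

Labels are embedded by lookup in a word2vec-style text file (or a JSON
fixture dialect). A multi-token label maps to the arithmetic mean of its
token vectors after lowercasing and splitting on whitespace/underscores; a
phrase vector stored under the full label name takes precedence, so
BioWordVec-style phrase embeddings pass through unchanged. Labels whose
tokens are all out-of-vocabulary are an error, not a silent zero.

Embeddings are L2-normalised before clustering: the semantic signal of
word vectors lives in direction, not magnitude, so clustering operates on
cosine geometry regardless of the chosen metric. The linkage criterion is
not dictated by the method; the default is average linkage on cosine
distance, with complete and Ward linkage and euclidean distance available
as configuration. Cuts are taken with `scipy.cluster.hierarchy.cut_tree`
at each requested cluster count (one call per count — this scipy version
mis-orders multi-count calls), which guarantees nested partitions because
all cuts come from the same merge sequence. Cluster ids are re-labelled to
dense integers in order of first leaf appearance so reports are
reproducible across runs. A trailing repeated count (e.g. 2, 4, 6, 6 for a
six-disease problem) duplicates the leaf stage; intermediate repeats are
rejected.

Prior-knowledge hierarchies come in as (child, parent) edge lists. A DAG
is resolved to a tree by keeping each node's first-listed parent (with a
warning): staged training needs a unique ancestor per level. Levels are
the depth strata of the resolved tree; a leaf shallower than the deepest
stratum stays its own cluster below its depth.

The random-grouping control (`random_hierarchy`) permutes leaf labels
uniformly and re-attaches them to the existing cluster skeleton, which
preserves the per-level cluster-size multisets and the nesting exactly —
the only thing destroyed is the semantic assignment.

## Losses

The embedding-regression term is mean(1 − cos(w, r)) over the batch, in
[0, 2]. The source construction is ambiguous about the sign (it writes
"1 − D_c" while calling D_c a distance, which would *reward*
anti-alignment); this implementation follows the similarity reading, under
which aligned pairs score 0, orthogonal 1, anti-aligned 2.

The supervising embedding for a coarse stage is the centroid of the member
leaves' embedding vectors (a singleton cluster keeps its own vector). This
is a design choice — the alternative of embedding the cluster's *name*
requires names coarse clusters do not naturally have.

Class weights are inverse-frequency, w_c = N/(K·n_c), so balanced data
gives unit weights and the weighted loss reduces to the plain mean NLL.
The weighted cross-entropy normalises by the batch's applied-weight sum,
keeping the loss scale comparable across imbalance regimes. Probabilities
are clamped at 1e−12 before the log; clamping is logged.

The schedule ties β to α: β = 1 − α for α < 1 (convex mix), β = 1 for
α ∈ [1, 7] (regression up-weighted). `resolve_weight_schedule` is the only
constructor used by training code, so invalid pairs cannot arise there.

## Cascade models and training

Networks are deliberately small and written in numpy with hand-derived
backpropagation: the object of study is the *training mechanism*, not
benchmark accuracy, and an analytic backward pass provides exact input
gradients for the saliency module. Feature blocks are dense
(affine + ReLU, He-initialised); the block registry accepts other kinds
(e.g. convolutional) without touching the trainer. Image inputs are
flattened at the model boundary and gradients reshaped back to image
geometry.

Each stage's output block is a projection to the embedding dimension u,
a ReLU, and an affine softmax head. The *pre*-ReLU projection is the
latent R supervised by the regression loss: a post-ReLU latent is
non-negative and can vanish identically, which makes cosine alignment
degenerate. Degenerate (near-zero-norm) latent rows inside training
contribute loss 1 and zero gradient and recover through the
classification term; the public `cosine_alignment_loss` rejects them
instead, as a user-facing contract.

Mechanism switches:

- `E2E`/`HE2E`: one stage grown at full depth, all parameters trainable;
  `HE2E` additionally requires α > 0 and label embeddings.
- `CL`/`NCL`: one stage per block, every head is leaf-wide; `CL` freezes
  pre-existing blocks, `NCL` fine-tunes them.
- `SCL`/`NSCL`: one stage per hierarchy level, head widths follow the
  level cluster counts, targets are the level-l ancestors; frozen vs
  nested as above.
- `RHCL`: `SCL` on the seeded random grouping. Frozen scope is the
  default (it is the cascade family's calibration; a flag flips it to
  nested).

Freezing is enforced, not assumed: pre-existing blocks are excluded from
the optimiser step *and* their parameter checksums (SHA-256 over the
serialised arrays) are verified unchanged after the stage; drift raises.
Earlier stages' output blocks are retained after growth, enabling
stage-head evaluation. The optimiser is Adam (lr 1e−3 default, fresh state
per stage); a non-finite loss aborts with a diagnostic.

Three numerical safeguards matter in the staged setting. (1) Softmax heads
are zero-initialised, so a freshly grown stage starts at cross-entropy
exactly log K regardless of how large the fine-tuned upstream activations
have become — random head init occasionally produced initial losses the
stage budget could not recover from. (2) Nested stages train only their
new blocks for the first few warm-up epochs (default 5, always capped
below the stage budget so fine-tuning still happens): the arbitrary early
gradients of freshly initialised blocks would otherwise occasionally
corrupt a well-trained earlier representation before the new head warms
up. (3) Gradients are clipped to a global L2 norm of 5 as a guard when
the regression term is heavily up-weighted. One global seed
expands through `numpy.random.SeedSequence` into the random-grouping seed
and per-stage seeds (initialisation and data shuffling), so fixed seed +
fixed data order reproduces loss histories bit for bit. Model parameters
persist as JSON (the models are small enough that a text store costs
nothing and keeps artifacts diff-able).

Per-stage learning-rate search is not implemented; the learning rate is a
config scalar. Named presets (`cifar_small`, `chexpert_small`,
`tabular_1d`) mirror published layer-width/epoch settings for orientation
but are not validated surfaces.

### The `fixture_tiny` preset

Training preset for the planted two-level world: block width 6, per-stage
epochs (30, 15), α = 7 (so β = 1), lr 1e−3. Two ingredients make the
mechanism contrast observable. The width sits just above the supergroup
count, so the first stage's representation is a genuine bottleneck. And
the heavily weighted regression term — α = 7 is the top of the explored
schedule and the strongest-regression setting reported to work well —
makes the coarse stage *imprint its grouping onto that bottleneck*: the
cosine loss pulls every sample's latent toward its group's centroid
embedding. For the semantic grouping those centroids are the four
supergroups, exactly the structure later stages need; for a random
grouping each centroid averages leaves from *different* supergroups, so
stage-1 training actively merges semantically distant classes in the
representation, and the frozen leaf stage inherits the damage as
across-supergroup errors. Projected-leaf severity records the difference.
With generous width, or with α near 0, every mechanism keeps enough
information for the leaf head to recover the geometry and the contrast
shrinks toward measurement noise; that regime is real but uninformative
about the mechanism. The random grouping is itself random: some draws
happen to respect the semantics and score as well as the semantic
hierarchy, which is why the validation property is stated over the mean
of ten seeds rather than per draw.

## Severity

Per-level mismatch is compared cluster-id by cluster-id; with propagation
(the default) every level at and below the first mismatch counts as an
error, giving severity (L − first_error + 1)/L. The non-propagated mean is
available behind a flag for diagnostics only. Severity from *projected
leaf* predictions is identical under both flags — ancestors that diverge
stay diverged — which is also why project-leaf mode is the default
prediction source: it scores single-stage and cascade models on identical
footing. Stage-heads mode (each level scored by its own head) is opt-in
and requires one stage per level.

The hierarchy-ordered confusion matrix orders leaves by depth-first
traversal (children in cluster-id order), zeroes the diagonal, and maps
error counts to −log((count + c)/(total + c·cells)) with pseudocount
c = 0.5 by default (Haldane–Anscombe convention) so empty cells stay
finite; with no errors at all the intensity is reported as undefined
rather than fabricated.

## Saliency

Vanilla input-gradient saliency: the per-pixel magnitude of the gradient
of the target-class *logit*, channels aggregated by maximum absolute
value. Masks keep the top `threshold_fraction` of salience by quantile
(default 0.15, configurable; the benchmark value behind the published
comparison is not printed anywhere authoritative). Ties at the threshold
are included, so a constant map yields an all-true mask with a warning.
IOU is 0 by convention when both masks are empty; coverage accuracy
(÷ annotation area) and coverage precision (÷ mask area) reject empty
denominators.

## Synthetic world

`simulate_label_embeddings` and `simulate_classification_dataset` plant
the same two-level structure in embedding and feature space respectively:
supergroup centres at exact pairwise separation `delta_between` (a scaled
random orthonormal frame when the dimension allows, rescaled Gaussian
directions otherwise), leaf means at isotropic spread `delta_within`
around their centre, samples at Gaussian noise `noise_sigma`. The stated
regime `delta_within ≪ noise_sigma ≪ delta_between` makes the supergroup
problem easy and the leaf problem hard, so any sensible classifier's
confusions concentrate inside supergroups — the error structure the
severity metric is designed to resolve. Defaults (4×3 groups, 20/1/2,
200 per class) are the recovery-regime dataset used by the validation
suite; `sample_seed` redraws samples while keeping the planted means, for
train/test splits. The imbalanced option draws per-class counts from a
seeded Dirichlet-multinomial floored at 2.

What the generator does **not** emulate: image texture, label noise,
uncertainty labels, covariate shift, or any relation between embedding
geometry and feature geometry beyond the shared group structure. A green
suite therefore establishes that the machinery is correct and that the
mechanism contrast behaves as designed in its intended regime — not that
it reproduces published benchmark numbers, which require external datasets
and GPU-scale training and are out of scope here.

## Known limitations

- Feature blocks are dense; convolutional blocks are registry-pluggable
  but not shipped, so published CNN architectures are mirrored only in
  width/epoch schedules.
- The NSCL-vs-RHCL severity gap is a bottleneck-plus-strong-regression
  phenomenon (see the preset discussion); with over-provisioned capacity
  or a weak regression term the mechanisms converge to the same error
  structure on this synthetic world. The gap is a difference of means:
  individual random groupings can match the semantic hierarchy by chance.
- `hierarchy_from_edges` resolves DAGs greedily (first-listed parent);
  no attempt is made to find an optimal tree extraction.
- Thread counts are pinned for reproducibility; results are deterministic
  per platform/BLAS build, not necessarily across builds.
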