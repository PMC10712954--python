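# Methods

This note documents the models, parameter choices and numerical decisions
behind `vistrat`, and what its synthetic data can and cannot show.

## Stimulus family and renderer

The object family is defined analytically as a signed-distance scene: a
rounded box (half-extents 0.62 × 0.40 × 0.35 scene units, edge rounding
0.06) whose x/z cross-section is scaled by $s(y) = 1 + c\,(1-(y/b_y)^2)$,
plus three spheres (radius 0.16) attached along the top edge at
x ∈ {−0.45, 0, +0.45}. The concavity level 0…10 maps linearly to
$c \in [-0.22, +0.22]$ (level 5 flat); negative $c$ caves the walls inward
(the trained target end), positive $c$ bulges them outward. The alignment
level 0…3 raises the left sphere and lowers the right one by one third of a
sphere radius per level, so level 3 displaces each by a full radius.

Images are produced by sphere tracing (110 steps, conservative step factor
0.7 because the bowed box is not exactly 1-Lipschitz), orthographic
projection over a ±1.15-unit window at 100 × 100 px, finite-difference
normals and Lambert shading under one directional light (ambient 0.10,
diffuse gain 0.85). Five light locations (front/left/right/up/under) tilt
the light vector; size scaling and position shifts act on the projected
rays, so they change neither shape parameters nor roles. Rendering is
deterministic: a spec renders to bit-identical pixels, and rotations by 0°
take the same code path as any other angle. With this geometry the convex
distractor is brighter than the concave target — the brightness confound
the behavioural analyses probe — and the mean silhouette width grows
strictly with the concavity level.

The published study rendered its stimuli in Blender with unpublished mesh,
camera and light parameters; this renderer is a faithful re-parameterisation
of the described geometry class, not a pixel-level replica.

### Task grid and roles

The 4 × 4 task grid keeps the two extreme concavity columns (the trained
base pair sits at opposite grid corners) and chooses the interior columns to
minimise the variance of adjacent-column pixel dissimilarity, ties broken
toward symmetric spacing. Under the default renderer the chosen columns are
(0, 3, 6, 10), frozen as the package default. Unconstrained variance
minimisation would degenerate to consecutive columns (variance 0), so
spanning the full range is part of the objective — this formalisation is
ours. On the grid, cells above the anti-diagonal are targets, below it
distractors, on it ambiguous (4 ambiguous, 6 targets, 6 distractors).

### Training set

The decoder trains on the union of the distinct stimuli of the three
training protocols: the base pair, two dimension-learning pairs (one
differing only in concavity, one only in alignment, drawn from the grid
interior so both members have proper roles), and the five transformed
versions (30° rotation about each axis, light from under, 80% size) of each
base-pair member — 16 stimuli, 8 per class. The original study counts 24
training stimuli, but its printed protocol descriptions do not determine
the remaining images; we use the reconstruction above and keep the training
set an explicit argument throughout, with PCA dimensionality tied to
min(n − 1, d, 23). Class balance matters: with an unbalanced set the
calibration target would be confounded with the majority-class rate.

## Feature hierarchy and readouts

The default backbone is a fixed-seed, randomly initialised convolutional
hierarchy with the 13 named sublayers (conv1, norm1, pool1, conv2, norm2,
pool2, conv3–5, pool5, fc6–8), He-scaled Gaussian weights, local response
normalisation, 3 × 3/stride-2 max pooling, operating on 100 × 100 grayscale
input directly. Convolution and fc activations are recorded before ReLU;
norm and pool stages at their output. Random hierarchies preserve the one
property the analyses need — representational depth increases along the
stack — without requiring pretrained weights; any object exposing the same
three-member surface (`sublayer_names`, `layer_dims`, `extract_batch`) can
be plugged in instead, e.g. a pretrained network.

Per sublayer, readout fitting is: PCA (components = min(n − 1, d, 23)),
per-component standardisation to unit training variance, then a max-margin
linear classifier (`SVC(kernel="linear", C=100)`; the near-hard margin makes
noiseless training accuracy 100% at every sublayer, the behaviour the study
design presumes). Distances are geometric margins ($\|w\|$-normalised), so
classification scores are comparable across sublayers after
standardisation.

**Noise model and calibration.** The readouts are fit on the clean training
stimuli; iid zero-mean Gaussian pixel noise (fresh draw per stimulus per
iteration, unclipped) enters at evaluation. Calibration brackets and bisects
the noise SD until the mean training accuracy over `iters` iterations (mean
over the 13 sublayers and all stimuli) is within ±0.02 of the 0.75 target,
re-using one seeded noise schedule across candidate SDs so the evaluated
curve is monotone in practice. An early design that fit the readouts on
noise-perturbed activations produced near-arbitrary clean-image hyperplanes
(one noisy draw per stimulus at noise comparable to the luminance range) and
was rejected: it contradicts the designed noiseless-ceiling behaviour.

## Informed pair selection

Candidates are sampled uniformly with replacement (default 10,000
iterations; duplicates collapse, and per-stimulus caching makes cost scale
with distinct stimuli drawn) from a pool of 3 target and 3 distractor
shapes — the grid cells nearest the trained corners, configurable — crossed
with all 7³ rotations and 5 lights: 5,145 stimuli per class. Early/late
block means (sublayers 1–3 and 11–13) are divided by their across-candidate
population SD; `zero_vs_high` keeps |early_z| ≤ 0.5 and late_z ≥ 1.5,
`high_vs_zero` the mirror image, both config-exposed since the original
cut-offs are unpublished. Survivors are ranked by the high-side z (ties by
pair id) and picked greedily under the constraint of distinct targets and
distinct distractors, so the k = 7 picks cross into a 49-pair protocol.

Two structural caveats, visible in the synthetic model and likely generic:
the z-criterion constrains the three-layer *mean score*, so an individual
sublayer inside a "zero" block can still sit away from zero; and a
near-zero score still casts a deterministic binary vote, so "zero" blocks
drift above 50% binary accuracy when tiny scores are sign-consistent. The
chance-level property is therefore asserted on the selected pairs' pooled
late-block decisions (exact binomial band), while the 49-pair cross is
checked for the dissociation direction.

## Observer simulation

Choice follows a lapse-probit model,
$p = \lambda/2 + (1-\lambda)\Phi(\sum_l w_l s_l/\sigma)$, over the clean
(deterministic) pair scores. The species presets are illustrative
parameters, chosen once to realise the qualitative contrast the pipeline is
designed to detect, not fitted to any behavioural dataset: rat-like weights
(3,3,3,2,2,1,1)/15 over sublayers 4–10 with σ = 1.5 and λ = 0.30; human-like
uniform weights over 11–13 with σ = 0.75 and λ = 0.05. Sessions reproduce
the protocol structure (100-trial training sessions with correction trials
after every error; 120-trial test sessions with one-third base-pair old
trials, correction trials only there, random reward at rate 0.8 on new
trials, affecting only the reward flag). Inter-trial timing, session time
limits and within-session learning are not modelled; no analysis consumes
them.

What passing tests show — and don't. The simulation demonstrates that the
pipeline *recovers planted structure*: observers driven by convolutional
sublayers yield correlation profiles and regression weights peaking there,
and the informed-protocol accuracy ordering reverses between the presets
(the human-like contrast is large; the rat-like contrast is a few
percentage points and becomes reliable only at adequate search scale —
2,000+ candidate iterations on the full pool). It does not validate the
choice model against real rats or humans, and real behavioural effect sizes
(e.g. the published ~62% vs ~94% species gap) are emulated only
qualitatively.

## Statistics

Conventions: correction trials never enter any accuracy; test sessions
whose old-trial accuracy falls below 0.65 are excluded wholesale; "pooled"
accuracy sums corrects over subjects before dividing (subject-level means
are also available). Permutation p-values use (count + 1)/(n_perm + 1) —
the unbiased-support estimator — because the raw count/n estimator can
return 0, outside a p-value's domain; permutations shuffle the accuracy
vector once per iteration across all sublayers jointly. Split-half
reliability averages the across-pair Pearson correlation of per-pair
accuracies over 100 random trial halvings (whether the original used random
halves or session parity is unpublished; random halves are the default).
The combined cross-dataset reliability is the geometric mean of the two
Spearman–Brown-corrected full-set reliabilities. The layer regression is
OLS with intercept on the 287 × 13 score matrix; we report the conventional
F degrees of freedom (13, 273) and √R² as the correlation-scale equivalent.
The pixel-similarity measure is the Pearson correlation of flattened pixel
vectors by default (negative Euclidean distance as an alternative); the
brightness predictor is the base-pair brightness difference minus each test
pair's, both invariant to uniform luminance offsets by construction.
Species comparison uses Welch t-tests across species on training-normalised
test accuracy and on the per-subject informed-protocol contrast, and paired
t-tests within species; zero-variance groups are flagged degenerate (t = 0
for identical groups, ±∞ for offset ones).

## Problem sizes and determinism

Full-scale defaults follow the study conditions: 100 calibration
iterations, 10,000 selection iterations, 1,000 permutations, 100 reliability
splits, 11 + 45 subjects. The test suite and the bundled examples run the
same code at reduced sizes chosen for statistical adequacy rather than
fidelity — 4,000 selection iterations on the full pool, 8 subjects × 10
sessions per protocol (enough that simulated split-half reliability exceeds
0.8, the precondition for the recovery checks) — with every stochastic
stage seeded. `pipeline.reproduce` derives one named seed per stage from
the base seed via SHA-256, writes CSV/JSON artefacts plus a hashed
manifest, and is byte-reproducible for a fixed configuration.

## Known limitations

- The renderer reproduces the geometry class, not the original pixel data;
  quantities that depend on exact pixel statistics (e.g. which concavity
  columns the dissimilarity criterion picks) can differ from the published
  grid.
- The random backbone's inter-layer score correlations differ from a
  pretrained network's; informed-pair selection finds genuinely
  dissociating pairs either way, but the specific pairs are
  backbone-dependent.
- The rat-like/human-like presets are caricatures for pipeline validation;
  conclusions about real species require real data, for which the analysis
  stack (trial tables in, statistics out) can be reused unchanged.
- Sessions are simulated as trial sequences only; time limits, intertrial
  intervals and motivational drift are out of scope.
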