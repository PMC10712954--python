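# vistrat

Tools for **computationally informed comparison of visual object-recognition
strategies**, built around a complete synthetic re-creation of a
rodent/human discrimination study: parametric 3D stimulus generation,
layer-wise linear decoding of a hierarchical feature model, model-guided
selection of stimulus pairs that dissociate early from late visual
processing, trial-level observer simulation, and the full statistical
comparison pipeline.

The package is aimed at researchers who design visual discrimination
experiments (touchscreen rodent setups, fast online human tasks) and want to
choose stimuli by what a hierarchical model says about them — rather than by
intuition — and at anyone who needs the accompanying analysis stack
(reliability-corrected behaviour/model correlations, layer regressions,
low-level feature predictors) in reusable form.

## The design in brief

**Stimuli.** Objects are a rounded body with three spheres attached on top,
parameterised by two task dimensions: *concavity* (11 levels, the body's
walls bow inward or outward) and *alignment* (4 levels, the outer spheres
slide diagonally apart). A 4 × 4 task grid is chosen from the 4 × 11 family
by pixel dissimilarity; cells above the anti-diagonal are *targets*
(concave, aligned side), below it *distractors*, on it *ambiguous*.
Identity-preserving transformations — rotations about x, y, z (0°–180° in
30° steps), five light locations, size scaling, position shifts — span a
space of 4 × 11 × 7³ × 5 = 75,460 images. Everything is rendered
deterministically at 100 × 100 px by a signed-distance ray marcher
(orthographic camera, Lambert shading).

**Decoding.** A fixed 13-sublayer convolutional hierarchy (conv1 … fc8,
activations taken before rectification) is read out per sublayer with a
PCA-standardised max-margin linear classifier fit on the training stimuli.
For a pair of images the *classification score* at sublayer $l$ is the
difference in signed distance to that sublayer's hyperplane,

$$s_l = d_l(\text{target}) - d_l(\text{distractor}), \qquad
  d_l(x) = \frac{w_l^\top \phi_l(x) + b_l}{\lVert w_l \rVert},$$

positive when the sublayer favours the correct choice. Zero-mean Gaussian
pixel noise is added to the inputs and its SD calibrated by bisection so
mean training accuracy over 100 noise iterations sits near 75% — off
ceiling, comparable to behaving subjects.

**Informed pair selection.** Candidate target/distractor pairs are sampled
from a pool of 5,145 × 5,145 transformed grid stimuli; each candidate's mean
score over sublayers 1–3 (early) and 11–13 (late) is expressed in units of
the across-candidate SD, and thresholds on these z-values pick *zero vs
high* pairs (early ≈ 0, late high) and *high vs zero* pairs (the reverse).
Each profile's 7 selected targets × 7 distractors form a 49-pair protocol.
Together with rotation, light, size, position and combined-rotation
protocols, the nine test protocols comprise 287 image pairs.

**Observers and statistics.** Synthetic observers are probit choice models
over the 13 layer scores with a lapse rate,
$p(\text{correct}) = \lambda/2 + (1-\lambda)\,\Phi(\sum_l w_l s_l / \sigma)$;
a rat-like preset weights convolutional sublayers 4–10 (high lapse), a
human-like preset the fully connected sublayers 11–13 (low lapse). Sessions
reproduce the task structure: one-third old (base-pair) trials, random
reward on 80% of new trials, correction trials after errors. The statistics
module computes per-pair accuracy matrices with exclusion rules, exact
binomial chance tests, per-sublayer Pearson correlation profiles with
permutation tests, split-half reliability with the Spearman–Brown
correction $r^* = 2r/(1+r)$ and the combined cross-dataset ceiling
$\sqrt{r_1^* r_2^*}$, the 13-regressor OLS layer regression, brightness and
pixel-similarity predictors, and species contrasts.

## Worked example

```bash
python examples/02_train_layer_readouts.py
```

prints (abridged):

```
noiseless training accuracy per sublayer:
  conv1  1.00
  ...
  fc8    1.00

calibrated pixel-noise SD: 0.250 (luminance units)
achieved mean training accuracy over 100 iterations: 73.6%

base-pair classification score (signed-distance difference) per sublayer:
  +2.00  +2.00  +2.00  ...  +2.00
```

Without noise, every sublayer separates the 16 training stimuli perfectly
(accuracy 1.00); the calibrated pixel noise (SD 0.25 on a [0, 1] luminance
scale) brings mean training accuracy to ~74%, inside the ±2-point band
around the 75% target. The base pair scores exactly +2.00 everywhere
because both members are margin-defining support vectors of every
sublayer's hyperplane — each sits at geometric distance 1 on its own side.

The other examples walk through the remaining capabilities: stimulus-space
generation (`01`), informed pair selection (`03`), observer simulation on
the informed protocols (`04`, the accuracy ordering reverses between the
rat-like and human-like presets), and the end-to-end statistics report
(`05`).

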