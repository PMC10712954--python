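"""Layer-wise linear readout decoding of the feature hierarchy.

For each of the 13 sublayers, activations of the 24 training stimuli are
projected onto their principal components, standardised, and classified with a
max-margin linear hyperplane (target vs distractor).  Zero-mean Gaussian pixel
noise is added to the inputs and its standard deviation calibrated by bisection
so that mean training accuracy over noise iterations lands at a target level
(default 75%), keeping the model off ceiling and comparable to behaviour.

The per-pair, per-layer *classification score* is the difference in signed
distance to the hyperplane between target and distractor (target - distractor),
measured as a geometric margin (normalised by the weight norm).  A positive
score means the layer favours the correct choice.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.svm import SVC

from .backbone import N_SUBLAYERS, SUBLAYER_NAMES
from .stimuli import ProtocolDef, RenderConfig, StimulusSpec, render

__all__ = [
    "NoiseModel",
    "LayerReadout",
    "DecoderEnsemble",
    "fit_readouts",
    "calibrate_noise",
    "CalibrationError",
    "score_pairs",
    "layer_generalization",
    "spec_id",
    "pair_id",
]

DEFAULT_MAX_COMPONENTS = 23  # n - 1 for the 24 training stimuli


class CalibrationError(RuntimeError):
    pass


@dataclass(frozen=True)
class NoiseModel:
    """Zero-mean Gaussian pixel noise added to network inputs."""

    sd: float
    n_iterations: int = 100
    target_accuracy: float = 0.75
    achieved_accuracy: float | None = None

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("noise sd must be >= 0")
        if not (0.5 < self.target_accuracy <= 1.0):
            raise ValueError("target accuracy must be in (0.5, 1]")


@dataclass
class LayerReadout:
    """PCA basis + standardisation + linear hyperplane for one sublayer."""

    mean: np.ndarray          # (d,) PCA centring
    components: np.ndarray    # (n_comp, d) orthonormal rows
    scale: np.ndarray         # (n_comp,) per-component training SD
    w: np.ndarray             # (n_comp,) hyperplane weights
    b: float

    def project(self, acts: np.ndarray) -> np.ndarray:
        """Standardised principal-component coordinates of raw activations."""
        return (acts - self.mean) @ self.components.T / self.scale

    def distance(self, acts: np.ndarray) -> np.ndarray:
        """Signed geometric distance to the hyperplane (normalised by ||w||)."""
        z = self.project(acts)
        return (z @ self.w + self.b) / np.linalg.norm(self.w)


@dataclass
class DecoderEnsemble:
    """13 per-sublayer readouts fitted on the labelled training stimuli."""

    readouts: list
    noise: NoiseModel
    seed: int
    provenance: str
    backbone: object = field(repr=False, default=None)

    def distances(self, images: np.ndarray) -> np.ndarray:
        """(B, 13) signed distances for an image batch."""
        acts = self.backbone.extract_batch(images)
        return np.column_stack([r.distance(a) for r, a in zip(self.readouts, acts)])

    def classification_scores(self, target_img: np.ndarray,
                              distractor_img: np.ndarray) -> np.ndarray:
        """13-vector of signed-distance differences (target - distractor)."""
        d = self.distances(np.stack([np.asarray(target_img), np.asarray(distractor_img)]))
        return d[0] - d[1]

    def classification_score(self, target_img: np.ndarray, distractor_img: np.ndarray,
                             layer: int) -> float:
        """Score at one sublayer (1-based index)."""
        if not (1 <= layer <= N_SUBLAYERS):
            raise ValueError(f"layer {layer} not in 1..{N_SUBLAYERS}")
        return float(self.classification_scores(target_img, distractor_img)[layer - 1])

    def training_accuracy(self, images: np.ndarray, labels: np.ndarray) -> np.ndarray:
        """(13,) fraction of stimuli on the correct side per sublayer."""
        d = self.distances(images)
        return (np.sign(d) == np.asarray(labels)[:, None]).mean(axis=0)

    # -- serialisation ------------------------------------------------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        arrays = {}
        for i, r in enumerate(self.readouts):
            arrays.update({
                f"mean_{i}": r.mean, f"components_{i}": r.components,
                f"scale_{i}": r.scale, f"w_{i}": r.w, f"b_{i}": np.array([r.b]),
            })
        meta = {
            "format_version": 1,
            "noise_sd": self.noise.sd,
            "noise_iterations": self.noise.n_iterations,
            "noise_target": self.noise.target_accuracy,
            "noise_achieved": self.noise.achieved_accuracy,
            "seed": self.seed,
            "provenance": self.provenance,
        }
        np.savez(path, meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path: str | Path, backbone: object = None) -> "DecoderEnsemble":
        data = np.load(path, allow_pickle=False)
        meta = json.loads(str(data["meta"]))
        readouts = []
        for i in range(N_SUBLAYERS):
            readouts.append(LayerReadout(
                mean=data[f"mean_{i}"], components=data[f"components_{i}"],
                scale=data[f"scale_{i}"], w=data[f"w_{i}"], b=float(data[f"b_{i}"][0]),
            ))
        noise = NoiseModel(sd=meta["noise_sd"], n_iterations=meta["noise_iterations"],
                           target_accuracy=meta["noise_target"],
                           achieved_accuracy=meta["noise_achieved"])
        return cls(readouts=readouts, noise=noise, seed=meta["seed"],
                   provenance=meta["provenance"], backbone=backbone)


def _noisy(images: np.ndarray, sd: float, rng: np.random.Generator) -> np.ndarray:
    if sd == 0.0:
        return images
    return images + rng.normal(0.0, sd, size=images.shape)


def fit_readouts(backbone, images: np.ndarray, labels: Sequence[int],
                 noise: NoiseModel | float = 0.0, seed: int = 0,
                 max_components: int = DEFAULT_MAX_COMPONENTS) -> DecoderEnsemble:
    """Fit the 13 sublayer readouts on labelled training images.

    Per sublayer: PCA on the training activations retaining
    ``min(n - 1, d, max_components)`` components, per-component
    standardisation, then a max-margin linear classifier.  The readouts are
    fit on the noise-free stimuli — every layer separates the training set
    perfectly — and the input-noise model (``noise``) degrades performance at
    evaluation time only; this is what keeps training accuracy at 100%
    without noise and at the calibrated level with it.  Deterministic given
    the seed.
    """
    images = np.asarray(images, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if images.ndim != 3:
        raise ValueError("expected (n, 100, 100) training images")
    if set(np.unique(labels)) != {-1, 1}:
        raise ValueError("labels must contain both classes, coded +1/-1")
    sd = noise.sd if isinstance(noise, NoiseModel) else float(noise)
    acts = backbone.extract_batch(images)

    n = images.shape[0]
    readouts = []
    for name, a in zip(SUBLAYER_NAMES, acts):
        if np.allclose(a.var(axis=0), 0.0):
            raise CalibrationError(f"degenerate sublayer {name!r}: zero variance")
        n_comp = min(n - 1, a.shape[1], max_components)
        pca = PCA(n_components=n_comp, svd_solver="full")
        z = pca.fit_transform(a)
        scale = z.std(axis=0, ddof=0)
        scale[scale == 0.0] = 1.0
        z = z / scale
        # near-hard-margin: on the noiseless training set every layer should
        # separate the classes perfectly, as the behaviour-matched model only
        # drops below ceiling once input noise is added
        clf = SVC(kernel="linear", C=100.0)
        clf.fit(z, labels)
        readouts.append(LayerReadout(
            mean=pca.mean_, components=pca.components_, scale=scale,
            w=clf.coef_.ravel().astype(float), b=float(clf.intercept_[0]),
        ))
    noise_model = noise if isinstance(noise, NoiseModel) else NoiseModel(sd=sd)
    return DecoderEnsemble(readouts=readouts, noise=noise_model, seed=seed,
                           provenance=getattr(backbone, "provenance", "unknown"),
                           backbone=backbone)


def _mean_training_accuracy(backbone, ensemble: DecoderEnsemble, images: np.ndarray,
                            labels: np.ndarray, sd: float, iters: int,
                            seed: int) -> float:
    """Mean over iterations and sublayers of noisy training-set accuracy."""
    rng = np.random.default_rng(seed)
    accs = np.empty(iters)
    for i in range(iters):
        acc = ensemble.training_accuracy(_noisy(images, sd, rng), labels)
        accs[i] = acc.mean()
    return float(accs.mean())


def calibrate_noise(backbone, images: np.ndarray, labels: Sequence[int],
                    target: float = 0.75, iters: int = 100, tol: float = 0.02,
                    seed: int = 0, sd_max: float = 4.0,
                    max_bisect: int = 24) -> NoiseModel:
    """Bisection on the input-noise SD until mean training accuracy hits target.

    The readouts are fit once on the clean training stimuli; each candidate
    SD is evaluated by re-classifying noise-perturbed inputs, using a common
    seeded noise schedule across SD values so the accuracy curve is
    effectively monotone.  Returns the calibrated SD together with the
    achieved mean accuracy.
    """
    images = np.asarray(images, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if not (0.5 < target <= 1.0):
        raise CalibrationError("target must lie in (0.5, 1]")
    fit_seed, eval_seed = seed, seed + 1
    ens = fit_readouts(backbone, images, labels, noise=0.0, seed=fit_seed)

    def accuracy_at(sd: float) -> float:
        return _mean_training_accuracy(backbone, ens, images, labels, sd, iters, eval_seed)

    acc0 = accuracy_at(0.0)
    if target >= acc0:
        if target - acc0 <= tol:
            return NoiseModel(sd=0.0, n_iterations=iters, target_accuracy=target,
                              achieved_accuracy=acc0)
        raise CalibrationError(
            f"target {target} is not below the noiseless training accuracy {acc0:.3f}")

    lo, acc_lo = 0.0, acc0
    hi = 0.25
    acc_hi = accuracy_at(hi)
    while acc_hi > target and hi < sd_max:
        lo, acc_lo = hi, acc_hi
        hi *= 2.0
        acc_hi = accuracy_at(hi)
    if acc_hi > target:
        raise CalibrationError(
            f"target {target} unreachable: accuracy {acc_hi:.3f} at sd={hi} "
            f"(bracket [{lo}, {hi}] -> [{acc_lo:.3f}, {acc_hi:.3f}])")

    best = (hi, acc_hi) if abs(acc_hi - target) < abs(acc_lo - target) else (lo, acc_lo)
    for _ in range(max_bisect):
        if abs(best[1] - target) <= tol:
            break
        mid = 0.5 * (lo + hi)
        acc_mid = accuracy_at(mid)
        if abs(acc_mid - target) < abs(best[1] - target):
            best = (mid, acc_mid)
        if acc_mid > target:
            lo = mid
        else:
            hi = mid
    if abs(best[1] - target) > tol:
        raise CalibrationError(
            f"bisection did not reach target {target} within tolerance {tol}; "
            f"best accuracy {best[1]:.3f} at sd={best[0]:.4f}")
    return NoiseModel(sd=best[0], n_iterations=iters, target_accuracy=target,
                      achieved_accuracy=best[1])


# --------------------------------------------------------------------------- #
# Pair scoring
# --------------------------------------------------------------------------- #

def spec_id(spec: StimulusSpec) -> str:
    s, t = spec.shape, spec.transform
    return (f"c{s.concavity_level}a{s.alignment_level}"
            f"_rx{t.rot_x}ry{t.rot_y}rz{t.rot_z}"
            f"_{t.light_location}_s{t.size_scale:g}_{t.position}")


def pair_id(target: StimulusSpec, distractor: StimulusSpec) -> str:
    return f"{spec_id(target)}|{spec_id(distractor)}"


def score_pairs(ensemble: DecoderEnsemble, protocol: ProtocolDef,
                cfg: RenderConfig | None = None,
                include_old_pair: bool = False) -> pd.DataFrame:
    """Per pair x sublayer classification scores and binary decisions.

    One row per (pair, sublayer); ``decision`` is True iff the score is
    strictly positive (ties count as incorrect).  With ``include_old_pair``
    the protocol's old (base) pair is scored too, flagged by ``is_old``.
    """
    pair_list = list(protocol.pairs)
    old_flags = [False] * len(pair_list)
    if include_old_pair and protocol.old_pair not in pair_list:
        pair_list.append(protocol.old_pair)
        old_flags.append(True)
    specs = []
    for t, d in pair_list:
        specs.extend([t, d])
    unique = list(dict.fromkeys(specs))
    imgs = np.stack([render(s, cfg).pixels for s in unique])
    dist = ensemble.distances(imgs)
    dist_of = {s: dist[i] for i, s in enumerate(unique)}

    rows = []
    for (t, d), is_old in zip(pair_list, old_flags):
        scores = dist_of[t] - dist_of[d]
        pid = pair_id(t, d)
        for layer in range(N_SUBLAYERS):
            rows.append({
                "pair_id": pid,
                "protocol": protocol.name,
                "target_id": spec_id(t),
                "distractor_id": spec_id(d),
                "sublayer": layer + 1,
                "sublayer_name": SUBLAYER_NAMES[layer],
                "classification_score": scores[layer],
                "decision": bool(scores[layer] > 0),
                "is_old": is_old,
            })
    return pd.DataFrame(rows)


def layer_generalization(ensemble: DecoderEnsemble, protocol: ProtocolDef,
                         noise_sd: float | None = None, iters: int = 1,
                         seed: int = 0, cfg: RenderConfig | None = None) -> pd.DataFrame:
    """Per-sublayer decision accuracy on a protocol, with jackknife 95% CIs.

    Accuracy is the fraction of pairs with positive classification score,
    averaged over noise iterations; the CI comes from a leave-one-iteration-out
    jackknife (zero width when ``iters == 1`` or the noise SD is zero).
    """
    sd = ensemble.noise.sd if noise_sd is None else float(noise_sd)
    specs = []
    for t, d in protocol.pairs:
        specs.extend([t, d])
    unique = list(dict.fromkeys(specs))
    imgs = np.stack([render(s, cfg).pixels for s in unique])
    index = {s: i for i, s in enumerate(unique)}
    t_idx = np.array([index[t] for t, _ in protocol.pairs])
    d_idx = np.array([index[d] for _, d in protocol.pairs])

    rng = np.random.default_rng(seed)
    n_iter = iters if sd > 0 else 1
    acc = np.empty((n_iter, N_SUBLAYERS))
    for i in range(n_iter):
        dist = ensemble.distances(_noisy(imgs, sd, rng))
        scores = dist[t_idx] - dist[d_idx]
        acc[i] = (scores > 0).mean(axis=0)

    mean = acc.mean(axis=0)
    if n_iter > 1:
        loo = (acc.sum(axis=0)[None, :] - acc) / (n_iter - 1)
        se = np.sqrt((n_iter - 1) / n_iter * ((loo - loo.mean(axis=0)) ** 2).sum(axis=0))
    else:
        se = np.zeros(N_SUBLAYERS)
    return pd.DataFrame({
        "sublayer": np.arange(1, N_SUBLAYERS + 1),
        "sublayer_name": SUBLAYER_NAMES,
        "accuracy": mean,
        "ci_low": mean - 1.96 * se,
        "ci_high": mean + 1.96 * se,
        "n_iterations": n_iter,
    })
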