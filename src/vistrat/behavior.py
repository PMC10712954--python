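"""Synthetic observers and trial-level behaviour simulation.

Real behavioural data for this task (touchscreen rats, online humans) are not
shipped with the package; instead, observers are simulated whose choices are
driven by the decoder's layer-wise classification scores.  An observer is a
probit choice model with a lapse rate:

    p(correct) = lambda / 2 + (1 - lambda) * Phi(sum_l w_l * s_l / sigma)

where ``w`` is a simplex of 13 sublayer weights (which stages of the
hierarchy drive choice), ``s`` the pair's classification scores, ``sigma``
the decision noise and ``lambda`` the lapse rate.  A rat-like preset puts its
weight on the convolutional sublayers 4-10 with a high lapse rate; a
human-like preset on the fully connected sublayers 11-13 with a low lapse
rate — the contrast the cross-species analyses are designed to detect.

Sessions reproduce the study's trial structure: 100-trial training sessions
with correction trials after errors, 120-trial test sessions with one-third
old (base-pair) trials, random reward on 80% of new trials, and correction
trials only on old trials.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .backbone import N_SUBLAYERS

__all__ = [
    "ObserverModel",
    "SessionConfig",
    "choice_probability",
    "simulate_sessions",
    "species_presets",
]


@dataclass(frozen=True)
class ObserverModel:
    """Layer-driven probit observer with decision noise and lapses."""

    layer_weights: tuple
    decision_noise: float
    lapse: float
    species: str = "custom"

    def __post_init__(self) -> None:
        w = np.asarray(self.layer_weights, dtype=float)
        if w.shape != (N_SUBLAYERS,):
            raise ValueError(f"need {N_SUBLAYERS} layer weights")
        if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
            raise ValueError("layer weights must be non-negative and sum to 1")
        if self.decision_noise <= 0:
            raise ValueError("decision noise must be positive")
        if not 0.0 <= self.lapse <= 1.0:
            raise ValueError("lapse must lie in [0, 1]")

    @property
    def weights(self) -> np.ndarray:
        return np.asarray(self.layer_weights, dtype=float)


@dataclass(frozen=True)
class SessionConfig:
    """Session structure of the discrimination task."""

    max_trials: int = 120
    old_fraction: float = 1 / 3
    random_reward_rate: float = 0.8
    correction_trials: bool = True
    max_corrections: int = 25
    base_pair_exclusion_threshold: float = 0.65
    is_training: bool = False

    def __post_init__(self) -> None:
        if self.max_trials < 1:
            raise ValueError("max_trials must be >= 1")
        for f in (self.old_fraction, self.random_reward_rate,
                  self.base_pair_exclusion_threshold):
            if not 0.0 <= f <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")


TRAINING_SESSION = SessionConfig(max_trials=100, old_fraction=0.0,
                                 random_reward_rate=1.0, is_training=True)
TEST_SESSION = SessionConfig()


def choice_probability(observer: ObserverModel, pair_scores: np.ndarray) -> float:
    """Probability the observer picks the target for a pair's 13 layer scores."""
    s = np.asarray(pair_scores, dtype=float)
    if s.shape != (N_SUBLAYERS,):
        raise ValueError(f"need {N_SUBLAYERS} layer scores")
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    drive = float(observer.weights @ s) / observer.decision_noise
    return float(observer.lapse / 2.0 + (1.0 - observer.lapse) * norm.cdf(drive))


def _score_lookup(scores: pd.DataFrame) -> dict[str, np.ndarray]:
    """pair_id -> (13,) score vector from a pair-score table."""
    lookup: dict[str, np.ndarray] = {}
    for pid, grp in scores.groupby("pair_id", sort=False):
        vec = grp.sort_values("sublayer")["classification_score"].to_numpy()
        if vec.shape != (N_SUBLAYERS,):
            raise ValueError(f"pair {pid!r} lacks scores for all sublayers")
        lookup[pid] = vec
    return lookup


def simulate_sessions(observer: ObserverModel,
                      scores: pd.DataFrame,
                      config: SessionConfig = TEST_SESSION,
                      n_sessions: int = 1,
                      subject: str = "sim-0",
                      seed: int = 0,
                      old_pair_id: str | None = None) -> pd.DataFrame:
    """Simulate trial records for one subject on one protocol.

    ``scores`` is a pair-score table (``decoder.score_pairs`` layout) for a
    single protocol; ``old_pair_id`` identifies the base pair within it (old
    trials are skipped when absent or when ``old_fraction`` is 0).  Returns a
    tidy trial table with one row per trial, correction trials included and
    flagged.
    """
    protocols = scores["protocol"].unique()
    if len(protocols) != 1:
        raise ValueError("scores must describe exactly one protocol")
    protocol = protocols[0]
    lookup = _score_lookup(scores)
    if old_pair_id is not None and old_pair_id not in lookup:
        raise ValueError(f"old pair {old_pair_id!r} has no scores")
    new_ids = [p for p in lookup if p != old_pair_id]
    if not new_ids:
        raise ValueError("no non-old pairs to present")
    p_correct = {pid: choice_probability(observer, vec) for pid, vec in lookup.items()}

    rng = np.random.default_rng(seed)
    rows = []
    for sess in range(n_sessions):
        for _ in range(config.max_trials):
            is_old = (old_pair_id is not None
                      and rng.random() < config.old_fraction)
            pid = old_pair_id if is_old else new_ids[rng.integers(len(new_ids))]
            correct = bool(rng.random() < p_correct[pid])
            if is_old or config.is_training:
                rewarded = correct
            else:
                rewarded = bool(rng.random() < config.random_reward_rate)
            rows.append((subject, observer.species, protocol, sess, pid,
                         is_old, False, correct, rewarded))
            # correction trials: repeat after errors, veridical trials only
            if (config.correction_trials and not correct
                    and (config.is_training or is_old)):
                for _ in range(config.max_corrections):
                    c = bool(rng.random() < p_correct[pid])
                    rows.append((subject, observer.species, protocol, sess, pid,
                                 is_old, True, c, c))
                    if c:
                        break
    return pd.DataFrame(rows, columns=[
        "subject", "species", "protocol", "session", "pair_id",
        "is_old", "is_correction", "correct", "rewarded",
    ])


def species_presets() -> tuple[ObserverModel, ObserverModel]:
    """(rat_like, human_like) observer presets.

    The rat-like observer reads out the convolutional sublayers 4-10 with
    extra weight on the earlier ones, a high lapse rate and coarse decision
    noise; the human-like observer reads out the fully connected sublayers
    11-13 with a low lapse rate and finer noise.  The parameters are
    illustrative: they are chosen to reproduce the qualitative species
    contrast (low-level vs high-level readout, large accuracy gap), not any
    quantitative behavioural values.
    """
    rat_w = np.zeros(N_SUBLAYERS)
    rat_w[3:10] = (3, 3, 3, 2, 2, 1, 1)  # sublayers 4..10
    rat_w /= rat_w.sum()
    human_w = np.zeros(N_SUBLAYERS)
    human_w[10:13] = 1 / 3               # sublayers 11..13
    rat = ObserverModel(layer_weights=tuple(rat_w), decision_noise=1.5,
                        lapse=0.30, species="rat_like")
    human = ObserverModel(layer_weights=tuple(human_w), decision_noise=0.75,
                          lapse=0.05, species="human_like")
    return rat, human
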