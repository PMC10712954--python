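"""Behavioural statistics: accuracy matrices, chance tests, layer correlation
profiles with permutation tests, reliability, layer regression, low-level
feature predictors and species comparisons.

Conventions follow the behavioural analyses the pipeline emulates: correction
trials never enter accuracy computations; test sessions whose base-pair (old
trial) accuracy falls below 65% are excluded; "pooled" accuracy sums correct
trials over subjects before dividing (subject-mean aggregation is also
available); permutation p-values are one-sided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .backbone import N_SUBLAYERS
from .stimuli import RenderConfig, StimulusSpec, brightness, pixel_dissimilarity, render

__all__ = [
    "PerformanceMatrix",
    "accuracy_table",
    "binomial_chance_test",
    "CorrelationProfile",
    "layer_correlation_profile",
    "split_half_reliability",
    "spearman_brown",
    "combined_reliability",
    "RegressionResult",
    "layer_regression",
    "brightness_predictor",
    "pixel_similarity_predictor",
    "SpeciesComparison",
    "species_comparison",
    "pooled_pair_accuracy",
]


# --------------------------------------------------------------------------- #
# Accuracy tables
# --------------------------------------------------------------------------- #

@dataclass
class PerformanceMatrix:
    """Per-pair accuracies for one protocol after exclusion rules."""

    protocol: str
    table: pd.DataFrame           # pair_id, n_trials, n_correct, accuracy
    old_accuracy: float | None
    old_n: int
    excluded_sessions: list
    empty: bool = False

    def matrix(self) -> pd.DataFrame:
        """Accuracy pivoted to a target x distractor matrix."""
        t = self.table.copy()
        t[["target_id", "distractor_id"]] = t["pair_id"].str.split("|", expand=True)
        return t.pivot(index="target_id", columns="distractor_id", values="accuracy")


def _apply_exclusions(trials: pd.DataFrame, threshold: float) -> tuple[pd.DataFrame, list]:
    """Drop correction trials and sessions failing the base-pair rule."""
    t = trials[~trials["is_correction"]]
    excluded = []
    keys = ["subject", "protocol", "session"]
    old = t[t["is_old"]]
    if len(old):
        sess_acc = old.groupby(keys)["correct"].mean()
        for key, acc in sess_acc.items():
            if acc < threshold:
                excluded.append(key)
    if excluded:
        idx = pd.MultiIndex.from_tuples(excluded, names=keys)
        mask = pd.MultiIndex.from_frame(t[keys]).isin(idx)
        t = t[~mask]
    return t, excluded


def accuracy_table(trials: pd.DataFrame, protocol: str,
                   base_pair_exclusion_threshold: float = 0.65) -> PerformanceMatrix:
    """Per-pair accuracy on new trials, pooled over subjects and sessions.

    Correction trials are dropped everywhere; sessions whose old-trial
    accuracy is below the threshold are excluded entirely; old-pair accuracy
    is reported separately and never mixed into the per-pair table.
    """
    sub = trials[trials["protocol"] == protocol]
    if len(sub) == 0:
        raise ValueError(f"protocol {protocol!r} absent from trial table")
    sub, excluded = _apply_exclusions(sub, base_pair_exclusion_threshold)

    old = sub[sub["is_old"]]
    old_acc = float(old["correct"].mean()) if len(old) else None
    new = sub[~sub["is_old"]]
    if len(new) == 0:
        return PerformanceMatrix(protocol=protocol,
                                 table=pd.DataFrame(columns=["pair_id", "n_trials",
                                                             "n_correct", "accuracy"]),
                                 old_accuracy=old_acc, old_n=len(old),
                                 excluded_sessions=excluded, empty=True)
    grp = new.groupby("pair_id")["correct"].agg(n_trials="size", n_correct="sum")
    grp["accuracy"] = grp["n_correct"] / grp["n_trials"]
    table = grp.reset_index()
    return PerformanceMatrix(protocol=protocol, table=table, old_accuracy=old_acc,
                             old_n=len(old), excluded_sessions=excluded)


def pooled_pair_accuracy(trials: pd.DataFrame, pair_order: list[str],
                         base_pair_exclusion_threshold: float = 0.65) -> np.ndarray:
    """Accuracy vector over ``pair_order`` pooled across protocols/subjects.

    Pairs with no usable trials come back as NaN (dropped pairwise by the
    correlation/regression stages).
    """
    t, _ = _apply_exclusions(trials, base_pair_exclusion_threshold)
    t = t[~t["is_old"]]
    acc = t.groupby("pair_id")["correct"].mean()
    return np.array([acc.get(p, np.nan) for p in pair_order])


def binomial_chance_test(k: int, n: int, p0: float = 0.5,
                         conf_level: float = 0.95) -> tuple[float, tuple[float, float]]:
    """Exact two-sided binomial test plus Clopper-Pearson CI for k/n."""
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    res = sps.binomtest(k, n, p0)
    ci = res.proportion_ci(confidence_level=conf_level, method="exact")
    return float(res.pvalue), (float(ci.low), float(ci.high))


# --------------------------------------------------------------------------- #
# Layer correlation profile
# --------------------------------------------------------------------------- #

@dataclass
class CorrelationProfile:
    """Per-sublayer Pearson r between behaviour and classification score."""

    r: np.ndarray                 # (13,)
    p: np.ndarray                 # (13,) one-sided permutation p-values
    n_permutations: int
    n_pairs: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"sublayer": np.arange(1, N_SUBLAYERS + 1),
                             "r": self.r, "p_perm": self.p})


def layer_correlation_profile(accuracies: np.ndarray, scores: np.ndarray,
                              n_perm: int = 1000, seed: int = 0) -> CorrelationProfile:
    """Correlate per-pair accuracy with per-layer classification scores.

    ``scores`` is (n_pairs, 13); pairs with missing accuracy are dropped.
    The permutation test shuffles the accuracy vector (the same permutation
    across layers) and counts permuted correlations >= the observed one;
    p = (count + 1) / (n_perm + 1), keeping p in (0, 1].
    """
    acc = np.asarray(accuracies, dtype=float)
    sc = np.asarray(scores, dtype=float)
    if sc.ndim != 2 or sc.shape[1] != N_SUBLAYERS:
        raise ValueError(f"scores must be (n_pairs, {N_SUBLAYERS})")
    if len(acc) != len(sc):
        raise ValueError("accuracies and scores must align")
    keep = np.isfinite(acc)
    acc, sc = acc[keep], sc[keep]
    n = len(acc)
    if n < 3:
        raise ValueError("need at least 3 pairs with usable accuracy")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")

    def corr_all(a: np.ndarray) -> np.ndarray:
        az = (a - a.mean()) / a.std(ddof=0)
        sz = (sc - sc.mean(axis=0)) / sc.std(axis=0, ddof=0)
        return az @ sz / n

    r_obs = corr_all(acc)
    rng = np.random.default_rng(seed)
    count = np.zeros(N_SUBLAYERS, dtype=int)
    for _ in range(n_perm):
        count += corr_all(rng.permutation(acc)) >= r_obs
    p = (count + 1) / (n_perm + 1)
    return CorrelationProfile(r=r_obs, p=p, n_permutations=n_perm, n_pairs=n)


# --------------------------------------------------------------------------- #
# Reliability
# --------------------------------------------------------------------------- #

def split_half_reliability(trials: pd.DataFrame, n_splits: int = 100,
                           seed: int = 0,
                           base_pair_exclusion_threshold: float = 0.65) -> float:
    """Mean Pearson correlation between per-pair accuracies of random
    trial halves, over ``n_splits`` splits.

    Trials of every pair are randomly halved; pairs with fewer than two usable
    trials are skipped.  Correction and old trials never enter.
    """
    t, _ = _apply_exclusions(trials, base_pair_exclusion_threshold)
    t = t[~t["is_old"]]
    groups = [(pid, g["correct"].to_numpy())
              for pid, g in t.groupby("pair_id") if len(g) >= 2]
    if len(groups) < 3:
        raise ValueError("need at least 3 pairs with >= 2 trials")
    rng = np.random.default_rng(seed)
    rs = np.empty(n_splits)
    for s in range(n_splits):
        a_half = np.empty(len(groups))
        b_half = np.empty(len(groups))
        for i, (_, correct) in enumerate(groups):
            perm = rng.permutation(len(correct))
            half = len(correct) // 2
            a_half[i] = correct[perm[:half]].mean()
            b_half[i] = correct[perm[half:]].mean()
        rs[s] = sps.pearsonr(a_half, b_half)[0]
    return float(np.nanmean(rs))


def spearman_brown(r: float, factor: float = 2.0) -> float:
    """Spearman-Brown prophecy: reliability of a test lengthened by ``factor``."""
    if not (-1.0 < r <= 1.0):
        raise ValueError("r must lie in (-1, 1]")
    return factor * r / (1.0 + (factor - 1.0) * r)


def combined_reliability(r1: float, r2: float) -> float:
    """Reliability ceiling for a correlation between two noisy datasets:
    the geometric mean of their full-set reliabilities."""
    for r in (r1, r2):
        if not (0.0 <= r <= 1.0):
            raise ValueError("full-set reliabilities must lie in [0, 1]")
    return float(np.sqrt(r1 * r2))


# --------------------------------------------------------------------------- #
# Layer regression
# --------------------------------------------------------------------------- #

@dataclass
class RegressionResult:
    """OLS of per-pair accuracy on the 13 layer scores."""

    r_squared: float
    f_statistic: float
    f_pvalue: float
    df_model: int
    df_resid: int
    coefficients: np.ndarray      # (13,) slopes, intercept excluded
    coef_pvalues: np.ndarray
    coef_tvalues: np.ndarray
    n_pairs: int

    @property
    def correlation_scale(self) -> float:
        """sqrt(R^2): the correlation-equivalent of the full model's fit."""
        return float(np.sqrt(self.r_squared))


def layer_regression(accuracies: np.ndarray, scores: np.ndarray) -> RegressionResult:
    """Multiple linear regression of accuracy on the 13 classification scores."""
    acc = np.asarray(accuracies, dtype=float)
    sc = np.asarray(scores, dtype=float)
    if sc.ndim != 2 or sc.shape[1] != N_SUBLAYERS:
        raise ValueError(f"scores must be (n_pairs, {N_SUBLAYERS})")
    keep = np.isfinite(acc)
    acc, sc = acc[keep], sc[keep]
    X = sm.add_constant(sc)
    model = sm.OLS(acc, X).fit()
    return RegressionResult(
        r_squared=float(model.rsquared),
        f_statistic=float(model.fvalue),
        f_pvalue=float(model.f_pvalue),
        df_model=int(model.df_model),
        df_resid=int(model.df_resid),
        coefficients=model.params[1:],
        coef_pvalues=model.pvalues[1:],
        coef_tvalues=model.tvalues[1:],
        n_pairs=len(acc),
    )


# --------------------------------------------------------------------------- #
# Low-level feature predictors
# --------------------------------------------------------------------------- #

def _image_of(spec: StimulusSpec, cfg: RenderConfig | None) -> np.ndarray:
    return render(spec, cfg).pixels


def brightness_predictor(base_pair: tuple[StimulusSpec, StimulusSpec],
                         test_pairs: list[tuple[StimulusSpec, StimulusSpec]],
                         accuracies: np.ndarray | None = None,
                         cfg: RenderConfig | None = None,
                         ) -> tuple[np.ndarray, float | None]:
    """Brightness-difference predictor per test pair, optionally correlated
    with per-pair accuracy.

    value = (B(base target) - B(base distractor))
            - (B(test target) - B(test distractor)).
    """
    bt, bd = (brightness(_image_of(s, cfg)) for s in base_pair)
    base_diff = bt - bd
    values = np.array([
        base_diff - (brightness(_image_of(t, cfg)) - brightness(_image_of(d, cfg)))
        for t, d in test_pairs
    ])
    r = _optional_corr(values, accuracies)
    return values, r


def _pearson_image_similarity(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.corrcoef(a.ravel(), b.ravel())[0, 1])


def pixel_similarity_predictor(base_pair: tuple[StimulusSpec, StimulusSpec],
                               test_pairs: list[tuple[StimulusSpec, StimulusSpec]],
                               accuracies: np.ndarray | None = None,
                               similarity: str = "pearson",
                               cfg: RenderConfig | None = None,
                               ) -> tuple[np.ndarray, float | None]:
    """Pixel-similarity predictor per test pair.

    With A = sim(base target, test distractor), B = sim(base target,
    test target), C = sim(base distractor, test distractor), D =
    sim(base distractor, test target), the value is (A + D)/2 - (C + B)/2:
    positive when the test pair's members resemble the *opposite* base-pair
    member, i.e. when pixel similarity works against the correct choice.
    ``similarity`` is "pearson" (pixel-vector correlation, default) or
    "neg_euclidean".
    """
    if similarity == "pearson":
        sim = _pearson_image_similarity
    elif similarity == "neg_euclidean":
        sim = lambda a, b: -pixel_dissimilarity(a, b)
    else:
        raise ValueError(f"unknown similarity {similarity!r}")
    bt, bd = (_image_of(s, cfg) for s in base_pair)
    values = np.empty(len(test_pairs))
    for i, (t, d) in enumerate(test_pairs):
        it, idd = _image_of(t, cfg), _image_of(d, cfg)
        A = sim(bt, idd)
        B = sim(bt, it)
        C = sim(bd, idd)
        D = sim(bd, it)
        values[i] = (A + D) / 2.0 - (C + B) / 2.0
    r = _optional_corr(values, accuracies)
    return values, r


def _optional_corr(values: np.ndarray, accuracies: np.ndarray | None) -> float | None:
    if accuracies is None:
        return None
    acc = np.asarray(accuracies, dtype=float)
    keep = np.isfinite(acc)
    return float(sps.pearsonr(values[keep], acc[keep])[0])


# --------------------------------------------------------------------------- #
# Species comparison
# --------------------------------------------------------------------------- #

@dataclass
class SpeciesComparison:
    """Training-normalised test performance and the species x protocol tests."""

    per_subject: pd.DataFrame     # subject, species, train_acc, test_acc, normalized
    normalized_t: float           # unpaired t on (test - train) across species
    normalized_p: float
    interaction_t: float | None   # unpaired t on (zero_vs_high - high_vs_zero)
    interaction_p: float | None
    paired_t: dict                # species -> (t, p) zero_vs_high vs high_vs_zero
    degenerate: bool = False


def _subject_accuracy(trials: pd.DataFrame, protocols: list[str] | None,
                      threshold: float) -> pd.Series:
    t, _ = _apply_exclusions(trials, threshold)
    t = t[~t["is_old"]]
    if protocols is not None:
        t = t[t["protocol"].isin(protocols)]
    return t.groupby("subject")["correct"].mean()


def species_comparison(trials_a: pd.DataFrame, trials_b: pd.DataFrame,
                       training_protocols: list[str] = ("training",
                                                        "dimension_learning",
                                                        "transformations"),
                       test_protocols: list[str] | None = None,
                       contrast: tuple[str, str] = ("zero_vs_high", "high_vs_zero"),
                       base_pair_exclusion_threshold: float = 0.65,
                       ) -> SpeciesComparison:
    """Compare two species' trial tables.

    Computes per-subject training and test accuracy, training-normalised test
    performance (test - train), a Welch t-test on the normalised performance
    across species, per-species paired t-tests between the two contrast
    protocols, and the species x protocol interaction (unpaired t on the
    per-subject contrast difference).
    """
    frames = []
    for trials in (trials_a, trials_b):
        species = trials["species"].iloc[0]
        all_protos = set(trials["protocol"].unique())
        have_training = bool(all_protos & set(training_protocols))
        if have_training:
            train = _subject_accuracy(
                trials[trials["protocol"].isin(training_protocols)],
                None, base_pair_exclusion_threshold)
        else:
            train = pd.Series(dtype=float)
        tests = (test_protocols if test_protocols is not None
                 else sorted(all_protos - set(training_protocols)))
        test = _subject_accuracy(trials, tests, base_pair_exclusion_threshold)
        df = pd.DataFrame({"train_acc": train, "test_acc": test})
        df = df[df["test_acc"].notna()]
        df["normalized"] = df["test_acc"] - df["train_acc"].fillna(0.0)
        df["species"] = species
        for proto in contrast:
            if proto in all_protos:
                df[proto] = _subject_accuracy(trials, [proto],
                                              base_pair_exclusion_threshold)
        frames.append(df.reset_index())
    per_subject = pd.concat(frames, ignore_index=True)

    a, b = (per_subject[per_subject["species"] == s]["normalized"].to_numpy()
            for s in per_subject["species"].unique()[:2])
    degenerate = (np.std(a, ddof=1) == 0.0 and np.std(b, ddof=1) == 0.0)
    if degenerate:
        # zero within-group variance: identical means -> t = 0, otherwise the
        # difference is infinitely many SEs away
        if np.mean(a) == np.mean(b):
            t_norm, p_norm = 0.0, 1.0
        else:
            t_norm, p_norm = np.inf, 0.0
    else:
        t_norm, p_norm = sps.ttest_ind(a, b, equal_var=False)

    paired = {}
    inter_t = inter_p = None
    c0, c1 = contrast
    if c0 in per_subject.columns and c1 in per_subject.columns:
        diffs = []
        for s in per_subject["species"].unique():
            sub = per_subject[per_subject["species"] == s][[c0, c1]].dropna()
            if len(sub) >= 2:
                paired[s] = tuple(map(float, sps.ttest_rel(sub[c0], sub[c1])))
            diffs.append((sub[c0] - sub[c1]).to_numpy())
        if len(diffs) == 2 and min(map(len, diffs)) >= 2:
            inter_t, inter_p = map(float, sps.ttest_ind(diffs[0], diffs[1],
                                                        equal_var=False))
    return SpeciesComparison(per_subject=per_subject,
                             normalized_t=float(t_norm), normalized_p=float(p_norm),
                             interaction_t=inter_t, interaction_p=inter_p,
                             paired_t=paired, degenerate=degenerate)
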