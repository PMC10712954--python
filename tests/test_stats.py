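"""Statistics: accuracy tables, chance tests, correlations, reliability,
regression, feature predictors, species contrasts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from vistrat import stats as sa
from vistrat import stimuli as st
from vistrat.backbone import N_SUBLAYERS
from vistrat.stimuli import DEFAULT_SUBGRID


def _trials(rows):
    cols = ["subject", "species", "protocol", "session", "pair_id",
            "is_old", "is_correction", "correct", "rewarded"]
    return pd.DataFrame(rows, columns=cols)


def _row(pair="p1", correct=True, old=False, corr=False, session=0,
         subject="s1", protocol="test"):
    return (subject, "sim", protocol, session, pair, old, corr, correct, correct)


class TestAccuracyTable:
    def test_simple_fraction(self):
        rows = [_row(correct=i < 7) for i in range(10)]
        pm = sa.accuracy_table(_trials(rows), "test")
        assert pm.table["accuracy"].iloc[0] == pytest.approx(0.7)
        assert pm.table["n_trials"].iloc[0] == 10

    def test_correction_trials_never_counted(self):
        rows = [_row(correct=True)] * 5 + [_row(correct=False, corr=True)] * 20
        pm = sa.accuracy_table(_trials(rows), "test")
        assert pm.table["accuracy"].iloc[0] == 1.0
        assert pm.table["n_trials"].iloc[0] == 5

    def test_session_below_base_pair_threshold_is_dropped(self):
        good = ([_row(pair="old", old=True, correct=True, session=0)] * 10
                + [_row(pair="p1", correct=True, session=0)] * 10)
        bad = ([_row(pair="old", old=True, correct=i < 6, session=1) for i in range(10)]
               + [_row(pair="p1", correct=False, session=1)] * 10)
        pm = sa.accuracy_table(_trials(good + bad), "test")
        # session 1 ran at 60% on the base pair: every one of its trials is excluded
        assert pm.excluded_sessions == [("s1", "test", 1)]
        assert pm.table["accuracy"].iloc[0] == 1.0
        assert pm.old_accuracy == 1.0

    def test_all_corrections_gives_flagged_empty_matrix(self):
        rows = [_row(correct=False, corr=True)] * 4
        pm = sa.accuracy_table(_trials(rows), "test")
        assert pm.empty
        assert len(pm.table) == 0

    def test_trial_order_invariance(self):
        rng = np.random.default_rng(0)
        rows = [_row(pair=f"p{i % 3}", correct=bool(rng.integers(2))) for i in range(60)]
        a = sa.accuracy_table(_trials(rows), "test").table
        b = sa.accuracy_table(_trials(list(reversed(rows))), "test").table
        pd.testing.assert_frame_equal(a, b)

    def test_missing_protocol_rejected(self):
        with pytest.raises(ValueError):
            sa.accuracy_table(_trials([_row()]), "nope")


class TestBinomialTest:
    def test_all_successes_closed_form(self):
        # two-sided exact test of 20/20 against 0.5: p = 2 * 0.5^20
        p, ci = sa.binomial_chance_test(20, 20)
        assert p == pytest.approx(2 * 0.5 ** 20)
        assert ci[1] == 1.0

    def test_point_at_null(self):
        p, _ = sa.binomial_chance_test(10, 20)
        assert p == 1.0

    @settings(max_examples=30, derandomize=True)
    @given(hst.integers(1, 60).flatmap(
        lambda n: hst.tuples(hst.integers(0, n), hst.just(n))))
    def test_ci_brackets_observed_proportion(self, kn):
        k, n = kn
        _, (lo, hi) = sa.binomial_chance_test(k, n)
        assert lo <= k / n <= hi

    def test_domain(self):
        with pytest.raises(ValueError):
            sa.binomial_chance_test(5, 4)


class TestCorrelationProfile:
    def test_accuracy_equal_to_one_layers_scores(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=(60, N_SUBLAYERS))
        prof = sa.layer_correlation_profile(scores[:, 4], scores, n_perm=100, seed=0)
        assert prof.r[4] == pytest.approx(1.0)
        assert prof.p[4] == pytest.approx(1 / 101)

    def test_p_values_lie_in_unit_interval_and_reproduce(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(size=(40, N_SUBLAYERS))
        acc = rng.random(40)
        a = sa.layer_correlation_profile(acc, scores, n_perm=200, seed=3)
        b = sa.layer_correlation_profile(acc, scores, n_perm=200, seed=3)
        assert np.array_equal(a.p, b.p)
        assert np.all((a.p > 0) & (a.p <= 1))

    def test_independent_accuracies_give_unremarkable_p(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=(100, N_SUBLAYERS))
        acc = rng.random(100)
        prof = sa.layer_correlation_profile(acc, scores, n_perm=400, seed=4)
        assert 0.05 < np.mean(prof.p) < 0.95

    def test_nan_accuracies_dropped_pairwise(self):
        rng = np.random.default_rng(4)
        scores = rng.normal(size=(30, N_SUBLAYERS))
        acc = scores[:, 0].copy()
        acc[:5] = np.nan
        prof = sa.layer_correlation_profile(acc, scores, n_perm=50, seed=0)
        assert prof.n_pairs == 25
        assert prof.r[0] == pytest.approx(1.0)


class TestReliability:
    def test_deterministic_mixed_observer_has_unit_reliability(self):
        rows = []
        for i in range(12):
            perfect = i % 2 == 0
            rows += [_row(pair=f"p{i}", correct=perfect, session=s) for s in range(20)]
        r = sa.split_half_reliability(_trials(rows), n_splits=10, seed=0)
        assert r == pytest.approx(1.0)

    def test_pure_guessing_has_near_zero_reliability(self):
        rng = np.random.default_rng(5)
        rows = [_row(pair=f"p{i}", correct=bool(rng.integers(2)))
                for i in range(40) for _ in range(40)]
        r = sa.split_half_reliability(_trials(rows), n_splits=40, seed=1)
        assert abs(r) < 0.15

    def test_duplicating_trials_preserves_expected_reliability(self):
        rng = np.random.default_rng(6)
        rows = [_row(pair=f"p{i}", correct=bool(rng.random() < 0.5 + 0.4 * np.sin(i)))
                for i in range(30) for _ in range(30)]
        base = _trials(rows)
        doubled = pd.concat([base, base], ignore_index=True)
        r1 = sa.split_half_reliability(base, n_splits=60, seed=2)
        r2 = sa.split_half_reliability(doubled, n_splits=60, seed=3)
        # doubling adds trials per half, so reliability cannot drop; it stays
        # in the same regime rather than jumping to a different statistic
        assert r2 >= r1 - 0.05

    def test_spearman_brown_published_examples(self):
        assert sa.spearman_brown(0.46) == pytest.approx(0.63, abs=0.005)
        assert sa.spearman_brown(0.0) == 0.0
        assert sa.spearman_brown(1.0) == 1.0

    @settings(max_examples=40, derandomize=True)
    @given(hst.floats(-0.99, 0.999), hst.floats(1e-4, 0.999))
    def test_spearman_brown_strictly_monotone(self, r, dr):
        r2 = min(r + dr, 0.9999)
        assert sa.spearman_brown(r2) > sa.spearman_brown(r)

    def test_spearman_brown_domain(self):
        with pytest.raises(ValueError):
            sa.spearman_brown(-1.0)

    def test_combined_reliability_published_example(self):
        # split-half values 0.40 and 0.46 -> full-set 0.571 and 0.630
        full1 = sa.spearman_brown(0.40)
        full2 = sa.spearman_brown(0.46)
        assert sa.combined_reliability(full1, full2) == pytest.approx(0.60, abs=0.005)

    def test_combined_reliability_fixed_points(self):
        assert sa.combined_reliability(0.7, 0.7) == pytest.approx(0.7)
        assert sa.combined_reliability(0.0, 0.9) == 0.0
        with pytest.raises(ValueError):
            sa.combined_reliability(-0.1, 0.5)


class TestRegression:
    def test_response_equal_to_single_regressor(self):
        rng = np.random.default_rng(7)
        scores = rng.normal(size=(50, N_SUBLAYERS))
        res = sa.layer_regression(scores[:, 2], scores)
        assert res.r_squared == pytest.approx(1.0)

    def test_response_orthogonal_to_all_regressors(self):
        rng = np.random.default_rng(8)
        scores = rng.normal(size=(60, N_SUBLAYERS))
        y = rng.normal(size=60)
        # residualise y against the regressors and the intercept
        X = np.column_stack([np.ones(60), scores])
        resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        res = sa.layer_regression(resid, scores)
        assert res.r_squared == pytest.approx(0.0, abs=1e-10)

    def test_correlation_scale_of_published_r_squared(self):
        res = sa.RegressionResult(r_squared=0.10, f_statistic=0, f_pvalue=1,
                                  df_model=13, df_resid=273,
                                  coefficients=np.zeros(13),
                                  coef_pvalues=np.ones(13),
                                  coef_tvalues=np.zeros(13), n_pairs=287)
        assert res.correlation_scale == pytest.approx(0.32, abs=0.005)

    def test_reported_degrees_of_freedom(self):
        rng = np.random.default_rng(9)
        scores = rng.normal(size=(287, N_SUBLAYERS))
        res = sa.layer_regression(rng.random(287), scores)
        assert (res.df_model, res.df_resid) == (13, 273)
        assert res.n_pairs == 287


class TestFeaturePredictors:
    BASE = (DEFAULT_SUBGRID.base_target, DEFAULT_SUBGRID.base_distractor)

    def test_base_pair_as_test_pair_scores_zero_brightness(self):
        values, _ = sa.brightness_predictor(self.BASE, [self.BASE])
        assert values[0] == pytest.approx(0.0)

    def test_brightness_matches_independent_arithmetic(self):
        pairs = [(self.BASE[0].with_transform(size_scale=0.8),
                  self.BASE[1].with_transform(size_scale=0.8)),
                 (self.BASE[0].with_transform(rot_y=60),
                  self.BASE[1].with_transform(rot_z=120))]
        values, _ = sa.brightness_predictor(self.BASE, pairs)
        def b(spec):
            return st.render(spec).pixels.mean()
        for v, (t, d) in zip(values, pairs):
            expect = (b(self.BASE[0]) - b(self.BASE[1])) - (b(t) - b(d))
            assert v == pytest.approx(expect)

    def test_brightness_invariant_to_uniform_offset(self):
        # the predictor is a difference of differences: adding the same
        # constant to every image cancels exactly
        rng = np.random.default_rng(10)
        imgs = rng.random((4, 100, 100)) * 0.5
        diff = (st.brightness(imgs[0]) - st.brightness(imgs[1])) - \
               (st.brightness(imgs[2]) - st.brightness(imgs[3]))
        shifted = [st.brightness(i + 0.25) for i in imgs]
        diff2 = (shifted[0] - shifted[1]) - (shifted[2] - shifted[3])
        assert diff == pytest.approx(diff2)

    def test_pixel_similarity_of_base_pair_is_nonpositive(self):
        values, _ = sa.pixel_similarity_predictor(self.BASE, [self.BASE])
        # substituting the base pair: value = sim(baseT, baseD) - 1 <= 0
        assert values[0] <= 0.0

    def test_pixel_similarity_matches_independent_arithmetic(self):
        pair = (self.BASE[0].with_transform(rot_x=90),
                self.BASE[1].with_transform(rot_x=90))
        values, _ = sa.pixel_similarity_predictor(self.BASE, [pair])
        bt = st.render(self.BASE[0]).pixels.ravel()
        bd = st.render(self.BASE[1]).pixels.ravel()
        tt = st.render(pair[0]).pixels.ravel()
        td = st.render(pair[1]).pixels.ravel()
        c = lambda a, b: np.corrcoef(a, b)[0, 1]
        expect = (c(bt, td) + c(bd, tt)) / 2 - (c(bd, td) + c(bt, tt)) / 2
        assert values[0] == pytest.approx(expect)

    def test_unknown_similarity_rejected(self):
        with pytest.raises(ValueError):
            sa.pixel_similarity_predictor(self.BASE, [self.BASE], similarity="cosine")


class TestSpeciesComparison:
    def _table(self, species, subject_accs, protocol="zero_vs_high"):
        rows = []
        for subj, acc in subject_accs.items():
            rows += [(subj, species, "training", 0, "p0", False, False,
                      bool(i < 10 * acc), True) for i in range(10)]
            rows += [(subj, species, protocol, 0, "p1", False, False,
                      bool(i < 10 * acc), True) for i in range(10)]
        return _trials(rows)

    def test_identical_groups_give_zero_t(self):
        a = self._table("a", {"s1": 0.8, "s2": 0.8})
        b = self._table("b", {"s3": 0.8, "s4": 0.8})
        comp = sa.species_comparison(a, b)
        assert comp.normalized_t == 0.0
        assert comp.degenerate

    def test_constant_offset_zero_variance_flagged_degenerate(self):
        a = self._table("a", {"s1": 0.9, "s2": 0.9})
        b = self._table("b", {"s3": 0.6, "s4": 0.6})
        # training accuracy equals test accuracy per subject here, so shift
        # the test protocol only
        b.loc[(b["protocol"] != "training"), "correct"] = False
        comp = sa.species_comparison(a, b)
        assert comp.degenerate
        assert np.isinf(comp.normalized_t)

    def test_species_dissociation_detected_on_simulated_presets(self, sim_trials):
        rat = sim_trials[sim_trials["species"] == "rat_like"]
        human = sim_trials[sim_trials["species"] == "human_like"]
        comp = sa.species_comparison(rat, human, training_protocols=())
        # per-subject contrast (zero_vs_high - high_vs_zero) by species
        ps = comp.per_subject
        rat_diff = (ps[ps.species == "rat_like"]["zero_vs_high"]
                    - ps[ps.species == "rat_like"]["high_vs_zero"]).mean()
        human_diff = (ps[ps.species == "human_like"]["zero_vs_high"]
                      - ps[ps.species == "human_like"]["high_vs_zero"]).mean()
        # the interaction: human-like observers favour zero-vs-high,
        # rat-like observers the opposite
        assert human_diff > 0 > rat_diff
        assert comp.interaction_p < 0.01
        for species, (t, p) in comp.paired_t.items():
            assert p < 0.05
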