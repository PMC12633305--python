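import numpy as np
import pandas as pd
import pytest

import fatefrag as ff
from fatefrag.model import (
    ElasticNetSpec,
    FeatureMatrix,
    apply_training_filters,
    delta_score,
    repeated_cv,
    stage_correlation,
    train,
    train_too,
)


def toy_matrix(n_per_class=20, n_noise=2, sep=3.0, seed=0, labels=("healthy", "cancer")):
    """Two Gaussian classes separated along the first feature."""
    rng = np.random.default_rng(seed)
    X0 = rng.normal(0, 1, size=(n_per_class, 2 + n_noise))
    X1 = rng.normal(0, 1, size=(n_per_class, 2 + n_noise))
    X1[:, 0] += sep
    X = np.vstack([X0, X1])
    cols = [f"f{i}" for i in range(2 + n_noise)]
    idx = [f"s{i}" for i in range(2 * n_per_class)]
    return FeatureMatrix(
        features=pd.DataFrame(X, columns=cols, index=idx),
        labels=pd.Series([labels[0]] * n_per_class + [labels[1]] * n_per_class, index=idx),
    )


FAST = ElasticNetSpec(n_repeats=5, seed=1)


class TestTrain:
    def test_separable_toy_reaches_training_auc_one(self):
        m = toy_matrix(sep=6.0)
        scorer = train(m, FAST)
        scores = scorer.score(m.features)
        y = (m.labels == "cancer").to_numpy()
        from sklearn.metrics import roc_auc_score

        assert roc_auc_score(y, scores) == 1.0

    def test_single_class_errors(self):
        m = toy_matrix()
        m2 = FeatureMatrix(m.features, pd.Series("cancer", index=m.features.index))
        with pytest.raises(ValueError, match="2 classes"):
            train(m2, FAST)

    def test_constant_feature_dropped(self):
        m = toy_matrix(sep=6.0)
        feats = m.features.copy()
        feats["flat"] = 1.0
        scorer = train(FeatureMatrix(feats, m.labels), FAST)
        assert "flat" not in scorer.feature_names

    def test_pure_l1_zeroes_redundant_features(self):
        m = toy_matrix(n_noise=6, sep=6.0, seed=3)
        spec = ElasticNetSpec(alpha=1.0, lambda_grid=(0.05,), n_repeats=1, seed=1)
        scorer = train(m, spec)
        assert np.sum(scorer.coef == 0.0) >= 1

    def test_lambda_ties_break_toward_stronger_regularization(self):
        # with a grid of two identical lambdas the larger must be chosen
        m = toy_matrix(sep=6.0)
        spec = ElasticNetSpec(lambda_grid=(0.03, 0.03), n_repeats=1, seed=1)
        assert train(m, spec).chosen_lambda == 0.03


class TestScore:
    def test_all_zero_standardized_features_give_sigmoid_intercept(self):
        m = toy_matrix(sep=4.0)
        scorer = train(m, FAST)
        mean_row = pd.DataFrame(
            [dict(zip(scorer.feature_names, scorer.means))]
        )
        from scipy.special import expit

        assert scorer.score(mean_row)[0] == pytest.approx(expit(scorer.intercept[0]))

    def test_monotone_in_positive_coefficient_feature(self):
        m = toy_matrix(sep=4.0)
        scorer = train(m, FAST)
        j = int(np.argmax(scorer.coef))
        assert scorer.coef[j] > 0
        row = dict(zip(scorer.feature_names, scorer.means))
        low = scorer.score(row)[0]
        row[scorer.feature_names[j]] += 2 * scorer.scales[j]
        assert scorer.score(row)[0] > low

    def test_schema_mismatch_lists_missing(self):
        m = toy_matrix()
        scorer = train(m, FAST)
        bad = m.features.rename(columns={"f0": "renamed"})
        with pytest.raises(ValueError, match="f0"):
            scorer.score(bad)

    def test_serialization_round_trip_is_bit_exact(self, tmp_path):
        m = toy_matrix(sep=4.0)
        scorer = train(m, FAST)
        before = scorer.score(m.features)
        path = tmp_path / "model.json"
        scorer.to_json(path)
        reloaded = ff.TrainedScorer.from_json(path)
        after = reloaded.score(m.features)
        assert np.array_equal(before, after)


class TestRepeatedCv:
    def test_well_separated_synthetic_cohort_auc(self, detection_cohort):
        res = repeated_cv(detection_cohort, ElasticNetSpec(n_repeats=5, seed=7))
        assert res.auc >= 0.95

    def test_label_permutation_stays_at_chance(self, detection_cohort):
        rng = np.random.default_rng(0)
        permuted = FeatureMatrix(
            detection_cohort.features,
            pd.Series(
                rng.permutation(detection_cohort.labels.to_numpy()),
                index=detection_cohort.features.index,
            ),
        )
        res = repeated_cv(permuted, ElasticNetSpec(n_repeats=5, seed=7))
        assert 0.35 <= res.auc <= 0.65

    def test_deterministic_given_seed(self):
        m = toy_matrix(sep=2.0, seed=5)
        a = repeated_cv(m, ElasticNetSpec(n_repeats=3, seed=9))
        b = repeated_cv(m, ElasticNetSpec(n_repeats=3, seed=9))
        assert np.array_equal(a.scores.to_numpy(), b.scores.to_numpy())
        assert a.auc == b.auc

    def test_averaging_shrinks_score_variance(self):
        # variance of per-sample scores across independent runs shrinks
        # as repetitions grow
        m = toy_matrix(sep=1.0, seed=6)

        def run_scores(n_repeats, seed):
            return repeated_cv(m, ElasticNetSpec(n_repeats=n_repeats, seed=seed)).scores

        one = np.var([run_scores(1, s).to_numpy() for s in range(6)], axis=0).mean()
        many = np.var([run_scores(10, s * 100) .to_numpy() for s in range(6)], axis=0).mean()
        assert many < one

    def test_pure_noise_matrix_stays_at_chance_and_label_leak_is_caught(self):
        rng = np.random.default_rng(4)
        n = 60
        labels = pd.Series(
            ["cancer"] * (n // 2) + ["healthy"] * (n // 2),
            index=[f"s{i}" for i in range(n)],
        )
        noise = pd.DataFrame(
            rng.normal(size=(n, 5)),
            columns=[f"n{i}" for i in range(5)],
            index=labels.index,
        )
        res_noise = repeated_cv(FeatureMatrix(noise, labels), ElasticNetSpec(n_repeats=3, seed=2))
        assert 0.3 <= res_noise.auc <= 0.7
        leaky = noise.copy()
        leaky["leak"] = (labels == "cancer").astype(float) + rng.normal(0, 0.1, n)
        res_leak = repeated_cv(FeatureMatrix(leaky, labels), ElasticNetSpec(n_repeats=3, seed=2))
        assert res_leak.auc > 0.95

    def test_scores_monotone_in_tf(self):
        # mean detection score rises with tumor fraction across TF levels
        tf_levels = (0.01, 0.03, 0.1)
        design = ff.CohortDesign(
            n_healthy=15,
            n_tumor=15,
            tf_per_tumor=tuple(np.repeat(tf_levels, 5)),
            n_fragments=60_000,
            seed=13,
        )
        fm = ff.cohort_feature_matrix(design)
        res = repeated_cv(fm, ElasticNetSpec(n_repeats=5, seed=13))
        tumors = res.scores[fm.labels == "cancer"]
        means = [
            tumors[np.isclose(fm.tf[tumors.index], tf)].mean() for tf in tf_levels
        ]
        assert means[0] < means[1] < means[2]


class TestTrainingFilters:
    def test_strict_inequality_filter_by_hand(self):
        feats = pd.DataFrame(
            {"f": [1.0, 2.0, 3.0, 4.0, 5.0]},
            index=["t1", "t2", "t3", "h1", "h2"],
        )
        labels = pd.Series(
            ["cancer", "cancer", "cancer", "healthy", "healthy"], index=feats.index
        )
        tf = pd.Series([0.02, 0.03, 0.05, 0.005, 0.02], index=feats.index)
        out = apply_training_filters(FeatureMatrix(feats, labels, tf=tf))
        assert sorted(out.samples) == ["h1", "t3"]

    def test_boundary_tumor_dropped(self):
        feats = pd.DataFrame({"f": [1.0, 2.0, 3.0]}, index=["t1", "t2", "h1"])
        labels = pd.Series(["cancer", "cancer", "healthy"], index=feats.index)
        tf = pd.Series([0.03, 0.05, 0.0], index=feats.index)
        out = apply_training_filters(FeatureMatrix(feats, labels, tf=tf))
        assert "t1" not in out.samples

    def test_missing_tf_errors(self):
        m = toy_matrix()
        with pytest.raises(ValueError, match="tf"):
            apply_training_filters(m)

    def test_emptied_class_errors(self):
        feats = pd.DataFrame({"f": [1.0, 2.0]}, index=["t1", "h1"])
        labels = pd.Series(["cancer", "healthy"], index=feats.index)
        tf = pd.Series([0.01, 0.005], index=feats.index)
        with pytest.raises(ValueError, match="emptied a class"):
            apply_training_filters(FeatureMatrix(feats, labels, tf=tf))


class TestTissueOfOrigin:
    @staticmethod
    def block_matrix(n_per_class=12, sep=4.0, seed=0, duplicate_pair=False):
        """Each class enriched only in its own feature block."""
        rng = np.random.default_rng(seed)
        classes = ["CRC", "LUAD", "BRCA"]
        rows, labels = [], []
        for ci, c in enumerate(classes):
            X = rng.normal(0, 1, size=(n_per_class, 6))
            block = ci if not (duplicate_pair and c == "LUAD") else 0
            X[:, 2 * block] += sep
            rows.append(X)
            labels += [c] * n_per_class
        cols = [f"{c}|{f}" for c in classes for f in ("a", "b")]
        X = np.vstack(rows)
        idx = [f"s{i}" for i in range(len(labels))]
        return FeatureMatrix(
            features=pd.DataFrame(X, columns=cols, index=idx),
            labels=pd.Series(labels, index=idx),
        )

    def test_block_separable_classes_reach_high_auc(self):
        m = self.block_matrix()
        res = train_too(m, ElasticNetSpec(n_repeats=3, seed=5))
        assert all(auc >= 0.9 for auc in res.class_auc.values())

    def test_probabilities_sum_to_one_and_argmax_prediction(self):
        m = self.block_matrix()
        res = train_too(m, ElasticNetSpec(n_repeats=2, seed=5))
        proba = res.scorer.predict_proba(m.features)
        assert np.allclose(proba.sum(axis=1), 1.0)
        assert (res.predicted == res.class_scores.idxmax(axis=1)).all()

    def test_indistinguishable_classes_score_near_chance(self):
        # LUAD built identically to CRC: the two are mutually
        # indistinguishable while BRCA stays separable
        from sklearn.metrics import roc_auc_score

        m = self.block_matrix(duplicate_pair=True, seed=2)
        res = train_too(m, ElasticNetSpec(n_repeats=3, seed=5))
        pair = m.labels.isin(["CRC", "LUAD"])
        mutual_auc = roc_auc_score(
            (m.labels[pair] == "LUAD").to_numpy(),
            res.class_scores.loc[pair, "LUAD"].to_numpy(),
        )
        assert 0.3 <= mutual_auc <= 0.7
        assert res.class_auc["BRCA"] >= 0.9

    def test_missing_feature_block_errors(self):
        m = self.block_matrix()
        feats = m.features.copy()
        feats.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing feature values"):
            FeatureMatrix(feats, m.labels)


class TestSummaries:
    def test_delta_score_arithmetic_and_sign(self):
        assert delta_score([0.9, 0.8], [0.1, 0.2]) == pytest.approx(0.70)
        assert delta_score([0.5], [0.5]) == 0.0
        assert delta_score([0.2], [0.8]) < 0

    def test_stage_correlation_perfect_orderings(self):
        r, _ = stage_correlation([0.0, 0.25, 0.5, 0.75, 1.0], ["H", "I", "II", "III", "IV"])
        assert r == pytest.approx(1.0)
        r, _ = stage_correlation([1.0, 0.75, 0.5], ["H", "I", "II"])
        assert r == pytest.approx(-1.0)

    def test_stage_correlation_null_is_weak(self):
        rng = np.random.default_rng(8)
        scores = rng.random(40)
        stages = rng.integers(0, 5, size=40)
        r, p = stage_correlation(scores, stages)
        assert abs(r) < 0.4 and p > 0.01

    def test_degenerate_inputs_error(self):
        with pytest.raises(ValueError, match="degenerate"):
            stage_correlation([0.5, 0.5, 0.5], ["H", "I", "II"])
        with pytest.raises(ValueError, match="degenerate"):
            stage_correlation([0.1, 0.2, 0.3], ["II", "II", "II"])


class TestStandardization:
    def test_prestandardized_features_equivalent(self):
        m = toy_matrix(sep=3.0, seed=7)
        X = m.features.to_numpy()
        Xs = (X - X.mean(axis=0)) / X.std(axis=0)
        ms = FeatureMatrix(
            pd.DataFrame(Xs, columns=m.features.columns, index=m.features.index),
            m.labels,
        )
        spec = ElasticNetSpec(lambda_grid=(0.02,), n_repeats=1, seed=1)
        a = train(m, spec)
        b = train(ms, spec)
        assert np.allclose(a.score(m.features), b.score(ms.features), atol=1e-6)
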