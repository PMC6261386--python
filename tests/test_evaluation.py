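"""Generalizability battery: NMF like-clustering, cross-validated ridge and
logistic prediction, covariate handling and target ranking."""

import numpy as np
import pandas as pd
import pytest

from langtraits import evaluation as ev
from langtraits import factor_model as fm
from langtraits import synthetic_data as sd


class TestClusterLikes:
    def _block_likes(self, n_users=120, n_items=60, n_clusters=3, seed=0,
                     within=1.0, background=0.0):
        cfg = sd.SyntheticConfig(
            n_users=n_users, vocab_size=20, n_factors=3, markers_per_factor=5, seed=seed,
            likes_specs=sd.LikesSpec(n_items=n_items, n_clusters=n_clusters,
                                     within_p=within, background_p=background),
        )
        pop = sd.generate_population(cfg)
        return sd.generate_likes(pop, cfg), pop

    def test_exact_block_structure_recovered(self):
        likes, pop = self._block_likes()
        cl = ev.cluster_likes(likes, top_items=60, n_clusters=3, seed=1)
        purity = ev.cluster_purity(cl.item_assignment(), pop.likes_truth["item_cluster"])
        assert purity == 1.0

    def test_noisy_blocks_recovered(self):
        likes, pop = self._block_likes(n_users=2000, n_items=300, seed=2,
                                       within=0.5, background=0.01)
        cl = ev.cluster_likes(likes, top_items=300, n_clusters=3, seed=1)
        purity = ev.cluster_purity(cl.item_assignment(), pop.likes_truth["item_cluster"])
        assert purity >= 0.95

    def test_same_seed_is_deterministic(self):
        likes, _ = self._block_likes(seed=3, within=0.6, background=0.05)
        a = ev.cluster_likes(likes, top_items=60, n_clusters=3, seed=9)
        b = ev.cluster_likes(likes, top_items=60, n_clusters=3, seed=9)
        assert np.array_equal(a.user_labels, b.user_labels)
        assert np.allclose(a.item_membership, b.item_membership)

    def test_popularity_restriction(self):
        likes, _ = self._block_likes(seed=4, within=0.8, background=0.1)
        cl = ev.cluster_likes(likes, top_items=20, n_clusters=3, seed=0)
        assert len(cl.item_ids) == 20

    def test_user_labels_balanced_by_median_split(self):
        likes, _ = self._block_likes(seed=5, within=0.7, background=0.05)
        cl = ev.cluster_likes(likes, top_items=60, n_clusters=3, seed=0)
        frac = cl.user_labels.mean(axis=0)
        assert np.all(frac > 0.2) and np.all(frac < 0.8)

    def test_invalid_cluster_counts_rejected(self):
        likes, _ = self._block_likes()
        with pytest.raises(ValueError):
            ev.cluster_likes(likes, n_clusters=1)
        with pytest.raises(ValueError):
            ev.cluster_likes(likes, top_items=60, n_clusters=500)


class TestRegression:
    def test_realizable_target_near_perfect(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, (500, 4))
        y = x @ np.array([1.0, -0.5, 0.3, 0.0])
        rep = ev.evaluate_regression(x, y, seed=1)
        assert rep.mean > 0.99
        assert rep.n_splits == len(rep.per_split) == 10

    def test_null_target_near_zero(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, (2000, 5))
        y = rng.normal(0, 1, 2000)
        rep = ev.evaluate_regression(x, y, seed=3)
        assert abs(rep.mean) < 0.05

    def test_factor_scores_close_to_trait_oracle(self, small_study):
        # FA-score features should predict a trait-driven outcome nearly as
        # well as the planted traits themselves
        pop, utm, out = small_study["pop"], small_study["utm"], small_study["outcomes"]
        _, scores = fm.fit_pipeline(utm, fm.FactorModelConfig(k=3))
        y = out.table["iq"].to_numpy()
        oracle = ev.evaluate_regression(pop.traits[0], y, seed=4)
        fitted = ev.evaluate_regression(scores.scores, y, seed=4)
        assert fitted.mean > oracle.mean - 0.1

    def test_constant_outcome_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            ev.evaluate_regression(np.random.default_rng(5).normal(size=(50, 2)),
                                   np.ones(50))

    def test_seeded_determinism(self):
        rng = np.random.default_rng(6)
        x = rng.normal(0, 1, (300, 3))
        y = x[:, 0] + rng.normal(0, 1, 300)
        a = ev.evaluate_regression(x, y, seed=7)
        b = ev.evaluate_regression(x, y, seed=7)
        assert a.per_split == b.per_split


class TestClassification:
    def test_separable_target_high_auc(self):
        rng = np.random.default_rng(8)
        x = rng.normal(0, 1, (600, 4))
        labels = (x @ np.array([1.0, 1.0, 0.0, 0.0]) > 0).astype(int)
        rep = ev.evaluate_classification(x, labels, seed=9)
        assert rep.mean > 0.95

    def test_random_labels_at_chance(self):
        rng = np.random.default_rng(10)
        x = rng.normal(0, 1, (2000, 5))
        labels = rng.integers(0, 2, (2000, 4))
        rep = ev.evaluate_classification(x, labels, seed=11)
        assert rep.mean == pytest.approx(0.5, abs=0.03)

    def test_duplicated_features_change_little(self):
        rng = np.random.default_rng(12)
        x = rng.normal(0, 1, (500, 3))
        labels = (x[:, 0] + 0.5 * rng.normal(size=500) > 0).astype(int)
        a = ev.evaluate_classification(x, labels, seed=13)
        b = ev.evaluate_classification(np.hstack([x, x]), labels, seed=13)
        assert abs(a.mean - b.mean) < 0.03

    def test_single_class_target_skipped(self, caplog):
        rng = np.random.default_rng(14)
        x = rng.normal(0, 1, (200, 3))
        labels = np.column_stack([np.zeros(200, dtype=int),
                                  rng.integers(0, 2, 200)])
        rep = ev.evaluate_classification(x, labels, seed=15, target_names=["dead", "ok"])
        assert set(rep.per_target) == {"ok"}

    def test_all_single_class_rejected(self):
        with pytest.raises(ValueError):
            ev.evaluate_classification(np.zeros((50, 2)), np.zeros(50, dtype=int))


class TestCovariates:
    def _demo(self, n, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {"age": rng.uniform(15, 60, n), "gender": rng.integers(0, 2, n)},
            index=pd.Index([f"u{i:03d}" for i in range(n)], name="user_id"),
        )

    def test_concatenation_shape_and_scaling(self):
        n = 100
        feats = pd.DataFrame(np.random.default_rng(1).normal(size=(n, 5)),
                             index=self._demo(n).index)
        out = ev.add_covariates(feats, self._demo(n))
        assert out.shape == (n, 7)
        assert abs(out["age_z"].mean()) < 1e-10
        assert out["gender"].isin([0, 1]).all()

    def test_demographics_only_baseline(self):
        demo = self._demo(50)
        empty = pd.DataFrame(index=demo.index)
        out = ev.add_covariates(empty, demo)
        assert list(out.columns) == ["age_z", "gender"]

    def test_permuted_user_order_aligned(self):
        n = 60
        demo = self._demo(n, seed=2)
        feats = pd.DataFrame(np.random.default_rng(3).normal(size=(n, 2)), index=demo.index)
        shuffled = demo.sample(frac=1, random_state=4)
        a = ev.add_covariates(feats, demo)
        b = ev.add_covariates(feats, shuffled)
        pd.testing.assert_frame_equal(a, b)

    def test_missing_demographics_dropped(self, caplog):
        demo = self._demo(30)
        demo.loc[demo.index[:5], "age"] = np.nan
        feats = pd.DataFrame(np.random.default_rng(5).normal(size=(30, 2)), index=demo.index)
        out = ev.add_covariates(feats, demo)
        assert len(out) == 25


class TestResidualize:
    def _scores_and_demo(self, n=500, seed=0):
        rng = np.random.default_rng(seed)
        users = [f"u{i:04d}" for i in range(n)]
        demo = pd.DataFrame(
            {"age": rng.uniform(15, 60, n), "gender": rng.integers(0, 2, n)},
            index=pd.Index(users, name="user_id"),
        )
        return users, demo, rng

    def test_orthogonal_scores_unchanged(self):
        users, demo, rng = self._scores_and_demo()
        raw = rng.normal(0, 1, (500, 2))
        age_z = (demo["age"] - demo["age"].mean()) / demo["age"].std()
        design = np.column_stack([np.ones(500), age_z, demo["gender"]])
        resid0 = raw - design @ np.linalg.lstsq(design, raw, rcond=None)[0]
        scores = fm.FactorScores(users, resid0)
        out = ev.residualize(scores, demo)
        assert np.allclose(out.scores, resid0, atol=1e-8)

    def test_pure_age_score_vanishes(self):
        users, demo, _ = self._scores_and_demo(seed=1)
        age_z = ((demo["age"] - demo["age"].mean()) / demo["age"].std()).to_numpy()
        scores = fm.FactorScores(users, (2 * age_z)[:, None])
        out = ev.residualize(scores, demo)
        assert np.abs(out.scores).max() < 1e-8

    def test_residuals_uncorrelated_with_covariates(self):
        users, demo, rng = self._scores_and_demo(seed=2)
        age_z = ((demo["age"] - demo["age"].mean()) / demo["age"].std()).to_numpy()
        signal = rng.normal(0, 1, 500)
        scores = fm.FactorScores(users, (signal + 0.3 * age_z)[:, None])
        out = ev.residualize(scores, demo)
        assert abs(np.corrcoef(out.scores[:, 0], age_z)[0, 1]) < 1e-8
        assert abs(np.corrcoef(out.scores[:, 0], demo["gender"])[0, 1]) < 1e-8
        # removing the planted age component improves recovery of the
        # age-independent signal
        before = abs(np.corrcoef(scores.scores[:, 0], signal)[0, 1])
        after = abs(np.corrcoef(out.scores[:, 0], signal)[0, 1])
        assert after > before

    def test_constant_covariate_dropped(self, caplog):
        users, demo, rng = self._scores_and_demo(seed=3)
        demo["gender"] = 1
        scores = fm.FactorScores(users, rng.normal(0, 1, (500, 1)))
        out = ev.residualize(scores, demo)
        assert out.scores.shape == (500, 1)


class TestRankTargets:
    def _report(self, name, values, metric="pearson_r"):
        return ev.PredictionReport(name, "FA", metric, list(values), len(values))

    def test_descending_order(self):
        reports = [self._report("a", [0.23]), self._report("b", [0.09]),
                   self._report("c", [0.22])]
        out = ev.rank_targets(reports)
        assert list(out.outcome) == ["a", "c", "b"]

    def test_single_item_is_top_and_bottom(self):
        out = ev.rank_targets([self._report("only", [0.5])])
        assert out.iloc[0]["slice"] == "top"

    def test_tie_break_by_name(self):
        out = ev.rank_targets([self._report("b", [0.2]), self._report("a", [0.2])])
        assert list(out.outcome) == ["a", "b"]

    def test_mixed_metrics_rejected(self):
        with pytest.raises(ValueError, match="mixed"):
            ev.rank_targets([self._report("a", [0.2]),
                             self._report("b", [0.6], metric="auc")])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ev.rank_targets([])


class TestLikesIO:
    def test_roundtrip(self, tmp_path, small_study):
        likes = small_study["likes"]
        ev.write_likes(likes, tmp_path / "likes.csv")
        back = ev.read_likes(tmp_path / "likes.csv")
        # users/items with no likes are absent from the triplet file
        orig_users = [u for i, u in enumerate(likes.user_ids)
                      if likes.matrix[i].nnz > 0]
        assert back.user_ids == sorted(orig_users)
        assert back.matrix.nnz == likes.matrix.nnz
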