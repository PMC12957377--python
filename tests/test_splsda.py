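"""Multiblock sparse PLS-DA: optimizer invariants, classical limits,
classification, grouped splitting, tuning and the composite disease score."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from longomics import splsda as spl
from tests.conftest import toy_matrix


def binary_outcome(n_per_class=5, classes=("WT", "MUT")):
    labels = np.array([classes[0]] * n_per_class + [classes[1]] * n_per_class)
    return spl.OutcomeBlock.from_labels(labels)


def random_instance(rng, n=12, widths=(4, 3)):
    out = binary_outcome(n // 2)
    blocks = {
        f"b{i}": toy_matrix(rng.normal(size=(n, w)), columns=[f"b{i}v{j}" for j in range(w)])
        for i, w in enumerate(widths)
    }
    return blocks, out


class TestFit:
    def test_single_block_full_cardinality_is_svd_limit(self, rng):
        """With one block and no sparsity the first loading is the dominant
        left singular vector of X_c^T Y_c."""
        X = toy_matrix(rng.normal(size=(20, 6)))
        out = binary_outcome(10)
        model = spl.fit({"b": X}, out, spl.SplsdaConfig(n_components=1))
        Xc = X.to_numpy() - X.to_numpy().mean(axis=0)
        u = np.linalg.svd(Xc.T @ out.centered(), full_matrices=False)[0][:, 0]
        a = model.loadings["b"][0].to_numpy()
        assert min(np.abs(a - u).max(), np.abs(a + u).max()) < 1e-6

    def test_indicator_column_selected_at_keepx_one(self, rng):
        out = binary_outcome(6)
        ind = out.centered()[:, -1]
        X = np.column_stack([rng.normal(size=(12, 3)), ind])
        model = spl.fit(
            {"b": toy_matrix(X, columns=["n1", "n2", "n3", "ind"])},
            out, spl.SplsdaConfig(n_components=1, keepx={"b": (1,)}),
        )
        assert model.selected_analytes(0)["b"] == ["ind"]

    def test_objective_monotone_over_iterations(self, rng):
        for _ in range(5):
            blocks, out = random_instance(rng)
            cfg = spl.SplsdaConfig(n_components=2, keepx={"b0": (2, 1), "b1": (2, 1)})
            model = spl.fit(blocks, out, cfg)
            for traj in model.objective_history:
                assert (np.diff(traj) >= -1e-10).all()

    def test_norm_sparsity_and_orthogonality_invariants(self, rng):
        blocks, out = random_instance(rng, n=14, widths=(6, 5))
        cfg = spl.SplsdaConfig(n_components=3, keepx={"b0": (3, 2, 1), "b1": (2, 2, 1)})
        model = spl.fit(blocks, out, cfg)
        for b in blocks:
            for h, a in enumerate(model.loadings[b]):
                assert np.linalg.norm(a) == pytest.approx(1.0, abs=1e-8)
                assert (a != 0).sum() <= cfg.keepx[b][h]
            T = model.scores[b]
            for h in range(3):
                for g in range(h + 1, 3):
                    cos = T[:, h] @ T[:, g] / (
                        np.linalg.norm(T[:, h]) * np.linalg.norm(T[:, g])
                    )
                    assert abs(cos) < 1e-6

    def test_sign_anchor_makes_first_block_loading_positive(self, rng):
        blocks, out = random_instance(rng)
        model = spl.fit(blocks, out, spl.SplsdaConfig(n_components=2))
        for h in range(2):
            a = model.loadings["b0"][h].to_numpy()
            assert a[np.argmax(np.abs(a))] > 0

    def test_missing_values_rejected(self, rng):
        blocks, out = random_instance(rng)
        blocks["b0"].iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            spl.fit(blocks, out)

    def test_keepx_wider_than_block_rejected(self, rng):
        blocks, out = random_instance(rng)
        with pytest.raises(ValueError):
            spl.fit(blocks, out, spl.SplsdaConfig(keepx={"b0": (99, 1)}))

    def test_exclude_analytes_refit(self, rng):
        """Dropping the top selected analyte forces a different selection."""
        out = binary_outcome(8)
        sig = out.centered()[:, -1]
        X = np.column_stack([sig * 2 + rng.normal(0, 0.1, 16),
                             sig + rng.normal(0, 0.1, 16),
                             rng.normal(size=16)])
        blocks = {"b": toy_matrix(X, columns=["best", "second", "noise"])}
        cfg = spl.SplsdaConfig(n_components=1, keepx={"b": (1,)})
        first = spl.fit(blocks, out, cfg)
        assert first.selected_analytes(0)["b"] == ["best"]
        import dataclasses
        refit = spl.fit(blocks, out, dataclasses.replace(cfg, exclude_analytes=("best",)))
        assert refit.selected_analytes(0)["b"] == ["second"]


class TestTransform:
    def test_training_scores_reproduced(self, rng):
        blocks, out = random_instance(rng)
        model = spl.fit(blocks, out, spl.SplsdaConfig(n_components=2))
        ts = spl.transform(model, blocks)
        for b in blocks:
            np.testing.assert_allclose(ts[b], model.scores[b], atol=1e-10)

    def test_mean_sample_and_duplicates(self, rng):
        blocks, out = random_instance(rng)
        model = spl.fit(blocks, out, spl.SplsdaConfig(n_components=2))
        # a sample at the training mean projects to the origin
        mean_blocks = {b: toy_matrix([model.block_means[b].to_numpy()],
                                     columns=list(blocks[b].columns)) for b in blocks}
        ts = spl.transform(model, mean_blocks)
        for b in blocks:
            np.testing.assert_allclose(ts[b], 0.0, atol=1e-10)
        dup = {b: pd.concat([blocks[b].iloc[[0]], blocks[b].iloc[[0]]]) for b in blocks}
        td = spl.transform(model, dup)
        for b in blocks:
            np.testing.assert_allclose(td[b][0], td[b][1])

    def test_analyte_mismatch_reported(self, rng):
        blocks, out = random_instance(rng)
        model = spl.fit(blocks, out)
        broken = {b: X.iloc[:, 1:] for b, X in blocks.items()}
        with pytest.raises(ValueError, match="b0v0"):
            spl.transform(model, broken)


class TestClassify:
    def test_sample_at_centroid_gets_its_class(self, rng):
        blocks, out = random_instance(rng, n=16)
        model = spl.fit(blocks, out, spl.SplsdaConfig(n_components=2))
        scores = {b: model.centroids[b].loc[["MUT"]].to_numpy() for b in blocks}
        assert spl.classify(model, scores)[0] == "MUT"

    def test_average_equals_majority_when_blocks_agree(self, rng):
        blocks, out = random_instance(rng, n=16)
        model = spl.fit(blocks, out, spl.SplsdaConfig(n_components=1))
        ts = spl.transform(model, blocks)
        maj = spl.classify(model, ts, vote="majority")
        avg = spl.classify(model, ts, vote="average")
        per_block = [
            spl.classify(model, ts, vote="majority")  # noqa: F841  (agreement below)
        ]
        dists = spl._block_distances(model, ts, "centroid")
        votes = np.stack([d.argmin(axis=1) for d in dists.values()])
        agree = votes.min(axis=0) == votes.max(axis=0)
        assert (maj[agree] == avg[agree]).all()

    def test_unknown_options_rejected(self, rng):
        blocks, out = random_instance(rng)
        model = spl.fit(blocks, out)
        ts = spl.transform(model, blocks)
        with pytest.raises(ValueError):
            spl.classify(model, ts, vote="plurality")
        with pytest.raises(ValueError):
            spl.classify(model, ts, distance="mahalanobis")


class TestBer:
    def test_arithmetic(self):
        assert spl.balanced_error_rate(list("AABB"), list("AABB")) == 0.0
        assert spl.balanced_error_rate(list("AABB"), list("AAAA")) == 0.5
        true = ["A"] * 4 + ["B"] * 8
        pred = ["B"] + ["A"] * 3 + ["A", "A"] + ["B"] * 6
        assert spl.balanced_error_rate(true, pred) == pytest.approx(0.25)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            spl.balanced_error_rate(["A"], ["A", "B"])


class TestGroupedSplit:
    def _meta(self, n_subjects=10, per_subject=2):
        rows = []
        for i in range(n_subjects):
            g = "WT" if i % 2 == 0 else "MUT"
            for t in range(per_subject):
                rows.append((f"p{i}_t{t}", f"p{i}", g))
        return pd.DataFrame(rows, columns=["sample_id", "subject_id", "genotype"]).set_index("sample_id")

    def test_subjects_disjoint_and_sized(self):
        meta = self._meta(10)
        train, test = spl.split_subjects(meta, 0.7, seed=0)
        assert len(train) == 7 and len(test) == 3
        assert set(train).isdisjoint(test)

    def test_deterministic_under_seed(self):
        meta = self._meta(12)
        assert spl.split_subjects(meta, 0.7, 5) == spl.split_subjects(meta, 0.7, 5)
        assert spl.split_subjects(meta, 0.7, 5) != spl.split_subjects(meta, 0.7, 6)

    def test_both_classes_on_both_sides(self):
        meta = self._meta(8)
        train, test = spl.split_subjects(meta, 0.5, seed=1)
        geno = meta.drop_duplicates("subject_id").set_index("subject_id")["genotype"]
        assert set(geno[train]) == {"WT", "MUT"} == set(geno[test])

    def test_too_few_subjects(self):
        meta = self._meta(2)  # one subject per genotype
        with pytest.raises(ValueError):
            spl.split_subjects(meta, 0.7, seed=0)


class TestRocAuc:
    def test_examples(self):
        auc, _ = spl.roc_auc([1, 2, 3, 4], [0, 0, 1, 1])
        assert auc == 1.0
        auc, _ = spl.roc_auc([1.0, 1.0, 1.0, 1.0], [0, 0, 1, 1])
        assert auc == 0.5
        auc, _ = spl.roc_auc([1, 3, 2, 4], [0, 0, 1, 1])
        assert auc == 0.75

    def test_curve_integral_equals_rank_auc(self, rng):
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, size=40)
        auc, curve = spl.roc_auc(scores, labels, positive=1)
        trap = np.trapezoid(curve["tpr"], curve["fpr"])
        assert trap == pytest.approx(auc, abs=1e-10)
        # independent cross-check against scikit-learn
        assert auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            spl.roc_auc([1, 2], [1, 1])


class TestSplsScore:
    def test_sum_and_linearity(self, rng):
        blocks, out = random_instance(rng)
        model = spl.fit(blocks, out, spl.SplsdaConfig(n_components=1))
        ts = spl.transform(model, blocks)
        np.testing.assert_allclose(
            spl.spls_score(model, ts), ts["b0"][:, 0] + ts["b1"][:, 0]
        )
        neg = {b: -t for b, t in ts.items()}
        np.testing.assert_allclose(spl.spls_score(model, neg), -spl.spls_score(model, ts))

    def test_missing_block_rejected(self, rng):
        blocks, out = random_instance(rng)
        model = spl.fit(blocks, out)
        with pytest.raises(ValueError):
            spl.spls_score(model, {"b0": np.zeros((2, 2))})


class TestTuneKeepx:
    def _grouped_instance(self, seed, n_groups=10, effect=3.0):
        rng = np.random.default_rng(seed)
        groups = np.repeat([f"g{i}" for i in range(n_groups)], 2)
        labels = np.repeat(["WT", "MUT"] * (n_groups // 2), 2)
        sig = (labels == "MUT").astype(float) - 0.5
        blocks = {}
        for b, w in [("b0", 5), ("b1", 4)]:
            X = rng.normal(size=(len(groups), w))
            X[:, 0] += effect * sig
            blocks[b] = toy_matrix(X, columns=[f"{b}v{j}" for j in range(w)],
                                   index=[f"s{i}" for i in range(len(groups))])
        return blocks, spl.OutcomeBlock.from_labels(labels), groups

    def test_deterministic_and_folds_respect_groups(self):
        blocks, out, groups = self._grouped_instance(0)
        grid = [{"b0": (k,), "b1": (k,)} for k in (1, 2)]
        cv1 = spl.tune_keepx(blocks, out, grid, groups, folds=3, repeats=2, seed=4)
        cv2 = spl.tune_keepx(blocks, out, grid, groups, folds=3, repeats=2, seed=4)
        np.testing.assert_array_equal(cv1.mean_ber, cv2.mean_ber)
        assert cv1.chosen == cv2.chosen
        for assign in cv1.fold_assignments:
            # every group is assigned exactly one fold
            assert set(assign) == set(np.unique(groups))

    def test_informative_analyte_recovered_with_low_ber(self):
        blocks, out, groups = self._grouped_instance(1)
        grid = [{"b0": (k,), "b1": (k,)} for k in (1, 2, 3)]
        cv = spl.tune_keepx(blocks, out, grid, groups, folds=5, repeats=2, seed=0)
        assert cv.chosen_ber[0] <= 0.1
        model = spl.fit(blocks, out, spl.SplsdaConfig(1, cv.chosen_keepx))
        sel = model.selected_analytes(0)
        assert "b0v0" in sel["b0"] and "b1v0" in sel["b1"]

    def test_pure_noise_ber_near_half(self):
        blocks, out, groups = self._grouped_instance(2, effect=0.0)
        grid = [{"b0": (2,), "b1": (2,)}]
        cv = spl.tune_keepx(blocks, out, grid, groups, folds=5, repeats=4, seed=0)
        assert 0.35 <= cv.mean_ber[0] <= 0.65

    def test_empty_grid_and_too_many_folds(self):
        blocks, out, groups = self._grouped_instance(3)
        with pytest.raises(ValueError):
            spl.tune_keepx(blocks, out, [], groups)
        with pytest.raises(ValueError):
            spl.tune_keepx(blocks, out, [{"b0": (1,), "b1": (1,)}], groups, folds=99)
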