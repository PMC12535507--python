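"""Staged growth, freeze/fine-tune contracts, and the seven mechanisms."""

import numpy as np
import pytest

from nscl.cascade import (
    BlockSpec,
    CascadeModel,
    DataBatch,
    StageSpec,
    TrainConfig,
    build_stage_targets,
    grow_model,
    predict_leaf,
    predict_levels,
    stage_embedding_matrix,
    train_cascade,
    train_stage,
)
from nscl.hierarchy import LabelHierarchy
from nscl.synthetic_data import (
    PRESETS,
    simulate_classification_dataset,
    simulate_label_embeddings,
)


def _fresh_model(input_dim=6, u=4, widths=(8,), heads=(3,), seed=0):
    model = CascadeModel((input_dim,), u)
    rng = np.random.default_rng(seed)
    for i, (w, k) in enumerate(zip(widths, heads), start=1):
        grow_model(
            model,
            StageSpec(level=i, n_classes=k, block=BlockSpec(width=w),
                      epochs=0),
            rng,
        )
    return model


class TestBuildStageTargets:
    def test_single_level_equals_leaf_targets(self):
        h = LabelHierarchy(("a", "b", "c"), np.arange(3)[:, None])
        y = np.array([2, 0, 1, 1])
        np.testing.assert_array_equal(
            build_stage_targets(h, y).ravel(), y
        )

    def test_two_level_hand_mapping(self, four_leaf_hierarchy):
        out = build_stage_targets(four_leaf_hierarchy, [3])
        np.testing.assert_array_equal(out, [[1, 3]])

    def test_agrees_with_ancestor_calls(self, three_level_hierarchy):
        rng = np.random.default_rng(4)
        y = rng.integers(0, 8, size=30)
        out = build_stage_targets(three_level_hierarchy, y)
        for i, leaf_idx in enumerate(y):
            leaf = three_level_hierarchy.leaf_labels[leaf_idx]
            for level in range(1, 4):
                assert out[i, level - 1] == (
                    three_level_hierarchy.ancestor_at_level(leaf, level)
                )

    def test_unknown_leaf_rejected(self, four_leaf_hierarchy):
        with pytest.raises(ValueError, match="not present"):
            build_stage_targets(four_leaf_hierarchy, [4])


class TestGrowModel:
    def test_first_stage_base_case(self):
        model = _fresh_model(widths=(8,), heads=(2,))
        assert model.n_stages == 1
        assert model.head_widths == [2]

    def test_three_grows_retain_all_blocks(self):
        model = _fresh_model(widths=(8, 8, 8), heads=(2, 3, 5))
        assert len(model.feature_blocks) == 3
        assert len(model.output_blocks) == 3
        assert model.head_widths == [2, 3, 5]

    def test_grow_leaves_prior_checksums_unchanged(self):
        model = _fresh_model(widths=(8,), heads=(2,))
        before = model.block_checksums()
        grow_model(
            model,
            StageSpec(level=2, n_classes=4, block=BlockSpec(width=8),
                      epochs=0),
            np.random.default_rng(1),
        )
        after = model.block_checksums()
        assert all(after[name] == digest for name, digest in before.items())

    def test_wrong_stage_level_rejected(self):
        model = _fresh_model()
        with pytest.raises(ValueError, match="extend"):
            grow_model(
                model,
                StageSpec(level=3, n_classes=4, block=BlockSpec(width=8),
                          epochs=0),
                np.random.default_rng(0),
            )


@pytest.fixture
def stage_world(tiny_world):
    data = tiny_world["data"]
    hierarchy = tiny_world["hierarchy"]
    return data, hierarchy, build_stage_targets(hierarchy, data.targets)


class TestTrainStage:
    def test_zero_epochs_is_noop(self, stage_world):
        data, hierarchy, targets = stage_world
        model = _fresh_model(input_dim=data.inputs.shape[1], heads=(2,))
        before = model.block_checksums()
        spec = StageSpec(level=1, n_classes=2, block=BlockSpec(width=8),
                         epochs=0)
        history = train_stage(model, spec, data, targets[:, 0],
                              TrainConfig(), np.random.default_rng(0))
        assert history == []
        assert model.block_checksums() == before

    def test_frozen_scope_keeps_earlier_blocks_bit_identical(self, stage_world):
        data, hierarchy, targets = stage_world
        model = _fresh_model(input_dim=data.inputs.shape[1],
                             widths=(8, 8), heads=(2, 4))
        before = model.block_checksums()
        spec = StageSpec(level=2, n_classes=4, block=BlockSpec(width=8),
                         epochs=2, trainable_scope="new-only")
        train_stage(model, spec, data, targets[:, 1], TrainConfig(),
                    np.random.default_rng(0))
        after = model.block_checksums()
        assert after["feature/1"] == before["feature/1"]
        assert after["output/1"] == before["output/1"]
        assert after["feature/2"] != before["feature/2"]

    def test_nested_scope_updates_an_earlier_block(self, stage_world):
        data, hierarchy, targets = stage_world
        model = _fresh_model(input_dim=data.inputs.shape[1],
                             widths=(8, 8), heads=(2, 4))
        before = model.block_checksums()
        spec = StageSpec(level=2, n_classes=4, block=BlockSpec(width=8),
                         epochs=1, trainable_scope="all")
        train_stage(model, spec, data, targets[:, 1], TrainConfig(),
                    np.random.default_rng(0))
        assert model.block_checksums()["feature/1"] != before["feature/1"]

    def test_loss_history_finite_with_length_epochs(self, stage_world):
        data, hierarchy, targets = stage_world
        model = _fresh_model(input_dim=data.inputs.shape[1], heads=(2,))
        spec = StageSpec(level=1, n_classes=2, block=BlockSpec(width=8),
                         epochs=3)
        history = train_stage(model, spec, data, targets[:, 0],
                              TrainConfig(), np.random.default_rng(0))
        assert len(history) == 3
        assert np.all(np.isfinite(history))


class TestTrainCascade:
    def test_nscl_head_width_schedule_matches_hierarchy(self):
        # three-level cut at 2, 3, 10 classes: one stage per level
        rng = np.random.default_rng(0)
        from nscl.hierarchy import (LabelEmbeddingTable, build_dendrogram,
                                    cut_dendrogram)

        table = LabelEmbeddingTable(
            tuple(f"c{i}" for i in range(10)), rng.normal(size=(10, 5))
        )
        hierarchy = cut_dendrogram(build_dendrogram(table), [2, 3, 10])
        inputs = rng.normal(size=(60, 5))
        targets = rng.integers(0, 10, size=60)
        model, report = train_cascade(
            DataBatch(inputs, targets), hierarchy,
            TrainConfig(mechanism="NSCL", epochs_per_stage=1),
        )
        assert report["head_widths"] == [2, 3, 10]
        assert model.n_stages == 3

    def test_e2e_single_stage(self, tiny_world):
        model, report = train_cascade(
            tiny_world["data"], tiny_world["hierarchy"],
            TrainConfig(mechanism="E2E", epochs_per_stage=1, n_blocks=2),
        )
        assert model.n_stages == 1
        assert len(model.feature_blocks) == 2
        assert report["head_widths"] == [4]

    def test_semantic_mechanism_requires_hierarchy(self, tiny_world):
        with pytest.raises(ValueError, match="hierarchy"):
            train_cascade(tiny_world["data"], None,
                          TrainConfig(mechanism="NSCL"))

    def test_he2e_requires_alpha_and_embeddings(self, tiny_world):
        with pytest.raises(ValueError, match="HE2E"):
            train_cascade(tiny_world["data"], tiny_world["hierarchy"],
                          TrainConfig(mechanism="HE2E", alpha=0.0))

    def test_stage1_separable_supergroups_high_accuracy(self, tiny_world):
        # the 2 supergroups are far apart: the 2-way stage is essentially
        # logistic-separable and the stage-1 head should nail it
        data, hierarchy = tiny_world["data"], tiny_world["hierarchy"]
        model, _ = train_cascade(
            data, hierarchy,
            TrainConfig(mechanism="SCL", epochs_per_stage=20, seed=0),
        )
        _, probs, _ = model.forward(data.inputs, stage=1)
        stage1_pred = probs.argmax(axis=1)
        truth = hierarchy.assignments[data.targets, 0]
        assert np.mean(stage1_pred == truth) >= 0.99

    def test_reproducible_histories_for_fixed_seed(self, tiny_world):
        cfg = TrainConfig(mechanism="NSCL", epochs_per_stage=2, seed=5)
        _, rep1 = train_cascade(tiny_world["data"], tiny_world["hierarchy"],
                                cfg)
        _, rep2 = train_cascade(tiny_world["data"], tiny_world["hierarchy"],
                                cfg)
        assert rep1["histories"] == rep2["histories"]

    def test_rhcl_trains_on_random_grouping(self, tiny_world):
        _, report = train_cascade(
            tiny_world["data"], tiny_world["hierarchy"],
            TrainConfig(mechanism="RHCL", epochs_per_stage=1, seed=3),
        )
        assert "train_hierarchy" in report
        sizes = [len(v) for v in report["train_hierarchy"]["levels"][0].values()]
        assert sorted(sizes) == [2, 2]

    def test_scl_alpha_zero_equals_hierarchy_targeted_cl(self):
        # degenerate hierarchy whose every level is the leaf partition:
        # SCL's stage targets collapse to leaf targets, i.e. plain CL
        rng = np.random.default_rng(2)
        leaves = ("u", "v", "w")
        hierarchy = LabelHierarchy(
            leaves, np.column_stack([np.arange(3), np.arange(3)])
        )
        data = DataBatch(rng.normal(size=(30, 4)),
                         rng.integers(0, 3, size=30))
        _, scl = train_cascade(
            data, hierarchy,
            TrainConfig(mechanism="SCL", epochs_per_stage=2, seed=1),
        )
        _, cl = train_cascade(
            data, hierarchy,
            TrainConfig(mechanism="CL", epochs_per_stage=2, seed=1,
                        n_blocks=2),
        )
        assert scl["histories"] == cl["histories"]

    def test_nscl_single_level_matches_he2e_stage_structure(self, tiny_world):
        table = tiny_world["table"]
        flat = LabelHierarchy(
            tiny_world["hierarchy"].leaf_labels,
            np.arange(4)[:, None],
        )
        model, report = train_cascade(
            tiny_world["data"], flat,
            TrainConfig(mechanism="NSCL", epochs_per_stage=1, alpha=0.2),
            embeddings=table,
        )
        assert model.n_stages == 1
        assert report["head_widths"] == [4]


class TestStageEmbeddings:
    def test_leaf_level_returns_own_vectors(self, tiny_world):
        table, hierarchy = tiny_world["table"], tiny_world["hierarchy"]
        mat = stage_embedding_matrix(hierarchy, table, hierarchy.n_levels)
        for i, leaf in enumerate(hierarchy.leaf_labels):
            cid = hierarchy.ancestor_at_level(leaf, hierarchy.n_levels)
            np.testing.assert_allclose(mat[cid], table.vector(leaf))

    def test_coarse_level_is_member_centroid(self, tiny_world):
        table, hierarchy = tiny_world["table"], tiny_world["hierarchy"]
        mat = stage_embedding_matrix(hierarchy, table, 1)
        for cid, members in hierarchy.clusters_at_level(1).items():
            want = np.mean([table.vector(m) for m in members], axis=0)
            np.testing.assert_allclose(mat[cid], want)


class TestPrediction:
    def test_forced_argmax(self):
        model = _fresh_model(input_dim=3, heads=(4,))
        ob = model.output_blocks[0]
        ob.Wp[:] = 0.0
        ob.bp[:] = 1.0
        ob.Wh[:] = 0.0
        ob.bh[:] = [0.0, 0.0, 9.0, 0.0]
        pred, scores = predict_leaf(model, np.zeros((2, 3)))
        np.testing.assert_array_equal(pred, [2, 2])
        np.testing.assert_allclose(scores.sum(axis=1), 1.0)

    def test_tie_breaks_to_lowest_index(self):
        model = _fresh_model(input_dim=3, heads=(6,))
        ob = model.output_blocks[0]
        ob.Wp[:] = 0.0
        ob.bp[:] = 1.0
        ob.Wh[:] = 0.0
        ob.bh[:] = [0.0, 0.0, 5.0, 0.0, 0.0, 5.0]
        pred, _ = predict_leaf(model, np.zeros((1, 3)))
        assert pred[0] == 2

    def test_project_leaf_rows_follow_ancestry(self, tiny_world):
        data, hierarchy = tiny_world["data"], tiny_world["hierarchy"]
        model, _ = train_cascade(
            data, hierarchy,
            TrainConfig(mechanism="NSCL", epochs_per_stage=1, seed=0),
        )
        pred_leaf, _ = predict_leaf(model, data.inputs[:10])
        levels = predict_levels(model, hierarchy, data.inputs[:10])
        for row, leaf_idx in zip(levels, pred_leaf):
            leaf = hierarchy.leaf_labels[leaf_idx]
            for level in range(1, hierarchy.n_levels + 1):
                assert row[level - 1] == hierarchy.ancestor_at_level(
                    leaf, level
                )

    def test_project_leaf_is_hierarchy_consistent(self, three_level_hierarchy):
        # each level-(l+1) prediction is a child of the level-l prediction
        rng = np.random.default_rng(7)
        data = DataBatch(rng.normal(size=(40, 5)),
                         rng.integers(0, 8, size=40))
        model, _ = train_cascade(
            data, three_level_hierarchy,
            TrainConfig(mechanism="NSCL", epochs_per_stage=1),
        )
        levels = predict_levels(model, three_level_hierarchy, data.inputs)
        a = three_level_hierarchy.assignments
        valid_rows = {tuple(row) for row in a}
        assert all(tuple(row) in valid_rows for row in levels)

    def test_stage_heads_on_single_stage_model_rejected(self, tiny_world):
        model, _ = train_cascade(
            tiny_world["data"], tiny_world["hierarchy"],
            TrainConfig(mechanism="E2E", epochs_per_stage=1, n_blocks=2),
        )
        with pytest.raises(ValueError, match="project-leaf"):
            predict_levels(model, tiny_world["hierarchy"],
                           tiny_world["data"].inputs, mode="stage-heads")


class TestPersistence:
    def test_save_load_round_trip(self, tiny_world, tmp_path):
        data, hierarchy = tiny_world["data"], tiny_world["hierarchy"]
        model, _ = train_cascade(
            data, hierarchy,
            TrainConfig(mechanism="SCL", epochs_per_stage=1, seed=2),
        )
        model.save(tmp_path / "model")
        back = CascadeModel.load(tmp_path / "model")
        assert back.block_checksums() == model.block_checksums()
        p1, _ = predict_leaf(model, data.inputs[:5])
        p2, _ = predict_leaf(back, data.inputs[:5])
        np.testing.assert_array_equal(p1, p2)
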