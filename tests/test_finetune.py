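import numpy as np
import pytest

from mvmol.chem_io import DatasetTable, parse_and_canonicalize
from mvmol.finetune import (
    ModelConfig,
    SCALED_METRIC_REGISTRY,
    ScaledMetricParams,
    TrainConfig,
    cluster_key,
    featurize_table,
    finetune_task,
    inverse_scale_metric,
    model_agreement,
    rank_screen,
    scale_metric,
    split_dataset,
)
from mvmol.synthetic_data import SynthesisSpec, gen_dataset

TINY_MODEL = ModelConfig(
    embed_dim=12, image_channels=3, depth=1, heads=2, output_dim=12, seed=0
)
TINY_TRAIN = TrainConfig(
    n_seeds=2, max_epochs=3, patience=2, batch_size=64,
    lr_graph=3e-3, lr_image=3e-3, lr_text=3e-3, lr_head=3e-3,
)


def _singleton_table(n):
    """n unique acyclic molecules: every record is its own scaffold cluster."""
    smiles = [f"OC{'C' * (i % 40)}{'N' if i % 2 else 'O'}C{'C' * (i // 40)}" for i in range(n)]
    records = [parse_and_canonicalize(s) for s in smiles]
    assert len({r.canonical_smiles for r in records}) == n
    return DatasetTable(records=records, labels=[float(i) for i in range(n)])


class TestSplitDataset:
    def test_singleton_scaffolds_fill_exact_counts(self):
        table = _singleton_table(100)
        split = split_dataset(table, "size_ordered_scaffold", (0.8, 0.1, 0.1), seed=0)
        assert split.counts() == {"train": 80, "validation": 10, "test": 10}

    def test_single_shared_scaffold_forced_to_train(self):
        smiles = [f"c1ccccc1{'C' * (i + 1)}" for i in range(20)]
        table = DatasetTable(records=[parse_and_canonicalize(s) for s in smiles])
        with pytest.warns(UserWarning, match="test partition is empty"):
            split = split_dataset(table, "balanced_scaffold", seed=1)
        assert split.counts()["train"] == 20

    def test_random_split_partitions_cover_everything(self, classification_table):
        split = split_dataset(classification_table, "random", (0.7, 0.1, 0.2), seed=3)
        counts = split.counts()
        assert sum(counts.values()) == len(classification_table)
        assert all(c > 0 for c in counts.values())

    @pytest.mark.parametrize("method", ["size_ordered_scaffold", "balanced_scaffold"])
    def test_no_scaffold_spans_partitions(self, classification_table, method):
        split = split_dataset(classification_table, method, seed=5)
        keys = {p: set() for p in ("train", "validation", "test")}
        for rec, part in zip(classification_table.records, split.partition):
            keys[part].add(cluster_key(rec))
        assert not (keys["train"] & keys["validation"])
        assert not (keys["train"] & keys["test"])
        assert not (keys["validation"] & keys["test"])

    def test_bad_ratios_rejected(self, classification_table):
        with pytest.raises(ValueError, match="sum to 1"):
            split_dataset(classification_table, "random", (0.5, 0.2, 0.2))

    def test_seeded_reproducibility(self, classification_table):
        a = split_dataset(classification_table, "balanced_scaffold", seed=9)
        b = split_dataset(classification_table, "balanced_scaffold", seed=9)
        assert np.array_equal(a.partition, b.partition)


class TestScaledMetric:
    @pytest.mark.parametrize(
        "name,m0,s",
        [
            ("esol", 0.7, 1.0),
            ("freesolv", 1.5, 5.0),
            ("lipophilicity", 0.50, 1.0),
            ("qm7", 55.0, 100.0),
            ("computational_adme", 0.30, 1.0),
        ],
    )
    def test_registry_and_identity_at_offset(self, name, m0, s):
        params = SCALED_METRIC_REGISTRY[name]
        assert (params.m0, params.s) == (m0, s)
        assert scale_metric(m0, params) == 1.0

    def test_qm7_example(self):
        assert abs(scale_metric(75.0, SCALED_METRIC_REGISTRY["qm7"]) - 0.8) < 1e-12

    def test_affine_and_invertible(self, rng):
        params = ScaledMetricParams(0.4, 2.5)
        for m in rng.normal(size=20):
            assert abs(inverse_scale_metric(scale_metric(m, params), params) - m) < 1e-12

    def test_strictly_decreasing(self):
        params = SCALED_METRIC_REGISTRY["esol"]
        assert scale_metric(1.0, params) < scale_metric(0.5, params)

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(ValueError):
            ScaledMetricParams(0.0, 0.0)


class TestModelAgreement:
    def test_identical_binary_predictions(self):
        p = np.array([0.9, 0.1, 0.8, 0.2])
        res = model_agreement(p, p, "classification")
        assert res.kind == "f1" and res.statistic == 1.0

    def test_asymmetric_f1_two_thirds(self):
        preds_a = np.ones(10)
        preds_b = np.array([1.0] * 5 + [0.0] * 5)
        res = model_agreement(preds_a, preds_b, "classification")
        assert abs(res.statistic - 2 / 3) < 1e-12

    def test_identical_regression_vectors(self, rng):
        p = rng.normal(size=30)
        res = model_agreement(p, p, "regression")
        assert res.kind == "pearson"
        assert abs(res.statistic - 1.0) < 1e-12
        assert res.p_value < 1e-6

    def test_degenerate_one_class_flagged(self):
        with pytest.warns(UserWarning, match="degenerate"):
            res = model_agreement(np.zeros(5), np.zeros(5), "classification")
        assert res.degenerate

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            model_agreement(np.zeros(3), np.zeros(4), "classification")


@pytest.fixture(scope="module")
def tiny_run():
    table = gen_dataset(SynthesisSpec(n_molecules=120, seed=21))
    split = split_dataset(table, "balanced_scaffold", seed=0)
    feats = featurize_table(table, views=TINY_MODEL.views, laplacian_k=TINY_MODEL.laplacian_k)
    result = finetune_task(table, split, TINY_MODEL, TINY_TRAIN, feats=feats)
    return table, split, feats, result


class TestFinetune:
    def test_report_structure(self, tiny_run):
        _, _, _, result = tiny_run
        assert result.report.n_seeds == 2
        assert len(result.report.per_seed) == 2
        assert np.isfinite(result.report.ci95)
        assert 0.0 <= result.report.mean <= 1.0

    def test_alpha_interpretable(self, tiny_run):
        _, _, _, result = tiny_run
        assert set(result.alpha) == {"graph", "image", "text"}
        assert abs(sum(result.alpha.values()) - 1.0) < 1e-9

    def test_prediction_deterministic_with_frozen_gates(self, tiny_run):
        _, _, feats, result = tiny_run
        a = result.best_model.predict(feats, np.arange(10))
        b = result.best_model.predict(feats, np.arange(10))
        assert np.array_equal(a, b)

    def test_single_molecule_prediction_batch_independent(self, tiny_run):
        _, _, feats, result = tiny_run
        solo = result.best_model.predict(feats, np.array([4]))
        batch = result.best_model.predict(feats, np.arange(10))
        assert abs(solo[0] - batch[4]) < 1e-10

    def test_zero_learning_rates_leave_parameters(self, tiny_run):
        table, split, feats, _ = tiny_run
        from mvmol.finetune import MultiViewModel, _train_one

        cfg = TrainConfig(
            n_seeds=1, max_epochs=1, patience=1, batch_size=64,
            lr_graph=0.0, lr_image=0.0, lr_text=0.0, lr_head=0.0,
        )
        model = MultiViewModel(TINY_MODEL, feats.get("vocabulary"))
        model.task_kind = "classification"
        before = [p.data.copy() for p in model.parameters()]
        _train_one(model, feats, np.asarray(table.labels), split, cfg,
                   np.random.default_rng(0))
        after = model.parameters()
        assert all(np.array_equal(b, a.data) for b, a in zip(before, after))

    def test_unlabeled_table_rejected(self, tiny_run):
        table, split, _, _ = tiny_run
        unlabeled = DatasetTable(records=table.records)
        with pytest.raises(ValueError, match="labels"):
            finetune_task(unlabeled, split, TINY_MODEL, TINY_TRAIN)


class TestRankScreen:
    def test_full_ranking_and_determinism(self, tiny_run):
        table, _, feats, result = tiny_run
        ranked, alpha = rank_screen(result.best_model, table, top_k=10**6, feats=feats)
        assert len(ranked) == len(table)
        assert list(ranked["score"]) == sorted(ranked["score"], reverse=True)
        again, _ = rank_screen(result.best_model, table, top_k=10**6, feats=feats)
        assert list(ranked["smiles"]) == list(again["smiles"])
        assert abs(sum(alpha.values()) - 1.0) < 1e-9

    def test_top_k_truncates(self, tiny_run):
        table, _, feats, result = tiny_run
        ranked, _ = rank_screen(result.best_model, table, top_k=5, feats=feats)
        assert len(ranked) == 5
        assert list(ranked["rank"]) == [1, 2, 3, 4, 5]
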