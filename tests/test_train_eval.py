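import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mpbind.fixtures import make_training_task
from mpbind.nn.egnn import EGNNConfig, MPBindModel
from mpbind.train_eval import (
    Adam,
    MetricError,
    TrainConfig,
    accuracy,
    auprc,
    auroc,
    bce_loss,
    evaluate,
    select_best_epoch,
    train,
)

SMALL_MODEL = dict(hidden_dim=16, message_dim=8, edge_proj_dim=4, head_dim=4)


def auroc_oracle(scores, labels):
    """O(n^2) pairwise comparison; ties count 1/2."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def auprc_oracle(scores, labels):
    """Exhaustive threshold sweep over unique scores (descending)."""
    n_pos = labels.sum()
    ap, prev_recall = 0.0, 0.0
    for t in sorted(set(scores), reverse=True):
        calls = scores >= t
        tp = int((calls & (labels == 1)).sum())
        fp = int((calls & (labels == 0)).sum())
        precision = tp / (tp + fp)
        recall = tp / n_pos
        ap += precision * (recall - prev_recall)
        prev_recall = recall
    return ap


class TestBCE:
    def test_perfect_prediction_near_zero(self):
        y = np.array([[0.0, 1.0], [1.0, 0.0]])
        assert bce_loss(y, y) <= 1e-5

    def test_half_probability_is_ln2(self):
        y = np.array([0.0, 1.0, 1.0, 0.0])
        assert bce_loss(np.full(4, 0.5), y) == pytest.approx(np.log(2), abs=1e-12)

    def test_matches_elementwise_formula(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0.01, 0.99, (10, 5))
        y = rng.integers(0, 2, (10, 5)).astype(float)
        expected = -(y * np.log(p) + (1 - y) * np.log(1 - p)).mean()
        assert bce_loss(p, y) == pytest.approx(expected, abs=1e-12)

    def test_mask_restricts_mean(self):
        p = np.array([0.5, 0.9])
        y = np.array([1.0, 1.0])
        m = np.array([1.0, 0.0])
        assert bce_loss(p, y, m) == pytest.approx(np.log(2), abs=1e-12)

    def test_all_masked_errors(self):
        with pytest.raises(MetricError):
            bce_loss(np.array([0.5]), np.array([1.0]), np.array([0.0]))


class TestAUROC:
    def test_perfect_separation(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        labels = np.array([1, 1, 0, 0])
        assert auroc(scores, labels) == 1.0

    def test_all_ties_half(self):
        scores = np.full(10, 0.5)
        labels = np.array([1, 0] * 5)
        assert auroc(scores, labels) == 0.5

    def test_single_class_errors(self):
        with pytest.raises(MetricError):
            auroc(np.array([0.1, 0.9]), np.array([1, 1]))

    def test_matches_pairwise_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            scores = np.round(rng.uniform(size=50), 2)  # rounding forces ties
            labels = rng.integers(0, 2, 50)
            if labels.sum() in (0, 50):
                continue
            assert auroc(scores, labels) == pytest.approx(
                auroc_oracle(scores, labels), abs=1e-12
            )

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_monotone_transform_invariance(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=30)
        labels = rng.integers(0, 2, 30)
        if labels.sum() in (0, 30):
            return
        a1 = auroc(scores, labels)
        a2 = auroc(np.exp(2.0 * scores) + 3.0, labels)
        assert a1 == pytest.approx(a2, abs=1e-12)


class TestAUPRC:
    def test_perfect_ranking(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        labels = np.array([1, 1, 0, 0])
        assert auprc(scores, labels) == 1.0

    def test_no_positives_errors(self):
        with pytest.raises(MetricError):
            auprc(np.array([0.5]), np.array([0]))

    def test_matches_threshold_sweep_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            scores = np.round(rng.uniform(size=20), 1)
            labels = rng.integers(0, 2, 20)
            if labels.sum() == 0:
                continue
            assert auprc(scores, labels) == pytest.approx(
                auprc_oracle(scores, labels), abs=1e-12
            )

    def test_random_scores_approach_prevalence(self):
        rng = np.random.default_rng(3)
        n = 10000
        labels = (rng.uniform(size=n) < 0.2).astype(int)
        scores = rng.uniform(size=n)
        prevalence = labels.mean()
        assert auprc(scores, labels) == pytest.approx(prevalence, abs=0.05)


class TestAccuracy:
    def test_formula(self):
        scores = np.array([0.9, 0.1, 0.2, 0.3])
        labels = np.array([1, 0, 0, 0])
        acc, conf = accuracy(scores, labels)
        assert acc == 1.0
        assert (conf.TP, conf.TN, conf.FP, conf.FN) == (1, 3, 0, 0)

    def test_all_wrong(self):
        acc, _ = accuracy(np.array([0.9, 0.1]), np.array([0, 1]))
        assert acc == 0.0

    def test_threshold_is_strictly_greater(self):
        acc, conf = accuracy(np.array([0.5]), np.array([1]))
        assert conf.FN == 1  # 0.5 is NOT a positive call

    def test_random_instance_matches_hand_count(self):
        rng = np.random.default_rng(4)
        scores = rng.uniform(size=100)
        labels = rng.integers(0, 2, 100)
        acc, conf = accuracy(scores, labels)
        calls = scores > 0.5
        assert conf.TP == int((calls & (labels == 1)).sum())
        assert conf.TN == int((~calls & (labels == 0)).sum())
        assert conf.total == 100
        assert acc == pytest.approx((calls == labels.astype(bool)).mean())

    def test_monotone_in_threshold_when_separated(self):
        scores = np.array([0.9, 0.85, 0.2, 0.1])
        labels = np.array([1, 1, 0, 0])
        accs = [accuracy(scores, labels, t)[0] for t in (0.3, 0.5, 0.87)]
        assert accs[0] >= accs[1] >= accs[2] or accs == sorted(accs, reverse=True)


@pytest.fixture(scope="module")
def tiny_task():
    return make_training_task(1, 8, n_residues=60)


@pytest.fixture(scope="module")
def eval_task():
    return make_training_task(5, 4, n_residues=50)


class TestAdamAndTrain:
    def test_lr_zero_keeps_parameters(self, tiny_task):
        model = MPBindModel(EGNNConfig(seed=0, **SMALL_MODEL))
        before = [p.copy() for p in model.state_arrays()]
        with pytest.raises(ValueError):
            TrainConfig(learning_rate=0.0)  # invariant: lr > 0
        # emulate with an Adam step on zero gradients instead
        opt = Adam(model.parameters(), lr=1e-3)
        opt.zero_grad()
        opt.step()
        for b, p in zip(before, model.state_arrays()):
            np.testing.assert_array_equal(b, p)

    def test_injected_val_sequence_argmin(self):
        assert select_best_epoch([0.9, 0.4, 0.6]) == 1

    def test_training_learns_planted_signal(self, tiny_task):
        model = MPBindModel(EGNNConfig(seed=0, **SMALL_MODEL))
        model, hist = train(
            model, tiny_task[:6], tiny_task[6:],
            TrainConfig(max_epochs=40, seed=0, patience=10),
        )
        assert hist.best_epoch == int(np.argmin(hist.val_loss))
        report = evaluate(model, tiny_task[6:])
        assert report.per_task["ion"].auroc > 0.95

    def test_best_checkpoint_restored(self, tiny_task):
        model = MPBindModel(EGNNConfig(seed=1, **SMALL_MODEL))
        model, hist = train(
            model, tiny_task[:6], tiny_task[6:],
            TrainConfig(max_epochs=6, seed=1),
        )
        from mpbind.train_eval import dataset_loss

        val = dataset_loss(model, tiny_task[6:])
        assert val == pytest.approx(min(hist.val_loss), abs=1e-9)

    def test_seeded_training_reproducible(self, tiny_task):
        runs = []
        for _ in range(2):
            model = MPBindModel(EGNNConfig(seed=2, **SMALL_MODEL))
            model, hist = train(model, tiny_task[:4], tiny_task[4:6],
                                TrainConfig(max_epochs=2, seed=3))
            runs.append((model.state_arrays(), tuple(hist.val_loss)))
        assert runs[0][1] == runs[1][1]
        for a, b in zip(runs[0][0], runs[1][0]):
            np.testing.assert_array_equal(a, b)

    def test_empty_sets_rejected(self):
        model = MPBindModel(EGNNConfig(**SMALL_MODEL))
        from mpbind.train_eval import TrainingError

        with pytest.raises(TrainingError):
            train(model, [], [], TrainConfig(max_epochs=1))


class TestEvaluate:
    def test_oracle_model_scores_one(self, eval_task):
        class Oracle:
            def __init__(self, examples):
                self._lookup = {id(ex.graph): ex.labels for ex in examples}

            def forward(self, graph):
                from mpbind.nn.egnn import PredictionResult

                y = self._lookup[id(graph)].astype(float)
                return PredictionResult("A", np.clip(y, 0.01, 0.99))

        report = evaluate(Oracle(eval_task), eval_task)
        m = report.per_task["ion"]
        assert m.auroc == 1.0 and m.auprc == 1.0 and m.acc == 1.0

    def test_constant_half_model(self, eval_task):
        class Constant:
            def forward(self, graph):
                from mpbind.nn.egnn import PredictionResult

                return PredictionResult("A", np.full((graph.num_nodes, 5), 0.5))

        report = evaluate(Constant(), eval_task)
        m = report.per_task["ion"]
        neg_prev = m.n_neg / (m.n_pos + m.n_neg)
        assert m.acc == pytest.approx(neg_prev)  # all calls negative at >0.5
        assert m.auroc == 0.5

    def test_micro_pooling_matches_composition(self, eval_task):
        model = MPBindModel(EGNNConfig(seed=9, **SMALL_MODEL))
        report = evaluate(model, eval_task)
        scores = np.concatenate([model.forward(ex.graph).probs[:, 3]
                                 for ex in eval_task])
        labels = np.concatenate([ex.labels[:, 3] for ex in eval_task])
        assert report.per_task["ion"].auroc == pytest.approx(auroc(scores, labels))
        assert report.per_task["ion"].auprc == pytest.approx(auprc(scores, labels))

    def test_empty_set_errors(self):
        model = MPBindModel(EGNNConfig(**SMALL_MODEL))
        with pytest.raises(MetricError):
            evaluate(model, [])

    def test_report_serializes(self, eval_task, tmp_path):
        model = MPBindModel(EGNNConfig(**SMALL_MODEL))
        report = evaluate(model, eval_task)
        out = tmp_path / "report.json"
        report.save_json(out)
        import json

        data = json.loads(out.read_text())
        assert set(data) == {"protein", "nucleic", "ligand", "ion", "lipid"}
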