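"""Training loop and residue-level evaluation.

Binary cross-entropy over the five task channels, Adam at learning rate
0.001, and best-model selection on the lowest validation loss. Metrics are
AUROC (Mann-Whitney, ties count 1/2), AUPRC (step-wise average precision)
and accuracy with calls at score > 0.5, pooled over residues by default.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import rankdata

from .nn.autograd import Tensor
from .nn.egnn import MPBindModel
from .registry import TASKS


class MetricError(ValueError):
    pass


class TrainingError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def bce_loss(probs: np.ndarray, labels: np.ndarray,
             mask: np.ndarray | None = None, eps: float = 1e-7) -> float:
    """Mean of -[y log p + (1-y) log(1-p)] over unmasked entries.

    Probabilities are clipped to [eps, 1-eps] for stability.
    """
    p = np.clip(np.asarray(probs, dtype=float), eps, 1.0 - eps)
    y = np.asarray(labels, dtype=float)
    m = np.ones_like(y) if mask is None else np.asarray(mask, dtype=float)
    n = m.sum()
    if n == 0:
        raise MetricError("bce_loss: all entries are masked")
    elem = -(y * np.log(p) + (1.0 - y) * np.log(1.0 - p))
    return float((elem * m).sum() / n)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

@dataclass
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


def auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUROC; tied scores contribute 1/2 per pair."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise MetricError("AUROC undefined: needs at least one positive and one negative")
    ranks = rankdata(scores)  # average ranks handle ties
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def auprc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Average precision: sum of precision * recall increments over
    descending unique score thresholds (ties collapse into one block)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise MetricError("AUPRC undefined: no positive labels")
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    ap = 0.0
    tp = fp = 0
    i = 0
    n = len(s)
    while i < n:
        j = i
        while j < n and s[j] == s[i]:
            j += 1
        tp += int(y[i:j].sum())
        fp += (j - i) - int(y[i:j].sum())
        precision = tp / (tp + fp)
        recall_prev = (tp - int(y[i:j].sum())) / n_pos
        recall = tp / n_pos
        ap += precision * (recall - recall_prev)
        i = j
    return float(ap)


def accuracy(scores: np.ndarray, labels: np.ndarray,
             threshold: float = 0.5) -> tuple[float, ConfusionCounts]:
    """Fraction of correct calls at score > threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    calls = (scores > threshold).astype(int)
    tp = int(((calls == 1) & (labels == 1)).sum())
    tn = int(((calls == 0) & (labels == 0)).sum())
    fp = int(((calls == 1) & (labels == 0)).sum())
    fn = int(((calls == 0) & (labels == 1)).sum())
    counts = ConfusionCounts(TP=tp, TN=tn, FP=fp, FN=fn)
    return (tp + tn) / counts.total, counts


@dataclass
class TaskMetrics:
    auroc: float | None
    auprc: float | None
    acc: float
    confusion: ConfusionCounts
    n_pos: int
    n_neg: int


@dataclass
class MetricsReport:
    per_task: dict[str, TaskMetrics]

    def to_dict(self) -> dict:
        out = {}
        for task, m in self.per_task.items():
            out[task] = {
                "auroc": m.auroc, "auprc": m.auprc, "acc": m.acc,
                "confusion": asdict(m.confusion),
                "n_pos": m.n_pos, "n_neg": m.n_neg,
            }
        return out

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------

class Adam:
    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for k, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            m_hat = self.m[k] / (1 - self.b1 ** self.t)
            v_hat = self.v[k] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    learning_rate: float = 1e-3
    max_epochs: int = 50
    batch_size: int = 1            # graphs per optimizer step (accumulated)
    validation_period: int = 1     # epochs between validation passes
    patience: int | None = None    # early stop after this many non-improving checks
    seed: int = 0
    mask_policy: str = "include_all"   # or "mask_absent": mask tasks with no positives

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.mask_policy not in ("include_all", "mask_absent"):
            raise ValueError("mask_policy must be 'include_all' or 'mask_absent'")


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = -1


def _example_mask(example, policy: str) -> np.ndarray:
    mask = np.asarray(example.mask, dtype=float)
    if policy == "mask_absent":
        mask = mask.copy()
        absent = np.asarray(example.labels).sum(axis=0) == 0
        mask[:, absent] = 0.0
    return mask


def dataset_loss(model: MPBindModel, dataset, policy: str = "include_all") -> float:
    """Mean per-entry BCE over a dataset (inference mode)."""
    total, n = 0.0, 0.0
    for ex in dataset:
        mask = _example_mask(ex, policy)
        m_sum = mask.sum()
        if m_sum == 0:
            continue
        logits = model.forward_logits(ex.graph, training=False)
        z = logits.data
        y = np.asarray(ex.labels, dtype=float)
        elem = np.maximum(z, 0.0) - z * y + np.log1p(np.exp(-np.abs(z)))
        total += float((elem * mask).sum())
        n += m_sum
    if n == 0:
        raise TrainingError("validation loss undefined: all entries masked")
    return total / n


def train(model: MPBindModel, train_set, val_set,
          cfg: TrainConfig | None = None) -> tuple[MPBindModel, TrainHistory]:
    """Train with Adam; return the model restored to the epoch with minimum
    validation loss, plus the loss history."""
    cfg = cfg or TrainConfig()
    if not train_set or not val_set:
        raise TrainingError("train and validation sets must be non-empty")
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    history = TrainHistory()
    best_val = np.inf
    best_state = [p.copy() for p in model.state_arrays()]
    checks_since_best = 0

    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(train_set))
        epoch_loss, n_batches = 0.0, 0
        opt.zero_grad()
        pending = 0
        for step, idx in enumerate(order):
            ex = train_set[idx]
            mask = _example_mask(ex, cfg.mask_policy)
            if mask.sum() == 0:
                continue
            logits = model.forward_logits(ex.graph, training=True)
            loss = logits.bce_with_logits(ex.labels, mask)
            if not np.isfinite(loss.data):
                raise TrainingError(
                    f"divergence: non-finite loss at epoch {epoch}, step {step}"
                )
            loss.backward(np.asarray(1.0 / cfg.batch_size))
            epoch_loss += float(loss.data)
            n_batches += 1
            pending += 1
            if pending == cfg.batch_size:
                opt.step()
                opt.zero_grad()
                pending = 0
        if pending:
            opt.step()
            opt.zero_grad()
        history.train_loss.append(epoch_loss / max(n_batches, 1))

        if (epoch + 1) % cfg.validation_period == 0 or epoch == cfg.max_epochs - 1:
            val = dataset_loss(model, val_set, cfg.mask_policy)
            history.val_loss.append(val)
            if val < best_val:
                best_val = val
                best_state = [p.copy() for p in model.state_arrays()]
                history.best_epoch = epoch
                checks_since_best = 0
            else:
                checks_since_best += 1
                if cfg.patience is not None and checks_since_best >= cfg.patience:
                    break

    model.load_state_arrays(best_state)
    return model, history


def select_best_epoch(val_losses: list[float]) -> int:
    """Argmin rule used for model selection (first minimum wins)."""
    if not val_losses:
        raise TrainingError("no validation losses recorded")
    return int(np.argmin(val_losses))


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def evaluate(model: MPBindModel, test_set, threshold: float = 0.5,
             mode: str = "micro") -> MetricsReport:
    """Per-task metrics pooled over all residues of all chains (micro), or
    averaged over chains (macro). Chains lacking positives for a task are
    excluded from that task's ranking metrics in macro mode; in micro mode
    pooling makes the question moot unless the whole pool is single-class,
    which reports None."""
    if not test_set:
        raise MetricError("evaluate: empty test set")
    if mode not in ("micro", "macro"):
        raise MetricError("mode must be 'micro' or 'macro'")

    all_scores, all_labels = [], []
    for ex in test_set:
        result = model.forward(ex.graph)
        all_scores.append(result.probs)
        all_labels.append(np.asarray(ex.labels, dtype=int))

    per_task: dict[str, TaskMetrics] = {}
    for t, task in enumerate(TASKS):
        if mode == "micro":
            scores = np.concatenate([s[:, t] for s in all_scores])
            labels = np.concatenate([y[:, t] for y in all_labels])
            try:
                roc = auroc(scores, labels)
            except MetricError:
                roc = None
            try:
                prc = auprc(scores, labels)
            except MetricError:
                prc = None
            acc, conf = accuracy(scores, labels, threshold)
        else:
            rocs, prcs, accs = [], [], []
            conf = ConfusionCounts(0, 0, 0, 0)
            for s, y in zip(all_scores, all_labels):
                a, c = accuracy(s[:, t], y[:, t], threshold)
                accs.append(a)
                conf = ConfusionCounts(conf.TP + c.TP, conf.TN + c.TN,
                                       conf.FP + c.FP, conf.FN + c.FN)
                if y[:, t].sum() and (1 - y[:, t]).sum():
                    rocs.append(auroc(s[:, t], y[:, t]))
                    prcs.append(auprc(s[:, t], y[:, t]))
            roc = float(np.mean(rocs)) if rocs else None
            prc = float(np.mean(prcs)) if prcs else None
            acc = float(np.mean(accs))
            labels = np.concatenate([y[:, t] for y in all_labels])
        per_task[task] = TaskMetrics(
            auroc=roc, auprc=prc, acc=acc, confusion=conf,
            n_pos=int(labels.sum()), n_neg=int(len(labels) - labels.sum()),
        )
    return MetricsReport(per_task=per_task)
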