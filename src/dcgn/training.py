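"""Loss, Adam optimizer and the minibatch training loop.

The loss is sparse categorical cross-entropy: softmax is folded into the
loss (the network emits logits) for numerical stability, and integer
labels are treated as one-hot targets.  Optimization is Adam with the
standard moment constants, minibatches of 256 by default, per-epoch
shuffling, and early stopping on validation loss.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .dcgn_model import LayerStack, TrainedDCGN, build_dcgn
from .io_config import DCGNConfig, ExpressionDataset


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def sparse_ce_loss(logits: np.ndarray, labels: np.ndarray) -> float:
    """Mean cross-entropy -1/N sum_i log p_{i, y_i} with p = softmax(logits)."""
    logits = np.asarray(logits, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n, c = logits.shape
    if labels.min() < 0 or labels.max() >= c:
        raise ValueError(f"labels outside 0..{c - 1}")
    z = logits - logits.max(axis=1, keepdims=True)
    log_p = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    return float(-log_p[np.arange(n), labels].mean())


def sparse_ce_grad(logits: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """d loss / d logits = (softmax - onehot) / N."""
    n = logits.shape[0]
    g = softmax(logits)
    g[np.arange(n), np.asarray(labels, dtype=int)] -= 1.0
    return g / n


@dataclass
class AdamState:
    """First/second moment estimates per parameter plus the step counter."""

    m: dict[str, np.ndarray]
    v: dict[str, np.ndarray]
    t: int = 0

    @classmethod
    def init(cls, params: dict[str, np.ndarray]) -> "AdamState":
        return cls(
            m={k: np.zeros_like(p) for k, p in params.items()},
            v={k: np.zeros_like(p) for k, p in params.items()},
        )


def adam_step(
    params: dict[str, np.ndarray],
    grads: dict[str, np.ndarray],
    state: AdamState,
    lr: float,
    beta1: float = 0.9,
    beta2: float = 0.999,
    eps: float = 1e-8,
) -> None:
    """One bias-corrected Adam update, applied to ``params`` in place."""
    state.t += 1
    t = state.t
    for k, p in params.items():
        g = grads[k]
        if not np.isfinite(g).all():
            raise FloatingPointError(
                f"non-finite gradient in {k!r} at Adam step {t}"
            )
        state.m[k] = beta1 * state.m[k] + (1.0 - beta1) * g
        state.v[k] = beta2 * state.v[k] + (1.0 - beta2) * g * g
        m_hat = state.m[k] / (1.0 - beta1**t)
        v_hat = state.v[k] / (1.0 - beta2**t)
        p -= lr * m_hat / (np.sqrt(v_hat) + eps)


@dataclass
class TrainState:
    """Per-epoch training record and the best-validation bookkeeping."""

    epoch: int = 0
    train_loss: float = np.inf
    val_loss: float = np.inf
    val_accuracy: float = 0.0
    best_epoch: int = 0
    history: list[dict] = field(default_factory=list)


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start : start + batch_size]


def train_dcgn(
    train: ExpressionDataset,
    val: ExpressionDataset,
    config: DCGNConfig,
    model: LayerStack | None = None,
    verbose: bool = False,
) -> tuple[TrainedDCGN, TrainState]:
    """Train the network on (already standardized) train/val partitions.

    Minibatch gradient descent with Adam; the final partial batch of each
    epoch is kept.  Training stops early when validation loss has not
    improved for ``config.early_stop_patience`` epochs, and the weights
    from the best validation epoch are returned.  Bitwise deterministic
    under ``config.seed`` in single-threaded execution.
    """
    n_classes = config.n_classes
    for part, name in ((train, "train"), (val, "validation")):
        if part.labels.size and part.labels.max() >= n_classes:
            raise ValueError(
                f"{name} labels reach {part.labels.max()} but config.n_classes "
                f"= {n_classes}"
            )
    if model is None:
        model = build_dcgn(config, train.n_genes)
    state = TrainState()
    adam = AdamState.init(model.parameters())
    rng = np.random.default_rng([config.seed, 7])

    best_params = copy.deepcopy(model.parameters())
    best_val = np.inf
    since_best = 0

    for epoch in range(config.epochs):
        losses = []
        for idx in _batches(train.n_samples, config.batch_size, rng):
            x, y = train.values[idx], train.labels[idx]
            logits = model.forward(x, training=True)
            losses.append(sparse_ce_loss(logits, y))
            model.backward(sparse_ce_grad(logits, y))
            adam_step(model.parameters(), model.gradients(), adam, config.learning_rate)
        val_logits = model.forward(val.values, training=False)
        val_loss = sparse_ce_loss(val_logits, val.labels)
        val_acc = float((val_logits.argmax(axis=1) == val.labels).mean())
        state.epoch = epoch
        state.train_loss = float(np.mean(losses))
        state.val_loss = val_loss
        state.val_accuracy = val_acc
        state.history.append(
            {
                "epoch": epoch,
                "train_loss": state.train_loss,
                "val_loss": val_loss,
                "val_accuracy": val_acc,
            }
        )
        if verbose:
            print(
                f"epoch {epoch:3d}  train_loss {state.train_loss:.4f}  "
                f"val_loss {val_loss:.4f}  val_acc {val_acc:.3f}"
            )
        if val_loss < best_val:
            best_val = val_loss
            state.best_epoch = epoch
            best_params = copy.deepcopy(model.parameters())
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.early_stop_patience:
                break

    if state.history:
        model.set_parameters(best_params)
    trained = TrainedDCGN(
        model=model,
        config=config,
        standardizer=None,
        label_names=list(train.label_names),
    )
    return trained, state
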