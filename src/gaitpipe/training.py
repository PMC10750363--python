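"""Training protocol for the clip classifier.

Adam at learning rate 1e-5 with batch size 8; training stops early when
the validation loss has not improved for 5 consecutive epochs, and the
learning rate halves when the validation accuracy has not improved for 3
consecutive epochs (the plateau counter restarts after each halving and
after each new best).  The loss is the mean binary cross-entropy of the
two sigmoid outputs against one-hot labels.  The checkpoint kept is the
one with the best validation loss.
"""

from __future__ import annotations


from dataclasses import dataclass, field

import numpy as np

from .nn import Adam, ResNet3d, sigmoid


@dataclass
class TrainConfig:
    learning_rate: float = 1e-5
    batch_size: int = 8
    early_stop_patience: int = 5
    lr_halve_patience: int = 3
    max_epochs: int = 100
    seed: int = 0
    mode: str = "scratch"  # "scratch" | "transfer"

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.early_stop_patience < 1 or self.lr_halve_patience < 1:
            raise ValueError("patiences must be >= 1")
        if self.mode not in ("scratch", "transfer"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)

    def __len__(self):
        return len(self.val_loss)


def early_stop_check(history: TrainHistory, patience: int) -> bool:
    """True iff the best validation loss is ``patience`` or more epochs old."""
    losses = history.val_loss
    if not losses:
        raise ValueError("history is empty")
    best = int(np.argmin(losses))  # first occurrence
    return (len(losses) - 1 - best) >= patience


def lr_schedule_step(history: TrainHistory, patience: int,
                     current_lr: float) -> float:
    """Halve the learning rate after ``patience`` consecutive epochs
    without a new best validation accuracy; the stagnation counter resets
    on every improvement and on every halving."""
    accs = history.val_accuracy
    if not accs:
        raise ValueError("history is empty")
    last_improve = 0
    best = accs[0]
    for i, a in enumerate(accs[1:], start=1):
        if a > best:
            best, last_improve = a, i
    # first epoch run at the current lr (epochs since the last halving)
    last_change = 0
    for i in range(1, len(history.lr)):
        if history.lr[i] != history.lr[i - 1]:
            last_change = i
    anchor = max(last_improve, last_change - 1 if last_change else 0)
    if (len(accs) - 1 - anchor) >= patience:
        return current_lr / 2.0
    return current_lr


def bce_loss_and_grad(logits: np.ndarray, onehot: np.ndarray
                      ) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy over the sigmoid outputs + logit gradient."""
    s = sigmoid(logits)
    eps = 1e-12
    loss = -np.mean(onehot * np.log(s + eps) + (1 - onehot) * np.log(1 - s + eps))
    dlogits = (s - onehot) / onehot.size
    return float(loss), dlogits.astype(np.float32)


def one_hot(labels: np.ndarray, n_classes: int = 2) -> np.ndarray:
    out = np.zeros((len(labels), n_classes), dtype=np.float32)
    out[np.arange(len(labels)), labels] = 1.0
    return out


def _evaluate(model: ResNet3d, x: np.ndarray, y: np.ndarray,
              batch_size: int) -> tuple[float, float]:
    losses, correct = [], 0
    for i in range(0, len(x), batch_size):
        xb, yb = x[i:i + batch_size], y[i:i + batch_size]
        logits = model.forward(xb, train=False, keep_cache=False)
        loss, _ = bce_loss_and_grad(logits, one_hot(yb, logits.shape[1]))
        losses.append(loss * len(xb))
        correct += int(np.sum(np.argmax(logits, axis=1) == yb))
    return float(np.sum(losses) / len(x)), correct / len(x)


def train_fold(model: ResNet3d, x_train: np.ndarray, y_train: np.ndarray,
               x_val: np.ndarray, y_val: np.ndarray, config: TrainConfig,
               verbose: bool = False
               ) -> tuple[ResNet3d, TrainHistory, dict]:
    """Train one cross-validation fold.

    ``x_*`` are (N, 3, T, side, side) float32 tensors, ``y_*`` integer
    class indices (0 = ASD, 1 = non-ASD).  Fully reproducible for a fixed
    seed under single-threaded execution.  Returns the model restored to
    the best-validation-loss epoch, the history, and that checkpoint
    (a state dict).
    """
    if len(x_train) == 0 or len(x_val) == 0:
        raise ValueError("train and val sets must be non-empty")
    rng = np.random.default_rng(config.seed)
    opt = Adam(model, lr=config.learning_rate)
    history = TrainHistory()
    best_state, best_loss = None, np.inf
    lr = config.learning_rate
    for epoch in range(config.max_epochs):
        order = rng.permutation(len(x_train))
        epoch_losses = []
        for i in range(0, len(order), config.batch_size):
            idx = order[i:i + config.batch_size]
            xb = x_train[idx]
            logits = model.forward(xb, train=True)
            loss, dlogits = bce_loss_and_grad(
                logits, one_hot(y_train[idx], logits.shape[1]))
            model.zero_grads()
            model.backward(dlogits)
            opt.step()
            epoch_losses.append(loss * len(idx))
        model.clear_caches()
        val_loss, val_acc = _evaluate(model, x_val, y_val, config.batch_size)
        history.train_loss.append(float(np.sum(epoch_losses) / len(order)))
        history.val_loss.append(val_loss)
        history.val_accuracy.append(val_acc)
        history.lr.append(lr)
        if verbose:
            print(f"epoch {epoch + 1}: train_loss={history.train_loss[-1]:.4f} "
                  f"val_loss={val_loss:.4f} val_acc={val_acc:.4f} lr={lr:.2e}")
        if val_loss < best_loss:
            best_loss = val_loss
            best_state = model.state_dict()
        new_lr = lr_schedule_step(history, config.lr_halve_patience, lr)
        if new_lr != lr:
            lr = new_lr
            opt.lr = lr
        if early_stop_check(history, config.early_stop_patience):
            break
    if best_state is not None:
        model.load_state_dict(best_state)
    return model, history, best_state
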