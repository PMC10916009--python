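"""Generic mini-batch training loop with early stopping.

A *model* here is any object exposing ``forward(X, train)``,
``backward(dpred)``, ``parameters()`` and ``zero_grad()``.  Training
minimises the masked RMSE with Adam under an exponentially decaying
learning rate, stops when the validation loss has not improved for
``patience`` consecutive epochs, and restores the best-validation weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..errors import ParameterError
from .losses import masked_rmse_grad
from .optim import Adam, ExponentialDecay


@dataclass
class TrainingHistory:
    epoch: list[int] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)

    @property
    def n_epochs(self) -> int:
        return len(self.epoch)

    @property
    def best_val_loss(self) -> float:
        return min(self.val_loss) if self.val_loss else float("nan")


class EarlyStopping:
    """Stop after ``patience`` consecutive epochs without improvement."""

    def __init__(self, patience: int = 20, min_delta: float = 0.0):
        if patience < 1:
            raise ParameterError("patience must be >= 1")
        self.patience = patience
        self.min_delta = min_delta
        self.best = np.inf
        self.counter = 0
        self.improved = False

    def update(self, loss: float) -> bool:
        """Record an epoch's validation loss; return True when training should stop."""
        self.improved = loss < self.best - self.min_delta
        if self.improved:
            self.best = loss
            self.counter = 0
        else:
            self.counter += 1
        return self.counter >= self.patience


def fit_model(
    model,
    X: np.ndarray,
    y: np.ndarray,
    mask: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    mask_val: np.ndarray,
    lr_init: float = 1e-3,
    lr_decay: float = 0.96,
    batch_size: int = 50,
    patience: int = 20,
    max_epochs: int = 1000,
    rng: np.random.Generator | None = None,
    verbose: bool = False,
) -> TrainingHistory:
    if len(X) == 0 or len(X_val) == 0:
        raise ParameterError("training and validation sets must be non-empty")
    rng = rng or np.random.default_rng(0)
    optimizer = Adam(model.parameters(), lr=lr_init)
    schedule = ExponentialDecay(lr_init, lr_decay)
    stopper = EarlyStopping(patience)
    history = TrainingHistory()
    best_weights = None

    n = len(X)
    for epoch in range(max_epochs):
        optimizer.lr = schedule(epoch)
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            pred = model.forward(X[idx], train=True)
            loss, dpred = masked_rmse_grad(pred, y[idx], mask[idx])
            model.zero_grad()
            model.backward(dpred)
            optimizer.step()
            losses.append(loss)

        val_pred = model.forward(X_val, train=False)
        val_loss, _ = masked_rmse_grad(val_pred, y_val, mask_val)
        history.epoch.append(epoch)
        history.train_loss.append(float(np.mean(losses)))
        history.val_loss.append(val_loss)
        history.lr.append(optimizer.lr)
        if verbose:
            print(
                f"epoch {epoch:4d}  train {history.train_loss[-1]:.4f}  "
                f"val {val_loss:.4f}  lr {optimizer.lr:.2e}"
            )

        stop = stopper.update(val_loss)
        if stopper.improved or best_weights is None:
            best_weights = [p.value.copy() for p in model.parameters()]
        if stop:
            break

    if best_weights is not None:
        for p, w in zip(model.parameters(), best_weights):
            p.value[...] = w
    return history
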