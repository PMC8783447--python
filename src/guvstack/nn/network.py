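"""Small CNN assembly and SGDM training with periodic validation."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .layers import (
    BatchNorm2d,
    Conv2d,
    Flatten,
    Linear,
    MaxPool2d,
    ReLU,
    cross_entropy_loss,
    mse_softmax_loss,
    softmax,
)


class SmallCnn:
    """conv->BN->ReLU blocks with max-pools after blocks 1 and 2, FC head.

    For 50x50 inputs the spatial flow is 50 -> 25 -> 12 before the fully
    connected layer; the softmax lives in the loss/prediction functions.
    """

    def __init__(
        self,
        conv_filters: tuple[int, ...],
        n_classes: int,
        input_size: int = 50,
        rng: np.random.Generator | None = None,
    ):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.conv_filters = tuple(conv_filters)
        self.n_classes = n_classes
        self.input_size = input_size
        self.layers: list = []
        cin = 1
        size = input_size
        for block, cout in enumerate(conv_filters):
            self.layers += [Conv2d(cin, cout, rng), BatchNorm2d(cout), ReLU()]
            if block < 2:  # pools after the first two blocks only
                self.layers.append(MaxPool2d())
                size //= 2
            cin = cout
        self.layers.append(Flatten())
        self.layers.append(Linear(cin * size * size, n_classes, rng))

    def parameters(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dlogits: np.ndarray) -> None:
        d = dlogits
        for layer in reversed(self.layers):
            d = layer.backward(d)

    def predict_proba(self, x: np.ndarray, batch_size: int = 512) -> np.ndarray:
        """Class probabilities using running batch-norm statistics."""
        probs = []
        for i in range(0, len(x), batch_size):
            logits = self.forward(x[i : i + batch_size], train=False)
            probs.append(softmax(logits))
        return np.concatenate(probs, axis=0)

    def layer_summary(self) -> list[dict]:
        """Auditable layer-by-layer description of the architecture."""
        rows = [
            {
                "type": "input",
                "shape": (self.input_size, self.input_size, 1),
                "normalization": "zerocenter",
            }
        ]
        for layer in self.layers:
            if isinstance(layer, Conv2d):
                rows.append(
                    {
                        "type": "conv",
                        "filters": layer.weight.shape[0],
                        "kernel": (3, 3),
                        "padding": "same",
                    }
                )
            elif isinstance(layer, BatchNorm2d):
                rows.append({"type": "batchnorm", "channels": len(layer.gamma)})
            elif isinstance(layer, ReLU):
                rows.append({"type": "relu"})
            elif isinstance(layer, MaxPool2d):
                rows.append({"type": "maxpool", "pool": (2, 2), "stride": (2, 2)})
            elif isinstance(layer, Flatten):
                rows.append({"type": "flatten"})
            elif isinstance(layer, Linear):
                rows.append({"type": "fc", "out": layer.weight.shape[0]})
        rows.append({"type": "softmax"})
        return rows


@dataclass
class TrainRecord:
    """One entry of the training history (validation checkpoint)."""

    iteration: int
    epoch: int
    train_loss: float
    val_loss: float
    val_accuracy: float


class _Sgdm:
    """velocity = momentum*velocity - lr*grad;  w += velocity."""

    def __init__(self, params, lr: float, momentum: float):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.velocity = [np.zeros_like(w) for w, _ in params]

    def step(self) -> None:
        for v, (w, g) in zip(self.velocity, self.params):
            v *= self.momentum
            v -= self.lr * g
            w += v


def _evaluate(net: SmallCnn, x: np.ndarray, y: np.ndarray, loss_fn) -> tuple[float, float]:
    logits = []
    for i in range(0, len(x), 512):
        logits.append(net.forward(x[i : i + 512], train=False))
    logits = np.concatenate(logits, axis=0)
    loss, _ = loss_fn(logits, y)
    acc = float((logits.argmax(axis=1) == y).mean())
    return loss, acc


def _snapshot(net: SmallCnn) -> list[tuple]:
    state = []
    for layer in net.layers:
        entry = {}
        for name in ("weight", "bias", "gamma", "beta", "running_mean", "running_var"):
            if hasattr(layer, name):
                entry[name] = getattr(layer, name).copy()
        state.append(entry)
    return state


def _restore(net: SmallCnn, state: list[dict]) -> None:
    for layer, entry in zip(net.layers, state):
        for name, value in entry.items():
            getattr(layer, name)[...] = value


def sgdm_train(
    net: SmallCnn,
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray,
    y_val: np.ndarray,
    learning_rate: float = 0.01,
    momentum: float = 0.9,
    max_epochs: int = 4,
    batch_size: int = 32,
    validation_frequency: int = 30,
    loss: str = "cross_entropy",
    output_network: str = "best_validation",
    rng: np.random.Generator | None = None,
) -> list[TrainRecord]:
    """Train with SGDM; validate every ``validation_frequency`` iterations.

    One epoch is a full pass over the shuffled training set.  The history
    holds one record per validation checkpoint plus a final one, so its
    length is floor(total_iterations / validation_frequency) + 1.

    With ``output_network="best_validation"`` (the default) the weights are
    restored to the checkpoint with the highest validation accuracy before
    returning, so the delivered network is not hostage to the noise of the
    final SGD iterate; ``"last"`` keeps the final iterate.
    """
    if output_network not in ("best_validation", "last"):
        raise ValueError(f"unknown output_network: {output_network!r}")
    rng = rng if rng is not None else np.random.default_rng(0)
    loss_fn = {"cross_entropy": cross_entropy_loss, "mse": mse_softmax_loss}[loss]
    opt = _Sgdm(net.parameters(), learning_rate, momentum)
    history: list[TrainRecord] = []
    iteration = 0
    train_loss = float("nan")
    best_acc = -1.0
    best_state = None
    for epoch in range(1, max_epochs + 1):
        order = rng.permutation(len(x_train))
        for start in range(0, len(order), batch_size):
            idx = order[start : start + batch_size]
            logits = net.forward(x_train[idx], train=True)
            train_loss, dlogits = loss_fn(logits, y_train[idx])
            net.backward(dlogits)
            opt.step()
            iteration += 1
            if iteration % validation_frequency == 0:
                val_loss, val_acc = _evaluate(net, x_val, y_val, loss_fn)
                history.append(
                    TrainRecord(iteration, epoch, train_loss, val_loss, val_acc)
                )
                if output_network == "best_validation" and val_acc > best_acc:
                    best_acc = val_acc
                    best_state = _snapshot(net)
    val_loss, val_acc = _evaluate(net, x_val, y_val, loss_fn)
    history.append(TrainRecord(iteration, max_epochs, train_loss, val_loss, val_acc))
    if output_network == "best_validation" and best_state is not None and best_acc > val_acc:
        _restore(net, best_state)
    return history
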