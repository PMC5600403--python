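"""Fitting the network to a peptide profile.

The objective is the plain sum of squared errors between measured and
predicted peptide probabilities, minimized with RMSprop (30 epochs at
learning rate 0.01 by default) with activation dropout during training and no
other regularization.  Gradient work for all-zero protein blocks is skipped:
with bias-free layers a zero input yields zero activations and a zero local
gradient, so the sparse path is exactly equivalent to the dense one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import cnn
from .cnn import CNNConfig, CNNModel
from .io_encoding import SparseEncoding


class NumericalError(RuntimeError):
    """Non-finite loss or gradient encountered."""


def sse_loss(predictions, targets) -> float:
    """Sum of squared errors over peptides."""
    predictions = np.asarray(predictions, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if predictions.shape != targets.shape:
        raise ValueError("predictions and targets must have equal length")
    if predictions.size == 0:
        raise ValueError("empty prediction set")
    return float(np.sum((targets - predictions) ** 2))


def rmse(predictions, targets) -> float:
    return float(np.sqrt(sse_loss(predictions, targets) / len(np.atleast_1d(predictions))))


@dataclass
class OptimizerState:
    """RMSprop state: per-parameter moving average of squared gradients."""

    v: dict[str, np.ndarray]
    learning_rate: float
    rho: float = 0.9
    eps: float = 1e-8

    @classmethod
    def for_params(cls, params: dict[str, np.ndarray], learning_rate: float,
                   rho: float = 0.9, eps: float = 1e-8) -> "OptimizerState":
        return cls({k: np.zeros_like(p) for k, p in params.items()},
                   learning_rate, rho, eps)


def rmsprop_step(
    params: dict[str, np.ndarray],
    grads: dict[str, np.ndarray],
    state: OptimizerState,
) -> None:
    """In-place RMSprop update: v <- rho v + (1-rho) g^2; theta -= lr g/sqrt(v+eps)."""
    for name, theta in params.items():
        g = grads[name]
        if not np.all(np.isfinite(g)):
            raise NumericalError(f"non-finite gradient in parameter group {name!r}")
        v = state.v[name]
        v *= state.rho
        v += (1.0 - state.rho) * g * g
        theta -= state.learning_rate * g / np.sqrt(v + state.eps)


@dataclass
class TrainingTrace:
    """Per-epoch root-mean-squared error of the fit (dropout disabled)."""

    rmse_per_epoch: list[float] = field(default_factory=list)
    seed: int = 0

    @property
    def epochs_run(self) -> int:
        return len(self.rmse_per_epoch)

    @property
    def final_rmse(self) -> float:
        if not self.rmse_per_epoch:
            raise ValueError("no epochs were run")
        return self.rmse_per_epoch[-1]

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("epoch\trmse\n")
            for e, r in enumerate(self.rmse_per_epoch, start=1):
                fh.write(f"{e}\t{r:.8g}\n")


def _example_blocks(
    model: CNNModel,
    encoding: SparseEncoding,
    peptide_idx: int,
    train: bool,
    rng: np.random.Generator | None,
    dense: bool,
    conv_weights: list[np.ndarray],
):
    """Forward one peptide, keeping per-block caches for backprop.

    Zero-input blocks are skipped on the sparse path; on the dense path they
    are computed (and provably contribute zero activations and gradients) but
    never consume dropout randomness, so both paths draw identical masks.
    """
    config = model.config
    blocks = []
    yhat = 0.0
    for j, prot in enumerate(encoding.layout.proteins):
        nonzero = j in encoding.positions[peptide_idx]
        if not (nonzero or dense):
            continue
        track = cnn._make_track(
            encoding, peptide_idx, j, config.padded_length(len(prot.sequence))
        )
        feats, caches = cnn._block_pass(
            conv_weights, config, track, train and nonzero, rng if nonzero else None
        )
        yhat += float(np.dot(model.output_weights[model.block_slice(j)], feats))
        blocks.append((j, feats, caches))
    return yhat, blocks


def _dropconnect_masks(model: CNNModel, rng: np.random.Generator) -> dict[str, np.ndarray]:
    q = 1.0 - model.config.dropout_rate
    return {
        name: (rng.random(p.shape) < q) / q
        for name, p in model.parameters().items()
    }


def train(
    model: CNNModel,
    encoding: SparseEncoding,
    targets=None,
    config: CNNConfig | None = None,
    dense: bool = False,
) -> tuple[CNNModel, TrainingTrace]:
    """Fit the model to the peptide probabilities; returns it with its trace.

    Peptides are visited in a seeded shuffled order each epoch, in
    mini-batches (``config.batch_size``; ``None`` means full batch).  Dropout
    is active only inside training passes; the per-epoch RMSE in the trace is
    measured with dropout disabled over the full profile.  ``dense=True``
    forces the dense gradient path (the oracle for the default sparse one).
    """
    if config is None:
        config = model.config
    if targets is None:
        targets = np.array([obs.probability for obs in encoding.peptides])
    targets = np.asarray(targets, dtype=float)
    n = encoding.n_peptides
    if len(targets) != n:
        raise ValueError("targets not aligned with the encoding")

    trace = TrainingTrace(seed=config.seed)
    if config.epochs == 0:
        return model, trace

    params = model.parameters()
    state = OptimizerState.for_params(
        params, config.learning_rate, config.rmsprop_rho, config.rmsprop_eps
    )
    shuffle_rng = np.random.default_rng([config.seed, 1])
    batch_size = config.batch_size or n

    for epoch in range(config.epochs):
        order = shuffle_rng.permutation(n)
        for start in range(0, n, batch_size):
            batch = order[start : start + batch_size]
            grads = {k: np.zeros_like(p) for k, p in params.items()}
            grads_conv = [grads[f"conv_{l}"] for l in range(config.n_layers)]
            for i in batch:
                i = int(i)
                ex_rng = np.random.default_rng([config.seed, 2, epoch, i])
                if config.dropconnect and config.dropout_rate > 0.0:
                    masks = _dropconnect_masks(model, ex_rng)
                    conv_w = [
                        model.conv_weights[l] * masks[f"conv_{l}"]
                        for l in range(config.n_layers)
                    ]
                    out_w = model.output_weights * masks["output"]
                else:
                    masks = None
                    conv_w = model.conv_weights
                    out_w = model.output_weights
                yhat, blocks = _example_blocks(
                    model, encoding, i, True, ex_rng, dense, conv_w
                )
                if masks is not None:
                    # recompute yhat against masked output weights
                    yhat = sum(
                        float(np.dot(out_w[model.block_slice(j)], feats))
                        for j, feats, _ in blocks
                    )
                dldy = -2.0 * (targets[i] - yhat)
                if not np.isfinite(dldy):
                    raise NumericalError(
                        f"non-finite loss gradient at epoch {epoch + 1}, "
                        f"peptide {i}"
                    )
                if masks is None:
                    ex_grads_conv = grads_conv
                    g_out = grads["output"]
                else:
                    ex_grads_conv = [np.zeros_like(W) for W in model.conv_weights]
                    g_out = np.zeros_like(model.output_weights)
                for j, feats, caches in blocks:
                    sl = model.block_slice(j)
                    g_out[sl] += dldy * feats
                    g_feats = dldy * out_w[sl]
                    cnn._block_backward(conv_w, config, caches, g_feats,
                                        ex_grads_conv)
                if masks is not None:
                    # chain rule through the per-example weight masks
                    for l in range(config.n_layers):
                        grads_conv[l] += ex_grads_conv[l] * masks[f"conv_{l}"]
                    grads["output"] += g_out * masks["output"]
            rmsprop_step(params, grads, state)

        preds = np.array([
            cnn.forward(model, encoding, i) for i in range(n)
        ])
        epoch_rmse = rmse(preds, targets)
        if not np.isfinite(epoch_rmse):
            raise NumericalError(f"non-finite RMSE at epoch {epoch + 1}")
        trace.rmse_per_epoch.append(epoch_rmse)
    return model, trace
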