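"""Bias-free convolutional network over per-protein binary tracks.

Architecture: for every candidate protein, the same stack of
(1-D valid convolution -> ReLU -> non-overlapping max-pool) blocks is applied
to that protein's binary match track; the pooled activations of the last
block, concatenated across proteins, feed a single linear output node that
predicts the peptide's identification probability.

Two structural constraints carry the whole method:

* **No bias term anywhere.**  An all-zero input track therefore produces
  exactly zero activations at every layer and contributes exactly zero to the
  output.  Peptide forward passes only need to touch the handful of proteins
  the peptide matches, and a protein's score contribution can be read off the
  cached penultimate representation (see :mod:`peptinfer.scoring`).
* **No window spans two proteins.**  Convolutions run per protein block, so
  the output decomposes additively over proteins.

Default configuration: four conv layers with 5/10/15/20 filters, convolution
window 4, max-pool window 2 (stride = window, remainder dropped).  Proteins
shorter than the minimum receptive length are right-padded with zeros, which
the bias-free stack maps to zeros.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .io_encoding import ProteomeLayout, SparseEncoding


class ConfigError(ValueError):
    """Invalid network or run configuration."""


@dataclass
class CNNConfig:
    """Hyperparameters of the network and its training run."""

    filters_per_layer: tuple[int, ...] = (5, 10, 15, 20)
    conv_windows: tuple[int, ...] = (4, 4, 4, 4)
    pool_windows: tuple[int, ...] = (2, 2, 2, 2)
    pool_kind: str = "max"
    dropout_rate: float = 0.2
    dropout_before_pool: bool = False
    dropconnect: bool = False
    learning_rate: float = 0.01
    epochs: int = 30
    batch_size: int | None = 32
    rmsprop_rho: float = 0.9
    rmsprop_eps: float = 1e-8
    seed: int = 0

    def __post_init__(self) -> None:
        self.filters_per_layer = tuple(int(f) for f in self.filters_per_layer)
        self.conv_windows = tuple(int(w) for w in self.conv_windows)
        self.pool_windows = tuple(int(w) for w in self.pool_windows)
        n = len(self.filters_per_layer)
        if n < 1:
            raise ConfigError("need at least one convolution layer")
        if len(self.conv_windows) != n or len(self.pool_windows) != n:
            raise ConfigError(
                "filters_per_layer, conv_windows and pool_windows must have "
                "equal length"
            )
        if any(f < 1 for f in self.filters_per_layer):
            raise ConfigError("filter counts must be positive")
        if list(self.filters_per_layer) != sorted(self.filters_per_layer):
            raise ConfigError("filter counts must be nondecreasing across layers")
        if any(w < 1 for w in self.conv_windows + self.pool_windows):
            raise ConfigError("all windows must be >= 1")
        if self.pool_kind != "max":
            raise ConfigError(f"unsupported pool_kind {self.pool_kind!r}")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ConfigError("dropout_rate must be in [0, 1)")
        if self.learning_rate <= 0:
            raise ConfigError("learning_rate must be positive")
        if self.epochs < 0:
            raise ConfigError("epochs must be nonnegative")
        if not 0.0 < self.rmsprop_rho < 1.0:
            raise ConfigError("rmsprop_rho must be in (0, 1)")

    @property
    def n_layers(self) -> int:
        return len(self.filters_per_layer)

    def min_receptive_length(self) -> int:
        """Shortest input track that still yields >= 1 penultimate position."""
        need = 1
        for w, p in zip(reversed(self.conv_windows), reversed(self.pool_windows)):
            need = need * p + w - 1
        return need

    def layer_lengths(self, input_length: int) -> list[int]:
        """Positions after each conv+pool block, for a (padded) track length."""
        cur = input_length
        out = []
        for w, p in zip(self.conv_windows, self.pool_windows):
            cur = cur - w + 1
            if cur < 1:
                raise ConfigError(
                    f"track length {input_length} too short for the window stack"
                )
            cur = cur // p
            out.append(cur)
        return out

    def padded_length(self, protein_length: int) -> int:
        return max(protein_length, self.min_receptive_length())

    def block_feature_length(self, protein_length: int) -> int:
        lens = self.layer_lengths(self.padded_length(protein_length))
        return lens[-1] * self.filters_per_layer[-1]

    def to_dict(self) -> dict:
        return asdict(self)


def conv_forward(x: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Valid 1-D convolution followed by ReLU.

    ``x`` has shape (positions, channels); ``weights`` has shape
    (filters, window, channels).  Output shape is
    (positions - window + 1, filters).
    """
    if x.ndim != 2 or weights.ndim != 3:
        raise ValueError("x must be 2-D and weights 3-D")
    if x.shape[1] != weights.shape[2]:
        raise ValueError(
            f"channel mismatch: input has {x.shape[1]}, weights expect "
            f"{weights.shape[2]}"
        )
    w = weights.shape[1]
    if x.shape[0] < w:
        raise ValueError("input shorter than the convolution window")
    windows = sliding_window_view(x, w, axis=0)  # (L-w+1, channels, w)
    z = np.tensordot(windows, weights, axes=((2, 1), (1, 2)))
    return np.maximum(z, 0.0)


def pool_forward(x: np.ndarray, window: int) -> np.ndarray:
    """Non-overlapping max-pool, stride = window, trailing remainder dropped.

    An input shorter than the window yields a zero-length output.
    """
    if window < 1:
        raise ValueError("pool window must be >= 1")
    n_out = x.shape[0] // window
    trimmed = x[: n_out * window].reshape(n_out, window, x.shape[1])
    return trimmed.max(axis=1)


def output_forward(penultimate: np.ndarray, output_weights: np.ndarray) -> float:
    """Linear output node: plain dot product, no activation, no clamping."""
    if penultimate.shape != output_weights.shape:
        raise ValueError(
            f"feature width {penultimate.shape} does not match output weights "
            f"{output_weights.shape}"
        )
    return float(np.dot(penultimate, output_weights))


class CNNModel:
    """Weights plus the proteome layout they were built against.

    ``conv_weights[l]`` has shape (filters_l, window_l, channels_{l-1}) and is
    shared across proteins; ``output_weights`` spans the concatenated
    penultimate features of all proteins, in layout order.
    """

    FORMAT_VERSION = 1

    def __init__(
        self,
        config: CNNConfig,
        layout: ProteomeLayout,
        conv_weights: list[np.ndarray],
        output_weights: np.ndarray,
    ):
        self.config = config
        self.layout = layout
        self.conv_weights = conv_weights
        self.output_weights = output_weights

    def block_slice(self, protein_idx: int) -> slice:
        off = int(self.layout.block_offsets[protein_idx])
        return slice(off, off + int(self.layout.block_lengths[protein_idx]))

    def parameters(self) -> dict[str, np.ndarray]:
        params = {f"conv_{l}": W for l, W in enumerate(self.conv_weights)}
        params["output"] = self.output_weights
        return params

    def copy(self) -> "CNNModel":
        return CNNModel(
            self.config,
            self.layout,
            [W.copy() for W in self.conv_weights],
            self.output_weights.copy(),
        )

    # -- persistence ------------------------------------------------------
    def save(self, path) -> None:
        arrays = {f"conv_{l}": W for l, W in enumerate(self.conv_weights)}
        arrays["output"] = self.output_weights
        meta = {
            "version": self.FORMAT_VERSION,
            "config": self.config.to_dict(),
            "layout_digest": layout_digest(self.layout),
            "n_layers": self.config.n_layers,
        }
        np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **arrays)

    @classmethod
    def load(cls, path, layout: ProteomeLayout) -> "CNNModel":
        with np.load(path) as data:
            meta = json.loads(bytes(data["meta"]))
            if meta["version"] != cls.FORMAT_VERSION:
                raise ValueError(f"unsupported checkpoint version {meta['version']}")
            config = CNNConfig(**{
                k: tuple(v) if isinstance(v, list) else v
                for k, v in meta["config"].items()
            })
            if meta["layout_digest"] != layout_digest(layout):
                raise ValueError("checkpoint layout does not match the given layout")
            conv = [data[f"conv_{l}"] for l in range(meta["n_layers"])]
            out = data["output"]
        model = cls(config, layout, conv, out)
        compute_blocks(layout, config)
        return model


def layout_digest(layout: ProteomeLayout) -> str:
    h = hashlib.sha256()
    for p in layout.proteins:
        h.update(p.id.encode())
        h.update(b"\x00")
        h.update(p.sequence.encode())
        h.update(b"\x01")
    return h.hexdigest()


def compute_blocks(layout: ProteomeLayout, config: CNNConfig) -> None:
    """Fill in the layout's per-protein penultimate feature-block geometry."""
    lengths = np.array(
        [config.block_feature_length(len(p.sequence)) for p in layout.proteins],
        dtype=np.intp,
    )
    offsets = np.concatenate([[0], np.cumsum(lengths)[:-1]]).astype(np.intp)
    layout.block_lengths = lengths
    layout.block_offsets = offsets


def build_model(config: CNNConfig, layout: ProteomeLayout, seed: int | None = None) -> CNNModel:
    """Initialize a model with seeded uniform(+-1/sqrt(fan-in)) weights."""
    if seed is None:
        seed = config.seed
    compute_blocks(layout, config)
    rng = np.random.default_rng(seed)
    conv_weights = []
    n_in = 1  # single binary match track per protein
    for nf, w in zip(config.filters_per_layer, config.conv_windows):
        bound = 1.0 / np.sqrt(w * n_in)
        conv_weights.append(rng.uniform(-bound, bound, size=(nf, w, n_in)))
        n_in = nf
    total = int(layout.block_lengths.sum())
    bound = 1.0 / np.sqrt(total)
    output_weights = rng.uniform(-bound, bound, size=total)
    return CNNModel(config, layout, conv_weights, output_weights)


# ---------------------------------------------------------------------------
# Per-block forward/backward with caches (internal engine)
# ---------------------------------------------------------------------------

def _block_pass(
    conv_weights: list[np.ndarray],
    config: CNNConfig,
    track: np.ndarray,
    train: bool,
    rng: np.random.Generator | None,
):
    """Run one protein track through the conv/pool stack.

    Returns (flattened penultimate features, caches).  In training mode a
    dropout mask (inverted scaling) is applied to each pooled activation map.
    """
    a = track[:, None]
    caches = []
    q = 1.0 - config.dropout_rate
    use_dropout = train and config.dropout_rate > 0.0 and not config.dropconnect
    before_pool = config.dropout_before_pool
    for W, pw in zip(conv_weights, config.pool_windows):
        w = W.shape[1]
        conv_len = a.shape[0] - w + 1
        windows = sliding_window_view(a, w, axis=0)
        z = np.tensordot(windows, W, axes=((2, 1), (1, 2)))
        relu_mask = z > 0
        h = np.where(relu_mask, z, 0.0)
        pre_mask = None
        if use_dropout and before_pool:
            pre_mask = (rng.random(h.shape) < q) / q
            h = h * pre_mask
        n_out = conv_len // pw
        trimmed = h[: n_out * pw].reshape(n_out, pw, h.shape[1])
        arg = trimmed.argmax(axis=1)
        pooled = np.take_along_axis(trimmed, arg[:, None, :], axis=1)[:, 0, :]
        if use_dropout and not before_pool:
            mask = (rng.random(pooled.shape) < q) / q
        else:
            mask = None
        caches.append((a, relu_mask, arg, mask, pre_mask, conv_len))
        a = pooled if mask is None else pooled * mask
    return a.reshape(-1), caches


def _block_backward(
    conv_weights: list[np.ndarray],
    config: CNNConfig,
    caches: list,
    g_feats: np.ndarray,
    grads_conv: list[np.ndarray],
) -> None:
    """Accumulate conv-weight gradients for one protein block.

    ``g_feats`` is the loss gradient w.r.t. the block's flattened penultimate
    features (after dropout).
    """
    g = g_feats
    for l in range(config.n_layers - 1, -1, -1):
        x_in, relu_mask, arg, mask, pre_mask, conv_len = caches[l]
        W = conv_weights[l]
        pw = config.pool_windows[l]
        nf = W.shape[0]
        g = g.reshape(-1, nf)
        if mask is not None:
            g = g * mask
        # un-pool: route gradient to the argmax row of each window
        n_out = g.shape[0]
        gh = np.zeros((conv_len, nf))
        if n_out:
            rows = np.arange(n_out)[:, None] * pw + arg
            gh[rows, np.arange(nf)[None, :]] = g
        if pre_mask is not None:
            gh = gh * pre_mask
        gz = np.where(relu_mask, gh, 0.0)
        w = W.shape[1]
        gx = np.zeros_like(x_in)
        gW = grads_conv[l]
        for j in range(w):
            seg = x_in[j : j + conv_len]
            gW[:, j, :] += gz.T @ seg
            gx[j : j + conv_len] += gz @ W[:, j, :]
        g = gx
    # gradient w.r.t. the binary input track is discarded


def _make_track(
    encoding: SparseEncoding, peptide_idx: int, protein_idx: int, padded_len: int
) -> np.ndarray:
    track = np.zeros(padded_len)
    pos = encoding.positions[peptide_idx].get(protein_idx)
    if pos is not None and len(pos):
        track[pos] = 1.0
    return track


def forward(
    model: CNNModel,
    encoding: SparseEncoding,
    peptide_idx: int,
    dense: bool = False,
) -> float:
    """Predicted probability for one peptide (dropout disabled).

    The sparse path visits only proteins the peptide matches; the dense path
    runs every protein block and serves as the oracle for the sparse one.
    """
    _check_layout(model, encoding)
    y = 0.0
    for j, feats in iter_block_features(model, encoding, peptide_idx, dense=dense):
        y += float(np.dot(model.output_weights[model.block_slice(j)], feats))
    return y


def iter_block_features(
    model: CNNModel,
    encoding: SparseEncoding,
    peptide_idx: int,
    dense: bool = False,
):
    """Yield (protein index, penultimate features) per processed block."""
    config = model.config
    for j, prot in enumerate(encoding.layout.proteins):
        nonzero = j in encoding.positions[peptide_idx]
        if not (nonzero or dense):
            continue
        track = _make_track(
            encoding, peptide_idx, j, config.padded_length(len(prot.sequence))
        )
        feats, _ = _block_pass(model.conv_weights, config, track, False, None)
        yield j, feats


def penultimate_features(
    model: CNNModel, encoding: SparseEncoding, peptide_idx: int
) -> dict[int, np.ndarray]:
    """Penultimate feature block per matching protein (zero blocks omitted —
    their features are exactly zero in a bias-free network)."""
    return dict(iter_block_features(model, encoding, peptide_idx))


def _check_layout(model: CNNModel, encoding: SparseEncoding) -> None:
    if encoding.layout is not model.layout and (
        layout_digest(encoding.layout) != layout_digest(model.layout)
    ):
        raise ValueError("encoding was built against a different layout")
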