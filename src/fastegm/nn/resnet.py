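"""1-D residual network (ResNet-18-style) for 5-s electrogram classification.

The network mirrors the standard 18-layer residual topology with 1-D
filters: a stride-2 stem convolution (kernel 7) with max pooling, four
stages of two residual blocks each (two 3-tap convolutions + batch
normalization per block, identity or 1x1-convolution shortcuts), global
average pooling, dropout, and a single fully connected output unit whose
logistic squashing yields the FaST probability.  Weights are
He-initialized; training uses Adam on binary cross-entropy.

Blocks are addressable by name (``stem``, ``stage1.block0`` ...
``stage4.block1``) so that forward activations and backward gradients at
any block can be probed for Grad-CAM importance traces.
"""

from __future__ import annotations

from collections import OrderedDict

import numpy as np

from .layers import (BatchNorm1d, Conv1d, Dense, Dropout, GlobalAvgPool,
                     Layer, MaxPool1d, Parameter, ReLU)

__all__ = ["BasicBlock", "Stem", "ResNet1d"]


class Stem(Layer):
    """Kernel-7 stride-2 convolution + BN + ReLU + 3/2 max pooling."""

    def __init__(self, out_channels: int, rng: np.random.Generator):
        self.conv = Conv1d(1, out_channels, kernel=7, stride=2, padding=3, rng=rng)
        self.bn = BatchNorm1d(out_channels)
        self.relu = ReLU()
        self.pool = MaxPool1d(3, 2, 1)
        self._seq = [self.conv, self.bn, self.relu, self.pool]

    def parameters(self) -> list[Parameter]:
        return [p for m in self._seq for p in m.parameters()]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for m in self._seq:
            x = m.forward(x, train)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for m in reversed(self._seq):
            grad = m.backward(grad)
        return grad


class BasicBlock(Layer):
    """Two 3-tap convolutions with BN and a residual connection."""

    def __init__(self, in_channels: int, out_channels: int, stride: int,
                 rng: np.random.Generator):
        self.conv1 = Conv1d(in_channels, out_channels, 3, stride=stride, rng=rng)
        self.bn1 = BatchNorm1d(out_channels)
        self.relu1 = ReLU()
        self.conv2 = Conv1d(out_channels, out_channels, 3, stride=1, rng=rng)
        self.bn2 = BatchNorm1d(out_channels)
        self.relu_out = ReLU()
        if stride != 1 or in_channels != out_channels:
            self.short_conv: Conv1d | None = Conv1d(
                in_channels, out_channels, 1, stride=stride, padding=0, rng=rng)
            self.short_bn: BatchNorm1d | None = BatchNorm1d(out_channels)
        else:
            self.short_conv = None
            self.short_bn = None

    def parameters(self) -> list[Parameter]:
        mods = [self.conv1, self.bn1, self.conv2, self.bn2]
        if self.short_conv is not None:
            mods += [self.short_conv, self.short_bn]
        return [p for m in mods for p in m.parameters()]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        y = self.conv1.forward(x, train)
        y = self.bn1.forward(y, train)
        y = self.relu1.forward(y, train)
        y = self.conv2.forward(y, train)
        y = self.bn2.forward(y, train)
        if self.short_conv is not None:
            s = self.short_bn.forward(self.short_conv.forward(x, train), train)
        else:
            s = x
        return self.relu_out.forward(y + s, train)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        grad = self.relu_out.backward(grad)
        g_main = self.bn2.backward(grad)
        g_main = self.conv2.backward(g_main)
        g_main = self.relu1.backward(g_main)
        g_main = self.bn1.backward(g_main)
        g_main = self.conv1.backward(g_main)
        if self.short_conv is not None:
            g_short = self.short_conv.backward(self.short_bn.backward(grad))
        else:
            g_short = grad
        return g_main + g_short


class ResNet1d:
    """The full classifier: stem, four residual stages, pooled logistic head.

    Parameters
    ----------
    input_length : int
        Samples per trace (1000 for a 5-s recording at 200 Hz).
    stage_channels, stage_blocks : sequences
        Channel width and block count per stage; the defaults give the
        standard 18-layer arrangement.  Quarter-width stages
        ``(16, 32, 64, 128)`` give the reduced model used in the scaled-down
        experiments.
    dropout_rate : float
        Dropout before the fully connected layer.
    seed : int
        Controls weight initialization (reproducible builds).
    """

    def __init__(self, input_length: int = 1000,
                 stage_channels: tuple[int, ...] = (64, 128, 256, 512),
                 stage_blocks: tuple[int, ...] = (2, 2, 2, 2),
                 dropout_rate: float = 0.2, seed: int = 0):
        if len(stage_channels) != len(stage_blocks):
            raise ValueError("stage_channels and stage_blocks lengths differ")
        rng = np.random.default_rng(seed)
        self.input_length = input_length
        self.stage_channels = tuple(stage_channels)
        self.stage_blocks = tuple(stage_blocks)
        self.blocks: OrderedDict[str, Layer] = OrderedDict()
        self.blocks["stem"] = Stem(stage_channels[0], rng)
        in_ch = stage_channels[0]
        for s, (ch, nb) in enumerate(zip(stage_channels, stage_blocks), start=1):
            for b in range(nb):
                stride = 2 if (b == 0 and s > 1) else 1
                self.blocks[f"stage{s}.block{b}"] = BasicBlock(in_ch, ch, stride, rng)
                in_ch = ch
        self.gap = GlobalAvgPool()
        self.dropout = Dropout(dropout_rate, rng=np.random.default_rng(seed + 1))
        self.fc = Dense(in_ch, 1, rng=rng)
        self._probe_activation: np.ndarray | None = None
        self._probe_gradient: np.ndarray | None = None
        self._probe_name: str | None = None

    # -- parameter access ---------------------------------------------------
    def parameters(self) -> list[Parameter]:
        params = [p for m in self.blocks.values() for p in m.parameters()]
        return params + self.fc.parameters()

    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.parameters()))

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    def state(self) -> list[np.ndarray]:
        arrays = [p.value.copy() for p in self.parameters()]
        for m in self._batchnorms():
            arrays += [m.running_mean.copy(), m.running_var.copy()]
        return arrays

    def load_state(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        for p, a in zip(params, arrays[:len(params)]):
            p.value[...] = a
        it = iter(arrays[len(params):])
        for m in self._batchnorms():
            m.running_mean[...] = next(it)
            m.running_var[...] = next(it)

    def _batchnorms(self) -> list[BatchNorm1d]:
        out = []
        for m in self.blocks.values():
            for attr in vars(m).values():
                if isinstance(attr, BatchNorm1d):
                    out.append(attr)
        return out

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False,
                probe: str | None = None) -> np.ndarray:
        """Return the logit for a batch shaped (B, input_length).

        With ``probe`` set to a block name, the activation at that block's
        output is stored for Grad-CAM; a subsequent :meth:`backward` stores
        the matching gradient.
        """
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 1:
            x = x[None, :]
        if x.shape[1] != self.input_length:
            raise ValueError(
                f"expected input length {self.input_length}, got {x.shape[1]}")
        if probe is not None and probe not in self.blocks:
            raise KeyError(f"unknown block {probe!r}; known: {list(self.blocks)}")
        h = x[:, None, :]
        self._probe_name = probe
        self._probe_activation = None
        self._probe_gradient = None
        for name, m in self.blocks.items():
            h = m.forward(h, train)
            if name == probe:
                self._probe_activation = h
        h = self.gap.forward(h, train)
        h = self.dropout.forward(h, train)
        logit = self.fc.forward(h, train)[:, 0]
        return logit

    def backward(self, dlogit: np.ndarray) -> None:
        """Backpropagate d(loss)/d(logit); fills parameter gradients and,
        when a probe was requested, the probe-layer gradient."""
        grad = self.fc.backward(np.asarray(dlogit, dtype=np.float64)[:, None])
        grad = self.dropout.backward(grad)
        grad = self.gap.backward(grad)
        for name, m in reversed(self.blocks.items()):
            if name == self._probe_name:
                self._probe_gradient = grad
            grad = m.backward(grad)
        return grad

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """FaST probabilities in (0, 1) for a batch of traces (eval mode)."""
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 1:
            x = x[None, :]
        out = []
        for i in range(0, len(x), batch_size):
            logit = self.forward(x[i:i + batch_size], train=False)
            out.append(1.0 / (1.0 + np.exp(-logit)))
        return np.concatenate(out)

    @property
    def probe_activation(self) -> np.ndarray | None:
        return self._probe_activation

    @property
    def probe_gradient(self) -> np.ndarray | None:
        return self._probe_gradient
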