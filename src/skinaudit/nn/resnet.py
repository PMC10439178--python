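"""An 18-layer residual convolutional network and its SGD trainer.

The topology is the standard 18-layer residual design: a 7x7 stride-2 stem
with batch norm and 3x3 stride-2 max pooling, four stages of two basic
blocks (64, 128, 256, 512 channels; stages 2-4 downsample by stride 2 with
a 1x1 projection shortcut), global average pooling and a fully connected
head.  With a 1000-way head the trainable parameter count is 11,689,512;
a 2-class head gives 11,177,538.

Implemented directly on NumPy: layers cache activations during the forward
pass and propagate gradients explicitly.  Training uses mini-batch SGD
with momentum on (optionally class-weighted) cross-entropy, with the
learning rate decaying linearly to zero across epochs.
"""

from __future__ import annotations

import numpy as np

from .layers import (BatchNorm2d, Conv2d, GlobalAvgPool, Linear, MaxPool2d,
                     Module, ReLU)

__all__ = ["ResNet18", "sgd_train", "softmax", "weighted_cross_entropy",
           "recalibrate_bn"]


class BasicBlock(Module):
    def __init__(self, cin: int, cout: int, stride: int, rng: np.random.Generator):
        super().__init__()
        self.conv1 = Conv2d(cin, cout, 3, stride, 1, rng)
        self.bn1 = BatchNorm2d(cout)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(cout, cout, 3, 1, 1, rng)
        self.bn2 = BatchNorm2d(cout)
        self.relu2 = ReLU()
        self.downsample = None
        if stride != 1 or cin != cout:
            self.ds_conv = Conv2d(cin, cout, 1, stride, 0, rng)
            self.ds_bn = BatchNorm2d(cout)
            self.downsample = (self.ds_conv, self.ds_bn)

    def modules(self):
        mods = [self.conv1, self.bn1, self.conv2, self.bn2]
        if self.downsample:
            mods += list(self.downsample)
        for m in mods:
            yield m

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        out = self.relu1.forward(self.bn1.forward(self.conv1.forward(x, train), train), train)
        out = self.bn2.forward(self.conv2.forward(out, train), train)
        if self.downsample:
            identity = self.ds_bn.forward(self.ds_conv.forward(x, train), train)
        else:
            identity = x
        return self.relu2.forward(out + identity, train)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        d = self.relu2.backward(dout)
        d_main = self.bn2.backward(d)
        d_main = self.conv2.backward(d_main)
        d_main = self.relu1.backward(d_main)
        d_main = self.bn1.backward(d_main)
        d_main = self.conv1.backward(d_main)
        if self.downsample:
            d_skip = self.ds_conv.backward(self.ds_bn.backward(d))
        else:
            d_skip = d
        return d_main + d_skip


class ResNet18(Module):
    """18-layer residual network with a configurable classification head.

    ``input_size`` only affects preprocessing (images are resized to
    input_size x input_size); the parameter count is independent of it
    thanks to global average pooling.
    """

    def __init__(self, num_classes: int = 1000, input_size: int = 224,
                 seed: int = 0):
        super().__init__()
        if num_classes < 2:
            raise ValueError("num_classes must be >= 2")
        rng = np.random.default_rng(seed)
        self.num_classes = num_classes
        self.input_size = input_size
        self.conv1 = Conv2d(3, 64, 7, 2, 3, rng)
        self.bn1 = BatchNorm2d(64)
        self.relu = ReLU()
        self.maxpool = MaxPool2d(3, 2, 1)
        cfg = [(64, 64, 1), (64, 128, 2), (128, 256, 2), (256, 512, 2)]
        self.stages: list[list[BasicBlock]] = []
        for cin, cout, stride in cfg:
            self.stages.append([BasicBlock(cin, cout, stride, rng),
                                BasicBlock(cout, cout, 1, rng)])
        self.avgpool = GlobalAvgPool()
        self.fc = Linear(512, num_classes, rng)

    def modules(self):
        yield self.conv1
        yield self.bn1
        for stage in self.stages:
            for block in stage:
                yield from block.modules()
        yield self.fc

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        out = self.relu.forward(self.bn1.forward(self.conv1.forward(x, train), train), train)
        out = self.maxpool.forward(out, train)
        for stage in self.stages:
            for block in stage:
                out = block.forward(out, train)
        out = self.avgpool.forward(out, train)
        return self.fc.forward(out, train)

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        d = self.fc.backward(dlogits)
        d = self.avgpool.backward(d)
        for stage in reversed(self.stages):
            for block in reversed(stage):
                d = block.backward(d)
        d = self.maxpool.backward(d)
        d = self.relu.backward(d)
        d = self.bn1.backward(d)
        return self.conv1.backward(d)

    # -- persistence helpers -------------------------------------------------

    def state_arrays(self) -> list[np.ndarray]:
        out = []
        for m in self.modules():
            for k in sorted(m.params):
                out.append(m.params[k])
            if isinstance(m, BatchNorm2d):
                out.extend([m.running_mean, m.running_var])
        return out

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        it = iter(arrays)
        try:
            for m in self.modules():
                for k in sorted(m.params):
                    a = np.asarray(next(it), dtype=np.float32)
                    if a.shape != m.params[k].shape:
                        raise ValueError(
                            f"weights incompatible with topology: expected "
                            f"{m.params[k].shape}, got {a.shape}")
                    m.params[k] = a
                if isinstance(m, BatchNorm2d):
                    m.running_mean = np.asarray(next(it), dtype=np.float32)
                    m.running_var = np.asarray(next(it), dtype=np.float32)
        except StopIteration:
            raise ValueError("weights incompatible with topology: too few arrays")


def recalibrate_bn(model: ResNet18, x: np.ndarray, batch_size: int = 32) -> None:
    """Replace batch-norm running statistics with exact averages over ``x``.

    After a short fine-tune the exponential running estimates lag behind
    the final weights; one forward sweep in cumulative-average mode fixes
    inference-mode predictions (the update_bn idea from stochastic weight
    averaging).  No parameters are modified.
    """
    bns = [m for m in model.modules() if isinstance(m, BatchNorm2d)]
    saved = [bn.momentum for bn in bns]
    for bn in bns:
        bn.reset_running_stats()
        bn.momentum = None
    for start in range(0, len(x), batch_size):
        model.forward(x[start:start + batch_size], train=True)
    for bn, mom in zip(bns, saved):
        bn.momentum = mom


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def weighted_cross_entropy(logits: np.ndarray, y: np.ndarray,
                           class_weights: np.ndarray | None = None
                           ) -> tuple[float, np.ndarray]:
    """Mean class-weighted cross-entropy and its gradient w.r.t. logits.

    Reduction is sum(w_y * ce) / sum(w_y), which collapses to the plain
    mean when all weights are equal.
    """
    n = logits.shape[0]
    p = softmax(logits.astype(np.float64))
    if class_weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(class_weights, dtype=np.float64)[y]
    wsum = w.sum()
    ce = -np.log(np.clip(p[np.arange(n), y], 1e-12, None))
    loss = float((w * ce).sum() / wsum)
    dlogits = p.copy()
    dlogits[np.arange(n), y] -= 1.0
    dlogits *= (w / wsum)[:, None]
    return loss, dlogits.astype(np.float32)


def sgd_train(model: ResNet18, x: np.ndarray, y: np.ndarray, *,
              epochs: int = 20, lr: float = 1e-3, batch_size: int = 32,
              class_weights: np.ndarray | None = None, momentum: float = 0.9,
              seed: int = 0) -> list[float]:
    """Mini-batch SGD with momentum and per-epoch linear LR decay.

    ``x`` is the preprocessed (N, 3, S, S) float32 tensor, ``y`` integer
    labels.  Returns the mean training loss per epoch.
    """
    if len(x) == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(seed)
    velocity = {id(m): {k: np.zeros_like(v) for k, v in m.params.items()}
                for m in model.modules()}
    history = []
    n = len(x)
    for epoch in range(epochs):
        lr_e = lr * (1.0 - epoch / epochs)
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            logits = model.forward(x[idx], train=True)
            loss, dlogits = weighted_cross_entropy(logits, y[idx], class_weights)
            model.backward(dlogits)
            for m in model.modules():
                vel = velocity[id(m)]
                for k, p in m.params.items():
                    g = m.grads.get(k)
                    if g is None:
                        continue
                    vel[k] = momentum * vel[k] - lr_e * g
                    m.params[k] = p + vel[k]
            losses.append(loss)
        history.append(float(np.mean(losses)))
    recalibrate_bn(model, x, batch_size)
    return history
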