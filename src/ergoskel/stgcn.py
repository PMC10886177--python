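"""A miniature spatial-temporal graph convolutional action classifier.

Pure-numpy implementation sized for desk-scale training on synthetic
sequences: two spatial graph-convolution blocks with residual connections,
followed by two spatial-temporal blocks with dense (concatenation)
connections, each convolution complemented by batch normalization and
ReLU; per-frame softmax over action labels. The graph convolution uses
the symmetrically normalized skeleton adjacency; the temporal convolution
has kernel 9 with zero padding. Gradients are analytic and checked
against finite differences in the test suite.

Layout convention: activations are ``(N, C, T, V)`` — batch, channels,
frames, keypoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .actions import ActionWeights
from .skeleton import SkeletonSequence
from .topology import BODY25, SkeletonTopology

HIDDEN = 32
TEMPORAL_KERNEL = 9


def normalized_adjacency(topology: SkeletonTopology = BODY25) -> np.ndarray:
    """Symmetrically normalized adjacency with self-loops, (V, V)."""
    V = max(topology.keypoint_ids) + 1
    A = np.eye(V)
    for p, c in topology.links:
        A[p, c] = A[c, p] = 1.0
    d = A.sum(axis=1)
    dinv = 1.0 / np.sqrt(d)
    return A * dinv[:, None] * dinv[None, :]


# --- layers ----------------------------------------------------------------


class _Layer:
    def params(self) -> list[tuple[np.ndarray, np.ndarray]]:
        """(parameter, gradient) pairs."""
        return []


class ChannelConv(_Layer):
    """1x1 convolution mixing channels: (N,C,T,V) -> (N,O,T,V)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.W = rng.normal(scale=np.sqrt(2.0 / c_in), size=(c_out, c_in))
        self.b = np.zeros(c_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return (
            np.einsum("oc,nctv->notv", self.W, x, optimize=True)
            + self.b[None, :, None, None]
        )

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.dW += np.einsum("notv,nctv->oc", dy, self._x, optimize=True)
        self.db += dy.sum(axis=(0, 2, 3))
        return np.einsum("oc,notv->nctv", self.W, dy, optimize=True)

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


class GraphConv(_Layer):
    """Neighborhood aggregation over the normalized adjacency + 1x1 mix."""

    def __init__(self, c_in: int, c_out: int, A: np.ndarray, rng):
        self.A = A
        self.conv = ChannelConv(c_in, c_out, rng)

    def forward(self, x: np.ndarray) -> np.ndarray:
        xa = np.einsum("nctv,vw->nctw", x, self.A, optimize=True)
        return self.conv.forward(xa)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dxa = self.conv.backward(dy)
        return np.einsum("nctw,vw->nctv", dxa, self.A, optimize=True)

    def params(self):
        return self.conv.params()


class TemporalConv(_Layer):
    """Convolution along the frame axis, kernel ``k``, zero 'same' padding."""

    def __init__(self, c_in: int, c_out: int, k: int, rng):
        assert k % 2 == 1, "temporal kernel must be odd"
        self.k = k
        self.W = rng.normal(scale=np.sqrt(2.0 / (c_in * k)), size=(c_out, c_in, k))
        self.b = np.zeros(c_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (0, 0)))
        self._win = np.lib.stride_tricks.sliding_window_view(xp, self.k, axis=2)
        return (
            np.einsum("nctvk,ock->notv", self._win, self.W, optimize=True)
            + self.b[None, :, None, None]
        )

    def backward(self, dy: np.ndarray) -> np.ndarray:
        p = self.k // 2
        self.dW += np.einsum("nctvk,notv->ock", self._win, dy, optimize=True)
        self.db += dy.sum(axis=(0, 2, 3))
        dyp = np.pad(dy, ((0, 0), (0, 0), (p, p), (0, 0)))
        dwin = np.lib.stride_tricks.sliding_window_view(dyp, self.k, axis=2)
        return np.einsum(
            "notvk,ock->nctv", dwin, self.W[:, :, ::-1], optimize=True
        )

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


class BatchNorm(_Layer):
    """Per-channel normalization over (N, T, V), with running statistics."""

    def __init__(self, c: int, eps: float = 1e-5, momentum: float = 0.9):
        self.gamma = np.ones(c)
        self.beta = np.zeros(c)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.eps = eps
        self.momentum = momentum
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        axes = (0, 2, 3)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mean
            )
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            )
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean[None, :, None, None]) / self._std[None, :, None, None]
        self._train = train
        return (
            self.gamma[None, :, None, None] * self._xhat
            + self.beta[None, :, None, None]
        )

    def backward(self, dy: np.ndarray) -> np.ndarray:
        axes = (0, 2, 3)
        self.dgamma += (dy * self._xhat).sum(axis=axes)
        self.dbeta += dy.sum(axis=axes)
        g = self.gamma[None, :, None, None] / self._std[None, :, None, None]
        if not self._train:
            return g * dy
        m_dy = dy.mean(axis=axes, keepdims=True)
        m_dyx = (dy * self._xhat).mean(axis=axes, keepdims=True)
        return g * (dy - m_dy - self._xhat * m_dyx)

    def params(self):
        return [(self.gamma, self.dgamma), (self.beta, self.dbeta)]


class ReLU(_Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class SpatialBlock(_Layer):
    """GraphConv + BN + ReLU with a residual connection."""

    def __init__(self, c_in: int, c_out: int, A: np.ndarray, rng):
        self.gc = GraphConv(c_in, c_out, A, rng)
        self.bn = BatchNorm(c_out)
        self.relu = ReLU()
        self.proj = ChannelConv(c_in, c_out, rng) if c_in != c_out else None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        h = self.bn.forward(self.gc.forward(x), train)
        res = self.proj.forward(x) if self.proj is not None else x
        return self.relu.forward(h + res)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        da = self.relu.backward(dy)
        dx = self.gc.backward(self.bn.backward(da))
        dx = dx + (self.proj.backward(da) if self.proj is not None else da)
        return dx

    def params(self):
        out = self.gc.params() + self.bn.params()
        if self.proj is not None:
            out += self.proj.params()
        return out


class SpatialTemporalBlock(_Layer):
    """Spatial then temporal convolution; output densely concatenated."""

    def __init__(self, c_in: int, c_out: int, A: np.ndarray, k: int, rng):
        self.c_in = c_in
        self.gc = GraphConv(c_in, c_out, A, rng)
        self.bn1 = BatchNorm(c_out)
        self.relu1 = ReLU()
        self.tc = TemporalConv(c_out, c_out, k, rng)
        self.bn2 = BatchNorm(c_out)
        self.relu2 = ReLU()

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        s = self.relu1.forward(self.bn1.forward(self.gc.forward(x), train))
        u = self.relu2.forward(self.bn2.forward(self.tc.forward(s), train))
        return np.concatenate([x, u], axis=1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx_direct, du = dy[:, : self.c_in], dy[:, self.c_in :]
        ds = self.tc.backward(self.bn2.backward(self.relu2.backward(du)))
        dx = self.gc.backward(self.bn1.backward(self.relu1.backward(ds)))
        return dx_direct + dx

    def params(self):
        return (
            self.gc.params()
            + self.bn1.params()
            + self.tc.params()
            + self.bn2.params()
        )


# --- network ---------------------------------------------------------------


class MiniSTGCN:
    """The full classifier: features (N,2,T,V) -> per-frame logits (N,L,T)."""

    def __init__(
        self,
        n_classes: int,
        labels: list[str],
        adjacency: np.ndarray | None = None,
        hidden: int = HIDDEN,
        temporal_kernel: int = TEMPORAL_KERNEL,
        seed: int = 0,
    ):
        if n_classes < 2:
            raise ValueError("need at least 2 action classes")
        A = normalized_adjacency() if adjacency is None else adjacency
        rng = np.random.default_rng(seed)
        self.labels = list(labels)
        self.temporal_kernel = temporal_kernel
        self.s1 = SpatialBlock(2, hidden, A, rng)
        self.s2 = SpatialBlock(hidden, hidden, A, rng)
        self.st1 = SpatialTemporalBlock(hidden, hidden, A, temporal_kernel, rng)
        self.st2 = SpatialTemporalBlock(2 * hidden, hidden, A, temporal_kernel, rng)
        self.head = ChannelConv(3 * hidden, n_classes, rng)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        h = self.s1.forward(x, train)
        h = self.s2.forward(h, train)
        h = self.st1.forward(h, train)
        h = self.st2.forward(h, train)
        self._V = x.shape[3]
        out = self.head.forward(h)  # (N, L, T, V)
        return out.mean(axis=3)  # pool keypoints -> per-frame logits

    def backward(self, dlogits: np.ndarray) -> None:
        d = np.broadcast_to(
            dlogits[:, :, :, None] / self._V,
            dlogits.shape + (self._V,),
        )
        d = self.head.backward(np.ascontiguousarray(d))
        d = self.st2.backward(d)
        d = self.st1.backward(d)
        d = self.s2.backward(d)
        self.s1.backward(d)

    def params(self):
        out = []
        for layer in (self.s1, self.s2, self.st1, self.st2, self.head):
            out += layer.params()
        return out

    def _bn_layers(self) -> list[BatchNorm]:
        return [
            self.s1.bn,
            self.s2.bn,
            self.st1.bn1,
            self.st1.bn2,
            self.st2.bn1,
            self.st2.bn2,
        ]

    def calibrate(self, X: np.ndarray) -> None:
        """Reset BN running statistics from one full pass over ``X``.

        Minibatch running averages lag the trained representation badly at
        desk scale (few optimizer steps); eval-mode inference needs exact
        dataset statistics.
        """
        saved = [(bn.momentum) for bn in self._bn_layers()]
        for bn in self._bn_layers():
            bn.momentum = 0.0
        self.forward(X, train=True)
        for bn, m in zip(self._bn_layers(), saved):
            bn.momentum = m

    def zero_grad(self) -> None:
        for _, g in self.params():
            g[...] = 0.0


def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def cross_entropy(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean per-frame cross-entropy and its gradient w.r.t. the logits.

    ``logits``: (N, L, T); ``targets``: (N, T) integer class ids.
    """
    p = softmax(logits, axis=1)
    N, L, T = logits.shape
    idx_n = np.arange(N)[:, None]
    idx_t = np.arange(T)[None, :]
    eps = 1e-12
    loss = float(-np.log(p[idx_n, targets, idx_t] + eps).mean())
    grad = p.copy()
    grad[idx_n, targets, idx_t] -= 1.0
    return loss, grad / (N * T)


class Adam:
    def __init__(self, params, lr: float = 1e-2, betas=(0.9, 0.999), eps=1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for i, (p, g) in enumerate(self.params):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# --- features and the public train/classify API ----------------------------


def sequence_features(seq: SkeletonSequence) -> np.ndarray:
    """Normalized (2, T, V) features: mid-hip centered, trunk-scaled."""
    data = seq.stacked()
    xy = data[:, :, :2]
    center = xy[:, 8:9, :]
    trunk = np.linalg.norm(xy[:, 1] - xy[:, 8], axis=1)
    scale = np.median(trunk)
    if scale <= 0:
        scale = 1.0
    feats = (xy - center) / scale
    return np.transpose(feats, (2, 0, 1))  # (2, T, V)


@dataclass
class TrainHistory:
    loss: list[float] = field(default_factory=list)
    accuracy: list[float] = field(default_factory=list)


def stgcn_train(
    sequences: list[SkeletonSequence],
    frame_labels: list[list[str]],
    epochs: int = 50,
    seed: int = 0,
    lr: float = 1e-2,
    batch_size: int = 8,
    target_accuracy: float = 0.99,
    hidden: int = HIDDEN,
) -> tuple[MiniSTGCN, TrainHistory]:
    """Train the classifier on equal-length labelled sequences.

    Deterministic under ``seed`` (initialization and shuffling). Stops
    early once per-frame training accuracy reaches ``target_accuracy``.

    Raises
    ------
    ValueError
        If fewer than two distinct action classes are present.
    """
    labels = sorted({lab for seq_labels in frame_labels for lab in seq_labels})
    if len(labels) < 2:
        raise ValueError("training data must contain at least 2 action classes")
    lab_to_idx = {lab: i for i, lab in enumerate(labels)}
    X = np.stack([sequence_features(s) for s in sequences])  # (N, 2, T, V)
    Y = np.array([[lab_to_idx[lab] for lab in ls] for ls in frame_labels])

    model = MiniSTGCN(len(labels), labels, hidden=hidden, seed=seed)
    opt = Adam(model.params(), lr=lr)
    rng = np.random.default_rng(seed + 1)
    history = TrainHistory()
    N = X.shape[0]
    for _ in range(epochs):
        order = rng.permutation(N)
        losses = []
        correct = total = 0
        for start in range(0, N, batch_size):
            idx = order[start : start + batch_size]
            logits = model.forward(X[idx], train=True)
            loss, dlogits = cross_entropy(logits, Y[idx])
            model.zero_grad()
            model.backward(dlogits)
            opt.step()
            losses.append(loss)
            pred = logits.argmax(axis=1)
            correct += int((pred == Y[idx]).sum())
            total += pred.size
        history.loss.append(float(np.mean(losses)))
        history.accuracy.append(correct / total)
        if history.accuracy[-1] >= target_accuracy:
            break
    model.calibrate(X)
    return model, history


def stgcn_classify(model: MiniSTGCN, seq: SkeletonSequence) -> list[ActionWeights]:
    """Per-frame normalized action weights for a sequence.

    Sequences shorter than the temporal receptive field are replicate-edge
    padded before the forward pass and the outputs cropped back.
    """
    feats = sequence_features(seq)
    T = feats.shape[1]
    pad = max(0, model.temporal_kernel - T)
    if pad:
        feats = np.pad(feats, ((0, 0), (0, pad), (0, 0)), mode="edge")
    logits = model.forward(feats[None], train=False)[0]  # (L, T')
    probs = softmax(logits, axis=0)[:, :T]
    return [
        ActionWeights(
            seq[t].frame_index,
            {lab: float(probs[i, t]) for i, lab in enumerate(model.labels)},
        )
        for t in range(T)
    ]
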