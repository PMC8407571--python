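"""Sparse feedforward and recurrent networks trained by SGD / BPTT.

Layers hold *unnormalised* weights ``v`` on an explicit boolean connection
mask; the forward pass uses the effective weights produced by the layer's
:class:`~dendronorm.normschemes.NormScheme` (or the raw ``v`` for the
unnormalised control).  Gradient descent therefore runs through the exact
chain rule of the normalisation and never creates or destroys connections —
only the evolutionary rewiring step (:mod:`dendronorm.set_rewiring`) changes
the mask.

The recurrent network is the binary-addition architecture: two input units
feeding a single hidden layer of ``M`` sigmoid units with sparse recurrent
connectivity and a single sigmoid output unit, trained by exact
backpropagation through time on each sequence with the hidden state reset
to zero at sequence boundaries.  Feedforward and recurrent afferents are
separate streams, each with its own norm and (when normalised) its own
trainable excitability scalar.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .normschemes import NormScheme, grad_matrix, normalise_matrix

__all__ = [
    "SparseLayer",
    "Network",
    "RecurrentNetwork",
    "TrainConfig",
    "init_sparse",
    "forward",
    "backward_sgd_step",
    "forward_recurrent",
    "bptt_step",
    "evaluate",
]

_ACTIVATIONS = ("sigmoid", "threshold_linear", "softmax")


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _activate(z: np.ndarray, kind: str) -> np.ndarray:
    if kind == "sigmoid":
        return sigmoid(z)
    if kind == "threshold_linear":
        return np.maximum(0.0, z)
    if kind == "softmax":
        z = z - z.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)
    raise ValueError(f"unknown activation {kind!r}")


@dataclass
class SparseLayer:
    """One sparse afferent weight structure (fan_in x M).

    ``v`` holds the unnormalised weights (zero off ``mask``), ``b`` the
    per-neuron biases.  ``scheme=None`` marks the unnormalised control, in
    which case ``v`` is used directly as the effective weight.
    """

    v: np.ndarray
    mask: np.ndarray
    b: np.ndarray
    scheme: NormScheme | None = None
    activation: str = "sigmoid"

    def __post_init__(self) -> None:
        if self.v.shape != self.mask.shape:
            raise ValueError("v and mask shapes differ")
        if self.b.shape != (self.v.shape[1],):
            raise ValueError("bias shape inconsistent with fan-out")
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")

    @property
    def fan_in(self) -> int:
        return self.v.shape[0]

    @property
    def m(self) -> int:
        return self.v.shape[1]

    @property
    def n(self) -> np.ndarray:
        """Per-neuron in-degree (the L0 norm of each afferent vector)."""
        return self.mask.sum(axis=0)

    def effective_weights(self) -> np.ndarray:
        return normalise_matrix(self.v, self.mask, self.scheme)

    def n_connections(self) -> int:
        return int(self.mask.sum())


@dataclass
class Network:
    """A stack of sparse layers; the last layer is the (softmax) readout."""

    layers: list[SparseLayer]
    cost: str = "log_likelihood"

    def __post_init__(self) -> None:
        if self.cost not in ("log_likelihood", "mse"):
            raise ValueError("cost must be 'log_likelihood' or 'mse'")
        for lo, hi in zip(self.layers, self.layers[1:]):
            if lo.m != hi.fan_in:
                raise ValueError("layer dimensions do not chain")


@dataclass
class TrainConfig:
    """Hyperparameters of SGD/BPTT training with SET rewiring."""

    eta: float = 0.05
    minibatch: int = 10
    epochs: int = 10
    seed: int = 0
    epsilon: float = 0.2
    zeta: float = 0.15

    def __post_init__(self) -> None:
        if self.eta <= 0:
            raise ValueError("eta must be positive")
        if self.minibatch < 1:
            raise ValueError("minibatch must be >= 1")
        if not 0 < self.epsilon <= 1:
            raise ValueError("epsilon must lie in (0, 1]")
        if not 0 <= self.zeta < 1:
            raise ValueError("zeta must lie in [0, 1)")


def init_sparse(
    fan_in: int,
    m: int,
    epsilon: float,
    rng: np.random.Generator,
    scheme: NormScheme | None = None,
    activation: str = "sigmoid",
) -> SparseLayer:
    """Erdős–Rényi sparse layer: each edge present with probability ε.

    Weights on existing connections are N(0, 1); biases start at zero.
    A neuron left with no afferents by the ER draw is given one uniformly
    random connection, since an empty afferent vector is degenerate for the
    dendritic normalisation.
    """
    if not 0 < epsilon <= 1:
        raise ValueError("epsilon must lie in (0, 1]")
    mask = rng.random((fan_in, m)) < epsilon
    for j in np.nonzero(mask.sum(axis=0) == 0)[0]:
        mask[rng.integers(fan_in), j] = True
    v = np.where(mask, rng.standard_normal((fan_in, m)), 0.0)
    return SparseLayer(v=v, mask=mask, b=np.zeros(m), scheme=scheme, activation=activation)


def forward(net: Network, batch: np.ndarray) -> list[np.ndarray]:
    """Activations per layer; ``[0]`` is the input batch itself."""
    a = np.asarray(batch, dtype=float)
    if a.ndim != 2 or a.shape[1] != net.layers[0].fan_in:
        raise ValueError("input dimension mismatch")
    acts = [a]
    for layer in net.layers:
        z = a @ layer.effective_weights() + layer.b
        a = _activate(z, layer.activation)
        acts.append(a)
    return acts


def _cost_value(net: Network, a_out: np.ndarray, y: np.ndarray) -> float:
    if net.cost == "log_likelihood":
        correct = np.clip(np.sum(a_out * y, axis=1), 1e-12, None)
        return float(-np.mean(np.log(correct)))
    return float(np.mean(np.sum((a_out - y) ** 2, axis=1)))


def _apply_updates(layer: SparseLayer, grad_w: np.ndarray, delta: np.ndarray, eta: float) -> None:
    gv, ge = grad_matrix(layer.v, layer.mask, layer.scheme, grad_w)
    layer.v -= eta * gv
    layer.b -= eta * delta.sum(axis=0)
    if layer.scheme is not None and ge is not None:
        if layer.scheme.excitability_mode == "constant":
            layer.scheme.s -= eta * float(ge.sum())
        else:
            layer.scheme.g = layer.scheme.excitability(layer.m) - eta * ge


def backward_sgd_step(net: Network, batch, config: TrainConfig) -> float:
    """One minibatch SGD step; returns the batch cost before the update.

    The minibatch gradient is the mean over samples.  Weight updates go to
    the unnormalised ``v`` through the scheme's exact chain rule; biases and
    excitability parameters are updated by the same learning rate; supports
    are untouched.
    """
    x, y = batch
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    acts = forward(net, x)
    a_out = acts[-1]
    cost = _cost_value(net, a_out, y)
    b = x.shape[0]

    out_layer = net.layers[-1]
    if net.cost == "log_likelihood":
        if out_layer.activation != "softmax":
            raise ValueError("log-likelihood cost requires a softmax output layer")
        delta = (a_out - y) / b
    else:
        if out_layer.activation == "softmax":
            raise ValueError("mse cost requires a sigmoid or linear output layer")
        delta = 2.0 * (a_out - y) / b
        if out_layer.activation == "sigmoid":
            delta = delta * a_out * (1.0 - a_out)
        else:
            delta = delta * (a_out > 0)

    weights = [layer.effective_weights() for layer in net.layers]
    deltas = [None] * len(net.layers)
    deltas[-1] = delta
    for idx in range(len(net.layers) - 1, 0, -1):
        a_prev = acts[idx]  # activation of layer idx-1
        upstream = deltas[idx] @ weights[idx].T
        if net.layers[idx - 1].activation == "sigmoid":
            deltas[idx - 1] = upstream * a_prev * (1.0 - a_prev)
        elif net.layers[idx - 1].activation == "threshold_linear":
            deltas[idx - 1] = upstream * (a_prev > 0)
        else:
            raise ValueError("softmax is only supported as the output activation")
    for idx, layer in enumerate(net.layers):
        grad_w = acts[idx].T @ deltas[idx]
        _apply_updates(layer, grad_w, deltas[idx], config.eta)
    return cost


@dataclass
class RecurrentNetwork:
    """Two input units, a recurrently connected hidden layer, one readout.

    ``w_in``/``mask_in`` hold the feedforward stream (dense when every mask
    entry is True), ``rec`` the recurrent stream; each stream has its own
    normalisation scheme (or None for the control).  The readout is a dense
    sigmoid unit.
    """

    w_in: np.ndarray
    mask_in: np.ndarray
    rec: SparseLayer
    w_out: np.ndarray
    b_out: float
    b_h: np.ndarray
    scheme_in: NormScheme | None = None
    allow_self: bool = True
    input_is_sparse: bool = False

    @property
    def m(self) -> int:
        return self.rec.m

    @property
    def dense_input(self) -> bool:
        return not self.input_is_sparse

    def input_weights(self) -> np.ndarray:
        return normalise_matrix(self.w_in, self.mask_in, self.scheme_in)

    @classmethod
    def create(
        cls,
        m: int,
        epsilon: float,
        rng: np.random.Generator,
        normalised: bool = False,
        sparse_input: bool = False,
        allow_self: bool = True,
    ) -> "RecurrentNetwork":
        """Binary-addition network: ER recurrent mask, optional sparse input.

        With ``normalised=True`` each sparse stream gets its own dendritic
        ({0}) scheme with an independently trained shared excitability.
        """
        rec = init_sparse(m, m, epsilon, rng,
                          scheme=NormScheme(frozenset({0}), "constant") if normalised else None)
        if not allow_self:
            np.fill_diagonal(rec.mask, False)
            np.fill_diagonal(rec.v, 0.0)
        if sparse_input:
            mask_in = rng.random((2, m)) < epsilon
            scheme_in = NormScheme(frozenset({0}), "constant") if normalised else None
        else:
            mask_in = np.ones((2, m), dtype=bool)
            scheme_in = None
        w_in = np.where(mask_in, rng.standard_normal((2, m)), 0.0)
        return cls(
            w_in=w_in,
            mask_in=mask_in,
            rec=rec,
            w_out=rng.standard_normal(m) / np.sqrt(m),
            b_out=0.0,
            b_h=np.zeros(m),
            scheme_in=scheme_in,
            allow_self=allow_self,
            input_is_sparse=sparse_input,
        )


class _InputStream:
    """View of the feedforward stream as a rewireable layer-like object."""

    def __init__(self, rnet: "RecurrentNetwork") -> None:
        self._rnet = rnet

    @property
    def v(self) -> np.ndarray:
        return self._rnet.w_in

    @property
    def mask(self) -> np.ndarray:
        return self._rnet.mask_in

    def effective_weights(self) -> np.ndarray:
        return self._rnet.input_weights()


def input_stream(rnet: RecurrentNetwork) -> _InputStream:
    """The feedforward stream of a recurrent net, for joint-pool rewiring."""
    return _InputStream(rnet)


def forward_recurrent(rnet: RecurrentNetwork, batch: np.ndarray):
    """Run sequences through the recurrent net.

    ``batch`` is (B, m, 2) — two input bits per timestep, least significant
    first.  Returns ``(outputs, hidden)`` with outputs (B, m) and hidden
    activations (B, m, M).  The hidden state starts at zero.
    """
    x = np.asarray(batch, dtype=float)
    if x.ndim != 3 or x.shape[2] != 2:
        raise ValueError("batch must have shape (B, seq_len, 2)")
    b, m_seq, _ = x.shape
    w_in = rnet.input_weights()
    w_rec = rnet.rec.effective_weights()
    h = np.zeros((b, rnet.m))
    hidden = np.empty((b, m_seq, rnet.m))
    out = np.empty((b, m_seq))
    for t in range(m_seq):
        z = rnet.b_h + x[:, t, :] @ w_in + h @ w_rec
        h = sigmoid(z)
        hidden[:, t, :] = h
        out[:, t] = sigmoid(h @ rnet.w_out + rnet.b_out)
    return out, hidden


def bptt_step(rnet: RecurrentNetwork, batch, config: TrainConfig) -> float:
    """Exact backpropagation through time on one minibatch of sequences.

    The cost is the sequence-averaged squared error of the raw sigmoid
    output (mean over the minibatch); gradients flow through both weight
    streams' normalisations.  Returns the batch cost before the update.
    """
    x, y = batch
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    b, m_seq, _ = x.shape
    out, hidden = forward_recurrent(rnet, x)
    cost = float(np.mean(np.mean((out - y) ** 2, axis=1)))

    w_in = rnet.input_weights()
    w_rec = rnet.rec.effective_weights()
    # gradients accumulate over timesteps (the sequence cost is reported as
    # the per-step mean, but BPTT sums the per-step gradients; the batch
    # gradient is the mean over sequences)
    scale = 2.0 / b

    grad_w_out = np.zeros_like(rnet.w_out)
    grad_b_out = 0.0
    grad_win = np.zeros_like(rnet.w_in)
    grad_wrec = np.zeros_like(rnet.rec.v)
    grad_bh = np.zeros_like(rnet.b_h)

    carry = np.zeros((b, rnet.m))  # dC/dh_t contribution from t+1
    for t in range(m_seq - 1, -1, -1):
        h_t = hidden[:, t, :]
        d_out = scale * (out[:, t] - y[:, t]) * out[:, t] * (1.0 - out[:, t])
        grad_w_out += h_t.T @ d_out
        grad_b_out += float(d_out.sum())
        dh = d_out[:, None] * rnet.w_out[None, :] + carry
        dz = dh * h_t * (1.0 - h_t)
        grad_bh += dz.sum(axis=0)
        grad_win += x[:, t, :].T @ dz
        h_prev = hidden[:, t - 1, :] if t > 0 else np.zeros((b, rnet.m))
        grad_wrec += h_prev.T @ dz
        carry = dz @ w_rec.T

    eta = config.eta
    gv, ge = grad_matrix(rnet.w_in, rnet.mask_in, rnet.scheme_in, grad_win)
    rnet.w_in -= eta * gv
    if rnet.scheme_in is not None and ge is not None:
        if rnet.scheme_in.excitability_mode == "constant":
            rnet.scheme_in.s -= eta * float(ge.sum())
        else:
            rnet.scheme_in.g = rnet.scheme_in.excitability(rnet.m) - eta * ge
    gv, ge = grad_matrix(rnet.rec.v, rnet.rec.mask, rnet.rec.scheme, grad_wrec)
    rnet.rec.v -= eta * gv
    if rnet.rec.scheme is not None and ge is not None:
        if rnet.rec.scheme.excitability_mode == "constant":
            rnet.rec.scheme.s -= eta * float(ge.sum())
        else:
            rnet.rec.scheme.g = rnet.rec.scheme.excitability(rnet.m) - eta * ge
    rnet.b_h -= eta * grad_bh
    rnet.w_out -= eta * grad_w_out
    rnet.b_out -= eta * grad_b_out
    return cost


def evaluate(net, dataset) -> tuple[float, float]:
    """Mean cost and accuracy on a labelled dataset.

    Feedforward networks score argmax classification accuracy; recurrent
    networks score a sequence as correct only if every rounded output bit
    matches the target sum.
    """
    x, y = dataset
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape[0] == 0:
        raise ValueError("empty dataset")
    if isinstance(net, RecurrentNetwork):
        out, _ = forward_recurrent(net, x)
        cost = float(np.mean(np.mean((out - y) ** 2, axis=1)))
        acc = float(np.mean(np.all(np.rint(out) == y, axis=1)))
        return cost, acc
    a_out = forward(net, x)[-1]
    cost = _cost_value(net, a_out, y)
    acc = float(np.mean(np.argmax(a_out, axis=1) == np.argmax(y, axis=1)))
    return cost, acc
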