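"""Neural layers used by the spectrum predictor.

Built directly on :mod:`glycospec.nn.autograd`: dense layers, (bi)LSTM
stacks over sequences, a child-sum tree LSTM over glycan trees, attention
pooling, and an Adam optimizer with support for frozen parameter groups.
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor

__all__ = [
    "Dense",
    "LSTM",
    "BiLSTMStack",
    "ChildSumTreeLSTM",
    "AttentionPool",
    "Adam",
]


def _init(rng: np.random.Generator, shape, fan_in: int) -> Tensor:
    bound = 1.0 / np.sqrt(fan_in)
    return Tensor(rng.uniform(-bound, bound, size=shape))


class Dense:
    def __init__(self, rng: np.random.Generator, d_in: int, d_out: int):
        self.W = _init(rng, (d_in, d_out), d_in)
        self.b = Tensor(np.zeros(d_out))

    def __call__(self, x: Tensor) -> Tensor:
        return ag.affine(x, self.W, self.b)

    def params(self, prefix: str) -> dict[str, Tensor]:
        return {f"{prefix}.W": self.W, f"{prefix}.b": self.b}


class LSTM:
    """Unidirectional LSTM; gate layout [i, f, g, o], forget bias +1.

    Input and recurrent projections are kept separate so a whole layer pass
    can run as one fused op (:func:`glycospec.nn.autograd.lstm_seq`).
    """

    def __init__(self, rng: np.random.Generator, d_in: int, hidden: int):
        self.hidden = hidden
        fan = d_in + hidden
        self.W_x = _init(rng, (d_in, 4 * hidden), fan)
        self.W_h = _init(rng, (hidden, 4 * hidden), fan)
        b = np.zeros(4 * hidden)
        b[hidden : 2 * hidden] = 1.0
        self.b = Tensor(b)

    def step(self, x_t: Tensor, h: Tensor, c: Tensor) -> tuple[Tensor, Tensor]:
        pre = ag.add(ag.affine(x_t, self.W_x, self.b), ag.matmul(h, self.W_h))
        return ag.lstm_step(pre, c)

    def run(self, xs: Tensor, reverse: bool = False) -> tuple[Tensor, Tensor]:
        """Run over an (L, d_in) sequence; returns ((L, h) outputs, final h)."""
        L = xs.data.shape[0]
        xW = ag.affine(xs, self.W_x, self.b)
        H = ag.lstm_seq(xW, self.W_h, reverse=reverse)
        final = ag.row(H, 0 if reverse else L - 1)
        return H, final

    def run_batch_steps(self, step_inputs: list[Tensor]) -> tuple[list[Tensor], Tensor]:
        """Run a batch of equal-length step inputs; each (B, d_in)."""
        B = step_inputs[0].data.shape[0]
        h = Tensor(np.zeros((B, self.hidden)))
        c = Tensor(np.zeros((B, self.hidden)))
        outs = []
        for x_t in step_inputs:
            h, c = self.step(x_t, h, c)
            outs.append(h)
        return outs, h

    def params(self, prefix: str) -> dict[str, Tensor]:
        return {
            f"{prefix}.W_x": self.W_x,
            f"{prefix}.W_h": self.W_h,
            f"{prefix}.b": self.b,
        }


class BiLSTMStack:
    """Stacked bidirectional LSTM layers; output width 2*hidden."""

    def __init__(self, rng, d_in: int, hidden: int, n_layers: int):
        self.layers: list[tuple[LSTM, LSTM]] = []
        d = d_in
        for _ in range(n_layers):
            self.layers.append((LSTM(rng, d, hidden), LSTM(rng, d, hidden)))
            d = 2 * hidden

    def run(self, xs: Tensor) -> tuple[Tensor, Tensor]:
        """Returns ((L, 2h) outputs of the last layer, (1, 2h) final states)."""
        out = xs
        final = None
        for fwd, bwd in self.layers:
            of, hf = fwd.run(out, reverse=False)
            ob, hb = bwd.run(out, reverse=True)
            out = ag.concat_cols([of, ob])
            final = ag.concat_cols([hf, hb])
        return out, final

    def params(self, prefix: str) -> dict[str, Tensor]:
        out: dict[str, Tensor] = {}
        for i, (fwd, bwd) in enumerate(self.layers):
            out.update(fwd.params(f"{prefix}.l{i}.fwd"))
            out.update(bwd.params(f"{prefix}.l{i}.bwd"))
        return out


class ChildSumTreeLSTM:
    """Child-sum tree LSTM cell applied along a traversal of a tree.

    Predecessor hidden states are summed (i, o, u gates) while each
    predecessor keeps its own forget gate, so the update is invariant to the
    order of children.  The same cell serves bottom-up (predecessors =
    children) and top-down (single predecessor = parent) traversals.
    """

    def __init__(self, rng, d_in: int, hidden: int):
        self.hidden = hidden
        self.W_iou = _init(rng, (d_in, 3 * hidden), d_in)
        self.U_iou = _init(rng, (hidden, 3 * hidden), hidden)
        self.b_iou = Tensor(np.zeros(3 * hidden))
        self.W_f = _init(rng, (d_in, hidden), d_in)
        self.U_f = _init(rng, (hidden, hidden), hidden)
        self.b_f = Tensor(np.ones(hidden))

    def run(
        self,
        x_nodes: Tensor,
        order: list[int],
        preds: dict[int, list[int]],
    ) -> Tensor:
        """Traverse nodes in ``order`` (predecessors first).

        ``x_nodes`` is (n, d_in); ``preds[v]`` lists the predecessor node ids
        of ``v``.  Returns the (n, hidden) matrix of hidden states.
        """
        x_iou = ag.affine(x_nodes, self.W_iou, self.b_iou)
        x_f = ag.affine(x_nodes, self.W_f, self.b_f)
        return ag.childsum_tree(x_iou, x_f, self.U_iou, self.U_f, order, preds)

    def params(self, prefix: str) -> dict[str, Tensor]:
        return {
            f"{prefix}.W_iou": self.W_iou,
            f"{prefix}.U_iou": self.U_iou,
            f"{prefix}.b_iou": self.b_iou,
            f"{prefix}.W_f": self.W_f,
            f"{prefix}.U_f": self.U_f,
            f"{prefix}.b_f": self.b_f,
        }


class AttentionPool:
    """Softmax attention over rows: dense scores, weighted sum of features."""

    def __init__(self, rng, d_in: int):
        self.score = Dense(rng, d_in, 1)

    def __call__(self, feats: Tensor) -> tuple[Tensor, np.ndarray]:
        """Returns ((1, d_in) pooled vector, attention weights as ndarray)."""
        w = ag.softmax_rows0(self.score(feats))
        pooled = ag.matmul(ag.transpose(w), feats)
        return pooled, w.data.ravel().copy()

    def params(self, prefix: str) -> dict[str, Tensor]:
        return self.score.params(f"{prefix}.score")


class Adam:
    """Adam over a named parameter dict; frozen names are never updated."""

    def __init__(
        self,
        params: dict[str, Tensor],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        frozen: set[str] | frozenset[str] = frozenset(),
    ):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.frozen = set(frozen)
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self, lr: float | None = None) -> None:
        if lr is None:
            lr = self.lr
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for k, p in self.params.items():
            if k in self.frozen or p.grad is None:
                continue
            g = p.grad
            m = self.m[k]
            v = self.v[k]
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.data -= lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
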