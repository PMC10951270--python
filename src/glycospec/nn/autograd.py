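"""Tape-based reverse-mode automatic differentiation on numpy arrays.

A deliberately small engine sized for this package's recurrent/tree-recurrent
models: tensors wrap float64 ndarrays, ops record backward closures on an
explicit :class:`Tape`, and a fused LSTM-gate op keeps the per-timestep op
count low.  When no tape is active (inference), ops run without recording.

Conventions: matrices are 2-D with rows = positions/batch items; scalars are
0-d arrays.  Gradients accumulate in ``Tensor.grad`` (lazily allocated).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Tape", "tensor"]


class Tensor:
    __slots__ = ("data", "grad")

    def __init__(self, data):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):
        return f"Tensor(shape={self.data.shape})"


def tensor(data) -> Tensor:
    return Tensor(data)


class Tape:
    """Records backward closures in execution order."""

    _active: "Tape | None" = None

    def __init__(self):
        self.ops: list = []

    def __enter__(self):
        self._prev = Tape._active
        Tape._active = self
        return self

    def __exit__(self, *exc):
        Tape._active = self._prev
        return False

    def backward(self, loss: Tensor, grad=None):
        loss.grad = np.asarray(1.0 if grad is None else grad, dtype=np.float64)
        for fn in reversed(self.ops):
            fn()


def _rec(fn):
    t = Tape._active
    if t is not None:
        t.ops.append(fn)


def _accum(t: Tensor, g):
    if t.grad is None:
        t.grad = np.array(g, dtype=np.float64)
    else:
        t.grad += g


def _unbroadcast(g: np.ndarray, shape) -> np.ndarray:
    """Reduce gradient ``g`` to ``shape`` by summing broadcast axes."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g.reshape(shape)


# ---------------------------------------------------------------------------
# elementwise arithmetic (numpy broadcasting, gradients unbroadcast)


def add(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data + b.data)

    def bw():
        if out.grad is None:
            return
        _accum(a, _unbroadcast(out.grad, a.data.shape))
        _accum(b, _unbroadcast(out.grad, b.data.shape))

    _rec(bw)
    return out


def sub(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data - b.data)

    def bw():
        if out.grad is None:
            return
        _accum(a, _unbroadcast(out.grad, a.data.shape))
        _accum(b, _unbroadcast(-out.grad, b.data.shape))

    _rec(bw)
    return out


def mul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data * b.data)

    def bw():
        if out.grad is None:
            return
        _accum(a, _unbroadcast(out.grad * b.data, a.data.shape))
        _accum(b, _unbroadcast(out.grad * a.data, b.data.shape))

    _rec(bw)
    return out


def div(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data / b.data)

    def bw():
        if out.grad is None:
            return
        _accum(a, _unbroadcast(out.grad / b.data, a.data.shape))
        _accum(b, _unbroadcast(-out.grad * a.data / b.data**2, b.data.shape))

    _rec(bw)
    return out


def scale(a: Tensor, c: float) -> Tensor:
    out = Tensor(a.data * c)

    def bw():
        if out.grad is None:
            return
        _accum(a, out.grad * c)

    _rec(bw)
    return out


def add_const(a: Tensor, c: float) -> Tensor:
    out = Tensor(a.data + c)

    def bw():
        if out.grad is None:
            return
        _accum(a, out.grad)

    _rec(bw)
    return out


def rsub_const(c: float, a: Tensor) -> Tensor:
    """c - a."""
    out = Tensor(c - a.data)

    def bw():
        if out.grad is None:
            return
        _accum(a, -out.grad)

    _rec(bw)
    return out


# ---------------------------------------------------------------------------
# linear algebra / shape


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data @ b.data)

    def bw():
        if out.grad is None:
            return
        _accum(a, out.grad @ b.data.T)
        _accum(b, a.data.T @ out.grad)

    _rec(bw)
    return out


def affine(x: Tensor, W: Tensor, b: Tensor) -> Tensor:
    """x @ W + b  (x: (n, d_in), W: (d_in, d_out), b: (d_out,))."""
    out = Tensor(x.data @ W.data + b.data)

    def bw():
        if out.grad is None:
            return
        _accum(x, out.grad @ W.data.T)
        _accum(W, x.data.T @ out.grad)
        _accum(b, out.grad.sum(axis=0))

    _rec(bw)
    return out


def concat_cols(tensors: list[Tensor]) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=1))
    widths = [t.data.shape[1] for t in tensors]

    def bw():
        if out.grad is None:
            return
        o = 0
        for t, w in zip(tensors, widths):
            _accum(t, out.grad[:, o : o + w])
            o += w

    _rec(bw)
    return out


def concat_rows(tensors: list[Tensor]) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=0))
    heights = [t.data.shape[0] for t in tensors]

    def bw():
        if out.grad is None:
            return
        o = 0
        for t, h in zip(tensors, heights):
            _accum(t, out.grad[o : o + h])
            o += h

    _rec(bw)
    return out


def rows(a: Tensor, idx) -> Tensor:
    idx = np.asarray(idx, dtype=int)
    out = Tensor(a.data[idx])

    def bw():
        if out.grad is None:
            return
        if a.grad is None:
            a.grad = np.zeros_like(a.data)
        np.add.at(a.grad, idx, out.grad)

    _rec(bw)
    return out


def reshape(a: Tensor, shape) -> Tensor:
    out = Tensor(a.data.reshape(shape))

    def bw():
        if out.grad is None:
            return
        _accum(a, out.grad.reshape(a.data.shape))

    _rec(bw)
    return out


def sum_rows(a: Tensor) -> Tensor:
    """Sum over rows -> (1, d)."""
    out = Tensor(a.data.sum(axis=0, keepdims=True))

    def bw():
        if out.grad is None:
            return
        _accum(a, np.broadcast_to(out.grad, a.data.shape))

    _rec(bw)
    return out


def sum_all(a: Tensor) -> Tensor:
    out = Tensor(a.data.sum())

    def bw():
        if out.grad is None:
            return
        _accum(a, np.broadcast_to(out.grad, a.data.shape))

    _rec(bw)
    return out


# ---------------------------------------------------------------------------
# nonlinearities


def relu(a: Tensor) -> Tensor:
    out = Tensor(np.maximum(a.data, 0.0))

    def bw():
        if out.grad is None:
            return
        _accum(a, out.grad * (a.data > 0))

    _rec(bw)
    return out


def sigmoid(a: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-a.data))
    out = Tensor(s)

    def bw():
        if out.grad is None:
            return
        _accum(a, out.grad * s * (1.0 - s))

    _rec(bw)
    return out


def tanh(a: Tensor) -> Tensor:
    t = np.tanh(a.data)
    out = Tensor(t)

    def bw():
        if out.grad is None:
            return
        _accum(a, out.grad * (1.0 - t * t))

    _rec(bw)
    return out


def softmax_rows0(a: Tensor) -> Tensor:
    """Softmax over axis 0 of an (n, 1) score column."""
    z = a.data - a.data.max(axis=0, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=0, keepdims=True)
    out = Tensor(s)

    def bw():
        if out.grad is None:
            return
        g = out.grad
        _accum(a, s * (g - (g * s).sum(axis=0, keepdims=True)))

    _rec(bw)
    return out


def dropout(a: Tensor, p: float, rng: np.random.Generator) -> Tensor:
    """Inverted dropout; call only in training mode."""
    if p <= 0:
        return a
    mask = (rng.random(a.data.shape) >= p) / (1.0 - p)
    out = Tensor(a.data * mask)

    def bw():
        if out.grad is None:
            return
        _accum(a, out.grad * mask)

    _rec(bw)
    return out


# ---------------------------------------------------------------------------
# fused recurrent / loss ops


def lstm_step(pre: Tensor, c_prev: Tensor) -> tuple[Tensor, Tensor]:
    """One LSTM cell step from gate pre-activations.

    ``pre`` is (B, 4h) laid out as [i, f, g, o]; ``c_prev`` is (B, h).
    Returns (h, c).  Both outputs feed gradients back through one closure.
    """
    B, four_h = pre.data.shape
    h = four_h // 4
    i = 1.0 / (1.0 + np.exp(-pre.data[:, :h]))
    f = 1.0 / (1.0 + np.exp(-pre.data[:, h : 2 * h]))
    g = np.tanh(pre.data[:, 2 * h : 3 * h])
    o = 1.0 / (1.0 + np.exp(-pre.data[:, 3 * h :]))
    c = f * c_prev.data + i * g
    tc = np.tanh(c)
    h_out = Tensor(o * tc)
    c_out = Tensor(c)

    def bw():
        gh = h_out.grad
        gc = c_out.grad
        if gh is None and gc is None:
            return
        dc = np.zeros_like(c)
        if gc is not None:
            dc += gc
        if gh is not None:
            do = gh * tc
            dc += gh * o * (1.0 - tc * tc)
        else:
            do = np.zeros_like(o)
        di = dc * g
        df = dc * c_prev.data
        dg = dc * i
        gpre = np.empty_like(pre.data)
        gpre[:, :h] = di * i * (1.0 - i)
        gpre[:, h : 2 * h] = df * f * (1.0 - f)
        gpre[:, 2 * h : 3 * h] = dg * (1.0 - g * g)
        gpre[:, 3 * h :] = do * o * (1.0 - o)
        _accum(pre, gpre)
        _accum(c_prev, dc * f)

    _rec(bw)
    return h_out, c_out


def spectral_angle_loss(pred: Tensor, target: np.ndarray, eps: float = 1e-9) -> Tensor:
    """SA = (2/pi) arccos(cosine(pred, target)) with analytic gradient.

    ``target`` is a constant non-negative vector with positive norm; ``pred``
    is a 1-D tensor.  The cosine is clipped away from ±1 for a finite
    gradient at perfect similarity.
    """
    t = np.asarray(target, dtype=np.float64).ravel()
    p = pred.data.ravel()
    nt = np.linalg.norm(t)
    np_ = np.linalg.norm(p)
    if nt <= 0:
        raise ValueError("target vector has zero norm")
    if np_ <= eps:
        np_ = eps
    cos = float(np.dot(p, t) / (np_ * nt))
    cos_c = min(1.0 - 1e-7, max(-1.0 + 1e-7, cos))
    out = Tensor(2.0 / np.pi * np.arccos(cos_c))

    def bw():
        if out.grad is None:
            return
        dcos = -2.0 / np.pi / np.sqrt(1.0 - cos_c * cos_c) * float(out.grad)
        gp = dcos * (t / (np_ * nt) - cos * p / (np_ * np_))
        _accum(pred, gp.reshape(pred.data.shape))

    _rec(bw)
    return out


def squared_error(pred: Tensor, target: float) -> Tensor:
    """(pred - target)^2 for a scalar tensor."""
    d = float(pred.data) - target
    out = Tensor(d * d)

    def bw():
        if out.grad is None:
            return
        _accum(pred, np.asarray(2.0 * d * float(out.grad)))

    _rec(bw)
    return out


def cols(a: Tensor, lo: int, hi: int) -> Tensor:
    out = Tensor(a.data[:, lo:hi])

    def bw():
        if out.grad is None:
            return
        g = np.zeros_like(a.data)
        g[:, lo:hi] = out.grad
        _accum(a, g)

    _rec(bw)
    return out


def transpose(a: Tensor) -> Tensor:
    out = Tensor(a.data.T)

    def bw():
        if out.grad is None:
            return
        _accum(a, out.grad.T)

    _rec(bw)
    return out


def softmax_rows1(a: Tensor) -> Tensor:
    """Row-wise softmax over axis 1 of an (n, k) score matrix."""
    z = a.data - a.data.max(axis=1, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=1, keepdims=True)
    out = Tensor(s)

    def bw():
        if out.grad is None:
            return
        g = out.grad
        _accum(a, s * (g - (g * s).sum(axis=1, keepdims=True)))

    _rec(bw)
    return out


def index_add_row(a: Tensor, i: int, v: Tensor) -> Tensor:
    """Copy of ``a`` with row ``i`` incremented by the (1, d) tensor ``v``."""
    data = a.data.copy()
    data[i] += v.data[0]
    out = Tensor(data)

    def bw():
        if out.grad is None:
            return
        _accum(a, out.grad)
        _accum(v, out.grad[i : i + 1])

    _rec(bw)
    return out


def row(a: Tensor, i: int) -> Tensor:
    """Single-row view (1, d) with allocation-free gradient accumulation."""
    out = Tensor(a.data[i : i + 1])

    def bw():
        if out.grad is None:
            return
        if a.grad is None:
            a.grad = np.zeros_like(a.data)
        a.grad[i] += out.grad[0]

    _rec(bw)
    return out


def _sig(x):
    return 1.0 / (1.0 + np.exp(-x))


def lstm_seq(xW: Tensor, W_h: Tensor, reverse: bool = False) -> Tensor:
    """A whole LSTM layer pass as one fused op.

    ``xW`` is the precomputed input projection + bias for every timestep,
    shape (L, 4h) with gate layout [i, f, g, o]; ``W_h`` is the recurrent
    weight (h, 4h).  Returns the (L, h) hidden states in sequence order.
    Backward runs truncated-free BPTT over the cached gate activations.
    """
    L, four_h = xW.data.shape
    h = four_h // 4
    Wh = W_h.data
    order = range(L - 1, -1, -1) if reverse else range(L)
    order = list(order)
    P = np.empty((L, four_h))  # post-activation gates
    C = np.empty((L, h))
    TC = np.empty((L, h))
    H = np.empty((L, h))
    h_prev = np.zeros(h)
    c_prev = np.zeros(h)
    for t in order:
        pre = xW.data[t] + h_prev @ Wh
        i = _sig(pre[:h])
        f = _sig(pre[h : 2 * h])
        g = np.tanh(pre[2 * h : 3 * h])
        o = _sig(pre[3 * h :])
        c = f * c_prev + i * g
        P[t, :h] = i
        P[t, h : 2 * h] = f
        P[t, 2 * h : 3 * h] = g
        P[t, 3 * h :] = o
        C[t] = c
        TC[t] = np.tanh(c)
        H[t] = P[t, 3 * h :] * TC[t]
        h_prev = H[t]
        c_prev = c
    out = Tensor(H)

    def bw():
        if out.grad is None:
            return
        gH = out.grad
        dxW = np.empty((L, four_h))
        Hprev = np.zeros((L, h))
        dh_next = np.zeros(h)
        dc_next = np.zeros(h)
        WhT = Wh.T
        for k in range(L - 1, -1, -1):
            t = order[k]
            t_prev = order[k - 1] if k > 0 else None
            if t_prev is not None:
                Hprev[t] = H[t_prev]
                cp = C[t_prev]
            else:
                cp = 0.0
            i = P[t, :h]
            f = P[t, h : 2 * h]
            g = P[t, 2 * h : 3 * h]
            o = P[t, 3 * h :]
            dh = gH[t] + dh_next
            do = dh * TC[t]
            dc = dc_next + dh * o * (1.0 - TC[t] * TC[t])
            dpre = np.empty(four_h)
            dpre[:h] = dc * g * i * (1.0 - i)
            dpre[h : 2 * h] = dc * cp * f * (1.0 - f)
            dpre[2 * h : 3 * h] = dc * i * (1.0 - g * g)
            dpre[3 * h :] = do * o * (1.0 - o)
            dxW[t] = dpre
            dh_next = dpre @ WhT
            dc_next = dc * f
        _accum(xW, dxW)
        _accum(W_h, Hprev.T @ dxW)

    _rec(bw)
    return out


def childsum_tree(
    x_iou: Tensor,
    x_f: Tensor,
    U_iou: Tensor,
    U_f: Tensor,
    order: list[int],
    preds: dict[int, list[int]],
) -> Tensor:
    """A whole child-sum tree-LSTM traversal as one fused op.

    ``x_iou`` (n, 3h) and ``x_f`` (n, h) are precomputed input projections
    (+bias) with gate layout [i, o, u]; ``preds[v]`` lists predecessor nodes
    (children for bottom-up, the parent for top-down); ``order`` visits
    predecessors first.  Predecessor hidden states are summed for the i/o/u
    gates; each predecessor has its own forget gate.  Returns (n, h) hidden
    states.
    """
    n, three_h = x_iou.data.shape
    h = three_h // 3
    Ui = U_iou.data
    Uf = U_f.data
    H = np.zeros((n, h))
    Cc = np.zeros((n, h))
    HS = np.zeros((n, h))  # summed predecessor hidden states
    IOU = np.empty((n, three_h))
    TCv = np.empty((n, h))
    FK: list[list[np.ndarray]] = [[] for _ in range(n)]
    for v in order:
        pred = preds.get(v, [])
        hsum = HS[v]
        for k in pred:
            hsum += H[k]
        iou = x_iou.data[v] + hsum @ Ui
        i = _sig(iou[:h])
        o = _sig(iou[h : 2 * h])
        u = np.tanh(iou[2 * h :])
        IOU[v, :h] = i
        IOU[v, h : 2 * h] = o
        IOU[v, 2 * h :] = u
        c = i * u
        for k in pred:
            f_k = _sig(x_f.data[v] + H[k] @ Uf)
            FK[v].append(f_k)
            c = c + f_k * Cc[k]
        Cc[v] = c
        TCv[v] = np.tanh(c)
        H[v] = o * TCv[v]
    out = Tensor(H)

    def bw():
        if out.grad is None:
            return
        dH = out.grad.copy()
        dC = np.zeros((n, h))
        dx_iou = np.zeros((n, three_h))
        dx_f = np.zeros((n, h))
        dUi = np.zeros_like(Ui)
        dUf = np.zeros_like(Uf)
        UiT = Ui.T
        UfT = Uf.T
        for v in reversed(order):
            pred = preds.get(v, [])
            i = IOU[v, :h]
            o = IOU[v, h : 2 * h]
            u = IOU[v, 2 * h :]
            dh = dH[v]
            do = dh * TCv[v]
            dc = dC[v] + dh * o * (1.0 - TCv[v] * TCv[v])
            dpre = np.empty(three_h)
            dpre[:h] = dc * u * i * (1.0 - i)
            dpre[h : 2 * h] = do * o * (1.0 - o)
            dpre[2 * h :] = dc * i * (1.0 - u * u)
            dx_iou[v] = dpre
            dUi += np.outer(HS[v], dpre)
            dh_sum = dpre @ UiT
            for j, k in enumerate(pred):
                f_k = FK[v][j]
                df = dc * Cc[k]
                dpf = df * f_k * (1.0 - f_k)
                dx_f[v] += dpf
                dUf += np.outer(H[k], dpf)
                dH[k] += dh_sum + dpf @ UfT
                dC[k] += dc * f_k
        _accum(x_iou, dx_iou)
        _accum(x_f, dx_f)
        _accum(U_iou, dUi)
        _accum(U_f, dUf)

    _rec(bw)
    return out
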