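"""Causal Transformer encoder with a per-time-point sigmoid head.

Baseline sequence classifier: pre-norm self-attention blocks whose attention
is masked to past and current time steps only, so the prediction at time t
never sees inputs after t.  Forward and backward passes are written directly
on numpy arrays; the backward pass is exercised against central-difference
numerical gradients in the test suite.

Architecture (widths are configuration, defaults are baseline choices):
input projection + learned positional embedding, then per block
``x += MHA(LN(x))`` and ``x += FFN(LN(x))`` with ReLU, finally
``y_t = sigmoid(w_out . x_t + b_out)``.
"""

from __future__ import annotations

import math

import numpy as np

from .models import sigmoid

_LN_EPS = 1e-5


def init_transformer_params(
    n_channels: int,
    T: int,
    d_model: int = 64,
    n_layers: int = 2,
    n_heads: int = 4,
    d_ff: int = 128,
    rng: np.random.Generator | None = None,
) -> dict[str, np.ndarray]:
    """Glorot-uniform weights, zero biases, small positional embeddings."""
    if d_model % n_heads:
        raise ValueError(f"d_model={d_model} not divisible by n_heads={n_heads}")
    rng = rng or np.random.default_rng(0)

    def u(fan_in, fan_out, shape):
        lim = math.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-lim, lim, size=shape)

    p: dict[str, np.ndarray] = {
        "W_in": u(n_channels, d_model, (n_channels, d_model)),
        "b_in": np.zeros(d_model),
        "pos": 0.02 * rng.standard_normal((T, d_model)),
        "w_out": u(d_model, 1, (d_model,)),
        "b_out": np.zeros(1),
    }
    for l in range(n_layers):
        for name in ("Wq", "Wk", "Wv", "Wo"):
            p[f"{name}{l}"] = u(d_model, d_model, (d_model, d_model))
        for name in ("bq", "bk", "bv", "bo"):
            p[f"{name}{l}"] = np.zeros(d_model)
        p[f"ln1g{l}"] = np.ones(d_model)
        p[f"ln1b{l}"] = np.zeros(d_model)
        p[f"ln2g{l}"] = np.ones(d_model)
        p[f"ln2b{l}"] = np.zeros(d_model)
        p[f"W1{l}"] = u(d_model, d_ff, (d_model, d_ff))
        p[f"b1{l}"] = np.zeros(d_ff)
        p[f"W2{l}"] = u(d_ff, d_model, (d_ff, d_model))
        p[f"b2{l}"] = np.zeros(d_model)
    p["_meta"] = np.array([n_layers, n_heads], dtype=np.int64)
    return p


def _layernorm_fwd(x, g, b):
    mu = x.mean(-1, keepdims=True)
    xc = x - mu
    var = (xc**2).mean(-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + _LN_EPS)
    xhat = xc * inv
    return g * xhat + b, (xhat, inv, g)


def _layernorm_bwd(dout, cache):
    xhat, inv, g = cache
    dxhat = dout * g
    dg = (dout * xhat).sum(axis=tuple(range(dout.ndim - 1)))
    db = dout.sum(axis=tuple(range(dout.ndim - 1)))
    m1 = dxhat.mean(-1, keepdims=True)
    m2 = (dxhat * xhat).mean(-1, keepdims=True)
    dx = inv * (dxhat - m1 - xhat * m2)
    return dx, dg, db


def _split_heads(x, n_heads):  # [B,T,D] -> [B,H,T,dh]
    B, T, D = x.shape
    return x.reshape(B, T, n_heads, D // n_heads).transpose(0, 2, 1, 3)


def _merge_heads(x):  # [B,H,T,dh] -> [B,T,D]
    B, H, T, dh = x.shape
    return x.transpose(0, 2, 1, 3).reshape(B, T, H * dh)


def transformer_forward(
    params: dict[str, np.ndarray],
    X: np.ndarray,
    dropout: float = 0.0,
    rng: np.random.Generator | None = None,
    need_cache: bool = False,
):
    """Run the causal encoder.  Returns (y [B,T], cache or None).

    ``dropout`` > 0 (training only) applies inverted dropout to the two
    residual branches; evaluation passes must leave it at 0.
    """
    n_layers, n_heads = (int(v) for v in params["_meta"])
    B, T, R = X.shape
    pos = params["pos"]
    if T > pos.shape[0]:
        raise ValueError(f"sequence length {T} exceeds positional table {pos.shape[0]}")
    x = X @ params["W_in"] + params["b_in"] + pos[:T]
    mask = np.triu(np.full((T, T), -np.inf), k=1)  # forbid attending to the future
    cache: dict = {"X": X, "layers": [], "T": T}
    for l in range(n_layers):
        lc: dict = {}
        u, lc["ln1"] = _layernorm_fwd(x, params[f"ln1g{l}"], params[f"ln1b{l}"])
        q = _split_heads(u @ params[f"Wq{l}"] + params[f"bq{l}"], n_heads)
        k = _split_heads(u @ params[f"Wk{l}"] + params[f"bk{l}"], n_heads)
        v = _split_heads(u @ params[f"Wv{l}"] + params[f"bv{l}"], n_heads)
        dh = q.shape[-1]
        scores = q @ k.transpose(0, 1, 3, 2) / math.sqrt(dh) + mask
        scores -= scores.max(-1, keepdims=True)
        e = np.exp(scores)
        A = e / e.sum(-1, keepdims=True)  # [B,H,T,T]
        ctx = _merge_heads(A @ v)
        attn = ctx @ params[f"Wo{l}"] + params[f"bo{l}"]
        if dropout > 0:
            m = (rng.random(attn.shape) >= dropout) / (1.0 - dropout)
            attn *= m
            lc["drop1"] = m
        x1 = x + attn
        w, lc["ln2"] = _layernorm_fwd(x1, params[f"ln2g{l}"], params[f"ln2b{l}"])
        z1 = w @ params[f"W1{l}"] + params[f"b1{l}"]
        r1 = np.maximum(z1, 0.0)
        f = r1 @ params[f"W2{l}"] + params[f"b2{l}"]
        if dropout > 0:
            m = (rng.random(f.shape) >= dropout) / (1.0 - dropout)
            f *= m
            lc["drop2"] = m
        x2 = x1 + f
        if need_cache:
            lc.update(u=u, q=q, k=k, v=v, A=A, ctx=ctx, x1=x1, w=w, r1=r1)
            cache["layers"].append(lc)
        x = x2
    z = x @ params["w_out"] + params["b_out"][0]
    y = sigmoid(z)
    if need_cache:
        cache["x_final"] = x
        cache["y"] = y
        return y, cache
    return y, None


def transformer_backward(
    params: dict[str, np.ndarray], cache: dict, dZ: np.ndarray
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Backward pass from dL/dz (pre-sigmoid, [B,T]).

    Returns (gradients keyed like params, dL/dX [B,T,R]).
    """
    n_layers, n_heads = (int(v) for v in params["_meta"])
    grads = {k: np.zeros_like(v) for k, v in params.items() if k != "_meta"}
    x = cache["x_final"]
    grads["w_out"] = np.einsum("bt,btd->d", dZ, x)
    grads["b_out"] = np.array([dZ.sum()])
    dx = dZ[:, :, None] * params["w_out"][None, None, :]
    for l in reversed(range(n_layers)):
        lc = cache["layers"][l]
        # FFN branch
        df = dx.copy()
        if "drop2" in lc:
            df *= lc["drop2"]
        grads[f"W2{l}"] = np.einsum("btf,btd->fd", lc["r1"], df)
        grads[f"b2{l}"] = df.sum((0, 1))
        dr1 = df @ params[f"W2{l}"].T
        dz1 = dr1 * (lc["r1"] > 0)
        grads[f"W1{l}"] = np.einsum("btd,btf->df", lc["w"], dz1)
        grads[f"b1{l}"] = dz1.sum((0, 1))
        dw = dz1 @ params[f"W1{l}"].T
        dx1_ln, grads[f"ln2g{l}"], grads[f"ln2b{l}"] = _layernorm_bwd(dw, lc["ln2"])
        dx1 = dx + dx1_ln
        # attention branch
        dattn = dx1.copy()
        if "drop1" in lc:
            dattn *= lc["drop1"]
        grads[f"Wo{l}"] = np.einsum("btd,bte->de", lc["ctx"], dattn)
        grads[f"bo{l}"] = dattn.sum((0, 1))
        dctx = _split_heads(dattn @ params[f"Wo{l}"].T, n_heads)
        A, q, k, v = lc["A"], lc["q"], lc["k"], lc["v"]
        dA = dctx @ v.transpose(0, 1, 3, 2)
        dv = A.transpose(0, 1, 3, 2) @ dctx
        dS = A * (dA - (dA * A).sum(-1, keepdims=True))
        dh = q.shape[-1]
        dS /= math.sqrt(dh)
        dq = dS @ k
        dk = dS.transpose(0, 1, 3, 2) @ q
        dq, dk, dv = _merge_heads(dq), _merge_heads(dk), _merge_heads(dv)
        u = lc["u"]
        du = np.zeros_like(u)
        for name, d in (("Wq", dq), ("Wk", dk), ("Wv", dv)):
            grads[f"{name}{l}"] = np.einsum("btd,bte->de", u, d)
            grads[f"b{name[1]}{l}"] = d.sum((0, 1))
            du += d @ params[f"{name}{l}"].T
        dx_ln, grads[f"ln1g{l}"], grads[f"ln1b{l}"] = _layernorm_bwd(du, lc["ln1"])
        dx = dx1 + dx_ln
    # input projection + positional table
    X = cache["X"]
    grads["W_in"] = np.einsum("btr,btd->rd", X, dx)
    grads["b_in"] = dx.sum((0, 1))
    grads["pos"][: cache["T"]] = dx.sum(0)
    dX = dx @ params["W_in"].T
    return grads, dX
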