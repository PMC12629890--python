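"""Minimal numpy transformer encoder for per-depth sequence labelling.

Implements a standard post-norm encoder (multi-head self-attention + ReLU
feed-forward, residual connections, layer norm) with sinusoidal positional
encoding and a softmax cross-entropy head, including full manual backprop
and an Adam optimiser. Written against numpy only so training runs anywhere
the package does; sizes are tiny (CPU seconds, not GPU hours).
"""

from __future__ import annotations

import numpy as np

_LN_EPS = 1e-5


def positional_encoding(length: int, dim: int) -> np.ndarray:
    """Sinusoidal position embeddings, (length, dim)."""
    pos = np.arange(length)[:, None].astype(np.float64)
    i = np.arange(dim // 2)[None, :].astype(np.float64)
    angle = pos / np.power(10000.0, 2.0 * i / dim)
    pe = np.zeros((length, dim))
    pe[:, 0::2] = np.sin(angle)
    pe[:, 1::2] = np.cos(angle)
    return pe


def init_params(
    dim: int, n_layers: int, n_heads: int, ffn_dim: int,
    n_features: int, n_classes: int, rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    if dim % n_heads:
        raise ValueError("embedding width must be divisible by n_heads")

    def glorot(shape):
        limit = np.sqrt(6.0 / (shape[0] + shape[1]))
        return rng.uniform(-limit, limit, size=shape)

    p: dict[str, np.ndarray] = {
        "We": glorot((n_features, dim)),
        "be": np.zeros(dim),
        "Wc": glorot((dim, n_classes)),
        "bc": np.zeros(n_classes),
    }
    for l in range(n_layers):
        for name in ("Wq", "Wk", "Wv", "Wo"):
            p[f"{name}{l}"] = glorot((dim, dim))
        for name in ("bq", "bk", "bv", "bo"):
            p[f"{name}{l}"] = np.zeros(dim)
        p[f"Wf1_{l}"] = glorot((dim, ffn_dim))
        p[f"bf1_{l}"] = np.zeros(ffn_dim)
        p[f"Wf2_{l}"] = glorot((ffn_dim, dim))
        p[f"bf2_{l}"] = np.zeros(dim)
        p[f"g1_{l}"] = np.ones(dim)
        p[f"b1_{l}"] = np.zeros(dim)
        p[f"g2_{l}"] = np.ones(dim)
        p[f"b2_{l}"] = np.zeros(dim)
    return p


def _layernorm_fwd(x, g, b):
    mu = x.mean(axis=-1, keepdims=True)
    var = x.var(axis=-1, keepdims=True)
    rstd = 1.0 / np.sqrt(var + _LN_EPS)
    xhat = (x - mu) * rstd
    return g * xhat + b, (xhat, rstd, g)


def _layernorm_bwd(dy, cache):
    xhat, rstd, g = cache
    dg = (dy * xhat).sum(axis=0)
    db = dy.sum(axis=0)
    dxhat = dy * g
    dx = rstd * (
        dxhat
        - dxhat.mean(axis=-1, keepdims=True)
        - xhat * (dxhat * xhat).mean(axis=-1, keepdims=True)
    )
    return dx, dg, db


def _split_heads(x, n_heads):
    L, d = x.shape
    return x.reshape(L, n_heads, d // n_heads).transpose(1, 0, 2)  # (h, L, dh)


def _merge_heads(x):
    h, L, dh = x.shape
    return x.transpose(1, 0, 2).reshape(L, h * dh)


def attention_mask(length: int, context_k: int | None) -> np.ndarray | None:
    """Additive mask restricting attention to |i - j| <= context_k."""
    if context_k is None:
        return None
    idx = np.arange(length)
    blocked = np.abs(idx[:, None] - idx[None, :]) > context_k
    mask = np.zeros((length, length))
    mask[blocked] = -np.inf
    return mask


def forward(
    params: dict,
    x: np.ndarray,
    n_layers: int,
    n_heads: int,
    context_k: int | None = None,
):
    """Run the encoder on one sequence of feature vectors (L, n_features).

    Returns (logits (L, n_classes), cache for backprop).
    """
    L = x.shape[0]
    dim = params["We"].shape[1]
    pe = positional_encoding(L, dim)
    H = x @ params["We"] + params["be"] + pe
    mask = attention_mask(L, context_k)
    cache = {"x": x, "layers": []}
    for l in range(n_layers):
        Q = H @ params[f"Wq{l}"] + params[f"bq{l}"]
        K = H @ params[f"Wk{l}"] + params[f"bk{l}"]
        V = H @ params[f"Wv{l}"] + params[f"bv{l}"]
        Qh, Kh, Vh = (_split_heads(z, n_heads) for z in (Q, K, V))
        dh = dim // n_heads
        S = Qh @ Kh.transpose(0, 2, 1) / np.sqrt(dh)
        if mask is not None:
            S = S + mask
        S = S - S.max(axis=-1, keepdims=True)
        A = np.exp(S)
        A /= A.sum(axis=-1, keepdims=True)
        Oh = A @ Vh
        Om = _merge_heads(Oh)
        attn_out = Om @ params[f"Wo{l}"] + params[f"bo{l}"]
        res1 = H + attn_out
        H1, ln1_cache = _layernorm_fwd(res1, params[f"g1_{l}"], params[f"b1_{l}"])
        F1 = H1 @ params[f"Wf1_{l}"] + params[f"bf1_{l}"]
        R = np.maximum(F1, 0.0)
        F2 = R @ params[f"Wf2_{l}"] + params[f"bf2_{l}"]
        res2 = H1 + F2
        H2, ln2_cache = _layernorm_fwd(res2, params[f"g2_{l}"], params[f"b2_{l}"])
        cache["layers"].append(
            dict(H=H, Qh=Qh, Kh=Kh, Vh=Vh, A=A, Om=Om, ln1=ln1_cache,
                 H1=H1, F1=F1, R=R, ln2=ln2_cache)
        )
        H = H2
    logits = H @ params["Wc"] + params["bc"]
    cache["H_final"] = H
    return logits, cache


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean token cross-entropy; returns (loss, dlogits, probabilities)."""
    z = logits - logits.max(axis=-1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=-1, keepdims=True)
    n = len(labels)
    loss = -np.log(probs[np.arange(n), labels] + 1e-300).mean()
    dlogits = probs.copy()
    dlogits[np.arange(n), labels] -= 1.0
    dlogits /= n
    return float(loss), dlogits, probs


def backward(
    params: dict,
    cache: dict,
    dlogits: np.ndarray,
    n_layers: int,
    n_heads: int,
) -> dict[str, np.ndarray]:
    """Gradients of the loss w.r.t. every parameter for one sequence."""
    grads = {k: np.zeros_like(v) for k, v in params.items()}
    H_final = cache["H_final"]
    grads["Wc"] = H_final.T @ dlogits
    grads["bc"] = dlogits.sum(axis=0)
    dH = dlogits @ params["Wc"].T
    dim = params["We"].shape[1]
    dh = dim // n_heads
    for l in reversed(range(n_layers)):
        c = cache["layers"][l]
        dres2, dg2, db2 = _layernorm_bwd(dH, c["ln2"])
        grads[f"g2_{l}"], grads[f"b2_{l}"] = dg2, db2
        dH1 = dres2.copy()
        dF2 = dres2
        grads[f"Wf2_{l}"] = c["R"].T @ dF2
        grads[f"bf2_{l}"] = dF2.sum(axis=0)
        dR = dF2 @ params[f"Wf2_{l}"].T
        dF1 = dR * (c["F1"] > 0)
        grads[f"Wf1_{l}"] = c["H1"].T @ dF1
        grads[f"bf1_{l}"] = dF1.sum(axis=0)
        dH1 += dF1 @ params[f"Wf1_{l}"].T
        dres1, dg1, db1 = _layernorm_bwd(dH1, c["ln1"])
        grads[f"g1_{l}"], grads[f"b1_{l}"] = dg1, db1
        dHin = dres1.copy()
        dattn = dres1
        grads[f"Wo{l}"] = c["Om"].T @ dattn
        grads[f"bo{l}"] = dattn.sum(axis=0)
        dOm = dattn @ params[f"Wo{l}"].T
        L = dOm.shape[0]
        dOh = dOm.reshape(L, n_heads, dh).transpose(1, 0, 2)
        A, Qh, Kh, Vh = c["A"], c["Qh"], c["Kh"], c["Vh"]
        dA = dOh @ Vh.transpose(0, 2, 1)
        dVh = A.transpose(0, 2, 1) @ dOh
        dS = A * (dA - (dA * A).sum(axis=-1, keepdims=True))
        dQh = dS @ Kh / np.sqrt(dh)
        dKh = dS.transpose(0, 2, 1) @ Qh / np.sqrt(dh)
        dQ = _merge_heads(dQh)
        dK = _merge_heads(dKh)
        dV = _merge_heads(dVh)
        H = c["H"]
        grads[f"Wq{l}"] = H.T @ dQ
        grads[f"bq{l}"] = dQ.sum(axis=0)
        grads[f"Wk{l}"] = H.T @ dK
        grads[f"bk{l}"] = dK.sum(axis=0)
        grads[f"Wv{l}"] = H.T @ dV
        grads[f"bv{l}"] = dV.sum(axis=0)
        dHin += dQ @ params[f"Wq{l}"].T
        dHin += dK @ params[f"Wk{l}"].T
        dHin += dV @ params[f"Wv{l}"].T
        dH = dHin
    grads["We"] = cache["x"].T @ dH
    grads["be"] = dH.sum(axis=0)
    return grads


class Adam:
    """Standard Adam over a parameter dict."""

    def __init__(self, params: dict, lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1**self.t
        b2c = 1.0 - self.beta2**self.t
        for k in params:
            g = grads[k]
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            params[k] -= self.lr * (self.m[k] / b1c) / (
                np.sqrt(self.v[k] / b2c) + self.eps
            )
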