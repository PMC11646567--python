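"""Small neural-network module system on top of :mod:`rsmanet._tensor`."""

from __future__ import annotations

from typing import Dict, Optional

import numpy as np

from ._tensor import Tensor, concat, dropout, layer_norm, softmax_rows


class Module:
    """Base class: recursive parameter registry + train/eval mode."""

    def __init__(self) -> None:
        self._params: Dict[str, Tensor] = {}
        self._modules: Dict[str, "Module"] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        elif isinstance(value, Tensor) and value.requires_grad:
            self.__dict__.setdefault("_params", {})[name] = value
        object.__setattr__(self, name, value)

    def parameters(self, prefix: str = "") -> Dict[str, Tensor]:
        out = {prefix + k: v for k, v in self._params.items()}
        for name, mod in self._modules.items():
            out.update(mod.parameters(prefix + name + "."))
        return out

    def train(self) -> None:
        self.training = True
        for m in self._modules.values():
            m.train()

    def eval(self) -> None:
        self.training = False
        for m in self._modules.values():
            m.eval()

    def zero_grad(self) -> None:
        for p in self.parameters().values():
            p.zero_grad()

    def load_state(self, state: Dict[str, np.ndarray]) -> None:
        params = self.parameters()
        missing = set(params) ^ set(state)
        if missing:
            raise KeyError(f"parameter name mismatch: {sorted(missing)}")
        for k, p in params.items():
            if p.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}")
            p.data = np.asarray(state[k], dtype=np.float64).copy()

    def state(self) -> Dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.parameters().items()}


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int,
           shape: Optional[tuple] = None) -> Tensor:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    shape = shape if shape is not None else (fan_in, fan_out)
    return Tensor(rng.uniform(-limit, limit, size=shape), requires_grad=True)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        self.W = glorot(rng, d_in, d_out)
        self.b = Tensor(np.zeros(d_out), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.W
        return y + self.b if self.b is not None else y


class Embedding(Module):
    def __init__(self, vocab: int, d: int, rng: np.random.Generator):
        super().__init__()
        self.table = Tensor(rng.normal(0.0, 0.02, size=(vocab, d)),
                            requires_grad=True)

    def __call__(self, indices: np.ndarray) -> Tensor:
        from ._tensor import embedding_lookup
        return embedding_lookup(self.table, indices)


class LayerNorm(Module):
    def __init__(self, d: int):
        super().__init__()
        self.gamma = Tensor(np.ones(d), requires_grad=True)
        self.beta = Tensor(np.zeros(d), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return layer_norm(x, self.gamma, self.beta)


def scaled_dot_attention(q: Tensor, k: Tensor, v: Tensor,
                         key_mask: Optional[np.ndarray] = None):
    """Scaled dot-product attention for one head.

    q: (n_q, d_h); k, v: (n_k, d_h).  `key_mask` (n_k,) marks valid keys;
    masked keys receive exactly zero attention weight.  Returns the output
    (n_q, d_h) and the row-stochastic score matrix (n_q, n_k).
    """
    d_h = q.shape[-1]
    logits = (q @ k.T) * (1.0 / np.sqrt(d_h))
    mask = None
    if key_mask is not None:
        mask = np.broadcast_to(np.asarray(key_mask, bool)[None, :], logits.shape)
    attn = softmax_rows(logits, mask)
    return attn @ v, attn


class MultiHeadAttention(Module):
    """Multi-head attention with separate query and key/value sources.

    Self-attention is the special case `source is query`.  Head outputs are
    concatenated (head width d/u) and passed through an output projection.
    """

    def __init__(self, d: int, n_heads: int, rng: np.random.Generator):
        super().__init__()
        if d % n_heads != 0:
            raise ValueError("d must be divisible by n_heads")
        self.n_heads = n_heads
        self.d_head = d // n_heads
        self.Wq = Linear(d, d, rng, bias=False)
        self.Wk = Linear(d, d, rng, bias=False)
        self.Wv = Linear(d, d, rng, bias=False)
        self.Wo = Linear(d, d, rng, bias=False)

    def __call__(self, query: Tensor, source: Tensor,
                 key_mask: Optional[np.ndarray] = None):
        q_all, k_all, v_all = self.Wq(query), self.Wk(source), self.Wv(source)
        outs, scores = [], []
        for h in range(self.n_heads):
            sl = slice(h * self.d_head, (h + 1) * self.d_head)
            o, a = scaled_dot_attention(q_all[:, sl], k_all[:, sl],
                                        v_all[:, sl], key_mask)
            outs.append(o)
            scores.append(a.data.copy())
        return self.Wo(concat(outs, axis=1)), scores


class FeedForward(Module):
    """Position-wise FFN: ReLU between two affine maps."""

    def __init__(self, d: int, d_hidden: int, rng: np.random.Generator):
        super().__init__()
        self.W1 = Linear(d, d_hidden, rng)
        self.W2 = Linear(d_hidden, d, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.W2(self.W1(x).relu())


class TransformerBlock(Module):
    """Post-norm Transformer block: MHA -> add&norm -> FFN -> add&norm."""

    def __init__(self, d: int, n_heads: int, rng: np.random.Generator,
                 ffn_mult: int = 2):
        super().__init__()
        self.attn = MultiHeadAttention(d, n_heads, rng)
        self.ln1 = LayerNorm(d)
        self.ffn = FeedForward(d, ffn_mult * d, rng)
        self.ln2 = LayerNorm(d)

    def __call__(self, x: Tensor, key_mask: Optional[np.ndarray] = None):
        a, scores = self.attn(x, x, key_mask)
        h = self.ln1(x + a)
        y = self.ln2(h + self.ffn(h))
        return y, scores


class MLPHead(Module):
    """Two-layer MLP with ReLU and dropout after the first layer."""

    def __init__(self, d_in: int, d_hidden: int, d_out: int,
                 dropout_rate: float, rng: np.random.Generator):
        super().__init__()
        self.W1 = Linear(d_in, d_hidden, rng)
        self.W2 = Linear(d_hidden, d_out, rng)
        self.rate = dropout_rate

    def __call__(self, x: Tensor, rng: np.random.Generator) -> Tensor:
        h = self.W1(x).relu()
        h = dropout(h, self.rate, rng, self.training)
        return self.W2(h)
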