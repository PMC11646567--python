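"""Adam optimizer with decoupled L2 weight decay (classic Adam + L2)."""

from __future__ import annotations

from typing import Dict

import numpy as np

from ._tensor import Tensor


class Adam:
    """Adam (Kingma & Ba) over a named parameter dict.

    Weight decay is applied as an L2 term added to the gradient, matching
    the conventional ``Adam(weight_decay=...)`` behaviour of mainstream
    deep-learning frameworks.
    """

    def __init__(self, params: Dict[str, Tensor], lr: float = 5e-4,
                 betas: tuple = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.zero_grad()

    def state(self) -> dict:
        return {
            "t": self.t,
            "m": {k: v.copy() for k, v in self.m.items()},
            "v": {k: v.copy() for k, v in self.v.items()},
        }

    def load_state(self, state: dict) -> None:
        self.t = int(state["t"])
        for k in self.m:
            self.m[k] = np.asarray(state["m"][k]).copy()
            self.v[k] = np.asarray(state["v"][k]).copy()
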