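"""Optimizers over autodiff tensors.

:class:`Adam` accepts either a flat parameter list or per-subnetwork
parameter groups with their own learning rates, which is how multi-rate
fine-tuning (separate rates for each encoder and the fusion head) is run.
"""

from __future__ import annotations

import numpy as np

from mvmol.nn.tensor import Tensor


class Adam:
    def __init__(
        self,
        params_or_groups,
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ):
        if params_or_groups and isinstance(params_or_groups[0], dict):
            self.groups = [
                {"params": list(g["params"]), "lr": float(g.get("lr", lr))}
                for g in params_or_groups
            ]
        else:
            self.groups = [{"params": list(params_or_groups), "lr": float(lr)}]
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m: dict[int, np.ndarray] = {}
        self._v: dict[int, np.ndarray] = {}

    @property
    def params(self) -> list[Tensor]:
        return [p for g in self.groups for p in g["params"]]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for group in self.groups:
            lr = group["lr"]
            if lr == 0.0:
                continue
            for p in group["params"]:
                if p.grad is None:
                    continue
                g = p.grad
                if self.weight_decay:
                    g = g + self.weight_decay * p.data
                m = self._m.setdefault(id(p), np.zeros_like(p.data))
                v = self._v.setdefault(id(p), np.zeros_like(p.data))
                m[...] = b1 * m + (1 - b1) * g
                v[...] = b2 * v + (1 - b2) * g * g
                m_hat = m / (1 - b1**self.t)
                v_hat = v / (1 - b2**self.t)
                p.data = p.data - lr * m_hat / (np.sqrt(v_hat) + self.eps)


class SGD:
    def __init__(self, params, lr: float = 1e-2):
        self.params = list(params)
        self.lr = lr

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        for p in self.params:
            if p.grad is not None:
                p.data = p.data - self.lr * p.grad
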