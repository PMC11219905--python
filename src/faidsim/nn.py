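"""Minimal fully connected network and Adam optimiser on numpy.

Sized for the bolus-calculator Q-networks (15 inputs, three hidden
layers of 28 ReLU units, 15 linear outputs), but the layer widths are
free parameters.  The only training entry point is a squared-error step
on a subset of output units — exactly what a DQN Bellman update needs.
"""

from __future__ import annotations

import numpy as np

__all__ = ["MLP"]


class MLP:
    """Fully connected ReLU network with per-parameter Adam updates."""

    def __init__(self, sizes: tuple[int, ...] = (15, 28, 28, 28, 15),
                 seed: int = 0, init_scale: float = 0.1,
                 zero_final: bool = False) -> None:
        """``zero_final`` zeroes the output layer so an untrained network
        emits identical values for every unit — downstream argmax
        consumers then fall back to their documented tie-break."""
        self.sizes = tuple(sizes)
        rng = np.random.default_rng(seed)
        self.W = [rng.normal(0.0, init_scale / np.sqrt(a), size=(a, b))
                  for a, b in zip(sizes[:-1], sizes[1:])]
        self.b = [np.zeros(b) for b in sizes[1:]]
        if zero_final:
            self.W[-1][:] = 0.0
        self._adam_m = [np.zeros_like(w) for w in self.W + self.b]
        self._adam_v = [np.zeros_like(w) for w in self.W + self.b]
        self._adam_t = 0

    # --- inference --------------------------------------------------------

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Batch forward pass; accepts (d,) or (B, d)."""
        h = np.atleast_2d(np.asarray(x, dtype=float))
        for W, b in zip(self.W[:-1], self.b[:-1]):
            h = np.maximum(h @ W + b, 0.0)
        out = h @ self.W[-1] + self.b[-1]
        return out[0] if np.ndim(x) == 1 else out

    __call__ = forward

    # --- training ---------------------------------------------------------

    def train_step(self, x: np.ndarray, actions: np.ndarray,
                   targets: np.ndarray, lr: float = 1e-3) -> float:
        """One Adam step on L = mean_i (target_i − out[i, action_i])².

        Returns the loss before the update.
        """
        x = np.atleast_2d(np.asarray(x, dtype=float))
        actions = np.asarray(actions, dtype=int)
        targets = np.asarray(targets, dtype=float)
        B = x.shape[0]
        # forward with caches
        hs = [x]
        pre = []
        h = x
        for W, b in zip(self.W[:-1], self.b[:-1]):
            z = h @ W + b
            pre.append(z)
            h = np.maximum(z, 0.0)
            hs.append(h)
        out = h @ self.W[-1] + self.b[-1]
        q_sel = out[np.arange(B), actions]
        err = q_sel - targets
        loss = float(np.mean(err**2))
        # backward
        dout = np.zeros_like(out)
        dout[np.arange(B), actions] = 2.0 * err / B
        grads_W: list[np.ndarray] = []
        grads_b: list[np.ndarray] = []
        delta = dout
        for i in range(len(self.W) - 1, -1, -1):
            grads_W.append(hs[i].T @ delta)
            grads_b.append(delta.sum(axis=0))
            if i > 0:
                delta = (delta @ self.W[i].T) * (pre[i - 1] > 0)
        grads_W.reverse()
        grads_b.reverse()
        self._adam(grads_W + grads_b, lr)
        return loss

    def _adam(self, grads: list[np.ndarray], lr: float,
              beta1: float = 0.9, beta2: float = 0.999,
              eps: float = 1e-8) -> None:
        self._adam_t += 1
        params = self.W + self.b
        for p, g, m, v in zip(params, grads, self._adam_m, self._adam_v):
            m *= beta1
            m += (1 - beta1) * g
            v *= beta2
            v += (1 - beta2) * g**2
            mh = m / (1 - beta1**self._adam_t)
            vh = v / (1 - beta2**self._adam_t)
            p -= lr * mh / (np.sqrt(vh) + eps)

    # --- weight plumbing ---------------------------------------------------

    def get_weights(self) -> list[np.ndarray]:
        return [w.copy() for w in self.W] + [b.copy() for b in self.b]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        n = len(self.W)
        self.W = [np.array(w, dtype=float) for w in weights[:n]]
        self.b = [np.array(b, dtype=float) for b in weights[n:]]

    def clone(self) -> "MLP":
        twin = MLP(self.sizes, seed=0)
        twin.set_weights(self.get_weights())
        return twin
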