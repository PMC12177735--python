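"""Small fully connected networks with analytic input gradients.

The energy network maps descriptor features to per-state energies; its
predicted gradients are the exact analytic derivatives of the predicted
energy with respect to the inputs (chain-ruled through the descriptor
Jacobian), and the combined loss fits energies and those derivative
gradients simultaneously.  That requires differentiating the network's
input gradient with respect to the weights ("double backprop"), which is
written out explicitly below for the two-hidden-layer architecture.

Activation is a leaky softplus f(z) = alpha z + (1 - alpha) softplus(z),
smooth to all orders (its second derivative enters the double backprop).
"""

from __future__ import annotations

import numpy as np

from ..errors import TrainingDivergenceError

ALPHA = 0.05  # leak fraction


def _sigmoid(z):
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def act(z):
    return ALPHA * z + (1.0 - ALPHA) * np.logaddexp(0.0, z)


def dact(z):
    return ALPHA + (1.0 - ALPHA) * _sigmoid(z)


def d2act(z):
    s = _sigmoid(z)
    return (1.0 - ALPHA) * s * (1.0 - s)


def softplus(z):
    return np.logaddexp(0.0, z)


class MLP:
    """Two-hidden-layer perceptron with optional softplus output head."""

    def __init__(self, n_in: int, n_out: int, hidden=(64, 64), seed: int = 0,
                 softplus_head: bool = False):
        if len(hidden) != 2:
            raise ValueError("this implementation is fixed at two hidden layers")
        rng = np.random.Generator(np.random.Philox(np.random.SeedSequence(seed)))
        h1, h2 = hidden
        self.W1 = rng.normal(0.0, np.sqrt(2.0 / n_in), (h1, n_in))
        self.b1 = np.zeros(h1)
        self.W2 = rng.normal(0.0, np.sqrt(2.0 / h1), (h2, h1))
        self.b2 = np.zeros(h2)
        self.W3 = rng.normal(0.0, np.sqrt(2.0 / h2), (n_out, h2))
        self.b3 = np.zeros(n_out)
        self.softplus_head = softplus_head
        self._adam = None

    # -- forward --------------------------------------------------------

    def _hidden(self, X):
        z1 = X @ self.W1.T + self.b1
        h1 = act(z1)
        z2 = h1 @ self.W2.T + self.b2
        h2 = act(z2)
        return z1, h1, z2, h2

    def forward(self, X: np.ndarray) -> np.ndarray:
        _, _, _, h2 = self._hidden(X)
        z3 = h2 @ self.W3.T + self.b3
        return softplus(z3) if self.softplus_head else z3

    def forward_with_input_grad(self, X: np.ndarray):
        """Outputs (N, S) and d outputs / d inputs (N, S, d)."""
        z1, h1, z2, h2 = self._hidden(X)
        z3 = h2 @ self.W3.T + self.b3
        a1, a2 = dact(z1), dact(z2)
        T = a2[:, None, :] * self.W3[None, :, :]
        A = T @ self.W2
        C = A * a1[:, None, :]
        G = C @ self.W1
        if self.softplus_head:
            s3 = _sigmoid(z3)
            return softplus(z3), G * s3[:, :, None]
        return z3, G

    # -- loss and analytic weight gradients ------------------------------

    def loss_and_grads(self, X, y, Jeff=None, gtar=None, w_energy=1.0,
                       w_grad=1.0):
        """Combined loss and its gradients with respect to all weights.

        X: (N, d) features; y: (N, S) targets.
        Jeff: (N, d, c) effective descriptor Jacobians; gtar: (N, S, c)
        gradient targets in the same (normalized) units.  Omit both to fit
        outputs only.
        """
        N = X.shape[0]
        z1 = X @ self.W1.T + self.b1
        h1 = act(z1)
        z2 = h1 @ self.W2.T + self.b2
        h2 = act(z2)
        z3 = h2 @ self.W3.T + self.b3
        out = softplus(z3) if self.softplus_head else z3

        diff = out - y
        loss = w_energy * np.mean(diff**2)
        dLdout = (2.0 * w_energy / diff.size) * diff
        d3 = dLdout * _sigmoid(z3) if self.softplus_head else dLdout

        gW3 = d3.T @ h2
        gb3 = d3.sum(axis=0)
        d2 = (d3 @ self.W3) * dact(z2)
        gW2 = d2.T @ h1
        gb2 = d2.sum(axis=0)
        d1 = (d2 @ self.W2) * dact(z1)
        gW1 = d1.T @ X
        gb1 = d1.sum(axis=0)

        if Jeff is not None:
            if self.softplus_head:
                raise NotImplementedError("gradient loss with softplus head")
            a1, a2 = dact(z1), dact(z2)
            T = a2[:, None, :] * self.W3[None, :, :]           # (N,S,h2)
            A = T @ self.W2                                    # (N,S,h1)
            C = A * a1[:, None, :]                             # (N,S,h1)
            G = C @ self.W1                                    # (N,S,d)
            P = np.einsum("nsd,ndc->nsc", G, Jeff)
            gdiff = P - gtar
            loss += w_grad * np.mean(gdiff**2)
            R = (2.0 * w_grad / gdiff.size) * np.einsum(
                "nsc,ndc->nsd", gdiff, Jeff
            )
            B = (self.W2[None, :, :] * a1[:, None, :]) @ self.W1  # (N,h2,d)
            Q = a2[:, :, None] * B                                # (N,h2,d)
            gW3 += np.einsum("nsd,nhd->sh", R, Q)
            gW1 += np.einsum("nsd,nsh->hd", R, C)
            X1 = np.einsum("nsd,nsh->nhd", R, T)
            W1a = a1[:, :, None] * self.W1[None, :, :]            # (N,h1,d)
            gW2 += np.einsum("nhd,nkd->hk", X1, W1a)
            # curvature of the activations (second-derivative paths)
            dLda2 = np.einsum("nsd,sh,nhd->nh", R, self.W3, B)
            dz2 = dLda2 * d2act(z2)
            gW2 += dz2.T @ h1
            gb2 += dz2.sum(axis=0)
            dh1 = dz2 @ self.W2
            dz1h = dh1 * dact(z1)
            gW1 += dz1h.T @ X
            gb1 += dz1h.sum(axis=0)
            dLda1 = np.einsum("nsd,nsk,kd->nk", R, A, self.W1)
            dz1 = dLda1 * d2act(z1)
            gW1 += dz1.T @ X
            gb1 += dz1.sum(axis=0)

        grads = {"W1": gW1, "b1": gb1, "W2": gW2, "b2": gb2,
                 "W3": gW3, "b3": gb3}
        return loss, grads

    # -- Adam -------------------------------------------------------------

    def adam_step(self, grads, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        if self._adam is None:
            self._adam = {
                k: (np.zeros_like(getattr(self, k)), np.zeros_like(getattr(self, k)))
                for k in grads
            }
            self._adam_t = 0
        self._adam_t += 1
        t = self._adam_t
        for k, g in grads.items():
            m, v = self._adam[k]
            m = beta1 * m + (1 - beta1) * g
            v = beta2 * v + (1 - beta2) * g * g
            self._adam[k] = (m, v)
            mhat = m / (1 - beta1**t)
            vhat = v / (1 - beta2**t)
            setattr(self, k, getattr(self, k) - lr * mhat / (np.sqrt(vhat) + eps))

    def parameters(self) -> dict:
        return {k: getattr(self, k).copy() for k in
                ("W1", "b1", "W2", "b2", "W3", "b3")}

    def set_parameters(self, params: dict):
        for k, v in params.items():
            setattr(self, k, np.asarray(v, float).copy())


def train(net: MLP, X, y, Jeff=None, gtar=None, *, epochs=300, batch_size=64,
          lr=1e-3, lr_final=1e-4, w_energy=1.0, w_grad=1.0, seed=0,
          X_val=None, callback=None):
    """Minibatch Adam training; returns the per-epoch loss history."""
    N = X.shape[0]
    rng = np.random.Generator(np.random.Philox(np.random.SeedSequence(seed)))
    history = []
    for epoch in range(epochs):
        cur_lr = lr * (lr_final / lr) ** (epoch / max(1, epochs - 1))
        order = rng.permutation(N)
        ep_loss = 0.0
        for start in range(0, N, batch_size):
            idx = order[start:start + batch_size]
            loss, grads = net.loss_and_grads(
                X[idx], y[idx],
                None if Jeff is None else Jeff[idx],
                None if gtar is None else gtar[idx],
                w_energy=w_energy, w_grad=w_grad,
            )
            if not np.isfinite(loss):
                raise TrainingDivergenceError(
                    f"non-finite loss at epoch {epoch} (lr={cur_lr:.2e})"
                )
            net.adam_step(grads, cur_lr)
            ep_loss += loss * len(idx)
        history.append(ep_loss / N)
        if callback is not None:
            callback(epoch, history[-1])
    return history
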