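"""Minimal numpy neural-network engine for short-text classification.

Implements exactly the two neural architectures the classifier module
needs — a multi-width convolutional text classifier and a bidirectional
LSTM — with manual gradients and an Adam optimizer supporting either
decoupled weight decay or learning-rate decay.  All randomness (parameter
init, batch shuffling, dropout) flows through a single ``numpy`` Generator,
so training is deterministic given a seed.

The text CNN follows the classic parallel-convolution design: token
embeddings feed parallel 1-d convolutions of several widths with ReLU
activations, global max pooling per filter, a ReLU dense layer with
(inverted) dropout, and a softmax output trained with cross-entropy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["AdamState", "TextCNN", "BiLSTMClassifier", "softmax", "cross_entropy"]


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(probs: np.ndarray, y: np.ndarray) -> float:
    eps = 1e-12
    return float(-np.mean(np.log(probs[np.arange(len(y)), y] + eps)))


@dataclass
class AdamState:
    """Adam with decoupled weight decay ('weight') or lr decay ('lr')."""

    lr: float = 1e-4
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    decay: float = 0.01
    decay_mode: str = "weight"  # 'weight' (decoupled) or 'lr'
    t: int = 0
    m: dict = field(default_factory=dict)
    v: dict = field(default_factory=dict)

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray],
             epoch: int = 0) -> None:
        self.t += 1
        lr = self.lr
        if self.decay_mode == "lr":
            lr = self.lr / (1.0 + self.decay * epoch)
        for name, p in params.items():
            g = grads.get(name)
            if g is None:
                continue
            m = self.m.setdefault(name, np.zeros_like(p))
            v = self.v.setdefault(name, np.zeros_like(p))
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            mhat = m / (1 - self.beta1**self.t)
            vhat = v / (1 - self.beta2**self.t)
            p -= lr * mhat / (np.sqrt(vhat) + self.eps)
            if self.decay_mode == "weight" and name.startswith("W"):
                p -= lr * self.decay * p


def _glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in, fan_out = shape[-1], shape[0]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class TextCNN:
    """Parallel-convolution text classifier over token-index sequences.

    Padding index 0 embeds to a frozen zero vector.  ``predict_proba`` is
    deterministic and batch-order independent (no batch-coupled layers).
    """

    def __init__(self, vocab_size: int, n_classes: int = 2, embedding_dim: int = 300,
                 n_filters: int = 256, kernel_widths: tuple[int, ...] = (3, 4, 5),
                 dense_units: int = 128, dropout: float = 0.1,
                 embeddings: np.ndarray | None = None,
                 train_embeddings: bool = True, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.widths = tuple(kernel_widths)
        self.dropout = dropout
        self.train_embeddings = train_embeddings
        self.rng = rng
        d = embedding_dim
        if embeddings is not None:
            if embeddings.shape != (vocab_size, d):
                raise ValueError("embedding table shape mismatch")
            emb = embeddings.astype(float).copy()
        else:
            emb = 0.1 * rng.standard_normal((vocab_size, d))
        emb[0] = 0.0  # padding row
        self.params: dict[str, np.ndarray] = {"E": emb}
        for w in self.widths:
            self.params[f"Wc{w}"] = _glorot(rng, (n_filters, w * d))
            self.params[f"bc{w}"] = np.zeros(n_filters)
        h = n_filters * len(self.widths)
        self.params["W1"] = _glorot(rng, (dense_units, h))
        self.params["b1"] = np.zeros(dense_units)
        self.params["W2"] = _glorot(rng, (n_classes, dense_units))
        self.params["b2"] = np.zeros(n_classes)
        self.d = d

    def _forward(self, x_idx: np.ndarray, train: bool):
        p = self.params
        x = p["E"][x_idx]  # (B, L, D)
        b, length, d = x.shape
        cache: dict = {"x_idx": x_idx, "x": x}
        pooled = []
        for w in self.widths:
            if length < w:
                pad = np.zeros((b, w - length, d))
                x_w = np.concatenate([x, pad], axis=1)
            else:
                x_w = x
            n_pos = x_w.shape[1] - w + 1
            cols = np.stack(
                [x_w[:, i : i + w, :].reshape(b, w * d) for i in range(n_pos)], axis=1
            )  # (B, P, wD)
            z = cols @ p[f"Wc{w}"].T + p[f"bc{w}"]  # (B, P, F)
            a = np.maximum(z, 0.0)
            arg = a.argmax(axis=1)  # (B, F)
            pool = np.take_along_axis(a, arg[:, None, :], axis=1)[:, 0, :]
            cache[w] = (cols, z, arg)
            pooled.append(pool)
        h = np.concatenate(pooled, axis=1)  # (B, 3F)
        pre1 = h @ p["W1"].T + p["b1"]
        d1 = np.maximum(pre1, 0.0)
        if train and self.dropout > 0:
            keep = 1.0 - self.dropout
            mask = (self.rng.random(d1.shape) < keep) / keep
            d1d = d1 * mask
        else:
            mask = None
            d1d = d1
        logits = d1d @ p["W2"].T + p["b2"]
        probs = softmax(logits)
        cache.update(h=h, pre1=pre1, d1=d1, mask=mask, d1d=d1d, probs=probs)
        return probs, cache

    def predict_proba(self, x_idx: np.ndarray) -> np.ndarray:
        probs, _ = self._forward(np.asarray(x_idx), train=False)
        return probs

    def train_batch(self, x_idx: np.ndarray, y: np.ndarray, opt: AdamState,
                    epoch: int = 0) -> float:
        p = self.params
        probs, cache = self._forward(x_idx, train=True)
        b = len(y)
        loss = cross_entropy(probs, y)
        dlogits = probs.copy()
        dlogits[np.arange(b), y] -= 1.0
        dlogits /= b
        grads: dict[str, np.ndarray] = {}
        grads["W2"] = dlogits.T @ cache["d1d"]
        grads["b2"] = dlogits.sum(axis=0)
        dd1d = dlogits @ p["W2"]
        if cache["mask"] is not None:
            dd1d = dd1d * cache["mask"]
        dpre1 = dd1d * (cache["pre1"] > 0)
        grads["W1"] = dpre1.T @ cache["h"]
        grads["b1"] = dpre1.sum(axis=0)
        dh = dpre1 @ p["W1"]
        n_f = p["W1"].shape[1] // len(self.widths)
        d_emb = np.zeros_like(cache["x"]) if self.train_embeddings else None
        for k, w in enumerate(self.widths):
            cols, z, arg = cache[w]
            dpool = dh[:, k * n_f : (k + 1) * n_f]  # (B, F)
            dz = np.zeros_like(z)
            np.put_along_axis(dz, arg[:, None, :], dpool[:, None, :], axis=1)
            dz *= z > 0
            bsz, n_pos, _ = z.shape
            dz2 = dz.reshape(bsz * n_pos, -1)
            cols2 = cols.reshape(bsz * n_pos, -1)
            grads[f"Wc{w}"] = dz2.T @ cols2
            grads[f"bc{w}"] = dz2.sum(axis=0)
            if d_emb is not None:
                dcols = (dz2 @ p[f"Wc{w}"]).reshape(bsz, n_pos, w, self.d)
                length = cache["x"].shape[1]
                for i in range(n_pos):
                    hi = min(i + w, length)
                    d_emb[:, i:hi, :] += dcols[:, i, : hi - i, :]
        if d_emb is not None:
            d_e = np.zeros_like(p["E"])
            np.add.at(d_e, cache["x_idx"], d_emb)
            d_e[0] = 0.0  # padding stays frozen
            grads["E"] = d_e
        opt.step(p, grads, epoch=epoch)
        p["E"][0] = 0.0
        return loss


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))


class BiLSTMClassifier:
    """Single-layer bidirectional LSTM with a softmax head.

    The two directions' final hidden states (at each sequence's true length)
    are concatenated and fed to the output layer.  Padded steps are masked:
    state carries through them unchanged.
    """

    def __init__(self, vocab_size: int, n_classes: int = 2, embedding_dim: int = 100,
                 hidden: int = 64, embeddings: np.ndarray | None = None,
                 train_embeddings: bool = False, seed: int = 0):
        rng = np.random.default_rng(seed)
        d = embedding_dim
        if embeddings is not None:
            emb = embeddings.astype(float).copy()
        else:
            emb = 0.1 * rng.standard_normal((vocab_size, d))
        emb[0] = 0.0
        self.params = {"E": emb}
        for tag in ("f", "b"):
            self.params[f"Wx{tag}"] = _glorot(rng, (4 * hidden, d))
            self.params[f"Wh{tag}"] = _glorot(rng, (4 * hidden, hidden))
            bias = np.zeros(4 * hidden)
            bias[hidden : 2 * hidden] = 1.0  # forget-gate bias
            self.params[f"bg{tag}"] = bias
        self.params["W2"] = _glorot(rng, (n_classes, 2 * hidden))
        self.params["b2"] = np.zeros(n_classes)
        self.hidden = hidden
        self.train_embeddings = train_embeddings
        self.rng = rng

    def _run_direction(self, x, mask, tag: str):
        p = self.params
        hdim = self.hidden
        b, length, _ = x.shape
        h = np.zeros((b, hdim))
        c = np.zeros((b, hdim))
        steps = range(length) if tag == "f" else range(length - 1, -1, -1)
        caches = []
        for t in steps:
            zbar = x[:, t, :] @ p[f"Wx{tag}"].T + h @ p[f"Wh{tag}"].T + p[f"bg{tag}"]
            i = _sigmoid(zbar[:, :hdim])
            f = _sigmoid(zbar[:, hdim : 2 * hdim])
            o = _sigmoid(zbar[:, 2 * hdim : 3 * hdim])
            g = np.tanh(zbar[:, 3 * hdim :])
            c_new = f * c + i * g
            h_new = o * np.tanh(c_new)
            m = mask[:, t][:, None]
            caches.append((t, h.copy(), c.copy(), i, f, o, g, c_new, m))
            c = m * c_new + (1 - m) * c
            h = m * h_new + (1 - m) * h
        return h, caches

    def _forward(self, x_idx: np.ndarray):
        p = self.params
        x = p["E"][x_idx]
        mask = (x_idx != 0).astype(float)
        # fully padded rows still need a defined state path
        mask[mask.sum(axis=1) == 0, 0] = 1.0
        h_f, cache_f = self._run_direction(x, mask, "f")
        h_b, cache_b = self._run_direction(x, mask, "b")
        feats = np.concatenate([h_f, h_b], axis=1)
        logits = feats @ p["W2"].T + p["b2"]
        probs = softmax(logits)
        return probs, {
            "x": x, "x_idx": x_idx, "mask": mask, "feats": feats,
            "cache_f": cache_f, "cache_b": cache_b,
        }

    def predict_proba(self, x_idx: np.ndarray) -> np.ndarray:
        probs, _ = self._forward(np.asarray(x_idx))
        return probs

    def _backprop_direction(self, dh_final, cache, tag: str, grads, dx):
        p = self.params
        hdim = self.hidden
        dh = dh_final
        dc = np.zeros_like(dh_final)
        g_wx = np.zeros_like(p[f"Wx{tag}"])
        g_wh = np.zeros_like(p[f"Wh{tag}"])
        g_b = np.zeros_like(p[f"bg{tag}"])
        for t, h_prev, c_prev, i, f, o, g, c_new, m in reversed(cache):
            dh_new = dh * m
            dc_carry = dc * (1 - m)
            dc_new = dc * m
            tanh_c = np.tanh(c_new)
            do = dh_new * tanh_c
            dc_new = dc_new + dh_new * o * (1 - tanh_c**2)
            di = dc_new * g
            df = dc_new * c_prev
            dg = dc_new * i
            dzbar = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), do * o * (1 - o),
                 dg * (1 - g**2)], axis=1,
            )
            x_t = self._x_cache[:, t, :]
            g_wx += dzbar.T @ x_t
            g_wh += dzbar.T @ h_prev
            g_b += dzbar.sum(axis=0)
            dx[:, t, :] += dzbar @ p[f"Wx{tag}"]
            dh = dh * (1 - m) + dzbar @ p[f"Wh{tag}"]
            dc = dc_carry + dc_new * f
        grads[f"Wx{tag}"] = g_wx
        grads[f"Wh{tag}"] = g_wh
        grads[f"bg{tag}"] = g_b

    def train_batch(self, x_idx: np.ndarray, y: np.ndarray, opt: AdamState,
                    epoch: int = 0) -> float:
        p = self.params
        probs, cache = self._forward(x_idx)
        b = len(y)
        loss = cross_entropy(probs, y)
        dlogits = probs.copy()
        dlogits[np.arange(b), y] -= 1.0
        dlogits /= b
        grads: dict[str, np.ndarray] = {
            "W2": dlogits.T @ cache["feats"],
            "b2": dlogits.sum(axis=0),
        }
        dfeats = dlogits @ p["W2"]
        hdim = self.hidden
        self._x_cache = cache["x"]
        dx = np.zeros_like(cache["x"])
        self._backprop_direction(dfeats[:, :hdim], cache["cache_f"], "f", grads, dx)
        self._backprop_direction(dfeats[:, hdim:], cache["cache_b"], "b", grads, dx)
        if self.train_embeddings:
            d_e = np.zeros_like(p["E"])
            np.add.at(d_e, cache["x_idx"], dx)
            d_e[0] = 0.0
            grads["E"] = d_e
        opt.step(p, grads, epoch=epoch)
        p["E"][0] = 0.0
        del self._x_cache
        return loss
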