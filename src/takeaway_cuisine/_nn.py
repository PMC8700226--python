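"""Minimal neural-network engine for the character models.

A small, self-contained NumPy implementation of exactly what the
character classifier needs: an embedding layer, a stacked LSTM with
full backpropagation through time, a tied next-character softmax head,
a concat-pooled classification head, inverted dropout, global-norm
gradient clipping and Adam.  Names are short (tens of characters), so
sequences are processed end to end without truncation; everything is
float32 and deterministic given the caller's Generator.

Shapes: batches are (B, T) int token ids right-padded with ``pad_id``;
hidden activations are (B, T, H).
"""

from __future__ import annotations

import numpy as np

__all__ = ["CharRNN", "Adam", "pad_batch", "softmax"]

_CLIP_NORM = 5.0


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def pad_batch(seqs: list[list[int]], pad_id: int) -> tuple[np.ndarray, np.ndarray]:
    """Right-pad token sequences to a (B, T) id array plus lengths."""
    lengths = np.array([len(s) for s in seqs], dtype=np.int64)
    ids = np.full((len(seqs), int(lengths.max())), pad_id, dtype=np.int64)
    for i, s in enumerate(seqs):
        ids[i, : len(s)] = s
    return ids, lengths


class Adam:
    """Adam with bias correction over a dict of parameter arrays."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 3e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray],
             lr: float | None = None, frozen: set[str] = frozenset()) -> None:
        lr = self.lr if lr is None else lr
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for k, g in grads.items():
            if k in frozen:
                continue
            m = self.m[k]
            v = self.v[k]
            m += (1.0 - self.beta1) * (g - m)
            v += (1.0 - self.beta2) * (g * g - v)
            params[k] -= lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def clip_grads(grads: dict[str, np.ndarray], max_norm: float = _CLIP_NORM) -> None:
    total = np.sqrt(sum(float((g * g).sum()) for g in grads.values()))
    if total > max_norm:
        scale = max_norm / (total + 1e-12)
        for g in grads.values():
            g *= scale


class CharRNN:
    """Embedding + stacked LSTM encoder with a language-model head and an
    optional concat-pooled classification head."""

    def __init__(self, vocab_size: int, embedding_dim: int, hidden_dim: int,
                 n_layers: int, n_classes: int | None, rng: np.random.Generator):
        self.vocab_size = vocab_size
        self.embedding_dim = embedding_dim
        self.hidden_dim = hidden_dim
        self.n_layers = n_layers
        self.n_classes = n_classes

        def init(shape, fan_in):
            return rng.normal(0.0, 1.0 / np.sqrt(fan_in), size=shape).astype(np.float32)

        H = hidden_dim
        p: dict[str, np.ndarray] = {"emb": init((vocab_size, embedding_dim), embedding_dim)}
        for layer in range(n_layers):
            d_in = embedding_dim if layer == 0 else H
            p[f"Wx{layer}"] = init((d_in, 4 * H), d_in)
            p[f"Wh{layer}"] = init((H, 4 * H), H)
            b = np.zeros(4 * H, dtype=np.float32)
            b[H:2 * H] = 1.0  # forget-gate bias: remember by default
            p[f"b{layer}"] = b
        p["lm_W"] = init((H, vocab_size), H)
        p["lm_b"] = np.zeros(vocab_size, dtype=np.float32)
        self.params = p
        if n_classes is not None:
            self.add_head(n_classes, rng)

    def add_head(self, n_classes: int, rng: np.random.Generator) -> None:
        H = self.hidden_dim
        if not hasattr(self, "params"):
            self.params = {}
        self.params["head_W"] = rng.normal(
            0.0, 1.0 / np.sqrt(3 * H), size=(3 * H, n_classes)
        ).astype(np.float32)
        self.params["head_b"] = np.zeros(n_classes, dtype=np.float32)
        self.n_classes = n_classes

    # ------------------------------------------------------------------ #
    # encoder

    def _encode(self, ids: np.ndarray, *, dropout: float = 0.0,
                rng: np.random.Generator | None = None):
        """Run the stacked LSTM.  Returns the top-layer hidden states
        (B, T, H) and the caches needed for backprop."""
        p = self.params
        B, T = ids.shape
        H = self.hidden_dim
        x = p["emb"][ids]  # (B, T, E)
        caches = []
        drop_masks = []
        inp = x
        for layer in range(self.n_layers):
            Wx, Wh, b = p[f"Wx{layer}"], p[f"Wh{layer}"], p[f"b{layer}"]
            xW = inp.reshape(B * T, -1) @ Wx
            xW = xW.reshape(B, T, 4 * H) + b
            h = np.zeros((B, H), dtype=np.float32)
            c = np.zeros((B, H), dtype=np.float32)
            I = np.empty((B, T, H), dtype=np.float32)
            F = np.empty_like(I)
            G = np.empty_like(I)
            O = np.empty_like(I)
            TC = np.empty_like(I)
            CP = np.empty_like(I)  # c_{t-1}
            Hs = np.empty_like(I)
            for t in range(T):
                z = xW[:, t] + h @ Wh
                i = sigmoid(z[:, :H])
                f = sigmoid(z[:, H:2 * H])
                g = np.tanh(z[:, 2 * H:3 * H])
                o = sigmoid(z[:, 3 * H:])
                CP[:, t] = c
                c = f * c + i * g
                tc = np.tanh(c)
                h = o * tc
                I[:, t], F[:, t], G[:, t], O[:, t], TC[:, t], Hs[:, t] = i, f, g, o, tc, h
            caches.append((inp, I, F, G, O, TC, CP, Hs))
            out = Hs
            if dropout > 0.0 and rng is not None:
                mask = (rng.random(out.shape) >= dropout).astype(np.float32) / (1.0 - dropout)
                out = out * mask
                drop_masks.append(mask)
            else:
                drop_masks.append(None)
            inp = out
        return inp, caches, drop_masks, ids

    def _encoder_backward(self, dTop: np.ndarray, caches, drop_masks, ids,
                          grads: dict[str, np.ndarray]) -> None:
        """Backprop ``dTop`` (grad wrt the possibly-dropped top output)
        through all LSTM layers down to the embedding."""
        p = self.params
        B, T = ids.shape
        H = self.hidden_dim
        d_out = dTop
        for layer in range(self.n_layers - 1, -1, -1):
            inp, I, F, G, O, TC, CP, Hs = caches[layer]
            mask = drop_masks[layer]
            dH = d_out * mask if mask is not None else d_out.copy()
            Wx, Wh = p[f"Wx{layer}"], p[f"Wh{layer}"]
            dZ = np.empty((B, T, 4 * H), dtype=np.float32)
            dh_next = np.zeros((B, H), dtype=np.float32)
            dc_next = np.zeros((B, H), dtype=np.float32)
            for t in range(T - 1, -1, -1):
                dh = dH[:, t] + dh_next
                i, f, g, o, tc, cp = I[:, t], F[:, t], G[:, t], O[:, t], TC[:, t], CP[:, t]
                do = dh * tc
                dtc = dh * o * (1.0 - tc * tc) + dc_next
                di = dtc * g
                df = dtc * cp
                dg = dtc * i
                dz = dZ[:, t]
                dz[:, :H] = di * i * (1.0 - i)
                dz[:, H:2 * H] = df * f * (1.0 - f)
                dz[:, 2 * H:3 * H] = dg * (1.0 - g * g)
                dz[:, 3 * H:] = do * o * (1.0 - o)
                dh_next = dz @ Wh.T
                dc_next = dtc * f
            h_prev = np.concatenate(
                [np.zeros((B, 1, H), dtype=np.float32), Hs[:, :-1]], axis=1
            )
            dZ2 = dZ.reshape(B * T, 4 * H)
            grads[f"Wx{layer}"] = grads.get(f"Wx{layer}", 0) + inp.reshape(B * T, -1).T @ dZ2
            grads[f"Wh{layer}"] = grads.get(f"Wh{layer}", 0) + h_prev.reshape(B * T, H).T @ dZ2
            grads[f"b{layer}"] = grads.get(f"b{layer}", 0) + dZ2.sum(axis=0)
            d_out = (dZ2 @ Wx.T).reshape(B, T, -1)
        # embedding gradient
        demb = np.zeros_like(p["emb"])
        np.add.at(demb, ids.reshape(-1), d_out.reshape(B * T, -1))
        grads["emb"] = grads.get("emb", 0) + demb

    # ------------------------------------------------------------------ #
    # language-model objective

    def lm_loss_and_grads(self, ids: np.ndarray, lengths: np.ndarray, pad_id: int,
                          *, dropout: float = 0.0,
                          rng: np.random.Generator | None = None,
                          backward: bool = True):
        """Mean next-token cross-entropy (nats) over non-pad targets.

        Inputs are ``ids[:, :-1]`` predicting ``ids[:, 1:]``.
        """
        p = self.params
        X = ids[:, :-1]
        Y = ids[:, 1:]
        mask = (Y != pad_id).astype(np.float32)
        top, caches, drop_masks, _ = self._encode(X, dropout=dropout, rng=rng)
        B, T, H = top.shape
        logits = top.reshape(B * T, H) @ p["lm_W"] + p["lm_b"]
        probs = softmax(logits)
        n_tok = float(mask.sum())
        flat_mask = mask.reshape(-1)
        logp = -np.log(probs[np.arange(B * T), Y.reshape(-1)] + 1e-12)
        loss = float((logp * flat_mask).sum() / n_tok)
        if not backward:
            return loss, None
        dlogits = probs
        dlogits[np.arange(B * T), Y.reshape(-1)] -= 1.0
        dlogits *= (flat_mask / n_tok)[:, None]
        grads: dict[str, np.ndarray] = {
            "lm_W": top.reshape(B * T, H).T @ dlogits,
            "lm_b": dlogits.sum(axis=0),
        }
        dTop = (dlogits @ p["lm_W"].T).reshape(B, T, H)
        self._encoder_backward(dTop, caches, drop_masks, X, grads)
        clip_grads(grads)
        return loss, grads

    # ------------------------------------------------------------------ #
    # classification objective

    def _pool(self, top: np.ndarray, lengths: np.ndarray):
        """Concat pooling over valid timesteps: [h_last, max, mean]."""
        B, T, H = top.shape
        valid = (np.arange(T)[None, :] < lengths[:, None])
        last = top[np.arange(B), lengths - 1]
        neg = np.where(valid[:, :, None], top, -np.inf)
        mx = neg.max(axis=1)
        argmx = neg.argmax(axis=1)
        mean = (top * valid[:, :, None]).sum(axis=1) / lengths[:, None].astype(np.float32)
        pooled = np.concatenate([last, mx, mean], axis=1)
        return pooled, (valid, argmx)

    def clf_forward(self, ids: np.ndarray, lengths: np.ndarray, *,
                    dropout: float = 0.0, rng: np.random.Generator | None = None):
        top, caches, drop_masks, _ = self._encode(ids, dropout=dropout, rng=rng)
        pooled, pool_cache = self._pool(top, lengths)
        logits = pooled @ self.params["head_W"] + self.params["head_b"]
        return logits, (top, caches, drop_masks, ids, lengths, pooled, pool_cache)

    def clf_loss_and_grads(self, ids: np.ndarray, lengths: np.ndarray, y: np.ndarray,
                           *, dropout: float = 0.0,
                           rng: np.random.Generator | None = None):
        """Mean cross-entropy over the batch; returns (loss, grads)."""
        logits, cache = self.clf_forward(ids, lengths, dropout=dropout, rng=rng)
        top, caches, drop_masks, ids_, lengths_, pooled, (valid, argmx) = cache
        B = len(y)
        probs = softmax(logits)
        loss = float(-np.log(probs[np.arange(B), y] + 1e-12).mean())
        dlogits = probs
        dlogits[np.arange(B), y] -= 1.0
        dlogits /= B
        grads: dict[str, np.ndarray] = {
            "head_W": pooled.T @ dlogits,
            "head_b": dlogits.sum(axis=0),
        }
        dpooled = dlogits @ self.params["head_W"].T
        H = self.hidden_dim
        B_, T, _ = top.shape
        dTop = np.zeros_like(top)
        # last-hidden part
        dTop[np.arange(B_), lengths_ - 1] += dpooled[:, :H]
        # max-pool part: route to the argmax timestep of each unit
        bi = np.repeat(np.arange(B_), H)
        dTop[bi, argmx.reshape(-1), np.tile(np.arange(H), B_)] += dpooled[:, H:2 * H].reshape(-1)
        # mean-pool part
        dTop += (dpooled[:, 2 * H:] / lengths_[:, None].astype(np.float32))[:, None, :] \
            * valid[:, :, None]
        self._encoder_backward(dTop, caches, drop_masks, ids_, grads)
        clip_grads(grads)
        return loss, grads

    def predict_proba(self, ids: np.ndarray, lengths: np.ndarray) -> np.ndarray:
        logits, _ = self.clf_forward(ids, lengths)
        return softmax(logits)

    # ------------------------------------------------------------------ #
    # state handling

    def copy_params(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def set_params_(self, params: dict[str, np.ndarray]) -> None:
        self.params = {k: v.copy() for k, v in params.items()}

    def encoder_param_names(self) -> list[str]:
        names = ["emb"]
        for layer in range(self.n_layers):
            names += [f"Wx{layer}", f"Wh{layer}", f"b{layer}"]
        return names
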