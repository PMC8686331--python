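"""Recurrent feature extractor for encoded mutation sequences.

A two-layer LSTM reads the encoded matrix from both ends toward the
mutation site (the two directional reads share weights, so one reader is
applied to both orderings).  The final hidden states of the two reads are
concatenated and mapped through one fully connected layer to a short
feature vector (8 dimensions by default) — the input ``x`` of the SOM
stage.  Because recency dominates a recurrent read, placing the mutation
row at the end of both reads maximizes its influence on the output.

Training fits the extractor's outputs to externally supplied label
vectors (the SOM-updated feature vectors) by mean squared error with the
Adam optimizer.  Forward and backward passes are implemented directly in
numpy; gradients are exercised against numerical differentiation in the
test suite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .encoding import EncodedMutation, encode_batch


@dataclass
class ExtractorConfig:
    hidden_layers: int = 2
    hidden_size: int = 64
    feature_dim: int = 8
    learning_rate: float = 0.001
    fit_iterations_per_round: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.feature_dim < 1:
            raise ValueError("feature_dim must be >= 1")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class _LSTMLayer:
    """One LSTM layer with gate order (input, forget, cell, output)."""

    def __init__(self, input_dim: int, hidden: int, rng: np.random.Generator):
        k = 1.0 / np.sqrt(hidden)
        self.Wx = rng.uniform(-k, k, size=(input_dim, 4 * hidden))
        self.Wh = rng.uniform(-k, k, size=(hidden, 4 * hidden))
        self.b = rng.uniform(-k, k, size=4 * hidden)
        self.hidden = hidden

    def params(self):
        return [self.Wx, self.Wh, self.b]

    def forward(self, x: np.ndarray, want_cache: bool = False):
        """x: (B, T, D) -> hidden sequence (B, T, H) [+ cache for backward]."""
        B, T, _ = x.shape
        H = self.hidden
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        h_seq = np.empty((B, T, H))
        cache = [] if want_cache else None
        for t in range(T):
            z = x[:, t] @ self.Wx + h @ self.Wh + self.b
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H:2 * H])
            g = np.tanh(z[:, 2 * H:3 * H])
            o = _sigmoid(z[:, 3 * H:])
            c_new = f * c + i * g
            tanh_c = np.tanh(c_new)
            h_new = o * tanh_c
            if want_cache:
                cache.append((x[:, t], h, c, i, f, g, o, tanh_c))
            h, c = h_new, c_new
            h_seq[:, t] = h
        return (h_seq, cache) if want_cache else h_seq

    def backward(self, dh_seq: np.ndarray, cache) -> tuple[np.ndarray, list]:
        """Backprop through time.

        dh_seq: (B, T, H) upstream gradient on every hidden output.
        Returns (dx_seq, [dWx, dWh, db]).
        """
        B, T, H = dh_seq.shape
        dWx = np.zeros_like(self.Wx)
        dWh = np.zeros_like(self.Wh)
        db = np.zeros_like(self.b)
        dx_seq = np.empty((B, T, self.Wx.shape[0]))
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            x_t, h_prev, c_prev, i, f, g, o, tanh_c = cache[t]
            dh = dh_seq[:, t] + dh_next
            do = dh * tanh_c
            dc = dc_next + dh * o * (1.0 - tanh_c ** 2)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g ** 2),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            dWx += x_t.T @ dz
            dWh += h_prev.T @ dz
            db += dz.sum(axis=0)
            dx_seq[:, t] = dz @ self.Wx.T
            dh_next = dz @ self.Wh.T
            dc_next = dc * f
        return dx_seq, [dWx, dWh, db]


class FeatureExtractor:
    """Bidirectional-read LSTM mapping encoded mutations to feature vectors."""

    def __init__(self, config: Optional[ExtractorConfig] = None, input_dim: int = 4):
        self.config = config or ExtractorConfig()
        self.input_dim = input_dim
        rng = np.random.default_rng(self.config.seed)
        H = self.config.hidden_size
        self.layers = []
        d = input_dim
        for _ in range(self.config.hidden_layers):
            self.layers.append(_LSTMLayer(d, H, rng))
            d = H
        k = 1.0 / np.sqrt(2 * H)
        self.W_out = rng.uniform(-k, k, size=(2 * H, self.config.feature_dim))
        self.b_out = rng.uniform(-k, k, size=self.config.feature_dim)
        self._adam_state: Optional[list] = None
        self._adam_t = 0

    # -- parameter bookkeeping -------------------------------------------
    def _params(self) -> list[np.ndarray]:
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        out.extend([self.W_out, self.b_out])
        return out

    # -- forward ----------------------------------------------------------
    @staticmethod
    def _directional_reads(batch: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Split (B, 2F+1, 4) into the two reads ending at the site row."""
        n = batch.shape[1]
        if n % 2 != 1:
            raise ValueError(f"encoded length must be odd (2F+1), got {n}")
        s = n // 2
        fwd = batch[:, : s + 1, :]
        rev = batch[:, s:, :][:, ::-1, :]
        return np.ascontiguousarray(fwd), np.ascontiguousarray(rev)

    def _forward_read(self, x: np.ndarray, want_cache: bool):
        caches = []
        h_seq = x
        for layer in self.layers:
            if want_cache:
                h_seq, cache = layer.forward(h_seq, want_cache=True)
                caches.append(cache)
            else:
                h_seq = layer.forward(h_seq)
        h_final = h_seq[:, -1]
        return (h_final, h_seq.shape[1], caches) if want_cache else h_final

    def _coerce(self, batch) -> np.ndarray:
        if isinstance(batch, np.ndarray):
            arr = batch.astype(np.float64, copy=False)
        else:
            seqs = list(batch)
            if seqs and isinstance(seqs[0], EncodedMutation):
                sites = {e.site_index for e in seqs}
                if len(sites) > 1:
                    raise ValueError(f"mixed site indices in batch: {sorted(sites)}")
                arr = np.stack([e.matrix for e in seqs]).astype(np.float64)
            else:
                arr = encode_batch(seqs)
        if arr.ndim != 3 or arr.shape[2] != 4:
            raise ValueError(f"batch must be (B, n, 4), got {arr.shape}")
        return arr

    def extract_features(self, batch) -> np.ndarray:
        """Feature vectors (B, feature_dim); deterministic at fixed weights."""
        arr = self._coerce(batch)
        fwd, rev = self._directional_reads(arr)
        h_f = self._forward_read(fwd, want_cache=False)
        h_r = self._forward_read(rev, want_cache=False)
        return np.concatenate([h_f, h_r], axis=1) @ self.W_out + self.b_out

    # -- training ---------------------------------------------------------
    def _forward_backward(self, arr: np.ndarray, labels: np.ndarray):
        fwd, rev = self._directional_reads(arr)
        h_f, T_f, caches_f = self._forward_read(fwd, want_cache=True)
        h_r, T_r, caches_r = self._forward_read(rev, want_cache=True)
        concat = np.concatenate([h_f, h_r], axis=1)
        out = concat @ self.W_out + self.b_out
        resid = out - labels
        loss = float(np.mean(resid ** 2))

        B, K = out.shape
        dout = 2.0 * resid / (B * K)
        dW_out = concat.T @ dout
        db_out = dout.sum(axis=0)
        dconcat = dout @ self.W_out.T
        H = self.config.hidden_size

        grads = [np.zeros_like(p) for p in self._params()]
        per_layer = 3
        for dh_final, caches, T in (
            (dconcat[:, :H], caches_f, T_f),
            (dconcat[:, H:], caches_r, T_r),
        ):
            dh_seq = np.zeros((B, T, H))
            dh_seq[:, -1] = dh_final
            upstream = dh_seq
            for li in range(len(self.layers) - 1, -1, -1):
                upstream, layer_grads = self.layers[li].backward(upstream, caches[li])
                for k, g in enumerate(layer_grads):
                    grads[li * per_layer + k] += g
        grads[-2] += dW_out
        grads[-1] += db_out
        return loss, grads

    def _adam_step(self, grads: list[np.ndarray]) -> None:
        lr = self.config.learning_rate
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        params = self._params()
        if self._adam_state is None:
            self._adam_state = [
                (np.zeros_like(p), np.zeros_like(p)) for p in params
            ]
        self._adam_t += 1
        t = self._adam_t
        for p, g, (m, v) in zip(params, grads, self._adam_state):
            m *= beta1
            m += (1 - beta1) * g
            v *= beta2
            v += (1 - beta2) * g ** 2
            m_hat = m / (1 - beta1 ** t)
            v_hat = v / (1 - beta2 ** t)
            p -= lr * m_hat / (np.sqrt(v_hat) + eps)

    def fit_to_labels(self, batch, labels, iterations: Optional[int] = None) -> float:
        """Fit outputs to label vectors by MSE; returns the last-pass loss.

        Runs ``fit_iterations_per_round`` full-batch gradient passes (2 by
        default) at the configured learning rate.
        """
        arr = self._coerce(batch)
        labels = np.asarray(labels, dtype=np.float64)
        if labels.ndim != 2 or labels.shape != (arr.shape[0], self.config.feature_dim):
            raise ValueError(
                f"labels must be ({arr.shape[0]}, {self.config.feature_dim}), "
                f"got {labels.shape}"
            )
        if not np.all(np.isfinite(labels)):
            raise ValueError("labels contain non-finite values")
        n_iter = self.config.fit_iterations_per_round if iterations is None else iterations
        loss = float(np.mean((self.extract_features(arr) - labels) ** 2))
        for _ in range(n_iter):
            loss, grads = self._forward_backward(arr, labels)
            if self.config.learning_rate > 0:
                self._adam_step(grads)
        return loss

    # -- persistence ------------------------------------------------------
    def save(self, path: str | Path) -> None:
        arrays = {f"p{i}": p for i, p in enumerate(self._params())}
        arrays["config"] = np.frombuffer(
            json.dumps(asdict(self.config)).encode(), dtype=np.uint8
        )
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "FeatureExtractor":
        data = np.load(path)
        config = ExtractorConfig(**json.loads(bytes(data["config"]).decode()))
        obj = cls(config)
        for i, p in enumerate(obj._params()):
            p[...] = data[f"p{i}"]
        return obj
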