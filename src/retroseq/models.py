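"""Encoder-decoder cores for retrosynthetic SMILES translation.

Two architectures are provided behind one interface:

* ``seq2seq`` — a bidirectional-LSTM encoder (one LSTM reads the source
  forward, one backward; their states are concatenated) with a
  unidirectional LSTM decoder whose input is augmented by an additive
  (Bahdanau-style) attention context over the encoder states.
* ``transformer`` — stacked multi-head self-attention + position-wise
  feed-forward blocks with post-norm residual connections (residual add,
  then layer normalization), sinusoidal position encodings, and a causally
  masked decoder self-attention plus encoder-decoder cross-attention.

Both expose teacher-forced training logits and an incremental decoding
interface (``encode`` / ``init_state`` / ``step`` / ``reorder_state``) used
by greedy decoding and beam search. All weights live in a flat name->Tensor
dict, which is what gets checkpointed and transferred.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import yaml

from .nn import (
    Tensor,
    concat,
    dropout,
    embedding,
    layer_norm,
    no_grad,
    stack,
)
from .vocab import TokenVocabulary

__all__ = [
    "ModelConfig",
    "Seq2SeqModel",
    "TransformerModel",
    "build_model",
    "build_seq2seq",
    "build_transformer",
    "save_checkpoint",
    "load_checkpoint",
]

NEG_INF = -1e9


@dataclass
class ModelConfig:
    """Architecture and optimization hyperparameters.

    Defaults follow the described architectures (six identical decoder
    layers for the transformer, mirrored by the encoder); the ``desk_*``
    constructors shrink every dimension to sizes that train in minutes on
    one CPU while keeping the architecture itself intact.
    """

    architecture: str = "transformer"
    # seq2seq dims
    embedding_dim: int = 256
    hidden_dim: int = 256  # per direction in the encoder
    # transformer dims
    model_dim: int = 256
    ff_dim: int = 1024
    n_heads: int = 8
    n_encoder_layers: int = 6
    n_decoder_layers: int = 6
    dropout: float = 0.1
    max_sequence_length: int = 200
    # optimization
    learning_rate: float = 1e-3
    schedule: str = "warmup"  # "constant" | "warmup"
    warmup_steps: int = 200
    batch_size: int = 64
    max_steps: int = 2000
    eval_every: int = 250
    eval_subset: int = 150  # validation examples per periodic evaluation
    grad_clip: float = 1.0
    label_smoothing: float = 0.0
    decode_max_len: int = 200
    eval_backend: str = "passthrough"  # canonicalization backend for matching
    seed: int = 0

    def __post_init__(self):
        if self.architecture not in ("seq2seq", "transformer"):
            raise ValueError(f"unknown architecture: {self.architecture!r}")
        if self.architecture == "transformer" and self.model_dim % self.n_heads:
            raise ValueError(
                f"model_dim ({self.model_dim}) must be divisible by n_heads ({self.n_heads})"
            )
        for name in ("embedding_dim", "hidden_dim", "model_dim", "ff_dim",
                     "n_heads", "n_encoder_layers", "n_decoder_layers"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def desk_transformer(cls, **overrides) -> "ModelConfig":
        """A tiny transformer that converges on the synthetic grammar in minutes."""
        base = dict(
            architecture="transformer",
            model_dim=64,
            ff_dim=128,
            n_heads=4,
            n_encoder_layers=2,
            n_decoder_layers=2,
            # the synthetic grammar is deterministic, so the tiny model is
            # trained without dropout; reference-scale defaults keep 0.1
            dropout=0.0,
            learning_rate=2e-3,
            schedule="warmup",
            warmup_steps=200,
            batch_size=64,
            decode_max_len=96,
            max_sequence_length=96,
        )
        base.update(overrides)
        return cls(**base)

    @classmethod
    def desk_seq2seq(cls, **overrides) -> "ModelConfig":
        base = dict(
            architecture="seq2seq",
            embedding_dim=64,
            hidden_dim=64,
            n_encoder_layers=1,
            n_decoder_layers=1,
            dropout=0.1,
            learning_rate=2e-3,
            schedule="constant",
            batch_size=64,
            decode_max_len=96,
            max_sequence_length=96,
        )
        base.update(overrides)
        return cls(**base)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)


def _glorot(rng: np.random.Generator, shape: Tuple[int, ...]) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


class _Model:
    """Shared parameter plumbing for both cores."""

    def __init__(self, config: ModelConfig, vocab: TokenVocabulary):
        self.config = config
        self.vocab = vocab
        self.params: Dict[str, Tensor] = {}
        self._init_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
        self._dropout_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 13]))

    def _param(self, name: str, shape: Tuple[int, ...], init: str = "glorot") -> Tensor:
        if init == "zeros":
            data = np.zeros(shape, dtype=np.float32)
        elif init == "ones":
            data = np.ones(shape, dtype=np.float32)
        elif init == "normal":
            data = (self._init_rng.standard_normal(shape) * 0.02).astype(np.float32)
        else:
            data = _glorot(self._init_rng, shape)
        t = Tensor(data, requires_grad=True)
        self.params[name] = t
        return t

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.params.values())

    def state_dict(self) -> Dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.params.items()}

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        if set(state) != set(self.params):
            missing = set(self.params) - set(state)
            extra = set(state) - set(self.params)
            raise ValueError(f"state dict mismatch: missing={sorted(missing)}, extra={sorted(extra)}")
        for k, p in self.params.items():
            if state[k].shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}: {state[k].shape} vs {p.data.shape}")
            p.data = state[k].astype(np.float32).copy()

    def _drop(self, x: Tensor, train: bool) -> Tensor:
        if not train:
            return x
        return dropout(x, self.config.dropout, self._dropout_rng)


# ---------------------------------------------------------------------------
# seq2seq: BLSTM encoder, LSTM decoder with additive attention
# ---------------------------------------------------------------------------


def _lstm_step(params, prefix, x: Tensor, h: Tensor, c: Tensor) -> Tuple[Tensor, Tensor]:
    gates = x @ params[f"{prefix}.Wx"] + h @ params[f"{prefix}.Wh"] + params[f"{prefix}.b"]
    i, f, g, o = gates.chunk(4, axis=-1)
    c_new = f.sigmoid() * c + i.sigmoid() * g.tanh()
    h_new = o.sigmoid() * c_new.tanh()
    return h_new, c_new


class Seq2SeqModel(_Model):
    def __init__(self, config: ModelConfig, vocab: TokenVocabulary):
        super().__init__(config, vocab)
        V, E, H = len(vocab), config.embedding_dim, config.hidden_dim
        A = H  # additive-attention projection width
        self._param("src_embed", (V, E), "normal")
        self._param("tgt_embed", (V, E), "normal")
        for l in range(config.n_encoder_layers):
            in_dim = E if l == 0 else 2 * H
            for d in ("fwd", "bwd"):
                self._lstm_params(f"enc{l}.{d}", in_dim, H)
        for l in range(config.n_decoder_layers):
            in_dim = (E + 2 * H) if l == 0 else H
            self._lstm_params(f"dec{l}", in_dim, H)
        # additive attention: score = v . tanh(Wq h + Uk enc)
        self._param("attn.Wq", (H, A))
        self._param("attn.Uk", (2 * H, A))
        self._param("attn.v", (A, 1))
        # bridge from masked-mean encoder state to decoder initial states
        for l in range(config.n_decoder_layers):
            self._param(f"bridge{l}.W", (2 * H, H))
            self._param(f"bridge{l}.b", (H,), "zeros")
        self._param("out.Wc", (H + 2 * H, E))
        self._param("out.bc", (E,), "zeros")
        self._param("out.W", (E, V))
        self._param("out.b", (V,), "zeros")

    def _lstm_params(self, prefix: str, in_dim: int, hidden: int) -> None:
        self._param(f"{prefix}.Wx", (in_dim, 4 * hidden))
        self._param(f"{prefix}.Wh", (hidden, 4 * hidden))
        b = np.zeros(4 * hidden, dtype=np.float32)
        b[hidden : 2 * hidden] = 1.0  # forget-gate bias
        self.params[f"{prefix}.b"] = Tensor(b, requires_grad=True)

    # -- encoder ------------------------------------------------------------
    def encode(self, src_ids: np.ndarray, train: bool = False) -> dict:
        B, S = src_ids.shape
        H = self.config.hidden_dim
        mask = (src_ids != 0).astype(np.float32)  # (B,S)
        xs: List[Tensor] = [
            self._drop(embedding(self.params["src_embed"], src_ids[:, t]), train)
            for t in range(S)
        ]
        # PAD positions must not perturb the recurrent state (the backward
        # direction starts at the padded tail), so updates are masked.
        keep = [Tensor(mask[:, t : t + 1]) for t in range(S)]
        drop_ = [Tensor(1.0 - mask[:, t : t + 1]) for t in range(S)]
        for l in range(self.config.n_encoder_layers):
            fwd_h, fwd_c = Tensor(np.zeros((B, H), np.float32)), Tensor(np.zeros((B, H), np.float32))
            bwd_h, bwd_c = Tensor(np.zeros((B, H), np.float32)), Tensor(np.zeros((B, H), np.float32))
            fwd_out, bwd_out = [], [None] * S
            for t in range(S):
                h, c = _lstm_step(self.params, f"enc{l}.fwd", xs[t], fwd_h, fwd_c)
                fwd_h = keep[t] * h + drop_[t] * fwd_h
                fwd_c = keep[t] * c + drop_[t] * fwd_c
                fwd_out.append(fwd_h)
            for t in reversed(range(S)):
                h, c = _lstm_step(self.params, f"enc{l}.bwd", xs[t], bwd_h, bwd_c)
                bwd_h = keep[t] * h + drop_[t] * bwd_h
                bwd_c = keep[t] * c + drop_[t] * bwd_c
                bwd_out[t] = bwd_h
            xs = [self._drop(concat([f, b], axis=-1), train) for f, b in zip(fwd_out, bwd_out)]
        enc_out = stack(xs, axis=1)  # (B,S,2H)
        # masked mean over time for the decoder-state bridge
        m = mask[:, :, None]
        mean = (enc_out * Tensor(m)).sum(axis=1) * Tensor(
            (1.0 / np.maximum(mask.sum(axis=1, keepdims=True), 1.0)).astype(np.float32)
        )
        uk = enc_out @ self.params["attn.Uk"]  # (B,S,A), precomputed keys
        init_h = [
            ((mean @ self.params[f"bridge{l}.W"]) + self.params[f"bridge{l}.b"]).tanh()
            for l in range(self.config.n_decoder_layers)
        ]
        return {"enc_out": enc_out, "uk": uk, "mask": mask, "init_h": init_h}

    def _attend(self, memory: dict, h_top: Tensor) -> Tensor:
        B, S = memory["mask"].shape
        q = (h_top @ self.params["attn.Wq"]).reshape(B, 1, -1)
        e = (q + memory["uk"]).tanh() @ self.params["attn.v"]  # (B,S,1)
        bias = (1.0 - memory["mask"])[:, :, None] * NEG_INF
        a = (e + Tensor(bias.astype(np.float32))).softmax(axis=1)  # (B,S,1)
        ctx = a.transpose(0, 2, 1) @ memory["enc_out"]  # (B,1,2H)
        return ctx.reshape(B, -1)

    def _decode_step(self, memory: dict, y_ids: np.ndarray, hs, cs, ctx, train: bool):
        y = self._drop(embedding(self.params["tgt_embed"], y_ids), train)
        x = concat([y, ctx], axis=-1)
        new_hs, new_cs = [], []
        for l in range(self.config.n_decoder_layers):
            h, c = _lstm_step(self.params, f"dec{l}", x, hs[l], cs[l])
            new_hs.append(h)
            new_cs.append(c)
            x = h
        ctx_new = self._attend(memory, new_hs[-1])
        feat = (concat([new_hs[-1], ctx_new], axis=-1) @ self.params["out.Wc"] + self.params["out.bc"]).tanh()
        logits = self._drop(feat, train) @ self.params["out.W"] + self.params["out.b"]
        return logits, new_hs, new_cs, ctx_new

    def forward_teacher(self, src_ids: np.ndarray, tgt_in: np.ndarray, train: bool = True) -> Tensor:
        memory = self.encode(src_ids, train=train)
        B, T = tgt_in.shape
        H = self.config.hidden_dim
        hs = list(memory["init_h"])
        cs = [Tensor(np.zeros((B, H), np.float32)) for _ in hs]
        ctx = Tensor(np.zeros((B, 2 * H), np.float32))
        outs = []
        for t in range(T):
            logits, hs, cs, ctx = self._decode_step(memory, tgt_in[:, t], hs, cs, ctx, train)
            outs.append(logits)
        return stack(outs, axis=1)  # (B,T,V)

    # -- incremental decoding ------------------------------------------------
    def init_state(self, memory: dict) -> dict:
        B = memory["mask"].shape[0]
        H = self.config.hidden_dim
        return {
            "memory": memory,
            "hs": list(memory["init_h"]),
            "cs": [Tensor(np.zeros((B, H), np.float32)) for _ in memory["init_h"]],
            "ctx": Tensor(np.zeros((B, 2 * H), np.float32)),
        }

    def step(self, state: dict, prev_ids: np.ndarray) -> np.ndarray:
        with no_grad():
            logits, hs, cs, ctx = self._decode_step(
                state["memory"], prev_ids, state["hs"], state["cs"], state["ctx"], train=False
            )
        state["hs"], state["cs"], state["ctx"] = hs, cs, ctx
        return _log_softmax(logits.data)

    def reorder_state(self, state: dict, idx: np.ndarray) -> dict:
        mem = state["memory"]
        new_mem = {
            "enc_out": Tensor(mem["enc_out"].data[idx]),
            "uk": Tensor(mem["uk"].data[idx]),
            "mask": mem["mask"][idx],
            "init_h": [Tensor(h.data[idx]) for h in mem["init_h"]],
        }
        return {
            "memory": new_mem,
            "hs": [Tensor(h.data[idx]) for h in state["hs"]],
            "cs": [Tensor(c.data[idx]) for c in state["cs"]],
            "ctx": Tensor(state["ctx"].data[idx]),
        }


# ---------------------------------------------------------------------------
# transformer
# ---------------------------------------------------------------------------


def _sinusoid_table(max_len: int, dim: int) -> np.ndarray:
    pos = np.arange(max_len)[:, None]
    i = np.arange(dim)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / dim)
    table = np.where(i % 2 == 0, np.sin(angle), np.cos(angle))
    return table.astype(np.float32)


def _log_softmax(x: np.ndarray) -> np.ndarray:
    shifted = x - x.max(axis=-1, keepdims=True)
    return shifted - np.log(np.exp(shifted).sum(axis=-1, keepdims=True))


class TransformerModel(_Model):
    def __init__(self, config: ModelConfig, vocab: TokenVocabulary):
        super().__init__(config, vocab)
        V, D, F = len(vocab), config.model_dim, config.ff_dim
        self._param("embed", (V, D), "normal")
        self._pe = _sinusoid_table(config.max_sequence_length, D)
        for l in range(config.n_encoder_layers):
            self._attn_params(f"enc{l}.self", D, fused=True)
            self._ff_params(f"enc{l}", D, F)
            self._ln_params(f"enc{l}.ln1", D)
            self._ln_params(f"enc{l}.ln2", D)
        for l in range(config.n_decoder_layers):
            self._attn_params(f"dec{l}.self", D, fused=True)
            self._attn_params(f"dec{l}.cross", D)
            self._ff_params(f"dec{l}", D, F)
            self._ln_params(f"dec{l}.ln1", D)
            self._ln_params(f"dec{l}.ln2", D)
            self._ln_params(f"dec{l}.ln3", D)
        # output projection tied to the (shared) token embedding
        self._param("out.b", (V,), "zeros")

    def _attn_params(self, prefix: str, D: int, fused: bool = False) -> None:
        if fused:  # self-attention: one projection for Q, K and V
            self._param(f"{prefix}.Wqkv", (D, 3 * D))
            self._param(f"{prefix}.Wo", (D, D))
        else:
            for n in ("Wq", "Wk", "Wv", "Wo"):
                self._param(f"{prefix}.{n}", (D, D))

    def _ff_params(self, prefix: str, D: int, F: int) -> None:
        self._param(f"{prefix}.W1", (D, F))
        self._param(f"{prefix}.b1", (F,), "zeros")
        self._param(f"{prefix}.W2", (F, D))
        self._param(f"{prefix}.b2", (D,), "zeros")

    def _ln_params(self, prefix: str, D: int) -> None:
        self._param(f"{prefix}.g", (D,), "ones")
        self._param(f"{prefix}.b", (D,), "zeros")

    def _ln(self, prefix: str, x: Tensor) -> Tensor:
        return layer_norm(x, self.params[f"{prefix}.g"], self.params[f"{prefix}.b"])

    def _mha(self, prefix: str, q_in: Tensor, kv_in: Tensor, bias: Optional[np.ndarray], train: bool) -> Tensor:
        D, nh = self.config.model_dim, self.config.n_heads
        dh = D // nh
        Bq, Tq = q_in.shape[0], q_in.shape[1]
        Tk = kv_in.shape[1]
        if f"{prefix}.Wqkv" in self.params:
            q, k, v = (q_in @ self.params[f"{prefix}.Wqkv"]).chunk(3, axis=-1)
        else:
            q = q_in @ self.params[f"{prefix}.Wq"]
            k = kv_in @ self.params[f"{prefix}.Wk"]
            v = kv_in @ self.params[f"{prefix}.Wv"]
        q = q.reshape(Bq, Tq, nh, dh).transpose(0, 2, 1, 3)
        k = k.reshape(Bq, Tk, nh, dh).transpose(0, 2, 1, 3)
        v = v.reshape(Bq, Tk, nh, dh).transpose(0, 2, 1, 3)
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dh))  # (B,h,Tq,Tk)
        if bias is not None:
            scores = scores + Tensor(bias)
        attn = scores.softmax(axis=-1)
        ctx = (attn @ v).transpose(0, 2, 1, 3).reshape(Bq, Tq, D)
        return ctx @ self.params[f"{prefix}.Wo"]

    def _embed_positions(self, ids: np.ndarray, train: bool) -> Tensor:
        T = ids.shape[1]
        if T > self.config.max_sequence_length:
            raise ValueError(f"sequence length {T} exceeds max_sequence_length")
        x = embedding(self.params["embed"], ids) * float(np.sqrt(self.config.model_dim))
        x = x + Tensor(self._pe[None, :T, :])
        return self._drop(x, train)

    @staticmethod
    def _pad_bias(ids: np.ndarray) -> np.ndarray:
        # (B,1,1,S): NEG_INF at padding key positions
        return ((ids == 0)[:, None, None, :] * NEG_INF).astype(np.float32)

    def encode(self, src_ids: np.ndarray, train: bool = False) -> dict:
        bias = self._pad_bias(src_ids)
        x = self._embed_positions(src_ids, train)
        for l in range(self.config.n_encoder_layers):
            a = self._mha(f"enc{l}.self", x, x, bias, train)
            x = self._ln(f"enc{l}.ln1", x + self._drop(a, train))
            f = (x @ self.params[f"enc{l}.W1"] + self.params[f"enc{l}.b1"]).relu()
            f = self._drop(f, train) @ self.params[f"enc{l}.W2"] + self.params[f"enc{l}.b2"]
            x = self._ln(f"enc{l}.ln2", x + self._drop(f, train))
        return {"mem": x, "src_bias": bias}

    def _decode(self, memory: dict, tgt_in: np.ndarray, train: bool) -> Tensor:
        B, T = tgt_in.shape
        causal = (np.triu(np.ones((T, T), np.float32), k=1) * NEG_INF)[None, None, :, :]
        self_bias = causal + self._pad_bias(tgt_in)
        x = self._embed_positions(tgt_in, train)
        for l in range(self.config.n_decoder_layers):
            a = self._mha(f"dec{l}.self", x, x, self_bias, train)
            x = self._ln(f"dec{l}.ln1", x + self._drop(a, train))
            a = self._mha(f"dec{l}.cross", x, memory["mem"], memory["src_bias"], train)
            x = self._ln(f"dec{l}.ln2", x + self._drop(a, train))
            f = (x @ self.params[f"dec{l}.W1"] + self.params[f"dec{l}.b1"]).relu()
            f = self._drop(f, train) @ self.params[f"dec{l}.W2"] + self.params[f"dec{l}.b2"]
            x = self._ln(f"dec{l}.ln3", x + self._drop(f, train))
        return x @ self.params["embed"].transpose(1, 0) + self.params["out.b"]  # (B,T,V)

    def forward_teacher(self, src_ids: np.ndarray, tgt_in: np.ndarray, train: bool = True) -> Tensor:
        memory = self.encode(src_ids, train=train)
        return self._decode(memory, tgt_in, train=train)

    # -- incremental decoding (KV-cached, pure numpy) ------------------------
    def init_state(self, memory: dict) -> dict:
        """Precompute cross-attention keys/values; start empty self-attn caches."""
        mem = memory["mem"].data if isinstance(memory["mem"], Tensor) else memory["mem"]
        B = mem.shape[0]
        D, nh = self.config.model_dim, self.config.n_heads
        dh = D // nh
        state = {"t": 0, "src_bias": memory["src_bias"][:, 0, 0, :][:, None, None, :]}
        for l in range(self.config.n_decoder_layers):
            p = self.params
            kc = (mem @ p[f"dec{l}.cross.Wk"].data).reshape(B, -1, nh, dh).transpose(0, 2, 1, 3)
            vc = (mem @ p[f"dec{l}.cross.Wv"].data).reshape(B, -1, nh, dh).transpose(0, 2, 1, 3)
            state[f"crossK{l}"], state[f"crossV{l}"] = kc, vc
            state[f"selfK{l}"] = np.zeros((B, nh, 0, dh), np.float32)
            state[f"selfV{l}"] = np.zeros((B, nh, 0, dh), np.float32)
        return state

    @staticmethod
    def _np_softmax(x: np.ndarray) -> np.ndarray:
        e = np.exp(x - x.max(axis=-1, keepdims=True))
        return e / e.sum(axis=-1, keepdims=True)

    def _np_ln(self, prefix: str, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=-1, keepdims=True)
        sd = np.sqrt(x.var(axis=-1, keepdims=True) + 1e-5)
        return (x - mu) / sd * self.params[f"{prefix}.g"].data + self.params[f"{prefix}.b"].data

    def step(self, state: dict, prev_ids: np.ndarray) -> np.ndarray:
        """Advance one decode position; returns next-token log-probabilities."""
        p = {k: v.data for k, v in self.params.items()}
        D, nh = self.config.model_dim, self.config.n_heads
        dh = D // nh
        t = state["t"]
        if t >= self.config.max_sequence_length:
            raise ValueError("decode length exceeds max_sequence_length")
        x = p["embed"][prev_ids] * np.float32(np.sqrt(D)) + self._pe[t]  # (B,D)
        B = x.shape[0]
        for l in range(self.config.n_decoder_layers):
            qkv = x @ p[f"dec{l}.self.Wqkv"]
            q = qkv[:, :D].reshape(B, nh, 1, dh)
            k = qkv[:, D : 2 * D].reshape(B, nh, 1, dh)
            v = qkv[:, 2 * D :].reshape(B, nh, 1, dh)
            K = np.concatenate([state[f"selfK{l}"], k], axis=2)
            V = np.concatenate([state[f"selfV{l}"], v], axis=2)
            state[f"selfK{l}"], state[f"selfV{l}"] = K, V
            a = self._np_softmax((q @ K.swapaxes(-1, -2)) / np.sqrt(dh))
            ctx = (a @ V).reshape(B, D) @ p[f"dec{l}.self.Wo"]
            x = self._np_ln(f"dec{l}.ln1", x + ctx)
            q = (x @ p[f"dec{l}.cross.Wq"]).reshape(B, nh, 1, dh)
            scores = (q @ state[f"crossK{l}"].swapaxes(-1, -2)) / np.sqrt(dh)
            a = self._np_softmax(scores + state["src_bias"])
            ctx = (a @ state[f"crossV{l}"]).reshape(B, D) @ p[f"dec{l}.cross.Wo"]
            x = self._np_ln(f"dec{l}.ln2", x + ctx)
            f = np.maximum(x @ p[f"dec{l}.W1"] + p[f"dec{l}.b1"], 0.0)
            x = self._np_ln(f"dec{l}.ln3", x + f @ p[f"dec{l}.W2"] + p[f"dec{l}.b2"])
        state["t"] = t + 1
        return _log_softmax(x @ p["embed"].T + p["out.b"])

    def reorder_state(self, state: dict, idx: np.ndarray) -> dict:
        new = {"t": state["t"], "src_bias": state["src_bias"][idx]}
        for l in range(self.config.n_decoder_layers):
            for key in (f"crossK{l}", f"crossV{l}", f"selfK{l}", f"selfV{l}"):
                new[key] = state[key][idx]
        return new


def build_seq2seq(config: ModelConfig, vocab: TokenVocabulary) -> Seq2SeqModel:
    if config.architecture != "seq2seq":
        raise ValueError("config.architecture must be 'seq2seq'")
    return Seq2SeqModel(config, vocab)


def build_transformer(config: ModelConfig, vocab: TokenVocabulary) -> TransformerModel:
    if config.architecture != "transformer":
        raise ValueError("config.architecture must be 'transformer'")
    return TransformerModel(config, vocab)


def build_model(config: ModelConfig, vocab: TokenVocabulary):
    return (build_seq2seq if config.architecture == "seq2seq" else build_transformer)(config, vocab)


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------


def save_checkpoint(model, path: Path | str, history: Optional[list] = None) -> None:
    """Write config (YAML), vocabulary (JSON), weights (NPZ) and history."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    (path / "config.yaml").write_text(yaml.safe_dump(model.config.to_dict()))
    model.vocab.save(path / "vocab.json")
    np.savez(path / "weights.npz", **model.state_dict())
    if history is not None:
        import json

        (path / "history.json").write_text(json.dumps(history, indent=1) + "\n")


def load_checkpoint(path: Path | str):
    """Rebuild a model from a checkpoint directory; returns (model, history)."""
    path = Path(path)
    config = ModelConfig.from_dict(yaml.safe_load((path / "config.yaml").read_text()))
    vocab = TokenVocabulary.load(path / "vocab.json")
    model = build_model(config, vocab)
    with np.load(path / "weights.npz") as z:
        model.load_state_dict({k: z[k] for k in z.files})
    history = None
    hist_path = path / "history.json"
    if hist_path.exists():
        import json

        history = json.loads(hist_path.read_text())
    return model, history
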