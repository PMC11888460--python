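"""The latent-space-regularized transformer autoencoder.

Architecture
------------
* **Encoder** — token embedding + sinusoidal positional encoding, followed by
  a stack of post-norm transformer encoder blocks (multi-head self-attention
  with padding-key masking, then a two-layer feed-forward network; residual
  connections, layer normalization, and dropout in each block).
* **Latent pooling** — per-token encoder outputs are pooled to a single
  d-dimensional latent vector, by default a mean over non-pad positions
  (configurable to start-token pooling), then linearly projected to d.
* **Decoder** — the latent vector is linearly expanded to a
  ``max_len x channels`` grid and passed through a stack of kernel-5,
  same-padded 1-D convolutions with ReLU, ending in a width-24 projection
  that yields per-position token logits.
* **Classifier head** — a two-layer perceptron ``d -> d -> 2`` with ReLU,
  producing class logits (column 0 = non-Cas, column 1 = Cas).

All parameters live in float64 NumPy arrays on the autodiff tape
(:mod:`casgen.autodiff`); construction is fully determined by
:class:`ModelConfig` including its ``rng_seed``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .autodiff import Tensor, concatenate, layer_norm, softmax
from .sequence_io import PAD, VOCAB_SIZE, TokenSequence

logger = logging.getLogger(__name__)

__all__ = ["ModelConfig", "CasGenModel", "save_checkpoint", "load_checkpoint"]


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the autoencoder.

    ``model_width`` must be divisible by ``attention_heads``.  Defaults are
    desk-scale; ``max_len`` bounds the longest encodable sequence at
    ``max_len - 2`` residues.
    """

    max_len: int = 1600
    latent_dim: int = 32
    encoder_layers: int = 4
    attention_heads: int = 4
    model_width: int = 128
    feedforward_width: int = 256
    dropout_rate: float = 0.1
    decoder_conv_layers: int = 3
    decoder_channels: int | None = None  # default: model_width // 2
    kernel_size: int = 5
    pooling: str = "mean"  # "mean" (pad-masked) or "start"
    rng_seed: int = 0
    vocab_size: int = field(default=VOCAB_SIZE)

    def __post_init__(self):
        if self.vocab_size != VOCAB_SIZE:
            raise ValueError(f"vocab_size is fixed at {VOCAB_SIZE}")
        if self.model_width % self.attention_heads:
            raise ValueError("model_width must be divisible by attention_heads")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.pooling not in ("mean", "start"):
            raise ValueError("pooling must be 'mean' or 'start'")

    @property
    def channels(self) -> int:
        return self.decoder_channels or self.model_width // 2


def _sinusoidal_positions(max_len: int, width: int) -> np.ndarray:
    pos = np.arange(max_len)[:, None]
    div = np.exp(-np.log(10000.0) * (np.arange(0, width, 2) / width))
    enc = np.zeros((max_len, width))
    enc[:, 0::2] = np.sin(pos * div)
    enc[:, 1::2] = np.cos(pos * div[: enc[:, 1::2].shape[1]])
    return enc


def _coerce_tokens(tokens) -> np.ndarray:
    """Accept a TokenSequence, a list of them, or an integer array; return (B, T)."""
    if isinstance(tokens, TokenSequence):
        arr = tokens.codes[None, :]
    elif isinstance(tokens, (list, tuple)) and tokens and isinstance(tokens[0], TokenSequence):
        arr = np.stack([t.codes for t in tokens])
    else:
        arr = np.asarray(tokens, dtype=np.int64)
        if arr.ndim == 1:
            arr = arr[None, :]
    if arr.min() < 0 or arr.max() >= VOCAB_SIZE:
        raise ValueError("token codes out of range 0..23")
    return arr


class CasGenModel:
    """Encoder, decoder, and classifier sharing one parameter store."""

    def __init__(self, config: ModelConfig):
        self.config = config
        self.params: dict[str, Tensor] = {}
        self._dropout_rng = np.random.default_rng(config.rng_seed + 1)
        self._positions = _sinusoidal_positions(config.max_len, config.model_width)
        self._init_params(np.random.default_rng(config.rng_seed))

    # ----------------------------------------------------------- parameters
    def _add(self, name: str, value: np.ndarray) -> None:
        self.params[name] = Tensor(value, requires_grad=True)

    def _init_params(self, rng: np.random.Generator) -> None:
        c = self.config
        w, f, d, ch = c.model_width, c.feedforward_width, c.latent_dim, c.channels

        def glorot(*shape):
            limit = np.sqrt(6.0 / (shape[-2] + shape[-1]))
            return rng.uniform(-limit, limit, size=shape)

        self._add("embed", rng.normal(0.0, 0.02, size=(c.vocab_size, w)))
        for layer in range(c.encoder_layers):
            p = f"enc{layer}."
            for name in ("wq", "wk", "wv", "wo"):
                self._add(p + name, glorot(w, w))
                self._add(p + name + "_b", np.zeros(w))
            self._add(p + "ff1", glorot(w, f))
            self._add(p + "ff1_b", np.zeros(f))
            self._add(p + "ff2", glorot(f, w))
            self._add(p + "ff2_b", np.zeros(w))
            for ln in ("ln1", "ln2"):
                self._add(p + ln + "_g", np.ones(w))
                self._add(p + ln + "_b", np.zeros(w))
        self._add("latent_w", glorot(w, d))
        self._add("latent_b", np.zeros(d))
        # classifier head: d -> d -> 2
        self._add("clf_w1", glorot(d, d))
        self._add("clf_b1", np.zeros(d))
        self._add("clf_w2", glorot(d, 2))
        self._add("clf_b2", np.zeros(2))
        # decoder: expand d -> (max_len, ch), then conv stack, then project to vocab
        self._add("dec_expand", glorot(d, c.max_len * ch))
        self._add("dec_expand_b", np.zeros(c.max_len * ch))
        for layer in range(c.decoder_conv_layers):
            self._add(f"dec{layer}.w", glorot(c.kernel_size * ch, ch).reshape(c.kernel_size, ch, ch))
            self._add(f"dec{layer}.b", np.zeros(ch))
        self._add("dec_out", glorot(ch, c.vocab_size))
        self._add("dec_out_b", np.zeros(c.vocab_size))

    # ------------------------------------------------------------- building
    def _dropout(self, x: Tensor, train: bool) -> Tensor:
        rate = self.config.dropout_rate
        if not train or rate == 0.0:
            return x
        keep = self._dropout_rng.random(x.shape) >= rate
        return x * Tensor(keep / (1.0 - rate))

    def _attention(self, x: Tensor, pad_mask: np.ndarray, prefix: str, train: bool) -> Tensor:
        c = self.config
        b, t, w = x.shape
        h, dh = c.attention_heads, c.model_width // c.attention_heads
        p = self.params

        def heads(proj):
            y = x @ p[prefix + proj] + p[prefix + proj + "_b"]
            return y.reshape(b, t, h, dh).transpose(0, 2, 1, 3)  # (b, h, t, dh)

        q, k, v = heads("wq"), heads("wk"), heads("wv")
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dh))
        # mask pad *keys*: pad positions may still act as queries, but their
        # outputs are excluded downstream by the pooling mask
        bias = np.where(pad_mask[:, None, None, :], -1e9, 0.0)
        attn = softmax(scores + Tensor(bias), axis=-1)
        attn = self._dropout(attn, train)
        ctx = (attn @ v).transpose(0, 2, 1, 3).reshape(b, t, w)
        return ctx @ p[prefix + "wo"] + p[prefix + "wo_b"]

    def _encode_tensor(self, tokens: np.ndarray, train: bool) -> Tensor:
        """Token codes (B, T) -> latent Tensor (B, d)."""
        c, p = self.config, self.params
        b, t = tokens.shape
        if t != c.max_len:
            raise ValueError(f"token sequences must have length max_len = {c.max_len}")
        pad_mask = tokens == PAD
        x = p["embed"][tokens] + Tensor(self._positions[None, :t, :])
        x = self._dropout(x, train)
        for layer in range(c.encoder_layers):
            pre = f"enc{layer}."
            attn = self._dropout(self._attention(x, pad_mask, pre, train), train)
            x = layer_norm(x + attn, p[pre + "ln1_g"], p[pre + "ln1_b"])
            ff = (x @ p[pre + "ff1"] + p[pre + "ff1_b"]).relu() @ p[pre + "ff2"] + p[pre + "ff2_b"]
            x = layer_norm(x + self._dropout(ff, train), p[pre + "ln2_g"], p[pre + "ln2_b"])
        if c.pooling == "start":
            pooled = x[:, 0, :]
        else:
            keep = (~pad_mask).astype(np.float64)
            pooled = (x * Tensor(keep[:, :, None])).sum(axis=1) / Tensor(keep.sum(axis=1)[:, None])
        return pooled @ p["latent_w"] + p["latent_b"]

    def _decode_tensor(self, latent: Tensor, train: bool) -> Tensor:
        """Latent (B, d) -> token logits (B, max_len, 24)."""
        c, p = self.config, self.params
        b = latent.shape[0]
        t, ch, k = c.max_len, c.channels, c.kernel_size
        x = (latent @ p["dec_expand"] + p["dec_expand_b"]).reshape(b, t, ch)
        half = k // 2
        for layer in range(c.decoder_conv_layers):
            w, bias = p[f"dec{layer}.w"], p[f"dec{layer}.b"]
            # same-padding conv as a sum of k shifted matmuls over a zero-padded grid
            zeros = Tensor(np.zeros((b, half, ch)))
            xp = concatenate([zeros, x, zeros], axis=1)
            y = None
            for offset in range(k):
                term = xp[:, offset : offset + t, :] @ w[offset]
                y = term if y is None else y + term
            x = (y + bias).relu()
            x = self._dropout(x, train)
        return x @ p["dec_out"] + p["dec_out_b"]

    def _classify_tensor(self, latent: Tensor) -> Tensor:
        p = self.params
        hidden = (latent @ p["clf_w1"] + p["clf_b1"]).relu()
        return hidden @ p["clf_w2"] + p["clf_b2"]

    # ------------------------------------------------------------ public API
    def encode_to_latent(self, tokens, mode: str = "eval") -> np.ndarray:
        """Encode token sequences to ``(B, d)`` latent vectors.

        In ``eval`` mode (the default) dropout is disabled and the map is
        deterministic.
        """
        arr = _coerce_tokens(tokens)
        return self._encode_tensor(arr, train=(mode == "train")).data

    def decode_from_latent(self, latent, mode: str = "eval") -> np.ndarray:
        """Decode latent vectors to per-position token logits.

        A single vector gives ``(max_len, 24)``; a batch gives
        ``(B, max_len, 24)``.
        """
        z = np.asarray(latent, dtype=np.float64)
        if not np.all(np.isfinite(z)):
            raise ValueError("latent entries must be finite")
        single = z.ndim == 1
        if single:
            z = z[None, :]
        if z.shape[1] != self.config.latent_dim:
            raise ValueError(f"latent dimension must be {self.config.latent_dim}")
        logits = self._decode_tensor(Tensor(z), train=(mode == "train")).data
        return logits[0] if single else logits

    def classify_latent(self, latent) -> np.ndarray:
        """Class probabilities for latent vectors: column 0 = non-Cas,
        column 1 = Cas.  Rows sum to 1."""
        z = np.asarray(latent, dtype=np.float64)
        if not np.all(np.isfinite(z)):
            raise ValueError("latent entries must be finite")
        single = z.ndim == 1
        if single:
            z = z[None, :]
        logits = self._classify_tensor(Tensor(z)).data
        probs = softmax(Tensor(logits), axis=-1).data
        return probs[0] if single else probs

    def decode_to_sequence(self, latent) -> str:
        """Greedy (argmax) decoding of one latent vector to an amino-acid string.

        If the decoder emits neither an end nor a pad token, the sequence is
        truncated to ``max_len - 2`` residues so any decoded candidate can be
        re-encoded under the model's own length budget.
        """
        from .sequence_io import decode_tokens

        logits = self.decode_from_latent(latent)
        seq = decode_tokens(np.argmax(logits, axis=-1))
        limit = self.config.max_len - 2
        if len(seq) > limit:
            logger.warning("decoded sequence has no terminator; truncated to %d residues", limit)
            seq = seq[:limit]
        return seq


# ------------------------------------------------------------- persistence
def save_checkpoint(model: CasGenModel, path: str | Path) -> None:
    """Serialize weights and config to a single ``.npz`` file."""
    arrays = {name: t.data for name, t in model.params.items()}
    arrays["__config__"] = np.frombuffer(
        json.dumps(asdict(model.config)).encode(), dtype=np.uint8
    )
    np.savez(str(path), **arrays)


def load_checkpoint(path: str | Path) -> CasGenModel:
    with np.load(str(path)) as data:
        config = ModelConfig(**json.loads(bytes(data["__config__"]).decode()))
        model = CasGenModel(config)
        for name in model.params:
            model.params[name] = Tensor(data[name], requires_grad=True)
    return model
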