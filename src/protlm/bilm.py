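"""Bidirectional language model over protein sentences.

The architecture follows the ELMo recipe: a character-level convolutional
word encoder (here each word is a single amino acid) with highway layers and
a linear projection, followed by two LSTM layers with projection, run
independently left-to-right (forward) and right-to-left (backward). The two
directions share the word encoder and the softmax head but keep separate
recurrent weights; the forward objective conditions only on tokens to the
left of the target and the backward objective only on tokens to the right,
so no direction ever sees its own target. Training uses a sampled softmax
(log-uniform negatives); evaluation uses the full softmax.

Two presets are provided: ``paper`` (projection 512, hidden 4096, the
1..7-wide convolution bank rising from 32 to 1024 filters; ~93.6 M free
parameters, per-layer embedding width 1024) and ``mini`` (projection 32,
hidden 64), the desk-scale configuration every trainable test uses.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .corpus import ProteinRecord, TokenVocabulary, build_vocabulary, tokenize
from .nn import (
    Adagrad,
    Adam,
    Module,
    Parameter,
    Tensor,
    concat,
    dropout,
    softmax_cross_entropy,
)

__all__ = [
    "BiLMConfig",
    "BiLM",
    "PerplexityValue",
    "build_bilm",
    "count_parameters",
    "train_bilm",
    "perplexity",
    "save_bilm",
    "load_bilm",
    "model_hash",
]

PAPER_CONV_BANK = ((1, 32), (2, 32), (3, 64), (4, 128), (5, 256), (6, 512), (7, 1024))
MINI_CONV_BANK = ((1, 16), (2, 16), (3, 16))


@dataclass(frozen=True)
class BiLMConfig:
    """Hyperparameters of the bidirectional language model."""

    vocab: TokenVocabulary
    char_embedding_dim: int = 16
    conv_bank: tuple[tuple[int, int], ...] = PAPER_CONV_BANK
    n_highway: int = 2
    projection_dim: int = 512
    hidden_dim: int = 4096
    n_layers: int = 2
    unroll_steps: int = 100
    n_negative_samples: int = 20
    dropout: float = 0.1
    share_recurrent: bool = False
    preset: str = "custom"

    def __post_init__(self) -> None:
        if self.n_layers != 2:
            raise ValueError("the architecture uses exactly two recurrent layers")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must be in [0, 1)")
        if self.unroll_steps < 1:
            raise ValueError("unroll_steps must be >= 1")
        if not (1 <= self.n_negative_samples < len(self.vocab)):
            raise ValueError("negative samples must be in [1, vocab size)")
        if any(w < 1 or f < 1 for w, f in self.conv_bank):
            raise ValueError("conv bank entries must have window and filters >= 1")

    @property
    def per_layer_dim(self) -> int:
        """Width of one contextual layer: forward + backward concatenated."""
        return 2 * self.projection_dim

    @staticmethod
    def paper(vocab: TokenVocabulary | None = None, **overrides) -> "BiLMConfig":
        vocab = vocab or build_vocabulary()
        return BiLMConfig(vocab=vocab, preset="paper", **overrides)

    @staticmethod
    def mini(vocab: TokenVocabulary | None = None, **overrides) -> "BiLMConfig":
        vocab = vocab or build_vocabulary()
        defaults = dict(
            char_embedding_dim=8,
            conv_bank=MINI_CONV_BANK,
            n_highway=1,
            projection_dim=32,
            hidden_dim=64,
            preset="mini",
        )
        defaults.update(overrides)
        return BiLMConfig(vocab=vocab, **defaults)


@dataclass(frozen=True)
class PerplexityValue:
    """exp(mean per-token negative log-likelihood) for one direction."""

    value: float
    direction: str  # forward | backward | mean

    def __post_init__(self) -> None:
        if self.value < 1.0 - 1e-9:
            raise ValueError("perplexity cannot be below 1")


def _uniform_init(rng: np.random.Generator, shape, scale: float | None = None):
    fan_in = shape[0] if len(shape) > 1 else shape[0]
    if scale is None:
        scale = math.sqrt(1.0 / fan_in)
    return Parameter(rng.uniform(-scale, scale, size=shape).astype(np.float32))


class CharCNN(Module):
    """Character-convolution word encoder over single-residue words.

    Every token is spelled as [begin-of-word, symbol, end-of-word] padded to
    a fixed width, embedded per character, convolved with the bank, max-pooled
    over positions, passed through highway layers and projected. Because the
    lexicon is tiny (28 tokens) the encoder is evaluated once per forward
    pass over the whole lexicon and looked up by token index.
    """

    def __init__(self, config: BiLMConfig, rng: np.random.Generator):
        self.config = config
        vocab_size = len(config.vocab)
        # char ids: 0 pad, 1 begin-of-word, 2 end-of-word, 3.. one per token symbol
        self.n_chars = 3 + vocab_size
        max_w = max(w for w, _ in config.conv_bank)
        self.word_length = max(max_w, 3)
        spelled = np.zeros((vocab_size, self.word_length), dtype=np.int64)
        spelled[:, 0] = 1
        spelled[:, 1] = 3 + np.arange(vocab_size)
        spelled[:, 2] = 2
        self._spelling = spelled
        d = config.char_embedding_dim
        self.char_embedding = _uniform_init(rng, (self.n_chars, d), scale=1.0)
        self.conv_w = [
            _uniform_init(rng, (w * d, f)) for w, f in config.conv_bank
        ]
        self.conv_b = [Parameter(np.zeros(f, dtype=np.float32))
                       for _, f in config.conv_bank]
        n_filters = sum(f for _, f in config.conv_bank)
        self.highway_t = [
            _uniform_init(rng, (n_filters, n_filters)) for _ in range(config.n_highway)
        ]
        # negative transform-gate bias: start close to the identity map
        self.highway_tb = [Parameter(np.full(n_filters, -2.0, dtype=np.float32))
                          for _ in range(config.n_highway)]
        self.highway_h = [
            _uniform_init(rng, (n_filters, n_filters)) for _ in range(config.n_highway)
        ]
        self.highway_hb = [Parameter(np.zeros(n_filters, dtype=np.float32))
                          for _ in range(config.n_highway)]
        self.proj_w = _uniform_init(rng, (n_filters, config.projection_dim))
        self.proj_b = Parameter(np.zeros(config.projection_dim, dtype=np.float32))

    def lexicon(self) -> Tensor:
        """(vocab size, projection dim) context-independent word vectors."""
        V, W = self._spelling.shape
        d = self.config.char_embedding_dim
        emb = self.char_embedding.take(self._spelling.reshape(-1), axis=0)
        emb = emb.reshape(V, W, d)
        pooled = []
        for (w, _f), cw, cb in zip(self.config.conv_bank, self.conv_w, self.conv_b):
            windows = np.stack([np.arange(i, i + w) for i in range(W - w + 1)])
            x = emb.take(windows.reshape(-1), axis=1).reshape(V, W - w + 1, w * d)
            conv = (x @ cw + cb).relu()
            pooled.append(conv.max(axis=1))
        h = concat(pooled, axis=1)
        for wt, bt, wh, bh in zip(self.highway_t, self.highway_tb,
                                  self.highway_h, self.highway_hb):
            t = (h @ wt + bt).sigmoid()
            g = (h @ wh + bh).relu()
            h = t * g + (1.0 - t) * h
        return h @ self.proj_w + self.proj_b


class LSTMPCell(Module):
    """LSTM cell with a linear projection of the hidden state."""

    def __init__(self, input_dim: int, hidden_dim: int, proj_dim: int,
                 rng: np.random.Generator):
        self.hidden_dim = hidden_dim
        self.proj_dim = proj_dim
        self.w_x = _uniform_init(rng, (input_dim, 4 * hidden_dim))
        self.w_h = _uniform_init(rng, (proj_dim, 4 * hidden_dim))
        b = np.zeros(4 * hidden_dim, dtype=np.float32)
        b[hidden_dim : 2 * hidden_dim] = 1.0  # forget-gate bias
        self.b = Parameter(b)
        self.w_p = _uniform_init(rng, (hidden_dim, proj_dim))

    def step(self, x: Tensor, h: Tensor, c: Tensor) -> tuple[Tensor, Tensor]:
        H = self.hidden_dim
        z = x @ self.w_x + h @ self.w_h + self.b
        i = z[:, :H].sigmoid()
        f = z[:, H : 2 * H].sigmoid()
        g = z[:, 2 * H : 3 * H].tanh()
        o = z[:, 3 * H :].sigmoid()
        c_new = f * c + i * g
        h_new = (o * c_new.tanh()) @ self.w_p
        return h_new, c_new


class BiLM(Module):
    """The bidirectional language model (see module docstring)."""

    def __init__(self, config: BiLMConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.config = config
        self.char_cnn = CharCNN(config, rng)
        P, H = config.projection_dim, config.hidden_dim
        self.forward_layers = [LSTMPCell(P, H, P, rng) for _ in range(config.n_layers)]
        if config.share_recurrent:
            self.backward_layers = []  # forward cells serve both directions
        else:
            self.backward_layers = [
                LSTMPCell(P, H, P, rng) for _ in range(config.n_layers)
            ]
        self.softmax_w = _uniform_init(rng, (P, len(config.vocab)))
        self.softmax_b = Parameter(np.zeros(len(config.vocab), dtype=np.float32))
        self.epochs_seen = 0
        self.perplexity_trace: list[dict[str, float]] = []

    def _cells(self, direction: str) -> list[LSTMPCell]:
        if direction == "forward" or self.config.share_recurrent:
            return self.forward_layers
        return self.backward_layers

    def initial_state(self, batch: int):
        P, H = self.config.projection_dim, self.config.hidden_dim
        return [
            (Tensor(np.zeros((batch, P), np.float32)),
             Tensor(np.zeros((batch, H), np.float32)))
            for _ in range(self.config.n_layers)
        ]

    def run_direction(
        self,
        tokens: np.ndarray,
        direction: str,
        state=None,
        training: bool = False,
        rng: np.random.Generator | None = None,
        lexicon: Tensor | None = None,
    ):
        """Run one direction over direction-oriented token indices.

        ``tokens`` is (batch, steps), already reversed by the caller for the
        backward direction. Returns (word vectors, per-layer output lists,
        final state); outputs are lists over time of (batch, proj) tensors.
        Layer 2 outputs include the residual connection from layer 1.
        """
        if direction not in ("forward", "backward"):
            raise ValueError(f"unknown direction {direction!r}")
        B, T = tokens.shape
        if lexicon is None:
            lexicon = self.char_cnn.lexicon()
        cells = self._cells(direction)
        state = state or self.initial_state(B)
        rate = self.config.dropout
        word_vecs: list[Tensor] = []
        outs1: list[Tensor] = []
        outs2: list[Tensor] = []
        for t in range(T):
            x = lexicon.take(tokens[:, t], axis=0)
            word_vecs.append(x)
            x_in = dropout(x, rate, rng, training) if training else x
            h1, c1 = cells[0].step(x_in, *state[0])
            state[0] = (h1, c1)
            h1_in = dropout(h1, rate, rng, training) if training else h1
            h2, c2 = cells[1].step(h1_in, *state[1])
            state[1] = (h2, c2)
            outs1.append(h1)
            outs2.append(h2 + h1)  # residual connection between layers
        return word_vecs, (outs1, outs2), state


def build_bilm(config: BiLMConfig, seed: int = 0) -> BiLM:
    """Instantiate a model with deterministic initialization from ``seed``."""
    return BiLM(config, seed=seed)


def count_parameters(model: Module) -> int:
    """Total size of trainable parameters, counting shared groups once."""
    unique = {id(p): p for _, p in model.named_parameters()}
    return int(sum(p.data.size for p in unique.values()))


# -- training --------------------------------------------------------------

def _reverse_padded(tokens: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """Reverse each row's valid prefix, leaving trailing padding in place."""
    out = np.zeros_like(tokens)
    for i, L in enumerate(lengths):
        out[i, :L] = tokens[i, :L][::-1]
    return out


def _pad_batch(token_lists: list[list[int]], pad: int) -> tuple[np.ndarray, np.ndarray]:
    lengths = np.array([len(t) for t in token_lists])
    T = int(lengths.max())
    mat = np.full((len(token_lists), T), pad, dtype=np.int64)
    for i, tl in enumerate(token_lists):
        mat[i, : len(tl)] = tl
    return mat, lengths


def _log_uniform_probs(n: int) -> np.ndarray:
    k = np.arange(n, dtype=np.float64)
    p = np.log((k + 2) / (k + 1)) / np.log(n + 1)
    return p / p.sum()


def _sampled_softmax_nll(
    model: BiLM,
    hidden: Tensor,            # (N, P)
    targets: np.ndarray,       # (N,)
    mask: np.ndarray,          # (N,) bool
    rng: np.random.Generator,
) -> Tensor:
    """Masked mean sampled-softmax NLL with log-uniform negatives.

    Candidate logits carry the standard log-proposal correction; negatives
    that collide with their row's target are masked out (accidental hits).
    """
    V = len(model.config.vocab)
    m = model.config.n_negative_samples
    q = _log_uniform_probs(V)
    negs = rng.choice(V, size=m, replace=False, p=q)
    w_pos = model.softmax_w.take(targets, axis=1).transpose(1, 0)   # (N, P)
    b_pos = model.softmax_b.take(targets, axis=0)                   # (N,)
    pos = (hidden * w_pos).sum(axis=1) + b_pos
    pos = pos.reshape(-1, 1) - Tensor(np.log(q[targets])[:, None])
    w_neg = model.softmax_w.take(negs, axis=1)                      # (P, m)
    neg = hidden @ w_neg + model.softmax_b.take(negs, axis=0)
    hit = (negs[None, :] == targets[:, None]).astype(np.float64) * -1e9
    neg = neg + Tensor((hit - np.log(q[negs])[None, :]))
    logits = concat([pos, neg], axis=1)
    nll = softmax_cross_entropy(logits, np.zeros(len(targets), dtype=np.int64))
    w = mask.astype(np.float64)
    return (nll * Tensor(w)).sum() / max(w.sum(), 1.0)


def _direction_nll(
    model: BiLM,
    tokens: np.ndarray,
    lengths: np.ndarray,
    direction: str,
    training: bool,
    rng: np.random.Generator | None,
    sampled: bool,
    lexicon: Tensor | None = None,
) -> tuple[Tensor | float, int]:
    """NLL over one direction of a padded batch.

    Returns (mean NLL per scored token, number of scored tokens). With
    ``sampled=False`` the full softmax is used and a float is returned.
    """
    pad = model.config.vocab.pad_index
    toks = tokens if direction == "forward" else _reverse_padded(tokens, lengths)
    inputs = toks[:, :-1]
    targets = toks[:, 1:]
    mask = targets != pad
    _, (outs1, outs2), _ = model.run_direction(
        inputs, direction, training=training, rng=rng, lexicon=lexicon
    )
    B = tokens.shape[0]
    hidden = concat([h.reshape(B, 1, -1) for h in outs2], axis=1)
    hidden = hidden.reshape(B * (tokens.shape[1] - 1), -1)
    flat_t = targets.reshape(-1)
    flat_m = mask.reshape(-1)
    if sampled:
        return _sampled_softmax_nll(model, hidden, flat_t, flat_m, rng), int(flat_m.sum())
    logits = (hidden @ model.softmax_w + model.softmax_b).data
    z = logits - logits.max(axis=1, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=1))
    nll = lse - z[np.arange(len(flat_t)), flat_t]
    n = int(flat_m.sum())
    return float(nll[flat_m].sum() / max(n, 1)), n


def train_bilm(
    model: BiLM,
    records: Sequence[ProteinRecord],
    epochs: int = 5,
    batch_size: int = 32,
    seed: int = 0,
    optimizer: str = "adam",
    lr: float | None = None,
    eval_records: int = 64,
) -> BiLM:
    """Train both directions with truncated backpropagation through time.

    Proteins are tokenized into length-sorted padded batches; each batch is
    processed in contiguous ``unroll_steps`` windows with recurrent state
    carried (detached) across windows within the batch and reset between
    batches. The forward and backward losses are averaged per step. Adam
    (lr 0.01) is the default optimizer -- it converges far faster than
    Adagrad at small corpus scale; Adagrad (lr 0.2) is available for the
    classic large-corpus recipe. Deterministic given (model, corpus, seed).
    """
    if not records:
        raise ValueError("empty corpus")
    if model.config.unroll_steps < 2:
        raise ValueError("unroll_steps must be >= 2 for training")
    vocab = model.config.vocab
    token_lists = [tokenize(r, vocab) for r in records]
    rng = np.random.default_rng(seed)
    params = list({id(p): p for _, p in model.named_parameters()}.values())
    if optimizer == "adam":
        opt = Adam(params, lr=0.01 if lr is None else lr)
    elif optimizer == "adagrad":
        opt = Adagrad(params, lr=0.2 if lr is None else lr)
    else:
        raise ValueError(f"unknown optimizer {optimizer!r}")
    unroll = model.config.unroll_steps
    # length-sorted batches minimize padding; batch order is shuffled per epoch
    sorted_idx = np.argsort([len(t) for t in token_lists], kind="stable")
    groups = [sorted_idx[i : i + batch_size]
              for i in range(0, len(sorted_idx), batch_size)]
    for _ in range(epochs):
        for gi in rng.permutation(len(groups)):
            batch = [token_lists[i] for i in groups[gi]]
            tokens, lengths = _pad_batch(batch, vocab.pad_index)
            B, T = tokens.shape
            states = {"forward": None, "backward": None}
            rev = _reverse_padded(tokens, lengths)
            for w0 in range(0, T - 1, unroll):
                hi = min(w0 + unroll + 1, T)
                losses = []
                lexicon = model.char_cnn.lexicon()
                for direction, toks in (("forward", tokens), ("backward", rev)):
                    window = toks[:, w0:hi]
                    inputs, targets = window[:, :-1], window[:, 1:]
                    mask = targets != vocab.pad_index
                    if not mask.any():
                        continue
                    _, (_, outs2), st = model.run_direction(
                        inputs, direction, state=states[direction],
                        training=True, rng=rng, lexicon=lexicon,
                    )
                    states[direction] = [(h.detach(), c.detach()) for h, c in st]
                    hidden = concat(
                        [h.reshape(B, 1, -1) for h in outs2], axis=1
                    ).reshape(B * inputs.shape[1], -1)
                    losses.append(
                        _sampled_softmax_nll(
                            model, hidden, targets.reshape(-1),
                            mask.reshape(-1), rng,
                        )
                    )
                if not losses:
                    continue
                loss = losses[0] if len(losses) == 1 else (losses[0] + losses[1]) * 0.5
                opt.zero_grad()
                loss.backward()
                opt.step()
        model.epochs_seen += 1
        subset = list(records[:eval_records])
        report = perplexity(model, subset, direction="all")
        model.perplexity_trace.append(
            {"epoch": model.epochs_seen, **{k: v.value for k, v in report.items()}}
        )
    return model


def perplexity(
    model: BiLM,
    records: Sequence[ProteinRecord],
    direction: str = "mean",
    batch_size: int = 32,
):
    """Full-softmax perplexity over a corpus.

    Per direction, every residue token plus that direction's terminal token
    is scored (forward: the end token; backward: the start token); padding
    is never scored. ``direction="mean"`` averages the forward and backward
    per-token NLL before exponentiation; ``"all"`` returns a dict with all
    three values.
    """
    if not records:
        raise ValueError("empty corpus")
    vocab = model.config.vocab
    token_lists = sorted((tokenize(r, vocab) for r in records), key=len)
    totals = {"forward": 0.0, "backward": 0.0}
    counts = {"forward": 0, "backward": 0}
    for b0 in range(0, len(token_lists), batch_size):
        tokens, lengths = _pad_batch(token_lists[b0 : b0 + batch_size], vocab.pad_index)
        for d in ("forward", "backward"):
            mean_nll, n = _direction_nll(
                model, tokens, lengths, d, training=False, rng=None, sampled=False
            )
            totals[d] += mean_nll * n
            counts[d] += n
    per_tok = {d: totals[d] / counts[d] for d in totals}
    values = {
        "forward": PerplexityValue(math.exp(per_tok["forward"]), "forward"),
        "backward": PerplexityValue(math.exp(per_tok["backward"]), "backward"),
        "mean": PerplexityValue(
            math.exp(0.5 * (per_tok["forward"] + per_tok["backward"])), "mean"
        ),
    }
    if direction == "all":
        return values
    try:
        return values[direction]
    except KeyError:
        raise ValueError(f"unknown direction {direction!r}") from None


# -- persistence -----------------------------------------------------------

def _config_to_json(config: BiLMConfig) -> str:
    d = {
        "tokens": list(config.vocab.tokens),
        "char_embedding_dim": config.char_embedding_dim,
        "conv_bank": [list(x) for x in config.conv_bank],
        "n_highway": config.n_highway,
        "projection_dim": config.projection_dim,
        "hidden_dim": config.hidden_dim,
        "n_layers": config.n_layers,
        "unroll_steps": config.unroll_steps,
        "n_negative_samples": config.n_negative_samples,
        "dropout": config.dropout,
        "share_recurrent": config.share_recurrent,
        "preset": config.preset,
    }
    return json.dumps(d)


def _config_from_json(text: str) -> BiLMConfig:
    d = json.loads(text)
    vocab = TokenVocabulary(tuple(d.pop("tokens")))
    d["conv_bank"] = tuple(tuple(x) for x in d["conv_bank"])
    return BiLMConfig(vocab=vocab, **d)


def model_hash(model: Module) -> str:
    """Stable sha256 over sorted parameter names and contents."""
    h = hashlib.sha256()
    for name, p in sorted(model.named_parameters(), key=lambda kv: kv[0]):
        h.update(name.encode())
        h.update(np.ascontiguousarray(p.data, dtype=np.float32).tobytes())
    return h.hexdigest()


def save_bilm(path, model: BiLM) -> None:
    """Save config (JSON) + named parameter arrays in one npz archive."""
    arrays = {f"param/{k}": v for k, v in model.state_dict().items()}
    arrays["config_json"] = np.frombuffer(
        _config_to_json(model.config).encode(), dtype=np.uint8
    )
    arrays["epochs_seen"] = np.array(model.epochs_seen)
    np.savez(path, **arrays)


def load_bilm(path) -> BiLM:
    with np.load(path) as npz:
        config = _config_from_json(bytes(npz["config_json"]).decode())
        model = BiLM(config, seed=0)
        state = {
            k[len("param/"):]: npz[k] for k in npz.files if k.startswith("param/")
        }
        model.load_state_dict(state)
        model.epochs_seen = int(npz["epochs_seen"])
    return model
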