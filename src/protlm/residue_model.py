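"""Per-residue multi-task convolutional predictor.

A two-layer CNN in the classic sequence-to-structure / structure-to-
structure arrangement: a width-7 convolution from the input channels to 32
filters (ReLU, 25% dropout), then a second width-7 convolution to 13 output
channels presented as three softmax heads -- 3-state secondary structure,
8-state secondary structure and binary disorder. The three task losses are
summed; padded positions and residues without defined labels are masked out
of both loss and metrics. Free-parameter count is X*7*32+32 + 32*7*13+13
for X input channels (e.g. 232,333 at X=1024; 7,437 at X=20).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .encoders import ResidueFeatureMatrix
from .metrics import SS3_STATES, SS8_STATES
from .nn import Adam, Module, Parameter, Tensor, concat, dropout, softmax_cross_entropy

__all__ = [
    "ResidueModelConfig",
    "ResiduePredictions",
    "ResidueCNN",
    "build_residue_model",
    "count_parameters",
    "train_residue_model",
    "predict_residues",
]

HEADS = {"ss3": (0, 3), "ss8": (3, 11), "disorder": (11, 13)}
N_OUT = 13


@dataclass(frozen=True)
class ResidueModelConfig:
    in_channels: int
    scheme: str = "seqvec"
    filters: int = 32
    window: int = 7
    dropout: float = 0.25
    learning_rate: float = 0.001
    batch_size: int = 128
    holdout_fraction: float = 0.05
    patience: int = 5
    max_epochs: int = 50

    def __post_init__(self) -> None:
        if self.window % 2 != 1:
            raise ValueError("window must be odd")
        if self.filters < 1 or self.in_channels < 1:
            raise ValueError("channel/filter counts must be positive")


def _im2col_np(x: np.ndarray, w: int) -> np.ndarray:
    """(B, L, C) -> (B, L, w*C) sliding windows with zero borders."""
    B, L, C = x.shape
    p = w // 2
    padded = np.zeros((B, L + 2 * p, C), dtype=x.dtype)
    padded[:, p : p + L] = x
    idx = np.arange(L)[:, None] + np.arange(w)[None, :]
    return padded[:, idx].reshape(B, L, w * C)


class ResidueCNN(Module):
    """Two width-7 convolutions with a 13-channel multi-head output."""

    def __init__(self, config: ResidueModelConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.config = config
        w, F, X = config.window, config.filters, config.in_channels

        def init(shape):
            scale = np.sqrt(1.0 / shape[0])
            return Parameter(rng.uniform(-scale, scale, shape).astype(np.float32))

        self.conv1_w = init((w * X, F))
        self.conv1_b = Parameter(np.zeros(F, dtype=np.float32))
        self.conv2_w = init((w * F, N_OUT))
        self.conv2_b = Parameter(np.zeros(N_OUT, dtype=np.float32))

    def forward(
        self,
        features: np.ndarray,  # (B, L, X)
        lengths: np.ndarray | None = None,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> Tensor:
        """Head logits of shape (B, L, 13).

        ``lengths`` marks the real (unpadded) prefix of each row; hidden
        activations beyond it are zeroed so that predictions for real
        positions are identical whether a protein is padded or not (the
        first convolution's bias would otherwise leak nonzero activations
        into the borders of shorter proteins in a batch).
        """
        w = self.config.window
        B, L, _ = features.shape
        x1 = Tensor(_im2col_np(features.astype(np.float32), w))
        h = (x1 @ self.conv1_w + self.conv1_b).relu()
        h = dropout(h, self.config.dropout, rng, training)
        if lengths is not None:
            mask = (np.arange(L)[None, :] < np.asarray(lengths)[:, None])
            h = h * Tensor(mask.astype(np.float32)[:, :, None])
        # im2col on the hidden tensor: zero-pad along L, gather windows
        p = w // 2
        F = self.config.filters
        zeros = Tensor(np.zeros((B, p, F), dtype=np.float32))
        padded = concat([zeros, h, zeros], axis=1)
        idx = (np.arange(L)[:, None] + np.arange(w)[None, :]).reshape(-1)
        h2 = padded.take(idx, axis=1).reshape(B, L, w, F).reshape(B, L, w * F)
        return h2 @ self.conv2_w + self.conv2_b


def build_residue_model(config: ResidueModelConfig, seed: int = 0) -> ResidueCNN:
    return ResidueCNN(config, seed=seed)


def count_parameters(model: Module) -> int:
    from .bilm import count_parameters as _cp

    return _cp(model)


@dataclass(frozen=True)
class ResiduePredictions:
    """Per-residue class probabilities and argmax labels for one protein."""

    record_id: str
    ss3_probs: np.ndarray
    ss8_probs: np.ndarray
    disorder_probs: np.ndarray
    ss3: str = field(init=False)
    ss8: str = field(init=False)
    disorder: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        for name, p in (("ss3", self.ss3_probs), ("ss8", self.ss8_probs),
                        ("disorder", self.disorder_probs)):
            if not np.allclose(p.sum(axis=1), 1.0, atol=1e-5):
                raise ValueError(f"{self.record_id}: {name} rows must sum to 1")
        object.__setattr__(
            self, "ss3", "".join(SS3_STATES[i] for i in self.ss3_probs.argmax(1))
        )
        object.__setattr__(
            self, "ss8", "".join(SS8_STATES[i] for i in self.ss8_probs.argmax(1))
        )
        object.__setattr__(self, "disorder", self.disorder_probs.argmax(1))


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def labels_to_arrays(labels: Mapping[str, str]) -> dict[str, np.ndarray]:
    """Encode one record's label strings as integer arrays.

    Expects keys ss3, ss8, disorder; unknown letters ('-') produce -1,
    excluded from the loss.
    """
    ss3 = np.array([SS3_STATES.find(c) for c in labels["ss3"]])
    ss8 = np.array([SS8_STATES.find(c) for c in labels["ss8"]])
    dis = np.array([int(c) if c in "01" else -1 for c in labels["disorder"]])
    return {"ss3": ss3, "ss8": ss8, "disorder": dis}


def _batch_arrays(
    features: Sequence[ResidueFeatureMatrix],
    labels: Sequence[dict[str, np.ndarray]] | None,
):
    B = len(features)
    L = max(len(f) for f in features)
    X = features[0].channels
    feat = np.zeros((B, L, X), dtype=np.float32)
    lab = {k: np.full((B, L), -1, dtype=np.int64) for k in HEADS}
    for i, f in enumerate(features):
        feat[i, : len(f)] = f.matrix
        if labels is not None:
            for k in HEADS:
                lab[k][i, : len(f)] = labels[i][k]
    lengths = np.array([len(f) for f in features])
    return feat, lab, lengths


def _multitask_loss(logits: Tensor, lab: dict[str, np.ndarray]) -> Tensor:
    """Sum of per-head masked mean cross-entropies."""
    B, L, _ = logits.shape
    flat = logits.reshape(B * L, N_OUT)
    total = None
    for head, (lo, hi) in HEADS.items():
        t = lab[head].reshape(-1)
        mask = t >= 0
        if not mask.any():
            continue
        nll = softmax_cross_entropy(flat[:, lo:hi], np.maximum(t, 0))
        w = mask.astype(np.float64)
        term = (nll * Tensor(w)).sum() / w.sum()
        total = term if total is None else total + term
    if total is None:
        raise ValueError("no labeled residues in batch")
    return total


def train_residue_model(
    model: ResidueCNN,
    features: Sequence[ResidueFeatureMatrix],
    labels: Mapping[str, Mapping[str, str]],
    seed: int = 0,
    max_epochs: int | None = None,
    verbose: bool = False,
) -> dict:
    """Train with Adam on summed task losses and hold-out early stopping.

    A random ~5% of proteins (at least one) is held out; training stops when
    the held-out summed loss has not improved for ``patience`` epochs, and
    the best parameters are restored. Deterministic given the seed.
    """
    cfg = model.config
    if not features:
        raise ValueError("no training features")
    for f in features:
        if len(f) != len(labels[f.record_id]["ss3"]):
            raise ValueError(f"record {f.record_id!r}: feature/label length mismatch")
        if f.channels != cfg.in_channels:
            raise ValueError(
                f"record {f.record_id!r}: expected {cfg.in_channels} channels, "
                f"got {f.channels}"
            )
    rng = np.random.default_rng(seed)
    arrays = [labels_to_arrays(labels[f.record_id]) for f in features]
    n = len(features)
    n_hold = max(1, int(round(cfg.holdout_fraction * n)))
    if n_hold >= n:
        raise ValueError("holdout split leaves no training data")
    perm = rng.permutation(n)
    hold_idx, train_idx = perm[:n_hold], perm[n_hold:]
    hold_feat, hold_lab, hold_len = _batch_arrays(
        [features[i] for i in hold_idx], [arrays[i] for i in hold_idx]
    )
    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    best = np.inf
    best_state = model.state_dict()
    since_best = 0
    history = {"train_loss": [], "holdout_loss": []}
    epochs = cfg.max_epochs if max_epochs is None else max_epochs
    for epoch in range(epochs):
        order = rng.permutation(len(train_idx))
        ep_loss = 0.0
        n_batches = 0
        for b0 in range(0, len(order), cfg.batch_size):
            sel = [train_idx[i] for i in order[b0 : b0 + cfg.batch_size]]
            feat, lab, lens = _batch_arrays([features[i] for i in sel],
                                            [arrays[i] for i in sel])
            logits = model.forward(feat, lengths=lens, training=True, rng=rng)
            loss = _multitask_loss(logits, lab)
            opt.zero_grad()
            loss.backward()
            opt.step()
            ep_loss += float(loss.data)
            n_batches += 1
        hold_logits = model.forward(hold_feat, lengths=hold_len, training=False)
        hold_loss = float(_multitask_loss(hold_logits, hold_lab).data)
        history["train_loss"].append(ep_loss / max(n_batches, 1))
        history["holdout_loss"].append(hold_loss)
        if verbose:
            print(f"epoch {epoch + 1}: train {history['train_loss'][-1]:.4f} "
                  f"holdout {hold_loss:.4f}")
        if hold_loss < best - 1e-6:
            best = hold_loss
            best_state = model.state_dict()
            since_best = 0
        else:
            since_best += 1
            if since_best >= cfg.patience:
                break
    model.load_state_dict(best_state)
    return history


def predict_residues(
    model: ResidueCNN, features: Sequence[ResidueFeatureMatrix],
    batch_size: int = 64,
) -> list[ResiduePredictions]:
    """Inference-mode predictions (dropout off) for a list of proteins."""
    cfg = model.config
    out = []
    for b0 in range(0, len(features), batch_size):
        batch = features[b0 : b0 + batch_size]
        for f in batch:
            if f.channels != cfg.in_channels:
                raise ValueError(
                    f"record {f.record_id!r}: model expects {cfg.in_channels} "
                    f"input channels ({cfg.scheme}), got {f.channels} ({f.scheme})"
                )
        feat, _, lens = _batch_arrays(batch, None)
        logits = model.forward(feat, lengths=lens, training=False).data
        for i, f in enumerate(batch):
            L = len(f)
            out.append(
                ResiduePredictions(
                    f.record_id,
                    _softmax(logits[i, :L, 0:3]),
                    _softmax(logits[i, :L, 3:11]),
                    _softmax(logits[i, :L, 11:13]),
                )
            )
    return out


# -- persistence -----------------------------------------------------------

def save_residue_model(path, model: ResidueCNN, lm_hash: str = "") -> None:
    """npz archive: config JSON + parameters (+ producing-LM hash guard)."""
    import json
    from dataclasses import asdict

    arrays = {f"param/{k}": v for k, v in model.state_dict().items()}
    meta = {"config": asdict(model.config), "lm_hash": lm_hash}
    arrays["meta_json"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_residue_model(path, expect_lm_hash: str | None = None) -> ResidueCNN:
    import json

    with np.load(path) as npz:
        meta = json.loads(bytes(npz["meta_json"]).decode())
        if expect_lm_hash is not None and meta["lm_hash"] not in ("", expect_lm_hash):
            raise ValueError(
                "model was trained against a different LM checkpoint "
                f"({meta['lm_hash'][:12]}...)"
            )
        model = ResidueCNN(ResidueModelConfig(**meta["config"]))
        model.load_state_dict(
            {k[len("param/"):]: npz[k] for k in npz.files if k.startswith("param/")}
        )
    model.lm_hash = meta["lm_hash"]
    return model
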