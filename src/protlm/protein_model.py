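"""Per-protein multi-task feed-forward predictor.

A mean-pooled protein vector (1024-d contextual embedding or 100-d 3-mer
embedding) is compressed to 32 features, passed through dropout (25%),
batch normalization and ReLU, and classified by two softmax heads:
10-class subcellular localization and membrane-bound vs. water-soluble.
The two cross-entropies are summed before backpropagation; proteins whose
membrane annotation is "unknown" contribute no membrane loss but still
train the localization head. Free parameters: d*32+32 + 64 + 330 + 66
(33,260 at d=1024).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .fixtures import LOCALIZATION_CLASSES
from .nn import Adam, Module, Parameter, Tensor, dropout, softmax_cross_entropy

__all__ = [
    "ProteinModelConfig",
    "ProteinPredictions",
    "ProteinMLP",
    "build_protein_model",
    "train_protein_model",
    "predict_protein",
]

N_LOC = 10
N_MEM = 2
_BN_EPS = 1e-5


@dataclass(frozen=True)
class ProteinModelConfig:
    input_dim: int
    hidden_dim: int = 32
    dropout: float = 0.25
    learning_rate: float = 0.001
    batch_size: int = 64
    holdout_fraction: float = 0.1
    patience: int = 10
    max_epochs: int = 200

    def __post_init__(self) -> None:
        if self.input_dim < 1 or self.hidden_dim < 1:
            raise ValueError("dimensions must be positive")


class ProteinMLP(Module):
    """compress -> dropout -> batch norm -> ReLU -> two softmax heads."""

    def __init__(self, config: ProteinModelConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.config = config
        d, h = config.input_dim, config.hidden_dim

        def init(shape):
            scale = np.sqrt(1.0 / shape[0])
            return Parameter(rng.uniform(-scale, scale, shape).astype(np.float32))

        self.w1 = init((d, h))
        self.b1 = Parameter(np.zeros(h, dtype=np.float32))
        self.bn_gamma = Parameter(np.ones(h, dtype=np.float32))
        self.bn_beta = Parameter(np.zeros(h, dtype=np.float32))
        self.w_loc = init((h, N_LOC))
        self.b_loc = Parameter(np.zeros(N_LOC, dtype=np.float32))
        self.w_mem = init((h, N_MEM))
        self.b_mem = Parameter(np.zeros(N_MEM, dtype=np.float32))
        # running statistics are buffers, not trainable parameters
        self._running_mean = np.zeros(h, dtype=np.float32)
        self._running_var = np.ones(h, dtype=np.float32)
        self._bn_momentum = 0.1

    def forward(
        self,
        x: np.ndarray,  # (B, d)
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> tuple[Tensor, Tensor]:
        """(localization logits, membrane logits)."""
        h = Tensor(x.astype(np.float32)) @ self.w1 + self.b1
        h = dropout(h, self.config.dropout, rng, training)
        if training:
            mu = h.mean(axis=0)
            var = ((h - mu) * (h - mu)).mean(axis=0)
            self._running_mean += self._bn_momentum * (
                mu.data - self._running_mean
            )
            self._running_var += self._bn_momentum * (var.data - self._running_var)
            norm = (h - mu) / (var + _BN_EPS).sqrt()
        else:
            norm = (h - Tensor(self._running_mean)) / Tensor(
                np.sqrt(self._running_var + _BN_EPS)
            )
        z = (norm * self.bn_gamma + self.bn_beta).relu()
        return z @ self.w_loc + self.b_loc, z @ self.w_mem + self.b_mem


def build_protein_model(config: ProteinModelConfig, seed: int = 0) -> ProteinMLP:
    return ProteinMLP(config, seed=seed)


@dataclass(frozen=True)
class ProteinPredictions:
    """Localization and membrane probabilities plus argmax labels."""

    record_id: str
    localization_probs: np.ndarray
    membrane_probs: np.ndarray
    localization: str = field(init=False)
    membrane: str = field(init=False)

    def __post_init__(self) -> None:
        if not np.isclose(self.localization_probs.sum(), 1.0, atol=1e-5):
            raise ValueError("localization probabilities must sum to 1")
        if not np.isclose(self.membrane_probs.sum(), 1.0, atol=1e-5):
            raise ValueError("membrane probabilities must sum to 1")
        object.__setattr__(
            self, "localization",
            LOCALIZATION_CLASSES[int(self.localization_probs.argmax())],
        )
        object.__setattr__(
            self, "membrane",
            ("soluble", "membrane")[int(self.membrane_probs.argmax())],
        )


def _encode_labels(
    ids: Sequence[str], labels: Mapping[str, tuple[str, str]]
) -> tuple[np.ndarray, np.ndarray]:
    loc = np.empty(len(ids), dtype=np.int64)
    mem = np.empty(len(ids), dtype=np.int64)
    for i, rid in enumerate(ids):
        loc_name, mem_name = labels[rid]
        try:
            loc[i] = LOCALIZATION_CLASSES.index(loc_name)
        except ValueError:
            raise ValueError(f"record {rid!r}: unknown localization {loc_name!r}")
        if mem_name == "membrane":
            mem[i] = 1
        elif mem_name == "soluble":
            mem[i] = 0
        elif mem_name == "unknown":
            mem[i] = -1
        else:
            raise ValueError(f"record {rid!r}: unknown membrane status {mem_name!r}")
    return loc, mem


def _summed_loss(
    logits_loc: Tensor, logits_mem: Tensor, loc: np.ndarray, mem: np.ndarray
) -> Tensor:
    loss = softmax_cross_entropy(logits_loc, loc).mean()
    mask = mem >= 0
    if mask.any():
        nll = softmax_cross_entropy(logits_mem, np.maximum(mem, 0))
        w = mask.astype(np.float64)
        loss = loss + (nll * Tensor(w)).sum() / w.sum()
    return loss


def train_protein_model(
    model: ProteinMLP,
    vectors: Mapping[str, np.ndarray],
    labels: Mapping[str, tuple[str, str]],
    seed: int = 0,
    max_epochs: int | None = None,
) -> dict:
    """Adam training with summed task losses and hold-out early stopping."""
    cfg = model.config
    ids = sorted(vectors)
    missing = [i for i in ids if i not in labels]
    if missing:
        raise ValueError(f"records without labels: {missing[:5]}")
    X = np.stack([np.asarray(vectors[i], dtype=np.float32) for i in ids])
    if X.shape[1] != cfg.input_dim:
        raise ValueError(f"model expects input dim {cfg.input_dim}, got {X.shape[1]}")
    loc, mem = _encode_labels(ids, labels)
    rng = np.random.default_rng(seed)
    n = len(ids)
    n_hold = max(1, int(round(cfg.holdout_fraction * n)))
    if n_hold >= n:
        raise ValueError("holdout split leaves no training data")
    perm = rng.permutation(n)
    hold, train = perm[:n_hold], perm[n_hold:]
    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    best = np.inf
    best_state = model.state_dict()
    best_stats = (model._running_mean.copy(), model._running_var.copy())
    since_best = 0
    history = {"train_loss": [], "holdout_loss": []}
    epochs = cfg.max_epochs if max_epochs is None else max_epochs
    for _ in range(epochs):
        order = rng.permutation(len(train))
        ep = 0.0
        nb = 0
        for b0 in range(0, len(order), cfg.batch_size):
            sel = train[order[b0 : b0 + cfg.batch_size]]
            lo, lm = model.forward(X[sel], training=True, rng=rng)
            loss = _summed_loss(lo, lm, loc[sel], mem[sel])
            opt.zero_grad()
            loss.backward()
            opt.step()
            ep += float(loss.data)
            nb += 1
        lo, lm = model.forward(X[hold], training=False)
        hold_loss = float(_summed_loss(lo, lm, loc[hold], mem[hold]).data)
        history["train_loss"].append(ep / max(nb, 1))
        history["holdout_loss"].append(hold_loss)
        if hold_loss < best - 1e-6:
            best = hold_loss
            best_state = model.state_dict()
            best_stats = (model._running_mean.copy(), model._running_var.copy())
            since_best = 0
        else:
            since_best += 1
            if since_best >= cfg.patience:
                break
    model.load_state_dict(best_state)
    model._running_mean, model._running_var = best_stats
    return history


def predict_protein(
    model: ProteinMLP, vectors: Mapping[str, np.ndarray]
) -> list[ProteinPredictions]:
    """Inference-mode predictions; deterministic functions of the input."""
    ids = list(vectors)
    X = np.stack([np.asarray(vectors[i], dtype=np.float32) for i in ids])
    if X.shape[1] != model.config.input_dim:
        raise ValueError(
            f"model expects input dim {model.config.input_dim}, got {X.shape[1]}"
        )
    lo, lm = model.forward(X, training=False)

    def softmax(z):
        z = z - z.max(axis=-1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=-1, keepdims=True)

    pl, pm = softmax(lo.data), softmax(lm.data)
    return [
        ProteinPredictions(rid, pl[i], pm[i]) for i, rid in enumerate(ids)
    ]


# -- persistence -----------------------------------------------------------

def save_protein_model(path, model: ProteinMLP, lm_hash: str = "") -> None:
    """npz archive: config JSON + parameters + batch-norm running buffers."""
    import json
    from dataclasses import asdict

    arrays = {f"param/{k}": v for k, v in model.state_dict().items()}
    arrays["buffer/running_mean"] = model._running_mean
    arrays["buffer/running_var"] = model._running_var
    meta = {"config": asdict(model.config), "lm_hash": lm_hash}
    arrays["meta_json"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_protein_model(path, expect_lm_hash: str | None = None) -> ProteinMLP:
    import json

    with np.load(path) as npz:
        meta = json.loads(bytes(npz["meta_json"]).decode())
        if expect_lm_hash is not None and meta["lm_hash"] not in ("", expect_lm_hash):
            raise ValueError(
                "model was trained against a different LM checkpoint "
                f"({meta['lm_hash'][:12]}...)"
            )
        model = ProteinMLP(ProteinModelConfig(**meta["config"]))
        model.load_state_dict(
            {k[len("param/"):]: npz[k] for k in npz.files if k.startswith("param/")}
        )
        model._running_mean = npz["buffer/running_mean"].copy()
        model._running_var = npz["buffer/running_var"].copy()
    model.lm_hash = meta["lm_hash"]
    return model
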