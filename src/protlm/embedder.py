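"""Contextual embedding extraction from a trained bidirectional LM.

Three layers are extracted per residue: layer 0 is the context-independent
word-encoder output (duplicated across the forward/backward halves so all
layers share one width), layers 1 and 2 are the recurrent outputs with the
forward and backward halves concatenated. The default combination sums the
three layer matrices elementwise (per-residue width = one layer, 1024 for
the paper preset); ``concat`` stacks them horizontally (3x the width) for
research use. Per-protein vectors are the arithmetic mean over residues.

Batching for inference follows the token-cap strategy: proteins sorted by
length and packed greedily into batches of at most ``token_cap`` residues
(default 15,000), oversized proteins going alone.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import h5py
import numpy as np

from .bilm import BiLM, model_hash, _pad_batch, _reverse_padded
from .corpus import ProteinRecord, tokenize

__all__ = [
    "ResidueEmbeddings",
    "ProteinEmbedding",
    "BatchPlan",
    "embed_residues",
    "pool_protein",
    "plan_batches",
    "write_store",
    "read_store",
]

MODES = ("sum", "concat")


@dataclass(frozen=True)
class ResidueEmbeddings:
    """Per-residue embedding matrix (length x D) for one protein."""

    record_id: str
    matrix: np.ndarray
    mode: str

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        if not np.isfinite(self.matrix).all():
            raise ValueError(f"{self.record_id}: non-finite embedding values")

    def __len__(self) -> int:
        return self.matrix.shape[0]


@dataclass(frozen=True)
class ProteinEmbedding:
    """Mean-pooled per-protein vector."""

    record_id: str
    vector: np.ndarray


def _layer_matrices(
    model: BiLM, records: Sequence[ProteinRecord]
) -> list[np.ndarray]:
    """Stacked (L, 3, 2P) layer representations per record.

    The forward state at residue i has read tokens up to and including i;
    the backward state has read from the end down to i. Start/end tokens are
    dropped from the output rows.
    """
    vocab = model.config.vocab
    token_lists = [tokenize(r, vocab) for r in records]
    tokens, lengths = _pad_batch(token_lists, vocab.pad_index)
    rev = _reverse_padded(tokens, lengths)
    lex = model.char_cnn.lexicon()
    wv_f, (f1, f2), _ = model.run_direction(tokens, "forward", lexicon=lex)
    _, (b1, b2), _ = model.run_direction(rev, "backward", lexicon=lex)
    # (B, T, P) arrays
    word = np.stack([t.data for t in wv_f], axis=1)
    fwd1 = np.stack([t.data for t in f1], axis=1)
    fwd2 = np.stack([t.data for t in f2], axis=1)
    bwd1 = np.stack([t.data for t in b1], axis=1)
    bwd2 = np.stack([t.data for t in b2], axis=1)
    out = []
    for i, rec in enumerate(records):
        L = len(rec)
        n_tok = L + 2
        sl = slice(1, L + 1)  # residue token positions in the forward layout
        # backward direction ran over reversed tokens; map back to sequence order
        rsl = slice(n_tok - L - 1, n_tok - 1)
        b1_i = bwd1[i, rsl][::-1]
        b2_i = bwd2[i, rsl][::-1]
        layer0 = np.concatenate([word[i, sl], word[i, sl]], axis=1)
        layer1 = np.concatenate([fwd1[i, sl], b1_i], axis=1)
        layer2 = np.concatenate([fwd2[i, sl], b2_i], axis=1)
        out.append(np.stack([layer0, layer1, layer2], axis=1).astype(np.float32))
    return out


def embed_residues(
    model: BiLM,
    records: Sequence[ProteinRecord],
    mode: str = "sum",
    token_cap: int = 15000,
) -> list[ResidueEmbeddings]:
    """Embed records with the trained model (inference mode, no dropout).

    ``mode="sum"`` sums the three layer matrices (D = 2 x projection);
    ``mode="concat"`` concatenates them (D = 6 x projection). Layers are
    combined unweighted -- no fine-tuning, no learned layer mixture.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    plan = plan_batches(records, token_cap=token_cap)
    by_id = {r.id: r for r in records}
    results: dict[str, ResidueEmbeddings] = {}
    for batch_ids in plan.batches:
        batch = [by_id[rid] for rid in batch_ids]
        for rec, layers in zip(batch, _layer_matrices(model, batch)):
            if mode == "sum":
                mat = layers.sum(axis=1)
            else:
                mat = layers.reshape(layers.shape[0], -1)
            results[rec.id] = ResidueEmbeddings(rec.id, mat, mode)
    return [results[r.id] for r in records]


def pool_protein(embeddings: ResidueEmbeddings) -> ProteinEmbedding:
    """Arithmetic mean over residue rows."""
    if len(embeddings) == 0:
        raise ValueError("cannot pool an empty embedding matrix")
    return ProteinEmbedding(embeddings.record_id,
                            embeddings.matrix.mean(axis=0))


@dataclass(frozen=True)
class BatchPlan:
    """Length-sorted greedy packing of records under a token cap."""

    batches: tuple[tuple[str, ...], ...]
    token_cap: int


def plan_batches(records: Sequence[ProteinRecord], token_cap: int = 15000) -> BatchPlan:
    """Sort records ascending by length and pack greedily under the cap.

    A single protein longer than the cap forms its own batch. Deterministic;
    every record appears exactly once.
    """
    if not records:
        raise ValueError("no records to batch")
    if token_cap < 1:
        raise ValueError("token cap must be >= 1")
    order = sorted(records, key=lambda r: (len(r), r.id))
    batches: list[tuple[str, ...]] = []
    current: list[str] = []
    used = 0
    for rec in order:
        if current and used + len(rec) > token_cap:
            batches.append(tuple(current))
            current, used = [], 0
        current.append(rec.id)
        used += len(rec)
    if current:
        batches.append(tuple(current))
    return BatchPlan(tuple(batches), token_cap)


def write_store(
    path, embeddings: Sequence[ResidueEmbeddings], model: BiLM | None = None,
    lm_hash: str | None = None,
) -> None:
    """Persist embeddings to HDF5, one float32 dataset per record id.

    File attributes record the layer-combination mode, the per-layer width
    and the hash of the producing checkpoint, so consumers can refuse
    embeddings from a mismatched model.
    """
    if not embeddings:
        raise ValueError("nothing to write")
    modes = {e.mode for e in embeddings}
    if len(modes) != 1:
        raise ValueError("mixed layer-combination modes in one store")
    ids = [e.record_id for e in embeddings]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate record ids: {dupes}")
    if lm_hash is None:
        lm_hash = model_hash(model) if model is not None else "unknown"
    with h5py.File(path, "w") as fh:
        fh.attrs["mode"] = embeddings[0].mode
        fh.attrs["model_hash"] = lm_hash
        d = embeddings[0].matrix.shape[1]
        fh.attrs["per_layer_dim"] = d // (1 if embeddings[0].mode == "sum" else 3)
        for e in embeddings:
            fh.create_dataset(e.record_id, data=e.matrix.astype(np.float32))


def read_store(
    path, ids: Sequence[str] | None = None, expect_mode: str | None = None,
    expect_hash: str | None = None,
) -> list[ResidueEmbeddings]:
    """Load embeddings back; optionally enforce mode/model-hash metadata."""
    with h5py.File(path, "r") as fh:
        mode = fh.attrs["mode"]
        if expect_mode is not None and mode != expect_mode:
            raise ValueError(
                f"store was written in mode {mode!r} but {expect_mode!r} was required"
            )
        if expect_hash is not None and fh.attrs["model_hash"] != expect_hash:
            raise ValueError(
                "store was produced by a different model checkpoint "
                f"({fh.attrs['model_hash'][:12]}... != {expect_hash[:12]}...)"
            )
        if ids is None:
            ids = list(fh.keys())
        out = []
        for rid in ids:
            if rid not in fh:
                raise KeyError(f"record id {rid!r} not present in store")
            out.append(ResidueEmbeddings(rid, fh[rid][()], mode))
    return out
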