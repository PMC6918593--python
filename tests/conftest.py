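"""Shared fixtures: the desk-scale study conditions.

The expensive artifacts (trained language models, embeddings, downstream
models) are session-scoped and shared across test modules. All seeds are
fixed so every run reproduces the same numbers.
"""

from __future__ import annotations

import numpy as np
import pytest

from protlm.bilm import BiLMConfig, build_bilm, train_bilm
from protlm.embedder import embed_residues, pool_protein
from protlm.encoders import (
    ResidueFeatureMatrix,
    kmer_encode,
    one_hot_encode,
    train_kmer_skipgram,
)
from protlm.fixtures import (
    default_grammar,
    generate_corpus,
    generate_uniform_corpus,
)
from protlm.metrics import q_accuracy
from protlm.protein_model import (
    ProteinModelConfig,
    build_protein_model,
    predict_protein,
    train_protein_model,
)
from protlm.residue_model import (
    ResidueModelConfig,
    build_residue_model,
    predict_residues,
    train_residue_model,
)


@pytest.fixture(scope="session")
def grammar_spec():
    return default_grammar()


@pytest.fixture(scope="session")
def lm_corpus(grammar_spec):
    """200 grammar proteins for language-model training."""
    return generate_corpus(grammar_spec, 200, seed=11)


@pytest.fixture(scope="session")
def trained_lm(lm_corpus):
    """Mini-preset biLM trained for 20 epochs on the grammar corpus."""
    model = build_bilm(BiLMConfig.mini(), seed=1)
    train_bilm(model, lm_corpus.records, epochs=20, seed=7, eval_records=24)
    return model


@pytest.fixture(scope="session")
def uniform_records():
    """300 i.i.d. uniform-residue proteins (analytic perplexity floor 20)."""
    return generate_uniform_corpus(300, seed=9)


@pytest.fixture(scope="session")
def uniform_lm(uniform_records):
    model = build_bilm(BiLMConfig.mini(), seed=2)
    train_bilm(model, uniform_records, epochs=15, seed=3, eval_records=24)
    return model


@pytest.fixture(scope="session")
def task_fixtures(grammar_spec):
    """250 labeled proteins for the per-residue task (200 train / 50 test)."""
    return generate_corpus(grammar_spec, 250, seed=21, id_prefix="task")


@pytest.fixture(scope="session")
def task_embeddings(trained_lm, task_fixtures):
    return embed_residues(trained_lm, task_fixtures.records, mode="sum")


@pytest.fixture(scope="session")
def residue_labels(task_fixtures):
    return {
        r.id: {
            "ss3": task_fixtures.ss3[r.id],
            "ss8": task_fixtures.ss8[r.id],
            "disorder": task_fixtures.disorder[r.id],
        }
        for r in task_fixtures.records
    }


@pytest.fixture(scope="session")
def q3_scores(task_fixtures, task_embeddings, residue_labels):
    """Held-out Q3/Q8 for LM-embedding vs one-hot inputs, matched budgets."""
    records = task_fixtures.records
    train, test = records[:200], records[200:]
    feats = {
        "seqvec": {
            e.record_id: ResidueFeatureMatrix(e.record_id, e.matrix, "seqvec")
            for e in task_embeddings
        },
        "onehot": {r.id: one_hot_encode(r) for r in records},
    }
    scores = {}
    for name, table in feats.items():
        dim = table[train[0].id].channels
        model = build_residue_model(
            ResidueModelConfig(dim, scheme=name, batch_size=32), seed=3
        )
        train_residue_model(
            model, [table[r.id] for r in train], residue_labels,
            seed=4, max_epochs=25,
        )
        preds = predict_residues(model, [table[r.id] for r in test])
        scores[name] = {
            "Q3": q_accuracy(
                [p.ss3 for p in preds], [task_fixtures.ss3[r.id] for r in test]
            ).value,
            "Q8": q_accuracy(
                [p.ss8 for p in preds], [task_fixtures.ss8[r.id] for r in test]
            ).value,
        }
    return scores


@pytest.fixture(scope="session")
def loc_fixtures(grammar_spec):
    """400 labeled proteins for the per-protein task (320 train / 80 test)."""
    return generate_corpus(grammar_spec, 400, seed=31, id_prefix="loc")


@pytest.fixture(scope="session")
def kmer_model(lm_corpus):
    return train_kmer_skipgram(lm_corpus.records, epochs=3, seed=5)


@pytest.fixture(scope="session")
def q10_scores(trained_lm, loc_fixtures, kmer_model):
    """Held-out Q10 for pooled LM embeddings vs mean 3-mer vectors."""
    records = loc_fixtures.records
    train, test = records[:320], records[320:]
    embs = embed_residues(trained_lm, records, mode="sum")
    vecs = {
        "seqvec": {e.record_id: pool_protein(e).vector for e in embs},
        "kmer": {r.id: kmer_encode(r, kmer_model, "protein") for r in records},
    }
    labels = {
        r.id: (loc_fixtures.localization[r.id], loc_fixtures.membrane[r.id])
        for r in records
    }
    scores = {}
    for name, table in vecs.items():
        dim = len(next(iter(table.values())))
        model = build_protein_model(ProteinModelConfig(dim), seed=3)
        train_protein_model(
            model, {r.id: table[r.id] for r in train}, labels,
            seed=4, max_epochs=80,
        )
        preds = predict_protein(model, {r.id: table[r.id] for r in test})
        scores[name] = 100.0 * np.mean(
            [p.localization == loc_fixtures.localization[p.record_id]
             for p in preds]
        )
    return scores
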