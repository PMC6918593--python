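"""Non-contextual baseline encodings of protein sequences.

Four residue-level input schemes complement the contextual LM embeddings:

* ``onehot20`` -- unit vectors over the 20 standard residues; the five
  non-standard letters (U, O, B, Z, X) map to all-zero rows.
* ``blosum23`` -- the residue's raw integer row of a BLOSUM-family
  substitution matrix over the 23 symbols (20 standard + B, Z, X).
  BLOSUM65 is the default matrix. Matrices lack U/O rows, so U is looked
  up as C and O as K (their closest biochemical parents).
* ``profile50`` -- evolutionary-profile features in the alignment-server
  layout [one-hot 20 | substitution profile 20 | HMM transitions 7 |
  alignment diversity 3].
* ``kmer100`` -- a context-free skip-gram embedding of overlapping
  amino-acid 3-mers (100 dimensions), trained with negative sampling; a
  distinct 3-mer always maps to the same vector, the property that
  contrasts these embeddings with the contextual ones.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .corpus import STANDARD_AA, ProteinRecord

__all__ = [
    "SCHEME_CHANNELS",
    "ResidueFeatureMatrix",
    "SubstitutionMatrix",
    "load_blosum65",
    "read_ncbi_matrix",
    "write_ncbi_matrix",
    "one_hot_encode",
    "blosum_encode",
    "read_profile_features",
    "KmerEmbeddingModel",
    "train_kmer_skipgram",
    "kmer_encode",
    "concat_features",
]

BLOSUM_SYMBOLS = STANDARD_AA + "BZX"  # 23, fixed column order
_BLOSUM_ALIASES = {"U": "C", "O": "K"}

#: channel contract per scheme; None = model-dependent (contextual embeddings)
SCHEME_CHANNELS: dict[str, int | None] = {
    "onehot20": 20,
    "blosum23": 23,
    "profile50": 50,
    "kmer100": 100,
    "seqvec": None,
}


@dataclass(frozen=True)
class ResidueFeatureMatrix:
    """(length x channels) per-residue features under a named scheme."""

    record_id: str
    matrix: np.ndarray
    scheme: str

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix)
        if m.ndim != 2:
            raise ValueError(f"{self.record_id}: feature matrix must be 2-D")
        expected = _expected_channels(self.scheme)
        if expected is not None and m.shape[1] != expected:
            raise ValueError(
                f"{self.record_id}: scheme {self.scheme!r} requires {expected} "
                f"channels, got {m.shape[1]}"
            )
        if not np.isfinite(m).all():
            raise ValueError(f"{self.record_id}: non-finite feature values")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def channels(self) -> int:
        return self.matrix.shape[1]


def _expected_channels(scheme: str) -> int | None:
    if scheme in SCHEME_CHANNELS:
        return SCHEME_CHANNELS[scheme]
    if "+" in scheme:
        total = 0
        for part in scheme.split("+"):
            sub = _expected_channels(part)
            if sub is None:
                return None
            total += sub
        return total
    raise ValueError(f"unknown feature scheme {scheme!r}")


# -- substitution matrices -------------------------------------------------

@dataclass(frozen=True)
class SubstitutionMatrix:
    """Symmetric integer substitution scores over the 23 BLOSUM symbols."""

    symbols: str
    scores: np.ndarray
    name: str

    def __post_init__(self) -> None:
        s = np.asarray(self.scores)
        if s.shape != (len(self.symbols), len(self.symbols)):
            raise ValueError("score matrix shape must match symbol count")
        if not np.array_equal(s, s.T):
            raise ValueError(f"{self.name}: substitution matrix must be symmetric")

    def row(self, symbol: str) -> np.ndarray:
        symbol = _BLOSUM_ALIASES.get(symbol, symbol)
        i = self.symbols.find(symbol)
        if i < 0:
            raise KeyError(f"no substitution scores for symbol {symbol!r}")
        return self.scores[i]


def load_blosum65() -> SubstitutionMatrix:
    """BLOSUM65 restricted to the 23 symbols, from biotite's matrix database."""
    from biotite.sequence import ProteinSequence
    from biotite.sequence.align import SubstitutionMatrix as BtMatrix

    alph = ProteinSequence.alphabet
    bt = BtMatrix(alph, alph, "BLOSUM65")
    full = bt.score_matrix()
    letters = alph.get_symbols()
    idx = [letters.index(ch) for ch in BLOSUM_SYMBOLS]
    scores = full[np.ix_(idx, idx)].astype(np.int64)
    return SubstitutionMatrix(BLOSUM_SYMBOLS, scores, "BLOSUM65")


def read_ncbi_matrix(path, name: str | None = None) -> SubstitutionMatrix:
    """Read a substitution matrix in NCBI text format (# comments, header row)."""
    with open(path, encoding="utf-8") as fh:
        rows: dict[str, dict[str, int]] = {}
        header: list[str] | None = None
        for line in fh:
            line = line.rstrip()
            if not line or line.lstrip().startswith("#"):
                continue
            parts = line.split()
            if header is None:
                header = parts
                continue
            sym, values = parts[0], parts[1:]
            rows[sym] = dict(zip(header, map(int, values)))
    if header is None:
        raise ValueError("no matrix content found")
    missing = set(BLOSUM_SYMBOLS) - set(rows)
    if missing:
        raise ValueError(f"matrix lacks required symbols: {sorted(missing)}")
    scores = np.array(
        [[rows[a][b] for b in BLOSUM_SYMBOLS] for a in BLOSUM_SYMBOLS],
        dtype=np.int64,
    )
    return SubstitutionMatrix(BLOSUM_SYMBOLS, scores,
                              name or str(path))


def write_ncbi_matrix(path, matrix: SubstitutionMatrix) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# {matrix.name}\n")
        fh.write("   " + "  ".join(matrix.symbols) + "\n")
        for i, sym in enumerate(matrix.symbols):
            fh.write(sym + " " + " ".join(f"{v:3d}" for v in matrix.scores[i]) + "\n")


# -- fixed encodings -------------------------------------------------------

def one_hot_encode(record: ProteinRecord) -> ResidueFeatureMatrix:
    """One-hot over the 20 standard residues; non-standard letters -> zeros."""
    mat = np.zeros((len(record), 20), dtype=np.float32)
    for i, ch in enumerate(record.sequence):
        j = STANDARD_AA.find(ch)
        if j >= 0:
            mat[i, j] = 1.0
    return ResidueFeatureMatrix(record.id, mat, "onehot20")


def blosum_encode(
    record: ProteinRecord, matrix: SubstitutionMatrix | None = None
) -> ResidueFeatureMatrix:
    """Raw integer substitution-score rows (23 channels) per residue."""
    if matrix is None:
        matrix = load_blosum65()
    mat = np.empty((len(record), 23), dtype=np.float32)
    for i, ch in enumerate(record.sequence):
        mat[i] = matrix.row(ch)
    return ResidueFeatureMatrix(record.id, mat, "blosum23")


def read_profile_features(
    path, records: Sequence[ProteinRecord]
) -> list[ResidueFeatureMatrix]:
    """Load 50-channel profile features for ``records`` from HDF5 or TSV.

    HDF5 stores one (length x 50) dataset per record id. The TSV layout has
    columns id, pos (1-based) and the 50 feature columns. Length mismatches
    and missing records raise errors naming the record.
    """
    path = str(path)
    if path.endswith((".h5", ".hdf5")):
        import h5py

        with h5py.File(path, "r") as fh:
            out = []
            for rec in records:
                if rec.id not in fh:
                    raise KeyError(f"no profile features for record {rec.id!r}")
                mat = fh[rec.id][()]
                _check_profile(rec, mat)
                out.append(ResidueFeatureMatrix(rec.id, mat.astype(np.float32),
                                                "profile50"))
            return out
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    out = []
    for rec in records:
        sub = df[df["id"] == rec.id].sort_values("pos")
        if sub.empty:
            raise KeyError(f"no profile features for record {rec.id!r}")
        mat = sub.drop(columns=["id", "pos"]).to_numpy(dtype=np.float32)
        _check_profile(rec, mat)
        out.append(ResidueFeatureMatrix(rec.id, mat, "profile50"))
    return out


def _check_profile(rec: ProteinRecord, mat: np.ndarray) -> None:
    if mat.shape != (len(rec), 50):
        raise ValueError(
            f"record {rec.id!r}: profile shape {mat.shape} does not match "
            f"sequence length {len(rec)} x 50"
        )
    if not np.isfinite(mat).all():
        raise ValueError(f"record {rec.id!r}: non-finite profile values")
    # substitution-profile block is a distribution; clip tiny numeric drift
    mat[:, 20:40] = np.clip(mat[:, 20:40], 0.0, 1.0)


# -- k-mer skip-gram embeddings --------------------------------------------

@dataclass
class KmerEmbeddingModel:
    """Context-free 3-mer -> vector mapping from skip-gram training."""

    k: int
    dim: int
    vocab: dict[str, int]
    vectors: np.ndarray  # (V, dim)
    corpus_hash: str = ""
    seed: int = 0

    def vector(self, kmer: str) -> np.ndarray:
        """Embedding of one 3-mer; unseen 3-mers map to the zero vector."""
        i = self.vocab.get(kmer)
        if i is None:
            return np.zeros(self.dim, dtype=np.float32)
        return self.vectors[i]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))


def train_kmer_skipgram(
    records: Sequence[ProteinRecord],
    dim: int = 100,
    window: int = 2,
    negatives: int = 5,
    epochs: int = 3,
    lr: float = 0.05,
    seed: int = 0,
) -> KmerEmbeddingModel:
    """Skip-gram with negative sampling over overlapping-3-mer sentences.

    Each protein is split into overlapping 3-mers (stride 1); the model
    predicts 3-mers within ``window`` positions of the center 3-mer.
    Negatives are drawn from the unigram distribution raised to 3/4. The
    learning rate decays linearly. Deterministic given the seed.
    """
    if not records:
        raise ValueError("empty corpus")
    k = 3
    sentences = []
    for rec in records:
        if len(rec) < k:
            continue
        seq = rec.sequence
        sentences.append([seq[i : i + k] for i in range(len(seq) - k + 1)])
    if not sentences:
        raise ValueError("no protein of length >= 3 in the corpus")
    vocab_list = sorted({km for s in sentences for km in s})
    vocab = {km: i for i, km in enumerate(vocab_list)}
    counts = np.zeros(len(vocab))
    centers, contexts = [], []
    for s in sentences:
        idx = np.array([vocab[km] for km in s])
        for km in idx:
            counts[km] += 1
        for off in range(1, window + 1):
            if len(idx) > off:
                centers.append(idx[:-off]); contexts.append(idx[off:])
                centers.append(idx[off:]); contexts.append(idx[:-off])
    centers = np.concatenate(centers)
    contexts = np.concatenate(contexts)
    noise = counts**0.75
    noise /= noise.sum()
    rng = np.random.default_rng(seed)
    V = len(vocab)
    U = ((rng.random((V, dim)) - 0.5) / dim).astype(np.float64)
    C = np.zeros((V, dim), dtype=np.float64)
    n_pairs = len(centers)
    total_steps = epochs * n_pairs
    done = 0
    chunk = 2048
    for _ in range(epochs):
        order = rng.permutation(n_pairs)
        for c0 in range(0, n_pairs, chunk):
            sel = order[c0 : c0 + chunk]
            cen, ctx = centers[sel], contexts[sel]
            neg = rng.choice(V, size=(len(sel), negatives), p=noise)
            step_lr = lr * max(1.0 - done / total_steps, 1e-4)
            u = U[cen]                                   # (B, d)
            vp = C[ctx]                                  # (B, d)
            vn = C[neg]                                  # (B, m, d)
            gp = _sigmoid((u * vp).sum(1)) - 1.0         # (B,)
            gn = _sigmoid((u[:, None, :] * vn).sum(2))   # (B, m)
            du = gp[:, None] * vp + (gn[:, :, None] * vn).sum(1)
            np.add.at(U, cen, -step_lr * du)
            np.add.at(C, ctx, -step_lr * gp[:, None] * u)
            np.add.at(C, neg.reshape(-1),
                      -step_lr * (gn[:, :, None] * u[:, None, :]).reshape(-1, dim))
            done += len(sel)
    h = hashlib.sha256("\n".join(r.sequence for r in records).encode()).hexdigest()
    return KmerEmbeddingModel(k, dim, vocab, U.astype(np.float32), h, seed)


def kmer_encode(
    record: ProteinRecord, model: KmerEmbeddingModel, level: str = "residue"
):
    """Encode a sequence with context-free 3-mer vectors.

    Residue level: residue i takes the vector of the 3-mer centered at i;
    the two terminal residues reuse the first/last 3-mer. Protein level:
    the mean over all overlapping 3-mer vectors (a ``dim``-vector).
    """
    L = len(record)
    if L < model.k:
        raise ValueError(f"record {record.id!r}: sequence shorter than {model.k}")
    seq = record.sequence
    kmers = [seq[i : i + model.k] for i in range(L - model.k + 1)]
    vecs = np.stack([model.vector(km) for km in kmers])
    if level == "protein":
        return vecs.mean(axis=0)
    if level != "residue":
        raise ValueError(f"unknown level {level!r}")
    rows = np.empty((L, model.dim), dtype=np.float32)
    rows[0] = vecs[0]
    rows[-1] = vecs[-1]
    for i in range(1, L - 1):
        rows[i] = vecs[i - 1]
    return ResidueFeatureMatrix(record.id, rows, "kmer100")


def concat_features(
    a: ResidueFeatureMatrix, b: ResidueFeatureMatrix
) -> ResidueFeatureMatrix:
    """Horizontal concatenation [a | b] of two schemes for one record."""
    if a.record_id != b.record_id:
        raise ValueError(f"record mismatch: {a.record_id!r} vs {b.record_id!r}")
    if len(a) != len(b):
        raise ValueError(f"{a.record_id}: length mismatch {len(a)} vs {len(b)}")
    return ResidueFeatureMatrix(
        a.record_id,
        np.concatenate([a.matrix, b.matrix], axis=1),
        f"{a.scheme}+{b.scheme}",
    )
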