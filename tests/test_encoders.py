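"""Baseline encodings: one-hot, BLOSUM65 rows, profiles, 3-mer skip-gram."""

import numpy as np
import pytest

from protlm.corpus import DEFAULT_ALPHABET, STANDARD_AA, ProteinRecord
from protlm.encoders import (
    ResidueFeatureMatrix,
    SCHEME_CHANNELS,
    blosum_encode,
    concat_features,
    kmer_encode,
    load_blosum65,
    one_hot_encode,
    read_ncbi_matrix,
    read_profile_features,
    train_kmer_skipgram,
    write_ncbi_matrix,
)
from protlm.fixtures import (
    default_grammar,
    generate_corpus,
    generate_profile_fixture,
    write_profile_store,
)


class TestOneHot:
    def test_standard_residue_is_unit_vector(self):
        m = one_hot_encode(ProteinRecord("p", "A")).matrix
        assert m.shape == (1, 20) and m.sum() == 1.0 and m[0, 0] == 1.0

    def test_rare_residues_map_to_zero_rows(self):
        m = one_hot_encode(ProteinRecord("p", "UOXBZ")).matrix
        assert np.array_equal(m, np.zeros((5, 20)))

    def test_row_sums_over_full_alphabet_are_binary(self):
        m = one_hot_encode(ProteinRecord("p", DEFAULT_ALPHABET.letters)).matrix
        sums = m.sum(axis=1)
        assert set(sums.tolist()) <= {0.0, 1.0}
        assert (sums[:20] == 1.0).all() and (sums[20:] == 0.0).all()


class TestBlosum:
    def test_every_residue_gets_23_channels(self):
        enc = blosum_encode(ProteinRecord("p", DEFAULT_ALPHABET.letters))
        assert enc.matrix.shape == (25, 23)
        assert enc.scheme == "blosum23"

    def test_identical_residues_identical_rows(self):
        m = blosum_encode(ProteinRecord("p", "AA")).matrix
        assert np.array_equal(m[0], m[1])

    def test_rows_match_independently_loaded_matrix(self):
        """Cross-check against biotite's matrix database, loaded separately."""
        from biotite.sequence import ProteinSequence
        from biotite.sequence.align import SubstitutionMatrix as BtMatrix

        alph = ProteinSequence.alphabet
        bt = BtMatrix(alph, alph, "BLOSUM65").score_matrix()
        letters = alph.get_symbols()
        enc = blosum_encode(ProteinRecord("p", "AW"))
        for row, ch in zip(enc.matrix, "AW"):
            for j, col in enumerate(STANDARD_AA + "BZX"):
                assert row[j] == bt[letters.index(ch), letters.index(col)]

    def test_u_and_o_alias_their_biochemical_parents(self):
        m = blosum_encode(ProteinRecord("p", "UCOK")).matrix
        assert np.array_equal(m[0], m[1])  # U -> C
        assert np.array_equal(m[2], m[3])  # O -> K

    def test_ncbi_text_format_roundtrip(self, tmp_path):
        mat = load_blosum65()
        path = tmp_path / "blosum65.txt"
        write_ncbi_matrix(path, mat)
        back = read_ncbi_matrix(path, name="BLOSUM65")
        assert np.array_equal(back.scores, mat.scores)
        assert back.symbols == mat.symbols


class TestProfiles:
    @pytest.fixture()
    def fixture_set(self):
        return generate_corpus(default_grammar(), 4, seed=2)

    def test_hdf5_reader_returns_expected_shapes(self, tmp_path, fixture_set):
        path = tmp_path / "prof.h5"
        write_profile_store(path, fixture_set, seed=0)
        feats = read_profile_features(path, fixture_set.records)
        for f, r in zip(feats, fixture_set.records):
            assert f.matrix.shape == (len(r), 50)
            assert f.scheme == "profile50"

    def test_onehot_block_matches_one_hot_encoder(self, tmp_path, fixture_set):
        path = tmp_path / "prof.h5"
        write_profile_store(path, fixture_set, seed=0)
        feats = read_profile_features(path, fixture_set.records)
        for f, r in zip(feats, fixture_set.records):
            assert np.array_equal(f.matrix[:, :20], one_hot_encode(r).matrix)

    def test_missing_record_raises(self, tmp_path, fixture_set):
        path = tmp_path / "prof.h5"
        write_profile_store(path, fixture_set.records[:2], seed=0)
        with pytest.raises(KeyError):
            read_profile_features(path, fixture_set.records)

    def test_length_mismatch_names_the_record(self, tmp_path, fixture_set):
        import h5py

        path = tmp_path / "prof.h5"
        rec = fixture_set.records[0]
        with h5py.File(path, "w") as fh:
            fh.create_dataset(rec.id, data=np.zeros((len(rec) + 1, 50)))
        with pytest.raises(ValueError, match=rec.id):
            read_profile_features(path, [rec])

    def test_tsv_reader_agrees_with_hdf5(self, tmp_path, fixture_set):
        rec = fixture_set.records[0]
        prof = generate_profile_fixture(rec, seed=0)
        tsv = tmp_path / "prof.tsv"
        cols = "\t".join(f"f{i}" for i in range(50))
        with open(tsv, "w") as fh:
            fh.write(f"id\tpos\t{cols}\n")
            for i in range(len(rec)):
                vals = "\t".join(f"{x:.8f}" for x in prof[i])
                fh.write(f"{rec.id}\t{i + 1}\t{vals}\n")
        (f,) = read_profile_features(tsv, [rec])
        assert np.allclose(f.matrix, prof, atol=1e-6)


class TestKmer:
    def test_homopolymer_corpus_has_single_kmer(self):
        model = train_kmer_skipgram(
            [ProteinRecord("p", "A" * 30)], epochs=1, seed=0
        )
        assert set(model.vocab) == {"AAA"}

    def test_vectors_are_context_free(self, kmer_model):
        rec = ProteinRecord("p", "ACDACDACD")
        enc = kmer_encode(rec, kmer_model, "residue")
        # residue 1 and residue 4 both sit on the 3-mer ACD
        assert np.array_equal(enc.matrix[1], enc.matrix[4])
        assert np.array_equal(
            kmer_model.vector("ACD"), kmer_model.vector("ACD")
        )

    def test_training_is_deterministic(self):
        fx = generate_corpus(default_grammar(), 10, seed=1)
        a = train_kmer_skipgram(fx.records, epochs=1, seed=3)
        b = train_kmer_skipgram(fx.records, epochs=1, seed=3)
        assert np.array_equal(a.vectors, b.vectors)

    def test_unseen_kmer_maps_to_zero(self, kmer_model):
        assert np.array_equal(
            kmer_model.vector("XXX"), np.zeros(kmer_model.dim)
        )

    def test_cooccurring_kmers_are_closer_than_non_cooccurring(
        self, kmer_model, lm_corpus
    ):
        """Mean cosine similarity, co-occurrence counted independently."""
        from collections import Counter

        co = Counter()
        for r in lm_corpus.records:
            kms = [r.sequence[i : i + 3] for i in range(len(r) - 2)]
            for i in range(len(kms) - 1):
                co[frozenset((kms[i], kms[i + 1]))] += 1
        ranked = sorted(
            (p for p in co if len(p) == 2), key=co.__getitem__, reverse=True
        )
        frequent = [tuple(p) for p in ranked[:200]]
        assert co[frozenset(frequent[0])] >= 3  # the pairs really do co-occur
        vocab = sorted(kmer_model.vocab)
        rng = np.random.default_rng(0)
        never = []
        while len(never) < 200:
            a, b = rng.choice(vocab, 2, replace=False)
            if frozenset((a, b)) not in co:
                never.append((a, b))

        def mean_cos(pairs):
            vals = []
            for a, b in pairs:
                va, vb = kmer_model.vector(a), kmer_model.vector(b)
                vals.append(
                    va @ vb / (np.linalg.norm(va) * np.linalg.norm(vb) + 1e-12)
                )
            return np.mean(vals)

        assert mean_cos(frequent[:200]) > mean_cos(never)

    def test_single_kmer_sequence_shares_one_vector(self, kmer_model):
        enc = kmer_encode(ProteinRecord("p", "ACD"), kmer_model, "residue")
        assert np.array_equal(enc.matrix[0], enc.matrix[1])
        assert np.array_equal(enc.matrix[1], enc.matrix[2])

    def test_protein_level_homopolymer_equals_single_vector(self, kmer_model):
        vec = kmer_encode(ProteinRecord("p", "AAAA"), kmer_model, "protein")
        assert np.allclose(vec, kmer_model.vector("AAA"))

    def test_residue_matrix_matches_per_kmer_lookup(self, kmer_model):
        rec = ProteinRecord("p", "ACDEFGHIKL")
        enc = kmer_encode(rec, kmer_model, "residue").matrix
        seq = rec.sequence
        kmers = [seq[i : i + 3] for i in range(len(seq) - 2)]
        expected = np.stack(
            [kmer_model.vector(kmers[0])]
            + [kmer_model.vector(kmers[i - 1]) for i in range(1, len(seq) - 1)]
            + [kmer_model.vector(kmers[-1])]
        )
        assert np.array_equal(enc, expected)

    def test_too_short_sequence_rejected(self, kmer_model):
        with pytest.raises(ValueError, match="shorter"):
            kmer_encode(ProteinRecord("p", "AC"), kmer_model)


class TestConcatAndSchemes:
    def test_profile_plus_embedding_channel_count(self):
        a = ResidueFeatureMatrix("r", np.zeros((5, 50)), "profile50")
        b = ResidueFeatureMatrix("r", np.ones((5, 1024)), "seqvec")
        c = concat_features(a, b)
        assert c.channels == 1074
        assert c.scheme == "profile50+seqvec"
        assert np.array_equal(c.matrix[:, :50], a.matrix)

    def test_mismatched_records_or_lengths_rejected(self):
        a = ResidueFeatureMatrix("r", np.zeros((5, 50)), "profile50")
        with pytest.raises(ValueError, match="record"):
            concat_features(
                a, ResidueFeatureMatrix("s", np.zeros((5, 20)), "onehot20")
            )
        with pytest.raises(ValueError, match="length"):
            concat_features(
                a, ResidueFeatureMatrix("r", np.zeros((6, 20)), "onehot20")
            )

    def test_concat_is_associative_in_column_order(self):
        rng = np.random.default_rng(4)
        mats = [rng.standard_normal((4, c)) for c in (50, 20, 23)]
        schemes = ["profile50", "onehot20", "blosum23"]
        parts = [
            ResidueFeatureMatrix("r", m, s) for m, s in zip(mats, schemes)
        ]
        left = concat_features(concat_features(parts[0], parts[1]), parts[2])
        assert np.array_equal(left.matrix, np.hstack(mats))

    @pytest.mark.parametrize(
        "scheme,channels",
        [("onehot20", 20), ("blosum23", 23), ("profile50", 50), ("kmer100", 100)],
    )
    def test_channel_contract_enforced(self, scheme, channels):
        assert SCHEME_CHANNELS[scheme] == channels
        ResidueFeatureMatrix("r", np.zeros((2, channels)), scheme)
        with pytest.raises(ValueError, match="channels"):
            ResidueFeatureMatrix("r", np.zeros((2, channels + 1)), scheme)
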