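"""The synthetic grammar generator: determinism, label consistency and the
statistical properties downstream modules rely on."""

import numpy as np
import pytest

from protlm.corpus import STANDARD_AA
from protlm.fixtures import (
    GrammarSpec,
    GrammarState,
    assign_protein_labels,
    default_grammar,
    generate_corpus,
    generate_profile_fixture,
    read_protein_labels,
    read_residue_labels,
    write_protein_labels,
    write_residue_labels,
)
from protlm.metrics import map_ss8_string


def test_same_spec_and_seed_reproduce_identical_sets():
    spec = default_grammar()
    a = generate_corpus(spec, 25, seed=3)
    b = generate_corpus(spec, 25, seed=3)
    assert [r.sequence for r in a.records] == [r.sequence for r in b.records]
    assert a.ss8 == b.ss8 and a.localization == b.localization
    assert a.membrane == b.membrane


def test_single_state_spec_yields_constant_labels():
    emission = np.zeros(20)
    emission[STANDARD_AA.index("A")] = 1.0
    spec = default_grammar()
    mono = GrammarSpec(
        states=(GrammarState("helix", "H", emission),),
        transitions=np.array([[1.0]]),
        class_state_weight={c: np.ones(1) for c in spec.class_state_weight},
        class_emission_tilt=spec.class_emission_tilt,
        unknown_membrane_fraction=0.0,
    )
    fx = generate_corpus(mono, 5, seed=1)
    for r in fx.records:
        assert set(r.sequence) == {"A"}
        assert set(fx.ss8[r.id]) == {"H"}


def test_degenerate_emissions_rejected():
    spec = default_grammar()
    bad_states = (
        GrammarState("a", "H", np.zeros(20)),
    )
    with pytest.raises(ValueError, match="sum to 1|degenerate"):
        GrammarSpec(
            states=bad_states,
            transitions=np.array([[1.0]]),
            class_state_weight={c: np.ones(1) for c in spec.class_state_weight},
            class_emission_tilt=spec.class_emission_tilt,
        )


def test_label_invariants_hold_on_generated_sets():
    fx = generate_corpus(default_grammar(), 60, seed=5)
    for r in fx.records:
        assert len(fx.ss8[r.id]) == len(r)
        assert fx.ss3[r.id] == map_ss8_string(fx.ss8[r.id])
        assert set(fx.disorder[r.id]) <= {"0", "1"}


def test_empirical_emissions_match_spec_within_three_se():
    """Per-state residue frequencies agree with the generating distribution."""
    spec = default_grammar()
    fx = generate_corpus(spec, 2000, seed=7)
    counts = np.zeros((spec.n_states, 20))
    for r in fx.records:
        path = fx.hidden_paths[r.id]
        tilt = spec.class_emission_tilt[fx.localization[r.id]]
        # remove the per-class tilt so states are comparable across classes
        if not np.allclose(tilt, 1.0):
            continue
        for s, ch in zip(path, r.sequence):
            counts[s, STANDARD_AA.index(ch)] += 1
    for s in range(spec.n_states):
        n = counts[s].sum()
        if n < 500:
            continue
        p = spec.states[s].emission
        se = np.sqrt(p * (1 - p) / n)
        assert (np.abs(counts[s] / n - p) <= 3 * se + 1e-12).mean() > 0.9


def test_membrane_label_agrees_with_independent_run_scan():
    spec = default_grammar()
    fx = generate_corpus(spec, 500, seed=9)
    mem_state = next(
        i for i, s in enumerate(spec.states) if s.membrane
    )
    for r in fx.records:
        if fx.membrane[r.id] == "unknown":
            continue
        path = fx.hidden_paths[r.id]
        best = run = 0
        for s in path:  # independent longest-run scan
            run = run + 1 if s == mem_state else 0
            best = max(best, run)
        expected = "membrane" if best >= spec.membrane_run_threshold else "soluble"
        assert fx.membrane[r.id] == expected


def test_assign_protein_labels_is_stored_provenance():
    fx = generate_corpus(default_grammar(), 10, seed=2)
    rec = fx.records[3]
    assert assign_protein_labels(fx, rec) == (
        fx.localization[rec.id], fx.membrane[rec.id]
    )
    foreign = generate_corpus(default_grammar(), 1, seed=99, id_prefix="other")
    with pytest.raises(KeyError):
        assign_protein_labels(fx, foreign.records[0])


def test_soluble_when_no_membrane_residues():
    spec = default_grammar(unknown_membrane_fraction=0.0)
    fx = generate_corpus(spec, 200, seed=13)
    mem_state = next(i for i, s in enumerate(spec.states) if s.membrane)
    for r in fx.records:
        if (fx.hidden_paths[r.id] == mem_state).sum() == 0:
            assert fx.membrane[r.id] == "soluble"


def test_grammar_is_learnable_by_bigram_entropy():
    """Conditional entropy of the corpus is below that of its shuffle."""
    fx = generate_corpus(default_grammar(), 150, seed=17)
    text = "".join(r.sequence for r in fx.records)
    rng = np.random.default_rng(0)
    shuffled = "".join(rng.permutation(list(text)))

    def bigram_conditional_entropy(s):
        from collections import Counter

        uni = Counter(s)
        bi = Counter(zip(s[:-1], s[1:]))
        n = len(s) - 1
        h = 0.0
        for (a, b), c in bi.items():
            pab = c / n
            h -= pab * np.log(pab / (uni[a] / len(s)))
        return h

    assert bigram_conditional_entropy(text) < bigram_conditional_entropy(shuffled) - 0.05


class TestProfileFixtures:
    def test_blocks_are_well_formed(self, grammar_spec):
        fx = generate_corpus(grammar_spec, 3, seed=4)
        rec = fx.records[0]
        prof = generate_profile_fixture(rec, seed=1)
        assert prof.shape == (len(rec), 50)
        # substitution-profile block is row-stochastic
        assert np.allclose(prof[:, 20:40].sum(axis=1), 1.0, atol=1e-6)
        assert ((prof[:, 40:47] >= 0) & (prof[:, 40:47] <= 1)).all()
        assert (prof[:, 47:50] >= 0).all()

    def test_onehot_block_matches_sequence(self, grammar_spec):
        fx = generate_corpus(grammar_spec, 2, seed=4)
        rec = fx.records[1]
        prof = generate_profile_fixture(rec, seed=1)
        for i, ch in enumerate(rec.sequence):
            j = STANDARD_AA.find(ch)
            expected = np.zeros(20)
            if j >= 0:
                expected[j] = 1.0
            assert np.array_equal(prof[i, :20], expected)

    def test_profile_peak_tracks_true_residue(self, grammar_spec):
        fx = generate_corpus(
            default_grammar(length_log_mean=np.log(200.0)), 60, seed=6
        )
        hits = total = 0
        for rec in fx.records:
            prof = generate_profile_fixture(rec, seed=2)
            for i, ch in enumerate(rec.sequence):
                j = STANDARD_AA.find(ch)
                if j < 0:
                    continue
                hits += int(prof[i, 20:40].argmax() == j)
                total += 1
        assert total > 10_000
        assert hits / total > 0.9

    def test_deterministic_given_seed(self, grammar_spec):
        fx = generate_corpus(grammar_spec, 1, seed=4)
        a = generate_profile_fixture(fx.records[0], seed=9)
        b = generate_profile_fixture(fx.records[0], seed=9)
        assert np.array_equal(a, b)


def test_label_files_roundtrip(tmp_path):
    fx = generate_corpus(default_grammar(), 12, seed=8)
    rp = tmp_path / "res.txt"
    pp = tmp_path / "prot.tsv"
    write_residue_labels(rp, fx)
    write_protein_labels(pp, fx)
    res = read_residue_labels(rp)
    prot = read_protein_labels(pp)
    for r in fx.records:
        assert res[r.id]["ss8"] == fx.ss8[r.id]
        assert res[r.id]["disorder"] == fx.disorder[r.id]
        assert prot[r.id] == (fx.localization[r.id], fx.membrane[r.id])
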