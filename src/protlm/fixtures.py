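"""Synthetic protein corpora with known latent structure.

Sequences are emitted by a hidden-state Markov grammar whose states mimic
local structural environments (helices, strands, turns, coil, intrinsically
disordered segments and hydrophobic membrane segments). Each state carries a
DSSP letter and an emission distribution over the 20 standard amino acids,
so every generated protein comes with consistent per-residue labels (8- and
3-state secondary structure, disorder mask) for free: the labels ARE the
generating hidden path.

Per-protein labels are equally grounded in the generator: each protein is
drawn from one of ten localization-class variants of the grammar (classes
re-weight which states are visited and tilt the emission distributions, the
way compartment proteomes differ in composition), and a protein is labeled
membrane-bound exactly when its hidden path contains a sufficiently long
run of the membrane state.

This emulates the statistical structure the downstream analyses assume --
local context predicts structural class, and global composition predicts
compartment -- while remaining fully controlled and reproducible. It does
not emulate real evolutionary families, domain architectures or long-range
contacts.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

from .corpus import STANDARD_AA, ProteinRecord
from .metrics import map_ss8_string

__all__ = [
    "GrammarState",
    "GrammarSpec",
    "FixtureSet",
    "default_grammar",
    "generate_corpus",
    "generate_uniform_corpus",
    "assign_protein_labels",
    "generate_profile_fixture",
    "write_residue_labels",
    "read_residue_labels",
    "write_protein_labels",
    "read_protein_labels",
    "write_profile_store",
    "LOCALIZATION_CLASSES",
    "MEMBRANE_STATUSES",
]

LOCALIZATION_CLASSES = (
    "Nucleus",
    "Cytoplasm",
    "Extracellular",
    "Mitochondrion",
    "Cell membrane",
    "Endoplasmic reticulum",
    "Plastid",
    "Golgi apparatus",
    "Lysosome/Vacuole",
    "Peroxisome",
)
MEMBRANE_STATUSES = ("membrane", "soluble", "unknown")


@dataclass(frozen=True)
class GrammarState:
    """One hidden state: its DSSP letter, emissions and flags."""

    name: str
    ss8: str
    emission: np.ndarray  # (20,) over STANDARD_AA
    disordered: bool = False
    membrane: bool = False


def _peaked(preferred: str, weight: float = 8.0, base: float = 0.4) -> np.ndarray:
    """Emission distribution concentrated on ``preferred`` residues."""
    p = np.full(20, base)
    for ch in preferred:
        p[STANDARD_AA.index(ch)] += weight
    return p / p.sum()


@dataclass(frozen=True)
class GrammarSpec:
    """Hidden-state grammar: states, transitions, class tilts and lengths.

    ``class_state_weight`` re-weights the columns of the transition matrix
    per localization class; ``class_emission_tilt`` multiplies emissions.
    Lengths are log-normal (``length_log_mean``/``length_log_sigma``) clipped
    to [length_min, length_max].
    """

    states: tuple[GrammarState, ...]
    transitions: np.ndarray  # (S, S)
    class_state_weight: dict[str, np.ndarray]
    class_emission_tilt: dict[str, np.ndarray]
    length_log_mean: float = np.log(90.0)
    length_log_sigma: float = 0.35
    length_min: int = 30
    length_max: int = 2000
    membrane_run_threshold: int = 15
    unknown_membrane_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        t = np.asarray(self.transitions, dtype=float)
        if t.shape != (len(self.states), len(self.states)):
            raise ValueError("transition matrix shape must match state count")
        if (t < 0).any() or not np.allclose(t.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition rows must be non-negative and sum to 1")
        for s in self.states:
            e = np.asarray(s.emission, dtype=float)
            if e.shape != (20,) or (e < 0).any():
                raise ValueError(f"state {s.name}: emission must be a length-20 simplex")
            if e.sum() == 0:
                raise ValueError(f"state {s.name}: degenerate (all-zero) emissions")
            if not np.isclose(e.sum(), 1.0, atol=1e-9):
                raise ValueError(f"state {s.name}: emissions must sum to 1")
        # emission rows must be pairwise distinguishable
        for i, a in enumerate(self.states):
            for b in self.states[i + 1:]:
                ea, eb = a.emission + 1e-12, b.emission + 1e-12
                if float(np.sum(ea * np.log(ea / eb))) <= 0:
                    raise ValueError(
                        f"states {a.name}/{b.name}: emissions are not distinguishable"
                    )

    @property
    def n_states(self) -> int:
        return len(self.states)

    def class_transitions(self, loc_class: str) -> np.ndarray:
        """Transition matrix for one localization class (column re-weighted)."""
        w = self.class_state_weight[loc_class]
        t = self.transitions * w[None, :]
        return t / t.sum(axis=1, keepdims=True)

    def class_emissions(self, loc_class: str) -> np.ndarray:
        """(S, 20) emission matrix for one localization class."""
        tilt = self.class_emission_tilt[loc_class]
        e = np.stack([s.emission for s in self.states]) * tilt[None, :]
        return e / e.sum(axis=1, keepdims=True)


def default_grammar(seed: int = 0, **overrides) -> GrammarSpec:
    """The default ten-state grammar with the ten localization variants."""
    states = (
        GrammarState("helix", "H", _peaked("ALEMQKR")),
        GrammarState("helix310", "G", _peaked("AGNDSK", weight=5.0)),
        GrammarState("pihelix", "I", _peaked("ALMEQW", weight=5.0)),
        GrammarState("strand", "E", _peaked("VIFYWT")),
        GrammarState("bridge", "B", _peaked("VITYCS", weight=5.0)),
        GrammarState("turn", "T", _peaked("GPNDS")),
        GrammarState("bend", "S", _peaked("GSDNPA", weight=5.0)),
        GrammarState("coil", "C", _peaked("GPSTNDEQ", weight=3.0)),
        GrammarState("disordered", "C", _peaked("PESQKGA", weight=6.0), disordered=True),
        GrammarState("membrane", "H", _peaked("LIVFAWM", weight=10.0), membrane=True),
    )
    names = [s.name for s in states]
    n = len(states)
    # self-transition probabilities control segment lengths
    self_p = {
        "helix": 0.93, "helix310": 0.60, "pihelix": 0.60, "strand": 0.90,
        "bridge": 0.50, "turn": 0.55, "bend": 0.55, "coil": 0.82,
        "disordered": 0.93, "membrane": 0.94,
    }
    # relative weights for leaving to each other state
    leave_w = {
        "helix": dict(turn=3, coil=3, bend=1.5, helix310=1, strand=0.8),
        "helix310": dict(helix=3, coil=2, turn=2, bend=1),
        "pihelix": dict(helix=3, coil=2, turn=1),
        "strand": dict(turn=3, coil=3, bend=1.5, bridge=1, helix=0.8),
        "bridge": dict(coil=3, turn=2, strand=1),
        "turn": dict(coil=3, helix=2, strand=2, bend=1),
        "bend": dict(coil=3, strand=2, helix=1.5),
        "coil": dict(helix=2.5, strand=2.5, turn=1.5, bend=1, disordered=0.8,
                     membrane=0.5, bridge=0.3, helix310=0.3, pihelix=0.05),
        "disordered": dict(coil=3, turn=1),
        "membrane": dict(coil=3, turn=1),
    }
    t = np.zeros((n, n))
    for i, s in enumerate(states):
        t[i, i] = self_p[s.name]
        w = leave_w[s.name]
        total = sum(w.values())
        for tgt, wt in w.items():
            t[i, names.index(tgt)] += (1 - self_p[s.name]) * wt / total

    def tilt(**kw) -> np.ndarray:
        v = np.ones(20)
        for ch, x in kw.items():
            v[STANDARD_AA.index(ch)] = x
        return v

    def weights(**kw) -> np.ndarray:
        v = np.ones(n)
        v[names.index("membrane")] = 0.02  # most compartments: no TM segments
        for nm, x in kw.items():
            v[names.index(nm)] = x
        return v

    class_state_weight = {
        "Nucleus": weights(disordered=2.0, coil=1.3),
        "Cytoplasm": weights(),
        "Extracellular": weights(strand=1.8, bridge=1.4, disordered=0.4),
        "Mitochondrion": weights(helix=1.6, disordered=0.5),
        "Cell membrane": weights(membrane=8.0, disordered=0.3),
        "Endoplasmic reticulum": weights(membrane=3.0, helix=1.2),
        "Plastid": weights(helix=1.3, bend=1.4),
        "Golgi apparatus": weights(membrane=2.0, turn=1.5),
        "Lysosome/Vacuole": weights(strand=1.3, turn=1.5, bridge=1.2),
        "Peroxisome": weights(coil=1.5, helix310=1.6),
    }
    class_emission_tilt = {
        "Nucleus": tilt(K=1.5, R=1.5, S=1.2),
        "Cytoplasm": tilt(),
        "Extracellular": tilt(C=1.8, N=1.3),
        "Mitochondrion": tilt(R=1.4, L=1.2),
        "Cell membrane": tilt(),
        "Endoplasmic reticulum": tilt(D=1.3, E=1.2),
        "Plastid": tilt(A=1.4, S=1.3),
        "Golgi apparatus": tilt(P=1.4, T=1.3),
        "Lysosome/Vacuole": tilt(N=1.5, S=1.3),
        "Peroxisome": tilt(H=1.6, W=1.4),
    }
    return GrammarSpec(
        states=states,
        transitions=t,
        class_state_weight=class_state_weight,
        class_emission_tilt=class_emission_tilt,
        seed=seed,
        **overrides,
    )


@dataclass
class FixtureSet:
    """Generated records plus all residue- and protein-level labels."""

    records: list[ProteinRecord]
    ss8: dict[str, str]
    ss3: dict[str, str]
    disorder: dict[str, str]  # '0'/'1' strings
    localization: dict[str, str]
    membrane: dict[str, str]
    hidden_paths: dict[str, np.ndarray]
    spec: GrammarSpec
    seed: int

    def __post_init__(self) -> None:
        for rec in self.records:
            L = len(rec)
            for table in (self.ss8, self.ss3, self.disorder):
                if len(table[rec.id]) != L:
                    raise ValueError(f"label length mismatch for {rec.id}")
            if self.ss3[rec.id] != map_ss8_string(self.ss8[rec.id]):
                raise ValueError(f"SS3 inconsistent with SS8 for {rec.id}")
            if self.localization[rec.id] not in LOCALIZATION_CLASSES:
                raise ValueError(f"unknown localization class for {rec.id}")
            if self.membrane[rec.id] not in MEMBRANE_STATUSES:
                raise ValueError(f"unknown membrane status for {rec.id}")


def _sample_length(spec: GrammarSpec, rng: np.random.Generator) -> int:
    L = int(round(rng.lognormal(spec.length_log_mean, spec.length_log_sigma)))
    return int(np.clip(L, spec.length_min, spec.length_max))


def _longest_membrane_run(path: np.ndarray, spec: GrammarSpec) -> int:
    is_mem = np.array([spec.states[s].membrane for s in path])
    best = run = 0
    for flag in is_mem:
        run = run + 1 if flag else 0
        best = max(best, run)
    return best


def generate_corpus(
    spec: GrammarSpec, n: int, seed: int | None = None, id_prefix: str = "syn"
) -> FixtureSet:
    """Generate ``n`` proteins with consistent labels; deterministic per seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if seed is None:
        seed = spec.seed
    rng = np.random.default_rng(seed)
    ss8_letters = np.array([s.ss8 for s in spec.states])
    aa = np.array(list(STANDARD_AA))

    records, ss8, ss3, dis, loc, mem, paths = [], {}, {}, {}, {}, {}, {}
    classes = list(LOCALIZATION_CLASSES)
    for i in range(n):
        cls = classes[int(rng.integers(len(classes)))]
        cum_t = np.cumsum(spec.class_transitions(cls), axis=1)
        cum_e = np.cumsum(spec.class_emissions(cls), axis=1)
        L = _sample_length(spec, rng)
        # start from the class-weighted stationary-ish initial distribution
        init = spec.class_state_weight[cls].astype(float)
        u = rng.random(L)
        v = rng.random(L)
        path = np.empty(L, dtype=np.int64)
        path[0] = int(np.searchsorted(np.cumsum(init / init.sum()), u[0], side="right"))
        for t in range(1, L):
            path[t] = np.searchsorted(cum_t[path[t - 1]], u[t], side="right")
        seq_idx = (cum_e[path] < v[:, None]).sum(axis=1)
        rid = f"{id_prefix}{i:05d}"
        rec = ProteinRecord(rid, "".join(aa[seq_idx]))
        records.append(rec)
        ss8[rid] = "".join(ss8_letters[path])
        ss3[rid] = map_ss8_string(ss8[rid])
        dis[rid] = "".join(
            "1" if spec.states[s].disordered else "0" for s in path
        )
        loc[rid] = cls
        if rng.random() < spec.unknown_membrane_fraction:
            mem[rid] = "unknown"
        else:
            mem[rid] = (
                "membrane"
                if _longest_membrane_run(path, spec) >= spec.membrane_run_threshold
                else "soluble"
            )
        paths[rid] = path
    return FixtureSet(records, ss8, ss3, dis, loc, mem, paths, spec, seed)


def generate_uniform_corpus(
    n: int, seed: int, length_min: int = 50, length_max: int = 150,
    id_prefix: str = "unif",
) -> list[ProteinRecord]:
    """i.i.d. uniform sequences over the 20 standard residues.

    The per-residue entropy of this corpus is exactly log(20), an analytic
    floor for any language model's perplexity on it.
    """
    rng = np.random.default_rng(seed)
    aa = np.array(list(STANDARD_AA))
    out = []
    for i in range(n):
        L = int(rng.integers(length_min, length_max + 1))
        out.append(ProteinRecord(f"{id_prefix}{i:05d}",
                                 "".join(aa[rng.integers(0, 20, size=L)])))
    return out


def assign_protein_labels(
    fixtures: FixtureSet, record: ProteinRecord
) -> tuple[str, str]:
    """Localization class and membrane status of a generated record.

    The class is stored provenance (which grammar variant emitted the
    protein); the membrane status is re-derived from the hidden path via the
    longest-run rule. Raises KeyError for records not from this generator.
    """
    if record.id not in fixtures.hidden_paths:
        raise KeyError(f"record {record.id!r} was not produced by this fixture set")
    return fixtures.localization[record.id], fixtures.membrane[record.id]


# -- profile fixtures ------------------------------------------------------

PROFILE_CHANNELS = 50  # [onehot 20 | substitution profile 20 | transitions 7 | diversity 3]


def generate_profile_fixture(record: ProteinRecord, seed: int = 0) -> np.ndarray:
    """Per-residue 50-feature profile fixture, deterministic per (record, seed).

    Layout mirrors alignment-server output: a one-hot encoding (20), a
    row-stochastic substitution profile peaked at the true residue (20),
    seven alignment-HMM transition-like features in [0, 1] and three
    non-negative diversity features.
    """
    sub = np.random.default_rng((seed, zlib.crc32(record.id.encode())))
    L = len(record)
    out = np.zeros((L, PROFILE_CHANNELS), dtype=np.float32)
    for i, ch in enumerate(record.sequence):
        if ch in STANDARD_AA:
            j = STANDARD_AA.index(ch)
            out[i, j] = 1.0
            prof = sub.gamma(0.3, size=20)
            prof[j] += 8.0
        else:
            prof = sub.gamma(0.3, size=20) + 0.4
        out[i, 20:40] = prof / prof.sum()
        out[i, 40:47] = sub.uniform(0.0, 1.0, size=7)
        out[i, 47:50] = sub.gamma(2.0, 1.0, size=3)
    return out


def write_profile_store(path, fixtures_or_records, seed: int = 0) -> None:
    """Write profile fixtures to an HDF5 store keyed by record id."""
    import h5py

    records = getattr(fixtures_or_records, "records", fixtures_or_records)
    with h5py.File(path, "w") as fh:
        fh.attrs["channels"] = PROFILE_CHANNELS
        for rec in records:
            fh.create_dataset(rec.id, data=generate_profile_fixture(rec, seed))


# -- label file formats ----------------------------------------------------

def write_residue_labels(path, fixtures: FixtureSet) -> None:
    """Write per-residue labels: '>id' then sequence / SS8 / disorder lines."""
    with open(path, "w", encoding="utf-8") as fh:
        for rec in fixtures.records:
            fh.write(f">{rec.id}\n{rec.sequence}\n"
                     f"{fixtures.ss8[rec.id]}\n{fixtures.disorder[rec.id]}\n")


def read_residue_labels(path) -> dict[str, dict[str, str]]:
    """Read the 3-line residue label format -> {id: {sequence, ss8, ss3, disorder}}."""
    out: dict[str, dict[str, str]] = {}
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if len(lines) % 4 != 0:
        raise ValueError("residue label file must be groups of 4 lines (>id/seq/ss8/dis)")
    for i in range(0, len(lines), 4):
        head, seq, ss8, dis = lines[i : i + 4]
        if not head.startswith(">"):
            raise ValueError(f"expected '>' header at line {i + 1}")
        rid = head[1:].split()[0]
        if not (len(seq) == len(ss8) == len(dis)):
            raise ValueError(f"record {rid}: label length mismatch")
        out[rid] = {"sequence": seq, "ss8": ss8,
                    "ss3": map_ss8_string(ss8), "disorder": dis}
    return out


def write_protein_labels(path, fixtures: FixtureSet) -> None:
    """Write per-protein labels as TSV: id, localization, membrane."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("id\tlocalization\tmembrane\n")
        for rec in fixtures.records:
            fh.write(f"{rec.id}\t{fixtures.localization[rec.id]}\t"
                     f"{fixtures.membrane[rec.id]}\n")


def read_protein_labels(path) -> dict[str, tuple[str, str]]:
    """Read the per-protein label TSV -> {id: (localization, membrane)}."""
    out: dict[str, tuple[str, str]] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["id", "localization", "membrane"]:
            raise ValueError("unexpected protein label header")
        for ln in fh:
            if not ln.strip():
                continue
            rid, loc, mem = ln.rstrip("\n").split("\t")[:3]
            if loc not in LOCALIZATION_CLASSES or mem not in MEMBRANE_STATUSES:
                raise ValueError(f"record {rid}: label outside closed vocabulary")
            out[rid] = (loc, mem)
    return out
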