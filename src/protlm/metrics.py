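"""Label conventions and the evaluation suite.

Secondary structure uses the eight DSSP states H, G, I (helices), E, B
(strands/bridges), T, S (turns/bends) and C (coil, the DSSP blank), mapped
to three states by the common convention [G,H,I] -> H, [B,E] -> E, all
others -> O. Intrinsic disorder is operationalized as residues without
atomic coordinates in the deposited structure.

Per-residue accuracies (Q3, Q8) are computed per protein and macro-averaged
over proteins; per-protein accuracies (Q2 membrane/soluble, Q10
localization) treat each protein as one item. Binary tasks additionally
report the Matthews correlation coefficient and the false-positive rate;
the K-class generalization of the MCC (the Gorodkin RK measure) is computed
from the confusion matrix. Standard errors come either from the per-protein
score distribution or from bootstrap resampling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "SS8_STATES",
    "SS3_STATES",
    "map_dssp8_to_3",
    "map_ss8_string",
    "disorder_from_coordinates",
    "ConfusionMatrix",
    "confusion_matrix",
    "QResult",
    "q_accuracy",
    "BinaryScore",
    "binary_mcc_and_fpr",
    "gorodkin_mcc",
    "mcc_macro_per_protein",
    "bootstrap_se",
    "se_over_proteins",
    "MetricsReport",
]

SS8_STATES = "HGIEBTSC"
SS3_STATES = "HEO"
_UNKNOWN_SS8 = "-"

_DSSP8_TO_3 = {
    "G": "H", "H": "H", "I": "H",
    "B": "E", "E": "E",
    "T": "O", "S": "O", "C": "O",
    _UNKNOWN_SS8: "O",
}


def map_dssp8_to_3(letter: str) -> str:
    """Map one eight-state DSSP letter (or '-' for unknown) to H/E/O."""
    try:
        return _DSSP8_TO_3[letter]
    except KeyError:
        raise ValueError(f"not an 8-state DSSP letter: {letter!r}") from None


def map_ss8_string(ss8: str) -> str:
    """Vectorized :func:`map_dssp8_to_3` over a label string."""
    return "".join(map_dssp8_to_3(ch) for ch in ss8)


def disorder_from_coordinates(coords_present: Sequence[bool]) -> np.ndarray:
    """Binary disorder labels: 1 where atomic coordinates are absent."""
    mask = np.asarray(coords_present, dtype=bool)
    if mask.ndim != 1:
        raise ValueError("coordinate mask must be one-dimensional")
    return (~mask).astype(np.int8)


@dataclass(frozen=True)
class ConfusionMatrix:
    """K x K counts; rows are true classes, columns predicted classes."""

    counts: np.ndarray
    classes: tuple[str, ...]

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] != c.shape[1] or c.shape[0] != len(self.classes):
            raise ValueError("counts must be K x K matching the class list")
        if (c < 0).any():
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.counts, index=list(self.classes),
                     columns=list(self.classes)).to_csv(path)


def confusion_matrix(
    true: Sequence, pred: Sequence, classes: Sequence[str]
) -> ConfusionMatrix:
    """Count a confusion matrix over a fixed class list."""
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for t, p in zip(true, pred, strict=True):
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts, tuple(classes))


@dataclass(frozen=True)
class QResult:
    """Macro-averaged accuracy in percent plus the per-protein distribution."""

    value: float
    per_protein: np.ndarray
    n_excluded: int = 0

    @property
    def se(self) -> float:
        return se_over_proteins(self.per_protein)


def q_accuracy(
    pred: Sequence[Sequence],
    true: Sequence[Sequence],
    valid: Sequence[np.ndarray] | None = None,
    aggregation: str = "macro",
) -> QResult:
    """Per-residue Q accuracy (percentage of correctly labeled residues).

    ``pred`` and ``true`` are per-protein label sequences (strings or arrays).
    ``valid`` optionally masks residues that should be scored. With
    ``aggregation="macro"`` (the reporting convention used throughout) the
    per-protein accuracies are averaged unweighted; ``"micro"`` pools all
    residues. Proteins with no valid residue are excluded and counted.
    """
    if len(pred) != len(true):
        raise ValueError("pred and true must have the same number of proteins")
    scores = []
    n_excluded = 0
    n_correct = 0
    n_valid = 0
    for i, (p, t) in enumerate(zip(pred, true)):
        p = np.asarray(list(p))
        t = np.asarray(list(t))
        if p.shape != t.shape:
            raise ValueError(f"protein {i}: prediction/label length mismatch")
        m = np.ones(len(p), dtype=bool) if valid is None else np.asarray(valid[i], bool)
        if m.sum() == 0:
            n_excluded += 1
            continue
        correct = int((p[m] == t[m]).sum())
        n_correct += correct
        n_valid += int(m.sum())
        scores.append(100.0 * correct / m.sum())
    if not scores:
        raise ValueError("no protein with valid residues to score")
    per_protein = np.asarray(scores)
    if aggregation == "macro":
        value = float(per_protein.mean())
    elif aggregation == "micro":
        value = 100.0 * n_correct / n_valid
    else:
        raise ValueError(f"unknown aggregation {aggregation!r}")
    return QResult(value, per_protein, n_excluded)


@dataclass(frozen=True)
class BinaryScore:
    mcc: float
    fpr: float
    degenerate: bool = False


def binary_mcc_and_fpr(pred: Sequence[int], true: Sequence[int]) -> BinaryScore:
    """Matthews correlation and false-positive rate for binary labels.

    MCC is defined as 0 (and flagged degenerate) when any marginal of the
    2x2 table is zero; FPR is NaN when there are no true negatives/positives
    to mispredict.
    """
    p = np.asarray(pred, dtype=int)
    t = np.asarray(true, dtype=int)
    if p.size == 0:
        raise ValueError("empty input")
    tp = int(((p == 1) & (t == 1)).sum())
    tn = int(((p == 0) & (t == 0)).sum())
    fp = int(((p == 1) & (t == 0)).sum())
    fn = int(((p == 0) & (t == 1)).sum())
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        mcc, degenerate = 0.0, True
    else:
        mcc = (tp * tn - fp * fn) / np.sqrt(float(denom))
        degenerate = False
    fpr = fp / (fp + tn) if (fp + tn) > 0 else float("nan")
    return BinaryScore(float(mcc), float(fpr), degenerate)


def gorodkin_mcc(confusion: ConfusionMatrix) -> float:
    """K-category Matthews correlation (the Gorodkin RK measure).

    Computed from the confusion matrix in covariance form:

        RK = (N * trace(C) - t . p) / sqrt((N^2 - p . p) (N^2 - t . t))

    with t, p the true/predicted marginals. Returns 0.0 when either variance
    term vanishes (all items in one true or one predicted class).
    """
    c = confusion.counts.astype(np.float64)
    n = c.sum()
    if n == 0:
        raise ValueError("empty confusion matrix")
    t = c.sum(axis=1)
    p = c.sum(axis=0)
    cov = n * np.trace(c) - t @ p
    var_t = n * n - t @ t
    var_p = n * n - p @ p
    if var_t <= 0 or var_p <= 0:
        return 0.0
    return float(cov / np.sqrt(var_t * var_p))


def mcc_macro_per_protein(
    pred: Sequence[Sequence[int]], true: Sequence[Sequence[int]],
    valid: Sequence[np.ndarray] | None = None,
) -> tuple[float, np.ndarray, int]:
    """Per-protein binary MCC, macro-averaged.

    Proteins whose true labels contain a single class (MCC undefined) are
    excluded from the average; the count of exclusions is returned.
    """
    scores = []
    n_excluded = 0
    for i, (p, t) in enumerate(zip(pred, true, strict=True)):
        p = np.asarray(p, dtype=int)
        t = np.asarray(t, dtype=int)
        if valid is not None:
            m = np.asarray(valid[i], bool)
            p, t = p[m], t[m]
        if len(np.unique(t)) < 2:
            n_excluded += 1
            continue
        scores.append(binary_mcc_and_fpr(p, t).mcc)
    if not scores:
        raise ValueError("no protein with both classes present")
    arr = np.asarray(scores)
    return float(arr.mean()), arr, n_excluded


def bootstrap_se(
    items: Sequence,
    statistic: Callable[[np.ndarray], float] | None = None,
    n_boot: int = 1000,
    seed: int = 0,
) -> float:
    """Bootstrap standard error of a statistic over per-item values.

    ``n_boot`` resamples of the same size are drawn with replacement; the SE
    is the standard deviation of the statistic across resamples.
    """
    arr = np.asarray(items)
    if arr.shape[0] < 2:
        raise ValueError("need at least two items to bootstrap")
    if statistic is None:
        statistic = np.mean
    rng = np.random.default_rng(seed)
    n = arr.shape[0]
    values = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        values[b] = statistic(arr[idx])
    return float(values.std(ddof=1))


def se_over_proteins(scores: Sequence[float]) -> float:
    """Standard error of the mean over the per-protein score distribution."""
    arr = np.asarray(scores, dtype=float)
    if arr.size < 2:
        return float("nan")
    return float(arr.std(ddof=1) / np.sqrt(arr.size))


@dataclass
class MetricsReport:
    """A named collection of metric values, standard errors and matrices."""

    values: dict[str, float] = field(default_factory=dict)
    standard_errors: dict[str, float] = field(default_factory=dict)
    confusions: dict[str, ConfusionMatrix] = field(default_factory=dict)
    notes: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "values": {k: float(v) for k, v in self.values.items()},
            "standard_errors": {k: float(v) for k, v in self.standard_errors.items()},
            "confusions": {
                k: {"classes": list(cm.classes), "counts": cm.counts.tolist()}
                for k, cm in self.confusions.items()
            },
            "notes": dict(self.notes),
        }

    def to_json(self, path=None, indent: int = 2) -> str:
        text = json.dumps(self.to_dict(), indent=indent)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text + "\n")
        return text

    def to_text(self) -> str:
        lines = []
        for k in sorted(self.values):
            se = self.standard_errors.get(k)
            tail = f" +/- {se:.1f}" if se is not None and np.isfinite(se) else ""
            lines.append(f"{k:>24s}: {self.values[k]:8.1f}{tail}")
        return "\n".join(lines)
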