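"""Evaluation of ranked protein lists.

ROC/PR areas over a labeled ranking, F1 for the top-k call (positive and
negative class), precision restricted to degenerate proteins (those sharing a
peptide with another candidate), and target-decoy evaluation with
tryptic-shuffle decoys: when no ground truth exists, decoy proteins built by
shuffling residues within each tryptic peptide serve as known negatives.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from sklearn.metrics import average_precision_score, f1_score, roc_auc_score

from .io_encoding import DataError, ProteinRecord, SparseEncoding
from .scoring import ProteinScore
from .synthetic import tryptic_digest

DECOY_PREFIX = "DECOY_"


@dataclass(frozen=True)
class LabeledRanking:
    """Ordered (id, score, label) triples, descending by score."""

    ids: tuple[str, ...]
    scores: tuple[float, ...]
    labels: tuple[bool, ...]  # True = positive

    @classmethod
    def from_scores(
        cls, ranked: list[ProteinScore], positive_ids: set[str]
    ) -> "LabeledRanking":
        ordered = sorted(ranked, key=lambda s: (-s.score, s.protein_id))
        return cls(
            tuple(s.protein_id for s in ordered),
            tuple(s.score for s in ordered),
            tuple(s.protein_id in positive_ids for s in ordered),
        )

    def __len__(self) -> int:
        return len(self.ids)


@dataclass
class EvaluationReport:
    auc_roc: float
    auc_pr: float
    f1_positive: float | None = None
    f1_negative: float | None = None
    degenerate_precision: float | None = None
    k: int | None = None

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)
            fh.write("\n")

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("metric\tvalue\n")
            for key, val in asdict(self).items():
                fh.write(f"{key}\t{'NA' if val is None else val}\n")


def roc_auc(ranking: LabeledRanking) -> float:
    """Area under the ROC curve (midrank tie convention)."""
    labels = np.asarray(ranking.labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("ROC AUC needs at least one positive and one negative")
    return float(roc_auc_score(labels, np.asarray(ranking.scores)))


def pr_auc(ranking: LabeledRanking) -> float:
    """Area under the precision-recall curve (step-wise interpolation)."""
    labels = np.asarray(ranking.labels, dtype=bool)
    if not labels.any():
        raise ValueError("PR AUC needs at least one positive")
    return float(average_precision_score(labels, np.asarray(ranking.scores)))


def f1_at_k(ranking: LabeledRanking, k: int) -> tuple[float, float]:
    """F1 of the positive and of the negative class when the top-k ranked
    proteins are called present and the rest absent."""
    n = len(ranking)
    if not 1 <= k <= n:
        raise ValueError(f"k = {k} out of range [1, {n}]")
    labels = np.asarray(ranking.labels, dtype=bool)
    predicted = np.zeros(n, dtype=bool)
    predicted[:k] = True
    f1_pos = float(f1_score(labels, predicted, pos_label=True, zero_division=0.0))
    f1_neg = float(f1_score(labels, predicted, pos_label=False, zero_division=0.0))
    return f1_pos, f1_neg


def degenerate_protein_ids(encoding: SparseEncoding) -> set[str]:
    """Candidates possessing at least one peptide matched by >= 2 candidates."""
    out: set[str] = set()
    for i in range(encoding.n_peptides):
        matched = encoding.matching_proteins(i)
        if len(matched) >= 2:
            out.update(encoding.layout.proteins[j].id for j in matched)
    return out


def degenerate_precision(
    ranking: LabeledRanking, encoding: SparseEncoding, k: int
) -> float | None:
    """Precision of the top-k call among degenerate proteins only.

    Returns None when no degenerate protein is predicted present (the metric
    is undefined).
    """
    if not 1 <= k <= len(ranking):
        raise ValueError(f"k = {k} out of range [1, {len(ranking)}]")
    degenerate = degenerate_protein_ids(encoding)
    called = [
        (pid, lab)
        for pid, lab in zip(ranking.ids[:k], ranking.labels[:k])
        if pid in degenerate
    ]
    if not called:
        return None
    return sum(lab for _, lab in called) / len(called)


def make_decoys(
    db: list[ProteinRecord], seed: int, mode: str = "residue"
) -> list[ProteinRecord]:
    """One decoy per target protein by shuffling its tryptic peptides.

    ``mode='residue'``: within each tryptic peptide, residues are permuted
    with every K, R and P held in place (K/R set the cleavage sites and P
    suppresses them, so fixing all three preserves the digestion pattern
    exactly); peptides are reassembled in order.  Decoys keep the target's
    length, amino-acid composition and tryptic peptide lengths.
    ``mode='peptide'`` shuffles the order of whole tryptic peptides instead.
    """
    if not db:
        raise DataError("empty database")
    if mode not in ("residue", "peptide"):
        raise ValueError(f"unknown decoy mode {mode!r}")
    rng = np.random.default_rng([seed, 30])
    decoys = []
    for prot in db:
        peptides = tryptic_digest(prot.sequence)
        if mode == "peptide":
            order = rng.permutation(len(peptides))
            shuffled = [peptides[int(i)] for i in order]
        else:
            shuffled = []
            for pep in peptides:
                chars = list(pep)
                movable = [i for i, aa in enumerate(chars) if aa not in "KRP"]
                perm = rng.permutation(len(movable))
                residues = [chars[i] for i in movable]
                for slot, src in zip(movable, perm):
                    chars[slot] = residues[int(src)]
                shuffled.append("".join(chars))
        decoys.append(ProteinRecord(DECOY_PREFIX + prot.id, "".join(shuffled)))
    return decoys


def decoy_augment(db: list[ProteinRecord], seed: int, mode: str = "residue") -> list[ProteinRecord]:
    """Target database plus its decoys (doubles the database size)."""
    return list(db) + make_decoys(db, seed, mode)


def target_decoy_eval(
    ranked: list[ProteinScore],
    k: int | None = None,
    encoding: SparseEncoding | None = None,
) -> EvaluationReport:
    """Evaluate a scored target+decoy run: targets positive, decoys negative."""
    positive = {s.protein_id for s in ranked if not s.protein_id.startswith(DECOY_PREFIX)}
    if len(positive) == len(ranked):
        raise DataError("no decoy proteins among the scored candidates")
    ranking = LabeledRanking.from_scores(ranked, positive)
    return evaluate(ranking, k=k, encoding=encoding)


def evaluate(
    ranking: LabeledRanking,
    k: int | None = None,
    encoding: SparseEncoding | None = None,
) -> EvaluationReport:
    """Full report for a labeled ranking; k defaults to the positive count."""
    if k is None:
        k = int(np.sum(ranking.labels))
    f1_pos, f1_neg = f1_at_k(ranking, k)
    degen = degenerate_precision(ranking, encoding, k) if encoding is not None else None
    return EvaluationReport(
        auc_roc=roc_auc(ranking),
        auc_pr=pr_auc(ranking),
        f1_positive=f1_pos,
        f1_negative=f1_neg,
        degenerate_precision=degen,
        k=k,
    )
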