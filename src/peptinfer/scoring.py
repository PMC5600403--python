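"""Protein scoring by masked-input differential prediction.

A protein is scored by how much the trained network's peptide-probability
predictions change when that protein's matches are erased from the input.
For protein i and peptide j:

    c_ij = |y_j - yhat_j(without protein i)| / n_ij

where n_ij is the number of input positions reset to zero (the peptide's
matched residues in that protein).  The protein score is the mean of c_ij
over peptides that actually match it (n_ij > 0); proteins are ranked by
descending score.

Because the network is bias-free and its output decomposes additively over
per-protein blocks, masking protein i simply removes its block's additive
contribution.  The shared path caches each peptide's per-block contributions
from a single forward pass and subtracts; the naive path re-runs a full
forward pass per (protein, peptide) pair and serves as the oracle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import cnn
from .cnn import CNNModel
from .io_encoding import SparseEncoding

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PeptideDelta:
    """Normalized prediction change for one (protein, peptide) pair."""

    protein_idx: int
    peptide_idx: int
    c: float
    n: int


@dataclass(frozen=True)
class ProteinScore:
    protein_id: str
    score: float
    n_peptides: int
    rank: int | None = None


def predict_absent(
    model: CNNModel, encoding: SparseEncoding, peptide_idx: int, protein_idx: int
) -> tuple[float, int]:
    """Naive masked prediction: erase protein ``protein_idx``'s matches from
    peptide ``peptide_idx``'s input and run a full forward pass.

    Returns (prediction, n positions reset).  Raises if the pair has no
    match (the pair is to be skipped, not evaluated).
    """
    n_ij = encoding.total_ones(peptide_idx, protein_idx)
    if n_ij == 0:
        raise ValueError(
            f"peptide {peptide_idx} has no match in protein {protein_idx}; "
            "pair must be skipped"
        )
    yhat = 0.0
    for j, feats in cnn.iter_block_features(model, encoding, peptide_idx):
        if j == protein_idx:
            continue  # masked block: all-zero input, exactly zero contribution
        yhat += float(np.dot(model.output_weights[model.block_slice(j)], feats))
    return yhat, n_ij


def _finalize(model, per_protein: dict[int, list[float]]) -> list[ProteinScore]:
    scores = []
    for j, prot in enumerate(model.layout.proteins):
        deltas = per_protein.get(j)
        assert deltas, (
            f"candidate protein {prot.id} has no matching peptide; "
            "candidate selection should have removed it"
        )
        scores.append(ProteinScore(prot.id, float(np.mean(deltas)), len(deltas)))
    return scores


def score_proteins_naive(
    model: CNNModel,
    encoding: SparseEncoding,
    targets=None,
    include_nonmatching: bool = False,
) -> list[ProteinScore]:
    """Score every candidate by re-running a masked forward pass per pair.

    ``include_nonmatching`` switches to averaging c_ij over *all* peptides
    with the convention c_ij = 0 when n_ij = 0 (the masked prediction then
    equals the unmasked one).
    """
    targets = _targets(encoding, targets)
    per_protein: dict[int, list[float]] = {}
    n_nonmatching = encoding.n_peptides if include_nonmatching else 0
    for i in range(encoding.n_peptides):
        for j in encoding.matching_proteins(i):
            yhat, n_ij = predict_absent(model, encoding, i, j)
            c = abs(targets[i] - yhat) / n_ij
            per_protein.setdefault(j, []).append(c)
    if include_nonmatching:
        for j, deltas in per_protein.items():
            deltas.extend([0.0] * (n_nonmatching - len(deltas)))
    return _finalize(model, per_protein)


def score_proteins_shared(
    model: CNNModel,
    encoding: SparseEncoding,
    targets=None,
    include_nonmatching: bool = False,
) -> list[ProteinScore]:
    """Score every candidate from one forward pass per peptide.

    The penultimate representation is computed once per peptide without any
    masking; each protein's masked prediction is the full prediction minus
    that protein's cached additive block contribution.  Exact because the
    final layer is a per-protein-separable linear map over bias-free blocks.
    """
    targets = _targets(encoding, targets)
    per_protein: dict[int, list[float]] = {}
    for i in range(encoding.n_peptides):
        contribs = {
            j: float(np.dot(model.output_weights[model.block_slice(j)], feats))
            for j, feats in cnn.iter_block_features(model, encoding, i)
        }
        yhat_full = sum(contribs.values())
        for j, s_ij in contribs.items():
            n_ij = encoding.total_ones(i, j)
            c = abs(targets[i] - (yhat_full - s_ij)) / n_ij
            per_protein.setdefault(j, []).append(c)
    if include_nonmatching:
        for j, deltas in per_protein.items():
            deltas.extend([0.0] * (encoding.n_peptides - len(deltas)))
    return _finalize(model, per_protein)


def _targets(encoding: SparseEncoding, targets) -> np.ndarray:
    if targets is None:
        targets = [obs.probability for obs in encoding.peptides]
    targets = np.asarray(targets, dtype=float)
    if len(targets) != encoding.n_peptides:
        raise ValueError("targets not aligned with the encoding")
    return targets


def rank_proteins(scores: list[ProteinScore]) -> list[ProteinScore]:
    """Order by descending score, ties broken by ascending protein id;
    assigns 1-based ranks."""
    ordered = sorted(scores, key=lambda s: (-s.score, s.protein_id))
    return [
        ProteinScore(s.protein_id, s.score, s.n_peptides, rank)
        for rank, s in enumerate(ordered, start=1)
    ]


def write_scores(ranked: list[ProteinScore], path) -> None:
    with open(path, "w") as fh:
        fh.write("rank\tprotein\tscore\tn_peptides\n")
        for s in ranked:
            fh.write(f"{s.rank}\t{s.protein_id}\t{s.score:.10g}\t{s.n_peptides}\n")


def read_scores(path) -> list[ProteinScore]:
    df = pd.read_csv(path, sep="\t")
    return [
        ProteinScore(str(r.protein), float(r.score), int(r.n_peptides), int(r.rank))
        for r in df.itertuples()
    ]


def delta_matrix(
    model: CNNModel, encoding: SparseEncoding, targets=None
) -> pd.DataFrame:
    """Per-pair c_ij matrix (proteins x peptides, NaN where no match) for
    heatmap-style diagnostics."""
    targets = _targets(encoding, targets)
    mat = np.full((len(model.layout), encoding.n_peptides), np.nan)
    for i in range(encoding.n_peptides):
        contribs = {
            j: float(np.dot(model.output_weights[model.block_slice(j)], feats))
            for j, feats in cnn.iter_block_features(model, encoding, i)
        }
        yhat_full = sum(contribs.values())
        for j, s_ij in contribs.items():
            n_ij = encoding.total_ones(i, j)
            mat[j, i] = abs(targets[i] - (yhat_full - s_ij)) / n_ij
    return pd.DataFrame(
        mat,
        index=[p.id for p in model.layout.proteins],
        columns=[obs.sequence for obs in encoding.peptides],
    )


def layer_change_profile(
    model: CNNModel, encoding: SparseEncoding, protein_idx: int
) -> np.ndarray:
    """Mean absolute per-layer activation change in protein ``protein_idx``'s
    block between the present and masked input, averaged over its matching
    peptides.  Masking zeroes the whole block, so the change at each layer is
    the mean |activation| itself.  Diagnostics only.
    """
    config = model.config
    prot = model.layout.proteins[protein_idx]
    padded = config.padded_length(len(prot.sequence))
    sums = np.zeros(config.n_layers)
    counts = np.zeros(config.n_layers)
    n_used = 0
    for i in range(encoding.n_peptides):
        if protein_idx not in encoding.positions[i]:
            continue
        n_used += 1
        track = cnn._make_track(encoding, i, protein_idx, padded)
        a = track[:, None]
        for l, (W, pw) in enumerate(zip(model.conv_weights, config.pool_windows)):
            h = cnn.conv_forward(a, W)
            sums[l] += np.abs(h).sum()
            counts[l] += h.size
            a = cnn.pool_forward(h, pw)
    if n_used == 0:
        return np.zeros(config.n_layers)
    with np.errstate(invalid="ignore"):
        return np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
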