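"""Input parsing and sparse binary positional encoding.

A peptide profile (peptide sequence + identification probability) is matched
against a candidate proteome.  Each peptide's network input is, per candidate
protein, a binary track with ones at every residue covered by a full
occurrence of the peptide and zeros elsewhere.  Because almost all tracks are
all-zero, the encoding is stored sparsely as position sets per
(peptide, protein) pair.

Coordinates are 0-based and half-open throughout the public API.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_MOD_BRACKET = re.compile(r"\[[^\]]*\]|\([^)]*\)|\{[^}]*\}")
_NON_UPPER = re.compile(r"[^A-Z]")


class DataError(ValueError):
    """Malformed or inconsistent input data."""


@dataclass(frozen=True)
class ProteinRecord:
    """A candidate protein: accession and uppercase amino-acid sequence."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise DataError(f"protein {self.id!r} has an empty sequence")

    @property
    def nonstandard_residues(self) -> set[str]:
        return set(self.sequence) - set(AMINO_ACIDS)


@dataclass(frozen=True)
class PeptideObservation:
    """An observed peptide with its identification probability in [0, 1]."""

    sequence: str
    probability: float

    def __post_init__(self) -> None:
        if not self.sequence:
            raise DataError("peptide observation with empty sequence")
        if not 0.0 <= self.probability <= 1.0:
            raise DataError(
                f"peptide {self.sequence!r}: probability {self.probability} "
                "outside [0, 1]"
            )


@dataclass
class ProteomeLayout:
    """Ordered candidate proteins plus their feature-block geometry.

    ``block_offsets``/``block_lengths`` describe where each protein's
    penultimate features live in the concatenated representation; they are
    filled in when a model is built (they depend on the network windows) and
    are ``None`` before that.
    """

    proteins: list[ProteinRecord]
    block_offsets: np.ndarray | None = None
    block_lengths: np.ndarray | None = None
    index_by_id: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.index_by_id = {p.id: i for i, p in enumerate(self.proteins)}
        if len(self.index_by_id) != len(self.proteins):
            raise DataError("duplicate protein ids in layout")

    def __len__(self) -> int:
        return len(self.proteins)

    @property
    def total_width(self) -> int:
        if self.block_offsets is None:
            raise ValueError("feature blocks not computed yet (build a model first)")
        return int(self.block_offsets[-1] + self.block_lengths[-1])


class SparseEncoding:
    """Per-peptide, per-protein match-position sets (the sparse model input).

    ``positions[i]`` maps protein index ``j`` to a sorted int array of 0-based
    residue indices covered by occurrences of peptide ``i`` in protein ``j``.
    Only nonempty entries are stored.
    """

    def __init__(
        self,
        layout: ProteomeLayout,
        peptides: list[PeptideObservation],
        positions: list[dict[int, np.ndarray]],
    ):
        self.layout = layout
        self.peptides = peptides
        self.positions = positions

    @property
    def n_peptides(self) -> int:
        return len(self.peptides)

    def total_ones(self, peptide_idx: int, protein_idx: int) -> int:
        return len(self.positions[peptide_idx].get(protein_idx, ()))

    def matching_proteins(self, peptide_idx: int) -> list[int]:
        return sorted(self.positions[peptide_idx])

    def proteins_matched_by(self, peptide_idx: int) -> int:
        return len(self.positions[peptide_idx])

    @property
    def sparsity(self) -> float:
        """Fraction of zeros in the dense equivalent of the input matrix."""
        total = self.n_peptides * sum(len(p.sequence) for p in self.layout.proteins)
        ones = sum(
            len(pos) for per_pep in self.positions for pos in per_pep.values()
        )
        return 1.0 - ones / total

    def dense_row(self, peptide_idx: int, min_length: int = 0) -> list[np.ndarray]:
        """Materialize peptide ``peptide_idx`` as one float vector per protein.

        Each protein's track is right-padded with zeros to ``min_length`` if
        shorter (padding is absorbed by the bias-free network).
        """
        row = []
        for j, prot in enumerate(self.layout.proteins):
            track = np.zeros(max(len(prot.sequence), min_length))
            pos = self.positions[peptide_idx].get(j)
            if pos is not None:
                track[pos] = 1.0
            row.append(track)
        return row


def read_fasta(path) -> list[ProteinRecord]:
    """Read a protein FASTA file.

    The id is the header token before the first whitespace; sequences are
    uppercased with gap (``-``) and stop (``*``) characters stripped.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = str(entry.seq).upper().replace("-", "").replace("*", "").replace(" ", "")
        if entry.id in seen:
            raise DataError(f"duplicate FASTA header {entry.id!r} in {path}")
        if not seq:
            raise DataError(f"empty sequence for FASTA header {entry.id!r} in {path}")
        seen.add(entry.id)
        records.append(ProteinRecord(entry.id, seq))
    if not records:
        raise DataError(f"no FASTA records found in {path}")
    for rec in records:
        bad = rec.nonstandard_residues
        if bad:
            logger.warning(
                "protein %s contains nonstandard residues %s", rec.id, sorted(bad)
            )
    return records


def strip_modifications(peptide: str) -> str:
    """Reduce a search-engine peptide string to its plain uppercase sequence.

    Bracketed mass tags (``M[147]``), parenthesized or braced annotations and
    separator characters are removed; lowercase letters (the common notation
    for modified residues) are restored to their plain uppercase form.
    """
    return _NON_UPPER.sub("", _MOD_BRACKET.sub("", peptide).upper())


def read_peptide_profile(path) -> list[PeptideObservation]:
    """Read a two-column TSV of (peptide, probability).

    ``#`` comment lines are ignored; a header row is auto-detected by a
    non-numeric second column.  Modification annotations are stripped before
    deduplication; duplicate peptides collapse to the maximum probability
    (the best spectrum match for that peptide).
    """
    df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype=str)
    if df.shape[1] < 2:
        raise DataError(f"{path}: expected at least two tab-separated columns")
    first_row = df.iloc[0]
    try:
        float(first_row.iloc[1])
    except (TypeError, ValueError):
        df = df.iloc[1:].reset_index(drop=True)
    if df.empty:
        raise DataError(f"{path}: no peptide rows")

    best: dict[str, float] = {}
    order: list[str] = []
    for row_num, (pep_raw, prob_raw) in enumerate(
        zip(df.iloc[:, 0], df.iloc[:, 1]), start=1
    ):
        try:
            prob = float(prob_raw)
        except (TypeError, ValueError) as exc:
            raise DataError(f"{path} row {row_num}: bad probability {prob_raw!r}") from exc
        if not 0.0 <= prob <= 1.0:
            raise DataError(
                f"{path} row {row_num}: probability {prob} outside [0, 1]"
            )
        pep = strip_modifications(str(pep_raw).strip())
        if not pep:
            raise DataError(f"{path} row {row_num}: empty peptide sequence")
        if pep not in best:
            order.append(pep)
            best[pep] = prob
        else:
            best[pep] = max(best[pep], prob)
    return [PeptideObservation(p, best[p]) for p in order]


def match_positions(peptide: str, protein: str) -> np.ndarray:
    """0-based residue indices of ``protein`` covered by full occurrences of
    ``peptide`` (union over overlapping occurrences); empty array if none."""
    if not peptide or not protein:
        raise ValueError("peptide and protein must be nonempty")
    covered: set[int] = set()
    start = protein.find(peptide)
    while start != -1:
        covered.update(range(start, start + len(peptide)))
        start = protein.find(peptide, start + 1)
    return np.array(sorted(covered), dtype=np.intp)


def select_candidates(
    db: list[ProteinRecord], peptides: list[PeptideObservation]
) -> tuple[ProteomeLayout, list[PeptideObservation]]:
    """Keep proteins with at least one observed-peptide occurrence.

    Returns the candidate layout (database order preserved) and the peptides
    that match no candidate (logged, not silently dropped).
    """
    if not db or not peptides:
        raise DataError("empty protein database or peptide profile")
    pep_seqs = [p.sequence for p in peptides]
    candidates = [
        prot for prot in db if any(s in prot.sequence for s in pep_seqs)
    ]
    if not candidates:
        raise DataError("zero candidate proteins: no peptide matches the database")
    cand_seqs = [c.sequence for c in candidates]
    unmatched = [
        obs for obs in peptides if not any(obs.sequence in s for s in cand_seqs)
    ]
    if unmatched:
        logger.warning(
            "%d peptide(s) match no candidate protein and are excluded from "
            "training: %s",
            len(unmatched),
            ", ".join(o.sequence for o in unmatched[:10]),
        )
    logger.info(
        "candidate selection: %d/%d proteins, %d/%d peptides matched",
        len(candidates), len(db), len(peptides) - len(unmatched), len(peptides),
    )
    return ProteomeLayout(candidates), unmatched


def build_encoding(
    layout: ProteomeLayout, peptides: list[PeptideObservation]
) -> SparseEncoding:
    """Build the sparse positional encoding for all (peptide, protein) pairs.

    Every peptide must occur in at least one candidate (guaranteed after
    :func:`select_candidates`); peptides are expected already deduplicated.
    """
    positions: list[dict[int, np.ndarray]] = []
    for obs in peptides:
        per_protein: dict[int, np.ndarray] = {}
        for j, prot in enumerate(layout.proteins):
            pos = match_positions(obs.sequence, prot.sequence)
            if len(pos):
                per_protein[j] = pos
        if not per_protein:
            raise DataError(
                f"peptide {obs.sequence!r} matches no candidate protein; "
                "run select_candidates first"
            )
        positions.append(per_protein)
    enc = SparseEncoding(layout, list(peptides), positions)
    logger.info("encoding sparsity: %.4f", enc.sparsity)
    return enc
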