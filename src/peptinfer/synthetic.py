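"""Synthetic proteomes and peptide profiles with the structure the method
assumes.

The generator emulates what a shotgun-proteomics search pipeline hands to a
protein-inference tool: a candidate proteome of amino-acid strings, a hidden
subset of truly present proteins, deterministic tryptic digestion (cleavage
after K/R unless followed by P), incomplete peptide detection, identification
probabilities concentrated near 1 for true peptides, a low-probability noise
floor of spurious peptides drawn from absent proteins, and degenerate
peptides shared between proteins via copied tryptic segments.

It does not model spectra (masses, charges, intensities), missed cleavages,
or protein abundance.
"""

from __future__ import annotations

import json
import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .io_encoding import (
    AMINO_ACIDS,
    DataError,
    PeptideObservation,
    ProteinRecord,
)


class ConfigError(ValueError):
    """Invalid simulation configuration."""


# Residue sampling frequencies, roughly vertebrate-proteome-like; K+R about
# 11% so random sequences digest into tryptic peptides of realistic length.
RESIDUE_FREQS = {
    "A": 0.074, "C": 0.025, "D": 0.054, "E": 0.068, "F": 0.047,
    "G": 0.074, "H": 0.026, "I": 0.068, "K": 0.058, "L": 0.099,
    "M": 0.025, "N": 0.045, "P": 0.039, "Q": 0.034, "R": 0.052,
    "S": 0.057, "T": 0.051, "V": 0.073, "W": 0.013, "Y": 0.033,
}


def tryptic_digest(sequence: str) -> list[str]:
    """Deterministic tryptic digestion.

    Cleaves after every K or R that is not immediately followed by P.  The
    concatenation of the returned peptides equals the input.
    """
    if not sequence:
        raise ValueError("cannot digest an empty sequence")
    peptides = []
    start = 0
    for i, aa in enumerate(sequence):
        if aa in "KR" and (i + 1 == len(sequence) or sequence[i + 1] != "P"):
            peptides.append(sequence[start : i + 1])
            start = i + 1
    if start < len(sequence):
        peptides.append(sequence[start:])
    return peptides


@dataclass
class SimulationConfig:
    """Generative conditions for a synthetic inference problem.

    Detected true peptides draw probabilities from a Beta(a, b) scaled into
    [low, high] concentrated near 1; noise peptides from absent proteins draw
    from a low-probability scaled Beta.
    """

    n_proteins: int = 60
    length_range: tuple[int, int] = (200, 400)
    n_true: int = 20
    detection_prob: float = 0.5
    true_prob_params: tuple[float, float, float, float] = (0.9, 1.0, 5.0, 1.0)
    noise_peptides: int = 30
    noise_prob_params: tuple[float, float, float, float] = (0.0, 0.3, 1.0, 3.0)
    degenerate_fraction: float = 0.15
    min_peptide_length: int = 6
    resample_budget: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_true > self.n_proteins:
            raise ConfigError(
                f"n_true ({self.n_true}) exceeds n_proteins ({self.n_proteins})"
            )
        if self.n_true < 1 or self.n_proteins < 1:
            raise ConfigError("n_true and n_proteins must be positive")
        lo, hi = self.length_range
        if lo < self.min_peptide_length or hi < lo:
            raise ConfigError(
                "length_range must satisfy min >= min_peptide_length and "
                "max >= min"
            )
        if not 0.0 <= self.detection_prob <= 1.0:
            raise ConfigError("detection_prob must be in [0, 1]")
        if not 0.0 <= self.degenerate_fraction <= 1.0:
            raise ConfigError("degenerate_fraction must be in [0, 1]")
        for name, (plo, phi, a, b) in (
            ("true_prob_params", self.true_prob_params),
            ("noise_prob_params", self.noise_prob_params),
        ):
            if not (0.0 <= plo <= phi <= 1.0) or a <= 0 or b <= 0:
                raise ConfigError(f"invalid {name}: {(plo, phi, a, b)}")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SyntheticSample:
    """A generated inference problem with its ground truth."""

    proteome: list[ProteinRecord]
    true_ids: set[str]
    observations: list[PeptideObservation]
    # per observed peptide sequence: ids of the proteins it was drawn from
    provenance: dict[str, set[str]] = field(default_factory=dict)


def _scaled_beta(rng: np.random.Generator, params, size: int) -> np.ndarray:
    lo, hi, a, b = params
    return lo + (hi - lo) * rng.beta(a, b, size=size)


def generate_proteome(config: SimulationConfig) -> list[ProteinRecord]:
    """Seeded i.i.d.-residue proteome with optional shared-segment injection.

    ``degenerate_fraction`` of the proteins are designated in consecutive
    (donor, recipient) pairs: one internal tryptic peptide of the donor
    replaces one of the recipient's, so the two proteins share a degenerate
    peptide while remaining valid tryptic structures.
    """
    rng = np.random.default_rng([config.seed, 10])
    alphabet = np.array(list(RESIDUE_FREQS))
    probs = np.array(list(RESIDUE_FREQS.values()))
    probs = probs / probs.sum()
    lo, hi = config.length_range
    proteins = []
    for idx in range(config.n_proteins):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(alphabet, size=length, p=probs))
        proteins.append(ProteinRecord(f"SYN{idx:04d}", seq))

    n_deg = int(round(config.degenerate_fraction * config.n_proteins))
    designated = list(rng.permutation(config.n_proteins)[:n_deg])
    for d in range(0, len(designated) - 1, 2):
        donor_i, recip_i = int(designated[d]), int(designated[d + 1])
        donor_peps = tryptic_digest(proteins[donor_i].sequence)
        recip_peps = tryptic_digest(proteins[recip_i].sequence)
        # internal peptides keep the digest structure intact when transplanted:
        # they end in K/R and must not start with P (which would suppress the
        # upstream cleavage at the new location)
        donor_ok = [
            p for p in donor_peps[:-1]
            if len(p) >= config.min_peptide_length and not p.startswith("P")
        ]
        recip_ok = [
            k for k, p in enumerate(recip_peps[:-1]) if not p.startswith("P")
        ]
        if not donor_ok or not recip_ok:
            continue
        pep = donor_ok[int(rng.integers(len(donor_ok)))]
        slot = recip_ok[int(rng.integers(len(recip_ok)))]
        recip_peps[slot] = pep
        proteins[recip_i] = ProteinRecord(
            proteins[recip_i].id, "".join(recip_peps)
        )
    return proteins


def simulate_profile(
    proteome: list[ProteinRecord], config: SimulationConfig
) -> SyntheticSample:
    """Draw the hidden protein set and its noisy peptide profile.

    ``n_true`` proteins are chosen uniformly.  Each of their tryptic peptides
    of length >= ``min_peptide_length`` is detected independently with
    ``detection_prob``; detection of a protein's peptides is resampled (up to
    ``resample_budget`` times) until the protein contributes at least one
    peptide.  ``noise_peptides`` spurious peptides come from absent proteins
    with low probabilities.  Duplicate peptide sequences collapse to their
    maximum probability.
    """
    if config.detection_prob == 0.0:
        raise ConfigError("detection_prob = 0 yields no observations")
    rng = np.random.default_rng([config.seed, 20])
    true_idx = rng.choice(len(proteome), size=config.n_true, replace=False)
    true_idx = sorted(int(i) for i in true_idx)
    true_ids = {proteome[i].id for i in true_idx}

    best: dict[str, float] = {}
    provenance: dict[str, set[str]] = {}
    order: list[str] = []

    def record(seq: str, prob: float, source: str) -> None:
        if seq not in best:
            order.append(seq)
            best[seq] = prob
        else:
            best[seq] = max(best[seq], prob)
        provenance.setdefault(seq, set()).add(source)

    for i in true_idx:
        prot = proteome[i]
        peps = [
            p for p in tryptic_digest(prot.sequence)
            if len(p) >= config.min_peptide_length
        ]
        if not peps:
            raise DataError(
                f"true protein {prot.id} has no tryptic peptide of length >= "
                f"{config.min_peptide_length}; increase length_range or lower "
                "min_peptide_length"
            )
        detected: list[str] = []
        for _ in range(config.resample_budget):
            detected = [p for p in peps if rng.random() < config.detection_prob]
            if detected:
                break
        if not detected:
            raise DataError(
                f"true protein {prot.id} detected no peptide within the "
                "resample budget; raise detection_prob"
            )
        probs = _scaled_beta(rng, config.true_prob_params, len(detected))
        for pep, prob in zip(detected, probs):
            record(pep, float(prob), prot.id)

    absent = [p for p in proteome if p.id not in true_ids]
    noise_pool = [
        (pep, prot.id)
        for prot in absent
        for pep in tryptic_digest(prot.sequence)
        if len(pep) >= config.min_peptide_length
    ]
    if config.noise_peptides > 0 and noise_pool:
        n_noise = min(config.noise_peptides, len(noise_pool))
        chosen = rng.choice(len(noise_pool), size=n_noise, replace=False)
        probs = _scaled_beta(rng, config.noise_prob_params, n_noise)
        for sel, prob in zip(chosen, probs):
            pep, src = noise_pool[int(sel)]
            record(pep, float(prob), src)

    observations = [PeptideObservation(s, best[s]) for s in order]
    return SyntheticSample(proteome, true_ids, observations, provenance)


def generate_sample(config: SimulationConfig) -> SyntheticSample:
    """Convenience: proteome + profile in one call."""
    return simulate_profile(generate_proteome(config), config)


def write_sample(sample: SyntheticSample, config: SimulationConfig, out_dir) -> dict[str, str]:
    """Write proteome FASTA, profile TSV, truth TSV and a manifest JSON.

    Returns the mapping of logical name to file path.  Outputs are
    byte-identical for identical configs (the manifest records the config and
    content digests)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "proteome": out / "proteome.fasta",
        "profile": out / "profile.tsv",
        "truth": out / "truth.tsv",
        "manifest": out / "manifest.json",
    }
    with open(paths["proteome"], "w") as fh:
        for prot in sample.proteome:
            fh.write(f">{prot.id}\n")
            for k in range(0, len(prot.sequence), 60):
                fh.write(prot.sequence[k : k + 60] + "\n")
    with open(paths["profile"], "w") as fh:
        fh.write("peptide\tprobability\n")
        for obs in sample.observations:
            fh.write(f"{obs.sequence}\t{obs.probability:.6f}\n")
    with open(paths["truth"], "w") as fh:
        fh.write("protein\n")
        for pid in sorted(sample.true_ids):
            fh.write(pid + "\n")
    digests = {
        name: hashlib.sha256(paths[name].read_bytes()).hexdigest()
        for name in ("proteome", "profile", "truth")
    }
    manifest = {"config": config.to_dict(), "digests": digests}
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, default=list)
        fh.write("\n")
    return {k: str(v) for k, v in paths.items()}
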