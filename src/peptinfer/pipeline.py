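"""End-to-end orchestration: candidates -> encoding -> train -> score -> rank."""

from __future__ import annotations

import logging

from . import cnn, io_encoding, scoring, training
from .cnn import CNNConfig
from .io_encoding import PeptideObservation, ProteinRecord

logger = logging.getLogger(__name__)


def infer_proteins(
    db: list[ProteinRecord],
    observations: list[PeptideObservation],
    config: CNNConfig,
    naive_scoring: bool = False,
):
    """Run the full inference pipeline on an in-memory problem.

    Returns (ranked scores, training trace, model, encoding).
    """
    layout, unmatched = io_encoding.select_candidates(db, observations)
    matched = [o for o in observations if o not in unmatched]
    encoding = io_encoding.build_encoding(layout, matched)
    model = cnn.build_model(config, layout, seed=config.seed)
    model, trace = training.train(model, encoding, config=config)
    if naive_scoring:
        scores = scoring.score_proteins_naive(model, encoding)
    else:
        scores = scoring.score_proteins_shared(model, encoding)
    ranked = scoring.rank_proteins(scores)
    return ranked, trace, model, encoding
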