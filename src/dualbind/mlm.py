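"""Masked-language-model data preparation for antibody sequences.

Desk-scale operators from the pLM adaptation recipe: per-position Bernoulli
masking at a configurable rate with CDR-prioritized boosting (CDR positions
masked at ``min(1, rate * cdr_boost)``, non-CDR positions at a compensating
probability so the overall expected masked fraction stays exactly at
``rate``), the masked-token cross-entropy loss, and sequence-length-aware
batch stratification.

By default every selected position is replaced by the mask token; the
BERT-style 80/10/10 mask/replace/keep scheme is available behind a flag.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .alphabet import (
    CANONICAL_AA,
    MASK_TOKEN_ID,
    MLM_VOCAB,
    residue_token_id,
)
from .sequences import ProteinSequence


class MaskingConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class MaskedSequence:
    """One masked sequence: token ids with masks applied, the masked position
    set M, and the original tokens at those positions (recoverable)."""

    sequence_id: str
    token_ids: np.ndarray          # (L,) int
    mask_positions: np.ndarray     # sorted indices in M
    original_tokens: np.ndarray    # original ids at mask_positions

    def unmask(self) -> np.ndarray:
        restored = self.token_ids.copy()
        restored[self.mask_positions] = self.original_tokens
        return restored


@dataclass(frozen=True)
class MaskedBatch:
    entries: tuple[MaskedSequence, ...]

    @property
    def mask_count(self) -> int:
        return sum(len(e.mask_positions) for e in self.entries)


def _cdr_indicator(seq: ProteinSequence) -> np.ndarray:
    ind = np.zeros(len(seq), dtype=bool)
    if seq.cdr_spans:
        for start, end in seq.cdr_spans:
            ind[start:end] = True
    return ind


def masking_probabilities(seq: ProteinSequence, rate: float, cdr_boost: float) -> np.ndarray:
    """Per-position masking probabilities with exact rate compensation.

    CDR positions get ``p_cdr = min(1, rate * cdr_boost)``; the non-CDR
    probability solves ``(p_cdr * n_cdr + p_out * n_out) / L = rate``.  An
    infeasible combination (p_out < 0) raises with the feasible boost bound.
    """
    if not (0.0 <= rate <= 1.0):
        raise MaskingConfigurationError(f"rate must be in [0, 1], got {rate}")
    if cdr_boost < 1.0:
        raise MaskingConfigurationError(f"cdr_boost must be >= 1, got {cdr_boost}")
    length = len(seq)
    in_cdr = _cdr_indicator(seq)
    n_cdr = int(in_cdr.sum())
    probs = np.full(length, rate)
    if n_cdr == 0 or cdr_boost == 1.0 or rate == 0.0:
        return probs
    if n_cdr == length:
        # no non-CDR positions to compensate with; the budget forces rate
        return probs
    p_cdr = min(1.0, rate * cdr_boost)
    p_out = (rate * length - p_cdr * n_cdr) / (length - n_cdr)
    if p_out < 0.0:
        feasible = (rate * length) / (rate * n_cdr) if rate > 0 else np.inf
        raise MaskingConfigurationError(
            f"cdr_boost={cdr_boost} infeasible for rate={rate} with {n_cdr}/{length} "
            f"CDR positions; maximum feasible boost is {feasible:.4g}"
        )
    probs[in_cdr] = p_cdr
    probs[~in_cdr] = p_out
    return probs


def mask_sequence(
    seq: ProteinSequence,
    rate: float = 0.15,
    cdr_boost: float = 1.0,
    rng: np.random.Generator | int | None = None,
    bert_style: bool = False,
) -> MaskedSequence:
    """Mask a sequence position-wise; see :func:`masking_probabilities`.

    With ``bert_style`` the selected positions are 80% mask-token, 10% random
    residue, 10% kept; otherwise all selected positions become the mask token.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    probs = masking_probabilities(seq, rate, cdr_boost)
    tokens = np.array([residue_token_id(c) for c in seq.residues], dtype=np.int64)
    selected = rng.random(len(seq)) < probs
    positions = np.flatnonzero(selected)
    originals = tokens[positions]
    masked = tokens.copy()
    if bert_style and len(positions):
        action = rng.random(len(positions))
        mask_it = action < 0.8
        replace_it = (action >= 0.8) & (action < 0.9)
        masked[positions[mask_it]] = MASK_TOKEN_ID
        masked[positions[replace_it]] = rng.integers(0, len(CANONICAL_AA), replace_it.sum())
    else:
        masked[positions] = MASK_TOKEN_ID
    return MaskedSequence(
        sequence_id=seq.id, token_ids=masked, mask_positions=positions,
        original_tokens=originals,
    )


def mlm_loss(predicted_distributions: np.ndarray, masked: MaskedSequence | MaskedBatch) -> float:
    """Cross-entropy over masked positions: ``-sum_{i in M} log P(x_i | context)``.

    ``predicted_distributions`` holds one categorical distribution per masked
    position (rows sum to 1 within 1e-6) over the residue vocabulary.
    """
    entries = masked.entries if isinstance(masked, MaskedBatch) else (masked,)
    dists = np.asarray(predicted_distributions, dtype=np.float64)
    truth = np.concatenate([e.original_tokens for e in entries]) if entries else np.empty(0, int)
    if dists.ndim != 2 or dists.shape[0] != truth.size:
        raise ValueError(
            f"expected {truth.size} distributions, got shape {dists.shape}"
        )
    sums = dists.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > 1e-6):
        bad = int(np.argmax(np.abs(sums - 1.0)))
        raise ValueError(f"distribution at row {bad} sums to {sums[bad]:.8f}, not 1")
    p_true = dists[np.arange(truth.size), truth]
    if np.any(p_true <= 0):
        return float(np.inf)
    return float(-np.sum(np.log(p_true)))


def stratify_batches(
    records: Sequence[ProteinSequence],
    batch_size: int,
    rng: np.random.Generator | int | None = None,
    n_buckets: int = 4,
) -> list[list[ProteinSequence]]:
    """Length-stratified batching: records are bucketed by length quantile,
    shuffled within buckets, and each batch is drawn from a single bucket.
    Every record appears in exactly one batch per epoch."""
    if batch_size < 1:
        raise MaskingConfigurationError("batch_size must be >= 1")
    if not records:
        return []
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    lengths = np.array([len(r) for r in records])
    edges = np.unique(np.quantile(lengths, np.linspace(0, 1, n_buckets + 1)[1:-1]))
    bucket_of = np.searchsorted(edges, lengths, side="left")
    batches: list[list[ProteinSequence]] = []
    for b in np.unique(bucket_of):
        idx = np.flatnonzero(bucket_of == b)
        rng.shuffle(idx)
        for s in range(0, len(idx), batch_size):
            batches.append([records[i] for i in idx[s : s + batch_size]])
    order = rng.permutation(len(batches))
    return [batches[i] for i in order]


def dump_masked_batch(batch: MaskedBatch, path: str | Path) -> None:
    """Write a JSON-lines inspection dump, one record per sequence."""
    with open(path, "w") as fh:
        for e in batch.entries:
            fh.write(json.dumps({
                "id": e.sequence_id,
                "tokens": [MLM_VOCAB[t] for t in e.token_ids],
                "mask_positions": e.mask_positions.tolist(),
                "original": [MLM_VOCAB[t] for t in e.original_tokens],
            }) + "\n")
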