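"""Embedding-provider contract, deterministic mock provider, and on-disk cache.

A provider turns a residue string into an ``L x D`` matrix of per-residue
context vectors (the role a protein language model plays in the full method).
The mock provider is a pure deterministic function of the residue string: each
row is a pseudo-random vector seeded by the residue letter together with a
small window of neighbours, so local context influences the embedding without
any learned weights.  This is enough for the interaction module to have
recoverable signal in tests while remaining bit-reproducible everywhere.

The cache stores matrices in an HDF5 container keyed by sequence hash, with
the provider name/version/dimension recorded so a stale or mismatched cache is
detected rather than silently recomputed.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Protocol, runtime_checkable

import h5py
import numpy as np

from .alphabet import CANONICAL_AA, EXTENDED_AA
from .sequences import ProteinSequence, SequenceValidationError


class CacheIntegrityError(RuntimeError):
    """Raised when an embedding cache is corrupt or inconsistent with the provider."""


@runtime_checkable
class EmbeddingProvider(Protocol):
    """Contract abstracting the residue-embedding model.

    Tokenization (special tokens, chain delimiters) is the adapter's business;
    the contract only promises an ``L x dim`` float matrix per residue string,
    deterministic for a fixed provider instance.
    """

    name: str
    version: str
    dim: int

    def embed_residues(self, residues: str) -> np.ndarray: ...


@dataclass(frozen=True)
class MockEmbeddingProvider:
    """Deterministic hash-seeded embedding provider for tests and desk runs.

    Row ``j`` is the sum of a unit-weight vector seeded by the residue letter
    at ``j`` and a ``context_scale``-weighted vector seeded by the window of
    ``window`` neighbours on each side (sequence boundaries padded with
    sentinels).  The letter component keeps residue identity decodable from
    the embedding (as it is from a real language model), while the window
    component makes local context matter.  Identical local contexts map to
    identical rows regardless of record id or batch order.  Nonstandard
    letters (X, B, Z, U, O) are collapsed to a single unknown letter before
    hashing, giving them a dedicated embedding.
    """

    dim: int = 32
    window: int = 1
    context_scale: float = 0.15
    version: str = "1"
    name: str = "mock"

    def _context(self, residues: str, j: int) -> str:
        padded = "^" * self.window + residues + "$" * self.window
        return padded[j : j + 2 * self.window + 1]

    def _hash_vector(self, key: str) -> np.ndarray:
        digest = hashlib.blake2b(
            f"{self.name}|{self.version}|{self.window}|{key}".encode(),
            digest_size=8,
        ).digest()
        seed = int.from_bytes(digest, "little")
        return np.random.default_rng(seed).standard_normal(self.dim)

    def embed_residues(self, residues: str) -> np.ndarray:
        clean = "".join("X" if c in EXTENDED_AA else c for c in residues)
        rows = np.empty((len(clean), self.dim), dtype=np.float64)
        row_cache: dict[str, np.ndarray] = {}
        letter_cache: dict[str, np.ndarray] = {}
        for j in range(len(clean)):
            ctx = self._context(clean, j)
            row = row_cache.get(ctx)
            if row is None:
                letter_vec = letter_cache.get(clean[j])
                if letter_vec is None:
                    letter_vec = self._hash_vector(f"letter:{clean[j]}")
                    letter_cache[clean[j]] = letter_vec
                row = letter_vec + self.context_scale * self._hash_vector(f"window:{ctx}")
                row_cache[ctx] = row
            rows[j] = row
        return rows


def embed(seq: ProteinSequence, provider: EmbeddingProvider) -> np.ndarray:
    """Embed a validated sequence into an ``L x D`` residue matrix.

    Deterministic for a fixed provider and sequence; the record id never
    influences the result.
    """
    valid = set(CANONICAL_AA) | EXTENDED_AA
    for pos, letter in enumerate(seq.residues):
        if letter not in valid:
            raise SequenceValidationError(
                f"sequence {seq.id!r}: unknown residue {letter!r} at position {pos}"
            )
    values = np.asarray(provider.embed_residues(seq.residues), dtype=np.float64)
    if values.shape != (len(seq), provider.dim):
        raise ValueError(
            f"provider returned shape {values.shape}, expected {(len(seq), provider.dim)}"
        )
    if not np.all(np.isfinite(values)):
        raise ValueError(f"sequence {seq.id!r}: non-finite embedding values")
    return values


def sequence_hash(residues: str) -> str:
    return hashlib.sha1(residues.encode()).hexdigest()


def cache_embeddings(
    records: Iterable[ProteinSequence],
    provider: EmbeddingProvider,
    path: str | Path,
) -> None:
    """Write embeddings for ``records`` to an HDF5 cache at ``path``.

    The cache is keyed by (provider name, provider version, sequence hash);
    round-trip reads are bit-identical to fresh computation.
    """
    with h5py.File(path, "w") as fh:
        meta = fh.create_group("meta")
        meta.attrs["provider_name"] = provider.name
        meta.attrs["provider_version"] = provider.version
        meta.attrs["dim"] = provider.dim
        grp = fh.create_group("embeddings")
        for seq in records:
            key = sequence_hash(seq.residues)
            if key not in grp:
                grp.create_dataset(key, data=embed(seq, provider))


def load_cached_embedding(
    path: str | Path, seq: ProteinSequence, provider: EmbeddingProvider
) -> np.ndarray:
    """Read one sequence's matrix from a cache, verifying provider compatibility."""
    with h5py.File(path, "r") as fh:
        if "meta" not in fh or "embeddings" not in fh:
            raise CacheIntegrityError(f"{path}: missing cache structure")
        meta = fh["meta"].attrs
        if (
            meta.get("provider_name") != provider.name
            or meta.get("provider_version") != provider.version
            or int(meta.get("dim", -1)) != provider.dim
        ):
            raise CacheIntegrityError(
                f"{path}: cache written by provider "
                f"{meta.get('provider_name')}/v{meta.get('provider_version')} "
                f"(D={meta.get('dim')}), requested {provider.name}/v{provider.version} "
                f"(D={provider.dim})"
            )
        key = sequence_hash(seq.residues)
        if key not in fh["embeddings"]:
            raise CacheIntegrityError(f"{path}: no cached embedding for sequence {seq.id!r}")
        values = np.asarray(fh["embeddings"][key], dtype=np.float64)
    if values.shape[0] != len(seq):
        raise CacheIntegrityError(
            f"{path}: cached length {values.shape[0]} != sequence length {len(seq)}"
        )
    return values
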