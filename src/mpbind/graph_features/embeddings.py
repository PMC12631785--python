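"""Residue-embedding providers.

The model consumes two 1024-dim per-residue embedding blocks that, in
production, come from external protein language models. The package never
downloads model weights: real embeddings are read from precomputed HDF5/NPZ
files keyed by sequence hash, and a deterministic stub provider stands in
for them everywhere in the test suite.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np

EMBEDDING_DIM = 1024

_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")


class EmbeddingError(ValueError):
    pass


def sequence_key(sequence: str) -> str:
    """Stable lookup key for a sequence (sha256 hex digest)."""
    return hashlib.sha256(sequence.encode("ascii")).hexdigest()


class StubEmbedder:
    """Deterministic pseudo-random embeddings with local context.

    Each residue's vector is a seeded draw from the tuple
    (provider name, window of letters centred on the residue), so identical
    sequences give identical matrices and a single-letter change only
    perturbs rows within the context window.
    """

    dim = EMBEDDING_DIM

    def __init__(self, name: str, window: int = 2, dim: int = EMBEDDING_DIM):
        self.name = name
        self.window = window
        self.dim = dim

    def embed(self, sequence: str) -> np.ndarray:
        if not set(sequence) <= _ALPHABET:
            bad = sorted(set(sequence) - _ALPHABET)
            raise EmbeddingError(f"sequence contains non-standard letters {bad}")
        L = len(sequence)
        padded = "^" * self.window + sequence + "$" * self.window
        out = np.empty((L, self.dim))
        for i in range(L):
            ctx = padded[i:i + 2 * self.window + 1]
            digest = hashlib.blake2b(
                f"{self.name}|{ctx}".encode("ascii"), digest_size=8
            ).digest()
            seed = int.from_bytes(digest, "little")
            out[i] = np.random.default_rng(seed).standard_normal(self.dim)
        return out


class PrecomputedEmbeddings:
    """Adapter reading per-sequence embedding matrices from HDF5 or NPZ.

    Files are keyed by :func:`sequence_key`; shape must be (L, 1024).
    """

    dim = EMBEDDING_DIM

    def __init__(self, name: str, path: str | Path):
        self.name = name
        self.path = Path(path)
        if not self.path.exists():
            raise EmbeddingError(f"embedding file not found: {self.path}")

    def embed(self, sequence: str) -> np.ndarray:
        key = sequence_key(sequence)
        if self.path.suffix in {".npz", ".npy"}:
            with np.load(self.path) as archive:
                if key not in archive:
                    raise EmbeddingError(f"{self.path}: no embedding for key {key}")
                mat = np.asarray(archive[key], dtype=float)
        else:
            import h5py

            with h5py.File(self.path, "r") as fh:
                if key not in fh:
                    raise EmbeddingError(f"{self.path}: no embedding for key {key}")
                mat = np.asarray(fh[key], dtype=float)
        if mat.shape != (len(sequence), self.dim):
            raise EmbeddingError(
                f"{self.path}[{key}]: shape {mat.shape} != ({len(sequence)}, {self.dim})"
            )
        return mat
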