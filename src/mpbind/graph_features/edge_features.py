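"""Geometric edge feature blocks and their assembly into the E x 450 matrix.

Per directed edge (i, j): 400 RBF-encoded virtual-atom cross distances,
30 frame-local unit directions (15 per direction), the 4-component relative
orientation quaternion of the two backbone frames, and a 16-dim sinusoidal
encoding of the signed index offset. All blocks are invariant under global
rigid motions of the input coordinates.
"""

from __future__ import annotations

from itertools import product

import numpy as np

from .common import (
    VIRTUAL_ATOM_ORDER,
    FeaturizationError,
    LocalFrame,
    rbf_encode,
    rotation_to_quaternion,
)

DISTANCE_DIM = 400   # 25 virtual-atom pairs x 16 RBFs
DIRECTION_DIM = 30   # 2 x 5 unit vectors in the local frames
ORIENTATION_DIM = 4
POSITIONAL_DIM = 16  # 8 frequencies x (sin, cos)
EDGE_FEATURE_DIM = DISTANCE_DIM + DIRECTION_DIM + ORIENTATION_DIM + POSITIONAL_DIM

_CROSS_PAIRS = tuple(product(VIRTUAL_ATOM_ORDER, VIRTUAL_ATOM_ORDER))  # 25 ordered


def edge_distances(res_i, res_j) -> np.ndarray:
    """400-vector: RBF encodings of the 25 virtual-atom cross distances."""
    va_i, va_j = res_i.virtual_atoms, res_j.virtual_atoms
    if va_i is None or va_j is None:
        raise FeaturizationError("edge endpoints must have virtual atoms")
    dists = np.array([np.linalg.norm(va_i[a] - va_j[b]) for a, b in _CROSS_PAIRS])
    return rbf_encode(dists).ravel()


def _frame_local_directions(origin: np.ndarray, basis: np.ndarray,
                            targets: np.ndarray) -> np.ndarray:
    vecs = targets - origin
    norms = np.linalg.norm(vecs, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        units = np.where(norms > 1e-9, vecs / norms, 0.0)
    return (basis.T @ units.T).T  # express in the local frame


def edge_directions(res_i, res_j, frame_i: LocalFrame, frame_j: LocalFrame) -> np.ndarray:
    """30-vector: unit directions CA_i -> virtual atoms of j in frame i,
    plus the symmetric CA_j -> virtual atoms of i block in frame j."""
    va_i, va_j = res_i.virtual_atoms, res_j.virtual_atoms
    if va_i is None or va_j is None:
        raise FeaturizationError("edge endpoints must have virtual atoms")
    q_j = np.stack([va_j[k] for k in VIRTUAL_ATOM_ORDER])
    q_i = np.stack([va_i[k] for k in VIRTUAL_ATOM_ORDER])
    fwd = _frame_local_directions(frame_i.origin, frame_i.basis, q_j)
    bwd = _frame_local_directions(frame_j.origin, frame_j.basis, q_i)
    return np.concatenate([fwd.ravel(), bwd.ravel()])


def edge_orientation(frame_i: LocalFrame, frame_j: LocalFrame) -> np.ndarray:
    """Unit quaternion (w >= 0) of the relative rotation basis_i^T basis_j."""
    frame_i.validate()
    frame_j.validate()
    return rotation_to_quaternion(frame_i.basis.T @ frame_j.basis)


def positional_embedding(i: int, j: int, dim: int = POSITIONAL_DIM) -> np.ndarray:
    """Sinusoidal encoding of the signed offset j - i: [sin x8 | cos x8]."""
    n_freq = dim // 2
    d = float(j - i)
    k = np.arange(n_freq)
    angle = d / (10000.0 ** (2.0 * k / dim))
    return np.concatenate([np.sin(angle), np.cos(angle)])


def assemble_edge_features(edges: np.ndarray, chain, frames: list[LocalFrame]) -> np.ndarray:
    """(E, 450) matrix for the directed edge list, blocks in fixed order
    [distances | directions | orientation | positional]."""
    residues = chain.residues
    out = np.empty((len(edges), EDGE_FEATURE_DIM))
    for k, (i, j) in enumerate(edges):
        parts = (
            edge_distances(residues[i], residues[j]),
            edge_directions(residues[i], residues[j], frames[i], frames[j]),
            edge_orientation(frames[i], frames[j]),
            positional_embedding(i, j),
        )
        row = np.concatenate(parts)
        if row.shape[0] != EDGE_FEATURE_DIM:
            raise FeaturizationError(
                f"edge feature width {row.shape[0]} != {EDGE_FEATURE_DIM}"
            )
        out[k] = row
    return out
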